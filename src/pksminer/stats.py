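"""Catalogue-level descriptive statistics: discovery time series and
doubling time, type/phylum distributions, orphan fraction, histograms."""

from __future__ import annotations

import datetime as _dt
import logging
import math
from typing import Optional, Sequence

import numpy as np

from .records import Catalog, PKS_TYPES

logger = logging.getLogger(__name__)


def discovery_timeseries(
    catalog: Catalog,
    cutoff: Optional[_dt.date] = None,
) -> tuple[dict[int, int], dict[int, int]]:
    """Per-year incremental and cumulative counts of catalogued clusters.

    Clusters deposited after ``cutoff`` (e.g. a mid-year census date)
    are excluded; undated clusters are excluded with a warning. Returns
    (incremental, cumulative); cumulative covers every year between the
    first and last deposit.
    """
    dated = []
    undated = []
    for c in catalog.clusters:
        if c.deposit_date is None:
            undated.append(c.cluster_id)
        elif cutoff is None or c.deposit_date <= cutoff:
            dated.append(c)
    if undated:
        logger.warning("excluding %d undated clusters: %s", len(undated), undated)
    if not dated:
        return {}, {}
    incremental: dict[int, int] = {}
    for c in dated:
        incremental[c.deposit_date.year] = incremental.get(c.deposit_date.year, 0) + 1
    years = range(min(incremental), max(incremental) + 1)
    cumulative: dict[int, int] = {}
    total = 0
    for y in years:
        total += incremental.get(y, 0)
        cumulative[y] = total
    return incremental, cumulative


def doubling_time(
    cumulative: dict[int, int],
    min_fraction: float = 0.025,
) -> tuple[float, float]:
    """Exponential-growth doubling time from a cumulative yearly series.

    Fits ln(cumulative) on year by ordinary least squares and returns
    (doubling time in years = ln 2 / slope, R² of the fit). Years whose
    cumulative count is below ``min_fraction`` of the final total are
    excluded: with a handful of early deposits the log-counts are
    dominated by Poisson noise and bias the slope, so the fit is
    restricted to the established exponential regime. Requires >= 3
    usable points and overall growth.
    """
    if cumulative:
        floor = max(1, min_fraction * max(cumulative.values()))
    else:
        floor = 1
    pts = [(y, n) for y, n in sorted(cumulative.items()) if n >= floor]
    if len(pts) < 3:
        raise ValueError("need at least 3 nonzero cumulative points")
    years = np.array([p[0] for p in pts], dtype=float)
    logn = np.log([p[1] for p in pts])
    slope, intercept = np.polyfit(years, logn, 1)
    if slope <= 0:
        raise ValueError("cumulative series does not grow; no doubling time")
    fitted = slope * years + intercept
    ss_res = float(np.sum((logn - fitted) ** 2))
    ss_tot = float(np.sum((logn - logn.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return math.log(2) / slope, r2


def type_distribution(catalog: Catalog) -> dict[str, int]:
    """Counts over the seven assembly-line categories (zero-filled)."""
    counts = {t: 0 for t in PKS_TYPES}
    for c in catalog.clusters:
        key = c.pks_type if c.pks_type in counts else "other hybrid"
        counts[key] += 1
    return counts


def orphan_fraction(catalog: Catalog) -> dict[str, float]:
    """Percent of clusters with characterized products, and the orphan
    complement."""
    if len(catalog) == 0:
        raise ValueError("empty catalogue")
    known = sum(1 for c in catalog.clusters if c.known_product)
    total = len(catalog)
    pct_known = 100.0 * known / total
    return {
        "n_total": total,
        "n_known": known,
        "percent_known": pct_known,
        "percent_orphan": 100.0 - pct_known,
    }


def histograms(
    catalog: Catalog,
    metric: str,
    bin_width: Optional[float] = None,
    bin_start: Optional[float] = None,
) -> dict[tuple[float, float], int]:
    """Binned counts of a per-cluster metric.

    Metrics: length_aa (summed protein residues), ks_count, gc_content
    (percent over cluster nucleotides). Bins are half-open
    [lo, lo+width) covering the data range exactly; the last bin closes
    at the maximum. Counts sum to the catalogue size.
    """
    extractors = {
        "length_aa": lambda c: float(c.length_aa),
        "ks_count": lambda c: float(c.ks_count),
        "gc_content": lambda c: c.gc_content,
    }
    if metric not in extractors:
        raise ValueError(f"unknown metric {metric!r}")
    values = np.array([extractors[metric](c) for c in catalog.clusters])
    if values.size == 0:
        return {}
    defaults = {"length_aa": 1000.0, "ks_count": 1.0, "gc_content": 2.0}
    width = bin_width if bin_width is not None else defaults[metric]
    lo = bin_start if bin_start is not None else math.floor(values.min() / width) * width
    n_bins = max(1, math.ceil((values.max() - lo) / width))
    if lo + n_bins * width <= values.max():
        n_bins += 1
    edges = lo + width * np.arange(n_bins + 1)
    counts, _ = np.histogram(values, bins=edges)
    return {
        (float(edges[i]), float(edges[i + 1])): int(counts[i])
        for i in range(n_bins)
        if counts[i] > 0
    }


def phylum_distribution(catalog: Catalog) -> dict[str, dict]:
    """Counts and percents per phylum; missing labels pool into
    "unclassified". Percents sum to 100."""
    counts: dict[str, int] = {}
    for c in catalog.clusters:
        key = c.phylum or "unclassified"
        counts[key] = counts.get(key, 0) + 1
    total = sum(counts.values())
    return {
        k: {"count": n, "percent": 100.0 * n / total if total else 0.0}
        for k, n in sorted(counts.items())
    }
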