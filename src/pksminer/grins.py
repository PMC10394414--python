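"""GRINS detection: genetic repeats of intense nucleotide skews.

A GRINS is a ~1 kbp segment of a PKS cluster that (i) shows GC and TA
skews both above 25 % in magnitude, with consistent sign across the
segment, and (ii) has high DNA identity (>= 90 % by default) to another
non-overlapping region of the same cluster. Skews are computed over a
sliding window; repeats are found by exact k-mer seeding followed by
chaining and edlib-based identity refinement.
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from typing import Optional, Sequence

import edlib
import pandas as pd

from .records import Catalog, GRINSParams, GRINSRegion, PKSCluster


def gc_skew(window: str) -> float:
    """(G − C) / (G + C); 0 for windows with no G or C (degenerate)."""
    if not window:
        raise ValueError("empty window")
    g = window.count("G")
    c = window.count("C")
    if g + c == 0:
        return 0.0
    return (g - c) / (g + c)


def ta_skew(window: str) -> float:
    """(T − A) / (T + A); 0 for windows with no T or A (degenerate)."""
    if not window:
        raise ValueError("empty window")
    t = window.count("T")
    a = window.count("A")
    if t + a == 0:
        return 0.0
    return (t - a) / (t + a)


def skew_profile(seq: str, window: int = 150, step: int = 30) -> list[tuple[int, float, float]]:
    """(start, gc_skew, ta_skew) for windows at 0, step, 2·step, …"""
    if window > len(seq):
        warnings.warn("window longer than sequence: empty profile")
        return []
    profile = []
    for start in range(0, len(seq) - window + 1, step):
        w = seq[start : start + window]
        profile.append((start, gc_skew(w), ta_skew(w)))
    return profile


def find_skewed_regions(
    profile: Sequence[tuple[int, float, float]],
    min_abs_skew: float = 0.25,
    min_region_len: int = 700,
    window: int = 150,
) -> list[tuple[int, int, float, float]]:
    """Maximal runs of consecutive windows with |gc| and |ta| skews both
    >= ``min_abs_skew`` and constant sign per skew; runs spanning at
    least ``min_region_len`` are reported with window-union coordinates
    and mean skews."""
    regions = []
    run: list[tuple[int, float, float]] = []

    def _flush():
        if not run:
            return
        start = run[0][0]
        end = run[-1][0] + window
        if end - start >= min_region_len:
            mean_gc = sum(r[1] for r in run) / len(run)
            mean_ta = sum(r[2] for r in run) / len(run)
            regions.append((start, end, mean_gc, mean_ta))

    for start, gc, ta in profile:
        ok = abs(gc) >= min_abs_skew and abs(ta) >= min_abs_skew
        if ok and run:
            same_sign = (gc > 0) == (run[-1][1] > 0) and (ta > 0) == (run[-1][2] > 0)
            if not same_sign:
                _flush()
                run = []
        if ok:
            run.append((start, gc, ta))
        else:
            _flush()
            run = []
    _flush()
    return regions


def _alignment_identity(s1: str, s2: str) -> float:
    """Global alignment identity (matches / alignment columns) via edlib."""
    res = edlib.align(s1, s2, task="path")
    cigar = res["cigar"]
    columns = 0
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            columns += int(num)
            num = ""
    if columns == 0:
        return 0.0
    return 100.0 * (columns - res["editDistance"]) / columns


def find_internal_repeats(
    cluster_seq: str,
    min_repeat_identity: float = 90.0,
    min_repeat_len: int = 700,
    k: int = 16,
    max_kmer_occ: int = 64,
    chain_gap: int = 200,
    diag_band: int = 20,
) -> list[tuple[tuple[int, int], tuple[int, int], float]]:
    """Non-overlapping duplicated region pairs within one sequence.

    Exact ``k``-mer seed matches off the self-diagonal are chained when
    close in position (<= chain_gap) and diagonal (<= diag_band); chains
    spanning >= ``min_repeat_len`` on both copies are scored by global
    alignment identity and filtered. Returns ((s1, e1), (s2, e2),
    identity) with s1 < s2.
    """
    n = len(cluster_seq)
    if n < 2 * min_repeat_len:
        return []
    positions: dict[str, list[int]] = defaultdict(list)
    for i in range(n - k + 1):
        positions[cluster_seq[i : i + k]].append(i)

    matches = []  # (i, j) seed pairs, i < j
    for pos_list in positions.values():
        if len(pos_list) < 2 or len(pos_list) > max_kmer_occ:
            continue
        for a in range(len(pos_list)):
            for b in range(a + 1, len(pos_list)):
                matches.append((pos_list[a], pos_list[b]))
    if not matches:
        return []
    matches.sort()

    # greedy chaining by (position, diagonal) proximity
    chains: list[list[tuple[int, int]]] = []
    for i, j in matches:
        d = j - i
        placed = False
        for chain in chains:
            li, lj = chain[-1]
            if 0 <= i - li <= chain_gap and abs(d - (lj - li)) <= diag_band and j > lj - k:
                chain.append((i, j))
                placed = True
                break
        if not placed:
            chains.append([(i, j)])

    candidates = []
    for chain in chains:
        i0, j0 = chain[0]
        i1, j1 = chain[-1]
        s1, e1 = i0, i1 + k
        s2, e2 = j0, j1 + k
        if e1 - s1 < min_repeat_len or e2 - s2 < min_repeat_len:
            continue
        if e1 > s2:  # copies overlap: trim to non-overlapping prefix
            e1 = min(e1, s2)
            e2 = min(e2, s2 + (e1 - s1))
            if e1 - s1 < min_repeat_len:
                continue
        identity = _alignment_identity(cluster_seq[s1:e1], cluster_seq[s2:e2])
        if identity >= min_repeat_identity:
            candidates.append(((s1, e1), (s2, e2), round(identity, 4)))

    # drop candidates contained in a longer accepted pair
    candidates.sort(key=lambda c: -(c[0][1] - c[0][0]))
    accepted: list[tuple[tuple[int, int], tuple[int, int], float]] = []
    for cand in candidates:
        (s1, e1), (s2, e2), _ = cand
        contained = False
        for (t1, u1), (t2, u2), _i in accepted:
            if s1 >= t1 - k and e1 <= u1 + k and s2 >= t2 - k and e2 <= u2 + k:
                contained = True
                break
        if not contained:
            accepted.append(cand)
    accepted.sort()
    return accepted


def _reciprocal_overlap(a: tuple[int, int], b: tuple[int, int]) -> float:
    ov = min(a[1], b[1]) - max(a[0], b[0])
    if ov <= 0:
        return 0.0
    return min(ov / (a[1] - a[0]), ov / (b[1] - b[0]))


def detect_grins(cluster: PKSCluster, params: Optional[GRINSParams] = None) -> list[GRINSRegion]:
    """GRINS = skewed region overlapping (>= 50 % reciprocally) one side
    of an internal repeat pair; both copies of a duplicated skewed
    segment are reported."""
    params = params or GRINSParams()
    if not cluster.sequence:
        raise ValueError(f"cluster {cluster.cluster_id!r} carries no sequence")
    profile = skew_profile(cluster.sequence, params.window, params.step)
    skewed = find_skewed_regions(
        profile, params.min_abs_skew, params.min_region_len, params.window
    )
    if not skewed:
        return []
    repeats = find_internal_repeats(
        cluster.sequence, params.min_repeat_identity, params.min_repeat_len
    )
    out: list[GRINSRegion] = []
    for start, end, mean_gc, mean_ta in skewed:
        best = None  # (overlap, partner, identity)
        for (s1, e1), (s2, e2), identity in repeats:
            for side, partner in (((s1, e1), (s2, e2)), ((s2, e2), (s1, e1))):
                ov = _reciprocal_overlap((start, end), side)
                if ov >= 0.5 and (best is None or ov > best[0]):
                    best = (ov, partner, identity)
        if best is None:
            continue
        _, (ps, pe), identity = best
        if start < pe and ps < end:
            continue  # degenerate: skew run bleeding into the partner copy
        out.append(
            GRINSRegion(
                cluster_id=cluster.cluster_id,
                start=start,
                end=end,
                mean_gc_skew=mean_gc,
                mean_ta_skew=mean_ta,
                partner_start=ps,
                partner_end=pe,
                repeat_identity=identity,
            )
        )
    out.sort(key=lambda r: r.start)
    return out


def grins_prevalence(
    catalog: Catalog,
    detections: dict[str, list[GRINSRegion]],
    group_by: str = "pks_type",
) -> pd.DataFrame:
    """Per-group prevalence table: (group, n_clusters, n_with_grins, percent)."""
    if group_by not in ("pks_type", "phylum"):
        raise ValueError(f"unknown group_by key {group_by!r}")
    rows: dict[str, list[int]] = {}
    for c in catalog.clusters:
        key = getattr(c, group_by) or "unclassified"
        n, w = rows.get(key, (0, 0))
        has = bool(detections.get(c.cluster_id))
        rows[key] = [n + 1, w + (1 if has else 0)]
    table = pd.DataFrame(
        [
            {
                group_by: key,
                "n_clusters": n,
                "n_with_grins": w,
                "percent": 100.0 * w / n,
            }
            for key, (n, w) in sorted(rows.items())
        ]
    )
    return table


def write_grins_bed(detections: dict[str, list[GRINSRegion]], path) -> None:
    """Cluster-relative BED (0-based half-open) of GRINS regions."""
    with open(path, "w") as fh:
        for cid in sorted(detections):
            for i, r in enumerate(detections[cid]):
                fh.write(f"{cid}\t{r.start}\t{r.end}\tGRINS_{i}\n")


def write_grins_table(detections: dict[str, list[GRINSRegion]], path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "cluster_id\tstart\tend\tmean_gc_skew\tmean_ta_skew\t"
            "partner_start\tpartner_end\trepeat_identity\n"
        )
        for cid in sorted(detections):
            for r in detections[cid]:
                fh.write(
                    f"{cid}\t{r.start}\t{r.end}\t{r.mean_gc_skew:.4f}\t"
                    f"{r.mean_ta_skew:.4f}\t{r.partner_start}\t{r.partner_end}\t"
                    f"{r.repeat_identity:.2f}\n"
                )
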