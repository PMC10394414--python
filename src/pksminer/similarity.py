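"""Customized pairwise similarity between assembly lines, redundancy
pruning, rediscovery and novelty statistics.

The score is amino-acid-level and local-alignment-based, so it does not
depend on gene annotation and copes with the repetitive module
structure of assembly-line PKSs. For clusters ``a`` and ``b`` the
directed score is

    S(a→b) = 100 · Σ_p  id_frac(p) · covered(p)  /  Σ_p |p|

over the proteins ``p`` of ``a``, where the best local alignment of
``p`` against any protein of ``b`` (BLOSUM62, gap open 11 / extend 1)
contributes its identity fraction weighted by the number of residues of
``p`` it covers; each query residue counts at most once. The reported
similarity is the mean of S(a→b) and S(b→a), hence symmetric and 100 on
identical clusters.
"""

from __future__ import annotations

import datetime as _dt
from typing import Mapping, Sequence

import numpy as np

from Bio.Align import PairwiseAligner, substitution_matrices

from .records import Catalog, PKSCluster, SimilarityMatrix


def _make_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner(mode="local")
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


def _pair_alignments(a: PKSCluster, b: PKSCluster, aligner: PairwiseAligner):
    """Best local alignment per (protein of a, protein of b) pair.

    Yields (i, j, score, id_frac, covered_a, covered_b). The alignment
    is symmetric in the two sequences, so one pass serves both directed
    scores.
    """
    for i, p in enumerate(a.proteins):
        for j, q in enumerate(b.proteins):
            alignments = aligner.align(p.sequence, q.sequence)
            if len(alignments) == 0:
                continue
            aln = alignments[0]
            if aln.score <= 0:
                continue
            counts = aln.counts()
            columns = counts.identities + counts.mismatches + counts.gaps
            if columns == 0:
                continue
            id_frac = counts.identities / columns
            covered_a = sum(int(e - s) for s, e in aln.aligned[0])
            covered_b = sum(int(e - s) for s, e in aln.aligned[1])
            yield i, j, float(aln.score), id_frac, covered_a, covered_b


def pairwise_similarity(a: PKSCluster, b: PKSCluster) -> float:
    """Symmetric percent similarity in [0, 100] (see module docstring)."""
    if not a.proteins or not b.proteins:
        raise ValueError("both clusters must carry protein sequences")
    total_a = sum(len(p) for p in a.proteins)
    total_b = sum(len(p) for p in b.proteins)
    if total_a == 0 or total_b == 0:
        raise ValueError("cluster has no protein residues")
    if a.cluster_id == b.cluster_id and [p.sequence for p in a.proteins] == [
        p.sequence for p in b.proteins
    ]:
        return 100.0
    aligner = _make_aligner()
    best_a: dict[int, tuple[float, float]] = {}  # i -> (score, id_frac*covered_a)
    best_b: dict[int, tuple[float, float]] = {}
    for i, j, score, id_frac, cov_a, cov_b in _pair_alignments(a, b, aligner):
        if score > best_a.get(i, (-np.inf, 0.0))[0]:
            best_a[i] = (score, id_frac * cov_a)
        if score > best_b.get(j, (-np.inf, 0.0))[0]:
            best_b[j] = (score, id_frac * cov_b)
    s_ab = 100.0 * sum(v for _s, v in best_a.values()) / total_a
    s_ba = 100.0 * sum(v for _s, v in best_b.values()) / total_b
    return min(100.0, 0.5 * (s_ab + s_ba))


def similarity_matrix(clusters: Sequence[PKSCluster]) -> SimilarityMatrix:
    """Score every unordered pair once; symmetric matrix, diagonal 100."""
    if not clusters:
        raise ValueError("need at least one cluster")
    n = len(clusters)
    scores = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            s = pairwise_similarity(clusters[i], clusters[j])
            scores[i, j] = scores[j, i] = s
    return SimilarityMatrix([c.cluster_id for c in clusters], scores)


def _retention_key(c: PKSCluster):
    # earliest deposit date, then longest protein length, then smallest id
    date = c.deposit_date or _dt.date.max
    return (date, -c.length_aa, c.cluster_id)


def remove_redundant(
    clusters: Sequence[PKSCluster],
    matrix: SimilarityMatrix,
    threshold: float = 90.0,
) -> Catalog:
    """Greedy redundancy pruning at ``threshold`` percent similarity.

    Clusters are swept in priority order (earliest deposit date, longest
    protein complement, smallest id); a cluster is retained iff its
    similarity to every already-retained cluster is <= threshold,
    otherwise it maps to the first retained cluster exceeding it.
    """
    if not (0.0 < threshold < 100.0):
        raise ValueError("threshold must lie strictly between 0 and 100")
    missing = [c.cluster_id for c in clusters if c.cluster_id not in set(matrix.ids)]
    if missing:
        raise ValueError(f"matrix does not cover clusters: {missing}")
    retained: list[PKSCluster] = []
    removed: dict[str, str] = {}
    for c in sorted(clusters, key=_retention_key):
        rep = None
        for r in retained:
            if matrix.get(c.cluster_id, r.cluster_id) > threshold:
                rep = r.cluster_id
                break
        if rep is None:
            retained.append(c)
        else:
            removed[c.cluster_id] = rep
    order = {c.cluster_id: i for i, c in enumerate(clusters)}
    retained.sort(key=lambda c: order[c.cluster_id])
    sub = matrix.submatrix([c.cluster_id for c in retained])
    return Catalog(clusters=retained, removed=removed, similarity=sub)


def rediscovery_rate(
    clusters: Sequence[PKSCluster],
    matrix: SimilarityMatrix,
    threshold: float = 90.0,
) -> dict[int, float]:
    """Cumulative rediscovery percentage per calendar year.

    Clusters are processed in deposit-date order (ties by id); a cluster
    is a rediscovery iff its similarity to any earlier cluster exceeds
    ``threshold``. Returns {year: cumulative percent redundant among
    clusters deposited up to that year}.
    """
    undated = [c.cluster_id for c in clusters if c.deposit_date is None]
    if undated:
        raise ValueError(f"clusters missing deposit dates: {undated}")
    ordered = sorted(clusters, key=lambda c: (c.deposit_date, c.cluster_id))
    n_redundant = 0
    per_year: dict[int, float] = {}
    for i, c in enumerate(ordered):
        for prev in ordered[:i]:
            if matrix.get(c.cluster_id, prev.cluster_id) > threshold:
                n_redundant += 1
                break
        per_year[c.deposit_date.year] = 100.0 * n_redundant / (i + 1)
    return per_year


def nearest_characterized(
    orphans: Sequence[PKSCluster],
    knowns: Sequence[PKSCluster],
    matrix: SimilarityMatrix,
) -> dict[str, tuple[str, float]]:
    """Best characterized neighbour per orphan: orphan_id -> (known_id, score).
    Ties break toward the lexicographically smaller known id."""
    if not knowns:
        raise ValueError("no characterized clusters supplied")
    out: dict[str, tuple[str, float]] = {}
    known_ids = sorted(k.cluster_id for k in knowns)
    for o in orphans:
        best_id, best_score = None, -1.0
        for kid in known_ids:
            s = matrix.get(o.cluster_id, kid)
            if s > best_score:
                best_id, best_score = kid, s
        out[o.cluster_id] = (best_id, best_score)
    return out


def novelty_fraction(nearest_map: Mapping[str, tuple[str, float]], threshold: float = 50.0) -> float:
    """Percent of orphans whose best characterized neighbour scores
    strictly below ``threshold`` (exactly-at-threshold is not novel)."""
    if not nearest_map:
        raise ValueError("empty nearest-neighbour map")
    novel = sum(1 for _, score in nearest_map.values() if score < threshold)
    return 100.0 * novel / len(nearest_map)
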