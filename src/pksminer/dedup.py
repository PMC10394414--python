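"""Elimination of identical clusters prior to similarity scoring.

Two clusters from the same species collapse when one's nucleotide
sequence equals or contains the other's (either strand) or when their
domain-architecture signatures are identical. Collapsing is an
equivalence closure (union-find), so chains of nested sub-sequences
resolve to a single representative.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass
from typing import Sequence

from Bio.Seq import Seq

from .mining import _ordered_domains
from .records import PKSCluster


@dataclass(frozen=True)
class ArchitectureSignature:
    """Canonical per-protein domain-kind string, e.g. "KS-AT-ACP|KS-AT-KR-ACP-TE"."""

    signature: str

    def __str__(self) -> str:
        return self.signature


def architecture_signature(cluster: PKSCluster) -> ArchitectureSignature:
    """Canonical architecture string: proteins in genomic order joined by
    '|', each protein's domain kinds (by aa_start) joined by '-'.
    Invariant to annotation row order."""
    per_protein: dict[str, list] = {p.id: [] for p in cluster.proteins}
    for d in _ordered_domains(cluster):
        per_protein.setdefault(d.protein_id, []).append(d)
    parts = []
    for p in cluster.proteins:
        doms = sorted(per_protein.get(p.id, []), key=lambda d: d.aa_start)
        parts.append("-".join(d.kind for d in doms))
    return ArchitectureSignature("|".join(parts))


def is_sequence_redundant(a: PKSCluster, b: PKSCluster) -> bool:
    """True iff one cluster's nucleotide sequence equals, or is an exact
    substring of, the other's — on either strand."""
    if not a.sequence or not b.sequence:
        raise ValueError("both clusters must carry nucleotide sequence")
    short, long_ = (a.sequence, b.sequence) if len(a.sequence) <= len(b.sequence) else (b.sequence, a.sequence)
    if short in long_:
        return True
    return str(Seq(short).reverse_complement()) in long_


class _UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[ra] = rb


def _priority_key(c: PKSCluster):
    # representative priority: longest span, earliest deposit, smallest id
    span = c.end - c.start
    date = c.deposit_date or _dt.date.max
    return (-span, date, c.cluster_id)


def dedup_identical(clusters: Sequence[PKSCluster]) -> tuple[list[PKSCluster], dict[str, str]]:
    """Collapse identical clusters within each species.

    Within a species group (exact case-insensitive name match; clusters
    without species never collapse), clusters equal by
    :func:`is_sequence_redundant` or by architecture signature are
    merged transitively; one representative per equivalence class is
    retained (longest span, then earliest deposit date, then smallest
    id). Returns (retained, removed_id -> representative_id).
    """
    by_id = {c.cluster_id: c for c in clusters}
    if len(by_id) != len(clusters):
        raise ValueError("duplicate cluster ids")
    groups: dict[str, list[PKSCluster]] = {}
    singletons: list[PKSCluster] = []
    for c in clusters:
        if c.species:
            groups.setdefault(c.species.strip().lower(), []).append(c)
        else:
            singletons.append(c)

    retained: list[PKSCluster] = list(singletons)
    removed: dict[str, str] = {}
    for members in groups.values():
        uf = _UnionFind([c.cluster_id for c in members])
        sigs = {c.cluster_id: architecture_signature(c) for c in members}
        for i, a in enumerate(members):
            for b in members[i + 1 :]:
                if sigs[a.cluster_id] == sigs[b.cluster_id] or (
                    a.sequence and b.sequence and is_sequence_redundant(a, b)
                ):
                    uf.union(a.cluster_id, b.cluster_id)
        classes: dict[str, list[PKSCluster]] = {}
        for c in members:
            classes.setdefault(uf.find(c.cluster_id), []).append(c)
        for group in classes.values():
            group.sort(key=_priority_key)
            rep = group[0]
            retained.append(rep)
            for other in group[1:]:
                removed[other.cluster_id] = rep.cluster_id

    order = {c.cluster_id: i for i, c in enumerate(clusters)}
    retained.sort(key=lambda c: order[c.cluster_id])
    return retained, removed
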