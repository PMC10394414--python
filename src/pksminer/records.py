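"""Domain types shared by every pipeline stage.

All coordinates are 0-based half-open on the plus strand. External
dialects (BLAST tabular, domain TSVs, GenBank) are converted at the I/O
boundary, never downstream.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

DNA_ALPHABET = frozenset("ACGTN")

#: Amino-acid alphabet accepted for protein records (standard 20 + X).
PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX*")

#: The seven assembly-line categories used for classification.
PKS_TYPES = (
    "cis-AT PKS",
    "cis-AT PKS-NRPS hybrid",
    "trans-AT PKS",
    "trans-AT PKS-NRPS hybrid",
    "mixed cis/trans PKS",
    "mixed cis/trans hybrid",
    "other hybrid",
)

#: Recognised module-domain vocabulary; anything else maps to "other".
DOMAIN_KINDS = ("KS", "AT", "ACP", "KR", "DH", "ER", "MT", "TE", "C", "A", "PCP", "other")

#: Domain kinds whose presence marks NRPS (hybrid) character.
NRPS_KINDS = frozenset({"C", "A", "PCP"})


class ParseError(ValueError):
    """Raised when an external file violates its format contract."""


@dataclass
class NucleotideRecord:
    """A nucleotide entry (genome, contig or gene record) to be mined."""

    id: str
    sequence: str
    species: Optional[str] = None
    phylum: Optional[str] = None
    deposit_date: Optional[_dt.date] = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"record {self.id!r}: empty sequence")
        bad = set(self.sequence) - DNA_ALPHABET
        if bad:
            raise ValueError(
                f"record {self.id!r}: illegal DNA characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class ProteinRecord:
    """An amino-acid sequence, optionally located on its source record."""

    id: str
    sequence: str
    record_id: Optional[str] = None
    start: Optional[int] = None  # nucleotide coords of the CDS, half-open
    end: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"protein {self.id!r}: empty sequence")
        bad = set(self.sequence) - PROTEIN_ALPHABET
        if bad:
            raise ValueError(
                f"protein {self.id!r}: illegal amino-acid characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class KSHit:
    """A raw ketosynthase similarity hit on a nucleotide record."""

    record_id: str
    start: int
    end: int
    strand: str = "+"
    frame: int = 0
    percent_identity: float = 0.0
    score: float = 0.0

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"KSHit on {self.record_id!r}: bad span {self.start}..{self.end}")
        if self.strand not in "+-":
            raise ValueError(f"KSHit strand must be '+' or '-', got {self.strand!r}")
        if self.frame not in (0, 1, 2):
            raise ValueError(f"KSHit frame must be 0/1/2, got {self.frame!r}")
        if not (0.0 <= self.percent_identity <= 100.0):
            raise ValueError("percent_identity outside [0, 100]")


@dataclass
class KSDomain:
    """A discrete KS locus: the union of hits closer than ``min_separation``."""

    record_id: str
    start: int
    end: int
    n_source_hits: int = 1

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"KSDomain on {self.record_id!r}: bad span")
        if self.n_source_hits < 1:
            raise ValueError("n_source_hits must be >= 1")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class DomainAnnotation:
    """One annotated catalytic domain within a protein (aa coordinates)."""

    protein_id: str
    kind: str
    aa_start: int
    aa_end: int

    def __post_init__(self) -> None:
        if self.kind not in DOMAIN_KINDS:
            raise ValueError(f"unknown domain kind {self.kind!r}")
        if not (0 <= self.aa_start < self.aa_end):
            raise ValueError(
                f"domain {self.kind} on {self.protein_id!r}: bad aa span "
                f"{self.aa_start}..{self.aa_end}"
            )


@dataclass
class PKSCluster:
    """A candidate (or catalogued) assembly line.

    ``proteins`` are ordered by genomic position; ``domains`` reference
    proteins by id. ``sequence`` is the nucleotide span of the cluster.
    """

    cluster_id: str
    record_id: str
    start: int
    end: int
    ks_domains: list[KSDomain] = field(default_factory=list)
    proteins: list[ProteinRecord] = field(default_factory=list)
    domains: list[DomainAnnotation] = field(default_factory=list)
    sequence: Optional[str] = None
    pks_type: Optional[str] = None
    species: Optional[str] = None
    phylum: Optional[str] = None
    deposit_date: Optional[_dt.date] = None
    known_product: bool = False

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"cluster {self.cluster_id!r}: bad span")
        if self.pks_type is not None and self.pks_type not in PKS_TYPES:
            raise ValueError(f"unknown pks_type {self.pks_type!r}")
        known_proteins = {p.id for p in self.proteins}
        for d in self.domains:
            if d.protein_id not in known_proteins:
                raise ValueError(
                    f"cluster {self.cluster_id!r}: domain references unknown "
                    f"protein {d.protein_id!r}"
                )

    @property
    def ks_count(self) -> int:
        return len(self.ks_domains)

    @property
    def length_aa(self) -> int:
        """Summed protein length in residues."""
        return sum(len(p) for p in self.proteins)

    @property
    def gc_content(self) -> float:
        """Percent G+C over the cluster nucleotide span."""
        if not self.sequence:
            raise ValueError(f"cluster {self.cluster_id!r} carries no sequence")
        s = self.sequence
        n = len(s)
        return 100.0 * (s.count("G") + s.count("C")) / n


@dataclass
class GRINSParams:
    """Sliding-window and repeat thresholds for GRINS detection."""

    window: int = 150
    step: int = 30
    min_abs_skew: float = 0.25
    min_region_len: int = 700
    target_region_len: int = 1000  # reporting only
    min_repeat_identity: float = 90.0
    min_repeat_len: int = 700

    def __post_init__(self) -> None:
        if self.window < self.step:
            raise ValueError("window must be >= step")
        if not (0.0 < self.min_abs_skew < 1.0):
            raise ValueError("min_abs_skew must lie in (0, 1)")
        if self.min_region_len <= 0 or self.min_repeat_len <= 0:
            raise ValueError("region/repeat lengths must be positive")


@dataclass
class MiningParams:
    """All tunable thresholds of the mining pipeline, with defaults from
    the published workflow (3 kbp KS separation, ≥3 KS within 20 kbp,
    90 % redundancy, 50 % network threshold)."""

    min_separation: int = 3000
    max_gap: int = 20000
    min_ks: int = 3
    redundancy_threshold: float = 90.0
    network_threshold: float = 50.0
    grins: GRINSParams = field(default_factory=GRINSParams)

    def __post_init__(self) -> None:
        for name in ("min_separation", "max_gap", "min_ks"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0 < self.network_threshold < self.redundancy_threshold <= 100):
            raise ValueError(
                "need 0 < network_threshold < redundancy_threshold <= 100"
            )


class SimilarityMatrix:
    """Symmetric percent-similarity scores between catalogued clusters."""

    def __init__(self, ids: list[str], scores: np.ndarray):
        scores = np.asarray(scores, dtype=float)
        n = len(ids)
        if scores.shape != (n, n):
            raise ValueError("score matrix shape does not match id list")
        if len(set(ids)) != n:
            raise ValueError("duplicate cluster ids")
        if not np.allclose(scores, scores.T, atol=1e-9):
            raise ValueError("score matrix is not symmetric")
        if not np.allclose(np.diag(scores), 100.0, atol=1e-9):
            raise ValueError("diagonal must be 100")
        if scores.min() < -1e-9 or scores.max() > 100 + 1e-9:
            raise ValueError("scores outside [0, 100]")
        self.ids = list(ids)
        self.scores = scores
        self._index = {c: i for i, c in enumerate(self.ids)}

    def __len__(self) -> int:
        return len(self.ids)

    def get(self, a: str, b: str) -> float:
        return float(self.scores[self._index[a], self._index[b]])

    def submatrix(self, ids: list[str]) -> "SimilarityMatrix":
        idx = [self._index[c] for c in ids]
        return SimilarityMatrix(list(ids), self.scores[np.ix_(idx, idx)])


@dataclass
class GRINSRegion:
    """A skewed, internally duplicated segment (cluster-relative coords)."""

    cluster_id: str
    start: int
    end: int
    mean_gc_skew: float
    mean_ta_skew: float
    partner_start: int
    partner_end: int
    repeat_identity: float

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError("bad region span")
        if not (0 <= self.partner_start < self.partner_end):
            raise ValueError("bad partner span")
        if self.start < self.partner_end and self.partner_start < self.end:
            raise ValueError("GRINS region overlaps its partner")
        for v in (self.mean_gc_skew, self.mean_ta_skew):
            if not (-1.0 <= v <= 1.0):
                raise ValueError("mean skew outside [-1, 1]")


@dataclass
class Catalog:
    """The non-redundant cluster set plus removal provenance."""

    clusters: list[PKSCluster]
    removed: dict[str, str] = field(default_factory=dict)
    similarity: Optional[SimilarityMatrix] = None

    def __post_init__(self) -> None:
        retained = {c.cluster_id for c in self.clusters}
        for removed_id, rep in self.removed.items():
            if rep not in retained:
                raise ValueError(
                    f"removed cluster {removed_id!r} maps to non-retained {rep!r}"
                )
            if removed_id in retained:
                raise ValueError(f"cluster {removed_id!r} both retained and removed")

    def __len__(self) -> int:
        return len(self.clusters)

    def __iter__(self):
        return iter(self.clusters)

    def get(self, cluster_id: str) -> PKSCluster:
        for c in self.clusters:
            if c.cluster_id == cluster_id:
                return c
        raise KeyError(cluster_id)


def parse_date(text: str) -> _dt.date:
    """Parse an ISO-8601 date; bare years map to July 1 (mid-year)."""
    text = text.strip()
    if not text:
        raise ValueError("empty date")
    if text.isdigit() and len(text) == 4:
        return _dt.date(int(text), 7, 1)
    return _dt.date.fromisoformat(text)
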