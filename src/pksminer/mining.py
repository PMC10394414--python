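"""KS-domain mining: six-frame scan, hit discretization, cluster calling,
and seven-way assembly-line classification.

The scan emulates a translated search (consensus KS protein vs a
nucleotide record) with affine-gap local alignment in all six reading
frames; hits closer than ``min_separation`` are merged into discrete KS
domains, and chains of at least ``min_ks`` domains with neighbour gaps
no larger than ``max_gap`` become candidate assembly lines.
"""

from __future__ import annotations

from typing import Optional, Sequence

from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Seq import Seq

from .records import (
    DomainAnnotation,
    KSDomain,
    KSHit,
    NRPS_KINDS,
    NucleotideRecord,
    PKSCluster,
)

#: Conventional protein-search scoring: BLOSUM62, gap open 11, extend 1.
GAP_OPEN = 11
GAP_EXTEND = 1

#: Default scan stringency (raw BLOSUM62 score and aligned residues);
#: conservative for a ~400-residue consensus query.
DEFAULT_MIN_SCORE = 200.0
DEFAULT_MIN_LEN_AA = 100


def _make_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner(mode="local")
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -GAP_OPEN
    aligner.extend_gap_score = -GAP_EXTEND
    return aligner


def _six_frames(seq: str) -> list[tuple[str, int, str]]:
    """(strand, frame, translation) for all six reading frames."""
    frames = []
    fwd = Seq(seq)
    rev = fwd.reverse_complement()
    for f in range(3):
        n = (len(seq) - f) // 3 * 3
        frames.append(("+", f, str(fwd[f : f + n].translate())))
        frames.append(("-", f, str(rev[f : f + n].translate())))
    return frames


def scan_ks(
    record: NucleotideRecord,
    consensus_ks: str,
    min_score: float = DEFAULT_MIN_SCORE,
    min_len_aa: int = DEFAULT_MIN_LEN_AA,
    max_hits_per_frame: int = 64,
) -> list[KSHit]:
    """Locate KS-like loci by aligning a consensus KS protein against all
    six reading frames of ``record``.

    Within a frame, successive non-overlapping local alignments are
    extracted by masking each accepted hit and re-aligning, until the
    score drops below ``min_score``. Hits are returned sorted by
    plus-strand start.
    """
    if not consensus_ks:
        raise ValueError("empty consensus KS sequence")
    if len(record) < 3:
        return []
    consensus = consensus_ks.upper()
    aligner = _make_aligner()
    L = len(record)
    hits: list[KSHit] = []
    for strand, frame, aa in _six_frames(record.sequence.replace("N", "X")):
        if len(aa) < min_len_aa:
            continue
        target = list(aa)
        for _ in range(max_hits_per_frame):
            alignments = aligner.align("".join(target), consensus)
            if len(alignments) == 0:
                break
            best = alignments[0]
            if best.score < min_score:
                break
            tstart = int(best.aligned[0][0][0])
            tend = int(best.aligned[0][-1][1])
            counts = best.counts()
            columns = counts.identities + counts.mismatches + counts.gaps
            pident = 100.0 * counts.identities / columns if columns else 0.0
            aligned_len = tend - tstart
            # mask regardless of acceptance so the loop advances
            for i in range(tstart, tend):
                target[i] = "*"
            if aligned_len < min_len_aa:
                continue
            if strand == "+":
                nt_start = frame + 3 * tstart
                nt_end = frame + 3 * tend
            else:
                nt_start = L - (frame + 3 * tend)
                nt_end = L - (frame + 3 * tstart)
            hits.append(
                KSHit(
                    record_id=record.id,
                    start=nt_start,
                    end=nt_end,
                    strand=strand,
                    frame=frame,
                    percent_identity=round(pident, 2),
                    score=float(best.score),
                )
            )
    hits.sort(key=lambda h: (h.start, h.end, h.strand))
    return hits


def discretize_hits(hits: Sequence[KSHit], min_separation: int = 3000) -> list[KSDomain]:
    """Merge KS hits into discrete KS domains.

    Hits whose inter-interval gap is <= ``min_separation`` are merged
    transitively (strand-agnostic); consecutive output domains are
    therefore separated by a gap strictly greater than ``min_separation``.
    """
    if not hits:
        return []
    record_ids = {h.record_id for h in hits}
    if len(record_ids) > 1:
        raise ValueError(f"hits span multiple records: {sorted(record_ids)}")
    record_id = hits[0].record_id
    ordered = sorted(hits, key=lambda h: (h.start, h.end))
    domains: list[KSDomain] = []
    cur_start, cur_end, n = ordered[0].start, ordered[0].end, 1
    for h in ordered[1:]:
        gap = h.start - cur_end
        if gap <= min_separation:
            cur_end = max(cur_end, h.end)
            n += 1
        else:
            domains.append(KSDomain(record_id, cur_start, cur_end, n))
            cur_start, cur_end, n = h.start, h.end, 1
    domains.append(KSDomain(record_id, cur_start, cur_end, n))
    return domains


def call_candidate_clusters(
    domains: Sequence[KSDomain],
    max_gap: int = 20000,
    min_ks: int = 3,
) -> list[tuple[str, int, int, list[KSDomain]]]:
    """Chain discrete KS domains into candidate assembly-line spans.

    Consecutive domains with gap <= ``max_gap`` (boundary inclusive) are
    chained; chains of at least ``min_ks`` domains are reported as
    (record_id, start, end, ks_domains).
    """
    if not domains:
        return []
    record_ids = {d.record_id for d in domains}
    if len(record_ids) > 1:
        raise ValueError(f"domains span multiple records: {sorted(record_ids)}")
    ordered = sorted(domains, key=lambda d: (d.start, d.end))
    clusters = []
    chain = [ordered[0]]
    for d in ordered[1:]:
        if d.start - chain[-1].end <= max_gap:
            chain.append(d)
        else:
            if len(chain) >= min_ks:
                clusters.append((chain[0].record_id, chain[0].start, chain[-1].end, list(chain)))
            chain = [d]
    if len(chain) >= min_ks:
        clusters.append((chain[0].record_id, chain[0].start, chain[-1].end, list(chain)))
    return clusters


def _ordered_domains(cluster: PKSCluster) -> list[DomainAnnotation]:
    """Cluster domains in genomic order: proteins by position, domains by aa_start."""
    order = {p.id: i for i, p in enumerate(cluster.proteins)}
    return sorted(
        cluster.domains,
        key=lambda d: (order.get(d.protein_id, len(order)), d.aa_start),
    )


def classify_cluster(cluster: PKSCluster) -> str:
    """Assign one of the seven assembly-line categories.

    Modules are delimited KS-to-next-KS over the genomically ordered
    domain list. A module owning an AT is cis-AT, otherwise trans-AT
    (relying on a stand-alone shared AT). Any C/A/PCP domain marks NRPS
    (hybrid) character. Clusters whose modules cannot be typed at all
    (no AT anywhere and no ACP) fall to "other hybrid".
    """
    ordered = _ordered_domains(cluster)
    kinds = [d.kind for d in ordered]
    if "KS" not in kinds:
        raise ValueError(f"cluster {cluster.cluster_id!r} has no KS domain annotation")
    is_hybrid = any(k in NRPS_KINDS for k in kinds)
    if "AT" not in kinds and "ACP" not in kinds:
        return "other hybrid"
    ks_positions = [i for i, k in enumerate(kinds) if k == "KS"]
    module_slices = [
        kinds[s:e]
        for s, e in zip(ks_positions, ks_positions[1:] + [len(kinds)])
    ]
    cis_flags = ["AT" in m for m in module_slices]
    if all(cis_flags):
        base = "cis"
    elif not any(cis_flags):
        base = "trans"
    else:
        base = "mixed"
    if base == "mixed":
        return "mixed cis/trans hybrid" if is_hybrid else "mixed cis/trans PKS"
    return f"{base}-AT PKS-NRPS hybrid" if is_hybrid else f"{base}-AT PKS"


def assemble_cluster(
    cluster_id: str,
    record: NucleotideRecord,
    span: tuple[int, int],
    ks_domains: Sequence[KSDomain],
    proteins: Sequence,
    domains: Sequence[DomainAnnotation],
    metadata: Optional[dict] = None,
    margin: int = 10000,
) -> PKSCluster:
    """Build a full PKSCluster for a called candidate span.

    Proteins within ``margin`` bp of the KS span are attached in genomic
    order together with their domain annotations — the called span
    covers only first-KS..last-KS, while cluster genes (terminal TE,
    downstream NRPS modules) extend up to a module length beyond it.
    The default margin is half the cluster-chaining gap, so two separate
    candidates can never absorb each other's core. The cluster boundary is
    then widened to whole CDSs, and the nucleotide slice and record
    metadata are carried on the cluster.
    """
    start, end = span
    selected = [
        p for p in proteins
        if p.record_id == record.id and p.start is not None
        and p.start < end + margin and p.end > start - margin
    ]
    selected.sort(key=lambda p: (p.start, p.id))
    if selected:
        start = min(start, selected[0].start)
        end = max(end, max(p.end for p in selected))
    pids = {p.id for p in selected}
    meta = metadata or {}
    cluster = PKSCluster(
        cluster_id=cluster_id,
        record_id=record.id,
        start=start,
        end=end,
        ks_domains=list(ks_domains),
        proteins=selected,
        domains=[d for d in domains if d.protein_id in pids],
        sequence=record.sequence[start:end],
        species=meta.get("species", record.species),
        phylum=meta.get("phylum", record.phylum),
        deposit_date=meta.get("deposit_date", record.deposit_date),
        known_product=bool(meta.get("known_product", False)),
    )
    if any(d.kind == "KS" for d in cluster.domains):
        cluster.pks_type = classify_cluster(cluster)
    return cluster
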