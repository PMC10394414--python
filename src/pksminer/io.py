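"""Readers and writers for every external format the pipeline touches.

External dialects use 1-based inclusive coordinates (BLAST tabular,
domain TSV); everything is normalized to 0-based half-open on the plus
strand here, at the boundary.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from pathlib import Path
from typing import Iterable, Optional, Union

import numpy as np
import yaml
from Bio import SeqIO

from .records import (
    Catalog,
    DomainAnnotation,
    DOMAIN_KINDS,
    GRINSParams,
    KSHit,
    MiningParams,
    NucleotideRecord,
    ParseError,
    PKSCluster,
    ProteinRecord,
    SimilarityMatrix,
    parse_date,
)

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]


def read_fasta(path: PathLike, kind: str = "nucleotide") -> list:
    """Read a FASTA file into Nucleotide/Protein records.

    The id is the header token before the first whitespace; sequences are
    upper-cased. Illegal characters raise :class:`ParseError` naming the
    offending line.
    """
    if kind not in ("nucleotide", "protein"):
        raise ValueError("kind must be 'nucleotide' or 'protein'")
    path = Path(path)
    records = []
    # manual parse so errors can carry line numbers
    current_id: Optional[str] = None
    chunks: list[str] = []
    start_line = 0

    def _flush(line_no: int):
        if current_id is None:
            return
        seq = "".join(chunks).upper()
        try:
            if kind == "nucleotide":
                records.append(NucleotideRecord(current_id, seq))
            else:
                records.append(ProteinRecord(current_id, seq))
        except ValueError as exc:
            raise ParseError(f"{path}:{start_line}: {exc}") from exc

    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if line.startswith(">"):
                _flush(line_no)
                header = line[1:].strip()
                if not header:
                    raise ParseError(f"{path}:{line_no}: empty FASTA header")
                current_id = header.split()[0]
                chunks = []
                start_line = line_no
            elif line.strip():
                if current_id is None:
                    raise ParseError(
                        f"{path}:{line_no}: sequence data before first header"
                    )
                chunks.append(line.strip())
        _flush(line_no if chunks or current_id else 0)
    return records


def write_fasta(records: Iterable, path: PathLike, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            seq = rec.sequence
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_blast_tab(path: PathLike) -> list[KSHit]:
    """Parse 12-column BLAST tabular output (outfmt 6) into KS hits.

    Subject coordinates are 1-based inclusive and reversed for
    minus-strand hits; they are normalized to plus-strand half-open
    intervals, with strand inferred from coordinate order. Frame is
    derived from the plus-strand start offset.
    """
    path = Path(path)
    hits: list[KSHit] = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise ParseError(
                    f"{path}:{line_no}: expected 12 tab-separated columns, "
                    f"got {len(fields)}"
                )
            (_q, sseqid, pident, _length, _mm, _go, _qs, _qe, sstart, send,
             _ev, bitscore) = fields[:12]
            try:
                sstart_i, send_i = int(sstart), int(send)
                pident_f = float(pident)
                score_f = float(bitscore)
            except ValueError as exc:
                raise ParseError(f"{path}:{line_no}: non-numeric field: {exc}") from exc
            if sstart_i <= send_i:
                start, end, strand = sstart_i - 1, send_i, "+"
            else:
                start, end, strand = send_i - 1, sstart_i, "-"
            hits.append(
                KSHit(
                    record_id=sseqid,
                    start=start,
                    end=end,
                    strand=strand,
                    frame=start % 3,
                    percent_identity=pident_f,
                    score=score_f,
                )
            )
    return hits


def write_blast_tab(hits: Iterable[KSHit], path: PathLike, query_id: str = "consensus_KS") -> None:
    """Emit hits in the 12-column tabular dialect (inverse of read_blast_tab)."""
    with open(path, "w") as fh:
        for h in hits:
            if h.strand == "+":
                sstart, send = h.start + 1, h.end
            else:
                sstart, send = h.end, h.start + 1
            aln_len = (h.end - h.start) // 3
            fh.write(
                f"{query_id}\t{h.record_id}\t{h.percent_identity:.2f}\t{aln_len}"
                f"\t0\t0\t1\t{aln_len}\t{sstart}\t{send}\t0.0\t{h.score:.1f}\n"
            )


def read_domain_table(path: PathLike) -> list[DomainAnnotation]:
    """Read per-protein domain calls from a TSV table.

    Columns: protein_id, kind, aa_start, aa_end (1-based inclusive).
    Unknown kinds map to "other" with a warning.
    """
    path = Path(path)
    out: list[DomainAnnotation] = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fields[0] == "protein_id":  # header
                continue
            if len(fields) < 4:
                raise ParseError(f"{path}:{line_no}: expected 4 columns")
            pid, kind, aa_start, aa_end = fields[:4]
            try:
                s, e = int(aa_start), int(aa_end)
            except ValueError as exc:
                raise ParseError(f"{path}:{line_no}: non-numeric coordinate") from exc
            if s > e:
                raise ParseError(f"{path}:{line_no}: aa_start > aa_end")
            if kind not in DOMAIN_KINDS:
                logger.warning(
                    "%s:%d: unknown domain kind %r mapped to 'other'",
                    path, line_no, kind,
                )
                kind = "other"
            out.append(DomainAnnotation(pid, kind, s - 1, e))
    return out


def write_domain_table(domains: Iterable[DomainAnnotation], path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("protein_id\tkind\taa_start\taa_end\n")
        for d in domains:
            fh.write(f"{d.protein_id}\t{d.kind}\t{d.aa_start + 1}\t{d.aa_end}\n")


def read_genbank(path: PathLike) -> tuple[list[NucleotideRecord], list[ProteinRecord]]:
    """Optional GenBank reader: records plus CDS translations as proteins."""
    nts: list[NucleotideRecord] = []
    prots: list[ProteinRecord] = []
    for rec in SeqIO.parse(str(path), "genbank"):
        nts.append(NucleotideRecord(rec.id, str(rec.seq).upper()))
        for feat in rec.features:
            if feat.type != "CDS":
                continue
            quals = feat.qualifiers
            pid = (quals.get("protein_id") or quals.get("locus_tag") or [f"{rec.id}_cds{len(prots)}"])[0]
            translation = quals.get("translation", [None])[0]
            if translation is None:
                continue
            prots.append(
                ProteinRecord(
                    pid,
                    translation.upper(),
                    record_id=rec.id,
                    start=int(feat.location.start),
                    end=int(feat.location.end),
                )
            )
    return nts, prots


# ---------------------------------------------------------------------------
# catalogue serialization

_CATALOG_COLUMNS = [
    "cluster_id", "record_id", "start", "end", "species", "phylum",
    "pks_type", "length_aa", "ks_count", "gc_content", "deposit_date",
    "known_product",
]


def _cluster_row(c: PKSCluster) -> dict:
    return {
        "cluster_id": c.cluster_id,
        "record_id": c.record_id,
        "start": c.start,
        "end": c.end,
        "species": c.species or "",
        "phylum": c.phylum or "",
        "pks_type": c.pks_type or "",
        "length_aa": c.length_aa,
        "ks_count": c.ks_count,
        "gc_content": round(c.gc_content, 4) if c.sequence else "",
        "deposit_date": c.deposit_date.isoformat() if c.deposit_date else "",
        "known_product": int(c.known_product),
    }


def write_catalog(catalog: Catalog, path: PathLike, format: str = "tsv") -> None:
    """Write the retained clusters (one row/object each) as TSV or JSON."""
    if format not in ("tsv", "json"):
        raise ValueError(f"unknown catalogue format {format!r}")
    path = Path(path)
    rows = [_cluster_row(c) for c in catalog.clusters]
    if format == "tsv":
        with open(path, "w") as fh:
            fh.write("\t".join(_CATALOG_COLUMNS) + "\n")
            for row in rows:
                fh.write("\t".join(str(row[k]) for k in _CATALOG_COLUMNS) + "\n")
    else:
        payload = {
            "clusters": rows,
            "removed": dict(sorted(catalog.removed.items())),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
            fh.write("\n")


def read_catalog(path: PathLike, format: str = "tsv") -> Catalog:
    """Round-trip reader for :func:`write_catalog` (summary fields only)."""
    path = Path(path)
    if format == "tsv":
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            rows = [dict(zip(header, line.rstrip("\n").split("\t"))) for line in fh if line.strip()]
        removed: dict[str, str] = {}
    elif format == "json":
        with open(path) as fh:
            payload = json.load(fh)
        rows = payload["clusters"]
        removed = payload.get("removed", {})
    else:
        raise ValueError(f"unknown catalogue format {format!r}")
    clusters = []
    for row in rows:
        clusters.append(
            PKSCluster(
                cluster_id=str(row["cluster_id"]),
                record_id=str(row["record_id"]),
                start=int(row["start"]),
                end=int(row["end"]),
                species=str(row["species"]) or None,
                phylum=str(row["phylum"]) or None,
                pks_type=str(row["pks_type"]) or None,
                deposit_date=parse_date(str(row["deposit_date"])) if str(row["deposit_date"]) else None,
                known_product=bool(int(row["known_product"])),
            )
        )
    return Catalog(clusters=clusters, removed=removed)


# ---------------------------------------------------------------------------
# similarity-matrix serialization

def write_matrix(matrix: SimilarityMatrix, path: PathLike) -> None:
    """Square TSV: id header row + one row of percent scores per cluster."""
    with open(path, "w") as fh:
        fh.write("cluster_id\t" + "\t".join(matrix.ids) + "\n")
        for i, cid in enumerate(matrix.ids):
            row = "\t".join(f"{v:.4f}" for v in matrix.scores[i])
            fh.write(f"{cid}\t{row}\n")


def read_matrix(path: PathLike) -> SimilarityMatrix:
    with open(path) as fh:
        ids = fh.readline().rstrip("\n").split("\t")[1:]
        rows = []
        for line in fh:
            if line.strip():
                rows.append([float(x) for x in line.rstrip("\n").split("\t")[1:]])
    return SimilarityMatrix(ids, np.array(rows))


def write_edges(matrix: SimilarityMatrix, path: PathLike, threshold: float = 0.0) -> None:
    """Long-form edge TSV of unordered pairs with score > threshold."""
    with open(path, "w") as fh:
        fh.write("id_a\tid_b\tsimilarity\n")
        for i, a in enumerate(matrix.ids):
            for j in range(i + 1, len(matrix.ids)):
                score = matrix.scores[i, j]
                if score > threshold:
                    fh.write(f"{a}\t{matrix.ids[j]}\t{score:.4f}\n")


# ---------------------------------------------------------------------------
# metadata + protein-location tables (pipeline side inputs)

def read_metadata(path: PathLike) -> dict[str, dict]:
    """Per-record metadata TSV: record_id, species, phylum, deposit_date,
    known_product (0/1). Returns a map keyed by record_id."""
    meta: dict[str, dict] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for line in fh:
            if not line.strip():
                continue
            row = dict(zip(header, line.rstrip("\n").split("\t")))
            meta[row["record_id"]] = {
                "species": row.get("species") or None,
                "phylum": row.get("phylum") or None,
                "deposit_date": parse_date(row["deposit_date"]) if row.get("deposit_date") else None,
                "known_product": bool(int(row.get("known_product", "0") or 0)),
            }
    return meta


def write_metadata(meta: dict[str, dict], path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("record_id\tspecies\tphylum\tdeposit_date\tknown_product\n")
        for rid in sorted(meta):
            m = meta[rid]
            date = m["deposit_date"].isoformat() if m.get("deposit_date") else ""
            fh.write(
                f"{rid}\t{m.get('species') or ''}\t{m.get('phylum') or ''}\t"
                f"{date}\t{int(bool(m.get('known_product')))}\n"
            )


def read_protein_locations(path: PathLike) -> list[dict]:
    """Protein location TSV: protein_id, record_id, start, end (0-based half-open)."""
    out = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for line in fh:
            if not line.strip():
                continue
            row = dict(zip(header, line.rstrip("\n").split("\t")))
            out.append(
                {
                    "protein_id": row["protein_id"],
                    "record_id": row["record_id"],
                    "start": int(row["start"]),
                    "end": int(row["end"]),
                }
            )
    return out


def write_protein_locations(rows: Iterable[dict], path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("protein_id\trecord_id\tstart\tend\n")
        for r in rows:
            fh.write(f"{r['protein_id']}\t{r['record_id']}\t{r['start']}\t{r['end']}\n")


# ---------------------------------------------------------------------------
# config

def params_to_dict(params: MiningParams) -> dict:
    d = dataclasses.asdict(params)
    return d


def params_from_dict(d: dict) -> MiningParams:
    d = dict(d)
    grins = d.pop("grins", {})
    return MiningParams(grins=GRINSParams(**grins), **d)


def read_params(path: PathLike) -> MiningParams:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return params_from_dict(data)


def write_params(params: MiningParams, path: PathLike) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(params_to_dict(params), fh, sort_keys=True)
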