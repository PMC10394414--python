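"""Ground-truthed synthetic inputs: assembly-line cluster DNA with a
module grammar, homolog families at controlled divergence, planted
GRINS-like skewed duplications, and exponentially growing deposit
dates.

Every generator is a pure function of (spec, seed): identical inputs
give identical bytes. Truth manifests record the planted coordinates,
family structure and dates so each pipeline stage can be scored without
re-deriving ground truth.

The DNA is deliberately simple — fixed one-codon-per-amino-acid
back-translation, uniform intergenic background — which is exactly what
makes planted-signal recovery unambiguous.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from . import io as pio
from .records import (
    Catalog,
    DomainAnnotation,
    GRINSParams,
    NucleotideRecord,
    PKSCluster,
    ProteinRecord,
)
from .mining import classify_cluster

AA = "ACDEFGHIKLMNPQRSTVWY"

#: Fixed back-translation table (one codon per residue, no stops).
CODON = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT",
    "G": "GGT", "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTG",
    "M": "ATG", "N": "AAT", "P": "CCG", "Q": "CAG", "R": "CGT",
    "S": "TCT", "T": "ACT", "V": "GTT", "W": "TGG", "Y": "TAT",
}

#: Approximate per-kind domain lengths in residues.
DOMAIN_AA_LEN = {
    "KS": 420, "AT": 330, "ACP": 80, "KR": 240, "DH": 200, "ER": 240,
    "MT": 280, "TE": 260, "C": 440, "A": 490, "PCP": 80, "other": 150,
}

_CONSENSUS_SEED = 20220801
_CONSENSUS_LEN = 420


def consensus_ks() -> str:
    """The fixed synthetic consensus KS protein used by every generator."""
    rng = np.random.default_rng(_CONSENSUS_SEED)
    return "".join(rng.choice(list(AA), size=_CONSENSUS_LEN))


def random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AA), size=length))


def mutate_protein(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Substitute each residue with a different one with probability rate."""
    out = list(seq)
    for i in range(len(out)):
        if rng.random() < rate:
            choices = AA.replace(out[i], "")
            out[i] = choices[rng.integers(len(choices))]
    return "".join(out)


def back_translate(protein: str) -> str:
    return "".join(CODON[a] for a in protein)


def random_dna(rng: np.random.Generator, length: int, probs=None) -> str:
    bases = ["A", "C", "G", "T"]
    p = probs or [0.25, 0.25, 0.25, 0.25]
    return "".join(rng.choice(bases, size=length, p=p))


def skewed_segment(rng: np.random.Generator, length: int, composition: dict) -> str:
    """Composition-biased DNA, e.g. {"G": .42, "C": .10, "T": .38, "A": .10}
    gives GC skew ≈ +0.62 and TA skew ≈ +0.58."""
    bases = sorted(composition)
    p = np.array([composition[b] for b in bases], dtype=float)
    p = p / p.sum()
    return "".join(rng.choice(bases, size=length, p=p))


#: Intense skews well above the 25 % detection threshold (GC ≈ +0.62,
#: TA ≈ +0.58), so single-window sampling noise does not sever a run.
_DEFAULT_GRINS_COMPOSITION = {"G": 0.42, "C": 0.10, "T": 0.38, "A": 0.10}


@dataclass
class GrinsPlant:
    """A planted skewed duplication: ``copies`` copies of one ``length``-bp
    composition-biased segment, dropped into intergenic spacers."""

    length: int = 1000
    composition: dict = field(default_factory=lambda: dict(_DEFAULT_GRINS_COMPOSITION))
    copies: int = 2


@dataclass
class SynthSpec:
    """Recipe for one synthetic assembly-line cluster."""

    n_modules: int = 5
    pks_type: str = "cis-AT PKS"
    module_grammar: Optional[list[list[str]]] = None  # explicit per-module kinds
    grins_plants: list[GrinsPlant] = field(default_factory=list)
    modules_per_protein: int = 2
    #: rich modules carry the reductive domains (KR/DH/ER/MT) so that
    #: consecutive KS loci sit more than 3 kbp apart, as in real
    #: assembly lines; compact modules (KS-AT-ACP) keep proteins short
    #: for alignment-heavy homolog-family work.
    rich_modules: bool = True
    ks_family_divergence: float = 0.25  # cluster KS vs the consensus
    ks_module_divergence: float = 0.05  # each module's KS vs the cluster KS
    spacer_len: int = 400
    flank_len: int = 500
    seed: int = 0

    def grammar(self) -> list[list[str]]:
        if self.module_grammar is not None:
            g = self.module_grammar
        else:
            g = _default_grammar(self.n_modules, self.pks_type, self.rich_modules)
        _check_grammar(g, self.pks_type)
        return g


def _default_grammar(n_modules: int, pks_type: str, rich: bool = True) -> list[list[str]]:
    if pks_type == "other hybrid":
        # untypable: KS modules with neither AT nor ACP, plus NRPS character
        ks_module = ["KS", "KR", "ER", "DH", "MT"] if rich else ["KS", "KR"]
        return [ks_module] * (n_modules - 1) + [["C", "A", "PCP"]]
    hybrid = "hybrid" in pks_type
    n_pks = n_modules - 1 if hybrid else n_modules
    if n_pks < 1:
        raise ValueError("n_modules too small for a hybrid grammar")
    if pks_type.startswith("cis"):
        flags = [True] * n_pks
    elif pks_type.startswith("trans"):
        flags = [False] * n_pks
    elif pks_type.startswith("mixed"):
        if n_pks < 2:
            raise ValueError("mixed grammar needs >= 2 PKS modules")
        flags = [i % 2 == 0 for i in range(n_pks)]
    else:
        raise ValueError(f"unknown pks_type {pks_type!r}")
    if rich:
        cis_module = ["KS", "AT", "DH", "ER", "KR", "ACP"]
        trans_module = ["KS", "DH", "ER", "MT", "KR", "ACP"]
    else:
        cis_module = ["KS", "AT", "ACP"]
        trans_module = ["KS", "ACP"]
    modules = [list(cis_module) if f else list(trans_module) for f in flags]
    modules[-1] = modules[-1] + ["TE"]
    if hybrid:
        modules.append(["C", "A", "PCP"])
    return modules


def _check_grammar(grammar: Sequence[Sequence[str]], pks_type: str) -> None:
    kinds = [k for m in grammar for k in m]
    has_at = "AT" in kinds
    if pks_type.startswith("trans") and has_at:
        raise ValueError("trans-AT spec with a cis grammar (AT present)")
    if pks_type.startswith("cis") and not has_at:
        raise ValueError("cis-AT spec with no AT in the grammar")
    if "hybrid" in pks_type and not any(k in ("C", "A", "PCP") for k in kinds):
        raise ValueError("hybrid spec without NRPS domains in the grammar")


def generate_cluster(
    spec: SynthSpec,
    cluster_id: str = "synth",
    metadata: Optional[dict] = None,
) -> tuple[NucleotideRecord, PKSCluster, dict]:
    """Build one synthetic cluster.

    Returns (record, cluster, truth manifest). The record carries the
    cluster DNA plus neutral flanks; the manifest lists true KS/domain
    coordinates (record-relative) and planted GRINS segments.
    """
    rng = np.random.default_rng(spec.seed)
    grammar = spec.grammar()
    cluster_ks = mutate_protein(consensus_ks(), spec.ks_family_divergence, rng)

    # per-module blocks -> proteins
    modules: list[list[tuple[str, str]]] = []  # [(kind, aa_seq), ...] per module
    for kinds in grammar:
        blocks = []
        for kind in kinds:
            if kind == "KS":
                aa = mutate_protein(cluster_ks, spec.ks_module_divergence, rng)
            else:
                aa = random_protein(rng, DOMAIN_AA_LEN[kind])
            blocks.append((kind, aa))
        modules.append(blocks)

    protein_blocks: list[list[tuple[str, str]]] = []
    mpp = max(1, spec.modules_per_protein)
    for i in range(0, len(modules), mpp):
        merged: list[tuple[str, str]] = []
        for m in modules[i : i + mpp]:
            merged.extend(m)
        protein_blocks.append(merged)

    # lay out DNA: flank | prot ( spacer prot )* | flank, GRINS into spacers
    n_prot = len(protein_blocks)
    spacers = [random_dna(rng, spec.spacer_len) for _ in range(n_prot - 1)]
    spacers.append(random_dna(rng, spec.spacer_len))  # trailing intra-cluster spacer
    # plants go into the inter-protein spacers only: those always fall
    # inside the first-KS..last-KS span that cluster calling reports
    n_copies = sum(p.copies for p in spec.grins_plants)
    n_plantable = n_prot - 1
    if n_copies > n_plantable:
        raise ValueError(
            f"{n_copies} GRINS copies requested but only {n_plantable} "
            "inter-protein spacers available; increase n_modules or "
            "lower modules_per_protein"
        )
    grins_truth = []
    slot = 0
    for plant in spec.grins_plants:
        seg = skewed_segment(rng, plant.length, plant.composition)
        for _copy in range(plant.copies):
            idx = slot % n_plantable
            mid = len(spacers[idx]) // 2
            spacers[idx] = spacers[idx][:mid] + seg + spacers[idx][mid:]
            slot += 1
        grins_truth.append({"length": plant.length, "copies": plant.copies})

    flank = random_dna(rng, spec.flank_len)
    parts = [flank]
    pos = len(flank)
    cluster_start = pos
    proteins: list[ProteinRecord] = []
    annotations: list[DomainAnnotation] = []
    ks_truth = []
    grins_positions = []
    for i, blocks in enumerate(protein_blocks):
        aa_seq = "".join(aa for _k, aa in blocks)
        dna = back_translate(aa_seq)
        pid = f"{cluster_id}_p{i}"
        proteins.append(
            ProteinRecord(pid, aa_seq, record_id=cluster_id, start=pos, end=pos + len(dna))
        )
        aa_pos = 0
        for kind, aa in blocks:
            annotations.append(DomainAnnotation(pid, kind, aa_pos, aa_pos + len(aa)))
            if kind == "KS":
                ks_truth.append({"start": pos + 3 * aa_pos, "end": pos + 3 * (aa_pos + len(aa))})
            aa_pos += len(aa)
        parts.append(dna)
        pos += len(dna)
        spacer = spacers[i] if i < len(spacers) else ""
        if spacer:
            start_sp = pos
            parts.append(spacer)
            pos += len(spacer)
            if len(spacer) > spec.spacer_len:  # a plant was inserted here
                mid = spec.spacer_len // 2
                plant_len = len(spacer) - spec.spacer_len
                grins_positions.append(
                    {"start": start_sp + mid, "end": start_sp + mid + plant_len}
                )
    cluster_end = pos
    parts.append(random_dna(rng, spec.flank_len))
    sequence = "".join(parts)

    meta = metadata or {}
    record = NucleotideRecord(
        cluster_id,
        sequence,
        species=meta.get("species"),
        phylum=meta.get("phylum"),
        deposit_date=meta.get("deposit_date"),
    )
    cluster = PKSCluster(
        cluster_id=cluster_id,
        record_id=cluster_id,
        start=cluster_start,
        end=cluster_end,
        ks_domains=[],
        proteins=proteins,
        domains=annotations,
        sequence=sequence[cluster_start:cluster_end],
        species=meta.get("species"),
        phylum=meta.get("phylum"),
        deposit_date=meta.get("deposit_date"),
        known_product=bool(meta.get("known_product", False)),
    )
    cluster.pks_type = classify_cluster(cluster)
    if cluster.pks_type != spec.pks_type:
        raise ValueError(
            f"inconsistent spec: grammar classifies as {cluster.pks_type!r}, "
            f"requested {spec.pks_type!r}"
        )
    manifest = {
        "cluster_id": cluster_id,
        "span": [cluster_start, cluster_end],
        "n_modules": len(grammar),
        "n_ks": len(ks_truth),
        "ks_domains": ks_truth,
        "grins_plants": grins_truth,
        "grins_regions": grins_positions,  # record-relative coordinates
        "pks_type": cluster.pks_type,
        "seed": spec.seed,
    }
    return record, cluster, manifest


def mutate_homolog(
    cluster: PKSCluster,
    subst_rate: float,
    indel_rate: float = 0.0,
    seed: int = 0,
    new_id: Optional[str] = None,
) -> PKSCluster:
    """Derive a homolog by codon-level mutation of the coding DNA.

    Substitutions replace a whole codon by the codon of a different
    residue with probability ``subst_rate`` per site, so the nominal
    rate equals the realised amino-acid divergence. Indels
    insert/delete whole codons at ``indel_rate`` per site, keeping
    frames intact. Intergenic DNA (including planted GRINS) is carried
    over unchanged; proteins and domain coordinates are re-derived.
    """
    if not (0.0 <= subst_rate < 1.0 and 0.0 <= indel_rate < 1.0):
        raise ValueError("rates must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    new_id = new_id or f"{cluster.cluster_id}_m"
    seq = cluster.sequence
    offset = cluster.start  # protein coords are record-relative
    parts: list[str] = []
    pos = 0
    new_proteins: list[ProteinRecord] = []
    new_domains: list[DomainAnnotation] = []
    dom_by_protein: dict[str, list[DomainAnnotation]] = {}
    for d in cluster.domains:
        dom_by_protein.setdefault(d.protein_id, []).append(d)
    for pi, p in enumerate(cluster.proteins):
        p_start = p.start - offset
        p_end = p.end - offset
        parts.append(seq[pos:p_start])  # preceding intergenic DNA
        new_start = sum(len(x) for x in parts)
        old_aa = list(p.sequence)
        # position map old aa index -> new aa index (None = deleted)
        new_aa: list[str] = []
        index_map: list[Optional[int]] = []
        for a in old_aa:
            if indel_rate and rng.random() < indel_rate:
                if rng.random() < 0.5:
                    index_map.append(None)  # deletion
                    continue
                new_aa.append(AA[rng.integers(len(AA))])  # insertion before site
            if rng.random() < subst_rate:
                choices = AA.replace(a, "")
                a = choices[rng.integers(len(choices))]
            index_map.append(len(new_aa))
            new_aa.append(a)
        aa_seq = "".join(new_aa)
        pid = f"{new_id}_p{pi}"
        dna = back_translate(aa_seq)
        parts.append(dna)
        new_proteins.append(
            ProteinRecord(pid, aa_seq, record_id=new_id, start=new_start, end=new_start + len(dna))
        )

        for d in dom_by_protein.get(p.id, []):
            s = d.aa_start
            while s < len(index_map) and index_map[s] is None:
                s += 1
            e = d.aa_end - 1
            while e >= 0 and index_map[e] is None:
                e -= 1
            if s >= len(index_map) or e < 0 or index_map[s] > index_map[e]:
                continue  # whole domain deleted
            new_domains.append(
                DomainAnnotation(pid, d.kind, index_map[s], index_map[e] + 1)
            )
        pos = p_end
    parts.append(seq[pos:])
    new_seq = "".join(parts)
    out = PKSCluster(
        cluster_id=new_id,
        record_id=new_id,
        start=0,
        end=len(new_seq),
        ks_domains=[],
        proteins=new_proteins,
        domains=new_domains,
        sequence=new_seq,
        species=cluster.species,
        phylum=cluster.phylum,
        deposit_date=cluster.deposit_date,
        known_product=cluster.known_product,
    )
    if any(d.kind == "KS" for d in new_domains):
        out.pks_type = classify_cluster(out)
    return out


# ---------------------------------------------------------------------------
# dated catalogues

def exponential_dates(
    n: int,
    growth_rate: float,
    seed: int,
    start_year: int = 1995,
    end_year: int = 2022,
) -> list[_dt.date]:
    """Draw n deposit dates whose cumulative count grows exponentially at
    ``growth_rate`` per year (inverse-CDF sampling), sorted ascending."""
    rng = np.random.default_rng(seed)
    u = rng.random(n)
    t0, t1 = float(start_year), float(end_year + 1)
    g = growth_rate
    if g <= 0:
        times = t0 + u * (t1 - t0)
    else:
        times = np.log(np.exp(g * t0) + u * (np.exp(g * t1) - np.exp(g * t0))) / g
    times.sort()
    dates = []
    for t in times:
        year = int(math.floor(t))
        frac = t - year
        day = min(int(frac * 365) + 1, 365)
        dates.append(_dt.date(year, 1, 1) + _dt.timedelta(days=day - 1))
    return dates


def generate_dated_catalog(
    n: int,
    growth_rate: float,
    seed: int,
    start_year: int = 1995,
    end_year: int = 2022,
) -> Catalog:
    """Lightweight date-only catalogue (stub clusters, no sequence) for
    growth-curve work at large n."""
    dates = exponential_dates(n, growth_rate, seed, start_year, end_year)
    clusters = [
        PKSCluster(
            cluster_id=f"stub{i:05d}",
            record_id=f"stub{i:05d}",
            start=0,
            end=1000,
            deposit_date=d,
        )
        for i, d in enumerate(dates)
    ]
    return Catalog(clusters=clusters)


_PHYLA = ["Actinobacteria", "Cyanobacteria", "Firmicutes", "Proteobacteria", "Apicomplexa"]
_TYPE_CYCLE = [
    "cis-AT PKS", "cis-AT PKS-NRPS hybrid", "trans-AT PKS",
    "trans-AT PKS-NRPS hybrid", "mixed cis/trans PKS",
    "mixed cis/trans hybrid", "other hybrid",
]


def generate_catalog(
    n_families: int,
    family_size: int,
    divergence: float = 0.02,
    growth_rate: float = math.log(2) / 2.5,
    seed: int = 0,
    known_fraction: float = 0.25,
    n_modules: int = 3,
    grins_families: int = 0,
) -> tuple[list[PKSCluster], dict]:
    """Families of homologs with exponential-in-time deposit dates.

    Each family is one independently generated cluster plus
    ``family_size − 1`` homologs mutated at ``divergence``; members of a
    family share a species. The truth manifest lists family membership,
    which clusters are redundant copies (non-founders at low
    divergence), each orphan family's characterized founder (if any),
    and the generating growth rate.
    """
    if n_families <= 0 or family_size <= 0:
        raise ValueError("sizes must be positive")
    rng = np.random.default_rng(seed)
    n_total = n_families * family_size
    dates = exponential_dates(n_total, growth_rate, seed + 1)
    clusters: list[PKSCluster] = []
    truth: dict = {
        "n_families": n_families,
        "family_size": family_size,
        "growth_rate": growth_rate,
        "divergence": divergence,
        "families": {},
        "redundant": [],
        "known_founders": [],
    }
    di = 0
    for f in range(n_families):
        fam_id = f"fam{f:03d}"
        pks_type = _TYPE_CYCLE[f % len(_TYPE_CYCLE)]
        known = f < int(round(known_fraction * n_families))
        meta = {
            "species": f"Synthetica familia{f:03d}",
            "phylum": _PHYLA[f % len(_PHYLA)],
            "deposit_date": dates[di],
            "known_product": known,
        }
        spec = SynthSpec(
            n_modules=n_modules,
            pks_type=pks_type,
            grins_plants=[GrinsPlant()] if f < grins_families else [],
            rich_modules=False,
            modules_per_protein=1,
            seed=int(rng.integers(2**31 - 1)),
        )
        _rec, founder, _mani = generate_cluster(spec, f"{fam_id}c0", metadata=meta)
        di += 1
        members = [founder]
        for m in range(1, family_size):
            hom = mutate_homolog(
                founder,
                subst_rate=divergence,
                indel_rate=0.0,
                seed=int(rng.integers(2**31 - 1)),
                new_id=f"{fam_id}c{m}",
            )
            hom.deposit_date = dates[di]
            di += 1
            members.append(hom)
            truth["redundant"].append(hom.cluster_id)
        clusters.extend(members)
        truth["families"][fam_id] = [c.cluster_id for c in members]
        if known:
            truth["known_founders"].append(founder.cluster_id)
    return clusters, truth


# ---------------------------------------------------------------------------
# on-disk corpus for the end-to-end pipeline

def write_corpus(
    outdir,
    n_clusters: int = 3,
    n_modules: int = 4,
    grins_clusters: int = 1,
    seed: int = 0,
) -> dict:
    """Write a small mining corpus: genome FASTA, protein FASTA + location
    TSV, domain TSV, metadata TSV, consensus KS FASTA and truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    records, proteins, domains, locations = [], [], [], []
    meta: dict[str, dict] = {}
    manifests = []
    for i in range(n_clusters):
        pks_type = _TYPE_CYCLE[i % 4]
        spec = SynthSpec(
            n_modules=n_modules,
            pks_type=pks_type,
            grins_plants=[GrinsPlant()] if i < grins_clusters else [],
            modules_per_protein=1,
            seed=int(rng.integers(2**31 - 1)),
        )
        cid = f"rec{i:03d}"
        m = {
            "species": f"Synthetica demo{i:03d}",
            "phylum": _PHYLA[i % len(_PHYLA)],
            "deposit_date": _dt.date(2000 + 3 * i, 6, 15),
            "known_product": i == 0,
        }
        record, cluster, manifest = generate_cluster(spec, cid, metadata=m)
        records.append(record)
        proteins.extend(cluster.proteins)
        domains.extend(cluster.domains)
        locations.extend(
            {"protein_id": p.id, "record_id": cid, "start": p.start, "end": p.end}
            for p in cluster.proteins
        )
        meta[cid] = m
        manifests.append(manifest)
    pio.write_fasta(records, outdir / "genomes.fna")
    pio.write_fasta(proteins, outdir / "proteins.faa")
    pio.write_domain_table(domains, outdir / "domains.tsv")
    pio.write_protein_locations(locations, outdir / "proteins.tsv")
    pio.write_metadata(meta, outdir / "metadata.tsv")
    pio.write_fasta(
        [ProteinRecord("consensus_KS", consensus_ks())], outdir / "consensus_ks.faa"
    )
    truth = {"n_clusters": n_clusters, "clusters": manifests, "seed": seed}
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return truth
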