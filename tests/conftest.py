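import datetime as dt

import numpy as np
import pytest

from pksminer.records import (
    Catalog,
    DomainAnnotation,
    PKSCluster,
    ProteinRecord,
    SimilarityMatrix,
)


def make_cluster(
    cluster_id="c",
    architecture=("KS-AT-ACP",),
    sequence=None,
    species="Streptomyces albus",
    phylum="Actinobacteria",
    deposit_date=None,
    known_product=False,
    protein_len=120,
):
    """Hand-built cluster whose domains follow an architecture string
    like ("KS-AT-ACP", "KS-AT-KR-ACP-TE"): one protein per element."""
    import zlib

    rng = np.random.default_rng(zlib.crc32(cluster_id.encode()) % (2**31))
    proteins, domains = [], []
    pos = 0
    for i, arch in enumerate(architecture):
        kinds = arch.split("-") if arch else []
        plen = max(protein_len, 10 * len(kinds))
        pid = f"{cluster_id}_p{i}"
        aa = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=plen))
        proteins.append(ProteinRecord(pid, aa, record_id=cluster_id, start=pos, end=pos + 3 * plen))
        step = plen // max(1, len(kinds))
        for k, kind in enumerate(kinds):
            domains.append(DomainAnnotation(pid, kind, k * step, k * step + step))
        pos += 3 * plen + 100
    seq = sequence or "".join(np.random.default_rng(1).choice(list("ACGT"), size=max(pos, 10)))
    return PKSCluster(
        cluster_id=cluster_id,
        record_id=cluster_id,
        start=0,
        end=len(seq),
        proteins=proteins,
        domains=domains,
        sequence=seq,
        species=species,
        phylum=phylum,
        deposit_date=deposit_date,
        known_product=known_product,
    )


def make_matrix(ids, pairs):
    """SimilarityMatrix from {frozenset({a, b}): score} with diagonal 100."""
    n = len(ids)
    scores = np.zeros((n, n))
    np.fill_diagonal(scores, 100.0)
    idx = {c: i for i, c in enumerate(ids)}
    for key, val in pairs.items():
        a, b = sorted(key)
        scores[idx[a], idx[b]] = scores[idx[b], idx[a]] = val
    return SimilarityMatrix(list(ids), scores)


@pytest.fixture
def toy_catalog():
    clusters = [
        make_cluster("A", ("KS-AT-ACP", "KS-AT-KR-ACP-TE"),
                     deposit_date=dt.date(1999, 5, 1), known_product=True),
        make_cluster("B", ("KS-ACP", "KS-ACP-TE"), species="Bacillus subtilis",
                     phylum="Firmicutes", deposit_date=dt.date(1999, 9, 9)),
        make_cluster("C", ("KS-AT-ACP", "C-A-PCP"), species="Nostoc sp.",
                     phylum="Cyanobacteria", deposit_date=dt.date(2001, 2, 2)),
    ]
    for c in clusters:
        from pksminer.mining import classify_cluster

        c.pks_type = classify_cluster(c)
    return Catalog(clusters=clusters)


@pytest.fixture
def rng():
    return np.random.default_rng(20230802)
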