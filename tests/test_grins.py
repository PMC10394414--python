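"""GRINS detection: skew algebra, sliding profiles, region calling,
internal-repeat finding, and the combined skew+repeat detector."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pksminer.grins import (
    detect_grins,
    find_internal_repeats,
    find_skewed_regions,
    gc_skew,
    grins_prevalence,
    skew_profile,
    ta_skew,
)
from pksminer.records import Catalog, GRINSParams, PKSCluster
from pksminer.synth import (
    GrinsPlant,
    SynthSpec,
    generate_cluster,
    random_dna,
    skewed_segment,
)
from .conftest import make_cluster

COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def revcomp(s):
    return "".join(COMP[b] for b in reversed(s))


def brute_repeats(seq, window, min_identity):
    """Windowed-identity oracle: slide a window over the sequence and ask
    (via edlib infix alignment) whether it matches anywhere outside its
    own span at >= min_identity; reports presence/absence of any
    internal repeat."""
    import edlib

    max_dist = int(window * (1 - min_identity / 100.0))
    for i in range(0, len(seq) - window + 1, 50):
        w = seq[i : i + window]
        for target in (seq[:i], seq[i + window :]):
            if len(target) < window - max_dist:
                continue
            res = edlib.align(w, target, mode="HW", k=max_dist)
            if res["editDistance"] != -1:
                return True
    return False


class TestSkewAlgebra:
    def test_gc_formula(self):
        assert gc_skew("GGGGCC") == pytest.approx(1 / 3)
        assert ta_skew("TTTA") == pytest.approx(0.5)

    def test_degenerate_windows_return_zero(self):
        assert gc_skew("ATATAT") == 0.0
        assert ta_skew("GCGC") == 0.0

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError):
            gc_skew("")
        with pytest.raises(ValueError):
            ta_skew("")

    def test_enumerated_4mer_closed_forms(self):
        from itertools import product

        for w in map("".join, product("ACGT", repeat=4)):
            g, c = w.count("G"), w.count("C")
            t, a = w.count("T"), w.count("A")
            assert gc_skew(w) == pytest.approx((g - c) / (g + c) if g + c else 0.0)
            assert ta_skew(w) == pytest.approx((t - a) / (t + a) if t + a else 0.0)

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(st.text(alphabet="ACGT", min_size=1, max_size=200))
    def test_reverse_complement_antisymmetry(self, w):
        assert gc_skew(revcomp(w)) == pytest.approx(-gc_skew(w))
        assert ta_skew(revcomp(w)) == pytest.approx(-ta_skew(w))


class TestSkewProfile:
    def test_window_count_formula(self):
        rng = np.random.default_rng(2)
        seq = random_dna(rng, 300)
        assert len(skew_profile(seq, 150, 30)) == 6

    def test_homogeneous_sequence_constant_profile(self):
        prof = skew_profile("GT" * 200, 100, 20)
        assert all(g == 1.0 and t == 1.0 for _s, g, t in prof)

    def test_locality_away_from_seam(self):
        rng = np.random.default_rng(3)
        left, right = random_dna(rng, 600), random_dna(rng, 600)
        whole = skew_profile(left + right, 150, 30)
        lp = skew_profile(left, 150, 30)
        assert whole[: len(lp)] == lp  # windows fully inside the left half

    def test_window_longer_than_sequence_warns_empty(self):
        with pytest.warns(UserWarning):
            assert skew_profile("ACGT", 150, 30) == []


class TestFindSkewedRegions:
    def test_planted_segment_recovered_within_one_window(self):
        rng = np.random.default_rng(14)
        seg = skewed_segment(rng, 1000, {"G": 0.40, "C": 0.15, "T": 0.30, "A": 0.15})
        seq = random_dna(rng, 3000) + seg + random_dna(rng, 3000)
        regions = find_skewed_regions(skew_profile(seq, 150, 30), 0.25, 700, 150)
        assert len(regions) == 1
        start, end, mgc, mta = regions[0]
        assert abs(start - 3000) <= 150 and abs(end - 4000) <= 150
        assert mgc >= 0.25 and mta >= 0.25

    def test_neutral_sequence_rarely_fires(self):
        false = 0
        for seed in range(100):
            seq = random_dna(np.random.default_rng(1000 + seed), 6000)
            if find_skewed_regions(skew_profile(seq, 150, 30), 0.25, 700, 150):
                false += 1
        assert false <= 2  # <= 2 % of replicates

    def test_both_skews_required(self):
        rng = np.random.default_rng(13)
        # strong GC skew, balanced T/A
        seg = skewed_segment(rng, 1000, {"G": 0.45, "C": 0.15, "T": 0.20, "A": 0.20})
        seq = random_dna(rng, 2000) + seg + random_dna(rng, 2000)
        assert find_skewed_regions(skew_profile(seq, 150, 30), 0.25, 700, 150) == []


class TestFindInternalRepeats:
    def test_exact_duplication_recovered(self):
        rng = np.random.default_rng(17)
        seg = random_dna(rng, 1000)
        seq = (
            random_dna(rng, 2000) + seg + random_dna(rng, 8000)
            + seg + random_dna(rng, 2000)
        )
        pairs = find_internal_repeats(seq, 90.0, 700)
        assert len(pairs) == 1
        (s1, e1), (s2, e2), identity = pairs[0]
        assert identity == pytest.approx(100.0)
        assert abs(s1 - 2000) <= 20 and abs(e1 - 3000) <= 20
        assert abs(s2 - 11000) <= 20 and abs(e2 - 12000) <= 20

    def test_mutated_duplication_identity_band(self):
        rng = np.random.default_rng(19)
        seg = random_dna(rng, 1000)
        bases = "ACGT"
        mutated = "".join(
            bases[(bases.index(b) + 1 + rng.integers(3)) % 4] if rng.random() < 0.05 else b
            for b in seg
        )
        seq = random_dna(rng, 1500) + seg + random_dna(rng, 4000) + mutated + random_dna(rng, 1500)
        pairs = find_internal_repeats(seq, 90.0, 700)
        assert pairs, "mutated duplication missed"
        identity = pairs[0][2]
        assert 93.0 <= identity <= 97.0

    def test_shuffled_sequence_has_no_pairs(self):
        rng = np.random.default_rng(23)
        assert find_internal_repeats(random_dna(rng, 8000), 90.0, 700) == []

    def test_agrees_with_windowed_identity_oracle(self):
        rng = np.random.default_rng(29)
        for trial in range(60):
            n = int(rng.integers(2000, 4500))
            seq = random_dna(rng, n)
            if rng.random() < 0.5:  # plant a duplication half the time
                seg_len = int(rng.integers(500, 700))
                src = int(rng.integers(0, n - 2 * seg_len - 200))
                dst = int(rng.integers(src + seg_len + 100, n - seg_len))
                seq = seq[:dst] + seq[src : src + seg_len] + seq[dst + seg_len :]
            found = bool(find_internal_repeats(seq, 95.0, 300))
            assert found == brute_repeats(seq, 300, 95.0)


class TestDetectGrins:
    def _planted(self, seed=1):
        spec = SynthSpec(
            n_modules=4, modules_per_protein=1,
            grins_plants=[GrinsPlant()], seed=seed,
        )
        rec, cluster, manifest = generate_cluster(spec, f"g{seed}")
        truth = [
            (g["start"] - cluster.start, g["end"] - cluster.start)
            for g in manifest["grins_regions"]
        ]
        return cluster, truth

    def test_planted_duplicated_skewed_segment_gives_two_regions(self):
        cluster, truth = self._planted()
        regions = detect_grins(cluster)
        assert len(regions) == 2
        for (ts, te), r in zip(truth, regions):
            assert abs(r.start - ts) <= 150 and abs(r.end - te) <= 150
            assert r.repeat_identity >= 90.0
            assert abs(r.mean_gc_skew) >= 0.25 and abs(r.mean_ta_skew) >= 0.25

    def test_skewed_but_unique_segment_is_not_grins(self):
        rng = np.random.default_rng(31)
        seq = (
            random_dna(rng, 3000)
            + skewed_segment(rng, 1000, {"G": 0.42, "C": 0.10, "T": 0.38, "A": 0.10})
            + random_dna(rng, 3000)
        )
        c = PKSCluster("x", "x", 0, len(seq), sequence=seq)
        assert detect_grins(c) == []

    def test_duplicated_but_unskewed_segment_is_not_grins(self):
        rng = np.random.default_rng(37)
        seg = random_dna(rng, 1000)
        seq = random_dna(rng, 2000) + seg + random_dna(rng, 4000) + seg + random_dna(rng, 2000)
        c = PKSCluster("x", "x", 0, len(seq), sequence=seg and seq)
        assert detect_grins(c) == []

    def test_translation_shifts_coordinates_exactly(self):
        cluster, _ = self._planted(seed=5)
        base = detect_grins(cluster)
        # flank length is a multiple of the 30 bp step, so the window
        # grid lands on the same sequence positions after the shift
        flank = "ACGT" * 300
        shifted = PKSCluster(
            "s", "s", 0, len(cluster.sequence) + 2400,
            sequence=flank + cluster.sequence + flank,
        )
        moved = detect_grins(shifted)
        assert len(moved) == len(base)
        for b, m in zip(base, moved):
            assert m.start == b.start + 1200 and m.end == b.end + 1200

    def test_recall_and_false_positives_on_plant_and_control_panels(self):
        found, total, fp = 0, 0, 0
        n_panel = 40
        for seed in range(n_panel):
            cluster, truth = self._planted(seed=100 + seed)
            regions = detect_grins(cluster)
            for ts, te in truth:
                total += 1
                if any(abs(r.start - ts) <= 150 and abs(r.end - te) <= 150 for r in regions):
                    found += 1
            spec = SynthSpec(n_modules=4, modules_per_protein=1, seed=5000 + seed)
            _rec, control, _m = generate_cluster(spec, f"ctrl{seed}")
            fp += len(detect_grins(control))
        assert found / total >= 0.95
        assert fp / n_panel <= 0.02


class TestPrevalence:
    def test_counts_and_percent(self, toy_catalog):
        det = {"A": [], "B": [], "C": []}
        # pretend A has a detection
        from pksminer.records import GRINSRegion

        det["A"] = [GRINSRegion("A", 0, 800, 0.4, 0.4, 2000, 2800, 95.0)]
        table = grins_prevalence(toy_catalog, det, "pks_type")
        row = table[table.pks_type == "cis-AT PKS"].iloc[0]
        assert row.n_clusters == 1 and row.n_with_grins == 1 and row.percent == 100.0
        assert table.n_clusters.sum() == len(toy_catalog)
        # percents recomputable from counts
        assert (
            table.percent == 100.0 * table.n_with_grins / table.n_clusters
        ).all()

    def test_unknown_group_key_rejected(self, toy_catalog):
        with pytest.raises(ValueError):
            grins_prevalence(toy_catalog, {}, "species")

    def test_empty_groups_absent(self, toy_catalog):
        table = grins_prevalence(toy_catalog, {}, "phylum")
        assert set(table.phylum) == {"Actinobacteria", "Firmicutes", "Cyanobacteria"}
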