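import numpy as np
import pytest

import scoredel as sd
from scoredel.simulate import CapacityError

from oracles import hamming20


class TestSimulateLocus:
    def test_same_seed_is_byte_identical(self, tmp_path):
        a = sd.simulate_locus(lcr_length=500, inter_lcr_length=1_000,
                              flank_length=500, decoy_spec=[2], seed=77)
        b = sd.simulate_locus(lcr_length=500, inter_lcr_length=1_000,
                              flank_length=500, decoy_spec=[2], seed=77)
        assert a.genome.sequence == b.genome.sequence
        assert a.truth == b.truth
        pa = a.write(tmp_path / "a")
        pb = b.write(tmp_path / "b")
        assert pa["fasta"].read_bytes() == pb["fasta"].read_bytes()
        assert pa["truth"].read_bytes() == pb["truth"].read_bytes()

    def test_different_seed_differs(self):
        a = sd.simulate_locus(lcr_length=500, inter_lcr_length=1_000,
                              flank_length=500, seed=1)
        b = sd.simulate_locus(lcr_length=500, inter_lcr_length=1_000,
                              flank_length=500, seed=2)
        assert a.genome.sequence != b.genome.sequence

    def test_truth_table_consistency(self):
        """Re-scanning the generated genome reproduces every planted and
        decoy record: positions, strands and mismatch counts."""
        locus = sd.simulate_locus(
            lcr_length=600, inter_lcr_length=1_500, flank_length=2_000,
            n_planted=2, decoy_spec=[1, 3], seed=13,
        )
        g = locus.genome
        for pg in locus.truth.planted_guides:
            for iv in (locus.lcr_a, locus.lcr_b):
                start = iv.start + pg.offset_in_lcr
                assert g.sequence[start : start + 20] == pg.protospacer
                assert g.sequence[start + 21 : start + 23] == "GG"
        for decoy in locus.truth.decoys:
            assert hamming20(decoy.protospacer_source, decoy.protospacer) == decoy.mismatches
            assert g.sequence[decoy.location : decoy.location + 20] == decoy.protospacer
        # the planted guides are exactly the shared set
        shared = sd.find_shared_guides(locus.assembly, locus.lcr_a, locus.lcr_b)
        assert sorted(s.protospacer for s in shared) == sorted(
            p.protospacer for p in locus.truth.planted_guides
        )

    def test_divergent_repeats_protect_planted_footprints(self):
        locus = sd.simulate_locus(
            lcr_length=1_000, inter_lcr_length=1_500, flank_length=500,
            identity=0.9, seed=21,
        )
        shared = sd.find_shared_guides(locus.assembly, locus.lcr_a, locus.lcr_b)
        assert {g.protospacer for g in shared} == {
            p.protospacer for p in locus.truth.planted_guides
        }
        a = locus.genome.sequence[locus.lcr_a.start : locus.lcr_a.end]
        b = locus.genome.sequence[locus.lcr_b.start : locus.lcr_b.end]
        ident = sum(x == y for x, y in zip(a, b)) / len(a)
        assert 0.88 <= ident <= 0.92

    def test_expected_deletion_size_matches_geometry(self):
        locus = sd.simulate_locus(lcr_length=500, inter_lcr_length=4_000,
                                  flank_length=500, seed=5)
        assert locus.truth.expected_deletion_size == 500 + 4_000

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            sd.simulate_locus(lcr_length=50)
        with pytest.raises(ValueError):
            sd.simulate_locus(identity=0.0)
        with pytest.raises(CapacityError):
            sd.simulate_locus(lcr_length=150, n_planted=10)

    def test_lcr_backgrounds_have_no_stray_guides(self):
        """Inside the repeats, planted sites are the only PAM-adjacent sites."""
        locus = sd.simulate_locus(lcr_length=2_000, inter_lcr_length=1_000,
                                  flank_length=500, n_planted=1, seed=99)
        for iv in (locus.lcr_a, locus.lcr_b):
            sites = sd.enumerate_guides(locus.genome, iv)
            assert len(sites) == 1


class TestSimulateCt:
    BASE = {"TBX1": 26.0, "CRKL": 25.0, "RPPH1": 20.0}

    def truth(self, cn_tbx1):
        t = {("cal", g): 2 for g in self.BASE}
        t |= {("cl", "TBX1"): cn_tbx1, ("cl", "CRKL"): 2, ("cl", "RPPH1"): 2}
        return t

    def test_noise_free_single_copy_gives_exact_half(self):
        table = sd.simulate_ct(self.truth(1), self.BASE, noise_sd=0.0,
                               calibrator_sample="cal")
        rcn = sd.relative_copy_number(table)
        assert rcn.loc["cl", "TBX1"] == 0.5
        assert rcn.loc["cl", "CRKL"] == 1.0

    def test_noise_free_diploid_gives_exact_one(self):
        table = sd.simulate_ct(self.truth(2), self.BASE, noise_sd=0.0,
                               calibrator_sample="cal")
        rcn = sd.relative_copy_number(table)
        assert (rcn.loc["cl"] == 1.0).all()

    def test_noise_free_classification_is_perfect(self):
        truth = {("cal", g): 2 for g in self.BASE}
        labels = {}
        for i in range(50):
            cn = 1 if i % 2 == 0 else 2
            labels[f"cl{i:02d}"] = "deletion" if cn == 1 else "no_deletion"
            for g in self.BASE:
                truth[(f"cl{i:02d}", g)] = cn if g == "TBX1" else 2
        table = sd.simulate_ct(truth, self.BASE, noise_sd=0.0, calibrator_sample="cal")
        calls = sd.classify_clones(
            sd.relative_copy_number(table), ["TBX1"], ["CRKL"]
        )
        for c in calls:
            if c.sample in labels:
                assert c.call == labels[c.sample]

    def test_seeded_reproducibility(self):
        t1 = sd.simulate_ct(self.truth(1), self.BASE, noise_sd=0.3, seed=4,
                            calibrator_sample="cal")
        t2 = sd.simulate_ct(self.truth(1), self.BASE, noise_sd=0.3, seed=4,
                            calibrator_sample="cal")
        assert t1.ct == t2.ct

    def test_validation(self):
        with pytest.raises(ValueError):
            sd.simulate_ct(self.truth(1), self.BASE, noise_sd=-0.1,
                           calibrator_sample="cal")
        bad = self.truth(1)
        bad[("cal", "TBX1")] = 1
        with pytest.raises(ValueError, match="calibrator"):
            sd.simulate_ct(bad, self.BASE, calibrator_sample="cal")


class TestSimulateExpression:
    def test_seeded_reproducibility(self):
        m1, _ = sd.simulate_expression(n_in_region=20, n_flanking=20, seed=6)
        m2, _ = sd.simulate_expression(n_in_region=20, n_flanking=20, seed=6)
        assert m1.values.equals(m2.values)

    def test_noise_free_limit_recovers_dosage(self):
        matrix, region = sd.simulate_expression(dispersion=0.0, dosage_factor=0.5, seed=2)
        s = sd.region_log2fc(matrix, region)
        assert s.in_region_mean == pytest.approx(-1.0, abs=0.1)
        assert s.flanking_mean == pytest.approx(0.0, abs=0.05)

    def test_null_simulation_centers_on_zero(self):
        means = []
        for seed in range(20):
            matrix, region = sd.simulate_expression(
                n_in_region=100, n_flanking=100, dosage_factor=1.0, seed=seed
            )
            s = sd.region_log2fc(matrix, region)
            means.append(s.in_region_mean - s.flanking_mean)
        assert abs(float(np.mean(means))) < 0.05

    def test_coordinates_partition_by_region(self):
        matrix, region = sd.simulate_expression(n_in_region=30, n_flanking=40, seed=9)
        s = sd.region_log2fc(matrix, region)
        assert len(s.in_region_features) == 30
        assert len(s.flanking_features) == 40
        assert s.n_excluded == 0
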