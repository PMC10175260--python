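import pytest

import scoredel as sd
from scoredel.clone_screen import CtTableError, ScreenConfigError


def table(cells, calibrator="WTC", reference="RPPH1"):
    return sd.CtTable(ct=cells, reference_gene=reference, calibrator_sample=calibrator)


class TestRelativeCopyNumber:
    def test_calibrator_identical_sample_gives_unit_rcn(self):
        cells = {
            ("WTC", "TBX1"): [26.0], ("WTC", "RPPH1"): [20.0],
            ("cl1", "TBX1"): [26.0], ("cl1", "RPPH1"): [20.0],
        }
        rcn = sd.relative_copy_number(table(cells))
        assert rcn.loc["cl1", "TBX1"] == pytest.approx(1.0)
        assert rcn.loc["cl1", "RPPH1"] == pytest.approx(1.0)

    def test_one_cycle_shift_halves_copy_number(self):
        cells = {
            ("WTC", "TBX1"): [26.0], ("WTC", "RPPH1"): [20.0],
            ("cl1", "TBX1"): [27.0], ("cl1", "RPPH1"): [20.0],
        }
        rcn = sd.relative_copy_number(table(cells))
        assert rcn.loc["cl1", "TBX1"] == pytest.approx(0.5)

    def test_replicates_are_mean_aggregated(self):
        cells = {
            ("WTC", "TBX1"): [26.0], ("WTC", "RPPH1"): [20.0],
            ("cl1", "TBX1"): [26.9, 27.1], ("cl1", "RPPH1"): [20.0],
        }
        rcn = sd.relative_copy_number(table(cells))
        assert rcn.loc["cl1", "TBX1"] == pytest.approx(0.5)

    def test_reference_gene_rcn_is_always_one(self):
        cells = {
            ("WTC", "TBX1"): [26.0], ("WTC", "RPPH1"): [20.0],
            ("cl1", "TBX1"): [28.3], ("cl1", "RPPH1"): [21.7],
        }
        rcn = sd.relative_copy_number(table(cells))
        assert (rcn["RPPH1"] == 1.0).all()

    def test_missing_cells_listed(self):
        cells = {
            ("WTC", "TBX1"): [26.0], ("WTC", "RPPH1"): [20.0],
            ("cl1", "RPPH1"): [20.0],
        }
        with pytest.raises(CtTableError, match="cl1.*TBX1"):
            sd.relative_copy_number(table(cells))

    def test_tsv_round_trip(self, tmp_path):
        cells = {
            ("WTC", "TBX1"): [26.0, 26.2], ("WTC", "RPPH1"): [20.0, 20.1],
            ("cl1", "TBX1"): [27.0, 27.2], ("cl1", "RPPH1"): [20.0, 20.1],
        }
        t = table(cells)
        p = tmp_path / "ct.tsv"
        t.to_tsv(p)
        back = sd.CtTable.from_tsv(p, calibrator_sample="WTC")
        assert back.ct == t.ct


class TestClassifyClones:
    def rcn_frame(self, rows):
        import pandas as pd
        return pd.DataFrame(rows).T

    def test_heterozygous_pattern_called_deletion(self):
        rcn = self.rcn_frame({"cl1": {"TBX1": 0.5, "CRKL": 1.0, "RPPH1": 1.0}})
        (call,) = sd.classify_clones(rcn, ["TBX1"], ["CRKL"])
        assert call.call == "deletion"

    def test_all_diploid_called_no_deletion(self):
        rcn = self.rcn_frame({"cl1": {"TBX1": 1.0, "CRKL": 1.0, "RPPH1": 1.0}})
        (call,) = sd.classify_clones(rcn, ["TBX1"], ["CRKL"])
        assert call.call == "no_deletion"

    def test_between_thresholds_is_ambiguous(self):
        rcn = self.rcn_frame({"cl1": {"TBX1": 0.75, "CRKL": 1.0}})
        (call,) = sd.classify_clones(rcn, ["TBX1"], ["CRKL"])
        assert call.call == "ambiguous"

    def test_flanking_loss_is_not_a_clean_deletion(self):
        rcn = self.rcn_frame({"cl1": {"TBX1": 0.5, "CRKL": 0.5}})
        (call,) = sd.classify_clones(rcn, ["TBX1"], ["CRKL"])
        assert call.call == "ambiguous"

    def test_gene_list_validation(self):
        rcn = self.rcn_frame({"cl1": {"TBX1": 1.0, "CRKL": 1.0}})
        with pytest.raises(ScreenConfigError):
            sd.classify_clones(rcn, [], ["CRKL"])
        with pytest.raises(ScreenConfigError):
            sd.classify_clones(rcn, ["TBX1"], ["TBX1"])
        with pytest.raises(ScreenConfigError):
            sd.classify_clones(rcn, ["HIRA"], ["CRKL"])


class TestInsilicoPcr:
    F = "GATTACAGATTACAG"  # 15 nt
    R = "CTGCTGCTGCTGCTG"  # 15 nt

    def template(self, spacer_len):
        return (
            "TTTT" + self.F + "A" * spacer_len
            + sd.reverse_complement(self.R) + "TTTT"
        )

    def test_constructed_template_product_length(self):
        pair = sd.PrimerPair("toy", self.F, self.R)
        g = sd.GenomeSequence("c", self.template(30))
        (amp,) = sd.insilico_pcr(g, pair)
        assert amp.length == 15 + 30 + 15
        assert amp.strand_of_forward == "+"

    @pytest.mark.parametrize("spacer", [0, 7, 100, 1000])
    def test_exactly_one_product_of_predicted_length(self, spacer):
        pair = sd.PrimerPair("toy", self.F, self.R)
        g = sd.GenomeSequence("c", self.template(spacer))
        amps = sd.insilico_pcr(g, pair)
        assert [a.length for a in amps] == [len(self.F) + spacer + len(self.R)]

    def test_single_primer_yields_no_product(self):
        g = sd.GenomeSequence("c", "TTTT" + self.F + "A" * 50)
        assert sd.insilico_pcr(g, sd.PrimerPair("toy", self.F, self.R)) == []

    def test_minus_orientation_found(self):
        plus = self.template(30)
        g = sd.GenomeSequence("c", sd.reverse_complement(plus))
        (amp,) = sd.insilico_pcr(g, sd.PrimerPair("toy", self.F, self.R))
        assert amp.length == 60
        assert amp.strand_of_forward == "-"

    def test_max_product_cap(self):
        pair = sd.PrimerPair("toy", self.F, self.R)
        g = sd.GenomeSequence("c", self.template(200))
        assert sd.insilico_pcr(g, pair, max_product=100) == []

    def test_primer_validation(self):
        with pytest.raises(ValueError):
            sd.PrimerPair("bad", "ACGTACGTACGTAC", self.R)  # 14 nt
        with pytest.raises(ValueError):
            sd.PrimerPair("bad", self.F, "CTGCTGCTGCTGCTN")


class TestPrimerPanel:
    def test_bundled_panel_contents(self):
        panel = sd.read_primer_panel()
        by_gene = {p.gene: p for p in panel}
        assert set(by_gene) == {"TBX1", "HIRA", "COMT", "CRKL", "BID", "MAPK1", "RPPH1"}
        assert by_gene["TBX1"].forward == "CCCTTACCTACCCGAGTGGA"
        assert by_gene["TBX1"].expected_size == 101
        assert by_gene["RPPH1"].expected_size == 120

    def test_panel_sizes_consistent_with_span_convention(self):
        """Each advertised size leaves a non-negative inner spacer under the
        inclusive outer-primer span convention, and a template built with that
        spacer yields exactly the advertised product size."""
        for pair in sd.read_primer_panel():
            spacer = pair.expected_size - len(pair.forward) - len(pair.reverse)
            assert spacer >= 0
            template = (
                "TTTTT" + pair.forward + "A" * spacer
                + sd.reverse_complement(pair.reverse) + "TTTTT"
            )
            amps = sd.insilico_pcr(sd.GenomeSequence("c", template), pair)
            assert [a.length for a in amps] == [pair.expected_size]
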