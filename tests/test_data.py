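import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wgblup import data
from wgblup.data import (GenotypeMatrix, MarkerMap, ParseError, Pedigree,
                         TraitTable, ValidationError, deregress,
                         garrick_weight, impute_mode, qc_filter_individuals,
                         qc_filter_markers)


def _toy_genotypes(calls, chroms=None):
    calls = np.asarray(calls, float)
    n, m = calls.shape
    mm = MarkerMap([f"M{j}" for j in range(m)],
                   chroms if chroms is not None else [1] * m,
                   np.arange(m) * 1000)
    return GenotypeMatrix([f"I{i}" for i in range(n)], calls, mm)


class TestRoundTrip:
    def test_genotype_roundtrip(self, tmp_path):
        rng = np.random.default_rng(0)
        calls = rng.integers(0, 3, size=(5, 10)).astype(float)
        calls[0, 0] = np.nan
        g = _toy_genotypes(calls)
        data.write_genotypes(g, tmp_path / "g.tsv", tmp_path / "map.tsv")
        g2 = data.read_genotypes(tmp_path / "g.tsv", tmp_path / "map.tsv")
        assert g2.individual_ids == g.individual_ids
        np.testing.assert_array_equal(g2.calls, g.calls)
        assert list(g2.map.marker_id) == list(g.map.marker_id)
        np.testing.assert_array_equal(g2.map.position_bp, g.map.position_bp)

    def test_pedigree_roundtrip_and_toposort(self, tmp_path):
        # offspring listed before its sire: must be reordered, not rejected
        ped = Pedigree(np.array(["c", "s", "d"], object),
                       np.array(["s", "0", "0"], object),
                       np.array(["d", "0", "0"], object))
        assert list(ped.ids).index("c") > list(ped.ids).index("s")
        data.write_pedigree(ped, tmp_path / "ped.tsv")
        ped2 = data.read_pedigree(tmp_path / "ped.tsv")
        assert list(ped2.ids) == list(ped.ids)
        assert list(ped2.sires) == list(ped.sires)

    def test_trait_and_annotation_roundtrip(self, tmp_path):
        t = TraitTable(["a", "b"], [1.0, 2.0], [0.8, 0.9], 0.4)
        data.write_traits(t, tmp_path / "t.tsv")
        t2 = data.read_traits(tmp_path / "t.tsv", 0.4)
        np.testing.assert_allclose(t2.pta, t.pta)
        ann = data.QTLAnnotation([1, 2], [100, 5], [200, 50])
        data.write_annotation(ann, tmp_path / "a.tsv")
        ann2 = data.read_annotation(tmp_path / "a.tsv")
        np.testing.assert_array_equal(ann2.start_bp, ann.start_bp)
        np.testing.assert_array_equal(ann2.stop_bp, ann.stop_bp)

    def test_bad_genotype_entry_rejected(self, tmp_path):
        (tmp_path / "map.tsv").write_text("marker\tchrom\tpos\nM0\t1\t1\n")
        (tmp_path / "g.tsv").write_text("id\tM0\nI0\t3\n")
        with pytest.raises((ParseError, ValidationError)):
            data.read_genotypes(tmp_path / "g.tsv", tmp_path / "map.tsv")

    def test_pedigree_cycle_rejected(self):
        with pytest.raises(ValidationError, match="cycle"):
            Pedigree(np.array(["a", "b"], object),
                     np.array(["b", "a"], object),
                     np.array(["0", "0"], object))


class TestMarkerQC:
    def test_maf_boundary_is_strict(self):
        # 10 individuals: MAF 0.04 impossible; use 50 for 0.04 and 0.05
        n = 50
        col_low = np.zeros(n)
        col_low[:4] = 1.0          # p = 0.04 -> removed
        col_exact = np.zeros(n)
        col_exact[:5] = 1.0        # p = 0.05 -> retained (strict <)
        g = _toy_genotypes(np.column_stack([col_low, col_exact]))
        out, report = qc_filter_markers(g)
        assert list(out.map.marker_id) == ["M1"]
        assert report["marker"].tolist() == ["M0"]

    def test_callrate_and_sex_chromosome_removal(self):
        n = 200
        calls = np.tile([0.0, 1.0, 2.0, 1.0], (n, 1))
        calls[:3, 0] = np.nan      # call rate 0.985 -> removed
        g = _toy_genotypes(calls, chroms=[1, "sex", "unmapped", 2])
        out, report = qc_filter_markers(g)
        assert list(out.map.marker_id) == ["M3"]
        reasons = dict(zip(report["marker"], report["reason"]))
        assert "low_callrate" in reasons["M0"]
        assert "non_autosomal" in reasons["M1"]

    def test_qc_idempotent(self, small_cohort):
        _, g, _, _ = small_cohort
        once, _ = qc_filter_markers(g)
        twice, rep = qc_filter_markers(once)
        assert rep.empty
        np.testing.assert_array_equal(once.calls, twice.calls)

    def test_empty_panel_error(self):
        g = _toy_genotypes(np.zeros((10, 2)))  # both monomorphic
        with pytest.raises(ValidationError, match="empty panel"):
            qc_filter_markers(g)


class TestIndividualQC:
    def test_individual_callrate(self):
        calls = np.ones((3, 100))
        calls[0, :2] = np.nan      # 0.98 -> removed
        g = _toy_genotypes(calls)
        out, report = qc_filter_individuals(g)
        assert out.individual_ids == ["I1", "I2"]
        assert report["id"].tolist() == ["I0"]
        # vacuous threshold removes nobody
        out2, _ = qc_filter_individuals(g, callrate_min=0.0)
        assert out2.n_individuals == 3


class TestImputation:
    def test_mode_and_tiebreak(self):
        calls = np.array([[0, 0, 1], [0, 2, 1], [2, 2, 1], [0, 0, 1],
                          [np.nan, np.nan, 1.0]])
        out = impute_mode(_toy_genotypes(calls))
        assert out.calls[4, 0] == 0.0           # mode
        assert out.calls[4, 1] == 0.0           # tie 0 vs 2 -> smaller
        np.testing.assert_array_equal(out.calls[:, 2], np.ones(5))
        assert out.imputed[4, 0] and not out.imputed[0, 0]

    def test_fully_missing_marker_errors(self):
        calls = np.full((4, 1), np.nan)
        with pytest.raises(ValidationError, match="entirely missing"):
            impute_mode(_toy_genotypes(calls))


class TestDeregression:
    def test_worked_example(self):
        # pta=10, r2=0.8, h2=0.5, c=0.5: depta = 12.5,
        # w = 0.5 / ((0.5 + 0.25) * 0.5) = 4/3
        t = TraitTable(["a"], [10.0], [0.8], 0.5)
        out = deregress(t, c_constant=0.5, rel_min=0.2)
        np.testing.assert_allclose(out.depta, [12.5])
        np.testing.assert_allclose(out.record_weight, [4.0 / 3.0])

    def test_high_reliability_limit(self):
        t = TraitTable(["a"], [10.0], [0.999999], 0.5)
        out = deregress(t)
        np.testing.assert_allclose(out.depta, [10.0], rtol=1e-5)

    def test_reliability_filter_strict(self):
        t = TraitTable(["lo", "hi"], [1.0, 1.0], [0.2, 0.21], 0.5)
        out = deregress(t, rel_min=0.2)
        assert out.ids == ["hi"]

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(r2=st.floats(0.25, 0.95), h2=st.floats(0.05, 0.95),
           c=st.floats(0.1, 2.0))
    def test_weight_positive_and_decreasing_in_c(self, r2, h2, c):
        w1 = garrick_weight(r2, h2, c)
        w2 = garrick_weight(r2, h2, c + 0.1)
        assert w1 > 0
        assert w2 < w1
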