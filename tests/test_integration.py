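"""Tests for AUC-proportional weighting and profile integration."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from herbipk import (
    WeightVector,
    auc_0_t,
    compute_weights,
    integrate_profiles,
    integrated_study,
)
from herbipk.errors import GridAlignmentError, InvalidAUCError, WeightCoverageError

from conftest import make_profile


class TestComputeWeights:
    def test_single_analyte(self):
        w = compute_weights({"A": 100.0})
        assert w.as_dict() == {"A": 1.0}

    def test_proportional_shares(self):
        w = compute_weights({"A": 2.0, "B": 3.0, "C": 5.0})
        assert w.as_dict() == pytest.approx({"A": 0.2, "B": 0.3, "C": 0.5})

    def test_reported_mean_aucs_give_eq1_arithmetic(self):
        # weights from the reported mean AUC0-inf values follow the
        # proportional-share formula; this asserts the arithmetic itself
        w = compute_weights(
            {"TSG": 758.2, "EG": 345.8, "PG": 205.0, "AE": 70.28, "EM": 1041.0}
        )
        d = w.as_dict()
        assert d["TSG"] == pytest.approx(0.3133, abs=5e-5)
        assert d["EG"] == pytest.approx(0.1429, abs=5e-5)
        assert d["PG"] == pytest.approx(0.0847, abs=5e-5)
        assert d["AE"] == pytest.approx(0.0290, abs=5e-5)
        assert d["EM"] == pytest.approx(0.4301, abs=5e-5)

    @pytest.mark.parametrize("bad", [0.0, -1.0, float("nan"), None])
    def test_invalid_auc_names_analyte(self, bad):
        with pytest.raises(InvalidAUCError, match="'B'"):
            compute_weights({"A": 10.0, "B": bad})

    @given(
        st.lists(st.floats(min_value=1e-6, max_value=1e6), min_size=1, max_size=12)
    )
    @settings(max_examples=200, deadline=None)
    def test_weights_sum_to_one(self, aucs):
        w = compute_weights({f"A{i}": v for i, v in enumerate(aucs)})
        assert abs(float(np.sum(w.weights)) - 1.0) <= 1e-12
        assert np.all(w.weights > 0) and np.all(w.weights <= 1)

    @given(
        st.lists(st.floats(min_value=1e-3, max_value=1e3), min_size=2, max_size=8),
        st.floats(min_value=1e-3, max_value=1e3),
    )
    @settings(max_examples=100, deadline=None)
    def test_scale_invariance(self, aucs, factor):
        ids = [f"A{i}" for i in range(len(aucs))]
        w1 = compute_weights(dict(zip(ids, aucs)))
        w2 = compute_weights(dict(zip(ids, [a * factor for a in aucs])))
        assert np.allclose(w1.weights, w2.weights, rtol=1e-12, atol=1e-15)

    def test_zero_weight_is_rejected(self):
        # the weight domain is (0, 1]: a degenerate 0-weight vector is invalid
        with pytest.raises(ValueError):
            WeightVector(("A", "B"), np.array([1.0, 0.0]), "auc_0_inf", "pooled-mean")


class TestIntegrateProfiles:
    def _pair(self, concs_a, concs_b, times=(0.5, 1, 2)):
        a = make_profile(times, concs_a, analyte="A")
        b = make_profile(times, concs_b, analyte="B")
        return [a, b]

    def test_convexity_identity_on_identical_profiles(self):
        profs = self._pair([10, 5, 2], [10, 5, 2])
        w = compute_weights({"A": 4.0, "B": 6.0})
        ip = integrate_profiles(profs, w)
        assert np.allclose(ip.concs, [10, 5, 2])

    def test_pointwise_average(self):
        profs = self._pair([10, 1, 1], [1, 1, 10])
        w = compute_weights({"A": 1.0, "B": 1.0})
        ip = integrate_profiles(profs, w)
        assert np.allclose(ip.concs, [5.5, 1.0, 5.5])

    def test_grid_mismatch_reports_offending_times(self):
        a = make_profile([0.5, 1, 2], [10, 5, 2], analyte="A")
        b = make_profile([0.5, 1, 3], [10, 5, 2], analyte="B")
        w = compute_weights({"A": 1.0, "B": 1.0})
        with pytest.raises(GridAlignmentError, match="3"):
            integrate_profiles([a, b], w)

    def test_weight_coverage_mismatch(self):
        profs = self._pair([10, 5, 2], [10, 5, 2])
        w = compute_weights({"A": 1.0, "C": 1.0})
        with pytest.raises(WeightCoverageError):
            integrate_profiles(profs, w)

    def test_blq_components_contribute_zero(self):
        a = make_profile([0.5, 1, 2], [10, 5, 0.1], blq=[0, 0, 1],
                         lloq=1.0, analyte="A")
        b = make_profile([0.5, 1, 2], [2, 4, 8], lloq=1e-6, analyte="B")
        w = compute_weights({"A": 1.0, "B": 1.0})
        ip = integrate_profiles([a, b], w)
        assert ip.concs[-1] == pytest.approx(4.0)  # A's BLQ point enters as 0


class TestIntegratedStudy:
    def test_single_analyte_collapses(self, profile_factory):
        times = [0.25, 0.5, 1, 2, 4, 8, 12, 24]
        profs = []
        for s in range(1, 4):
            concs = 100 * np.exp(-0.3 * np.asarray(times)) * (s * 0.5 + 0.5)
            profs.append(
                profile_factory(times, concs, subject=f"S{s}", analyte="A")
            )
        res = integrated_study(profs)
        assert res.weights.as_dict() == {"A": 1.0}
        for (_, row_a), (_, row_i) in zip(
            res.per_analyte.iterrows(), res.integrated.iterrows()
        ):
            assert row_i["auc_0_t"] == pytest.approx(row_a["auc_0_t"], rel=1e-12)
            assert row_i["cmax"] == pytest.approx(row_a["cmax"], rel=1e-12)

    def test_linear_auc_is_weighted_sum(self, uncensored_study):
        """Trapezoid linearity: integrated AUC0-t = sum_j w_j AUC0-t,j."""
        cfg, conc, truth, profiles = uncensored_study
        res = integrated_study(profiles, method="linear")
        w = res.weights.as_dict()
        by_subject = {}
        for p in profiles:
            by_subject.setdefault(p.subject_id, {})[p.analyte_id] = p
        for _, row in res.integrated.iterrows():
            sid = row["subject_id"]
            expected = sum(
                w[a] * auc_0_t(p, "linear")[0] for a, p in by_subject[sid].items()
            )
            assert row["auc_0_t"] == pytest.approx(expected, rel=1e-9)

    def test_integrated_cmax_convexity_bound(self, uncensored_study):
        cfg, conc, truth, profiles = uncensored_study
        res = integrated_study(profiles)
        w = res.weights.as_dict()
        cmax_by = {}
        for _, row in res.per_analyte.iterrows():
            cmax_by.setdefault(row["subject_id"], {})[row["analyte_id"]] = row["cmax"]
        for _, row in res.integrated.iterrows():
            bound = sum(w[a] * c for a, c in cmax_by[row["subject_id"]].items())
            assert row["cmax"] <= bound + 1e-9

    def test_integrated_tmax_within_component_range(self):
        # convexity property of unimodal curves: holds exactly when the
        # components are noise-free (assay error can break unimodality)
        from herbipk import SimStudyConfig, profiles_from_table, simulate_pk_study

        cfg = SimStudyConfig(error_prop=0.0, error_add=0.0, seed=42)
        conc, _ = simulate_pk_study(cfg)
        profiles = profiles_from_table(
            conc, cfg.dose, {a: k.lloq for a, k in cfg.analytes.items()}
        )
        res = integrated_study(profiles)
        tmax_by = {}
        for _, row in res.per_analyte.iterrows():
            tmax_by.setdefault(row["subject_id"], []).append(row["tmax"])
        for _, row in res.integrated.iterrows():
            lo, hi = min(tmax_by[row["subject_id"]]), max(tmax_by[row["subject_id"]])
            assert lo <= row["tmax"] <= hi

    def test_summary_has_integrated_column(self, default_study):
        *_, profiles = default_study
        res = integrated_study(profiles)
        assert "Integrated Data" in res.summary.columns
        assert set(res.summary.columns) == {"TSG", "EG", "PG", "AE", "EM",
                                            "Integrated Data"}
        assert len(res.summary) == 9

    def test_per_subject_scope(self, uncensored_study):
        *_, profiles = uncensored_study
        res = integrated_study(profiles, scope="per-subject")
        assert isinstance(res.weights, dict)
        for wv in res.weights.values():
            assert abs(float(np.sum(wv.weights)) - 1.0) <= 1e-12
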