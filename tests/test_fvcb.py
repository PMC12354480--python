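import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from leafn.fvcb import (DEFAULT_KINETICS, ACiCurve, FvCBParams,
                        InsufficientSpanError, KineticConstants, fit_aci,
                        fvcb_assimilation, read_gas_exchange, rubisco_limited,
                        rubp_limited, transition_ci)
from leafn.synthetic import generate_aci_curve


class TestForwardModel:
    def test_compensation_point_returns_minus_rd(self):
        p = FvCBParams(vcmax=60, jmax=120, rd=1.5)
        assert fvcb_assimilation(DEFAULT_KINETICS.gamma_star, p) == pytest.approx(-1.5)

    def test_hand_evaluated_limitation_rates(self, default_params):
        p = FvCBParams(vcmax=60, jmax=120, rd=0.0)
        assert rubisco_limited(400.0, 60.0) == pytest.approx(19.30, abs=0.01)
        assert rubp_limited(400.0, 120.0) == pytest.approx(22.07, abs=0.01)
        assert fvcb_assimilation(400.0, p) == pytest.approx(19.30, abs=0.01)

    def test_infinite_vcmax_limit_is_rubp_limb(self):
        huge = FvCBParams(vcmax=1e9, jmax=120.0, rd=0.7, flags=["jmax-vcmax-ratio"])
        assert fvcb_assimilation(800.0, huge) == pytest.approx(
            rubp_limited(800.0, 120.0) - 0.7
        )

    def test_nonpositive_ci_rejected(self, default_params):
        with pytest.raises(ValueError):
            fvcb_assimilation(0.0, default_params)

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(
        vcmax=st.floats(min_value=10, max_value=150),
        ratio=st.floats(min_value=1.2, max_value=3.0),
        rd=st.floats(min_value=0, max_value=3),
    )
    def test_monotone_in_ci_and_capacities(self, vcmax, ratio, rd):
        """A is non-decreasing in Ci above gamma*, and in Vcmax and Jmax."""
        p = FvCBParams(vcmax=vcmax, jmax=ratio * vcmax, rd=rd)
        ci = np.linspace(DEFAULT_KINETICS.gamma_star, 1600, 120)
        a = fvcb_assimilation(ci, p)
        assert np.all(np.diff(a) >= -1e-12)
        bigger = FvCBParams(vcmax=vcmax * 1.1, jmax=ratio * vcmax * 1.1, rd=rd)
        assert np.all(fvcb_assimilation(ci, bigger) >= a - 1e-12)

    def test_transition_ci_closed_form(self):
        ci_t = transition_ci(60.0, 120.0)
        assert rubisco_limited(ci_t, 60.0) == pytest.approx(rubp_limited(ci_t, 120.0))


class TestFitACi:
    def test_noiseless_recovery_within_0p1_percent(self, default_params):
        curve = generate_aci_curve(default_params, noise_sd=0.0, seed=0)
        fit = fit_aci(curve)
        assert fit.vcmax == pytest.approx(60.0, rel=1e-3)
        assert fit.jmax == pytest.approx(120.0, rel=1e-3)
        assert fit.rd == pytest.approx(1.0, rel=1e-3)
        assert fit.sse < 1e-12
        assert fit.n_points_c + fit.n_points_j == len(curve)

    @pytest.mark.parametrize("vcmax,jmax,rd", [(45.0, 110.0, 0.5), (90.0, 160.0, 2.0)])
    def test_noiseless_recovery_other_regimes(self, vcmax, jmax, rd):
        true = FvCBParams(vcmax=vcmax, jmax=jmax, rd=rd)
        fit = fit_aci(generate_aci_curve(true, noise_sd=0.0, seed=0))
        assert fit.vcmax == pytest.approx(vcmax, rel=1e-3)
        assert fit.jmax == pytest.approx(jmax, rel=1e-3)

    def test_scale_consistency(self, default_params):
        """Scaling observed A by k scales all three parameters by k exactly."""
        curve = generate_aci_curve(default_params, noise_sd=0.0, seed=0)
        k = 1.7
        scaled = ACiCurve(sample_id="s", ci=curve.ci, a=k * curve.a)
        fit = fit_aci(scaled)
        assert fit.vcmax == pytest.approx(k * 60.0, rel=1e-6)
        assert fit.jmax == pytest.approx(k * 120.0, rel=1e-6)
        assert fit.rd == pytest.approx(k * 1.0, rel=1e-6)

    def test_optimizer_beats_dense_grid(self, default_params, rng):
        """Brute-force grid search never improves on the fitted sse (tolerance 1e-6)."""
        curve = generate_aci_curve(default_params, noise_sd=0.5, seed=rng)
        fit = fit_aci(curve)
        grid_sse = _grid_sse(curve, (30, 90), (60, 180), (0, 3), 50, 50, 10)
        assert fit.sse <= grid_sse + 1e-6

    def test_missing_low_ci_region_named(self):
        curve = ACiCurve(sample_id="s", ci=np.array([400.0, 600, 800, 1000, 1200, 1500]),
                         a=np.linspace(15, 30, 6))
        with pytest.raises(InsufficientSpanError, match="Rubisco"):
            fit_aci(curve)

    def test_missing_high_ci_region_named(self):
        curve = ACiCurve(sample_id="s", ci=np.array([50.0, 100, 150, 200, 250, 300]),
                         a=np.linspace(1, 15, 6))
        with pytest.raises(InsufficientSpanError, match="RuBP"):
            fit_aci(curve)

    def test_off_temperature_rejected_unless_disabled(self, default_params):
        curve = generate_aci_curve(default_params, noise_sd=0.0, seed=0)
        curve.leaf_temp = 30.0
        with pytest.raises(ValueError, match="25"):
            fit_aci(curve)
        fit = fit_aci(curve, allow_off_temperature=True)
        assert fit.vcmax == pytest.approx(60.0, rel=1e-3)

    def test_noisy_recovery_median_bias(self, default_params):
        rng = np.random.default_rng(7)
        errs = []
        for _ in range(60):
            curve = generate_aci_curve(default_params, noise_sd=0.5, seed=rng)
            fit = fit_aci(curve)
            errs.append(abs(fit.vcmax - 60.0) / 60.0)
        assert np.median(errs) < 0.02


def _grid_sse(curve, v_range, j_range, r_range, nv, nj, nr):
    """Dense-grid oracle: minimum sse of the forward model over a parameter box."""
    kin = DEFAULT_KINETICS
    f = np.asarray(rubisco_limited(curve.ci, 1.0, kin))
    g = np.asarray(rubp_limited(curve.ci, 1.0, kin))
    vs = np.linspace(*v_range, nv)
    js = np.linspace(*j_range, nj)
    rs = np.linspace(*r_range, nr)
    ac = vs[:, None, None, None] * f  # (nv, 1, 1, npts)
    aj = js[None, :, None, None] * g
    model = np.minimum(ac, aj) - rs[None, None, :, None]
    sse = ((curve.a - model) ** 2).sum(axis=-1)
    return float(sse.min())


class TestReadGasExchange:
    def test_round_trip_from_synthetic(self, noisy_dataset, tmp_path):
        path = tmp_path / "aci.csv"
        noisy_dataset.aci.to_csv(path, index=False)
        curves = read_gas_exchange(path)
        assert len(curves) == 30
        assert all(len(c) == 13 for c in curves)
        assert all(c.is_fittable for c in curves)

    def test_shuffled_rows_regroup_identically(self, noisy_dataset, tmp_path, rng):
        ordered = tmp_path / "a.csv"
        shuffled = tmp_path / "b.csv"
        noisy_dataset.aci.to_csv(ordered, index=False)
        noisy_dataset.aci.sample(frac=1.0, random_state=3).to_csv(shuffled, index=False)
        for c1, c2 in zip(read_gas_exchange(ordered), read_gas_exchange(shuffled)):
            assert c1.sample_id == c2.sample_id
            np.testing.assert_array_equal(c1.ci, c2.ci)
            np.testing.assert_array_equal(c1.a, c2.a)

    def test_short_curve_flagged_unfittable(self, tmp_path):
        path = tmp_path / "short.csv"
        path.write_text(
            "sample_id,step,ci,a\n" + "\n".join(f"s1,{i},{100*i},{i}" for i in range(1, 5))
        )
        (curve,) = read_gas_exchange(path)
        assert not curve.is_fittable
        assert "too-few-points" in curve.flags

    def test_missing_column_listed(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("sample_id,ci\ns1,400\n")
        with pytest.raises(ValueError, match="a"):
            read_gas_exchange(path)

    def test_non_numeric_cell_reports_row(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("sample_id,ci,a\ns1,400,12.0\ns1,oops,13.0\n")
        with pytest.raises(ValueError, match="row"):
            read_gas_exchange(path)

    def test_column_mapping_for_instrument_exports(self, tmp_path):
        path = tmp_path / "licor.csv"
        path.write_text("obs,Ci,Photo\nL1,400,12.0\nL1,300,10.0\n")
        (curve,) = read_gas_exchange(
            path, column_map={"obs": "sample_id", "Ci": "ci", "Photo": "a"}
        )
        assert curve.sample_id == "L1"
        assert list(curve.ci) == [400.0, 300.0]


def test_kinetic_constants_validated():
    with pytest.raises(ValueError):
        KineticConstants(kc=-1.0)
    assert DEFAULT_KINETICS.km == pytest.approx(404.9 * (1 + 210 / 278.4))


def test_params_ratio_flagged():
    p = FvCBParams(vcmax=100.0, jmax=450.0)
    assert "jmax-vcmax-ratio" in p.flags
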