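"""Vulnerability curves, steady-state network solver and resistance fitting."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import aquadust as aq
from aquadust.errors import ConvergenceError, DomainError, IdentifiabilityError
from conftest import make_gradient_frame

E_MEAN = aq.MEAN_TRANSPIRATION


def constant_resistance(r_sat: float) -> aq.VulnerabilityCurve:
    """Vulnerability disabled: exponential shape in its slope->0 limit."""
    return aq.VulnerabilityCurve(r_sat, -1.0, steepness=1e-9, shape="exponential")


class TestVulnerabilityCurve:
    def test_saturated_value_exact(self, ox_curve, xylem_curve):
        assert ox_curve.resistance(0.0) == 3.7e3
        assert xylem_curve.resistance(0.0) == 3.47e3

    def test_doubling_at_psi50(self, ox_curve):
        # the log-logistic form doubles resistance at psi50 for any exponent
        assert ox_curve.resistance(ox_curve.psi50) == pytest.approx(2 * ox_curve.r_sat)

    def test_exponential_sharp_slope_doubling(self):
        v = aq.VulnerabilityCurve(1e3, -0.5, shape="exponential")
        assert v.resistance(0.0) == pytest.approx(1e3)
        assert v.resistance(-0.5) == pytest.approx(2e3, rel=1e-3)

    def test_slope_zero_limit_is_constant(self):
        v = constant_resistance(3.7e3)
        for psi in (0.0, -0.5, -2.0, -8.0):
            assert v.resistance(psi) == pytest.approx(3.7e3, rel=1e-8)

    @pytest.mark.parametrize("shape", ["log_logistic", "exponential"])
    def test_monotone_nonincreasing_conductance(self, shape):
        v = aq.VulnerabilityCurve(2e3, -0.8, shape=shape)
        grid = np.linspace(0.0, -6.0, 200)
        r = v.resistance_array(grid)
        assert np.all(np.diff(r) >= 0)  # resistance grows with stress

    def test_invalid_params(self):
        with pytest.raises(DomainError):
            aq.VulnerabilityCurve(-1.0, -0.5)
        with pytest.raises(DomainError):
            aq.VulnerabilityCurve(1.0, 0.5)


@settings(derandomize=True, max_examples=30, deadline=None)
@given(
    r_sat=st.floats(1e2, 1e5),
    psi50=st.floats(-3.0, -0.1),
    steep=st.floats(0.5, 3.0),
    shape=st.sampled_from(["log_logistic", "exponential"]),
)
def test_vulnerability_normalization_property(r_sat, psi50, steep, shape):
    v = aq.VulnerabilityCurve(r_sat, psi50, steepness=steep, shape=shape)
    assert v.resistance(0.0) == pytest.approx(r_sat, rel=1e-12)
    assert v.resistance(-0.01) >= v.resistance(0.0) - 1e-9


class TestSteadyState:
    def test_zero_flux_uniform_state(self, segmentation, xylem_curve, ox_curve):
        st_ = aq.solve_steady_state(0.0, -0.3, segmentation, xylem_curve, ox_curve)
        np.testing.assert_allclose(st_.psi_xyl, -0.3)
        np.testing.assert_allclose(st_.psi_ox, -0.3)

    def test_single_segment_constant_resistance_drop(self):
        # drop = E * Rox for a single segment with negligible xylem resistance:
        # the product of the two field constants, 4.2e-5 * 3.7e3 = 0.1554 MPa
        seg = aq.LeafSegmentation(n_segments=1)
        st_ = aq.solve_steady_state(
            E_MEAN, 0.0, seg, constant_resistance(1e-9), constant_resistance(3.7e3)
        )
        assert -st_.psi_ox[0] == pytest.approx(4.2e-5 * 3.7e3, rel=1e-6)

    @pytest.mark.parametrize("n_segments", [1, 2, 3])
    def test_matches_grid_scan_oracle(self, n_segments, xylem_curve, ox_curve):
        # independent path: per-segment 1-D grid argmin at 1e-4 MPa resolution
        seg = aq.LeafSegmentation(n_segments=n_segments)
        st_ = aq.solve_steady_state(E_MEAN, -0.1, seg, xylem_curve, ox_curve)
        prev = -0.1
        for i in range(n_segments):
            j = E_MEAN * seg.downstream_fractions[i]
            grid = np.arange(prev, prev - 1.0, -1e-4)
            resid = [abs(p + j * xylem_curve.resistance(p) / n_segments - prev) for p in grid]
            psi_x = grid[int(np.argmin(resid))]
            assert st_.psi_xyl[i] == pytest.approx(psi_x, abs=1e-3)
            grid = np.arange(psi_x, psi_x - 2.0, -1e-4)
            resid = [abs(p + E_MEAN * ox_curve.resistance(p) - psi_x) for p in grid]
            assert st_.psi_ox[i] == pytest.approx(grid[int(np.argmin(resid))], abs=1e-3)
            prev = st_.psi_xyl[i]

    def test_mass_conservation(self, segmentation, xylem_curve, ox_curve):
        st_ = aq.solve_steady_state(E_MEAN, -0.2, segmentation, xylem_curve, ox_curve)
        assert st_.lateral_flux.sum() == pytest.approx(E_MEAN, rel=1e-12)
        np.testing.assert_allclose(
            st_.j_axial, E_MEAN * np.cumsum(segmentation.area_fractions[::-1])[::-1]
        )

    def test_axial_flux_decreases_toward_tip(self, segmentation, xylem_curve, ox_curve):
        st_ = aq.solve_steady_state(E_MEAN, 0.0, segmentation, xylem_curve, ox_curve)
        assert np.all(np.diff(st_.j_axial) < 0)

    def test_potential_ordering(self, segmentation, xylem_curve, ox_curve):
        st_ = aq.solve_steady_state(E_MEAN, 0.0, segmentation, xylem_curve, ox_curve)
        assert np.all(st_.psi_ox <= st_.psi_xyl)
        assert np.all(st_.psi_xyl <= 0.0)
        assert np.all(np.diff(st_.psi_ox) < 0)  # tip drier than node

    def test_monotone_in_transpiration(self, segmentation, xylem_curve, ox_curve):
        last = np.zeros(3)
        for e in np.linspace(0.0, 5e-5, 20):
            st_ = aq.solve_steady_state(e, 0.0, segmentation, xylem_curve, ox_curve)
            assert np.all(st_.psi_ox <= last + 1e-12)
            last = st_.psi_ox

    def test_runaway_vulnerability_diverges(self, segmentation, xylem_curve):
        # an exponential outside-xylem curve cannot sustain the mean flux
        # once the boundary potential drops past its knee
        sharp = aq.VulnerabilityCurve(3.7e3, -0.45, shape="exponential")
        with pytest.raises(ConvergenceError, match="runaway|converge"):
            aq.solve_steady_state(E_MEAN, -0.5, segmentation, xylem_curve, sharp)

    def test_wl_amplification_joint_with_fit(self, segmentation):
        # joint property of fit + forward model: after fitting a scenario with
        # a severe-stress day, the fitted model's node-to-tip drop at that
        # day's inferred boundary potential is >= 3x its well-watered drop
        df = make_gradient_frame(
            0.067, 12,
            psi_base={("WW", 1): 0.0, ("WL", 1): -0.3, ("WL", 2): -0.8,
                      ("WL", 3): -1.5},
        )
        res = aq.fit_outside_xylem(df)
        v_xyl, v_ox = res.model._curves(res.rox_sat, res.psi50_ox)
        drop = lambda s: s.psi_ox[0] - s.psi_ox[-1]
        ww = aq.solve_steady_state(E_MEAN, min(res.psi_base[("WW", 1)], 0.0),
                                   segmentation, v_xyl, v_ox)
        wl = aq.solve_steady_state(E_MEAN, res.psi_base[("WL", 3)],
                                   segmentation, v_xyl, v_ox)
        assert drop(wl) >= 3.0 * drop(ww)


class TestSitesAndGradient:
    def test_site_mapping_identity(self, segmentation, xylem_curve, ox_curve):
        st_ = aq.solve_steady_state(E_MEAN, 0.0, segmentation, xylem_curve, ox_curve)
        np.testing.assert_array_equal(aq.predict_sites(st_, segmentation), st_.psi_ox)

    def test_uniform_state_zero_gradient(self, segmentation):
        assert aq.gradient_mpa_per_m([-0.4, -0.4, -0.4], segmentation) == 0.0

    def test_gradient_arithmetic(self):
        seg = aq.LeafSegmentation(leaf_length=1.0)
        # 0.10 MPa over 2/3 m between sites at L/6 and 5L/6
        assert aq.gradient_mpa_per_m([-0.1, -0.15, -0.2], seg) == pytest.approx(0.15)

    def test_missing_leaf_length(self):
        seg = aq.LeafSegmentation(leaf_length=None)
        with pytest.raises(DomainError, match="leaf_length"):
            aq.gradient_mpa_per_m([-0.1, -0.2, -0.3], seg)

    def test_default_sites_are_segment_midpoints(self, segmentation):
        assert segmentation.site_positions == pytest.approx((1 / 6, 1 / 2, 5 / 6))


class TestGradientData:
    def test_validation_catches_missing_node(self):
        df = pd.DataFrame(
            {"plant_id": ["P1"] * 2, "condition": ["WW"] * 2, "day": [1, 1],
             "position": ["mid", "tip"], "psi_mpa": [-0.3, -0.4]}
        )
        with pytest.raises(DomainError, match="node"):
            aq.validate_gradient_data(df)

    def test_round_trip_csv(self, tmp_path):
        df = make_gradient_frame(0.0, 1)
        path = tmp_path / "grad.csv"
        df.to_csv(path, index=False)
        back = aq.read_gradient_csv(path)
        assert len(back) == len(df)


class TestOutsideXylemFit:
    def test_noise_free_recovery_is_exact(self):
        res = aq.fit_outside_xylem(make_gradient_frame(0.0, 5))
        assert res.rox_sat == pytest.approx(3.7e3, rel=0.01)
        assert res.psi50_ox == pytest.approx(-0.45, abs=0.01)
        assert res.rmse < 1e-4
        assert not res.boundary_warning

    def test_objective_beats_dense_grid(self):
        # optimum SSE must be <= the best of a 50x50 parameter grid
        model = aq.LeafGradientModel(make_gradient_frame(0.067, 9))
        res = model.fit()
        best = min(
            model._objective(r, p)[0]
            for r in np.geomspace(1e2, 1e5, 50)
            for p in np.linspace(-3.0, -0.05, 50)
        )
        assert res.sse <= best + 1e-9

    def test_anchoring_matches_node_means(self):
        # WL groups are anchored at their node means; WW groups use the
        # saturated boundary psi_base = 0 under the default anchoring
        df = make_gradient_frame(0.067, 3)
        res = aq.fit_outside_xylem(df)
        node = df[df.position == "node"].groupby(["condition", "day"])["psi_mpa"].mean()
        for (cond, day), mean_node in node.items():
            if cond == "WW":
                assert res.psi_base[(cond, day)] == 0.0
                continue
            pred = res.predict(cond, day)
            assert pred.loc[pred.position == "node", "psi_ox_mpa"].iloc[0] == pytest.approx(
                mean_node, abs=1e-6
            )

    def test_node_anchoring_mode_matches_all_groups(self):
        df = make_gradient_frame(0.067, 3)
        model = aq.LeafGradientModel(df, anchoring="node")
        res = model.fit(refine=False)
        node = df[df.position == "node"].groupby(["condition", "day"])["psi_mpa"].mean()
        for (cond, day), mean_node in node.items():
            if res.psi_base[(cond, day)] == 0.0:
                continue  # physical cap engaged: node mean wetter than attainable
            pred = res.predict(cond, day)
            assert pred.loc[pred.position == "node", "psi_ox_mpa"].iloc[0] == pytest.approx(
                mean_node, abs=1e-6
            )

    def test_identifiability_guard(self):
        df = make_gradient_frame(0.0, 1).iloc[:1]
        with pytest.raises((IdentifiabilityError, DomainError)):
            aq.LeafGradientModel(df).fit()

    def test_stochastic_recovery_median(self):
        """Median parameter recovery over stochastic replicates stays near truth."""
        rs, ps = [], []
        for seed in range(1, 51):
            res = aq.fit_outside_xylem(make_gradient_frame(0.067, seed))
            rs.append(res.rox_sat)
            ps.append(res.psi50_ox)
        assert abs(np.median(ps) - (-0.45)) < 0.05
        assert abs(np.median(rs) / 3.7e3 - 1.0) < 0.10

    def test_summary_mentions_fit(self):
        res = aq.fit_outside_xylem(make_gradient_frame(0.0, 2))
        text = res.summary()
        assert "outside-xylem" in text and "rmse" in text

    def test_json_round_trip(self, tmp_path):
        import json

        res = aq.fit_outside_xylem(make_gradient_frame(0.0, 2))
        path = tmp_path / "fit.json"
        res.to_json(path)
        payload = json.loads(path.read_text())
        assert payload["r_sat"] == pytest.approx(res.rox_sat)
        assert payload["fitted_role"] == "outside_xylem"


class TestXylemOnlyFit:
    def test_self_recovery_on_xylem_limited_data(self):
        df = make_gradient_frame(0.0, 4, xylem_only_truth=True)
        res = aq.xylem_only_fit(df)
        assert res.rxyl_sat == pytest.approx(3.47e3, rel=0.02)
        assert res.psi50_xyl == pytest.approx(-1.58, abs=0.05)
        assert res.rmse < 1e-3

    def test_rejected_against_full_model(self):
        # data carry the outside-xylem signature; the xylem-limited
        # alternative cannot reproduce the water-limited variations
        df = make_gradient_frame(0.067, 8)
        full = aq.fit_outside_xylem(df)
        alt = aq.xylem_only_fit(df)
        assert alt.rmse > full.rmse
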