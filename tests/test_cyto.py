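"""Event-level processing: scatter gating, crosstalk estimation and
linear unmixing."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from reporterscreen import cyto, synthlib
from reporterscreen.cyto import CrosstalkMatrix, GateSpec

from conftest import identity_config


def make_events(rng, n=2000, fsc_mean=5e4, ssc_mean=3e4, ch1=1000.0, ch2=1000.0):
    return pd.DataFrame({
        "cell_id": np.arange(n),
        "fsc": rng.lognormal(np.log(fsc_mean), 0.3, n),
        "ssc": rng.lognormal(np.log(ssc_mean), 0.3, n),
        "ch1_raw": rng.lognormal(np.log(ch1), 0.25, n),
        "ch2_raw": rng.lognormal(np.log(ch2), 0.25, n),
    })


class TestScatterGate:
    def test_identity_gate_retains_everything(self, rng):
        ev = make_events(rng)
        out = cyto.gate_scatter(ev, GateSpec(scatter_density_quantile=1.0))
        assert out["pass_scatter"].all()

    def test_quantile_semantics_on_diffuse_scatter(self, rng):
        ev = make_events(rng, n=5000)
        out = cyto.gate_scatter(ev, GateSpec(scatter_density_quantile=0.90))
        assert abs(int(out["pass_scatter"].sum()) - round(0.9 * 5000)) <= 1

    def test_sparse_minority_cluster_removed(self, rng):
        # a distant, diffuse debris cluster (2% of events, twice the
        # log-scatter spread) sits everywhere below the main cluster's
        # density: the 0.95 gate removes essentially all of it
        major = make_events(rng, n=4900)
        n_minor = 100
        minor = pd.DataFrame({
            "cell_id": np.arange(4900, 5000),
            "fsc": rng.lognormal(np.log(5e6), 0.6, n_minor),
            "ssc": rng.lognormal(np.log(3e6), 0.6, n_minor),
            "ch1_raw": rng.lognormal(np.log(1000), 0.25, n_minor),
            "ch2_raw": rng.lognormal(np.log(1000), 0.25, n_minor),
        })
        ev = pd.concat([major, minor], ignore_index=True)
        out = cyto.gate_scatter(ev, GateSpec(scatter_density_quantile=0.95))
        kept = out["pass_scatter"].to_numpy()
        assert kept[4900:].sum() <= 2
        assert kept[:4900].mean() > 0.96

    def test_refuses_tiny_tables(self, rng):
        with pytest.raises(ValueError, match="events"):
            cyto.gate_scatter(make_events(rng, n=20))

    def test_constant_scatter_retains_all_with_warning(self, rng):
        ev = make_events(rng, n=100)
        ev["fsc"] = 1.0
        ev["ssc"] = 1.0
        with pytest.warns(UserWarning, match="constant scatter"):
            out = cyto.gate_scatter(ev)
        assert out["pass_scatter"].all()

    def test_gate_is_idempotent(self, rng):
        ev = make_events(rng)
        once = cyto.gate_scatter(ev, GateSpec())
        twice = cyto.gate_scatter(once, GateSpec())
        assert (once["pass_scatter"] == twice["pass_scatter"]).all()


def simulate_controls(m: CrosstalkMatrix, n=10_000, seed=0):
    cfg = identity_config(events_per_strain=n, crosstalk=m,
                          autofluorescence_mean=20.0, seed=seed)
    mk = lambda g, mch: synthlib.simulate_strain_events(
        synthlib.TrueStrainState("c", 1, g, 0.25, mch, 0.25), cfg, seed=seed)
    return mk(1000.0, 0.0), mk(0.0, 1000.0), mk(0.0, 0.0)


class TestCrosstalkEstimation:
    def test_two_point_exact_slope(self):
        blank = pd.DataFrame({"ch1_raw": [0.0, 0.0], "ch2_raw": [0.0, 0.0]})
        gfp = pd.DataFrame({"ch1_raw": [1.0, 2.0], "ch2_raw": [0.1, 0.2]})
        mch = pd.DataFrame({"ch1_raw": [0.0, 0.0], "ch2_raw": [1.0, 2.0]})
        m = cyto.estimate_crosstalk(gfp, mch, blank)
        assert m.m21 == pytest.approx(0.1, abs=1e-12)
        assert m.m12 == pytest.approx(0.0, abs=1e-12)

    def test_identity_mixing_gives_zero_offdiagonals(self):
        gfp, mch, blank = simulate_controls(CrosstalkMatrix(0.0, 0.0), seed=4)
        m = cyto.estimate_crosstalk(gfp, mch, blank)
        assert m.m21 < 0.01 and m.m12 < 0.01

    def test_recovers_known_crosstalk(self):
        # closed-form regression through the origin vs the generative truth
        gfp, mch, blank = simulate_controls(CrosstalkMatrix(m12=0.03, m21=0.08), seed=2)
        m = cyto.estimate_crosstalk(gfp, mch, blank)
        assert m.m21 == pytest.approx(0.08, abs=0.005)
        assert m.m12 == pytest.approx(0.03, abs=0.005)

    def test_regression_matches_brute_force_residual_minimization(self, rng):
        x = rng.lognormal(3, 0.4, 500)
        y = 0.07 * x + rng.normal(0, 0.5, 500)
        blank = pd.DataFrame({"ch1_raw": np.zeros(10), "ch2_raw": np.zeros(10)})
        gfp = pd.DataFrame({"ch1_raw": x, "ch2_raw": y})
        mch = pd.DataFrame({"ch1_raw": np.zeros(500), "ch2_raw": x})
        m = cyto.estimate_crosstalk(gfp, mch, blank)
        grid = np.linspace(0, 0.2, 20001)
        rss = ((y[:, None] - grid[None, :] * x[:, None]) ** 2).sum(axis=0)
        assert abs(m.m21 - grid[rss.argmin()]) < 1e-4

    def test_swapped_controls_refused(self):
        gfp, mch, blank = simulate_controls(CrosstalkMatrix(m12=0.03, m21=0.08), seed=2)
        with pytest.raises(ValueError, match="swapped|inver"):
            cyto.estimate_crosstalk(mch, gfp, blank)

    def test_estimate_invariant_under_rescaling(self):
        gfp, mch, blank = simulate_controls(CrosstalkMatrix(m12=0.03, m21=0.08), seed=5)
        m1 = cyto.estimate_crosstalk(gfp, mch, blank)
        scale = lambda df, c: df.assign(ch1_raw=df.ch1_raw * c, ch2_raw=df.ch2_raw * c)
        m2 = cyto.estimate_crosstalk(scale(gfp, 37.5), scale(mch, 37.5), scale(blank, 37.5))
        assert m1.m21 == pytest.approx(m2.m21, rel=1e-9)
        assert m1.m12 == pytest.approx(m2.m12, rel=1e-9)


class TestUnmix:
    def test_identity_matrix_zero_background_is_noop(self, rng):
        ev = make_events(rng, n=100)
        out = cyto.unmix(ev, CrosstalkMatrix(0.0, 0.0), background=np.zeros(2))
        np.testing.assert_allclose(out["gfp"], ev["ch1_raw"])
        np.testing.assert_allclose(out["mcherry"], ev["ch2_raw"])

    @given(m12=st.floats(0, 0.3, allow_nan=False), m21=st.floats(0, 0.3, allow_nan=False))
    @settings(max_examples=50, deadline=None)
    def test_unmix_inverts_mixing_exactly(self, m12, m21):
        m = CrosstalkMatrix(m12=m12, m21=m21)
        true = np.array([[1000.0, 200.0], [50.0, 800.0], [0.0, 30.0]])
        raw = true @ m.matrix.T
        ev = pd.DataFrame({"cell_id": range(3), "fsc": 1.0, "ssc": 1.0,
                           "ch1_raw": raw[:, 0], "ch2_raw": raw[:, 1]})
        out = cyto.unmix(ev, m, background=np.zeros(2))
        np.testing.assert_allclose(out[["gfp", "mcherry"]].to_numpy(), true,
                                   rtol=1e-12, atol=1e-9)

    def test_unmix_with_estimated_matrix_bias_below_one_percent(self):
        truth = CrosstalkMatrix(m12=0.03, m21=0.08)
        gfp, mch, blank = simulate_controls(truth, seed=3)
        m_est = cyto.estimate_crosstalk(gfp, mch, blank)
        cfg = identity_config(events_per_strain=10_000, crosstalk=truth,
                              autofluorescence_mean=20.0, seed=10)
        ev = synthlib.simulate_strain_events(
            synthlib.TrueStrainState("s", 1, 1000.0, 0.25, 1000.0, 0.25), cfg, seed=10)
        out = cyto.unmix(ev, m_est, blank)
        assert abs(out["gfp"].mean() - 1000.0) / 1000.0 < 0.01
        assert abs(out["mcherry"].mean() - 1000.0) / 1000.0 < 0.01

    def test_negative_values_retained_by_default(self):
        ev = pd.DataFrame({"cell_id": [0], "fsc": [1.0], "ssc": [1.0],
                           "ch1_raw": [5.0], "ch2_raw": [100.0]})
        out = cyto.unmix(ev, CrosstalkMatrix(m12=0.2, m21=0.0), background=np.zeros(2))
        assert out["gfp"].iloc[0] < 0
        clipped = cyto.unmix(ev, CrosstalkMatrix(m12=0.2, m21=0.0),
                             background=np.zeros(2), clip_negative=True)
        assert clipped["gfp"].iloc[0] == 0.0


class TestDualPositivityGate:
    def test_all_positive_cells_kept(self, rng):
        ev = make_events(rng, n=500)
        ev["gfp"], ev["mcherry"] = ev["ch1_raw"], ev["ch2_raw"]
        out = cyto.gate_dual_positive(ev, GateSpec(gfp_threshold=0.0, mcherry_threshold=0.0))
        assert out["pass_dual"].all()

    def test_dropout_cells_removed_at_expected_rate(self):
        # strains lose one fluorophore in ~2% of cells; the dual gate
        # should remove about that fraction
        cfg = identity_config(events_per_strain=20_000, loh_rate=0.02,
                              autofluorescence_mean=20.0, seed=6)
        ev = synthlib.simulate_strain_events(
            synthlib.TrueStrainState("s", 1, 1000.0, 0.25, 1000.0, 0.25), cfg, seed=6)
        blank = synthlib.simulate_strain_events(
            synthlib.TrueStrainState("b", 1, 0.0, 0.25, 0.0, 0.25), cfg, seed=7)
        m = CrosstalkMatrix(0.0, 0.0)
        un = cyto.unmix(ev, m, blank)
        out = cyto.gate_dual_positive(un, GateSpec(), blank_unmixed=cyto.unmix(blank, m, blank))
        removed = 1 - out["pass_dual"].mean()
        se = np.sqrt(0.02 * 0.98 / len(ev))
        assert abs(removed - 0.02) < 4 * se

    def test_threshold_above_all_cells_warns_and_empties(self, rng):
        ev = make_events(rng, n=200)
        ev["gfp"], ev["mcherry"] = ev["ch1_raw"], ev["ch2_raw"]
        with pytest.warns(UserWarning, match="removed every event"):
            out = cyto.gate_dual_positive(
                ev, GateSpec(gfp_threshold=1e12, mcherry_threshold=0.0))
        assert out["pass_dual"].sum() == 0

    def test_gate_flags_are_monotone(self, small_library):
        cfg, _, events, controls = small_library
        blank = controls["blank"]
        first = next(iter(events.values()))
        out = cyto.process_events(first, cfg.crosstalk, blank, GateSpec())
        assert not (out["pass_dual"] & ~out["pass_scatter"]).any()
        assert (out["gated"] == out["pass_dual"]).all()


class TestEventIO:
    def test_roundtrip(self, rng, tmp_path):
        ev = make_events(rng, n=50)
        path = tmp_path / "events.csv"
        cyto.write_events_csv(ev, path)
        back = cyto.read_events_csv(path)
        pd.testing.assert_frame_equal(ev, back)

    def test_missing_columns_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        pd.DataFrame({"cell_id": [1], "fsc": [1.0]}).to_csv(path, index=False)
        with pytest.raises(ValueError, match="missing event columns"):
            cyto.read_events_csv(path)
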