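"""Direct nonlinear fits, reciprocal diagnostics and secondary replots."""

import numpy as np
import pandas as pd
import pytest

import glkit as g
from glkit.errors import IdentifiabilityError, InputError
from glkit.kinetics_fit import VelocityDataset, aicc


class TestFitMechanism:
    def test_noiseless_recovery_is_exact(self, clean_velocity_data, table1):
        fit = g.fit_mechanism(clean_velocity_data, "ordered_bibi")
        assert fit.converged
        assert fit.params["Km_A"] == pytest.approx(table1.Km_A, rel=1e-6)
        assert fit.params["Km_B"] == pytest.approx(table1.Km_B, rel=1e-6)
        assert fit.params["Vmax"] == pytest.approx(table1.Vmax, rel=1e-6)

    def test_single_level_design_is_unidentifiable(self, table1):
        design = g.VelocityDesign(b_levels=(218.5,))
        data = g.gen_velocity_data(design, table1)
        with pytest.raises(IdentifiabilityError) as err:
            g.fit_mechanism(data, "ordered_bibi")
        assert err.value.parameter == "Km_B"

    def test_product_rows_rejected(self, table1):
        data = g.gen_inhibition_data("Q", "A", (0.0, 100.0, 200.0), truth=table1)
        with pytest.raises(InputError):
            g.fit_mechanism(data, "ordered_bibi")

    def test_noisy_fits_unbiased_with_calibrated_intervals(self, table1):
        """2% proportional noise, repeated simulate+fit: median relative
        bias < 2% per constant, 95% Wald coverage within [90%, 99%]."""
        n_rep = 200
        est = {k: [] for k in ("Vmax", "Km_A", "Km_B")}
        cover = {k: 0 for k in est}
        truth = {"Vmax": table1.Vmax, "Km_A": table1.Km_A, "Km_B": table1.Km_B}
        for rep in range(n_rep):
            data = g.gen_velocity_data(
                g.VelocityDesign(noise_proportional=0.02, seed=1000 + rep), table1)
            fit = g.fit_mechanism(data, "ordered_bibi")
            for k in est:
                est[k].append(fit.params[k])
                half = 1.96 * fit.stderr[k]
                if np.isfinite(half) and abs(fit.params[k] - truth[k]) <= half:
                    cover[k] += 1
        for k in est:
            bias = (np.median(est[k]) - truth[k]) / truth[k]
            assert abs(bias) < 0.02, f"{k} biased by {bias:.3%}"
            assert 0.90 <= cover[k] / n_rep <= 0.99, f"{k} coverage {cover[k]/n_rep:.2%}"

    def test_aicc_penalizes_parameters(self):
        assert aicc(1.0, 50, 4) > aicc(1.0, 50, 3)


class TestReciprocalDiagnostics:
    def test_sequential_data_intersects(self, clean_velocity_data):
        diag = g.reciprocal_diagnostics(clean_velocity_data, varied="A", fixed="B")
        assert diag.classification == "intersecting"
        assert len(diag.lines) == 8
        assert len(diag.intersections) == 8 * 7 // 2

    def test_ping_pong_data_parallel(self, table1):
        pp = g.MechanismParams(Vmax=table1.Vmax, Km_A=table1.Km_A,
                               Km_B=table1.Km_B, Ki_A=table1.Ki_A,
                               mechanism="ping_pong")
        data = g.gen_velocity_data(g.VelocityDesign(), pp)
        diag = g.reciprocal_diagnostics(data, varied="A", fixed="B")
        assert diag.classification == "parallel"
        assert diag.slope_cv < 0.05

    def test_ping_pong_slope_is_cosubstrate_independent(self, table1):
        """Algebraic check behind the parallel-line diagnostic: the
        ping-pong reciprocal slope Km_A/Vmax does not involve B."""
        pp = g.MechanismParams(Vmax=table1.Vmax, Km_A=table1.Km_A,
                               Km_B=table1.Km_B, Ki_A=table1.Ki_A,
                               mechanism="ping_pong")
        for b in (50.0, 200.0, 1000.0):
            a = np.array([5.0, 10.0, 20.0, 50.0])
            v = np.array([g.rate_ping_pong(pp, g.ConcentrationState(A=x, B=b)) for x in a])
            slope = np.polyfit(1 / a, 1 / v, 1)[0]
            assert slope == pytest.approx(pp.Km_A / pp.Vmax, rel=1e-10)

    def test_single_fixed_level_refused(self, table1):
        data = g.gen_velocity_data(g.VelocityDesign(b_levels=(218.5,)), table1)
        with pytest.raises(InputError):
            g.reciprocal_diagnostics(data, varied="A", fixed="B")


class TestLinearInhibition:
    def test_competitive_recovery(self, table1):
        """Q vs A is competitive: flat intercept replot, Kis = Ki_Q."""
        data = g.gen_inhibition_data("Q", "A", (0.0, 250.0, 500.0, 1000.0), truth=table1)
        rep = g.fit_linear_inhibition(data, "A", "Q")
        assert rep.pattern == "competitive"
        assert rep.linear
        assert rep.Kis == pytest.approx(table1.Ki_Q, rel=1e-6)
        assert np.isinf(rep.Kii)

    def test_competitive_kis_recovered_under_noise(self, table1):
        errs = []
        for rep_i in range(20):
            data = g.gen_inhibition_data(
                "Q", "A", (0.0, 250.0, 500.0, 1000.0), truth=table1,
                noise_proportional=0.02, seed=300 + rep_i)
            rep = g.fit_linear_inhibition(data, "A", "Q")
            errs.append(abs(rep.Kis - table1.Ki_Q) / table1.Ki_Q)
        assert np.median(errs) < 0.05

    def test_mixed_patterns_for_remaining_cells(self, table1):
        for inhibitor, varied, levels in (("Q", "B", (0.0, 250.0, 500.0, 1000.0)),
                                          ("P", "A", (0.0, 500.0, 1000.0, 2000.0)),
                                          ("P", "B", (0.0, 500.0, 1000.0, 2000.0))):
            data = g.gen_inhibition_data(inhibitor, varied, levels, truth=table1)
            rep = g.fit_linear_inhibition(data, varied, inhibitor)
            assert rep.pattern == "mixed", (inhibitor, varied)
            assert rep.Kis > 0 and rep.Kii > 0

    def test_pattern_concordance_with_scheme_prediction(self, table1, ordered_scheme):
        """The fitted label equals the pattern predicted from the scheme."""
        for inhibitor, varied in (("Q", "A"), ("Q", "B"), ("P", "A"), ("P", "B")):
            predicted = g.predict_inhibition_pattern(ordered_scheme, varied, inhibitor)
            levels = (0.0, 250.0, 500.0, 1000.0) if inhibitor == "Q" else \
                     (0.0, 500.0, 1000.0, 2000.0)
            data = g.gen_inhibition_data(inhibitor, varied, levels, truth=table1)
            fitted = g.fit_linear_inhibition(data, varied, inhibitor).pattern
            assert fitted == predicted, (inhibitor, varied)

    def test_zero_inhibitor_everywhere_is_none(self, table1):
        data = g.gen_inhibition_data("Q", "A", (0.0,), truth=table1)
        frame = pd.concat([data.frame] * 3, ignore_index=True)
        with pytest.raises(InputError):
            # inhibitor never varied -> not a valid 3-level design
            g.fit_linear_inhibition(VelocityDataset(frame), "A", "Q")

    def test_mixed_with_equal_constants(self):
        """Generator with Kis = Kii: recovered ratio within 10%."""
        truth = g.MechanismParams(Vmax=50.0, Km_A=10.0, Km_B=100.0, Ki_A=10.0,
                                  Ki_P=300.0, Ki_Q=300.0)
        # build synthetic mixed data directly from the linear Cleland form
        kis = kii = 300.0
        slope0, int0 = truth.Km_A / truth.Vmax, 1.0 / truth.Vmax
        rows = []
        for i_conc in (0.0, 150.0, 300.0, 600.0):
            for s in g.kinetics_core.reciprocal_grid(truth.Km_A):
                inv_v = slope0 * (1 + i_conc / kis) / s + int0 * (1 + i_conc / kii)
                rows.append({"A": s, "B": 100.0, "P": i_conc, "Q": 0.0, "v": 1.0 / inv_v})
        rep = g.fit_linear_inhibition(VelocityDataset(pd.DataFrame(rows)), "A", "P")
        assert rep.pattern == "mixed"
        assert rep.Kis / rep.Kii == pytest.approx(1.0, abs=0.1)


class TestDiscrimination:
    def test_noise_free_ordered_beats_ping_pong(self, clean_velocity_data):
        disc = g.discriminate_mechanisms(clean_velocity_data,
                                         ("ordered_bibi", "ping_pong"))
        assert disc.best == "ordered_bibi"
        rss = {f.mechanism: f.rss for f in disc.ranked}
        assert rss["ping_pong"] > rss["ordered_bibi"]

    def test_ordered_wins_on_noisy_replicates(self, table1):
        wins = 0
        n_rep = 100
        for rep in range(n_rep):
            data = g.gen_velocity_data(
                g.VelocityDesign(noise_proportional=0.02, seed=5000 + rep), table1)
            disc = g.discriminate_mechanisms(data, ("ordered_bibi", "ping_pong"))
            wins += disc.best == "ordered_bibi"
        assert wins >= 95

    def test_pure_noise_is_indeterminate(self):
        rng = np.random.default_rng(7)
        frame = pd.DataFrame({
            "A": np.tile([5.0, 10, 20, 50, 100], 5),
            "B": np.repeat([50.0, 100, 200, 400, 800], 5),
            "v": 10.0 + 0.01 * rng.standard_normal(25)})
        disc = g.discriminate_mechanisms(VelocityDataset(frame),
                                         ("ordered_bibi", "ping_pong"))
        assert disc.indeterminate

    def test_requires_two_candidates(self, clean_velocity_data):
        with pytest.raises(InputError):
            g.discriminate_mechanisms(clean_velocity_data, ("ordered_bibi",))


class TestTwoRouteConsistency:
    def test_replot_constants_match_direct_fit(self, table1):
        """Secondary-replot route and direct nonlinear route agree within
        5% on clean data (slope replot of the substrate-only family gives
        Km_A/Vmax·(1+Kia·Km_B/(Km_A·B)) etc.)."""
        data = g.gen_velocity_data(g.VelocityDesign(), table1)
        fit = g.fit_mechanism(data, "ordered_bibi")
        diag = g.reciprocal_diagnostics(data, varied="A", fixed="B")
        # secondary replots: slope and intercept vs 1/B are linear with
        # intercepts Km_A/Vmax and 1/Vmax
        inv_b = 1.0 / diag.lines["level"].to_numpy()
        s_b = np.polyfit(inv_b, diag.lines["slope"].to_numpy(), 1)
        i_b = np.polyfit(inv_b, diag.lines["intercept"].to_numpy(), 1)
        vmax_replot = 1.0 / i_b[1]
        km_a_replot = s_b[1] * vmax_replot
        km_b_replot = i_b[0] * vmax_replot
        assert vmax_replot == pytest.approx(fit.params["Vmax"], rel=0.05)
        assert km_a_replot == pytest.approx(fit.params["Km_A"], rel=0.05)
        assert km_b_replot == pytest.approx(fit.params["Km_B"], rel=0.05)


class TestDatasetIO:
    def test_csv_round_trip(self, clean_velocity_data, tmp_path):
        path = tmp_path / "v.csv"
        clean_velocity_data.to_csv(path)
        back = VelocityDataset.from_csv(path)
        assert np.allclose(back.frame["v"], clean_velocity_data.frame["v"])

    def test_negative_velocity_rejected(self):
        with pytest.raises(InputError):
            VelocityDataset(pd.DataFrame({"A": [1.0], "B": [1.0], "v": [-1.0]}))
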