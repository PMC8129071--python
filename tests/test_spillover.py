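import numpy as np
import pytest

import autospill as a
from autospill.io import EventTable, SpilloverMatrix
from autospill.spillover import (
    RefinementConfig,
    SingularSpilloverError,
    compensate,
    compensate_table,
    compensation_errors,
    initial_spillover,
    refine_step,
    refine_until_convergence,
    resolve_primary,
    traditional_spillover,
)


def _matrix(coef, primaries=None):
    coef = np.asarray(coef, dtype=float)
    d, c = coef.shape
    dyes = tuple(f"d{i}" for i in range(d))
    detectors = tuple(f"c{j}" for j in range(c))
    primary = primaries or {f"d{i}": i for i in range(d)}
    return SpilloverMatrix(coef, dyes, detectors, primary)


def _grid_control_events(s_row, levels):
    """Noise-free single-color events on a grid of fluorescence levels."""
    return np.outer(levels, s_row)


class TestResolvePrimary:
    def test_explicit_assignment_overrides_auto(self):
        table = EventTable(np.ones((20, 3)) * [1.0, 100.0, 2.0], ("a", "b", "c"))
        assert resolve_primary(table, "c") == "c"

    def test_auto_picks_highest_median_channel(self):
        table = EventTable(np.ones((20, 3)) * [1.0, 2.0, 100.0], ("a", "b", "c"))
        assert resolve_primary(table) == "c"

    def test_auto_matches_generator_peak(self, noisy_small_panel):
        spec = noisy_small_panel.spec
        for i, dye in enumerate(noisy_small_panel.controls.dyes):
            table = noisy_small_panel.controls.tables[dye]
            assert resolve_primary(table) == f"FL{i + 1}-A"


class TestInitialSpillover:
    def test_noise_free_recovery_is_exact(self, clean_small_panel):
        controls = clean_small_panel.controls
        s0 = initial_spillover(controls)
        np.testing.assert_allclose(
            s0.coef, clean_small_panel.spillover.coef, atol=1e-10
        )

    def test_spillover_free_control_gives_unit_row(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(100, 1e4, 500)
        values = np.zeros((500, 3))
        values[:, 1] = x
        controls = a.ControlSet(
            dyes=["d"],
            tables={"d": EventTable(values, ("c0", "c1", "c2"))},
            primaries={"d": "c1"},
        )
        s0 = initial_spillover(controls)
        np.testing.assert_allclose(s0.coef, [[0.0, 1.0, 0.0]], atol=1e-12)

    def test_smear_control_recovers_truth_within_noise(self):
        spec = a.SyntheticPanelSpec(
            n_dyes=2,
            n_detectors=2,
            intensity_models=("smear", "smear"),
            autofluorescence=False,
            debris_fraction=0.0,
            n_events=20_000,
            seed=5,
        )
        panel = a.generate_panel(spec)
        s0 = initial_spillover(panel.controls)
        np.testing.assert_allclose(s0.coef, panel.spillover.coef, atol=5e-3)


class TestCompensate:
    def test_identity_matrix_is_noop(self):
        y = np.random.default_rng(1).normal(size=(50, 3))
        np.testing.assert_allclose(compensate(y, _matrix(np.eye(3))), y)

    def test_square_roundtrip_to_machine_precision(self):
        rng = np.random.default_rng(2)
        s = _matrix([[1.0, 0.3, 0.1], [0.2, 1.0, 0.15], [0.05, 0.4, 1.0]])
        x0 = rng.uniform(0, 1e4, size=(200, 3))
        np.testing.assert_allclose(compensate(x0 @ s.coef, s), x0, rtol=1e-10)

    def test_rectangular_roundtrip_and_per_event_oracle(self):
        rng = np.random.default_rng(3)
        coef = np.array(
            [[1.0, 0.3, 0.2, 0.05], [0.1, 1.0, 0.4, 0.2]]
        )
        s = _matrix(coef)
        x0 = rng.uniform(0, 1e4, size=(100, 2))
        y = x0 @ coef + rng.normal(0, 5, size=(100, 4))
        x = compensate(y, s)
        for k in range(100):  # brute-force least-squares per event
            expected, *_ = np.linalg.lstsq(coef.T, y[k], rcond=None)
            np.testing.assert_allclose(x[k], expected, rtol=1e-8)
        # recovery of the true abundances is limited by the injected noise
        np.testing.assert_allclose(x, x0, atol=40.0)

    def test_singular_matrix_raises(self):
        coef = np.array([[1.0, 1.0], [1.0, 1.0]])
        s = SpilloverMatrix(coef, ("d0", "d1"), ("c0", "c1"), {"d0": 0, "d1": 1})
        with pytest.raises(SingularSpilloverError):
            compensate(np.ones((5, 2)), s)


class TestCompensationErrors:
    def _event_tables(self, s_true, u, levels=None):
        levels = levels if levels is not None else np.linspace(100, 1e5, 60)
        tables = {}
        for i in range(s_true.shape[0]):
            y = _grid_control_events(s_true[i], levels)
            tables[f"d{i}"] = compensate_table(
                EventTable(y, tuple(f"c{j}" for j in range(s_true.shape[1]))), u
            )
        return tables

    def test_perfect_compensation_gives_zero_errors(self):
        s_true = np.array([[1.0, 0.25, 0.05], [0.1, 1.0, 0.3], [0.02, 0.15, 1.0]])
        u = _matrix(s_true)
        e = compensation_errors(self._event_tables(s_true, u), u.dyes)
        assert e.max_abs() < 1e-10

    def test_matches_per_event_error_propagation_oracle(self):
        """Residual slopes after compensating with a perturbed matrix must
        match the per-event oracle: p_j / x_i for p = x (S U^-1 - I)."""
        rng = np.random.default_rng(4)
        s_true = np.array([[1.0, 0.25, 0.05], [0.1, 1.0, 0.3], [0.02, 0.15, 1.0]])
        delta = rng.uniform(-1, 1, size=s_true.shape) * 1e-3
        np.fill_diagonal(delta, 0.0)
        u = _matrix(s_true + delta)
        e = compensation_errors(self._event_tables(s_true, u), u.dyes)
        c = s_true @ np.linalg.inv(u.coef) - np.eye(3)
        for i in range(3):
            for j in range(3):
                if i != j:
                    # module slope is p_j / x-hat_i = c_ij / (1 + c_ii)
                    assert e.coef[i, j] == pytest.approx(
                        c[i, j] / (1.0 + c[i, i]), abs=1e-10
                    )

    def test_undercompensation_yields_positive_slope(self):
        s_true = np.array([[1.0, 0.3], [0.0, 1.0]])
        u = _matrix([[1.0, 0.2], [0.0, 1.0]])  # spill underestimated
        e = compensation_errors(self._event_tables(s_true, u), u.dyes)
        assert e.coef[0, 1] > 0


class TestRefineStep:
    def test_zero_errors_is_fixed_point(self):
        s = _matrix([[1.0, 0.2], [0.1, 1.0]])
        e = a.CompensationErrorMatrix(np.zeros((2, 2)), s.dyes)
        np.testing.assert_array_equal(refine_step(s, e).coef, s.coef)

    def test_one_step_reduces_error_on_noise_free_data(self):
        s_true = np.array([[1.0, 0.25, 0.05], [0.1, 1.0, 0.3], [0.02, 0.15, 1.0]])
        rng = np.random.default_rng(5)
        delta = rng.uniform(-1, 1, size=s_true.shape) * 5e-3
        np.fill_diagonal(delta, 0.0)
        u = _matrix(s_true + delta)
        tables = TestCompensationErrors()._event_tables(s_true, u)
        e = compensation_errors(tables, u.dyes)
        s_next = refine_step(u, e)
        before = np.abs(u.coef - s_true).max()
        after = np.abs(s_next.coef - s_true).max()
        assert after < before

    def test_damped_update_is_ten_percent_of_full(self):
        s = _matrix([[1.0, 0.2], [0.1, 1.0]])
        e = a.CompensationErrorMatrix(
            np.array([[0.0, 0.05], [-0.02, 0.0]]), s.dyes
        )
        damped = s.coef + 0.1 * (e.coef @ s.coef)
        expected = damped / np.diag(damped)[:, None]
        np.testing.assert_allclose(refine_step(s, e, damping=0.1).coef, expected, rtol=1e-12)

    def test_row_normalization_exact_after_step(self):
        s = _matrix([[1.0, 0.4], [0.3, 1.0]])
        e = a.CompensationErrorMatrix(np.array([[0.0, 0.1], [0.2, 0.0]]), s.dyes)
        out = refine_step(s, e)
        assert out.coef[0, 0] == 1.0 and out.coef[1, 1] == 1.0


class TestRefineUntilConvergence:
    def test_noise_free_panel_converges_to_truth(self, clean_small_panel):
        controls = clean_small_panel.controls
        s0 = initial_spillover(controls)
        final, trace, compensated = refine_until_convergence(controls, s0)
        assert trace.status == "converged"
        assert trace.records[-1].max_abs_error < 1e-4
        assert np.abs(final.coef - clean_small_panel.spillover.coef).max() < 1e-6
        assert len(compensated) == 4

    def test_true_matrix_is_immediate_fixed_point(self, clean_small_panel):
        final, trace, _ = refine_until_convergence(
            clean_small_panel.controls, clean_small_panel.spillover
        )
        assert trace.status == "converged"
        assert len(trace) == 1
        np.testing.assert_array_equal(final.coef, clean_small_panel.spillover.coef)

    def test_noisy_panel_converges(self, noisy_small_panel):
        controls = a.SpilloverModel(
            noisy_small_panel.controls, gate=False, autofluorescence=True
        ).fit()
        assert controls.converged
        assert controls.trace.records[-1].max_abs_error < 1e-4

    def test_row_normalization_holds_every_iteration(self, noisy_small_panel):
        from autospill.autofluorescence import augment_with_af
        from autospill.spillover import resolve_primaries

        controls = resolve_primaries(noisy_small_panel.controls)
        controls = augment_with_af(controls)
        s = initial_spillover(controls)
        for _ in range(3):
            compensated = {
                dye: compensate_table(controls.tables[dye], s) for dye in controls.dyes
            }
            e = compensation_errors(compensated, s.dyes)
            s = refine_step(s, e)
            for i, dye in enumerate(s.dyes):
                assert s.coef[i, s.primary[dye]] == 1.0

    def test_subsampling_needs_more_iterations(self):
        base = dict(
            n_dyes=4, n_detectors=5, debris_fraction=0.0, autofluorescence=True
        )
        big = a.generate_panel(a.SyntheticPanelSpec(n_events=20_000, seed=23, **base))
        small = a.generate_panel(a.SyntheticPanelSpec(n_events=500, seed=23, **base))
        fit_big = a.SpilloverModel(big.controls, gate=False, autofluorescence=True).fit()
        fit_small = a.SpilloverModel(
            small.controls, gate=False, autofluorescence=True
        ).fit()
        assert fit_big.converged and fit_small.converged
        assert fit_small.n_iterations >= fit_big.n_iterations

    def test_damped_regime_decays_monotonically_on_noise_free_data(
        self, clean_small_panel
    ):
        """Force damping from the start (oscillation threshold above the
        initial moving average): max |E| must be non-increasing."""
        controls = clean_small_panel.controls
        rng = np.random.default_rng(6)
        delta = rng.uniform(-1, 1, size=clean_small_panel.spillover.coef.shape) * 0.02
        for i, dye in enumerate(clean_small_panel.spillover.dyes):
            delta[i, clean_small_panel.spillover.primary[dye]] = 0.0
        u = SpilloverMatrix(
            clean_small_panel.spillover.coef + delta,
            clean_small_panel.spillover.dyes,
            clean_small_panel.spillover.detectors,
            clean_small_panel.spillover.primary,
        )
        config = RefinementConfig(oscillation_threshold=10.0, max_iterations=200)
        final, trace, _ = refine_until_convergence(controls, u, config)
        assert all(r.damping == 0.1 for r in trace.records)
        errs = [r.max_abs_error for r in trace.records]
        assert all(b <= x * (1 + 1e-9) for x, b in zip(errs, errs[1:]))
        assert trace.status == "converged"

    def test_forced_biexp_scale_still_converges(self, noisy_small_panel):
        from autospill.autofluorescence import augment_with_af
        from autospill.spillover import resolve_primaries

        controls = resolve_primaries(noisy_small_panel.controls)
        controls = augment_with_af(controls)
        s0 = initial_spillover(controls)
        config = RefinementConfig(scale_switch_threshold=10.0)
        final, trace, _ = refine_until_convergence(controls, s0, config)
        assert trace.status == "converged"
        assert any(r.scale == "biexp" for r in trace.records)

    def test_nonconvergence_reports_status_not_raise(self, noisy_small_panel):
        from autospill.spillover import resolve_primaries

        controls = resolve_primaries(noisy_small_panel.controls)
        s0 = initial_spillover(controls)
        config = RefinementConfig(convergence_threshold=1e-15, max_iterations=3)
        _, trace, _ = refine_until_convergence(controls, s0, config)
        assert trace.status == "not_converged"
        assert len(trace) == 3


class TestTraditionalSpillover:
    def test_agrees_with_regression_on_clean_bimodal(self):
        spec = a.SyntheticPanelSpec(
            n_dyes=2,
            n_detectors=2,
            intensity_models=("bimodal", "bimodal"),
            autofluorescence=False,
            debris_fraction=0.0,
            n_events=20_000,
            seed=9,
        )
        panel = a.generate_panel(spec)
        trad, flagged = traditional_spillover(panel.controls)
        robust = initial_spillover(panel.controls)
        assert not flagged.any()
        np.testing.assert_allclose(trad.coef, robust.coef, atol=5e-3)

    def test_smear_control_hurts_traditional_more(self):
        spec = a.SyntheticPanelSpec(
            n_dyes=2,
            n_detectors=2,
            intensity_models=("smear", "smear"),
            autofluorescence=False,
            debris_fraction=0.0,
            n_events=20_000,
            seed=10,
        )
        panel = a.generate_panel(spec)
        trad, _ = traditional_spillover(panel.controls)
        fit = a.SpilloverModel(panel.controls, gate=False).fit()
        err_trad = np.abs(trad.coef - panel.spillover.coef).max()
        err_fit = np.abs(fit.spillover.coef - panel.spillover.coef).max()
        assert err_fit < err_trad

    def test_identical_populations_flagged(self):
        values = np.ones((100, 2))
        values[:, 0] = 5.0  # constant primary: no separation
        controls = a.ControlSet(
            dyes=["d"],
            tables={"d": a.EventTable(values, ("c0", "c1"))},
            primaries={"d": "c0"},
        )
        _, flagged = traditional_spillover(controls)
        assert flagged.all()
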