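"""Equilibrium enumeration, Jacobians, stability labels, and their oracles."""

import numpy as np
import pytest

import sesdebt as sd
from sesdebt import equilibria as eq
from sesdebt.equilibria import interior_root_scan


def finite_difference_jacobian(state, params, variant="extended", rel_step=1e-6):
    """Central-difference oracle for the analytic Jacobian."""
    f = sd.__dict__[f"rhs_{variant}"]
    y = np.asarray(state, dtype=float)
    n = y.size
    J = np.zeros((n, n))
    for j in range(n):
        h = rel_step * max(abs(y[j]), 1.0)
        up, dn = y.copy(), y.copy()
        up[j] += h
        dn[j] -= h
        J[:, j] = (f(up, params) - f(dn, params)) / (2.0 * h)
    return J


class TestInteriorEquilibria:
    def test_no_harvest_single_stable_equilibrium(self, params):
        recs = eq.interior_equilibria(params.replace(h=0.0))
        assert len(recs) == 1
        rec = recs[0]
        assert rec.stability == "stable" and rec.feasible
        np.testing.assert_allclose(rec.state, [700.0, 625.0, 2500.0 / 3.0], rtol=1e-12)

    def test_no_harvest_equilibrium_is_global_attractor_from_afar(self, params, fast_opts):
        traj = sd.integrate("extended", [350.0, 10.0, 100.0], params.replace(h=0.0),
                            (0.0, 20_000.0), fast_opts)
        np.testing.assert_allclose(traj.y_end, [700.0, 625.0, 2500.0 / 3.0], rtol=1e-5)

    def test_bistable_regime_has_two_interior_points(self, bistable):
        recs = eq.interior_equilibria(bistable)
        assert [r.kind for r in recs] == ["interior-low", "interior-high"]
        assert [r.stability for r in recs] == ["unstable", "stable"]

    def test_above_fold_no_interior_points(self, params):
        assert eq.interior_equilibria(params.replace(c0=0.0044, h=0.002)) == []

    def test_every_record_is_a_true_equilibrium(self, bistable):
        for rec in eq.interior_equilibria(bistable):
            assert rec.residual < 1e-8

    def test_closed_form_agrees_with_scan_oracle(self, rng):
        """Quadratic roots vs. dense sign-change scan over random (c0, h)."""
        base = sd.ModelParams()
        for _ in range(200):
            p = base.replace(
                c0=float(rng.uniform(1e-4, 0.044)), h=float(rng.uniform(1e-5, 0.0132))
            )
            closed = sorted(r.R for r in eq.interior_equilibria(p))
            scanned = interior_root_scan(p, n=100_000)
            assert len(closed) == len(scanned)
            for a, b in zip(closed, scanned):
                assert abs(a - b) < 1e-4 * p.K_max

    def test_baseline_interior_matches_closed_form(self, params):
        p = params.replace(c0=0.01, h=0.004)
        (rec,) = eq.interior_equilibria(p, "baseline")
        assert rec.R == pytest.approx(p.K_max * (1 - p.h * p.q / p.c0), rel=1e-12)
        assert rec.P == pytest.approx(p.q * rec.R, rel=1e-12)
        assert eq.interior_equilibria(params.replace(c0=0.001, h=0.002), "baseline") == []

    def test_quasistatic_shares_extended_equilibria(self, bistable):
        ext = eq.interior_equilibria(bistable, "extended")
        qs = eq.interior_equilibria(bistable, "quasistatic")
        assert len(ext) == len(qs)
        for a, b in zip(ext, qs):
            np.testing.assert_allclose(a.state[:2], b.state, rtol=1e-12)

    def test_numeric_fallback_for_alternative_forms(self, params):
        p = params.replace(c0=0.0044, h=0.001, es_form="exponential")
        recs = eq.interior_equilibria(p)
        assert recs, "alternative form should retain a sustainable equilibrium"
        for rec in recs:
            assert rec.residual < 1e-8


class TestBoundaryEquilibria:
    def test_human_free_point_coordinates(self, params):
        recs = {r.kind: r for r in eq.boundary_equilibria(params)}
        np.testing.assert_allclose(
            recs["human-free"].state, [700.0, 0.0, 2500.0 / 3.0], rtol=1e-12
        )

    def test_human_free_point_invadable_by_humans(self, params, rng):
        """Positive services and r > 0 make the empty system unstable."""
        for _ in range(10):
            p = params.replace(
                c0=float(rng.uniform(1e-4, 0.044)), h=float(rng.uniform(0.0, 0.0132))
            )
            recs = {r.kind: r for r in eq.boundary_equilibria(p)}
            assert recs["human-free"].stability == "unstable"
            assert np.max(recs["human-free"].eigenvalues.real) == pytest.approx(p.r)

    def test_origin_has_zero_residual(self, bistable):
        recs = {r.kind: r for r in eq.boundary_equilibria(bistable)}
        assert recs["origin"].residual == 0.0


class TestJacobian:
    def test_coupling_structure_zeros(self, bistable, rng):
        for _ in range(20):
            state = rng.uniform([1, 1, 10], [700, 700, 1000])
            J = sd.jacobian(state, bistable)
            assert J[0, 2] == 0.0 and J[1, 0] == 0.0 and J[2, 1] == 0.0

    @pytest.mark.parametrize("variant", ["extended", "baseline", "quasistatic"])
    def test_matches_finite_differences(self, bistable, rng, variant):
        dim = 3 if variant == "extended" else 2
        for _ in range(100):
            state = rng.uniform([1.0, 1.0, 10.0][:dim], [700.0, 700.0, 1000.0][:dim])
            J = sd.jacobian(state, bistable, variant)
            J_fd = finite_difference_jacobian(state, bistable, variant)
            np.testing.assert_allclose(J_fd, J, rtol=1e-5, atol=1e-8)

    def test_richness_diagonal_is_minus_relaxation_rate(self, bistable, rng):
        state = rng.uniform([1, 1, 10], [700, 700, 1000])
        assert sd.jacobian(state, bistable)[2, 2] == -bistable.d

    def test_no_harvest_equilibrium_is_linearly_stable(self, params):
        (rec,) = eq.interior_equilibria(params.replace(h=0.0))
        assert np.all(rec.eigenvalues.real < 0)

    def test_regularization_floor_rejected(self, params):
        with pytest.raises(ValueError, match="floor"):
            sd.jacobian([100.0, 10.0, 0.0], params)


class TestStabilityClassification:
    def test_non_equilibrium_input_rejected(self, params):
        rec = eq.EquilibriumRecord(
            variant="extended", kind="interior-high", state=np.array([300.0, 300.0, 500.0])
        )
        with pytest.raises(ValueError, match="not an equilibrium"):
            eq.classify_stability(rec, params)

    def test_stable_point_attracts_small_perturbations(self, bistable, fast_opts):
        recs = {r.kind: r for r in eq.interior_equilibria(bistable)}
        high = recs["interior-high"]
        t_back = 50.0 / bistable.r
        traj = sd.integrate("extended", high.state * 1.001, bistable, (0.0, t_back), fast_opts)
        rel = np.linalg.norm(traj.y_end - high.state) / np.linalg.norm(high.state)
        assert rel < 1e-4

    def test_unstable_point_repels_along_leading_eigenvector(self, bistable, fast_opts):
        recs = {r.kind: r for r in eq.interior_equilibria(bistable)}
        low = recs["interior-low"]
        J = sd.jacobian(low.state, bistable)
        vals, vecs = np.linalg.eig(J)
        v = np.real(vecs[:, np.argmax(vals.real)])
        start = np.clip(low.state + 1e-4 * np.linalg.norm(low.state) * v, 0.0, None)
        traj = sd.integrate("extended", start, bistable, (0.0, 50.0 / bistable.r), fast_opts)
        rel = np.linalg.norm(traj.y_end - low.state) / np.linalg.norm(low.state)
        assert rel > 0.01


def test_equilibrium_table_columns(bistable):
    records = eq.interior_equilibria(bistable) + eq.boundary_equilibria(bistable)
    df = eq.equilibrium_table(records)
    assert list(df.columns[:4]) == ["kind", "R", "P", "S"]
    assert set(df["stability"]) <= {"stable", "unstable", "marginal"}
    assert (df["residual"] < 1e-8).all()
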