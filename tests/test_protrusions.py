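"""Tests for protrusion dynamics and the Eshelby inclusion mechanics."""

import itertools

import numpy as np
import pytest
from scipy.integrate import quad

from mesomig.protrusions import (
    ElasticityParams,
    InvalidThresholdsError,
    Protrusion,
    StrainParams,
    ThresholdSet,
    axial_constraint_factor,
    birth_protrusion,
    classify_events,
    constrained_strain,
    eshelby_tensor,
    free_strain,
    isotropic_stiffness,
    spheroid_eshelby_integrals,
    step_protrusions,
    update_length,
)
from mesomig.surface import SurfaceComponent, SurfaceGrid

GRID = SurfaceGrid(n_alpha=16, n_beta=8)
STRAIN = StrainParams()
ELAST = ElasticityParams()


def make_protrusion(pid=0, length=50.0, alpha=0.2, beta=np.pi / 2, birth=5.0):
    return Protrusion(
        id=pid,
        direction=np.array([np.sin(beta) * np.cos(alpha), np.sin(beta) * np.sin(alpha), np.cos(beta)]),
        length_um=length,
        alpha=alpha,
        beta=beta,
        birth_time_min=birth,
    )


def component_at(row, col, grid=GRID):
    return SurfaceComponent(
        centroid_alpha=float(grid.alpha[col]),
        centroid_beta=float(grid.beta[row]),
        rows=np.array([row]),
        cols=np.array([col]),
        area=1.0,
    )


class TestThresholds:
    def test_valid_ordering_accepted(self):
        ThresholdSet(s_birth=85, s_exp=76, s_ret=0)

    @pytest.mark.parametrize(
        "birth, exp, ret",
        [(50, 76, 0), (85, 76, 76), (85, 76, 90)],
    )
    def test_invalid_orderings_rejected(self, birth, exp, ret):
        with pytest.raises(InvalidThresholdsError):
            ThresholdSet(s_birth=birth, s_exp=exp, s_ret=ret)


class TestClassification:
    def test_no_death_at_threshold_equality(self):
        """s == s_ret keeps the protrusion (the retract branch is s_ret <= s)."""
        thresholds = ThresholdSet(s_birth=85, s_exp=76, s_ret=0)
        p = make_protrusion()
        s = np.zeros(GRID.shape)
        actions, _ = classify_events(s, np.zeros(GRID.shape), [], [p], thresholds, GRID)
        assert actions[p.id] == "hold"

    def test_birth_above_s_birth(self):
        thresholds = ThresholdSet(s_birth=85, s_exp=76, s_ret=0)
        s = np.zeros(GRID.shape)
        s[4, 3] = 90.0
        comp = component_at(4, 3)
        _, births = classify_events(s, np.zeros(GRID.shape), [comp], [], thresholds, GRID)
        assert births == [comp]

    def test_low_signal_kills(self):
        thresholds = ThresholdSet(s_birth=85, s_exp=76, s_ret=10)
        p = make_protrusion()
        s = np.full(GRID.shape, 5.0)
        actions, _ = classify_events(s, np.zeros(GRID.shape), [], [p], thresholds, GRID)
        assert actions[p.id] == "die"

    def test_high_signal_reinforces(self):
        thresholds = ThresholdSet(s_birth=85, s_exp=76, s_ret=0)
        p = make_protrusion()
        s = np.full(GRID.shape, 80.0)
        actions, _ = classify_events(s, np.zeros(GRID.shape), [], [p], thresholds, GRID)
        assert actions[p.id] == "reinforce"

    def test_no_simultaneous_birth_and_death(self, rng):
        """With a valid ordering, a birth site (s > s_birth) can never satisfy
        the death rule (s < s_ret) since s_ret < s_birth."""
        thresholds = ThresholdSet(s_birth=60, s_exp=40, s_ret=20)
        for _ in range(50):
            s_val = rng.uniform(0, 100)
            births_possible = s_val > thresholds.s_birth
            death_possible = s_val < thresholds.s_ret
            assert not (births_possible and death_possible)

    def test_occupied_component_reinforces_instead_of_double_birth(self):
        thresholds = ThresholdSet(s_birth=85, s_exp=76, s_ret=0)
        p = make_protrusion(alpha=float(GRID.alpha[3]), beta=float(GRID.beta[4]))
        s = np.full(GRID.shape, 90.0)
        comp = component_at(4, 3)
        actions, births = classify_events(s, np.zeros(GRID.shape), [comp], [p], thresholds, GRID)
        assert births == []
        assert actions[p.id] == "reinforce"


class TestFreeStrain:
    def test_zero_ds_zero_strain(self):
        eps, inc = free_strain(0.0, 50.0, STRAIN, "exp")
        assert eps == 0.0 and inc == 0.0

    def test_worked_expansion_example(self):
        # alpha_exp=0.14 mm, beta_exp=100, ds=100, length 70 um
        eps, inc = free_strain(100.0, 70.0, StrainParams(beta_exp=100.0), "exp")
        assert inc == pytest.approx(70.0)
        assert eps == pytest.approx(1.0)

    def test_increment_saturates_at_alpha(self):
        _, inc_small = free_strain(1e2, 1e6, STRAIN, "exp")
        _, inc_huge = free_strain(1e9, 1e6, STRAIN, "exp")
        assert inc_huge < 1000.0 * STRAIN.alpha_exp_mm + 1e-9
        assert inc_huge == pytest.approx(1000.0 * STRAIN.alpha_exp_mm, rel=1e-6)
        assert inc_small < inc_huge

    def test_retraction_negative_increment(self):
        eps, inc = free_strain(-10.0, 50.0, STRAIN, "ret")
        expected = 1000.0 * STRAIN.alpha_ret_mm * (-10.0) / (STRAIN.beta_ret - 10.0)
        assert inc == pytest.approx(expected)
        assert eps < 0

    def test_retraction_denominator_guard_full_retraction(self):
        eps, inc = free_strain(-60.0, 50.0, StrainParams(beta_ret=54.86), "ret")
        assert inc == -50.0 and eps == -1.0

    def test_mode_sign_mismatch_rejected(self):
        with pytest.raises(ValueError):
            free_strain(-1.0, 50.0, STRAIN, "exp")
        with pytest.raises(ValueError):
            free_strain(1.0, 50.0, STRAIN, "ret")


def _integrals_oracle(axes):
    a1, a2, a3 = axes

    def delta(s):
        return np.sqrt((a1 * a1 + s) * (a2 * a2 + s) * (a3 * a3 + s))

    vol = 2 * np.pi * a1 * a2 * a3
    I = [vol * quad(lambda s, ai=ai: 1 / ((ai * ai + s) * delta(s)), 0, np.inf, limit=200)[0] for ai in axes]
    Iij = np.zeros((3, 3))
    for i, ai in enumerate(axes):
        for j, aj in enumerate(axes):
            Iij[i, j] = vol * quad(
                lambda s: 1 / ((ai * ai + s) * (aj * aj + s) * delta(s)), 0, np.inf, limit=200
            )[0]
    return I, Iij


def _eshelby_oracle(t, nu):
    """Eshelby tensor assembled from numerically integrated I-integrals."""
    I, Iij = _integrals_oracle((t, 1.0, 1.0))
    a = np.array([t, 1.0, 1.0])
    Q = 3.0 / (8 * np.pi * (1 - nu))
    R = (1 - 2 * nu) / (8 * np.pi * (1 - nu))
    S = np.zeros((6, 6))
    for i in range(3):
        S[i, i] = Q * a[i] ** 2 * Iij[i, i] + R * I[i]
        for j in range(3):
            if i != j:
                S[i, j] = (Q / 3) * a[j] ** 2 * Iij[i, j] - R * I[i]
    pairs = {3: (1, 2), 4: (0, 2), 5: (0, 1)}
    for v, (i, j) in pairs.items():
        S[v, v] = 2 * (
            ((a[i] ** 2 + a[j] ** 2) / (16 * np.pi * (1 - nu))) * Iij[i, j]
            + ((1 - 2 * nu) / (16 * np.pi * (1 - nu))) * (I[i] + I[j])
        )
    return S


class TestEshelby:
    def test_sphere_component_closed_form(self):
        nu = 0.3
        S = eshelby_tensor(1.0, nu)
        assert S[0, 0] == pytest.approx((7 - 5 * nu) / (15 * (1 - nu)), abs=1e-12)

    def test_sphere_isotropy(self):
        S = eshelby_tensor(1.0, 0.25)
        assert S[0, 0] == S[1, 1] == S[2, 2]
        assert S[3, 3] == S[4, 4] == S[5, 5]

    def test_needle_limit_axial_vanishes(self):
        assert eshelby_tensor(1e6, 0.3)[0, 0] < 1e-6

    @pytest.mark.parametrize("t", [1.3, 2.5, 7.0, 20.0])
    @pytest.mark.parametrize("nu", [0.0, 0.3, 0.45])
    def test_matches_numerical_integral_oracle(self, t, nu):
        assert np.allclose(eshelby_tensor(t, nu), _eshelby_oracle(t, nu), rtol=1e-6, atol=1e-9)

    def test_prolate_convention_enforced(self):
        with pytest.raises(ValueError):
            spheroid_eshelby_integrals(0.5)


class TestConstrainedStrain:
    E1 = np.array([1.0, 0, 0, 0, 0, 0])

    def test_identical_media_reduce_to_S_contraction(self):
        S = eshelby_tensor(3.0, 0.3)
        C = isotropic_stiffness(1e7, 0.3)
        assert np.allclose(constrained_strain(self.E1, C, C, S), S @ self.E1, atol=1e-14)

    def test_soft_matrix_limit_recovers_free_strain(self):
        el = ElasticityParams(e_protrusion_Pa=1e7, e_matrix_Pa=1e7 * 1e-8)
        assert axial_constraint_factor(2.0, el) == pytest.approx(1.0, rel=1e-4)

    def test_rigid_matrix_limit_suppresses_strain(self):
        el = ElasticityParams(e_protrusion_Pa=1e7, e_matrix_Pa=1e7 * 1e8)
        assert abs(axial_constraint_factor(2.0, el)) < 1e-4

    def test_matches_first_principles_assembly(self, rng):
        """Literal 6x6 evaluation assembled independently, 100 random draws."""
        for _ in range(100):
            t = rng.uniform(1.0, 30.0)
            nu_i, nu_m = rng.uniform(0.0, 0.45, 2)
            e_i, e_m = 10 ** rng.uniform(2, 8, 2)
            eps_f = rng.normal(size=6)
            S = eshelby_tensor(t, nu_m)

            def lame_stiffness(E, nu):
                lam = E * nu / ((1 + nu) * (1 - 2 * nu))
                mu = E / (2 * (1 + nu))
                C = np.diag([2 * mu] * 3 + [mu] * 3).astype(float)
                C[:3, :3] += lam
                return C

            C_I = lame_stiffness(e_i, nu_i)
            C_M = lame_stiffness(e_m, nu_m)
            expected = S @ np.linalg.solve((C_I - C_M) @ S + C_M, C_I @ eps_f)
            got = constrained_strain(
                eps_f, isotropic_stiffness(e_i, nu_i), isotropic_stiffness(e_m, nu_m), S
            )
            assert np.allclose(got, expected, rtol=1e-10, atol=1e-12)

    def test_stiffer_matrix_shortens_increment(self):
        factors = [
            axial_constraint_factor(10.0, ElasticityParams(e_matrix_Pa=em))
            for em in (1e3, 1e4, 1e5, 1e6, 1e7)
        ]
        assert all(f1 >= f2 for f1, f2 in zip(factors, factors[1:]))
        assert all(f > 0 for f in factors)


class TestLengthUpdate:
    def test_no_strain_no_change(self):
        p = make_protrusion(length=70.0)
        update_length(p, 0.0, 0.0)
        assert p.length_um == 70.0 and p.alive

    def test_death_branch_zeroes_length(self):
        p = make_protrusion(length=70.0)
        update_length(p, 0.0, -1.0)
        assert p.length_um == 0.0 and not p.alive

    def test_growth_arithmetic(self):
        p = make_protrusion(length=70.0)
        update_length(p, 0.1, 0.0)
        assert p.length_um == pytest.approx(77.0)


class TestBirth:
    def test_direction_follows_centroid(self):
        comp = SurfaceComponent(0.0, np.pi / 2, np.array([4]), np.array([0]), 1.0)
        p = birth_protrusion(comp, 100.0, STRAIN, ELAST, 0, 10.0)
        assert np.allclose(p.direction, [1, 0, 0], atol=1e-12)
        assert p.length_um > 0

    def test_zero_ds_no_birth(self):
        comp = SurfaceComponent(0.0, np.pi / 2, np.array([4]), np.array([0]), 1.0)
        assert birth_protrusion(comp, 0.0, STRAIN, ELAST, 0, 10.0) is None

    def test_antipodal_births_oppose(self):
        c1 = SurfaceComponent(0.0, np.pi / 2, np.array([4]), np.array([0]), 1.0)
        c2 = SurfaceComponent(np.pi, np.pi / 2, np.array([4]), np.array([8]), 1.0)
        p1 = birth_protrusion(c1, 50.0, STRAIN, ELAST, 0, 0.0)
        p2 = birth_protrusion(c2, 50.0, STRAIN, ELAST, 1, 0.0)
        assert p1.direction @ p2.direction == pytest.approx(-1.0)

    def test_seed_length_is_constrained_increment(self):
        comp = SurfaceComponent(0.0, np.pi / 2, np.array([4]), np.array([0]), 1.0)
        ds = 200.0
        p = birth_protrusion(comp, ds, STRAIN, ELAST, 0, 0.0)
        free = 1000.0 * STRAIN.alpha_exp_mm * ds / (STRAIN.beta_exp + ds)
        factor = axial_constraint_factor(1.0 + 1e-6, ELAST)
        assert p.length_um == pytest.approx(factor * free)


class TestPopulationStep:
    def test_death_is_permanent_and_new_birth_is_new_object(self):
        thresholds = ThresholdSet(s_birth=85, s_exp=76, s_ret=10)
        ids = itertools.count(100)
        p = make_protrusion(pid=7, alpha=float(GRID.alpha[3]), beta=float(GRID.beta[4]))
        s = np.zeros(GRID.shape)  # below s_ret: the protrusion dies
        out = step_protrusions([p], [], s, np.zeros(GRID.shape), thresholds,
                               STRAIN, ELAST, GRID, 10.0, ids)
        assert out == [] and not p.alive
        # a later birth at the same centroid gets a fresh identity
        s2 = np.full(GRID.shape, 90.0)
        ds2 = np.full(GRID.shape, 50.0)
        comp = component_at(4, 3)
        out2 = step_protrusions([], [comp], s2, ds2, thresholds,
                                STRAIN, ELAST, GRID, 15.0, ids)
        assert len(out2) == 1 and out2[0].id != 7 and out2[0].birth_time_min == 15.0
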