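"""Protrusion birth, growth, retraction and death under ECM constraint.

A protrusion is a one-dimensional bar of fixed unit direction e and length
||p||, rooted at a membrane centroid.  The accumulated signal variation
delta-s drives a saturating free strain

    free length increment = alpha * ds / (beta + ds)        (<= alpha)

which, interpreted as an eigenstrain of a prolate-spheroidal inclusion
embedded in the linear-elastic ECM, is reduced by Eshelby's solution

    eps_c = S [ (C_I - C_M) S + C_M ]^{-1} C_I eps_f

before updating the length as ||p||_{n+1} = (1 + eps_EXP + eps_RET)||p||_n.
Signal thresholds gate the events: s above s_birth sprouts a new protrusion,
s above s_exp reinforces an existing one, s below s_ret kills it.

The saturating-ratio reading of the free-strain law is deliberate: with the
calibrated beta values the product form diverges, while the ratio bounds the
free increment by alpha, which is the only biologically sized choice.  The
form is isolated in :func:`free_strain` so alternatives can be swapped in.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .surface import SurfaceComponent, sphere_direction

__all__ = [
    "InvalidThresholdsError",
    "Protrusion",
    "ThresholdSet",
    "StrainParams",
    "ElasticityParams",
    "classify_events",
    "free_strain",
    "spheroid_eshelby_integrals",
    "eshelby_tensor",
    "isotropic_stiffness",
    "constrained_strain",
    "axial_constraint_factor",
    "update_length",
    "birth_protrusion",
    "step_protrusions",
]


class InvalidThresholdsError(ValueError):
    """Threshold ordering violates the biological validity rule."""


@dataclass
class Protrusion:
    """A live (or dead) dendritic protrusion."""

    id: int
    direction: np.ndarray
    length_um: float
    alpha: float
    beta: float
    birth_time_min: float
    alive: bool = True
    ds_accum: float = 0.0

    def __post_init__(self) -> None:
        self.direction = np.asarray(self.direction, dtype=float)
        n = np.linalg.norm(self.direction)
        if not np.isclose(n, 1.0, atol=1e-9):
            raise ValueError("protrusion direction must be a unit vector")
        if self.length_um < 0:
            raise ValueError("length must be >= 0")


@dataclass(frozen=True)
class ThresholdSet:
    """Signal filter levels; biological validity requires s_ret < s_exp < s_birth."""

    s_birth: float = 85.0
    s_exp: float = 76.0
    s_ret: float = 0.0
    s_binary: float = 62500.0

    def __post_init__(self) -> None:
        if min(self.s_birth, self.s_exp, self.s_ret, self.s_binary) < 0:
            raise ValueError("thresholds must be >= 0")
        if not (self.s_ret < self.s_exp < self.s_birth):
            raise InvalidThresholdsError(
                "require s_ret < s_exp < s_birth "
                f"(got {self.s_ret}, {self.s_exp}, {self.s_birth})"
            )


@dataclass(frozen=True)
class StrainParams:
    """Free expansion/retraction law parameters (alpha in mm, beta dimensionless)."""

    alpha_exp_mm: float = 0.14
    beta_exp: float = 100.0
    alpha_ret_mm: float = 0.05
    beta_ret: float = 54.86

    def __post_init__(self) -> None:
        if self.alpha_exp_mm <= 0 or self.alpha_ret_mm <= 0:
            raise ValueError("alpha parameters must be > 0")
        if self.beta_exp <= 0 or self.beta_ret <= 0:
            raise ValueError("beta parameters must be > 0")


@dataclass(frozen=True)
class ElasticityParams:
    """Inclusion (protrusion) and matrix (ECM) elastic constants."""

    e_protrusion_Pa: float = 1.0e7
    e_matrix_Pa: float = 1.0e4
    nu_protrusion: float = 0.3
    nu_matrix: float = 0.3
    diameter_um: float = 2.0

    def __post_init__(self) -> None:
        if self.e_protrusion_Pa <= 0 or self.e_matrix_Pa <= 0:
            raise ValueError("elastic moduli must be > 0")
        for nu in (self.nu_protrusion, self.nu_matrix):
            if not (0 <= nu < 0.5):
                raise ValueError("Poisson ratio must be in [0, 0.5)")
        if self.diameter_um <= 0:
            raise ValueError("protrusion diameter must be > 0")


# ---------------------------------------------------------------------------
# event classification


def classify_events(
    s_map: np.ndarray,
    ds_map: np.ndarray,
    components: list[SurfaceComponent],
    protrusions: list[Protrusion],
    thresholds: ThresholdSet,
    grid,
) -> tuple[dict[int, str], list[SurfaceComponent]]:
    """Decide the per-protrusion action and the list of new-birth components.

    Live protrusions: signal above s_exp reinforces, below s_ret kills
    (equality holds — no death at s == s_ret), otherwise the protrusion holds
    (retracting only if its accumulated delta-s is negative).  A component
    whose signal exceeds s_birth sprouts a new protrusion unless it already
    contains a live protrusion's centroid, in which case it reinforces that
    one instead of double-creating.
    """
    actions: dict[int, str] = {}
    live = [p for p in protrusions if p.alive]
    for p in live:
        row, col = _nearest_site(p.alpha, p.beta, grid)
        s_here = float(s_map[row, col])
        if s_here > thresholds.s_exp:
            actions[p.id] = "reinforce"
        elif s_here >= thresholds.s_ret:
            ds_here = float(ds_map[row, col])
            actions[p.id] = "retract" if ds_here < 0 else "hold"
        else:
            actions[p.id] = "die"
    births: list[SurfaceComponent] = []
    for comp in components:
        row, col = _nearest_site(comp.centroid_alpha, comp.centroid_beta, grid)
        if float(s_map[row, col]) <= thresholds.s_birth:
            continue
        occupied = False
        for p in live:
            prow, pcol = _nearest_site(p.alpha, p.beta, grid)
            if comp.contains_site(prow, pcol):
                occupied = True
                break
        if not occupied:
            births.append(comp)
    return actions, births


def _nearest_site(alpha: float, beta: float, grid) -> tuple[int, int]:
    col = int(np.floor((alpha % (2 * np.pi)) / (2 * np.pi) * grid.n_alpha)) % grid.n_alpha
    row = int(np.floor(beta / np.pi * grid.n_beta))
    row = min(max(row, 0), grid.n_beta - 1)
    return row, col


# ---------------------------------------------------------------------------
# strain laws


def free_strain(
    ds: float, length_um: float, params: StrainParams, mode: str
) -> tuple[float, float]:
    """Free (unconstrained) strain and length increment.

    Returns ``(eps_f, increment_um)`` where ``increment_um = eps_f * length``.
    Expansion (``mode='exp'``, ds >= 0) saturates at alpha_exp; retraction
    (``mode='ret'``, ds < 0) uses the retraction constants, with the
    denominator guarded: if beta_ret + ds <= 0 the protrusion fully retracts.
    The strain magnitude is capped at 1 (infinitesimal-strain regime).
    """
    if length_um <= 0:
        raise ValueError("free_strain requires length > 0 (births are separate)")
    if mode == "exp":
        if ds < 0:
            raise ValueError("expansion requires ds >= 0")
        inc_um = 1000.0 * params.alpha_exp_mm * ds / (params.beta_exp + ds)
    elif mode == "ret":
        if ds >= 0:
            raise ValueError("retraction requires ds < 0")
        denom = params.beta_ret + ds
        if denom <= 0:
            inc_um = -length_um
        else:
            inc_um = 1000.0 * params.alpha_ret_mm * ds / denom
    else:
        raise ValueError("mode must be 'exp' or 'ret'")
    eps = inc_um / length_um
    eps = float(np.clip(eps, -1.0, 1.0))
    return eps, eps * length_um


def free_increment_um(ds: float, params: StrainParams) -> float:
    """Saturating free length increment for ds >= 0 (used at birth)."""
    if ds < 0:
        raise ValueError("ds must be >= 0")
    return 1000.0 * params.alpha_exp_mm * ds / (params.beta_exp + ds)


# ---------------------------------------------------------------------------
# Eshelby mechanics (prolate spheroid, long axis = x1)


def spheroid_eshelby_integrals(aspect_ratio: float) -> dict[str, float]:
    """Eshelby I-integrals for a prolate spheroid with axes (t, 1, 1), t >= 1.

    Closed elementary forms; the sphere limit uses the exact values to avoid
    cancellation for t near 1.
    """
    t = float(aspect_ratio)
    if t < 1.0:
        raise ValueError("prolate convention requires aspect ratio >= 1")
    if t < 1.0 + 1e-7:
        I1 = I2 = I3 = 4.0 * np.pi / 3.0
        I11 = I12 = I13 = I22 = I23 = 4.0 * np.pi / 5.0
        return dict(I1=I1, I2=I2, I3=I3, I11=I11, I12=I12, I22=I22, I23=I23)
    u = t * t - 1.0
    g = t * (t * np.sqrt(u) - np.arccosh(t)) / u**1.5
    I2 = 2.0 * np.pi * g  # minor axes
    I3 = I2
    I1 = 4.0 * np.pi - 2.0 * I2
    I12 = (I2 - I1) / u  # (a1^2 - a2^2) = t^2 - 1
    I22 = (4.0 * np.pi - I12) / 4.0
    I23 = I22
    I11 = (4.0 * np.pi / (t * t) - 2.0 * I12) / 3.0
    return dict(I1=I1, I2=I2, I3=I3, I11=I11, I12=I12, I22=I22, I23=I23)


def eshelby_tensor(aspect_ratio: float, nu_matrix: float) -> np.ndarray:
    """Eshelby tensor of a prolate spheroid in 6x6 Voigt (engineering-shear) form.

    The long axis is x1.  Minor symmetries hold by construction; the matrix
    acts on strain vectors (e11, e22, e33, g23, g13, g12) with g = 2e.
    """
    if not (0 <= nu_matrix < 0.5):
        raise ValueError("Poisson ratio must be in [0, 0.5)")
    t = float(aspect_ratio)
    I = spheroid_eshelby_integrals(t)
    nu = nu_matrix
    Q = 3.0 / (8.0 * np.pi * (1.0 - nu))
    R = (1.0 - 2.0 * nu) / (8.0 * np.pi * (1.0 - nu))
    t2 = t * t

    S = np.zeros((6, 6))
    S1111 = Q * t2 * I["I11"] + R * I["I1"]
    S2222 = Q * I["I22"] + R * I["I2"]
    S3333 = S2222
    S1122 = (Q / 3.0) * I["I12"] - R * I["I1"]
    S1133 = S1122
    S2211 = (Q / 3.0) * t2 * I["I12"] - R * I["I2"]
    S3311 = S2211
    S2233 = (Q / 3.0) * I["I23"] - R * I["I2"]
    S3322 = S2233
    S2323 = (Q / 3.0) * I["I23"] + R * I["I2"]
    S1212 = (Q / 6.0) * (t2 + 1.0) * I["I12"] + (R / 2.0) * (I["I1"] + I["I2"])
    S1313 = S1212

    S[0, 0], S[1, 1], S[2, 2] = S1111, S2222, S3333
    S[0, 1], S[0, 2] = S1122, S1133
    S[1, 0], S[2, 0] = S2211, S3311
    S[1, 2], S[2, 1] = S2233, S3322
    S[3, 3] = 2.0 * S2323
    S[4, 4] = 2.0 * S1313
    S[5, 5] = 2.0 * S1212
    return S


def isotropic_stiffness(e_modulus: float, nu: float) -> np.ndarray:
    """Isotropic stiffness in 6x6 Voigt (engineering-shear) form."""
    if e_modulus <= 0:
        raise ValueError("elastic modulus must be > 0")
    if not (0 <= nu < 0.5):
        raise ValueError("Poisson ratio must be in [0, 0.5)")
    lam = e_modulus * nu / ((1.0 + nu) * (1.0 - 2.0 * nu))
    mu = e_modulus / (2.0 * (1.0 + nu))
    C = np.zeros((6, 6))
    C[:3, :3] = lam
    C[:3, :3] += 2.0 * mu * np.eye(3)
    C[3:, 3:] = mu * np.eye(3)
    return C


def constrained_strain(
    eps_f: np.ndarray, C_I: np.ndarray, C_M: np.ndarray, S: np.ndarray
) -> np.ndarray:
    """Eshelby-constrained strain eps_c = S [(C_I - C_M) S + C_M]^{-1} C_I eps_f.

    All operators are 6x6 Voigt with engineering shears; ``eps_f`` is the free
    (eigen)strain vector.
    """
    eps_f = np.asarray(eps_f, dtype=float)
    A = (C_I - C_M) @ S + C_M
    try:
        y = np.linalg.solve(A, C_I @ eps_f)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - admissible moduli
        raise np.linalg.LinAlgError(f"degenerate Eshelby bracket: {exc}") from exc
    return S @ y


def axial_constraint_factor(
    aspect_ratio: float, elasticity: ElasticityParams
) -> float:
    """Ratio eps_c_axial / eps_f_axial for a uniaxial free strain along x1."""
    S = eshelby_tensor(aspect_ratio, elasticity.nu_matrix)
    C_I = isotropic_stiffness(elasticity.e_protrusion_Pa, elasticity.nu_protrusion)
    C_M = isotropic_stiffness(elasticity.e_matrix_Pa, elasticity.nu_matrix)
    e1 = np.array([1.0, 0, 0, 0, 0, 0])
    return float(constrained_strain(e1, C_I, C_M, S)[0])


# ---------------------------------------------------------------------------
# length update / birth


def update_length(
    protrusion: Protrusion, eps_exp: float, eps_ret: float
) -> Protrusion:
    """Apply the multiplicative length update (1 + eps_EXP + eps_RET)||p||.

    The result is floored at zero; a zero length marks the protrusion dead.
    """
    new_len = (1.0 + eps_exp + eps_ret) * protrusion.length_um
    if new_len <= 0.0:
        protrusion.length_um = 0.0
        protrusion.alive = False
    else:
        protrusion.length_um = new_len
    return protrusion


def birth_protrusion(
    component: SurfaceComponent,
    ds: float,
    strain: StrainParams,
    elasticity: ElasticityParams,
    new_id: int,
    birth_time_min: float,
) -> Protrusion | None:
    """Sprout a new protrusion at a component centroid.

    The direction is the outward radial unit vector through the centroid; the
    seed length is the Eshelby-constrained free increment so newborns sit on
    the same mechanical footing as one growth step.  Returns None for ds <= 0
    (no signal, no sprout).
    """
    if ds <= 0:
        return None
    inc = free_increment_um(ds, strain)
    factor = axial_constraint_factor(1.0 + 1e-6, elasticity)
    length = factor * inc
    if length <= 0:
        return None
    direction = sphere_direction(component.centroid_alpha, component.centroid_beta)
    return Protrusion(
        id=new_id,
        direction=direction,
        length_um=float(length),
        alpha=component.centroid_alpha,
        beta=component.centroid_beta,
        birth_time_min=birth_time_min,
    )


def _component_ds(
    comp: SurfaceComponent, ds_map: np.ndarray, grid
) -> float:
    """Delta-s integrated over a component: area-weighted mean x area."""
    w = grid.area_weights()[comp.rows, comp.cols]
    vals = ds_map[comp.rows, comp.cols]
    mean = float(np.sum(w * vals) / w.sum())
    return mean * comp.area


def step_protrusions(
    protrusions: list[Protrusion],
    components: list[SurfaceComponent],
    s_map: np.ndarray,
    ds_map: np.ndarray,
    thresholds: ThresholdSet,
    strain: StrainParams,
    elasticity: ElasticityParams,
    grid,
    t_min: float,
    id_counter: itertools.count,
) -> list[Protrusion]:
    """One mechanical step of the protrusion population.

    Classifies events, applies Eshelby-constrained strains to live
    protrusions and sprouts births.  Dead protrusions are dropped from the
    returned list (death is permanent; a later birth at the same centroid is
    a new object).
    """
    actions, births = classify_events(
        s_map, ds_map, components, protrusions, thresholds, grid
    )
    survivors: list[Protrusion] = []
    comp_of_site: dict[tuple[int, int], SurfaceComponent] = {}
    for comp in components:
        for r, c in zip(comp.rows, comp.cols):
            comp_of_site[(int(r), int(c))] = comp
    for p in protrusions:
        if not p.alive:
            continue
        action = actions.get(p.id, "hold")
        if action == "die":
            p.alive = False
            p.length_um = 0.0
            continue
        site = _nearest_site(p.alpha, p.beta, grid)
        comp = comp_of_site.get(site)
        ds = _component_ds(comp, ds_map, grid) if comp is not None else float(
            ds_map[site[0], site[1]]
        )
        eps_exp = 0.0
        eps_ret = 0.0
        if action == "reinforce" and ds > 0:
            eps_f, _ = free_strain(ds, p.length_um, strain, "exp")
            aspect = max(p.length_um / elasticity.diameter_um, 1.0 + 1e-6)
            eps_exp = axial_constraint_factor(aspect, elasticity) * eps_f
            eps_exp = float(np.clip(eps_exp, 0.0, 1.0))
        elif action == "retract" and ds < 0:
            eps_f, _ = free_strain(ds, p.length_um, strain, "ret")
            aspect = max(p.length_um / elasticity.diameter_um, 1.0 + 1e-6)
            eps_ret = axial_constraint_factor(aspect, elasticity) * eps_f
            eps_ret = float(np.clip(eps_ret, -1.0, 0.0))
        update_length(p, eps_exp, eps_ret)
        if p.alive:
            survivors.append(p)
    for comp in births:
        ds = _component_ds(comp, ds_map, grid)
        newborn = birth_protrusion(
            comp, ds, strain, elasticity, next(id_counter), t_min
        )
        if newborn is not None:
            survivors.append(newborn)
    return survivors
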