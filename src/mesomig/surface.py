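"""Membrane surface signal: deposition, smoothing and peak localisation.

The cell membrane is flattened onto a regular chart in the polar coordinates
(alpha, beta): alpha in [0, 2pi) is periodic, beta in [0, pi] runs pole to
pole.  Each PI3K activation event (an R3 firing of the chemistry module) is
attributed to a membrane site drawn from a non-homogeneous Poisson field
whose intensity is proportional to the local chemoattractant concentration
times the site area (inverse-CDF sampling).  Per-epoch event maps are
smoothed by convolution with a normalised kernel whose footprint is roughly
a protrusion cross-section, then accumulated into the persistence signal
``s``; a separate ``delta-s`` accumulator collects everything deposited since
the last mechanical step.  Candidate protrusion centroids are the connected
components of the thresholded map ``s >= s_binary``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal as _signal

__all__ = [
    "GridMismatchError",
    "SurfaceGrid",
    "ChemoattractantField",
    "SmoothingKernel",
    "SignalField",
    "SurfaceComponent",
    "sphere_direction",
    "concentration_at",
    "membrane_profile",
    "sample_activation_sites",
    "allocate_event_counts",
    "deposit_and_convolve",
    "binarize",
    "find_components",
    "binarize_and_find_centroids",
]


class GridMismatchError(ValueError):
    """Fields defined on different grids were combined."""


def sphere_direction(alpha, beta) -> np.ndarray:
    """Unit vector(s) for surface coordinates; (alpha=0, beta=pi/2) is +x."""
    alpha = np.asarray(alpha, dtype=float)
    beta = np.asarray(beta, dtype=float)
    return np.stack(
        [np.sin(beta) * np.cos(alpha), np.sin(beta) * np.sin(alpha), np.cos(beta)],
        axis=-1,
    )


@dataclass(frozen=True)
class SurfaceGrid:
    """Regular (alpha, beta) chart of the membrane of a spherical cell."""

    n_alpha: int = 72
    n_beta: int = 36
    radius_um: float = 10.0

    def __post_init__(self) -> None:
        if self.n_alpha < 8 or self.n_beta < 8:
            raise ValueError("grid resolution must be at least 8x8")
        if self.radius_um <= 0:
            raise ValueError("cell radius must be > 0")

    @property
    def alpha(self) -> np.ndarray:
        """Site-centre alphas, shape (n_alpha,)."""
        return (np.arange(self.n_alpha) + 0.5) * 2.0 * np.pi / self.n_alpha

    @property
    def beta(self) -> np.ndarray:
        """Site-centre betas, shape (n_beta,)."""
        return (np.arange(self.n_beta) + 0.5) * np.pi / self.n_beta

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_beta, self.n_alpha)

    def area_weights(self) -> np.ndarray:
        """Relative site areas (sin beta), normalised to mean 1, shape (n_beta, n_alpha)."""
        w = np.sin(self.beta)[:, None] * np.ones((1, self.n_alpha))
        return w / w.mean()

    def unit_vectors(self) -> np.ndarray:
        """Outward unit normals at site centres, shape (n_beta, n_alpha, 3)."""
        a, b = np.meshgrid(self.alpha, self.beta)
        return sphere_direction(a, b)

    def membrane_points_mm(self, center_mm: np.ndarray) -> np.ndarray:
        """3D site positions (mm) for a cell centred at ``center_mm``."""
        return np.asarray(center_mm, dtype=float) + self.radius_um * 1e-3 * self.unit_vectors()


@dataclass(frozen=True)
class ChemoattractantField:
    """Time-invariant linear chemoattractant profile.

    ``c0_uM`` is the concentration at ``origin_mm`` (the cell's initial
    position); the gradient is constant in uM/mm.  Concentrations are clamped
    at zero.
    """

    c0_uM: float
    gradient_uM_per_mm: np.ndarray = field(default_factory=lambda: np.zeros(3))
    origin_mm: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "gradient_uM_per_mm", np.asarray(self.gradient_uM_per_mm, dtype=float)
        )
        object.__setattr__(self, "origin_mm", np.asarray(self.origin_mm, dtype=float))
        if self.gradient_uM_per_mm.shape != (3,) or self.origin_mm.shape != (3,):
            raise ValueError("gradient and origin must be 3-vectors")


def concentration_at(fld: ChemoattractantField, point_mm) -> np.ndarray:
    """Concentration (uM) at 3D point(s); clamped at zero."""
    p = np.asarray(point_mm, dtype=float)
    c = fld.c0_uM + (p - fld.origin_mm) @ fld.gradient_uM_per_mm
    return np.maximum(c, 0.0)


def membrane_profile(
    fld: ChemoattractantField, center_mm, grid: SurfaceGrid
) -> np.ndarray:
    """Per-site chemoattractant concentration in nM, shape (n_beta, n_alpha)."""
    pts = grid.membrane_points_mm(np.asarray(center_mm, dtype=float))
    return concentration_at(fld, pts) * 1000.0


@dataclass(frozen=True)
class SmoothingKernel:
    """Normalised discrete 2D kernel (entries >= 0, summing to 1)."""

    weights: np.ndarray
    sigma_sites: float

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if np.any(w < 0):
            raise ValueError("kernel entries must be >= 0")
        object.__setattr__(self, "weights", w / w.sum())

    @property
    def radius(self) -> int:
        return self.weights.shape[0] // 2

    @classmethod
    def gaussian(cls, sigma_sites: float = 2.0, radius: int | None = None) -> "SmoothingKernel":
        """Isotropic Gaussian on the flattened chart.

        The default bandwidth of two grid sites makes the kernel footprint
        comparable to a protrusion cross-section on the default 72x36 grid.
        """
        if sigma_sites <= 0:
            raise ValueError("sigma must be > 0")
        r = int(np.ceil(3 * sigma_sites)) if radius is None else int(radius)
        ax = np.arange(-r, r + 1)
        g1 = np.exp(-0.5 * (ax / sigma_sites) ** 2)
        k = np.outer(g1, g1)
        return cls(k, sigma_sites)


def sample_activation_sites(
    n_events: int, weights: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Draw flat site indices for activation events (inverse-CDF method).

    Each event lands independently on a site with probability proportional to
    its weight (intensity x area); this realises the non-homogeneous Poisson
    allocation of receptor activations over the membrane.
    """
    if n_events == 0:
        return np.empty(0, dtype=np.intp)
    w = np.asarray(weights, dtype=float).ravel()
    if np.any(w < 0):
        raise ValueError("weights must be >= 0")
    total = w.sum()
    if total <= 0:
        raise ValueError("all-zero weights with n_events > 0")
    cdf = np.cumsum(w) / total
    idx = np.searchsorted(cdf, rng.random(n_events), side="right")
    return np.minimum(idx, w.size - 1).astype(np.intp)


def allocate_event_counts(
    n_events: int, weights: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Per-site event counts, multinomially — the aggregated form of
    :func:`sample_activation_sites` (identical joint distribution), used for
    the simulator's bulk path."""
    w = np.asarray(weights, dtype=float)
    flat = w.ravel()
    if n_events == 0:
        return np.zeros(w.shape, dtype=np.int64)
    if np.any(flat < 0):
        raise ValueError("weights must be >= 0")
    total = flat.sum()
    if total <= 0:
        raise ValueError("all-zero weights with n_events > 0")
    counts = rng.multinomial(n_events, flat / total)
    return counts.reshape(w.shape).astype(np.int64)


def deposit_and_convolve(counts_map: np.ndarray, kernel: SmoothingKernel) -> np.ndarray:
    """Smooth an event-count map over the chart.

    Boundary handling follows the chart geometry: periodic wrap in alpha
    (columns), mirror reflection at the beta poles (rows).  Total mass is
    preserved exactly up to the pole-reflection bookkeeping.
    """
    c = np.asarray(counts_map, dtype=float)
    r = kernel.radius
    if r == 0:
        return c * kernel.weights[0, 0]
    padded = np.pad(c, ((0, 0), (r, r)), mode="wrap")
    padded = np.pad(padded, ((r, r), (0, 0)), mode="symmetric")
    return _signal.convolve2d(padded, kernel.weights, mode="valid")


@dataclass
class SignalField:
    """Cumulative persistence signal ``s`` plus the delta-s accumulator."""

    grid: SurfaceGrid
    s: np.ndarray = None
    ds: np.ndarray = None

    def __post_init__(self) -> None:
        if self.s is None:
            self.s = np.zeros(self.grid.shape)
        if self.ds is None:
            self.ds = np.zeros(self.grid.shape)
        if self.s.shape != self.grid.shape or self.ds.shape != self.grid.shape:
            raise GridMismatchError("signal arrays do not match the grid shape")

    def accumulate(self, s_t: np.ndarray) -> None:
        """Add one epoch's smoothed deposition (Eq.-style running sum)."""
        s_t = np.asarray(s_t, dtype=float)
        if s_t.shape != self.grid.shape:
            raise GridMismatchError(
                f"epoch field shape {s_t.shape} != grid shape {self.grid.shape}"
            )
        self.s += s_t
        self.ds += s_t

    def consume_ds(self) -> np.ndarray:
        """Return and zero the accumulated variation since the last mechanical step."""
        out = self.ds.copy()
        self.ds[:] = 0.0
        return out


@dataclass
class SurfaceComponent:
    """A connected component of the binarised signal map."""

    centroid_alpha: float
    centroid_beta: float
    rows: np.ndarray
    cols: np.ndarray
    area: float

    def contains_site(self, row: int, col: int) -> bool:
        return bool(np.any((self.rows == row) & (self.cols == col)))


def binarize(s: np.ndarray, s_binary: float) -> np.ndarray:
    """Threshold map: 1 where s >= s_binary, else 0."""
    if s_binary < 0:
        raise ValueError("s_binary must be >= 0")
    return np.asarray(s) >= s_binary


def _merge_seam_labels(labels: np.ndarray) -> np.ndarray:
    """Union labels that touch across the periodic alpha seam (8-connectivity)."""
    n_beta = labels.shape[0]
    parent = {}

    def find(x):
        while parent.get(x, x) != x:
            parent[x] = parent.get(parent[x], parent[x])
            x = parent[x]
        return x

    def union(x, y):
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[max(rx, ry)] = min(rx, ry)

    left = labels[:, 0]
    right = labels[:, -1]
    for j in range(n_beta):
        if left[j] == 0:
            continue
        for dj in (-1, 0, 1):
            jj = j + dj
            if 0 <= jj < n_beta and right[jj] != 0:
                union(int(left[j]), int(right[jj]))
    if not parent:
        return labels
    out = labels.copy()
    for lab in np.unique(labels):
        if lab == 0:
            continue
        root = find(int(lab))
        if root != lab:
            out[labels == lab] = root
    return out


def find_components(
    mask: np.ndarray, grid: SurfaceGrid, values: np.ndarray | None = None
) -> list[SurfaceComponent]:
    """8-connected components of a binary map, periodic in alpha.

    Centroids are area-weighted means of the member site coordinates, with a
    circular mean in alpha.  A component wrapping (almost) the whole sphere
    has no well-defined circular mean — its resultant vector vanishes and the
    arctangent would resolve floating-point noise into a fixed, biased
    direction.  In that degenerate case the centroid falls back to the
    component's peak site of ``values`` (the signal map when called through
    :func:`binarize_and_find_centroids`), which is where the protrusion peak
    sits anyway.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != grid.shape:
        raise GridMismatchError("mask shape does not match grid")
    labels, _ = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    labels = _merge_seam_labels(labels)
    w = grid.area_weights()
    alpha = grid.alpha
    beta = grid.beta
    comps: list[SurfaceComponent] = []
    for lab in np.unique(labels):
        if lab == 0:
            continue
        rows, cols = np.nonzero(labels == lab)
        ww = w[rows, cols]
        a = alpha[cols]
        sin_sum = float(np.sum(ww * np.sin(a)))
        cos_sum = float(np.sum(ww * np.cos(a)))
        resultant = np.hypot(sin_sum, cos_sum)
        if resultant > 1e-3 * ww.sum():
            ca = float(np.arctan2(sin_sum, cos_sum)) % (2.0 * np.pi)
            cb = float(np.sum(ww * beta[rows]) / ww.sum())
        else:  # degenerate (near-symmetric) component: use the peak site
            vals = values[rows, cols] if values is not None else ww
            k = int(np.argmax(vals))
            ca = float(alpha[cols[k]])
            cb = float(beta[rows[k]])
        comps.append(
            SurfaceComponent(
                centroid_alpha=ca,
                centroid_beta=cb,
                rows=rows,
                cols=cols,
                area=float(ww.sum()),
            )
        )
    comps.sort(key=lambda c: (c.centroid_beta, c.centroid_alpha))
    return comps


def binarize_and_find_centroids(
    s: np.ndarray, s_binary: float, grid: SurfaceGrid
) -> list[SurfaceComponent]:
    """Threshold the signal and return the centroid of every component."""
    return find_components(binarize(s, s_binary), grid, values=np.asarray(s, dtype=float))
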