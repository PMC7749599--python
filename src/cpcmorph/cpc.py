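"""Voxelwise tissue-probability transition matrices.

For each interior voxel, a 4x4 non-negative matrix F mapping the four
tissue probabilities (g, w, c, b) at baseline to those at follow-up is
fitted by non-negative least squares over the surrounding 3x3x3
neighborhood: four independent per-target solves with 4 unknowns each,
27 equations per target (108 stacked equations, 16 unknowns in total).
Probabilities below a threshold (default 0.2) are zeroed and survivors
renormalized before fitting; fitted elements are capped (default 5.0,
the reciprocal of the threshold).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.optimize import nnls

from cpcmorph.phantom import TISSUES, ProbabilityMapSet

#: Channel names of the flattened 4x4 matrix, source-major:
#: F_gg, F_gw, F_gc, F_gb, F_wg, ... (F_st = source tissue s -> target t).
ELEMENT_NAMES = tuple(f"F_{s}{t}" for s in TISSUES for t in TISSUES)

_CLOSURE_TOL = 1e-3


def element_index(source: str, target: str) -> int:
    """Flat channel index of element F_{source}{target}."""
    return TISSUES.index(source) * 4 + TISSUES.index(target)


@dataclass(frozen=True)
class CpcConfig:
    """Fit configuration.

    ``cpc_cap`` defaults to ``1 / prob_threshold`` (5.0 at the default
    threshold of 0.2): with sub-threshold probabilities excluded, no
    ratio of surviving probabilities can exceed that bound.
    """

    prob_threshold: float = 0.2
    cpc_cap: float | None = None
    neighborhood_radius: int = 1
    min_valid_voxels: int = 14

    def __post_init__(self) -> None:
        if not 0.0 < self.prob_threshold < 1.0:
            raise ValueError("prob_threshold must be in (0, 1)")
        if self.cpc_cap is None:
            object.__setattr__(self, "cpc_cap", 1.0 / self.prob_threshold)
        if self.cpc_cap <= 0:
            raise ValueError("cpc_cap must be positive")
        if self.neighborhood_radius < 1:
            raise ValueError("neighborhood_radius must be >= 1")
        if self.min_valid_voxels < 4:
            raise ValueError("min_valid_voxels must be >= 4 (unknowns per solve)")

    @property
    def neighborhood_size(self) -> int:
        return (2 * self.neighborhood_radius + 1) ** 3


@dataclass
class CpcMatrix:
    """Fitted transition matrix at one voxel.

    ``elements[j, i]`` maps source tissue ``i`` to target tissue ``j``
    (``p_tt = elements @ p_t``); ``element(s, t)`` gives F_st.
    """

    elements: np.ndarray
    fit_residual: np.ndarray  # per-target sum of squared residuals
    identifiable: np.ndarray  # per-source bool (nonzero design column)

    def element(self, source: str, target: str) -> float:
        return float(self.elements[TISSUES.index(target), TISSUES.index(source)])

    def flat(self) -> np.ndarray:
        """Elements in :data:`ELEMENT_NAMES` (source-major) order."""
        return self.elements.T.reshape(-1)


@dataclass
class CpcVolume:
    """Per-voxel fitted elements over a grid.

    ``channels`` has shape ``(16,) + grid_shape`` in :data:`ELEMENT_NAMES`
    order; values are defined only where ``validity_mask`` is true.
    """

    channels: np.ndarray
    validity_mask: np.ndarray
    config_used: CpcConfig
    identifiable: np.ndarray = field(default=None)  # (4,) + grid, per-source

    @property
    def grid_shape(self) -> tuple[int, ...]:
        return self.channels.shape[1:]

    def element_map(self, source: str, target: str) -> np.ndarray:
        return self.channels[element_index(source, target)]


def close_background(g: np.ndarray, w: np.ndarray, c: np.ndarray) -> ProbabilityMapSet:
    """Complete three tissue maps with background by subtraction.

    ``b = clip(1 - g - w - c, 0, 1)``; voxels whose tissue probabilities
    already exceed 1 by more than 1e-3 are flagged invalid.
    """
    g, w, c = (np.asarray(a, dtype=np.float64) for a in (g, w, c))
    if not (g.shape == w.shape == c.shape):
        raise ValueError(f"shape mismatch: {g.shape}, {w.shape}, {c.shape}")
    total = g + w + c
    b = np.clip(1.0 - total, 0.0, 1.0)
    validity = total <= 1.0 + _CLOSURE_TOL
    return ProbabilityMapSet(np.stack([g, w, c, b], axis=0), validity)


def threshold_and_renormalize(p: np.ndarray, tau: float) -> np.ndarray:
    """Zero components below ``tau`` and rescale survivors to sum to 1.

    Operates on the last axis (length 4); accepts a single 4-vector or a
    stack of them.  A 4-vector summing to 1 always keeps at least one
    component for tau < 0.25; inputs left all-zero raise ``ValueError``.
    """
    if not 0.0 < tau < 1.0:
        raise ValueError("tau must be in (0, 1)")
    p = np.asarray(p, dtype=np.float64)
    if p.shape[-1] != 4:
        raise ValueError("expected length-4 probability vectors on the last axis")
    kept = np.where(p < tau, 0.0, p)
    sums = kept.sum(axis=-1)
    if np.any(sums <= 0):
        raise ValueError("thresholding removed all components of at least one vector")
    return kept / sums[..., None]


def assemble_system(
    neigh_t: np.ndarray, neigh_tt: np.ndarray, target: int
) -> tuple[np.ndarray, np.ndarray]:
    """Build the regression system for one target tissue.

    Rows of ``design`` are the four source probabilities at baseline;
    ``response`` holds the target-tissue probability at follow-up.  The
    four per-target systems of a full 3x3x3 neighborhood together stack
    27 x 4 = 108 equations for 16 unknowns.
    """
    neigh_t = np.asarray(neigh_t, dtype=np.float64)
    neigh_tt = np.asarray(neigh_tt, dtype=np.float64)
    if neigh_t.shape != neigh_tt.shape or neigh_t.ndim != 2 or neigh_t.shape[1] != 4:
        raise ValueError("neighborhoods must be matching (m, 4) arrays")
    if not 0 <= target < 4:
        raise ValueError("target must index one of the 4 tissues")
    return neigh_t, neigh_tt[:, target]


def solve_nnls(design: np.ndarray, response: np.ndarray) -> tuple[np.ndarray, float]:
    """Non-negative least squares for one target tissue.

    Returns the coefficient 4-vector (>= 0) minimizing the residual
    2-norm, and the sum of squared residuals.  Identically-zero design
    columns yield coefficient 0.
    """
    design = np.asarray(design, dtype=np.float64)
    response = np.asarray(response, dtype=np.float64)
    if design.ndim != 2 or design.shape[1] != 4:
        raise ValueError("design must be (m, 4)")
    if design.shape[0] < 4:
        raise ValueError(f"underdetermined system: {design.shape[0]} rows < 4 unknowns")
    coeffs, rnorm = nnls(design, response)
    return coeffs, float(rnorm) ** 2


def design_identifiability(design: np.ndarray) -> np.ndarray:
    """Per-source flag: does the design carry any signal for this tissue?"""
    return np.linalg.norm(np.asarray(design, dtype=np.float64), axis=0) > 0


def fit_voxel(neigh_t: np.ndarray, neigh_tt: np.ndarray, config: CpcConfig) -> CpcMatrix:
    """Fit the 4x4 transition matrix from one (already thresholded) neighborhood.

    Four independent per-target NNLS solves; every element is then
    capped at ``config.cpc_cap``.
    """
    elements = np.zeros((4, 4))
    residuals = np.zeros(4)
    for target in range(4):
        design, response = assemble_system(neigh_t, neigh_tt, target)
        coeffs, ssr = solve_nnls(design, response)
        elements[target] = coeffs
        residuals[target] = ssr
    np.clip(elements, 0.0, config.cpc_cap, out=elements)
    return CpcMatrix(elements, residuals, design_identifiability(neigh_t))


def fit_voxel_joint(
    neigh_t: np.ndarray, neigh_tt: np.ndarray, config: CpcConfig
) -> CpcMatrix:
    """Single joint NNLS on the stacked block-diagonal 108x16 system.

    The joint problem is block-diagonal over target tissues, so its
    solution coincides with the four per-target solves; kept as an
    internal equivalence check.
    """
    m = neigh_t.shape[0]
    big_design = np.zeros((4 * m, 16))
    big_response = np.zeros(4 * m)
    for target in range(4):
        design, response = assemble_system(neigh_t, neigh_tt, target)
        big_design[target * m : (target + 1) * m, target * 4 : (target + 1) * 4] = design
        big_response[target * m : (target + 1) * m] = response
    coeffs, rnorm = nnls(big_design, big_response)
    elements = np.clip(coeffs.reshape(4, 4), 0.0, config.cpc_cap)
    residuals = np.array(
        [
            float(np.sum((neigh_t @ elements[t] - neigh_tt[:, t]) ** 2))
            for t in range(4)
        ]
    )
    return CpcMatrix(elements, residuals, design_identifiability(neigh_t))


def _thresholded_stack(
    maps: ProbabilityMapSet, tau: float
) -> tuple[np.ndarray, np.ndarray]:
    """Threshold + renormalize a whole volume; returns (X,Y,Z,4) and validity."""
    p = np.moveaxis(maps.data, 0, -1)
    kept = np.where(p < tau, 0.0, p)
    sums = kept.sum(axis=-1)
    ok = (sums > 0) & maps.voxel_validity
    out = np.zeros_like(kept)
    np.divide(kept, sums[..., None], out=out, where=ok[..., None])
    return out, ok


def compute_cpc_volume(
    maps_t: ProbabilityMapSet, maps_tt: ProbabilityMapSet, config: CpcConfig
) -> CpcVolume:
    """Fit the transition matrix at every interior voxel (sliding window).

    The neighborhood of radius ``config.neighborhood_radius`` is centered
    on each voxel; the fitted matrix is assigned to the center.  Border
    voxels (incomplete neighborhoods) and centers with fewer than
    ``min_valid_voxels`` valid neighbors are marked invalid.
    Deterministic given inputs and config.
    """
    if maps_t.grid_shape != maps_tt.grid_shape:
        raise ValueError(
            f"grid mismatch: {maps_t.grid_shape} vs {maps_tt.grid_shape}"
        )
    shape = maps_t.grid_shape
    r = config.neighborhood_radius
    side = 2 * r + 1
    if any(n < side for n in shape):
        raise ValueError(f"grid {shape} too small for neighborhood side {side}")

    p_t, ok_t = _thresholded_stack(maps_t, config.prob_threshold)
    p_tt, ok_tt = _thresholded_stack(maps_tt, config.prob_threshold)
    ok = ok_t & ok_tt

    # (X-2r, Y-2r, Z-2r, 4, side, side, side) windows
    win_t = sliding_window_view(p_t, (side, side, side), axis=(0, 1, 2))
    win_tt = sliding_window_view(p_tt, (side, side, side), axis=(0, 1, 2))
    win_ok = sliding_window_view(ok, (side, side, side))

    channels = np.zeros((16,) + shape)
    validity = np.zeros(shape, dtype=bool)
    identifiable = np.zeros((4,) + shape, dtype=bool)
    n = side**3
    min_rows = max(config.min_valid_voxels, 4)

    inner = tuple(s - 2 * r for s in shape)
    for ix in range(inner[0]):
        for iy in range(inner[1]):
            for iz in range(inner[2]):
                rows_ok = win_ok[ix, iy, iz].reshape(n)
                if rows_ok.sum() < min_rows:
                    continue
                neigh_t = win_t[ix, iy, iz].reshape(4, n).T[rows_ok]
                neigh_tt = win_tt[ix, iy, iz].reshape(4, n).T[rows_ok]
                fit = fit_voxel(neigh_t, neigh_tt, config)
                cx, cy, cz = ix + r, iy + r, iz + r
                channels[:, cx, cy, cz] = fit.flat()
                validity[cx, cy, cz] = True
                identifiable[:, cx, cy, cz] = fit.identifiable
    return CpcVolume(channels, validity, config, identifiable)
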