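"""Synthetic longitudinal atrophy phantoms.

Generates co-registered pairs of tissue-probability-map sets (GM, WM,
CSF, background) with known, parametric atrophy injected as probability
transfer from GM to CSF at tissue boundaries, so that every downstream
stage can be validated against ground truth without real MRI.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.ndimage import binary_dilation, gaussian_filter

#: Tissue channel order used throughout the package.
TISSUES = ("g", "w", "c", "b")

_SUM_TOL = 1e-6

# Structural label codes used by the phantom geometries.
LABEL_BACKGROUND = 0
LABEL_CSF = 1
LABEL_GM = 2
LABEL_WM = 3


class GeometryError(ValueError):
    """Raised when phantom geometry does not fit the grid."""


@dataclass(frozen=True)
class AtrophyPhantomSpec:
    """Parameters of a synthetic longitudinal phantom.

    Parameters
    ----------
    grid_shape
        Voxel grid dimensions; each axis must be >= 7 so that full
        3x3x3 neighborhoods exist away from the volume border.
    geometry
        ``"nested_spheres"`` (CSF core, GM shell, WM surround) or
        ``"slab_stack"`` (CSF / GM / WM slabs along the first axis).
    structure_radii
        Increasing boundary radii (or slab boundaries) in voxels:
        CSF outer, GM outer, WM outer.
    atrophy_rate
        Fraction in [0, 1] of GM probability transferred to CSF at
        GM/CSF boundary voxels between the two time points.
    blur_sigma
        Gaussian partial-volume smoothing width in voxels.
    noise_sd
        Standard deviation of additive probability noise (applied
        independently at both time points, then re-projected onto the
        probability simplex).
    seed
        RNG seed; identical specs produce bit-identical phantoms.
    """

    grid_shape: tuple[int, int, int] = (16, 16, 16)
    geometry: str = "nested_spheres"
    structure_radii: tuple[float, ...] = (3.0, 5.5, 7.0)
    atrophy_rate: float = 0.0
    blur_sigma: float = 1.0
    noise_sd: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if len(self.grid_shape) != 3 or any(int(n) < 7 for n in self.grid_shape):
            raise GeometryError(
                f"grid_shape must be a triple with every axis >= 7, got {self.grid_shape}"
            )
        if self.geometry not in ("nested_spheres", "slab_stack"):
            raise GeometryError(f"unknown geometry {self.geometry!r}")
        if not 0.0 <= self.atrophy_rate <= 1.0:
            raise ValueError(f"atrophy_rate must be in [0, 1], got {self.atrophy_rate}")
        if self.blur_sigma < 0 or self.noise_sd < 0:
            raise ValueError("blur_sigma and noise_sd must be >= 0")
        radii = tuple(float(r) for r in self.structure_radii)
        if len(radii) != 3 or any(r <= 0 for r in radii):
            raise GeometryError(f"structure_radii must be 3 positive lengths, got {radii}")
        if not (radii[0] < radii[1] < radii[2]):
            raise GeometryError(f"structure_radii must be strictly increasing, got {radii}")
        if self.geometry == "nested_spheres":
            if 2 * radii[2] >= min(self.grid_shape):
                raise GeometryError(
                    f"outer radius {radii[2]} does not fit grid {self.grid_shape}"
                )
        else:
            if radii[2] >= self.grid_shape[0]:
                raise GeometryError(
                    f"outermost slab boundary {radii[2]} exceeds axis length "
                    f"{self.grid_shape[0]}"
                )


@dataclass
class ProbabilityMapSet:
    """Four co-registered probability volumes over one grid.

    ``data`` has shape ``(4,) + grid_shape`` with channels ordered as
    :data:`TISSUES` (g, w, c, b).  At every valid voxel the four values
    sum to 1 within 1e-6.
    """

    data: np.ndarray
    voxel_validity: np.ndarray
    timepoint_tag: str = "t"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 4 or self.data.shape[0] != 4:
            raise ValueError(f"data must have shape (4, X, Y, Z), got {self.data.shape}")
        self.voxel_validity = np.asarray(self.voxel_validity, dtype=bool)
        if self.voxel_validity.shape != self.grid_shape:
            raise ValueError("voxel_validity shape does not match grid")

    @property
    def grid_shape(self) -> tuple[int, ...]:
        return self.data.shape[1:]

    def channel(self, tissue: str) -> np.ndarray:
        return self.data[TISSUES.index(tissue)]

    @property
    def g(self) -> np.ndarray:
        return self.data[0]

    @property
    def w(self) -> np.ndarray:
        return self.data[1]

    @property
    def c(self) -> np.ndarray:
        return self.data[2]

    @property
    def b(self) -> np.ndarray:
        return self.data[3]

    def check_invariants(self, tol: float = _SUM_TOL) -> None:
        if self.data.min() < -tol or self.data.max() > 1 + tol:
            raise ValueError("probability values outside [0, 1]")
        sums = self.data.sum(axis=0)
        bad = np.abs(sums[self.voxel_validity] - 1.0)
        if bad.size and bad.max() > tol:
            raise ValueError(f"probabilities do not sum to 1 (max dev {bad.max():.2e})")


@dataclass
class PhantomTruth:
    """Ground truth of injected atrophy for parameter-recovery tests."""

    atrophy_mask: np.ndarray
    injected_gm_loss: np.ndarray  # per-voxel fraction of GM probability moved to CSF


@dataclass
class PhantomSubject:
    subject_id: str
    group: str
    maps_t: ProbabilityMapSet
    maps_tt: ProbabilityMapSet
    truth: PhantomTruth
    spec: AtrophyPhantomSpec = field(repr=False, default=None)


def _structural_labels(spec: AtrophyPhantomSpec) -> np.ndarray:
    shape = tuple(int(n) for n in spec.grid_shape)
    r0, r1, r2 = (float(r) for r in spec.structure_radii)
    if spec.geometry == "nested_spheres":
        center = (np.asarray(shape, dtype=float) - 1.0) / 2.0
        grids = np.meshgrid(*(np.arange(n, dtype=float) for n in shape), indexing="ij")
        dist = np.sqrt(sum((axis - ctr) ** 2 for axis, ctr in zip(grids, center)))
        labels = np.full(shape, LABEL_BACKGROUND, dtype=np.int16)
        labels[dist < r2] = LABEL_WM
        labels[dist < r1] = LABEL_GM
        labels[dist < r0] = LABEL_CSF
    else:  # slab_stack
        x = np.arange(shape[0], dtype=float)
        slab = np.full(shape[0], LABEL_BACKGROUND, dtype=np.int16)
        slab[x < r2] = LABEL_WM
        slab[x < r1] = LABEL_GM
        slab[x < r0] = LABEL_CSF
        labels = np.broadcast_to(slab[:, None, None], shape).copy()
    return labels


def _labels_to_probabilities(labels: np.ndarray, blur_sigma: float) -> np.ndarray:
    data = np.zeros((4,) + labels.shape, dtype=np.float64)
    data[0] = labels == LABEL_GM
    data[1] = labels == LABEL_WM
    data[2] = labels == LABEL_CSF
    data[3] = labels == LABEL_BACKGROUND
    if blur_sigma > 0:
        for k in range(4):
            data[k] = gaussian_filter(data[k], sigma=blur_sigma, mode="nearest")
    return _renormalize(np.clip(data, 0.0, 1.0))


def _renormalize(data: np.ndarray) -> np.ndarray:
    """Project channel stack back onto the probability simplex."""
    sums = data.sum(axis=0)
    degenerate = sums <= 0
    if degenerate.any():
        # all-zero voxels become pure background
        data = data.copy()
        data[3, degenerate] = 1.0
        sums = data.sum(axis=0)
    return data / sums


def _add_noise(data: np.ndarray, noise_sd: float, rng: np.random.Generator) -> np.ndarray:
    if noise_sd <= 0:
        return data
    noisy = data + rng.normal(0.0, noise_sd, size=data.shape)
    return _renormalize(np.clip(noisy, 0.0, 1.0))


def atrophy_boundary_mask(spec: AtrophyPhantomSpec) -> np.ndarray:
    """GM-labeled voxels adjacent to the CSF compartment (pre-blur labels)."""
    labels = _structural_labels(spec)
    near_csf = binary_dilation(labels == LABEL_CSF)
    return (labels == LABEL_GM) & near_csf


def generate_phantom_pair(
    spec: AtrophyPhantomSpec,
) -> tuple[ProbabilityMapSet, ProbabilityMapSet, PhantomTruth]:
    """Generate a co-registered baseline / follow-up probability-map pair.

    Follow-up differs from baseline only by (a) GM->CSF probability
    transfer of ``atrophy_rate`` at the GM/CSF boundary, (b) the shared
    partial-volume blur, and (c) independent additive noise re-projected
    onto the simplex.  Deterministic given ``spec``.
    """
    spec.validate()
    labels = _structural_labels(spec)
    base = _labels_to_probabilities(labels, spec.blur_sigma)

    mask = atrophy_boundary_mask(spec) & (base[0] > 0)
    moved = np.zeros(labels.shape, dtype=np.float64)
    moved[mask] = spec.atrophy_rate

    follow = base.copy()
    dg = moved * base[0]
    follow[0] -= dg
    follow[2] += dg

    rng = np.random.default_rng(spec.seed)
    noisy_t = _add_noise(base, spec.noise_sd, rng)
    noisy_tt = _add_noise(follow, spec.noise_sd, rng)

    validity = np.ones(labels.shape, dtype=bool)
    maps_t = ProbabilityMapSet(noisy_t, validity.copy(), timepoint_tag="t")
    maps_tt = ProbabilityMapSet(noisy_tt, validity.copy(), timepoint_tag="tt")
    maps_t.check_invariants()
    maps_tt.check_invariants()
    return maps_t, maps_tt, PhantomTruth(atrophy_mask=mask, injected_gm_loss=moved)


def make_cohort(
    n_per_group: int,
    atrophy_rates_by_group: dict[str, float],
    base_spec: AtrophyPhantomSpec,
    seed: int,
) -> list[PhantomSubject]:
    """Simulate a cohort whose group differences are driven only by atrophy rate.

    Per-subject seeds are derived deterministically from the cohort seed
    via :class:`numpy.random.SeedSequence`, so a fixed cohort seed yields
    identical subjects across runs.
    """
    if n_per_group < 1:
        raise ValueError("n_per_group must be >= 1")
    groups = list(atrophy_rates_by_group)
    if len(set(groups)) != len(groups):
        raise ValueError("groups must be distinct")
    children = np.random.SeedSequence(seed).spawn(len(groups) * n_per_group)
    subjects: list[PhantomSubject] = []
    idx = 0
    for group in groups:
        rate = float(atrophy_rates_by_group[group])
        for i in range(n_per_group):
            subj_seed = int(children[idx].generate_state(1)[0])
            idx += 1
            spec = replace(base_spec, atrophy_rate=rate, seed=subj_seed)
            maps_t, maps_tt, truth = generate_phantom_pair(spec)
            subjects.append(
                PhantomSubject(f"{group}_{i:03d}", group, maps_t, maps_tt, truth, spec)
            )
    return subjects


def apply_transfer_matrix(maps: ProbabilityMapSet, matrix: np.ndarray) -> ProbabilityMapSet:
    """Apply a known 4x4 transition matrix voxelwise: ``p' = matrix @ p``.

    ``matrix[j, i]`` is the contribution of source tissue ``i`` to target
    tissue ``j`` (both in :data:`TISSUES` order).  Used to build map pairs
    whose exact per-voxel transition is known a priori.
    """
    matrix = np.asarray(matrix, dtype=np.float64)
    if matrix.shape != (4, 4):
        raise ValueError("transfer matrix must be 4x4")
    data = np.einsum("ji,i...->j...", matrix, maps.data)
    return ProbabilityMapSet(data, maps.voxel_validity.copy(), timepoint_tag="tt")


def gm_to_csf_transfer(phi: float) -> np.ndarray:
    """Transition matrix moving fraction ``phi`` of GM probability to CSF."""
    if not 0.0 <= phi <= 1.0:
        raise ValueError("phi must be in [0, 1]")
    matrix = np.eye(4)
    matrix[0, 0] = 1.0 - phi
    matrix[2, 0] = phi
    return matrix


#: Four probability vectors (g, w, c, b) with entries either 0 or >= 0.2,
#: jointly of full rank.  Tiling them guarantees every 3x3x3 neighborhood
#: yields a full-column-rank design untouched by the 0.2 threshold, even
#: after a GM->CSF transfer of up to 50%.
FULL_RANK_VECTORS = np.array(
    [
        [0.4, 0.3, 0.3, 0.0],
        [0.4, 0.2, 0.2, 0.2],
        [0.5, 0.0, 0.3, 0.2],
        [0.4, 0.4, 0.2, 0.0],
    ]
)


def tiled_probability_volume(
    grid_shape: Sequence[int], vectors: np.ndarray | None = None
) -> ProbabilityMapSet:
    """Volume where voxel (x, y, z) holds ``vectors[(x + y + z) % 4]``.

    Any 3x3x3 window spans seven consecutive values of x+y+z, hence all
    four residues mod 4, so every neighborhood contains all four vectors.
    """
    if vectors is None:
        vectors = FULL_RANK_VECTORS
    vectors = np.asarray(vectors, dtype=np.float64)
    if vectors.shape != (4, 4):
        raise ValueError("need exactly 4 probability 4-vectors")
    if not np.allclose(vectors.sum(axis=1), 1.0, atol=1e-9):
        raise ValueError("each vector must sum to 1")
    shape = tuple(int(n) for n in grid_shape)
    grids = np.meshgrid(*(np.arange(n) for n in shape), indexing="ij")
    phase = (grids[0] + grids[1] + grids[2]) % 4
    data = np.moveaxis(vectors[phase], -1, 0)
    return ProbabilityMapSet(np.ascontiguousarray(data), np.ones(shape, dtype=bool))
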