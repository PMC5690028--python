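"""Alternating energy-minimization solver.

Model: ``f(x) = sum_i c_i u_i(x) + w^T G(x) + noise`` over the object support.
The energy ``sum_x (f - c_label(x) - w^T G(x))**2`` is convex in each block
(w, c, u) separately, so each sub-update below is an exact minimizer and the
energy never increases.  Iteration stops when the Euclidean change in the
tissue-mean vector (on the internal [0, 1] intensity scale) drops below
``eps``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
from scipy.cluster.vq import kmeans2

from emmcup.basis import BasisSet, build_polynomial_basis, orthonormalize
from emmcup.errors import (
    DegenerateInputError,
    NumericalFailureError,
    RankDeficiencyError,
)

logger = logging.getLogger("emmcup")

__all__ = [
    "ImageGrid",
    "MembershipMap",
    "TissueMeans",
    "BiasCoefficients",
    "CorrectionState",
    "DecompositionResult",
    "SolverConfig",
    "auto_mask",
    "evaluate_energy",
    "update_coefficients",
    "update_means",
    "update_membership",
    "initialize_state",
    "run_correction",
]


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ImageGrid:
    """A 2-D reconstructed slice with an object-support mask.

    ``intensity_scale`` records the (min, max) of the data the grid was
    built from, so a normalized copy can restore original units exactly.
    """

    intensities: np.ndarray
    mask: np.ndarray
    intensity_scale: tuple[float, float]

    def __post_init__(self):
        if self.intensities.ndim != 2:
            raise ValueError("intensities must be 2-D")
        if self.mask.shape != self.intensities.shape:
            raise ValueError("mask shape differs from intensities shape")
        if self.mask.dtype != bool:
            object.__setattr__(self, "mask", self.mask.astype(bool))
        if not self.mask.any():
            raise ValueError("mask has no true pixels")
        if not np.all(np.isfinite(self.intensities[self.mask])):
            raise ValueError("non-finite intensity inside the mask")

    @classmethod
    def from_array(cls, data, mask=None) -> "ImageGrid":
        data = np.asarray(data, dtype=np.float64)
        if mask is None:
            mask = np.ones(data.shape, dtype=bool)
        else:
            mask = np.asarray(mask, dtype=bool)
        lo = float(data[mask].min())
        hi = float(data[mask].max())
        return cls(intensities=data, mask=mask, intensity_scale=(lo, hi))

    @property
    def shape(self) -> tuple[int, int]:
        return self.intensities.shape

    def masked_values(self) -> np.ndarray:
        return self.intensities[self.mask]

    def normalized(self) -> "ImageGrid":
        """Copy with masked intensities affinely mapped onto [0, 1]."""
        lo, hi = self.intensity_scale
        span = hi - lo if hi > lo else 1.0
        return ImageGrid(
            intensities=(self.intensities - lo) / span,
            mask=self.mask,
            intensity_scale=(lo, hi),
        )


@dataclass(frozen=True)
class MembershipMap:
    """Hard tissue partition: label field with values 1..N inside the mask."""

    labels: np.ndarray
    count: int

    def binary_map(self, i: int) -> np.ndarray:
        """u_i as a boolean field (1-based tissue index)."""
        return self.labels == i


@dataclass(frozen=True)
class TissueMeans:
    values: np.ndarray

    def __post_init__(self):
        object.__setattr__(
            self, "values", np.asarray(self.values, dtype=np.float64)
        )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite tissue mean")


@dataclass(frozen=True)
class BiasCoefficients:
    values: np.ndarray

    def __post_init__(self):
        object.__setattr__(
            self, "values", np.asarray(self.values, dtype=np.float64)
        )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite bias coefficient")


@dataclass
class CorrectionState:
    membership: MembershipMap
    means: TissueMeans
    coefficients: BiasCoefficients
    energy_trace: list = field(default_factory=list)

    @property
    def iteration(self) -> int:
        return len(self.energy_trace) - 1


@dataclass(frozen=True)
class DecompositionResult:
    """Estimated decomposition in original intensity units.

    ``bias_field`` has zero mean over the mask (the constant component of
    the fitted field is folded into the tissue means, keeping the corrected
    image's mean intensity equal to the input's), so
    ``corrected + bias_field == f`` exactly.
    """

    bias_field: np.ndarray
    piecewise_image: np.ndarray
    corrected: np.ndarray
    converged: bool
    iterations: int
    final_energy: float
    energy_trace: tuple
    state: CorrectionState
    mask: np.ndarray


@dataclass(frozen=True)
class SolverConfig:
    n_tissues: int = 3
    degree: int = 3
    eps: float = 1e-3
    max_iter: int = 50
    orthonormalize: bool = False
    # seeded k-means is the default: the quantile initializer can merge
    # tissue classes when the cupping spread exceeds the class separation
    init: str = "kmeans"  # or "quantile"
    seed: int = 0

    def __post_init__(self):
        if self.n_tissues < 1:
            raise ValueError("n_tissues must be >= 1")
        if self.eps <= 0:
            raise ValueError("eps must be > 0")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.degree < 0:
            raise ValueError("degree must be >= 0")


# --------------------------------------------------------------------------
# masking
# --------------------------------------------------------------------------


def auto_mask(intensities: np.ndarray) -> np.ndarray:
    """Object-support mask: Otsu threshold, largest component, holes filled.

    Falls back to an all-true mask for (near-)constant images.
    """
    from scipy import ndimage
    from skimage.filters import threshold_otsu
    from skimage.measure import label

    data = np.asarray(intensities, dtype=np.float64)
    if np.ptp(data) == 0:
        return np.ones(data.shape, dtype=bool)
    thresh = threshold_otsu(data)
    fg = data > thresh
    if not fg.any():
        return np.ones(data.shape, dtype=bool)
    lab = label(fg)
    counts = np.bincount(lab.ravel())
    counts[0] = 0
    fg = lab == counts.argmax()
    return ndimage.binary_fill_holes(fg)


# --------------------------------------------------------------------------
# sub-updates
# --------------------------------------------------------------------------


def _check_dims(grid: ImageGrid, basis: BasisSet, n_tissues=None, labels=None):
    if basis.functions.shape[1:] != grid.shape:
        raise ValueError("basis grid shape differs from image shape")
    if labels is not None and labels.shape != grid.shape:
        raise ValueError("membership shape differs from image shape")


def evaluate_energy(grid: ImageGrid, basis: BasisSet, state: CorrectionState) -> float:
    """Sum of squared residuals ``(f - c_label - w^T G)**2`` over the mask."""
    _check_dims(grid, basis, labels=state.membership.labels)
    c = state.means.values
    if state.membership.count != c.size:
        raise ValueError("membership count differs from number of tissue means")
    if state.coefficients.values.size != basis.count:
        raise ValueError("coefficient count differs from basis size")
    mask = grid.mask
    fs = state.coefficients.values @ basis.functions[:, mask]
    fp = c[state.membership.labels[mask] - 1]
    r = grid.intensities[mask] - fp - fs
    return float(np.dot(r, r))


def update_coefficients(
    grid: ImageGrid,
    basis: BasisSet,
    membership: MembershipMap,
    means: TissueMeans,
) -> BiasCoefficients:
    """Exact minimizer in w: solve ``A w = v`` with the masked normal equations."""
    _check_dims(grid, basis, labels=membership.labels)
    mask = grid.mask
    residual = grid.intensities[mask] - means.values[membership.labels[mask] - 1]
    v = basis.functions[:, mask] @ residual
    try:
        w = scipy.linalg.solve(basis.gram, v, assume_a="pos")
    except (scipy.linalg.LinAlgError, ValueError) as exc:
        raise RankDeficiencyError(
            "Gram matrix is singular; use a smaller basis degree or a larger "
            f"mask ({exc})"
        ) from exc
    if not np.all(np.isfinite(w)):
        raise RankDeficiencyError(
            "Gram solve produced non-finite coefficients; the basis is "
            "rank-deficient on this mask"
        )
    return BiasCoefficients(values=w)


def update_means(
    grid: ImageGrid,
    basis: BasisSet,
    membership: MembershipMap,
    coefficients: BiasCoefficients,
    previous: TissueMeans | None = None,
) -> TissueMeans:
    """Exact minimizer in c: per-class mean of the bias-subtracted image.

    A tissue class with no member pixels keeps its ``previous`` value
    (division-by-zero guard); if no previous means are supplied an empty
    class raises :class:`DegenerateInputError`.
    """
    _check_dims(grid, basis, labels=membership.labels)
    mask = grid.mask
    fs = coefficients.values @ basis.functions[:, mask]
    debiased = grid.intensities[mask] - fs
    labels = membership.labels[mask]
    n = membership.count
    counts = np.bincount(labels - 1, minlength=n).astype(np.float64)
    sums = np.bincount(labels - 1, weights=debiased, minlength=n)
    values = np.empty(n, dtype=np.float64)
    nonempty = counts > 0
    values[nonempty] = sums[nonempty] / counts[nonempty]
    if not nonempty.all():
        if previous is None:
            empty = np.nonzero(~nonempty)[0] + 1
            raise DegenerateInputError(
                f"tissue class(es) {empty.tolist()} have no pixels and no "
                "previous means to fall back on"
            )
        values[~nonempty] = previous.values[~nonempty]
    return TissueMeans(values=values)


def update_membership(
    grid: ImageGrid,
    basis: BasisSet,
    means: TissueMeans,
    coefficients: BiasCoefficients,
) -> MembershipMap:
    """Exact minimizer in u: per-pixel argmin of the squared residual.

    Ties resolve to the smallest tissue index.
    """
    _check_dims(grid, basis)
    mask = grid.mask
    fs = coefficients.values @ basis.functions[:, mask]
    debiased = grid.intensities[mask] - fs
    resid = (debiased[None, :] - means.values[:, None]) ** 2
    best = np.argmin(resid, axis=0)  # argmin takes the first minimum: tie-break
    labels = np.zeros(grid.shape, dtype=np.int32)
    labels[mask] = best + 1
    return MembershipMap(labels=labels, count=means.values.size)


def initialize_state(
    grid: ImageGrid,
    basis: BasisSet,
    n_tissues: int,
    seed: int = 0,
    method: str = "quantile",
) -> CorrectionState:
    """Initial (u, c, w): quantile means, zero coefficients, nearest-mean labels.

    The default quantile initializer places the means at the
    ``(i - 0.5)/N`` quantiles of the masked intensities and is fully
    deterministic; ``method="kmeans"`` runs a seeded 1-D k-means instead.
    """
    if n_tissues < 1:
        raise ValueError("n_tissues must be >= 1")
    values = grid.masked_values()
    if np.unique(values).size < n_tissues:
        raise DegenerateInputError(
            f"requested {n_tissues} tissues but the mask holds only "
            f"{np.unique(values).size} distinct intensity value(s)"
        )
    if method == "quantile":
        levels = (np.arange(n_tissues) + 0.5) / n_tissues
        c = np.quantile(values, levels)
    elif method == "kmeans":
        centroids, _ = kmeans2(
            values.reshape(-1, 1), n_tissues, minit="++", seed=seed
        )
        c = centroids.ravel()
    else:
        raise ValueError(f"unknown initializer {method!r}")
    means = TissueMeans(values=np.sort(c))
    coeffs = BiasCoefficients(values=np.zeros(basis.count))
    membership = update_membership(grid, basis, means, coeffs)
    state = CorrectionState(
        membership=membership, means=means, coefficients=coeffs
    )
    state.energy_trace.append(evaluate_energy(grid, basis, state))
    return state


# --------------------------------------------------------------------------
# solver loop
# --------------------------------------------------------------------------


def run_correction(grid: ImageGrid, config: SolverConfig | None = None) -> DecompositionResult:
    """Run the alternating minimization to convergence.

    Per iteration: coefficient update, mean update, membership update, then
    the stopping test ``||c_new - c_old|| < eps`` on the normalized scale.
    """
    if config is None:
        config = SolverConfig()
    ngrid = grid.normalized()
    basis = build_polynomial_basis(ngrid, config.degree)
    if config.orthonormalize:
        basis = orthonormalize(basis)
    state = initialize_state(
        ngrid, basis, config.n_tissues, seed=config.seed, method=config.init
    )
    logger.info("iter %3d  energy %.6e", 0, state.energy_trace[0])
    converged = False
    iterations = 0
    for it in range(1, config.max_iter + 1):
        c_old = state.means.values
        coeffs = update_coefficients(ngrid, basis, state.membership, state.means)
        means = update_means(
            ngrid, basis, state.membership, coeffs, previous=state.means
        )
        membership = update_membership(ngrid, basis, means, coeffs)
        state = CorrectionState(
            membership=membership,
            means=means,
            coefficients=coeffs,
            energy_trace=state.energy_trace,
        )
        energy = evaluate_energy(ngrid, basis, state)
        if not np.isfinite(energy):
            raise NumericalFailureError(
                f"non-finite energy at iteration {it}"
            )
        state.energy_trace.append(energy)
        delta = float(np.linalg.norm(means.values - c_old))
        logger.info("iter %3d  energy %.6e  |dc| %.3e", it, energy, delta)
        iterations = it
        if delta < config.eps:
            converged = True
            break

    lo, hi = grid.intensity_scale
    span = hi - lo if hi > lo else 1.0
    mask = grid.mask

    fs = state.coefficients.values @ basis.functions.reshape(basis.count, -1)
    fs = fs.reshape(grid.shape)
    fs = np.where(mask, fs, 0.0)
    fs_mean = fs[mask].mean()
    fs[mask] -= fs_mean  # zero mean over mask: corrected keeps the input mean
    bias_field = fs * span

    fp = np.where(
        mask,
        (state.means.values[np.maximum(state.membership.labels, 1) - 1] + fs_mean)
        * span
        + lo,
        grid.intensities,
    )
    corrected = grid.intensities - bias_field
    return DecompositionResult(
        bias_field=bias_field,
        piecewise_image=fp,
        corrected=corrected,
        converged=converged,
        iterations=iterations,
        final_energy=float(state.energy_trace[-1]),
        energy_trace=tuple(state.energy_trace),
        state=state,
        mask=mask.copy(),
    )
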