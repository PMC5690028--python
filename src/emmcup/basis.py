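"""Polynomial basis functions on a masked image grid.

The smooth bias field is expanded in the complete set of bivariate monomials
``x**a * y**b`` with ``a + b <= degree``, evaluated on coordinates affinely
normalized to [-1, 1] over the mask's bounding box (x along columns, y along
rows).  For ``degree = 3`` this yields 10 functions.  The Gram matrix is the
sum of outer products of the basis vector over masked pixels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from emmcup.errors import RankDeficiencyError

__all__ = ["BasisSet", "build_polynomial_basis", "orthonormalize", "monomial_exponents"]


def monomial_exponents(degree: int) -> list[tuple[int, int]]:
    """Exponent pairs ``(a, b)`` with ``a + b <= degree``.

    Ordered by total degree, then lexicographically by ``(a, b)``.
    """
    if degree < 0:
        raise ValueError(f"degree must be >= 0, got {degree}")
    return [(a, d - a) for d in range(degree + 1) for a in range(d + 1)]


def normalized_coordinates(mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel (x, y) coordinates mapped to [-1, 1] over the mask bbox.

    x varies along columns, y along rows.  A degenerate (single row/column)
    extent maps to 0.
    """
    rows, cols = np.nonzero(mask)
    if rows.size == 0:
        raise ValueError("mask is empty")
    r0, r1 = rows.min(), rows.max()
    c0, c1 = cols.min(), cols.max()
    rr = np.arange(mask.shape[0], dtype=np.float64)
    cc = np.arange(mask.shape[1], dtype=np.float64)
    y1d = np.zeros_like(rr) if r1 == r0 else -1.0 + 2.0 * (rr - r0) / (r1 - r0)
    x1d = np.zeros_like(cc) if c1 == c0 else -1.0 + 2.0 * (cc - c0) / (c1 - c0)
    y, x = np.meshgrid(y1d, x1d, indexing="ij")
    return x, y


@dataclass(frozen=True)
class BasisSet:
    """M smooth basis fields sampled on a grid plus their Gram matrix.

    Attributes
    ----------
    functions : (M, rows, cols) float array
        Basis fields evaluated on the full grid.
    count : int
        Number of basis functions M.
    gram : (M, M) float array
        ``sum_x G(x) G(x)^T`` over masked pixels; symmetric positive definite
        for any mask of >= M pixels in general position.
    mask_reference : (rows, cols) bool array
        The mask used for the Gram accumulation.
    orthonormalized : bool
        True if the functions were re-combined so that ``gram`` is identity.
    exponents : tuple of (a, b) pairs or None
        Monomial exponents for a raw polynomial basis.
    """

    functions: np.ndarray
    count: int
    gram: np.ndarray
    mask_reference: np.ndarray
    orthonormalized: bool = False
    exponents: tuple | None = field(default=None)

    def masked_matrix(self) -> np.ndarray:
        """(M, m) matrix of basis values at masked pixels."""
        return self.functions[:, self.mask_reference]


def build_polynomial_basis(grid, degree: int) -> BasisSet:
    """Complete bivariate monomial basis of total degree <= ``degree``.

    Raises
    ------
    ValueError
        If ``degree`` is negative.
    RankDeficiencyError
        If the mask holds fewer pixels than basis functions.
    """
    exps = monomial_exponents(degree)
    m_pix = int(grid.mask.sum())
    if m_pix < len(exps):
        raise RankDeficiencyError(
            f"mask has {m_pix} pixels but the degree-{degree} basis needs "
            f"{len(exps)}; enlarge the mask or lower the degree"
        )
    x, y = normalized_coordinates(grid.mask)
    functions = np.stack([x**a * y**b for a, b in exps])
    v = functions[:, grid.mask]
    gram = v @ v.T
    gram = 0.5 * (gram + gram.T)
    return BasisSet(
        functions=functions,
        count=len(exps),
        gram=gram,
        mask_reference=grid.mask.copy(),
        orthonormalized=False,
        exponents=tuple(exps),
    )


def orthonormalize(basis: BasisSet) -> BasisSet:
    """Re-combine the basis so its Gram matrix over the mask is the identity.

    Equivalent to Gram-Schmidt with respect to the masked-pixel inner
    product; implemented via a QR factorization of the pixel-by-function
    matrix.  The span is unchanged.
    """
    v = basis.masked_matrix().T  # (m, M)
    q, r = np.linalg.qr(v)
    diag = np.abs(np.diag(r))
    col_norms = np.linalg.norm(v, axis=0)
    bad = np.nonzero(diag <= 1e-12 * np.maximum(col_norms, 1.0))[0]
    if bad.size:
        raise RankDeficiencyError(
            f"basis function {int(bad[0])} is numerically dependent on its "
            "predecessors over this mask"
        )
    # fix signs so the transform is the Gram-Schmidt one (positive diagonal)
    signs = np.sign(np.diag(r))
    transform = np.linalg.inv(r * signs[:, None])  # V @ T has identity Gram
    functions = np.einsum("kij,kl->lij", basis.functions, transform)
    w = functions[:, basis.mask_reference]
    gram = w @ w.T
    return BasisSet(
        functions=functions,
        count=basis.count,
        gram=gram,
        mask_reference=basis.mask_reference,
        orthonormalized=True,
        exponents=None,
    )
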