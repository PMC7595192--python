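"""Polynomial kernels for exposure-response surfaces.

The exposure-response function within each collection window is modelled in
the reproducing-kernel Hilbert space of a quadratic polynomial kernel,

    k(z, z') = (offset + <z, z'>) ** degree,

which with ``degree=2`` spans linear, quadratic and two-way product terms of
the metal concentrations -- exactly the surface class the contrast estimands
interrogate.  A small jitter is added to Gram-matrix diagonals so the matrix
is strictly positive definite and can be Cholesky-factored.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class KernelSpec:
    """Polynomial kernel parameters.

    degree=2, offset=1 give the quadratic kernel used throughout; ``jitter``
    is the ridge added to square Gram matrices (>= 0).
    """

    degree: int = 2
    offset: float = 1.0
    jitter: float = 1e-8

    def __post_init__(self) -> None:
        if self.degree < 1:
            raise ValueError("kernel degree must be >= 1")
        if self.offset < 0:
            raise ValueError("kernel offset must be >= 0")
        if self.jitter < 0:
            raise ValueError("kernel jitter must be >= 0")


def _check_finite(Z: np.ndarray, name: str) -> np.ndarray:
    Z = np.asarray(Z, dtype=float)
    if Z.ndim != 2:
        raise ValueError(f"{name} must be a 2-d array, got shape {Z.shape}")
    if not np.all(np.isfinite(Z)):
        raise ValueError(f"non-finite entries in {name}")
    return Z


def build_kernel(Z: np.ndarray, spec: KernelSpec) -> np.ndarray:
    """Square Gram matrix of ``Z`` with jitter on the diagonal."""
    Z = _check_finite(Z, "exposure matrix")
    K = (spec.offset + Z @ Z.T) ** spec.degree
    K[np.diag_indices_from(K)] += spec.jitter
    return K


def build_cross_kernel(Z_new: np.ndarray, Z: np.ndarray, spec: KernelSpec) -> np.ndarray:
    """Cross Gram matrix k(Z_new, Z); no jitter."""
    Z_new = _check_finite(Z_new, "new exposure matrix")
    Z = _check_finite(Z, "exposure matrix")
    if Z_new.shape[1] != Z.shape[1]:
        raise ValueError(
            f"dimension mismatch: new points have {Z_new.shape[1]} exposure "
            f"columns, training points have {Z.shape[1]}"
        )
    return (spec.offset + Z_new @ Z.T) ** spec.degree


def polynomial_features(Z: np.ndarray, spec: KernelSpec) -> np.ndarray:
    """Explicit degree-2 feature map whose inner products equal the kernel.

    Columns: [offset, sqrt(2*offset)*z_i, z_i**2, sqrt(2)*z_i*z_j (i<j)], so
    Phi @ Phi.T == (offset + Z Z')**2 exactly.  Used by the low-rank posterior
    solver and by the feature-map cross-check of the Gram matrix.
    """
    if spec.degree != 2:
        raise ValueError("explicit feature map implemented for degree 2 only")
    Z = _check_finite(Z, "exposure matrix")
    n, m = Z.shape
    cols = []
    if spec.offset > 0:
        cols.append(np.full((n, 1), spec.offset))
        cols.append(np.sqrt(2.0 * spec.offset) * Z)
    cols.append(Z**2)
    for i in range(m):
        for j in range(i + 1, m):
            cols.append(np.sqrt(2.0) * (Z[:, i] * Z[:, j])[:, None])
    return np.hstack(cols)
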