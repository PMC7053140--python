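"""Diffusion-map and PCA cell ordering for coverage heat maps.

Cells are reordered by a one-dimensional "local pseudo-time": the first
diffusion component (DC1) of a diffusion map computed on the cells x bins
coverage matrix of the focal region, or alternatively the first principal
component. Ordering can be applied across all cells jointly or
independently within user-defined cell groups (group-wise), in which case
each group stays a contiguous block of the heat map.

The diffusion map uses the classical density-normalized construction:
a Gaussian kernel on Euclidean row distances with zeroed diagonal,
W_ij = exp(-||x_i - x_j||^2 / (2 sigma^2)); the anisotropic (alpha = 1)
normalization W~ = D^-1 W D^-1 with D the diagonal of row sums of W; and
the eigendecomposition of the resulting transition operator via its
symmetric conjugate. The trivial constant eigenvector is discarded and each
remaining component is scaled by its eigenvalue. No k-nearest-neighbor
sparsification is applied: the matrices here hold the cells of one plot and
dense kernels suffice.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Optional, Sequence, Union

import numpy as np
import scipy.linalg

from .coverage import CoverageMatrix, group_order

__all__ = [
    "DegenerateGeometry",
    "DiffusionResult",
    "CellOrdering",
    "diffusion_map",
    "pca_first_component",
    "order_cells",
]

_SIGN_TOL = 1e-12


class DegenerateGeometry(Exception):
    """Raised when an embedding is undefined (identical rows, zero bandwidth).

    Callers fall back to input order.
    """


@dataclass(frozen=True)
class DiffusionResult:
    """Diffusion components of one coverage matrix.

    ``components`` is cells x k with DC1 in column 0; ``eigenvalues`` are
    the corresponding eigenvalues of the transition operator, descending,
    with the trivial unit eigenvalue already discarded.
    """

    components: np.ndarray
    eigenvalues: np.ndarray
    kernel_sigma: float


@dataclass(frozen=True)
class CellOrdering:
    """A permutation of cell indices with provenance.

    ``permutation[j]`` is the input index of the cell drawn in display row
    ``j``. ``scores`` holds the per-cell ordering value (DC1 or PC1) indexed
    by input position; NaN marks cells ordered by fallback (degenerate or
    undersized groups, or ``method="none"``).
    """

    permutation: np.ndarray
    method: Literal["diffusion", "pca", "none"]
    scope: Literal["all_cells", "group_wise"]
    scores: np.ndarray

    def __post_init__(self) -> None:
        perm = np.asarray(self.permutation, dtype=np.intp)
        object.__setattr__(self, "permutation", perm)
        object.__setattr__(self, "scores", np.asarray(self.scores, dtype=float))
        if sorted(perm.tolist()) != list(range(len(perm))):
            raise ValueError("permutation must be a bijection on cell indices")


def _fix_sign(vec: np.ndarray, tol: float = _SIGN_TOL) -> np.ndarray:
    """Orient a component so the lowest-index cell with |value| > tol is positive."""
    scale = np.max(np.abs(vec)) if vec.size else 0.0
    nz = np.nonzero(np.abs(vec) > tol * max(scale, 1.0))[0]
    if nz.size and vec[nz[0]] < 0:
        return -vec
    return vec


def auto_sigma(m: np.ndarray) -> float:
    """Default kernel bandwidth: median pairwise nonzero distance / sqrt(2).

    Deterministic and scale-free; raises :class:`DegenerateGeometry` when
    all rows coincide (no nonzero distance exists).
    """
    d2 = _pairwise_sq_dists(m)
    iu = np.triu_indices(m.shape[0], k=1)
    dists = np.sqrt(d2[iu])
    nonzero = dists[dists > 0]
    if nonzero.size == 0:
        raise DegenerateGeometry("all rows identical; no usable bandwidth")
    return float(np.median(nonzero)) / np.sqrt(2.0)


def _pairwise_sq_dists(m: np.ndarray) -> np.ndarray:
    sq = np.sum(m * m, axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (m @ m.T)
    np.maximum(d2, 0.0, out=d2)
    return d2


def diffusion_map(
    m: np.ndarray,
    k: int = 1,
    sigma: Union[float, Literal["auto"]] = "auto",
) -> DiffusionResult:
    """Compute the first *k* diffusion components of the rows of *m*.

    Parameters
    ----------
    m
        cells x features matrix with finite entries; at least 3 rows.
    k
        Number of non-trivial components, ``k < n_cells``.
    sigma
        Gaussian kernel bandwidth in units of row Euclidean distance, or
        ``"auto"`` for the median-distance heuristic.

    The result is deterministic: eigenvector sign ambiguity is resolved by
    orienting each component so its value for the lowest-index cell with a
    nonzero entry is positive.
    """
    m = np.asarray(m, dtype=float)
    if m.ndim != 2:
        raise ValueError("input must be a 2-D matrix")
    n = m.shape[0]
    if n < 3:
        raise DegenerateGeometry(f"diffusion map needs >= 3 cells, got {n}")
    if not (1 <= k < n):
        raise ValueError(f"k must satisfy 1 <= k < n_cells, got k={k}, n={n}")
    if not np.all(np.isfinite(m)):
        raise ValueError("input matrix contains non-finite entries")

    if sigma == "auto":
        sig = auto_sigma(m)
    else:
        sig = float(sigma)
    if not np.isfinite(sig) or sig <= 0:
        raise DegenerateGeometry(f"degenerate kernel bandwidth {sig}")

    d2 = _pairwise_sq_dists(m)
    W = np.exp(-d2 / (2.0 * sig * sig))
    np.fill_diagonal(W, 0.0)
    q = W.sum(axis=1)
    if np.any(q <= 0):
        raise DegenerateGeometry("isolated cell: kernel row sum is zero")

    # anisotropic alpha=1 normalization, then the symmetric conjugate of the
    # transition matrix P = Dt^-1 Wt:  S = Dt^-1/2 Wt Dt^-1/2
    Wt = W / np.outer(q, q)
    dt = Wt.sum(axis=1)
    inv_sqrt = 1.0 / np.sqrt(dt)
    S = Wt * np.outer(inv_sqrt, inv_sqrt)
    S = (S + S.T) / 2.0  # enforce exact symmetry against rounding

    evals, evecs = scipy.linalg.eigh(S)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]

    # drop the trivial lambda=1 / constant eigenvector, keep k components
    comps = np.empty((n, k))
    lams = np.empty(k)
    for j in range(k):
        psi = inv_sqrt * evecs[:, j + 1]
        norm = np.linalg.norm(psi)
        if norm > 0:
            psi = psi / norm
        comps[:, j] = _fix_sign(evals[j + 1] * psi)
        lams[j] = evals[j + 1]
    return DiffusionResult(components=comps, eigenvalues=lams, kernel_sigma=sig)


def pca_first_component(m: np.ndarray) -> np.ndarray:
    """Per-cell scores on the first principal component of the rows of *m*.

    Rows are column-mean-centered and projected onto the first right
    singular direction; the sign is fixed by the same convention as the
    diffusion components.
    """
    m = np.asarray(m, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2:
        raise DegenerateGeometry("PCA ordering needs >= 2 cells")
    if not np.all(np.isfinite(m)):
        raise ValueError("input matrix contains non-finite entries")
    x = m - m.mean(axis=0)
    if not np.any(np.abs(x) > 0):
        raise DegenerateGeometry("all rows identical; PC1 undefined")
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    return _fix_sign(u[:, 0] * s[0])


def _scores_for_block(
    m: np.ndarray, method: str, sigma: Union[float, str], log1p: bool
) -> np.ndarray:
    x = np.log1p(m) if log1p else m
    if method == "diffusion":
        return diffusion_map(x, k=1, sigma=sigma).components[:, 0]
    if method == "pca":
        return pca_first_component(x)
    raise ValueError(f"unknown ordering method {method!r}")


def order_cells(
    m: Union[CoverageMatrix, np.ndarray],
    method: Literal["diffusion", "pca", "none"] = "diffusion",
    scope: Literal["all_cells", "group_wise"] = "all_cells",
    groups: Optional[Sequence[str]] = None,
    sigma: Union[float, Literal["auto"]] = "auto",
    log1p: bool = False,
) -> CellOrdering:
    """Produce the display ordering of cells for a coverage heat map.

    With ``scope="all_cells"`` cells are sorted by ascending score computed
    on all rows jointly. With ``scope="group_wise"`` scores are computed
    independently per group from that group's rows only, each group stays a
    contiguous block, and blocks follow first-appearance group order. Ties
    are broken by input order (stable sort). A degenerate group — fewer
    than 3 cells for the diffusion map, or geometrically degenerate rows —
    keeps its input order with a warning.
    """
    if isinstance(m, CoverageMatrix):
        data = m.matrix
        if groups is None:
            groups = m.groups
    else:
        data = np.asarray(m, dtype=float)
    n = data.shape[0]
    scores = np.full(n, np.nan)

    if method == "none":
        return CellOrdering(np.arange(n), "none", scope, scores)

    if scope == "all_cells":
        blocks = [np.arange(n)]
    elif scope == "group_wise":
        if groups is None:
            raise ValueError("group_wise ordering requires group labels")
        blocks = [
            np.array([i for i, g in enumerate(groups) if g == label], dtype=np.intp)
            for label in group_order(groups)
        ]
    else:
        raise ValueError(f"unknown scope {scope!r}")

    permutation = []
    for idx in blocks:
        try:
            block_scores = _scores_for_block(data[idx], method, sigma, log1p)
            scores[idx] = block_scores
            permutation.extend(idx[np.argsort(block_scores, kind="stable")])
        except DegenerateGeometry as exc:
            warnings.warn(
                f"ordering fallback to input order for {len(idx)} cells: {exc}",
                stacklevel=2,
            )
            permutation.extend(idx)
    return CellOrdering(np.array(permutation, dtype=np.intp), method, scope, scores)
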