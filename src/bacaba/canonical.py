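"""Canonical variable analysis of genotype divergence.

Canonical variables are the linear trait combinations maximising
between-genotype relative to pooled within-genotype variance: the
eigen-solution of W^-1 B, with W the pooled within-group covariance (error
SSCP / df, per-observation scale) and B the between-group covariance on the
same scale (treatment SSCP / (G-1), i.e. including the replicate factor r).
The generalized problem is solved in symmetric reduced form
L^-1 B L^-T u = lambda u with W = L L^T, and the weighting vectors
a = L^-T u satisfy a' W a = 1, so squared Euclidean distances between
genotype scores in the full canonical space equal Mahalanobis D².
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg

from .datatypes import DesignError, TraitTable, ValidityError
from .divergence import pooled_residual_covariance

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class CanonicalResult:
    traits: tuple[str, ...]
    eigenvalues: np.ndarray            # descending, >= 0 up to round-off
    percent_variance: np.ndarray
    accumulated_percent: np.ndarray
    weights: np.ndarray                # columns a_j, normalized a'Wa = 1
    scores: pd.DataFrame               # genotypes x canonical variables

    @property
    def n_axes(self) -> int:
        return len(self.eigenvalues)


def _whitening_factor(W: np.ndarray) -> tuple[np.ndarray, bool]:
    """Lower-triangular L with W = L L', or a spectral factor if W is singular."""
    try:
        return linalg.cholesky(W, lower=True), False
    except linalg.LinAlgError:
        warnings.warn("singular within-group covariance; spectral pseudo-factor used")
        lam, V = np.linalg.eigh(W)
        cutoff = 1e-12 * max(lam.max(), 1.0)
        lam = np.where(lam > cutoff, lam, np.inf)  # inf -> zero weight directions
        return V * np.sqrt(np.where(np.isinf(lam), 1.0, lam)), True


def canonical_variables(
    table: TraitTable, traits: list[str] | None = None
) -> CanonicalResult:
    """Eigenvalues, variance shares, weighting vectors and genotype scores."""
    if not table.balanced:
        raise DesignError("canonical analysis requires a balanced table")
    traits = list(traits) if traits is not None else table.traits
    psi = pooled_residual_covariance(table, traits)
    W = psi.psi
    means = table.genotype_means(traits)
    X = means.to_numpy(dtype=float)
    G, p = X.shape
    r = table.n_replicates
    centred = X - X.mean(axis=0)
    B = r * (centred.T @ centred) / (G - 1)

    L, pseudo = _whitening_factor(W)
    if pseudo:
        Winv_half = np.linalg.pinv(L, rcond=1e-12)
        M = Winv_half @ B @ Winv_half.T
    else:
        Linv = linalg.solve_triangular(L, np.eye(p), lower=True)
        M = Linv @ B @ Linv.T
    M = (M + M.T) / 2.0
    lam, U = np.linalg.eigh(M)
    order = np.argsort(lam)[::-1]
    lam, U = lam[order], U[:, order]
    if lam.min() < -1e-10 * max(lam.max(), 1.0):
        warnings.warn("markedly negative canonical eigenvalue; clamped")
    lam = np.clip(lam, 0.0, None)

    if pseudo:
        A = Winv_half.T @ U
    else:
        A = linalg.solve_triangular(L, U, lower=True, trans="T")
    # sign convention: largest-|element| of each weighting vector positive
    for j in range(A.shape[1]):
        i = int(np.argmax(np.abs(A[:, j])))
        if A[i, j] < 0:
            A[:, j] = -A[:, j]

    total = lam.sum()
    pct = 100.0 * lam / total if total > 0 else np.zeros_like(lam)
    scores = pd.DataFrame(
        X @ A,
        index=means.index,
        columns=[f"CV{j + 1}" for j in range(p)],
    )
    log.info("canonical: %d axes, first two explain %.1f%%",
             p, pct[:2].sum() if p >= 2 else pct.sum())
    return CanonicalResult(
        traits=tuple(traits), eigenvalues=lam, percent_variance=pct,
        accumulated_percent=np.cumsum(pct), weights=A, scores=scores,
    )


def biplot_scores(result: CanonicalResult, dims: int = 2) -> pd.DataFrame:
    """First ``dims`` canonical score columns for 2D (or higher) dispersion."""
    if dims < 1:
        raise ValidityError("dims must be >= 1")
    if dims > result.n_axes:
        raise ValidityError(f"dims={dims} exceeds available axes {result.n_axes}")
    return result.scores.iloc[:, :dims].copy()


def projected_distances(result: CanonicalResult, dims: int):
    """Euclidean distance matrix between genotypes in the projected space."""
    from .datatypes import DistanceMatrix

    S = biplot_scores(result, dims).to_numpy()
    diff = S[:, None, :] - S[None, :, :]
    d = np.sqrt((diff ** 2).sum(axis=2))
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(tuple(str(i) for i in result.scores.index), d)
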