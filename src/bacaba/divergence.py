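"""Mahalanobis D² divergence between genotype means and its trait decomposition.

D² between genotypes i and i' is (xbar_i - xbar_i')' Psi^-1 (xbar_i - xbar_i')
with Psi the pooled residual covariance on the per-observation scale (error
SSCP divided by its degrees of freedom).  Singh's criterion decomposes the
total D² over all genotype pairs exactly into per-trait terms
S_j = sum_pairs delta_j * (Psi^-1 delta)_j, whose normalised form is each
trait's relative contribution to divergence.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg

from .datatypes import DesignError, DistanceMatrix, TraitTable, ValidityError

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PooledCovariance:
    traits: tuple[str, ...]
    psi: np.ndarray          # residual covariance, per-observation scale
    df_e: int
    singular: bool = False


def pooled_residual_covariance(
    table: TraitTable, traits: list[str] | None = None
) -> PooledCovariance:
    """Error SSCP / error df over the balanced one-way layout."""
    if not table.balanced:
        raise DesignError("pooled covariance requires a balanced table")
    traits = list(traits) if traits is not None else table.traits
    sub = table.subset(traits)
    X = sub.data[traits].to_numpy(dtype=float)
    geno = sub.data["genotype"].astype(str).to_numpy()
    sscp = np.zeros((len(traits), len(traits)))
    n_groups = 0
    df_e = 0
    for g in dict.fromkeys(geno):
        block = X[geno == g]
        centred = block - block.mean(axis=0)
        sscp += centred.T @ centred
        df_e += len(block) - 1
        n_groups += 1
    psi = sscp / df_e
    eigvals = np.linalg.eigvalsh(psi)
    singular = bool(eigvals.min() <= 1e-12 * max(eigvals.max(), 1.0))
    if singular:
        warnings.warn("pooled residual covariance is singular; D2 will use a pseudo-inverse")
    log.info("pooled covariance: %d traits, df_e=%d, singular=%s", len(traits), df_e, singular)
    return PooledCovariance(tuple(traits), psi, df_e, singular)


def _solver(psi: PooledCovariance):
    """Return a solve(b) -> Psi^-1 b callable; Cholesky when possible."""
    if not psi.singular:
        cho = linalg.cho_factor(psi.psi)
        return lambda b: linalg.cho_solve(cho, b)
    pinv = np.linalg.pinv(psi.psi, rcond=1e-12)
    return lambda b: pinv @ b


def mahalanobis_matrix(means: pd.DataFrame, psi: PooledCovariance) -> DistanceMatrix:
    """Pairwise squared generalized distances between genotype mean vectors."""
    traits = list(psi.traits)
    if list(means.columns) != traits:
        if set(means.columns) >= set(traits):
            means = means[traits]
        else:
            raise ValidityError("mean table traits do not match the covariance")
    X = means.to_numpy(dtype=float)
    labels = tuple(str(i) for i in means.index)
    n = X.shape[0]
    solve = _solver(psi)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            delta = X[i] - X[j]
            d2 = float(delta @ solve(delta))
            d[i, j] = d[j, i] = max(d2, 0.0)
    log.info("D2 matrix: %d genotypes, range %.3f-%.3f", n,
             d[np.triu_indices(n, 1)].min(initial=np.nan),
             d[np.triu_indices(n, 1)].max(initial=np.nan))
    return DistanceMatrix(labels, d)


@dataclass(frozen=True)
class DistanceSummary:
    min: float
    max: float
    mean: float
    argmin: tuple[str, str]
    argmax: tuple[str, str]
    pct_above_mean: float


def distance_summary(D: DistanceMatrix) -> DistanceSummary:
    """Statistics over the n(n-1)/2 unordered off-diagonal pairs.

    ``pct_above_mean`` counts pairs strictly greater than the mean; ties at
    the mean count as not above.
    """
    if D.n < 2:
        raise ValidityError("need at least 2 genotypes")
    vals = D.condensed()
    pairs = D.pairs()
    mean = float(vals.mean())
    return DistanceSummary(
        min=float(vals.min()),
        max=float(vals.max()),
        mean=mean,
        argmin=pairs[int(vals.argmin())],
        argmax=pairs[int(vals.argmax())],
        pct_above_mean=100.0 * float((vals > mean).sum()) / len(vals),
    )


@dataclass(frozen=True)
class SinghContribution:
    traits: tuple[str, ...]
    S: np.ndarray            # absolute per-trait contributions
    CR_pct: np.ndarray       # relative contributions, sum to 100

    def as_series(self) -> pd.Series:
        return pd.Series(self.CR_pct, index=list(self.traits), name="CR_pct")


def singh_contribution(means: pd.DataFrame, psi: PooledCovariance) -> SinghContribution:
    """Exact per-trait decomposition of the total pairwise D²."""
    traits = list(psi.traits)
    means = means[traits]
    X = means.to_numpy(dtype=float)
    n = X.shape[0]
    solve = _solver(psi)
    S = np.zeros(len(traits))
    for i in range(n):
        for j in range(i + 1, n):
            delta = X[i] - X[j]
            S += delta * solve(delta)
    total = S.sum()
    if total == 0:
        raise ValidityError("all genotype means identical: relative contribution undefined")
    CR = 100.0 * S / total
    tiny_neg = (CR < 0) & (CR > -1e-8)
    if tiny_neg.any():
        warnings.warn("clamping near-zero negative Singh contributions")
        CR = np.where(tiny_neg, 0.0, CR)
        CR = 100.0 * CR / CR.sum()
    return SinghContribution(tuple(traits), S, CR)
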