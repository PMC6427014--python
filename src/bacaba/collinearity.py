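"""Multicollinearity diagnostics of a trait correlation matrix.

Severity follows the usual condition-number bands for correlation matrices:
CN < 100 weak, 100-1000 moderate, > 1000 severe.  Condition indices are
ratios of singular values sigma_1/sigma_j = sqrt(lambda_1/lambda_j); VIFs
are the diagonal of the inverse correlation matrix.  Offending traits are
excluded iteratively by largest VIF until the matrix passes both gates.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import TraitTable, ValidityError

log = logging.getLogger(__name__)

EIG_ZERO = 1e-12  # eigenvalues below this are treated as exact zeros


def correlation_matrix(means: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlations among traits over genotype means.

    ``means`` is genotypes x traits (e.g. ``TraitTable.genotype_means()``).
    """
    if means.shape[0] < 3:
        raise ValidityError("need at least 3 genotypes for a correlation matrix")
    sd = means.std(ddof=1)
    dead = sd[sd == 0].index.tolist()
    if dead:
        raise ValidityError(f"zero-variance trait(s): {dead}")
    R = means.corr()
    return R


@dataclass(frozen=True)
class CollinearityDiagnostics:
    traits: tuple[str, ...]
    R: np.ndarray
    eigenvalues: np.ndarray          # descending
    eigenvectors: np.ndarray         # columns matched to eigenvalues
    singular_values: np.ndarray
    condition_number: float
    condition_indices: np.ndarray
    vif: np.ndarray
    severity: str
    offenders: tuple[str, ...]


def classify_cn(cn: float) -> str:
    if cn < 100:
        return "weak"
    if cn <= 1000:
        return "moderate"
    return "severe"


def diagnose(R: pd.DataFrame, n_small: int = 1) -> CollinearityDiagnostics:
    """Eigen-structure, condition number/indices and VIFs of a correlation matrix."""
    traits = tuple(str(c) for c in R.columns)
    A = np.asarray(R, dtype=float)
    p = A.shape[0]
    if A.shape != (p, p) or np.abs(A - A.T).max() > 1e-8:
        raise ValidityError("correlation matrix must be square and symmetric")
    if np.abs(np.diag(A) - 1.0).max() > 1e-8:
        raise ValidityError("correlation matrix must have a unit diagonal")

    lam, vec = np.linalg.eigh(A)
    order = np.argsort(lam)[::-1]
    lam, vec = lam[order], vec[:, order]
    lam_clipped = np.clip(lam, 0.0, None)
    sing = np.sqrt(lam_clipped)
    lam_min = lam[-1]
    if lam_min <= EIG_ZERO:
        warnings.warn("numerically singular correlation matrix; using pseudo-inverse")
        cn = np.inf if lam_min <= EIG_ZERO else lam[0] / lam_min
        keep = lam > EIG_ZERO
        Rinv = (vec[:, keep] / lam[keep]) @ vec[:, keep].T
        ci = np.where(sing > np.sqrt(EIG_ZERO), sing[0] / np.where(sing > 0, sing, 1.0), np.inf)
    else:
        cn = lam[0] / lam_min
        Rinv = np.linalg.inv(A)
        ci = sing[0] / sing
    vif = np.diag(Rinv).copy()
    offenders = identify_offenders_from(lam, vec, traits, n_small=n_small)
    diag = CollinearityDiagnostics(
        traits=traits, R=A, eigenvalues=lam, eigenvectors=vec,
        singular_values=sing, condition_number=float(cn),
        condition_indices=np.asarray(ci, dtype=float), vif=vif,
        severity=classify_cn(float(cn)), offenders=offenders,
    )
    log.info("collinearity: p=%d CN=%.2f severity=%s max VIF=%.2f",
             p, diag.condition_number, diag.severity, vif.max())
    return diag


def identify_offenders_from(
    lam: np.ndarray, vec: np.ndarray, traits: tuple[str, ...], n_small: int
) -> tuple[str, ...]:
    """Trait with the largest |loading| in each of the smallest eigenvectors.

    Ordered by eigenvalue ascending; duplicates collapsed.  Ties resolve to
    the first trait index, with a warning (degenerate spectra only).
    """
    p = len(traits)
    if n_small < 1 or n_small > p:
        raise ValidityError(f"n_small must be in [1, {p}]")
    out: list[str] = []
    for j in range(p - 1, p - 1 - n_small, -1):
        load = np.abs(vec[:, j])
        best = int(np.argmax(load))
        if (load == load[best]).sum() > 1:
            warnings.warn("tied eigenvector loadings; offender resolved to first trait")
        if traits[best] not in out:
            out.append(traits[best])
    return tuple(out)


def identify_offenders(diag: CollinearityDiagnostics, n_small: int) -> tuple[str, ...]:
    return identify_offenders_from(diag.eigenvalues, diag.eigenvectors, diag.traits, n_small)


@dataclass(frozen=True)
class ExclusionStep:
    excluded: str
    cn_before: float
    max_vif_before: float


@dataclass(frozen=True)
class ExclusionTrail:
    steps: tuple[ExclusionStep, ...]
    retained: tuple[str, ...]
    final: CollinearityDiagnostics
    passed: bool


def iterative_exclusion(
    means: pd.DataFrame, cn_limit: float = 100.0, vif_limit: float = 10.0
) -> ExclusionTrail:
    """Drop the worst-VIF trait until CN and VIF pass their gates.

    Ties on VIF resolve to the offender flagged by the smallest eigenvalue,
    then to the later column.  Fails (``passed=False``) if fewer than two
    traits would remain.
    """
    if means.shape[1] < 3:
        raise ValidityError("need at least 3 traits to screen")
    current = means.copy()
    steps: list[ExclusionStep] = []
    while True:
        diag = diagnose(correlation_matrix(current))
        max_vif = float(np.max(diag.vif))
        if diag.condition_number < cn_limit and max_vif <= vif_limit:
            return ExclusionTrail(tuple(steps), diag.traits, diag, passed=True)
        if current.shape[1] <= 2:
            warnings.warn("collinearity screen failed: only 2 traits remain")
            return ExclusionTrail(tuple(steps), diag.traits, diag, passed=False)
        vif = diag.vif
        worst = np.flatnonzero(vif == vif.max())
        if len(worst) > 1:
            offender = diag.offenders[0]
            tied = [i for i in worst if diag.traits[i] == offender]
            drop_idx = tied[0] if tied else int(worst[-1])
        else:
            drop_idx = int(worst[0])
        drop = diag.traits[drop_idx]
        steps.append(ExclusionStep(drop, diag.condition_number, max_vif))
        log.info("excluding %s (CN=%.1f, max VIF=%.1f)", drop, diag.condition_number, max_vif)
        current = current.drop(columns=[drop])


def screen_table(
    table: TraitTable, cn_limit: float = 100.0, vif_limit: float = 10.0
) -> ExclusionTrail:
    """Convenience: run the exclusion loop on a trait table's genotype means."""
    return iterative_exclusion(table.genotype_means(), cn_limit, vif_limit)
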