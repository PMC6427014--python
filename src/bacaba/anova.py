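"""Balanced one-way ANOVA per trait, genetic parameters, Scott-Knott groups.

For a completely randomized design with G genotypes and r replicates the
genotype mean square (GMS) estimates sigma2_e + r*sigma2_g and the residue
mean square (RMS) estimates sigma2_e, so

    sigma2_g = (GMS - RMS) / r
    h2mp     = 1 - RMS / GMS        (heritability of genotype means)
    CVg%     = 100 * sqrt(sigma2_g) / grand_mean
    CVe%     = 100 * sqrt(RMS)      / grand_mean

These estimators are only defined for balanced layouts; an unbalanced table
may be analysed with the harmonic mean of the replicate counts in place of
r, behind an explicit flag, at the caller's risk.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .datatypes import DesignError, TraitTable, ValidityError

log = logging.getLogger(__name__)

_PI = math.pi


@dataclass(frozen=True)
class AnovaResult:
    """One row of the genetic-parameter table (one trait)."""

    trait: str
    GMS: float
    RMS: float
    df_g: int
    df_e: int
    F: float
    p_value: float
    grand_mean: float
    CVe_pct: float
    CVg_pct: float
    cvg_over_cve: float
    h2mp: float
    sigma2_g: float
    sigma2_e: float


@dataclass(frozen=True)
class GeneticParameters:
    """Genetic parameters derived from mean squares alone."""

    sigma2_g: float
    sigma2_e: float
    h2mp: float
    CVe_pct: float
    CVg_pct: float
    cvg_over_cve: float


def genetic_parameters_from_mean_squares(
    GMS: float, RMS: float, grand_mean: float, r: float
) -> GeneticParameters:
    """Derive sigma2_g, h2mp, CVe%, CVg% and their ratio from GMS and RMS.

    Useful for recomputing published genetic-parameter tables from their
    printed mean squares.  Negative (GMS - RMS) is clamped to zero.
    """
    if GMS < 0 or RMS < 0 or r < 1:
        raise ValidityError("GMS, RMS must be >= 0 and r >= 1")
    if grand_mean == 0:
        raise ValidityError("zero grand mean: CV undefined")
    sigma2_g = (GMS - RMS) / r
    if sigma2_g < 0:
        warnings.warn("GMS < RMS: genetic variance clamped to zero")
        sigma2_g = 0.0
    h2mp = min(max(1.0 - RMS / GMS, 0.0), 1.0) if GMS > 0 else 0.0
    CVe = 100.0 * math.sqrt(RMS) / abs(grand_mean)
    CVg = 100.0 * math.sqrt(sigma2_g) / abs(grand_mean)
    ratio = CVg / CVe if CVe > 0 else math.inf
    return GeneticParameters(sigma2_g, RMS, h2mp, CVe, CVg, ratio)


def _effective_r(table: TraitTable, allow_unbalanced: bool) -> float:
    counts = table.data.groupby("genotype", sort=False).size()
    if counts.min() < 2:
        raise DesignError("every genotype needs at least 2 replicates")
    if counts.nunique() == 1:
        return float(counts.iloc[0])
    if not allow_unbalanced:
        raise DesignError(
            "unbalanced design: the mean-square estimators assume a common "
            "replicate count (pass allow_unbalanced=True to use the harmonic mean)"
        )
    return float(stats.hmean(counts.to_numpy()))


def one_way_anova(
    table: TraitTable, trait: str, allow_unbalanced: bool = False
) -> AnovaResult:
    """Genotype ANOVA and genetic parameters for a single trait."""
    if trait not in table.traits:
        raise ValidityError(f"unknown trait {trait!r}")
    df = table.data
    groups = [g.to_numpy(dtype=float) for _, g in df.groupby("genotype", sort=False)[trait]]
    G = len(groups)
    if G < 2:
        raise DesignError("need at least 2 genotypes")
    r = _effective_r(table, allow_unbalanced)
    y = np.concatenate(groups)
    if np.ptp(y) == 0:
        raise DesignError(f"trait {trait!r} is constant across all observations")
    grand = float(y.mean())
    if grand == 0:
        raise DesignError(f"trait {trait!r} has zero grand mean; CV undefined")

    group_means = np.array([g.mean() for g in groups])
    ss_g = float(sum(len(g) * (m - grand) ** 2 for g, m in zip(groups, group_means)))
    ss_e = float(sum(((g - m) ** 2).sum() for g, m in zip(groups, group_means)))
    df_g = G - 1
    df_e = len(y) - G
    GMS = ss_g / df_g
    RMS = ss_e / df_e

    if RMS == 0:
        warnings.warn(f"trait {trait!r}: zero residue mean square; F set to +inf")
        F, p = math.inf, 0.0
    else:
        F = GMS / RMS
        p = float(stats.f.sf(F, df_g, df_e))

    gp = genetic_parameters_from_mean_squares(GMS, RMS, grand, r)
    return AnovaResult(
        trait=trait, GMS=GMS, RMS=RMS, df_g=df_g, df_e=df_e, F=F, p_value=p,
        grand_mean=grand, CVe_pct=gp.CVe_pct, CVg_pct=gp.CVg_pct,
        cvg_over_cve=gp.cvg_over_cve, h2mp=gp.h2mp,
        sigma2_g=gp.sigma2_g, sigma2_e=gp.sigma2_e,
    )


def genetic_parameter_table(
    table: TraitTable, allow_unbalanced: bool = False
) -> list[AnovaResult]:
    """One :class:`AnovaResult` per trait, in input column order."""
    results = [one_way_anova(table, t, allow_unbalanced) for t in table.traits]
    log.info(
        "genetic parameters: %d traits, h2mp range %.3f-%.3f",
        len(results), min(x.h2mp for x in results), max(x.h2mp for x in results),
    )
    return results


@dataclass(frozen=True)
class ScottKnottGrouping:
    """Partition of ordered genotype means into homogeneous groups."""

    genotypes: tuple[str, ...]       # sorted by descending mean
    means: tuple[float, ...]
    groups: tuple[str, ...]          # letter per genotype, 'a' = highest means
    alpha: float

    def as_dict(self) -> dict[str, str]:
        return dict(zip(self.genotypes, self.groups))


def _best_split(means: np.ndarray) -> tuple[float, int]:
    """Maximal between-groups sum of squares over contiguous 2-partitions."""
    k = len(means)
    total = means.sum()
    best_b0, best_cut = -math.inf, 1
    for cut in range(1, k):
        t1 = means[:cut].sum()
        t2 = total - t1
        b0 = t1 ** 2 / cut + t2 ** 2 / (k - cut) - total ** 2 / k
        if b0 > best_b0:
            best_b0, best_cut = b0, cut
    return best_b0, best_cut


def _sk_lambda(means: np.ndarray, b0: float, s2y: float, df_e: int) -> float:
    k = len(means)
    sigma0 = (((means - means.mean()) ** 2).sum() + df_e * s2y) / (k + df_e)
    if sigma0 <= 0:
        return math.inf if b0 > 0 else 0.0
    return (_PI / (2.0 * (_PI - 2.0))) * b0 / sigma0


def scott_knott(
    means: dict[str, float] | "np.ndarray | list[float]",
    RMS: float,
    df_e: int,
    r: int,
    alpha: float = 0.05,
) -> ScottKnottGrouping:
    """Likelihood-based recursive binary partitioning of treatment means.

    At each node holding k sorted means the contiguous 2-partition maximising
    the between-groups sum of squares B0 is tested with the statistic
    lambda = pi/(2(pi-2)) * B0 / sigma0^2, referred to a chi-square critical
    value with the fractional degrees of freedom k/(pi-2); the node splits
    when lambda exceeds it.  ``RMS / r`` is the variance of a treatment mean.
    """
    if isinstance(means, dict):
        labels = [str(k) for k in means]
        vals = np.array([float(v) for v in means.values()])
    else:
        vals = np.asarray(means, dtype=float)
        labels = [str(i) for i in range(len(vals))]
    if len(vals) == 0:
        raise ValidityError("no means supplied")
    if not np.isfinite(vals).all():
        raise ValidityError("non-finite mean")
    if RMS < 0 or r < 1 or not 0 < alpha < 1:
        raise ValidityError("invalid RMS, r or alpha")

    order = np.argsort(-vals, kind="stable")
    sorted_vals = vals[order]
    sorted_labels = [labels[i] for i in order]
    s2y = RMS / r

    group_of = np.zeros(len(vals), dtype=int)
    next_group = [0]

    def recurse(lo: int, hi: int) -> None:
        k = hi - lo
        if k < 2:
            group_of[lo:hi] = next_group[0]
            next_group[0] += 1
            return
        seg = sorted_vals[lo:hi]
        b0, cut = _best_split(seg)
        lam = _sk_lambda(seg, b0, s2y, df_e)
        crit = stats.chi2.ppf(1.0 - alpha, k / (_PI - 2.0))
        if lam > crit:
            recurse(lo, lo + cut)
            recurse(lo + cut, hi)
        else:
            group_of[lo:hi] = next_group[0]
            next_group[0] += 1

    recurse(0, len(vals))

    letters = []
    for g in group_of:
        q, rem = divmod(int(g), 26)
        letters.append(chr(ord("a") + rem) * (q + 1))
    return ScottKnottGrouping(
        genotypes=tuple(sorted_labels),
        means=tuple(float(v) for v in sorted_vals),
        groups=tuple(letters),
        alpha=alpha,
    )
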