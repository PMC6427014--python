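"""Synthetic phenotype trials with known genetic ground truth.

The generator emulates the structure the divergence analysis assumes: a
balanced completely randomized design in which genotype i, fruit k, trait t
is

    y_ikt = mu_t + c_it + g_it + e_ikt,

with genotype effects g_i ~ MVN(0, G), residuals e_ik ~ MVN(0, E) and c_i an
optional planted cluster centroid shift.  Normality is the ANOVA-consistent
choice; the truth record carries the exact effect vectors, the implied
progeny-mean heritabilities h2mp_t = G_tt / (G_tt + E_tt/r), genetic
coefficients of variation, and the planted cluster assignment.

Defaults reproduce the bacaba fruit study's design: 15 genotypes, 14 fruits
each, 8 traits with grand means, CVg and h2mp matching the published
genetic-parameter table.  No genetic correlation matrix was published, so
traits are uncorrelated by default; ``derive_py=True`` instead computes pulp
yield per fruit as PY = 100*PM/FM, reproducing the collinearity pathology of
ratio traits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datasets import reference_genetic_parameters, TRAITS
from .datatypes import TraitTable, ValidityError

log = logging.getLogger(__name__)


def _check_psd(M: np.ndarray, name: str) -> None:
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValidityError(f"{name} must be square")
    if np.abs(M - M.T).max(initial=0.0) > 1e-10:
        raise ValidityError(f"{name} must be symmetric")
    lam = np.linalg.eigvalsh(M)
    if lam.min() < -1e-8 * max(lam.max(), 1.0):
        raise ValidityError(f"{name} is not positive semidefinite")


def _factor(M: np.ndarray) -> np.ndarray:
    """Symmetric square root (works for singular covariances)."""
    lam, V = np.linalg.eigh(np.asarray(M, dtype=float))
    lam = np.clip(lam, 0.0, None)
    return V * np.sqrt(lam)


@dataclass(frozen=True)
class SimulationConfig:
    n_genotypes: int
    n_replicates: int
    trait_names: tuple[str, ...]
    mu: np.ndarray
    G: np.ndarray                       # genetic covariance (per-genotype effect)
    E: np.ndarray                       # residual covariance (within genotype)
    clusters: tuple[tuple[np.ndarray, int], ...] | None = None
    derive_py: bool = False             # PY = 100*PM/FM per fruit
    seed: int = 0

    def __post_init__(self) -> None:
        p = len(self.trait_names)
        object.__setattr__(self, "mu", np.asarray(self.mu, dtype=float))
        object.__setattr__(self, "G", np.asarray(self.G, dtype=float))
        object.__setattr__(self, "E", np.asarray(self.E, dtype=float))
        if self.mu.shape != (p,):
            raise ValidityError("mu dimension must match trait count")
        _check_psd(self.G, "G")
        _check_psd(self.E, "E")
        if self.G.shape != (p, p) or self.E.shape != (p, p):
            raise ValidityError("G and E dimension must match trait count")
        if self.n_genotypes < 2 or self.n_replicates < 2:
            raise ValidityError("need at least 2 genotypes and 2 replicates")
        if self.clusters is not None:
            shifts = tuple(
                (np.asarray(s, dtype=float), int(c)) for s, c in self.clusters
            )
            if sum(c for _, c in shifts) != self.n_genotypes:
                raise ValidityError("cluster member counts must sum to n_genotypes")
            for s, _ in shifts:
                if s.shape != (p,):
                    raise ValidityError("cluster shift dimension must match traits")
            object.__setattr__(self, "clusters", shifts)
        if self.derive_py and not {"FM", "PM", "PY"} <= set(self.trait_names):
            raise ValidityError("derive_py requires FM, PM and PY traits")

    @property
    def true_h2mp(self) -> np.ndarray:
        g = np.diag(self.G)
        e = np.diag(self.E)
        return g / (g + e / self.n_replicates)

    @property
    def true_cvg_pct(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            out = 100.0 * np.sqrt(np.diag(self.G)) / np.abs(self.mu)
        return np.where(self.mu != 0, out, np.nan)


@dataclass(frozen=True)
class PlantedTruth:
    genotype_effects: pd.DataFrame      # genotypes x traits (c_i + g_i)
    true_h2mp: pd.Series
    true_cvg_pct: pd.Series
    cluster_assignment: dict[str, int] | None


def simulate_population(config: SimulationConfig) -> tuple[TraitTable, PlantedTruth]:
    """Draw one balanced trial; identical seed gives identical output."""
    rng = np.random.default_rng(config.seed)
    p = len(config.trait_names)
    nG, r = config.n_genotypes, config.n_replicates
    Lg, Le = _factor(config.G), _factor(config.E)

    g = rng.standard_normal((nG, p)) @ Lg.T
    shifts = np.zeros((nG, p))
    assignment: dict[str, int] | None = None
    if config.clusters is not None:
        assignment = {}
        i = 0
        for m, (shift, count) in enumerate(config.clusters):
            shifts[i : i + count] = shift
            for j in range(i, i + count):
                assignment[str(j + 1)] = m
            i += count
    effects = shifts + g

    e = rng.standard_normal((nG, r, p)) @ Le.T
    y = config.mu + effects[:, None, :] + e

    labels = [str(i + 1) for i in range(nG)]
    rows = {
        "genotype": np.repeat(labels, r),
        "replicate": np.tile([str(k + 1) for k in range(r)], nG),
    }
    flat = y.reshape(nG * r, p)
    for t, name in enumerate(config.trait_names):
        rows[name] = flat[:, t]
    df = pd.DataFrame(rows)

    h2 = pd.Series(config.true_h2mp, index=list(config.trait_names))
    cvg = pd.Series(config.true_cvg_pct, index=list(config.trait_names))
    if config.derive_py:
        df["PY"] = 100.0 * df["PM"] / df["FM"]
        h2["PY"] = np.nan   # ratio trait: no closed-form variance components
        cvg["PY"] = np.nan
    truth = PlantedTruth(
        genotype_effects=pd.DataFrame(
            effects, index=labels, columns=list(config.trait_names)
        ),
        true_h2mp=h2,
        true_cvg_pct=cvg,
        cluster_assignment=assignment,
    )
    log.info("simulated %d genotypes x %d replicates x %d traits (seed=%d)",
             nG, r, p, config.seed)
    return TraitTable(df), truth


def simulate_from_target_parameters(
    n_genotypes: int,
    n_replicates: int,
    means: np.ndarray,
    cvg_pct: np.ndarray,
    h2mp: np.ndarray,
    genetic_correlation: np.ndarray | None = None,
    trait_names: tuple[str, ...] | None = None,
    seed: int = 0,
    **kwargs,
) -> SimulationConfig:
    """Invert the genetic-parameter definitions into a simulation config.

    G_tt = (cvg_pct_t * means_t / 100)^2 and
    E_tt = r * G_tt * (1 - h2mp_t) / h2mp_t, so the estimators recover the
    targets in expectation; off-diagonals of G and E follow the supplied
    genetic correlation (identity when omitted).
    """
    means = np.asarray(means, dtype=float)
    cvg_pct = np.asarray(cvg_pct, dtype=float)
    h2mp = np.asarray(h2mp, dtype=float)
    p = len(means)
    if not (cvg_pct.shape == h2mp.shape == (p,)):
        raise ValidityError("means, cvg_pct and h2mp must have equal length")
    if np.any(cvg_pct <= 0) or np.any((h2mp <= 0) | (h2mp >= 1)):
        raise ValidityError("need cvg_pct > 0 and 0 < h2mp < 1")
    C = np.eye(p) if genetic_correlation is None else np.asarray(genetic_correlation, float)
    if C.shape != (p, p):
        raise ValidityError("genetic_correlation dimension mismatch")
    _check_psd(C, "genetic_correlation")

    sg = cvg_pct * means / 100.0
    se = np.sqrt(n_replicates * sg ** 2 * (1.0 - h2mp) / h2mp)
    G = C * np.outer(sg, sg)
    E = C * np.outer(se, se)
    names = trait_names or tuple(f"T{i + 1}" for i in range(p))
    return SimulationConfig(
        n_genotypes=n_genotypes, n_replicates=n_replicates, trait_names=tuple(names),
        mu=means, G=G, E=E, seed=seed, **kwargs,
    )


def study_design_config(
    seed: int = 0,
    clusters: tuple[tuple[np.ndarray, int], ...] | None = None,
    derive_py: bool = False,
) -> SimulationConfig:
    """The published study's design: 15 genotypes x 14 fruits x 8 traits.

    Grand means, CVg and h2mp targets come from the bundled reference
    genetic-parameter table; traits are genetically uncorrelated (no
    correlation matrix was published).
    """
    ref = reference_genetic_parameters().loc[list(TRAITS)]
    return simulate_from_target_parameters(
        n_genotypes=15,
        n_replicates=14,
        means=ref["mean"].to_numpy(),
        cvg_pct=ref["CVg_pct"].to_numpy(),
        h2mp=ref["h2mp_pct"].to_numpy() / 100.0,
        trait_names=TRAITS,
        seed=seed,
        clusters=clusters,
        derive_py=derive_py,
    )


def planted_cluster_shifts(
    config: SimulationConfig,
    sizes: tuple[int, ...] = (5, 5, 5),
    separation: float = 6.0,
) -> tuple[tuple[np.ndarray, int], ...]:
    """Centroid shifts for well-separated, equidistant planted clusters.

    Centroids sit at the vertices of a regular simplex in the per-trait
    scale of a genotype mean's standard deviation, sqrt(diag(G + E/r)), so
    every pair of centroids is the same distance apart — ``separation``
    standard deviations per trait in root-mean-square, hence a Euclidean
    separation of at least ``separation * sqrt(max diag(G + E/r))``.  The
    shift is additive, leaving G, E and the heritability targets untouched.
    Up to three clusters are supported.
    """
    if not 1 <= len(sizes) <= 3:
        raise ValidityError("planted_cluster_shifts supports 1-3 clusters")
    p = len(config.trait_names)
    sd_mean = np.sqrt(np.diag(config.G) + np.diag(config.E) / config.n_replicates)
    e1 = np.ones(p) / np.sqrt(p)
    e2 = np.array([1.0] * (p // 2) + [-1.0] * (p - p // 2))
    e2 -= (e2 @ e1) * e1
    e2 /= np.linalg.norm(e2)
    side = separation * np.sqrt(p)
    verts = [
        np.zeros(2),
        np.array([side, 0.0]),
        np.array([side / 2.0, side * np.sqrt(3.0) / 2.0]),
    ][: len(sizes)]
    centre = np.mean(verts, axis=0)
    return tuple(
        ((v - centre)[0] * e1 * sd_mean + (v - centre)[1] * e2 * sd_mean, size)
        for v, size in zip(verts, sizes)
    )


def with_clusters(config: SimulationConfig, **kwargs) -> SimulationConfig:
    """Copy of ``config`` with planted clusters added."""
    from dataclasses import replace

    return replace(config, clusters=planted_cluster_shifts(config, **kwargs))
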