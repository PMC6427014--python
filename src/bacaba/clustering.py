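"""Grouping of genotypes from a dissimilarity matrix.

Two complementary methods, as is customary in divergence studies:

* **Tocher optimization** — one-pass grouping that seeds a group with the
  closest remaining pair and admits further genotypes while their average
  distance to the group stays at or below theta, the largest
  nearest-neighbour distance of the full matrix.
* **UPGMA** (average linkage) with the **Mojena cut** at
  mean + k*sd of the fusion levels, plus the cophenetic correlation and
  distortion/stress diagnostics of how faithfully a represented set of
  distances reproduces the original ones.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.cluster import hierarchy
from scipy.stats import pearsonr

from .datatypes import DistanceMatrix, ValidityError

log = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# Tocher optimization

@dataclass(frozen=True)
class TocherGrouping:
    groups: tuple[tuple[str, ...], ...]   # members in admission order
    theta: float

    def partition(self) -> list[set[str]]:
        return [set(g) for g in self.groups]

    def assignment(self) -> dict[str, int]:
        return {m: k for k, g in enumerate(self.groups) for m in g}


def tocher(D: DistanceMatrix) -> TocherGrouping:
    """Tocher optimization grouping.

    theta is fixed once from the full matrix as the maximum over genotypes
    of the distance to their nearest neighbour.  Candidates are admitted in
    order of ascending average distance to the current group (ties by label
    order); a group closes when the best candidate's average exceeds theta.
    A final leftover genotype forms a singleton group.
    """
    if D.n < 2:
        raise ValidityError("need at least 2 genotypes")
    d = D.d
    n = D.n
    off = d + np.diag(np.full(n, np.inf))
    theta = float(off.min(axis=1).max())

    remaining = list(range(n))
    groups: list[tuple[str, ...]] = []
    while remaining:
        if len(remaining) == 1:
            groups.append((D.labels[remaining[0]],))
            break
        # seed with the closest remaining pair
        sub = off[np.ix_(remaining, remaining)]
        i_s, j_s = np.unravel_index(np.argmin(sub), sub.shape)
        a, b = remaining[i_s], remaining[j_s]
        group = [a, b]
        remaining = [x for x in remaining if x not in (a, b)]
        while remaining:
            avgs = np.array([d[np.ix_([x], group)].mean() for x in remaining])
            best = int(np.argmin(avgs))          # ties: earliest remaining label
            if avgs[best] <= theta:
                group.append(remaining.pop(best))
            else:
                break
        groups.append(tuple(D.labels[i] for i in group))
    log.info("tocher: theta=%.3f, %d groups of sizes %s",
             theta, len(groups), [len(g) for g in groups])
    return TocherGrouping(tuple(groups), theta)


# --------------------------------------------------------------------------
# UPGMA

@dataclass(frozen=True)
class Dendrogram:
    """UPGMA merge history.

    ``merges`` holds (node_a, node_b, fusion_level, new_node); leaves are
    numbered 0..n-1 in label order and internal nodes n..2n-2, the scipy
    linkage convention.
    """

    labels: tuple[str, ...]
    merges: tuple[tuple[int, int, float, int], ...]

    @property
    def linkage(self) -> np.ndarray:
        Z = np.zeros((len(self.merges), 4))
        sizes = {i: 1 for i in range(len(self.labels))}
        for k, (a, b, h, new) in enumerate(self.merges):
            sizes[new] = sizes[a] + sizes[b]
            Z[k] = (a, b, h, sizes[new])
        return Z

    @property
    def fusion_levels(self) -> np.ndarray:
        return np.array([m[2] for m in self.merges])


def upgma(D: DistanceMatrix) -> Dendrogram:
    """Average-linkage agglomeration directly on the supplied dissimilarities."""
    if D.n < 2:
        raise ValidityError("need at least 2 genotypes")
    Z = hierarchy.linkage(D.condensed(), method="average")
    n = D.n
    merges = tuple(
        (int(Z[k, 0]), int(Z[k, 1]), float(Z[k, 2]), n + k) for k in range(n - 1)
    )
    levels = [m[2] for m in merges]
    if any(b < a - 1e-12 for a, b in zip(levels, levels[1:])):
        warnings.warn("non-monotone fusion levels (pathological input)")
    return Dendrogram(D.labels, merges)


def cophenetic_matrix(tree: Dendrogram) -> DistanceMatrix:
    """Pairwise fusion level of the lowest common merge, as a matrix."""
    coph = hierarchy.cophenet(tree.linkage)
    n = len(tree.labels)
    d = np.zeros((n, n))
    d[np.triu_indices(n, 1)] = coph
    return DistanceMatrix(tree.labels, d + d.T)


def cophenetic_correlation(D: DistanceMatrix, tree: Dendrogram) -> float:
    """Pearson correlation of cophenetic vs original distances over all pairs."""
    if tuple(tree.labels) != tuple(D.labels):
        raise ValidityError("tree and matrix labels differ")
    orig = D.condensed()
    coph = cophenetic_matrix(tree).condensed()
    if np.ptp(orig) == 0 or np.ptp(coph) == 0:
        raise ValidityError("zero variance: cophenetic correlation undefined")
    return float(pearsonr(coph, orig)[0])


def mojena_cut(tree: Dendrogram, k: float = 1.25, sd_ddof: int = 1) -> dict[str, int]:
    """Flat partition from cutting the dendrogram at mean + k*sd of fusion levels.

    Clusters are the connected components below the first fusion exceeding
    the threshold.  ``sd_ddof=1`` is the sample standard deviation; the n-2
    denominator variant is available via ``sd_ddof=2``.
    """
    if k < 0:
        raise ValidityError("k must be non-negative")
    levels = tree.fusion_levels
    threshold = float(levels.mean() + k * levels.std(ddof=sd_ddof))
    flat = hierarchy.fcluster(tree.linkage, t=threshold, criterion="distance")
    # renumber clusters in order of first appearance for stable output
    remap: dict[int, int] = {}
    out: dict[str, int] = {}
    for label, c in zip(tree.labels, flat):
        remap.setdefault(int(c), len(remap))
        out[label] = remap[int(c)]
    log.info("mojena cut: k=%.2f threshold=%.3f -> %d clusters",
             k, threshold, len(remap))
    return out


# --------------------------------------------------------------------------
# Representation fidelity

@dataclass(frozen=True)
class ProjectionFit:
    cophenetic_correlation: float
    distortion_pct: float          # floored at 0
    distortion_signed_pct: float
    stress_pct: float


def projection_fit(D_original: DistanceMatrix, D_represented: DistanceMatrix) -> ProjectionFit:
    """Distortion and stress of a represented distance set vs the original.

    stress% = 100*sqrt(sum (d-dhat)^2 / sum d^2) (Kruskal stress-1 form);
    distortion% = 100*(1 - sum dhat^2 / sum d^2), reported both signed and
    floored at zero.
    """
    if tuple(D_original.labels) != tuple(D_represented.labels):
        raise ValidityError("label sets differ")
    d = D_original.condensed()
    dhat = D_represented.condensed()
    ssq = float((d ** 2).sum())
    if ssq == 0:
        raise ValidityError("all original distances zero")
    stress = 100.0 * float(np.sqrt(((d - dhat) ** 2).sum() / ssq))
    signed = 100.0 * (1.0 - float((dhat ** 2).sum()) / ssq)
    if np.ptp(d) == 0 or np.ptp(dhat) == 0:
        corr = float("nan")
    else:
        corr = float(pearsonr(dhat, d)[0])
    return ProjectionFit(
        cophenetic_correlation=corr,
        distortion_pct=max(signed, 0.0),
        distortion_signed_pct=signed,
        stress_pct=stress,
    )


# --------------------------------------------------------------------------
# Newick export

def to_newick(tree: Dendrogram) -> str:
    """Ultrametric Newick string: leaf depth equals half the root fusion level."""
    n = len(tree.labels)
    height = {i: 0.0 for i in range(n)}
    text = {i: tree.labels[i] for i in range(n)}
    for a, b, h, new in tree.merges:
        half = h / 2.0
        la = half - height[a]
        lb = half - height[b]
        text[new] = f"({text[a]}:{la:.10g},{text[b]}:{lb:.10g})"
        height[new] = half
    root = tree.merges[-1][3] if tree.merges else 0
    return text[root] + ";"
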