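"""Core data containers shared by every analysis stage.

The pipeline operates on a replicated phenotype trial — a balanced one-way
layout in which each genotype is measured on ``r`` fruits for a common set
of biometric traits — and on labeled symmetric dissimilarity matrices
(Mahalanobis D², cophenetic distances, projected distances).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

ID_COLUMNS = ("genotype", "replicate")


class BacabaError(Exception):
    """Base class for all pipeline errors."""


class FormatError(BacabaError):
    """A file does not have the expected layout (missing columns, empty)."""


class ParseError(BacabaError):
    """A cell could not be converted to a number."""


class IntegrityError(BacabaError):
    """Data violate a structural invariant (duplicates, asymmetry...)."""


class DesignError(BacabaError):
    """The experimental design does not support the requested estimator."""


class ValidityError(BacabaError):
    """An argument is outside the domain of an operation."""


@dataclass(frozen=True)
class TraitTable:
    """Replicated phenotype measurements keyed by genotype and replicate.

    ``data`` is a wide frame with columns ``genotype``, ``replicate`` and one
    numeric column per trait.  Genotype and replicate labels are opaque
    strings and are never reindexed: group identities in downstream tables
    depend on them.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in ID_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"trait table lacks id columns {missing}")
        if not self.traits:
            raise FormatError("trait table has no trait columns")
        dup = df.duplicated(subset=list(ID_COLUMNS))
        if dup.any():
            pairs = df.loc[dup, list(ID_COLUMNS)].to_records(index=False)
            raise IntegrityError(f"duplicate (genotype, replicate) pairs: {list(pairs)[:5]}")
        vals = df[self.traits].to_numpy()
        if not np.issubdtype(vals.dtype, np.number):
            raise ParseError("non-numeric trait values present")
        if not np.isfinite(vals).all():
            bad = np.argwhere(~np.isfinite(vals))[0]
            raise IntegrityError(
                f"non-finite value for trait {self.traits[bad[1]]!r} at row {bad[0]}"
            )

    @property
    def traits(self) -> list[str]:
        return [c for c in self.data.columns if c not in ID_COLUMNS]

    @property
    def genotypes(self) -> list[str]:
        seen: dict[str, None] = {}
        for g in self.data["genotype"].astype(str):
            seen.setdefault(g, None)
        return list(seen)

    @property
    def balanced(self) -> bool:
        counts = self.data.groupby("genotype", sort=False).size()
        return bool(counts.nunique() == 1 and counts.iloc[0] >= 2)

    @property
    def n_replicates(self) -> int:
        """Common replicate count r; defined only for balanced tables."""
        counts = self.data.groupby("genotype", sort=False).size()
        if counts.nunique() != 1:
            raise DesignError("replicate count is not constant across genotypes")
        return int(counts.iloc[0])

    def genotype_means(self, traits: Sequence[str] | None = None) -> pd.DataFrame:
        """Per-genotype trait means, genotypes in order of first appearance."""
        traits = list(traits) if traits is not None else self.traits
        unknown = [t for t in traits if t not in self.traits]
        if unknown:
            raise ValidityError(f"unknown traits {unknown}")
        df = self.data.copy()
        df["genotype"] = df["genotype"].astype(str)
        means = df.groupby("genotype", sort=False)[traits].mean()
        means.index.name = "genotype"
        return means

    def subset(self, traits: Sequence[str]) -> "TraitTable":
        unknown = [t for t in traits if t not in self.traits]
        if unknown:
            raise ValidityError(f"unknown traits {unknown}")
        return TraitTable(self.data[list(ID_COLUMNS) + list(traits)].copy())


@dataclass(frozen=True)
class DistanceMatrix:
    """Labeled symmetric dissimilarity matrix with zero diagonal."""

    labels: tuple[str, ...]
    d: np.ndarray

    ATOL = 1e-9

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=float)
        object.__setattr__(self, "d", d)
        object.__setattr__(self, "labels", tuple(str(x) for x in self.labels))
        n = len(self.labels)
        if d.shape != (n, n):
            raise IntegrityError(f"matrix shape {d.shape} does not match {n} labels")
        if not np.isfinite(d).all():
            raise IntegrityError("non-finite distance entries")
        if np.abs(d - d.T).max(initial=0.0) > self.ATOL:
            raise IntegrityError("distance matrix is asymmetric beyond tolerance")
        if np.abs(np.diag(d)).max(initial=0.0) > self.ATOL:
            raise IntegrityError("distance matrix has a nonzero diagonal")
        if d.min(initial=0.0) < -self.ATOL:
            raise IntegrityError("negative distance entries")

    @property
    def n(self) -> int:
        return len(self.labels)

    def condensed(self) -> np.ndarray:
        """Upper-triangle entries in scipy's condensed pair order."""
        iu = np.triu_indices(self.n, 1)
        return self.d[iu]

    def pairs(self) -> list[tuple[str, str]]:
        iu = np.triu_indices(self.n, 1)
        return [(self.labels[i], self.labels[j]) for i, j in zip(*iu)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=list(self.labels), columns=list(self.labels))

    def permuted(self, order: Sequence[str]) -> "DistanceMatrix":
        idx = [self.labels.index(str(x)) for x in order]
        if sorted(idx) != list(range(self.n)):
            raise ValidityError("order must be a permutation of the labels")
        return DistanceMatrix(tuple(self.labels[i] for i in idx), self.d[np.ix_(idx, idx)])


@dataclass
class PipelineConfig:
    """Tunable thresholds of the full divergence pipeline.

    Defaults follow common practice for this analysis family: 5% test level
    for means grouping, condition-number limit 100 and VIF limit 10 for the
    multicollinearity gate, Mojena constant 1.25, network hard limit 0 with
    display cut-offs 0.3 and 0.7.
    """

    traits: list[str] | None = None
    alpha: float = 0.05
    cn_limit: float = 100.0
    vif_limit: float = 10.0
    mojena_k: float = 1.25
    network_rho: float = 0.0
    display_cutoffs: tuple[float, ...] = (0.3, 0.7)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValidityError("alpha must lie in (0, 1)")
        if self.cn_limit <= 1:
            raise ValidityError("cn_limit must exceed 1")
        if self.vif_limit <= 1:
            raise ValidityError("vif_limit must exceed 1")
        if self.mojena_k < 0:
            raise ValidityError("mojena_k must be non-negative")
        if self.network_rho < 0:
            raise ValidityError("network_rho must be non-negative")
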