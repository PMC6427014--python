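"""Published reference values bundled as small text fixtures.

The raw fruit measurements behind the bacaba-de-leque (*Oenocarpus
distichus*) divergence study were never deposited; what the study prints —
the 15×15 Mahalanobis D² matrix, the per-trait genetic-parameter table, and
the eigenvalue spectra of the trait correlation matrix before and after the
multicollinearity screen — is transcribed here.  These fixtures are the
desk-checkable anchors of the test suite and the reproduction scripts.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .datatypes import DistanceMatrix
from .io import read_distance_matrix

TRAITS = ("FL", "WF", "FM", "PM", "SM", "PT", "AT", "PY")
RETAINED_TRAITS = ("FL", "WF", "SM", "PT", "AT", "PY")

#: grouping reported for the Tocher method on the published D² matrix
REFERENCE_TOCHER_GROUPS = (
    ("3", "15", "7", "1", "6", "5", "10", "12", "11", "9", "13", "4"),
    ("2", "14"),
    ("8",),
)


def _data_path(name: str):
    return resources.files("bacaba.data") / name


def reference_d2() -> DistanceMatrix:
    """Published Mahalanobis D² matrix among the 15 palm genotypes."""
    with resources.as_file(_data_path("reference_d2.csv")) as p:
        return read_distance_matrix(p, shape="square")


def reference_genetic_parameters() -> pd.DataFrame:
    """Published per-trait ANOVA mean squares and genetic parameters.

    Columns: trait, unit, GMS, RMS, mean, CVe_pct, CVg_pct, cvg_over_cve,
    h2mp_pct — all at the 2-decimal precision of the printed table.
    """
    with resources.as_file(_data_path("reference_genetic_parameters.csv")) as p:
        return pd.read_csv(p, index_col="trait")


def reference_eigenvalues(trait_set: str = "six_traits") -> list[float]:
    """Published eigenvalue spectrum of the trait correlation matrix.

    ``trait_set`` is ``"eight_traits"`` (all biometric traits, severe
    collinearity) or ``"six_traits"`` (after excluding fruit and pulp mass).
    """
    with resources.as_file(_data_path("reference_eigenvalues.csv")) as p:
        df = pd.read_csv(p, index_col="trait_set")
    if trait_set not in df.index:
        raise KeyError(f"unknown trait_set {trait_set!r}")
    return [float(x) for x in df.loc[trait_set, "eigenvalues"].split(",")]
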