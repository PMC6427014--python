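"""Multicollinearity screen of the trait correlation matrix.

Diagnoses the genotype-mean correlation matrix of the synthetic population
(eigenvalues, condition number, condition indices, VIFs), identifies the
traits driving near-singularity, and excludes them iteratively until the
condition number falls below 100 and every VIF is at most 10.  With PY
derived from PM/FM the screen removes members of that ratio family.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from bacaba import collinearity, io as bio

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    table = bio.read_trait_table(OUT / "synthetic_population.csv")
    means = table.genotype_means()

    diag = collinearity.diagnose(collinearity.correlation_matrix(means), n_small=2)
    print(f"full trait set: CN = {diag.condition_number:.1f} ({diag.severity}), "
          f"max VIF = {diag.vif.max():.1f}")
    print("eigenvalues:", np.round(diag.eigenvalues, 3))
    print("offenders (two smallest eigenvectors):", ", ".join(diag.offenders))

    trail = collinearity.iterative_exclusion(means, cn_limit=100, vif_limit=10)
    for step in trail.steps:
        print(f"excluded {step.excluded}: CN before {step.cn_before:.1f}, "
              f"max VIF before {step.max_vif_before:.1f}")
    print(f"retained: {', '.join(trail.retained)} "
          f"(CN = {trail.final.condition_number:.1f}, {trail.final.severity})")

    bio.write_report(trail, OUT / "collinearity_trail.json")
    pd.Series(list(trail.retained)).to_csv(
        OUT / "retained_traits.csv", index=False, header=["trait"]
    )
    print(f"wrote {OUT / 'collinearity_trail.json'}")


if __name__ == "__main__":
    main()
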