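"""Group the synthetic genotypes and project them on canonical variables.

Runs Tocher grouping and the UPGMA dendrogram with the Mojena cut on the
synthetic D² matrix from the previous step, reports the cophenetic
correlation and representation fit, and computes canonical variables with
their variance shares and 2D genotype scores.
"""

from pathlib import Path

import pandas as pd

from bacaba import canonical, clustering, divergence, io as bio
from bacaba.datatypes import DistanceMatrix

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    table = bio.read_trait_table(OUT / "synthetic_population.csv")
    retained = pd.read_csv(OUT / "retained_traits.csv")["trait"].tolist()
    d2 = bio.read_distance_matrix(OUT / "synthetic_d2.csv")

    grouping = clustering.tocher(d2)
    print(f"Tocher: {len(grouping.groups)} groups (theta={grouping.theta:.2f})")
    for i, g in enumerate(grouping.groups, 1):
        print(f"  group {i}: {' '.join(g)}")

    tree = clustering.upgma(d2)
    ccc = clustering.cophenetic_correlation(d2, tree)
    mojena = clustering.mojena_cut(tree, k=1.25)
    print(f"UPGMA + Mojena(k=1.25): {len(set(mojena.values()))} groups, "
          f"cophenetic r = {ccc:.3f}")
    (OUT / "synthetic_upgma.nwk").write_text(clustering.to_newick(tree) + "\n")

    result = canonical.canonical_variables(table, retained)
    acc = result.accumulated_percent
    print(f"canonical variables: first two explain {acc[1]:.1f}% of the variation")
    scores = canonical.biplot_scores(result, dims=2)
    scores.to_csv(OUT / "canonical_scores_2d.csv")

    proj = canonical.projected_distances(result, dims=2)
    fit = clustering.projection_fit(d2, DistanceMatrix(proj.labels, proj.d**2))
    print(f"2D canonical projection: distortion {fit.distortion_pct:.1f}%, "
          f"stress {fit.stress_pct:.1f}%")

    bio.write_report(
        {
            "tocher": grouping,
            "mojena_groups": mojena,
            "cophenetic_correlation": ccc,
            "canonical_eigenvalues": result.eigenvalues,
            "canonical_accumulated_pct": acc,
            "projection_fit_2d": fit,
        },
        OUT / "clustering_canonical.json",
    )
    print(f"wrote {OUT / 'clustering_canonical.json'}")


if __name__ == "__main__":
    main()
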