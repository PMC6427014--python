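"""End-to-end divergence workflow.

Stage order mirrors how this analysis family is reported: per-trait ANOVA
with genetic parameters and Scott-Knott means grouping; multicollinearity
screen of the trait correlation matrix with iterative exclusion; pooled
residual covariance and Mahalanobis D² on the retained traits; distance
summaries; Tocher grouping; UPGMA with Mojena cut and cophenetic
correlation; canonical variables and Singh contributions; and correlation
networks for both the full and the retained trait sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from . import anova, canonical, clustering, collinearity, divergence, network
from .datatypes import DistanceMatrix, PipelineConfig, TraitTable

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineReport:
    schema_version: str
    config: PipelineConfig
    anova_table: list[anova.AnovaResult]
    scott_knott: dict[str, dict[str, str]]
    collinearity_trail: collinearity.ExclusionTrail
    retained_traits: tuple[str, ...]
    d2: DistanceMatrix
    d2_summary: divergence.DistanceSummary
    tocher_groups: clustering.TocherGrouping
    dendrogram: clustering.Dendrogram
    newick: str
    mojena_groups: dict[str, int]
    cophenetic_correlation: float
    dendrogram_fit: clustering.ProjectionFit
    canonical_result: canonical.CanonicalResult
    canonical_2d_fit: clustering.ProjectionFit | None
    singh: divergence.SinghContribution
    network_full: list
    network_retained: list


def run_full(table: TraitTable, config: PipelineConfig | None = None) -> PipelineReport:
    """Run every stage on a replicated trait table."""
    config = config or PipelineConfig()
    traits = list(config.traits) if config.traits else table.traits
    table = table.subset(traits)
    r = table.n_replicates
    log.info("pipeline start: %d genotypes x r=%d, traits=%s",
             len(table.genotypes), r, traits)

    results = anova.genetic_parameter_table(table)
    sk = {
        res.trait: anova.scott_knott(
            table.genotype_means([res.trait])[res.trait].to_dict(),
            res.RMS, res.df_e, r, config.alpha,
        ).as_dict()
        for res in results
    }

    trail = collinearity.iterative_exclusion(
        table.genotype_means(), config.cn_limit, config.vif_limit
    )
    retained = list(trail.retained)

    psi = divergence.pooled_residual_covariance(table, retained)
    means = table.genotype_means(retained)
    d2 = divergence.mahalanobis_matrix(means, psi)
    summary = divergence.distance_summary(d2)

    toch = clustering.tocher(d2)
    tree = clustering.upgma(d2)
    ccc = clustering.cophenetic_correlation(d2, tree)
    dend_fit = clustering.projection_fit(d2, clustering.cophenetic_matrix(tree))
    mojena = clustering.mojena_cut(tree, config.mojena_k)

    canon = canonical.canonical_variables(table, retained)
    canon_fit = None
    if canon.n_axes >= 2:
        proj = canonical.projected_distances(canon, dims=2)
        proj_sq = DistanceMatrix(proj.labels, proj.d ** 2)
        canon_fit = clustering.projection_fit(d2, proj_sq)

    singh = divergence.singh_contribution(means, psi)

    net_full = network.build_graph(
        collinearity.correlation_matrix(table.genotype_means()),
        config.network_rho, config.display_cutoffs,
    )
    net_ret = network.build_graph(
        collinearity.correlation_matrix(means),
        config.network_rho, config.display_cutoffs,
    )

    def edge_list(cg: network.CorrelationGraph) -> list:
        return [
            {
                "a": u, "b": v, "r": attrs["r"], "sign": attrs["sign"],
                "displayed": {str(k): val for k, val in attrs["displayed"].items()},
            }
            for u, v, attrs in cg.graph.edges(data=True)
        ]

    return PipelineReport(
        schema_version="1",
        config=config,
        anova_table=results,
        scott_knott=sk,
        collinearity_trail=trail,
        retained_traits=tuple(retained),
        d2=d2,
        d2_summary=summary,
        tocher_groups=toch,
        dendrogram=tree,
        newick=clustering.to_newick(tree),
        mojena_groups=mojena,
        cophenetic_correlation=ccc,
        dendrogram_fit=dend_fit,
        canonical_result=canon,
        canonical_2d_fit=canon_fit,
        singh=singh,
        network_full=edge_list(net_full),
        network_retained=edge_list(net_ret),
    )


def run_from_distances(d2: DistanceMatrix, config: PipelineConfig | None = None) -> dict:
    """Clustering-only entry point for a precomputed dissimilarity matrix."""
    config = config or PipelineConfig()
    summary = divergence.distance_summary(d2)
    toch = clustering.tocher(d2)
    tree = clustering.upgma(d2)
    return {
        "d2_summary": summary,
        "tocher_groups": toch,
        "dendrogram": tree,
        "newick": clustering.to_newick(tree),
        "mojena_groups": clustering.mojena_cut(tree, config.mojena_k),
        "cophenetic_correlation": clustering.cophenetic_correlation(d2, tree),
        "dendrogram_fit": clustering.projection_fit(
            d2, clustering.cophenetic_matrix(tree)
        ),
    }
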