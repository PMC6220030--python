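"""Model/Results front-end over the pipeline modules.

`RegionSpecificExpression` fits the per-probe donor+region linear models
with empirical-Bayes variance moderation for one focal region; its
results object carries the moderated probe statistics, the per-gene
summaries, the signed genome-wide ranking, and methods for gene-set
enrichment and the brain-wide specificity sweep.

`MarkerGeneProfile` estimates relative cell-type proportions per region
from marker-gene first principal components.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from . import cellprop, diffexpr, enrichment, ranking, specificity
from .cellprop import MarkerSet, ProportionEstimate
from .diffexpr import VariancePrior
from .io import ExpressionBundle, GeneSetCollection

__all__ = [
    "RegionSpecificExpression",
    "RegionSpecificExpressionResults",
    "MarkerGeneProfile",
]


class RegionSpecificExpression:
    """Region-specificity model for one focal region of an expression atlas.

    Parameters
    ----------
    bundle : ExpressionBundle
        Probes x samples log2 expression with probe and sample annotations.
    focal_region : str
        The named region whose specific expression is modelled.

    Examples
    --------
    >>> model = RegionSpecificExpression(bundle, "focal")
    >>> res = model.fit()
    >>> res.ranking.head()
    """

    def __init__(self, bundle: ExpressionBundle, focal_region: str):
        self.bundle = bundle
        self.focal_region = focal_region

    @classmethod
    def from_frames(
        cls,
        matrix: pd.DataFrame,
        probe_annot: pd.Series,
        sample_annot: pd.DataFrame,
        focal_region: str,
    ) -> "RegionSpecificExpression":
        return cls(ExpressionBundle(matrix, probe_annot, sample_annot), focal_region)

    def fit(self) -> "RegionSpecificExpressionResults":
        stats_df = diffexpr.fit_region_model(self.bundle, self.focal_region)
        d = float(stats_df["d"].iloc[0])
        prior = diffexpr.estimate_variance_prior(
            stats_df.loc[stats_df["s2"] > 0, "s2"].to_numpy(), d
        )
        moderated = diffexpr.moderate(stats_df, prior)
        gene_stats = ranking.collapse_probes_to_genes(moderated, self.bundle.probe_annot)
        ranked = ranking.signed_ranking(gene_stats)
        return RegionSpecificExpressionResults(self, prior, moderated, gene_stats, ranked)


class RegionSpecificExpressionResults:
    """Fitted region-specificity results.

    Attributes
    ----------
    prior : VariancePrior
        Estimated (d0, s0sq) of the variance prior.
    probe_stats : DataFrame
        Per-probe beta, moderated variance, moderated t, p, BH q.
    gene_stats : DataFrame
        One representative (lowest-p) probe per gene.
    ranking : DataFrame
        Signed genome-wide ranking, most specifically expressed first.
    """

    def __init__(
        self,
        model: RegionSpecificExpression,
        prior: VariancePrior,
        probe_stats: pd.DataFrame,
        gene_stats: pd.DataFrame,
        ranked: pd.DataFrame,
    ):
        self.model = model
        self.prior = prior
        self.probe_stats = probe_stats
        self.gene_stats = gene_stats
        self.ranking = ranked

    def significant_probes(self, alpha: float = 0.05) -> pd.DataFrame:
        """Probes up-regulated in the focal region at BH q < alpha."""
        return diffexpr.significant_upregulated(self.probe_stats, alpha)

    def significant_genes(self, alpha: float = 0.05) -> pd.DataFrame:
        """Genes whose representative probe is up-regulated at q < alpha."""
        sig = self.gene_stats[(self.gene_stats["q"] < alpha) & (self.gene_stats["beta"] > 0)]
        return sig.sort_values("p", kind="mergesort")

    def enrich(
        self,
        collection: GeneSetCollection,
        min_size: int = 10,
        max_size: int = 200,
    ) -> pd.DataFrame:
        """AUROC / Mann-Whitney enrichment of each set against the ranking."""
        filtered = enrichment.filter_sets(
            collection, set(self.ranking.index), min_size, max_size
        )
        return enrichment.enrich_all(self.ranking, filtered)

    def summary(self, alpha: float = 0.05) -> str:
        n_sig = len(self.significant_probes(alpha))
        n_sig_genes = len(self.significant_genes(alpha))
        d0 = "inf" if math.isinf(self.prior.d0) else f"{self.prior.d0:.3f}"
        lines = [
            "Region-specific expression results",
            "==================================",
            f"Focal region:         {self.model.focal_region}",
            f"Probes / genes:       {len(self.probe_stats)} / {len(self.gene_stats)}",
            f"Samples / donors:     {self.model.bundle.n_samples} / {len(self.model.bundle.donors)}",
            f"Variance prior d0:    {d0}",
            f"Variance prior s0sq:  {self.prior.s0sq:.5f}",
            f"Up-regulated probes (q < {alpha:g}): {n_sig}",
            f"Up-regulated genes  (q < {alpha:g}): {n_sig_genes}",
        ]
        top = self.ranking.head(10)
        lines.append("")
        lines.append("Top genes (most specifically expressed):")
        lines.append(f"{'rank':>4}  {'gene':<12} {'score':>9} {'beta':>8} {'p':>12}")
        for gene, row in top.iterrows():
            lines.append(
                f"{int(row['rank']):>4}  {gene:<12} {row['signed_score']:>9.3f} "
                f"{row['beta']:>8.3f} {row['p']:>12.3e}"
            )
        return "\n".join(lines)

    def sweep_specificity(
        self, collection: GeneSetCollection, min_size: int = 10, max_size: int = 200
    ) -> "specificity.RegionAUROCMatrix":
        """Run the identical procedure with every region as focal."""
        filtered = enrichment.filter_sets(
            collection, set(self.ranking.index), min_size, max_size
        )
        return specificity.sweep_regions(self.model.bundle, filtered)


class MarkerGeneProfile:
    """Relative cell-type proportions from marker-gene first PCs.

    Estimation is per donor (each marker standardized across that donor's
    samples), aggregated to regions, z-scored, averaged across donors and
    ranked — see :mod:`regiospec.cellprop`.
    """

    def __init__(self, bundle: ExpressionBundle, markers: MarkerSet | dict):
        self.bundle = bundle
        self.markers = markers if isinstance(markers, MarkerSet) else MarkerSet(markers)

    def fit(self) -> "MarkerGeneProfileResults":
        est = cellprop.estimate_cell_proportions(self.bundle, self.markers)
        return MarkerGeneProfileResults(self, est)


class MarkerGeneProfileResults:
    """Fitted marker-gene-profile estimates."""

    def __init__(self, model: MarkerGeneProfile, estimate: ProportionEstimate):
        self.model = model
        self.estimate = estimate

    @property
    def region_scores(self) -> pd.DataFrame:
        return self.estimate.region_scores

    @property
    def region_ranks(self) -> pd.DataFrame:
        return self.estimate.region_ranks

    def rank_of(self, region: str, cell_type: str) -> int:
        """Number of regions with a strictly higher estimate (0 = top)."""
        return int(self.estimate.region_ranks.loc[region, cell_type])

    def summary(self) -> str:
        lines = [
            "Marker gene profile estimates",
            "=============================",
            f"Cell types: {', '.join(self.region_scores.columns)}",
            f"Regions:    {len(self.region_scores)}",
            "",
            "Top region per cell type (rank 0):",
        ]
        for ct in self.region_scores.columns:
            top = self.region_scores[ct].idxmax()
            lines.append(f"  {ct:<20} {top} (score {self.region_scores.loc[top, ct]:.3f})")
        return "\n".join(lines)
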