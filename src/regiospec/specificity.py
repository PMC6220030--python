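"""Brain-wide specificity: sweep the full pipeline over every named region.

For each named region of the atlas the identical procedure is run with
that region as the focal region — fit the donor+region model, estimate the
variance prior, moderate, collapse probes to genes, build the signed
ranking, and score every gene set by AUROC.  A gene set's *specificity
rank* for the focal region is the number of other regions with a strictly
higher AUROC; rank 0 means no other region is more enriched for the set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import diffexpr, enrichment, ranking
from .diffexpr import DesignError
from .io import ExpressionBundle, GeneSetCollection

logger = logging.getLogger(__name__)

__all__ = ["RegionAUROCMatrix", "sweep_regions", "specificity_rank", "cross_dataset_validate"]


@dataclass
class RegionAUROCMatrix:
    """Per-region AUROC (and one-sided p) for every gene set."""

    auroc: pd.DataFrame  # regions x sets
    p: pd.DataFrame  # regions x sets
    skipped_regions: list[str] = field(default_factory=list)

    @property
    def regions(self) -> list[str]:
        return list(self.auroc.index)

    @property
    def set_names(self) -> list[str]:
        return list(self.auroc.columns)


def analyze_region(bundle: ExpressionBundle, focal_region: str) -> pd.DataFrame:
    """fit -> moderate -> collapse -> rank for one focal region."""
    stats_df = diffexpr.fit_region_model(bundle, focal_region)
    prior = diffexpr.estimate_variance_prior(
        stats_df.loc[stats_df["s2"] > 0, "s2"].to_numpy(), float(stats_df["d"].iloc[0])
    )
    moderated = diffexpr.moderate(stats_df, prior)
    genes = ranking.collapse_probes_to_genes(moderated, bundle.probe_annot)
    return ranking.signed_ranking(genes)


def sweep_regions(
    bundle: ExpressionBundle,
    collection: GeneSetCollection,
    regions: list[str] | None = None,
) -> RegionAUROCMatrix:
    """Run the region-specific expression + enrichment procedure per region.

    Regions whose design is rank-deficient are skipped with a warning and
    excluded from the matrix (hence from specificity ranks).
    """
    if regions is None:
        regions = bundle.regions
    set_names = sorted(collection)
    auroc_rows: dict[str, pd.Series] = {}
    p_rows: dict[str, pd.Series] = {}
    skipped: list[str] = []
    for region in regions:
        try:
            ranked = analyze_region(bundle, region)
        except DesignError as err:
            logger.warning("skipping region %r: %s", region, err)
            skipped.append(region)
            continue
        enriched = enrichment.enrich_all(ranked, collection).set_index("set_name")
        auroc_rows[region] = enriched["auroc"].reindex(set_names)
        p_rows[region] = enriched["p"].reindex(set_names)
    if not auroc_rows:
        raise DesignError("no region could be analyzed")
    return RegionAUROCMatrix(
        auroc=pd.DataFrame(auroc_rows).T.reindex(columns=set_names),
        p=pd.DataFrame(p_rows).T.reindex(columns=set_names),
        skipped_regions=skipped,
    )


def specificity_rank(matrix: RegionAUROCMatrix, focal: str, set_name: str) -> int:
    """Number of non-focal regions whose AUROC strictly exceeds the focal one."""
    if set_name not in matrix.auroc.columns:
        raise KeyError(f"gene set {set_name!r} not in the AUROC matrix")
    if focal not in matrix.auroc.index:
        raise KeyError(f"region {focal!r} not in the AUROC matrix")
    col = matrix.auroc[set_name]
    focal_value = col.loc[focal]
    others = col.drop(index=focal)
    return int((others > focal_value).sum())


def specificity_table(matrix: RegionAUROCMatrix, focal: str) -> pd.DataFrame:
    """Specificity rank of every set for one focal region."""
    rows = [
        {
            "set_name": name,
            "focal_region": focal,
            "auroc": matrix.auroc.loc[focal, name],
            "specificity_rank": specificity_rank(matrix, focal, name),
        }
        for name in matrix.set_names
    ]
    return pd.DataFrame(rows)


def cross_dataset_validate(
    primary: pd.DataFrame,
    replication: pd.DataFrame,
    max_spec_rank: int = 0,
    replication_alpha: float = 0.05,
    primary_alpha: float = 0.05,
) -> pd.DataFrame:
    """Keep sets significant in the primary atlas, specific brain-wide, and
    nominally replicated in the second atlas.

    ``primary`` must carry ``set_name``, ``q`` and ``specificity_rank``;
    ``replication`` must carry ``set_name``, ``p`` and ``auroc``.  A set is
    kept when primary q < primary_alpha, specificity_rank <= max_spec_rank,
    and replication p < replication_alpha with replication AUROC > 0.5.
    Sets absent from the replication table are excluded with a warning.
    """
    if len(replication) == 0:
        logger.warning("replication table is empty; nothing validates")
        return primary.iloc[0:0].copy()
    rep = replication.set_index("set_name")
    keep_rows = []
    for _, row in primary.iterrows():
        name = row["set_name"]
        if not (row["q"] < primary_alpha and row["specificity_rank"] <= max_spec_rank):
            continue
        if name not in rep.index:
            logger.warning("set %r absent from the replication table; excluded", name)
            continue
        r = rep.loc[name]
        if r["p"] < replication_alpha and r["auroc"] > 0.5:
            out = row.copy()
            out["replication_p"] = r["p"]
            out["replication_auroc"] = r["auroc"]
            keep_rows.append(out)
    if not keep_rows:
        return primary.iloc[0:0].copy()
    return pd.DataFrame(keep_rows).reset_index(drop=True)
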