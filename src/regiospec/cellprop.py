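"""Marker-gene-profile estimation of relative cell-type proportions.

For each donor separately, the expression of a cell type's marker genes
(collapsed probe -> gene by the probe with the highest mean expression,
each marker standardized across the donor's samples) is summarized by the
first principal component of the samples-by-markers matrix; the component
is oriented so the sum of marker loadings is positive, making higher
scores mean more of the cell type.  Per donor, sample scores are averaged
within each region and z-scored across regions; cross-donor means of
those z-scores give the regional estimate, and a region's rank for a cell
type is the number of regions with a strictly higher estimate (0 = most).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ExpressionBundle, GeneSetCollection

logger = logging.getLogger(__name__)

__all__ = ["MarkerSet", "ProportionEstimate", "estimate_donor_scores", "aggregate_proportions", "estimate_cell_proportions"]


@dataclass
class MarkerSet:
    """Cell type name -> marker gene symbols (duplicates removed)."""

    markers: dict[str, list[str]]

    def __post_init__(self) -> None:
        cleaned = {}
        for cell_type, genes in self.markers.items():
            uniq = list(dict.fromkeys(g.strip() for g in genes if g.strip()))
            if not uniq:
                raise ValueError(f"marker list for {cell_type!r} is empty")
            cleaned[cell_type] = uniq
        self.markers = cleaned

    @classmethod
    def from_collection(cls, collection: GeneSetCollection) -> "MarkerSet":
        return cls({name: sorted(collection[name]) for name in collection})

    def require_disjoint(self) -> None:
        seen: dict[str, str] = {}
        for cell_type, genes in self.markers.items():
            for g in genes:
                if g in seen:
                    raise ValueError(
                        f"marker {g!r} appears in both {seen[g]!r} and {cell_type!r}"
                    )
                seen[g] = cell_type

    def __iter__(self):
        return iter(self.markers)

    def __getitem__(self, cell_type: str) -> list[str]:
        return self.markers[cell_type]


@dataclass
class ProportionEstimate:
    """Per-donor sample scores, regional estimates and ranks per cell type."""

    sample_scores: pd.DataFrame  # columns: donor_id, sample_id, cell_type, score
    region_scores: pd.DataFrame  # regions x cell types (cross-donor mean z-scores)
    region_ranks: pd.DataFrame  # regions x cell types, 0 = highest estimate
    skipped: list[tuple[str, str]] = field(default_factory=list)  # (donor, cell type)


def _collapse_markers(bundle: ExpressionBundle, markers: list[str]) -> pd.DataFrame:
    """Marker genes x samples, collapsing probes by the highest-mean probe."""
    present = bundle.probe_annot[bundle.probe_annot.isin(markers)]
    if present.empty:
        return pd.DataFrame(columns=bundle.matrix.columns)
    sub = bundle.matrix.loc[present.index]
    means = sub.mean(axis=1)
    rows = []
    for gene, probe_ids in present.groupby(present).groups.items():
        best = means.loc[probe_ids].sort_index().idxmax()
        rows.append((gene, best))
    return pd.DataFrame({gene: bundle.matrix.loc[probe] for gene, probe in rows}).T


def estimate_donor_scores(
    donor_bundle: ExpressionBundle, markers: MarkerSet, cell_type: str
) -> pd.Series | None:
    """First-PC sample scores of standardized marker expression for one donor.

    Returns None (with a warning) when fewer than two usable markers are
    present; zero-variance markers are dropped.
    """
    if donor_bundle.n_samples < 2:
        raise ValueError("donor must have at least 2 samples")
    expr = _collapse_markers(donor_bundle, markers[cell_type])  # genes x samples
    sd = expr.std(axis=1, ddof=1)
    expr = expr.loc[sd > 0]
    if expr.shape[0] < 2:
        logger.warning(
            "cell type %r skipped for donor %s: only %d usable markers",
            cell_type,
            donor_bundle.donors[0],
            expr.shape[0],
        )
        return None
    z = expr.sub(expr.mean(axis=1), axis=0).div(expr.std(axis=1, ddof=1), axis=0)
    mat = z.to_numpy().T  # samples x markers
    u, s, vt = np.linalg.svd(mat, full_matrices=False)
    loadings = vt[0]
    scores = u[:, 0] * s[0]
    if loadings.sum() < 0:
        loadings = -loadings
        scores = -scores
    return pd.Series(scores, index=z.columns, name=cell_type)


def aggregate_proportions(
    donor_scores: dict[str, dict[str, pd.Series]],
    sample_annot: pd.DataFrame,
) -> ProportionEstimate:
    """Regional means -> per-donor z-scores -> cross-donor means -> ranks.

    ``donor_scores[donor][cell_type]`` are per-sample scores.  Regions
    present in only a subset of donors use the available donors' z-scores.
    """
    long_rows = []
    per_donor_region: dict[str, dict[str, pd.Series]] = {}
    for donor, by_type in donor_scores.items():
        per_donor_region[donor] = {}
        for cell_type, scores in by_type.items():
            if scores is None:
                continue
            for sample_id, score in scores.items():
                long_rows.append(
                    {"donor_id": donor, "sample_id": sample_id, "cell_type": cell_type, "score": score}
                )
            regions = sample_annot.loc[scores.index, "region_name"]
            region_mean = scores.groupby(regions).mean()
            sd = region_mean.std(ddof=1)
            if not np.isfinite(sd) or sd == 0:
                zs = region_mean * 0.0
            else:
                zs = (region_mean - region_mean.mean()) / sd
            per_donor_region[donor][cell_type] = zs
    cell_types = sorted({ct for d in per_donor_region.values() for ct in d})
    all_regions = sorted(sample_annot["region_name"].unique())
    region_scores = pd.DataFrame(index=all_regions, columns=cell_types, dtype=float)
    for cell_type in cell_types:
        frames = [
            per_donor_region[d][cell_type]
            for d in per_donor_region
            if cell_type in per_donor_region[d]
        ]
        stacked = pd.concat(frames, axis=1)
        region_scores[cell_type] = stacked.mean(axis=1).reindex(all_regions)
    uncovered = region_scores.index[region_scores.isna().all(axis=1)]
    for region in uncovered:
        logger.warning("region %r sampled in no donor; excluded from proportions", region)
    region_scores = region_scores.drop(index=uncovered)
    # rank = number of regions with a strictly higher cross-donor estimate
    ranks = region_scores.apply(
        lambda col: col.map(lambda x: int((col > x).sum())), axis=0
    )
    return ProportionEstimate(
        sample_scores=pd.DataFrame(
            long_rows, columns=["donor_id", "sample_id", "cell_type", "score"]
        ),
        region_scores=region_scores,
        region_ranks=ranks.astype(int),
    )


def estimate_cell_proportions(bundle: ExpressionBundle, markers: MarkerSet) -> ProportionEstimate:
    """Full per-donor -> regional aggregation for every cell type."""
    markers.require_disjoint()
    donor_scores: dict[str, dict[str, pd.Series]] = {}
    skipped: list[tuple[str, str]] = []
    for donor in bundle.donors:
        sub = bundle.subset_donor(donor)
        if sub.n_samples < 2:
            logger.warning("donor %s has <2 samples; skipped", donor)
            continue
        donor_scores[donor] = {}
        for cell_type in markers:
            scores = estimate_donor_scores(sub, markers, cell_type)
            if scores is None:
                skipped.append((donor, cell_type))
            else:
                donor_scores[donor][cell_type] = scores
    est = aggregate_proportions(donor_scores, bundle.sample_annot)
    est.skipped = skipped
    return est
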