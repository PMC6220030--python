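"""Synthetic expression atlases with known ground truth.

The generator emulates the structure the region-specificity analysis
assumes: several donors, many named regions with only a handful of
samples each, many-to-one probe-to-gene mapping, per-probe variances
drawn from a scaled inverse-chi-square prior, gene-by-donor shifts, and a
focal region in which a fraction of genes carry a log2 expression shift.
Gene sets can be spiked with those focal genes, and a separate mixture
generator produces marker-gene expression that tracks known per-region
cell-type proportions.

Every draw is recorded in a :class:`SyntheticTruth`, the oracle used by
the acceptance tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ExpressionBundle, GeneSetCollection

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "generate_atlas",
    "generate_gene_sets",
    "generate_marker_mixture",
    "default_proportion_profile",
    "default_marker_sets",
]


def _default_regions() -> dict[str, int]:
    """Focal region with 3 samples per donor; 24 decoys with 1-3 each."""
    regions = {"focal": 3}
    for i in range(24):
        regions[f"region_{i + 1:02d}"] = 1 + (i % 3)
    return regions


@dataclass
class SyntheticConfig:
    """Generation parameters; the defaults are the package's study conditions.

    ``variance_prior`` is the (d0, s0sq) of the scaled inverse-chi-square
    prior that per-probe variances are drawn from; ``effect_size_delta``
    is the log2 shift of spiked genes in the focal region.
    """

    n_genes: int = 1500
    probes_per_gene: dict[int, float] = field(
        default_factory=lambda: {1: 0.6, 2: 0.3, 3: 0.1}
    )
    n_donors: int = 3
    regions: dict[str, int] = field(default_factory=_default_regions)
    focal_region: str = "focal"
    donors_missing_focal: list[str] = field(default_factory=list)
    spike_fraction: float = 0.05
    effect_size_delta: float = 2.0
    donor_shift_sd: float = 0.5
    variance_prior: tuple[float, float] = (4.0, 0.25)
    n_spiked_sets: int = 5
    set_size_range: tuple[int, int] = (10, 30)
    spiked_purity: float = 0.9
    baseline_mean: float = 7.0
    baseline_sd: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0 or self.n_donors <= 0:
            raise ValueError("counts must be positive")
        if not (0.0 <= self.spike_fraction <= 1.0):
            raise ValueError("spike_fraction must be in [0, 1]")
        if self.focal_region not in self.regions:
            raise ValueError(f"focal region {self.focal_region!r} not in regions")
        lo, hi = self.set_size_range
        if not (2 <= lo <= hi <= self.n_genes):
            raise ValueError("set_size_range must lie within [2, n_genes]")
        if any(c < 1 for c in self.regions.values()):
            raise ValueError("every region needs at least one sample per sampled donor")
        d0, s0sq = self.variance_prior
        if d0 <= 0 or s0sq <= 0:
            raise ValueError("variance prior parameters must be positive")

    @property
    def donors(self) -> list[str]:
        return [f"donor{i + 1}" for i in range(self.n_donors)]


@dataclass
class SyntheticTruth:
    """Ground truth recorded during generation (the acceptance oracle)."""

    spiked_genes: dict[str, float]  # gene -> true log2 delta (spiked genes only)
    gene_deltas: pd.Series  # all genes -> delta (0 for null genes)
    probe_variances: pd.Series  # probe -> true sigma^2
    set_membership: dict[str, dict] = field(default_factory=dict)  # name -> {members, spiked}
    true_proportions: pd.DataFrame | None = None  # regions x cell types

    def spiked_set_names(self) -> list[str]:
        return sorted(n for n, rec in self.set_membership.items() if rec["spiked"])

    def null_set_names(self) -> list[str]:
        return sorted(n for n, rec in self.set_membership.items() if not rec["spiked"])


def _draw_variances(rng: np.random.Generator, n: int, d0: float, s0sq: float) -> np.ndarray:
    return s0sq * d0 / rng.chisquare(d0, size=n)


def generate_atlas(config: SyntheticConfig) -> tuple[ExpressionBundle, SyntheticTruth]:
    """Draw a complete atlas:
    ``y = mu_gene + donor_shift[gene, donor] + delta_gene * 1[focal] + eps``
    with ``eps ~ N(0, sigma^2_probe)`` and probe variances from the prior.
    """
    rng = np.random.default_rng(config.seed)
    genes = [f"G{i + 1:05d}" for i in range(config.n_genes)]
    # spiked genes
    n_spiked = int(round(config.spike_fraction * config.n_genes))
    spiked_idx = rng.choice(config.n_genes, size=n_spiked, replace=False)
    deltas = np.zeros(config.n_genes)
    deltas[spiked_idx] = config.effect_size_delta
    gene_deltas = pd.Series(deltas, index=genes)
    # probe structure
    counts = np.array(sorted(config.probes_per_gene))
    probs = np.array([config.probes_per_gene[c] for c in counts], dtype=float)
    probs = probs / probs.sum()
    n_probes_per_gene = rng.choice(counts, size=config.n_genes, p=probs)
    probe_ids, probe_gene = [], []
    for g, gene in enumerate(genes):
        for j in range(int(n_probes_per_gene[g])):
            probe_ids.append(f"P{g + 1:05d}_{j + 1}")
            probe_gene.append(gene)
    n_probes = len(probe_ids)
    d0, s0sq = config.variance_prior
    sigma2 = _draw_variances(rng, n_probes, d0, s0sq)
    mu_gene = rng.normal(config.baseline_mean, config.baseline_sd, size=config.n_genes)
    mu = pd.Series(mu_gene, index=genes)
    donors = config.donors
    # gene-by-donor shifts make the donor covariate non-trivial
    shifts = rng.normal(0.0, config.donor_shift_sd, size=(config.n_genes, len(donors)))
    shift_df = pd.DataFrame(shifts, index=genes, columns=donors)
    # sample layout
    sample_ids, sample_donor, sample_region = [], [], []
    for donor in donors:
        for region, count in config.regions.items():
            if region == config.focal_region and donor in config.donors_missing_focal:
                continue
            for i in range(count):
                sample_ids.append(f"{donor}_{len(sample_ids):04d}")
                sample_donor.append(donor)
                sample_region.append(region)
    if config.focal_region not in sample_region:
        raise ValueError("no donor contributes focal-region samples")
    n_samples = len(sample_ids)
    gene_index = {g: i for i, g in enumerate(genes)}
    gene_of_probe = np.array([gene_index[g] for g in probe_gene])
    donor_idx = np.array([donors.index(d) for d in sample_donor])
    is_focal = np.array([r == config.focal_region for r in sample_region], dtype=float)
    mean_matrix = (
        mu.to_numpy()[gene_of_probe][:, None]
        + shift_df.to_numpy()[gene_of_probe][:, donor_idx]
        + gene_deltas.to_numpy()[gene_of_probe][:, None] * is_focal[None, :]
    )
    noise = rng.normal(0.0, 1.0, size=(n_probes, n_samples)) * np.sqrt(sigma2)[:, None]
    matrix = pd.DataFrame(mean_matrix + noise, index=probe_ids, columns=sample_ids)
    bundle = ExpressionBundle(
        matrix=matrix,
        probe_annot=pd.Series(probe_gene, index=probe_ids, name="gene_symbol"),
        sample_annot=pd.DataFrame(
            {"donor_id": sample_donor, "region_name": sample_region},
            index=pd.Index(sample_ids, name="sample_id"),
        ),
    )
    truth = SyntheticTruth(
        spiked_genes={genes[i]: config.effect_size_delta for i in sorted(spiked_idx)},
        gene_deltas=gene_deltas,
        probe_variances=pd.Series(sigma2, index=probe_ids),
    )
    return bundle, truth


def generate_gene_sets(truth: SyntheticTruth, config: SyntheticConfig) -> GeneSetCollection:
    """Spiked sets (mostly focal genes) plus size-matched null sets.

    Spiked sets draw ``spiked_purity`` of their members from spiked genes;
    null sets are sampled uniformly from non-spiked genes.  Membership and
    flags are recorded in the truth object.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    spiked = sorted(truth.spiked_genes)
    null_genes = sorted(set(truth.gene_deltas.index) - set(spiked))
    lo, hi = config.set_size_range
    sets: dict[str, frozenset[str]] = {}
    prov: dict[str, str] = {}
    sizes = []
    for i in range(config.n_spiked_sets):
        size = int(rng.integers(lo, hi + 1))
        sizes.append(size)
        n_from_spiked = int(np.ceil(config.spiked_purity * size))
        if n_from_spiked > len(spiked) or size - n_from_spiked > len(null_genes):
            raise ValueError("requested set size exceeds available genes")
        members = list(rng.choice(spiked, size=n_from_spiked, replace=False)) + list(
            rng.choice(null_genes, size=size - n_from_spiked, replace=False)
        )
        name = f"spiked_set_{i + 1}"
        sets[name] = frozenset(members)
        prov[name] = "synthetic-spiked"
        truth.set_membership[name] = {"members": frozenset(members), "spiked": True}
    for i, size in enumerate(sizes):
        if size > len(null_genes):
            raise ValueError("requested set size exceeds available genes")
        members = list(rng.choice(null_genes, size=size, replace=False))
        name = f"null_set_{i + 1}"
        sets[name] = frozenset(members)
        prov[name] = "synthetic-null"
        truth.set_membership[name] = {"members": frozenset(members), "spiked": False}
    return GeneSetCollection(sets=sets, provenance=prov)


def default_proportion_profile(
    regions: list[str], cell_types: list[str], seed: int = 0
) -> pd.DataFrame:
    """Dirichlet per-region cell-type fractions (rows sum to 1)."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2]))
    fractions = rng.dirichlet(np.ones(len(cell_types)), size=len(regions))
    return pd.DataFrame(fractions, index=regions, columns=cell_types)


def default_marker_sets(cell_types: list[str], markers_per_type: int = 21) -> dict[str, list[str]]:
    return {
        ct: [f"MK_{ct}_{j + 1:02d}" for j in range(markers_per_type)] for ct in cell_types
    }


def generate_marker_mixture(
    config: SyntheticConfig,
    marker_sets: dict[str, list[str]],
    proportion_profile: pd.DataFrame,
    lam: float = 1.0,
    noise_sd: float = 0.3,
    samples_per_region: int = 3,
) -> tuple[ExpressionBundle, SyntheticTruth]:
    """Marker expression = baseline + lam * proportion[region, cell type] + noise.

    ``proportion_profile`` is regions x cell types with rows summing to 1;
    marker lists must be disjoint.
    """
    seen: dict[str, str] = {}
    for ct, genes in marker_sets.items():
        for g in genes:
            if g in seen:
                raise ValueError(f"marker {g!r} shared by {seen[g]!r} and {ct!r}")
            seen[g] = ct
    rowsums = proportion_profile.sum(axis=1)
    if not np.allclose(rowsums, 1.0, atol=1e-8):
        raise ValueError("proportions must sum to 1 within each region")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
    regions = list(proportion_profile.index)
    donors = config.donors
    sample_ids, sample_donor, sample_region = [], [], []
    for donor in donors:
        for region in regions:
            for _ in range(samples_per_region):
                sample_ids.append(f"{donor}_{len(sample_ids):04d}")
                sample_donor.append(donor)
                sample_region.append(region)
    probe_ids, probe_gene, rows = [], [], []
    for ct in sorted(marker_sets):
        props = proportion_profile[ct]
        for gene in marker_sets[ct]:
            baseline = rng.normal(config.baseline_mean, 1.0)
            mean = baseline + lam * np.array([props.loc[r] for r in sample_region])
            noise = rng.normal(0.0, noise_sd, size=len(sample_ids)) if noise_sd > 0 else 0.0
            probe_ids.append(f"P_{gene}")
            probe_gene.append(gene)
            rows.append(mean + noise)
    matrix = pd.DataFrame(np.vstack(rows), index=probe_ids, columns=sample_ids)
    bundle = ExpressionBundle(
        matrix=matrix,
        probe_annot=pd.Series(probe_gene, index=probe_ids, name="gene_symbol"),
        sample_annot=pd.DataFrame(
            {"donor_id": sample_donor, "region_name": sample_region},
            index=pd.Index(sample_ids, name="sample_id"),
        ),
    )
    truth = SyntheticTruth(
        spiked_genes={},
        gene_deltas=pd.Series(0.0, index=probe_gene),
        probe_variances=pd.Series(noise_sd**2, index=probe_ids),
        true_proportions=proportion_profile.copy(),
    )
    return bundle, truth
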