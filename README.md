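# regiospec

Region-specific expression analysis for anatomically annotated expression
atlases.

Anatomical expression atlases (such as the Allen Human Brain Atlas
microarray survey) profile hundreds of named brain regions with only a
handful of samples per region, spread over a few donors. `regiospec`
answers the question those atlases make possible: *which genes — and which
functional gene sets — are specifically expressed in one focal region,
and is that enrichment unique to the region brain-wide?* It was built for
computational neuroscientists and transcriptomics analysts characterizing
small structures (e.g. the habenula's lateral and medial divisions) where
per-region sample counts are too small for ordinary per-probe tests.

## The method

For each microarray probe $g$, the log2 expression of sample $i$ is
modelled with donor and focal-region coefficients:

$$y_{gi} = \mu_g + \textstyle\sum_d \alpha_{gd}\,\mathbb{1}[\text{donor}(i)=d] + \beta_g\,\mathbb{1}[\text{region}(i)=\text{focal}] + \varepsilon_{gi},\qquad \varepsilon_{gi}\sim\mathcal N(0,\sigma_g^2).$$

Per-probe residual variances $s_g^2$ (on $d$ residual degrees of freedom)
are shrunk with an empirical-Bayes prior $\sigma_g^2 \sim s_0^2 d_0/\chi^2_{d_0}$
fitted by the method of moments on log variances:

$$\tilde s_g^2 = \frac{d_0 s_0^2 + d\, s_g^2}{d_0 + d},\qquad \tilde t_g = \frac{\hat\beta_g}{\sqrt{\tilde s_g^2 v_g}} \sim t_{d_0+d},$$

with $v_g$ the unscaled coefficient variance of the region indicator.
Two-sided p-values are Benjamini–Hochberg corrected; probes with
$q < 0.05$ and $\hat\beta > 0$ are the region's up-regulated probes.

Probes are collapsed to genes by the lowest-p probe, and genes are
ordered by the signed score $\mathrm{sign}(\tilde t)\cdot(-\log_{10} p)$
— from most specifically expressed to most depleted. A gene set's
enrichment is the AUROC: the probability that a set member precedes a
non-member in that ranking, tested one-sided with the Mann–Whitney U
statistic ($\mathrm{AUROC} = U/(n_1 n_2)$; exact enumeration for small
sets, tie- and continuity-corrected normal approximation otherwise).
Running the identical procedure with *every* named region as focal gives
each set a **specificity rank** — the number of other regions with a
strictly higher AUROC; rank 0 means no region in the atlas is more
enriched. Cross-atlas agreement is quantified with upper-tail
hypergeometric overlap and binomial replication tests, and relative
cell-type proportions per region are estimated as the first principal
component of standardized marker-gene expression (per donor, then
aggregated, z-scored, averaged and ranked across regions).

A synthetic-atlas generator reproduces the statistical structure all of
this assumes — multi-donor sampling, sparse regions, probe multiplicity,
inverse-chi-square probe variances, spiked focal-region effects, spiked
and null gene sets, and marker mixtures with known cell-type proportions
— so every stage can be validated against ground truth.

## Worked example

```python
from regiospec import simulate
from regiospec.model import RegionSpecificExpression

cfg = simulate.SyntheticConfig(seed=7)          # default study conditions
bundle, truth = simulate.generate_atlas(cfg)    # 2,248 probes x 153 samples
res = RegionSpecificExpression(bundle, "focal").fit()
print(res.summary())
```

```
Region-specific expression results
==================================
Focal region:         focal
Probes / genes:       2248 / 1500
Samples / donors:     153 / 3
Variance prior d0:    4.006
Variance prior s0sq:  0.25002
Up-regulated probes (q < 0.05): 116
Up-regulated genes  (q < 0.05): 78

Top genes (most specifically expressed):
rank  gene             score     beta            p
   1  G00978          49.117    2.188    7.631e-50
   2  G00146          45.859    1.882    1.385e-46
   3  G00500          44.545    2.133    2.849e-45
...
```

The atlas was generated with a variance prior of $(d_0, s_0^2) = (4, 0.25)$
and a 2-log2-unit spike in 5% of genes; the fitted prior (4.006, 0.25002)
recovers it, and the up-regulated genes are dominated by the spiked ones.
Enrichment against the generated gene sets puts the spiked sets first:

```python
res.enrich(simulate.generate_gene_sets(truth, cfg), min_size=5).sort_values("q").head(4)
```

```
    set_name  n_set    auroc       U            p            q  examined
spiked_set_1     28 0.939077 38705.0 7.929452e-16 4.147779e-15      True
spiked_set_4     27 0.946670 37650.0 8.295558e-16 4.147779e-15      True
spiked_set_5     28 0.932648 38440.0 2.025264e-15 6.750880e-15      True
spiked_set_3     23 0.945660 32125.0 1.035123e-13 2.587809e-13      True
```

An AUROC of 0.94 means a spiked-set gene precedes a non-member 94% of the
time in the genome-wide ranking; `res.sweep_specificity(...)` then shows
the focal region attains the highest AUROC of all 25 regions
(specificity rank 0) for each spiked set.

The same stages are available from a shell:

```bash
regiospec simulate --seed 7 --out demo/
regiospec rank --bundle demo/bundle --region focal --out demo/ranking.tsv
regiospec enrich --ranking demo/ranking.tsv --sets demo/sets.gmt --min 5 --out demo/enrichment.tsv
regiospec overlap --k 42 --K 405 --n 127 --N 20779
```

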