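# microtrait

Statistical machinery for linking a 16S feature table (OTUs or taxa) from a
cohort study to quantitative serum phenotypes — glucose and the lipid panel
(TC, TG, HDL, LDL, plus the derived LDL/HDL ratio and atherosclerosis index
AI = (TC − HDL)/HDL). It is written for microbiome researchers who have a
counts table, a Greengenes-style taxonomy and per-animal phenotypes, and
want association tests that respect zero inflation, multiple-testing control
that respects the min-P statistic, and an estimate of how much trait
variance the microbiome explains.

## The model

Relative microbial abundances are zero-inflated: a feature is absent from
many samples and, where present, varies over orders of magnitude. A single
regression on abundance conflates those two signals, so each feature *j* is
decomposed into two parts tested separately against a trait *y* (with sex
and batch as optional covariates):

* **binary part** — OLS of *y* on the presence indicator
  *b<sub>j</sub>* ∈ {0, 1}; effect β₁, two-tailed *P*<sub>b</sub>;
* **quantitative part** — OLS of *y* on *q<sub>j</sub>*, the z-standardised
  log₁₀ relative abundance computed over the samples where the feature is
  present; effect β₂, *P*<sub>q</sub>;
* **meta part** — the signed normal scores of the two parts combined with
  the unweighted Z-score (Stouffer) method,
  *Z*<sub>meta</sub> = (*Z*<sub>b</sub> + *Z*<sub>q</sub>)/√2.

The per-feature final *P* is min(*P*<sub>b</sub>, *P*<sub>q</sub>,
*P*<sub>meta</sub>) over the parts that are computable, and its *source*
(which part won) says whether presence, abundance, or both drive the
association. Because a minimum of three correlated *P* values is not
uniform under the null, significance is calibrated by permutation:
covariate-adjusted trait residuals are permuted (Freedman–Lane), the full
scan is recomputed per permutation, and plug-in FDR q-values are read off
the permutation null.

The microbiome's contribution to a trait is then estimated with an additive
microbial risk score. On a random 70% discovery set the two-part scan is
fitted, features with final *P* ≤ *P*<sub>t</sub> are selected, and each
validation sample is scored

&nbsp;&nbsp;&nbsp;&nbsp;*r<sub>m</sub>* = Σ<sub>j</sub> (β₁ⱼ·*b*ⱼ + β₂ⱼ·*q*ⱼ),

with *q*ⱼ computed using the discovery transform parameters. The trait
variance explained is the incremental *R*² of *r<sub>m</sub>* over sex and
batch on the validation samples, averaged over 100 random splits and swept
over a threshold grid (10⁻⁵ … 0.1).

The package also carries the surrounding pipeline: BIOM-TSV reading,
rarefaction (multivariate hypergeometric, seeded), relative-abundance
closure, mean-abundance/prevalence filtering (≥ 0.05%, ≥ 20% of samples by
default), taxonomy aggregation, alpha diversity (observed OTUs, Shannon in
nats) with Welch-t group contrasts and Shapiro–Wilk checks, univariate
pathway regression with the > 80%-presence / > 10⁻⁴-abundance filters, and
a synthetic-cohort generator with known planted truth for validation.

## Worked example

```python
import microtrait as mt

cfg = mt.SimulationConfig(n_samples=240, n_features=300, target_r2=0.25, seed=11)
table = mt.simulate_community(cfg)                 # counts, 10,000 tags/sample
pheno, truth = mt.simulate_traits(table, cfg)      # planted GLU effects
filt, report = table.filter_features(5e-4, 0.2)    # >=0.05% mean, >=20% samples

res = mt.TwoPartAssociation.from_tables(filt, pheno, "GLU").fit(n_perm=1000, seed=1)
print(res.summary())

ve = mt.MicrobiomeVarianceExplained(filt, pheno, "GLU").fit(repeats=100, seed=1)
print(ve.summary())
```

prints (abridged):

```
Two-part association: GLU
========================================
samples: 240   features tested: 216 / 216
permutations: 1000   FDR alpha: 0.05
significant features: 1   P threshold: 4.45e-14

top associations:
            prevalence  P_binary       P_quant    P_meta       P_final        source
OTU0050       0.966667       NaN  4.445034e-14       NaN  4.445034e-14  quantitative
OTU0261       0.841667  0.000914  4.750591e-01  0.065833  9.138165e-04        binary
OTU0058       0.462500  0.010357  4.535513e-02  0.001247  1.246728e-03          meta

Microbiome variance explained: GLU
============================================
trait  threshold  mean_R2    sd_R2  mean_n_selected  repeats
  GLU    0.00001 0.215061 0.067139             1.01      100
  GLU    0.00010 0.211457 0.070430             1.06      100
  GLU    0.00100 0.173372 0.074969             1.69      100
  GLU    0.01000 0.103209 0.065267             8.39      100
  GLU    0.05000 0.079028 0.052593            31.21      100
  GLU    0.10000 0.073896 0.051875            54.04      100

max mean R^2 = 0.2151 at threshold 1e-05
```

Reading this: after filtering, 216 features are scanned. The strongest
planted feature is abundance-driven (`source=quantitative`, *P* ≈ 4×10⁻¹⁴)
and survives the 1000-permutation FDR at 0.05. NaNs mark parts that are not
computable — OTU0050 is present in 97% of samples, so its presence
indicator is near-constant and the binary (hence meta) part is skipped. The
cross-validated risk score recovers a mean *R*² of 0.215 against a planted
microbiome contribution of 0.25; the shortfall is the expected attenuation
from estimating weights on 168 discovery samples.

A command-line pipeline mirrors the library
(`microtrait simulate|filter|diversity|associate|fdr|pathways|varexp|run`);
`microtrait run --config run.yaml` chains the stages and writes per-stage
TSVs plus a manifest with input checksums and stage timings.

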