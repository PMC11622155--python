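# geascan

Genotype–environment association scans, allelic-turnover modelling and
climate-adjusted donor matching for estuarine seagrass meadows.

## The problem

Restoration programs increasingly want *climate-adjusted provenancing*:
choosing donor populations whose standing genotypes are already adapted
to the conditions a recipient site will face decades from now. For
seagrasses in south-east Australian estuaries — warming far faster than
open-coast models predict — that requires (1) finding SNP loci whose
allele frequencies track environmental gradients across meadows,
(2) describing *where* along each gradient the allelic composition
turns over, and (3) matching each meadow's projected future conditions
to a meadow that experiences them today.

`geascan` implements that workflow end to end, for anyone working with
biallelic SNP panels (0/1/2 calls) from populations sampled along
environmental gradients:

- **QC** — technical-replicate error from bitwise distances (0.9%
  threshold), sequential filtering (locus call rate ≥ 0.67, individual
  call rate ≥ 0.25, reproducibility ≥ 0.99, depth 2–50, MAF ≥ 0.01),
  nearest-neighbour imputation. Clones are kept for outlier scans.
- **Environment** — warm-season daylight summaries of raw water-quality
  series, annual rates from monthly means, correlation (|r| > 0.7) and
  VIF pruning of predictors. The 13-meadow × 9-variable NSW table ships
  as `load_nsw_env_table()`.
- **Ancestry** — sparse-NMF admixture coefficients with held-out
  cross-entropy selection of K; binomially scaled genotype PCA.
- **Three GEA scans and consensus** — redundancy analysis (loadings
  beyond ±2.5 SD on constrained axes, permutation tests), a PCA outlier
  scan (robust Mahalanobis distances of K-dimensional z-scores,
  genomic-inflation calibration, q < 0.1), and a latent-factor ridge
  scan per predictor (K latent factors, GIF-calibrated z-scores,
  BH FDR 5% *and* raw p < 0.001). Candidates are loci flagged by ≥ 2
  of the 3 methods.
- **Turnover forests** — per-locus regression forests (500 trees) whose
  split importances, standardized by split-opportunity density and
  weighted by out-of-bag R², accumulate into monotone cumulative-
  importance curves per predictor: the allelic turnover function.
- **Zygosity mapping** — per-meadow proportions of reference
  homozygotes / heterozygotes / alternate homozygotes at candidate
  loci, ordered along any gradient.
- **Donor registry** — `projected = current + rate × years` (default
  +0.2 °C yr⁻¹ from 2024 to 2030/2040/2050) and donor = the meadow with
  the smallest current value ≥ the projection, plus a discrepancy
  report against a published registry grid.
- **Synthetic data** — Balding–Nichols demes with a tunable F_ST,
  planted logit-linear environmental clines, missingness, replicate
  pairs and clones, so every stage is testable with known truth.

## Worked example

The donor registry from the shipped NSW environment table:

```python
import geascan as g

env = g.load_nsw_env_table()          # 13 meadows x 9 variables
reg = g.build_registry(env)           # AvTemp & MaxTemp, +0.2/yr, 2030/40/50
print(reg.cell("Port Hacking", "MaxTemp", 2030))
```

```
meadow               Port Hacking
variable                  MaxTemp
current                     28.73
rate                          0.2
horizon                      2030
projected                   29.93
projected_display           29.93
donor                 Wallis Lake
```

Port Hacking's maximum summer temperature, 28.73 °C today, projects to
29.93 °C by 2030 at +0.2 °C yr⁻¹, and Wallis Lake (30.31 °C today) is
the coolest meadow already above that projection — the least-extreme
pre-adapted donor. By 2040 the projection reaches 31.93 °C, beyond any
meadow's current maximum, so the 2040 cell has no donor. Comparing the
full 78-cell grid with the published registry:

```
$ python analysis/08_registry.py
projections matching the published grid: 78/78
donor cells agreeing with the published grid: 69/78
published donors violating the >= rule: 8
  Port Stephens AvTemp 2030: printed Wallis Lake has current < projected 23.52
  ...
  Bermagui AvTemp 2040: printed Pittwater satisfies >= but Wallis Lake is the
  smallest sufficient donor
```

All 78 projected temperatures reproduce the published values exactly
after rounding; the 9 donor disagreements are cells where the published
grid departs from its own stated "contemporary adaptation ≥ projected
condition" rule, and the report pinpoints each one rather than silently
matching.

On the simulated study panel (13 meadows, 60 loci planted on the AvTemp
gradient at β = 2, 20% missing), the chained drivers print, among other
things:

```
consensus (>=2 methods): 59 loci; recovers 51/51 planted loci surviving QC
relative predictor importance:
AvTemp       37.5%
TurbRange    13.5%
...
mean zygosity composition per meadow, ordered by AvTemp:
                AvTemp  p_ref_hom  p_het  p_alt_hom
Bermagui         20.14      0.767  0.183      0.050
...
Port Hacking     24.82      0.059  0.172      0.769
```

— the two-of-three consensus recovers every planted locus, the planted
variable dominates the turnover importances, and alternate-homozygote
proportions rise monotonically along the planted gradient, the pattern a
stacked zygosity histogram visualises.

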