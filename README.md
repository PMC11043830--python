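# mossdiv

Multi-scale diversity analysis for hierarchical moss-community data from
paired herbivore-exclosure experiments.

Arctic goose grubbing disturbs the moss carpet of polygon-fen wetlands.
A long-running way to measure its effect is a paired design: fenced
exclosures (geese **absent**) next to open control plots (geese
**present**), sampled hierarchically — shoot counts of every moss
species in 2 × 2 cm **cells** (25 per quadrat) within 10 × 10 cm
**quadrats** (5 per plot) within **exclosure-scale plots** (10 pairs).
`mossdiv` implements the full analysis chain for such data, and a
synthetic generator that emulates the paired hierarchical design so the
whole pipeline is testable without any field data.

## What it computes

**Alpha diversity** per unit at each scale:

- richness *S* (species with abundance > 0);
- evenness (Smith & Wilson's E<sub>var</sub>):
  `E = 1 − (2/π)·arctan(V)` with `V` the population variance of
  `ln x_i` over the *S* present species;
- bias-corrected inverse Simpson `1/λ`,
  `λ = Σ n_i(n_i−1) / (T(T−1))` (undefined when `T < 2` or all species
  are singletons; undefined values propagate as missing, never as 0).

**Beta diversity** between units, as Bray–Curtis dissimilarity
partitioned (Baselga's abundance-based decomposition) into balanced
variation (turnover) and abundance gradients (nestedness). With
`A = Σ min(x_ij, x_ik)`, `B` and `C` the abundances unique to each unit:

```
β_BC  = (B + C) / (2A + B + C)
β_bal = min(B, C) / (A + min(B, C))
β_gra = |B − C| / (2A + B + C) · A / (A + min(B, C))
```

with `β_bal + β_gra = β_BC` exactly. Per-unit means are taken within
each unit's comparison group (cells within their quadrat, quadrats
within their plot, exclosure-scale plots within their treatment).

**SCBD** — species contributions to beta diversity,
`SCBD_i = SS_i / Σ SS`, each species' share of the among-unit sum of
squares of raw abundances.

**Interspecific association** — Schluter's variance-ratio test on
presence/absence (`VR = S_T² / δ_T²`, `W = VR·N`, two-sided chi-square
criterion with *N* df), and pairwise Spearman rank correlations of
abundance with Holm-adjusted p-values.

**Permutation inference** — PERMANOVA (pseudo-F on Bray–Curtis, label
permutations, optional strata) and a paired sign-flip contrast for
treatment effects on any per-unit statistic, respecting the paired
blocks. Growth-form summaries (acrocarp / pleurocarp / *Sphagnum*
relative abundance and richness) round out the reports.

## Worked example

```python
from mossdiv import (default_config, simulate_dataset, shoot_density,
                     alpha_by_scale, aggregate, per_unit_beta,
                     variance_ratio_test)

cfg = default_config()          # 10 pairs x 5 quadrats x 25 cells, 52 species
cfg.seed = 7
ds = simulate_dataset(cfg)

shoot_density(ds, "absence"), shoot_density(ds, "presence")
# (9.08, 15.24)  shoots/cm^2 — the configured 1.7x density contrast

alpha_by_scale(ds, scales=("quadrat",)).summary
#  treatment  n_units  S_mean   S_se  E_mean  inv_simpson_mean
#    absence       50   35.06  0.415   0.330             8.827
#   presence       50   46.06  0.335   0.388            17.612

per_unit_beta(aggregate(ds, "quadrat")).summary
#  treatment  beta_bc_mean  beta_bal_mean  beta_gra_mean
#    absence         0.401          0.391          0.010
#   presence         0.249          0.237          0.012

variance_ratio_test(aggregate(ds, "quadrat"), "absence")
# VR=1.41, W=70.30, N=50, verdict='positive'
```

The default synthetic treatment effects reproduce the qualitative
pattern of goose foraging: higher richness and evenness in presence,
lower dissimilarity (driven by the turnover component β_bal, which is
several times larger than β_gra), and a ~70% higher shoot density.

The same pipeline runs from the shell and writes CSV report tables plus
a JSON manifest:

```sh
mossdiv report --seed 7 --n-perm 999 --out results/
mossdiv simulate --seed 7 --out data/
mossdiv analyze --input data/abundance.csv --registry data/registry.csv \
    --scales cell,quadrat,exclosure --n-perm 999 --seed 7 --out results/
```

Given the same configuration and seed the outputs are byte-identical.

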