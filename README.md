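# nestarch

Multivariate phylogenetic comparative analysis of bird nest architecture.

Bird nests vary in where they are placed, how they are built and how they
attach to their substrate, and these traits do not evolve independently of
one another. `nestarch` treats nest architecture as a single multivariate
trait: five nominal nest traits (cavity vs non-cavity, structure, site,
attachment, binned nest height) are combined into a morphospace, and the
relative contributions of abiotic (climate) and biotic (vegetation,
predator diversity, island endemism) factors plus body mass to variation
in that morphospace are quantified with phylogenetic comparative methods.
It is written for researchers who have a species × nest-trait table, a
species × covariate table and a dated phylogeny, and want a reproducible,
testable version of this analysis — including a synthetic-data generator
with known ground truth for validating every stage.

## What it computes

1. **Trait recoding** — nest height becomes a nominal trait via the
   geometric mean of the recorded min/max heights, binned at 0 m (ground)
   and at the 10th/90th percentiles of the non-ground species; rare site
   states (ant nest, water body) are merged into vegetation and ground.
   The five traits carry 2 + 4 + 4 + 3 + 4 = 17 states.
2. **Morphospace** — Gower dissimilarity (for all-nominal traits, the
   proportion of mismatching traits, d(i,j) = m/5) followed by principal
   coordinates analysis; all axes with non-zero eigenvalues are retained
   (at most 17 − 5 = 12).
3. **Multivariate PGLS with RRPP** — the full morphospace **Y** is
   regressed on scaled-and-centred predictors under a Brownian-motion
   covariance **C** (whitening by C^(−1/2)), with sequential (type I)
   sums of squares, per-term marginal R² = SS_term/SS_total, and
   residual-randomization permutation (RRPP) p-values and Z effect sizes
   (standard deviate of log F in its permutation distribution).
4. **Regression scores and associations** — species' centred morphospace
   positions are projected onto each predictor's coefficient direction;
   a trait state is *strongly* associated when all of its species score
   on one side of zero, and shows a *tendency* when the interquartile
   range does.
5. **Phylogenetic signal** — multivariate Blomberg's K,
   K = [tr(E′E)/tr(E′C⁻¹E)] / [(tr C − n/Σ(C⁻¹))/(n − 1)],
   calibrated to 1 under Brownian motion, with a tip-shuffling
   permutation test.
6. **Univariate comparison arm** — each of the 17 trait-state indicators
   is fitted by phylogenetic logistic regression (Firth-bias-adjusted
   quasi-score estimator with tree-structured latent correlation), and
   sign congruence with the multivariate associations is tabulated.

## Worked example

Simulate a 128-species dataset in which vegetation availability (NDVI)
truly drives the cavity/non-cavity liability, then analyse it:

```sh
python - <<'PY'
from nestarch.synthetic_data import SimConfig
open("config.json", "w").write(
    SimConfig(seed=42, n_tips=128, coupling={"nest_type": {"ndvi": 1.5}}).to_json())
PY
nestarch simulate --config config.json --out data
nestarch analyze --traits data/traits.csv --covariates data/covariates.csv \
    --tree data/tree.nwk --out run --seed 7 --n-perm 999
nestarch report --out run
```

The report (abridged) reads:

```
## Morphospace
- retained axes: 12
- axis 1 variance share: 0.1966

## Multivariate phylogenetic regression

| term | R2 | Z | p |
|---|---|---|---|
| climate_pc1 | 0.0042 | -0.861 | 0.8150 |
| climate_pc2 | 0.0077 | 0.264 | 0.4160 |
| predator_diversity | 0.0104 | 0.836 | 0.1960 |
| island_endemic | 0.0126 | 1.236 | 0.0980 |
| ndvi | 0.0431 | 3.517 | 0.0010 |
| geo_mean_mass | 0.0051 | -0.552 | 0.7170 |

## Phylogenetic signal
- multivariate Blomberg's K = 0.3124, p = 0.001 (1000 iterations)
```

The planted NDVI effect is the only clearly significant term (marginal
R² = 0.043, permutation p = 0.001 — the floor for 999 permutations plus
the observed arrangement), every other predictor behaves like noise, and
the liability-threshold trait generation leaves the morphospace with
weak phylogenetic signal (K ≪ 1). The associations table in the full
report classifies each of the 17 trait states against each predictor;
the species-level projections behind it are in
`run/regression_scores.csv`.

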