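# isofoodweb

Bayesian stable-isotope analysis of how an invading apex predator restructures
a riverine food web. The package targets the classic two-part question of the
*trophic disruption hypothesis*: after an opportunistic predator (here, a
large invasive catfish) establishes, do resident species shift trophic
position (**displacement**), and do their diets become more variable
(**dispersion**)? It answers both from δ15N/δ13C measurements of consumers
(two resident predatory fishes, minnows, crayfish, and the invader) sampled
at river sites with and without the invader.

## What it computes

**Hierarchical isotope model.** For individual *i* of group *j* at site *k*,

```
SI_ijk ~ Normal(mu_ijk, sigma^2)
mu_ijk = alpha_j + beta1_j * length_ijk + beta2_j * invaded_k + gamma_k
gamma_k ~ Normal(0, tau^2)
```

fitted separately to baseline-adjusted δ15N (consumer δ15N minus the site's
algae mean — raw δ15N is not comparable across sites) and to δ13C, with
rstanarm-style auto-scaled weakly informative priors. Sampling is by a
blocked Gibbs scheme (the full location vector has a closed-form Gaussian
conditional; sigma and tau move by slice sampling), 3 chains × 1500
iterations, 750 burn-in, 2250 retained draws, split R-hat diagnostics.

**Trophic position.** `TP = δ15N_adjusted / 3.4 + 1` (trophic enrichment
factor 3.4 ‰ per level, algae at TP 1), evaluated on posterior predictions
for an *average-sized* individual so body-size differences between invaded
and non-invaded samples cannot masquerade as invasion effects. Directional
claims are posterior probabilities (PPR), e.g. P(TP non-invaded > TP
invaded), with > 0.85 the conventional "ecologically meaningful" bar.

**Isotopic niche.** Standard ellipse areas in (δ13C, δ15N) space — SEA =
π·√det(Σ), small-sample-corrected SEAc, and Bayesian SEAb from a conjugate
normal–inverse-Wishart posterior — plus ellipse overlap and the six Layman
point-cloud metrics (convex-hull area, δ13C/δ15N ranges, mean distance to
centroid, mean and SD of nearest-neighbour distance) with invaded vs
non-invaded percent change.

A seeded synthetic-data generator reproduces the study design (5 groups, 9
invaded + 4 non-invaded sites, survey sample sizes and length
distributions, site-varying baselines, inflated within-group covariance at
invaded sites), so the whole pipeline is testable with known ground truth.

## Worked example

```sh
python analysis/01_simulate.py      # synthetic tables -> results/data/
python analysis/03_trophic_position.py
```

prints (seed 1):

```
           group  invaded  length_tag  tp_mean  tp_lo  tp_hi  ppr_noninvaded_gt_invaded
 channel_catfish     True     average    2.443  2.342  2.541                      0.999
 channel_catfish    False     average    2.758  2.598  2.919                      0.999
flathead_catfish     True     average    3.377  3.282  3.474                        NaN
...
channel catfish: PPR(TP non-invaded > invaded) = 1.00 — ecologically meaningful (> 0.85)
```

The invader occupies the top trophic position (TP ≈ 3.4 for an average
730-mm fish); the resident channel catfish — the generative truth plants a
−1.05 ‰ invasion effect on its δ15N, about −0.31 trophic levels — is
displaced from TP 2.76 to 2.44 where the invader is present, and the PPR
flags the displacement as meaningful. `02_fit_models.py`, `04_niche_ellipses.py`
and `05_layman_metrics.py` produce the posterior summaries, ellipse areas
(SEAb roughly doubling at invaded sites under the default dispersion factor
2.5) and the Layman table with per-group average percent change.

The same pipeline runs from the shell:

```sh
isofoodweb simulate --seed 1 --out data/
isofoodweb qc --input data/consumers.csv
isofoodweb run --config cfg.yaml
```

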