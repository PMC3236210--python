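# biomespec

Tools for studying **biomic specialization** and its macroevolutionary
consequences in species assemblages scored over the ten Walter biome
classes (evergreen tropical rainforest I … tundra IX, with the savannah
II/III as its own class).

The package is aimed at macroecologists and comparative biologists who
want to test the *resource-use hypothesis* — the prediction that biome
specialists, being more exposed to vicariance when their biome
fragments during climatic cycles, speciate (and go extinct) faster than
biome generalists — on a clade with known geographic ranges and a
phylogeny.

## What it computes

**1. Biomic specialization index (BSI).** Species ranges are scored
against *climatic dominions* (sub-biome climatic regions). A species is
present in a biome when at least 15% of its range falls in that biome,
or when it covers at least 50% of one of the biome's dominions (both
comparisons inclusive); montane dominions count toward the biome whose
altitudinal vegetation belts they mirror. BSI is the number of biomes
occupied (1–10); species are stenobiomic (BSI = 1), semi-eurybiomic
(1 < BSI < 5) or extreme eurybiomic (BSI ≥ 5).

**2. Richness-constrained Monte Carlo nulls.** Are there more
specialists than chance predicts? Each null replicate places species in
biomes at random while holding each biome's observed species richness
`sp_b` fixed (biome *b* receives `sp_b` distinct species drawn
uniformly, independently across biomes). Observed BSI frequencies and
per-biome specialist proportions are compared with the replicate
distribution via inclusive empirical p-values. An exact oracle backs
the engine: per species the null BSI is Poisson-binomial over
`p_b = sp_b / N`, conditioned on occupying ≥ 1 biome, and the
probability that an occupant of biome *b* is a specialist is
`∏_{j≠b} (1 − p_j)`.

**3. Trait-dependent speciation.** Speciation rate λ(x) is a function
of BSI *x* (constant, linear, sigmoid or modal), extinction μ is
constant, and the trait evolves by Brownian diffusion σ² with optional
directional drift φ. The package provides the forward birth–death
simulator, a grid-based likelihood in the quantitative-state
speciation–extinction (QuaSSE) family, maximum-likelihood fitting,
random polytomy resolution, and AIC comparison (`AIC = 2n − 2 lnL`,
differences > 2 treated as meaningful) across a distribution of
resolved trees.

A synthetic-data module generates presence matrices with exact richness
marginals and a tunable specialist excess, overlap tables that code
back to a given matrix exactly, and trees from the trait-dependent
process — so the full pipeline is testable without any external data.

## Worked example

```python
from biomespec import (RichnessMarginals, SynthesisConfig, analytic_null_bsi,
                       generate_presence_matrix, run_null_analysis)

# a 197-species assemblage with per-biome richness
# (44, 93, 48, 35, 26, 44, 29, 45, 40, 10) and ~40% specialists
matrix = generate_presence_matrix(SynthesisConfig(seed=42))
res = run_null_analysis(matrix, n_reps=10_000, seed=1)

row = res.bsi_table.loc[1]
print(f"observed BSI=1: {row['observed_pct']:.1f}%")
print(f"null mean:      {row['null_mean']:.2f}%  (sd {row['null_sd']:.2f}, "
      f"range {row['null_min']:.1f}-{row['null_max']:.1f})")
print(f"p ({row['tail']} tail): {row['p_display']}")

an = analytic_null_bsi(RichnessMarginals((44, 93, 48, 35, 26, 44, 29, 45, 40, 10), 197))
print(f"analytic check: {an['bsi_pmf'][0] * 100:.2f}%")
```

prints

```
observed BSI=1: 39.6%
null mean:      27.44%  (sd 2.63, range 17.8-37.6)
p (upper tail): <0.001
analytic check: 27.48%
```

Four in ten species are single-biome specialists while random placement
with the same per-biome richness yields only ~27.5% — a specialist
excess far outside the null range, exactly the signature the
resource-use hypothesis predicts. The analytic Poisson-binomial value
confirms the Monte Carlo mean independently.

The same analyses are available from the shell:

```sh
biomespec synth matrix --seed 42 --out presence.csv
biomespec nulltest --matrix presence.csv --reps 10000 --seed 1
biomespec synth tree --shape sigmoid --lambda0 0.17 --lambda1 0.018 \
    --xmid 4.61 --tips 100 --seed 1
biomespec fit --tree synth.nwk --traits synth_traits.csv --shape sigmoid
biomespec pipeline --presence presence.csv --reps 10000 --seed 1 --out run/
```

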