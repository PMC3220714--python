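# patchdemog

Demographic analysis of small-mammal populations in fragmented landscapes:
how much does landscape-wide forest cover — as opposed to the size of the
individual forest patch — control population density, survival, growth, and
above all **immigration** into patches? The package is aimed at population
ecologists working with live-trapping data from patch networks, and it ships
a synthetic-data generator with known truth so every estimator can be
validated without access to field data.

It implements two linked analyses:

**1. Density versus patch area.** One count per surveyed patch (distinct
individuals caught on a standardized trap line) is confronted with eight
candidate models built from two component families — a constant
negative-binomial density (no area effect; var = μ + μ²/k) and a Poisson
density with log μ linear in log₁₀(patch area) — assigned globally or per
landscape class (50/30/10 % forest cover). Model log-likelihood is the sum
of independently fitted component log-likelihoods; ranking is by AICc, with
Δ ≤ 2 marking equally plausible models. The scientifically interesting
outcomes are the models that place an area effect only below a
habitat-amount threshold (D8: area effect at 30 % only; D6: at 30 % and 10 %).

**2. Robust-design capture–recapture and immigration.** Encounter histories
from T = 5 primary trapping sessions × K = 5 nights in 6 patches are fitted
with a joint likelihood: Huggins closed-capture conditional likelihood
within sessions (first-capture rate p, recapture rate c per night;
abundance derived as N̂ = M/p̂*, p* = 1 − (1−p)ᴷ) and an entry/exit open
process between sessions parameterised by apparent survival φ and
population rate of change λ (entry masses B₁ = 1, Bₜ = λᵗ⁻¹ − φλᵗ⁻²).
Nine structures vary φ and λ over constant / landscape-specific /
patch-specific (I1–I9; logit links for φ, p, c, log link for λ), are ranked
by AICc and model-averaged with Akaike weights and unconditional SEs. The
immigrant number per patch and interval is then

    Î = N̂_adult(t+1) − φ̂ · N̂(t)

with the adult abundances estimated from histories whose young-age captures
(aged by tooth eruption) were removed, and landscape means are compared
with an exact permutation test over the C(6,3) = 20 patch-to-landscape
assignments.

See `docs/methods.md` for model details, assumptions, defaults and
limitations.

## Worked example

Simulate a density survey from the default truth (constant NB mean 12.9 at
50 % cover, area effect with slope ≈ 0.9 per log₁₀ ha at 30 %, structural
absence at 10 %) and rank the candidate set:

```python
from patchdemog import synthetic_data as sd, density_models as dm

records = sd.simulate_density(sd.density_truth_study_default(), seed=7)
table, fits = dm.select(records)
print(table.round(2).to_string(index=False))
```

```
model  K  loglik   aicc  delta  weight
   D6  6 -107.86 229.68   0.00     0.5
   D8  6 -107.86 229.68   0.00     0.5
   D3  6 -118.02 250.00  20.32     0.0
   D4  6 -126.38 266.72  37.04     0.0
   D7  6 -126.38 266.72  37.04     0.0
   D5  6 -136.54 287.04  57.36     0.0
   D1  2 -151.87 308.00  78.32     0.0
   D2  2 -305.59 615.43 385.75     0.0
```

D8 and D6 tie at the top (Δ = 0): with every 10 %-landscape count zero, the
10 % component fits identically as a constant or as a boundary line, so the
two models that put the real area effect at 30 % are indistinguishable —
the same redundancy the threshold hypothesis predicts. The fitted top model
recovers the truth: slope 1.00 at 30 % (true 0.9), constant mean
e^2.625 ≈ 13.8 with k ≈ 2.2 at 50 % (true 12.9, k ≈ 2.1).

Demographic analysis of a simulated robust-design study (66 individuals,
landscape truth φ = 0.61/0.50, λ = 1.04/0.93), fitting four of the nine
structures and estimating immigration:

```python
from patchdemog import robust_design as rd, capture_data as cd, immigration as im

truth = sd.rd_truth_study_default()
_, data = sd.simulate_dataset(truth, seed=7)
structures = {k: v for k, v in rd.table1_structures().items()
              if k in ("I1", "I2", "I3", "I4")}
table, fits = rd.fit_all(data, structures, n_random_starts=1, seed=0)
avg = rd.model_average_demography(table, fits)

adults = cd.reduce_to_adults(data)
table_a, fits_a = rd.fit_all(adults, structures, n_random_starts=1, seed=0)
avg_a = rd.model_average_demography(table_a, fits_a)
series = im.immigration_series(avg, avg_a, dict(data.design.patches))
comparison = im.compare_landscapes(series)
```

```
model  K   loglik     aicc  delta  weight
   I3 23 -509.952 1092.190  0.000   0.510
   I1 22 -512.795 1093.125  0.935   0.320
   I2 24 -508.820 1094.909  2.718   0.131
   I4 23 -512.530 1097.346  5.155   0.039

patch_id  landscape  estimate   se  ci_low  ci_high   (model-averaged phi)
      p1         50      0.54 0.07    0.39     0.69
      p4         30      0.35 0.13    0.10     0.61

mean immigrants per interval: 1.85 (50 %) vs 0.38 (30 %)
observed difference 1.42, exact permutation p = 0.2 (20 arrangements)
```

The landscape-survival structure I3 ranks first and the model-averaged φ̂
separates the landscapes in the right direction; with only three patches
per landscape the permutation test cannot go below p = 0.1, which is the
honest resolution of a design this size. The same run from the command
line:

```bash
patchdemog simulate --seed 7 --out sim/
patchdemog fit-density --csv sim/density.csv --out out/
patchdemog fit-rd --csv sim/captures.csv --out out/ --structures I1,I2,I3,I4
```

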