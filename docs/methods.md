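# Methods

`patchdemog` implements a two-part demographic analysis for a forest
specialist in fragmented landscapes, with a synthetic-data generator that
provides known truth for every stage.

## 1. Density versus patch area

The first dataset is one count per surveyed patch (distinct individuals
captured under a standardized trapping line), with patch area in hectares
and a landscape class (50 / 30 / 10 % forest cover). Eight candidate models
combine two component families:

* **constant negative binomial** — counts NB-distributed around a constant
  mean (log-scale intercept plus a dispersion parameter k, var = mu +
  mu²/k), used where no patch-area effect is postulated, because constant
  components must absorb the full between-patch variance;
* **linear Poisson** — counts Poisson with log mean linear in log10(area).

D1 and D2 pool all three landscapes into a single global component; D3–D8
give each landscape its own component, placing the area effect in none, all,
or particular landscapes (D5: 50 % only; D6: 30 % and 10 %; D7: 50 % and
30 %; D8: 30 % only). A model's log-likelihood is the sum of its component
log-likelihoods, fitted independently (nothing is shared across components:
each constant component carries its own dispersion, each linear component
its own slope, which makes every model worth 2 parameters per component and
keeps K auditable: K = 2 for D1/D2, K = 6 for D3–D8). Poisson components are
fitted by GLM (log link, log10-area covariate); the NB mean MLE is the
sample mean exactly, and k maximises the profile likelihood by bounded 1-D
search on log k in [1e-6, 1e6]. Under-dispersed or degenerate samples push
k to the cap and are flagged as boundary fits (for Poisson-dispersed data
this happens in about half of samples — the 1/k MLE sits at its zero
boundary whenever the sample variance is at most the mean). All-zero counts
(structural absence) are represented as a boundary fit with log-likelihood
0. Models are ranked by AICc with n = number of patches; models with
n ≤ K + 1 are excluded with a warning. Δ ≤ 2 marks equally plausible models.

## 2. Robust-design capture–recapture

The second dataset is individual encounter histories from T = 5 primary
sessions of K = 5 secondary occasions in 6 patches (3 per landscape at 50 %
and 30 % cover), with each capture aged young/adult by tooth eruption.

**Within sessions (closed).** Detection follows a behavioural-response
model: probability p per occasion until the first capture of that session,
then c (the response resets between sessions; two trap types in the field
protocol make p ≠ c the default expectation). The Huggins conditional
likelihood divides each history's probability by p* = 1 − (1 − p)^K, so
abundance is not a likelihood parameter; it is derived afterwards as
N̂ = M_{t+1}/p̂* with delta-method variance
M(1 − p*)/p*² + (M/p*²)² var(p̂*) and a lognormal CI on f0 = N̂ − M_{t+1},
whose lower limit can never fall below the animals actually caught.
The within-session likelihood depends on the data only through sufficient
statistics (number caught, occasions before first capture, post-first
captures and misses), which makes evaluation cost independent of abundance.

**Between sessions (open).** Relative expected abundances E_t = λ^(t−1)
imply per-capita entry masses B_1 = 1, B_t = E_t − φ·E_{t−1}, normalised to
an entry distribution β. A collapsed history h (detected per session or
not) has probability summing over entry session b ≤ first(h) and last-alive
session d ≥ last(h) of β_b φ^(d−b) · exit(d) · Π_t p*_t^{h_t}(1−p*_t)^{1−h_t},
with exit(d) = (1 − φ) before the last session and survival-to-end at it,
all conditioned on being detected at least once. When λ < φ the raw entry
masses go negative; they are floored at zero and a smooth quadratic penalty
(weight 1e4 on the squared violation) is added to the negative
log-likelihood, so the optimiser is steered back without a hard constraint
failure. Probabilities are accumulated in linear space — with T = 5 each
term is a product of at most ~2T probabilities, far from underflow — with a
1e-300 floor before the final log.

**Joint fit.** The full log-likelihood is the sum over patches and sessions
of the Huggins terms plus the sum over patches of the open-process terms,
with each patch-session's p* computed from that patch-session's p. Nine
structures vary φ and λ over {constant, landscape-specific, patch-specific}
(I1–I9) while p and c are additive in patch and session on the logit scale;
λ uses a log link. With 6 patches and 5 sessions, K runs from 22 (I1) to 32
(I9). Optimisation is L-BFGS-B (gradient tolerance 1e-6) from a data-driven
null start (crude p from first-capture frequencies, φ = 0.5, λ = 1) plus
5 random perturbations (N(0, 0.5) on the link scale; seeded); the variance
matrix is the pseudo-inverse of the numerically differentiated observed
information, with SEs reported unavailable when it is singular. Structures
that fail to converge are dropped from selection tables with a warning.

AICc uses the total number of captured individuals as effective sample
size. Program-MARK-style analyses use a different (undocumented here) ESS
convention, so absolute AICc values are not comparable across software;
Δ, weights and K are. The reported deviance is −2·log L without a
saturated-model constant.

**Model averaging.** Estimates are averaged over structures with Akaike
weights; the unconditional SE is Σ w_i sqrt(var_i + (θ̂_i − θ̄)²).
Averaged abundances get the same lognormal-on-f0 CI with M_{t+1} as the
hard lower bound.

## 3. Immigrant numbers

For each patch and interval t → t+1 (t = 1..4),

    Î = N̂_adult(t+1) − φ̂ · N̂(t)

where N̂(t) and φ̂ come from the full histories and N̂_adult(t+1) from
histories with young captures removed. The adult reduction erases young-age
encounters and drops individuals never captured as adults; an animal first
caught young and later adult therefore keeps its adult captures — it was
born on the grid, and counting its adult reappearance as immigration would
inflate Î. (A stricter drop-ever-young mode removes such animals
entirely.) Young animals make the estimator consistent rather than biased:
in expectation N_adult(t+1) = φ·(adults_t + young_t) + immigrants, and
φ·N(t) subtracts exactly the survivors of both age classes. Negative
estimates are legal noise and kept by default; flooring at zero (available
as an option) biases interval means upward.

Landscape means are compared by an exact permutation test: each patch is
summarised by its mean Î over intervals, the statistic is the difference in
landscape means, and all C(6,3) = 20 patch-to-landscape assignments are
enumerated, so the p-value is exact and deterministic with a floor of 0.1
(2/20) at three patches per landscape. A mixed-model-with-MCMC comparison
of the field study's kind needs the original data and sampler; at this
design size the permutation test is the defensible equivalent, and its
resolution limit is stated rather than hidden. Designs too large to
enumerate (> 10⁴ arrangements) fall back to seeded Monte-Carlo permutation.

## 4. Synthetic data: what it emulates, and what not

**Density generator.** Per landscape, patch areas are log-uniform over the
surveyed ranges (3–145, 2–374, 6–106 ha; 15/20/15 patches) and counts
follow the component families above. The default truth is calibrated to the
study's landscape means — a constant NB with mean 12.9 and k matched to
SD 9.6 at 50 %, an area effect (slope 0.9 per log10 ha) at 30 % with the
intercept set so the *marginal* mean over the sampled areas is 8.9, and
structural absence at 10 %.

**Capture–recapture generator.** A latent roster is drawn first: initial
adults at session 1; adult immigrants and in-situ young arriving as Poisson
counts per interval (the minimal-assumption arrival model, which makes
truth recovery analytic); young mature after one interval; everyone
survives each interval with probability φ. The accounting identity
adults(t+1) = surviving adults(t) + matured young(t) + immigrants holds
exactly in every replicate. λ is emergent from (φ, immigration, birth)
rather than a dial: the stationary choice imm = (λ−φ)·N1 − φ·young places
realized growth at the target. Detection overlays the same
behavioural-response model the estimator assumes. The default study truth
uses φ = 0.61/0.50 and λ = 1.04/0.93 by landscape, initial abundances 3, 3,
8 / 2, 4, 5, one young recruit per interval per patch, and p = 0.35,
c = 0.5 per occasion.

Not emulated: spatially explicit movement (immigrants appear, they do not
travel), density dependence, time-varying survival or detection,
trap-level heterogeneity, and tag loss. Passing recovery tests therefore
demonstrates correctness of the estimators under the model's own
assumptions, not robustness to these violations.

## 5. Problem sizes and numerical choices

Recovery experiments use sizes at which the estimators' sampling error is
informative without being wasteful: detection-parameter recovery and
Huggins-abundance calibration run 100 replicates of 6 patches × 40
individuals (φ = 0.6, λ = 1, p = c = 0.4); the landscape-φ power experiment
(0.62 vs 0.50) runs 60 replicates at the same per-patch size, roughly ten
times the field study's captures; density model-structure recovery runs 100
replicates of the 50-patch default; immigrant-number recovery runs 100
replicates at the study's own abundance scale (equilibrium ≈ 7 adults per
patch, immigration 2 per interval, young 1 per interval, p = c = 0.6).
Experiments with homogeneous simulated detection fit constant-detection
structures (p(.), c(.)); the Table-1-style additive structures are
exercised wherever the parameter-count surface or the nine-model table is
itself the object under test. Where an expectation is checked, tolerances
are multiples of the Monte-Carlo standard error of the quantity under its
known truth; normalization oracles are exact (1e-8).

Known limitations: time-constant φ and λ within a structure (the candidate
set never varies them over time); no temporary-emigration parameters; no
overdispersion correction (QAICc); abundance SEs treat p̂* as the only
source of detection uncertainty within a session; and the permutation
test's resolution floor of p = 0.1 at three patches per landscape.
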