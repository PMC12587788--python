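# Methods

This note documents the statistical model behind `cieagree`, the defaults
and their rationale, the numerical choices, and what the synthetic-data
generator does and does not emulate.

## Scoring model

The CIBDAI is the sum of six ordinal items graded 0–3; the CCECAI adds
three more (albumin, ascites/peripheral edema, pruritus). The package
scores raw observations with the published bands, extended from the printed
integer anchors to real-valued inputs so that every mapper is total,
piecewise-constant and monotone:

| input | bands (score 0 / 1 / 2 / 3) |
|---|---|
| mean PSFS (1–7) | [1, 2.5) / [2.5, 4.5) / [4.5, 6.5) / [6.5, 7] |
| vomits per week | [0, 1) / [1, 2) / [2, 3] / (3, ∞) |
| stools per day | [0, 2) / [2, 3.5) / [3.5, 5.5) / [5.5, ∞); blood or mucus floors the score at 1, combined by maximum |
| weight loss % | exactly 0 / (0, 5) / [5, 10] / (10, ∞) |
| albumin g/L | [20, ∞) / [15, 20) / [12, 15) / (0, 12) (for a lower reference limit of 24 g/L) |

Interval edges between printed integer anchors sit at midpoints; the
printed decimal gaps in the albumin scale (e.g. 14.9–15) are closed with
half-open bands so coverage is continuous. Any sign flagged as a problem
for the animal carries a minimum score of 1; the floor can only raise a
score, never lower it. Weight loss of exactly 5 % is scored 2 (the "5–10 %"
band is read as closed at both ends, ">10 %" as strict).

Severity categories: totals 0–3 insignificant, 4–5 mild, 6–8 moderate,
≥ 9 severe, and ≥ 12 very severe for the CCECAI only. Treatment response is
a strict >50 % reduction of the baseline total or a final total ≤ 3; a zero
baseline is decided by the ≤ 3 branch alone, so no ratio is ever formed.

## Agreement statistics

**Lin's CCC.** For paired readings (x, y), ρ̂c = 2s_xy / (s_x² + s_y² +
(x̄ − ȳ)²). Moments use 1/n denominators (Lin's original estimator); a
sample-moment variant is available via `ddof=1` — the two differ only
through the weighting of the squared mean difference and converge at
moderate n. The confidence interval is built on the Fisher-z scale,
ẑ = atanh(ρ̂c), with Lin's asymptotic variance (using the later-corrected
coefficient on the location-shift term)

    var(ẑ) = 1/(n−2) · [ (1−r²)ρ̂c²/((1−ρ̂c²)r²)
                        + 2ρ̂c³(1−ρ̂c)u²/(r(1−ρ̂c²)²)
                        − ρ̂c⁴u⁴/(2r²(1−ρ̂c²)²) ]

where r is the Pearson correlation and u the standardized mean difference;
back-transforming keeps both bounds inside (−1, 1). The test suite checks
the analytic interval against a 2,000-replicate percentile bootstrap at
n = 50 (agreement within ±0.03 on each endpoint). Two constant, identical
reading sets have no defined CCC (the denominator vanishes); the analysis
layer reports such variables — typically ascites/edema, which is almost
always 0 — as "not assessable" instead of failing. A point estimate of
exactly ±1 has a degenerate Fisher-z interval; the CI is then undefined and
the dedicated function raises with guidance.

**Bland–Altman.** Differences are oriented first-minus-second: session T1
minus T2 for repeatability, first-listed observer minus second-listed for
reproducibility, so swapping sides negates the bias and mirrors the limits.
With d̄ the mean and s_d the sample SD (n−1 denominator) of the
differences:

* 95 % limits of agreement: d̄ ± 1.96·s_d (exactly 1.96, not a t quantile —
  this choice makes reconstructed published limits exactly symmetric about
  the bias);
* bias CI: d̄ ± t_{0.975, n−1}·s_d/√n (the t quantile, not a normal one,
  reproduces published bias CI bounds at n = 41 and n = 59 to the printed
  precision, which adjudicates the otherwise-unstated choice);
* LoA CIs: each limit ± t_{0.975, n−1}·s_d·√(1/n + 1.96²/(2(n−1))), the
  exact standard-error formula. Published LoA CI half-widths for comparable
  n are ≈ 0.015 wider than this formula (and than the √(3/n)
  approximation) produce; the source of that residual discrepancy is
  unknown and deliberately not imitated. The multiplier is configurable.

`bland_altman_from_summary(n, bias, sd)` rebuilds all intervals from
summary statistics, which is how published table rows (bias and one limit)
can be re-derived and fed to the verdict without raw readings.

**Composite verdict.** Concordant ⇔ CCC > 0.81 (strict, on the point
estimate — the rule is read literally rather than applied to the CI lower
bound) AND |bias| ≤ 1 AND both limits of agreement within ±1 (single items)
/ ±2 (index totals). Presets `relaxed_1` (±1.5, ±2.5) and `relaxed_2`
(±2, ±3) are provided; all failed criteria are enumerated as reason codes.

Missing values are handled by pairwise deletion per variable and per
comparison, with the effective n reported in every result row.

## Study analyses

One `ScoreRecord` per (form, observer, session) holds the item grades;
totals are always recomputed from items. Repeatability compares an
observer's T1 and T2 readings over shared forms; reproducibility compares
two observers at T1. Severity stratification assigns each form by its mean
index total over all available observer × session ratings: low < cutoff ≤
high, with defaults 5.5 (CIBDAI) and 7.0 (CCECAI). Ties at the cutoff go to
the high group — a documented convention, not an inference. A cutoff
outside the observed range produces a trivial split (one empty subgroup,
the other identical to the unstratified analysis); a non-empty subgroup
with fewer than 3 forms is an error. Multiple forms from the same dog are
treated as independent (they were completed by different staff without
access to each other); `dog_id` is retained for sensitivity analyses.

Within-subgroup CCCs are mechanically lower than whole-sample CCCs because
stratification restricts the latent range; results are reported as
computed, without correction.

## Sample-size design

n = ⌈1 + 2k(z_{1−α} + z_{power})² / ((k−1)(ln C₀)²)⌉ with
C₀ = (1 + kρ₀/(1−ρ₀))/(1 + kρ₁/(1−ρ₁)). α is one-sided by default: testing
ρ > ρ₀ is a one-sided hypothesis, and the one-sided reading reproduces the
canonical design value 40 at (ρ₀, ρ₁, k, power) = (0.81, 0.91, 2, 0.80)
where a two-sided α would give 50. The continuous solution is rounded up to
guarantee the nominal power.

## Synthetic-data generator

Observed item score for form f, observer o, session s, item i:

    y = clamp( round_half_up( λ_fi + β_oi + m_f·(δ_foi + ε_fosi) ), 0, 3 )

* λ_fi ~ Normal(μ_i, σ_i), with a fraction `severity_share` (default 0.25)
  of each item's variance carried by a per-form common severity factor —
  clinically, sicker dogs score high on many items at once; statistically,
  this sets the index-total spread without touching per-item moments.
* β_oi: fixed observer interpretation offsets.
* δ_foi ~ Normal(0, between_observer_sd), shared by both sessions — one
  observer's stable reading of one form; drives reproducibility.
* ε_fosi ~ Normal(0, within_observer_sd), fresh each session; drives
  repeatability. The marginal noise of a single reading is
  Normal(0, √(within² + between²)).
* m_f = 1 + c·T_f/9 with T_f the clamped latent CIBDAI total and
  c = `severity_noise_factor` (default 0): optional severity-dependent
  noise inflation emulating scoring getting harder in complex cases.

Rounding is half-up (floor(x + 0.5)); half-even rounding would
systematically distort item frequencies at the band edges. Identical
configuration and seed give a bitwise-identical dataset.

Pre-discretization moments are closed-form, so `theoretical_ccc` provides
an exact oracle: same-observer session pairs have CCC
(σ̄² + b²)/(σ̄² + b² + w²) with σ̄² the mean latent item variance.
`calibrate_noise` inverts that relation for the session SD by bisection.
Quantization usually attenuates the latent CCC slightly, but can also
*suppress* small noise (nearby readings snap to the same integer), so
discrete CCC is only bounded by latent CCC + 0.02 rather than strictly
below it.

**Presets.** `pilot`: 41 forms × 2 observers × 2 sessions. `phase2`:
59 forms × (2 experts + 2 non-experts) × 2 sessions. Default latent item
means (0.75, 0.75, 0.85, 1.30, 1.10, 0.85; extras 0.2, 0.0, 0.2), SDs 0.9
(extras 0.5), within/between noise 0.10/0.15 and observer biases
(0, +0.04, −0.06, +0.06) were chosen so the simulated study matches the
reported score distribution (CIBDAI totals mean ≈ 6, IQR ≈ 4–8, range well
inside 0–18) and the reported agreement pattern: repeatability
concordant with total-score CCC ≈ 0.95, reproducibility CCC ≈ 0.92 yet
mostly non-concordant because the limits of agreement exceed ±2. The
severity-heteroscedastic regression scenario uses the phase2 parameters
with `severity_noise_factor = 1.2` at 300 forms — the larger study makes
the subgroup contrast stable against sampling noise; at 59 forms the
low/high ordering of concordant counts varies between seeds.

**What the generator does not emulate.** Real per-item score histograms
(only total-score summaries are targeted), owner-report dynamics and
cyclically fluctuating signs, form free text, non-Gaussian latent tails,
and correlated forms from the same dog. Passing simulation-based tests
therefore demonstrates the correctness and internal consistency of the
statistical machinery under a plausible generative model, not the field
reliability of the indices themselves.

## Known limitations

* The raw observer scores behind the published agreement tables are not
  public, so published CCC/bias/LoA values can only be checked through
  internal relationships (LoA symmetry, CI reconstruction from n, bias and
  one limit), not recomputed from data.
* The CCC confidence interval is asymptotic; for n < ~15 or ρ̂c near ±1 a
  bootstrap is preferable.
* The composite verdict compares the CCC *point estimate* to 0.81; a
  CI-based rule would be more conservative and is easy to apply from the
  reported intervals.
* Item-level agreement on near-constant variables (ascites/edema) is
  reported as not assessable; no continuity correction is attempted.
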