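# Methods

This note records the models implemented in `berrymetrics`, the parameter
choices that matter, what the synthetic generator does and does not
emulate, and the numerical decisions a maintainer would want written down.

## Validation data and its quirks

The packaged fixtures hold the ten-bunch Flame-variety validation set: per
bunch the caliper-verified total berry count N_T, mean radius
r_mean,T ± σ (mm), and three views at 0°/120°/240° rotations about the
vertical bunch axis, each with the visible count N_i and the mean visible
radius in px; plus the detector's estimated counts for all 30 views,
stored as the raw published count together with the signed difference
against ground truth.

Two estimate cells are internally inconsistent (the raw count and the
signed difference disagree with each other given the reference count:
Bunch_06 view 3 and Bunch_08 view 2). The difference column is taken as
authoritative everywhere, because all aggregate statistics are computed
from errors; the raw count is retained in a provenance field and the rows
carry an `inconsistent` flag. Note the consequence: the difference-based
aggregates are ME = −44/30 = −1.467 and σ_E = 2.063, whereas the
conventionally quoted single-bunch law is (−1.57, 1.9); the two cannot be
reconciled from the printed data. Every downstream operation therefore
takes (ME, σ_E) as explicit inputs, and the extrapolation analyses use the
quoted (−1.57, 1.9).

Per-berry radii were never published — only per-view means — so
reference volumes computed from the fixtures use the mean-radius
approximation N·(4/3)πr̄³ and are flagged `approximation: mean-radius`.
By convexity of r³ this underestimates the per-berry sum; at the observed
radius spread (σ/r̄ ≈ 5%) the gap is ≈ 3(σ/r̄)² ≈ 0.7%.

## Error metrics

Errors are estimate − reference. Standard deviations use the K−1 sample
denominator (GUM type-A convention; the choice is stated because the
source tables do not fix it). Percentages are on the 0–100 scale.
On the packaged counts: ME = −1.467, MPE = −4.67% (rounds to −5%),
MAE = 58/30 = 1.933, σ_E = 2.063, MPE sd = 6.53%.

## Multi-bunch extrapolation

With independent per-bunch errors E ~ N(ME, σ_E²), a B-bunch image has
E_B ~ N(B·ME, B·σ_E²). The three expected metrics are computed in closed
form: ME^B = μ_B, MAE^B is the folded-normal mean, RMSE^B = √(μ_B² + σ_B²).
The *root* in RMSE^B is deliberate: the raw second moment ∫x²f dx is a
mean square (533.7 berries² for the 14-bunch configuration), and only its
square root (23.10) is comparable to a finite-sample RMSE; the quoted
multi-bunch tables print the rooted value. Φ is evaluated via `scipy`'s
`ndtr` (erf-based), never interpolation tables. B is restricted to
integers ≥ 1: fractional bunch counts have no meaning in the convolution
model.

An adaptive-quadrature oracle integrates x·f, |x|·f, x²·f directly
(domain truncated at μ ± 12σ, where the discarded normal mass is ~1e−32,
with a breakpoint at the |x| kink; tolerance 1e−10, non-convergence raises
rather than truncating silently). Closed form and quadrature agree to
1e−6 relative across (ME ∈ [−10,10], σ_E ∈ (0,10], B ≤ 50); a seeded
Monte Carlo over sums of B normal draws provides the third, simulation
route.

## Camera model

Weak perspective throughout: all berries of a bunch share one object
distance d, so r_px = r_mm·f/d and C_px−mm = d/f. Depth variation inside
a bunch is absorbed into σ_d. Defaults follow the validation set-up:
d = 500 ± 25 mm (half the vine thickness) and σ_f = 2 px. The focal
length itself has **no default** — the calibrated f of the validation
camera was never published, and silently assuming one would corrupt every
metric volume — so real-data entry points require it explicitly.
Annotation resolution enters as a type-B uniform uncertainty a/√3 with
a = 1 px (image) and a = 0.3 mm (caliper repeatability).

## Volume chain and the ratio R

R is the mean of per-image ratios V_b,mm / V_I,mm (not the ratio of
means), with σ_R their sample sd — images, not bunches, are the unit of
observation. The whole-bunch estimate is V_b,mm = V_I,px·C³·R. Units are
carried as tags (`px3`, `mm3`, `mm/px`) and mixing them raises, never
warns. The recovery experiment estimates R on a calibration subset
disjoint from the scored bunches (the bias the original all-data
calibration could not avoid), with the subset fraction exposed
(default 30%).

## Uncertainty budget

V_b,mm is a power product, so the linear GUM law gives
(σ_V/V)² = Σ p_i²(σ_i/x_i)², p = (+1, +3, −3, +1) on (V_I,px, d, f, R).
UPC_i = p_i²(σ_i/x_i)² / Σ_j p_j²(σ_j/x_j)² · 100 — a share of the
combined **variance**, the only definition under which the column sums to
100%. All sources are treated as independent normals; no covariances.
The uncertainty of the estimated visible volume is type-A style: the RMSE
of Ṽ_I,px against its per-berry references. The Monte Carlo oracle
(default 10⁶ samples, seeded) samples the sources and takes the empirical
sd; its UPC uses one-at-a-time resampling, which omits interaction
variance — exactly the quantity the linear budget also omits, making the
two comparable.

Linearization quality: the linear and MC budgets agree within 2% when
each source's *effective* relative contribution |p_i|σ_i/x_i stays below
5% (for cubed sources the bare σ/x must be three times smaller — the
linearization error grows with the contribution, not the bare sigma). At
the realistic σ_R/R ≈ 18% the linear combined sigma is ~3% low against
MC; this is documented, not asserted, and the MC value is the better
estimate there.

Compatibility uses k = 2 (≈95% coverage under normality):
|E_k| ≤ 2σ. A zero σ is accepted only with an exactly zero error (the
noiseless control).

## Synthetic generator

What it emulates: bunches of M ~ uniform{36..76} near-spherical berries
with radii from a truncated normal (9.5 ± 0.45 mm, truncated at 0),
packed by random sequential addition into a prolate ellipsoid envelope;
three views at 0°/120°/240°; occlusion by projected disc-union coverage;
and a detector whose count error is N(−1.57, 1.9²) berries (rounded,
floored at 0) and mean-radius error N(0.15, 1.5²) px.

Parameter choices, made once:

* **Envelope and packing.** Semi-axes auto-sized for a packing fraction
  of 0.35 at aspect ratio c/a = 1.4, with per-bunch uniform jitter
  (±0.07 on the fraction, ±0.35 on the aspect) because real bunches vary
  in compactness and elongation; that heterogeneity is what spreads the
  per-view ratio R between images. Berries may approach to 0.85 of their
  radius sum (they press together in a real bunch). Auto-sized envelopes
  relax by 5% and repack when random addition jams; explicitly supplied
  envelopes fail loudly instead.
* **Occlusion.** A berry is visible iff < 75% of its projected disc is
  covered by the union of strictly nearer discs, coverage estimated on a
  fixed 4-ring × 12-angle area-uniform polar grid (deterministic, so
  scenes are exactly reproducible from their seed). The 0.75 threshold
  and the packing defaults were calibrated to the validation data's
  observable statistics — per-view visible fractions N_i/N_T ≈ 0.5–0.8 —
  since no occlusion mechanism is observable directly.
* **Synthetic camera.** f = 1150 px at d = 500 mm, so a 9.5 mm berry
  images at ≈ 22 px, matching the annotated per-view mean radii
  (19–25 px). This default applies to synthetic scenes only.

What it does not emulate: stems, leaves and wires; non-spherical berries;
annotation error on the references; correlated count/radius detector
errors; lighting. Two consequences worth stating. First, the generator's
between-image spread of R (≈ 0.17) is about half the σ_R = 0.32 observed
on real annotated images — the missing share comes from annotation noise
and real shape complexity — so coverage results transfer to real data
only insofar as the budget's σ_R input is taken from real data, as it is
in the shipped budget analyses. Second, emulated count errors are
independent of the scene, whereas a real detector's errors correlate with
occlusion severity; the recovery experiment therefore validates the
propagation arithmetic, not the detector.

Distributional self-checks assert the emulator's empirical count-error
mean and sd over 10⁴ draws against the configured law within 3 standard
errors; the sd target is √(σ_E² + 1/12) — integer rounding adds the
Sheppard discretization variance, and pretending otherwise would test the
wrong distribution.

## Recovery experiment

For each scored view: emulate the detector, form
Ṽ_I,px = Ñ·(4/3)πr̃³, convert with C³ and the calibrated R̂, score
E_k = Ṽ_b,mm − V_b,mm against the generator's truth, attach the
four-source budget (σ_Ṽ from the calibration RMSE, σ_d = 25 mm,
σ_f = 2 px, σ_R from the calibration spread), and test k=2 compatibility.
The zero-noise control uses exact per-view ratios and per-berry reference
volumes and recovers every volume to machine precision — the pipeline
identity V_I,px·(d/f)³·R = V_b,mm holds exactly when its inputs do.
Default problem sizes: 200 bunches (≈ 420 scored views) for the noisy
run, 10⁴ draws for emulator checks, 2–4·10⁵ samples for MC budget
cross-checks — large enough that the 3-standard-error assertions have
sub-percent resolution, small enough to run comfortably on one core.

## Known limitations

* The published UPC column (22.1 / 0.3 / 32.6 / 45%) is not exactly
  reproducible: it depends on the unpublished nominal f, R and mean
  Ṽ_I,px. The budget analyses reproduce the procedure and the dominance
  ranking at stand-in nominals, not those four numbers.
* The quoted single-bunch law (−1.57, 1.9) vs the table-derived
  (−1.467, 2.063) discrepancy is left open; both are accepted as inputs.
* The mean-radius approximation biases reference volumes low by ~0.7% at
  the observed radius spread; with per-berry radii supplied the exact
  per-berry sums are used instead.
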