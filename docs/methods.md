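# Methods

## Generative model

Skin-conductance fluctuations are modeled as the output of a linear
time-invariant peripheral system driven by sudomotor-nerve (SN) bursts:
`SF = SN * SCRF`. An SN burst is a Gaussian bump in time with standard
deviation 0.3 s — the compact firing bursts seen in microneurography —
and the SCRF is the impulse response of a cascade of three first-order
lags with pairwise-distinct time constants `(τ1, τ2, τ3)`.

**Defaults:** `(0.3, 0.7, 3.07)` s. The slow pair mirrors the canonical
skin-conductance response function used throughout the field (a
bi-exponential with ≈0.7 s rise and ≈3.1 s decay constants); the fast
0.3 s stage rounds the foot of the response and makes the system third
order. The resulting response peaks ≈1.8 s after the driving burst and
recovers to half-peak ≈2.9 s later. The compactness of this waveform is
not cosmetic: it determines how much neighbouring fluctuations overlap,
and therefore where the greedy inversion starts to underestimate counts
(see "Behavior" below). Substantially slower constants make the method
underestimate already at moderate rates. All three constants are
overridable (`ScrfParams`, or `scrf.time_constants` in a YAML config).

**Calibration:** the gain is set (once, numerically, by golden-section
refinement of the peak) so a unit-amplitude burst produces a response
peaking at exactly 1 µS. Amplitude estimates are therefore in µS.

**Evaluation:** because the input is Gaussian and the poles are simple,
the response has a closed form — a sum of exponential × complementary-
error-function terms per pole, evaluated through `erfcx` with a switch
to the unscaled form deep in the tail to avoid overflow. Simulated
traces and dictionary atoms are exact samples of the continuous-time
response: linearity, time invariance and superposition hold to machine
precision, and no integration step size exists to tune. The price is
that repeated time constants are rejected (perturb one by a small
amount if needed); the rendered SN bump signal itself is truncated at
±4 SD (discarding < 1e-4 of its mass), while the closed form uses the
untruncated Gaussian — a discrepancy of the same 1e-4 order, far below
every tolerance used here.

## Inversion

The dictionary holds one atom per candidate onset, −9 s to +1 s around
the data window in 0.1 s steps, each the within-window response to a
unit burst; atoms with no within-window energy are dropped. Matching
pursuit then iterates: select the atom maximizing the *normalized*
signed inner product `⟨g, R⟩/‖g‖` (ties: earliest onset), apply the
optimal projection `a = ⟨g, R⟩/‖g‖²`, subtract. Normalization matters
near the window edges, where truncated atoms have smaller norms; the
`‖g‖²` scaling keeps `a` in SN-amplitude units and guarantees each
applied iteration strictly reduces the residual. A configuration switch
(`normalize_argmax=False`) reproduces the plain inner-product selection
rule instead; the projection formula for `a` is kept in both modes.

Stopping follows a post-test loop: after each pass, stop if
`‖R‖₂ < ε = √(0.001·N)`, then if 30 atoms per minute of data have been
selected (`ceil` for partial minutes), then if the best coefficient was
not positive (such a coefficient is never applied). Evaluating the
residual rule first means an all-zero trace reports `residual_below_eps`
with zero selections. Because the first pass always runs, a single small
fluctuation whose whole-trace norm is below ε is still detected — ε acts
as a "nothing further worth explaining" rule, not an input gate.

Numerical guard: a selection whose cosine with the residual is below
1e-7 would explain less than ~1e-14 of the residual variance — an
exact-arithmetic zero that floating point can render as a denormal
positive inner product. It is treated as nonpositive. Inner products are
computed as a dense matrix–vector product; this agrees with naive
summation to ≤1e-10 (asserted by the test oracles).

Amplitudes are then re-estimated jointly: ordinary least squares of the
data on the selected atoms, no intercept (the 0.0159 Hz high-pass has
removed the level; atoms model fluctuations, not baseline). Duplicate
selections collapse to one predictor; rank-deficient sets take the
minimum-norm solution and are flagged. Negative weights can arise for
heavily collinear sets; they are retained in the result but never
counted. The arousal estimate is the number of re-estimated amplitudes
at or above the threshold (default 0.1 µS, the value with maximal
predictive validity on training data) per minute.

**Threshold boundary.** A burst with amplitude exactly at the threshold
and an off-grid onset re-estimates a fraction of a percent *below* the
threshold (sub-grid misalignment attenuates the projection by ~3·10⁻⁴)
and is then, by definition, not counted. This is a property of
thresholded counting, not an estimation failure — the amplitude itself
is recovered within 1%.

## Simulator

Each trace is 60 s at 10 Hz (defaults). Inter-burst intervals are
exponential with mean `60/rate` seconds plus a 1 s refractory addition,
accumulated from the window start; the first onset is one interval from
t = 0. Amplitudes are uniform on [0.1, 2.0] SN units. Traces are
rendered noiselessly through the forward model: the benchmark isolates
inversion error from measurement error, so passing it says nothing
about robustness to recording noise, drift, or motion artifacts (none
of which are modeled). Corpora are built by sweeping target rates
1–30/min cyclically and binning each drawn sequence by its *realized*
burst count until every requested bin is full; a draw cap turns an
unreachable bin into an explicit error. One seeded generator drives
onsets then amplitudes per kept trace, making corpora bitwise
reproducible. Full-scale replication uses 1,000 traces per bin; the
shipped validation uses 100 per bin at true counts {2, 5, 10, 15, 20},
which bounds the whole benchmark to seconds while leaving Monte-Carlo
error on per-bin means well inside the ±10% band checked.

## Benchmarking and validity statistics

Estimated SF (the above-threshold set) are matched to true bursts
greedily: the globally smallest |Δt| pair first, each item used once,
until the short side is exhausted; ties break toward the earlier true,
then earlier estimated onset (the matching rule itself does not
prescribe a tie order; this convention is ours). Count RMSE is computed
per bin across traces; amplitude and onset RMSE over matched pairs
only.

Predictive validity: the GLM regresses the condition contrast on the
arousal estimates — intercept plus estimates, with subject dummies for
within-subject designs. This orientation makes RSS, and hence
`NLL = n·log(RSS/n)`, comparable across methods (same response
variable, same complexity); the t statistic of the arousal coefficient
is nevertheless identical to the closed-form paired or independent-
samples t test by partial-correlation symmetry, which the tests verify
to 1e-8. NLL comparisons across methods require identical n and raise
otherwise. |LBF| > 3 is flagged decisive (1/e³ ≤ .05). When the arousal
predictor is collinear with the nuisance columns (identical conditions
under subject effects) its association is zero by construction: t is
reported as 0 and the RSS is that of the nuisance-only model.

## Preprocessing

Causal (single-pass) Butterworth band-pass, realized as a cascaded
high-pass at 0.0159 Hz and low-pass at 5 Hz — cascading is numerically
safer than a single band-pass design across a three-decade cutoff
ratio. Default order 1 per section, matching the first-order analog
coupler this stage mirrors; the order is configurable, and a high
cutoff at or above Nyquist is clipped just below it with a warning.
Decimation to the 10 Hz analysis grid keeps every k-th sample, with the
5 Hz low-pass as the anti-alias stage; non-integer ratios are an error
directing the user to resample explicitly. Phase delay of the causal
filter is accepted and shifts all onsets alike.

## Behavior and known limitations

* **Count bias.** Counts track truth closely at low rates and
  underestimate as overlap grows: on the shipped benchmark, mean
  estimated counts are within ±10% of truth at 2, 5 and 10 bursts/min
  and fall clearly short at 20/min. The greedy search cannot revisit
  early, overlap-contaminated commitments (negative corrections are
  forbidden), so dense windows lose fluctuations. Above ~10 SF/min the
  estimates should be treated as lower bounds.
* **Heavy-tailed amplitude errors.** When the greedy pass selects two
  atoms 0.1 s apart around an off-grid burst, the regression may fit
  them as a large positive/negative pair (their difference approximates
  a sub-grid shift). Counting is unaffected — the negative partner is
  excluded — but matched-amplitude RMSE has heavy tails; medians are
  more informative for amplitude accuracy at higher rates.
* **Conduction delay** is a configurable constant subtraction (default
  0) applied only when reporting central SF-generation times; the
  peripheral model itself carries none.
* The dictionary assumes a *fixed, known* SCRF; no joint estimation of
  response-function parameters from data is attempted, and mismatch
  between the assumed and true SCRF translates directly into amplitude
  and count error.
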