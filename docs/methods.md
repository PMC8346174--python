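# Methods

## Scope and data model

The package analyzes uniformly sampled membrane-voltage recordings of
spontaneously beating cardiomyocytes, voltage-clamp step families, and
ratiometric Ca²⁺ signals. Times are seconds, voltages mV, durations at the
table layer ms, current densities pA/pF. Traces carry only a sample array, a
sampling rate and a start time, so grid jitter is zero by construction;
recordings read from disk are validated for grid uniformity and for header/
time-column consistency (0.1% tolerance on fs).

## Synthetic action potentials

The generator is deliberately phenomenological rather than an ionic ODE
model: the acceptance of every analysis stage rests on round trips against
ground truth, so each waveform parameter must be recoverable in closed form.

Each beat consists of four pieces:

1. **Upstroke** — a half-cosine of finite duration from the diastolic
   take-off level (8% of APA above the MDP) to the peak. Its maximal slope —
   attained exactly at the centre, which defines the activation time — equals
   `dvdt_max` by construction: duration T_u = (APA − takeoff)·π / (2·dV/dt_max).
2. **Repolarization** — four exponential segments pinned so that the
   crossings of the 20/50/90% levels occur exactly at `apd20/50/90` after the
   activation instant. Each segment's time constant has the closed form
   τ = Δt / ln(f_start/f_end). (An earlier design sketch used a single
   biexponential with a root-finder; the segmented form hits all three
   targets exactly without iteration and is monotone by construction, which
   also guarantees that an event-free diastole contains no local maxima.)
   After the 90% crossing the tail decays with τ ≤ 20 ms so the trace reaches
   the MDP within ~8 tail time constants — this is what makes the measured
   MDP equal the ground-truth value to <0.01 mV.
3. **Diastolic depolarization** — an exponential rise (time constant
   `diastolic_tau`, default 0.8 s) that is exactly zero until the tail has
   decayed and reaches the take-off level at the next upstroke onset, keeping
   the waveform continuous.
4. **Afterdepolarizations** — raised-cosine bumps of height
   `amplitude_fraction · APA` and width `width_ms`, centred `latency_ms`
   after (DAD) or before (EAD, negative latency) the 90%-repolarization
   crossing. Bumps that would overlap the next upstroke, or an EAD that would
   straddle the 90% crossing, are generator errors, not silent truncations.

Noise is additive white Gaussian (default SD 0.5 mV — recording noise of the
original experiments is not reported, so this is a stated choice, not a fit).
A fixed seed yields bit-identical traces.

Inter-beat intervals follow an AR(1)-plus-white model,
IBI_n = μ + L_n + W_n with L_n = φ·L_{n−1} + ε_n,
ε ~ N(0, σ_long²(1−φ²)), L₀ = 0, W ~ N(0, σ_short²), clipped below at 0.2·μ.
The white term loads the Poincaré short-term descriptor SD1 and the slow
AR(1) term the long-term descriptor SD2, so the interpretation of both
descriptors is testable by construction. Cohort presets use
σ_short = 2% and σ_long = 4% of the mean IBI with φ = 0.8.

Intervention sessions concatenate constant-rate segments (isoproterenol
ramp: per-segment rate = baseline × multiplier; a `cease` flag renders the
segment silent) or pacing trains (20 stimuli per frequency at 0.5/1/1.5/2 Hz,
each followed by a 20-s unpaced window in which spontaneous firing resumes).
Paced beats reuse the spontaneous morphology with APDs scaled down when the
pacing period requires it.

## Beat detection and AP features

Upstrokes are maxima of the Savitzky–Golay first derivative (polyorder 2,
default window 1 ms) above `dvdt_threshold` (default 2 V/s), separated by a
refractory period (default 0.25 s), and gated on a directional voltage rise:
the post-candidate maximum minus the pre-candidate minimum within ±50 ms must
exceed 20 mV. The directional gate is what rejects both derivative noise on
the falling phase-3 limb and afterdepolarization bumps (≤ ~10% APA) as beat
candidates. The first and last upstroke of a recording lack a bounding
diastolic minimum and are dropped.

Per beat: MDP_pre/MDP_post are the minima of the adjacent diastolic
intervals; APA = peak − MDP_pre (the dominant convention; the original
reports do not state theirs, so both minima are stored and `mdp_pre` is
reported); APDx is the time from the maximal-slope instant (sub-sample
refined by quadratic interpolation) to the first downward crossing of
peak − (x/100)·APA, linearly interpolated between samples. Beats whose
repolarization never reaches the 90% level are flagged unmeasurable and
excluded from APD statistics but still count toward the firing rate.
Firing rate = (number of complete IBIs / their sum) · 60.

On noiseless 5-kHz synthetic traces the round-trip errors are ≲0.04 ms for
the APDs, ≲0.02% for APA/MDP and ≲0.3% for dV/dt_max — far inside the 0.5 ms
/ 2% recovery tolerances asserted by the test suite. With 0.5 mV noise the
dV/dt_max and MDP estimates acquire small noise-driven biases (derivative
maximum and interval minimum are extreme-value statistics); binary event
verdicts are unaffected.

## Afterdepolarization scoring

Candidates are local maxima of the smoothed trace (Savitzky–Golay, 11 ms)
with prominence ≥ 1 mV, restricted to the interval from 10 ms after a beat's
peak to 30 ms before the next activation. Event amplitude is the maximum of a
lightly smoothed trace (5 ms) over ±10 ms around the candidate, measured
above a local baseline: the line through the medians of two 50-ms flanking
windows placed 30 ms on either side of the candidate, so a sloping diastolic
depolarization cancels to first order. Events with amplitude
≥ (3% − 0.05%)·APA of the preceding beat are kept; the 0.05%-of-APA guard
absorbs the sub-sample bias of the amplitude estimator so a bump generated
exactly at threshold is retained, while a 2.9%-of-APA bump is still rejected.
Classification: DAD after the host beat's 90%-repolarization crossing, EAD
between the AP peak and that crossing. On the curved phase-3 limb the linear
baseline under-shoots, so EAD amplitudes read high by a few percent of APA;
DAD amplitudes on the flat diastole are accurate to <0.5% relative.

"Arrhythmia" is flagged when any IBI exceeds twice the recording's median IBI
— a proxy chosen here (no quantitative definition exists in the
afterdepolarization framework) and reported separately from the DAD/EAD
flags. Cessation is any activation-free span longer than
max(10 s, 5 × median IBI), including a beat-free trace tail; both constants
are package choices. Chronotropy: positive when any drug condition's rate
strictly exceeds baseline (a 10⁻⁹ relative guard absorbs float jitter between
numerically identical rates). Post-pacing scoring classifies the 20-s window
after each train's last stimulus; 0.5-Hz trains are recorded but excluded
from the abnormality tally, since faster-firing control cells cannot be
captured at that rate.

## Beat-rate variability

COV = 100·SD/mean on the full IBI series (sample SD throughout). SD1/SD2 use
the standard difference-based Poincaré estimators: SD1² = Var(ΔIBI)/2 and
SD2² = 2·σ_pair² − SD1², where σ_pair² is the mean of the variances of the
two pair-cloud axes. With that dispersion the ellipse identity
SD1² + SD2² = 2σ² is exact at finite n, and both descriptors coincide exactly
with the SDs of the rotated pair coordinates (y−x)/√2 and (x+y)/√2; SD2 is
evaluated in the rotated form, which is algebraically identical and
numerically stable for near-alternating series (the difference form loses
all significant digits when SD2 → 0). Using the full-series SD instead of
σ_pair would perturb the identity at O(1/n). IBI extraction keeps intervals
whose starting beat lies within the analysis window (default 100 s).

## Voltage clamp

I_f density = (mean current over the final 100 ms of the 2-s pulse − mean
over the pre-step baseline window) / C_m, sign preserved (inward negative);
quantifying at pulse-end quasi-steady state was chosen because no
tail-current analysis is part of the protocol. No leak subtraction is
performed beyond baseline referencing (I_K1 block is an experimental, not
computational, step). I_Ca,L density = (minimum current during the 200-ms
step − baseline) / C_m. `build_iv` averages duplicate step voltages and
sorts by voltage; mixing protocols is an error.

The synthetic clamp model uses Boltzmann gates
a∞(V) = 1/(1+exp((V−V½)/k)) — k > 0 activates on hyperpolarization (HCN-like,
defaults V½ = −90 mV, k = 10 mV, E_rev = −20 mV, mono-exponential activation
τ = 0.3 s), k < 0 on depolarization (L-type, V½ = −10 mV, k = −6 mV,
E_rev = +60 mV, with a mild inactivation gate at +40 mV/10 mV and a fast-
activating, inactivating envelope). Because the envelope is voltage-
independent, the voltage of the peak measured density coincides exactly with
the argmin of the closed-form peak I(V) — the recovery check exploits this.
A least-squares Boltzmann fit (`fit_if_activation`, E_rev known) recovers
V½ and k of a noiseless family to machine precision; the 1 mV / 0.5 mV
tolerances in the tests are deliberately loose.

## Ca²⁺ transients and caffeine response

Transients are normalized double exponentials
(e^{−t/τ_decay} − e^{−t/τ_rise}), paced at `pacing_hz` (defaults 1 Hz,
τ_rise 30 ms, τ_decay 150 ms, amplitude 0.5 ratio units over baseline 1.0).
The caffeine transient uses amplitude factor × paced amplitude with its own
decay constant (default 1.5 s); pacing resumes so the first post-caffeine
transient peaks exactly `post_caffeine_pause` after the caffeine peak, making
the ground-truth recovery time trivially the pause. Peak value, peak time and
area (A·(τ_d−τ_r)/g_max) are closed form.

Measurement: peaks by prominence above a rolling local baseline (minimum over
a window of ~0.6 typical peak spacings); amplitude = peak − baseline; area =
trapezoidal integral above baseline from the 5%-rise onset to the 2%-decay
return. The truncation at the 2% return level removes the same *fraction* of
an exponential tail regardless of its time constant, so the percent area
change is unbiased to ~0.5% even though absolute areas are ~2% low. The
pre-caffeine reference is the mean of the last three paced transients (the
protocol does not specify n). "First transient" for recovery requires
amplitude ≥ 25% of the pre-caffeine amplitude (configurable); when no such
transient exists the recovery time is censored at the trace end and flagged.
Area is measured above the local baseline, not above zero — the alternative
reading of "area" would differ by baseline × duration and is not
scale-invariant.

## Cohort statistics

Outlier exclusion is a single pass per (group, metric): mean and sample SD
computed once on the full sample, values outside mean ± 2·SD removed,
boundary values kept, nothing removed when SD = 0. The rule is intentionally
not iterated; re-running it on the kept values can remove more points, and a
test documents this non-idempotence. Sample (n−1) SD was chosen (population
SD is the other defensible reading). SEM = SD/√n, undefined and flagged for
n = 1. Holm–Šidák: sort p ascending, adjusted₍ᵢ₎ = 1 − (1−p₍ᵢ₎)^(m−i+1),
running-maximum monotonicity, returned in input order; verified against
statsmodels on random inputs. Omnibus ANOVA is delegated to standard
packages and not reimplemented.

## File formats and CLI

Traces are plain delimited text with a `# key: value` header (fs, units,
kind, optional caffeine_time/pacing_hz/meta.*) — a deliberate choice over
vendor acquisition formats, for which a reader adapter can be added. Values
are written at full precision so round trips are bit-exact. Ground truth is
a JSON sidecar. Decimation (for MEA-style 1 kHz → 200 Hz down-sampling) is
polyphase FIR anti-aliased resampling with line-extension padding; a 10-Hz
sinusoid survives 1000 → 200 Hz decimation with <1% amplitude error.
The `cardiokit` CLI exposes simulate / features / afterdep / brv / iv /
calcium / cohort / demo as thin wrappers; `demo` is exactly
simulate + features + afterdep + brv + cohort on its own outputs, and every
table is reproducible bit-for-bit from the manifest's seed and config.

## Problem sizes used by the test and acceptance runs

Recovery tests run on 170-s traces at 5 kHz (the digitization range of such
recordings is 4–10 kHz; 5 kHz is the package default). The parameter-recovery
grid is 3 rates × 3 APD triplets × 3 amplitude/upstroke combinations; the
threshold-fidelity check uses 50 seeded 60-s noisy traces; the incidence
cohorts are 14 and 28 recordings of 170 s. The full suite runs in well under
a minute on one core.

## Known limitations

- The waveform family is phenomenological; it does not reproduce ionic
  mechanisms (no Na⁺ current, no stochastic gating, no rate-dependent APD
  adaptation within a trace), and noise is white, not 1/f.
- Quantitative I–V densities and BRV magnitudes of the patient lines exist
  only as figures in the original report, so the presets reproduce directions
  and rates, not exact curves.
- EAD amplitudes are over-read by a few percent of APA on strongly curved
  phase-3 baselines (the detection decision is unaffected).
- MDP and dV/dt_max acquire small extreme-value biases under noise; summary
  statistics on noisy recordings inherit them.
- The arrhythmia and cessation rules are package-defined proxies; results
  based on them should be reported as such alongside the paper-defined
  DAD/EAD criterion.
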