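# Methods

This note documents the models, the numerical choices and the synthetic
study conditions behind `fetalica`, and states what passing its tests does
and does not demonstrate about real recordings.

## Signal model

The observed abdominal recording is modelled as an instantaneous linear
mixture

    x(t) = A s(t) + b(t) + n(t)

with `x` the three observed channels, `s` the unobserved sources
(maternal ECG, fetal ECG, and optionally a residual interference
component), `A` a full-column-rank mixing matrix, `b` slow baseline
wander, and `n` white sensor noise. The sources are assumed mutually
statistically independent and non-Gaussian — the assumptions under which
independent component analysis identifies them up to permutation, sign
and scale. Those three indeterminacies are inherent: every consumer of the
separated sources (entropy-based channel selection, polarity orientation,
unit-variance fetal trace) is written so as not to depend on them.

## Preprocessing

Baseline wander is estimated per channel with a third-order Butterworth
low-pass at 5 Hz and subtracted. Two filtering modes exist:
zero-phase (forward–backward, the default — no group delay, so the
baseline estimate stays aligned with the signal inside each window) and
causal (for strict sample-by-sample streaming; it trades a group delay
for causality). Note a consequence of the 5 Hz cut-off: P- and T-wave
energy below 5 Hz is partly removed from the beats themselves. This is
intentional — the downstream stages only need the QRS complexes — but it
means the "clean" reference for preprocessing tests is the filtered clean
signal, not the raw one.

Centering subtracts the per-channel mean. Whitening diagonalises the
sample covariance (denominator `n − 1`) through its eigendecomposition,
`V = D^(−1/2) Eᵀ`; an eigenvalue below `1e-12 × trace` marks the window
as rank-deficient and raises a degenerate-input error that names the most
correlated channel pair. Preprocessing is applied independently to each
400-sample window; no filter state crosses window boundaries.

## FastICA

Non-Gaussianity is measured by the negentropy approximation
`J(y) ≈ (E[G(y)] − E[G(v)])²` with the quartic contrast `G(y) = y⁴/4`
(`v` is the standard-Gaussian reference; it appears only analytically).
Stationarity of the constrained optimum gives
`E{X g(wᵀX)} − βw = 0` with `g(y) = y³` and `β = E{wᵀX g(wᵀX)}`; a Newton
step with the near-diagonal Jacobian of whitened data reduces to the
simplified fixed-point update

    w ← E{X g(wᵀX)} − E{g′(wᵀX)} w ,

followed by renormalisation. All expectations are sample means over the
window's columns. The un-simplified damped Newton form is retained behind
`use_newton_form` purely as a cross-check; the two have identical fixed
points up to scaling, which the normalisation removes.

Choices the formulation leaves open, and what this package does:

* **Convergence** — `|1 − |w_{k+1}·w_k|| < tol`, default `1e-6`; the
  absolute dot product makes the test immune to the iteration's inherent
  sign alternation. `max_iter` = 200 per component. Apparent convergence
  is confirmed by 25 further iterations: when two sources have similar
  kurtosis the iterate can transit within tolerance of the symmetric
  saddle between their directions before escaping exponentially, and
  only a point that survives continued iteration is accepted (a saddle
  pass-through resumes the search from wherever the escape led).
* **Initialisation** — seeded standard-normal draws, renormalised; up to
  5 re-draws on non-convergence. A component that still fails is kept and
  flagged rather than raised, so a noisy streaming window degrades
  gracefully.
* **Multiple components** — deflation: each iterate is projected onto the
  orthogonal complement of the accepted unmixing vectors (valid because
  independent directions are orthogonal after whitening). Symmetric
  orthogonalisation is out of scope.
* **Streaming warm start** — the previous window's separation matrix
  seeds the next window's iteration (on by default in the pipeline). This
  reduces permutation flicker between windows; single-window calls
  default to cold start for reproducibility in isolation.

The number of components defaults to the number of channels (three).

## Sample entropy and channel selection

`SampEn(m, r, N) = −ln(ΣA/ΣB)` over the `N − m` template vectors, with
Chebyshev distance, matches counted as `d ≤ r`, and self-matches excluded.
Defaults `m = 2`, `r = 0.2 × SD` of the analysed window — the standard
convention for physiological series of a few hundred points; both are
configurable because entropy magnitudes (unlike their ordering) depend
strongly on them. Edge cases: no surviving `m+1` match returns `+inf`
(maximal irregularity is indistinguishable from "no evidence", so the
value is never used alone — selection compares channels); a constant
series has no meaningful tolerance and raises a degenerate-input error;
during selection a degenerate channel scores `−inf` so it can never win.
Exact ties break to the lowest index and are logged.

Why the fetal component has the largest SampEn: after separation each
unit-variance component carries sensor noise roughly inversely
proportional to its source's strength in the mixture. The fetal ECG is
2–10× the weakest, so its component has the largest noise fraction and
hence the greatest irregularity; the maternal component is cleaner; a
large smooth residual component is cleanest and most regular. This is a
property of noisy recordings — in a strictly noise-free simulation the
weak fetal source would be as regular as its clean template and the
ranking collapses. That is why the synthetic "clean recording" condition
below retains a small noise floor.

## Heart rate

The selected source is flipped, if necessary, so its largest-magnitude
sample is positive (idempotent). R-peaks are local maxima above
`0.6 × max(window)` separated by at least 0.2 s (the refractory period
admits rates up to 300 bpm; of two conflicting candidates the larger
survives). The per-window rate is `60 / mean(RR)`; fewer than two peaks
give an indeterminate result. The record-level estimate used in studies
is the **median** of per-window rates — robust against the occasional
window where a noise spike or a missed peak corrupts the mean RR. For
display smoothing the pipeline also reports an exponential moving average
(α = 0.3); the raw per-window values are always retained. The normal band
defaults to 110–160 bpm, bounds inclusive, configurable.

## Streaming protocol

Only the totals of the data package are externally fixed: 146 bytes
carrying 45 sample values, 15 per three-channel time point, with 24-bit
ADC counts. The internal layout (magic `0xA5 0x5A`, big-endian sequence
counter, count byte, channel-interleaved 3-byte two's-complement payload,
CRC-16/CCITT-FALSE over bytes 0–139, four reserved bytes) is this
package's own codec dialect, version 1 — self-consistent with every
published count, but making no claim of wire compatibility with any
particular firmware. Sample counts pass through unscaled by default (no
published calibration constant); a linear gain is configurable. The
window accumulator emits non-overlapping 400-sample windows (1.6 s at
250 Hz); a sequence discontinuity is logged and clears the partial
buffer rather than emitting a window with a hidden time gap.

## Synthetic generator and study conditions

Each heartbeat is a sum of five Gaussians (P, Q, R, S, T) whose centres
and widths are fixed fractions of the RR interval, so morphology scales
with heart rate and R-peak positions are exact by construction. Optional
Gaussian RR jitter exists but defaults to 0, keeping the peak ground
truth on an exact grid. Defaults: 250 Hz sampling, 10 s records, maternal
72 bpm, fetal 140 bpm (conventional resting rates), maternal-to-fetal
peak-amplitude ratio 5 (the middle of the physiological 2–10 range),
baseline wander 0.3 Hz at half the maternal peak amplitude, sensor noise
σ = 0.013 units — a few µV against a tens-of-µV fetal ECG, i.e. the noise
floor of a good acquisition front end. Amplitudes are in arbitrary units
(1 unit ≈ the maternal R amplitude, of the order of 10² µV on the
abdomen).

The optional third source — standing in for the residual "mixed"
abdominal component that appears when three channels are separated into
fetal, maternal and remainder — is a single smooth tone, centre frequency
drawn from 8–11 Hz (well above the 5 Hz baseline cut-off so it survives
preprocessing essentially intact) with peak amplitude 0.8 of the maternal
peak: strong and smooth, hence the lowest-entropy component, as the
irregularity mechanism above requires. Its instantaneous frequency
wanders slowly (σ = 0.2 Hz, ~2 s correlation time): a perfectly fixed
tone would occasionally sit on a harmonic of a beat train and be
genuinely correlated with that ECG source over long records — violating
the independence the mixture model assumes — while the wander de-coheres
it from any fixed harmonic yet leaves it effectively pure within one
1.6 s window. Mixing matrices default to random
maternal-dominant draws (maternal coefficients 0.6–1.0, others
0.25–0.75, condition number < 15), one per seed.

Two named study conditions are used by the validation runners and tests:

* **Default recording** (`SynthConfig()` defaults + residual source):
  sensor noise at the collector floor. Used for the entropy-ordering
  study. Under it the fetal component has maximal SampEn in ≈97% of
  windows, and the full ranking fetal > maternal > residual holds in
  ≈85% (the latter is tracked as a soft, logged property — the margins
  between maternal and residual depend on the mixing draw).
* **Clean recording** (`noise_sd = CLEAN_NOISE_SD = 0.003`, ~1.5% of the
  fetal peak): a high-quality recording. Used for the end-to-end
  heart-rate study. The noise is deliberately not zero — see the SampEn
  section; identification and ±2 bpm recovery both hold in ≥95% of
  records with margin.

Separation-accuracy studies use noise-free, baseline-free mixtures
(entropy plays no role there) on 150 s records: ICA estimation error
shrinks as `1/√n`, and at 150 s the kurtosis contrast — statistically
inefficient on strongly spiky sources — reaches correlation > 0.99 and
Amari index < 0.05 per record with comfortable margin. The Amari index
is evaluated on `W · V · A · diag(SD(s))`, i.e. with mixing columns
rescaled to unit-variance sources — the normalisation under which a
perfect separation is a scaled permutation; without it, sources of very
different physical amplitude make the index meaningless. Grid-search
cross-checks compare undeflated one-unit fixed points against exhaustive
kurtosis maxima (deflated rows are forced exactly orthogonal while
finite-sample optima are only approximately so, which would contaminate
the comparison).

### What the synthetic corpus does not emulate

Electrode-motion artifacts, uterine EMG, mains interference, non-
stationary mixing (fetal movement), heart-rate variability (by default),
twin pregnancies, and realistic ECG morphology beyond a Gaussian-bump
caricature. Passing the studies therefore demonstrates the correctness
and internal consistency of the algorithms under the stated model — not
clinical performance on real abdominal recordings, whose noise levels and
artifact structure are substantially harsher.

## Known limitations

* The threshold R-peak detector assumes the fetal QRS dominates the
  selected component; at realistic (sensor-floor) noise the fetal trace
  is noise-dominated and per-window rates are unreliable even when the
  channel is correctly identified. Matched filtering or maternal-beat
  suppression would be the next step and is out of scope.
* SampEn magnitudes depend on (m, r) and on window length; only the
  cross-channel ordering is treated as meaningful.
* The ST segment of the extracted fetal trace is not analysed.
* Processing-time accounting per window is diagnostic only; no real-time
  guarantee is made or asserted.
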