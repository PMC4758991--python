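# Methods

## Model

`petcrt` simulates the complete timing chain of a scintillation detector for
511 keV annihilation photons, from interaction to discriminator firing, for
three readout geometries: a photodetector on the entrance surface A
(mirrored rear face), on the rear surface B (mirrored entrance face), or on
both faces.

**Interaction.** Each annihilation photon deposits its full energy at a
single depth Z sampled from an exponential with attenuation length μ,
truncated to the crystal length L by inverse-transform sampling
(Z = −μ ln R, R uniform on [e^{−L/μ}, 1]). Compton/photoelectric structure,
energy spectra and multi-site events are out of scope.

**Light collection.** The fraction of light reaching the near surface falls
linearly with depth: f_A(Z) = a − (2a−1)Z/L, f_B = 1 − f_A. The sharing
fraction a subsumes surface finish and reflector properties; a = 0.7 is the
default (achievable with practical surface treatments, and a compromise
between far-end signal loss at a → 1 and loss of depth sensitivity at
a = 0.5). Expected photoelectron counts are N_pe·f; observed counts add
Gaussian noise with variance equal to the expectation — the model's stated
noise process, kept as such rather than replaced by Poisson sampling — then
are rounded to the nearest integer and clamped at zero, because a count
indexes discrete photoelectron generation. (Rounding/clamping is this
package's choice; at the yields of interest, ≥ hundreds of photoelectrons,
it is numerically irrelevant.)

**Photon transport timing.** A swarm of photons travelling a geometric path
s arrives no earlier than n·s/c after emission, with an exponential
dispersion tail of time constant D(s) = n·√(d1² + d2² s²). The constants
d1 = 0.00873 ns and d2 = 0.0186 ns/cm are inputs, obtained externally from
optical ray-tracing of a polished 3×3×30 mm crystal; the linear scaling
with refractive index n reflects that the photon paths are geometry-limited
while the transit time scales with the phase velocity. Per readout mode the
swarms are:

| mode | swarm | leading-edge offset | dispersion path |
|---|---|---|---|
| single-A | direct | Z/c + nZ/c | Z |
| single-A | reflected | Z/c + n(2L−Z)/c | 2L−Z |
| single-B | direct | Z/c + n(L−Z)/c | L−Z |
| single-B | reflected | Z/c + n(L+Z)/c | L+Z |
| double | detector A | Z/c + nZ/c | Z |
| double | detector B | Z/c + n(L−Z)/c | L−Z |

Each photoelectron time adds Exp(τ_r) + Exp(τ d) scintillation delays and
Gaussian photodetector jitter of fwhm J (σ = J/2.3548). The constant
photodetector transit delay is set to zero — it is common to all photons
and cancels in any CRT.

**Pulse and discrimination.** The photodetector output is the superposition
of one unit-area bi-exponential single-electron response (SER),
S(t) = [e^{−t/S_d} − e^{−t/S_r}]/(S_d − S_r), per photoelectron; amplitudes
are reported in SER-peak units (one photoelectron peaks at 1.0). Between
consecutive sorted photoelectron times the summed pulse is exactly
C·(u_j e^{−d/S_d} − v_j e^{−d/S_r}) with stable prefix recurrences for
u_j, v_j, so the pulse maximum is found analytically (each inter-arrival
segment is unimodal) and each trigger level's *first* crossing by bisection
on the segment's rising branch, to 1e−9 ns. This closed-form evaluation
replaces any tabulated-pulse approximation: there is no grid error, and the
first-crossing, shift-equivariance and ratio-invariance contracts hold to
floating-point precision (verified against a 0.0001 ns dense-grid oracle in
the tests). A tabulated SER (`physics.tabulate_ser`) is still provided for
inspection. Constant-fraction levels are referenced to each event's own
pulse maximum; leading-edge levels are absolute. First crossing is used
because a physical discriminator fires once.

**CRT statistics.** For each trigger level the CRT is
2.3548·√2·std(per-event times) (sample std, n−1 denominator; no outlier
trimming — skewed single-ended distributions are accepted as-is). The
optimum is the grid argmin over the trigger table (the minimum is shallow,
so no interpolation between levels; ties break to the lower level), and the
quoted standard error is CRT/√(2N_g). The default constant-fraction table
is 60 log-spaced fractions from 0.002 to 0.95 — dense enough (≈11% spacing)
that grid quantization is well below the statistical error at the shallow
minimum. The default leading-edge table is 60 log-spaced absolute levels
from 0.25 to 100 SER-peak units.

**Double-ended estimation.** The DOI estimate inverts the light-sharing
relation, Ẑ = (L/2)[1 − ((m_A−m_B)/(m_A+m_B))/(2a−1)], clamped to [0, L]
(physical delays are undefined outside the crystal; clamping also slightly
tightens the DOI resolution for shallow events, which is why the simulated
W_Z runs a few percent below the unclamped error-propagation closed form
2.3548·(L/2)/((2a−1)√N_pe)). A pulse-height-ratio variant (P_max ratios in
place of counts) is available as an option. A two-pass calibration run with
disjoint random streams, binned by *true* depth (what a laser scan of a
production crystal would provide), tabulates per depth band and trigger
level (1) the mean trigger delay δ = mean(T − Z/c − n·path/c) and (2) the
variance of the corrected entrance-time estimates. The measurement run then
uses only Ẑ: E_A = T_A − Ẑ/c − nẐ/c − δ_A(Ẑ), E_B likewise with the
(L−Ẑ) path, and combines them as a simple average and as the
inverse-variance weighted average E_WAB = (E_A/V_A + E_B/V_B)/(1/V_A+1/V_B).
Seven CRT summaries (W_DA, W_DB, W_DAB, W_EA, W_EB, W_EAB, W_WAB) and the
DOI resolution W_Z = 2.3548·std(Ẑ − Z) are reported.

## Numerical and design choices

- **Depth bands:** 15 uniform bands over [0, L], matching the granularity
  at which the dispersion model itself was characterized; δ and V are
  interpolated linearly between band centers with constant extrapolation
  beyond the end bands (the tables vary smoothly, and nearest-band lookup
  would add step artifacts). Doubling the band count changes W_WAB by less
  than one standard error (tested).
- **Calibration size:** defaults to the measurement event count; the
  calibration depth distribution is the same truncated exponential as the
  measurement (every band keeps hundreds of events at the defaults).
- **Exclusions:** an event with zero observed photoelectrons on a detector
  that must trigger has no defined pulse; such events are dropped and
  tallied (`n_events_excluded`). At realistic yields this never happens.
- **Random streams:** named, independent generators (depths, counts, photon
  times, jitter) spawned from one master seed; calibration uses a further
  keyed, disjoint family. Identical seeds reproduce results bit-exactly.
- **Direct/reflected dispersion in single-B mode:** the direct swarm
  (path L−Z) uses the L−Z dispersion constant and the reflected swarm
  (path L+Z) the L+Z constant, keeping the dispersion argument equal to the
  geometric path for every swarm.
- **Event counts:** the pipelines default to N_g = 100 000
  (SE ≈ CRT/447); the test suite and the acceptance script run reduced
  sizes (hundreds to tens of thousands of events, chosen per check so the
  quoted CRT/√(2N_g) error stays a few percent or below) and state the N
  used. Batches are internally chunked to bound memory at high N_pe.

## What the generator does and does not emulate

The synthetic events reproduce the statistical structure that limits PET
timing — exponential depth distribution, depth-dependent light sharing and
dispersion, counting noise, scintillation decay, SER pile-up and jitter.
They do not include Compton scatter or partial energy deposits, optical
ray-tracing (surface finish enters only through a, d1, d2), electronic
noise or digitization, or inter-crystal effects in arrays. Agreement with
published measured CRTs (short-crystal validation, 2 cm double-ended
comparison) therefore validates the timing model at full-energy photopeak
conditions, not a full detector system.

## Known limitations

- The statistical lower-bound analysis for the entrance-time estimate is
  not implemented; the package's weighted estimator is compared against its
  own simpler estimators only.
- The trigger-level table is a fixed grid; the reported optimum is a grid
  point, not an interpolated minimum (negligible at the shallow minima
  observed, but a caveat for very fast scintillators where the optimum
  shifts to large fractions).
- Gaussian count noise mis-models very small expected counts (< ~20); the
  clamp at zero is a pragmatic guard, and results at such yields should not
  be trusted.
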