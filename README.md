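# petcrt

Monte Carlo calculation of the coincidence resolving time (CRT) of
scintillation detector pairs for time-of-flight PET, with single-ended and
double-ended photodetector readout.

## What it computes, and for whom

In PET, two back-to-back 511 keV annihilation photons are detected in
coincidence; the precision of the measured arrival-time difference (the CRT,
quoted as a fwhm) sets how well time-of-flight information can localize the
annihilation point. `petcrt` is for detector physicists exploring how the CRT
depends on the scintillator (rise time τ_r, decay time τ_d, attenuation
length μ, refractive index n, photoelectron yield N_pe), the optical
transport inside the crystal, the photodetector (transit-time jitter J,
single-electron-response shape), and the readout/discrimination strategy.

The simulation chain per event k:

1. **Interaction depth** — Z_k = −μ ln(R_k) with R uniform on [e^{−L/μ}, 1]
   (exponential attenuation truncated to the crystal length L).
2. **Light sharing** — fractions f_A(Z) = a − (2a−1)Z/L and f_B = 1 − f_A of
   the N_pe photoelectrons reach the entrance (A) and rear (B) surfaces;
   observed counts add Gaussian noise of variance equal to the expectation.
3. **Photoelectron times** — each photoelectron arrives at
   T = Z/c + n·s/c + Exp(τ_r) + Exp(τ_d) + Exp(D(s)) + Gauss(0, J/2.3548),
   where s is the swarm's geometric path and D(s) = n·√(d1² + d2²s²) is the
   optical transport dispersion. Single-ended readout sees a direct swarm
   plus a swarm reflected off the opposite (mirrored) face.
4. **Pulse and trigger** — the photodetector pulse is a superposition of
   bi-exponential single-electron responses; a constant-fraction (or
   leading-edge) discriminator fires at the first crossing of each level in
   a trigger table.
5. **CRT** — W(F) = 2.3548 · √2 · std(trigger times) per level; the optimum
   over levels is reported, with standard error CRT/√(2N_g).

Double-ended readout additionally estimates the depth of interaction (DOI)
from the count (or pulse-height) ratio,
Ẑ = (L/2)[1 − ((m_A−m_B)/(m_A+m_B))/(2a−1)], corrects each trigger time for
the annihilation-photon, optical-photon and calibrated trigger delays, and
combines the two corrected entrance-time estimates by inverse-variance
weighting — which nearly eliminates depth-dependent timing spread. A TOF
sensitivity figure of merit FOM = 6.5·E²/CRT (unity for non-TOF whole-body
LSO at E = 0.6) compares scintillators.

## Worked example

```python
from petcrt import (ScintillatorSpec, OpticalTransportSpec, PhotodetectorSpec,
                    SimulationConfig, DoubleEndedRun, run_double_ended)

lso = ScintillatorSpec(attenuation_length_cm=1.2, refractive_index=1.82,
                       length_cm=3.0, rise_time_ns=0.0, decay_time_ns=37.0,
                       photoelectron_yield=4000)
run = DoubleEndedRun(lso, OpticalTransportSpec(),
                     PhotodetectorSpec(jitter_fwhm_ns=0.2),
                     sim=SimulationConfig(n_events=10_000, seed=11))
result = run_double_ended(run)   # calibrates, then measures
print(f"W_Z    = {result.w_z_fwhm_cm:.3f} cm fwhm")
print(f"W_DAB  = {result.w_dab.crt_at_optimum_ns:.4f} ns fwhm")
print(f"W_WAB  = {result.w_wab.crt_at_optimum_ns:.4f} ns fwhm "
      f"(F_opt = {result.w_wab.optimal_level:.4f})")
```

prints (about a half minute on one core)

```
W_Z    = 0.133 cm fwhm
W_DAB  = 0.1440 ns fwhm
W_WAB  = 0.1112 ns fwhm (F_opt = 0.0162)
```

i.e. for a 3×3×30 mm LSO crystal with 4000 photoelectrons and 0.2 ns-fwhm
photodetector jitter, the count ratio locates the interaction depth to
1.3 mm fwhm; averaging the two raw trigger times gives a 0.144 ns CRT, and
the fully corrected inverse-variance-weighted estimator improves it to
0.111 ns at a constant fraction of about 0.016 of the pulse height.

The same calculations are available from the shell:

```bash
petcrt single --config run.yaml --mode B --out wsb.csv
petcrt calibrate --config run.yaml --out calib.json
petcrt double --config run.yaml --calib calib.json --out crt.csv
petcrt table T3 --events 20000 --out table3.csv
petcrt fom 0.6 0.111
```

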