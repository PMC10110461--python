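# starss

Simulation and analysis of **selective time-resolved anisotropy with
reversibly switchable states** (STARSS): fluorescence-anisotropy
measurements that use the long-lived ON/OFF states of reversibly switchable
fluorescent proteins (rsFPs, e.g. rsEGFP2) instead of the nanosecond
fluorescence lifetime, extending the observable window for rotational
diffusion from nanoseconds out to milliseconds.  That window covers rigid
particles from roughly 5 nm to beyond 100 nm hydrodynamic diameter —
protein complexes, virus-like particles, chromatin domains — in aqueous or
cellular environments.

## Who this is for

Researchers who want to (i) design or sanity-check STARSS-style pulse
schemes before building them, (ii) fit measured polarization-resolved decay
curves and convert them into rotational correlation times and apparent
sizes, or (iii) test analysis pipelines against a controlled forward model
with known ground truth.  No instrument data are required: every input can
be generated by the package's synthetic-data machinery.

## The model

Molecules carry an orientation-dependent density per photo-state on the
unit sphere.  Polarized light drives transitions with the one-photon
photoselection law (rate ∝ (μ̂·ê)² for linear polarization, ∝ (1−μ̂_z²)/2
for circular), while rotational diffusion obeys the spherical Smoluchowski
equation, whose modes decay at l(l+1)·D_r.  Emission is projected onto two
orthogonal analyzers and the anisotropy is

    r = (I∥ − G·I⊥) / (I∥ + 2·G·I⊥),

after subtracting the cross-talk background measured at the end of the
OFF-switching reset, with G the detector-imbalance factor calibrated on an
isotropic sample.  A free sphere gives r(t) = r₀·exp(−t/τ_rot) with
r₀ ≤ 0.4 and τ_rot = 1/(6·D_r); the Stokes–Einstein–Debye relation
τ_rot = π·η·d³/(6·k_B·T) converts a fitted τ_rot into an apparent
hydrodynamic diameter d.

Three pulse schemes are implemented end to end:

1. **Scheme 1** — linear 405-nm pulse switches ~10% of molecules ON
   (cos²-photoselected); a circular 488-nm probe reads the decay of r(t).
2. **Scheme 2** — all molecules start ON; a linear 488-nm probe excites and
   OFF-switches simultaneously, so the anisotropy decays only when
   OFF-switching outcompetes rotation (~10× more photons per cycle).
3. **Scheme 3** — two delayed linear 405-nm pulses plus a circular readout;
   the delay-dependence of the total (polarization-summed) signal encodes
   rotation on 0.2–500 µs timescales.

## Worked example

Simulate a 60-nm bead measured with scheme 1 at a 10⁷-photon budget, then
fit the anisotropy decay and read off the size:

```python
import numpy as np
from starss import (EnvironmentParams, FluorophoreModel, Illumination,
                    RotorModel, SphereGrid, simulate_method1,
                    compute_anisotropy, fit_monoexponential)

env = EnvironmentParams(293.0, 1e-3)          # 293 K, 1 cP
fluor = FluorophoreModel.from_preset("rsEGFP2")
rotor = RotorModel.from_diameter(60e-9, env)  # tau_rot = 28.0 us
probe = Illumination(role="probe_488", polarization="circular",
                     power_density=100.0, duration=500e-6)

curve = simulate_method1(fluor, rotor, probe_488=probe,
                         grid=SphereGrid(32, 64), mode="poisson",
                         bin_width=1e-6, cycles=650_000_000, seed=1)
fit = fit_monoexponential(compute_anisotropy(curve), env)
print(f"tau = {fit.tau*1e6:.1f} us, d = {fit.diameter*1e9:.1f} nm "
      f"(95% CI {fit.diameter_ci95[0]*1e9:.1f}-{fit.diameter_ci95[1]*1e9:.1f})")
```

Output:

```
tau = 28.8 us, d = 60.6 nm (95% CI 60.3-60.8)
```

The true correlation time of a 60-nm sphere at these conditions is 28.0 µs;
the fitted decay recovers it within ~2% and the cube-root Stokes–Einstein
inversion turns the τ interval into a diameter interval.

The same pipeline is available from the shell:

```bash
starss simulate --scheme method1 --diameter-nm 60 --seed 1 --out run/
starss fit run/decay.csv --model monoexp
starss fixtures --scenario arc_like --seed 7 --out fixtures/
```

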