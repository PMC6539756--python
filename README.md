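# braggloc

Thermoacoustic Bragg-peak pulse simulation and TDOA acoustic source
localization for proton-therapy range monitoring studies.

A pulsed proton beam stopping in water deposits its energy in a sharply
peaked depth-dose profile (the Bragg curve). The rapid localized heating
launches a pressure wave that can be picked up by an array of acoustic
sensors, and the heating region can then be located from the arrival-time
differences. `braggloc` implements that full chain as a library plus CLI:

1. **`bragg_dose`** — analytical (Bortfeld-style) proton depth-dose model:
   power-law range-energy relation, linear nuclear fluence loss, Gaussian
   range straggling via parabolic cylinder functions.
2. **`thermoacoustic`** — voxelized heating field (depth curve × Gaussian
   beam cross-section × Gaussian time profile) and the Kirchhoff
   retarded-time integral giving the bipolar pressure pulse at a sensor.
3. **`tdoa`** — time-of-arrival estimation by (generalized)
   cross-correlation with optional PHAT/SCOT weighting, zero-phase
   band-pass prefiltering and parabolic sub-sample peak refinement.
4. **`localization`** — damped Gauss-Newton multilateration of the
   range-difference system with an analytic Jacobian; honest convergence
   reporting, least-squares handling of overdetermined arrays.
5. **`experiments`** — seeded study drivers: a four-sensor cube array
   (edge H, three fixed sources), an initial-guess convergence study, a
   full signal-level surrogate of a 12-sensor water-tank measurement, and
   a solver timing table.
6. **`io` / `cli`** — delimited-text and `.npz` readers/writers, run
   manifests, and the command-line interface.

## CLI

Every subcommand writes a JSON run manifest (parameters, seed, package
version, input digests) next to its outputs.

```bash
# depth-dose curve, 100 MeV, 3.4e6 protons
bragg-curve --energy-mev 100 --protons 3.4e6 --out curve.csv

# pressure waveform at a sensor 40 mm lateral of the Bragg peak
bragg-pressure --energy-mev 100 --pulse-us 1 --protons 3.4e6 \
    --sensor 0.04,0,0.0756 --out pulse.csv

# correlation delay between two stored waveforms
bragg-toa --emitted emitted.csv --received received.csv

# multilateration from a geometry table and reference-relative TDOAs
bragg-localize --geometry sensors.csv --units m --tdoa tdoas.csv --c 1492

# seeded studies (cube / tank / convergence / timing)
bragg-study cube --H 300,400,500,600,700 --repeats 20 --seed 42 --out results/
bragg-study tank --groups all --snr-db 20 --seed 42 --out results/
```

Geometry files are CSV with header `x,y,z` (units selectable via
`--units mm|cm|m`); waveforms are CSV (`t_s, ch0, ...`) or `.npz`.

## Conventions

* SI units (m, s, Pa, J) everywhere except `bragg_dose`, which uses
  cm/MeV internally to match the conventional model parameters.
* All physical constants live in `braggloc.constants`.
* Every source of randomness is an explicit integer seed; study results
  rerun bit-identically from their recorded configuration.
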