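# lovfret

Kinetic modelling and trace analysis for LOV2-based optogenetic actuators
read out by resonance energy transfer (RET).

A fluorescent protein fused next to a LOV2 photoswitch is quenched (donor
mode) or sensitized (acceptor mode) by RET with the flavin chromophore;
blue-light switching of LOV2 therefore modulates the tag's emission. This
package implements the quantitative machinery built on that readout:

- **`lovfret.units`** — photon-flux ↔ irradiance conversions from physical
  constants, photon-dose bookkeeping, and the 6th-power Förster arithmetic
  used to reason about spacer-mediated RET reduction.
- **`lovfret.photocycle`** — the two-state first-order reversible switching
  model (forward rate = flux/sensitivity, reverse rate = 1/relaxation time)
  and all closed-form trace equations: dequench/quench cycle traces,
  per-cycle exponentials, dark-recovery amplitudes, ED50 and apparent
  sensitivity.
- **`lovfret.adduct`** — adduct-state fraction simulator for arbitrary
  illumination trains (piecewise-exponential propagation, closed-form
  periodic steady state, an independent ODE oracle, and minimal-light
  protocol design by bisection).
- **`lovfret.fitting`** — shared-parameter nonlinear least-squares fits of
  normalized traces: control normalization, the two-stage
  per-cycle-exponential → dark-relaxation pipeline, the global
  four-parameter switch fit, the variable-dose reversible-kinetics fit,
  single-site dose-response fits, the extra-sum-of-squares F-test and
  Holm–Šidák step-down correction.
- **`lovfret.translocation`** — per-flash nuclear-export gradients,
  saturating dose-response analysis, and bidirectional kinase-reporter
  kinetics including the relaxing-inhibitor forward-rate variant.
- **`lovfret.synth`** — seeded generators for every input the pipeline
  consumes (cycle traces with matched bleaching controls, plate-reader
  recovery traces, translocation ratio series, reporter curves), so the
  whole analysis is testable at desk scale without imaging data.

## Test

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (printed-value
checks plus the property-based recovery/calibration harnesses).

## CLI

```sh
# unit conversion (irradiance ↔ photon flux)
lovfret units convert --from uW_cm2 --to umol_m2_s --wavelength-nm 465 60

# simulate adduct-state fraction under an illumination train
lovfret simulate --params params.json --train train.json --dt 0.05 --out trace.csv

# generate synthetic datasets, then fit them
lovfret generate cycles --seed 42 --out data/
lovfret fit-cycles --in data/cycles.csv --mode donor --out fit.json
lovfret fit-dose-series --in doses.csv --out fit.json
lovfret compare --restricted a.json --full b.json
lovfret translocation --in ratios.csv --fit dose-response
lovfret reporter --in jnkktr.csv --share-span --relaxing-kf --rho 120
```

Parameter JSON uses explicit unit suffixes
(`sensitivity_umol_m2`, `relaxation_s`, `transfer_limit_frac`, `mode`);
train JSON is either `{"periodic": {"dose_umol_m2", "flash_s", "period_s",
"count"}}` or `{"events": [[start_s, duration_s, flux], ...]}`.

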