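# ribotrace

Electropherogram analysis for mRNA purity, integrity and degradation
kinetics in lipid-nanoparticle (LNP) vaccine samples.

Microchip capillary gel electrophoresis (MCE) separates detergent-liberated,
formamide-denatured mRNA by size in ~70 s runs: a lower-marker internal
standard, a broad smear of unresolved degradation fragments, the intact
"main" peak (~2000 nt for a typical vaccine construct), and sometimes a
high-molecular-weight (HMW) species near twice the construct size caused by
incomplete denaturation. `ribotrace` turns such traces into the quality
attributes an analytical-development lab reports:

* **% main peak / % fragments / % HMW** — dropped-line region integration
  on the baseline-corrected signal; each region as a percentage of the
  marker-excluded total peak area. The % main peak is the sample's *purity*
  at release and its *integrity* on stability.
* **RNA size calibration** — ladder peak detection and a log-linear fit of
  migration time `t` against size `s`: `t = a + b·log10(s)`, inverted to
  report the size of the main and HMW peaks.
* **Assay qualification** — specificity on empty-LNP blanks, percent
  recovery of high/low-purity mixtures, %CV precision, linearity of total
  area vs concentration, and LOD/LOQ from signal-to-noise (S/N 3 and 10).
* **Degradation kinetics** — per-temperature first-order rate constants
  from `ln I(t)/I(0) = −k·t`, the Arrhenius activation energy from
  `ln k = ln A − Ea/(R·T)`, and shelf-life extrapolation under first-order
  or zero-order assumptions.

Because instrument data are proprietary in this field, the package ships a
first-class synthetic-data module that generates traces and whole
heat-stress stability studies with known ground truth (seeded, bit
reproducible), so every analysis stage is testable end to end.

## Worked example

```python
import ribotrace as rt
from ribotrace.calibration import detect_peaks, fit_ladder

# calibrate from a synthetic ladder injection
ladder = rt.LadderSpec()
lad_trace = rt.generate_ladder_trace(ladder, noise=rt.NoiseModel(seed=1))
baseline = rt.estimate_baseline(lad_trace)
cal = fit_ladder(detect_peaks(lad_trace, baseline), ladder)
print(f"migration slope: {cal.slope:.2f} s/decade")

# integrate a partially degraded sample
trace = rt.generate_trace(rt.SampleScenario(intact_fraction=0.8),
                          noise=rt.NoiseModel(seed=2))
res = rt.integrate_regions(trace, rt.estimate_baseline(trace), cal, 2000.0)
print(f"% main = {res.pct_main:.1f}, % fragments = {res.pct_fragments:.1f}, "
      f"% HMW = {res.pct_hmw:.1f}")
print(f"main peak size = {res.main_size_nt:.0f} nt")

# fit a whole stability study
study = rt.simulate_stability_study(rt.KineticTruth(), seed=3,
                                    noise=rt.NoiseModel())
frame = study.truth.rename(columns={"integrity_pct": "integrity"})
results = rt.DegradationStudy(frame).fit(mode="full-curve",
                                         weighted_arrhenius=False)
print(results.summary())
```

prints

```
migration slope: 23.30 s/decade
% main = 79.3, % fragments = 20.0, % HMW = 0.7
main peak size = 2000 nt
Degradation kinetics (first-order / Arrhenius)
======================================================
fit mode: full-curve

   T (C)      k (1/day)           SE    n  excl
   -20.0    5.39372e-05    8.916e-19    7     0
     4.0    1.17076e-03    5.542e-19    7     0
    25.0    1.15201e-02    1.986e-18    7     0
    37.0    3.70260e-02    4.240e-19    7     0
    45.0    7.67875e-02    6.703e-19    7     0
    60.0    2.74317e-01    1.199e-18    7     0

Ea  =    74.80 +/- 0.00 kJ/mol
lnA =   25.712 +/- 0.000 (A in 1/day)
R^2 (ln k vs 1/T) = 1.000000
```

The sample trace was generated with an 80% intact fraction and read back at
79.3% main peak — the small deficit is fragment-tail signal crossing the
dropped line, quantified in `docs/methods.md`. The kinetic fit here runs on
the study's noiseless ground-truth integrity curves, so the programmed
activation energy (74.8 kJ/mol) is recovered exactly with R² = 1; the
`ln k` regression standard errors are at machine-noise level (~1e-18) for
the same reason. With detector noise the per-temperature
rate constants acquire realistic uncertainties and the Arrhenius fit
weights them accordingly.

## Command line

```sh
ribotrace simulate --out-dir runs/demo --seed 7     # traces + sample sheet
ribotrace analyze  --sheet runs/demo/samples.csv --out runs/demo/results.csv --seed 7
ribotrace qualify  --results runs/demo/results.csv --sheet runs/demo/samples.csv --out runs/demo/qual.json
ribotrace kinetics --results runs/demo/results.csv --sheet runs/demo/samples.csv --out runs/demo/kin.json
ribotrace run      --out-dir runs/full --seed 7     # all of the above
```

Every command takes `--config` (YAML; see `examples/demo_config.yaml`) and
`--seed`; a run is reproducible byte-for-byte from those two alone.

## Layout

```
src/ribotrace/
  synthetic.py      trace + stability-study generator (ground truth)
  traceio.py        trace / sample-sheet / result-table IO, run reports
  calibration.py    peak detection, ladder fit, size mapping
  integration.py    baseline, dropped-line regions, % purity
  qualification.py  recovery, precision, linearity, LOD/LOQ, specificity
  kinetics.py       first-order fits, Arrhenius, shelf life
  pipeline.py       simulate -> analyze -> qualify / kinetics
  cli.py            click entry points
docs/methods.md     model assumptions, parameter choices, limitations
```
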