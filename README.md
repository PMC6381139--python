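# fpchar — in vivo fluorescent-protein characterisation

`fpchar` implements the analysis pipeline used to characterise
fluorescent proteins (FPs) *in vivo* in budding yeast: ratiometric
(practical) brightness against a co-expressed control FP, photobleaching
kinetics with exponential-decay fitting and BIC model selection, a
three-state kinetic model of photochromism, offset-Hill pH-quenching
analysis, and the secondary assays (OSER monomerism, flow-histogram
overlap, frequency-domain phase lifetime).  It is aimed at microscopy
and photophysics labs that want these quantifications as tested,
scriptable library code rather than ad-hoc spreadsheet or macro
analysis.

Because raw microscopy data are large and instrument-specific, the
package ships a first-class synthetic-data generator that emulates the
statistical structure of the assays (lognormal per-cell intensity
variation with day effects, bleaching traces driven by the kinetic model
under realistic exposure schedules, replicate titration curves,
zero-inflated whorl counts, disk-phantom images), so every stage is
testable end to end.

## The models

**Practical brightness.** Each FP is expressed stoichiometrically with a
control FP (T2A linkage).  Per cell, brightness is the ratio of
exposure-normalized mean intensities,
`(I_own / t_own) / (I_ctrl / t_ctrl)`, summarised as median with
quartiles; day-to-day variation is the CV of the daily mean ratio.

**Bleaching kinetics.** Normalized bleaching curves F(t) are fitted with

    F(t) = (1 − a) + a·e^(−t·r)                      (one-phase)
    F(t) = (1 − a − b) + a·e^(−t·r) + b·e^(−t·s)     (two-phase)

with rates in s⁻¹; the Bayesian information criterion
`n·ln(SSE/n) + k·ln n` (k = 2 or 4) picks the order, and half-times
`T½ = ln 2 / rate` are reported per component.  Photostability is
model-free: the normalized fluorescence of the last frame
(frame 181 / frame 1 under the default protocol).

**Photochromism.** The chromophore occupies a natural (fluorescent, N),
a reversible dark (D) or an irreversible dark (I) state.  Light drives
N↔D at channel-specific rates while that channel illuminates;
spontaneous N↔D exchange and the drain D→I act at all times.
Propagation over any constant-illumination interval is the exact matrix
exponential of the 3×3 rate matrix.  Traces from single-wavelength
(0.5 s interval, 0.2 s exposure, 181 frames) and dual-wavelength
alternating (3 s interval, own wavelength first) protocols are fitted
jointly; the photochromism score is 100× the largest deviation between
the dual-schedule prediction and the same prediction with the second
wavelength's light-driven rates ablated, and an FP is called
photochromic when the score exceeds 50.

**pH response.** Titration curves are normalized to the peak-fluorescence
pH and fitted with the offset sigmoid

    F(pH) = offset + (1 − offset) / (1 + 10^((pKa − pH)·hill)),

yielding pKa, Hill coefficient and the low-pH plateau; pH50 (the pH of an
absolute 50% drop) is `pKa − (1/hill)·log10(0.5/(0.5 − offset))`,
undefined when the offset is ≥ 0.5.

## Worked example

Characterise the default five-FP panel (generating values follow the
published in-vivo property table for the yeast-optimised palette):

```
$ fpchar report --seed 1 --out fpchar_run
characterised 5 FPs (seed 1) -> fpchar_run/report.csv
```

or run the numbered analysis scripts, which write their tables under
`results/`:

```
$ python analysis/01_simulate_panel.py --seed 1
$ python analysis/02_brightness.py
ymTq2: median ratio 2.351 (IQR 1.930-2.893, n=450), daily CV 0.064
ymNeongreen: median ratio 4.334 (IQR 3.544-5.393, n=450), daily CV 0.107
...
$ python analysis/05_ph_response.py
ymTq2: pKa 4.45, Hill 0.67, offset 0.00, pH50 4.45
ymScarletI: pKa 4.38, Hill 0.51, offset 0.17, pH50 4.04
...
```

Reading the output: ymTq2's median per-cell ratio of 2.35 means it is
2.35× brighter than the co-expressed mCherry control under these
simulated conditions (generating truth 2.24; the offset is sampling
noise at 450 cells).  Its fitted pKa of 4.45 against a generating 4.48
shows the Hill fit recovering the titration truth through replicate
noise; for ymScarletI the fitted offset (0.17) separates pH50 (4.04)
from the pKa (4.38), the signature of a low-pH fluorescence plateau.
`analysis/03_photostability.py` and `analysis/04_photochromism.py`
report photostability/half-times and the three-state fits with
photochromism scores (all five panel members are non-photochromic by
construction and classify accordingly).

The `fpchar` CLI exposes the same stages individually (`simulate`,
`brightness`, `bleach`, `photochrom`, `ph`, `oser`, `overlap`,
`report`); see `fpchar --help`.

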