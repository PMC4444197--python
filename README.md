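# ccsvsim

A desk-scale simulator and analysis toolkit for **Chest Compression
Synchronized Ventilation (CCSV)**, a pressure-controlled ventilator mode for
cardiopulmonary resuscitation that insufflates a short breath exactly at the
onset of every mechanical chest compression, and for the conventional
comparator, volume-controlled **Intermittent Positive Pressure Ventilation
(IPPV)**.

It is intended for respiratory-device engineers and resuscitation researchers
who want to study the mode's trigger/cycling logic, its synchronization
behavior against a compression device, and the nonparametric cross-over
statistics used in resuscitation ventilation studies — without animals or
hardware.

## What is modelled

**Lung mechanics.** A linear one-compartment model,

```
dV/dt = (P_aw − P_alv)/R,    P_alv = V/C + P_pl
```

with compliance `C` (default 25 ml/mbar), airway resistance `R`
(0.02 mbar·s/ml) and pleural pressure `P_pl` driven by a mechanical
compression device (default 100/min, trapezoid waveform, 15 mbar peak pleural
rise). During expiration the circuit is open to PEEP through an expiratory
valve resistance, so compressions produce a visible airway-pressure excursion
at the proximal sensor — the physical signal CCSV exploits.

**The CCSV inverse trigger.** An inspiration starts when three criteria hold
simultaneously:

1. airway pressure exceeds PEEP by the trigger level (0.9–3.7 mbar);
2. the pressure gradient is at least the threshold (25–375 mbar/s);
3. at least the minimum expiration time (200–340 ms) has elapsed.

The breath then commands the preset plateau pressure and cycles off after a
fixed inspiratory time. Presets: **A** = 60 mbar / 205 ms, **B** = 60 mbar /
265 ms, **C** = 45 mbar / 265 ms, all at PEEP 0.

**IPPV.** Constant-flow volume control: 7 ml/kg at 10 breaths/min, I:E 1:1.5
(2.4 s inspiration / 3.6 s expiration), passive exhalation, 60 mbar pressure
limit enforced by flow throttling.

**Protocol & statistics.** The five-period cross-over design (IPPV first and
last, the three CCSV presets randomized in between; 6 allocation orders,
balanced over a multiple of 6 subjects), plus the analysis pipeline:
nonparametric descriptives (median, quartiles, min/max), Friedman omnibus
test on within-subject ranks (chi-squared or permutation p), exact Wilcoxon
signed-rank post-hoc comparisons, and Bonferroni-Holm correction. A synthetic
generator produces per-animal cross-over tables with realistic magnitudes for
PaO₂, PaCO₂, pH, MAP, MAP−CVP and related variables.

## Worked example

```python
import numpy as np
import ccsvsim as c
import ccsvsim.breath_metrics as bm

res = c.simulate(c.CompressionProfile(), c.LungParams(),
                 c.CCSVPreset.named("B"), duration=60.0)
breaths = bm.detect_breaths(res.airway, res.flow, "CCSV", res.events)
sync = bm.sync_metrics(breaths, res.event_times("compression_onset"))
print(f"compressions: {len(res.event_times('compression_onset'))}")
print(f"insufflations: {len(breaths)}")
print(f"sync fraction: {sync.sync_fraction:.2f}")
print(f"trigger latency: {sync.latency_median:.0f} ms")
print(f"median peak paw: {np.median([b.peak_paw for b in breaths]):.0f} mbar")
print(f"median tidal volume: {np.median([b.tidal_volume for b in breaths]):.0f} ml")
```

prints

```
compressions: 100
insufflations: 100
sync fraction: 1.00
trigger latency: 5 ms
median peak paw: 60 mbar
median tidal volume: 232 ml
```

i.e. over one minute the mode delivers exactly one insufflation per
compression (100/min), each triggered a few milliseconds after the
compression onset, at the preset 60 mbar plateau, with a small tidal volume —
the defining behavior of compression-synchronized ventilation.

The same can be driven from the shell:

```sh
ccsvsim simulate --preset B --duration 60 --out run/     # trace.csv + metrics.json
ccsvsim protocol run --subjects 12 --seed 1 --out proto/ # full cross-over run
ccsvsim synth --n 12 --seed 7 --variable PaO2 --out pao2.csv
ccsvsim stats --input pao2.csv --variable PaO2
```

The `stats` command on the synthetic PaO₂ table above prints the per-treatment
descriptives, `Friedman chi2 = 29.133, df = 4, p = 7.345e-06`, and the
Holm-adjusted pairwise p-value triangle — the same report layout used for a
real per-animal spreadsheet ingested with `read_period_table`.

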