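# whiskvib

Flow-induced vibration analysis of pinniped whiskers (vibrissae), built as a
fully synthetic, testable re-implementation of a classic flume + micro-CT
study design.

Seal and sea lion whiskers are hydrodynamic sensors. When a whisker is towed
through water, vortex shedding in its wake drives vibrations of the shaft;
how strongly it vibrates depends on its cross-sectional shape and on the
**angle of attack** — 0° means the thin edge of the flattened cross-section
faces into the flow, 90° the broad face. The analysis chain this package
implements has four parts:

1. **Morphometry** (`whiskvib.morph`) — per-slice cross-sectional metrics of
   a CT whisker volume: area, maximum/minimum caliper (Feret) width by a
   0.5° rotating-projection sweep, principal-axis angle *θ* from second
   image moments, eccentricity *e* = √(1 − (min/max)²), and crest/trough
   detection along undulated shafts.
2. **Spectra** (`whiskvib.spectra`) — averaged-FFT analysis of
   laser-vibrometer velocity recordings (1200 Hz, 6 s), 240-point segments
   (5 Hz bins), amplitude-calibrated so an on-bin tone of amplitude *A*
   reads *A*; peak frequency/velocity extraction with optional exclusion of
   the low-frequency sting-mount artifact band.
3. **Theory** (`whiskvib.theory`) — empirical vortex-shedding model:
   Re = U·d/ν, St(Re) = 0.212 − 4.5/Re (laminar, 50 ≤ Re ≤ 150) or
   0.212 − 2.7/Re (turbulent, 300 ≤ Re ≤ 2000) with a linear blend in
   between, and f = St·U/d for the stream-wise diameter d at each angle.
4. **Stats** (`whiskvib.stats`) — mixed-design two-factor repeated-measures
   ANOVA (species between subjects, angle within), Tukey HSD within each
   species, length regressions, and group summaries.

Because no real scans or recordings ship with the package, a first-class
generator module (`whiskvib.synth`) produces every input with known ground
truth: voxelized whisker phantoms (smooth or undulated archetypes),
composite velocity recordings (shedding tone + 15 Hz sting artifact +
noise), and multi-subject species×angle study tables. The pipeline module
ties it all together **closed-loop**: recording tones are set to the theory
predictions derived from the phantoms' own measured geometry, so the whole
chain can be checked for self-consistency.

## Worked example

```python
from whiskvib.theory import FlowConditions, shedding_frequency

flow = FlowConditions()          # 0.5 m/s, fresh water (nu = 1e-6 m^2/s)
for d in (0.45e-3, 1.0e-3):      # thin edge vs broad face, metres
    p = shedding_frequency(flow, d)
    print(f"d={d*1000:.2f} mm  Re={p.Re:.0f}  St={p.St:.4f}  "
          f"f={p.f:.1f} Hz  [{p.regime}]")
```

```
d=0.45 mm  Re=225  St=0.1960  f=217.8 Hz  [transition_blend]
d=1.00 mm  Re=500  St=0.2066  f=103.3 Hz  [turbulent_fit]
```

A whisker presents its ~0.45 mm thin edge at 0° and its ~1 mm broad face at
90°, so rotating from 0° to 90° roughly halves the predicted vibration
frequency — the study's headline frequency ordering.

Running the full synthetic study:

```python
from whiskvib.pipeline import StudyConfig, run_study

report = run_study(StudyConfig(seed=42), out_dir="study_out")
print(report.summaries["peak_freq_hz"][["species", "angle_deg", "mean"]])
```

```
            species  angle_deg       mean
california_sea_lion          0 214.375000
california_sea_lion         45 175.000000
california_sea_lion         90 141.250000
      elephant_seal          0 225.625000
      elephant_seal         45 182.500000
      elephant_seal         90 139.375000
        harbor_seal          0 215.833333
        harbor_seal         45 180.000000
        harbor_seal         90 134.166667
```

Measured peak frequency falls monotonically from 0° to 90° in every species;
the ANOVA angle effect is enormous (F(2, 38) ≈ 1362, p ≈ 4e-36 at this
seed), and because the study is closed-loop the measured group means sit
within a few percent of the theoretical predictions
(`report.percent_diff`). Peak velocity shows the opposite trend, rising
from 0° to 90°. The same stages are available from the shell via
`whiskvib simulate|morph|spectra|theory|stats|run-study`.

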