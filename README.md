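# spiralflow

Simulation and analysis tools for **spiral-space optic-flow psychophysics
with cortical microstimulation** — the experimental logic in which weak
electrical stimulation of direction-tuned multiunit (MU) sites in area MSTd
is read out through a monkey's four-alternative forced-choice (4-AFC)
reports of optic-flow pattern (roll rotation vs. lateral translation) and
direction (CW/CCW or leftward/rightward).

The package is aimed at systems/computational neuroscientists who want to

* model the stimulus: a 3D star cloud advected by camera motion, with
  per-frame Bernoulli coherence, and the idealized screen-plane velocity
  templates of the spiral space (expansion ↔ rotation, expansion ↔ laminar
  flow);
* quantify MU tuning: ANOVA cell-type classification, the 3D resultant
  vector and **spiral index** `SI = (cos α − cos β)/(cos α + cos β)` (α, β
  the angles of the resultant to the translation and roll planes; −1 = pure
  roll preference, +1 = pure translation), `d′` and ROC discriminability
  between a plane's poles, depth-wise clustering (Pearson r), and the
  receptive-field flow-similarity index;
* generate behavior from an explicit two-stage **labeled-line decision
  model** — axis evidence `d_R = x_R + δ_R·1[stim] + ε_R` (likewise `d_T`),
  pattern arbitration by `|d_R| − |d_T|`, direction by sign — with the three
  microstimulation variants (within one pattern; within both; plus a bias
  *between* patterns);
* analyze sessions the way the experiment is analyzed: the normal /
  general-error / flow-pattern psychometric constructions, binomial-ML
  cumulative-Gaussian fits `p(x) = Φ((x−μ)/σ)` (PSE μ, threshold σ = the
  84%-correct offset), probit regression for stimulation-induced PSE and
  slope changes, signed and threshold-normalized ΔPSE, the choice-change
  index `CCI = (Choice_stim − Choice_nonstim)/Choice_nonstim` on ambiguous
  conditions, and correct-rate changes.

## Worked example

`examples/04_psychometric_fit.py` simulates one fine-version 4-AFC session
(15 reps × 17 conditions, stimulation on half of trials, a 0.75° labeled-line
offset on the roll axis) and analyzes the roll task:

```
ctrl: PSE = +0.22 deg, threshold = 1.36 deg
stim: PSE = -0.79 deg, threshold = 1.62 deg
probit: p(PSE shift) = 0.0407, p(slope change) = 0.563
dPSE raw = +1.02 deg, signed = +1.02 deg, normalized = +0.75 (thresholds)
```

Reading: under stimulation the point of subjective equality moved ~1° toward
the stimulated site's anti-preferred side of the axis — i.e. choices moved
toward its preferred direction — an effect of ~0.75 control thresholds that
the probit regression calls significant for the PSE term but not the slope.

The other examples cover the stimulus generator (`01`), tuning statistics
(`02`), session simulation and the psychometric constructions (`03`), a
population-level pipeline run (`05`), and the signatures separating the
three microstimulation model variants (`06`). A thin CLI wraps the pipeline:

```bash
spiralflow simulate --seed 1 --sessions 8 --out run/
spiralflow analyze --run-dir run/
spiralflow recover --seed 1 --out recovery/
```

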