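# Methods

## The spiral space and its stimuli

Optic-flow stimuli are points in a 3D "spiral space" spanned by two
orthogonal planes that share the forward/backward radial axis. Within the
**roll plane** an angle θ_R mixes forward motion with self-rotation about
the line of sight (θ_R = 0 is pure expansion, ±90° pure CW/CCW rotation);
within the **translation plane** θ_T mixes forward with lateral self-motion
(±90° pure leftward/rightward laminar flow). Sign conventions throughout:
positive θ_R = CW as seen by the observer, positive θ_T = leftward screen
flow; screen coordinates are degrees of visual angle with the fovea at the
origin, +x rightward, +y up.

`flowfield` implements the stimulus at two levels of idealization:

* a **3D star cloud** (default 100 × 100 × 40 cm at 0.01 dots/cm³ = 4,000
  dots, viewed from 32 cm, ~90° × 90°) advected by the camera-motion rule
  for (plane, θ). Coherence is an independent per-dot, per-frame Bernoulli
  draw: a `coherence` fraction moves coherently, the rest are re-drawn
  uniformly in the volume. Dots that exit under coherent motion re-enter
  through the opposite face (periodic wrap), which keeps density exactly
  stationary; the alternative (uniform re-seeding on the entry face) differs
  only in the within-face position distribution and neither choice is
  constrained by the task design.
* **first-order screen velocity templates**
  `v(p) = cos θ · radial(p) + sin θ · secondary(p)`, with `radial(p) = s·p`
  (speed grows linearly with eccentricity; `s` = speed at 1° eccentricity),
  `secondary` = the rigid CW tangential field `s·(y, −x)` in the roll plane
  or the uniform leftward field `s·(−1, 0)` in the translation plane. The
  templates carry no depth dependence; the receptive-field similarity
  analysis uses them because the quantity of interest is vector *direction*
  within the RF, not speed. The linearity
  `v(θ) = cos θ·v(0) + sin θ·v(90°)` holds exactly by construction and is
  asserted as a property test.

The physical dot speed (cm/s of simulated self-motion) is not constrained
anywhere downstream, so `speed_scale` is a free configuration parameter with
a nominal default of 10.

## MU tuning statistics

Tuning is measured per plane at 8 directions in 45° steps (granularity is
configurable; 8 is the coarsest grid containing all four cardinal
conditions). The two planes share the radial poles 0°/180°.

* **Classification**: one-way ANOVA across directions per plane on
  single-trial rates, radial poles excluded; spiral / roll-only /
  translation-only / untuned at p < 0.001 per plane.
* **Resultant vector**: Σ rate·û(dir) with roll-plane directions embedded in
  the (forward, roll) coordinate plane and translation-plane directions in
  (forward, translation); the shared radial poles contribute once, averaged
  across the two planes' measurements. Raw mean rates are used (no
  spontaneous subtraction) by default; `subtract_spontaneous=True` switches
  this, since which convention the field uses varies.
* **Spiral index** `(cos α − cos β)/(cos α + cos β)` with α the angle of the
  resultant to the translation plane and β to the roll plane. The cosines
  are computed directly from vector components
  (`cos α = √(f²+t²)/‖v‖`), which is exact at the extremes. The denominator
  cannot vanish for a non-zero vector (that would need α = β = 90°
  simultaneously); the guard raises if numerical degeneracy ever produced
  it. A pure forward vector has α = β = 0 and index 0 — balanced, as it
  should be.
* **d′** between a plane's poles: `(R(−90°) − R(+90°)) / √((σ²₊+σ²₋)/2)` —
  i.e. (CCW − CW) and (rightward − leftward) under the sign conventions
  above. **ROC area** is the Mann–Whitney U statistic normalized by n₁n₂
  (ties half-credited); tests pin it to an explicit all-pairs oracle.
* **Clustering index**: Pearson r between same-plane tuning curves of sites
  paired at 100–300 µm depth separations.
* **Similarity index**: fraction of RF grid points (1° spacing, 0.5° foveal
  exclusion to avoid the radial/tangential singularity) where the preferred
  roll-plane and translation-plane templates subtend < 45°. The RF is an
  axis-aligned rectangle. For pure rotation vs. pure laminar preferences
  over a fovea-centered RF the index is analytically 0.25 (a 90° wedge of a
  4-fold-symmetric region), which anchors the implementation.

The synthetic-site generator uses a von Mises bump
`rate(θ) = baseline + amp·exp(κ(cos(θ−pref)−1))` with Poisson counts over a
1-s window (Gaussian with configurable Fano factor as an option) — the
simplest circular tuning model with rate-scaled variability. It emulates
tuned, noisy MU activity but not real MSTd features such as
position-dependent RF substructure, correlated trial-to-trial noise across
directions, or non-stationary excitability; tests passing on it certify the
statistics, not those aspects of real data.

## The decision model

Each 4-AFC trial yields two independent Gaussian decision variables,
`d_R ~ N(x_R + δ_R·1[stim], σ_R²)` and `d_T` analogously. The flow pattern
is arbitrated by evidence magnitude — roll iff
`|d_R| − |d_T| > pattern_bias (+ pattern_shift·1[stim], variant 3)` — and
the direction is the sign of the chosen axis's variable; a lapse parameter
mixes in uniform guessing. The published model descriptions specify
*outcomes*, not mechanisms; this two-stage rule is the simplest generator
that reproduces all three outcome patterns and it is deliberately pluggable.
Variant 1 restricts the stimulation offset δ to a single axis, variant 2
allows both axes, variant 3 adds the between-pattern shift (positive =
toward translation). Ties `|d_R| = |d_T|` are measure-zero and broken by the
integration convention. In the coarse task version the decision-variable
mean is taken linear in signed coherence with the slope absorbed into σ, so
fine and coarse sessions share one machinery.

Choice probabilities have a closed form via 1D Gaussian quadrature
(`scipy.integrate.quad`, absolute tolerance 1e-13; the four probabilities
are renormalized to remove ~1e-12 residual quadrature error and sum to 1
within 1e-9). The trial simulator draws from this closed form, which doubles
as its exact oracle; a 10⁶-draw Monte-Carlo check agrees within 3 SE per
cell.

Default study conditions: fine-version stimulus levels
(roll ±11.54°, ±5.74°, ±2.87°, ±1.15°, 0°; translation ±5°, ±2.4°, ±1.15°,
±0.55°, 0°) and coarse-version signed coherences ±8, ±4, ±2, ±1, 0%, 15
repetitions per condition per stimulation state, stimulation interleaved on
half of trials; the 17-condition 4-AFC design shares the straight-forward
reference between the planes. Reward follows the visual stimulus only
(never the stimulation state): correct direction within the shown pattern;
on the ambiguous reference, reward is random at probability 0.5 (the
schedule for ambiguous trials is not otherwise constrained, and 0.5 is the
symmetric choice). Internal noise defaults σ_R = 2.0°, σ_T = 1.0° were
chosen so the simulated observer's general correct rate (~71%) resembles a
well-trained animal that passes the >65% inclusion gate, with thresholds
well inside the stimulus range; stimulation offsets default to 0.75° (roll)
and 0.91° (translation), the scale of reported fine-task PSE shifts.

## Psychophysical analysis

* **Constructions.** Normal: CW/(CW+CCW) (roll) or Left/(Left+Right)
  (translation) per signed level, cross-pattern choices excluded. General
  error: the same numerators over all four choices. Flow-pattern: the
  proportion of translation choices on the normalized axis −1 (all roll
  magnitudes) / 0 (ambiguous) / +1 (all translation magnitudes). Empty
  denominators are flagged missing, never coerced to 0.
* **Fitting.** `p(x) = Φ((x−μ)/σ)` by binomial maximum likelihood (not least
  squares): levels with unequal trial counts are thereby weighted
  automatically. Initialization from a probit-transformed linear regression;
  Nelder–Mead refinement on (μ, log σ); σ floored at 1e-6 axis units;
  one-sided data (all 0s/1s) returns boundary estimates flagged
  non-converged. Standard errors come from the numerical Hessian at the
  optimum; μ's 95% CI is Wald. No lapse parameter is fitted (the fit has
  exactly two free parameters) — a known limitation at high lapse rates.
* **Stimulation test.** One probit model
  `P = Φ(b₀ + b₁x + b₂s + b₃xs)` over control and stimulated trials jointly
  (s = stimulation indicator), two-sided Wald p for b₂ (PSE) and b₃ (slope)
  at α = 0.05. This nests the two-separate-curves readout: with s constant
  the model reduces to the cumulative-Gaussian fit (−b₀/b₁ = μ̂, 1/b₁ = σ̂,
  verified in tests). No multiple-testing correction is applied across
  sites; per-site significance is reported as-is.
* **ΔPSE.** `signed = preferred_sign × (μ_ctrl − μ_stim)`, positive when
  choices moved toward the stimulated site's preferred direction;
  `normalized = signed/σ_ctrl` is unitless and comparable across patterns
  and task versions. The tuning→axis-sign mapping lives in one function
  (`tuning.preferred_axis_sign`) to keep the orientation convention in a
  single place.
* **CCI.** Translation-choice frequency among the ambiguous conditions
  (reference plus, per axis, the smallest non-zero magnitude by default;
  fully configurable), split by stimulation state:
  `(Choice_stim − Choice_nonstim)/Choice_nonstim ≥ −1`. Sessions are gated
  on the *control-trial general correct rate* > 65%; undefined when the
  control frequency is 0.
* **Correct rates.** Over non-ambiguous trials: intra (direction correct
  given pattern correct; 4-AFC chance 0.5), general (fully correct; chance
  0.25), flow-pattern (pattern correct; chance 0.5); ΔCR in percentage
  points (stimulated − control).
* **Population summaries** (medians, sign tests, Wilcoxon) call standard
  scipy routines. The preference-resolved summary uses 30° sliding windows
  in 10° steps on the circular preference axis, reporting mean ± SEM and
  omitting empty windows.

## Pipeline and reproducibility

`pipeline.RunConfig` (plain dataclass, YAML round-trip, unknown keys
rejected) drives simulate → analyze → recover. One master seed; session i
uses `SeedSequence(entropy=seed, spawn_key=(i,))`, recorded with SHA-256
file hashes in the run manifest, making runs byte-reproducible. Each
simulated session pairs a synthetic stimulated site with a behavioral
session whose labeled-line offsets are oriented by the site's preferred-axis
signs, so signed ΔPSE has a known expected direction. The recovery harness
sweeps (variant, δ, σ) and reports bias of the recovered PSE shift, fitted
threshold scaling and CCI per cell.

## Problem sizes

Defaults used by the test and validation suites: sessions of 9–17
conditions × 15 reps × 2 stimulation states; 500 replicates for PSE-recovery
coverage; 1,000 2-AFC sessions for probit type-I calibration; 200 4-AFC
sessions for the variant-3 CCI sign check; 10⁵–10⁶ draws for Monte-Carlo
oracles. These sizes give simulation error comfortably below the margins
being tested while keeping a full run on one CPU in a few minutes.

## Known limitations

* The decision rule is one concrete mechanism consistent with the three
  outcome patterns; other arbitration schemes (e.g. probability matching on
  pattern evidence) would produce different ambiguous-condition structure.
* No fitted lapse; generative lapse > a few percent biases σ̂ upward.
* Axis noises are independent by default (a correlation hook exists but is
  untested against data).
* Velocity templates ignore per-dot depth; speed-dependent analyses should
  use the 3D cloud.
* The synthetic tuning generator does not model RF substructure or
  inter-directional noise correlations (see above).
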