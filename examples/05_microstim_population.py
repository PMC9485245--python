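"""Population analysis of a simulated microstimulation experiment.

Runs the full pipeline: simulate sessions (each with its own synthetic
stimulated site; labeled-line offsets oriented to the site's preference),
analyze per session, and summarize the population PSE shifts and CCI.
"""

import json
from pathlib import Path
from tempfile import TemporaryDirectory

import numpy as np

from spiralflow.pipeline import RunConfig, run_analyze, run_simulate
from spiralflow.psychometrics import bin_dpse_by_preference
from spiralflow import tuning as tn

cfg = RunConfig(seed=42, n_sessions=12, reps_per_level=15)

with TemporaryDirectory() as tmp:
    out = run_simulate(cfg, Path(tmp) / "run")
    manifest = json.loads((out / "manifest.json").read_text())
    trial_files = sorted(out.glob("trials_*.csv"))
    report = run_analyze(trial_files, cfg, out_dir=out, manifest=manifest)
    sites = tn.read_sites(out / "sites.csv", out / "sites.json")

for plane, summ in report["planes"].items():
    print(f"{plane:>5s}: median normalized dPSE = {summ['median_dpse_normalized']:+.2f} "
          f"(sign test p = {summ['sign_test_p']:.3g}; "
          f"{100*summ['prop_expected_direction']:.0f}% expected direction; "
          f"{100*summ['prop_significant_pse']:.0f}% significant)")
if "cci" in report:
    print(f"CCI (variant-{cfg.model_variant} model): median = {report['cci']['median']:+.2f}")

# sliding-window summary of the shift by the sites' preferred roll direction
effects = report["effects"]
prefs = np.array([tn.preferred_direction(s.curve_roll) for s in sites])
ok = effects["roll_dpse_normalized"].notna().to_numpy()
binned = bin_dpse_by_preference(prefs[ok], effects.loc[ok, "roll_dpse_normalized"])
print(f"dPSE-by-preference profile over {len(binned)} windows "
      f"(30-deg bins, 10-deg steps); peak mean = {binned['mean'].max():+.2f}")
# With the variant-2 generator every session injects an offset toward the
# site's preferred direction, so the population median shift is positive.
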