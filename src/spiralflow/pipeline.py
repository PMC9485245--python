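"""End-to-end orchestration: simulate sessions, analyze them, check recovery.

A run is driven by a single :class:`RunConfig` (YAML-serializable, unknown
keys rejected) and a master seed.  Per-session child seeds are derived with a
counter-based ``numpy.random.SeedSequence`` scheme and recorded in the run
manifest, so any session can be regenerated in isolation and a full run is
byte-reproducible.

``run_simulate`` writes one trial-table CSV (+ JSON provenance sidecar) per
session together with the synthetic site tables; ``run_analyze`` applies the
psychometric analysis per session and aggregates population summaries;
``run_recover`` sweeps a (variant, delta, sigma) grid and reports bias and
coverage of the recovered quantities against generative truth.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import behavior, psychometrics, tuning

__all__ = ["RunConfig", "run_simulate", "run_analyze", "run_recover", "load_config"]


@dataclass
class RunConfig:
    """Complete, serializable description of a simulation-analysis run."""

    seed: int = 0
    n_sessions: int = 8
    out_dir: str = "run_out"
    # task design
    paradigm: str = "AFC4"
    version: str = "fine"
    reps_per_level: int = 15
    stim_fraction: float = 0.5
    # decision model
    sigma_roll: float = 2.0
    sigma_trans: float = 1.0
    lapse: float = 0.02
    model_variant: int = 2
    delta_magnitude_roll: float = 0.75
    delta_magnitude_trans: float = 0.91
    pattern_shift: float = 0.0
    pattern_bias: float = 0.0
    # tuning generator
    tuning_amp: float = 40.0
    tuning_baseline: float = 10.0
    tuning_kappa: float = 1.5
    tuning_reps: int = 10
    # analysis options
    alpha_level: float = 0.05
    cr_gate: float = 0.65
    # recovery grid
    recover_deltas: tuple[float, ...] = (0.0, 0.75, 1.5, 3.0)
    recover_sigmas: tuple[float, ...] = (2.0,)
    recover_variants: tuple[int, ...] = (2,)
    recover_replicates: int = 20

    def design(self) -> behavior.TaskDesign:
        if self.version == "fine":
            return behavior.TaskDesign.fine(
                paradigm=self.paradigm,
                reps_per_level=self.reps_per_level,
                stim_fraction=self.stim_fraction,
            )
        return behavior.TaskDesign.coarse(
            paradigm=self.paradigm,
            reps_per_level=self.reps_per_level,
            stim_fraction=self.stim_fraction,
        )

    def to_yaml(self, path) -> None:
        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - names
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        for f in dataclasses.fields(cls):
            if f.name in d and isinstance(d[f.name], list):
                d[f.name] = tuple(d[f.name])
        return cls(**d)


def load_config(path) -> RunConfig:
    return RunConfig.from_dict(yaml.safe_load(Path(path).read_text()) or {})


def _session_rng(master_seed: int, index: int) -> tuple[np.random.Generator, list[int]]:
    ss = np.random.SeedSequence(entropy=int(master_seed), spawn_key=(int(index),))
    return np.random.default_rng(ss), [int(master_seed), int(index)]


def _session_site_and_params(
    config: RunConfig, rng: np.random.Generator, site_id: str
) -> tuple[tuning.MUSite, behavior.DecisionModelParams, dict]:
    """Draw a stimulated site and orient the labeled-line offsets to it."""
    def draw_pref() -> float:
        # keep preferences off the radial axis so the axis sign is defined
        v = float(rng.uniform(-180.0, 180.0))
        return v + 15.0 if abs(np.sin(np.deg2rad(v))) < 0.05 else v

    pref_roll = draw_pref()
    pref_trans = draw_pref()
    params_t = tuning.TuningParams(
        pref_roll=pref_roll,
        pref_trans=pref_trans,
        amp_roll=config.tuning_amp,
        amp_trans=config.tuning_amp,
        kappa=config.tuning_kappa,
        baseline=config.tuning_baseline,
        n_reps=config.tuning_reps,
        depth=float(rng.integers(0, 30) * 100.0),
    )
    site = tuning.synth_mu(params_t, rng, site_id=site_id)
    sign_roll = tuning.preferred_axis_sign(tuning.preferred_direction(site.curve_roll))
    sign_trans = tuning.preferred_axis_sign(tuning.preferred_direction(site.curve_trans))
    delta_roll = sign_roll * config.delta_magnitude_roll
    delta_trans = sign_trans * config.delta_magnitude_trans
    if config.model_variant == 1:
        delta_trans = 0.0
    params_b = behavior.DecisionModelParams(
        sigma_roll=config.sigma_roll,
        sigma_trans=config.sigma_trans,
        pattern_bias=config.pattern_bias,
        lapse=config.lapse,
        delta_roll=delta_roll,
        delta_trans=delta_trans,
        model_variant=config.model_variant,
        pattern_shift=config.pattern_shift if config.model_variant == 3 else 0.0,
    )
    meta = {"sign_roll": sign_roll, "sign_trans": sign_trans}
    return site, params_b, meta


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_simulate(config: RunConfig, out_dir=None) -> Path:
    """Simulate all sessions; write trial tables, site tables and a manifest."""
    out = Path(out_dir or config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    design = config.design()
    sites = []
    manifest = {"seed": config.seed, "sessions": []}
    for i in range(config.n_sessions):
        rng, seed_path = _session_rng(config.seed, i)
        sid = f"s{i:03d}"
        site, params_b, meta = _session_site_and_params(config, rng, site_id=sid)
        sites.append(site)
        table = behavior.simulate_session(design, params_b, rng, session_id=sid)
        csv = out / f"trials_{sid}.csv"
        side = out / f"trials_{sid}.json"
        table.to_csv(csv, side)
        # sidecar seed is None (generator passed in); record the derivation path
        manifest["sessions"].append(
            {
                "session_id": sid,
                "seed_path": seed_path,
                "trials_csv": csv.name,
                "sidecar": side.name,
                "preferred_sign_roll": meta["sign_roll"],
                "preferred_sign_trans": meta["sign_trans"],
            }
        )
    tuning.write_sites(sites, out / "sites.csv", out / "sites.json")
    config.to_yaml(out / "config.yaml")
    for entry in manifest["sessions"]:
        entry["sha256"] = _sha256(out / entry["trials_csv"])
    manifest["sites_sha256"] = _sha256(out / "sites.csv")
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out


def _analyze_one(
    table: behavior.TrialTable,
    preferred_signs: dict[str, int],
    config: RunConfig,
) -> dict:
    """Full psychometric analysis of one session."""
    counts = psychometrics.build_counts(table)
    row: dict = {"session_id": table.df["session_id"].iloc[0]}
    for plane in ("roll", "translation"):
        if table.design.paradigm == "AFC2_roll" and plane == "translation":
            continue
        if table.design.paradigm == "AFC2_translation" and plane == "roll":
            continue
        fits = {}
        for flag, tag in ((False, "ctrl"), (True, "stim")):
            d = psychometrics.psychometric_normal(counts, plane, microstim=flag)
            ok = d.informative
            fits[tag] = psychometrics.fit_cumgauss(
                d.levels[ok], d.successes()[ok], d.n[ok]
            )
        probit = psychometrics.probit_stim_test(table, plane)
        prefix = "roll" if plane == "roll" else "trans"
        row[f"{prefix}_mu_ctrl"] = fits["ctrl"].mu
        row[f"{prefix}_sigma_ctrl"] = fits["ctrl"].sigma
        row[f"{prefix}_mu_stim"] = fits["stim"].mu
        row[f"{prefix}_sigma_stim"] = fits["stim"].sigma
        row[f"{prefix}_converged"] = fits["ctrl"].converged and fits["stim"].converged
        row[f"{prefix}_p_pse"] = probit.p_pse
        row[f"{prefix}_p_slope"] = probit.p_slope
        row[f"{prefix}_delta_threshold"] = fits["stim"].sigma - fits["ctrl"].sigma
        if row[f"{prefix}_converged"]:
            dp = psychometrics.delta_pse(
                fits["ctrl"], fits["stim"], preferred_signs[plane]
            )
            row[f"{prefix}_dpse_raw"] = dp.raw
            row[f"{prefix}_dpse_signed"] = dp.signed
            row[f"{prefix}_dpse_normalized"] = dp.normalized
        else:
            row[f"{prefix}_dpse_raw"] = np.nan
            row[f"{prefix}_dpse_signed"] = np.nan
            row[f"{prefix}_dpse_normalized"] = np.nan
    if table.design.paradigm == "AFC4":
        c = psychometrics.cci(table, cr_gate=config.cr_gate)
        row["cci"] = c.value
        row["cci_included"] = c.included
        for mode in ("intra", "general", "flow_pattern"):
            cr = psychometrics.correct_rate(table, mode=mode, by_stim=True)
            row[f"delta_cr_{mode}_pp"] = cr["delta_cr_pp"]
            row[f"cr_{mode}_ctrl"] = cr["cr_ctrl"]
    return row


def run_analyze(trial_files, config: RunConfig, out_dir=None, manifest=None) -> dict:
    """Analyze simulated (or schema-compatible real) sessions.

    Returns the report dict; writes ``effects.csv`` and ``report.json`` when
    ``out_dir`` is given.
    """
    signs_by_session: dict[str, dict[str, int]] = {}
    if manifest is not None:
        for entry in manifest["sessions"]:
            signs_by_session[entry["session_id"]] = {
                "roll": entry["preferred_sign_roll"],
                "translation": entry["preferred_sign_trans"],
            }
    rows = []
    for f in trial_files:
        f = Path(f)
        table = behavior.TrialTable.from_csv(f, f.with_suffix(".json"))
        sid = table.df["session_id"].iloc[0]
        signs = signs_by_session.get(sid, {"roll": 1, "translation": 1})
        rows.append(_analyze_one(table, signs, config))
    effects = pd.DataFrame(rows)

    report = {"n_sessions": len(effects), "planes": {}}
    for prefix in ("roll", "trans"):
        col = f"{prefix}_dpse_normalized"
        if col not in effects:
            continue
        vals = effects[col].dropna().to_numpy()
        if len(vals) == 0:
            continue
        n_pos = int((vals > 0).sum())
        sign_p = float(stats.binomtest(n_pos, len(vals), 0.5).pvalue)
        pvals = effects[f"{prefix}_p_pse"].dropna().to_numpy()
        report["planes"][prefix] = {
            "median_dpse_normalized": float(np.median(vals)),
            "sign_test_p": sign_p,
            "prop_expected_direction": float(np.mean(vals > 0)),
            "prop_significant_pse": float(np.mean(pvals < config.alpha_level))
            if len(pvals)
            else float("nan"),
            "n": int(len(vals)),
        }
    if "cci" in effects:
        cvals = effects.loc[effects.get("cci_included", True) == True, "cci"].dropna()  # noqa: E712
        if len(cvals):
            report["cci"] = {
                "median": float(cvals.median()),
                "n": int(len(cvals)),
            }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        effects.to_csv(out / "effects.csv", index=False)
        (out / "report.json").write_text(json.dumps(report, indent=1))
    report["effects"] = effects
    return report


def run_recover(config: RunConfig, out_dir=None) -> pd.DataFrame:
    """Parameter-recovery sweep over a (variant, delta, sigma) grid.

    For each cell, simulates ``recover_replicates`` roll-axis sessions with
    the microstimulation offset injected toward +CW, fits control and
    stimulated psychometric functions, and summarizes bias of the recovered
    PSE shift and threshold along with CCI behavior.
    """
    design = config.design()
    rows = []
    counter = 0
    for variant in config.recover_variants:
        for delta in config.recover_deltas:
            for sigma in config.recover_sigmas:
                for rep in range(config.recover_replicates):
                    rng, _ = _session_rng(config.seed, 10_000 + counter)
                    counter += 1
                    params = behavior.DecisionModelParams(
                        sigma_roll=sigma,
                        sigma_trans=config.sigma_trans,
                        lapse=config.lapse,
                        delta_roll=delta,
                        delta_trans=0.0 if variant == 1 else delta / 2.0,
                        model_variant=variant,
                        pattern_shift=config.pattern_shift if variant == 3 else 0.0,
                    )
                    table = behavior.simulate_session(
                        design, params, rng, session_id=f"r{counter:04d}"
                    )
                    counts = psychometrics.build_counts(table)
                    fits = {}
                    for flag, tag in ((False, "ctrl"), (True, "stim")):
                        d = psychometrics.psychometric_normal(
                            counts, "roll", microstim=flag
                        )
                        ok = d.informative
                        fits[tag] = psychometrics.fit_cumgauss(
                            d.levels[ok], d.successes()[ok], d.n[ok]
                        )
                    rec: dict = {
                        "variant": variant,
                        "delta": delta,
                        "sigma": sigma,
                        "rep": rep,
                        "mu_ctrl": fits["ctrl"].mu,
                        "sigma_ctrl": fits["ctrl"].sigma,
                        "converged": fits["ctrl"].converged and fits["stim"].converged,
                    }
                    if rec["converged"]:
                        dp = psychometrics.delta_pse(fits["ctrl"], fits["stim"], +1)
                        rec["dpse_signed"] = dp.signed
                        rec["dpse_normalized"] = dp.normalized
                    else:
                        rec["dpse_signed"] = np.nan
                        rec["dpse_normalized"] = np.nan
                    if design.paradigm == "AFC4":
                        rec["cci"] = psychometrics.cci(table, cr_gate=0.0).value
                    rows.append(rec)
    table_df = pd.DataFrame(rows)
    summary = (
        table_df.groupby(["variant", "delta", "sigma"])
        .agg(
            dpse_mean=("dpse_signed", "mean"),
            dpse_sd=("dpse_signed", "std"),
            sigma_ctrl_mean=("sigma_ctrl", "mean"),
            cci_mean=("cci", "mean") if "cci" in table_df else ("mu_ctrl", "size"),
            n=("rep", "size"),
        )
        .reset_index()
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        table_df.to_csv(out / "recovery_replicates.csv", index=False)
        summary.to_csv(out / "recovery_summary.csv", index=False)
    summary.attrs["replicates"] = table_df
    return summary
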