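"""Psychophysical analysis of 4-AFC / 2-AFC flow-discrimination sessions.

Implements the full analysis layer applied to microstimulation sessions:

* choice tabulation per (plane, stimulus level, stimulation state);
* the psychometric constructions —
  "normal" (within-pattern: CW/(CW+CCW), Left/(Left+Right)),
  "general error" (same numerators over all four choices), and the
  "flow-pattern" function (translation choices vs. a normalized [-1, +1]
  pattern axis with the ambiguous reference at 0);
* two-parameter cumulative-Gaussian fits, p(x) = Phi((x - mu)/sigma), by
  binomial maximum likelihood: mu is the point of subjective equality (PSE)
  and sigma the psychophysical threshold (the curve passes 0.84 one
  threshold above the PSE);
* probit regression testing microstimulation-induced changes in PSE (the
  stimulation main effect) and slope (the stimulation x stimulus
  interaction);
* signed and threshold-normalized PSE shifts (positive = toward the
  stimulated site's preferred direction);
* the choice-change index CCI = (Choice_stim - Choice_nonstim)/Choice_nonstim
  over ambiguous conditions, gated on session correct rate;
* correct-rate statistics (within-pattern, general four-choice, and
  flow-pattern levels) and stimulation-induced changes;
* sliding-window summaries of normalized PSE shift by preferred direction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.stats import norm

import statsmodels.api as sm

from .behavior import ROLL_CHOICES, TRANS_CHOICES, CHOICES, TrialTable, correct_choice

__all__ = [
    "ChoiceCounts",
    "PsychometricData",
    "PsychometricFit",
    "ProbitStimResult",
    "DeltaPSE",
    "CCIResult",
    "MicrostimEffect",
    "build_counts",
    "psychometric_normal",
    "psychometric_general",
    "psychometric_flowpattern",
    "fit_cumgauss",
    "probit_stim_test",
    "delta_pse",
    "cci",
    "correct_rate",
    "bin_dpse_by_preference",
]


# ---------------------------------------------------------------------------
# tabulation


@dataclass
class ChoiceCounts:
    """Choice counts per (plane_shown, stim_value, microstim) cell.

    ``df`` has one row per cell with columns plane_shown, stim_value,
    microstim, CW, CCW, LEFT, RIGHT.
    """

    df: pd.DataFrame

    def filtered(self, microstim: bool | None) -> pd.DataFrame:
        if microstim is None:
            return self.df
        return self.df[self.df["microstim"] == microstim]

    @property
    def total(self) -> int:
        return int(self.df[list(CHOICES)].to_numpy().sum())


def build_counts(trials: TrialTable | pd.DataFrame) -> ChoiceCounts:
    """Exhaustive, order-invariant tabulation of choices per condition cell."""
    df = trials.df if isinstance(trials, TrialTable) else trials
    bad = set(df["choice"]) - set(CHOICES)
    if bad:
        raise ValueError(f"unknown choice labels: {sorted(bad)}")
    if len(df) == 0:
        empty = pd.DataFrame(
            columns=["plane_shown", "stim_value", "microstim", *CHOICES]
        )
        return ChoiceCounts(df=empty)
    tab = (
        df.groupby(["plane_shown", "stim_value", "microstim"])["choice"]
        .value_counts()
        .unstack(fill_value=0)
        .reindex(columns=list(CHOICES), fill_value=0)
        .reset_index()
    )
    tab.columns.name = None
    return ChoiceCounts(df=tab)


# ---------------------------------------------------------------------------
# psychometric constructions


@dataclass
class PsychometricData:
    """One psychometric construction: levels, choice proportions and trials.

    ``n`` is the per-level denominator; levels with an empty denominator carry
    ``prop = NaN`` (flagged missing, never coerced to 0).
    """

    levels: np.ndarray
    prop: np.ndarray
    n: np.ndarray
    construction: str

    @property
    def informative(self) -> np.ndarray:
        return self.n > 0

    def successes(self) -> np.ndarray:
        k = np.zeros_like(self.prop)
        ok = self.informative
        k[ok] = self.prop[ok] * self.n[ok]
        return k


def _plane_rows(counts: ChoiceCounts, plane: str, microstim: bool | None) -> pd.DataFrame:
    """Rows of the axis of one plane; the shared ambiguous reference is its 0."""
    df = counts.filtered(microstim)
    return df[df["plane_shown"].isin([plane, "ambiguous"])]


def _aggregate(df: pd.DataFrame, num_cols: list[str], den_cols: list[str], construction: str) -> PsychometricData:
    g = df.groupby("stim_value")[list(CHOICES)].sum()
    levels = g.index.to_numpy(float)
    num = g[num_cols].sum(axis=1).to_numpy(float)
    den = g[den_cols].sum(axis=1).to_numpy(float)
    prop = np.full(len(levels), np.nan)
    ok = den > 0
    prop[ok] = num[ok] / den[ok]
    return PsychometricData(levels=levels, prop=prop, n=den, construction=construction)


def psychometric_normal(
    counts: ChoiceCounts, plane: str, microstim: bool | None = None
) -> PsychometricData:
    """Within-pattern psychometric function.

    Roll: proportion of CW among CW+CCW choices per signed roll level;
    translation: proportion of LEFT among LEFT+RIGHT.  Trials in which the
    other pattern was chosen are excluded.
    """
    if plane not in ("roll", "translation"):
        raise ValueError(f"unknown plane {plane!r}")
    df = _plane_rows(counts, plane, microstim)
    num = ["CW"] if plane == "roll" else ["LEFT"]
    den = list(ROLL_CHOICES) if plane == "roll" else list(TRANS_CHOICES)
    return _aggregate(df, num, den, "normal")


def psychometric_general(
    counts: ChoiceCounts, plane: str, microstim: bool | None = None
) -> PsychometricData:
    """General-error psychometric function: same numerator as the normal
    construction but with all four choices in the denominator, so
    cross-pattern errors count against performance."""
    if plane not in ("roll", "translation"):
        raise ValueError(f"unknown plane {plane!r}")
    df = _plane_rows(counts, plane, microstim)
    num = ["CW"] if plane == "roll" else ["LEFT"]
    return _aggregate(df, num, list(CHOICES), "general_error")


def psychometric_flowpattern(
    counts: ChoiceCounts, microstim: bool | None = None
) -> PsychometricData:
    """Flow-pattern psychometric function on the normalized pattern axis.

    All roll magnitudes map to -1, all translation magnitudes to +1, the
    ambiguous reference to 0; the response is the proportion of translation
    (LEFT+RIGHT) choices among all four.
    """
    df = counts.filtered(microstim).copy()
    axis = df["plane_shown"].map({"roll": -1.0, "ambiguous": 0.0, "translation": 1.0})
    df = df.assign(stim_value=axis)
    return _aggregate(df, list(TRANS_CHOICES), list(CHOICES), "flow_pattern")


# ---------------------------------------------------------------------------
# cumulative-Gaussian fitting


@dataclass
class PsychometricFit:
    """Two-parameter cumulative-Gaussian fit: PSE ``mu`` and threshold ``sigma``."""

    mu: float
    sigma: float
    construction: str
    loglik: float
    n_trials: int
    converged: bool
    se_mu: float = float("nan")
    se_sigma: float = float("nan")

    def predict(self, x) -> np.ndarray:
        return norm.cdf((np.asarray(x, float) - self.mu) / self.sigma)

    @property
    def mu_ci95(self) -> tuple[float, float]:
        h = 1.959963984540054 * self.se_mu
        return (self.mu - h, self.mu + h)


_SIGMA_FLOOR = 1e-6


def _nll(theta: np.ndarray, x: np.ndarray, k: np.ndarray, n: np.ndarray) -> float:
    mu, logsig = theta
    sigma = max(np.exp(logsig), _SIGMA_FLOOR)
    p = np.clip(norm.cdf((x - mu) / sigma), 1e-12, 1.0 - 1e-12)
    return float(-np.sum(k * np.log(p) + (n - k) * np.log1p(-p)))


def fit_cumgauss(levels, successes, totals, construction: str = "normal") -> PsychometricFit:
    """Binomial maximum-likelihood fit of p(x) = Phi((x - mu)/sigma).

    Initialized from a probit-transformed linear regression and refined by
    Nelder-Mead on (mu, log sigma); sigma is floored at 1e-6 axis units.
    Standard errors come from the numerical Hessian of the log-likelihood at
    the optimum.  Degenerate data (all 0s or all 1s) yields boundary
    estimates with ``converged=False``.
    """
    x = np.asarray(levels, float)
    n = np.asarray(totals, float)
    k = np.asarray(successes, float)
    ok = n > 0
    x, n, k = x[ok], n[ok], k[ok]
    if len(x) < 3:
        raise ValueError("need at least three informative levels")
    if (k > n).any() or (k < 0).any():
        raise ValueError("successes must lie in [0, totals]")

    ntot = int(round(n.sum()))
    p_obs = k / n
    if p_obs.max() == 0.0 or p_obs.min() == 1.0:
        # one-sided data: no interior PSE
        return PsychometricFit(
            mu=float(x.max() if p_obs.max() == 0.0 else x.min()),
            sigma=_SIGMA_FLOOR,
            construction=construction,
            loglik=0.0,
            n_trials=ntot,
            converged=False,
        )

    # probit-linear initialization
    z = norm.ppf(np.clip(p_obs, 0.02, 0.98))
    b1, b0 = np.polyfit(x, z, 1)
    if b1 > 1e-8:
        mu0, sig0 = -b0 / b1, 1.0 / b1
    else:
        mu0, sig0 = float(np.mean(x)), float(np.ptp(x) / 2.0 or 1.0)
    sig0 = max(sig0, 10 * _SIGMA_FLOOR)

    res = optimize.minimize(
        _nll,
        x0=np.array([mu0, np.log(sig0)]),
        args=(x, k, n),
        method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 4000},
    )
    mu, sigma = float(res.x[0]), float(max(np.exp(res.x[1]), _SIGMA_FLOOR))

    # numerical Hessian in (mu, sigma) for delta-method standard errors
    se_mu = se_sigma = float("nan")
    try:
        def nll_ms(t):
            return _nll(np.array([t[0], np.log(max(t[1], _SIGMA_FLOOR))]), x, k, n)

        h = np.array([1e-4 * max(abs(mu), 1.0), 1e-4 * max(sigma, 1e-3)])
        H = np.zeros((2, 2))
        t0 = np.array([mu, sigma])
        f0 = nll_ms(t0)
        for i in range(2):
            for j in range(i, 2):
                ei = np.eye(2)[i] * h[i]
                ej = np.eye(2)[j] * h[j]
                H[i, j] = H[j, i] = (
                    nll_ms(t0 + ei + ej)
                    - nll_ms(t0 + ei - ej)
                    - nll_ms(t0 - ei + ej)
                    + nll_ms(t0 - ei - ej)
                ) / (4 * h[i] * h[j])
        cov = np.linalg.inv(H)
        if cov[0, 0] > 0:
            se_mu = float(np.sqrt(cov[0, 0]))
        if cov[1, 1] > 0:
            se_sigma = float(np.sqrt(cov[1, 1]))
        _ = f0
    except np.linalg.LinAlgError:
        pass

    return PsychometricFit(
        mu=mu,
        sigma=sigma,
        construction=construction,
        loglik=float(-res.fun),
        n_trials=ntot,
        converged=bool(res.success and sigma > _SIGMA_FLOOR),
        se_mu=se_mu,
        se_sigma=se_sigma,
    )


# ---------------------------------------------------------------------------
# probit microstimulation test


@dataclass
class ProbitStimResult:
    """Probit regression P(choice) = Phi(b0 + b1 x + b2 s + b3 x s).

    ``p_pse`` is the Wald p-value of the stimulation main effect (a PSE
    shift), ``p_slope`` that of the stimulation x stimulus interaction (a
    slope/threshold change).
    """

    p_pse: float
    p_slope: float
    coefficients: np.ndarray
    converged: bool


def _binary_response(df: pd.DataFrame, plane: str, construction: str) -> pd.DataFrame:
    """Per-trial binary outcome for a plane's psychometric construction."""
    sub = df[df["plane_shown"].isin([plane, "ambiguous"])].copy()
    pattern = ROLL_CHOICES if plane == "roll" else TRANS_CHOICES
    positive = "CW" if plane == "roll" else "LEFT"
    if construction == "normal":
        sub = sub[sub["choice"].isin(pattern)]
    elif construction != "general_error":
        raise ValueError(f"unknown construction {construction!r}")
    sub["y"] = (sub["choice"] == positive).astype(int)
    return sub


def probit_stim_test(
    trials: TrialTable | pd.DataFrame,
    plane: str,
    construction: str = "normal",
) -> ProbitStimResult:
    """Test microstimulation effects on one plane's psychometric function.

    Fits a single probit model to stimulated and control trials jointly with
    a stimulation indicator and its interaction with the stimulus; Wald
    p-values for the two terms assess PSE and slope changes at alpha = 0.05.
    """
    df = trials.df if isinstance(trials, TrialTable) else trials
    if df["microstim"].nunique() < 2:
        raise ValueError("need both stimulated and control trials")
    sub = _binary_response(df, plane, construction)
    x = sub["stim_value"].to_numpy(float)
    s = sub["microstim"].to_numpy(float)
    X = np.column_stack([np.ones_like(x), x, s, x * s])
    try:
        fit = sm.Probit(sub["y"].to_numpy(), X).fit(disp=0, maxiter=200)
        converged = bool(fit.mle_retvals.get("converged", True))
        return ProbitStimResult(
            p_pse=float(fit.pvalues[2]),
            p_slope=float(fit.pvalues[3]),
            coefficients=np.asarray(fit.params, float),
            converged=converged,
        )
    except (np.linalg.LinAlgError, sm.tools.sm_exceptions.PerfectSeparationError):
        return ProbitStimResult(
            p_pse=float("nan"),
            p_slope=float("nan"),
            coefficients=np.full(4, np.nan),
            converged=False,
        )


# ---------------------------------------------------------------------------
# microstimulation effect measures


@dataclass
class DeltaPSE:
    """Raw, signed and threshold-normalized PSE shift.

    ``signed`` is positive when the shift moves choices toward the stimulated
    site's preferred direction; ``normalized`` divides by the control
    threshold, making shifts comparable across tasks and versions.
    """

    raw: float
    signed: float
    normalized: float


def delta_pse(
    fit_ctrl: PsychometricFit, fit_stim: PsychometricFit, preferred_sign: int
) -> DeltaPSE:
    """Signed and normalized microstimulation-induced PSE shift.

    ``preferred_sign`` (+1/-1) is the stimulus-axis sign of the stimulated
    site's preferred direction (see ``tuning.preferred_axis_sign``).  A shift
    that produces more preferred-direction choices moves the PSE *away* from
    the preferred side, so the expected-direction shift is
    ``preferred_sign * (mu_ctrl - mu_stim) > 0``.
    """
    if preferred_sign not in (-1, 1):
        raise ValueError("preferred_sign must be +1 or -1")
    if not (fit_ctrl.converged and fit_stim.converged):
        raise ValueError("both fits must have converged")
    if fit_ctrl.sigma <= 0:
        raise ValueError("control threshold must be positive")
    raw = fit_ctrl.mu - fit_stim.mu
    signed = preferred_sign * raw
    return DeltaPSE(raw=raw, signed=signed, normalized=signed / fit_ctrl.sigma)


@dataclass
class CCIResult:
    """Choice-change index over the ambiguous conditions.

    CCI = (Choice_stim - Choice_nonstim) / Choice_nonstim where Choice_* is
    the frequency of translation-target choices.  Positive values mean
    microstimulation biased the pattern choice toward translation; CCI >= -1
    always.  Sessions failing the correct-rate gate are excluded.
    """

    value: float
    included: bool
    reason: str
    choice_stim: float
    choice_nonstim: float
    n_stim: int
    n_nonstim: int


def _default_ambiguous_sets(trials: TrialTable) -> dict[str, set[float]]:
    """Reference plus the smallest non-zero magnitude on each axis."""
    d = trials.design
    out = {}
    for plane, levels in (("roll", d.roll_levels), ("translation", d.trans_levels)):
        mags = sorted({abs(v) for v in levels if v != 0.0})
        out[plane] = {mags[0]} if mags else set()
    return out


def cci(
    trials: TrialTable,
    ambiguous_levels: dict[str, set[float]] | None = None,
    cr_gate: float = 0.65,
) -> CCIResult:
    """Choice-change index between flow patterns on ambiguous conditions.

    The condition set is the shared reference plus, per axis, the configured
    adjacent magnitudes (default: the smallest non-zero level), where pattern
    errors are frequent enough to be informative.  Sessions whose control
    general correct rate does not exceed ``cr_gate`` are excluded.
    """
    df = trials.df
    gate_cr = correct_rate(trials, mode="general", by_stim=True)["cr_ctrl"]
    if not np.isnan(gate_cr) and gate_cr <= cr_gate:
        return CCIResult(float("nan"), False, f"control correct rate {gate_cr:.3f} <= gate", np.nan, np.nan, 0, 0)

    sets = ambiguous_levels if ambiguous_levels is not None else _default_ambiguous_sets(trials)
    keep = df["plane_shown"] == "ambiguous"
    for plane, mags in sets.items():
        keep |= (df["plane_shown"] == plane) & df["stim_value"].abs().isin(list(mags))
    sub = df[keep]

    freqs = {}
    ns = {}
    for flag in (True, False):
        g = sub[sub["microstim"] == flag]
        ns[flag] = len(g)
        freqs[flag] = (
            float(g["choice"].isin(TRANS_CHOICES).mean()) if len(g) else float("nan")
        )
    if not ns[False] or np.isnan(freqs[False]) or freqs[False] == 0.0:
        return CCIResult(
            float("nan"), False, "no translation choices in control trials",
            freqs.get(True, np.nan), freqs.get(False, np.nan), ns[True], ns[False],
        )
    value = (freqs[True] - freqs[False]) / freqs[False]
    return CCIResult(value, True, "", freqs[True], freqs[False], ns[True], ns[False])


def correct_rate(
    trials: TrialTable | pd.DataFrame,
    mode: str = "general",
    by_stim: bool = False,
    plane: str | None = None,
):
    """Correct-rate statistics over non-ambiguous trials.

    Modes: ``intra`` — correct direction among trials where the chosen
    pattern matched the shown one (chance 0.5 in 4-AFC); ``general`` —
    fully-correct choices among all trials (chance 0.25); ``flow_pattern`` —
    correct-pattern choices among all trials (chance 0.5).  With ``by_stim``
    returns control and stimulated rates and their difference in percentage
    points.
    """
    df = trials.df if isinstance(trials, TrialTable) else trials
    df = df[(df["plane_shown"] != "ambiguous") & (df["stim_value"] != 0.0)].copy()
    if plane is not None:
        df = df[df["plane_shown"] == plane]

    chosen_pattern = np.where(df["choice"].isin(ROLL_CHOICES), "roll", "translation")
    pattern_ok = chosen_pattern == df["plane_shown"].to_numpy()
    target = df.apply(lambda r: correct_choice(r["plane_shown"], r["stim_value"]), axis=1) if len(df) else pd.Series(dtype=object)
    fully_ok = (df["choice"].to_numpy() == target.to_numpy()) if len(df) else np.array([], bool)

    def rate(mask_rows: np.ndarray) -> float:
        if mode == "intra":
            sel = mask_rows & pattern_ok
            return float(fully_ok[sel].mean()) if sel.sum() else float("nan")
        if mode == "general":
            return float(fully_ok[mask_rows].mean()) if mask_rows.sum() else float("nan")
        if mode == "flow_pattern":
            return float(pattern_ok[mask_rows].mean()) if mask_rows.sum() else float("nan")
        raise ValueError(f"unknown mode {mode!r}")

    all_rows = np.ones(len(df), bool)
    if not by_stim:
        return rate(all_rows)
    stim = df["microstim"].to_numpy(bool)
    cr_ctrl = rate(all_rows & ~stim)
    cr_stim = rate(all_rows & stim)
    return {
        "cr_ctrl": cr_ctrl,
        "cr_stim": cr_stim,
        "delta_cr_pp": 100.0 * (cr_stim - cr_ctrl),
    }


@dataclass
class MicrostimEffect:
    """Per-site microstimulation effect summary."""

    site_id: str
    plane: str
    dpse_raw: float
    dpse_signed: float
    dpse_normalized: float
    p_pse: float
    p_slope: float
    delta_threshold: float
    cci: float
    delta_cr_intra: float
    delta_cr_general: float
    delta_cr_flowpattern: float


def bin_dpse_by_preference(
    preferences_deg: np.ndarray,
    dpse_normalized: np.ndarray,
    window: float = 30.0,
    step: float = 10.0,
) -> pd.DataFrame:
    """Sliding-window mean +/- SEM of normalized PSE shift by preference.

    Windows of ``window`` degrees advance in ``step``-degree increments over
    the circular preferred-direction axis; empty windows are omitted.
    """
    pref = np.asarray(preferences_deg, float)
    vals = np.asarray(dpse_normalized, float)
    if pref.shape != vals.shape:
        raise ValueError("preferences and values must align")
    centers = np.arange(-180.0, 180.0, step)
    rows = []
    for c in centers:
        d = np.abs((pref - c + 180.0) % 360.0 - 180.0)  # circular distance
        sel = d <= window / 2.0
        n = int(sel.sum())
        if n == 0:
            continue
        v = vals[sel]
        sem = float(v.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
        rows.append({"center_deg": c, "mean": float(v.mean()), "sem": sem, "n": n})
    return pd.DataFrame(rows)
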