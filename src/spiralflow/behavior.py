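"""Generative 4-AFC / 2-AFC choice model with labeled-line microstimulation.

The task: the animal views one optic-flow stimulus per trial — a roll stimulus
(signed rotation angle or coherence), a translation stimulus (signed lateral
angle or coherence), or the ambiguous straight-forward reference — and reports
both the flow pattern and its direction by choosing one of four targets
(CW, CCW, LEFT, RIGHT); 2-AFC variants restrict choices to one pattern.

The decision model is a two-stage labeled-line readout.  Each axis carries a
noisy decision variable

    d_R = x_R + delta_R * 1[stim] + eps_R,   eps_R ~ N(0, sigma_R^2)
    d_T = x_T + delta_T * 1[stim] + eps_T,   eps_T ~ N(0, sigma_T^2)

where x is the signed stimulus value on the shown axis (0 on the other) and
delta is the microstimulation offset injected along the stimulated site's
labeled line.  The flow pattern is arbitrated by evidence magnitude:
roll is chosen iff |d_R| - |d_T| > pattern_bias (+ pattern_shift on
stimulated trials under model variant 3), and the direction is the sign of
the chosen axis's variable.  A lapse parameter mixes in uniform guessing.

The three model variants describe where microstimulation acts:

1. within a single flow pattern only (one delta non-zero, no pattern shift);
2. within both patterns, along the site's preferred stimulus in each
   (both deltas allowed, no pattern shift);
3. variant 2 plus a bias *between* patterns (pattern_shift, positive values
   pushing choices toward translation).

Choice probabilities are available in closed form (1D Gaussian quadrature),
which serves as the exact oracle for the trial simulator.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import integrate
from scipy.stats import norm

__all__ = [
    "CHOICES",
    "TaskDesign",
    "DecisionModelParams",
    "Trial",
    "TrialTable",
    "choice_probabilities",
    "simulate_session",
    "reward_rule",
    "correct_choice",
]

CHOICES = ("CW", "CCW", "LEFT", "RIGHT")
ROLL_CHOICES = ("CW", "CCW")
TRANS_CHOICES = ("LEFT", "RIGHT")

FINE_ROLL_LEVELS = (-11.54, -5.74, -2.87, -1.15, 0.0, 1.15, 2.87, 5.74, 11.54)
FINE_TRANS_LEVELS = (-5.0, -2.4, -1.15, -0.55, 0.0, 0.55, 1.15, 2.4, 5.0)
COARSE_LEVELS = (-8.0, -4.0, -2.0, -1.0, 0.0, 1.0, 2.0, 4.0, 8.0)


def _check_levels(levels: tuple[float, ...]) -> None:
    arr = np.asarray(levels, float)
    if 0.0 not in arr:
        raise ValueError("levels must include the ambiguous reference 0")
    pos = np.sort(arr[arr > 0])
    neg = np.sort(-arr[arr < 0])
    if len(pos) != len(neg) or not np.allclose(pos, neg):
        raise ValueError("levels must be symmetric about 0")


@dataclass(frozen=True)
class TaskDesign:
    """A session design: paradigm, task version, stimulus levels and counts.

    ``reps_per_level`` is the repetition count per (condition, stimulation
    state) cell at the default ``stim_fraction`` of 0.5, matching interleaved
    microstimulation on half of trials.
    """

    paradigm: str = "AFC4"  # AFC4 | AFC2_roll | AFC2_translation
    version: str = "fine"  # fine | coarse
    roll_levels: tuple[float, ...] = FINE_ROLL_LEVELS
    trans_levels: tuple[float, ...] = FINE_TRANS_LEVELS
    reps_per_level: int = 15
    stim_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.paradigm not in ("AFC4", "AFC2_roll", "AFC2_translation"):
            raise ValueError(f"unknown paradigm {self.paradigm!r}")
        if self.version not in ("fine", "coarse"):
            raise ValueError(f"unknown version {self.version!r}")
        _check_levels(self.roll_levels)
        _check_levels(self.trans_levels)
        if self.reps_per_level < 1:
            raise ValueError("reps_per_level must be >= 1")
        if not (0.0 <= self.stim_fraction <= 1.0):
            raise ValueError("stim_fraction must lie in [0, 1]")

    @classmethod
    def fine(cls, paradigm: str = "AFC4", **kw) -> "TaskDesign":
        return cls(paradigm=paradigm, version="fine", **kw)

    @classmethod
    def coarse(cls, paradigm: str = "AFC4", **kw) -> "TaskDesign":
        return cls(
            paradigm=paradigm,
            version="coarse",
            roll_levels=COARSE_LEVELS,
            trans_levels=COARSE_LEVELS,
            **kw,
        )

    def conditions(self) -> list[tuple[str, float]]:
        """Unique (plane_shown, stim_value) conditions; the 0 reference is
        shared between the planes and appears once, as 'ambiguous'."""
        conds: list[tuple[str, float]] = []
        if self.paradigm in ("AFC4", "AFC2_roll"):
            conds += [("roll", v) for v in self.roll_levels if v != 0.0]
        if self.paradigm in ("AFC4", "AFC2_translation"):
            conds += [("translation", v) for v in self.trans_levels if v != 0.0]
        conds.append(("ambiguous", 0.0))
        return conds

    @property
    def allowed_choices(self) -> tuple[str, ...]:
        if self.paradigm == "AFC2_roll":
            return ROLL_CHOICES
        if self.paradigm == "AFC2_translation":
            return TRANS_CHOICES
        return CHOICES


@dataclass(frozen=True)
class DecisionModelParams:
    """Parameters of the two-stage labeled-line decision model (see module docs)."""

    sigma_roll: float = 2.0
    sigma_trans: float = 1.0
    pattern_bias: float = 0.0
    lapse: float = 0.0
    delta_roll: float = 0.0
    delta_trans: float = 0.0
    model_variant: int = 2
    pattern_shift: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma_roll <= 0 or self.sigma_trans <= 0:
            raise ValueError("internal noise SDs must be positive")
        if not (0.0 <= self.lapse <= 0.2):
            raise ValueError("lapse must lie in [0, 0.2]")
        if self.model_variant not in (1, 2, 3):
            raise ValueError("model_variant must be 1, 2 or 3")
        if self.model_variant == 1 and self.delta_roll != 0 and self.delta_trans != 0:
            raise ValueError("variant 1 allows a microstimulation offset on one axis only")
        if self.model_variant != 3 and self.pattern_shift != 0:
            raise ValueError("pattern_shift is used only by model variant 3")


@dataclass(frozen=True)
class Trial:
    session_id: str
    trial_index: int
    plane_shown: str  # roll | translation | ambiguous
    stim_value: float
    microstim: bool
    choice: str
    rewarded: bool


def _axis_means(
    params: DecisionModelParams, plane_shown: str, stim_value: float, microstim: bool
) -> tuple[float, float, float]:
    """Decision-variable means (m_R, m_T) and the arbitration criterion c."""
    if plane_shown == "ambiguous":
        if stim_value != 0.0:
            raise ValueError("ambiguous trials have stim_value 0")
        x_r = x_t = 0.0
    elif plane_shown == "roll":
        x_r, x_t = stim_value, 0.0
    elif plane_shown == "translation":
        x_r, x_t = 0.0, stim_value
    else:
        raise ValueError(f"unknown plane {plane_shown!r}")
    m_r = x_r + (params.delta_roll if microstim else 0.0)
    m_t = x_t + (params.delta_trans if microstim else 0.0)
    c = params.pattern_bias
    if microstim and params.model_variant == 3:
        c += params.pattern_shift
    return m_r, m_t, c


def _interval_prob(w: np.ndarray, m: float, s: float) -> np.ndarray:
    """P(|N(m, s^2)| <= w), with w possibly negative (probability 0)."""
    w = np.maximum(w, 0.0)
    return norm.cdf((w - m) / s) - norm.cdf((-w - m) / s)


@lru_cache(maxsize=4096)
def _choice_probs_cached(
    params: DecisionModelParams, plane_shown: str, stim_value: float, microstim: bool
) -> tuple[float, float, float, float]:
    m_r, m_t, c = _axis_means(params, plane_shown, stim_value, microstim)
    s_r, s_t = params.sigma_roll, params.sigma_trans

    # roll pattern chosen iff |d_R| - |d_T| > c; direction = sign(d_R)
    def p_roll_dir(sign: int) -> float:
        def f(u: float) -> float:
            # u = |d_R| on the chosen side
            dens = norm.pdf((sign * u - m_r) / s_r) / s_r
            return dens * _interval_prob(np.asarray(u - c), m_t, s_t)

        val, _ = integrate.quad(f, 0.0, np.inf, epsabs=1e-13, epsrel=1e-11, limit=400)
        return val

    def p_trans_dir(sign: int) -> float:
        def f(u: float) -> float:
            dens = norm.pdf((sign * u - m_t) / s_t) / s_t
            return dens * _interval_prob(np.asarray(u + c), m_r, s_r)

        val, _ = integrate.quad(f, 0.0, np.inf, epsabs=1e-13, epsrel=1e-11, limit=400)
        return val

    p = np.array(
        [p_roll_dir(+1), p_roll_dir(-1), p_trans_dir(+1), p_trans_dir(-1)]
    )
    p = p / p.sum()  # renormalize residual quadrature error (~1e-12)
    p = (1.0 - params.lapse) * p + params.lapse / 4.0
    return tuple(float(v) for v in p)


def choice_probabilities(
    params: DecisionModelParams,
    plane_shown: str,
    stim_value: float,
    microstim: bool,
    paradigm: str = "AFC4",
) -> np.ndarray:
    """Closed-form choice probabilities over (CW, CCW, LEFT, RIGHT).

    For the 2-AFC paradigms, the arbitration stage is bypassed: the direction
    is the sign of the relevant axis's decision variable and the disallowed
    pattern's probabilities are identically zero.
    """
    m_r, m_t, _ = _axis_means(params, plane_shown, stim_value, microstim)
    if paradigm == "AFC2_roll":
        p_cw = norm.cdf(m_r / params.sigma_roll)
        p = np.array([p_cw, 1.0 - p_cw, 0.0, 0.0])
        lapse_mix = np.array([0.5, 0.5, 0.0, 0.0])
        return (1.0 - params.lapse) * p + params.lapse * lapse_mix
    if paradigm == "AFC2_translation":
        p_left = norm.cdf(m_t / params.sigma_trans)
        p = np.array([0.0, 0.0, p_left, 1.0 - p_left])
        lapse_mix = np.array([0.0, 0.0, 0.5, 0.5])
        return (1.0 - params.lapse) * p + params.lapse * lapse_mix
    if paradigm != "AFC4":
        raise ValueError(f"unknown paradigm {paradigm!r}")
    return np.array(_choice_probs_cached(params, plane_shown, stim_value, microstim))


def correct_choice(plane_shown: str, stim_value: float) -> str | None:
    """The rewarded choice for a non-ambiguous condition (None if ambiguous).

    Positive roll values are CW, negative CCW; positive translation values are
    LEFT, negative RIGHT.
    """
    if plane_shown == "ambiguous" or stim_value == 0.0:
        return None
    if plane_shown == "roll":
        return "CW" if stim_value > 0 else "CCW"
    if plane_shown == "translation":
        return "LEFT" if stim_value > 0 else "RIGHT"
    raise ValueError(f"unknown plane {plane_shown!r}")


def reward_rule(
    plane_shown: str, stim_value: float, choice: str, rng: np.random.Generator
) -> bool:
    """Reward: correct direction within the shown pattern; 50% random reward
    on the ambiguous reference (which carries no information).  Reward never
    depends on the microstimulation state."""
    target = correct_choice(plane_shown, stim_value)
    if target is None:
        return bool(rng.random() < 0.5)
    return choice == target


@dataclass
class TrialTable:
    """An ordered collection of trials plus full generative provenance."""

    df: pd.DataFrame
    design: TaskDesign
    params: DecisionModelParams | None
    seed: int | None

    COLUMNS = (
        "session_id",
        "trial",
        "paradigm",
        "version",
        "plane_shown",
        "stim_value",
        "microstim",
        "choice",
        "rewarded",
    )

    def __len__(self) -> int:
        return len(self.df)

    def subset(self, microstim: bool | None = None) -> pd.DataFrame:
        if microstim is None:
            return self.df
        return self.df[self.df["microstim"] == microstim]

    def to_csv(self, csv_path, sidecar_path=None) -> None:
        self.df.to_csv(csv_path, index=False)
        if sidecar_path is not None:
            side = {
                "design": asdict(self.design),
                "params": asdict(self.params) if self.params else None,
                "seed": self.seed,
            }
            Path(sidecar_path).write_text(json.dumps(side, indent=1))

    @classmethod
    def from_csv(cls, csv_path, sidecar_path=None) -> "TrialTable":
        df = pd.read_csv(csv_path)
        missing = set(cls.COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"trial table missing columns: {sorted(missing)}")
        design, params, seed = None, None, None
        if sidecar_path is not None and Path(sidecar_path).exists():
            side = json.loads(Path(sidecar_path).read_text())
            d = dict(side["design"])
            d["roll_levels"] = tuple(d["roll_levels"])
            d["trans_levels"] = tuple(d["trans_levels"])
            design = TaskDesign(**d)
            if side.get("params"):
                params = DecisionModelParams(**side["params"])
            seed = side.get("seed")
        if design is None:
            design = _design_from_frame(df)
        return cls(df=df, design=design, params=params, seed=seed)


def _design_from_frame(df: pd.DataFrame) -> TaskDesign:
    """Reconstruct a minimal TaskDesign from an external trial table."""
    paradigm = str(df["paradigm"].iloc[0])
    version = str(df["version"].iloc[0])
    roll = sorted(
        set(df.loc[df["plane_shown"] == "roll", "stim_value"]).union({0.0})
    )
    trans = sorted(
        set(df.loc[df["plane_shown"] == "translation", "stim_value"]).union({0.0})
    )
    reps = max(1, int(len(df) / max(1, df.groupby(["plane_shown", "stim_value"]).ngroups) / 2))
    if len(roll) < 3:
        roll = [-1.0, 0.0, 1.0]
    if len(trans) < 3:
        trans = [-1.0, 0.0, 1.0]
    return TaskDesign(
        paradigm=paradigm,
        version=version,
        roll_levels=tuple(roll),
        trans_levels=tuple(trans),
        reps_per_level=reps,
    )


def simulate_session(
    design: TaskDesign,
    params: DecisionModelParams,
    seed: int | np.random.Generator,
    session_id: str = "s000",
) -> TrialTable:
    """Simulate one session: conditions interleaved in random order, choices
    drawn from the closed-form probabilities, reward per the task rule.

    Each condition contributes ``2 * reps_per_level`` trials of which
    ``round(stim_fraction * 2 * reps_per_level)`` carry microstimulation.
    """
    seed_int = None if isinstance(seed, np.random.Generator) else int(seed)
    rng = np.random.default_rng(seed)

    cells: list[tuple[str, float, bool]] = []
    for plane, value in design.conditions():
        n_total = 2 * design.reps_per_level
        n_stim = int(round(design.stim_fraction * n_total))
        cells += [(plane, value, True)] * n_stim
        cells += [(plane, value, False)] * (n_total - n_stim)
    order = rng.permutation(len(cells))

    # per-cell probabilities (cached across repeats of the same condition)
    prob_cache: dict[tuple[str, float, bool], np.ndarray] = {}
    records = []
    allowed = design.allowed_choices
    for i, k in enumerate(order):
        plane, value, stim = cells[k]
        key = (plane, value, stim)
        if key not in prob_cache:
            prob_cache[key] = choice_probabilities(
                params, plane, value, stim, paradigm=design.paradigm
            )
        p = prob_cache[key]
        choice = CHOICES[rng.choice(4, p=p)]
        assert choice in allowed
        rewarded = reward_rule(plane, value, choice, rng)
        records.append(
            {
                "session_id": session_id,
                "trial": i,
                "paradigm": design.paradigm,
                "version": design.version,
                "plane_shown": plane,
                "stim_value": value,
                "microstim": stim,
                "choice": choice,
                "rewarded": rewarded,
            }
        )
    df = pd.DataFrame(records, columns=list(TrialTable.COLUMNS))
    return TrialTable(df=df, design=design, params=params, seed=seed_int)
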