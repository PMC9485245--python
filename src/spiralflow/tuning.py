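"""Multiunit (MU) site tuning in spiral space and its summary statistics.

An MSTd MU site carries one direction-tuning curve per spiral-space plane
(roll and translation).  The two planes share the radial axis: direction 0 deg
is pure expansion (forward) and 180 deg pure contraction in both planes, while
+/-90 deg are the plane-specific poles (CW/CCW rotation; leftward/rightward
laminar flow).

From the two curves this module derives the statistics used to characterize a
site and to interpret microstimulation effects:

* ANOVA-based cell-type classification (spiral / roll-only / translation-only /
  untuned),
* the 3D resultant (residual) vector and the spiral index in [-1, +1]
  (-1 = strong roll preference, +1 = strong translation preference),
* direction discriminability d' and ROC area between the two poles of a plane,
* the clustering index (Pearson r of tuning curves at nearby depths),
* the receptive-field flow-similarity index (fraction of RF locations where
  the preferred roll-plane and translation-plane flow templates point within
  45 deg of each other).

A seeded generator (:func:`synth_mu`) produces synthetic sites with von
Mises-shaped tuning and Poisson or Gaussian trial noise for testing and
simulation studies.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .flowfield import ROLL, TRANSLATION, FlowFieldSpec, screen_velocity_template

__all__ = [
    "TuningCurve",
    "ReceptiveField",
    "MUSite",
    "SpiralVector",
    "CellClass",
    "TuningParams",
    "classify_site",
    "resultant_vector",
    "spiral_index",
    "dprime",
    "roc_discriminability",
    "clustering_index",
    "similarity_index",
    "preferred_direction",
    "preferred_axis_sign",
    "synth_mu",
    "write_sites",
    "read_sites",
]

RADIAL_POLES = (0.0, 180.0)


def _cosd(deg: float) -> float:
    """cos of an angle in degrees, exact at multiples of 90."""
    r = deg % 360.0
    if r in (90.0, 270.0):
        return 0.0
    return float(np.cos(np.deg2rad(deg)))


def _sind(deg: float) -> float:
    """sin of an angle in degrees, exact at multiples of 90."""
    r = deg % 360.0
    if r in (0.0, 180.0):
        return 0.0
    return float(np.sin(np.deg2rad(deg)))


class ZeroVectorError(ValueError):
    """All rates zero: the resultant vector has no direction."""


class UndefinedIndexError(ValueError):
    """The spiral-index denominator vanished."""


@dataclass
class TuningCurve:
    """Direction tuning within one spiral-space plane.

    ``directions`` are in-plane angles in degrees (0 = expansion, 180 =
    contraction, +/-90 = the plane's poles).  ``trial_rates`` holds one array
    of single-trial firing rates per direction when available; mean/SD are
    derived from it otherwise they must be supplied.
    """

    plane: str
    directions: np.ndarray
    mean_rate: np.ndarray
    sd_rate: np.ndarray
    n_reps: np.ndarray
    spontaneous: float = 0.0
    trial_rates: list[np.ndarray] | None = None

    def __post_init__(self) -> None:
        self.directions = np.asarray(self.directions, float)
        self.mean_rate = np.asarray(self.mean_rate, float)
        self.sd_rate = np.asarray(self.sd_rate, float)
        self.n_reps = np.broadcast_to(
            np.asarray(self.n_reps, int), self.directions.shape
        ).copy()
        if len(np.unique(np.mod(self.directions, 360.0))) != len(self.directions):
            raise ValueError("directions must be unique")
        if (self.mean_rate < 0).any():
            raise ValueError("mean rates must be non-negative")
        if (self.n_reps < 3).any():
            raise ValueError("each direction needs at least three repetitions")

    @classmethod
    def from_trials(
        cls,
        plane: str,
        directions: np.ndarray,
        trial_rates: list[np.ndarray],
        spontaneous: float = 0.0,
    ) -> "TuningCurve":
        trial_rates = [np.asarray(t, float) for t in trial_rates]
        return cls(
            plane=plane,
            directions=np.asarray(directions, float),
            mean_rate=np.array([t.mean() for t in trial_rates]),
            sd_rate=np.array([t.std(ddof=1) for t in trial_rates]),
            n_reps=np.array([len(t) for t in trial_rates]),
            spontaneous=spontaneous,
            trial_rates=trial_rates,
        )

    def rate_at(self, direction: float) -> float:
        """Mean rate at one measured direction (exact match, mod 360)."""
        m = np.isclose(np.mod(self.directions, 360.0), np.mod(direction, 360.0))
        if not m.any():
            raise KeyError(f"direction {direction} not measured")
        return float(self.mean_rate[m][0])

    def has_direction(self, direction: float) -> bool:
        return bool(
            np.isclose(np.mod(self.directions, 360.0), np.mod(direction, 360.0)).any()
        )


@dataclass(frozen=True)
class ReceptiveField:
    """Axis-aligned rectangular receptive field in screen degrees."""

    center: tuple[float, float]
    half_width: float
    half_height: float

    def __post_init__(self) -> None:
        if self.half_width <= 0 or self.half_height <= 0:
            raise ValueError("RF half-extents must be positive")

    @property
    def covers_fovea(self) -> bool:
        cx, cy = self.center
        return abs(cx) <= self.half_width and abs(cy) <= self.half_height

    def grid(self, step: float, fovea_exclusion: float = 0.0) -> np.ndarray:
        """Regular sample grid inside the RF, optionally excluding the fovea."""
        cx, cy = self.center
        xs = np.arange(cx - self.half_width, cx + self.half_width + step / 2, step)
        ys = np.arange(cy - self.half_height, cy + self.half_height + step / 2, step)
        gx, gy = np.meshgrid(xs, ys)
        pts = np.column_stack([gx.ravel(), gy.ravel()])
        if fovea_exclusion > 0:
            pts = pts[np.hypot(pts[:, 0], pts[:, 1]) > fovea_exclusion]
        return pts


@dataclass
class MUSite:
    """A multiunit recording site: depth, the two plane curves, and its RF."""

    site_id: str
    depth: float
    curve_roll: TuningCurve
    curve_trans: TuningCurve
    rf: ReceptiveField

    def __post_init__(self) -> None:
        if self.depth < 0:
            raise ValueError("depth must be non-negative")
        if self.curve_roll.plane != ROLL or self.curve_trans.plane != TRANSLATION:
            raise ValueError("curves must be (roll, translation) in that order")


@dataclass(frozen=True)
class SpiralVector:
    """Resultant vector in (forward, roll, translation) coordinates.

    ``alpha`` is the angle (deg) between the vector and the translation plane,
    ``beta`` the angle to the roll plane; both lie in [0, 90].
    """

    f: float
    r: float
    t: float

    @property
    def norm(self) -> float:
        return float(np.sqrt(self.f**2 + self.r**2 + self.t**2))

    @property
    def alpha(self) -> float:
        return float(np.degrees(np.arcsin(min(1.0, abs(self.r) / self.norm))))

    @property
    def beta(self) -> float:
        return float(np.degrees(np.arcsin(min(1.0, abs(self.t) / self.norm))))


@dataclass(frozen=True)
class CellClass:
    """ANOVA cell-type label with the per-plane p-values that produced it."""

    label: str  # spiral | roll_only | translation_only | untuned
    p_roll: float
    p_trans: float


def _anova_p(curve: TuningCurve) -> float:
    """One-way ANOVA p across directions, radial poles excluded."""
    if curve.trial_rates is None:
        raise ValueError("classification requires per-trial rates")
    groups = [
        t
        for d, t in zip(curve.directions, curve.trial_rates)
        if not np.isclose(np.mod(d, 360.0), RADIAL_POLES).any()
    ]
    if len(groups) < 2:
        raise ValueError("need at least two non-radial directions for ANOVA")
    return float(stats.f_oneway(*groups).pvalue)


def classify_site(site: MUSite, alpha_level: float = 0.001) -> CellClass:
    """Four-way cell-type classification from per-plane one-way ANOVAs.

    The two radial directions (pure expansion/contraction), shared by both
    planes, are dropped before testing.  With the default 0.001 rule: spiral
    iff both planes significant, roll-only / translation-only iff exactly one
    is, untuned otherwise.
    """
    p_roll = _anova_p(site.curve_roll)
    p_trans = _anova_p(site.curve_trans)
    if p_roll < alpha_level and p_trans < alpha_level:
        label = "spiral"
    elif p_roll < alpha_level:
        label = "roll_only"
    elif p_trans < alpha_level:
        label = "translation_only"
    else:
        label = "untuned"
    return CellClass(label=label, p_roll=p_roll, p_trans=p_trans)


def resultant_vector(site: MUSite, subtract_spontaneous: bool = False) -> SpiralVector:
    """Vector sum of MU activity embedded in the 3D spiral space.

    Roll-plane directions map to unit vectors in the (forward, roll) plane and
    translation-plane directions to the (forward, translation) plane.  The
    radial poles (0/180 deg), measured in both planes, contribute once with
    the mean of the two planes' rates.
    """
    f = r = t = 0.0
    total = 0.0

    def rate(curve: TuningCurve, i: int) -> float:
        v = curve.mean_rate[i]
        if subtract_spontaneous:
            v = v - curve.spontaneous
        return float(v)

    for curve, axis in ((site.curve_roll, "r"), (site.curve_trans, "t")):
        for i, d in enumerate(curve.directions):
            is_pole = np.isclose(np.mod(d, 360.0), RADIAL_POLES).any()
            if is_pole:
                continue
            w = rate(curve, i)
            f += w * _cosd(d)
            if axis == "r":
                r += w * _sind(d)
            else:
                t += w * _sind(d)
            total += abs(w)

    # shared radial poles: one contribution, averaged over the planes measuring it
    for pole in RADIAL_POLES:
        vals = [
            rate(c, int(np.flatnonzero(
                np.isclose(np.mod(c.directions, 360.0), pole)
            )[0]))
            for c in (site.curve_roll, site.curve_trans)
            if c.has_direction(pole)
        ]
        if vals:
            w = float(np.mean(vals))
            f += w * np.cos(np.deg2rad(pole))
            total += abs(w)

    if total == 0.0 or (f == 0.0 and r == 0.0 and t == 0.0):
        raise ZeroVectorError("all rates zero: no preferred direction")
    return SpiralVector(f=f, r=r, t=t)


def spiral_index(v: SpiralVector) -> float:
    """Spiral index (cos(alpha) - cos(beta)) / (cos(alpha) + cos(beta)).

    -1 indicates strong roll preference (vector along the roll axis), +1
    strong translation preference; 0 means equal alignment with both planes.
    """
    n = v.norm
    if n == 0.0:
        raise ZeroVectorError("zero vector has no spiral index")
    # cos of the angle to a plane = |projection onto the plane| / |v|
    ca = np.sqrt(v.f**2 + v.t**2) / n
    cb = np.sqrt(v.f**2 + v.r**2) / n
    denom = ca + cb
    if denom < 1e-12:
        raise UndefinedIndexError("spiral index undefined: cos(alpha)+cos(beta)=0")
    return float((ca - cb) / denom)


def dprime(curve: TuningCurve) -> float:
    """Discriminability between the two poles of a plane.

    Roll plane: (R_CCW - R_CW) / sqrt((sd_CCW^2 + sd_CW^2)/2) with CW at
    +90 deg and CCW at -90 deg; translation plane: (R_right - R_left) /
    pooled SD with leftward at +90 deg and rightward at -90 deg.  In both
    planes this is (R(-90) - R(+90)) over the pooled SD.  If both SDs are
    zero the result is signed infinity (NaN when the means are also equal).
    """
    i_pos = np.flatnonzero(np.isclose(curve.directions, 90.0))
    i_neg = np.flatnonzero(np.isclose(curve.directions, -90.0) | np.isclose(curve.directions, 270.0))
    if len(i_pos) == 0 or len(i_neg) == 0:
        raise ValueError("curve must include the +/-90 deg conditions")
    num = curve.mean_rate[i_neg[0]] - curve.mean_rate[i_pos[0]]
    pooled = np.sqrt((curve.sd_rate[i_neg[0]] ** 2 + curve.sd_rate[i_pos[0]] ** 2) / 2.0)
    if pooled == 0.0:
        return float(np.sign(num) * np.inf) if num != 0 else float("nan")
    return float(num / pooled)


def roc_discriminability(trials_pos: np.ndarray, trials_neg: np.ndarray) -> float:
    """Area under the ROC curve for two trial-rate distributions.

    Computed as the Mann-Whitney U statistic normalized by n1*n2 (the
    probability, with ties counted half, that a draw from ``trials_pos``
    exceeds one from ``trials_neg``).
    """
    trials_pos = np.asarray(trials_pos, float)
    trials_neg = np.asarray(trials_neg, float)
    if len(trials_pos) < 3 or len(trials_neg) < 3:
        raise ValueError("need at least three trials per side")
    u = stats.mannwhitneyu(trials_pos, trials_neg, alternative="two-sided").statistic
    return float(u / (len(trials_pos) * len(trials_neg)))


def clustering_index(curve_a: TuningCurve, curve_b: TuningCurve) -> float:
    """Pearson r between two same-plane tuning curves (NaN if either is flat).

    Used to quantify clustering along a penetration: callers pair sites at
    depth separations of 100, 200 or 300 um.
    """
    if curve_a.plane != curve_b.plane:
        raise ValueError("curves must come from the same plane")
    if len(curve_a.directions) != len(curve_b.directions) or not np.allclose(
        np.sort(np.mod(curve_a.directions, 360)), np.sort(np.mod(curve_b.directions, 360))
    ):
        raise ValueError("curves must share the same directions")
    order_a = np.argsort(np.mod(curve_a.directions, 360))
    order_b = np.argsort(np.mod(curve_b.directions, 360))
    a = curve_a.mean_rate[order_a]
    b = curve_b.mean_rate[order_b]
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return float("nan")
    return float(stats.pearsonr(a, b).statistic)


def preferred_direction(curve: TuningCurve) -> float:
    """In-plane preferred direction (deg) from the 2D vector sum of rates."""
    th = np.deg2rad(curve.directions)
    x = float(np.sum(curve.mean_rate * np.cos(th)))
    y = float(np.sum(curve.mean_rate * np.sin(th)))
    if x == 0.0 and y == 0.0:
        raise ZeroVectorError("flat curve: no preferred direction")
    return float(np.degrees(np.arctan2(y, x)))


def preferred_axis_sign(preferred_deg: float) -> int:
    """Sign of the stimulus axis favored by a site's preferred direction.

    +1 when the preference leans toward the positive pole of the plane's axis
    (CW rotation, leftward translation; in-plane angle in (0, 180)), -1 toward
    the negative pole.  This single mapping fixes the orientation of signed
    PSE shifts everywhere.
    """
    s = np.sin(np.deg2rad(preferred_deg))
    if abs(s) < 1e-12:
        raise ValueError("preference on the radial axis has no direction sign")
    return 1 if s > 0 else -1


def similarity_index(
    site: MUSite,
    grid_step: float = 1.0,
    fovea_exclusion: float = 0.5,
    angle_cutoff: float = 45.0,
) -> float:
    """RF flow-similarity between the preferred roll and translation patterns.

    Samples the two preferred-flow velocity templates on a grid inside the
    receptive field and returns the fraction of points where the two vectors
    subtend less than ``angle_cutoff`` degrees.  0 means orthogonal-or-opposed
    fields, 1 identical fields.  Grid points within ``fovea_exclusion`` deg of
    the fovea (where the radial/tangential templates vanish) and points where
    either vector is numerically zero are excluded.
    """
    pref_roll = preferred_direction(site.curve_roll)
    pref_trans = preferred_direction(site.curve_trans)
    grid = site.rf.grid(grid_step, fovea_exclusion=fovea_exclusion)
    if len(grid) == 0:
        raise ValueError("receptive field produced no usable grid points")
    v1 = screen_velocity_template(FlowFieldSpec(ROLL, pref_roll), grid).vectors
    v2 = screen_velocity_template(FlowFieldSpec(TRANSLATION, pref_trans), grid).vectors
    n1 = np.linalg.norm(v1, axis=1)
    n2 = np.linalg.norm(v2, axis=1)
    ok = (n1 > 1e-9) & (n2 > 1e-9)
    if not ok.any():
        raise ValueError("all flow vectors degenerate inside the RF")
    cosang = np.einsum("ij,ij->i", v1[ok], v2[ok]) / (n1[ok] * n2[ok])
    ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    return float(np.mean(ang < angle_cutoff))


# ---------------------------------------------------------------------------
# synthetic sites


@dataclass(frozen=True)
class TuningParams:
    """Generative parameters for a synthetic MU site.

    Tuning in each plane is a von Mises bump on a baseline:
    ``rate(theta) = baseline + amp * exp(kappa * (cos(theta - pref) - 1))``.
    Trial rates are Poisson counts over ``duration`` seconds (divided back to
    rates), or Gaussian with variance ``fano * rate`` when ``noise='gaussian'``.
    """

    pref_roll: float = 90.0
    pref_trans: float = 90.0
    amp_roll: float = 40.0
    amp_trans: float = 40.0
    kappa: float = 1.5
    baseline: float = 10.0
    noise: str = "poisson"
    fano: float = 1.0
    n_reps: int = 10
    n_directions: int = 8
    duration: float = 1.0
    depth: float = 0.0
    rf: ReceptiveField = field(
        default_factory=lambda: ReceptiveField((10.0, 5.0), 25.0, 25.0)
    )

    def __post_init__(self) -> None:
        if self.amp_roll < 0 or self.amp_trans < 0 or self.kappa < 0:
            raise ValueError("amplitudes and tuning width must be non-negative")
        if self.baseline < 0 or self.n_reps < 3:
            raise ValueError("baseline >= 0 and n_reps >= 3 required")
        if self.noise not in ("poisson", "gaussian"):
            raise ValueError("noise must be 'poisson' or 'gaussian'")

    def mean_rate(self, plane: str, direction_deg: float) -> float:
        pref = self.pref_roll if plane == ROLL else self.pref_trans
        amp = self.amp_roll if plane == ROLL else self.amp_trans
        d = np.deg2rad(direction_deg - pref)
        return float(self.baseline + amp * np.exp(self.kappa * (np.cos(d) - 1.0)))


def synth_mu(params: TuningParams, seed: int | np.random.Generator, site_id: str = "synthetic") -> MUSite:
    """Draw a synthetic MU site with i.i.d. trial noise (seed-reproducible)."""
    rng = np.random.default_rng(seed)
    directions = np.arange(params.n_directions) * (360.0 / params.n_directions)
    directions = np.where(directions > 180.0, directions - 360.0, directions)
    curves = {}
    for plane in (ROLL, TRANSLATION):
        trials = []
        for d in directions:
            lam = params.mean_rate(plane, d)
            if params.noise == "poisson":
                t = rng.poisson(lam * params.duration, params.n_reps) / params.duration
            else:
                sd = np.sqrt(max(params.fano * lam, 1e-12))
                t = np.clip(rng.normal(lam, sd, params.n_reps), 0.0, None)
            trials.append(t.astype(float))
        curves[plane] = TuningCurve.from_trials(
            plane, directions, trials, spontaneous=params.baseline
        )
    return MUSite(
        site_id=site_id,
        depth=params.depth,
        curve_roll=curves[ROLL],
        curve_trans=curves[TRANSLATION],
        rf=params.rf,
    )


# ---------------------------------------------------------------------------
# site table I/O
#
# CSV: one row per (site, plane, direction) with columns
#   site_id, plane, direction_deg, mean_rate, sd_rate, n_reps, trial_rates
# (trial_rates is a ';'-joined list, empty when unavailable).  A JSON sidecar
# keyed by site_id stores depth, spontaneous rate and RF geometry.


def write_sites(sites: list[MUSite], csv_path, json_path) -> None:
    rows = []
    meta = {}
    for s in sites:
        for curve in (s.curve_roll, s.curve_trans):
            for i, d in enumerate(curve.directions):
                tr = ""
                if curve.trial_rates is not None:
                    tr = ";".join(f"{v:.6g}" for v in curve.trial_rates[i])
                rows.append(
                    {
                        "site_id": s.site_id,
                        "plane": curve.plane,
                        "direction_deg": d,
                        "mean_rate": curve.mean_rate[i],
                        "sd_rate": curve.sd_rate[i],
                        "n_reps": int(curve.n_reps[i]),
                        "trial_rates": tr,
                    }
                )
        meta[s.site_id] = {
            "depth": s.depth,
            "spontaneous_roll": s.curve_roll.spontaneous,
            "spontaneous_trans": s.curve_trans.spontaneous,
            "rf": {
                "center": list(s.rf.center),
                "half_width": s.rf.half_width,
                "half_height": s.rf.half_height,
            },
        }
    pd.DataFrame(rows).to_csv(csv_path, index=False)
    Path(json_path).write_text(json.dumps(meta, indent=1))


def read_sites(csv_path, json_path) -> list[MUSite]:
    df = pd.read_csv(csv_path, dtype={"trial_rates": str}, keep_default_na=False)
    meta = json.loads(Path(json_path).read_text())
    sites = []
    for site_id, g in df.groupby("site_id", sort=False):
        m = meta[str(site_id)]
        curves = {}
        for plane, gp in g.groupby("plane", sort=False):
            trial_rates = None
            if (gp["trial_rates"] != "").all():
                trial_rates = [
                    np.array([float(v) for v in s.split(";")])
                    for s in gp["trial_rates"]
                ]
            curves[plane] = TuningCurve(
                plane=plane,
                directions=gp["direction_deg"].to_numpy(),
                mean_rate=gp["mean_rate"].to_numpy(),
                sd_rate=gp["sd_rate"].to_numpy(),
                n_reps=gp["n_reps"].to_numpy(),
                spontaneous=m["spontaneous_roll" if plane == ROLL else "spontaneous_trans"],
                trial_rates=trial_rates,
            )
        rf = ReceptiveField(
            tuple(m["rf"]["center"]), m["rf"]["half_width"], m["rf"]["half_height"]
        )
        sites.append(
            MUSite(
                site_id=str(site_id),
                depth=m["depth"],
                curve_roll=curves[ROLL],
                curve_trans=curves[TRANSLATION],
                rf=rf,
            )
        )
    return sites
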