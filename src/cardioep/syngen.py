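"""Seeded synthetic-data generators with exact ground truth.

Four generators emulate the raw materials of a rat volume-overload
(aorto-caval fistula, ACF) heart-failure study:

* ``gen_ecg`` — single-lead rodent ECG traces (1 kHz default) built from a
  Gaussian P, a piecewise-linear triphasic QRS, and a Gaussian T, placed so
  the requested P/PR/QRS/QT intervals are realized exactly in the
  noise-free limit.
* ``gen_map_movie`` — epicardial fluorescence movies (500 fps, 80 μm pixels,
  8×8 mm field defaults) of elliptically anisotropic paced propagation with
  an analytic activation-time field and action-potential templates whose
  APD50/APD90 are exact by construction.
* ``gen_cohort`` — per-animal cohort tables drawn from per-group normal
  distributions with cross-variable correlations imposed through a shared
  latent severity factor.
* ``gen_lane_profile`` — 1-D Western-blot lane densitometry profiles as
  sums of Gaussian bands over a polynomial baseline.

Every generator is a pure function of its parameter object (including the
seed): the same parameters give bit-identical output.  Group presets carry
the study's published group means (sham / ACF mild / moderate / severe).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator
from scipy.optimize import least_squares

from .ecg import EcgRecording
from .omap import Movie

__all__ = [
    "EcgSimParams", "EcgGroundTruth", "gen_ecg",
    "MapSimParams", "MapGroundTruth", "gen_map_movie",
    "CohortSimParams", "gen_cohort",
    "LaneProfileTruth", "gen_lane_profile",
    "ECG_PRESETS", "MAP_PRESETS", "default_cohort_params", "GROUPS",
]

GROUPS = ("sham", "mild", "moderate", "severe")


# ---------------------------------------------------------------------------
# ECG
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EcgSimParams:
    """Simulation parameters; defaults are the sham-group means."""

    heart_rate: float = 414.0        # beats/min
    rr_jitter_frac: float = 0.02     # SD of RR as a fraction of the mean
    sampling_rate: float = 1000.0    # Hz
    duration: float = 10.0           # s
    p_amplitude: float = 40.0        # μV
    q_amplitude: float = -40.0       # μV
    r_amplitude: float = 280.0       # μV
    s_amplitude: float = -66.0       # μV
    t_amplitude: float = 70.0        # μV
    p_duration: float = 15.0         # ms
    pr_interval: float = 47.0        # ms, P onset -> QRS onset
    qrs_duration: float = 18.0       # ms
    qt_interval: float = 78.0        # ms, QRS onset -> T end
    baseline_offset: float = 0.0     # μV
    noise_sd: float = 0.0            # μV
    seed: int = 0

    def validate(self) -> None:
        if self.sampling_rate <= 0 or self.duration <= 0 or self.heart_rate <= 0:
            raise ValueError("sampling_rate, duration and heart_rate must be positive")
        if self.pr_interval < self.p_duration:
            raise ValueError("pr_interval must be >= p_duration")
        if self.qt_interval < self.qrs_duration:
            raise ValueError("qt_interval must be >= qrs_duration")
        if self.rr_jitter_frac < 0:
            raise ValueError("rr_jitter_frac must be >= 0")
        mean_rr = 60000.0 / self.heart_rate
        if mean_rr < 1.05 * (self.pr_interval + self.qt_interval):
            raise ValueError(
                f"beat of extent PR+QT = {self.pr_interval + self.qt_interval:.0f} ms "
                f"overlaps the next beat at RR = {mean_rr:.0f} ms")


@dataclass
class EcgGroundTruth:
    """Per-beat fiducial times in ms from the start of the recording."""

    p_onset: np.ndarray
    p_peak: np.ndarray
    p_end: np.ndarray
    qrs_onset: np.ndarray
    r_peak: np.ndarray
    qrs_offset: np.ndarray
    t_peak: np.ndarray
    t_end: np.ndarray
    isoelectric_level: float

    @property
    def n_beats(self) -> int:
        return int(self.p_onset.size)


# group means from the study's summary table; QRS partitioned ~(10.4/72.5/17.1)%
ECG_PRESETS: dict[str, EcgSimParams] = {
    "sham": EcgSimParams(),
    "mild": EcgSimParams(heart_rate=415, p_amplitude=80, p_duration=19,
                         pr_interval=55, qrs_duration=21, qt_interval=82,
                         q_amplitude=-59, r_amplitude=413, s_amplitude=-97,
                         t_amplitude=54),
    "moderate": EcgSimParams(heart_rate=397, p_amplitude=80, p_duration=18,
                             pr_interval=52, qrs_duration=21, qt_interval=80,
                             q_amplitude=-61, r_amplitude=429, s_amplitude=-101,
                             t_amplitude=47),
    "severe": EcgSimParams(heart_rate=403, p_amplitude=61, p_duration=18,
                           pr_interval=58, qrs_duration=22, qt_interval=77,
                           q_amplitude=-75, r_amplitude=520, s_amplitude=-123,
                           t_amplitude=-10),
}

_LEAD_IN_MS = 10.0   # quiet margin before the first P onset


def _trunc_gauss(t: np.ndarray, center: float, half_width: float,
                 amplitude: float) -> np.ndarray:
    """Gaussian truncated at ±half_width (= 2σ) and shifted to reach exactly
    zero at the window edges, rescaled so the peak equals ``amplitude``."""
    sigma = half_width / 2.0
    u = (t - center) / sigma
    edge = np.exp(-2.0)
    y = (np.exp(-0.5 * u * u) - edge) / (1.0 - edge)
    y[np.abs(u) > 2.0] = 0.0
    return amplitude * y


def _qrs_wave(t: np.ndarray, onset: float, p: EcgSimParams) -> np.ndarray:
    d = p.qrs_duration
    nodes_t = onset + d * np.array([0.0, 0.15, 0.40, 0.75, 1.0])
    nodes_v = np.array([0.0, p.q_amplitude, p.r_amplitude, p.s_amplitude, 0.0])
    y = np.interp(t, nodes_t, nodes_v, left=0.0, right=0.0)
    y[(t < onset) | (t > onset + d)] = 0.0
    return y


def gen_ecg(params: EcgSimParams) -> tuple[EcgRecording, EcgGroundTruth]:
    """Generate a synthetic single-lead ECG and its fiducial ground truth.

    Beats are placed at lognormally jittered RR intervals; only beats fully
    contained in the recording (P onset ≥ 0, T end ≤ duration) are emitted
    and listed in the truth.
    """
    p = params
    p.validate()
    rng = np.random.default_rng(p.seed)
    fs = p.sampling_rate
    n = int(round(p.duration * fs))
    t = np.arange(n) / fs * 1000.0          # ms
    v = np.full(n, p.baseline_offset, dtype=float)

    mean_rr = 60000.0 / p.heart_rate
    dur_ms = p.duration * 1000.0

    # QRS-onset times
    onsets = []
    t0 = p.pr_interval + _LEAD_IN_MS
    while t0 + p.qt_interval <= dur_ms:
        onsets.append(t0)
        if p.rr_jitter_frac > 0:
            rr = mean_rr * np.exp(rng.normal(0.0, p.rr_jitter_frac))
        else:
            rr = mean_rr
        t0 = t0 + rr
    onsets = np.asarray(onsets)

    qd = p.qrs_duration
    st_gap = 0.25 * (p.qt_interval - qd)
    t_dur = p.qt_interval - qd - st_gap
    for T0 in onsets:
        lo = max(0, int((T0 - p.pr_interval - 1) * fs / 1000.0))
        hi = min(n, int((T0 + p.qt_interval + 1) * fs / 1000.0) + 1)
        ts = t[lo:hi]
        seg = np.zeros(ts.size)
        seg += _trunc_gauss(ts, T0 - p.pr_interval + p.p_duration / 2.0,
                            p.p_duration / 2.0, p.p_amplitude)
        seg += _qrs_wave(ts, T0, p)
        seg += _trunc_gauss(ts, T0 + qd + st_gap + t_dur / 2.0,
                            t_dur / 2.0, p.t_amplitude)
        v[lo:hi] += seg

    if p.noise_sd > 0:
        v += rng.normal(0.0, p.noise_sd, size=n)

    truth = EcgGroundTruth(
        p_onset=onsets - p.pr_interval,
        p_peak=onsets - p.pr_interval + p.p_duration / 2.0,
        p_end=onsets - p.pr_interval + p.p_duration,
        qrs_onset=onsets.copy(),
        r_peak=onsets + 0.40 * qd,
        qrs_offset=onsets + qd,
        t_peak=onsets + qd + st_gap + t_dur / 2.0,
        t_end=onsets + p.qt_interval,
        isoelectric_level=p.baseline_offset,
    )
    return EcgRecording(v, fs), truth


# ---------------------------------------------------------------------------
# optical-mapping movies
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MapSimParams:
    """Movie simulation parameters; defaults give the study's acquisition
    geometry (8×8 mm field at 80 μm pixels, 500 fps, 300 ms pacing from the
    field center) with the sham conduction velocities and APDs."""

    n_rows: int = 100
    n_cols: int = 100
    pixel_size: float = 80.0         # μm
    frame_interval: float = 2.0      # ms (500 fps)
    n_frames: int = 160
    pacing_site: tuple[int, int] = (50, 50)
    pacing_cycle: float = 300.0      # ms
    first_stim: float = 10.0         # ms
    cv_long: float = 102.0           # cm/s
    cv_trans: float = 14.6           # cm/s
    fiber_angle: float = 0.0         # degrees, CCW from the image row axis
    ap_amplitude: float = 1.0        # a.u.
    apd50: float = 56.0              # ms
    apd90: float = 94.0              # ms
    upstroke_rise: float = 4.0       # ms; two frame intervals at 500 fps
    noise_sd: float = 0.0            # a.u.
    block_mask: np.ndarray | None = None    # bool (n_rows, n_cols)
    seed: int = 0

    def validate(self) -> None:
        if not (self.cv_long >= self.cv_trans > 0):
            raise ValueError("require cv_long >= cv_trans > 0")
        if not (self.apd90 >= self.apd50 > 0):
            raise ValueError("require apd90 >= apd50 > 0")
        r, c = self.pacing_site
        if not (0 <= r < self.n_rows and 0 <= c < self.n_cols):
            raise ValueError("pacing_site outside grid")
        if self.frame_interval <= 0 or self.n_frames < 2:
            raise ValueError("need frame_interval > 0 and n_frames >= 2")
        if self.upstroke_rise <= 0 or self.upstroke_rise >= self.apd50:
            raise ValueError("upstroke_rise must be in (0, apd50)")
        if self.block_mask is not None:
            bm = np.asarray(self.block_mask, bool)
            if bm.shape != (self.n_rows, self.n_cols):
                raise ValueError("block_mask shape mismatch")


@dataclass
class MapGroundTruth:
    activation_time: np.ndarray      # ms from recording start (first stimulus)
    apd50_field: np.ndarray          # ms
    apd90_field: np.ndarray          # ms
    valid_mask: np.ndarray           # False inside block


def _elliptical_activation(p: MapSimParams) -> np.ndarray:
    """Analytic activation time (ms, relative to a stimulus at t=0)."""
    r0, c0 = p.pacing_site
    dr, dc = np.meshgrid(np.arange(p.n_rows) - r0, np.arange(p.n_cols) - c0,
                         indexing="ij")
    um = p.pixel_size
    alpha = np.deg2rad(p.fiber_angle)
    a = (dr * np.cos(alpha) + dc * np.sin(alpha)) * um / 1e4     # cm, along fiber
    b = (-dr * np.sin(alpha) + dc * np.cos(alpha)) * um / 1e4    # cm, across
    return np.sqrt((a / p.cv_long) ** 2 + (b / p.cv_trans) ** 2) * 1000.0


def ap_template(p: MapSimParams, dt: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Densely sampled AP shape (time rel. activation, fraction of amplitude).

    A linear upstroke of duration ``upstroke_rise`` centered on t=0 (so the
    derivative maximum sits exactly at the truth activation time), followed
    by a monotone PCHIP repolarization pinned to (apd50, 0.5) and
    (apd90, 0.1) so the noise-free APDs are exact by construction.
    """
    half = p.upstroke_rise / 2.0
    tail = p.apd90 + 0.5 * (p.apd90 - p.apd50)
    dec_x = np.array([half, p.apd50, p.apd90, tail])
    dec = PchipInterpolator(dec_x, np.array([1.0, 0.5, 0.1, 0.0]))
    xs_up = np.array([-half, half])
    xs_dec = np.arange(half + dt, tail + dt, dt)
    xs = np.concatenate([xs_up, xs_dec])
    ys = np.concatenate([[0.0, 1.0], np.clip(dec(np.minimum(xs_dec, tail)), 0, None)])
    return xs, ys


def gen_map_movie(params: MapSimParams) -> tuple[Movie, MapGroundTruth]:
    """Generate an anisotropic paced-propagation movie plus ground truth.

    Per-pixel trace = AP template delayed by the analytic elliptical
    activation time, repeated for every stimulus, plus white noise.  Pixels
    under ``block_mask`` carry baseline + noise only.
    """
    p = params
    p.validate()
    rng = np.random.default_rng(p.seed)

    travel = _elliptical_activation(p)
    act = p.first_stim + travel
    duration = (p.n_frames - 1) * p.frame_interval
    valid = np.ones((p.n_rows, p.n_cols), bool)
    if p.block_mask is not None:
        valid &= ~np.asarray(p.block_mask, bool)
    reach = act + p.upstroke_rise / 2.0
    if np.any(reach[valid] > duration):
        bad = np.argwhere(valid & (reach > duration))
        i, j = min(map(tuple, bad), key=lambda ij: act[ij])
        raise ValueError(
            f"pixel ({i}, {j}) activates at {act[i, j]:.1f} ms, beyond the "
            f"movie duration of {duration:.1f} ms; increase n_frames or the "
            "conduction velocities")

    xs, ys = ap_template(p)
    tf = np.arange(p.n_frames) * p.frame_interval
    stim_times = [p.first_stim + k * p.pacing_cycle
                  for k in range(max(1, int(np.ceil((duration - p.first_stim)
                                                    / p.pacing_cycle))))]
    stim_times = [s for s in stim_times if s <= duration]

    data = np.zeros((p.n_frames, p.n_rows, p.n_cols))
    for s in stim_times:
        tt = tf[:, None, None] - (travel[None] + s)
        data += np.interp(tt, xs, ys, left=0.0, right=0.0)
    data *= p.ap_amplitude
    data[:, ~valid] = 0.0
    if p.noise_sd > 0:
        data += rng.normal(0.0, p.noise_sd, size=data.shape)

    movie = Movie(data=data, frame_interval=p.frame_interval,
                  pixel_size=p.pixel_size, stim_times=list(stim_times),
                  pacing_site=p.pacing_site, polarity=+1)
    truth = MapGroundTruth(
        activation_time=act,
        apd50_field=np.full_like(act, p.apd50),
        apd90_field=np.full_like(act, p.apd90),
        valid_mask=valid,
    )
    return movie, truth


# optical-mapping presets: group CV/APD means from the summary table
MAP_PRESETS: dict[str, MapSimParams] = {
    "sham": MapSimParams(),
    "mild": MapSimParams(cv_long=184.0, cv_trans=32.0, apd50=69.0, apd90=101.0),
    "moderate": MapSimParams(cv_long=136.0, cv_trans=13.7, apd50=75.0, apd90=121.0),
    "severe": MapSimParams(cv_long=102.0, cv_trans=12.3, apd50=65.0, apd90=97.0),
}


# ---------------------------------------------------------------------------
# cohort tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortSimParams:
    """Cohort generator parameters.

    ``variables`` maps a variable name to its per-group ``(mean, sd)``;
    ``correlations`` maps a frozenset-able pair of variable names to the
    target Pearson correlation, imposed through a single shared latent
    severity factor per animal (corr(u, v) = λ_u λ_v).
    """

    group_sizes: dict[str, int]
    variables: dict[str, dict[str, tuple[float, float]]]
    correlations: dict[tuple[str, str], float] = field(default_factory=dict)
    seed: int = 0

    def validate(self) -> None:
        for g, n in self.group_sizes.items():
            if n < 0:
                raise ValueError(f"group size for {g!r} must be >= 0")
        for name, per_group in self.variables.items():
            for g, (_, sd) in per_group.items():
                if sd < 0:
                    raise ValueError(f"SD of {name!r} in {g!r} must be >= 0")
        for (u, v), rho in self.correlations.items():
            if abs(rho) > 1:
                raise ValueError(f"|rho| <= 1 required for ({u}, {v})")
            if u not in self.variables or v not in self.variables:
                raise ValueError(f"correlation names unknown variable in ({u}, {v})")


def _solve_loadings(variables: list[str],
                    pairs: dict[tuple[str, str], float]) -> dict[str, float]:
    """Single-factor loadings λ with λ_u λ_v = rho_uv for the requested pairs."""
    if not pairs:
        return {v: 0.0 for v in variables}
    involved = sorted({n for pair in pairs for n in pair})
    index = {n: i for i, n in enumerate(involved)}

    def resid(lam):
        return [lam[index[u]] * lam[index[v]] - rho
                for (u, v), rho in pairs.items()]

    x0 = np.full(len(involved), 0.5)
    # sign heuristic from the first pair touching each variable
    for (u, v), rho in pairs.items():
        x0[index[u]] = np.sqrt(abs(rho))
        x0[index[v]] = np.sign(rho) * np.sqrt(abs(rho))
        break
    sol = least_squares(resid, x0, bounds=(-1, 1))
    if np.max(np.abs(sol.fun)) > 1e-6:
        raise ValueError(
            "requested correlation structure is not attainable with a single "
            "latent factor (correlation matrix not positive semidefinite)")
    lam = {v: 0.0 for v in variables}
    lam.update({n: float(sol.x[i]) for n, i in index.items()})
    return lam


def gen_cohort(params: CohortSimParams) -> pd.DataFrame:
    """Draw a tidy per-animal cohort table.

    One row per animal with ``animal_id``, ``cohort`` (sham/ACF), ``group``
    and one column per variable.  Derived columns ``heart_weight``, ``hbwr``
    and ``lungs_bw`` are appended whenever their parents are present, so the
    anatomical identities (HW = LV + septum + RV, HBWR = HW/BW × 1000) hold
    exactly.
    """
    p = params
    p.validate()
    rng = np.random.default_rng(p.seed)
    lam = _solve_loadings(list(p.variables), dict(p.correlations))

    rows = []
    counter = itertools.count(1)
    for g, n_g in p.group_sizes.items():
        for _ in range(n_g):
            z = rng.standard_normal()
            row = {"animal_id": f"{g}-{next(counter):03d}",
                   "cohort": "sham" if g == "sham" else "ACF",
                   "group": g}
            for name, per_group in p.variables.items():
                if g not in per_group:
                    row[name] = np.nan
                    continue
                mu, sd = per_group[g]
                lv = lam[name]
                eps = rng.standard_normal()
                row[name] = mu + sd * (lv * z + np.sqrt(1.0 - lv * lv) * eps)
            rows.append(row)
    df = pd.DataFrame(rows)

    parts = ("lv_weight", "septum_weight", "rv_weight")
    if all(c in df.columns for c in parts):
        df["heart_weight"] = df[list(parts)].sum(axis=1)
        if "body_weight" in df.columns:
            df["hbwr"] = df["heart_weight"] / df["body_weight"] * 1000.0
    if {"lungs_weight", "body_weight"} <= set(df.columns):
        df["lungs_bw"] = df["lungs_weight"] / df["body_weight"] * 1000.0
    return df


def default_cohort_params(seed: int = 0,
                          group_sizes: dict[str, int] | None = None,
                          ) -> CohortSimParams:
    """Study-condition cohort: group sizes n = (10, 5, 8, 4) and per-group
    means ± SD from the summary table.  Heart weight and HBWR are derived
    from the ventricular components rather than drawn.  Protein densities
    (relative to the sham mean) follow the monotone decline reported for
    connexin43 and the innervation markers; connexin43 is negatively
    coupled to right-ventricular weight through the latent severity factor.
    """
    gs = group_sizes or {"sham": 10, "mild": 5, "moderate": 8, "severe": 4}

    def per_group(sham, mild, moderate, severe):
        return {"sham": sham, "mild": mild, "moderate": moderate, "severe": severe}

    variables = {
        "body_weight": per_group((578, 48), (610, 46), (581, 48), (595, 45)),
        "lv_weight": per_group((1.03, 0.15), (1.74, 0.08), (1.95, 0.19), (2.27, 0.24)),
        "septum_weight": per_group((0.31, 0.09), (0.54, 0.08), (0.56, 0.08), (0.70, 0.05)),
        "rv_weight": per_group((0.31, 0.03), (0.62, 0.04), (0.65, 0.11), (0.93, 0.10)),
        "lungs_weight": per_group((1.91, 0.06), (2.42, 0.40), (2.59, 0.42), (3.50, 0.40)),
        "heart_rate": per_group((414, 39), (415, 38), (397, 40), (403, 36)),
        "p_amplitude": per_group((40, 27), (80, 20), (80, 29), (61, 28)),
        "p_duration": per_group((15, 1.5), (19, 1.4), (18, 1.6), (18, 1.4)),
        "pr_duration": per_group((47, 3), (55, 4), (52, 3), (58, 3)),
        "qrs_duration": per_group((18, 1.2), (21, 1.4), (21, 1.3), (22, 1.2)),
        "qt_duration": per_group((78, 9), (82, 8), (80, 8), (77, 10)),
        "qrs_sum": per_group((386, 210), (569, 200), (591, 209), (718, 190)),
        "t_amplitude": per_group((70, 36), (54, 38), (47, 37), (-10, 47)),
        "st_height": per_group((16, 63), (-34, 60), (-33, 61), (-121, 57)),
        "apd50": per_group((56, 12), (69, 12), (75, 13), (65, 12)),
        "apd90": per_group((94, 21), (101, 20), (121, 21), (97, 19)),
        "cv_min": per_group((14.6, 11.1), (32, 7.4), (13.7, 7.7), (12.3, 7.1)),
        "cv_max": per_group((102, 72), (184, 48), (136, 50), (102, 47)),
        # relative densities, sham mean = 1; synthetic monotone decline
        "cx43": per_group((1.00, 0.12), (0.75, 0.10), (0.55, 0.10), (0.35, 0.08)),
        "p_cx43": per_group((1.00, 0.15), (0.70, 0.12), (0.50, 0.10), (0.30, 0.08)),
        "chat": per_group((1.00, 0.15), (0.80, 0.12), (0.60, 0.10), (0.35, 0.10)),
        "th": per_group((1.00, 0.15), (0.85, 0.12), (0.65, 0.10), (0.45, 0.10)),
    }
    correlations = {("cx43", "rv_weight"): -0.7}
    return CohortSimParams(group_sizes=gs, variables=variables,
                           correlations=correlations, seed=seed)


# ---------------------------------------------------------------------------
# lane profiles
# ---------------------------------------------------------------------------

@dataclass
class LaneProfileTruth:
    areas: list[float]
    centers: list[float]
    widths: list[float]
    overlap_warning: bool


def gen_lane_profile(bands: list[tuple[float, float, float]],
                     baseline: tuple[float, ...] = (0.0,),
                     noise_sd: float = 0.0,
                     length: int = 200,
                     seed: int = 0) -> tuple[np.ndarray, LaneProfileTruth]:
    """1-D lane profile = sum of Gaussian bands + polynomial baseline + noise.

    ``bands`` is a list of (center, width, area) with width the Gaussian SD
    in position units; ``baseline`` holds polynomial coefficients in
    ascending order.  Truth flags overlap when two band centers are closer
    than half the sum of their widths, meaning the truth areas are not
    independently recoverable by windowed integration.
    """
    for _, w, _ in bands:
        if w <= 0:
            raise ValueError("band widths must be positive")
    rng = np.random.default_rng(seed)
    x = np.arange(length, dtype=float)
    y = np.polyval(list(baseline)[::-1], x)
    for c, w, a in bands:
        y += a / (w * np.sqrt(2 * np.pi)) * np.exp(-0.5 * ((x - c) / w) ** 2)
    if noise_sd > 0:
        y += rng.normal(0.0, noise_sd, size=length)

    overlap = False
    for (c1, w1, _), (c2, w2, _) in itertools.combinations(bands, 2):
        if abs(c1 - c2) < 0.5 * (w1 + w2):
            overlap = True
    truth = LaneProfileTruth(areas=[a for _, _, a in bands],
                             centers=[c for c, _, _ in bands],
                             widths=[w for _, w, _ in bands],
                             overlap_warning=overlap)
    return y, truth
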