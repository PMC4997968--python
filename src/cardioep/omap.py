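"""Epicardial optical-mapping analysis.

Processing chain for voltage-dye fluorescence movies of paced hearts:
temporal band-pass + 3×3 spatial median filtering, per-pixel activation
detection at the maximal dV/dt with parabolic sub-frame refinement,
isochrone banding, ROI action-potential duration (APD50/APD90), a wedge
regression scan for directional conduction velocity and anisotropy, and
connected-component detection of conduction block.

Times are ms, distances derived from pixel index × pixel size (μm),
velocities cm/s.  Pixel coordinates are 0-based (row, col).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy import signal as sps

__all__ = [
    "Movie", "ActivationMap", "IsochroneMap", "ApdResult", "CvResult",
    "BlockComponent", "preprocess", "activation_map", "isochrones",
    "measure_apd", "measure_cv", "detect_block",
]


@dataclass
class Movie:
    """T×H×W fluorescence stack with acquisition metadata."""

    data: np.ndarray                 # (n_frames, n_rows, n_cols), a.u.
    frame_interval: float            # ms
    pixel_size: float                # μm
    stim_times: list[float]          # ms
    pacing_site: tuple[int, int]     # (row, col)
    polarity: int = +1               # +1: depolarization = signal increase

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3 or self.data.shape[0] < 2:
            raise ValueError("data must be (T>=2, H, W)")
        if self.frame_interval <= 0 or self.pixel_size <= 0:
            raise ValueError("frame_interval and pixel_size must be positive")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape[1:]

    @property
    def duration(self) -> float:
        return (self.n_frames - 1) * self.frame_interval


@dataclass
class ActivationMap:
    activation_time: np.ndarray      # ms relative to reference_stim; NaN invalid
    max_dvdt: np.ndarray             # a.u./ms
    valid_mask: np.ndarray
    reference_stim: float            # ms
    pixel_size: float                # μm
    pacing_site: tuple[int, int] | None = None
    invalid_reason: dict[str, np.ndarray] = field(default_factory=dict)


@dataclass
class IsochroneMap:
    band_index: np.ndarray           # int; -1 on invalid pixels
    band_width: float                # ms
    boundaries: list[np.ndarray] = field(default_factory=list)  # (N,2) row/col polylines


@dataclass
class ApdResult:
    roi_id: str
    apd50: float                     # ms
    apd90: float                     # ms
    n_pixels: int


@dataclass
class CvResult:
    cv_max: float                    # cm/s
    cv_min: float                    # cm/s
    angle_max: float                 # degrees, [0, 180)
    angle_min: float
    anisotropy: float                # cv_max / cv_min
    fit_r2_max: float
    fit_r2_min: float


@dataclass
class BlockComponent:
    area: int
    bbox: tuple[int, int, int, int]  # (row0, col0, row1, col1), half-open
    mask: np.ndarray


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def preprocess(movie: Movie, band: tuple[float, float] | None = (0.5, 100.0),
               order: int = 4, median_size: int = 3) -> Movie:
    """Zero-phase temporal band-pass per pixel, then a per-frame spatial
    median filter with reflect padding; polarity is normalized so
    depolarization is positive.  Output shape is unchanged."""
    fs = 1000.0 / movie.frame_interval
    data = movie.data * movie.polarity
    if band is not None:
        lo, hi = band
        nyq = fs / 2.0
        if hi >= nyq or lo >= nyq:
            raise ValueError(f"band-pass cutoffs {band} must be below the "
                             f"Nyquist frequency {nyq:.1f} Hz")
        sos = sps.butter(order, [lo, hi], btype="bandpass", fs=fs, output="sos")
        flat = data.reshape(movie.n_frames, -1)
        data = sps.sosfiltfilt(sos, flat, axis=0).reshape(movie.data.shape)
    if median_size and median_size > 1:
        data = ndimage.median_filter(data, size=(1, median_size, median_size),
                                     mode="reflect")
    return Movie(data=data, frame_interval=movie.frame_interval,
                 pixel_size=movie.pixel_size, stim_times=list(movie.stim_times),
                 pacing_site=movie.pacing_site, polarity=+1)


def normalize_polarity(movie: Movie) -> Movie:
    """Polarity normalization and spatial median filtering without the
    temporal band-pass (the preferred input for APD measurement)."""
    return preprocess(movie, band=None)


# ---------------------------------------------------------------------------
# activation detection
# ---------------------------------------------------------------------------

def _cycle_window(movie: Movie, stim_index: int) -> tuple[int, int, float]:
    if not (0 <= stim_index < len(movie.stim_times)):
        raise ValueError(f"stimulus index {stim_index} out of range "
                         f"(movie has {len(movie.stim_times)} stimuli)")
    stim = movie.stim_times[stim_index]
    f0 = int(np.floor(stim / movie.frame_interval))
    if stim_index + 1 < len(movie.stim_times):
        # stop two frames short of the next stimulus so its upstroke (which
        # may begin fractionally early at frame resolution) stays outside
        nxt = movie.stim_times[stim_index + 1]
        f1 = max(f0 + 3, int(np.floor(nxt / movie.frame_interval)) - 1)
    else:
        f1 = movie.n_frames
    f1 = min(movie.n_frames, f1)
    return f0, f1, stim


def activation_map(movie: Movie, stim_index: int = 0, snr_k: float = 4.0,
                   amp_frac: float = 0.1) -> ActivationMap:
    """Per-pixel activation time within one pacing cycle.

    Activation is the time of the maximal forward-difference derivative,
    refined by parabolic interpolation over the three derivative samples
    around the discrete maximum (sub-frame precision).  Pixels whose
    upstroke amplitude is below ``snr_k`` × the pre-stimulus noise SD, or
    below ``amp_frac`` × the median upstroke amplitude, are invalid with
    reason "low SNR".
    """
    f0n, f1, stim = _cycle_window(movie, stim_index)
    if f1 - f0n < 3:
        raise ValueError("chosen stimulus has fewer than 3 frames of data")
    # start two frames early so upstrokes right after the stimulus keep the
    # left neighbor of their derivative maximum (needed for sub-frame fit)
    f0 = max(0, f0n - 2)
    win = movie.data[f0:f1]
    dt = movie.frame_interval

    d = np.diff(win, axis=0)                       # (F-1, H, W)
    j = np.argmax(d, axis=0)
    dmax = np.take_along_axis(d, j[None], axis=0)[0]

    # parabolic vertex through the three derivative samples around the max
    jm = np.clip(j - 1, 0, d.shape[0] - 1)
    jp = np.clip(j + 1, 0, d.shape[0] - 1)
    dm = np.take_along_axis(d, jm[None], axis=0)[0]
    dp = np.take_along_axis(d, jp[None], axis=0)[0]
    denom = dm - 2.0 * dmax + dp
    with np.errstate(divide="ignore", invalid="ignore"):
        delta = np.where(np.abs(denom) > 1e-12 * np.maximum(np.abs(dmax), 1e-300),
                         0.5 * (dm - dp) / denom, 0.0)
    delta = np.clip(delta, -0.5, 0.5)
    delta[(j == 0) | (j == d.shape[0] - 1)] = 0.0

    # the forward difference between frames k and k+1 localizes the upstroke
    # at the interval center (k + 0.5) Δ
    act = (f0 + j + 0.5 + delta) * dt - stim

    # validity: upstroke amplitude vs. pre-stimulus noise
    if f0n >= 2:
        pre = movie.data[:f0n]
        noise_sd = pre.std(axis=0, ddof=1) if f0n > 2 else pre.std(axis=0)
        baseline = pre.mean(axis=0)
    else:
        noise_sd = np.zeros(movie.shape)
        baseline = win[0]
    amp = win.max(axis=0) - baseline
    thresh = np.maximum(snr_k * noise_sd, amp_frac * max(np.median(amp), 0.0))
    low_snr = amp < thresh
    valid = ~low_snr & (act >= 0)

    act_out = np.where(valid, act, np.nan)
    return ActivationMap(activation_time=act_out, max_dvdt=dmax / dt,
                         valid_mask=valid, reference_stim=stim,
                         pixel_size=movie.pixel_size,
                         pacing_site=movie.pacing_site,
                         invalid_reason={"low SNR": low_snr})


def activation_brute_force(movie: Movie, stim_index: int = 0) -> np.ndarray:
    """Discrete activation oracle: exhaustive argmax of finite differences,
    no interpolation.  Returns ms relative to the stimulus."""
    f0, f1, stim = _cycle_window(movie, stim_index)
    win = movie.data[f0:f1]
    n_fr, h, w = win.shape
    out = np.empty((h, w))
    for r in range(h):
        for c in range(w):
            best, bj = -np.inf, 0
            for k in range(n_fr - 1):
                dd = win[k + 1, r, c] - win[k, r, c]
                if dd > best:
                    best, bj = dd, k
            out[r, c] = (f0 + bj + 0.5) * movie.frame_interval - stim
    return out


# ---------------------------------------------------------------------------
# isochrones
# ---------------------------------------------------------------------------

def isochrones(act: ActivationMap, band_width: float = 2.0) -> IsochroneMap:
    """Integer activation-time bands (``floor(t / band_width)``) plus band
    boundary polylines for plotting; invalid pixels get band −1."""
    t = act.activation_time
    band = np.full(t.shape, -1, dtype=int)
    band[act.valid_mask] = np.floor(t[act.valid_mask] / band_width).astype(int)

    boundaries: list[np.ndarray] = []
    if np.any(act.valid_mask):
        from skimage import measure as skmeasure
        filled = np.where(act.valid_mask, t, np.nanmax(t[act.valid_mask]) + band_width)
        lo = np.nanmin(t[act.valid_mask])
        hi = np.nanmax(t[act.valid_mask])
        for level in np.arange(np.ceil(lo / band_width) * band_width, hi, band_width):
            boundaries.extend(skmeasure.find_contours(filled, level))
    return IsochroneMap(band_index=band, band_width=band_width,
                        boundaries=boundaries)


# ---------------------------------------------------------------------------
# APD
# ---------------------------------------------------------------------------

def measure_apd(movie: Movie, act: ActivationMap,
                rois: dict[str, tuple[int, int, int, int]],
                levels: tuple[int, ...] = (50, 90),
                stim_index: int = 0,
                edge_frac: float = 0.4) -> dict[str, ApdResult]:
    """ROI action-potential durations from the aligned averaged trace.

    For each ROI (row0, row1, col0, col1, half-open), valid pixel traces are
    aligned on their activation frame and averaged; amplitude = peak −
    pre-upstroke baseline, and APD_x is the time from activation to the last
    crossing of baseline + (1 − x/100) × amplitude before the next stimulus,
    linearly interpolated between frames.  A fall of more than ``edge_frac``
    of the amplitude between adjacent frames is treated as an under-resolved
    instantaneous edge: every level crossing inside it is assigned the
    segment midpoint (this makes square-pulse APDs exact).
    """
    f0, f1, stim = _cycle_window(movie, stim_index)
    dt = movie.frame_interval
    out: dict[str, ApdResult] = {}
    for roi_id, (r0, r1, c0, c1) in rois.items():
        if not (0 <= r0 < r1 <= movie.shape[0] and 0 <= c0 < c1 <= movie.shape[1]):
            raise ValueError(f"ROI {roi_id!r} outside the movie grid")
        sub_valid = act.valid_mask[r0:r1, c0:c1]
        if not np.any(sub_valid):
            raise ValueError(f"ROI {roi_id!r} contains no valid pixels")
        rr, cc = np.nonzero(sub_valid)
        rr, cc = rr + r0, cc + c0
        acts = act.activation_time[rr, cc] + stim          # ms, absolute
        shifts = np.round(acts / dt).astype(int)           # integer-frame alignment

        pre = int(np.ceil(10.0 / dt))                      # 10 ms of baseline
        m_lo = -pre
        m_hi = int(np.floor((f1 - 1) - shifts.max()))
        if m_hi - m_lo < 4:
            raise ValueError(f"ROI {roi_id!r}: not enough frames after activation")
        m = np.arange(m_lo, m_hi + 1)
        frames = shifts[:, None] + m[None, :]
        ok = frames[:, 0] >= 0
        frames = np.clip(frames, 0, movie.n_frames - 1)
        traces = movie.data[frames, rr[:, None], cc[:, None]]
        avg = traces[ok].mean(axis=0) if np.any(ok) else traces.mean(axis=0)
        # mean sub-frame remainder: where activation truly sits on the m-grid
        rho = float(np.mean(acts - shifts * dt))

        tgrid = m * dt
        base_sel = tgrid < -2.0
        baseline = float(avg[base_sel].mean()) if np.any(base_sel) else float(avg[0])
        peak_idx = int(np.argmax(avg))
        amplitude = float(avg[peak_idx] - baseline)
        if amplitude <= 0:
            raise ValueError(f"ROI {roi_id!r}: non-positive upstroke amplitude")

        apds: dict[int, float] = {}
        for x in levels:
            thr = baseline + (1.0 - x / 100.0) * amplitude
            k_cross = None
            for k in range(avg.size - 2, peak_idx - 1, -1):
                if avg[k] >= thr and avg[k + 1] < thr:
                    k_cross = k
                    break
            if k_cross is None:
                raise ValueError(f"ROI {roi_id!r}: trace never recrosses the "
                                 f"{x}% level before the next stimulus")
            drop = avg[k_cross] - avg[k_cross + 1]
            if drop > edge_frac * amplitude:
                t_cross = 0.5 * (tgrid[k_cross] + tgrid[k_cross + 1])
            else:
                frac = (avg[k_cross] - thr) / drop
                t_cross = tgrid[k_cross] + frac * dt
            apds[x] = t_cross - rho
        out[roi_id] = ApdResult(roi_id=roi_id, apd50=apds.get(50, np.nan),
                                apd90=apds.get(90, np.nan),
                                n_pixels=int(sub_valid.sum()))
    return out


# ---------------------------------------------------------------------------
# conduction velocity
# ---------------------------------------------------------------------------

def measure_cv(act: ActivationMap, pacing_site: tuple[int, int] | None = None,
               angular_step: float = 5.0, r_min: float = 0.4, r_max: float = 3.0,
               min_pixels: int = 5, max_speed: float = 2000.0) -> CvResult:
    """Directional conduction velocity by a wedge regression scan.

    For each direction θ in 0..180°−step, valid pixels in the annulus
    ``r_min``..``r_max`` (mm) within ±step/2 of the line {θ, θ+180°} are
    collected and activation time is regressed on radial distance from the
    pacing site; the directional speed is 1/slope.  cv_max is the fastest
    direction; cv_min is the direction orthogonal to it (long-axis /
    short-axis convention), and anisotropy = cv_max / cv_min.
    """
    site = pacing_site or act.pacing_site
    if site is None:
        raise ValueError("pacing site required for CV measurement")
    r0, c0 = site
    h, w = act.activation_time.shape
    dr, dc = np.meshgrid(np.arange(h) - r0, np.arange(w) - c0, indexing="ij")
    mm = act.pixel_size / 1000.0
    r = np.hypot(dr, dc) * mm
    phi = np.degrees(np.arctan2(dc, dr)) % 180.0

    annulus = act.valid_mask & (r >= r_min) & (r <= r_max)
    if annulus.sum() < 10:
        raise ValueError("insufficient coverage: fewer than 10 valid pixels "
                         "in the fitting annulus")

    thetas = np.arange(0.0, 180.0, angular_step)
    speeds = np.full(thetas.size, np.nan)
    r2s = np.full(thetas.size, np.nan)
    for i, th in enumerate(thetas):
        dang = np.abs(phi - th)
        dang = np.minimum(dang, 180.0 - dang)
        sel = annulus & (dang <= angular_step / 2.0)
        if sel.sum() < min_pixels:
            continue
        rs = r[sel] / 10.0                       # cm
        ts = act.activation_time[sel]            # ms
        if np.ptp(rs) <= 0:
            continue
        A = np.vstack([rs, np.ones_like(rs)]).T
        (slope, intercept), res, *_ = np.linalg.lstsq(A, ts, rcond=None)
        if slope <= 1000.0 / max_speed:
            # flat or inverted wavefront: no finite physiological speed
            warnings.warn(f"non-positive slope in direction {th:.0f} deg; skipped")
            continue
        pred = A @ [slope, intercept]
        ss_tot = np.sum((ts - ts.mean()) ** 2)
        r2s[i] = 1.0 - np.sum((ts - pred) ** 2) / ss_tot if ss_tot > 0 else 1.0
        speeds[i] = 1000.0 / slope               # cm/s  (ms/cm -> cm/s)

    if np.all(np.isnan(speeds)):
        raise ValueError("insufficient coverage: no direction produced a "
                         "positive-slope fit")
    i_max = int(np.nanargmax(speeds))
    th_max = thetas[i_max]
    # refine the fast-axis angle below the scan step: for elliptical spread
    # 1/v(θ)^2 is sinusoidal in 2θ, locally parabolic around its minimum
    im = (i_max - 1) % thetas.size
    ip = (i_max + 1) % thetas.size
    if np.isfinite(speeds[im]) and np.isfinite(speeds[ip]):
        g = 1.0 / speeds[np.array([im, i_max, ip])] ** 2
        denom = g[0] - 2.0 * g[1] + g[2]
        if denom > 0:
            off = 0.5 * (g[0] - g[2]) / denom
            th_max = float((thetas[i_max] + np.clip(off, -1, 1) * angular_step)
                           % 180.0)
    th_min = (th_max + 90.0) % 180.0
    i_min = int(np.argmin(np.abs(((thetas - th_min) + 90) % 180 - 90)))
    if np.isnan(speeds[i_min]):
        raise ValueError("insufficient coverage: no fit in the direction "
                         "orthogonal to the fastest axis")
    return CvResult(cv_max=float(speeds[i_max]), cv_min=float(speeds[i_min]),
                    angle_max=float(th_max),
                    angle_min=float((th_max + 90.0) % 180.0),
                    anisotropy=float(speeds[i_max] / speeds[i_min]),
                    fit_r2_max=float(r2s[i_max]), fit_r2_min=float(r2s[i_min]))


# ---------------------------------------------------------------------------
# conduction block
# ---------------------------------------------------------------------------

def detect_block(act: ActivationMap, delay_thresh: float = 10.0,
                 min_area: int = 10) -> list[BlockComponent]:
    """Connected components (8-neighborhood) of pixels that are invalid or
    activate more than ``delay_thresh`` ms after all their valid 4-neighbors,
    with area at least ``min_area``."""
    t = act.activation_time
    valid = act.valid_mask
    h, w = t.shape

    late = np.zeros((h, w), bool)
    tv = np.where(valid, t, np.nan)
    shifts = [np.roll(tv, s, axis=a) for a, s in
              ((0, 1), (0, -1), (1, 1), (1, -1))]
    # invalidate wrapped borders
    shifts[0][0, :] = np.nan
    shifts[1][-1, :] = np.nan
    shifts[2][:, 0] = np.nan
    shifts[3][:, -1] = np.nan
    nb = np.stack(shifts)
    with np.errstate(invalid="ignore"):
        has_nb = np.any(np.isfinite(nb), axis=0)
        max_ok = np.nanmax(np.where(np.isfinite(nb), nb, -np.inf), axis=0)
        late = valid & has_nb & (t - max_ok > delay_thresh)

    blocked = (~valid) | late
    labels, n = ndimage.label(blocked, structure=np.ones((3, 3), int))
    comps: list[BlockComponent] = []
    for lab in range(1, n + 1):
        mask = labels == lab
        area = int(mask.sum())
        if area < min_area:
            continue
        rows, cols = np.nonzero(mask)
        comps.append(BlockComponent(
            area=area,
            bbox=(int(rows.min()), int(cols.min()),
                  int(rows.max()) + 1, int(cols.max()) + 1),
            mask=mask))
    comps.sort(key=lambda c: -c.area)
    return comps
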