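"""Rodent surface-ECG analysis: beat detection, quality classification,
signal averaging, and fiducial delineation.

The workflow mirrors standard signal-averaged ECG practice for anesthetized
rats recorded at 1 kHz: QRS complexes are detected on a band-passed trace,
beats are screened by template correlation and RR regularity, a run of
consecutive good beats (200 by default) is aligned on the QRS maximum and
averaged, and the averaged beat is delineated into P/QRS/T fiducials from
which intervals, amplitudes, and the Bazett-corrected QT are measured.

All voltages are in microvolts, all times in milliseconds unless a field
name says otherwise. Sample indices are 0-based.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

__all__ = [
    "EcgRecording",
    "BeatSet",
    "AveragedBeat",
    "Delineation",
    "EcgMeasures",
    "DelineationConfig",
    "detect_beats",
    "classify_beats",
    "average_beats",
    "delineate",
    "measure",
    "analyze_recording",
]


@dataclass(frozen=True)
class EcgRecording:
    """A single-lead voltage trace with uniform sampling."""

    samples: np.ndarray          # μV
    sampling_rate: float         # Hz
    lead_label: str = "aVR"

    def __post_init__(self):
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if samples.ndim != 1 or samples.size < 2:
            raise ValueError("samples must be a 1-D array of length >= 2")

    @property
    def duration_ms(self) -> float:
        return (self.samples.size - 1) / self.sampling_rate * 1000.0


@dataclass
class BeatSet:
    """Detected R peaks with per-beat quality annotations."""

    r_peak_indices: np.ndarray                 # sample indices, strictly increasing
    quality: np.ndarray | None = None          # bool per beat, True = good
    template_correlation: np.ndarray | None = None
    reasons: list[str] = field(default_factory=list)

    def __post_init__(self):
        idx = np.asarray(self.r_peak_indices, dtype=int)
        if idx.size and np.any(np.diff(idx) <= 0):
            raise ValueError("r_peak_indices must be strictly increasing")
        self.r_peak_indices = idx

    def __len__(self) -> int:
        return int(self.r_peak_indices.size)

    @property
    def n_good(self) -> int:
        return 0 if self.quality is None else int(np.sum(self.quality))


@dataclass
class AveragedBeat:
    samples: np.ndarray          # μV
    alignment_index: int         # sample of the QRS maximum within `samples`
    n_averaged: int
    window: tuple[float, float]  # (pre_ms, post_ms) around the R peak
    sampling_rate: float         # Hz

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if not (0 <= self.alignment_index < self.samples.size):
            raise ValueError("alignment_index outside sample range")
        if self.n_averaged < 1:
            raise ValueError("n_averaged must be >= 1")


@dataclass
class Delineation:
    """Fiducial sample indices on an averaged beat.

    Any fiducial may be ``None``; ``absent`` then maps its name to a short
    reason code.  ``p_end`` is the return of the P deflection to the
    isoelectric band (used for P duration, symmetric with the T-end rule).
    """

    isoelectric_level: float
    p_onset: int | None = None
    p_peak: int | None = None
    p_end: int | None = None
    qrs_onset: int | None = None
    q_trough: int | None = None
    r_peak: int | None = None
    s_trough: int | None = None
    qrs_offset: int | None = None
    t_peak: int | None = None
    t_end: int | None = None
    st_index: int | None = None
    absent: dict[str, str] = field(default_factory=dict)

    def ordered_present(self) -> list[tuple[str, int]]:
        order = ["p_onset", "p_peak", "qrs_onset", "q_trough", "r_peak",
                 "s_trough", "qrs_offset", "t_peak", "t_end"]
        return [(k, getattr(self, k)) for k in order if getattr(self, k) is not None]


@dataclass
class EcgMeasures:
    heart_rate: float            # beats/min
    p_amplitude: float           # μV, signed, relative to isoelectric
    p_duration: float            # ms, P onset -> P end
    pr_duration: float           # ms, P onset -> QRS onset
    qrs_duration: float          # ms
    qt_duration: float           # ms, QRS onset -> T end
    qtc: float                   # ms, Bazett
    qrs_sum: float               # μV, |Q| + |R| + |S|
    t_amplitude: float           # μV, signed
    st_height: float             # μV, signed, 15 ms after alignment point


@dataclass(frozen=True)
class DelineationConfig:
    """Tunables for the slope-based delineator.

    slope_frac
        "Sufficiently low" |dV/dt| for QRS bounds, as a fraction of the
        maximal intra-QRS |dV/dt|.
    quiet_run
        Number of consecutive sub-threshold slope samples required.
    t_significance
        T peak must deviate from the isoelectric line by at least this many
        noise SDs (robust MAD estimate from the pre-QRS window).
    return_frac
        Relative band (fraction of the wave's own peak deviation) used for
        the provisional P onset and the P-end return-to-baseline rule.
    qrs_search_ms
        Half-width of the window around the R peak searched for the maximal
        intra-QRS slope.
    """

    slope_frac: float = 0.10
    quiet_run: int = 3
    t_significance: float = 2.0
    return_frac: float = 0.05
    qrs_search_ms: float = 40.0
    st_offset_ms: float = 15.0


# ---------------------------------------------------------------------------
# beat detection
# ---------------------------------------------------------------------------

def _qrs_bandpass(x: np.ndarray, fs: float) -> np.ndarray:
    """Band-pass emphasizing rat QRS energy for detection only."""
    hi = min(90.0, 0.45 * fs)
    sos = sps.butter(2, [5.0, hi], btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, x)


def detect_beats(rec: EcgRecording, refine_ms: float = 25.0,
                 lockout_ms: float = 50.0) -> BeatSet:
    """Detect R peaks with a threshold-crossing detector.

    Candidate beats are threshold crossings of the band-passed trace; each
    R peak is then refined to the most positive raw sample within
    ``±refine_ms``, with a refractory lockout of ``lockout_ms``.
    """
    x = rec.samples
    fs = rec.sampling_rate
    f = _qrs_bandpass(x, fs)
    mag = np.abs(f)
    thr = 0.5 * np.percentile(mag, 99)
    if thr <= 0 or not np.isfinite(thr):
        warnings.warn("no beats found: trace has no detectable QRS energy")
        return BeatSet(np.array([], dtype=int), reasons=["no beats found"])

    above = mag > thr
    crossings = np.flatnonzero(above[1:] & ~above[:-1]) + 1
    lockout = int(round(lockout_ms * fs / 1000.0))
    refine = int(round(refine_ms * fs / 1000.0))

    peaks: list[int] = []
    last = -lockout - 1
    for c in crossings:
        if c - last <= lockout:
            continue
        lo = max(0, c - refine)
        hi = min(x.size, c + refine + 1)
        p = lo + int(np.argmax(x[lo:hi]))
        if peaks and p - peaks[-1] <= lockout:
            continue
        peaks.append(p)
        last = c

    if not peaks:
        warnings.warn("no beats found: no threshold crossings")
        return BeatSet(np.array([], dtype=int), reasons=["no beats found"])
    idx = np.unique(np.asarray(peaks, dtype=int))
    return BeatSet(idx)


# ---------------------------------------------------------------------------
# beat quality classification
# ---------------------------------------------------------------------------

def _running_median(x: np.ndarray, win: int = 11) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    h = win // 2
    for i in range(x.size):
        lo = max(0, i - h)
        out[i] = np.median(x[lo:i + h + 1])
    return out


def classify_beats(rec: EcgRecording, beats: BeatSet,
                   window_ms: tuple[float, float] = (80.0, 120.0),
                   corr_min: float = 0.9,
                   rr_tol: float = 0.20) -> BeatSet:
    """Fill per-beat quality: template correlation and RR regularity.

    A beat is good iff (a) its Pearson correlation to the median-beat
    template over the averaging window is at least ``corr_min`` and (b) both
    adjacent RR intervals are within ``±rr_tol`` of the running-median RR.
    Beats whose window exceeds the recording are bad ("edge").
    """
    n = len(beats)
    if n < 3:
        return replace_quality(beats, np.zeros(n, bool), np.full(n, np.nan),
                               ["insufficient beats"])

    fs = rec.sampling_rate
    pre = int(round(window_ms[0] * fs / 1000.0))
    post = int(round(window_ms[1] * fs / 1000.0))
    idx = beats.r_peak_indices

    in_bounds = (idx - pre >= 0) & (idx + post < rec.samples.size)
    segs = np.array([rec.samples[i - pre:i + post + 1]
                     for i in idx[in_bounds]])
    if segs.shape[0] < 1:
        return replace_quality(beats, np.zeros(n, bool), np.full(n, np.nan),
                               ["all beats truncated by recording edges"])
    template = np.median(segs, axis=0)

    corr = np.full(n, np.nan)
    tstd = template.std()
    for j, i in enumerate(idx):
        if not in_bounds[j]:
            continue
        seg = rec.samples[i - pre:i + post + 1]
        sstd = seg.std()
        if tstd == 0 or sstd == 0:
            corr[j] = 1.0 if np.allclose(seg, template) else 0.0
        else:
            corr[j] = float(np.corrcoef(seg, template)[0, 1])

    rr = np.diff(idx).astype(float)
    good = np.zeros(n, bool)
    reasons = []
    if rr.size:
        med = _running_median(rr)
        for j in range(n):
            if not in_bounds[j]:
                reasons.append(f"beat {j}: edge")
                continue
            if not (corr[j] >= corr_min):
                reasons.append(f"beat {j}: template correlation {corr[j]:.3f}")
                continue
            ok = True
            for k in (j - 1, j):        # RR before and after beat j
                if 0 <= k < rr.size:
                    ref = med[k]
                    if abs(rr[k] - ref) > rr_tol * ref:
                        ok = False
                        reasons.append(f"beat {j}: irregular RR {rr[k]:.0f} ms")
                        break
            good[j] = ok
    return replace_quality(beats, good, corr, reasons)


def replace_quality(beats: BeatSet, quality, corr, reasons) -> BeatSet:
    out = BeatSet(beats.r_peak_indices.copy())
    out.quality = np.asarray(quality, bool)
    out.template_correlation = np.asarray(corr, float)
    out.reasons = list(reasons)
    return out


# ---------------------------------------------------------------------------
# averaging
# ---------------------------------------------------------------------------

def average_beats(rec: EcgRecording, beats: BeatSet, n_target: int = 200,
                  window_ms: tuple[float, float] = (80.0, 120.0)) -> AveragedBeat:
    """Average the first ``n_target`` consecutive good beats aligned on R.

    Each good beat is windowed ``window_ms`` around its R-peak sample and
    averaged sample-wise; the R peak of every contributing beat lands on
    ``alignment_index``.
    """
    if beats.quality is None:
        raise ValueError("beats must be classified before averaging")
    good = np.flatnonzero(beats.quality)
    if good.size == 0:
        raise ValueError("zero good beats: nothing to average")
    if good.size < n_target:
        warnings.warn(f"only {good.size} good beats available "
                      f"(requested {n_target}); averaging all of them")
    take = good[:n_target]

    fs = rec.sampling_rate
    pre = int(round(window_ms[0] * fs / 1000.0))
    post = int(round(window_ms[1] * fs / 1000.0))
    segs = []
    for i in beats.r_peak_indices[take]:
        if i - pre < 0 or i + post >= rec.samples.size:
            continue
        segs.append(rec.samples[i - pre:i + post + 1])
    if not segs:
        raise ValueError("no good beat fits the averaging window")
    avg = np.mean(segs, axis=0)
    return AveragedBeat(avg, alignment_index=pre, n_averaged=len(segs),
                        window=window_ms, sampling_rate=fs)


# ---------------------------------------------------------------------------
# delineation
# ---------------------------------------------------------------------------

def _quiet_edge(quiet: np.ndarray, start: int, run: int, direction: int) -> int | None:
    """Walk from ``start`` in ``direction`` and return the index adjacent to
    the first run of ``run`` consecutive quiet samples (i.e. the QRS bound)."""
    n = quiet.size
    count = 0
    j = start
    while 0 <= j < n:
        count = count + 1 if quiet[j] else 0
        if count >= run:
            # bound is the sample next to the near end of the quiet run
            return j + (run - 1) + 1 if direction < 0 else j - (run - 1)
        j += direction
    return None


def delineate(beat: AveragedBeat, cfg: DelineationConfig | None = None) -> Delineation:
    """Delineate an averaged beat into P/QRS/T fiducials.

    QRS bounds are the first samples, scanning outward from the R peak,
    where |dV/dt| stays below ``slope_frac`` of the maximal intra-QRS
    |dV/dt| for at least ``quiet_run`` consecutive samples.  The isoelectric
    level is the median of everything before the QRS onset (two passes are
    unnecessary because the onset itself is slope-derived).  The P peak is
    the greatest absolute deviation before QRS onset; the P onset is the
    intersection of the isoelectric line with a least-squares line through
    the upstroke points 15–60% of the onset-to-peak span before the peak.
    The T peak is the first extremum after the QRS offset deviating by at
    least ``t_significance`` noise SDs, and the T end the first subsequent
    return into that band.
    """
    cfg = cfg or DelineationConfig()
    v = beat.samples
    fs = beat.sampling_rate
    ms = fs / 1000.0                      # samples per ms
    r = beat.alignment_index
    n = v.size
    absent: dict[str, str] = {}

    dv = np.diff(v)                       # forward difference, per sample
    lo = max(0, int(r - cfg.qrs_search_ms * ms))
    hi = min(dv.size, int(r + cfg.qrs_search_ms * ms))
    max_slope = np.max(np.abs(dv[lo:hi])) if hi > lo else 0.0
    if max_slope == 0:
        raise ValueError("no QRS: beat is flat")
    thr = cfg.slope_frac * max_slope
    quiet = np.abs(dv) < thr

    qrs_onset = _quiet_edge(quiet, min(r - 1, dv.size - 1), cfg.quiet_run, -1)
    qrs_offset = _quiet_edge(quiet, r, cfg.quiet_run, +1)
    if qrs_onset is None or qrs_offset is None or qrs_onset < 1:
        raise ValueError("no QRS: could not bound the complex")

    iso = float(np.median(v[:qrs_onset]))
    dev = v - iso
    # robust noise SD from the pre-QRS window (MAD; P occupies a minority)
    noise_sd = 1.4826 * float(np.median(np.abs(dev[:qrs_onset])))
    band = max(cfg.t_significance * noise_sd, 1e-9)

    q = qrs_onset + int(np.argmin(v[qrs_onset:r + 1])) if r > qrs_onset else None
    s = r + int(np.argmin(v[r:qrs_offset + 1])) if qrs_offset > r else None

    # ---- P wave ----
    p_peak = p_onset = p_end = None
    p_stop = max(qrs_onset - int(2 * ms), 1)
    if p_stop > 1:
        pp = int(np.argmax(np.abs(dev[:p_stop])))
        p_amp = dev[pp]
        if abs(p_amp) >= band:
            p_peak = pp
            pband = max(band, cfg.return_frac * abs(p_amp))
            # provisional onset: walk left until inside the isoelectric band
            i0 = p_peak
            while i0 > 0 and abs(dev[i0 - 1]) > pband:
                i0 -= 1
            span = p_peak - i0
            if span >= 3:
                a = p_peak - int(round(0.60 * span))
                b = p_peak - int(round(0.15 * span))
                xs = np.arange(a, b + 1, dtype=float)
                if xs.size >= 2 and np.ptp(v[a:b + 1]) > 0:
                    slope, intercept = np.polyfit(xs, v[a:b + 1], 1)
                    if slope != 0:
                        x0 = (iso - intercept) / slope
                        cand = int(round(x0))
                        if 0 <= cand < p_peak:
                            p_onset = cand
                        else:
                            absent["p_onset"] = "upstroke fit outside window"
                    else:
                        absent["p_onset"] = "flat P upstroke"
                else:
                    absent["p_onset"] = "flat P upstroke"
            else:
                absent["p_onset"] = "P upstroke too short"
            # P end: first return into the band after the peak, capped at QRS onset
            j = p_peak
            while j < qrs_onset and abs(dev[j]) > pband:
                j += 1
            p_end = min(j, qrs_onset)
        else:
            absent["p_peak"] = "no significant P deflection"
    else:
        absent["p_peak"] = "no pre-QRS window"
    if p_peak is None:
        absent.setdefault("p_onset", "no P wave")
        absent.setdefault("p_end", "no P wave")

    # ---- T wave ----
    t_peak = t_end = None
    t_start = min(qrs_offset + int(2 * ms), n - 1)
    if t_start < n - 2:
        seg = dev[t_start:]
        k = min(max(int(round(3 * ms)) | 1, 3), max(seg.size // 2 * 2 - 1, 3))
        sm = np.convolve(seg, np.ones(k) / k, mode="same")
        d = np.diff(sm)
        sign_change = np.flatnonzero(np.sign(d[1:]) * np.sign(d[:-1]) < 0) + 1
        for c in sign_change:
            # refine on the raw trace near the smoothed extremum
            a = max(0, c - int(2 * ms))
            b = min(seg.size, c + int(2 * ms) + 1)
            loc = a + int(np.argmax(np.abs(seg[a:b])))
            if abs(seg[loc]) >= band:
                t_peak = t_start + loc
                break
        if t_peak is not None:
            j = t_peak + 1
            while j < n and abs(dev[j]) > band:
                j += 1
            if j < n:
                t_end = j
            else:
                absent["t_end"] = "no return to isoelectric"
        else:
            absent["t_peak"] = "no significant T deflection"
            absent["t_end"] = "no T wave"
    else:
        absent["t_peak"] = "no post-QRS window"
        absent["t_end"] = "no post-QRS window"

    st_index = min(r + int(round(cfg.st_offset_ms * ms)), n - 1)

    return Delineation(
        isoelectric_level=iso, p_onset=p_onset, p_peak=p_peak, p_end=p_end,
        qrs_onset=qrs_onset, q_trough=q, r_peak=r, s_trough=s,
        qrs_offset=qrs_offset, t_peak=t_peak, t_end=t_end,
        st_index=st_index, absent=absent)


# ---------------------------------------------------------------------------
# measures
# ---------------------------------------------------------------------------

def measure(delin: Delineation, beat: AveragedBeat, mean_rr: float) -> EcgMeasures:
    """Interval and amplitude measures from a delineated averaged beat.

    ``mean_rr`` is the mean RR of the averaged beats in ms; QTc uses the
    classical Bazett form with RR in seconds.  Measures whose fiducials are
    absent come back as NaN.
    """
    if mean_rr <= 0:
        raise ValueError("mean_rr must be positive")
    if delin.qrs_onset is None or delin.qrs_offset is None:
        raise ValueError("delineation lacks QRS bounds")
    v = beat.samples
    iso = delin.isoelectric_level
    ms = beat.sampling_rate / 1000.0

    def gap(a, b):
        if a is None or b is None:
            return float("nan")
        return (b - a) / ms

    def amp(i):
        return float(v[i] - iso) if i is not None else float("nan")

    qrs = gap(delin.qrs_onset, delin.qrs_offset)
    qt = gap(delin.qrs_onset, delin.t_end)
    qtc = qt / np.sqrt(mean_rr / 1000.0)
    qrs_sum = sum(abs(amp(i)) for i in (delin.q_trough, delin.r_peak, delin.s_trough))
    return EcgMeasures(
        heart_rate=60000.0 / mean_rr,
        p_amplitude=amp(delin.p_peak),
        p_duration=gap(delin.p_onset, delin.p_end),
        pr_duration=gap(delin.p_onset, delin.qrs_onset),
        qrs_duration=qrs,
        qt_duration=qt,
        qtc=float(qtc),
        qrs_sum=float(qrs_sum),
        t_amplitude=amp(delin.t_peak),
        st_height=amp(delin.st_index),
    )


def analyze_recording(rec: EcgRecording, n_target: int = 200,
                      window_ms: tuple[float, float] = (80.0, 120.0),
                      cfg: DelineationConfig | None = None,
                      ) -> tuple[AveragedBeat, Delineation, EcgMeasures]:
    """End-to-end convenience: detect, classify, average, delineate, measure."""
    beats = detect_beats(rec)
    beats = classify_beats(rec, beats, window_ms=window_ms)
    avg = average_beats(rec, beats, n_target=n_target, window_ms=window_ms)
    good = beats.r_peak_indices[beats.quality]
    rr = np.diff(good) / rec.sampling_rate * 1000.0
    mean_rr = float(np.mean(rr)) if rr.size else float("nan")
    delin = delineate(avg, cfg)
    return avg, delin, measure(delin, avg, mean_rr)
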