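"""File formats, configuration, and the end-to-end pipeline.

Formats
-------
* ECG: CSV with columns ``time_ms, voltage_uV`` plus a JSON sidecar
  (sampling rate, seed, parameters); or a ``.npy`` array with the sidecar.
* Movies: multi-page TIFF (frame-major) or ``.npy`` 3-D array plus a JSON
  sidecar (``frame_interval_ms``, ``pixel_size_um``, ``pacing_site``,
  ``stim_times_ms``, ``polarity``).
* Maps: single-page float TIFF.
* Cohorts: CSV, one row per animal (see ``COLUMN_DICTIONARY``).

``run_pipeline`` wires the stages together: simulate a cohort with
per-animal ECGs and optical-mapping movies, analyze them, quantify
synthetic blot lanes, and emit per-animal measures, group summaries,
correlations, activation maps and a run manifest.  Everything is
deterministic for a fixed config + seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import blot as blotmod
from . import ecg as ecgmod
from . import omap
from . import stats as statsmod
from . import syngen

logger = logging.getLogger(__name__)

__all__ = [
    "read_ecg", "write_ecg", "read_movie", "write_movie", "write_map_tiff",
    "load_config", "validate_config", "run_pipeline", "default_config",
    "COLUMN_DICTIONARY",
]

COLUMN_DICTIONARY = {
    "animal_id": "unique animal identifier",
    "cohort": "sham or ACF (aorto-caval fistula)",
    "group": "severity group: sham / mild / moderate / severe",
    "body_weight": "g", "lv_weight": "g", "septum_weight": "g",
    "rv_weight": "g", "heart_weight": "g (LV + septum + RV)",
    "lungs_weight": "g", "hbwr": "heart/body weight, g/kg",
    "lungs_bw": "lungs/body weight, g/kg",
    "heart_rate": "beats/min", "p_amplitude": "μV", "p_duration": "ms",
    "pr_duration": "ms", "qrs_duration": "ms", "qt_duration": "ms",
    "qrs_sum": "μV", "t_amplitude": "μV", "st_height": "μV",
    "apd50": "ms", "apd90": "ms", "cv_min": "cm/s", "cv_max": "cm/s",
    "cx43": "connexin43 relative density (sham mean = 1)",
    "p_cx43": "phospho-connexin43 relative density",
    "chat": "choline acetyltransferase relative density",
    "th": "tyrosine hydroxylase relative density",
}


# ---------------------------------------------------------------------------
# ECG I/O
# ---------------------------------------------------------------------------

def write_ecg(rec: ecgmod.EcgRecording, path: str | Path,
              extra_meta: dict | None = None) -> Path:
    """Write time/voltage CSV plus a JSON sidecar next to it."""
    path = Path(path)
    t = np.arange(rec.samples.size) / rec.sampling_rate * 1000.0
    pd.DataFrame({"time_ms": t, "voltage_uV": rec.samples}).to_csv(
        path, index=False, float_format="%.9g")
    meta = {"sampling_rate": rec.sampling_rate, "lead_label": rec.lead_label}
    meta.update(extra_meta or {})
    path.with_suffix(".json").write_text(json.dumps(meta, sort_keys=True, indent=1))
    return path


def read_ecg(path: str | Path) -> ecgmod.EcgRecording:
    """Read an ECG from CSV (``time_ms, voltage_uV``) or ``.npy`` + sidecar.

    Timestamp uniformity is verified to a relative tolerance of 1e-6; the
    first offending row is named in the error.
    """
    path = Path(path)
    sidecar = path.with_suffix(".json")
    if path.suffix == ".npy":
        if not sidecar.exists():
            raise ValueError(f"missing sidecar {sidecar} for array input")
        meta = json.loads(sidecar.read_text())
        if "sampling_rate" not in meta:
            raise ValueError("sidecar must declare sampling_rate")
        return ecgmod.EcgRecording(np.load(path), float(meta["sampling_rate"]),
                                   meta.get("lead_label", "aVR"))
    df = pd.read_csv(path)
    if not {"time_ms", "voltage_uV"} <= set(df.columns):
        raise ValueError("CSV must have columns time_ms and voltage_uV")
    t = df["time_ms"].to_numpy(float)
    dt = np.diff(t)
    if dt.size == 0:
        raise ValueError("recording too short")
    step = np.median(dt)
    bad = np.flatnonzero(np.abs(dt - step) > 1e-6 * max(step, 1.0))
    if bad.size:
        raise ValueError(f"non-uniform timestamps: first gap at row {bad[0] + 1} "
                         f"(dt = {dt[bad[0]]:.6g} ms, expected {step:.6g} ms)")
    fs = 1000.0 / step
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        declared = meta.get("sampling_rate")
        if declared is not None and abs(declared - fs) > 1e-6 * declared:
            raise ValueError(f"sidecar sampling_rate {declared} Hz disagrees "
                             f"with data spacing ({fs:.6g} Hz)")
    return ecgmod.EcgRecording(df["voltage_uV"].to_numpy(float), fs)


# ---------------------------------------------------------------------------
# movie I/O
# ---------------------------------------------------------------------------

def write_movie(movie: omap.Movie, path: str | Path,
                meta_path: str | Path | None = None) -> Path:
    path = Path(path)
    meta_path = Path(meta_path) if meta_path else path.with_suffix(".json")
    if path.suffix in (".tif", ".tiff"):
        tifffile.imwrite(path, movie.data.astype(np.float32))
    else:
        np.save(path, movie.data)
    meta = {
        "frame_interval_ms": movie.frame_interval,
        "pixel_size_um": movie.pixel_size,
        "pacing_site": list(movie.pacing_site),
        "stim_times_ms": list(movie.stim_times),
        "polarity": movie.polarity,
        "n_frames": movie.n_frames,
    }
    meta_path.write_text(json.dumps(meta, sort_keys=True, indent=1))
    return path


def read_movie(path: str | Path, meta_path: str | Path | None = None) -> omap.Movie:
    path = Path(path)
    meta_path = Path(meta_path) if meta_path else path.with_suffix(".json")
    if not meta_path.exists():
        raise ValueError(f"missing metadata sidecar {meta_path}")
    meta = json.loads(meta_path.read_text())
    for key in ("frame_interval_ms", "pixel_size_um", "stim_times_ms"):
        if key not in meta:
            raise ValueError(f"metadata missing required key {key!r}")
    if path.suffix in (".tif", ".tiff"):
        data = tifffile.imread(path)
    else:
        data = np.load(path)
    data = np.asarray(data, float)
    if data.ndim != 3:
        raise ValueError("movie must be a 3-D stack")
    if "n_frames" in meta and meta["n_frames"] != data.shape[0]:
        raise ValueError(f"frame count mismatch: metadata declares "
                         f"{meta['n_frames']}, file holds {data.shape[0]}")
    return omap.Movie(data=data, frame_interval=float(meta["frame_interval_ms"]),
                      pixel_size=float(meta["pixel_size_um"]),
                      stim_times=[float(s) for s in meta["stim_times_ms"]],
                      pacing_site=tuple(meta.get("pacing_site", (0, 0))),
                      polarity=int(meta.get("polarity", 1)))


def write_map_tiff(field: np.ndarray, path: str | Path) -> Path:
    path = Path(path)
    tifffile.imwrite(path, np.asarray(field, np.float32))
    return path


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

_SCHEMA: dict[str, set[str]] = {
    "": {"seed", "out", "log_level", "simulate", "ecg", "map", "blot", "stats"},
    "simulate": {"group_sizes"},
    "ecg": {"duration", "noise_sd", "n_target"},
    "map": {"n_rows", "n_cols", "noise_sd", "first_stim", "pixel_size",
            "frame_interval"},
    "blot": {"n_per_group", "noise_sd"},
    "stats": {"variables", "correlations"},
}


def default_config() -> dict:
    """The demo pipeline configuration: the full 27-animal study layout."""
    return {
        "seed": 0,
        "out": "pipeline_out",
        "log_level": "INFO",
        "simulate": {"group_sizes": {"sham": 10, "mild": 5, "moderate": 8,
                                     "severe": 4}},
        "ecg": {"duration": 6.0, "noise_sd": 10.0, "n_target": 40},
        "map": {"n_rows": 100, "n_cols": 100, "noise_sd": 0.02,
                "first_stim": 10.0, "pixel_size": 80.0, "frame_interval": 2.0},
        "blot": {"n_per_group": 3, "noise_sd": 2.0},
        "stats": {
            "variables": ["body_weight", "heart_weight", "hbwr", "lungs_bw",
                          "meas_p_duration", "meas_pr_duration",
                          "meas_qrs_duration", "meas_qt_duration",
                          "meas_apd50", "meas_apd90", "meas_cv_min",
                          "meas_cv_max", "cx43_measured"],
            "correlations": [["cx43_measured", "heart_weight"],
                             ["hbwr", "lv_weight"],
                             ["hbwr", "rv_weight"],
                             ["meas_apd50", "meas_apd90"]],
        },
    }


def validate_config(config: dict) -> dict:
    """Reject unknown keys anywhere in the config; merge over defaults."""
    base = default_config()
    for key in config:
        if key not in _SCHEMA[""]:
            raise ValueError(f"unknown config key {key!r}")
    for stage, allowed in _SCHEMA.items():
        if not stage or stage not in config:
            continue
        block = config[stage]
        if not isinstance(block, dict):
            raise ValueError(f"config section {stage!r} must be a mapping")
        for key in block:
            if key not in allowed:
                raise ValueError(f"unknown key {key!r} in config section {stage!r}")
        base[stage].update(block)
    for key in ("seed", "out", "log_level"):
        if key in config:
            base[key] = config[key]
    return base


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return validate_config(raw)


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def _clip(x, lo, hi):
    return float(min(max(x, lo), hi))


def _ecg_params_for_row(row, seed: int, duration: float, noise_sd: float
                        ) -> syngen.EcgSimParams:
    """Per-animal ECG generator parameters from the drawn cohort values,
    clamped to physiologically representable ranges."""
    p_dur = _clip(row["p_duration"], 8, 30)
    pr = max(_clip(row["pr_duration"], 20, 90), p_dur + 5)
    qrs = _clip(row["qrs_duration"], 10, 35)
    qt = max(_clip(row["qt_duration"], 40, 130), qrs + 20)
    hr = _clip(row["heart_rate"], 250, 480)
    hr = min(hr, 60000.0 / (1.06 * (pr + qt)))
    qsum = _clip(row["qrs_sum"], 100, 1500)
    t_amp = _clip(row["t_amplitude"], -150, 150)
    if abs(t_amp) < 5:
        t_amp = 5.0 if t_amp >= 0 else -5.0
    return syngen.EcgSimParams(
        heart_rate=hr, duration=duration, noise_sd=noise_sd,
        p_amplitude=_clip(row["p_amplitude"], 10, 200), p_duration=p_dur,
        pr_interval=pr, qrs_duration=qrs, qt_interval=qt,
        q_amplitude=-0.104 * qsum, r_amplitude=0.725 * qsum,
        s_amplitude=-0.171 * qsum, t_amplitude=t_amp, seed=seed)


def _map_params_for_row(row, seed: int, cfg: dict, rng: np.random.Generator
                        ) -> syngen.MapSimParams:
    cv_t = _clip(row["cv_min"], 8, 60)
    cv_l = max(_clip(row["cv_max"], 20, 250), cv_t)
    apd50 = _clip(row["apd50"], 30, 110)
    apd90 = _clip(row["apd90"], apd50 + 5, 170)
    h, w = int(cfg["n_rows"]), int(cfg["n_cols"])
    px, dt = float(cfg["pixel_size"]), float(cfg["frame_interval"])
    first = float(cfg["first_stim"])
    diag_mm = np.hypot(h / 2, w / 2) * px / 1000.0
    travel = diag_mm / (cv_t / 100.0)          # ms
    tail = apd90 + 0.5 * (apd90 - apd50)
    n_frames = int(np.ceil((first + travel + tail + 10.0) / dt)) + 2
    return syngen.MapSimParams(
        n_rows=h, n_cols=w, pixel_size=px, frame_interval=dt,
        n_frames=n_frames, pacing_site=(h // 2, w // 2), first_stim=first,
        cv_long=cv_l, cv_trans=cv_t, apd50=apd50, apd90=apd90,
        fiber_angle=float(rng.uniform(0, 180)),
        noise_sd=float(cfg["noise_sd"]), seed=seed)


def run_pipeline(config: dict, out_dir: str | Path | None = None) -> dict:
    """Simulate, analyze and summarize a full synthetic study.

    Returns a result bundle with the per-animal table, the group summary,
    and the correlation table; writes CSVs, activation maps and a manifest
    under the output directory.  Byte-identical outputs for the same config
    and seed.
    """
    cfg = validate_config(config)
    seed = int(cfg["seed"])
    out = Path(out_dir or cfg["out"])
    out.mkdir(parents=True, exist_ok=True)
    (out / "maps").mkdir(exist_ok=True)
    logging.basicConfig(level=getattr(logging, str(cfg["log_level"]).upper(), 20))

    # ---- simulate cohort ----
    cp = syngen.default_cohort_params(
        seed=seed, group_sizes=dict(cfg["simulate"]["group_sizes"]))
    table = syngen.gen_cohort(cp)
    if table.empty:
        raise ValueError("missing dependency: cohort table is empty")

    rng = np.random.default_rng(seed + 1)
    ecg_cfg, map_cfg, blot_cfg = cfg["ecg"], cfg["map"], cfg["blot"]

    # ---- per-animal ECG and optical mapping ----
    meas_rows = []
    for i, row in table.iterrows():
        animal = row["animal_id"]
        m: dict[str, float] = {"animal_id": animal}
        ep = _ecg_params_for_row(row, seed=seed * 1000 + 2 * i,
                                 duration=float(ecg_cfg["duration"]),
                                 noise_sd=float(ecg_cfg["noise_sd"]))
        rec, _ = syngen.gen_ecg(ep)
        try:
            _, _, meas = ecgmod.analyze_recording(
                rec, n_target=int(ecg_cfg["n_target"]))
            m.update({f"meas_{k}": getattr(meas, k) for k in
                      ("heart_rate", "p_amplitude", "p_duration", "pr_duration",
                       "qrs_duration", "qt_duration", "qtc", "qrs_sum",
                       "t_amplitude", "st_height")})
        except ValueError as exc:
            logger.warning("ECG analysis failed for %s: %s", animal, exc)

        mp = _map_params_for_row(row, seed=seed * 1000 + 2 * i + 1,
                                 cfg=map_cfg, rng=rng)
        movie, _ = syngen.gen_map_movie(mp)
        try:
            # spatial median + polarity only: the temporal band-pass blurs
            # sub-frame activation timing and is reserved for drifting signals
            filtered = omap.normalize_polarity(movie)
            act = omap.activation_map(filtered)
            cv = omap.measure_cv(act)
            r0, c0 = mp.pacing_site
            roi = {"central": (r0 + 3, r0 + 13, c0 - 5, c0 + 5)}
            apd = omap.measure_apd(omap.normalize_polarity(movie), act, roi)["central"]
            blocks = omap.detect_block(act)
            m.update({"meas_cv_max": cv.cv_max, "meas_cv_min": cv.cv_min,
                      "meas_anisotropy": cv.anisotropy,
                      "meas_apd50": apd.apd50, "meas_apd90": apd.apd90,
                      "n_block_components": len(blocks)})
            write_map_tiff(act.activation_time, out / "maps" / f"{animal}_activation.tif")
            iso = omap.isochrones(act)
            write_map_tiff(iso.band_index.astype(np.float32),
                           out / "maps" / f"{animal}_isochrones.tif")
        except ValueError as exc:
            logger.warning("map analysis failed for %s: %s", animal, exc)
        meas_rows.append(m)
    table = table.merge(pd.DataFrame(meas_rows), on="animal_id")

    # ---- severity / failing re-derivation from the simulated anatomy ----
    sev = [statsmod.assign_severity(r["cohort"], r["hbwr"], r["lungs_bw"])
           for _, r in table.iterrows()]
    table["severity_assigned"] = [s.label for s in sev]
    table["failing"] = [s.failing for s in sev]

    # ---- blot quantification on n_per_group animals per group ----
    n_per = int(blot_cfg["n_per_group"])
    noise = float(blot_cfg["noise_sd"])
    chosen = table.groupby("group", sort=False).head(n_per)
    ratios = {}
    for j, (_, row) in enumerate(chosen.iterrows()):
        target_area = 1000.0 * max(row["cx43"], 0.05)
        profile, _ = syngen.gen_lane_profile(
            bands=[(60.0, 5.0, target_area), (140.0, 5.0, 1000.0)],
            baseline=(20.0, 0.05), noise_sd=noise, length=200,
            seed=seed * 1000 + 700 + j)
        lane = blotmod.LaneProfile(profile)
        tq = blotmod.quantify_band(lane, (40, 80))
        cq = blotmod.quantify_band(lane, (120, 160))
        ratios[row["animal_id"]] = blotmod.normalize(tq, cq).target_over_control
    sham_ids = chosen.loc[chosen["group"] == "sham", "animal_id"]
    ref = [ratios[a] for a in sham_ids if a in ratios]
    table["cx43_measured"] = [
        (ratios[a] / np.mean(ref) if a in ratios and ref else np.nan)
        for a in table["animal_id"]]

    # ---- statistics ----
    stats_cfg = cfg["stats"]
    variables = [v for v in stats_cfg["variables"] if v in table.columns]
    summary = statsmod.group_summary(table, variables)

    corr_rows = []
    acf = table[table["cohort"] == "ACF"]
    for xv, yv in stats_cfg["correlations"]:
        if xv not in table.columns or yv not in table.columns:
            continue
        sub = acf[[xv, yv]].dropna()
        if len(sub) < 3:
            continue
        try:
            c = statsmod.pearson(sub[xv], sub[yv])
        except ValueError:
            continue
        corr_rows.append({"x": xv, "y": yv, "r": c.r, "p": c.p_value,
                          "n": c.n, "slope": c.slope, "intercept": c.intercept})
    corr_df = pd.DataFrame(corr_rows)

    # ---- outputs ----
    table.to_csv(out / "animals.csv", index=False, float_format="%.6g")
    summary.table.to_csv(out / "group_summary.csv", index=False,
                         float_format="%.6g")
    pd.DataFrame([
        {"variable": v, "anova_p": summary.anova_p.get(v, np.nan),
         **{f"dunnett_p_{g}": summary.dunnett_p.get(v, {}).get(g, np.nan)
            for g in ("mild", "moderate", "severe")}}
        for v in variables
    ]).to_csv(out / "tests.csv", index=False, float_format="%.6g")
    corr_df.to_csv(out / "correlations.csv", index=False, float_format="%.6g")

    resolved = yaml.safe_dump(cfg, sort_keys=True)
    (out / "config_resolved.yaml").write_text(resolved)
    manifest = {
        "seed": seed,
        "config_sha256": hashlib.sha256(resolved.encode()).hexdigest(),
        "n_animals": int(len(table)),
        "outputs": sorted(p.name for p in out.iterdir() if p.is_file()),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, sort_keys=True,
                                                  indent=1))
    return {"animals": table, "summary": summary, "correlations": corr_df,
            "out_dir": out}
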