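"""End-to-end analysis pipeline.

``run_pipeline`` executes the full sequence on simulated or user-supplied
data: (simulate) -> hourly/daily averaging -> gap filling -> rate-of-change
transform -> segmentation -> per-segment Morlet spectra and the aggregated
global spectrum -> coherence with Monte-Carlo significance and phase
histograms.  All intermediates are written as CSV; a machine-readable
summary (peak periods per variable and cadence, phase statistics per pair)
lands in ``summary.json``.  Every output directory carries the seed and a
hash of the configuration.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .coherence import mc_coherence_significance, phase_distribution, wavelet_coherence
from .io import write_timeseries, write_truth
from .preprocess import (
    MIN_SEGMENT_DAILY,
    MIN_SEGMENT_HOURLY,
    daily_average,
    fill_small_gaps,
    hourly_average,
    log_smooth_diff,
    segment,
)
from .synthetic import (
    EcosystemParams,
    HarmonicConstituent,
    TideConfig,
    generate_ecosystem,
    generate_water_level,
    inject_gaps,
)
from .tides import tidal_current_speed, tidal_range
from .timeseries import TimeSeries, overlap
from .wavelet import (
    WaveletParams,
    estimate_ar1,
    global_spectrum,
    morlet_cwt,
    peak_period,
    rednoise_significance,
)

log = logging.getLogger("tidewave")

#: Variables transformed to relative rates of change before wavelet analysis.
RATE_VARIABLES = ("chlorophyll", "spm", "salinity", "temperature")

#: Named period bands (minutes) reported in the summary.
DEFAULT_BANDS = {
    "quarter_diurnal": (300.0, 450.0),
    "semidiurnal": (600.0, 900.0),
    "diel": (20 * 60.0, 30 * 60.0),
    "spring_neap": (10 * 1440.0, 20 * 1440.0),
}


@dataclass
class CoherencePair:
    """One coherence analysis: two prepared series and a phase band."""

    x: str  # key into the prepared-series registry
    y: str
    band: tuple[float, float]  # minutes
    bin_width: float = 20.0


@dataclass
class PipelineConfig:
    simulate: dict | None = None  # TideConfig/EcosystemParams fields
    inputs: dict | None = None  # variable -> CSV path
    out_dir: str = "tidewave_out"
    seed: int = 0
    dj: float = 1.0 / 24.0
    level: float = 0.95
    n_surrogates: int = 300
    dark_threshold: float = 1.0
    min_segment_hourly: int = MIN_SEGMENT_HOURLY
    min_segment_daily: int = MIN_SEGMENT_DAILY
    coherence_pairs: list[CoherencePair] = field(
        default_factory=lambda: [
            CoherencePair("rate(chlorophyll)@hourly", "tc@hourly", (300.0, 450.0)),
            CoherencePair("chlorophyll@daily", "tidal_range@daily", (13 * 1440.0, 17 * 1440.0)),
        ]
    )

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        pairs = [
            CoherencePair(p["x"], p["y"], tuple(p["band"]), p.get("bin_width", 20.0))
            for p in raw.pop("coherence_pairs", [])
        ]
        cfg = cls(**raw)
        if pairs:
            cfg.coherence_pairs = pairs
        return cfg

    def digest(self) -> str:
        fields = asdict(self)
        fields.pop("out_dir")  # where results land is not part of the analysis
        payload = json.dumps(fields, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def simulate_dataset(spec: dict, seed: int):
    """Build a :class:`SyntheticDataset` from a flat config mapping."""
    spec = dict(spec or {})
    gaps = spec.pop("gaps", None)
    tide_keys = {"start_time", "duration", "sampling_interval", "mean_level"}
    tide_kwargs = {k: spec.pop(k) for k in list(spec) if k in tide_keys}
    constituents = spec.pop("constituents", None)
    if constituents is not None:
        tide_kwargs["constituents"] = [
            HarmonicConstituent(c["name"], c["amplitude"], c["period"], c.get("phase", 0.0))
            for c in constituents
        ]
    if "bloom_window" in spec and spec["bloom_window"] is not None:
        spec["bloom_window"] = tuple(spec["bloom_window"])
    tide = generate_water_level(TideConfig(**tide_kwargs))
    params = EcosystemParams(seed=seed, **spec)
    ds = generate_ecosystem(tide, params)
    if gaps:
        for name, lengths in gaps.items():
            series = getattr(ds, name)
            offset = sum(ord(c) for c in name)  # stable per-variable stream
            setattr(ds, name, inject_gaps(series, lengths, seed=seed + offset))
    return ds


def _analyse_series(
    ts: TimeSeries, min_segment: int, dj: float, level: float
) -> dict | None:
    """Segment, transform, aggregate: global spectrum peaks per named band."""
    segs = segment(ts, min_segment)
    if not segs:
        return None
    params = WaveletParams(dj=dj)
    spectra = []
    # common scale ladder across segments: size it from the longest segment
    longest = max(segs, key=lambda s: s.length)
    params.n_scales = len(params.scales(longest.length, ts.step))
    alphas, variances, weights = [], [], []
    for sg in segs:
        piece = sg.extract(ts)
        model = estimate_ar1(piece)
        sp = rednoise_significance(morlet_cwt(piece, params), model, level)
        spectra.append(sp)
        alphas.append(model.alpha)
        variances.append(model.variance)
        weights.append(sg.length)
    from .wavelet import RedNoiseModel

    model = RedNoiseModel(
        alpha=float(np.average(alphas, weights=weights)),
        variance=float(np.average(variances, weights=weights)),
    )
    gs = global_spectrum(spectra, model, level)
    peaks = {}
    for name, band in DEFAULT_BANDS.items():
        lo, hi = band
        if hi / ts.step < 4 or lo > gs.fourier_periods[-1]:
            continue
        sel = (gs.fourier_periods >= lo) & (gs.fourier_periods <= hi)
        if not sel.any():
            continue
        period, at_boundary = peak_period(gs, band)
        sig = bool(
            (gs.mean_power[sel] > gs.signif[sel]).any()
        )
        peaks[name] = {
            "period_minutes": period,
            "at_boundary": at_boundary,
            "significant": sig,
        }
    return {
        "n_segments": len(segs),
        "n_timepoints": gs.n_timepoints,
        "alpha": model.alpha,
        "peaks": peaks,
        "_global": gs,
        "_spectra": spectra,
    }


def _joint_gapfree(x: TimeSeries, y: TimeSeries, min_len: int):
    """Longest common gap-free stretch of two co-registered series."""
    x, y = overlap(x, y)
    valid = ~np.isnan(x.values) & ~np.isnan(y.values)
    best = None
    i = 0
    n = len(valid)
    while i < n:
        if valid[i]:
            j = i
            while j < n and valid[j]:
                j += 1
            if best is None or j - i > best[1] - best[0]:
                best = (i, j)
            i = j
        else:
            i += 1
    if best is None or best[1] - best[0] < min_len:
        return None
    return x.slice(*best), y.slice(*best)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured analysis; returns the summary dictionary."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO, format="%(levelname)s %(name)s: %(message)s")
    meta = {"version": __version__, "seed": config.seed, "config_hash": config.digest()}
    log.info("pipeline start (seed=%s, hash=%s)", config.seed, meta["config_hash"])

    # --- obtain the data ------------------------------------------------------
    if config.simulate is not None:
        ds = simulate_dataset(config.simulate, config.seed)
        series = ds.series()
        truth = dict(ds.truth, **meta)
        write_truth(truth, out / "truth.json")
    elif config.inputs:
        from .io import read_timeseries

        series = {name: read_timeseries(path, variable=name) for name, path in config.inputs.items()}
    else:
        raise ValueError("config must provide either `simulate` or `inputs`")
    for name, ts in series.items():
        write_timeseries(ts, out / "raw" / f"{name}.csv")

    # --- prepared-series registry --------------------------------------------
    prepared: dict[str, TimeSeries] = {}
    summary: dict = {"meta": meta, "variables": {}, "coherence": {}}

    w = series.get("water_level")
    if w is not None:
        prepared["water_level@hourly"] = fill_small_gaps(hourly_average(w))
        prepared["tc@hourly"] = tidal_current_speed(w, hourly=True)
        prepared["tidal_range@daily"] = tidal_range(w)
    par = series.get("par")
    for name, ts in series.items():
        if name in ("water_level", "par"):
            continue
        hourly = fill_small_gaps(hourly_average(ts))
        daily = fill_small_gaps(
            daily_average(ts, par=par if name == "chlorophyll" else None,
                          dark_threshold=config.dark_threshold)
        )
        prepared[f"{name}@hourly"] = hourly
        prepared[f"{name}@daily"] = daily
        if name in RATE_VARIABLES:
            prepared[f"rate({name})@hourly"] = log_smooth_diff(hourly)
            prepared[f"rate({name})@daily"] = log_smooth_diff(daily)

    # --- wavelet analysis per variable/cadence ---------------------------------
    analysed = [
        k for k in prepared
        if k.startswith("rate(") or k.split("@")[0] in ("water_level", "tidal_range", "tc")
    ]
    for key in analysed:
        ts = prepared[key]
        min_seg = config.min_segment_daily if key.endswith("@daily") else config.min_segment_hourly
        res = _analyse_series(ts, min_seg, config.dj, config.level)
        if res is None:
            summary["variables"][key] = {"n_segments": 0, "peaks": {}}
            continue
        gs = res.pop("_global")
        res.pop("_spectra")
        summary["variables"][key] = res
        pd.DataFrame(
            {"period_minutes": gs.fourier_periods, "mean_power": gs.mean_power,
             "signif": gs.signif}
        ).to_csv(out / f"global_spectrum_{key.replace('@','_').replace('(','_').replace(')','')}.csv", index=False)

    # --- coherence pairs --------------------------------------------------------
    for pair in config.coherence_pairs:
        key = f"{pair.x}~{pair.y}"
        if pair.x not in prepared or pair.y not in prepared:
            summary["coherence"][key] = {"skipped": "series unavailable"}
            continue
        joint = _joint_gapfree(prepared[pair.x], prepared[pair.y], min_len=16)
        if joint is None:
            summary["coherence"][key] = {"skipped": "no common gap-free stretch"}
            continue
        x, y = joint
        params = WaveletParams(dj=config.dj)
        cs = wavelet_coherence(x, y, params)
        cs = mc_coherence_significance(
            x, y, cs, n_surrogates=config.n_surrogates, seed=config.seed, level=config.level
        )
        hist = phase_distribution(cs, pair.band, pair.bin_width)
        summary["coherence"][key] = {
            "band_minutes": list(pair.band),
            "n_significant_cells": hist.n,
            "circular_mean_deg": hist.circular_mean,
            "circular_std_deg": hist.circular_std,
            "empty": hist.empty,
        }
        pd.DataFrame(
            {"bin_left_deg": hist.bin_edges[:-1], "count": hist.counts}
        ).to_csv(out / f"phase_hist_{key.replace('@','_').replace('~','_vs_').replace('(','_').replace(')','')}.csv", index=False)

    def _jsonify(obj):
        if isinstance(obj, dict):
            return {k: _jsonify(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [_jsonify(v) for v in obj]
        if isinstance(obj, (np.floating, float)):
            return None if np.isnan(obj) else float(obj)
        if isinstance(obj, (np.integer, np.bool_)):
            return obj.item()
        return obj

    summary = _jsonify(summary)
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
        fh.write("\n")
    log.info("pipeline done: %s", out / "summary.json")
    return summary
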