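"""Multi-domain feature extraction and participant-level feature tables.

Every segment x channel yields a fixed registry of 84 features: 42
time-domain statistics, 22 spectral statistics from the one-sided DFT
power spectrum (rectangular window), and the top 10 power amplitudes of
the DFT and of the Lomb-Scargle periodogram (fixed 0.1-20 Hz grid). Each
segment additionally yields 3 features for each of the 15 unordered
channel pairs. For the two-trial tasks (TUG, cogTUG) every base feature
appears in four derivations: trial 1, trial 2, the trial mean and the
trial difference. The registry is versioned by its explicit name lists;
counts are enforced at import time.

Table preprocessing (constant/non-finite column elimination and median
imputation) is fit on training rows only and reusable on held-out rows,
so cross-validation stays leakage-free.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
from numpy.fft import rfft, rfftfreq
from numpy.lib.stride_tricks import sliding_window_view
from scipy.signal import correlate, lombscargle

from .segmentation import SegmentationError, SegmentationParams, segment_task
from .signal_io import CHANNELS, FilterSpec, SensorRecording, lowpass_filter
from .simulate import Participant, STANCE_TASKS, TASKS

# ---------------------------------------------------------------------------
# registry

TIME_FEATURES: tuple[str, ...] = (
    "mean", "sd", "var", "rms", "min", "max", "range", "median", "iqr", "mad",
    "skewness", "kurtosis", "energy", "mean_abs", "median_abs", "p5", "p25",
    "p75", "p95", "trimmed_mean", "sem", "zero_cross_rate", "mean_cross_rate",
    "peak_rate", "frac_above_mean", "hist_entropy", "diff_mean_abs", "diff_sd",
    "diff_rms", "diff_max_abs", "diff2_rms", "autocorr_lag1", "autocorr_lag5",
    "autocorr_lag10", "autocorr_lag25", "sample_entropy", "hjorth_mobility",
    "hjorth_complexity", "crest_factor", "impulse_factor", "shape_factor",
    "margin_factor",
)

FREQ_FEATURES: tuple[str, ...] = (
    "total_power", "centroid", "spread", "spec_skewness", "spec_kurtosis",
    "spec_entropy", "flatness", "dominant_freq", "dominant_power",
    "median_freq", "edge95_freq", "bp_0p5_3", "bp_3_8", "bp_8_12", "bp_12_20",
    "rbp_0p5_3", "rbp_3_8", "rbp_8_12", "rbp_12_20", "low_high_ratio",
    "spec_slope", "peakiness",
)

DFT_FEATURES: tuple[str, ...] = tuple(f"dft_amp{i}" for i in range(1, 11))
LSP_FEATURES: tuple[str, ...] = tuple(f"lsp_amp{i}" for i in range(1, 11))
PAIR_FEATURES: tuple[str, ...] = ("pearson_r", "max_xcorr", "mag_area_ratio")

assert len(TIME_FEATURES) == 42 and len(set(TIME_FEATURES)) == 42
assert len(FREQ_FEATURES) == 22 and len(set(FREQ_FEATURES)) == 22
assert len(PAIR_FEATURES) == 3

CHANNEL_PAIRS: tuple[tuple[str, str], ...] = tuple(combinations(CHANNELS, 2))
LSP_GRID_HZ = np.arange(0.1, 20.0 + 1e-9, 0.1)

#: per segment x channel base feature count, and per segment pairwise count
N_CHANNEL_FEATURES = len(TIME_FEATURES) + len(FREQ_FEATURES) + 10 + 10  # 84
N_PAIRWISE = len(CHANNEL_PAIRS) * len(PAIR_FEATURES)  # 45
N_SEGMENT_FEATURES = len(CHANNELS) * N_CHANNEL_FEATURES + N_PAIRWISE  # 549

_EPS = 1e-30


# ---------------------------------------------------------------------------
# per-series feature functions

def time_domain_features(x: np.ndarray) -> dict[str, float]:
    """The registry's 42 time-domain statistics of one channel segment."""
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 2:
        raise ValueError("time_domain_features needs at least 2 samples")
    with np.errstate(all="ignore"):
        mean = x.mean()
        sd = x.std(ddof=1)
        xc = x - mean
        absx = np.abs(x)
        mean_abs = absx.mean()
        rms = np.sqrt((x * x).mean())
        p5, p25, med, p75, p95 = np.percentile(x, [5, 25, 50, 75, 95])
        d1 = np.diff(x)
        d2 = np.diff(d1) if n > 2 else np.array([np.nan])
        sd_d1 = d1.std(ddof=1) if n > 2 else np.nan
        sd_d2 = d2.std(ddof=1) if n > 3 else np.nan
        mobility = sd_d1 / sd if sd > 0 else np.nan
        mobility_d = sd_d2 / sd_d1 if n > 3 and sd_d1 > 0 else np.nan
        k = max(1, int(round(0.1 * n)))
        trimmed = np.sort(x)[k : n - k].mean() if n - 2 * k > 0 else med
        sign_zero = np.signbit(x)
        sign_mean = np.signbit(xc)
        peaks = 0
        if n > 2:
            peaks = int(np.sum((x[1:-1] > x[:-2]) & (x[1:-1] > x[2:])))
        hist, _ = np.histogram(x, bins=16)
        p_hist = hist[hist > 0] / n
        out = {
            "mean": mean, "sd": sd, "var": x.var(ddof=1), "rms": rms,
            "min": x.min(), "max": x.max(), "range": np.ptp(x), "median": med,
            "iqr": p75 - p25, "mad": np.median(np.abs(x - med)),
            "skewness": (xc**3).mean() / (xc**2).mean() ** 1.5 if sd > 0 else np.nan,
            "kurtosis": (xc**4).mean() / (xc**2).mean() ** 2 if sd > 0 else np.nan,
            "energy": float((x * x).sum()), "mean_abs": mean_abs,
            "median_abs": np.median(absx), "p5": p5, "p25": p25, "p75": p75,
            "p95": p95, "trimmed_mean": trimmed, "sem": sd / np.sqrt(n),
            "zero_cross_rate": np.count_nonzero(sign_zero[1:] != sign_zero[:-1]) / (n - 1),
            "mean_cross_rate": np.count_nonzero(sign_mean[1:] != sign_mean[:-1]) / (n - 1),
            "peak_rate": peaks / n, "frac_above_mean": np.mean(x > mean),
            "hist_entropy": float(-(p_hist * np.log(p_hist)).sum()),
            "diff_mean_abs": np.abs(d1).mean(), "diff_sd": sd_d1,
            "diff_rms": np.sqrt((d1 * d1).mean()), "diff_max_abs": np.abs(d1).max(),
            "diff2_rms": np.sqrt((d2 * d2).mean()) if n > 2 else np.nan,
            "autocorr_lag1": _autocorr(xc, 1), "autocorr_lag5": _autocorr(xc, 5),
            "autocorr_lag10": _autocorr(xc, 10), "autocorr_lag25": _autocorr(xc, 25),
            "sample_entropy": sample_entropy(x),
            "hjorth_mobility": mobility, "hjorth_complexity": mobility_d,
            "crest_factor": absx.max() / rms if rms > 0 else np.nan,
            "impulse_factor": absx.max() / mean_abs if mean_abs > 0 else np.nan,
            "shape_factor": rms / mean_abs if mean_abs > 0 else np.nan,
            "margin_factor": absx.max() / (np.sqrt(absx).mean() ** 2 + _EPS),
        }
    return out


def _autocorr(xc: np.ndarray, lag: int) -> float:
    n = xc.size
    if n <= lag + 1:
        return np.nan
    denom = float((xc * xc).sum())
    if denom <= 0:
        return np.nan
    return float((xc[:-lag] * xc[lag:]).sum() / denom)


def sample_entropy(x: np.ndarray, m: int = 2, r_frac: float = 0.2, max_n: int = 200) -> float:
    """Sample entropy (template length m, tolerance 0.2 SD, Chebyshev).

    Series longer than ``max_n`` are decimated to ``max_n`` points on a
    uniform grid; this keeps the quadratic template comparison bounded and
    is part of the registry definition.
    """
    x = np.asarray(x, dtype=float)
    if x.size > max_n:
        x = x[np.linspace(0, x.size - 1, max_n).astype(int)]
    n = x.size
    r = r_frac * x.std()
    if n <= m + 1 or r <= 0:
        return np.nan
    # Chebyshev template matches from one shared close-pair matrix
    close = np.abs(x[:, None] - x[None, :]) <= r
    cm = close[: n - m + 1, : n - m + 1].copy()
    for s in range(1, m):
        cm &= close[s : s + n - m + 1, s : s + n - m + 1]
    b = int(cm.sum()) - (n - m + 1)
    cm = cm[: n - m, : n - m] & close[m:, m:]
    a = int(cm.sum()) - (n - m)
    if a == 0 or b == 0:
        return np.nan
    return float(-np.log(a / b))


def _power_spectrum(x: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    """One-sided DFT power spectrum of the demeaned series, DC excluded."""
    n = x.size
    X = rfft(x - x.mean())
    P = (np.abs(X) ** 2) / n
    f = rfftfreq(n, 1.0 / fs)
    return f[1:], P[1:]


def frequency_domain_features(x: np.ndarray, sample_rate: float) -> dict[str, float]:
    """The registry's 22 spectral statistics, from bins in (0, 20] Hz."""
    x = np.asarray(x, dtype=float)
    if x.size < 8:
        raise ValueError("frequency_domain_features needs at least 8 samples")
    f_all, p_all = _power_spectrum(x, sample_rate)
    keep = f_all <= 20.0
    f, p = f_all[keep], p_all[keep]
    total = float(p.sum())
    with np.errstate(all="ignore"):
        if total <= 0:
            nanpack = {k: (0.0 if k.startswith(("bp_", "total")) else np.nan) for k in FREQ_FEATURES}
            nanpack["total_power"] = 0.0
            return nanpack
        w = p / total
        centroid = float((w * f).sum())
        spread = float(np.sqrt((w * (f - centroid) ** 2).sum()))
        cum = np.cumsum(w)
        bands = {
            "bp_0p5_3": (0.5, 3.0), "bp_3_8": (3.0, 8.0),
            "bp_8_12": (8.0, 12.0), "bp_12_20": (12.0, 20.0),
        }
        bp = {k: float(p[(f > lo) & (f <= hi)].sum()) for k, (lo, hi) in bands.items()}
        low = bp["bp_0p5_3"] + bp["bp_3_8"]
        high = bp["bp_8_12"] + bp["bp_12_20"]
        out = {
            "total_power": total, "centroid": centroid, "spread": spread,
            "spec_skewness": float((w * (f - centroid) ** 3).sum() / spread**3) if spread > 0 else np.nan,
            "spec_kurtosis": float((w * (f - centroid) ** 4).sum() / spread**4) if spread > 0 else np.nan,
            "spec_entropy": float(-(w[w > 0] * np.log(w[w > 0])).sum() / np.log(len(w))) if len(w) > 1 else np.nan,
            "flatness": float(np.exp(np.mean(np.log(p + _EPS))) / p.mean()),
            "dominant_freq": float(f[int(np.argmax(p))]),
            "dominant_power": float(p.max()),
            "median_freq": float(f[int(np.searchsorted(cum, 0.5))]),
            "edge95_freq": float(f[int(np.searchsorted(cum, 0.95))]),
            **bp,
            "rbp_0p5_3": bp["bp_0p5_3"] / total, "rbp_3_8": bp["bp_3_8"] / total,
            "rbp_8_12": bp["bp_8_12"] / total, "rbp_12_20": bp["bp_12_20"] / total,
            "low_high_ratio": low / high if high > 0 else np.nan,
            "spec_slope": float(np.polyfit(f, np.log(p + _EPS), 1)[0]),
            "peakiness": float(p.max() / p.mean()),
        }
    return out


def top_power_amplitudes(
    x: np.ndarray, sample_rate: float, method: str = "dft", k: int = 10
) -> np.ndarray:
    """The k largest spectral power values, sorted descending.

    ``dft`` uses the one-sided DFT power spectrum (DC excluded); ``lsp``
    the Lomb-Scargle periodogram on a fixed 0.1-20 Hz grid.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2 * k:
        raise ValueError(f"top_power_amplitudes needs at least {2 * k} samples")
    if method == "dft":
        _, p = _power_spectrum(x, sample_rate)
    elif method == "lsp":
        p = _lsp_cache.power(x - x.mean(), sample_rate)
    else:
        raise ValueError(f"unknown spectral method {method!r}")
    top = np.sort(p)[::-1][:k]
    return top


class _LombScargleCache:
    """Lomb-Scargle power on the fixed grid for uniformly indexed series.

    All segments share ``t = arange(n)/fs``, so the trig matrices and the
    time-shift terms of the Scargle normalization depend only on (fs, n)
    and can be precomputed once; each periodogram then costs two matrix-
    vector products. Numerically identical to ``scipy.signal.lombscargle``
    on the same grid (cross-checked in the test suite).
    """

    def __init__(self, grid_hz: np.ndarray) -> None:
        self.w = 2 * np.pi * grid_hz  # (nf,)
        self._per_fs: dict[float, tuple] = {}

    def _ensure(self, fs: float, n: int):
        key = round(fs, 9)
        entry = self._per_fs.get(key)
        if entry is None or entry[0] < n:
            n_max = max(n, 2560)
            t = np.arange(n_max) / fs
            wt = self.w[:, None] * t[None, :]
            C, S = np.cos(wt), np.sin(wt)
            cum_c2 = np.cumsum(np.cos(2 * wt), axis=1)
            cum_s2 = np.cumsum(np.sin(2 * wt), axis=1)
            entry = (n_max, C, S, cum_c2, cum_s2)
            self._per_fs[key] = entry
        return entry

    def power(self, x: np.ndarray, fs: float) -> np.ndarray:
        n = x.size
        _, C, S, cum_c2, cum_s2 = self._ensure(fs, n)
        sum_c2, sum_s2 = cum_c2[:, n - 1], cum_s2[:, n - 1]
        two_wtau = np.arctan2(sum_s2, sum_c2)
        cwt, swt = np.cos(two_wtau / 2), np.sin(two_wtau / 2)
        cx = C[:, :n] @ x
        sx = S[:, :n] @ x
        a = cwt * cx + swt * sx  # sum x cos w(t - tau)
        b = cwt * sx - swt * cx  # sum x sin w(t - tau)
        cos_sq = 0.5 * (n + np.cos(two_wtau) * sum_c2 + np.sin(two_wtau) * sum_s2)
        sin_sq = 0.5 * (n - np.cos(two_wtau) * sum_c2 - np.sin(two_wtau) * sum_s2)
        return 0.5 * (a * a / cos_sq + b * b / sin_sq)


_lsp_cache = _LombScargleCache(LSP_GRID_HZ)


def pairwise_features(a: np.ndarray, b: np.ndarray) -> dict[str, float]:
    """Registry trio for a channel pair: Pearson r, max normalized
    cross-correlation magnitude, and the ratio of signal magnitude areas."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size != b.size:
        raise ValueError("pairwise_features needs equal-length channels")
    if a.size < 2:
        raise ValueError("pairwise_features needs at least 2 samples")
    ac, bc = a - a.mean(), b - b.mean()
    na = float(np.sqrt((ac * ac).sum()))
    nb = float(np.sqrt((bc * bc).sum()))
    with np.errstate(all="ignore"):
        r = float((ac * bc).sum() / (na * nb)) if na > 0 and nb > 0 else np.nan
        if na > 0 and nb > 0:
            xc = correlate(ac, bc, mode="full", method="auto")
            max_xc = float(np.abs(xc).max() / (na * nb))
        else:
            max_xc = np.nan
        sb = float(np.abs(b).sum())
        ratio = float(np.abs(a).sum() / sb) if sb > 0 else np.nan
    return {"pearson_r": r, "max_xcorr": max_xc, "mag_area_ratio": ratio}


def _segment_vector(channels: dict[str, np.ndarray], fs: float) -> np.ndarray:
    """Base feature vector (length 549) for one segment, fixed order."""
    vals = np.empty(N_SEGMENT_FEATURES)
    i = 0
    for c in CHANNELS:
        x = channels[c]
        td = time_domain_features(x)
        for name in TIME_FEATURES:
            vals[i] = td[name]
            i += 1
        fd = frequency_domain_features(x, fs)
        for name in FREQ_FEATURES:
            vals[i] = fd[name]
            i += 1
        vals[i : i + 10] = top_power_amplitudes(x, fs, "dft")
        i += 10
        vals[i : i + 10] = top_power_amplitudes(x, fs, "lsp")
        i += 10
    for ca, cb in CHANNEL_PAIRS:
        pf = pairwise_features(channels[ca], channels[cb])
        for name in PAIR_FEATURES:
            vals[i] = pf[name]
            i += 1
    return vals


# ---------------------------------------------------------------------------
# table assembly

TASK_SUBTASKS: dict[str, tuple[str, ...]] = {
    "tug": ("sit_to_stand", "walk1", "turn1", "walk2", "turn2", "stand_to_sit"),
    "cogtug": ("sit_to_stand", "walk1", "turn1", "walk2", "turn2", "stand_to_sit"),
    "walk32ft": ("walk1",),
    "stand_eo_20s": ("stance",),
    "stand_ec_20s": ("stance",),
}


def _base_names() -> list[tuple[str, str, str]]:
    """(channel-or-pair, domain, feature) triples in segment-vector order."""
    out = []
    for c in CHANNELS:
        out += [(c, "time", n) for n in TIME_FEATURES]
        out += [(c, "frequency", n) for n in FREQ_FEATURES]
        out += [(c, "dft", n) for n in DFT_FEATURES]
        out += [(c, "lsp", n) for n in LSP_FEATURES]
    for ca, cb in CHANNEL_PAIRS:
        out += [(f"{ca}-{cb}", "pairwise", n) for n in PAIR_FEATURES]
    return out


_BASE = _base_names()


def build_catalogue(tasks: tuple[str, ...] = tuple(TASKS)) -> pd.DataFrame:
    """Column metadata for the feature table of a task roster.

    One row per column: task, subtask, channel, domain, derivation, feature.
    """
    rows = []
    for task in tasks:
        derivs = ("trial1", "trial2", "mean", "diff") if TASKS[task] == 2 else ("trial1",)
        for deriv in derivs:
            for sub in TASK_SUBTASKS[task]:
                for chan, domain, feat in _BASE:
                    rows.append(
                        {
                            "column": f"{task}.{deriv}.{sub}.{chan}.{feat}",
                            "task": task, "subtask": sub, "channel": chan,
                            "domain": domain, "derivation": deriv, "feature": feat,
                        }
                    )
    meta = pd.DataFrame(rows).set_index("column")
    if meta.index.duplicated().any():
        raise RuntimeError("duplicate feature column names in catalogue")
    return meta


@dataclass
class FeatureTable:
    """Participants x named features, with per-column group metadata."""

    values: pd.DataFrame  # index: participant id
    metadata: pd.DataFrame  # index: column name

    def __post_init__(self) -> None:
        if list(self.values.columns) != list(self.metadata.index):
            raise ValueError("metadata must describe exactly the table columns")

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def columns_for(self, **conditions: str) -> list[str]:
        """Column names whose metadata matches all conditions (e.g. task='tug')."""
        mask = np.ones(len(self.metadata), dtype=bool)
        for key, val in conditions.items():
            mask &= (self.metadata[key] == val).to_numpy()
        return list(self.metadata.index[mask])

    def restrict(self, columns: list[str]) -> "FeatureTable":
        return FeatureTable(self.values[columns], self.metadata.loc[columns])

    def task_groups(self) -> dict[str, list[str]]:
        """Feature-group map keyed by mobility task (for group importance)."""
        return {t: g.index.tolist() for t, g in self.metadata.groupby("task", sort=False)}

    def write(self, path: str | Path) -> None:
        path = Path(path)
        self.values.to_csv(path)
        self.metadata.reset_index().to_json(path.with_suffix(".meta.json"), orient="records")

    @classmethod
    def read(cls, path: str | Path) -> "FeatureTable":
        path = Path(path)
        values = pd.read_csv(path, index_col=0)
        meta = pd.read_json(path.with_suffix(".meta.json"), orient="records").set_index("column")
        return cls(values, meta)


def _task_trial_vector(
    rec: SensorRecording,
    task: str,
    trial: int,
    filter_spec: FilterSpec,
    seg_params: SegmentationParams,
) -> np.ndarray:
    """Per-subtask base vectors for one task trial, concatenated; NaN on
    segmentation failure."""
    subtasks = TASK_SUBTASKS[task]
    out = np.full(len(subtasks) * N_SEGMENT_FEATURES, np.nan)
    filtered = lowpass_filter(rec, filter_spec)
    fs = filtered.sample_rate
    if task in STANCE_TASKS:
        windows = [(0, filtered.n_samples)]
    else:
        try:
            seg = segment_task(filtered, task, trial, seg_params)
        except SegmentationError:
            return out
        windows = [(s, e) for _, s, e in seg.segments]
    for j, (s, e) in enumerate(windows):
        chans = {c: filtered.channels[c][s:e] for c in CHANNELS}
        if e - s >= 20:
            out[j * N_SEGMENT_FEATURES : (j + 1) * N_SEGMENT_FEATURES] = _segment_vector(chans, fs)
    return out


def assemble_feature_table(
    cohort: list[Participant],
    tasks: tuple[str, ...] | None = None,
    filter_spec: FilterSpec | None = None,
    seg_params: SegmentationParams | None = None,
) -> FeatureTable:
    """Filter, segment and featurize a cohort into one participants x
    features table with full column metadata.

    Two-trial tasks contribute trial1/trial2/mean/diff derivations per base
    feature; a missing trial or failed segmentation leaves NaN cells, to be
    imputed later by :class:`TablePreprocessor`.
    """
    filter_spec = filter_spec or FilterSpec()
    seg_params = seg_params or SegmentationParams()
    if tasks is None:
        tasks = tuple(t for t in TASKS if any((t, 1) in p.recordings for p in cohort[:1]))
        tasks = tasks or tuple(TASKS)
    meta = build_catalogue(tasks)
    n_cols = len(meta)
    X = np.full((len(cohort), n_cols), np.nan)
    for i, part in enumerate(cohort):
        pieces = []
        for task in tasks:
            width = len(TASK_SUBTASKS[task]) * N_SEGMENT_FEATURES
            trials = []
            for trial in range(1, TASKS[task] + 1):
                rec = part.recordings.get((task, trial))
                if rec is None:
                    trials.append(np.full(width, np.nan))
                else:
                    trials.append(_task_trial_vector(rec, task, trial, filter_spec, seg_params))
            if TASKS[task] == 2:
                t1, t2 = trials
                pieces += [t1, t2, (t1 + t2) / 2.0, t1 - t2]
            else:
                pieces.append(trials[0])
        X[i] = np.concatenate(pieces)
    values = pd.DataFrame(X, index=[p.pid for p in cohort], columns=meta.index)
    return FeatureTable(values, meta)


# ---------------------------------------------------------------------------
# preprocessing

class TablePreprocessor:
    """Constant/non-finite column elimination + per-column median imputation.

    ``fit`` sees training rows only; the fitted state (kept columns and
    medians) is applied unchanged to held-out rows, so no test-row value
    ever enters the medians.
    """

    def __init__(self) -> None:
        self.kept_columns: list[str] | None = None
        self.medians_: np.ndarray | None = None

    def fit(self, table: FeatureTable, rows: np.ndarray | list[int]) -> "TablePreprocessor":
        rows = np.asarray(rows)
        if rows.size == 0:
            raise ValueError("fit_rows must be non-empty")
        X = table.values.to_numpy()[rows]
        with np.errstate(all="ignore"):
            has_inf = np.isinf(X).any(axis=0)
            lo = np.nanmin(np.where(np.isinf(X), np.nan, X), axis=0)
            hi = np.nanmax(np.where(np.isinf(X), np.nan, X), axis=0)
        all_nan = np.isnan(X).all(axis=0)
        constant = (lo == hi) | all_nan
        keep = ~(has_inf | constant)
        if not keep.any():
            raise ValueError("preprocessing dropped all columns")
        self.kept_columns = list(table.values.columns[keep])
        self.medians_ = np.nanmedian(X[:, keep], axis=0)
        return self

    def transform(self, table: FeatureTable, rows: np.ndarray | list[int] | None = None) -> pd.DataFrame:
        if self.kept_columns is None:
            raise RuntimeError("preprocessor not fitted")
        df = table.values[self.kept_columns]
        if rows is not None:
            df = df.iloc[np.asarray(rows)]
        X = df.to_numpy(copy=True)
        bad = ~np.isfinite(X)
        if bad.any():
            X[bad] = np.broadcast_to(self.medians_, X.shape)[bad]
        return pd.DataFrame(X, index=df.index, columns=self.kept_columns)


def preprocess_table(
    table: FeatureTable, fit_rows: np.ndarray | list[int]
) -> tuple[pd.DataFrame, TablePreprocessor]:
    """Fit preprocessing on ``fit_rows`` and return the transformed full
    table plus the fitted state (reusable on held-out rows)."""
    prep = TablePreprocessor().fit(table, fit_rows)
    return prep.transform(table), prep
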