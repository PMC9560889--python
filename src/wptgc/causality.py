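"""Directed Granger causality, sliding-window time-varying GC, and
time-frequency map assembly over wavelet-packet bands.

GC in each direction is the log ratio of restricted to full one-step
prediction-error variances, ln(var(Y|Y-)/var(Y|Y-,X-)).  The full model
is refit on the union of the restricted model's terms and the
FROLS-selected input-bearing terms, over the same sample rows, so the
ratio is monotone (>= 1) up to numerics; reported map values are clamped
at zero and the raw values kept in metadata.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .narx import NARXModel, StopRule, fit_nar, fit_narx
from .wpt import extract_band, wpt_decompose

logger = logging.getLogger(__name__)

__all__ = [
    "GCPair",
    "TVGCSeries",
    "TFGCMap",
    "BandSummary",
    "GroupComparison",
    "DEFAULT_BANDS",
    "DEFAULT_PERIODS",
    "gc_pair",
    "tv_gc",
    "tf_gc_map",
    "band_average",
    "compare_groups",
    "surrogate_threshold",
]

#: canonical EEG rhythm bands (Hz, half-open); the gamma upper edge is
#: capped at the 50 Hz extraction limit.
DEFAULT_BANDS = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (9.0, 12.0),
    "beta": (13.0, 35.0),
    "gamma": (35.0, 50.0),
}

#: movement preparation / execution windows (s) of a 7 s segment
DEFAULT_PERIODS = {"preparation": (0.0, 3.0), "execution": (3.0, 7.0)}

_MIN_FULL_VARIANCE = 1e-15


@dataclass
class GCPair:
    """Both directed GC values for one signal pair."""

    g_xy: float
    g_yx: float
    raw_xy: float
    raw_yx: float
    models: dict[str, NARXModel] = field(default_factory=dict)


def _directed_gc(target, source, p, q, stop, degree, refit):
    offset = max(p, q)
    restricted = fit_nar(target, p, stop=stop, degree=degree, refit=refit,
                         offset=offset)
    full = fit_narx(target, source, p, q, stop=stop, degree=degree,
                    refit=refit, offset=offset, extra_terms=restricted.terms)
    if full.residual_variance < _MIN_FULL_VARIANCE:
        raise ValueError(
            "full-model residual variance below 1e-15; the log variance "
            "ratio is numerically unstable (near-noiseless coupling)"
        )
    raw = float(np.log(restricted.residual_variance / full.residual_variance))
    return raw, restricted, full


def gc_pair(y, x, p: int = 5, q: int = 5, stop: StopRule | None = None,
            degree: int = 2, refit: bool = True) -> GCPair:
    """Directed GC between two equal-length series, both directions.

    Fits NAR(y), NARX(y|x), NAR(x), NARX(x|y); g_xy =
    ln(var(Y|Y-)/var(Y|Y-,X-)) clamped at zero, likewise g_yx.
    """
    y = np.asarray(y, dtype=float).ravel()
    x = np.asarray(x, dtype=float).ravel()
    if y.size != x.size:
        raise ValueError(f"length mismatch: y has {y.size}, x has {x.size}")
    max_lag = max(p, q)
    if y.size <= 10 * max_lag:
        raise ValueError(
            f"series too short: need more than {10 * max_lag} samples for "
            f"max lag {max_lag}"
        )
    if stop is None:
        stop = StopRule()
    raw_xy, m_y_r, m_y_f = _directed_gc(y, x, p, q, stop, degree, refit)
    raw_yx, m_x_r, m_x_f = _directed_gc(x, y, p, q, stop, degree, refit)
    return GCPair(
        g_xy=max(raw_xy, 0.0), g_yx=max(raw_yx, 0.0),
        raw_xy=raw_xy, raw_yx=raw_yx,
        models={"y|y": m_y_r, "y|yx": m_y_f, "x|x": m_x_r, "x|xy": m_x_f},
    )


@dataclass
class TVGCSeries:
    """Sliding-window GC: one value per window center per direction."""

    window_centers: np.ndarray   # seconds
    window_length: float         # seconds
    step: float                  # seconds
    g_xy: np.ndarray
    g_yx: np.ndarray
    raw_xy: np.ndarray
    raw_yx: np.ndarray


def tv_gc(y, x, fs: float, window: float = 1.0, step: float = 0.1,
          p: int = 5, q: int = 5, stop: StopRule | None = None,
          degree: int = 2, refit: bool = True) -> TVGCSeries:
    """Time-varying GC under short-time invariance.

    A time-invariant model pair is refit inside each sliding window of
    ``window`` seconds, advanced by ``step`` seconds; one full-length
    window reduces exactly to `gc_pair`.
    """
    y = np.asarray(y, dtype=float).ravel()
    x = np.asarray(x, dtype=float).ravel()
    if y.size != x.size:
        raise ValueError(f"length mismatch: y has {y.size}, x has {x.size}")
    n = y.size
    wlen = min(int(round(window * fs)), n)
    max_lag = max(p, q)
    if wlen <= 10 * max_lag:
        raise ValueError(
            f"window of {wlen} samples too short: need more than "
            f"{10 * max_lag} samples ({(10 * max_lag + 1) / fs:.3f} s at "
            f"fs={fs})"
        )
    step_samples = max(int(round(step * fs)), 1)
    starts = np.arange(0, n - wlen + 1, step_samples)
    centers = (starts + wlen / 2.0) / fs
    g_xy, g_yx, raw_xy, raw_yx = [], [], [], []
    for s in starts:
        pair = gc_pair(y[s: s + wlen], x[s: s + wlen], p=p, q=q, stop=stop,
                       degree=degree, refit=refit)
        g_xy.append(pair.g_xy)
        g_yx.append(pair.g_yx)
        raw_xy.append(pair.raw_xy)
        raw_yx.append(pair.raw_yx)
    return TVGCSeries(
        window_centers=centers, window_length=wlen / fs, step=step,
        g_xy=np.asarray(g_xy), g_yx=np.asarray(g_yx),
        raw_xy=np.asarray(raw_xy), raw_yx=np.asarray(raw_yx),
    )


@dataclass
class TFGCMap:
    """Frequency x time matrix of directed GC values."""

    freqs: np.ndarray      # band center frequencies, Hz, ascending
    times: np.ndarray      # window centers, s, ascending
    values: np.ndarray     # shape (len(freqs), len(times)), clamped >= 0
    direction: str         # "x->y" or "y->x"

    def __post_init__(self):
        if self.values.shape != (self.freqs.size, self.times.size):
            raise ValueError("map dimensions inconsistent with axes")

    def time_averaged(self) -> np.ndarray:
        """Mean over time per frequency row (NaN-aware)."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(self.values, axis=1)


def tf_gc_map(y, x, fs: float, freqs=None, wavelet: str = "coif5",
              levels: int = 7, window: float = 1.0, step: float = 0.1,
              p: int = 5, q: int = 5, stop: StopRule | None = None,
              degree: int = 2, refit: bool = True):
    """Band-wise time-varying GC: the full time-frequency method.

    Each signal is wavelet-packet decomposed once; for every requested
    center frequency the matching narrowband reconstructions are passed
    through `tv_gc`.  A band whose fit fails is recorded as a NaN row
    (missing), never as zero.  Returns (map x->y, map y->x).
    """
    if freqs is None:
        freqs = np.arange(1, 51, dtype=float)
    freqs = np.asarray(sorted(freqs), dtype=float)
    if np.any(freqs <= 0) or np.any(freqs >= fs / 2):
        raise ValueError(f"frequencies must lie in (0, {fs / 2})")
    dec_y = wpt_decompose(y, wavelet, levels, fs)
    dec_x = wpt_decompose(x, wavelet, levels, fs)
    rows_xy, rows_yx, times = [], [], None
    for f in freqs:
        band_y = extract_band(dec_y, f)
        band_x = extract_band(dec_x, f)
        try:
            tv = tv_gc(band_y.w, band_x.w, fs, window=window, step=step,
                       p=p, q=q, stop=stop, degree=degree, refit=refit)
        except (ValueError, np.linalg.LinAlgError) as exc:
            logger.warning("band %.3f Hz failed, recorded as missing: %s",
                           f, exc)
            if times is None:
                raise ValueError(
                    f"first band ({f} Hz) failed; cannot size the map"
                ) from exc
            rows_xy.append(np.full(times.size, np.nan))
            rows_yx.append(np.full(times.size, np.nan))
            continue
        if times is None:
            times = tv.window_centers
        rows_xy.append(tv.g_xy)
        rows_yx.append(tv.g_yx)
        logger.info("band %.3f Hz done", f)
    return (
        TFGCMap(freqs=freqs, times=times, values=np.vstack(rows_xy),
                direction="x->y"),
        TFGCMap(freqs=freqs, times=times, values=np.vstack(rows_yx),
                direction="y->x"),
    )


@dataclass
class BandSummary:
    """Mean GC per (band, period) for one direction."""

    direction: str
    bands: dict[str, tuple[float, float]]
    periods: dict[str, tuple[float, float]]
    means: dict[str, dict[str, float]]   # band -> period -> mean GC

    def as_records(self) -> list[dict]:
        return [
            {"direction": self.direction, "band": b, "period": p,
             "f_lo": self.bands[b][0], "f_hi": self.bands[b][1],
             "t_start": self.periods[p][0], "t_end": self.periods[p][1],
             "mean_gc": v}
            for b, by_period in self.means.items()
            for p, v in by_period.items()
        ]


def band_average(tf_map: TFGCMap, bands: dict | None = None,
                 periods: dict | None = None) -> BandSummary:
    """Average map cells into named (frequency band, time period) boxes.

    Membership is half-open on both axes: a cell belongs to a band if
    f_lo <= f_center < f_hi and to a period if t0 <= window center < t1.
    """
    if bands is None:
        bands = DEFAULT_BANDS
    if periods is None:
        periods = DEFAULT_PERIODS
    means: dict[str, dict[str, float]] = {}
    for bname, (f_lo, f_hi) in bands.items():
        fmask = (tf_map.freqs >= f_lo) & (tf_map.freqs < f_hi)
        if not fmask.any():
            raise ValueError(f"band {bname!r} [{f_lo}, {f_hi}) contains no "
                             "map frequencies")
        means[bname] = {}
        for pname, (t0, t1) in periods.items():
            tmask = (tf_map.times >= t0) & (tf_map.times < t1)
            if not tmask.any():
                raise ValueError(f"period {pname!r} [{t0}, {t1}) contains no "
                                 "map windows")
            cells = tf_map.values[np.ix_(fmask, tmask)]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                means[bname][pname] = float(np.nanmean(cells))
    return BandSummary(direction=tf_map.direction, bands=dict(bands),
                       periods=dict(periods), means=means)


@dataclass
class GroupComparison:
    """Routed group test: ANOVA when the parametric gate passes, else KW."""

    route: str                  # "anova" | "kruskal"
    statistic: float
    p_value: float
    normality_p: dict[str, float]
    homogeneity_p: float
    alpha_gate: float

    def as_dict(self) -> dict:
        return {
            "route": self.route, "statistic": self.statistic,
            "p_value": self.p_value, "normality_p": self.normality_p,
            "homogeneity_p": self.homogeneity_p,
            "alpha_gate": self.alpha_gate,
        }


def compare_groups(samples: dict[str, list | np.ndarray],
                   alpha_gate: float = 0.05) -> GroupComparison:
    """Gate on Shapiro-Wilk normality and Levene homogeneity, then test.

    One-way ANOVA when every group looks normal and variances look
    homogeneous (all gate p-values > ``alpha_gate``); otherwise the
    Kruskal-Wallis test.
    """
    if len(samples) < 2:
        raise ValueError("need at least 2 groups")
    arrays = {k: np.asarray(v, dtype=float).ravel() for k, v in samples.items()}
    for name, arr in arrays.items():
        if arr.size < 3:
            raise ValueError(f"group {name!r} has fewer than 3 values")
    normality_p = {}
    for name, arr in arrays.items():
        if np.ptp(arr) == 0:
            normality_p[name] = 1.0     # constant group: nothing to reject
        else:
            normality_p[name] = float(stats.shapiro(arr).pvalue)
    groups = list(arrays.values())
    if all(np.ptp(a) == 0 for a in groups):
        homogeneity_p = 1.0
    else:
        homogeneity_p = float(stats.levene(*groups).pvalue)
    parametric = (min(normality_p.values()) > alpha_gate
                  and homogeneity_p > alpha_gate)
    if parametric:
        res = stats.f_oneway(*groups)
        route = "anova"
    else:
        res = stats.kruskal(*groups)
        route = "kruskal"
    return GroupComparison(
        route=route, statistic=float(res.statistic),
        p_value=float(res.pvalue), normality_p=normality_p,
        homogeneity_p=homogeneity_p, alpha_gate=alpha_gate,
    )


def surrogate_threshold(y, x, n_surr: int = 99, alpha: float = 0.05,
                        seed: int | None = None, p: int = 5, q: int = 5,
                        stop: StopRule | None = None, degree: int = 2,
                        refit: bool = True) -> dict[str, float]:
    """Empirical per-direction GC significance thresholds.

    The putative cause is circularly time-shifted by a random offset (at
    least 2*max lag away from zero), destroying the causal alignment
    while preserving the marginal spectra; the threshold per direction is
    the rank-based (1 - alpha) quantile of the surrogate GC values.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if (n_surr + 1) * alpha < 1:
        raise ValueError(
            f"n_surr={n_surr} too small for alpha={alpha}; need at least "
            f"{int(np.ceil(1 / alpha)) - 1}"
        )
    y = np.asarray(y, dtype=float).ravel()
    x = np.asarray(x, dtype=float).ravel()
    rng = np.random.default_rng(seed)
    n = y.size
    min_shift = min(2 * max(p, q) + 1, n // 4)
    if stop is None:
        stop = StopRule()
    vals_xy, vals_yx = [], []
    for _ in range(n_surr):
        sx = np.roll(x, int(rng.integers(min_shift, n - min_shift)))
        raw, _, _ = _directed_gc(y, sx, p, q, stop, degree, refit)
        vals_xy.append(max(raw, 0.0))
        sy = np.roll(y, int(rng.integers(min_shift, n - min_shift)))
        raw, _, _ = _directed_gc(x, sy, p, q, stop, degree, refit)
        vals_yx.append(max(raw, 0.0))
    k = int(np.ceil((1 - alpha) * (n_surr + 1))) - 1   # exact rank quantile
    return {
        "x->y": float(np.sort(vals_xy)[k]),
        "y->x": float(np.sort(vals_yx)[k]),
    }
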