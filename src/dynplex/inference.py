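"""Functional network inference from multichannel voltage time series.

Pipeline: zero-phase band-pass filtering (forward-reverse FIR), short
overlapping windows normalized per channel, then a significant
cross-correlation test per channel pair and window.  The pair statistic is
the maximum absolute cross-correlation over lags up to ``max_lag``; its
null scale is a single dataset-wide number, the average variance of the
cross-correlation sequence over all pairs and windows.  The statistic is
mapped to a p-value as the maximum of the per-lag two-sided normal tests
(treating the scanned lags as independent, which is conservative for
band-limited data), and edges are the pairs passing Benjamini-Hochberg FDR
within each window.  One graph layer per window; the whole pipeline is
deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal
from scipy.special import ndtr
from statsmodels.stats.multitest import multipletests

from .graphs import LayeredGraph


@dataclass(frozen=True)
class InferenceConfig:
    band: tuple[float, float] = (4.0, 50.0)  # Hz
    fir_order: int = 1000
    window: float = 1.0  # s
    overlap: float = 0.5  # s
    max_lag: float = 0.2  # s
    fdr_q: float = 0.05

    def validate(self, rate: float) -> None:
        lo, hi = self.band
        if not (0 < lo < hi < rate / 2):
            raise ValueError(f"band {self.band} must lie inside (0, rate/2)")
        if not (self.window > self.overlap >= 0):
            raise ValueError("need window > overlap >= 0")
        if self.max_lag < 0 or self.max_lag >= self.window:
            raise ValueError("max_lag must be in [0, window)")


@dataclass
class WindowedSeries:
    """Filtered, windowed, per-channel normalized data.

    ``data`` has shape (windows, channels, samples); ``flat`` marks
    zero-variance (channel, window) combinations, which are zeroed and
    excluded from edge testing.
    """

    data: np.ndarray
    rate: float
    flat: np.ndarray  # (windows, channels) bool


def design_bandpass(config: InferenceConfig, rate: float) -> np.ndarray:
    """FIR band-pass taps (order ``fir_order``, i.e. order+1 taps)."""
    return signal.firwin(
        config.fir_order + 1, list(config.band), pass_zero=False, fs=rate
    )


def preprocess(
    series: np.ndarray, rate: float, config: InferenceConfig = InferenceConfig()
) -> WindowedSeries:
    """Band-pass filter (zero phase), window, and normalize a recording.

    ``series`` is channels x samples.  Windows of ``window`` seconds hop by
    ``window - overlap``; a partial window at the tail is dropped.  Each
    channel within each window is scaled to zero mean and unit variance.
    """
    series = np.asarray(series, dtype=float)
    if series.ndim != 2:
        raise ValueError("series must be channels x samples")
    config.validate(rate)
    wlen = int(round(config.window * rate))
    hop = int(round((config.window - config.overlap) * rate))
    if series.shape[1] < wlen:
        raise ValueError("series shorter than one window")
    taps = design_bandpass(config, rate)
    padlen = min(3 * len(taps), series.shape[1] - 1)
    filtered = signal.filtfilt(taps, [1.0], series, axis=1, padlen=padlen)
    n_windows = (filtered.shape[1] - wlen) // hop + 1
    n_ch = series.shape[0]
    data = np.empty((n_windows, n_ch, wlen))
    flat = np.zeros((n_windows, n_ch), dtype=bool)
    for w in range(n_windows):
        seg = filtered[:, w * hop : w * hop + wlen]
        mu = seg.mean(axis=1, keepdims=True)
        sd = seg.std(axis=1, keepdims=True)
        flat[w] = sd[:, 0] == 0
        sd[sd == 0] = 1.0
        data[w] = (seg - mu) / sd
    return WindowedSeries(data, rate, flat)


def _window_crosscorr(x: np.ndarray, n_lags: int) -> tuple[np.ndarray, np.ndarray]:
    """Max |cross-correlation| over lags and its per-pair variance over lags.

    ``x`` is channels x samples (unit variance).  Returns the (ch, ch)
    matrices of the max statistic and of the variance of the correlation
    sequence across the 2*n_lags+1 scanned lags.
    """
    n_ch, n = x.shape
    best = np.zeros((n_ch, n_ch))
    s1 = np.zeros((n_ch, n_ch))
    s2 = np.zeros((n_ch, n_ch))
    for lag in range(n_lags + 1):
        c = x[:, : n - lag] @ x[:, lag:].T / n
        a = np.abs(c)
        np.maximum(best, np.maximum(a, a.T), out=best)
        if lag == 0:
            s1 += c
            s2 += c * c
        else:  # lag and -lag: c[i,j] at +lag equals c[j,i] at -lag
            s1 += c + c.T
            s2 += c * c + (c * c).T
    total = 2 * n_lags + 1
    var = s2 / total - (s1 / total) ** 2
    return best, var


def correlation_network(
    windows: WindowedSeries, config: InferenceConfig = InferenceConfig()
) -> LayeredGraph:
    """Build one binary graph layer per window from significant correlations.

    The null scale sigma^2 is computed once: the average, over all valid
    pairs and all windows, of the variance of the cross-correlation over
    scanned lags.  Per window, pair p-values are BH-FDR corrected at
    ``fdr_q``; surviving pairs become edges.
    """
    n_win, n_ch, _ = windows.data.shape
    if n_ch < 2:
        return LayeredGraph.from_edge_lists(max(n_ch, 1), [[] for _ in range(n_win)])
    n_lags = int(round(config.max_lag * windows.rate))
    total_lags = 2 * n_lags + 1
    iu = np.triu_indices(n_ch, k=1)

    stats = np.empty((n_win, len(iu[0])))
    var_sum = 0.0
    var_n = 0
    valid = np.empty((n_win, len(iu[0])), dtype=bool)
    for w in range(n_win):
        best, var = _window_crosscorr(windows.data[w], n_lags)
        ok = ~(windows.flat[w][:, None] | windows.flat[w][None, :])
        stats[w] = best[iu]
        valid[w] = ok[iu]
        var_sum += var[iu][valid[w]].sum()
        var_n += int(valid[w].sum())
    if var_n == 0 or var_sum <= 0:
        return LayeredGraph.from_edge_lists(n_ch, [[] for _ in range(n_win)])
    sigma = np.sqrt(var_sum / var_n)

    layers = []
    for w in range(n_win):
        z = stats[w] / sigma
        # max of total_lags two-sided normal tests, treated as independent
        per_lag = 2.0 * ndtr(-z)
        with np.errstate(divide="ignore"):
            pvals = -np.expm1(total_lags * np.log1p(-np.minimum(per_lag, 1.0 - 1e-16)))
        pvals = np.clip(pvals, 0.0, 1.0)
        pvals[~valid[w]] = 1.0
        reject, *_ = multipletests(pvals, alpha=config.fdr_q, method="fdr_bh")
        reject &= valid[w]
        edges = [
            (int(iu[0][i]), int(iu[1][i])) for i in np.flatnonzero(reject)
        ]
        layers.append(edges)
    return LayeredGraph.from_edge_lists(n_ch, layers)


def infer_network(
    series: np.ndarray, rate: float, config: InferenceConfig = InferenceConfig()
) -> LayeredGraph:
    """Full front-end: preprocess then threshold cross-correlations."""
    return correlation_network(preprocess(series, rate, config), config)
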