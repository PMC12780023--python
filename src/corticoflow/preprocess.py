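"""Window selection, trial equalization, stationarity checks, differencing
and global lag selection.

The connectivity estimators downstream assume stationary inputs. Broadband
EEG source signals are not stationary over an evoked epoch, so the pipeline
unconditionally applies double differencing (the second-order finite
difference) to every ROI time series; the KPSS/ADF battery is run before and
after for logging but the pipeline never branches on its outcome. The
embedding/shift depth ``T`` shared by the non-reversibility and transfer
entropy stages is the first local minimum of the autocorrelation function,
located on the ACF averaged across trials, ROIs, conditions and
participants.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from statsmodels.tools.sm_exceptions import InterpolationWarning
from statsmodels.tsa.stattools import adfuller, kpss

from .datatypes import Condition, EpochedRoiSeries, SyntheticDataset

logger = logging.getLogger(__name__)

__all__ = [
    "crop_window",
    "equalize_trials",
    "StationarityReport",
    "stationarity_battery",
    "double_difference",
    "acf",
    "acf_first_minimum",
    "select_global_lag",
    "difference_series",
]

DEFAULT_MAX_LAG = 20


def crop_window(series: EpochedRoiSeries, start_s: float, end_s: float) -> EpochedRoiSeries:
    """Restrict an epoch to the half-open time window ``[start_s, end_s)``.

    Times are seconds relative to the event; samples are selected as the
    half-open interval ``[round((start - t0) * fs), round((end - t0) * fs))``.
    """
    if start_s >= end_s:
        raise ValueError(f"window start {start_s} s must precede end {end_s} s")
    fs = series.sampling_rate
    first = int(round((start_s - series.t0) * fs))
    last = int(round((end_s - series.t0) * fs))
    if first < 0 or last > series.n_time:
        epoch_end = series.t0 + series.n_time / fs
        raise ValueError(
            f"window [{start_s}, {end_s}) s outside epoch "
            f"[{series.t0}, {epoch_end}) s"
        )
    return series.replace_values(series.values[:, :, first:last], t0=series.t0 + first / fs)


def equalize_trials(
    blocks: list[EpochedRoiSeries], seed: int
) -> tuple[list[EpochedRoiSeries], list[np.ndarray]]:
    """Subsample every block to the minimum trial count across blocks.

    Selection is a stratified "pseudo-selection": each block's recording
    order is split into as many contiguous strata as trials to keep, and one
    trial is drawn uniformly from each stratum, so the kept trials stay
    spread across the block's recording order. Returns the subsampled blocks
    and the selected trial indices per block.
    """
    if not blocks:
        raise ValueError("no blocks given")
    counts = [b.n_trials for b in blocks]
    if min(counts) == 0:
        raise ValueError("a condition block has zero trials; cannot equalize")
    m = min(counts)
    rng = np.random.default_rng(seed)
    out_blocks: list[EpochedRoiSeries] = []
    out_idx: list[np.ndarray] = []
    for block in blocks:
        n = block.n_trials
        if n == m:
            idx = np.arange(n)
        else:
            edges = np.floor(np.linspace(0, n, m + 1)).astype(int)
            idx = np.array(
                [rng.integers(lo, hi) for lo, hi in zip(edges[:-1], edges[1:])], dtype=int
            )
        out_idx.append(idx)
        out_blocks.append(block.replace_values(block.values[idx]))
    return out_blocks, out_idx


@dataclass
class StationarityReport:
    kpss_pass: bool
    adf_pass: bool
    kpss_p: float
    adf_p: float
    degenerate: bool = False

    @property
    def stationary(self) -> bool:
        return self.kpss_pass and self.adf_pass and not self.degenerate


def stationarity_battery(x: np.ndarray, alpha: float = 0.05) -> StationarityReport:
    """KPSS trend-stationarity test plus ADF unit-root test at level ``alpha``.

    A series counts stationary only if it passes both: KPSS must fail to
    reject stationarity (p > alpha) and ADF must reject a unit root
    (p < alpha). Constant series are flagged degenerate and reported as
    failing both.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("stationarity_battery expects a 1-D series")
    if x.size < 20:
        raise ValueError(f"series too short for the battery ({x.size} < 20 samples)")
    if np.ptp(x) == 0:
        return StationarityReport(False, False, np.nan, np.nan, degenerate=True)
    with warnings.catch_warnings():
        # statsmodels warns when the statistic falls outside the tabulated
        # p-value range; the clipped value is exactly what we want
        warnings.simplefilter("ignore", InterpolationWarning)
        kpss_p = kpss(x, regression="c", nlags="auto")[1]
    adf_p = adfuller(x, autolag="AIC")[1]
    return StationarityReport(
        kpss_pass=bool(kpss_p > alpha),
        adf_pass=bool(adf_p < alpha),
        kpss_p=float(kpss_p),
        adf_p=float(adf_p),
    )


def double_difference(x: np.ndarray) -> np.ndarray:
    """Second-order finite difference along the last axis.

    ``out[t] = x[t+2] - 2 x[t+1] + x[t]``; output is two samples shorter.
    """
    x = np.asarray(x, dtype=float)
    if x.shape[-1] < 3:
        raise ValueError(f"double differencing needs >= 3 samples, got {x.shape[-1]}")
    return np.diff(x, n=2, axis=-1)


def difference_series(series: EpochedRoiSeries) -> EpochedRoiSeries:
    """Apply double differencing to every trial and ROI of a block."""
    return series.replace_values(
        double_difference(series.values), t0=series.t0 + 2.0 / series.sampling_rate
    )


def acf(x: np.ndarray, max_lag: int) -> np.ndarray:
    """Biased sample autocorrelation up to ``max_lag``, along the last axis.

    Works on arrays of series; the leading axes are preserved and the result
    has ``max_lag + 1`` lags (lag 0 first). Constant series raise.
    """
    x = np.asarray(x, dtype=float)
    n = x.shape[-1]
    if max_lag >= n:
        raise ValueError(f"max_lag {max_lag} must be < series length {n}")
    xc = x - x.mean(axis=-1, keepdims=True)
    denom = np.sum(xc**2, axis=-1)
    if np.any(denom == 0):
        raise ValueError("ACF undefined for a constant series")
    out = np.empty(x.shape[:-1] + (max_lag + 1,))
    for lag in range(max_lag + 1):
        out[..., lag] = np.sum(xc[..., : n - lag] * xc[..., lag:], axis=-1) / denom
    return out


def _first_minimum_of_acf(rho: np.ndarray, max_lag: int) -> tuple[int, str]:
    """Locate the first local minimum of an ACF curve, with a fallback ladder.

    Returns the lag and which rule fired: ``"minimum"`` for the smallest lag
    ``l >= 1`` with ``rho[l] < rho[l-1]`` and ``rho[l] <= rho[l+1]``;
    otherwise ``"zero_crossing"`` for the first lag where the ACF goes
    negative; otherwise ``"max_lag"``.
    """
    upto = min(max_lag, len(rho) - 2)
    for lag in range(1, upto + 1):
        if rho[lag] < rho[lag - 1] and rho[lag] <= rho[lag + 1]:
            return lag, "minimum"
    for lag in range(1, min(max_lag, len(rho) - 1) + 1):
        if rho[lag] < 0:
            return lag, "zero_crossing"
    return max_lag, "max_lag"


def acf_first_minimum(x: np.ndarray, max_lag: int = DEFAULT_MAX_LAG) -> int:
    """Lag of the first local minimum of the sample ACF of a 1-D series.

    If the ACF decays monotonically within ``max_lag`` (no local minimum),
    the first zero-crossing is used instead, and failing that the ``max_lag``
    cap; the fallback is logged.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("acf_first_minimum expects a 1-D series")
    if 2 * max_lag >= x.size:
        raise ValueError(f"max_lag {max_lag} must be < length/2 ({x.size / 2:g})")
    rho = acf(x, max_lag + 1)
    lag, rule = _first_minimum_of_acf(rho, max_lag)
    if rule != "minimum":
        logger.info("no ACF local minimum within %d lags; %s fallback -> T=%d", max_lag, rule, lag)
    return lag


def select_global_lag(
    dataset: SyntheticDataset | dict[tuple[str, Condition], EpochedRoiSeries],
    max_lag: int = DEFAULT_MAX_LAG,
    aggregate: str = "mean_acf",
) -> int:
    """Single study-wide lag T from the grand-average autocorrelation.

    Per-trial, per-ROI ACFs are averaged within each participant x condition
    block, the block curves averaged across the study, and the first-minimum
    rule applied to the grand-average curve (``aggregate='mean_acf'``). The
    alternative ``'mean_lag'`` locates the minimum per block and rounds the
    mean of the per-block lags. Input series are expected to be differenced
    already.
    """
    blocks = dataset.blocks if isinstance(dataset, SyntheticDataset) else dataset
    if not blocks:
        raise ValueError("empty dataset")
    curves = []
    lags = []
    for series in blocks.values():
        n_time = series.n_time
        if 2 * (max_lag + 1) >= n_time:
            raise ValueError(
                f"max_lag {max_lag} too large for epochs of {n_time} samples"
            )
        block_acf = acf(series.values, max_lag + 1).mean(axis=(0, 1))
        curves.append(block_acf)
        if aggregate == "mean_lag":
            lags.append(_first_minimum_of_acf(block_acf, max_lag)[0])
    if aggregate == "mean_acf":
        grand = np.mean(curves, axis=0)
        T, rule = _first_minimum_of_acf(grand, max_lag)
        if rule != "minimum":
            logger.info("global lag fell back to %s rule -> T=%d", rule, T)
    elif aggregate == "mean_lag":
        T = int(round(float(np.mean(lags))))
    else:
        raise ValueError(f"unknown aggregate mode {aggregate!r}")
    n_time = min(s.n_time for s in blocks.values())
    if not 1 <= T < n_time - 1:
        raise ValueError(f"selected lag T={T} violates 1 <= T < n_time-1 ({n_time - 1})")
    return T
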