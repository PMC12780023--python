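"""Whole-cortex temporal non-reversibility from time-shifted correlations.

A system at equilibrium is statistically indistinguishable from its
time-reversed self. Departure from that symmetry — the "arrow of time" in
the signals — is quantified by comparing the lag-T correlation structure of
the forward series with that of the time-reversed series. Correlations are
converted to Gaussian mutual information, and the non-reversibility score NR
is the mean squared difference between the forward and reversed shifted-MI
matrices. One NR scalar is produced per participant x condition, the input
to the factorial analysis.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .datatypes import EpochedRoiSeries, FsMatrixPair, NonReversibility, SyntheticDataset
from .preprocess import difference_series

logger = logging.getLogger(__name__)

__all__ = [
    "shifted_correlation",
    "reverse_time",
    "corr_to_mi",
    "nonreversibility",
    "insideout_condition",
    "nr_table",
]

_CLAMP = 1.0 - 1e-9


def shifted_correlation(
    values: np.ndarray, T: int, trial_mode: str = "average"
) -> np.ndarray:
    """Lag-T correlation matrix pooled over trials.

    ``values`` has shape (trials, rois, time); entry ``(i, j)`` of the result
    is the Pearson correlation of ROI i at time t with ROI j at time t + T.
    With ``trial_mode='average'`` (default) the correlation matrix is
    computed per trial and averaged across trials, which avoids spurious
    transitions across trial boundaries; ``'concatenate'`` pools the lagged
    sample pairs of all trials (each trial demeaned first) into one estimate.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 3:
        raise ValueError("expected a (trials, rois, time) array")
    n_trials, n_rois, n_time = values.shape
    if T < 0:
        raise ValueError("lag T must be >= 0")
    if n_time <= T + 2:
        raise ValueError(f"need n_time > T + 2 (got n_time={n_time}, T={T})")
    a = values[:, :, : n_time - T]
    b = values[:, :, T:] if T > 0 else a
    am = a - a.mean(axis=-1, keepdims=True)
    bm = b - b.mean(axis=-1, keepdims=True)
    a_sd = am.std(axis=-1)
    b_sd = bm.std(axis=-1)
    for name, sd in (("lagged-source", a_sd), ("lagged-target", b_sd)):
        if np.any(sd == 0):
            trial, roi = np.argwhere(sd == 0)[0]
            raise ValueError(
                f"zero-variance ROI {roi} (trial {trial}) in {name} segment; "
                "correlation undefined"
            )
    m = n_time - T
    if trial_mode == "average":
        corr = np.einsum("kit,kjt->kij", am / a_sd[:, :, None], bm / b_sd[:, :, None]) / m
        return corr.mean(axis=0)
    if trial_mode == "concatenate":
        a_flat = am.transpose(1, 0, 2).reshape(n_rois, -1)
        b_flat = bm.transpose(1, 0, 2).reshape(n_rois, -1)
        a_flat = a_flat / a_flat.std(axis=-1, keepdims=True)
        b_flat = b_flat / b_flat.std(axis=-1, keepdims=True)
        return (a_flat @ b_flat.T) / a_flat.shape[1]
    raise ValueError(f"unknown trial_mode {trial_mode!r}")


def reverse_time(values: np.ndarray) -> np.ndarray:
    """Flip the time axis (last axis) of every trial; an involution."""
    return np.asarray(values)[..., ::-1].copy()


def corr_to_mi(r: np.ndarray | float) -> np.ndarray | float:
    """Gaussian mutual information (nats) of a correlation: -0.5 ln(1 - r^2).

    Even in r and nonnegative. Magnitudes at or above 1 are clamped to
    1 - 1e-9 (perfect correlation has infinite MI); non-finite input raises.
    """
    r = np.asarray(r, dtype=float)
    if not np.all(np.isfinite(r)):
        raise ValueError("correlation input contains non-finite values")
    n_clamped = int(np.sum(np.abs(r) >= 1.0))
    if n_clamped:
        logger.info("clamped %d correlation value(s) with |r| >= 1", n_clamped)
    rc = np.clip(r, -_CLAMP, _CLAMP)
    out = -0.5 * np.log1p(-(rc**2))
    return float(out) if out.ndim == 0 else out


def nonreversibility(pair: FsMatrixPair, include_diagonal: bool = False) -> float:
    """Mean squared difference between forward and reversed shifted-MI matrices.

    The diagonal is excluded by default: the self-lagged correlation carries
    no cross-ROI directionality and its inclusion only dilutes the mean.
    """
    diff = pair.fs_forward - pair.fs_reversal
    if include_diagonal:
        return float(np.mean(diff**2))
    n = diff.shape[0]
    off = ~np.eye(n, dtype=bool)
    return float(np.mean(diff[off] ** 2))


def insideout_condition(
    series: EpochedRoiSeries,
    T: int,
    trial_mode: str = "average",
    include_diagonal: bool = False,
) -> NonReversibility:
    """Non-reversibility of one participant x condition block.

    The input is expected to be differenced/stationarized. The reversed
    branch flips each trial in time and recomputes the same lag-T shifted
    correlation; both matrices are converted to mutual information before
    the squared difference is averaged.
    """
    fwd = shifted_correlation(series.values, T, trial_mode)
    rev = shifted_correlation(reverse_time(series.values), T, trial_mode)
    pair = FsMatrixPair(fs_forward=corr_to_mi(fwd), fs_reversal=corr_to_mi(rev), T=T)
    nr = nonreversibility(pair, include_diagonal=include_diagonal)
    return NonReversibility(nr=nr, condition=series.condition, participant_id=series.participant_id)


def nr_table(
    dataset: SyntheticDataset,
    T: int,
    difference: bool = True,
    trial_mode: str = "average",
) -> pd.DataFrame:
    """Tidy table of NR per participant x condition.

    Columns: participant, attention, cue, motion, nr — the exact layout the
    factorial analysis consumes. ``difference=True`` applies the standard
    double-differencing step to each block first.
    """
    rows = []
    for (pid, cond), block in sorted(dataset.blocks.items()):
        if difference:
            block = difference_series(block)
        res = insideout_condition(block, T, trial_mode=trial_mode)
        rows.append(
            {
                "participant": pid,
                "attention": cond.attention,
                "cue": cond.cue,
                "motion": cond.motion,
                "nr": res.nr,
            }
        )
    return pd.DataFrame(rows)
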