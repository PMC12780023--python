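"""Surrogate-based significance of NDTE connections and the masked C_All.

Null distributions per directed ROI pair come from circular time-shift
surrogates: rotating one series preserves its marginal distribution and
(up to edge effects) its autocorrelation while destroying its temporal
alignment with the other series. By default the surrogate rotation is
applied to the SOURCE series, which removes the directed coupling under
test while leaving the target's own dynamics — the conditioning set —
untouched. P-values use the add-one rule so they are strictly positive, as
required by the normal-quantile transform of Stouffer's method. Per-pair
p-values are aggregated in two levels (across trials within participant,
then across participants), corrected with Benjamini-Hochberg FDR within
each condition, and the surviving pairs' trial-averaged F values form the
condition connectivity matrix C_All.
"""

from __future__ import annotations

import logging
from collections.abc import Mapping, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datatypes import Condition, ConditionConnectivity
from .ndte import ndte_pair_batch

logger = logging.getLogger(__name__)

__all__ = [
    "circular_shift",
    "draw_offsets",
    "pair_pvalue",
    "stouffer",
    "aggregate_two_level",
    "bh_fdr",
    "trial_pvalue_matrix",
    "build_condition_connectivity",
]

_P_CLIP = 1e-15


def circular_shift(x: np.ndarray, offset: int) -> np.ndarray:
    """Rotate a series by ``offset`` samples; the value multiset is preserved.

    ``offset`` must satisfy ``0 < offset < len(x)`` — a zero or full-length
    rotation would reproduce the original series and is disallowed.
    """
    x = np.asarray(x)
    if x.ndim != 1:
        raise ValueError("circular_shift expects a 1-D series")
    if not 0 < offset < x.size:
        raise ValueError(f"offset must be in (0, {x.size}), got {offset}")
    return np.roll(x, offset)


def draw_offsets(
    rng: np.random.Generator, length: int, T: int, n_iter: int
) -> np.ndarray:
    """Surrogate rotation offsets, uniform on ``[T+1, length - (T+1)]``.

    The minimum rotation of T+1 samples guarantees that no surrogate can
    trivially reproduce the original lag-T alignment.
    """
    minshift = T + 1
    if length - minshift < minshift:
        raise ValueError(
            f"series of length {length} too short for min rotation {minshift}"
        )
    return rng.integers(minshift, length - minshift + 1, size=n_iter)


def pair_pvalue(observed: float, surrogate_values: np.ndarray) -> float:
    """One-sided surrogate p-value with the add-one rule.

    ``p = (1 + #{surrogate F >= observed}) / (1 + n_iter)`` — strictly in
    (0, 1], so the normal quantile used by Stouffer aggregation is finite.
    NaN surrogates (failed estimates) are excluded from the count and the
    denominator.
    """
    surrogate_values = np.asarray(surrogate_values, dtype=float)
    valid = surrogate_values[np.isfinite(surrogate_values)]
    if valid.size == 0:
        raise ValueError("empty surrogate ensemble")
    return float((1 + np.sum(valid >= observed)) / (1 + valid.size))


def stouffer(pvals: Sequence[float] | np.ndarray) -> float:
    """Stouffer's combined p-value: ``1 - Phi(sum(Phi^{-1}(1 - p_k)) / sqrt(K))``.

    Inputs are clipped away from {0, 1} before the quantile transform.
    """
    p = np.asarray(pvals, dtype=float)
    p = p[np.isfinite(p)]
    if p.size == 0:
        raise ValueError("stouffer requires at least one p-value")
    n_clip = int(np.sum((p <= _P_CLIP) | (p >= 1 - _P_CLIP)))
    if n_clip:
        logger.debug("clipped %d extreme p-value(s) before Stouffer", n_clip)
    p = np.clip(p, _P_CLIP, 1 - _P_CLIP)
    z = stats.norm.isf(p)
    return float(stats.norm.sf(z.sum() / np.sqrt(p.size)))


def _stouffer_stack(p_stack: np.ndarray, axis: int) -> np.ndarray:
    """Vectorized Stouffer along one axis of a p-value array, ignoring NaN."""
    p = np.clip(p_stack, _P_CLIP, 1 - _P_CLIP)
    z = stats.norm.isf(p)
    z = np.where(np.isfinite(p_stack), z, np.nan)
    k = np.sum(np.isfinite(p_stack), axis=axis)
    with np.errstate(invalid="ignore"):
        zsum = np.nansum(z, axis=axis)
        combined = stats.norm.sf(zsum / np.sqrt(np.maximum(k, 1)))
    return np.where(k > 0, combined, np.nan)


def aggregate_two_level(
    trial_pvals: Mapping[str, np.ndarray],
) -> np.ndarray:
    """Two-level Stouffer aggregation of per-trial, per-pair p-values.

    ``trial_pvals`` maps participant id to an array of shape
    (n_trials, rois, rois) of per-trial p-values (NaN = missing pair).
    P-values are first combined across trials within each participant, then
    across participants. Pairs missing everywhere yield NaN; partial
    missingness is excluded from the respective sum and logged.
    """
    if not trial_pvals:
        raise ValueError("no participants given")
    per_participant = []
    for pid, arr in sorted(trial_pvals.items()):
        arr = np.asarray(arr, dtype=float)
        if arr.ndim != 3:
            raise ValueError(f"participant {pid}: expected (trials, rois, rois) p array")
        if arr.shape[0] < 1:
            raise ValueError(f"participant {pid} has no trials")
        per_participant.append(_stouffer_stack(arr, axis=0))
    stack = np.stack(per_participant, axis=0)
    n_missing = int(np.sum(~np.isfinite(stack)))
    if n_missing:
        logger.info("%d participant-level pair p-value(s) missing before group Stouffer", n_missing)
    return _stouffer_stack(stack, axis=0)


def bh_fdr(pvals: np.ndarray, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up mask over all tested directed pairs.

    ``pvals`` is a square ROI x ROI matrix (diagonal and NaN entries are not
    part of the family). Returns a boolean matrix; True = significant.
    """
    if not 0 < q < 1:
        raise ValueError(f"q must be in (0, 1), got {q}")
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 2 or p.shape[0] != p.shape[1]:
        raise ValueError("expected a square p-value matrix")
    family = ~np.eye(p.shape[0], dtype=bool) & np.isfinite(p)
    mask = np.zeros_like(p, dtype=bool)
    if family.sum() == 0:
        return mask
    reject, *_ = multipletests(p[family], alpha=q, method="fdr_bh")
    mask[family] = reject
    return mask


def trial_pvalue_matrix(
    trial: np.ndarray,
    T: int,
    n_iter: int,
    rng: np.random.Generator,
    surrogate_target: str = "source",
) -> tuple[np.ndarray, np.ndarray]:
    """Observed F matrix and per-pair surrogate p-values for one trial.

    For every directed pair, ``n_iter`` circular-shift surrogates of the
    source (default) or target series are generated with independent
    offsets, F recomputed for each, and the add-one p-value taken. Returns
    ``(f_observed, p)`` with NaN for failed pairs.
    """
    trial = np.asarray(trial, dtype=float)
    n_rois, n_time = trial.shape
    if surrogate_target not in ("source", "target"):
        raise ValueError(f"surrogate_target must be 'source' or 'target', got {surrogate_target!r}")
    f_obs = np.zeros((n_rois, n_rois))
    p = np.full((n_rois, n_rois), np.nan)
    np.fill_diagonal(p, np.nan)
    for i in range(n_rois):  # target
        y = trial[i]
        for j in range(n_rois):  # source
            if i == j:
                continue
            x = trial[j]
            offsets = draw_offsets(rng, n_time, T, n_iter)
            if surrogate_target == "source":
                variants = np.empty((n_iter + 1, n_time))
                variants[0] = x
                for k, off in enumerate(offsets):
                    variants[k + 1] = np.roll(x, off)
                f_all = ndte_pair_batch(variants, y, T)
                obs, sur = f_all[0], f_all[1:]
            else:
                obs = float(ndte_pair_batch(x[None, :], y, T)[0])
                sur = np.array(
                    [
                        float(ndte_pair_batch(x[None, :], np.roll(y, off), T)[0])
                        for off in offsets
                    ]
                )
            f_obs[i, j] = obs
            if np.isfinite(obs):
                p[i, j] = pair_pvalue(float(obs), sur)
    return f_obs, p


def build_condition_connectivity(
    trial_matrices: Mapping[str, np.ndarray],
    mask: np.ndarray,
    condition: Condition | None = None,
) -> ConditionConnectivity:
    """Significance-masked, averaged connectivity matrix for one condition.

    ``trial_matrices`` maps participant id to an (n_trials, rois, rois)
    array of per-trial F values. Trials are averaged within participant,
    participants averaged, and the result zeroed outside the mask.
    """
    if not trial_matrices:
        raise ValueError("no trial matrices given")
    per_part = [np.nanmean(np.asarray(m, dtype=float), axis=0) for m in trial_matrices.values()]
    c_all = np.nanmean(np.stack(per_part, axis=0), axis=0)
    c_all = np.where(np.isfinite(c_all), c_all, 0.0)
    c_all = c_all * mask
    return ConditionConnectivity(c_all=c_all, mask=np.asarray(mask, dtype=bool), condition=condition)
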