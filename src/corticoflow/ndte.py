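"""Normalized directed transfer entropy (NDTE) from Gaussian entropies.

For source X and target Y, the directed statistic is the conditional mutual
information between the source's past and the target's immediate future,
given the target's own past:

    I(Y_{i+1}; X^i | Y^i) = H(Y_{i+1} | Y^i) - H(Y_{i+1} | X^i, Y^i)

with pasts X^i = [X_i, ..., X_{i-(T-1)}] of depth T. To make values
comparable across ROI pairs it is normalized by the total predictive
information both pasts carry about the future:

    F_XY = I(Y_{i+1}; X^i | Y^i) / I(Y_{i+1}; X^i, Y^i)

All entropies are Gaussian, computed from the joint sample covariance of
(Y_future, X_past, Y_past); the dimension-dependent 2*pi*e constants cancel
in both ratios, leaving log-determinant differences. One F matrix is
produced per trial: ``f[target, source]``, inflow along rows.
"""

from __future__ import annotations

import logging

import numpy as np

from .datatypes import NdteMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "EmbeddedPair",
    "embed",
    "gaussian_entropy",
    "conditional_mi",
    "ndte_pair",
    "ndte_pair_batch",
    "ndte_matrix",
]

_JITTER = 1e-10
_DENOM_TOL = 1e-12
_LN_2PIE = float(np.log(2.0 * np.pi * np.e))


class EmbeddedPair:
    """Lag-embedded source/target arrays aligned on a common row index.

    Row k aligns the target's future sample ``y[k + T + 1]`` with the source
    and target pasts ending at index ``k + T``; columns are ordered
    newest-first. All three arrays share ``len(y) - T - 1`` rows.
    """

    def __init__(self, y_future: np.ndarray, x_past: np.ndarray, y_past: np.ndarray):
        self.y_future = y_future
        self.x_past = x_past
        self.y_past = y_past
        if not (len(y_future) == len(x_past) == len(y_past)):
            raise ValueError("embedded arrays must share their row count")

    @property
    def T(self) -> int:
        return self.x_past.shape[1]

    @property
    def n_rows(self) -> int:
        return len(self.y_future)


def _past_index(n: int, T: int) -> np.ndarray:
    """Row/column index matrix for newest-first lag stacking."""
    m = n - T - 1
    k = np.arange(m)[:, None]
    c = np.arange(T)[None, :]
    return k + T - c


def embed(x: np.ndarray, y: np.ndarray, T: int) -> EmbeddedPair:
    """Lag-embed a source/target series pair at depth ``T``."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or y.ndim != 1 or x.size != y.size:
        raise ValueError("x and y must be 1-D series of equal length")
    n = x.size
    if T < 1:
        raise ValueError("embedding depth T must be >= 1")
    if n <= T + 1:
        raise ValueError(f"series of length {n} too short for T={T} (need > T + 1)")
    idx = _past_index(n, T)
    return EmbeddedPair(
        y_future=y[T + 1 :].copy(),
        x_past=x[idx],
        y_past=y[idx],
    )


def gaussian_entropy(cov: np.ndarray) -> float:
    """Differential entropy (nats) of a Gaussian with covariance ``cov``.

    ``H = 0.5 * ln((2 pi e)^d det cov)``. A diagonal jitter of 1e-10 is added
    once if the matrix is not positive definite; failure after that raises.
    """
    cov = np.atleast_2d(np.asarray(cov, dtype=float))
    d = cov.shape[0]
    sign, logdet = np.linalg.slogdet(cov)
    if sign <= 0:
        logger.info("covariance not PD; adding diagonal jitter %.0e", _JITTER)
        sign, logdet = np.linalg.slogdet(cov + _JITTER * np.eye(d))
        if sign <= 0:
            raise np.linalg.LinAlgError(
                "covariance matrix not positive definite even after jitter"
            )
    return 0.5 * (d * _LN_2PIE + logdet)


def _subset_logdet(cov: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Batched log-determinant of a principal submatrix of stacked covariances."""
    sub = cov[..., idx[:, None], idx[None, :]]
    sign, logdet = np.linalg.slogdet(sub)
    bad = sign <= 0
    if np.any(bad):
        sub = sub + _JITTER * np.eye(len(idx))
        sign2, logdet2 = np.linalg.slogdet(sub)
        logdet = np.where(bad, logdet2, logdet)
        still = sign2 <= 0
        if np.any(np.asarray(bad) & np.asarray(still)):
            logdet = np.where(np.asarray(bad) & np.asarray(still), np.nan, logdet)
    return logdet


def _cmi_from_cov(cov: np.ndarray, T: int) -> tuple[np.ndarray, np.ndarray]:
    """Numerator and denominator MI terms from stacked joint covariances.

    ``cov`` has shape (..., 2T+1, 2T+1) with variables ordered
    (Y_future, X_past[T], Y_past[T]). The dimension constants of the
    Gaussian entropies cancel, so both terms reduce to log-determinant
    combinations of principal submatrices.
    """
    d = 2 * T + 1
    if cov.shape[-1] != d or cov.shape[-2] != d:
        raise ValueError(f"covariance must be {d}x{d} for T={T}")
    all_idx = np.arange(d)
    yp = np.arange(T + 1, d)
    xp_yp = np.arange(1, d)
    yf_yp = np.concatenate(([0], yp))
    yf = np.array([0])
    ld_full = _subset_logdet(cov, all_idx)
    ld_xp_yp = _subset_logdet(cov, xp_yp)
    ld_yp = _subset_logdet(cov, yp)
    ld_yf_yp = _subset_logdet(cov, yf_yp)
    ld_yf = _subset_logdet(cov, yf)
    numerator = 0.5 * (ld_yf_yp - ld_yp - ld_full + ld_xp_yp)
    denominator = 0.5 * (ld_yf + ld_xp_yp - ld_full)
    return numerator, denominator


def conditional_mi(ep: EmbeddedPair) -> dict[str, float]:
    """Conditional and total Gaussian MI terms for one embedded pair.

    Returns ``{"numerator": I(Y+; Xp | Yp), "denominator": I(Y+; Xp, Yp)}``,
    both in nats, estimated from the unbiased joint sample covariance.
    """
    T = ep.T
    if ep.n_rows < 2 * T + 2:
        raise ValueError(
            f"need at least 2T+2={2 * T + 2} embedded rows to estimate the "
            f"joint covariance, got {ep.n_rows}"
        )
    z = np.column_stack([ep.y_future, ep.x_past, ep.y_past])
    cov = np.cov(z, rowvar=False)
    num, den = _cmi_from_cov(cov, T)
    if not (np.isfinite(num) and np.isfinite(den)):
        cond = np.linalg.cond(cov)
        raise np.linalg.LinAlgError(
            f"singular joint covariance (condition number {cond:.3e}); "
            "series may be collinear or too short"
        )
    return {"numerator": float(num), "denominator": float(den)}


def _finish_f(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    """Ratio with the degenerate-denominator and clipping rules applied."""
    num = np.asarray(num, dtype=float)
    den = np.asarray(den, dtype=float)
    f = np.full(np.broadcast(num, den).shape, np.nan)
    ok = np.isfinite(num) & np.isfinite(den)
    small = ok & (den < _DENOM_TOL)
    if np.any(small):
        logger.info(
            "%d pair(s) with near-zero total predictive information; F set to 0",
            int(np.sum(small)),
        )
    good = ok & ~small
    with np.errstate(invalid="ignore"):
        ratio = np.where(good, num / np.where(good, den, 1.0), np.nan)
    n_clip = int(np.sum(good & ((ratio < 0) | (ratio > 1))))
    if n_clip:
        logger.debug("clipped %d F value(s) outside [0, 1]", n_clip)
    f[good] = np.clip(ratio[good], 0.0, 1.0)
    f[small] = 0.0
    return f


def ndte_pair(x: np.ndarray, y: np.ndarray, T: int) -> float:
    """Normalized directed transfer entropy from source ``x`` to target ``y``.

    The ratio is clipped to [0, 1]; if the total predictive information is
    below tolerance (the target's future is unpredictable from either past),
    F is defined as 0.
    """
    terms = conditional_mi(embed(x, y, T))
    return float(_finish_f(terms["numerator"], terms["denominator"]))


def _demean(a: np.ndarray, axis: int) -> np.ndarray:
    return a - a.mean(axis=axis, keepdims=True)


def ndte_pair_batch(x_variants: np.ndarray, y: np.ndarray, T: int) -> np.ndarray:
    """F values of many source variants against one fixed target.

    ``x_variants`` has shape (S, n); the target embedding and all covariance
    blocks that involve only the target are computed once, the source-
    dependent blocks are batched with einsum, and the log-determinants are
    evaluated with stacked ``slogdet``. This is the fast path used by the
    circular-shift surrogate test. Returns an array of S values; entries
    where the joint covariance was singular are NaN.
    """
    x_variants = np.atleast_2d(np.asarray(x_variants, dtype=float))
    y = np.asarray(y, dtype=float)
    S, n = x_variants.shape
    if y.size != n:
        raise ValueError("source variants and target must share length")
    if n <= T + 1:
        raise ValueError(f"series of length {n} too short for T={T}")
    idx = _past_index(n, T)
    m = idx.shape[0]
    if m < 2 * T + 2:
        raise ValueError(f"need at least 2T+2={2 * T + 2} embedded rows, got {m}")
    yf = _demean(y[T + 1 :], axis=0)
    Yp = _demean(y[idx], axis=0)
    Xp = _demean(x_variants[:, idx], axis=1)  # (S, m, T)
    denom = m - 1
    d = 2 * T + 1
    cov = np.empty((S, d, d))
    s_yy = float(yf @ yf) / denom
    s_yf_yp = (yf @ Yp) / denom  # (T,)
    s_yp_yp = (Yp.T @ Yp) / denom  # (T, T)
    s_xf = np.einsum("smt,m->st", Xp, yf) / denom  # (S, T)
    s_x_yp = np.einsum("smt,mu->stu", Xp, Yp) / denom  # (S, T, T)
    s_xx = np.einsum("smt,smu->stu", Xp, Xp) / denom  # (S, T, T)
    cov[:, 0, 0] = s_yy
    cov[:, 0, 1 : T + 1] = s_xf
    cov[:, 1 : T + 1, 0] = s_xf
    cov[:, 0, T + 1 :] = s_yf_yp
    cov[:, T + 1 :, 0] = s_yf_yp
    cov[:, 1 : T + 1, 1 : T + 1] = s_xx
    cov[:, 1 : T + 1, T + 1 :] = s_x_yp
    cov[:, T + 1 :, 1 : T + 1] = s_x_yp.transpose(0, 2, 1)
    cov[:, T + 1 :, T + 1 :] = s_yp_yp
    num, den = _cmi_from_cov(cov, T)
    return _finish_f(num, den)


def ndte_matrix(trial: np.ndarray, T: int, trial_id: int | None = None) -> NdteMatrix:
    """All-pairs NDTE for one stationarized trial, shape (rois, time).

    ``f[i, j]`` is the flow from source ROI j into target ROI i; the
    diagonal is stored as 0. A pair whose covariance estimate fails is
    recorded as NaN (missing) so downstream significance masking is not
    biased by silent zeros.
    """
    trial = np.asarray(trial, dtype=float)
    if trial.ndim != 2:
        raise ValueError("expected a (rois, time) array")
    n_rois = trial.shape[0]
    f = np.zeros((n_rois, n_rois))
    for i in range(n_rois):  # target
        sources = np.delete(np.arange(n_rois), i)
        vals = ndte_pair_batch(trial[sources], trial[i], T)
        f[i, sources] = vals
    n_missing = int(np.sum(np.isnan(f)))
    if n_missing:
        logger.warning("%d ROI pair(s) failed covariance estimation (stored NaN)", n_missing)
    return NdteMatrix(f=f, T=T, trial=trial_id)
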