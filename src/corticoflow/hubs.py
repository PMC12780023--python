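"""Inflow/outflow vectors and the Monte-Carlo functional hub search.

Per-ROI inflow is the row sum of the condition connectivity matrix C_All
(targets along rows) and outflow the column sum. The hub score of a subset
k of ROIs combines its within-subset flow with the members' global flows:

    G_hub(k) = sum_k C_All_k + a * sum_k G_in(k) - b * sum_k G_out(k)

with multipliers (a=1, b=1) for inflow hubs and (a=-1, b=-1) for outflow
hubs. Significance of a subset is assessed by Monte-Carlo substitution:
each permutation swaps one uniformly chosen member for a uniformly chosen
non-member and recomputes G_hub; the hub search grows a prefix of the
flow-sorted ROI list while the subset stays significant.
"""

from __future__ import annotations

import logging
from collections.abc import Sequence

import numpy as np

from .datatypes import FlowVectors, HubResult, Parcellation

logger = logging.getLogger(__name__)

__all__ = ["flows", "g_hub", "mc_subset_pvalue", "find_hubs", "top_fraction_filter"]

_MODE_MULTIPLIERS = {"in": (1.0, 1.0), "out": (-1.0, -1.0)}


def _check_square(c_all: np.ndarray) -> np.ndarray:
    c_all = np.asarray(c_all, dtype=float)
    if c_all.ndim != 2 or c_all.shape[0] != c_all.shape[1]:
        raise ValueError(f"connectivity matrix must be square, got shape {c_all.shape}")
    return c_all


def flows(c_all: np.ndarray) -> FlowVectors:
    """Total inflow (row sums) and outflow (column sums) per ROI."""
    c_all = _check_square(c_all)
    return FlowVectors(g_in=c_all.sum(axis=1), g_out=c_all.sum(axis=0))


def _subset_score(
    c_all: np.ndarray,
    g_in: np.ndarray,
    g_out: np.ndarray,
    subset: np.ndarray,
    a: float,
    b: float,
) -> float:
    within = float(c_all[np.ix_(subset, subset)].sum())
    return within + a * float(g_in[subset].sum()) - b * float(g_out[subset].sum())


def g_hub(c_all: np.ndarray, subset: Sequence[int], mode: str) -> float:
    """Combined flow score of an ROI subset for one flow direction.

    The within-subset term sums the full subset x subset submatrix (both
    directions); the G_in/G_out terms use the full-matrix flow of each
    member.
    """
    c_all = _check_square(c_all)
    if mode not in _MODE_MULTIPLIERS:
        raise ValueError(f"mode must be 'in' or 'out', got {mode!r}")
    subset = np.asarray(subset, dtype=int)
    if subset.size == 0:
        raise ValueError("subset must be nonempty")
    if len(np.unique(subset)) != subset.size:
        raise ValueError("subset contains duplicate ROIs")
    if subset.min() < 0 or subset.max() >= c_all.shape[0]:
        raise ValueError(f"subset contains unknown ROI index (matrix has {c_all.shape[0]} ROIs)")
    fl = flows(c_all)
    a, b = _MODE_MULTIPLIERS[mode]
    return _subset_score(c_all, fl.g_in, fl.g_out, subset, a, b)


def mc_subset_pvalue(
    c_all: np.ndarray,
    subset: Sequence[int],
    mode: str,
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
) -> float:
    """Monte-Carlo p-value of a subset's hub score under member substitution.

    Each of ``n_perm`` permutations replaces one uniformly chosen member with
    a uniformly chosen non-member and recomputes G_hub; the add-one p-value
    is the fraction of permuted scores at or above the observed one.
    """
    c_all = _check_square(c_all)
    subset = np.asarray(subset, dtype=int)
    n = c_all.shape[0]
    non_members = np.setdiff1d(np.arange(n), subset)
    if non_members.size == 0:
        raise ValueError("subset covers the whole parcellation; no substitutes available")
    fl = flows(c_all)
    a, b = _MODE_MULTIPLIERS[mode]
    observed = _subset_score(c_all, fl.g_in, fl.g_out, subset, a, b)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out_pos = rng.integers(0, subset.size, size=n_perm)
    in_idx = non_members[rng.integers(0, non_members.size, size=n_perm)]
    count = 0
    perm = subset.copy()
    for pos, repl in zip(out_pos, in_idx):
        old = perm[pos]
        perm[pos] = repl
        score = _subset_score(c_all, fl.g_in, fl.g_out, perm, a, b)
        if score >= observed:
            count += 1
        perm[pos] = old
    return (1 + count) / (1 + n_perm)


def find_hubs(
    c_all: np.ndarray,
    mode: str,
    alpha: float = 0.05,
    n_perm: int = 1000,
    seed: int = 0,
    parcellation: Parcellation | None = None,
) -> HubResult:
    """Iterative prefix-growth hub search.

    ROIs are sorted by the mode's flow, descending (ties broken by ROI
    index); starting from the single top ROI, the current prefix is tested
    with the Monte-Carlo substitution p-value and grown by one ROI while it
    stays within significance limits (p < ``alpha``). The final set is the
    longest consecutively significant prefix — empty when even the top ROI
    is indistinguishable from same-sized substituted sets, as on a flat
    matrix. Exactly tied flows (a measure-zero event on estimated
    connectivity) can mask a genuine multi-ROI hub at step one, because
    substituting one co-hub for the other ties the singleton score; the full
    growth trace is returned so such cases are inspectable.
    """
    c_all = _check_square(c_all)
    if mode not in _MODE_MULTIPLIERS:
        raise ValueError(f"mode must be 'in' or 'out', got {mode!r}")
    n = c_all.shape[0]
    fl = flows(c_all)
    flow = fl.g_in if mode == "in" else fl.g_out
    # stable sort on negated flow: descending, ties broken by ROI index
    order = np.argsort(-flow, kind="stable")
    if np.any(np.diff(flow[order]) == 0):
        logger.info("ties in %sflow broken by ROI index", mode)
    rng = np.random.default_rng(seed)
    members: list[int] = []
    scores: list[float] = []
    pvals: list[float] = []
    final_size = 0
    for size in range(1, n):  # need at least one non-member for substitution
        prefix = order[:size]
        score = g_hub(c_all, prefix, mode)
        p = mc_subset_pvalue(c_all, prefix, mode, n_perm=n_perm, seed=rng)
        members.append(int(order[size - 1]))
        scores.append(score)
        pvals.append(p)
        if p < alpha:
            final_size = size
        else:
            break
    final = [int(i) for i in order[:final_size]]
    labels = (
        [parcellation.labels[i] for i in members] if parcellation is not None else []
    )
    return HubResult(
        mode=mode,
        members=members,
        g_hub=scores,
        p=pvals,
        final_set=final,
        alpha=alpha,
        labels=labels,
    )


def top_fraction_filter(
    c_all: np.ndarray, fraction: float = 0.30
) -> list[tuple[int, int, float]]:
    """Strongest edges of a connectivity matrix, for display/export only.

    Nonzero off-diagonal edges are ranked by strength and the top
    ``ceil(fraction * n_nonzero)`` retained; ties at the cutoff are all
    kept (and logged). Returns (target, source, weight) triples sorted by
    descending weight. Never used in inference.
    """
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    c_all = _check_square(c_all)
    off = ~np.eye(c_all.shape[0], dtype=bool)
    ti, si = np.nonzero(off & (c_all != 0))
    w = c_all[ti, si]
    if w.size == 0:
        return []
    k = int(np.ceil(fraction * w.size))
    order = np.argsort(-w, kind="stable")
    cutoff = w[order[k - 1]]
    keep = np.nonzero(w >= cutoff)[0]
    if keep.size > k:
        logger.info("%d tied edge(s) at the cutoff retained beyond top-%d", keep.size - k, k)
    keep_sorted = keep[np.argsort(-w[keep], kind="stable")]
    return [(int(ti[i]), int(si[i]), float(w[i])) for i in keep_sorted]
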