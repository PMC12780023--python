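"""Group-level factorial analysis of non-reversibility.

The design is fully within-subject: attention (active/passive) x cue
(intensity/spectral) x motion (looming/receding), one NR value per
participant and cell. A standard repeated-measures ANOVA decomposes the
variance into three main effects, three two-way interactions and the
three-way interaction, each tested against its own participant-by-effect
error term. All factors have two levels, so sphericity holds trivially and
no correction is needed. Partial eta squared is reported per effect as
SS_effect / (SS_effect + SS_error), computed from F and the degrees of
freedom (an exact identity in this balanced design). A significant
interaction is followed up by separate ANOVAs per level of one factor with
Bonferroni-adjusted p-values.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from statsmodels.stats.anova import AnovaRM

logger = logging.getLogger(__name__)

__all__ = ["rm_anova", "bonferroni_followup"]

_FACTORS = ("attention", "cue", "motion")


def _complete_participants(table: pd.DataFrame, factors: tuple[str, ...]) -> pd.DataFrame:
    """Listwise-exclude participants with an incomplete factorial crossing."""
    n_cells = int(np.prod([table[f].nunique() for f in factors]))
    counts = table.groupby("participant", observed=True).size()
    complete = counts[counts == n_cells].index
    dropped = sorted(set(counts.index) - set(complete))
    if dropped:
        logger.warning("excluding %d participant(s) with incomplete cells: %s", len(dropped), dropped)
    out = table[table["participant"].isin(complete)]
    if out["participant"].nunique() < 2:
        raise ValueError("repeated-measures ANOVA needs >= 2 complete participants")
    return out


def rm_anova(
    table: pd.DataFrame,
    depvar: str = "nr",
    factors: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Repeated-measures ANOVA over within-subject factors.

    ``table`` is tidy with columns participant, the factor columns and the
    dependent variable. Factors present with more than one level are used;
    by default attention, cue and motion. Returns one row per effect with
    F, df1, df2, p and partial eta squared.
    """
    if factors is None:
        factors = tuple(f for f in _FACTORS if f in table.columns and table[f].nunique() > 1)
    if not factors:
        raise ValueError("no within-subject factors with more than one level")
    data = _complete_participants(table, factors)
    fit = AnovaRM(data, depvar=depvar, subject="participant", within=list(factors)).fit()
    at = fit.anova_table
    rows = []
    for effect, row in at.iterrows():
        f_val = float(row["F Value"])
        df1 = float(row["Num DF"])
        df2 = float(row["Den DF"])
        rows.append(
            {
                "effect": effect.replace(":", " x "),
                "F": f_val,
                "df1": df1,
                "df2": df2,
                "p": float(row["Pr > F"]),
                # SSe/(SSe+SSerr) == F*df1/(F*df1 + df2) in the balanced design
                "eta_p2": f_val * df1 / (f_val * df1 + df2),
            }
        )
    return pd.DataFrame(rows)


def bonferroni_followup(
    table: pd.DataFrame,
    split_by: str = "cue",
    depvar: str = "nr",
) -> dict[str, pd.DataFrame]:
    """Separate ANOVA per level of ``split_by`` with Bonferroni-adjusted p.

    Each follow-up drops the split factor and analyses the remaining
    within-subject factors; raw p-values are multiplied by the number of
    follow-ups and capped at 1 (column ``p_bonf``).
    """
    if split_by not in table.columns:
        raise ValueError(f"split factor {split_by!r} not in table")
    levels = sorted(table[split_by].unique())
    remaining = tuple(
        f for f in _FACTORS if f != split_by and f in table.columns and table[f].nunique() > 1
    )
    out: dict[str, pd.DataFrame] = {}
    k = len(levels)
    for level in levels:
        sub = table[table[split_by] == level]
        res = rm_anova(sub, depvar=depvar, factors=remaining)
        res["p_bonf"] = np.minimum(res["p"] * k, 1.0)
        out[str(level)] = res
    return out
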