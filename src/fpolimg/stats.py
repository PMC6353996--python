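"""Group summaries and hierarchical significance testing.

Per-cell measurements (Fpol, Pearson R, lifetimes) are summarized per cell
line as mean +/- standard error over N cells, and pairs of lines are
compared by (a) the percent difference of the group means, using the second
(normal) group as denominator, and (b) a hierarchical permutation test that
respects the replicate structure: cells are not independent across imaging
experiments, so labels are permuted within experiments (paired replicates)
or whole experiments are reassigned (unpaired replicates) rather than
permuting cells freely.  The test statistic is the difference of group
means and the two-sided p-value uses the add-one convention
``(1 + #{|T*| >= |T|}) / (B + 1)``, so p is never 0 and never below
``1/(B+1)``.

A random-intercept linear mixed model (statsmodels) is available as an
optional cross-check of the permutation p-value; it is not the validated
surface.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GroupSummary",
    "PairwiseComparison",
    "summarize",
    "summarize_table",
    "percent_difference",
    "round_half_up",
    "compare_groups",
    "mixed_model_pvalue",
]

DEFAULT_PERMUTATIONS = 10_000
#: display threshold for flagging significance in reports
ALPHA_DISPLAY = 1e-4


@dataclass(frozen=True)
class GroupSummary:
    group: str
    n_cells: int
    mean: float
    se: float
    experiment_ids: tuple = ()


@dataclass(frozen=True)
class PairwiseComparison:
    group_a: str
    group_b: str
    percent_difference: float  # unrounded; see round_half_up for display
    p_value: float
    method: str
    statistic: float = math.nan
    n_permutations: int = 0

    @property
    def percent_difference_display(self) -> int:
        return round_half_up(self.percent_difference)

    @property
    def significant(self) -> bool:
        return self.p_value < ALPHA_DISPLAY


def summarize(values, group: str = "", experiment_ids=None) -> GroupSummary:
    """Mean and SE (= sd/sqrt(N)) of per-cell values for one group."""
    values = np.asarray(values, dtype=float)
    n = len(values)
    if n < 2:
        raise ValueError(f"group {group!r} has {n} records; need at least 2")
    mean = float(values.mean())
    se = float(values.std(ddof=1) / np.sqrt(n))
    if se <= 1e-12 * max(1.0, abs(mean)):
        logger.warning("group %r has zero variance (degenerate SE)", group)
    exps = tuple(sorted(set(experiment_ids))) if experiment_ids is not None else ()
    return GroupSummary(group=group, n_cells=n, mean=mean, se=se,
                        experiment_ids=exps)


def summarize_table(
    df: pd.DataFrame,
    value_col: str = "value",
    group_col: str = "group",
    experiment_col: str | None = "experiment_id",
) -> pd.DataFrame:
    """Per-group summaries of a tidy records table."""
    rows = []
    for g, sub in df.groupby(group_col, sort=True):
        exps = sub[experiment_col] if experiment_col and experiment_col in sub else None
        s = summarize(sub[value_col].to_numpy(), group=str(g), experiment_ids=exps)
        rows.append({"group": s.group, "n_cells": s.n_cells, "mean": s.mean,
                     "se": s.se, "n_experiments": len(s.experiment_ids)})
    return pd.DataFrame(rows)


def round_half_up(x: float) -> int:
    """Round to the nearest integer, halves away from zero (report display)."""
    return int(math.floor(abs(x) + 0.5) * (1 if x >= 0 else -1))


def percent_difference(summary_a: GroupSummary | float, summary_b: GroupSummary | float) -> float:
    """Percent difference of group means, ``100 (mean_a - mean_b)/mean_b``.

    ``b`` is the reference (normal) group.  Accepts summaries or raw means.
    """
    mean_a = summary_a.mean if isinstance(summary_a, GroupSummary) else float(summary_a)
    mean_b = summary_b.mean if isinstance(summary_b, GroupSummary) else float(summary_b)
    if mean_b <= 0:
        raise ValueError(f"reference mean must be positive, got {mean_b}")
    return 100.0 * (mean_a - mean_b) / mean_b


# ---------------------------------------------------------------------------
# hierarchical permutation test


def _stratified_null(values, is_a, strata, n_perm, rng):
    """Null statistics permuting group labels within each experiment stratum."""
    n_a, n_b = is_a.sum(), (~is_a).sum()
    sum_a = np.zeros(n_perm)
    for s in np.unique(strata):
        idx = np.nonzero(strata == s)[0]
        keys = rng.random((n_perm, len(idx)))
        order = np.argsort(keys, axis=1)
        labels = is_a[idx][order]  # (n_perm, m) permuted labels, counts preserved
        sum_a += labels @ values[idx]
    total = values.sum()
    return sum_a / n_a - (total - sum_a) / n_b


def _experiment_level_null(values, is_a, strata, n_perm, rng):
    """Null statistics reassigning whole experiments to the two groups."""
    exps = np.unique(strata)
    exp_is_a = np.array([is_a[strata == e].all() for e in exps])
    n_exp_a = int(exp_is_a.sum())
    stats = np.empty(n_perm)
    for i in range(n_perm):
        chosen = rng.choice(len(exps), size=n_exp_a, replace=False)
        sel = np.isin(strata, exps[chosen])
        stats[i] = values[sel].mean() - values[~sel].mean()
    return stats


def compare_groups(
    records_a,
    records_b,
    experiments_a=None,
    experiments_b=None,
    group_a: str = "a",
    group_b: str = "b",
    n_permutations: int = DEFAULT_PERMUTATIONS,
    seed: int = 0,
) -> PairwiseComparison:
    """Hierarchical permutation test of a difference in group means.

    When both groups were measured in the same experiments (paired
    replicate design), group labels are permuted within each experiment.
    When the experiments are disjoint, whole experiments are reassigned to
    groups (requires >= 2 experiments per group).  Without usable replicate
    structure the test falls back to permuting cells freely, with a logged
    warning: that ignores within-experiment correlation (pseudo-replication).
    """
    va = np.asarray(records_a, dtype=float)
    vb = np.asarray(records_b, dtype=float)
    if len(va) < 2 or len(vb) < 2:
        raise ValueError("need at least 2 records per group")
    values = np.concatenate([va, vb])
    is_a = np.zeros(len(values), dtype=bool)
    is_a[: len(va)] = True
    observed = float(va.mean() - vb.mean())
    rng = np.random.default_rng(seed)

    have_exps = experiments_a is not None and experiments_b is not None
    if have_exps:
        ea = np.asarray(experiments_a)
        eb = np.asarray(experiments_b)
        strata = np.concatenate([ea, eb])
        shared = set(ea) & set(eb)
        if shared:
            method = "permutation_within_experiment"
            null = _stratified_null(values, is_a, strata, n_permutations, rng)
        elif len(set(ea)) >= 2 and len(set(eb)) >= 2:
            method = "permutation_experiment_level"
            null = _experiment_level_null(values, is_a, strata, n_permutations, rng)
        else:
            logger.warning(
                "fewer than 2 disjoint experiments per group: falling back to "
                "cell-level permutation (ignores replicate correlation)")
            method = "permutation_cell_level"
            null = _stratified_null(values, is_a, np.zeros(len(values)),
                                    n_permutations, rng)
    else:
        logger.warning("no experiment ids given: cell-level permutation only "
                       "(pseudo-replication risk)")
        method = "permutation_cell_level"
        null = _stratified_null(values, is_a, np.zeros(len(values)),
                                n_permutations, rng)

    exceed = int(np.sum(np.abs(null) >= abs(observed) - 1e-12))
    p = (1.0 + exceed) / (n_permutations + 1.0)
    pct = percent_difference(float(va.mean()), float(vb.mean()))
    return PairwiseComparison(
        group_a=group_a, group_b=group_b, percent_difference=pct,
        p_value=p, method=method, statistic=observed,
        n_permutations=n_permutations,
    )


def mixed_model_pvalue(df: pd.DataFrame, value_col="value", group_col="group",
                       experiment_col="experiment_id") -> float:
    """Optional cross-check: random-intercept model p-value for the group effect."""
    import statsmodels.formula.api as smf

    data = df.rename(columns={value_col: "y", group_col: "g", experiment_col: "e"})
    model = smf.mixedlm("y ~ C(g)", data, groups=data["e"])
    fit = model.fit(reml=True)
    pvals = [p for name, p in fit.pvalues.items() if name.startswith("C(g)")]
    return float(min(pvals))
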