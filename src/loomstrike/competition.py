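"""Prey-survival competition indices and the assay's statistical tests.

In a competition trial, two wing-clip-marked groups of flies share a
chamber with damselfly predators; at the end of the trial the eaten flies
are counted per group.  Two normalized difference indices summarize a
trial:

* WCB (wing clipping bias) = (left-clipped eaten - right-clipped eaten) /
  (total eaten) — a control for the wing-marking scheme itself.
* PCI (prey consumption index) = (silenced eaten - control eaten) /
  (total eaten) — positive when giant-fibre-silenced flies are eaten
  preferentially.

Both lie in [-1, 1]: 0 means no bias, +/-1 means only one group was
consumed.  Indices are tested against zero with a one-sample Student
t-test; group comparisons use two-sample t-tests, attack-angle groups a
one-way ANOVA with Tukey HSD post hoc contrasts, and binomial escape
proportions get Wilson score intervals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "CompetitionTrial",
    "IndexSummary",
    "UndefinedIndexError",
    "wcb",
    "pci",
    "summarize_indices",
    "one_sample_t",
    "two_sample_t",
    "wilson_interval",
    "outcome_split_by_speed",
    "angle_group_test",
    "read_trials",
]


@dataclass(frozen=True)
class CompetitionTrial:
    """Eaten-fly counts for one competition trial between two groups."""

    group_a_label: str
    group_b_label: str
    n_a_eaten: int
    n_b_eaten: int
    trial_id: str = ""

    def __post_init__(self) -> None:
        if self.n_a_eaten < 0 or self.n_b_eaten < 0:
            raise ValueError("eaten counts must be non-negative")


class UndefinedIndexError(ValueError):
    """Raised when zero flies of either group were eaten (index undefined)."""


def _index(n_a: int, n_b: int) -> float:
    total = n_a + n_b
    if total == 0:
        raise UndefinedIndexError("no flies eaten in either group; index undefined")
    return (n_a - n_b) / total


def wcb(trial: CompetitionTrial) -> float:
    """Wing clipping bias index: (left eaten - right eaten) / total eaten.

    Group a is the left-wing-clipped group, group b the right-wing-clipped
    group.  Positive means left-clipped flies were eaten preferentially.
    """
    return _index(trial.n_a_eaten, trial.n_b_eaten)


def pci(trial: CompetitionTrial) -> float:
    """Prey consumption index: (silenced eaten - control eaten) / total eaten.

    Group a is the giant-fibre-silenced group, group b the driver-only
    control.  Positive means silenced flies were eaten preferentially.
    """
    return _index(trial.n_a_eaten, trial.n_b_eaten)


@dataclass(frozen=True)
class IndexSummary:
    """Per-trial index values with a one-sample t-test against zero."""

    values: tuple[float, ...]
    mean: float
    sem: float
    n_trials: int
    n_excluded: int
    t_statistic: float
    p_value: float


def summarize_indices(trials: Sequence[CompetitionTrial], index=pci) -> IndexSummary:
    """Compute an index per trial and test the mean against zero.

    Trials in which no flies of either group were eaten have an undefined
    index; they are excluded and counted in ``n_excluded``.
    """
    values, excluded = [], 0
    for tr in trials:
        try:
            values.append(index(tr))
        except UndefinedIndexError:
            excluded += 1
    if len(values) < 2:
        raise ValueError(f"need >= 2 trials with a defined index, got {len(values)}")
    arr = np.asarray(values)
    t, p, mean, sem = one_sample_t(arr)
    return IndexSummary(
        values=tuple(values),
        mean=mean,
        sem=sem,
        n_trials=len(values),
        n_excluded=excluded,
        t_statistic=t,
        p_value=p,
    )


def one_sample_t(values: Sequence[float], mu0: float = 0.0) -> tuple[float, float, float, float]:
    """One-sample Student t-test of the mean against ``mu0``.

    Returns ``(t, p_two_sided, mean, sem)``.  A zero-variance sample is
    degenerate: p = 1 if its mean equals ``mu0``, else p = 0 (the sample
    is identically off-target).
    """
    arr = np.asarray(list(values), dtype=float)
    if len(arr) < 2:
        raise ValueError("need n >= 2")
    if not np.all(np.isfinite(arr)):
        raise ValueError("values must be finite")
    mean = float(np.mean(arr))
    sd = float(np.std(arr, ddof=1))
    sem = sd / math.sqrt(len(arr))
    if sd == 0.0:
        if mean == mu0:
            return 0.0, 1.0, mean, 0.0
        return math.inf if mean > mu0 else -math.inf, 0.0, mean, 0.0
    res = stats.ttest_1samp(arr, mu0)
    return float(res.statistic), float(res.pvalue), mean, sem


def two_sample_t(a: Sequence[float], b: Sequence[float], welch: bool = False) -> tuple[float, float]:
    """Two-sided two-sample t-test; Student (equal-variance) form by default.

    ``welch=True`` switches to the unequal-variance Welch form.
    """
    a = np.asarray(list(a), dtype=float)
    b = np.asarray(list(b), dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs n >= 2")
    res = stats.ttest_ind(a, b, equal_var=not welch)
    if np.isnan(res.statistic):  # both samples constant and equal
        return 0.0, 1.0
    return float(res.statistic), float(res.pvalue)


def wilson_interval(k: int, n: int, conf: float = 0.95) -> tuple[float, float]:
    """Wilson score confidence interval for a binomial proportion k/n."""
    if not (0 <= k <= n) or n < 1:
        raise ValueError(f"require 0 <= k <= n with n >= 1, got k={k}, n={n}")
    lo, hi = proportion_confint(k, n, alpha=1 - conf, method="wilson")
    # exact at the degenerate proportions (the closed form gives 0/1 there;
    # floating point can land a hair inside)
    lo = 0.0 if k == 0 else min(float(lo), k / n)
    hi = 1.0 if k == n else max(float(hi), k / n)
    return max(lo, 0.0), min(hi, 1.0)


def outcome_split_by_speed(
    events: Sequence[tuple[float, str]],
    threshold: float,
    conf: float = 0.95,
) -> dict:
    """Escape proportions for attacks slower vs faster than a speed threshold.

    ``events`` are ``(peak_speed m/s, outcome)`` pairs with outcome
    ``"escape"`` or ``"capture"``; the split is strict-below vs at-or-above
    ``threshold``.  Each side reports the escape fraction with a Wilson
    interval; an empty side is flagged and its interval omitted.
    """
    if len(events) == 0:
        raise ValueError("no events")
    out = {"threshold_m_per_s": float(threshold)}
    for side, keep in (
        ("slow", lambda v: v < threshold),
        ("fast", lambda v: v >= threshold),
    ):
        side_events = [(v, o) for v, o in events if keep(v)]
        n = len(side_events)
        if n == 0:
            out[side] = {"n": 0, "empty": True}
            continue
        k = sum(1 for _, o in side_events if o == "escape")
        out[side] = {
            "n": n,
            "escaped": k,
            "proportion": k / n,
            "ci": wilson_interval(k, n, conf),
            "empty": False,
        }
    return out


def angle_group_test(groups: Sequence[Sequence[float]], labels: Sequence[str] | None = None) -> dict:
    """One-way ANOVA with Tukey HSD post hoc contrasts across angle groups.

    Returns the omnibus F and p plus a pairwise table of mean differences
    and Tukey-adjusted p-values (studentized-range distribution, family
    level alpha applied to all pairwise contrasts).
    """
    arrays = [np.asarray(list(g), dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need >= 2 groups")
    if any(len(g) < 2 for g in arrays):
        raise ValueError("every group needs n >= 2")
    if labels is None:
        labels = [f"group{i}" for i in range(len(arrays))]
    f, p = stats.f_oneway(*arrays)
    # Tukey HSD on the studentized range; MSE pooled across groups
    k = len(arrays)
    ns = np.array([len(g) for g in arrays])
    means = np.array([g.mean() for g in arrays])
    df_err = int(ns.sum() - k)
    mse = sum(((g - g.mean()) ** 2).sum() for g in arrays) / df_err
    rows = []
    for i, j in combinations(range(k), 2):
        diff = means[i] - means[j]
        se = math.sqrt(mse / 2.0 * (1.0 / ns[i] + 1.0 / ns[j]))
        q = abs(diff) / se if se > 0 else (0.0 if diff == 0 else math.inf)
        p_adj = float(stats.studentized_range.sf(q, k, df_err)) if math.isfinite(q) else 0.0
        rows.append(
            {
                "group1": labels[i],
                "group2": labels[j],
                "mean_diff": float(diff),
                "p_adj": min(p_adj, 1.0),
            }
        )
    return {
        "F": float(f),
        "p": float(p),
        "pairwise": pd.DataFrame(rows),
        "df": (k - 1, df_err),
    }


def read_trials(path) -> list[tuple[CompetitionTrial, str]]:
    """Read a trials CSV: trial_id,group_a,group_b,n_a_eaten,n_b_eaten,match_type.

    ``match_type`` is ``WCB`` or ``PCI``; returned alongside each trial so
    callers can route to the matching index.
    """
    df = pd.read_csv(path)
    required = {"trial_id", "group_a", "group_b", "n_a_eaten", "n_b_eaten", "match_type"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    out = []
    for row in df.itertuples(index=False):
        match = str(row.match_type).upper()
        if match not in ("WCB", "PCI"):
            raise ValueError(f"{path}: unknown match_type {row.match_type!r}")
        out.append(
            (
                CompetitionTrial(
                    group_a_label=str(row.group_a),
                    group_b_label=str(row.group_b),
                    n_a_eaten=int(row.n_a_eaten),
                    n_b_eaten=int(row.n_b_eaten),
                    trial_id=str(row.trial_id),
                ),
                match,
            )
        )
    return out
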