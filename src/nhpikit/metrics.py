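"""Population-level variation metrics for NHPI coefficients.

Given per-individual-year NHPI coefficients x_i (= minus the fitted
dissimilarity coefficient) the module computes:

* ``average``     — mean of x_i (population-level direction);
* ``specialization`` — mean |x_i| (magnitude regardless of direction;
  informative when the average is near zero or the population bimodal);
* ``heterogeneity``  — SD of x_i (n−1 denominator);
* ``consistency``    — mean |x_{i,p} − x_{i,s}| over individuals with a
  prospecting/settlement coefficient pair (0 = perfectly consistent);
* ``reversal``       — fraction of individuals whose coefficient
  changes sign between the phases;
* ``interannual_consistency`` — per individual, the mean absolute
  change between consecutive prospecting years, averaged over
  individuals.

Coefficient uncertainty is propagated by simulation: each coefficient
is perturbed with Normal(x_i, se_i) noise, independently across
records, and every metric recomputed per replicate (1000 by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import f as f_dist
from statsmodels.stats.multicomp import pairwise_tukeyhsd

REQUIRED_COLUMNS = ("individual", "x", "se")

PHASE_PROSPECTING = "prospecting"
PHASE_SETTLEMENT = "settlement"


def average(x) -> float:
    """Arithmetic mean of the coefficients."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("empty coefficient vector")
    return float(x.mean())


def specialization(x) -> float:
    """Mean magnitude of the coefficients; always >= |average|."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("empty coefficient vector")
    return float(np.abs(x).mean())


def heterogeneity(x) -> float:
    """Between-record SD of the coefficients (n−1 denominator)."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 coefficients for heterogeneity")
    return float(x.std(ddof=1))


def _complete_pairs(pairs) -> np.ndarray:
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("pairs must be (n, 2): one (x_p, x_s) row per individual")
    complete = np.isfinite(arr).all(axis=1)
    if not complete.all():
        warnings.warn(
            f"excluding {int((~complete).sum())} incomplete phase pairs", stacklevel=3
        )
    arr = arr[complete]
    if len(arr) == 0:
        raise ValueError("no complete phase pairs")
    return arr


def consistency(pairs) -> float:
    """Mean absolute coefficient change between the two dispersal phases."""
    arr = _complete_pairs(pairs)
    return float(np.abs(arr[:, 0] - arr[:, 1]).mean())


def reversal(pairs) -> float:
    """Fraction of individuals whose coefficient changes sign between phases.

    sign(0) counts as positive (a fixed convention; an exactly-zero
    coefficient has measure zero after simulation perturbation).
    """
    arr = _complete_pairs(pairs)
    sign = np.where(arr >= 0, 1, -1)
    return float((sign[:, 0] != sign[:, 1]).mean())


def interannual_consistency(sequences) -> float:
    """Mean (over individuals) of mean |x_{j+1} − x_j| over consecutive years.

    ``sequences`` is an iterable of per-individual coefficient
    sequences ordered by year; individuals with fewer than 2 years are
    excluded with a warning.
    """
    inner = []
    excluded = 0
    for seq in sequences:
        seq = np.asarray(seq, dtype=float)
        if seq.size < 2:
            excluded += 1
            continue
        inner.append(float(np.abs(np.diff(seq)).mean()))
    if excluded:
        warnings.warn(f"excluding {excluded} individuals with < 2 years", stacklevel=2)
    if not inner:
        raise ValueError("no individual with >= 2 years")
    return float(np.mean(inner))


# ---------------------------------------------------------------------------
# Metric evaluation on coefficient record tables


def _records_to_pairs(records: pd.DataFrame) -> np.ndarray:
    wide = records.pivot_table(index="individual", columns="phase", values="x", aggfunc="first")
    for phase in (PHASE_PROSPECTING, PHASE_SETTLEMENT):
        if phase not in wide:
            wide[phase] = np.nan
    return wide[[PHASE_PROSPECTING, PHASE_SETTLEMENT]].to_numpy()


def _records_to_sequences(records: pd.DataFrame) -> list[np.ndarray]:
    out = []
    for _, grp in records.sort_values("year").groupby("individual"):
        out.append(grp["x"].to_numpy(dtype=float))
    return out


def evaluate_metric(metric: str, records: pd.DataFrame) -> float:
    """Evaluate one named metric on a coefficient record table."""
    if metric == "average":
        return average(records["x"])
    if metric == "specialization":
        return specialization(records["x"])
    if metric == "heterogeneity":
        return heterogeneity(records["x"])
    if metric == "consistency":
        return consistency(_records_to_pairs(records))
    if metric == "reversal":
        return reversal(_records_to_pairs(records))
    if metric == "interannual_consistency":
        return interannual_consistency(_records_to_sequences(records))
    raise KeyError(f"unknown metric {metric!r}")


POINT_METRICS = ("average", "specialization", "heterogeneity")
PAIR_METRICS = ("consistency", "reversal")
ALL_METRICS = POINT_METRICS + PAIR_METRICS + ("interannual_consistency",)


@dataclass
class MetricDistribution:
    """Point estimate + simulation replicates of one metric in one group."""

    metric: str
    group: str
    point: float
    replicates: np.ndarray

    @property
    def median(self) -> float:
        return float(np.median(self.replicates))

    def quantiles(self, q=(0.025, 0.975)) -> np.ndarray:
        return np.quantile(self.replicates, q)

    def summary(self) -> dict:
        lo, hi = self.quantiles()
        return {
            "metric": self.metric,
            "group": self.group,
            "point": self.point,
            "median": self.median,
            "q2.5": float(lo),
            "q97.5": float(hi),
        }


def propagate_uncertainty(
    records: pd.DataFrame,
    metrics: tuple[str, ...] = POINT_METRICS,
    n_sim: int = 1000,
    seed: int | np.random.Generator = 0,
    by: list[str] | None = None,
    include_nonconverged: bool = False,
) -> list[MetricDistribution]:
    """Simulation-based uncertainty for each metric (per group).

    For every replicate each coefficient is redrawn from
    Normal(x_i, se_i), independently across records, and every
    requested metric recomputed.  ``by`` names grouping columns (e.g.
    ``["cluster", "phase"]``); the ungrouped table is the group
    ``"all"``.  Records with missing SE are excluded with a warning;
    so are non-converged fits if a ``converged`` column is present
    (unless ``include_nonconverged``).
    """
    if n_sim < 1:
        raise ValueError("n_sim must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    df = records.copy()
    if "converged" in df.columns and not include_nonconverged:
        bad = ~df["converged"].astype(bool)
        if bad.any():
            warnings.warn(f"excluding {int(bad.sum())} non-converged fits", stacklevel=2)
            df = df[~bad]
    missing = df["se"].isna()
    if missing.any():
        warnings.warn(f"excluding {int(missing.sum())} records with missing SE", stacklevel=2)
        df = df[~missing]
    df = df.reset_index(drop=True)
    x = df["x"].to_numpy(dtype=float)
    se = df["se"].to_numpy(dtype=float)
    draws = x[None, :] + rng.standard_normal((n_sim, len(df))) * se[None, :]

    groups: list[tuple[str, np.ndarray]] = [("all", np.arange(len(df)))]
    if by:
        groups = [
            (":".join(map(str, key)) if isinstance(key, tuple) else str(key), np.asarray(idx))
            for key, idx in df.groupby(by, sort=True).groups.items()
        ]
    out = []
    for gname, idx in groups:
        sub = df.loc[idx]
        for metric in metrics:
            try:
                point = evaluate_metric(metric, sub)
            except ValueError as exc:  # group too small for this metric
                warnings.warn(f"{metric} skipped for group {gname!r}: {exc}", stacklevel=2)
                continue
            reps = np.empty(n_sim)
            for r in range(n_sim):
                pert = sub.copy()
                pert["x"] = draws[r][idx]
                reps[r] = evaluate_metric(metric, pert)
            out.append(MetricDistribution(metric, gname, point, reps))
    return out


# ---------------------------------------------------------------------------
# Group comparison: ANOVA + Tukey HSD with a compact letter display


def compact_letter_display(groups: list[str], differ: set[tuple[str, str]]) -> dict[str, str]:
    """Assign letters so that groups sharing a letter do not differ.

    Insert-and-absorb algorithm over the significant-difference pairs.
    """
    letter_sets: list[set[str]] = [set(groups)]
    for a, b in sorted(differ):
        for s in [s for s in letter_sets if a in s and b in s]:
            letter_sets.remove(s)
            sa, sb = s - {a}, s - {b}
            for t in (sa, sb):
                if not any(t <= other for other in letter_sets):
                    letter_sets.append(t)
    letter_sets.sort(key=lambda s: sorted(s))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {g: "" for g in groups}
    for i, s in enumerate(letter_sets):
        for g in sorted(s):
            out[g] += alphabet[i % len(alphabet)]
    return out


def compare_groups(
    distributions: list[MetricDistribution],
    design: str = "one-way",
    alpha: float = 0.05,
) -> dict:
    """ANOVA on replicate values + Tukey HSD compact letter display.

    ``design="two-way"`` splits the group label on ``:`` into habitat
    and phase factors and fits the additive two-factor ANOVA; Tukey
    letters are computed on the combined groups.  Letters are omitted
    when the omnibus p >= alpha.  Operating on simulation replicates is
    anti-conservative (replicates are not independent samples); treat
    p-values as descriptive and read them alongside the replicate
    quantile overlaps.
    """
    if len(distributions) < 2:
        raise ValueError("need at least 2 groups to compare")
    values = np.concatenate([d.replicates for d in distributions])
    labels = np.concatenate([[d.group] * len(d.replicates) for d in distributions])
    if design == "one-way":
        table = _one_way_anova(values, labels)
        p = table["p"]
    elif design == "two-way":
        table = _two_way_anova(values, labels)
        p = min(table["p_factor1"], table["p_factor2"])
    else:
        raise ValueError(f"unknown design {design!r}")
    letters: dict[str, str] = {}
    if p < alpha:
        from itertools import combinations

        tukey = pairwise_tukeyhsd(values, labels, alpha=alpha)
        pairs = list(combinations(tukey.groupsunique, 2))
        differ = {(str(a), str(b)) for (a, b), rej in zip(pairs, tukey.reject) if rej}
        letters = compact_letter_display(sorted({d.group for d in distributions}), differ)
    return {"anova": table, "letters": letters, "alpha": alpha}


def _one_way_anova(values: np.ndarray, labels: np.ndarray) -> dict:
    """Textbook fixed-effects one-way ANOVA."""
    grand = values.mean()
    groups = [values[labels == g] for g in np.unique(labels)]
    if any(len(g) < 2 for g in groups):
        raise ValueError("each group needs at least 2 replicate values")
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_between = len(groups) - 1
    df_within = len(values) - len(groups)
    ms_between = ss_between / df_between
    ms_within = ss_within / df_within
    F = ms_between / ms_within if ms_within > 0 else 0.0
    p = float(f_dist.sf(F, df_between, df_within)) if ms_within > 0 else 1.0
    return {
        "F": float(F),
        "p": p,
        "df_between": df_between,
        "df_within": df_within,
        "ss_between": float(ss_between),
        "ss_within": float(ss_within),
    }


def _two_way_anova(values: np.ndarray, labels: np.ndarray) -> dict:
    """Additive two-factor ANOVA; factors split from 'habitat:phase' labels."""
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    parts = [lab.split(":") for lab in labels]
    if any(len(p) < 2 for p in parts):
        raise ValueError("two-way design needs 'factor1:factor2' group labels")
    df = pd.DataFrame(
        {"value": values, "f1": [p[0] for p in parts], "f2": [p[1] for p in parts]}
    )
    model = smf.ols("value ~ C(f1) + C(f2)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    return {
        "p_factor1": float(table.loc["C(f1)", "PR(>F)"]),
        "p_factor2": float(table.loc["C(f2)", "PR(>F)"]),
        "F_factor1": float(table.loc["C(f1)", "F"]),
        "F_factor2": float(table.loc["C(f2)", "F"]),
        "table": table,
    }
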