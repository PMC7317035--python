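"""Longitudinal assembly: responder stratification, group statistics, MRI-PET
correlation.

Animals challenged with a fibrogenic insult split into two phenotypes by
their total-lung-volume trajectory: "high responders" whose volume keeps
rising through the final imaging day, and "low responders" whose volume
returns toward the normal growth of saline controls.  The split is
quantified here as a control-referenced z-threshold on relative growth
V(final)/V(baseline): an animal is a high responder when its growth exceeds
the control mean by more than k control standard deviations (default k=2).
Relative rather than absolute growth is used so that animal size cancels.

The rank statistics (Mann-Whitney U, Spearman rho) and the one-way
ANOVA/Bonferroni chain are implemented from their standard definitions so
that exact small-sample behaviour is enumerable; only distribution tail
functions come from scipy.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps


# ---------------------------------------------------------------------------
# Time-course containers


@dataclass
class DayRecord:
    """Per-day imaging read-outs for one animal."""

    lung_volume_mm3: Optional[float] = None
    high_signal_volume_long_mm3: Optional[float] = None
    high_signal_volume_short_mm3: Optional[float] = None
    fractional_uptake_total: Optional[float] = None


@dataclass
class AnimalTimecourse:
    """Longitudinal record of one animal: day -> imaging read-outs."""

    animal_id: str
    arm: str  # exposure label: "saline" or "bleomycin"
    records: Dict[int, DayRecord] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.records and 0 not in self.records:
            raise ValueError(f"{self.animal_id}: baseline (day 0) record is required")

    @property
    def days(self) -> List[int]:
        return sorted(self.records)

    def volume(self, day: int) -> Optional[float]:
        rec = self.records.get(day)
        return None if rec is None else rec.lung_volume_mm3


@dataclass
class ResponderLabel:
    """Stratification outcome for one animal."""

    animal_id: str
    label: str  # control / low / high / unclassifiable
    statistic: Optional[float] = None  # relative growth V(final)/V(0)
    threshold: Optional[float] = None  # control mean + k * control SD


def classify_responders(
    cohort: Sequence[AnimalTimecourse],
    k: float = 2.0,
    baseline_day: int = 0,
    final_day: Optional[int] = None,
) -> List[ResponderLabel]:
    """Label each challenged animal high/low responder against control growth.

    Controls define normal growth: their mean and SD of relative growth
    g = V(final)/V(baseline) set the decision boundary mean + k*SD.  A
    challenged animal with g above the boundary is "high", otherwise "low";
    controls are always labelled "control".  Animals missing either volume
    are flagged "unclassifiable" rather than dropped.
    """
    if final_day is None:
        final_day = max(d for a in cohort for d in a.days)

    def growth(a: AnimalTimecourse) -> Optional[float]:
        v0, vf = a.volume(baseline_day), a.volume(final_day)
        if v0 is None or vf is None or v0 <= 0:
            return None
        return vf / v0

    controls = [a for a in cohort if a.arm == "saline"]
    control_g = [g for g in (growth(a) for a in controls) if g is not None]
    challenged = [a for a in cohort if a.arm != "saline"]
    if challenged and len(control_g) < 2:
        raise ValueError(
            f"need >= 2 classifiable controls to set the boundary, got {len(control_g)}"
        )
    if control_g:
        mean_c = float(np.mean(control_g))
        sd_c = float(np.std(control_g, ddof=1)) if len(control_g) > 1 else 0.0
        boundary = mean_c + k * sd_c
    else:
        boundary = None

    labels: List[ResponderLabel] = []
    for a in cohort:
        g = growth(a)
        if a.arm == "saline":
            labels.append(ResponderLabel(a.animal_id, "control", g, None))
        elif g is None:
            labels.append(ResponderLabel(a.animal_id, "unclassifiable", None, boundary))
        else:
            lab = "high" if g > boundary else "low"
            labels.append(ResponderLabel(a.animal_id, lab, g, boundary))
    return labels


def cohort_to_frame(cohort: Sequence[AnimalTimecourse]) -> pd.DataFrame:
    """Tidy long-format table: animal_id, arm, day, metric, value."""
    rows = []
    for a in cohort:
        for day in a.days:
            rec = a.records[day]
            for metric in (
                "lung_volume_mm3",
                "high_signal_volume_long_mm3",
                "high_signal_volume_short_mm3",
                "fractional_uptake_total",
            ):
                val = getattr(rec, metric)
                if val is not None:
                    rows.append(
                        {
                            "animal_id": a.animal_id,
                            "arm": a.arm,
                            "day": day,
                            "metric": metric,
                            "value": val,
                        }
                    )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Rank statistics from first principles


def significance_stars(p: float) -> str:
    """Figure-legend star bands: * <0.05, ** <0.01, *** <0.001, **** <0.0001."""
    for stars, cut in (("****", 1e-4), ("***", 1e-3), ("**", 1e-2), ("*", 0.05)):
        if p < cut:
            return stars
    return "ns"


def _average_ranks(values: np.ndarray) -> np.ndarray:
    """Midranks: ties receive the average of the ranks they span."""
    order = np.argsort(values, kind="stable")
    ranks = np.empty(len(values), dtype=float)
    i = 0
    sorted_vals = values[order]
    while i < len(values):
        j = i
        while j + 1 < len(values) and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def mann_whitney_u(
    x: Sequence[float], y: Sequence[float], exact_max_n: int = 20
) -> Tuple[float, float]:
    """Two-tailed Mann-Whitney U test; returns (U of the first sample, p).

    For combined n <= ``exact_max_n`` the null distribution of U is built by
    full enumeration of rank assignments (midranks for ties); otherwise the
    normal approximation with tie correction and continuity correction is
    used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 < 1 or n2 < 1:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([x, y])
    ranks = _average_ranks(pooled)
    r1 = float(ranks[:n1].sum())
    u1 = r1 - n1 * (n1 + 1) / 2.0

    if n1 + n2 <= exact_max_n:
        # enumerate every assignment of n1 of the pooled ranks to sample 1
        offset = n1 * (n1 + 1) / 2.0
        u_lo = min(u1, n1 * n2 - u1)
        count = 0
        total = 0
        for combo in itertools.combinations(ranks, n1):
            u = sum(combo) - offset
            total += 1
            if min(u, n1 * n2 - u) <= u_lo + 1e-9:
                count += 1
        return u1, count / total

    # normal approximation with tie correction
    n = n1 + n2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    mu = n1 * n2 / 2.0
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var == 0:
        return u1, 1.0
    z = (abs(u1 - mu) - 0.5) / math.sqrt(var)
    return u1, float(2.0 * sps.norm.sf(max(z, 0.0)))


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> Tuple[float, float]:
    """Spearman rank correlation with midranks for ties; returns (rho, p).

    p is the two-sided t-approximation p-value; |rho| = 1 gives p = 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need >= 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("rho undefined: constant variable")
    rx, ry = _average_ranks(x), _average_ranks(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    n = len(x)
    if abs(rho) >= 1.0 - 1e-15:
        return float(np.sign(rho)), 0.0
    t = rho * math.sqrt((n - 2) / (1.0 - rho**2))
    return rho, float(2.0 * sps.t.sf(abs(t), df=n - 2))


def ols_fit(x: Sequence[float], y: Sequence[float]) -> Tuple[float, float, float]:
    """Ordinary least-squares line: (slope, intercept, R^2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xm, ym = x.mean(), y.mean()
    sxx = float(np.sum((x - xm) ** 2))
    if sxx == 0:
        raise ValueError("OLS undefined: constant x")
    slope = float(np.sum((x - xm) * (y - ym))) / sxx
    intercept = ym - slope * xm
    ss_res = float(np.sum((y - (slope * x + intercept)) ** 2))
    ss_tot = float(np.sum((y - ym) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return slope, intercept, r2


# ---------------------------------------------------------------------------
# Group comparisons


@dataclass
class Comparison:
    """One pairwise (or omnibus) comparison with its adjusted p-value."""

    group_a: str
    group_b: str
    statistic: float
    p_value: float
    p_adjusted: float
    stars: str


@dataclass
class GroupCompareResult:
    method: str
    omnibus_statistic: Optional[float]  # ANOVA F, when applicable
    omnibus_p: Optional[float]
    comparisons: List[Comparison]


def group_compare(
    values_by_group: Dict[str, Sequence[float]],
    method: str = "anova_bonferroni",
) -> GroupCompareResult:
    """Compare groups by one-way ANOVA + Bonferroni post hoc, or Mann-Whitney.

    ``anova_bonferroni``: omnibus F ratio from the between/within mean
    squares, then pairwise pooled-variance t tests with p multiplied by the
    number of comparisons (capped at 1).  ``mann_whitney``: two-tailed
    pairwise rank tests (exact null for combined n <= 20), Bonferroni
    adjusted when more than one pair.
    """
    groups = {k: np.asarray(v, dtype=float) for k, v in values_by_group.items()}
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for name, vals in groups.items():
        if len(vals) < 2:
            raise ValueError(f"group {name!r} has fewer than 2 observations")

    names = list(groups)
    pairs = list(itertools.combinations(names, 2))
    n_comp = len(pairs)
    comparisons: List[Comparison] = []

    if method == "anova_bonferroni":
        all_vals = np.concatenate(list(groups.values()))
        grand = all_vals.mean()
        k = len(groups)
        n_tot = len(all_vals)
        ss_between = sum(len(v) * (v.mean() - grand) ** 2 for v in groups.values())
        ss_within = sum(float(np.sum((v - v.mean()) ** 2)) for v in groups.values())
        df_b, df_w = k - 1, n_tot - k
        if df_w <= 0 or ss_within == 0:
            raise ValueError("within-group variance is degenerate")
        msb, msw = ss_between / df_b, ss_within / df_w
        f_stat = msb / msw
        f_p = float(sps.f.sf(f_stat, df_b, df_w))
        for a, b in pairs:
            va, vb = groups[a], groups[b]
            se = math.sqrt(msw * (1.0 / len(va) + 1.0 / len(vb)))
            t = (va.mean() - vb.mean()) / se
            p = float(2.0 * sps.t.sf(abs(t), df=df_w))
            p_adj = min(1.0, p * n_comp)
            comparisons.append(Comparison(a, b, float(t), p, p_adj, significance_stars(p_adj)))
        return GroupCompareResult("anova_bonferroni", float(f_stat), f_p, comparisons)

    if method == "mann_whitney":
        for a, b in pairs:
            u, p = mann_whitney_u(groups[a], groups[b])
            p_adj = min(1.0, p * n_comp) if n_comp > 1 else p
            comparisons.append(Comparison(a, b, float(u), p, p_adj, significance_stars(p_adj)))
        return GroupCompareResult("mann_whitney", None, None, comparisons)

    raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# MRI-PET correlation


@dataclass
class CorrelationResult:
    spearman_rho: Optional[float]
    p_value: Optional[float]
    slope: Optional[float]
    intercept: Optional[float]
    r_squared: Optional[float]
    n: int
    note: str = ""


def correlate_pet_mri(
    cohort: Sequence[AnimalTimecourse],
    x_metric: str = "high_signal_volume_long_mm3",
    y_metric: str = "fractional_uptake_total",
    animal_ids: Optional[Iterable[str]] = None,
) -> CorrelationResult:
    """Spearman rank correlation and OLS fit between two imaging read-outs.

    Pools all (animal, day) observations where both metrics are present,
    optionally restricted to a subgroup of animals (e.g. the high
    responders).  A constant variable makes rho undefined; this is reported
    in ``note`` rather than raised.
    """
    keep = set(animal_ids) if animal_ids is not None else None
    xs, ys = [], []
    for a in cohort:
        if keep is not None and a.animal_id not in keep:
            continue
        for day in a.days:
            rec = a.records[day]
            x, y = getattr(rec, x_metric), getattr(rec, y_metric)
            if x is not None and y is not None:
                xs.append(float(x))
                ys.append(float(y))
    n = len(xs)
    if n < 3:
        raise ValueError(f"need >= 3 paired observations, got {n}")
    x_arr, y_arr = np.asarray(xs), np.asarray(ys)
    if np.ptp(x_arr) == 0 or np.ptp(y_arr) == 0:
        return CorrelationResult(None, None, None, None, None, n, "constant variable: rho undefined")
    rho, p = spearman_rho(x_arr, y_arr)
    slope, intercept, r2 = ols_fit(x_arr, y_arr)
    return CorrelationResult(rho, p, slope, intercept, r2, n)
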