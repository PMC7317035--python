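"""Relative gene-expression quantification by the ddCt method.

Per sample, each target gene's Ct is referenced to the combined level of a
panel of stable reference genes (here five, e.g. beta-actin, B2M, HPRT1,
LDHA, RPLP1): dCt = Ct_target - Ct_ref.  The "geometric mean of the
reference genes" acts on the expression scale 2^-Ct, which on the Ct
(log2) scale is simply the arithmetic mean of the reference Cts — that is
what ``reference_ct`` computes.  ddCt then subtracts the mean dCt of the
control samples at the same time point (control normalisation stratified by
day), and the fold change is 2^-ddCt with the usual assumption of
amplification efficiency 2 per cycle.

Missing reference Cts are dropped from the per-sample mean with a warning;
missing target Cts propagate as missing fold changes, never imputed.
"""

from __future__ import annotations

import warnings
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

META_COLUMNS = ("sample_id", "group", "day")


def _check_table(t: pd.DataFrame, genes: Sequence[str]) -> None:
    missing_meta = [c for c in META_COLUMNS if c not in t.columns]
    if missing_meta:
        raise ValueError(f"Ct table lacks metadata columns {missing_meta}")
    missing = [g for g in genes if g not in t.columns]
    if missing:
        raise ValueError(f"Ct table lacks gene columns {missing}")


def reference_ct(t: pd.DataFrame, ref_genes: Sequence[str]) -> pd.Series:
    """Per-sample reference level: arithmetic mean of the reference-gene Cts.

    Equivalent to the geometric mean of the reference expression levels
    2^-Ct.  Samples with some (not all) reference Cts missing use the mean
    of the available ones, with a warning.
    """
    ref_genes = list(ref_genes)
    if len(ref_genes) < 1:
        raise ValueError("at least one reference gene is required")
    _check_table(t, ref_genes)
    ref = t[ref_genes].astype(float)
    n_missing = ref.isna().sum(axis=1)
    if (n_missing == len(ref_genes)).any():
        bad = t.loc[n_missing == len(ref_genes), "sample_id"].tolist()
        raise ValueError(f"all reference genes missing for samples {bad}")
    if (n_missing > 0).any():
        warnings.warn(
            f"{int((n_missing > 0).sum())} sample(s) missing some reference Cts; "
            "averaging the available ones",
            stacklevel=2,
        )
    return ref.mean(axis=1, skipna=True)


def delta_delta_ct(
    t: pd.DataFrame,
    ref_genes: Sequence[str],
    target_genes: Optional[Sequence[str]] = None,
    control_group: str = "control",
) -> pd.DataFrame:
    """Long-format ddCt table: per sample x target gene dCt, ddCt, fold change.

    dCt = Ct_target - reference_ct per sample; ddCt subtracts the mean
    control dCt of the same day stratum; fold_change = 2^-ddCt.  Every day
    stratum must contain at least one control sample with a measurable dCt.
    """
    ref_genes = list(ref_genes)
    if target_genes is None:
        target_genes = [
            c for c in t.columns if c not in META_COLUMNS and c not in ref_genes
        ]
    target_genes = list(target_genes)
    _check_table(t, list(ref_genes) + target_genes)
    if control_group not in set(t["group"]):
        raise ValueError(f"no {control_group!r} samples in the table")

    ref = reference_ct(t, ref_genes)
    rows: List[dict] = []
    for gene in target_genes:
        dct = t[gene].astype(float) - ref
        for day, idx in t.groupby("day").groups.items():
            stratum = t.loc[idx]
            ctrl_mask = stratum["group"] == control_group
            ctrl_dct = dct.loc[idx][ctrl_mask.values].dropna()
            if ctrl_dct.empty:
                raise ValueError(
                    f"day {day}: no control sample with measurable dCt for {gene}"
                )
            ctrl_mean = float(ctrl_dct.mean())
            for i in idx:
                d = dct.loc[i]
                dd = d - ctrl_mean if pd.notna(d) else np.nan
                rows.append(
                    {
                        "sample_id": t.loc[i, "sample_id"],
                        "group": t.loc[i, "group"],
                        "day": int(day),
                        "gene": gene,
                        "dCt": d if pd.notna(d) else np.nan,
                        "ddCt": dd,
                        "fold_change": 2.0 ** (-dd) if pd.notna(dd) else np.nan,
                    }
                )
    return pd.DataFrame(rows)


def summarize_folds(folds: pd.DataFrame) -> pd.DataFrame:
    """Group summaries per gene/day/group: mean fold change and its SEM."""

    def sem(v: pd.Series) -> float:
        v = v.dropna()
        if len(v) < 2:
            return float("nan")
        return float(v.std(ddof=1) / np.sqrt(len(v)))

    out = (
        folds.groupby(["gene", "day", "group"])["fold_change"]
        .agg(mean_fold="mean", sem_fold=sem, n="count")
        .reset_index()
    )
    return out
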