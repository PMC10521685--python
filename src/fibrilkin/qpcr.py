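"""Relative gene expression by the 2^-ddCt (Livak) method.

Ct tables are tidy DataFrames with columns ``gene``, ``group``,
``replicate``, ``ct``.  Per replicate, dCt = Ct(gene) - Ct(reference
gene); ddCt subtracts the control group's mean dCt for that gene; the
fold change is 2^-ddCt.  Amplification efficiency is fixed at 2 (no
efficiency correction).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import DomainError

__all__ = ["delta_delta_ct", "group_summary"]

REQUIRED_COLUMNS = ("gene", "group", "replicate", "ct")


def _validate_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise DomainError(f"Ct table is missing columns: {missing}")
    if not np.all(np.isfinite(table["ct"])) or (table["ct"] <= 0).any():
        raise DomainError("all Ct values must be finite and positive")
    return table


def delta_delta_ct(table: pd.DataFrame, ref_gene: str = "actin",
                   control_group: str = "NC") -> pd.DataFrame:
    """Per-replicate fold changes 2^-ddCt relative to the control group.

    Parameters
    ----------
    table : DataFrame with columns gene, group, replicate, ct.
    ref_gene : str
        Housekeeping gene used for normalisation (must be present in every
        group/replicate that carries a target gene).
    control_group : str
        Group whose mean dCt defines ddCt = 0 (fold = 1 on average).

    Returns
    -------
    DataFrame with columns gene, group, replicate, delta_ct,
    delta_delta_ct, fold for every non-reference gene.
    """
    table = _validate_table(table)
    if ref_gene not in set(table["gene"]):
        raise DomainError(f"reference gene {ref_gene!r} not present in the table")
    if control_group not in set(table["group"]):
        raise DomainError(f"control group {control_group!r} not present in the table")

    ref = (table[table["gene"] == ref_gene]
           .rename(columns={"ct": "ct_ref"})[["group", "replicate", "ct_ref"]])
    targets = table[table["gene"] != ref_gene]
    merged = targets.merge(ref, on=["group", "replicate"], how="left")
    if merged["ct_ref"].isna().any():
        gaps = merged.loc[merged["ct_ref"].isna(), ["gene", "group", "replicate"]]
        pairs = sorted({(g, int(r)) for g, r in zip(gaps["group"], gaps["replicate"])})
        raise DomainError(
            f"reference gene {ref_gene!r} missing for (group, replicate): {pairs}"
        )

    merged["delta_ct"] = merged["ct"] - merged["ct_ref"]
    control_mean = (merged[merged["group"] == control_group]
                    .groupby("gene")["delta_ct"].mean())
    missing_ctrl = sorted(set(merged["gene"]) - set(control_mean.index))
    if missing_ctrl:
        raise DomainError(f"no control-group measurements for genes: {missing_ctrl}")
    merged["delta_delta_ct"] = merged["delta_ct"] - merged["gene"].map(control_mean)
    merged["fold"] = np.exp2(-merged["delta_delta_ct"])
    return merged[["gene", "group", "replicate", "delta_ct", "delta_delta_ct", "fold"]]


def group_summary(folds: pd.DataFrame) -> pd.DataFrame:
    """Mean fold, SD (NaN for n = 1, not 0) and n per (gene, group)."""
    out = (folds.groupby(["gene", "group"], as_index=False)
           .agg(mean_fold=("fold", "mean"),
                sd_fold=("fold", lambda x: x.std(ddof=1)),
                n=("fold", "size")))
    return out
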