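"""qPCR relative expression (delta-Ct) and two-group Student's t-tests.

Relative expression of a target against a reference gene (actin) is
``2^-(Ct_target - Ct_reference)``.  Group comparisons use the classic
equal-variance two-sided Student's t-test with the conventional star
annotation (* p < 0.05, ** p < 0.01); Welch's correction is available as a
flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

QPCR_COLUMNS = ["species", "tissue", "gene", "replicate", "ct_target", "ct_reference"]


def relative_expression(ct_target: float, ct_reference: float) -> float:
    """Delta-Ct fold value ``2**-(Ct_target - Ct_reference)``."""
    if not (np.isfinite(ct_target) and np.isfinite(ct_reference)):
        raise ValueError("Ct values must be finite")
    return float(2.0 ** -(ct_target - ct_reference))


def stars(p: float) -> str:
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


@dataclass(frozen=True)
class GroupComparison:
    t: float
    p: float
    stars: str
    degenerate: bool = False


def compare_groups(
    group_a: list[float] | np.ndarray,
    group_b: list[float] | np.ndarray,
    welch: bool = False,
) -> GroupComparison:
    """Two-sided two-sample t-test between replicate expression values.

    Zero pooled variance is handled explicitly: equal means give p = 1,
    unequal means give p = 0 flagged degenerate.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs >= 2 replicates")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return GroupComparison(t=0.0, p=1.0, stars="")
        return GroupComparison(t=np.inf, p=0.0, stars="**", degenerate=True)
    t, p = stats.ttest_ind(a, b, equal_var=not welch)
    return GroupComparison(t=float(t), p=float(p), stars=stars(float(p)))


def load_qpcr_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in QPCR_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"qPCR table missing columns: {missing}")
    if not np.isfinite(df[["ct_target", "ct_reference"]].to_numpy()).all():
        raise ValueError("Ct values must be finite")
    if (df[["ct_target", "ct_reference"]] <= 0).any().any():
        raise ValueError("Ct values must be positive")
    return df


def analyze_qpcr(df: pd.DataFrame) -> pd.DataFrame:
    """Per-(species, gene) leaf-vs-fruit comparison of delta-Ct expression.

    Returns one row per group pair with mean +/- sd of replicates and the
    t-test verdict (the shape of a qPCR bar-plot annotation table).
    """
    df = df.copy()
    df["expression"] = [
        relative_expression(t, r) for t, r in zip(df["ct_target"], df["ct_reference"])
    ]
    rows = []
    for (species, gene), grp in df.groupby(["species", "gene"], sort=True):
        tissues = sorted(grp["tissue"].unique())
        if len(tissues) != 2:
            continue
        va = grp.loc[grp["tissue"] == tissues[0], "expression"].to_numpy()
        vb = grp.loc[grp["tissue"] == tissues[1], "expression"].to_numpy()
        cmp_ = compare_groups(va, vb)
        rows.append(
            {
                "species": species,
                "gene": gene,
                f"mean_{tissues[0]}": va.mean(),
                f"sd_{tissues[0]}": va.std(ddof=1),
                f"mean_{tissues[1]}": vb.mean(),
                f"sd_{tissues[1]}": vb.std(ddof=1),
                "t": cmp_.t,
                "p": cmp_.p,
                "stars": cmp_.stars,
            }
        )
    return pd.DataFrame(rows)
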