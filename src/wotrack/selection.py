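"""Paired-sample t-test feature selection between pre and post Levodopa.

Each feature column of the pre and post stride-feature tables is compared
with a two-sided paired Student's t-test at alpha = 0.05 (no
multiple-testing correction by default, mirroring the per-feature
reading of the source analysis; Bonferroni is available).  The default
pairing matches the i-th valid stride of a subject's pre session with the
i-th of its post session, truncating to the shorter; a subject-level-mean
pairing is provided as an alternative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

ALPHA_DEFAULT = 0.05


@dataclass
class PairedTestResult:
    t_statistic: float
    dof: int
    p_value: float
    degenerate: bool = False    # zero-variance differences with nonzero mean


def paired_ttest(x_pre, x_post) -> PairedTestResult:
    """Two-sided paired t-test on elementwise differences.

    All-zero differences give t = 0, p = 1; zero-variance nonzero
    differences are reported as p -> 0 with the ``degenerate`` flag.
    """
    x_pre = np.asarray(x_pre, dtype=float)
    x_post = np.asarray(x_post, dtype=float)
    if x_pre.shape != x_post.shape:
        raise ValueError("paired samples must have equal length")
    n = x_pre.size
    if n < 2:
        raise ValueError("need at least 2 pairs")
    d = x_pre - x_post
    dof = n - 1
    if np.ptp(d) == 0.0:
        if d[0] == 0.0:
            return PairedTestResult(0.0, dof, 1.0)
        t = np.inf if d[0] > 0 else -np.inf
        return PairedTestResult(t, dof, 0.0, degenerate=True)
    res = stats.ttest_rel(x_pre, x_post)
    return PairedTestResult(float(res.statistic), dof, float(res.pvalue))


def _pair_tables(pre: pd.DataFrame, post: pd.DataFrame, columns, scheme: str):
    if scheme == "stride":
        groups = []
        if "subject_id" in pre.columns and "subject_id" in post.columns:
            subjects = sorted(set(pre["subject_id"]) & set(post["subject_id"]))
            for s in subjects:
                groups.append((pre[pre["subject_id"] == s], post[post["subject_id"] == s]))
        else:
            groups.append((pre, post))
        pre_parts, post_parts = [], []
        for a, b in groups:
            n = min(len(a), len(b))
            pre_parts.append(a[columns].iloc[:n])
            post_parts.append(b[columns].iloc[:n])
        return pd.concat(pre_parts), pd.concat(post_parts)
    if scheme == "subject_mean":
        a = pre.groupby("subject_id")[columns].mean()
        b = post.groupby("subject_id")[columns].mean()
        common = a.index.intersection(b.index)
        return a.loc[common], b.loc[common]
    raise ValueError(f"unknown pairing scheme {scheme!r}")


def build_report(
    table_pre: pd.DataFrame,
    table_post: pd.DataFrame,
    alpha: float = ALPHA_DEFAULT,
    *,
    pairing: str = "stride",
    bonferroni: bool = False,
    feature_columns=None,
) -> pd.DataFrame:
    """One paired t-test per shared feature column; selection at p < alpha."""
    if feature_columns is None:
        skip = {"subject_id", "leg", "condition", "stride_idx", "onset", "valid", "run_id"}
        feature_columns = [
            c for c in table_pre.columns
            if c in table_post.columns and c not in skip
            and pd.api.types.is_numeric_dtype(table_pre[c])
        ]
    if not feature_columns:
        raise ValueError("no shared feature columns to test")
    pre, post = _pair_tables(table_pre, table_post, feature_columns, pairing)
    if len(pre) != len(post):
        n = min(len(pre), len(post))
        pre, post = pre.iloc[:n], post.iloc[:n]
    thresh = alpha / len(feature_columns) if bonferroni else alpha
    rows = []
    for col in feature_columns:
        a = pre[col].to_numpy(dtype=float)
        b = post[col].to_numpy(dtype=float)
        keep = ~(np.isnan(a) | np.isnan(b))
        res = paired_ttest(a[keep], b[keep])
        rows.append({
            "feature": col,
            "mean_pre": a[keep].mean(),
            "mean_post": b[keep].mean(),
            "t_statistic": res.t_statistic,
            "dof": res.dof,
            "p_value": res.p_value,
            # alpha = 1 means "select everything", including exact nulls (p = 1)
            "selected": res.p_value < thresh or thresh >= 1.0,
            "degenerate": res.degenerate,
            "n_pairs": int(keep.sum()),
            "alpha": alpha,
            "pairing_scheme": pairing,
        })
    return pd.DataFrame(rows)
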