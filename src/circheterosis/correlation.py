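"""Paired Pearson correlation between circRNA RPM and parent-gene FPKM."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats


def pair_correlation(
    circ_expr: pd.DataFrame,
    gene_expr: pd.DataFrame,
    circ_gene_map: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Pearson r and two-sided p across all shared samples for each
    (circRNA, parent gene) pair.

    Pairs where either vector has zero variance get NaN r/p and are excluded
    from downstream summaries. Significance is unadjusted p <= alpha.
    """
    shared = [s for s in circ_expr.columns if s in gene_expr.columns]
    if len(shared) < 3:
        raise ValueError("need at least 3 shared samples for a defined p-value")
    rows = []
    for rec in circ_gene_map.itertuples():
        cid, gid = rec.circ_id, rec.gene_id
        if cid not in circ_expr.index or gid not in gene_expr.index:
            continue
        x = circ_expr.loc[cid, shared].to_numpy(dtype=float)
        y = gene_expr.loc[gid, shared].to_numpy(dtype=float)
        if np.std(x) == 0 or np.std(y) == 0:
            r, p = np.nan, np.nan
        else:
            r, p = stats.pearsonr(x, y)
        rows.append(
            {"circ_id": cid, "gene_id": gid, "r": r, "p": p, "n": len(shared),
             "significant": bool(p <= alpha) if not np.isnan(p) else False}
        )
    return pd.DataFrame(rows, columns=["circ_id", "gene_id", "r", "p", "n", "significant"])


def summarize_correlation(
    records: pd.DataFrame, class_sets: dict[str, set] | None = None
) -> pd.DataFrame:
    """Positive/negative proportions among all pairs and among significant
    pairs, per circRNA class plus an 'all' row. r = 0 counts as positive
    (a measure-zero tie rule)."""
    class_sets = dict(class_sets or {})
    ok = records.dropna(subset=["r"])
    rows = []
    for name, sub in [("all", ok)] + [
        (cls, ok.loc[ok["circ_id"].isin(ids)]) for cls, ids in class_sets.items()
    ]:
        if name != "all" and sub.empty:
            import warnings

            warnings.warn(f"class {name!r} has no correlation records; row omitted")
            continue
        n = len(sub)
        pos = int((sub["r"] >= 0).sum())
        sig = sub.loc[sub["significant"]]
        n_sig = len(sig)
        pos_sig = int((sig["r"] >= 0).sum())
        rows.append(
            {
                "class": name, "n_pairs": n,
                "positive_pct": 100.0 * pos / n if n else np.nan,
                "negative_pct": 100.0 * (n - pos) / n if n else np.nan,
                "n_significant": n_sig,
                "sig_positive_pct": 100.0 * pos_sig / n_sig if n_sig else np.nan,
                "sig_negative_pct": 100.0 * (n_sig - pos_sig) / n_sig if n_sig else np.nan,
            }
        )
    return pd.DataFrame(rows)
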