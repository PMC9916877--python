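"""Weighted co-expression network analysis on a combined DEG+DEC matrix.

Unsigned adjacency a_ij = |cor(i, j)|^beta, topological overlap
TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij), average-
linkage clustering of 1 - TOM with a static height cut, module eigengenes as
first principal components, module-genotype correlation, intramodular-
connectivity hubs, and hypergeometric term enrichment.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .design import SampleDesign

#: WGCNA's conventional module colour order
MODULE_COLORS = [
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "white",
]
GREY = "grey"


def _drop_constant(expr: pd.DataFrame) -> pd.DataFrame:
    sd = expr.std(axis=1)
    constant = sd == 0
    if constant.any():
        warnings.warn(f"dropping {int(constant.sum())} constant feature(s) before network construction")
    return expr.loc[~constant]


def adjacency_matrix(expr: pd.DataFrame, beta: float) -> pd.DataFrame:
    """Unsigned adjacency |cor|^beta (diagonal 1)."""
    if beta < 1:
        raise ValueError("beta must be >= 1")
    expr = _drop_constant(expr)
    cor = np.corrcoef(expr.to_numpy())
    a = np.abs(cor) ** beta
    return pd.DataFrame(a, index=expr.index, columns=expr.index)


def pick_beta(
    expr: pd.DataFrame,
    candidate_powers=tuple(range(1, 21)),
    r2_target: float = 0.8,
    default: int = 6,
    n_bins: int = 10,
) -> int:
    """Smallest power with scale-free topology fit R^2 >= r2_target.

    The fit regresses log10 p(k) on log10 k over connectivity histogram bins;
    falls back to ``default`` when no candidate qualifies.
    """
    if expr.shape[1] < 4:
        raise ValueError("need at least 4 samples to pick a soft threshold")
    expr = _drop_constant(expr)
    cor = np.abs(np.corrcoef(expr.to_numpy()))
    np.fill_diagonal(cor, 0.0)
    for beta in candidate_powers:
        k = (cor**beta).sum(axis=1)
        if np.allclose(k, 0):
            continue
        hist, edges = np.histogram(k, bins=n_bins)
        centers = (edges[:-1] + edges[1:]) / 2
        ok = (hist > 0) & (centers > 0)
        if ok.sum() < 3:
            continue
        x = np.log10(centers[ok])
        y = np.log10(hist[ok] / hist.sum())
        _, _, r, _, _ = stats.linregress(x, y)
        if r**2 >= r2_target:
            return int(beta)
    return int(default)


def build_tom(expr: pd.DataFrame, beta: float) -> pd.DataFrame:
    """Topological overlap matrix; symmetric, entries in [0, 1], diagonal 1."""
    adj = adjacency_matrix(expr, beta)
    a = adj.to_numpy().copy()
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    shared = a @ a
    denom = np.minimum.outer(k, k) + 1.0 - a
    tom = (shared + a) / denom
    np.fill_diagonal(tom, 1.0)
    tom = np.clip((tom + tom.T) / 2.0, 0.0, 1.0)
    return pd.DataFrame(tom, index=adj.index, columns=adj.columns)


def detect_modules(
    tom: pd.DataFrame, min_module_size: int = 5, cut_height: float = 0.99
) -> pd.Series:
    """Average-linkage clustering of 1 - TOM cut at a static height.

    Clusters smaller than ``min_module_size`` become grey (unassigned);
    module labels follow the WGCNA colour convention, ordered by size.
    """
    features = tom.index
    diss = 1.0 - tom.to_numpy()
    np.fill_diagonal(diss, 0.0)
    z = linkage(squareform(diss, checks=False), method="average")
    raw = fcluster(z, t=cut_height, criterion="distance")
    labels = pd.Series(GREY, index=features, dtype=object)
    sizes = pd.Series(raw).value_counts()
    kept = [c for c in sizes.index if sizes[c] >= min_module_size]
    kept.sort(key=lambda c: (-sizes[c], c))
    for rank, cluster in enumerate(kept):
        name = MODULE_COLORS[rank] if rank < len(MODULE_COLORS) else f"module_{rank + 1}"
        labels[np.asarray(raw) == cluster] = name
    if (labels == GREY).all():
        warnings.warn("all features unassigned (grey)")
    return labels.rename("module")


def module_eigengenes(expr: pd.DataFrame, assignments: pd.Series) -> pd.DataFrame:
    """First principal component per module over standardized features.

    Eigengenes are unit-norm over samples and sign-oriented so that the mean
    feature-eigengene correlation is positive (ties: largest-magnitude entry
    made positive) — a deterministic orientation rule.
    """
    out = {}
    for module in assignments[assignments != GREY].unique():
        feats = assignments.index[assignments == module]
        mat = expr.loc[feats].to_numpy(dtype=float)
        mat = (mat - mat.mean(axis=1, keepdims=True))
        sd = mat.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        mat = mat / sd
        _, _, vt = np.linalg.svd(mat, full_matrices=False)
        eig = vt[0]
        mean_cor = np.mean([np.corrcoef(row, eig)[0, 1] for row in mat])
        if mean_cor < 0 or (mean_cor == 0 and eig[np.argmax(np.abs(eig))] < 0):
            eig = -eig
        out[module] = eig
    return pd.DataFrame(out, index=expr.columns).T


def module_trait(
    eigengenes: pd.DataFrame,
    design: SampleDesign,
    encoding: str = "genotype",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pearson r and p between each module eigengene and binary sample
    indicators (one per genotype, or per role group)."""
    if encoding == "genotype":
        levels = {gt: design.samples_of(gt) for gt in design.genotypes}
    elif encoding == "role":
        levels = {
            role: [s for gt in design.genotypes_of_role(role) for s in design.samples_of(gt)]
            for role in ("FP", "MP", "F1_high", "F1_low")
            if design.genotypes_of_role(role)
        }
    else:
        raise ValueError("encoding must be 'genotype' or 'role'")
    samples = list(eigengenes.columns)
    r_out = pd.DataFrame(index=eigengenes.index, columns=levels, dtype=float)
    p_out = r_out.copy()
    for trait, members in levels.items():
        indicator = np.array([1.0 if s in members else 0.0 for s in samples])
        if indicator.sum() < 2 or indicator.std() == 0:
            continue  # single-sample or degenerate trait level -> NA
        for module in eigengenes.index:
            r, p = stats.pearsonr(eigengenes.loc[module, samples], indicator)
            r_out.loc[module, trait] = r
            p_out.loc[module, trait] = p
    return r_out, p_out


def select_hubs(
    expr: pd.DataFrame,
    assignments: pd.Series,
    module: str,
    k: int = 25,
    beta: float = 6,
) -> pd.DataFrame:
    """Top-k features of a module by intramodular connectivity
    kWithin_i = sum_{j in module} a_ij; ties broken by feature id."""
    feats = list(assignments.index[assignments == module])
    if not feats:
        raise KeyError(f"module {module!r} has no members")
    if len(feats) < k:
        warnings.warn(f"module {module!r} smaller than k={k}; returning all members")
    adj = adjacency_matrix(expr.loc[feats], beta)
    kwithin = adj.to_numpy().sum(axis=1) - 1.0  # exclude self-adjacency
    ranked = (
        pd.DataFrame({"feature": feats, "kWithin": kwithin})
        .sort_values(["kWithin", "feature"], ascending=[False, True])
        .head(k)
        .reset_index(drop=True)
    )
    return ranked


def enrich_hypergeometric(
    feature_set: set,
    term_assignments: dict[str, set],
    universe: set,
    bh: bool = False,
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment p-value per term.

    p = P(X >= x) for x observed term members in the feature set, with
    universe size M, term size K, draw size N. Terms with no member in the
    universe are skipped.
    """
    if not set(feature_set) <= set(universe):
        raise ValueError("feature_set must be a subset of the universe")
    M, N = len(universe), len(feature_set)
    rows = []
    for term, members in term_assignments.items():
        in_universe = set(members) & set(universe)
        if not in_universe:
            continue
        K = len(in_universe)
        x = len(in_universe & set(feature_set))
        p = float(stats.hypergeom.sf(x - 1, M, K, N))
        rows.append({"term": term, "overlap": x, "term_size": K, "set_size": N, "p": p})
    df = pd.DataFrame(rows, columns=["term", "overlap", "term_size", "set_size", "p"])
    if bh and len(df):
        from .diffexpr import adjust_bh

        df["q"] = adjust_bh(df["p"].to_numpy())
    return df


def module_size_summary(assignments: pd.Series) -> dict:
    """Bookkeeping: number of modules, assigned features, mean features per
    module (grey excluded)."""
    assigned = assignments[assignments != GREY]
    n_modules = assigned.nunique()
    return {
        "n_modules": int(n_modules),
        "n_assigned": int(len(assigned)),
        "mean_per_module": float(len(assigned)) / n_modules if n_modules else np.nan,
    }
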