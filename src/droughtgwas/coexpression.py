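"""Weighted gene co-expression network analysis, single-block.

Correlation-based adjacency raised to a soft-threshold power (default 9),
topological overlap transformation, average-linkage clustering of 1 - TOM
with a simplified dynamic tree cut (recursive branch-size descent, minimum
module size 50), eigengene summarization, eigengene-similarity module
merging, and module-trait correlation with the usual significance stars.

The dynamic cut here is a documented simplification of the published hybrid
algorithm: starting from the root of the dendrogram, a branch keeps being
split while both children still hold at least ``min_module_size`` leaves;
when splitting would orphan a small child, the branch is accepted as a
module.  Genes in accepted branches smaller than the minimum land in the
"grey" (unassigned) module.  Module labels follow the conventional
colour-name sequence in decreasing size order.

Differential expression is a declared simple stand-in for the off-the-shelf
negative-binomial callers: Welch's test on log2(FPKM + 1) with
Benjamini-Hochberg correction and |log2FC| / q cutoffs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import linkage
from statsmodels.stats.multitest import multipletests

from .datatypes import ExpressionMatrix

MODULE_COLORS = [
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "white", "skyblue", "saddlebrown", "steelblue",
    "paleturquoise", "violet", "darkolivegreen", "darkmagenta",
]

UNASSIGNED = "grey"


def filter_expression(
    expr: ExpressionMatrix, min_fpkm: float = 1.0, min_samples: int = 3
) -> ExpressionMatrix:
    """Keep genes expressed at >= min_fpkm in >= min_samples samples."""
    if min_fpkm < 0 or min_samples < 0:
        raise ValueError("thresholds must be non-negative")
    keep = (expr.values >= min_fpkm).sum(axis=1) >= min_samples
    if not keep.any():
        raise ValueError(
            f"no genes pass min_fpkm={min_fpkm} in >= {min_samples} samples"
        )
    planted = expr.planted_modules[keep] if expr.planted_modules is not None else None
    return ExpressionMatrix(values=expr.values[keep], design=expr.design, planted_modules=planted)


def adjacency_tom(
    expr_values: pd.DataFrame, power: float = 9.0, network: str = "unsigned"
) -> pd.DataFrame:
    """Soft-threshold adjacency and its topological overlap matrix.

    Unsigned: a_ij = |cor(x_i, x_j)|^power; signed: ((1 + cor)/2)^power.
    TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij), with
    connectivities k_i excluding the diagonal; TOM diagonal is set to 1.
    """
    if expr_values.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    X = expr_values.to_numpy(float)
    sd = X.std(axis=1)
    if (sd == 0).any():
        names = list(expr_values.index[sd == 0])
        raise ValueError(f"constant gene(s) reached adjacency: {names[:5]}")
    cor = np.corrcoef(X)
    if network == "unsigned":
        adj = np.abs(cor) ** power
    elif network == "signed":
        adj = ((1.0 + cor) / 2.0) ** power
    else:
        raise ValueError(f"unknown network type {network!r}")
    np.fill_diagonal(adj, 0.0)
    k = adj.sum(axis=1)
    numer = adj @ adj + adj
    denom = np.minimum.outer(k, k) + 1.0 - adj
    tom = numer / denom
    np.fill_diagonal(tom, 1.0)
    tom = np.clip((tom + tom.T) / 2.0, 0.0, 1.0)
    return pd.DataFrame(tom, index=expr_values.index, columns=expr_values.index)


@dataclass
class ModuleSet:
    labels: pd.Series             # gene -> module colour name ("grey" = unassigned)
    eigengenes: pd.DataFrame      # modules x samples, unit variance
    sizes: pd.Series              # module -> gene count


def _cut_tree(Z: np.ndarray, n_leaves: int, min_module_size: int) -> list[list[int]]:
    """Simplified dynamic cut by recursive branch descent.

    From the root downwards, a branch keeps being split while at least one
    child still holds ``min_module_size`` leaves; children below the minimum
    are shaved off as unassigned.  A branch whose both children are below
    the minimum is accepted as a module.  Over-splitting of one true module
    into sister branches is repaired later by eigengene merging.
    """
    children: dict[int, tuple[int, int]] = {
        n_leaves + i: (int(Z[i, 0]), int(Z[i, 1])) for i in range(len(Z))
    }

    def leaves(node: int) -> list[int]:
        stack, out = [node], []
        while stack:
            v = stack.pop()
            if v < n_leaves:
                out.append(v)
            else:
                stack.extend(children[v])
        return out

    modules: list[list[int]] = []
    root = n_leaves + len(Z) - 1 if len(Z) else None
    stack = [root] if root is not None else []
    while stack:
        node = stack.pop()
        node_leaves = leaves(node)
        if len(node_leaves) < min_module_size:
            continue  # shaved: unassigned
        if node < n_leaves:
            modules.append(node_leaves)
            continue
        left, right = children[node]
        n_left = len(leaves(left))
        n_right = len(leaves(right))
        if n_left >= min_module_size or n_right >= min_module_size:
            stack.extend([left, right])
        else:
            modules.append(node_leaves)
    return modules


def module_eigengenes(expr_values: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    """First principal component per module across samples, unit variance,
    sign-aligned with the module's mean standardized expression."""
    samples = expr_values.columns
    rows = {}
    for module in labels.unique():
        if module == UNASSIGNED:
            continue
        genes = labels.index[labels == module]
        X = expr_values.loc[genes].to_numpy(float)
        sd = X.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        Z = (X - X.mean(axis=1, keepdims=True)) / sd
        if Z.shape[0] == 1:
            e = Z[0]
        else:
            _, _, Vt = np.linalg.svd(Z, full_matrices=False)
            e = Vt[0]
        if np.corrcoef(e, Z.mean(axis=0))[0, 1] < 0:
            e = -e
        e_sd = e.std()
        rows[module] = e / e_sd if e_sd > 0 else e
    return pd.DataFrame(rows, index=samples).T


def detect_modules(
    tom: pd.DataFrame,
    expr_values: pd.DataFrame,
    min_module_size: int = 50,
    merge_cut: float = 0.25,
    kme_threshold: float = 0.5,
) -> ModuleSet:
    """Cluster 1 - TOM (average linkage), cut into modules, merge look-alikes.

    After the branch cut, unassigned genes with eigengene correlation (kME)
    of at least ``kme_threshold`` are rescued into their best module, and
    modules whose eigengene correlation exceeds 1 - ``merge_cut`` merge
    iteratively.  Labels are colour names assigned by decreasing size;
    remaining genes are "grey".
    """
    genes = list(tom.index)
    n = len(genes)
    if n < min_module_size:
        warnings.warn(f"{n} genes < min_module_size {min_module_size}: all unassigned")
        labels = pd.Series(UNASSIGNED, index=genes, name="module")
        return ModuleSet(labels=labels, eigengenes=pd.DataFrame(columns=expr_values.columns), sizes=pd.Series(dtype=int))

    from scipy.spatial.distance import squareform

    dist = 1.0 - tom.to_numpy(float)
    np.fill_diagonal(dist, 0.0)
    Z = linkage(squareform(dist, checks=False), method="average")
    branches = _cut_tree(Z, n, min_module_size)

    labels = pd.Series(UNASSIGNED, index=genes, name="module", dtype=object)
    accepted = [b for b in branches if len(b) >= min_module_size]
    accepted.sort(key=len, reverse=True)
    for i, branch in enumerate(accepted):
        name = MODULE_COLORS[i] if i < len(MODULE_COLORS) else f"module{i + 1}"
        labels.iloc[branch] = name

    # PAM-like rescue stage: an unassigned gene joins the module whose
    # eigengene it correlates with best, when that correlation (kME) is
    # strong enough.  This recovers genes shaved off by the branch descent.
    if accepted:
        me = module_eigengenes(expr_values, labels)
        grey_genes = labels.index[labels == UNASSIGNED]
        if len(grey_genes) and len(me):
            X = expr_values.loc[grey_genes].to_numpy(float)
            Xz = (X - X.mean(axis=1, keepdims=True))
            sd = Xz.std(axis=1, keepdims=True)
            sd[sd == 0] = 1.0
            Xz /= sd
            E = me.to_numpy(float)
            Ez = (E - E.mean(axis=1, keepdims=True)) / E.std(axis=1, keepdims=True)
            kme = (Xz @ Ez.T) / expr_values.shape[1]
            best = np.argmax(np.abs(kme), axis=1)
            strong = np.abs(kme[np.arange(len(grey_genes)), best]) >= kme_threshold
            for g, b, ok in zip(grey_genes, best, strong):
                if ok:
                    labels[g] = me.index[b]

    # Iterative eigengene-similarity merging.
    while True:
        current = [m for m in labels.unique() if m != UNASSIGNED]
        if len(current) < 2:
            break
        me = module_eigengenes(expr_values, labels)
        cor = np.corrcoef(me.to_numpy(float))
        np.fill_diagonal(cor, -np.inf)
        i, j = np.unravel_index(np.argmax(cor), cor.shape)
        if cor[i, j] <= 1.0 - merge_cut:
            break
        keep, drop = me.index[i], me.index[j]
        if (labels == drop).sum() > (labels == keep).sum():
            keep, drop = drop, keep
        labels[labels == drop] = keep

    # Re-rank colour names by final size.
    sizes = labels[labels != UNASSIGNED].value_counts()
    rename = {
        old: (MODULE_COLORS[i] if i < len(MODULE_COLORS) else f"module{i + 1}")
        for i, old in enumerate(sizes.index)
    }
    labels = labels.map(lambda m: rename.get(m, m))
    sizes = labels[labels != UNASSIGNED].value_counts()
    me = module_eigengenes(expr_values, labels)
    return ModuleSet(labels=labels, eigengenes=me, sizes=sizes)


def _stars(p: float) -> str:
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return "NS"


def module_trait_correlation(
    eigengenes: pd.DataFrame, sample_traits: pd.DataFrame
) -> pd.DataFrame:
    """Pearson r and t-test p per module x covariate, with star codes.

    P-values use the exact t transform t = r sqrt((n-2)/(1-r^2)) on n - 2
    degrees of freedom.  Zero-variance covariates are skipped with a warning.
    """
    n = eigengenes.shape[1]
    if n < 3:
        raise ValueError("need at least 3 samples")
    rows = []
    for cov in sample_traits.columns:
        x = sample_traits[cov].to_numpy(float)
        if np.std(x) == 0:
            warnings.warn(f"covariate {cov!r} has zero variance; skipped")
            continue
        for module in eigengenes.index:
            e = eigengenes.loc[module].to_numpy(float)
            r = float(np.corrcoef(e, x)[0, 1])
            r_clip = min(max(r, -1.0), 1.0)
            if abs(r_clip) == 1.0:
                p = 0.0
            else:
                t = r_clip * np.sqrt((n - 2) / (1.0 - r_clip**2))
                p = float(2.0 * stats.t.sf(abs(t), n - 2))
            rows.append({"module": module, "covariate": cov, "r": r, "p": p, "stars": _stars(p)})
    return pd.DataFrame(rows, columns=["module", "covariate", "r", "p", "stars"])


def differential_expression(
    expr: ExpressionMatrix,
    group_a: list[str],
    group_b: list[str],
    min_log2fc: float = 2.0,
    max_q: float = 0.01,
) -> pd.DataFrame:
    """Two-group DE stand-in: Welch's test on log2(FPKM+1) + BH correction.

    A gene is flagged differential iff |log2FC| > ``min_log2fc`` and
    BH-adjusted q < ``max_q``; direction is up when group A exceeds B.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs at least 2 samples")
    la = np.log2(expr.values[group_a].to_numpy(float) + 1.0)
    lb = np.log2(expr.values[group_b].to_numpy(float) + 1.0)
    log2fc = la.mean(axis=1) - lb.mean(axis=1)
    t, p = stats.ttest_ind(la, lb, axis=1, equal_var=False)
    p = np.where(np.isnan(p), 1.0, p)
    _, q, _, _ = multipletests(p, method="fdr_bh")
    de = (np.abs(log2fc) > min_log2fc) & (q < max_q)
    return pd.DataFrame(
        {
            "gene": expr.values.index,
            "log2fc": log2fc,
            "p": p,
            "q": q,
            "significant": de,
            "direction": np.where(log2fc > 0, "up", "down"),
        }
    ).set_index("gene")
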