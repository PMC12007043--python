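"""Fuzzy-membership comprehensive evaluation of drought tolerance.

The scoring chain is the standard comprehensive-evaluation procedure for
stress-tolerance panels:

1. relative trait value  TR = Xd / Xc  (stress over control mean),
2. drought tolerance index  DI = (YD/YP) * (YD/mean(YD))  from a yield trait,
3. PCA of the standardized indicator matrix -> composite-indicator scores and
   contribution-rate weights  w_i = P_i / sum(P_i),
4. min-max membership  mu(X_i) = (X_i - X_imin) / (X_imax - X_imin),
5. composite score  D = sum_i mu(X_i) * w_i  in [0, 1],

followed by Ward clustering of the membership vectors into tolerant /
medium / sensitive classes, and Table-style descriptive statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.decomposition import PCA

CLASS_NAMES_3 = ["tolerant", "medium", "sensitive"]


def relative_trait(pheno: pd.DataFrame, control_code: str = "CK") -> pd.DataFrame:
    """Per accession x trait x stress-treatment x environment ratio TR = Xd/Xc.

    Replicates are averaged within each cell before the ratio.  Cells whose
    control mean is zero are flagged undefined (TR = NaN) and a count is
    logged via a warning.
    """
    means = (
        pheno.groupby(["accession", "trait", "treatment", "environment"], sort=False)["value"]
        .mean()
        .rename("mean_value")
        .reset_index()
    )
    control = means[means["treatment"] == control_code].rename(columns={"mean_value": "control_mean"})
    stress = means[means["treatment"] != control_code]
    merged = stress.merge(
        control[["accession", "trait", "environment", "control_mean"]],
        on=["accession", "trait", "environment"],
        how="left",
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        tr = merged["mean_value"] / merged["control_mean"]
    undefined = (merged["control_mean"] == 0) | merged["control_mean"].isna()
    tr[undefined] = np.nan
    n_undef = int(undefined.sum())
    if n_undef:
        warnings.warn(f"{n_undef} relative-trait cells undefined (control mean 0 or absent)")
    out = merged[["accession", "trait", "treatment", "environment"]].copy()
    out["TR"] = tr.values
    return out


def drought_tolerance_index(
    pheno: pd.DataFrame,
    yield_trait: str = "yield",
    control_code: str = "CK",
    stress_code: str = "M",
    environment: str | None = None,
    di_formula: str = "ratio",
) -> pd.Series:
    """Per-accession drought tolerance index from a yield-like trait.

    Default ("ratio"): DI = (YD/YP) * (YD/mean(YD)), dimensionless.  The
    alternative literal reading DI = (YD/YP) * mean(YD) is selectable with
    ``di_formula="literal"``.
    """
    if di_formula not in {"ratio", "literal"}:
        raise ValueError(f"unknown di_formula {di_formula!r}")
    sub = pheno[pheno["trait"] == yield_trait]
    if environment is not None:
        sub = sub[sub["environment"] == environment]
    means = sub.groupby(["accession", "treatment"])["value"].mean().unstack("treatment")
    for code in (stress_code, control_code):
        if code not in means.columns:
            raise ValueError(f"treatment {code!r} absent for trait {yield_trait!r}")
    yd = means[stress_code]
    yp = means[control_code]
    yd_bar = yd.mean()
    if yd_bar == 0:
        raise ValueError("panel mean of stress yield is zero; DI undefined")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = yd / yp
    ratio[yp == 0] = np.nan
    if (yp == 0).any():
        warnings.warn(f"{int((yp == 0).sum())} accessions with zero control yield; DI undefined")
    if di_formula == "ratio":
        di = ratio * (yd / yd_bar)
    else:
        di = ratio * yd_bar
    return di.rename("DI")


@dataclass
class CompositeResult:
    scores: pd.DataFrame        # accessions x retained components (composite indicators)
    weights: np.ndarray         # contribution-rate weights, sum to 1
    explained_variance_ratio: np.ndarray


def composite_weights(
    indicator_matrix: pd.DataFrame,
    cum_var_target: float = 0.85,
) -> CompositeResult:
    """PCA of the standardized indicator matrix -> scores and weights.

    Components are retained until cumulative explained variance reaches
    ``cum_var_target`` (the crossing component included).  Weights are the
    retained components' explained-variance proportions renormalized to 1.
    """
    if indicator_matrix.shape[1] < 2 or indicator_matrix.shape[0] < 3:
        raise ValueError("need >= 3 accessions and >= 2 indicators")
    X = indicator_matrix.to_numpy(float)
    sd = X.std(axis=0, ddof=0)
    constant = np.flatnonzero(sd == 0)
    if constant.size:
        names = list(indicator_matrix.columns[constant])
        raise ValueError(f"constant indicator column(s): {names}")
    Z = (X - X.mean(axis=0)) / sd
    pca = PCA()
    scores = pca.fit_transform(Z)
    evr = pca.explained_variance_ratio_
    n_keep = int(np.searchsorted(np.cumsum(evr), cum_var_target) + 1)
    n_keep = min(n_keep, len(evr))
    # Drop numerically null components (perfect collinearity).
    n_keep = max(1, min(n_keep, int((evr > 1e-12).sum())))
    kept = evr[:n_keep]
    weights = kept / kept.sum()
    score_df = pd.DataFrame(
        scores[:, :n_keep],
        index=indicator_matrix.index,
        columns=[f"CI{i + 1}" for i in range(n_keep)],
    )
    return CompositeResult(scores=score_df, weights=weights, explained_variance_ratio=evr)


def membership(scores: pd.DataFrame) -> pd.DataFrame:
    """Min-max membership per indicator: mu = (X - min) / (max - min)."""
    lo = scores.min(axis=0)
    hi = scores.max(axis=0)
    flat = hi == lo
    if flat.any():
        raise ValueError(f"indicator(s) with max == min: {list(scores.columns[flat])}")
    return (scores - lo) / (hi - lo)


def d_value(mu: pd.DataFrame, weights: np.ndarray) -> pd.Series:
    """Composite drought-tolerance score D = sum_i mu_i * w_i."""
    weights = np.asarray(weights, float)
    if mu.shape[1] != weights.size:
        raise ValueError(f"{mu.shape[1]} membership columns vs {weights.size} weights")
    if abs(weights.sum() - 1.0) > 1e-10:
        raise ValueError("weights must sum to 1")
    return pd.Series(mu.to_numpy(float) @ weights, index=mu.index, name="D")


def classify_accessions(
    mu: pd.DataFrame,
    d: pd.Series,
    k: int = 3,
) -> pd.Series:
    """Ward/Euclidean clustering of membership vectors, cut at k clusters.

    Clusters are ranked by mean D and labelled tolerant (highest) / medium /
    sensitive (lowest) for k = 3, else ``class1`` (highest D) .. ``classk``.
    A fully degenerate panel (all D equal) is flagged with a warning.
    """
    if k > len(mu):
        raise ValueError(f"k={k} exceeds {len(mu)} accessions")
    if d.nunique() == 1:
        warnings.warn("all D values identical; classification is degenerate")
    Z = linkage(mu.to_numpy(float), method="ward")
    assign = fcluster(Z, t=k, criterion="maxclust")
    cluster_mean_d = d.groupby(assign).mean()
    order = cluster_mean_d.sort_values(ascending=False, kind="stable").index
    names = CLASS_NAMES_3 if k == 3 else [f"class{i + 1}" for i in range(k)]
    label_of = {cluster: names[rank] for rank, cluster in enumerate(order)}
    return pd.Series([label_of[c] for c in assign], index=mu.index, name="class")


def descriptive_stats(pheno: pd.DataFrame, value_col: str = "value") -> pd.DataFrame:
    """Per trait x treatment x environment summary in the usual table layout.

    Skewness is adjusted Fisher-Pearson and kurtosis is bias-corrected excess
    kurtosis (spreadsheet convention); CV = 100 * sd / mean.  Cells with
    fewer than 3 observations get missing skewness/kurtosis and a warning.
    """
    rows = []
    short = 0
    for (trait, treatment, env), grp in pheno.groupby(["trait", "treatment", "environment"], sort=True):
        x = grp[value_col].dropna().to_numpy(float)
        mean = x.mean() if x.size else np.nan
        sd = x.std(ddof=1) if x.size > 1 else np.nan
        if x.size >= 3:
            skew = stats.skew(x, bias=False)
            kurt = stats.kurtosis(x, bias=False)
        else:
            short += 1
            skew = kurt = np.nan
        rows.append(
            {
                "trait": trait,
                "treatment": treatment,
                "environment": env,
                "n": x.size,
                "mean": mean,
                "sd": sd,
                "max": x.max() if x.size else np.nan,
                "min": x.min() if x.size else np.nan,
                "skewness": skew,
                "kurtosis": kurt,
                "cv_percent": 100.0 * sd / mean if x.size > 1 and mean != 0 else (0.0 if sd == 0 else np.nan),
            }
        )
    if short:
        warnings.warn(f"{short} cells with < 3 observations; skewness/kurtosis omitted")
    return pd.DataFrame(rows)


def score_panel(
    pheno: pd.DataFrame,
    control_code: str = "CK",
    yield_trait: str = "yield",
    indicator_traits: list[str] | None = None,
    di_formula: str = "ratio",
    k: int = 3,
    cum_var_target: float = 0.85,
    impute: bool = False,
) -> pd.DataFrame:
    """Full scoring chain: TR -> DI -> PCA -> membership -> D -> classes.

    The indicator matrix holds, per accession: each relative trait per stress
    treatment (averaged over environments) plus DI per stress treatment.
    Accessions with missing indicator cells are dropped (or mean-imputed when
    ``impute=True``) with a logged report.
    """
    tr = relative_trait(pheno, control_code=control_code)
    if indicator_traits is not None:
        tr = tr[tr["trait"].isin(indicator_traits)]
    wide = (
        tr.groupby(["accession", "trait", "treatment"])["TR"]
        .mean()  # average environments
        .unstack(["trait", "treatment"])
    )
    wide.columns = [f"TR_{trait}_{treat}" for trait, treat in wide.columns]

    stress_codes = sorted(set(pheno["treatment"]) - {control_code})
    if yield_trait in set(pheno["trait"]):
        for code in stress_codes:
            di = drought_tolerance_index(
                pheno, yield_trait=yield_trait, control_code=control_code,
                stress_code=code, di_formula=di_formula,
            )
            wide[f"DI_{code}"] = di

    incomplete = wide.isna().any(axis=1)
    if incomplete.any():
        if impute:
            wide = wide.fillna(wide.mean())
            warnings.warn(f"mean-imputed indicator cells for {int(incomplete.sum())} accessions")
        else:
            warnings.warn(f"dropped {int(incomplete.sum())} accessions with missing indicators")
            wide = wide[~incomplete]

    comp = composite_weights(wide, cum_var_target=cum_var_target)
    mu = membership(comp.scores)
    d = d_value(mu, comp.weights)
    labels = classify_accessions(mu, d, k=k)

    out = mu.add_prefix("mu_")
    out.insert(0, "accession", out.index)
    for code in stress_codes:
        if f"DI_{code}" in wide.columns:
            out[f"DI_{code}"] = wide[f"DI_{code}"]
    out["D"] = d
    out["class"] = labels
    return out.reset_index(drop=True)
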