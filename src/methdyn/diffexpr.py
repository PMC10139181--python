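"""Negative-binomial Wald differential expression.

A deliberately small NB pipeline: median-of-ratios size factors,
method-of-moments gene dispersions shrunk toward a fitted mean-dispersion
trend, a Wald test on the difference of log2 group means (delta-method
standard error), and the Bonferroni + |log2FC| > 1 decision rule:
a gene is differentially expressed iff Bonferroni-adjusted p < 0.05 and
|log2 fold change| > 1.  No covariates, no LFC shrinkage, no independent
filtering.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

ALPHA = 0.05
LFC_THRESHOLD = 1.0
PSEUDOCOUNT = 0.5
DISP_CLIP = (1e-8, 10.0)


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios normalization factors, rescaled to geometric mean 1.

    Per sample, the median over genes of count / geometric-mean count,
    taken over genes whose geometric mean is nonzero.
    """
    mat = counts.to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        log_gm = np.mean(np.log(mat), axis=1)  # -inf for genes with any zero
    usable = np.isfinite(log_gm)
    if not usable.any():
        raise ValueError("no gene has all-nonzero counts; cannot normalize")
    ratios = np.log(mat[usable]) - log_gm[usable, None]
    log_sf = np.median(ratios, axis=0)
    log_sf -= log_sf.mean()  # geometric mean 1
    return pd.Series(np.exp(log_sf), index=counts.columns, name="size_factor")


def estimate_nb_dispersion(
    counts: pd.DataFrame,
    factors: pd.Series,
    groups: pd.Series | None = None,
    prior_weight: float = 4.0,
) -> pd.Series:
    """Per-gene NB dispersion alpha-tilde, shrunk toward a fitted trend.

    Method-of-moments on normalized counts: Var = mu + alpha mu^2 (pooled
    within groups when labels are given).  Gene estimates are shrunk on the
    log scale toward the trend alpha(mu) = a1/mu + a0 fitted by iteratively
    reweighted least squares over genes with positive raw estimates.
    Clipped to [1e-8, 10].
    """
    mat = counts.to_numpy(dtype=float) / factors.to_numpy()[None, :]
    n_genes, n_samples = mat.shape
    if groups is None:
        labels = np.zeros(n_samples, dtype=int)
    else:
        labels = pd.Categorical(groups.loc[counts.columns]).codes
    uniq = np.unique(labels)

    ss = np.zeros(n_genes)
    dof = 0
    mu_bar = mat.mean(axis=1)
    for g in uniq:
        cols = labels == g
        k = int(cols.sum())
        if k < 2:
            continue
        gm = mat[:, cols].mean(axis=1)
        ss += ((mat[:, cols] - gm[:, None]) ** 2).sum(axis=1)
        dof += k - 1
    if dof == 0:
        raise ValueError("dispersion estimation needs >= 2 replicates in a group")
    var = ss / dof
    with np.errstate(invalid="ignore", divide="ignore"):
        alpha_hat = (var - mu_bar) / np.maximum(mu_bar, 1e-300) ** 2
    alpha_hat = np.clip(alpha_hat, *DISP_CLIP)

    # mean-dispersion trend alpha(mu) = a0 + a1/mu (gamma-family style IRLS)
    ok = (mu_bar > 0) & (alpha_hat > DISP_CLIP[0] * 10)
    a0, a1 = 1e-3, 1.0
    if ok.sum() >= 10:
        x = 1.0 / mu_bar[ok]
        y = alpha_hat[ok]
        w = np.ones(ok.sum())
        for _ in range(8):
            X = np.column_stack([np.ones_like(x), x])
            beta, *_ = np.linalg.lstsq(X * w[:, None], y * w, rcond=None)
            fit = np.maximum(X @ beta, 1e-8)
            w = 1.0 / fit  # gamma-like weights damp high-dispersion outliers
        a0, a1 = float(max(beta[0], 1e-8)), float(max(beta[1], 0.0))
    trend = np.clip(a0 + a1 / np.maximum(mu_bar, 1e-300), *DISP_CLIP)

    lam = prior_weight / (prior_weight + dof)
    log_shrunk = lam * np.log(trend) + (1 - lam) * np.log(alpha_hat)
    out = np.clip(np.exp(log_shrunk), *DISP_CLIP)
    out[~np.isfinite(out)] = trend[~np.isfinite(out)]
    return pd.Series(out, index=counts.index, name="dispersion")


def nb_wald_test(
    counts: pd.DataFrame,
    groups: pd.Series,
    contrast: tuple[str, str],
    factors: pd.Series | None = None,
    dispersions: pd.Series | None = None,
    pseudocount: float = PSEUDOCOUNT,
) -> pd.DataFrame:
    """Per-gene Wald test between the two groups of ``contrast``.

    log2FC = log2((mean normalized A + pc) / (mean normalized B + pc));
    the SE comes from the delta-method NB variance of each group's log mean.
    Genes with zero counts in every sample are excluded from testing (and
    from the Bonferroni family).
    """
    group_a, group_b = contrast
    cols_a = [s for s in counts.columns if groups.loc[s] == group_a]
    cols_b = [s for s in counts.columns if groups.loc[s] == group_b]
    if not cols_a or not cols_b:
        raise ValueError(f"contrast {contrast} has an empty group")
    sub = counts[cols_a + cols_b]
    if factors is None:
        factors = size_factors(sub)
    if dispersions is None:
        sub_groups = pd.Series(
            [group_a] * len(cols_a) + [group_b] * len(cols_b), index=cols_a + cols_b
        )
        dispersions = estimate_nb_dispersion(sub, factors, sub_groups)

    norm = sub.to_numpy(dtype=float) / factors.loc[sub.columns].to_numpy()[None, :]
    alpha = dispersions.loc[sub.index].to_numpy()
    nonzero = sub.to_numpy().sum(axis=1) > 0

    def group_stats_(cols):
        idx = [sub.columns.get_loc(c) for c in cols]
        mean = norm[:, idx].mean(axis=1)
        s = factors.loc[cols].to_numpy()
        # Var(K_i/s_i) = mu/s_i + alpha mu^2 under NB(mu s_i, alpha)
        var_mean = (mean[:, None] / s[None, :] + alpha[:, None] * mean[:, None] ** 2).sum(
            axis=1
        ) / len(cols) ** 2
        return mean, var_mean

    mean_a, var_a = group_stats_(cols_a)
    mean_b, var_b = group_stats_(cols_b)
    log2fc = np.log2(mean_a + pseudocount) - np.log2(mean_b + pseudocount)
    ln2sq = np.log(2.0) ** 2
    se = np.sqrt(
        var_a / ((mean_a + pseudocount) ** 2 * ln2sq)
        + var_b / ((mean_b + pseudocount) ** 2 * ln2sq)
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        wald = np.where(se > 0, log2fc / np.maximum(se, 1e-300), 0.0)
    p = 2 * stats.norm.sf(np.abs(wald))

    out = pd.DataFrame(
        {
            "gene_id": sub.index,
            "base_mean": norm.mean(axis=1),
            "log2fc": log2fc,
            "se_log2fc": se,
            "wald_stat": wald,
            "p_value": p,
            "tested": nonzero,
        }
    ).set_index("gene_id")
    out.loc[~out["tested"], ["log2fc", "se_log2fc", "wald_stat", "p_value"]] = np.nan
    out.attrs["contrast"] = (group_a, group_b)
    return out


def call_degs(
    results: pd.DataFrame, alpha: float = ALPHA, lfc: float = LFC_THRESHOLD
) -> pd.DataFrame:
    """Apply the Bonferroni + fold-change rule and count DEGs per direction.

    p_adj = min(1, p * G) over the G tested genes; is_deg iff p_adj < alpha
    and |log2fc| > lfc.  The per-direction counts live in
    ``result.attrs['n_up'] / ['n_down']``.
    """
    out = results.copy()
    tested = out["tested"].to_numpy() if "tested" in out else np.ones(len(out), bool)
    n_tested = int(tested.sum())
    out["p_adj"] = np.nan
    if n_tested:
        out.loc[tested, "p_adj"] = np.minimum(
            1.0, out.loc[tested, "p_value"] * n_tested
        )
    out["is_deg"] = (
        tested
        & (out["p_adj"] < alpha).fillna(False).to_numpy()
        & (out["log2fc"].abs() > lfc).fillna(False).to_numpy()
    )
    out.attrs.update(results.attrs)
    out.attrs["n_up"] = int((out["is_deg"] & (out["log2fc"] > 0)).sum())
    out.attrs["n_down"] = int((out["is_deg"] & (out["log2fc"] < 0)).sum())
    return out


def read_counts(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.astype(int)


def read_sample_sheet(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t")
    return df.set_index("sample")["group"]
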