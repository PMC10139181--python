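"""Differentially methylated region detection.

A two-group comparison runs, per context stream (CG, CHG and CHH sites are
never mixed):

1. align cytosine reports across samples; a site is testable when it has
   depth >= 1 in every sample of both groups;
2. smooth methylation fractions per group with a coverage-weighted moving
   average over a +-250 bp window (counts aggregated within the window);
3. estimate a per-site beta-binomial dispersion by the method of moments
   and shrink it on the log scale toward the genome-wide mean, with the
   prior dominating as per-site depth falls;
4. Wald-test the smoothed group means, with the variance of each group mean
   taken as that of the coverage-weighted window estimator under the
   beta-binomial model: Var = mu(1-mu) * sum_i n_i (1 + (n_i - 1) phi) / N^2
   summed over samples and window sites, N the window total depth;
5. merge runs of significant, sign-consistent sites into regions.

The beta-binomial is parameterized by mean mu and dispersion phi with
Var(X) = n mu (1-mu) (1 + (n-1) phi); phi = 0 degenerates to the binomial.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

#: caller defaults
P_THRESHOLD = 1e-5
MIN_LEN = 50
MIN_SITES = 3
PCT_SIG = 0.5
MERGE_GAP = 100
SMOOTH_WINDOW = 500
PHI_CLIP = (1e-6, 0.999)
SHRINK_DEPTH = 2000.0  # prior weight, in units of per-site total depth


@dataclass
class DmrCallerConfig:
    window: int = SMOOTH_WINDOW
    p_threshold: float = P_THRESHOLD
    min_len: int = MIN_LEN
    min_sites: int = MIN_SITES
    pct_sig: float = PCT_SIG
    merge_gap: int = MERGE_GAP
    min_depth: int = 1  # per-sample depth required for a site to be tested
    true_methylated_only: bool = False


# -- alignment -------------------------------------------------------------


def align_counts(
    reports_a: dict[str, pd.DataFrame],
    reports_b: dict[str, pd.DataFrame],
    context: str = "CG",
    min_depth: int = 1,
    exclude_chroms: tuple[str, ...] = ("lambda",),
) -> pd.DataFrame:
    """Site-by-sample methylated/total count matrix for one context.

    Returns a frame indexed by (chrom, pos, strand) with columns
    ``m:<sample>`` and ``n:<sample>``, keeping sites with depth >=
    ``min_depth`` in every sample of both groups.
    """
    pieces = []
    for name, rep in {**reports_a, **reports_b}.items():
        sub = rep[(rep["context"] == context) & ~rep["chrom"].isin(exclude_chroms)]
        piece = sub.set_index(["chrom", "pos", "strand"])[["m", "u"]]
        piece = piece.rename(columns={"m": f"m:{name}", "u": f"u:{name}"})
        pieces.append(piece)
    merged = pd.concat(pieces, axis=1, join="inner").sort_index()
    out = pd.DataFrame(index=merged.index)
    keep = np.ones(len(merged), dtype=bool)
    for name in list(reports_a) + list(reports_b):
        n = merged[f"m:{name}"].to_numpy() + merged[f"u:{name}"].to_numpy()
        out[f"m:{name}"] = merged[f"m:{name}"].to_numpy()
        out[f"n:{name}"] = n
        keep &= n >= min_depth
    out = out[keep]
    out.attrs["samples_a"] = list(reports_a)
    out.attrs["samples_b"] = list(reports_b)
    return out


# -- smoothing -------------------------------------------------------------


def smooth_methylation(
    pos: np.ndarray, m: np.ndarray, n: np.ndarray, window: int = SMOOTH_WINDOW
) -> np.ndarray:
    """Coverage-weighted moving-average methylation fraction.

    For each site, the fraction sum(m)/sum(n) over all sites within
    +-window/2 bp on the same chromosome.  Isolated sites (alone in their
    window) are returned unchanged; ``window=0`` disables smoothing.
    ``m``/``n`` may be per-sample matrices (sites x samples) or vectors;
    totals are summed over samples first.
    """
    m = np.atleast_2d(np.asarray(m, dtype=float).T).T.sum(axis=1)
    n = np.atleast_2d(np.asarray(n, dtype=float).T).T.sum(axis=1)
    if window <= 0:
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n > 0, m / np.maximum(n, 1), np.nan)
    order = np.argsort(pos, kind="stable")
    inv = np.argsort(order, kind="stable")
    p_sorted = np.asarray(pos)[order]
    agg = _window_aggregate(p_sorted, np.column_stack([m[order], n[order]]), window)
    with np.errstate(invalid="ignore", divide="ignore"):
        sm = np.where(agg[:, 1] > 0, agg[:, 0] / np.maximum(agg[:, 1], 1e-300), np.nan)
    return sm[inv]


def _window_aggregate(sorted_pos, mat, window):
    """Window sums for each column of ``mat`` (sites x k)."""
    half = window / 2.0
    lo = np.searchsorted(sorted_pos, sorted_pos - half, side="left")
    hi = np.searchsorted(sorted_pos, sorted_pos + half, side="right")
    csum = np.vstack([np.zeros((1, mat.shape[1])), np.cumsum(mat, axis=0)])
    return csum[hi] - csum[lo]


# -- dispersion ------------------------------------------------------------


def estimate_dispersion(
    m: np.ndarray,
    n: np.ndarray,
    groups: np.ndarray,
    shrink_depth: float = SHRINK_DEPTH,
) -> np.ndarray:
    """Per-site shrunk beta-binomial dispersion phi-tilde.

    ``m``/``n`` are sites x samples count matrices, ``groups`` labels the
    columns.  A method-of-moments estimate from replicate residuals around
    the group means is shrunk, on the log scale, toward the genome-wide mean
    of log-dispersions; the prior weight corresponds to ``shrink_depth``
    units of per-site total depth, so shallow sites are pulled harder.
    Sites without a usable estimate take the prior mean.  Clipped to
    [1e-6, 0.999].
    """
    m = np.asarray(m, dtype=float)
    n = np.asarray(n, dtype=float)
    groups = np.asarray(groups)
    n_sites, n_samples = m.shape
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, m / np.maximum(n, 1e-300), np.nan)

    num = np.zeros(n_sites)
    den = np.zeros(n_sites)
    n_grp = 0
    for g in np.unique(groups):
        cols = groups == g
        n_grp += 1
        ng = n[:, cols]
        pg = p[:, cols]
        wsum = np.nansum(ng, axis=1)
        mu = np.nansum(m[:, cols], axis=1) / np.maximum(wsum, 1e-300)
        v = mu * (1 - mu)
        resid2 = (pg - mu[:, None]) ** 2
        with np.errstate(invalid="ignore", divide="ignore"):
            contrib = resid2 / np.maximum(v, 1e-12)[:, None] - 1.0 / np.maximum(ng, 1e-300)
        valid = (ng > 0) & np.isfinite(contrib) & (v > 1e-12)[:, None]
        num += np.where(valid, contrib, 0.0).sum(axis=1)
        den += np.where(valid, (ng - 1) / np.maximum(ng, 1e-300), 0.0).sum(axis=1)

    k = (n > 0).sum(axis=1)
    dof = np.maximum(k - n_grp, 0)
    usable = (den > 0) & (dof > 0)
    phi_hat = np.full(n_sites, np.nan)
    # small-sample inflation: residuals around fitted group means lose n_grp dof
    phi_hat[usable] = (num[usable] / den[usable]) * (k[usable] / np.maximum(dof[usable], 1))

    # genome-wide prior: pooled moment estimate (stable, unlike a mean of
    # noisy per-site logs, many of which clip at zero), with the same
    # residual-dof inflation applied before pooling
    infl = np.where(dof > 0, k / np.maximum(dof, 1), 0.0)
    phi_global = (
        float((num[usable] * infl[usable]).sum() / den[usable].sum())
        if usable.any()
        else 1e-2
    )
    phi_global = float(np.clip(phi_global, *PHI_CLIP))
    # floor per-site estimates well below the prior before taking logs so a
    # handful of zero-variance replicate draws cannot collapse the estimate
    phi_hat = np.clip(phi_hat, max(PHI_CLIP[0], phi_global / 20), PHI_CLIP[1])

    depth = n.sum(axis=1)
    lam = shrink_depth / (shrink_depth + depth)  # prior weight on the log scale
    with np.errstate(invalid="ignore"):
        log_shrunk = np.where(
            usable, lam * np.log(phi_global) + (1 - lam) * np.log(phi_hat),
            np.log(phi_global),
        )
    return np.clip(np.exp(log_shrunk), *PHI_CLIP)


# -- Wald test -------------------------------------------------------------


def wald_site_test(
    aligned: pd.DataFrame,
    window: int = SMOOTH_WINDOW,
    context: str = "CG",
    shrink_depth: float = SHRINK_DEPTH,
) -> pd.DataFrame:
    """Per-site Wald statistics for one aligned two-group count frame.

    Returns chrom, pos, strand, smoothed group means mu1/mu2, shrunk phi,
    the raw group fractions, w and p_value.  Sites in ``aligned`` must all
    share one context.  w = (mu1 - mu2) / sqrt(V1 + V2), two-sided normal p.
    """
    samples_a = aligned.attrs["samples_a"]
    samples_b = aligned.attrs["samples_b"]
    all_samples = samples_a + samples_b
    m = aligned[[f"m:{s}" for s in all_samples]].to_numpy(dtype=float)
    n = aligned[[f"n:{s}" for s in all_samples]].to_numpy(dtype=float)
    groups = np.array([0] * len(samples_a) + [1] * len(samples_b))
    phi = estimate_dispersion(m, n, groups, shrink_depth=shrink_depth)

    idx = aligned.index.to_frame(index=False)
    chrom_arr = idx["chrom"].to_numpy()
    pos_arr = idx["pos"].to_numpy()

    mu = np.zeros((len(aligned), 2))
    var = np.zeros((len(aligned), 2))
    raw = np.zeros((len(aligned), 2))
    for gi, cols in enumerate((groups == 0, groups == 1)):
        mg = m[:, cols]
        ng = n[:, cols]
        raw[:, gi] = mg.sum(axis=1) / np.maximum(ng.sum(axis=1), 1e-300)
        msum = np.zeros(len(aligned))
        nsum = np.zeros(len(aligned))
        qsum = np.zeros(len(aligned))  # sum of n^2 terms for the variance
        for chrom in pd.unique(chrom_arr):
            sel = np.flatnonzero(chrom_arr == chrom)
            order = sel[np.argsort(pos_arr[sel], kind="stable")]
            spos = pos_arr[order]
            mat = np.column_stack(
                [
                    mg[order].sum(axis=1),
                    ng[order].sum(axis=1),
                    (ng[order] * (ng[order] - 1)).sum(axis=1),
                ]
            )
            agg = (
                _window_aggregate(spos, mat, window) if window > 0 else mat
            )
            msum[order], nsum[order], qsum[order] = agg[:, 0], agg[:, 1], agg[:, 2]
        mu_g = msum / np.maximum(nsum, 1e-300)
        mu[:, gi] = mu_g
        # variance floor: keep mu(1-mu) away from 0 at extreme fractions
        mu_v = np.clip(mu_g, 1.0 / (nsum + 2), 1.0 - 1.0 / (nsum + 2))
        var[:, gi] = mu_v * (1 - mu_v) * (nsum + phi * qsum) / np.maximum(nsum, 1e-300) ** 2

    diff = mu[:, 0] - mu[:, 1]
    se = np.sqrt(var.sum(axis=1))
    w = np.where(se > 0, diff / np.maximum(se, 1e-300), 0.0)
    p = 2 * stats.norm.sf(np.abs(w))
    return pd.DataFrame(
        {
            "chrom": chrom_arr,
            "pos": pos_arr,
            "strand": idx["strand"].to_numpy(),
            "mu1": mu[:, 0],
            "mu2": mu[:, 1],
            "raw1": raw[:, 0],
            "raw2": raw[:, 1],
            "phi": phi,
            "w": w,
            "p_value": p,
            "context": context,
        }
    )


# -- region calling --------------------------------------------------------


def _max_sum_segment(scores: np.ndarray) -> tuple[int, int]:
    """Indices (inclusive) of the maximum-sum contiguous stretch (Kadane).

    Falls back to the single best element when every score is negative.
    """
    best_lo = best_hi = 0
    best = -np.inf
    cur = 0.0
    cur_lo = 0
    for i, s in enumerate(np.asarray(scores, dtype=float)):
        if cur <= 0:
            cur = s
            cur_lo = i
        else:
            cur += s
        if cur > best:
            best = cur
            best_lo, best_hi = cur_lo, i
    return best_lo, best_hi


@dataclass
class Dmr:
    """A called differentially methylated region (1-based inclusive)."""

    chrom: str
    start: int
    end: int
    n_sites: int
    n_significant: int
    mean_meth1: float
    mean_meth2: float
    meth_diff: float
    area_stat: float
    context: str
    direction: str

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def call_dmrs(
    site_results: pd.DataFrame,
    p_threshold: float = P_THRESHOLD,
    min_len: int = MIN_LEN,
    min_sites: int = MIN_SITES,
    pct_sig: float = PCT_SIG,
    merge_gap: int = MERGE_GAP,
    trim_frac: float = 0.5,
    group_labels: tuple[str, str] = ("A", "B"),
) -> pd.DataFrame:
    """Merge significant, sign-consistent sites into regions.

    Runs are maximal chains of significant same-sign sites with successive
    gaps <= ``merge_gap`` bp; a run qualifies when its span >= ``min_len``,
    it contains >= ``min_sites`` tested sites and >= ``pct_sig`` of those
    are significant.  Because smoothing lets sites just outside a true
    region borrow its signal, run boundaries are refined on the raw
    (unsmoothed) per-site differences: the region is the maximum-sum
    contiguous stretch of sites scoring ``direction * raw_diff - tau``,
    with ``tau`` equal to ``trim_frac`` times the run's smoothed plateau
    difference — the changepoint where the local mean difference falls
    below half the plateau.  Region methylation summaries come from the
    raw pooled counts.  Contexts are processed separately.
    """
    records = []
    for (chrom, context), sub in site_results.groupby(["chrom", "context"], sort=True):
        sub = sub.sort_values("pos")
        pos = sub["pos"].to_numpy()
        p = sub["p_value"].to_numpy()
        w = sub["w"].to_numpy()
        sig = (p < p_threshold) & (w != 0)
        if not sig.any():
            continue
        sig_idx = np.flatnonzero(sig)
        runs: list[list[int]] = [[sig_idx[0]]]
        for i in sig_idx[1:]:
            prev = runs[-1][-1]
            if np.sign(w[i]) == np.sign(w[prev]) and pos[i] - pos[prev] <= merge_gap:
                runs[-1].append(i)
            else:
                runs.append([i])
        # merge adjacent same-sign runs whose spans touch or overlap
        merged: list[list[int]] = []
        for run in runs:
            if (
                merged
                and np.sign(w[run[0]]) == np.sign(w[merged[-1][-1]])
                and pos[run[0]] - pos[merged[-1][-1]] <= merge_gap
            ):
                merged[-1].extend(run)
            else:
                merged.append(run)
        raw_diff = sub["raw1"].to_numpy() - sub["raw2"].to_numpy()
        smooth_diff = sub["mu1"].to_numpy() - sub["mu2"].to_numpy()
        for run in merged:
            direction = np.sign(w[run[0]])
            members_idx = np.arange(run[0], run[-1] + 1)
            plateau = float(np.max(direction * smooth_diff[members_idx]))
            # the smoothed plateau is diluted when the region is shorter than
            # the window; the median raw difference over significant sites is
            # the sharper effect estimate of the two
            effect = max(plateau, float(np.median(direction * raw_diff[run])), 0.0)
            tau = trim_frac * effect
            scores = direction * raw_diff[members_idx] - tau
            lo, hi = _max_sum_segment(scores)
            run = [i for i in run if members_idx[lo] <= i <= members_idx[hi]]
            if not run:
                continue
            start, end = int(pos[run[0]]), int(pos[run[-1]])
            members = (pos >= start) & (pos <= end)
            n_members = int(members.sum())
            n_sig_members = int((sig & members & (np.sign(w) == np.sign(w[run[0]]))).sum())
            if end - start + 1 < min_len or n_members < min_sites:
                continue
            if n_sig_members / n_members < pct_sig:
                continue
            mm = sub[members]
            # unweighted mean of per-site pooled raw fractions
            mean1 = float(mm["raw1"].mean())
            mean2 = float(mm["raw2"].mean())
            diff = mean1 - mean2
            records.append(
                Dmr(
                    chrom=str(chrom),
                    start=start,
                    end=end,
                    n_sites=n_members,
                    n_significant=n_sig_members,
                    mean_meth1=mean1,
                    mean_meth2=mean2,
                    meth_diff=diff,
                    area_stat=float(mm["w"].sum()),
                    context=str(context),
                    direction=(
                        f"higher at {group_labels[0]}"
                        if diff > 0
                        else f"higher at {group_labels[1]}"
                    ),
                )
            )
    if not records:
        return pd.DataFrame(
            columns=[
                "chrom", "start", "end", "length", "n_sites", "n_significant",
                "mean_meth1", "mean_meth2", "meth_diff", "area_stat", "context",
                "direction",
            ]
        )
    df = pd.DataFrame([vars(r) | {"length": r.length} for r in records])
    cols = ["chrom", "start", "end", "length", "n_sites", "n_significant",
            "mean_meth1", "mean_meth2", "meth_diff", "area_stat", "context",
            "direction"]
    return df[cols].sort_values(["chrom", "start"]).reset_index(drop=True)


def test_contrast(
    reports_a: dict[str, pd.DataFrame],
    reports_b: dict[str, pd.DataFrame],
    config: DmrCallerConfig | None = None,
    contexts: tuple[str, ...] = ("CG", "CHG", "CHH"),
    group_labels: tuple[str, str] = ("A", "B"),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """End-to-end two-group DMR scan; returns (site results, DMR table)."""
    cfg = config or DmrCallerConfig()
    site_frames = []
    for context in contexts:
        aligned = align_counts(
            reports_a, reports_b, context=context, min_depth=cfg.min_depth
        )
        if len(aligned) == 0:
            continue
        site_frames.append(wald_site_test(aligned, window=cfg.window, context=context))
    if not site_frames:
        empty = pd.DataFrame()
        return empty, call_dmrs(pd.DataFrame(columns=["chrom", "pos", "context",
                                                      "p_value", "w", "raw1", "raw2"]))
    sites = pd.concat(site_frames, ignore_index=True)
    dmrs = call_dmrs(
        sites,
        p_threshold=cfg.p_threshold,
        min_len=cfg.min_len,
        min_sites=cfg.min_sites,
        pct_sig=cfg.pct_sig,
        merge_gap=cfg.merge_gap,
        group_labels=group_labels,
    )
    return sites, dmrs


# -- derived quantities ----------------------------------------------------


def dmr_methylation_log2fc(mean_meth1: float, mean_meth2: float, eps: float = 0.01) -> float:
    """log2 of the (pseudo-counted) group methylation ratio."""
    return float(np.log2((mean_meth1 + eps) / (mean_meth2 + eps)))


def annotate_dmrs(dmrs: pd.DataFrame, catalog) -> pd.DataFrame:
    """Expand a DMR table to one row per (DMR, associated gene, region label).

    Region labels are the table-style set (Promoter, Utr5, Exon, Intron,
    Utr3, TSS, TES); DMRs associated with no gene are dropped.  Coordinates
    in the DMR table are 1-based inclusive.
    """
    from .annotation import associate_gene, region_labels_for_gene

    rows = []
    for i, row in dmrs.iterrows():
        query = (row["chrom"], int(row["start"]) - 1, int(row["end"]))
        for gid in sorted(associate_gene(query, catalog)):
            gene = catalog.genes[gid]
            labels = region_labels_for_gene(query, gene, catalog) or ["Intergenic"]
            for label in labels:
                rows.append(
                    dict(row)
                    | {
                        "dmr_index": i,
                        "gene_id": gid,
                        "gene_name": gene.gene_name,
                        "region": label,
                        "log2fc_methylation": dmr_methylation_log2fc(
                            row["mean_meth1"], row["mean_meth2"]
                        ),
                    }
                )
    if not rows:
        return pd.DataFrame(
            columns=list(dmrs.columns)
            + ["dmr_index", "gene_id", "gene_name", "region", "log2fc_methylation"]
        )
    return pd.DataFrame(rows)


def summarize_dmrs(dmrs: pd.DataFrame, catalog=None) -> dict:
    """Descriptive statistics of a DMR table.

    Length quantiles and the fraction of regions at or below 200 bp, mean
    site count, per-chromosome and per-context counts, and (when a catalog
    is given) per-feature intersection percentages and per-gene DMR lists
    split by direction.
    """
    out: dict = {"n_dmrs": int(len(dmrs))}
    if len(dmrs) == 0:
        return out
    lengths = dmrs["length"].to_numpy()
    out["length_median"] = float(np.median(lengths))
    out["length_quantiles"] = {
        q: float(np.quantile(lengths, q)) for q in (0.25, 0.5, 0.75, 0.97)
    }
    out["frac_length_le_200"] = float(np.mean(lengths <= 200))
    out["mean_sites_per_dmr"] = float(dmrs["n_sites"].mean())
    out["per_chromosome"] = dmrs.groupby("chrom").size().to_dict()
    out["per_context"] = dmrs.groupby("context").size().to_dict()
    if catalog is not None:
        from .annotation import FEATURE_LABELS, assign_features

        feature_counts = dict.fromkeys(FEATURE_LABELS, 0)
        for _, row in dmrs.iterrows():
            hit = assign_features(
                (row["chrom"], int(row["start"]) - 1, int(row["end"])), catalog
            )
            for label in hit.labels:
                feature_counts[label] += 1
        out["feature_counts"] = feature_counts
        out["feature_pct"] = {
            k: 100.0 * v / len(dmrs) for k, v in feature_counts.items()
        }
        annotated = annotate_dmrs(dmrs, catalog)
        per_gene: dict[str, dict[str, list[int]]] = {}
        for _, row in annotated.iterrows():
            d = per_gene.setdefault(row["gene_id"], {})
            d.setdefault(row["direction"], []).append(int(row["dmr_index"]))
        out["per_gene_direction"] = per_gene
    return out


def write_dmrs(dmrs: pd.DataFrame, tsv_path, bed_path=None) -> None:
    dmrs.to_csv(tsv_path, sep="\t", index=False)
    if bed_path is not None:
        with open(bed_path, "w") as fh:
            for i, row in dmrs.iterrows():
                fh.write(
                    f"{row['chrom']}\t{int(row['start']) - 1}\t{int(row['end'])}"
                    f"\tdmr_{i}\t{row['meth_diff']:.3f}\t+\n"
                )
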