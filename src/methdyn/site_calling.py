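"""Per-cytosine methylation calling.

A cytosine is a "true methylated site" in a sample when a one-tailed
binomial test of its methylated count against H0: P(methylated read) = 0.5
survives Benjamini-Hochberg correction at FDR <= 0.01, at sequencing depth
>= 5.  The test direction is excess methylation, P(X >= m | n, 0.5) — the
only direction consistent with calling *methylated* sites.  BH is applied
within each sample over all sites meeting the depth threshold (contexts
pooled); a pooled-across-samples mode is available via
:func:`call_true_methylated_pooled`.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .synthetic import CONTROL_CHROM, REPORT_COLUMNS

VALID_CONTEXTS = frozenset({"CG", "CHG", "CHH"})


class ReportFormatError(ValueError):
    """A cytosine report row violates the 7-column CX dialect."""


def read_cytosine_report(path) -> pd.DataFrame:
    """Parse a 7-column CX-style cytosine report.

    Columns: chrom, 1-based position, strand, methylated count,
    unmethylated count, context (CG/CHG/CHH), trinucleotide.  Zero-depth
    sites are retained.  Malformed rows raise with their line number.
    """
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            names=REPORT_COLUMNS,
            dtype={"chrom": str, "strand": str, "context": str, "tri": str},
        )
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=REPORT_COLUMNS)

    for col in ("pos", "m", "u"):
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() | (np.mod(converted.fillna(0.5), 1) != 0)
        if bad.any():
            line = int(np.flatnonzero(bad.to_numpy())[0]) + 1
            raise ReportFormatError(f"line {line}: non-integer value in column {col!r}")
        df[col] = converted.astype(int)
    for col, check, msg in (
        ("pos", df["pos"] >= 1, "position must be >= 1"),
        ("m", df["m"] >= 0, "negative methylated count"),
        ("u", df["u"] >= 0, "negative unmethylated count"),
        ("strand", df["strand"].isin(["+", "-"]), "strand must be + or -"),
        ("context", df["context"].isin(VALID_CONTEXTS), "bad context token"),
    ):
        ok = check.to_numpy()
        if not ok.all():
            line = int(np.flatnonzero(~ok)[0]) + 1
            raise ReportFormatError(f"line {line}: {msg}")
    return df


def binomial_site_test(m, u):
    """One-tailed exact binomial p-value P(X >= m | n = m + u, p0 = 0.5).

    Vectorized over arrays; raises on zero-depth input.
    """
    m = np.asarray(m)
    u = np.asarray(u)
    n = m + u
    if np.any(n < 1):
        raise ValueError("binomial test undefined at zero depth")
    p = stats.binom.sf(m - 1, n, 0.5)
    return float(p) if p.ndim == 0 else p


def call_true_methylated(
    sites: pd.DataFrame,
    min_depth: int = 5,
    fdr: float = 0.01,
    p0: float = 0.5,
) -> pd.DataFrame:
    """Flag true methylated sites in one sample.

    Adds depth, meth_fraction, p_value, q_value (BH over all sites with
    depth >= ``min_depth`` in this sample) and is_true_methylated columns.
    Sites below the depth threshold are never called and carry NaN q-values.
    ``p0`` overrides the 0.5 null (e.g. a conversion-failure-based null).
    """
    out = sites.copy()
    depth = out["m"] + out["u"]
    out["depth"] = depth
    with np.errstate(invalid="ignore"):
        out["meth_fraction"] = np.where(depth > 0, out["m"] / depth.replace(0, 1), np.nan)
    out["p_value"] = np.nan
    tested = (depth >= min_depth).to_numpy()
    covered = (depth >= 1).to_numpy()
    out.loc[covered, "p_value"] = stats.binom.sf(
        out.loc[covered, "m"] - 1, depth[covered], p0
    )
    out["q_value"] = np.nan
    if tested.any():
        _, q, _, _ = multipletests(
            out.loc[tested, "p_value"].to_numpy(), method="fdr_bh"
        )
        out.loc[tested, "q_value"] = np.clip(q, 0.0, 1.0)
    out["is_true_methylated"] = tested & (out["q_value"] <= fdr).fillna(False).to_numpy()
    return out


def call_true_methylated_pooled(
    sites_by_sample: dict[str, pd.DataFrame],
    min_depth: int = 5,
    fdr: float = 0.01,
    p0: float = 0.5,
) -> dict[str, pd.DataFrame]:
    """Variant correcting across all samples jointly (one BH family)."""
    augmented = {}
    p_all, keys = [], []
    for sample, sites in sites_by_sample.items():
        df = call_true_methylated(sites, min_depth=min_depth, fdr=fdr, p0=p0)
        augmented[sample] = df
        tested = df["depth"] >= min_depth
        p_all.append(df.loc[tested, "p_value"].to_numpy())
        keys.append((sample, tested))
    if p_all and sum(len(p) for p in p_all):
        _, q, _, _ = multipletests(np.concatenate(p_all), method="fdr_bh")
        offset = 0
        for (sample, tested), p in zip(keys, p_all):
            df = augmented[sample]
            df.loc[tested, "q_value"] = q[offset : offset + len(p)]
            df["is_true_methylated"] = tested.to_numpy() & (
                df["q_value"] <= fdr
            ).fillna(False).to_numpy()
            offset += len(p)
    return augmented


def conversion_rate(control_sites: pd.DataFrame) -> float:
    """Bisulfite conversion rate (%) from spike-in control cytosines.

    100 * sum(unmethylated) / sum(total); raises on empty input.
    """
    if len(control_sites) == 0:
        raise ValueError("no control-chromosome sites supplied")
    total = int((control_sites["m"] + control_sites["u"]).sum())
    if total == 0:
        raise ValueError("control sites have zero total depth")
    return 100.0 * float(control_sites["u"].sum()) / total


def context_breakdown(calls: pd.DataFrame) -> dict[str, float]:
    """Fraction of called methylated cytosines per context; sums to 1."""
    called = calls[calls["is_true_methylated"]] if "is_true_methylated" in calls else calls
    counts = called["context"].value_counts()
    total = int(counts.sum())
    return {
        ctx: (float(counts.get(ctx, 0)) / total if total else 0.0)
        for ctx in ("CG", "CHG", "CHH")
    }


def methylated_context_fractions(reports: dict[str, pd.DataFrame]) -> dict[str, float]:
    """Fraction of methylated-read calls per context, pooled over samples."""
    totals = {"CG": 0, "CHG": 0, "CHH": 0}
    for report in reports.values():
        body = report[report["chrom"] != CONTROL_CHROM]
        for ctx, msum in body.groupby("context")["m"].sum().items():
            totals[str(ctx)] += int(msum)
    grand = sum(totals.values())
    return {k: (v / grand if grand else 0.0) for k, v in totals.items()}


def sample_summaries(
    calls_by_sample: dict[str, pd.DataFrame],
    chrom_sizes: dict[str, int],
) -> dict:
    """Per-chromosome methylated-site counts, size regression and sample correlations.

    Returns per-chromosome counts of called sites per sample, the OLS
    regression of per-chromosome count on chromosome size (slope, R^2, p)
    per sample, and pairwise Pearson r / p between samples' methylation
    fractions on shared called sites.  The control chromosome is excluded.
    """
    chroms = sorted(c for c in chrom_sizes if c != CONTROL_CHROM)
    sizes = np.array([chrom_sizes[c] for c in chroms], dtype=float)

    counts = pd.DataFrame(index=chroms, dtype=float)
    for sample, calls in calls_by_sample.items():
        called = calls[calls["is_true_methylated"] & (calls["chrom"] != CONTROL_CHROM)]
        by = called.groupby("chrom").size()
        counts[sample] = [float(by.get(c, 0)) for c in chroms]

    regressions = {}
    for sample in counts.columns:
        y = counts[sample].to_numpy()
        if len(chroms) >= 3 and np.ptp(sizes) > 0:
            res = stats.linregress(sizes, y)
            regressions[sample] = {
                "slope": float(res.slope),
                "intercept": float(res.intercept),
                "r_squared": float(res.rvalue**2),
                "p_value": float(res.pvalue),
            }

    correlations = []
    names = list(calls_by_sample)
    for i, a in enumerate(names):
        for b in names[i:]:
            ca = calls_by_sample[a]
            cb = calls_by_sample[b]
            ka = ca[ca["is_true_methylated"] & (ca["chrom"] != CONTROL_CHROM)]
            kb = cb[cb["is_true_methylated"] & (cb["chrom"] != CONTROL_CHROM)]
            merged = ka.merge(
                kb,
                on=["chrom", "pos", "strand", "context"],
                suffixes=("_a", "_b"),
            )
            if len(merged) < 3:
                continue
            fa = merged["meth_fraction_a"].to_numpy()
            fb = merged["meth_fraction_b"].to_numpy()
            if np.ptp(fa) == 0 or np.ptp(fb) == 0:
                # constant fractions (e.g. saturated methylation): r undefined,
                # but identical vectors are still a perfect correlation
                if not np.array_equal(fa, fb):
                    continue
                r, p = 1.0, 0.0
            else:
                r, p = stats.pearsonr(fa, fb)
            correlations.append(
                {"sample_a": a, "sample_b": b, "n_shared": len(merged),
                 "r": float(r), "p_value": float(p)}
            )
    return {
        "per_chromosome_counts": counts,
        "size_regression": regressions,
        "pairwise_pearson": pd.DataFrame(correlations),
    }


def write_calls(calls: pd.DataFrame, tsv_path, bedgraph_path=None) -> None:
    """Write a call table as TSV and optionally as bedGraph of fractions."""
    calls.to_csv(tsv_path, sep="\t", index=False)
    if bedgraph_path is not None:
        tested = calls[calls["depth"] > 0]
        bg = pd.DataFrame(
            {
                "chrom": tested["chrom"],
                "start": tested["pos"] - 1,
                "end": tested["pos"],
                "value": tested["meth_fraction"].round(4),
            }
        )
        bg.to_csv(bedgraph_path, sep="\t", header=False, index=False)
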