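"""Methylome-transcriptome concordance.

Joins the genes called differentially expressed with the genes carrying
differentially methylated regions in the same two-group comparison, one
record per (gene, DMR, region label), and classifies each record:

* ``concordant`` — expression and methylation log2 fold changes have
  strictly opposite signs (methylation down / expression up, or the
  reverse): the canonical repressive pattern.
* ``discordant_positive`` — both strictly positive with the DMR in the
  gene body (exon or intron): a positive gene-body
  methylation-expression correlation.
* ``discordant_other`` — anything else, including exact zeros.

The published overlap table ships as a packaged fixture
(``data/published_dmr_deg_overlap.tsv``) for golden tests; its
``narrative_listed`` column flags concordant rows whose gene the
accompanying narrative lists omit.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .annotation import GENE_BODY_LABELS

AGREEMENT_CLASSES = ("concordant", "discordant_positive", "discordant_other")

#: printed-table vocabulary -> agreement class
TABLE_AGREEMENT_MAP = {
    "Yes": "concordant",
    "No *": "discordant_positive",
    "No": "discordant_other",
}


def classify_agreement(
    log2fc_expression: float, log2fc_methylation: float, region: str | None = None
) -> str:
    """Agreement class from the two fold-change signs (and optional region).

    Opposite nonzero signs are concordant.  Both strictly positive is
    ``discordant_positive`` when the region is gene body (exon/intron) or
    unspecified; any other pattern (both negative, or a zero on either
    side) is ``discordant_other``.
    """
    e, m = float(log2fc_expression), float(log2fc_methylation)
    if e != 0 and m != 0 and np.sign(e) == -np.sign(m):
        return "concordant"
    if e > 0 and m > 0 and (region is None or region in GENE_BODY_LABELS):
        return "discordant_positive"
    return "discordant_other"


def overlap_deg_dmr(
    degs: pd.DataFrame,
    annotated_dmrs: pd.DataFrame,
    comparison: str,
) -> pd.DataFrame:
    """One record per (DEG gene x overlapping DMR x region label).

    ``degs`` is a called differential-expression table (indexed by gene_id,
    with ``log2fc`` and ``is_deg``); ``annotated_dmrs`` is the per-gene
    expansion from :func:`methdyn.dmr.annotate_dmrs`.  Both must have been
    computed for the same pair of groups: when either carries a
    ``comparison``/contrast annotation that disagrees, this raises.
    """
    deg_cmp = degs.attrs.get("contrast")
    if deg_cmp is not None and " vs ".join(deg_cmp) != comparison:
        raise ValueError(
            f"DEG table was computed for {' vs '.join(deg_cmp)!r}, not {comparison!r}"
        )
    dmr_cmp = annotated_dmrs.attrs.get("comparison")
    if dmr_cmp is not None and dmr_cmp != comparison:
        raise ValueError(
            f"DMR table was computed for {dmr_cmp!r}, not {comparison!r}"
        )
    hits = degs[degs["is_deg"]] if "is_deg" in degs else degs
    rows = []
    for _, drow in annotated_dmrs.iterrows():
        gid = drow["gene_id"]
        if gid not in hits.index:
            continue
        expr_lfc = float(hits.loc[gid, "log2fc"])
        meth_lfc = float(drow["log2fc_methylation"])
        region = str(drow["region"])
        rows.append(
            {
                "gene_id": gid,
                "gene_name": drow.get("gene_name", gid),
                "chrom": drow["chrom"],
                "comparison": comparison,
                "log2fc_expression": expr_lfc,
                "log2fc_methylation": meth_lfc,
                "context": drow.get("context", "CG"),
                "region": region,
                "agreement": classify_agreement(expr_lfc, meth_lfc, region),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id", "gene_name", "chrom", "comparison", "log2fc_expression",
            "log2fc_methylation", "context", "region", "agreement",
        ],
    )


def count_concordant_genes(
    records: pd.DataFrame, comparison: str, direction: str
) -> tuple[int, list[str]]:
    """Unique genes with >= 1 concordant record in one comparison/direction.

    ``direction`` is ``"up"`` (expression higher in the first group) or
    ``"down"``.  Gene identity keys on gene_id, falling back to gene_name
    where the id is missing.  Order- and duplicate-invariant.
    """
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    if len(records) == 0:
        return 0, []
    sign_ok = (
        records["log2fc_expression"] > 0
        if direction == "up"
        else records["log2fc_expression"] < 0
    )
    sel = records[
        (records["comparison"] == comparison)
        & (records["agreement"] == "concordant")
        & sign_ok
    ]
    ids = sel["gene_id"].where(sel["gene_id"].notna() & (sel["gene_id"] != ""),
                               sel["gene_name"])
    genes = sorted(set(ids))
    return len(genes), genes


def region_distribution(records: pd.DataFrame) -> dict[str, float]:
    """Record-level percentage per region label; sums to 100 up to rounding."""
    if len(records) == 0:
        return {}
    counts = records["region"].value_counts()
    total = int(counts.sum())
    return {str(k): 100.0 * int(v) / total for k, v in counts.items()}


def recurrent_dmr_genes(gene_sets: dict[str, set[str]], k: int = 2) -> set[str]:
    """Genes carrying DMRs in at least ``k`` of the supplied comparisons."""
    tally: dict[str, int] = {}
    for genes in gene_sets.values():
        for g in set(genes):
            tally[g] = tally.get(g, 0) + 1
    return {g for g, c in tally.items() if c >= k}


# -- packaged published-table fixture --------------------------------------


def load_published_overlap() -> pd.DataFrame:
    """The published DEG/DMR overlap table (one row per gene-DMR-region)."""
    ref = resources.files("methdyn").joinpath("data/published_dmr_deg_overlap.tsv")
    with resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t", comment="#")
    df["narrative_listed"] = df["narrative_listed"].astype(bool)
    return df


def published_records(narrative_only: bool = False) -> pd.DataFrame:
    """Published table reshaped into integration records (classified here).

    The agreement column is recomputed by :func:`classify_agreement`; the
    printed value is retained as ``agreement_printed``.
    """
    df = load_published_overlap()
    if narrative_only:
        df = df[df["narrative_listed"]]
    out = df.rename(columns={"agreement": "agreement_printed"}).copy()
    out["agreement"] = [
        classify_agreement(e, m, r)
        for e, m, r in zip(
            out["log2fc_expression"], out["log2fc_methylation"], out["region"]
        )
    ]
    return out


def write_integration(records: pd.DataFrame, path) -> None:
    records.to_csv(path, sep="\t", index=False)
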