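"""End-to-end orchestration: simulate -> call-sites -> annotate -> call-dmrs
-> call-degs -> integrate, with a manifest and a text report.

Every stage reads only files, writes only into the run directory, and logs
its parameters; all randomness flows from the single configured seed via
the simulator's named substreams, so a rerun with the same config is
bit-identical for the deterministic stages (which is all of them — the
statistical stages have no randomness of their own).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import pandas as pd
import yaml

from . import annotation, diffexpr, dmr, integration, site_calling, synthetic

log = logging.getLogger("methdyn")

STAGES = ("simulate", "call_sites", "annotate", "call_dmrs", "call_degs", "integrate")

DEFAULT_PARAMS = {
    "min_depth": 5,
    "fdr": 0.01,
    "window": dmr.SMOOTH_WINDOW,
    "p_threshold": dmr.P_THRESHOLD,
    "min_len": dmr.MIN_LEN,
    "min_sites": dmr.MIN_SITES,
    "pct_sig": dmr.PCT_SIG,
    "merge_gap": dmr.MERGE_GAP,
    "alpha": diffexpr.ALPHA,
    "lfc": diffexpr.LFC_THRESHOLD,
    "flank": annotation.GENE_FLANK,
    "eps": 0.01,
}


def load_run_config(path) -> dict:
    """YAML run configuration: a ``sim`` block plus stage parameters."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    return cfg


def _file_hash(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _comparison(pair: tuple[str, str]) -> str:
    return f"{pair[0]} vs {pair[1]}"


def run_pipeline(
    out_dir,
    seed: int = 0,
    config: dict | None = None,
    force: bool = True,
) -> dict:
    """Run all six stages into ``out_dir`` and return the manifest.

    ``config`` may carry a ``sim`` block (fields of
    :class:`methdyn.synthetic.SimConfig`) and any of the stage parameters in
    :data:`DEFAULT_PARAMS`.  With ``force=False`` a stage whose outputs all
    exist is skipped (stale-aware reruns recompute everything downstream of
    a missing file; the default is a full rerun).
    """
    t0 = time.time()
    cfg = dict(config or {})
    params = {**DEFAULT_PARAMS, **{k: v for k, v in cfg.items() if k in DEFAULT_PARAMS}}
    sim_kwargs = dict(cfg.get("sim", {}))
    sim_kwargs["seed"] = seed
    sim = synthetic.SimConfig(**sim_kwargs)

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": seed, "params": params, "stages": []}

    def stage_done(name: str, outputs: dict[str, str]):
        manifest["stages"].append(
            {
                "stage": name,
                "outputs": {k: str(v) for k, v in outputs.items()},
                "hashes": {
                    k: _file_hash(Path(v)) for k, v in outputs.items() if Path(v).is_file()
                },
                "elapsed_s": round(time.time() - t0, 2),
            }
        )
        log.info("stage %s complete (%d outputs)", name, len(outputs))

    # 1. simulate ---------------------------------------------------------
    sim_dir = out / "sim"
    log.info("stage simulate: %s", dataclasses.asdict(sim))
    if force or not (sim_dir / "truth.json").exists():
        paths = synthetic.simulate_all(sim, sim_dir)
    else:
        paths = {"truth": str(sim_dir / "truth.json")}
    stage_done("simulate", paths)

    # 2. call-sites -------------------------------------------------------
    log.info("stage call_sites: min_depth=%s fdr=%s", params["min_depth"], params["fdr"])
    calls_dir = out / "calls"
    calls_dir.mkdir(exist_ok=True)
    reports = {
        s: site_calling.read_cytosine_report(sim_dir / f"{s}.CX_report.txt")
        for s, _g in sim.samples
    }
    calls = {
        s: site_calling.call_true_methylated(
            rep, min_depth=params["min_depth"], fdr=params["fdr"]
        )
        for s, rep in reports.items()
    }
    call_paths = {}
    for s, df in calls.items():
        p = calls_dir / f"{s}.calls.tsv"
        site_calling.write_calls(df, p, calls_dir / f"{s}.bedGraph")
        call_paths[s] = str(p)
    conv = {
        s: site_calling.conversion_rate(df[df["chrom"] == synthetic.CONTROL_CHROM])
        for s, df in calls.items()
    }
    (calls_dir / "conversion_rates.json").write_text(json.dumps(conv, indent=1))
    call_paths["conversion_rates"] = str(calls_dir / "conversion_rates.json")
    stage_done("call_sites", call_paths)

    # 3. annotate ---------------------------------------------------------
    log.info("stage annotate: flank=%s", params["flank"])
    catalog = annotation.load_annotation(
        sim_dir / "genes.gtf",
        sim_dir / "cgi.bed",
        sim_dir / "repeats.bed",
        sim_dir / "chrom.sizes",
    )
    profile = annotation.feature_methylation_profile(
        calls, catalog, min_depth=params["min_depth"]
    )
    ann_dir = out / "annotation"
    ann_dir.mkdir(exist_ok=True)
    profile.to_csv(ann_dir / "feature_methylation.tsv", sep="\t", index=False)
    stats_report = annotation.group_stats(profile, dict(sim.samples))
    with open(ann_dir / "feature_stats.json", "w") as fh:
        json.dump(_jsonable(stats_report), fh, indent=1)
    stage_done(
        "annotate",
        {
            "profile": str(ann_dir / "feature_methylation.tsv"),
            "stats": str(ann_dir / "feature_stats.json"),
        },
    )

    # 4. call-dmrs --------------------------------------------------------
    dmr_dir = out / "dmrs"
    dmr_dir.mkdir(exist_ok=True)
    caller = dmr.DmrCallerConfig(
        window=params["window"],
        p_threshold=params["p_threshold"],
        min_len=params["min_len"],
        min_sites=params["min_sites"],
        pct_sig=params["pct_sig"],
        merge_gap=params["merge_gap"],
    )
    groups = dict(sim.samples)
    dmr_paths = {}
    annotated_by_pair: dict[tuple[str, str], pd.DataFrame] = {}
    for pair in sim.group_pairs:
        rep_a = {s: reports[s] for s, g in sim.samples if g == pair[0]}
        rep_b = {s: reports[s] for s, g in sim.samples if g == pair[1]}
        log.info("stage call_dmrs: %s (%s)", _comparison(pair), vars(caller))
        _sites, dmrs = dmr.test_contrast(rep_a, rep_b, caller, group_labels=pair)
        tag = f"{pair[0]}_vs_{pair[1]}"
        dmr.write_dmrs(dmrs, dmr_dir / f"{tag}.tsv", dmr_dir / f"{tag}.bed")
        annotated = dmr.annotate_dmrs(dmrs, catalog)
        annotated.attrs["comparison"] = _comparison(pair)
        annotated.to_csv(dmr_dir / f"{tag}.genes.tsv", sep="\t", index=False)
        annotated_by_pair[pair] = annotated
        dmr_paths[tag] = str(dmr_dir / f"{tag}.tsv")
    stage_done("call_dmrs", dmr_paths)

    # 5. call-degs --------------------------------------------------------
    de_dir = out / "degs"
    de_dir.mkdir(exist_ok=True)
    counts = diffexpr.read_counts(sim_dir / "counts.tsv")
    sample_groups = pd.Series(groups)
    de_paths = {}
    degs_by_pair: dict[tuple[str, str], pd.DataFrame] = {}
    for pair in sim.group_pairs:
        log.info("stage call_degs: %s (alpha=%s lfc=%s)", _comparison(pair),
                 params["alpha"], params["lfc"])
        res = diffexpr.nb_wald_test(counts, sample_groups, pair)
        flagged = diffexpr.call_degs(res, alpha=params["alpha"], lfc=params["lfc"])
        tag = f"{pair[0]}_vs_{pair[1]}"
        flagged.to_csv(de_dir / f"{tag}.tsv", sep="\t")
        de_paths[tag] = str(de_dir / f"{tag}.tsv")
        degs_by_pair[pair] = flagged
    stage_done("call_degs", de_paths)

    # 6. integrate --------------------------------------------------------
    int_dir = out / "integration"
    int_dir.mkdir(exist_ok=True)
    int_paths = {}
    all_records = []
    for pair in sim.group_pairs:
        comparison = _comparison(pair)
        records = integration.overlap_deg_dmr(
            degs_by_pair[pair], annotated_by_pair[pair], comparison
        )
        tag = f"{pair[0]}_vs_{pair[1]}"
        integration.write_integration(records, int_dir / f"{tag}.tsv")
        int_paths[tag] = str(int_dir / f"{tag}.tsv")
        all_records.append(records)
    combined = (
        pd.concat(all_records, ignore_index=True) if all_records else pd.DataFrame()
    )
    integration.write_integration(combined, int_dir / "all_records.tsv")
    int_paths["all"] = str(int_dir / "all_records.tsv")
    stage_done("integrate", int_paths)

    manifest["elapsed_s"] = round(time.time() - t0, 2)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="records")
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if hasattr(obj, "item"):
        return obj.item()
    return obj


def report(run_dir) -> str:
    """Human-readable summary of a finished run; tolerates empty stages."""
    run = Path(run_dir)
    lines = ["methylome-transcriptome run summary", "=" * 36]
    manifest_path = run / "manifest.json"
    if manifest_path.exists():
        manifest = json.loads(manifest_path.read_text())
        lines.append(
            f"stages completed: {len(manifest['stages'])} "
            f"({', '.join(s['stage'] for s in manifest['stages'])})"
        )
    conv_path = run / "calls" / "conversion_rates.json"
    if conv_path.exists():
        conv = json.loads(conv_path.read_text())
        lines.append("")
        lines.append("bisulfite conversion rate per sample (%):")
        for s, v in conv.items():
            lines.append(f"  {s}: {v:.2f}")
    dmr_dir = run / "dmrs"
    if dmr_dir.is_dir():
        lines.append("")
        lines.append("DMRs per comparison:")
        for path in sorted(dmr_dir.glob("*_vs_*.tsv")):
            if path.name.endswith(".genes.tsv"):
                continue
            df = pd.read_csv(path, sep="\t")
            tag = path.stem.replace("_vs_", " vs ")
            if len(df):
                med = df["length"].median()
                lines.append(
                    f"  {tag}: {len(df)} DMRs (median length {med:.0f} bp, "
                    f"mean {df['n_sites'].mean():.1f} sites)"
                )
            else:
                lines.append(f"  {tag}: 0 DMRs")
    de_dir = run / "degs"
    if de_dir.is_dir():
        lines.append("")
        lines.append("DEGs per comparison (Bonferroni p<0.05, |log2FC|>1):")
        for path in sorted(de_dir.glob("*_vs_*.tsv")):
            df = pd.read_csv(path, sep="\t")
            tag = path.stem.replace("_vs_", " vs ")
            if "is_deg" in df and len(df):
                up = int((df["is_deg"] & (df["log2fc"] > 0)).sum())
                down = int((df["is_deg"] & (df["log2fc"] < 0)).sum())
                lines.append(f"  {tag}: {up + down} DEGs ({up} up, {down} down)")
            else:
                lines.append(f"  {tag}: 0 DEGs")
    int_path = run / "integration" / "all_records.tsv"
    if int_path.exists():
        try:
            rec = pd.read_csv(int_path, sep="\t")
        except pd.errors.EmptyDataError:
            rec = pd.DataFrame()
        lines.append("")
        if len(rec):
            lines.append("DMR-DEG concordance:")
            for comparison in sorted(rec["comparison"].unique()):
                for direction in ("up", "down"):
                    n, genes = integration.count_concordant_genes(
                        rec, comparison, direction
                    )
                    if n:
                        lines.append(
                            f"  {comparison}, expression {direction}: {n} genes "
                            f"({', '.join(genes)})"
                        )
            dist = integration.region_distribution(
                rec[rec["agreement"] == "concordant"]
            )
            if dist:
                lines.append(
                    "  concordant-record regions: "
                    + ", ".join(f"{k} {v:.1f}%" for k, v in sorted(dist.items()))
                )
        else:
            lines.append("DMR-DEG concordance: no overlapping genes")
    return "\n".join(lines) + "\n"


def fixture_report() -> str:
    """Concordance section computed from the packaged published table only."""
    rec = integration.published_records()
    lines = ["published-table concordance", "-" * 27]
    for comparison in sorted(rec["comparison"].unique()):
        for direction in ("up", "down"):
            n, genes = integration.count_concordant_genes(rec, comparison, direction)
            lines.append(f"{comparison}, expression {direction}: {n} genes")
    return "\n".join(lines) + "\n"
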