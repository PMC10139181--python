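"""Deterministic toy genome + bisulfite / expression simulator.

Emulates the data shape of a three-stage placental study: 3 groups
("4M", "6M", "10M") x 3 biological replicates, per-cytosine Bismark-style
CX reports dominated by CG-context methylation, an unmethylated spike-in
control chromosome ("lambda") whose residual methylated calls encode the
bisulfite conversion failure rate, planted differentially methylated
regions of 50-500 bp with ~0.30 methylation-fraction differences, and a
negative-binomial expression matrix with planted |log2FC| = 1.5 effects.

All randomness flows from ``SimConfig.seed`` through named substreams, so a
fixed seed reproduces byte-identical output files.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import FEATURE_PRIORITY, FeatureCatalog, GeneModel

CONTROL_CHROM = "lambda"

#: substream ids so that each stage draws from an independent generator
_STREAMS = {"annotation": 1, "methylome": 2, "expression": 3}


class CapacityError(ValueError):
    """Requested gene/DMR content does not fit the configured genome."""


@dataclass
class SimConfig:
    """Generative settings for the toy study.

    Defaults mirror the study conditions: 3 gestational-stage groups of 3
    samples, ~30 percentage-point methylation differences in planted DMRs
    of 50-500 bp, 2% of cytosines in non-CG context (so >97% of methylated
    calls land in CG), a 0.59% conversion-failure rate (99.41% conversion),
    and expression effects of |log2FC| = 1.5 under the Bonferroni +
    |log2FC| > 1 calling rule.
    """

    seed: int = 0
    n_groups: int = 3
    group_names: tuple[str, ...] = ("4M", "6M", "10M")
    n_per_group: int = 3
    n_chroms: int = 4
    chrom_length: int = 300_000
    n_genes: int = 120
    cpg_rate: float = 100.0  # expected CpG dyads per kb (RRBS-like density)
    coverage_mean: float = 30.0
    coverage_dispersion: float = 0.2  # NB dispersion of per-site depth
    baseline_meth_by_feature: dict[str, float] = field(
        default_factory=lambda: {
            "utr5": 0.12,
            "promoter": 0.18,
            "cgi": 0.22,
            "shore": 0.35,
            "utr3": 0.50,
            "exon": 0.55,
            "intron": 0.60,
            "repeat": 0.70,
            "intergenic": 0.50,
        }
    )
    site_dispersion: float = 0.05  # beta-binomial phi across replicates
    n_dmrs: int = 30
    dmr_delta: float = 0.30
    dmr_len_range: tuple[int, int] = (50, 500)
    frac_chh_chg: float = 0.02  # fraction of cytosines in non-CG context
    noncg_meth: float = 0.02  # mean methylation of non-CG cytosines
    conversion_failure: float = 0.0059
    control_sites: int = 6000  # control-chromosome cytosines per sample
    control_length: int = 48_502  # phage-like control chromosome length
    n_degs: int = 60
    deg_log2fc: float = 1.5
    nb_dispersion: float = 0.05
    mean_expr: float = 200.0
    deg_from_dmr_genes: float = 0.5  # fraction of DEGs planted on DMR genes
    #: group -> {feature: additive methylation shift}, e.g. a late-gestation
    #: rise in promoter/intron methylation: {"10M": {"promoter": 0.08}}
    stage_shift: dict[str, dict[str, float]] = field(default_factory=dict)

    def __post_init__(self):
        for name in ("frac_chh_chg", "noncg_meth", "conversion_failure",
                     "site_dispersion"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for k, v in self.baseline_meth_by_feature.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"baseline methylation for {k} outside [0, 1]")
        if not -1.0 <= self.dmr_delta <= 1.0:
            raise ValueError("dmr_delta must be in [-1, 1]")
        lo, hi = self.dmr_len_range
        if lo < 1 or hi < lo:
            raise ValueError("dmr_len_range must satisfy 1 <= min <= max")
        if self.n_groups != len(self.group_names):
            raise ValueError("group_names must match n_groups")

    @property
    def samples(self) -> list[tuple[str, str]]:
        """(sample_name, group) pairs, e.g. ('4M_1', '4M')."""
        return [
            (f"{g}_{i + 1}", g)
            for g in self.group_names
            for i in range(self.n_per_group)
        ]

    @property
    def group_pairs(self) -> list[tuple[str, str]]:
        names = self.group_names
        return [(a, b) for i, a in enumerate(names) for b in names[i + 1 :]]

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), _STREAMS[stream]])


@dataclass
class TruthSet:
    """Ground truth of planted effects.

    ``dmr_intervals``: (chrom, start, end, shifted_group, delta, context)
    with 0-based half-open coordinates; the shifted group's methylation mean
    is ``baseline + delta`` inside the interval, all other groups stay at
    baseline, so the interval is differential for every pair involving the
    shifted group.  ``deg_table``: (gene_id, group_pair, true_log2fc) where
    the second group of the pair carries the fold change.
    """

    dmr_intervals: list[tuple[str, int, int, str, float, str]] = field(
        default_factory=list
    )
    deg_table: list[tuple[str, tuple[str, str], float]] = field(default_factory=list)
    size_factors: dict[str, float] = field(default_factory=dict)

    def dmrs_for_pair(self, group_a: str, group_b: str):
        """Planted intervals that are differential between two named groups."""
        return [
            t for t in self.dmr_intervals if t[3] in (group_a, group_b)
        ]

    def degs_for_pair(self, group_a: str, group_b: str):
        pair = {group_a, group_b}
        return [t for t in self.deg_table if set(t[1]) == pair]

    def to_json(self) -> str:
        return json.dumps(
            {
                "dmr_intervals": [list(t) for t in self.dmr_intervals],
                "deg_table": [[g, list(p), f] for g, p, f in self.deg_table],
                "size_factors": self.size_factors,
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "TruthSet":
        obj = json.loads(text)
        return cls(
            dmr_intervals=[tuple(t) for t in obj["dmr_intervals"]],
            deg_table=[(g, tuple(p), f) for g, p, f in obj["deg_table"]],
            size_factors=obj.get("size_factors", {}),
        )


# -- toy annotation --------------------------------------------------------


def build_toy_annotation(config: SimConfig) -> FeatureCatalog:
    """Place non-overlapping gene models plus CGIs, shores and repeats.

    Genes get 1-5 exons, UTRs at both ends and a strand; CGIs are placed
    preferentially at promoters; repeats fill intergenic space.  Raises
    :class:`CapacityError` when the requested genes do not fit.
    """
    rng = config.rng("annotation")
    chroms = [f"chr{i + 1}" for i in range(config.n_chroms)]
    chrom_sizes = {c: config.chrom_length for c in chroms}

    footprint = 6_000  # typical gene span + spacing budget
    capacity = config.n_chroms * (config.chrom_length // footprint)
    if config.n_genes > capacity:
        raise CapacityError(
            f"{config.n_genes} genes need ~{config.n_genes * footprint} bp but "
            f"only {config.n_chroms * config.chrom_length} bp are available"
        )

    genes: list[GeneModel] = []
    cgi: list[tuple[str, int, int]] = []
    repeats: list[tuple[str, int, int]] = []
    slots_per_chrom = int(np.ceil(config.n_genes / config.n_chroms))
    gene_idx = 0
    for chrom in chroms:
        cursor = 2_000
        for _ in range(slots_per_chrom):
            if gene_idx >= config.n_genes:
                break
            span = int(rng.integers(2_000, 5_000))
            gap = int(rng.integers(1_200, 3_000))
            start = cursor + gap
            end = start + span
            if end + 2_000 > config.chrom_length:
                break
            strand = "+" if rng.random() < 0.5 else "-"
            n_exons = int(rng.integers(1, 6))
            bounds = np.sort(rng.choice(np.arange(1, span), 2 * n_exons - 2,
                                        replace=False)) if n_exons > 1 else np.array([], int)
            edges = [0, *bounds.tolist(), span]
            exons = [
                (start + edges[2 * k], start + edges[2 * k + 1])
                for k in range(n_exons)
            ]
            exons = [(s, e) for s, e in exons if e > s]
            first, last = exons[0], exons[-1]
            left_len = min(200, first[1] - first[0] - 1)
            right_len = min(200, last[1] - last[0] - 1)
            left = [(first[0], first[0] + left_len)] if left_len > 0 else []
            right = [(last[1] - right_len, last[1])] if right_len > 0 else []
            utr5, utr3 = (left, right) if strand == "+" else (right, left)
            gid = f"G{gene_idx + 1:05d}"
            genes.append(
                GeneModel(gid, f"gene{gene_idx + 1}", chrom, strand, start, end,
                          exons=exons, utr5=utr5, utr3=utr3)
            )
            # CGI preferentially at the promoter (70%), else inside the gene
            if rng.random() < 0.7:
                tss = start if strand == "+" else end - 1
                cgi_len = int(rng.integers(300, 800))
                s = max(0, tss - cgi_len // 2)
                cgi.append((chrom, s, min(config.chrom_length, s + cgi_len)))
            elif rng.random() < 0.5:
                s = int(rng.integers(start, max(start + 1, end - 400)))
                cgi.append((chrom, s, min(end, s + 400)))
            cursor = end
            gene_idx += 1
        # repeats in the remaining intergenic tail
        tail = config.chrom_length - cursor - 2_000
        n_rep = max(0, tail // 4_000)
        for _ in range(n_rep):
            s = int(rng.integers(cursor + 500, config.chrom_length - 600))
            repeats.append((chrom, s, s + int(rng.integers(150, 500))))

    if gene_idx < config.n_genes:
        raise CapacityError(
            f"placed only {gene_idx} of {config.n_genes} genes; "
            "increase n_chroms or chrom_length"
        )

    chrom_sizes[CONTROL_CHROM] = config.control_length
    # de-overlap CGIs (merging keeps shore derivation well defined)
    cgi = _merge_intervals(cgi)
    repeats = _merge_intervals(repeats)
    return FeatureCatalog(chrom_sizes, genes=genes, cgi=cgi, repeats=repeats)


def _merge_intervals(ivs):
    out = []
    for chrom, s, e in sorted(ivs):
        if out and out[-1][0] == chrom and s <= out[-1][2]:
            out[-1] = (chrom, out[-1][1], max(out[-1][2], e))
        else:
            out.append((chrom, s, e))
    return out


# -- methylome simulation --------------------------------------------------


def _site_baselines(catalog: FeatureCatalog, chrom, pos0, config: SimConfig):
    """Baseline methylation mean and priority feature label per site."""
    base = np.full(len(pos0), config.baseline_meth_by_feature["intergenic"])
    label_arr = np.full(len(pos0), "intergenic", dtype=object)
    order = [lbl for lbl in FEATURE_PRIORITY if lbl in config.baseline_meth_by_feature]
    # later assignments win, so iterate from lowest to highest priority
    for label in reversed(order):
        sel = catalog.membership(label, chrom, pos0)
        base[sel] = config.baseline_meth_by_feature[label]
        label_arr[sel] = label
    return base, label_arr


def _beta_binomial(rng, n, mu, phi):
    """Counts with mean n*mu and variance n*mu*(1-mu)*(1+(n-1)*phi)."""
    n = np.asarray(n)
    mu = np.clip(np.asarray(mu, dtype=float), 0.0, 1.0)
    out = np.zeros(n.shape, dtype=np.int64)
    if phi <= 0:
        return rng.binomial(n, mu)
    a = mu * (1 - phi) / phi
    b = (1 - mu) * (1 - phi) / phi
    interior = (mu > 0) & (mu < 1)
    if interior.any():
        p = rng.beta(a[interior], b[interior])
        out[interior] = rng.binomial(n[interior], p)
    out[mu >= 1] = n[mu >= 1]
    return out


def _place_dmrs(
    config: SimConfig,
    rng,
    catalog: FeatureCatalog,
    cg_positions: dict[str, np.ndarray],
) -> list[tuple[str, int, int, str, float, str]]:
    """Non-overlapping planted intervals with headroom-aware shift signs.

    Intervals are required to be CpG-dense (at least 80% of the expected
    site count for their length) — mirroring the CpG-dense character of
    bisulfite-captured regions — and the shift direction is chosen so the
    full |dmr_delta| is expressible: low-methylation baselines gain
    methylation, high ones lose it.  Otherwise sparse intervals or clipping
    at [0.01, 0.99] would silently shrink the planted effect below the
    configured size.
    """
    chroms = [c for c in cg_positions]
    placed: list[tuple[str, int, int, str, float, str]] = []
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    pad = 1_000  # keep planted regions from merging into each other
    magnitude = abs(config.dmr_delta)
    for k in range(config.n_dmrs):
        group = config.group_names[k % config.n_groups]
        length = int(rng.integers(config.dmr_len_range[0], config.dmr_len_range[1] + 1))
        min_sites = 0.8 * 2 * config.cpg_rate * length / 1000  # both strands
        for _attempt in range(500):
            chrom = chroms[int(rng.integers(len(chroms)))]
            start = int(rng.integers(1_000, config.chrom_length - length - 1_000))
            end = start + length
            if not all(end + pad <= s or e + pad <= start for s, e in occupied[chrom]):
                continue
            pos = cg_positions[chrom]
            n_inside = int(np.searchsorted(pos, end) - np.searchsorted(pos, start))
            if n_inside < min_sites:
                continue
            probe = np.arange(start, end, max(1, length // 20))
            base, _ = _site_baselines(catalog, chrom, probe, config)
            delta = magnitude if float(base.mean()) <= 0.5 else -magnitude
            occupied[chrom].append((start, end))
            placed.append((chrom, start, end, group, float(delta), "CG"))
            break
        else:
            raise CapacityError(
                f"could not place DMR #{k + 1} of length {length} after 500 tries"
            )
    return placed


def simulate_methylome(
    config: SimConfig, catalog: FeatureCatalog
) -> tuple[dict[str, pd.DataFrame], TruthSet]:
    """Per-sample CX-style cytosine reports plus the planted-effect truth.

    Returns ``{sample_name: report}`` where a report has columns
    (chrom, pos, strand, m, u, context, tri) with 1-based positions, and the
    :class:`TruthSet`.  Plus- and minus-strand cytosines of a CpG are
    separate rows.  The control chromosome carries only truly unmethylated
    cytosines read as methylated at the conversion-failure rate.
    """
    rng = config.rng("methylome")

    site_arrays: dict[str, tuple] = {}
    for chrom in sorted(c for c in catalog.chrom_sizes if c != CONTROL_CHROM):
        size = catalog.chrom_sizes[chrom]
        n_dyads = rng.poisson(config.cpg_rate * size / 1000)
        dyad_pos = np.sort(rng.choice(size - 1, size=min(n_dyads, size - 1),
                                      replace=False))
        pos0 = np.repeat(dyad_pos, 2)
        pos0[1::2] += 1  # G-strand cytosine of the dyad
        strand = np.tile(np.array(["+", "-"]), len(dyad_pos))
        context = np.full(pos0.shape, "CG", dtype=object)
        tri = np.full(pos0.shape, "CGN", dtype=object)
        # sprinkle non-CG cytosines: frac_chh_chg of all cytosine sites
        n_noncg = rng.poisson(
            len(pos0) * config.frac_chh_chg / max(1e-12, 1 - config.frac_chh_chg)
        )
        if n_noncg:
            np0 = rng.integers(0, size, n_noncg)
            nstrand = np.where(rng.random(n_noncg) < 0.5, "+", "-")
            nctx = np.where(rng.random(n_noncg) < 0.7, "CHH", "CHG")
            ntri = np.where(nctx == "CHH", "CTT", "CTG")
            pos0 = np.concatenate([pos0, np0])
            strand = np.concatenate([strand, nstrand])
            context = np.concatenate([context, nctx])
            tri = np.concatenate([tri, ntri])
        order = np.argsort(pos0, kind="stable")
        pos0, strand, context, tri = pos0[order], strand[order], context[order], tri[order]
        # a position/strand can host only one cytosine record
        strand_code = (strand == "+").astype(np.int64)
        _, first = np.unique(pos0 * 2 + strand_code, return_index=True)
        site_arrays[chrom] = (pos0[first], strand[first], context[first], tri[first])

    cg_positions = {
        chrom: pos0[context == "CG"]
        for chrom, (pos0, _s, context, _t) in site_arrays.items()
    }
    truth = TruthSet(
        dmr_intervals=(
            _place_dmrs(config, rng, catalog, cg_positions) if config.n_dmrs else []
        )
    )

    chrom_site_tables = []
    for chrom, (pos0, strand, context, tri) in site_arrays.items():
        mu, feature_label = _site_baselines(catalog, chrom, pos0, config)
        mu[context != "CG"] = config.noncg_meth
        # per-group means: baseline, plus stage-level feature shifts, plus
        # planted DMR shifts
        group_mu = {g: mu.copy() for g in config.group_names}
        for grp, shifts in config.stage_shift.items():
            for feat, delta in shifts.items():
                sel = (feature_label == feat) & (context == "CG")
                group_mu[grp][sel] = np.clip(mu[sel] + delta, 0.01, 0.99)
        for c, s, e, grp, delta, _ctx in truth.dmr_intervals:
            if c != chrom:
                continue
            sel = (pos0 >= s) & (pos0 < e) & (context == "CG")
            group_mu[grp][sel] = np.clip(mu[sel] + delta, 0.01, 0.99)
        chrom_site_tables.append(
            (chrom, pos0, strand, context, tri, group_mu)
        )

    reports: dict[str, pd.DataFrame] = {}
    r = 1.0 / max(config.coverage_dispersion, 1e-8)
    p_nb = r / (r + config.coverage_mean)
    for sample, group in config.samples:
        frames = []
        for chrom, pos0, strand, context, tri, group_mu in chrom_site_tables:
            depth = rng.negative_binomial(r, p_nb, len(pos0))
            mu_obs = group_mu[group]
            mu_obs = mu_obs + (1 - mu_obs) * config.conversion_failure
            m = _beta_binomial(rng, depth, mu_obs, config.site_dispersion)
            frames.append(
                pd.DataFrame(
                    {
                        "chrom": chrom,
                        "pos": pos0 + 1,
                        "strand": strand,
                        "m": m,
                        "u": depth - m,
                        "context": context,
                        "tri": tri,
                    }
                )
            )
        # control chromosome: truly unmethylated spike-in
        cpos = np.sort(
            rng.choice(config.control_length, size=config.control_sites, replace=False)
        )
        cdepth = rng.negative_binomial(r, p_nb, config.control_sites)
        cm = rng.binomial(cdepth, config.conversion_failure)
        frames.append(
            pd.DataFrame(
                {
                    "chrom": CONTROL_CHROM,
                    "pos": cpos + 1,
                    "strand": np.where(rng.random(config.control_sites) < 0.5, "+", "-"),
                    "m": cm,
                    "u": cdepth - cm,
                    "context": "CG",
                    "tri": "CGN",
                }
            )
        )
        reports[sample] = pd.concat(frames, ignore_index=True)
    return reports, truth


# -- expression simulation -------------------------------------------------


def simulate_expression(
    config: SimConfig,
    catalog: FeatureCatalog,
    methylome_truth: TruthSet | None = None,
) -> tuple[pd.DataFrame, TruthSet]:
    """Integer count matrix (genes x samples) with planted DEGs.

    Counts ~ NB(mean * size_factor * 2^(log2fc * indicator), nb_dispersion);
    per-sample size factors are drawn uniformly in [0.7, 1.4].  When a
    methylome truth is given, a fraction of DEGs is planted on genes
    overlapped by planted DMRs, with expression sign opposite to the
    methylation shift (emulating concordant methylation-expression pairs).
    """
    if len(catalog.genes) == 0:
        raise ValueError("expression simulation needs at least one gene")
    if config.n_degs > len(catalog.genes):
        raise ValueError(
            f"n_degs={config.n_degs} exceeds the {len(catalog.genes)} genes available"
        )
    rng = config.rng("expression")
    gene_ids = sorted(catalog.genes)
    n_genes = len(gene_ids)
    base_mean = config.mean_expr * np.exp(rng.normal(0.0, 1.0, n_genes) - 0.5)
    size_factors = rng.uniform(0.7, 1.4, len(config.samples))

    # choose DEG genes; optionally anchor some on DMR-carrying genes
    from .annotation import associate_gene

    deg_rows: list[tuple[str, tuple[str, str], float]] = []
    chosen: dict[str, tuple[tuple[str, str], float]] = {}
    if methylome_truth is not None and config.deg_from_dmr_genes > 0:
        n_anchor = int(round(config.n_degs * config.deg_from_dmr_genes))
        for chrom, s, e, grp, delta, _ctx in methylome_truth.dmr_intervals:
            if len(chosen) >= n_anchor:
                break
            for gid in sorted(associate_gene((chrom, s, e), catalog)):
                if gid in chosen:
                    continue
                other = [g for g in config.group_names if g != grp]
                partner = other[int(rng.integers(len(other)))]
                pair = tuple(
                    sorted((grp, partner), key=config.group_names.index)
                )
                # expression shift on the methylation-shifted group, sign
                # opposite to the methylation change -> concordant pair
                lfc = -np.sign(delta) * config.deg_log2fc
                if pair[0] == grp:  # truth stores the fold change on pair[1]
                    lfc = -lfc
                chosen[gid] = (pair, float(lfc))
                break
    remaining = [g for g in gene_ids if g not in chosen]
    n_free = config.n_degs - len(chosen)
    free = rng.choice(len(remaining), size=n_free, replace=False)
    pairs = config.group_pairs
    for j, idx in enumerate(sorted(free)):
        sign = 1.0 if j % 2 == 0 else -1.0
        chosen[remaining[idx]] = (pairs[j % len(pairs)], sign * config.deg_log2fc)

    lfc_matrix = np.zeros((n_genes, len(config.samples)))
    for gid, (pair, lfc) in chosen.items():
        gi = gene_ids.index(gid)
        for si, (_sample, group) in enumerate(config.samples):
            if group == pair[1]:
                lfc_matrix[gi, si] = lfc
        deg_rows.append((gid, pair, lfc))

    mean = base_mean[:, None] * size_factors[None, :] * 2.0 ** lfc_matrix
    r_expr = 1.0 / max(config.nb_dispersion, 1e-12)
    counts = rng.negative_binomial(r_expr, r_expr / (r_expr + mean))
    matrix = pd.DataFrame(
        counts, index=pd.Index(gene_ids, name="gene_id"),
        columns=[s for s, _ in config.samples],
    )
    sf = {s: float(f) for (s, _g), f in zip(config.samples, size_factors)}
    return matrix, TruthSet(deg_table=sorted(deg_rows), size_factors=sf)


# -- file emission ---------------------------------------------------------

REPORT_COLUMNS = ["chrom", "pos", "strand", "m", "u", "context", "tri"]


def write_cytosine_report(report: pd.DataFrame, path) -> None:
    report[REPORT_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def write_counts(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t")


def simulate_all(config: SimConfig, out_dir) -> dict:
    """Run the full simulation and write every artifact under ``out_dir``.

    Emits genes.gtf, cgi/repeats/promoters/shores BEDs, chrom.sizes, one
    ``<sample>.CX_report.txt`` per sample, counts.tsv, samples.tsv and
    truth.json.  Returns a manifest of paths.
    """
    from .annotation import write_catalog

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    catalog = build_toy_annotation(config)
    paths = write_catalog(catalog, out)

    reports, meth_truth = simulate_methylome(config, catalog)
    for sample, report in reports.items():
        p = out / f"{sample}.CX_report.txt"
        write_cytosine_report(report, p)
        paths[f"report:{sample}"] = str(p)

    counts, expr_truth = simulate_expression(config, catalog, meth_truth)
    write_counts(counts, out / "counts.tsv")
    paths["counts"] = str(out / "counts.tsv")

    sheet = out / "samples.tsv"
    pd.DataFrame(config.samples, columns=["sample", "group"]).to_csv(
        sheet, sep="\t", index=False
    )
    paths["samples"] = str(sheet)

    truth = TruthSet(
        meth_truth.dmr_intervals, expr_truth.deg_table, expr_truth.size_factors
    )
    (out / "truth.json").write_text(truth.to_json())
    paths["truth"] = str(out / "truth.json")
    (out / "sim_config.json").write_text(
        json.dumps(dataclasses.asdict(config), default=list, indent=1)
    )
    return paths
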