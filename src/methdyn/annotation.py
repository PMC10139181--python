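"""Genomic feature catalogs and feature/gene assignment.

Coordinates are 0-based half-open everywhere inside the package; file
interchange converts at the boundary (GTF emitted 1-based inclusive, BED
0-based half-open).  The feature vocabulary is the eight classes evaluated
throughout: CpG islands (``cgi``), CGI shores (``shore``), ``promoter``,
``utr5``, ``utr3``, ``exon``, ``intron`` and ``repeat``.

A promoter is the 1 kb upstream of the transcription start site through the
TSS base itself, strand-aware.  Shores are the 2 kb flanks of each CGI,
clipped at neighbouring CGIs and chromosome ends.  A query is associated
with a gene when it falls within the gene span extended by ``flank``
(default 1 kb) on both sides — i.e. 1 kb upstream of the TSS or 1 kb
downstream of the TTS.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

FEATURE_LABELS = ("cgi", "shore", "promoter", "utr5", "utr3", "exon", "intron", "repeat")

#: priority used when a single label per query is requested
FEATURE_PRIORITY = ("promoter", "utr5", "exon", "utr3", "intron", "repeat", "shore", "cgi")

#: labels counted as gene body for concordance classification
GENE_BODY_LABELS = frozenset({"Exon", "Intron"})

PROMOTER_SIZE = 1000
SHORE_SIZE = 2000
GENE_FLANK = 1000


@dataclass
class GeneModel:
    """One gene: span, strand and exon structure (0-based half-open)."""

    gene_id: str
    gene_name: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: list[tuple[int, int]] = field(default_factory=list)
    utr5: list[tuple[int, int]] = field(default_factory=list)
    utr3: list[tuple[int, int]] = field(default_factory=list)

    @property
    def tss(self) -> int:
        """0-based position of the transcription start site base."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def tts(self) -> int:
        """0-based position of the transcription termination site base."""
        return self.end - 1 if self.strand == "+" else self.start

    @property
    def introns(self) -> list[tuple[int, int]]:
        """Gene span minus exons, as maximal gaps between sorted exons."""
        out = []
        exons = sorted(self.exons)
        for (s1, e1), (s2, _) in zip(exons, exons[1:]):
            if s2 > e1:
                out.append((e1, s2))
        return out

    def promoter(self, size: int = PROMOTER_SIZE) -> tuple[int, int]:
        """``size`` bp upstream of the TSS through the TSS base, strand-aware."""
        if self.strand == "+":
            return max(0, self.tss - size), self.tss + 1
        return self.tss, self.tss + size + 1


class FeatureCatalog:
    """Chromosome sizes, gene models and the derived/imported feature intervals."""

    def __init__(
        self,
        chrom_sizes: dict[str, int],
        genes: list[GeneModel] | None = None,
        cgi: list[tuple[str, int, int]] | None = None,
        repeats: list[tuple[str, int, int]] | None = None,
    ):
        self.chrom_sizes = dict(chrom_sizes)
        self.genes: dict[str, GeneModel] = {}
        for g in genes or []:
            if g.gene_id in self.genes:
                raise ValueError(f"duplicate gene id {g.gene_id}")
            self.genes[g.gene_id] = g
        self.cgi = sorted(cgi or [])
        self.repeats = sorted(repeats or [])
        self._validate()
        self._features = self._collect_features()
        self._trees = self._build_trees()
        self._gene_trees = self._build_gene_trees()

    # -- construction ------------------------------------------------------

    def _validate(self) -> None:
        errors = []
        for g in self.genes.values():
            if g.chrom not in self.chrom_sizes:
                errors.append(f"{g.gene_id}: unknown chromosome {g.chrom}")
                continue
            size = self.chrom_sizes[g.chrom]
            if not (0 <= g.start < g.end <= size):
                errors.append(f"{g.gene_id}: span {g.start}-{g.end} outside [0,{size})")
            for s, e in g.exons:
                if not (g.start <= s < e <= g.end):
                    errors.append(f"{g.gene_id}: exon {s}-{e} outside gene span")
        for name, ivs in (("cgi", self.cgi), ("repeat", self.repeats)):
            for chrom, s, e in ivs:
                if chrom not in self.chrom_sizes:
                    errors.append(f"{name} {chrom}:{s}-{e}: unknown chromosome")
                elif not (0 <= s < e <= self.chrom_sizes[chrom]):
                    errors.append(f"{name} {chrom}:{s}-{e}: outside chromosome bounds")
        if errors:
            raise ValueError("invalid catalog:\n" + "\n".join(errors))

    def _shores(self) -> list[tuple[str, int, int]]:
        """2 kb flanks of every CGI, clipped at neighbouring CGIs and chrom ends."""
        shores = []
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, s, e in self.cgi:
            by_chrom.setdefault(chrom, []).append((s, e))
        for chrom, ivs in by_chrom.items():
            ivs = sorted(ivs)
            size = self.chrom_sizes[chrom]
            for i, (s, e) in enumerate(ivs):
                left = max(0, s - SHORE_SIZE)
                if i > 0:
                    left = max(left, ivs[i - 1][1])
                right = min(size, e + SHORE_SIZE)
                if i + 1 < len(ivs):
                    right = min(right, ivs[i + 1][0])
                if left < s:
                    shores.append((chrom, left, s))
                if e < right:
                    shores.append((chrom, e, right))
        return shores

    def _collect_features(self) -> dict[str, list[tuple[str, int, int, str | None]]]:
        feats: dict[str, list] = {label: [] for label in FEATURE_LABELS}
        feats["cgi"] = [(c, s, e, None) for c, s, e in self.cgi]
        feats["repeat"] = [(c, s, e, None) for c, s, e in self.repeats]
        feats["shore"] = [(c, s, e, None) for c, s, e in self._shores()]
        for g in self.genes.values():
            s, e = g.promoter()
            e = min(e, self.chrom_sizes[g.chrom])
            feats["promoter"].append((g.chrom, s, e, g.gene_id))
            for a, b in g.exons:
                feats["exon"].append((g.chrom, a, b, g.gene_id))
            for a, b in g.introns:
                feats["intron"].append((g.chrom, a, b, g.gene_id))
            for a, b in g.utr5:
                feats["utr5"].append((g.chrom, a, b, g.gene_id))
            for a, b in g.utr3:
                feats["utr3"].append((g.chrom, a, b, g.gene_id))
        return feats

    def _build_trees(self) -> dict[tuple[str, str], IntervalTree]:
        trees: dict[tuple[str, str], IntervalTree] = {}
        for label, ivs in self._features.items():
            for chrom, s, e, gid in ivs:
                trees.setdefault((label, chrom), IntervalTree()).addi(s, e, gid)
        return trees

    def _build_gene_trees(self) -> dict[str, IntervalTree]:
        trees: dict[str, IntervalTree] = {}
        for g in self.genes.values():
            trees.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end, g.gene_id)
        return trees

    # -- queries -----------------------------------------------------------

    def membership(self, label: str, chrom: str, positions: np.ndarray) -> np.ndarray:
        """Vectorized point-in-feature test (0-based positions)."""
        key = (label, chrom)
        if not hasattr(self, "_merged"):
            self._merged: dict = {}
        if key not in self._merged:
            ivs = sorted(
                (s, e) for c, s, e, _g in self._features[label] if c == chrom
            )
            merged: list[list[int]] = []
            for s, e in ivs:
                if merged and s <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], e)
                else:
                    merged.append([s, e])
            starts = np.array([s for s, _ in merged], dtype=np.int64)
            ends = np.array([e for _, e in merged], dtype=np.int64)
            self._merged[key] = (starts, ends)
        starts, ends = self._merged[key]
        positions = np.asarray(positions)
        if len(starts) == 0:
            return np.zeros(positions.shape, dtype=bool)
        idx = np.searchsorted(starts, positions, side="right") - 1
        ok = idx >= 0
        out = np.zeros(positions.shape, dtype=bool)
        out[ok] = positions[ok] < ends[idx[ok]]
        return out

    def feature_intervals(self, label: str) -> list[tuple[str, int, int, str | None]]:
        if label not in FEATURE_LABELS:
            raise KeyError(f"unknown feature label {label!r}")
        return list(self._features[label])

    def overlapping(self, label: str, chrom: str, start: int, end: int):
        """(start, end, gene_id) of every ``label`` interval hit by the query."""
        tree = self._trees.get((label, chrom))
        if tree is None:
            return []
        return [(iv.begin, iv.end, iv.data) for iv in tree.overlap(start, end)]


@dataclass
class FeatureAssignment:
    """All feature labels (and gene associations) intersected by one query."""

    chrom: str
    start: int
    end: int
    labels: set[str]
    gene_ids: set[str]


def associate_gene(
    query: tuple[str, int, int], catalog: FeatureCatalog, flank: int = GENE_FLANK
) -> set[str]:
    """Genes whose span extended by ``flank`` bp both ways intersects the query.

    This is the 1 kb upstream-of-TSS / downstream-of-TTS association rule;
    several genes may match.
    """
    chrom, start, end = query
    tree = catalog._gene_trees.get(chrom)
    if tree is None:
        return set()
    return {iv.data for iv in tree.overlap(start - flank, end + flank)}


def assign_features(
    query: tuple[str, int, int],
    catalog: FeatureCatalog,
    single_label: bool = False,
) -> FeatureAssignment:
    """All feature labels intersected by a query interval (multi-label).

    A query spanning an exon–intron junction counts in both categories.
    With ``single_label=True`` only the highest-priority label is kept
    (promoter > utr5 > exon > utr3 > intron > repeat > shore > cgi).
    """
    chrom, start, end = query
    labels = {
        label
        for label in FEATURE_LABELS
        if catalog.overlapping(label, chrom, start, end)
    }
    if single_label and labels:
        labels = {next(lbl for lbl in FEATURE_PRIORITY if lbl in labels)}
    return FeatureAssignment(
        chrom, start, end, labels, associate_gene(query, catalog)
    )


def region_labels_for_gene(
    query: tuple[str, int, int],
    gene: GeneModel,
    catalog: FeatureCatalog,
    flank: int = GENE_FLANK,
) -> list[str]:
    """Table-style region labels of a query relative to one gene.

    Labels: Promoter, Utr5, Exon, Intron, Utr3, plus TSS / TES when the
    query overlaps TSS±flank / TTS±flank.
    """
    chrom, start, end = query
    if chrom != gene.chrom:
        return []
    labels = []
    pieces = [
        ("Promoter", [gene.promoter()]),
        ("Utr5", gene.utr5),
        ("Exon", gene.exons),
        ("Intron", gene.introns),
        ("Utr3", gene.utr3),
    ]
    for label, ivs in pieces:
        if any(start < e and s < end for s, e in ivs):
            labels.append(label)
    if start < gene.tss + flank + 1 and gene.tss - flank < end:
        labels.append("TSS")
    if start < gene.tts + flank + 1 and gene.tts - flank < end:
        labels.append("TES")
    return labels


# -- file I/O --------------------------------------------------------------


def read_chrom_sizes(path) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "size"])
    return dict(zip(df["chrom"].astype(str), df["size"].astype(int)))


def read_bed(path) -> list[tuple[str, int, int]]:
    """BED intervals (first three columns, 0-based half-open)."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            out.append((parts[0], int(parts[1]), int(parts[2])))
    return out


def load_annotation(gtf_path, cgi_bed, repeat_bed, chrom_sizes_path) -> FeatureCatalog:
    """Build a catalog from a GTF plus CGI/repeat BEDs and a chrom.sizes table.

    Promoters, introns and shores are derived here; the GTF supplies gene,
    exon and UTR records.
    """
    import gffutils

    db = gffutils.create_db(
        str(gtf_path),
        ":memory:",
        force=True,
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    genes: dict[str, GeneModel] = {}
    for feat in db.all_features():
        gid = feat.attributes.get("gene_id", [None])[0]
        if gid is None:
            continue
        if feat.featuretype == "gene":
            name = feat.attributes.get("gene_name", [gid])[0]
            genes[gid] = GeneModel(
                gid, name, feat.seqid, feat.strand, feat.start - 1, feat.end
            )
    for feat in db.all_features():
        gid = feat.attributes.get("gene_id", [None])[0]
        if gid not in genes:
            continue
        iv = (feat.start - 1, feat.end)
        if feat.featuretype == "exon":
            genes[gid].exons.append(iv)
        elif feat.featuretype == "five_prime_utr":
            genes[gid].utr5.append(iv)
        elif feat.featuretype == "three_prime_utr":
            genes[gid].utr3.append(iv)
    return FeatureCatalog(
        read_chrom_sizes(chrom_sizes_path),
        genes=list(genes.values()),
        cgi=read_bed(cgi_bed) if cgi_bed else [],
        repeats=read_bed(repeat_bed) if repeat_bed else [],
    )


def write_catalog(catalog: FeatureCatalog, out_dir) -> dict[str, str]:
    """Emit genes.gtf, cgi.bed, repeats.bed, promoters.bed, shores.bed, chrom.sizes."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    gtf = out / "genes.gtf"
    with open(gtf, "w") as fh:
        for g in sorted(catalog.genes.values(), key=lambda g: (g.chrom, g.start)):
            attrs = f'gene_id "{g.gene_id}"; gene_name "{g.gene_name}";'
            rows = [("gene", g.start, g.end)]
            rows += [("exon", s, e) for s, e in sorted(g.exons)]
            rows += [("five_prime_utr", s, e) for s, e in sorted(g.utr5)]
            rows += [("three_prime_utr", s, e) for s, e in sorted(g.utr3)]
            for ftype, s, e in rows:
                fh.write(
                    f"{g.chrom}\ttoy\t{ftype}\t{s + 1}\t{e}\t.\t{g.strand}\t.\t{attrs}\n"
                )
    paths["gtf"] = str(gtf)

    for name, label in (
        ("cgi", "cgi"),
        ("repeats", "repeat"),
        ("promoters", "promoter"),
        ("shores", "shore"),
    ):
        path = out / f"{name}.bed"
        with open(path, "w") as fh:
            for chrom, s, e, gid in sorted(catalog.feature_intervals(label)):
                fh.write(f"{chrom}\t{s}\t{e}\t{gid or name}\t0\t+\n")
        paths[name] = str(path)

    sizes = out / "chrom.sizes"
    with open(sizes, "w") as fh:
        for chrom, size in catalog.chrom_sizes.items():
            fh.write(f"{chrom}\t{size}\n")
    paths["chrom_sizes"] = str(sizes)
    return paths


# -- feature methylation profiles and stage statistics ---------------------


def feature_methylation_profile(
    calls_by_sample: dict[str, pd.DataFrame],
    catalog: FeatureCatalog,
    min_depth: int = 5,
) -> pd.DataFrame:
    """Mean per-site methylation percentage per feature per sample.

    For each of the eight features and each sample, the unweighted mean of
    per-site methylation fractions over tested sites (depth >= ``min_depth``)
    inside the feature, times 100.  Features with no tested site give NaN
    (absence, not zero).
    """
    rows = []
    for sample, calls in calls_by_sample.items():
        tested = calls[(calls["m"] + calls["u"]) >= min_depth]
        frac = (tested["m"] / (tested["m"] + tested["u"])).to_numpy()
        chrom_arr = tested["chrom"].to_numpy()
        pos0 = tested["pos"].to_numpy() - 1  # 1-based report -> 0-based
        for label in FEATURE_LABELS:
            hit = np.zeros(len(tested), dtype=bool)
            for chrom in np.unique(chrom_arr):
                sel = chrom_arr == chrom
                hit[sel] = catalog.membership(label, chrom, pos0[sel])
            rows.append(
                {
                    "sample": sample,
                    "feature": label,
                    "n_sites": int(hit.sum()),
                    "meth_pct": float(np.mean(frac[hit]) * 100) if hit.any() else np.nan,
                }
            )
    return pd.DataFrame(rows)


def _dunn_pairwise(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    """Dunn's post-hoc z statistics on joint ranks, Bonferroni-adjusted."""
    names = list(groups)
    values = np.concatenate([np.asarray(groups[k], dtype=float) for k in names])
    sizes = [len(groups[k]) for k in names]
    ranks = stats.rankdata(values)
    n = len(values)
    # tie correction term for the rank variance
    _, counts = np.unique(values, return_counts=True)
    tie_term = (counts**3 - counts).sum() / (12 * (n - 1)) if n > 1 else 0.0
    mean_ranks = {}
    offset = 0
    for name, size in zip(names, sizes):
        mean_ranks[name] = ranks[offset : offset + size].mean()
        offset += size
    rows = []
    n_pairs = len(names) * (len(names) - 1) // 2
    for a, b in itertools.combinations(names, 2):
        na, nb = len(groups[a]), len(groups[b])
        sigma = np.sqrt((n * (n + 1) / 12 - tie_term) * (1 / na + 1 / nb))
        z = (mean_ranks[b] - mean_ranks[a]) / sigma
        p = 2 * stats.norm.sf(abs(z))
        rows.append(
            {
                "group_a": a,
                "group_b": b,
                "z": float(z),
                "p_value": float(p),
                "p_adj": float(min(1.0, p * n_pairs)),
            }
        )
    return pd.DataFrame(rows)


def group_stats(profile: pd.DataFrame, sample_groups: dict[str, str]) -> dict:
    """Descriptive statistics of feature methylation across stages.

    Returns Shapiro–Wilk normality per (feature, stage) variable, pairwise
    t statistics between stages per feature, one-way ANOVA across features,
    and Kruskal–Wallis plus Dunn pairwise z across stages per feature.
    Groups with fewer than 3 observations skip the normality test with a
    warning.
    """
    df = profile.dropna(subset=["meth_pct"]).copy()
    df["stage"] = df["sample"].map(sample_groups)
    report: dict = {"shapiro": [], "t_tests": [], "dunn": {}, "kruskal": {}}

    for (feature, stage), sub in df.groupby(["feature", "stage"]):
        vals = sub["meth_pct"].to_numpy()
        if len(vals) < 3:
            warnings.warn(
                f"normality test skipped for {feature}/{stage}: "
                f"only {len(vals)} observations",
                stacklevel=2,
            )
            continue
        if np.ptp(vals) == 0:
            continue  # Shapiro undefined for constant input
        w, p = stats.shapiro(vals)
        report["shapiro"].append(
            {"feature": feature, "stage": stage, "W": float(w), "p_value": float(p)}
        )

    stages = sorted(set(sample_groups.values()))
    for feature, sub in df.groupby("feature"):
        by_stage = {
            st: sub.loc[sub["stage"] == st, "meth_pct"].to_numpy() for st in stages
        }
        by_stage = {k: v for k, v in by_stage.items() if len(v) > 0}
        for a, b in itertools.combinations(sorted(by_stage), 2):
            if len(by_stage[a]) < 2 or len(by_stage[b]) < 2:
                continue
            t, p = stats.ttest_ind(by_stage[a], by_stage[b])
            report["t_tests"].append(
                {
                    "feature": feature,
                    "stage_a": a,
                    "stage_b": b,
                    "t": float(t),
                    "p_value": float(p),
                }
            )
        if len(by_stage) >= 2 and all(len(v) >= 2 for v in by_stage.values()):
            h, hp = stats.kruskal(*by_stage.values())
            report["kruskal"][feature] = {"H": float(h), "p_value": float(hp)}
            report["dunn"][feature] = _dunn_pairwise(by_stage)

    by_feature = [
        grp["meth_pct"].to_numpy()
        for _, grp in df.groupby("feature")
        if len(grp) >= 2
    ]
    if len(by_feature) >= 2:
        f, p = stats.f_oneway(*by_feature)
        report["anova_features"] = {"F": float(f), "p_value": float(p)}
    return report


def shapiro_wilk(values) -> tuple[float, float]:
    """Shapiro–Wilk W and p for one variable."""
    w, p = stats.shapiro(np.asarray(values, dtype=float))
    return float(w), float(p)


def dunn_test(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    """Public wrapper: Dunn pairwise rank comparisons across named groups."""
    return _dunn_pairwise({k: np.asarray(v, dtype=float) for k, v in groups.items()})
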