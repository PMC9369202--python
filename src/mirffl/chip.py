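"""ChIP-seq peak consolidation and candidate target assignment.

Consolidates replicate peak calls into high-confidence binding sites and
assigns them to genes through a strand-oriented promoter window running from
3 kb upstream of the TSS to 1 kb downstream of the TTS.  The merge rule is
summit-distance based: overlapping peaks merge when their summits are within
600 bp, non-overlapping peaks when within 300 bp, applied as a transitive
closure so that chains of nearby peaks collapse into one consolidated peak.

Coordinates are 0-based half-open internally; BED I/O keeps that convention
and GFF3 I/O converts from/to 1-based inclusive at the boundary.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

REGION_UPSTREAM = "upstream"
REGION_GENIC = "genic"
REGION_DOWNSTREAM = "downstream"
REGION_INTERGENIC = "intergenic"


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Peak:
    """A single called peak with its summit (absolute bp) and -log10 p-value."""

    chrom: str
    start: int
    end: int
    summit: int
    neg_log10_p: float
    replicate: str = ""
    name: str = ""

    def __post_init__(self) -> None:
        if not (self.start <= self.summit < self.end):
            raise ValueError(
                f"peak {self.name or self.chrom}: summit {self.summit} outside "
                f"[{self.start}, {self.end})"
            )
        if self.neg_log10_p < 0:
            raise ValueError("neg_log10_p must be >= 0")


@dataclass(frozen=True)
class MergedPeak:
    """A consolidated peak: union span, summit of the most significant member."""

    chrom: str
    start: int
    end: int
    summit: int
    best_neg_log10_p: float
    member_count: int = 1
    replicates_supporting: frozenset[str] = field(default_factory=frozenset)


@dataclass
class ChipParams:
    """Merge distances, replicate-support distance, significance threshold and
    the candidate-target window sizes (bp)."""

    overlap_merge_dist: int = 600
    gap_merge_dist: int = 300
    replicate_support_dist: int = 600
    p_threshold: float = 1e-5
    upstream_window: int = 3000
    downstream_window: int = 1000

    def __post_init__(self) -> None:
        for f in ("overlap_merge_dist", "gap_merge_dist", "replicate_support_dist",
                  "upstream_window", "downstream_window"):
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be >= 0")
        if not 0 < self.p_threshold <= 1:
            raise ValueError("p_threshold must be in (0, 1]")


@dataclass(frozen=True)
class GeneModel:
    """A gene or miRNA-gene locus; TSS/TTS follow the strand."""

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    biotype: str = "protein_coding"

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: strand must be + or -")
        if not self.start < self.end:
            raise ValueError(f"{self.gene_id}: start must be < end")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def tts(self) -> int:
        return self.end - 1 if self.strand == "+" else self.start


@dataclass(frozen=True)
class TargetAssignment:
    """One (gene, peak) candidate-target link; distance is signed in gene
    orientation, negative upstream of the TSS."""

    gene_id: str
    peak: MergedPeak
    summit_to_tss: int
    region_class: str


# ---------------------------------------------------------------------------
# Merging
# ---------------------------------------------------------------------------

class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def _pair_merges(a: Peak | MergedPeak, b: Peak | MergedPeak, params: ChipParams) -> bool:
    overlap = a.start < b.end and b.start < a.end
    d = abs(a.summit - b.summit)
    if overlap:
        return d <= params.overlap_merge_dist
    return d <= params.gap_merge_dist


def merge_peaks(peaks: list[Peak], params: ChipParams | None = None) -> list[MergedPeak]:
    """Merge peaks of one replicate by the summit-distance rule.

    Two peaks merge iff (spans overlap and summits within
    ``overlap_merge_dist``) or (spans disjoint and summits within
    ``gap_merge_dist``); merging is the transitive closure of this pairwise
    relation, so it is independent of input order and idempotent.  The merged
    summit and significance come from the most significant member (ties
    broken toward the leftmost summit).
    """
    params = params or ChipParams()
    if not peaks:
        return []
    order = sorted(range(len(peaks)), key=lambda i: (peaks[i].chrom, peaks[i].summit))
    uf = _UnionFind(len(peaks))
    window = max(params.overlap_merge_dist, params.gap_merge_dist)
    for a_pos, i in enumerate(order):
        pi = peaks[i]
        for j in order[a_pos + 1:]:
            pj = peaks[j]
            if pj.chrom != pi.chrom or pj.summit - pi.summit > window:
                break
            if _pair_merges(pi, pj, params):
                uf.union(i, j)
    groups: dict[int, list[Peak]] = {}
    for i in range(len(peaks)):
        groups.setdefault(uf.find(i), []).append(peaks[i])
    merged = []
    for members in groups.values():
        best = max(members, key=lambda p: (p.neg_log10_p, -p.summit))
        reps = frozenset(p.replicate for p in members if p.replicate)
        merged.append(MergedPeak(
            chrom=members[0].chrom,
            start=min(p.start for p in members),
            end=max(p.end for p in members),
            summit=best.summit,
            best_neg_log10_p=best.neg_log10_p,
            member_count=len(members),
            replicates_supporting=reps,
        ))
    merged.sort(key=lambda m: (m.chrom, m.start, m.summit))
    return merged


def high_confidence_peaks(
    rep1: list[MergedPeak],
    rep2: list[MergedPeak],
    params: ChipParams | None = None,
) -> list[MergedPeak]:
    """Keep rep1 peaks reproduced in rep2 (summits within
    ``replicate_support_dist``), union the span with the nearest supporting
    partner, then filter to ``best_neg_log10_p > -log10(p_threshold)``."""
    params = params or ChipParams()
    if not rep1 or not rep2:
        logger.warning("high_confidence_peaks: empty replicate, returning no peaks")
        return []
    by_chrom: dict[str, list[MergedPeak]] = {}
    for p in rep2:
        by_chrom.setdefault(p.chrom, []).append(p)
    for chrom in by_chrom:
        by_chrom[chrom].sort(key=lambda p: p.summit)

    cutoff = -math.log10(params.p_threshold)
    out: list[MergedPeak] = []
    seen: set[tuple] = set()
    for p in rep1:
        partners = by_chrom.get(p.chrom, [])
        best_partner = None
        for q in partners:
            d = abs(q.summit - p.summit)
            if d <= params.replicate_support_dist:
                key = (d, q.summit)
                if best_partner is None or key < (abs(best_partner.summit - p.summit),
                                                  best_partner.summit):
                    best_partner = q
        if best_partner is None:
            continue
        hc = MergedPeak(
            chrom=p.chrom,
            start=min(p.start, best_partner.start),
            end=max(p.end, best_partner.end),
            summit=p.summit,
            best_neg_log10_p=max(p.best_neg_log10_p, best_partner.best_neg_log10_p),
            member_count=p.member_count + best_partner.member_count,
            replicates_supporting=p.replicates_supporting | best_partner.replicates_supporting,
        )
        if hc.best_neg_log10_p <= cutoff:
            continue
        ident = (hc.chrom, hc.start, hc.end, hc.summit)
        if ident not in seen:
            seen.add(ident)
            out.append(hc)
    out.sort(key=lambda m: (m.chrom, m.start, m.summit))
    return out


# ---------------------------------------------------------------------------
# Target assignment and summaries
# ---------------------------------------------------------------------------

def _gene_window(gene: GeneModel, params: ChipParams) -> tuple[int, int]:
    """Genomic (inclusive) candidate-target window: TSS-3kb .. TTS+1kb in
    gene orientation."""
    if gene.strand == "+":
        return gene.start - params.upstream_window, gene.end - 1 + params.downstream_window
    return gene.start - params.downstream_window, gene.end - 1 + params.upstream_window


def _summit_to_tss(gene: GeneModel, summit: int) -> int:
    return summit - gene.tss if gene.strand == "+" else gene.tss - summit


def _region_class(gene: GeneModel, summit: int) -> str:
    if gene.start <= summit < gene.end:
        return REGION_GENIC
    before = summit < gene.start
    if gene.strand == "+":
        return REGION_UPSTREAM if before else REGION_DOWNSTREAM
    return REGION_DOWNSTREAM if before else REGION_UPSTREAM


def assign_candidate_targets(
    hc_peaks: list[MergedPeak],
    genes: list[GeneModel],
    params: ChipParams | None = None,
) -> list[TargetAssignment]:
    """Assign each high-confidence summit to every gene whose strand-oriented
    window [TSS - upstream_window, TTS + downstream_window] contains it."""
    params = params or ChipParams()
    _warn_overlapping(genes)
    out: list[TargetAssignment] = []
    for gene in genes:
        lo, hi = _gene_window(gene, params)
        for p in hc_peaks:
            if p.chrom == gene.chrom and lo <= p.summit <= hi:
                out.append(TargetAssignment(
                    gene_id=gene.gene_id,
                    peak=p,
                    summit_to_tss=_summit_to_tss(gene, p.summit),
                    region_class=_region_class(gene, p.summit),
                ))
    return out


def _warn_overlapping(genes: list[GeneModel]) -> None:
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for chrom, gs in by_chrom.items():
        gs = sorted(gs, key=lambda g: g.start)
        for a, b in zip(gs, gs[1:]):
            if b.start < a.end:
                logger.warning("genes %s and %s overlap on %s", a.gene_id, b.gene_id, chrom)
                return


def peak_location_profile(
    hc_peaks: list[MergedPeak],
    genes: list[GeneModel],
    anchor: str = "TSS",
    flank: int = 3000,
    bin: int = 100,
    params: ChipParams | None = None,
) -> dict:
    """Histogram of nearest-summit distances to the TSS (or TTS) per gene.

    Returns bin edges and counts over [-flank, flank) plus the fraction of
    candidate-target genes whose nearest summit lies within +-500 bp of the
    TSS (the headline promoter-proximality statistic).
    """
    if bin <= 0:
        raise ValueError("bin must be > 0")
    if flank % bin != 0:
        raise ValueError("flank must be a multiple of bin")
    params = params or ChipParams()
    lists: dict[str, list[int]] = {}
    for p in hc_peaks:
        lists.setdefault(p.chrom, []).append(p.summit)
    summits_by_chrom = {c: np.sort(np.asarray(v)) for c, v in lists.items()}

    distances = {}
    for gene in genes:
        summits = summits_by_chrom.get(gene.chrom)
        if summits is None or len(summits) == 0:
            continue
        pos = gene.tss if anchor == "TSS" else gene.tts
        signed = (summits - pos) if gene.strand == "+" else (pos - summits)
        distances[gene.gene_id] = signed[np.argmin(np.abs(signed))]

    edges = np.arange(-flank, flank + bin, bin)
    in_window = [d for d in distances.values() if -flank <= d < flank]
    counts, _ = np.histogram(in_window, bins=edges)

    assigned = {a.gene_id for a in assign_candidate_targets(hc_peaks, genes, params)}
    near = [g for g in assigned if g in distances and abs(distances[g]) <= 500]
    frac = len(near) / len(assigned) if assigned else float("nan")
    return {
        "bin_edges": edges,
        "counts": counts,
        "n_genes_profiled": len(distances),
        "n_assigned": len(assigned),
        "fraction_within_500bp_tss": frac,
    }


def genic_distribution(
    hc_peaks: list[MergedPeak],
    genes: list[GeneModel],
    params: ChipParams | None = None,
) -> dict[str, float]:
    """Classify each summit as upstream / genic / downstream / intergenic
    relative to the nearest gene window; returns fractions summing to 1.

    Precedence when windows of distinct genes collide is
    upstream > genic > downstream; within a class, the gene with the smaller
    |summit - TSS| wins (this only picks the gene, not the class).
    """
    params = params or ChipParams()
    counts = {REGION_UPSTREAM: 0, REGION_GENIC: 0, REGION_DOWNSTREAM: 0, REGION_INTERGENIC: 0}
    for p in hc_peaks:
        candidates: list[tuple[str, int]] = []
        for gene in genes:
            if gene.chrom != p.chrom:
                continue
            cls = _candidate_class(gene, p.summit, params)
            if cls is not None:
                candidates.append((cls, abs(_summit_to_tss(gene, p.summit))))
        counts[_pick_class(candidates)] += 1
    total = max(1, len(hc_peaks))
    return {k: v / total for k, v in counts.items()}


def _candidate_class(gene: GeneModel, summit: int, params: ChipParams) -> str | None:
    if gene.start <= summit < gene.end:
        return REGION_GENIC
    d = _summit_to_tss(gene, summit)
    if -params.upstream_window <= d < 0:
        return REGION_UPSTREAM
    # downstream window hangs off the TTS in gene orientation
    if gene.strand == "+":
        dd = summit - gene.tts
    else:
        dd = gene.tts - summit
    if 0 < dd <= params.downstream_window:
        return REGION_DOWNSTREAM
    return None


_PRECEDENCE = {REGION_UPSTREAM: 0, REGION_GENIC: 1, REGION_DOWNSTREAM: 2}


def _pick_class(candidates: list[tuple[str, int]]) -> str:
    if not candidates:
        return REGION_INTERGENIC
    candidates.sort(key=lambda ct: (_PRECEDENCE[ct[0]], ct[1]))
    return candidates[0][0]


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

PEAK_COLUMNS = ["chrom", "start", "end", "name", "neg_log10_p", "strand", "summit_offset"]


def read_peaks(path: str | Path, replicate: str = "") -> list[Peak]:
    """Read a MACS-style BED-like TSV: chrom, start, end, name, -log10 p,
    strand (unused, '.'), summit offset from start."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None, names=PEAK_COLUMNS)
    return [
        Peak(chrom=str(r.chrom), start=int(r.start), end=int(r.end),
             summit=int(r.start) + int(r.summit_offset),
             neg_log10_p=float(r.neg_log10_p), replicate=replicate, name=str(r.name))
        for r in df.itertuples()
    ]


def write_peaks(peaks: list[Peak], path: str | Path) -> None:
    rows = [(p.chrom, p.start, p.end, p.name or f"peak_{i}", p.neg_log10_p, ".",
             p.summit - p.start) for i, p in enumerate(peaks)]
    pd.DataFrame(rows, columns=PEAK_COLUMNS).to_csv(path, sep="\t", header=False, index=False)


def write_merged_peaks(peaks: list[MergedPeak], path: str | Path) -> None:
    rows = [(p.chrom, p.start, p.end, f"merged_{i}", p.best_neg_log10_p, ".",
             p.summit - p.start, p.member_count, ",".join(sorted(p.replicates_supporting)))
            for i, p in enumerate(peaks)]
    pd.DataFrame(rows, columns=PEAK_COLUMNS + ["member_count", "replicates"]).to_csv(
        path, sep="\t", index=False)


def read_merged_peaks(path: str | Path) -> list[MergedPeak]:
    df = pd.read_csv(path, sep="\t")
    return [
        MergedPeak(chrom=str(r.chrom), start=int(r.start), end=int(r.end),
                   summit=int(r.start) + int(r.summit_offset),
                   best_neg_log10_p=float(r.neg_log10_p),
                   member_count=int(r.member_count),
                   replicates_supporting=frozenset(
                       str(r.replicates).split(",")) if str(r.replicates) != "nan" else frozenset())
        for r in df.itertuples()
    ]


def write_assignments(assignments: list[TargetAssignment], path: str | Path) -> None:
    rows = [(a.gene_id, a.peak.chrom, a.peak.start, a.peak.end, a.peak.summit,
             a.summit_to_tss, a.region_class) for a in assignments]
    pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "summit",
                                "summit_to_tss", "region_class"]).to_csv(
        path, sep="\t", index=False)


def read_gff3_genes(path: str | Path) -> list[GeneModel]:
    """Read gene models from GFF3 (1-based inclusive -> 0-based half-open)."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None,
                     names=["seqid", "source", "type", "start", "end", "score",
                            "strand", "phase", "attributes"])
    genes = []
    for r in df.itertuples():
        if r.type not in ("gene", "miRNA_gene"):
            continue
        attrs = dict(kv.split("=", 1) for kv in str(r.attributes).split(";") if "=" in kv)
        genes.append(GeneModel(
            gene_id=attrs.get("ID", f"{r.seqid}:{r.start}"),
            chrom=str(r.seqid), strand=str(r.strand),
            start=int(r.start) - 1, end=int(r.end),
            biotype=attrs.get("biotype", "protein_coding"),
        ))
    return genes


def write_gff3_genes(genes: list[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            ftype = "miRNA_gene" if g.biotype == "miRNA_gene" else "gene"
            fh.write(f"{g.chrom}\tmirffl\t{ftype}\t{g.start + 1}\t{g.end}\t.\t"
                     f"{g.strand}\t.\tID={g.gene_id};biotype={g.biotype}\n")


def write_gene_table(genes: list[GeneModel], path: str | Path) -> None:
    """Tabular gene models, 0-based half-open."""
    rows = [(g.gene_id, g.chrom, g.strand, g.start, g.end, g.biotype) for g in genes]
    pd.DataFrame(rows, columns=["gene_id", "chrom", "strand", "start", "end",
                                "biotype"]).to_csv(path, sep="\t", index=False)


def read_gene_table(path: str | Path) -> list[GeneModel]:
    df = pd.read_csv(path, sep="\t")
    return [GeneModel(gene_id=str(r.gene_id), chrom=str(r.chrom), strand=str(r.strand),
                      start=int(r.start), end=int(r.end), biotype=str(r.biotype))
            for r in df.itertuples()]
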