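"""Synthetic regulatory-genomics data with planted ground truth.

Emulates the inputs of a TF loss-of-function study: gene/miRNA annotation,
two-replicate ChIP peak tables with summit jitter and noise peaks, promoter
sequences carrying a degenerate motif planted ~200 bp upstream of the TSS,
differential-expression tables in which planted repressed miRNAs go up and
planted activated targets go down, and a miRNA->target map embedding a
planted excess of coherent type-IV feed-forward loops among decoy edges.

Every generator is a pure function of (config, seed): each draws from its own
named random stream derived from the seed, so outputs are byte-identical
across runs and independent of the order in which generators are called.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .chip import GeneModel, Peak
from .motifs import IUPAC_SETS, PROMOTER_FLANK

# fixed geometry of the simulated genome
_PEAK_HALF_WIDTH = 150
_GENE_LEN_RANGE = (1000, 3000)
_MIRNA_LEN_RANGE = (120, 400)
_INTERGENIC_SPACER = 1000


class CapacityError(ValueError):
    """Raised when the requested features cannot be placed."""


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic experiment.

    Defaults describe one TF contrast: 200 protein-coding genes forming the
    target universe, 30 miRNA genes, 50 ChIP-bound loci, an 8-mer YTAATYAW
    motif planted at -200 +- 50 bp from the TSS, a log2 effect of 2.0 +- 0.3
    for planted features, and 40 planted coherent type-IV loops.
    """

    seed: int = 0
    n_chroms: int = 2
    chrom_length: int = 1_200_000
    n_genes: int = 200
    n_mirna_genes: int = 30
    n_bound_genes: int = 50
    summit_jitter_sd: float = 50.0
    n_noise_peaks_per_replicate: int = 10
    planted_motif: str = "YTAATYAW"
    motif_offset_mean: float = -200.0
    motif_offset_sd: float = 50.0
    lfc_effect_mean: float = 2.0
    lfc_effect_sd: float = 0.3
    null_lfc_sd: float = 0.25
    alpha_sig: float = 0.05
    n_planted_c4: int = 40
    n_planted_per_other_type: int = 0
    targets_per_mirna: int = 6
    planted_loops_per_mirna: int = 5
    bg_de_fraction: float = 0.0

    def __post_init__(self) -> None:
        counts = ("n_chroms", "chrom_length", "n_genes", "n_mirna_genes",
                  "n_bound_genes", "n_noise_peaks_per_replicate",
                  "n_planted_c4", "n_planted_per_other_type", "targets_per_mirna")
        for f in counts:
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be >= 0")
        if self.n_bound_genes > self.n_genes + self.n_mirna_genes:
            raise ValueError("n_bound_genes exceeds number of loci")
        if not 0 < self.alpha_sig < 1:
            raise ValueError("alpha_sig must be in (0, 1)")
        for sym in self.planted_motif:
            if sym not in IUPAC_SETS:
                raise ValueError(f"illegal IUPAC symbol {sym!r} in planted_motif")


@dataclass
class GroundTruth:
    """Planted structure: which loci are bound, where summits and motifs were
    planted, the true TF edge sign per feature, and the planted loops."""

    bound_gene_ids: list[str] = field(default_factory=list)
    planted_peak_summits: dict[str, int] = field(default_factory=dict)
    planted_motif_positions: dict[str, int] = field(default_factory=dict)
    edge_signs: dict[str, int] = field(default_factory=dict)
    planted_ffls: list[tuple[str, str, str]] = field(default_factory=list)
    mirna_gene_map: dict[str, str] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        d = asdict(self)
        d["planted_ffls"] = [list(t) for t in self.planted_ffls]
        Path(path).write_text(json.dumps(d, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        d["planted_ffls"] = [tuple(t) for t in d["planted_ffls"]]
        return cls(**d)


def _stream(cfg: SimulationConfig, name: str) -> np.random.Generator:
    # named stream: deterministic under seed, independent of call order
    return np.random.default_rng([cfg.seed, zlib.crc32(name.encode())])


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------

def simulate_annotation(cfg: SimulationConfig) -> tuple[list[GeneModel], GroundTruth]:
    """Place non-overlapping, strand-assigned gene models and pick the
    ChIP-bound loci with their planted motif offsets.

    Genes are laid out left to right with enough intergenic room that the
    TSS-3kb .. TTS+1kb candidate windows of neighbouring genes never overlap
    (upstream 3000 + downstream 1000 + spacer); a configuration that does not
    fit raises :class:`CapacityError` stating the required span.
    """
    rng = _stream(cfg, "annotation")
    n_total = cfg.n_genes + cfg.n_mirna_genes
    lengths = np.concatenate([
        rng.integers(*_GENE_LEN_RANGE, size=cfg.n_genes, endpoint=True),
        rng.integers(*_MIRNA_LEN_RANGE, size=cfg.n_mirna_genes, endpoint=True),
    ])
    is_mirna = np.zeros(n_total, bool)
    is_mirna[cfg.n_genes:] = True
    order = rng.permutation(n_total)
    strands = np.array(["+", "-"])[rng.integers(0, 2, size=n_total)]

    gap = 3000 + 1000 + _INTERGENIC_SPACER
    per_chrom = np.array_split(order, cfg.n_chroms)
    genes: list[GeneModel] = []
    gene_counter = mir_counter = 0
    truth = GroundTruth()
    for ci, idxs in enumerate(per_chrom):
        chrom = f"chr{ci + 1}"
        required = 3000 + int(lengths[idxs].sum()) + gap * len(idxs) + 1000
        if required > cfg.chrom_length:
            raise CapacityError(
                f"{chrom}: {len(idxs)} genes need {required} bp "
                f"(gene bodies + {gap} bp windows/spacer per gene) but "
                f"chrom_length is {cfg.chrom_length}")
        cursor = 3000
        for k in idxs:
            length = int(lengths[k])
            if is_mirna[k]:
                mir_counter += 1
                gid = f"MIR{mir_counter:03d}"
                truth.mirna_gene_map[f"miR{mir_counter:03d}"] = gid
                biotype = "miRNA_gene"
            else:
                gene_counter += 1
                gid = f"G{gene_counter:04d}"
                biotype = "protein_coding"
            genes.append(GeneModel(gene_id=gid, chrom=chrom, strand=str(strands[k]),
                                   start=cursor, end=cursor + length, biotype=biotype))
            cursor += length + gap

    bound_rng = _stream(cfg, "bound")
    all_ids = [g.gene_id for g in genes]
    bound = sorted(bound_rng.choice(all_ids, size=cfg.n_bound_genes, replace=False))
    truth.bound_gene_ids = list(bound)

    w = len(cfg.planted_motif)
    offset_rng = _stream(cfg, "motif_offsets")
    by_id = {g.gene_id: g for g in genes}
    for gid in bound:
        off = int(round(offset_rng.normal(cfg.motif_offset_mean, cfg.motif_offset_sd)))
        off = int(np.clip(off, -PROMOTER_FLANK, PROMOTER_FLANK - w + 1))
        truth.planted_motif_positions[gid] = off
        g = by_id[gid]
        pos = g.tss + off if g.strand == "+" else g.tss - off
        truth.planted_peak_summits[gid] = int(pos)
    return genes, truth


# ---------------------------------------------------------------------------
# ChIP replicates
# ---------------------------------------------------------------------------

def simulate_chip_experiment(
    annotation: list[GeneModel],
    truth: GroundTruth,
    cfg: SimulationConfig,
) -> tuple[list[Peak], list[Peak]]:
    """Two replicate peak tables: one strongly significant peak per bound
    locus with summit = planted position + N(0, jitter), plus replicate-
    specific noise peaks placed uniformly with p-values above 1e-5."""
    known = {g.gene_id for g in annotation}
    missing = set(truth.bound_gene_ids) - known
    if missing:
        raise ValueError(f"bound genes absent from annotation: {sorted(missing)}")
    by_id = {g.gene_id: g for g in annotation}
    rng = _stream(cfg, "chip")
    replicates: list[list[Peak]] = []
    for rep in ("rep1", "rep2"):
        peaks: list[Peak] = []
        for gid in truth.bound_gene_ids:
            g = by_id[gid]
            summit = truth.planted_peak_summits[gid]
            summit += int(round(rng.normal(0.0, cfg.summit_jitter_sd)))
            summit = int(np.clip(summit, 1, cfg.chrom_length - 2))
            start = max(0, summit - _PEAK_HALF_WIDTH)
            peaks.append(Peak(
                chrom=g.chrom, start=start, end=summit + _PEAK_HALF_WIDTH + 1,
                summit=summit, neg_log10_p=float(rng.uniform(8.0, 30.0)),
                replicate=rep, name=f"{rep}_{gid}"))
        for i in range(cfg.n_noise_peaks_per_replicate):
            chrom = f"chr{int(rng.integers(1, cfg.n_chroms + 1))}"
            summit = int(rng.integers(_PEAK_HALF_WIDTH, cfg.chrom_length - _PEAK_HALF_WIDTH))
            peaks.append(Peak(
                chrom=chrom, start=summit - _PEAK_HALF_WIDTH,
                end=summit + _PEAK_HALF_WIDTH + 1, summit=summit,
                neg_log10_p=float(rng.uniform(1.0, 4.9)),
                replicate=rep, name=f"{rep}_noise{i}"))
        peaks.sort(key=lambda p: (p.chrom, p.start))
        replicates.append(peaks)
    return replicates[0], replicates[1]


# ---------------------------------------------------------------------------
# Expression and the target map
# ---------------------------------------------------------------------------

_TYPE_SIGNS = {
    # ffl type -> (miRNA lfc sign, target lfc sign) in the loss-of-function contrast
    "C4": (+1, -1),   # TF represses miRNA (up in mutant), activates target (down)
    "I1": (-1, -1),
    "I2": (+1, +1),
    "C3": (-1, +1),
}


def simulate_expression(
    annotation: list[GeneModel],
    truth: GroundTruth,
    cfg: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, list[str]]]:
    """DE tables (genes, mature miRNAs) and the miRNA->target map.

    Planted loops fix the sign of the miRNA and target log2 fold changes per
    loop type; their adjusted p-values fall well below ``alpha_sig``.  All
    other features are null: LFC ~ N(0, null_lfc_sd) with uniform adjusted
    p-values, so ~alpha_sig of them are flagged by chance.  Decoy map edges
    point at genes that carry no planted effect.
    """
    rng = _stream(cfg, "expression")
    gene_ids = [g.gene_id for g in annotation if g.biotype == "protein_coding"]
    mirna_ids = sorted(truth.mirna_gene_map)
    loop_types = (["C4"] * cfg.n_planted_c4
                  + [t for t in ("I1", "I2", "C3")
                     for _ in range(cfg.n_planted_per_other_type)])
    n_loops = len(loop_types)
    if n_loops > len(gene_ids):
        raise CapacityError(
            f"{n_loops} planted loops need distinct targets but only "
            f"{len(gene_ids)} genes are available")
    if mirna_ids and n_loops > len(mirna_ids) * max(1, cfg.planted_loops_per_mirna):
        raise CapacityError("planted loops exceed miRNA x planted_loops_per_mirna capacity")
    if n_loops and not mirna_ids:
        raise CapacityError("planted loops requested but no miRNA genes simulated")

    # group loop types by the miRNA sign they impose (a miRNA cannot carry
    # two contradictory planted signs); loops spread over
    # ceil(n / planted_loops_per_mirna) miRNAs so that part of the miRNA set
    # stays null and the permutation test has a background to shuffle
    up_loops = [t for t in loop_types if _TYPE_SIGNS[t][0] > 0]
    down_loops = [t for t in loop_types if _TYPE_SIGNS[t][0] < 0]
    cap = max(1, cfg.planted_loops_per_mirna)
    n_up_pool = -(-len(up_loops) // cap)
    n_down_pool = -(-len(down_loops) // cap)
    if n_up_pool + n_down_pool > len(mirna_ids):
        raise CapacityError(
            f"planting {n_loops} loops needs {n_up_pool + n_down_pool} miRNAs "
            f"at {cap} targets each but only {len(mirna_ids)} are simulated")
    shuffled_mirnas = list(rng.permutation(mirna_ids))
    up_pool = shuffled_mirnas[:n_up_pool]
    down_pool = shuffled_mirnas[n_up_pool:n_up_pool + n_down_pool]
    targets = list(rng.choice(gene_ids, size=n_loops, replace=False))

    planted_pairs: list[tuple[str, str, str]] = []
    mirna_sign: dict[str, int] = {}
    target_sign: dict[str, int] = {}
    ti = 0
    for pool, loops in ((up_pool, up_loops), (down_pool, down_loops)):
        for k, t in enumerate(loops):
            mid = pool[k % len(pool)]
            tgt = targets[ti]
            ti += 1
            planted_pairs.append((mid, tgt, t))
            mirna_sign[mid] = _TYPE_SIGNS[t][0]
            target_sign[tgt] = _TYPE_SIGNS[t][1]
    truth.planted_ffls = planted_pairs

    def _draw(ids: list[str], signs: dict[str, int]) -> pd.DataFrame:
        # features outside planted loops respond with prob bg_de_fraction and
        # a random direction, emulating the widespread remodelling a TF
        # knockout causes; the rest are exact nulls with uniform adjusted p
        rows = []
        for fid in ids:
            s = signs.get(fid, 0)
            if s == 0 and rng.uniform() < cfg.bg_de_fraction:
                s = int(rng.choice([-1, 1]))
            if s != 0:
                lfc = s * abs(rng.normal(cfg.lfc_effect_mean, cfg.lfc_effect_sd))
                padj = float(rng.uniform(0.0, cfg.alpha_sig / 10.0))
            else:
                lfc = rng.normal(0.0, cfg.null_lfc_sd)
                padj = float(rng.uniform(0.0, 1.0))
            pval = padj * float(rng.uniform(0.1, 1.0))
            rows.append((fid, float(lfc), pval, padj))
            truth.edge_signs[fid] = -s
        return pd.DataFrame(rows, columns=["feature_id", "log2fc", "pvalue", "padj"])

    gene_de = _draw(gene_ids, target_sign)
    mirna_de = _draw(mirna_ids, mirna_sign)

    # planted loop edges are embedded among targets_per_mirna decoys: every
    # miRNA draws the same number of background decoy edges, so under the
    # permutation null all nodes carry identical expected non-planted target
    # content and only the planted edges separate signal from background
    planted_targets = set(target_sign)
    decoy_pool = [g for g in gene_ids if g not in planted_targets]
    target_map: dict[str, list[str]] = {m: [] for m in mirna_ids}
    for mid, tgt, _ in planted_pairs:
        target_map[mid].append(tgt)
    n_decoys = min(cfg.targets_per_mirna, len(decoy_pool))
    for mid in mirna_ids:
        if n_decoys:
            target_map[mid].extend(rng.choice(decoy_pool, size=n_decoys, replace=False))
        target_map[mid] = sorted(target_map[mid])
    return gene_de, mirna_de, target_map


# ---------------------------------------------------------------------------
# Promoters
# ---------------------------------------------------------------------------

_BASES = np.frombuffer(b"ACGT", dtype="S1")


def simulate_promoters(
    annotation: list[GeneModel],
    truth: GroundTruth,
    cfg: SimulationConfig,
) -> list[SeqRecord]:
    """One promoter per gene: TSS +- 1000 bp (strand-oriented), i.i.d. uniform
    ACGT background; bound genes carry one concrete expansion of the planted
    IUPAC motif starting at the recorded offset from the TSS."""
    w = len(cfg.planted_motif)
    length = 2 * PROMOTER_FLANK + 1
    if w > length:
        raise ValueError("motif longer than promoter window")
    rng = _stream(cfg, "promoters")
    records = []
    for g in annotation:
        seq = _BASES[rng.integers(0, 4, size=length)]
        if g.gene_id in truth.planted_motif_positions:
            off = truth.planted_motif_positions[g.gene_id]
            site = "".join(
                str(rng.choice(sorted(IUPAC_SETS[sym]))) for sym in cfg.planted_motif)
            start = off + PROMOTER_FLANK
            seq[start:start + w] = np.frombuffer(site.encode(), dtype="S1")
        pstart, pend = g.tss - PROMOTER_FLANK, g.tss + PROMOTER_FLANK + 1
        rec = SeqRecord(Seq(seq.tobytes().decode()),
                        id=f"{g.gene_id}|{g.chrom}:{pstart}-{pend}({g.strand})",
                        description="")
        records.append(rec)
    return records


def write_promoters(records: list[SeqRecord], path: str | Path) -> None:
    SeqIO.write(records, str(path), "fasta")


def write_de_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def write_target_map(target_map: dict[str, list[str]], path: str | Path) -> None:
    rows = [(m, t) for m in sorted(target_map) for t in target_map[m]]
    pd.DataFrame(rows, columns=["mirna_id", "target_id"]).to_csv(path, sep="\t", index=False)
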