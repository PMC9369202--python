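"""Promoter motif scanning: PWM log-odds and IUPAC degenerate matching.

Scans promoter windows (TSS +- 1 kb) on both strands, reports match offsets
relative to the TSS in gene orientation, summarises their positional
distribution, and tests over-representation of a motif in a foreground
promoter set against resampled random genomic background sets of matched
number and length (empirical p with add-one correction, significance called
at p < 0.001).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from Bio import motifs as bio_motifs

logger = logging.getLogger(__name__)

PROMOTER_FLANK = 1000  # bp either side of the TSS in a promoter window

IUPAC_SETS = {
    "A": {"A"}, "C": {"C"}, "G": {"G"}, "T": {"T"},
    "R": {"A", "G"}, "Y": {"C", "T"}, "W": {"A", "T"}, "S": {"C", "G"},
    "K": {"G", "T"}, "M": {"A", "C"},
    "B": {"C", "G", "T"}, "D": {"A", "G", "T"}, "H": {"A", "C", "T"},
    "V": {"A", "C", "G"}, "N": {"A", "C", "G", "T"},
}
_COMPLEMENT = str.maketrans("ACGTRYWSKMBDHVN", "TGCAYRWSMKVHDBN")

UNIFORM_BACKGROUND = np.array([0.25, 0.25, 0.25, 0.25])


@dataclass(frozen=True)
class MotifModel:
    """A position probability matrix over A,C,G,T (rows sum to 1)."""

    id: str
    width: int
    matrix: np.ndarray  # shape (width, 4)
    iupac_consensus: str | None = None

    def __post_init__(self) -> None:
        if self.width < 1 or self.matrix.shape != (self.width, 4):
            raise ValueError("matrix must be (width, 4) with width >= 1")
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("matrix rows must sum to 1")
        if self.iupac_consensus is not None and len(self.iupac_consensus) != self.width:
            raise ValueError("consensus length must equal width")

    def max_score(self, background: np.ndarray = UNIFORM_BACKGROUND) -> float:
        with np.errstate(divide="ignore"):
            lo = np.log2(self.matrix) - np.log2(background)
        return float(np.max(lo, axis=1).sum())


@dataclass(frozen=True)
class MotifMatch:
    """One motif occurrence; offset is the match's 5'-most base relative to
    the TSS in gene orientation (negative = upstream)."""

    sequence_id: str
    offset_to_tss: int
    strand: str
    score: float


@dataclass(frozen=True)
class Promoter:
    """A promoter sequence with the index of the TSS inside it."""

    sequence_id: str
    sequence: str
    tss_index: int


# ---------------------------------------------------------------------------
# PWM I/O (MEME minimal format)
# ---------------------------------------------------------------------------

def load_pwm(path: str | Path) -> MotifModel:
    """Read the first motif from a MEME minimal-format file; zero cells get a
    1e-3 pseudocount before renormalisation."""
    try:
        with open(path) as fh:
            parsed = bio_motifs.parse(fh, "minimal")
        if not parsed:
            raise ValueError("no MOTIF record found")
        m = parsed[0]
        mat = np.array([[m.pwm[b][i] for b in "ACGT"] for i in range(m.length)], float)
    except Exception as exc:  # noqa: BLE001 - report file context
        raise ValueError(f"cannot parse MEME minimal PWM {path}: {exc}") from exc
    if (mat == 0).any():
        mat = mat + 1e-3
    mat = mat / mat.sum(axis=1, keepdims=True)
    return MotifModel(id=str(m.name), width=mat.shape[0], matrix=mat)


def write_pwm(motif: MotifModel, path: str | Path) -> None:
    lines = [
        "MEME version 4", "",
        "ALPHABET= ACGT", "",
        "strands: + -", "",
        "Background letter frequencies",
        "A 0.25 C 0.25 G 0.25 T 0.25", "",
        f"MOTIF {motif.id}",
        f"letter-probability matrix: alength= 4 w= {motif.width} nsites= 20 E= 0",
    ]
    lines += [" ".join(f"{v:.10f}" for v in row) for row in motif.matrix]
    Path(path).write_text("\n".join(lines) + "\n")


def pwm_from_iupac(pattern: str, motif_id: str | None = None) -> MotifModel:
    """0/1-probability PWM equivalent of a degenerate pattern: scanning it at
    threshold = max score reproduces exact IUPAC matching."""
    _validate_iupac(pattern)
    mat = np.zeros((len(pattern), 4))
    for i, sym in enumerate(pattern):
        allowed = IUPAC_SETS[sym]
        for j, b in enumerate("ACGT"):
            if b in allowed:
                mat[i, j] = 1.0 / len(allowed)
    return MotifModel(id=motif_id or pattern, width=len(pattern), matrix=mat,
                      iupac_consensus=pattern)


# ---------------------------------------------------------------------------
# Scanning
# ---------------------------------------------------------------------------

_ENC = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _ENC[_b] = _i
    _ENC[_b + 32] = _i  # lowercase


def _encode(seq: str) -> np.ndarray:
    return _ENC[np.frombuffer(seq.encode(), dtype=np.uint8)]


def _logodds(motif: MotifModel, background: np.ndarray) -> np.ndarray:
    """(width, 5) log-odds; column 4 is N and contributes 0 bits."""
    with np.errstate(divide="ignore"):
        lo = np.log2(motif.matrix) - np.log2(background)
    return np.hstack([lo, np.zeros((motif.width, 1))])


def _window_scores(codes: np.ndarray, lo: np.ndarray) -> np.ndarray:
    w = lo.shape[0]
    if len(codes) < w:
        return np.empty(0)
    wins = np.lib.stride_tricks.sliding_window_view(codes, w)
    return lo[np.arange(w), wins].sum(axis=1)


def scan_pwm(
    promoters: Sequence[Promoter],
    motif: MotifModel,
    score_threshold: float,
    background: np.ndarray = UNIFORM_BACKGROUND,
) -> list[MotifMatch]:
    """Log-odds scan of both strands; positions scoring >= threshold are
    matches.  N bases score 0 bits.  The minus-strand scan scores each window
    against the reverse-complement of the matrix, so offsets refer to the
    window start in the given (gene) orientation either way."""
    lo = _logodds(motif, np.asarray(background, float))
    lo_rc = lo[::-1, [3, 2, 1, 0, 4]]
    if score_threshold > motif.max_score(np.asarray(background, float)) + 1e-9:
        logger.warning("score threshold %.3f exceeds maximum attainable score %.3f",
                       score_threshold, motif.max_score())
        return []
    out: list[MotifMatch] = []
    for prom in promoters:
        codes = _encode(prom.sequence)
        for strand, mat in (("+", lo), ("-", lo_rc)):
            scores = _window_scores(codes, mat)
            for pos in np.nonzero(scores >= score_threshold - 1e-12)[0]:
                out.append(MotifMatch(
                    sequence_id=prom.sequence_id,
                    offset_to_tss=int(pos) - prom.tss_index,
                    strand=strand, score=float(scores[pos])))
    out.sort(key=lambda m: (m.sequence_id, m.offset_to_tss, m.strand))
    return out


def _validate_iupac(pattern: str) -> None:
    for i, sym in enumerate(pattern):
        if sym.upper() not in IUPAC_SETS:
            raise ValueError(f"illegal IUPAC symbol {sym!r} at position {i}")


def _iupac_regex(pattern: str) -> re.Pattern:
    return re.compile("(?=(" + "".join(
        "[" + "".join(sorted(IUPAC_SETS[sym.upper()])) + "]" for sym in pattern) + "))")


def reverse_complement_pattern(pattern: str) -> str:
    return pattern.upper().translate(_COMPLEMENT)[::-1]


def iupac_scan(promoters: Sequence[Promoter], pattern: str) -> list[MotifMatch]:
    """Exact degenerate matching of an IUPAC pattern on both strands; the
    minus strand is matched via the reverse-complement pattern on the given
    sequence, so offsets are window starts in gene orientation."""
    _validate_iupac(pattern)
    score = pwm_from_iupac(pattern).max_score()
    patterns = (("+", _iupac_regex(pattern)), ("-", _iupac_regex(reverse_complement_pattern(pattern))))
    out: list[MotifMatch] = []
    for prom in promoters:
        seq = prom.sequence.upper()
        for strand, rx in patterns:
            for m in rx.finditer(seq):
                out.append(MotifMatch(
                    sequence_id=prom.sequence_id,
                    offset_to_tss=m.start() - prom.tss_index,
                    strand=strand, score=score))
    out.sort(key=lambda m: (m.sequence_id, m.offset_to_tss, m.strand))
    return out


# ---------------------------------------------------------------------------
# Positional distribution and over-representation
# ---------------------------------------------------------------------------

def positional_distribution(
    matches: Sequence[MotifMatch], flank: int = PROMOTER_FLANK, bin: int = 50,
) -> dict:
    """Histogram of offsets over [-flank, flank); modal-bin ties break toward
    the TSS-proximal bin (then upstream)."""
    if bin <= 0 or (2 * flank) % bin != 0:
        raise ValueError("bin must be > 0 and divide 2*flank")
    edges = np.arange(-flank, flank + bin, bin)
    offs = [m.offset_to_tss for m in matches if -flank <= m.offset_to_tss < flank]
    counts, _ = np.histogram(offs, bins=edges)
    centers = (edges[:-1] + edges[1:]) / 2.0
    best = max(range(len(counts)),
               key=lambda i: (counts[i], -abs(centers[i]), -centers[i]))
    return {"bin_edges": edges, "counts": counts, "modal_bin_index": int(best),
            "modal_bin": (int(edges[best]), int(edges[best + 1]))}


def count_matches(
    promoters: Sequence[Promoter], motif: MotifModel, score_threshold: float,
    background: np.ndarray = UNIFORM_BACKGROUND,
) -> int:
    return len(scan_pwm(promoters, motif, score_threshold, background))


def uniform_background_sampler(
    rng: np.random.Generator, lengths: Sequence[int],
) -> list[Promoter]:
    """Length-matched random genomic sequences under a uniform base model."""
    bases = np.frombuffer(b"ACGT", dtype="S1")
    return [
        Promoter(sequence_id=f"bg_{i}",
                 sequence=bases[rng.integers(0, 4, size=n)].tobytes().decode(),
                 tss_index=(n - 1) // 2)
        for i, n in enumerate(lengths)
    ]


def overrepresentation_test(
    fg_promoters: Sequence[Promoter],
    bg_sampler: Callable[[np.random.Generator, Sequence[int]], Sequence[Promoter]],
    motif: MotifModel,
    score_threshold: float,
    n_bg_sets: int = 999,
    seed: int | None = None,
    background: np.ndarray = UNIFORM_BACKGROUND,
) -> dict:
    """Empirical over-representation test: count motif occurrences in the
    foreground, then in ``n_bg_sets`` background sets of matched cardinality
    and lengths; p = (#{bg count >= observed} + 1) / (n_bg_sets + 1)."""
    if n_bg_sets < 1:
        raise ValueError("n_bg_sets must be >= 1")
    rng = np.random.default_rng(seed)
    observed = count_matches(fg_promoters, motif, score_threshold, background)
    lengths = [len(p.sequence) for p in fg_promoters]
    bg_counts = []
    for _ in range(n_bg_sets):
        bg = bg_sampler(rng, lengths)
        bg_counts.append(count_matches(bg, motif, score_threshold, background))
    bg_counts = np.asarray(bg_counts)
    p = (int((bg_counts >= observed).sum()) + 1) / (n_bg_sets + 1)
    return {"observed": observed, "bg_counts": bg_counts, "p_value": float(p),
            "n_bg_sets": n_bg_sets}


# ---------------------------------------------------------------------------
# Promoter FASTA I/O
# ---------------------------------------------------------------------------

_HEADER_RX = re.compile(r"^(?P<gene>[^|]+)\|(?P<chrom>[^:]+):(?P<start>\d+)-(?P<end>\d+)\((?P<strand>[+-])\)$")


def read_promoters(path: str | Path) -> list[Promoter]:
    """Read promoter FASTA written by the simulator; the TSS sits at the
    centre of each window (header 'geneID|chrom:start-end(strand)')."""
    from Bio import SeqIO

    proms = []
    for rec in SeqIO.parse(str(path), "fasta"):
        m = _HEADER_RX.match(rec.id)
        sid = m.group("gene") if m else rec.id
        seq = str(rec.seq)
        proms.append(Promoter(sequence_id=sid, sequence=seq, tss_index=(len(seq) - 1) // 2))
    return proms
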