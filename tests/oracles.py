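"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written for clarity, not speed, and deliberately avoids
the code paths it checks.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

from mirffl.chip import ChipParams, GeneModel, MergedPeak, Peak

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "W": "AT", "S": "CG", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def merge_oracle(peaks: list[Peak], params: ChipParams) -> list[set[int]]:
    """O(n^2) transitive closure of the pairwise merge rule; returns the
    partition of peak indices."""
    n = len(peaks)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            i = parent[i]
        return i

    for i, j in itertools.combinations(range(n), 2):
        a, b = peaks[i], peaks[j]
        if a.chrom != b.chrom:
            continue
        overlap = a.start < b.end and b.start < a.end
        d = abs(a.summit - b.summit)
        rule = d <= params.overlap_merge_dist if overlap else d <= params.gap_merge_dist
        if rule:
            ri, rj = find(i), find(j)
            if ri != rj:
                parent[rj] = ri
    groups: dict[int, set[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), set()).add(i)
    return sorted(groups.values(), key=lambda s: min(s))


def window_membership_oracle(gene: GeneModel, summit: int, params: ChipParams) -> bool:
    """Per-base check that the summit lies in TSS-up .. TTS+down (gene
    orientation), enumerated one base at a time."""
    if gene.strand == "+":
        positions = range(gene.tss - params.upstream_window,
                          gene.tts + params.downstream_window + 1)
    else:
        positions = range(gene.tts - params.downstream_window,
                          gene.tss + params.upstream_window + 1)
    return summit in positions


def pwm_scan_oracle(seq: str, matrix: np.ndarray, threshold: float,
                    background: np.ndarray) -> list[tuple[int, str, float]]:
    """Naive per-window rescoring on both strands; (position, strand, score)."""
    w = matrix.shape[0]
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    out = []
    for pos in range(len(seq) - w + 1):
        window = seq[pos:pos + w].upper()
        for strand in "+-":
            if strand == "-":
                window_eff = "".join(comp[b] for b in reversed(window))
            else:
                window_eff = window
            score = 0.0
            for k, base in enumerate(window_eff):
                if base == "N":
                    continue
                p = matrix[k, idx[base]]
                score += -math.inf if p == 0 else math.log2(p / background[idx[base]])
            if score >= threshold - 1e-12:
                out.append((pos, strand, score))
    return out


def iupac_match_oracle(seq: str, pattern: str) -> list[tuple[int, str]]:
    """Degenerate matching by explicit per-symbol set membership."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    rc = "".join(comp[b] for b in reversed(seq))
    out = []
    w = len(pattern)
    for pos in range(len(seq) - w + 1):
        if all(seq[pos + k] in IUPAC[pattern[k]] for k in range(w)):
            out.append((pos, "+"))
        rpos = len(seq) - w - pos
        if all(rc[rpos + k] in IUPAC[pattern[k]] for k in range(w)):
            out.append((pos, "-"))
    return sorted(out)


def exhaustive_enrichment_oracle(mi_states, tg_states, edges):
    """Exact per-type permutation p-values and means by enumerating every
    joint (miRNA, target) permutation.  States: 0 null, 1 up, 2 down;
    edges: (mi index, tg index) pairs."""
    def count(ms, ts):
        c = {"I1": 0, "I2": 0, "C3": 0, "C4": 0}
        for mi, tg in edges:
            key = (ms[mi], ts[tg])
            if key == (2, 2):
                c["I1"] += 1
            elif key == (1, 1):
                c["I2"] += 1
            elif key == (2, 1):
                c["C3"] += 1
            elif key == (1, 2):
                c["C4"] += 1
        return c

    observed = count(mi_states, tg_states)
    totals = {t: 0 for t in observed}
    ge = {t: 0 for t in observed}
    n = 0
    for mperm in itertools.permutations(mi_states):
        for tperm in itertools.permutations(tg_states):
            c = count(mperm, tperm)
            n += 1
            for t in observed:
                totals[t] += c[t]
                if c[t] >= observed[t]:
                    ge[t] += 1
    return (observed,
            {t: ge[t] / n for t in observed},
            {t: totals[t] / n for t in observed},
            n)


def iupac_hit_probability(pattern: str) -> float:
    """Per-window match probability of a degenerate pattern under an
    i.i.d. uniform base model, forward strand."""
    p = 1.0
    for sym in pattern:
        p *= len(IUPAC[sym]) / 4.0
    return p
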