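"""Peak merging, replicate support, window assignment and summaries."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mirffl import (
    ChipParams,
    GeneModel,
    MergedPeak,
    Peak,
    SimulationConfig,
    assign_candidate_targets,
    genic_distribution,
    high_confidence_peaks,
    merge_peaks,
    peak_location_profile,
    simulate_annotation,
    simulate_chip_experiment,
)
from mirffl.chip import read_peaks, write_peaks, read_gff3_genes, write_gff3_genes

from oracles import merge_oracle, window_membership_oracle

PARAMS = ChipParams()


def _peak(start, end, summit, p=10.0, chrom="chr1", rep="rep1"):
    return Peak(chrom=chrom, start=start, end=end, summit=summit,
                neg_log10_p=p, replicate=rep)


# ---------------------------------------------------------------------------
# merge_peaks
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("peaks,n_merged", [
    # overlapping spans, summits 400 apart (<= 600) -> merge
    ([_peak(0, 1000, 300), _peak(500, 1500, 700)], 1),
    # disjoint spans, summits 250 apart (<= 300) -> merge
    ([_peak(0, 100, 50), _peak(200, 400, 300)], 1),
    # disjoint spans, summits 400 apart (> 300) -> stay separate
    ([_peak(0, 100, 50), _peak(400, 600, 450)], 2),
    # overlapping spans, summits 700 apart (> 600) -> stay separate
    ([_peak(0, 1000, 100), _peak(50, 1200, 800)], 2),
    ([_peak(10, 500, 200)], 1),
])
def test_merge_rule_on_printed_distances(peaks, n_merged):
    merged = merge_peaks(peaks, PARAMS)
    assert len(merged) == n_merged
    if n_merged == 1 and len(peaks) > 1:
        assert merged[0].start == min(p.start for p in peaks)
        assert merged[0].end == max(p.end for p in peaks)
        assert merged[0].member_count == len(peaks)


def test_merge_single_peak_identity():
    p = _peak(10, 500, 200, p=7.5)
    m, = merge_peaks([p], PARAMS)
    assert (m.start, m.end, m.summit, m.best_neg_log10_p) == (10, 500, 200, 7.5)


def test_merge_summit_from_most_significant_member():
    peaks = [_peak(0, 1000, 300, p=5.0), _peak(100, 1100, 600, p=9.0)]
    m, = merge_peaks(peaks, PARAMS)
    assert m.summit == 600 and m.best_neg_log10_p == 9.0


def test_merge_equals_pairwise_closure_oracle_on_random_peaks():
    rng = np.random.default_rng(42)
    peaks = []
    for _ in range(1000):
        chrom = f"chr{rng.integers(1, 3)}"
        start = int(rng.integers(0, 500_000))
        length = int(rng.integers(100, 800))
        summit = start + int(rng.integers(0, length))
        peaks.append(Peak(chrom=chrom, start=start, end=start + length,
                          summit=summit, neg_log10_p=float(rng.uniform(0, 20))))
    merged = merge_peaks(peaks, PARAMS)
    groups = merge_oracle(peaks, PARAMS)
    oracle_spans = sorted(
        (peaks[next(iter(g))].chrom,
         min(peaks[i].start for i in g), max(peaks[i].end for i in g), len(g))
        for g in [sorted(g) for g in groups])
    got_spans = sorted((m.chrom, m.start, m.end, m.member_count) for m in merged)
    assert got_spans == oracle_spans


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.lists(st.tuples(st.integers(0, 20_000), st.integers(50, 600),
                          st.floats(0, 20)), min_size=1, max_size=25),
       st.randoms(use_true_random=False))
def test_merge_idempotent_and_order_invariant(raw, rnd):
    peaks = [Peak(chrom="chr1", start=s, end=s + w, summit=s + w // 2,
                  neg_log10_p=p) for s, w, p in raw]
    merged = merge_peaks(peaks, PARAMS)
    shuffled = list(peaks)
    rnd.shuffle(shuffled)
    key = lambda ms: sorted((m.chrom, m.start, m.end, m.summit, m.member_count)
                            for m in ms)
    assert key(merge_peaks(shuffled, PARAMS)) == key(merged)
    # re-merging merged peaks changes nothing
    reinput = [Peak(chrom=m.chrom, start=m.start, end=m.end, summit=m.summit,
                    neg_log10_p=m.best_neg_log10_p) for m in merged]
    again = merge_peaks(reinput, PARAMS)
    assert key(again) == sorted((m.chrom, m.start, m.end, m.summit, 1) for m in merged)


# ---------------------------------------------------------------------------
# high_confidence_peaks
# ---------------------------------------------------------------------------

def _merged(summit, p=10.0, chrom="chr1", half=150):
    return MergedPeak(chrom=chrom, start=summit - half, end=summit + half,
                      summit=summit, best_neg_log10_p=p)


def test_replicate_support_within_distance_retained():
    hc = high_confidence_peaks([_merged(1000)], [_merged(1350)], PARAMS)
    assert len(hc) == 1
    assert hc[0].start == 850 and hc[0].end == 1500


def test_peak_without_replicate_support_dropped():
    hc = high_confidence_peaks([_merged(1000)], [_merged(5000)], PARAMS)
    assert hc == []


def test_supported_pair_below_significance_dropped():
    # p = 1e-4 on both replicates -> fails the p < 1e-5 cutoff
    hc = high_confidence_peaks([_merged(1000, p=4.0)], [_merged(1100, p=4.0)], PARAMS)
    assert hc == []


def test_empty_replicate_yields_empty_result():
    assert high_confidence_peaks([], [_merged(1000)], PARAMS) == []


def test_replicate_support_is_symmetric():
    rng = np.random.default_rng(7)
    rep1 = [_merged(int(s), p=float(rng.uniform(6, 12)))
            for s in rng.integers(0, 100_000, 40)]
    rep2 = [_merged(int(s), p=float(rng.uniform(6, 12)))
            for s in rng.integers(0, 100_000, 40)]
    ab = high_confidence_peaks(rep1, rep2, PARAMS)
    ba = high_confidence_peaks(rep2, rep1, PARAMS)
    for p in ab:
        assert any(abs(p.summit - q.summit) <= PARAMS.replicate_support_dist
                   for q in ba)
    for q in ba:
        assert any(abs(q.summit - p.summit) <= PARAMS.replicate_support_dist
                   for p in ab)


# ---------------------------------------------------------------------------
# assign_candidate_targets
# ---------------------------------------------------------------------------

GENE_PLUS = GeneModel(gene_id="gP", chrom="chr1", strand="+", start=10_000, end=12_000)
GENE_MINUS = GeneModel(gene_id="gM", chrom="chr1", strand="-", start=50_000, end=52_000)


@pytest.mark.parametrize("summit,gene,expected_class,expected_d", [
    (10_000 - 2999, GENE_PLUS, "upstream", -2999),   # 3 kb upstream of TSS
    (12_000 - 1 + 999, GENE_PLUS, "downstream", 2998),  # 1 kb downstream of TTS
    (11_000, GENE_PLUS, "genic", 1000),
    (52_000 - 1 + 2999, GENE_MINUS, "upstream", -2999),  # strand-reflected
])
def test_assignment_window_and_signed_distance(summit, gene, expected_class, expected_d):
    assignments = assign_candidate_targets([_merged(summit)], [gene], PARAMS)
    assert len(assignments) == 1
    a = assignments[0]
    assert a.region_class == expected_class
    assert a.summit_to_tss == expected_d
    assert window_membership_oracle(gene, summit, PARAMS)


def test_summit_just_outside_window_not_assigned():
    summit = 10_000 - 3001
    assert assign_candidate_targets([_merged(summit)], [GENE_PLUS], PARAMS) == []
    assert not window_membership_oracle(GENE_PLUS, summit, PARAMS)


def test_assignment_agrees_with_per_base_oracle_on_random_summits():
    rng = np.random.default_rng(3)
    genes = [GENE_PLUS, GENE_MINUS]
    for summit in rng.integers(0, 60_000, 300):
        got = {a.gene_id for a in assign_candidate_targets(
            [_merged(int(summit))], genes, PARAMS)}
        expected = {g.gene_id for g in genes
                    if window_membership_oracle(g, int(summit), PARAMS)}
        assert got == expected


# ---------------------------------------------------------------------------
# profiles and genic distribution
# ---------------------------------------------------------------------------

def test_profile_all_summits_at_tss():
    genes = [GENE_PLUS, GENE_MINUS]
    hc = [_merged(10_000), _merged(51_999)]
    prof = peak_location_profile(hc, genes)
    assert prof["fraction_within_500bp_tss"] == 1.0
    assert prof["counts"].sum() == 2


def test_profile_uniform_summits_give_one_sixth_within_500bp():
    rng = np.random.default_rng(12)
    genes, hc = [], []
    pos = 10_000
    for i in range(6000):
        g = GeneModel(gene_id=f"g{i}", chrom=f"c{i}", strand="+",
                      start=pos, end=pos + 4000)
        offset = int(rng.integers(-3000, 3000))
        genes.append(g)
        hc.append(_merged(g.start + offset, chrom=g.chrom))
    prof = peak_location_profile(hc, genes)
    frac = prof["fraction_within_500bp_tss"]
    sd = np.sqrt((1 / 6) * (5 / 6) / 6000)
    assert abs(frac - 1 / 6) < 4 * sd


def test_profile_planted_jitter_modal_bin_at_tss():
    cfg = SimulationConfig(seed=8, n_chroms=1, chrom_length=600_000,
                           n_genes=60, n_mirna_genes=2, n_bound_genes=40,
                           motif_offset_mean=0.0, motif_offset_sd=0.0,
                           summit_jitter_sd=200.0, n_noise_peaks_per_replicate=0,
                           n_planted_c4=0)
    genes, truth = simulate_annotation(cfg)
    rep1, rep2 = simulate_chip_experiment(genes, truth, cfg)
    hc = high_confidence_peaks(merge_peaks(rep1), merge_peaks(rep2))
    prof = peak_location_profile(hc, genes, flank=3000, bin=500)
    edges = prof["bin_edges"]
    i = int(np.argmax(prof["counts"]))
    lo, hi = edges[i], edges[i + 1]
    assert lo <= 0 <= hi or abs(lo) == 0 or abs(hi) == 0
    assert -500 <= lo and hi <= 500


def test_genic_distribution_trivial_and_oracle_cases():
    genes = [GENE_PLUS]
    inside = [_merged(s) for s in (10_100, 11_000, 11_900)]
    frac = genic_distribution(inside, genes, PARAMS)
    assert frac["genic"] == 1.0
    one_each = [_merged(9_000), _merged(11_000), _merged(12_500), _merged(40_000)]
    frac = genic_distribution(one_each, genes, PARAMS)
    assert frac == {"upstream": 0.25, "genic": 0.25, "downstream": 0.25,
                    "intergenic": 0.25}
    assert abs(sum(frac.values()) - 1.0) < 1e-9


def test_genic_distribution_precedence_upstream_over_downstream():
    # summit in gene A's downstream window and gene B's upstream window
    a = GeneModel(gene_id="a", chrom="chr1", strand="+", start=1000, end=2000)
    b = GeneModel(gene_id="b", chrom="chr1", strand="+", start=5000, end=6000)
    frac = genic_distribution([_merged(2500)], [a, b], PARAMS)
    assert frac["upstream"] == 1.0


# ---------------------------------------------------------------------------
# round trips
# ---------------------------------------------------------------------------

def test_peak_and_gff3_round_trips(tmp_path, small_dataset):
    peaks = small_dataset["rep1"]
    write_peaks(peaks, tmp_path / "p.bed")
    back = read_peaks(tmp_path / "p.bed", replicate="rep1")
    assert [(p.chrom, p.start, p.end, p.summit) for p in back] == \
           [(p.chrom, p.start, p.end, p.summit) for p in peaks]
    genes = small_dataset["genes"]
    write_gff3_genes(genes, tmp_path / "g.gff3")
    back_genes = read_gff3_genes(tmp_path / "g.gff3")
    assert back_genes == genes
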