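"""Pipeline orchestration: simulate -> chip -> scan -> integrate -> ffl.

Each stage reads the previous stage's files from the output directory, so
stages can be toggled off and replaced by precomputed inputs.  A RunReport
collects per-stage record counts, echoed parameters, and the enrichment
table; reruns with the same config and seed reproduce identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import chip as chip_mod
from . import expression as expr_mod
from . import ffl as ffl_mod
from . import motifs as motif_mod
from . import synthetic as sim_mod

logger = logging.getLogger("mirffl")

__version__ = "0.1.0"


def setup_logging(level: str = "INFO", log_file: str | Path | None = None) -> None:
    handlers: list[logging.Handler] = [logging.StreamHandler(sys.stderr)]
    if log_file is not None:
        handlers.append(logging.FileHandler(log_file))
    logging.basicConfig(
        level=getattr(logging, level.upper()),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
        handlers=handlers, force=True)


@dataclass
class PipelineConfig:
    outdir: str = "mirffl_out"
    seed: int = 0
    tf_id: str = "TF1"
    alpha: float = 0.05
    n_randomizations: int = 10_000
    n_bg_sets: int = 999
    score_threshold_frac: float = 0.8
    motif_pattern: str | None = None     # IUPAC; falls back to the simulated motif
    pwm_path: str | None = None          # MEME minimal file; overrides pattern
    histogram_bin: int = 50
    stages: list[str] = field(default_factory=lambda: [
        "simulate", "chip", "scan", "integrate", "ffl"])
    simulation: dict = field(default_factory=dict)  # SimulationConfig overrides
    chip_params: dict = field(default_factory=dict)  # ChipParams overrides

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def sim_config(self) -> sim_mod.SimulationConfig:
        return sim_mod.SimulationConfig(seed=self.seed, **self.simulation)

    def chip_config(self) -> chip_mod.ChipParams:
        return chip_mod.ChipParams(**self.chip_params)


@dataclass
class RunReport:
    version: str = __version__
    parameters: dict = field(default_factory=dict)
    stage_counts: dict = field(default_factory=dict)
    stage_seconds: dict = field(default_factory=dict)
    enrichment: dict = field(default_factory=dict)
    categories: dict = field(default_factory=dict)
    assignment_summary: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True))


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def _stage_simulate(cfg: PipelineConfig, out: Path, report: RunReport) -> None:
    sim = cfg.sim_config()
    genes, truth = sim_mod.simulate_annotation(sim)
    rep1, rep2 = sim_mod.simulate_chip_experiment(genes, truth, sim)
    gene_de, mirna_de, target_map = sim_mod.simulate_expression(genes, truth, sim)
    promoters = sim_mod.simulate_promoters(genes, truth, sim)

    chip_mod.write_gff3_genes(genes, out / "annotation.gff3")
    chip_mod.write_gene_table(genes, out / "genes.tsv")
    chip_mod.write_peaks(rep1, out / "peaks_rep1.bed")
    chip_mod.write_peaks(rep2, out / "peaks_rep2.bed")
    sim_mod.write_de_table(gene_de, out / "gene_de.tsv")
    sim_mod.write_de_table(mirna_de, out / "mirna_de.tsv")
    sim_mod.write_target_map(target_map, out / "target_map.tsv")
    sim_mod.write_promoters(promoters, out / "promoters.fasta")
    truth.to_json(out / "ground_truth.json")
    report.stage_counts["simulate"] = {
        "genes": len(genes), "peaks_rep1": len(rep1), "peaks_rep2": len(rep2),
        "gene_de_rows": len(gene_de), "mirna_de_rows": len(mirna_de),
        "map_edges": sum(len(v) for v in target_map.values()),
        "promoters": len(promoters),
    }


def _stage_chip(cfg: PipelineConfig, out: Path, report: RunReport) -> None:
    params = cfg.chip_config()
    genes = chip_mod.read_gene_table(out / "genes.tsv")
    rep1 = chip_mod.merge_peaks(chip_mod.read_peaks(out / "peaks_rep1.bed", "rep1"), params)
    rep2 = chip_mod.merge_peaks(chip_mod.read_peaks(out / "peaks_rep2.bed", "rep2"), params)
    hc = chip_mod.high_confidence_peaks(rep1, rep2, params)
    assignments = chip_mod.assign_candidate_targets(hc, genes, params)
    chip_mod.write_merged_peaks(hc, out / "hc_peaks.tsv")
    chip_mod.write_assignments(assignments, out / "assignments.tsv")
    profile = chip_mod.peak_location_profile(hc, genes, params=params)
    genic = chip_mod.genic_distribution(hc, genes, params)
    (out / "target_ids.txt").write_text(
        "\n".join(sorted({a.gene_id for a in assignments})) + "\n")
    report.stage_counts["chip"] = {
        "merged_rep1": len(rep1), "merged_rep2": len(rep2),
        "high_confidence": len(hc), "assignments": len(assignments),
        "candidate_targets": len({a.gene_id for a in assignments}),
    }
    report.assignment_summary = {
        "fraction_within_500bp_tss": profile["fraction_within_500bp_tss"],
        "genic_distribution": genic,
    }


def _stage_scan(cfg: PipelineConfig, out: Path, report: RunReport) -> None:
    promoters = motif_mod.read_promoters(out / "promoters.fasta")
    if cfg.pwm_path:
        motif = motif_mod.load_pwm(cfg.pwm_path)
    else:
        pattern = cfg.motif_pattern or cfg.sim_config().planted_motif
        motif = motif_mod.pwm_from_iupac(pattern)
    threshold = cfg.score_threshold_frac * motif.max_score()
    matches = motif_mod.scan_pwm(promoters, motif, threshold)
    dist = motif_mod.positional_distribution(matches, bin=cfg.histogram_bin)
    test = motif_mod.overrepresentation_test(
        promoters, motif_mod.uniform_background_sampler, motif, threshold,
        n_bg_sets=cfg.n_bg_sets, seed=cfg.seed)
    (out / "motif_report.json").write_text(json.dumps({
        "motif": motif.id, "n_matches": len(matches),
        "modal_bin": dist["modal_bin"],
        "observed": test["observed"], "p_value": test["p_value"],
        "n_bg_sets": test["n_bg_sets"],
    }, indent=1))
    import pandas as pd
    pd.DataFrame({
        "bin_start": dist["bin_edges"][:-1], "bin_end": dist["bin_edges"][1:],
        "count": dist["counts"],
    }).to_csv(out / "motif_histogram.tsv", sep="\t", index=False)
    pd.DataFrame(
        [(m.sequence_id, m.offset_to_tss, m.strand, m.score) for m in matches],
        columns=["sequence_id", "offset_to_tss", "strand", "score"],
    ).to_csv(out / "motif_matches.tsv", sep="\t", index=False)
    report.stage_counts["scan"] = {
        "matches": len(matches), "overrepresentation_p": test["p_value"],
    }


def _stage_integrate(cfg: PipelineConfig, out: Path, report: RunReport) -> None:
    gene_recs = expr_mod.parse_de_table(out / "gene_de.tsv", cfg.alpha, "gene")
    mirna_recs = expr_mod.parse_de_table(out / "mirna_de.tsv", cfg.alpha, "mirna")
    target_map = expr_mod.read_target_map(out / "target_map.tsv")
    edges = [e for r in gene_recs + mirna_recs
             if (e := expr_mod.infer_edge_sign(r, cfg.tf_id)) is not None]
    expr_mod.write_edges(edges, out / "edges.tsv")
    by_id = {r.feature_id: r for r in gene_recs}
    categories = {
        m: expr_mod.classify_mirna_category(
            rec, [by_id[t] for t in target_map.get(m, []) if t in by_id])
        for m in target_map
        for rec in [next(r for r in mirna_recs if r.feature_id == m)]
    }
    import pandas as pd
    pd.DataFrame(sorted(categories.items()), columns=["mirna_id", "category"]).to_csv(
        out / "mirna_categories.tsv", sep="\t", index=False)
    report.stage_counts["integrate"] = {
        "edges": len(edges),
        "mirnas_classified": len(categories),
    }
    report.categories = {c: sum(1 for v in categories.values() if v == c)
                         for c in ("I", "II", "III", "unclassified")}


def _stage_ffl(cfg: PipelineConfig, out: Path, report: RunReport) -> None:
    gene_recs = expr_mod.parse_de_table(out / "gene_de.tsv", cfg.alpha, "gene")
    mirna_recs = expr_mod.parse_de_table(out / "mirna_de.tsv", cfg.alpha, "mirna")
    target_map = expr_mod.read_target_map(out / "target_map.tsv")
    net = ffl_mod.network_from_tables(cfg.tf_id, mirna_recs, gene_recs, target_map)
    instances, _counts = ffl_mod.enumerate_ffls(net)
    chip_ids_path = out / "target_ids.txt"
    truth_path = out / "ground_truth.json"
    if chip_ids_path.exists() and truth_path.exists():
        chip_ids = set(chip_ids_path.read_text().split())
        truth = sim_mod.GroundTruth.from_json(truth_path)
        instances = ffl_mod.annotate_direct(instances, chip_ids, truth.mirna_gene_map)
    result = ffl_mod.permutation_enrichment(
        net, n_randomizations=cfg.n_randomizations, seed=cfg.seed)
    ffl_mod.write_instances(instances, out / "ffl_instances.tsv")
    (out / "enrichment.json").write_text(json.dumps({
        "observed": result.observed, "randomized_mean": result.randomized_mean,
        "p_value": result.p_value, "n_randomizations": result.n_randomizations,
        "total_observed": result.total_observed,
    }, indent=1, sort_keys=True))
    (out / "enrichment_table.tsv").write_text(format_enrichment_table(result))
    report.stage_counts["ffl"] = {"instances": len(instances)}
    report.enrichment = {
        "observed": result.observed, "randomized_mean": result.randomized_mean,
        "p_value": result.p_value, "total_observed": result.total_observed,
    }


_STAGES = {
    "simulate": _stage_simulate,
    "chip": _stage_chip,
    "scan": _stage_scan,
    "integrate": _stage_integrate,
    "ffl": _stage_ffl,
}

_TYPE_LABELS = {
    "I1": "Incoherent type I", "I2": "Incoherent type II",
    "C3": "Coherent type III", "C4": "Coherent type IV",
}


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Run the configured stages in dependency order; any stage failure
    aborts with the stage named."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(parameters=dataclasses.asdict(config))
    for stage in ("simulate", "chip", "scan", "integrate", "ffl"):
        if stage not in config.stages:
            continue
        logger.info("stage %s starting", stage)
        t0 = time.perf_counter()
        try:
            _STAGES[stage](config, out, report)
        except Exception as exc:
            raise RuntimeError(f"stage '{stage}' failed: {exc}") from exc
        report.stage_seconds[stage] = round(time.perf_counter() - t0, 3)
        logger.info("stage %s done in %.2fs", stage, report.stage_seconds[stage])
    report.to_json(out / "run_report.json")
    return report


def format_enrichment_table(result: "ffl_mod.EnrichmentResult") -> str:
    """Per-type enrichment table: observed count, randomized mean (4
    decimals), permutation p, and a ``***`` star for p < 0.001; the Total row
    sums the observed counts."""
    lines = ["type\tobserved\trandomized_mean\tp_value\tstars"]
    for t in ffl_mod.FFL_TYPES:
        stars = "***" if result.p_value[t] < 0.001 else "NS"
        lines.append(f"{_TYPE_LABELS[t]}\t{result.observed[t]}\t"
                     f"{result.randomized_mean[t]:.4f}\t{result.p_value[t]:.4f}\t{stars}")
    total_mean = sum(result.randomized_mean.values())
    lines.append(f"Total\t{result.total_observed}\t{total_mean:.4f}\t\t")
    return "\n".join(lines) + "\n"
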