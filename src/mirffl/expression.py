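"""Differential-expression integration for a TF loss-of-function contrast.

Edge-sign inference follows the loss-of-function logic: a feature that goes
up when the TF is removed is inferred to be repressed by the TF (edge sign
-1), and one that goes down is activated (+1).  miRNA-target co-expression
is summarised into three categories: I (miRNA up, significant targets mostly
down), II (miRNA down, significant targets mostly up), and III (miRNA
significant but targets not anticorrelated).  Family-level summaries report
how many members of each TF family respond and in which direction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.05


@dataclass(frozen=True)
class ExpressionRecord:
    feature_id: str
    log2fc: float
    pvalue: float
    padj: float
    significant: bool
    feature_class: str = "gene"


@dataclass(frozen=True)
class RegulatoryEdge:
    source: str
    dest: str
    sign: int
    evidence: str = "de_inferred"


def parse_de_table(
    path: str | Path,
    alpha: float = DEFAULT_ALPHA,
    feature_class: str = "gene",
    use_raw_p: bool = False,
) -> list[ExpressionRecord]:
    """Read a DE TSV (feature_id, log2fc, pvalue, padj; extra columns
    ignored); significance is padj < alpha (or pvalue < alpha with
    ``use_raw_p``).  Duplicate ids are an error; NA log2fc rows are dropped
    with a warning."""
    df = pd.read_csv(path, sep="\t")
    required = {"feature_id", "log2fc", "pvalue", "padj"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    dupes = df.loc[df["feature_id"].duplicated(), "feature_id"]
    if len(dupes):
        raise ValueError(f"{path}: duplicate feature ids {sorted(set(dupes))}")
    n_na = int(df["log2fc"].isna().sum())
    if n_na:
        logger.warning("%s: dropping %d rows with NA log2fc", path, n_na)
        df = df.dropna(subset=["log2fc"])
    return records_from_frame(df, alpha=alpha, feature_class=feature_class,
                              use_raw_p=use_raw_p)


def records_from_frame(
    df: pd.DataFrame,
    alpha: float = DEFAULT_ALPHA,
    feature_class: str = "gene",
    use_raw_p: bool = False,
) -> list[ExpressionRecord]:
    pcol = "pvalue" if use_raw_p else "padj"
    return [
        ExpressionRecord(
            feature_id=str(r.feature_id), log2fc=float(r.log2fc),
            pvalue=float(r.pvalue), padj=float(r.padj),
            significant=bool(getattr(r, pcol) < alpha),
            feature_class=feature_class)
        for r in df.itertuples()
    ]


def infer_edge_sign(record: ExpressionRecord, tf: str) -> RegulatoryEdge | None:
    """Signed TF->feature edge from the loss-of-function contrast, or None
    when the feature did not respond significantly."""
    if not record.significant:
        return None
    if record.log2fc == 0:
        logger.warning("%s: significant with log2fc exactly 0; no edge", record.feature_id)
        return None
    sign = -1 if record.log2fc > 0 else +1
    return RegulatoryEdge(source=tf, dest=record.feature_id, sign=sign)


def classify_mirna_category(
    mirna: ExpressionRecord, targets: list[ExpressionRecord],
) -> str:
    """Co-expression category of a miRNA and its targets.

    A strict majority of the *significant* targets must run opposite to the
    miRNA for categories I/II; ties or co-directional patterns fall into III;
    a non-significant miRNA is unclassified.
    """
    if not mirna.significant:
        return "unclassified"
    sig = [t for t in targets if t.significant and t.log2fc != 0]
    n_down = sum(1 for t in sig if t.log2fc < 0)
    n_up = len(sig) - n_down
    if mirna.log2fc > 0 and n_down > n_up:
        return "I"
    if mirna.log2fc < 0 and n_up > n_down:
        return "II"
    return "III"


def family_de_summary(
    records: list[ExpressionRecord], family_map: dict[str, str],
) -> pd.DataFrame:
    """Per-family DE summary: family size, number significant, mean log2fc of
    the significant members (NaN when none), and up/down tallies."""
    rows = []
    by_family: dict[str, list[ExpressionRecord]] = {}
    for rec in records:
        fam = family_map.get(rec.feature_id)
        if fam is not None:
            by_family.setdefault(fam, []).append(rec)
    for fam in sorted(set(family_map.values())):
        members = by_family.get(fam, [])
        de = [m for m in members if m.significant]
        rows.append({
            "family": fam,
            "n_family": len(members),
            "n_de": len(de),
            "mean_log2fc_de": float(np.mean([m.log2fc for m in de])) if de else float("nan"),
            "n_up": sum(1 for m in de if m.log2fc > 0),
            "n_down": sum(1 for m in de if m.log2fc < 0),
        })
    return pd.DataFrame(rows)


def read_target_map(path: str | Path) -> dict[str, list[str]]:
    df = pd.read_csv(path, sep="\t")
    out: dict[str, list[str]] = {}
    for r in df.itertuples():
        m, t = str(r.mirna_id), str(r.target_id)
        if m == t:
            raise ValueError(f"self-loop in target map: {m}")
        out.setdefault(m, []).append(t)
    return {m: sorted(ts) for m, ts in out.items()}


def read_family_map(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t")
    return {str(r.feature_id): str(r.family) for r in df.itertuples()}


def write_edges(edges: list[RegulatoryEdge], path: str | Path) -> None:
    rows = [(e.source, e.dest, e.sign, e.evidence) for e in edges]
    pd.DataFrame(rows, columns=["source", "dest", "sign", "evidence"]).to_csv(
        path, sep="\t", index=False)
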