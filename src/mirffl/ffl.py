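"""Feed-forward loop enumeration and permutation enrichment.

Three-node loops TF -> miRNA -> target with the miRNA->target edge fixed
repressive.  The two TF edge signs then admit exactly four loop types:

    (TF->miRNA, TF->target):  (+,+) I1   (-,-) I2   (+,-) C3   (-,+) C4

C4 — TF represses the miRNA and activates the target — is the coherent
sign-sensitive-delay configuration.  Loops are enumerated from the
loss-of-function DE tables: every (significant miRNA, significant target in
its map) pair is one instance, typed by the inferred edge signs.

Enrichment per type is a randomisation test: expression tuples are shuffled
among the miRNA nodes and, independently, among the target nodes (topology
fixed), loop counts are recomputed for each of n shuffles, and
p(type) = #{shuffles with count >= observed} / n — no add-one correction,
so the minimum attainable p is 0 and a count every shuffle reproduces
(e.g. an observed count of 0) gives p = 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .expression import ExpressionRecord

FFL_TYPES = ("I1", "I2", "C3", "C4")

_SIGNS_TO_TYPE = {(+1, +1): "I1", (-1, -1): "I2", (+1, -1): "C3", (-1, +1): "C4"}


@dataclass(frozen=True)
class FflInstance:
    tf: str
    mirna: str
    target: str
    type: str
    direct: bool = False


@dataclass
class FflNetwork:
    """The measured network: all miRNA records, all gene records appearing in
    the target map, and the fixed miRNA->target topology."""

    tf: str
    mirna_records: list[ExpressionRecord]
    target_records: list[ExpressionRecord]
    target_map: dict[str, list[str]]

    def __post_init__(self) -> None:
        mids = [r.feature_id for r in self.mirna_records]
        tids = [r.feature_id for r in self.target_records]
        if len(set(mids)) != len(mids) or len(set(tids)) != len(tids):
            raise ValueError("duplicate feature ids in network records")
        known_t = set(tids)
        known_m = set(mids)
        for m, ts in self.target_map.items():
            if m not in known_m:
                raise ValueError(f"target map references unmeasured miRNA {m}")
            unknown = set(ts) - known_t
            if unknown:
                raise ValueError(f"target map references unmeasured targets {sorted(unknown)}")


@dataclass
class EnrichmentResult:
    observed: dict[str, int]
    randomized_mean: dict[str, float]
    p_value: dict[str, float]
    n_randomizations: int
    total_observed: int = field(init=False)

    def __post_init__(self) -> None:
        self.total_observed = sum(self.observed.values())


def classify_ffl(sign_tf_mirna: int, sign_tf_target: int) -> str:
    """Loop type from the two TF edge signs (miRNA->target fixed at -1)."""
    if sign_tf_mirna == 0 or sign_tf_target == 0:
        raise ValueError("edge signs must be nonzero (filter to significant features first)")
    return _SIGNS_TO_TYPE[(int(np.sign(sign_tf_mirna)), int(np.sign(sign_tf_target)))]


# node states: 0 = not significant, 1 = up in mutant, 2 = down in mutant
def _state(rec: ExpressionRecord) -> int:
    if not rec.significant or rec.log2fc == 0:
        return 0
    return 1 if rec.log2fc > 0 else 2

# (miRNA state, target state) -> type; up in the loss-of-function mutant
# means the TF represses (edge sign -1), down means it activates (+1)
_STATE_TO_TYPE = {(2, 2): "I1", (1, 1): "I2", (2, 1): "C3", (1, 2): "C4"}


def enumerate_ffls(net: FflNetwork) -> tuple[list[FflInstance], dict[str, int]]:
    """All typed loop instances over (significant miRNA, significant target)
    pairs of the map, in deterministic (mirna, target) order."""
    mstate = {r.feature_id: _state(r) for r in net.mirna_records}
    tstate = {r.feature_id: _state(r) for r in net.target_records}
    instances: list[FflInstance] = []
    counts = {t: 0 for t in FFL_TYPES}
    for mid in sorted(net.target_map):
        if mstate.get(mid, 0) == 0:
            continue
        for tid in sorted(net.target_map[mid]):
            if tstate.get(tid, 0) == 0:
                continue
            ftype = _STATE_TO_TYPE[(mstate[mid], tstate[tid])]
            instances.append(FflInstance(tf=net.tf, mirna=mid, target=tid, type=ftype))
            counts[ftype] += 1
    return instances, counts


def _edge_arrays(net: FflNetwork) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    mids = [r.feature_id for r in net.mirna_records]
    tids = [r.feature_id for r in net.target_records]
    midx = {m: i for i, m in enumerate(mids)}
    tidx = {t: i for i, t in enumerate(tids)}
    e_m, e_t = [], []
    for m in sorted(net.target_map):
        for t in sorted(net.target_map[m]):
            e_m.append(midx[m])
            e_t.append(tidx[t])
    mstates = np.array([_state(r) for r in net.mirna_records], np.int8)
    tstates = np.array([_state(r) for r in net.target_records], np.int8)
    return mstates, tstates, np.asarray(e_m), np.asarray(e_t)


def _count_types(m_e: np.ndarray, t_e: np.ndarray) -> np.ndarray:
    """Per-type loop counts from per-edge states; works on 1-D (one network)
    or 2-D (randomizations x edges) arrays.  Order follows FFL_TYPES."""
    return np.stack([
        ((m_e == 2) & (t_e == 2)).sum(axis=-1),   # I1
        ((m_e == 1) & (t_e == 1)).sum(axis=-1),   # I2
        ((m_e == 2) & (t_e == 1)).sum(axis=-1),   # C3
        ((m_e == 1) & (t_e == 2)).sum(axis=-1),   # C4
    ], axis=-1)


def permutation_enrichment(
    net: FflNetwork,
    n_randomizations: int = 10_000,
    seed: int | None = None,
    permute: str = "all",
) -> EnrichmentResult:
    """Randomisation test for per-type loop enrichment.

    Each shuffle independently permutes the expression tuples among the
    miRNA nodes and among the target nodes while the miRNA->target map stays
    fixed; p(type) is the fraction of shuffles whose count reaches or
    exceeds the observed count, which keeps the test conservative under the
    null.  ``permute="significant"`` restricts the shuffle to
    significant nodes only (the alternative null in which non-responding
    features keep their status).
    """
    if n_randomizations < 1:
        raise ValueError("n_randomizations must be >= 1")
    if not net.mirna_records or not net.target_records:
        raise ValueError("degenerate network: no measured features")
    if permute not in ("all", "significant"):
        raise ValueError("permute must be 'all' or 'significant'")
    rng = np.random.default_rng(seed)
    mstates, tstates, e_m, e_t = _edge_arrays(net)
    observed = _count_types(mstates[e_m], tstates[e_t])

    def _permuted(states: np.ndarray) -> np.ndarray:
        tiled = np.tile(states, (n_randomizations, 1))
        if permute == "all":
            return rng.permuted(tiled, axis=1)
        idx = np.nonzero(states != 0)[0]
        sub = rng.permuted(tiled[:, idx], axis=1)
        tiled[:, idx] = sub
        return tiled

    m_perm = _permuted(mstates)
    t_perm = _permuted(tstates)
    if len(e_m):
        rand_counts = _count_types(m_perm[:, e_m], t_perm[:, e_t])
    else:
        rand_counts = np.zeros((n_randomizations, 4), int)

    p = (rand_counts >= observed).mean(axis=0)
    means = rand_counts.mean(axis=0)
    return EnrichmentResult(
        observed={t: int(observed[i]) for i, t in enumerate(FFL_TYPES)},
        randomized_mean={t: float(means[i]) for i, t in enumerate(FFL_TYPES)},
        p_value={t: float(p[i]) for i, t in enumerate(FFL_TYPES)},
        n_randomizations=n_randomizations,
    )


def annotate_direct(
    ffls: list[FflInstance],
    chip_targets: set[str],
    mirna_gene_map: dict[str, str],
) -> list[FflInstance]:
    """Mark loops as direct when ChIP supports binding at both the miRNA's
    hosting gene and the target."""
    out = []
    for f in ffls:
        host = mirna_gene_map.get(f.mirna)
        direct = host is not None and host in chip_targets and f.target in chip_targets
        out.append(replace(f, direct=direct))
    return out


def network_from_tables(
    tf: str,
    mirna_records: list[ExpressionRecord],
    gene_records: list[ExpressionRecord],
    target_map: dict[str, list[str]],
) -> FflNetwork:
    """Assemble the network: miRNAs appearing in the map with their records,
    and the measured genes referenced by the map."""
    measured_m = {r.feature_id for r in mirna_records}
    measured_g = {r.feature_id for r in gene_records}
    tmap = {m: sorted(set(ts) & measured_g)
            for m, ts in target_map.items() if m in measured_m}
    referenced = set().union(*tmap.values()) if tmap else set()
    return FflNetwork(
        tf=tf,
        mirna_records=list(mirna_records),
        target_records=[r for r in gene_records if r.feature_id in referenced],
        target_map=tmap,
    )


def write_instances(ffls: list[FflInstance], path) -> None:
    rows = [(f.tf, f.mirna, f.target, f.type, f.direct) for f in ffls]
    pd.DataFrame(rows, columns=["tf", "mirna", "target", "type", "direct"]).to_csv(
        path, sep="\t", index=False)
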