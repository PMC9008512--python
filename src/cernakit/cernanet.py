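"""ceRNA triplet integration, correlation filtering and network assembly.

Under the competing-endogenous-RNA hypothesis a lncRNA sponges a miRNA and
thereby de-represses that miRNA's mRNA targets.  Candidate triplets are all
(lncRNA, miRNA, mRNA) combinations in which one miRNA targets both the
lncRNA and the mRNA.  A triplet passes when, across the shared samples,

* Spearman rho(miRNA, lncRNA) < -0.6,
* Spearman rho(miRNA, mRNA)  < -0.6,
* Pearson  r(lncRNA, mRNA)   >  0.6,

all strict.  miRNA expression enters on the RPM scale and lncRNA/mRNA on
FPKM; Spearman is rank-based (scale-free) and Pearson is computed on
log2(FPKM + 1) by default.  The network keeps unique (miRNA, target) edges
of passed triplets; lncRNA-mRNA co-expression links are not edges.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._errors import ValidationError
from .containers import ExpressionMatrix
from .targets import TargetHit

DEFAULT_THRESHOLDS = (-0.6, -0.6, 0.6)

TRIPLET_COLUMNS = ["lncrna_id", "mirna_id", "mrna_id",
                   "scc_mir_lnc", "scc_mir_mrna", "pcc_lnc_mrna", "passed"]


@dataclass
class CeRNATriplet:
    lncrna_id: str
    mirna_id: str
    mrna_id: str
    scc_mir_lnc: float = np.nan
    scc_mir_mrna: float = np.nan
    pcc_lnc_mrna: float = np.nan
    passed: bool = False


@dataclass
class CeRNANetwork:
    """Deduplicated node/edge view over the passed triplets."""

    nodes: dict[str, str] = field(default_factory=dict)  # id -> type
    edges: set[tuple[str, str]] = field(default_factory=set)  # (miRNA, target)
    triplets: list[CeRNATriplet] = field(default_factory=list)


def correlate(x, y, method: str = "spearman") -> float:
    """Correlation coefficient; NaN flags an undefined (constant-input) case.

    Spearman uses average ranks for ties.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 3:
        raise ValidationError("need at least three observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if method == "spearman":
            return float(stats.spearmanr(x, y).statistic)
        if method == "pearson":
            return float(stats.pearsonr(x, y).statistic)
    raise ValidationError(f"unknown method {method!r}")


def assemble_triplets(mir2lnc: list[TargetHit], mir2mrna: list[TargetHit]
                      ) -> list[CeRNATriplet]:
    """All (lncRNA, miRNA, mRNA) combinations sharing the miRNA.

    Hit lists are deduplicated to the (miRNA, target) level first, so the
    triplet count is the product of target-set sizes summed over miRNAs.
    """
    lnc_of: dict[str, list[str]] = {}
    for h in mir2lnc:
        targets = lnc_of.setdefault(h.mirna_id, [])
        if h.transcript_id not in targets:
            targets.append(h.transcript_id)
    mrna_of: dict[str, list[str]] = {}
    for h in mir2mrna:
        targets = mrna_of.setdefault(h.mirna_id, [])
        if h.transcript_id not in targets:
            targets.append(h.transcript_id)
    out = []
    for mir in lnc_of:
        for lnc in lnc_of[mir]:
            for mrna in mrna_of.get(mir, []):
                out.append(CeRNATriplet(lncrna_id=lnc, mirna_id=mir,
                                        mrna_id=mrna))
    return out


def filter_triplets(triplets: list[CeRNATriplet],
                    expr_mirna: ExpressionMatrix,
                    expr_rna: ExpressionMatrix,
                    thresholds: tuple[float, float, float] = DEFAULT_THRESHOLDS,
                    samples: list[str] | None = None,
                    log_pcc: bool = True) -> CeRNANetwork:
    """Correlation-filter candidate triplets and build the network.

    Triplets with members missing from the matrices are skipped with a
    warning.  Constant-expression members give undefined correlations and
    fail.  All three thresholds are strict inequalities.
    """
    t_mir_lnc, t_mir_mrna, t_lnc_mrna = thresholds
    if samples is None:
        samples = [s for s in expr_rna.sample_ids
                   if s in set(expr_mirna.sample_ids)]
    if len(samples) < 3:
        raise ValidationError("need at least three shared samples")
    rna = expr_rna.values[samples]
    mir = expr_mirna.values[samples]
    rna_log = np.log2(rna + 1.0) if log_pcc else rna

    net = CeRNANetwork()
    evaluated: list[CeRNATriplet] = []
    for t in triplets:
        missing = [i for i, frame in ((t.mirna_id, mir), (t.lncrna_id, rna),
                                      (t.mrna_id, rna))
                   if i not in frame.index]
        if missing:
            warnings.warn(f"triplet members missing from matrices, "
                          f"skipped: {missing}", stacklevel=2)
            continue
        v_mir = mir.loc[t.mirna_id].to_numpy()
        v_lnc = rna.loc[t.lncrna_id].to_numpy()
        v_mrna = rna.loc[t.mrna_id].to_numpy()
        t.scc_mir_lnc = correlate(v_mir, v_lnc, "spearman")
        t.scc_mir_mrna = correlate(v_mir, v_mrna, "spearman")
        t.pcc_lnc_mrna = correlate(rna_log.loc[t.lncrna_id].to_numpy(),
                                   rna_log.loc[t.mrna_id].to_numpy(),
                                   "pearson")
        t.passed = bool(
            t.scc_mir_lnc < t_mir_lnc
            and t.scc_mir_mrna < t_mir_mrna
            and t.pcc_lnc_mrna > t_lnc_mrna)
        evaluated.append(t)

    net.triplets = [t for t in evaluated if t.passed]
    for t in net.triplets:
        net.nodes[t.lncrna_id] = "lncRNA"
        net.nodes[t.mirna_id] = "miRNA"
        net.nodes[t.mrna_id] = "mRNA"
        net.edges.add((t.mirna_id, t.lncrna_id))
        net.edges.add((t.mirna_id, t.mrna_id))
    net.all_candidates = evaluated  # type: ignore[attr-defined]
    return net


def summarize_network(net: CeRNANetwork) -> dict[str, int]:
    """Triplet, node (total and per type) and unique-edge counts."""
    by_type = {"lncRNA": 0, "miRNA": 0, "mRNA": 0}
    for t in net.nodes.values():
        by_type[t] += 1
    return {
        "n_triplets": len(net.triplets),
        "n_nodes": len(net.nodes),
        "n_lncrna": by_type["lncRNA"],
        "n_mirna": by_type["miRNA"],
        "n_mrna": by_type["mRNA"],
        "n_edges": len(net.edges),
    }


def subnetwork_by_genes(net: CeRNANetwork, gene_set) -> CeRNANetwork:
    """Restrict to passed triplets whose mRNA is in ``gene_set``; nodes and
    edges are rebuilt from the kept triplets."""
    gene_set = set(gene_set)
    if not gene_set:
        raise ValidationError("gene_set must be non-empty")
    sub = CeRNANetwork()
    sub.triplets = [t for t in net.triplets if t.mrna_id in gene_set]
    for t in sub.triplets:
        sub.nodes[t.lncrna_id] = "lncRNA"
        sub.nodes[t.mirna_id] = "miRNA"
        sub.nodes[t.mrna_id] = "mRNA"
        sub.edges.add((t.mirna_id, t.lncrna_id))
        sub.edges.add((t.mirna_id, t.mrna_id))
    return sub


# ---------------------------------------------------------------- export

def triplet_table(triplets: list[CeRNATriplet]) -> pd.DataFrame:
    return pd.DataFrame(
        [[t.lncrna_id, t.mirna_id, t.mrna_id, t.scc_mir_lnc,
          t.scc_mir_mrna, t.pcc_lnc_mrna, t.passed] for t in triplets],
        columns=TRIPLET_COLUMNS)


def edge_table(net: CeRNANetwork) -> pd.DataFrame:
    rows = []
    for mir, tgt in sorted(net.edges):
        kind = "mir-lnc" if net.nodes.get(tgt) == "lncRNA" else "mir-mrna"
        rows.append([mir, kind, tgt])
    return pd.DataFrame(rows, columns=["mirna_id", "interaction", "target_id"])


def write_sif(net: CeRNANetwork, path) -> None:
    """Cytoscape simple-interaction format: node1 TAB interaction TAB node2."""
    with open(path, "w") as fh:
        for _, row in edge_table(net).iterrows():
            fh.write(f"{row.mirna_id}\t{row.interaction}\t{row.target_id}\n")
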