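"""Synthetic staged-bud transcriptome with planted ground truth.

The generator emulates the study design the rest of the toolkit targets:
12 libraries = 4 developmental stages (ST1, ST2, ST3-1, ST3-2) x 3
biological replicates, negative-binomial counts for mRNAs+lncRNAs, an
RPM-scale abundance matrix for miRNAs, and a small two-chromosome genome
annotation.  Planted structure, all recorded in machine-readable truth
tables:

* temporal prototypes (up, down, peak at ST2, peak at ST3-1, flat) acting
  multiplicatively on a lognormal baseline; flat is the majority class so
  null behaviour is testable;
* ceRNA triplets: a miRNA with a "down" profile whose exact 21-nt
  reverse-complement site is written into one "up" lncRNA and one "up"
  mRNA, so the miRNA anti-correlates with both partners while they
  co-express;
* cis lncRNA-gene neighbours at a recorded distance <= 10 kb, with every
  other adjacent feature placed > 10 kb apart (decoys);
* a term->gene map whose prototype terms cover exactly the mRNAs of each
  temporal class, for enrichment testing.

Decoy transcripts are rejection-sampled so no miRNA has a site at or below
the target-scanner cutoff anywhere in the background; lncRNA sequences are
rejection-sampled to fail the coding-potential rule and mRNAs always carry
a long ORF.  Identical configs (including the seed) give byte-identical
outputs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._errors import GenerationError, ValidationError
from .containers import ExpressionMatrix, TranscriptRecord
from .io import (write_fasta, write_gff3, write_matrix, write_sample_sheet,
                 write_tsv)
from .targets import reverse_complement, site_expectations
from .txclass import coding_potential

PROTOTYPES = ("up", "down", "peak2", "peak3", "flat")
_BASES = np.array(list("ACGT"))
_STOPS = {"TAA", "TAG", "TGA"}
_SENSE_CODONS = ["".join(c) for c in itertools.product("ACGT", repeat=3)
                 if "".join(c) not in _STOPS]
_MAX_REJECT = 200


@dataclass
class SyntheticConfig:
    """Study-design parameters of the generator.

    Defaults reproduce the conditions the toolkit's recovery tests assume:
    strong temporal effects (4-fold), low biological dispersion within a
    stage, 4 stages x 3 replicates.
    """

    n_mrna: int = 60
    n_lncrna: int = 30
    n_mirna: int = 12
    n_stages: int = 4
    n_reps: int = 3
    n_triplets: int = 3
    n_cis_pairs: int = 5
    dispersion: float = 0.02
    baseline_log_mean: float = 5.0
    effect_size: float = 4.0
    seed: int = 0
    de_fraction: float = 0.4          # non-flat share of non-planted features
    mirna_length: int = 21
    chrom_lengths: tuple[int, int] = (2_000_000, 2_000_000)
    site_cutoff: float = 5.0          # decoys must stay above this
    min_orf_aa: int = 100
    min_orf_coverage: float = 0.5

    def __post_init__(self) -> None:
        if self.n_stages < 2:
            raise ValidationError("n_stages must be at least 2")
        if self.n_reps < 1:
            raise ValidationError("n_reps must be at least 1")
        if self.dispersion < 0:
            raise ValidationError("dispersion must be non-negative")
        for name in ("n_mrna", "n_lncrna", "n_mirna", "n_triplets",
                     "n_cis_pairs"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")
        if self.n_triplets > min(self.n_mrna, self.n_lncrna, self.n_mirna):
            raise ValidationError("n_triplets exceeds available features")
        if self.effect_size < 1:
            raise ValidationError("effect_size must be at least 1")


@dataclass
class SyntheticTruth:
    planted_triplets: list[tuple[str, str, str]]   # (lncRNA, miRNA, mRNA)
    prototype_of: dict[str, str]
    de_status: dict[str, dict[str, bool]]          # feature -> comparison -> DE
    cis_pairs: list[tuple[str, str, int]]          # (lncRNA, gene, distance bp)


@dataclass
class SyntheticDataset:
    annotation: list[TranscriptRecord]
    sequences: dict[str, str]
    mirna_sequences: dict[str, str]
    counts_rna: ExpressionMatrix
    abundance_mirna: ExpressionMatrix
    truth: SyntheticTruth
    term2genes: dict[str, set[str]] = field(default_factory=dict)
    stage_labels: list[str] = field(default_factory=list)


# ------------------------------------------------------------ primitives

def simulate_counts(mean: float, dispersion: float, n: int,
                    rng: np.random.Generator | int = 0) -> np.ndarray:
    """``n`` negative-binomial draws via the Gamma-Poisson mixture.

    Variance is mean + dispersion * mean^2; dispersion 0 degenerates to
    Poisson and mean 0 to the point mass at 0.
    """
    if mean < 0 or dispersion < 0:
        raise ValidationError("mean and dispersion must be non-negative")
    if n < 1:
        raise ValidationError("n must be at least 1")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    if mean == 0:
        return np.zeros(n, dtype=np.int64)
    if dispersion == 0:
        return rng.poisson(mean, size=n)
    lam = rng.gamma(shape=1.0 / dispersion, scale=mean * dispersion, size=n)
    return rng.poisson(lam)


def prototype_profiles(n_stages: int = 4, effect_size: float = 4.0
                       ) -> dict[str, np.ndarray]:
    """Stage-mean multiplier vectors for the five temporal prototypes.

    "up" is a non-decreasing geometric ramp whose largest step sits at the
    middle transition (so staged comparisons concentrate differential
    signal mid-series, as bud transcriptomes do); "down" is its reverse;
    "peak2"/"peak3" rise linearly to a maximum at stages 2 and 3 then fall
    back; "flat" is constant 1.
    """
    if n_stages < 2:
        raise ValidationError("n_stages must be at least 2")
    e = float(effect_size)
    w = np.ones(n_stages - 1)
    w[(n_stages - 1) // 2] = 10.0
    cum = np.concatenate([[0.0], np.cumsum(w)]) / w.sum()
    up = e ** cum

    def peak_at(p: int) -> np.ndarray:
        p = min(p, n_stages - 1)
        v = np.ones(n_stages)
        for i in range(n_stages):
            if i <= p:
                frac = i / p if p else 1.0
            else:
                frac = (n_stages - 1 - i) / (n_stages - 1 - p)
            v[i] = 1.0 + (e - 1.0) * frac
        return v

    return {
        "up": up,
        "down": up[::-1].copy(),
        "peak2": peak_at(1),
        "peak3": peak_at(2),
        "flat": np.ones(n_stages),
    }


# ------------------------------------------------------------ sequences

def _random_seq(rng: np.random.Generator, length: int,
                gc: float = 0.5) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(_BASES[rng.choice(4, size=length, p=p)])


def _has_site(seq: str, mirnas: dict[str, str], cutoff: float,
              ignore: set[str] = frozenset()) -> bool:
    for mid, mseq in mirnas.items():
        if mid in ignore:
            continue
        scores = site_expectations(mseq, seq)
        if scores.size and scores.min() <= cutoff:
            return True
    return False


def _make_mrna_seq(rng: np.random.Generator) -> str:
    utr5 = _random_seq(rng, int(rng.integers(30, 120)), gc=0.45)
    n_aa = int(rng.integers(120, 300))
    codons = [_SENSE_CODONS[i]
              for i in rng.integers(0, len(_SENSE_CODONS), size=n_aa)]
    stop = ("TAA", "TAG", "TGA")[rng.integers(0, 3)]
    utr3 = _random_seq(rng, int(rng.integers(150, 450)), gc=0.45)
    return utr5 + "ATG" + "".join(codons) + stop + utr3


def _make_lncrna_seq(rng: np.random.Generator, cfg: SyntheticConfig) -> str:
    for _ in range(_MAX_REJECT):
        seq = _random_seq(rng, int(rng.integers(300, 1200)), gc=0.38)
        cp = coding_potential(seq, min_orf_aa=cfg.min_orf_aa,
                              min_coverage=cfg.min_orf_coverage)
        if cp.label == "non-coding":
            return seq
    raise GenerationError("could not sample a non-coding lncRNA sequence")


def _insert_site(seq: str, site: str, pos: int) -> str:
    """Overwrite ``len(site)`` bases starting at 0-based ``pos``."""
    return seq[:pos] + site + seq[pos + len(site):]


# ------------------------------------------------------------ generator

def stage_labels(n_stages: int) -> list[str]:
    if n_stages == 4:
        return ["ST1", "ST2", "ST3-1", "ST3-2"]
    return [f"ST{i + 1}" for i in range(n_stages)]


def generate_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Generate the full synthetic dataset with its truth tables."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    stages = stage_labels(cfg.n_stages)
    protos = prototype_profiles(cfg.n_stages, cfg.effect_size)

    mrna_ids = [f"G{i + 1:04d}" for i in range(cfg.n_mrna)]
    lnc_ids = [f"L{i + 1:04d}" for i in range(cfg.n_lncrna)]
    mir_ids = [f"miR{i + 1:03d}" for i in range(cfg.n_mirna)]

    # --- miRNA sequences (distinct)
    mirna_seqs: dict[str, str] = {}
    for mid in mir_ids:
        for _ in range(_MAX_REJECT):
            seq = _random_seq(rng, cfg.mirna_length)
            if seq not in mirna_seqs.values():
                mirna_seqs[mid] = seq
                break
        else:
            raise GenerationError("could not sample distinct miRNA sequences")

    # --- planted triplets: first n_triplets of each id list
    triplets = [(lnc_ids[i], mir_ids[i], mrna_ids[i])
                for i in range(cfg.n_triplets)]

    # --- prototype assignment
    prototype_of: dict[str, str] = {}
    for lnc, mir, mrna in triplets:
        prototype_of[lnc] = "up"
        prototype_of[mrna] = "up"
        prototype_of[mir] = "down"
    free = [f for f in mrna_ids + lnc_ids if f not in prototype_of]
    n_de = int(round(cfg.de_fraction * len(free)))
    shapes = ["up", "down", "peak2", "peak3"]
    order = rng.permutation(len(free))
    for rank, idx in enumerate(order):
        prototype_of[free[idx]] = shapes[rank % 4] if rank < n_de else "flat"
    for mir in mir_ids:
        prototype_of.setdefault(mir, "flat")

    # --- DE truth per adjacent comparison, from the prototype multipliers
    comparisons = [f"{a}_vs_{b}" for a, b in zip(stages, stages[1:])]
    de_status: dict[str, dict[str, bool]] = {}
    for fid, label in prototype_of.items():
        v = protos[label]
        de_status[fid] = {
            comp: bool(abs(np.log2(v[i + 1] / v[i])) > 1.0)
            for i, comp in enumerate(comparisons)}

    # --- sequences; decoys must carry no site for any miRNA
    sequences: dict[str, str] = {}
    planted_target_of = {t: mir for (lnc, mir, mrna) in triplets
                         for t in (lnc, mrna)}
    for tid in mrna_ids + lnc_ids:
        is_mrna = tid.startswith("G")
        planted_mir = planted_target_of.get(tid)
        for _ in range(_MAX_REJECT):
            seq = (_make_mrna_seq(rng) if is_mrna
                   else _make_lncrna_seq(rng, cfg))
            if planted_mir is not None:
                site = reverse_complement(mirna_seqs[planted_mir])
                lo = len(seq) - (250 if is_mrna else len(seq) // 2)
                pos = int(rng.integers(max(0, lo), len(seq) - len(site)))
                seq = _insert_site(seq, site, pos)
                if not is_mrna:
                    cp = coding_potential(
                        seq, min_orf_aa=cfg.min_orf_aa,
                        min_coverage=cfg.min_orf_coverage)
                    if cp.label == "coding":
                        continue
            if _has_site(seq, mirna_seqs, cfg.site_cutoff,
                         ignore={planted_mir} if planted_mir else set()):
                continue
            sequences[tid] = seq
            break
        else:
            raise GenerationError(
                f"could not sample a site-free sequence for {tid}")

    # --- genomic placement: cis pairs adjacent within 10 kb, all other
    #     neighbours separated by > 10 kb
    used = set(planted_target_of)
    cis_lnc = [l for l in lnc_ids if l not in used][:cfg.n_cis_pairs]
    cis_gene = [g for g in mrna_ids if g not in used][:cfg.n_cis_pairs]
    if len(cis_lnc) < cfg.n_cis_pairs or len(cis_gene) < cfg.n_cis_pairs:
        raise GenerationError("not enough free features for cis pairs")
    cis_partner = dict(zip(cis_lnc, cis_gene))

    units: list[list[str]] = []
    in_pair = set(cis_partner) | set(cis_partner.values())
    units += [[l, g] for l, g in cis_partner.items()]
    units += [[f] for f in mrna_ids + lnc_ids if f not in in_pair]
    perm = rng.permutation(len(units))
    units = [units[i] for i in perm]

    annotation: list[TranscriptRecord] = []
    cis_records: list[tuple[str, str, int]] = []
    n_chrom = len(cfg.chrom_lengths)
    cursors = [1] * n_chrom
    chrom_of_unit = [i % n_chrom for i in range(len(units))]
    for unit, ci in zip(units, chrom_of_unit):
        chrom = f"chr{ci + 1}"
        pos = cursors[ci] + int(rng.integers(10_050, 15_000))
        for j, fid in enumerate(unit):
            if j > 0:   # cis partner: recorded gap <= 10 kb
                gap = int(rng.integers(200, 10_001))
                pos = prev_end + gap + 1
                cis_records.append((unit[0], fid, gap))
            seq = sequences[fid]
            end = pos + len(seq) - 1
            if end > cfg.chrom_lengths[ci]:
                raise GenerationError(
                    f"chromosome {chrom} too short ({cfg.chrom_lengths[ci]} "
                    f"bp) for the requested features; increase chrom_lengths")
            is_mrna = fid.startswith("G")
            annotation.append(TranscriptRecord(
                id=fid, chrom=chrom, strand="+-"[rng.integers(0, 2)],
                start=pos, end=end,
                class_code="=" if is_mrna else "uixo"[rng.integers(0, 4)],
                exon_count=(int(rng.integers(2, 11)) if is_mrna
                            else (1 if rng.random() < 0.75
                                  else int(rng.integers(2, 4)))),
                sequence=seq,
                biotype="mRNA" if is_mrna else "lncRNA",
            ))
            prev_end = end
            pos = end + 1
        cursors[ci] = prev_end

    # --- expression
    sample_ids = [f"S{i + 1}" for i in range(cfg.n_stages * cfg.n_reps)]
    meta = pd.DataFrame(
        {"stage": [stages[i // cfg.n_reps] for i in range(len(sample_ids))],
         "replicate": [i % cfg.n_reps + 1 for i in range(len(sample_ids))]},
        index=pd.Index(sample_ids, name="sample_id"))

    def expression_for(ids: list[str]) -> pd.DataFrame:
        rows = np.zeros((len(ids), len(sample_ids)), dtype=np.int64)
        for r, fid in enumerate(ids):
            base = float(rng.lognormal(cfg.baseline_log_mean, 0.5))
            mult = protos[prototype_of[fid]]
            for s in range(cfg.n_stages):
                draws = simulate_counts(base * mult[s], cfg.dispersion,
                                        cfg.n_reps, rng)
                rows[r, s * cfg.n_reps:(s + 1) * cfg.n_reps] = draws
        return pd.DataFrame(rows, index=ids, columns=sample_ids)

    counts_rna = ExpressionMatrix(
        values=expression_for(mrna_ids + lnc_ids), unit="counts",
        sample_meta=meta)
    abundance_mirna = ExpressionMatrix(
        values=expression_for(mir_ids).astype(float), unit="RPM",
        sample_meta=meta)

    # --- annotation-term map: prototype terms + random decoy terms
    term2genes: dict[str, set[str]] = {
        f"TERM:{shape}": {g for g in mrna_ids if prototype_of[g] == shape}
        for shape in shapes}
    for i in range(3):
        size = int(rng.integers(5, max(6, cfg.n_mrna // 4)))
        members = rng.choice(cfg.n_mrna, size=min(size, cfg.n_mrna),
                             replace=False)
        term2genes[f"TERM:random{i + 1}"] = {mrna_ids[j] for j in members}

    truth = SyntheticTruth(
        planted_triplets=triplets, prototype_of=prototype_of,
        de_status=de_status, cis_pairs=cis_records)
    return SyntheticDataset(
        annotation=annotation, sequences=sequences,
        mirna_sequences=mirna_seqs, counts_rna=counts_rna,
        abundance_mirna=abundance_mirna, truth=truth,
        term2genes=term2genes, stage_labels=stages)


# ------------------------------------------------------------ output

def write_dataset(ds: SyntheticDataset, outdir) -> dict[str, Path]:
    """Emit the dataset as GFF3 + FASTA + TSV files; returns the manifest."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "annotation": out / "annotation.gff3",
        "transcripts": out / "transcripts.fa",
        "mirna_mature": out / "mirna_mature.fa",
        "counts_rna": out / "counts_rna.tsv",
        "mirna_rpm": out / "mirna_rpm.tsv",
        "samples": out / "samples.tsv",
        "term2genes": out / "term2genes.tsv",
        "truth_triplets": out / "truth_triplets.tsv",
        "truth_prototypes": out / "truth_prototypes.tsv",
        "truth_de": out / "truth_de.tsv",
        "truth_cis": out / "truth_cis.tsv",
    }
    write_gff3(ds.annotation, paths["annotation"])
    write_fasta(ds.sequences, paths["transcripts"])
    write_fasta(ds.mirna_sequences, paths["mirna_mature"])
    write_matrix(ds.counts_rna, paths["counts_rna"])
    write_matrix(ds.abundance_mirna, paths["mirna_rpm"])
    write_sample_sheet(ds.counts_rna.sample_meta, paths["samples"])
    write_tsv(pd.DataFrame(
        [(t, g) for t, genes in sorted(ds.term2genes.items())
         for g in sorted(genes)], columns=["term_id", "gene_id"]),
        paths["term2genes"])
    write_tsv(pd.DataFrame(ds.truth.planted_triplets,
                           columns=["lncrna_id", "mirna_id", "mrna_id"]),
              paths["truth_triplets"])
    write_tsv(pd.DataFrame(sorted(ds.truth.prototype_of.items()),
                           columns=["feature_id", "prototype"]),
              paths["truth_prototypes"])
    de_rows = [(f, c, int(v)) for f, d in sorted(ds.truth.de_status.items())
               for c, v in d.items()]
    write_tsv(pd.DataFrame(de_rows,
                           columns=["feature_id", "comparison", "is_de"]),
              paths["truth_de"])
    write_tsv(pd.DataFrame(ds.truth.cis_pairs,
                           columns=["lncrna_id", "gene_id", "distance_bp"]),
              paths["truth_cis"])
    return paths
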