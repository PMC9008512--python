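"""miRNA target scanning, cis-window pairing and trans pairing-energy.

Three relationship predictors used to wire the regulatory network:

* :func:`scan_targets` — a psRNATarget-style expectation score.  The reverse
  complement of the miRNA is slid (ungapped) along the transcript; each
  aligned position contributes a penalty (match 0, G:U wobble 0.5, mismatch
  1.0) and penalties are doubled in the seed region, miRNA positions 2-13
  counted 5'->3'.  The expectation of a site is the total penalty; low is
  good, 0 is perfect complementarity.
* :func:`cis_pairs` — lncRNA/gene neighbourhoods: a pair is reported when
  both lie on the same chromosome with a genomic gap of at most ``window``
  bp (10 kb by default, inclusive; overlap counts as distance 0).  Strand is
  ignored for the distance and used only to orient the reported relation.
* :func:`trans_pairs` — an lncTar-flavoured base-pairing energy: the best
  ungapped antiparallel window alignment between the two transcripts under
  per-pair energies GC=-3, AU=-2, GU=-1, scored as dg and normalised by the
  shorter transcript length (ndg); pairs at or below the (negative)
  threshold are reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._errors import ValidationError
from .containers import TranscriptRecord

# Base encoding: A=0, C=1, G=2, T/U=3.
_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3, "N": 4}
_COMPLEMENT = str.maketrans("ACGTUN", "TGCAAN")

#: penalty[miRNA base, target base]; N (code 4) always counts as a mismatch.
_PENALTY = np.ones((5, 5))
for _m, _t in ((0, 3), (1, 2), (2, 1), (3, 0)):   # Watson-Crick
    _PENALTY[_m, _t] = 0.0
_PENALTY[2, 3] = 0.5   # miRNA G : target U
_PENALTY[3, 2] = 0.5   # miRNA U : target G

#: pair energy[base a, base b] for trans pairing (antiparallel).
_ENERGY = np.zeros((5, 5))
for _a, _b in ((2, 1), (1, 2)):
    _ENERGY[_a, _b] = -3.0   # G:C
for _a, _b in ((0, 3), (3, 0)):
    _ENERGY[_a, _b] = -2.0   # A:U
for _a, _b in ((2, 3), (3, 2)):
    _ENERGY[_a, _b] = -1.0   # G:U

SEED_START, SEED_END = 2, 13   # miRNA positions with doubled penalty, 1-based


def _encode(seq: str) -> np.ndarray:
    seq = seq.upper().replace("U", "T")
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValidationError(f"non-nucleotide characters: {sorted(bad)}")
    return np.frombuffer(seq.encode().translate(
        bytes.maketrans(b"ACGTN", bytes([0, 1, 2, 3, 4]))), dtype=np.uint8)


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


@dataclass
class TargetHit:
    """One predicted miRNA binding site on a transcript."""

    mirna_id: str
    transcript_id: str
    site_start: int          # 1-based on the transcript
    expectation: float
    alignment: tuple[str, str, str]   # miRNA 3'->5', pairing row, target 5'->3'


@dataclass
class CisPair:
    lncrna_id: str
    gene_id: str
    distance: int            # bp; 0 when the intervals overlap
    relation: str            # upstream | downstream | overlapping


@dataclass
class TransPair:
    lncrna_id: str
    mrna_id: str
    ndg: float               # length-normalised pairing energy, <= 0 useful
    dg: float
    window_start_lnc: int    # 1-based
    window_start_mrna: int


def site_expectations(mirna_seq: str, transcript_seq: str) -> np.ndarray:
    """Expectation score at every sliding offset (vectorised core)."""
    m = _encode(mirna_seq)
    t = _encode(transcript_seq)
    L = len(m)
    if len(t) < L:
        return np.empty(0)
    # target window position i (left->right, 5'->3') pairs with miRNA
    # position p = L - i (1-based, 5'->3'): the duplex is antiparallel.
    m_at_i = m[::-1]                      # miRNA base facing window slot i
    weights = np.ones(L)
    p = L - np.arange(L)                  # miRNA position per slot
    weights[(p >= SEED_START) & (p <= SEED_END)] = 2.0
    windows = np.lib.stride_tricks.sliding_window_view(t, L)
    pen = _PENALTY[m_at_i[None, :], windows]
    return (pen * weights).sum(axis=1)


def _alignment_strings(mirna_seq: str, window_seq: str) -> tuple[str, str, str]:
    mir_3to5 = mirna_seq.upper().replace("T", "U")[::-1]
    tgt = window_seq.upper()
    row = []
    for mb, tb in zip(mir_3to5, tgt):
        mb_dna = mb.replace("U", "T")
        if tb == mb_dna.translate(_COMPLEMENT):
            row.append("|")
        elif (mb_dna == "G" and tb == "T") or (mb_dna == "T" and tb == "G"):
            row.append("o")
        else:
            row.append(" ")
    return mir_3to5, "".join(row), tgt


def scan_targets(mirna_seq: str, transcript_seq: str, *,
                 mirna_id: str = "miRNA", transcript_id: str = "transcript",
                 cutoff: float = 5.0) -> list[TargetHit]:
    """Best-scoring site (plus ties) with expectation <= ``cutoff``.

    Equality with the cutoff is a hit.  Returns an empty list when the best
    site scores above the cutoff or the transcript is shorter than the
    miRNA.
    """
    if not 18 <= len(mirna_seq) <= 26:
        raise ValidationError(
            f"miRNA length {len(mirna_seq)} outside 18-26 nt")
    scores = site_expectations(mirna_seq, transcript_seq)
    if scores.size == 0:
        return []
    best = scores.min()
    if best > cutoff:
        return []
    hits = []
    L = len(mirna_seq)
    for off in np.flatnonzero(scores == best):
        window = transcript_seq[off:off + L]
        hits.append(TargetHit(
            mirna_id=mirna_id, transcript_id=transcript_id,
            site_start=int(off) + 1, expectation=float(best),
            alignment=_alignment_strings(mirna_seq, window),
        ))
    return hits


def scan_target_table(mirnas: dict[str, str], transcripts: dict[str, str],
                      cutoff: float = 5.0) -> list[TargetHit]:
    """All (miRNA, transcript) hits at the given cutoff."""
    out: list[TargetHit] = []
    for mid, mseq in mirnas.items():
        for tid, tseq in transcripts.items():
            out.extend(scan_targets(
                mseq, tseq, mirna_id=mid, transcript_id=tid, cutoff=cutoff))
    return out


# ---------------------------------------------------------------- cis

def interval_gap(start_a: int, end_a: int, start_b: int, end_b: int) -> int:
    """Gap in bp between two 1-based inclusive intervals; 0 when overlapping.

    For disjoint [a1,b1], [a2,b2] with b1 < a2 the gap is a2 - b1 - 1
    (the number of bases strictly between them).
    """
    if end_a < start_b:
        return start_b - end_a - 1
    if end_b < start_a:
        return start_a - end_b - 1
    return 0


def cis_pairs(lncrnas: list[TranscriptRecord], genes: list[TranscriptRecord],
              window: int = 10_000) -> list[CisPair]:
    """All lncRNA/gene pairs on the same chromosome within ``window`` bp.

    The boundary is inclusive ("10 kb" means gap <= 10000).  The relation is
    oriented by the lncRNA's strand: a gene 5' of the lncRNA is upstream.
    """
    out: list[CisPair] = []
    for lnc in lncrnas:
        for g in genes:
            if lnc.chrom != g.chrom or lnc.id == g.id:
                continue
            gap = interval_gap(lnc.start, lnc.end, g.start, g.end)
            if gap > window:
                continue
            if gap == 0:
                relation = "overlapping"
            else:
                gene_is_left = g.end < lnc.start
                if lnc.strand == "+":
                    relation = "upstream" if gene_is_left else "downstream"
                else:
                    relation = "downstream" if gene_is_left else "upstream"
            out.append(CisPair(lncrna_id=lnc.id, gene_id=g.id,
                               distance=gap, relation=relation))
    return out


# ---------------------------------------------------------------- trans

def trans_pairs(lnc_seq: str, mrna_seq: str, *,
                lncrna_id: str = "lncRNA", mrna_id: str = "mRNA",
                window: int = 40, threshold: float = -0.1
                ) -> list[TransPair]:
    """Best ungapped antiparallel window duplex between two transcripts.

    dg is minimised (most negative) over all window-offset pairs; ndg divides
    by the shorter transcript length.  The single best pair is returned when
    ndg <= threshold, else nothing.
    """
    if len(lnc_seq) < window or len(mrna_seq) < window:
        raise ValidationError(
            f"sequences must be at least the window length ({window} nt)")
    a = _encode(lnc_seq)
    b = _encode(mrna_seq)[::-1]           # antiparallel: reverse the mRNA
    n, m = len(a), len(b)
    score = _ENERGY[a[:, None], b[None, :]]
    best = (0.0, 0, 0)
    # window sums along every diagonal of the pair-score matrix
    for d in range(-(n - window), m - window + 1):
        diag = np.diagonal(score, offset=d)
        if diag.size < window:
            continue
        sums = np.convolve(diag, np.ones(window), mode="valid")
        k = int(np.argmin(sums))
        if sums[k] < best[0]:
            i = k + max(0, -d)            # row (lnc) index of window start
            j = k + max(0, d)             # column index in reversed mRNA
            best = (float(sums[k]), i, j)
    dg, i, j = best
    ndg = dg / min(len(lnc_seq), len(mrna_seq))
    if ndg > threshold:
        return []
    # convert reversed-mRNA column back to a 1-based 5'->3' position
    mrna_start = m - (j + window) + 1
    return [TransPair(lncrna_id=lncrna_id, mrna_id=mrna_id, ndg=ndg, dg=dg,
                      window_start_lnc=i + 1, window_start_mrna=mrna_start)]
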