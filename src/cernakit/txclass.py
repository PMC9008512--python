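"""lncRNA identification cascade, small-RNA cataloguing and feature summary.

A transcript is called lncRNA when it survives three filters applied in
order: (1) a GffCompare class code in {u, i, x, o} — i.e. it does not match
a reference protein-coding model; (2) spliced length strictly greater than
200 nt; (3) no evidence of protein-coding capacity.  The coding-potential
call here is a self-contained ORF rule (longest forward-frame ORF and its
coverage of the transcript) standing in for consensus tools that require
external databases; its thresholds are exposed so users can tighten or relax
the call.

Small-RNA reads are catalogued against a set of known mature miRNAs by
ungapped equal-length matching with at most one mismatch (Hamming distance),
after discarding reads shorter than 18 nt.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._errors import ValidationError
from .containers import LNCRNA_CLASS_CODES, TranscriptRecord

MIN_LNCRNA_LENGTH = 200      # strict: length must exceed this
_START = "ATG"
_STOPS = {"TAA", "TAG", "TGA"}


@dataclass
class CodingPotentialResult:
    transcript_id: str
    longest_orf_aa: int
    orf_coverage: float
    label: str               # "coding" | "non-coding"


@dataclass
class SmallRNARecord:
    sequence: str
    length: int
    status: str              # "conserved" | "unassigned"
    matched_mature_id: str | None
    mismatches: int | None


def filter_lncrna_candidates(transcripts: list[TranscriptRecord]
                             ) -> list[TranscriptRecord]:
    """Positional + length filter: class code in {u,i,x,o} and length > 200 nt.

    Input order is preserved; records missing a class code raise a
    validation error naming them.
    """
    missing = [t.id for t in transcripts if t.class_code is None]
    if missing:
        raise ValidationError(f"records without class_code: {missing}")
    return [t for t in transcripts
            if t.class_code in LNCRNA_CLASS_CODES
            and t.length > MIN_LNCRNA_LENGTH]


def coding_potential(sequence: str, transcript_id: str = "",
                     min_orf_aa: int = 100, min_coverage: float = 0.5
                     ) -> CodingPotentialResult:
    """ORF-based coding call over the three forward frames.

    An ORF is an in-frame ATG..stop; its length in aa counts the codons
    from the ATG up to (not including) the stop.  ``coding`` when the
    longest ORF reaches ``min_orf_aa`` amino acids or covers
    ``min_coverage`` of the transcript (ORF nt incl. start and stop codons
    over transcript length).
    """
    if not sequence:
        raise ValidationError("empty sequence")
    seq = sequence.upper().replace("U", "T")
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValidationError(f"non-nucleotide characters: {sorted(bad)}")
    best_nt = 0
    for frame in range(3):
        i = frame
        while i + 3 <= len(seq):
            if seq[i:i + 3] == _START:
                j = i + 3
                while j + 3 <= len(seq):
                    if seq[j:j + 3] in _STOPS:
                        best_nt = max(best_nt, j + 3 - i)
                        break
                    j += 3
                # an ORF without a stop codon does not count
            i += 3
    # aa = codons from ATG to just before the stop
    longest_aa = max(0, best_nt // 3 - 1)
    coverage = best_nt / len(seq)
    label = ("coding" if longest_aa >= min_orf_aa or coverage >= min_coverage
             else "non-coding")
    return CodingPotentialResult(
        transcript_id=transcript_id, longest_orf_aa=longest_aa,
        orf_coverage=coverage, label=label)


def classify_transcripts(transcripts: list[TranscriptRecord],
                         min_orf_aa: int = 100, min_coverage: float = 0.5
                         ) -> list[TranscriptRecord]:
    """Apply the full cascade; every record comes back labelled.

    ``biotype`` is set to ``lncRNA`` for survivors and ``other`` for
    everything else — records are never dropped.
    """
    candidates = {t.id for t in filter_lncrna_candidates(transcripts)}
    out = []
    for t in transcripts:
        biotype = "other"
        if t.id in candidates:
            if t.sequence is None:
                raise ValidationError(f"{t.id}: candidate without sequence")
            cp = coding_potential(t.sequence, t.id, min_orf_aa, min_coverage)
            if cp.label == "non-coding":
                biotype = "lncRNA"
        out.append(TranscriptRecord(
            id=t.id, chrom=t.chrom, strand=t.strand, start=t.start,
            end=t.end, class_code=t.class_code, exon_count=t.exon_count,
            sequence=t.sequence, biotype=biotype))
    return out


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def catalog_small_rna(sequences: list[str], known_mature: dict[str, str],
                      min_len: int = 18) -> list[SmallRNARecord]:
    """Match reads to known mature miRNAs at Hamming distance <= 1.

    Reads shorter than ``min_len`` are discarded (absent from the output).
    Matching is ungapped and equal-length only; ties go to the lowest
    mismatch count, then the lexicographically smallest mature id.
    """
    if not known_mature:
        raise ValidationError("known_mature must be non-empty")
    out = []
    for raw in sequences:
        seq = raw.upper().replace("U", "T")
        bad = set(seq) - set("ACGTN")
        if bad:
            raise ValidationError(
                f"non-nucleotide characters in read: {sorted(bad)}")
        if len(seq) < min_len:
            continue
        best: tuple[int, str] | None = None
        for mid in sorted(known_mature):
            mat = known_mature[mid].upper().replace("U", "T")
            if len(mat) != len(seq):
                continue
            d = _hamming(seq, mat)
            if d <= 1 and (best is None or d < best[0]):
                best = (d, mid)
        if best is None:
            out.append(SmallRNARecord(seq, len(seq), "unassigned", None, None))
        else:
            out.append(SmallRNARecord(
                seq, len(seq), "conserved", best[1], best[0]))
    return out


def gc_content(sequence: str) -> float:
    seq = sequence.upper()
    return (seq.count("G") + seq.count("C")) / len(seq)


def summarize_features(lncrnas: list[TranscriptRecord],
                       mrnas: list[TranscriptRecord]) -> dict:
    """Descriptive lncRNA-vs-mRNA comparison.

    Reports mean spliced length, the exon-count distribution and per-group
    GC content, plus a two-sided Welch two-sample t-test on GC content
    (t, df, p); the t-test entries are None when a group has fewer than two
    members.
    """
    if not lncrnas or not mrnas:
        raise ValidationError("both groups must be non-empty")
    gc_l = np.array([gc_content(t.sequence) for t in lncrnas])
    gc_m = np.array([gc_content(t.sequence) for t in mrnas])
    summary = {
        "n_lncrna": len(lncrnas),
        "n_mrna": len(mrnas),
        "mean_length_lncrna": float(np.mean([t.length for t in lncrnas])),
        "mean_length_mrna": float(np.mean([t.length for t in mrnas])),
        "exon_counts_lncrna": pd.Series(
            [t.exon_count for t in lncrnas]).value_counts().to_dict(),
        "exon_counts_mrna": pd.Series(
            [t.exon_count for t in mrnas]).value_counts().to_dict(),
        "mean_gc_lncrna": float(gc_l.mean()),
        "mean_gc_mrna": float(gc_m.mean()),
        "gc_t": None, "gc_df": None, "gc_p": None,
    }
    if len(gc_l) >= 2 and len(gc_m) >= 2:
        res = stats.ttest_ind(gc_l, gc_m, equal_var=False)
        summary["gc_t"] = float(res.statistic)
        summary["gc_df"] = float(res.df)
        summary["gc_p"] = float(res.pvalue)
    return summary
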