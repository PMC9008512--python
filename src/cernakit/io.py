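"""Readers and writers for the plain-text interchange formats.

GFF3 carries the transcript annotation with GffCompare-style class codes in a
``class_code=`` attribute; FASTA carries transcript and mature-miRNA
sequences; expression matrices and sample sheets are TSV with a
``feature_id`` / ``sample_id`` key column.
"""

from __future__ import annotations

import io as _stdio
from pathlib import Path

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._errors import ValidationError
from .containers import ExpressionMatrix, TranscriptRecord

_SOURCE = "cernakit"


# ---------------------------------------------------------------- FASTA

def write_fasta(sequences: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="")
               for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------- GFF3

def write_gff3(transcripts, path) -> None:
    """Write one ``transcript`` feature per record, attributes holding the
    class code, biotype and exon count."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for t in transcripts:
            attrs = f"ID={t.id}"
            if t.class_code is not None:
                attrs += f";class_code={t.class_code}"
            attrs += f";biotype={t.biotype};exon_count={t.exon_count}"
            fh.write(
                f"{t.chrom}\t{_SOURCE}\ttranscript\t{t.start}\t{t.end}"
                f"\t.\t{t.strand}\t.\t{attrs}\n"
            )


def read_gff3(path, sequences: dict[str, str] | None = None
              ) -> list[TranscriptRecord]:
    """Parse transcript records from GFF3, optionally attaching sequences.

    Uses an in-memory gffutils database, so any GFF3 dialect with
    ``transcript`` (or ``mRNA``/``lnc_RNA``) features and an ``ID`` attribute
    is accepted.
    """
    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    out: list[TranscriptRecord] = []
    for feat in db.all_features(order_by=("seqid", "start")):
        if feat.featuretype not in ("transcript", "mRNA", "lnc_RNA"):
            continue
        tid = feat.attributes.get("ID", [feat.id])[0]
        class_code = feat.attributes.get("class_code", [None])[0]
        biotype = feat.attributes.get("biotype", ["other"])[0]
        exon_count = int(feat.attributes.get("exon_count", [1])[0])
        seq = sequences.get(tid) if sequences else None
        out.append(TranscriptRecord(
            id=tid, chrom=feat.seqid, strand=feat.strand,
            start=feat.start, end=feat.end, class_code=class_code,
            exon_count=exon_count, sequence=seq, biotype=biotype,
        ))
    return out


# ---------------------------------------------------------------- TSV

def write_matrix(matrix: ExpressionMatrix, path) -> None:
    matrix.values.rename_axis("feature_id").to_csv(path, sep="\t")


def read_matrix(path, unit: str, sample_sheet) -> ExpressionMatrix:
    values = pd.read_csv(path, sep="\t", index_col="feature_id")
    meta = read_sample_sheet(sample_sheet)
    return ExpressionMatrix(values=values, unit=unit, sample_meta=meta)


def write_sample_sheet(sample_meta: pd.DataFrame, path) -> None:
    sample_meta.rename_axis("sample_id").to_csv(path, sep="\t")


def read_sample_sheet(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", index_col="sample_id")
    for col in ("stage", "replicate"):
        if col not in meta.columns:
            raise ValidationError(f"sample sheet lacks column {col!r}")
    return meta


def write_tsv(df: pd.DataFrame, path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
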