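"""Core in-memory containers shared by every analysis stage.

Coordinates are 1-based inclusive throughout (GFF3 convention).  Expression
values live in a features x samples :class:`pandas.DataFrame` wrapped together
with sample metadata and a unit tag, so downstream stages can refuse input in
the wrong unit (e.g. the differential-expression test requires raw counts).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._errors import ValidationError

#: GffCompare single-character class codes (the vocabulary consumed here).
CLASS_CODES = set("=ckmnjeoisxyrup.")

#: Class codes that mark a transcript as a positional lncRNA candidate:
#: u = intergenic, i = intronic, x = antisense exonic overlap, o = other
#: same-strand exonic overlap.
LNCRNA_CLASS_CODES = frozenset("uixo")

VALID_UNITS = ("counts", "FPKM", "RPM")


@dataclass
class TranscriptRecord:
    """One annotated transcript.

    ``length`` is the mature (spliced) length in nt and must equal
    ``len(sequence)`` whenever a sequence is attached; ``start``/``end`` are
    genomic, 1-based inclusive.
    """

    id: str
    chrom: str
    strand: str
    start: int
    end: int
    class_code: str | None = None
    exon_count: int = 1
    sequence: str | None = None
    biotype: str = "other"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValidationError(
                f"{self.id}: start ({self.start}) > end ({self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValidationError(f"{self.id}: strand must be '+' or '-'")
        if self.class_code is not None and self.class_code not in CLASS_CODES:
            raise ValidationError(
                f"{self.id}: unknown class code {self.class_code!r}"
            )

    @property
    def length(self) -> int:
        """Spliced transcript length in nt."""
        if self.sequence is not None:
            return len(self.sequence)
        return self.end - self.start + 1

    @property
    def span(self) -> int:
        """Genomic footprint in bp (1-based inclusive)."""
        return self.end - self.start + 1


@dataclass
class ExpressionMatrix:
    """Features x samples expression values plus sample metadata.

    Parameters
    ----------
    values
        DataFrame indexed by feature id with one column per sample.
    unit
        One of ``counts``, ``FPKM``, ``RPM``.
    sample_meta
        DataFrame indexed by sample id with columns ``stage`` and
        ``replicate``; must cover every column of ``values``.
    """

    values: pd.DataFrame
    unit: str
    sample_meta: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        if self.unit not in VALID_UNITS:
            raise ValidationError(f"unknown unit {self.unit!r}")
        if (np.asarray(self.values) < 0).any():
            raise ValidationError("expression values must be non-negative")
        missing = set(self.values.columns) - set(self.sample_meta.index)
        if missing:
            raise ValidationError(
                f"samples without metadata: {sorted(missing)}"
            )

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def stages(self) -> list[str]:
        """Stage labels in first-appearance order of the sample columns."""
        seen: dict[str, None] = {}
        for s in self.values.columns:
            seen.setdefault(self.sample_meta.loc[s, "stage"], None)
        return list(seen)

    def samples_of_stage(self, stage: str) -> list[str]:
        return [
            s for s in self.values.columns
            if self.sample_meta.loc[s, "stage"] == stage
        ]

    def stage_means(self) -> pd.DataFrame:
        """Per-feature mean over replicates, one column per stage."""
        cols = {st: self.values[self.samples_of_stage(st)].mean(axis=1)
                for st in self.stages}
        return pd.DataFrame(cols, index=self.values.index)

    def subset(self, feature_ids) -> "ExpressionMatrix":
        return replace(self, values=self.values.loc[list(feature_ids)])
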