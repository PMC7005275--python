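"""Deconvolution of pooled-screen sequencing reads into guide counts.

Reads from a pooled CRISPR screen carry the 20-nt sgRNA spacer immediately
downstream of the vector sequence ``CACCG``; an 8-nt sample barcode
(delivered on the P7 primer) identifies the condition.  Counting is exact:
a read contributes to cell ``(guide, condition)`` only if its extracted
spacer matches a library spacer exactly and its barcode matches a known
condition barcode exactly.  Unmatched reads are tallied, never raised.
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

SPACER_ANCHOR = "CACCG"
SPACER_LENGTH = 20
BARCODE_LENGTH = 8

_SPACER_ALPHABET = frozenset("ACGT")


class ConfigurationError(ValueError):
    """Invalid reference table, barcode map, or analysis configuration."""


@dataclass(frozen=True)
class GuideReference:
    """Library of guides: guide_id -> (20-nt spacer, target gene symbol).

    Spacers must be unique so that exact matching is unambiguous; each guide
    targets exactly one gene (or carries a control-category label).
    """

    guide_ids: tuple[str, ...]
    spacers: tuple[str, ...]
    gene_symbols: tuple[str, ...]
    library_name: str = "library"
    _spacer_to_guide: dict[str, str] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not self.guide_ids:
            raise ConfigurationError("guide reference is empty")
        if not (len(self.guide_ids) == len(self.spacers) == len(self.gene_symbols)):
            raise ConfigurationError("guide reference columns have unequal lengths")
        for sp in self.spacers:
            if len(sp) != SPACER_LENGTH or not set(sp) <= _SPACER_ALPHABET:
                raise ConfigurationError(f"invalid spacer {sp!r}: need {SPACER_LENGTH} nt over ACGT")
        if len(set(self.spacers)) != len(self.spacers):
            raise ConfigurationError("spacers are not unique within the reference")
        if len(set(self.guide_ids)) != len(self.guide_ids):
            raise ConfigurationError("guide_ids are not unique")
        object.__setattr__(
            self, "_spacer_to_guide", dict(zip(self.spacers, self.guide_ids))
        )

    def guide_for_spacer(self, spacer: str) -> str | None:
        return self._spacer_to_guide.get(spacer)

    @property
    def guide_to_gene(self) -> dict[str, str]:
        return dict(zip(self.guide_ids, self.gene_symbols))

    @classmethod
    def from_tsv(cls, path: str | Path, library_name: str | None = None) -> "GuideReference":
        """Load a reference from TSV with columns guide_id, spacer, gene_symbol."""
        df = pd.read_csv(path, sep="\t", dtype=str)
        required = {"guide_id", "spacer", "gene_symbol"}
        if not required <= set(df.columns):
            raise ConfigurationError(f"reference TSV needs columns {sorted(required)}")
        return cls(
            guide_ids=tuple(df["guide_id"]),
            spacers=tuple(df["spacer"]),
            gene_symbols=tuple(df["gene_symbol"]),
            library_name=library_name or Path(path).stem,
        )

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"guide_id": self.guide_ids, "spacer": self.spacers, "gene_symbol": self.gene_symbols}
        ).to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class BarcodeMap:
    """8-nt sample barcode -> condition identifier."""

    barcode_to_condition: dict[str, str]

    def __post_init__(self) -> None:
        if not self.barcode_to_condition:
            raise ConfigurationError("barcode map is empty")
        for bc, cond in self.barcode_to_condition.items():
            if len(bc) != BARCODE_LENGTH or not set(bc) <= _SPACER_ALPHABET:
                raise ConfigurationError(f"invalid barcode {bc!r}: need {BARCODE_LENGTH} nt over ACGT")
            if not cond:
                raise ConfigurationError(f"barcode {bc} maps to an empty condition id")

    @property
    def conditions(self) -> list[str]:
        # insertion order; conditions may share a barcode only via distinct keys
        seen: dict[str, None] = {}
        for cond in self.barcode_to_condition.values():
            seen.setdefault(cond)
        return list(seen)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "BarcodeMap":
        df = pd.read_csv(path, sep="\t", dtype=str)
        if not {"barcode", "condition_id"} <= set(df.columns):
            raise ConfigurationError("barcode TSV needs columns barcode, condition_id")
        if df["barcode"].duplicated().any():
            raise ConfigurationError("duplicate barcodes in barcode map")
        return cls(dict(zip(df["barcode"], df["condition_id"])))

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"barcode": list(self.barcode_to_condition),
             "condition_id": list(self.barcode_to_condition.values())}
        ).to_csv(path, sep="\t", index=False)


@dataclass
class DeconvolutionStats:
    """Read-level bookkeeping for a counting run."""

    total_reads: int = 0
    spacer_matched: int = 0
    barcode_matched: int = 0
    assigned: int = 0

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2) + "\n")


def extract_spacer(read_sequence: str) -> str | None:
    """Return the 20 nt following the first ``CACCG``, or None.

    A read is unassignable when the anchor is absent, fewer than 20
    characters follow it, or the putative spacer contains a non-ACGT
    character (e.g. an N basecall).
    """
    idx = read_sequence.find(SPACER_ANCHOR)
    if idx < 0:
        return None
    start = idx + len(SPACER_ANCHOR)
    spacer = read_sequence[start : start + SPACER_LENGTH]
    if len(spacer) < SPACER_LENGTH or not set(spacer) <= _SPACER_ALPHABET:
        return None
    return spacer


def count_reads(
    reads: Iterable[tuple[str, str]],
    reference: GuideReference,
    barcodes: BarcodeMap,
) -> tuple[pd.DataFrame, DeconvolutionStats]:
    """Tally (sequence, barcode) pairs into a guide-by-condition count matrix.

    Every reference guide gets a row (zeros included, needed by the
    downstream pseudocount) and every mapped condition a column.  Cell
    ``(g, c)`` is the number of reads whose extracted spacer equals guide
    g's spacer and whose barcode maps to condition c.
    """
    conditions = barcodes.conditions
    col_index = {c: j for j, c in enumerate(conditions)}
    row_index = {g: i for i, g in enumerate(reference.guide_ids)}
    counts = np.zeros((len(row_index), len(col_index)), dtype=np.int64)
    stats = DeconvolutionStats()

    for sequence, barcode in reads:
        stats.total_reads += 1
        spacer = extract_spacer(sequence)
        guide = reference.guide_for_spacer(spacer) if spacer is not None else None
        condition = barcodes.barcode_to_condition.get(barcode)
        if guide is not None:
            stats.spacer_matched += 1
        if condition is not None:
            stats.barcode_matched += 1
        if guide is not None and condition is not None:
            stats.assigned += 1
            counts[row_index[guide], col_index[condition]] += 1

    matrix = pd.DataFrame(counts, index=list(row_index), columns=conditions)
    matrix.index.name = "guide_id"
    return matrix, stats


def read_fastq_reads(
    fastq_path: str | Path, barcode: str | None = None
) -> Iterator[tuple[str, str]]:
    """Yield (sequence, barcode) pairs from a FASTQ file, gzipped or plain.

    The per-read barcode is taken from the last whitespace-separated token
    of the header line (the convention used by ``simulate_fastq`` and by
    demultiplexers that copy the index read into the comment); passing
    ``barcode`` overrides it for single-sample files.
    """
    from Bio import SeqIO

    path = Path(fastq_path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as handle:
        for record in SeqIO.parse(handle, "fastq"):
            if barcode is not None:
                bc = barcode
            else:
                desc = record.description.split()
                bc = desc[-1] if len(desc) > 1 else ""
            yield str(record.seq), bc


def write_count_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t")


def read_count_matrix(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = "guide_id"
    return df
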