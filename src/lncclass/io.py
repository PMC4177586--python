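"""FASTA input/output and feature-matrix export.

Transcripts are plain DNA strings over {A,C,G,T}. RNA `U`/`u` is mapped to
`T` and lowercase is uppercased at parse time, so every downstream module
sees a normalised alphabet. The FASTA id is the header token up to the
first whitespace, as produced by Biopython.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import InputError

logger = logging.getLogger(__name__)

_NORMALISE = str.maketrans("acgtuUnN", "ACGTTTNN")


def normalize_sequence(seq: str) -> str:
    """Uppercase a nucleotide string and map U to T."""
    return seq.translate(_NORMALISE).upper()


@dataclass(frozen=True)
class TranscriptRecord:
    """One transcript: FASTA id plus a normalised nucleotide sequence."""

    id: str
    sequence: str = field(repr=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", normalize_sequence(self.sequence))

    @property
    def length(self) -> int:
        return len(self.sequence)


def read_fasta(path: str | Path) -> list[TranscriptRecord]:
    """Read a FASTA file into TranscriptRecords.

    Records with an empty sequence are kept (they featurize to a zero
    vector, with a warning); a file with zero parseable records raises
    :class:`InputError`.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"FASTA file not found: {path}")
    records = [
        TranscriptRecord(id=rec.id, sequence=str(rec.seq))
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise InputError(f"no FASTA records parsed from {path}")
    return records


def write_fasta(records: Iterable[TranscriptRecord], path: str | Path,
                wrap: int = 70) -> None:
    """Write records as wrapped FASTA."""
    seq_records = [
        SeqRecord(Seq(rec.sequence), id=rec.id, description="")
        for rec in records
    ]
    writer = SeqIO.FastaIO.FastaWriter(str(path), wrap=wrap)
    writer.write_file(seq_records)


def write_feature_tsv(path: str | Path, ids: Sequence[str],
                      matrix: np.ndarray, columns: Sequence[str]) -> None:
    """Export a feature matrix as a TSV table (id + one column per k-mer)."""
    import pandas as pd

    frame = pd.DataFrame(np.asarray(matrix), columns=list(columns))
    frame.insert(0, "id", list(ids))
    frame.to_csv(path, sep="\t", index=False)


def write_svmlight(path: str | Path, matrix: np.ndarray,
                   labels: Sequence[int]) -> None:
    """Export features in the sparse `label index:value` text format.

    Indices are 1-based, matching the convention of SVM tooling that
    consumes this format.
    """
    from sklearn.datasets import dump_svmlight_file

    dump_svmlight_file(np.asarray(matrix), np.asarray(labels), str(path),
                       zero_based=False)
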