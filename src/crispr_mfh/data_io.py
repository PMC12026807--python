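"""Reading and writing sgRNA/DNA pair tables.

The on-disk format is delimited text (comma by default, tab supported) with
a header row naming the columns ``sgRNA``, ``DNA`` and ``label``
(case-insensitive). No FASTA support: the unit of data is an aligned pair,
not a single sequence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .encoding import GAP, GuideTargetPair
from .exceptions import CrisprMfhError, SchemaError

logger = logging.getLogger(__name__)

_REQUIRED_COLUMNS = ("sgrna", "dna", "label")
_TRUE_LABELS = {"1", "true"}
_FALSE_LABELS = {"0", "false"}


@dataclass
class PairDataset:
    """An ordered, validated collection of guide/target pairs."""

    pairs: list[GuideTargetPair]
    name: str = "dataset"
    indel_mode: bool = field(default=False)

    def __post_init__(self):
        if not self.pairs:
            raise SchemaError("a PairDataset must contain at least one pair")
        lengths = {p.length for p in self.pairs}
        if len(lengths) > 1:
            raise SchemaError(
                f"all pairs must share one alignment length, got {sorted(lengths)}"
            )
        has_gap = any(GAP in p.sgrna or GAP in p.dna for p in self.pairs)
        self.indel_mode = self.indel_mode or has_gap

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self):
        return iter(self.pairs)

    def __getitem__(self, index):
        return self.pairs[index]

    @property
    def length(self) -> int:
        return self.pairs[0].length

    @property
    def labels(self) -> list[int]:
        return [p.label for p in self.pairs]

    @property
    def n_positive(self) -> int:
        return sum(self.labels)

    @property
    def n_negative(self) -> int:
        return len(self) - self.n_positive


def _parse_label(raw, line: int) -> int:
    text = str(raw).strip().lower()
    if text in _TRUE_LABELS:
        return 1
    if text in _FALSE_LABELS:
        return 0
    raise SchemaError(f"line {line}: label {raw!r} not in {{0, 1, true, false}}")


def read_pairs_table(path, delimiter: str = ",", name: str | None = None) -> PairDataset:
    """Read a delimited pair table into a validated :class:`PairDataset`.

    Row order is preserved; the first data row is line 2 of the file. A
    malformed row raises :class:`SchemaError` citing its line number.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path, sep=delimiter, dtype=str, skipinitialspace=True)
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"{path}: empty input file") from exc
    frame.columns = [str(c).strip().lower() for c in frame.columns]
    missing = [c for c in _REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    if frame.empty:
        raise SchemaError(f"{path}: no data rows")

    pairs = []
    for row_index, row in enumerate(frame.itertuples(index=False)):
        line = row_index + 2  # header is line 1
        record = dict(zip(frame.columns, row))
        label = _parse_label(record["label"], line)
        try:
            pairs.append(GuideTargetPair(str(record["sgrna"]),
                                         str(record["dna"]), label))
        except CrisprMfhError as exc:
            raise SchemaError(f"{path} line {line}: {exc}") from exc

    dataset = PairDataset(pairs, name=name or path.stem)
    logger.info(
        "read %d pairs from %s (%d positive, %d negative, L=%d)",
        len(dataset), path, dataset.n_positive, dataset.n_negative,
        dataset.length,
    )
    return dataset


def write_pairs_table(dataset: PairDataset, path, delimiter: str = ",") -> Path:
    """Write a dataset as delimited text with header ``sgRNA,DNA,label``."""
    path = Path(path)
    frame = pd.DataFrame(
        {
            "sgRNA": [p.sgrna for p in dataset],
            "DNA": [p.dna for p in dataset],
            "label": [p.label for p in dataset],
        }
    )
    frame.to_csv(path, sep=delimiter, index=False)
    return path
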