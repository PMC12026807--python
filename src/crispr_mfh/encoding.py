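"""Multi-feature encoding of sgRNA-target DNA sequence pairs.

A guide/target alignment of length ``L`` (23 for mismatch-only data, 24
when the alignment carries an indel column) is turned into three binary
feature matrices that are fed to the network side by side:

* an ``L x 5`` one-hot matrix of the sgRNA over channels ``[A, T, C, G, _]``;
* an ``L x 5`` one-hot matrix of the target DNA over the same channels;
* an ``L x 7`` fused matrix whose first five columns are the element-wise OR
  of the two one-hot rows and whose last two columns are direction bits that
  disambiguate mismatch orientation (``TC`` vs ``CT`` would otherwise both
  collapse to ``[0,1,1,0,0]``).

The fused encoding is lossless: the map (sgRNA symbol, DNA symbol) -> fused
7-vector is injective over all valid ordered symbol pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import AlignmentError, AlphabetError, DimensionError

#: Fixed channel order of every one-hot matrix.
ALPHABET = "ATCG_"
GAP = "_"
CHANNEL_INDEX = {symbol: i for i, symbol in enumerate(ALPHABET)}

#: Alignment lengths accepted for guide/target pairs.
VALID_LENGTHS = (23, 24)


def normalize_sequence(seq: str) -> str:
    """Upper-case a sequence and map RNA uracil ('U') to 'T'."""
    return seq.upper().replace("U", "T")


def _validate_symbols(seq: str, name: str = "sequence") -> None:
    for pos, symbol in enumerate(seq):
        if symbol not in CHANNEL_INDEX:
            raise AlphabetError(
                f"{name} has invalid symbol {symbol!r} at position {pos + 1} "
                f"(alphabet is {ALPHABET})"
            )


@dataclass(frozen=True)
class GuideTargetPair:
    """One sgRNA/DNA alignment with its binary activity label.

    Sequences are normalized on construction (upper case, U -> T). Positions
    are conventionally numbered 1..L with 1 at the PAM-distal end.
    """

    sgrna: str
    dna: str
    label: int

    def __post_init__(self):
        object.__setattr__(self, "sgrna", normalize_sequence(self.sgrna))
        object.__setattr__(self, "dna", normalize_sequence(self.dna))
        if len(self.sgrna) != len(self.dna):
            raise DimensionError(
                f"sgRNA length {len(self.sgrna)} != DNA length {len(self.dna)}"
            )
        if len(self.sgrna) not in VALID_LENGTHS:
            raise DimensionError(
                f"alignment length {len(self.sgrna)} not in {VALID_LENGTHS}"
            )
        _validate_symbols(self.sgrna, "sgRNA")
        _validate_symbols(self.dna, "DNA")
        for pos, (a, b) in enumerate(zip(self.sgrna, self.dna)):
            if a == GAP and b == GAP:
                raise AlignmentError(f"double gap at position {pos + 1}")
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label!r}")

    @property
    def length(self) -> int:
        return len(self.sgrna)

    def mismatch_positions(self) -> list[int]:
        """1-based positions where the two strands differ (incl. indels)."""
        return [i + 1 for i, (a, b) in enumerate(zip(self.sgrna, self.dna)) if a != b]


@dataclass(frozen=True)
class EncodedTriple:
    """The three feature matrices consumed by the model."""

    sgrna_matrix: np.ndarray  # L x 5
    dna_matrix: np.ndarray  # L x 5
    fused_matrix: np.ndarray  # L x 7


def encode_sequence(seq: str, length: int | None = None) -> np.ndarray:
    """One-hot encode a nucleotide (or gapped) sequence as an ``L x 5`` matrix.

    Channel order is ``[A, T, C, G, _]``; row ``i`` carries a single 1 in the
    channel of ``seq[i]``.
    """
    seq = normalize_sequence(seq)
    if length is not None and len(seq) != length:
        raise DimensionError(f"expected length {length}, got {len(seq)}")
    _validate_symbols(seq)
    matrix = np.zeros((len(seq), len(ALPHABET)), dtype=np.int8)
    for i, symbol in enumerate(seq):
        matrix[i, CHANNEL_INDEX[symbol]] = 1
    return matrix


def encode_fused(sgrna: str, dna: str) -> np.ndarray:
    """Fuse an sgRNA/DNA alignment into an ``L x 7`` matrix.

    Columns 0-4 are the element-wise OR of the two one-hot rows; columns 5-6
    are direction bits: ``[0, 0]`` for a match, ``[1, 0]`` when the sgRNA
    symbol's channel index is lower than the DNA symbol's, ``[0, 1]``
    otherwise. The direction bits make the encoding injective over ordered
    symbol pairs.
    """
    sgrna = normalize_sequence(sgrna)
    dna = normalize_sequence(dna)
    if len(sgrna) != len(dna):
        raise DimensionError(
            f"sgRNA length {len(sgrna)} != DNA length {len(dna)}"
        )
    _validate_symbols(sgrna, "sgRNA")
    _validate_symbols(dna, "DNA")
    fused = np.zeros((len(sgrna), 7), dtype=np.int8)
    for i, (a, b) in enumerate(zip(sgrna, dna)):
        if a == GAP and b == GAP:
            raise AlignmentError(f"double gap at position {i + 1}")
        ia, ib = CHANNEL_INDEX[a], CHANNEL_INDEX[b]
        fused[i, ia] = 1
        fused[i, ib] = 1
        if ia < ib:
            fused[i, 5] = 1
        elif ia > ib:
            fused[i, 6] = 1
    return fused


def encode_triple(pair: GuideTargetPair) -> EncodedTriple:
    """Encode a pair into its three feature matrices (deterministic)."""
    return EncodedTriple(
        sgrna_matrix=encode_sequence(pair.sgrna, pair.length),
        dna_matrix=encode_sequence(pair.dna, pair.length),
        fused_matrix=encode_fused(pair.sgrna, pair.dna),
    )


def encode_dataset(pairs) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Encode an iterable of pairs into stacked float32 arrays.

    Returns ``(sgrna, dna, fused, labels)`` with shapes
    ``(n, L, 5), (n, L, 5), (n, L, 7), (n,)``.
    """
    triples = [encode_triple(p) for p in pairs]
    if not triples:
        raise DimensionError("cannot encode an empty collection of pairs")
    sg = np.stack([t.sgrna_matrix for t in triples]).astype(np.float32)
    dn = np.stack([t.dna_matrix for t in triples]).astype(np.float32)
    fu = np.stack([t.fused_matrix for t in triples]).astype(np.float32)
    labels = np.array([p.label for p in pairs], dtype=np.int64)
    return sg, dn, fu, labels


def save_encoded(path, sgrna: np.ndarray, dna: np.ndarray, fused: np.ndarray,
                 labels: np.ndarray) -> None:
    """Cache encoded tensors as a compressed ``.npz`` archive."""
    np.savez_compressed(path, sgrna=sgrna, dna=dna, fused=fused, labels=labels)


def load_encoded(path) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Load tensors written by :func:`save_encoded`."""
    with np.load(path) as archive:
        return (archive["sgrna"], archive["dna"], archive["fused"],
                archive["labels"])
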