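"""Dataset characterization: GC content, imbalance ratio, mismatch profiles.

Positions are numbered 1..L with position 1 at the PAM-distal end and
position L adjacent to / inside the PAM, where mismatches are least
tolerated by Cas9.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations
from pathlib import Path

import pandas as pd

from .data_io import PairDataset
from .encoding import ALPHABET, GAP, normalize_sequence
from .exceptions import DimensionError

#: All ordered (sgRNA, DNA) symbol pairs that constitute a mismatch or indel.
MISMATCH_PAIRS = [f"{a}>{b}" for a, b in permutations(ALPHABET, 2)]


def gc_content(seq: str) -> float:
    """Fraction of G/C bases in a sequence; gap symbols are excluded.

    GC content modulates duplex stability and Cas9-sgRNA binding, which is
    why it is profiled alongside mismatch structure.
    """
    seq = normalize_sequence(seq)
    bases = [s for s in seq if s != GAP]
    if not bases:
        raise DimensionError("gc_content of an empty (or all-gap) sequence")
    return sum(1 for s in bases if s in "GC") / len(bases)


def imbalance_ratio(n_major: int, n_minor: int) -> int:
    """Floored ratio of majority- to minority-class counts.

    Flooring (rather than rounding) is what reproduces the conventional
    printed IR values for heavily imbalanced off-target benchmarks, e.g.
    213,966 negatives / 3,767 positives -> 56.
    """
    if n_minor < 1:
        raise DimensionError("minority class count must be >= 1")
    if n_major < n_minor:
        raise DimensionError("majority count must be >= minority count")
    return n_major // n_minor


def dataset_imbalance_ratio(dataset: PairDataset) -> int:
    """Imbalance ratio of a dataset's label distribution."""
    n_pos, n_neg = dataset.n_positive, dataset.n_negative
    return imbalance_ratio(max(n_pos, n_neg), min(n_pos, n_neg))


@dataclass
class MismatchProfile:
    """Position x ordered-symbol-pair counts of mismatched alignment columns.

    ``counts`` is indexed by 1-based position and has one column per ordered
    (sgRNA symbol > DNA symbol) pair, indels included as ``base>_`` or
    ``_>base``.
    """

    counts: pd.DataFrame

    @property
    def total(self) -> int:
        return int(self.counts.to_numpy().sum())

    def position_marginal(self) -> pd.Series:
        """Mismatch counts summed over pair types, per position."""
        return self.counts.sum(axis=1)

    def type_marginal(self) -> pd.Series:
        """Mismatch counts summed over positions, per ordered pair type."""
        return self.counts.sum(axis=0)

    def to_csv(self, path, delimiter: str = ",") -> Path:
        path = Path(path)
        self.counts.to_csv(path, sep=delimiter, index_label="position")
        return path

    @classmethod
    def from_csv(cls, path, delimiter: str = ",") -> "MismatchProfile":
        counts = pd.read_csv(path, sep=delimiter, index_col="position")
        return cls(counts=counts)


def mismatch_profile(dataset: PairDataset, positives_only: bool = True) -> MismatchProfile:
    """Tally mismatched/indel columns per position and ordered symbol pair.

    By default only active (label 1) pairs are profiled, since the question
    of interest is where mismatches are tolerated at real off-target sites;
    set ``positives_only=False`` to profile every pair.
    """
    length = dataset.length
    counts = pd.DataFrame(
        0, index=pd.RangeIndex(1, length + 1, name="position"),
        columns=MISMATCH_PAIRS, dtype=int,
    )
    for pair in dataset:
        if positives_only and pair.label != 1:
            continue
        for i, (a, b) in enumerate(zip(pair.sgrna, pair.dna)):
            if a != b:
                counts.loc[i + 1, f"{a}>{b}"] += 1
    return MismatchProfile(counts=counts)


def dataset_summary(dataset: PairDataset) -> dict:
    """Headline statistics of a pair dataset."""
    gc_pos = [gc_content(p.sgrna) for p in dataset if p.label == 1]
    return {
        "name": dataset.name,
        "n_pairs": len(dataset),
        "n_positive": dataset.n_positive,
        "n_negative": dataset.n_negative,
        "imbalance_ratio": dataset_imbalance_ratio(dataset),
        "length": dataset.length,
        "indel_mode": dataset.indel_mode,
        "mean_gc_positive_sgrna": (sum(gc_pos) / len(gc_pos)) if gc_pos else None,
    }


def plot_mismatch_profile(profile: MismatchProfile, path) -> Path:
    """Render the position marginal as a bar chart (PNG/SVG by extension)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    marginal = profile.position_marginal()
    fig, ax = plt.subplots(figsize=(8, 3))
    ax.bar(marginal.index, marginal.to_numpy(), color="#4878b0")
    ax.set_xlabel("position (1 = PAM-distal)")
    ax.set_ylabel("mismatch count")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)
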