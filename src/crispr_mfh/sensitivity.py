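"""Base-control-variable sensitivity analysis.

A trained scorer is probed by in-silico saturation substitution: for a set
of random 23-mers terminating in the canonical "AGG" PAM, every target-DNA
position is substituted in turn with each of the three alternative
nucleotides or a gap ('_', an indel), the guide strand held fixed. The
change in predicted off-target score relative to the perfect-match baseline
is averaged per (position, introduced symbol), exposing which positions and
substitution types the model is sensitive to — typically the PAM-proximal
region.

The sweep is scorer-agnostic: any callable mapping a list of
:class:`~crispr_mfh.encoding.GuideTargetPair` to an array of positive-class
probabilities can be profiled.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .encoding import GAP, GuideTargetPair, normalize_sequence, _validate_symbols
from .exceptions import DimensionError, ScoringError

BASES = "ATCG"
PAM = "AGG"
GUIDE_LENGTH = 23
#: Substitution categories, keyed by the symbol introduced into the DNA.
CATEGORIES = ("A", "T", "C", "G", "indel")
#: Variants per sequence: every position x (3 alternative bases + 1 indel).
VARIANTS_PER_SEQUENCE = GUIDE_LENGTH * 4


def generate_pam_sequences(n: int, seed: int = 0) -> list[str]:
    """Draw ``n`` random 23-mers ending in the canonical "AGG" PAM.

    Positions 1-20 are i.i.d. uniform over {A, T, C, G}; positions 21-23
    are fixed to "AGG". Deterministic given ``seed``.
    """
    if n < 1:
        raise DimensionError("n must be >= 1")
    rng = np.random.default_rng(seed)
    body = rng.integers(0, 4, size=(n, GUIDE_LENGTH - len(PAM)))
    lookup = np.array(list(BASES))
    return ["".join(row) + PAM for row in lookup[body]]


def substitution_sweep(seq: str) -> list[tuple[int, str, GuideTargetPair]]:
    """Enumerate all single-position DNA substitutions of a 23-mer.

    Returns ``(position, introduced_symbol, variant_pair)`` triples: for
    each of the 23 positions, the three alternative nucleotides plus a gap
    in the DNA strand, the guide unchanged — 92 variants in total. The
    baseline is the perfect-match pair ``(seq, seq)``; a base is never
    substituted by itself.
    """
    seq = normalize_sequence(seq)
    if len(seq) != GUIDE_LENGTH:
        raise DimensionError(f"expected a {GUIDE_LENGTH}-mer, got length {len(seq)}")
    _validate_symbols(seq)
    if GAP in seq:
        raise DimensionError("baseline sequence must be gap-free")
    variants = []
    for index, base in enumerate(seq):
        for symbol in BASES + GAP:
            if symbol == base:
                continue
            dna = seq[:index] + symbol + seq[index + 1:]
            variants.append((index + 1, symbol,
                             GuideTargetPair(seq, dna, label=0)))
    return variants


@dataclass
class SensitivityResult:
    """Mean score deltas per position and substitution category.

    ``delta_table`` is 23 x 5 (positions x introduced symbol, indel last);
    a cell where the introduced symbol equals a sequence's baseline base
    receives no contribution from that sequence, so base-category cells
    aggregate over the subset of baselines whose base differs, while the
    indel column aggregates over all ``n_baseline`` sequences.
    ``count_table`` records the number of deltas behind each cell.
    """

    delta_table: pd.DataFrame
    count_table: pd.DataFrame
    n_baseline: int
    seed: int | None = None

    def position_profile(self) -> pd.Series:
        """Mean delta per position, aggregated over all substitutions."""
        weighted = (self.delta_table * self.count_table).sum(axis=1)
        return weighted / self.count_table.sum(axis=1)

    def to_csv(self, path, delimiter: str = ",") -> Path:
        path = Path(path)
        self.delta_table.to_csv(path, sep=delimiter, index_label="position")
        return path

    @classmethod
    def from_csv(cls, path, delimiter: str = ",") -> pd.DataFrame:
        return pd.read_csv(path, sep=delimiter, index_col="position")


def sensitivity_profile(scorer, sequences, batch_size: int = 2048,
                        seed: int | None = None,
                        delta_sign: int = +1) -> SensitivityResult:
    """Run the saturation-substitution sweep and aggregate score deltas.

    ``scorer`` maps a list of :class:`GuideTargetPair` to an array of
    positive-class probabilities and must be deterministic. The per-variant
    delta is ``score(variant) - score(baseline)`` (positive = the
    substitution raises the predicted off-target score); pass
    ``delta_sign=-1`` for the opposite convention.
    """
    sequences = list(sequences)
    n = len(sequences)
    if n < 1:
        raise DimensionError("need at least one baseline sequence")

    category_index = {c: i for i, c in enumerate(CATEGORIES)}
    sums = np.zeros((GUIDE_LENGTH, len(CATEGORIES)))
    counts = np.zeros((GUIDE_LENGTH, len(CATEGORIES)), dtype=int)

    step = max(1, batch_size // (VARIANTS_PER_SEQUENCE + 1))
    for start in range(0, n, step):
        chunk = sequences[start:start + step]
        pairs, rows, cols = [], [], []
        for seq in chunk:
            pairs.append(GuideTargetPair(seq, seq, label=0))  # baseline first
            for pos, symbol, variant in substitution_sweep(seq):
                pairs.append(variant)
                rows.append(pos - 1)
                cols.append(category_index["indel" if symbol == GAP else symbol])
        scores = np.asarray(scorer(pairs), dtype=float)
        if scores.shape != (len(pairs),):
            raise ScoringError(
                f"scorer returned shape {scores.shape}, expected ({len(pairs)},)")
        if not np.all(np.isfinite(scores)):
            raise ScoringError("scorer returned non-finite values")
        per_seq = 1 + VARIANTS_PER_SEQUENCE
        scores = scores.reshape(len(chunk), per_seq)
        deltas = delta_sign * (scores[:, 1:] - scores[:, :1]).reshape(-1)
        rows, cols = np.asarray(rows), np.asarray(cols)
        np.add.at(sums, (rows, cols), deltas)
        np.add.at(counts, (rows, cols), 1)

    positions = pd.RangeIndex(1, GUIDE_LENGTH + 1, name="position")
    count_table = pd.DataFrame(counts, index=positions, columns=list(CATEGORIES))
    with np.errstate(invalid="ignore"):
        table = pd.DataFrame(np.where(counts > 0, sums / np.maximum(counts, 1),
                                      np.nan),
                             index=positions, columns=list(CATEGORIES))
    return SensitivityResult(delta_table=table, count_table=count_table,
                             n_baseline=n, seed=seed)


def model_scorer(model, batch_size: int = 512):
    """Adapt a trained network to the sweep's pair->probability contract."""

    def scorer(pairs):
        return model.score_pairs(pairs, batch_size=batch_size)

    return scorer


def export_heatmap(result: SensitivityResult, path) -> Path:
    """Render the delta table as a heatmap with a per-position bar profile.

    A numeric sidecar (same stem, ``.csv``) is written alongside the figure
    so the plotted values round-trip.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    path = Path(path)
    table = result.delta_table
    fig, (ax_bar, ax_heat) = plt.subplots(
        2, 1, figsize=(9, 6), gridspec_kw={"height_ratios": [1, 2]})

    profile = result.position_profile()
    ax_bar.bar(profile.index, profile.to_numpy(), color="#4878b0")
    ax_bar.axhline(0.0, color="black", linewidth=0.6)
    ax_bar.set_ylabel("mean Δ score")
    ax_bar.set_xlim(0.5, GUIDE_LENGTH + 0.5)

    values = table.to_numpy(dtype=float)
    limit = np.nanmax(np.abs(values)) if np.isfinite(values).any() else 1.0
    limit = limit if limit > 0 else 1.0
    image = ax_heat.imshow(values.T, aspect="auto", cmap="RdBu_r",
                           vmin=-limit, vmax=limit,
                           extent=(0.5, GUIDE_LENGTH + 0.5, -0.5,
                                   len(CATEGORIES) - 0.5))
    ax_heat.set_yticks(range(len(CATEGORIES)))
    ax_heat.set_yticklabels(reversed(CATEGORIES))
    ax_heat.set_xlabel("position (1 = PAM-distal)")
    fig.colorbar(image, ax=ax_heat, label="mean Δ score")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)

    result.to_csv(path.with_suffix(".csv"))
    return path
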