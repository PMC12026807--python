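"""Synthetic sgRNA-DNA pair datasets with a planted activity rule.

Real off-target benchmarks share three structural features the model and
its evaluation stack must cope with: fixed-length guide/target alignments,
activity that depends on *where* mismatches fall (PAM-proximal mismatches
are least tolerated), and extreme class imbalance. The generator emulates
all three with a deterministic planted rule, so every pipeline stage is
testable without external downloads and, with zero label noise, the rule is
perfectly recoverable — a known ceiling for any classifier trained on it.

The planted rule assigns each mismatched or indel column a position weight
(1 for PAM-distal positions 1-8, 2 for 9-12, 3 for 13-20, 4 for the
PAM-region 21-23; indels count double) and labels a pair active iff the
summed burden is at most 4. It is monotone in PAM-proximal mismatch burden,
so a correctly implemented model must learn position-dependent weights —
exactly the property the encoding is designed to expose.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .data_io import PairDataset
from .encoding import GAP, GuideTargetPair
from .exceptions import ConfigurationError, FeasibilityError

BASES = "ATCG"
GUIDE_LENGTH = 23

#: Position weights of the planted rule, index 0 = position 1 (PAM-distal).
POSITION_WEIGHTS = np.array([1] * 8 + [2] * 4 + [3] * 8 + [4] * 3)
#: A pair is active iff its weighted mismatch burden is <= this threshold.
BURDEN_THRESHOLD = 4
#: Indel columns count double in the burden.
INDEL_MULTIPLIER = 2


@dataclass
class SimulationParams:
    """Generator settings.

    ``mismatch_count_distribution`` is the categorical distribution of the
    number of mutated columns per candidate pair (0..6, geometric-like with
    P(0)=0.1 by default); ``indel_probability`` is the chance that one of a
    pair's mutated columns is a gap rather than a base substitution;
    ``target_ir`` is the floored negative/positive imbalance ratio the
    emitted dataset must hit exactly.
    """

    n_pairs: int = 1000
    guide_length: int = GUIDE_LENGTH
    mismatch_count_distribution: tuple[float, ...] = (
        0.10, 0.30, 0.20, 0.14, 0.10, 0.09, 0.07)
    indel_probability: float = 0.05
    target_ir: int = 9
    label_noise: float = 0.0
    seed: int = 0

    def __post_init__(self):
        dist = np.asarray(self.mismatch_count_distribution, dtype=float)
        if dist.min() < 0 or not np.isclose(dist.sum(), 1.0):
            raise ConfigurationError(
                "mismatch_count_distribution must be non-negative and sum to 1")
        if not 0.0 <= self.indel_probability <= 1.0:
            raise ConfigurationError("indel_probability must lie in [0, 1]")
        if not 0.0 <= self.label_noise <= 1.0:
            raise ConfigurationError("label_noise must lie in [0, 1]")
        if self.target_ir < 1:
            raise ConfigurationError("target_ir must be >= 1")
        if self.guide_length != GUIDE_LENGTH:
            raise ConfigurationError(
                f"generator emits length-{GUIDE_LENGTH} alignments only")

    def to_json(self, path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(asdict(self), indent=2))
        return path


def weighted_burden(pair: GuideTargetPair) -> int:
    """Weighted mismatch burden of a pair under the planted rule."""
    burden = 0
    for index, (a, b) in enumerate(zip(pair.sgrna, pair.dna)):
        if a == b:
            continue
        weight = int(POSITION_WEIGHTS[min(index, GUIDE_LENGTH - 1)])
        if a == GAP or b == GAP:
            weight *= INDEL_MULTIPLIER
        burden += weight
    return burden


def planted_label(pair: GuideTargetPair) -> int:
    """Deterministic activity label: 1 iff the weighted burden is <= 4."""
    return int(weighted_burden(pair) <= BURDEN_THRESHOLD)


def _sample_candidates(n: int, params: SimulationParams,
                       rng: np.random.Generator
                       ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized draw of ``n`` candidate pairs; returns (guides, dnas, labels).

    Guides are uniform over positions 1-20 with an NGG-compatible end
    (position 21 uniform, positions 22-23 fixed to GG); mutated columns are
    uniform without replacement; substituted bases are uniform over the
    three alternatives; an indel replaces the DNA base of one mutated
    column with a gap.
    """
    lookup = np.array(list(BASES))
    guides = lookup[rng.integers(0, 4, size=(n, GUIDE_LENGTH))]
    guides[:, 21:] = "G"  # NGG-compatible 3' end

    dnas = guides.copy()
    dist = np.asarray(params.mismatch_count_distribution)
    n_mut = rng.choice(len(dist), size=n, p=dist)
    # Uniform mutated columns without replacement, via per-row random ranks.
    ranks = rng.random((n, GUIDE_LENGTH)).argsort(axis=1)
    offsets = rng.integers(1, 4, size=(n, GUIDE_LENGTH))
    code_of = {b: i for i, b in enumerate(BASES)}
    guide_codes = np.vectorize(code_of.get)(guides)
    has_indel = rng.random(n) < params.indel_probability

    for row in range(n):
        k = n_mut[row]
        if k == 0:
            continue
        columns = ranks[row, :k]
        new_codes = (guide_codes[row, columns] + offsets[row, columns]) % 4
        dnas[row, columns] = lookup[new_codes]
        if has_indel[row]:
            dnas[row, columns[0]] = GAP

    mismatch = dnas != guides
    indel = dnas == GAP
    weights = POSITION_WEIGHTS * np.ones((n, GUIDE_LENGTH), dtype=int)
    burden = (mismatch * weights * np.where(indel, INDEL_MULTIPLIER, 1)).sum(axis=1)
    labels = (burden <= BURDEN_THRESHOLD).astype(int)
    return guides, dnas, labels


def _class_quota(n_pairs: int, target_ir: int) -> tuple[int, int]:
    """Positive/negative counts whose floored ratio equals ``target_ir``."""
    n_pos = n_pairs // (target_ir + 1)
    if n_pos < 1:
        raise FeasibilityError(
            f"target_ir={target_ir} needs at least {target_ir + 1} pairs, "
            f"got n_pairs={n_pairs}")
    n_neg = min(n_pairs - n_pos, (target_ir + 1) * n_pos - 1)
    if n_neg < target_ir * n_pos:
        raise FeasibilityError(
            f"cannot realize target_ir={target_ir} with n_pairs={n_pairs}")
    return n_pos, n_neg


def simulate_pairs(params: SimulationParams) -> PairDataset:
    """Generate a labelled pair dataset hitting ``target_ir`` exactly.

    Candidates are drawn in bulk, labelled by the planted rule, and the
    majority class is subsampled (never duplicated, to avoid leakage across
    CV folds) until ``floor(n_negative / n_positive) == target_ir``. Label
    noise, if any, flips labels after the quota is met. Same seed, same
    dataset, bit for bit.
    """
    rng = np.random.default_rng(params.seed)
    n_pos_quota, n_neg_quota = _class_quota(params.n_pairs, params.target_ir)

    pos_rows: list[tuple[str, str]] = []
    neg_rows: list[tuple[str, str]] = []
    attempts = 0
    while (len(pos_rows) < n_pos_quota or len(neg_rows) < n_neg_quota):
        attempts += 1
        if attempts > 200:
            raise FeasibilityError(
                "candidate sampling failed to meet the class quotas; "
                "the mismatch distribution may be too skewed")
        draw = max(2 * params.n_pairs, 1000)
        guides, dnas, labels = _sample_candidates(draw, params, rng)
        for row in range(draw):
            target = pos_rows if labels[row] else neg_rows
            quota = n_pos_quota if labels[row] else n_neg_quota
            if len(target) < quota:
                target.append(("".join(guides[row]), "".join(dnas[row])))

    flip = rng.random(n_pos_quota + n_neg_quota) < params.label_noise
    pairs = []
    for i, (sg, dna) in enumerate(pos_rows + neg_rows):
        label = 1 if i < n_pos_quota else 0
        if flip[i]:
            label = 1 - label
        pairs.append(GuideTargetPair(sg, dna, label))
    order = rng.permutation(len(pairs))
    return PairDataset([pairs[i] for i in order],
                       name=f"synthetic_ir{params.target_ir}_seed{params.seed}")
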