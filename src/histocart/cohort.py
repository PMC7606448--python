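"""Slide labeling, OOD designation and subject-level splits from bulk expression.

Slides are labeled per trait from their sample's bulk-expression percentile:
only the distribution extremes (percentile < 0.2 or > 0.8) enter model
development (label 1 above, 0 below); slides between the 20th and 80th
percentiles are set aside as out-of-distribution (OOD) evaluation sets.
The OOD-near tier is the next decile beyond the development extremes
([0.2, 0.3] and [0.7, 0.8]); OOD-all is the whole [0.2, 0.8] band.

Subjects — not slides — are split: a single held-out test draw (10%) shared
by all traits and rounds, then 5 independent re-partitions of the remainder
into train (80% of the cohort) and validation (10%).  All of a subject's
slides follow the subject.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SplitAssignment",
    "percentile_transform",
    "designate_sets",
    "split_subjects",
    "expected_training_count",
    "rank_traits_by_variance",
    "inherit_tile_labels",
]

# percentile band edges for model eligibility and OOD tiers
LOW_EXTREME = 0.2
HIGH_EXTREME = 0.8
OOD_NEAR_BANDS = ((0.2, 0.3), (0.7, 0.8))


@dataclass
class SplitAssignment:
    """Subject-level split: one shared test set, per-round train/val partitions.

    The test draw happens once, before any trait is processed, so every
    trait and every round sees the same test subjects.  Within each round,
    train and validation partition the non-test pool.
    """

    test: set = field(default_factory=set)
    rounds: list[dict[str, set]] = field(default_factory=list)  # [{"train":…, "val":…}]
    seed: int = 0

    def set_of(self, subject_id, round_index: int) -> str:
        """'test', 'train' or 'val' for a subject in a 1-based round."""
        if subject_id in self.test:
            return "test"
        rd = self.rounds[round_index - 1]
        if subject_id in rd["train"]:
            return "train"
        if subject_id in rd["val"]:
            return "val"
        raise KeyError(f"subject {subject_id!r} not in split")


def percentile_transform(values) -> np.ndarray:
    """Rank-based percentiles in (0, 1] with average ranks for ties.

    Percentile = average rank / n, so the maximum value maps to 1.0 and
    duplicated values share a percentile.
    """
    values = np.asarray(values, dtype=float)
    if np.unique(values).size < 2:
        raise ValueError("degenerate distribution: need >= 2 distinct values")
    return stats.rankdata(values, method="average") / values.size


def designate_sets(percentiles) -> pd.DataFrame:
    """Designate each slide's eligibility tiers from its percentile.

    Returns a DataFrame with, per slide:

    - ``label``: 1 above the 80th percentile, 0 below the 20th, -1
      otherwise (unlabeled for model development);
    - ``label_median``: median-split label (1 iff percentile > 0.5), used
      for evaluating OOD slides whose development label is undefined;
    - ``model_eligible``: percentile < 0.2 or > 0.8;
    - ``ood_near``: percentile in [0.2, 0.3] or [0.7, 0.8];
    - ``ood_all``: percentile in [0.2, 0.8].

    Boundary mass (exactly 0.2 or 0.8) goes to OOD — the set-aside interval
    is closed, conservative for training.
    """
    p = np.asarray(percentiles, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("percentiles must lie in [0, 1]")
    model_eligible = (p < LOW_EXTREME) | (p > HIGH_EXTREME)
    ood_near = np.zeros_like(model_eligible)
    for lo, hi in OOD_NEAR_BANDS:
        ood_near |= (p >= lo) & (p <= hi)
    ood_all = (p >= LOW_EXTREME) & (p <= HIGH_EXTREME)
    label = np.where(p > HIGH_EXTREME, 1, np.where(p < LOW_EXTREME, 0, -1))
    return pd.DataFrame(
        {
            "percentile": p,
            "label": label,
            "label_median": (p > 0.5).astype(int),
            "model_eligible": model_eligible,
            "ood_near": ood_near,
            "ood_all": ood_all,
        }
    )


def split_subjects(
    subject_ids,
    test_frac: float = 0.1,
    rounds: int = 5,
    val_frac_of_rest: float = 1.0 / 9.0,
    seed: int = 0,
) -> SplitAssignment:
    """Draw the shared test set and the per-round train/validation partitions.

    ``floor(n * test_frac)`` subjects form the test set, drawn once.  Per
    round the remaining pool is re-partitioned without replacement:
    ``floor(pool * val_frac_of_rest)`` validation subjects (1/9 of the 90%
    pool = 10% of the cohort), the rest train.  Deterministic under seed.
    """
    subject_ids = sorted(set(subject_ids))
    n = len(subject_ids)
    if not 0 < test_frac < 1 or not 0 < val_frac_of_rest < 1:
        raise ValueError("fractions must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    n_test = math.floor(n * test_frac)
    pool_size = n - n_test
    n_val = math.floor(pool_size * val_frac_of_rest)
    if n_test < 1 or n_val < 1 or pool_size - n_val < 1:
        raise ValueError(f"{n} subjects are too few for non-empty test/val/train")
    perm = rng.permutation(n)
    test = {subject_ids[i] for i in perm[:n_test]}
    pool = [subject_ids[i] for i in perm[n_test:]]
    round_sets = []
    for _ in range(rounds):
        order = rng.permutation(pool_size)
        val = {pool[i] for i in order[:n_val]}
        train = {pool[i] for i in order[n_val:]}
        round_sets.append({"train": train, "val": val})
    return SplitAssignment(test=test, rounds=round_sets, seed=seed)


def expected_training_count(
    n_slides: int, train_frac: float = 0.8, retained_frac: float = 0.4
) -> int:
    """Expected number of training slides under the inclusion criteria.

    ``floor(n_slides * train_frac * retained_frac)``: of the cohort, the
    training share times the fraction surviving the extremes-only
    (non-OOD) criterion.
    """
    if n_slides < 0:
        raise ValueError("n_slides must be non-negative")
    if not (0 < train_frac <= 1 and 0 < retained_frac <= 1):
        raise ValueError("fractions must lie in (0, 1]")
    # epsilon guards against 0.8*0.4 binary-rounding just below an integer
    return math.floor(n_slides * train_frac * retained_frac + 1e-9)


def rank_traits_by_variance(expression: pd.DataFrame) -> list[str]:
    """Trait names ordered by descending sample variance, ties lexicographic.

    ``expression`` is samples x traits.  Traits are screened by how much
    their bulk expression varies across the cohort; the most variable are
    the most informative to model.
    """
    if expression.shape[0] < 2:
        raise ValueError("variance undefined with a single sample")
    var = expression.var(axis=0, ddof=1)
    order = sorted(expression.columns, key=lambda t: (-var[t], str(t)))
    return list(order)


def inherit_tile_labels(slide_label, grid) -> dict[tuple[int, int], int]:
    """Propagate a slide's binary label to every retained tile.

    Weak supervision: each tile inherits the label of its parent slide.
    Unlabeled (OOD) slides cannot contribute training tiles.
    """
    if slide_label not in (0, 1):
        raise ValueError(
            f"slide is unlabeled (label={slide_label!r}): OOD slides do not "
            "participate in model development"
        )
    return {pos: int(slide_label) for pos in grid.retained_positions()}
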