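"""Heterogeneity index (HTI) from trait-combination proportions.

For T binary molecular traits there are ``C = 2**T - 1`` non-empty trait
combinations a tile can be positive for.  Given the proportion ``p_i`` of
tiles falling into each combination, the heterogeneity index is the Shannon
entropy of the combination distribution in log base C::

    HTI = -sum_i p_i * log_C(p_i)

The base-C logarithm normalizes the index to [0, 1]: HTI = 0 when a single
combination dominates (clonal homogeneity) and HTI = 1 when all C
combinations are equally represented (maximal mixing).  HTI depends only on
the composition of a slide, never on the spatial arrangement of its tiles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "HTIResult",
    "UndefinedHTIError",
    "combination_count",
    "combination_proportions",
    "compute_hti",
    "hti_for_map",
]


class UndefinedHTIError(ValueError):
    """Raised when combination proportions are undefined.

    This happens in ``positive_tiles`` mode when a slide has no tile
    positive for any trait: the conditional distribution over non-empty
    combinations has an empty support.
    """


@dataclass
class HTIResult:
    """HTI for one slide, with the proportions it was computed from.

    Attributes
    ----------
    slide_id : str
        Slide identifier.
    traits : list of str
        Ordered trait names; ``C = 2**len(traits) - 1``.
    C : int
        Number of non-empty trait combinations.
    p : numpy.ndarray
        Proportions over the C non-empty combinations (index ``i`` is the
        combination whose binary encoding is ``i``; bit t set means trait t
        positive).
    denominator_mode : str
        ``"positive_tiles"`` (p sums to 1 over tiles with >= 1 positive
        trait) or ``"all_tiles"`` (denominator includes all-negative tiles).
    n_tiles : int
        Non-missing tiles in the map.
    n_positive_tiles : int
        Tiles positive for at least one trait.
    hti : float
        The index, in [0, 1]; ``nan`` when undefined.
    """

    slide_id: str
    traits: list[str]
    C: int
    p: np.ndarray
    denominator_mode: str
    n_tiles: int
    n_positive_tiles: int
    hti: float = field(default=float("nan"))

    @property
    def defined(self) -> bool:
        return not math.isnan(self.hti)


def combination_count(trait_count: int) -> int:
    """Number of non-empty trait combinations, ``C = 2**T - 1``."""
    if trait_count < 1:
        raise ValueError(f"trait_count must be >= 1, got {trait_count}")
    return 2 ** trait_count - 1


def combination_proportions(
    combo_map: np.ndarray,
    trait_count: int,
    denominator_mode: str = "positive_tiles",
) -> np.ndarray:
    """Proportions of tiles falling into each non-empty trait combination.

    Parameters
    ----------
    combo_map : array
        Matrix (or vector) of combination indices in ``0..C`` with NaN for
        missing (background) tiles.  Index 0 means no trait positive; index
        ``i >= 1`` encodes the exact positive-trait subset in binary.
    trait_count : int
        Declared number of traits T; C is derived from it, not from the
        combinations actually observed.
    denominator_mode : {"positive_tiles", "all_tiles"}
        Divide combination counts by the number of tiles positive for at
        least one trait, or by all non-missing tiles.

    Returns
    -------
    numpy.ndarray of length C; entry ``i-1`` is the proportion of tiles in
    combination ``i``.

    Raises
    ------
    UndefinedHTIError
        In ``positive_tiles`` mode when no tile is positive for any trait.
    """
    if denominator_mode not in ("positive_tiles", "all_tiles"):
        raise ValueError(f"unknown denominator_mode {denominator_mode!r}")
    C = combination_count(trait_count)
    arr = np.asarray(combo_map, dtype=float).ravel()
    arr = arr[~np.isnan(arr)]
    if arr.size == 0:
        raise ValueError("combination map has no non-missing tiles")
    idx = arr.astype(np.int64)
    if (idx < 0).any() or (idx > C).any():
        raise ValueError(f"combination indices must lie in [0, {C}]")
    counts = np.bincount(idx, minlength=C + 1).astype(float)
    n_positive = counts[1:].sum()
    if denominator_mode == "positive_tiles":
        if n_positive == 0:
            raise UndefinedHTIError(
                "no positive tiles: proportions undefined in positive_tiles mode"
            )
        denom = n_positive
    else:
        denom = float(idx.size)
    return counts[1:] / denom


def compute_hti(p: np.ndarray, C: int) -> float:
    """Evaluate ``HTI = -sum p_i log_C(p_i)`` with ``0 * log 0 := 0``.

    ``p`` must have length C with entries in [0, 1].  For ``C == 1`` a
    single combination exists, so the slide is homogeneous by definition and
    the index is 0.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or p.size != C:
        raise ValueError(f"p must have length C={C}, got shape {p.shape}")
    if (p < 0).any():
        raise ValueError("proportions must be non-negative")
    if (p > 1 + 1e-12).any():
        raise ValueError("proportions must not exceed 1")
    if C == 1:
        return 0.0
    pos = p[p > 0]
    # entropy in nats, normalized by log C
    h = -(pos * np.log(pos)).sum() / math.log(C)
    # clip tiny negative/overshoot from rounding; + 0.0 normalizes -0.0
    return float(min(max(h, 0.0), 1.0) + 0.0)


def hti_for_map(
    combo_map: np.ndarray,
    trait_count: int,
    slide_id: str = "",
    traits: list[str] | None = None,
    denominator_mode: str = "positive_tiles",
) -> HTIResult:
    """Compute an :class:`HTIResult` straight from a combination map.

    An undefined index (no positive tiles in ``positive_tiles`` mode) is
    returned as ``hti = nan`` rather than raised, so cohort-level loops can
    exclude such slides downstream.
    """
    if traits is None:
        traits = [f"trait_{t}" for t in range(trait_count)]
    C = combination_count(trait_count)
    arr = np.asarray(combo_map, dtype=float).ravel()
    valid = arr[~np.isnan(arr)]
    n_tiles = int(valid.size)
    n_pos = int((valid > 0).sum())
    try:
        p = combination_proportions(combo_map, trait_count, denominator_mode)
    except UndefinedHTIError:
        return HTIResult(
            slide_id=slide_id, traits=list(traits), C=C,
            p=np.zeros(C), denominator_mode=denominator_mode,
            n_tiles=n_tiles, n_positive_tiles=n_pos, hti=float("nan"),
        )
    return HTIResult(
        slide_id=slide_id, traits=list(traits), C=C, p=p,
        denominator_mode=denominator_mode,
        n_tiles=n_tiles, n_positive_tiles=n_pos,
        hti=compute_hti(p, C),
    )
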