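"""Synthetic slides, tile predictors and survival cohorts with planted truth.

The generator plants a known trait-combination composition on a tile grid
(so the heterogeneity index of the slide is known exactly), renders tiles
whose dominant color encodes their combination (so a trivial color-threshold
predictor can stand in as an oracle classifier), emits noisy per-tile trait
predictions by flipping the true bits, and simulates cohorts whose survival
hazard depends on the planted heterogeneity.  Everything is deterministic
under a seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from histocart.scoring import TilePredictionSet
from histocart.cartography import default_palette

__all__ = [
    "PlantedSlide",
    "SyntheticCohort",
    "gen_planted_slide",
    "gen_tile_images",
    "noisy_oracle",
    "gen_cohort",
    "color_threshold_predictor",
]

# baseline median survival of 60 months; hazard h0 = ln 2 / 60 per month
BASELINE_MEDIAN_MONTHS = 60.0
DX2_FRACTION = 0.10


@dataclass
class PlantedSlide:
    """A synthetic slide with a known combination assigned to every tile.

    ``combo_assignment[r, c]`` is the tile's combination index in
    ``0..C`` with ``C = 2**trait_count - 1``; 0 means no trait positive.
    """

    rows: int
    cols: int
    trait_count: int
    combo_assignment: np.ndarray
    spatial_pattern: str
    seed: int
    slide_id: str = "S1"

    def __post_init__(self) -> None:
        self.combo_assignment = np.asarray(self.combo_assignment, dtype=int)
        if self.combo_assignment.shape != (self.rows, self.cols):
            raise ValueError("combo_assignment shape must equal rows x cols")
        C = 2 ** self.trait_count - 1
        if (self.combo_assignment < 0).any() or (self.combo_assignment > C).any():
            raise ValueError(f"combination indices must lie in [0, {C}]")

    @property
    def C(self) -> int:
        return 2 ** self.trait_count - 1

    def trait_layer(self, t: int) -> np.ndarray:
        """True binary membership of trait t at every tile."""
        return (self.combo_assignment >> t) & 1

    def planted_proportions(self, denominator_mode: str = "positive_tiles") -> np.ndarray:
        """Empirical proportions over the C non-empty combinations."""
        counts = np.bincount(self.combo_assignment.ravel(), minlength=self.C + 1)
        pos = counts[1:].astype(float)
        denom = pos.sum() if denominator_mode == "positive_tiles" else counts.sum()
        if denom == 0:
            raise ValueError("no positive tiles")
        return pos / denom


@dataclass
class SyntheticCohort:
    """Simulated subjects with slides, bulk expression and survival.

    One row per (subject, slide, trait) in :meth:`to_frame`; subject-level
    fields (time, event, planted HTI) repeat across a subject's rows.
    """

    subjects: list[dict] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.subjects:
            for slide_id in s["slide_ids"]:
                for trait, value in s["expression"].items():
                    rows.append(
                        {
                            "subject_id": s["subject_id"],
                            "slide_id": slide_id,
                            "trait": trait,
                            "expression": value,
                            "time_months": s["time_months"],
                            "event": s["event"],
                            "planted_hti": s["planted_hti"],
                        }
                    )
        return pd.DataFrame(rows)

    def survival_frame(self) -> pd.DataFrame:
        """One row per subject: subject_id, time_months, event, planted_hti."""
        return pd.DataFrame(
            [
                {
                    "subject_id": s["subject_id"],
                    "time_months": s["time_months"],
                    "event": s["event"],
                    "planted_hti": s["planted_hti"],
                }
                for s in self.subjects
            ]
        )


def _apportion(proportions: np.ndarray, n: int) -> np.ndarray:
    """Integer counts summing to n, largest-remainder rounding, ties by index."""
    exact = proportions * n
    counts = np.floor(exact + 1e-9).astype(int)
    short = n - counts.sum()
    if short > 0:
        frac = exact - counts
        order = sorted(range(len(frac)), key=lambda i: (-frac[i], i))
        for i in order[:short]:
            counts[i] += 1
    return counts


def gen_planted_slide(
    rows: int,
    cols: int,
    trait_count: int,
    combo_proportions,
    spatial_pattern: str = "blocks",
    seed: int = 0,
    slide_id: str = "S1",
) -> PlantedSlide:
    """Plant a combination composition on a rows x cols tile grid.

    ``combo_proportions`` is a vector over combinations ``0..C`` (entry 0 =
    all-negative tiles) summing to 1.  Tile counts per combination follow
    largest-remainder apportionment, so integral ``p_i * rows * cols`` are
    honored exactly.  Spatial patterns:

    - ``blocks``: each combination occupies a contiguous band (column-major
      fill), mimicking compact clonal patches;
    - ``random``: the multiset of assignments is shuffled uniformly;
    - ``gradient``: combinations are ordered along rows (row-major fill),
      a smooth top-to-bottom transition.
    """
    if rows * cols < 1:
        raise ValueError("grid must contain at least one tile")
    C = 2 ** trait_count - 1
    p = np.asarray(combo_proportions, dtype=float)
    if p.size != C + 1:
        raise ValueError(f"combo_proportions must have length C+1={C + 1}, got {p.size}")
    if (p < 0).any():
        raise ValueError("proportions must be non-negative")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"proportions must sum to 1, got {p.sum()}")
    if spatial_pattern not in ("blocks", "random", "gradient"):
        raise ValueError(f"unknown spatial_pattern {spatial_pattern!r}")
    counts = _apportion(p, rows * cols)
    flat = np.repeat(np.arange(C + 1), counts)
    if spatial_pattern == "random":
        rng = np.random.default_rng(seed)
        flat = rng.permutation(flat)
        combo = flat.reshape(rows, cols)
    elif spatial_pattern == "blocks":
        combo = flat.reshape(cols, rows).T  # column-major bands
    else:  # gradient
        combo = flat.reshape(rows, cols)  # row-major ordering
    return PlantedSlide(
        rows=rows, cols=cols, trait_count=trait_count,
        combo_assignment=combo, spatial_pattern=spatial_pattern,
        seed=seed, slide_id=slide_id,
    )


def _combo_color(index: int, trait_count: int) -> tuple[int, int, int]:
    """Dominant tissue color for a combination index (never near-white)."""
    color = default_palette(trait_count)[index]
    # keep channels clear of the 220 whiteness threshold
    return tuple(min(c, 200) for c in color)


def gen_tile_images(
    slide: PlantedSlide,
    out_dir: str | Path,
    tile_size: int = 64,
    background_tiles: set | None = None,
    seed: int = 0,
) -> list[Path]:
    """Write one PNG per tile whose dominant color encodes its combination.

    Non-background tiles are solid-colored (with mild pixel noise) in their
    combination's color, so a color-threshold predictor can recover the
    planted truth.  Background tiles get > 60% near-white pixels, so the
    default background filter removes them.  Files are named
    ``{slide_id}_{row}_{col}.png``.
    """
    if tile_size < 16:
        raise ValueError("tile_size must be >= 16")
    background_tiles = background_tiles or set()
    for (r, c) in background_tiles:
        if not (0 <= r < slide.rows and 0 <= c < slide.cols):
            raise ValueError(f"background position ({r}, {c}) outside grid")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    paths = []
    for r in range(slide.rows):
        for c in range(slide.cols):
            base = _combo_color(int(slide.combo_assignment[r, c]), slide.trait_count)
            img = np.empty((tile_size, tile_size, 3), dtype=np.int16)
            img[:] = base
            img += rng.integers(-10, 11, size=img.shape, dtype=np.int16)
            img = np.clip(img, 0, 219).astype(np.uint8)
            if (r, c) in background_tiles:
                # ~80% of pixels near-white, comfortably above the 60% floor
                mask = rng.random((tile_size, tile_size)) < 0.8
                white = rng.integers(240, 256, size=(tile_size, tile_size, 3))
                img = np.where(mask[..., None], white, img).astype(np.uint8)
            path = out_dir / f"{slide.slide_id}_{r}_{c}.png"
            Image.fromarray(img).save(path)
            paths.append(path)
    return paths


def color_threshold_predictor(trait: int, trait_count: int):
    """Oracle predictor: classify a tile by nearest combination color.

    Returns a callable mapping a tile image to the trait's true bit, by
    matching the tile's mean color to the closest planted combination color.
    """
    combos = np.arange(2 ** trait_count)
    colors = np.array([_combo_color(int(i), trait_count) for i in combos], dtype=float)

    def predict(tile: np.ndarray) -> int:
        tissue = np.asarray(tile, dtype=float)
        mean = tissue.reshape(-1, 3).mean(axis=0)
        nearest = int(np.argmin(((colors - mean) ** 2).sum(axis=1)))
        return int(combos[nearest] >> trait & 1)

    return predict


def noisy_oracle(
    slide: PlantedSlide,
    flip_prob: float,
    seed: int = 0,
    model: str = "1",
    traits: list[str] | None = None,
) -> TilePredictionSet:
    """Emit per-trait tile predictions: the true bit, flipped with ``flip_prob``.

    Stands in for a trained tile classifier of tunable accuracy.  Each
    (tile, trait) bit is flipped independently.  ``flip_prob=0`` reproduces
    the planted tensor cartography exactly; ``flip_prob=1`` is its bitwise
    complement.
    """
    if not 0.0 <= flip_prob <= 1.0:
        raise ValueError("flip_prob must lie in [0, 1]")
    if traits is None:
        traits = [f"trait_{t}" for t in range(slide.trait_count)]
    rng = np.random.default_rng(seed)
    records = []
    for t, trait_name in enumerate(traits):
        truth = slide.trait_layer(t)
        flips = rng.random((slide.rows, slide.cols)) < flip_prob
        pred = np.where(flips, 1 - truth, truth)
        for r in range(slide.rows):
            for c in range(slide.cols):
                records.append(
                    {
                        "slide_id": slide.slide_id,
                        "row": r,
                        "col": c,
                        "trait": trait_name,
                        "model": str(model),
                        "prediction": int(pred[r, c]),
                    }
                )
    return TilePredictionSet.from_records(records)


def gen_cohort(
    n_subjects: int,
    trait_count: int = 2,
    hti_hazard_coef: float = 0.0,
    seed: int = 0,
    baseline_median: float = BASELINE_MEDIAN_MONTHS,
    dx2_fraction: float = DX2_FRACTION,
    censor: bool = True,
) -> SyntheticCohort:
    """Simulate a cohort whose survival hazard depends on planted heterogeneity.

    Each subject gets a planted HTI uniform on [0, 1], per-trait bulk
    expression (standard normal), and an exponential survival time with
    hazard ``h0 * exp(hti_hazard_coef * hti)`` where ``h0 = ln 2 /
    baseline_median``.  Censoring is independent uniform on
    ``[0, 2 * baseline_median]``, yielding roughly 40-60% observed events.
    A ``dx2_fraction`` of subjects carries a second (DX2) diagnostic slide.
    ``censor=False`` disables censoring (all events observed), useful for
    distributional checks on the raw event times.
    """
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    rng = np.random.default_rng(seed)
    h0 = math.log(2.0) / baseline_median
    traits = [f"trait_{t}" for t in range(trait_count)]
    subjects = []
    for i in range(n_subjects):
        hti = float(rng.uniform())
        hazard = h0 * math.exp(hti_hazard_coef * hti)
        t_event = float(rng.exponential(1.0 / hazard))
        t_cens = float(rng.uniform(0.0, 2.0 * baseline_median))
        if censor:
            time = min(t_event, t_cens)
            event = int(t_event <= t_cens)
        else:
            time, event = t_event, 1
        sid = f"SUBJ{i:04d}"
        slide_ids = [f"{sid}-DX1"]
        if rng.random() < dx2_fraction:
            slide_ids.append(f"{sid}-DX2")
        subjects.append(
            {
                "subject_id": sid,
                "slide_ids": slide_ids,
                "expression": {tr: float(rng.normal()) for tr in traits},
                "time_months": max(time, 1e-6),
                "event": event,
                "planted_hti": hti,
            }
        )
    return SyntheticCohort(subjects=subjects)
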