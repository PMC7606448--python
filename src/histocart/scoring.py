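"""Per-tile predictor contract, slide scoring, AUC, ensembles, correlations.

The deep tile classifier is abstracted behind a predictor contract: any
callable mapping a tile image to a binary call.  Slide-level prediction is
the fraction of retained tiles classified positive; slide-level performance
is the Mann-Whitney AUC of those scores against the slides' bulk labels.
Five models are trained per trait on different train/validation splits; the
top three by validation AUC are combined by per-tile majority vote.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from histocart.tiling import TileGrid

__all__ = [
    "ENSEMBLE_KEY",
    "TilePredictionSet",
    "predict_tiles",
    "slide_score",
    "slide_auc",
    "select_top_models",
    "ensemble_vote",
    "ensemble_predictions",
    "correlate_scores",
]

logger = logging.getLogger(__name__)

ENSEMBLE_KEY = "ensemble"

_COLUMNS = ["slide_id", "row", "col", "trait", "model", "prediction"]


@dataclass
class TilePredictionSet:
    """Binary tile predictions keyed by (slide_id, row, col, trait, model).

    ``model`` is a round label ("1".."5" for single models) or the
    distinguished ensemble key.  Backed by a DataFrame with columns
    ``slide_id, row, col, trait, model, prediction``.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(_COLUMNS) - set(self.frame.columns)
        if missing:
            raise ValueError(f"prediction table missing columns {sorted(missing)}")
        preds = self.frame["prediction"]
        if len(preds) and not preds.isin([0, 1]).all():
            raise ValueError("predictions must be binary 0/1")

    @classmethod
    def from_records(cls, records: list[dict]) -> "TilePredictionSet":
        frame = pd.DataFrame(records, columns=_COLUMNS)
        return cls(frame)

    def select(
        self,
        slide_id: str | None = None,
        trait: str | None = None,
        model: str | None = None,
    ) -> pd.DataFrame:
        f = self.frame
        if slide_id is not None:
            f = f[f["slide_id"] == slide_id]
        if trait is not None:
            f = f[f["trait"] == trait]
        if model is not None:
            f = f[f["model"] == str(model)]
        return f

    def merge(self, other: "TilePredictionSet") -> "TilePredictionSet":
        return TilePredictionSet(
            pd.concat([self.frame, other.frame], ignore_index=True)
        )

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "TilePredictionSet":
        frame = pd.read_csv(path, sep="\t", dtype={"model": str})
        return cls(frame)


def predict_tiles(
    predictor,
    tiles: dict[tuple[int, int], np.ndarray],
    grid: TileGrid,
    trait: str,
    model: str = "1",
) -> tuple[TilePredictionSet, list[tuple[int, int]]]:
    """Apply a binary predictor to every retained tile of a slide.

    Background tiles are skipped.  A predictor failure on a tile is
    recorded and the slide flagged incomplete via the returned error list;
    callers should exclude incomplete slides from AUC.

    Returns
    -------
    (predictions, failed_positions)
    """
    records, failed = [], []
    positions = grid.retained_positions()
    if not positions:
        logger.warning("slide %s has no retained tiles", grid.slide_id)
    for (r, c) in positions:
        try:
            pred = int(predictor(tiles[(r, c)]))
        except Exception:  # noqa: BLE001 - per-tile fault isolation
            logger.warning(
                "predictor failed on slide %s tile (%d, %d)", grid.slide_id, r, c
            )
            failed.append((r, c))
            continue
        if pred not in (0, 1):
            raise ValueError(f"predictor returned non-binary value {pred!r}")
        records.append(
            {
                "slide_id": grid.slide_id,
                "row": r,
                "col": c,
                "trait": trait,
                "model": str(model),
                "prediction": pred,
            }
        )
    return TilePredictionSet.from_records(records), failed


def slide_score(predictions: pd.DataFrame | TilePredictionSet) -> float:
    """Slide-level score: fraction of the slide's retained tiles predicted positive.

    ``predictions`` holds one row per retained tile of a single slide,
    trait and model.
    """
    if isinstance(predictions, TilePredictionSet):
        predictions = predictions.frame
    n = len(predictions)
    if n == 0:
        raise ValueError("slide score undefined with zero retained tiles")
    return float(predictions["prediction"].sum() / n)


def slide_auc(scores, labels) -> float:
    """Slide-level AUC of scores against binary labels.

    Computed by the midrank formulation of the Mann-Whitney statistic:
    the fraction of (positive, negative) slide pairs where the positive
    slide scores higher, ties counted 1/2.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    if not np.isin(labels, [0, 1]).all():
        raise ValueError("labels must be binary 0/1")
    n1 = int((labels == 1).sum())
    n0 = int((labels == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC undefined: both classes must be present")
    ranks = stats.rankdata(scores)  # midranks
    u = ranks[labels == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def select_top_models(validation_aucs, k: int = 3) -> list[int]:
    """1-based indices of the k rounds with highest validation AUC.

    Ties are broken toward the lower round index.  Returned in descending
    AUC order.
    """
    aucs = list(validation_aucs)
    if k > len(aucs):
        raise ValueError(f"k={k} exceeds the {len(aucs)} available rounds")
    order = sorted(range(len(aucs)), key=lambda i: (-aucs[i], i))
    return [i + 1 for i in order[:k]]


def ensemble_vote(votes) -> int:
    """Majority vote of exactly three binary tile predictions."""
    votes = list(votes)
    if len(votes) != 3:
        raise ValueError(f"ensemble requires exactly 3 votes, got {len(votes)}")
    if any(v not in (0, 1) for v in votes):
        raise ValueError(f"votes must be binary, got {votes}")
    return int(sum(votes) >= 2)


def ensemble_predictions(
    predictions: TilePredictionSet,
    trait: str,
    member_rounds: list[int],
) -> TilePredictionSet:
    """Combine three model rounds into per-tile majority-vote predictions.

    Every retained tile must carry a vote from each member round; a tile
    with missing votes raises (incomplete ensemble).
    """
    if len(member_rounds) != 3:
        raise ValueError("ensemble is fixed at 3 member models")
    members = [str(m) for m in member_rounds]
    f = predictions.frame
    f = f[(f["trait"] == trait) & (f["model"].isin(members))]
    wide = f.pivot_table(
        index=["slide_id", "row", "col"],
        columns="model",
        values="prediction",
        aggfunc="first",
    )
    if wide.isna().any().any() or wide.shape[1] != 3:
        raise ValueError("incomplete ensemble: some tiles lack a member vote")
    maj = (wide.sum(axis=1) >= 2).astype(int)
    out = maj.reset_index().rename(columns={0: "prediction"})
    out["trait"] = trait
    out["model"] = ENSEMBLE_KEY
    return TilePredictionSet(out[_COLUMNS])


def correlate_scores(
    scores_by_trait: dict[str, np.ndarray],
    percentiles_by_trait: dict[str, np.ndarray],
) -> pd.DataFrame:
    """Spearman correlation of slide scores vs expression percentiles, per trait.

    p-values are adjusted across traits with Benjamini-Hochberg FDR.
    Returns a DataFrame with columns ``trait, rho, p_value, fdr_p``.
    """
    rows = []
    for trait in scores_by_trait:
        s = np.asarray(scores_by_trait[trait], dtype=float)
        q = np.asarray(percentiles_by_trait[trait], dtype=float)
        if s.size != q.size:
            raise ValueError(f"trait {trait}: unequal score/percentile lengths")
        if s.size < 3:
            raise ValueError(f"trait {trait}: need >= 3 paired observations")
        if np.all(s == s[0]) or np.all(q == q[0]):
            raise ValueError(f"trait {trait}: constant vector, correlation undefined")
        rho, p = stats.spearmanr(s, q)
        rows.append({"trait": trait, "rho": float(rho), "p_value": float(p)})
    out = pd.DataFrame(rows)
    out["fdr_p"] = multipletests(out["p_value"], method="fdr_bh")[1]
    return out
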