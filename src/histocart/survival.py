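"""HTI-based survival stratification: Kaplan-Meier curves and the log-rank test.

Patients are represented by one slide each (the DX1 diagnostic slide when
several exist), restricted to slides outside model development for both
traits of the cartography (the held-out test slides plus slides designated
OOD for both traits), and split into high and low heterogeneity groups by
HTI threshold.  Group survival is compared with Mantel's log-rank test and
visualized with Kaplan-Meier curves carrying 95% confidence bands.

Estimation is delegated to lifelines (Kaplan-Meier product-limit estimator
with log-transformed Greenwood intervals; chi-square log-rank test).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test

__all__ = [
    "LogrankResult",
    "select_primary_slide",
    "eligible_slides",
    "stratify",
    "km_curve",
    "logrank",
    "plot_km",
]

logger = logging.getLogger(__name__)


@dataclass
class LogrankResult:
    statistic: float
    p_value: float
    n_a: int
    n_b: int


def select_primary_slide(slide_ids) -> str:
    """The patient's primary diagnostic slide: DX1 when present.

    Falls back to the lexicographically first slide (with a warning) for
    patients without a DX1-suffixed slide.
    """
    slide_ids = list(slide_ids)
    if not slide_ids:
        raise ValueError("patient has no slides")
    dx1 = [s for s in slide_ids if str(s).upper().endswith("DX1")]
    if dx1:
        return dx1[0]
    chosen = sorted(slide_ids, key=str)[0]
    logger.warning("no DX1 slide among %s; falling back to %s", slide_ids, chosen)
    return chosen


def eligible_slides(
    designations: dict[str, pd.DataFrame],
    test_slides: set,
    include_test: bool = True,
) -> set:
    """Slides usable for survival analysis under a two-trait cartography.

    Only slides that never entered either trait's model development
    qualify: the shared held-out test slides plus slides designated OOD
    (``ood_all``) for *both* traits.  A slide OOD for one trait but in
    train/validation for the other is excluded.

    Parameters
    ----------
    designations : {trait: DataFrame indexed by slide_id with bool ``ood_all``}
        Exactly two traits.
    test_slides : set
        Slide ids of held-out test subjects (shared across traits).
    """
    if len(designations) != 2:
        raise ValueError("survival stratification uses exactly two traits")
    (da, db) = designations.values()
    common = set(da.index) & set(db.index)
    for trait, d in designations.items():
        missing = (set(da.index) | set(db.index)) - set(d.index)
        if missing:
            raise ValueError(f"missing designation for trait {trait}: {sorted(missing)[:3]}")
    ood_both = {s for s in common if bool(da.loc[s, "ood_all"]) and bool(db.loc[s, "ood_all"])}
    return (ood_both | set(test_slides)) if include_test else ood_both


def stratify(
    hti: pd.Series,
    low_thr: float = 0.5,
    high_thr: float = 0.5,
) -> pd.Series:
    """Assign patients to heterogeneity groups by HTI threshold.

    ``hti > high_thr`` -> "high"; ``hti <= low_thr`` -> "low"; values in
    between (when ``low_thr < high_thr``, e.g. the 0.3/0.7 variant) and
    undefined (NaN) HTIs -> "excluded".
    """
    if low_thr > high_thr:
        raise ValueError("low_thr must be <= high_thr")
    hti = pd.Series(hti, dtype=float)
    groups = pd.Series("excluded", index=hti.index, dtype=object)
    groups[hti > high_thr] = "high"
    groups[hti <= low_thr] = "low"
    n_undef = int(hti.isna().sum())
    if n_undef:
        logger.info("%d patients with undefined HTI excluded", n_undef)
    return groups


def km_curve(times, events, alpha: float = 0.05) -> pd.DataFrame:
    """Kaplan-Meier product-limit estimate with a 95% confidence band.

    Returns a DataFrame indexed by time with columns ``survival``,
    ``ci_lower``, ``ci_upper`` (log-transformed Greenwood band).  Censored
    subjects reduce the risk set without producing steps.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events)
    if times.size == 0:
        raise ValueError("need at least one subject")
    if (times < 0).any():
        raise ValueError("times must be non-negative")
    kmf = KaplanMeierFitter(alpha=alpha)
    kmf.fit(times, events)
    out = kmf.survival_function_.copy()
    out.columns = ["survival"]
    ci = kmf.confidence_interval_
    out["ci_lower"] = ci.iloc[:, 0].to_numpy()
    out["ci_upper"] = ci.iloc[:, 1].to_numpy()
    return out


def logrank(times_a, events_a, times_b, events_b) -> LogrankResult:
    """Mantel's log-rank test comparing two survival distributions.

    At each distinct event time the expected events in group A are
    ``d * n_A / n`` with hypergeometric variance; the statistic
    ``(sum(O - E))^2 / sum(Var)`` is chi-square with 1 df under the null.
    """
    times_a, times_b = np.asarray(times_a, float), np.asarray(times_b, float)
    events_a, events_b = np.asarray(events_a), np.asarray(events_b)
    if times_a.size == 0 or times_b.size == 0:
        raise ValueError("both groups must be non-empty")
    if events_a.sum() + events_b.sum() == 0:
        raise ValueError("log-rank test undefined with no events in either group")
    res = logrank_test(times_a, times_b, event_observed_A=events_a, event_observed_B=events_b)
    return LogrankResult(
        statistic=float(res.test_statistic),
        p_value=float(res.p_value),
        n_a=int(times_a.size),
        n_b=int(times_b.size),
    )


def plot_km(
    groups: dict[str, tuple[np.ndarray, np.ndarray]],
    out_path=None,
    title: str = "Survival by heterogeneity group",
):
    """Plot Kaplan-Meier curves (with 95% bands) for named groups.

    ``groups`` maps a label (e.g. "high"/"low") to ``(times, events)``.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4.5))
    for label, (times, events) in groups.items():
        kmf = KaplanMeierFitter()
        kmf.fit(times, events, label=f"{label} (n={len(times)})")
        kmf.plot_survival_function(ax=ax, ci_show=True)
    ax.set_xlabel("Time (months)")
    ax.set_ylabel("Survival probability")
    ax.set_title(title)
    ax.set_ylim(0, 1.02)
    fig.tight_layout()
    if out_path is not None:
        fig.savefig(out_path, dpi=150)
        plt.close(fig)
    return fig
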