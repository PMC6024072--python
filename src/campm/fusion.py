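"""Time-alignment of minute PM2.5 with annotations, and descriptive outputs.

Produces the study's descriptive layers: per-concept exposure summaries
(mean/SD/median of 1-minute PM2.5 over minutes carrying the concept, plus
minutes of frequency), per-participant-day time budgets by concept, and
24-hour daily means by sex.  Minutes with missing PM are excluded from both
numerator and denominator everywhere; a minute flagged for several concepts
contributes to every one of them (concepts are non-exclusive).
"""

from __future__ import annotations

import logging

import pandas as pd

from .concepts import ConceptVocabulary, DEFAULT_VOCABULARY

__all__ = [
    "fuse",
    "fuse_intervals",
    "summarize_by_concept",
    "time_budget",
    "daily_mean",
]

log = logging.getLogger(__name__)


def _concept_cols(df: pd.DataFrame, vocabulary: ConceptVocabulary) -> list[str]:
    return [c for c in df.columns if c in vocabulary.concepts]


def fuse(
    minute_pm: pd.DataFrame,
    minute_annotations: pd.DataFrame,
    metadata: pd.DataFrame,
    vocabulary: ConceptVocabulary = DEFAULT_VOCABULARY,
) -> pd.DataFrame:
    """Inner-join minute PM with minute annotations on (participant_day, minute).

    Unmatched minutes on either side are counted and logged; disjoint time
    ranges produce an empty frame and a warning.  Participant sex is attached
    from the session metadata.
    """
    pm = minute_pm.copy()
    ann = minute_annotations.copy()
    pm["minute"] = pd.to_datetime(pm["minute"])
    ann["minute"] = pd.to_datetime(ann["minute"])
    fused = pm.merge(ann, on=["participant_day", "minute"], how="inner")
    n_pm_only = len(pm) - len(fused)
    n_ann_only = len(ann) - len(fused)
    if fused.empty:
        log.warning(
            "fuse: no overlapping minutes (pm rows=%d, annotation rows=%d)",
            len(pm), len(ann))
    else:
        log.info("fuse: %d matched minutes (%d pm-only, %d annotation-only)",
                 len(fused), n_pm_only, n_ann_only)
    sex = metadata[["participant_day", "sex"]].drop_duplicates()
    fused = fused.merge(sex, on="participant_day", how="left")
    return fused


def fuse_intervals(
    minute_pm: pd.DataFrame,
    interval_annotations: pd.DataFrame,
    metadata: pd.DataFrame,
    interval_min: int = 5,
    vocabulary: ConceptVocabulary = DEFAULT_VOCABULARY,
) -> pd.DataFrame:
    """5-minute fusion: interval mean PM joined to concept proportions.

    ``pm_mean_5min`` is the mean of the available (non-missing) minute values
    within the half-open 5-minute interval.
    """
    pm = minute_pm.copy()
    pm["interval_start"] = pd.to_datetime(pm["minute"]).dt.floor(f"{interval_min}min")
    pm5 = (pm.groupby(["participant_day", "interval_start"])["pm"]
             .mean().rename("pm_mean_5min").reset_index())
    ann = interval_annotations.copy()
    ann["interval_start"] = pd.to_datetime(ann["interval_start"])
    fused = pm5.merge(ann, on=["participant_day", "interval_start"], how="inner")
    sex = metadata[["participant_day", "sex"]].drop_duplicates()
    fused = fused.merge(sex, on="participant_day", how="left")
    fused["interval_index"] = (
        fused.sort_values(["participant_day", "interval_start"])
             .groupby("participant_day").cumcount())
    return fused.sort_values(["participant_day", "interval_start"]).reset_index(drop=True)


def summarize_by_concept(
    fused: pd.DataFrame,
    vocabulary: ConceptVocabulary = DEFAULT_VOCABULARY,
    by_sex: bool = True,
) -> pd.DataFrame:
    """Per-concept exposure table: mean, SD, median PM2.5 and total minutes.

    One row per (concept, sex) over fused minutes carrying the concept with
    non-missing PM.  Concepts never observed in a stratum are absent from the
    output (they would be "NA" rows).
    """
    if fused.empty:
        raise ValueError("fused minute table is empty")
    cols = _concept_cols(fused, vocabulary)
    strata = fused.groupby("sex") if by_sex else [("all", fused)]
    rows = []
    for sex, g in strata:
        ok = g["pm"].notna()
        for c in cols:
            sel = g.loc[ok & g[c].astype(bool), "pm"]
            if len(sel) == 0:
                continue
            rows.append({
                "concept": c,
                "category": vocabulary.category_of(c),
                "sex": sex,
                "mean": float(sel.mean()),
                "sd": float(sel.std(ddof=1)) if len(sel) > 1 else 0.0,
                "median": float(sel.median()),
                "total_minutes": int(len(sel)),
            })
    return pd.DataFrame(rows)


def time_budget(
    minute_annotations: pd.DataFrame,
    metadata: pd.DataFrame | None = None,
    vocabulary: ConceptVocabulary = DEFAULT_VOCABULARY,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Minutes per participant-day per concept, plus per-sex medians/IQRs.

    Returns ``(long, summary)``: ``long`` has one row per (participant_day,
    concept) with the minutes the concept was present that day (zero rows
    included), ``summary`` the per-sex median and quartiles of minutes/day.
    """
    cols = _concept_cols(minute_annotations, vocabulary)
    per_day = (minute_annotations.groupby("participant_day")[cols].sum()
               .astype(int))
    long = per_day.reset_index().melt(
        id_vars="participant_day", var_name="concept", value_name="minutes")
    if metadata is not None:
        sex = metadata[["participant_day", "sex"]].drop_duplicates()
        long = long.merge(sex, on="participant_day", how="left")
        summary = (long.groupby(["sex", "concept"])["minutes"]
                   .agg(median="median",
                        q1=lambda s: s.quantile(0.25),
                        q3=lambda s: s.quantile(0.75),
                        n_days="size")
                   .reset_index())
    else:
        summary = (long.groupby("concept")["minutes"]
                   .agg(median="median",
                        q1=lambda s: s.quantile(0.25),
                        q3=lambda s: s.quantile(0.75),
                        n_days="size")
                   .reset_index())
    return long, summary


def daily_mean(
    minute_pm: pd.DataFrame,
    metadata: pd.DataFrame | None = None,
    coverage_warn: float = 0.5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """24-h mean exposure per participant-day and per-sex overall means.

    The participant-day mean is the unweighted mean over available minutes
    (missing minutes are ignored, never zero-filled); the stratum mean is the
    mean of participant-day means, weighting each monitored day equally as
    the repeated-measures design does.  Days with under ``coverage_warn``
    minute coverage (relative to the longest day observed) are flagged.
    """
    g = minute_pm.groupby("participant_day")["pm"]
    per_day = g.agg(daily_mean="mean", n_minutes="count").reset_index()
    expected = minute_pm.groupby("participant_day")["minute"].size().max()
    per_day["low_coverage"] = per_day["n_minutes"] < coverage_warn * expected
    if metadata is not None:
        sex = metadata[["participant_day", "sex"]].drop_duplicates()
        per_day = per_day.merge(sex, on="participant_day", how="left")
        overall = (per_day.groupby("sex")["daily_mean"]
                   .agg(mean="mean", sd="std", n_days="size").reset_index())
    else:
        overall = pd.DataFrame([{
            "sex": "all",
            "mean": per_day["daily_mean"].mean(),
            "sd": per_day["daily_mean"].std(),
            "n_days": len(per_day),
        }])
    return per_day, overall
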