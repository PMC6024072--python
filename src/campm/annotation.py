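"""Inter-rater agreement and photo -> minute -> 5-minute aggregation.

Wearable-camera photographs are manually annotated with boolean visual
concepts.  Agreement between annotators is measured with two-category Cohen's
kappa per concept (or per category group); annotators must reach a kappa
threshold on a training set before coding study data.  Annotations are then
aggregated: a minute carries a concept if any codeable photo in that minute
does, and a 5-minute interval carries the proportion of its observed minutes
that carry it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .concepts import ConceptVocabulary, DEFAULT_VOCABULARY
from .config import AggregationConfig

__all__ = [
    "KappaResult",
    "cohens_kappa",
    "gate_annotator",
    "photos_to_minutes",
    "minutes_to_intervals",
    "concept_frequency",
]


@dataclass(frozen=True)
class KappaResult:
    """Two-rater, two-category Cohen's kappa for one concept or category."""

    category: str
    kappa: float | None  # None when chance agreement p_e == 1 (undefined)
    n_items: int
    p_observed: float
    p_expected: float

    @property
    def defined(self) -> bool:
        return self.kappa is not None


def cohens_kappa(ratings_a, ratings_b, category: str = "") -> KappaResult:
    """Cohen's kappa between two paired boolean rating vectors.

    kappa = (p_o - p_e) / (1 - p_e) with p_o the observed agreement fraction
    and p_e the agreement expected from the raters' marginal TRUE rates.
    When both raters are constant and identical, p_e = 1 and kappa is
    undefined (returned as None rather than a number).
    """
    a = np.asarray(ratings_a, dtype=bool)
    b = np.asarray(ratings_b, dtype=bool)
    if a.ndim != 1 or b.ndim != 1:
        raise ValueError("ratings must be 1-d vectors")
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    n = len(a)
    if n == 0:
        raise ValueError("empty rating vectors")
    pa, pb = a.mean(), b.mean()
    p_o = float(np.mean(a == b))
    p_e = float(pa * pb + (1 - pa) * (1 - pb))
    if p_e >= 1.0:
        return KappaResult(category, None, n, p_o, p_e)
    kappa = (p_o - p_e) / (1.0 - p_e)
    return KappaResult(category, float(kappa), n, p_o, p_e)


@dataclass(frozen=True)
class GateResult:
    passed: bool
    kappas: dict[str, KappaResult]
    failing: tuple[str, ...]
    undefined: tuple[str, ...]
    missing: tuple[str, ...]


def gate_annotator(
    ratings_a: pd.DataFrame,
    ratings_b: pd.DataFrame,
    threshold: float = 0.85,
    by: str = "concept",
    vocabulary: ConceptVocabulary = DEFAULT_VOCABULARY,
) -> GateResult:
    """Pass/fail an annotator against a reference on a training set.

    Both frames carry one boolean column per concept, row-aligned by photo.
    ``by="concept"`` computes one kappa per concept column; ``by="category"``
    pools the concepts of each of the five annotation categories (a photo
    counts as positive for the category when any member concept is flagged).
    Pass requires kappa >= threshold (inclusive) in every unit with a defined
    kappa; undefined-kappa units are reported, not failed.  Concepts present
    in the reference but absent from the candidate's columns fail the gate as
    incomplete.
    """
    if by not in ("concept", "category"):
        raise ValueError("by must be 'concept' or 'category'")
    if len(ratings_a) != len(ratings_b):
        raise ValueError("training ratings must be row-aligned")
    ref_cols = [c for c in ratings_a.columns if c in vocabulary.concepts]
    missing = tuple(c for c in ref_cols if c not in ratings_b.columns)
    units: dict[str, tuple[pd.Series, pd.Series]] = {}
    usable = [c for c in ref_cols if c not in missing]
    if by == "concept":
        for c in usable:
            units[c] = (ratings_a[c], ratings_b[c])
    else:
        cats = sorted({vocabulary.category_of(c) for c in usable})
        for cat in cats:
            members = [c for c in usable if vocabulary.category_of(c) == cat]
            units[cat] = (ratings_a[members].any(axis=1), ratings_b[members].any(axis=1))
    kappas = {name: cohens_kappa(a, b, category=name) for name, (a, b) in units.items()}
    failing = tuple(n for n, k in kappas.items() if k.defined and k.kappa < threshold)
    undefined = tuple(n for n, k in kappas.items() if not k.defined)
    passed = not failing and not missing
    return GateResult(passed, kappas, failing, undefined, missing)


def _concept_columns(records: pd.DataFrame, vocabulary: ConceptVocabulary) -> list[str]:
    cols = [c for c in records.columns if c in vocabulary.concepts]
    if not cols:
        raise ValueError("no concept columns found in records")
    return cols


def photos_to_minutes(
    records: pd.DataFrame,
    aggregation: AggregationConfig | None = None,
    vocabulary: ConceptVocabulary = DEFAULT_VOCABULARY,
) -> pd.DataFrame:
    """Collapse photo annotations to minute-level booleans.

    One output row per minute containing at least one photo; a concept flag is
    the OR over codeable photos in that minute.  Minutes with photos but no
    codeable photo are kept with all-false flags by default
    (``uncodeable="as_absent"``) or dropped (``"as_missing"``).  Minutes with
    no photos (camera off) are absent.  Expects a single participant-day and
    annotator; duplicate photo_id raises.
    """
    aggregation = aggregation or AggregationConfig()
    cols = _concept_columns(records, vocabulary)
    out_cols = ["minute", *cols, "n_photos", "n_codeable"]
    if records.empty:
        return pd.DataFrame(columns=out_cols)
    if records["photo_id"].duplicated().any():
        dupes = records.loc[records["photo_id"].duplicated(), "photo_id"].tolist()
        raise ValueError(f"duplicate photo_id values: {dupes[:5]}")
    rec = records.copy()
    rec["minute"] = pd.to_datetime(rec["timestamp"]).dt.floor("min")
    codeable = rec["codeable"].astype(bool)
    flags = rec[cols].astype(bool).where(codeable, False)
    grouped = flags.groupby(rec["minute"]).any()
    counts = rec.groupby("minute").agg(
        n_photos=("photo_id", "size"), n_codeable=("codeable", "sum"))
    out = grouped.join(counts).reset_index()
    if aggregation.uncodeable == "as_missing":
        out = out.loc[out["n_codeable"] > 0].reset_index(drop=True)
    out["n_codeable"] = out["n_codeable"].astype(int)
    return out[out_cols]


def minutes_to_intervals(
    minutes: pd.DataFrame,
    aggregation: AggregationConfig | None = None,
    vocabulary: ConceptVocabulary = DEFAULT_VOCABULARY,
) -> pd.DataFrame:
    """Aggregate minute booleans into 5-minute presence proportions.

    Intervals are half-open [t, t+5 min), aligned to wall-clock minutes
    divisible by 5.  The proportion for a concept is (# observed minutes with
    the flag) / (# observed minutes in the interval) — observed meaning the
    minute appears in the input at all.  Intervals with fewer observed minutes
    than ``min_minutes_per_interval`` are dropped.
    """
    aggregation = aggregation or AggregationConfig()
    cols = _concept_columns(minutes, vocabulary)
    out_cols = ["interval_start", *cols, "n_minutes_observed"]
    if minutes.empty:
        return pd.DataFrame(columns=out_cols)
    m = minutes.copy()
    m["interval_start"] = pd.to_datetime(m["minute"]).dt.floor(f"{aggregation.interval_min}min")
    props = m.groupby("interval_start")[cols].mean()
    nobs = m.groupby("interval_start").size().rename("n_minutes_observed")
    out = props.join(nobs).reset_index()
    out = out.loc[out["n_minutes_observed"] >= aggregation.min_minutes_per_interval]
    return out.reset_index(drop=True)[out_cols]


def concept_frequency(
    records: pd.DataFrame,
    vocabulary: ConceptVocabulary = DEFAULT_VOCABULARY,
) -> pd.Series:
    """Photos flagged per concept (pooled over the given records).

    Feeds the modelling exclusion rule for infrequent concepts (< 100 photos).
    """
    cols = _concept_columns(records, vocabulary)
    if records.empty:
        return pd.Series(0, index=cols, dtype=int)
    return records[cols].astype(bool).sum().astype(int)
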