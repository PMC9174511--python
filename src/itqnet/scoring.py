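"""ICD-11 PTSD / complex-PTSD diagnostic algorithm and reliability.

The diagnostic rule: a respondent screens positive for PTSD when they were
trauma exposed, endorse (score >= 2) at least one of the two symptoms in each
of the three PTSD clusters (re-experiencing, avoidance, sense of current
threat) and endorse at least one PTSD-related functional impairment item.
They screen positive for complex PTSD (cPTSD) when, in addition, each of the
three disturbances-in-self-organization (DSO) clusters has an endorsed symptom
and at least one DSO-related impairment item is endorsed.  The two diagnoses
are mutually exclusive: cPTSD supersedes PTSD.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from itqnet.constants import (
    DEFAULT_EVENT_CLASSES,
    DSO_CLUSTERS,
    DSO_IMPAIRMENT,
    DSO_ITEMS,
    ENDORSEMENT_CUT,
    EXPOSURE_CLASSES,
    IMPAIRMENT_ITEMS,
    N_CHECKLIST_ITEMS,
    PERIODS,
    PTSD_CLUSTERS,
    PTSD_IMPAIRMENT,
    PTSD_ITEMS,
    SYMPTOM_ITEMS,
    exposure_column,
)

DIAGNOSIS_CATEGORIES = ("none", "PTSD", "cPTSD")


def _check_score(score, name: str = "score"):
    arr = np.asarray(score)
    if arr.dtype.kind not in "iuf":
        raise ValueError(f"{name} must be numeric, got dtype {arr.dtype}")
    finite = arr[~pd.isna(arr)]
    if finite.size and ((finite < 0) | (finite > 4) | (finite % 1 != 0)).any():
        raise ValueError(f"{name} must be an integer in 0..4, got {score!r}")


def endorse(score) -> bool | np.ndarray:
    """True when an item score meets the diagnostic cut (>= 2, 'Moderately')."""
    _check_score(score)
    return np.asarray(score) >= ENDORSEMENT_CUT if np.ndim(score) else score >= ENDORSEMENT_CUT


def cluster_met(score_a, score_b) -> bool:
    """A symptom cluster is met when at least one of its two items is endorsed."""
    return bool(endorse(score_a) or endorse(score_b))


def diagnose(record: Mapping, require_exposure: bool = True) -> str:
    """Apply the ICD-11 screening algorithm to one respondent.

    Parameters
    ----------
    record : mapping
        Item scores keyed by ``Re1 .. Rel2`` and ``Pimp1 .. Dimp3``, plus a
        boolean ``trauma_exposed``.  Any missing diagnostic item yields a
        missing diagnosis (``None``); such records are excluded from
        prevalence denominators.
    require_exposure : bool
        Gate the diagnosis on the trauma-exposure flag (default).  When
        False the algorithm is purely symptom-based.

    Returns
    -------
    str or None
        ``"cPTSD"``, ``"PTSD"`` or ``"none"``; ``None`` for unscorable records.
    """
    needed = list(SYMPTOM_ITEMS) + list(IMPAIRMENT_ITEMS)
    vals = {}
    for item in needed:
        v = record[item]
        if pd.isna(v):
            return None
        _check_score(v, name=item)
        vals[item] = int(v)

    exposed = bool(record["trauma_exposed"]) if require_exposure else True
    ptsd_clusters = all(cluster_met(vals[a], vals[b]) for a, b in PTSD_CLUSTERS)
    ptsd_imp = any(endorse(vals[i]) for i in PTSD_IMPAIRMENT)
    ptsd_criteria = exposed and ptsd_clusters and ptsd_imp

    dso_clusters = all(cluster_met(vals[a], vals[b]) for a, b in DSO_CLUSTERS)
    dso_imp = any(endorse(vals[i]) for i in DSO_IMPAIRMENT)

    if ptsd_criteria and dso_clusters and dso_imp:
        return "cPTSD"
    if ptsd_criteria:
        return "PTSD"
    return "none"


def subscale_scores(record: Mapping) -> tuple[int, int]:
    """Sum scores of the six PTSD and the six DSO symptom items."""
    for item in SYMPTOM_ITEMS:
        _check_score(record[item], name=item)
    ptsd_sum = int(sum(record[i] for i in PTSD_ITEMS))
    dso_sum = int(sum(record[i] for i in DSO_ITEMS))
    return ptsd_sum, dso_sum


def diagnose_table(
    X: pd.DataFrame, exposed: pd.Series, require_exposure: bool = True
) -> pd.Categorical:
    """Vectorized ICD-11 screening over a cohort table.

    Semantically identical to applying :func:`diagnose` row-wise (asserted in
    the test suite); records with any missing diagnostic item get NA.
    """
    items = X[list(SYMPTOM_ITEMS + IMPAIRMENT_ITEMS)]
    vals = items.to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        if np.nanmin(vals, initial=0) < 0 or np.nanmax(vals, initial=0) > 4:
            bad = items.columns[np.nanmax(vals, axis=0) > 4].tolist() + \
                items.columns[np.nanmin(vals, axis=0) < 0].tolist()
            raise ValueError(f"item scores outside 0..4 in columns {bad}")
    complete = ~np.isnan(vals).any(axis=1)
    E = vals >= ENDORSEMENT_CUT
    col = {c: i for i, c in enumerate(items.columns)}

    def met(pairs):
        return np.logical_and.reduce([
            E[:, col[a]] | E[:, col[b]] for a, b in pairs
        ])

    exp = np.ones(len(X), dtype=bool) if not require_exposure else np.asarray(exposed, bool)
    ptsd_criteria = (
        exp
        & met(PTSD_CLUSTERS)
        & np.logical_or.reduce([E[:, col[i]] for i in PTSD_IMPAIRMENT])
    )
    cptsd = (
        ptsd_criteria
        & met(DSO_CLUSTERS)
        & np.logical_or.reduce([E[:, col[i]] for i in DSO_IMPAIRMENT])
    )
    labels = np.where(cptsd, "cPTSD", np.where(ptsd_criteria, "PTSD", "none"))
    labels = np.where(complete, labels, None)
    return pd.Categorical(labels, categories=DIAGNOSIS_CATEGORIES)


@dataclass(frozen=True)
class ReliabilityResult:
    """Cronbach's alpha with the dimensions it was computed on."""

    alpha: float
    n_items: int
    n_subjects: int


def cronbach_alpha(item_matrix) -> ReliabilityResult:
    """Internal-consistency reliability of a set of items.

    alpha = k/(k-1) * (1 - sum of item variances / variance of total score),
    with a common (ML, ddof=0) variance denominator throughout.

    Raises
    ------
    ValueError
        If fewer than 2 items or 3 subjects, on missing entries, or when the
        total-score variance is zero (alpha undefined).
    """
    X = np.asarray(item_matrix, dtype=float)
    if X.ndim != 2:
        raise ValueError("item_matrix must be 2-dimensional (subjects x items)")
    n, k = X.shape
    if k < 2:
        raise ValueError("cronbach_alpha needs at least 2 items")
    if n < 3:
        raise ValueError("cronbach_alpha needs at least 3 subjects")
    if np.isnan(X).any():
        raise ValueError("item_matrix contains missing entries")
    total_var = X.sum(axis=1).var(ddof=0)
    if total_var <= 0:
        raise ValueError("total-score variance is zero; alpha undefined")
    item_var = X.var(axis=0, ddof=0).sum()
    alpha = k / (k - 1.0) * (1.0 - item_var / total_var)
    return ReliabilityResult(alpha=float(alpha), n_items=k, n_subjects=n)


class EventClassificationMap:
    """Partition of the 21 checklist events into intentional / unintentional /
    excluded classes.  The default reproduces the adjudicated classification
    of the Italian validation cohort."""

    def __init__(self, classes: Mapping[int, str] | None = None):
        classes = dict(DEFAULT_EVENT_CLASSES if classes is None else classes)
        if set(classes) != set(range(1, N_CHECKLIST_ITEMS + 1)):
            raise ValueError("classification must cover checklist items 1..21 exactly")
        bad = {i: c for i, c in classes.items() if c not in ("intentional", "unintentional", "excluded")}
        if bad:
            raise ValueError(f"unknown event classes: {bad}")
        self.classes = classes

    def items_of(self, cls: str) -> list[int]:
        return sorted(i for i, c in self.classes.items() if c == cls)

    def to_json(self) -> dict:
        return {str(i): c for i, c in sorted(self.classes.items())}

    @classmethod
    def from_json(cls, obj: Mapping) -> "EventClassificationMap":
        return cls({int(k): v for k, v in obj.items()})


def classify_exposures(
    exposure_flags: pd.DataFrame,
    event_map: EventClassificationMap | None = None,
) -> pd.DataFrame:
    """Collapse per-item/per-period checklist flags into class/period indicators.

    Returns a frame with one boolean column per (class, period) plus lifetime
    aggregates, e.g. ``intentional_childhood`` .. ``unintentional_lifetime``
    and ``any_lifetime``.  Excluded events never contribute.
    """
    event_map = event_map or EventClassificationMap()
    out = pd.DataFrame(index=exposure_flags.index)
    for cls in EXPOSURE_CLASSES:
        items = event_map.items_of(cls)
        per_period = []
        for period in PERIODS:
            cols = [exposure_column(i, period) for i in items]
            missing = [c for c in cols if c not in exposure_flags.columns]
            if missing:
                raise ValueError(f"missing exposure columns: {missing[:3]}...")
            ind = exposure_flags[cols].astype(bool).any(axis=1)
            out[f"{cls}_{period}"] = ind
            per_period.append(ind)
        out[f"{cls}_lifetime"] = np.logical_or.reduce(per_period)
    # "any" uses non-excluded items only, consistent with the class indicators
    out["any_lifetime"] = out[["intentional_lifetime", "unintentional_lifetime"]].any(axis=1)
    return out


class ItqScorer(BaseEstimator, TransformerMixin):
    """Score a cohort table: diagnoses, subscale sums and exposure classes.

    A stateless transformer in the scikit-learn sense: ``fit`` validates the
    schema, ``transform`` appends ``diagnosis`` (categorical none/PTSD/cPTSD,
    NA when unscorable), ``ptsd_sum``, ``dso_sum``, and — when exposure flags
    are present — the class/period exposure indicators.

    Parameters
    ----------
    require_exposure : bool, default True
        Gate diagnoses on trauma exposure.  The exposure flag is the
        ``trauma_exposed`` column when present, otherwise derived as any
        endorsement of a non-excluded checklist event.
    event_map : EventClassificationMap, optional
        Checklist-event classification; defaults to the adjudicated map.
    """

    def __init__(self, require_exposure: bool = True, event_map: EventClassificationMap | None = None):
        self.require_exposure = require_exposure
        self.event_map = event_map

    def fit(self, X: pd.DataFrame, y=None):
        missing = [c for c in SYMPTOM_ITEMS + IMPAIRMENT_ITEMS if c not in X.columns]
        if missing:
            raise ValueError(f"cohort table lacks item columns: {missing}")
        self.n_features_in_ = X.shape[1]
        self.columns_ = list(X.columns)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "columns_"):
            self.fit(X)
        out = X.copy()
        has_flags = all(
            exposure_column(i, p) in X.columns for i in (1, 21) for p in PERIODS
        )
        if has_flags:
            classes = classify_exposures(X, self.event_map)
            out = out.join(classes)
        if "trauma_exposed" in X.columns:
            exposed = X["trauma_exposed"].astype(bool)
        elif has_flags:
            exposed = classes["any_lifetime"]
        elif self.require_exposure:
            raise ValueError(
                "no trauma_exposed column and no exposure flags to derive it from"
            )
        else:
            exposed = pd.Series(True, index=X.index)

        out["diagnosis"] = diagnose_table(
            X, exposed, require_exposure=self.require_exposure
        )
        sym = X[list(SYMPTOM_ITEMS)].to_numpy(dtype=float)
        out["ptsd_sum"] = sym[:, :6].sum(axis=1)
        out["dso_sum"] = sym[:, 6:].sum(axis=1)
        return out
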