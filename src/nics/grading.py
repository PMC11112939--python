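"""Random-forest euploidy-probability grading (A/B/C) and transfer ranking.

Grade thresholds: A for p >= 0.94, C for p <= 0.70, B in between (the
two closed inequalities are preserved; the B interval is open).  Within a
grade, ranking is by descending probability, then morphology priority
(high-quality AA/AB/BA/BB blastocysts before AC/BC/CA/CB), then input
order; grade-C embryos are excluded from the transfer list.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from nics.feature_extraction import FEATURE_NAMES, EmbryoFeatures
from nics._util import round_half_up

GRADE_A_MIN = 0.94
GRADE_C_MAX = 0.70

_HIGH_QUALITY = {"AA", "AB", "BA", "BB"}
_USABLE = {"AC", "BC", "CA", "CB"}


@dataclass(frozen=True)
class GradeResult:
    embryo_id: str
    p_euploid: float
    grade: str
    morphology_grade: str | None = None


@dataclass(frozen=True)
class ClassifierModel:
    forest: RandomForestClassifier = field(repr=False)
    metadata: dict = field(default_factory=dict)


def assign_grade(
    p_euploid: float, a_min: float = GRADE_A_MIN, c_max: float = GRADE_C_MAX
) -> str:
    if not 0 <= p_euploid <= 1:
        raise ValueError("p_euploid must be in [0, 1]")
    if not 0 < c_max < a_min < 1:
        raise ValueError("thresholds must satisfy 0 < c_max < a_min < 1")
    if p_euploid >= a_min:
        return "A"
    if p_euploid <= c_max:
        return "C"
    return "B"


def _feature_matrix(features: list[EmbryoFeatures]) -> np.ndarray:
    return np.vstack([f.as_array() for f in features])


def train_classifier(
    features: list[EmbryoFeatures],
    labels: list[bool],
    n_trees: int = 500,
    seed: int | None = 0,
    class_weight: str | None = "balanced",
    max_features: str | int = "sqrt",
    **forest_kwargs,
) -> ClassifierModel:
    """Fit the forest on labeled feature vectors (label True = euploid)."""
    if len(features) != len(labels):
        raise ValueError("features and labels must align")
    y = np.asarray(labels, dtype=bool)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    X = _feature_matrix(features)
    forest = RandomForestClassifier(
        n_estimators=n_trees,
        class_weight=class_weight,
        max_features=max_features,
        oob_score=True,
        random_state=seed,
        n_jobs=1,
        **forest_kwargs,
    )
    forest.fit(X, y)
    meta = {
        "seed": seed,
        "n_trees": n_trees,
        "n_training_embryos": int(len(y)),
        "class_balance": {"euploid": int(y.sum()), "aneuploid": int((~y).sum())},
        "oob_accuracy": float(forest.oob_score_),
        "feature_names": list(FEATURE_NAMES),
    }
    return ClassifierModel(forest=forest, metadata=meta)


def predict_euploid_probability(
    model: ClassifierModel, features: EmbryoFeatures | list[EmbryoFeatures]
) -> float | np.ndarray:
    single = isinstance(features, EmbryoFeatures)
    feats = [features] if single else list(features)
    X = _feature_matrix(feats)
    if X.shape[1] != 11:
        raise ValueError("feature vectors must have 11 entries")
    euploid_col = list(model.forest.classes_).index(True)
    p = model.forest.predict_proba(X)[:, euploid_col]
    return float(p[0]) if single else p


def grade_embryos(
    model: ClassifierModel,
    features: list[EmbryoFeatures],
    morphology: dict[str, str] | None = None,
) -> list[GradeResult]:
    probs = predict_euploid_probability(model, features)
    morphology = morphology or {}
    return [
        GradeResult(
            embryo_id=f.embryo_id,
            p_euploid=float(p),
            grade=assign_grade(float(p)),
            morphology_grade=morphology.get(f.embryo_id),
        )
        for f, p in zip(features, np.atleast_1d(probs))
    ]


def _morphology_priority(morphology_grade: str | None) -> int:
    if not morphology_grade:
        return 2
    suffix = morphology_grade[-2:].upper()
    if suffix in _HIGH_QUALITY:
        return 0
    if suffix in _USABLE:
        return 1
    return 2


def rank_embryos(results: list[GradeResult]) -> list[GradeResult]:
    """Transfer order: A-grades, then B-grades; C excluded.

    Stable sort: within a grade descending p_euploid, ties broken by
    morphology priority, then by input order.
    """
    transferable = [r for r in results if r.grade in ("A", "B")]
    return sorted(
        transferable,
        key=lambda r: (
            0 if r.grade == "A" else 1,
            -r.p_euploid,
            _morphology_priority(r.morphology_grade),
        ),
    )


def cohort_grade_summary(results) -> dict:
    """Per-grade counts and the A+B utilization share (one-decimal %).

    Accepts a list of :class:`GradeResult` or a mapping of per-grade
    counts like ``{"A": 222, "B": 112, "C": 172}``.
    """
    if isinstance(results, dict):
        counts = {g: int(results.get(g, 0)) for g in ("A", "B", "C")}
    else:
        counts = {"A": 0, "B": 0, "C": 0}
        for r in results:
            counts[r.grade] += 1
    total = sum(counts.values())
    ab = counts["A"] + counts["B"]
    utilization = round_half_up(100.0 * ab / total, 1) if total else 0.0
    return {
        "counts": counts,
        "total": total,
        "transferable": ab,
        "utilization_pct": utilization,
    }


# ---------------------------------------------------------------------------
# persistence / reports
# ---------------------------------------------------------------------------


def save_model(model: ClassifierModel, path: str | Path) -> None:
    path = Path(path)
    joblib.dump(model.forest, path)
    with open(path.with_suffix(path.suffix + ".meta.json"), "w") as fh:
        json.dump({"format_version": 1, **model.metadata}, fh, indent=1, sort_keys=True)


def load_model(path: str | Path) -> ClassifierModel:
    path = Path(path)
    forest = joblib.load(path)
    meta_path = path.with_suffix(path.suffix + ".meta.json")
    metadata = {}
    if meta_path.exists():
        with open(meta_path) as fh:
            metadata = json.load(fh)
    return ClassifierModel(forest=forest, metadata=metadata)


def grades_to_frame(results: list[GradeResult]) -> pd.DataFrame:
    ranked = rank_embryos(results)
    rank = {r.embryo_id: i + 1 for i, r in enumerate(ranked)}
    return pd.DataFrame(
        [
            {
                "embryo_id": r.embryo_id,
                "p_euploid": round(r.p_euploid, 6),
                "grade": r.grade,
                "transfer_rank": rank.get(r.embryo_id, 0),
            }
            for r in results
        ]
    )


def write_grades_csv(results: list[GradeResult], path: str | Path) -> None:
    grades_to_frame(results).to_csv(path, index=False)
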