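"""Per-reaction expression scores from a gene-expression matrix.

A gene's score in a condition is its raw value divided by its median
across all conditions in the matrix.  A reaction's score walks the GPR
normal form: max over complexes of min over subunits of max over genes.
Reactions scoring below the threshold (default 0.2, strict) are "low
expression"; reactions with no GPR or no scorable gene are unscored.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .model_core.types import MetabolicModel, ModelValidationError

__all__ = [
    "ExpressionMatrix",
    "ReactionScoreSet",
    "normalize",
    "score_reaction",
    "score_model",
    "classify",
    "score_and_classify",
    "threshold_scan",
    "category_summary",
]

DEFAULT_THRESHOLD = 0.2

CLASS_HIGH = "high"
CLASS_LOW = "low"
CLASS_UNSCORED = "unscored"


@dataclass
class ExpressionMatrix:
    """Genes x conditions matrix of non-negative expression values."""

    data: pd.DataFrame  # index = gene ids, columns = condition labels

    def __post_init__(self) -> None:
        if self.data.columns.duplicated().any():
            raise ModelValidationError("duplicate condition labels")
        if self.data.index.duplicated().any():
            raise ModelValidationError("duplicate gene ids")
        if (self.data.values < 0).any():
            raise ModelValidationError("expression values must be non-negative")

    @property
    def genes(self) -> List[str]:
        return list(self.data.index)

    @property
    def conditions(self) -> List[str]:
        return list(self.data.columns)

    @classmethod
    def from_tsv(cls, path) -> "ExpressionMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
        return cls(df.astype(float))

    def to_tsv(self, path) -> None:
        out = self.data.copy()
        out.index.name = "gene_id"
        out.to_csv(path, sep="\t", float_format="%.6g")


def normalize(matrix: ExpressionMatrix, condition: str) -> Dict[str, float]:
    """Median-normalized gene scores for one condition.

    ``score(g) = value(g, condition) / median over all conditions``.
    Genes whose median is zero are unscorable and omitted.
    """
    if condition not in matrix.data.columns:
        raise KeyError(f"unknown condition {condition!r}")
    med = matrix.data.median(axis=1)
    col = matrix.data[condition]
    ok = med > 0
    return dict(zip(matrix.data.index[ok], (col[ok] / med[ok]).astype(float)))


def score_reaction(gpr, gene_scores: Mapping[str, float]) -> Optional[float]:
    """Expression score of one GPR rule; None when unscorable."""
    if gpr is None:
        return None
    return gpr.score(gene_scores)


def score_model(
    model: MetabolicModel, gene_scores: Mapping[str, float]
) -> Dict[str, Optional[float]]:
    return {
        rid: score_reaction(rxn.gpr, gene_scores)
        for rid, rxn in model.reactions.items()
    }


@dataclass
class ReactionScoreSet:
    """Scores plus the high/low/unscored classification at a threshold."""

    scores: Dict[str, float]  # scored reactions only
    threshold: float = DEFAULT_THRESHOLD
    classes: Dict[str, str] = field(default_factory=dict)

    @property
    def high_ids(self) -> List[str]:
        return [r for r, c in self.classes.items() if c == CLASS_HIGH]

    @property
    def low_ids(self) -> List[str]:
        return [r for r, c in self.classes.items() if c == CLASS_LOW]

    @property
    def unscored_ids(self) -> List[str]:
        return [r for r, c in self.classes.items() if c == CLASS_UNSCORED]

    def to_tsv(self, path) -> None:
        import csv

        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
            writer.writerow(["reaction_id", "score", "class"])
            for rid, cls in self.classes.items():
                s = self.scores.get(rid)
                writer.writerow([rid, "" if s is None else f"{s:.6g}", cls])


def classify(
    model: MetabolicModel,
    scores: Mapping[str, Optional[float]],
    threshold: float = DEFAULT_THRESHOLD,
) -> ReactionScoreSet:
    """Classify every model reaction.

    The boundary is strict: ``score < threshold`` is low, a score equal
    to the threshold is high.
    """
    if threshold <= 0:
        raise ModelValidationError("threshold must be positive")
    kept: Dict[str, float] = {}
    classes: Dict[str, str] = {}
    for rid in model.reactions:
        s = scores.get(rid)
        if s is None:
            classes[rid] = CLASS_UNSCORED
        else:
            kept[rid] = float(s)
            classes[rid] = CLASS_LOW if s < threshold else CLASS_HIGH
    return ReactionScoreSet(scores=kept, threshold=threshold, classes=classes)


def score_and_classify(
    model: MetabolicModel,
    matrix: ExpressionMatrix,
    condition: str,
    threshold: float = DEFAULT_THRESHOLD,
) -> ReactionScoreSet:
    gene_scores = normalize(matrix, condition)
    return classify(model, score_model(model, gene_scores), threshold)


def threshold_scan(
    model: MetabolicModel,
    matrix: ExpressionMatrix,
    conditions: Sequence[str],
    thresholds: Sequence[float],
) -> pd.DataFrame:
    """Fraction of scored reactions meeting each threshold, per condition.

    The denominator is the number of reactions that received a score in
    that condition (gene-associated reactions with at least one scorable
    complex).  Rows are non-increasing left to right.
    """
    thresholds = list(thresholds)
    if any(b <= a for a, b in zip(thresholds, thresholds[1:])):
        raise ModelValidationError("thresholds must be strictly increasing")
    rows = {}
    for cond in conditions:
        gene_scores = normalize(matrix, cond)
        scores = [
            s for s in score_model(model, gene_scores).values() if s is not None
        ]
        n = len(scores)
        arr = np.asarray(scores)
        rows[cond] = [
            float((arr >= t).sum()) / n if n else float("nan") for t in thresholds
        ]
    return pd.DataFrame.from_dict(rows, orient="index", columns=thresholds)


def category_summary(
    score_set: ReactionScoreSet, category_map: Mapping[str, str]
) -> pd.DataFrame:
    """Score distributions per pathway category.

    Columns: n, n_zero, min, q1, median, q3, max.  Categories with no
    scored reaction get n=0 and NaN statistics.
    """
    cats: Dict[str, List[float]] = {}
    for rid, cat in category_map.items():
        cats.setdefault(cat, [])
        if rid in score_set.scores:
            cats[cat].append(score_set.scores[rid])
    records = {}
    for cat in sorted(cats):
        vals = np.asarray(cats[cat], dtype=float)
        if vals.size == 0:
            records[cat] = dict(
                n=0, n_zero=0, min=np.nan, q1=np.nan, median=np.nan,
                q3=np.nan, max=np.nan,
            )
            continue
        q1, med, q3 = np.percentile(vals, [25, 50, 75])
        records[cat] = dict(
            n=int(vals.size),
            n_zero=int((vals == 0).sum()),
            min=float(vals.min()),
            q1=float(q1),
            median=float(med),
            q3=float(q3),
            max=float(vals.max()),
        )
    return pd.DataFrame.from_dict(records, orient="index")
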