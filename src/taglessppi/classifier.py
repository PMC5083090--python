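"""Logistic-regression PPI classification with one-operon-out cross-validation.

Two logistic regressions are supported: MS-only (the five co-fractionation
features) and MS+STRING (all eight).  Because interacting pairs that share a
protein — and, in bacteria, an operon — are not independent observations,
cross-validation holds out one operon at a time: every candidate pair that
touches any protein of the held-out operon is scored by a model trained only
on gold pairs touching none of them.

Predictions are thresholded at a target false discovery rate estimated from
the gold-standard labels: at threshold t, FDR(t) = negatives>=t /
(positives>=t + negatives>=t).  The estimator is the plain gold-count ratio;
it is calibrated to the candidate universe only insofar as the gold pairs
are representative of candidates (see docs/methods.md).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
from sklearn.linear_model import LogisticRegression

from .features import ALL_FEATURES, MS_FEATURES, PairFeatures
from .iodata import PairKey

logger = logging.getLogger(__name__)

MODEL_KINDS = {"MS_ONLY": MS_FEATURES, "MS_STRING": ALL_FEATURES}

#: L2 regularization strength (sklearn C); light, fixed for determinism.
DEFAULT_C = 10.0


@dataclass(frozen=True)
class GoldStandard:
    """Labeled positive/negative pair sets with operon annotations."""

    positives: frozenset[PairKey]
    negatives: frozenset[PairKey]
    operon_map: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.positives & self.negatives:
            raise ValueError("gold positives and negatives overlap")

    def operon_of(self, protein_id: str) -> str:
        """Singleton proteins without annotation form one-protein operons."""
        return self.operon_map.get(protein_id, protein_id)

    def label(self, pair: PairKey) -> int | None:
        if pair in self.positives:
            return 1
        if pair in self.negatives:
            return 0
        return None

    def restricted_to(self, proteins: set[str]) -> "GoldStandard":
        """Keep only gold pairs whose both members are in ``proteins``."""
        keep = lambda s: frozenset(p for p in s if p.a in proteins and p.b in proteins)
        return GoldStandard(keep(self.positives), keep(self.negatives), self.operon_map)


@dataclass(frozen=True)
class Fold:
    operon_id: str
    train_pairs: frozenset[PairKey]       # gold pairs only
    validation_pairs: frozenset[PairKey]  # all candidate pairs touching the operon


@dataclass
class LogisticModel:
    """Standardized logistic regression with plain-text persistence."""

    feature_names: tuple[str, ...]
    coef: np.ndarray
    intercept: float
    mean: np.ndarray
    scale: np.ndarray

    def score(self, X: np.ndarray) -> np.ndarray:
        z = (X - self.mean) / self.scale
        logit = z @ self.coef + self.intercept
        return 1.0 / (1.0 + np.exp(-logit))

    def save(self, path: str | Path) -> None:
        lines = [f"features={','.join(self.feature_names)}",
                 f"intercept={float(self.intercept)!r}"]
        for name, c, m, s in zip(self.feature_names, self.coef, self.mean, self.scale):
            lines.append(f"coef.{name}={float(c)!r}")
            lines.append(f"mean.{name}={float(m)!r}")
            lines.append(f"scale.{name}={float(s)!r}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "LogisticModel":
        kv = {}
        for line in Path(path).read_text().splitlines():
            if line.strip():
                k, _, v = line.partition("=")
                kv[k] = v
        names = tuple(kv["features"].split(","))
        return cls(
            feature_names=names,
            coef=np.array([float(kv[f"coef.{n}"]) for n in names]),
            intercept=float(kv["intercept"]),
            mean=np.array([float(kv[f"mean.{n}"]) for n in names]),
            scale=np.array([float(kv[f"scale.{n}"]) for n in names]),
        )


@dataclass
class PredictionSet:
    """Cross-validated scores thresholded at a target FDR."""

    scores: dict[PairKey, float]
    threshold: float
    predicted: list[PairKey]            # score >= threshold, descending
    fdr_estimate: float | None
    model_kind: str
    fold_ids: dict[PairKey, tuple[str, ...]] = field(default_factory=dict)

    def write_tsv(self, path: str | Path) -> None:
        import pandas as pd

        pred = set(self.predicted)
        rows = sorted(
            self.scores.items(), key=lambda kv: (-kv[1], kv[0].a, kv[0].b)
        )
        pd.DataFrame(
            [
                (pk.a, pk.b, repr(s), int(pk in pred),
                 ";".join(self.fold_ids.get(pk, ())))
                for pk, s in rows
            ],
            columns=["protein_a", "protein_b", "score", "predicted", "fold_id"],
        ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Folds
# ---------------------------------------------------------------------------

def one_operon_out_folds(
    gold: GoldStandard, candidate_pairs: Iterable[PairKey]
) -> list[Fold]:
    """One fold per operon touched by any candidate or gold pair.

    A fold validates every candidate pair touching any protein of its operon
    and trains on gold pairs touching none of them.  A pair spanning two
    operons is validated in both folds and trains in neither.
    """
    candidates = set(candidate_pairs)
    if not gold.operon_map and not candidates and not gold.positives:
        raise ValueError("empty operon map and no pairs to fold")
    proteins = {p for pk in candidates for p in pk}
    proteins |= {p for pk in gold.positives | gold.negatives for p in pk}

    operons: dict[str, set[str]] = {}
    for p in proteins:
        operons.setdefault(gold.operon_of(p), set()).add(p)

    gold_pairs = gold.positives | gold.negatives
    folds = []
    for oid in sorted(operons):
        members = frozenset(operons[oid])
        val = frozenset(pk for pk in candidates if pk.touches(members))
        if not val:
            continue
        train = frozenset(pk for pk in gold_pairs if not pk.touches(members))
        folds.append(Fold(operon_id=oid, train_pairs=train, validation_pairs=val))
    return folds


# ---------------------------------------------------------------------------
# Fitting and scoring
# ---------------------------------------------------------------------------

def _design_matrix(
    features: Mapping[PairKey, PairFeatures],
    pairs: Sequence[PairKey],
    names: tuple[str, ...],
) -> np.ndarray:
    return np.array([features[pk].as_tuple(names) for pk in pairs])


def fit_logistic(
    features: Iterable[PairFeatures] | Mapping[PairKey, PairFeatures],
    gold: GoldStandard,
    model_kind: str = "MS_STRING",
    C: float = DEFAULT_C,
    train_pairs: Iterable[PairKey] | None = None,
) -> LogisticModel:
    """Fit a standardized logistic regression on gold-labeled feature rows.

    Features are z-scaled with statistics from the training rows only;
    sentinel feature values participate as ordinary numbers.  Deterministic
    for fixed inputs (lbfgs, fixed L2 strength).
    """
    names = MODEL_KINDS[model_kind]
    fmap = _feature_map(features)
    if train_pairs is None:
        train_pairs = gold.positives | gold.negatives
    pairs = sorted(pk for pk in train_pairs if pk in fmap)
    y = np.array([gold.label(pk) for pk in pairs], dtype=float)
    if len(pairs) == 0 or len(np.unique(y)) < 2:
        raise ValueError("training set must contain both gold classes")
    X = _design_matrix(fmap, pairs, names)
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale[scale == 0.0] = 1.0
    Z = (X - mean) / scale
    lr = LogisticRegression(C=C, solver="lbfgs", max_iter=2000)
    lr.fit(Z, y)
    return LogisticModel(
        feature_names=names,
        coef=lr.coef_.ravel().copy(),
        intercept=float(lr.intercept_[0]),
        mean=mean,
        scale=scale,
    )


def cross_validate_scores(
    features: Iterable[PairFeatures] | Mapping[PairKey, PairFeatures],
    gold: GoldStandard,
    model_kind: str = "MS_STRING",
    C: float = DEFAULT_C,
) -> tuple[dict[PairKey, float], dict[PairKey, tuple[str, ...]]]:
    """Held-out scores for every candidate pair under one-operon-out CV.

    Implements the same folds as :func:`one_operon_out_folds` with indexed
    bookkeeping so whole-experiment candidate tables are feasible.  A pair
    validated in several folds (it spans two operons) gets the mean of its
    held-out scores.  Folds whose training set collapses to one class are
    skipped with a warning; pairs never scored in any usable fold are
    excluded from the result (logged).
    """
    fmap = _feature_map(features)
    names = MODEL_KINDS[model_kind]
    cand = sorted(fmap)
    if not cand:
        return {}, {}
    X_cand = np.array([fmap[pk].as_tuple(names) for pk in cand])

    gold_pairs = sorted(pk for pk in gold.positives | gold.negatives if pk in fmap)
    X_gold = np.array([fmap[pk].as_tuple(names) for pk in gold_pairs])
    y_gold = np.array([gold.label(pk) for pk in gold_pairs], dtype=float)

    # operon -> candidate (validation) and gold (excluded-from-training) indices
    val_of: dict[str, list[int]] = {}
    for i, pk in enumerate(cand):
        oa, ob = gold.operon_of(pk.a), gold.operon_of(pk.b)
        val_of.setdefault(oa, []).append(i)
        if ob != oa:
            val_of.setdefault(ob, []).append(i)
    gold_touch: dict[str, list[int]] = {}
    for i, pk in enumerate(gold_pairs):
        for oid in {gold.operon_of(pk.a), gold.operon_of(pk.b)}:
            gold_touch.setdefault(oid, []).append(i)

    sums = np.zeros(len(cand))
    counts = np.zeros(len(cand), dtype=int)
    fold_ids: dict[int, list[str]] = {}
    for oid in sorted(val_of):
        val_idx = np.array(val_of[oid])
        train_mask = np.ones(len(gold_pairs), dtype=bool)
        train_mask[gold_touch.get(oid, [])] = False
        y = y_gold[train_mask]
        if y.size == 0 or y.min() == y.max():
            logger.warning("fold %s skipped: single-class training set", oid)
            continue
        X = X_gold[train_mask]
        mean = X.mean(axis=0)
        scale = X.std(axis=0)
        scale[scale == 0.0] = 1.0
        lr = LogisticRegression(C=C, solver="lbfgs", max_iter=2000)
        lr.fit((X - mean) / scale, y)
        s = lr.predict_proba((X_cand[val_idx] - mean) / scale)[:, 1]
        sums[val_idx] += s
        counts[val_idx] += 1
        for i in val_idx:
            fold_ids.setdefault(int(i), []).append(oid)

    unscored = int((counts == 0).sum())
    if unscored:
        logger.info("%d candidate pairs never held out; excluded", unscored)
    scores = {
        cand[i]: float(sums[i] / counts[i]) for i in range(len(cand)) if counts[i]
    }
    folds_out = {cand[i]: tuple(v) for i, v in fold_ids.items()}
    return scores, folds_out


# ---------------------------------------------------------------------------
# FDR machinery
# ---------------------------------------------------------------------------

def fdr_at_threshold(
    scores: Mapping[PairKey, float], gold: GoldStandard, t: float
) -> float | None:
    """Gold-count FDR estimate at threshold t: neg>=t / (pos>=t + neg>=t).

    ``None`` (not estimable) when no gold pair scores >= t."""
    npos = sum(1 for pk in gold.positives if scores.get(pk, -np.inf) >= t)
    nneg = sum(1 for pk in gold.negatives if scores.get(pk, -np.inf) >= t)
    if npos + nneg == 0:
        return None
    return nneg / (npos + nneg)


def threshold_for_fdr(
    scores: Mapping[PairKey, float],
    gold: GoldStandard,
    target: float = 0.20,
    model_kind: str = "MS_STRING",
    fold_ids: Mapping[PairKey, tuple[str, ...]] | None = None,
) -> PredictionSet:
    """Lowest threshold whose gold-count FDR estimate is <= target.

    Thresholds sweep the distinct observed scores (inclusive >=, so ties at
    the threshold are all predicted).  When no threshold attains the target
    an empty prediction set is returned with a warning.
    """
    distinct = np.array(sorted(set(scores.values())))
    pos_scores = np.sort([scores[pk] for pk in gold.positives if pk in scores])
    neg_scores = np.sort([scores[pk] for pk in gold.negatives if pk in scores])
    # gold counts >= t for every distinct threshold, via sorted-array search
    npos = len(pos_scores) - np.searchsorted(pos_scores, distinct, side="left")
    nneg = len(neg_scores) - np.searchsorted(neg_scores, distinct, side="left")
    total = npos + nneg
    best_t = None
    best_fdr = None
    with np.errstate(invalid="ignore", divide="ignore"):
        fdr = np.where(total > 0, nneg / np.maximum(total, 1), np.nan)
    admissible = np.nonzero((total > 0) & (fdr <= target))[0]
    if admissible.size:  # ascending scan: first admissible t is the lowest
        k = int(admissible[0])
        best_t, best_fdr = float(distinct[k]), float(fdr[k])
    if best_t is None:
        logger.warning("target FDR %.3f unreachable; empty prediction set", target)
        return PredictionSet(
            scores=dict(scores), threshold=np.inf, predicted=[],
            fdr_estimate=None, model_kind=model_kind,
            fold_ids=dict(fold_ids or {}),
        )
    predicted = sorted(
        (pk for pk, s in scores.items() if s >= best_t),
        key=lambda pk: (-scores[pk], pk.a, pk.b),
    )
    return PredictionSet(
        scores=dict(scores), threshold=best_t, predicted=predicted,
        fdr_estimate=best_fdr, model_kind=model_kind,
        fold_ids=dict(fold_ids or {}),
    )


def select_high_confidence(
    predictions: PredictionSet,
    metrics_provider: Callable[[list[PairKey]], Mapping[str, float]] | None,
    score_cut: float,
) -> tuple[list[PairKey], dict[str, Mapping[str, float]]]:
    """Top-scoring subset with score >= score_cut, plus a kept/discarded
    quality-metric report (the high- vs low-confidence split)."""
    kept = [pk for pk in predictions.predicted if predictions.scores[pk] >= score_cut]
    discarded = [pk for pk in predictions.predicted if predictions.scores[pk] < score_cut]
    report: dict[str, Mapping[str, float]] = {}
    if metrics_provider is not None:
        report["kept"] = metrics_provider(kept)
        report["discarded"] = metrics_provider(discarded)
    return kept, report


def _feature_map(
    features: Iterable[PairFeatures] | Mapping[PairKey, PairFeatures]
) -> dict[PairKey, PairFeatures]:
    if isinstance(features, Mapping):
        return dict(features)
    return {f.pair: f for f in features}
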