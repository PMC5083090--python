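"""Interactome audit statistics.

Given a co-fractionation experiment and one or more interactomes (pair
sets), this module computes the statistics used to cross-validate them:

* **PPI fold enrichment** — how much more often a pair set co-elutes tightly
  (CC >= 0.85 in both SEC and HIC) than co-occurring pairs at large.
* **False negative rate** — 1 - recovered/eligible, for pairs of a reference
  interactome whose proteins were detected by the assay.
* **Overlap accounting** — union/intersection bookkeeping between two
  interactomes, with conditional overlaps restricted to pairs detectable by
  the other assay (the quantity that should approximate 1 - FNR).
* **Held-out FDR** — re-estimating an interactome's FDR from gold-standard
  pairs that were not used to train it.
* **Overlap-enrichment accuracy bound** — if gold pairs overlap an
  independent reference k-fold more often than novel pairs do, the novel
  pairs are at most 100/k % accurate even when the gold pairs are perfect.
* **Quality metrics** — same-operon percentage, functional-annotation
  (TIGR role) sharing enrichment, and percent overlap with reference sets.

Percentages are reported at full precision; ``round`` to integer percent for
display only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .features import FeatureConfig, PairFeatures
from .iodata import ElutionDataset, PairKey

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PairSet:
    """A named interactome: a set of unordered protein pairs."""

    name: str
    pairs: frozenset[PairKey]

    def __len__(self) -> int:
        return len(self.pairs)

    @classmethod
    def from_pairs(cls, name: str, pairs: Iterable[PairKey]) -> "PairSet":
        return cls(name=name, pairs=frozenset(pairs))

    @classmethod
    def from_tsv(cls, path: str | Path, name: str | None = None) -> "PairSet":
        from .iodata import read_pair_list

        pairs = frozenset(pk for pk, _ in read_pair_list(path))
        return cls(name=name or Path(path).stem, pairs=pairs)

    def to_tsv(self, path: str | Path) -> None:
        from .iodata import write_pair_list

        write_pair_list(self.pairs, path)

    def restricted_to(self, proteins: set[str]) -> frozenset[PairKey]:
        return frozenset(
            pk for pk in self.pairs if pk.a in proteins and pk.b in proteins
        )


@dataclass(frozen=True)
class EnrichmentResult:
    set_name: str
    frac_high_cc: float
    reference_frac: float
    fold_enrichment: float
    n_detected_pairs: int
    n_high_cc_pairs: int


@dataclass(frozen=True)
class OverlapReport:
    n_a: int
    n_b: int
    n_shared: int
    union_size: int
    only_a: int
    only_b: int
    #: fraction of a's pairs detectable by assay b that are found in b, and v.v.
    frac_a_in_b_detected: float | None
    frac_b_in_a_detected: float | None
    n_a_detected_in_b: int
    n_b_detected_in_a: int


# ---------------------------------------------------------------------------
# Fold enrichment
# ---------------------------------------------------------------------------

def high_cc_fraction(
    pairs: Iterable[PairKey],
    features: Mapping[PairKey, PairFeatures],
    detected: set[str],
    cc_threshold: float,
) -> tuple[float, int, int]:
    """Fraction of the given pairs, among those with both members detected,
    that co-elute with CC >= threshold in both dimensions."""
    eligible = [pk for pk in pairs if pk.a in detected and pk.b in detected]
    if not eligible:
        return float("nan"), 0, 0
    high = sum(
        1
        for pk in eligible
        if pk in features
        and features[pk].cc_sec >= cc_threshold
        and features[pk].cc_hic >= cc_threshold
    )
    return high / len(eligible), len(eligible), high


def ppi_fold_enrichment(
    query: PairSet,
    dataset: ElutionDataset,
    features: Iterable[PairFeatures] | Mapping[PairKey, PairFeatures],
    cc_threshold: float = FeatureConfig().cc_threshold,
) -> EnrichmentResult:
    """Tight-co-elution enrichment of a pair set over all co-occurring pairs.

    Both the query fraction and the reference fraction are "pairs with
    CC >= threshold in both dimensions, among the set's pairs whose members
    are both detected"; the reference set is the set of all co-occurring
    pairs, so that set itself scores a fold enrichment of exactly 1.
    Returns NaN fold enrichment (not estimable) when the reference fraction
    is zero or the query has no detected pairs.
    """
    fmap = features if isinstance(features, Mapping) else {f.pair: f for f in features}
    detected = dataset.detected_proteins
    q_frac, n_det, n_high = high_cc_fraction(query.pairs, fmap, detected, cc_threshold)
    ref_frac, _, _ = high_cc_fraction(fmap.keys(), fmap, detected, cc_threshold)
    if not np.isfinite(q_frac) or not np.isfinite(ref_frac) or ref_frac == 0.0:
        logger.warning("fold enrichment for %s not estimable", query.name)
        fold = float("nan")
    else:
        fold = q_frac / ref_frac
    return EnrichmentResult(
        set_name=query.name,
        frac_high_cc=q_frac,
        reference_frac=ref_frac,
        fold_enrichment=fold,
        n_detected_pairs=n_det,
        n_high_cc_pairs=n_high,
    )


# ---------------------------------------------------------------------------
# FNR / overlap arithmetic
# ---------------------------------------------------------------------------

def estimate_fnr(recovered: int, eligible: int) -> float:
    """False negative rate, percent: 100 * (1 - recovered/eligible)."""
    if eligible <= 0:
        raise ValueError("eligible count must be positive")
    if not 0 <= recovered <= eligible:
        raise ValueError("recovered must lie in [0, eligible]")
    return 100.0 * (1.0 - recovered / eligible)


def overlap_report(
    a: PairSet,
    b: PairSet,
    detected_in_a: set[str] | None = None,
    detected_in_b: set[str] | None = None,
) -> OverlapReport:
    """Union/intersection accounting for two interactomes.

    The conditional fractions restrict each set to pairs whose both proteins
    were detected by the *other* assay — the denominator under which the
    overlap should approach 1 - FNR of the other assay.
    """
    if not a.pairs or not b.pairs:
        raise ValueError("pair sets must be nonempty")
    shared = a.pairs & b.pairs
    rep = {
        "n_a": len(a.pairs),
        "n_b": len(b.pairs),
        "n_shared": len(shared),
        "union_size": len(a.pairs | b.pairs),
        "only_a": len(a.pairs - b.pairs),
        "only_b": len(b.pairs - a.pairs),
    }
    a_in_b = a.restricted_to(detected_in_b) if detected_in_b is not None else a.pairs
    b_in_a = b.restricted_to(detected_in_a) if detected_in_a is not None else b.pairs
    return OverlapReport(
        **rep,
        frac_a_in_b_detected=(len(shared & a_in_b) / len(a_in_b)) if a_in_b else None,
        frac_b_in_a_detected=(len(shared & b_in_a) / len(b_in_a)) if b_in_a else None,
        n_a_detected_in_b=len(a_in_b),
        n_b_detected_in_a=len(b_in_a),
    )


def heldout_fdr(
    predicted: PairSet, heldout_positives: PairSet, heldout_negatives: PairSet
) -> float | None:
    """FDR (percent) of a prediction set against held-out gold pairs.

    ``None`` (not estimable) when the prediction set contains no held-out
    gold pair of either class."""
    if heldout_positives.pairs & heldout_negatives.pairs:
        raise ValueError("held-out positive and negative sets overlap")
    npos = len(predicted.pairs & heldout_positives.pairs)
    nneg = len(predicted.pairs & heldout_negatives.pairs)
    if npos + nneg == 0:
        return None
    return 100.0 * nneg / (npos + nneg)


def fdr_from_counts(n_positive: int, n_negative: int) -> float:
    """FDR (percent) from gold counts above a threshold."""
    if n_positive + n_negative == 0:
        raise ValueError("no gold pairs above threshold")
    return 100.0 * n_negative / (n_positive + n_negative)


def overlap_enrichment_bound(
    gold_overlap_rate: float, novel_overlap_rate: float
) -> tuple[float, float]:
    """(implied max accuracy %, implied min FDR %) of a novel pair set.

    If pairs from the gold-standard positives overlap an independent
    reference at rate g while novel pairs overlap at rate v, and gold pairs
    are taken as 100% accurate, the novel set is at most 100*v/g percent
    accurate, hence at least 100 - that FDR."""
    if gold_overlap_rate <= 0:
        raise ValueError("gold overlap rate must be positive")
    if novel_overlap_rate < 0:
        raise ValueError("novel overlap rate must be non-negative")
    accuracy = 100.0 * novel_overlap_rate / gold_overlap_rate
    return accuracy, 100.0 - accuracy


# ---------------------------------------------------------------------------
# Quality metrics
# ---------------------------------------------------------------------------

def same_operon_percent(
    pairs: Iterable[PairKey], operon_map: Mapping[str, str]
) -> float:
    """Percent of pairs whose members are encoded in the same operon."""
    pairs = list(pairs)
    if not pairs:
        return float("nan")
    same = sum(
        1
        for pk in pairs
        if operon_map.get(pk.a) is not None
        and operon_map.get(pk.a) == operon_map.get(pk.b)
    )
    return 100.0 * same / len(pairs)


def role_sharing_enrichment(
    pairs: Iterable[PairKey],
    role_map: Mapping[str, str],
    universe: Iterable[str],
    rng: np.random.Generator | None = None,
    n_permutations: int = 0,
) -> float | tuple[float, tuple[float, float]]:
    """Fold enrichment of pairs sharing a functional (TIGR role) annotation.

    The null expectation is the probability that two distinct proteins drawn
    from the annotated universe share a role: sum_r C(n_r, 2) / C(n, 2).
    With ``n_permutations`` > 0, role labels are shuffled across the universe
    and the (2.5, 97.5) percentile interval of the permuted enrichments is
    returned alongside the observed value.
    """
    pairs = list(pairs)
    universe = sorted(set(universe))
    roles = [role_map[p] for p in universe if role_map.get(p) is not None]
    n = len(roles)
    if n < 2 or not pairs:
        return float("nan")
    _, counts = np.unique(roles, return_counts=True)
    expected = float((counts * (counts - 1)).sum() / (n * (n - 1)))
    if expected == 0.0:
        return float("nan")

    def observed_frac(rm: Mapping[str, str]) -> float:
        annotated = [
            pk for pk in pairs if rm.get(pk.a) is not None and rm.get(pk.b) is not None
        ]
        if not annotated:
            return float("nan")
        return sum(1 for pk in annotated if rm[pk.a] == rm[pk.b]) / len(annotated)

    enrich = observed_frac(role_map) / expected
    if n_permutations <= 0:
        return enrich
    rng = rng or np.random.default_rng()
    annotated_universe = [p for p in universe if role_map.get(p) is not None]
    labels = [role_map[p] for p in annotated_universe]
    perm_vals = []
    for _ in range(n_permutations):
        shuffled = dict(zip(annotated_universe, rng.permutation(labels)))
        perm_vals.append(observed_frac(shuffled) / expected)
    lo, hi = np.nanpercentile(perm_vals, [2.5, 97.5])
    return enrich, (float(lo), float(hi))


def quality_metrics(
    query: PairSet,
    operon_map: Mapping[str, str],
    role_map: Mapping[str, str],
    reference_sets: Sequence[PairSet] = (),
    universe: Iterable[str] | None = None,
) -> dict[str, float]:
    """Quality-metric record for one pair set.

    Keys: ``same_operon_pct``, ``role_enrichment``, and
    ``overlap_<ref name>_pct`` (percent of the query's pairs present in each
    reference set)."""
    prots = universe if universe is not None else {p for pk in query.pairs for p in pk}
    out: dict[str, float] = {
        "n_pairs": float(len(query.pairs)),
        "same_operon_pct": same_operon_percent(query.pairs, operon_map),
        "role_enrichment": role_sharing_enrichment(query.pairs, role_map, prots),
    }
    for ref in reference_sets:
        frac = (
            100.0 * len(query.pairs & ref.pairs) / len(query.pairs)
            if query.pairs
            else float("nan")
        )
        out[f"overlap_{ref.name}_pct"] = frac
    return out


def all_detected_pairs(detected: set[str]) -> set[PairKey]:
    """All C(n, 2) pairs over a detected-protein universe (small n only)."""
    return {PairKey(a, b) for a, b in combinations(sorted(detected), 2)}
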