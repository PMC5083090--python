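"""Per-pair features separating bona fide PPIs from fortuitous co-eluters.

Eight features are computed for every co-occurring protein pair.  Five come
from the co-fractionation MS data itself:

1. ``cc_sec`` — maximal Pearson correlation (CC) of the pair's normalized
   elution profiles over multiplexes in the SEC dimension; -1 when the pair
   never shares an eligible SEC multiplex.
2. ``cc_hic`` — same over the HIC dimension.
3. ``dice`` — co-migration coefficient: the number of multiplexes in which
   the two proteins are observed together divided by the sum of each
   protein's individual observances over all multiplexes (range [0, 0.5]).
   Penalizes "frequent fliers" that show up everywhere.
4. ``peptide_ratio`` — per shared multiplex, each protein's unique-peptide
   count relative to its own maximum across all multiplexes; the pair gets
   the smaller of the two ratios, maximized over shared multiplexes.
5. ``min_proteins`` — over multiplexes where the pair co-elutes with
   CC >= 0.85, the protein count of the sparsest such multiplex; dense
   regions of fraction space generate correlated pairs by chance.

Three genome-context features (``string_neighborhood``,
``string_cooccurrence``, ``string_fusion``) are ingested from a STRING-style
subscore table, defaulting to 0 for unlisted pairs.

A pair's CC within one multiplex is only computed when the raw iTRAQ
intensity of at least one of the two proteins is >= `eligibility_intensity`
in >= `eligibility_fractions` fractions of that multiplex; otherwise the
multiplex is skipped for that pair.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .iodata import ElutionDataset, PairKey

logger = logging.getLogger(__name__)

MS_FEATURES = ("cc_sec", "cc_hic", "dice", "peptide_ratio", "min_proteins")
STRING_FEATURES = ("string_neighborhood", "string_cooccurrence", "string_fusion")
ALL_FEATURES = MS_FEATURES + STRING_FEATURES


@dataclass(frozen=True)
class FeatureConfig:
    """Thresholds governing feature computation.

    eligibility_intensity / eligibility_fractions: a multiplex contributes a
    CC for a pair only if at least one of the two proteins has raw intensity
    >= `eligibility_intensity` in >= `eligibility_fractions` of its
    fractions.  cc_threshold: the "tight co-elution" cutoff used by
    ``min_proteins`` (and by the validation module's fold enrichment).
    classic_dice: use the textbook Dice coefficient 2T/(Na+Nb) instead of
    the as-defined T/(Na+Nb); the monotone classifier is insensitive to the
    constant factor.
    """

    eligibility_intensity: float = 0.01
    eligibility_fractions: int = 3
    cc_threshold: float = 0.85
    classic_dice: bool = False


@dataclass(frozen=True)
class PairFeatures:
    pair: PairKey
    cc_sec: float
    cc_hic: float
    dice: float
    peptide_ratio: float
    min_proteins: int
    string_neighborhood: float = 0.0
    string_cooccurrence: float = 0.0
    string_fusion: float = 0.0

    def as_tuple(self, names: tuple[str, ...] = ALL_FEATURES) -> tuple[float, ...]:
        return tuple(float(getattr(self, n)) for n in names)


class GenomeContextTable:
    """PairKey -> (neighborhood, cooccurrence, fusion) scores in [0, 1].

    Pairs without an entry score (0, 0, 0)."""

    def __init__(self, scores: Mapping[PairKey, tuple[float, float, float]] | None = None):
        self._scores: dict[PairKey, tuple[float, float, float]] = {}
        for pk, triple in (scores or {}).items():
            self[pk] = triple

    def __setitem__(self, pair: PairKey, triple: Iterable[float]) -> None:
        t = tuple(float(x) for x in triple)
        if len(t) != 3 or any(not (0.0 <= x <= 1.0) for x in t):
            raise ValueError(f"context scores for {pair} must be 3 values in [0,1]")
        self._scores[pair] = t  # type: ignore[assignment]

    def get(self, pair: PairKey) -> tuple[float, float, float]:
        return self._scores.get(pair, (0.0, 0.0, 0.0))

    def __len__(self) -> int:
        return len(self._scores)

    def __contains__(self, pair: PairKey) -> bool:
        return pair in self._scores

    def items(self):
        return self._scores.items()

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GenomeContextTable":
        df = pd.read_csv(path, sep="\t")
        table = cls()
        for row in df.itertuples(index=False):
            table[PairKey(str(row.protein_a), str(row.protein_b))] = (
                row.neighborhood, row.cooccurrence, row.fusion,
            )
        return table

    def to_tsv(self, path: str | Path) -> None:
        rows = [
            (pk.a, pk.b, n, c, f) for pk, (n, c, f) in sorted(self._scores.items())
        ]
        pd.DataFrame(
            rows,
            columns=["protein_a", "protein_b", "neighborhood", "cooccurrence", "fusion"],
        ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Per-pair operations
# ---------------------------------------------------------------------------

def multiplex_eligible(
    dataset: ElutionDataset,
    pair: PairKey,
    multiplex_id: str,
    config: FeatureConfig = FeatureConfig(),
) -> bool:
    """Both proteins detected and raw-intensity eligibility satisfied."""
    if not (dataset.detected(pair.a, multiplex_id) and dataset.detected(pair.b, multiplex_id)):
        return False
    for pid in pair:
        raw = dataset.raw_vector(pid, multiplex_id)
        if int(np.sum(raw >= config.eligibility_intensity)) >= config.eligibility_fractions:
            return True
    return False


def multiplex_cc(
    dataset: ElutionDataset,
    pair: PairKey,
    multiplex_id: str,
    config: FeatureConfig = FeatureConfig(),
) -> float | None:
    """Pearson CC of the pair's normalized profiles in one multiplex.

    Returns ``None`` (multiplex skipped) when the eligibility rule fails or
    either profile has zero variance (Pearson undefined)."""
    if not multiplex_eligible(dataset, pair, multiplex_id, config):
        return None
    x = dataset.abundance[(pair.a, multiplex_id)]
    y = dataset.abundance[(pair.b, multiplex_id)]
    sx, sy = float(np.std(x)), float(np.std(y))
    if sx == 0.0 or sy == 0.0:
        logger.debug("constant profile for %s in %s; CC undefined", pair, multiplex_id)
        return None
    return float(np.corrcoef(x, y)[0, 1])


def max_cc(
    dataset: ElutionDataset,
    pair: PairKey,
    dimension: str,
    config: FeatureConfig = FeatureConfig(),
) -> float:
    """Maximal per-multiplex CC over one dimension; -1 when the pair shares
    no eligible multiplex of that dimension."""
    best = None
    for mid, m in dataset.multiplexes.items():
        if m.dimension != dimension:
            continue
        cc = multiplex_cc(dataset, pair, mid, config)
        if cc is not None and (best is None or cc > best):
            best = cc
    return best if best is not None else -1.0


def observance_count(dataset: ElutionDataset, protein_id: str) -> int:
    """Number of multiplexes (both dimensions) in which a protein is detected.

    Joint fractions appear in two multiplexes and count once per multiplex:
    the multiplex is the unit of observation."""
    return len(dataset.multiplexes_of(protein_id))


def dice_coefficient(
    dataset: ElutionDataset,
    pair: PairKey,
    config: FeatureConfig = FeatureConfig(),
) -> float:
    """Co-migration coefficient: together / (observances_a + observances_b)."""
    count_a = observance_count(dataset, pair.a)
    count_b = observance_count(dataset, pair.b)
    if count_a == 0 or count_b == 0:
        raise ValueError(f"{pair}: protein with zero observances")
    together = len(set(dataset.multiplexes_of(pair.a)) & set(dataset.multiplexes_of(pair.b)))
    factor = 2.0 if config.classic_dice else 1.0
    return factor * together / (count_a + count_b)


def peptide_ratio(dataset: ElutionDataset, pair: PairKey) -> float:
    """Max over shared multiplexes of the pair's smaller relative peptide count.

    Each protein's count in a multiplex is divided by its maximum count over
    all multiplexes; 0.0 (sentinel) when the pair shares no multiplex."""
    max_a = max((dataset.peptides[(pair.a, m)] for m in dataset.multiplexes_of(pair.a)), default=0)
    max_b = max((dataset.peptides[(pair.b, m)] for m in dataset.multiplexes_of(pair.b)), default=0)
    shared = set(dataset.multiplexes_of(pair.a)) & set(dataset.multiplexes_of(pair.b))
    best = 0.0
    for mid in shared:
        ra = dataset.peptides[(pair.a, mid)] / max_a
        rb = dataset.peptides[(pair.b, mid)] / max_b
        best = max(best, min(ra, rb))
    return best


def min_proteins_sentinel(dataset: ElutionDataset) -> int:
    """Worst-possible multiplex density: max detected count over multiplexes + 1."""
    return max((len(dataset.proteins_in(m)) for m in dataset.multiplexes), default=0) + 1


def min_proteins(
    dataset: ElutionDataset,
    pair: PairKey,
    cc_threshold: float | None = None,
    config: FeatureConfig = FeatureConfig(),
) -> int:
    """Protein count of the sparsest multiplex where the pair's CC >= threshold.

    Sentinel (densest multiplex + 1) when no multiplex qualifies, so "never
    tightly co-eluting" reads as maximally unfavorable density."""
    thr = config.cc_threshold if cc_threshold is None else cc_threshold
    best: int | None = None
    for mid in dataset.multiplexes:
        cc = multiplex_cc(dataset, pair, mid, config)
        if cc is not None and cc >= thr:
            n = len(dataset.proteins_in(mid))
            if best is None or n < best:
                best = n
    return best if best is not None else min_proteins_sentinel(dataset)


def pair_features(
    dataset: ElutionDataset,
    pair: PairKey,
    context: GenomeContextTable | None = None,
    config: FeatureConfig = FeatureConfig(),
) -> PairFeatures:
    """All eight features for one pair (reference per-pair path)."""
    ctx = context.get(pair) if context is not None else (0.0, 0.0, 0.0)
    return PairFeatures(
        pair=pair,
        cc_sec=max_cc(dataset, pair, "SEC", config),
        cc_hic=max_cc(dataset, pair, "HIC", config),
        dice=dice_coefficient(dataset, pair, config),
        peptide_ratio=peptide_ratio(dataset, pair),
        min_proteins=min_proteins(dataset, pair, config=config),
        string_neighborhood=ctx[0],
        string_cooccurrence=ctx[1],
        string_fusion=ctx[2],
    )


# ---------------------------------------------------------------------------
# Vectorized assembly over all co-occurring pairs
# ---------------------------------------------------------------------------

def assemble_features(
    dataset: ElutionDataset,
    context: GenomeContextTable | None = None,
    config: FeatureConfig = FeatureConfig(),
) -> list[PairFeatures]:
    """One :class:`PairFeatures` per co-occurring pair of the dataset.

    Equivalent to calling :func:`pair_features` on every co-occurring pair,
    but computed multiplex-by-multiplex with vectorized Pearson correlations
    so whole-experiment tables are feasible.
    """
    pids = sorted(dataset.detected_proteins)
    n = len(pids)
    if n < 2:
        return []
    index = {p: i for i, p in enumerate(pids)}

    size = n * n  # flat upper-triangle addressing: i * n + j with i < j
    together = np.zeros(size, dtype=np.int32)
    cc_best = {
        "SEC": np.full(size, -np.inf),
        "HIC": np.full(size, -np.inf),
    }
    minprot = np.full(size, np.iinfo(np.int32).max, dtype=np.int64)
    pepbest = np.zeros(size)

    max_pep = np.zeros(n)
    obs = np.zeros(n, dtype=np.int64)
    for (pid, mid), npep in dataset.peptides.items():
        i = index[pid]
        obs[i] += 1
        max_pep[i] = max(max_pep[i], npep)

    for mid, m in dataset.multiplexes.items():
        members = dataset.proteins_in(mid)
        d = len(members)
        if d < 2:
            continue
        rows = np.array(sorted(index[p] for p in members))
        pid_rows = [pids[i] for i in rows]
        X = np.vstack([dataset.abundance[(p, mid)] for p in pid_rows])
        R = np.vstack([dataset.raw_vector(p, mid) for p in pid_rows])
        ii, jj = np.triu_indices(d, k=1)
        flat = rows[ii] * n + rows[jj]

        together[flat] += 1

        pep = np.array([dataset.peptides[(p, mid)] for p in pid_rows], dtype=float)
        ratio = pep / max_pep[rows]
        np.maximum.at(pepbest, flat, np.minimum(ratio[ii], ratio[jj]))

        elig = (R >= config.eligibility_intensity).sum(axis=1) >= config.eligibility_fractions
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = np.corrcoef(X) if d > 1 else np.ones((1, 1))
        cc = corr[ii, jj]
        valid = (elig[ii] | elig[jj]) & np.isfinite(cc)
        np.maximum.at(cc_best[m.dimension], flat[valid], cc[valid])

        tight = valid & (cc >= config.cc_threshold)
        np.minimum.at(minprot, flat[tight], d)

    sentinel = min_proteins_sentinel(dataset)
    mask = together > 0
    idx = np.nonzero(mask)[0]
    dice_factor = 2.0 if config.classic_dice else 1.0

    out: list[PairFeatures] = []
    for k in idx:
        i, j = divmod(int(k), n)
        pk = PairKey(pids[i], pids[j])
        ctx = context.get(pk) if context is not None else (0.0, 0.0, 0.0)
        sec = cc_best["SEC"][k]
        hic = cc_best["HIC"][k]
        mp = minprot[k]
        out.append(
            PairFeatures(
                pair=pk,
                cc_sec=float(sec) if math.isfinite(sec) else -1.0,
                cc_hic=float(hic) if math.isfinite(hic) else -1.0,
                dice=dice_factor * int(together[k]) / float(obs[i] + obs[j]),
                peptide_ratio=float(pepbest[k]),
                min_proteins=int(mp) if mp < np.iinfo(np.int32).max else sentinel,
                string_neighborhood=ctx[0],
                string_cooccurrence=ctx[1],
                string_fusion=ctx[2],
            )
        )
    return out


# ---------------------------------------------------------------------------
# Tabular form
# ---------------------------------------------------------------------------

def features_to_frame(features: Iterable[PairFeatures]) -> pd.DataFrame:
    rows = [
        (f.pair.a, f.pair.b) + f.as_tuple() for f in features
    ]
    return pd.DataFrame(rows, columns=["protein_a", "protein_b", *ALL_FEATURES])


def write_feature_table(features: Iterable[PairFeatures], path: str | Path) -> None:
    df = features_to_frame(features)
    for col in df.columns:
        if df[col].dtype == float:  # repr round-trips doubles exactly
            df[col] = df[col].map(repr)
    df.to_csv(path, sep="\t", index=False)


def read_feature_table(path: str | Path) -> list[PairFeatures]:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    out = []
    for row in df.itertuples(index=False):
        out.append(
            PairFeatures(
                pair=PairKey(str(row.protein_a), str(row.protein_b)),
                cc_sec=float(row.cc_sec),
                cc_hic=float(row.cc_hic),
                dice=float(row.dice),
                peptide_ratio=float(row.peptide_ratio),
                min_proteins=int(row.min_proteins),
                string_neighborhood=float(row.string_neighborhood),
                string_cooccurrence=float(row.string_cooccurrence),
                string_fusion=float(row.string_fusion),
            )
        )
    return out
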