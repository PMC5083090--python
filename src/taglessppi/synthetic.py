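"""Synthetic tagless copurification experiments with known ground truth.

The generator emulates the statistical structure of a two-dimensional
co-fractionation experiment: a proteome is partitioned into complexes and
monomers, each protein gets an elution apex in the HIC dimension and in the
SEC dimension, and complex members share their complex's apices up to a
small jitter.  Elution peaks are Gaussian over fraction index (the
conventional chromatographic approximation).  One HIC column's fractions are
each separated on an SEC column; fractions are pooled into iTRAQ multiplexes
that tile each SEC column (8 + 8 + 5 fractions with two joint fractions) and,
at regular SEC retention times, each HIC series (8 + 5 with one joint
fraction), mirroring the two labeling schemes of the real assay.

Realism knobs with known ground truth:

* per-(protein, multiplex) detection dropout emulates data-dependent
  acquisition losses (the motivation for the -1 "never co-observed" CC
  sentinel);
* "frequent fliers" are proteins with broad multi-peak profiles that appear
  in many multiplexes and generate spurious correlations (the failure mode
  the co-migration/Dice feature addresses);
* a few proteins carry a ribosomal annotation so exclusion filtering has
  something to remove;
* operon membership is concordant with complex membership with a set
  probability, and STRING-style genome-context scores are elevated for
  co-operonic / co-complex pairs.

The gold standard is sampled from co-occurring candidate pairs at one common
rate per truth class (positives from co-complex pairs, negatives from
cross-complex pairs), so the gold-count FDR estimator is calibrated to the
candidate universe.  All outputs are a pure function of the config,
including its seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .classifier import GoldStandard, PredictionSet
from .features import GenomeContextTable
from .iodata import (
    ElutionDataset,
    Multiplex,
    PairKey,
    ProteinRecord,
    cooccurring_pairs,
    default_exclusions,
)
from .validation import PairSet


@dataclass(frozen=True)
class SimulationConfig:
    """Study-condition parameters of a synthetic experiment."""

    n_proteins: int = 500
    n_complexes: int = 60
    #: complex size = 2 + Poisson(complex_size_poisson), clipped to <= 8
    complex_size_poisson: float = 1.5
    n_hic_fractions: int = 12          # one HIC column
    sec_fractions: int = 19            # fractions per SEC column
    multiplex_width: int = 8           # iTRAQ 8-plex with 1 joint fraction
    hic_series_stride: int = 2         # HIC multiplex series every k-th SEC fraction
    peak_sigma_sec: float = 1.3        # Gaussian peak width, fraction units
    peak_sigma_hic: float = 1.0
    member_jitter: float = 0.35        # sd of a member's apex offset from its complex
    abundance_sigma: float = 0.7       # lognormal sd of protein amplitude
    measurement_noise: float = 0.25    # lognormal sd multiplying each intensity
    detection_min: float = 0.05        # max raw intensity needed to call detection
    dropout: float = 0.15              # per (protein, multiplex) loss probability
    frequent_flier_frac: float = 0.03
    frequent_flier_peaks: int = 4
    n_ribosomal: int = 10              # planted exclusion-list proteins
    operon_concordance: float = 0.7    # P(complex is encoded operonically)
    max_operon_size: int = 4
    monomer_operon_p: float = 0.1      # P(a monomer joins a small random operon)
    peptide_scale: float = 6.0         # peptide count ~ 1 + Poisson(scale * peak)
    gold_rate: float = 0.3             # sampling rate of co-occurring pairs into gold
    context_noise: float = 0.05        # P(background pair gets a nonzero context score)
    seed: int = 0

    def validate(self) -> None:
        probs = {
            "dropout": self.dropout,
            "frequent_flier_frac": self.frequent_flier_frac,
            "operon_concordance": self.operon_concordance,
            "monomer_operon_p": self.monomer_operon_p,
            "gold_rate": self.gold_rate,
            "context_noise": self.context_noise,
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be a probability, got {p}")
        for name in ("n_proteins", "n_complexes", "n_hic_fractions", "sec_fractions"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 2 <= self.multiplex_width <= 8:
            raise ValueError("multiplex_width must be 2-8 (iTRAQ plex limit)")
        if self.multiplex_width > min(self.sec_fractions, self.n_hic_fractions):
            raise ValueError(
                "multiplex cannot be wider than the column it tiles"
            )


@dataclass(frozen=True)
class GroundTruth:
    """What the generator knows: complexes, true pairs, elution apices."""

    complexes: dict[str, tuple[str, ...]]
    true_pairs: PairSet
    apices: dict[str, tuple[float, float]]  # protein -> (hic apex, sec apex)

    def is_true(self, pair: PairKey) -> bool:
        return pair in self.true_pairs.pairs


# ---------------------------------------------------------------------------

def _tile_column(n_fractions: int, width: int) -> list[list[int]]:
    """Tile a column into multiplexes of <= width fractions, consecutive
    multiplexes sharing one joint fraction."""
    tiles: list[list[int]] = []
    start = 0
    while True:
        end = min(start + width, n_fractions)
        tiles.append(list(range(start, end)))
        if end == n_fractions:
            break
        start = end - 1  # the last fraction of this tile is the next's joint
    # avoid trailing single-fraction multiplexes (invalid): merge backwards
    if len(tiles) > 1 and len(tiles[-1]) < 2:
        tiles.pop()
    return tiles


def simulate_experiment(
    config: SimulationConfig = SimulationConfig(),
) -> tuple[ElutionDataset, GroundTruth, GoldStandard, GenomeContextTable]:
    """Generate a complete synthetic experiment.

    Returns the raw (un-normalized, unfiltered) dataset, the ground truth,
    a gold standard over co-occurring non-excluded pairs, and a
    genome-context score table.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    pids = [f"P{i:04d}" for i in range(config.n_proteins)]

    # --- complexes -----------------------------------------------------
    complexes: dict[str, tuple[str, ...]] = {}
    pool = list(pids)
    cursor = 0
    for c in range(config.n_complexes):
        size = int(min(8, 2 + rng.poisson(config.complex_size_poisson)))
        if cursor + size > len(pool):
            break
        complexes[f"CPX{c:03d}"] = tuple(pool[cursor : cursor + size])
        cursor += size
    monomers = pool[cursor:]

    # --- planted exclusions (ribosomal-annotated monomers) -------------
    ribosomal = set(monomers[: config.n_ribosomal])

    # --- frequent fliers (broad multi-peak monomers) --------------------
    ff_candidates = [p for p in monomers if p not in ribosomal]
    n_ff = int(round(config.frequent_flier_frac * config.n_proteins))
    fliers = set(ff_candidates[:n_ff])

    # --- apices ---------------------------------------------------------
    apices: dict[str, tuple[float, float]] = {}
    peaks: dict[str, list[tuple[float, float, float]]] = {}  # (h, s, weight)
    for cid, members in complexes.items():
        ch = rng.uniform(0, config.n_hic_fractions - 1)
        cs = rng.uniform(0, config.sec_fractions - 1)
        for p in members:
            h = ch + rng.normal(0, config.member_jitter)
            s = cs + rng.normal(0, config.member_jitter)
            apices[p] = (h, s)
            peaks[p] = [(h, s, 1.0)]
    for p in monomers:
        h = rng.uniform(0, config.n_hic_fractions - 1)
        s = rng.uniform(0, config.sec_fractions - 1)
        apices[p] = (h, s)
        if p in fliers:
            pk = [(h, s, 1.0)]
            for _ in range(config.frequent_flier_peaks - 1):
                pk.append(
                    (
                        rng.uniform(0, config.n_hic_fractions - 1),
                        rng.uniform(0, config.sec_fractions - 1),
                        rng.uniform(0.5, 1.0),
                    )
                )
            peaks[p] = pk
        else:
            peaks[p] = [(h, s, 1.0)]

    amplitude = {p: float(rng.lognormal(0.0, config.abundance_sigma)) for p in pids}

    # noise-free intensity of every protein on the (HIC, SEC) fraction grid
    hh = np.arange(config.n_hic_fractions)[:, None]
    ss = np.arange(config.sec_fractions)[None, :]
    grid: dict[str, np.ndarray] = {}
    for p in pids:
        g = np.zeros((config.n_hic_fractions, config.sec_fractions))
        for ph, ps, w in peaks[p]:
            g += w * np.exp(
                -0.5 * ((hh - ph) / config.peak_sigma_hic) ** 2
                - 0.5 * ((ss - ps) / config.peak_sigma_sec) ** 2
            )
        grid[p] = amplitude[p] * g

    # --- multiplex geometry ---------------------------------------------
    multiplexes: dict[str, Multiplex] = {}
    cells: dict[str, list[tuple[int, int]]] = {}  # multiplex -> (h, s) per fraction

    def fid(h: int, s: int) -> str:
        return f"H{h:02d}S{s:02d}"

    sec_tiles = _tile_column(config.sec_fractions, config.multiplex_width)
    for h in range(config.n_hic_fractions):
        for t, tile in enumerate(sec_tiles):
            mid = f"SEC-H{h:02d}-{t}"
            joints = set()
            if t > 0:
                joints.add(fid(h, tile[0]))
            if t < len(sec_tiles) - 1:
                joints.add(fid(h, tile[-1]))
            multiplexes[mid] = Multiplex(
                multiplex_id=mid,
                dimension="SEC",
                fraction_ids=tuple(fid(h, s) for s in tile),
                joint_fraction_ids=frozenset(joints),
            )
            cells[mid] = [(h, s) for s in tile]

    hic_tiles = _tile_column(config.n_hic_fractions, config.multiplex_width)
    for s in range(0, config.sec_fractions, config.hic_series_stride):
        for t, tile in enumerate(hic_tiles):
            mid = f"HIC-S{s:02d}-{t}"
            joints = set()
            if t > 0:
                joints.add(fid(tile[0], s))
            if t < len(hic_tiles) - 1:
                joints.add(fid(tile[-1], s))
            multiplexes[mid] = Multiplex(
                multiplex_id=mid,
                dimension="HIC",
                fraction_ids=tuple(fid(h, s) for h in tile),
                joint_fraction_ids=frozenset(joints),
            )
            cells[mid] = [(h, s) for h in tile]

    # --- measurement ----------------------------------------------------
    abundance: dict[tuple[str, str], np.ndarray] = {}
    peptides: dict[tuple[str, str], int] = {}
    cell_idx = {
        mid: (np.array([h for h, _ in hs]), np.array([s for _, s in hs]))
        for mid, hs in cells.items()
    }
    for p in pids:
        for mid in multiplexes:
            hi, si = cell_idx[mid]
            base = grid[p][hi, si]
            if float(base.max()) < config.detection_min:
                continue
            if rng.random() < config.dropout:
                continue
            noise = rng.lognormal(0.0, config.measurement_noise, size=base.size)
            vec = base * noise
            vec[vec < 1e-4] = 0.0
            if float(vec.max()) <= 0.0:
                continue
            abundance[(p, mid)] = vec
            peptides[(p, mid)] = 1 + int(
                rng.poisson(config.peptide_scale * min(float(vec.max()), 3.0))
            )

    # --- operons and roles ----------------------------------------------
    operon_of: dict[str, str] = {}
    n_op = 0
    for cid, members in complexes.items():
        if rng.random() < config.operon_concordance:
            for chunk_start in range(0, len(members), config.max_operon_size):
                chunk = members[chunk_start : chunk_start + config.max_operon_size]
                if len(chunk) >= 2:
                    oid = f"OPN{n_op:04d}"
                    n_op += 1
                    for p in chunk:
                        operon_of[p] = oid
    free = [p for p in monomers if rng.random() < config.monomer_operon_p]
    for i in range(0, len(free) - 1, 2):
        oid = f"OPN{n_op:04d}"
        n_op += 1
        operon_of[free[i]] = oid
        operon_of[free[i + 1]] = oid

    roles = [f"ROLE{r:02d}" for r in range(15)]
    role_of: dict[str, str] = {}
    for cid, members in complexes.items():
        crole = roles[int(rng.integers(len(roles)))]
        for p in members:
            role_of[p] = (
                crole if rng.random() < 0.8 else roles[int(rng.integers(len(roles)))]
            )
    for p in monomers:
        role_of[p] = roles[int(rng.integers(len(roles)))]
    for p in ribosomal:
        role_of[p] = "Ribosomal proteins: synthesis and modification"

    proteins = {
        p: ProteinRecord(
            protein_id=p,
            operon_id=operon_of.get(p),
            tigr_role=role_of[p],
            excluded=p in ribosomal,
        )
        for p in pids
    }

    dataset = ElutionDataset(
        proteins=proteins,
        multiplexes=multiplexes,
        abundance=abundance,
        peptides=peptides,
    )
    dataset.validate()

    # --- ground truth ----------------------------------------------------
    true_pairs = {
        PairKey(a, b)
        for members in complexes.values()
        for i, a in enumerate(members)
        for b in members[i + 1 :]
    }
    truth = GroundTruth(
        complexes=complexes,
        true_pairs=PairSet.from_pairs("true_ppis", true_pairs),
        apices=apices,
    )

    # --- gold standard (equal-rate sample of co-occurring candidates) ----
    excluded = default_exclusions(dataset)
    candidates = sorted(
        pk
        for pk in cooccurring_pairs(dataset)
        if pk.a not in excluded and pk.b not in excluded
    )
    gold_pos, gold_neg = [], []
    for pk in candidates:
        if rng.random() < config.gold_rate:
            (gold_pos if pk in true_pairs else gold_neg).append(pk)
    gold = GoldStandard(
        positives=frozenset(gold_pos),
        negatives=frozenset(gold_neg),
        operon_map=dict(operon_of),
    )

    # --- genome-context scores -------------------------------------------
    context = GenomeContextTable()
    seen: set[PairKey] = set()

    def put(pk: PairKey, n: float, c: float, f: float) -> None:
        context[pk] = (min(max(n, 0.0), 1.0), min(max(c, 0.0), 1.0), min(max(f, 0.0), 1.0))
        seen.add(pk)

    by_operon: dict[str, list[str]] = {}
    for p, oid in operon_of.items():
        by_operon.setdefault(oid, []).append(p)
    for oid, members in sorted(by_operon.items()):
        for i, a in enumerate(members):
            for b in members[i + 1 :]:
                put(
                    PairKey(a, b),
                    rng.beta(8, 2),
                    rng.beta(4, 2),
                    rng.beta(2, 2) if rng.random() < 0.1 else 0.0,
                )
    for pk in sorted(true_pairs):
        if pk in seen:
            continue
        if rng.random() < 0.6:
            put(pk, rng.beta(2, 5), rng.beta(4, 2), 0.0)
    n_background = 2 * config.n_proteins
    for _ in range(n_background):
        if rng.random() >= config.context_noise:
            continue
        i, j = rng.integers(0, config.n_proteins, size=2)
        if i == j:
            continue
        pk = PairKey(pids[int(i)], pids[int(j)])
        if pk not in seen:
            put(pk, rng.beta(1, 10), rng.beta(1, 10), 0.0)

    return dataset, truth, gold, context


# ---------------------------------------------------------------------------

def truth_metrics(
    predictions: PredictionSet | Iterable[PairKey], truth: GroundTruth
) -> dict[str, float | None]:
    """Empirical FDR, precision and recall against the planted true pairs."""
    if isinstance(predictions, PredictionSet):
        predicted = set(predictions.predicted)
    else:
        predicted = set(predictions)
    true = truth.true_pairs.pairs
    tp = len(predicted & true)
    n_pred = len(predicted)
    return {
        "n_predicted": float(n_pred),
        "fdr": (n_pred - tp) / n_pred if n_pred else None,
        "precision": tp / n_pred if n_pred else None,
        "recall": tp / len(true) if true else None,
    }
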