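"""Independent brute-force reference implementations used as test oracles.

Everything here is written as plain double loops over the dataset dicts and
uses scipy.stats.pearsonr for correlations, deliberately sharing no code
with the package's feature machinery.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from taglessppi.iodata import ElutionDataset, Multiplex, PairKey, ProteinRecord


def random_dataset(rng: np.random.Generator) -> ElutionDataset:
    """A small random elution dataset exercising all feature edge cases:
    missing detections, sub-eligibility intensities, constant profiles."""
    n_prot = int(rng.integers(5, 10))
    n_mult = int(rng.integers(3, 7))
    pids = [f"X{i}" for i in range(n_prot)]
    multiplexes = {}
    for m in range(n_mult):
        width = int(rng.integers(3, 7))
        fids = tuple(f"M{m}F{k}" for k in range(width))
        multiplexes[f"M{m}"] = Multiplex(
            multiplex_id=f"M{m}",
            dimension="SEC" if rng.random() < 0.5 else "HIC",
            fraction_ids=fids,
            joint_fraction_ids=frozenset([fids[0]] if rng.random() < 0.3 else []),
        )
    abundance, peptides = {}, {}
    for p in pids:
        for mid, mx in multiplexes.items():
            if rng.random() < 0.45:
                continue
            kind = rng.random()
            if kind < 0.15:  # constant profile: Pearson undefined
                vec = np.full(mx.n_fractions, float(rng.uniform(0.05, 1.0)))
            elif kind < 0.35:  # sub-eligibility intensities
                vec = rng.uniform(0, 0.009, size=mx.n_fractions)
            else:
                vec = rng.uniform(0, 1, size=mx.n_fractions)
            if vec.max() <= 0:
                continue
            abundance[(p, mid)] = vec
            peptides[(p, mid)] = int(rng.integers(1, 12))
    # ensure every protein is detected somewhere
    for p in pids:
        if not any(k[0] == p for k in abundance):
            mid = f"M{int(rng.integers(n_mult))}"
            abundance[(p, mid)] = rng.uniform(0.1, 1, size=multiplexes[mid].n_fractions)
            peptides[(p, mid)] = int(rng.integers(1, 12))
    proteins = {p: ProteinRecord(protein_id=p) for p in pids}
    ds = ElutionDataset(
        proteins=proteins, multiplexes=multiplexes, abundance=abundance,
        peptides=peptides,
    )
    ds.validate()
    return ds


# ---------------------------------------------------------------------------
# brute-force feature oracles (thresholds are the package defaults)
# ---------------------------------------------------------------------------

ELIG_INTENSITY = 0.01
ELIG_FRACTIONS = 3
CC_THRESHOLD = 0.85


def brute_eligible(ds: ElutionDataset, a: str, b: str, mid: str) -> bool:
    if (a, mid) not in ds.abundance or (b, mid) not in ds.abundance:
        return False
    raw = ds.raw_abundance if ds.raw_abundance is not None else ds.abundance
    for p in (a, b):
        if sum(1 for v in raw[(p, mid)] if v >= ELIG_INTENSITY) >= ELIG_FRACTIONS:
            return True
    return False


def brute_cc(ds: ElutionDataset, a: str, b: str, mid: str) -> float | None:
    if not brute_eligible(ds, a, b, mid):
        return None
    x, y = ds.abundance[(a, mid)], ds.abundance[(b, mid)]
    if np.std(x) == 0 or np.std(y) == 0:
        return None
    return float(stats.pearsonr(x, y).statistic)


def brute_max_cc(ds: ElutionDataset, a: str, b: str, dimension: str) -> float:
    ccs = [
        cc
        for mid, m in ds.multiplexes.items()
        if m.dimension == dimension
        for cc in [brute_cc(ds, a, b, mid)]
        if cc is not None
    ]
    return max(ccs) if ccs else -1.0


def brute_observances(ds: ElutionDataset, p: str) -> list[str]:
    return [mid for mid in ds.multiplexes if (p, mid) in ds.abundance]


def brute_dice(ds: ElutionDataset, a: str, b: str) -> float:
    oa, ob = brute_observances(ds, a), brute_observances(ds, b)
    together = len([m for m in oa if m in ob])
    return together / (len(oa) + len(ob))


def brute_peptide_ratio(ds: ElutionDataset, a: str, b: str) -> float:
    oa, ob = brute_observances(ds, a), brute_observances(ds, b)
    max_a = max(ds.peptides[(a, m)] for m in oa)
    max_b = max(ds.peptides[(b, m)] for m in ob)
    vals = [
        min(ds.peptides[(a, m)] / max_a, ds.peptides[(b, m)] / max_b)
        for m in oa
        if m in ob
    ]
    return max(vals) if vals else 0.0


def brute_min_proteins(ds: ElutionDataset, a: str, b: str) -> int:
    counts = []
    for mid in ds.multiplexes:
        cc = brute_cc(ds, a, b, mid)
        if cc is not None and cc >= CC_THRESHOLD:
            counts.append(len({p for (p, m) in ds.abundance if m == mid}))
    if counts:
        return min(counts)
    densest = max(
        len({p for (p, m) in ds.abundance if m == mid}) for mid in ds.multiplexes
    )
    return densest + 1


def brute_cooccurring(ds: ElutionDataset) -> set[PairKey]:
    out = set()
    pids = sorted(ds.proteins)
    for i, a in enumerate(pids):
        for b in pids[i + 1 :]:
            for mid in ds.multiplexes:
                if (a, mid) in ds.abundance and (b, mid) in ds.abundance:
                    out.add(PairKey(a, b))
                    break
    return out
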