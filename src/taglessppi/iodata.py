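"""Data model and I/O for tagless co-fractionation elution datasets.

A tagless copurification experiment quantifies the relative abundance of
endogenous proteins across chromatographic fractions using isobaric (iTRAQ)
labeling.  Fractions are pooled into *multiplexes* of up to eight fractions
that are measured together; multiplexes belong to one of two orthogonal
separation dimensions (size exclusion, SEC, or hydrophobic interaction, HIC).
Adjacent multiplexes from the same column share a "joint" fraction so that
per-column elution profiles can be stitched together.

This module defines the in-memory containers (:class:`ProteinRecord`,
:class:`Multiplex`, :class:`ElutionDataset`, :class:`PairKey`), the TSV
readers/writers for the tabular interchange formats, apex normalization of
iTRAQ relative abundances, exclusion filtering of ribosomal/chaperonin
proteins, and enumeration of co-occurring protein pairs.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DIMENSIONS = ("SEC", "HIC")

#: Highly abundant chaperonins removed before PPI analysis, alongside
#: ribosomal proteins (annotation regex below).  Datasets from other
#: organisms supply their own exclusion list.
DEFAULT_CHAPERONINS = frozenset({"DVU0811", "DVU0812", "DVU1976", "DVU1977"})

#: Matches TIGR-role style annotations of ribosomal proteins.
RIBOSOMAL_ROLE_PATTERN = re.compile(r"ribosom", re.IGNORECASE)


class ParseError(ValueError):
    """A malformed row in an input table (message names the line)."""


class ConsistencyError(ValueError):
    """A row references an undeclared multiplex, fraction or protein."""


@dataclass(frozen=True)
class ProteinRecord:
    """Annotation record for one protein."""

    protein_id: str
    operon_id: str | None = None
    tigr_role: str | None = None
    excluded: bool = False


@dataclass(frozen=True)
class Multiplex:
    """One iTRAQ multiplex: an ordered pool of 2-8 fractions from one dimension."""

    multiplex_id: str
    dimension: str
    fraction_ids: tuple[str, ...]
    joint_fraction_ids: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.dimension not in DIMENSIONS:
            raise ConsistencyError(
                f"multiplex {self.multiplex_id}: dimension must be one of "
                f"{DIMENSIONS}, got {self.dimension!r}"
            )
        if not 2 <= len(self.fraction_ids) <= 8:
            raise ConsistencyError(
                f"multiplex {self.multiplex_id}: needs 2-8 fractions, "
                f"got {len(self.fraction_ids)}"
            )
        if len(set(self.fraction_ids)) != len(self.fraction_ids):
            raise ConsistencyError(
                f"multiplex {self.multiplex_id}: duplicate fraction ids"
            )
        if not set(self.joint_fraction_ids) <= set(self.fraction_ids):
            raise ConsistencyError(
                f"multiplex {self.multiplex_id}: joint fractions must be a "
                f"subset of its fractions"
            )

    @property
    def n_fractions(self) -> int:
        return len(self.fraction_ids)


@dataclass(frozen=True, order=True)
class PairKey:
    """Canonically ordered unordered protein pair (lexicographic a < b)."""

    a: str
    b: str

    def __init__(self, a: str, b: str) -> None:
        if a == b:
            raise ValueError(f"self-pair not allowed: {a!r}")
        if b < a:
            a, b = b, a
        object.__setattr__(self, "a", a)
        object.__setattr__(self, "b", b)

    def __iter__(self):
        return iter((self.a, self.b))

    def touches(self, proteins: frozenset[str] | set[str]) -> bool:
        return self.a in proteins or self.b in proteins


@dataclass
class ElutionDataset:
    """Proteins x multiplexes x fractions relative abundances with metadata.

    ``abundance[(protein_id, multiplex_id)]`` is a vector aligned with the
    multiplex's ``fraction_ids`` order.  A protein is *detected* in a
    multiplex iff such a record exists.  ``raw_abundance`` holds the
    pre-normalization intensities once :func:`normalize_apex` has run (the
    CC-eligibility rule is defined on raw intensities).
    """

    proteins: dict[str, ProteinRecord]
    multiplexes: dict[str, Multiplex]
    abundance: dict[tuple[str, str], np.ndarray]
    peptides: dict[tuple[str, str], int]
    raw_abundance: dict[tuple[str, str], np.ndarray] | None = None
    _by_multiplex: dict[str, list[str]] | None = field(
        default=None, repr=False, compare=False
    )
    _by_protein: dict[str, list[str]] | None = field(
        default=None, repr=False, compare=False
    )

    # -- indexes ---------------------------------------------------------
    def _build_indexes(self) -> None:
        by_m: dict[str, list[str]] = {m: [] for m in self.multiplexes}
        by_p: dict[str, list[str]] = {p: [] for p in self.proteins}
        for pid, mid in self.abundance:
            by_m[mid].append(pid)
            by_p[pid].append(mid)
        self._by_multiplex = by_m
        self._by_protein = by_p

    def proteins_in(self, multiplex_id: str) -> list[str]:
        """Protein ids detected in a multiplex (declaration order)."""
        if self._by_multiplex is None:
            self._build_indexes()
        return self._by_multiplex[multiplex_id]

    def multiplexes_of(self, protein_id: str) -> list[str]:
        if self._by_protein is None:
            self._build_indexes()
        return self._by_protein[protein_id]

    def detected(self, protein_id: str, multiplex_id: str) -> bool:
        return (protein_id, multiplex_id) in self.abundance

    @property
    def detected_proteins(self) -> set[str]:
        """Proteins with at least one abundance record."""
        return {pid for pid, _ in self.abundance}

    @property
    def normalized(self) -> bool:
        return self.raw_abundance is not None

    def raw_vector(self, protein_id: str, multiplex_id: str) -> np.ndarray:
        """Pre-normalization intensity vector (falls back to current values)."""
        key = (protein_id, multiplex_id)
        if self.raw_abundance is not None and key in self.raw_abundance:
            return self.raw_abundance[key]
        return self.abundance[key]

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        ids = list(self.proteins)
        if len(set(ids)) != len(ids):
            raise ConsistencyError("duplicate protein ids")
        for (pid, mid), vec in self.abundance.items():
            if pid not in self.proteins:
                raise ConsistencyError(f"abundance for undeclared protein {pid!r}")
            if mid not in self.multiplexes:
                raise ConsistencyError(f"abundance for undeclared multiplex {mid!r}")
            if len(vec) != self.multiplexes[mid].n_fractions:
                raise ConsistencyError(
                    f"abundance vector for ({pid}, {mid}) has length {len(vec)}, "
                    f"expected {self.multiplexes[mid].n_fractions}"
                )
            if np.any(vec < 0) or not np.all(np.isfinite(vec)):
                raise ConsistencyError(
                    f"abundance for ({pid}, {mid}) must be finite and non-negative"
                )
            if self.peptides.get((pid, mid), 0) < 1:
                raise ConsistencyError(
                    f"({pid}, {mid}) detected but has no unique-peptide count"
                )


# ---------------------------------------------------------------------------
# TSV readers / writers
# ---------------------------------------------------------------------------

def read_design_table(design_path: str | Path) -> dict[str, Multiplex]:
    """Read the multiplex design TSV.

    Columns: multiplex_id, dimension (SEC|HIC), fraction_id, is_joint (0|1);
    fraction order within a multiplex is the row order (fraction ids are
    opaque strings, never parsed numerically).
    """
    df = _read_tsv(design_path, ["multiplex_id", "dimension", "fraction_id", "is_joint"])
    multiplexes: dict[str, Multiplex] = {}
    for mid, grp in df.groupby("multiplex_id", sort=False):
        dims = grp["dimension"].unique()
        if len(dims) != 1:
            raise ConsistencyError(f"multiplex {mid}: inconsistent dimension labels")
        joints = frozenset(grp.loc[grp["is_joint"].astype(int) == 1, "fraction_id"])
        multiplexes[str(mid)] = Multiplex(
            multiplex_id=str(mid),
            dimension=str(dims[0]),
            fraction_ids=tuple(grp["fraction_id"].astype(str)),
            joint_fraction_ids=joints,
        )
    return multiplexes


def read_annotation_table(annotation_path: str | Path) -> dict[str, ProteinRecord]:
    """Read the annotation TSV (protein_id, operon_id, tigr_role, excluded)."""
    df = _read_tsv(annotation_path, ["protein_id", "operon_id", "tigr_role", "excluded"])
    records: dict[str, ProteinRecord] = {}
    for row in df.itertuples(index=False):
        pid = str(row.protein_id)
        if pid in records:
            raise ConsistencyError(f"duplicate annotation for protein {pid!r}")
        records[pid] = ProteinRecord(
            protein_id=pid,
            operon_id=_opt_str(row.operon_id),
            tigr_role=_opt_str(row.tigr_role),
            excluded=bool(int(row.excluded)),
        )
    return records


def read_elution_tables(
    abundance_path: str | Path,
    design_path: str | Path,
    annotation_path: str | Path | None = None,
) -> ElutionDataset:
    """Assemble a validated :class:`ElutionDataset` from the TSV triplet.

    Abundance columns: protein_id, multiplex_id, fraction_id, abundance,
    peptides (the unique-peptide count of that protein in that multiplex,
    repeated on each of its rows).  Rows referencing undeclared multiplexes
    or fractions raise :class:`ConsistencyError`.  Proteins missing from the
    annotation table get a bare record.
    """
    multiplexes = read_design_table(design_path)
    annotations = (
        read_annotation_table(annotation_path) if annotation_path is not None else {}
    )
    df = _read_tsv(
        abundance_path,
        ["protein_id", "multiplex_id", "fraction_id", "abundance", "peptides"],
    )

    frac_index = {
        (mid, fid): i
        for mid, m in multiplexes.items()
        for i, fid in enumerate(m.fraction_ids)
    }
    abundance: dict[tuple[str, str], np.ndarray] = {}
    peptides: dict[tuple[str, str], int] = {}
    for lineno, row in enumerate(df.itertuples(index=False), start=2):
        pid, mid, fid = str(row.protein_id), str(row.multiplex_id), str(row.fraction_id)
        if mid not in multiplexes:
            raise ConsistencyError(
                f"{abundance_path}, line {lineno}: unknown multiplex {mid!r}"
            )
        if (mid, fid) not in frac_index:
            raise ConsistencyError(
                f"{abundance_path}, line {lineno}: fraction {fid!r} not declared "
                f"for multiplex {mid!r}"
            )
        try:
            value = float(row.abundance)
            npep = int(row.peptides)
        except (TypeError, ValueError) as exc:
            raise ParseError(f"{abundance_path}, line {lineno}: {exc}") from exc
        key = (pid, mid)
        if key not in abundance:
            abundance[key] = np.zeros(multiplexes[mid].n_fractions)
            peptides[key] = npep
        elif peptides[key] != npep:
            raise ConsistencyError(
                f"{abundance_path}, line {lineno}: inconsistent peptide count "
                f"for ({pid}, {mid})"
            )
        abundance[key][frac_index[(mid, fid)]] = value

    proteins = dict(annotations)
    for pid, _ in abundance:
        proteins.setdefault(pid, ProteinRecord(protein_id=pid))

    ds = ElutionDataset(
        proteins=proteins, multiplexes=multiplexes, abundance=abundance,
        peptides=peptides,
    )
    ds.validate()
    return ds


def write_elution_tables(
    dataset: ElutionDataset,
    abundance_path: str | Path,
    design_path: str | Path,
    annotation_path: str | Path | None = None,
) -> None:
    """Write a dataset back to the TSV dialect read by :func:`read_elution_tables`."""
    rows = []
    for m in dataset.multiplexes.values():
        for fid in m.fraction_ids:
            rows.append(
                (m.multiplex_id, m.dimension, fid, int(fid in m.joint_fraction_ids))
            )
    pd.DataFrame(
        rows, columns=["multiplex_id", "dimension", "fraction_id", "is_joint"]
    ).to_csv(design_path, sep="\t", index=False)

    arows = []
    for (pid, mid), vec in dataset.abundance.items():
        fids = dataset.multiplexes[mid].fraction_ids
        npep = dataset.peptides[(pid, mid)]
        for fid, v in zip(fids, vec):
            arows.append((pid, mid, fid, repr(float(v)), npep))
    pd.DataFrame(
        arows,
        columns=["protein_id", "multiplex_id", "fraction_id", "abundance", "peptides"],
    ).to_csv(abundance_path, sep="\t", index=False)

    if annotation_path is not None:
        prows = [
            (p.protein_id, p.operon_id or "", p.tigr_role or "", int(p.excluded))
            for p in dataset.proteins.values()
        ]
        pd.DataFrame(
            prows, columns=["protein_id", "operon_id", "tigr_role", "excluded"]
        ).to_csv(annotation_path, sep="\t", index=False)


def read_pair_list(path: str | Path) -> list[tuple[PairKey, str | None]]:
    """Read a pair-list TSV (protein_a, protein_b[, label])."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"protein_a", "protein_b"}
    if not required <= set(df.columns):
        raise ParseError(f"{path}: pair list needs columns {sorted(required)}")
    has_label = "label" in df.columns
    out = []
    for row in df.itertuples(index=False):
        out.append(
            (PairKey(str(row.protein_a), str(row.protein_b)),
             str(row.label) if has_label else None)
        )
    return out


def write_pair_list(
    pairs: Iterable[PairKey],
    path: str | Path,
    labels: Mapping[PairKey, str] | None = None,
) -> None:
    rows = []
    for pk in sorted(set(pairs)):
        if labels is None:
            rows.append((pk.a, pk.b))
        else:
            rows.append((pk.a, pk.b, labels[pk]))
    cols = ["protein_a", "protein_b"] + (["label"] if labels is not None else [])
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Normalization / filtering / co-occurrence
# ---------------------------------------------------------------------------

def normalize_apex(dataset: ElutionDataset) -> ElutionDataset:
    """Rescale every (protein, multiplex) vector so its apex fraction is 1.

    Relative iTRAQ abundances are divided by the per-multiplex maximum, so the
    fraction in which the polypeptide is most abundant gets the value 1 and
    every other fraction a value in [0, 1].  When several fractions tie at the
    maximum they all become 1.  All-zero records are dropped with a warning
    (nothing was quantified there).  Idempotent; the pre-normalization values
    are kept as ``raw_abundance`` because the correlation-eligibility rule is
    defined on raw intensities.
    """
    raw = dataset.raw_abundance if dataset.raw_abundance is not None else dataset.abundance
    norm: dict[tuple[str, str], np.ndarray] = {}
    kept_raw: dict[tuple[str, str], np.ndarray] = {}
    peptides: dict[tuple[str, str], int] = {}
    for key, vec in dataset.abundance.items():
        apex = float(np.max(vec))
        if apex <= 0.0:
            logger.warning("dropping all-zero abundance record %s", key)
            continue
        norm[key] = vec / apex
        kept_raw[key] = raw[key]
        peptides[key] = dataset.peptides[key]
    return ElutionDataset(
        proteins=dict(dataset.proteins),
        multiplexes=dict(dataset.multiplexes),
        abundance=norm,
        peptides=peptides,
        raw_abundance=kept_raw,
    )


def default_exclusions(dataset: ElutionDataset) -> set[str]:
    """Proteins to exclude by default: flagged records, ribosomal annotations,
    and the four named chaperonins (DnaK, GrpE, GroEL, GroES)."""
    out: set[str] = set()
    for p in dataset.proteins.values():
        if p.excluded or p.protein_id in DEFAULT_CHAPERONINS:
            out.add(p.protein_id)
        elif p.tigr_role and RIBOSOMAL_ROLE_PATTERN.search(p.tigr_role):
            out.add(p.protein_id)
    return out


def filter_exclusions(
    dataset: ElutionDataset, exclusion_list: Iterable[str] | None = None
) -> ElutionDataset:
    """Remove excluded proteins (ribosomal/chaperonin) from every record.

    ``exclusion_list`` defaults to :func:`default_exclusions`.  Listed
    proteins absent from the dataset are ignored.
    """
    excl = set(exclusion_list) if exclusion_list is not None else default_exclusions(dataset)
    proteins = {
        pid: rec for pid, rec in dataset.proteins.items() if pid not in excl
    }
    abundance = {
        key: vec for key, vec in dataset.abundance.items() if key[0] not in excl
    }
    peptides = {k: v for k, v in dataset.peptides.items() if k[0] not in excl}
    raw = (
        {k: v for k, v in dataset.raw_abundance.items() if k[0] not in excl}
        if dataset.raw_abundance is not None
        else None
    )
    return ElutionDataset(
        proteins=proteins,
        multiplexes=dict(dataset.multiplexes),
        abundance=abundance,
        peptides=peptides,
        raw_abundance=raw,
    )


def cooccurring_pairs(dataset: ElutionDataset) -> set[PairKey]:
    """Every unordered pair of proteins detected together in >=1 multiplex."""
    pairs: set[PairKey] = set()
    for mid in dataset.multiplexes:
        members = sorted(dataset.proteins_in(mid))
        for a, b in combinations(members, 2):
            pairs.add(PairKey(a, b))
    return pairs


def operon_map_from_records(proteins: Mapping[str, ProteinRecord]) -> dict[str, str]:
    """protein_id -> operon_id; proteins without annotation become singleton
    operons named after themselves."""
    return {
        pid: (rec.operon_id if rec.operon_id else pid)
        for pid, rec in proteins.items()
    }


# ---------------------------------------------------------------------------

def _read_tsv(path: str | Path, required: list[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ParseError(f"{path}: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required columns {missing}")
    return df


def _opt_str(value: object) -> str | None:
    s = str(value)
    return s if s not in ("", "nan", "None") else None
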