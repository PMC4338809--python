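"""Binary substrate-affinity profiles and community niche metrics.

A species' metabolic niche is its set of utilized carbon substrates (a binary
row over, by default, the 95 substrates of a Biolog-GN-style plate).  From a
species x substrate indicator matrix this module derives:

* per-species niche breadth (row sum),
* community metabolic diversity, CMD (cardinality of the union of member
  substrate sets),
* pairwise niche overlap (Jaccard index of two substrate sets), and
* community redundancy (1 - CMD / sum of member breadths).

It also builds the fixed 17-consortium assembly design (seven richness levels,
compositions A-C, nested within columns) from an ordered 12-species pool.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DesignError, DomainError, FormatError

__all__ = [
    "AffinityMatrix",
    "Consortium",
    "ConsortiumDesign",
    "NicheMetrics",
    "load_affinity_matrix",
    "write_affinity_matrix",
    "niche_breadth",
    "community_metabolic_diversity",
    "pairwise_overlap",
    "community_redundancy",
    "consortium_metrics",
    "build_design",
    "design_to_json",
    "design_from_json",
    "cmd_richness_curve",
    "NESTED_DESIGN_ROWS",
]

N_SUBSTRATES_DEFAULT = 95

# Nested assembly layout: (nominal richness level, composition label,
# 1-based positional indices into the species pool).  The richness-7/C row
# lists six members by construction; true cardinality is tracked separately.
NESTED_DESIGN_ROWS: tuple[tuple[int, str, tuple[int, ...]], ...] = (
    (2, "A", (1, 2)),
    (2, "B", (6, 7)),
    (2, "C", (11, 12)),
    (3, "A", (1, 2, 3)),
    (3, "B", (6, 7, 8)),
    (3, "C", (10, 11, 12)),
    (4, "A", (1, 2, 3, 4)),
    (4, "B", (5, 6, 7, 8)),
    (4, "C", (9, 10, 11, 12)),
    (5, "A", (1, 2, 3, 4, 5)),
    (5, "B", (5, 6, 7, 8, 9)),
    (5, "C", (8, 9, 10, 11, 12)),
    (7, "A", (1, 2, 3, 4, 5, 6, 7)),
    (7, "B", (4, 5, 6, 7, 8, 9, 10)),
    (7, "C", (7, 8, 9, 10, 11, 12)),
    (11, "single", tuple(range(1, 12))),
    (12, "single", tuple(range(1, 13))),
)


@dataclass(frozen=True)
class AffinityMatrix:
    """Species x substrate binary indicator table.

    ``cells[i, j] == 1`` iff species ``species_ids[i]`` utilizes substrate
    ``substrate_ids[j]``.
    """

    species_ids: tuple[str, ...]
    substrate_ids: tuple[str, ...]
    cells: np.ndarray  # shape (n_species, n_substrates), dtype int8, values {0,1}

    def __post_init__(self) -> None:
        cells = np.asarray(self.cells, dtype=np.int8)
        object.__setattr__(self, "cells", cells)
        object.__setattr__(self, "species_ids", tuple(str(s) for s in self.species_ids))
        object.__setattr__(self, "substrate_ids", tuple(str(s) for s in self.substrate_ids))
        if len(self.species_ids) == 0 or len(self.substrate_ids) == 0:
            raise FormatError("affinity matrix must have at least one species and one substrate")
        if len(set(self.species_ids)) != len(self.species_ids):
            raise FormatError("duplicate species ids in affinity matrix")
        if len(set(self.substrate_ids)) != len(self.substrate_ids):
            raise FormatError("duplicate substrate ids in affinity matrix")
        if cells.shape != (len(self.species_ids), len(self.substrate_ids)):
            raise FormatError(
                f"cell block shape {cells.shape} does not match "
                f"{len(self.species_ids)} species x {len(self.substrate_ids)} substrates"
            )
        bad = ~np.isin(cells, (0, 1))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise FormatError(
                f"non-binary cell at species {self.species_ids[i]!r}, "
                f"substrate {self.substrate_ids[j]!r}"
            )

    @property
    def n_species(self) -> int:
        return len(self.species_ids)

    @property
    def n_substrates(self) -> int:
        return len(self.substrate_ids)

    def row(self, species: str) -> np.ndarray:
        try:
            i = self.species_ids.index(species)
        except ValueError:
            raise KeyError(f"unknown species {species!r}") from None
        return self.cells[i]

    def substrate_set(self, species: str) -> frozenset[str]:
        row = self.row(species)
        return frozenset(s for s, v in zip(self.substrate_ids, row) if v)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.cells, columns=list(self.substrate_ids))
        df.insert(0, "species_id", list(self.species_ids))
        return df


def load_affinity_matrix(path: str | Path) -> AffinityMatrix:
    """Read a TSV affinity matrix (first column ``species_id``, cells 0/1).

    Row and column order are preserved.  Non-binary cells and duplicate
    species ids raise :class:`FormatError` naming the offending entry.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.columns[0] != "species_id":
        raise FormatError(f"first column must be 'species_id', got {df.columns[0]!r}")
    species = df["species_id"].tolist()
    substrates = df.columns[1:].tolist()
    raw = df.iloc[:, 1:].to_numpy()
    cells = np.empty(raw.shape, dtype=np.int8)
    for i in range(raw.shape[0]):
        for j in range(raw.shape[1]):
            v = str(raw[i, j]).strip()
            if v not in ("0", "1"):
                raise FormatError(
                    f"non-binary cell {v!r} at species {species[i]!r}, "
                    f"substrate {substrates[j]!r}"
                )
            cells[i, j] = int(v)
    return AffinityMatrix(tuple(species), tuple(substrates), cells)


def write_affinity_matrix(matrix: AffinityMatrix, path: str | Path) -> None:
    matrix.to_frame().to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class Consortium:
    """An assembled set of species.

    ``level`` is the nominal design richness level; ``richness`` is always
    the true member cardinality (the two differ only for the
    richness-7/C row, which lists six members).
    """

    member_ids: frozenset[str]
    composition_label: str
    level: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "member_ids", frozenset(self.member_ids))
        if self.composition_label not in ("A", "B", "C", "single"):
            raise DesignError(f"unknown composition label {self.composition_label!r}")
        if not self.member_ids:
            raise DesignError("consortium must have at least one member")

    @property
    def richness(self) -> int:
        return len(self.member_ids)

    @property
    def label(self) -> str:
        return f"SR{self.level}-{self.composition_label}"


@dataclass(frozen=True)
class ConsortiumDesign:
    consortia: tuple[Consortium, ...]
    replicates_per_consortium: int = 3
    pool: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        object.__setattr__(self, "consortia", tuple(self.consortia))
        object.__setattr__(self, "pool", tuple(self.pool))
        if self.replicates_per_consortium < 1:
            raise DesignError("replicates_per_consortium must be positive")
        if self.pool:
            pool = set(self.pool)
            for c in self.consortia:
                if not c.member_ids <= pool:
                    raise DesignError(f"consortium {c.label} has members outside the pool")

    @property
    def n_units(self) -> int:
        """Total experimental units (consortia x replicates)."""
        return len(self.consortia) * self.replicates_per_consortium


def build_design(
    pool: Sequence[str], replicates_per_consortium: int = 3
) -> ConsortiumDesign:
    """Build the default 17-consortium nested design from a 12-species pool.

    Species are assigned by positional index (1-based) into ``pool``; e.g. the
    richness-4/B consortium takes pool positions 5-8.
    """
    pool = [str(s) for s in pool]
    if len(pool) != 12:
        raise DesignError(f"species pool must have exactly 12 labels, got {len(pool)}")
    if len(set(pool)) != 12:
        raise DesignError("species pool labels must be distinct")
    consortia = tuple(
        Consortium(frozenset(pool[i - 1] for i in idx), comp, level)
        for level, comp, idx in NESTED_DESIGN_ROWS
    )
    return ConsortiumDesign(consortia, replicates_per_consortium, tuple(pool))


def design_to_json(design: ConsortiumDesign) -> str:
    rows = []
    pool = list(design.pool)
    for c in design.consortia:
        rows.append(
            {
                "richness": c.level,
                "composition_label": c.composition_label,
                "member_indices": sorted(pool.index(m) + 1 for m in c.member_ids),
            }
        )
    return json.dumps(
        {
            "pool": pool,
            "replicates_per_consortium": design.replicates_per_consortium,
            "consortia": rows,
        },
        indent=2,
    )


def design_from_json(text: str) -> ConsortiumDesign:
    obj = json.loads(text)
    pool = [str(s) for s in obj["pool"]]
    consortia = tuple(
        Consortium(
            frozenset(pool[i - 1] for i in row["member_indices"]),
            row["composition_label"],
            int(row["richness"]),
        )
        for row in obj["consortia"]
    )
    return ConsortiumDesign(consortia, int(obj.get("replicates_per_consortium", 3)), tuple(pool))


def niche_breadth(matrix: AffinityMatrix, species: str) -> int:
    """Number of substrates utilized by one species."""
    return int(matrix.row(species).sum())


def community_metabolic_diversity(matrix: AffinityMatrix, consortium: Consortium) -> int:
    """CMD: number of unique substrates utilized by at least one member."""
    if not consortium.member_ids:
        raise DomainError("CMD undefined for an empty consortium")
    rows = np.stack([matrix.row(m) for m in sorted(consortium.member_ids)])
    return int(rows.any(axis=0).sum())


def pairwise_overlap(matrix: AffinityMatrix, a: str, b: str) -> float:
    """Jaccard overlap |A n B| / |A u B| of two species' substrate sets."""
    ra, rb = matrix.row(a), matrix.row(b)
    union = int(np.logical_or(ra, rb).sum())
    if union == 0:
        raise DomainError(f"overlap undefined: both {a!r} and {b!r} have zero breadth")
    inter = int(np.logical_and(ra, rb).sum())
    return inter / union


def community_redundancy(matrix: AffinityMatrix, consortium: Consortium) -> float:
    """1 - CMD / (sum of member breadths); 0 iff member profiles are disjoint."""
    breadth_sum = sum(niche_breadth(matrix, m) for m in consortium.member_ids)
    if breadth_sum == 0:
        raise DomainError("redundancy undefined: all members have zero breadth")
    return 1.0 - community_metabolic_diversity(matrix, consortium) / breadth_sum


def mean_pairwise_overlap(matrix: AffinityMatrix, consortium: Consortium) -> float:
    """Mean Jaccard overlap across member pairs (pairs with a nonzero union)."""
    members = sorted(consortium.member_ids)
    vals = []
    for i in range(len(members)):
        for j in range(i + 1, len(members)):
            ra, rb = matrix.row(members[i]), matrix.row(members[j])
            union = int(np.logical_or(ra, rb).sum())
            if union:
                vals.append(int(np.logical_and(ra, rb).sum()) / union)
    return float(np.mean(vals)) if vals else 0.0


@dataclass(frozen=True)
class NicheMetrics:
    breadth_per_species: Mapping[str, int]
    cmd: int
    mean_pairwise_overlap: float
    redundancy: float


def consortium_metrics(matrix: AffinityMatrix, consortium: Consortium) -> NicheMetrics:
    breadths = {m: niche_breadth(matrix, m) for m in sorted(consortium.member_ids)}
    return NicheMetrics(
        breadth_per_species=breadths,
        cmd=community_metabolic_diversity(matrix, consortium),
        mean_pairwise_overlap=mean_pairwise_overlap(matrix, consortium),
        redundancy=community_redundancy(matrix, consortium),
    )


def cmd_richness_curve(matrix: AffinityMatrix, design: ConsortiumDesign) -> pd.DataFrame:
    """One row per consortium: (richness, composition_label, cmd, redundancy)."""
    rows = []
    for c in design.consortia:
        rows.append(
            {
                "level": c.level,
                "richness": c.richness,
                "composition_label": c.composition_label,
                "cmd": community_metabolic_diversity(matrix, c),
                "redundancy": community_redundancy(matrix, c),
            }
        )
    return pd.DataFrame(rows)
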