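"""Segregation tests, recombinant screening, and candidate-interval delimitation.

Works on F2 fine-mapping tables: ordered markers with physical positions,
per-individual genotype codes in {A, H, B, missing} (A = homozygous for the
trait-negative parent, B = homozygous for the trait-positive parent) and a
phenotype per individual.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .synthio import PHENO_NEG, PHENO_POS

logger = logging.getLogger(__name__)

_CODES = {"A", "H", "B"}
MISSING = "-"


@dataclass
class MarkerGenotypeTable:
    """Individuals x ordered markers, with a phenotype vector.

    ``genotypes`` is a DataFrame indexed by individual id with one column per
    marker; ``positions`` maps marker name -> 1-based physical position and
    must be strictly increasing in marker order.
    """

    genotypes: pd.DataFrame
    positions: dict[str, int]
    phenotypes: pd.Series

    def __post_init__(self) -> None:
        markers = list(self.genotypes.columns)
        if list(self.positions) != markers:
            raise ValueError("positions must cover exactly the marker columns, in order")
        pos = list(self.positions.values())
        if any(b <= a for a, b in zip(pos, pos[1:])):
            raise ValueError("marker positions must be strictly increasing")
        if not self.phenotypes.index.equals(self.genotypes.index):
            raise ValueError("phenotype vector must cover every individual")
        bad = set(self.genotypes.values.ravel()) - _CODES - {MISSING}
        if bad:
            raise ValueError(f"unknown genotype codes: {sorted(bad)}")
        bad_ph = set(self.phenotypes) - {PHENO_POS, PHENO_NEG}
        if bad_ph:
            raise ValueError(f"unknown phenotypes: {sorted(bad_ph)}")

    @property
    def markers(self) -> list[str]:
        return list(self.genotypes.columns)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, positions: dict[str, int]) -> "MarkerGenotypeTable":
        """Build from a flat frame with ``id`` and ``phenotype`` columns."""
        df = df.set_index("id")
        phen = df.pop("phenotype")
        return cls(df[list(positions)], positions, phen)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "MarkerGenotypeTable":
        """TSV whose marker column headers are ``name@position``."""
        df = pd.read_csv(path, sep="\t", dtype=str)
        positions = {}
        rename = {}
        for col in df.columns:
            if "@" in col:
                name, pos = col.rsplit("@", 1)
                positions[name] = int(pos)
                rename[col] = name
        return cls.from_frame(df.rename(columns=rename), positions)

    def write_tsv(self, path: str | Path) -> None:
        df = self.genotypes.copy()
        df.columns = [f"{m}@{self.positions[m]}" for m in df.columns]
        df.insert(0, "phenotype", self.phenotypes)
        df.index.name = "id"
        df.reset_index().to_csv(path, sep="\t", index=False)

    def subset(self, ids: Sequence[str]) -> "MarkerGenotypeTable":
        return MarkerGenotypeTable(self.genotypes.loc[list(ids)], self.positions,
                                   self.phenotypes.loc[list(ids)])


@dataclass(frozen=True)
class IntervalCall:
    left_marker: str
    right_marker: str
    left_pos: int
    right_pos: int
    supporting_recombinants: tuple[str, ...]

    def to_dict(self) -> dict:
        return {
            "left_marker": self.left_marker, "right_marker": self.right_marker,
            "left_pos": self.left_pos, "right_pos": self.right_pos,
            "width_bp": self.right_pos - self.left_pos,
            "supporting_recombinants": list(self.supporting_recombinants),
        }


def segregation_chi2(observed: Sequence[int],
                     expected_ratio: Sequence[float]) -> tuple[float, int, float]:
    """Pearson chi-square of observed class counts against an expected ratio.

    Returns (chi2, df, p) with df = classes - 1.
    """
    observed = np.asarray(observed, dtype=float)
    ratio = np.asarray(expected_ratio, dtype=float)
    if observed.shape != ratio.shape:
        raise ValueError("observed and expected_ratio must have the same length")
    if np.any(observed < 0) or observed.sum() <= 0:
        raise ValueError("counts must be nonnegative with positive total")
    if np.any(ratio <= 0):
        raise ValueError("ratio terms must be positive")
    expected = observed.sum() * ratio / ratio.sum()
    chi2, p = stats.chisquare(observed, expected)
    return float(chi2), observed.size - 1, float(p)


def find_recombinants(table: MarkerGenotypeTable, left: str, right: str) -> list[str]:
    """Individuals whose genotypes at the two flanking markers differ.

    Individuals missing either genotype are excluded (and counted in the log).
    Symmetric in left/right.
    """
    for m in (left, right):
        if m not in table.genotypes.columns:
            raise KeyError(f"unknown marker {m!r}")
    g = table.genotypes
    informative = (g[left] != MISSING) & (g[right] != MISSING)
    n_dropped = int((~informative).sum())
    if n_dropped:
        logger.info("find_recombinants: %d individuals missing a flanking genotype", n_dropped)
    mask = informative & (g[left] != g[right])
    return list(g.index[mask])


def _trait_consistent(genotype: str, phenotype: str) -> bool:
    # dominant-B model: trait-negative must be A; trait-positive must carry B
    if phenotype == PHENO_NEG:
        return genotype == "A"
    return genotype in ("H", "B")


def delimit_interval(table: MarkerGenotypeTable,
                     trait_model: str = "dominant_B") -> IntervalCall:
    """Bound the causal locus using the recombinants' trait-inferred genotypes.

    Under dominant_B a trait-negative individual must be A at the causal
    locus and a trait-positive one H or B. Markers whose genotypes match the
    trait-inferred class are consistent for that individual; each maximal
    run of consistent markers [a, b] (bounded by mismatching markers or the
    table edges) allows the causal locus to lie in the inter-marker gaps
    a .. b+1 — a crossover inside a flanking gap explains the adjacent
    mismatch. The candidate interval is the intersection of every
    recombinant's allowed gaps (ties between equally wide feasible blocks go
    to the wider, leftmost one); its bounds are the markers immediately
    outside the feasible block, and ``supporting_recombinants`` are the
    individuals whose mismatches set those bounds. Missing genotypes are
    excluded per comparison: they neither break a run nor count as evidence.
    """
    if trait_model != "dominant_B":
        raise ValueError(f"unknown trait model {trait_model!r}")
    markers = table.markers
    if len(markers) < 2:
        raise ValueError("need at least 2 markers")
    if len(table.genotypes) == 0:
        raise ValueError("need at least 1 recombinant")
    n_m = len(markers)
    all_gaps = set(range(n_m + 1))  # gap j sits before marker j; j = n_m is the right edge
    feasible = set(all_gaps)
    allowed_by: dict[str, set[int]] = {}
    for ind_id, row in table.genotypes.iterrows():
        phen = table.phenotypes[ind_id]
        codes = [row[m] for m in markers]
        informative = [c != MISSING for c in codes]
        consistent = [inf and _trait_consistent(c, phen)
                      for c, inf in zip(codes, informative)]
        if not any(consistent):
            continue  # uninformative under this model (or genotyping error)
        allowed: set[int] = set()
        for a, b in _consistent_runs(consistent, informative):
            allowed.update(range(a, b + 2))
        allowed_by[ind_id] = allowed
        feasible &= allowed
    if not allowed_by or not feasible:
        raise ValueError("trait not linked to this region")
    g_lo, g_hi = _widest_block(feasible)
    li = max(g_lo - 1, 0)
    ri = min(g_hi, n_m - 1)
    supporting = [ind for ind, allowed in allowed_by.items()
                  if (g_lo > 0 and g_lo - 1 not in allowed)
                  or (g_hi < n_m and g_hi + 1 not in allowed)]
    return IntervalCall(
        left_marker=markers[li], right_marker=markers[ri],
        left_pos=table.positions[markers[li]], right_pos=table.positions[markers[ri]],
        supporting_recombinants=tuple(supporting),
    )


def _consistent_runs(consistent: list[bool], informative: list[bool]) -> list[tuple[int, int]]:
    """Maximal runs of consistent markers; missing markers bridge runs."""
    runs: list[tuple[int, int]] = []
    start = None
    for i, (cons, inf) in enumerate(zip(consistent, informative)):
        if cons or (not inf and start is not None):
            if start is None:
                start = i
        else:
            if start is not None:
                runs.append((start, i - 1))
            start = None
    if start is not None:
        runs.append((start, len(consistent) - 1))
    # trim trailing missing markers off each run end
    trimmed = []
    for a, b in runs:
        while b > a and not informative[b]:
            b -= 1
        trimmed.append((a, b))
    return trimmed


def _widest_block(gaps: set[int]) -> tuple[int, int]:
    """Bounds of the widest contiguous block of feasible gaps; ties -> leftmost."""
    best = None
    ordered = sorted(gaps)
    i = 0
    while i < len(ordered):
        j = i
        while j + 1 < len(ordered) and ordered[j + 1] == ordered[j] + 1:
            j += 1
        if best is None or ordered[j] - ordered[i] > best[1] - best[0]:
            best = (ordered[i], ordered[j])
        i = j + 1
    return best


def interval_width(left_pos: int, right_pos: int) -> int:
    """Physical distance between two marker anchor coordinates."""
    if left_pos >= right_pos:
        raise ValueError("left_pos must be strictly less than right_pos")
    return right_pos - left_pos


def write_interval_report(call: IntervalCall, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(call.to_dict(), fh, indent=2)
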