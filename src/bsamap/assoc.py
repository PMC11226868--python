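"""Genotype-phenotype association on germplasm panels.

Builds D/H/R frequency summaries, collapses carriers (D or H) against
non-carriers (R) into a 2x2 table, and computes Fisher's exact test in
log-space so that extreme P-values stay accurate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import hypergeom

from .synthio import PHENO_NEG, PHENO_POS

_GENOTYPES = ("D", "H", "R")


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Rows: phenotype (positive, negative); columns: carrier (D or H), non-carrier (R)."""

    a: int  # positive, carrier
    b: int  # positive, non-carrier
    c: int  # negative, carrier
    d: int  # negative, non-carrier

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cells must be nonnegative")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


def _round2(x: float) -> float:
    return float(Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def _validate_panel(panel: pd.DataFrame) -> None:
    if len(panel) == 0:
        raise ValueError("empty panel")
    for col in ("accession", "phenotype", "genotype"):
        if col not in panel.columns:
            raise ValueError(f"panel missing column {col!r}")
    bad = panel.loc[~panel["genotype"].isin(_GENOTYPES), "accession"]
    if len(bad):
        raise ValueError(f"unknown genotype code for accession(s): {', '.join(map(str, bad))}")
    bad = panel.loc[~panel["phenotype"].isin((PHENO_POS, PHENO_NEG)), "accession"]
    if len(bad):
        raise ValueError(f"unknown phenotype for accession(s): {', '.join(map(str, bad))}")


def genotype_frequencies(panel: pd.DataFrame) -> dict:
    """Per-phenotype D/H/R counts and within-phenotype percentages.

    Percentages are rounded half-up to 2 decimals.
    """
    _validate_panel(panel)
    out: dict = {}
    for phen in (PHENO_POS, PHENO_NEG):
        sub = panel[panel["phenotype"] == phen]
        counts = {g: int((sub["genotype"] == g).sum()) for g in _GENOTYPES}
        n = len(sub)
        pct = {g: (_round2(100.0 * counts[g] / n) if n else 0.0) for g in _GENOTYPES}
        out[phen] = {"n": n, "counts": counts, "percent": pct}
    return out


def carrier_table(panel: pd.DataFrame) -> ContingencyTable2x2:
    """Collapse D and H into 'carrier' against R, by phenotype row."""
    _validate_panel(panel)
    carrier = panel["genotype"].isin(("D", "H"))
    pos = panel["phenotype"] == PHENO_POS
    return ContingencyTable2x2(
        a=int((pos & carrier).sum()), b=int((pos & ~carrier).sum()),
        c=int((~pos & carrier).sum()), d=int((~pos & ~carrier).sum()),
    )


def fisher_exact(table: ContingencyTable2x2, sided: str = "two") -> float:
    """Fisher's exact test on a 2x2 table with fixed margins.

    Two-sided P sums the probabilities of all tables with the same margins
    whose point probability is <= the observed one (with a 1 + 1e-7 relative
    guard against floating-point ties); one-sided P is the tail in the
    direction of the observed association. Evaluated in log-space.
    """
    if table.total == 0:
        raise ValueError("all-zero table")
    a, b, c, d = table.a, table.b, table.c, table.d
    n = table.total
    row1 = a + b
    col1 = a + c
    k_min = max(0, row1 + col1 - n)
    k_max = min(row1, col1)
    ks = np.arange(k_min, k_max + 1)
    logp = hypergeom.logpmf(ks, n, row1, col1)
    log_obs = hypergeom.logpmf(a, n, row1, col1)
    if sided == "two":
        keep = logp <= log_obs + np.log1p(1e-7)
        return float(min(1.0, np.exp(logsumexp(logp[keep]))))
    if sided == "one":
        expected_a = row1 * col1 / n
        tail = ks >= a if a >= expected_a else ks <= a
        return float(min(1.0, np.exp(logsumexp(logp[tail]))))
    raise ValueError(f"sided must be 'two' or 'one', got {sided!r}")


def genotype_table_2x3(panel: pd.DataFrame) -> np.ndarray:
    """Full phenotype x {D,H,R} count table (extension; not the headline test)."""
    _validate_panel(panel)
    rows = []
    for phen in (PHENO_POS, PHENO_NEG):
        sub = panel[panel["phenotype"] == phen]
        rows.append([int((sub["genotype"] == g).sum()) for g in _GENOTYPES])
    return np.array(rows, dtype=np.int64)


def association_report(panel: pd.DataFrame) -> dict:
    freqs = genotype_frequencies(panel)
    table = carrier_table(panel)
    return {
        "genotype_frequencies": freqs,
        "carrier_table": {"a": table.a, "b": table.b, "c": table.c, "d": table.d},
        "fisher_p_two_sided": fisher_exact(table, "two"),
    }


def write_association_report(panel: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(association_report(panel), fh, indent=2)
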