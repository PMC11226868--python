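"""Delta(SNP-index) scanning with simulated no-QTL confidence envelopes.

Pipeline: per-SNP indices -> Monte-Carlo null CI table (depth grid) ->
sliding-window means -> merged significant regions. Pool 1 is the
trait-positive bulk, so delta = index_pool1 - index_pool2.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .variantio import VariantCall


@dataclass(frozen=True)
class BsaConfig:
    window_size_bp: int = 400_000
    step_bp: int = 200_000
    ci_replicates: int = 10_000
    n_per_bulk: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.window_size_bp, self.step_bp, self.ci_replicates, self.n_per_bulk) <= 0:
            raise ValueError("all BsaConfig values must be positive")
        if self.step_bp > self.window_size_bp:
            raise ValueError("step_bp must not exceed window_size_bp")


@dataclass(frozen=True)
class SnpIndexRecord:
    chrom: str
    pos: int
    index_pool1: float
    index_pool2: float
    delta: float
    depth_pool1: int
    depth_pool2: int


@dataclass(frozen=True)
class NullCiTable:
    """Empirical no-QTL bounds on delta, indexed by read depth.

    For each depth d, two F2 bulks of ``n_per_bulk`` are drawn at an
    unlinked locus (genotype probabilities 1/4 : 1/2 : 1/4), the pool allele
    frequency feeds a Binomial(d, p) read draw, and the bounds are the
    empirical 2.5/97.5 and 0.5/99.5 percentiles of delta over the replicates.
    """

    depth_grid: np.ndarray
    lo95: np.ndarray
    hi95: np.ndarray
    lo99: np.ndarray
    hi99: np.ndarray
    n_replicates: int
    n_per_bulk: int
    seed: int
    population_type: str = "F2"

    def bounds_for_depth(self, depth: float) -> tuple[float, float, float, float]:
        """(lo95, hi95, lo99, hi99) at the nearest grid depth."""
        i = int(np.argmin(np.abs(self.depth_grid - depth)))
        return (float(self.lo95[i]), float(self.hi95[i]),
                float(self.lo99[i]), float(self.hi99[i]))


@dataclass(frozen=True)
class WindowStat:
    chrom: str
    start: int  # 0-based half-open
    end: int
    n_snps: int
    mean_delta: float
    mean_lo95: float
    mean_hi95: float
    mean_lo99: float
    mean_hi99: float


@dataclass(frozen=True)
class SignificantRegion:
    chrom: str
    start: int
    end: int
    level: str  # "p05" | "p01"
    peak_delta: float


def snp_index(calls: Iterable[VariantCall]) -> list[SnpIndexRecord]:
    """Per-SNP alt-allele fraction in each pool and their difference."""
    out = []
    for c in calls:
        d1, d2 = c.depth_pool1, c.depth_pool2
        if d1 == 0 or d2 == 0:
            raise ValueError(
                f"{c.chrom}:{c.pos}: zero depth in a pool; filter before computing indices")
        i1 = c.alt_depth_pool1 / d1
        i2 = c.alt_depth_pool2 / d2
        out.append(SnpIndexRecord(c.chrom, c.pos, i1, i2, i1 - i2, d1, d2))
    return out


def null_ci(config: BsaConfig, depth_grid: Sequence[int]) -> NullCiTable:
    """Simulate the no-QTL null of delta for each depth on the grid."""
    depth_grid = np.asarray(sorted(depth_grid), dtype=np.int64)
    if depth_grid.size == 0 or depth_grid[0] <= 0:
        raise ValueError("depth_grid must be nonempty and positive")
    rng = np.random.default_rng(config.seed)
    n2 = 2 * config.n_per_bulk  # pool B-allele count ~ Binomial(2n, 1/2) at an unlinked locus
    lo95 = np.empty(depth_grid.size)
    hi95 = np.empty(depth_grid.size)
    lo99 = np.empty(depth_grid.size)
    hi99 = np.empty(depth_grid.size)
    for i, d in enumerate(depth_grid):
        p1 = rng.binomial(n2, 0.5, size=config.ci_replicates) / n2
        p2 = rng.binomial(n2, 0.5, size=config.ci_replicates) / n2
        delta = rng.binomial(d, p1) / d - rng.binomial(d, p2) / d
        lo99[i], lo95[i], hi95[i], hi99[i] = np.percentile(delta, [0.5, 2.5, 97.5, 99.5])
    return NullCiTable(depth_grid, lo95, hi95, lo99, hi99,
                       config.ci_replicates, config.n_per_bulk, config.seed)


def default_depth_grid(records: Sequence[SnpIndexRecord],
                       n_points: int = 12) -> list[int]:
    """A small grid spanning the harmonic-mean pool depths seen in the data."""
    hm = np.array([_harmonic_depth(r) for r in records])
    lo, hi = max(1, int(hm.min())), int(np.ceil(hm.max()))
    return sorted(set(np.linspace(lo, hi, min(n_points, hi - lo + 1)).round().astype(int).tolist()))


def _harmonic_depth(r: SnpIndexRecord) -> float:
    return 2.0 / (1.0 / r.depth_pool1 + 1.0 / r.depth_pool2)


def sliding_windows(records: Sequence[SnpIndexRecord], ci: NullCiTable,
                    config: BsaConfig) -> list[WindowStat]:
    """Average delta and depth-matched CI bounds in tiling windows.

    Windows are anchored at 0 on each chromosome and advance by ``step_bp``;
    a SNP at 1-based position p belongs to [start, start + window) when
    start <= p-1 < start + window (half-open, 0-based). Each SNP's bounds
    come from the null table at its harmonic-mean pool depth. Empty windows
    are omitted.
    """
    if config.window_size_bp <= 0 or config.step_bp <= 0:
        raise ValueError("window and step must be positive")
    windows: list[WindowStat] = []
    by_chrom: dict[str, list[SnpIndexRecord]] = {}
    for r in records:
        by_chrom.setdefault(r.chrom, []).append(r)
    for chrom in sorted(by_chrom):
        recs = sorted(by_chrom[chrom], key=lambda r: r.pos)
        pos0 = np.array([r.pos - 1 for r in recs])
        delta = np.array([r.delta for r in recs])
        bounds = np.array([ci.bounds_for_depth(_harmonic_depth(r)) for r in recs])
        max_pos = pos0[-1]
        start = 0
        while start <= max_pos:
            lo_i, hi_i = np.searchsorted(pos0, [start, start + config.window_size_bp])
            if hi_i > lo_i:
                sl = slice(lo_i, hi_i)
                windows.append(WindowStat(
                    chrom=chrom, start=start, end=start + config.window_size_bp,
                    n_snps=hi_i - lo_i,
                    mean_delta=float(delta[sl].mean()),
                    mean_lo95=float(bounds[sl, 0].mean()),
                    mean_hi95=float(bounds[sl, 1].mean()),
                    mean_lo99=float(bounds[sl, 2].mean()),
                    mean_hi99=float(bounds[sl, 3].mean()),
                ))
            start += config.step_bp
    return windows


def call_regions(windows: Sequence[WindowStat]) -> list[SignificantRegion]:
    """Merge consecutive significant windows into regions at each level.

    A window is significant at a level when its mean delta lies strictly
    outside the level's mean bounds. Overlapping or adjacent significant
    windows merge into [min start, max end]; peak_delta is the extremal
    window mean inside the region.
    """
    regions: list[SignificantRegion] = []
    for level, lo_attr, hi_attr in (("p05", "mean_lo95", "mean_hi95"),
                                    ("p01", "mean_lo99", "mean_hi99")):
        sig = [w for w in windows
               if w.mean_delta > getattr(w, hi_attr) or w.mean_delta < getattr(w, lo_attr)]
        sig.sort(key=lambda w: (w.chrom, w.start))
        cur: list[WindowStat] = []
        for w in sig:
            if cur and w.chrom == cur[-1].chrom and w.start <= cur[-1].end:
                cur.append(w)
            else:
                if cur:
                    regions.append(_make_region(cur, level))
                cur = [w]
        if cur:
            regions.append(_make_region(cur, level))
    regions.sort(key=lambda r: (r.chrom, r.start, r.level))
    return regions


def _make_region(windows: list[WindowStat], level: str) -> SignificantRegion:
    peak = max(windows, key=lambda w: abs(w.mean_delta)).mean_delta
    return SignificantRegion(
        chrom=windows[0].chrom,
        start=min(w.start for w in windows),
        end=max(w.end for w in windows),
        level=level,
        peak_delta=float(peak),
    )


# ---------------------------------------------------------------------------
# serialization

def snp_table(records: Sequence[SnpIndexRecord], ci: NullCiTable) -> pd.DataFrame:
    rows = []
    for r in records:
        lo95, hi95, lo99, hi99 = ci.bounds_for_depth(_harmonic_depth(r))
        rows.append((r.chrom, r.pos, r.index_pool1, r.index_pool2, r.delta,
                     r.depth_pool1, r.depth_pool2, lo95, hi95, lo99, hi99))
    return pd.DataFrame(rows, columns=[
        "chrom", "pos", "index_pool1", "index_pool2", "delta",
        "depth_pool1", "depth_pool2", "lo95", "hi95", "lo99", "hi99"])


def window_table(windows: Sequence[WindowStat]) -> pd.DataFrame:
    return pd.DataFrame(
        [(w.chrom, w.start, w.end, w.n_snps, w.mean_delta,
          w.mean_lo95, w.mean_hi95, w.mean_lo99, w.mean_hi99) for w in windows],
        columns=["chrom", "start", "end", "n_snps", "mean_delta",
                 "mean_lo95", "mean_hi95", "mean_lo99", "mean_hi99"])


def write_regions_bed(regions: Sequence[SignificantRegion], path: str | Path) -> None:
    """BED (0-based half-open) with the significance level in the name column."""
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.level}\t{r.peak_delta:.4f}\n")


def plot_scan(records: Sequence[SnpIndexRecord], windows: Sequence[WindowStat],
              path: str | Path) -> None:
    """Delta(SNP-index) scatter with windowed means and CI envelopes."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(10, 4))
    ax.scatter([r.pos for r in records], [r.delta for r in records],
               s=4, c="0.7", label="per-SNP delta")
    mids = [(w.start + w.end) / 2 for w in windows]
    ax.plot(mids, [w.mean_delta for w in windows], c="k", label="window mean")
    ax.plot(mids, [w.mean_hi95 for w in windows], c="green", lw=0.8, label="95% CI")
    ax.plot(mids, [w.mean_lo95 for w in windows], c="green", lw=0.8)
    ax.plot(mids, [w.mean_hi99 for w in windows], c="red", lw=0.8, label="99% CI")
    ax.plot(mids, [w.mean_lo99 for w in windows], c="red", lw=0.8)
    ax.set_xlabel("position (bp)")
    ax.set_ylabel("delta(SNP-index)")
    ax.legend(loc="upper left", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
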