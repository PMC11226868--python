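"""Seeded generators for every input the mapping pipeline consumes.

Simulates an F2 cross segregating a single dominant locus, pooled bulk
read depths over the F2, fine-mapping marker tables, and a germplasm panel
genotyped at a diagnostic SNP. All generators are deterministic under a
given seed: identical config + seed reproduces byte-identical output.

Model choices
-------------
* Crossovers: interference-free (Haldane map) — per gamete the crossover
  count is Poisson(map length in Morgans) with uniform positions.
* Bulks: individuals sampled without replacement, contributing equally.
* Per-SNP depth: negative binomial around ``mean_depth``; dispersion 0
  degenerates to a fixed depth.
* Bulks are treated as genomic allele pools; expression-level allele bias
  is deliberately not modelled.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .variantio import VariantCall, VariantRecords

PHENO_POS = "prickly"      # trait-positive: carries >=1 dominant B allele
PHENO_NEG = "prickleless"  # trait-negative: homozygous A at the causal locus

_DOSAGE_TO_CODE = {0: "AA", 1: "AB", 2: "BB"}

# 31-bp promoter haplotypes flanking the diagnostic SNP (position 16).
PROMOTER_HAPLOTYPE_POS = "GAGTTTTTTTTCAATATTTAAAATAGTTGAA"  # trait-positive allele
PROMOTER_HAPLOTYPE_NEG = "GAGTTTTTTTTCAATGTTTAAAATAGTTGAA"  # trait-negative allele
_HAPLOTYPE_SNP_OFFSET = 16  # 1-based position of the SNP within the 31-mer


@dataclass(frozen=True)
class F2SimConfig:
    """Design of a simulated F2 cross on one chromosome."""

    chrom_name: str
    chrom_length_bp: int
    n_individuals: int
    snp_positions: Sequence[int]
    causal_pos_bp: int | None = None
    dominance: bool = True  # dominant allele comes from the trait-positive parent (B)
    recomb_rate_cM_per_Mb: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.chrom_length_bp <= 0 or self.n_individuals <= 0:
            raise ValueError("chrom_length_bp and n_individuals must be positive")
        pos = np.asarray(self.snp_positions, dtype=np.int64)
        if pos.size and (np.any(np.diff(pos) <= 0)
                         or pos[0] < 1 or pos[-1] > self.chrom_length_bp):
            raise ValueError("snp_positions must be strictly increasing within [1, chrom_length_bp]")
        if self.causal_pos_bp is not None and not (1 <= self.causal_pos_bp <= self.chrom_length_bp):
            raise ValueError("causal_pos_bp outside chromosome")
        if self.recomb_rate_cM_per_Mb < 0:
            raise ValueError("recomb_rate_cM_per_Mb must be nonnegative")


@dataclass(frozen=True)
class F2Individual:
    """One F2 plant: per-SNP dosage of the B (trait-positive parent) allele."""

    id: str
    dosage: np.ndarray  # int8 in {0,1,2}, one entry per SNP position
    causal_dosage: int | None = None
    phenotype: str | None = None

    @property
    def genotypes(self) -> list[str]:
        """Genotype codes {AA, AB, BB} along the chromosome (A = P1 allele)."""
        return [_DOSAGE_TO_CODE[int(d)] for d in self.dosage]


@dataclass(frozen=True)
class BulkReadConfig:
    """Read-depth sampling for the two phenotype bulks."""

    n_per_bulk: int = 30
    mean_depth: int = 40
    depth_dispersion: float = 0.0  # NB dispersion; 0 = fixed depth
    decoy_fraction: float = 0.0    # fraction of SNPs emitted with sub-threshold quality
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_bulk <= 0 or self.mean_depth <= 0:
            raise ValueError("n_per_bulk and mean_depth must be positive")
        if self.depth_dispersion < 0 or not (0 <= self.decoy_fraction <= 1):
            raise ValueError("invalid depth_dispersion or decoy_fraction")


@dataclass(frozen=True)
class PanelSimConfig:
    """Germplasm panel: phenotype classes and genotype codes at one SNP.

    Defaults mirror a 190-accession panel with 18 trait-positive and 172
    trait-negative accessions, 6 of the latter discordantly carrying the
    D genotype.
    """

    n_prickly: int = 18
    n_prickleless: int = 172
    n_discordant_prickleless_D: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_prickly, self.n_prickleless, self.n_discordant_prickleless_D) < 0:
            raise ValueError("panel counts must be nonnegative")
        if self.n_discordant_prickleless_D > self.n_prickleless:
            raise ValueError("n_discordant_prickleless_D exceeds n_prickleless")


def _simulate_gametes(rng: np.random.Generator, n_gametes: int,
                      eval_positions: np.ndarray, chrom_length_bp: int,
                      recomb_rate_cM_per_Mb: float) -> np.ndarray:
    """Alleles (0/1) carried by each gamete at each evaluation position."""
    map_length_morgans = recomb_rate_cM_per_Mb * (chrom_length_bp / 1e6) / 100.0
    alleles = np.empty((n_gametes, eval_positions.size), dtype=np.int8)
    start = rng.integers(0, 2, size=n_gametes)
    n_xo = rng.poisson(map_length_morgans, size=n_gametes)
    for g in range(n_gametes):
        if n_xo[g] == 0:
            alleles[g] = start[g]
            continue
        xo = np.sort(rng.uniform(1.0, chrom_length_bp, size=n_xo[g]))
        parity = np.searchsorted(xo, eval_positions) % 2
        alleles[g] = (start[g] + parity) % 2
    return alleles


def simulate_f2(config: F2SimConfig, assign_phenotypes: bool = True) -> list[F2Individual]:
    """Simulate F2 individuals from two independent recombinant gametes each.

    Phenotypes follow full dominance at the causal locus: dosage >= 1 of the
    B allele gives the trait-positive phenotype. Expected segregation is 3:1.
    """
    if assign_phenotypes and config.causal_pos_bp is None:
        raise ValueError("no causal locus: cannot assign phenotypes without causal_pos_bp")
    rng = np.random.default_rng(config.seed)
    snp_pos = np.asarray(config.snp_positions, dtype=np.float64)
    eval_pos = snp_pos
    causal_idx = None
    if config.causal_pos_bp is not None:
        eval_pos = np.append(snp_pos, float(config.causal_pos_bp))
        causal_idx = snp_pos.size
    n = config.n_individuals
    gametes = _simulate_gametes(rng, 2 * n, eval_pos, config.chrom_length_bp,
                                config.recomb_rate_cM_per_Mb)
    dosage = gametes[0::2] + gametes[1::2]
    individuals = []
    for i in range(n):
        causal_dosage = int(dosage[i, causal_idx]) if causal_idx is not None else None
        phenotype = None
        if assign_phenotypes:
            phenotype = PHENO_POS if causal_dosage >= 1 else PHENO_NEG
        individuals.append(F2Individual(
            id=f"F2_{i + 1:05d}",
            dosage=dosage[i, :snp_pos.size].copy(),
            causal_dosage=causal_dosage,
            phenotype=phenotype,
        ))
    return individuals


def _draw_depths(rng: np.random.Generator, n: int, mean_depth: int,
                 dispersion: float) -> np.ndarray:
    if dispersion == 0:
        return np.full(n, mean_depth, dtype=np.int64)
    # NB with mean m, variance m + m^2/k where k = 1/dispersion
    k = 1.0 / dispersion
    p = k / (k + mean_depth)
    return rng.negative_binomial(k, p, size=n)


def _random_alleles(rng: np.random.Generator, n: int) -> tuple[np.ndarray, np.ndarray]:
    bases = np.array(list("ACGT"))
    ref = rng.integers(0, 4, size=n)
    alt = (ref + rng.integers(1, 4, size=n)) % 4
    return bases[ref], bases[alt]


def simulate_bulk_reads(individuals: Sequence[F2Individual], config: BulkReadConfig,
                        chrom_name: str, snp_positions: Sequence[int],
                        split: str = "phenotype") -> VariantRecords:
    """Sample pooled allele depths for the two bulks at every SNP.

    For each SNP and bulk the true pool allele frequency is the mean B-allele
    dosage / 2 over the sampled individuals; the alt depth is then
    Binomial(d, p) with d from the configured depth law. Pool 1 is the
    trait-positive bulk. ``split="random"`` draws both bulks at random
    irrespective of phenotype (a no-QTL null).
    """
    rng = np.random.default_rng(config.seed)
    n_ind = len(individuals)
    if split == "phenotype":
        pos_idx = [i for i, ind in enumerate(individuals) if ind.phenotype == PHENO_POS]
        neg_idx = [i for i, ind in enumerate(individuals) if ind.phenotype == PHENO_NEG]
        if len(pos_idx) < config.n_per_bulk or len(neg_idx) < config.n_per_bulk:
            raise ValueError(
                f"insufficient individuals per phenotype: "
                f"{len(pos_idx)} {PHENO_POS} / {len(neg_idx)} {PHENO_NEG}, "
                f"need {config.n_per_bulk} each")
        bulk1 = rng.choice(pos_idx, size=config.n_per_bulk, replace=False)
        bulk2 = rng.choice(neg_idx, size=config.n_per_bulk, replace=False)
    elif split == "random":
        if n_ind < 2 * config.n_per_bulk:
            raise ValueError("insufficient individuals for two random bulks")
        picked = rng.choice(n_ind, size=2 * config.n_per_bulk, replace=False)
        bulk1, bulk2 = picked[:config.n_per_bulk], picked[config.n_per_bulk:]
    else:
        raise ValueError(f"unknown split mode {split!r}")

    dosage = np.stack([ind.dosage for ind in individuals])  # (n_ind, n_snp)
    snp_positions = np.asarray(snp_positions, dtype=np.int64)
    n_snp = snp_positions.size
    if dosage.shape[1] != n_snp:
        raise ValueError("snp_positions length does not match individual genotype vectors")

    p1 = dosage[bulk1].mean(axis=0) / 2.0
    p2 = dosage[bulk2].mean(axis=0) / 2.0
    d1 = _draw_depths(rng, n_snp, config.mean_depth, config.depth_dispersion)
    d2 = _draw_depths(rng, n_snp, config.mean_depth, config.depth_dispersion)
    alt1 = rng.binomial(d1, p1)
    alt2 = rng.binomial(d2, p2)
    ref_allele, alt_allele = _random_alleles(rng, n_snp)
    mq = np.round(50.0 + 10.0 * rng.random(n_snp), 2)
    bq = np.round(30.0 + 10.0 * rng.random(n_snp), 2)

    is_decoy = rng.random(n_snp) < config.decoy_fraction
    decoy_kind = rng.integers(0, 3, size=n_snp)  # 0: low depth, 1: low MQ, 2: low BQ
    for j in np.nonzero(is_decoy)[0]:
        if decoy_kind[j] == 0:
            cap = rng.integers(0, 20)
            d1[j] = cap
            alt1[j] = rng.binomial(cap, p1[j])
        elif decoy_kind[j] == 1:
            mq[j] = np.round(rng.uniform(0, 19.99), 2)
        else:
            bq[j] = np.round(rng.uniform(0, 19.99), 2)

    records = [
        VariantCall(
            chrom=chrom_name, pos=int(snp_positions[j]),
            ref_allele=str(ref_allele[j]), alt_allele=str(alt_allele[j]),
            ref_depth_pool1=int(d1[j] - alt1[j]), alt_depth_pool1=int(alt1[j]),
            ref_depth_pool2=int(d2[j] - alt2[j]), alt_depth_pool2=int(alt2[j]),
            mapping_quality=float(mq[j]), base_quality=float(bq[j]),
        )
        for j in range(n_snp)
    ]
    return VariantRecords(records)


def simulate_panel(config: PanelSimConfig) -> pd.DataFrame:
    """Germplasm panel table: one row per accession with phenotype and D/H/R code.

    Trait-positive accessions draw their genotype from {D, H}; trait-negative
    accessions are R except for the configured discordant count coded D.
    """
    rng = np.random.default_rng(config.seed)
    rows = []
    for i in range(config.n_prickly):
        code = rng.choice(["D", "H"])
        rows.append((f"ACC_P{i + 1:03d}", PHENO_POS, code))
    neg_codes = np.array(["R"] * config.n_prickleless, dtype=object)
    discordant = rng.choice(config.n_prickleless, size=config.n_discordant_prickleless_D,
                            replace=False) if config.n_discordant_prickleless_D else []
    neg_codes[list(discordant)] = "D"
    for i in range(config.n_prickleless):
        rows.append((f"ACC_N{i + 1:03d}", PHENO_NEG, neg_codes[i]))
    return pd.DataFrame(rows, columns=["accession", "phenotype", "genotype"])


class PromoterFixtures(NamedTuple):
    prickly: str
    prickleless: str
    embed: Callable[[str, int, int], str]


def embed_haplotype(haplotype: str, amplicon_length: int, snp_offset_1based: int) -> str:
    """Pad a promoter haplotype into an amplicon with its SNP at a fixed offset.

    Padding is G/C-only so no A/T-containing recognition site can span the
    junctions or the pad. Raises if the haplotype does not fit.
    """
    start = snp_offset_1based - _HAPLOTYPE_SNP_OFFSET  # 0-based insert position
    if start < 0 or start + len(haplotype) > amplicon_length:
        raise ValueError(
            f"snp offset {snp_offset_1based} incompatible with amplicon length {amplicon_length}")
    pad = "GC" * amplicon_length
    return pad[:start] + haplotype + pad[: amplicon_length - start - len(haplotype)]


def fixture_sequences() -> PromoterFixtures:
    """The two printed 31-bp promoter haplotypes plus an amplicon constructor."""
    return PromoterFixtures(PROMOTER_HAPLOTYPE_POS, PROMOTER_HAPLOTYPE_NEG, embed_haplotype)


def caps_amplicons(amplicon_length: int = 391, snp_offset_1based: int = 153) -> tuple[str, str]:
    """Reconstructed diagnostic amplicons for the D and R alleles.

    With the defaults the D allele's single enzyme site cuts after base 152,
    so digestion yields 152 + 239 bp fragments while the R allele stays
    uncut at 391 bp.
    """
    fx = fixture_sequences()
    return (embed_haplotype(fx.prickly, amplicon_length, snp_offset_1based),
            embed_haplotype(fx.prickleless, amplicon_length, snp_offset_1based))


def marker_table_from_f2(individuals: Sequence[F2Individual],
                         snp_positions: Sequence[int],
                         marker_positions: Sequence[int],
                         marker_names: Sequence[str] | None = None) -> pd.DataFrame:
    """Extract a marker-genotype table (codes A/H/B) at a subset of SNP positions.

    Returns a DataFrame with one row per individual: ``id``, ``phenotype``,
    then one column per marker. Column names carry no positions; use
    :func:`bsamap.genmap.MarkerGenotypeTable` to attach them.
    """
    snp_positions = np.asarray(snp_positions, dtype=np.int64)
    marker_positions = np.asarray(marker_positions, dtype=np.int64)
    idx = np.searchsorted(snp_positions, marker_positions)
    if np.any(idx >= snp_positions.size) or np.any(snp_positions[idx] != marker_positions):
        raise ValueError("marker positions must be a subset of snp_positions")
    if marker_names is None:
        marker_names = [f"M{i + 1:02d}" for i in range(marker_positions.size)]
    code = {0: "A", 1: "H", 2: "B"}
    rows = []
    for ind in individuals:
        rows.append([ind.id, ind.phenotype] + [code[int(ind.dosage[j])] for j in idx])
    return pd.DataFrame(rows, columns=["id", "phenotype", *marker_names])
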