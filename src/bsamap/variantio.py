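"""Variant table I/O (VCF dialect and TSV) and SNP retention filtering.

The on-disk contract is a two-pool variant table: each record carries
per-pool ref/alt allele depths plus site-level mapping and base quality.
Pool 1 is the bulk of trait-positive individuals by convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd
import pysam

logger = logging.getLogger(__name__)

_BASES = frozenset("ACGT")

TSV_COLUMNS = [
    "chrom", "pos", "ref", "alt",
    "ad_ref_p1", "ad_alt_p1", "ad_ref_p2", "ad_alt_p2",
    "mq", "bq",
]


@dataclass(frozen=True)
class VariantCall:
    """One biallelic SNP with two-pool allele depths and quality fields."""

    chrom: str
    pos: int  # 1-based
    ref_allele: str
    alt_allele: str
    ref_depth_pool1: int
    alt_depth_pool1: int
    ref_depth_pool2: int
    alt_depth_pool2: int
    mapping_quality: float
    base_quality: float

    def __post_init__(self) -> None:
        if self.ref_allele not in _BASES or self.alt_allele not in _BASES:
            raise ValueError(
                f"{self.chrom}:{self.pos}: alleles must be single bases in ACGT, "
                f"got {self.ref_allele!r}/{self.alt_allele!r}"
            )
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"{self.chrom}:{self.pos}: ref and alt alleles are identical")
        for name in ("ref_depth_pool1", "alt_depth_pool1", "ref_depth_pool2", "alt_depth_pool2"):
            if getattr(self, name) < 0:
                raise ValueError(f"{self.chrom}:{self.pos}: negative depth in {name}")

    @property
    def depth_pool1(self) -> int:
        return self.ref_depth_pool1 + self.alt_depth_pool1

    @property
    def depth_pool2(self) -> int:
        return self.ref_depth_pool2 + self.alt_depth_pool2


class VariantRecords(list):
    """A sorted list of :class:`VariantCall` that remembers skipped input rows."""

    def __init__(self, records: Iterable[VariantCall] = (), n_skipped: int = 0):
        super().__init__(records)
        self.n_skipped = n_skipped


@dataclass(frozen=True)
class FilterResult:
    retained: VariantRecords
    tallies: dict  # per-criterion rejection counts


def _sorted_records(records: Iterable[VariantCall], n_skipped: int) -> VariantRecords:
    out = VariantRecords(sorted(records, key=lambda r: (r.chrom, r.pos)), n_skipped)
    return out


def read_variants(path: str | Path, format: str | None = None) -> VariantRecords:
    """Read a two-pool variant table.

    Multi-allelic or non-SNP records are skipped; the skip count is logged
    and exposed as ``.n_skipped`` on the returned collection. Records come
    back sorted by (chrom, pos).
    """
    path = Path(path)
    if format is None:
        format = "vcf" if path.suffix.lower() == ".vcf" else "tsv"
    if format == "vcf":
        return _read_vcf(path)
    if format == "tsv":
        return _read_tsv(path)
    raise ValueError(f"unknown variant table format: {format!r}")


def _read_vcf(path: Path) -> VariantRecords:
    records: list[VariantCall] = []
    n_skipped = 0
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        if len(samples) != 2:
            raise ValueError(f"{path}: expected exactly 2 pool samples, found {len(samples)}")
        for rec in vcf:
            alts = rec.alts or ()
            if len(alts) != 1 or len(rec.ref) != 1 or len(alts[0]) != 1 \
                    or rec.ref not in _BASES or alts[0] not in _BASES:
                n_skipped += 1
                continue
            ads = []
            for s in samples:
                ad = rec.samples[s].get("AD")
                if ad is None or ad[0] is None:
                    raise ValueError(f"{path}: record {rec.chrom}:{rec.pos} missing AD field")
                ads.append((int(ad[0]), int(ad[1])))
            mq = rec.info.get("MQ")
            bq = rec.info.get("BQ")
            if mq is None or bq is None:
                raise ValueError(f"{path}: record {rec.chrom}:{rec.pos} missing MQ/BQ INFO")
            records.append(VariantCall(
                chrom=rec.chrom, pos=rec.pos,
                ref_allele=rec.ref, alt_allele=alts[0],
                ref_depth_pool1=ads[0][0], alt_depth_pool1=ads[0][1],
                ref_depth_pool2=ads[1][0], alt_depth_pool2=ads[1][1],
                mapping_quality=float(mq), base_quality=float(bq),
            ))
    if n_skipped:
        logger.info("read_variants: skipped %d non-SNP/multi-allelic records", n_skipped)
    return _sorted_records(records, n_skipped)


def _read_tsv(path: Path) -> VariantRecords:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = set(TSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing TSV columns {sorted(missing)}")
    records: list[VariantCall] = []
    n_skipped = 0
    for row in df.itertuples(index=False):
        if len(row.ref) != 1 or len(row.alt) != 1 or row.ref not in _BASES or row.alt not in _BASES:
            n_skipped += 1
            continue
        records.append(VariantCall(
            chrom=row.chrom, pos=int(row.pos),
            ref_allele=row.ref, alt_allele=row.alt,
            ref_depth_pool1=int(row.ad_ref_p1), alt_depth_pool1=int(row.ad_alt_p1),
            ref_depth_pool2=int(row.ad_ref_p2), alt_depth_pool2=int(row.ad_alt_p2),
            mapping_quality=float(row.mq), base_quality=float(row.bq),
        ))
    if n_skipped:
        logger.info("read_variants: skipped %d non-SNP rows", n_skipped)
    return _sorted_records(records, n_skipped)


def write_variants(records: Iterable[VariantCall], path: str | Path,
                   format: str | None = None,
                   contig_lengths: dict[str, int] | None = None,
                   sample_names: tuple[str, str] = ("pool1", "pool2")) -> None:
    """Write records as uncompressed VCF or flat TSV."""
    path = Path(path)
    if format is None:
        format = "vcf" if path.suffix.lower() == ".vcf" else "tsv"
    records = sorted(records, key=lambda r: (r.chrom, r.pos))
    if format == "tsv":
        df = pd.DataFrame(
            [(r.chrom, r.pos, r.ref_allele, r.alt_allele,
              r.ref_depth_pool1, r.alt_depth_pool1, r.ref_depth_pool2, r.alt_depth_pool2,
              r.mapping_quality, r.base_quality) for r in records],
            columns=TSV_COLUMNS,
        )
        df.to_csv(path, sep="\t", index=False)
        return
    if format != "vcf":
        raise ValueError(f"unknown variant table format: {format!r}")

    header = pysam.VariantHeader()
    header.add_meta("source", "bsamap")
    contigs: dict[str, int] = dict(contig_lengths or {})
    for r in records:
        contigs[r.chrom] = max(contigs.get(r.chrom, 0), r.pos)
    for chrom, length in contigs.items():
        header.contigs.add(chrom, length=length)
    header.info.add("MQ", 1, "Float", "RMS mapping quality")
    header.info.add("BQ", 1, "Float", "Mean base quality at site")
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("AD", "R", "Integer", "Allelic depths (ref, alt)")
    header.formats.add("DP", 1, "Integer", "Total depth")
    for name in sample_names:
        header.add_sample(name)
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for r in records:
            rec = vcf.new_record(
                contig=r.chrom, start=r.pos - 1, stop=r.pos,
                alleles=(r.ref_allele, r.alt_allele),
            )
            rec.info["MQ"] = float(r.mapping_quality)
            rec.info["BQ"] = float(r.base_quality)
            for name, (ad_ref, ad_alt) in zip(
                    sample_names,
                    [(r.ref_depth_pool1, r.alt_depth_pool1),
                     (r.ref_depth_pool2, r.alt_depth_pool2)]):
                rec.samples[name]["GT"] = (None, None)
                rec.samples[name]["AD"] = (ad_ref, ad_alt)
                rec.samples[name]["DP"] = ad_ref + ad_alt
            vcf.write(rec)


def filter_variants(calls: Iterable[VariantCall],
                    min_depth: int = 20,
                    min_mq: float = 20.0,
                    min_bq: float = 20.0) -> FilterResult:
    """Apply the SNP retention filters.

    A record is kept when BOTH pools have total depth >= ``min_depth`` (the
    depth criterion is per pool: a shallow pool makes its SNP-index
    unreliable) and its mapping and base qualities meet their inclusive
    thresholds. Input order is preserved; a record can fail several criteria
    and then counts in every tally it fails.
    """
    retained: list[VariantCall] = []
    tallies = {"depth": 0, "mq": 0, "bq": 0}
    for r in calls:
        ok = True
        if r.depth_pool1 < min_depth or r.depth_pool2 < min_depth:
            tallies["depth"] += 1
            ok = False
        if r.mapping_quality < min_mq:
            tallies["mq"] += 1
            ok = False
        if r.base_quality < min_bq:
            tallies["bq"] += 1
            ok = False
        if ok:
            retained.append(r)
    return FilterResult(VariantRecords(retained), tallies)
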