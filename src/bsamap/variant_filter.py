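"""Site selection and polarization for bulk-sequencing variant tables.

Reads a four-sample VCF (two parents, two phenotype bulks), keeps
biallelic SNPs where the parents are homozygous for opposite alleles
and both bulks are adequately covered, and orients each site so the
"index allele" is the green-parent allele.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd
from cyvcf2 import VCF

logger = logging.getLogger(__name__)

__all__ = [
    "VariantSite",
    "FilterConfig",
    "ReadStats",
    "read_variants",
    "select_informative",
    "polarize",
    "write_sites_tsv",
    "read_sites_tsv",
]

HOM_REF = "hom_ref"
HOM_ALT = "hom_alt"
HET = "het"
MISSING = "missing"

# cyvcf2 gt_types: 0=HOM_REF 1=HET 2=UNKNOWN 3=HOM_ALT
_CYVCF2_GT = {0: HOM_REF, 1: HET, 2: MISSING, 3: HOM_ALT}


@dataclass(frozen=True)
class VariantSite:
    """One biallelic SNP with parental genotypes and per-bulk depths.

    ``index_allele`` is None until :func:`polarize` orients the site;
    afterwards it names which VCF allele ("ref"/"alt") is the
    green-parent allele.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    qual: float
    parent_yellow_gt: str
    parent_green_gt: str
    bulk_yellow_ref: int
    bulk_yellow_alt: int
    bulk_green_ref: int
    bulk_green_alt: int
    index_allele: str | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError("pos must be >= 1")
        for d in (
            self.bulk_yellow_ref,
            self.bulk_yellow_alt,
            self.bulk_green_ref,
            self.bulk_green_alt,
        ):
            if d < 0:
                raise ValueError("depths must be non-negative")

    def bulk_depth(self, bulk: str) -> int:
        if bulk == "yellow":
            return self.bulk_yellow_ref + self.bulk_yellow_alt
        return self.bulk_green_ref + self.bulk_green_alt

    def _oriented(self, ref_d: int, alt_d: int) -> tuple[int, int]:
        if self.index_allele is None:
            raise ValueError("site not polarized")
        return (alt_d, ref_d) if self.index_allele == "alt" else (ref_d, alt_d)

    def green_counts(self) -> tuple[int, int]:
        """(index-allele reads, other reads) in the green bulk."""
        return self._oriented(self.bulk_green_ref, self.bulk_green_alt)

    def yellow_counts(self) -> tuple[int, int]:
        """(index-allele reads, other reads) in the yellow bulk."""
        return self._oriented(self.bulk_yellow_ref, self.bulk_yellow_alt)


@dataclass(frozen=True)
class FilterConfig:
    min_bulk_depth: int = 10
    min_qual: float = 100.0
    require_parents_homozygous_opposite: bool = True
    depth_rule: str = "both"  # "both" or "either" bulk must reach min depth

    def __post_init__(self) -> None:
        if self.min_bulk_depth < 0 or self.min_qual < 0:
            raise ValueError("thresholds must be >= 0")
        if self.depth_rule not in ("both", "either"):
            raise ValueError("depth_rule must be 'both' or 'either'")


@dataclass
class ReadStats:
    n_records: int = 0
    n_yielded: int = 0
    n_multiallelic: int = 0
    n_indel: int = 0
    n_bad_format: int = 0


def read_variants(
    vcf_path,
    sample_map: Mapping[str, str] | None = None,
    stats: ReadStats | None = None,
) -> Iterator[VariantSite]:
    """Stream biallelic SNPs out of a four-sample VCF.

    ``sample_map`` maps the roles parent_yellow / parent_green /
    bulk_yellow / bulk_green to sample names in the file; by default the
    role names themselves are expected as sample names.  Multiallelic
    records, indels and records with unparseable AD are skipped and
    counted.
    """
    roles = ("parent_yellow", "parent_green", "bulk_yellow", "bulk_green")
    if sample_map is None:
        sample_map = {r: r for r in roles}
    vcf = VCF(str(vcf_path))
    try:
        idx = {}
        for role in roles:
            name = sample_map[role]
            if name not in vcf.samples:
                raise ValueError(f"sample {name!r} (role {role}) not found in VCF")
            idx[role] = vcf.samples.index(name)
        if stats is None:
            stats = ReadStats()
        for rec in vcf:
            stats.n_records += 1
            if len(rec.ALT) != 1:
                stats.n_multiallelic += 1
                continue
            if len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
                stats.n_indel += 1
                continue
            ad = rec.format("AD")
            if ad is None or ad.shape[1] < 2:
                stats.n_bad_format += 1
                logger.warning("record %s:%d lacks AD; skipped", rec.CHROM, rec.POS)
                continue
            ad = np.where(ad < 0, 0, ad)  # cyvcf2 encodes missing as negative
            gt = rec.gt_types
            stats.n_yielded += 1
            yield VariantSite(
                chrom=rec.CHROM,
                pos=rec.POS,
                ref=rec.REF,
                alt=rec.ALT[0],
                qual=float(rec.QUAL) if rec.QUAL is not None else 0.0,
                parent_yellow_gt=_CYVCF2_GT[gt[idx["parent_yellow"]]],
                parent_green_gt=_CYVCF2_GT[gt[idx["parent_green"]]],
                bulk_yellow_ref=int(ad[idx["bulk_yellow"], 0]),
                bulk_yellow_alt=int(ad[idx["bulk_yellow"], 1]),
                bulk_green_ref=int(ad[idx["bulk_green"], 0]),
                bulk_green_alt=int(ad[idx["bulk_green"], 1]),
            )
        if stats.n_multiallelic or stats.n_indel or stats.n_bad_format:
            logger.info(
                "skipped %d multiallelic, %d indel, %d malformed records",
                stats.n_multiallelic,
                stats.n_indel,
                stats.n_bad_format,
            )
    finally:
        vcf.close()


def _depth_ok(site: VariantSite, config: FilterConfig) -> bool:
    dy = site.bulk_depth("yellow")
    dg = site.bulk_depth("green")
    if config.depth_rule == "both":
        return dy >= config.min_bulk_depth and dg >= config.min_bulk_depth
    return dy >= config.min_bulk_depth or dg >= config.min_bulk_depth


def select_informative(
    sites: Iterable[VariantSite], config: FilterConfig | None = None
) -> list[VariantSite]:
    """Apply the site-selection filters, preserving input order.

    A site passes when the parents are homozygous for different alleles,
    QUAL reaches ``min_qual``, and the bulk depth rule is satisfied.
    """
    if config is None:
        config = FilterConfig()
    out = []
    opposite = {(HOM_REF, HOM_ALT), (HOM_ALT, HOM_REF)}
    for site in sites:
        if config.require_parents_homozygous_opposite:
            if (site.parent_yellow_gt, site.parent_green_gt) not in opposite:
                continue
        if site.qual < config.min_qual:
            continue
        if not _depth_ok(site, config):
            continue
        out.append(site)
    return out


def polarize(site: VariantSite) -> VariantSite:
    """Orient a site so the index allele is the green-parent allele.

    Idempotent; requires an unambiguous homozygous green-parent
    genotype.
    """
    if site.index_allele is not None:
        return site
    if site.parent_green_gt == HOM_ALT:
        return replace(site, index_allele="alt")
    if site.parent_green_gt == HOM_REF:
        return replace(site, index_allele="ref")
    raise ValueError(
        f"cannot polarize {site.chrom}:{site.pos}: green parent is "
        f"{site.parent_green_gt}"
    )


_TSV_COLUMNS = [
    "chrom",
    "pos",
    "ref",
    "alt",
    "qual",
    "parent_yellow_gt",
    "parent_green_gt",
    "bulk_yellow_ref",
    "bulk_yellow_alt",
    "bulk_green_ref",
    "bulk_green_alt",
    "index_allele",
]


def write_sites_tsv(sites: Iterable[VariantSite], path) -> None:
    df = pd.DataFrame(
        [
            {c: ("" if getattr(s, c) is None else getattr(s, c)) for c in _TSV_COLUMNS}
            for s in sites
        ],
        columns=_TSV_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def read_sites_tsv(path) -> list[VariantSite]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False, dtype={"index_allele": str})
    out = []
    for r in df.itertuples():
        out.append(
            VariantSite(
                chrom=str(r.chrom),
                pos=int(r.pos),
                ref=str(r.ref),
                alt=str(r.alt),
                qual=float(r.qual),
                parent_yellow_gt=str(r.parent_yellow_gt),
                parent_green_gt=str(r.parent_green_gt),
                bulk_yellow_ref=int(r.bulk_yellow_ref),
                bulk_yellow_alt=int(r.bulk_yellow_alt),
                bulk_green_ref=int(r.bulk_green_ref),
                bulk_green_alt=int(r.bulk_green_alt),
                index_allele=r.index_allele or None,
            )
        )
    return out
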