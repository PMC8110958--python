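"""Population and spatial summary statistics over called SNPs.

MAF and observed heterozygosity are genotype-based (allele counts over called
diploid genotypes). Inter-SNP distances are between consecutive variants on
the same chromosome only — a cross-chromosome distance is physically
undefined. Summary means are reported with the population SD (divisor n) by
default; pass ``sample_sd=True`` for the n-1 divisor.
"""

from __future__ import annotations

import logging
from typing import Iterable, Optional

import numpy as np

from .models import GenomicInterval, Variant

logger = logging.getLogger(__name__)


def compute_maf(v: Variant) -> Optional[float]:
    """Minor allele frequency min(p, 1-p) over called alleles; None if no calls."""
    alleles = [a for gt in v.genotypes if gt is not None for a in gt]
    if not alleles:
        logger.warning("all genotypes missing at %s:%d; excluded", v.chrom, v.vcf_pos)
        return None
    p = sum(alleles) / len(alleles)
    return min(p, 1 - p)


def compute_obs_het(v: Variant) -> Optional[float]:
    """Fraction of called genotypes that are heterozygous; None if no calls."""
    called = [gt for gt in v.genotypes if gt is not None]
    if not called:
        logger.warning("all genotypes missing at %s:%d; excluded", v.chrom, v.vcf_pos)
        return None
    het = sum(1 for gt in called if gt[0] != gt[1])
    return het / len(called)


def inter_snp_distances(variants: Iterable[Variant]) -> dict:
    """Distance stats (bp) between consecutive distinct sites per chromosome.

    Split multi-allelic records share one physical site, so positions are
    deduplicated before differencing.
    """
    by_chrom: dict[str, set[int]] = {}
    for v in variants:
        by_chrom.setdefault(v.chrom, set()).add(v.pos)
    dists: list[int] = []
    for pos_set in by_chrom.values():
        positions = sorted(pos_set)
        dists.extend(b - a for a, b in zip(positions, positions[1:]))
    if not dists:
        return {"n": 0, "mean_bp": None, "sd_bp": None, "min_bp": None, "max_bp": None}
    arr = np.asarray(dists, dtype=float)
    return {
        "n": len(dists),
        "mean_bp": float(arr.mean()),
        "sd_bp": float(arr.std()),
        "min_bp": int(arr.min()),
        "max_bp": int(arr.max()),
    }


def density_per_kb(n_snps: int, region_length_bp: int) -> float:
    """SNPs per kilobase over a region, reported to one decimal."""
    if region_length_bp <= 0:
        raise ValueError("region length must be positive")
    return round(n_snps / (region_length_bp / 1000.0), 1)


def coverage_percent(covered_bp: int, total_bp: int) -> float:
    """Percentage of a targeted region covered by probes, to one decimal."""
    if total_bp <= 0:
        raise ValueError("total length must be positive")
    return round(100.0 * covered_bp / total_bp, 1)


def total_length(intervals: Iterable[GenomicInterval]) -> int:
    return sum(len(iv) for iv in intervals)


def snp_summary(variants: Iterable[Variant], sample_sd: bool = False) -> dict:
    """Per-cohort MAF / heterozygosity / distance summary.

    SNPs with no called genotype are excluded from the means (logged).
    """
    snps = [v for v in variants if v.is_snp]
    mafs = [m for m in (compute_maf(v) for v in snps) if m is not None]
    hets = [h for h in (compute_obs_het(v) for v in snps) if h is not None]
    ddof = 1 if sample_sd else 0
    out = {
        "n_snps": len(snps),
        "n_with_calls": len(mafs),
        "mean_maf": float(np.mean(mafs)) if mafs else None,
        "sd_maf": float(np.std(mafs, ddof=ddof)) if len(mafs) > ddof else None,
        "mean_obs_het": float(np.mean(hets)) if hets else None,
        "sd_obs_het": float(np.std(hets, ddof=ddof)) if len(hets) > ddof else None,
    }
    out["distances"] = inter_snp_distances(snps)
    return out
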