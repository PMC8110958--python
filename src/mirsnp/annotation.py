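"""Compartment classification of SNPs within miRNA precursors.

A SNP falling inside a pre-miRNA is placed in one of three compartments with
priority seed > mature_nonseed > precursor_nonmature:

* ``seed`` — mature positions 2–8 (1-based from the mature 5' end);
* ``mature_nonseed`` — position 1 or positions >= 9 of a mature miRNA;
* ``precursor_nonmature`` — inside the hairpin but outside every mature.

On minus-strand precursors mature position 1 is the genomically rightmost
mature base, and substitution alleles are complemented onto the miRNA sense
strand (configurable back to the VCF reference convention).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Optional

from .models import MirnaAnnotation, Variant

SEED_POSITIONS = range(2, 9)  # mature positions 2..8 inclusive

COMPARTMENTS = ("seed", "mature_nonseed", "precursor_nonmature")

#: The 12 possible single-base substitutions, in fixed reporting order.
SUBSTITUTION_CLASSES = (
    "A>C", "A>G", "A>T",
    "C>A", "C>G", "C>T",
    "G>A", "G>C", "G>T",
    "T>A", "T>C", "T>G",
)

_TRANSITIONS = {frozenset("AG"), frozenset("CT")}
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def is_transition(ref: str, alt: str) -> bool:
    return frozenset((ref, alt)) in _TRANSITIONS


@dataclass
class CompartmentCall:
    """Placement of one SNP within one precursor."""

    variant: Variant
    precursor_id: str
    compartment: str
    mature_id: Optional[str] = None
    mature_position: Optional[int] = None  # 1-based from the mature 5' end
    sense_ref: str = ""
    sense_alt: str = ""
    ambiguous: bool = False  # SNP inside two overlapping matures of one precursor

    @property
    def substitution(self) -> str:
        return f"{self.sense_ref}>{self.sense_alt}"

    @property
    def is_transition(self) -> bool:
        return is_transition(self.sense_ref, self.sense_alt)

    @property
    def in_mature(self) -> bool:
        return self.compartment in ("seed", "mature_nonseed")


def classify_snp(
    v: Variant,
    ann: MirnaAnnotation,
    strand_convention: str = "sense",
) -> list[CompartmentCall]:
    """Classify one SNP against one precursor annotation.

    Returns an empty list when the SNP lies outside the precursor, one call
    normally, and two calls flagged ``ambiguous`` when the SNP falls inside
    two overlapping matures of the same precursor.

    ``strand_convention="sense"`` reports alleles on the miRNA sense strand
    (complemented for minus-strand precursors); ``"vcf_ref"`` keeps the VCF
    reference-strand alleles.
    """
    if not v.is_snp:
        raise ValueError(f"classify_snp requires a SNP, got {v.variant_class.value}")
    if strand_convention not in ("sense", "vcf_ref"):
        raise ValueError(f"unknown strand convention {strand_convention!r}")
    iv = ann.precursor_interval
    if not iv.contains(v.chrom, v.pos):
        return []

    minus = iv.strand == "-"
    if strand_convention == "sense" and minus:
        sense_ref = _COMPLEMENT[v.ref_allele]
        sense_alt = _COMPLEMENT[v.alt_allele]
    else:
        sense_ref = v.ref_allele
        sense_alt = v.alt_allele

    hits = []
    for mid, miv in ann.matures:
        if miv.contains(v.chrom, v.pos):
            if minus:
                mpos = miv.end - v.pos  # rightmost base is position 1
            else:
                mpos = v.pos - miv.start + 1
            hits.append((mid, mpos))

    def _call(mid, mpos, ambiguous=False):
        comp = "seed" if mpos in SEED_POSITIONS else "mature_nonseed"
        return CompartmentCall(
            variant=v,
            precursor_id=ann.precursor_id,
            compartment=comp,
            mature_id=mid,
            mature_position=mpos,
            sense_ref=sense_ref,
            sense_alt=sense_alt,
            ambiguous=ambiguous,
        )

    if not hits:
        return [
            CompartmentCall(
                variant=v,
                precursor_id=ann.precursor_id,
                compartment="precursor_nonmature",
                sense_ref=sense_ref,
                sense_alt=sense_alt,
            )
        ]
    if len(hits) == 1:
        return [_call(*hits[0])]
    return [_call(mid, mpos, ambiguous=True) for mid, mpos in hits]


def classify_all(
    variants: Iterable[Variant],
    annotations: Iterable[MirnaAnnotation],
    strand_convention: str = "sense",
) -> list[CompartmentCall]:
    """Classify every SNP against every precursor (one call per overlap)."""
    anns = list(annotations)
    calls: list[CompartmentCall] = []
    for v in variants:
        if not v.is_snp:
            continue
        for ann in anns:
            calls.extend(classify_snp(v, ann, strand_convention))
    return calls


def dedupe_by_site(calls: Iterable[CompartmentCall]) -> list[CompartmentCall]:
    """Keep one call per genomic site, preferring the highest-priority compartment.

    Used for genome-level summaries where a site covered by two precursors
    must not count twice; per-precursor tables keep all calls.
    """
    priority = {c: i for i, c in enumerate(COMPARTMENTS)}
    best: dict[tuple, CompartmentCall] = {}
    for call in calls:
        key = (call.variant.chrom, call.variant.pos, call.variant.alt_allele)
        cur = best.get(key)
        if cur is None or priority[call.compartment] < priority[cur.compartment]:
            best[key] = call
    return list(best.values())


def substitution_spectrum(
    calls: Iterable[CompartmentCall],
    scope: str = "precursor_all",
) -> dict:
    """Count the 12 substitution classes and the Ts/Tv split.

    ``scope="precursor_all"`` uses every call; ``"mature_only"`` restricts to
    calls inside a mature miRNA (seed or mature_nonseed).
    """
    if scope not in ("precursor_all", "mature_only"):
        raise ValueError(f"unknown scope {scope!r}")
    selected = [c for c in calls if scope == "precursor_all" or c.in_mature]
    counts = Counter(c.substitution for c in selected)
    total = len(selected)
    ts = sum(1 for c in selected if c.is_transition)
    tv = total - ts
    return {
        "scope": scope,
        "total": total,
        "counts": {cls: counts.get(cls, 0) for cls in SUBSTITUTION_CLASSES},
        "transitions": ts,
        "transversions": tv,
        "transition_pct": round(100 * ts / total, 1) if total else 0.0,
        "transversion_pct": round(100 * tv / total, 1) if total else 0.0,
    }


def compartment_summary(
    calls: Iterable[CompartmentCall],
    n_annotated_precursors: Optional[int] = None,
) -> dict:
    """Per-compartment counts and percentages, plus unique-precursor counts.

    Calls are deduplicated by genomic site first so a SNP under two
    precursors contributes once. Percentages are over total SNPs, rounded to
    one decimal; the unique-precursor percentage is over the number of
    annotated precursors when given.
    """
    calls = list(calls)
    unique = dedupe_by_site(calls)
    counts = Counter(c.compartment for c in unique)
    total = len(unique)
    summary = {"total_snps": total}
    for comp in COMPARTMENTS:
        n = counts.get(comp, 0)
        summary[f"{comp}_count"] = n
        summary[f"{comp}_pct"] = round(100 * n / total, 1) if total else 0.0
    uniq_pre = {c.precursor_id for c in calls}
    summary["unique_precursors"] = len(uniq_pre)
    if n_annotated_precursors:
        summary["annotated_precursors"] = n_annotated_precursors
        summary["unique_precursor_pct"] = round(
            100 * len(uniq_pre) / n_annotated_precursors, 1
        )
    return summary
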