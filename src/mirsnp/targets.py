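"""Canonical seed-match target prediction and seed-SNP target switching.

A gene is a predicted target when its 3'UTR (DNA, sense strand) contains at
least one canonical site complementary to the miRNA seed (mature positions
2–8). Site stringencies follow the standard nomenclature:

* ``6mer``     — perfect match to seed positions 2–7;
* ``7mer_m8``  — seed match extended by position 8;
* ``7mer_A1``  — seed 2–7 match with an A opposite mature position 1;
* ``8mer``     — both the m8 match and the A1 anchor;
* ``any7plus`` — union of 7mer_m8, 7mer_A1 and 8mer (default).

Hybridization-energy scoring of full-length duplexes is intentionally not
modelled; the switch statistics quantify set changes (common / lost /
gained), which is what a seed SNP acts on directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

from .annotation import CompartmentCall
from .models import MirnaAnnotation, revcomp_dna, rna_to_dna

SITE_RULES = ("6mer", "7mer_m8", "7mer_A1", "8mer", "any7plus")


@dataclass(frozen=True)
class SeedSpec:
    """A 7-nt seed (mature positions 2–8) for one miRNA variant."""

    mirna_id: str
    seed7: str
    variant_label: str = "reference"  # or "snp_altered"

    def __post_init__(self) -> None:
        if len(self.seed7) != 7 or set(self.seed7) - set("ACGU"):
            raise ValueError(f"seed7 must be 7 RNA bases, got {self.seed7!r}")


@dataclass
class TargetSwitch:
    mirna_id: str
    targets_ref: frozenset
    targets_alt: frozenset
    common: frozenset = field(init=False)
    lost: frozenset = field(init=False)
    gained: frozenset = field(init=False)

    def __post_init__(self) -> None:
        self.common = frozenset(self.targets_ref & self.targets_alt)
        self.lost = frozenset(self.targets_ref - self.targets_alt)
        self.gained = frozenset(self.targets_alt - self.targets_ref)

    def venn_counts(self) -> dict:
        return {
            "mirna_id": self.mirna_id,
            "n_ref": len(self.targets_ref),
            "n_alt": len(self.targets_alt),
            "n_common": len(self.common),
            "n_lost": len(self.lost),
            "n_gained": len(self.gained),
        }


def extract_seed(
    ann: MirnaAnnotation,
    mature_id: str,
    snp: Optional[CompartmentCall] = None,
) -> SeedSpec:
    """Sense-strand seed (positions 2–8) of a mature, optionally SNP-altered."""
    if ann.hairpin_seq is None:
        raise ValueError(f"no hairpin sequence attached to {ann.precursor_id}")
    off = ann.mature_sense_offset(mature_id)
    length = next(len(iv) for mid, iv in ann.matures if mid == mature_id)
    if length < 8:
        raise ValueError(f"mature {mature_id} too short for a seed ({length} nt)")
    mature_seq = ann.hairpin_seq[off : off + length]
    label = "reference"
    if snp is not None:
        if snp.mature_id != mature_id or snp.compartment != "seed":
            raise ValueError(
                f"SNP at {snp.variant.chrom}:{snp.variant.vcf_pos} is not a seed "
                f"SNP of {mature_id}"
            )
        idx = snp.mature_position - 1
        alt = snp.sense_alt.replace("T", "U")
        mature_seq = mature_seq[:idx] + alt + mature_seq[idx + 1 :]
        label = "snp_altered"
    return SeedSpec(mirna_id=mature_id, seed7=mature_seq[1:8], variant_label=label)


def _site_strings(seed: SeedSpec) -> dict:
    """UTR match strings (DNA, 5'->3') for each site type."""
    site7 = revcomp_dna(rna_to_dna(seed.seed7))  # complements positions 8..2
    site6 = site7[1:]  # positions 7..2
    return {
        "6mer": site6,
        "7mer_m8": site7,
        "7mer_A1": site6 + "A",
        "8mer": site7 + "A",
    }


def find_sites(seed: SeedSpec, utr: str, site_rule: str = "any7plus") -> list:
    """All (position, site_type) matches of a seed in one UTR."""
    if site_rule not in SITE_RULES:
        raise ValueError(f"unknown site rule {site_rule!r}; choose from {SITE_RULES}")
    utr = utr.upper()
    strings = _site_strings(seed)
    rules = ("7mer_m8", "7mer_A1", "8mer") if site_rule == "any7plus" else (site_rule,)
    hits = []
    for rule in rules:
        s = strings[rule]
        start = utr.find(s)
        while start != -1:
            hits.append((start, rule))
            start = utr.find(s, start + 1)
    return sorted(set(hits))


def match_targets(
    seed: SeedSpec,
    utrs: dict[str, str],
    site_rule: str = "any7plus",
) -> frozenset:
    """Gene ids whose UTR carries at least one qualifying site."""
    return frozenset(
        gene for gene, utr in utrs.items() if find_sites(seed, utr, site_rule)
    )


def switch_analysis(
    ref_targets: Iterable[str],
    alt_targets: Iterable[str],
    mirna_id: str = "",
) -> TargetSwitch:
    """Common / lost / gained target sets between the two seed variants."""
    return TargetSwitch(
        mirna_id=mirna_id,
        targets_ref=frozenset(ref_targets),
        targets_alt=frozenset(alt_targets),
    )
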