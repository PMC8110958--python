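"""Core domain types shared across the pipeline.

Coordinate convention: every interval and variant position held in memory is
0-based, half-open. Conversion to/from 1-based inclusive conventions (VCF POS,
GFF3) happens exactly once, at the format boundary in :mod:`mirsnp.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

DNA_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")
RNA_COMPLEMENT = str.maketrans("ACGUacgu", "UGCAugca")


def revcomp_dna(seq: str) -> str:
    return seq.translate(DNA_COMPLEMENT)[::-1]


def revcomp_rna(seq: str) -> str:
    return seq.translate(RNA_COMPLEMENT)[::-1]


def dna_to_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def rna_to_dna(seq: str) -> str:
    return seq.upper().replace("U", "T")


class VariantClass(str, Enum):
    SNP = "SNP"
    INSERTION = "insertion"
    DELETION = "deletion"
    COMPLEX = "complex"


@dataclass(frozen=True)
class GenomicInterval:
    """A stranded genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(require 0 <= start < end)"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos < self.end

    def contains_interval(self, other: "GenomicInterval") -> bool:
        return (
            other.chrom == self.chrom
            and self.start <= other.start
            and other.end <= self.end
        )


@dataclass
class Variant:
    """A single called variant with per-sample diploid genotypes.

    ``pos`` is 0-based; ``vcf_pos`` gives back the source 1-based POS.
    Genotypes are tuples of allele indices (0 = ref, 1 = alt) or ``None`` when
    the call is missing (either absent in the source or masked by the GQ
    filter). Multi-allelic source records are split upstream, so allele
    indices never exceed 1.
    """

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    variant_class: VariantClass
    site_depth: Optional[int] = None
    genotypes: list = field(default_factory=list)
    genotype_quals: list = field(default_factory=list)

    @property
    def vcf_pos(self) -> int:
        return self.pos + 1

    @property
    def is_snp(self) -> bool:
        return self.variant_class is VariantClass.SNP

    @staticmethod
    def classify_alleles(ref: str, alt: str) -> VariantClass:
        if len(ref) == 1 and len(alt) == 1 and ref != alt:
            return VariantClass.SNP
        if len(ref) < len(alt) and alt.startswith(ref):
            return VariantClass.INSERTION
        if len(ref) > len(alt) and ref.startswith(alt):
            return VariantClass.DELETION
        return VariantClass.COMPLEX


@dataclass
class MirnaAnnotation:
    """A pre-miRNA hairpin with its nested mature miRNA(s).

    ``hairpin_seq`` is the precursor read sense-strand 5'->3' in the RNA
    alphabet; it may be attached after GFF ingest from a hairpin FASTA.
    """

    precursor_id: str
    precursor_interval: GenomicInterval
    matures: list = field(default_factory=list)  # list[(mature_id, GenomicInterval)]
    hairpin_seq: Optional[str] = None

    def __post_init__(self) -> None:
        for mid, iv in self.matures:
            self._check_mature(mid, iv)
        if self.hairpin_seq is not None:
            self.set_hairpin(self.hairpin_seq)

    def _check_mature(self, mature_id: str, iv: GenomicInterval) -> None:
        if not self.precursor_interval.contains_interval(iv):
            raise ValueError(
                f"mature {mature_id} {iv.chrom}:{iv.start}-{iv.end} not contained "
                f"in precursor {self.precursor_id}"
            )
        if iv.strand != self.precursor_interval.strand:
            raise ValueError(
                f"mature {mature_id} strand {iv.strand} differs from precursor "
                f"{self.precursor_id} strand {self.precursor_interval.strand}"
            )

    def add_mature(self, mature_id: str, iv: GenomicInterval) -> None:
        self._check_mature(mature_id, iv)
        self.matures.append((mature_id, iv))

    def set_hairpin(self, seq: str) -> None:
        seq = dna_to_rna(seq)
        if len(seq) != len(self.precursor_interval):
            raise ValueError(
                f"hairpin length {len(seq)} != precursor interval length "
                f"{len(self.precursor_interval)} for {self.precursor_id}"
            )
        self.hairpin_seq = seq

    def hairpin_offset(self, genomic_pos: int) -> int:
        """Sense-strand 5'->3' offset of a genomic position within the hairpin."""
        iv = self.precursor_interval
        if not iv.contains(iv.chrom, genomic_pos):
            raise ValueError(
                f"position {genomic_pos} outside precursor {self.precursor_id}"
            )
        if iv.strand == "+":
            return genomic_pos - iv.start
        return iv.end - 1 - genomic_pos

    def mature_sense_offset(self, mature_id: str) -> int:
        """Offset of a mature's 5' end within the hairpin (sense strand)."""
        for mid, miv in self.matures:
            if mid == mature_id:
                if self.precursor_interval.strand == "+":
                    return miv.start - self.precursor_interval.start
                return self.precursor_interval.end - miv.end
        raise KeyError(f"no mature {mature_id} in precursor {self.precursor_id}")
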