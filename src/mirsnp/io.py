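"""Readers and writers for the external formats the pipeline touches.

All conversions between source coordinate conventions (VCF and GFF3 are
1-based inclusive; BED is already 0-based half-open) and the internal 0-based
half-open convention happen here and nowhere else.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional

import gffutils
import pandas as pd
import pysam
from Bio import SeqIO

from .models import GenomicInterval, MirnaAnnotation, Variant, dna_to_rna

logger = logging.getLogger(__name__)


class FormatError(ValueError):
    """Raised for malformed or inconsistent input files."""


@dataclass
class FilterSpec:
    """Hard filters applied at VCF ingest.

    Both thresholds are exclusive: a record is kept when site depth
    ``DP > min_total_depth`` and a genotype is kept when
    ``GQ > min_genotype_quality``. With ``strict`` (default) a record or
    genotype lacking the relevant field is an error; otherwise it passes
    through unfiltered.
    """

    min_total_depth: int = 5
    min_genotype_quality: int = 30
    strict: bool = True


def read_vcf(path, filters: Optional[FilterSpec] = None) -> list[Variant]:
    """Read a VCF 4.x file into filtered, biallelic :class:`Variant` records.

    Multi-allelic records are split into one record per alternate allele;
    genotype allele indices referring to a different alternate become missing
    in each split record. Site-level DP filtering drops whole records;
    genotype-level GQ filtering masks individual genotypes to missing.
    """
    filters = filters or FilterSpec()
    out: list[Variant] = []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        for rec in vcf:
            dp = rec.info.get("DP")
            if dp is None:
                if filters.strict:
                    raise FormatError(
                        f"record {rec.chrom}:{rec.pos} lacks INFO/DP "
                        "(strict filtering requested)"
                    )
            elif dp <= filters.min_total_depth:
                continue
            alts = rec.alts or ()
            for alt_idx, alt in enumerate(alts, start=1):
                genotypes = []
                quals = []
                for name in samples:
                    sample = rec.samples[name]
                    gt = sample.get("GT")
                    gq = sample.get("GQ")
                    if gq is None and filters.strict and gt is not None and None not in (gt or (None,)):
                        raise FormatError(
                            f"record {rec.chrom}:{rec.pos} sample {name} lacks GQ "
                            "(strict filtering requested)"
                        )
                    call = None
                    if gt is not None and None not in gt:
                        mapped = []
                        for a in gt:
                            if a == 0:
                                mapped.append(0)
                            elif a == alt_idx:
                                mapped.append(1)
                            else:
                                mapped = None
                                break
                        if mapped is not None:
                            call = tuple(mapped)
                    if call is not None and gq is not None and gq <= filters.min_genotype_quality:
                        call = None
                    genotypes.append(call)
                    quals.append(gq)
                out.append(
                    Variant(
                        chrom=rec.chrom,
                        pos=rec.pos - 1,
                        ref_allele=rec.ref,
                        alt_allele=alt,
                        variant_class=Variant.classify_alleles(rec.ref, alt),
                        site_depth=dp,
                        genotypes=genotypes,
                        genotype_quals=quals,
                    )
                )
    return out


_PRECURSOR_TYPES = {"miRNA_primary_transcript", "pre_miRNA", "precursor"}
_MATURE_TYPES = {"miRNA", "mature_miRNA"}


def read_mirna_gff(path) -> tuple[list[MirnaAnnotation], dict]:
    """Read a miRBase-dialect GFF3 of precursor + mature miRNA features.

    Mature features are linked to their precursor by ``Derives_from`` when
    present, otherwise by containment. Returns the annotations and an ingest
    report listing orphan matures (warned, not fatal).
    """
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="error",
    )
    precursors: dict[str, MirnaAnnotation] = {}
    for feat in db.all_features():
        if feat.featuretype not in _PRECURSOR_TYPES:
            continue
        pid = feat.attributes.get("ID", [feat.id])[0]
        if pid in precursors:
            raise FormatError(f"duplicate precursor ID {pid}")
        precursors[pid] = MirnaAnnotation(
            precursor_id=pid,
            # GFF3 1-based inclusive -> 0-based half-open
            precursor_interval=GenomicInterval(
                feat.seqid, feat.start - 1, feat.end, feat.strand
            ),
        )

    orphans = []
    for feat in db.all_features():
        if feat.featuretype not in _MATURE_TYPES:
            continue
        mid = feat.attributes.get("ID", [feat.id])[0]
        iv = GenomicInterval(feat.seqid, feat.start - 1, feat.end, feat.strand)
        parent_ids = feat.attributes.get("Derives_from", [])
        parent = None
        for pid in parent_ids:
            if pid in precursors:
                parent = precursors[pid]
                break
        if parent is None:
            for ann in precursors.values():
                if ann.precursor_interval.contains_interval(iv):
                    parent = ann
                    break
        if parent is None:
            orphans.append(mid)
            warnings.warn(f"mature {mid} not contained in any precursor; skipped")
            continue
        parent.add_mature(mid, iv)

    report = {"n_precursors": len(precursors), "orphan_matures": orphans}
    return list(precursors.values()), report


def read_fasta(path, alphabet: str = "dna") -> dict[str, str]:
    """Read a FASTA into an id -> upper-cased sequence map.

    ``alphabet="rna"`` converts T->U (used for hairpin precursors); the
    default leaves DNA untouched. Duplicate ids and empty sequences are
    errors.
    """
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise FormatError(f"duplicate FASTA id {rec.id}")
        seq = str(rec.seq).upper()
        if not seq:
            raise FormatError(f"empty sequence for FASTA id {rec.id}")
        seqs[rec.id] = dna_to_rna(seq) if alphabet == "rna" else seq
    if not seqs:
        raise FormatError(f"no FASTA records in {path}")
    return seqs


def attach_hairpins(annotations: Iterable[MirnaAnnotation], hairpins: dict[str, str]) -> None:
    """Attach hairpin RNA sequences (keyed by precursor id) to annotations."""
    for ann in annotations:
        if ann.precursor_id in hairpins:
            ann.set_hairpin(hairpins[ann.precursor_id])


def read_bed(path) -> list[GenomicInterval]:
    """Read a BED file (already 0-based half-open) of targeted regions."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            strand = parts[5] if len(parts) > 5 else "+"
            out.append(GenomicInterval(parts[0], int(parts[1]), int(parts[2]), strand))
    return out


def write_report(tables: dict, outdir, prefix: str = "") -> list[Path]:
    """Write a name -> table/dict bundle as TSV (DataFrames) / JSON (mappings)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, obj in tables.items():
        stem = f"{prefix}{name}"
        if isinstance(obj, pd.DataFrame):
            p = outdir / f"{stem}.tsv"
            obj.to_csv(p, sep="\t", index=False)
        else:
            p = outdir / f"{stem}.json"
            with open(p, "w") as fh:
                json.dump(obj, fh, indent=2, default=_json_default)
        written.append(p)
    return written


def _json_default(obj):
    if hasattr(obj, "item"):  # numpy scalars
        return obj.item()
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
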