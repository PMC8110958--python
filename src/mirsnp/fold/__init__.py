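"""Hairpin folding and SNP structure-impact analysis.

Three interchangeable MFE engines satisfy one contract (same sequence in,
deterministic structure + energy out):

* ``nussinov`` — base-pair maximization; reports the negated pair count as a
  pseudo-energy. Teaching/oracle engine.
* ``loop_energy`` — the package's own nearest-neighbor free-energy model
  (stacking + loop penalties, Turner-style parameter file shipped with the
  package), in kcal/mol.
* ``external`` — ViennaRNA's RNAfold, the backend matching the energies the
  original study printed; requires the ``RNA`` Python bindings.

ΔΔG is MFE(SNP-altered) − MFE(reference): positive values destabilize the
hairpin ("increase" of MFE).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np

from ..annotation import CompartmentCall
from ..models import MirnaAnnotation, dna_to_rna
from . import nearest_neighbor, nussinov, vienna
from .nearest_neighbor import EnergyParams, evaluate_structure
from .pairs import (
    MIN_HAIRPIN_LOOP,
    check_structure,
    dotbracket_to_pairs,
    pairs_to_dotbracket,
    validate_rna,
)

ENGINES = ("nussinov", "loop_energy", "external")

#: |ΔΔG| below this (kcal/mol) rounds to 0.0 at one-decimal reporting and is
#: treated as "no energy change".
DDG_EPSILON = 0.05

MIN_FOLD_LEN = 10


class ReferenceMismatchError(ValueError):
    """Hairpin base does not match the call's reference allele (strand/offset bug guard)."""


@dataclass(frozen=True)
class FoldResult:
    sequence: str
    structure: str
    mfe: float
    engine: str

    @property
    def pairs(self) -> frozenset:
        return dotbracket_to_pairs(self.structure)


@dataclass
class DeltaGRecord:
    precursor_id: str
    call: CompartmentCall
    mfe_ref: float
    mfe_alt: float
    structure_ref: str
    structure_alt: str
    structure_changed: bool

    @property
    def ddg(self) -> float:
        return self.mfe_alt - self.mfe_ref

    @property
    def abs_ddg(self) -> float:
        return abs(self.ddg)

    @property
    def direction(self) -> str:
        if self.ddg >= DDG_EPSILON:
            return "increase"
        if self.ddg <= -DDG_EPSILON:
            return "decrease"
        return "none"


def fold_mfe(
    seq: str,
    engine: str = "loop_energy",
    params: Optional[EnergyParams] = None,
) -> FoldResult:
    """Fold one RNA sequence with the selected engine."""
    seq = validate_rna(seq)
    if len(seq) < MIN_FOLD_LEN:
        raise ValueError(f"sequence too short to fold ({len(seq)} < {MIN_FOLD_LEN})")
    if engine == "nussinov":
        npairs, pairs = nussinov.max_pairs(seq)
        structure = pairs_to_dotbracket(len(seq), pairs)
        mfe = float(-npairs)
    elif engine == "loop_energy":
        mfe, pairs = nearest_neighbor.fold(seq, params)
        structure = pairs_to_dotbracket(len(seq), pairs)
    elif engine == "external":
        mfe, structure = vienna.fold(seq)
    else:
        raise ValueError(f"unknown fold engine {engine!r}; choose from {ENGINES}")
    check_structure(seq, structure)
    return FoldResult(sequence=seq, structure=structure, mfe=mfe, engine=engine)


def apply_snp_to_hairpin(ann: MirnaAnnotation, call: CompartmentCall) -> str:
    """Substitute the call's alternate base into the sense-strand hairpin.

    Raises :class:`ReferenceMismatchError` when the hairpin base at the
    mapped offset differs from the call's sense reference allele — the guard
    that catches strand or offset bookkeeping errors.
    """
    if ann.hairpin_seq is None:
        raise ValueError(f"no hairpin sequence attached to {ann.precursor_id}")
    off = ann.hairpin_offset(call.variant.pos)
    ref_rna = dna_to_rna(call.sense_ref)
    alt_rna = dna_to_rna(call.sense_alt)
    if ann.hairpin_seq[off] != ref_rna:
        raise ReferenceMismatchError(
            f"{ann.precursor_id} offset {off}: hairpin has "
            f"{ann.hairpin_seq[off]}, call expects sense ref {ref_rna}"
        )
    return ann.hairpin_seq[:off] + alt_rna + ann.hairpin_seq[off + 1 :]


def ddg_analysis(
    ann: MirnaAnnotation,
    call: CompartmentCall,
    engine: str = "loop_energy",
    params: Optional[EnergyParams] = None,
) -> DeltaGRecord:
    """Fold reference and SNP-altered hairpins with one engine; compare."""
    alt_seq = apply_snp_to_hairpin(ann, call)
    ref = fold_mfe(ann.hairpin_seq, engine, params)
    alt = fold_mfe(alt_seq, engine, params)
    return DeltaGRecord(
        precursor_id=ann.precursor_id,
        call=call,
        mfe_ref=ref.mfe,
        mfe_alt=alt.mfe,
        structure_ref=ref.structure,
        structure_alt=alt.structure,
        structure_changed=ref.pairs != alt.pairs,
    )


def cohort_ddg_summary(records: Iterable[DeltaGRecord]) -> dict:
    """Cohort-level ΔΔG distribution: counts by direction, mean |ΔΔG|, range."""
    records = list(records)
    nonzero = [r for r in records if r.direction != "none"]
    abs_nonzero = [r.abs_ddg for r in nonzero]
    return {
        "n_records": len(records),
        "n_nonzero": len(nonzero),
        "n_increase": sum(1 for r in records if r.direction == "increase"),
        "n_decrease": sum(1 for r in records if r.direction == "decrease"),
        "n_none": sum(1 for r in records if r.direction == "none"),
        "mean_abs_ddg": round(float(np.mean(abs_nonzero)), 2) if abs_nonzero else 0.0,
        "mean_abs_ddg_defined": bool(abs_nonzero),
        "min_abs_ddg": round(min(abs_nonzero), 1) if abs_nonzero else None,
        "max_abs_ddg": round(max(abs_nonzero), 1) if abs_nonzero else None,
        "n_structure_changed": sum(1 for r in records if r.structure_changed),
    }
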