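"""End-to-end orchestration: annotate -> stats -> fold -> switch -> enrich.

``run_all`` is a pure function of (input files, config): it validates all
paths up front, logs row counts at every filter boundary (the audit funnel
from raw VCF records down to compartment-classified miRNA SNPs), and writes
a consolidated JSON report plus per-stage TSVs and a MANIFEST. A stage
failure aborts the run with the failing stage named; partial outputs are
kept and the MANIFEST marks the run incomplete.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from . import __version__
from .annotation import classify_all, compartment_summary, dedupe_by_site, substitution_spectrum
from .enrich import compare_enrichment, hypergeom_enrich, read_go_annotation
from .fold import EnergyParams, cohort_ddg_summary, ddg_analysis
from .io import FilterSpec, attach_hairpins, read_bed, read_fasta, read_mirna_gff, read_vcf
from .popgen import density_per_kb, snp_summary, total_length
from .targets import extract_seed, match_targets, switch_analysis

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    vcf: str
    gff: str
    hairpin_fasta: str
    utr_fasta: Optional[str] = None
    go_tsv: Optional[str] = None
    bed: Optional[str] = None
    outdir: str = "mirsnp_out"
    min_dp: int = 5  # exclusive: keep DP > min_dp
    min_gq: int = 30  # exclusive: keep GQ > min_gq
    strand_convention: str = "sense"
    fold_engine: str = "loop_energy"
    fold_params: Optional[str] = None
    site_rule: str = "any7plus"
    alpha: float = 0.05
    threshold_by: str = "fdr"
    universe: str = "annotated"  # or "all_utr_genes"
    sample_sd: bool = False

    def validate(self) -> None:
        required = {"vcf": self.vcf, "gff": self.gff, "hairpin_fasta": self.hairpin_fasta}
        optional = {"utr_fasta": self.utr_fasta, "go_tsv": self.go_tsv,
                    "bed": self.bed, "fold_params": self.fold_params}
        for name, path in {**required, **{k: v for k, v in optional.items() if v}}.items():
            if not Path(path).exists():
                raise FileNotFoundError(f"{name} path does not exist: {path}")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")


@dataclass
class RunResult:
    summary: dict
    calls: list
    variants: list
    ddg_records: list = field(default_factory=list)
    switches: list = field(default_factory=list)


def run_all(cfg: RunConfig) -> RunResult:
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _setup_logging(outdir)
    completed: list[str] = []
    manifest = {"version": __version__, "config": asdict(cfg),
                "status": "incomplete", "stages": completed}
    summary: dict = {"config": asdict(cfg), "version": __version__}
    result = RunResult(summary=summary, calls=[], variants=[])
    try:
        _run_stages(cfg, outdir, summary, result, completed)
        manifest["status"] = "complete"
    except PipelineError:
        raise
    except Exception as exc:
        stage = completed[-1] if completed else "setup"
        raise PipelineError(f"after:{stage}", exc) from exc
    finally:
        with open(outdir / "MANIFEST.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
        with open(outdir / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, default=_jsonable)
    return result


def _run_stages(cfg, outdir, summary, result, completed):
    # ---------------------------------------------------------- ingest
    stage = "ingest"
    try:
        filters = FilterSpec(min_total_depth=cfg.min_dp, min_genotype_quality=cfg.min_gq)
        variants = read_vcf(cfg.vcf, filters)
        annotations, gff_report = read_mirna_gff(cfg.gff)
        attach_hairpins(annotations, read_fasta(cfg.hairpin_fasta, alphabet="rna"))
        bed = read_bed(cfg.bed) if cfg.bed else None
    except Exception as exc:
        raise PipelineError(stage, exc) from exc
    result.variants = variants
    snps = [v for v in variants if v.is_snp]
    logger.info("ingest: %d records pass DP>%d; %d SNPs; %d precursors",
                len(variants), cfg.min_dp, len(snps), gff_report["n_precursors"])
    summary["funnel"] = {"vcf_records_pass_dp": len(variants), "snps": len(snps)}
    summary["gff_report"] = gff_report
    completed.append(stage)

    # -------------------------------------------------------- annotate
    stage = "annotate"
    try:
        calls = classify_all(snps, annotations, cfg.strand_convention)
        unique_calls = dedupe_by_site(calls)
        comp = compartment_summary(calls, gff_report["n_precursors"])
        spectrum_pre = substitution_spectrum(unique_calls, "precursor_all")
        spectrum_mat = substitution_spectrum(unique_calls, "mature_only")
    except Exception as exc:
        raise PipelineError(stage, exc) from exc
    result.calls = calls
    premirna_variants = [
        v for v in variants
        if any(a.precursor_interval.contains(v.chrom, v.pos) for a in annotations)
    ]
    summary["funnel"]["variants_in_premirna"] = len(premirna_variants)
    summary["funnel"]["snps_in_premirna"] = comp["total_snps"]
    summary["compartments"] = comp
    summary["spectrum_premirna"] = spectrum_pre
    summary["spectrum_mature"] = spectrum_mat
    logger.info("annotate: %d pre-miRNA variants, %d SNPs in %d precursors",
                len(premirna_variants), comp["total_snps"], comp["unique_precursors"])
    _write_calls_tsv(calls, outdir / "snp_calls.tsv")
    completed.append(stage)

    # ----------------------------------------------------------- stats
    stage = "stats"
    try:
        mirna_snps = list({(c.variant.chrom, c.variant.pos): c.variant
                           for c in calls}.values())
        stats_all = snp_summary(snps, cfg.sample_sd)
        stats_pre = snp_summary(mirna_snps, cfg.sample_sd)
        pre_bp = sum(len(a.precursor_interval) for a in annotations)
        summary["popgen"] = {
            "all_snps": stats_all,
            "premirna_snps": stats_pre,
            "premirna_bp": pre_bp,
            "density_premirna_per_kb": density_per_kb(len(mirna_snps), pre_bp),
        }
        if bed:
            bed_bp = total_length(bed)
            in_target = [v for v in snps
                         if any(iv.contains(v.chrom, v.pos) for iv in bed)]
            summary["popgen"]["targeted_bp"] = bed_bp
            summary["popgen"]["density_targeted_per_kb"] = density_per_kb(
                len(in_target), bed_bp)
    except Exception as exc:
        raise PipelineError(stage, exc) from exc
    completed.append(stage)

    # ------------------------------------------------------ fold-impact
    stage = "fold-impact"
    try:
        params = EnergyParams.from_file(cfg.fold_params) if cfg.fold_params else None
        ann_by_id = {a.precursor_id: a for a in annotations}
        per_precursor: dict[str, int] = {}
        for c in calls:
            per_precursor[c.precursor_id] = per_precursor.get(c.precursor_id, 0) + 1
        records = []
        for c in calls:
            ann = ann_by_id[c.precursor_id]
            if ann.hairpin_seq is None:
                logger.warning("no hairpin for %s; skipped in folding", c.precursor_id)
                continue
            records.append(ddg_analysis(ann, c, cfg.fold_engine, params))
        result.ddg_records = records
        ddg = cohort_ddg_summary(records)
        ddg["n_multi_snp_precursors"] = sum(1 for n in per_precursor.values() if n > 1)
        summary["ddg"] = ddg
        _write_ddg_tsv(records, outdir / "ddg_records.tsv")
    except Exception as exc:
        raise PipelineError(stage, exc) from exc
    logger.info("fold-impact: %d records, %d nonzero ddg", ddg["n_records"],
                ddg["n_nonzero"])
    completed.append(stage)

    if not (cfg.utr_fasta and cfg.go_tsv):
        summary["target_switch"] = None
        summary["enrichment"] = None
        completed.append("target-switch:skipped")
        return

    # ---------------------------------------------------- target-switch
    stage = "target-switch"
    try:
        utrs = read_fasta(cfg.utr_fasta, alphabet="dna")
        seed_calls = [c for c in calls if c.compartment == "seed"]
        switches = []
        seeds_by_mirna = {}
        for c in seed_calls:
            ann = ann_by_id[c.precursor_id]
            ref_seed = extract_seed(ann, c.mature_id)
            alt_seed = extract_seed(ann, c.mature_id, snp=c)
            sw = switch_analysis(
                match_targets(ref_seed, utrs, cfg.site_rule),
                match_targets(alt_seed, utrs, cfg.site_rule),
                mirna_id=c.mature_id,
            )
            switches.append(sw)
            seeds_by_mirna[c.mature_id] = (ref_seed, alt_seed)
        result.switches = switches
        summary["target_switch"] = [sw.venn_counts() for sw in switches]
    except Exception as exc:
        raise PipelineError(stage, exc) from exc
    logger.info("target-switch: %d seed SNPs analyzed", len(switches))
    completed.append(stage)

    # ---------------------------------------------------------- enrich
    stage = "enrich"
    try:
        go = read_go_annotation(cfg.go_tsv)
        annotated_genes = set().union(*go.values()) if go else set()
        if cfg.universe == "annotated":
            universe = annotated_genes & set(utrs)
        else:
            universe = set(utrs)
        comparisons = []
        for sw in switches:
            rows_ref = hypergeom_enrich(sw.targets_ref & universe, go, universe)
            rows_alt = hypergeom_enrich(sw.targets_alt & universe, go, universe)
            comp_df = compare_enrichment(rows_ref, rows_alt, cfg.alpha, cfg.threshold_by)
            rows_ref.to_csv(outdir / f"enrichment_{sw.mirna_id}_ref.tsv",
                            sep="\t", index=False)
            rows_alt.to_csv(outdir / f"enrichment_{sw.mirna_id}_alt.tsv",
                            sep="\t", index=False)
            comp_df.to_csv(outdir / f"enrichment_{sw.mirna_id}_comparison.tsv",
                           sep="\t", index=False)
            comparisons.append({
                "mirna_id": sw.mirna_id,
                "n_significant_ref": int((rows_ref[cfg.threshold_by] <= cfg.alpha).sum())
                if len(rows_ref) else 0,
                "n_significant_alt": int((rows_alt[cfg.threshold_by] <= cfg.alpha).sum())
                if len(rows_alt) else 0,
                "status_counts": comp_df["status"].value_counts().to_dict()
                if len(comp_df) else {},
            })
        summary["enrichment"] = comparisons
    except Exception as exc:
        raise PipelineError(stage, exc) from exc
    logger.info("enrich: %d comparisons", len(comparisons))
    completed.append(stage)


def _write_calls_tsv(calls, path) -> None:
    rows = [
        dict(chrom=c.variant.chrom, pos=c.variant.vcf_pos,
             precursor_id=c.precursor_id, compartment=c.compartment,
             mature_id=c.mature_id or "", mature_position=c.mature_position or "",
             substitution=c.substitution,
             change_type="transition" if c.is_transition else "transversion",
             ambiguous=c.ambiguous)
        for c in calls
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _write_ddg_tsv(records, path) -> None:
    rows = [
        dict(precursor_id=r.precursor_id, chrom=r.call.variant.chrom,
             pos=r.call.variant.vcf_pos, substitution=r.call.substitution,
             mfe_ref=round(r.mfe_ref, 2), mfe_alt=round(r.mfe_alt, 2),
             ddg=round(r.ddg, 2), direction=r.direction,
             structure_changed=r.structure_changed,
             structure_ref=r.structure_ref, structure_alt=r.structure_alt)
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _setup_logging(outdir: Path) -> None:
    root = logging.getLogger("mirsnp")
    root.setLevel(logging.INFO)
    have_file = any(isinstance(h, logging.FileHandler) for h in root.handlers)
    if not have_file:
        fh = logging.FileHandler(outdir / "run.log")
        fh.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
        root.addHandler(fh)


def _jsonable(obj):
    if hasattr(obj, "item"):
        return obj.item()
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    return str(obj)
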