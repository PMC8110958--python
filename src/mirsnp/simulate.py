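"""Synthetic cohort generator with machine-readable ground truth.

Every pipeline stage can be exercised without downloads: the generator emits
a small genome, a miRBase-style GFF3 of hairpin precursors with nested
matures (both strands), a genotyped VCF whose planted SNPs have known
compartments, substitution types and allele frequencies, hairpin and 3'UTR
FASTAs with planted seed-match sites, a gene->GO table with planted
enrichment, and a BED of targeted capture regions.

Defaults emulate the targeted-sequencing study design this pipeline was
built around: 23 diploid samples, 381 precursors (~80 nt stem-loops, ~30 kb
of pre-miRNA sequence in total), 73 SNPs placed 2/12/59 across the
seed / mature-beyond-seed / precursor-beyond-mature compartments in 50
distinct precursors, 60 of them transitions (2 seed, 8 mature_nonseed, 50
precursor_nonmature), plus 8 pre-miRNA indels, off-target variants, and
records planted to fail the DP/GQ ingest filters. Planted allele
frequencies are uniform on [0.05, 0.5] (mean 0.275) with Hardy-Weinberg
genotypes.

Hairpins are constructed as stem + loop + revcomp(stem) rather than sampled
from a database, so folding behaviour (stem-disrupting vs loop-neutral SNPs)
is known by construction.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import classify_snp
from .fold.pairs import can_pair
from .models import (
    GenomicInterval,
    MirnaAnnotation,
    Variant,
    VariantClass,
    dna_to_rna,
    revcomp_dna,
    rna_to_dna,
)
from .targets import extract_seed, find_sites

_DNA = np.array(list("ACGT"))
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}


@dataclass
class SimConfig:
    """Study-design knobs for the synthetic cohort (defaults = study scale)."""

    seed: int = 0
    n_precursors: int = 381
    frac_minus_strand: float = 0.5
    stem_len_range: tuple = (30, 43)
    loop_len_range: tuple = (4, 9)
    wc_stem_frac: float = 0.95
    # planted SNPs per compartment and their transition counts
    n_seed_snps: int = 2
    n_mature_nonseed_snps: int = 12
    n_precursor_nonmature_snps: int = 59
    n_unique_snp_precursors: int = 50
    n_transitions: tuple = (2, 8, 50)  # per compartment, same order as above
    # cohort / genotypes
    n_samples: int = 23
    maf_range: tuple = (0.05, 0.5)
    missing_rate: float = 0.0
    mean_depth: int = 57
    # extra records exercising ingest
    n_premirna_indels: int = 8
    n_fail_dp: int = 3
    n_offtarget_snps: int = 20
    n_multiallelic: int = 1
    n_fail_gq_sites: int = 1
    flank_bp: int = 80
    # target prediction / enrichment fixtures
    n_utr_genes: int = 400
    utr_len: int = 240
    # (ref_only, common, alt_only) planted target genes per seed SNP:
    # one loss-dominant switch and one gain-dominant switch
    target_plan: tuple = ((30, 10, 15), (12, 8, 25))
    n_go_terms: int = 30
    go_terms_per_gene: int = 3
    go_planted_frac: float = 0.8

    @property
    def n_total_snps(self) -> int:
        return (
            self.n_seed_snps
            + self.n_mature_nonseed_snps
            + self.n_precursor_nonmature_snps
        )

    def validate(self) -> None:
        if self.n_unique_snp_precursors > self.n_precursors:
            raise ValueError("more SNP-bearing precursors than precursors")
        if self.n_total_snps < self.n_unique_snp_precursors:
            raise ValueError("fewer SNPs than unique SNP-bearing precursors")
        if self.n_seed_snps > self.n_unique_snp_precursors:
            raise ValueError("at most one seed SNP is planted per precursor")
        if self.n_seed_snps > 6 * self.n_precursors:
            raise ValueError("more seed SNPs than available seed positions")
        for comp_n, ts in zip(
            (self.n_seed_snps, self.n_mature_nonseed_snps,
             self.n_precursor_nonmature_snps),
            self.n_transitions,
        ):
            if ts > comp_n:
                raise ValueError("transition count exceeds compartment SNP count")


@dataclass
class SimResult:
    """In-memory cohort plus the paths of everything written to disk."""

    config: SimConfig
    annotations: list
    chrom_seqs: dict
    records: list
    truth_snps: pd.DataFrame
    truth_targets: pd.DataFrame
    truth_go: pd.DataFrame
    truth_summary: dict
    utrs: dict
    go_annotation: dict
    seed_specs: list  # [(mature_id, ref SeedSpec, alt SeedSpec)]
    bed: list
    paths: dict = field(default_factory=dict)


def make_hairpin(stem_len: int, loop_len: int, rng, wc_frac: float = 0.95) -> str:
    """A stem-loop RNA: random stem, A/C-rich loop, reverse-complement closure.

    A fraction ``1 - wc_frac`` of stem positions is converted to G.U wobbles;
    the rest are Watson-Crick, so the intended stem is the dominant fold.
    """
    if stem_len < 5 or loop_len < 3:
        raise ValueError("need stem_len >= 5 and loop_len >= 3")
    stem5 = rng.choice(_DNA, size=stem_len)
    stem3 = np.array([_COMPLEMENT[b] for b in stem5[::-1]])
    for idx in range(stem_len):
        if rng.random() < 1 - wc_frac:
            b5 = stem5[idx]
            if b5 == "G":
                stem3[stem_len - 1 - idx] = "T"  # G.U wobble
            elif b5 == "T":
                stem3[stem_len - 1 - idx] = "G"
    loop = rng.choice(np.array(list("AAAC")), size=loop_len)
    return dna_to_rna("".join(stem5) + "".join(loop) + "".join(stem3))


def _pick_alt(ref_dna: str, transition: bool, rng) -> str:
    if transition:
        return _TRANSITION[ref_dna]
    return str(rng.choice(list(_TRANSVERSIONS[ref_dna])))


def _hw_genotypes(p: float, n_samples: int, missing_rate: float, rng):
    gts = []
    for _ in range(n_samples):
        if missing_rate and rng.random() < missing_rate:
            gts.append(None)
        else:
            gts.append(tuple(int(rng.random() < p) for _ in range(2)))
    return gts


def make_cohort(cfg: SimConfig, outdir=None) -> SimResult:
    """Generate the full synthetic cohort; write files when ``outdir`` given."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    # ------------------------------------------------------------------ loci
    annotations = []
    geometry = {}  # pid -> dict(stem, loop, mature_off, mature_id, L)
    chrom_cursor = {"chr1": 1000, "chr2": 1000}
    chroms = ["chr1", "chr2"]
    for i in range(cfg.n_precursors):
        pid = f"sim-mir-{i + 1}"
        stem = int(rng.integers(cfg.stem_len_range[0], cfg.stem_len_range[1] + 1))
        loop = int(rng.integers(cfg.loop_len_range[0], cfg.loop_len_range[1] + 1))
        hairpin = make_hairpin(stem, loop, rng, cfg.wc_stem_frac)
        L = len(hairpin)
        strand = "-" if rng.random() < cfg.frac_minus_strand else "+"
        chrom = chroms[i % 2]
        start = chrom_cursor[chrom] + int(rng.integers(200, 601))
        chrom_cursor[chrom] = start + L
        iv = GenomicInterval(chrom, start, start + L, strand)
        arm = "5p" if rng.random() < 0.5 else "3p"
        d = int(rng.integers(0, 4))
        mature_off = d if arm == "5p" else L - 22 - d
        mid = f"sim-miR-{i + 1}-{arm}"
        if strand == "+":
            miv = GenomicInterval(chrom, start + mature_off, start + mature_off + 22, "+")
        else:
            miv = GenomicInterval(chrom, iv.end - mature_off - 22, iv.end - mature_off, "-")
        annotations.append(MirnaAnnotation(pid, iv, matures=[(mid, miv)], hairpin_seq=hairpin))
        geometry[pid] = {"stem": stem, "loop": loop, "mature_off": mature_off,
                         "mature_id": mid, "L": L}

    def genomic_pos(ann, off):
        iv = ann.precursor_interval
        return iv.start + off if iv.strand == "+" else iv.end - 1 - off

    # ------------------------------------------------------- SNP placement
    host_idx = rng.choice(cfg.n_precursors, size=cfg.n_unique_snp_precursors, replace=False)
    hosts = [annotations[int(i)] for i in host_idx]
    slots = list(hosts)  # one SNP per unique precursor, extras over the same hosts
    extra = cfg.n_total_snps - cfg.n_unique_snp_precursors
    slots += [hosts[int(i)] for i in
              rng.choice(cfg.n_unique_snp_precursors, size=extra, replace=True)]

    labels = (
        ["seed"] * cfg.n_seed_snps
        + ["mature_nonseed"] * cfg.n_mature_nonseed_snps
        + ["precursor_nonmature"] * cfg.n_precursor_nonmature_snps
    )
    ts_flags = []
    for comp_n, n_ts in zip(
        (cfg.n_seed_snps, cfg.n_mature_nonseed_snps, cfg.n_precursor_nonmature_snps),
        cfg.n_transitions,
    ):
        ts_flags += [True] * n_ts + [False] * (comp_n - n_ts)
    # seed SNPs stay on the first slots (distinct precursors); shuffle the rest
    rest = list(zip(labels[cfg.n_seed_snps:], ts_flags[cfg.n_seed_snps:]))
    rng.shuffle(rest)
    plan = list(zip(labels[: cfg.n_seed_snps], ts_flags[: cfg.n_seed_snps])) + rest

    used_offsets: dict[str, set] = {}
    truth_rows = []
    records = []  # dicts: chrom,pos0,ref,alts,dp,genotypes,gqs,tag
    seed_snp_info = []  # (ann, mature_id, pos0)

    for (comp, is_ts), ann in zip(plan, slots):
        geo = geometry[ann.precursor_id]
        mo, L = geo["mature_off"], geo["L"]
        stem, loop = geo["stem"], geo["loop"]
        used = used_offsets.setdefault(ann.precursor_id, set())
        if comp == "seed":
            # positions 2-7 only: keeps ref/alt seed-site cores distinguishable
            candidates = [mo + p - 1 for p in range(2, 8)]
        elif comp == "mature_nonseed":
            candidates = [mo] + [mo + p - 1 for p in range(9, 23)]
        else:
            candidates = [o for o in range(L) if not (mo <= o < mo + 22)]
        candidates = [o for o in candidates if o not in used]
        if not candidates:
            raise ValueError(
                f"infeasible placement: no free {comp} position in {ann.precursor_id}"
            )
        off = int(rng.choice(candidates))
        used.add(off)
        sense_ref = rna_to_dna(ann.hairpin_seq[off])
        sense_alt = _pick_alt(sense_ref, is_ts, rng)
        strand = ann.precursor_interval.strand
        g_ref = sense_ref if strand == "+" else _COMPLEMENT[sense_ref]
        g_alt = sense_alt if strand == "+" else _COMPLEMENT[sense_alt]
        pos0 = genomic_pos(ann, off)
        p_alt = float(rng.uniform(*cfg.maf_range))
        records.append(
            dict(chrom=ann.precursor_interval.chrom, pos0=pos0, ref=g_ref,
                 alts=[g_alt], dp=max(6, int(rng.poisson(cfg.mean_depth))),
                 genotypes=_hw_genotypes(p_alt, cfg.n_samples, cfg.missing_rate, rng),
                 gqs=[int(rng.integers(31, 100)) for _ in range(cfg.n_samples)],
                 tag="mirna_snp")
        )
        in_loop = stem <= off < stem + loop
        stem_disrupting = False
        if not in_loop:
            partner = L - 1 - off
            five, three = (off, partner) if off < partner else (partner, off)
            ref_pairable = can_pair(ann.hairpin_seq[five], ann.hairpin_seq[three])
            alt_h = dna_to_rna(sense_alt)
            if off < partner:
                alt_pairable = can_pair(alt_h, ann.hairpin_seq[partner])
            else:
                alt_pairable = can_pair(ann.hairpin_seq[partner], alt_h)
            stem_disrupting = ref_pairable and not alt_pairable
        mpos = off - mo + 1 if mo <= off < mo + 22 else 0
        truth_rows.append(
            dict(chrom=ann.precursor_interval.chrom, vcf_pos=pos0 + 1,
                 precursor_id=ann.precursor_id,
                 mature_id=geo["mature_id"] if mpos else "",
                 compartment=comp, mature_position=mpos,
                 hairpin_offset=off, sense_ref=sense_ref, sense_alt=sense_alt,
                 is_transition=is_ts, true_p=p_alt, true_maf=min(p_alt, 1 - p_alt),
                 in_loop=in_loop, stem_disrupting=stem_disrupting)
        )
        if comp == "seed":
            seed_snp_info.append((ann, geo["mature_id"], pos0))

    # ------------------------------------------------- extra ingest records
    def _random_clean_offset(ann, width=2):
        used = used_offsets.setdefault(ann.precursor_id, set())
        L = geometry[ann.precursor_id]["L"]
        for _ in range(200):
            off = int(rng.integers(0, L - width))
            span = set(range(off, off + width))
            if not (span & used):
                used |= span
                return off
        raise RuntimeError("could not place record")

    for k in range(cfg.n_premirna_indels):
        ann = annotations[int(rng.choice(cfg.n_precursors))]
        off = _random_clean_offset(ann)
        pos0 = min(genomic_pos(ann, off), genomic_pos(ann, off + 1))
        records.append(
            dict(chrom=ann.precursor_interval.chrom, pos0=pos0, ref=None, alts=None,
                 dp=max(6, int(rng.poisson(cfg.mean_depth))),
                 genotypes=_hw_genotypes(0.2, cfg.n_samples, 0.0, rng),
                 gqs=[int(rng.integers(31, 100)) for _ in range(cfg.n_samples)],
                 tag="indel_del" if k % 2 == 0 else "indel_ins")
        )

    for _ in range(cfg.n_fail_dp):
        ann = annotations[int(rng.choice(cfg.n_precursors))]
        off = _random_clean_offset(ann, width=1)
        records.append(
            dict(chrom=ann.precursor_interval.chrom, pos0=genomic_pos(ann, off),
                 ref=None, alts="snp", dp=int(rng.integers(1, 6)),
                 genotypes=_hw_genotypes(0.3, cfg.n_samples, 0.0, rng),
                 gqs=[int(rng.integers(31, 100)) for _ in range(cfg.n_samples)],
                 tag="fail_dp")
        )

    n_flank = cfg.n_offtarget_snps + cfg.n_multiallelic + cfg.n_fail_gq_sites
    flank_hosts = rng.choice(cfg.n_precursors, size=n_flank, replace=False)
    offtarget_specs = []
    for j, hi in enumerate(flank_hosts):
        iv = annotations[int(hi)].precursor_interval
        pos0 = iv.start - int(rng.integers(10, cfg.flank_bp - 5))
        tag = ("offtarget_snp" if j < cfg.n_offtarget_snps
               else "multiallelic" if j < cfg.n_offtarget_snps + cfg.n_multiallelic
               else "fail_gq")
        offtarget_specs.append((iv.chrom, pos0, tag))

    # --------------------------------------------------------------- genome
    chrom_arrays = {}
    for chrom in chroms:
        length = chrom_cursor[chrom] + 2000
        chrom_arrays[chrom] = np.array(rng.choice(_DNA, size=length), dtype="<U1")
    for ann in annotations:
        iv = ann.precursor_interval
        dna = rna_to_dna(ann.hairpin_seq)
        if iv.strand == "-":
            dna = revcomp_dna(dna)
        chrom_arrays[iv.chrom][iv.start : iv.end] = list(dna)

    # reference alleles that depend on the assembled genome
    for rec in records:
        if rec["tag"] == "mirna_snp":
            continue
        seq = chrom_arrays[rec["chrom"]]
        base = str(seq[rec["pos0"]])
        if rec["tag"] == "indel_del":
            rec["ref"], rec["alts"] = base + str(seq[rec["pos0"] + 1]), [base]
        elif rec["tag"] == "indel_ins":
            rec["ref"], rec["alts"] = base, [base + str(rng.choice(_DNA))]
        else:  # fail_dp SNP
            rec["ref"] = base
            rec["alts"] = [str(rng.choice([b for b in "ACGT" if b != base]))]
    for chrom, pos0, tag in offtarget_specs:
        base = str(chrom_arrays[chrom][pos0])
        others = [b for b in "ACGT" if b != base]
        if tag == "multiallelic":
            alts = [str(a) for a in rng.choice(others, size=2, replace=False)]
            gts = [(int(rng.integers(0, 3)), int(rng.integers(0, 3)))
                   for _ in range(cfg.n_samples)]
        else:
            alts = [str(rng.choice(others))]
            gts = _hw_genotypes(float(rng.uniform(*cfg.maf_range)),
                                cfg.n_samples, 0.0, rng)
        gqs = [int(rng.integers(31, 100)) for _ in range(cfg.n_samples)]
        if tag == "fail_gq":
            for s in range(0, cfg.n_samples, 4):
                gqs[s] = int(rng.integers(1, 31))  # masked to missing at ingest
        records.append(
            dict(chrom=chrom, pos0=pos0, ref=base, alts=alts,
                 dp=max(6, int(rng.poisson(cfg.mean_depth))),
                 genotypes=gts, gqs=gqs, tag=tag)
        )
    records.sort(key=lambda r: (r["chrom"], r["pos0"]))

    # ----------------------------------------------------- targeted regions
    bed = [
        GenomicInterval(a.precursor_interval.chrom,
                        a.precursor_interval.start - cfg.flank_bp,
                        a.precursor_interval.end + cfg.flank_bp,
                        a.precursor_interval.strand)
        for a in sorted(annotations,
                        key=lambda a: (a.precursor_interval.chrom,
                                       a.precursor_interval.start))
    ]

    # ------------------------------------------- UTRs with planted seed sites
    seed_specs = []
    for ann, mid, pos0 in seed_snp_info:
        rec = next(r for r in records
                   if r["tag"] == "mirna_snp"
                   and r["chrom"] == ann.precursor_interval.chrom
                   and r["pos0"] == pos0)
        v = Variant(rec["chrom"], rec["pos0"], rec["ref"], rec["alts"][0],
                    VariantClass.SNP)
        call = classify_snp(v, ann)[0]
        assert call.compartment == "seed"
        seed_specs.append((mid, extract_seed(ann, mid), extract_seed(ann, mid, snp=call)))

    all_specs = [sp for _, r, a in seed_specs for sp in (r, a)]
    site_cores = [revcomp_dna(rna_to_dna(sp.seed7))[1:] for sp in all_specs]  # 6mer cores

    genes = [f"g{idx + 1:04d}" for idx in range(cfg.n_utr_genes)]

    def _clean_utr():
        while True:
            utr = "".join(rng.choice(_DNA, size=cfg.utr_len))
            if not any(core in utr for core in site_cores):
                return utr

    utrs = {g: _clean_utr() for g in genes}
    wanted: dict[str, set] = {g: set() for g in genes}
    planted_regions: dict[str, list] = {g: [] for g in genes}

    def _plant(gene, spec):
        """Insert one 8mer site for ``spec``, preserving earlier planted sites."""
        site = revcomp_dna(rna_to_dna(spec.seed7)) + "A"
        for _ in range(200):
            utr = utrs[gene]
            pos = int(rng.integers(10, len(utr) - len(site) - 10))
            if any(pos < e and pos + len(site) > s for s, e in planted_regions[gene]):
                continue
            new = utr[:pos] + site + utr[pos + len(site):]
            # the splice must not create a site for any seed not wanted here
            spurious = any(
                sp.seed7 not in wanted[gene] and find_sites(sp, new)
                for sp in all_specs
            )
            if not spurious:
                utrs[gene] = new
                planted_regions[gene].append((pos, pos + len(site)))
                return
        raise RuntimeError(f"could not plant site in {gene}")

    target_truth_rows = []
    gene_pool = list(genes)
    rng.shuffle(gene_pool)
    cursor = 0
    for (mid, ref_seed, alt_seed), (n_ref_only, n_common, n_alt_only) in zip(
        seed_specs, cfg.target_plan
    ):
        block = gene_pool[cursor : cursor + n_ref_only + n_common + n_alt_only]
        cursor += len(block)
        ref_only = block[:n_ref_only]
        common = block[n_ref_only : n_ref_only + n_common]
        alt_only = block[n_ref_only + n_common :]
        for g in ref_only + common:
            wanted[g].add(ref_seed.seed7)
        for g in common + alt_only:
            wanted[g].add(alt_seed.seed7)
        for g in ref_only + common:
            _plant(g, ref_seed)
        for g in common + alt_only:
            _plant(g, alt_seed)
        target_truth_rows += (
            [dict(mirna_id=mid, gene=g, role="ref_only") for g in ref_only]
            + [dict(mirna_id=mid, gene=g, role="common") for g in common]
            + [dict(mirna_id=mid, gene=g, role="alt_only") for g in alt_only]
        )
    truth_targets = pd.DataFrame(target_truth_rows)

    # --------------------------------------------------------- GO annotation
    terms = [f"GO:{7000000 + t}" for t in range(cfg.n_go_terms)]
    go_annotation: dict[str, set] = {t: set() for t in terms}
    for g in genes:
        for t in rng.choice(terms, size=cfg.go_terms_per_gene, replace=False):
            go_annotation[str(t)].add(g)
    go_truth_rows = []
    for snp_i, (mid, _, _) in enumerate(seed_specs):
        sub = truth_targets[truth_targets.mirna_id == mid]
        ref_genes = sorted(sub[sub.role.isin(["ref_only", "common"])].gene)
        # alt-enriched term drawn from alt-ONLY genes so it cannot reach
        # significance in the reference run (k_ref = 0)
        alt_genes = sorted(sub[sub.role == "alt_only"].gene)
        t_ref, t_alt = f"GO:{7100000 + snp_i}", f"GO:{7200000 + snp_i}"
        n_ref = min(len(ref_genes), max(3, int(cfg.go_planted_frac * len(ref_genes))))
        n_alt = min(len(alt_genes), max(3, int(cfg.go_planted_frac * len(alt_genes))))
        go_annotation[t_ref] = {str(g) for g in
                                rng.choice(ref_genes, size=n_ref, replace=False)}
        go_annotation[t_alt] = {str(g) for g in
                                rng.choice(alt_genes, size=n_alt, replace=False)}
        go_truth_rows.append(dict(mirna_id=mid, term=t_ref, enriched_in="reference"))
        go_truth_rows.append(dict(mirna_id=mid, term=t_alt, enriched_in="snp_altered"))

    # ----------------------------------------------------------- summaries
    truth_summary = {
        "n_vcf_records": len(records),
        "n_fail_dp": cfg.n_fail_dp,
        "n_premirna_variants": cfg.n_total_snps + cfg.n_premirna_indels,
        "n_premirna_snps": cfg.n_total_snps,
        "n_unique_snp_precursors": cfg.n_unique_snp_precursors,
        "compartment_counts": {
            "seed": cfg.n_seed_snps,
            "mature_nonseed": cfg.n_mature_nonseed_snps,
            "precursor_nonmature": cfg.n_precursor_nonmature_snps,
        },
        "n_transitions_total": int(sum(cfg.n_transitions)),
        "total_premirna_bp": int(sum(len(a.precursor_interval) for a in annotations)),
        "total_targeted_bp": int(sum(len(iv) for iv in bed)),
        "venn": [
            dict(mirna_id=mid, n_ref=tp[0] + tp[1], n_alt=tp[1] + tp[2],
                 n_common=tp[1], n_lost=tp[0], n_gained=tp[2])
            for (mid, _, _), tp in zip(seed_specs, cfg.target_plan)
        ],
    }

    result = SimResult(
        config=cfg,
        annotations=annotations,
        chrom_seqs={c: "".join(s) for c, s in chrom_arrays.items()},
        records=records,
        truth_snps=pd.DataFrame(truth_rows),
        truth_targets=truth_targets,
        truth_go=pd.DataFrame(go_truth_rows),
        truth_summary=truth_summary,
        utrs=utrs,
        go_annotation=go_annotation,
        seed_specs=seed_specs,
        bed=bed,
    )
    if outdir is not None:
        _write_cohort(result, Path(outdir))
    return result


# ---------------------------------------------------------------- writers

def _write_cohort(res: SimResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    p = res.paths

    p["genome_fasta"] = outdir / "genome.fa"
    with open(p["genome_fasta"], "w") as fh:
        for chrom, seq in res.chrom_seqs.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")

    p["hairpin_fasta"] = outdir / "hairpins.fa"
    with open(p["hairpin_fasta"], "w") as fh:
        for ann in res.annotations:
            fh.write(f">{ann.precursor_id}\n{ann.hairpin_seq}\n")

    p["gff"] = outdir / "mirna.gff3"
    with open(p["gff"], "w") as fh:
        fh.write("##gff-version 3\n")
        for ann in res.annotations:
            iv = ann.precursor_interval
            fh.write(
                f"{iv.chrom}\t.\tmiRNA_primary_transcript\t{iv.start + 1}\t{iv.end}"
                f"\t.\t{iv.strand}\t.\tID={ann.precursor_id};Name={ann.precursor_id}\n"
            )
            for mid, miv in ann.matures:
                fh.write(
                    f"{miv.chrom}\t.\tmiRNA\t{miv.start + 1}\t{miv.end}\t.\t{miv.strand}"
                    f"\t.\tID={mid};Name={mid};Derives_from={ann.precursor_id}\n"
                )

    p["bed"] = outdir / "targets.bed"
    with open(p["bed"], "w") as fh:
        for iv in res.bed:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t.\t0\t{iv.strand}\n")

    p["vcf"] = outdir / "variants.vcf"
    _write_vcf(p["vcf"], res.records, res.chrom_seqs, res.config.n_samples)

    p["utr_fasta"] = outdir / "utrs.fa"
    with open(p["utr_fasta"], "w") as fh:
        for gene, utr in res.utrs.items():
            fh.write(f">{gene}\n{utr}\n")

    p["go_tsv"] = outdir / "go.tsv"
    with open(p["go_tsv"], "w") as fh:
        for term in sorted(res.go_annotation):
            for gene in sorted(res.go_annotation[term]):
                fh.write(f"{gene}\t{term}\n")

    p["truth_snps"] = outdir / "truth_snps.tsv"
    res.truth_snps.to_csv(p["truth_snps"], sep="\t", index=False)
    p["truth_targets"] = outdir / "truth_targets.tsv"
    res.truth_targets.to_csv(p["truth_targets"], sep="\t", index=False)
    p["truth_go"] = outdir / "truth_go.tsv"
    res.truth_go.to_csv(p["truth_go"], sep="\t", index=False)
    p["truth_summary"] = outdir / "truth_summary.json"
    with open(p["truth_summary"], "w") as fh:
        json.dump(res.truth_summary, fh, indent=2)
    p["config"] = outdir / "sim_config.json"
    with open(p["config"], "w") as fh:
        json.dump(asdict(res.config), fh, indent=2)


def _write_vcf(path, records, chrom_seqs, n_samples) -> None:
    samples = [f"S{i + 1:02d}" for i in range(n_samples)]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom, seq in chrom_seqs.items():
            fh.write(f"##contig=<ID={chrom},length={len(seq)}>\n")
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Total depth">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for rec in records:
            gt_strs = []
            for gt, gq in zip(rec["genotypes"], rec["gqs"]):
                g = "./." if gt is None else f"{gt[0]}/{gt[1]}"
                gt_strs.append(f"{g}:{gq}")
            fh.write(
                f"{rec['chrom']}\t{rec['pos0'] + 1}\t.\t{rec['ref']}\t"
                f"{','.join(rec['alts'])}\t100\tPASS\tDP={rec['dp']}\tGT:GQ\t"
                + "\t".join(gt_strs) + "\n"
            )
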