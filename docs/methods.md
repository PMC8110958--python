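# Methods

## Coordinates, strands and alleles

All intervals and positions are held 0-based, half-open; conversion from the
1-based inclusive conventions of VCF and GFF3 happens once, at the format
boundary. Hairpin sequences are stored sense-strand 5′→3′ in the RNA
alphabet; genome and UTR FASTAs are DNA. For a precursor on the − strand,
mature position 1 is the genomically rightmost mature base, and substitution
alleles are complemented onto the miRNA sense strand before classification.
Because published tables do not always state their strand convention,
reporting can be switched to the raw VCF alleles (`strand_convention:
vcf_ref`); the transition/transversion aggregate is identical either way,
since complementation maps transitions to transitions.

## Ingest filters

The VCF stage applies the two hard filters of the upstream calling protocol:
site depth `DP > 5` (exclusive, record-level, from INFO/DP) and genotype
quality `GQ > 30` (exclusive, genotype-level — a failing genotype becomes
missing rather than dropping the record, because depth is a property of the
site while quality is a property of the call). Whether "total depth" means
INFO/DP or summed sample depth is ambiguous in such protocols; INFO/DP is
the default and the thresholds are configurable. Multi-allelic records are
split into per-alternate biallelic records first, since all downstream
statistics are per-substitution; a genotype referencing a different
alternate becomes missing in each split record. Indels and complex variants
survive ingest (they appear in the audit funnel) but are excluded from all
miRNA-SNP statistics.

## Compartment classification

Seed = mature positions 2–8, 1-based from the mature 5′ end; position 1 and
positions ≥ 9 are `mature_nonseed`; anything else inside the precursor is
`precursor_nonmature`. Priority is seed > mature_nonseed >
precursor_nonmature. A SNP inside two overlapping matures of one precursor
yields both calls, flagged ambiguous; a site under two distinct precursors
yields one call per precursor, and genome-level summaries deduplicate by
site (keeping the highest-priority compartment) so the compartment counts
partition the SNP set. Percentages are reported to one decimal by round-half
-even; the unique-precursor percentage is taken over all annotated
precursors.

## Population statistics

MAF and observed heterozygosity are genotype-based (the cohort sizes this
pipeline is aimed at — tens of animals — make read-count frequencies
inappropriate). Sites with no called genotype are excluded from means with a
logged note. Summary means are reported ± population SD (divisor n), with a
flag for the n−1 convention. Inter-SNP distances are between consecutive
distinct sites on the same chromosome; cross-chromosome pairs are physically
undefined and excluded, which must be remembered when comparing against
published genome-wide averages. Density is SNPs per kb of a stated region
(total precursor length, or the capture BED).

## Folding model

`ΔΔG = MFE(alt) − MFE(ref)`; both folds use the same engine, and "increase"
(ΔΔG ≥ +0.05 kcal/mol) means destabilization. The 0.05 threshold makes 0.1
the smallest nonzero change at one-decimal reporting, matching how such
energy shifts are conventionally printed. Structure change is decided by
comparing base-pair sets of the two MFE structures, so it can be positive
even when ΔΔG rounds to ~0.1 — and, conversely, a hairpin-loop SNP that
leaves the structure intact changes the energy by exactly 0 under the
built-in model, whose loop terms depend only on loop size.

The `loop_energy` engine is a Zuker-style dynamic program over an additive
loop decomposition: Turner-style stacking free energies for the six
canonical pair types, length-dependent initiation penalties for hairpin
(≥3 nt), bulge and internal loops with `1.079·ln(n/n_max)` extrapolation and
a capped asymmetry term, an affine multiloop cost (closing 3.4, branch 0.4,
unpaired 0.0 kcal/mol), interior loops capped at 30 nt, and integer
0.1-kcal/mol arithmetic so the DP is exact. Dangles, terminal-AU penalties
and sequence-dependent loop bonuses are deliberately omitted so that the
dynamic program and the independent structure evaluator implement the
identical model — the test suite verifies DP optimality against exhaustive
enumeration of all structures for lengths ≤ 20. Co-optimal structures are
resolved by a fixed traceback order (prefer the 5′-most, then
shortest-range pair in `nussinov`; hairpin, two-loop by ascending inner
index, then multiloop split in `loop_energy`), so folding is bit-for-bit
deterministic and the structure-changed flag is reproducible. Lonely pairs
are not prohibited outright; the loop model penalizes them energetically.

Absolute energies from `loop_energy` are close to but not identical with
RNAfold's (which adds dangles, mismatch terms and special loops); analyses
that must match published absolute energies should use the `external`
engine. Per-hairpin results for the same engine are comparable regardless.

Hairpins carrying several SNPs are folded once per SNP (one substitution at
a time) and the number of multi-SNP precursors is reported, rather than
silently dropping them or compounding substitutions.

## Target prediction and switching

Full hybridization/alignment scoring of miRNA–mRNA duplexes is intentionally
out of scope: seed-SNP switching is driven by canonical seed pairing, so the
stage implements exact seed matching with the standard site taxonomy (6mer,
7mer-m8, 7mer-A1, 8mer; default `any7plus` = any ≥7-nt site). UTRs are
scanned on the given strand only; multiple sites in one UTR count once.
Absolute target counts from consensus predictors depend on their scoring
and UTR database and are not comparable; the set identities
(|ref| = |common| + |lost|, |alt| = |common| + |gained|) and exact recovery
of planted sites are the testable contract.

## Enrichment

Over-representation only: `p = P(X ≥ k)` from the hypergeometric
distribution with BH step-up FDR across tested terms. The default universe
is the annotated UTR genes (`--universe all_utr_genes` uses every UTR gene);
terms with no annotated universe gene are skipped. GO-graph propagation and
term-redundancy reduction are out of scope. Both an FDR and a raw-p
threshold are exposed (default FDR ≤ 0.05) since published figures sometimes
label raw-p cuts. The discrete test is conservative: under the null the
fraction of p ≤ 0.05 sits slightly below 0.05, which the calibration test
accounts for by using a large universe and binomial-CI bounds.

## Synthetic cohort

The generator's defaults emulate the targeted-sequencing study design this
pipeline was built around: 23 diploid samples; 381 precursors, half on each
strand, built as stem (30–43 nt) + A/C-rich loop (4–9 nt) + reverse
complement with 5% G·U wobbles — ~80 nt each, ~30.5 kb in total, matching
typical pre-miRNA lengths; 73 SNPs in 50 distinct precursors split 2/12/59
across seed / mature-nonseed / precursor-nonmature with 2/8/50 transitions
(≈82% transitions over all precursor SNPs, ≈71% within matures); planted
alternate-allele frequencies uniform on [0.05, 0.5] (mean 0.275) with
Hardy–Weinberg genotypes; mean site depth 57. Ingest is exercised by 8
planted pre-miRNA indels, records failing DP > 5, a multi-allelic record,
low-GQ genotypes and off-target flank SNPs. Seed SNPs are planted at mature
positions 2–7 (a position-8 SNP leaves the 6mer site core unchanged, which
would make ref and alt planted sites indistinguishable). UTRs are
rejection-sampled to contain no accidental site core for any seed variant
before 8mer sites are spliced in, so target recovery is exact; GO truth
plants one term concentrated in each reference target set and one in the
alt-only genes.

What the generator does not emulate: linkage between sites, sequencing-error
or mapping artifacts, non-templated isomiR variation, realistic miRNA
sequence composition (stems are near-perfectly paired, so planted
stem-disrupting SNPs destabilize more strongly than typical natural
variants — cohort mean |ΔΔG| runs higher than published estimates from real
hairpins, and most changes are increases), and heterozygote excess relative
to Hardy–Weinberg (observed cohorts can show obs-het above 2p(1−p); the
generator is HW-neutral, giving mean obs-het ≈ 0.37 at the default allele
frequencies). Passing tests therefore demonstrate correctness of the
computations and bookkeeping, not distributional realism of real capture
data.

## Problem sizes in tests

Per-module tests use a scaled cohort (40 precursors, 17 SNPs, 12 samples);
the acceptance tests and `scripts/acceptance.py` use the full study-scale
design (381/73/23). Folding property tests enumerate all structures for 200
random sequences of length ≤ 20; Monte-Carlo checks use 500 Hardy–Weinberg
replicates at n = 23 and 1000 null-enrichment replicates, all with fixed
seeds.
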