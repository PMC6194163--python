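# Methods

## Scope and model

`mitotriage` implements the two-step diagnostic workflow for suspected
mitochondrial disease as a deterministic, testable pipeline over a
*synthetic* cohort. A cohort manifest describes each family's structure
(strategy A: consanguineous and/or >1 affected patient; strategy B: a
single patient of non-consanguineous parents), its clinical group
(1: probable/definite mitochondrial disease by the MDC score; 2: possible),
and its planted causal defect, if any. The simulator expands the manifest
into the raw inputs the callers consume; the callers and filters never see
the planted truth. The packaged manifest contains 117 families: 23 with
mtDNA defects, 57 with nuclear defects (27 strategy A, 30 strategy B,
8 de novo), and 37 defect-free. One manifest row is one family and one
unit of every yield denominator; two families contribute two affected
siblings each to the mtDNA stage, so patient-wise counting would differ —
row-wise counting is the convention throughout.

## mtDNA stage

**Coordinates.** The mitochondrial genome is numbered 1..16569 (rCRS
convention without the historical placeholder at 3107). The packaged
reference sequence is synthetic: a fixed-seed pseudo-random 16,569 nt
sequence with the reference alleles at the classical pathogenic sites
pinned (m.3243 A, m.11778 G, m.13513 G, m.14484 T) and with the planted
deletion junction boundaries kept free of direct repeats, so every planted
junction is its own leftmost representation. All calling logic is
content-agnostic; the synthetic sequence exists so no genomic data needs
shipping.

**Heteroplasmy.** Estimated as mutant read depth over total depth. The
simulator draws the alternate depth Binomial(depth, h) at the planted
heteroplasmy h, which makes the estimator exactly unbiased; the test suite
checks the 100-replicate mean at h = 0.5, depth 1000 against a 3-standard-
error band. Cutoffs: 2% for alleles in the known-pathogenic table, 5%
otherwise, both *inclusive* (the boundary case passes; the source
convention is unstated, and inclusivity makes a 2.0% known call
reportable). The D-loop is excluded with bounds 16024–16569 and 1–576
(standard control-region definition; configurable, since only "the
highly polymorphic D-loop" is specified clinically).

**Deletion breakpoints.** Junction-spanning reads are emitted unaligned
and the caller places them: the maximal exact reference match of the read
prefix and of the read suffix (each anchored by ≥20 exactly matching
bases; configurable) must jointly cover the read, and the interval of
consistent split points — a direct repeat at the junction makes several
splits sequence-equivalent — is resolved to the *leftmost* (b5, b3).
Repeat-shifted observations of one event therefore merge; an event needs
≥3 supporting reads (default), and >1 distinct event classifies the
sample as carrying multiple deletions. Size is `b3 − b5 − 1`, the unique
convention consistent with all three published breakpoint/size pairs the
suite pins (8482:13460→4977, 7462:15747→8284, 9514:15792→6277).
Circularity is handled by doubling the linear reference and reducing
coordinates modulo 16569; origin-spanning deletions are not simulated and
calls with b3 ≤ b5 after reduction are discarded (documented contract).
The exact-anchor specialisation is correct at the simulator's default
error rate of 0; with a configured error rate the anchors must still
match exactly, which is the caller's main robustness limitation. A
brute-force oracle — exhaustive enumeration of all (b5, b3) pairs whose
junction sequence contains the read spanning the junction — verifies the
placement, including the leftmost-normalisation, on toy references.

**Copy number.** qPCR is modelled as one mt/nuclear ratio per patient
plus a healthy-control set (default 10 controls, ratios ~ Normal(1, 0.05)).
Percent-of-control is the patient ratio over the control mean × 100;
depletion families are planted at 12–28% of the control mean (inside the
10–30% band typical of depletion syndromes) and the depletion threshold
defaults to 35%, comfortably separating the two populations at the
simulated noise level.

**Triage.** Multiple deletions or depletion always escalate to the exome
stage (they indicate a nuclear maintenance-gene defect), taking precedence
over any point-variant finding; then a passing known-pathogenic point
variant solves, then a single large deletion solves; otherwise the family
is negative and proceeds to the exome stage.

## Homozygosity mapping

Genotype tracks are biallelic marker arrays (50 kb spacing in the
simulator). A run of homozygosity is a maximal stretch of non-heterozygous
informative markers — missing calls neither break nor extend a run —
whose physical span (first to last marker) reaches the cutoff, default
5 Mb. The het tolerance defaults to 0 (simulated tracks are error-free);
with a positive tolerance the scan is greedy left-to-right and runs stay
disjoint. Consanguineous families are given one ≥5 Mb run containing their
planted homozygous variant plus sub-cutoff decoys (3 Mb and 4.9 Mb);
non-consanguineous families only sub-cutoff runs. ROH overlap *ranks*
recessive candidates, it never excludes them — a hard filter would kill
legitimate compound heterozygotes in consanguineous families.

## Exome stage

The filter cascade is: frequency (annotated variants kept iff population
AF < 1% strictly; non-annotated kept iff in-house AF ≤ 5% — "exceeding"
read as strict), then effect (nonsense/frameshift/splice kept
unconditionally, even when predictors call them benign; missense kept
with ≥1 of 4 damaging predictor calls, configurable; synonymous/other
removed). The two filters commute, which the suite asserts.

Inheritance models: AR-homozygous (all affected hom-alt, no unaffected
hom-alt), AR-compound-heterozygous (≥2 kept heterozygous variants in one
gene, in trans by parental genotypes; unphasable pairs are retained and
flagged rather than dropped, since parental data may be missing; cis
pairs are rejected), and X-linked recessive (hemizygous affected males,
carrier-or-absent unaffecteds) are evaluated for *every* family — most
solved singleton families are in fact recessive. Dominant screening
applies only to strategy-B families and is restricted to the packaged
OMIM-derived dominant-disease gene panel: a heterozygous panel-gene
variant absent from both parents is de novo; present in a parent it is
retained but flagged inherited, and segregation then requires that parent
to be flagged subclinical; with missing parents the de novo status is
unknown. This panel restriction reproduces the workflow as practised —
including its known blind spot for de novo variants in novel genes.

Segregation requires every affected member to carry the mode-consistent
genotype and no unaffected member to carry a disease-consistent one.
A family is *solved* only by a segregating candidate whose variants all
carry class 4/5 annotations; pathogenicity classes are consumed as
annotations (an ACMG engine is out of scope), so class ≤3 candidates are
variants of unknown significance and never solve. Multi-genic families
(up to three causal genes) report all passing genes, each with its own
gene-panel membership flag.

## Simulator guarantees and limits

Planted truth — which defect a family carries, variant identities,
zygosities, annotations — is a deterministic function of the manifest
(stable hashes of gene names); the run seed only moves read noise,
background variants and control values. Regeneration under one seed is
byte-identical; per-family generators are independent streams keyed by
(seed, family id). Background exome variants (default 120 per family)
are constructed to fall out of the cascade: common, benign-predicted,
synonymous, in-house-common, panel-external heterozygous, cis pairs, or
segregation-inconsistent homozygotes — and all carry class ≤3, so even a
pathological survivor could not produce a false diagnosis. The suite
checks zero candidates on defect-free families across 20 seeds.

What the simulator does *not* emulate: sequencing chemistry and quality
strings, origin-spanning mtDNA fragments, tissue-specific heteroplasmy
drift (tissue exists only as a label), realistic linkage-disequilibrium
structure in genotype tracks, population-realistic background variant
spectra, and real gene coordinates (genes live on a synthetic 150 Mb-per-
chromosome canvas; the gene panels are synthetic stand-ins listing the
cohort's causal genes with their printed panel-membership flags plus
fillers). Passing tests therefore demonstrate the correctness of the
*decision logic* under clean, controlled inputs — not calling performance
on real reads, which depends on upstream alignment quality out of scope
here.

## Numerical and design choices

- Percentages are displayed as whole percent, rounded half away from zero
  (e.g. 27/40 → 68%); exact numerator/denominator pairs always accompany
  the percentage, and zero denominators are reported as undefined rather
  than raising.
- MDC scoring takes the three section scores (each capped at 4 with a
  warning) as inputs; the total bins as 0–1 unlikely (0 is a documented
  extension of the published 1/2–4/5–7/8–12 boundaries), 2–4 possible,
  5–7 probable, 8–12 definite. Group assignment defaults to total ≥5 →
  group 1; the source material is internally inconsistent about MDC = 5
  (both strict inequalities are quoted, and printed tables contain MDC-5
  patients in group 2), so the packaged manifest always uses the groups
  as printed and never recomputes them.
- mtDNA group-1 families in the packaged manifest have no published MDC
  scores; they are assigned scores 6–8, consistent with their printed
  group-1 (probable/definite) membership.
- Simulation defaults: mtDNA depth 1000×, read length 300 nt, base error
  rate 0 (so cutoff decisions are noise-free by construction;
  configurable upward for robustness experiments), 50 junction reads per
  deletion event, 120 background exome variants per family, 10 qPCR
  controls. The full 117-family pipeline runs in about one second on one
  CPU at these sizes.
- Per-family failures in a cohort run are flagged and excluded from
  denominators with a warning; `strict=True` aborts instead.

## Known limitations

- The deletion caller requires exact anchor matches; indel-tolerant arm
  alignment would be needed for noisy long reads.
- Compound-heterozygous phasing uses parental genotypes only (no
  read-backed phasing); both-parent carriers leave a pair unphasable.
- The dominant screen inherits the panel's blind spot for de novo
  variants in genes without reported dominant disease; trio-wide de novo
  discovery is deliberately not implemented.
- Heteroplasmy of large deletions is not quantified from reads (junction
  support is a detection count, not a load estimate); copy-number style
  quantification would be required, as in practice.
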