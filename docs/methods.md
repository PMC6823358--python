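# Methods

This note documents the models, thresholds and design choices behind
`cstyper`, and what the synthetic-data round trips do and do not
demonstrate about real data.

## Genomic-aberration subtyping

Samples are classified by an ordered decision tree; the order encodes the
etiological hierarchy (a proofreading-deficient tumor is POLE even when it
is also MSI-high, because the polymerase defect explains the phenotype):

1. **POLE** — any somatic nonsynonymous POLE variant whose codon (parsed
   from the `p.` protein change) lies in the exonuclease domain, codons
   268–471, or whose protein change is in the hotspot list (default
   P286R, V411L, S297F, A456P, S459F; configurable).
2. **MSI** — instability at ≥ 2 of the 6 panel markers (BAT25, BAT26,
   D2S123, D5S346, D17S250, BAT40). A plain count is used; no marker is
   privileged.
3. **CNH** — decided jointly over the remaining samples by consensus
   clustering of region-level copy number: the mean segment log2 ratio is
   computed per chromosome arm (a configurable region list; the default is
   the 44 arms of the synthetic genome model), then clustered with
   subsampled k-means (Euclidean distance, subsampling ratio 0.8, 1000
   repetitions, k ∈ {2,3,4}). The number of clusters is chosen by
   minimising PAC (proportion of ambiguous clustering, consensus values in
   (0.1, 0.9)); the area-under-consensus-CDF delta rule is also
   implemented (`k_selection="delta_area"`), but PAC discriminates planted
   k > 2 much more reliably, so it is the default. A cluster is labeled
   CNH when its median aberrant-segment count (segments with
   |log2R| ≥ 0.3) exceeds the cohort median by a margin (default 4) **or**
   reaches an absolute threshold (default 8). The absolute rule is needed
   because a purely relative rule degenerates when one class dominates the
   clustered residue (CNH is ~86% of it at the default cohort mix). With
   fewer than 10 clusterable samples the scalar rule (count ≥ 8) is used
   directly.
4. **CNL** — the residual class.

The driver-mutation genotype is independent: PTEN/ARID1A ⇒
endometrioid-like (evaluated first, mirroring the rule's statement order);
else TP53/PPP2R1A ⇒ serous-like; tumors mutated in both pairs are
endometrioid-like and flagged ambiguous.

## Variant processing

Per-caller tables are merged by a 2-of-3 consensus on (chrom, pos, ref,
alt); VAF and depth of a consensus call are the medians across supporting
callers (the merge rule does not specify an aggregation; the median is
robust to one outlier caller). Artifact filters, applied as independent
set intersections (order-free):

- mapping quality < 30 removed; depth < 50 removed (depth exactly 50 is
  retained — the strict reading of the printed inequality);
- indels at the edge of a homopolymer run: a run of ≥ 5 identical bases
  ("more than 4") starting or ending within 1 bp of the indel footprint,
  scanned in a ±6 bp reference context carried on the variant; a missing
  context on an indel is an error naming the variant;
- cohort-recurrent alleles (≥ 2 samples by default, exact-allele keying)
  unless whitelisted (the whitelist stands in for a hotspot catalogue);
- variants on aneuploid chromosomes, where aneuploid means the
  segment-length-weighted modal integer copy number of the chromosome
  differs from 2.

Germline variants are kept when nonsynonymous, depth > 20, VAF > 0.2 and
population MAF < 0.01. LOH is called per variant at VAF > 0.6 (strict:
0.60 is not LOH).

## Repair-deficiency annotation

Promoter methylation probes are selected cohort-wide per gene
(MLH1, BRCA1, RAD51C): a probe is informative when its range across
samples exceeds 0.4 and its median is below 0.1; a sample is
hypermethylated when its mean β over informative probes is ≥ 0.4 (the
cutoff is inclusive; the source rule states a cutoff without resolving
equality, and an inclusive boundary keeps the call monotone in β).
Copy-number classes: CN ≥ 6 amplification, 3–5 gain, 2 neutral, 1 loss,
0 homozygous deletion.

Evidence is collected for all three pathways and one call is reported per
sample using the fixed precedence MMR > HR > non-HRD, and within a pathway
hypermethylation > germline+LOH > somatic. Co-occurring mechanisms are
retained as secondary evidence rather than discarded. Biallelic evidence
is required for mutation-driven MMR calls (LOH on the variant or a second
somatic hit); somatic PTEN counts as HR evidence on its own, ranked last
within HR.

## Purity, CCF and phylogenies

- **Purity**: in an LOH region with single-copy loss, a tumor of purity
  *p* mixed with diploid normal shows major-allele BAF b = 1/(2 − p), so
  p = 2 − 1/b. The estimate is the median over informative regions
  (b > 0.5), clipped to (0, 1]; a copy-neutral variant (p = 2b − 1) is
  available by option. No informative region is an error, not a default.
- **CCF** = VAF · (p·n_t + (1 − p)·n_n) / (p·m). When multiplicity m is
  unknown it is chosen in 1..n_t to minimise |CCF − 1| subject to
  CCF ≤ 1.2, the standard resolution; clonal ⇔ CCF ≥ 0.8. The boundary is
  inclusive: the source states "more than 0.8" in one place and
  "CCF ≥ 0.8" in another; the inclusive form is adopted.
- **Trees**: binary presence/absence characters over 2–8 regions plus an
  implicit all-absent germline outgroup. All unrooted topologies (≤ 9
  leaves, double-factorial counts up to 135,135) are scored by the Fitch
  algorithm vectorised over characters; among equally parsimonious trees
  the lexicographically smallest leaf-partition representation is
  returned, making the output deterministic. Branch lengths are per-edge
  changes of a minimum reconstruction (top-down refinement with the root
  forced to the reference state); drivers are placed on their 0→1 edges,
  with multiple gain edges flagged as homoplasy. Characters with missing
  data are treated as absent. Trees count SNVs and indels alike.

## EMT score

PCA on column-centered (not variance-scaled — log expression is already
on a comparable scale; scaling is available by flag) log10(FPKM+1)
expression over the 81-gene marker panel; the score is the PC1 projection,
sign-fixed so the mean loading of mesenchymal markers exceeds that of
epithelial markers, i.e. high score = mesenchymal. The shipped gene list
(`data/emt_markers_synthetic.tsv`) is a synthetic stand-in panel of
canonical EMT markers with polarity labels, editable and replaceable.
Methylome correlation uses the top 20% variance probes (ties broken by
probe id) and per-probe Spearman rho, reported without multiple-testing
adjustment (descriptive, as in the source analysis).

## Synthetic cohort generator

The generator defines the study conditions; its defaults are the cohort
structure the pipeline is meant to resolve.

- **Cohort mix**: 109 samples, 11 POLE / 24 MSI / 64 CNH / 10 CNL (the CNL
  count is the remainder of the published totals).
- **Burdens**: per-subtype (min, median, max) anchors — POLE SNVs
  (190, 479, 1999), indels (1, 3, 56), CNVs (0, 1, 28); MSI SNVs
  (8, 55, 207), indels (10, 27, 63), CNVs (0, 2, 7); CNH SNVs (1, 6, 19),
  indels (0, 1, 6), CNVs (1, 17, 48); CNL low counts (chosen: SNVs
  (1, 5, 19), indels (0, 1, 6), CNVs (0, 1, 5)). Counts are drawn from a
  split lognormal centred at the median (each side's log-spread set so the
  printed extreme sits ~3 SD out, clipped to [0.10, 0.55]) and truncated
  to the printed range. A plain log-uniform over the printed ranges was
  rejected: it places ~30% of CNH mass at burden levels indistinguishable
  from CNL, which no burden-based classifier could separate; the clipped
  lognormal keeps the printed medians exact and the ranges as truncation
  bounds while confining between-class overlap to the extreme tails.
- **Spectra**: six-class substitution weights with T>C elevated in MSI
  (0.45) and T>G elevated in POLE (0.30), C>T dominant elsewhere.
- **Genome model**: a synthetic 596-gene panel on 22 chromosomes of
  150 Mb; passenger variants live on chr1–12 (kept diploid so artifact
  filters are inert for planted biology), copy-number aberrations on
  chr13–20 arms (CNH fills a fixed 12-arm gain/loss signature with
  amplitudes 0.5–1.3, emulating recurrent arm-level events; other
  subtypes scatter 0.3–0.6 segments), CCNE1/RB1/NF1 on chr21 (so random
  segments cannot fake a non-HRD lesion), and chr22 carries four LOH
  regions whose BAF encodes purity.
- **Reads**: purity ~ U(0.40, 0.95) (independent of subtype); VAF =
  Binomial(depth, CCF·p·m/(p·n_t+(1−p)·n_n))/depth at depth 300
  (panel-like coverage); region BAF aggregates 5000 allele reads,
  reflecting that a region-level BAF pools many SNP sites. A no-noise mode
  makes every forward model exactly invertible.
- **Lesions**: MMR lesions in 22/24 of MSI samples (60% MLH1
  hypermethylation, 20% germline+LOH, 20% somatic biallelic), HR lesions
  in 23/64 and non-HRD in 17/64 of CNH samples (non-HRD split 15:2
  CCNE1 amplification : RB1 deletion), planted mutually exclusively.
- **Trunk fractions**: CNL 15/16, CNH 56/74, POLE 0.30, MSI 0.40 (chosen
  low for the hypermutators, whose trees have short trunks). Drivers count
  within the mutation total and sit on the trunk with probability 1 in
  CNH/CNL and 0.6 in hypermutators.
- **Multi-region tumors**: a random bifurcating region tree; edge counts
  Poisson (trunk mean 30, branch mean 8) with internal edges forced ≥ 1 so
  the planted topology is identifiable; optional homoplasy rate.
- **EMT**: expression = mixture of epithelial/mesenchymal archetypes
  weighted by the planted sarcoma fraction + Gaussian noise (SD 0.3);
  six `cg_mir200_*` probes have β = 0.1 + 0.7·fraction + noise, the rest
  are probe-specific baselines with SD 0.05 noise.

**What passing round trips do not show**: the generator plants clean,
identifiable signals — diploid passenger background, noiseless marker
panels, mutually exclusive lesions, perfect-phylogeny characters. Real
cohorts add FFPE damage beyond the filtered classes, subclonal copy
number, intra-gene hotspot structure, batch effects in arrays, and
incomplete panels; recovery rates here bound what the algorithms do under
the stated model, not under those confounders.

## Numerical and testing choices

- Fisher exact p-values use the probability-mass two-sided definition
  (tables with probability ≤ observed, relative tolerance 1e-7), which
  reproduces the reference value 0.0123 for the (2,10; 9,3) table and is
  checked against exact rational enumeration in the tests.
- Mann–Whitney switches from the exact distribution to the tie-corrected
  normal approximation at combined n > 20 or any tie.
- Acceptance-scale simulations: ten default cohorts (1090 samples) for
  subtype/repair recovery; 500 random instances (≤ 6 regions, ≤ 30
  characters) for parsimony-vs-brute-force equality; trunk fractions
  measured at the pooled per-subtype mutation totals (16 CNL, 74 CNH),
  where the realized shared count is exact by construction.
- Degenerate inputs raise rather than default: all-zero contingency
  tables, constant vectors in Spearman, empty probe sets, missing MSI
  panels, absent LOH regions, > 8 tree regions.

## Known limitations

- The exhaustive tree search is exact but exponential; beyond 8 regions
  the API refuses rather than silently switching to a heuristic.
- CNH assignment is cohort-relative; single-sample classification falls
  back to the scalar aberrant-count rule and should be interpreted
  accordingly.
- The EMT panel is a stand-in list; swapping in a published 81-gene panel
  changes loadings but not the scoring machinery.
- Consensus-clustering k selection is limited to small k (default 2–4);
  the intended use is separating high- from low-burden copy-number
  profiles, not general cluster discovery.
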