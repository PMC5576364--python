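# Methods

## Coordinate frame and variant model

All statistics are computed in CDS space: the concatenated exonic coding
bases of one transcript, 5′→3′ in transcript orientation, positions 1-based
(HGVS "c." convention; c.103T>C is CDS position 103). Genomic intervals are
0-based half-open everywhere (BED convention). Genomic variants are projected
onto transcripts through their exon blocks; on the minus strand the position
is counted from the transcript 5′ end and alleles are reverse-complemented.
Projection round-trips exactly on both strands and across introns.

Consequences of single-nucleotide substitutions follow the standard genetic
code (NCBI table 1, taken from Biopython): synonymous (amino acid unchanged;
stop→stop counts as synonymous), missense, nonsense (amino acid→stop),
stop-lost, and start-lost (a non-synonymous change in the initiator ATG,
assigned at annotation time). Only substitutions are modelled; indels are
carried through prioritisation as an opaque protein-altering class and never
enter dN/dS, MDR or EMD computations. Multi-allelic records are decomposed
into one variant per alternative allele. Transcripts with internal stop
codons are flagged with a warning (reference dumps contain such edge cases)
and excluded from genome-wide scans by default rather than dropped.
Selenocysteine recoding and alternative genetic codes are not supported.

## Potential sites and genic dN/dS

Potential site counts follow Nei and Gojobori's per-codon scheme: at each of
the three positions of a sense codon, the fraction *f* of the three possible
substitutions that are synonymous accrues to *S* and 1 − *f* to *N*, so every
codon contributes exactly 3 sites and the 61 sense codons contribute 183.
Stop-creating changes count toward *N*. The terminal stop codon contributes
no sites.

Observed counts are **distinct variant sites**, not allele-frequency-weighted
and not per-allele: a CDS position carrying at least one missense allele adds
1 to *n*; one with at least one synonymous allele adds 1 to *s*; a position
with both adds to both. Nonsense, stop-lost and start-lost variants count in
neither class — the statistic targets missense depletion, and loss-of-function
intolerance is a different axis. dN/dS is the raw proportion ratio
(n/N)/(s/S) with no multiple-hit (Jukes–Cantor) correction: population
variants are rare polymorphisms, not fixed differences, so saturation is
negligible and the correction would only add noise.

When *s* = 0 the score is undefined and the gene is flagged
(`low_synonymous`) rather than given a pseudocount; the prioritiser handles
flags explicitly so candidates never silently disappear. An optional
pseudocount mode (+0.5 on all four counts) is available but off by default.
Genes with several transcripts are represented by the longest CDS when a
single per-gene value is needed.

Category comparisons (e.g. dN/dS by inheritance pattern of known disease
genes) use rank-based tests: the two-sample Wilcoxon rank-sum test for two
categories, Kruskal–Wallis for more, with unscored genes excluded and
reported.

**Estimator bias under the synthetic model.** The generator places
nonsense-creating alternatives at the missense rate, but *n* excludes
nonsense sites while *N* includes stop-creating changes, and distinct-site
counting loses a little mass to same-site collisions. Together these depress
recovered dN/dS by ≈ 4–7% relative to the planted rate ratio at the default
rates — visible in the acceptance run (e.g. ≈ 0.93 recovered at a true ratio
of 1.0) and well inside the 10% recovery band the studies check.

## MDR scanning

An MDR candidate is a maximal missense-free stretch: the interval between
two consecutive missense variant sites (exclusive of the sites themselves),
or between a CDS end and the nearest missense site. This is equivalent to a
sliding-window scan under the reporting criteria below but cheaper and with
canonical boundaries. Boundaries are not forced to codon alignment. A
candidate is reported iff

1. length ≥ `min_length` (default 300 bp),
2. it contains ≥ `min_syn` synonymous sites (default 10), and
3. it meets the aggregate density floor of one synonymous site per 10-codon
   group: `syn_count ≥ floor(length × density_floor)` with
   `density_floor = 1/30` per bp.

The floor in criterion 3 is rounded **down** to whole sites — a 610 bp region
needs 20 synonymous sites, not 20.33. The density requirement is aggregate
over the region by default; a strict per-30-bp-block occupancy check is
available (`strict_blocks`). Nonsense sites do not break an MDR (they are not
missense); `break_on_nonsense` makes them breaking. Synonymous variation
inside the region is required because it certifies that the region was
sequenced and mutable — a missense gap without synonymous coverage is more
likely a data hole than selection.

Intervals are reported in CDS coordinates and projected to genomic BED blocks
(split across introns) when exon mappings exist. The size sweep rescans under
a list of length criteria with the synonymous requirement scaled by the
300 bp / 10-site ratio (`min_syn = max(1, round(length/30))`); because the
qualifying sets are nested, counts are non-increasing in length.

## EMD score

Each transcript yields two empirical positional distributions: one atom per
distinct missense site and one per distinct synonymous site, at normalised
midpoints (p − 0.5)/L, each distribution normalised to unit mass ("equal
masses") so the score compares shapes rather than counts. The score is the
order-1 Mallows/Wasserstein distance, computed in closed form as the integral
of the absolute difference of the two step CDFs — the exact 1-D optimal
transport cost, verified in tests against both an explicit
linear-programming transport solution and an independent library
implementation. Order 2 is available as an option; order 1 is the default
because the distance is used for ranking and the first-order form is the
standard Mallows reading. The midpoint convention is immaterial to ranking
(it shifts both distributions identically) and is fixed for reproducibility.

Genes with fewer than `min_sites` (default 3) distinct sites of either class
are unscored and flagged: with a handful of atoms the distance is dominated
by sampling noise. This threshold is deliberately permissive; see
Limitations for the consequences at moderate counts.

## Prioritisation

Proband variants are filtered to protein-altering consequences (missense,
nonsense, stop-lost, start-lost, opaque indels) with population MAF below 1%
(absent MAF = unobserved = rare). Each surviving variant is joined to its
gene's constraint scores, and genes are ranked genome-wide: `dnds_rank`
ascending in dN/dS (1 = most depleted), `emd_rank` descending in EMD
(1 = largest shift). Ranks are computed on the full scored gene universe and
then read off for the proband's genes, so a rank is a position in the
exome-wide distribution; a proband-only ranking is available as an option.
Ties break deterministically by total observed sites (better-sampled gene
first), then gene symbol. Unscored genes sort after all scored genes,
flagged, rather than being dropped. `in_mdr` is set by interval containment
of the variant's CDS position.

Trio annotation never changes scores or ranks — it only fills the
inheritance column. With both parent sets present, a site absent from a
parent's calls is taken as hom-ref in that parent; a missing parent set
yields `unknown`. Classes: `de_novo` (proband carrier, both parents
hom-ref), `inherited_maternal`/`inherited_paternal` (exactly one carrier
parent), `homozygous` (proband hom-alt, not de novo), `compound_het` (≥ 2
het variants in one gene with at least one inherited from each parent — a
cis-by-parent pair does not qualify), `hemizygous` (male proband on X outside
the pseudoautosomal regions; PAR coordinates for GRCh37/38 are built in),
`unknown` otherwise (including phase-ambiguous sites carried by both parents
and mitochondrial variants). Genotypes are taken as given; genotype-quality
modelling belongs upstream.

## Synthetic data

The stochastic generator mirrors the rare-variant regime the statistics
assume: every possible (position, alternative-base) substitution is an
independent Bernoulli event with probability λ_class/3 — λ_s per potential
synonymous site for synonymous-creating changes, λ_m per potential
nonsynonymous site for missense- and nonsense-creating changes (nonsense is
placed like missense but labelled by its true consequence, which keeps the
classifier honest). Expected class counts therefore equal λ × potential
sites. Depleted regions are planted by multiplying the missense/nonsense
probability inside an interval by ε (default 0). Allele frequencies are
decorative for the site-based statistics but exercise the MAF filter; they
follow a log-uniform spectrum on [10⁻⁵, 5×10⁻³], the shape of a large exome
cohort's rare tail. The default rate λ_s = 0.2 gives ≈ one synonymous site
per 21 bp, the coverage scale at which the MDR density criterion is
satisfiable — comparable to what a cohort of several thousand exomes yields.

Two structured fixtures complement the Bernoulli model where
near-deterministic densities are needed to calibrate the scanner:
`regular_synonymous_sites` places one synonymous site per spacing-bp grid
point (density exactly 1/spacing), and `blockwise_missense_sites` places one
missense site uniformly at random per consecutive block (exact density,
maximum gap below two blocks). Under a pure Bernoulli model at missense
density 1/50 per bp, a 2 kb CDS has a ≈ 6–9% chance of a ≥ 300 bp missense
gap purely by chance, so a meaningful false-positive calibration requires
the bounded-gap fixture; likewise, exact planted-recovery counts require
regular synonymous placement, since Poisson fluctuation around the density
floor would otherwise dominate the measurement.

Trio simulation gives the proband exactly `n_background` rare
protein-altering variants, each het and inherited from one random parent,
plus one de novo causal missense placed inside the causal gene's planted
interval and absent from both parents, plus decoy synonymous and common
(MAF ≥ 2%) variants that must not survive the rare-coding filter. A truth
record lists every assignment. All outputs are reproducible from the single
config seed.

What the generator does **not** emulate: mutation-rate heterogeneity (CpG
transitions, sequence context), linkage and haplotype structure, coverage
variation and call errors, recurrence of common alleles, or selection models
beyond class-specific rates. Passing the studies therefore shows the
estimators are correct and well calibrated under the independence model —
not that real-data confounders (uneven coverage creating fake missense gaps,
CpG hotspots inflating local rates) are handled; on real cohorts those
require the synonymous-coverage criterion and user judgement.

## Validation studies and problem sizes

The studies behind `scripts/acceptance.py` use sizes chosen to make Monte
Carlo error small relative to the margins being checked: exhaustive
enumeration for the genetic code (576 substitutions, 61 codons); 200 random
≤ 10-atom instances against the LP transport oracle (tolerance 10⁻⁹); dN/dS
recovery on a 30 kb CDS at λ_s = 0.15, 20 seeds per planted ratio; scanner
equivalence against brute-force interval enumeration on 100 random ≤ 2 kb
transcripts; planted recovery of 450 bp intervals over 500
transcript-replicates (boundary tolerance 30 bp); false positives over 1,000
transcripts; and 50 trio replicates of a 500-gene universe (background genes
900–2,400 bp at dN/dS ratios U(0.6, 1.2), causal gene 1,800 bp at ratio 0.1
with a 450 bp planted interval, 480 background variants per proband).
Population variation is resimulated per trio replicate so the reported rates
reflect study-to-study variability, not one frozen exome.

## Known limitations

- **EMD at low missense counts.** A strongly depleted gene is precisely one
  with few missense sites, so its EMD estimate is noisy exactly when its
  signal matters most: with ~20 missense atoms the sampling deviation (~0.03)
  is comparable to the planted regional signal (~0.125 for a 25% depleted
  interval), while the maximum of several hundred background null scores
  reaches 0.10–0.12. In the trio study the causal gene reaches the EMD top 5
  in only ≈ 75% of replicates (`trio_causal_top5_emd_pct`), even though it
  ranks first on the dN/dS axis in 100%. The EMD axis is best treated as
  corroborating evidence, not a primary filter — consistent with how the two
  axes surface different candidates on real data.
- dN/dS recovery carries the ≈ 4–7% downward bias described above; rankings
  are unaffected because the bias is shared across genes.
- The scanner's boundaries are the bases flanking the nearest missense
  sites, so boundary precision is limited by the local missense density
  (mean overshoot ≈ 1/density per side).
- Splice-site and UTR consequences, transcript-selection logic beyond a
  user-supplied canonical flag, and pathogenicity meta-predictors are out of
  scope; homozygous and mitochondrial candidates are ranked on the same gene
  axes as everything else.
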