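# Methods

This note records the models, defaults, numerical choices and known
limitations behind `bsamap`. Nothing here states an empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## The genetic model

The package targets the textbook map-based-cloning setting: two inbred
parents fixed for opposite alleles at every informative site, an F1
heterozygous everywhere, and an F2 in which a single fully penetrant
recessive locus controls the phenotype (mutant iff homozygous for the
mutant-parent allele, expected 3:1 normal:mutant). All linkage and BSA
statistics assume this design; dominance, incomplete penetrance and
multi-locus traits are out of scope.

## Synthetic data generator (`simgen`)

**Meiosis.** Crossovers follow the no-interference model: the count per
chromosome is Poisson with mean equal to the map length in Morgans,
breakpoints uniform on the genetic map, no obligate chiasma. The
population simulator uses the equivalent Markov-chain form (a switch
between adjacent markers with probability given by the Haldane map
function of the interval), which is exact under no interference and
vectorizes over gametes; `simulate_gamete` implements the
Poisson/uniform form directly and the two are cross-checked by tests.
Simulation is Haldane even though linkage *estimation* reports Kosambi
distances (the estimator the field's mapping software uses); at the
≤ a-few-cM scale relevant to fine mapping the two map functions differ
negligibly, and the map-assembly recovery test is run at that scale.

**Defaults** (the stated experimental world): 11 chromosomes of 34 Mb
and 1.2 Morgans (≈ genome size / chromosome count and a typical
~120 cM watermelon chromosome), 200 informative markers per chromosome
(a deliberately sparse stand-in for a filtered whole-genome SNP set; the
causal position is always included as a site), an F2 of 500 plants,
bulks of 20 + 20, mean depth 34×, and a symmetric per-read sequencing
error of 0.001 (typical Illumina post-filter substitution rate). Bulk
allele frequency is the unweighted mean of member dosages / 2 (equal
DNA per plant); total depth per site per bulk is Poisson, alt reads
binomial at the error-perturbed frequency. Only biallelic
parent-fixed-different sites are emitted. The reference allele is the
wild-type parent's by default; because a real assembly's polarity
relative to either parent is unknowable in general, a
`randomize_polarity` flag swaps ref/alt per site with probability 1/2
(parental columns track the physical alleles, so all statistics are
polarity-invariant).

**What the generator does not emulate:** read-level artifacts (mapping
error, duplicated reads, indel realignment), depth overdispersion
beyond Poisson, structural variation, segregation distortion, and
shared-haplotype structure among "normal" alleles. A green recovery
test therefore establishes correctness of the statistical machinery on
idealized pooled counts, not robustness to alignment pathology.

## BSA statistics (`bsastats`)

SNP-indices are computed as the dwarf(mutant)-parent-allele read
fraction in *both* bulks — the only polarity under which the recessive
F2 threshold of 2/3 is attained at the causal locus. Sites need
≥ `min_depth` (default 5) reads in both bulks; a site failing depth in
one bulk is dropped entirely, since Δ needs both indices. ED is
computed over the two observed alleles (the four-nucleotide
generalization collapses to √2·|Δf| for biallelic sites) and raised to
the configurable power k = 5.

Smoothing is a sliding-window mean (window 1 Mb, step 10 kb by
default — the bandwidth of the original scan is unpublished, so these
are exposed in `ScanConfig` and recorded in output headers). Regions
are maximal runs of windows at or above threshold, merged across gaps
≤ 1 Mb, with bounds tightened to the outermost supporting sites. The
ΔSNP-index threshold is the theoretical 0.67; the ED⁵ line is a
*descriptive* mean + 3 SD rule (not a formal test), with a quantile
alternative. A `top_n_peaks` mode reports the highest local maxima even
when sub-threshold, for underpowered scans whose peaks are still
visually obvious.

**Known statistical limit (kept honest, not tuned away).** The expected
ΔSNP-index at the causal site is exactly 2/3 ≈ 0.6667, *below* the
rounded 0.67 threshold, and smoothing only pulls the window mean
further down (linked flanking sites have expectation 2/3 − (4/3)r).
Whether the smoothed peak crosses 0.67 therefore rests on zero-mean
bulk-composition noise (SD ≈ 0.05 with 20-plant bulks) — about a coin
flip per run. Measured over seeds 1–100 of the default world: the
Δ region is called in 72/100 runs, contains the causal position in
53/100, and never appears on a non-causal chromosome; the top smoothed
ED⁵ window sits on the causal chromosome in 100/100 runs. The
acceptance test asserting ≥ 95/100 Δ-region containment fails by
design and documents this; ED⁵ (or `top_n_peaks`) is the statistic
that localizes reliably at this bulk size, matching the original
experiment, where the SNP-index scan also showed only sub-threshold
peaks and the ED scan drove the localization.

## Linkage (`linkmap`)

The 3:1 segregation χ² uses the Yates continuity correction by default
(sum of (|o−e|−0.5)²/e over the two classes): it exactly reproduces the
published worked values for this design, which the uncorrected
statistic does not; a flag disables it.

Marker–marker r is the maximum-likelihood estimate under the nine-class
F2 two-locus multinomial, via EM: all classes except the double
heterozygote have a known recombinant-gamete count; a double
heterozygote contributes 2r²/(r² + (1−r)²) expected recombinant gametes
(its phase is latent). Convergence tolerance 1e-12, 500 iterations
max, r clipped to [0, 0.5]; ties toward 0.5. LOD is
log₁₀ L(r̂)/L(0.5) under the same likelihood, floored at 0; linkage is
declared at LOD ≥ 5.0 (configurable).

Trait–marker r for a recessive trait defaults to the fine-mapper's
recombinant count over unambiguous classes: mutant plants contribute 1
(heterozygous marker) or 2 (wild-type homozygous) events over 2
chromosomes each; normal plants homozygous for the mutant-parent marker
allele contribute ≥ 1 event, counted once; other normal plants are
excluded from the denominator because their causal genotype (DD vs Dd)
is latent. A full-likelihood estimator over the mutant/normal mixture
is available via `method="ml"`; LOD always uses the full likelihood.
Map assembly takes marker order from physical coordinates (de novo
ordering is out of scope) and places the trait in the interval whose
flanks minimize trait–marker distances.

## Candidate genes and markers (`candgene`)

Coordinates are GFF3 1-based inclusive; indels are expected VCF-anchored
and left-aligned and are placed by their leftmost affected base. Effect
prediction applies the alternate allele to the spliced CDS
(strand-aware): SNPs are classified by codon comparison (a stop-gain is
reported as `missense` — the effect enum has no nonsense class — with
the truncation visible in the mutant protein length); CDS indels with
length change ≢ 0 (mod 3) are frameshifts, translated from ATG to the
first stop (`nonstop` when none is reached). Indels spanning a
splice boundary are rejected rather than mis-modelled.

The packaged toy gene ("Cla010337-like", id `ClDWG01`) is a synthetic
fixture: 10 exons / 9 introns, spliced CDS exactly 3,753 bp → 1,250-aa
protein, genomic span 6,377 bp, with planted variants (missense and
synonymous exonic SNPs, an intron-5 SNP, a 1-bp exon-4 deletion at
spliced-CDS position 631, a 5-bp deletion wholly inside intron 8). Its
sequence is random at a frozen seed; only the coordinate arithmetic and
variant consequences are meaningful. The 631 position is counted on
the spliced CDS of the *reference* allele (the source text does not
say which; this choice is recorded here).

dCAPS design searches all enzymes (a packaged, user-extensible table of
~30 common six-cutters with IUPAC support), both strands, and every
recognition-site placement overlapping the variant: first for a plain
CAPS (site present in exactly one allele, no engineering), then for a
single introduced base change within the primer-covered 20 bases
adjacent to the variant (never at the variant itself) that completes
the site for exactly one allele. The same introduced base is applied to
both alleles' sequences before the deciding re-scan, since the primer
mutates both amplicons. Every returned design re-verifies that exactly
one allele's full sequence is cuttable (self-checking postcondition).
Tie-break is deterministic: enzyme name, then leftmost placement, then
forward strand. Melting temperature, GC content and product-size
optimization are out of scope (a thermodynamic primer designer's job);
the reported fragment-length difference is nominal. For indels the CAPS
pass applies but no mismatch search is attempted.

## Expression (`expr`)

Technical replicates are averaged (mean, no outlier trimming) per
(sample, gene, biological replicate); ΔCt = Ct(target) − Ct(reference
gene); ΔΔCt subtracts the calibrator line's mean ΔCt per tissue; fold
change is 2^−ΔΔCt (amplification efficiency fixed at 2.0; efficiency
correction out of scope). The between-line test is Student's t on
per-biological-replicate ΔCt values (Welch optional) — statistically
preferable to testing fold ratios and identical in |t| and p to testing
log₂ fold, which is an affine transform of ΔCt; a `test_on` flag
matches the literal fold-change comparison.

## Pipeline and I/O

The end-to-end demo runs simulate → scan → linkage (restricted to the
top called region, mirroring the validate-and-confirm workflow) →
candidate-gene triage (the toy gene planted near the causal position
plus variant-free decoys, standing in for a real annotation), and
writes a JSON manifest with the config snapshot, seed, and sha256 of
every output; re-running a config reproduces byte-identical outputs.
VCF/GFF coordinates are 1-based inclusive, BED 0-based half-open, with
exact inverse converters. The simulator's VCF records the mutant-parent
allele in an INFO tag (`DWA`) so polarity survives a round trip; real
VCFs without it default to alt = mutant allele with a warning.
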