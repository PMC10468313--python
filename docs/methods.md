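# Methods

## The inference

The object of interest is the set of somatic variants private to one clonal
lineage of a vegetatively propagated cultivar. Two filters define it over a
cohort of clones with biological replicates, genotyped against the
cultivar's reference assembly:

* **replicate concordance** — a variant counts for clone *c* only if every
  replicate of *c* carries the alternate allele (dosage ≥ 1). A missing call
  ("./.") counts as not-present, so one dropout in one replicate removes the
  site. Single-replicate clones are legal; their "concordant" set is simply
  their presence set, with correspondingly less noise protection.
* **exclusivity** — the variant must additionally be absent from every
  sample of every other clone. By default a missing call in a non-focal
  sample counts as absence, which is the correct reading of joint-genotyper
  output (every sample is genotyped at every emitted site); a strict mode
  treats missing as potentially-present and drops the site, the conservative
  choice when independently called per-sample files are merged.

Concordance is deliberately defined on *presence*, not on an exact het/hom
genotype match across replicates; requiring genotype equality would couple
the filter to genotyping error rather than to allele presence.

Everything upstream of the VCF (mapping, calling) and downstream of locus
selection (primer thermodynamics, wet-lab PCR) is out of scope; the package
consumes caller-level records and emits candidate windows for external
primer design.

### Filters and their order

Calls first pass the quality filter Q > 100 (strict inequality; site QUAL,
not per-sample GQ, since that is what a joint caller emits at site level —
users with GQ-based conventions should prefilter). Multi-allelic rows are
split per ALT before anything else; site identity is always the full
(contig, pos, ref, alt) tuple, and a normalizer (shared-base trimming plus
VCF-style left alignment with an anchor base) is provided so that
representation differences can never defeat the exclusivity comparison.

### Summaries

Ts/Tv counts transitions (A↔G, C↔T) over transversions on SNVs only and is
reported as missing when no transversion was observed. Heterozygous fraction
is het calls / called variant sites × 100, per sample when a sample is
named; otherwise a record counts as het when its maximum observed dosage
is 1. Densities are count × 1000 / genome length per kbp, plus windowed
counts (default 100 kbp, BED-like 0-based half-open, last window partial).

### PCA

Samples are encoded as alt-allele dosage {0,1,2} over the union of
replicate-consistent sites, missing imputed to the site mean, no variance
scaling, plain SVD. Signs are canonicalized (largest-magnitude coordinate
positive per axis) so repeated runs are identical. Dosage encoding without
scaling is the simplest reproducible choice; clone separation at the planted
burdens is insensitive to it.

## The synthetic cohort generator

The generator emulates joint-genotyper *output*, not reads: there is no
mapping or calling step to simulate faithfully at desk scale, and the
methods under test operate strictly at the VCF level.

* **Reference**: i.i.d. bases at GC 0.345 (the observed grapevine assembly
  range is 34.1–34.8%), split over `n_contigs` contigs.
* **Background heterozygosity**: het-in-everyone variants at
  `background_het_rate` = 0.005/bp, matching the ~4.4–5.5 SNV/kbp plus
  1–2 InDel/kbp a cultivar shows against its own assembly.
* **Clone-specific variants**: exactly `clone_specific_count[c]` per clone
  (default 1,000, the order of the published per-clone exclusive SNV
  counts), heterozygous with probability 0.94, hom-alt otherwise; carried by
  all replicates of the focal clone and nobody else. SNV substitutions are
  drawn to a target Ts/Tv of 2.1; a fraction 0.258 of planted variants are
  InDels (the published SNV:InDel split), sizes uniform on 1–15 bp,
  planted left-aligned and non-overlapping with an anchor base.
* **Call noise**: each true variant is dropped per replicate with
  probability `dropout_rate` (genotype → missing; a site dropped in all its
  carriers is not emitted at all — a caller cannot report an allele it never
  saw). Spurious het singletons are injected at `false_positive_rate` per
  site per replicate. Site QUAL comes from two shifted normals — true calls
  N(500, 80), false calls N(60, 30), clipped at 0 — so the Q > 100 filter
  removes most injected noise while costing essentially no true calls.
  Dropout 0.05 and FP 1e-5 are free parameters of the noise model (real
  caller noise is unobservable from the published tables); they are chosen
  so every downstream filter has measurable work to do.
* **Amplicon reads**: for a het genotype, reads are drawn from the two
  allele sequences with probability `allele_bias` (default 0.5) and
  per-base substitution errors applied; the realized draws are returned as
  ground truth alongside the reads.

All randomness flows from one integer seed through named
`numpy.random.Generator` streams; repeated runs are byte-identical.

What the generator does **not** model: repetitive or redundant reference
sequence (which in real assemblies depresses the InDel heterozygous fraction
— values as low as ~43% occur — and creates mapping artifacts), linkage
between nearby variants, coverage heterogeneity, index hopping or chimeric
amplicons, and allele-specific PCR bias beyond a single global parameter.
Tests passing on synthetic cohorts therefore demonstrate the correctness of
the *filtering and decision logic* under the stated noise model, not
robustness to reference artifacts.

### What recovery can and cannot reach

Concordance across *r* replicates bounds recall by (1 − dropout)^r: at
dropout 0.05 that is 0.857 for three replicates and 0.9025 for two. The
noisy-recovery checks therefore run at two replicates per clone (a third of
the published cohort's clones have two replicates) with 4 × 1,000 planted
variants per seed so the pooled estimate concentrates tightly; the noiseless
checks use three replicates. Precision under these conditions is ≈ 1.0:
a false-positive singleton cannot be replicate-concordant for any
multi-replicate clone, and surviving the Q > 100 filter is already rare.

## Marker selection

Only heterozygous exclusive variants (every focal replicate at dosage 1)
become candidates: the amplicon readout of a marker is an allele balance,
and a hom-alt readout is indistinguishable from assay failure modes that
also skew balance. Windows are `target_len` = 200 bp (the published
amplicons average ~202 bp), centered on the variant, with both allele
lengths required in [141, 487] bp, the variant ≥ 30 bp from each amplicon
end, and no other known variant inside the window (the automatable proxy
for visual pileup inspection). Candidates are ranked by QUAL descending,
ties by position. Clone identifiers are canonicalized by stripping a leading
"c" before an all-digit remainder, reconciling the two spellings ("c46" /
"46") that nursery catalogs use for the same clone.

The packaged panel fixture is a verbatim transcription of a published
46-marker validated grapevine panel, including its idiosyncratic position
strings; the parser therefore tolerates thousands separators and unusual
digit grouping. Its companion roster lists the 18 evaluated clones and
replicate counts (46 genomes). Clone coverage is truncated — not rounded —
to one decimal (14/18 → 77.7%), matching the convention of the source
panel's reporting. The mean InDel size of the packaged panel computes to
≈ 10.3 bp from the allele-length differences; it is reported but not
asserted against any external figure.

## Genotype calling and identification

Calling thresholds (assigned depth ≥ 20; minor-allele fraction ≥ 0.20 →
het; ≤ 0.05 → hom of the major allele; between → no-call) are package
choices with an explicit ambiguous zone — published validation work shows
read-coverage bars but no cutoffs — and are fully configurable. The caller
is symmetric in the two alleles by construction.

Read→allele assignment uses edit distance to the two allele sequences
(infix mode when the read is shorter than the amplicon), default tolerance
4 mismatches, ties unassigned; markers known only by their two allele
lengths fall back to length matching. An SNV marker without sequences is a
configuration error rather than a silent guess.

Identification: a positive marker is a het call at a panel marker; positives
for exactly one clone assign that clone (one suffices); no positives →
unassigned (clones without validated markers can never be positively
identified); positives for two or more clones → ambiguous, with all
conflicting markers listed. A diagnostic tool must not guess, so ambiguity
is never tie-broken.

## Problem sizes and numerical choices

The shipped checks run cohorts of 1 Mbp × 4 clones (recovery, estimator
calibration), 200–250 kbp × 3–5 clones (PCA, identification), and 50
identification trials at depth 200 with 0.5% read error — sizes at which
every binomial estimate involved is tight to a few tenths of a percent while
a full run stays in the minutes range on one CPU. Estimator checks use
3-standard-error bands (delta-method SE for the Ts/Tv ratio). Degenerate
inputs are defined, not errors: identical samples give an all-zero PCA,
empty VCFs give zero-count summaries and empty exclusive sets, depth-0
amplicons give (0, 0) counts.

## Known limitations

* Site QUAL (not GQ) carries the quality filter; data filtered on other
  conventions should be prefiltered upstream.
* The generator's noise is unlinked and homogeneous; it cannot expose
  failure modes driven by repeats, structural variation, or epigenetic
  differences between clones (all of which occur in real material and are
  documented causes of clonal phenotype differences).
* Exclusivity is defined within the analyzed cohort: a marker is diagnostic
  against the clones it was discovered against, not against all clones in
  existence.
* Candidate windows are amplification-feasible but not primer-validated;
  thermodynamic design is explicitly external.
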