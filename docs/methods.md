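# Methods

## Problem setting

Single-cell genome sequencing of bacteria recovers single-amplified genomes
(SAGs): assemblies derived from whole-genome amplification (MDA) of one
cell. MDA artifacts make individual SAGs incomplete and noisy — extreme
coverage skew, locus dropout, and chimeric molecules that join
non-contiguous loci. When several SAGs from the same host turn out to be
the same bacterial strain, their reads can be pooled and co-assembled into
a composite SAG (CoSAG) of much higher completeness — provided the pooled
reads are first cleaned of chimeras, and provided "same strain" is decided
correctly: merging distinct strains destroys exactly the strain resolution
that motivates single-cell sequencing.

`cosag` implements that decision and cleaning machinery: read QC,
marker-based genome quality estimation and tiering, three genome-similarity
measures, threshold-graph strain grouping, dereplication, and iterative
cross-reference chimera splitting, ending at co-assembly-ready pooled
FASTQ. De novo assembly itself is out of scope (an external assembler
command line is emitted instead), as are taxonomy, annotation, and
mobile-genetic-element analysis.

## Synthetic data model

All tests and benchmark studies run on a generator with exactly known
truth. It emulates:

- **Strain structure.** A random ancestor genome (i.i.d. bases at a chosen
  GC) evolves into `n_strains` strains by uniform per-site substitution
  under a star phylogeny; per-strain divergence is chosen so pairwise
  identity hits the requested ANI (for strains i, j with divergences
  p_i, p_j from the ancestor, pairwise identity ≈ 1 − p_i − p_j). Within a
  strain, each SAG receives its own small substitution load so that
  pairwise within-strain identity equals `within_strain_ani` (default
  0.999). No indels or rearrangements are simulated.
- **Single-copy markers.** `n_markers` non-overlapping 900-bp loci of the
  ancestor are recorded as a marker FASTA before strain derivation
  (placement by multinomial gap sampling, uniform over valid layouts). This
  replaces lineage-specific HMM marker sets with a fully known truth:
  completeness and contamination keep their usual semantics (fraction of
  markers found / fraction with extra copies) without external databases.
  Marker count is capped at 60% genome occupancy; at the default 100-kb
  test genome that is 66 markers, giving a completeness estimator
  granularity of ~1.5 points.
- **Dropout and assembly.** Contiguous 5-kb windows are dropped until the
  retained fraction matches the target completeness; retained runs become
  the SAG's contigs. Assemblies are this truncation of the true genome,
  *not* an assembly of the simulated reads — true completeness is then
  exact and no assembler is needed. 5 kb is locus-scale dropout; windows
  shorter than the 1-kb contig filter would vanish silently.
- **Reads.** Read count = mean_depth × retained_length / read_length;
  starts are drawn per 5-kb window with lognormal weights (σ =
  `lognormal_sigma`, mean normalized to 1) emulating MDA skew; substitution
  errors at `error_rate`. With probability `chimera_rate` a read is a
  junction of two loci: split point uniform in [0.25, 0.75] of the read,
  second segment from a uniform random locus and strand (MDA chimeras are
  predominantly intramolecular; the uniform model is the simplest
  falsifiable one). Contaminant reads come from an unrelated simulated
  species at GC 0.35; host reads from a simulated host decoy. Every read's
  origin, junction position, and contaminant/host flags go into a TSV truth
  manifest. Qualities are constant Q30, with an optional per-read degraded
  tail to exercise the QC filters.

What the generator does **not** emulate: indels and rearrangements,
gene-content differences between strains, paired-end insert-size structure,
GC-dependent amplification bias, and assembly errors. Passing tests
therefore demonstrate correctness of the decision rules and cleaning logic
under substitution-dominated divergence, not robustness to structural
variation. The lognormal σ (default 0.8) is a plausible MDA skew scale, not
a fitted value; the studies only require that depth variance increase
with σ, which is checked.

## Pipeline stages and parameters

**Read QC.** Right-end quality trimming at Q10 (cut maximizing the sum of
(10 − Q) over the removed suffix — the classic Phred-style objective), then
keep reads with length ≥ 40 bp, ≤ 1 N, and mean quality ≥ Q15. If either
mate of a pair fails, both are dropped (conservative, assembler-friendly).
Host-read removal: reads whose alignments to the decoy cover ≥ 60% of the
read at identity ≥ 0.95 are removed, using the internal mapper rather than
a masked-index mapping tool; the small-indel assumption is honored by a
16-diagonal band and a 3-gap cap in verification alignments. Adapter
trimming and duplicate removal are out of scope.

**Contig filter and quality.** Contigs < 1,000 bp are excluded. A marker
counts as found where it aligns at ≥ 90% identity over ≥ 80% of its length
(truncated markers at contig ends may qualify via their 80% prefix/suffix);
each extra disjoint qualifying locus counts once toward duplication.
Completeness = 100 × found/expected; contamination = 100 ×
duplicated/expected. Tier boundaries are applied exactly as stated:
HQ strictly > 90% complete and < 5% contaminated; MQ ≥ 50% and < 10%;
LQ < 50% and < 10%; ≥ 10% contamination is excluded. Grouping candidates
need completeness ≥ 20% and contamination < 10%. rRNA/tRNA presence
criteria (full MIMAG) are not implemented.

**Similarity.** Three measures per pair:

- *Fragment ANI*: the query genome is chopped into non-overlapping 1,000-bp
  fragments (trailing partial windows dropped); each fragment's best
  placement on the partner (seed chains, then exact base counting along the
  placement diagonal to the fragment/contig bounds) yields an identity and
  a coverage; fragments at identity ≥ 0.70 and coverage ≥ 0.70 contribute
  their identity; the mean over ≥ 5 qualifying fragments is the one-way
  ANI, and the two directions are averaged. These floors are the
  fragment-ANI convention of the enveomics-style calculators. Extending
  placements to the fragment bounds rather than stopping at an x-drop
  makes the identity an exact Hamming identity for substitution-only
  divergence — self-ANI is exactly 100 and calibration error at 95–99.9%
  identity is ≤ ~0.2 points.
- *TNF correlation*: Pearson correlation of 136-bin canonical
  (strand-collapsed) tetranucleotide frequency profiles; canonical
  collapse makes the profile exactly orientation-invariant, which
  clustering requires. Pearson is the field convention for TNF similarity.
- *Marker homology*: mean global-alignment identity (edlib) over markers
  found single-copy and full-length in both assemblies, ≥ 10 shared
  markers required; when one extraction is truncated at a contig end it is
  aligned as an infix of the other so truncation is not charged as
  divergence.

An undefined measure (too little homologous sequence) is treated as
*below threshold* — conservative grouping, never missing-at-random.

**Strain grouping.** An edge joins each pair strictly exceeding ANI > 99%,
TNF > 0.90, and marker homology > threshold; groups are connected
components (single linkage — matching the binary "same strain group"
reading; the stringency of three simultaneous thresholds makes pathological
chaining unlikely, and raising any threshold only refines the partition).
The marker-homology threshold defaults to 99.9% with 99.0% as a supported
configuration: at a within-strain divergence of exactly 0.1%, measured
homology fluctuates *around* 99.9, so the strict 99.9% rule is not a usable
decision boundary for data at that divergence, and the simulation studies
use the 99.0% variant. Grouping is per-host by default ("one CoSAG per
strain per host"); `--cross-host` links across hosts for cohabitation
analyses.

**Dereplication.** Genomes cluster at two-way ANI > 99%; each cluster keeps
the genome maximizing completeness − 5 × contamination (the two dominant
terms of the usual dereplication score; strain-heterogeneity and N50 terms
are dropped because qualities here come from one internal estimator), ties
broken by larger assembly then lexicographic id.

**Chimera splitting.** Within a group, every member's reads are mapped
against every other member's assembly (k = 15 seeding, per-(contig, strand,
diagonal-band) chaining, x-drop extension with match +1 / mismatch −3 /
drop 12; segments < 25 bp are discarded as seed noise; overlapping segments
of ≤ k bp around a junction are trimmed at the overlap midpoint, tie toward
the longer segment). Classification per read:

1. unmapped → kept whole (the locus may simply be absent from the partner;
   discarding would delete genuine strain-specific sequence);
2. any partner aligns the read end-to-end (≥ 95% of its length) → kept
   whole (*full-alignment veto*: a genuine chimera cannot align end-to-end
   to any real genome, whereas a clean read spanning one partner's dropout
   boundary looks partially aligned to that partner but fully aligned to
   another — without the veto such reads are falsely split at roughly the
   dropout-boundary density, well above 1%);
3. otherwise the read is cut at the segment boundaries of the most
   fragmenting partner (a junction is evidence wherever it is visible, and
   partner dropout can hide it), fragments < 20 bp discarded.

Cycles repeat until no read is split or 5 cycles. Reads classified clean
are final (assemblies are fixed), so later cycles revisit only new
fragments; the splittable count is non-increasing and the fixpoint is
stable. Reads are treated as single-ended during cleaning.

## Numerical choices and degenerate inputs

- k-mer seeds are exact 15-mers; seed starts are subsampled (step 4 for
  1-kb fragments, step 2 for 900-bp markers) where seed density is far
  above what detection needs.
- Chimeric junction localization is accurate to ±(k−1) bp (seed-edge
  ambiguity), matched by the splitting tolerance.
- Zero-variance TNF profiles, assemblies < 5 kb, empty marker sets, empty
  decoys, and empty sample manifests raise configuration errors or return
  undefined values rather than fabricating numbers.
- All randomness flows from explicit integer seeds; identical configs give
  byte-identical FASTA/FASTQ/TSV outputs and pipeline reports (the config
  hash excludes the output directory).

## Study problem sizes

The simulation studies use 100-kb genomes (50–60 kb where reads are
simulated) as a desk-scale stand-in for Mb-scale bacterial genomes, 66
planted markers, 150-bp reads, depth 5–10×, error 0.005, chimera rate 0.05.
ANI calibration runs 5 replicates at each of {95, 97, 99, 99.9}% identity;
partition recovery runs 10 fixtures of 2–4 strains × 3–8 SAGs at
completeness U(0.5, 1.0), within-strain identity 99.9%, between-strain
96–98%, plus a two-host fixture with one shared strain; chimera cleaning
runs 5 seeded 3-member groups; completeness recovery runs 5 replicates at
each true level {30, 50, 70, 90, 100}%.

## Known limitations

- The aligner assumes substitution-dominated divergence; large indels or
  rearrangements between same-strain SAGs would surface as spurious splits
  and depressed fragment coverage.
- Marker-based contamination only sees duplicated markers; contamination
  from a genome that contributes no marker copies is invisible (as with any
  single-copy-marker scheme).
- The TNF discrimination band was only validated down to GC differences of
  ~0.3 vs 0.65; compositionally similar species pairs may exceed 0.90
  correlation and must be separated by ANI/homology.
- Per-host grouping with the cross-host flag is the only batch structure
  supported; finer batch scoping is left to the sample manifest.
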