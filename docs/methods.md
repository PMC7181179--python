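# Methods

`gcsplice` implements the computational core of a reporter-and-genomics
study design in which GC content and splicing jointly control mRNA
expression and localization. This note documents the models, the
parameters that matter, the synthetic-data generator, and the numerical
choices made where the design was genuinely open.

## Synonymous variant design (`seqdesign`)

A variant of a template coding sequence at target GC3 `g` is produced by
replacing every codon, independently, with a synonymous codon drawn from a
per-amino-acid distribution: the mass `g` is split uniformly over the
G/C-ending synonymous codons and `1 - g` uniformly over the A/T-ending
ones. For glycine at `g = 0.25` this yields GGA 37.5%, GGT 37.5%,
GGC 12.5%, GGG 12.5%. Consequences of this construction:

- The expected G/C indicator at every *degenerate* third position equals
  `g` exactly. Methionine and tryptophan have a single codon and are kept
  fixed, so the whole-sequence expected GC3 deviates slightly from `g`;
  we quantify realized GC3 over degenerate positions only.
- Six-codon families (L, R, S) are split by third-position class alone;
  first/second-position differences between their sub-boxes are ignored.
- Stop codons are never resampled (only synonymous coding positions vary).
- Sampling is inverse-CDF from a named, seedable NumPy generator. Panel
  designs derive one sub-seed per target from the panel seed via
  `SeedSequence(seed).spawn(i)`, reduced below 2^31, so element `i` of a
  panel can be reproduced in isolation.
- We draw fresh from the distribution at every position regardless of the
  template codon; the expected composition is identical to resampling
  schemes and the protein is conserved by construction.

## Sequence features (`seqfeatures`, `pssm`, `folding`)

- **GC3** — G/C fraction at third codon positions; codons with ambiguous
  bases are excluded from numerator and denominator.
- **GC4** — GC3 restricted to the eight fourfold-degenerate families
  (CT\*, GT\*, TC\*, CC\*, AC\*, GC\*, CG\*, GG\*), where the third base
  carries no protein information. `nan` when no fourfold codon exists.
- **Regional GC3** — GC3 over a codon-aligned nucleotide range; the
  default "halves" split is nt 1–360 versus 361–720 (midpoint for shorter
  genes), matching reporter-length sequences.
- **Folding energy (dG)** — MFE of the 42-nt window `[-4, 38)` around the
  A of the start codon (4 nt of 5' UTR context plus the first 38 nt of
  CDS). The default backend shells out to ViennaRNA's `RNAfold` (RNA
  parameters, 37 °C); a coarse bundled Nussinov-style stacking model
  (`basic`: GC −3, AU −2, GU −1 kcal/mol, hairpin ≥ 3 nt) is available
  when the executable is absent. Absolute energies are backend-dependent,
  so analyses and tests use only sign and relative order.
- **CAI / tAI** — geometric-mean relative adaptiveness over codons of
  amino acids with >1 synonym (M/W/stop excluded). Default CAI weights
  derive from a bundled representative human codon-usage table; the
  bundled tAI table is an explicitly *synthetic* stand-in with the right
  mathematical shape (max 1 per family). Both are configuration: supply
  organism-specific weights for real analyses.
- **PSSM scans** — motifs (the 5-position cryptic polyadenylation matrix,
  the 8-position splice-donor matrix, and the ATTTA AU-rich element as a
  degenerate-free matrix) are scored additively in log2 odds against a
  uniform 0th-order background with pseudocount 0.1, A/C/G/T column
  order, forward strand only (reporter amplicons are single-stranded mRNA
  features). A match is an offset whose score's *exact* null p-value —
  computed by convolving the per-position score distributions under the
  background — is ≤ 1e-4 by default. The ARE feature reports the best
  log-odds score rather than a count.
- **AT/GC stretches** — `(AT){9}` and `(GC){9}` read literally as 18-nt
  tandem repeats, counted with overlaps.
- All features are pure functions: same input and configuration give
  bit-identical output.

## Pooled-assay scores (`sortquant`)

For a variant with reads `n(i)` across `k` ordered compartments:

- Flow-seq fluorescence score: `sum(i * n(i)) / sum(n(i))`, bins 1..8 in
  increasing fluorescence. Bin columns are depth-normalized to equal
  totals by default (bins are sorted to roughly equal cell numbers, so
  unequal sequencing depth is technical); disable with `--no-normalize`.
- RCC: `n(cyto) / (n(cyto) + n(nuc))`; 0 is fully nuclear, 1 fully
  cytoplasmic. Computed on raw counts, as is ribosome density
  `sum(i * n(i)) / sum(n(i))` over free=1..heavy=4 and ribosome
  association `(mono + light + heavy) / free` (unbounded, hence flagged,
  when the free pool has no reads).
- The 1000-read minimum filter always applies to raw, pre-normalization
  totals: it is a sampling-noise filter. Replicate score tables are
  averaged over passing replicates only, with the count reported.

## Genome composition (`genomecomp`)

Intervals are 0-based half-open internally (GTF read as 1-based
inclusive). Exon rank is counted 1..n in transcription order from the
first exon even when it is noncoding. Each codon is assigned to the exon
containing its **third** nucleotide — the position where the GC4 signal
lives — which makes junction-spanning codons unambiguous. TSS distance is
the third position's offset in mature-transcript coordinates,
orientation-aware on both strands; the TSS profile therefore bins per
codon (per-nucleotide binning of all three codon positions is a
documented alternative that would triple counts without adding
information at fourfold sites). One isoform per gene is kept (longest
CDS, ties by transcript id), and one random member per paralog cluster
(seeded). Genes failing frame/stop sanity checks are skipped and logged,
never repaired. The retrocopy-versus-parent comparison takes a curated
pair table as input and reports the median GC4 difference with a
one-tailed Wilcoxon signed-rank p-value (zero differences dropped, per
the signed-rank convention).

## Expression modeling (`exprmodel`)

Measures of exactly zero are removed **before** the 0.0001 pseudocount is
added and log2 is taken — the only order in which removal is not a no-op;
export fractions (`nuc/(nuc+cyto)`, the complement of RCC) stay on their
raw bounded scale. Transcripts are split into unspliced (one exon) and
spliced (more than one), and log2 expression is regressed on GC4 by OLS
separately per stratum; rows are transcripts (genes with several
transcripts contribute each transcript once). For the confidence region,
transcript rows are resampled with replacement (1000 replicates by
default), both strata are refit per replicate — degenerate replicates are
redrawn and counted — and the joint (unspliced, spliced) coefficient
cloud defines the 95% region as a Mahalanobis-quantile ellipse: center at
the cloud mean, shape from the cloud covariance, radius at the 95th
percentile of replicate Mahalanobis distances, so ≥95% of replicates are
enclosed by construction and no Gaussian assumption is needed. The
vectorized resampling path computes slopes from masked sufficient
statistics and agrees with the OLS point fit to machine precision.

Decay curves are fit log-linearly to `a·e^{kx}`; the half-life is
`ln(2)/|k|` for decaying series and flagged infinite otherwise.

## Synthetic data (`synthgen`)

One global seed; each simulator draws from a child stream under a fixed
labeling scheme and emits a truth table. Defaults mirror the study
conditions the pipeline targets:

- **Flow-seq**: 217 variants (the pooled library size), latent log10
  fluorescence means spanning two decades (the observed span between
  lowest and highest bins is about 100-fold), lognormal per-cell noise
  with SD 0.25 log10 units (typical FACS spread; no noise model is
  prescribed by the assay, lognormal matches practice), 10^4 cells per
  variant, 10^5 reads per bin. Bin boundaries default to pooled octiles,
  mirroring bins holding ~equal fractions of the positive population.
  Reads per bin are multinomial over variant cell shares within the bin.
- **Fractionation**: planted RCC spanning 0.09–0.64 (the observed range
  for unspliced variants), 10^4 reads per variant, binomial splits.
- **Polysome**: pool profiles are `Binomial(3, p)` over pools 1..4, so
  the planted density is exactly `1 + 3p` (default span 1.5–3.5) and the
  planted association `(1 - (1-p)^3)/(1-p)^3`; explicit profiles can be
  supplied. 10^5 reads per variant.
- **Gene models**: 500 genes, exon counts geometric (p = 0.15, truncated
  at 20; human-like skew), GC4 target `0.65 - 0.02·exons + N(0, 0.05)`
  clipped to [0, 1] with a warning, 200-codon CDS assembled from the
  design distributions (so the realized GC4 is centered on the target),
  60-nt 5' UTR in exon 1 (rank is counted from the transcript start),
  GT..AG introns, alternating strands on one synthetic chromosome.
- **Expression**: 2000 transcripts, planted coefficients
  `b_unspliced = 4`, `b_spliced = 0` (a clear separation for calibration
  studies), intercepts 2, noise SD 1 log2 unit, GC4 uniform on
  [0.2, 0.95], half unspliced (desk-scale choice; the genome-wide
  unspliced fraction of ~3% would starve one stratum at n = 2000),
  optional zero-inflation.
- **Decay**: `k = 0.1/h` over timepoints 0–8 h with 5% multiplicative
  noise.

What the generator does **not** emulate: sequencing error, PCR bias, cell
cycle or induction kinetics, bimodal silencing of a variant subpopulation,
correlated noise between compartments, and real genome annotation
irregularities (overlapping genes, non-canonical splice sites, seleno-
proteins). Passing recovery tests therefore shows that the estimators
invert the stated sampling models, not that those models capture every
property of the deposited data.

## Problem sizes in tests

The test suite runs everything at desk scale: 1000-seed design
expectations on a 240-codon template; oracle equivalence on 1000 random
sequences; 50-variant/10^5-read Flow-seq recovery; 200 fractionation
simulations at 10^4 reads; 500 simulated genes for the exon-count
correlation; 100 retrogene simulations at n = 49; 100 expression datasets
of n = 2000 with 1000 bootstraps each; 100 decay series. These sizes give
standard errors comfortably below the asserted tolerances while keeping
the full suite fast.

## Known limitations

- Default CAI/tAI tables are generic; results on real organisms require
  supplied weights (the tAI default is synthetic by design).
- The `basic` folding backend is a toy model; use ViennaRNA for anything
  quantitative.
- The GTF reader expects `transcript`/`exon`/`CDS` features with
  `gene_id`/`transcript_id` attributes (GENCODE/Ensembl style) and does
  not infer missing features.
- The ellipse is a quantile region of the bootstrap cloud; with very few
  replicates (<100) the 95th-percentile radius is noisy.
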