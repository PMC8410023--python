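# Methods

## Clonotype model

A clonotype is the set of T cells sharing a TCRβ CDR3 sequence. `clonodyn`
keys clonotypes by **CDR3 amino-acid sequence alone** (not aa+V+J, not
nucleotide): specificity annotation operates at the amino-acid level, and
convergent nucleotide rearrangements translating to the same CDR3 are one
functional specificity, so their template counts are summed on ingestion.
An `aa_vfamily` key scheme is available for sensitivity analyses. Abundance
is measured in genomic templates — sequenced DNA molecules — so a clonotype's
count is a physical cell-count proxy, and a sample's depth is the template
total. Only productive rearrangements (in-frame, stop-free translation) are
retained; out-of-frame and stop-containing rows never reach a
`ClonotypeTable`.

## Depth normalization

Richness and overlap scale strongly with sequencing depth, so every
cross-sample analysis runs at a common depth: the minimum depth among
samples passing a floor (`min_acceptable`, default 5,420 templates, the
documented default for reproducing the reference analysis; samples below
the floor are excluded and reported). Each sample is then subsampled to
that depth **without replacement** — a multivariate hypergeometric draw over
its clonotype counts, i.e. a uniform subsample of physical molecules. This
guarantees exact depth conservation, sampled counts never exceeding
originals, and monotone richness. Multinomial (with-replacement) resampling
was rejected because it can inflate a clonotype beyond its molecule count.

Seed policy: a single master seed; each sample's generator seed is
`blake2b(master:sample_id:replicate) mod 2³¹`, so adding or removing a
sample never perturbs any other sample's draw. One draw per sample is the
default (one normalized data set); `n_replicates > 1` supports averaging
stochastic metrics across draws.

## Expansion threshold and metrics

Clonotypes of size 1 are nonexpanded; size > 1 expanded. The pathological
cutoff τ is derived from a reference cohort of donors and healthy controls
at the common depth: per reference sample, the mean size of its expanded
clonotypes; across samples, a Student-t confidence interval (n−1 df,
default level 0.95) on the mean of those means; τ = ⌊upper limit⌋, and
"pathologically expanded" means size **strictly greater** than τ. The
t-interval was chosen over a normal approximation because it is exact under
the normality assumption and remains safe for small synthetic reference
cohorts; at reference sizes in the hundreds the two are indistinguishable.
On real transplant-cohort data normalized to 5,420 templates this rule
yields τ = 5; on the bundled synthetic cohorts it typically yields τ = 3–4
because the generator's clone-size law has a somewhat heavier expanded
fraction than real healthy repertoires (see *Limitations*).

Per-sample metrics: richness; counts of expanded, pathological (> τ) and
hyperexpanded clonotypes (> 100 templates by default, configurable — an
absolute count associated with alloreactive expansion); mean/median
expansion sizes (both exported); `ISI = 1/Σpᵢ²`, the effective number of
equally abundant clonotypes, bounded by 1 and richness; and clonal space
occupancy — the fractions of template space held by nonexpanded, normally
expanded (1 < size ≤ τ) and pathological clones, which partition 1 exactly.
Rank-abundance distributions report template mass in rank bands
(top 1–10, 11–100, 101–1,000, 1,001–10,000, beyond); ties are broken by
clonotype key so results are reproducible.

## Overlap and public background

For a recipient–donor pair at common depth: shared clonotype set (optionally
restricted to a size class, applied to *both* sides), the count overlap
coefficient `|A∩B|/min(|A|,|B|)`, and an abundance-weighted coefficient
`Σ_shared min(p_A, p_B)`. Both are exposed because the two capture different
things — the count form is the classical coefficient; the weighted form
accounts for the relative abundance of each shared clonotype; all output
tables carry both.

Public background: unrelated individuals share CDR3s through convergent
recombination, so raw donor–recipient sharing overstates graft carry-over.
The background is the mean shared-clonotype count over all unordered pairs
of unrelated reference samples (related pairs removed via the pairing
manifest), divided by the mean per-sample richness of the size class — a
denominator chosen so that a cohort of identical samples yields a background
of exactly 1 and a pairwise-disjoint cohort exactly 0. The adjusted overlap
is `max(0, recipient_shared_fraction − background)`; the raw (unfloored)
difference is retained alongside.

Origin composition cross-tabulates every recipient clonotype by its
recipient expansion class × donor class (absent / nonexpanded / normal /
pathological), so row sums equal recipient class sizes. The recipient–donor
size association over shared clonotypes is summarized by Spearman rank
correlation (undefined, and refused, for all-tied inputs or fewer than
three shared clonotypes).

## Specificity annotation

References aggregate VDJdb/McPAS-style TSVs (column and category mappings
per source, YAML-configurable) into CDR3 → (epitope, antigen source,
category, disease, provenance) entries; exact duplicate
(CDR3, epitope, provenance) triples collapse, and provenance is kept so
per-source recounts survive upstream database updates. Matching is **exact
uppercase amino-acid identity** — fuzzy matching would change counts in ways
that cannot be validated against the reference. A clonotype may match
several categories and is counted in each (the double-counting is
deliberate and surfaced); the overall annotated fraction counts each
clonotype once. CMV clonotype counting defaults to **non-normalized**
tables so that downsampling does not discard low-abundance specificities; a
flag enables normalized-mode comparisons.

## HLA evolutionary divergence

HED at a locus is the mean Grantham (1974) chemical distance over the
aligned peptide-binding-domain protein sequences of the individual's two
alleles (class I: the exon 2–3 region); mean class I HED averages loci A, B
and C. Divergence is normalized by the number of gap-free aligned positions
(the convention of the HED literature; a raw-sum mode exists behind a
flag); gap positions are excluded from numerator and denominator. The
published integer Grantham table is embedded as the authoritative matrix;
the composition/polarity/volume formula and property constants are kept
alongside for independent recomputation (the printed table's Asp–Trp entry
deviates from the formula by ~10 units and is retained as printed). Allele
FASTA input must be pre-aligned per locus — this module does not align.
Genotypes resolve at two-field (protein-level) resolution; unresolvable
alleles fail loudly rather than falling back to a nearest allele.

## Synthetic cohort generator

The generator emulates the statistical structure the pipeline assumes,
with construction-time ground truth for carry-over, public, spike and
labeled clonotypes.

* **Clone sizes**: i.i.d. truncated discrete power law `P(k) ∝ k^−α`,
  k = 1..`max_clone_size` (defaults α = 2.5, cap 30). The power law is the
  simplest heavy-tailed law putting most clonotypes at one template; the
  cap reflects that healthy repertoires at 5–100k templates rarely carry
  clones beyond a few tens of templates — larger clones enter only as
  explicit pathological/hyperexpanded spikes, which is also what gives the
  generator labeled ground truth. Sizes are drawn until they fill the
  sample's target depth exactly (only the final clone trimmed), so depth is
  exact and richness emergent (≈ depth / E[size]); a fixed-richness mode
  exists. With independent draws, richness and depth cannot both be fixed
  targets simultaneously; depth was chosen as the exact one because the
  normalization stage keys on it.
* **Depths**: uniform in (5,000, 100,000) by default, the depth range of
  the emulated assay. Tests and the acceptance script run scaled-down
  cohorts (depths 2,000–12,000, 4–50 pairs) to keep the suite within
  desk-scale runtimes; all statistical checks are sized to their own
  Monte-Carlo error, not to a particular cohort scale.
* **Public pool**: `round(public_rate × expected richness)` CDR3 keys
  (default rate 0.009) included in *every* sample with law-distributed
  sizes, making both the expected fraction-of-repertoire drawn from the
  pool and the measured unrelated-pair background ≈ `public_rate`.
* **Carry-over**: each recipient timepoint inherits
  `round(carryover_fraction × richness)` keys (default 2.5%) sampled from
  the donor's private clonotypes, with sizes rank-correlated to the donor's
  through a Gaussian-copula reordering (default ρ = 0.7), emulating the
  observed donor–recipient size correlation.
* **Timepoints**: per-timepoint richness multipliers (defaults 0.9, 0.85,
  0.8 for day +30/+100/+180) and growing pathological spike counts
  (20, 30, 50; sizes uniform 15–45 templates, above any reference-derived
  τ); `gvhd_mode` adds hyperexpanded spikes (120–300 templates) at the last
  timepoint. When the configured depth is fixed, de-novo clone counts are
  nudged (removal proportional to excess-over-1, addition
  size-proportional) so every emitted table hits the depth exactly while
  carry-over, public and spike clones stay untouched.
* **Labels**: every cohort key is labeled per category with configurable
  Bernoulli rates (pathogen 0.02, cancer 0.005, autoimmune 0.004, allergy
  0.002, CMV 0.01); the generated reference contains exactly the labeled
  keys plus decoy entries absent from all samples.
* **Keys/seeds**: CDR3-like strings (C…F, length 8–20) from a > 10¹²
  keyspace; accidental collisions < 10⁻⁶ per cohort. All draws derive from
  `master_seed` via the same per-sample hash as normalization, so cohorts
  are byte-reproducible and composition-independent.

### What the generator does and does not emulate

It reproduces: heavy-tailed clone sizes with singleton dominance, a ≲1%
public background, low donor carry-over recoverable after background
subtraction, post-transplant richness contraction with growing pathological
and hyperexpanded fractions, and minority specificity labels. It does
**not** reproduce: V/J gene usage or generation-probability structure
(keys are random strings), the exact singleton fraction of real repertoires
(α = 2.5 gives ≈ 75% singletons vs ≈ 95% in deep real data, so absolute
ISI, expanded-clone counts and pathological occupancy on synthetic cohorts
are not calibrated to real cohort values — trends and recovery properties
are what the tests certify), sample-to-sample batch effects, or sequencing
error. Passing tests therefore demonstrate correctness of the measurement
machinery and recoverability of known ground truth, not numerical agreement
with any particular clinical cohort.

## Numerical and design notes

* Threshold: strict inequality `size > τ`, τ = ⌊upper CI⌋; degenerate
  zero-variance references give τ = ⌊mean⌋; reference samples without any
  expanded clonotype are excluded with a warning, and fewer than two usable
  samples is an error.
* Downsampling at full depth is an exact identity (no draw); depth above
  sample depth is refused (no upsampling).
* ISI and occupancy are undefined on empty tables and raise.
* Fold changes against a zero reference count are NaN-flagged, not ±inf.
* Overlap size-class comparisons refuse unequal depths; background
  subtraction floors at 0 with the raw value retained.
* All TSV outputs are UTF-8, tab-separated, single header; the pipeline
  writes a JSON manifest with sha256 of every output, so idempotence is
  checkable byte-for-byte.

## Limitations

* Absolute annotated fractions and CMV counts depend entirely on the
  reference database supplied; on synthetic cohorts they reflect the
  configured label rates, and on real data they are reference-version
  dependent — treat them as qualitative comparisons.
* The derived τ is a property of the supplied reference cohort at its
  normalized depth; it is not transferable across depths or cohorts.
* HED requires pre-aligned allele sequences; no class II loci, no
  imputation of low-resolution typings.
* Survival/competing-risk modeling of the exported metric tables is out of
  scope; the per-sample metrics TSV is designed to feed standard survival
  packages directly.
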