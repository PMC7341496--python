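# Methods

## Data model and coordinates

Genotypes are allele-dosage matrices (individuals × SNPs) counting copies
of each marker's declared reference allele; missing calls use a distinct
sentinel (−1), never 0, since 0 is a valid homozygote. All coordinates
are 1-based inclusive internally; BED's half-open 0-based convention is
converted only at the I/O boundary. Markers are kept in canonical
(chromosome, position) order and non-autosomal markers (X, Y, MT,
unplaced) are dropped at read time with a logged count; the autosome set
defaults to 1–31 (the horse karyotype). Interval lengths are
end − start + 1.

Every downstream statistic is invariant to swapping the reference allele
(d → 2 − d): homozygosity, folded allele frequency and |r| do not depend
on the coding, and the test suite asserts this.

## Quality control

Filters run in a fixed order — SNP call rate, HWE, MAF, then sample call
rate — with removals recorded per step so attrition is auditable.
Defaults: call rates ≥ 0.90, HWE p ≥ 10⁻⁶, MAF ≥ 0.01. MAF and HWE are
computed on post-call-rate, pre-sample-filter data (one pass per
criterion). The HWE test is the standard two-sided exact test
conditioning on the observed minor-allele count, without mid-p
correction; it is computed in log space and verified against an
exact-rational enumeration oracle. Re-applying QC to its own output is a
no-op on the fixtures tested; this is not a theorem (removing samples can
in principle re-lower SNP call rates) but holds away from threshold
boundaries.

## Runs of homozygosity

Detection is the consecutive-runs method (no sliding window). A valid
run is anchored on homozygous non-missing SNPs at both ends and
satisfies: ≥ 15 homozygous SNPs, ≥ 500 kb, no inter-SNP gap > 1000 kb, at
most one heterozygous and one missing call, and ≥ 1 SNP per 100 kb.
Heterozygous/missing calls inside a run do not count toward the SNP
minimum but lie inside the reported interval. The density limit —
natively a sliding-window parameter — is enforced as the post-hoc filter
n_snp/length; because a denser sub-window can pass where its maximal
extent fails, the scanner falls back to an exact sub-window enumeration
in that (rare) case, so it returns exactly the maximal rule-passing
windows. An exhaustive window-enumeration oracle confirms this on short
chromosomes.

Maximal windows can overlap (a run may absorb its single allowed
heterozygote in either direction); the longest window wins, ties broken
toward the smaller start, making reported segments non-overlapping per
individual per chromosome. Class boundaries (0.5/1/2/4/8 Mbp) are
half-open with exact boundaries promoted to the upper class.

## Inbreeding

F_ROH divides the summed run length by L_AUTO, the autosomal length
covered by SNPs (sum of per-chromosome max − min + 1 spans; chromosomes
with < 2 SNPs are excluded with a warning). L_AUTO is computed from the
map by default and can be pinned (e.g. to 2,276,000,000 bp, the covered
length of a 65k equine panel on EquCab3) for cross-study comparability.
Class components share the genome-wide denominator, so they sum exactly
to the total. Per-chromosome components are normalized by each
chromosome's own covered span — a chromosome-level inbreeding of 0.21 is
only interpretable on that scale; the genome-wide-denominator alternative
can be recovered by multiplying by the chromosome's length share.

Run length dates the inbreeding event: a segment of L Morgans points to
a common ancestor ~1/(2L) generations back, with physical length
converted at a genome-wide 1 cM = 1.24 Mbp (so 2 Mbp → ~31 generations,
8 Mbp → 7.75). Per-chromosome F_ROH distributions are screened with
population-moment skewness and non-excess kurtosis (normal = 3, matching
the kurtosis-above-three outlier convention); no bias correction is
applied to the moment estimators.

## ROH islands

The incidence track counts, per SNP, the individuals with a run spanning
its position (deduplicated per individual). Islands are maximal stretches
of consecutive SNPs with incidence strictly above the threshold (default
0.70, "more than 70%"; an inclusive mode exists). A single
below-threshold SNP separates islands, and island coordinates are SNP
positions, not segment boundaries — a map-anchored, testable convention.
Each island reports its best- and worst-supported SNP fractions; the best
(support_max) is the single percentage printed in reports. Annotation
overlap is closed-interval intersection (≥ 1 bp shared) against
user-supplied BED/GFF3 features via an interval tree.

## Effective population size

Pairwise r² is the squared Pearson correlation of dosage vectors over
pairwise-complete samples, within chromosomes, for pairs 0.5–26 Mbp apart
(pairs with < 10 complete observations or zero variance are skipped).
Pairs are binned into 30 equal-width physical-distance bins; each bin's
mean distance maps to c Morgans (linear map at 1.24 Mbp/cM by default;
Haldane and Kosambi transforms available) and yields

    Ne = (1 / (4 f(c))) * (1 / E[r²_adj] − α),   t = 1 / (2 f(c)),

with α ∈ {1, 2, 2.2} (default 2.2, the Sved & Feldman mutation-rate
modifier). The sample-size correction subtracts 1/n (n individuals) for
unphased genotypes and 1/(2n) for phased haplotypes — the convention of
the LD-Ne tools this reimplements; forward-simulation checks show it
recovers a constant true Ne essentially unbiased, whereas subtracting
only 1/(2n) from unphased r² underestimates Ne by ~25%. Bins whose
corrected r² reaches 1/α admit no positive estimate and are dropped with
a log message.

NeS slopes: with estimates sorted by t ascending, each segment's slope is
normalized by the median of the two slopes immediately deeper in time and
reported as ratio − 1, so any affine Ne(t) is a flat line at 0; the raw
ratio is also emitted, and points with a zero reference slope are
omitted. The trajectory is reported only over the t range the distance
bins imply (≈ 2.4–58 generations under the defaults); no extrapolation
to more recent generations is attempted.

## Synthetic data

The generators define the package's verification conditions:

* **Panel** — 31 chromosomes by default with exponential inter-SNP gaps
  of mean 40 kb and uniform reference-allele frequencies on [0.05, 0.5],
  emulating a 65k equine array; deterministic under a seed.
* **Planted ROH** — background genotypes are Hardy–Weinberg draws (or a
  fixed heterozygosity rate); truth intervals are forced homozygous for a
  single allele. Two flanking SNPs on each side of every truth interval
  are forced heterozygous (`mark_boundaries`): with one heterozygote
  allowed inside a run, an unmarked boundary would frequently extend
  through background homozygotes, so the double-het flank makes planted
  boundaries identifiable to within one inter-SNP spacing by
  construction. Missingness is applied after planting.
* **Gene dropping** — founders carry two globally unique haplotype
  labels; each meiosis recombines its parent's label tracks with
  independent per-interval Haldane switch probabilities at 1.24 Mbp/cM.
  Autozygosity truth is exact (intervals where an individual's two labels
  coincide); genotypes are realized from per-founder-haplotype allele
  draws. Full-sib-mating offspring average an autozygous fraction of
  0.25 across replicates, the pedigree expectation.
* **Wright–Fisher** — forward-in-time diploid random mating (monoecious,
  selfing allowed), no mutation or selection, piecewise-constant size
  history; the emitted sample is a fresh offspring draw from the final
  generation, so the sample size may exceed the census size. Fixed SNPs
  are retained for QC to remove. The constant-Ne recovery check runs 30
  chromosomes × 1000 SNPs, Ne = 50 for 100 generations, 60 sampled
  diploids, 20 seeds (~90 s total) — sizes chosen so the LD at the
  distances used has equilibrated while the suite stays desk-scale.

What the simulations do not emulate: real site-frequency spectra and LD
from deep coalescent history, chromosome-specific recombination maps
(the 1.24 Mbp/cM constant is global), genotyping error, and family
structure in the sampled cohort. Passing tests therefore demonstrate
correctness of the algorithms under the stated models, not calibration
on any particular real dataset.

## Numerical and degenerate-input conventions

HWE p-values are exact to ~1e-12 relative; r² uses float64 matrix
algebra (agreement with the textbook covariance formula to 1e-12); the
adjusted r² is floored at 1e-9 with a warning when the correction
exceeds the observed mean. Monomorphic SNPs have MAF 0 and HWE p 1.
Chromosomes absent from the map raise errors rather than silently
dropping segments. Empty QC output, empty LD bin sets and sub-four-point
Ne trajectories raise explicit errors. All generators and the pipeline
are bit-reproducible under fixed seeds; pipeline reruns produce
byte-identical TSVs.

## Known limitations

The consecutive-runs scanner is exact but single-threaded Python per
individual-chromosome; a 90 × 65k dataset takes tens of seconds. The
sliding-window ROH method, phased-haplotype LD, pedigree-based
inbreeding, between-breed Fst scans and coordinate liftover are out of
scope. Birth-year cohort filtering is supported only through sample
metadata supplied via the API (the PLINK formats carry no birth year).
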