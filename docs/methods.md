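# Methods

## Scope and model

The package analyses satellite DNA (satDNA) — tandemly repeated,
non-coding DNA organized in long head-to-tail arrays — in low-coverage
short-read libraries, and screens SNP genotype matrices for perfectly
sex-linked loci. The working assumptions throughout are:

* a satDNA family is represented by one consensus monomer of length `rul`
  (repeat-unit length, bp); reads derived from its arrays are ungapped
  windows onto a tandem concatenation of monomer variants;
* monomers have no intrinsic phase or strand: two deposited consensuses of
  the same family may be arbitrary rotations and/or reverse complements of
  each other;
* sequencing is uniform over the genome, so a family's share of a
  library's reads equals its share of the genome.

## Pairwise catalog identity

Identity between two monomers is computed by aligning the shorter
sequence end-to-end against the head-to-tail dimer of the longer one
(both strands), scoring match +1, mismatch −1, gap open −5, gap extend −1,
with free end gaps on the dimer only. Identity is matches over aligned
columns of the placed query; `N` never counts as a match. Dimerization
makes the measure rotation-invariant (every rotation of the partner is a
substring of its dimer), and the query-global ("glocal") formulation is
what keeps the percentage meaningful: a plain local alignment under
match/mismatch scoring degenerates to the longest shared word — two
unrelated monomers always share some exact 5-mer, which would read as
"100% identity". With the glocal form, unrelated random monomers of
≥ 100 bp score ~43–49%, safely below the 50% superfamily bound, while
substitution-only variants score exactly their best rotation/strand
Hamming identity (verified against a brute-force rotation oracle in the
tests).

Classification uses strict thresholds — same variant > 95%, same family
> 80%, superfamily > 50% — with boundary values falling to the lower
class. Because documented cross-catalog overlaps include pairs in the
50–80% band, the default criterion for "family shared between catalogs"
is one cross-partner above 50% (superfamily level), counted over the
smaller catalog; the stricter 80% reading is a flag
(`--family-threshold`).

## Read mapping and abundance

Each read (and its reverse complement) is aligned with edlib in infix
mode against a concatemer of every catalog consensus long enough to
contain the read plus two monomers, so monomer phase never matters. The
read is assigned to the family with the most matching bases, subject to
identity ≥ 80% over the alignment and ≥ 28 bp aligned (one unit of the
shortest monomer handled; both configurable), and counts at most once.
Abundance defaults to aligned bp over analyzed bp — the masked-fraction
definition comparable across families of different `rul`; the literal
reads-per-nucleotide variant is available as `abundance_mode`. Library
subsampling defaults to 2 × 5,000,000 reads, scaled down by configuration
in all tests and synthetic runs (synthetic libraries here are 10³–10⁴
reads, which already give ~1% counting error on planted ratios).

Per-read divergence uses the Kimura 2-parameter estimator
`K = −1/2 ln((1 − 2P − Q)·sqrt(1 − 2Q))` on transition/transversion
proportions over ungapped aligned columns; `1 − 2P − Q ≤ 0` or
`1 − 2Q ≤ 0` raises a saturation error, and saturated reads are excluded
from the per-family mean, which is weighted by aligned bp. The male:female
abundance ratio uses an `inf` sentinel for male-specific families and
flags candidates at ≥ 1.5-fold bias in either direction (a deliberately
conservative shortlist threshold; configurable). The pipeline aggregates
same-sex libraries by mean abundance before forming the ratio, so with
two karyomorphs a family biased 3× in one karyomorph shows a ~2× pooled
ratio — per-library tables are retained for karyomorph-specific ratios.

Paired catalog comparison is the classical paired t
(`t = mean(d)/(sd(d)/√n)`, df = n − 1, two-sided, 95% confidence), with
degenerate inputs handled explicitly: all-zero differences give
(t = 0, p = 1); zero-variance nonzero differences give (±inf, p = 0).

## Monomer extraction and haplotype networks

Monomer excision deliberately avoids edit-distance alignment. For
substitution-only divergence, an edit-distance aligner can return a
gapped path of equal cost (e.g. `1D+1X+1I` instead of three
substitutions), which spuriously breaks every complete monomer window.
Since the model treats reads as ungapped array windows, extraction scans
all `rul` rotation phases of the consensus (both read strands) with a
vectorized Hamming comparison and keeps the phase with fewest
mismatches; ties prefer the forward strand. Reads below 80% whole-read
identity are discarded (the floor is configurable and is an acknowledged
free parameter of this analysis). From the winning phase, the complete
in-frame monomer window with the most matches to the consensus is excised
(leftmost on ties); an `all_copies` mode returns every complete window.
Length-changing variants are therefore not recovered — they would fail
the identity floor under any phase — which matches the decision to treat
indel-bearing copies as outside the haplotype set.

Haplotypes are exact-sequence equivalence classes; classes seen once
across all libraries (singletons) are removed as probable sequencing
errors. The minimum spanning tree is Kruskal over the complete pairwise
Hamming-distance graph with a documented deterministic tie-break: among
equal-weight edges, higher combined node totals first, then lexicographic
endpoint order. Tie-breaking can change topology but never total weight
(the weight is checked against exhaustive Prüfer-sequence enumeration of
all spanning trees for up to 7 nodes in the tests). Unequal-length node
sets require an explicit edit-distance flag. Group statistics partition
the haplotype set into per-group exclusive (nonzero counts in exactly one
group), shared-by-all, and partially shared categories.

## Sex-linked marker screen

A locus is XY-patterned when every non-missing male is heterozygous
(code 2) and every non-missing female homozygous (0 or 1); ZW is the
mirror image. By default loci with any missing call are excluded
(`max_missing = 0`), because "all males" is undefined under missingness;
relaxation is explicit. The chance expectation per pattern is binomial:
`E = L · h^(n_het-sex) · (1 − h)^(n_hom-sex)`, which at h = ½ reduces to
`L · 2^−(n_m+n_f)`. `h` defaults to the dataset's observed heterozygosity
rate, with an override (e.g. 0.5). The verdict rule is concrete where
qualitative reasoning is common: a system is "suggestive" only when the
observed count exceeds E and the one-sided Poisson tail
`P(X ≥ observed | E)` is below 0.05. The Monte-Carlo calibration in the
tests confirms the scan's null false-positive count is an unbiased
estimator of E across (L, n_m, n_f, h) settings.

## Synthetic data

The generator reproduces the structure the analyses assume, with a truth
ledger for recovery tests:

* **Haplotypes.** A random consensus plus substitution variants at a
  per-site mutation rate (default 0.05; 0.08 in the study-shaped design,
  i.e. ~2 substitutions on a 28-mer). Any haplotype's divergence from the
  consensus is capped at 15% (`max_divergence`): a "variant" beyond
  family-level similarity would not be recognized as the same satDNA by
  the 80% identity floor, and in real catalogs would be a different
  family.
* **Arrays.** Each haplotype occupies one contiguous run of copies and
  only run order is randomized. This mirrors concerted evolution, under
  which neighboring copies are near-identical; it is also what makes
  copy-number recovery well-posed, since a 150 bp read then samples one
  haplotype rather than a mixture biased toward the consensus-like copy.
* **Reads.** Uniform random substrings of the arrays (random strand),
  with the family's read share equal to
  `copies × multiplier × rul / genome_size`, plus i.i.d. uniform random
  background. No sequencing-error or quality model (fixed quality
  strings), no coverage bias, no junction reads between array and
  flanking sequence — so passing recovery tests demonstrates correctness
  of the measurement chain, not robustness to base-call errors or to
  partially repetitive reads.
* **Genotypes.** Null loci i.i.d. heterozygous with probability h
  (otherwise 0/1 equally); planted XY/ZW loci follow their pattern
  exactly; missingness applies to null loci only, keeping planted loci
  recoverable by construction. Codes follow the collapsed single-row
  DArT dialect {0, 1, 2, "-"}.

Fixed seeds make all outputs byte-identical; the pipeline manifest
records SHA-256 hashes so whole runs can be compared for equality.

## Default problem sizes

Synthetic runs use 1,500 reads per library over a 50 kb genome model,
300-copy arrays, and 500-locus genotype matrices with 5 males and
5 females — large enough that every planted haplotype is sampled well
past the singleton filter and planted ratios resolve within a few
percent, small enough for interactive use. Monte-Carlo calibrations use
100–500 replicate matrices, with agreement judged within three standard
errors of the replicate mean.

## Known limitations

* The 36-vs-80% ambiguity in "shared family" is inherent to threshold
  curation; both readings are exposed rather than resolved.
* Identity between short (< ~50 bp) unrelated monomers can exceed 50% by
  chance under gapped glocal alignment; superfamily calls between very
  short monomers deserve manual review.
* The monomer extractor's identity floor (80%) is a free parameter; real
  haplotype counts are sensitive to it, so absolute counts from different
  floors are not comparable.
* The chance-expectation formula treats loci as independent and
  individuals as exchangeable; linked loci or family structure in a real
  DArT panel would inflate the true chance rate above E.
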