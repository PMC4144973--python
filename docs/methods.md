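# Methods

## The measurement model

`tagdge` implements a SAGE-derived digital gene expression (DGE) workflow:
each polyadenylated transcript is represented by a single 21-nt sequence
tag — the NlaIII recognition site CATG at the transcript's 3'-most
qualifying position plus the 17 nt released immediately downstream by
MmeI. A library is the multiset of such tags from one sample; a gene's
expression is its tag count, normalized to tags per million clean tags
(TPM = count / clean-tag total x 1e6). The study design is two grape
cultivars (X, sunlight-dependent berry coloration; Y, sunlight-independent)
each contrasted between sunlight exposure and exclusion.

A transcript with no CATG followed by at least 17 nt yields no tag and is
invisible to the assay; such genes are excluded from both simulation and
indexing, with a warning.

## The synthetic-data generator

The generator is first-class, tested code; every downstream stage is
exercised against libraries with known truth.

- **Transcriptomes.** Uniform-random A/C/G/T sequences (default lengths
  200–2000 nt); when no qualifying CATG arises by chance one is planted
  21 nt from the 3' end, so every gene has a canonical tag by construction.
- **Expression.** Baseline per-gene tag fractions are log-normal with
  shape sigma = 1.5. This long-tailed choice reproduces a realistic
  copy-number spectrum (most distinct tags at low copy number, a small
  set of very abundant tags); it is a modeling stand-in, not an inference
  from any particular dataset. An optional floor on the normalized
  baseline fraction guarantees a minimum expected count at a given depth.
- **Differential structure.** Independently per cultivar, a configurable
  fraction of genes (default 10%) has its exclusion-condition mean
  multiplied by 2^(+-effect) with random sign (default effect 2.0 in
  log2). Per-library expected fractions are renormalized to sum to one.
- **Sequencing.** A library of depth N is a multinomial sample of N tags
  over genes' canonical tags. Each sampled tag independently receives one
  uniform substitution in its 17-nt suffix with probability 0.01 (about
  0.06% per base over 17 nt, an Illumina-scale error rate); the CATG
  anchor is structural and never mutated, and at most one substitution
  occurs per tag, so every erroneous tag sits at Hamming distance 1 from
  its source. Random streams are seed-isolated per operation.

What the generator does **not** emulate: PCR amplification bias, adapter
chemistry, quality scores, multi-mapping across paralogous transcripts
beyond chance 17-mer collisions, biological replicate dispersion
(libraries are exact multinomials), or genes whose 3' tag spans a splice
junction. Passing tests therefore demonstrate correctness of the
algorithms under the stated sampling model, not robustness to every
artifact of real tag data — in particular, the Audic–Claverie test's
clean type-I calibration here reflects the absence of overdispersion by
construction.

## Tag processing and mapping

- **Cleaning** removes tags that are not exactly 21 nt, lack the CATG
  prefix, or contain ambiguous characters, and aggregates duplicates;
  counts are conserved exactly for valid input.
- **Copy-number profiles** partition distinct tags into the closed integer
  bins {1}, [2,5], [6,10], [11,20], [21,50], [51,100], >100. (Published
  DGE tables sometimes tally copy-number-1 tags separately from "unique
  tags"; here the bins always partition all distinct tags.)
- **Saturation curves** subsample tags without replacement via a permuted
  expansion of the count multiset and report distinct detected genes (or
  tags) at depths step, 2·step, …, full depth. The subsampling grid is
  configurable; curves are non-decreasing and terminally exact by
  construction.
- **Mapping** indexes one canonical tag per gene (the assay sees only the
  3'-most site; all-site indexing is deliberately out of scope) and
  resolves each library tag in tiered priority: exact hash hit, else the
  union of genes whose canonical tags lie at Hamming distance 1, found by
  enumerating the 51 single substitutions of the suffix (anchor mismatches
  are never considered). A tag whose best tier hits more than one gene is
  discarded into an ambiguous counter — conservative, never fractionally
  split — and unresolved tags are counted unmapped, so
  mapped + ambiguous + unmapped always equals the clean-tag total.

## The differential test

For counts x (control/exposure, total n1) and y (treatment/exclusion,
total n2), the Audic–Claverie conditional distribution of y given x under
equal abundance is

    p(y | x) = (n2/n1)^y (x+y)! / ( x! y! (1 + n2/n1)^(x+y+1) ),

which is the negative binomial NB(r = x+1, p = n1/(n1+n2)). Both tails are
computed directly as regularized incomplete beta functions — P(Y<=y) =
I_p(x+1, y+1) and P(Y>=y) = I_{1-p}(y, x+1) — never as one minus the
other, so no catastrophic cancellation occurs for counts up to 1e6 and
totals up to 1e8 (p-values below ~1e-308 underflow to exactly 0, the
correct float64 answer). The two-sided p-value is min(1, 2·min of the two
tails), each tail including the observed point.

**A note on orientation.** With both tails point-inclusive, the p-value is
*not* exactly invariant under swapping (x, n1) with (y, n2): the two
orientations' minimal tails differ by exactly the observed table's point
mass (the swapped lower tail equals one minus the original lower tail,
while the swapped upper tail equals the original lower tail plus the
swapped point mass). The property suite asserts agreement at precisely
that bound, with exact equality on the balanced diagonal.

**Calling rules** (defaults): genes with TPM < 10 in *both* libraries are
excluded before testing; zero counts are replaced by 1 before the ratio
(so a 100-vs-0 gene gets log2(1/100) ≈ −6.64), computed on the TPM scale
so unequal depths are handled; the raw p-value comes from the unmodified
counts. A gene is called up/down when its BH-adjusted q-value <= 0.001
*and* its raw p <= 1e-4 *and* |log2 ratio| >= 1; the twofold tier flags
|log2 ratio| >= 2. The two significance ceilings are applied conjointly
because both appear as stated thresholds in this workflow's lineage and
conjunction is the conservative reading; each is independently relaxable.
BH is the default adjustment with Bonferroni selectable — the historical
description ("Bonferroni corrected P-value … to control the FDR")
conflates the two procedures, so both are provided. The adjustment is
computed over the genes surviving the TPM floor.

**A compositional caveat** the synthetic experiments make visible: because
TPM fractions must sum to one, an asymmetric amount of truly up- vs
down-regulated mass shifts every observed ratio by the libraries' total
composition factor. With 10% DE split evenly at |log2fc| = 2, observed up
ratios shrink toward ~1.85 while down ratios deepen toward ~2.15, so the
twofold tier under-calls up-regulated genes while tier 1 remains balanced.
This is a property of ratio normalization itself, not a defect of the
test, and it is why parameter-recovery checks are stated at tier 1.

## Response classification and clustering

The nine-way labels are the cross product of each cultivar's
up/down/unchanged call: concordant (Xup-Yup, Xdown-Ydown), single-cultivar
(Xup, Xdown, Yup, Ydown), discordant (Xup-Ydown, Xdown-Yup), and
unchanged. A gene filtered out (or absent) in one cultivar counts as
unchanged there, so the labels always partition the full gene universe and
the bookkeeping identities hold exactly, e.g.

    total up in X = Xup + Xup-Yup + Xup-Ydown.

At the twofold tier a tier-1-only call demotes to unchanged.

Clustering of genes' (log2 ratio in X, log2 ratio in Y) profiles is
average linkage (UPGMA) under Euclidean distance, implemented in-package
with the Lance–Williams update so the tie-break is pinned: among equally
distant pairs the lexicographically smallest (i, j) cluster-id pair merges
first (ids follow the standard convention — inputs 0..n-1, merge k creates
id n+k). Heights are non-decreasing because average linkage is reducible.
The implementation is validated against both a brute-force oracle that
recomputes every inter-cluster average from raw points and scipy's
`linkage(method="average")` on tie-free instances. The O(n^3) scan is
intended for the hundreds-to-low-thousands of regulated genes this
workflow clusters.

Functional-bin cross-tabulation counts each bin's genes per regulated
label, recomputing the Total column rather than trusting input (published
bin tables are known to carry internal inconsistencies between row sums
and narrative counts); genes in several bins count once per bin, and
unknown gene references are skipped with a warning.

## qPCR cross-validation

Relative expression uses the pure Livak 2^-ddCt estimator (no
amplification-efficiency correction), with replicates averaged on the Ct
scale first and single-reference normalization (multi-reference averaging
available). Fold changes are invariant to any constant Ct shift and
reciprocal under condition swap — both property-tested. Comparisons with
digital ratios use the signed-integer fold convention (+f = f-fold up,
−f = f-fold down); a transcript undetectable by qPCR propagates as an ND
sentinel and, under the default policy, scores as down-regulation in sign
concordance, matching how undetectable anthocyanin-pathway transcripts
under sunlight exclusion are interpreted. Signs are compared with plain
sign (zero = unchanged), so a |fold| = 1 table entry counts as regulated;
on the packaged 16-gene reference comparison this yields 15/16 agreement
in cultivar X and 9/16 in cultivar Y (24/32 overall) — Y's lower score
reflects its many near-zero entries straddling the unchanged boundary.

## Problem sizes and numerical choices

The synthetic study runs at 2,000 genes and 1e6 tags per library
(matching the calibration and recovery experiment sizes this workflow is
specified at; published libraries are ~1e7 tags, and nothing in the
implementation depends on the smaller depth). Type-I calibration uses
10,000 null genes; the expected-count floor for recovery experiments is
30 tags at baseline. Exact-summation oracles for the test statistic sum
the point-mass series in log-gamma space over a support wide enough that
the truncated tail is below 1e-300. Determinism: every stochastic
operation takes an explicit seed; the pipeline derives per-stage seeds
from one master seed via `SeedSequence`, and identical configurations
produce byte-identical output files.

## Known limitations

- Two-library exact-style testing only; no dispersion modeling across
  biological replicates (replicate tables can be pooled, mirroring the
  pooled-library design this workflow descends from).
- Tag-level identification cannot distinguish genes sharing a canonical
  tag; such collisions are surfaced as ambiguous counts, not resolved.
- The log-normal expression model and substitution-only error process are
  idealizations; see the generator section for what passing tests do and
  do not establish.
- Percent bookkeeping reproduces printed per-cultivar up/down percentages
  from category counts; genome-fraction percentages are not reproduced
  because they require the full annotation universe.
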