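# Methods

## Distance model

Distances between aligned COI barcodes are computed under the Kimura
2-parameter (K2P) model. For each unordered pair, sites where either
sequence carries a gap, `N`, or an IUPAC ambiguity code are excluded
(*pairwise deletion*: each pair keeps its own compared-site count L;
*complete deletion*, removing such columns once for the whole alignment, is
available as an option). Remaining mismatches are classified as transitions
(A↔G, C↔T) or transversions; with P = transitions/L and Q = transversions/L
the distance is

d = −½·ln(1 − 2P − Q) − ¼·ln(1 − 2Q)   [substitutions/site].

Ambiguity codes are excluded rather than probabilistically resolved so that
distances are deterministic and reproducible. When 1 − 2P − Q ≤ 0 or
1 − 2Q ≤ 0 the pair is saturated and the entry is stored as *undefined*
(NaN), never as a clamped large number; downstream statistics skip
undefined entries and log how many were skipped. Distances are held as
substitutions/site everywhere and converted to percent only in
report-facing tables, which print one decimal by default (two where
convention prints two).

The choice of pairwise deletion matters only for data with gaps or
ambiguities; on a gap-free alignment (the intended input — COI barcodes
aligned without indels) pairwise and complete deletion coincide.

## Gap statistics

The headline statistic is deliberately strict: per species, the **maximum**
intraspecific distance (defined only for ≥ 2 specimens) and the **minimum**
distance to a congeneric heterospecific specimen (defined only when the
genus holds ≥ 2 sampled species). Species lacking a value are excluded from
the respective mean — a single-specimen species is not counted as zero
intraspecific divergence, which would deflate the average. The gap ratio is
the quotient of the two means, computed from unrounded values and compared
against the conventional 10× criterion. A zero average maximum
intraspecific distance is reported as an infinite-gap flag rather than a
division error.

Every specimen pair belongs to exactly one primary class: intraspecific,
congeneric-interspecific, intrasubfamilial-interspecific (same subfamily,
different genus), or other. The *within-subfamily interspecific* summary
class is the union of the congeneric and intrasubfamilial classes —
congeners are inside their subfamily, and only with them included can a
subfamily's interspecific range reach 0 when congeners share haplotypes.

## Discrimination criteria

Whether a barcode "identifies" a species is operationalized two ways, and
the default (`both`) requires passing each where assessable:

- **nearest-neighbor**: a species fails if any of its specimens has a
  heterospecific specimen at a distance ≤ that specimen's nearest
  conspecific distance. Single-specimen species fail only on an exact
  haplotype tie (distance 0).
- **local-gap**: a species fails if its maximum intraspecific distance is
  ≥ its minimum distance to any heterospecific specimen.

A distance of exactly 0 to a heterospecific specimen fails under every
criterion: shared haplotypes defeat identification regardless of how the
clusters look. The two criteria capture different readings of "unique
barcode" (literal haplotype uniqueness vs. cluster distinctness); both are
reported per species together with the offending partner species.

## Neighbor joining

The tree is built by plain neighbor joining in the Studier–Keppler
formulation: at each step merge the pair minimizing
Q(i,j) = (n−2)·d(i,j) − R(i) − R(j), with branch lengths from the standard
split formula. Ties in Q are broken toward the smallest index pair in
current matrix order, making trees bit-reproducible. A negative branch
length is clamped to zero and its deficit moved to the sister branch, so
the pair's summed length (and hence path distances) is preserved; on
additive matrices no clamping triggers and the generating topology and
lengths are recovered exactly (verified to 1e−9 on random trees with 5–12
leaves). Undefined matrix entries are handled by policy: `strict` raises,
`drop-specimen` (default) removes a greedy highest-degree vertex cover of
the undefined-pair graph, which is minimal on the star-like patterns
saturation actually produces. No bootstrap is computed.

Monophyly on the unrooted tree is decided by bipartitions: a label set is
monophyletic iff some edge splits the leaves into exactly that set and the
rest; the answer is independent of where the tree is drawn rooted.

## Synthetic data generator

The simulator exists so the whole pipeline is testable without any
external data, and its assumptions deliberately match the estimator's:
sites evolve independently under the continuous-time K2P process
(transition rate α, transversion rate β per target, κ = α/β, total rate
α + 2β normalized to 1 so branch lengths are in expected
substitutions/site), the root sequence is uniform over {A,C,G,T}, and
there is no rate heterogeneity or codon structure. Under these conditions
the K2P estimator is asymptotically unbiased for the path length, so
parameter recovery is a clean test of the pipeline rather than of model
mismatch; conversely, passing tests say nothing about real-data violations
(base-composition bias, among-site rate variation, NUMTs, sequencing
error).

Lineages form a four-level star hierarchy: root → subfamily ancestors →
genus ancestors → species ancestors → specimens. Each configured divergence
is the expected pairwise K2P distance between the corresponding lineages
and is split equally over the two connecting branches: specimens sit
intra/2 from their species ancestor (a star per species, the simplest
structure for conspecific variation without modeling coalescence), species
ancestors congener/2 from the genus ancestor, genus ancestors subfamily/2
from the subfamily ancestor. The root → subfamily branch is
subfamily_divergence/4; cross-subfamily pairs fall in no configured
comparison class, so this only has to keep subfamilies clearly separated.

Defaults emulate a regional mirid survey: 7 subfamilies, 4–8 genera per
subfamily, 2–4 species per genus (~126 species expected), 658-site
barcodes, κ = 2, intraspecific divergence 0.002, congeneric 0.11,
within-subfamily 0.19. Specimens per species are drawn from
{1: 10%, 2: 65%, 3: 20%, 4: 5%} (mean 2.2). That distribution was chosen,
besides matching the survey-scale average, so that most multi-specimen
species contribute exactly one intraspecific pair: the gap statistic takes
a per-species *maximum* of noisy estimates (biased upward) against a
per-species *minimum* (biased downward), and a generator heavy in 3–4
specimen series would compound that extreme-value bias and make the
recovered ratio systematically understate the configured
congener/intra ratio. Even so the recovered ratio sits below the configured
one (e.g. ≈ 45 vs 55 at the defaults) for exactly this reason; recovery is
asserted to 25% relative error, which the bias analysis predicts
comfortably.

The optional *lumped trio* plants the known failure mode: the first genus
with ≥ 3 species gets one shared species-ancestor sequence for three
species, and the first specimen of each is an exact copy of it, so
pairwise heterospecific distances of 0 are guaranteed and exactly those
three species fail discrimination.

All randomness flows from one `numpy` generator seeded by the config, so a
seed reproduces the dataset byte-for-byte.

## Numerical and formatting choices

- Undefined distances propagate as NaN; every aggregation skips them
  explicitly and logs the count, so no statistic silently averages a
  sentinel.
- Reports store full-precision values (JSON, 10-significant-digit TSV);
  paper-style rounding (one decimal percent, integer ratio) happens only at
  presentation, so rounding never compounds.
- Newick output writes branch lengths with 12 significant digits
  (round-trips preserve them to ≥ 10), quotes labels containing spaces and
  leaves underscores untouched on both write and read.
- Problem sizes in the test-suite simulations (default survey ≈ 260
  specimens of 658 sites; unbiasedness checks with 200 replicate pairs of
  10,000 sites; 50 random trees of 5–12 leaves) are chosen so that every
  statistical assertion has comfortable Monte-Carlo margin while the whole
  suite runs in seconds.

## Known limitations

- Only the K2P model is implemented; no JC69/TN93/GTR, model selection or
  Γ rate heterogeneity.
- The discrimination criteria are distance-based; no formal
  species-delimitation methods (ABGD, GMYC, PTP) and no fixed universal
  threshold rule.
- The greedy drop policy for undefined distances is not guaranteed to be a
  minimum vertex cover on adversarial NaN patterns.
- The simulator's star phylogenies ignore coalescent structure within
  species and phylogenetic structure within genera; real surveys have
  correlated, unequal divergences.
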