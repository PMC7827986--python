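# Methods

## The audit in one paragraph

A subfamily label is *reliable* if replicate copies of one TE insertion
receive the same label. The package measures unreliability on replicate
pairs extracted from two-copy segmental duplications, then asks how much
of it three mechanisms explain: random point mutation at diagnostic
sites (a closed-form probability model), gene conversion from divergent
donors (a windowed binomial scan), and genuine annotation ambiguity
(an ensemble confidence over competing alignment scores). Because the
real inputs are genome-scale, the package ships a generator that
produces the same statistical structure — library, divergence,
duplication, conversion — with complete ground truth, and every
statistic is validated against that truth.

## Coordinates and formats

All internal coordinates are 0-based half-open; RepeatMasker's 1-based
inclusive columns and `C` strand are converted once, in the reader.
A record naming only a family ("Alu" with no subfamily, or a name in a
configurable ambiguous-name list, default {Alu, L1}) carries an
AMBIGUOUS marker and is excluded from pairing. `N` letters are accepted
in sequences; an alignment column containing `N` counts as non-gap and
non-identical everywhere identity is measured.

## Replicate pair extraction

TEs annotated on the two copies of a duplication are matched by
projecting both annotation sets onto alignment columns. Filters are
conjunctive (order-independent) and each candidate pair records a full
trace of rule outcomes:

* **multiplicity** — any TE overlapping ≥ 2 TEs in the other copy
  invalidates all its candidate pairs (independent insertions can
  masquerade as partial overlaps);
* **min_length** — both copies strictly longer than 50 bp (default);
* **coverage** — reciprocal projected coverage ≥ 0.8, computed on
  alignment columns so gapped data is handled consistently;
* **contiguity** — "related in one contiguous alignment" is
  operationalized as: no indel/unaligned block longer than 30 columns
  (config-exposed; no published value exists) inside the projected
  overlap;
* **ambiguity** — neither member AMBIGUOUS.

Concordance is exact subfamily-name equality. The per-family summary
counts each pair once. The type-level cross table lists a discordant
pair in both member types' rows when the types differ (which makes
cross-type cells symmetric and row mismatch percents exceed the
family-level rate), while a same-type discordant pair counts once in
its type's diagonal cell; partners outside the tracked types fall into
an `other` column. This convention is the one under which the published
type-table counts reproduce their printed row percents.

For annotation sets already mapped into one coordinate system (e.g.
cross-species comparisons after liftOver), `pair_by_overlap` applies
the same multiplicity/length/coverage/ambiguity rules to plain
interval overlaps, pairing greedily by descending overlap.

## Drift model

Parameters per source subfamily *i*: identity `p_a = P(A_i)` — the
probability a site is unmutated since insertion, estimated in practice
as mean instance-to-consensus identity, supplied here from a table or
the generator's ground truth (no hidden estimation). Derived per-site
probabilities: flip to *j*'s nucleotide `(1−p_a)/3`, third ("other")
value `2(1−p_a)/3`, and `P(c) = 3 p_a/(1+2 p_a)`, the probability of
keeping *i*'s value conditional on not mutating to a third value.
The conversion probability sums over the number of sites lost to third
values; among the remaining informative sites, *strictly more* must
agree with *j* than with *i* (the `floor((n−k−1)/2)` CDF bound). A
non-strict "at least half" reading is available via `majority="half"`
for sensitivity analysis; the strict form is the default because it is
what the summation formula states. Each site mutates at most once in
this model; back-mutation is ignored, as the closed form implies.

Diagnostic sites between two consensuses are the substitution columns
of their pairwise comparison (global alignment when lengths differ);
indel columns are excluded — the model is substitution-only. Type-level
aggregation weights each source subfamily by its genome frequency; the
combined-mismatch column sums over all targets and therefore equals the
row sum whenever the type columns partition the library.

The implementation is verified two independent ways: exhaustive
enumeration over all 3ⁿ per-site outcome vectors (exact to ~1e−16 for
n ≤ 6), and simulation — 10⁵ instances mutated under the generator's
model and re-annotated by strict diagnostic-site majority (ties keep
the original label) agree with the closed form within 3 binomial
standard errors.

## Recombination scan

Identity of a two-row alignment is identical columns over non-gap
columns (gap in either row excludes the column). A pair's alignment is
tiled into non-overlapping windows of 100 non-gap columns starting at
the first aligned position; trailing `n mod 100` columns are unused,
which biases the scan conservative. The smallest per-window identical
count is tested with the binomial CDF at the background identity of the
*full containing segment* (not the TE sub-alignment), multiplied by the
number of windows (Bonferroni, per pair only — no across-pair
correction), and flagged when the corrected *P* < 0.001. Pairs shorter
than one window yield zero windows and are never flagged.

Calibration uses 400 bp TEs inside ~4.4 kb segments (2 kb flanks).
Segment size matters: the converted tract must be a small fraction of
the segment so the segment-wide background reflects the unconverted
divergence, as it does in real multi-kilobase duplications; with
segments only ~2× the TE length the tract itself drags the background
down and power drops. At these sizes the scan flags 0–0.15% of 2000
null pairs (bound: 0.1% per pair) and ≥ 97% of 500 pairs carrying a
200 bp tract from a 20%-divergent donor — a full window always lies
inside a tract twice the window length, and its expected identity sits
≥ 15 points below background.

## Annotation confidence and λ

Scores are treated as base-2 scaled log-odds throughout. Confidence is
a base-2 softmax over competing scores computed with the maximum
subtracted first, making it exactly invariant to score shifts; ties set
a flag and adjudication breaks them toward the lexicographically
smallest subfamily name (deterministic; no published tie rule exists).
Gap penalties contribute to scores but carry no probabilistic meaning,
and all candidates are assumed to cover the same genomic range.

λ is the unique positive root of Σ p_a p_b 2^(s_ab/λ) = 1, found by
bisection on 1/λ to relative tolerance 1e−10 after geometric
bracketing; preconditions (negative expected score, at least one
positive score) raise a dedicated error. Background frequencies default
to uniform and are config-exposed.

λ recovery is validated with `matrix_with_lambda`: a random symmetric
integer matrix (matches +1..+3, mismatches −3..−8) whose background is
tuned along a line in the frequency simplex until its true λ equals the
requested value exactly; the implied joint P(a,b) = p_a p_b 2^(s/λ₀) is
then a valid distribution whose λ₀-scaled log-odds are integral, so the
matrix is its own rounded log-odds matrix and recovery is exact up to
solver tolerance. This construction is used because rounding real-valued
log-odds of generic random joints perturbs O(1)-magnitude scores by up
to ±0.5 — at small λ₀ that alone moves the root by tens of percent, so
generic joints cannot isolate solver error from construction error. A
separate check keeps the rounding path honest at λ₀ = 10 with a fixed
diagonal-mixture joint (recovery within ~3%).

## Synthetic generator: what it emulates and what it does not

Emulated: diagnostic-site library structure (each split substitutes a
fixed number of positions, disjoint across splits, so any two
subfamilies differ at ≥ that many sites and sibling subfamilies are
never identical); i.i.d. uniform substitutions at rate 1 − identity;
exactly one duplication per segment with uniform-random flanks sharing
the TE's post-duplication divergence; gene conversion as a single
uniform-length tract wholly inside one TE copy, copied from the
homologous coordinates of a donor.

Not emulated: indels by default (an optional geometric-indel mode was
considered and rejected so that duplicated copies stay positionally
aligned — the local-alignment scoring mode exists for gapped inputs),
insertion-site preference, 5′ truncation of L1-like elements, CpG
hypermutability, rate heterogeneity across sites, selection, tandem or
repeated duplication, single-breakpoint recombination. Passing tests
therefore demonstrate internal consistency of the statistics under the
stated model, not performance on real genomes, where all of the above
add discordance the model does not predict.

Default study conditions (config-exposed): 300 bp consensuses, 4–6
subfamilies, 2–4 diagnostic sites per split, instance identity
0.85–0.95, post-duplication identity 0.975–0.99 per copy (segment pairs
> 90% identical, matching the character of curated duplication sets),
0.5–2 kb flanks, conversion tracts 50–300 bp. Problem sizes in the
shipped analyses — 1000 segments for the audit, 10⁵ instances for drift
calibration, 2000 + 500 pairs for the scan — were chosen to put
3-standard-error bands well inside the effect sizes of interest while
keeping any single script under a minute on one core.

## Numerical and degenerate-input choices

Binomial CDFs come from scipy (`binom.cdf`) with saturated tails
(x < 0 → 0, x ≥ n → 1). Empty annotation sets produce empty pair lists;
groups with zero pairs are omitted from summaries rather than dividing
by zero; a zero-weight type in drift aggregation is an error. An empty
concordant or discordant group skips the KS comparison with a warning
rather than failing. `identity = 0` gives P(c) = 0 by convention (the
0/0 limit). Pipeline runs are bit-reproducible from (config, seed):
every stage derives its generator from the single seed, and report
tables carry no timestamps.

## Known limitations

* The discordance audit assumes annotations are correct *as calls* and
  only measures their reproducibility; it cannot distinguish "both
  copies mislabeled identically" from true concordance.
* The scan misses conversions from near-identical donors (no identity
  dip) and single-breakpoint events, and its absolute rates depend on
  window length and segment background; it is a comparative instrument.
* Fragmented elements are not merged across RepeatMasker fragment IDs;
  the ID is exposed but each fragment is treated independently.
* Positional scoring requires equal-length sequences and is intended
  for the generator's substitution-only output; use local mode for
  anything gapped.
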