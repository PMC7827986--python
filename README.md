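# teaudit — a reliability audit for TE subfamily annotation

Transposable-element (TE) annotation pipelines assign each genomic TE
remnant to a *subfamily* (AluSx, AluY, L1PA2, ...) by aligning it to a
consensus library and keeping the single highest-scoring hit. Subfamily
labels are meant to carry replication history, so they should be
reproducible: two copies of the *same* ancestral insertion — replicate
pairs created by segmental duplication, or shared between closely
related species — ought to receive the same label. In practice a
substantial fraction do not.

`teaudit` implements the full audit of that failure mode for anyone who
builds TE libraries or consumes subfamily annotations:

* **Replicate pair extraction** — project TE annotations through a
  segmental-duplication alignment, keep only trustworthy pairs (both
  copies > 50 bp, ≥ 80% reciprocal coverage, one contiguous alignment,
  no one-to-many overlaps, no family-only calls), and tabulate
  *discordant* pairs per family and per subfamily type.
* **Drift model** — the probability that random point mutation alone
  flips an instance of subfamily *i* across the *n* diagnostic sites
  separating it from subfamily *j*. With per-site identity
  *P(A<sub>i</sub>)* and mutations uniform over the three alternative
  nucleotides,

  *P(S: i→j) = Σ<sub>k=0</sub><sup>n−1</sup> C(n,k) (1−P(O))<sup>n−k</sup> P(O)<sup>k</sup> · B(⌊(n−k−1)/2⌋, n−k, P(c))*

  where *P(O) = 2(1−P(A<sub>i</sub>))/3* is the chance a site mutates to
  a value informative for neither subfamily,
  *P(c) = 3P(A<sub>i</sub>)/(1+2P(A<sub>i</sub>))* is the chance a site
  keeps *i*'s value given it did not, and *B* is the binomial CDF.
* **Recombination scan** — gene conversion from a divergent donor leaves
  a local dip in copy–copy identity. Each pair alignment is split into
  non-overlapping windows of 100 non-gap columns; the smallest identical
  count is tested against the binomial CDF at the *whole-segment*
  identity, Bonferroni-corrected over windows, flagged at *P* < 0.001.
* **Annotation confidence** — integer alignment scores are scaled
  log-odds, *score(t,q<sub>i</sub>) = λ log₂ P(t|q<sub>i</sub>)/P(t|R)*,
  so the ensemble of competing scores yields

  *Conf(q<sub>i</sub>|t) = 2^(s<sub>i</sub>/λ) / Σ<sub>j</sub> 2^(s<sub>j</sub>/λ)*,

  with λ recovered from the scoring matrix as the unique positive root
  of Σ<sub>ab</sub> p<sub>a</sub>p<sub>b</sub> 2^(s<sub>ab</sub>/λ) = 1.
  For a pair, the lower of the two members' best-candidate confidences
  (*smallest-best-confidence*) proxies the confidence that both copies
  are labeled correctly.
* **Synthetic genome generator** — subfamily libraries grown along a
  random tree with a fixed number of diagnostic substitutions per split,
  instances diverged by i.i.d. substitutions, one duplication per
  segment, optional gene-conversion tracts — with complete ground truth,
  so every statistic above can be validated end to end.

No external genome data is required; everything runs on generated data.

## Worked example

The numbered scripts under `analysis/` run the audit on a synthetic
study: 4 subfamilies in 2 types separated by only 2 diagnostic sites per
split (a "clique" of barely distinguishable subfamilies), 1000 instances
at 85% identity, each duplicated once with 2% post-duplication
divergence per copy, 5% of pairs receiving a 100–250 bp gene-conversion
tract from a random cousin instance.

```bash
python analysis/01_simulate.py       # materialize the dataset (results/sim/)
python analysis/02_audit_pipeline.py # the audit itself (results/audit/)
python analysis/03_drift_model.py
python analysis/04_recombination.py
python analysis/05_confidence.py
```

Script 02 prints:

```
pairs kept: 1000 (dropped by filter: {'multiplicity': 0, 'min_length': 0, 'coverage': 0, 'contiguity': 0, 'ambiguity': 0})
discordant replicate pairs: 58/1000 = 5.8%
type-level cross table:
type  concordant  nonmatch_T1  nonmatch_T2  other  mismatch_percent
  T1         548           14           41      0          9.121061
  T2         394           41            3      0         10.045662
recombination flags: 45 of 1000 pairs
confidence KS statistic (discordant vs concordant): 0.583 (p = 2.66e-18)
```

Even though every pair descends from a single insertion, 5.8% of
replicate pairs are annotated discordantly; cross-type cells of the
table are symmetric (41 appears in both rows) because a cross-type pair
is listed in both member types' rows. Script 03 shows the drift model
predicts a combined per-instance conversion probability of 2.8% (type
T1) and 1.9% (T2) and matches direct simulation within sampling error;
script 04 calibrates the recombination scan (0.0% false positives on
2000 null pairs, 97.6% power against injected 200 bp tracts); script 05
reports median smallest-best-confidence of 99.6% for concordant but
49.9% for discordant pairs — discordant pairs are exactly the ones the
ensemble already distrusts.

The same pipeline is scriptable (`teaudit run --config run.yaml`) and
each stage has its own subcommand (`teaudit simulate|annotate|pairs|
drift|recomb`).

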