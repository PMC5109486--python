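# Methods

## Model

A compound's pharmacology is summarized by the set of proteins it is known
to bind.  Writing *A<sub>c</sub>* for compound *c*'s target set (its
*interaction profile*), similarity between compounds is the Tanimoto
coefficient TC(a, b) = |A<sub>a</sub> ∩ A<sub>b</sub>| / |A<sub>a</sub> ∪
A<sub>b</sub>|.  The screening hypothesis is guilt-by-association at the
profile level: if two compounds share most of their targets, each is a
candidate for the other's remaining targets.  Every compound–target
combination (c, t) is therefore scored by the maximum TC between *c* and
the known binders of *t*, excluding *c* itself; the maximizing binder is
reported as the reference compound.  The score carries no potency
information — it ranks hypotheses for experimental follow-up, nothing more.

The method assumes compounds cluster into pharmacological families with
heavily overlapping profiles, and that profiles are dense enough to make
the Tanimoto ratio informative.  The curation floor (≥ 15 distinct targets
per compound) exists to enforce the second assumption.

## Curation rules and their parameters

| parameter | default | meaning |
|---|---|---|
| `potency_ceiling_nM` | 50,000 | records whose potency is established as ">"/">=" at or above this, or measured above it, are rejected |
| `min_targets_per_compound` | 15 | compounds with fewer distinct curated targets are dropped |
| `allowed_target_types` | {SINGLE PROTEIN} | everything else is rejected (`TARGET_TYPE`) |
| `excluded_comments` | not active, not determined, not soluble, potential missing data | case-insensitive substring match on the activity comment |
| `inactive_comments` | not active | excluded records matching these become *known inactives* |

Design choices in the gaps the rules leave open:

- **Assay clustering.** Different assays measuring one (compound, target)
  pair collapse to one record per activity class (active-like vs
  explicitly inactive), concatenating assay/organism provenance.
  Deduplication is subsumed by clustering.
- **Conflicting evidence.** A pair with both active and inactive evidence
  is kept as positive; the inactive claim is dropped and logged.  The same
  principle applies within potency evidence: the strongest (lowest nM)
  measurement represents the collapsed record, so one good measurement
  keeps a pair even if another assay found it weak.  A pair whose *only*
  evidence violates the ceiling is rejected.
- **Units.** Only nM values are compared to the ceiling; any other unit is
  rejected (`UNIT_UNSUPPORTED`) rather than silently converted.
- **Ceiling on measured values.** Rejecting measured ("=") values above
  the ceiling, not only ">"-relations, keeps the standard internally
  consistent; `reject_measured_above_ceiling=False` restores the narrower
  rule.
- **Determinism.** All universes and output files are sorted
  lexicographically; re-runs are byte-identical.

## Numerical choices

TC values are exact `Fraction`s; threshold comparisons (`tc >= min_tc`)
are exact rational comparisons, so there are no float-boundary artifacts
at thresholds like 0.5.  Floats appear only in reports, rendered to six
decimals.  The all-pairs search prunes with an inverted index over targets
(pairs with tc > 0 must share a target) and the cardinality bound
tc ≤ min(|A|,|B|)/max(|A|,|B|); both prunes are lossless and the output is
contractually identical to the naive double loop (property-tested on
randomized instances).  Ties in the reference-compound argmax break to the
lexicographically smallest compound id.  Candidates below the
materialization floor (`min_tc`, default 0.5) are not stored; the
evaluator treats every unscored combination as predicted-negative and
refuses thresholds below the floor, where counts would be wrong.

## Evaluation

The evaluation universe is all compound × target combinations of the
standard, minus known-inactive pairs (they form their own candidate class;
`count_known_inactives_as_negatives=True` restores them as negatives).
Sensitivity = tp/(tp+fn), specificity = tn/(tn+fp), precision = tp/(tp+fp)
(0, flagged, when nothing is predicted), and the enrichment factor is
precision divided by the positive base rate of the universe, so the
all-inclusive threshold yields EF = 1 exactly.

**Hold-out.** Positive pairs are split uniformly at random at the pair
level (compound-level splitting is an option); profiles and scores are
rebuilt from training pairs only, with the minimum-target filter
re-applied.  The ranked prediction list excludes known training positives
— they are inputs, not predictions; including them makes the comparison of
training fractions misleading, because richer training fills the top ranks
with its own knowns.  Sensitivity at rank N is reported with two
denominators: scoreable test pairs (compound and target survive in the
training universe) and all test pairs; unscoreable pairs are counted
separately rather than silently as misses.  Specificity is computed over
training-universe combinations that are neither training positives nor
held-out positives.  Rank thresholds are supplied by the caller and should
be scaled to the universe at hand.

**Fisher exact test.** Two-sided by the minimum-likelihood convention: the
p-value sums the hypergeometric probabilities of all tables with the
observed margins that are no more probable than the observed table,
computed from exact integer binomial coefficients with a 1e-7 relative
slack on the probability comparison to protect ties.  A one-sided variant
is not exposed; the package performs a single planned comparison.

## Synthetic data

The generator emulates the one structural feature the method needs:
pharmacological families.  Each family owns a disjoint block of targets
(`targets_per_family`); each compound carries a `within_family_share`
fraction of its block (default 0.9 of 20) plus out-of-family interactions
drawn per compound–target at probability `cross_family_noise` (default
0.02).  Defaults give 4 families × 10 compounds — a small matrix whose
compounds clear the 15-target floor.  Decorations wrap the clean pairs in
raw-record pathologies (inactive comments, above-ceiling potencies,
protein-complex targets, duplicate assays), each tied to exactly one
intended curation outcome so the rule coverage is a checkable bijection.

Masking removes chosen positives from the emitted records while keeping
them in the truth object.  At most one pair is masked per compound, which
keeps the noiseless identical-profile expectation in closed form: the
masked compound retains m−1 of the family's m targets, a fully profiled
family binder gives TC = (m−1)/m, and that is the maximum (when every
intact binder is itself masked elsewhere the form degrades to (m−2)/m,
which the truth also records).  With share < 1 or noise > 0 no closed form
is attempted; recovery is then a statistical property checked over seeds.

Hold-out experiments use richer profiles (30-target blocks, share 0.95)
so compounds survive the 15-target floor after a 60/40 split; with
20-target blocks most compounds drop out of the training matrix at 60%
training and the experiment degenerates.  What passing on synthetic data
does *not* show: real bioactivity data has correlated assay noise,
promiscuity ranging over orders of magnitude, target families with shared
ligands across "families", and annotation biases — none of which the
generator emulates.  Results here validate the machinery, not the
biological error rate.

## Problem sizes

Tests and the acceptance script run on matrices up to ~150 compounds ×
~120 targets, 25 randomized oracle-equivalence instances, and 20-seed
hold-out repetitions — sizes chosen so exhaustive brute-force oracles
(O(n²) pair loops, full-universe confusion labeling, complete contingency
enumeration) remain exact and fast.

## Known limitations

- Similarity is purely profile-based; a compound outside every family, or
  below the target floor, cannot be scored.
- The score is not calibrated to potency or probability; thresholds are
  operating points, not significance levels.
- Known-inactive handling assumes explicit "not active" annotations are
  reliable; a noisy annotation becomes a permanent exclusion from the
  negative universe (default) or a hard negative (flag).
- Target identity is exact-string; orthologs and protein complexes are not
  merged.
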