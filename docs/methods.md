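# Methods

## Data model

A sample is an AU combination (FACS notation, e.g. `1+4+25`, optionally
with `L`/`R` laterality prefixes and A–E intensity suffixes) plus an
emotion score vector over the six basic emotions — happiness, surprise,
anger, fear, disgust, sadness, in that fixed canonical order — and neutral.
Scores are vote proportions of independent raters, so each lies in [0, 1]
and the vector sums to at most 1 (sums below 1 are allowed, since raters
can be excluded; sums above 1 + 1e-6 are rejected). AU equality is by
number alone: intensity and laterality are carried as metadata because the
downstream analyses never use them.

## Contribution scoring

Two accumulation schemes turn a record collection into an emotion × AU
contribution matrix.

*Max/dedup.* Each record's emotion E is the argmax of its six basic scores
(neutral never competes; exact ties break by the canonical emotion order
and are logged). Only the first occurrence of each (canonical AU
combination string, E) pair contributes — the deduplication key is the full
combination, not individual AUs — and what is added to every AU of the
combination is score(E), the single max emotion's score. Rows are finally
normalized to sum to 1, so entries are within-emotion proportions. Records
whose basic scores are all zero (fully neutral crowds) are skipped with a
warning rather than failing the run.

*Weighted sum.* Every record adds score(e) to C[e][au] for each AU it
contains and every basic emotion e, with no deduplication and no
normalization; repeated sample types therefore weigh in proportion to their
frequency. An optional row-normalized variant is provided for comparison,
but the raw sums are the definition; the two differ only by a per-row
scale, so rankings are identical.

The matrix is stored sparsely over AUs actually observed — a dense
6 × max-AU array would add nothing. Top-k ranking sorts each row descending
by score with ties broken by ascending AU number, giving deterministic
tables.

## Exclusive-AU derivation

From the per-emotion association sets S₁…S₆ the exclusive set of emotion i
is Qᵢ = Sᵢ \ ⋃_{j≠i} Sⱼ, i.e. the AUs appearing in exactly one emotion's
set. The set difference `\` is asymmetric (elements of the left set not in
the right). An alternative "literal" form subtracting the *intersection* of
the other five sets is kept behind `literal=True` for auditability: on the
built-in table that intersection is empty for every emotion, so the literal
form degenerates to Qᵢ = Sᵢ and has no discriminating power — which is why
the union form is the operative definition. On the built-in table the
derivation yields happiness {6, 12, 28}, surprise {2}, anger {16, 22, 23},
fear {20}, disgust {7, 24}, sadness {43} — eleven exclusive AUs in total.

## Rule-based coding

The coder is categorical: a rule fires when its required AUs are all
present, and the first firing rule (by priority) decides. Priorities encode
specificity:

1. *Conflict guard* (before any rule): if exclusive AUs of two or more
   different emotions are present simultaneously, the evidence is
   contradictory and the sample is coded `other` with the conflicting
   emotions reported.
2. *Exclusive-AU rules*: any single exclusive AU codes its emotion
   (12, 6, 28 → happiness; 2 → surprise; 16, 22, 23 → anger; 20 → fear;
   7, 24 → disgust; 43 → sadness).
3. *Combination rules*, larger patterns first: AU1+4+5+25 → fear, then
   AU4+5 → sadness. Ordering by pattern size prevents the sadness pair from
   shadowing the fear quadruple.
4. *Generic valence rule*: AU4 (frown) alone signals a negative emotion
   without identifying which; it codes as `other` with a `negative` valence
   annotation rather than inventing a specific emotion.

If nothing fires the label is `other`, so the coder is total over non-empty
AU sets and always returns one of the seven non-neutral labels. A known
quirk of the rule base is inherited as printed: AU4+AU5 codes sadness even
though AU5 belongs to the surprise/anger/fear association sets and the
sadness set lacks it; we implement the rule as stated and document rather
than resolve the inconsistency. The rule base is serializable as JSON
(`{aus, outcome, priority, description, valence?}`) with unique priorities
enforced on load.

Emotion labels map onto four micro-expression classes: happiness →
positive; disgust, sadness, fear, anger → negative; surprise → surprise
(interpretable only from context, so tied to neither valence); neutral and
other → other.

## Anatomy metadata

Each AU of the association table carries the muscles that produce it, one
of the five facial-nerve (CN VII) branches — temporal, zygomatic, buccal,
marginal mandibular, cervical — and a face region (upper/mid/lower). Three
entries are deliberate approximations: upper-lid raising (AU5) involves the
levator palpebrae superioris (oculomotor) and jaw movements (AU26, AU27)
involve trigeminal-innervated muscles, but the table records the CN VII
branch of the surrounding facial territory because its purpose is to tell a
coder where on the face to look, not to be an innervation atlas. Unknown
AUs raise a lookup error rather than guessing. The valence→focus-region
guidance follows the muscle physiology: positive expressions ride on
zygomaticus activity (watch the mid-face and mouth), negative ones on
corrugator activity (watch the brows and forehead).

## Reliability

For N ≥ 2 coders with label sets C₁…C_N, R = N·|⋂Cᵢ|/|⋃Cᵢ|. R is N exactly
when all sets are equal and non-empty, 0 exactly when no label is common to
all, and is invariant to coder order. Because the raw statistic's range
grows with N, the normalized R/N ∈ [0, 1] is always reported alongside; no
acceptance threshold is built in. All-empty panels leave 0/0 undefined and
are rejected. Set elements are opaque strings, so the same statistic serves
emotion labels or AU numbers; the pooled report concatenates each coder's
(sample, label) pairs so that identical labels on different samples stay
distinct. No chance correction (kappa, alpha) is attempted — the statistic
is intersection-over-union by construction.

## Temporal coding

An episode is onset ≤ apex ≤ offset frame indices (0-based) at fps > 0.
Duration is (offset − onset)/fps; the apex marks peak intensity and plays
no part in duration. The micro-expression band is [1/25, 1/5] s with both
boundaries inclusive (the band is stated without boundary semantics
anywhere authoritative; inclusive is the choice least likely to drop true
boundary cases, and a 1e-12 epsilon absorbs float noise at the edges). The
micro/macro decision is invariant to scaling frames and fps by a common
factor.

## Synthetic data generator

The generator emulates a crowdsourced in-the-wild AU database: per sample a
latent true emotion is drawn from the prior (uniform over the six basic
emotions by default); the AU set keeps each of the true emotion's
association AUs with probability `emission_rate` (at least one forced, so
records are never empty) and adds each AU from the 1–30 noise pool with
probability `noise_au_rate`; rater votes over the seven labels are a single
multinomial draw — probability `rater_accuracy` on the true emotion, the
remainder uniform over the other six labels including neutral — which is
equivalent to `n_raters` independent categorical raters. Defaults
(n_raters = 40, rater_accuracy = 0.9, emission_rate = 0.9,
noise_au_rate = 0.05) are the emulated study conditions: a ~40-rater crowd
with high but imperfect agreement and sparse spurious AUs. One explicit
`numpy` Generator per dataset; a fixed seed gives bit-identical output.

What the generator does *not* model: real AU co-occurrence structure
(independent emissions are a stand-in for unknown combination
frequencies), rater confusion structure (errors are uniform, real raters
confuse specific emotion pairs), intensity/laterality, and sample
imbalance. Passing structure-recovery tests therefore show the algorithms
recover planted structure under these idealized conditions, not performance
on real crowdsourced data. The noise pool stops at AU30 so AU43 (sadness)
can only arrive via true emission — mirroring that the high AU numbers are
rare outside their emotion.

The coder-panel generator labels each sample with the true emotion with
probability `coder_accuracy`, else one of the other six labels uniformly;
for two single-label coders the per-sample agreement probability is
p² + (1−p)²/6, which the reliability analysis checks to three standard
errors.

## Problem sizes and numerics

The analysis drivers and end-to-end tests use 2,000 samples × 40 raters
(structure recovery over five seeds, requiring ≥ 4/5 full recoveries — a
deliberately strict bar that the default conditions meet with margin) and
500 samples for the reliability expectation check; oracle-equivalence
checks run on ≤ 50-record datasets against naive brute-force
reimplementations kept independent of the library code. Row sums are
checked to 1e-9; ranked scores print to 4 decimals; weighted sums are
compared to the oracle exactly (identical accumulation order per row makes
float equality attainable at these sizes).

## Known limitations

- The contribution algorithms summarize, they do not test: no statistical
  inference on contribution differences is provided.
- The rule coder has no soft/probabilistic output and ignores AU intensity.
- The exclusive-AU derivation depends entirely on the association table;
  a different table changes every downstream exclusive-AU behavior.
- Reliability is raw intersection-over-union agreement without chance
  correction, so it is optimistic for small label vocabularies.
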