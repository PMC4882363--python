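# Methods

## Model

`toxbasket` casts qualitative structure–activity modeling as market-basket
analysis. A chemical is a transaction; its items are (i) the set of
atom-pair substructure features it exhibits and (ii) exactly one hazard
label derived from its 96-h fathead minnow LC50 via the GHS acute aquatic
bands (CAT1 ≤ 1 mg/L < CAT2 ≤ 10 < CAT3 ≤ 100 < CAT4). Apriori enumerates
all frequent itemsets and emits rules with a single category consequent and
a feature-only antecedent. Confidence — the conditional probability of the
category given the substructures — is the primary statistic; lift measures
enrichment over the category's base rate; support measures coverage and is
deliberately secondary (rare rules can be the most informative).

Assumptions worth stating explicitly:

- presence/absence semantics: a feature occurring five times in a molecule
  counts once, as in a shopper's basket;
- category labels are error-free discretizations of a single LC50 per
  chemical (no inter-laboratory variability model);
- rules are correlational. A toxicophore here is "a minimal substructure
  combination statistically aligned with a hazard band in this dataset",
  not a mechanistic claim.

## Atom-pair features

An atom descriptor is (element, heavy-neighbor count, π-electron count),
with π electrons counted as

    min(2, #double bonds + 2·#triple bonds + [atom is aromatic])

so an aromatic ring carbon has 1, a carbonyl or nitro oxygen 1, a nitrile
nitrogen 2. A feature is an unordered pair of descriptors plus the
shortest-path bond distance between the atoms (1 ≤ d ≤ `max_distance`,
default 15 — generous relative to the ≤ 6-bond alerts that typically
matter, while bounding the feature count). Hydrogens are excluded
throughout; nitro groups are normalized to the charge-separated form during
sanitization so both common spellings fingerprint identically; for
disconnected inputs (salts) only the largest fragment is kept, ties going
to the fragment written first.

The feature universe is the set of atom pairs observed in the training
data, not an external dictionary: any fixed dictionary would immediately be
filtered to the observed pairs anyway, and the dataset-derived universe
keeps the encoding self-contained. Features serialize as human-readable
strings (`C [2 neighbor(s),1 pi electrons] <-3-> C [...]`), which are also
the canonical sort keys; no integer bit encoding is used or reproduced.

## Mining

The Apriori implementation is level-wise with the classic join (two
frequent (k−1)-itemsets sharing a (k−2)-prefix), which by downward closure
generates every frequent k-itemset exactly once. Internally items are
re-indexed and transaction covers are integer bitmasks, so candidate
support is a bitwise AND plus popcount; this keeps dense chemical baskets
(dozens of shared features per molecule) tractable. All supports,
confidences and lifts are exact `Fraction`s over the transaction count;
floats appear only at the reporting surface. This makes two things exact by
construction: the miner-vs-enumeration equivalence checks, and the
equal-statistics test used by rule minimization.

Defaults: `min_support = 0.05` (an itemset must occur in ≥ 3 of 60
chemicals — small enough to admit rules covering ~10 % of a dataset),
`min_confidence = 0.75`, `max_len = 5` (itemset size, i.e. at most four
antecedent items plus the category). The confidence filter is applied after
rule formation; pre- and post-filtering yield identical rule sets, so the
simpler post-filter is used.

**Toxicophore minimization.** If a rule's antecedent is a superset of
another rule's with the same consequent and *identical* support, confidence
and lift, the extra items add no information; `minimize_rule` returns the
smallest such sub-rule (ties broken lexicographically). Because equality is
tested on exact rationals, the operation is deterministic and idempotent.

**Ordering.** Rules are ranked by lift (descending), then confidence, then
antecedent size, then lexicographic rendering — a total order, so mined
output is byte-stable across runs.

## Prediction

A query chemical is classified by the matching rule (antecedent ⊆
fingerprint) with the highest confidence; ties break by higher lift, then
by the more hazardous category (a conservative bias fixed here because the
statistics alone leave the choice open), then by the total rule order.
Chemicals with no matching rule receive the *rule-predicted* category of
their Tanimoto-nearest training neighbor, skipping neighbors that have no
rule prediction themselves — the surrogate consumes model predictions, not
ground-truth labels, so it cannot leak labels at evaluation time. Nearest
neighbors tie-break by larger fingerprint intersection, then lexicographic
id. Queries with empty fingerprints (single heavy atoms) are
"unclassifiable", as Tanimoto similarity is undefined for two empty sets.

`MarketBasketGHSClassifier` wraps the pipeline as a scikit-learn estimator
(`fit(smiles, y)` where `y` is categories or raw LC50 values, `predict`,
`get_params`/`set_params`, `classes_`, clone-compatible), so it composes
with sklearn model selection; `predict_detail` exposes the evidence (rule
or neighbor) per query.

## Evaluation

Cross-validation is stratified k-fold (default k = 5) with a fixed seed;
stratification stabilizes fold composition when categories are skewed, and
the splitter falls back to plain k-fold when a class has fewer members than
folds (e.g. leave-one-out). Rules are re-mined per fold on training
chemicals only. The default fold rate counts only rule-classified
chemicals — the model abstains on the rest — with a flag to include
surrogate predictions; the denominator policy is recorded in the result.
The summary rate is the unweighted mean of per-fold rates. Confusion
matrices are 4×4 (truth × predicted) with an explicit "unclassified" spill
column so no chemical is silently dropped.

## Synthetic data

The generator emulates a small munitions-flavored screening table: 60
chemicals by default, mixed 10/30/40/20 % across CAT1–4 (most chemicals in
CAT3, then CAT2 — the typical skew of such datasets), each built as
`decoration + scaffold + fragment` from a fixed library of 16 small
scaffolds (benzene, pyridine, pyrimidine, pyrrole, furan, thiophene,
oxazole and friends alternating with cycloalkanes, cyclic and acyclic
ethers). The fragment is the category's planted motif with probability
`fidelity` (default 0.9) and a small decoy otherwise. Default motifs are
chemically distinctive so their internal atom pairs cannot arise elsewhere:
dichloromethyl (CAT1), nitro (CAT2), nitrile (CAT3), difluoromethyl (CAT4).
LC50 values are log-uniform inside the assigned category's band and
re-discretize to it exactly. Category counts use largest-remainder
rounding; everything is deterministic given the seed, down to byte-identical
CSV output.

Two structural choices matter for what the generator can certify:

- **Contexts align across categories.** The (scaffold, decoration,
  attachment side) context of a category's j-th chemical depends only on j,
  so the same context sequence recurs in every category. Any
  substructure combination not derived from a motif therefore spans
  categories and cannot reach high confidence for a single one; only
  motif-derived atom pairs can. This is what makes "the minimal antecedent
  of the top rule consists of motif-derived pairs" a provable property
  rather than a tendency.
- **Contexts diversify within categories.** Scaffold and decoration cycles
  are staggered (coprime periods, alternating aromatic/aliphatic blocks,
  alternating attachment side), so near-duplicate molecules never recur
  often enough to reach the support floor, keeping the frequent-itemset
  lattice tractable (~10⁵ itemsets at the defaults rather than ~10⁶ for a
  naive library).

The planted-motif table reported with each dataset is computed
operationally: per category, the union over its chemicals of
fingerprint(with motif) − fingerprint(without), i.e. every atom pair the
motif actually introduces, including motif–scaffold cross pairs.

What the generator does *not* emulate: real chemical diversity (its
scaffolds are a closed library), activity cliffs, measurement noise in
LC50s, correlated motifs, or categories defined by anything other than a
planted fragment. A perfect cross-validation rate on fidelity-1.0 data
therefore certifies the pipeline's correctness — mining, matching,
fold hygiene — not real-world predictive performance, which on actual
screening data is bounded by the weaker structure–category association
found there.

## Numerical and design notes

- The GHS boundary value 1.0 mg/L is assigned to CAT1 (official GHS uses
  "≤ 1"; the more hazardous assignment also closes the band gap left by a
  strict-inequality reading). 10 and 100 close CAT2 and CAT3 likewise.
  Units are fixed at mg/L; no auto-conversion.
- Exact rational arithmetic makes the rule-statistic identities
  (confidence = supp(lhs ∪ rhs)/supp(lhs), lift = confidence/supp(rhs))
  hold to machine identity, tested to 1e-12 after float conversion.
- Rule sets serialize to JSON with both float and exact-fraction fields, so
  a round trip is lossless.
- Problem sizes used by the test suite and the acceptance script: 60
  synthetic chemicals, fivefold CV, 100 random transaction sets of ≤ 12
  transactions × ≤ 10 items for the enumeration cross-check, 10 seeds for
  the fidelity-0.9 recovery sweep — sizes chosen to exercise every code
  path at full defaults while staying quick on a single CPU.

## Limitations

- Coarse descriptors: (element, degree, π) cannot distinguish, e.g., an
  alcohol oxygen from a nitro O⁻; structurally distinct groups can share
  features. This is inherent to the representation, not a bug — but it is
  the main reason rule antecedents need several pairs to be specific.
- Categories with few chemicals rarely clear the confidence filter; on
  skewed real datasets the model typically cannot predict the extreme bands
  at all, and the surrogate inherits that gap (it can only relay rule
  predictions).
- The miner enumerates the full frequent lattice; pathological datasets
  (many near-duplicate structures above the support floor) can still blow
  up combinatorially. Raising `min_support` or `min_feature_count`, or
  lowering `max_len`, bounds the lattice.
- Single-label, single-endpoint: one LC50 per chemical, one species, acute
  exposure only.
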