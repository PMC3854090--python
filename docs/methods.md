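# Methods

## The fingerprint-pair model

`fppairs` analyses structure–activity tables — here motivated by hERG
potassium-channel inhibition, where IC50s come from a dofetilide
radioligand-displacement assay with a 30 μM ceiling — by treating every
ordered pair of compounds as a *transformation* and asking which
transformations shift potency consistently.

A molecule is represented as a counted multiset of circular
(Morgan/ECFP-style) features: one hashed feature per atom-centred
substructure of every even diameter up to `N` bonds (`ECFP-N`). The
transformation between molecules *A* and *B* is the **difference
fingerprint**

    removed = features(A) − features(B)    (multiset difference)
    added   = features(B) − features(A)

Features present with equal counts in both molecules cancel, so the key
captures the changed atoms *plus their local context* out to radius
`N/2`. Two compound pairs make the same transformation **iff** their
difference fingerprints are equal; that equality is the aggregation
relation. In contrast to matched-molecular-pair schemes, no bond
cleavage or attachment-point convention is required, and context is
implicit in the key.

Each aggregate of pairs sharing one key is summarised by:

* `n`, `n_increase`, `n_decrease`, `n_tie` — direction counts of
  Δlog10 IC50 = log10 IC50(final) − log10 IC50(initial) (μM scale;
  positive = weaker inhibition);
* the geometric-mean fold change `10^|mean Δlog10 IC50|` (the
  exponentiated arithmetic mean of logs);
* exact sign-test and exact Wilcoxon signed-rank p-values under the
  null that a pair is equally likely to move either way;
* ΔSlogP, the Wildman–Crippen logP change, constant across an
  aggregate because the model is atom-typed and additive.

Because every unordered pair is enumerated in both directions, each
transformation exists together with its mirror image; reports keep the
canonical orientation (mean Δlog ≤ 0, i.e. the inhibition-reducing
direction), with an exact-zero mean broken lexicographically on the
serialized key so runs are deterministic.

## Exact small-sample statistics

Aggregates are small (most are singletons; the size distribution is
heavy-tailed, roughly power-law), so both tests use exact null
distributions rather than asymptotics:

* **Sign test.** With ties removed, the two-sided p-value is the
  binomial(n, ½) probability of a split at least as extreme as
  observed, doubled and capped at 1. Five concordant pairs give
  2·(½)^5 = 6.25%, which is why the default reporting threshold is
  `min_examples = 5` — below that no direction pattern can look
  unusual.
* **Wilcoxon signed-rank.** Absolute differences are ranked (average
  ranks on ties, made integral by doubling), and the tail of the
  smaller signed-rank sum is counted by dynamic programming over rank
  subsets — arithmetically identical to enumerating all 2^n sign
  assignments. For n = 8 with one discordant pair of rank 4 the
  two-sided tail is 14/256 ≈ 5.47%. Above `EXACT_ENUMERATION_LIMIT`
  (20) observations a tie-corrected, continuity-corrected normal
  approximation takes over with a logged notice; aggregates that large
  are rare and far beyond the regime where exactness matters.

No multiple-testing correction is applied by default: p-values are
reported per aggregate, and filtering is on aggregate size (`n ≥ 5`),
with an optional `alpha` cut.

## Censoring

Off-scale measurements (`">30"` μM, or nM equivalents) are clamped to
the assay ceiling and flagged. A pair in which **both** values are
censored in the same direction carries no information about the
difference and is excluded; a pair with one censored member is kept at
the clamped value, which biases its |Δlog| toward zero —
conservative for detecting consistent effects. Lower censoring (`"<"`)
is accepted and, by default, not clamped (no lower limit is configured
out of the box). Replicate measurements of one compound are collapsed
by the geometric mean of the clamped values (configurable to `first`
or `error`), since the analysis lives on the log scale.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `diameter` | 6 | max feature diameter in bonds (`ECFP-6`). Diameter 0 is equivalent to the molecular formula and 2 is scarcely better — both merge chemically different transformations; 4 still conflates some; 6 makes aggregates correspond to one chemical change at the cost of spreading data over more aggregates. |
| `upper_limit_um` | 30 μM | assay ceiling for clamping and censoring. |
| `min_examples` | 5 | smallest aggregate reported; below 5 even a unanimous direction pattern exceeds the conventional 5% level. |
| `max_changed_features` | unlimited | optional cap on the total count of changed feature occurrences, to restrict to small transformations. |
| `alpha` | none | optional p-value filter (sign, signed-rank, or both). |

Feature hashes come from RDKit's Morgan generator. Hash values are
toolkit-specific; the analysis depends only on within-run key
equality, never on particular bit values, and reports carry a
feature-id → environment-SMILES legend so keys are human-readable.
Stereochemistry is ignored in atom invariants by default
(configurable). Standardization keeps the largest covalent fragment
(salt stripping) and preserves charges; no tautomer canonicalization
is attempted.

## Synthetic data generator

Real hERG archives are proprietary, so the generator builds congeneric
series: scaffolds sharing a ≥6-bond stalk around a single attachment
point, crossed with a substituent panel. log10 IC50 = base + scaffold
offset + substituent effect + N(0, noise_sd); values above the ceiling
are written as `">30"` strings. Because the stalk exceeds the
fingerprint radius context, the same substituent swap yields the
identical difference fingerprint on every scaffold, so the planted
additive shift (difference of substituent effects) is exactly what the
corresponding aggregate should estimate. Per-substituent effects (not
per-swap) guarantee all swap effects are mutually consistent.

Defaults: 10 scaffolds × 6 substituents; base log10 IC50 = 0.5 (~3 μM,
mid-range for a lead-optimization series flagged for hERG risk);
scaffold offsets SD 0.3; measurement noise SD 0.2 log units (typical
assay reproducibility); planted substituent effects between −0.2 and
+0.7 log units, matching the few-fold shifts consistent transformations
show in practice.

What the generator does *not* emulate: structural diversity beyond one
attachment point, correlated assay drift, ionization/pKa effects on
both potency and logP, and transformations whose effect depends on
context (an optional interaction hook exists but is off by default).
Passing recovery tests therefore demonstrate the pipeline's
correctness and calibration, not predictive validity on real
chemistry.

Cross-scaffold pairs (different decorations and/or different
substituents) still form valid transformations; decoration-change
aggregates inherit the scaffold-offset difference as their true
effect, and mixed swaps are singletons. The aggregate-size histogram
of the default fixture accordingly has its mode at 1, echoing the
heavy-tailed size distribution seen in real archives.

## Numerical choices and degenerate inputs

* Zero Δlog ties count toward aggregate membership but are removed
  before both tests (standard practice); an all-tie aggregate reports
  p = 1 with a warning.
* The signed-rank DP doubles ranks so average ranks stay integral; the
  two-sided p is min(1, 2 × lower tail of the smaller rank sum),
  matching exact-mode convention in standard software.
* Identical molecules (empty difference fingerprint) form no pair;
  fewer than two records yields an empty pair list with a warning, not
  an error.
* Geometric means of IC50s are computed in log space; `%.10g`
  serialization keeps table round-trips lossless at float precision.
* ΔSlogP should be bitwise-constant within an aggregate; a spread
  beyond 1e-6 logs a warning naming the key rather than failing the
  run (it would indicate atom-typing sensitivity to remote context).

## Known limitations

* Wildman–Crippen implementations disagree on some nitrogen/hydrogen
  atom types: RDKit and Open Babel differ by up to ~1 logP unit on
  primary/secondary amines (agreement is to printed precision
  elsewhere). Absolute SlogP values therefore depend on the toolkit;
  ΔSlogP within an aggregate does not.
* Feature-hash collisions are possible in principle (32-bit Morgan
  space); a collision scan over the test corpus finds none, and a
  collision would merge two transformations rather than corrupt
  statistics.
* All-pairs enumeration is O(n²) in compounds; the optional
  changed-feature cap and series restriction are the intended levers
  for large tables.
* The exact tests assume exchangeable pair directions under the null;
  pairs sharing a compound are not independent, so aggregate p-values
  are per-transformation descriptions, not family-wise statements.

## Problem sizes used in the checks

The bundled suites run on generated fixtures sized for a desk machine:
the standard fixture is 10 scaffolds × 6 substituents (60 molecules,
~1,770 unordered pairs), recovery calibration uses 200 replicates of
an 8-series two-substituent design, and the null calibration uses 500
replicates of a 5-scaffold × 4-substituent design (3,000 size-5 null
aggregates), which bounds the binomial sampling error of the 6.25%
all-one-direction rate below half a percentage point.
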