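# fppairs — fingerprint-pair analysis of structure–activity data

`fppairs` finds chemical transformations that consistently change a
measured potency. It was built for hERG potassium-channel inhibition
data (dofetilide-displacement IC50s with a 30 μM assay ceiling), where
medicinal chemists want to know which small structural changes
reliably *reduce* channel binding during lead optimization — but it
works on any molecule/IC50 table.

## The method

Every compound is fingerprinted as a counted multiset of circular
(Morgan/ECFP) features up to diameter *N* bonds (default ECFP-6). An
ordered pair of compounds *A* → *B* defines a transformation by its
**difference fingerprint**: the features that disappear from *A* and
the features that appear in *B* (features with equal counts in both
cancel). Pairs are aggregated **iff** their difference fingerprints are
identical, so a transformation carries its local chemical context
implicitly — no pre-specified transformation list and no
attachment-point convention, unlike classical matched molecular pairs.

For each aggregate the package reports

* Δlog₁₀ IC50 direction counts (`n_increase` / `n_decrease`, positive
  Δ = weaker inhibition),
* the geometric-mean fold change `10^|mean Δlog₁₀ IC50|`,
* **exact** sign-test and Wilcoxon signed-rank p-values (full
  enumeration of the 2ⁿ sign assignments — under the null, five
  concordant pairs occur 6.25% of the time, which motivates the
  default `n ≥ 5` reporting threshold),
* ΔSlogP, the Wildman–Crippen lipophilicity change, constant within
  an aggregate by construction.

Censored measurements (`">30"`) are clamped to the ceiling; pairs
censored in the same direction on both sides are excluded. Every
transformation also exists in reverse; reports keep the
inhibition-reducing orientation.

## Worked example

Real hERG archives are proprietary, so the bundled generator emulates
one: congeneric series (10 scaffolds sharing an attachment stalk × 6
substituents) with planted additive log-IC50 effects, assay noise, and
30 μM censoring.

```bash
fppairs simulate --seed 7 --out herg_synthetic.csv
fppairs run --input herg_synthetic.csv --out results --min-examples 5
```

prints

```json
{
  "n_molecules": 60,
  "n_ordered_pairs": 3538,
  "n_aggregates": 1410,
  "n_singletons": 1350,
  "n_significant": 60,
  "diameter": 6,
  "min_examples": 5
}
```

60 molecules give 1,769 usable unordered pairs (one pair of `">30"`
values is excluded) and 1,410 transformations, of which 1,350 occur
once — the heavy-tailed, roughly power-law size distribution written
to `results/size_histogram.tsv`. The 60 aggregates with ≥ 5 examples
land in `results/aggregates.tsv`, sorted by fold reduction; the top
row of the `--seed 7` run is the planted hydroxyl→ethyl substituent
swap (planted shift 0.9 log units, i.e. 10^0.9 ≈ 7.9-fold):

```
 n  n_increase  n_decrease  fold_reduction  p_sign    delta_slogp
10           0          10         9.37     0.001953  1.81
```

read as: in all 10 pairs making this transformation the IC50 moved the
same way, a 9.4-fold mean reduction in hERG inhibition (the planted
7.9-fold, within noise), with exact sign-test p = 2/2¹⁰ and a +1.81
increase in SlogP. `removed_envs`/`added_envs` columns give the
changed atom environments as SMILES via `results/feature_legend.tsv`.
`results/slogp_vs_delta.tsv` exports the ΔSlogP-versus-effect scatter
data.

The exact-test calculator is exposed directly:

```bash
$ fppairs stats --n-up 0 --n-down 5 --test sign --sided two
0.0625
```

See `docs/methods.md` for the model, defaults, and limitations.

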