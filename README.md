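# fmskit

Supervised dimensionality reduction for sparse, redundant relative-abundance
tables — the kind produced by 16S rRNA microbiome surveys, where a handful of
taxa discriminate disease states, many taxa are strongly correlated with each
other, and most entries are zero.

Classical feature *selection* ranks taxa one by one and discards the
relationships between them; classical feature *transformation* (LDA, PCA)
mixes every taxon into every output dimension and is hard to interpret.
`fmskit` implements **feature merging and selection (FMS)**, which sits
between the two: correlated discriminative taxa are greedily merged into
weighted linear combinations, uninformative taxa are deleted, and every
surviving taxon belongs to exactly one combination.

## The algorithm

For a single (possibly combined) feature *x* with class labels, the
discrimination score is the one-way ANOVA **Fisher statistic**

    F(x) = [ Σₖ nₖ(mₖ − m)² / (K−1) ] / [ Σₖ (nₖ−1)σₖ² / (n−K) ]

with K classes of sizes nₖ, class means mₖ, grand mean m.  For a feature
pair (xᵢ, xⱼ), a 2-D linear discriminant analysis — with the within-class
scatter matrix repaired by repeatedly adding a small multiple of the
identity whenever it is singular — yields the best linear combination
a·xᵢ + b·xⱼ and its score F_new.  The pair chosen for merging maximizes the
**merging value**

    F_new · |r(xᵢ, xⱼ)| / √(F(xᵢ) · F(xⱼ))

where r is the Pearson correlation: merge what is *both* discriminative
after combination *and* redundant.  Weights propagate through successive
merges and are re-estimated per combination by LDA once merging stops.
Features are then ranked by |weight| × combination Fisher score (or by
mutual information with the class on noisy data, flagged when the best
feature carries < 0.03 bits) and deleted one by one.  Both the merge degree
and the deletion count are chosen by proportional (stratified) 5-fold
cross-validation of a plug-in classifier — an RBF-kernel SVM or a
distance-weighted kNN, composed into a two-stage cascade for three-class
problems or a cluster-and-vote scheme for imbalanced two-class problems —
scored by the mean per-class error rate.

## Worked example

Simulate a small two-class cohort (8 informative taxa in two correlated
blocks, 32 sparse noise taxa), then fit:

```sh
fmskit simulate --n-per-class 30,30 --n-features 40 --n-informative 8 \
    --groups 4:0.95,4:0.9 --sparsity 0.6 --effect-size 1.5 --seed 2 \
    --outdir demo
fmskit fit --table demo/table.tsv --labels demo/labels.tsv \
    --classifier svm --seed 1 --outdir demo/fit
```

The log reports what was decided and why:

```
fmskit: noisy branch: False | merge degree 5 | deletions 17 | dimension 18 | features 23
```

Cross-validation chose 5 merges and 17 deletions: of 40 taxa (35 after
zero-variance removal), 23 survive inside 18 combinations — deletion mostly
removed sparse noise taxa.  `demo/fit/combinations.tsv` lists combinations
sorted by Fisher score, best discriminators first:

```
combination	fisher	members	weights
FMS_comb_15	56.5842	taxon_26,taxon_32	0.185653,-0.982615
FMS_comb_16	53.3292	taxon_7,taxon_31	0.402765,0.915304
```

A combination's members are original taxa; its weights define the merged
column (here, `0.186·taxon_26 − 0.983·taxon_32` with Fisher score 56.6).
`merge_curve.tsv` / `deletion_curve.tsv` hold the CV learning curves;
`model.json` is the frozen model, reusable via `fmskit transform` and
`fmskit evaluate` on held-out data.

The same pipeline is available as a library:

```python
from fmskit import FmsConfig, SyntheticSpec, fit, generate

table, truth = generate(SyntheticSpec(seed=0))
model = fit(table, config=FmsConfig(classifier="svm", seed=0))
reduced = model.transform(table.values)   # samples × combinations
```

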