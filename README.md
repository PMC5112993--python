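# funcascade

Multi-label protein function prediction by a sequential cascade of three
guilt-by-association voters — sequence similarity, weighted interactions,
and pseudo amino acid composition (PseAAC) — with an order-k accuracy
evaluation harness for leave-one-out and repeated ten-fold cross-validation.

The toolkit is aimed at function-annotation work on proteomes labelled with
the 24 top-level FunCat categories (metabolism, energy, transcription, ...),
where a protein typically carries several categories at once and many
proteins have neither close homologues nor known interaction partners.

## The method

Annotations of the *n* reference proteins form a binary indicator matrix
*D* ∈ {0,1}^(24×n) with *d*ⱼᵢ = 1 iff protein *Pᵢ* has function *fⱼ*.
Each evidence branch scores the query *P* by a weighted vote

  *W* = *D s*,  *Y* = *D t*,  *R* = *D Δ*,

where *sᵢ* are alignment bit scores of the query's homologues, *tᵢ* are
combined interaction-confidence weights of its network neighbours, and
*Δᵢ* = cos(*V_P*, *V_{Pᵢ}*) are cosine similarities between 270-dimensional
PseAAC descriptors. A descriptor stacks the 20 amino-acid frequencies with
λ = 50 lag-correlation factors

  *Cᵢ* = (1/(N−i)) Σₖ (F(Xₖ) − F(Xₖ₊ᵢ))²

for each of five physicochemical property scales (polarity, secondary
structure, molecular volume, codon diversity, electrostatic charge),
weighted by ϖ = 0.15. Sorting a score vector descending yields the
*order-k* predictions: the top category is the 1st-order call, the
runner-up the 2nd-order call, and so on.

The cascade applies the branches in order of reliability: similarity if the
query has any homologue, otherwise interactions if it has any annotated
neighbour, otherwise the PseAAC vote — which is always defined, so every
query receives a full ranked prediction. Performance is measured by the
order-k accuracy ACC_k, the fraction of evaluated proteins whose k-th-ranked
category is truly annotated.

## Worked example

```python
from funcascade import GeneratorConfig, generate_dataset, leave_one_out

dataset = generate_dataset(GeneratorConfig(n_proteins=200, seed=7))
report = leave_one_out(dataset)

for j in (1, 2, 3):
    print(f"ACC_{j} = {report.order_accuracies[j - 1]:.4f}")
for branch, stat in report.branch_stats.items():
    print(f"{branch:12s} n={stat.count:3d} share={stat.proportion:.2%} ACC_1={stat.acc1:.4f}")
```

prints

```
ACC_1 = 0.8550
ACC_2 = 0.7450
ACC_3 = 0.4550
interaction  n=112 share=56.00% ACC_1=0.8036
pseaac       n= 11 share=5.50% ACC_1=0.9091
similarity   n= 77 share=38.50% ACC_1=0.9221
```

0.8550 of the 200 held-out proteins get a truly annotated category as their
top-ranked call; every protein is covered, with the similarity branch
serving the 38.5% of queries that have homologues at the highest per-branch
accuracy and the PseAAC branch catching the evidence-less orphans.

The same machinery is scriptable from the shell:

```
funcascade simulate -o fixture --n-proteins 200 --seed 7
funcascade evaluate --annotations fixture/annotations.csv \
    --fasta fixture/sequences.fasta --similarity fixture/similarity.tsv \
    --interactions fixture/interactions.tsv --loo
funcascade encode fixture/sequences.fasta -o features.tsv
```

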