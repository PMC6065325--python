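# patternet

Candidate-gene prioritization for paired three-timepoint expression studies,
built around a drug self-administration design: gene abundance is profiled in
the same animals at baseline (CON), right after methamphetamine
self-administration (MASA), and after a withdrawal period (WD). The package
classifies genes by the shape of their temporal trajectory, induces a
functional-association network on the patterned genes, ranks genes by
betweenness centrality, and asks whether genes from a curated
addiction-related knowledgebase concentrate in the top centrality tier. It is
aimed at researchers who have a gene-level expression table, a STRING-style
interaction file and a curated gene list, and want a reproducible, testable
path from those inputs to a ranked candidate table.

## The method

**Pattern groups.** For each gene, two fold-change ratios are computed per
rat: r₁ = MASA/CON and r₂ = WD/MASA. Each ratio is called *up* (r > 1.1),
*down* (r < 0.9) or *constant* (boundaries inclusive to constant). The
ordered direction pair maps to six groups — G1 (up-up), G2 (up-down),
G3 (constant-up), G4 (constant-down), G5 (down-up), G6 (down-down); pairs
whose second step is constant are unpatterned (NONE). A gene is patterned
only if every rat lands in the same group (unanimity consensus; a mean-ratio
variant is available). A one-way ANOVA across the three timepoints
(uncorrected p < 0.05) pre-filters genes before classification.

**Network topology.** Interaction edges with combined score ≥ 400 are induced
on the patterned (seed) genes; isolated seeds are dropped. For each node v,
betweenness centrality

  BC(v) = Σ_{s≠v≠t} σ_st(v)/σ_st  ÷  (n−1)(n−2)/2

is computed with Brandes' algorithm over unweighted shortest paths (σ_st is
the number of shortest s–t paths, σ_st(v) those through v). Within-group link
clustering is quantified by the likelihood score — the mean per-gene fraction
of same-group neighbours divided by its random-neighbour expectation
(n_g−1)/(N−1) — with a Mann-Whitney U p-value and a label-permutation null.

**Enrichment.** A curated gene list is mapped onto the network
(case-insensitive symbol identity). With N nodes, K curated nodes, a top tier
of m = ⌊0.1·N⌋ nodes by BC containing k curated nodes, the fold enrichment is
(k/m)/(K/N) and its one-sided hypergeometric p-value is P(X ≥ k) for
X ~ HG(N, K, m).

A synthetic-data module generates complete study bundles — planted pattern
groups in realistic proportions, a stochastic-block-model interaction network
whose modules coincide with the groups, and curated lists planted uniformly
or degree-biased — so every stage is testable against known ground truth.

## Worked example

The package ships a 43-gene reference candidate table (top 10% betweenness
tier of a methamphetamine self-administration whisker-follicle study) at
`patternet.reference_candidates_path()`. Re-validating it:

```
$ patternet report --candidates src/patternet/data/reference_candidates.tsv
43 candidates, 17 curated (39.5%); group mismatches: 0
```

Every printed pattern group is reproduced from the normalised MASA and WD
columns by the 1.1/0.9 direction rules, and 17 of the 43 top-ranked genes
(39.5%) carry the curated addiction annotation. The implied enrichment
arithmetic — 82 curated genes among 432 network nodes, 17 among the top 43 —
gives a fold enrichment of (17/43)/(82/432) = 2.083 with hypergeometric
p = 7.5 × 10⁻⁴.

A full synthetic run (2,000 genes, three rats, planted group proportions
3:422:2:51:25:163):

```
$ printf 'synthesis:\n  seed: 17\nn_perm: 1000\nseed: 17\n' > cfg.yaml
$ patternet run-all --config cfg.yaml --out demo/
wrote 7 artifacts to demo/
```

`demo/summary.json` from that run reports 567 patterned genes
(census G1:3, G2:385, G3:3, G4:8, G5:24, G6:144), a 556-node / 1,141-edge
seed network with 707 within-group links (62%), likelihood score 1.135
(MWU p = 2.1 × 10⁻⁴, permutation p = 0.001), and — because the synthetic
curated list is planted degree-biased — 30 curated genes among the 55-gene
top tier, fold enrichment 2.369 (hypergeometric p = 7.8 × 10⁻⁸).
`demo/candidates.tsv` is the ranked report; its first row is the network's
most central gene with its group and normalised fold-changes.

Identical config and seed reproduce every artifact byte for byte.

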