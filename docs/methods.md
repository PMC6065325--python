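# Methods notes

## Pipeline model and assumptions

The pipeline assumes a paired design: the same animals are sampled at three
timepoints (CON → MASA → WD), so per-rat fold-change ratios are meaningful
and noise that is multiplicative per sample cancels nowhere but in the
ratio's variance. Abundances are treated as FPKM-like nonnegative reals; no
library-size renormalisation is attempted, because ratio classification is
invariant to any common rescaling of a gene's values.

Pattern classification is deliberately threshold-based rather than
model-based: a ratio is *up* above 1.1, *down* below 0.9, *constant*
otherwise, with the boundary values assigned to constant (the thresholds are
strict inequalities). The 1.1/0.9 defaults are the conventional fold-change
window for this assay scale and are exposed as flags (`--fc-up`,
`--fc-down`). The ordered direction pair defines groups G1–G6; the three
pairs with a constant second step are not groups — a trajectory that rises
and then stays put is not distinguishable from a plateau artifact under this
scheme, so it maps to NONE.

Two classification variants exist. The default requires unanimity: each rat
is classified separately and the gene is patterned only if all rats agree on
the same non-NONE group. The `mean` variant classifies the rat-mean ratios
(norm_masa, and norm_wd/norm_masa). Unanimity is stringent around the
constant band: a gene whose true ratio sits exactly at 1.0 is called
constant by a single rat only with probability ≈ Φ(ln 1.1/(σ√2)) −
Φ(−ln 1.1/(σ√2)) under log-normal noise (≈ 0.50 at σ = 0.1), so unanimity
across three rats recovers constant-step groups rarely at realistic noise.
This is a property of the rule, not a defect of the implementation; the
recovery guarantees quoted below are therefore scoped to genes whose
planted effects are genuinely shifted (≥ 1.3× or ≤ 0.77× at every step),
and the mean-ratio variant is the recommended alternative when
constant-step groups matter.

The ANOVA pre-filter (one-way, uncorrected p < 0.05 across timepoints, with
the per-timepoint rat values as replicates) runs before fold-change
classification, and no multiple-testing correction is applied — the filter
is a permissive gate, not an inference. Degenerate genes: zero
within-timepoint variance with unequal means is retained with p = 0 and
logged; all-identical values are dropped with p = 1. Genes with a zero
abundance at any timepoint are excluded before ratio computation unless a
pseudocount is supplied (`--pseudocount`); a zero makes one of the ratios
undefined or nonpositive, and inventing a magnitude silently seemed worse
than exclusion.

## Network statistics

Edges are filtered at combined score ≥ 400 — inclusive, because 400 is the
conventional medium-confidence cutoff on the 0–1000 scale (`--score-min`
changes it). Scores are used only as a filter; shortest paths are
unweighted, since no principled mapping from confidence score to edge length
exists in this setting. Reciprocal duplicate rows keep the maximum score
(undirected semantics); self-pairs are dropped.

Betweenness centrality uses Brandes' accumulation; raw values count
unordered source–target pairs and are normalised by (n−1)(n−2)/2 with n the
global node count, including for disconnected graphs (the common tooling
default). Graphs with n < 3 have normalised BC defined as 0. Ranks break
ties by higher degree, then lexicographic node ID — documented and stable,
so reruns are byte-identical. The top tier takes m = ⌊frac·N⌋ nodes
(minimum 1) by rank; boundary ties are resolved by the rank rule rather
than by including all tied nodes, which keeps the printed tier size exact.

The "expected" within-group link fraction is realised two ways and reported
side by side, because a single definition is not canonical: (a) the analytic
random-neighbour expectation (n_g − 1)/(N − 1) per node, and (b) a label
permutation null that shuffles group labels preserving group sizes and
recomputes the likelihood score, with empirical
p = (1 + #{null ≥ observed})/(n_perm + 1). The Mann-Whitney U comparison of
the observed and expected per-gene vectors is unpaired and two-sided.

## Statistical procedures

`stats.mann_whitney_u` enumerates the exact permutation distribution of U
when n₁ + n₂ ≤ 12 and the pooled sample is tie-free; otherwise it uses the
normal approximation with tie correction and a 0.5 continuity correction.
Two-sided p-values are defined by |U − n₁n₂/2| at least as extreme, which
matches the symmetric exact distribution. `stats.hypergeom_sf` sums the
upper tail in log space via lgamma with a peak-shifted logsumexp, accurate
to better than 1e−10 relative against rational arithmetic for populations
up to the hundreds used here. `stats.one_way_anova` computes F from sums of
squares with the F tail from scipy. All three are cross-checked in the test
suite against independent oracles (full enumeration by pair counting,
`fractions.Fraction` arithmetic, and scipy's implementations).

The hypergeometric enrichment test is one-sided (P(X ≥ k)), the standard
over-representation direction. The fold-enrichment definition (k/m)/(K/N)
applied to the reference table's counts (17, 43, 82, 432) gives 2.083; the
report the table comes from prints 2.07 for this quantity, a near-match we
surface rather than absorb — no choice of one-decimal rounding of the four
counts reproduces 2.07 exactly, and the same counts give hypergeometric
p = 7.5 × 10⁻⁴ against a printed 5.4 × 10⁻⁴.

## What the generator emulates — and what it does not

`synth.generate_expression` plants group proportions 3:422:2:51:25:163
(the published census shape) among a patterned fraction of 0.333 of
n_genes = 2000 by default, so a default bundle plants 666 patterned genes.
Baselines are log-normal (median ≈ e³ ≈ 20, log-sd 1.2 — a typical FPKM
spread); up effects are uniform on [1.2, 4.0], down effects on [0.25, 0.83],
chosen so planted ratios straddle the 1.1/0.9 thresholds with margin; noise
is multiplicative log-normal per value with σ = 0.1, the standard model for
positive abundance data. MASA means are baseline × e₁, WD means are
baseline × e₁ × e₂, so the two planted effects are per-step fold-changes.

`synth.generate_network` is a stochastic block model whose modules are the
pattern groups; unpatterned genes form a background block that participates
only at the between-module rate. Defaults p_in = 0.008 and p_out = 0.0055
were calibrated once to the published network's density and within-link
share (a default bundle yields ≈1,100 links on ≈550 seed nodes, ≈60%
within) and left alone.
Sub-threshold decoy edges (rate 0.05, scores 100–399) exercise the score
filter on every run. Curated lists are planted degree-biased (β = 2) over
~19% of the network's nodes by default, padded with off-network symbols to
a ≈6.5% mapping rate — the geometry of a large knowledgebase meeting a
small tissue-specific network.

The generator does **not** emulate: count noise at low abundance (no
mean-variance relationship), correlated co-expression within modules
(expression and network structure are planted independently beyond the
shared group labels), synonym/identifier mess, or hub topology beyond what
the SBM produces. Passing tests therefore demonstrate correctness of the
algorithms under a clean generative model, not robustness to the full mess
of real transcriptome/interactome data.

## Problem sizes and determinism

Test and acceptance runs use deliberately modest sizes — 8-node graphs for
the exhaustive betweenness oracle (50 random graphs, tolerance 1e−12),
200 small instances for exact-MWU enumeration, populations ≤ 60 for
rational hypergeometric checks, 500 seeded replicates for null calibration
(rejection ≤ 7% at α = 0.05), 100 replicates for the SBM likelihood-signal
and hub-detection power properties, and 20 replicates of 400-gene bundles
for noisy recovery. These sizes give the property assertions comfortable
binomial margins while keeping the whole suite under a minute.

Every stochastic component takes a seed; the pipeline derives fixed-order
substreams from one master seed (generator, permutation null), so a config
plus seed reproduces the entire output tree byte for byte.

## Known limitations

* The unanimity consensus cannot recover constant-step groups at realistic
  noise (see above); use the mean variant if G3/G4 are of interest.
* Identifier matching is exact after case-folding; no synonym expansion.
  An explicit two-column mapping table is the only remapping mechanism.
* The permutation null permutes labels, not graph structure; it conditions
  on the observed topology.
* Exact Mann-Whitney enumeration is combinatorial and capped at a combined
  sample size of 12; above that the tie-corrected normal approximation is
  used (agreement within 0.02 in p is asserted in tests).
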