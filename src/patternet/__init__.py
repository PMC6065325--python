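"""patternet: time-course expression pattern grouping and network-centrality
gene prioritization.

The pipeline classifies genes by the direction of their fold-changes across
three timepoints (baseline, after drug self-administration, after
withdrawal), induces a functional-association network on the patterned
genes, quantifies within-group link enrichment, ranks genes by betweenness
centrality, and tests a curated gene set for over-representation in the top
centrality tier.
"""

from importlib.resources import files as _files

from .enrich import (
    EnrichmentResult,
    compare_centrality,
    enrichment_result,
    fold_enrichment,
    hypergeom_enrichment,
    map_gene_set,
    select_candidates,
    top_fraction,
)
from .io import (
    CandidateRecord,
    CuratedGeneSet,
    ExpressionMatrix,
    InteractionEdge,
    read_candidate_table,
    read_expression_table,
    read_gene_set,
    read_string_links,
    write_candidate_table,
)
from .network import (
    GeneNetwork,
    betweenness_centrality,
    brute_force_betweenness,
    build_network,
    count_links_by_group,
    likelihood_score,
    permutation_null,
)
from .patterns import (
    PatternGroup,
    RatioProfile,
    anova_filter,
    classify_direction,
    classify_pattern,
    classify_profiles,
    compute_ratio_profiles,
    consensus_pattern,
    group_census,
)
from .pipeline import RunConfig, RunReport, run_all
from .stats import hypergeom_sf, mann_whitney_u, one_way_anova
from .synth import (
    CuratedParams,
    ExpressionParams,
    NetworkParams,
    StudyConfig,
    generate_expression,
    generate_network,
    generate_study,
    plant_curated_set,
)

__version__ = "0.1.0"


def reference_candidates_path():
    """Path to the packaged 43-gene reference candidate table."""
    return _files("patternet").joinpath("data/reference_candidates.tsv")
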