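"""zincsig — transcriptomic zinc-signature derivation, scoring and association.

Derives a consensus zinc-stimulated gene (ZSG) signature from heterogeneous
treatment/depletion expression datasets by vote counting, scores tissue
cohorts for inferred zinc status (mean normalized log2 expression of the
signature genes), and runs the downstream association analyses: fold change
versus controls, quartile comparison, genome-wide score-gene correlation and
pre-ranked gene set enrichment.
"""

from importlib import resources

from .datasets_io import (
    ExpressionDataset,
    GeneSetCollection,
    harmonize_genes,
    read_gmt,
    read_matrix,
    write_gmt,
    write_matrix,
)
from .diffexpr import (
    ModerationParams,
    bh_adjust,
    call_regulated,
    counts_to_logcpm,
    fit_moderation,
    log_transform,
    moderated_t_test,
    quantile_normalize,
    run_de,
)
from .consensus import (
    ConsensusTable,
    SignatureDefinition,
    assemble_preliminary,
    filter_stress,
    ora_hypergeom,
    validate_with_depletion,
    vote_count,
)
from .score import (
    ScoredCohort,
    compute_score,
    correlate_covariates,
    quartile_stratify,
    rank_sum_test,
    score_cohort,
    score_log2fc,
)
from .association import (
    CorrelationRanking,
    EnrichmentResult,
    correlate_score_genomewide,
    cross_dataset_top,
    merge_batches,
    preranked_gsea,
)
from .pipeline import RunConfig, associate_cohorts, derive_signature
from . import synthetic_data

__version__ = "0.1.0"


def default_stress_sets() -> GeneSetCollection:
    """The shipped heat-shock / DNA-damage stress gene sets."""
    path = resources.files("zincsig").joinpath("data/stress_sets.gmt")
    with resources.as_file(path) as p:
        return read_gmt(p)


def default_signature() -> list[str]:
    """The six consensus signature genes shipped as the documented floor.

    The full nine-gene membership is configurable; the shipped list carries
    the six members that are fixed (metallothioneins plus the zinc exporter
    SLC30A1), with the remainder supplied by the user's configuration.
    """
    path = resources.files("zincsig").joinpath("data/default_signature.txt")
    with resources.as_file(path) as p:
        return [line.strip().upper() for line in open(p) if line.strip()]
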