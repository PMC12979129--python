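"""End-to-end orchestration: derive → score → associate.

These functions chain the module-level operations with the default thresholds
(1.5-fold, p < 0.05, 5-of-N votes) and collect a JSON-serializable run summary
recording parameters, seeds and the gene/sample counts at every filter stage.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import association, consensus, diffexpr, score
from .datasets_io import ExpressionDataset, GeneSetCollection

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Pipeline thresholds and options; defaults are the derivation defaults."""

    fold_threshold: float = 1.5
    alpha: float = 0.05
    min_votes: int = 5
    use_fdr: bool = False
    quantile: bool = True
    relative_votes: bool = False
    drop_discordant: bool = False
    min_fraction_present: float = 0.5
    gsea_weight: float = 1.0
    gsea_n_perm: int = 1000
    gsea_min_size: int = 5
    gsea_max_fraction: float = 0.5
    top_k: int = 50
    seed: int = 0
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.fold_threshold <= 0 or self.alpha <= 0:
            raise ValueError("thresholds must be positive")
        if self.min_votes < 1:
            raise ValueError("min_votes must be >= 1")

    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items()}
        return d


@dataclass
class DeriveResult:
    signature: consensus.SignatureDefinition
    votes: consensus.ConsensusTable
    preliminary: list[str]
    de_results: dict[str, pd.DataFrame]
    depletion_results: dict[str, pd.DataFrame]
    summary: dict


def derive_signature(
    treatment_datasets: list[ExpressionDataset],
    stress_sets: GeneSetCollection,
    depletion_datasets: list[ExpressionDataset] | None = None,
    config: RunConfig | None = None,
) -> DeriveResult:
    """Derive the consensus signature from treatment (and depletion) datasets."""
    cfg = config or RunConfig()
    if len(treatment_datasets) < 2:
        raise ValueError("derivation requires at least 2 treatment datasets")

    de_results: dict[str, pd.DataFrame] = {}
    for ds in treatment_datasets:
        de_results[ds.dataset_id] = diffexpr.run_de(
            ds, fold_threshold=cfg.fold_threshold, alpha=cfg.alpha,
            use_fdr=cfg.use_fdr, quantile=cfg.quantile,
        )
    votes = consensus.vote_count(de_results)
    preliminary = consensus.assemble_preliminary(
        votes, min_votes=cfg.min_votes, relative=cfg.relative_votes,
    )

    summary = {
        "config": cfg.to_dict(),
        "n_treatment_datasets": len(treatment_datasets),
        "per_dataset_up_counts": {
            ds_id: int(res["up"].sum()) for ds_id, res in de_results.items()
        },
        "n_preliminary": len(preliminary),
    }

    if not preliminary:
        empty = consensus.SignatureDefinition(
            genes=[], provenance=pd.DataFrame(
                columns=["gene", "stress_flagged", "depletion_status"]
            ),
        )
        summary.update({"n_signature": 0, "n_stress_removed": 0})
        return DeriveResult(empty, votes, preliminary, de_results, {}, summary)

    universe = sorted(set(votes.table["gene"]))
    per_dataset_up = {
        ds_id: list(res.loc[res["up"], "gene"]) for ds_id, res in de_results.items()
    }
    sig = consensus.filter_stress(
        preliminary, stress_sets, per_dataset_up=per_dataset_up, universe=universe,
    )
    summary["n_stress_removed"] = len(sig.removed_stress)

    depl_results: dict[str, pd.DataFrame] = {}
    if depletion_datasets:
        for ds in depletion_datasets:
            depl_results[ds.dataset_id] = diffexpr.run_de(
                ds, fold_threshold=cfg.fold_threshold, alpha=cfg.alpha,
                use_fdr=cfg.use_fdr, quantile=cfg.quantile,
            )
        sig = consensus.validate_with_depletion(sig, depl_results)
        if cfg.drop_discordant:
            keep = [g for g in sig.genes
                    if sig.provenance.loc[g, "depletion_status"] != consensus.DISCORDANT]
            sig = consensus.SignatureDefinition(
                genes=keep, provenance=sig.provenance,
                removed_stress=sig.removed_stress, stress_report=sig.stress_report,
            )
    summary["n_signature"] = len(sig.genes)
    summary["signature"] = list(sig.genes)
    return DeriveResult(sig, votes, preliminary, de_results, depl_results, summary)


@dataclass
class AssociateResult:
    rankings: list[association.CorrelationRanking]
    consensus_top: pd.DataFrame
    enrichment: dict[str, list[association.EnrichmentResult]]
    summary: dict


def associate_cohorts(
    cohorts: list[ExpressionDataset],
    signature: list[str],
    gene_sets: GeneSetCollection,
    config: RunConfig | None = None,
    merge: bool = False,
) -> AssociateResult:
    """Score each cohort, correlate genome-wide, build the consensus top list
    and run pre-ranked enrichment on every cohort's correlation ranking."""
    cfg = config or RunConfig()
    work = list(cohorts)
    if merge and len(cohorts) >= 2:
        merged = association.merge_batches(cohorts)
        work = work + [merged]

    rankings = []
    for ds in work:
        scores = score.compute_score(ds, signature,
                                     min_fraction_present=cfg.min_fraction_present)
        rankings.append(association.correlate_score_genomewide(ds, scores))

    top = None
    if len(rankings) >= 2:
        top = association.cross_dataset_top(rankings, k=cfg.top_k,
                                            exclude=list(signature))
    enrichment = {}
    for rk in rankings:
        enrichment[rk.dataset_id] = association.preranked_gsea(
            rk, gene_sets, weight_p=cfg.gsea_weight, n_perm=cfg.gsea_n_perm,
            seed=cfg.seed, min_size=cfg.gsea_min_size,
            max_fraction=cfg.gsea_max_fraction,
        )
    summary = {
        "config": cfg.to_dict(),
        "n_cohorts": len(work),
        "merged": bool(merge and len(cohorts) >= 2),
        "n_consensus_top": 0 if top is None else len(top),
    }
    return AssociateResult(rankings, top, enrichment, summary)


def write_json(obj: dict, path) -> None:
    Path(path).write_text(json.dumps(_jsonable(obj), indent=2, sort_keys=True) + "\n")


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, pd.Series):
        return _jsonable(obj.to_dict())
    return obj
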