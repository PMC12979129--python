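"""Replicated synthetic-benchmark experiments for the pipeline.

Each function runs the pipeline end-to-end on freshly generated synthetic
data under the default study conditions (11 mixed-platform treatment
datasets of 2,000 genes at 4 vs 4; a 41 vs 10 disease cohort; a planted
20-gene co-regulated module) over several replicate seeds and returns the
measured operating characteristics: signature recovery, null false-call
behaviour, score and covariate recovery, and association/enrichment
recovery.  The derived seeds stay below 2^31 so results are reproducible
from a single base seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from . import association, consensus, diffexpr, score, synthetic_data
from .datasets_io import GeneSetCollection
from .pipeline import RunConfig, derive_signature

_SEED_MOD = 2**31 - 1


def _sub_seed(base: int, stream: int, rep: int) -> int:
    return (base * 1_000_003 + stream * 10_007 + rep) % _SEED_MOD


@dataclass
class RecoveryOutcome:
    n_seeds: int
    recovered_counts: list[int] = field(default_factory=list)
    stress_counts: list[int] = field(default_factory=list)

    @property
    def success_rate(self) -> float:
        ok = [r >= 8 and s == 0
              for r, s in zip(self.recovered_counts, self.stress_counts)]
        return float(np.mean(ok))


def signature_recovery(n_seeds: int = 20, genes: int = 2000,
                       base_seed: int = 0) -> RecoveryOutcome:
    """Derive the signature on replicate synthetic panels with defaults.

    Returns, per seed, how many of the 9 planted zinc genes reached the final
    signature and how many planted stress genes leaked into it.
    """
    out = RecoveryOutcome(n_seeds=n_seeds)
    cfg = RunConfig()
    for rep in range(n_seeds):
        datasets, truth = synthetic_data.simulate_treatment_datasets(
            genes=genes, seed=_sub_seed(base_seed, 1, rep))
        stress = GeneSetCollection(
            sets=synthetic_data.stress_gene_sets(sorted(truth.stress_genes)))
        result = derive_signature(datasets, stress, config=cfg)
        recovered = set(result.signature.genes)
        out.recovered_counts.append(
            len(recovered & set(truth.planted_zinc_genes)))
        out.stress_counts.append(len(recovered & set(truth.stress_genes)))
    return out


@dataclass
class NullOutcome:
    per_dataset_p_rates: list[float] = field(default_factory=list)
    max_votes: int = 0
    n_genes_per_dataset: int = 2000

    @property
    def mean_rate(self) -> float:
        return float(np.mean(self.per_dataset_p_rates))

    @property
    def per_dataset_mc_se(self) -> float:
        return float(np.sqrt(0.05 * 0.95 / self.n_genes_per_dataset))


def null_behavior(n_seeds: int = 50, genes: int = 2000,
                  base_seed: int = 0) -> NullOutcome:
    """Zero-effect panels: raw-p calibration and consensus vote behaviour.

    Records each dataset's fraction of measured genes at raw p < 0.05 and the
    maximum number of up-votes any gene accumulates across the panel.
    """
    out = NullOutcome(n_genes_per_dataset=genes)
    for rep in range(n_seeds):
        datasets, _ = synthetic_data.simulate_treatment_datasets(
            genes=genes, zinc_effect_log2=0.0, n_stress=0, high_dose_datasets=0,
            seed=_sub_seed(base_seed, 2, rep))
        de_results = {}
        for ds in datasets:
            res = diffexpr.run_de(ds)
            de_results[ds.dataset_id] = res
            m = res["measured"]
            out.per_dataset_p_rates.append(
                float((res.loc[m, "p"] < 0.05).mean()))
        votes = consensus.vote_count(de_results)
        out.max_votes = max(out.max_votes, int(votes.table["votes_up"].max()))
    return out


@dataclass
class ScoreOutcome:
    log2fcs: list[float] = field(default_factory=list)
    covariate_ok: list[bool] = field(default_factory=list)

    def in_band_rate(self, lo: float = -1.15, hi: float = -0.85) -> float:
        return float(np.mean([lo <= fc <= hi for fc in self.log2fcs]))

    @property
    def covariate_rate(self) -> float:
        return float(np.mean(self.covariate_ok))


def score_recovery(n_seeds: int = 20, genes: int = 2000,
                   base_seed: int = 0) -> ScoreOutcome:
    """Disease-cohort scoring: LOG2FC and covariate-sign recovery per seed."""
    out = ScoreOutcome()
    for rep in range(n_seeds):
        cohort, truth = synthetic_data.simulate_disease_cohort(
            genes=genes, seed=_sub_seed(base_seed, 3, rep))
        sig = sorted(truth.planted_zinc_genes)
        sc = score.score_cohort(cohort, sig)
        out.log2fcs.append(float(sc.score_log2fc))
        corr = sc.correlations.set_index("covariate")
        ok = (corr.loc["AST", "r"] < 0 and corr.loc["AST", "p"] < 0.05
              and corr.loc["ALB", "r"] > 0 and corr.loc["ALB", "p"] < 0.05)
        out.covariate_ok.append(bool(ok))
    return out


@dataclass
class AssociationOutcome:
    module_in_top: list[int] = field(default_factory=list)
    nes_values: list[float] = field(default_factory=list)
    p_values: list[float] = field(default_factory=list)

    @property
    def success_rate(self) -> float:
        ok = [m >= 15 and n > 0 and p < 0.05
              for m, n, p in zip(self.module_in_top, self.nes_values,
                                 self.p_values)]
        return float(np.mean(ok))


def association_recovery(n_seeds: int = 20, genes: int = 2000, n_perm: int = 1000,
                         base_seed: int = 0) -> AssociationOutcome:
    """Planted-module recovery: consensus top-50 membership and enrichment.

    Two synthetic cohorts per seed; counts how many of the 20 planted module
    genes enter the cross-cohort consensus top 50, and the module set's NES
    and permutation p on the first cohort's correlation ranking.
    """
    out = AssociationOutcome()
    for rep in range(n_seeds):
        rankings = []
        module = None
        sig = None
        for c in range(2):
            cohort, truth = synthetic_data.simulate_disease_cohort(
                genes=genes, dataset_id=f"COHORT{c}",
                seed=_sub_seed(base_seed, 4, 2 * rep + c))
            sig = sorted(truth.planted_zinc_genes)
            scores = score.compute_score(cohort, sig)
            rankings.append(association.correlate_score_genomewide(cohort, scores))
            module = truth.module_genes
        top = association.cross_dataset_top(rankings, k=50, exclude=sig)
        out.module_in_top.append(len(set(top["gene"]) & set(module)))
        sets = GeneSetCollection(sets={"MODULE": ("planted module", module)})
        enr = association.preranked_gsea(
            rankings[0], sets, n_perm=n_perm, seed=_sub_seed(base_seed, 5, rep))
        out.nes_values.append(float(enr[0].nes))
        out.p_values.append(float(enr[0].p_perm))
    return out


def gsea_null_uniformity(n_sets: int = 200, genes: int = 1000, set_size: int = 20,
                         n_perm: int = 1000, base_seed: int = 0) -> float:
    """KS statistic of permutation p-values for random sets on a random ranking."""
    rng = np.random.default_rng(_sub_seed(base_seed, 6, 0))
    import pandas as pd

    names = [f"G{i:04d}" for i in range(genes)]
    r = np.sort(rng.normal(size=genes))[::-1]
    table = pd.DataFrame({"r": r, "p": 0.5, "rank": np.arange(1, genes + 1)},
                         index=names)
    ranking = association.CorrelationRanking(dataset_id="NULL", table=table)
    sets = GeneSetCollection(sets={
        f"S{j:03d}": ("random", list(rng.choice(names, set_size, replace=False)))
        for j in range(n_sets)})
    res = association.preranked_gsea(ranking, sets, n_perm=n_perm,
                                     seed=_sub_seed(base_seed, 6, 1))
    pvals = np.array([e.p_perm for e in res])
    return float(stats.kstest(pvals, "uniform").statistic)
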