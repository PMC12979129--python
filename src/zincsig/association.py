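"""Genome-wide association of the signature score with expression.

Covers four steps: merging cohorts with a per-gene location-scale batch
adjustment, Pearson correlation of every gene against the per-sample score,
cross-dataset consensus of the top correlated genes by mean rank, and
pre-ranked gene set enrichment on the correlation-ranked list with a
gene-label permutation null.

The batch adjustment standardizes each gene within each batch to the pooled
per-gene mean and variance.  It is a deliberately simplified location-scale
correction, not a full empirical-Bayes batch model: the downstream analyses
consume ranks and correlations, which are insensitive to the difference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datasets_io import ExpressionDataset, GeneSetCollection
from .diffexpr import bh_adjust, prepare_dataset, quantile_normalize

logger = logging.getLogger(__name__)


@dataclass
class CorrelationRanking:
    """Per-gene Pearson correlation with the signature score, ranked."""

    dataset_id: str
    table: pd.DataFrame  # index gene; columns r, p, rank

    def ranked_genes(self) -> list[str]:
        return list(self.table.sort_values("rank").index)


@dataclass
class EnrichmentResult:
    set_name: str
    es: float
    nes: float | None
    p_perm: float | None
    q: float | None
    n_hits: int
    leading_edge: list[str]


def merge_batches(
    datasets: list[ExpressionDataset],
    min_common_genes: int = 100,
) -> ExpressionDataset:
    """Merge cohorts on their common genes with location-scale batch adjustment.

    Each dataset is quantile normalized on the intersection genes, then every
    gene is standardized within each batch to the pooled per-gene mean and
    variance.  Genes with zero within-batch variance get a location-only
    shift for that batch.
    """
    if not datasets:
        raise ValueError("merge_batches requires at least one dataset")
    common = set(datasets[0].genes)
    for ds in datasets[1:]:
        common &= set(ds.genes)
    common = sorted(common)
    if len(common) < min_common_genes:
        raise ValueError(
            f"only {len(common)} genes shared across datasets "
            f"(minimum {min_common_genes})"
        )
    all_samples = [s for ds in datasets for s in ds.samples]
    prefix = len(set(all_samples)) < len(all_samples) or len(datasets) == 1
    blocks = []
    batch_labels = []
    group_vals = []
    for ds in datasets:
        sub = quantile_normalize(ds.values.loc[common])
        if prefix and len(datasets) > 1:
            sub = sub.rename(columns={s: f"{ds.dataset_id}:{s}" for s in sub.columns})
        blocks.append(sub)
        batch_labels.extend([ds.dataset_id] * ds.n_samples)
        group_vals.extend(ds.groups.loc[ds.samples].tolist())
    merged = pd.concat(blocks, axis=1)
    group_s = pd.Series(group_vals, index=merged.columns)
    batch_s = pd.Series(batch_labels, index=merged.columns)
    if len(datasets) == 1:
        ds = datasets[0]
        return ExpressionDataset(
            dataset_id=ds.dataset_id, platform="intensity", values=merged,
            groups=group_s, batch=batch_s, covariates=ds.covariates,
            log_scale=True,
        )

    arr = merged.to_numpy(dtype=float)
    pooled_mean = arr.mean(axis=1)
    pooled_sd = arr.std(axis=1, ddof=1)
    out = arr.copy()
    for b in batch_s.unique():
        cols = np.flatnonzero((batch_s == b).to_numpy())
        block = arr[:, cols]
        m = block.mean(axis=1)
        sd = block.std(axis=1, ddof=1)
        centered = block - m[:, None]
        scale = np.ones_like(sd)
        ok = (sd > 0) & (pooled_sd > 0)
        scale[ok] = pooled_sd[ok] / sd[ok]
        out[:, cols] = centered * scale[:, None] + pooled_mean[:, None]
    values = pd.DataFrame(out, index=merged.index, columns=merged.columns)

    covs = []
    for ds in datasets:
        if ds.covariates is None:
            continue
        c = ds.covariates
        if prefix:
            c = c.rename(index={s: f"{ds.dataset_id}:{s}" for s in c.index})
        covs.append(c)
    covariates = pd.concat(covs) if covs else None
    return ExpressionDataset(
        dataset_id="+".join(ds.dataset_id for ds in datasets),
        platform="intensity",
        values=values,
        groups=group_s,
        batch=batch_s,
        covariates=covariates,
        log_scale=True,
    )


def correlate_score_genomewide(
    dataset: ExpressionDataset,
    scores: pd.Series,
) -> CorrelationRanking:
    """Pearson r between the score vector and every gene's expression.

    Zero-variance genes are reported with NaN r and excluded from the
    ranking; ranking is by r descending with ties broken by symbol.
    """
    if len(scores) < 3:
        raise ValueError("genome-wide correlation requires at least 3 samples")
    x = scores.loc[dataset.samples].to_numpy(dtype=float)
    mat = dataset.values.to_numpy(dtype=float)
    n = len(x)
    xc = x - x.mean()
    xs = np.sqrt((xc ** 2).sum())
    mc = mat - np.nanmean(mat, axis=1, keepdims=True)
    num = np.nansum(mc * xc[None, :], axis=1)
    denom = np.sqrt(np.nansum(mc ** 2, axis=1)) * xs
    with np.errstate(divide="ignore", invalid="ignore"):
        r = num / denom
    r[~np.isfinite(r)] = np.nan
    r = np.clip(r, -1.0, 1.0)
    # two-sided p via the t transform on n-2 df
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1e-300, 1.0 - r ** 2))
    p = 2.0 * stats.t.sf(np.abs(t), n - 2)
    table = pd.DataFrame({"r": r, "p": p}, index=dataset.values.index)
    valid = table.dropna(subset=["r"])
    # rank by r descending, ties broken by symbol for determinism
    order = sorted(valid.index, key=lambda g: (-valid.loc[g, "r"], g))
    table["rank"] = np.nan
    table.loc[order, "rank"] = np.arange(1, len(order) + 1)
    return CorrelationRanking(dataset_id=dataset.dataset_id, table=table)


def cross_dataset_top(
    rankings: list[CorrelationRanking],
    k: int = 50,
    exclude: list[str] | None = None,
) -> pd.DataFrame:
    """Consensus of top score-correlated genes across cohorts by mean rank.

    Genes ranked in every cohort are ordered by mean rank (ties by symbol);
    the top k are returned with per-dataset r values.  ``exclude`` drops e.g.
    the signature genes themselves.
    """
    if len(rankings) < 2:
        raise ValueError("cross_dataset_top requires at least 2 rankings")
    common: set[str] | None = None
    for rk in rankings:
        genes = set(rk.table.dropna(subset=["rank"]).index)
        common = genes if common is None else (common & genes)
    common = common or set()
    if exclude:
        common -= set(exclude)
    if not common:
        raise ValueError("no genes ranked in all datasets")
    if k > len(common):
        logger.warning("k=%d exceeds %d common genes; truncating", k, len(common))
        k = len(common)
    rows = []
    for gene in common:
        ranks = [float(rk.table.loc[gene, "rank"]) for rk in rankings]
        row = {"gene": gene, "mean_rank": float(np.mean(ranks))}
        for rk in rankings:
            row[f"r_{rk.dataset_id}"] = float(rk.table.loc[gene, "r"])
        rows.append(row)
    out = pd.DataFrame(rows).sort_values(
        ["mean_rank", "gene"], ascending=[True, True]
    ).head(k)
    return out.reset_index(drop=True)


def _es_curve(weights: np.ndarray, hit_mask: np.ndarray) -> np.ndarray:
    """Running enrichment sum for one ranked list and hit indicator."""
    n = len(weights)
    m = int(hit_mask.sum())
    hit_w = np.where(hit_mask, weights, 0.0)
    total_hit = hit_w.sum()
    if total_hit <= 0 or m == 0 or m == n:
        return np.zeros(n)
    step = hit_w / total_hit - (~hit_mask).astype(float) / (n - m)
    return np.cumsum(step)


def _es_stat(curve: np.ndarray) -> float:
    i = int(np.argmax(np.abs(curve)))
    return float(curve[i])


def _null_es(weights: np.ndarray, m: int, n_perm: int, rng) -> np.ndarray:
    """Null ES for random m-gene sets, vectorized across permutations."""
    n = len(weights)
    pos = np.argpartition(rng.random((n_perm, n)), m, axis=1)[:, :m]
    hit_w = weights[pos]
    totals = hit_w.sum(axis=1)
    totals[totals <= 0] = np.inf  # degenerate all-zero-weight draw -> flat walk
    step = np.full((n_perm, n), -1.0 / (n - m))
    np.put_along_axis(step, pos, hit_w / totals[:, None], axis=1)
    walk = np.cumsum(step, axis=1)
    idx = np.argmax(np.abs(walk), axis=1)
    return np.take_along_axis(walk, idx[:, None], axis=1).ravel()


def preranked_gsea(
    ranking: CorrelationRanking,
    sets: GeneSetCollection,
    weight_p: float = 1.0,
    n_perm: int = 1000,
    seed: int | None = 0,
    min_size: int = 5,
    max_fraction: float = 0.5,
) -> list[EnrichmentResult]:
    """Pre-ranked gene set enrichment with a gene-label permutation null.

    The walking-sum statistic increments by |r|^p (normalized by the total
    hit weight) at set members and decrements by 1/(N-m) elsewhere; ES is the
    signed extremum of the running sum.  The null permutes gene labels (set
    positions) with a fixed seed; NES divides ES by the mean |null ES| of
    matching sign and p_perm = (1 + #{null >= observed, same sign}) /
    (1 + #{null of that sign}).  BH adjustment across tested sets.
    """
    tab = ranking.table.dropna(subset=["rank"]).sort_values("rank")
    genes = list(tab.index)
    n = len(genes)
    weights = np.abs(tab["r"].to_numpy(dtype=float)) ** weight_p
    gene_pos = {g: i for i, g in enumerate(genes)}
    rng = np.random.default_rng(seed)

    tested = []
    for name in sets.names():
        members = [g for g in sets.genes(name) if g in gene_pos]
        if len(members) < min_size:
            logger.warning("set %s: %d ranked genes (<%d); skipped",
                           name, len(members), min_size)
            continue
        if len(members) > max_fraction * n:
            logger.warning("set %s covers more than %.0f%% of ranked genes; skipped",
                           name, 100 * max_fraction)
            continue
        tested.append((name, members))

    results: list[EnrichmentResult] = []
    for name, members in tested:
        mask = np.zeros(n, dtype=bool)
        mask[[gene_pos[g] for g in members]] = True
        curve = _es_curve(weights, mask)
        es = _es_stat(curve)
        m = len(members)

        if n_perm <= 0:
            peak = int(np.argmax(np.abs(curve)))
            leading = _leading_edge(genes, mask, curve, es, peak)
            results.append(EnrichmentResult(name, es, None, None, None, m, leading))
            continue

        null_es = _null_es(weights, m, n_perm, rng)

        same_sign = null_es >= 0 if es >= 0 else null_es < 0
        n_sign = int(same_sign.sum())
        if n_sign == 0:
            nes = np.nan
            p_perm = 1.0 / (1.0 + n_perm)
        else:
            mean_abs = np.abs(null_es[same_sign]).mean()
            nes = es / mean_abs if mean_abs > 0 else np.nan
            extreme = int((np.abs(null_es[same_sign]) >= abs(es) - 1e-15).sum())
            p_perm = (1 + extreme) / (1 + n_sign)
        peak = int(np.argmax(np.abs(curve)))
        leading = _leading_edge(genes, mask, curve, es, peak)
        results.append(EnrichmentResult(name, es, float(nes), float(p_perm),
                                        None, m, leading))

    pvals = [r.p_perm for r in results if r.p_perm is not None]
    if pvals:
        q = bh_adjust(np.array(pvals))
        qi = iter(q)
        for r in results:
            if r.p_perm is not None:
                r.q = float(next(qi))
    return results


def _leading_edge(genes, mask, curve, es, peak) -> list[str]:
    if es >= 0:
        idx = np.flatnonzero(mask[: peak + 1])
    else:
        idx = np.flatnonzero(mask[peak:]) + peak
    return [genes[i] for i in idx]


def enrichment_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame([
        {"set": r.set_name, "ES": r.es, "NES": r.nes, "p_perm": r.p_perm,
         "q": r.q, "n_hits": r.n_hits,
         "leading_edge": ",".join(r.leading_edge)}
        for r in results
    ])
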