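"""Per-sample zinc signature scores and cohort-level comparisons.

The zinc signature score of a sample is the arithmetic mean, with equal
weights, of the signature genes' normalized log2 expression values
(log2-CPM for sequencing data, log2 intensity for arrays).  Scores are
comparable only within one dataset/platform; cross-dataset statements are
made as LOG2 fold changes against each dataset's own healthy controls.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .datasets_io import ExpressionDataset

logger = logging.getLogger(__name__)


@dataclass
class ScoredCohort:
    """Per-sample scores and quartiles plus cohort-level summaries."""

    dataset: ExpressionDataset
    scores: pd.Series
    quartiles: pd.Series | None = None
    score_log2fc: float | None = None
    gene_log2fc: pd.Series | None = None
    correlations: pd.DataFrame | None = None
    signature_used: list[str] = field(default_factory=list)

    def frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"sample": self.scores.index,
                            "score": self.scores.values})
        if self.quartiles is not None:
            out["quartile"] = self.quartiles.loc[self.scores.index].values
        out["group"] = self.dataset.groups.loc[self.scores.index].values
        return out


def compute_score(
    dataset: ExpressionDataset,
    signature: list[str],
    min_fraction_present: float = 0.5,
) -> pd.Series:
    """Mean normalized log2 expression of the measured signature genes.

    Requires the dataset to already be on the log2 scale.  At least
    ceil(min_fraction_present x |signature|) signature genes must be measured;
    the mean is over those measured genes, identical weights.
    """
    if not dataset.log_scale:
        raise ValueError("dataset must be normalized to log2 scale before scoring")
    if not signature:
        raise ValueError("empty signature")
    measured_mask = dataset.measured_mask()
    present = [g for g in signature if g in dataset.values.index and measured_mask[g]]
    needed = math.ceil(min_fraction_present * len(signature))
    if len(present) < needed:
        missing = sorted(set(signature) - set(present))
        raise ValueError(
            f"only {len(present)}/{len(signature)} signature genes measured "
            f"(need {needed}); missing: {missing}"
        )
    scores = dataset.values.loc[present].mean(axis=0)
    scores.name = "score"
    return scores


def score_log2fc(
    dataset: ExpressionDataset,
    scores: pd.Series,
    signature: list[str],
    disease_level: str | None = None,
    healthy_level: str | None = None,
) -> tuple[float, pd.Series]:
    """LOG2 fold change of the score and of each signature gene vs controls.

    Per gene: mean(disease log2) - mean(healthy log2); score-level: difference
    of group mean scores.  On log2 data a difference of means is a log2 fold
    change.
    """
    disease_level, healthy_level = _resolve_levels(dataset.groups, disease_level,
                                                  healthy_level)
    d_samples = dataset.group_samples(disease_level)
    h_samples = dataset.group_samples(healthy_level)
    if not d_samples or not h_samples:
        raise ValueError("both disease and healthy groups must be non-empty")
    present = [g for g in signature if g in dataset.values.index]
    gene_fc = (dataset.values.loc[present, d_samples].mean(axis=1)
               - dataset.values.loc[present, h_samples].mean(axis=1))
    gene_fc.name = "log2fc"
    s_fc = float(scores.loc[d_samples].mean() - scores.loc[h_samples].mean())
    return s_fc, gene_fc


def _resolve_levels(groups: pd.Series, disease: str | None, healthy: str | None):
    levels = sorted(groups.unique())
    if disease is not None and healthy is not None:
        return disease, healthy
    healthy_names = {"healthy", "control", "normal", "mock"}
    guess_h = [l for l in levels if l.lower() in healthy_names]
    if len(guess_h) == 1:
        h = guess_h[0]
        d = [l for l in levels if l != h]
        if len(d) == 1:
            return d[0], h
    if len(levels) == 2:
        return levels[0], levels[1]
    raise ValueError(f"cannot resolve disease/healthy levels from {levels}")


def quartile_stratify(scores: pd.Series) -> pd.Series:
    """Assign quartiles 1 (highest scores) .. 4 (lowest).

    Samples are sorted by score descending, ties broken by sample id
    ascending; the sample at descending rank r (1-based) gets quartile
    floor(4*(r-1)/n) + 1, so quartile sizes differ by at most one.
    """
    n = len(scores)
    if n < 4:
        raise ValueError("quartile stratification requires at least 4 samples")
    order = sorted(scores.index, key=lambda s: (-scores[s], s))
    q = {s: (4 * r) // n + 1 for r, s in enumerate(order)}
    out = pd.Series({s: q[s] for s in scores.index}, name="quartile").loc[scores.index]
    return out.astype(int)


def rank_sum_test(group_a, group_b) -> tuple[float, float]:
    """Two-sided Wilcoxon-Mann-Whitney rank-sum test.

    Exact p by enumeration of all rank assignments when n_a + n_b <= 12
    (ties handled via midranks); otherwise the normal approximation with tie
    correction.  Returns (U statistic of group_a, two-sided p).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    n1, n2 = len(a), len(b)
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 values")
    combined = np.concatenate([a, b])
    ranks = stats.rankdata(combined, method="average")
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    if n1 + n2 <= 12:
        mid = n1 * n2 / 2.0
        dev_obs = abs(u_obs - mid)
        total = 0
        hits = 0
        for idx in combinations(range(n1 + n2), n1):
            u = ranks[list(idx)].sum() - n1 * (n1 + 1) / 2.0
            total += 1
            if abs(u - mid) >= dev_obs - 1e-12:
                hits += 1
        return float(u_obs), hits / total
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return float(u_obs), float(res.pvalue)


def correlate_covariates(
    scores: pd.Series,
    covariates: pd.DataFrame,
    names: list[str] | None = None,
) -> pd.DataFrame:
    """Pearson correlation of the score against each clinical covariate.

    Missing covariate values are dropped pairwise; a covariate with zero
    variance (or < 3 paired observations) is reported with NaN r and p.
    Returns a frame with covariate, n, r, p.
    """
    names = list(names) if names is not None else list(covariates.columns)
    rows = []
    for name in names:
        if name not in covariates.columns:
            rows.append({"covariate": name, "n": 0, "r": np.nan, "p": np.nan})
            continue
        pair = pd.concat([scores, covariates[name]], axis=1).dropna()
        x = pair.iloc[:, 0].to_numpy(dtype=float)
        y = pair.iloc[:, 1].to_numpy(dtype=float)
        if len(pair) < 3 or np.std(y) == 0 or np.std(x) == 0:
            logger.warning("covariate %s: undefined correlation "
                           "(n=%d or zero variance)", name, len(pair))
            rows.append({"covariate": name, "n": len(pair), "r": np.nan, "p": np.nan})
            continue
        r, p = stats.pearsonr(x, y)
        rows.append({"covariate": name, "n": len(pair), "r": float(r), "p": float(p)})
    return pd.DataFrame(rows)


def score_cohort(
    dataset: ExpressionDataset,
    signature: list[str],
    with_controls: bool = True,
    min_fraction_present: float = 0.5,
) -> ScoredCohort:
    """Score a normalized cohort and attach quartiles, LOG2FC and correlations."""
    scores = compute_score(dataset, signature,
                           min_fraction_present=min_fraction_present)
    quart = quartile_stratify(scores) if len(scores) >= 4 else None
    s_fc = None
    g_fc = None
    if with_controls:
        s_fc, g_fc = score_log2fc(dataset, scores, signature)
    corr = None
    if dataset.covariates is not None and not dataset.covariates.empty:
        corr = correlate_covariates(scores, dataset.covariates)
    return ScoredCohort(dataset=dataset, scores=scores, quartiles=quart,
                        score_log2fc=s_fc, gene_log2fc=g_fc, correlations=corr,
                        signature_used=[g for g in signature
                                        if g in dataset.values.index])
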