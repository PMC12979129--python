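"""Per-dataset two-group differential expression with moderated t-statistics.

Intensity matrices are log2-transformed (when detected as linear scale) and
quantile normalized; count matrices are converted to log2 counts-per-million
after an expression filter.  Both then pass through one moderated t engine:
per-gene residual variances are shrunk toward a scaled inverse-chi-square
prior fitted by moment matching on log variances, and the resulting posterior
variances feed a t-test with augmented degrees of freedom.  Zinc-stimulated
gene (ZSG) calls use the fold-change/significance rule: up-regulated means a
>=1.5-fold induction at p < 0.05, down-regulated the reciprocal.

The count path here is a log-CPM + moderated-t approximation of a
quasi-likelihood count model; the downstream consensus vote consumes only
(log2 fold change, p) and is robust to this choice.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .datasets_io import COUNTS, INTENSITY, ExpressionDataset

logger = logging.getLogger(__name__)

FOLD_THRESHOLD = 1.5
ALPHA = 0.05
LINEAR_SCALE_MAX = 50.0  # matrices with max above this are taken as linear scale


@dataclass
class ModerationParams:
    """Scaled inverse-chi-square prior for gene-wise variances.

    d0 is the prior degrees of freedom (np.inf means complete shrinkage to the
    common variance) and s0_sq the prior variance, in squared log2 units.
    """

    d0: float
    s0_sq: float

    def __post_init__(self) -> None:
        if self.d0 < 0:
            raise ValueError("d0 must be non-negative")
        if not self.s0_sq > 0:
            raise ValueError("s0_sq must be positive")


def log_transform(dataset: ExpressionDataset, offset: float = 0.0) -> ExpressionDataset:
    """log2-transform an intensity matrix if it looks linear-scale.

    A matrix whose maximum exceeds ``LINEAR_SCALE_MAX`` is treated as linear
    and replaced by log2(value + offset); otherwise it is passed through
    unchanged and flagged already-log.
    """
    if dataset.platform != INTENSITY:
        raise ValueError("log_transform applies to intensity datasets")
    arr = dataset.values.to_numpy(dtype=float)
    max_val = np.nanmax(arr)
    if max_val > LINEAR_SCALE_MAX:
        shifted = arr + offset
        if np.nanmin(shifted) <= 0:
            raise ValueError(
                "linear-scale matrix has non-positive values; configure a log offset"
            )
        out = pd.DataFrame(np.log2(shifted), index=dataset.values.index,
                           columns=dataset.values.columns)
        meta = dict(dataset.meta, log_transformed=True)
        return dataset.with_values(out, log_scale=True, meta=meta)
    meta = dict(dataset.meta, log_transformed=False)
    return dataset.with_values(dataset.values.copy(), log_scale=True, meta=meta)


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Force every sample to share the across-sample mean quantile distribution.

    Each column's sorted values are replaced by the mean, across columns, of
    the values at the same sort position; ties within a column receive the
    mean of the quantile values they span.  Rows with missing values are left
    untouched (they are unmeasured and excluded from the reference).
    """
    complete = ~matrix.isna().any(axis=1)
    sub = matrix.loc[complete]
    if sub.shape[0] == 0 or sub.shape[1] <= 1:
        return matrix.copy()
    arr = sub.to_numpy(dtype=float)
    ref = np.sort(arr, axis=0).mean(axis=1)
    out = np.empty_like(arr)
    for j in range(arr.shape[1]):
        col = arr[:, j]
        order = np.argsort(col, kind="mergesort")
        mapped = np.empty_like(ref)
        mapped[order] = ref
        # tied values share the mean of the quantile values they span
        _, inv, counts = np.unique(col, return_inverse=True, return_counts=True)
        if (counts > 1).any():
            sums = np.bincount(inv, weights=mapped)
            mapped = sums[inv] / counts[inv]
        out[:, j] = mapped
    result = matrix.copy()
    result.loc[complete] = out
    return result


def counts_to_logcpm(
    dataset: ExpressionDataset,
    min_cpm: float = 1.0,
    min_samples: int | None = None,
) -> tuple[ExpressionDataset, list[str]]:
    """Convert counts to log2(CPM + 0.5), filtering weakly expressed genes.

    A gene is kept iff its CPM is >= ``min_cpm`` in at least ``min_samples``
    samples (default: the size of the smaller group).  Returns the converted
    dataset and the list of filtered-out genes.
    """
    if dataset.platform != COUNTS:
        raise ValueError("counts_to_logcpm applies to counts datasets")
    counts = dataset.values.to_numpy(dtype=float)
    lib = counts.sum(axis=0)
    if (lib <= 0).any():
        bad = [dataset.samples[i] for i in np.flatnonzero(lib <= 0)]
        raise ValueError(f"all-zero library for samples: {bad}")
    if min_samples is None:
        min_samples = int(dataset.groups.value_counts().min())
    cpm = counts / lib * 1e6
    keep = (cpm >= min_cpm).sum(axis=1) >= min_samples
    filtered = [g for g, k in zip(dataset.genes, keep) if not k]
    logcpm = np.log2(cpm[keep] + 0.5)
    out = pd.DataFrame(logcpm, index=dataset.values.index[keep],
                       columns=dataset.values.columns)
    meta = dict(dataset.meta, n_filtered_low_expression=len(filtered))
    converted = ExpressionDataset(
        dataset_id=dataset.dataset_id,
        platform=INTENSITY,
        values=out,
        groups=dataset.groups,
        batch=dataset.batch,
        covariates=dataset.covariates,
        log_scale=True,
        meta=meta,
    )
    return converted, filtered


def _trigamma_inverse(x: np.ndarray | float) -> np.ndarray | float:
    """Solve trigamma(y) = x by Newton iteration (monotone decreasing)."""
    x = np.asarray(x, dtype=float)
    y = 0.5 + 1.0 / x  # good starting value for all x > 0
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y = y + dif
        if np.all(np.abs(dif) < 1e-10 * np.maximum(y, 1.0)):
            break
    return y


def _group_arrays(matrix: pd.DataFrame, groups: pd.Series) -> tuple[np.ndarray, np.ndarray, str, str]:
    levels = sorted(groups.unique())
    if len(levels) != 2:
        raise ValueError(f"exactly two groups required, got {levels}")
    # treated/disease is the 'positive' level when recognizably labelled
    positive_names = {"treated", "disease", "zinc", "depleted", "ah"}
    if levels[0].lower() in positive_names:
        pos, neg = levels[0], levels[1]
    elif levels[1].lower() in positive_names:
        pos, neg = levels[1], levels[0]
    else:
        pos, neg = levels[1], levels[0]
    a = matrix.loc[:, groups.index[groups == pos]].to_numpy(dtype=float)
    b = matrix.loc[:, groups.index[groups == neg]].to_numpy(dtype=float)
    return a, b, pos, neg


def fit_moderation(matrix: pd.DataFrame, groups: pd.Series) -> ModerationParams:
    """Fit the variance prior by moment matching on log residual variances.

    Gene-wise residual variances s_g^2 on d_g degrees of freedom follow, under
    the scaled inverse-chi-square prior, a scaled F distribution; matching the
    mean and variance of log(s_g^2) to digamma/trigamma moments yields (d0,
    s0^2).  When the observed spread of log variances does not exceed the
    sampling spread, the prior degrees of freedom are infinite and s0^2 is the
    mean variance.
    """
    a, b, _, _ = _group_arrays(matrix, groups)
    measured = ~(np.isnan(a).any(axis=1) | np.isnan(b).any(axis=1))
    a, b = a[measured], b[measured]
    n1, n2 = a.shape[1], b.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 samples")
    dg = n1 + n2 - 2
    s2 = (a.var(axis=1, ddof=1) * (n1 - 1) + b.var(axis=1, ddof=1) * (n2 - 1)) / dg
    s2 = s2[s2 > 0]
    if s2.size < 10:
        raise ValueError("insufficient genes to estimate prior")
    z = np.log(s2)
    e_z = z.mean()
    var_z = z.var(ddof=1)
    expected_var = special.polygamma(1, dg / 2.0)
    excess = var_z - expected_var
    if excess <= 0:
        return ModerationParams(d0=np.inf, s0_sq=float(s2.mean()))
    d0 = 2.0 * float(_trigamma_inverse(excess))
    log_s0 = e_z - special.polygamma(0, dg / 2.0) + np.log(dg / 2.0) \
        + special.polygamma(0, d0 / 2.0) - np.log(d0 / 2.0)
    return ModerationParams(d0=d0, s0_sq=float(np.exp(log_s0)))


def moderated_t_test(
    matrix: pd.DataFrame,
    groups: pd.Series,
    params: ModerationParams,
) -> pd.DataFrame:
    """Moderated two-sample t-test per gene.

    Posterior variance per gene is the prior-weighted combination
    (d0*s0^2 + d_g*s_g^2) / (d0 + d_g); the t statistic uses it in place of
    the pooled variance and is referred to a t distribution on d0 + d_g
    degrees of freedom (standard normal in the d0 = inf limit).  Genes with
    missing values in either group are flagged unmeasured with NaN statistics.
    """
    a, b, pos, neg = _group_arrays(matrix, groups)
    n1, n2 = a.shape[1], b.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 samples")
    dg = n1 + n2 - 2
    measured = ~(np.isnan(a).any(axis=1) | np.isnan(b).any(axis=1))

    with np.errstate(invalid="ignore"):
        mean_a = a.mean(axis=1)
        mean_b = b.mean(axis=1)
        s2 = (a.var(axis=1, ddof=1) * (n1 - 1) + b.var(axis=1, ddof=1) * (n2 - 1)) / dg

    log2fc = mean_a - mean_b
    if np.isinf(params.d0):
        post_var = np.full_like(s2, params.s0_sq)
        df_total = np.inf
    else:
        post_var = (params.d0 * params.s0_sq + dg * s2) / (params.d0 + dg)
        df_total = params.d0 + dg

    se = np.sqrt(post_var * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = log2fc / se
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p = np.clip(p, np.nextafter(0, 1), 1.0)

    res = pd.DataFrame({
        "gene": matrix.index,
        "log2fc": log2fc,
        "t": t,
        "p": p,
        "measured": measured,
    }).set_index("gene", drop=False)
    res.index.name = None
    res.loc[~res["measured"], ["log2fc", "t", "p"]] = np.nan
    res["fdr"] = np.nan
    m = res["measured"]
    if m.any():
        res.loc[m, "fdr"] = bh_adjust(res.loc[m, "p"].to_numpy())
    res.attrs["contrast"] = (pos, neg)
    return res


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def call_regulated(
    results: pd.DataFrame,
    fold_threshold: float = FOLD_THRESHOLD,
    alpha: float = ALPHA,
    use_fdr: bool = False,
) -> pd.DataFrame:
    """Flag up- (ZSG) and down-regulated genes at the fold/significance rule.

    up: log2fc >= log2(fold_threshold) and p (or FDR) < alpha;
    down: log2fc <= -log2(fold_threshold) and p (or FDR) < alpha.
    The fold boundary is inclusive, the significance boundary strict.
    """
    out = results.copy()
    gate = out["fdr"] if use_fdr else out["p"]
    lfc_cut = np.log2(fold_threshold)
    measured = out["measured"].to_numpy(dtype=bool)
    sig = (gate.to_numpy() < alpha) & measured
    out["up"] = sig & (out["log2fc"].to_numpy() >= lfc_cut)
    out["down"] = sig & (out["log2fc"].to_numpy() <= -lfc_cut)
    return out


def prepare_dataset(
    dataset: ExpressionDataset,
    quantile: bool = True,
    log_offset: float = 0.0,
    min_cpm: float = 1.0,
    min_samples: int | None = None,
) -> ExpressionDataset:
    """Normalize one dataset onto the log2 scale used by testing and scoring.

    Intensity: log2 transform (if linear) then quantile normalization.
    Counts: expression filter then log2-CPM.
    """
    if dataset.platform == COUNTS:
        converted, filtered = counts_to_logcpm(dataset, min_cpm=min_cpm,
                                               min_samples=min_samples)
        logger.info("%s: counts→logCPM, %d genes filtered",
                    dataset.dataset_id, len(filtered))
        return converted
    ds = dataset if dataset.log_scale else log_transform(dataset, offset=log_offset)
    if quantile:
        ds = ds.with_values(quantile_normalize(ds.values))
    return ds


def run_de(
    dataset: ExpressionDataset,
    fold_threshold: float = FOLD_THRESHOLD,
    alpha: float = ALPHA,
    use_fdr: bool = False,
    quantile: bool = True,
) -> pd.DataFrame:
    """Full per-dataset DE pipeline: normalize, fit prior, test, call."""
    ds = prepare_dataset(dataset, quantile=quantile)
    params = fit_moderation(ds.values, ds.groups)
    res = moderated_t_test(ds.values, ds.groups, params)
    return call_regulated(res, fold_threshold=fold_threshold, alpha=alpha,
                          use_fdr=use_fdr)
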