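"""Synthetic expression datasets with the structure the pipeline assumes.

Three generators emulate the study designs the pipeline consumes:

* ``simulate_treatment_datasets`` — a panel of small two-group zinc-treatment
  studies of mixed platform (microarray-like Gaussian intensities and
  negative-binomial RNA-seq counts) with planted zinc-responsive genes induced
  everywhere and stress-response genes induced only in designated high-dose
  datasets; each gene is randomly unmeasured per dataset to mimic platform
  coverage gaps.
* ``simulate_depletion_dataset`` — a zinc-depletion study in which the planted
  zinc genes are reciprocally down-regulated, with optional discordant
  members shifted up instead (mimicking non-specific chelation artifacts).
* ``simulate_disease_cohort`` — a disease/healthy cohort driven by a latent
  per-sample zinc level: signature genes track the latent level (shifted down
  in disease), a co-regulated module correlates with it, and clinical
  covariates are linear in it plus noise.

All generators are pure functions of (parameters, seed) and return both the
datasets and a SimulationTruth record of everything planted.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .datasets_io import COUNTS, INTENSITY, ExpressionDataset

NB_DISPERSION = 0.1  # typical bulk RNA-seq magnitude
STRESS_EFFECT_LOG2 = 2.0


@dataclass
class SimulationTruth:
    """Record of every planted effect, round-trippable through JSON."""

    planted_zinc_genes: dict[str, float] = field(default_factory=dict)
    stress_genes: dict[str, list[str]] = field(default_factory=dict)
    disease_shift: float | None = None
    covariate_model: dict[str, tuple[float, float, float]] = field(default_factory=dict)
    discordant_genes: list[str] = field(default_factory=list)
    module_genes: list[str] = field(default_factory=list)
    seed: int | None = None
    params: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationTruth":
        d = dict(d)
        d["covariate_model"] = {k: tuple(v) for k, v in d.get("covariate_model", {}).items()}
        return cls(**d)


def _gene_names(n: int) -> list[str]:
    return [f"G{i:05d}" for i in range(n)]


def _intensity_matrix(rng, genes, n_samples):
    mu = rng.uniform(4.0, 12.0, size=len(genes))
    sigma = rng.uniform(0.2, 0.6, size=len(genes))
    vals = rng.normal(mu[:, None], sigma[:, None], size=(len(genes), n_samples))
    return vals, mu, sigma


def simulate_treatment_datasets(
    n_datasets: int = 11,
    n_intensity: int = 6,
    n_counts: int = 5,
    genes: int = 2000,
    n_per_group: int = 4,
    zinc_effect_log2: float = 1.5,
    n_zinc: int = 9,
    n_stress: int = 6,
    high_dose_datasets: int = 3,
    measured_fraction: float = 0.85,
    min_measured_planted: int = 8,
    seed: int = 0,
) -> tuple[list[ExpressionDataset], SimulationTruth]:
    """Panel of two-group zinc-treatment datasets with planted effects.

    Planted zinc genes are shifted +``zinc_effect_log2`` (log2 units) in
    treated samples of every dataset where measured; stress genes are shifted
    +2.0 log2 only in the first ``high_dose_datasets`` datasets.  Each gene is
    independently unmeasured (dropped from the matrix) per dataset with
    probability 1 - ``measured_fraction``, except that planted zinc genes are
    never allowed below ``min_measured_planted`` measured datasets.
    """
    if n_intensity + n_counts != n_datasets:
        raise ValueError("n_intensity + n_counts must equal n_datasets")
    if n_zinc + n_stress >= genes:
        raise ValueError("planted genes must number fewer than total genes")
    if high_dose_datasets > n_datasets:
        raise ValueError("high_dose_datasets exceeds n_datasets")
    if not 0 < measured_fraction <= 1:
        raise ValueError("measured_fraction must be in (0, 1]")
    rng = np.random.default_rng(seed)

    n_background = genes - n_zinc - n_stress
    background = _gene_names(n_background)
    zinc_genes = [f"ZN{i:02d}" for i in range(n_zinc)]
    stress_genes = [f"STR{i:02d}" for i in range(n_stress)]
    all_genes = background + zinc_genes + stress_genes

    dataset_ids = [f"SIM{i:02d}" for i in range(n_datasets)]
    high_dose = dataset_ids[:high_dose_datasets]

    # measured map: gene x dataset, resampled rows that starve planted genes
    measured = rng.random((len(all_genes), n_datasets)) < measured_fraction
    gene_index = {g: i for i, g in enumerate(all_genes)}
    for g in zinc_genes:
        gi = gene_index[g]
        while measured[gi].sum() < min_measured_planted:
            measured[gi] = rng.random(n_datasets) < measured_fraction

    platforms = [INTENSITY] * n_intensity + [COUNTS] * n_counts
    datasets = []
    for d, (ds_id, platform) in enumerate(zip(dataset_ids, platforms)):
        keep = [g for g in all_genes if measured[gene_index[g], d]]
        n_total = 2 * n_per_group
        samples = [f"{ds_id}_S{j}" for j in range(n_total)]
        group = ["treated"] * n_per_group + ["control"] * n_per_group
        treated_cols = np.arange(n_per_group)

        effect = np.zeros(len(keep))
        for i, g in enumerate(keep):
            if g in zinc_genes:
                effect[i] = zinc_effect_log2
            elif g in stress_genes and ds_id in high_dose:
                effect[i] = STRESS_EFFECT_LOG2

        if platform == INTENSITY:
            vals, mu, sigma = _intensity_matrix(rng, keep, n_total)
            vals[:, treated_cols] += effect[:, None]
            # emit on linear scale so the pipeline exercises log detection
            mat = 2.0 ** vals
        else:
            base = rng.lognormal(mean=np.log(50.0), sigma=1.2, size=len(keep))
            mean = np.tile(base[:, None], (1, n_total))
            mean[:, treated_cols] *= 2.0 ** effect[:, None]
            r = 1.0 / NB_DISPERSION
            p = r / (r + mean)
            mat = rng.negative_binomial(r, p).astype(float)

        values = pd.DataFrame(mat, index=keep, columns=samples)
        groups = pd.Series(group, index=samples)
        datasets.append(ExpressionDataset(
            dataset_id=ds_id, platform=platform, values=values, groups=groups,
            meta={"high_dose": ds_id in high_dose},
        ))

    truth = SimulationTruth(
        planted_zinc_genes={g: zinc_effect_log2 for g in zinc_genes},
        stress_genes={g: list(high_dose) for g in stress_genes},
        seed=seed,
        params={
            "n_datasets": n_datasets, "n_intensity": n_intensity,
            "n_counts": n_counts, "genes": genes, "n_per_group": n_per_group,
            "zinc_effect_log2": zinc_effect_log2, "n_zinc": n_zinc,
            "n_stress": n_stress, "high_dose_datasets": high_dose_datasets,
            "measured_fraction": measured_fraction,
        },
    )
    return datasets, truth


def simulate_depletion_dataset(
    genes: int = 2000,
    n_per_group: int = 6,
    n_zinc: int = 9,
    depletion_effect_log2: float = -1.0,
    discordant_genes: list[str] | None = None,
    platform: str = INTENSITY,
    dataset_id: str = "DEPL00",
    seed: int = 0,
) -> tuple[ExpressionDataset, SimulationTruth]:
    """Zinc-depletion dataset: planted zinc genes shifted down in depleted samples.

    Genes listed in ``discordant_genes`` (must be planted zinc genes) are
    shifted UP by the same magnitude instead, mimicking paradoxical induction
    under non-specific chelation.
    """
    rng = np.random.default_rng(seed)
    zinc_genes = [f"ZN{i:02d}" for i in range(n_zinc)]
    discordant = list(discordant_genes or [])
    bad = [g for g in discordant if g not in zinc_genes]
    if bad:
        raise ValueError(f"discordant genes not in planted zinc set: {bad}")
    background = _gene_names(genes - n_zinc)
    all_genes = background + zinc_genes

    n_total = 2 * n_per_group
    samples = [f"{dataset_id}_S{j}" for j in range(n_total)]
    group = ["treated"] * n_per_group + ["control"] * n_per_group  # treated = depleted
    treated_cols = np.arange(n_per_group)

    effect = np.zeros(len(all_genes))
    mag = abs(depletion_effect_log2)
    for i, g in enumerate(all_genes):
        if g in zinc_genes:
            effect[i] = mag if g in discordant else -mag

    vals, _, _ = _intensity_matrix(rng, all_genes, n_total)
    vals[:, treated_cols] += effect[:, None]
    values = pd.DataFrame(2.0 ** vals, index=all_genes, columns=samples)
    groups = pd.Series(group, index=samples)
    ds = ExpressionDataset(dataset_id=dataset_id, platform=INTENSITY,
                           values=values, groups=groups)
    truth = SimulationTruth(
        planted_zinc_genes={g: (mag if g in discordant else -mag) for g in zinc_genes},
        discordant_genes=discordant,
        seed=seed,
        params={"genes": genes, "n_per_group": n_per_group,
                "depletion_effect_log2": depletion_effect_log2},
    )
    return ds, truth


DEFAULT_COVARIATES = {"AST": (100.0, -30.0, 15.0), "ALB": (30.0, 4.0, 2.0)}


def simulate_disease_cohort(
    n_disease: int = 41,
    n_healthy: int = 10,
    genes: int = 2000,
    signature: list[str] | None = None,
    disease_shift_log2: float = -1.0,
    module_size: int = 20,
    module_r: float = 0.7,
    covariates: dict[str, tuple[float, float, float]] | None = None,
    latent_sd: float = 0.15,
    dataset_id: str = "COHORT",
    seed: int = 0,
) -> tuple[ExpressionDataset, SimulationTruth]:
    """Disease/healthy cohort driven by a latent per-sample zinc level.

    Each sample has a latent zinc level z ~ Normal(0, latent_sd^2), shifted by
    ``disease_shift_log2`` in disease samples.  Signature genes are
    baseline + z + noise; module genes are coupled to z so their cohort-level
    correlation with it is ~ ``module_r``; each covariate is
    a + b*z + Normal(0, sigma).

    The within-group latent spread (``latent_sd``, log2 units) is kept small
    relative to the disease shift: the latent level enters every signature
    gene coherently, so it — not the per-gene measurement noise — bounds how
    precisely the cohort's score fold change recovers the planted shift at
    realistic sample sizes.
    """
    if not (0 <= module_r < 1):
        raise ValueError("module_r must be in [0, 1)")
    rng = np.random.default_rng(seed)
    if signature is None:
        signature = [f"ZN{i:02d}" for i in range(9)]
    covariates = dict(DEFAULT_COVARIATES if covariates is None else covariates)

    n_total = n_disease + n_healthy
    samples = [f"{dataset_id}_S{j}" for j in range(n_total)]
    group = ["disease"] * n_disease + ["healthy"] * n_healthy
    disease_cols = np.arange(n_disease)

    z = rng.normal(0.0, latent_sd, size=n_total)
    z[disease_cols] += disease_shift_log2

    module_genes = [f"MOD{i:02d}" for i in range(module_size)]
    background = _gene_names(genes - len(signature) - module_size)
    all_genes = background + module_genes + list(signature)
    if len(set(all_genes)) != len(all_genes):
        raise ValueError("signature collides with generated gene names")

    vals = np.empty((len(all_genes), n_total))
    mu = rng.uniform(4.0, 12.0, size=len(all_genes))
    sigma = rng.uniform(0.2, 0.6, size=len(all_genes))
    vals[:] = rng.normal(mu[:, None], sigma[:, None], size=vals.shape)

    gene_index = {g: i for i, g in enumerate(all_genes)}
    sig_noise_sd = 0.2
    for g in signature:
        gi = gene_index[g]
        vals[gi] = mu[gi] + z + rng.normal(0.0, sig_noise_sd, size=n_total)
    if module_r > 0:
        # couple module genes so corr(gene, z) ~ module_r across the cohort,
        # accounting for the between-group component of var(z)
        p_dis = n_disease / n_total
        var_z = latent_sd ** 2 + p_dis * (1 - p_dis) * disease_shift_log2 ** 2
        lam = module_r / np.sqrt(1.0 - module_r ** 2) / np.sqrt(var_z)
        for g in module_genes:
            gi = gene_index[g]
            vals[gi] = mu[gi] + lam * z + rng.normal(0.0, 1.0, size=n_total)

    cov = pd.DataFrame(index=samples)
    for name, (a, b, s) in covariates.items():
        cov[name] = a + b * z + rng.normal(0.0, s, size=n_total)

    values = pd.DataFrame(vals, index=all_genes, columns=samples)
    groups = pd.Series(group, index=samples)
    ds = ExpressionDataset(dataset_id=dataset_id, platform=INTENSITY,
                           values=values, groups=groups, covariates=cov,
                           log_scale=True)
    truth = SimulationTruth(
        planted_zinc_genes={g: 1.0 for g in signature},
        disease_shift=disease_shift_log2,
        covariate_model=covariates,
        module_genes=module_genes,
        seed=seed,
        params={"n_disease": n_disease, "n_healthy": n_healthy, "genes": genes,
                "module_size": module_size, "module_r": module_r,
                "disease_shift_log2": disease_shift_log2},
    )
    return ds, truth


def stress_gene_sets(stress_genes: list[str]) -> dict[str, tuple[str, list[str]]]:
    """GMT-shaped stress set covering the planted stress genes."""
    return {"SIM_STRESS_RESPONSE": ("planted stress module", list(stress_genes))}
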