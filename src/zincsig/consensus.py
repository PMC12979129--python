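"""Consensus signature assembly from per-dataset differential expression.

The consensus rule is vote counting: a gene enters the preliminary signature
when it is called up-regulated (>=1.5-fold, p < 0.05) in at least ``min_votes``
of the treatment datasets — by default 5 of the 11, an absolute threshold
chosen below a strict majority to accommodate genes not measured on every
platform.  Stress-response transcripts (heat-shock / DNA-damage genes such as
HSPA6 or DDIT3, induced only by supraphysiological zinc doses or ionophores)
are then removed by membership in configured stress gene sets, and the
surviving genes are validated for reciprocal down-regulation in zinc-depletion
datasets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datasets_io import GeneSetCollection
from .diffexpr import bh_adjust

logger = logging.getLogger(__name__)

MIN_VOTES = 5

VALIDATED = "validated"
DISCORDANT = "discordant"
UNMEASURED = "unmeasured"


@dataclass
class ConsensusTable:
    """Gene × dataset record of up-regulation calls.

    ``table`` has one row per gene with columns votes_up, datasets_up,
    datasets_measured and mean_log2fc (mean over datasets where measured);
    ``per_dataset`` maps dataset id → its DE result frame.
    """

    table: pd.DataFrame
    per_dataset: dict[str, pd.DataFrame]
    n_datasets: int


@dataclass
class SignatureDefinition:
    """The derived signature: ordered genes with per-gene provenance."""

    genes: list[str]
    provenance: pd.DataFrame  # votes_up, stress_flagged, depletion_status
    removed_stress: list[str] = field(default_factory=list)
    stress_report: pd.DataFrame | None = None

    def __len__(self) -> int:
        return len(self.genes)


def vote_count(de_results: dict[str, pd.DataFrame]) -> ConsensusTable:
    """Tally, per gene, the datasets in which it was called up-regulated.

    Unmeasured gene/dataset pairs contribute neither votes nor denominator
    adjustments; the vote threshold downstream is absolute.
    """
    if len(de_results) < 2:
        raise ValueError("vote_count requires at least 2 datasets")
    rows: dict[str, dict] = {}
    for ds_id, res in de_results.items():
        measured = res["measured"].to_numpy(dtype=bool)
        up = res["up"].to_numpy(dtype=bool) if "up" in res else np.zeros(len(res), bool)
        for gene, is_meas, is_up, lfc in zip(res["gene"], measured, up, res["log2fc"]):
            rec = rows.setdefault(gene, {
                "votes_up": 0, "datasets_up": [], "datasets_measured": [],
                "_lfc": [],
            })
            if is_meas:
                rec["datasets_measured"].append(ds_id)
                rec["_lfc"].append(lfc)
                if is_up:
                    rec["votes_up"] += 1
                    rec["datasets_up"].append(ds_id)
    table = pd.DataFrame(
        {
            "gene": list(rows),
            "votes_up": [r["votes_up"] for r in rows.values()],
            "datasets_up": [r["datasets_up"] for r in rows.values()],
            "datasets_measured": [r["datasets_measured"] for r in rows.values()],
            "mean_log2fc": [float(np.mean(r["_lfc"])) if r["_lfc"] else np.nan
                            for r in rows.values()],
        }
    ).set_index("gene", drop=False)
    table.index.name = None
    return ConsensusTable(table=table, per_dataset=dict(de_results),
                          n_datasets=len(de_results))


def assemble_preliminary(
    table: ConsensusTable,
    min_votes: int = MIN_VOTES,
    relative: bool = False,
    min_fraction: float = 0.5,
) -> list[str]:
    """Select preliminary signature genes by the vote threshold.

    Default is the absolute rule (votes_up >= min_votes regardless of how many
    datasets measured the gene).  ``relative=True`` switches to
    votes_up >= min_fraction x datasets_measured, the principled alternative
    when missingness is severe.  Ordering: votes desc, mean log2fc desc,
    symbol asc.
    """
    t = table.table
    if relative:
        denom = t["datasets_measured"].apply(len).clip(lower=1)
        sel = t[t["votes_up"] >= min_fraction * denom]
    else:
        sel = t[t["votes_up"] >= min_votes]
    if sel.empty:
        logger.warning("no gene reached the vote threshold; empty preliminary signature")
        return []
    sel = sel.sort_values(["votes_up", "mean_log2fc", "gene"],
                          ascending=[False, False, True])
    return list(sel["gene"])


def ora_hypergeom(
    query: set[str] | list[str],
    reference: set[str] | list[str],
    universe: list[str],
) -> tuple[int, float]:
    """Upper-tail hypergeometric over-representation test.

    Returns (overlap k, P(X >= k)) for drawing |query| genes from the
    universe containing |reference| successes.
    """
    uni = set(universe)
    if not uni:
        raise ValueError("empty universe")
    q = set(query)
    stray = sorted(q - uni)
    if stray:
        raise ValueError(f"query genes not in universe: {stray}")
    ref = set(reference) & uni
    k = len(q & ref)
    if k == 0:
        return 0, 1.0
    p = float(stats.hypergeom.sf(k - 1, len(uni), len(ref), len(q)))
    return k, min(p, 1.0)


def filter_stress(
    preliminary: list[str],
    stress_sets: GeneSetCollection,
    per_dataset_up: dict[str, list[str]] | None = None,
    universe: list[str] | None = None,
    q_threshold: float = 0.05,
) -> SignatureDefinition:
    """Remove stress-response transcripts and report stress-confounded datasets.

    Any preliminary gene belonging to any configured stress set is flagged and
    removed.  Additionally each dataset's full up-regulated list is ORA-tested
    against every stress set; datasets with BH-adjusted p < ``q_threshold``
    are reported as stress-confounded (report only — their votes stand).
    """
    if not preliminary:
        raise ValueError("preliminary signature is empty")
    if len(stress_sets) == 0:
        logger.warning("no stress sets configured; stress filter is the identity")
        prov = pd.DataFrame({
            "gene": preliminary,
            "stress_flagged": False,
            "depletion_status": UNMEASURED,
        }).set_index("gene", drop=False)
        prov.index.name = None
        return SignatureDefinition(genes=list(preliminary), provenance=prov)

    stress_genes = stress_sets.all_genes()
    flagged = [g for g in preliminary if g in stress_genes]
    kept = [g for g in preliminary if g not in stress_genes]
    prov = pd.DataFrame({
        "gene": preliminary,
        "stress_flagged": [g in stress_genes for g in preliminary],
        "depletion_status": UNMEASURED,
    }).set_index("gene", drop=False)
    prov.index.name = None

    report = None
    if per_dataset_up is not None and universe:
        rows = []
        for ds_id, up_genes in per_dataset_up.items():
            up_in_uni = [g for g in up_genes if g in set(universe)]
            for set_name in stress_sets.names():
                k, p = ora_hypergeom(up_in_uni, stress_sets.genes(set_name), universe)
                rows.append({"dataset": ds_id, "stress_set": set_name,
                             "overlap": k, "p": p})
        report = pd.DataFrame(rows)
        if not report.empty:
            report["q"] = bh_adjust(report["p"].to_numpy())
            report["stress_confounded"] = report["q"] < q_threshold
            for ds_id in report.loc[report["stress_confounded"], "dataset"].unique():
                logger.info("dataset %s flagged stress-confounded", ds_id)

    return SignatureDefinition(genes=kept, provenance=prov,
                               removed_stress=flagged, stress_report=report)


def validate_with_depletion(
    signature: SignatureDefinition,
    depletion_results: dict[str, pd.DataFrame],
) -> SignatureDefinition:
    """Set per-gene depletion status from zinc-depletion contrasts.

    validated: down-regulated (>=1.5-fold reduction, p < 0.05) in at least one
    depletion dataset and up-regulated in none; discordant: up-regulated in at
    least one (e.g. induced by non-specific chelation); unmeasured otherwise.
    Discordant genes are reported, not removed, by default.
    """
    if not depletion_results:
        raise ValueError("at least one depletion dataset required")
    status = {}
    for gene in signature.genes:
        any_down = False
        any_up = False
        for res in depletion_results.values():
            if gene not in res.index:
                continue
            row = res.loc[gene]
            if not bool(row["measured"]):
                continue
            any_down |= bool(row["down"])
            any_up |= bool(row["up"])
        if any_up:
            status[gene] = DISCORDANT
        elif any_down:
            status[gene] = VALIDATED
        else:
            # absent from every depletion dataset, or measured without a
            # significant reciprocal call — either way not validated
            status[gene] = UNMEASURED
    prov = signature.provenance.copy()
    for gene, st in status.items():
        prov.loc[gene, "depletion_status"] = st
    return SignatureDefinition(
        genes=list(signature.genes),
        provenance=prov,
        removed_stress=list(signature.removed_stress),
        stress_report=signature.stress_report,
    )


def signature_to_frame(sig: SignatureDefinition, votes: pd.DataFrame | None = None) -> pd.DataFrame:
    """Flat TSV-ready view: gene, votes_up, datasets_up, stress_flagged, depletion_status."""
    prov = sig.provenance
    rows = []
    for gene in prov["gene"]:
        row = {"gene": gene,
               "stress_flagged": bool(prov.loc[gene, "stress_flagged"]),
               "depletion_status": prov.loc[gene, "depletion_status"],
               "in_signature": gene in set(sig.genes)}
        if votes is not None and gene in votes.index:
            row["votes_up"] = int(votes.loc[gene, "votes_up"])
            row["datasets_up"] = ",".join(votes.loc[gene, "datasets_up"])
        rows.append(row)
    cols = ["gene", "votes_up", "datasets_up", "stress_flagged",
            "depletion_status", "in_signature"]
    out = pd.DataFrame(rows, columns=cols if not rows else None)
    return out.reindex(columns=[c for c in cols if c in out.columns or not rows])
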