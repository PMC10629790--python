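"""End-to-end convenience drivers tying the stages together.

``run_association`` is the voxel arm: restrict samples by structure label,
apply the sequential probe filters on the pooled donor table, correlate every
surviving probe with the t-map per donor (MEM-adjusted Spearman), combine
donors with weighted Z and average probes to gene level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .association import (
    CombinedGeneTable,
    combine_probe_results,
    donor_association,
    gene_level,
)
from .expression import DonorExpression, filter_probes, filter_samples, pool_donors
from .glm import TMap

__all__ = ["AssociationRun", "run_association", "ranking_auc"]


@dataclass
class AssociationRun:
    genes: CombinedGeneTable
    probe_table: pd.DataFrame
    filter_counts: dict[str, int]
    n_probes_kept: int


def run_association(
    donors: list[DonorExpression],
    tmap: TMap,
    hemisphere: str | None = "L",
    cortical: bool | None = True,
    min_cortical_samples: int | None = None,
    mem_k: int | None = None,
    mem_rule: str = "half",
    weight_scheme: str = "n",
) -> AssociationRun:
    """Full voxel-arm association from donor tables to a per-gene table.

    ``min_cortical_samples`` defaults to half the pooled cortical sample
    count, so the background rule scales with the synthetic cohort size the
    way a fixed count does against a fixed atlas.
    """
    restricted = [
        filter_samples(d, hemisphere=hemisphere, cortical=cortical) for d in donors
    ]
    restricted = [d for d in restricted if d.n_samples > 0]
    if not restricted:
        raise ValueError("no samples survive the structure-label restriction")
    pooled = pool_donors(restricted)
    if min_cortical_samples is None:
        n_cort = int(pooled.samples["cortical"].sum())
        min_cortical_samples = n_cort // 2
    filtered, counts = filter_probes(pooled, min_cortical_samples=min_cortical_samples)
    keep_ids = set(filtered.probes["probe_id"])
    results = []
    for d in restricted:
        keep = np.flatnonzero(d.probes["probe_id"].isin(keep_ids).to_numpy())
        sub = d.take_probes(keep)
        results.append(
            donor_association(sub, tmap, mem_k=mem_k, mem_rule=mem_rule)
        )
    probe_table = combine_probe_results(results, weight_scheme=weight_scheme)
    genes = gene_level(probe_table)
    return AssociationRun(
        genes=genes,
        probe_table=probe_table,
        filter_counts=counts,
        n_probes_kept=len(filtered.probes),
    )


def ranking_auc(scores: pd.Series, positives: list[str], negatives: list[str]) -> float:
    """AUC of a signed score for separating two labelled gene sets.

    Probability (with tie correction) that a random positive gene outranks a
    random negative one.
    """
    pos = scores.reindex(positives).dropna().to_numpy()
    neg = scores.reindex(negatives).dropna().to_numpy()
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both gene sets must be non-empty and scored")
    from scipy.stats import mannwhitneyu

    u = mannwhitneyu(pos, neg, alternative="two-sided").statistic
    return float(u / (len(pos) * len(neg)))
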