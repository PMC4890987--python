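"""Differentially expressed protein pool and candidate-network assembly.

The pool is selected by a one-way ANOVA per protein across sample-group
labels (young vs elderly by default; any grouping carried by the sample
labels works, e.g. gender strata).  The candidate GEN is then restricted to
the pool: edges survive only if their protein/gene endpoints are pooled, and
miRNAs are retained only while they still target at least one pooled gene.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import EDGE_TYPES, CandidateGEN, CohortDataset

logger = logging.getLogger(__name__)


def anova_pvalues(datasets: Sequence[CohortDataset]) -> pd.Series:
    """Per-node one-way ANOVA p-values across the group labels of ``datasets``.

    Nodes with zero within-group variance in every group have an undefined F
    statistic and are assigned p = 1 (and logged).
    """
    combined = CohortDataset.concat(list(datasets))
    expr = combined.proteins
    labels = combined.sample_groups.loc[expr.columns]
    groups = sorted(set(labels))
    if len(groups) < 2:
        raise ValueError("need at least two groups for ANOVA")
    blocks = [expr.loc[:, (labels == g).to_numpy()].to_numpy() for g in groups]
    if any(b.shape[1] < 2 for b in blocks):
        raise ValueError("need at least 2 samples per group")
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.f_oneway(*blocks, axis=1)
    pvals = np.asarray(res.pvalue, dtype=float)
    degenerate = np.all(
        [np.ptp(b, axis=1) == 0 for b in blocks], axis=0
    ) | ~np.isfinite(pvals)
    if degenerate.any():
        bad = [n for n, d in zip(expr.index, degenerate) if d]
        logger.warning(
            "ANOVA undefined for %d node(s) (zero within-group variance): %s",
            len(bad), ", ".join(bad[:10]),
        )
        pvals[degenerate] = 1.0
    return pd.Series(pvals, index=expr.index, name="p")


def select_protein_pool(
    datasets: Sequence[CohortDataset], alpha: float = 0.05
) -> set[str]:
    """Nodes whose expression differs across groups at level ``alpha``.

    For two groups the F statistic equals the square of the pooled-variance
    t statistic, so this reduces to a two-sample t-test selection.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    pvals = anova_pvalues(datasets)
    return set(pvals.index[pvals < alpha])


def assemble_candidate_gen(
    pool: Iterable[str],
    edges: pd.DataFrame,
    node_ids: Sequence[str],
    mirna_ids: Sequence[str],
) -> CandidateGEN:
    """Restrict a raw edge table to the protein pool.

    ``edges`` has columns source, target, edge_type with edge_type in
    {ppi, tf, mirna}.  Duplicates collapse, PPI self-pairs are dropped, and
    miRNAs are kept only while they target at least one pooled gene.
    Unknown edge types raise with the offending row index.
    """
    pool = set(pool)
    bad = ~edges["edge_type"].isin(EDGE_TYPES)
    if bad.any():
        row = edges.index[bad][0]
        raise ValueError(
            f"unknown edge_type {edges.loc[row, 'edge_type']!r} at row {row}"
        )
    ppi: set[tuple[str, str]] = set()
    tf: set[tuple[str, str]] = set()
    mirna: set[tuple[str, str]] = set()
    for source, target, etype in edges[["source", "target", "edge_type"]].itertuples(
        index=False
    ):
        if etype == "ppi":
            if source == target:
                continue
            if source in pool and target in pool:
                ppi.add(tuple(sorted((source, target))))
        elif etype == "tf":
            if source in pool and target in pool:
                tf.add((source, target))
        else:
            if target in pool:
                mirna.add((source, target))
    kept_mirnas = {m for m, _ in mirna}
    cand = CandidateGEN(
        ppi_edges=ppi,
        tf_edges=tf,
        mirna_edges=mirna,
        node_ids=sorted(pool & set(node_ids)),
        mirna_ids=[m for m in mirna_ids if m in kept_mirnas],
    )
    cand.validate()
    return cand
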