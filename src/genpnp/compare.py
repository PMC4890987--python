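"""Differential core-network analysis between two cohorts.

The intersection of two cohorts' core GENs is the common core GEN; the set
differences are the cohort-specific core GENs.  Two candidate annotations
are derived on top: nodes whose fitted basal levels k_i differ between the
cohorts (a DNA-methylation surrogate, tested by a two-estimate z-test on the
least-squares standard errors) and nodes whose expression differs between
the cohorts (a mutation surrogate, tested by a pooled-variance t-test).
Both are emitted as candidate annotations, not biological claims.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import CohortDataset, CoreGEN, GENComparison, IdentifiedGEN

logger = logging.getLogger(__name__)


def compare_core_gens(core_a: CoreGEN, core_b: CoreGEN) -> GENComparison:
    """Node- and edge-level intersection/differences of two core GENs."""
    nodes_a, nodes_b = core_a.members, core_b.members
    edges_a, edges_b = core_a.edge_set(), core_b.edge_set()
    return GENComparison(
        group_a=core_a.group,
        group_b=core_b.group,
        common_nodes=nodes_a & nodes_b,
        specific_nodes_a=nodes_a - nodes_b,
        specific_nodes_b=nodes_b - nodes_a,
        common_edges=edges_a & edges_b,
        specific_edges_a=edges_a - edges_b,
        specific_edges_b=edges_b - edges_a,
    )


def flag_methylation_candidates(
    gen_a: IdentifiedGEN,
    gen_b: IdentifiedGEN,
    alpha: float = 0.05,
    model: str = "grn",
    abs_threshold: float | None = None,
) -> pd.DataFrame:
    """Nodes whose basal level differs between cohorts — methylation candidates.

    Tests z = (k_a - k_b) / sqrt(se_a^2 + se_b^2) against the standard
    normal (two-sided); flags p < alpha.  ``model='ppi'`` tests h instead of
    k.  With ``abs_threshold`` set, flags |delta| >= threshold instead of
    the z-test.  Nodes lacking a basal SE in either fit are skipped with a
    warning.
    """
    a = gen_a.basal_levels(model)
    b = gen_b.basal_levels(model)
    shared = sorted(set(a.index) & set(b.index))
    rows = []
    for node in shared:
        ka, sa = a.loc[node, "estimate"], a.loc[node, "se"]
        kb, sb = b.loc[node, "estimate"], b.loc[node, "se"]
        if not np.isfinite(sa) or not np.isfinite(sb):
            logger.warning("node %s lacks a basal SE; skipped", node)
            continue
        delta = ka - kb
        pooled = np.sqrt(sa**2 + sb**2)
        if pooled > 0:
            z = delta / pooled
            p = 2.0 * stats.norm.sf(abs(z))
        else:
            z = np.inf * np.sign(delta) if delta != 0 else 0.0
            p = 0.0 if delta != 0 else 1.0
        if abs_threshold is not None:
            flagged = bool(abs(delta) >= abs_threshold)
        else:
            flagged = bool(p < alpha)
        rows.append((node, ka, sa, kb, sb, delta, z, p, flagged))
    return pd.DataFrame(
        rows,
        columns=[
            "node", "basal_a", "se_a", "basal_b", "se_b",
            "delta", "z", "p", "flagged",
        ],
    )


def flag_differential_expression(
    data_a: CohortDataset, data_b: CohortDataset, alpha: float = 0.05
) -> pd.DataFrame:
    """Per-node pooled-variance two-sample t-test between cohorts.

    Flags p < alpha; nodes with zero pooled variance get t = 0, p = 1
    (logged).  Differentially expressed core genes are mutation candidates
    in the aging interpretation.
    """
    if data_a.n_samples < 2 or data_b.n_samples < 2:
        raise ValueError("need at least 2 samples per cohort")
    shared = [n for n in data_a.proteins.index if n in set(data_b.proteins.index)]
    xa = data_a.proteins.loc[shared].to_numpy(dtype=float)
    xb = data_b.proteins.loc[shared].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.ttest_ind(xa, xb, axis=1, equal_var=True)
    t = np.asarray(res.statistic, dtype=float)
    p = np.asarray(res.pvalue, dtype=float)
    degenerate = ~np.isfinite(t)
    if degenerate.any():
        logger.warning(
            "zero pooled variance for %d node(s); p set to 1", int(degenerate.sum())
        )
        t[degenerate] = 0.0
        p[degenerate] = 1.0
    return pd.DataFrame(
        {"node": shared, "t": t, "p": p, "flagged": p < alpha}
    )
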