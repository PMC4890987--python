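"""Support-recovery evaluation against a known ground truth.

Two evaluation designs are provided:

* ``joint_recovery`` runs the full identification stage on a jointly
  simulated cohort — the pipeline's own data path.  Note that on such data
  the association model's product regressors y_i * y_j contain the response
  y_i itself, so the regressors are correlated with the regression noise;
  association decoys are retained far above the nominal level (see the
  methods note).
* ``faithful_recovery`` identifies each target on its own
  regression-faithful draw (exogenous regressors), the design classical
  least-squares inference assumes; it is the appropriate design for
  parameter- and support-recovery claims.
"""

from __future__ import annotations

import logging

from .datatypes import CandidateGEN
from .identification import build_grn_problem, build_ppi_problem, detect_order_and_prune
from .synthetic import GroundTruth, simulate_cohort, simulate_faithful_target

logger = logging.getLogger(__name__)

Edge = tuple[str, str, str]


def support_metrics(recovered: set[Edge], true: set[Edge]) -> dict[str, float]:
    """Edge-level false discovery rate and sensitivity of a recovered support."""
    tp = len(recovered & true)
    fp = len(recovered - true)
    fn = len(true - recovered)
    return {
        "tp": tp,
        "fp": fp,
        "fn": fn,
        "fdr": fp / max(1, tp + fp),
        "sensitivity": tp / max(1, tp + fn),
    }


def joint_recovery(
    gt: GroundTruth,
    candidates: CandidateGEN,
    group: str,
    n: int,
    seed: int,
    alpha: float = 0.05,
) -> set[Edge]:
    """Recovered support from the identification stage on one joint cohort."""
    from .identification import identify_gen

    data = simulate_cohort(gt, group, n, seed)
    return identify_gen(data, candidates, alpha).edge_set()


def faithful_recovery(
    gt: GroundTruth,
    candidates: CandidateGEN,
    group: str,
    n: int,
    seed: int,
    alpha: float = 0.05,
) -> set[Edge]:
    """Recovered support, one regression-faithful draw per target."""
    recovered: set[Edge] = set()
    for offset, target in enumerate(gt.node_ids):
        data = simulate_faithful_target(gt, target, group, n, seed + offset)
        for builder in (build_ppi_problem, build_grn_problem):
            fit = detect_order_and_prune(builder(target, data, candidates), alpha)
            for lab in fit.labels:
                if lab.kind != "basal":
                    recovered.add((lab.ref, target, lab.kind))
    return recovered
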