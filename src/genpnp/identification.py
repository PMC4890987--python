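"""System identification of the GEN: least squares, AIC order detection, pruning.

Each target is fitted independently ("one protein/gene by one protein/gene"):

* association model — response y_i, one design column y_i * y_j per candidate
  partner j, plus intercept; the coefficient on column j is the association
  ability a_ij and the intercept is the basal level h_i;
* regulatory model — response x_i, one column y_j per candidate TF, one
  column -mir_l per candidate miRNA (so the fitted coefficient is the
  repression ability c_il under the positive-c-means-repression convention),
  plus intercept k_i.

Order detection is backward elimination ranked by |t|: starting from the
full candidate model, the weakest non-intercept regressor is removed and the
model refitted until only the intercept remains; the model minimising
AIC = n ln(RSS/n) + 2p over the visited nested path is selected, after which
a single Student's t-test sweep removes any remaining regressor with
p >= alpha.  The intercept (basal level) is never pruned.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import (
    BASAL,
    BASAL_COLUMNS,
    EDGE_COLUMNS,
    CandidateGEN,
    CohortDataset,
    FitResult,
    IdentifiedGEN,
    RegressionProblem,
    RegressorLabel,
)

logger = logging.getLogger(__name__)

_RANK_TOL = 1e-10


def build_ppi_problem(
    target: str, data: CohortDataset, candidates: CandidateGEN
) -> RegressionProblem:
    """Association regression for one protein: y_i on {y_i*y_j} + intercept."""
    proteins = data.proteins
    if target not in proteins.index:
        raise KeyError(f"target {target!r} missing from expression data")
    partners = candidates.ppi_partners(target)
    missing = [p for p in partners if p not in proteins.index]
    if missing:
        raise KeyError(f"candidate partner(s) missing from data: {missing}")
    y_i = proteins.loc[target].to_numpy(dtype=float)
    cols = [y_i * proteins.loc[j].to_numpy(dtype=float) for j in partners]
    cols.append(np.ones_like(y_i))
    labels = [RegressorLabel("ppi", j) for j in partners] + [BASAL]
    problem = RegressionProblem(
        target_id=target,
        response=y_i,
        design=np.column_stack(cols),
        labels=labels,
    )
    problem.validate()
    return problem


def build_grn_problem(
    target: str, data: CohortDataset, candidates: CandidateGEN
) -> RegressionProblem:
    """Regulatory regression for one gene: x_i on {y_j, -mir_l} + intercept."""
    if target not in data.gene_expr.index:
        raise KeyError(f"target {target!r} missing from expression data")
    tfs = [j for j in candidates.tf_regulators(target) if j != target]
    mirs = candidates.mirna_regulators(target)
    proteins = data.proteins
    missing = [j for j in tfs if j not in proteins.index] + [
        l for l in mirs if l not in data.mirna_expr.index
    ]
    if missing:
        raise KeyError(f"candidate regulator(s) missing from data: {missing}")
    x_i = data.gene_expr.loc[target].to_numpy(dtype=float)
    cols = [proteins.loc[j].to_numpy(dtype=float) for j in tfs]
    cols += [-data.mirna_expr.loc[l].to_numpy(dtype=float) for l in mirs]
    cols.append(np.ones_like(x_i))
    labels = (
        [RegressorLabel("tf", j) for j in tfs]
        + [RegressorLabel("mirna", l) for l in mirs]
        + [BASAL]
    )
    problem = RegressionProblem(
        target_id=target,
        response=x_i,
        design=np.column_stack(cols),
        labels=labels,
    )
    problem.validate()
    return problem


def aic_score(rss: float, n: int, p: int) -> float:
    """Gaussian-likelihood AIC up to constants: n ln(RSS/n) + 2p.

    A perfect fit (RSS = 0) returns -inf so it dominates any imperfect one.
    """
    if n <= 0 or p < 0 or rss < 0:
        raise ValueError("need n > 0, p >= 0, rss >= 0")
    if rss == 0.0:
        logger.debug("AIC sentinel: perfect fit (rss=0, p=%d)", p)
        return -math.inf
    return n * math.log(rss / n) + 2 * p


def _independent_columns(X: np.ndarray) -> list[int]:
    """Greedy left-to-right selection of linearly independent columns.

    Guarantees the deterministic rightmost-first drop policy: a column is
    dropped iff it lies in the span of the columns before it.
    """
    kept: list[int] = []
    for j in range(X.shape[1]):
        cols = X[:, kept + [j]]
        if np.linalg.matrix_rank(cols, tol=_RANK_TOL * max(1.0, np.abs(cols).max())) == len(kept) + 1:
            kept.append(j)
    return kept


def least_squares_fit(problem: RegressionProblem) -> FitResult:
    """Ordinary least squares with classical normal-theory inference.

    Standard errors use the unbiased residual variance RSS/(n-p); t
    statistics are estimate/SE and p-values come from Student's t with n-p
    degrees of freedom.  Constant non-intercept columns (collinear with the
    intercept) and linearly dependent columns are dropped deterministically
    (rightmost first) before fitting, with a logged warning.
    """
    y = np.asarray(problem.response, dtype=float)
    X = np.asarray(problem.design, dtype=float)
    labels = list(problem.labels)
    n = y.shape[0]

    dropped: list[tuple[RegressorLabel, str]] = []
    keep = []
    for j, lab in enumerate(labels):
        if lab.kind != "basal" and np.ptp(X[:, j]) == 0:
            dropped.append((lab, "constant"))
            logger.warning("dropping constant regressor %s for %s", lab, problem.target_id)
        else:
            keep.append(j)
    X, labels = X[:, keep], [labels[j] for j in keep]

    # fast path: a QR with a well-conditioned R means full column rank
    R = np.linalg.qr(X, mode="r")
    diag = np.abs(np.diag(R))
    if diag.min() > _RANK_TOL * max(1.0, diag.max()):
        indep = list(range(X.shape[1]))
    else:
        indep = _independent_columns(X)
    if len(indep) < X.shape[1]:
        dep = [labels[j] for j in range(X.shape[1]) if j not in indep]
        for lab in dep:
            dropped.append((lab, "collinear"))
        logger.warning(
            "dropping %d collinear regressor(s) for %s: %s",
            len(dep), problem.target_id, ", ".join(map(str, dep)),
        )
        X, labels = X[:, indep], [labels[j] for j in indep]

    p = X.shape[1]
    if n <= p:
        raise ValueError(
            f"{problem.target_id}: {n} samples cannot identify {p} parameters; "
            "reduce the candidate set"
        )

    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    rss = float(resid @ resid)
    dof = n - p
    sigma2 = rss / dof
    # a residual sd below 1e-8 of the response RMS is numerically a perfect
    # fit; floor it so numerically-zero coefficients do not test significant
    floor = (1e-8 * np.sqrt(np.mean(y**2))) ** 2
    sigma2 = max(sigma2, floor)
    xtx_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(np.maximum(sigma2 * np.diag(xtx_inv), 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, coef / np.where(se > 0, se, 1.0), np.where(coef != 0, np.inf * np.sign(coef), 0.0))
    pvals = 2.0 * stats.t.sf(np.abs(t), dof)

    return FitResult(
        target_id=problem.target_id,
        labels=labels,
        estimates=coef,
        se=se,
        t=t,
        p=pvals,
        rss=rss,
        n_samples=n,
        n_params=p,
        aic=aic_score(rss, n, p),
        dropped=dropped,
    )


def _subproblem(problem: RegressionProblem, labels: list[RegressorLabel]) -> RegressionProblem:
    cols = [problem.labels.index(lab) for lab in labels]
    return RegressionProblem(
        target_id=problem.target_id,
        response=problem.response,
        design=problem.design[:, cols],
        labels=labels,
    )


def detect_order_and_prune(
    problem: RegressionProblem, alpha: float = 0.05
) -> FitResult:
    """Backward-elimination order detection plus a final t-test sweep.

    Visits the nested model path obtained by repeatedly removing the
    non-intercept regressor with the smallest |t| (ties broken toward the
    lexicographically last label), selects the minimal-AIC model on that
    path (ties toward the smaller model), then removes every remaining
    regressor with p >= alpha and refits once.  Eliminated regressors are
    recorded with their reason ('aic' or 'ttest').
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    fit = least_squares_fit(problem)
    path = [fit]
    current = fit
    while any(lab.kind != "basal" for lab in current.labels):
        abs_t = {
            lab: abs(current.t[j])
            for j, lab in enumerate(current.labels)
            if lab.kind != "basal"
        }
        min_t = min(abs_t.values())
        # ties on |t|: drop the lexicographically last label
        victim = max(lab for lab, t_abs in abs_t.items() if t_abs == min_t)
        remaining = [lab for lab in current.labels if lab != victim]
        current = least_squares_fit(_subproblem(problem, remaining))
        path.append(current)

    aics = [f.aic for f in path]
    best_aic = min(aics)
    best_idx = max(i for i, a in enumerate(aics) if a == best_aic)
    selected = path[best_idx]
    kept_labels = set(selected.labels)
    aic_eliminated = [
        (lab, "aic")
        for lab in path[0].labels
        if lab not in kept_labels and lab.kind != "basal"
    ]

    survivors = [
        lab
        for j, lab in enumerate(selected.labels)
        if lab.kind == "basal" or selected.p[j] < alpha
    ]
    ttest_eliminated = [
        (lab, "ttest")
        for lab in selected.labels
        if lab not in survivors and lab.kind != "basal"
    ]
    if len(survivors) < len(selected.labels):
        selected = least_squares_fit(_subproblem(problem, survivors))

    selected.dropped = path[0].dropped
    selected.eliminated = aic_eliminated + ttest_eliminated
    return selected


def identify_gen(
    data: CohortDataset, candidates: CandidateGEN, alpha: float = 0.05
) -> IdentifiedGEN:
    """Fit and prune both models for every node of the candidate GEN.

    Per-target failures are logged and skipped; the run fails only if every
    target fails.  Deterministic given its inputs.
    """
    group_labels = data.groups()
    group = group_labels[0] if len(group_labels) == 1 else "+".join(group_labels)
    edge_rows: list[tuple] = []
    basal_rows: list[tuple] = []
    n_failed = 0
    targets = [node for node in candidates.node_ids if node in data.gene_expr.index]
    if not targets:
        raise ValueError("no candidate node present in the expression data")
    for node in targets:
        for model, builder in (("ppi", build_ppi_problem), ("grn", build_grn_problem)):
            try:
                fit = detect_order_and_prune(builder(node, data, candidates), alpha)
            except Exception:
                logger.exception("identification failed for %s (%s model)", node, model)
                n_failed += 1
                continue
            for j, lab in enumerate(fit.labels):
                if lab.kind == "basal":
                    basal_rows.append(
                        (node, model, float(fit.estimates[j]), float(fit.se[j]),
                         fit.residual_var)
                    )
                else:
                    edge_rows.append(
                        (node, lab.ref, lab.kind, float(fit.estimates[j]),
                         float(fit.se[j]), float(fit.t[j]), float(fit.p[j]))
                    )
    if n_failed == 2 * len(targets):
        raise RuntimeError("identification failed for every target")
    return IdentifiedGEN(
        group=group,
        node_ids=list(candidates.node_ids),
        mirna_ids=list(candidates.mirna_ids),
        edges=pd.DataFrame(edge_rows, columns=EDGE_COLUMNS),
        basal=pd.DataFrame(basal_rows, columns=BASAL_COLUMNS),
    )
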