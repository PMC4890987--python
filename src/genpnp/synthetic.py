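"""Ground-truth network generation and forward simulation of cohort expression.

The generator emulates the statistical structure the identification stage
assumes: a sparse true GEN (PPI associations a, TF regulations b, miRNA
repressions c), basal levels (h for the association model, group-specific k
for the regulatory model — the group shifts act as DNA-methylation
surrogates), a candidate edge superset contaminated with decoys standing in
for database false positives, and two cohorts of unequal size with planted
differential expression.

Forward model per sample n:

* miRNA profiles mir_l(n) are i.i.d. log-normal (expression-like positivity).
* protein profiles solve the association consistency relation
  y_i = (h_i + v_i) / (1 - sum_j a_ij y_j), iterated Gauss-Seidel to a fixed
  point; draws where any denominator comes within 0.2 of zero are rejected
  as ill-conditioned.
* gene profiles follow x_i = sum_j b_ij y_j - sum_l c_il mir_l + k_i + w_i
  with Gaussian noise w.
* differentially expressed nodes receive an additive group mean shift on
  their protein profile before x is formed, so the shift propagates through
  the regulatory model; the shift is exogenous to the network parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .datatypes import BASAL_COLUMNS, EDGE_COLUMNS, CandidateGEN, CohortDataset, IdentifiedGEN

_FIXED_POINT_TOL = 1e-8
_FIXED_POINT_MAX_PASSES = 100
_STABILITY_BOUND = 0.2


@dataclass
class SimulationConfig:
    """Study-design knobs for the synthetic GEN and its cohorts.

    Defaults mirror a two-cohort aging study: 30 young and 146 elderly
    samples, a candidate network with half of its edges false, modest noise
    relative to basal expression on the order of 1.
    """

    n_nodes: int = 100
    n_mirnas: int = 20
    n_samples: Mapping[str, int] = field(
        default_factory=lambda: {"young": 30, "elderly": 146}
    )
    ppi_density: float = 0.04
    tf_density: float = 0.15
    mirna_density: float = 0.15
    tf_fraction: float = 0.2
    fp_fraction: float = 0.5
    a_range: tuple[float, float] = (0.01, 0.05)
    b_range: tuple[float, float] = (0.3, 1.0)
    c_range: tuple[float, float] = (0.3, 1.0)
    h_range: tuple[float, float] = (0.5, 1.5)
    k_range: tuple[float, float] = (0.5, 1.5)
    methylation_fraction: float = 0.1
    methylation_shift: float = 1.0
    de_fraction: float = 0.1
    de_shift: float = 0.3
    noise_sd: float = 0.1
    mirna_log_mean: float = 0.0
    mirna_log_sd: float = 0.5
    max_ppi_partners: int = 8
    max_tf_regulators: int = 6
    max_mirna_regulators: int = 6
    seed: int = 0

    def validate(self) -> None:
        if self.n_nodes <= 0 or self.n_mirnas <= 0:
            raise ValueError("node and miRNA counts must be positive")
        if any(n <= 0 for n in self.n_samples.values()) or len(self.n_samples) < 1:
            raise ValueError("sample counts must be positive")
        if not 0.0 <= self.fp_fraction < 1.0:
            raise ValueError("fp_fraction must lie in [0, 1)")
        for name in ("ppi_density", "tf_density", "mirna_density"):
            d = getattr(self, name)
            if not 0.0 <= d <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if not 0.0 < self.tf_fraction <= 1.0:
            raise ValueError("tf_fraction must lie in (0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        n_tfs = max(1, round(self.tf_fraction * self.n_nodes))
        expected = {
            "PPI partners": (self.ppi_density * (self.n_nodes - 1), self.max_ppi_partners),
            "TF regulators": (self.tf_density * n_tfs, self.max_tf_regulators),
            "miRNA regulators": (self.mirna_density * self.n_mirnas, self.max_mirna_regulators),
        }
        for what, (exp, cap) in expected.items():
            if exp > cap:
                raise ValueError(
                    f"density implies ~{exp:.1f} {what} per target, above the "
                    f"configured maximum {cap}"
                )

    @property
    def groups(self) -> list[str]:
        return list(self.n_samples)


@dataclass
class GroundTruth:
    """True network parameters underlying a simulated study.

    ``true_ppi`` is keyed by sorted node pairs (the association ability is
    symmetric by pair); ``true_tf_reg`` and ``true_mirna_reg`` by
    (regulator, target).  ``basal_gene`` maps each group label to its k
    vector; groups differ exactly on ``methylation_nodes``.
    """

    node_ids: list[str]
    mirna_ids: list[str]
    tf_ids: list[str]
    true_ppi: dict[tuple[str, str], float]
    true_tf_reg: dict[tuple[str, str], float]
    true_mirna_reg: dict[tuple[str, str], float]
    basal_protein: pd.Series
    basal_gene: dict[str, pd.Series]
    methylation_nodes: set[str]
    de_nodes: set[str]
    de_group: str
    de_shift: float
    noise_sd: float
    mirna_log_mean: float
    mirna_log_sd: float

    @property
    def groups(self) -> list[str]:
        return list(self.basal_gene)

    def ppi_partners(self, node: str) -> list[str]:
        return sorted(
            v if u == node else u for u, v in self.true_ppi if node in (u, v)
        )

    def edge_set(self) -> set[tuple[str, str, str]]:
        """All true edges as (regulator, target, type); PPI in both directions."""
        out: set[tuple[str, str, str]] = set()
        for (u, v) in self.true_ppi:
            out.add((u, v, "ppi"))
            out.add((v, u, "ppi"))
        out.update((s, t, "tf") for s, t in self.true_tf_reg)
        out.update((m, t, "mirna") for m, t in self.true_mirna_reg)
        return out

    def ability_frame(self) -> pd.DataFrame:
        """Long-format table of true abilities (source, target, edge_type, ability)."""
        rows = [
            {"source": u, "target": v, "edge_type": "ppi", "ability": a}
            for (u, v), a in sorted(self.true_ppi.items())
        ]
        rows += [
            {"source": s, "target": t, "edge_type": "tf", "ability": b}
            for (s, t), b in sorted(self.true_tf_reg.items())
        ]
        rows += [
            {"source": m, "target": t, "edge_type": "mirna", "ability": c}
            for (m, t), c in sorted(self.true_mirna_reg.items())
        ]
        return pd.DataFrame(rows, columns=["source", "target", "edge_type", "ability"])


def _signed_uniform(rng: np.random.Generator, lo: float, hi: float, size: int) -> np.ndarray:
    return rng.uniform(lo, hi, size) * rng.choice([-1.0, 1.0], size)


def _cap_ppi_degree(
    edges: list[tuple[int, int]], cap: int, rng: np.random.Generator
) -> list[tuple[int, int]]:
    """Drop random incident edges until every node has at most ``cap`` partners."""
    degree: dict[int, int] = {}
    for u, v in edges:
        degree[u] = degree.get(u, 0) + 1
        degree[v] = degree.get(v, 0) + 1
    keep = set(edges)
    for node in sorted(degree):
        while degree.get(node, 0) > cap:
            incident = sorted(e for e in keep if node in e)
            drop = incident[rng.integers(len(incident))]
            keep.discard(drop)
            for end in drop:
                degree[end] -= 1
    return sorted(keep)


def generate_ground_truth(config: SimulationConfig) -> GroundTruth:
    """Draw a sparse true GEN with group-specific basal levels and DE nodes.

    Deterministic given ``config.seed``.  Raises ValueError when the edge
    densities imply per-target regulator counts above the configured maxima.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    N, O = config.n_nodes, config.n_mirnas
    node_ids = [f"G{i:04d}" for i in range(1, N + 1)]
    mirna_ids = [f"mir-{l:03d}" for l in range(1, O + 1)]
    n_tfs = max(1, round(config.tf_fraction * N))
    tf_idx = sorted(rng.choice(N, size=n_tfs, replace=False))
    tf_ids = [node_ids[i] for i in tf_idx]

    # PPI: Bernoulli(density) on unordered pairs, then per-node degree cap.
    upper = np.triu(rng.random((N, N)) < config.ppi_density, k=1)
    pair_list = [(int(i), int(j)) for i, j in zip(*np.nonzero(upper))]
    pair_list = _cap_ppi_degree(pair_list, config.max_ppi_partners, rng)
    a_vals = _signed_uniform(rng, *config.a_range, len(pair_list))
    true_ppi = {
        (node_ids[i], node_ids[j]): float(a) for (i, j), a in zip(pair_list, a_vals)
    }

    # TF regulations: Bernoulli per (tf, target), per-target count cap.
    true_tf: dict[tuple[str, str], float] = {}
    for t in range(N):
        cands = [s for s in tf_idx if s != t and rng.random() < config.tf_density]
        if len(cands) > config.max_tf_regulators:
            cands = sorted(
                rng.choice(cands, size=config.max_tf_regulators, replace=False)
            )
        for s in cands:
            true_tf[(node_ids[s], node_ids[t])] = float(
                _signed_uniform(rng, *config.b_range, 1)[0]
            )

    # miRNA repressions: positive c (repression enters the model as -c*mir).
    true_mirna: dict[tuple[str, str], float] = {}
    for t in range(N):
        cands = [l for l in range(O) if rng.random() < config.mirna_density]
        if len(cands) > config.max_mirna_regulators:
            cands = sorted(
                rng.choice(cands, size=config.max_mirna_regulators, replace=False)
            )
        for l in cands:
            true_mirna[(mirna_ids[l], node_ids[t])] = float(
                rng.uniform(*config.c_range)
            )

    h = pd.Series(rng.uniform(*config.h_range, N), index=node_ids, name="h")
    k_base = pd.Series(rng.uniform(*config.k_range, N), index=node_ids, name="k")
    groups = config.groups
    n_meth = round(config.methylation_fraction * N)
    meth_nodes = set(
        node_ids[i] for i in sorted(rng.choice(N, size=n_meth, replace=False))
    )
    basal_gene = {groups[0]: k_base.copy()}
    for g in groups[1:]:
        k_g = k_base.copy()
        for node in sorted(meth_nodes):
            k_g[node] += config.methylation_shift * rng.choice([-1.0, 1.0])
        basal_gene[g] = k_g

    n_de = round(config.de_fraction * N)
    de_nodes = set(node_ids[i] for i in sorted(rng.choice(N, size=n_de, replace=False)))
    de_group = groups[-1] if len(groups) > 1 else groups[0]

    return GroundTruth(
        node_ids=node_ids,
        mirna_ids=mirna_ids,
        tf_ids=tf_ids,
        true_ppi=true_ppi,
        true_tf_reg=true_tf,
        true_mirna_reg=true_mirna,
        basal_protein=h,
        basal_gene=basal_gene,
        methylation_nodes=meth_nodes,
        de_nodes=de_nodes,
        de_group=de_group,
        de_shift=config.de_shift,
        noise_sd=config.noise_sd,
        mirna_log_mean=config.mirna_log_mean,
        mirna_log_sd=config.mirna_log_sd,
    )


def emit_candidate_network(
    gt: GroundTruth, fp_fraction: float, seed: int
) -> CandidateGEN:
    """Contaminate the true edge sets with decoys, database-style.

    ``fp_fraction`` is the fraction of emitted candidates that are false:
    round(n_true * fp / (1 - fp)) decoys are drawn uniformly from the
    complement of the true set (same typing rules: decoy TF edges keep TF
    sources, no self-pairs), so every true edge is always a candidate.
    """
    if not 0.0 <= fp_fraction < 1.0:
        raise ValueError("fp_fraction must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    nodes, mirnas, tfs = gt.node_ids, gt.mirna_ids, gt.tf_ids

    def n_decoys(n_true: int) -> int:
        return round(n_true * fp_fraction / (1.0 - fp_fraction))

    ppi = {tuple(sorted(e)) for e in gt.true_ppi}
    pool = [
        (nodes[i], nodes[j])
        for i in range(len(nodes))
        for j in range(i + 1, len(nodes))
        if (nodes[i], nodes[j]) not in ppi
    ]
    picks = rng.choice(len(pool), size=min(n_decoys(len(ppi)), len(pool)), replace=False)
    ppi |= {pool[i] for i in picks}

    tf = set(gt.true_tf_reg)
    pool = [(s, t) for s in tfs for t in nodes if s != t and (s, t) not in tf]
    picks = rng.choice(len(pool), size=min(n_decoys(len(tf)), len(pool)), replace=False)
    tf |= {pool[i] for i in picks}

    mir = set(gt.true_mirna_reg)
    pool = [(m, t) for m in mirnas for t in nodes if (m, t) not in mir]
    picks = rng.choice(len(pool), size=min(n_decoys(len(mir)), len(pool)), replace=False)
    mir |= {pool[i] for i in picks}

    cand = CandidateGEN(
        ppi_edges=ppi, tf_edges=tf, mirna_edges=mir,
        node_ids=list(nodes), mirna_ids=list(mirnas),
    )
    cand.validate()
    return cand


def _solve_association_fixed_point(
    A: np.ndarray, h_plus_v: np.ndarray
) -> np.ndarray:
    """Gauss-Seidel iteration of y_i = (h_i + v_i) / (1 - sum_j a_ij y_j).

    A is the symmetric ability matrix (zero diagonal); h_plus_v is N x n.
    Raises RuntimeError if the iteration fails to converge or any
    denominator violates the conditioning bound.
    """
    y = h_plus_v.copy()
    active = np.nonzero(np.abs(A).sum(axis=1) > 0)[0]
    for _ in range(_FIXED_POINT_MAX_PASSES):
        delta = 0.0
        for i in active:
            denom = 1.0 - A[i] @ y
            if np.any(np.abs(denom) < _STABILITY_BOUND):
                raise RuntimeError(
                    "association fixed point ill-conditioned: |1 - sum a_ij y_j| "
                    f"< {_STABILITY_BOUND} at node index {i}"
                )
            new = h_plus_v[i] / denom
            delta = max(delta, float(np.max(np.abs(new - y[i]))))
            y[i] = new
        if delta < _FIXED_POINT_TOL:
            break
    else:
        raise RuntimeError("association fixed point did not converge in 100 passes")
    return y


def simulate_cohort(
    gt: GroundTruth, group: str, n: int, seed: int
) -> CohortDataset:
    """Forward-simulate one cohort of ``n`` samples from the true GEN."""
    if group not in gt.basal_gene:
        raise ValueError(f"group {group!r} has no basal gene levels")
    if n < 2:
        raise ValueError("need at least 2 samples")
    rng = np.random.default_rng(seed)
    N, O = len(gt.node_ids), len(gt.mirna_ids)
    idx = {g: i for i, g in enumerate(gt.node_ids)}
    midx = {m: l for l, m in enumerate(gt.mirna_ids)}

    mir = rng.lognormal(gt.mirna_log_mean, gt.mirna_log_sd, size=(O, n))

    A = np.zeros((N, N))
    for (u, v), a in gt.true_ppi.items():
        A[idx[u], idx[v]] = a
        A[idx[v], idx[u]] = a
    B = np.zeros((N, N))
    for (s, t), b in gt.true_tf_reg.items():
        B[idx[t], idx[s]] = b
    C = np.zeros((N, O))
    for (m, t), c in gt.true_mirna_reg.items():
        C[idx[t], midx[m]] = c

    h = gt.basal_protein.to_numpy()[:, None]
    v = rng.normal(0.0, gt.noise_sd, size=(N, n)) if gt.noise_sd > 0 else np.zeros((N, n))
    y = _solve_association_fixed_point(A, h + v)

    if group == gt.de_group and gt.de_nodes:
        de_rows = [idx[g] for g in sorted(gt.de_nodes)]
        y[de_rows] += gt.de_shift

    k = gt.basal_gene[group].to_numpy()[:, None]
    w = rng.normal(0.0, gt.noise_sd, size=(N, n)) if gt.noise_sd > 0 else np.zeros((N, n))
    x = B @ y - C @ mir + k + w

    samples = [f"{group}_{j + 1:03d}" for j in range(n)]
    data = CohortDataset(
        gene_expr=pd.DataFrame(x, index=gt.node_ids, columns=samples),
        mirna_expr=pd.DataFrame(mir, index=gt.mirna_ids, columns=samples),
        sample_groups=pd.Series(group, index=samples),
        protein_expr=pd.DataFrame(y, index=gt.node_ids, columns=samples),
    )
    data.validate()
    return data


def simulate_faithful_target(
    gt: GroundTruth, target: str, group: str, n: int, seed: int
) -> CohortDataset:
    """Regression-faithful draw for one target: exogenous regressor profiles.

    All protein profiles are drawn freely (log-normal), except the target's
    own, which is set by the solved association form
    y_t = (h_t + v_t) / (1 - sum_j a_tj y_j); gene profiles are then computed
    from the regulatory model using the observed protein matrix.  Both of
    the target's regressions therefore hold exactly up to their independent
    noise terms, with regressors independent of that noise — the design the
    classical least-squares theory assumes.  Other nodes' association
    relations do *not* hold; use the returned dataset for ``target`` only.
    """
    if group not in gt.basal_gene:
        raise ValueError(f"group {group!r} has no basal gene levels")
    rng = np.random.default_rng(seed)
    N, O = len(gt.node_ids), len(gt.mirna_ids)
    idx = {g: i for i, g in enumerate(gt.node_ids)}
    midx = {m: l for l, m in enumerate(gt.mirna_ids)}
    y = rng.lognormal(gt.mirna_log_mean, gt.mirna_log_sd, size=(N, n))
    mir = rng.lognormal(gt.mirna_log_mean, gt.mirna_log_sd, size=(O, n))

    acc = np.zeros(n)
    for p in gt.ppi_partners(target):
        acc += gt.true_ppi[tuple(sorted((target, p)))] * y[idx[p]]
    denom = 1.0 - acc
    if np.any(np.abs(denom) < _STABILITY_BOUND):
        raise RuntimeError("solved form ill-conditioned for this draw")
    v = rng.normal(0.0, gt.noise_sd, size=n) if gt.noise_sd > 0 else np.zeros(n)
    y[idx[target]] = (gt.basal_protein[target] + v) / denom

    B = np.zeros((N, N))
    for (s, t), b in gt.true_tf_reg.items():
        B[idx[t], idx[s]] = b
    C = np.zeros((N, O))
    for (m, t), c in gt.true_mirna_reg.items():
        C[idx[t], midx[m]] = c
    k = gt.basal_gene[group].to_numpy()[:, None]
    w = rng.normal(0.0, gt.noise_sd, size=(N, n)) if gt.noise_sd > 0 else np.zeros((N, n))
    x = B @ y - C @ mir + k + w

    samples = [f"s{j + 1:03d}" for j in range(n)]
    return CohortDataset(
        gene_expr=pd.DataFrame(x, index=gt.node_ids, columns=samples),
        mirna_expr=pd.DataFrame(mir, index=gt.mirna_ids, columns=samples),
        sample_groups=pd.Series(group, index=samples),
        protein_expr=pd.DataFrame(y, index=gt.node_ids, columns=samples),
    )


def plant_dominant_regulators(
    gt: GroundTruth,
    n_regulators: int = 5,
    out_degree: int = 4,
    scale: float = 10.0,
    seed: int = 0,
) -> list[str]:
    """Rewire ``n_regulators`` TFs to dominate the network, in place.

    Each designated TF gets exactly ``out_degree`` targets with regulatory
    ability magnitude ``scale`` times the maximum magnitude of the ability
    ranges (signs random), replacing its previous out-edges.  Equal
    out-degrees give the planted rows comparable energy so the projection
    stage should rank all of them above every background regulator.
    Returns the designated TF ids.
    """
    rng = np.random.default_rng(seed)
    if n_regulators > len(gt.tf_ids):
        raise ValueError("not enough TFs to designate")
    chosen = [str(s) for s in rng.choice(gt.tf_ids, n_regulators, replace=False)]
    background = [
        abs(b) for (s, _), b in gt.true_tf_reg.items() if s not in chosen
    ] + [abs(a) for a in gt.true_ppi.values()] + list(gt.true_mirna_reg.values())
    magnitude = scale * max(background, default=1.0)
    for (s, t) in [e for e in gt.true_tf_reg if e[0] in chosen]:
        del gt.true_tf_reg[(s, t)]
    for s in chosen:
        pool = [t for t in gt.node_ids if t != s]
        targets = rng.choice(pool, out_degree, replace=False)
        for t in targets:
            gt.true_tf_reg[(s, str(t))] = float(magnitude * rng.choice([-1.0, 1.0]))
    return chosen


def ground_truth_gen(gt: GroundTruth, group: str) -> IdentifiedGEN:
    """Cast the true network as an IdentifiedGEN (zero SEs, p = 0).

    Convenient for exercising the projection stage against known abilities.
    """
    rows = []
    for (u, v), a in sorted(gt.true_ppi.items()):
        rows.append((u, v, "ppi", a))
        rows.append((v, u, "ppi", a))
    rows += [(t, s, "tf", b) for (s, t), b in sorted(gt.true_tf_reg.items())]
    rows += [(t, m, "mirna", c) for (m, t), c in sorted(gt.true_mirna_reg.items())]
    edges = pd.DataFrame(rows, columns=["target", "regulator", "edge_type", "ability"])
    edges["se"] = 0.0
    edges["t"] = np.inf
    edges["p"] = 0.0
    basal_rows = [
        (node, "ppi", float(gt.basal_protein[node]), 0.0, gt.noise_sd**2)
        for node in gt.node_ids
    ] + [
        (node, "grn", float(gt.basal_gene[group][node]), 0.0, gt.noise_sd**2)
        for node in gt.node_ids
    ]
    return IdentifiedGEN(
        group=group,
        node_ids=list(gt.node_ids),
        mirna_ids=list(gt.mirna_ids),
        edges=edges[EDGE_COLUMNS],
        basal=pd.DataFrame(basal_rows, columns=BASAL_COLUMNS),
    )
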