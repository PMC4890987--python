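"""Principal network projection: SVD of the stacked ability matrix.

The identified abilities are stacked into the network matrix H of shape
(2N+O) x N — association rows, TF rows, then miRNA rows (carrying -c).  A
thin SVD H = U D V^T yields the eigen-expression fractions
E_m = d_m^2 / sum d^2; the top M right singular vectors are kept, M minimal
with cumulative energy >= 0.85 by default.  Each row k is scored by its
projection S(k, m) = h_k . v_m and its 2-norm distance
D(k) = sqrt(sum_m S(k, m)^2); rows far from zero load on the principal
network structure.  Core membership applies a class-specific threshold:
th1 on association rows, th2 on TF rows, th3 on miRNA rows.
"""

from __future__ import annotations

import numpy as np

from .datatypes import CoreGEN, IdentifiedGEN, NetworkMatrix, PNPResult

_ROW_CLASS_THRESHOLD = {"ppi": 0, "tf": 1, "mirna": 2}

#: (th1, th2, th3) used for each cohort in the aging study these methods
#: reproduce; no selection rule was given, so they are plain constants
COHORT_THRESHOLDS = {
    "young": (4.0, 0.015, 0.01),
    "elderly": (0.6, 0.35, 0.03),
    "elderly_women": (0.5, 0.4, 0.1),
    "elderly_men": (0.8, 0.003, 0.003),
}


def build_network_matrix(gen: IdentifiedGEN) -> NetworkMatrix:
    """Stack identified abilities into H ((2N+O) x N); pruned entries stay 0.

    H[j, i] = a_ij for association rows, H[N+j, i] = b_ij for TF rows and
    H[2N+l, i] = -c_il for miRNA rows, with i the target column.  Duplicate
    (regulator, target, type) entries raise.
    """
    N, O = len(gen.node_ids), len(gen.mirna_ids)
    idx = {g: i for i, g in enumerate(gen.node_ids)}
    midx = {m: l for l, m in enumerate(gen.mirna_ids)}
    H = np.zeros((2 * N + O, N))
    seen: set[tuple[str, str, str]] = set()
    for target, regulator, etype, ability in gen.edges[
        ["target", "regulator", "edge_type", "ability"]
    ].itertuples(index=False):
        key = (regulator, target, etype)
        if key in seen:
            raise ValueError(f"duplicate edge entry {key}")
        seen.add(key)
        col = idx[target]
        if etype == "ppi":
            H[idx[regulator], col] = ability
        elif etype == "tf":
            H[N + idx[regulator], col] = ability
        elif etype == "mirna":
            H[2 * N + midx[regulator], col] = -ability
        else:
            raise ValueError(f"unknown edge_type {etype!r}")
    row_labels = (
        [("ppi", g) for g in gen.node_ids]
        + [("tf", g) for g in gen.node_ids]
        + [("mirna", m) for m in gen.mirna_ids]
    )
    return NetworkMatrix(H=H, row_labels=row_labels, col_labels=list(gen.node_ids))


def pnp_decompose(nm: NetworkMatrix, energy: float = 0.85) -> PNPResult:
    """Thin SVD of H with minimal-M energy selection.

    E_m = d_m^2 / sum d^2 and M is the smallest count whose cumulative
    eigen-expression fraction reaches ``energy``.  An all-zero H has no
    decomposition and raises.
    """
    if not 0.0 < energy <= 1.0:
        raise ValueError("energy must lie in (0, 1]")
    H = nm.H
    if not np.any(H):
        raise ValueError("network matrix is all-zero; nothing to decompose")
    _, d, Vt = np.linalg.svd(H, full_matrices=False)
    fractions = d**2 / np.sum(d**2)
    cumulative = np.cumsum(fractions)
    M = int(np.argmax(cumulative >= energy - 1e-12)) + 1
    return PNPResult(
        singular_values=d,
        eigen_fractions=fractions,
        M=M,
        V=Vt.T,
        row_labels=list(nm.row_labels),
        col_labels=list(nm.col_labels),
        energy=energy,
    )


def project_and_score(result: PNPResult, nm: NetworkMatrix) -> PNPResult:
    """Fill projection scores S(k, m) = h_k . v_m and distances D(k)."""
    V_top = result.V[:, : result.M]
    scores = nm.H @ V_top
    result.scores = scores
    result.distances = np.sqrt(np.sum(scores**2, axis=1))
    return result


def thresholds_from_quantile(
    result: PNPResult, q: float = 0.9
) -> tuple[float, float, float]:
    """Quantile-based (th1, th2, th3): the q-quantile of D among the nonzero
    rows of each class (zero rows carry no network content).  A class with
    no nonzero row gets threshold inf (no core rows)."""
    if result.distances is None:
        raise ValueError("distances not computed; run project_and_score first")
    out = []
    classes = np.array([r[0] for r in result.row_labels])
    for cls in ("ppi", "tf", "mirna"):
        d = result.distances[(classes == cls) & (result.distances > 0)]
        out.append(float(np.quantile(d, q)) if d.size else np.inf)
    return tuple(out)


def extract_core(
    result: PNPResult,
    gen: IdentifiedGEN,
    th1: float,
    th2: float,
    th3: float,
) -> CoreGEN:
    """Threshold projection distances per row class and induce the core GEN.

    A protein/gene is core if its association row passes th1 or its TF row
    passes th2; a miRNA is core if its row passes th3.  The core subnetwork
    keeps the identified edges whose endpoints are both core.
    """
    if min(th1, th2, th3) < 0:
        raise ValueError("thresholds must be nonnegative")
    if result.distances is None:
        raise ValueError("distances not computed; run project_and_score first")
    ths = (th1, th2, th3)
    frame = result.distance_frame()
    frame["threshold"] = [
        ths[_ROW_CLASS_THRESHOLD[c]] for c in frame["row_class"]
    ]
    # zero-distance rows carry no surviving network content and are never
    # core, so th = 0 selects exactly the rows that load on the projection
    frame["core"] = (frame["distance"] >= frame["threshold"]) & (
        frame["distance"] > 0
    )

    core_rows = frame[frame["core"]]
    core_nodes = set(core_rows.loc[core_rows["row_class"] != "mirna", "row_id"])
    core_mirnas = set(core_rows.loc[core_rows["row_class"] == "mirna", "row_id"])
    members = core_nodes | core_mirnas
    edges = gen.edges[
        gen.edges["regulator"].isin(members) & gen.edges["target"].isin(core_nodes)
    ].reset_index(drop=True)
    return CoreGEN(
        group=gen.group,
        core_nodes=core_nodes,
        core_mirnas=core_mirnas,
        edges=edges,
        scores=frame[["row_id", "row_class", "distance", "core"]],
        thresholds=ths,
    )
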