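"""Shared containers for the GEN identification / projection pipeline.

Conventions used throughout:

* Expression matrices are pandas DataFrames with one row per molecular
  species (protein/gene or miRNA) and one column per sample.
* A GEN (genetic-and-epigenetic network) is the union of three typed edge
  sets over one node universe: undirected protein-protein associations
  (``ppi``), directed TF->gene regulations (``tf``) and directed
  miRNA->gene repressions (``mirna``).
* miRNA repression abilities ``c`` are stored with the model's sign
  convention: repression enters the gene-regulatory model as ``-c * mir``,
  so a positive ``c`` denotes inhibition.  The stacked network matrix H
  carries the negated value ``-c`` in its miRNA block.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd

EDGE_TYPES = ("ppi", "tf", "mirna")

#: column layout of the identified-network edge table
EDGE_COLUMNS = ["target", "regulator", "edge_type", "ability", "se", "t", "p"]
#: column layout of the basal-level table ('model' is 'ppi' for h, 'grn' for k)
BASAL_COLUMNS = ["node", "model", "estimate", "se", "residual_var"]


class RegressorLabel(NamedTuple):
    """Typed label of one design-matrix column.

    kind is one of ``ppi`` (association partner), ``tf`` (transcription
    factor), ``mirna`` (repressor) or ``basal`` (intercept); ``ref`` names
    the regulator, or is the empty string for the intercept.
    """

    kind: str
    ref: str

    def __str__(self) -> str:  # pragma: no cover - repr convenience
        return f"{self.kind}:{self.ref}" if self.ref else self.kind


BASAL = RegressorLabel("basal", "")


@dataclass
class CohortDataset:
    """Expression matrices plus sample-group labels for one (or a pooled) cohort.

    ``gene_expr`` holds the gene-regulatory responses x_i(n); ``protein_expr``
    holds the protein-association profiles y_i(n).  When a study provides a
    single matrix (gene expression overlaid onto proteins by identity),
    ``protein_expr`` may be left as None and ``proteins`` falls back to
    ``gene_expr``.
    """

    gene_expr: pd.DataFrame
    mirna_expr: pd.DataFrame
    sample_groups: pd.Series
    protein_expr: Optional[pd.DataFrame] = None

    @property
    def node_ids(self) -> list[str]:
        return list(self.gene_expr.index)

    @property
    def mirna_ids(self) -> list[str]:
        return list(self.mirna_expr.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.gene_expr.columns)

    @property
    def proteins(self) -> pd.DataFrame:
        """Protein-association profiles (identity overlay if not distinct)."""
        return self.gene_expr if self.protein_expr is None else self.protein_expr

    @property
    def n_samples(self) -> int:
        return self.gene_expr.shape[1]

    def groups(self) -> list[str]:
        return sorted(set(self.sample_groups))

    def validate(self) -> None:
        if self.gene_expr.shape[1] != self.mirna_expr.shape[1]:
            raise ValueError("gene and miRNA matrices have different sample counts")
        if list(self.gene_expr.columns) != list(self.mirna_expr.columns):
            raise ValueError("gene and miRNA matrices have different sample ids")
        if self.protein_expr is not None and list(self.protein_expr.columns) != list(
            self.gene_expr.columns
        ):
            raise ValueError("protein and gene matrices have different sample ids")
        for name, frame in (("gene", self.gene_expr), ("miRNA", self.mirna_expr)):
            if frame.index.has_duplicates:
                raise ValueError(f"duplicate {name} identifiers")
            if not np.isfinite(frame.to_numpy()).all():
                raise ValueError(f"non-finite entries in {name} expression")
        missing = set(self.gene_expr.columns) - set(self.sample_groups.index)
        if missing:
            raise ValueError(f"samples without group label: {sorted(missing)}")

    @staticmethod
    def concat(datasets: Sequence["CohortDataset"]) -> "CohortDataset":
        """Column-concatenate cohorts sharing the same node/miRNA universe."""
        first = datasets[0]
        for d in datasets[1:]:
            if d.node_ids != first.node_ids or d.mirna_ids != first.mirna_ids:
                raise ValueError("cohorts do not share a node universe")
        return CohortDataset(
            gene_expr=pd.concat([d.gene_expr for d in datasets], axis=1),
            mirna_expr=pd.concat([d.mirna_expr for d in datasets], axis=1),
            sample_groups=pd.concat([d.sample_groups for d in datasets]),
            protein_expr=(
                None
                if all(d.protein_expr is None for d in datasets)
                else pd.concat([d.proteins for d in datasets], axis=1)
            ),
        )


@dataclass
class CandidateGEN:
    """Database-style candidate edge superset over a shared node universe.

    ``ppi_edges`` holds unordered pairs stored as sorted tuples; ``tf_edges``
    and ``mirna_edges`` hold (regulator, target) ordered pairs.
    """

    ppi_edges: set[tuple[str, str]]
    tf_edges: set[tuple[str, str]]
    mirna_edges: set[tuple[str, str]]
    node_ids: list[str]
    mirna_ids: list[str]

    def validate(self) -> None:
        nodes, mirnas = set(self.node_ids), set(self.mirna_ids)
        for u, v in self.ppi_edges:
            if u == v:
                raise ValueError(f"self-association {u}")
            if u not in nodes or v not in nodes:
                raise ValueError(f"ppi endpoint outside node universe: ({u},{v})")
        for s, t in self.tf_edges:
            if s not in nodes or t not in nodes:
                raise ValueError(f"tf edge endpoint outside node universe: ({s},{t})")
        for m, t in self.mirna_edges:
            if m not in mirnas or t not in nodes:
                raise ValueError(f"mirna edge endpoint unknown: ({m},{t})")

    def n_edges(self) -> int:
        return len(self.ppi_edges) + len(self.tf_edges) + len(self.mirna_edges)

    def ppi_partners(self, node: str) -> list[str]:
        out = {v if u == node else u for u, v in self.ppi_edges if node in (u, v)}
        return sorted(out)

    def tf_regulators(self, node: str) -> list[str]:
        return sorted({s for s, t in self.tf_edges if t == node})

    def mirna_regulators(self, node: str) -> list[str]:
        return sorted({m for m, t in self.mirna_edges if t == node})


@dataclass
class RegressionProblem:
    """One target's least-squares problem: response over samples, typed design."""

    target_id: str
    response: np.ndarray
    design: np.ndarray
    labels: list[RegressorLabel]

    def validate(self) -> None:
        if self.design.shape[0] != self.response.shape[0]:
            raise ValueError("design row count != response length")
        if self.design.shape[1] != len(self.labels):
            raise ValueError("design column count != label count")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("duplicate regressor labels")
        if sum(1 for lab in self.labels if lab.kind == "basal") != 1:
            raise ValueError("exactly one intercept column required")


@dataclass
class FitResult:
    """Classical linear-model fit of one target's regression problem."""

    target_id: str
    labels: list[RegressorLabel]
    estimates: np.ndarray
    se: np.ndarray
    t: np.ndarray
    p: np.ndarray
    rss: float
    n_samples: int
    n_params: int
    aic: float
    #: columns removed before/without fitting: (label, reason)
    dropped: list[tuple[RegressorLabel, str]] = field(default_factory=list)
    #: regressors eliminated by order detection / pruning: (label, reason)
    eliminated: list[tuple[RegressorLabel, str]] = field(default_factory=list)

    @property
    def residual_var(self) -> float:
        dof = self.n_samples - self.n_params
        return self.rss / dof if dof > 0 else float("nan")

    def coef(self, label: RegressorLabel) -> float:
        return float(self.estimates[self.labels.index(label)])

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "kind": [lab.kind for lab in self.labels],
                "ref": [lab.ref for lab in self.labels],
                "estimate": self.estimates,
                "se": self.se,
                "t": self.t,
                "p": self.p,
            }
        )


@dataclass
class IdentifiedGEN:
    """Pruned network with fitted abilities, basal levels and uncertainties."""

    group: str
    node_ids: list[str]
    mirna_ids: list[str]
    #: columns per EDGE_COLUMNS; 'ability' is a for ppi, b for tf, c for mirna
    edges: pd.DataFrame
    #: columns per BASAL_COLUMNS; model 'ppi' stores h_i, 'grn' stores k_i
    basal: pd.DataFrame

    def edge_set(self) -> set[tuple[str, str, str]]:
        return set(
            zip(self.edges["regulator"], self.edges["target"], self.edges["edge_type"])
        )

    def basal_levels(self, model: str) -> pd.DataFrame:
        """Basal estimates for one model ('ppi' -> h, 'grn' -> k), indexed by node."""
        sub = self.basal[self.basal["model"] == model]
        return sub.set_index("node")[["estimate", "se"]]


@dataclass
class NetworkMatrix:
    """Stacked ability matrix H of shape (2N+O) x N.

    Rows 0..N-1 are association profiles (entry a[target, partner]), rows
    N..2N-1 TF-regulation profiles (b[target, tf]), rows 2N..2N+O-1 miRNA
    profiles carrying the negated repression ability (-c[target, mirna]).
    Columns index target nodes.
    """

    H: np.ndarray
    row_labels: list[tuple[str, str]]
    col_labels: list[str]

    @property
    def n_nodes(self) -> int:
        return len(self.col_labels)

    @property
    def n_mirnas(self) -> int:
        return self.H.shape[0] - 2 * self.n_nodes

    def row_class(self, k: int) -> str:
        return self.row_labels[k][0]


@dataclass
class PNPResult:
    """SVD projection of a network matrix onto its leading components."""

    singular_values: np.ndarray
    eigen_fractions: np.ndarray
    M: int
    V: np.ndarray
    row_labels: list[tuple[str, str]]
    col_labels: list[str]
    energy: float
    scores: Optional[np.ndarray] = None
    distances: Optional[np.ndarray] = None

    def distance_frame(self) -> pd.DataFrame:
        if self.distances is None:
            raise ValueError("distances not computed; run project_and_score first")
        return pd.DataFrame(
            {
                "row_id": [r[1] for r in self.row_labels],
                "row_class": [r[0] for r in self.row_labels],
                "distance": self.distances,
            }
        )

    def components_frame(self) -> pd.DataFrame:
        cum = np.cumsum(self.eigen_fractions)
        return pd.DataFrame(
            {
                "m": np.arange(1, len(self.singular_values) + 1),
                "singular_value": self.singular_values,
                "eigen_fraction": self.eigen_fractions,
                "cumulative": cum,
            }
        )


@dataclass
class CoreGEN:
    """Core subnetwork extracted by row-class projection-distance thresholds."""

    group: str
    core_nodes: set[str]
    core_mirnas: set[str]
    #: induced subset of the identified edge table (both endpoints core)
    edges: pd.DataFrame
    #: per-row distances with core flags (row_id, row_class, distance, core)
    scores: pd.DataFrame
    thresholds: tuple[float, float, float]

    @property
    def members(self) -> set[str]:
        return self.core_nodes | self.core_mirnas

    def edge_set(self) -> set[tuple[str, str, str]]:
        return set(
            zip(self.edges["regulator"], self.edges["target"], self.edges["edge_type"])
        )


@dataclass
class GENComparison:
    """Common / specific core networks of two cohorts plus candidate flags."""

    group_a: str
    group_b: str
    common_nodes: set[str]
    specific_nodes_a: set[str]
    specific_nodes_b: set[str]
    common_edges: set[tuple[str, str, str]]
    specific_edges_a: set[tuple[str, str, str]]
    specific_edges_b: set[tuple[str, str, str]]
    #: basal-level (k_i) shift test per node — DNA-methylation candidates
    methylation: Optional[pd.DataFrame] = None
    #: two-sample expression test per node — mutation candidates
    mutation: Optional[pd.DataFrame] = None

    def methylation_candidates(self) -> set[str]:
        if self.methylation is None:
            return set()
        return set(self.methylation.loc[self.methylation["flagged"], "node"])

    def mutation_candidates(self) -> set[str]:
        if self.mutation is None:
            return set()
        return set(self.mutation.loc[self.mutation["flagged"], "node"])
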