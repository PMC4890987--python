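"""Delimited-text round-trip for every pipeline artifact.

All tables are tab-separated with a header row.  Expression tables have one
row per node/miRNA (index column ``id``) and one column per sample; edge
lists carry source, target, edge_type; identified networks and basal levels
use the column layouts of :mod:`genpnp.datatypes`.
"""

from __future__ import annotations

from pathlib import Path
from typing import Union

import pandas as pd

from .datatypes import BASAL_COLUMNS, EDGE_COLUMNS, CandidateGEN, CohortDataset, IdentifiedGEN

PathLike = Union[str, Path]
_SEP = "\t"


def write_matrix(frame: pd.DataFrame, path: PathLike) -> None:
    # %.17g round-trips float64 exactly, so stages rerun from files
    # reproduce in-memory results bit for bit
    frame.to_csv(path, sep=_SEP, index_label="id", float_format="%.17g")


def read_matrix(path: PathLike) -> pd.DataFrame:
    frame = pd.read_csv(path, sep=_SEP, index_col="id", float_precision="round_trip")
    frame.index.name = None
    return frame


def write_group_map(groups: pd.Series, path: PathLike) -> None:
    groups.rename("group").to_csv(path, sep=_SEP, index_label="sample")


def read_group_map(path: PathLike) -> pd.Series:
    frame = pd.read_csv(path, sep=_SEP, index_col="sample")
    frame.index.name = None
    return frame["group"].rename(None)


def write_cohort(data: CohortDataset, prefix: PathLike) -> dict[str, Path]:
    """Write a cohort as <prefix>.{genes,mirnas,proteins,groups}.tsv."""
    prefix = Path(prefix)
    paths = {
        "genes": prefix.with_suffix(".genes.tsv"),
        "mirnas": prefix.with_suffix(".mirnas.tsv"),
        "groups": prefix.with_suffix(".groups.tsv"),
    }
    write_matrix(data.gene_expr, paths["genes"])
    write_matrix(data.mirna_expr, paths["mirnas"])
    write_group_map(data.sample_groups, paths["groups"])
    if data.protein_expr is not None:
        paths["proteins"] = prefix.with_suffix(".proteins.tsv")
        write_matrix(data.protein_expr, paths["proteins"])
    return paths


def read_cohort(prefix: PathLike) -> CohortDataset:
    prefix = Path(prefix)
    protein_path = prefix.with_suffix(".proteins.tsv")
    data = CohortDataset(
        gene_expr=read_matrix(prefix.with_suffix(".genes.tsv")),
        mirna_expr=read_matrix(prefix.with_suffix(".mirnas.tsv")),
        sample_groups=read_group_map(prefix.with_suffix(".groups.tsv")),
        protein_expr=read_matrix(protein_path) if protein_path.exists() else None,
    )
    data.validate()
    return data


def candidate_to_frame(cand: CandidateGEN) -> pd.DataFrame:
    rows = (
        [(u, v, "ppi") for u, v in sorted(cand.ppi_edges)]
        + [(s, t, "tf") for s, t in sorted(cand.tf_edges)]
        + [(m, t, "mirna") for m, t in sorted(cand.mirna_edges)]
    )
    return pd.DataFrame(rows, columns=["source", "target", "edge_type"])


def write_candidate(cand: CandidateGEN, path: PathLike) -> None:
    candidate_to_frame(cand).to_csv(path, sep=_SEP, index=False)


def read_edge_table(path: PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep=_SEP)


def frame_to_candidate(
    frame: pd.DataFrame, node_ids: list[str], mirna_ids: list[str]
) -> CandidateGEN:
    cand = CandidateGEN(
        ppi_edges={
            tuple(sorted((s, t)))
            for s, t in frame.loc[frame["edge_type"] == "ppi", ["source", "target"]]
            .itertuples(index=False)
            if s != t
        },
        tf_edges={
            (s, t)
            for s, t in frame.loc[frame["edge_type"] == "tf", ["source", "target"]]
            .itertuples(index=False)
        },
        mirna_edges={
            (s, t)
            for s, t in frame.loc[frame["edge_type"] == "mirna", ["source", "target"]]
            .itertuples(index=False)
        },
        node_ids=node_ids,
        mirna_ids=mirna_ids,
    )
    cand.validate()
    return cand


def write_pool(pool: set[str], path: PathLike) -> None:
    Path(path).write_text("".join(f"{node}\n" for node in sorted(pool)))


def read_pool(path: PathLike) -> set[str]:
    return {line.strip() for line in Path(path).read_text().splitlines() if line.strip()}


def write_identified(gen: IdentifiedGEN, edges_path: PathLike, basal_path: PathLike) -> None:
    gen.edges.to_csv(edges_path, sep=_SEP, index=False)
    gen.basal.to_csv(basal_path, sep=_SEP, index=False)


def read_identified(
    edges_path: PathLike,
    basal_path: PathLike,
    group: str,
    node_ids: list[str],
    mirna_ids: list[str],
) -> IdentifiedGEN:
    edges = pd.read_csv(edges_path, sep=_SEP)
    if edges.empty:
        edges = pd.DataFrame(columns=EDGE_COLUMNS)
    basal = pd.read_csv(basal_path, sep=_SEP)
    if basal.empty:
        basal = pd.DataFrame(columns=BASAL_COLUMNS)
    return IdentifiedGEN(
        group=group, node_ids=node_ids, mirna_ids=mirna_ids,
        edges=edges[EDGE_COLUMNS], basal=basal[BASAL_COLUMNS],
    )


def write_table(frame: pd.DataFrame, path: PathLike) -> None:
    frame.to_csv(path, sep=_SEP, index=False)


def read_table(path: PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep=_SEP)
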