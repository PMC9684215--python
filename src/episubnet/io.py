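"""Readers and writers for the pipeline's tabular text formats."""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from .diffnet import DifferentialNetwork, InteractionNetwork, OmicsMatrix
from .survival import SurvivalTable

logger = logging.getLogger(__name__)

__all__ = [
    "read_omics_matrix",
    "read_conditions",
    "read_ppi",
    "read_survival",
    "write_edge_table",
    "write_module_table",
    "write_eigengenes",
]


def read_conditions(path: str | Path) -> pd.Series:
    """Sample -> condition mapping from a two-column TSV (sample, condition)."""
    tab = pd.read_csv(path, sep="\t", dtype=str)
    if tab.shape[1] < 2:
        raise ValueError("condition file needs columns (sample, condition)")
    return pd.Series(tab.iloc[:, 1].to_numpy(), index=tab.iloc[:, 0].to_numpy())


def read_omics_matrix(matrix_path: str | Path, conditions: str | Path | pd.Series | dict) -> OmicsMatrix:
    """Load a gene x sample TSV (first column gene id, header = sample ids).

    Genes with any missing entry are dropped (logged) since the Pearson and
    SVD stages assume complete data.
    """
    frame = pd.read_csv(matrix_path, sep="\t", index_col=0)
    frame.index = frame.index.astype(str)
    n_missing = int(frame.isna().any(axis=1).sum())
    if n_missing:
        logger.warning("dropping %d gene(s) with missing values", n_missing)
        frame = frame.dropna(axis=0)
    if isinstance(conditions, (str, Path)):
        conditions = read_conditions(conditions)
    return OmicsMatrix.from_dataframe(frame, conditions)


def read_ppi(path: str | Path) -> InteractionNetwork:
    """Edge list: two whitespace/tab-separated gene symbols per line.

    Extra columns are ignored; lines starting with '#' are comments.
    """
    edges = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 2:
                raise ValueError(f"malformed edge line: {line!r}")
            edges.append((parts[0], parts[1]))
    return InteractionNetwork(edges)


def read_survival(path: str | Path) -> SurvivalTable:
    """CSV with columns (patient_id, time_days, event)."""
    tab = pd.read_csv(path)
    return SurvivalTable(tab)


def write_edge_table(dn: DifferentialNetwork, path: str | Path) -> None:
    cols = ["gene_a", "gene_b", "z", "weight", "p", "p_adj", "significant"]
    dn.edges.sort_values(["gene_a", "gene_b"])[cols].to_csv(path, sep="\t", index=False)


def write_module_table(modset, path: str | Path) -> None:
    modset.gene_table().sort_values(["module_id", "gene"]).to_csv(path, sep="\t", index=False)


def write_eigengenes(eigengenes: pd.DataFrame, var_explained: pd.Series, path: str | Path) -> None:
    path = Path(path)
    eigengenes.sort_index().to_csv(path, sep="\t", index_label="module_id")
    var_explained.sort_index().to_csv(
        path.with_suffix(".var_explained.tsv"), sep="\t", index_label="module_id"
    )
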