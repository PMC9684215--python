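"""Differential co-expression / co-methylation networks on a PPI scaffold.

A differential network re-weights the edges of a protein--protein
interaction (PPI) network by how strongly the correlation of the two
incident genes *changes* between tumor and normal samples.  Per edge, the
Pearson correlations in each condition are Fisher-transformed and compared
with the classical two-sample z statistic

    Z = (F(rho_t) - F(rho_n)) / sqrt(1/(n_t-3) + 1/(n_n-3)),

whose absolute value becomes the edge weight.  Edges are tested against the
standard normal null, Benjamini-Hochberg corrected across all tested edges,
and genes that show no significant differential co-expression with any
differentially expressed gene are removed before module detection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

TUMOR = "tumor"
NORMAL = "normal"

__all__ = [
    "TUMOR",
    "NORMAL",
    "OmicsMatrix",
    "InteractionNetwork",
    "DifferentialNetwork",
    "fisher_transform",
    "differential_z",
    "edge_pvalue",
    "detect_de_genes",
    "build_differential_network",
    "to_similarity_matrix",
]


@dataclass
class OmicsMatrix:
    """A gene x sample omics matrix with a tumor/normal label per sample.

    ``values[i, j]`` is the measurement (log-normalised expression, or a
    methylation beta/M value) of gene ``gene_ids[i]`` in sample
    ``sample_ids[j]``; ``condition[j]`` is ``"tumor"`` or ``"normal"``.
    """

    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]
    condition: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.condition = np.asarray(self.condition, dtype=object)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D gene x sample matrix")
        n_genes, n_samples = self.values.shape
        if len(self.gene_ids) != n_genes:
            raise ValueError("gene_ids length does not match values")
        if len(self.sample_ids) != n_samples or len(self.condition) != n_samples:
            raise ValueError("sample_ids/condition length does not match values")
        dupes = pd.Index(self.gene_ids)[pd.Index(self.gene_ids).duplicated()]
        if len(dupes):
            raise ValueError(f"duplicate gene ids: {sorted(set(dupes))}")
        bad = set(self.condition) - {TUMOR, NORMAL}
        if bad:
            raise ValueError(f"unknown condition labels: {sorted(bad)}")
        for cond in (TUMOR, NORMAL):
            n = int(np.sum(self.condition == cond))
            if 0 < n < 4:
                raise ValueError(
                    f"need at least 4 {cond} samples for the differential "
                    f"z statistic, got {n}"
                )
        if np.isnan(self.values).any():
            raise ValueError("values contain missing entries; drop or impute at load")

    @property
    def n_tumor(self) -> int:
        return int(np.sum(self.condition == TUMOR))

    @property
    def n_normal(self) -> int:
        return int(np.sum(self.condition == NORMAL))

    def condition_values(self, cond: str) -> np.ndarray:
        """Sub-matrix of the samples with the given condition label."""
        return self.values[:, self.condition == cond]

    def tumor_frame(self) -> pd.DataFrame:
        mask = self.condition == TUMOR
        return pd.DataFrame(
            self.values[:, mask],
            index=self.gene_ids,
            columns=[s for s, m in zip(self.sample_ids, mask) if m],
        )

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, condition: dict[str, str] | pd.Series) -> "OmicsMatrix":
        cond = pd.Series(condition).reindex(frame.columns)
        if cond.isna().any():
            missing = list(frame.columns[cond.isna()])
            raise ValueError(f"no condition label for samples: {missing}")
        return cls(
            values=frame.to_numpy(dtype=float),
            gene_ids=[str(g) for g in frame.index],
            sample_ids=[str(s) for s in frame.columns],
            condition=cond.to_numpy(),
        )


class InteractionNetwork:
    """Undirected gene-gene interaction network (e.g. a PPI network)."""

    def __init__(self, edges: Iterable[tuple[str, str]]):
        g = nx.Graph()
        for a, b in edges:
            a, b = str(a), str(b)
            if a == b:
                continue  # self-interactions carry no co-expression signal
            g.add_edge(a, b)
        self.graph = g

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set[frozenset[str]]:
        return {frozenset(e) for e in self.graph.edges}

    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def has_edge(self, a: str, b: str) -> bool:
        return self.graph.has_edge(a, b)

    def subgraph_edges(self, genes: Sequence[str]) -> list[tuple[str, str]]:
        """Edges with both endpoints in ``genes``, sorted for determinism."""
        keep = set(genes)
        out = []
        for a, b in self.graph.edges:
            if a in keep and b in keep:
                out.append(tuple(sorted((a, b))))
        return sorted(out)

    def cross_edge_count(self, set_a: Iterable[str], set_b: Iterable[str]) -> int:
        """Number of edges with one endpoint in each set."""
        sa, sb = set(set_a), set(set_b)
        count = 0
        for a, b in self.graph.edges:
            if (a in sa and b in sb) or (a in sb and b in sa):
                count += 1
        return count

    def __len__(self) -> int:
        return self.graph.number_of_nodes()


@dataclass
class DifferentialNetwork:
    """Weighted differential network plus the post-filter gene set.

    ``edges`` has one row per tested PPI edge with columns
    (gene_a, gene_b, rho_tumor, rho_normal, z, weight, p, p_adj,
    significant); ``retained_genes`` is the sorted gene set that survives
    the DE-anchored filter, and ``de_genes`` records the differentially
    expressed genes used as anchors.
    """

    edges: pd.DataFrame
    retained_genes: list[str]
    de_genes: set[str] = field(default_factory=set)

    def retained_edges(self) -> pd.DataFrame:
        keep = set(self.retained_genes)
        mask = self.edges["gene_a"].isin(keep) & self.edges["gene_b"].isin(keep)
        return self.edges.loc[mask].reset_index(drop=True)


def fisher_transform(rho):
    """Fisher z-transform ``0.5 * ln((1 + rho) / (1 - rho))``.

    Correlations within 1e-12 of +/-1 are clipped (logged); values outside
    [-1, 1] indicate a degenerate correlation and raise.
    """
    r = np.asarray(rho, dtype=float)
    if np.any(np.abs(r) > 1 + 1e-8):
        raise ValueError("correlation outside [-1, 1]: degenerate input")
    limit = 1.0 - 1e-12
    if np.any(np.abs(r) > limit):
        logger.warning("clipping %d correlation(s) at +/-%r", int(np.sum(np.abs(r) > limit)), limit)
        r = np.clip(r, -limit, limit)
    out = np.arctanh(r)
    return float(out) if np.isscalar(rho) else out


def differential_z(rho_t, rho_n, n_t: int, n_n: int):
    """Z statistic for the change in correlation between conditions."""
    if n_t <= 3:
        raise ValueError(f"need more than 3 tumor samples, got {n_t}")
    if n_n <= 3:
        raise ValueError(f"need more than 3 normal samples, got {n_n}")
    denom = np.sqrt(1.0 / (n_t - 3) + 1.0 / (n_n - 3))
    z = (fisher_transform(rho_t) - fisher_transform(rho_n)) / denom
    return float(z) if np.isscalar(rho_t) and np.isscalar(rho_n) else z


def edge_pvalue(z):
    """Two-sided standard-normal p-value ``2 * (1 - Phi(|z|))``."""
    z = np.asarray(z, dtype=float)
    if not np.all(np.isfinite(z)):
        raise ValueError("z statistic must be finite")
    p = 2.0 * stats.norm.sf(np.abs(z))
    return float(p) if p.ndim == 0 else p


def detect_de_genes(omics: OmicsMatrix, fdr: float = 0.05) -> set[str]:
    """Differentially expressed genes by Welch t-test + Benjamini-Hochberg.

    The gene filter of the differential network only needs a defensible DE
    anchor set; an unequal-variance two-sample t-test per gene, BH-corrected
    across genes at ``fdr``, provides it.
    """
    xt = omics.condition_values(TUMOR)
    xn = omics.condition_values(NORMAL)
    res = stats.ttest_ind(xt, xn, axis=1, equal_var=False)
    pvals = np.where(np.isfinite(res.pvalue), res.pvalue, 1.0)
    reject, _, _, _ = multipletests(pvals, alpha=fdr, method="fdr_bh")
    return {g for g, r in zip(omics.gene_ids, reject) if r}


def _pearson_rows(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-standardised matrix and per-row SD (population convention)."""
    mean = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (x - mean) / sd
    return z, sd.ravel()


def build_differential_network(
    omics: OmicsMatrix,
    ppi: InteractionNetwork,
    fdr: float = 0.05,
    de_genes: set[str] | None = None,
) -> DifferentialNetwork:
    """Score every PPI edge among measured genes and filter the gene set.

    Per edge: Pearson correlations in tumor and normal, differential Z,
    two-sided p, BH-adjusted p across all tested edges.  Edges incident to
    a gene with zero variance in either condition are dropped (logged).
    Genes are then retained only if they have at least one significant edge
    (adjusted p < ``fdr``) to a differentially expressed gene; edges touching
    removed genes are pruned from the similarity-matrix view but kept in the
    full edge table.
    """
    genes = sorted(set(omics.gene_ids) & ppi.nodes)
    edges = ppi.subgraph_edges(genes)
    if not edges:
        raise ValueError("no PPI edges among measured genes")

    idx = {g: i for i, g in enumerate(omics.gene_ids)}
    xt = omics.condition_values(TUMOR)
    xn = omics.condition_values(NORMAL)
    n_t, n_n = xt.shape[1], xn.shape[1]
    zt, sd_t = _pearson_rows(xt)
    zn, sd_n = _pearson_rows(xn)
    constant = {
        g for g in genes if sd_t[idx[g]] == 0.0 or sd_n[idx[g]] == 0.0
    }
    if constant:
        logger.warning(
            "dropping edges of %d gene(s) constant in a condition: %s",
            len(constant), sorted(constant)[:10],
        )
        edges = [e for e in edges if e[0] not in constant and e[1] not in constant]
        if not edges:
            raise ValueError("all PPI edges dropped: incident genes are constant")

    ia = np.array([idx[a] for a, _ in edges])
    ib = np.array([idx[b] for _, b in edges])
    rho_t = np.einsum("ij,ij->i", zt[ia], zt[ib]) / n_t
    rho_n = np.einsum("ij,ij->i", zn[ia], zn[ib]) / n_n
    rho_t = np.clip(rho_t, -1.0, 1.0)
    rho_n = np.clip(rho_n, -1.0, 1.0)
    z = differential_z(rho_t, rho_n, n_t, n_n)
    p = edge_pvalue(z)
    reject, p_adj, _, _ = multipletests(p, alpha=fdr, method="fdr_bh")

    table = pd.DataFrame(
        {
            "gene_a": [a for a, _ in edges],
            "gene_b": [b for _, b in edges],
            "rho_tumor": rho_t,
            "rho_normal": rho_n,
            "z": z,
            "weight": np.abs(z),
            "p": p,
            "p_adj": p_adj,
            "significant": reject,
        }
    )

    if de_genes is None:
        de_genes = detect_de_genes(omics, fdr=fdr)
    sig = table.loc[table["significant"]]
    retained: set[str] = set()
    for a, b in zip(sig["gene_a"], sig["gene_b"]):
        if b in de_genes:
            retained.add(a)
        if a in de_genes:
            retained.add(b)
    logger.info(
        "differential network: %d edges tested, %d significant, %d/%d genes retained",
        len(table), int(table["significant"].sum()), len(retained), len(genes),
    )
    return DifferentialNetwork(
        edges=table, retained_genes=sorted(retained), de_genes=set(de_genes)
    )


def to_similarity_matrix(dn: DifferentialNetwork) -> pd.DataFrame:
    """Dense symmetric |Z|-weighted adjacency over the retained genes.

    Entry (i, j) is the edge weight if the (pruned) differential network has
    the edge, else 0; the diagonal is 0.
    """
    genes = sorted(dn.retained_genes)
    if not genes:
        raise ValueError("retained gene set is empty")
    pos = {g: i for i, g in enumerate(genes)}
    a = np.zeros((len(genes), len(genes)))
    for row in dn.retained_edges().itertuples(index=False):
        i, j = pos[row.gene_a], pos[row.gene_b]
        a[i, j] = a[j, i] = row.weight
    return pd.DataFrame(a, index=genes, columns=genes)
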