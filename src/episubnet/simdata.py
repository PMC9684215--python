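"""Synthetic multi-omics study generator.

Emulates a controlled epigenetic-subnetwork study: predictor (methylation)
and response (expression) modules are drawn as correlated Gaussian blocks
whose covariance comes from an inverse-Wishart distribution,

    Sigma ~ InverseWishart(df, (1 - c) I + c J),

so the mean pairwise correlation within a module is ~ c.  Planted linear
wiring adds predictor signal to selected responses,

    y_S = y + sum_{x in S} x A + E,

with A a constant matrix of association signal a and E unit-variance
Gaussian noise.  A random bipartite prior network connects predictor and
response genes with probability p_c inside a true subnetwork and p_cn
elsewhere.  Everything is reproducible from (config, seed).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .diffnet import InteractionNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "SimConfig",
    "SimBundle",
    "simulate_module",
    "wire_response",
    "simulate_prior_network",
    "generate_study",
    "simulate_survival",
]

DEFAULT_WIRING = {
    "y1": ("x1",),
    "y2": ("x2",),
    "y3": ("x1", "x2"),
    "y4": (),
}


@dataclass
class SimConfig:
    """Study conditions for the synthetic bundle.

    Defaults are the reference conditions: n = 200 samples, four predictor
    modules of p = 25 genes with within-module correlation signals
    c_p = (0.3, 0.5, 0.3, 0.5), four response modules of q = 30 genes
    sharing one correlation signal c_r per dataset, inverse-Wishart df 60,
    association signal a, and a prior network with p_c = 0.1 within true
    subnetworks and p_cn = 0.05 elsewhere.
    """

    n: int = 200
    p: int = 25
    q: int = 30
    c_p: tuple = (0.3, 0.5, 0.3, 0.5)
    c_r: float = 0.3
    df: int = 60
    a: float = 0.1
    wiring: dict = field(default_factory=lambda: dict(DEFAULT_WIRING))
    p_c: float = 0.1
    p_cn: float = 0.05
    seed: int = 0
    uniform_signal: bool = False  # A ~ U(a/2, a) instead of constant a
    n_normal: int = 0  # optional uncorrelated "normal" samples for pipeline tests

    def __post_init__(self) -> None:
        if self.df <= max(self.p, self.q) + 1:
            raise ValueError("df must exceed module dimension + 1")
        for c in (*self.c_p, self.c_r):
            if not 0 <= c < 1:
                raise ValueError("correlation signals must be in [0, 1)")
        for prob in (self.p_c, self.p_cn):
            if not 0 <= prob <= 1:
                raise ValueError("connection probabilities must be in [0, 1]")


@dataclass
class SimBundle:
    """One generated dataset plus its ground truth."""

    config: SimConfig
    predictors: dict  # module id -> n x p sample-by-gene matrix
    responses: dict  # module id -> n x q wired response matrix
    predictor_genes: dict  # module id -> gene name list
    response_genes: dict
    network: InteractionNetwork
    manifest: dict  # response id -> tuple of true predictor ids
    sample_ids: list[str]
    normal_predictors: dict | None = None
    normal_responses: dict | None = None

    def methylation_frame(self) -> pd.DataFrame:
        return self._frame(self.predictors, self.predictor_genes, self.normal_predictors)

    def expression_frame(self) -> pd.DataFrame:
        return self._frame(self.responses, self.response_genes, self.normal_responses)

    def _frame(self, tumor, genes, normal):
        blocks, index = [], []
        for mid in sorted(tumor):
            mats = [tumor[mid].T]
            if normal:
                mats.append(normal[mid].T)
            blocks.append(np.hstack(mats))
            index.extend(genes[mid])
        cols = list(self.sample_ids)
        if normal:
            cols += [f"N{i:03d}" for i in range(next(iter(normal.values())).shape[0])]
        return pd.DataFrame(np.vstack(blocks), index=index, columns=cols)

    def condition(self) -> pd.Series:
        cols = self.methylation_frame().columns
        return pd.Series(
            ["normal" if c.startswith("N") else "tumor" for c in cols], index=cols
        )

    def write(self, outdir: str | Path) -> None:
        """Emit the bundle in the pipeline's native text formats."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.methylation_frame().to_csv(outdir / "methylation.tsv", sep="\t", index_label="gene")
        self.expression_frame().to_csv(outdir / "expression.tsv", sep="\t", index_label="gene")
        cond = self.condition()
        cond.rename("condition").to_csv(outdir / "conditions.tsv", sep="\t", index_label="sample")
        with open(outdir / "network.tsv", "w") as fh:
            for edge in sorted(tuple(sorted(e)) for e in self.network.edges):
                fh.write(f"{edge[0]}\t{edge[1]}\n")
        manifest = {
            "wiring": {k: list(v) for k, v in self.manifest.items()},
            "predictor_genes": self.predictor_genes,
            "response_genes": self.response_genes,
            "config": {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in vars(self.config).items()
                if k != "wiring"
            },
        }
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)


def _child_seeds(seed: int, n: int) -> list[int]:
    return [int(s % (2**31)) for s in np.random.SeedSequence(seed).generate_state(n, dtype=np.uint64)]


def simulate_module(n: int, dim: int, c: float, df: int, seed: int = 0) -> np.ndarray:
    """Draw one correlated module: n samples x dim variables.

    One covariance Sigma ~ InverseWishart(df, (1-c) I + c J) (scale-matrix
    convention, mean Psi/(df - dim - 1)) per module, then n i.i.d. rows
    from N(0, Sigma).
    """
    if df <= dim + 1:
        raise ValueError(f"df={df} must exceed dim+1={dim + 1} for the mean to exist")
    rng = np.random.default_rng(seed)
    psi = (1.0 - c) * np.eye(dim) + c * np.ones((dim, dim))
    sigma = stats.invwishart.rvs(df=df, scale=psi, random_state=rng)
    return rng.multivariate_normal(np.zeros(dim), sigma, size=n, method="cholesky")


def wire_response(
    y: np.ndarray,
    predictors,
    a: float,
    seed: int = 0,
    uniform_signal: bool = False,
) -> np.ndarray:
    """Add planted predictor signal plus unit-variance noise to a response.

    Returns y + sum_x x A_x + E with A_x either constant a (default) or
    elementwise U(a/2, a), and E ~ N(0, 1) i.i.d.
    """
    y = np.asarray(y, dtype=float)
    rng = np.random.default_rng(seed)
    out = y.copy()
    for x in predictors:
        x = np.asarray(x, dtype=float)
        if x.shape[0] != y.shape[0]:
            raise ValueError("predictor and response sample counts differ")
        if uniform_signal:
            A = rng.uniform(a / 2.0, a, size=(x.shape[1], y.shape[1]))
        else:
            A = np.full((x.shape[1], y.shape[1]), a)
        out += x @ A
    out += rng.standard_normal(y.shape)
    return out


def simulate_prior_network(
    predictor_genes: dict,
    response_genes: dict,
    wiring: dict,
    p_c: float,
    p_cn: float,
    seed: int = 0,
) -> InteractionNetwork:
    """Random bipartite predictor-response prior network.

    Gene pairs across a (predictor, response) module pair are connected
    with probability ``p_c`` when the pair belongs to a true subnetwork
    (per ``wiring``) and ``p_cn`` otherwise.
    """
    for prob in (p_c, p_cn):
        if not 0 <= prob <= 1:
            raise ValueError("probabilities must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    edges = []
    for rid in sorted(response_genes):
        true_preds = set(wiring.get(rid, ()))
        for pid in sorted(predictor_genes):
            prob = p_c if pid in true_preds else p_cn
            if prob == 0:
                continue
            pg, rg = predictor_genes[pid], response_genes[rid]
            mask = rng.random((len(pg), len(rg))) < prob
            for i, j in zip(*np.nonzero(mask)):
                edges.append((pg[i], rg[j]))
    return InteractionNetwork(edges)


def generate_study(config: SimConfig) -> SimBundle:
    """Generate one full dataset bundle under the study conditions.

    Four predictor modules (correlation signals ``c_p``), four response
    modules at ``c_r``, planted wiring, prior network, and a ground-truth
    manifest; optionally ``n_normal`` uncorrelated normal-condition samples
    per module (off by default) so the differential-network stage can be
    exercised on synthetic data.
    """
    cfg = config
    n_pred = len(cfg.c_p)
    n_resp = len(cfg.wiring)
    seeds = _child_seeds(cfg.seed, 2 * (n_pred + n_resp) + n_resp + 4)
    it = iter(seeds)

    predictor_genes = {
        f"x{i + 1}": [f"x{i + 1}_g{j:03d}" for j in range(cfg.p)] for i in range(n_pred)
    }
    response_genes = {
        rid: [f"{rid}_g{j:03d}" for j in range(cfg.q)] for rid in sorted(cfg.wiring)
    }

    predictors = {
        f"x{i + 1}": simulate_module(cfg.n, cfg.p, c, cfg.df, seed=next(it))
        for i, c in enumerate(cfg.c_p)
    }
    base_responses = {
        rid: simulate_module(cfg.n, cfg.q, cfg.c_r, cfg.df, seed=next(it))
        for rid in sorted(cfg.wiring)
    }
    responses = {
        rid: wire_response(
            base_responses[rid],
            [predictors[p] for p in cfg.wiring[rid]],
            cfg.a,
            seed=next(it),
            uniform_signal=cfg.uniform_signal,
        )
        for rid in sorted(cfg.wiring)
    }
    network = simulate_prior_network(
        predictor_genes, response_genes, cfg.wiring, cfg.p_c, cfg.p_cn, seed=next(it)
    )

    normal_predictors = normal_responses = None
    if cfg.n_normal > 0:
        # Normal-condition samples: per-gene independent draws matched to the
        # tumor scale but mean-shifted by one SD, so both differential
        # co-expression (correlation lost) and differential expression (mean
        # shift) are present and the full network stage can run.
        nrng = np.random.default_rng(next(it))

        def _normals(mat):
            sd = mat.std(axis=0, ddof=1)
            return nrng.normal(sd, sd, size=(cfg.n_normal, mat.shape[1]))

        normal_predictors = {mid: _normals(predictors[mid]) for mid in sorted(predictors)}
        normal_responses = {mid: _normals(responses[mid]) for mid in sorted(responses)}
        # Within-module scaffold edges give the differential networks a
        # same-layer backbone (the bipartite prior alone spans the layers).
        srng = np.random.default_rng(next(it))
        scaffold = []
        for genes in list(predictor_genes.values()) + list(response_genes.values()):
            for i in range(len(genes)):
                for j in range(i + 1, len(genes)):
                    if srng.random() < 0.5:
                        scaffold.append((genes[i], genes[j]))
        network = InteractionNetwork(list(network.graph.edges) + scaffold)

    return SimBundle(
        config=cfg,
        predictors=predictors,
        responses=responses,
        predictor_genes=predictor_genes,
        response_genes=response_genes,
        network=network,
        manifest={rid: tuple(cfg.wiring[rid]) for rid in sorted(cfg.wiring)},
        sample_ids=[f"T{i:03d}" for i in range(cfg.n)],
        normal_predictors=normal_predictors,
        normal_responses=normal_responses,
    )


def simulate_survival(
    eigengenes: pd.DataFrame | pd.Series,
    beta_true,
    baseline_rate: float = 1.0 / 1000.0,
    censor_rate: float = 1.0 / 2000.0,
    seed: int = 0,
):
    """Exponential survival with hazard proportional to exp(beta' E).

    Event times ~ Exp(baseline_rate * exp(beta' E_i)), independent
    exponential censoring at ``censor_rate``.  Returns a per-patient
    DataFrame (patient_id, time_days, event).
    """
    if baseline_rate <= 0 or censor_rate <= 0:
        raise ValueError("rates must be positive")
    if isinstance(eigengenes, pd.Series):
        eigengenes = eigengenes.to_frame()
    beta = np.broadcast_to(np.asarray(beta_true, dtype=float), (eigengenes.shape[1],))
    lin = eigengenes.to_numpy(dtype=float) @ beta
    rng = np.random.default_rng(seed)
    event_t = rng.exponential(1.0 / (baseline_rate * np.exp(lin)))
    censor_t = rng.exponential(1.0 / censor_rate, size=len(lin))
    time = np.minimum(event_t, censor_t)
    event = (event_t <= censor_t).astype(int)
    return pd.DataFrame(
        {
            "patient_id": list(eigengenes.index),
            "time_days": time,
            "event": event,
        }
    )
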