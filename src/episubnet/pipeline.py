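"""End-to-end orchestration: differential networks -> modules -> eigengenes
-> g-prior subset selection -> survival, plus recovery scoring for
synthetic studies with a known ground truth."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import diffnet as dnet
from . import eigengene as eg
from . import io as eio
from . import modules as mods
from . import regression as reg
from . import survival as surv
from .simdata import SimBundle

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "PipelineResult",
    "run_pipeline",
    "score_recovery",
    "bundle_eigengenes",
    "fit_bundle",
]

DEFAULT_MU_GRID = (0.0, 0.2, 0.4, 0.6, 0.8, 1.0, 2.0, 4.0, 6.0, 8.0, 10.0)


@dataclass
class PipelineConfig:
    """Paths and tuning knobs of a full run.

    Thresholds default to 0.05 everywhere (edge FDR, module density alpha,
    coefficient alpha); the rank grid spans 5..70, permutation tests use
    B = 1000, and the prior-weight grid is
    (0, 0.2, 0.4, 0.6, 0.8, 1, 2, 4, 6, 8, 10).
    """

    expression: str | Path
    methylation: str | Path
    conditions: str | Path
    ppi: str | Path
    survival: str | Path | None = None
    outdir: str | Path | None = None
    edge_fdr: float = 0.05
    module_alpha: float = 0.05
    coef_alpha: float = 0.05
    k_grid: tuple = tuple(range(5, 71))
    permutations: int = 1000
    mu_grid: tuple = DEFAULT_MU_GRID
    max_subset_size: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("edge_fdr", "module_alpha", "coef_alpha"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0, 1)")
        if not self.k_grid or not self.mu_grid:
            raise ValueError("k_grid and mu_grid must be nonempty")


@dataclass
class PipelineResult:
    networks: dict
    module_sets: dict
    eigengenes: dict
    var_explained: dict
    relatedness: pd.DataFrame | None
    mu_star: float | None
    mu_table: pd.DataFrame | None
    subnetworks: dict
    dropped_subnetworks: list
    survival_results: pd.DataFrame | None
    log: dict = field(default_factory=dict)


def _stage(name):
    def wrap(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as err:
            raise RuntimeError(f"pipeline stage {name!r} failed: {err}") from err
    return wrap


def _standardize_columns(frame: pd.DataFrame) -> pd.DataFrame:
    vals = frame.to_numpy(dtype=float)
    sd = vals.std(axis=0, ddof=1)
    if (sd == 0).any():
        raise ValueError("constant eigengene column")
    return pd.DataFrame(
        (vals - vals.mean(axis=0)) / sd, index=frame.index, columns=frame.columns
    )


def _layer_modules(omics, ppi, cfg, layer_seed, layer):
    dn = dnet.build_differential_network(omics, ppi, fdr=cfg.edge_fdr)
    sim = dnet.to_similarity_matrix(dn)
    n = sim.shape[0]
    grid = [k for k in cfg.k_grid if k < n]
    if not grid:
        raise ValueError(f"{layer}: only {n} retained genes; rank grid empty")
    k_star, modset = mods.select_rank(
        sim, grid, B=cfg.permutations, alpha=cfg.module_alpha, seed=layer_seed
    )
    modset.gene_ids = list(sim.index)
    genes = {
        f"{layer[0]}{m}": [sim.index[i] for i in modset.members(m)]
        for m in modset.significant_modules()
    }
    logger.info("%s layer: K*=%d, %d significant module(s)", layer, k_star, len(genes))
    return dn, modset, genes


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run every stage on files; returns the result bundle and writes outputs.

    Expression is the response layer, methylation the predictor layer.  The
    survival stage runs only when a survival table is configured.
    """
    cfg = config
    seeds = np.random.SeedSequence(cfg.seed).generate_state(8, dtype=np.uint64)
    s_resp, s_pred, s_mu, s_surv = (int(s % (2**31)) for s in seeds[:4])

    load = _stage("load")
    expr = load(eio.read_omics_matrix, cfg.expression, cfg.conditions)
    meth = load(eio.read_omics_matrix, cfg.methylation, cfg.conditions)
    ppi = load(eio.read_ppi, cfg.ppi)
    survival_table = load(eio.read_survival, cfg.survival) if cfg.survival else None

    dn_r, mods_r, resp_genes = _stage("modules:expression")(
        _layer_modules, expr, ppi, cfg, s_resp, "response"
    )
    dn_p, mods_p, pred_genes = _stage("modules:methylation")(
        _layer_modules, meth, ppi, cfg, s_pred, "predictor"
    )
    if not resp_genes or not pred_genes:
        raise RuntimeError("pipeline stage 'modules' found no significant modules")

    eg_stage = _stage("eigengene")
    resp_eg, resp_var = eg_stage(eg.module_eigengenes, expr.tumor_frame(), resp_genes, "expression")
    pred_eg, pred_var = eg_stage(eg.module_eigengenes, meth.tumor_frame(), pred_genes, "methylation")

    reg_stage = _stage("regression")
    r = reg_stage(reg.relatedness_matrix, pred_genes, resp_genes, ppi)
    X_all = _standardize_columns(pred_eg.T)
    responses = _standardize_columns(resp_eg.T).T
    mu_star, mu_table, fits = reg_stage(
        reg.tune_mu, X_all, responses, r, cfg.mu_grid,
        B=cfg.permutations, seed=s_mu, max_size=cfg.max_subset_size,
    )
    subnetworks, dropped = {}, []
    for rid, sub in fits.items():
        y = responses.loc[rid].to_numpy()
        sub.confidence = reg.confidence_score(sub, X_all, y)
        if np.all(sub.fit.coef_p >= cfg.coef_alpha):
            dropped.append(rid)  # no coefficient separates from zero
        else:
            subnetworks[rid] = sub

    survival_results = None
    if survival_table is not None:
        rows = []
        sstage = _stage("survival")
        for rid, sub in subnetworks.items():
            covs = pd.DataFrame(
                {pid: X_all[pid] for pid in sub.predictors}
                | {rid: responses.loc[rid]},
            )
            try:
                beta = sstage(surv.fit_cox, covs, survival_table)
                pi = surv.prognostic_index(beta, covs)
                groups = surv.risk_groups(pi)
                _, p, flagged = surv.km_logrank(groups, survival_table)
                rows.append((rid, ",".join(sub.predictors), float(p), flagged))
            except RuntimeError as err:
                logger.warning("survival skipped for %s: %s", rid, err)
        survival_results = pd.DataFrame(
            rows, columns=["response", "predictors", "logrank_p", "zero_event_flag"]
        )

    result = PipelineResult(
        networks={"response": dn_r, "predictor": dn_p},
        module_sets={"response": mods_r, "predictor": mods_p},
        eigengenes={"response": resp_eg, "predictor": pred_eg},
        var_explained={"response": resp_var, "predictor": pred_var},
        relatedness=r,
        mu_star=mu_star,
        mu_table=mu_table,
        subnetworks=subnetworks,
        dropped_subnetworks=dropped,
        survival_results=survival_results,
        log={"seed": cfg.seed, "stage_seeds": [s_resp, s_pred, s_mu, s_surv]},
    )
    if cfg.outdir is not None:
        _write_outputs(result, Path(cfg.outdir))
    return result


def _write_outputs(result: PipelineResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    for layer, dn in result.networks.items():
        eio.write_edge_table(dn, outdir / f"diffnet_{layer}.tsv")
    for layer, modset in result.module_sets.items():
        eio.write_module_table(modset, outdir / f"modules_{layer}.tsv")
    for layer, mat in result.eigengenes.items():
        eio.write_eigengenes(mat, result.var_explained[layer], outdir / f"eigengenes_{layer}.tsv")
    if result.mu_table is not None:
        result.mu_table.to_csv(outdir / "mu_tuning.tsv", sep="\t")
    payload, rows = {}, []
    for rid in sorted(result.subnetworks, key=str):
        sub = result.subnetworks[rid]
        payload[str(rid)] = {
            "predictors": [str(p) for p in sub.predictors],
            "beta": [float(b) for b in sub.fit.beta_tilde],
            "coef_p": [float(p) for p in sub.fit.coef_p],
            "expected_bic": float(sub.fit.expected_bic),
            "correlation_p": sub.correlation_p,
            "confidence_incremental_r2": {str(k): float(v) for k, v in (sub.confidence or {}).items()},
        }
        for pid, b, p in zip(sub.predictors, sub.fit.beta_tilde, sub.fit.coef_p):
            rows.append((str(rid), str(pid), float(b), float(p)))
    with open(outdir / "subnetworks.json", "w") as fh:
        json.dump(payload, fh, indent=2)
    pd.DataFrame(rows, columns=["response", "predictor", "coefficient", "p_value"]).to_csv(
        outdir / "subnetworks.tsv", sep="\t", index=False
    )
    if result.survival_results is not None:
        result.survival_results.to_csv(outdir / "survival.tsv", sep="\t", index=False)
    with open(outdir / "run_log.json", "w") as fh:
        json.dump(result.log, fh, indent=2)


# ---------------------------------------------------------------------------
# Synthetic-study protocol: modules are known, eigengenes feed the regression.


def bundle_eigengenes(bundle: SimBundle) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Standardised predictor/response eigengenes of a synthetic bundle.

    Returns ``(X_all, responses)``: X_all is sample x predictor-module,
    responses is response-module x sample, both column-standardised.
    """
    pred = {}
    for mid in sorted(bundle.predictors):
        mat = bundle.predictors[mid].T  # gene x sample
        pred[mid] = eg.compute_eigengene(eg.standardize_rows(mat), module_id=mid).values
    resp = {}
    for rid in sorted(bundle.responses):
        mat = bundle.responses[rid].T
        resp[rid] = eg.compute_eigengene(eg.standardize_rows(mat), module_id=rid).values
    X_all = _standardize_columns(pd.DataFrame(pred, index=bundle.sample_ids))
    responses = _standardize_columns(
        pd.DataFrame(resp, index=bundle.sample_ids)
    ).T
    return X_all, responses


def fit_bundle(bundle: SimBundle, mu: float = 1.0, max_size: int = 4) -> dict:
    """Subset selection for every response of a synthetic bundle.

    ``mu = 0`` runs the no-prior OLS/BIC baseline; otherwise the g-prior
    model with relatedness computed from the bundle's prior network.
    """
    X_all, responses = bundle_eigengenes(bundle)
    gspec = None
    if mu > 0:
        r = reg.relatedness_matrix(
            bundle.predictor_genes, bundle.response_genes, bundle.network
        )
        gspec = reg.GPriorSpec(r=r, mu=mu)
    return reg.fit_all_responses(X_all, responses, gspec, max_size=max_size)


def score_recovery(fits: dict, manifest: dict, coef_alpha: float = 0.05) -> pd.DataFrame:
    """Per-response true/false-positive report against a ground truth.

    A response with a nonempty true set is an exact match when the selected
    predictors equal the planted ones.  A response with an empty true set
    counts as correct when no selected coefficient is significant at
    ``coef_alpha`` (the subset search must select >= 1 predictor, so the
    significance filter decides).
    """
    rows = []
    for rid, true in manifest.items():
        if rid not in fits:
            raise KeyError(f"unknown response id: {rid}")
        sub = fits[rid]
        selected = set(sub.predictors)
        true = set(true)
        sig_any = bool(np.any(sub.fit.coef_p < coef_alpha))
        tp = len(selected & true)
        fp = len(selected - true)
        if true:
            exact = selected == true
        else:
            exact = not sig_any
            fp = fp if sig_any else 0
        rows.append((rid, ",".join(sorted(true)), ",".join(sorted(selected)), exact, tp, fp))
    return pd.DataFrame(
        rows, columns=["response", "true", "selected", "exact", "tp", "fp"]
    ).set_index("response")
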