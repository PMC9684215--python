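"""Prognostic-index survival analysis of modules and subnetworks.

A Cox proportional-hazards model is fitted with module eigengenes as
covariates; each patient's prognostic index is PI_i = sum_c beta_c^cox E_ci.
Patients in the lower/upper 30% tails of the PI distribution form low- and
high-risk groups whose Kaplan-Meier curves are compared by the log-rank
test.  The Cox/KM/log-rank machinery is provided by lifelines; this module
owns the PI construction, the tail grouping rule, and the eigengene-vs-
survival screening.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test

logger = logging.getLogger(__name__)

__all__ = [
    "SurvivalTable",
    "PrognosticIndex",
    "fit_cox",
    "prognostic_index",
    "risk_groups",
    "km_logrank",
    "eigengene_survival_screen",
]


@dataclass
class SurvivalTable:
    """Per-patient follow-up: id, time in days (> 0), event (1 = death)."""

    data: pd.DataFrame  # columns: patient_id, time_days, event

    def __post_init__(self) -> None:
        required = {"patient_id", "time_days", "event"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"survival table lacks columns: {sorted(missing)}")
        if (self.data["time_days"] <= 0).any():
            raise ValueError("survival times must be positive")
        if not self.data["event"].isin([0, 1]).all():
            raise ValueError("event indicator must be 0 or 1")
        self.data = self.data.reset_index(drop=True)

    @property
    def n_events(self) -> int:
        return int(self.data["event"].sum())

    def aligned(self, sample_ids) -> pd.DataFrame:
        """Rows for the given patients, in the given order; errors if absent."""
        sub = self.data.set_index("patient_id").reindex(sample_ids)
        if sub["time_days"].isna().any():
            missing = list(sub.index[sub["time_days"].isna()])
            raise ValueError(f"patients missing from survival table: {missing[:10]}")
        return sub.reset_index()


@dataclass
class PrognosticIndex:
    scores: pd.Series  # per patient
    source: object = None

    def __post_init__(self) -> None:
        self.scores = self.scores.astype(float)


def fit_cox(covariates: pd.DataFrame, surv: SurvivalTable) -> pd.Series:
    """Multivariate Cox partial-likelihood coefficients (Efron ties).

    ``covariates`` is patient x covariate (eigengene values per patient,
    indexed by patient id).  Requires at least 10 observed events.
    """
    table = surv.aligned(covariates.index)
    if table["event"].sum() < 10:
        raise ValueError(
            f"need >= 10 observed events for a stable Cox fit, got {int(table['event'].sum())}"
        )
    if not np.isfinite(covariates.to_numpy()).all():
        raise ValueError("covariates must be finite")
    frame = covariates.copy()
    frame["time_days"] = table["time_days"].to_numpy()
    frame["event"] = table["event"].to_numpy()
    cph = CoxPHFitter()
    try:
        cph.fit(frame, duration_col="time_days", event_col="event")
    except ConvergenceError as err:  # pragma: no cover - depends on data
        raise RuntimeError(f"Cox regression failed to converge: {err}") from err
    return cph.params_.rename("beta_cox")


def prognostic_index(beta_cox, eigengenes) -> PrognosticIndex:
    """PI_i = sum_c beta_c^cox * E_ci.

    ``eigengenes`` is patient x covariate with columns matching
    ``beta_cox``; a Series is treated as the single-module case.
    """
    if isinstance(eigengenes, pd.Series):
        eigengenes = eigengenes.to_frame()
    beta = pd.Series(beta_cox)
    missing = set(beta.index) - set(eigengenes.columns)
    if missing:
        raise ValueError(f"eigengene columns missing for: {sorted(missing)}")
    scores = eigengenes.loc[:, beta.index].to_numpy() @ beta.to_numpy()
    return PrognosticIndex(scores=pd.Series(scores, index=eigengenes.index, name="PI"))


def risk_groups(pis: PrognosticIndex | pd.Series, low_pct: float = 30.0, high_pct: float = 70.0):
    """Split patients into low/high-risk PI tails.

    Low risk: PI strictly below the ``low_pct`` percentile; high risk: PI
    strictly above the ``high_pct`` percentile (linear-interpolation
    percentiles); the middle patients are excluded from the comparison.
    """
    scores = pis.scores if isinstance(pis, PrognosticIndex) else pd.Series(pis).astype(float)
    if len(scores) < 10:
        raise ValueError("need at least 10 patients to form risk groups")
    if scores.nunique() == 1:
        raise ValueError("all prognostic indices are identical")
    lo = np.percentile(scores, low_pct)
    hi = np.percentile(scores, high_pct)
    low = scores.index[scores < lo]
    high = scores.index[scores > hi]
    if len(low) == 0 or len(high) == 0:
        raise ValueError("degenerate PI distribution: an empty risk group")
    return pd.Series(
        np.where(scores < lo, "low", np.where(scores > hi, "high", "mid")),
        index=scores.index,
        name="risk_group",
    )


def km_logrank(groups: pd.Series, surv: SurvivalTable):
    """Kaplan-Meier curves for the low/high tails and the log-rank p-value.

    Returns ``(curves, p, flagged)`` where ``curves`` maps group name to
    the KM survival-function DataFrame and ``flagged`` is True when a group
    contributed no events (p is still computed but unreliable).
    """
    tails = groups[groups.isin(["low", "high"])]
    if (tails == "low").sum() == 0 or (tails == "high").sum() == 0:
        raise ValueError("both risk groups must be nonempty")
    table = surv.aligned(tails.index)
    table = table.assign(group=tails.to_numpy())
    curves = {}
    flagged = False
    for name, chunk in table.groupby("group"):
        if chunk["event"].sum() == 0:
            logger.warning("risk group %r has zero events", name)
            flagged = True
        km = KaplanMeierFitter()
        km.fit(chunk["time_days"], chunk["event"], label=str(name))
        curves[name] = km.survival_function_
    lo = table[table["group"] == "low"]
    hi = table[table["group"] == "high"]
    res = logrank_test(
        lo["time_days"], hi["time_days"],
        event_observed_A=lo["event"], event_observed_B=hi["event"],
    )
    return curves, float(res.p_value), flagged


def eigengene_survival_screen(
    eigengene: pd.Series, surv: SurvivalTable, B: int = 1000, seed: int = 0
) -> tuple[float, float]:
    """Correlation between an eigengene and observed survival times.

    Restricted to patients whose death was observed (event = 1): returns
    (Pearson r, permutation p) with the null built by permuting the sample
    labels of the eigengene B times (two-sided on |r|).
    """
    table = surv.aligned(eigengene.index)
    mask = table["event"].to_numpy() == 1
    if mask.sum() < 3:
        raise ValueError("need at least 3 patients with observed death times")
    x = eigengene.to_numpy(dtype=float)[mask]
    t = table["time_days"].to_numpy(dtype=float)[mask]
    r = float(np.corrcoef(x, t)[0, 1])
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(B):
        rp = np.corrcoef(rng.permutation(x), t)[0, 1]
        if abs(rp) >= abs(r):
            hits += 1
    return r, (1 + hits) / (B + 1)
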