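"""Module eigengenes: one representative profile per module via SVD.

Each module's gene x sample profile (tumor samples) is row-standardised and
decomposed as Y = U D V^T; the first right-singular vector is the module
eigengene, and d1^2 / sum_j dj^2 measures the fraction of the module's
variance it explains.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["Eigengene", "standardize_rows", "compute_eigengene", "module_eigengenes"]


@dataclass
class Eigengene:
    """Unit-norm length-m module summary over (tumor) samples."""

    values: np.ndarray
    var_explained: float
    module_id: str | int | None = None
    layer: str | None = None


def standardize_rows(Y, ddof: int = 1):
    """Standardise each row to mean 0, variance 1 (n-1 denominator).

    Constant rows carry no correlation information and are dropped with a
    warning; an all-constant matrix raises.
    """
    frame = isinstance(Y, pd.DataFrame)
    vals = Y.to_numpy(dtype=float) if frame else np.asarray(Y, dtype=float)
    if vals.ndim != 2:
        raise ValueError("expected a 2-D gene x sample matrix")
    sd = vals.std(axis=1, ddof=ddof)
    keep = sd > 0
    if not keep.any():
        raise ValueError("all rows are constant: nothing to standardise")
    if not keep.all():
        logger.warning("dropping %d constant row(s)", int((~keep).sum()))
    vals = vals[keep]
    out = (vals - vals.mean(axis=1, keepdims=True)) / sd[keep, None]
    if frame:
        return pd.DataFrame(out, index=Y.index[keep], columns=Y.columns)
    return out


def compute_eigengene(Y, module_id=None, layer: str | None = None) -> Eigengene:
    """First right-singular vector of a standardised module matrix.

    The sign is fixed so the mean correlation between the eigengene and the
    module's gene profiles is nonnegative, making downstream regression
    coefficients reproducible.
    """
    vals = Y.to_numpy(dtype=float) if isinstance(Y, pd.DataFrame) else np.asarray(Y, dtype=float)
    if vals.ndim != 2 or vals.shape[0] < 1 or vals.shape[1] < 2:
        raise ValueError("need a matrix with >= 1 row and >= 2 columns")
    _, d, vt = np.linalg.svd(vals, full_matrices=False)
    total = float(np.sum(d**2))
    if total <= 0:
        raise ValueError("rank-0 matrix: no eigengene")
    v1 = vt[0]
    if np.mean(vals @ v1) < 0:
        v1 = -v1
    return Eigengene(
        values=v1,
        var_explained=float(d[0] ** 2 / total),
        module_id=module_id,
        layer=layer,
    )


def module_eigengenes(
    profiles: pd.DataFrame,
    modules: dict,
    layer: str | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Eigengenes for a set of modules over one omics profile.

    ``profiles`` is a gene x sample frame (tumor samples); ``modules`` maps
    module id -> list of gene ids.  Returns (eigengene matrix with modules
    as rows and samples as columns, var_explained per module).
    """
    rows, var = {}, {}
    for mid, genes in modules.items():
        present = [g for g in genes if g in profiles.index]
        if not present:
            logger.warning("module %s: no genes present in profile, skipped", mid)
            continue
        eg = compute_eigengene(standardize_rows(profiles.loc[present]), module_id=mid, layer=layer)
        rows[mid] = eg.values
        var[mid] = eg.var_explained
    if not rows:
        raise ValueError("no module produced an eigengene")
    mat = pd.DataFrame.from_dict(rows, orient="index", columns=profiles.columns)
    return mat, pd.Series(var, name="var_explained")
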