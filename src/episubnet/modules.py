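"""Module detection by symmetric NMF with permutation-tested density.

The similarity matrix A (|Z| edge weights of a differential network) is
factorised as A ~ H H^T with H >= 0; each gene joins the module whose
column of H carries its largest loading.  The rank K is chosen by scanning
a grid and keeping the K that yields the most modules whose density

    density(M) = sum_{p != q in M} a_pq / (|M| (|M| - 1))

is significant under a same-size random-module permutation null
(Bonferroni-corrected within each rank).  Module quality is additionally
screened by the separability score

    separability(Mi, Mj) = 1 - interAdj(Mi, Mj) / sqrt(density(Mi) density(Mj)).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "SymFactor",
    "ModuleSet",
    "SeparabilityReport",
    "symnmf",
    "assign_modules",
    "module_density",
    "density_permutation_test",
    "select_rank",
    "separability",
    "separability_permutation_test",
]


@dataclass
class SymFactor:
    """Result of a symmetric NMF run: A ~ H H^T with H >= 0."""

    H: np.ndarray
    K: int
    loss: float
    n_iter: int
    seed: int
    loss_history: np.ndarray = field(repr=False, default_factory=lambda: np.array([]))


@dataclass
class ModuleSet:
    """Hard gene->module partition with per-module density statistics.

    ``labels[i]`` is the 1-based module index of gene i, or -1 for genes
    whose H row is all zero (unassigned).  ``stats`` (filled by the rank
    scan) has one row per module: size, density, p, p_adj, significant.
    """

    labels: np.ndarray
    K: int
    gene_ids: list[str] | None = None
    stats: pd.DataFrame | None = None

    def members(self, module: int) -> np.ndarray:
        """Row indices of the genes in 1-based module ``module``."""
        return np.flatnonzero(self.labels == module)

    def module_ids(self) -> list[int]:
        return sorted(int(m) for m in np.unique(self.labels) if m > 0)

    def significant_modules(self) -> list[int]:
        if self.stats is None:
            raise ValueError("no density statistics attached")
        return sorted(int(m) for m in self.stats.index[self.stats["significant"]])

    def gene_table(self) -> pd.DataFrame:
        genes = self.gene_ids or [str(i) for i in range(len(self.labels))]
        tab = pd.DataFrame({"gene": genes, "module_id": self.labels})
        if self.stats is not None:
            tab = tab.merge(
                self.stats, left_on="module_id", right_index=True, how="left"
            )
        return tab


@dataclass
class SeparabilityReport:
    scores: pd.DataFrame
    pvalues: pd.DataFrame | None = None


def _check_similarity(A: np.ndarray) -> np.ndarray:
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("similarity matrix must be square")
    scale = max(1.0, float(np.abs(A).max(initial=0.0)))
    if np.abs(A - A.T).max(initial=0.0) > 1e-8 * scale:
        raise ValueError("similarity matrix is not symmetric (tolerance 1e-8)")
    if A.min(initial=0.0) < 0:
        raise ValueError("similarity matrix has negative entries")
    return A


def _loss(A: np.ndarray, H: np.ndarray) -> float:
    return float(np.linalg.norm(A - H @ H.T, "fro") ** 2)


def _pgd(A: np.ndarray, H: np.ndarray, max_iter: int, tol: float):
    """Projected gradient descent on ||A - H H^T||_F^2 with backtracking.

    The Armijo-style backtracking accepts a step only if the objective
    decreases, so the loss sequence is nonincreasing by construction.
    """
    f = _loss(A, H)
    history = [f]
    step = 1.0 / max(1.0, np.linalg.norm(A, "fro"))
    it = 0
    for it in range(1, max_iter + 1):
        grad = 4.0 * ((H @ H.T) @ H - A @ H)
        accepted = False
        for _ in range(30):
            H_new = np.maximum(H - step * grad, 0.0)
            f_new = _loss(A, H_new)
            if f_new <= f:
                accepted = True
                break
            step *= 0.5
        if not accepted:
            break
        rel = (f - f_new) / max(f, np.finfo(float).tiny)
        H, f = H_new, f_new
        history.append(f)
        step *= 1.2  # try a slightly bolder step next round
        if rel < tol:
            break
    return H, f, it, np.asarray(history)


def symnmf(
    A,
    K: int,
    max_iter: int = 500,
    tol: float = 1e-5,
    seed: int = 0,
    n_init: int = 5,
) -> SymFactor:
    """Factorise a symmetric nonnegative matrix as A ~ H H^T, H >= 0.

    Runs ``n_init`` projected-gradient descents from seeded uniform
    initialisations H0 ~ U(0, 2 sqrt(mean(A)/K)) and keeps the lowest final
    loss.  Deterministic given ``seed``.
    """
    A = _check_similarity(A if not isinstance(A, pd.DataFrame) else A.to_numpy())
    n = A.shape[0]
    if not 1 <= K < n:
        raise ValueError(f"rank K={K} must satisfy 1 <= K < n={n}")
    ss = np.random.SeedSequence(seed)
    best: SymFactor | None = None
    scale = 2.0 * np.sqrt(max(A.mean(), np.finfo(float).tiny) / K)
    for child in ss.spawn(max(1, n_init)):
        rng = np.random.default_rng(child)
        H0 = rng.uniform(0.0, scale, size=(n, K))
        H, f, it, hist = _pgd(A, H0, max_iter, tol)
        if best is None or f < best.loss:
            best = SymFactor(H=H, K=K, loss=f, n_iter=it, seed=seed, loss_history=hist)
    assert best is not None
    return best


def assign_modules(f: SymFactor, gene_ids: list[str] | None = None) -> ModuleSet:
    """Hard assignment: gene i joins the module with the largest h_ik.

    Ties go to the lowest module index; all-zero rows are left unassigned
    (label -1).  Both cases are logged.
    """
    H = f.H
    if H.size == 0:
        raise ValueError("empty factor matrix")
    labels = np.argmax(H, axis=1) + 1  # argmax already takes the lowest index on ties
    zero_rows = ~H.any(axis=1)
    if zero_rows.any():
        logger.warning("%d gene(s) have all-zero loadings: left unassigned", int(zero_rows.sum()))
        labels[zero_rows] = -1
    n_ties = int(np.sum((H == H.max(axis=1, keepdims=True)).sum(axis=1) > 1) - zero_rows.sum())
    if n_ties > 0:
        logger.info("%d tie(s) broken toward the lowest module index", n_ties)
    return ModuleSet(labels=labels, K=f.K, gene_ids=gene_ids)


def module_density(members, A) -> float:
    """Mean edge weight over ordered within-module gene pairs."""
    A = np.asarray(A if not isinstance(A, pd.DataFrame) else A.to_numpy(), dtype=float)
    members = np.asarray(members, dtype=int)
    m = len(members)
    if m < 2:
        logger.warning("singleton module: density defined as 0")
        return 0.0
    sub = A[np.ix_(members, members)]
    return float((sub.sum() - np.trace(sub)) / (m * (m - 1)))


def _random_set_densities(A: np.ndarray, size: int, B: int, rng: np.random.Generator) -> np.ndarray:
    n = A.shape[0]
    out = np.empty(B)
    for b in range(B):
        pick = rng.choice(n, size=size, replace=False)
        out[b] = module_density(pick, A)
    return out


def density_permutation_test(members, A, B: int = 1000, seed: int = 0) -> float:
    """Permutation p-value for module density.

    Draws ``B`` uniform same-size gene sets from the background (all genes
    of the similarity matrix) and reports the fraction whose density is
    >= the observed density (so p may be exactly 0).
    """
    A = np.asarray(A if not isinstance(A, pd.DataFrame) else A.to_numpy(), dtype=float)
    members = np.asarray(members, dtype=int)
    if len(members) >= A.shape[0]:
        raise ValueError("module size must be smaller than the background gene set")
    observed = module_density(members, A)
    rng = np.random.default_rng(seed)
    null = _random_set_densities(A, len(members), B, rng)
    # tolerance so a redraw of the observed set counts as a tie despite
    # summation-order floating noise
    tol = 1e-9 * max(1.0, abs(observed))
    return float(np.mean(null >= observed - tol))


def select_rank(
    A,
    k_grid,
    B: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-5,
    n_init: int = 5,
):
    """Scan candidate ranks; keep the one with most significant modules.

    For each k: run SymNMF, assign modules, permutation-test each module's
    density, Bonferroni-correct within the rank (factor = number of modules
    produced at that rank), and count modules with adjusted p < ``alpha``.
    Returns ``(K*, ModuleSet)`` for the count-maximising rank (ties to the
    smallest k), with per-module statistics attached.
    """
    A = np.asarray(A if not isinstance(A, pd.DataFrame) else A.to_numpy(), dtype=float)
    k_grid = sorted(set(int(k) for k in k_grid))
    if not k_grid:
        raise ValueError("empty rank grid")
    ss = np.random.SeedSequence(seed)
    child_seeds = {k: s.generate_state(2) for k, s in zip(k_grid, ss.spawn(len(k_grid)))}
    best_k, best_count, best_modset = None, -1, None
    for k in k_grid:
        nmf_seed, perm_seed0 = (int(s % (2**31)) for s in child_seeds[k])
        factor = symnmf(A, k, max_iter=max_iter, tol=tol, seed=nmf_seed, n_init=n_init)
        modset = assign_modules(factor)
        mod_ids = modset.module_ids()
        rows = []
        for j, m in enumerate(mod_ids):
            members = modset.members(m)
            if len(members) < 2:  # singleton: density 0 by convention, untestable
                rows.append((m, len(members), 0.0, 1.0))
                continue
            dens = module_density(members, A)
            if len(members) >= A.shape[0]:
                p = 1.0
            else:
                p = density_permutation_test(members, A, B=B, seed=perm_seed0 + j)
            rows.append((m, len(members), dens, p))
        n_modules = len(rows)
        stats = pd.DataFrame(
            rows, columns=["module_id", "size", "density", "p"]
        ).set_index("module_id")
        stats["p_adj"] = np.minimum(1.0, stats["p"] * n_modules)
        stats["significant"] = stats["p_adj"] < alpha
        modset.stats = stats
        count = int(stats["significant"].sum())
        logger.info("rank %d: %d module(s), %d significant", k, n_modules, count)
        if count > best_count:
            best_k, best_count, best_modset = k, count, modset
    return best_k, best_modset


def separability(mi, mj, A) -> float:
    """1 - interAdj(Mi, Mj) / sqrt(density(Mi) * density(Mj)).

    interAdj is the mean cross-pair edge weight.  Undefined (NaN, logged)
    when either module has zero density.
    """
    A = np.asarray(A if not isinstance(A, pd.DataFrame) else A.to_numpy(), dtype=float)
    mi = np.asarray(mi, dtype=int)
    mj = np.asarray(mj, dtype=int)
    if set(mi) & set(mj):
        raise ValueError("modules must be disjoint")
    di, dj = module_density(mi, A), module_density(mj, A)
    if di <= 0 or dj <= 0:
        logger.warning("separability undefined: a module has zero density")
        return float("nan")
    inter = float(A[np.ix_(mi, mj)].sum()) / (len(mi) * len(mj))
    return 1.0 - inter / np.sqrt(di * dj)


def separability_permutation_test(mi, mj, A, B: int = 1000, seed: int = 0) -> float:
    """Permutation p-value for separability of a disjoint module pair.

    The null draws random disjoint same-size pairs from the background and
    counts scores >= the observed one (high separability = well separated).
    Draws where either random module has zero density yield an undefined
    score and are discarded; p is the fraction over valid draws.
    """
    A = np.asarray(A if not isinstance(A, pd.DataFrame) else A.to_numpy(), dtype=float)
    mi = np.asarray(mi, dtype=int)
    mj = np.asarray(mj, dtype=int)
    n = A.shape[0]
    if len(mi) + len(mj) > n:
        raise ValueError("module pair larger than the background gene set")
    observed = separability(mi, mj, A)
    if np.isnan(observed):
        raise ValueError("observed separability undefined (zero density)")
    rng = np.random.default_rng(seed)
    hits = valid = 0
    for _ in range(B):
        pick = rng.choice(n, size=len(mi) + len(mj), replace=False)
        ri, rj = pick[: len(mi)], pick[len(mi):]
        di, dj = module_density(ri, A), module_density(rj, A)
        if di <= 0 or dj <= 0:
            continue
        inter = float(A[np.ix_(ri, rj)].sum()) / (len(ri) * len(rj))
        s = 1.0 - inter / np.sqrt(di * dj)
        valid += 1
        if s >= observed - 1e-9 * max(1.0, abs(observed)):
            hits += 1
    if valid == 0:
        raise ValueError("all null draws had zero-density modules")
    if valid < B:
        logger.info("separability null: %d/%d draws discarded (zero density)", B - valid, B)
    return hits / valid
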