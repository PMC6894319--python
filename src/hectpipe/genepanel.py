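"""Targeted gene-panel expression analysis.

Implements the analysis chain for small targeted count panels (nCounter
style): reference-gene (housekeeping) normalization by geometric mean,
optional background subtraction, cardiac-content normalization to TNNT2,
per-gene group fold changes with Student t-tests (raw p primary,
Benjamini-Hochberg q alongside), cardiomyocyte maturation isoform ratios
(MYH7/MYH6, MYL2/MYL7, TNNI3/TNNI1), PCA, and NIPALS partial least
squares regression (PLS2) linking expression profiles to contractile
metrics, with correlation loadings and leave-one-out predictability R².
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .mechanics import DataError, ParameterError

__all__ = [
    "PanelMatrix",
    "NormalizedPanel",
    "normalize_panel",
    "differential_expression",
    "isoform_ratio",
    "pca_scores",
    "PLSRModel",
    "plsr_nipals",
    "DEFAULT_HOUSEKEEPING",
]

DEFAULT_HOUSEKEEPING = ("B2M", "EEF1A1", "GAPDH", "RNPS1", "SRP14")


@dataclass
class PanelMatrix:
    """Genes x samples count table with gene-class and group annotation.

    ``counts``: DataFrame indexed by gene symbol, columns = sample names.
    ``gene_classes``: per-gene label, ``endogenous`` or ``housekeeping``.
    ``groups``: per-sample group label.
    """

    counts: pd.DataFrame
    gene_classes: pd.Series
    groups: pd.Series
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise DataError("counts must be non-negative")
        self.gene_classes = self.gene_classes.reindex(self.counts.index)
        if self.gene_classes.isna().any():
            missing = self.gene_classes.index[self.gene_classes.isna()][0]
            raise DataError(f"gene {missing} has no class annotation")
        if (self.gene_classes == "housekeeping").sum() < 2:
            raise DataError("need at least 2 housekeeping genes")
        self.groups = self.groups.reindex(self.counts.columns)
        if self.groups.isna().any():
            missing = self.groups.index[self.groups.isna()][0]
            raise DataError(f"sample {missing} has no group label")

    @property
    def housekeeping_genes(self) -> list[str]:
        return list(self.gene_classes.index[self.gene_classes == "housekeeping"])


@dataclass
class NormalizedPanel:
    """Normalized expression values plus normalization provenance."""

    values: pd.DataFrame
    groups: pd.Series
    provenance: dict = field(default_factory=dict)


def normalize_panel(
    pm: PanelMatrix,
    reference_gene: str = "TNNT2",
    background_genes: Optional[Sequence[str]] = None,
    housekeeping_aggregate: str = "geometric",
) -> NormalizedPanel:
    """Two-stage normalization: housekeeping genes, then a cardiac reference.

    Stage 0 (optional): subtract the per-sample mean of user-flagged
    negative-control genes (background), clipping at zero.

    Stage 1: per sample, divide all counts by the aggregate (geometric
    mean by default) of that sample's housekeeping counts, then multiply
    by the global mean of those aggregates so values stay on a count-like
    scale.  This removes per-sample library-size / hybridization factors.

    Stage 2: divide each sample by its stage-1 value of
    ``reference_gene`` (TNNT2), expressing every gene relative to cardiac
    content; the reference gene maps to exactly 1 in every sample.
    """
    counts = pm.counts.astype(float)
    if background_genes:
        bg = counts.loc[list(background_genes)].mean(axis=0)
        counts = (counts - bg).clip(lower=0.0)
        counts = counts.drop(index=list(background_genes))
    hk = pm.housekeeping_genes
    hk_counts = counts.loc[hk]
    bad = (hk_counts <= 0).stack()
    if bad.any():
        gene, sample = bad.index[np.argmax(bad.to_numpy())]
        raise DataError(f"non-positive housekeeping count: gene {gene}, sample {sample}")
    if housekeeping_aggregate == "geometric":
        agg = np.exp(np.log(hk_counts).mean(axis=0))
    elif housekeeping_aggregate == "arithmetic":
        agg = hk_counts.mean(axis=0)
    else:
        raise ParameterError(f"unknown aggregate {housekeeping_aggregate!r}")
    stage1 = counts.div(agg, axis=1) * agg.mean()

    if reference_gene not in stage1.index:
        raise DataError(f"reference gene {reference_gene} not in panel")
    ref = stage1.loc[reference_gene]
    zero = ref[ref <= 0]
    if not zero.empty:
        raise DataError(f"non-positive {reference_gene} count in sample {zero.index[0]}")
    stage2 = stage1.div(ref, axis=1)
    endogenous = pm.gene_classes.reindex(stage2.index) == "endogenous"
    return NormalizedPanel(
        values=stage2.loc[endogenous],
        groups=pm.groups.copy(),
        provenance={
            "housekeeping_genes": hk,
            "housekeeping_aggregate": housekeeping_aggregate,
            "housekeeping_factors": agg.to_dict(),
            "reference_gene": reference_gene,
            "background_genes": list(background_genes) if background_genes else [],
        },
    )


def differential_expression(
    normalized: NormalizedPanel,
    control_group: str = "control",
    treated_group: str = "treated",
    equal_var: bool = True,
) -> pd.DataFrame:
    """Per-gene fold change (treated/control of group means) and t-test.

    Classic equal-variance Student t by default (Welch via
    ``equal_var=False``); raw two-sided p-values are the primary output,
    with Benjamini-Hochberg q-values in an extra column.  Genes whose
    control mean is zero get an undefined (NaN) fold change and are
    flagged.
    """
    vals = normalized.values
    groups = normalized.groups
    a = vals.loc[:, groups == control_group]
    b = vals.loc[:, groups == treated_group]
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise DataError("need >= 2 samples per group")
    mean_a = a.mean(axis=1)
    mean_b = b.mean(axis=1)
    fold = mean_b / mean_a.where(mean_a > 0)
    t, p = sps.ttest_ind(b, a, axis=1, equal_var=equal_var)
    q = np.full_like(p, np.nan, dtype=float)
    ok = np.isfinite(p)
    if ok.any():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return pd.DataFrame(
        {
            "fold_change": fold,
            "t": t,
            "p_value": p,
            "q_value": q,
            "control_mean": mean_a,
            "treated_mean": mean_b,
            "undefined_fold": ~(mean_a > 0),
        },
        index=vals.index,
    )


def isoform_ratio(
    normalized: NormalizedPanel, gene_a: str, gene_b: str
) -> pd.DataFrame:
    """Per-group maturation isoform ratio of two genes (A over B).

    Primary convention: mean over samples of the per-sample ratio A/B
    (mean of ratios); the ratio of group means is reported alongside,
    since the two differ whenever per-sample levels vary.
    """
    vals = normalized.values
    for g in (gene_a, gene_b):
        if g not in vals.index:
            raise DataError(f"gene {g} not in panel")
    denom = vals.loc[gene_b]
    zero = denom[denom <= 0]
    if not zero.empty:
        raise DataError(f"non-positive {gene_b} in sample {zero.index[0]}")
    ratio = vals.loc[gene_a] / denom
    rows = []
    for group, samples in normalized.groups.groupby(normalized.groups):
        r = ratio[samples.index]
        rows.append(
            {
                "group": group,
                "mean_of_ratios": float(r.mean()),
                "sd_of_ratios": float(r.std(ddof=1)) if len(r) > 1 else 0.0,
                "ratio_of_means": float(vals.loc[gene_a, samples.index].mean() / vals.loc[gene_b, samples.index].mean()),
                "n": int(len(r)),
            }
        )
    return pd.DataFrame(rows).set_index("group")


def pca_scores(
    matrix: pd.DataFrame, scale: bool = False, n_components: Optional[int] = None
) -> dict:
    """PCA of a samples x variables matrix via singular values.

    Columns are centered (and optionally unit-variance scaled); returns
    scores (samples x components), loadings (variables x components) and
    the explained-variance fraction per component (summing to 1 over the
    full rank).
    """
    x = matrix.to_numpy(dtype=float)
    if x.shape[0] < 2:
        raise DataError("need >= 2 samples")
    x = x - x.mean(axis=0)
    if scale:
        sd = x.std(axis=0, ddof=1)
        if np.any(sd == 0):
            raise DataError("zero-variance column cannot be scaled")
        x = x / sd
    if not np.any(x):
        raise DataError("constant matrix: explained variance undefined")
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    rank = int(np.sum(s > s[0] * 1e-12))
    k = rank if n_components is None else min(n_components, rank)
    explained = (s**2) / np.sum(s[:rank] ** 2)
    return {
        "scores": u[:, :k] * s[:k],
        "loadings": vt[:k].T,
        "explained_variance": explained[:k],
        "singular_values": s[:k],
        "rank": rank,
    }


@dataclass
class PLSRModel:
    """NIPALS PLS2 decomposition linking X (expression) to Y (function).

    Scores/weights/loadings are stored per extracted component on the
    autoscaled data.  ``correlation_loadings_*`` hold the Pearson
    correlation of each (scaled) variable with each X-score; plotted in
    the unit disc they show how variables align with the latent
    components.  ``loo_r2`` is the predictability: coefficient of
    determination of leave-one-out predicted vs reference Y.
    """

    x_weights: np.ndarray        # genes x comps (w)
    x_loadings: np.ndarray       # genes x comps (p)
    y_loadings: np.ndarray       # targets x comps (q)
    x_scores: np.ndarray         # samples x comps (t)
    y_scores: np.ndarray         # samples x comps (u)
    coef: np.ndarray             # genes x targets, on autoscaled data
    x_mean: np.ndarray
    x_std: np.ndarray
    y_mean: np.ndarray
    y_std: np.ndarray
    explained_x_pct: np.ndarray  # % of X variance per component
    explained_y_pct: np.ndarray  # % of Y variance per component
    correlation_loadings_x: np.ndarray  # genes x comps
    correlation_loadings_y: np.ndarray  # targets x comps
    train_r2: float
    loo_r2: Optional[float]
    x_names: list = field(default_factory=list)
    y_names: list = field(default_factory=list)
    n_iterations: list = field(default_factory=list)

    def predict(self, x_new: np.ndarray) -> np.ndarray:
        z = (np.asarray(x_new, dtype=float) - self.x_mean) / self.x_std
        return z @ self.coef * self.y_std + self.y_mean


def _autoscale(a: np.ndarray, names: Sequence[str]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mean = a.mean(axis=0)
    sd = a.std(axis=0, ddof=1)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        raise DataError(f"zero-variance variable: {names[zero[0]]}")
    return (a - mean) / sd, mean, sd


def _nipals_core(
    x: np.ndarray, y: np.ndarray, n_components: int, tol: float, max_iter: int
) -> tuple[list, list, list, list, list, list]:
    """Classic NIPALS PLS2 loop on already-scaled matrices."""
    ws, ps, qs, ts, us, iters = [], [], [], [], [], []
    xk, yk = x.copy(), y.copy()
    for _ in range(n_components):
        u = yk[:, int(np.argmax(yk.var(axis=0)))].copy()
        t_old = np.zeros(x.shape[0])
        for it in range(1, max_iter + 1):
            w = xk.T @ u
            w /= np.linalg.norm(w)
            t = xk @ w
            q = yk.T @ t
            q /= np.linalg.norm(q)
            u = yk @ q
            if np.linalg.norm(t - t_old) < tol * max(np.linalg.norm(t), 1e-30):
                break
            t_old = t
        else:
            raise DataError(f"NIPALS failed to converge in {max_iter} iterations")
        p = xk.T @ t / (t @ t)
        q_load = yk.T @ t / (t @ t)
        xk = xk - np.outer(t, p)
        yk = yk - np.outer(t, q_load)
        ws.append(w)
        ps.append(p)
        qs.append(q_load)
        ts.append(t)
        us.append(u)
        iters.append(it)
    return ws, ps, qs, ts, us, iters


def _pls_coef(ws: list, ps: list, qs: list) -> np.ndarray:
    w_mat = np.column_stack(ws)
    p_mat = np.column_stack(ps)
    q_mat = np.column_stack(qs)
    return w_mat @ np.linalg.inv(p_mat.T @ w_mat) @ q_mat.T


def plsr_nipals(
    x: pd.DataFrame,
    y: pd.DataFrame,
    n_components: int = 2,
    tol: float = 1e-10,
    max_iter: int = 500,
    cross_validate: bool = True,
) -> PLSRModel:
    """NIPALS partial least squares regression of Y on X (PLS2).

    Both blocks are autoscaled (column centering + unit variance).  Per
    component the classic NIPALS inner loop iterates
    ``w ∝ X'u, t = Xw, q ∝ Y't, u = Yq`` to convergence, then deflates
    both blocks by the X-score.  Predictability is the leave-one-out
    cross-validated R² of predicted vs reference Y, pooled over targets.
    """
    x_arr = x.to_numpy(dtype=float)
    y_arr = y.to_numpy(dtype=float)
    if y_arr.ndim == 1:
        y_arr = y_arr[:, None]
    if x_arr.shape[0] != y_arr.shape[0]:
        raise DataError("X and Y must share the sample dimension")
    n = x_arr.shape[0]
    max_rank = min(n - 1, x_arr.shape[1])
    if n_components > max_rank:
        raise ParameterError(f"n_components > attainable rank ({max_rank})")

    xs, xm, xsd = _autoscale(x_arr, list(x.columns))
    y_names = list(y.columns) if hasattr(y, "columns") else [f"y{i}" for i in range(y_arr.shape[1])]
    ys, ym, ysd = _autoscale(y_arr, y_names)

    ws, ps, qs, ts, us, iters = _nipals_core(xs, ys, n_components, tol, max_iter)
    t_mat = np.column_stack(ts)
    coef = _pls_coef(ws, ps, qs)

    ssx = np.sum(xs**2)
    ssy = np.sum(ys**2)
    expl_x = np.array([(t @ t) * (p @ p) / ssx * 100.0 for t, p in zip(ts, ps)])
    expl_y = np.array([(t @ t) * (q @ q) / ssy * 100.0 for t, q in zip(ts, qs)])

    def corr_with_scores(block: np.ndarray) -> np.ndarray:
        out = np.empty((block.shape[1], t_mat.shape[1]))
        for j in range(block.shape[1]):
            for k in range(t_mat.shape[1]):
                out[j, k] = np.corrcoef(block[:, j], t_mat[:, k])[0, 1]
        return out

    y_hat = xs @ coef
    train_r2 = 1.0 - np.sum((ys - y_hat) ** 2) / np.sum(ys**2)

    loo_r2 = None
    if cross_validate and n >= 3:
        preds = np.empty_like(y_arr)
        for i in range(n):
            keep = np.arange(n) != i
            xt, xmt, xst = _autoscale(x_arr[keep], list(x.columns))
            yt, ymt, yst = _autoscale(y_arr[keep], y_names)
            k_i = min(n_components, min(keep.sum() - 1, xt.shape[1]))
            w_i, p_i, q_i, *_ = _nipals_core(xt, yt, k_i, tol, max_iter)
            coef_i = _pls_coef(w_i, p_i, q_i)
            preds[i] = ((x_arr[i] - xmt) / xst) @ coef_i * yst + ymt
        ss_res = np.sum((y_arr - preds) ** 2)
        ss_tot = np.sum((y_arr - y_arr.mean(axis=0)) ** 2)
        loo_r2 = float(1.0 - ss_res / ss_tot)

    return PLSRModel(
        x_weights=np.column_stack(ws),
        x_loadings=np.column_stack(ps),
        y_loadings=np.column_stack(qs),
        x_scores=t_mat,
        y_scores=np.column_stack(us),
        coef=coef,
        x_mean=xm,
        x_std=xsd,
        y_mean=ym,
        y_std=ysd,
        explained_x_pct=expl_x,
        explained_y_pct=expl_y,
        correlation_loadings_x=corr_with_scores(xs),
        correlation_loadings_y=corr_with_scores(ys),
        train_r2=float(train_r2),
        loo_r2=loo_r2,
        x_names=list(x.columns),
        y_names=y_names,
        n_iterations=iters,
    )
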