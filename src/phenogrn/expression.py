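"""Expression-side summary statistics.

Gene selection from a differential-expression table (BH-FDR and |logFC|
thresholds) and TF-gene pseudo p-values obtained by inverse quantile
normalisation, Elastic-Net support selection along a regularisation path,
and OLS t-test p-values on the selected support.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.linear_model import enet_path

from phenogrn.model import P_FLOOR

logger = logging.getLogger(__name__)


@dataclass
class ElasticNetSpec:
    """Settings of the penalised pre-selection step.

    ``rho`` is the L1 mixing weight of the loss
    ``1/(2n)||y - Xw||^2 + alpha*rho*||w||_1 + alpha*(1-rho)/2*||w||^2``.
    ``max_selected`` caps the support so the follow-up OLS keeps at least
    three residual degrees of freedom.
    """

    rho: float = 0.5
    path_length: int = 50
    max_selected: int = 15
    eps: float = 1e-3

    def __post_init__(self):
        if not 0.0 < self.rho <= 1.0:
            raise ValueError("rho must lie in (0, 1]")
        if self.path_length < 2:
            raise ValueError("path_length must be >= 2")


@dataclass(frozen=True)
class ElasticNetSelection:
    tfs: tuple[str, ...]
    alpha: float
    coefficients: dict


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, clipped to 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value sequence")
    if np.any(p <= 0) or np.any(p > 1) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(n)
    out[order] = adj
    return out


def select_de_genes(de: pd.DataFrame, fdr_max: float = 0.01, abs_lfc_min: float = 2.0) -> set:
    """Genes passing fdr < fdr_max and |logFC| > abs_lfc_min (both strict)."""
    if fdr_max <= 0 or abs_lfc_min <= 0:
        raise ValueError("thresholds must be positive")
    if de.empty:
        return set()
    cols = _de_columns(de)
    if "fdr" in cols:
        fdr = de[cols["fdr"]].to_numpy(dtype=float)
    else:
        fdr = bh_adjust(de[cols["pvalue"]].to_numpy(dtype=float))
    keep = (fdr < fdr_max) & (de[cols["logFC"]].abs().to_numpy() > abs_lfc_min)
    return set(de.loc[keep, cols["gene"]])


def _de_columns(de: pd.DataFrame) -> dict:
    """Resolve the edgeR-style column dialect of a DE table."""
    mapping = {}
    lower = {c.lower(): c for c in de.columns}
    for key, names in {
        "gene": ("gene", "genes", "gene_id"),
        "logFC": ("logfc", "log2fc", "log2foldchange"),
        "pvalue": ("pvalue", "p_value", "p.value"),
        "fdr": ("fdr", "padj", "adj_pvalue"),
    }.items():
        for name in names:
            if name in lower:
                mapping[key] = lower[name]
                break
        else:
            if key != "fdr":
                raise ValueError(
                    f"DE table lacks a {key!r} column; available: {list(de.columns)}"
                )
    return mapping


def inverse_quantile_normalize(values) -> np.ndarray:
    """Map values through ranks onto a standard normal.

    Uses the plotting position (rank - 0.5) / n with average ranks on ties;
    constant input degenerates to all zeros (logged, not raised).
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least two values")
    if not np.all(np.isfinite(x)):
        raise ValueError("values must be finite")
    if np.ptp(x) == 0:
        logger.warning("constant vector in inverse quantile normalization; returning zeros")
        return np.zeros_like(x)
    ranks = stats.rankdata(x, method="average")
    return stats.norm.ppf((ranks - 0.5) / x.size)


def elastic_net_path_select(y, X, spec: ElasticNetSpec, tf_names=None) -> ElasticNetSelection:
    """Select a capped TF support along a geometric Elastic-Net path.

    The path runs from alpha_max (smallest penalty with an all-zero
    solution) downward; the returned support is the one at the last path
    point whose size stays within min(max_selected, n - 3).
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, k = X.shape
    if tf_names is None:
        tf_names = [f"x{i}" for i in range(k)]
    if n < 4:
        raise ValueError("need at least 4 samples")
    cap = min(spec.max_selected, n - 3)
    if np.allclose(y, 0.0):
        return ElasticNetSelection(tfs=(), alpha=np.inf, coefficients={})
    alpha_max = float(np.max(np.abs(X.T @ y)) / (n * spec.rho))
    if alpha_max <= 0:
        return ElasticNetSelection(tfs=(), alpha=np.inf, coefficients={})
    alphas = np.geomspace(alpha_max, alpha_max * spec.eps, spec.path_length)
    # enet_path expects decreasing alphas and fits without intercept
    _, coefs, _ = enet_path(X, y, l1_ratio=spec.rho, alphas=alphas, eps=spec.eps, tol=1e-10)
    support_sizes = (np.abs(coefs) > 0).sum(axis=0)
    ok = np.where(support_sizes <= cap)[0]
    if ok.size == 0:
        return ElasticNetSelection(tfs=(), alpha=float(alphas[0]), coefficients={})
    idx = int(ok[-1])  # last (smallest-penalty) admissible path point
    sel = np.abs(coefs[:, idx]) > 0
    chosen = tuple(tf_names[i] for i in np.where(sel)[0])
    coefficients = {tf_names[i]: float(coefs[i, idx]) for i in np.where(sel)[0]}
    return ElasticNetSelection(tfs=chosen, alpha=float(alphas[idx]), coefficients=coefficients)


def ols_pseudo_pvalues(y, X_sel, tf_names=None) -> pd.DataFrame:
    """Two-sided OLS t-test p-values per selected TF (intercept included).

    Rank-deficient design matrices drop dependent columns with a warning.
    Returns a DataFrame with columns tf, pseudo_p, coefficient.
    """
    y = np.asarray(y, dtype=float)
    X_sel = np.asarray(X_sel, dtype=float)
    n, k = X_sel.shape
    if tf_names is None:
        tf_names = [f"x{i}" for i in range(k)]
    if k > n - 3:
        raise ValueError(f"too many regressors ({k}) for {n} samples")
    rank = np.linalg.matrix_rank(np.column_stack([np.ones(n), X_sel]))
    if rank < k + 1:
        keep = _independent_columns(X_sel)
        logger.warning("rank-deficient design; dropping %d dependent columns", k - len(keep))
        X_sel = X_sel[:, keep]
        tf_names = [tf_names[i] for i in keep]
        k = len(keep)
    res = sm.OLS(y, sm.add_constant(X_sel, has_constant="add")).fit()
    pvals = np.clip(res.pvalues[1:], P_FLOOR, 1.0)
    return pd.DataFrame(
        {"tf": list(tf_names), "pseudo_p": pvals, "coefficient": res.params[1:]}
    )


def _independent_columns(X) -> list:
    keep = []
    n = X.shape[0]
    base = np.ones((n, 1))
    for i in range(X.shape[1]):
        trial = np.column_stack([base, X[:, i]])
        if np.linalg.matrix_rank(trial) > base.shape[1]:
            keep.append(i)
            base = trial
    return keep


def compute_tf_gene_expr_stats(
    expr: pd.DataFrame,
    tfs,
    genes,
    spec: ElasticNetSpec | None = None,
) -> pd.DataFrame:
    """Per-gene Elastic-Net selection + OLS pseudo p-values against TF expression.

    ``expr`` is a (genes+TFs) x samples matrix.  Each target gene's row is
    inverse quantile-normalised; TF columns are standardised once.  Genes
    whose selection is empty contribute no rows.
    """
    spec = spec or ElasticNetSpec()
    tfs, genes = list(tfs), list(genes)
    if set(tfs) & set(genes):
        raise ValueError("tfs and genes must be disjoint")
    missing = [g for g in tfs + genes if g not in expr.index]
    if missing:
        raise KeyError(f"identifiers missing from expression matrix: {missing[:5]}")
    X = expr.loc[tfs].to_numpy(dtype=float).T  # samples x TFs
    sd = X.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    X = (X - X.mean(axis=0)) / sd
    rows = []
    for gene in genes:
        y = inverse_quantile_normalize(expr.loc[gene].to_numpy(dtype=float))
        sel = elastic_net_path_select(y, X, spec, tf_names=tfs)
        if not sel.tfs:
            continue
        idx = [tfs.index(tf) for tf in sel.tfs]
        stats_df = ols_pseudo_pvalues(y, X[:, idx], tf_names=list(sel.tfs))
        stats_df.insert(1, "gene", gene)
        rows.append(stats_df)
    if not rows:
        return pd.DataFrame(columns=["tf", "gene", "pseudo_p", "coefficient"])
    return pd.concat(rows, ignore_index=True)[["tf", "gene", "pseudo_p", "coefficient"]]
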