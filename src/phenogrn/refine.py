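"""Network refinement: per-gene normalisation, three filters, final assembly.

Per gene the mean posterior scores of candidates and negative controls are
min-max normalised jointly, then pruned by an elbow cut on the descending
score list (Filter1), by the negative-control thresholds (Filter2), and by
the prior-mean threshold mu (Filter3).  Equality at any boundary survives.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from phenogrn.model import CONTROL_LABELS

logger = logging.getLogger(__name__)

DEFAULT_MU = 2.0 / 22.0

FILTER_LABELS = ("Filter1", "Filter2", "Filter3")


@dataclass(frozen=True)
class ScoredEdge:
    tf: str
    gene: str
    raw_score: float
    norm_score: float
    passed: frozenset = frozenset()


@dataclass
class FinalGRN:
    edges: list[ScoredEdge] = field(default_factory=list)
    total_genes: int = 0

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "tf": e.tf,
                "gene": e.gene,
                "confidence": e.norm_score,
                "raw_score": e.raw_score,
                "filters_passed": ",".join(sorted(e.passed)),
            }
            for e in self.edges
        ]
        return pd.DataFrame(
            rows, columns=["tf", "gene", "confidence", "raw_score", "filters_passed"]
        )


def normalize_gene_scores(scores: dict) -> dict:
    """Min-max normalise one gene's scores (candidates and controls jointly)."""
    if not scores:
        raise ValueError("empty score mapping")
    vals = np.array(list(scores.values()), dtype=float)
    lo, hi = vals.min(), vals.max()
    if hi == lo:
        logger.warning("constant scores for a gene; normalized to zeros")
        return {k: 0.0 for k in scores}
    return {k: (v - lo) / (hi - lo) for k, v in scores.items()}


def elbow_keep_count(sorted_scores) -> int:
    """Number of leading scores to keep: first local maximum of the drops.

    With drops d_k = s_k - s_(k+1) (1-based k) and sentinels d_0 = d_K =
    -inf, returns the smallest k with d_k >= d_(k-1) and d_k >= d_(k+1).
    """
    s = np.asarray(sorted_scores, dtype=float)
    if np.any(np.diff(s) > 0):
        raise ValueError("scores must be sorted in descending order")
    K = s.size
    if K <= 1:
        return K
    drops = np.concatenate([[-np.inf], -np.diff(s), [-np.inf]])  # drops[k] = d_k
    tol = 1e-9  # ties in the drop sequence must compare equal despite fp noise
    for k in range(1, K):
        if drops[k] >= drops[k - 1] - tol and drops[k] >= drops[k + 1] - tol:
            return k
    return K  # pragma: no cover - sentinel guarantees a local maximum


def control_filter(edges: dict, controls: dict) -> dict:
    """Keep edges whose normalised score >= every control score."""
    if not controls:
        raise ValueError("controls missing for gene")
    threshold = max(controls.values())
    return {tf: s for tf, s in edges.items() if s >= threshold}


def mu_filter(edges: dict, mu: float = DEFAULT_MU) -> dict:
    """Keep edges whose normalised score >= mu."""
    if not 0.0 < mu < 1.0:
        raise ValueError("mu must lie in (0, 1)")
    return {tf: s for tf, s in edges.items() if s >= mu}


def assemble_grn(posterior, mu: float = DEFAULT_MU) -> FinalGRN:
    """Normalise and filter posterior scores into the final network.

    ``posterior`` maps gene -> {tf_or_control: mean posterior}.  Filter1's
    elbow runs over the joint candidate+control ranking; Filter2 compares
    against all controls regardless of whether they survived Filter1.
    """
    scores = posterior.scores if hasattr(posterior, "scores") else dict(posterior)
    edges = []
    for gene in sorted(scores):
        entry = scores[gene]
        raw = dict(entry)
        norm = normalize_gene_scores(raw)
        controls = {k: v for k, v in norm.items() if k in CONTROL_LABELS}
        cands = {k: v for k, v in norm.items() if k not in CONTROL_LABELS}
        # Filter1: elbow over the joint descending ranking, ties at the
        # threshold retained
        ordered = sorted(norm.items(), key=lambda kv: (-kv[1], kv[0]))
        keep = elbow_keep_count([v for _, v in ordered])
        threshold = ordered[keep - 1][1]
        f1 = {tf: s for tf, s in cands.items() if s >= threshold}
        f2 = control_filter(f1, controls) if controls else dict(f1)
        f3 = mu_filter(f2, mu)
        for tf in sorted(f3):
            passed = {"Filter1"}
            if controls:
                passed.add("Filter2")
            passed.add("Filter3")
            edges.append(
                ScoredEdge(
                    tf=tf,
                    gene=gene,
                    raw_score=float(raw[tf]),
                    norm_score=float(norm[tf]),
                    passed=frozenset(passed),
                )
            )
    return FinalGRN(edges=edges, total_genes=len(scores))


def summarize_grn(grn: FinalGRN, total_genes: int | None = None) -> tuple[pd.DataFrame, float]:
    """Per-TF target counts and percentages of the final-gene universe.

    Returns (table sorted by count descending, mean of the per-TF
    percentages).  Percentages are rounded to two decimals.
    """
    total = total_genes if total_genes is not None else grn.total_genes
    if total <= 0:
        raise ValueError("total_genes must be positive")
    counts: dict[str, int] = {}
    for e in grn.edges:
        counts[e.tf] = counts.get(e.tf, 0) + 1
    if not counts:
        warnings.warn("empty network; mean percentage reported as 0", RuntimeWarning, stacklevel=2)
        return pd.DataFrame(columns=["tf", "n_targets", "percentage"]), 0.0
    rows = [
        {"tf": tf, "n_targets": n, "percentage": round(100.0 * n / total, 2)}
        for tf, n in counts.items()
    ]
    table = pd.DataFrame(rows).sort_values(
        ["n_targets", "tf"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
    mean_pct = round(float(table["percentage"].mean()), 2)
    return table, mean_pct


def grn_from_counts(counts: dict, total_genes: int) -> FinalGRN:
    """Build a degenerate network with the given per-TF target counts.

    Convenience for summary arithmetic on externally tabulated networks.
    """
    edges = [
        ScoredEdge(tf=tf, gene=f"{tf}_target_{i}", raw_score=1.0, norm_score=1.0)
        for tf, n in counts.items()
        for i in range(n)
    ]
    return FinalGRN(edges=edges, total_genes=total_genes)
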