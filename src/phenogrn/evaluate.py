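"""Precision-recall evaluation against a ground-truth edge list.

The headline metric is the AUPRC ratio: average precision divided by the
positive prevalence (the AUPRC of a random predictor), so 1 is chance
level.  Scores are rankings over (tf, gene) pairs; universe pairs the
method never scored rank last as one tied group.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GroundTruthNetwork:
    positives: frozenset
    universe: frozenset

    def __post_init__(self):
        object.__setattr__(self, "positives", frozenset(self.positives))
        object.__setattr__(self, "universe", frozenset(self.universe))
        if not self.positives <= self.universe:
            raise ValueError("positives must be a subset of the universe")


@dataclass(frozen=True)
class PRResult:
    auprc: float
    prevalence: float
    auprc_ratio: float
    n_pos: int
    n_total: int


def auprc(scores: dict, truth: GroundTruthNetwork) -> PRResult:
    """Tie-grouped average precision and its ratio to the random baseline.

    The evaluation universe is the union of the truth universe and all
    scored pairs; unscored universe pairs receive -inf (one trailing tie
    group).  Equal scores form a single threshold group.
    """
    universe = set(truth.universe) | set(scores)
    if not universe & set(scores):
        raise ValueError("no scored pair intersects the universe")
    positives = set(truth.positives)
    n_pos = len(positives)
    if n_pos == 0:
        raise ValueError("ground truth has no positives")
    n_total = len(universe)
    pairs = sorted(universe)
    s = np.array([scores.get(p, -np.inf) for p in pairs], dtype=float)
    y = np.array([p in positives for p in pairs], dtype=bool)

    order = np.argsort(-s, kind="stable")
    s, y = s[order], y[order]
    ap = 0.0
    cum_pos = 0
    cum_n = 0
    i = 0
    while i < len(s):
        j = i
        while j < len(s) and s[j] == s[i]:
            j += 1
        grp_pos = int(y[i:j].sum())
        cum_pos += grp_pos
        cum_n += j - i
        if grp_pos:
            ap += grp_pos * cum_pos / cum_n
        i = j
    ap /= n_pos
    prevalence = n_pos / n_total
    return PRResult(
        auprc=float(ap),
        prevalence=float(prevalence),
        auprc_ratio=float(ap / prevalence),
        n_pos=n_pos,
        n_total=n_total,
    )


def per_tf_evaluation(scores: dict, truth: GroundTruthNetwork, tf_subset=None) -> dict:
    """AUPRC ratio per TF, restricting universe and scores to that TF's pairs."""
    tfs = sorted(tf_subset) if tf_subset is not None else sorted({tf for tf, _ in truth.positives})
    out = {}
    for tf in tfs:
        pos = {pr for pr in truth.positives if pr[0] == tf}
        if not pos:
            logger.warning("TF %s has no positives; skipped", tf)
            continue
        uni = {pr for pr in truth.universe if pr[0] == tf}
        sub_scores = {pr: v for pr, v in scores.items() if pr[0] == tf}
        if not (uni | set(sub_scores)):
            logger.warning("TF %s absent from universe and scores; skipped", tf)
            continue
        out[tf] = auprc(sub_scores, GroundTruthNetwork(positives=pos, universe=uni | pos))
    return out
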