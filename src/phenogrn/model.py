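"""Core probabilistic model: evidence containers, likelihoods and oracles.

The model places a Bernoulli(gamma) prior on each latent edge indicator
T_ij, with gamma drawn from a truncated Normal shared across genes.  The
three observed summary statistics are modelled with Beta(a, 1) / Uniform
mixtures:

* gene-phenotype p-value  P_j  ~ Uniform(0,1) when no candidate edge of
  gene j is active, Beta(alpha_prime, 1) otherwise;
* expression pseudo p-value p_ij ~ Beta(a_h1, 1) when T_ij = 1, and an
  r-weighted mixture of Beta(a_h1, 1) and Beta(a_h0, 1) otherwise;
* binding pseudo p-value q_ij, same functional form with its own latents.

Per-gene mixture latents carry Uniform hyperpriors: r ~ U(0,1),
a_h1 ~ U(0, 0.5), a_h0 ~ U(0.5, 1).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy import stats

logger = logging.getLogger(__name__)

P_FLOOR = 1e-300

#: labels of the per-gene negative-control pseudo-candidates
CONTROL_LABELS = ("ref_PIE", "ref_Q", "ref_PIE_Q")

VARIANTS = ("RnCnP", "RnP", "CnP")


def clip_pvalues(x):
    """Clip p-value-like quantities into [1e-300, 1] for log densities."""
    return np.clip(x, P_FLOOR, 1.0)


# ---------------------------------------------------------------------------
# evidence containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Candidate:
    """One candidate regulator of a gene with its two evidence channels."""

    tf: str
    p_gex: float
    p_chip: float
    is_control: bool = False

    def __post_init__(self):
        for name in ("p_gex", "p_chip"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ValueError(f"{name}={v} outside (0, 1] for tf {self.tf!r}")


@dataclass(frozen=True)
class GeneEvidence:
    """Observed summary statistics of one gene.

    ``candidates`` holds the m_j candidate regulators (and, after
    :func:`add_controls`, the per-gene negative controls).
    """

    gene: str
    p_pheno: float
    candidates: tuple[Candidate, ...]

    def __post_init__(self):
        object.__setattr__(self, "candidates", tuple(self.candidates))
        if not (0.0 < self.p_pheno <= 1.0):
            raise ValueError(f"p_pheno={self.p_pheno} outside (0, 1] for {self.gene!r}")
        if len(self.real_candidates()) < 1:
            raise ValueError(f"gene {self.gene!r} has no real candidates")
        tfs = [c.tf for c in self.candidates]
        if len(set(tfs)) != len(tfs):
            raise ValueError(f"duplicate candidate TFs for gene {self.gene!r}")

    def real_candidates(self) -> tuple[Candidate, ...]:
        return tuple(c for c in self.candidates if not c.is_control)

    def control_candidates(self) -> tuple[Candidate, ...]:
        return tuple(c for c in self.candidates if c.is_control)


# ---------------------------------------------------------------------------
# hyperparameters
# ---------------------------------------------------------------------------


@dataclass
class ModelHyperparams:
    """Fixed parameters and hyper-prior settings of the edge model.

    ``mu_gamma`` doubles as the score threshold of the final network filter.
    ``sigma_gamma`` is the sd of the *untruncated* Normal on gamma; the
    default 1/22 places the truncation bounds two sd away from the mean.
    """

    mu_gamma: float = 2.0 / 22.0
    gamma_bounds: tuple[float, float] = (0.0, 4.0 / 22.0)
    sigma_gamma: float = 1.0 / 22.0
    alpha_prime: float = 0.5
    variant: str = "RnCnP"

    def __post_init__(self):
        lo, hi = self.gamma_bounds
        if not math.isclose(self.mu_gamma - lo, hi - self.mu_gamma, rel_tol=1e-9):
            raise ValueError("gamma_bounds must be symmetric around mu_gamma")
        if not (0.0 < self.alpha_prime < 1.0):
            raise ValueError("alpha_prime must lie in (0, 1)")
        self.variant = _canonical_variant(self.variant)
        if self.sigma_gamma <= 0:
            raise ValueError("sigma_gamma must be positive")

    @property
    def uses_gex(self) -> bool:
        return self.variant in ("RnCnP", "RnP")

    @property
    def uses_chip(self) -> bool:
        return self.variant in ("RnCnP", "CnP")


def _canonical_variant(name: str) -> str:
    for v in VARIANTS:
        if name.lower() == v.lower():
            return v
    raise ValueError(f"unknown variant {name!r}; expected one of {VARIANTS}")


# ---------------------------------------------------------------------------
# densities
# ---------------------------------------------------------------------------


def beta1_pdf(x: float, a: float) -> float:
    """Density of Beta(a, 1) at x: a * x**(a-1).

    The second shape fixed at 1 makes the density monotone decreasing for
    a < 1, the model's shape for evidence-bearing p-values.
    """
    if not (0.0 < a <= 1.0):
        raise ValueError(f"shape a={a} outside (0, 1]")
    if np.any(np.asarray(x) <= 0.0) or np.any(np.asarray(x) > 1.0):
        raise ValueError("x must lie in (0, 1]; clip zeros upstream")
    return a * np.power(x, a - 1.0)


def pheno_loglik(p_pheno: float, any_edge: bool, alpha_prime: float) -> float:
    """Log-density of the gene-phenotype p-value given the edge disjunction."""
    if not any_edge:
        return 0.0  # Uniform(0,1)
    return float(np.log(beta1_pdf(p_pheno, alpha_prime)))


def evidence_loglik(x: float, edge: bool, r: float, a_h1: float, a_h0: float) -> float:
    """Log-density of one TF-gene evidence channel given its indicator."""
    if edge:
        return float(np.log(beta1_pdf(x, a_h1)))
    d = r * beta1_pdf(x, a_h1) + (1.0 - r) * beta1_pdf(x, a_h0)
    return float(np.log(d))


# ---------------------------------------------------------------------------
# alpha_prime fitting
# ---------------------------------------------------------------------------


def fit_alpha_prime(p_pheno_values, max_iter: int = 500, tol: float = 1e-8):
    """Fit lam*Beta(a,1) + (1-lam)*Uniform(0,1) to gene-phenotype p-values by EM.

    Returns ``(alpha_prime, mix_weight)``.  The M-step for the Beta shape is
    closed form: a = -sum(z) / sum(z * log(x)).
    """
    x = np.asarray(p_pheno_values, dtype=float)
    if x.size < 50:
        raise ValueError(f"need >= 50 p-values to fit alpha_prime, got {x.size}")
    if np.any(x <= 0) or np.any(x > 1):
        raise ValueError("p-values must lie in (0, 1]")
    x = clip_pvalues(x)
    logx = np.log(x)

    a, lam = 0.5, 0.5
    prev_ll = -np.inf
    for _ in range(max_iter):
        comp1 = lam * a * np.power(x, a - 1.0)
        denom = comp1 + (1.0 - lam)
        z = comp1 / denom
        sz = z.sum()
        s_zlog = float(z @ logx)
        if sz <= 0 or s_zlog >= -1e-12:
            # no mass on the Beta component (e.g. all values at 1)
            warnings.warn(
                "degenerate p-value distribution; alpha_prime at boundary guard",
                RuntimeWarning,
                stacklevel=2,
            )
            return 1.0 - 1e-6, 0.0
        a = float(np.clip(-sz / s_zlog, 1e-6, 1.0 - 1e-6))
        lam = float(np.clip(sz / x.size, 0.0, 1.0))
        ll = float(np.sum(np.log(lam * a * np.power(x, a - 1.0) + (1.0 - lam))))
        if ll - prev_ll < tol:
            break
        prev_ll = ll
    return a, lam


# ---------------------------------------------------------------------------
# negative controls
# ---------------------------------------------------------------------------


def add_controls(ev: GeneEvidence, variant: str = "RnCnP") -> GeneEvidence:
    """Append the per-gene negative-control pseudo-candidates.

    For the full variant three controls are added: ref_PIE (p=1, q=q*),
    ref_Q (p=p*, q=1) and ref_PIE_Q (p=1, q=1), where p* and q* are the
    smallest observed values over the gene's real candidates.  Ablated
    variants get the single control whose active channel they retain.
    """
    variant = _canonical_variant(variant)
    real = ev.real_candidates()
    if not real:
        raise ValueError(f"gene {ev.gene!r} has no real candidates")
    if ev.control_candidates():
        raise ValueError(f"gene {ev.gene!r} already carries controls")
    p_star = min(c.p_gex for c in real)
    q_star = min(c.p_chip for c in real)
    if variant == "RnCnP":
        controls = (
            Candidate("ref_PIE", 1.0, q_star, is_control=True),
            Candidate("ref_Q", p_star, 1.0, is_control=True),
            Candidate("ref_PIE_Q", 1.0, 1.0, is_control=True),
        )
    elif variant == "RnP":
        controls = (Candidate("ref_PIE", 1.0, 1.0, is_control=True),)
    else:  # CnP
        controls = (Candidate("ref_Q", 1.0, 1.0, is_control=True),)
    return replace(ev, candidates=ev.candidates + controls)


# ---------------------------------------------------------------------------
# quadrature oracle
# ---------------------------------------------------------------------------


def _gl_nodes(lo: float, hi: float, n: int):
    x, w = leggauss(n)
    mid, half = 0.5 * (lo + hi), 0.5 * (hi - lo)
    return mid + half * x, half * w


def oracle_posterior_single_gene(
    ev: GeneEvidence,
    hp: ModelHyperparams,
    n_quad: int = 200,
) -> float:
    """Exact single-candidate posterior P(T=1 | data) by Gauss-Legendre quadrature.

    Valid only for a gene with one real candidate and no controls; in that
    case the posterior integrals over the independent uniform hyper-priors
    factor into one-dimensional expectations:

        P(T=1) prop. to  E[gamma] * f(P|alt) * E_a1[f(p|1)] * E_a1[f(q|1)]
        P(T=0) prop. to  (1-E[gamma]) * 1 * E[f(p|0)] * E[f(q|0)]

    with E[f(x|0)] = 0.5*E_a1[Beta(x;a1,1)] + 0.5*E_a0[Beta(x;a0,1)] since
    the mixing weight r is Uniform(0,1).
    """
    if ev.control_candidates():
        raise ValueError("oracle expects a gene without controls")
    real = ev.real_candidates()
    if len(real) != 1:
        raise ValueError(f"oracle requires exactly one candidate, got {len(real)}")
    cand = real[0]

    lo, hi = hp.gamma_bounds
    a_ = (lo - hp.mu_gamma) / hp.sigma_gamma
    b_ = (hi - hp.mu_gamma) / hp.sigma_gamma
    e_gamma = float(stats.truncnorm.mean(a_, b_, loc=hp.mu_gamma, scale=hp.sigma_gamma))

    def channel_factors(x: float):
        x = float(clip_pvalues(x))
        n1, w1 = _gl_nodes(0.0, 0.5, n_quad)
        n0, w0 = _gl_nodes(0.5, 1.0, n_quad)
        e_h1 = float(np.sum(w1 * n1 * np.power(x, n1 - 1.0)) / 0.5)
        e_h0 = float(np.sum(w0 * n0 * np.power(x, n0 - 1.0)) / 0.5)
        return e_h1, 0.5 * e_h1 + 0.5 * e_h0

    f_alt = beta1_pdf(float(clip_pvalues(ev.p_pheno)), hp.alpha_prime)
    num = e_gamma * f_alt
    den0 = (1.0 - e_gamma) * 1.0
    if hp.uses_gex:
        e1, e0 = channel_factors(cand.p_gex)
        num *= e1
        den0 *= e0
    if hp.uses_chip:
        e1, e0 = channel_factors(cand.p_chip)
        num *= e1
        den0 *= e0
    return num / (num + den0)
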