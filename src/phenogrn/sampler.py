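"""MCMC posterior estimation for the latent edge indicators.

The binary indicators are marginalised exactly: conditioned on the
continuous latents, the likelihood of a gene with candidate weights
A_i = gamma*f(p_i|1)*f(q_i|1) and B_i = (1-gamma)*f(p_i|0)*f(q_i|0) is

    L = 1 * prod(B_i) + f(P|alt) * (prod(A_i + B_i) - prod(B_i))

because the gene-phenotype p-value is Uniform only when every indicator is
zero.  The remaining continuous latents (the shared truncated-Normal gamma
and the six per-gene mixture parameters, all with bounded support) are
updated by shrinkage slice sampling, vectorised across chains and the
genes of a batch.  Posterior means of the indicators are Rao-Blackwellised
averages of P(T_i = 1 | continuous draw) over retained draws, which has
strictly lower Monte-Carlo variance than averaging sampled indicators.

Negative controls are modelled as independent single-edge replicas that
share gamma and the gene's mixture latents and re-observe the gene's
phenotype p-value.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from phenogrn.model import GeneEvidence, ModelHyperparams, add_controls, clip_pvalues

logger = logging.getLogger(__name__)

_EPS = 1e-12
_RHAT_WARN = 1.05


@dataclass
class SamplerConfig:
    """MCMC settings: draws/tuning/chains mirror the published defaults."""

    n_draws: int = 4000
    n_tune: int = 2000
    n_chains: int = 4
    n_burn: int | None = None  # defaults to 10% of n_draws
    seed: int = 0
    batch_size: int = 50

    def __post_init__(self):
        if self.n_burn is None:
            self.n_burn = int(round(0.1 * self.n_draws))
        if min(self.n_draws, self.n_tune, self.n_chains, self.batch_size) <= 0:
            raise ValueError("draws, tune, chains and batch_size must be positive")
        if not 0 <= self.n_burn < self.n_draws:
            raise ValueError("n_burn must satisfy 0 <= n_burn < n_draws")


@dataclass
class PosteriorScores:
    """Mean posterior edge probability per gene for candidates and controls."""

    scores: dict[str, dict[str, float]]
    diagnostics: dict = field(default_factory=dict)

    def items(self):
        return self.scores.items()

    def __getitem__(self, gene):
        return self.scores[gene]


# ---------------------------------------------------------------------------
# batch data layout
# ---------------------------------------------------------------------------


class _BatchData:
    """Padded arrays for one batch of genes (shared across chains)."""

    def __init__(self, evs: list[GeneEvidence], hp: ModelHyperparams):
        self.genes = [ev.gene for ev in evs]
        G = len(evs)
        reals = [ev.real_candidates() for ev in evs]
        ctrls = [ev.control_candidates() for ev in evs]
        M = max(len(r) for r in reals)
        C = max((len(c) for c in ctrls), default=0)
        self.G, self.M, self.C = G, M, C
        self.mask = np.zeros((G, M), dtype=bool)
        p = np.ones((G, M))
        q = np.ones((G, M))
        self.cand_tfs: list[list[str]] = []
        for g, cands in enumerate(reals):
            self.cand_tfs.append([c.tf for c in cands])
            for i, c in enumerate(cands):
                self.mask[g, i] = True
                p[g, i] = c.p_gex
                q[g, i] = c.p_chip
        self.cmask = np.zeros((G, C), dtype=bool)
        pc = np.ones((G, C))
        qc = np.ones((G, C))
        self.ctrl_labels: list[list[str]] = []
        for g, cands in enumerate(ctrls):
            self.ctrl_labels.append([c.tf for c in cands])
            for i, c in enumerate(cands):
                self.cmask[g, i] = True
                pc[g, i] = c.p_gex
                qc[g, i] = c.p_chip
        self.logp = np.log(clip_pvalues(p))
        self.logq = np.log(clip_pvalues(q))
        self.logpc = np.log(clip_pvalues(pc))
        self.logqc = np.log(clip_pvalues(qc))
        P = clip_pvalues(np.array([ev.p_pheno for ev in evs]))
        self.log_falt = np.log(hp.alpha_prime) + (hp.alpha_prime - 1.0) * np.log(P)


# ---------------------------------------------------------------------------
# likelihood kernels (chains x genes x candidates)
# ---------------------------------------------------------------------------


def _channel_terms(logx, r, a1, a0):
    """Return (log f(x|edge), log f(x|no edge)) for one evidence channel.

    logx: (G, M); r, a1, a0: (K, G) -> outputs (K, G, M).
    """
    l1 = np.log(a1)[:, :, None] + (a1 - 1.0)[:, :, None] * logx[None, :, :]
    l_h0 = np.log(a0)[:, :, None] + (a0 - 1.0)[:, :, None] * logx[None, :, :]
    l0 = np.logaddexp(
        np.log(r)[:, :, None] + l1, np.log1p(-r)[:, :, None] + l_h0
    )
    return l1, l0


def _gene_loglik(loggam, log1mgam, log_falt, l1, l0, mask):
    """Marginal log-likelihood of each gene given continuous latents.

    loggam/log1mgam: (K,) or (K, 1); log_falt: (G,); l1/l0: (K, G, M) sums
    of per-channel edge/no-edge log densities; mask: (G, M).
    """
    logA = loggam[:, None, None] + l1
    logB = log1mgam[:, None, None] + l0
    sB = np.where(mask[None, :, :], logB, 0.0).sum(axis=2)
    sAB = np.where(mask[None, :, :], np.logaddexp(logA, logB), 0.0).sum(axis=2)
    d = sB - sAB  # <= 0
    f = np.exp(log_falt)[None, :]
    # L = f*exp(sAB) + (1-f)*exp(sB), stable on both sides of f = 1
    with np.errstate(divide="ignore"):
        small = sAB + np.log(np.maximum(f + (1.0 - f) * np.exp(d), 1e-300))
        big = sAB + log_falt[None, :] + np.log1p(
            -np.clip((1.0 - np.exp(-log_falt))[None, :] * np.exp(d), None, 1.0 - 1e-16)
        )
    return np.where(f <= 1.0, small, big), logA, logB, sAB


def _control_loglik(loggam, log1mgam, log_falt, l1c, l0c, cmask):
    """Summed log-likelihood of the control replicas per gene: (K, G)."""
    logAc = loggam[:, None, None] + log_falt[None, :, None] + l1c
    logBc = log1mgam[:, None, None] + l0c
    return np.where(cmask[None, :, :], np.logaddexp(logAc, logBc), 0.0).sum(axis=2)


class _Likelihood:
    """Evaluates total per-chain-per-gene log-likelihood with channel caching."""

    def __init__(self, data: _BatchData, hp: ModelHyperparams, prior_only: bool):
        self.data = data
        self.hp = hp
        self.prior_only = prior_only

    def channel_cache(self, lat):
        """Compute per-channel terms for current latents; (K,G,M)+(K,G,C) sums."""
        d, hp = self.data, self.hp
        K, G = lat["r_gex"].shape if hp.uses_gex else lat["r_chip"].shape
        l1 = np.zeros((K, G, d.M))
        l0 = np.zeros((K, G, d.M))
        l1c = np.zeros((K, G, d.C))
        l0c = np.zeros((K, G, d.C))
        if hp.uses_gex:
            a, b = _channel_terms(d.logp, lat["r_gex"], lat["a1_gex"], lat["a0_gex"])
            l1 += a
            l0 += b
            if d.C:
                a, b = _channel_terms(d.logpc, lat["r_gex"], lat["a1_gex"], lat["a0_gex"])
                l1c += a
                l0c += b
        if hp.uses_chip:
            a, b = _channel_terms(d.logq, lat["r_chip"], lat["a1_chip"], lat["a0_chip"])
            l1 += a
            l0 += b
            if d.C:
                a, b = _channel_terms(d.logqc, lat["r_chip"], lat["a1_chip"], lat["a0_chip"])
                l1c += a
                l0c += b
        return l1, l0, l1c, l0c

    def total(self, gamma, l1, l0, l1c, l0c):
        """(K, G) total data log-likelihood given gamma (K,) and channel terms."""
        if self.prior_only:
            return np.zeros((gamma.shape[0], self.data.G))
        loggam = np.log(gamma)
        log1mgam = np.log1p(-gamma)
        ll, *_ = _gene_loglik(loggam, log1mgam, self.data.log_falt, l1, l0, self.data.mask)
        if self.data.C:
            ll = ll + _control_loglik(
                loggam, log1mgam, self.data.log_falt, l1c, l0c, self.data.cmask
            )
        return ll


# ---------------------------------------------------------------------------
# slice sampling
# ---------------------------------------------------------------------------


def _slice_update(logf, x0, lo, hi, rng, max_shrink=200):
    """Shrinkage slice sampler on a bounded support, vectorised elementwise.

    ``logf`` maps an array shaped like ``x0`` to per-element log densities.
    The initial bracket is the full support, which is valid for bounded
    targets and needs no stepping out.
    """
    shape = x0.shape
    ly = logf(x0) + np.log(rng.random(shape))
    L = np.full(shape, lo, dtype=float)
    R = np.full(shape, hi, dtype=float)
    x = x0.copy()
    active = np.ones(shape, dtype=bool)
    for _ in range(max_shrink):
        prop = L + rng.random(shape) * (R - L)
        np.clip(prop, lo + _EPS, hi - _EPS, out=prop)
        trial = np.where(active, prop, x)
        fv = logf(trial)
        acc = fv >= ly
        x = np.where(active & acc, prop, x)
        shrink = active & ~acc
        L = np.where(shrink & (prop < x0), prop, L)
        R = np.where(shrink & (prop >= x0), prop, R)
        active &= ~acc
        if not active.any():
            break
    else:  # pragma: no cover - numerical safety net
        x = np.where(active, x0, x)
    return x


_LATENT_BOUNDS = {
    "r_gex": (0.0, 1.0),
    "a1_gex": (0.0, 0.5),
    "a0_gex": (0.5, 1.0),
    "r_chip": (0.0, 1.0),
    "a1_chip": (0.0, 0.5),
    "a0_chip": (0.5, 1.0),
}


def _active_latents(hp: ModelHyperparams):
    names = []
    if hp.uses_gex:
        names += ["r_gex", "a1_gex", "a0_gex"]
    if hp.uses_chip:
        names += ["r_chip", "a1_chip", "a0_chip"]
    return names


# ---------------------------------------------------------------------------
# posterior edge probabilities given continuous draws
# ---------------------------------------------------------------------------


def _indicator_probs(gamma, log_falt, l1, l0, l1c, l0c, data: _BatchData):
    """Rao-Blackwellised P(T=1 | continuous latents) for candidates and controls."""
    loggam = np.log(gamma)
    log1mgam = np.log1p(-gamma)
    logL, logA, logB, sAB = _gene_loglik(loggam, log1mgam, log_falt, l1, l0, data.mask)
    lognum = log_falt[None, :, None] + logA + (
        sAB[:, :, None] - np.logaddexp(logA, logB)
    )
    probs = np.exp(lognum - logL[:, :, None])
    probs = np.where(data.mask[None, :, :], np.clip(probs, 0.0, 1.0), 0.0)
    if data.C:
        logAc = loggam[:, None, None] + log_falt[None, :, None] + l1c
        logBc = log1mgam[:, None, None] + l0c
        cprobs = np.where(data.cmask[None, :, :], expit(logAc - logBc), 0.0)
    else:
        cprobs = np.zeros((gamma.shape[0], data.G, 0))
    return probs, cprobs


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------


def split_rhat(chains: np.ndarray) -> float:
    """Split-R-hat of a (n_chains, n_draws) array of scalar draws."""
    n = chains.shape[1] // 2
    if n < 2:
        return float("nan")
    halves = np.concatenate([chains[:, :n], chains[:, n : 2 * n]], axis=0)
    m, n_ = halves.shape
    means = halves.mean(axis=1)
    w = halves.var(axis=1, ddof=1).mean()
    b = n_ * means.var(ddof=1)
    if w <= 0:
        return 1.0
    var_plus = (n_ - 1) / n_ * w + b / n_
    return float(np.sqrt(var_plus / w))


# ---------------------------------------------------------------------------
# main driver
# ---------------------------------------------------------------------------


def _init_state(data: _BatchData, hp: ModelHyperparams, rng, n_chains):
    from scipy import stats

    lo, hi = hp.gamma_bounds
    a_ = (lo - hp.mu_gamma) / hp.sigma_gamma
    b_ = (hi - hp.mu_gamma) / hp.sigma_gamma
    gamma = stats.truncnorm.ppf(
        rng.random(n_chains), a_, b_, loc=hp.mu_gamma, scale=hp.sigma_gamma
    )
    gamma = np.clip(gamma, lo + _EPS, hi - _EPS)
    lat = {}
    for name, (blo, bhi) in _LATENT_BOUNDS.items():
        lat[name] = np.clip(
            blo + rng.random((n_chains, data.G)) * (bhi - blo), blo + _EPS, bhi - _EPS
        )
    return gamma, lat


def _run_batch(
    data: _BatchData,
    hp: ModelHyperparams,
    sc: SamplerConfig,
    seed_seq: np.random.SeedSequence,
    prior_only: bool,
):
    lik = _Likelihood(data, hp, prior_only)
    rng = np.random.default_rng(seed_seq)
    K = sc.n_chains
    gamma, lat = _init_state(data, hp, rng, K)
    names = [] if prior_only else _active_latents(hp)

    l1, l0, l1c, l0c = lik.channel_cache(lat)
    ll0 = lik.total(gamma, l1, l0, l1c, l0c)
    if not np.all(np.isfinite(ll0)):
        bad = data.genes[int(np.argwhere(~np.isfinite(ll0))[0][1])]
        raise FloatingPointError(f"non-finite log-likelihood at init for gene {bad!r}")

    glo, ghi = hp.gamma_bounds
    mu, sig = hp.mu_gamma, hp.sigma_gamma

    def gamma_logf(g):
        lp = -0.5 * ((g - mu) / sig) ** 2
        return lp + lik.total(g, l1, l0, l1c, l0c).sum(axis=1)

    cand_sum = np.zeros((K, data.G, data.M))
    ctrl_sum = np.zeros((K, data.G, data.C))
    n_kept = np.zeros(K)
    gamma_trace = np.zeros((K, sc.n_draws))

    total_iters = sc.n_tune + sc.n_draws
    for it in range(total_iters):
        gamma = _slice_update(gamma_logf, gamma, glo, ghi, rng)
        for name in names:
            blo, bhi = _LATENT_BOUNDS[name]

            def lat_logf(vals, _name=name):
                trial = dict(lat)
                trial[_name] = vals
                t1, t0, t1c, t0c = lik.channel_cache(trial)
                return lik.total(gamma, t1, t0, t1c, t0c)

            lat[name] = _slice_update(lat_logf, lat[name], blo, bhi, rng)
        if names:
            l1, l0, l1c, l0c = lik.channel_cache(lat)
        draw = it - sc.n_tune
        if draw >= 0:
            gamma_trace[:, draw] = gamma
            if draw >= sc.n_burn:
                if prior_only:
                    cand_sum += gamma[:, None, None]
                    n_kept += 1
                else:
                    probs, cprobs = _indicator_probs(
                        gamma, data.log_falt, l1, l0, l1c, l0c, data
                    )
                    cand_sum += probs
                    ctrl_sum += cprobs
                    n_kept += 1

    rhat = split_rhat(gamma_trace[:, sc.n_burn :])
    cand_mean = cand_sum.sum(axis=0) / n_kept.sum()
    ctrl_mean = ctrl_sum.sum(axis=0) / n_kept.sum() if data.C else None
    return cand_mean, ctrl_mean, rhat


def sample_posterior(
    evidence,
    hp: ModelHyperparams,
    sc: SamplerConfig,
    include_controls: bool = True,
    prior_only: bool = False,
) -> PosteriorScores:
    """Estimate mean posterior edge probabilities for every candidate and control.

    ``evidence`` is an iterable of :class:`GeneEvidence`.  Controls are
    appended per gene (variant-aware) unless already present or
    ``include_controls`` is False.  Genes are processed in batches; gamma is
    shared within a batch and independent across batches.
    """
    evs = list(evidence)
    if not evs:
        raise ValueError("evidence set is empty")
    if include_controls and not prior_only:
        evs = [ev if ev.control_candidates() else add_controls(ev, hp.variant) for ev in evs]

    batches = [evs[i : i + sc.batch_size] for i in range(0, len(evs), sc.batch_size)]
    seqs = np.random.SeedSequence(sc.seed).spawn(len(batches))
    scores: dict[str, dict[str, float]] = {}
    rhats = []
    for b, (batch, seq) in enumerate(zip(batches, seqs)):
        t0 = time.perf_counter()
        data = _BatchData(batch, hp)
        cand_mean, ctrl_mean, rhat = _run_batch(data, hp, sc, seq, prior_only)
        rhats.append(rhat)
        if np.isfinite(rhat) and rhat > _RHAT_WARN:
            logger.warning("batch %d: split-Rhat(gamma) = %.3f > %.2f", b, rhat, _RHAT_WARN)
        for g, gene in enumerate(data.genes):
            entry = {}
            for i, tf in enumerate(data.cand_tfs[g]):
                entry[tf] = float(cand_mean[g, i])
            if ctrl_mean is not None:
                for i, label in enumerate(data.ctrl_labels[g]):
                    entry[label] = float(ctrl_mean[g, i])
            scores[gene] = entry
        logger.info(
            "batch %d/%d: %d genes, %.2fs, split-Rhat(gamma)=%.3f",
            b + 1,
            len(batches),
            data.G,
            time.perf_counter() - t0,
            rhat,
        )
    return PosteriorScores(scores=scores, diagnostics={"rhat_gamma": rhats})
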