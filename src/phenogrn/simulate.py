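"""Synthetic planted-network generator.

Produces ground-truth networks and the three summary-statistic tables with
exactly the statistical structure the edge model assumes (Uniform /
Beta(a, 1) mixtures with planted edges), plus an optional linear-effect
expression matrix, so the whole pipeline can be exercised without any
external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from phenogrn.model import Candidate, GeneEvidence, P_FLOOR

_STAGES = ("network", "evidence", "expression")


@dataclass
class SimulationConfig:
    n_tfs: int = 22
    n_genes: int = 200
    frac_pheno_genes: float = 0.3
    edges_per_pheno_gene: float = 2.0
    alpha_prime_true: float = 0.2
    alpha_h1_gex: float = 0.1
    alpha_h0_gex: float = 0.8
    alpha_h1_chip: float = 0.1
    alpha_h0_chip: float = 0.8
    r_gex: float = 0.2
    r_chip: float = 0.2
    n_decoys: int = 5
    n_samples_per_class: int = 14
    effect_size: float = 1.0
    class_shift: float = 1.0
    noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.n_tfs <= 0 or self.n_genes <= 0:
            raise ValueError("n_tfs and n_genes must be positive")
        if not 0.0 <= self.frac_pheno_genes <= 1.0:
            raise ValueError("frac_pheno_genes must lie in [0, 1]")
        for name in ("alpha_prime_true", "alpha_h1_gex", "alpha_h0_gex",
                     "alpha_h1_chip", "alpha_h0_chip"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name}={v} outside (0, 1]")
        for mod in ("gex", "chip"):
            if getattr(self, f"alpha_h1_{mod}") >= getattr(self, f"alpha_h0_{mod}"):
                raise ValueError(f"alpha_h1_{mod} must be < alpha_h0_{mod}")
        for name in ("r_gex", "r_chip"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.edges_per_pheno_gene > self.n_tfs:
            raise ValueError("edges_per_pheno_gene cannot exceed n_tfs")

    def rng(self, stage: str) -> np.random.Generator:
        """Stage-specific generator split from the shared seed."""
        children = np.random.SeedSequence(self.seed).spawn(len(_STAGES))
        return np.random.default_rng(children[_STAGES.index(stage)])


@dataclass(frozen=True)
class PlantedNetwork:
    tfs: tuple[str, ...]
    genes: tuple[str, ...]
    edges: frozenset
    pheno_genes: frozenset

    def __post_init__(self):
        tfs, genes = set(self.tfs), set(self.genes)
        for tf, gene in self.edges:
            if tf not in tfs or gene not in genes:
                raise ValueError(f"edge ({tf}, {gene}) references unknown node")
            if gene not in self.pheno_genes:
                raise ValueError(f"edge target {gene} is not a phenotype gene")

    def tfs_of(self, gene: str) -> list[str]:
        return sorted(tf for tf, g in self.edges if g == gene)


def generate_planted_network(cfg: SimulationConfig) -> PlantedNetwork:
    """Plant phenotype genes and >= 1 regulator edge each, reproducibly."""
    rng = cfg.rng("network")
    tfs = tuple(f"TF{i + 1}" for i in range(cfg.n_tfs))
    genes = tuple(f"G{j + 1}" for j in range(cfg.n_genes))
    n_pheno = int(round(cfg.frac_pheno_genes * cfg.n_genes))
    pheno = sorted(rng.choice(cfg.n_genes, size=n_pheno, replace=False).tolist())
    pheno_genes = frozenset(genes[j] for j in pheno)
    edges = set()
    for gene in sorted(pheno_genes):
        k = max(1, int(rng.poisson(cfg.edges_per_pheno_gene)))
        k = min(k, cfg.n_tfs)
        chosen = rng.choice(cfg.n_tfs, size=k, replace=False)
        for i in chosen:
            edges.add((tfs[i], gene))
    return PlantedNetwork(tfs=tfs, genes=genes, edges=frozenset(edges), pheno_genes=pheno_genes)


def _beta1(rng, a, size=None):
    """Beta(a, 1) draws clipped away from exact zero."""
    return np.clip(rng.beta(a, 1.0, size=size), P_FLOOR, 1.0)


def _null_mix(rng, r, a1, a0):
    if rng.random() < r:
        return float(_beta1(rng, a1))
    return float(_beta1(rng, a0))


def generate_summary_evidence(net: PlantedNetwork, cfg: SimulationConfig) -> list[GeneEvidence]:
    """Draw (P_j, p_ij, q_ij) tables from the model's generative assumptions.

    Candidate regulators of a gene are its planted TFs plus up to
    ``cfg.n_decoys`` decoy TFs; planted pairs draw both channels from the
    alternative Beta, all other pairs from the r-weighted null mixtures.
    """
    rng = cfg.rng("evidence")
    out = []
    tf_index = {tf: i for i, tf in enumerate(net.tfs)}
    for gene in net.genes:
        if gene in net.pheno_genes:
            p_pheno = float(_beta1(rng, cfg.alpha_prime_true))
        else:
            p_pheno = float(np.clip(rng.random(), P_FLOOR, 1.0))
        planted = net.tfs_of(gene)
        pool = [tf for tf in net.tfs if tf not in planted]
        n_decoys = min(cfg.n_decoys, len(pool))
        decoys = [pool[i] for i in rng.choice(len(pool), size=n_decoys, replace=False)] \
            if n_decoys else []
        cands = []
        for tf in sorted(planted + decoys, key=lambda t: tf_index[t]):
            if (tf, gene) in net.edges:
                p = float(_beta1(rng, cfg.alpha_h1_gex))
                q = float(_beta1(rng, cfg.alpha_h1_chip))
            else:
                p = _null_mix(rng, cfg.r_gex, cfg.alpha_h1_gex, cfg.alpha_h0_gex)
                q = _null_mix(rng, cfg.r_chip, cfg.alpha_h1_chip, cfg.alpha_h0_chip)
            cands.append(Candidate(tf=tf, p_gex=p, p_chip=q))
        if cands:
            out.append(GeneEvidence(gene=gene, p_pheno=p_pheno, candidates=tuple(cands)))
    return out


def generate_expression(net: PlantedNetwork, cfg: SimulationConfig):
    """Linear TF-effect expression matrix plus binary phenotype labels.

    TF rows are standard normal per sample; each gene row is the sum of its
    planted TF rows scaled by ``effect_size``, a ``class_shift`` offset on
    the positive class for phenotype genes, and Gaussian noise.
    """
    if cfg.n_samples_per_class < 3:
        raise ValueError("need at least 3 samples per phenotype class")
    rng = cfg.rng("expression")
    n = 2 * cfg.n_samples_per_class
    labels = np.array([0] * cfg.n_samples_per_class + [1] * cfg.n_samples_per_class)
    samples = [f"S{i + 1}" for i in range(n)]
    tf_expr = rng.standard_normal((cfg.n_tfs, n))
    gene_expr = np.zeros((cfg.n_genes, n))
    tf_index = {tf: i for i, tf in enumerate(net.tfs)}
    for j, gene in enumerate(net.genes):
        for tf in net.tfs_of(gene):
            gene_expr[j] += cfg.effect_size * tf_expr[tf_index[tf]]
        if gene in net.pheno_genes:
            gene_expr[j] += cfg.class_shift * labels
        if cfg.noise_sd > 0:
            gene_expr[j] += rng.normal(0.0, cfg.noise_sd, size=n)
    expr = pd.DataFrame(
        np.vstack([tf_expr, gene_expr]),
        index=list(net.tfs) + list(net.genes),
        columns=samples,
    )
    label_series = pd.Series(labels, index=samples, name="label")
    return expr, label_series


# ---------------------------------------------------------------------------
# tabular views (the same TSV dialects the pipeline consumes)
# ---------------------------------------------------------------------------


def evidence_to_tables(evidence: list[GeneEvidence]):
    """Return (pair-level, gene-level) DataFrames of an evidence set."""
    pair_rows = []
    gene_rows = []
    for ev in evidence:
        gene_rows.append({"gene": ev.gene, "p_pheno": ev.p_pheno})
        for c in ev.real_candidates():
            pair_rows.append(
                {"gene": ev.gene, "tf": c.tf, "p_gex": c.p_gex, "p_chip": c.p_chip}
            )
    return pd.DataFrame(pair_rows), pd.DataFrame(gene_rows)


def truth_table(net: PlantedNetwork) -> pd.DataFrame:
    rows = sorted(net.edges)
    return pd.DataFrame(rows, columns=["tf", "gene"])
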