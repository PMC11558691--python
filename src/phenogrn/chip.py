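"""Binding-side summary statistics.

Reads peak-to-gene link tables with distance p-values, consolidates them to
one pseudo p-value per TF-gene pair (minimum over all peaks and
conditions, requiring coverage in every required condition), and merges the
binding and expression candidate tables with the p/q = 1 fallbacks.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from phenogrn.model import Candidate, GeneEvidence, P_FLOOR
from phenogrn.expression import _de_columns

logger = logging.getLogger(__name__)

DEFAULT_COLUMN_MAP = {"gene": "Gene_ID", "distance_p": "Distance_P_Value"}


def read_link_table(path, tf: str, condition: str, column_map: dict | None = None) -> pd.DataFrame:
    """Read one T-Gene-style TSV of peak-to-gene links for a single TF/condition.

    Malformed rows (unparseable or out-of-range p-values) are skipped with a
    logged count; p-values of exactly zero are clipped to 1e-300.
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    raw = pd.read_csv(path, sep="\t")
    for key in ("gene", "distance_p"):
        if cmap[key] not in raw.columns:
            raise ValueError(
                f"required column {cmap[key]!r} absent from {path}; "
                f"available: {list(raw.columns)}"
            )
    p = pd.to_numeric(raw[cmap["distance_p"]], errors="coerce")
    bad = p.isna() | (p < 0) | (p > 1)
    if bad.any():
        logger.warning("%s: skipped %d malformed link rows", path, int(bad.sum()))
    frame = pd.DataFrame(
        {
            "tf": tf,
            "gene": raw.loc[~bad, cmap["gene"]].astype(str),
            "condition": condition,
            "distance_p": np.clip(p[~bad].to_numpy(dtype=float), P_FLOOR, 1.0),
        }
    )
    peak_col = cmap.get("peak_id")
    if peak_col and peak_col in raw.columns:
        frame["peak_id"] = raw.loc[~bad, peak_col].astype(str).to_numpy()
    return frame.reset_index(drop=True)


def consolidate_chip_pvalues(links: pd.DataFrame, required_conditions) -> pd.DataFrame:
    """One q per TF-gene pair: min distance p over all links, all conditions.

    Pairs lacking a link in any required condition are dropped entirely.
    """
    required = set(required_conditions)
    if not required:
        raise ValueError("required_conditions must be non-empty")
    if links.empty:
        return pd.DataFrame(columns=["tf", "gene", "q", "imputed"])
    grouped = links.groupby(["tf", "gene"], sort=True)
    rows = []
    for (tf, gene), sub in grouped:
        if not required <= set(sub["condition"]):
            continue
        rows.append({"tf": tf, "gene": gene, "q": float(sub["distance_p"].min()), "imputed": False})
    return pd.DataFrame(rows, columns=["tf", "gene", "q", "imputed"])


def merge_candidates(expr: pd.DataFrame, chip: pd.DataFrame) -> pd.DataFrame:
    """Union of expression and binding candidates with symmetric 1-fallbacks.

    A pair present only in the expression table gets q = 1 (flagged
    imputed); a pair present only in the binding table gets p = 1 likewise.
    """
    for name, df in (("expression", expr), ("binding", chip)):
        if not df.empty and df.duplicated(["tf", "gene"]).any():
            raise ValueError(f"duplicate (tf, gene) rows in the {name} table")
    e = expr.rename(columns={"pseudo_p": "p"})[["tf", "gene", "p"]] if not expr.empty else \
        pd.DataFrame(columns=["tf", "gene", "p"])
    c = chip[["tf", "gene", "q"]] if not chip.empty else pd.DataFrame(columns=["tf", "gene", "q"])
    merged = e.merge(c, on=["tf", "gene"], how="outer")
    merged["p_imputed"] = merged["p"].isna()
    merged["q_imputed"] = merged["q"].isna()
    merged["p"] = np.clip(merged["p"].fillna(1.0).astype(float), P_FLOOR, 1.0)
    merged["q"] = np.clip(merged["q"].fillna(1.0).astype(float), P_FLOOR, 1.0)
    merged = merged.sort_values(["gene", "tf"], kind="stable").reset_index(drop=True)
    return merged[["gene", "tf", "p", "q", "p_imputed", "q_imputed"]]


def build_gene_evidence(
    de: pd.DataFrame,
    candidates: pd.DataFrame,
    de_gene_set,
    chip_genes=None,
) -> list[GeneEvidence]:
    """Assemble per-gene evidence for the model.

    A gene is retained iff it was selected as differentially expressed, it
    appears in the binding-data universe, and it has at least one candidate
    pair.  ``chip_genes`` defaults to genes carrying any non-imputed q.
    """
    cols = _de_columns(de)
    pmap = dict(zip(de[cols["gene"]].astype(str), de[cols["pvalue"]].astype(float)))
    if chip_genes is None:
        chip_genes = set(candidates.loc[~candidates["q_imputed"], "gene"].astype(str))
    else:
        chip_genes = set(chip_genes)
    de_gene_set = set(de_gene_set)
    evidence = []
    for gene, sub in candidates.groupby("gene", sort=True):
        gene = str(gene)
        if gene not in de_gene_set or gene not in chip_genes or sub.empty:
            continue
        if gene not in pmap:
            logger.warning("gene %s has candidates but no DE record; dropped", gene)
            continue
        cands = tuple(
            Candidate(tf=str(r.tf), p_gex=float(r.p), p_chip=float(r.q))
            for r in sub.itertuples()
        )
        evidence.append(
            GeneEvidence(
                gene=gene,
                p_pheno=float(np.clip(pmap[gene], P_FLOOR, 1.0)),
                candidates=cands,
            )
        )
    return evidence
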