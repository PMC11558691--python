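"""TSV readers and writers for every pipeline table.

All writers emit tab-separated files with a header, C-locale decimal
points, and floats at six significant digits — except confidence/score
columns, written at full round-trip precision.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from phenogrn.model import Candidate, GeneEvidence


def _write(df: pd.DataFrame, path, full_precision=()):
    out = df.copy()
    for col in out.columns:
        if col in full_precision:
            out[col] = out[col].map(lambda v: repr(float(v)))
        elif pd.api.types.is_float_dtype(out[col]):
            out[col] = out[col].map(lambda v: f"{v:.6g}")
    out.to_csv(path, sep="\t", index=False)


def write_expression(expr: pd.DataFrame, path):
    expr.to_csv(path, sep="\t", index=True, index_label="id", float_format="%.6g")


def read_expression(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_labels(labels: pd.Series, path):
    frame = labels.rename("label").rename_axis("sample").reset_index()
    frame.to_csv(path, sep="\t", index=False)


def read_labels(path) -> pd.Series:
    frame = pd.read_csv(path, sep="\t")
    return frame.set_index("sample")["label"]


def write_de_table(de: pd.DataFrame, path):
    _write(de, path)


def read_de_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_evidence(evidence: list[GeneEvidence], pair_path, gene_path):
    from phenogrn.simulate import evidence_to_tables

    pair, gene = evidence_to_tables(evidence)
    _write(pair, pair_path, full_precision=("p_gex", "p_chip"))
    _write(gene, gene_path, full_precision=("p_pheno",))


def read_evidence(pair_path, gene_path) -> list[GeneEvidence]:
    pair = pd.read_csv(pair_path, sep="\t", float_precision="round_trip")
    gene = pd.read_csv(gene_path, sep="\t", float_precision="round_trip")
    pmap = dict(zip(gene["gene"].astype(str), gene["p_pheno"].astype(float)))
    out = []
    for g, sub in pair.groupby("gene", sort=True):
        g = str(g)
        if g not in pmap:
            raise ValueError(f"gene {g!r} present in pair table but not gene table")
        cands = tuple(
            Candidate(tf=str(r.tf), p_gex=float(r.p_gex), p_chip=float(r.p_chip))
            for r in sub.itertuples()
        )
        out.append(GeneEvidence(gene=g, p_pheno=pmap[g], candidates=cands))
    return out


def write_posterior(posterior, path):
    scores = posterior.scores if hasattr(posterior, "scores") else dict(posterior)
    rows = [
        {"gene": gene, "tf_or_control": label, "score": val}
        for gene in sorted(scores)
        for label, val in sorted(scores[gene].items())
    ]
    _write(pd.DataFrame(rows, columns=["gene", "tf_or_control", "score"]),
           path, full_precision=("score",))


def read_posterior(path) -> dict:
    frame = pd.read_csv(path, sep="\t", float_precision="round_trip")
    out: dict[str, dict[str, float]] = {}
    for r in frame.itertuples():
        out.setdefault(str(r.gene), {})[str(r.tf_or_control)] = float(r.score)
    return out


def write_grn(grn, path):
    _write(grn.to_frame(), path, full_precision=("confidence", "raw_score"))


def read_grn(path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", float_precision="round_trip")
    frame["filters_passed"] = frame.get("filters_passed", pd.Series(dtype=str)).fillna("")
    return frame


def write_truth(truth: pd.DataFrame, path):
    _write(truth[["tf", "gene"]], path)


def read_truth(path) -> set:
    frame = pd.read_csv(path, sep="\t")
    return {(str(r.tf), str(r.gene)) for r in frame.itertuples()}


def write_summary(table: pd.DataFrame, mean_pct: float, path):
    _write(table, path)
    with open(path, "a") as fh:
        fh.write(f"# mean_percentage\t{mean_pct}\n")


def write_report(results: dict, path):
    rows = []
    for level, res in results.items():
        rows.append(
            {
                "level": level,
                "auprc": res.auprc,
                "prevalence": res.prevalence,
                "ratio": res.auprc_ratio,
                "n_pos": res.n_pos,
                "n_total": res.n_total,
            }
        )
    _write(pd.DataFrame(rows), path, full_precision=("auprc", "prevalence", "ratio"))
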