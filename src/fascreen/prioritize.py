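"""Candidate-gene ranking against a supplied FA-relevance score table.

Three criteria are counted per gene: apparently relevant function (DNA
interaction/repair), physical interaction with known FA proteins, and a high
FA-likeness score from an external ranking tool.  Genes sort by criteria
count, then score, then symbol; genes absent from the table sink to the
bottom flagged unscored.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: score at list position 150 of the external FA-ranking tool; at or above it
#: a gene counts as "high-scoring" (top-150-like)
DEFAULT_SCORE_CUT = 6.224

TABLE_COLUMNS = ["gene", "score", "position", "function_relevant", "fa_interactor"]


def load_gene_scores(path) -> pd.DataFrame:
    """Read a gene-score TSV (gene, score, position, function_relevant, fa_interactor)."""
    df = pd.read_csv(path, sep="\t")
    missing = set(TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"gene score table missing columns {sorted(missing)}")
    for col in ("function_relevant", "fa_interactor"):
        if df[col].dtype != bool:
            df[col] = df[col].astype(str).str.lower().isin(["true", "1", "yes"])
    return df


def rank_candidates(
    hits,
    table: pd.DataFrame,
    score_cut: float = DEFAULT_SCORE_CUT,
) -> pd.DataFrame:
    """Rank the genes of a CandidateHit list.

    Returns a DataFrame (gene, models, criteria_count, score, position,
    function_relevant, fa_interactor, high_score, scored) sorted best first.
    The order is total and independent of input order: criteria count
    descending, score descending, then gene symbol; unscored genes last,
    alphabetical.
    """
    if table["gene"].duplicated().any():
        dups = table.loc[table["gene"].duplicated(), "gene"].tolist()
        raise ValueError(f"duplicate gene rows in score table: {dups}")
    by_gene: dict[str, set[str]] = {}
    for h in hits:
        by_gene.setdefault(h.gene, set()).add(h.model)
    if not by_gene:
        return pd.DataFrame(
            columns=["gene", "models", "criteria_count", "score", "position",
                     "function_relevant", "fa_interactor", "high_score", "scored"]
        )
    tab = table.set_index("gene")
    rows = []
    for gene, models in by_gene.items():
        if gene in tab.index:
            r = tab.loc[gene]
            high = bool(r["score"] >= score_cut)
            count = int(r["function_relevant"]) + int(r["fa_interactor"]) + int(high)
            rows.append(
                dict(gene=gene, models=",".join(sorted(models)), criteria_count=count,
                     score=float(r["score"]), position=int(r["position"]),
                     function_relevant=bool(r["function_relevant"]),
                     fa_interactor=bool(r["fa_interactor"]), high_score=high, scored=True)
            )
        else:
            rows.append(
                dict(gene=gene, models=",".join(sorted(models)), criteria_count=-1,
                     score=float("-inf"), position=-1, function_relevant=False,
                     fa_interactor=False, high_score=False, scored=False)
            )
    df = pd.DataFrame(rows)
    df = df.sort_values(
        by=["criteria_count", "score", "gene"],
        ascending=[False, False, True],
        kind="mergesort",
    ).reset_index(drop=True)
    return df
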