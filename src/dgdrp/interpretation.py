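"""Per-drug selected gene sets and pathway over-representation analysis.

After training, each (drug, cell line) forward pass yields a binary gene
mask. Masks for one drug are aggregated across test cell lines into a
per-gene selection frequency; genes selected in at least half the cell
lines (by default) form the drug's selected set. That set is tested for
pathway over-representation with a one-sided hypergeometric test against
the network gene background, Benjamini-Hochberg adjusted per drug.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .io_chem import PathwayCollection


@dataclass
class SelectedGeneSet:
    drug_id: str
    genes: frozenset[str]
    selection_frequency: dict[str, float]  # gene -> fraction of cell lines


@dataclass
class EnrichmentResult:
    drug_id: str
    table: pd.DataFrame  # pathway_id, overlap, pathway_size, background, p, p_adj

    def significant(self, alpha: float = 0.05) -> pd.DataFrame:
        return self.table[self.table["p_adj"] < alpha]

    def top(self, n: int) -> pd.DataFrame:
        return self.table.nsmallest(n, "p", keep="all")


def aggregate_masks(drug_id: str, masks: np.ndarray, gene_ids: list[str],
                    freq_cutoff: float = 0.5, mode: str = "frequency",
                    ) -> SelectedGeneSet:
    """Aggregate per-cell-line masks into one selected set per drug.

    ``masks`` is (n_cells, g) binary. Modes: ``frequency`` keeps genes with
    selection frequency >= ``freq_cutoff``; ``union`` and ``intersection``
    are the degenerate cutoffs (>0 and ==1).
    """
    masks = np.atleast_2d(np.asarray(masks))
    if masks.shape[1] != len(gene_ids):
        raise ValueError(f"mask width {masks.shape[1]} != {len(gene_ids)} genes")
    if masks.shape[0] == 0:
        raise ValueError("need at least one mask")
    freq = masks.mean(axis=0)
    if mode == "union":
        keep = freq > 0
    elif mode == "intersection":
        keep = freq >= 1.0
    elif mode == "frequency":
        keep = freq >= freq_cutoff
    else:
        raise ValueError(f"unknown aggregation mode {mode!r}")
    genes = frozenset(g for g, k in zip(gene_ids, keep) if k)
    return SelectedGeneSet(drug_id, genes,
                           {g: float(f) for g, f in zip(gene_ids, freq)})


def hypergeom_pvalue(overlap: int, set_size: int, pathway_size: int,
                     background_size: int) -> float:
    """Upper-tail hypergeometric P(X >= overlap)."""
    return float(hypergeom.sf(overlap - 1, background_size, pathway_size,
                              set_size))


def enrich(gene_set, pathways: PathwayCollection, background,
           drug_id: str = "") -> EnrichmentResult:
    """Over-representation of a gene set in each pathway.

    ``background`` is the gene universe (typically the network genes
    intersected with the model's gene universe); the set and all pathways
    are intersected with it. Benjamini-Hochberg correction is applied
    across the pathways tested here (one family per drug).
    """
    background = set(background)
    if not background:
        raise ValueError("empty background")
    gene_set = set(gene_set) & background
    rows = []
    for pid, (name, members) in pathways:
        members = set(members) & background
        if not members:
            continue
        overlap = len(gene_set & members)
        p = hypergeom_pvalue(overlap, len(gene_set), len(members), len(background))
        rows.append((pid, name, overlap, len(members), p))
    if not rows:
        raise ValueError("no pathway overlaps the background")
    df = pd.DataFrame(rows, columns=["pathway_id", "name", "overlap",
                                     "pathway_size", "p"])
    df["p_adj"] = multipletests(df["p"], method="fdr_bh")[1]
    df["background"] = len(background)
    df["set_size"] = len(gene_set)
    df = df.sort_values(["p", "pathway_id"]).reset_index(drop=True)
    return EnrichmentResult(drug_id, df)


def selected_sets_from_predictions(masks_by_drug: dict, gene_ids: list[str],
                                   freq_cutoff: float = 0.5,
                                   mode: str = "frequency",
                                   ) -> dict[str, SelectedGeneSet]:
    """Convenience wrapper over the mask dict from ``predict_pairs``."""
    out = {}
    for drug_id, (_, masks) in masks_by_drug.items():
        out[drug_id] = aggregate_masks(drug_id, masks, gene_ids,
                                       freq_cutoff=freq_cutoff, mode=mode)
    return out
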