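"""Drug-level gene-set enrichment between two groups of cell lines.

For each drug and gene set the RZS signatures of the two groups are
compared with an unpaired two-sample t-test, restricted to an
expressed-gene background.  Two variants are exposed:

v1 (default)
    Each cell line is summarized to its mean RZS over the set's
    background-restricted genes; a Welch t-test compares the group
    summaries.  Cell lines are the replication unit.
v2
    The set-gene RZS values of all lines in a group are pooled and a
    pooled-variance Student t-test compares the two pools.

p-values are two-sided; FDR is Benjamini--Hochberg within one family per
(comparison, set category).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import GeneSetCollection
from .signatures import SignatureTensor

MIN_TESTED_SET_SIZE = 5


@dataclass
class BackgroundSet:
    """Gene ids considered expressed, with provenance."""

    genes: frozenset[str]
    provenance: str = ""

    def __len__(self):
        return len(self.genes)


def estimate_background(counts: pd.DataFrame, min_reads: int = 10,
                        min_fraction: float = 0.5) -> BackgroundSet:
    """Expressed-gene background from a genes x cell-lines counts matrix.

    A gene is expressed when it has at least ``min_reads`` mapped reads in
    at least ``ceil(min_fraction * n_lines)`` cell lines.
    """
    if (counts.to_numpy() < 0).any():
        raise ValueError("counts must be non-negative")
    n_lines = counts.shape[1]
    need = int(np.ceil(min_fraction * n_lines))
    passing = (counts >= min_reads).sum(axis=1) >= need
    genes = frozenset(counts.index[passing])
    if not genes:
        raise ValueError("background is empty")
    return BackgroundSet(
        genes, provenance=f"counts>= {min_reads} in >= {need}/{n_lines} lines")


def adjust_fdr(p_values, method: str = "fdr_bh") -> np.ndarray:
    """Benjamini--Hochberg step-up q-values (monotone in p)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method=method)[1]


def _set_t(slab_a: np.ndarray, slab_b: np.ndarray, gene_idx: np.ndarray,
           variant: str) -> tuple[float, float]:
    """t and two-sided p for one (drug, set); slabs are lines x genes."""
    if variant == "v1":
        a = slab_a[:, gene_idx].mean(axis=1)
        b = slab_b[:, gene_idx].mean(axis=1)
        t, p = stats.ttest_ind(a, b, equal_var=False)
    elif variant == "v2":
        a = slab_a[:, gene_idx].ravel()
        b = slab_b[:, gene_idx].ravel()
        t, p = stats.ttest_ind(a, b, equal_var=True)
    else:
        raise ValueError(f"unknown variant {variant!r}")
    return float(t), float(p)


def set_enrichment(tensor: SignatureTensor, group_a: str, group_b: str,
                   sets: GeneSetCollection,
                   background: BackgroundSet | None = None,
                   variant: str = "v1",
                   drugs: list[str] | None = None,
                   min_set_size: int = MIN_TESTED_SET_SIZE) -> pd.DataFrame:
    """Per-(drug, set) enrichment comparing group_a against group_b.

    Sets whose intersection with the background falls below
    ``min_set_size`` are reported with ``tested = False`` (never
    zero-filled).  q-values are BH within the whole returned family
    (one comparison x one set category).
    """
    idx_a = [tensor.cell_lines.index(c)
             for c in tensor.lines_in_group(group_a)]
    idx_b = [tensor.cell_lines.index(c)
             for c in tensor.lines_in_group(group_b)]
    if variant == "v1" and (len(idx_a) < 2 or len(idx_b) < 2):
        raise ValueError("variant v1 needs >= 2 cell lines per group")
    bg = background.genes if background is not None else None
    gene_pos = {g: i for i, g in enumerate(tensor.genes)}
    drugs = drugs if drugs is not None else tensor.drugs

    rows = []
    for drug in drugs:
        d = tensor.drugs.index(drug)
        slab_a = tensor.data[d][idx_a]   # lines_a x genes
        slab_b = tensor.data[d][idx_b]
        for name, genes in sets:
            eligible = genes if bg is None else genes & bg
            gene_idx = np.array(sorted(gene_pos[g] for g in eligible
                                       if g in gene_pos), dtype=int)
            if gene_idx.size < min_set_size:
                rows.append((drug, name, np.nan, np.nan, 0, False))
                continue
            t, p = _set_t(slab_a, slab_b, gene_idx, variant)
            rows.append((drug, name, t, p, gene_idx.size, True))
    result = pd.DataFrame(rows, columns=["drug", "set", "t_statistic",
                                         "p_value", "n_genes", "tested"])
    result["q_value"] = np.nan
    tested = result["tested"]
    if tested.any():
        result.loc[tested, "q_value"] = adjust_fdr(
            result.loc[tested, "p_value"])
    result["direction"] = np.sign(result["t_statistic"])
    result["variant"] = variant
    result["category"] = sets.category
    result["group_a"] = group_a
    result["group_b"] = group_b
    return result


def landmark_consistency(enrich_full: pd.DataFrame,
                         enrich_landmark: pd.DataFrame
                         ) -> tuple[float, float]:
    """Pearson correlation between full and landmark-only t-statistics.

    Results are matched on (drug, set); untested entries are dropped.
    """
    merged = enrich_full.merge(enrich_landmark, on=["drug", "set"],
                               suffixes=("_full", "_landmark"))
    merged = merged[merged["tested_full"] & merged["tested_landmark"]]
    if len(merged) < 3:
        raise ValueError("need >= 3 matched (drug, set) pairs")
    r, p = stats.pearsonr(merged["t_statistic_full"],
                          merged["t_statistic_landmark"])
    return float(r), float(p)
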