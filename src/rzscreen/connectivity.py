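"""Connectivity scoring of drug signatures against a disease signature.

The score is the classic Kolmogorov--Smirnov tag-enrichment statistic of
the Connectivity Map lineage: genes are ranked by descending RZS (ties
broken by gene id), and for each tag set (the disease signature's up- and
down-regulated genes) the signed extremum of the two-sample KS running
sum is taken.  With t tag genes at sorted ranks r_1 < ... < r_t among n
ranked genes, the tag and non-tag empirical CDFs differ at the tag
positions by

    a = max_j ( j/t - (r_j - j)/(n - t) )          # toward the top
    b = max_j ( (r_j - j)/(n - t) - (j-1)/t )      # toward the bottom
    es = a if a > b else -b

(both maxima floored at 0, the boundary value of the running sum).  This
form is exactly antisymmetric under rank reversal and reaches +-1 exactly
for a tag set at the very top or bottom.  The connectivity score is 0 when
es_up and es_down share a sign, else (es_up - es_down)/2, so it lies in
[-1, 1]: +1 means the drug concordantly recapitulates the disease
signature, -1 means perfect reversal.

Reversal screening attaches permutation p-values (random tag sets of
matching sizes) and BH q-values; a drug is reversing when its score is
negative at q below the FDR cut.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .enrichment import adjust_fdr
from .io import GeneSetCollection
from .signatures import DrugSignature, SignatureTensor


@dataclass
class DiseaseSignature:
    """Disjoint up- and down-regulated gene-id sets with a label."""

    up_genes: frozenset[str]
    down_genes: frozenset[str]
    label: str = ""

    def __post_init__(self):
        self.up_genes = frozenset(self.up_genes)
        self.down_genes = frozenset(self.down_genes)
        if not self.up_genes or not self.down_genes:
            raise ValueError("up and down gene sets must be non-empty")
        overlap = self.up_genes & self.down_genes
        if overlap:
            raise ValueError(f"up/down sets overlap: {sorted(overlap)[:5]}")


@dataclass
class ConnectivityRecord:
    drug: str
    context: str          # cell line or group id
    es_up: float
    es_down: float
    score: float
    p_value: float = np.nan
    q_value: float = np.nan


def _es_from_ranks(ranks: np.ndarray, n: int) -> float:
    """Signed KS extremum for tag positions ``ranks`` (1-based, sorted).

    Two-sample ECDF running sum evaluated at the tag positions; exactly
    antisymmetric under rank reversal, +-1 at the extremes.
    """
    t = ranks.shape[-1]
    if t >= n:
        raise ValueError("tag set must be smaller than the gene universe")
    j = np.arange(1, t + 1)
    rest = (ranks - j) / (n - t)
    a = np.maximum(np.max(j / t - rest, axis=-1), 0.0)
    b = np.maximum(np.max(rest - (j - 1) / t, axis=-1), 0.0)
    # equally extreme in both directions = no dominant deviation; calling
    # it 0 keeps the statistic exactly antisymmetric under rank reversal
    tol = 1e-12
    return np.where(a - b > tol, a, np.where(b - a > tol, -b, 0.0))


def _rank_genes(rzs: np.ndarray, genes: list[str]) -> dict[str, int]:
    """1-based rank by descending RZS, ties broken by ascending gene id."""
    order = np.lexsort((genes, -rzs))
    ranks = np.empty(len(genes), dtype=int)
    ranks[order] = np.arange(1, len(genes) + 1)
    return {g: int(r) for g, r in zip(genes, ranks)}


def _score_from_es(es_up: float, es_down: float) -> float:
    if np.sign(es_up) == np.sign(es_down):
        return 0.0
    return (es_up - es_down) / 2.0


def connectivity_score(signature: DrugSignature,
                       disease: DiseaseSignature) -> ConnectivityRecord:
    """KS connectivity of one drug signature with a disease signature."""
    genes = list(signature.rzs.index)
    universe = set(genes)
    up = sorted(disease.up_genes & universe)
    down = sorted(disease.down_genes & universe)
    if not up or not down:
        raise ValueError("no tag genes present in the signature's universe")
    rank = _rank_genes(signature.rzs.to_numpy(), genes)
    n = len(genes)
    es_up = float(_es_from_ranks(
        np.sort([rank[g] for g in up]).astype(float), n))
    es_down = float(_es_from_ranks(
        np.sort([rank[g] for g in down]).astype(float), n))
    return ConnectivityRecord(signature.drug_id, signature.cell_line_id,
                              es_up, es_down, _score_from_es(es_up, es_down))


def build_connectivity_matrix(tensor: SignatureTensor,
                              disease: DiseaseSignature,
                              aggregate: str = "none") -> pd.DataFrame:
    """Drug x context score matrix.

    ``aggregate="none"`` scores each cell line's signature;
    ``aggregate="by_group"`` first takes the per-gene median RZS across
    each group's cell lines, then scores the aggregate signature.
    """
    genes = tensor.genes
    universe = set(genes)
    up = sorted(disease.up_genes & universe)
    down = sorted(disease.down_genes & universe)
    if not up or not down:
        raise ValueError("no tag genes present in the tensor's universe")
    if aggregate == "none":
        contexts = tensor.cell_lines
        slabs = {c: tensor.data[:, i, :]
                 for i, c in enumerate(tensor.cell_lines)}
    elif aggregate == "by_group":
        contexts = sorted(set(tensor.group_labels.values()))
        slabs = {g: np.median(tensor.group_slice(g), axis=1)
                 for g in contexts}
    else:
        raise ValueError(f"unknown aggregate mode {aggregate!r}")

    n = len(genes)
    scores = np.empty((len(tensor.drugs), len(contexts)))
    for ci, ctx in enumerate(contexts):
        slab = slabs[ctx]                    # drugs x genes
        for di in range(len(tensor.drugs)):
            rank = _rank_genes(slab[di], genes)
            es_up = float(_es_from_ranks(
                np.sort([rank[g] for g in up]).astype(float), n))
            es_down = float(_es_from_ranks(
                np.sort([rank[g] for g in down]).astype(float), n))
            scores[di, ci] = _score_from_es(es_up, es_down)
    return pd.DataFrame(scores, index=tensor.drugs, columns=contexts)


def _null_scores(n_genes: int, n_up: int, n_down: int, n_permutations: int,
                 rng: np.random.Generator) -> np.ndarray:
    """Null connectivity scores from random tag sets of matching sizes.

    Random tag ranks against any fixed ranking are a uniform sample of
    rank positions, so the null depends only on (n_genes, sizes).
    """
    perm = np.empty(n_permutations)
    ranks = np.empty((n_permutations, n_up + n_down))
    for i in range(n_permutations):
        ranks[i] = rng.choice(n_genes, size=n_up + n_down,
                              replace=False) + 1
    up = np.sort(ranks[:, :n_up], axis=1)
    down = np.sort(ranks[:, n_up:], axis=1)
    es_up = _es_from_ranks(up, n_genes)
    es_down = _es_from_ranks(down, n_genes)
    same = np.sign(es_up) == np.sign(es_down)
    perm = np.where(same, 0.0, (es_up - es_down) / 2.0)
    return perm


def reversal_screen(matrix: pd.DataFrame, disease: DiseaseSignature,
                    n_genes: int, n_permutations: int = 1000,
                    seed: int | None = None,
                    fdr: float = 0.1) -> pd.DataFrame:
    """Attach permutation p / BH q to a score matrix and flag reversers.

    Two-sided p = (1 + #{|null| >= |observed|}) / (n_permutations + 1);
    BH within each context column; a drug reverses the disease signature
    in a context when score < 0 and q < ``fdr``.  When the matrix holds an
    SZ and a control NPC column, reversers are also classified as
    both / SZ-only / control-only.
    """
    if seed is None:
        raise ValueError("reversal_screen requires an explicit seed")
    if n_permutations < 100:
        raise ValueError("need n_permutations >= 100")
    rng = np.random.default_rng(seed)
    null = np.sort(np.abs(_null_scores(
        n_genes, len(disease.up_genes), len(disease.down_genes),
        n_permutations, rng)))
    rows = []
    for ctx in matrix.columns:
        obs = matrix[ctx].to_numpy()
        exceed = null.size - np.searchsorted(null, np.abs(obs), side="left")
        p = (1.0 + exceed) / (n_permutations + 1.0)
        q = adjust_fdr(p)
        for drug, s, pi, qi in zip(matrix.index, obs, p, q):
            rows.append((drug, ctx, s, pi, qi, bool(s < 0 and qi < fdr)))
    out = pd.DataFrame(rows, columns=["drug", "context", "score",
                                      "p_value", "q_value", "reversing"])
    if {"NPC_SZ", "NPC_control"} <= set(matrix.columns):
        flags = out.pivot(index="drug", columns="context",
                          values="reversing")
        def classify(row):
            sz, ctl = row.get("NPC_SZ", False), row.get("NPC_control", False)
            if sz and ctl:
                return "both"
            if sz:
                return "SZ_only"
            if ctl:
                return "control_only"
            return "none"
        spec = flags.apply(classify, axis=1)
        out = out.merge(spec.rename("specificity"), left_on="drug",
                        right_index=True)
    return out


def mds_embed(matrix: pd.DataFrame, n_dims: int = 2) -> pd.DataFrame:
    """Classical (Torgerson) MDS of cell lines from their score profiles.

    Rows of the embedding are the matrix's columns (cell lines/contexts);
    distances are Euclidean between drug-score profiles.  Output is
    centered and deterministic up to axis sign (eigenvector convention:
    largest-magnitude component positive).
    """
    profiles = matrix.to_numpy().T          # contexts x drugs
    m = profiles.shape[0]
    if m < n_dims + 1:
        raise ValueError(f"need >= {n_dims + 1} cell lines for "
                         f"{n_dims}-D embedding")
    sq = ((profiles[:, None, :] - profiles[None, :, :]) ** 2).sum(axis=2)
    j = np.eye(m) - np.ones((m, m)) / m
    b = -0.5 * j @ sq @ j
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1][:n_dims]
    coords = vecs[:, order] * np.sqrt(np.maximum(vals[order], 0.0))
    for k in range(coords.shape[1]):       # fix sign for determinism
        pivot = np.argmax(np.abs(coords[:, k]))
        if coords[pivot, k] < 0:
            coords[:, k] = -coords[:, k]
    return pd.DataFrame(coords, index=matrix.columns,
                        columns=[f"dim{k + 1}" for k in range(n_dims)])


def prioritize_drugs(tensor: SignatureTensor,
                     target_sets: GeneSetCollection,
                     top_k: int | None = None,
                     aggregate: str = "by_group") -> pd.DataFrame:
    """Rank drugs by their strongest absolute connectivity across sets.

    Undirected target sets are scored as a single KS tag set against each
    drug's ranking (the signed running-sum extremum); a drug's score for a
    set is the largest |es| across contexts, and drugs are ranked by their
    best score over all sets.  For directed screening prefer
    :func:`build_connectivity_matrix` with an explicit disease signature.
    Ties break by drug id.
    """
    if not tensor.drugs:
        raise ValueError("empty drug library")
    genes = tensor.genes
    n = len(genes)
    if aggregate == "by_group":
        contexts = sorted(set(tensor.group_labels.values()))
        slabs = [np.median(tensor.group_slice(g), axis=1) for g in contexts]
    else:
        slabs = [tensor.data[:, i, :] for i in range(len(tensor.cell_lines))]
    per_set = {}
    for name, gset in target_sets:
        present = sorted(gset & set(genes))
        if not present:
            continue
        best = np.zeros(len(tensor.drugs))
        for slab in slabs:                  # drugs x genes
            for di in range(len(tensor.drugs)):
                rank = _rank_genes(slab[di], genes)
                es = float(_es_from_ranks(
                    np.sort([rank[g] for g in present]).astype(float), n))
                best[di] = max(best[di], abs(es))
        per_set[name] = pd.Series(best, index=tensor.drugs)
    if not per_set:
        raise ValueError("no target set intersects the gene universe")
    table = pd.DataFrame(per_set)
    table["best_abs_score"] = table.max(axis=1)
    # descending score, ties by ascending drug id
    table = table.iloc[np.lexsort((table.index,
                                   -table["best_abs_score"].to_numpy()))]
    if top_k is not None:
        table = table.head(min(top_k, len(table)))
    return table
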