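"""DE calling and cross-group accounting on RZS signature tensors.

A drug--gene perturbation is DE within a group when the absolute median
RZS across the group's cell lines is >= 2 (inclusive); it is differentially
DE between two groups when the absolute difference of the group medians is
>= 2.  Pairs that are DE in at least one of two groups are partitioned into
four disjoint response categories, and overall group responsiveness is
compared with a Cochran--Mantel--Haenszel test stratified by drug--gene
perturbation.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd
from scipy import stats

from .signatures import SignatureTensor


@dataclass
class AnalysisConfig:
    de_threshold: float = 2.0
    diff_threshold: float = 2.0
    negligible_threshold: float = 0.5
    alpha: float = 0.05

    def __post_init__(self):
        if min(self.de_threshold, self.diff_threshold,
               self.negligible_threshold) <= 0:
            raise ValueError("thresholds must be > 0")


class ResponseCategory(str, Enum):
    OPPOSITE_SUBTHRESHOLD = "opposite_subthreshold"
    SINGLE_GROUP = "single_group"
    SAME_DIRECTION_MAGNITUDE = "same_direction_magnitude"
    OPPOSITE_DE = "opposite_de"


def group_medians(tensor: SignatureTensor, group: str) -> np.ndarray:
    """drugs x genes median RZS across the group's cell lines."""
    return np.median(tensor.group_slice(group), axis=1)


def call_de(tensor: SignatureTensor, group: str,
            config: AnalysisConfig | None = None) -> pd.DataFrame:
    """Per drug--gene DE calls for one group.

    Returns a long table with columns drug, gene, group_label, median_rzs,
    is_de.
    """
    config = config or AnalysisConfig()
    med = group_medians(tensor, group)
    n_drugs, n_genes = med.shape
    return pd.DataFrame({
        "drug": np.repeat(tensor.drugs, n_genes),
        "gene": np.tile(tensor.genes, n_drugs),
        "group_label": group,
        "median_rzs": med.ravel(),
        "is_de": (np.abs(med) >= config.de_threshold).ravel(),
    })


def differential_de(tensor: SignatureTensor, group_a: str, group_b: str,
                    config: AnalysisConfig | None = None) -> pd.DataFrame:
    """Differential DE between two disjoint groups.

    delta = median_a - median_b; flagged when |delta| >= diff_threshold
    (the flag depends only on the difference, not on either group's own
    DE status).
    """
    config = config or AnalysisConfig()
    lines_a = set(tensor.lines_in_group(group_a))
    lines_b = set(tensor.lines_in_group(group_b))
    if lines_a & lines_b:
        raise ValueError(f"groups {group_a!r} and {group_b!r} share "
                         f"cell lines: {sorted(lines_a & lines_b)}")
    med_a = group_medians(tensor, group_a)
    med_b = group_medians(tensor, group_b)
    delta = med_a - med_b
    n_drugs, n_genes = delta.shape
    return pd.DataFrame({
        "drug": np.repeat(tensor.drugs, n_genes),
        "gene": np.tile(tensor.genes, n_drugs),
        "median_a": med_a.ravel(),
        "median_b": med_b.ravel(),
        "delta": delta.ravel(),
        "is_differential": (np.abs(delta)
                            >= config.diff_threshold).ravel(),
    })


def categorize_response(median_a: float, median_b: float,
                        config: AnalysisConfig | None = None
                        ) -> ResponseCategory:
    """Classify a drug--gene pair DE in at least one of two groups.

    opposite_de: both DE, opposite signs; opposite_subthreshold: exactly
    one DE and the signs disagree; single_group: exactly one DE and the
    other value is negligible (|value| < negligible_threshold);
    same_direction_magnitude: same sign, the non-DE value non-negligible.
    The four categories are disjoint and exhaustive.
    """
    config = config or AnalysisConfig()
    t = config.de_threshold
    de_a, de_b = abs(median_a) >= t, abs(median_b) >= t
    if not (de_a or de_b):
        raise ValueError("pair is DE in neither group")
    if de_a and de_b:
        if np.sign(median_a) != np.sign(median_b):
            return ResponseCategory.OPPOSITE_DE
        return ResponseCategory.SAME_DIRECTION_MAGNITUDE
    big, small = (median_a, median_b) if de_a else (median_b, median_a)
    if small != 0 and np.sign(big) != np.sign(small):
        return ResponseCategory.OPPOSITE_SUBTHRESHOLD
    if abs(small) < config.negligible_threshold:
        return ResponseCategory.SINGLE_GROUP
    return ResponseCategory.SAME_DIRECTION_MAGNITUDE


def categorize_table(tensor: SignatureTensor, group_a: str, group_b: str,
                     config: AnalysisConfig | None = None) -> pd.DataFrame:
    """Response-category accounting over all pairs DE in >= 1 group."""
    config = config or AnalysisConfig()
    med_a = group_medians(tensor, group_a)
    med_b = group_medians(tensor, group_b)
    de_any = ((np.abs(med_a) >= config.de_threshold)
              | (np.abs(med_b) >= config.de_threshold))
    rows = []
    for d, g in zip(*np.nonzero(de_any)):
        rows.append((tensor.drugs[d], tensor.genes[g],
                     med_a[d, g], med_b[d, g],
                     categorize_response(med_a[d, g], med_b[d, g],
                                         config).value))
    return pd.DataFrame(rows, columns=["drug", "gene", "median_a",
                                       "median_b", "category"])


# ---------------------------------------------------------------------------
# Mantel--Haenszel responsiveness comparison
# ---------------------------------------------------------------------------

@dataclass
class MHResult:
    common_odds_ratio: float
    chi_square: float
    p_value: float
    bonferroni_p: float
    n_strata: int

    def __post_init__(self):
        if self.common_odds_ratio <= 0:
            raise ValueError("common odds ratio must be > 0")


def mantel_haenszel(strata: np.ndarray, n_comparisons: int = 1) -> MHResult:
    """Cochran--Mantel--Haenszel test over 2x2 strata [[a,b],[c,d]].

    Common OR = sum(a*d/n) / sum(b*c/n); chi-square without continuity
    correction; one df.  ``n_comparisons`` sets the Bonferroni family size.
    Degenerate strata (a zero row or column margin) contribute nothing and
    are ignored; an all-degenerate input is an error.
    """
    strata = np.asarray(strata, dtype=float)
    if strata.ndim != 3 or strata.shape[1:] != (2, 2):
        raise ValueError("strata must be k x 2 x 2")
    a, b = strata[:, 0, 0], strata[:, 0, 1]
    c, d = strata[:, 1, 0], strata[:, 1, 1]
    n = a + b + c + d
    row1, col1 = a + b, a + c
    ok = (n > 0) & (row1 > 0) & (row1 < n) & (col1 > 0) & (col1 < n)
    if not ok.any():
        raise ValueError("all strata degenerate")
    a, b, c, d, n = a[ok], b[ok], c[ok], d[ok], n[ok]
    row1, row2 = a + b, c + d
    col1, col2 = a + c, b + d
    num = np.sum(a * d / n)
    den = np.sum(b * c / n)
    if den == 0:
        odds = np.inf
    elif num == 0:
        odds = np.finfo(float).tiny
    else:
        odds = num / den
    expect = np.sum(row1 * col1 / n)
    var = np.sum(row1 * row2 * col1 * col2 / (n ** 2 * (n - 1)))
    if var == 0:
        chi2, p = 0.0, 1.0
    else:
        chi2 = (np.sum(a) - expect) ** 2 / var
        p = float(stats.chi2.sf(chi2, df=1))
    return MHResult(common_odds_ratio=float(odds), chi_square=float(chi2),
                    p_value=p, bonferroni_p=min(1.0, p * n_comparisons),
                    n_strata=int(ok.sum()))


def mantel_haenszel_responsiveness(tensor: SignatureTensor, group_a: str,
                                   group_b: str,
                                   config: AnalysisConfig | None = None,
                                   n_comparisons: int = 1) -> MHResult:
    """Compare DE proportions between groups, stratified by drug--gene pair.

    Each stratum is the 2x2 table of (group x DE/not-DE) counts over
    individual cell lines, where a line's DE call uses its own
    (replicate-collapsed) RZS against the threshold.  Cell lines pool
    across phases.
    """
    config = config or AnalysisConfig()
    slab_a = tensor.group_slice(group_a)   # drugs x lines_a x genes
    slab_b = tensor.group_slice(group_b)
    de_a = np.abs(slab_a) >= config.de_threshold
    de_b = np.abs(slab_b) >= config.de_threshold
    n_a, n_b = slab_a.shape[1], slab_b.shape[1]
    a = de_a.sum(axis=1).ravel().astype(float)
    c = de_b.sum(axis=1).ravel().astype(float)
    strata = np.stack([np.stack([a, n_a - a], axis=1),
                       np.stack([c, n_b - c], axis=1)], axis=1)
    return mantel_haenszel(strata, n_comparisons=n_comparisons)


def gene_drug_counts(de_table: pd.DataFrame) -> tuple[pd.Series, dict]:
    """Score each gene by the number of drugs for which it is DE.

    Returns the per-gene counts (perturbed genes only) and a summary with
    the number of perturbed genes and the mean number of drugs per
    perturbed gene.
    """
    de = de_table[de_table["is_de"]]
    counts = (de.groupby("gene")["drug"].nunique()
              .sort_values(ascending=False))
    summary = {
        "n_perturbed_genes": int(len(counts)),
        "mean_drugs_per_gene": float(counts.mean()) if len(counts) else 0.0,
    }
    return counts, summary
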