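"""Chemogenomic feature enrichment over drug groups.

Drugs that differentially regulate a gene set (enrichment q below the FDR
cut, at least three such drugs) form a drug group; for each annotation
class (target, enzyme, transporter, carrier, therapeutic_class,
side_effect, predicted_target) the class background is the set of screened
drugs carrying at least one annotation of that class — side effects, for
instance, are only meaningful for clinically used compounds — and each
feature is tested for over-representation in the group with a one-sided
Fisher exact test, BH-adjusted within the (set, class) family.

The same machinery covers target-overlap drug prioritization: per drug and
target set, a one-sided Fisher exact on (drug targets x set membership)
over the gene universe.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .enrichment import adjust_fdr
from .io import GeneSetCollection

logger = logging.getLogger("rzscreen")

ANNOTATION_CLASSES = ("target", "enzyme", "transporter", "carrier",
                      "therapeutic_class", "side_effect", "predicted_target")


@dataclass
class FisherResult:
    """One feature's 2x2 over-representation test within a drug group."""

    set_name: str
    annotation_class: str
    feature: str
    table: tuple  # ((in-group & feature, in-group & not), (out & feature, out & not))
    odds_ratio: float
    p_value: float
    q_value: float = np.nan
    contributing_drugs: tuple = ()

    def __post_init__(self):
        if self.odds_ratio < 0:
            raise ValueError("odds ratio must be >= 0")


def fisher_one_sided(table) -> tuple[float, float]:
    """Odds ratio and one-sided (greater) Fisher exact p for a 2x2 table."""
    odds, p = stats.fisher_exact(np.asarray(table), alternative="greater")
    return float(odds), float(p)


def group_set_drugs(enrichments: pd.DataFrame, fdr: float = 0.1,
                    min_drugs: int = 3) -> dict[str, list[str]]:
    """Per gene set, the drugs with enrichment q < fdr (strict).

    Sets with fewer than ``min_drugs`` qualifying drugs are dropped.
    """
    if "q_value" not in enrichments.columns:
        raise ValueError("enrichment table lacks q_value")
    hits = enrichments[enrichments["q_value"] < fdr]
    groups = {}
    for name, sub in hits.groupby("set"):
        drugs = sorted(sub["drug"].unique())
        if len(drugs) >= min_drugs:
            groups[name] = drugs
    if not groups:
        logger.warning("group_set_drugs: no set retained >= %d drugs "
                       "at q < %g", min_drugs, fdr)
    return groups


def feature_enrichment(group: list[str], annotations: pd.DataFrame,
                       annotation_class: str, screened_drugs: list[str],
                       set_name: str = "") -> list[FisherResult]:
    """Fisher over-representation of every feature of a class in a group.

    The background is restricted to screened drugs with at least one
    annotation in the class; results are BH-adjusted within this
    (set, class) family.
    """
    cls = annotations[annotations["class"] == annotation_class]
    background = sorted(set(cls["drug"]) & set(screened_drugs))
    group_bg = sorted(set(group) & set(background))
    if not group_bg:
        logger.warning("feature_enrichment: group %r disjoint from the "
                       "%s background; all features untested",
                       set_name, annotation_class)
        return []
    results = []
    bg_set = set(background)
    grp = set(group_bg)
    for feature, sub in cls.groupby("feature"):
        have = set(sub["drug"]) & bg_set
        a = len(have & grp)                       # in group, has feature
        b = len(grp) - a                          # in group, lacks it
        c = len(have) - a                         # background, has it
        d = len(bg_set) - len(grp) - c
        odds, p = fisher_one_sided([[a, b], [c, d]])
        results.append(FisherResult(
            set_name=set_name, annotation_class=annotation_class,
            feature=feature, table=((a, b), (c, d)),
            odds_ratio=odds, p_value=p,
            contributing_drugs=tuple(sorted(have & grp))))
    if results:
        qs = adjust_fdr([r.p_value for r in results])
        for r, q in zip(results, qs):
            r.q_value = float(q)
    return results


def chemogenomic_screen(groups: dict[str, list[str]],
                        annotations: pd.DataFrame,
                        screened_drugs: list[str],
                        classes=None) -> pd.DataFrame:
    """Feature enrichment for every (set group, annotation class) pair."""
    classes = classes or sorted(annotations["class"].unique())
    rows = []
    for set_name, group in sorted(groups.items()):
        for cls in classes:
            for r in feature_enrichment(group, annotations, cls,
                                        screened_drugs, set_name=set_name):
                (a, b), (c, d) = r.table
                rows.append((r.set_name, r.annotation_class, r.feature,
                             a, b, c, d, r.odds_ratio, r.p_value,
                             r.q_value, ",".join(r.contributing_drugs)))
    return pd.DataFrame(rows, columns=[
        "set", "class", "feature", "group_with", "group_without",
        "bg_with", "bg_without", "odds_ratio", "p_value", "q_value",
        "contributing_drugs"])


def target_overlap_prioritization(annotations: pd.DataFrame,
                                  target_sets: GeneSetCollection,
                                  gene_universe: list[str],
                                  target_classes=("target",
                                                  "predicted_target")
                                  ) -> pd.DataFrame:
    """Rank drugs by Fisher overlap of their targets with each gene set.

    Targets are gene ids intersected with the universe; drugs with zero
    in-universe targets are excluded (logged).  Ranking is by each drug's
    best (smallest) p over the sets, ties by drug id.
    """
    universe = set(gene_universe)
    n = len(universe)
    targets = annotations[annotations["class"].isin(target_classes)]
    per_drug = {d: sorted(set(sub["feature"]) & universe)
                for d, sub in targets.groupby("drug")}
    skipped = [d for d, t in per_drug.items() if not t]
    if skipped:
        logger.warning("target_overlap: %d drugs with no in-universe "
                       "targets excluded", len(skipped))
    per_drug = {d: t for d, t in per_drug.items() if t}
    if not per_drug:
        raise ValueError("no drug has targets within the gene universe")
    rows = []
    for drug, tg in sorted(per_drug.items()):
        tg_set = set(tg)
        for name, gset in target_sets:
            members = gset & universe
            if not members:
                continue  # untested after universe intersection
            a = len(tg_set & members)
            b = len(tg_set) - a
            c = len(members) - a
            d = n - a - b - c
            odds, p = fisher_one_sided([[a, b], [c, d]])
            rows.append((drug, name, a, len(tg), len(members), odds, p))
    table = pd.DataFrame(rows, columns=["drug", "set", "overlap",
                                        "n_targets", "n_set_genes",
                                        "odds_ratio", "p_value"])
    best = (table.groupby("drug")["p_value"].min()
            .rename("best_p").reset_index()
            .sort_values(["best_p", "drug"], kind="mergesort"))
    best["rank"] = np.arange(1, len(best) + 1)
    return table.merge(best, on="drug").sort_values(
        ["rank", "set"], kind="mergesort").reset_index(drop=True)
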