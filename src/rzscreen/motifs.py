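"""Degenerate RNA-motif scanning and motif-based enrichment.

Patterns use IUPAC degenerate codes over RNA (K = G/U, W = A/U, R = A/G,
Y = C/U, S = C/G, M = A/C, N = any); DNA input is accepted with T treated
as U.  The ACUK pattern associated with FMRP binding ships in the default
catalog; further patterns are configuration, never hardcoded.

Three analyses build on the scanner: per-sequence motif density
(occurrences per kb) compared between sequence groups with a two-sample
t-test; per-variant in-motif status (an occurrence fully inside the
reference window spanning the variant offset); and cohort-level Fisher
enrichment of in-motif variants (e.g. disease cohorts against controls),
optionally restricted to an annotation stratum such as essential splice
sites.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .chemgen import FisherResult, fisher_one_sided
from .enrichment import adjust_fdr

IUPAC_RNA = {
    "A": "A", "C": "C", "G": "G", "U": "U",
    "K": "GU", "W": "AU", "R": "AG", "Y": "CU", "S": "CG", "M": "AC",
    "B": "CGU", "D": "AGU", "H": "ACU", "V": "ACG",
    "N": "ACGU",
}

DEFAULT_MOTIF_CATALOG = {"ACUK": "ACUK"}  # named FMRP-binding pattern


@dataclass(frozen=True)
class MotifPattern:
    """A degenerate RNA pattern, e.g. ``ACUK`` (K = G or U)."""

    pattern: str
    name: str = ""

    def __post_init__(self):
        pat = self.pattern.upper().replace("T", "U")
        object.__setattr__(self, "pattern", pat)
        if len(pat) < 2:
            raise ValueError("motif must be at least 2 nt")
        bad = [c for c in pat if c not in IUPAC_RNA]
        if bad:
            raise ValueError(f"illegal motif codes {bad}")
        if not self.name:
            object.__setattr__(self, "name", pat)

    def __len__(self):
        return len(self.pattern)

    def matches_at(self, base: str, position: int) -> bool:
        """Does ``base`` satisfy the motif code at ``position``?"""
        return base.upper().replace("T", "U") \
            in IUPAC_RNA[self.pattern[position]]


def _normalize_seq(seq: str) -> str:
    s = seq.upper().replace("T", "U")
    bad = set(s) - set("ACGUN")
    if bad:
        raise ValueError(f"illegal sequence characters {sorted(bad)}")
    return s


def realize_motif(motif: MotifPattern,
                  rng: np.random.Generator) -> list[str]:
    """One concrete sequence drawn uniformly from the motif's matches."""
    return [IUPAC_RNA[c][int(rng.integers(len(IUPAC_RNA[c])))]
            for c in motif.pattern]


def scan_motif(seq: str, motif: MotifPattern | str) -> list[int]:
    """All 0-based start positions of (possibly overlapping) occurrences.

    A motif longer than the sequence yields an empty result; N in the
    sequence matches nothing but N-containing motif codes per the IUPAC
    table (plain N in the sequence only matches motif code N).
    """
    if not isinstance(motif, MotifPattern):
        motif = MotifPattern(motif)
    s = _normalize_seq(seq)
    m = len(motif)
    allowed = [IUPAC_RNA[c] for c in motif.pattern]
    return [i for i in range(len(s) - m + 1)
            if all(s[i + j] in allowed[j] for j in range(m))]


def motif_density(seq: str, motif: MotifPattern | str) -> float:
    """Occurrences per kb of the provided sequence."""
    return len(scan_motif(seq, motif)) * 1000.0 / len(seq)


def motif_density_test(group1: list[str], group2: list[str],
                       motif: MotifPattern | str) -> dict:
    """Two-sample t-test of per-sequence motif densities between groups.

    Densities are per kb of each provided sequence; p is two-sided.
    """
    if not isinstance(motif, MotifPattern):
        motif = MotifPattern(motif)
    if min(len(group1), len(group2)) < 2:
        raise ValueError("each group needs >= 2 sequences")
    d1 = np.array([motif_density(s, motif) for s in group1])
    d2 = np.array([motif_density(s, motif) for s in group2])
    if d1.std() == 0 and d2.std() == 0:
        raise ValueError("degenerate (zero) density variance in both groups")
    t, p = stats.ttest_ind(d1, d2, equal_var=True)
    return {"motif": motif.name, "t_statistic": float(t),
            "p_value": float(p),
            "density_group1": float(d1.mean()),
            "density_group2": float(d2.mean())}


def variant_in_motif(window_seq: str, offset: int,
                     motif: MotifPattern | str) -> bool:
    """Does a motif occurrence fully inside the window span the offset?

    Occurrences truncated by the window edge never count; the match must
    satisfy start <= offset < start + len(motif).
    """
    if not isinstance(motif, MotifPattern):
        motif = MotifPattern(motif)
    if not 0 <= offset < len(window_seq):
        raise ValueError("offset outside window")
    m = len(motif)
    return any(start <= offset < start + m
               for start in scan_motif(window_seq, motif))


def cohort_enrichment(variants: pd.DataFrame, motif: MotifPattern | str,
                      case_cohorts: list[str], control_cohort: str,
                      annotation_filter: str | None = None) -> pd.DataFrame:
    """Fisher enrichment of in-motif variants, case cohorts vs control.

    One 2x2 (cohort x in-motif) one-sided (greater) test per case cohort;
    BH across the tested family.  ``annotation_filter`` restricts all
    cohorts to one annotation stratum (e.g. ``essential_splice_site``).
    """
    if not isinstance(motif, MotifPattern):
        motif = MotifPattern(motif)
    v = variants
    if annotation_filter is not None:
        v = v[v["annotation"] == annotation_filter]
    in_motif = v.apply(lambda r: variant_in_motif(r["window_seq"],
                                                  int(r["offset"]), motif),
                       axis=1)
    rows = []
    ctrl = v["cohort"] == control_cohort
    if not ctrl.any():
        raise ValueError(f"control cohort {control_cohort!r} empty"
                         + (f" after filter {annotation_filter!r}"
                            if annotation_filter else ""))
    c_in = int(in_motif[ctrl].sum())
    c_out = int(ctrl.sum()) - c_in
    for cohort in case_cohorts:
        mask = v["cohort"] == cohort
        if not mask.any():
            raise ValueError(f"cohort {cohort!r} empty"
                             + (f" after filter {annotation_filter!r}"
                                if annotation_filter else ""))
        a = int(in_motif[mask].sum())
        b = int(mask.sum()) - a
        odds, p = fisher_one_sided([[a, b], [c_in, c_out]])
        rows.append((motif.name, cohort, control_cohort, a, b, c_in, c_out,
                     odds, p))
    out = pd.DataFrame(rows, columns=[
        "motif", "cohort", "control", "case_in_motif", "case_out",
        "control_in_motif", "control_out", "odds_ratio", "p_value"])
    out["q_value"] = adjust_fdr(out["p_value"])
    out["annotation_filter"] = annotation_filter or "all"
    return out
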