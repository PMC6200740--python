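"""Plate-matched robust Z-score (RZS) drug signatures.

A drug signature compares treated wells with the cell-line-matched vehicle
(DMSO) wells on the same treatment plate:

    RZS_gene = (treated - median(vehicle)) / MAD(vehicle)

where MAD is the raw median absolute deviation of the vehicle wells
(no 1.4826 consistency constant by default; ``mad_constant="normal"``
enables it).  Because the vehicle statistics come from the same plate and
cell line, any additive plate- or batch-wide offset cancels exactly — the
transform is invariant to plate-wide location shifts and positive scalings.

Signatures for a drug assayed on multiple plates of the same cell line are
collapsed to the per-gene median, yielding one signature per
(drug, cell line); these are stacked into a :class:`SignatureTensor`
(drugs x cell lines x genes), the pipeline's central currency.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import (EMPTY, POSITIVE_CONTROL, VEHICLE, GctMatrix,
                 validate_plate_annotation)

logger = logging.getLogger("rzscreen")

MAD_NORMAL_CONSTANT = 1.4826
MAD_FLOOR_FALLBACK = 1e-6


@dataclass
class ExpressionScreen:
    """A gene x well matrix joined to its plate/well annotation."""

    matrix: GctMatrix
    annotation: pd.DataFrame

    def __post_init__(self):
        validate_plate_annotation(self.annotation)
        ann_wells = set(self.annotation["well_id"])
        missing = [c for c in self.matrix.col_ids if c not in ann_wells]
        if missing:
            raise ValueError(
                f"matrix columns without annotation: {missing[:5]}")

    @property
    def genes(self) -> list[str]:
        return self.matrix.row_ids


@dataclass
class DrugSignature:
    """Per-gene robust Z-scores for one (drug, cell line) combination."""

    drug_id: str
    cell_line_id: str
    rzs: pd.Series  # index = gene ids
    n_replicates: int = 1

    def __post_init__(self):
        if not np.isfinite(self.rzs.to_numpy()).all():
            raise ValueError(
                f"non-finite RZS in signature ({self.drug_id}, "
                f"{self.cell_line_id})")


@dataclass
class SignatureTensor:
    """Median-collapsed RZS, drugs x cell lines x genes.

    ``group_labels`` maps each cell line to its screening context
    (CCL / NPC_control / NPC_SZ).
    """

    data: np.ndarray
    drugs: list[str]
    cell_lines: list[str]
    genes: list[str]
    group_labels: dict[str, str]

    def __post_init__(self):
        expected = (len(self.drugs), len(self.cell_lines), len(self.genes))
        if self.data.shape != expected:
            raise ValueError(
                f"tensor shape {self.data.shape} != {expected}")

    def lines_in_group(self, group: str) -> list[str]:
        lines = [c for c in self.cell_lines if self.group_labels[c] == group]
        if not lines:
            raise KeyError(f"no cell lines in group {group!r}")
        return lines

    def group_slice(self, group: str) -> np.ndarray:
        """drugs x lines-in-group x genes view."""
        idx = [self.cell_lines.index(c) for c in self.lines_in_group(group)]
        return self.data[:, idx, :]

    def signature(self, drug: str, cell_line: str) -> DrugSignature:
        d = self.drugs.index(drug)
        c = self.cell_lines.index(cell_line)
        return DrugSignature(drug, cell_line,
                             pd.Series(self.data[d, c], index=self.genes))


# ---------------------------------------------------------------------------
# Probe collapsing
# ---------------------------------------------------------------------------

def collapse_probes(matrix: GctMatrix, probe_to_gene: dict[str, str]
                    ) -> GctMatrix:
    """Collapse a probe-level matrix to one row per gene.

    For genes measured by several probes, the probe with the highest mean
    expression across all columns is retained; exact ties go to the
    lexicographically smaller probe id.  Probes absent from the mapping are
    dropped with a warning.
    """
    keep = [p for p in matrix.row_ids if p in probe_to_gene]
    dropped = len(matrix.row_ids) - len(keep)
    if dropped:
        logger.warning("collapse_probes: %d probes not in mapping, dropped",
                       dropped)
    if not keep:
        raise ValueError("no probes left after applying the mapping")
    sub = matrix.values.loc[keep]
    means = sub.mean(axis=1)
    best: dict[str, str] = {}
    for probe in sorted(keep):  # lexicographic order makes ties deterministic
        gene = probe_to_gene[probe]
        if gene not in best or means[probe] > means[best[gene]]:
            best[gene] = probe
    genes = sorted(best)
    values = sub.loc[[best[g] for g in genes]]
    values.index = genes
    return GctMatrix(values, version_tag=matrix.version_tag)


# ---------------------------------------------------------------------------
# RZS
# ---------------------------------------------------------------------------

def _mad(values: np.ndarray, axis: int = -1) -> np.ndarray:
    med = np.median(values, axis=axis, keepdims=True)
    return np.median(np.abs(values - med), axis=axis)


def _floor_mad(mad: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Replace zero MADs with the smallest positive MAD on the plate.

    Falls back to ``MAD_FLOOR_FALLBACK`` when every gene's MAD is zero.
    Returns the floored MADs and a boolean mask of floored genes.
    """
    flagged = mad == 0
    if flagged.any():
        positive = mad[mad > 0]
        floor = positive.min() if positive.size else MAD_FLOOR_FALLBACK
        mad = np.where(flagged, floor, mad)
    return mad, flagged


def compute_rzs(screen: ExpressionScreen, drug: str, cell_line: str,
                plate: str, mad_constant: str = "raw") -> DrugSignature:
    """Robust Z-score signature for one (drug, cell line, plate) stratum.

    Multiple treated wells of the same drug on the plate are averaged
    before the transform.  Requires >= 3 vehicle wells in the stratum so
    the median/MAD have support.
    """
    ann = screen.annotation
    stratum = ann[(ann["plate_id"] == plate)
                  & (ann["cell_line_id"] == cell_line)]
    treated = stratum[stratum["treatment"] == drug]["well_id"].tolist()
    vehicle = stratum[stratum["treatment"] == VEHICLE]["well_id"].tolist()
    if not treated:
        raise ValueError(f"no wells treated with {drug!r} on plate "
                         f"{plate!r} for {cell_line!r}")
    if len(vehicle) < 3:
        raise ValueError(
            f"need >=3 vehicle wells on ({plate}, {cell_line}), "
            f"found {len(vehicle)}")
    values = screen.matrix.values
    treated_mean = values[treated].to_numpy().mean(axis=1)
    veh = values[vehicle].to_numpy()
    veh_median = np.median(veh, axis=1)
    mad = _mad(veh)
    if mad_constant == "normal":
        mad = mad * MAD_NORMAL_CONSTANT
    elif mad_constant != "raw":
        raise ValueError(f"mad_constant must be 'raw' or 'normal', "
                         f"got {mad_constant!r}")
    mad, flagged = _floor_mad(mad)
    if flagged.any():
        logger.debug("compute_rzs: MAD floor applied to %d genes on "
                     "(%s, %s)", int(flagged.sum()), plate, cell_line)
    rzs = (treated_mean - veh_median) / mad
    return DrugSignature(drug, cell_line,
                         pd.Series(rzs, index=screen.genes),
                         n_replicates=1)


def collapse_replicates(signatures: list[DrugSignature]) -> DrugSignature:
    """Per-gene median over replicate signatures of one (drug, cell line)."""
    if not signatures:
        raise ValueError("no signatures to collapse")
    first = signatures[0]
    for sig in signatures[1:]:
        if (sig.drug_id, sig.cell_line_id) != (first.drug_id,
                                               first.cell_line_id):
            raise ValueError("signatures span different (drug, cell line)")
        if list(sig.rzs.index) != list(first.rzs.index):
            raise ValueError("mismatched gene universes")
    stacked = np.vstack([s.rzs.to_numpy() for s in signatures])
    return DrugSignature(first.drug_id, first.cell_line_id,
                         pd.Series(np.median(stacked, axis=0),
                                   index=first.rzs.index),
                         n_replicates=len(signatures))


def build_signature_tensor(screen: ExpressionScreen,
                           mad_constant: str = "raw") -> SignatureTensor:
    """All (drug, cell line) signatures of a screen as one tensor.

    Per-plate RZS first, then median collapse of replicate plates — the
    replicate structure never leaks across the plate-matched transform.
    Vectorized over genes and wells within each (plate, cell line) stratum.
    """
    ann = screen.annotation
    is_drug = ~ann["treatment"].isin([VEHICLE, POSITIVE_CONTROL, EMPTY])
    drugs = sorted(ann.loc[is_drug, "treatment"].unique())
    cell_lines = sorted(ann.loc[ann["treatment"] != EMPTY,
                                "cell_line_id"].unique())
    genes = screen.genes
    group_labels = (ann[ann["treatment"] != EMPTY]
                    .drop_duplicates("cell_line_id")
                    .set_index("cell_line_id")["group_label"].to_dict())

    values = screen.matrix.values
    # per (drug, cell): list of per-plate RZS vectors
    per_pair: dict[tuple[str, str], list[np.ndarray]] = {}
    strata = ann[ann["treatment"] != EMPTY].groupby(
        ["plate_id", "cell_line_id"], sort=True)
    for (plate, cell), stratum in strata:
        veh_wells = stratum.loc[stratum["treatment"] == VEHICLE,
                                "well_id"].tolist()
        treated = stratum[stratum["treatment"].isin(drugs)]
        if treated.empty:
            continue
        if len(veh_wells) < 3:
            raise ValueError(
                f"need >=3 vehicle wells on ({plate}, {cell}), "
                f"found {len(veh_wells)}")
        veh = values[veh_wells].to_numpy()
        veh_median = np.median(veh, axis=1)
        mad = _mad(veh)
        if mad_constant == "normal":
            mad = mad * MAD_NORMAL_CONSTANT
        mad, _ = _floor_mad(mad)
        for drug, wells in treated.groupby("treatment")["well_id"]:
            tr = values[list(wells)].to_numpy().mean(axis=1)
            per_pair.setdefault((drug, cell), []).append(
                (tr - veh_median) / mad)

    data = np.full((len(drugs), len(cell_lines), len(genes)), np.nan)
    for (drug, cell), reps in per_pair.items():
        data[drugs.index(drug), cell_lines.index(cell)] = np.median(
            np.vstack(reps), axis=0)
    if np.isnan(data).any():
        missing = [(d, c) for di, d in enumerate(drugs)
                   for ci, c in enumerate(cell_lines)
                   if np.isnan(data[di, ci]).any()]
        raise ValueError(f"missing (drug, cell) signatures: {missing[:5]}")
    return SignatureTensor(data, drugs, cell_lines, genes, group_labels)


def variance_component_fraction(values: np.ndarray,
                                labels: list) -> float:
    """Mean fraction of per-gene variance attributable to a grouping.

    One-way random-effects ANOVA method-of-moments estimate, averaged over
    genes: sigma_group^2 = (MS_between - MS_within) / n0 (clipped at 0),
    reported as sigma_group^2 / (sigma_group^2 + MS_within).  Used as a QC
    check that plate/phase batch structure is gone from RZS signatures.

    ``values`` is genes x samples; ``labels`` assigns each sample to a
    group (e.g. its plate).
    """
    labels = list(labels)
    uniq = sorted(set(labels))
    if len(uniq) < 2:
        raise ValueError("need >= 2 groups")
    n = values.shape[1]
    k = len(uniq)
    groups = [np.flatnonzero([lab == u for lab in labels]) for u in uniq]
    n0 = (n - sum(len(idx) ** 2 for idx in groups) / n) / (k - 1)
    fracs = np.empty(values.shape[0])
    for g in range(values.shape[0]):
        y = values[g]
        overall = y.mean()
        means = [y[idx].mean() for idx in groups]
        ssb = sum(len(idx) * (m - overall) ** 2
                  for idx, m in zip(groups, means))
        ssw = sum(((y[idx] - m) ** 2).sum()
                  for idx, m in zip(groups, means))
        msb, msw = ssb / (k - 1), ssw / (n - k)
        s2 = max(0.0, (msb - msw) / n0)
        fracs[g] = s2 / (s2 + msw) if (s2 + msw) > 0 else 0.0
    return float(fracs.mean())


def vehicle_pseudo_signatures(screen: "ExpressionScreen", cell_line: str
                              ) -> tuple[np.ndarray, list[str]]:
    """RZS of each vehicle well against its own plate's vehicle stats.

    Returns the genes x wells matrix and the plate label per well; the
    input for batch-variance QC on signatures rather than raw expression.
    """
    ann = screen.annotation
    veh = ann[(ann["treatment"] == VEHICLE)
              & (ann["cell_line_id"] == cell_line)]
    if veh.empty:
        raise ValueError(f"no vehicle wells for {cell_line!r}")
    raw = screen.matrix.values[list(veh["well_id"])].to_numpy()
    plates = list(veh["plate_id"])
    rzs = np.empty_like(raw)
    for plate in sorted(set(plates)):
        idx = [i for i, p in enumerate(plates) if p == plate]
        cols = raw[:, idx]
        med = np.median(cols, axis=1, keepdims=True)
        mad, _ = _floor_mad(_mad(cols)[:, None])
        rzs[:, idx] = (cols - med) / mad
    return rzs, plates


def tensor_to_gct(tensor: SignatureTensor) -> GctMatrix:
    """Flatten a tensor to a genes x (drug:cell) GCT for export."""
    cols, mat = [], []
    for di, drug in enumerate(tensor.drugs):
        for ci, cell in enumerate(tensor.cell_lines):
            cols.append(f"{drug}:{cell}")
            mat.append(tensor.data[di, ci])
    return GctMatrix(pd.DataFrame(np.array(mat).T, index=tensor.genes,
                                  columns=cols))
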