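"""Synthetic drug screens with planted ground truth.

The generator emulates the structure of a plate-based L1000-style screen:
96-well treatment plates dedicated to one cell line each, carrying one
empty well, a block of vehicle (DMSO) wells, duplicated positive-control
wells, and one well per test drug; the same layout is repeated across
screening phases and replicate plates.  Expression is additive on the log2
scale:

    x[g, w] = baseline[g] + cell_line_offset + plate_offset + phase_offset
              + drug_effect[g] + N(0, noise_sd)

Drug effects decompose into a base effect shared by all cell lines, a
cell-type modifier applied only in NPC lines, and a diagnosis modifier
applied only in SZ NPC lines.  Batch (plate/phase) offsets are additive
scalars shared by every well of the plate or phase — exactly the structure
the plate-matched robust Z-score transform cancels.  Every planted effect
is recorded in a :class:`TruthTable` so downstream recovery is testable.

Companion generators produce gene-set collections with planted group-wise
shifts, transcript sequences with planted motif densities, variant cohorts
with planted in-motif fractions, and drug-annotation tables with planted
feature over-representation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .io import (EMPTY, POSITIVE_CONTROL, VEHICLE, GctMatrix,
                 GeneSetCollection)
from .signatures import ExpressionScreen

NPC_GROUPS = ("NPC_control", "NPC_SZ")
COMPARISON_GROUPS = {"NPC_vs_CCL": "celltype", "SZ_vs_control": "diagnosis"}


@dataclass
class ScreenConfig:
    """Everything that determines a synthetic screen; the seed fixes all."""

    n_genes: int = 500
    n_drugs: int = 20
    n_cell_lines: dict = field(
        default_factory=lambda: {"CCL": 3, "NPC_control": 3, "NPC_SZ": 2})
    wells_per_plate: int = 96
    n_vehicle_wells: int = 12
    n_positive_wells: int = 4  # two positive controls in duplicate
    n_plates: int = 2          # replicate plate sets per (cell line, phase)
    n_phases: int = 2
    noise_sd: float = 0.3
    batch_sd: float = 1.0
    cell_line_sd: float = 1.0
    baseline_mean: float = 6.0
    baseline_sd: float = 1.0
    batch_per_gene: bool = False
    # planted effects
    de_fraction: float = 0.02       # fraction of (drug, gene) pairs with base effect
    effect_size: float = 2.0        # |log2 shift| of planted effects
    celltype_fraction: float = 0.01  # pairs with an NPC-only extra shift
    diagnosis_fraction: float = 0.005  # pairs with a SZ-NPC-only extra shift
    ccl_deficit_fraction: float = 0.0  # planted base effects present in NPC but absent in CCL
    n_disease_up: int = 50
    n_disease_down: int = 50
    n_reversers: int = 2
    reverser_strength: float = 2.0
    positive_control_effect: float = 3.0
    planted_set_shifts: dict = field(default_factory=dict)
    # gene -> {"NPC_vs_CCL": shift} and/or {"SZ_vs_control": shift}
    seed: int = 0

    def __post_init__(self):
        counts = [self.n_genes, self.n_drugs, self.wells_per_plate,
                  self.n_plates, self.n_phases, *self.n_cell_lines.values()]
        if any(c < 1 for c in counts):
            raise ValueError("all counts must be >= 1")
        if self.n_vehicle_wells < 3:
            raise ValueError("need n_vehicle_wells >= 3 for median/MAD")
        capacity = (self.wells_per_plate - self.n_vehicle_wells
                    - self.n_positive_wells - 1)
        if capacity < 1:
            raise ValueError("no treated-well capacity on a plate")
        if self.n_disease_up + self.n_disease_down > self.n_genes // 2:
            raise ValueError(
                "disease signature (n_disease_up + n_disease_down) must "
                "stay below half the gene universe")

    @classmethod
    def scaled_down(cls, **overrides) -> "ScreenConfig":
        """Default desk-scale preset: 20 drugs, 500 genes, 3+3+2 lines."""
        return cls(**overrides)

    @classmethod
    def full_size(cls, **overrides) -> "ScreenConfig":
        """Study-sized preset: 135 drugs, 12 control + 12 SZ NPC + 8 CCL."""
        params = dict(
            n_drugs=135,
            n_cell_lines={"CCL": 8, "NPC_control": 12, "NPC_SZ": 12},
            n_plates=1,
        )
        params.update(overrides)
        return cls(**params)


@dataclass
class TruthTable:
    """Planted ground truth of one synthetic screen.

    Effect arrays are dense drugs x genes matrices; modifiers are zero
    outside the planted entries.  Reverser drugs carry
    ``base_effect = -disease_effect`` on the disease-signature genes.
    """

    drugs: list
    genes: list
    base_effect: np.ndarray
    celltype_modifier: np.ndarray   # added in NPC_control and NPC_SZ lines
    diagnosis_modifier: np.ndarray  # added in NPC_SZ lines only
    reverser_drugs: list
    disease_up: list
    disease_down: list
    enriched_sets: list = field(default_factory=list)
    # (set name, comparison, shift) triples
    plate_offsets: dict = field(default_factory=dict)
    phase_offsets: dict = field(default_factory=dict)
    cell_line_offsets: dict = field(default_factory=dict)

    def effect(self, drug_idx: int, group: str) -> np.ndarray:
        """Total planted per-gene effect of a drug in a screening group."""
        eff = self.base_effect[drug_idx].copy()
        if group in NPC_GROUPS:
            eff += self.celltype_modifier[drug_idx]
        if group == "NPC_SZ":
            eff += self.diagnosis_modifier[drug_idx]
        return eff

    def expected_de(self, group: str, threshold: float = 2.0,
                    noise_rzs: float = 0.0) -> np.ndarray:
        """Boolean drugs x genes mask of effects that should be DE calls."""
        effects = np.stack([self.effect(d, group)
                            for d in range(len(self.drugs))])
        return np.abs(effects) >= threshold * (1 + noise_rzs)


def _plant_pairs(rng, shape, fraction, size):
    """Sparse +-size entries on a random ``fraction`` of matrix cells."""
    n = int(round(fraction * shape[0] * shape[1]))
    out = np.zeros(shape)
    if n == 0:
        return out
    flat = rng.choice(shape[0] * shape[1], size=n, replace=False)
    signs = rng.choice([-1.0, 1.0], size=n)
    out.flat[flat] = signs * size
    return out


def simulate_screen(config: ScreenConfig
                    ) -> tuple[ExpressionScreen, TruthTable]:
    """Generate a plate-structured screen and its planted truth.

    Identical configs (same seed) produce bit-identical output.
    """
    rng = np.random.default_rng(config.seed)
    genes = [f"G{i:05d}" for i in range(config.n_genes)]
    drugs = [f"DRUG_{i:03d}" for i in range(config.n_drugs)]
    cells, groups = [], {}
    for group, n in sorted(config.n_cell_lines.items()):
        for i in range(n):
            cid = f"{group}_{i:02d}"
            cells.append(cid)
            groups[cid] = group

    base = _plant_pairs(rng, (config.n_drugs, config.n_genes),
                        config.de_fraction, config.effect_size)
    celltype = _plant_pairs(rng, (config.n_drugs, config.n_genes),
                            config.celltype_fraction, config.effect_size)
    diagnosis = _plant_pairs(rng, (config.n_drugs, config.n_genes),
                             config.diagnosis_fraction, config.effect_size)

    # responsiveness deficit: move part of the base effect into the
    # cell-type modifier, so it is present in NPC lines but absent in CCLs
    if config.ccl_deficit_fraction > 0:
        planted = np.flatnonzero(base)
        k = int(round(config.ccl_deficit_fraction * planted.size))
        move = rng.choice(planted, size=k, replace=False)
        celltype.flat[move] += base.flat[move]
        base.flat[move] = 0.0

    # disease signature and reverser drugs
    sig_genes = rng.choice(config.n_genes,
                           size=config.n_disease_up + config.n_disease_down,
                           replace=False)
    disease_up = sorted(genes[i] for i in sig_genes[:config.n_disease_up])
    disease_down = sorted(genes[i] for i in sig_genes[config.n_disease_up:])
    disease_effect = np.zeros(config.n_genes)
    disease_effect[[genes.index(g) for g in disease_up]] = \
        config.reverser_strength
    disease_effect[[genes.index(g) for g in disease_down]] = \
        -config.reverser_strength
    n_rev = min(config.n_reversers, config.n_drugs)
    reverser_idx = rng.choice(config.n_drugs, size=n_rev, replace=False)
    for d in reverser_idx:
        base[d] = -disease_effect
        celltype[d] = 0.0
        diagnosis[d] = 0.0
    reversers = sorted(drugs[d] for d in reverser_idx)

    # planted gene-set shifts (drug-independent group-wise shifts)
    set_celltype = np.zeros(config.n_genes)
    set_diagnosis = np.zeros(config.n_genes)
    for gene, shifts in config.planted_set_shifts.items():
        gi = genes.index(gene)
        set_celltype[gi] += shifts.get("NPC_vs_CCL", 0.0)
        set_diagnosis[gi] += shifts.get("SZ_vs_control", 0.0)

    baseline = rng.normal(config.baseline_mean, config.baseline_sd,
                          config.n_genes)
    cell_offsets = {c: rng.normal(0, config.cell_line_sd) for c in cells}
    phase_ids = [f"PH{p}" for p in range(config.n_phases)]
    if config.batch_per_gene:
        phase_offsets = {p: rng.normal(0, config.batch_sd, config.n_genes)
                         for p in phase_ids}
    else:
        phase_offsets = {p: rng.normal(0, config.batch_sd)
                         for p in phase_ids}

    capacity = (config.wells_per_plate - config.n_vehicle_wells
                - config.n_positive_wells - 1)
    chunks = [drugs[i:i + capacity] for i in range(0, len(drugs), capacity)]

    records = []          # annotation rows
    effects = []          # per-well planted effect vector (or None)
    batch = []            # per-well plate+phase offset (scalar or vector)
    plate_offsets: dict = {}
    drug_index = {d: i for i, d in enumerate(drugs)}
    for cell in cells:
        group = groups[cell]
        is_npc = group in NPC_GROUPS
        is_sz = group == "NPC_SZ"
        for phase in phase_ids:
            for rep in range(config.n_plates):
                for ch, chunk in enumerate(chunks):
                    plate = f"{phase}_{cell}_R{rep}C{ch}"
                    if config.batch_per_gene:
                        plate_offsets[plate] = rng.normal(
                            0, config.batch_sd, config.n_genes)
                    else:
                        plate_offsets[plate] = rng.normal(0, config.batch_sd)
                    off = plate_offsets[plate] + phase_offsets[phase]
                    w = 0

                    def add(treatment, effect, cell_id=cell,
                            group_id=group):
                        nonlocal w
                        records.append((f"{plate}:W{w:02d}", plate, phase,
                                        cell_id, group_id, treatment, 10.0))
                        effects.append(effect)
                        batch.append(off)
                        w += 1

                    add(EMPTY, None, cell_id="", group_id="")
                    for _ in range(config.n_vehicle_wells):
                        add(VEHICLE, np.zeros(config.n_genes))
                    pos_effect = np.zeros(config.n_genes)
                    pos_effect[:min(20, config.n_genes)] = \
                        config.positive_control_effect
                    for _ in range(config.n_positive_wells):
                        add(POSITIVE_CONTROL, pos_effect)
                    for drug in chunk:
                        d = drug_index[drug]
                        eff = base[d].copy()
                        if is_npc:
                            eff += celltype[d] + set_celltype
                        if is_sz:
                            eff += diagnosis[d] + set_diagnosis
                        add(drug, eff)

    n_wells = len(records)
    noise = rng.normal(0, config.noise_sd, (config.n_genes, n_wells))
    matrix = np.empty((config.n_genes, n_wells))
    for j in range(n_wells):
        col = baseline + batch[j] + noise[:, j]
        rec = records[j]
        if rec[3]:
            col = col + cell_offsets[rec[3]]
        if effects[j] is not None:
            col = col + effects[j]
        matrix[:, j] = col

    ann = pd.DataFrame(records, columns=[
        "well_id", "plate_id", "phase_id", "cell_line_id",
        "group_label", "treatment", "dose"])
    gct = GctMatrix(pd.DataFrame(matrix, index=genes,
                                 columns=ann["well_id"].tolist()))
    screen = ExpressionScreen(gct, ann)
    truth = TruthTable(
        drugs=drugs, genes=genes, base_effect=base,
        celltype_modifier=celltype, diagnosis_modifier=diagnosis,
        reverser_drugs=reversers, disease_up=disease_up,
        disease_down=disease_down,
        enriched_sets=[],
        plate_offsets=plate_offsets, phase_offsets=phase_offsets,
        cell_line_offsets=cell_offsets)
    return screen, truth


# ---------------------------------------------------------------------------
# Gene sets
# ---------------------------------------------------------------------------

def simulate_gene_sets(universe: list[str], n_sets: int, set_size: int,
                       planted: dict | None = None, seed: int = 0,
                       category: str = "synthetic"
                       ) -> tuple[GeneSetCollection, dict]:
    """Sample gene sets; optionally plant group-wise shifts on some.

    ``planted`` maps a set name to ``(comparison, shift)`` with comparison
    in {"NPC_vs_CCL", "SZ_vs_control"}.  Planted sets are added on top of
    ``n_sets - len(planted)`` null sets.  Returns the collection and a
    truth-update dict with keys ``enriched_sets`` (list of
    (name, comparison, shift)) and ``set_shifts`` (gene -> comparison ->
    shift, suitable for ``ScreenConfig.planted_set_shifts``).
    """
    planted = planted or {}
    if len(planted) > n_sets:
        raise ValueError("more planted sets than n_sets")
    if set_size > len(universe):
        raise ValueError("set_size exceeds universe")
    rng = np.random.default_rng(seed)
    sets: dict[str, frozenset] = {}
    names = list(planted) + [f"null_set_{i:03d}"
                             for i in range(n_sets - len(planted))]
    if len(set(names)) != len(names):
        raise ValueError("planted set name collides with a null set name")
    for name in names:
        idx = rng.choice(len(universe), size=set_size, replace=False)
        sets[name] = frozenset(universe[i] for i in idx)
    set_shifts: dict[str, dict[str, float]] = {}
    enriched = []
    for name, (comparison, shift) in planted.items():
        if comparison not in COMPARISON_GROUPS:
            raise ValueError(f"unknown comparison {comparison!r}")
        enriched.append((name, comparison, shift))
        for gene in sets[name]:
            set_shifts.setdefault(gene, {})
            set_shifts[gene][comparison] = \
                set_shifts[gene].get(comparison, 0.0) + shift
    collection = GeneSetCollection(sets, category=category)
    return collection, {"enriched_sets": enriched, "set_shifts": set_shifts}


# ---------------------------------------------------------------------------
# Sequences and variants
# ---------------------------------------------------------------------------

_RNA = np.array(list("ACGU"))


def _scrub(seq: list[str], motif, rng, max_rounds: int = 20) -> list[str]:
    """Mutate chance motif occurrences away until none remain."""
    from .motifs import scan_motif
    for _ in range(max_rounds):
        hits = scan_motif("".join(seq), motif)
        if not hits:
            return seq
        for start in hits:
            pos = start + int(rng.integers(len(motif.pattern)))
            choices = [c for c in "ACGU"
                       if not motif.matches_at(c, pos - start)]
            if choices:
                seq[pos] = choices[int(rng.integers(len(choices)))]
    raise RuntimeError("could not scrub motif occurrences")


def simulate_sequences_and_variants(
        n_seqs: int, length: int, motif, density_high: float,
        density_low: float, n_variants: dict, in_motif_fraction: dict,
        seed: int = 0, window: int = 10
) -> tuple[dict[str, str], pd.DataFrame, dict]:
    """Transcripts with planted motif densities plus variant cohorts.

    Two sequence groups ("high"/"low") of ``n_seqs`` each carry planted
    motif occurrences at about ``density_high`` / ``density_low`` per kb
    (Poisson counts, chance background occurrences scrubbed first).
    ``n_variants`` and ``in_motif_fraction`` map cohort name -> count and
    -> probability that the variant site lies inside a motif occurrence.
    Variant windows span ``+-window`` nt around the site.

    Returns (sequences, variant table, truth).
    """
    from .motifs import MotifPattern, realize_motif
    if not isinstance(motif, MotifPattern):
        motif = MotifPattern(motif)
    mlen = len(motif.pattern)
    if mlen > length:
        raise ValueError("motif longer than sequence")
    for name, frac in in_motif_fraction.items():
        if not 0 <= frac <= 1:
            raise ValueError(f"in_motif_fraction[{name}] outside [0,1]")
    for dens in (density_high, density_low):
        if dens * length / 1000 * mlen > length / 2:
            raise ValueError("motif density infeasible for sequence length")
    rng = np.random.default_rng(seed)

    seqs: dict[str, str] = {}
    truth_counts: dict[str, int] = {}
    for group, density in (("high", density_high), ("low", density_low)):
        for i in range(n_seqs):
            seq = list(rng.choice(_RNA, size=length))
            seq = _scrub(seq, motif, rng)
            k = int(rng.poisson(density * length / 1000))
            placed = 0
            occupied: list[int] = []
            for _ in range(10 * k):
                if placed >= k:
                    break
                start = int(rng.integers(0, length - mlen + 1))
                if any(abs(start - o) < mlen for o in occupied):
                    continue
                seq[start:start + mlen] = realize_motif(motif, rng)
                occupied.append(start)
                placed += 1
            name = f"{group}_seq_{i:03d}"
            seqs[name] = "".join(seq)
            truth_counts[name] = placed

    win_len = 2 * window + 1
    rows = []
    truth_in_motif: dict[str, bool] = {}
    for cohort, n in n_variants.items():
        frac = in_motif_fraction.get(cohort, 0.0)
        for i in range(n):
            w = list(rng.choice(_RNA, size=win_len))
            w = _scrub(w, motif, rng)
            in_motif = bool(rng.random() < frac)
            if in_motif:
                start = int(rng.integers(max(0, window - mlen + 1),
                                         min(window, win_len - mlen) + 1))
                w[start:start + mlen] = realize_motif(motif, rng)
            window_seq = "".join(w)
            ref = window_seq[window]
            alt = str(rng.choice([c for c in "ACGU" if c != ref]))
            annotation = str(rng.choice(
                ["missense", "essential_splice_site", "synonymous"],
                p=[0.6, 0.2, 0.2]))
            vid = f"{cohort}_var_{i:04d}"
            rows.append((vid, cohort, annotation, window_seq, window,
                         ref, alt))
            truth_in_motif[vid] = in_motif
    variants = pd.DataFrame(rows, columns=[
        "variant_id", "cohort", "annotation", "window_seq", "offset",
        "ref", "alt"])
    truth = {"planted_counts": truth_counts, "in_motif": truth_in_motif,
             "in_motif_fraction": dict(in_motif_fraction)}
    return seqs, variants, truth


# ---------------------------------------------------------------------------
# Drug annotations
# ---------------------------------------------------------------------------

def simulate_drug_annotations(
        drugs: list[str], classes: list[str], n_features: int | dict = 10,
        planted: list | None = None, seed: int = 0,
        annotated_fraction: float = 0.8, base_prevalence: float = 0.2,
        planted_prevalence: float = 0.8
) -> tuple[pd.DataFrame, dict]:
    """Drug-annotation table with planted feature over-representation.

    ``planted`` is a list of ``(drug_group, class, feature)`` triples: each
    drug of the group gets the feature with probability
    ``planted_prevalence`` (background drugs keep ``base_prevalence``).
    A fraction ``1 - annotated_fraction`` of drugs carries no annotation in
    a class at all (and so falls outside that class's background).
    """
    planted = planted or []
    if isinstance(n_features, int):
        n_features = {c: n_features for c in classes}
    catalog = {c: [f"{c}_feat{i:02d}" for i in range(n_features[c])]
               for c in classes}
    for group, cls, feature in planted:
        if cls not in catalog:
            raise ValueError(f"planted class {cls!r} not in classes")
        if feature not in catalog[cls]:
            raise ValueError(f"planted feature {feature!r} outside the "
                             f"{cls!r} catalog")
        unknown = set(group) - set(drugs)
        if unknown:
            raise ValueError(f"planted drugs not screened: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    planted_map = {(cls, feat): set(group) for group, cls, feat in planted}
    rows = []
    for cls in classes:
        for drug in drugs:
            if rng.random() >= annotated_fraction:
                continue  # drug has no annotations in this class
            got_any = False
            for feat in catalog[cls]:
                p = (planted_prevalence
                     if drug in planted_map.get((cls, feat), ())
                     else base_prevalence)
                if rng.random() < p:
                    rows.append((drug, cls, feat))
                    got_any = True
            if not got_any:  # annotated drugs carry at least one feature
                feat = catalog[cls][int(rng.integers(len(catalog[cls])))]
                rows.append((drug, cls, feat))
    table = pd.DataFrame(rows, columns=["drug", "class", "feature"])
    truth = {"planted": planted, "catalog": catalog}
    return table, truth
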