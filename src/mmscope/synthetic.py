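"""Synthetic multiple-myeloma cohort generator with planted ground truth.

Generates 10x-style negative-binomial count matrices that emulate the
statistical structure the downstream analysis assumes: per-patient tumor
subclones carrying arm-level copy-number dosage effects (including 1q gain
at controllable fractions), a normal-plasma-cell (nPC) reference
population, bone-marrow-microenvironment (BME) cell types with marker
genes, and planted ligand-receptor co-expression between chosen cell
types. Every generated cell carries truth labels, so each analysis stage
can be validated without access to patient data.

Counts are drawn as ``NB(mean = base_mean x dosage x marker_shift x
lib_factor, inverse-dispersion r)``, where the dosage multiplier for a
gene inside a copy-number event is ``copy_number / 2`` (the standard
expression-CNA assumption: expression scales with DNA copies, neutral
regions are unchanged). Genes live on a compressed toy genome of 22
autosomes with declared arm boundaries mirroring real arm proportions
(acrocentric chromosomes carry only q-arm genes); only ordering and arm
membership matter for the analysis. Because ~2,000 panel genes stand in
for a ~20,000-gene transcriptome, each synthetic gene behaves like an
aggregate of roughly ten real genes: default base means (~12 counts) and
inverse-dispersion (10) are those of such meta-gene sums at typical
10x sequencing depth, which keeps the information content per smoothing
window comparable to real data on the shortened genome.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
import yaml

from . import io_core
from .interactions import load_default_pairs

__all__ = [
    "ConfigError",
    "CNAEvent",
    "SubcloneSim",
    "PatientSim",
    "BMEType",
    "LRTruth",
    "SimConfig",
    "SimulatedDataset",
    "simulate_cohort",
    "make_default_fixtures",
    "default_cohort_config",
    "three_clone_config",
    "minor_clone_config",
    "signature_cohort_config",
    "save_config",
    "load_config",
]


class ConfigError(ValueError):
    """A simulation configuration violates its invariants."""


@dataclass
class CNAEvent:
    """Arm-level copy-number event; ``copy_number`` in {1, 2, 3, 4}."""

    arm: str
    copy_number: int


@dataclass
class SubcloneSim:
    name: str
    fraction_pre: float
    fraction_post: float
    events: list[CNAEvent] = field(default_factory=list)


@dataclass
class PatientSim:
    patient_id: str
    n_tumor_pre: int
    n_tumor_post: int
    n_reference: int
    n_bme_pre: int
    n_bme_post: int
    subclones: list[SubcloneSim] = field(default_factory=list)
    bme_fractions: dict[str, float] | None = None


@dataclass
class BMEType:
    name: str
    fraction: float
    markers: dict[str, float] = field(default_factory=dict)


@dataclass
class LRTruth:
    """A planted ligand-receptor co-expression axis."""

    ligand: str
    receptors: list[str]
    sender: str
    receiver: str
    fold: float


@dataclass
class SimConfig:
    seed: int = 0
    n_genes: int = 2000
    n_chromosomes: int = 22
    n_chr1_genes: int | None = None  # None: weight-based allocation
    chr1_weight: float = 2.0  # chromosome 1 is the most gene-dense
    base_mean_log_mu: float = 2.5
    base_mean_log_sigma: float = 0.5
    nb_inverse_dispersion: float = 10.0
    libsize_log_sigma: float = 0.35
    patient_effect_sigma: float = 0.1  # per-patient tumor expression programs
    dosage_attenuation: tuple[float, float] | None = None  # Beta(a, b) response
    n_mito_genes: int = 10
    mito_mean: float = 15.0
    marker_base_mean: float = 0.5
    marker_fold_default: float = 8.0
    plasma_marker_fold: float = 20.0
    lr_base_mean: float = 0.8
    junk_cell_frac: float = 0.02
    doublet_frac: float = 0.03
    patients: list[PatientSim] = field(default_factory=list)
    bme_types: list[BMEType] = field(default_factory=list)
    lr_truth: list[LRTruth] = field(default_factory=list)


@dataclass
class SimulatedDataset:
    """A generated cohort plus all truth tables."""

    adata: ad.AnnData
    gene_order: pd.DataFrame  # gene, chrom, start, end, arm (autosomes)
    arm_boundaries: pd.DataFrame  # chrom, arm, boundary
    sample_truth: pd.DataFrame  # patient_id, timepoint, true_1q_fraction
    clone_truth: pd.DataFrame  # patient_id, subclone, arm, copy_number
    lr_truth: pd.DataFrame
    config: SimConfig


PLASMA_MARKERS = ("TNFRSF17", "SDC1", "SLAMF7", "CD38")

#: Approximate fraction of each chromosome's genes on the q arm, mirroring
#: real centromere positions; acrocentric chromosomes carry q-arm genes only.
Q_ARM_FRACTION = {
    "1": 0.50, "2": 0.62, "3": 0.55, "4": 0.63, "5": 0.60, "6": 0.65,
    "7": 0.62, "8": 0.62, "9": 0.60, "10": 0.60, "11": 0.60, "12": 0.65,
    "13": 1.00, "14": 1.00, "15": 1.00, "16": 0.60, "17": 0.70, "18": 0.65,
    "19": 0.55, "20": 0.55, "21": 1.00, "22": 1.00,
}

_DEFAULT_BME = [
    ("T_CD4", 0.20, ("CD3D", "CD3E", "IL7R")),
    ("T_CD8", 0.16, ("CD8A", "CD8B", "GZMK")),
    ("NK", 0.12, ("NKG7", "GNLY", "KLRD1")),
    ("gdT", 0.08, ("TRDC", "TRGC1", "KLRG1")),
    ("Mono_CD14", 0.18, ("CD14", "LYZ", "S100A8")),
    ("TAM", 0.10, ("FCGR3A", "CD68", "C1QA")),
    ("B", 0.10, ("CD79A", "MS4A1", "CD19")),
    ("pDC", 0.06, ("LILRA4", "IRF8", "CLEC4C")),
]

# BME composition shift planted in patients carrying a detectable 1q gain:
# TAM-like macrophages accumulate while NK cells are depleted.
_SHIFTED_BME_FRACTIONS = {
    "T_CD4": 0.19, "T_CD8": 0.15, "NK": 0.06, "gdT": 0.09,
    "Mono_CD14": 0.19, "TAM": 0.17, "B": 0.09, "pDC": 0.06,
}


# ---------------------------------------------------------------------------
# Gene panel
# ---------------------------------------------------------------------------

def _special_gene_names(cfg: SimConfig) -> list[str]:
    names: list[str] = list(PLASMA_MARKERS)
    for _, _, markers in _DEFAULT_BME:
        names.extend(markers)
    for t in cfg.bme_types:
        names.extend(t.markers)
    pairs = load_default_pairs()
    for _, row in pairs.iterrows():
        names.extend(row["ligand_genes"])
        names.extend(row["receptor_genes"])
    for lr in cfg.lr_truth:
        names.append(lr.ligand)
        names.extend(lr.receptors)
    seen: dict[str, None] = {}
    for n in names:
        seen.setdefault(n)
    return list(seen)


def _build_gene_panel(cfg: SimConfig, rng: np.random.Generator):
    """Lay out the gene panel on a compressed toy genome.

    Returns (var, gene_order, arm_boundaries). Named marker / ligand /
    receptor genes are placed on chromosomes 2-22 so chromosome 1 carries
    only generic dosage-responsive genes; mitochondrial genes sit outside
    the autosomal gene order.
    """
    n_chrom = cfg.n_chromosomes
    if cfg.n_chr1_genes is not None:
        n_chr1 = cfg.n_chr1_genes
        rest = cfg.n_genes - n_chr1
        per = [n_chr1] + [rest // (n_chrom - 1)] * (n_chrom - 1)
        for i in range(rest - sum(per[1:])):
            per[1 + i] += 1
    else:
        weights = np.array([cfg.chr1_weight] + [1.0] * (n_chrom - 1))
        raw = weights / weights.sum() * cfg.n_genes
        per = np.floor(raw).astype(int)
        for i in np.argsort(-(raw - per))[: cfg.n_genes - per.sum()]:
            per[i] += 1
        per = per.tolist()

    chroms, starts, ends, arms = [], [], [], []
    arm_rows = []
    for ci, n_on_chrom in enumerate(per, start=1):
        chrom = str(ci)
        q_frac = Q_ARM_FRACTION.get(chrom, 0.6)
        n_p = int(round(n_on_chrom * (1.0 - q_frac)))
        boundary = (n_p + 1) * 100_000 - 1 if n_p else 0
        if n_p:
            arm_rows.append((chrom, f"{chrom}p", boundary))
        arm_rows.append((chrom, f"{chrom}q", (n_on_chrom + 1) * 100_000))
        for gi in range(n_on_chrom):
            start = (gi + 1) * 100_000
            chroms.append(chrom)
            starts.append(start)
            ends.append(start + 1_000)
            arms.append(f"{chrom}p" if start <= boundary else f"{chrom}q")

    n_auto = len(chroms)
    names = np.array([f"GENE{i:04d}" for i in range(n_auto)], dtype=object)
    special = _special_gene_names(cfg)
    off_chr1 = np.flatnonzero(np.array(chroms) != "1")
    if len(special) > len(off_chr1):
        raise ConfigError("gene panel too small to place all named genes")
    slots = off_chr1[np.linspace(0, len(off_chr1) - 1, len(special)).astype(int)]
    names[slots] = special

    gene_order = pd.DataFrame(
        {"gene": names, "chrom": chroms, "start": starts, "end": ends, "arm": arms}
    )
    arm_boundaries = pd.DataFrame(arm_rows, columns=["chrom", "arm", "boundary"])

    base_mean = rng.lognormal(cfg.base_mean_log_mu, cfg.base_mean_log_sigma, n_auto)
    special_set = set(special)
    marker_set = {m for _, _, ms in _DEFAULT_BME for m in ms}
    marker_set |= {m for t in cfg.bme_types for m in t.markers}
    for i, name in enumerate(names):
        if name in special_set:
            base_mean[i] = cfg.marker_base_mean if name in marker_set else cfg.lr_base_mean
    for name in PLASMA_MARKERS:
        base_mean[names == name] = cfg.marker_base_mean

    mito_names = [f"MT-GENE{i}" for i in range(cfg.n_mito_genes)]
    var = pd.DataFrame(
        {
            "chrom": list(gene_order["chrom"]) + ["MT"] * cfg.n_mito_genes,
            "start": list(gene_order["start"]) + [(i + 1) * 1_000 for i in range(cfg.n_mito_genes)],
            "mito": [False] * n_auto + [True] * cfg.n_mito_genes,
            "base_mean": list(base_mean) + [cfg.mito_mean] * cfg.n_mito_genes,
        },
        index=pd.Index(list(names) + mito_names, name="gene_id"),
    )
    return var, gene_order, arm_boundaries


def _allocate(n: int, fractions: np.ndarray) -> np.ndarray:
    """Deterministic largest-remainder allocation of n cells to fractions."""
    raw = fractions * n
    counts = np.floor(raw).astype(int)
    for i in np.argsort(-(raw - counts), kind="stable")[: n - counts.sum()]:
        counts[i] += 1
    return counts


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

def _validate(cfg: SimConfig) -> None:
    for p in cfg.patients:
        for tp, n in (("pre", p.n_tumor_pre), ("post", p.n_tumor_post)):
            if n == 0:
                continue
            total = sum(
                s.fraction_pre if tp == "pre" else s.fraction_post for s in p.subclones
            )
            if abs(total - 1.0) > 1e-9:
                raise ConfigError(
                    f"{p.patient_id}/{tp}: subclone fractions sum to {total}, not 1"
                )
        for s in p.subclones:
            for ev in s.events:
                if ev.copy_number not in (1, 2, 3, 4):
                    raise ConfigError(
                        f"{p.patient_id}/{s.name}: copy number {ev.copy_number} outside 1..4"
                    )
    if cfg.bme_types:
        total = sum(t.fraction for t in cfg.bme_types)
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"BME type fractions sum to {total}, not 1")


def _dosage_multiplier(
    events: list[CNAEvent], arm_of_gene: np.ndarray, response: np.ndarray
) -> np.ndarray:
    mult = np.ones(len(arm_of_gene))
    for ev in events:
        on_arm = arm_of_gene == ev.arm
        mult[on_arm] = 1.0 + response[on_arm] * (ev.copy_number / 2.0 - 1.0)
    return mult


def simulate_cohort(cfg: SimConfig) -> SimulatedDataset:
    """Generate a full cohort; identical config and seed give identical data."""
    _validate(cfg)
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
    var, gene_order, arm_boundaries = _build_gene_panel(cfg, rng)

    gene_names = var.index.to_numpy()
    base_mean = var["base_mean"].to_numpy().copy()
    mito = var["mito"].to_numpy()
    n_genes = len(var)
    arm_of_gene = np.array(
        list(gene_order["arm"]) + [""] * int(mito.sum()), dtype=object
    )
    gene_idx = {g: i for i, g in enumerate(gene_names)}
    r = cfg.nb_inverse_dispersion

    if cfg.dosage_attenuation is not None:
        a, b = cfg.dosage_attenuation
        response = rng.beta(a, b, n_genes)
    else:
        response = np.ones(n_genes)

    bme_frac_default = {t.name: t.fraction for t in cfg.bme_types}
    bme_markers = {t.name: t.markers for t in cfg.bme_types}

    def lr_multiplier(population: str) -> np.ndarray:
        mult = np.ones(n_genes)
        for lr in cfg.lr_truth:
            if lr.sender == population:
                mult[gene_idx[lr.ligand]] *= lr.fold
            if lr.receiver == population:
                for g in lr.receptors:
                    mult[gene_idx[g]] *= lr.fold
        return mult

    plasma_mult = np.ones(n_genes)
    for g in PLASMA_MARKERS:
        plasma_mult[gene_idx[g]] = cfg.plasma_marker_fold

    blocks: list[sp.csr_matrix] = []
    obs_rows: list[dict] = []
    sample_truth_rows: list[dict] = []
    clone_truth_rows: list[dict] = []

    def draw_block(n_cells: int, group_mult: np.ndarray) -> None:
        if n_cells == 0:
            return
        lib = rng.lognormal(0.0, cfg.libsize_log_sigma, n_cells)
        junk = rng.random(n_cells) < cfg.junk_cell_frac
        means = lib[:, None] * (base_mean * group_mult)[None, :]
        if junk.any():
            scale = np.ones((int(junk.sum()), n_genes))
            scale[:, ~mito] = 0.01
            scale[:, mito] = 6.0
            means[junk] *= scale
        counts = rng.negative_binomial(r, r / (r + means)).astype(np.int32)
        blocks.append(sp.csr_matrix(counts))
        score = rng.beta(1.5, 20.0, n_cells)
        is_doublet = rng.random(n_cells) < cfg.doublet_frac
        score[is_doublet] = rng.uniform(0.5, 0.9, int(is_doublet.sum()))
        for i in range(n_cells):
            obs_rows.append({"doublet_score": float(score[i]), "junk": bool(junk[i])})

    for p in cfg.patients:
        patient_effect = rng.lognormal(0.0, cfg.patient_effect_sigma, n_genes)
        for s in p.subclones:
            for ev in s.events:
                clone_truth_rows.append(
                    {
                        "patient_id": p.patient_id,
                        "subclone": s.name,
                        "arm": ev.arm,
                        "copy_number": ev.copy_number,
                    }
                )
        for tp, n_tumor in (("pre", p.n_tumor_pre), ("post", p.n_tumor_post)):
            if n_tumor == 0:
                continue
            fracs = np.array(
                [s.fraction_pre if tp == "pre" else s.fraction_post for s in p.subclones]
            )
            counts_per_clone = _allocate(n_tumor, fracs)
            gained = [
                s.name
                for s in p.subclones
                if any(ev.arm == "1q" and ev.copy_number > 2 for ev in s.events)
            ]
            true_frac = counts_per_clone[
                [i for i, s in enumerate(p.subclones) if s.name in gained]
            ].sum() / n_tumor
            sample_truth_rows.append(
                {
                    "patient_id": p.patient_id,
                    "timepoint": tp,
                    "true_1q_fraction": float(true_frac),
                }
            )
            tumor_lr = lr_multiplier("Myeloma")
            for s, n_cells in zip(p.subclones, counts_per_clone):
                start = len(obs_rows)
                mult = (
                    _dosage_multiplier(s.events, arm_of_gene, response)
                    * plasma_mult
                    * patient_effect
                    * tumor_lr
                )
                draw_block(int(n_cells), mult)
                for row in obs_rows[start:]:
                    row.update(
                        patient_id=p.patient_id,
                        timepoint=tp,
                        fraction="CD138pos",
                        cell_type="Myeloma",
                        subclone=s.name,
                    )
        # reference normal plasma cells (split across timepoints)
        n_ref_pre = p.n_reference // 2 if p.n_tumor_post else p.n_reference
        for tp, n_ref in (("pre", n_ref_pre), ("post", p.n_reference - n_ref_pre)):
            start = len(obs_rows)
            draw_block(n_ref, plasma_mult * lr_multiplier("nPC"))
            for row in obs_rows[start:]:
                row.update(
                    patient_id=p.patient_id,
                    timepoint=tp,
                    fraction="CD138pos",
                    cell_type="nPC",
                    subclone="normal",
                )
        # BME cells
        for tp, n_bme in (("pre", p.n_bme_pre), ("post", p.n_bme_post)):
            if n_bme == 0:
                continue
            fracs_map = p.bme_fractions or bme_frac_default
            type_names = [t.name for t in cfg.bme_types]
            counts_per_type = _allocate(
                n_bme, np.array([fracs_map[t] for t in type_names])
            )
            for tname, n_cells in zip(type_names, counts_per_type):
                mult = lr_multiplier(tname)
                for g, fold in bme_markers[tname].items():
                    mult[gene_idx[g]] *= fold
                start = len(obs_rows)
                draw_block(int(n_cells), mult)
                for row in obs_rows[start:]:
                    row.update(
                        patient_id=p.patient_id,
                        timepoint=tp,
                        fraction="CD138neg",
                        cell_type=tname,
                        subclone="",
                    )

    x = sp.vstack(blocks, format="csr") if blocks else sp.csr_matrix((0, n_genes))
    obs = pd.DataFrame(obs_rows)
    obs.index = pd.Index(
        [
            f"{row['patient_id']}_{row['timepoint']}_{i:05d}"
            for i, row in enumerate(obs_rows)
        ],
        name="cell_id",
    )
    adata = ad.AnnData(X=x, obs=obs, var=var.copy())

    lr_truth = pd.DataFrame(
        [
            {
                "ligand": lr.ligand,
                "receptors": "+".join(lr.receptors),
                "sender": lr.sender,
                "receiver": lr.receiver,
                "fold": lr.fold,
            }
            for lr in cfg.lr_truth
        ],
        columns=["ligand", "receptors", "sender", "receiver", "fold"],
    )
    return SimulatedDataset(
        adata=adata,
        gene_order=gene_order,
        arm_boundaries=arm_boundaries,
        sample_truth=pd.DataFrame(
            sample_truth_rows, columns=["patient_id", "timepoint", "true_1q_fraction"]
        ),
        clone_truth=pd.DataFrame(
            clone_truth_rows, columns=["patient_id", "subclone", "arm", "copy_number"]
        ),
        lr_truth=lr_truth,
        config=cfg,
    )


# ---------------------------------------------------------------------------
# Stock configurations
# ---------------------------------------------------------------------------

_BASE_EVENTS = [
    CNAEvent("13q", 1), CNAEvent("9q", 3), CNAEvent("16q", 1),
    CNAEvent("3p", 3), CNAEvent("11q", 3), CNAEvent("8p", 1),
    CNAEvent("6q", 1), CNAEvent("15q", 3), CNAEvent("17p", 1),
    CNAEvent("5q", 3),
]

#: True 1q-gain cell fractions (pre-treatment) of the stock cohort; they span
#: the not-detected/rare (<10%), subclonal (10-80%) and dominant (>80%) bands.
DEFAULT_1Q_FRACTIONS = (0.0, 0.02, 0.05, 0.15, 0.30, 0.45, 0.55, 0.70, 0.90, 1.0)


def _default_bme_types() -> list[BMEType]:
    return [
        BMEType(name, frac, {m: 8.0 for m in markers})
        for name, frac, markers in _DEFAULT_BME
    ]


def _default_lr_truth() -> list[LRTruth]:
    return [
        LRTruth("MIF", ["CD74", "CD44"], "Myeloma", "Mono_CD14", 4.0),
        LRTruth("IL18", ["IL18R1", "IL18RAP"], "TAM", "NK", 4.0),
        LRTruth("CD48", ["CD244"], "Myeloma", "NK", 4.0),
        LRTruth("FAM3C", ["KIR2DL3"], "Myeloma", "gdT", 4.0),
        LRTruth("CD47", ["SIRPA"], "Myeloma", "Mono_CD14", 4.0),
    ]


def default_cohort_config(
    seed: int = 0,
    n_tumor: int = 500,
    n_reference: int = 120,
    n_bme: int = 400,
) -> SimConfig:
    """Stock 10-patient cohort with paired pre/post samples.

    Planted 1q-gain fractions span all three abundance bands; gained clones
    expand after treatment while the remaining clones shrink
    proportionally, and patients with detectable 1q gain carry a shifted
    BME composition (more TAM, fewer NK cells).
    """
    patients = []
    for i, f in enumerate(DEFAULT_1Q_FRACTIONS):
        pid = f"P{i + 1:02d}"
        base = _BASE_EVENTS[i % len(_BASE_EVENTS)]
        f_post = min(1.0, f + 0.15) if f > 0 else 0.0
        if f == 0.0:
            clones = [
                SubcloneSim("A", 0.6, 0.5, [base]),
                SubcloneSim("B", 0.4, 0.5, [base, CNAEvent("11q", 3)]),
            ]
        elif f == 1.0:
            clones = [
                SubcloneSim("A", 0.7, 0.6, [base, CNAEvent("1q", 3)]),
                SubcloneSim("B", 0.3, 0.4, [base, CNAEvent("1q", 3), CNAEvent("8q", 3)]),
            ]
        else:
            clones = [
                SubcloneSim("A", (1 - f) * 0.55, (1 - f_post) * 0.55, [base]),
                SubcloneSim(
                    "C", (1 - f) * 0.45, (1 - f_post) * 0.45, [base, CNAEvent("11q", 3)]
                ),
                SubcloneSim("B", f, f_post, [base, CNAEvent("1q", 3)]),
            ]
        patients.append(
            PatientSim(
                patient_id=pid,
                n_tumor_pre=n_tumor,
                n_tumor_post=n_tumor,
                n_reference=n_reference,
                n_bme_pre=n_bme,
                n_bme_post=n_bme,
                subclones=clones,
                bme_fractions=dict(_SHIFTED_BME_FRACTIONS) if f >= 0.1 else None,
            )
        )
    return SimConfig(
        seed=seed,
        patients=patients,
        bme_types=_default_bme_types(),
        lr_truth=_default_lr_truth(),
    )


def three_clone_config(seed: int = 0, n_tumor: int = 2000) -> SimConfig:
    """One patient, three subclones at fractions 0.5/0.3/0.2 separated by
    arm-level events at dosage 1.5 (plus one arm loss at dosage 0.5)."""
    clones = [
        SubcloneSim("A", 0.5, 0.5, []),
        SubcloneSim("B", 0.3, 0.3, [CNAEvent("3q", 3), CNAEvent("13q", 1)]),
        SubcloneSim("C", 0.2, 0.2, [CNAEvent("11q", 3)]),
    ]
    return SimConfig(
        seed=seed,
        junk_cell_frac=0.0,
        doublet_frac=0.0,
        patients=[
            PatientSim("SIM", n_tumor, 0, 300, 0, 0, subclones=clones)
        ],
    )


def minor_clone_config(seed: int = 0, n_tumor: int = 2000) -> SimConfig:
    """Two major clones plus a 30-cell 1q-gained clone (below the 40-cell
    subclone floor, so it must be absorbed into its nearest neighbour)."""
    clones = [
        SubcloneSim("A", 0.6, 0.6, []),
        SubcloneSim("B", 0.385, 0.385, [CNAEvent("5q", 3)]),
        SubcloneSim("M", 0.015, 0.015, [CNAEvent("1q", 3)]),
    ]
    return SimConfig(
        seed=seed,
        junk_cell_frac=0.0,
        doublet_frac=0.0,
        patients=[
            PatientSim("SIM", n_tumor, 0, 300, 0, 0, subclones=clones)
        ],
    )


def signature_cohort_config(
    seed: int = 0, n_patients: int = 10, n_tumor: int = 700
) -> SimConfig:
    """Cohort for signature recovery: every patient carries a subclonal
    1q-gain clone (dosage 1.5) next to its 1q-neutral relative; chromosome 1
    holds 200 genes so the q arm carries 100 dosage-responsive genes."""
    patients = []
    for i in range(n_patients):
        pid = f"S{i + 1:02d}"
        base = _BASE_EVENTS[i % len(_BASE_EVENTS)]
        clones = [
            SubcloneSim("A", 0.55, 0.55, [base]),
            SubcloneSim("B", 0.45, 0.45, [base, CNAEvent("1q", 3)]),
        ]
        patients.append(
            PatientSim(pid, n_tumor, 0, 150, 0, 0, subclones=clones)
        )
    return SimConfig(
        seed=seed,
        n_chr1_genes=200,
        junk_cell_frac=0.0,
        doublet_frac=0.0,
        patients=patients,
    )


# ---------------------------------------------------------------------------
# Config (de)serialization and fixtures on disk
# ---------------------------------------------------------------------------

def save_config(cfg: SimConfig, path: str | Path) -> Path:
    path = Path(path)
    payload = dataclasses.asdict(cfg)
    path.write_text(yaml.safe_dump(payload, sort_keys=True))
    return path


def load_config(path: str | Path) -> SimConfig:
    payload = yaml.safe_load(Path(path).read_text())
    payload["patients"] = [
        PatientSim(
            **{
                **p,
                "subclones": [
                    SubcloneSim(
                        **{**s, "events": [CNAEvent(**e) for e in s["events"]]}
                    )
                    for s in p["subclones"]
                ],
            }
        )
        for p in payload.get("patients", [])
    ]
    payload["bme_types"] = [BMEType(**t) for t in payload.get("bme_types", [])]
    payload["lr_truth"] = [LRTruth(**t) for t in payload.get("lr_truth", [])]
    if payload.get("dosage_attenuation") is not None:
        payload["dosage_attenuation"] = tuple(payload["dosage_attenuation"])
    return SimConfig(**payload)


def write_dataset(ds: SimulatedDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write a simulated cohort in the exact formats the reader consumes."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = io_core.write_counts(ds.adata, out)
    meta = ds.adata.obs.copy()
    meta.to_csv(out / "cell_meta.tsv", sep="\t")
    paths["cell_meta"] = out / "cell_meta.tsv"
    paths["gene_order"] = io_core.write_gene_order(ds.gene_order, out / "gene_order.tsv")
    paths["arm_boundaries"] = io_core.write_arm_boundaries(
        ds.arm_boundaries, out / "arm_boundaries.tsv"
    )
    ds.sample_truth.to_csv(out / "truth_samples.tsv", sep="\t", index=False)
    paths["truth_samples"] = out / "truth_samples.tsv"
    ds.clone_truth.to_csv(out / "truth_clones.tsv", sep="\t", index=False)
    paths["truth_clones"] = out / "truth_clones.tsv"
    ds.lr_truth.to_csv(out / "truth_lr.tsv", sep="\t", index=False)
    paths["truth_lr"] = out / "truth_lr.tsv"
    paths["config"] = save_config(ds.config, out / "config.yaml")
    return paths


def make_default_fixtures(out_dir: str | Path, seed: int = 0) -> dict[str, Path]:
    """Write the stock cohort to ``out_dir``; byte-stable for a fixed seed."""
    ds = simulate_cohort(default_cohort_config(seed=seed))
    return write_dataset(ds, out_dir)
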