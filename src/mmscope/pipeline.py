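"""End-to-end orchestration: QC, per-patient subclone inference, signature
derivation and scoring, interaction testing, and composition analysis.

The pipeline operates on a :class:`~mmscope.synthetic.SimulatedDataset`
(or any dataset assembled in the same shape) and produces plain-text
tables; a single seed deterministically fans out to every stochastic
stage, so identical seeds give identical outputs.
"""

from __future__ import annotations

import json
import logging
import math
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd

from . import cna, composition, interactions, io_core, signature
from .synthetic import SimulatedDataset

logger = logging.getLogger(__name__)

__all__ = ["PipelineResult", "run_pipeline", "write_pipeline_outputs", "stage_seed"]


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    return (seed * 1_000_003 + zlib.crc32(stage.encode())) % (2**31)


@dataclass
class PatientResult:
    patient_id: str
    subclones: cna.SubcloneSet
    fractions: pd.DataFrame  # timepoint x subclone
    one_q_fraction: dict[str, float]
    group: dict[str, str]
    stability: float | None = None
    matched_pair: tuple[str, str] | None = None  # (1q-gain clone, neutral relative)
    de: pd.DataFrame | None = None


@dataclass
class PipelineResult:
    norm: ad.AnnData
    patients: dict[str, PatientResult]
    signature_set: signature.SignatureGeneSet | None = None
    scores: pd.Series | None = None
    sample_table: pd.DataFrame | None = None  # per sample: mean score, 1q fraction
    score_fraction_r: float | None = None
    ppv: dict | None = None
    interaction_results: dict[str, interactions.InteractionResult] = field(default_factory=dict)
    interaction_counts: pd.DataFrame | None = None
    interaction_strengths: pd.DataFrame | None = None
    network: object = None
    composition_fractions: pd.DataFrame | None = None
    composition_comparison: pd.DataFrame | None = None
    params: dict = field(default_factory=dict)


def _per_patient(
    norm: ad.AnnData,
    order: pd.DataFrame,
    patient_id: str,
    min_cells: int,
    window: int,
    mean_cutoff: float,
) -> PatientResult:
    obs = norm.obs
    mask = (obs["patient_id"] == patient_id) & obs["cell_type"].isin(["Myeloma", "nPC"])
    sub_adata = norm[mask.to_numpy()]
    reference = list(sub_adata.obs_names[sub_adata.obs["cell_type"] == "nPC"])
    profiles = cna.infer_cna_profiles(
        sub_adata, order, reference, mean_cutoff=mean_cutoff, window=window
    )
    subclones = cna.call_subclones(profiles, min_cells=min_cells)

    timepoints = sub_adata.obs.loc[subclones.labels.index, "timepoint"]
    fractions = cna.clone_fractions(subclones.labels, timepoints)
    one_q, group = {}, {}
    states = subclones.arm_states["1q"] if "1q" in subclones.arm_states else None
    gained = set(states.index[states == "gain"]) if states is not None else set()
    for tp in fractions.index:
        lab_tp = subclones.labels[timepoints == tp]
        f = float(lab_tp.isin(gained).sum() / len(lab_tp)) if len(lab_tp) else 0.0
        one_q[tp] = f
        group[tp] = cna.classify_1q_group(f)
    stability = None
    if {"pre", "post"} <= set(fractions.index):
        stability = cna.clone_stability_score(
            fractions.loc["pre"].to_dict(), fractions.loc["post"].to_dict()
        )
    logger.info(
        "patient %s: %d cells, %d subclones, 1q fraction %s",
        patient_id, len(subclones.labels), len(subclones.subclone_ids), one_q,
    )
    return PatientResult(
        patient_id=patient_id,
        subclones=subclones,
        fractions=fractions,
        one_q_fraction=one_q,
        group=group,
        stability=stability,
    )


def run_pipeline(
    ds: SimulatedDataset,
    seed: int = 0,
    *,
    min_cells: int = 40,
    window: int = 101,
    mean_cutoff: float = 0.1,
    min_recurrence: int | None = None,
    score_threshold: float = 0.2,
    n_perm: int = 1000,
    interaction_min_cells: int = 20,
    run_interactions: bool = True,
) -> PipelineResult:
    """Run the full analysis chain on one cohort.

    ``min_recurrence`` defaults to half the number of patients that
    contribute a matched-clone comparison (rounded up).
    """
    qc = io_core.qc_filter(ds.adata)
    norm = io_core.normalize_log(qc)
    order = ds.gene_order

    patients = {}
    for pid in pd.unique(norm.obs["patient_id"]):
        if (norm.obs.loc[norm.obs["patient_id"] == pid, "cell_type"] == "Myeloma").sum() == 0:
            continue
        patients[pid] = _per_patient(norm, order, pid, min_cells, window, mean_cutoff)

    # matched-clone differential expression in patients where the 1q gain is
    # subclonal (a gained clone and a 1q-neutral relative coexist)
    de_tables: dict[str, pd.DataFrame] = {}
    for pid, pres in patients.items():
        states = pres.subclones.arm_states.get("1q")
        if states is None:
            continue
        gained = [s for s in states.index if states[s] == "gain"]
        neutral = [s for s in states.index if states[s] != "gain"]
        if not gained or not neutral:
            continue
        target = max(gained, key=lambda s: pres.subclones.sizes[s])
        try:
            partner = cna.match_closest_clone(pres.subclones, target, exclude_arm="1q")
        except ValueError:
            continue
        cells_a = list(pres.subclones.labels.index[pres.subclones.labels == target])
        cells_b = list(pres.subclones.labels.index[pres.subclones.labels == partner])
        if len(cells_a) < 3 or len(cells_b) < 3:
            continue
        pres.matched_pair = (target, partner)
        pres.de = signature.differential_expression(norm, cells_a, cells_b)
        de_tables[pid] = pres.de

    sig_set = None
    if de_tables:
        if min_recurrence is None:
            min_recurrence = max(1, math.ceil(len(de_tables) / 2))
        sig_set = signature.derive_signature(de_tables, min_recurrence, order, arm="1q")
        logger.info(
            "signature: %d genes from %d contributing patients", len(sig_set), len(de_tables)
        )

    result = PipelineResult(norm=norm, patients=patients, signature_set=sig_set)
    result.params = {
        "seed": seed,
        "min_cells": min_cells,
        "window": window,
        "mean_cutoff": mean_cutoff,
        "min_recurrence": min_recurrence,
        "score_threshold": score_threshold,
        "n_perm": n_perm,
    }

    tumor_mask = (norm.obs["cell_type"] == "Myeloma").to_numpy()
    if sig_set is not None and len(sig_set) and tumor_mask.any():
        tumor = norm[tumor_mask]
        msv = signature.score_signature(
            tumor, sig_set, seed=stage_seed(seed, "score")
        )
        result.scores = msv.scores

        sample_of_cell = (
            tumor.obs["patient_id"].astype(str) + "_" + tumor.obs["timepoint"].astype(str)
        )
        rows = []
        truth_flags = pd.Series(False, index=tumor.obs_names)
        for pid, pres in patients.items():
            states = pres.subclones.arm_states.get("1q")
            gained = set(states.index[states == "gain"]) if states is not None else set()
            in_gain = pres.subclones.labels.isin(gained)
            truth_flags.loc[in_gain.index.intersection(truth_flags.index)] = in_gain[
                in_gain.index.intersection(truth_flags.index)
            ]
            for tp, f in pres.one_q_fraction.items():
                rows.append(
                    {
                        "sample": f"{pid}_{tp}",
                        "patient_id": pid,
                        "timepoint": tp,
                        "cna_1q_fraction": f,
                        "group": pres.group[tp],
                    }
                )
        sample_table = pd.DataFrame(rows).set_index("sample")
        sample_table["mean_score"] = msv.scores.groupby(sample_of_cell).mean()
        result.sample_table = sample_table
        if len(sample_table) >= 3 and sample_table["cna_1q_fraction"].std() > 0:
            result.score_fraction_r = signature.score_fraction_correlation(
                sample_table["mean_score"], sample_table["cna_1q_fraction"]
            )
        result.ppv = signature.evaluate_ppv(msv, truth_flags, score_threshold)

    bme_mask = (norm.obs["fraction"] == "CD138neg").to_numpy()
    if run_interactions and bme_mask.any():
        pairs = interactions.load_default_pairs()
        inter_mask = bme_mask | tumor_mask
        inter = norm[inter_mask]
        sample_ids = (
            inter.obs["patient_id"].astype(str) + "_" + inter.obs["timepoint"].astype(str)
        )
        for sample in sorted(sample_ids.unique()):
            cells = sample_ids == sample
            try:
                res = interactions.test_interactions(
                    inter[cells.to_numpy()],
                    inter.obs.loc[cells, "cell_type"],
                    pairs,
                    n_perm=n_perm,
                    min_cells=interaction_min_cells,
                    seed=stage_seed(seed, f"interactions:{sample}"),
                )
            except ValueError as exc:
                logger.info("sample %s skipped for interactions: %s", sample, exc)
                continue
            result.interaction_results[sample] = res
        if result.interaction_results:
            result.interaction_counts = interactions.count_interactions(
                result.interaction_results
            )
            result.interaction_strengths = interactions.interaction_strength(
                result.interaction_results
            )
            result.network = interactions.build_network(result.interaction_strengths, k=4)

        bme = norm[bme_mask]
        bme_samples = (
            bme.obs["patient_id"].astype(str) + "_" + bme.obs["timepoint"].astype(str)
        )
        result.composition_fractions = composition.compute_fractions(
            bme.obs["cell_type"], bme_samples
        )
        if patients:
            group_of_sample = {
                f"{pid}_{tp}": g
                for pid, p in patients.items()
                for tp, g in p.group.items()
            }
            frac = result.composition_fractions
            a = [s for s in frac.index if group_of_sample.get(s) == "ND_rare"]
            b = [s for s in frac.index if group_of_sample.get(s) in ("subclonal", "dominant")]
            if len(a) >= 3 and len(b) >= 3:
                result.composition_comparison = composition.compare_fractions(frac, a, b)

    return result


def write_pipeline_outputs(result: PipelineResult, out_dir: str | Path) -> dict[str, Path]:
    """Write every stage's tables as TSV/JSON; deterministic bytes for a
    fixed input and seed."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    fmt = "%.6g"

    def save(df: pd.DataFrame, name: str, **kw) -> None:
        p = out / name
        df.to_csv(p, sep="\t", float_format=fmt, **kw)
        paths[name] = p

    labels = []
    states_rows = []
    frac_rows = []
    stab_rows = []
    for pid in sorted(result.patients):
        pres = result.patients[pid]
        lab = pres.subclones.labels.to_frame()
        lab.insert(0, "patient_id", pid)
        labels.append(lab)
        st = pres.subclones.arm_states.copy()
        st.insert(0, "patient_id", pid)
        states_rows.append(st)
        fr = pres.fractions.copy()
        fr.insert(0, "patient_id", pid)
        frac_rows.append(fr.reset_index(names="timepoint"))
        stab_rows.append(
            {
                "patient_id": pid,
                "stability": pres.stability,
                **{f"cna_1q_fraction_{tp}": f for tp, f in pres.one_q_fraction.items()},
                **{f"group_{tp}": g for tp, g in pres.group.items()},
            }
        )
    if labels:
        save(pd.concat(labels), "subclones.tsv", index_label="cell_id")
        save(pd.concat(states_rows), "arm_states.tsv", index_label="subclone")
        save(pd.concat(frac_rows, ignore_index=True), "clone_fractions.tsv", index=False)
        save(pd.DataFrame(stab_rows), "clone_stability.tsv", index=False)

    if result.signature_set is not None:
        sig_df = pd.DataFrame(
            {
                "gene": result.signature_set.genes,
                "recurrence": [
                    result.signature_set.recurrence[g] for g in result.signature_set.genes
                ],
            }
        )
        save(sig_df, "signature_genes.tsv", index=False)
    for pid in sorted(result.patients):
        de = result.patients[pid].de
        if de is not None:
            save(de.sort_index(), f"de_{pid}.tsv", index_label="gene")
    if result.scores is not None:
        save(result.scores.to_frame(), "cell_scores.tsv", index_label="cell_id")
    if result.sample_table is not None:
        save(result.sample_table.sort_index(), "sample_scores.tsv")
    if result.interaction_results:
        all_tables = [
            r.table.assign(sample=s)
            for s, r in sorted(result.interaction_results.items())
        ]
        save(pd.concat(all_tables, ignore_index=True), "interactions.tsv", index=False)
        save(result.interaction_counts, "interaction_counts.tsv")
        save(result.interaction_strengths, "interaction_strengths.tsv")
        net = interactions.network_to_json(result.network)
        p = out / "network.json"
        p.write_text(json.dumps(net, indent=2, sort_keys=True))
        paths["network.json"] = p
    if result.composition_fractions is not None:
        save(result.composition_fractions.sort_index(), "composition_fractions.tsv")
    if result.composition_comparison is not None:
        save(result.composition_comparison, "composition_comparison.tsv")

    summary = {
        "score_fraction_pearson_r": result.score_fraction_r,
        "ppv": result.ppv,
        "n_patients": len(result.patients),
        "signature_size": len(result.signature_set) if result.signature_set else 0,
        "params": result.params,
    }
    p = out / "summary.json"
    p.write_text(json.dumps(summary, indent=2, sort_keys=True))
    paths["summary.json"] = p
    return paths
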