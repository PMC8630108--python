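"""Shared fixtures: simulated cohorts and pipeline runs, built once per session."""

from __future__ import annotations

from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from mmscope import cna, io_core, pipeline, synthetic


def make_adata(x, cell_ids=None, gene_ids=None, obs=None, var=None) -> ad.AnnData:
    x = np.asarray(x)
    cell_ids = cell_ids or [f"cell{i}" for i in range(x.shape[0])]
    gene_ids = gene_ids or [f"gene{i}" for i in range(x.shape[1])]
    adata = ad.AnnData(
        X=sp.csr_matrix(x),
        obs=pd.DataFrame(obs or {}, index=pd.Index(cell_ids, name="cell_id")),
        var=pd.DataFrame(var or {}, index=pd.Index(gene_ids, name="gene_id")),
    )
    return adata


@dataclass
class CloneFixture:
    ds: synthetic.SimulatedDataset
    profiles: cna.CNAProfileMatrix
    subclones: cna.SubcloneSet
    truth: pd.Series  # per-tumor-cell planted subclone


def _clone_fixture(cfg) -> CloneFixture:
    ds = synthetic.simulate_cohort(cfg)
    norm = io_core.normalize_log(io_core.qc_filter(ds.adata))
    ref = list(norm.obs_names[norm.obs["cell_type"] == "nPC"])
    profiles = cna.infer_cna_profiles(norm, ds.gene_order, ref)
    subclones = cna.call_subclones(profiles)
    truth = ds.adata.obs.loc[profiles.tumor_ids, "subclone"]
    return CloneFixture(ds=ds, profiles=profiles, subclones=subclones, truth=truth)


@pytest.fixture(scope="session")
def three_clone():
    """2,000 tumor cells, three planted clones (0.5/0.3/0.2) with arm-level
    dosage 1.5 gains and one dosage-0.5 loss."""
    return _clone_fixture(synthetic.three_clone_config(seed=1))


@pytest.fixture(scope="session")
def minor_clone():
    """Two major clones plus a planted 30-cell 1q-gained clone."""
    return _clone_fixture(synthetic.minor_clone_config(seed=1))


@dataclass
class CohortFixture:
    ds: synthetic.SimulatedDataset
    result: pipeline.PipelineResult


@pytest.fixture(scope="session")
def default_cohort():
    """Stock 10-patient pre/post cohort run through the full pipeline."""
    ds = synthetic.simulate_cohort(synthetic.default_cohort_config(seed=11))
    result = pipeline.run_pipeline(ds, seed=11, n_perm=200)
    return CohortFixture(ds=ds, result=result)


@pytest.fixture(scope="session")
def signature_cohort():
    """Ten patients, each with a subclonal 1q-gain clone; chromosome 1q
    carries 100 dosage-responsive genes."""
    ds = synthetic.simulate_cohort(synthetic.signature_cohort_config(seed=5))
    result = pipeline.run_pipeline(ds, seed=5, min_recurrence=5, run_interactions=False)
    return CohortFixture(ds=ds, result=result)
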