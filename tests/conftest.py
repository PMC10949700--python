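"""Shared fixtures: small simulated experiments and pipeline runs."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from slam_mzt import synthdata as sd
from slam_mzt.mzt import PipelineConfig
from slam_mzt.pipeline import RunConfig, run_pipeline


def make_single_gene(
    gene_id="g1",
    utr=None,
    length=200,
    t_fraction=0.3,
    seed=0,
    **kw,
) -> sd.GeneSpec:
    if utr is None:
        utr = sd.make_utr_sequence(length, t_fraction, (), seed)
    return sd.GeneSpec(gene_id=gene_id, utr_sequence=utr, **kw)


@pytest.fixture(scope="session")
def recovery_run(tmp_path_factory):
    """Class-recovery study: 100 genes per truth class, 6 hourly timepoints,
    3 replicates, plus transcription-off and non-injected controls for the
    SNP mask.  Shared by the classification and activation recovery checks."""
    rundir = tmp_path_factory.mktemp("recovery")
    cfg = RunConfig(
        n_pm=100,
        n_mz=100,
        n_pz=100,
        frac_masked_decay=0.0,
        library_size=20_000,
        timepoints_h=(2, 3, 4, 5, 6, 7),
        replicates=3,
        include_lna=False,
        thresholds=PipelineConfig(maternal_window_h=(2, 3), zygotic_window_h=(4, 5, 6, 7)),
    )
    manifest = run_pipeline(cfg, seed=20260929, outdir=rundir)
    return rundir, cfg, manifest


@pytest.fixture(scope="session")
def tiny_run(tmp_path_factory):
    """A fast full pipeline run used by I/O, determinism and CLI checks."""
    rundir = tmp_path_factory.mktemp("tiny")
    cfg = RunConfig(n_pm=12, n_mz=16, n_pz=12, library_size=4000, replicates=2, lna_replicates=2)
    manifest = run_pipeline(cfg, seed=7, outdir=rundir)
    return rundir, cfg, manifest


@pytest.fixture()
def toy_tricounts():
    """Hand-built TriCounts: 3 genes + 2 spike-ins, 4 samples, 2 conditions."""
    from slam_mzt.quant import TriCounts

    samples = pd.DataFrame(
        {
            "condition": ["a", "a", "b", "b"],
            "timepoint_h": [2.0, 2.0, 7.0, 7.0],
            "replicate": [1, 2, 1, 2],
        },
        index=pd.Index(["s1", "s2", "s3", "s4"], name="sample_id"),
    )
    total = pd.DataFrame(
        {
            "s1": [100, 40, 0, 500, 500],
            "s2": [120, 35, 0, 500, 500],
            "s3": [80, 50, 0, 500, 500],
            "s4": [90, 45, 0, 500, 500],
        },
        index=["g1", "g2", "g3", "ERCC-00001", "ERCC-00002"],
    )
    labeled = pd.DataFrame(
        {
            "s1": [10, 0, 0, 0, 0],
            "s2": [12, 0, 0, 0, 0],
            "s3": [40, 5, 0, 0, 0],
            "s4": [45, 4, 0, 0, 0],
        },
        index=total.index,
    )
    return TriCounts(total, labeled, samples)
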