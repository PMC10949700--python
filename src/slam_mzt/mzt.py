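"""Zygotic component scoring and maternal-to-zygotic gene classification.

The zygotic component score (ZCS) of a gene is the ratio of labeled to total
CPM, i.e. the fraction of its mRNA pool that is zygotically made.  Genes are
called *transcribed* when any zygotic-window timepoint (4-7 h) shows mean
ZCS > 5% or mean labeled CPM > 1; apparent labeling before 4 h is treated as
false positive (it tracks T>C polymorphism rather than metabolic labeling).
Classes:

* maternal_zygotic -- transcribed and expressed during the maternal window (1-3 h)
* pure_zygotic     -- transcribed but not expressed during 1-3 h
* pure_maternal    -- expressed somewhere but never transcribed
* not_detected     -- never expressed

Transcriptional activation is dated as the earliest timepoint with
> 1 labeled CPM in at least two replicates; post-activation labeled-CPM
trajectories are labelled up/down/flat from consecutive-timepoint
differential tests (|log2FC| >= log2(1.5), BH-adjusted p <= 0.2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CLASS_PM = "pure_maternal"
CLASS_MZ = "maternal_zygotic"
CLASS_PZ = "pure_zygotic"
CLASS_ND = "not_detected"

TRUTH_TO_CLASS = {"PM": CLASS_PM, "MZ": CLASS_MZ, "PZ": CLASS_PZ}


@dataclass
class PipelineConfig:
    """Every threshold the downstream classification and stats stages use."""

    expressed_cpm_threshold: float = 5.0
    zcs_transcribed_threshold: float = 0.05
    labeled_cpm_transcribed_threshold: float = 1.0
    activation_min_replicates: int = 2
    maternal_window_h: tuple = (1, 2, 3)
    zygotic_window_h: tuple = (4, 5, 6, 7)
    trajectory_log2fc_threshold: float = math.log2(1.5)
    trajectory_padj_threshold: float = 0.2
    masked_decay_total_fc_floor: float = -1.5  # log2 scale
    masked_decay_padj: float = 0.05
    conversion_fp_cutoff: float = 0.01
    snp_min_fraction: float = 0.15
    snp_min_coverage: int = 7
    min_conversions: int = 2
    lna_labeled_cpm_min: float = 2.0  # target filter for LNA shift tests
    excluded_samples: tuple = ()

    def __post_init__(self):
        if set(self.maternal_window_h) & set(self.zygotic_window_h):
            raise ValueError("maternal and zygotic windows must be disjoint")


def zcs(labeled_cpm, total_cpm, expressed_cpm_threshold: float = 5.0):
    """Zygotic component score: labeled/total CPM, clamped to [0, 1].

    Missing (NaN) when the total CPM is below the expression threshold --
    the score is meaningless for barely detected genes.  Accepts scalars or
    aligned arrays/Series.
    """
    labeled = np.asarray(labeled_cpm, dtype=float)
    total = np.asarray(total_cpm, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        score = np.clip(np.where(total > 0, labeled / np.where(total > 0, total, 1.0), 0.0), 0, 1)
    score = np.where(total < expressed_cpm_threshold, np.nan, score)
    if np.isscalar(labeled_cpm) and np.isscalar(total_cpm):
        return float(score)
    if isinstance(labeled_cpm, pd.Series):
        return pd.Series(score, index=labeled_cpm.index)
    if isinstance(labeled_cpm, pd.DataFrame):
        return pd.DataFrame(score, index=labeled_cpm.index, columns=labeled_cpm.columns)
    return score


def is_expressed(mean_total_cpm: float, threshold: float = 5.0) -> bool:
    """Expressed means strictly more than ``threshold`` mean CPM."""
    return bool(mean_total_cpm > threshold)


def is_transcribed(
    mean_zcs_by_tp: dict[float, float] | pd.Series,
    mean_labeled_cpm_by_tp: dict[float, float] | pd.Series,
    config: PipelineConfig = PipelineConfig(),
) -> bool:
    """Significant labeling at any zygotic-window timepoint.

    True iff mean ZCS > 5% *or* mean labeled CPM > 1 at some timepoint in
    the zygotic window (inclusive or, evaluated on replicate means).
    """
    zcs_map = dict(mean_zcs_by_tp) if not isinstance(mean_zcs_by_tp, dict) else mean_zcs_by_tp
    lab_map = (
        dict(mean_labeled_cpm_by_tp)
        if not isinstance(mean_labeled_cpm_by_tp, dict)
        else mean_labeled_cpm_by_tp
    )
    for t in config.zygotic_window_h:
        z = zcs_map.get(t, np.nan)
        lab = lab_map.get(t, np.nan)
        if (not np.isnan(z) and z > config.zcs_transcribed_threshold) or (
            not np.isnan(lab) and lab > config.labeled_cpm_transcribed_threshold
        ):
            return True
    return False


def assign_class(
    expressed_maternal_window: bool,
    expressed_anywhere: bool,
    transcribed: bool,
) -> str:
    """Combine expression and transcription flags into an MZT class."""
    if transcribed:
        return CLASS_MZ if expressed_maternal_window else CLASS_PZ
    if expressed_anywhere:
        return CLASS_PM
    return CLASS_ND


def activation_time(
    labeled_cpm_by_tp: dict[float, list[float]],
    config: PipelineConfig = PipelineConfig(),
) -> float | None:
    """Earliest timepoint with >1 labeled CPM in >= 2 replicates, else None.

    Timepoints with fewer than ``activation_min_replicates`` replicates are
    ineligible.
    """
    for t in sorted(labeled_cpm_by_tp):
        reps = labeled_cpm_by_tp[t]
        if len(reps) < config.activation_min_replicates:
            continue
        n_over = sum(1 for v in reps if v > config.labeled_cpm_transcribed_threshold)
        if n_over >= config.activation_min_replicates:
            return float(t)
    return None


def trajectory_label(log2fc: float, padj: float, config: PipelineConfig = PipelineConfig()) -> str:
    """up / down / flat for one consecutive-timepoint interval."""
    if padj <= config.trajectory_padj_threshold:
        if log2fc >= config.trajectory_log2fc_threshold:
            return "up"
        if log2fc <= -config.trajectory_log2fc_threshold:
            return "down"
    return "flat"


def trajectory(
    de_by_interval: pd.DataFrame,
    config: PipelineConfig = PipelineConfig(),
) -> pd.DataFrame:
    """Label every gene x interval from consecutive-timepoint DE results.

    ``de_by_interval`` needs columns gene_id, interval (e.g. ``"4h-5h"``),
    log2fc, padj.
    """
    lab = de_by_interval.apply(
        lambda r: trajectory_label(r["log2fc"], r["padj"], config), axis=1
    )
    out = de_by_interval[["gene_id", "interval"]].copy()
    out["label"] = lab
    return out


# ---------------------------------------------------------------------------
# cohort-level classification from CPM matrices
# ---------------------------------------------------------------------------

@dataclass
class GeneClassification:
    gene_id: str
    biotype: str
    mzt_class: str
    activation_hour: float | None
    mean_zcs_by_tp: dict = field(default_factory=dict)
    trajectory: str = ""


def _tp_means(values: pd.DataFrame, samples: pd.DataFrame, condition: str) -> pd.DataFrame:
    """Gene x timepoint replicate means for one condition's samples."""
    ids = samples.index[samples["condition"] == condition]
    ids = [s for s in ids if s in values.columns]
    sub = values[ids]
    tps = samples.loc[ids, "timepoint_h"]
    return sub.T.groupby(tps.values).mean().T


def classify_genes(
    cpm_total: pd.DataFrame,
    cpm_labeled: pd.DataFrame,
    samples: pd.DataFrame,
    config: PipelineConfig = PipelineConfig(),
    condition: str = "timecourse",
    biotypes: pd.Series | None = None,
) -> pd.DataFrame:
    """Classify every gene from time-course CPM matrices.

    Returns a DataFrame indexed by gene_id with mzt_class, activation_hour,
    and the per-timepoint mean ZCS trail used for the call.
    """
    mean_total = _tp_means(cpm_total, samples, condition)
    mean_labeled = _tp_means(cpm_labeled, samples, condition)
    zcs_mat = zcs(mean_labeled, mean_total, config.expressed_cpm_threshold)

    # per-replicate labeled CPM grouped by timepoint, for activation dating
    ids = [
        s
        for s in samples.index[samples["condition"] == condition]
        if s in cpm_labeled.columns
    ]
    tp_of = samples.loc[ids, "timepoint_h"]

    records = []
    for gene_id in cpm_total.index:
        tm = mean_total.loc[gene_id]
        expressed_any = bool((tm > config.expressed_cpm_threshold).any())
        expressed_mat = bool(
            (tm.reindex(list(config.maternal_window_h)).dropna() > config.expressed_cpm_threshold).any()
        )
        transcribed = is_transcribed(
            zcs_mat.loc[gene_id].to_dict(), mean_labeled.loc[gene_id].to_dict(), config
        )
        cls = assign_class(expressed_mat, expressed_any, transcribed)
        act = None
        if cls in (CLASS_MZ, CLASS_PZ):
            by_tp = {
                t: list(cpm_labeled.loc[gene_id, tp_of.index[tp_of == t]])
                for t in sorted(tp_of.unique())
            }
            act = activation_time(by_tp, config)
        rec = {
            "gene_id": gene_id,
            "biotype": biotypes.get(gene_id, "coding") if biotypes is not None else "coding",
            "mzt_class": cls,
            "activation_hour": act,
        }
        for t in mean_total.columns:
            rec[f"zcs_{t}h"] = zcs_mat.loc[gene_id, t]
        records.append(rec)
    return pd.DataFrame(records).set_index("gene_id")
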