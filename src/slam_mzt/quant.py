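"""Expression filtering, ERCC spike-in scaling, and CPM normalisation.

Spike-ins are added to every library at equal molarity, so between-sample
differences in their totals measure relative capture efficiency.  Scaling
factors are computed on the spike-in/library ratio scale (geometric-mean
anchored, median re-centred to 1) and fold into an effective library size;
counts-per-million for the total, labeled, and unlabeled fractions all use
the *total* fraction's effective sizes, so labeled + unlabeled CPM equals
total CPM exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SPIKEIN_PREFIX = "ERCC-"


@dataclass
class TriCounts:
    """Gene x sample integer count matrices for total/labeled (+ derived unlabeled).

    ``total`` and ``labeled`` share index (features incl. spike-in rows) and
    columns (sample ids).  ``samples`` carries condition / timepoint_h /
    replicate metadata indexed by sample id.
    """

    total: pd.DataFrame
    labeled: pd.DataFrame
    samples: pd.DataFrame
    spikein: pd.Series | None = None  # boolean per feature row

    def __post_init__(self):
        if not self.total.index.equals(self.labeled.index) or not self.total.columns.equals(
            self.labeled.columns
        ):
            raise ValueError("total and labeled matrices must be aligned")
        if self.spikein is None:
            self.spikein = pd.Series(
                self.total.index.str.startswith(SPIKEIN_PREFIX), index=self.total.index
            )
        if (self.total.to_numpy() < 0).any() or (self.labeled.to_numpy() < 0).any():
            raise ValueError("negative counts")
        bad = (self.labeled > self.total).any(axis=1)
        if bad.any():
            raise ValueError(f"labeled > total for rows: {list(self.total.index[bad])[:5]}")
        missing = [s for s in self.total.columns if s not in self.samples.index]
        if missing:
            raise ValueError(f"samples missing metadata: {missing[:5]}")

    @property
    def unlabeled(self) -> pd.DataFrame:
        return self.total - self.labeled

    @property
    def gene_index(self) -> pd.Index:
        return self.total.index[~self.spikein]

    def subset_genes(self, keep: pd.Index) -> "TriCounts":
        rows = self.total.index.isin(keep) | self.spikein.to_numpy()
        return TriCounts(
            self.total.loc[rows], self.labeled.loc[rows], self.samples, self.spikein.loc[rows]
        )


@dataclass
class NormalizedMatrix:
    """CPM values for one fraction, with the scaling provenance attached."""

    fraction: str  # {total, labeled, unlabeled}
    values: pd.DataFrame  # gene x sample CPM
    effective_library_size: pd.Series
    scaling_factor: pd.Series
    factor_source: str = "total"


def counts_from_table(
    gene_counts: pd.DataFrame, spike_counts: pd.DataFrame | None, samples: pd.DataFrame
) -> TriCounts:
    """Assemble a TriCounts from a long count_gene table plus spike-in rows.

    ``gene_counts`` is the long-format output of ``conversion.count_gene``;
    ``spike_counts`` is a wide spike x sample matrix of total counts
    (spike-ins have no labeled reads of their own: their labeled counts are 0).
    """
    total = gene_counts.pivot_table(
        index="gene_id", columns="sample_id", values="total_reads", fill_value=0
    )
    labeled = gene_counts.pivot_table(
        index="gene_id", columns="sample_id", values="labeled_reads", fill_value=0
    )
    total.columns.name = None
    labeled.columns.name = None
    if spike_counts is not None:
        spike = spike_counts.reindex(columns=total.columns, fill_value=0)
        total = pd.concat([total, spike])
        labeled = pd.concat([labeled, spike * 0])
    order = [s for s in samples.index if s in total.columns]
    return TriCounts(total[order].astype(int), labeled[order].astype(int), samples)


def filter_genes(
    tri: TriCounts,
    min_reads: int = 10,
    min_samples: int = 2,
    min_condition_reads: int = 20,
) -> TriCounts:
    """Remove lowly expressed genes; spike-ins are never filtered.

    A gene is retained iff all three clauses hold:
      1. >= ``min_reads`` total reads in at least ``min_samples`` samples;
      2. >= ``min_condition_reads`` total reads summed within at least one
         condition;
      3. in that same condition, > 0 reads in at least half of its samples.

    A "condition" here is a replicate group: samples sharing condition label
    and timepoint.  (Grouping the whole time course as one condition would
    discard genuinely late-activating genes that are silent at early hours.)
    """
    lost = [s for s in tri.total.columns if s not in tri.samples.index]
    if lost:
        raise ValueError(f"samples without design metadata: {lost[:5]}")
    meta = tri.samples.loc[tri.total.columns]
    if "timepoint_h" in meta.columns:
        key = list(zip(meta["condition"], meta["timepoint_h"]))
    else:
        key = list(meta["condition"])
    counts_by_cond: dict = {}
    for sid, k in zip(meta.index, key):
        counts_by_cond.setdefault(k, []).append(sid)
    for c, ids in counts_by_cond.items():
        if len(ids) == 0:
            raise ValueError(f"condition {c!r} has no samples")

    genes = tri.total.loc[~tri.spikein]
    clause1 = (genes >= min_reads).sum(axis=1) >= min_samples

    clause23 = pd.Series(False, index=genes.index)
    for c, ids in counts_by_cond.items():
        sub = genes[[s for s in ids if s in genes.columns]]
        if sub.shape[1] == 0:
            continue
        cond_sum_ok = sub.sum(axis=1) >= min_condition_reads
        half_pos_ok = (sub > 0).sum(axis=1) * 2 >= sub.shape[1]
        clause23 |= cond_sum_ok & half_pos_ok

    keep = genes.index[clause1 & clause23]
    return tri.subset_genes(keep)


def spikein_scaling(tri: TriCounts) -> pd.DataFrame:
    """Per-sample spike-in scaling factors and effective library sizes.

    The factor is the sample's spike-in/gene-library ratio anchored to the
    cohort geometric mean and re-centred so the median factor is 1; the
    effective library size is raw gene library x factor.  Built this way the
    resulting CPMs are exactly invariant to jointly rescaling one sample's
    gene and spike-in counts.
    """
    spike_total = tri.total.loc[tri.spikein].sum(axis=0).astype(float)
    raw_lib = tri.total.loc[~tri.spikein].sum(axis=0).astype(float)
    bad = spike_total[spike_total <= 0]
    if len(bad):
        raise ValueError(f"zero spike-in counts in samples: {list(bad.index)}")
    if (raw_lib <= 0).any():
        raise ValueError("sample with zero gene counts")
    ratio = spike_total / raw_lib
    factor = ratio / np.exp(np.log(ratio).mean())
    factor = factor / factor.median()
    eff = raw_lib * factor
    return pd.DataFrame(
        {
            "raw_library_size": raw_lib,
            "spikein_total": spike_total,
            "scaling_factor": factor,
            "effective_library_size": eff,
        }
    )


def cpm(tri: TriCounts, factors: pd.DataFrame | None = None) -> dict[str, NormalizedMatrix]:
    """Counts-per-million for the total, labeled and unlabeled fractions.

    All three fractions are scaled by the *total* fraction's effective
    library sizes (derived from spike-ins), preserving
    CPM(labeled) + CPM(unlabeled) = CPM(total) per gene x sample.
    Spike-in rows are excluded from library-size sums but still receive CPM
    values.
    """
    if factors is None:
        factors = spikein_scaling(tri)
    eff = factors["effective_library_size"]
    if (eff <= 0).any():
        raise ValueError("non-positive effective library size")
    out = {}
    for fraction, mat in (
        ("total", tri.total),
        ("labeled", tri.labeled),
        ("unlabeled", tri.unlabeled),
    ):
        vals = mat.astype(float).div(eff, axis=1) * 1e6
        out[fraction] = NormalizedMatrix(
            fraction, vals, eff, factors["scaling_factor"], factor_source="total"
        )
    return out
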