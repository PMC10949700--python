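"""T>C conversion calling: SNP masking, labeled-read classification, counting.

A read is deemed *labeled* (evidence of zygotic origin) when it carries at
least two T>C conversions at positions not masked as SNPs.  SNP positions
are called from pooled control libraries (transcription-inhibited and
non-injected), where any conversion signal must be genomic rather than
metabolic: an offset is masked when its control coverage reaches
``min_coverage`` (default 7) and its conversion fraction reaches
``min_fraction`` (default 0.15).
"""

from __future__ import annotations

from collections.abc import Iterable
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synthdata import ReadRecord

DEFAULT_SNP_MIN_FRACTION = 0.15
DEFAULT_SNP_MIN_COVERAGE = 7
DEFAULT_MIN_CONVERSIONS = 2


@dataclass
class SnpMask:
    """Per-gene sets of UTR offsets flagged as T>C variants."""

    positions: dict[str, frozenset] = field(default_factory=dict)
    min_fraction: float = DEFAULT_SNP_MIN_FRACTION
    min_coverage: int = DEFAULT_SNP_MIN_COVERAGE

    def get(self, gene_id: str) -> frozenset:
        return self.positions.get(gene_id, frozenset())

    @classmethod
    def empty(cls) -> "SnpMask":
        return cls()

    @property
    def n_positions(self) -> int:
        return sum(len(v) for v in self.positions.values())


def _flatten_reads(reads) -> Iterable[ReadRecord]:
    if isinstance(reads, dict):
        for sample_reads in reads.values():
            yield from sample_reads
    else:
        yield from reads


def call_snps(
    control_reads,
    min_fraction: float = DEFAULT_SNP_MIN_FRACTION,
    min_coverage: int = DEFAULT_SNP_MIN_COVERAGE,
    allow_empty: bool = False,
) -> SnpMask:
    """Call T>C SNP offsets from pooled control reads.

    ``control_reads`` is either a flat iterable of :class:`ReadRecord` or a
    ``{sample_id: [reads]}`` dict; all control samples are pooled before
    thresholding, mirroring variant calling on a single merged alignment.
    An offset is flagged iff coverage >= ``min_coverage`` and
    converted/coverage >= ``min_fraction``.
    """
    cov_by_gene: dict[str, list] = {}
    conv_by_gene: dict[str, list] = {}
    n_reads = 0
    for read in _flatten_reads(control_reads):
        n_reads += 1
        cov_by_gene.setdefault(read.gene_id, []).extend(read.t_positions)
        conv_by_gene.setdefault(read.gene_id, []).extend(read.converted_positions)
    if n_reads == 0 and not allow_empty:
        raise ValueError(
            "no control reads supplied for SNP calling; pass allow_empty=True "
            "to run with an explicitly empty mask"
        )

    positions: dict[str, frozenset] = {}
    for gene_id, t_offs in cov_by_gene.items():
        cov = np.bincount(np.asarray(t_offs, dtype=np.int64))
        conv_offs = conv_by_gene.get(gene_id, [])
        conv = np.bincount(np.asarray(conv_offs, dtype=np.int64), minlength=len(cov))
        conv = conv[: len(cov)]
        with np.errstate(divide="ignore", invalid="ignore"):
            frac = np.where(cov > 0, conv / np.maximum(cov, 1), 0.0)
        flagged = np.nonzero((cov >= min_coverage) & (frac >= min_fraction))[0]
        if flagged.size:
            positions[gene_id] = frozenset(int(x) for x in flagged)
    return SnpMask(positions, min_fraction, min_coverage)


def classify_read(
    read: ReadRecord,
    mask: SnpMask,
    min_conversions: int = DEFAULT_MIN_CONVERSIONS,
) -> str:
    """Return ``"labeled"`` or ``"unlabeled"`` for a single read.

    Conversions at masked offsets are excluded before applying the
    at-least-``min_conversions`` rule.
    """
    masked = mask.get(read.gene_id)
    n = sum(1 for p in read.converted_positions if p not in masked)
    return "labeled" if n >= min_conversions else "unlabeled"


def count_gene(
    reads_by_sample: dict[str, list[ReadRecord]],
    mask: SnpMask | None = None,
    min_conversions: int = DEFAULT_MIN_CONVERSIONS,
    gene_ids: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Collapse classified reads into per-gene, per-sample count rows.

    Returns a DataFrame with columns gene_id, sample_id, total_reads,
    labeled_reads, unlabeled_reads, covered_T_bases, conversion_events.
    ``covered_T_bases`` / ``conversion_events`` count unmasked reference-T
    positions only, so a per-base conversion rate is their ratio.  Genes
    listed in ``gene_ids`` but absent from a sample get an all-zero row.
    """
    mask = mask or SnpMask.empty()
    rows = []
    universe = list(gene_ids) if gene_ids is not None else None
    for sample_id, reads in reads_by_sample.items():
        acc: dict[str, list] = {}
        if universe is not None:
            for g in universe:
                acc[g] = [0, 0, 0, 0]
        for read in reads:
            masked = mask.get(read.gene_id)
            n_conv = sum(1 for p in read.converted_positions if p not in masked)
            n_t = sum(1 for p in read.t_positions if p not in masked)
            a = acc.setdefault(read.gene_id, [0, 0, 0, 0])
            a[0] += 1
            a[1] += 1 if n_conv >= min_conversions else 0
            a[2] += n_t
            a[3] += min(n_conv, n_t)
        for gene_id, (tot, lab, cov_t, conv) in acc.items():
            rows.append(
                {
                    "gene_id": gene_id,
                    "sample_id": sample_id,
                    "total_reads": tot,
                    "labeled_reads": lab,
                    "unlabeled_reads": tot - lab,
                    "covered_T_bases": cov_t,
                    "conversion_events": conv,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "sample_id",
            "total_reads",
            "labeled_reads",
            "unlabeled_reads",
            "covered_T_bases",
            "conversion_events",
        ],
    )


def conversion_rate_per_base(counts: pd.DataFrame) -> pd.Series:
    """Mean T>C conversion rate normalised by covered (unmasked) 3'UTR T base.

    Input is a :func:`count_gene` table (optionally pre-filtered to one
    sample group).  Genes with zero covered T bases get NaN (undefined).
    """
    grp = counts.groupby("gene_id")[["conversion_events", "covered_T_bases"]].sum()
    rate = grp["conversion_events"] / grp["covered_T_bases"].where(grp["covered_T_bases"] > 0)
    rate.name = "conversion_rate"
    return rate


def count_false_positive_genes(
    rates: pd.Series, cutoff: float = 0.01
) -> int:
    """Number of genes whose per-base conversion rate exceeds the cutoff.

    Applied to control groups (non-injected, transcription-inhibited) this
    estimates false-positive labeling calls; 0.01 is the conventional
    screening cutoff.
    """
    return int((rates.dropna() > cutoff).sum())
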