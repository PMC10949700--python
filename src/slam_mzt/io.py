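"""File formats: count tables, read TSVs, FASTA/BED, gene lists, configs.

The count-table CSV dialect mirrors the published supplementary layout:
feature id, chromosome, start, end, strand, number of Ts within the
feature, then a block of total-count columns and a block of labeled-count
columns (one of each per sample).  ERCC-prefixed rows are spike-ins.
Coordinates are 0-based half-open everywhere on disk.
"""

from __future__ import annotations

import hashlib
import json
import re
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .quant import SPIKEIN_PREFIX, TriCounts
from .synthdata import ReadRecord

_COORD_COLS = ["feature_id", "chromosome", "start", "end", "strand", "n_T"]


def write_counts_table(
    tri: TriCounts, path, feature_meta: pd.DataFrame | None = None
) -> None:
    """Write a TriCounts in the supplementary-table CSV dialect."""
    idx = tri.total.index
    if feature_meta is not None:
        meta = feature_meta.reindex(idx)
        meta = meta.fillna({"chromosome": "chrS", "start": 0, "strand": "+"})
        if "end" in meta:
            meta["end"] = meta["end"].fillna(0)
    else:
        meta = pd.DataFrame(
            {"chromosome": "chrS", "start": 0, "end": 0, "strand": "+", "n_T": 0}, index=idx
        )
    out = pd.DataFrame({"feature_id": idx})
    for col in ("chromosome", "start", "end", "strand", "n_T"):
        out[col] = meta.get(col, pd.Series(0, index=idx)).to_numpy()
    for s in tri.total.columns:
        out[f"total_{s}"] = tri.total[s].to_numpy()
    for s in tri.total.columns:
        out[f"labeled_{s}"] = tri.labeled[s].to_numpy()
    out.to_csv(path, index=False)


_SAMPLE_RE = re.compile(r"^(?P<prefix>.+?)(?:_(?P<tp>[0-9.]+)h)?(?:_r(?P<rep>\d+))?$")
_CONDITION_ALIASES = {"tc": "timecourse", "noninj": "noninjected"}


def infer_sample_metadata(sample_ids) -> pd.DataFrame:
    """Best-effort parse of condition/timepoint/replicate from sample ids.

    Recognises ids like ``tc_4h_r2``, ``amanitin_6h_r1``, ``dose50_r1``,
    ``lna_mir430_6h_r3``; anything unparsed gets condition = the raw prefix.
    """
    rows = []
    for sid in sample_ids:
        m = _SAMPLE_RE.match(sid)
        prefix = m.group("prefix") if m else sid
        cond = _CONDITION_ALIASES.get(prefix, prefix)
        if cond.startswith("dose"):
            cond = "dose_series"
        rows.append(
            {
                "sample_id": sid,
                "condition": cond,
                "timepoint_h": float(m.group("tp")) if m and m.group("tp") else np.nan,
                "replicate": int(m.group("rep")) if m and m.group("rep") else 1,
            }
        )
    return pd.DataFrame(rows).set_index("sample_id")


def read_counts_table(path, samples: pd.DataFrame | None = None) -> TriCounts:
    """Read a supplementary-dialect counts CSV back into a TriCounts.

    Unlabeled counts are derived as total - labeled; any row where labeled
    exceeds total is a hard error naming the row.  ERCC-prefixed features
    are flagged as spike-ins.  Sample metadata is taken from ``samples`` or
    inferred from the column names.
    """
    df = pd.read_csv(path)
    missing = [c for c in _COORD_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"counts table missing columns: {missing}")
    total_cols = [c for c in df.columns if c.startswith("total_")]
    labeled_cols = [c for c in df.columns if c.startswith("labeled_")]
    if not total_cols or len(total_cols) != len(labeled_cols):
        raise ValueError("counts table needs matching total_/labeled_ column blocks")
    sample_ids = [c[len("total_") :] for c in total_cols]

    total = df.set_index("feature_id")[total_cols]
    total.columns = sample_ids
    labeled = df.set_index("feature_id")[labeled_cols]
    labeled.columns = sample_ids
    bad = (labeled.to_numpy() > total.to_numpy()).any(axis=1)
    if bad.any():
        rows = list(total.index[bad])[:5]
        raise ValueError(f"labeled > total in rows: {rows}")
    if samples is None:
        samples = infer_sample_metadata(sample_ids)
    else:
        keep = [s for s in samples.index if s in sample_ids]
        total, labeled = total[keep], labeled[keep]
    return TriCounts(total.astype(int), labeled.astype(int), samples)


def feature_meta_from_specs(gene_specs, spike_ids=()) -> pd.DataFrame:
    """Coordinate/T-content metadata block for the counts-table dialect."""
    rows = []
    offset = 0
    for spec in gene_specs:
        L = len(spec.utr_sequence)
        rows.append(
            {
                "feature_id": spec.gene_id,
                "chromosome": "chrS",
                "start": offset,
                "end": offset + L,
                "strand": "+",
                "n_T": spec.utr_sequence.count("T"),
            }
        )
        offset += L + 100
    for sid in spike_ids:
        rows.append(
            {"feature_id": sid, "chromosome": "spikein", "start": 0, "end": 0, "strand": "+", "n_T": 0}
        )
    return pd.DataFrame(rows).set_index("feature_id")


# -- mutation-annotated reads ------------------------------------------------

def write_reads_tsv(reads: list[ReadRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\twindow_start\twindow_end\tt_positions\tconverted_positions\ttruth_labeled\n")
        for r in reads:
            fh.write(
                f"{r.gene_id}\t{r.window_start}\t{r.window_end}\t"
                f"{','.join(map(str, r.t_positions))}\t"
                f"{','.join(map(str, r.converted_positions))}\t"
                f"{int(r.truth_labeled)}\n"
            )


def read_reads_tsv(path) -> list[ReadRecord]:
    reads = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("gene_id\t"):
            raise ValueError(f"{path}: not a reads TSV")
        for line in fh:
            gene_id, ws, we, tpos, cpos, lab = line.rstrip("\n").split("\t")
            reads.append(
                ReadRecord(
                    gene_id,
                    int(ws),
                    int(we),
                    tuple(int(x) for x in tpos.split(",") if x),
                    tuple(int(x) for x in cpos.split(",") if x),
                    bool(int(lab)),
                )
            )
    return reads


# -- sequences and coordinates ----------------------------------------------

def write_utr_fasta(gene_specs, path) -> None:
    records = [
        SeqRecord(Seq(s.utr_sequence), id=s.gene_id, description="") for s in gene_specs
    ]
    SeqIO.write(records, str(path), "fasta")


def read_utr_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_bed(intervals: pd.DataFrame, path) -> None:
    """Write a BED table (columns chrom, start, end, name[, score, strand])."""
    intervals.to_csv(path, sep="\t", header=False, index=False)


def write_sites_bed(sites_by_gene: dict[str, list], path) -> None:
    rows = []
    for gene_id, sites in sites_by_gene.items():
        for s in sites:
            rows.append((gene_id, s.start, s.end, s.site_type, 0, "+"))
    with open(path, "w") as fh:
        for row in rows:
            fh.write("\t".join(map(str, row)) + "\n")


# -- gene lists, configs, manifests -----------------------------------------

def read_gene_list(path) -> set[str]:
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()}


def write_gene_list(genes, path) -> None:
    with open(path, "w") as fh:
        for g in sorted(genes):
            fh.write(f"{g}\n")


def read_yaml(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def write_yaml(obj: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=True)


def file_digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(manifest: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)


def read_manifest(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
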