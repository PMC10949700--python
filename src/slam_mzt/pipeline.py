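"""End-to-end orchestration: simulate -> call -> normalise -> classify -> test.

Every stage reads and writes canonical filenames inside one run directory,
so the CLI subcommands and :func:`run_pipeline` compose to identical
outputs.  A JSON manifest records the config snapshot, seed, per-stage row
counts, timings, output digests, and warnings.
"""

from __future__ import annotations

import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import annot, conversion, io, mzt, quant, stats, synthdata

FILES = {
    "config": "config.yaml",
    "samples": "samples.csv",
    "genes": "genes.csv",
    "truth": "truth.csv",
    "utr_fasta": "utrs.fasta",
    "utr_bed": "utrs.bed",
    "spike_counts": "spike_counts.csv",
    "known_targets": "known_targets.txt",
    "snp_mask": "snp_mask.csv",
    "counts": "counts.csv",
    "factors": "factors.csv",
    "cpm_total": "cpm_total.csv",
    "cpm_labeled": "cpm_labeled.csv",
    "cpm_unlabeled": "cpm_unlabeled.csv",
    "sites_bed": "sites.bed",
    "site_counts": "site_counts.csv",
    "classification": "classification.csv",
    "de_total_7v2": "de_total_7v2.csv",
    "de_tvu_7h": "de_unlabeled_vs_total_7h.csv",
    "de_intervals": "de_intervals_labeled.csv",
    "de_lna": "de_lna430_vs_control.csv",
    "masked_decay": "masked_decay.csv",
    "lna_shift": "lna_shift.csv",
    "manifest": "manifest.json",
}


@dataclass
class RunConfig:
    """Study design + thresholds for one synthetic pipeline run."""

    cohort_kind: str = "standard"  # or "masked_decay": MZ-only masked/stable split
    n_pm: int = 40
    n_mz: int = 60
    n_pz: int = 40
    frac_targets: float = 0.3
    frac_masked_decay: float = 0.2
    utr_length: int = 400
    t_fraction: float = 0.3
    snp_prob: float = 0.02
    library_size: int = 20_000
    timepoints_h: tuple = (1, 2, 3, 4, 5, 6, 7)
    replicates: int = 3
    include_timecourse: bool = True
    include_controls: bool = True
    include_dose_series: bool = False
    include_lna: bool = True
    lna_replicates: int = 3
    use_snp_mask: bool = True
    known_target_fraction: float = 0.6
    read_length: int = synthdata.DEFAULT_READ_LENGTH
    thresholds: mzt.PipelineConfig = field(default_factory=mzt.PipelineConfig)

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        thr = d.pop("thresholds", {})
        if isinstance(thr, dict):
            for k in ("maternal_window_h", "zygotic_window_h", "excluded_samples"):
                if k in thr and isinstance(thr[k], list):
                    thr[k] = tuple(thr[k])
            thr = mzt.PipelineConfig(**thr)
        for k in ("timepoints_h",):
            if k in d and isinstance(d[k], list):
                d[k] = tuple(d[k])
        return cls(thresholds=thr, **d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(io.read_yaml(path))

    def to_yaml(self, path) -> None:
        io.write_yaml(self.to_dict(), path)


def build_designs(cfg: RunConfig) -> list[synthdata.SampleDesign]:
    designs: list[synthdata.SampleDesign] = []
    if cfg.include_timecourse:
        designs += synthdata.make_timecourse_designs(
            cfg.timepoints_h, cfg.replicates, cfg.library_size
        )
    if cfg.include_controls:
        designs += synthdata.make_control_designs(library_size=cfg.library_size)
    if cfg.include_dose_series:
        designs += synthdata.make_dose_series_designs(library_size=cfg.library_size)
    if cfg.include_lna:
        designs += synthdata.make_lna_designs(
            replicates=cfg.lna_replicates, library_size=cfg.library_size
        )
    if not designs:
        raise ValueError("config enables no sample blocks")
    return designs


def _samples_frame(designs) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample_id": d.sample_id,
                "condition": d.condition,
                "timepoint_h": d.timepoint_h,
                "replicate": d.replicate,
                "library_size": d.library_size,
                "s4utp_dose_mM": d.s4utp_dose_mM,
            }
            for d in designs
        ]
    ).set_index("sample_id")


def _read_samples(rundir: Path) -> pd.DataFrame:
    return pd.read_csv(rundir / FILES["samples"], index_col="sample_id")


def _read_all_reads(rundir: Path, sample_ids) -> dict[str, list]:
    return {sid: io.read_reads_tsv(rundir / "reads" / f"{sid}.tsv") for sid in sample_ids}


def stage_simulate(cfg: RunConfig, seed: int, rundir: Path) -> dict:
    """Generate the cohort, designs, reads, spike-ins, truth, and sequences."""
    rundir.mkdir(parents=True, exist_ok=True)
    (rundir / "reads").mkdir(exist_ok=True)
    if cfg.cohort_kind == "masked_decay":
        specs = synthdata.make_masked_decay_cohort(
            cfg.n_mz - cfg.n_mz // 2,
            cfg.n_mz // 2,
            seed=seed,
            utr_length=cfg.utr_length,
            t_fraction=cfg.t_fraction,
            frac_targets=cfg.frac_targets,
        )
    else:
        specs = synthdata.make_gene_cohort(
            cfg.n_pm,
            cfg.n_mz,
            cfg.n_pz,
            seed=seed,
            utr_length=cfg.utr_length,
            t_fraction=cfg.t_fraction,
            frac_targets=cfg.frac_targets,
            frac_masked_decay=cfg.frac_masked_decay,
            snp_prob=cfg.snp_prob,
        )
    designs = build_designs(cfg)
    reads, truth = synthdata.simulate_experiment(
        specs, designs, seed=seed, read_length=cfg.read_length
    )
    spikes = synthdata.emit_spikeins(designs, seed=seed)

    cfg.to_yaml(rundir / FILES["config"])
    _samples_frame(designs).to_csv(rundir / FILES["samples"])
    genes = pd.DataFrame(
        [
            {
                "gene_id": s.gene_id,
                "biotype": s.biotype,
                "mzt_class_truth": s.mzt_class_truth,
                "is_mir430_target": s.is_mir430_target,
                "zygotic_onset_h": s.zygotic_onset_h,
                "utr_length": len(s.utr_sequence),
                "n_snps": len(s.snp_positions),
            }
            for s in specs
        ]
    ).set_index("gene_id")
    genes.to_csv(rundir / FILES["genes"])
    truth.to_csv(rundir / FILES["truth"], index=False)
    io.write_utr_fasta(specs, rundir / FILES["utr_fasta"])
    meta = io.feature_meta_from_specs(specs)
    bed = meta.reset_index()[["chromosome", "start", "end", "feature_id"]]
    io.write_bed(bed, rundir / FILES["utr_bed"])
    spikes.to_csv(rundir / FILES["spike_counts"])
    for sid, rs in reads.items():
        io.write_reads_tsv(rs, rundir / "reads" / f"{sid}.tsv")

    # "known" miR-430 targets: the subset of true targets present on prior
    # loss-of-function lists; the remainder are discoverable as putative
    rng = np.random.default_rng(np.random.SeedSequence([seed, 777]).spawn(1)[0])
    true_targets = sorted(genes.index[genes["is_mir430_target"]])
    known = [g for g in true_targets if rng.random() < cfg.known_target_fraction]
    io.write_gene_list(known, rundir / FILES["known_targets"])
    return {"n_genes": len(specs), "n_samples": len(designs), "n_known_targets": len(known)}


def stage_snps(cfg: RunConfig, rundir: Path) -> dict:
    """Call the SNP mask from pooled transcription-off and non-injected reads."""
    samples = _read_samples(rundir)
    ctrl_ids = list(samples.index[samples["condition"].isin(["amanitin", "noninjected"])])
    thr = cfg.thresholds
    if cfg.use_snp_mask and ctrl_ids:
        ctrl_reads = _read_all_reads(rundir, ctrl_ids)
        mask = conversion.call_snps(ctrl_reads, thr.snp_min_fraction, thr.snp_min_coverage)
    else:
        mask = conversion.SnpMask.empty()
    rows = [
        {"gene_id": g, "offset": off}
        for g, offs in sorted(mask.positions.items())
        for off in sorted(offs)
    ]
    pd.DataFrame(rows, columns=["gene_id", "offset"]).to_csv(
        rundir / FILES["snp_mask"], index=False
    )
    return {"n_control_samples": len(ctrl_ids), "n_snp_positions": mask.n_positions}


def _read_mask(rundir: Path) -> conversion.SnpMask:
    df = pd.read_csv(rundir / FILES["snp_mask"])
    positions = {
        g: frozenset(int(o) for o in grp["offset"]) for g, grp in df.groupby("gene_id")
    }
    return conversion.SnpMask(positions)


def stage_count(cfg: RunConfig, rundir: Path) -> dict:
    """Classify reads against the mask and write the tri-layer counts table."""
    samples = _read_samples(rundir)
    reads = _read_all_reads(rundir, samples.index)
    mask = _read_mask(rundir)
    genes = pd.read_csv(rundir / FILES["genes"], index_col="gene_id")
    counts = conversion.count_gene(
        reads, mask, cfg.thresholds.min_conversions, gene_ids=genes.index
    )
    spikes = pd.read_csv(rundir / FILES["spike_counts"], index_col="feature_id")
    tri = quant.counts_from_table(counts, spikes, samples)
    specs_meta = None
    utrs = io.read_utr_fasta(rundir / FILES["utr_fasta"])

    class _Shim:
        def __init__(self, gid, seq):
            self.gene_id, self.utr_sequence = gid, seq

    specs_meta = io.feature_meta_from_specs(
        [_Shim(g, utrs[g]) for g in genes.index], spike_ids=spikes.index
    )
    io.write_counts_table(tri, rundir / FILES["counts"], specs_meta)
    return {"n_rows": tri.total.shape[0], "n_samples": tri.total.shape[1]}


def stage_normalize(cfg: RunConfig, rundir: Path) -> dict:
    """Filter low-expression genes, derive spike-in factors, write CPMs."""
    samples = _read_samples(rundir)
    keep = [s for s in samples.index if s not in cfg.thresholds.excluded_samples]
    samples = samples.loc[keep]
    tri = io.read_counts_table(rundir / FILES["counts"], samples)
    tri = quant.filter_genes(tri)
    factors = quant.spikein_scaling(tri)
    factors.to_csv(rundir / FILES["factors"])
    mats = quant.cpm(tri, factors)
    for fraction, mat in mats.items():
        out = mat.values.copy()
        out.insert(0, "fraction", fraction)
        out.to_csv(rundir / FILES[f"cpm_{fraction}"])
    return {"n_genes_kept": int((~tri.spikein).sum()), "n_samples": tri.total.shape[1]}


def _read_cpm(rundir: Path, fraction: str) -> pd.DataFrame:
    df = pd.read_csv(rundir / FILES[f"cpm_{fraction}"], index_col=0)
    return df.drop(columns=["fraction"])


def stage_sites(cfg: RunConfig, rundir: Path) -> dict:
    """Scan 3'UTRs for miR-430 sites and label target status."""
    utrs = io.read_utr_fasta(rundir / FILES["utr_fasta"])
    known = io.read_gene_list(rundir / FILES["known_targets"])
    sites_by_gene = {g: annot.scan_mir430_sites(seq) for g, seq in utrs.items()}
    io.write_sites_bed(sites_by_gene, rundir / FILES["sites_bed"])
    table = annot.site_count_table(utrs)
    table["target_status"] = [
        annot.target_status(bool(table.loc[g, "has_site"]), g, known) for g in table.index
    ]
    table.to_csv(rundir / FILES["site_counts"])
    return {"n_genes_with_site": int(table["has_site"].sum())}


def stage_classify(cfg: RunConfig, rundir: Path) -> dict:
    """ZCS, MZT classes, activation hours, and labeled-CPM trajectories."""
    samples = _read_samples(rundir)
    samples = samples.loc[[s for s in samples.index if s not in cfg.thresholds.excluded_samples]]
    cpm_total = _read_cpm(rundir, "total")
    cpm_labeled = _read_cpm(rundir, "labeled")
    genes_meta = pd.read_csv(rundir / FILES["genes"], index_col="gene_id")
    gene_rows = [g for g in cpm_total.index if not g.startswith(quant.SPIKEIN_PREFIX)]
    cls = mzt.classify_genes(
        cpm_total.loc[gene_rows],
        cpm_labeled.loc[gene_rows],
        samples,
        cfg.thresholds,
        biotypes=genes_meta["biotype"],
    )

    # trajectories on labeled counts between consecutive zygotic-window hours
    tri = io.read_counts_table(rundir / FILES["counts"], samples)
    factors = pd.read_csv(rundir / FILES["factors"], index_col=0)
    eff = factors["effective_library_size"]
    tc = samples[samples["condition"] == "timecourse"]
    de_rows = []
    zw = sorted(cfg.thresholds.zygotic_window_h)
    labeled = tri.labeled.reindex(cls.index).fillna(0).astype(int)
    for t0, t1 in zip(zw[:-1], zw[1:]):
        ids0 = [s for s in tc.index[tc["timepoint_h"] == t0] if s in labeled.columns]
        ids1 = [s for s in tc.index[tc["timepoint_h"] == t1] if s in labeled.columns]
        if not ids0 or not ids1:
            continue
        de = stats.nb_fold_change_test(
            labeled[ids1],
            labeled[ids0],
            eff[ids1],
            eff[ids0],
            comparison=f"{t1}h_vs_{t0}h",
            fraction="labeled",
        )
        de["interval"] = f"{t0}h-{t1}h"
        de_rows.append(de.reset_index())
    if de_rows:
        de_all = pd.concat(de_rows, ignore_index=True)
        de_all.to_csv(rundir / FILES["de_intervals"], index=False)
        labels = mzt.trajectory(de_all, cfg.thresholds)
        traj = (
            labels.sort_values("interval")
            .groupby("gene_id")["label"]
            .apply(lambda s: ",".join(s))
        )
    else:
        traj = pd.Series(dtype=str)

    site_counts = pd.read_csv(rundir / FILES["site_counts"], index_col="gene_id")
    out = cls.copy()
    out["trajectory"] = traj.reindex(out.index).fillna("")
    for col in list(annot.SITE_TYPES) + ["has_site", "target_status"]:
        out[col] = site_counts[col].reindex(out.index)
    out.to_csv(rundir / FILES["classification"])
    n_by_class = out["mzt_class"].value_counts().to_dict()
    return {"classes": n_by_class}


def stage_diffexp(cfg: RunConfig, rundir: Path) -> dict:
    """DE tables: 7 h vs 2 h total; unlabeled vs total at 7 h; LNA contrasts."""
    samples = _read_samples(rundir)
    samples = samples.loc[[s for s in samples.index if s not in cfg.thresholds.excluded_samples]]
    tri = io.read_counts_table(rundir / FILES["counts"], samples)
    cls = pd.read_csv(rundir / FILES["classification"], index_col="gene_id")
    factors = pd.read_csv(rundir / FILES["factors"], index_col=0)
    eff = factors["effective_library_size"]
    genes = cls.index

    info = {}
    tc = samples[samples["condition"] == "timecourse"]
    ids2 = list(tc.index[tc["timepoint_h"] == 2])
    ids7 = list(tc.index[tc["timepoint_h"] == 7])
    total = tri.total.reindex(genes).fillna(0).astype(int)
    labeled = tri.labeled.reindex(genes).fillna(0).astype(int)
    unlabeled = total - labeled
    if ids2 and ids7:
        de = stats.nb_fold_change_test(
            total[ids7], total[ids2], eff[ids7], eff[ids2], comparison="7h_vs_2h", fraction="total"
        )
        de.to_csv(rundir / FILES["de_total_7v2"])
        info["n_7v2"] = len(de)
        # paired-by-sample contrast: same 7 h libraries for both fractions
        de_tvu = stats.nb_fold_change_test(
            unlabeled[ids7],
            total[ids7],
            eff[ids7],
            eff[ids7],
            comparison="unlabeled_vs_total_7h",
            fraction="unlabeled",
        )
        de_tvu.to_csv(rundir / FILES["de_tvu_7h"])

    lna = samples[samples["condition"].isin(["lna_control", "lna_mir430"])]
    if len(lna):
        ids_430 = list(lna.index[lna["condition"] == "lna_mir430"])
        ids_ctl = list(lna.index[lna["condition"] == "lna_control"])
        parts = []
        for fraction, mat in (("total", total), ("labeled", labeled), ("unlabeled", unlabeled)):
            de = stats.nb_fold_change_test(
                mat[ids_430],
                mat[ids_ctl],
                eff[ids_430],
                eff[ids_ctl],
                comparison="lna430_vs_control",
                fraction=fraction,
            )
            parts.append(de.reset_index())
        pd.concat(parts, ignore_index=True).to_csv(rundir / FILES["de_lna"], index=False)
        info["n_lna"] = len(parts[0])
    return info


def stage_masked_decay(cfg: RunConfig, rundir: Path) -> dict:
    """Flag masked-decay maternal-zygotic genes and split by site presence."""
    if not (rundir / FILES["de_total_7v2"]).exists():
        return {"skipped": "no 2 h / 7 h time-course DE available"}
    cls = pd.read_csv(rundir / FILES["classification"], index_col="gene_id")
    de_7v2 = pd.read_csv(rundir / FILES["de_total_7v2"], index_col="gene_id")
    de_tvu = pd.read_csv(rundir / FILES["de_tvu_7h"], index_col="gene_id")
    known = io.read_gene_list(rundir / FILES["known_targets"])
    thr = cfg.thresholds
    out = stats.masked_decay_genes(
        de_7v2,
        de_tvu,
        cls["mzt_class"],
        cls["has_site"].astype(bool),
        known,
        total_fc_floor=thr.masked_decay_total_fc_floor,
        padj_threshold=thr.masked_decay_padj,
    )
    out.to_csv(rundir / FILES["masked_decay"], index_label="gene_id")
    return {
        "n_masked_decay": int(out["masked_decay"].sum()),
        "n_masked_decay_targets": int((out["group"] == "masked_decay_target").sum()),
    }


def stage_lna_shift(cfg: RunConfig, rundir: Path) -> dict:
    """One-sided KS de-repression tests of targets vs non-target controls."""
    if not (rundir / FILES["de_lna"]).exists():
        return {"skipped": "no LNA samples in the design"}
    de_lna = pd.read_csv(rundir / FILES["de_lna"])
    cls = pd.read_csv(rundir / FILES["classification"], index_col="gene_id")
    known = io.read_gene_list(rundir / FILES["known_targets"])
    samples = _read_samples(rundir)
    cpm_labeled = _read_cpm(rundir, "labeled")
    ctl_ids = [
        s for s in samples.index[samples["condition"] == "lna_control"] if s in cpm_labeled.columns
    ]
    control_labeled = cpm_labeled[ctl_ids].mean(axis=1)
    controls = set(cls.index[~cls["has_site"].astype(bool)]) - known
    de_by_fraction = {
        f: de_lna[de_lna["fraction"] == f].set_index("gene_id") for f in de_lna["fraction"].unique()
    }
    res = stats.lna_derepression(
        de_by_fraction,
        set(known),
        controls,
        control_labeled_cpm=control_labeled,
        min_labeled_cpm=cfg.thresholds.lna_labeled_cpm_min,
    )
    rows = [vars(r) | {"fraction": f} for f, r in res.items()]
    pd.DataFrame(rows).to_csv(rundir / FILES["lna_shift"], index=False)
    return {f: r.pvalue for f, r in res.items()}


STAGES = [
    ("simulate", stage_simulate),
    ("snps", stage_snps),
    ("count", stage_count),
    ("normalize", stage_normalize),
    ("sites", stage_sites),
    ("classify", stage_classify),
    ("diffexp", stage_diffexp),
    ("masked_decay", stage_masked_decay),
    ("lna_shift", stage_lna_shift),
]


def run_pipeline(cfg: RunConfig, seed: int, outdir) -> dict:
    """Execute every stage in dependency order and write the run manifest."""
    rundir = Path(outdir)
    rundir.mkdir(parents=True, exist_ok=True)
    manifest = {"seed": seed, "version": __version__, "config": cfg.to_dict(), "stages": {}}
    for name, fn in STAGES:
        t0 = time.perf_counter()
        try:
            info = fn(cfg, seed, rundir) if name == "simulate" else fn(cfg, rundir)
        except Exception as exc:
            manifest["stages"][name] = {"error": str(exc)}
            io.write_manifest(manifest, rundir / FILES["manifest"])
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
        manifest["stages"][name] = {"info": info, "seconds": round(time.perf_counter() - t0, 3)}
    manifest["outputs"] = {
        key: io.file_digest(rundir / fname)
        for key, fname in FILES.items()
        if fname != FILES["manifest"] and (rundir / fname).exists()
    }
    io.write_manifest(manifest, rundir / FILES["manifest"])
    return manifest
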