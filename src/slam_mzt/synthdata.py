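"""Seeded synthetic SLAM-seq experiments with known ground truth.

The generator emulates metabolic-labeling 3'-end sequencing of early
zebrafish embryos: maternally deposited transcripts decay exponentially,
zygotic transcription switches on per gene at an onset hour and accumulates
toward a synthesis/decay steady state, and only zygotically made molecules
incorporate the UTP analog, so their reference-T positions convert to C with
a dose-dependent probability while maternal molecules convert only at a
background error rate.  T>C SNP positions read as C on every molecule.

Expected abundances per gene and sample (t hours post injection):

    m(t) = M0 * exp(-d_base * max(0, t - decay_onset))
              * exp(-d_mir * max(0, t - mir430_onset))      [miR component
                                                            only for targets
                                                            with miR active]
    z(t) = (k / d_z) * (1 - exp(-d_z * (t - t_on)))   for t >= t_on, else 0

Transcription-inhibited (alpha-amanitin) samples produce no zygotic
molecules at all; un-injected or 0 mM samples produce zygotic molecules but
label them only at the background rate.  The miR-430-complementary LNA
removes the miR-430 decay components (scaled by a knockdown fraction).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .annot import MIR430_MOTIFS

CONDITIONS = (
    "dose_series",
    "timecourse",
    "amanitin",
    "lna_control",
    "lna_mir430",
    "noninjected",
)

#: per-T conversion probability gained per mM of s4-UTP; 75 mM -> ~0.30
CONVERSION_SLOPE_PER_MM = 0.004

#: hour at which miR-430, one of the earliest zygotic products, becomes active
DEFAULT_MIR430_ONSET_H = 3.0

# Background (non-incorporation) per-T conversion probability.  Alkylated
# SLAM-seq libraries typically show 0.01-0.1% background T>C; 0.03% sits in
# that range.  At desk scale the cohort has ~100x fewer genes than a real
# transcriptome, so each gene's read share -- and with it the false-positive
# sensitivity of absolute labeled-CPM thresholds -- is correspondingly
# inflated; a mid-range background keeps the generator's per-gene
# false-positive behaviour comparable to the real data the thresholds were
# designed for.
DEFAULT_ERROR_PROB = 3e-4
DEFAULT_READ_LENGTH = 80


def conversion_prob_for_dose(dose_mm: float, error_prob: float = DEFAULT_ERROR_PROB) -> float:
    """Per-T conversion probability of a labeled molecule at a given dose.

    Strictly increasing in dose; at 0 mM it equals the background error rate
    (no analog, no incorporation signal).
    """
    return error_prob + CONVERSION_SLOPE_PER_MM * dose_mm


@dataclass
class GeneSpec:
    """Ground-truth generative parameters for one gene."""

    gene_id: str
    biotype: str = "coding"  # {coding, noncoding}
    mzt_class_truth: str = "MZ"  # {PM, MZ, PZ}
    maternal_abundance_M0: float = 100.0
    maternal_decay_rate_base: float = 0.1  # per hour
    maternal_decay_rate_mir430: float = 0.0  # extra, only when miR-430 active
    decay_onset_h: float = 0.0
    zygotic_onset_h: float = 4.0
    zygotic_synthesis_rate: float = 0.0  # units/hour
    zygotic_decay_rate_base: float = 0.05
    zygotic_decay_rate_mir430: float = 0.0
    utr_sequence: str = ""
    snp_positions: frozenset = field(default_factory=frozenset)
    embedded_site_types: tuple = ()

    @property
    def is_mir430_target(self) -> bool:
        return len(self.embedded_site_types) > 0

    def validate(self) -> None:
        rates = (
            self.maternal_abundance_M0,
            self.maternal_decay_rate_base,
            self.maternal_decay_rate_mir430,
            self.zygotic_synthesis_rate,
            self.zygotic_decay_rate_base,
            self.zygotic_decay_rate_mir430,
        )
        if any(r < 0 for r in rates):
            raise ValueError(f"{self.gene_id}: negative abundance or rate")
        if not self.utr_sequence:
            raise ValueError(f"{self.gene_id}: empty UTR sequence")
        if self.mzt_class_truth == "PM" and self.zygotic_synthesis_rate != 0:
            raise ValueError(f"{self.gene_id}: PM gene with zygotic synthesis")
        if self.mzt_class_truth == "PZ" and self.maternal_abundance_M0 != 0:
            raise ValueError(f"{self.gene_id}: PZ gene with maternal deposit")
        for off in self.snp_positions:
            if not 0 <= off < len(self.utr_sequence) or self.utr_sequence[off] != "T":
                raise ValueError(f"{self.gene_id}: SNP offset {off} is not a reference T")


@dataclass
class SampleDesign:
    """One sequencing library: condition, timing, dose, depth, and noise knobs."""

    sample_id: str
    condition: str
    timepoint_h: float
    replicate: int = 1
    library_size: int = 20_000
    s4utp_dose_mM: float = 75.0
    conversion_prob: float | None = None  # derived from dose when None
    error_prob: float = DEFAULT_ERROR_PROB
    spikein_efficiency: float = 1.0

    def __post_init__(self):
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.conversion_prob is None:
            self.conversion_prob = conversion_prob_for_dose(self.s4utp_dose_mM, self.error_prob)

    @property
    def transcription_on(self) -> bool:
        return self.condition != "amanitin"


@dataclass(frozen=True)
class ReadRecord:
    """A mutation-annotated read over a gene's 3'UTR (sense strand, 0-based)."""

    gene_id: str
    window_start: int
    window_end: int
    t_positions: tuple  # offsets of reference-T bases in the window
    converted_positions: tuple  # subset observed as C
    truth_labeled: bool  # molecule of zygotic origin


def expected_abundances(
    spec: GeneSpec,
    design: SampleDesign,
    mir430_onset_h: float = DEFAULT_MIR430_ONSET_H,
    lna_knockdown: float = 1.0,
) -> tuple[float, float]:
    """Expected maternal and zygotic molecule abundances for one gene/sample."""
    t = design.timepoint_h
    mir_scale = 1.0
    if design.condition == "lna_mir430":
        mir_scale = 1.0 - lna_knockdown
    mir_active = spec.is_mir430_target and t >= mir430_onset_h

    m = spec.maternal_abundance_M0 * math.exp(
        -spec.maternal_decay_rate_base * max(0.0, t - spec.decay_onset_h)
    )
    if mir_active:
        m *= math.exp(
            -mir_scale * spec.maternal_decay_rate_mir430 * max(0.0, t - mir430_onset_h)
        )

    z = 0.0
    if design.transcription_on and t >= spec.zygotic_onset_h and spec.zygotic_synthesis_rate > 0:
        dz = spec.zygotic_decay_rate_base
        if mir_active:
            dz += mir_scale * spec.zygotic_decay_rate_mir430
        dt = t - spec.zygotic_onset_h
        if dz > 0:
            z = spec.zygotic_synthesis_rate / dz * (1.0 - math.exp(-dz * dt))
        else:
            z = spec.zygotic_synthesis_rate * dt
    return m, z


def _simulate_gene_reads(
    rng: np.random.Generator,
    spec: GeneSpec,
    n_reads: int,
    p_zygotic: float,
    conversion_prob: float,
    error_prob: float,
    read_length: int,
) -> list[ReadRecord]:
    L = len(spec.utr_sequence)
    w = min(read_length, L)
    seq = np.frombuffer(spec.utr_sequence.encode(), dtype=np.uint8)
    is_t = seq == ord("T")
    is_snp = np.zeros(L, dtype=bool)
    if spec.snp_positions:
        is_snp[list(spec.snp_positions)] = True

    starts = rng.integers(0, L - w + 1, size=n_reads)
    zyg = rng.random(n_reads) < p_zygotic
    offsets = starts[:, None] + np.arange(w)[None, :]
    t_mask = is_t[offsets]
    snp_mask = is_snp[offsets]
    p_conv = np.where(zyg, conversion_prob, error_prob)
    draw = rng.random((n_reads, w)) < p_conv[:, None]
    conv_mask = (t_mask & ~snp_mask & draw) | snp_mask

    reads = []
    for i in range(n_reads):
        t_pos = tuple(int(x) for x in offsets[i][t_mask[i]])
        c_pos = tuple(int(x) for x in offsets[i][conv_mask[i]])
        reads.append(
            ReadRecord(spec.gene_id, int(starts[i]), int(starts[i]) + w, t_pos, c_pos, bool(zyg[i]))
        )
    return reads


def simulate_experiment(
    gene_specs: list[GeneSpec],
    designs: list[SampleDesign],
    seed: int,
    read_length: int = DEFAULT_READ_LENGTH,
    mir430_onset_h: float = DEFAULT_MIR430_ONSET_H,
    lna_knockdown: float = 1.0,
) -> tuple[dict[str, list[ReadRecord]], pd.DataFrame]:
    """Simulate reads for every sample and return them with per-gene truth.

    Returns
    -------
    reads
        ``{sample_id: [ReadRecord, ...]}``.
    truth
        DataFrame with one row per gene x sample: expected maternal/zygotic
        abundances, realised read counts, and realised zygotic-read counts.
        Deterministic given identical inputs and seed.
    """
    if not designs:
        raise ValueError("designs must be non-empty")
    for spec in gene_specs:
        spec.validate()

    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(designs))
    reads_by_sample: dict[str, list[ReadRecord]] = {}
    truth_rows = []
    for design, child in zip(designs, children):
        rng = np.random.default_rng(child)
        m = np.empty(len(gene_specs))
        z = np.empty(len(gene_specs))
        for j, spec in enumerate(gene_specs):
            m[j], z[j] = expected_abundances(spec, design, mir430_onset_h, lna_knockdown)
        total = m + z
        if total.sum() <= 0:
            raise ValueError(f"sample {design.sample_id}: zero total abundance")
        counts = rng.multinomial(design.library_size, total / total.sum())

        sample_reads: list[ReadRecord] = []
        for j, spec in enumerate(gene_specs):
            n = int(counts[j])
            n_zyg = 0
            if n > 0:
                p_zyg = z[j] / total[j] if total[j] > 0 else 0.0
                gene_reads = _simulate_gene_reads(
                    rng, spec, n, p_zyg, design.conversion_prob, design.error_prob, read_length
                )
                n_zyg = sum(r.truth_labeled for r in gene_reads)
                sample_reads.extend(gene_reads)
            truth_rows.append(
                {
                    "gene_id": spec.gene_id,
                    "sample_id": design.sample_id,
                    "maternal_expected": m[j],
                    "zygotic_expected": z[j],
                    "n_reads": n,
                    "n_zygotic_reads": n_zyg,
                }
            )
        reads_by_sample[design.sample_id] = sample_reads
    return reads_by_sample, pd.DataFrame(truth_rows)


def make_utr_sequence(
    length: int,
    t_fraction: float,
    embedded_site_types: list[str] | tuple = (),
    seed: int | np.random.Generator = 0,
    max_tries: int = 1000,
) -> str:
    """Random UTR sequence with a target T fraction and embedded miR-430 motifs.

    Each requested motif is placed verbatim at a random position, with
    placements pairwise non-overlapping.  Raises if the motifs cannot be
    packed into ``length``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    motifs = [MIR430_MOTIFS[t] for t in embedded_site_types]
    if motifs and length < max(len(m) for m in motifs):
        raise ValueError("UTR shorter than longest embedded motif")
    if sum(len(m) for m in motifs) > length:
        raise ValueError("embedded motifs cannot be packed into UTR length")

    if not 0.0 <= t_fraction <= 1.0:
        raise ValueError("t_fraction must be in [0, 1]")
    p_other = (1.0 - t_fraction) / 3.0
    bases = rng.choice(
        np.array(["A", "C", "G", "T"]), size=length, p=[p_other, p_other, p_other, t_fraction]
    )

    placed: list[tuple[int, int]] = []
    for motif in sorted(motifs, key=len, reverse=True):
        for _ in range(max_tries):
            s = int(rng.integers(0, length - len(motif) + 1))
            e = s + len(motif)
            if all(e <= ps or s >= pe for ps, pe in placed):
                placed.append((s, e))
                bases[s:e] = list(motif)
                break
        else:
            raise ValueError("could not place embedded motifs without overlap")
    return "".join(bases)


def default_spikein_catalog(n: int = 92) -> dict[str, float]:
    """Fixed spike-in abundance ladder (ERCC-92-like): ~4 orders of magnitude."""
    return {
        f"ERCC-{i + 1:05d}": round(4.0 * 2.0 ** (12.0 * i / (n - 1)), 3) for i in range(n)
    }


def emit_spikeins(
    designs: list[SampleDesign],
    spikein_catalog: dict[str, float] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Poisson spike-in counts per sample: catalog x sample capture efficiency.

    The catalog is identical for every sample (spike-ins added at equal
    molarity); sample-to-sample differences come only from the design's
    ``spikein_efficiency`` and Poisson sampling noise.
    """
    catalog = default_spikein_catalog() if spikein_catalog is None else spikein_catalog
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    abund = np.array(list(catalog.values()), dtype=float)
    cols = {}
    for design in designs:
        cols[design.sample_id] = rng.poisson(abund * design.spikein_efficiency)
    df = pd.DataFrame(cols, index=list(catalog))
    df.index.name = "feature_id"
    return df


# ---------------------------------------------------------------------------
# study-condition builders: cohorts and designs mirroring the experiments
# ---------------------------------------------------------------------------

def make_gene_cohort(
    n_pm: int = 100,
    n_mz: int = 100,
    n_pz: int = 100,
    seed: int = 0,
    utr_length: int = 400,
    t_fraction: float = 0.3,
    frac_targets: float = 0.3,
    frac_masked_decay: float = 0.0,
    snp_prob: float = 0.02,
    noncoding_frac: float = 0.1,
) -> list[GeneSpec]:
    """Build a cohort of PM/MZ/PZ genes with well-separated kinetics.

    ``frac_targets`` of each class receive an embedded miR-430 site and
    nonzero miR-430 decay components.  ``frac_masked_decay`` of the MZ genes
    are built so zygotic synthesis offsets maternal decay (total mRNA flat
    while the maternal fraction decays) -- the masked-decay regime.
    A small fraction of T offsets are declared SNPs (always read as C).
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 9151]).spawn(1)[0])
    specs: list[GeneSpec] = []
    site_choices = [("8mer",), ("7mer-M8",), ("7mer-A1",), ("6mer",), ("8mer", "6mer")]

    def _finish(spec: GeneSpec, idx: int) -> GeneSpec:
        seq = make_utr_sequence(utr_length, t_fraction, spec.embedded_site_types, rng)
        t_offs = [i for i, b in enumerate(seq) if b == "T"]
        snps = frozenset(
            off for off in t_offs if rng.random() < snp_prob
        ) if snp_prob > 0 else frozenset()
        biotype = "noncoding" if rng.random() < noncoding_frac else "coding"
        return replace(spec, utr_sequence=seq, snp_positions=snps, biotype=biotype)

    idx = 0
    for _ in range(n_pm):
        target = rng.random() < frac_targets
        specs.append(
            _finish(
                GeneSpec(
                    gene_id=f"gPM{idx:04d}",
                    mzt_class_truth="PM",
                    maternal_abundance_M0=float(rng.lognormal(math.log(120), 0.5)),
                    maternal_decay_rate_base=float(rng.uniform(0.02, 0.15)),
                    maternal_decay_rate_mir430=float(rng.uniform(0.3, 0.6)) if target else 0.0,
                    zygotic_synthesis_rate=0.0,
                    embedded_site_types=site_choices[int(rng.integers(len(site_choices)))]
                    if target
                    else (),
                ),
                idx,
            )
        )
        idx += 1

    n_masked = int(round(frac_masked_decay * n_mz))
    for i in range(n_mz):
        target = rng.random() < frac_targets
        masked = i < n_masked
        if masked:
            # maternal decay offset by synthesis: total roughly flat 2->7 h
            m0 = float(rng.lognormal(math.log(150), 0.3))
            decay = float(rng.uniform(0.25, 0.4))
            onset = float(rng.uniform(3.0, 4.0))
            # synthesis sized to roughly replace the decayed maternal pool by 7 h
            lost_by_7 = m0 * (1 - math.exp(-decay * 7.0))
            k = lost_by_7 / (7.0 - onset) * float(rng.uniform(0.9, 1.3))
            spec = GeneSpec(
                gene_id=f"gMZ{idx:04d}",
                mzt_class_truth="MZ",
                maternal_abundance_M0=m0,
                maternal_decay_rate_base=decay,
                zygotic_onset_h=onset,
                zygotic_synthesis_rate=k,
                zygotic_decay_rate_base=0.0,
                embedded_site_types=("7mer-M8",) if target else (),
                maternal_decay_rate_mir430=0.0,
            )
        else:
            spec = GeneSpec(
                gene_id=f"gMZ{idx:04d}",
                mzt_class_truth="MZ",
                maternal_abundance_M0=float(rng.lognormal(math.log(120), 0.5)),
                maternal_decay_rate_base=float(rng.uniform(0.02, 0.15)),
                maternal_decay_rate_mir430=float(rng.uniform(0.3, 0.6)) if target else 0.0,
                zygotic_onset_h=float(rng.choice([3.5, 4.0, 4.5, 5.0])),
                zygotic_synthesis_rate=float(rng.uniform(30.0, 80.0)),
                zygotic_decay_rate_base=float(rng.uniform(0.02, 0.1)),
                zygotic_decay_rate_mir430=float(rng.uniform(0.3, 0.6)) if target else 0.0,
                embedded_site_types=site_choices[int(rng.integers(len(site_choices)))]
                if target
                else (),
            )
        specs.append(_finish(spec, idx))
        idx += 1

    for _ in range(n_pz):
        target = rng.random() < frac_targets
        specs.append(
            _finish(
                GeneSpec(
                    gene_id=f"gPZ{idx:04d}",
                    mzt_class_truth="PZ",
                    maternal_abundance_M0=0.0,
                    maternal_decay_rate_base=0.0,
                    zygotic_onset_h=float(rng.choice([3.0, 4.0, 5.0, 6.0])),
                    zygotic_synthesis_rate=float(rng.uniform(40.0, 120.0)),
                    zygotic_decay_rate_base=float(rng.uniform(0.02, 0.1)),
                    zygotic_decay_rate_mir430=float(rng.uniform(0.3, 0.6)) if target else 0.0,
                    embedded_site_types=site_choices[int(rng.integers(len(site_choices)))]
                    if target
                    else (),
                ),
                idx,
            )
        )
        idx += 1
    return specs


def make_masked_decay_cohort(
    n_masked: int = 60,
    n_stable: int = 60,
    seed: int = 0,
    utr_length: int = 400,
    t_fraction: float = 0.3,
    frac_targets: float = 0.5,
) -> list[GeneSpec]:
    """Maternal-zygotic genes in two regimes for masked-decay studies.

    *Masked* genes lose most of their maternal pool by 7 h but zygotic
    synthesis is sized to replace it, leaving total mRNA roughly flat.
    *Stable* genes have no maternal decay and only a small zygotic trickle
    (enough labeling to classify as maternal-zygotic, too little to shift
    the unlabeled fraction detectably) -- the negative control regime.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 40231]).spawn(1)[0])
    specs = []
    for i in range(n_masked + n_stable):
        masked = i < n_masked
        target = rng.random() < frac_targets
        m0 = float(rng.lognormal(math.log(150), 0.3))
        if masked:
            decay = float(rng.uniform(0.25, 0.4))
            onset = float(rng.uniform(3.0, 4.0))
            lost_by_7 = m0 * (1 - math.exp(-decay * 7.0))
            k = lost_by_7 / (7.0 - onset) * float(rng.uniform(0.9, 1.2))
        else:
            decay = 0.0
            onset = float(rng.uniform(3.0, 4.0))
            # small trickle: ~8% zygotic fraction by 7 h
            k = 0.08 * m0 / (7.0 - onset)
        sites = ("7mer-M8",) if target else ()
        seq = make_utr_sequence(utr_length, t_fraction, sites, rng)
        specs.append(
            GeneSpec(
                gene_id=f"g{'MD' if masked else 'ST'}{i:04d}",
                mzt_class_truth="MZ",
                maternal_abundance_M0=m0,
                maternal_decay_rate_base=decay,
                zygotic_onset_h=onset,
                zygotic_synthesis_rate=k,
                zygotic_decay_rate_base=0.0,
                utr_sequence=seq,
                embedded_site_types=sites,
            )
        )
    return specs


def make_timecourse_designs(
    timepoints_h=(1, 2, 3, 4, 5, 6, 7),
    replicates: int = 3,
    library_size: int = 20_000,
    dose_mM: float = 75.0,
) -> list[SampleDesign]:
    """Hourly time-course libraries at the working s4-UTP dose."""
    return [
        SampleDesign(
            sample_id=f"tc_{t}h_r{r}",
            condition="timecourse",
            timepoint_h=float(t),
            replicate=r,
            library_size=library_size,
            s4utp_dose_mM=dose_mM,
        )
        for t in timepoints_h
        for r in range(1, replicates + 1)
    ]


def make_control_designs(
    timepoint_h: float = 6.0,
    replicates: int = 3,
    library_size: int = 20_000,
) -> list[SampleDesign]:
    """Transcription-inhibited (75 mM analog) and non-injected controls."""
    designs = [
        SampleDesign(
            sample_id=f"amanitin_{int(timepoint_h)}h_r{r}",
            condition="amanitin",
            timepoint_h=timepoint_h,
            replicate=r,
            library_size=library_size,
            s4utp_dose_mM=75.0,
        )
        for r in range(1, replicates + 1)
    ]
    designs += [
        SampleDesign(
            sample_id=f"noninj_{int(timepoint_h)}h_r{r}",
            condition="noninjected",
            timepoint_h=timepoint_h,
            replicate=r,
            library_size=library_size,
            s4utp_dose_mM=0.0,
        )
        for r in range(1, replicates + 1)
    ]
    return designs


def make_dose_series_designs(
    doses_mM=(25.0, 50.0, 75.0),
    timepoint_h: float = 6.0,
    replicates: int = 2,
    library_size: int = 20_000,
) -> list[SampleDesign]:
    return [
        SampleDesign(
            sample_id=f"dose{int(d)}_r{r}",
            condition="dose_series",
            timepoint_h=timepoint_h,
            replicate=r,
            library_size=library_size,
            s4utp_dose_mM=d,
        )
        for d in doses_mM
        for r in range(1, replicates + 1)
    ]


def make_lna_designs(
    timepoint_h: float = 6.0,
    replicates: int = 3,
    library_size: int = 20_000,
    dose_mM: float = 50.0,
) -> list[SampleDesign]:
    """miR-430-LNA vs control-LNA libraries at shield stage (~6 h)."""
    designs = []
    for cond in ("lna_control", "lna_mir430"):
        for r in range(1, replicates + 1):
            designs.append(
                SampleDesign(
                    sample_id=f"{cond}_{int(timepoint_h)}h_r{r}",
                    condition=cond,
                    timepoint_h=timepoint_h,
                    replicate=r,
                    library_size=library_size,
                    s4utp_dose_mM=dose_mM,
                )
            )
    return designs
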