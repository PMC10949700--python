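"""Labeled-read calling: SNP mask thresholds, the >=2-conversion rule."""

import math

import numpy as np
import pytest

from slam_mzt import synthdata as sd
from slam_mzt.conversion import (
    SnpMask,
    call_snps,
    classify_read,
    conversion_rate_per_base,
    count_false_positive_genes,
    count_gene,
)
from slam_mzt.synthdata import ReadRecord

from conftest import make_single_gene


def read_at(gene="g", t=(), conv=(), start=0, end=50, labeled=False):
    return ReadRecord(gene, start, end, tuple(t), tuple(conv), labeled)


class TestCallSnps:
    @pytest.mark.parametrize(
        "coverage, converted, flagged",
        [
            (10, 8, True),  # 0.8 >= 0.15 and 10 >= 7
            (6, 6, False),  # below coverage floor
            (20, 2, False),  # 0.10 below fraction floor
        ],
    )
    def test_thresholds(self, coverage, converted, flagged):
        reads = [
            read_at(t=[5], conv=[5] if i < converted else [])
            for i in range(coverage)
        ]
        mask = call_snps(reads)
        assert (5 in mask.get("g")) is flagged

    def test_controls_are_pooled_before_thresholding(self):
        # 4 + 4 converted reads in two control samples: only pooled coverage
        # (8 >= 7) allows the call
        by_sample = {
            "amanitin_r1": [read_at(t=[3], conv=[3]) for _ in range(4)],
            "noninj_r1": [read_at(t=[3], conv=[3]) for _ in range(4)],
        }
        assert 3 in call_snps(by_sample).get("g")
        assert 3 not in call_snps(by_sample["amanitin_r1"]).get("g")

    def test_no_controls_refused(self):
        with pytest.raises(ValueError):
            call_snps([])
        assert call_snps([], allow_empty=True).n_positions == 0


class TestClassifyRead:
    def test_two_unmasked_conversions_labeled(self):
        r = read_at(t=[10, 42, 50], conv=[10, 42])
        assert classify_read(r, SnpMask.empty()) == "labeled"

    def test_single_conversion_unlabeled(self):
        r = read_at(t=[10, 42], conv=[10])
        assert classify_read(r, SnpMask.empty()) == "unlabeled"

    def test_masked_conversion_excluded_before_counting(self):
        r = read_at(t=[10, 42], conv=[10, 42])
        mask = SnpMask({"g": frozenset({42})})
        assert classify_read(r, mask) == "unlabeled"

    def test_raising_min_conversions_never_adds_labels(self):
        rng = np.random.default_rng(0)
        reads = [
            read_at(t=list(range(10)), conv=list(rng.choice(10, size=k, replace=False)))
            for k in rng.integers(0, 6, size=200)
        ]
        labels = [
            sum(classify_read(r, SnpMask.empty(), mc) == "labeled" for r in reads)
            for mc in (1, 2, 3, 4)
        ]
        assert labels == sorted(labels, reverse=True)


class TestCountGene:
    def test_zero_reads_gives_zero_row(self):
        table = count_gene({"s1": []}, gene_ids=["gX"])
        row = table.set_index("gene_id").loc["gX"]
        assert (row[["total_reads", "labeled_reads", "unlabeled_reads"]] == 0).all()

    def test_definitional_totals(self):
        reads = [read_at(t=[1, 2], conv=[1, 2])] * 30 + [read_at(t=[1, 2], conv=[])] * 70
        table = count_gene({"s1": reads})
        row = table.iloc[0]
        assert (row.total_reads, row.labeled_reads, row.unlabeled_reads) == (100, 30, 70)

    def test_labeled_fraction_matches_sensitivity_oracle(self):
        # truth-zygotic fraction 0.5, p=0.3, n=20 T per read
        p, n = 0.3, 20
        spec = sd.GeneSpec(
            gene_id="g1",
            maternal_abundance_M0=100.0,
            maternal_decay_rate_base=0.0,
            zygotic_onset_h=0.0,
            zygotic_synthesis_rate=100.0,  # z(1)=100 with no zygotic decay
            zygotic_decay_rate_base=0.0,
            utr_sequence="T" * n,
        )
        design = sd.SampleDesign(
            sample_id="s1",
            condition="timecourse",
            timepoint_h=1.0,
            library_size=10_000,
            conversion_prob=p,
            error_prob=0.0,
        )
        reads, _ = sd.simulate_experiment([spec], [design], seed=21, read_length=n)
        sens = 1 - (1 - p) ** n - n * p * (1 - p) ** (n - 1)
        expected = 0.5 * sens
        table = count_gene(reads)
        rate = table["labeled_reads"].sum() / table["total_reads"].sum()
        se = math.sqrt(expected * (1 - expected) / 10_000)
        assert abs(rate - expected) < 3 * se


class TestConversionRate:
    def test_extremes(self):
        no_conv = count_gene({"s": [read_at(t=[1, 2, 3], conv=[])] * 5})
        assert conversion_rate_per_base(no_conv).loc["g"] == 0.0
        all_conv = count_gene({"s": [read_at(t=[1, 2, 3], conv=[1, 2, 3])] * 5})
        assert conversion_rate_per_base(all_conv).loc["g"] == 1.0

    def test_zero_covered_t_is_missing(self):
        table = count_gene({"s": [read_at(t=[], conv=[])]})
        assert np.isnan(conversion_rate_per_base(table).loc["g"])

    def test_background_rate_recovered(self):
        spec = make_single_gene("g1", maternal_abundance_M0=100.0, length=500)
        design = sd.SampleDesign(
            sample_id="s1",
            condition="noninjected",
            timepoint_h=6.0,
            library_size=5000,
            s4utp_dose_mM=0.0,
            error_prob=0.001,
        )
        reads, _ = sd.simulate_experiment([spec], [design], seed=13)
        table = count_gene(reads)
        rate = conversion_rate_per_base(table).loc["g1"]
        n_bases = table["covered_T_bases"].sum()
        se = math.sqrt(0.001 * 0.999 / n_bases)
        assert abs(rate - 0.001) < 3 * se
        assert count_false_positive_genes(conversion_rate_per_base(table)) == 0


def test_snp_recovery_from_controls():
    """Simulated SNP offsets with control coverage >= 7 are recovered with
    sensitivity 1; spurious calls stay at the binomial-tail level."""
    spec = make_single_gene("g1", maternal_abundance_M0=100.0, length=300, seed=5)
    t_offs = [i for i, b in enumerate(spec.utr_sequence) if b == "T"]
    snps = frozenset(t_offs[::10])
    spec.snp_positions = snps
    designs = sd.make_control_designs(replicates=3, library_size=8000)
    reads, _ = sd.simulate_experiment([spec], designs, seed=6)
    mask = call_snps(reads)
    # coverage at any offset is ~ lib * window/L >> 7
    assert snps <= mask.get("g1")
    false_calls = mask.get("g1") - snps
    assert len(false_calls) == 0  # P(binom(cov, 3e-4)/cov >= 0.15) ~ 0
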