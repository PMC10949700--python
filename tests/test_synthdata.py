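"""Generator checks: determinism, truth conservation, binomial oracles."""

import math

import numpy as np
import pytest

from slam_mzt import synthdata as sd
from slam_mzt.annot import scan_mir430_sites
from slam_mzt.conversion import SnpMask, count_gene

from conftest import make_single_gene


def _design(**kw):
    base = dict(
        sample_id="s1",
        condition="timecourse",
        timepoint_h=6.0,
        library_size=5000,
        s4utp_dose_mM=75.0,
    )
    base.update(kw)
    return sd.SampleDesign(**base)


class TestSimulateExperiment:
    def test_same_seed_is_byte_identical(self):
        specs = [make_single_gene("gA", zygotic_synthesis_rate=30.0, zygotic_onset_h=3.0)]
        designs = [_design()]
        r1, t1 = sd.simulate_experiment(specs, designs, seed=5)
        r2, t2 = sd.simulate_experiment(specs, designs, seed=5)
        assert r1 == r2
        assert t1.equals(t2)
        r3, _ = sd.simulate_experiment(specs, designs, seed=6)
        assert r1 != r3

    def test_amanitin_suppresses_zygotic_molecules(self):
        specs = [
            make_single_gene("gM", maternal_abundance_M0=50.0),
            make_single_gene(
                "gZ",
                mzt_class_truth="PZ",
                maternal_abundance_M0=0.0,
                zygotic_synthesis_rate=60.0,
                zygotic_onset_h=3.0,
                seed=1,
            ),
        ]
        reads, truth = sd.simulate_experiment(specs, [_design(condition="amanitin")], seed=2)
        assert not any(r.truth_labeled for r in reads["s1"])
        assert (truth["zygotic_expected"] == 0).all()
        # the pure-zygotic gene gets no reads at all without transcription
        assert truth.set_index("gene_id").loc["gZ", "n_reads"] == 0

    def test_zygotic_read_fraction_matches_binomial(self):
        # m = z at t: M0=100 no decay; k=50/h from 2 h -> z(4)=100
        spec = make_single_gene(
            "g1",
            maternal_abundance_M0=100.0,
            maternal_decay_rate_base=0.0,
            zygotic_onset_h=2.0,
            zygotic_synthesis_rate=50.0,
            zygotic_decay_rate_base=0.0,
        )
        design = _design(timepoint_h=4.0, library_size=10_000)
        reads, _ = sd.simulate_experiment([spec], [design], seed=11)
        frac = np.mean([r.truth_labeled for r in reads["s1"]])
        se = math.sqrt(0.25 / 10_000)
        assert abs(frac - 0.5) < 3 * se

    def test_read_conservation_and_window_invariants(self):
        specs = [
            make_single_gene("gA", zygotic_synthesis_rate=30.0, zygotic_onset_h=3.0),
            make_single_gene("gB", maternal_abundance_M0=20.0, seed=3),
        ]
        design = _design(library_size=3000)
        reads, truth = sd.simulate_experiment(specs, [design], seed=4)
        assert truth["n_reads"].sum() == 3000
        assert (truth["n_zygotic_reads"] <= truth["n_reads"]).all()
        by_gene = {s.gene_id: s for s in specs}
        for r in reads["s1"]:
            spec = by_gene[r.gene_id]
            assert 0 <= r.window_start < r.window_end <= len(spec.utr_sequence)
            allowed = set(r.t_positions) | set(spec.snp_positions)
            assert set(r.converted_positions) <= allowed

    def test_rejects_bad_inputs(self):
        good = make_single_gene("g1")
        with pytest.raises(ValueError):
            sd.simulate_experiment([good], [], seed=0)
        bad = make_single_gene("g2", maternal_decay_rate_base=-0.1)
        with pytest.raises(ValueError):
            sd.simulate_experiment([bad], [_design()], seed=0)
        empty = sd.GeneSpec(gene_id="g3", utr_sequence="")
        with pytest.raises(ValueError):
            sd.simulate_experiment([empty], [_design()], seed=0)


class TestMakeUtrSequence:
    def test_exact_8mer_fills_short_sequence(self):
        assert sd.make_utr_sequence(8, 0.5, ["8mer"], seed=3) == "AGCACTTA"

    def test_zero_t_fraction_has_no_t(self):
        seq = sd.make_utr_sequence(300, 0.0, (), seed=1)
        assert "T" not in seq

    def test_t_fraction_realised_within_tolerance(self):
        seq = sd.make_utr_sequence(1000, 0.25, (), seed=2)
        assert abs(seq.count("T") / 1000 - 0.25) < 0.05

    def test_embedded_motif_found_by_scanner(self):
        seq = sd.make_utr_sequence(1000, 0.25, ["7mer-M8"], seed=4)
        assert "AGCACTT" in seq
        assert len(scan_mir430_sites(seq)) >= 1

    def test_impossible_packing_rejected(self):
        with pytest.raises(ValueError):
            sd.make_utr_sequence(6, 0.3, ["8mer"], seed=0)
        with pytest.raises(ValueError):
            sd.make_utr_sequence(10, 0.3, ["8mer", "8mer"], seed=0)


class TestSpikeins:
    def test_equal_efficiency_equal_expectation(self):
        designs = [_design(sample_id=f"s{i}") for i in range(3)]
        counts = sd.emit_spikeins(designs, seed=1)
        totals = counts.sum(axis=0)
        se = math.sqrt(totals.mean())
        assert totals.max() - totals.min() < 6 * se

    def test_double_efficiency_doubles_totals(self):
        designs = [
            _design(sample_id="ref"),
            _design(sample_id="boost", spikein_efficiency=2.0),
        ]
        counts = sd.emit_spikeins(designs, seed=2)
        ratio = counts["boost"].sum() / counts["ref"].sum()
        assert abs(ratio - 2.0) < 0.1

    def test_zero_abundance_yields_zero_counts(self):
        catalog = {"ERCC-X": 0.0, "ERCC-Y": 100.0}
        counts = sd.emit_spikeins([_design()], catalog, seed=3)
        assert counts.loc["ERCC-X", "s1"] == 0
        assert counts.loc["ERCC-Y", "s1"] > 0


def test_labeling_sensitivity_closed_form():
    """Downstream labeled-call rate on truth-zygotic reads matches
    1-(1-p)^n - n p (1-p)^(n-1) for an all-T read window."""
    p, n = 0.3, 20
    spec = sd.GeneSpec(
        gene_id="g1",
        mzt_class_truth="PZ",
        maternal_abundance_M0=0.0,
        maternal_decay_rate_base=0.0,
        zygotic_onset_h=0.0,
        zygotic_synthesis_rate=10.0,
        zygotic_decay_rate_base=0.0,
        utr_sequence="T" * n,
    )
    design = sd.SampleDesign(
        sample_id="s1",
        condition="timecourse",
        timepoint_h=6.0,
        library_size=10_000,
        conversion_prob=p,
    )
    reads, _ = sd.simulate_experiment([spec], [design], seed=9, read_length=n)
    counts = count_gene(reads, SnpMask.empty())
    expected = 1 - (1 - p) ** n - n * p * (1 - p) ** (n - 1)
    rate = counts["labeled_reads"].sum() / counts["total_reads"].sum()
    se = math.sqrt(expected * (1 - expected) / 10_000)
    assert abs(rate - expected) < 3 * se


def test_dose_monotonic_conversion_rates():
    """Mean per-base conversion rate strictly increases with the analog dose."""
    specs = [
        make_single_gene("g1", zygotic_synthesis_rate=50.0, zygotic_onset_h=1.0, seed=i)
        for i in range(3)
    ]
    designs = sd.make_dose_series_designs(replicates=1, library_size=4000)
    reads, _ = sd.simulate_experiment(specs, designs, seed=3)
    rates = []
    for d in designs:
        counts = count_gene({d.sample_id: reads[d.sample_id]}, SnpMask.empty())
        rates.append(counts["conversion_events"].sum() / counts["covered_T_bases"].sum())
    assert rates[0] < rates[1] < rates[2]
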