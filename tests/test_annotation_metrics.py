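import numpy as np
import pandas as pd
import pytest

import circadyn as cd
from circadyn.annotation_metrics import (assign_starts, element_oe,
                                         intron_exon_proportions,
                                         partition_labels, repeat_ratio)
from circadyn.io_formats import AnnotationSet

from conftest import SEED, make_catalog


def _annot(rows):
    return AnnotationSet(df=pd.DataFrame(
        rows, columns=["chrom", "start", "end", "track", "label", "parent"]))


class TestAssignStarts:
    def test_independent_tracks_both_label(self):
        annot = _annot([("c", 100, 200, "element", "exon", "gA"),
                        ("c", 50, 300, "element", "CpG", "")])
        cat = make_catalog("c", [150], [180])
        assert assign_starts(cat, annot, "element") == [{"exon", "CpG"}]

    def test_unannotated_start_empty(self):
        annot = _annot([("c", 100, 200, "element", "exon", "gA")])
        cat = make_catalog("c", [500], [600])
        assert assign_starts(cat, annot, "element") == [set()]

    def test_half_open_end_not_contained(self):
        annot = _annot([("c", 100, 200, "element", "exon", "gA")])
        cat = make_catalog("c", [200, 199, 100], [300, 300, 300])
        labels = assign_starts(cat, annot, "element")
        assert labels == [set(), {"exon"}, {"exon"}]


class TestElementOE:
    def test_formula_arithmetic(self):
        # exon spans 3% of a 100 kb genome; place 15% of starts inside
        genome = {"c": "A" * 100_000}
        annot = _annot([("c", 0, 3000, "element", "exon", "gA")])
        starts = np.concatenate([np.linspace(0, 2900, 15).astype(int),
                                 np.linspace(3000, 99_000, 85).astype(int)])
        cat = make_catalog("c", starts, starts + 50)
        tab = element_oe(cat, annot, genome, labels=("exon",)).iloc[0]
        assert tab["observed"] == pytest.approx(0.15)
        assert tab["expected"] == pytest.approx(0.03)
        assert tab["ratio"] == pytest.approx(5.0)

    def test_all_starts_in_introns(self):
        genome = {"c": "A" * 10_000}
        annot = _annot([("c", 0, 1000, "element", "intron", "gA"),
                        ("c", 2000, 3000, "element", "exon", "gA")])
        starts = np.arange(0, 1000, 100)
        cat = make_catalog("c", starts, starts + 10)
        tab = element_oe(cat, annot, genome,
                         labels=("exon", "intron")).set_index("label")
        assert tab.loc["intron", "observed"] == 1.0
        assert tab.loc["exon", "observed"] == 0.0

    def test_zero_span_class_flagged_undefined(self):
        genome = {"c": "A" * 10_000}
        annot = _annot([("c", 0, 1000, "element", "intron", "gA")])
        cat = make_catalog("c", [10], [60])
        tab = element_oe(cat, annot, genome,
                         labels=("exon",)).set_index("label")
        assert bool(tab.loc["exon", "undefined"])
        assert np.isnan(tab.loc["exon", "ratio"])

    def test_uniform_null_ratios_near_one(self, toy_genome):
        genome, annot = toy_genome
        rng = np.random.default_rng(SEED)
        names = list(genome.contigs)
        n = 200_000
        ci = rng.integers(0, len(names), n)
        lens = np.array([len(genome.contigs[c]) for c in names])
        starts = rng.integers(0, lens[ci] - 1)
        cat = make_catalog([names[i] for i in ci], starts, starts + 1)
        el = element_oe(cat, annot, genome)
        assert ((el["ratio"] > 0.95) & (el["ratio"] < 1.05)).all()
        rp = repeat_ratio(cat, annot, genome)
        assert ((rp["ratio"] > 0.9) & (rp["ratio"] < 1.1)).all()


class TestRepeatRatio:
    def test_formula(self):
        genome = {"c": "A" * 100_000}
        annot = _annot([("c", 0, 10_000, "repeat", "SINE", ""),
                        ("c", 20_000, 30_000, "repeat", "LINE", "")])
        starts = np.concatenate([
            np.linspace(0, 9_900, 10).astype(int),       # 10% in SINE
            np.linspace(20_000, 29_900, 20).astype(int),  # 20% in LINE
            np.linspace(40_000, 99_000, 70).astype(int)])
        cat = make_catalog("c", starts, starts + 10)
        tab = repeat_ratio(cat, annot, genome).set_index("label")
        assert tab.loc["SINE", "ratio"] == pytest.approx(1.0)
        assert tab.loc["LINE", "ratio"] == pytest.approx(2.0)

    def test_empty_repeat_track_no_crash(self):
        genome = {"c": "A" * 10_000}
        annot = _annot([("c", 0, 100, "element", "exon", "gA")])
        cat = make_catalog("c", [10], [60])
        assert len(repeat_ratio(cat, annot, genome)) == 0

    def test_read_interval_input(self):
        genome = {"c": "A" * 10_000}
        annot = _annot([("c", 0, 1000, "repeat", "SINE", "")])
        reads = pd.DataFrame({"chrom": ["c"] * 10,
                              "start": np.arange(0, 5000, 500),
                              "end": np.arange(100, 5100, 500)})
        tab = repeat_ratio(reads, annot, genome).set_index("label")
        # 2 of 10 read starts inside the 10%-of-genome SINE span
        assert tab.loc["SINE", "ratio"] == pytest.approx(2.0)


class TestIntronExon:
    def test_all_exonic(self):
        annot = _annot([("c", 0, 1000, "element", "exon", "gA")])
        starts = np.arange(0, 1000, 100)
        cat = make_catalog("c", starts, starts + 10)
        assert intron_exon_proportions(cat, annot) == (1.0, 0.0)

    def test_utr_overlapping_exon_counts_once(self):
        annot = _annot([("c", 0, 1000, "element", "exon", "gA"),
                        ("c", 0, 1000, "element", "5UTR", "gA")])
        cat = make_catalog("c", [100], [200])
        exon_f, _ = intron_exon_proportions(cat, annot)
        assert exon_f == 1.0

    def test_partition_mode_sums_to_one(self, catalog_50k, toy_genome):
        _, annot = toy_genome
        labels = partition_labels(catalog_50k, annot)
        fracs = pd.Series(labels).value_counts(normalize=True)
        assert fracs.sum() == pytest.approx(1.0)
        exon_f, intron_f = intron_exon_proportions(catalog_50k, annot,
                                                   mode="partition")
        assert exon_f == pytest.approx(fracs.get("exon", 0.0))
        assert intron_f == pytest.approx(fracs.get("intron", 0.0))

    def test_default_catalog_hits_configured_fraction(self, catalog_50k,
                                                      toy_genome,
                                                      calibrated_config):
        _, annot = toy_genome
        exon_f, _ = intron_exon_proportions(catalog_50k, annot)
        assert abs(exon_f - calibrated_config.exon_start_fraction) <= 0.01


def test_oe_stable_under_subsampling(catalog_50k, toy_genome):
    """O/E is invariant in expectation under uniform subsampling."""
    genome, annot = toy_genome
    full = element_oe(catalog_50k, annot, genome).set_index("label")
    rng = np.random.default_rng(SEED)
    idx = rng.choice(len(catalog_50k.df), size=10_000, replace=False)
    sub = cd.Catalog(sample_id="sub",
                     df=catalog_50k.df.iloc[np.sort(idx)].reset_index(drop=True),
                     total_mapped_reads=catalog_50k.total_mapped_reads)
    subtab = element_oe(sub, annot, genome).set_index("label")
    for lab in full.index:
        o, n = full.loc[lab, "observed"], 10_000
        sd = np.sqrt(max(o * (1 - o), 1e-12) / n)
        assert abs(subtab.loc[lab, "observed"] - o) <= 3 * sd + 1e-9
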