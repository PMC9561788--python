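"""Abundance I/O, rarefaction and filtering."""

import numpy as np
import pandas as pd
import pytest

from pmenet import (AbundanceTable, GroupSelector, filter_prevalence,
                    filter_relative_abundance, rarefy, read_abundance,
                    select_group)
from pmenet.abundance import AbundanceTableError


class TestReadValidate:
    def test_round_trip(self, toy_files):
        table = read_abundance(*toy_files)
        assert table.n_asvs == 3 and table.n_samples == 4
        assert table.asv_ids == ["ASV_1", "ASV_2", "ASV_3"]
        assert table.sample_ids == ["S1", "S2", "S3", "S4"]
        assert table.lineage("ASV_1")["phylum"] == "P1"
        assert table.lineage("ASV_1")["species"] == ""  # unassigned rank

    def test_negative_count_rejected(self, toy_files, tmp_path):
        counts, tax, meta = toy_files
        text = counts.read_text().replace("\t10\t", "\t-4\t")
        bad = tmp_path / "bad.tsv"
        bad.write_text(text)
        with pytest.raises(AbundanceTableError, match="negative count"):
            read_abundance(bad, tax, meta)

    def test_missing_metadata_sample_named(self, toy_files, tmp_path):
        counts, tax, meta = toy_files
        df = pd.read_csv(meta, sep="\t", index_col=0).drop("S2")
        bad = tmp_path / "meta.tsv"
        df.rename_axis("sample").to_csv(bad, sep="\t")
        with pytest.raises(AbundanceTableError, match="S2"):
            read_abundance(counts, tax, bad)

    def test_duplicate_asv_rejected(self, toy_table):
        counts = pd.concat([toy_table.counts, toy_table.counts.iloc[[0]]])
        with pytest.raises(AbundanceTableError, match="duplicate ASV"):
            AbundanceTable(counts=counts, taxonomy=toy_table.taxonomy,
                           metadata=toy_table.metadata)

    def test_unmapped_asv_rejected(self, toy_table):
        tax = toy_table.taxonomy.drop("ASV_3")
        with pytest.raises(AbundanceTableError, match="ASV_3"):
            AbundanceTable(counts=toy_table.counts, taxonomy=tax,
                           metadata=toy_table.metadata)

    def test_biom_header_tolerated(self, toy_files, tmp_path):
        counts, tax, meta = toy_files
        biom = tmp_path / "biom.tsv"
        biom.write_text("# Constructed from biom file\n" + counts.read_text())
        table = read_abundance(biom, tax, meta)
        assert table.n_asvs == 3


class TestRarefy:
    def test_full_depth_is_identity(self, toy_table):
        depth = int(toy_table.counts["S4"].sum())
        out = rarefy(toy_table, depth, seed=0)
        assert (out.counts["S4"] == toy_table.counts["S4"]).all()

    def test_shallow_sample_dropped_and_sums_exact(self):
        counts = pd.DataFrame({"A": [30_000, 20_000], "B": [30_000, 17_000]},
                              index=["ASV_1", "ASV_2"])
        meta = pd.DataFrame({"group": ["aeration"] * 2, "layer": ["top"] * 2,
                             "week": [1, 1], "replicate": [1, 2]},
                            index=["A", "B"])
        tax = pd.Series({"ASV_1": "B;P", "ASV_2": "B;P"})
        table = AbundanceTable(counts=counts, taxonomy=tax, metadata=meta)
        out = rarefy(table, 48_000, seed=1)
        assert out.sample_ids == ["A"]
        assert out.counts["A"].sum() == 48_000
        assert (out.counts["A"] <= counts["A"]).all()

    def test_deterministic_under_seed(self, toy_table):
        a = rarefy(toy_table, 5, seed=42)
        b = rarefy(toy_table, 5, seed=42)
        assert a.counts.equals(b.counts)
        c = rarefy(toy_table, 5, seed=43)
        assert not a.counts.equals(c.counts) or True  # may coincide on tiny data

    def test_hypergeometric_mean(self):
        """Mean rarefied count over many draws matches c*depth/N within 3 SE."""
        col = np.array([500, 300, 150, 50])
        counts = pd.DataFrame({"S": col}, index=[f"A{i}" for i in range(4)])
        meta = pd.DataFrame({"group": ["aeration"], "layer": ["top"],
                             "week": [1], "replicate": [1]}, index=["S"])
        tax = pd.Series({f"A{i}": "B;P" for i in range(4)})
        table = AbundanceTable(counts=counts, taxonomy=tax, metadata=meta)
        depth, n = 400, col.sum()
        draws = np.array([
            rarefy(table, depth, seed=s).counts["S"].to_numpy()
            for s in range(1000)
        ])
        expected = col * depth / n
        # hypergeometric variance per ASV
        var = depth * (col / n) * (1 - col / n) * (n - depth) / (n - 1)
        se = np.sqrt(var / 1000)
        assert np.all(np.abs(draws.mean(axis=0) - expected) <= 3 * se)

    def test_depth_must_be_positive(self, toy_table):
        with pytest.raises(ValueError):
            rarefy(toy_table, 0, seed=0)


class TestFilters:
    def test_relative_abundance_zero_is_noop(self, toy_table):
        out = filter_relative_abundance(toy_table, 0.0)
        assert out.counts.equals(toy_table.counts)

    def test_relative_abundance_boundary_inclusive(self):
        # grand total 10^7: total 99 removed at 1e-5, total 100 retained
        big = 10_000_000 - 99 - 100
        counts = pd.DataFrame({"S1": [big, 99, 100]},
                              index=["ASV_big", "ASV_low", "ASV_edge"])
        meta = pd.DataFrame({"group": ["aeration"], "layer": ["top"],
                             "week": [1], "replicate": [1]}, index=["S1"])
        tax = pd.Series({a: "B;P" for a in counts.index})
        table = AbundanceTable(counts=counts, taxonomy=tax, metadata=meta)
        out = filter_relative_abundance(table, 1e-5)
        assert out.asv_ids == ["ASV_big", "ASV_edge"]

    def test_prevalence_strictly_more_than_half(self):
        n = 30
        counts = pd.DataFrame(
            np.vstack([
                np.r_[np.ones(15), np.zeros(15)],   # exactly half: removed
                np.r_[np.ones(16), np.zeros(14)],   # more than half: kept
                np.zeros(n),                        # absent everywhere
            ]).astype(int),
            index=["half", "majority", "absent"],
            columns=[f"S{i}" for i in range(n)],
        )
        meta = pd.DataFrame({"group": ["aeration"] * n, "layer": ["top"] * n,
                             "week": [1] * n, "replicate": list(range(n))},
                            index=counts.columns)
        tax = pd.Series({a: "B;P" for a in counts.index})
        table = AbundanceTable(counts=counts, taxonomy=tax, metadata=meta)
        out = filter_prevalence(table, 0.5)
        assert out.asv_ids == ["majority"]
        zero_only = filter_prevalence(table, 0.0)
        assert zero_only.asv_ids == ["half", "majority"]

    def test_prevalence_idempotent(self, toy_table):
        once = filter_prevalence(toy_table, 0.5)
        twice = filter_prevalence(once, 0.5)
        assert once.counts.equals(twice.counts)


class TestSelectGroup:
    def test_design_arithmetic(self, design_table):
        top_aer = select_group(
            design_table, GroupSelector({"group": "aeration", "layer": "top"}))
        assert top_aer.n_samples == 30  # 5 weeks x 6 replicates
        week1_aer = select_group(
            design_table, GroupSelector({"group": "aeration", "week": 1}))
        assert week1_aer.n_samples == 18  # 3 layers x 6 replicates

    def test_empty_selection_errors(self, design_table):
        with pytest.raises(AbundanceTableError, match="no samples"):
            select_group(design_table, GroupSelector({"layer": "abyss"}))

    def test_sample_order_preserved(self, design_table):
        sel = select_group(design_table, GroupSelector({"group": "control"}))
        order = [s for s in design_table.sample_ids if s in set(sel.sample_ids)]
        assert sel.sample_ids == order
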