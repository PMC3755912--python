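import numpy as np
import pytest

from birthsize import distio
from birthsize.distio import (PanelFormatError, PhenotypeRecord,
                              SizeDistribution)

from util import random_distribution


def write_matrix(path, header, rows):
    lines = ["\t".join(header)]
    lines += ["\t".join(str(v) for v in row) for row in rows]
    path.write_text("\n".join(lines) + "\n")


class TestReadDistributionMatrix:
    def test_direct_readback(self, tmp_path):
        f = tmp_path / "panel.tsv"
        write_matrix(f, ["bin_fl", "YAL001C"], [[20, 1], [21, 2], [22, 1]])
        records = distio.read_distribution_matrix(f)
        assert len(records) == 1
        rec = records[0]
        assert rec.orf == "YAL001C"
        assert rec.role == distio.ROLE_MUTANT
        assert rec.distribution.total_count == 4

    def test_wildtype_role_from_id_list(self, tmp_path):
        f = tmp_path / "panel.tsv"
        write_matrix(f, ["bin_fl", "WT1", "YAL001C"],
                     [[20, 5, 1], [21, 9, 2], [22, 3, 1]])
        records = distio.read_distribution_matrix(f, wildtype_ids=["WT1"])
        roles = {r.orf: r.role for r in records}
        assert roles == {"WT1": distio.ROLE_WILD_TYPE,
                         "YAL001C": distio.ROLE_MUTANT}

    def test_non_monotone_grid_rejected(self, tmp_path):
        f = tmp_path / "panel.tsv"
        write_matrix(f, ["bin_fl", "A"], [[22, 1], [21, 2], [20, 1]])
        with pytest.raises(PanelFormatError, match="increasing"):
            distio.read_distribution_matrix(f)

    def test_duplicate_strain_rejected(self, tmp_path):
        f = tmp_path / "panel.tsv"
        write_matrix(f, ["bin_fl", "A", "A"], [[20, 1, 1], [21, 2, 2],
                                               [22, 1, 1]])
        with pytest.raises(PanelFormatError, match="duplicate"):
            distio.read_distribution_matrix(f)

    def test_non_numeric_cell_rejected(self, tmp_path):
        f = tmp_path / "panel.tsv"
        write_matrix(f, ["bin_fl", "A"], [[20, 1], [21, "oops"], [22, 1]])
        with pytest.raises(PanelFormatError):
            distio.read_distribution_matrix(f)

    def test_all_zero_column_flagged_not_dropped(self, tmp_path):
        f = tmp_path / "panel.tsv"
        write_matrix(f, ["bin_fl", "A", "B"], [[20, 1, 0], [21, 2, 0],
                                               [22, 1, 0]])
        records = distio.read_distribution_matrix(f)
        assert len(records) == 2
        flags = {r.orf: r.flags for r in records}
        assert flags["A"] == [] and flags["B"] == ["all_zero"]

    @pytest.mark.parametrize("suffix", [".tsv", ".csv"])
    def test_roundtrip_bit_exact(self, tmp_path, suffix):
        rng = np.random.default_rng(5)
        dist = random_distribution(rng)
        records = [
            distio.StrainRecord(f"S{i}", distio.ROLE_MUTANT, dist)
            for i in range(3)
        ]
        f = tmp_path / f"panel{suffix}"
        distio.write_distribution_matrix(records, f)
        back = distio.read_distribution_matrix(f)
        for a, b in zip(records, back):
            assert a.orf == b.orf
            np.testing.assert_array_equal(a.distribution.bin_sizes,
                                          b.distribution.bin_sizes)
            np.testing.assert_array_equal(a.distribution.counts,
                                          b.distribution.counts)

    def test_xlsx_same_layout(self, tmp_path):
        pd = pytest.importorskip("pandas")
        f = tmp_path / "panel.xlsx"
        pd.DataFrame({"bin_fl": [20, 21, 22], "A": [1, 2, 1]}).to_excel(
            f, sheet_name="asynchronous", index=False)
        records = distio.read_distribution_matrix(f, sheet="asynchronous")
        assert records[0].distribution.total_count == 4


class TestSizeDistribution:
    def test_frequencies_sum_to_one(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            dist = random_distribution(rng)
            assert dist.frequencies().sum() == pytest.approx(1.0, abs=1e-9)

    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            SizeDistribution([20, 21], [1, 1])  # too few bins
        with pytest.raises(ValueError):
            SizeDistribution([20, 21, 22], [1, -1, 1])

    def test_bin_interval_last_uses_preceding(self):
        d = SizeDistribution([20.0, 20.5, 21.5], [1, 1, 1])
        assert d.bin_interval(0) == 0.5
        assert d.bin_interval(1) == 1.0
        assert d.bin_interval(2) == 1.0  # no successor: preceding interval


class TestPhenotypeTable:
    def test_full_row_readback(self, tmp_path):
        f = tmp_path / "phen.tsv"
        f.write_text("orf\tmean_size\tfitness_rank\tpct_g1\n"
                     "YAL001C\t42.0\t3\t28.5\n")
        (rec,) = distio.read_phenotype_table(f)
        assert rec == PhenotypeRecord("YAL001C", 42.0, 3, 28.5)

    def test_blank_fitness_is_missing_not_error(self, tmp_path):
        f = tmp_path / "phen.tsv"
        f.write_text("orf\tmean_size\tfitness_rank\tpct_g1\n"
                     "YAL001C\t42.0\t\t28.5\n")
        (rec,) = distio.read_phenotype_table(f)
        assert rec.fitness_rank is None
        assert rec.mean_size_published == 42.0

    def test_out_of_range_fitness_rejected_with_diagnostic(self, tmp_path,
                                                           caplog):
        f = tmp_path / "phen.tsv"
        f.write_text("orf\tfitness_rank\nYAL001C\t25\nYAL002W\t21\n")
        with caplog.at_level("WARNING"):
            records = distio.read_phenotype_table(f)
        assert [r.orf for r in records] == ["YAL002W"]
        assert "rejected" in caplog.text

    def test_missing_required_column_is_hard_error(self, tmp_path):
        f = tmp_path / "phen.tsv"
        f.write_text("gene\tfitness_rank\nYAL001C\t3\n")
        with pytest.raises(PanelFormatError, match="orf"):
            distio.read_phenotype_table(f)
        # but resolvable through the column map
        records = distio.read_phenotype_table(f, column_map={"orf": "gene"})
        assert records[0].orf == "YAL001C"


class TestJoinPanel:
    def _dists(self, orfs):
        d = SizeDistribution([20, 21, 22], [1, 2, 1])
        return [distio.StrainRecord(o, distio.ROLE_MUTANT, d) for o in orfs]

    def test_left_join_with_misses(self):
        phen = [PhenotypeRecord("A", 40.0), PhenotypeRecord("B", 41.0)]
        joined = distio.join_panel(self._dists(["A", "B", "C"]), phen)
        assert len(joined) == 3
        assert joined[0].phenotypes.mean_size_published == 40.0
        assert joined[2].phenotypes is None

    def test_empty_phenotypes(self):
        joined = distio.join_panel(self._dists(["A", "B"]), [])
        assert all(r.phenotypes is None for r in joined)

    def test_duplicate_phenotype_orf_is_hard_error(self):
        phen = [PhenotypeRecord("A", 40.0), PhenotypeRecord("A", 41.0)]
        with pytest.raises(PanelFormatError, match="duplicate"):
            distio.join_panel(self._dists(["A"]), phen)

    def test_join_order_independent(self):
        phen = [PhenotypeRecord("A", 40.0), PhenotypeRecord("C", 42.0)]
        a = distio.join_panel(self._dists(["A", "B", "C"]), phen)
        b = distio.join_panel(self._dists(["C", "B", "A"]), phen[::-1])
        by_orf_a = {r.orf: r.phenotypes for r in a}
        by_orf_b = {r.orf: r.phenotypes for r in b}
        assert by_orf_a == by_orf_b


class TestValidateBinGrid:
    def test_interval_arithmetic(self):
        d = SizeDistribution([20.0, 20.5, 21.5], [1, 1, 1])
        recs = [distio.StrainRecord("A", distio.ROLE_MUTANT, d)]
        report = distio.validate_bin_grid(recs)
        assert report.min_interval == 0.5
        assert report.max_interval == 1.0
        assert report.n_bins == 3

    def test_uniform_grid(self):
        d = SizeDistribution([20.0, 21.0, 22.0, 23.0], [1, 1, 1, 1])
        recs = [distio.StrainRecord("A", distio.ROLE_MUTANT, d)]
        report = distio.validate_bin_grid(recs)
        assert report.min_interval == report.max_interval == 1.0

    def test_mismatched_grids_rejected(self):
        d1 = SizeDistribution([20, 21, 22], [1, 1, 1])
        d2 = SizeDistribution([20, 21, 23], [1, 1, 1])
        recs = [distio.StrainRecord("A", distio.ROLE_MUTANT, d1),
                distio.StrainRecord("B", distio.ROLE_MUTANT, d2)]
        with pytest.raises(PanelFormatError):
            distio.validate_bin_grid(recs)
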