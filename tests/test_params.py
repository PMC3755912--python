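import numpy as np
import pytest

from birthsize import params
from birthsize.distio import ROLE_MUTANT, SizeDistribution, StrainRecord
from birthsize.params import (AbnormalProfileError, QC_ABNORMAL,
                              QC_MANUAL_EXCLUDED, QC_PASS, SupportConfig)

from util import brute_force_birth_size, random_distribution, split_half_bins


def dist(bins, counts):
    return SizeDistribution(np.asarray(bins, float), np.asarray(counts, float))


class TestDetectSupport:
    def test_clean_profile_support_is_positive_range(self):
        d = dist(range(18, 27), [0, 0, 5, 9, 12, 7, 3, 1, 0])
        assert params.detect_support(d, SupportConfig()) == (20.0, 25.0)

    def test_isolated_debris_spike_fails_consecutive_rule(self):
        # a large low-channel spike separated by empty bins is noise even
        # though it clears the count threshold on its own
        d = dist(range(18, 26), [40, 0, 0, 5, 9, 12, 7, 3])
        x0, xy = params.detect_support(d, SupportConfig(alpha=0.01, k=3))
        assert x0 == 21.0
        assert xy == 25.0

    def test_spike_rule_matches_exhaustive_candidate_scan(self):
        # independently enumerate candidate start bins for the spike case
        d = dist(range(18, 26), [40, 0, 0, 5, 9, 12, 7, 3])
        cfg = SupportConfig(alpha=0.01, k=3)
        thr = cfg.alpha * max(d.counts)
        candidates = [
            b for i, b in enumerate(d.bin_sizes)
            if all(c >= thr for c in d.counts[i:i + cfg.k])
        ]
        assert params.detect_support(d, cfg)[0] == min(candidates)

    def test_manual_override_wins(self):
        d = dist(range(18, 26), [40, 0, 0, 5, 9, 12, 7, 3])
        cfg = SupportConfig(manual_overrides={"A": (19.0, 24.0)})
        assert params.detect_support(d, cfg, orf="A") == (19.0, 24.0)

    def test_unsatisfiable_rule_is_abnormal(self):
        d = dist([20, 21, 22], [0, 0, 1])
        with pytest.raises(AbnormalProfileError):
            params.detect_support(d, SupportConfig(k=3))


class TestFindMode:
    def test_unique_argmax(self):
        d = dist([20, 21, 22, 23], [5, 9, 12, 7])
        assert params.find_mode(d, 20, 23) == 22.0

    def test_tie_breaks_to_smallest_bin(self):
        d = dist([20, 21, 22, 23], [5, 12, 12, 7])
        assert params.find_mode(d, 20, 23) == 21.0

    def test_mode_at_support_start_has_no_daughter_range(self):
        d = dist([20, 21, 22], [12, 5, 3])
        with pytest.raises(AbnormalProfileError):
            params.find_mode(d, 20, 22)

    def test_smoothing_still_reports_on_original_grid(self):
        d = dist([20, 21, 22, 23, 24], [2, 9, 8, 9.5, 1])
        raw = params.find_mode(d, 20, 24)
        smoothed = params.find_mode(d, 20, 24, smoothing_window=3)
        assert raw == 23.0
        assert smoothed in d.bin_sizes


class TestBirthSize:
    def test_hand_run_cumulative(self):
        # threshold 0.2 * 20 = 4; cumulative 2, 5 -> second bin
        d = dist([20, 21, 22, 23], [2, 3, 5, 10])
        assert params.birth_size(d, 20, 23, 0.20) == 21.0

    def test_single_occupied_bin_forces_xb(self):
        d = dist([29, 30, 31], [0, 7, 0])
        for q in (0.10, 0.15, 0.20, 0.25):
            assert params.birth_size(d, 29, 30, q) == 30.0

    def test_zero_daughter_count_is_abnormal(self):
        d = dist([20, 21, 22, 23], [0, 0, 0, 5])
        with pytest.raises(AbnormalProfileError):
            params.birth_size(d, 20, 22, 0.2)

    def test_threshold_equality_counts(self):
        # cumulative hits the threshold exactly: ">=" includes that bin
        d = dist([20, 21, 22, 23], [1, 1, 1, 1])
        assert params.birth_size(d, 20, 23, 0.25) == 20.0


class TestMeanSize:
    def test_single_bin_identity(self):
        d = dist([39, 40, 41], [0, 7, 0])
        assert params.mean_size(d, 39, 41) == 40.0

    def test_symmetry(self):
        d = dist([20, 30, 40], [3, 0, 3])
        assert params.mean_size(d, 20, 40) == 30.0

    def test_weighted_mean_by_hand(self):
        d = dist([20, 22, 24], [1, 0, 3])
        assert params.mean_size(d, 20, 24) == (20 + 3 * 24) / 4

    def test_noise_outside_support_excluded(self):
        d = dist([10, 20, 22, 24], [100, 1, 0, 3])
        assert params.mean_size(d, 20, 24) == 23.0
        assert params.mean_size(d, 10, 24, over_support=False) < 23.0


class TestExtractParameters:
    def rec(self, d, orf="A"):
        return StrainRecord(orf, ROLE_MUTANT, d)

    def test_well_formed_distribution_passes_with_invariants(self):
        d = dist(range(18, 28), [0, 1, 5, 9, 12, 9, 6, 3, 1, 0])
        p = params.extract_parameters(self.rec(d))
        assert p.qc == QC_PASS
        for q, xb in p.xb.items():
            assert p.x0 <= xb <= p.xd <= p.xy
        assert p.x0 <= p.xm <= p.xy
        qs = sorted(p.xb)
        assert all(p.xb[a] <= p.xb[b] for a, b in zip(qs, qs[1:]))

    def test_monotone_decreasing_profile_is_abnormal(self):
        d = dist([20, 21, 22, 23], [12, 8, 4, 1])
        p = params.extract_parameters(self.rec(d))
        assert p.qc == QC_ABNORMAL
        assert p.x0 is not None  # earlier stages retained for diagnostics

    def test_exclusion_list_gives_manual_excluded(self):
        d = dist(range(18, 28), [0, 1, 5, 9, 12, 9, 6, 3, 1, 0])
        cfg = SupportConfig(exclusion_list=frozenset({"A"}))
        assert params.extract_parameters(self.rec(d), cfg).qc == \
            QC_MANUAL_EXCLUDED

    def test_error_bound_is_local_grid_interval(self):
        # interval at the xb bin is 0.5 fl on this grid
        d = dist([20.0, 20.5, 21.5, 23.0], [2, 3, 5, 10])
        p = params.extract_parameters(self.rec(d), cutoffs=(0.20,))
        assert p.xb[0.20] == 20.5
        assert p.err["xb_20"] == 1.0  # 21.5 - 20.5
        assert p.err["x0"] == 0.5  # 20.5 - 20.0


class TestProperties:
    """Randomised invariants of the extraction pipeline."""

    def _passing(self, n, seed):
        rng = np.random.default_rng(seed)
        out = []
        while len(out) < n:
            d = random_distribution(rng)
            rec = StrainRecord("X", ROLE_MUTANT, d)
            p = params.extract_parameters(rec)
            if p.qc == QC_PASS:
                out.append((d, p))
        return out

    def test_birth_size_equals_brute_force_oracle(self):
        for d, p in self._passing(200, seed=42):
            for q in (0.10, 0.15, 0.20, 0.25):
                assert p.xb[q] == brute_force_birth_size(d, p.x0, p.xd, q)

    def test_ordering_and_monotonicity(self):
        for d, p in self._passing(200, seed=7):
            xbs = [p.xb[q] for q in sorted(p.xb)]
            assert xbs == sorted(xbs)
            assert p.x0 <= xbs[0] and xbs[-1] <= p.xd <= p.xy
            assert p.x0 <= p.xm <= p.xy

    def test_zero_count_padding_outside_support_changes_nothing(self):
        for d, p in self._passing(60, seed=3):
            step = float(d.bin_sizes[1] - d.bin_sizes[0])
            bins = np.concatenate((
                [d.bin_sizes[0] - 2 * step, d.bin_sizes[0] - step],
                d.bin_sizes,
                [d.bin_sizes[-1] + step],
            ))
            counts = np.concatenate(([0.0, 0.0], d.counts, [0.0]))
            p2 = params.extract_parameters(
                StrainRecord("X", ROLE_MUTANT, SizeDistribution(bins, counts)))
            assert p2.qc == QC_PASS
            assert (p2.x0, p2.xd, p2.xm, p2.xy) == (p.x0, p.xd, p.xm, p.xy)
            assert p2.xb == p.xb

    def test_half_bin_refinement_moves_parameters_at_most_one_interval(self):
        for d, p in self._passing(60, seed=19):
            p2 = params.extract_parameters(
                StrainRecord("X", ROLE_MUTANT, split_half_bins(d)))
            if p2.qc != QC_PASS:
                continue
            max_step = float(np.diff(d.bin_sizes).max())
            assert abs(p2.x0 - p.x0) <= max_step
            assert abs(p2.xd - p.xd) <= max_step
            assert abs(p2.xm - p.xm) <= max_step
            for q in p.xb:
                assert abs(p2.xb[q] - p.xb[q]) <= max_step


def test_params_table_layout(planted_panel):
    _, records, _ = planted_panel
    table = params.params_table(records)
    assert {"orf", "x0", "xd", "xb_20", "xm", "xy", "qc"} <= set(table.columns)
    assert len(table) == len(records)
    assert (table["qc"] == QC_PASS).all()


def test_qc_bookkeeping_conserves_strains(planted_panel):
    _, records, _ = planted_panel
    qc = params.qc_summary(records)
    assert qc["ingested"] == (qc[QC_PASS] + qc[QC_ABNORMAL]
                              + qc[QC_MANUAL_EXCLUDED])
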