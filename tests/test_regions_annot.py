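import numpy as np
import pytest
from scipy import stats

from xvar.regions_annot import (
    Region,
    annotate_cgi,
    annotate_xci,
    call_regions,
    count_distinct_loci,
    enrichment_test,
    merge_intervals,
    meth_category,
    read_bed_intervals,
)


def brute_force_regions(sig, allp, max_gap=1000, max_nonsig=3, min_members=3):
    """Independent oracle: enumerate all valid windows from scratch and take
    the leftmost-maximal disjoint ones."""
    sig = list(map(int, sig))
    nonsig = sorted(set(map(int, allp)) - set(sig))

    def valid(i, j):
        if j - i + 1 < min_members:
            return False
        if any(sig[k + 1] - sig[k] > max_gap for k in range(i, j)):
            return False
        inside = sum(1 for p in nonsig if sig[i] < p < sig[j])
        return inside <= max_nonsig

    out = []
    i = 0
    while i < len(sig):
        best_j = None
        for j in range(len(sig) - 1, i + 1, -1):
            if valid(i, j):
                best_j = j
                break
        if best_j is None:
            i += 1
        else:
            out.append((sig[i], sig[best_j], tuple(sig[i:best_j + 1])))
            i = best_j + 1
    return out


class TestCallRegions:
    def test_three_close_cpgs_form_one_region(self):
        regs = call_regions([100, 600, 1100], [100, 600, 1100])
        assert len(regs) == 1
        assert (regs[0].start, regs[0].end, regs[0].n_members) == (100, 1100, 3)

    def test_two_distant_cpgs_no_region(self):
        assert call_regions([100, 1200], [100, 1200]) == []

    def test_gap_rule_breaks_region(self):
        # 4 non-significant CpGs between the first two members exceed the
        # allowance, so no region of 3 can form
        sig = [100, 300, 500]
        allp = [100, 150, 200, 220, 260, 300, 500]
        assert call_regions(sig, allp) == []
        # with only 3 intervening CpGs the region survives
        allp_ok = [100, 150, 200, 260, 300, 500]
        regs = call_regions(sig, allp_ok)
        assert len(regs) == 1 and regs[0].n_gaps == 3

    def test_unsorted_input_rejected(self):
        with pytest.raises(ValueError):
            call_regions([300, 100, 500], [100, 300, 500])
        with pytest.raises(ValueError):
            call_regions([100, 500], [500, 100])

    def test_sig_must_be_subset_of_all(self):
        with pytest.raises(ValueError):
            call_regions([100, 200, 300], [100, 300])

    def test_matches_brute_force_oracle_on_random_instances(self):
        r = np.random.default_rng(2024)
        for trial in range(1000):
            n = int(r.integers(1, 41))
            allp = np.sort(r.choice(np.arange(1, 12000, 7), n, replace=False))
            k = int(r.integers(0, n + 1))
            sig = np.sort(r.choice(allp, k, replace=False))
            got = [(g.start, g.end, g.members) for g in call_regions(sig, allp)]
            assert got == brute_force_regions(sig, allp), f"trial {trial}"


class TestDistinctLoci:
    def test_no_regions_means_every_hit_is_a_locus(self):
        assert count_distinct_loci(33, []) == 33

    def test_region_members_collapse_to_one_locus(self):
        reg = Region(100, 700, (100, 300, 500, 700), 0)
        assert count_distinct_loci(10, [reg]) == 7

    def test_zero_hits(self):
        assert count_distinct_loci(0, []) == 0

    def test_member_outside_hit_set_rejected(self):
        reg = Region(100, 500, (100, 300, 500), 0)
        with pytest.raises(ValueError):
            count_distinct_loci(5, [reg], hit_positions=[100, 300])

    def test_never_exceeds_hits(self, rng):
        for _ in range(50):
            n = int(rng.integers(3, 30))
            pos = np.sort(rng.choice(10000, n, replace=False))
            regs = call_regions(pos, pos)
            assert count_distinct_loci(n, regs) <= n


class TestMethCategory:
    @pytest.mark.parametrize(
        "beta,expected",
        [(0.1, "hypo"), (0.24999, "hypo"), (0.25, "intermediate"),
         (0.5, "intermediate"), (0.7, "intermediate"), (0.70001, "hyper"),
         (0.9, "hyper")],
    )
    def test_thresholds(self, beta, expected):
        assert meth_category(beta) == expected


class TestAnnotateCgi:
    ISLANDS = merge_intervals(np.array([[10000, 11000]]))

    def test_inside_island(self):
        assert annotate_cgi(10500, self.ISLANDS) == "CGI"

    def test_shore_boundary_arithmetic(self):
        assert annotate_cgi(12999, self.ISLANDS) == "shore"
        assert annotate_cgi(13000, self.ISLANDS) == "shore"
        assert annotate_cgi(13001, self.ISLANDS) == "nonCGI"
        assert annotate_cgi(8000, self.ISLANDS) == "shore"
        assert annotate_cgi(7999, self.ISLANDS) == "nonCGI"

    def test_island_body_beats_other_islands_shore(self):
        islands = merge_intervals(np.array([[10000, 11000], [11500, 12500]]))
        # inside the second island but within 2 kb of the first one's edge
        assert annotate_cgi(11600, islands) == "CGI"

    def test_negative_position_rejected(self):
        with pytest.raises(ValueError):
            annotate_cgi(-5, self.ISLANDS)

    def test_bed_round_trip_is_one_based_inclusive(self, tmp_path):
        bed = tmp_path / "cgi.bed"
        bed.write_text("chrX\t9999\t11000\tCGI\n")
        iv = read_bed_intervals(bed)
        np.testing.assert_array_equal(iv, [[10000, 11000]])
        assert annotate_cgi(10000, iv) == "CGI"
        assert annotate_cgi(9999, iv) == "shore"


class TestAnnotateXci:
    def test_within_window_takes_nearest_status(self):
        assert annotate_xci(6500, [5000], ["subject"]) == "subject"

    def test_beyond_window_unannotated(self):
        assert annotate_xci(7100, [5000], ["subject"]) == "unannotated"
        assert annotate_xci(7000, [5000], ["subject"]) == "subject"

    def test_equidistant_tie_goes_to_lower_coordinate(self):
        assert annotate_xci(5000, [4000, 6000], ["escape", "subject"]) == "escape"

    def test_empty_tss_table_rejected(self):
        with pytest.raises(ValueError):
            annotate_xci(100, [], [])


class TestEnrichment:
    def test_chi_square_matches_hand_computed_pearson(self):
        table = np.array([[40, 10], [500, 500]])
        expected = stats.contingency.expected_freq(table)
        pearson = ((table - expected) ** 2 / expected).sum()
        stat, p, method = enrichment_test([40, 10], [500, 500])
        assert method == "chi-square"
        assert stat == pytest.approx(pearson, rel=1e-12)

    def test_small_expected_counts_switch_to_fisher(self):
        _, p, method = enrichment_test([8, 2], [50, 50])
        assert method == "fisher"
        _, p_ref = stats.fisher_exact([[8, 2], [50, 50]])
        assert p == pytest.approx(p_ref, rel=1e-12)

    def test_null_calibration(self, rng):
        ps = []
        for _ in range(200):
            hits = rng.multinomial(60, [0.5, 0.3, 0.2])
            bg = rng.multinomial(2000, [0.5, 0.3, 0.2])
            _, p, _ = enrichment_test(hits, bg)
            ps.append(p)
        assert 0.01 < np.mean(np.array(ps) < 0.05) < 0.12

    def test_zero_table_rejected(self):
        with pytest.raises(ValueError):
            enrichment_test([0, 0], [0, 0])
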