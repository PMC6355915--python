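"""PRR windows, the statistic itself, and the stratified comparisons."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from polpause.pausing import (
    change_correlation, compute_prr, gene_windows, intron_class_stratify,
    prr_compare, prr_table, quartile_stratify, select_tss, window_change_test,
)
from conftest import make_track, simple_gene


# -- windows -----------------------------------------------------------------

def test_plus_strand_windows_match_stated_definitions():
    gene = simple_gene(start=10_000, end=30_000)
    win = gene_windows(gene, tss=10_000)
    assert win.tss_window == (9_750, 10_250)
    assert win.body_window == (10_500, 29_500)
    assert win.eligible


def test_short_gene_is_ineligible_not_an_error():
    win = gene_windows(simple_gene(start=0, end=900))
    assert not win.eligible and win.body_window is None


def test_minus_strand_windows_are_mirrored():
    gene = simple_gene(strand="-", start=10_000, end=30_000)
    win = gene_windows(gene, tss=30_000)
    assert win.tss_window == (29_750, 30_250)
    assert win.body_window == (10_500, 29_500)


# -- TSS selection -----------------------------------------------------------

def test_single_tss_returns_itself():
    gene = simple_gene(start=5_000, end=9_000)
    track = make_track("chr1", np.zeros(10))
    assert select_tss(gene, track) == 5_000


def test_tss_with_highest_control_signal_wins():
    gene = simple_gene(start=5_000, end=9_000, tss_list=[5_000, 6_000])
    dense = np.zeros(10_000)
    dense[4_750:5_250] = 5.0
    dense[5_750:6_250] = 1.0
    assert select_tss(gene, make_track("chr1", dense)) == 5_000
    dense[5_750:6_250] = 9.0
    assert select_tss(gene, make_track("chr1", dense)) == 6_000


@pytest.mark.parametrize("strand,expected", [("+", 5_000), ("-", 6_000)])
def test_exact_tie_resolves_five_prime_most(strand, expected):
    if strand == "+":
        gene = simple_gene(start=5_000, end=9_000, tss_list=[5_000, 6_000])
    else:
        gene = simple_gene(strand="-", start=1_000, end=6_000,
                           tss_list=[6_000, 5_000])
    track = make_track("chr1", np.ones(10_000))  # symmetric signal
    assert select_tss(gene, track) == expected


# -- PRR ---------------------------------------------------------------------

def test_uniform_enrichment_gives_prr_zero():
    gene = simple_gene(start=2_000, end=22_000)
    track = make_track("chr1", np.full(30_000, 2.0))
    rec = compute_prr(track, gene)
    assert rec.prr == pytest.approx(0.0) and rec.eligible


def test_prr_log2_of_window_ratio():
    gene = simple_gene(start=2_000, end=22_000)
    dense = np.full(30_000, 2.0)
    dense[1_750:2_250] = 8.0
    rec = compute_prr(make_track("chr1", dense), gene)
    assert rec.prr == pytest.approx(-2.0)


def test_no_signal_gene_flagged_ineligible():
    gene = simple_gene(start=2_000, end=22_000)
    rec = compute_prr(make_track("chr1", np.zeros(10)), gene)
    assert not rec.eligible and rec.reason == "no signal"


def test_prr_matches_dense_per_base_oracle():
    """50 synthetic genes: pipeline PRR vs brute-force dense windows."""
    rng = np.random.default_rng(11)
    dense = rng.gamma(2.0, 2.0, 400_000)
    track = make_track("chr1", dense)
    floor = 0.01
    for i in range(50):
        start = int(rng.integers(1_000, 390_000 - 25_000))
        end = start + int(rng.integers(3_000, 25_000))
        strand = "+" if rng.random() < 0.5 else "-"
        gene = simple_gene(f"g{i}", strand=strand, start=start, end=end)
        rec = compute_prr(track, gene)
        win = gene_windows(gene, gene.tss)
        tss_mean = max(dense[slice(*win.tss_window)].mean(), floor)
        body_mean = max(dense[slice(*win.body_window)].mean(), floor)
        assert rec.prr == pytest.approx(np.log2(body_mean / tss_mean), abs=1e-9)


def test_prr_invariant_under_positive_scaling():
    gene = simple_gene(start=2_000, end=22_000)
    dense = np.random.default_rng(5).gamma(3, 1, 30_000) + 0.5
    base = compute_prr(make_track("chr1", dense), gene).prr
    for c in (0.1, 7.0, 1e3):
        scaled = compute_prr(make_track("chr1", c * dense), gene).prr
        assert scaled == pytest.approx(base, abs=1e-9)


def test_prr_decreases_with_promoter_peak_amplitude():
    gene = simple_gene(start=5_000, end=25_000)
    prrs = []
    for amp in (0.0, 2.0, 8.0, 32.0):
        dense = np.full(30_000, 2.0)
        x = np.arange(30_000)
        dense += amp * np.exp(-0.5 * ((x - 5_000) / 100) ** 2)
        prrs.append(compute_prr(make_track("chr1", dense), gene).prr)
    assert all(a > b for a, b in zip(prrs, prrs[1:]))


# -- KS comparison -----------------------------------------------------------

def _records(vals):
    return {f"g{i}": v for i, v in enumerate(vals)}


def test_identical_samples_give_d_zero_p_one():
    res = prr_compare(_records([1.0, 2.0, 3.0] * 10), _records([1.0, 2.0, 3.0] * 10))
    assert res.statistic == 0.0 and res.pvalue == pytest.approx(1.0)


def test_disjoint_supports_give_d_one():
    a = {f"a{i}": v for i, v in enumerate([1.0, 2.0, 3.0] * 5)}
    b = {f"a{i}": v for i, v in enumerate([4.0, 5.0, 6.0] * 5)}
    res = prr_compare(a, b)
    assert res.statistic == 1.0


def test_ks_d_matches_brute_force_ecdf_gap():
    rng = np.random.default_rng(21)
    a = rng.normal(0, 1, 200)
    b = rng.normal(0.3, 1.2, 200)
    res = prr_compare({f"g{i}": v for i, v in enumerate(a)},
                      {f"g{i}": v for i, v in enumerate(b)})
    pooled = np.concatenate([a, b])
    d_oracle = max(abs((a <= x).mean() - (b <= x).mean()) for x in pooled)
    assert res.statistic == pytest.approx(d_oracle, abs=1e-12)


def test_ks_is_symmetric_and_restricted_to_shared_genes():
    a = {"g1": 0.0, "g2": 1.0, "g3": 2.0, "shared_only_in_a": 9.0}
    b = {"g1": 5.0, "g2": 6.0, "g3": 7.0, "other": -9.0}
    with pytest.warns(UserWarning, match="low-power"):
        fwd = prr_compare(a, b)
    with pytest.warns(UserWarning):
        rev = prr_compare(b, a)
    assert fwd.n == 3 and fwd.statistic == rev.statistic


# -- quartiles ---------------------------------------------------------------

def test_eight_genes_split_two_per_quartile():
    ref = {f"g{i}": float(i) for i in range(1, 9)}
    delta = {g: 0.0 for g in ref}
    assignments, summary = quartile_stratify(ref, delta)
    groups = {q: sorted(g for g, qq in assignments.items() if qq == q)
              for q in (1, 2, 3, 4)}
    assert groups == {1: ["g1", "g2"], 2: ["g3", "g4"],
                      3: ["g5", "g6"], 4: ["g7", "g8"]}
    assert list(summary["n"]) == [2, 2, 2, 2]


def test_constant_reference_degenerates_with_warning():
    ref = {f"g{i}": 1.0 for i in range(8)}
    with pytest.warns(UserWarning, match="constant reference"):
        assignments, _ = quartile_stratify(ref, ref)
    assert set(assignments.values()) == {1}


def test_quartile_counts_near_balanced():
    rng = np.random.default_rng(9)
    ref = {f"g{i}": float(v) for i, v in enumerate(rng.normal(size=1000))}
    assignments, summary = quartile_stratify(ref, ref)
    assert all(abs(n - 250) <= 1 for n in summary["n"])


# -- intron classes ----------------------------------------------------------

def test_intron_breaks_split_classes():
    g1 = simple_gene("a", start=0, end=2_000,
                     blocks=[(0, 500), (1_000, 2_000)])       # intron 500
    g2 = simple_gene("b", start=10_000, end=20_000,
                     blocks=[(10_000, 11_000), (16_000, 20_000)])  # intron 5000
    res = intron_class_stratify([g1, g2], {"a": 1.0, "b": 2.0},
                                class_breaks=[1_000])
    assert list(res.summary["n"]) == [1, 1]
    assert res.assignments == {"a": "<=1000", "b": ">1000"}


def test_identical_class_means_give_f_near_zero():
    genes, values = [], {}
    for k, intron in enumerate([100, 100, 5_000, 5_000]):
        g = simple_gene(f"g{k}", start=k * 20_000, end=k * 20_000 + 10_000,
                        blocks=[(k * 20_000, k * 20_000 + 1_000),
                                (k * 20_000 + 1_000 + intron, k * 20_000 + 10_000)])
        genes.append(g)
        values[g.gene_id] = float(k % 2)  # same {0,1} pair per class
    res = intron_class_stratify(genes, values, class_breaks=[1_000])
    assert res.f_statistic == pytest.approx(0.0, abs=1e-12)


def test_anova_matches_sums_of_squares_oracle():
    rng = np.random.default_rng(17)
    genes, values, groups = [], {}, []
    for c, mean in enumerate([0.0, 1.0, 2.0]):
        intron = [100, 2_000, 20_000][c]
        vals = rng.normal(mean, 0.1, 50)
        groups.append(vals)
        for k, v in enumerate(vals):
            gid = f"c{c}_{k}"
            s = (c * 50 + k) * 40_000
            genes.append(simple_gene(gid, start=s, end=s + 30_000,
                                     blocks=[(s, s + 1_000),
                                             (s + 1_000 + intron, s + 30_000)]))
            values[gid] = float(v)
    res = intron_class_stratify(genes, values, class_breaks=[1_000, 10_000])
    all_vals = np.concatenate(groups)
    grand = all_vals.mean()
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    f_oracle = (ssb / 2) / (ssw / (len(all_vals) - 3))
    assert res.f_statistic == pytest.approx(f_oracle, rel=1e-10)
    assert res.pvalue < 1e-16


# -- window change test ------------------------------------------------------

def test_identical_tracks_give_degenerate_test():
    genes = [simple_gene(f"g{i}", start=i * 5_000 + 1_000,
                         end=i * 5_000 + 4_000) for i in range(6)]
    dense = np.random.default_rng(2).gamma(5, 1, 40_000) + 1
    track = make_track("chr1", dense)
    res = window_change_test(track, track, genes, "tss", {"g0", "g1", "g2"})
    assert (res.table["change"] == 0).all()
    assert res.t_statistic == 0.0 and res.pvalue == 1.0


def test_simulated_bound_shift_recovered():
    rng = np.random.default_rng(4)
    genes = [simple_gene(f"g{i}", start=i * 5_000 + 1_000,
                         end=i * 5_000 + 4_000) for i in range(40)]
    bound = {f"g{i}" for i in range(20)}
    dense_a = rng.gamma(20, 0.5, 250_000) + 1
    dense_b = dense_a.copy()
    for i in range(20):  # +1 log2 unit at bound TSS windows
        tss = genes[i].tss
        dense_b[tss - 250:tss + 250] *= 2.0
    res = window_change_test(make_track("chr1", dense_a),
                             make_track("chr1", dense_b), genes, "tss", bound)
    t = res.table
    diff = t.loc[t.group == "bound", "change"].mean() - \
        t.loc[t.group == "unbound", "change"].mean()
    assert diff == pytest.approx(1.0, abs=0.05)
    assert res.pvalue < 1e-10


def test_welch_t_matches_closed_form():
    a = np.array([1.1, 2.3, 0.7, 1.9, 2.5])
    b = np.array([3.2, 2.8, 4.1, 3.6])
    t_oracle = (a.mean() - b.mean()) / np.sqrt(
        a.var(ddof=1) / len(a) + b.var(ddof=1) / len(b))
    t_scipy, _ = sps.ttest_ind(a, b, equal_var=False)
    assert t_scipy == pytest.approx(t_oracle, rel=1e-12)


def test_empty_group_skips_test():
    genes = [simple_gene("g0", start=1_000, end=4_000)]
    track = make_track("chr1", np.ones(5_000))
    res = window_change_test(track, track, genes, "tss", set())
    assert np.isnan(res.t_statistic) and "skipped" in res.note


# -- correlation -------------------------------------------------------------

def test_perfect_correlations():
    x = {f"g{i}": float(i) for i in range(10)}
    y_pos = {g: 2 * v + 1 for g, v in x.items()}
    y_neg = {g: -v for g, v in x.items()}
    assert change_correlation(x, y_pos).r == pytest.approx(1.0)
    assert change_correlation(x, y_neg).r == pytest.approx(-1.0)


def test_pearson_matches_covariance_oracle():
    rng = np.random.default_rng(8)
    xv, yv = rng.normal(size=100), rng.normal(size=100)
    x = {f"g{i}": v for i, v in enumerate(xv)}
    y = {f"g{i}": v for i, v in enumerate(yv)}
    r_oracle = np.mean((xv - xv.mean()) * (yv - yv.mean())) / (
        xv.std() * yv.std())
    assert change_correlation(x, y).r == pytest.approx(r_oracle, rel=1e-10)


def test_zero_variance_flagged_not_raised():
    x = {f"g{i}": 1.0 for i in range(5)}
    y = {f"g{i}": float(i) for i in range(5)}
    res = change_correlation(x, y)
    assert np.isnan(res.r) and "zero variance" in res.note


def test_too_few_shared_genes_raises():
    with pytest.raises(ValueError, match=">=3"):
        change_correlation({"a": 1.0, "b": 2.0}, {"a": 1.0, "b": 2.0})
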