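"""Peak-to-gene assignment, bound sets, and enrichment/binding rules."""

from math import comb

import numpy as np
import pandas as pd
import pytest

from polpause.genome_io import PeakCall
from polpause.targets import (
    BoundSet, assign_peaks_to_genes, class_enrichment, expressed_genes,
    expression_quartiles, intersect_bound, pausing_index_bound,
)
from conftest import make_track, simple_gene


def peak(summit, fold, contig="chr1", name="p"):
    return PeakCall(contig, summit - 100, summit + 100, summit, fold, name)


# -- assignment --------------------------------------------------------------

def test_subthreshold_peak_dropped():
    genes = [simple_gene("g", start=900, end=5_000)]
    bound = assign_peaks_to_genes([peak(1_000, 1.9)], genes)
    assert len(bound) == 0
    bound = assign_peaks_to_genes([peak(1_000, 2.0)], genes)
    assert bound.gene_ids == {"g"}


def test_nearest_tss_wins():
    genes = [simple_gene("near", start=800, end=3_000),
             simple_gene("far", start=5_000, end=9_000)]
    bound = assign_peaks_to_genes([peak(1_000, 3.0)], genes)
    assert bound.gene_ids == {"near"}


def test_equidistant_summit_assigned_to_both():
    genes = [simple_gene("a", start=1_000, end=4_000),
             simple_gene("b", start=5_000, end=9_000)]
    bound = assign_peaks_to_genes([peak(3_000, 3.0)], genes)
    assert bound.gene_ids == {"a", "b"}


def test_peak_on_geneless_contig_warned_and_unassigned():
    genes = [simple_gene("g", start=1_000, end=4_000)]
    with pytest.warns(UserWarning, match="no gene"):
        bound = assign_peaks_to_genes([peak(500, 3.0, contig="chrX")], genes)
    assert len(bound) == 0


def test_assignment_matches_exhaustive_oracle():
    rng = np.random.default_rng(12)
    genes = [simple_gene(f"g{i}", start=int(s), end=int(s) + 2_000)
             for i, s in enumerate(np.sort(rng.choice(10**6, 100, replace=False)))]
    peaks = [peak(int(p), 2.5, name=f"p{k}")
             for k, p in enumerate(rng.integers(0, 10**6 + 2_000, 100))]
    bound = assign_peaks_to_genes(peaks, genes)
    oracle: dict[str, set] = {}
    for pk in peaks:
        dists = {g.gene_id: min(abs(t - pk.summit) for t in g.tss_list)
                 for g in genes}
        best = min(dists.values())
        for gid, d in dists.items():
            if d == best:
                oracle.setdefault(gid, set()).add(pk.name)
    assert bound.gene_ids == set(oracle)
    for gid in oracle:
        assert set(bound.provenance[gid]) == oracle[gid]


# -- intersection ------------------------------------------------------------

def bset(label, ids):
    return BoundSet(label, frozenset(ids), {g: (label,) for g in ids})


def test_intersection_of_three_sets():
    inter, report = intersect_bound([bset("m", {"A", "B"}), bset("y", {"B", "C"}),
                                     bset("e", {"B"})])
    assert inter.gene_ids == {"B"}
    pairwise = report[report.set_b != ""]
    assert list(pairwise["n_overlap"]) == [1, 1, 1]


def test_identical_sets_fully_overlap():
    s = bset("a", {"x", "y", "z"})
    inter, report = intersect_bound([s, bset("b", {"x", "y", "z"})])
    assert inter.gene_ids == {"x", "y", "z"}
    assert report["union_fraction"].iloc[-1] == 1.0


def test_intersection_order_invariant_and_idempotent():
    sets = [bset("a", {"1", "2", "3"}), bset("b", {"2", "3", "4"}),
            bset("c", {"3", "2"})]
    i1, _ = intersect_bound(sets)
    i2, _ = intersect_bound(sets[::-1])
    i3, _ = intersect_bound(sets + [sets[0]])
    assert i1.gene_ids == i2.gene_ids == i3.gene_ids == {"2", "3"}


def test_random_set_counts_match_enumeration():
    rng = np.random.default_rng(13)
    universe = [f"g{i}" for i in range(50)]
    sets = [bset(f"s{k}", {g for g in universe if rng.random() < 0.4})
            for k in range(3)]
    inter, report = intersect_bound(sets)
    brute = {g for g in universe
             if all(g in s.gene_ids for s in sets)}
    assert inter.gene_ids == brute


# -- Fisher class enrichment -------------------------------------------------

def fisher_oracle(a, b, c, d):
    """Two-sided Fisher p by exact hypergeometric enumeration."""
    r1, c1, n = a + b, a + c, a + b + c + d
    pmf = {k: comb(r1, k) * comb(n - r1, c1 - k)
           for k in range(max(0, c1 - (n - r1)), min(r1, c1) + 1)}
    total = sum(pmf.values())
    return sum(v for v in pmf.values() if v <= pmf[a]) / total


def test_diagonal_table_p_matches_enumeration():
    # bound = class1 exactly: table [[5,0],[0,5]] -> p = 2/252 = 1/126
    classes = {f"g{i}": ("c1" if i < 5 else "c2") for i in range(10)}
    bound = bset("b", {f"g{i}" for i in range(5)})
    res = class_enrichment(bound, classes, set(classes))
    p = res.loc[res["class"] == "c1", "pvalue"].item()
    assert p == pytest.approx(1 / 126, rel=1e-9)
    assert p == pytest.approx(fisher_oracle(5, 0, 0, 5), rel=1e-9)


def test_independent_table_has_odds_ratio_one():
    # bound hits each class proportionally
    classes = {f"g{i}": ("c1" if i < 20 else "c2") for i in range(40)}
    bound = bset("b", {f"g{i}" for i in list(range(5)) + list(range(20, 25))})
    res = class_enrichment(bound, classes, set(classes))
    assert np.allclose(res["odds_ratio"], 1.0)


def test_two_class_odds_ratios_are_reciprocal():
    classes = {f"g{i}": ("c1" if i < 12 else "c2") for i in range(30)}
    bound = bset("b", {f"g{i}" for i in list(range(8)) + [14, 20, 25]})
    res = class_enrichment(bound, classes, set(classes)).set_index("class")
    assert res.loc["c1", "odds_ratio"] == pytest.approx(
        1 / res.loc["c2", "odds_ratio"])


def test_missing_class_label_raises():
    bound = bset("b", {"g1"})
    with pytest.raises(ValueError, match="lack a class"):
        class_enrichment(bound, {"g1": "c"}, {"g1", "g2"})


# -- pausing-index bound call ------------------------------------------------

@pytest.mark.parametrize("level,expected", [(1.4, True), (1.3, False),
                                            (0.0, False)])
def test_threshold_is_strictly_greater(level, expected):
    gene = simple_gene("g", start=2_000, end=6_000)
    track = make_track("chr1", np.full(8_000, level))
    table = pausing_index_bound(track, [gene])
    assert bool(table.loc[0, "bound"]) is expected
    assert table.loc[0, "tss_mean_enrichment"] == pytest.approx(level)


# -- expressed genes and quartiles -------------------------------------------

def rpkm(d):
    return pd.DataFrame(d, index=["rep1", "rep2"]).T


def test_expressed_above_one_rpkm_mean():
    table = rpkm({"hi": [1.5, 0.9], "lo": [0.5, 0.5], "edge": [1.0, 1.0]})
    assert expressed_genes(table) == {"hi"}  # mean 1.2 > 1; 1.0 exactly is out


def test_missing_genes_warned_as_zero():
    table = rpkm({"a": [2.0, 2.0]})
    with pytest.warns(UserWarning, match="missing"):
        out = expressed_genes(table, gene_ids=["a", "b"])
    assert out == {"a"}


def test_expression_quartiles_balanced():
    table = rpkm({f"g{i}": [float(i), float(i)] for i in range(1, 9)})
    q = expression_quartiles(table)
    counts = pd.Series(q).value_counts()
    assert set(counts) == {2} and set(q.values()) == {"Q1", "Q2", "Q3", "Q4"}
    assert q["g1"] == "Q1" and q["g8"] == "Q4"


def test_quartile_sizes_near_balanced_random():
    rng = np.random.default_rng(14)
    table = rpkm({f"g{i}": [v, v] for i, v in
                  enumerate(rng.lognormal(1, 1, 403))})
    counts = pd.Series(expression_quartiles(table)).value_counts()
    assert all(abs(c - 403 / 4) <= 1 for c in counts)


def test_fewer_than_four_genes_raises():
    with pytest.raises(ValueError, match="at least 4"):
        expression_quartiles(rpkm({"a": [1, 1], "b": [2, 2]}))
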