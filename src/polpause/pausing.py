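"""The Pol II release ratio (PRR) and stratified condition comparisons.

The PRR of a gene is the log2 ratio of its mean gene-body signal to
its mean TSS-window signal:

    PRR = log2( mean signal over [TSS+500, TES-500)
              / mean signal over [TSS-250, TSS+250) )

computed on input-normalized (linear) enrichment for ChIP data, or on
fragmented nascent-RNA coverage normalized to the t0 library for
4sU data. A strongly paused gene piles polymerase at the promoter
and has a low (negative) PRR; release into elongation raises it.
Windows are strand-aware; genes too short to hold a non-empty body
window are excluded rather than erroring.

Both window means are floored at a small pseudo-enrichment before the
ratio, so the PRR is finite; a gene at the floor in both windows has
no usable signal and is marked ineligible. Because the statistic is a
log-ratio of means of the same track, it is invariant under any
uniform positive rescaling of the track — in particular under the
spike-in calibration factor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from polpause.genome_io import CoverageTrack, GeneModel

__all__ = [
    "GeneWindows",
    "PRRRecord",
    "PRRComparison",
    "gene_windows",
    "select_tss",
    "compute_prr",
    "prr_table",
    "prr_compare",
    "quartile_stratify",
    "intron_class_stratify",
    "window_change_test",
    "change_correlation",
]

TSS_FLANK = 250     # bp either side of the TSS
BODY_OFFSET = 500   # bp inset from TSS and TES for the gene body
SIGNAL_FLOOR = 0.01


@dataclass(frozen=True)
class GeneWindows:
    """Strand-aware TSS and gene-body windows, half-open intervals."""

    tss_window: tuple[int, int]
    body_window: tuple[int, int] | None
    eligible: bool
    reason: str = ""


def gene_windows(gene: GeneModel, tss: int | None = None,
                 tss_flank: int = TSS_FLANK,
                 body_offset: int = BODY_OFFSET) -> GeneWindows:
    """TSS window (TSS +/- ``tss_flank``) and body window
    (``body_offset`` downstream of TSS to ``body_offset`` upstream of
    TES), mirrored on the minus strand.

    A gene shorter than the span the two insets require gets an empty
    body window and is marked ineligible (no exception is raised).
    """
    if tss is None:
        tss = gene.tss
    tss_window = (tss - tss_flank, tss + tss_flank)
    if gene.strand == "+":
        body = (tss + body_offset, gene.tes - body_offset)
    else:
        body = (gene.tes + body_offset, tss - body_offset)
    if body[1] <= body[0]:
        return GeneWindows(tss_window, None, False,
                           "gene shorter than required for body window")
    return GeneWindows(tss_window, body, True)


def select_tss(gene: GeneModel, control_enrichment: CoverageTrack,
               tss_flank: int = TSS_FLANK) -> int:
    """Pick among alternative TSSs the one with the highest mean
    control signal in its +/- ``tss_flank`` window.

    Exact ties resolve to the 5'-most candidate (smallest coordinate
    on '+', largest on '-'), so the choice is deterministic.
    """
    candidates = list(gene.tss_list)
    if len(candidates) == 1:
        return candidates[0]
    starts = np.array([t - tss_flank for t in candidates])
    ends = np.array([t + tss_flank for t in candidates])
    means = control_enrichment.window_mean(gene.contig, starts, ends)
    best = means.max()
    tied = [t for t, m in zip(candidates, means) if m == best]
    return min(tied) if gene.strand == "+" else max(tied)


@dataclass(frozen=True)
class PRRRecord:
    gene_id: str
    condition: str
    selected_tss: int
    tss_enrichment: float
    body_enrichment: float
    prr: float              # log2(body/tss); nan when ineligible
    eligible: bool
    reason: str = ""


def compute_prr(enrichment: CoverageTrack, gene: GeneModel,
                tss: int | None = None, condition: str = "",
                floor: float = SIGNAL_FLOOR) -> PRRRecord:
    """PRR of one gene on a non-negative signal track.

    ``enrichment`` is linear input-normalized enrichment (ChIP) or
    t0-normalized nascent coverage (4sU); the same code path serves
    both. Window means are floored at ``floor``; a gene at the floor
    in both windows is ineligible ("no signal").
    """
    if tss is None:
        tss = gene.tss
    win = gene_windows(gene, tss)
    if not win.eligible:
        return PRRRecord(gene.gene_id, condition, tss, np.nan, np.nan,
                         np.nan, False, win.reason)
    tss_mean = float(enrichment.window_mean(gene.contig, *win.tss_window))
    body_mean = float(enrichment.window_mean(gene.contig, *win.body_window))
    if tss_mean <= floor and body_mean <= floor:
        return PRRRecord(gene.gene_id, condition, tss, tss_mean, body_mean,
                         np.nan, False, "no signal")
    prr = float(np.log2(max(body_mean, floor) / max(tss_mean, floor)))
    return PRRRecord(gene.gene_id, condition, tss, tss_mean, body_mean,
                     prr, True)


def prr_table(enrichment: CoverageTrack, genes: Iterable[GeneModel],
              control_enrichment: CoverageTrack | None = None,
              condition: str = "", floor: float = SIGNAL_FLOOR) -> pd.DataFrame:
    """PRR for every gene; TSS chosen on the control track when given.

    Returns a DataFrame with one row per gene (eligible or not);
    filter on ``eligible`` for downstream statistics.
    """
    records = []
    for gene in genes:
        picker = control_enrichment if control_enrichment is not None else enrichment
        tss = select_tss(gene, picker)
        records.append(compute_prr(enrichment, gene, tss=tss,
                                   condition=condition, floor=floor))
    return pd.DataFrame(records)


# ---------------------------------------------------------------------------
# condition comparisons
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PRRComparison:
    statistic: float            # two-sample KS D
    pvalue: float
    n: int                      # shared eligible genes
    gene_ids: tuple[str, ...]
    values_a: np.ndarray = field(repr=False)
    values_b: np.ndarray = field(repr=False)
    low_power: bool = False


def _prr_map(records) -> dict[str, float]:
    if isinstance(records, pd.DataFrame):
        ok = records[records["eligible"]]
        return dict(zip(ok["gene_id"], ok["prr"]))
    if isinstance(records, Mapping):
        return {k: v for k, v in records.items() if np.isfinite(v)}
    return {r.gene_id: r.prr for r in records if r.eligible}


def prr_compare(records_a, records_b, min_genes: int = 10) -> PRRComparison:
    """Two-sample Kolmogorov-Smirnov comparison of per-gene PRR
    between conditions, restricted to genes eligible in both.

    Uses the exact two-sided null distribution below n=30 per sample
    and the asymptotic one otherwise. Fewer than ``min_genes`` shared
    genes flags the result low-power (with a warning) rather than
    failing.
    """
    a_map, b_map = _prr_map(records_a), _prr_map(records_b)
    shared = sorted(set(a_map) & set(b_map))
    a = np.array([a_map[g] for g in shared])
    b = np.array([b_map[g] for g in shared])
    low_power = len(shared) < min_genes
    if low_power:
        warnings.warn(f"only {len(shared)} shared eligible genes; "
                      "KS comparison is low-power", stacklevel=2)
    if len(shared) == 0:
        return PRRComparison(np.nan, np.nan, 0, (), a, b, True)
    method = "exact" if min(len(a), len(b)) < 30 else "asymp"
    res = sps.ks_2samp(a, b, method=method)
    return PRRComparison(float(res.statistic), float(res.pvalue),
                         len(shared), tuple(shared), a, b, low_power)


def quartile_stratify(reference: Mapping[str, float],
                      delta: Mapping[str, float]):
    """Split genes into quartiles of a reference value (e.g. control
    PRR, low to high) and summarize the per-gene deltas within each.

    Genes exactly on a 25/50/75 percentile boundary fall in the lower
    quartile. Returns ``(assignments, summary)``: a gene -> quartile
    (1..4) mapping and a DataFrame with n, median and IQR per quartile.
    A constant reference degenerates to a single quartile, with a
    warning.
    """
    shared = sorted(set(reference) & set(delta))
    if not shared:
        raise ValueError("no genes shared between reference and delta")
    ref = np.array([reference[g] for g in shared])
    breaks = np.percentile(ref, [25, 50, 75])
    if ref.min() == ref.max():
        warnings.warn("constant reference: all genes in quartile 1", stacklevel=2)
        quartiles = np.ones(len(shared), dtype=int)
    else:
        quartiles = np.searchsorted(breaks, ref, side="left") + 1
    assignments = dict(zip(shared, (int(q) for q in quartiles)))
    rows = []
    for q in (1, 2, 3, 4):
        vals = np.array([delta[g] for g, qq in assignments.items() if qq == q])
        rows.append({
            "quartile": q, "n": len(vals),
            "median": float(np.median(vals)) if len(vals) else np.nan,
            "iqr": float(np.subtract(*np.percentile(vals, [75, 25]))) if len(vals) else np.nan,
        })
    return assignments, pd.DataFrame(rows)


@dataclass(frozen=True)
class StratifiedANOVA:
    summary: pd.DataFrame = field(repr=False)
    f_statistic: float
    pvalue: float
    assignments: dict[str, str] = field(repr=False)


def intron_class_stratify(genes: Sequence[GeneModel],
                          values: Mapping[str, float],
                          class_breaks: Sequence[int] | None = None) -> StratifiedANOVA:
    """Bin genes by largest-intron size and compare a per-gene value
    across the size classes with a one-way ANOVA.

    ``class_breaks`` are ascending bp thresholds; a gene with largest
    intron exactly on a break falls in the lower class. When omitted,
    breaks default to the quartiles of largest-intron size among the
    given genes (logged in the summary). Empty classes are reported
    with n=0 and excluded from the ANOVA.
    """
    genes = [g for g in genes if g.gene_id in values]
    if not genes:
        raise ValueError("no genes with values to stratify")
    introns = np.array([g.largest_intron for g in genes])
    if class_breaks is None:
        class_breaks = [int(x) for x in np.percentile(introns, [25, 50, 75])]
    breaks = list(class_breaks)
    if breaks != sorted(breaks):
        raise ValueError("class_breaks must be ascending")
    labels = ([f"<={breaks[0]}"]
              + [f"({lo},{hi}]" for lo, hi in zip(breaks, breaks[1:])]
              + [f">{breaks[-1]}"])
    idx = np.searchsorted(breaks, introns, side="left")
    assignments = {g.gene_id: labels[i] for g, i in zip(genes, idx)}
    groups, rows = [], []
    for k, label in enumerate(labels):
        vals = np.array([values[g.gene_id] for g, i in zip(genes, idx) if i == k])
        rows.append({"class": label, "n": len(vals),
                     "mean": float(vals.mean()) if len(vals) else np.nan,
                     "median": float(np.median(vals)) if len(vals) else np.nan})
        if len(vals) >= 2:
            groups.append(vals)
    if len(groups) >= 2:
        f, p = sps.f_oneway(*groups)
    else:
        f, p = np.nan, np.nan
    return StratifiedANOVA(pd.DataFrame(rows), float(f), float(p), assignments)


@dataclass(frozen=True)
class WindowChangeResult:
    table: pd.DataFrame = field(repr=False)   # gene_id, change, group
    t_statistic: float
    pvalue: float
    n_bound: int
    n_unbound: int
    note: str = ""


_WINDOW_KINDS = ("tss", "body", "tes")


def _window_for(gene: GeneModel, kind: str, tss: int,
                flank: int = TSS_FLANK) -> tuple[int, int] | None:
    if kind == "tss":
        return (tss - flank, tss + flank)
    if kind == "tes":
        return (gene.tes - flank, gene.tes + flank)
    win = gene_windows(gene, tss)
    return win.body_window


def window_change_test(track_a: CoverageTrack, track_b: CoverageTrack,
                       genes: Iterable[GeneModel], window: str,
                       bound_set: set[str],
                       tss_map: Mapping[str, int] | None = None,
                       floor: float = SIGNAL_FLOOR) -> WindowChangeResult:
    """Per-gene log2 change of window signal between two conditions,
    compared between bound and unbound genes by Welch's t-test.

    ``window`` is one of 'tss' (TSS +/- 250 bp), 'body', 'tes'
    (TES +/- 250 bp). Means are floored before the ratio. When both
    change vectors are constant (e.g. identical tracks) the test is
    degenerate: t=0, p=1 by convention. An empty group skips the test
    with a diagnostic note.
    """
    if window not in _WINDOW_KINDS:
        raise ValueError(f"window must be one of {_WINDOW_KINDS}")
    rows = []
    for gene in genes:
        tss = tss_map[gene.gene_id] if tss_map else gene.tss
        win = _window_for(gene, window, tss)
        if win is None:
            continue
        mean_a = max(float(track_a.window_mean(gene.contig, *win)), floor)
        mean_b = max(float(track_b.window_mean(gene.contig, *win)), floor)
        rows.append({"gene_id": gene.gene_id,
                     "change": float(np.log2(mean_b / mean_a)),
                     "group": "bound" if gene.gene_id in bound_set else "unbound"})
    table = pd.DataFrame(rows)
    bound = table.loc[table["group"] == "bound", "change"].to_numpy()
    unbound = table.loc[table["group"] == "unbound", "change"].to_numpy()
    if len(bound) == 0 or len(unbound) == 0:
        return WindowChangeResult(table, np.nan, np.nan, len(bound),
                                  len(unbound), "one group empty; test skipped")
    if np.ptp(bound) == 0 and np.ptp(unbound) == 0 and bound[0] == unbound[0]:
        return WindowChangeResult(table, 0.0, 1.0, len(bound), len(unbound),
                                  "degenerate: identical constant changes")
    t, p = sps.ttest_ind(bound, unbound, equal_var=False)
    return WindowChangeResult(table, float(t), float(p), len(bound), len(unbound))


@dataclass(frozen=True)
class ChangeCorrelation:
    r: float
    pvalue: float
    n: int
    table: pd.DataFrame = field(repr=False)   # gene_id, x, y, highlighted
    note: str = ""


def change_correlation(changes_x: Mapping[str, float],
                       changes_y: Mapping[str, float],
                       highlight_set: set[str] | None = None) -> ChangeCorrelation:
    """Pearson correlation of two per-gene change vectors over their
    shared genes, carrying highlight-set membership for plotting."""
    shared = sorted(set(changes_x) & set(changes_y))
    if len(shared) < 3:
        raise ValueError(f"need >=3 shared genes, got {len(shared)}")
    x = np.array([changes_x[g] for g in shared])
    y = np.array([changes_y[g] for g in shared])
    table = pd.DataFrame({
        "gene_id": shared, "x": x, "y": y,
        "highlighted": [g in (highlight_set or set()) for g in shared],
    })
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return ChangeCorrelation(np.nan, np.nan, len(shared), table,
                                 "zero variance; correlation undefined")
    r, p = sps.pearsonr(x, y)
    return ChangeCorrelation(float(r), float(p), len(shared), table)
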