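"""Peak-to-gene assignment, bound-set construction and enrichment tests.

Target genes of a ChIP'd factor are called from peak summits: peaks
below a fold-enrichment cutoff (2.0 by default, matching a MACS2
post-filter) are dropped and each surviving summit is assigned to the
gene with the nearest TSS. The factor complex's joint target set is
the intersection of its components' bound sets. Bound sets are then
tested for association with gene classes (expression quartiles,
intron-size classes) by Fisher's exact test on the 2x2 bound/unbound
x in-class/out-of-class table.

Also here: the pausing-index style bound call (mean TSS-window
enrichment above a threshold, strict), and the expressed-gene filter
(mean control RPKM strictly above 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence
import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps

from polpause.genome_io import CoverageTrack, GeneModel, PeakCall
from polpause.pausing import select_tss, TSS_FLANK

__all__ = [
    "BoundSet",
    "PausingIndexRecord",
    "assign_peaks_to_genes",
    "intersect_bound",
    "class_enrichment",
    "pausing_index_bound",
    "expressed_genes",
    "expression_quartiles",
]


@dataclass(frozen=True)
class BoundSet:
    """A labelled set of bound genes with per-gene supporting peaks."""

    label: str
    gene_ids: frozenset[str]
    provenance: Mapping[str, tuple[str, ...]] = field(default_factory=dict,
                                                      repr=False)

    def __len__(self) -> int:
        return len(self.gene_ids)


def assign_peaks_to_genes(peaks: Iterable[PeakCall],
                          genes: Sequence[GeneModel],
                          fold_cutoff: float = 2.0,
                          label: str = "bound") -> BoundSet:
    """Call a bound set: drop peaks with fold enrichment below
    ``fold_cutoff``, then assign each summit to the gene with the
    nearest TSS on the same contig.

    A summit exactly equidistant between two TSSs is assigned to both
    genes. Peaks on contigs with no annotated gene are left
    unassigned (warned, not an error). Genes with several annotated
    TSSs use whichever is nearest.
    """
    by_contig: dict[str, list[tuple[int, str]]] = {}
    for g in genes:
        for t in g.tss_list:
            by_contig.setdefault(g.contig, []).append((t, g.gene_id))
    for contig in by_contig:
        by_contig[contig].sort()
    provenance: dict[str, list[str]] = {}
    unassigned = 0
    for peak in peaks:
        if peak.fold_enrichment < fold_cutoff:
            continue
        entries = by_contig.get(peak.contig)
        if not entries:
            unassigned += 1
            continue
        dists = [abs(t - peak.summit) for t, _ in entries]
        best = min(dists)
        hits = {gid for (t, gid), d in zip(entries, dists) if d == best}
        for gid in hits:
            provenance.setdefault(gid, []).append(peak.name)
    if unassigned:
        warnings.warn(f"{unassigned} peak(s) on contigs with no gene; "
                      "left unassigned", stacklevel=2)
    return BoundSet(label, frozenset(provenance),
                    {g: tuple(p) for g, p in provenance.items()})


def intersect_bound(sets: Sequence[BoundSet], label: str = "intersection"):
    """Intersection of component bound sets plus an overlap report.

    Returns ``(bound, report)`` where ``bound`` holds the genes bound
    by every component and ``report`` is a DataFrame of pairwise and
    k-way overlap counts with the union fraction (the "degree of
    overlap": intersection / union).
    """
    if len(sets) < 2:
        raise ValueError("need at least two bound sets to intersect")
    ids = [set(s.gene_ids) for s in sets]
    inter = frozenset(set.intersection(*ids))
    union = set.union(*ids)
    rows = []
    for i, a in enumerate(sets):
        for j in range(i + 1, len(sets)):
            b = sets[j]
            both = len(ids[i] & ids[j])
            rows.append({"set_a": a.label, "set_b": b.label,
                         "n_a": len(ids[i]), "n_b": len(ids[j]),
                         "n_overlap": both})
    rows.append({"set_a": " & ".join(s.label for s in sets), "set_b": "",
                 "n_a": len(union), "n_b": 0, "n_overlap": len(inter)})
    report = pd.DataFrame(rows)
    report["union_fraction"] = report["n_overlap"] / len(union) if union else np.nan
    provenance = {g: tuple(sorted(set().union(
        *(s.provenance.get(g, ()) for s in sets)))) for g in inter}
    return BoundSet(label, inter, provenance), report


def class_enrichment(bound: BoundSet, classes: Mapping[str, str],
                     universe: set[str]) -> pd.DataFrame:
    """Per-class over/under-representation of bound genes.

    ``classes`` must label every gene in ``universe``. For each class
    the 2x2 table (bound/unbound x in-class/out-of-class) is tested
    with two-sided Fisher's exact test; the output also carries the
    percentage of bound genes falling in the class and the class's
    share of the whole universe, so the two compositions can be
    compared directly.
    """
    missing = universe - set(classes)
    if missing:
        raise ValueError(f"{len(missing)} universe gene(s) lack a class label")
    bound_ids = bound.gene_ids & universe
    rows = []
    for cls in sorted(set(classes[g] for g in universe)):
        in_cls = {g for g in universe if classes[g] == cls}
        a = len(bound_ids & in_cls)
        b = len(bound_ids - in_cls)
        c = len(in_cls - bound_ids)
        d = len(universe) - a - b - c
        odds, p = sps.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        rows.append({
            "class": cls,
            "n_bound_in_class": a,
            "n_class": len(in_cls),
            "pct_of_bound": 100.0 * a / len(bound_ids) if bound_ids else np.nan,
            "pct_of_universe": 100.0 * len(in_cls) / len(universe),
            "odds_ratio": float(odds),
            "pvalue": float(p),
        })
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class PausingIndexRecord:
    gene_id: str
    selected_tss: int
    tss_mean_enrichment: float
    bound: bool


def pausing_index_bound(enrichment: CoverageTrack,
                        genes: Iterable[GeneModel],
                        threshold: float = 1.3,
                        tss_flank: int = TSS_FLANK) -> pd.DataFrame:
    """Pausing-index style bound call: a gene is bound when its mean
    enrichment over TSS +/- ``tss_flank`` exceeds ``threshold``
    (strictly). TSS selection uses the same highest-control-signal
    rule as the PRR."""
    records = []
    for gene in genes:
        tss = select_tss(gene, enrichment, tss_flank)
        mean = float(enrichment.window_mean(gene.contig, tss - tss_flank,
                                            tss + tss_flank))
        records.append(PausingIndexRecord(gene.gene_id, tss, mean,
                                          mean > threshold))
    return pd.DataFrame(records)


def expressed_genes(rpkm_table: pd.DataFrame, threshold: float = 1.0,
                    gene_ids: Iterable[str] | None = None) -> set[str]:
    """Genes whose mean RPKM across control replicate columns is
    strictly above ``threshold``.

    ``rpkm_table`` is indexed by gene_id with one column per control
    replicate. Genes listed in ``gene_ids`` but absent from the table
    count as 0 RPKM (warned).
    """
    means = rpkm_table.mean(axis=1)
    if gene_ids is not None:
        missing = set(gene_ids) - set(means.index)
        if missing:
            warnings.warn(f"{len(missing)} gene(s) missing from RPKM table; "
                          "treated as 0", stacklevel=2)
    return set(means.index[means > threshold])


def expression_quartiles(rpkm_table: pd.DataFrame) -> dict[str, str]:
    """Split expressed genes into four expression quartiles (Q1 low
    to Q4 high) on mean control RPKM; boundary ties fall in the lower
    quartile. Feeds :func:`class_enrichment` as the class labels."""
    means = rpkm_table.mean(axis=1)
    if len(means) < 4:
        raise ValueError("need at least 4 genes for quartiles")
    breaks = np.percentile(means.to_numpy(), [25, 50, 75])
    idx = np.searchsorted(breaks, means.to_numpy(), side="left") + 1
    return {g: f"Q{q}" for g, q in zip(means.index, idx)}
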