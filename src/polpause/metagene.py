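"""Metagene profiles and TSS-centered occupancy matrices.

Two coordinate frames are supported: a scaled frame (fixed-width
flanks upstream of the TSS and downstream of the TES, the gene body
rescaled to a fixed number of bins) and a TSS-centered frame (fixed
bp window around the TSS). Profiles report the across-gene mean and
standard error of the mean per position, strand-aware throughout:
a minus-strand gene contributes its signal 5'->3'.

Body rescaling pools the per-base signal into equal-width source
windows by exact fractional-overlap averaging (via the cumulative
integral), so the profile is linear in the track and independent of
how gene length divides the bin count.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from polpause.genome_io import CoverageTrack, GeneModel

__all__ = [
    "MetaProfile",
    "scaled_metagene",
    "tss_centered_profile",
    "tss_heatmap_matrix",
]


@dataclass(frozen=True)
class MetaProfile:
    """Across-gene mean signal with SEM on a common coordinate frame.

    ``x`` is bp relative to the TSS in tss_centered mode; in scaled
    mode it is a position index over upstream flank, body bins and
    downstream flank (boundaries in ``upstream``/``n_body_bins``).
    """

    x: np.ndarray = field(repr=False)
    mean: np.ndarray = field(repr=False)
    sem: np.ndarray = field(repr=False)
    n_genes: int
    mode: str
    upstream: int = 0
    n_body_bins: int = 0
    n_clipped: int = 0      # genes whose flanks ran past covered contig ends


def _sem(matrix: np.ndarray) -> np.ndarray:
    n = matrix.shape[0]
    if n < 2:
        return np.zeros(matrix.shape[1])
    return matrix.std(axis=0, ddof=1) / np.sqrt(n)


def _gene_oriented_array(track: CoverageTrack, gene: GeneModel,
                         start: int, end: int) -> np.ndarray:
    arr = track.to_array(gene.contig, start, end)
    return arr if gene.strand == "+" else arr[::-1]


def _rescale_body(arr: np.ndarray, n_bins: int) -> np.ndarray:
    """Mean-pool a per-base array into ``n_bins`` equal-width source
    windows, exactly (fractional base overlap handled by the
    cumulative integral)."""
    cum = np.concatenate(([0.0], np.cumsum(arr)))
    edges = np.linspace(0.0, len(arr), n_bins + 1)
    integ = np.interp(edges, np.arange(len(arr) + 1), cum)
    return np.diff(integ) / np.diff(edges)


def scaled_metagene(track: CoverageTrack, genes: Iterable[GeneModel],
                    upstream: int = 600, downstream: int = 600,
                    n_body_bins: int = 100,
                    min_length: int | None = None) -> MetaProfile:
    """Scaled metagene profile: ``upstream`` bp of per-base flank
    before the TSS, the gene body rescaled to ``n_body_bins``, and
    ``downstream`` bp after the TES; mean and SEM across genes.

    Genes shorter than ``min_length`` (default 2 x ``n_body_bins``)
    are skipped; flanks that run past the covered contig extent are
    zero-padded and tallied in ``n_clipped``.
    """
    if min_length is None:
        min_length = 2 * n_body_bins
    rows, n_clipped = [], 0
    for gene in genes:
        if gene.length < min_length:
            continue
        lo, hi = gene.start - upstream, gene.end + downstream
        if gene.strand == "-":
            lo, hi = gene.start - downstream, gene.end + upstream
        if lo < 0:
            n_clipped += 1
        arr = _gene_oriented_array(track, gene, lo, hi)
        flank5, body, flank3 = (arr[:upstream],
                                arr[upstream:upstream + gene.length],
                                arr[upstream + gene.length:])
        rows.append(np.concatenate([flank5, _rescale_body(body, n_body_bins),
                                    flank3]))
    if not rows:
        raise ValueError("no genes long enough for a scaled metagene")
    matrix = np.vstack(rows)
    x = np.arange(matrix.shape[1], dtype=float)
    return MetaProfile(x, matrix.mean(axis=0), _sem(matrix), len(rows),
                       "scaled", upstream, n_body_bins, n_clipped)


def tss_centered_profile(track: CoverageTrack, genes: Iterable[GeneModel],
                         halfwidth: int = 1000) -> MetaProfile:
    """Profile centered at each gene's TSS in a +/- ``halfwidth``
    window; x is bp relative to the TSS, positive downstream."""
    rows, n_clipped = [], 0
    for gene in genes:
        lo, hi = gene.tss - halfwidth, gene.tss + halfwidth
        if lo < 0:
            n_clipped += 1
        rows.append(_gene_oriented_array(track, gene, lo, hi))
    if not rows:
        raise ValueError("empty gene set")
    matrix = np.vstack(rows)
    x = np.arange(-halfwidth, halfwidth, dtype=float)
    return MetaProfile(x, matrix.mean(axis=0), _sem(matrix), len(rows),
                       "tss_centered", n_clipped=n_clipped)


def tss_heatmap_matrix(track: CoverageTrack, genes: Iterable[GeneModel],
                       sort_track: CoverageTrack | None = None,
                       halfwidth: int = 1000, bin_width: int = 10,
                       sort_halfwidth: int = 250):
    """Gene x position occupancy matrix around the TSS, rows sorted
    by decreasing mean of ``sort_track`` (default: ``track`` itself)
    over TSS +/- ``sort_halfwidth``; ties break by gene_id.

    Returns ``(matrix, row_order, x)``: the binned matrix, gene ids
    top to bottom, and bin-center coordinates relative to the TSS.
    """
    genes = list(genes)
    if not genes:
        raise ValueError("empty gene set")
    if sort_track is None:
        sort_track = track
    if halfwidth % bin_width:
        raise ValueError("halfwidth must be a multiple of bin_width")
    rows = {}
    keys = {}
    for gene in genes:
        arr = _gene_oriented_array(track, gene, gene.tss - halfwidth,
                                   gene.tss + halfwidth)
        rows[gene.gene_id] = arr.reshape(-1, bin_width).mean(axis=1)
        keys[gene.gene_id] = float(sort_track.window_mean(
            gene.contig, gene.tss - sort_halfwidth, gene.tss + sort_halfwidth))
    row_order = sorted(rows, key=lambda g: (-keys[g], g))
    matrix = np.vstack([rows[g] for g in row_order])
    x = np.arange(-halfwidth, halfwidth, bin_width, dtype=float) + bin_width / 2
    return matrix, row_order, x
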