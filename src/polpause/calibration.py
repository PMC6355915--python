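"""Spike-in library calibration and input-normalized enrichment tracks.

Libraries sequenced with a foreign-genome ("spike-in") chromatin
admixture are put on a common occupancy scale by dividing every
signal value by a per-library normalization factor: the number of
reads mapped to the spike-in genome per million reads mapped to the
experimental genome. All libraries, inputs included, are calibrated
before enrichment is computed against the matched input.

Because the factor is a pure ratio of read counts, calibration is
linear in the track, and any uniform factor cancels in log-ratio
statistics downstream (the PRR is calibration-invariant); what the
calibration changes is the *comparison across conditions*.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from polpause.genome_io import CoverageTrack

__all__ = [
    "CalibrationError",
    "LibraryStats",
    "read_library_stats",
    "spikein_factor",
    "calibrate_track",
    "log2_enrichment",
    "ratio_normalize",
]


class CalibrationError(ValueError):
    """Library read counts do not admit a spike-in factor."""


@dataclass(frozen=True)
class LibraryStats:
    """Read counts for one sequencing library.

    ``reads_experimental`` — reads mapped to the experimental genome;
    ``reads_spikein`` — reads mapped to the spike-in reference genome.
    """

    library_id: str
    reads_experimental: int
    reads_spikein: int

    def __post_init__(self):
        if self.reads_experimental < 0 or self.reads_spikein < 0:
            raise ValueError("read counts must be >= 0")


def read_library_stats(path) -> dict[str, LibraryStats]:
    """Read a TSV of (library_id, reads_experimental, reads_spikein)."""
    df = pd.read_csv(path, sep="\t", dtype={"library_id": str})
    return {
        row.library_id: LibraryStats(row.library_id,
                                     int(row.reads_experimental),
                                     int(row.reads_spikein))
        for row in df.itertuples()
    }


def spikein_factor(stats: LibraryStats) -> float:
    """Normalization factor: spike-in reads per million experimental reads.

    factor = reads_spikein / (reads_experimental / 1e6). Undefined
    (raises CalibrationError) if either count is zero.
    """
    if stats.reads_experimental <= 0:
        raise CalibrationError(
            f"{stats.library_id}: no experimental-genome reads; factor undefined")
    if stats.reads_spikein <= 0:
        raise CalibrationError(
            f"{stats.library_id}: no spike-in reads; factor undefined")
    return stats.reads_spikein / (stats.reads_experimental / 1e6)


def calibrate_track(track: CoverageTrack, stats: LibraryStats,
                    depth_normalize: bool = False) -> CoverageTrack:
    """Divide every signal value by the library's spike-in factor.

    Applied to IP and input libraries alike, before any enrichment
    ratio is formed. With ``depth_normalize=True`` the raw-count
    track is first converted to counts per million experimental
    reads; the combined scaling is then counts per spike-in read,
    which makes calibrated signal invariant to sequencing depth at a
    fixed spike-in chromatin fraction — the variant to use when
    comparing conditions sequenced to different depths. The default
    applies the factor alone, appropriate for tracks that are already
    depth-normalized.
    """
    factor = spikein_factor(stats)
    scale = 1.0 / factor
    if depth_normalize:
        scale *= 1e6 / stats.reads_experimental
    return track.scale(scale, label=track.label)


def _check_pseudocount(pseudocount: float) -> None:
    if not pseudocount > 0:
        raise ValueError(f"pseudocount must be > 0, got {pseudocount}")


def log2_enrichment(ip: CoverageTrack, input_track: CoverageTrack,
                    pseudocount: float = 0.01,
                    bin_width: int | None = None) -> CoverageTrack:
    """Per-base log2((ip + p) / (input + p)) enrichment track.

    The symmetric pseudocount ``p`` keeps the ratio finite and makes
    enrichment antisymmetric: swapping IP and input flips the sign.
    By default the ratio is computed exactly on the merged run-length
    segmentation; pass ``bin_width`` to average both tracks over
    fixed-width bins first (coarser, smaller output).
    """
    _check_pseudocount(pseudocount)
    if bin_width is not None:
        ip = _bin_track(ip, bin_width)
        input_track = _bin_track(input_track, bin_width)
    out = ip.combine(input_track,
                     lambda a, b: np.log2((a + pseudocount) / (b + pseudocount)),
                     label=ip.label)
    out.assay = "log2_enrichment"
    return out


def ratio_normalize(track_a: CoverageTrack, track_b: CoverageTrack,
                    pseudocount: float = 0.01,
                    bin_width: int | None = None) -> CoverageTrack:
    """Linear ratio (a + p) / (b + p), e.g. a histone mark over
    nucleosomal occupancy, for window quantification downstream.

    Note bases covered by neither track read as 0, not 1: the ratio
    is only defined where at least one input has signal.
    """
    _check_pseudocount(pseudocount)
    if bin_width is not None:
        track_a = _bin_track(track_a, bin_width)
        track_b = _bin_track(track_b, bin_width)
    out = track_a.combine(track_b, lambda a, b: (a + pseudocount) / (b + pseudocount),
                          label=track_a.label)
    out.assay = "ratio"
    return out


def _bin_track(track: CoverageTrack, bin_width: int) -> CoverageTrack:
    if bin_width < 1:
        raise ValueError("bin_width must be >= 1")
    out = CoverageTrack(label=track.label, assay=track.assay)
    for contig in track.contigs:
        starts, ends, _ = track.segments(contig)
        if len(starts) == 0:
            continue
        lo = (starts[0] // bin_width) * bin_width
        hi = -(-ends[-1] // bin_width) * bin_width
        edges = np.arange(lo, hi + bin_width, bin_width)
        means = track.window_sum(contig, edges[:-1], edges[1:]) / bin_width
        nz = means != 0
        out.add_segments(contig, edges[:-1][nz], edges[1:][nz], means[nz])
    return out
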