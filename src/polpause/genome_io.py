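"""Genomic file formats and the in-memory gene / coverage model.

All coordinates inside the package are 0-based, half-open (BED
convention). GTF input, which is 1-based inclusive on disk, is
converted at the parsing boundary. "Upstream" and "downstream" are
always strand-aware relative to a gene's TSS/TES.

Coverage is kept run-length encoded per contig: sorted non-overlapping
segments with a constant value each; any base not covered by a segment
reads as 0. Window sums and means are computed from segment integrals,
so queries are exact (no binning) and independent of how the signal
was run-length split on disk.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence, TextIO

import numpy as np

__all__ = [
    "FormatError",
    "GeneModel",
    "CoverageTrack",
    "PeakCall",
    "read_gene_models",
    "read_bedgraph",
    "write_bedgraph",
    "read_narrowpeak",
    "write_narrowpeak",
]


class FormatError(ValueError):
    """A malformed line or inconsistent record in a genomic text format."""


def _as_handle(stream) -> TextIO:
    if isinstance(stream, str):
        if stream == "" or "\n" in stream or "\t" in stream:
            return io.StringIO(stream)
        return open(stream)
    return stream


# ---------------------------------------------------------------------------
# gene models
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneModel:
    """A strand-aware gene with exon structure.

    ``tss_list`` carries every annotated transcript start (one entry
    for BED12 input); selection among alternative starts is done
    downstream against a control track. On the minus strand the TSS
    coordinates are numerically >= the TES.
    """

    gene_id: str
    contig: str
    strand: str
    tss_list: tuple[int, ...]
    tes: int
    exon_blocks: tuple[tuple[int, int], ...]

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        blocks = tuple(sorted(tuple(b) for b in self.exon_blocks))
        object.__setattr__(self, "exon_blocks", blocks)
        for (s0, e0), (s1, e1) in zip(blocks, blocks[1:]):
            if s1 < e0:
                raise ValueError(f"{self.gene_id}: overlapping exon blocks")
        if self.strand == "-" and any(t < self.tes for t in self.tss_list):
            raise ValueError(f"{self.gene_id}: minus-strand TSS upstream of TES")

    @property
    def start(self) -> int:
        return self.exon_blocks[0][0]

    @property
    def end(self) -> int:
        return self.exon_blocks[-1][1]

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def tss(self) -> int:
        """The first (annotation-order) TSS; use pausing.select_tss to pick
        among alternatives by control signal."""
        return self.tss_list[0]

    @property
    def largest_intron(self) -> int:
        gaps = [s1 - e0 for (_, e0), (s1, _) in zip(self.exon_blocks, self.exon_blocks[1:])]
        return max(gaps, default=0)


@dataclass(frozen=True)
class PeakCall:
    """One called peak with its summit and fold enrichment over input."""

    contig: str
    start: int
    end: int
    summit: int
    fold_enrichment: float
    name: str = "."

    def __post_init__(self):
        if not (self.start <= self.summit < self.end):
            raise ValueError(f"summit {self.summit} outside [{self.start},{self.end})")


# ---------------------------------------------------------------------------
# run-length encoded coverage
# ---------------------------------------------------------------------------

class CoverageTrack:
    """Per-contig run-length encoded non-negative signal.

    Parameters
    ----------
    label, assay:
        Free-text identifiers (condition / replicate, assay type).
    """

    def __init__(self, label: str = "", assay: str = ""):
        self.label = label
        self.assay = assay
        # contig -> (starts, ends, values) sorted, non-overlapping
        self._seg: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        self._cum: dict[str, np.ndarray] = {}

    # -- construction ------------------------------------------------------

    def add_segments(self, contig: str, starts, ends, values,
                     allow_negative: bool = False) -> None:
        starts = np.asarray(starts, dtype=np.int64)
        ends = np.asarray(ends, dtype=np.int64)
        values = np.asarray(values, dtype=np.float64)
        if not allow_negative and np.any(values < 0):
            raise ValueError("coverage values must be >= 0")
        if np.any(ends <= starts):
            raise FormatError("empty or inverted interval")
        order = np.argsort(starts, kind="stable")
        starts, ends, values = starts[order], ends[order], values[order]
        if np.any(starts[1:] < ends[:-1]):
            raise FormatError(f"overlapping intervals on {contig}")
        # merge runs of equal adjacent values that touch
        if len(starts) > 1:
            new_run = (starts[1:] != ends[:-1]) | (values[1:] != values[:-1])
            first = np.concatenate(([True], new_run))
            last = np.concatenate((new_run, [True]))
            starts, ends, values = starts[first], ends[last], values[first]
        self._seg[contig] = (starts, ends, values)
        self._cum.pop(contig, None)

    @classmethod
    def from_dense(cls, contig: str, array, label: str = "", assay: str = "",
                   offset: int = 0) -> "CoverageTrack":
        """Run-length encode a dense per-base array starting at ``offset``."""
        arr = np.asarray(array, dtype=np.float64)
        track = cls(label=label, assay=assay)
        if arr.size == 0:
            track._seg[contig] = (np.empty(0, np.int64), np.empty(0, np.int64),
                                  np.empty(0, np.float64))
            return track
        change = np.flatnonzero(arr[1:] != arr[:-1]) + 1
        starts = np.concatenate(([0], change)) + offset
        ends = np.concatenate((change, [arr.size])) + offset
        values = arr[starts - offset]
        nz = values != 0
        track.add_segments(contig, starts[nz], ends[nz], values[nz])
        return track

    # -- queries -----------------------------------------------------------

    @property
    def contigs(self) -> list[str]:
        return sorted(self._seg)

    def segments(self, contig: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return self._seg.get(contig, (np.empty(0, np.int64), np.empty(0, np.int64),
                                      np.empty(0, np.float64)))

    def _integral(self, contig: str, pos) -> np.ndarray:
        """Integral of the signal over [0, pos) — vectorized in pos."""
        starts, ends, values = self.segments(contig)
        if contig not in self._cum:
            seg_area = values * (ends - starts)
            self._cum[contig] = np.concatenate(([0.0], np.cumsum(seg_area)))
        cum = self._cum[contig]
        pos = np.asarray(pos, dtype=np.int64)
        idx = np.searchsorted(starts, pos, side="right") - 1
        out = np.where(idx >= 0, cum[np.maximum(idx, 0)], 0.0)
        inside = idx >= 0
        if np.any(inside):
            i = np.maximum(idx, 0)
            partial = np.clip(pos - starts[i], 0, ends[i] - starts[i]) * values[i]
            out = out + np.where(inside, partial, 0.0)
        return out

    def window_sum(self, contig: str, start, end) -> np.ndarray:
        """Exact signal integral over [start, end); vectorized."""
        start = np.maximum(np.asarray(start, dtype=np.int64), 0)
        end = np.asarray(end, dtype=np.int64)
        return self._integral(contig, end) - self._integral(contig, start)

    def window_mean(self, contig: str, start, end) -> np.ndarray:
        start = np.asarray(start, dtype=np.int64)
        end = np.asarray(end, dtype=np.int64)
        width = np.maximum(end - np.maximum(start, 0), 1)
        return self.window_sum(contig, start, end) / width

    def to_array(self, contig: str, start: int, end: int) -> np.ndarray:
        """Dense per-base signal over [start, end); out-of-coverage bases are 0."""
        out = np.zeros(end - start, dtype=np.float64)
        starts, ends, values = self.segments(contig)
        lo = np.searchsorted(ends, start, side="right")
        hi = np.searchsorted(starts, end, side="left")
        for s, e, v in zip(starts[lo:hi], ends[lo:hi], values[lo:hi]):
            out[max(s, start) - start: min(e, end) - start] = v
        return out

    # -- arithmetic --------------------------------------------------------

    def scale(self, factor: float, label: str | None = None) -> "CoverageTrack":
        """Return a copy with every value multiplied by ``factor`` (> 0)."""
        if factor <= 0:
            raise ValueError("scale factor must be > 0")
        out = CoverageTrack(label=self.label if label is None else label,
                            assay=self.assay)
        for contig, (s, e, v) in self._seg.items():
            out._seg[contig] = (s.copy(), e.copy(), v * factor)
        return out

    def combine(self, other: "CoverageTrack", func, label: str = "") -> "CoverageTrack":
        """Apply ``func(a_values, b_values)`` on the merged segmentation.

        The result is exact wherever either track is covered; bases
        covered by neither remain uncovered (read as 0), so ``func``
        must map (0, 0) to the value the caller wants outside coverage
        only if that value is 0 — otherwise use dense extraction.
        """
        out = CoverageTrack(label=label, assay=self.assay)
        for contig in sorted(set(self._seg) | set(other._seg)):
            sa, ea, va = self.segments(contig)
            sb, eb, vb = other.segments(contig)
            edges = np.concatenate([sa, ea, sb, eb])
            edges.sort(kind="stable")
            if edges.size:
                edges = edges[np.concatenate(([True], edges[1:] != edges[:-1]))]
            if edges.size < 2:
                continue
            mids = edges[:-1]
            a = _values_at(sa, ea, va, mids)
            b = _values_at(sb, eb, vb, mids)
            vals = np.asarray(func(a, b), dtype=np.float64)
            nz = vals != 0
            # derived tracks (log2 enrichment) may legitimately go negative
            out.add_segments(contig, edges[:-1][nz], edges[1:][nz], vals[nz],
                             allow_negative=True)
        return out


def _values_at(starts, ends, values, pos):
    idx = np.searchsorted(starts, pos, side="right") - 1
    ok = (idx >= 0) & (pos < ends[np.maximum(idx, 0)] if len(ends) else False)
    out = np.zeros(len(pos))
    if len(values):
        out[ok] = values[idx[ok]]
    return out


# ---------------------------------------------------------------------------
# bedGraph
# ---------------------------------------------------------------------------

def read_bedgraph(stream, label: str = "", assay: str = "") -> CoverageTrack:
    """Parse 4-column bedGraph text into a :class:`CoverageTrack`.

    Intervals must be non-overlapping per contig; values must be >= 0.
    """
    handle = _as_handle(stream)
    per_contig: dict[str, list[tuple[int, int, float]]] = {}
    for lineno, line in enumerate(handle, start=1):
        line = line.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split()
        if len(fields) != 4:
            raise FormatError(f"line {lineno}: expected 4 bedGraph columns, got {len(fields)}")
        try:
            contig, start, end, value = fields[0], int(fields[1]), int(fields[2]), float(fields[3])
        except ValueError as exc:
            raise FormatError(f"line {lineno}: {exc}") from None
        if value < 0:
            raise ValueError(f"line {lineno}: negative coverage value {value}")
        per_contig.setdefault(contig, []).append((start, end, value))
    track = CoverageTrack(label=label, assay=assay)
    for contig, rows in per_contig.items():
        starts, ends, values = zip(*rows)
        track.add_segments(contig, starts, ends, values)
    return track


def write_bedgraph(track: CoverageTrack, stream) -> None:
    """Write non-zero segments as 4-column bedGraph.

    Values are written with full float precision so that
    write-then-read reproduces the track exactly (uncovered and
    zero-valued bases are equivalent: both read back as 0).
    """
    own = isinstance(stream, str)
    handle = open(stream, "w") if own else stream
    try:
        for contig in track.contigs:
            starts, ends, values = track.segments(contig)
            for s, e, v in zip(starts, ends, values):
                if v != 0:
                    handle.write(f"{contig}\t{s}\t{e}\t{float(v)!r}\n")
    finally:
        if own:
            handle.close()


# ---------------------------------------------------------------------------
# BED12 / GTF gene models
# ---------------------------------------------------------------------------

_GTF_ATTR = re.compile(r'(\w+)\s+"([^"]*)"')


def read_gene_models(stream, fmt: str = "auto") -> list[GeneModel]:
    """Read gene models from BED12 or GTF text.

    GTF coordinates (1-based inclusive) are converted to 0-based
    half-open. A GTF gene with several annotated transcripts yields
    one GeneModel whose ``tss_list`` holds every distinct transcript
    start, 5'-most first.
    """
    handle = _as_handle(stream)
    lines = handle.read().splitlines()
    if fmt == "auto":
        fmt = _sniff_gene_format(lines)
    if fmt == "bed12":
        return _parse_bed12(lines)
    if fmt == "gtf":
        return _parse_gtf(lines)
    raise ValueError(f"unknown gene-model format {fmt!r}")


def _sniff_gene_format(lines: Sequence[str]) -> str:
    for line in lines:
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) >= 9 and fields[3].isdigit() and fields[4].isdigit():
            return "gtf"
        return "bed12"
    return "bed12"


def _parse_bed12(lines: Sequence[str]) -> list[GeneModel]:
    genes = []
    for lineno, line in enumerate(lines, start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        f = line.split("\t")
        if len(f) < 12:
            raise FormatError(f"line {lineno}: expected 12 BED12 columns, got {len(f)}")
        try:
            contig, start, end = f[0], int(f[1]), int(f[2])
            name, strand = f[3], f[5]
            n_blocks = int(f[9])
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            offsets = [int(x) for x in f[11].rstrip(",").split(",")]
        except ValueError as exc:
            raise FormatError(f"line {lineno}: {exc}") from None
        if len(sizes) != n_blocks or len(offsets) != n_blocks:
            raise FormatError(
                f"line {lineno}: blockCount {n_blocks} inconsistent with "
                f"blockSizes/blockStarts lengths {len(sizes)}/{len(offsets)}")
        blocks = tuple((start + o, start + o + s) for o, s in zip(offsets, sizes))
        if blocks[0][0] != start or blocks[-1][1] != end:
            raise FormatError(f"line {lineno}: blocks do not span [chromStart, chromEnd)")
        if strand == "+":
            tss, tes = start, end
        else:
            tss, tes = end, start
        genes.append(GeneModel(gene_id=name, contig=contig, strand=strand,
                               tss_list=(tss,), tes=tes, exon_blocks=blocks))
    return genes


def _parse_gtf(lines: Sequence[str]) -> list[GeneModel]:
    exons: dict[str, list[tuple[int, int]]] = {}
    tx_spans: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, tuple[str, str]] = {}
    for lineno, line in enumerate(lines, start=1):
        if not line.strip() or line.startswith("#"):
            continue
        f = line.split("\t")
        if len(f) < 9:
            raise FormatError(f"line {lineno}: expected 9 GTF columns, got {len(f)}")
        contig, _, feature, start, end, _, strand = f[0], f[1], f[2], f[3], f[4], f[5], f[6]
        try:
            start0, end0 = int(start) - 1, int(end)  # 1-based incl -> 0-based half-open
        except ValueError as exc:
            raise FormatError(f"line {lineno}: {exc}") from None
        attrs = dict(_GTF_ATTR.findall(f[8]))
        gene_id = attrs.get("gene_id")
        if gene_id is None:
            raise FormatError(f"line {lineno}: missing gene_id attribute")
        meta.setdefault(gene_id, (contig, strand))
        if feature == "exon":
            exons.setdefault(gene_id, []).append((start0, end0))
        elif feature == "transcript":
            tx_spans.setdefault(gene_id, []).append((start0, end0))
    genes = []
    for gene_id, blocks in exons.items():
        contig, strand = meta[gene_id]
        merged = _merge_blocks(blocks)
        gstart, gend = merged[0][0], merged[-1][1]
        spans = tx_spans.get(gene_id, [(gstart, gend)])
        if strand == "+":
            tss_list = tuple(sorted({s for s, _ in spans}))
            tes = gend
        else:
            tss_list = tuple(sorted({e for _, e in spans}, reverse=True))
            tes = gstart
        genes.append(GeneModel(gene_id=gene_id, contig=contig, strand=strand,
                               tss_list=tss_list, tes=tes, exon_blocks=merged))
    return genes


def _merge_blocks(blocks: Iterable[tuple[int, int]]) -> tuple[tuple[int, int], ...]:
    merged: list[list[int]] = []
    for s, e in sorted(blocks):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return tuple((s, e) for s, e in merged)


# ---------------------------------------------------------------------------
# narrowPeak
# ---------------------------------------------------------------------------

def read_narrowpeak(stream, summit_dialect: str = "midpoint") -> list[PeakCall]:
    """Parse ENCODE 10-column narrowPeak text.

    The summit is ``start + offset`` (column 10). An offset of -1
    (summit not reported) maps to the interval midpoint when
    ``summit_dialect='midpoint'``; pass ``'error'`` to reject such rows.
    Column 7 (signalValue) is taken as the fold enrichment.
    """
    handle = _as_handle(stream)
    peaks = []
    for lineno, line in enumerate(handle, start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        f = line.split("\t")
        if len(f) != 10:
            raise FormatError(f"line {lineno}: expected 10 narrowPeak columns, got {len(f)}")
        try:
            contig, start, end = f[0], int(f[1]), int(f[2])
            fold = float(f[6])
            offset = int(f[9])
        except ValueError as exc:
            raise FormatError(f"line {lineno}: {exc}") from None
        if offset == -1:
            if summit_dialect == "error":
                raise FormatError(f"line {lineno}: summit offset -1 not allowed")
            summit = (start + end) // 2
        else:
            summit = start + offset
        peaks.append(PeakCall(contig=contig, start=start, end=end,
                              summit=summit, fold_enrichment=fold, name=f[3]))
    return peaks


def write_bed12(genes: Iterable[GeneModel], stream) -> None:
    """Write gene models as BED12 (one line per gene, exon blocks).

    Only the first (annotation-primary) TSS survives a BED12 round
    trip; alternative starts need GTF.
    """
    own = isinstance(stream, str)
    handle = open(stream, "w") if own else stream
    try:
        for g in genes:
            start, end = g.start, g.end
            sizes = ",".join(str(e - s) for s, e in g.exon_blocks)
            offsets = ",".join(str(s - start) for s, _ in g.exon_blocks)
            handle.write("\t".join([
                g.contig, str(start), str(end), g.gene_id, "0", g.strand,
                str(start), str(end), "0", str(len(g.exon_blocks)),
                sizes, offsets,
            ]) + "\n")
    finally:
        if own:
            handle.close()


def write_narrowpeak(peaks: Iterable[PeakCall], stream) -> None:
    own = isinstance(stream, str)
    handle = open(stream, "w") if own else stream
    try:
        for p in peaks:
            handle.write("\t".join([
                p.contig, str(p.start), str(p.end), p.name, "0", ".",
                f"{p.fold_enrichment:g}", "-1", "-1", str(p.summit - p.start),
            ]) + "\n")
    finally:
        if own:
            handle.close()
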