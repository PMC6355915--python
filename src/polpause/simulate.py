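"""Synthetic data with the statistical structure the estimators assume.

The generator emulates, on one synthetic contig, the coverage
structure of a spike-in-calibrated Pol II ChIP / 4sU nascent-RNA
study: genes with log-normal lengths and intron sizes, IP tracks
with a promoter-proximal Gaussian peak of per-gene strength over a
gene-body plateau against a flat input, Poisson count noise on 10 bp
bins, spike-in read fractions in the library stats, post-DRB-release
nascent waves advancing at a configurable elongation rate with a
logistic (not hard-step) front edge, and narrowPeak calls over a
planted "bound" gene subset plus sub-cutoff decoys.

Every quantity an estimator is supposed to recover is recorded as
truth at generation time (expected PRR from the expectation profile,
front positions, the bound set), so recovery can be tested without
external data. All randomness flows from ``SimulationConfig.seed``
plus a stable per-condition offset: the same config yields
byte-identical output files.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

from polpause.calibration import LibraryStats
from polpause.genome_io import CoverageTrack, GeneModel, PeakCall

__all__ = [
    "SimulationConfig",
    "SimulatedGenome",
    "ChIPSim",
    "DRBSim",
    "simulate_genes",
    "simulate_chip",
    "simulate_drb_timecourse",
    "simulate_peaks",
]

CONTIG = "chr_sim"
BIN = 10  # bp; Poisson noise is drawn per 10 bp bin


@dataclass(frozen=True)
class SimulationConfig:
    """Study-condition parameters of the generator.

    Signal levels are expected counts per base at the reference
    sequencing depth ``depth``; ``pause_strength`` is the height of
    the promoter Gaussian in the same units, multiplied per gene by a
    log-normal factor (``pause_strength_log_sd``) so pausing strength
    varies across genes as it does in real data. DRB plateau and
    background are expected counts per 100 bp wave-front bin.
    """

    n_genes: int = 200
    seed: int = 0
    genome_length: int | None = None        # auto-sized when None
    # gene structure
    length_log_mu: float = 9.0              # ln bp; median ~8.1 kb
    length_log_sigma: float = 0.8
    frac_genes_over_10kb: float | None = None  # overrides length_log_mu
    intron_log_mu: float = 7.0              # ln bp; median ~1.1 kb
    intron_log_sigma: float = 1.0
    multi_exon_fraction: float = 0.8
    multi_tss_fraction: float = 0.1
    min_gene_gap: int = 2_000
    bound_fraction: float = 0.3
    # ChIP signal (counts/bp at reference depth)
    pause_strength: float = 8.0
    pause_strength_log_sd: float = 0.8
    body_level: float = 2.0
    background: float = 0.2
    peak_sd: float = 100.0                  # bp
    spike_fraction: float = 0.05
    depth: int = 2_000_000
    # DRB/4sU wave front
    elongation_rate: float = 1_000.0        # bp/min
    timepoints: tuple[float, ...] = (0.0, 2.0, 8.0, 16.0)
    drb_plateau: float = 50.0               # counts per 100 bp bin
    drb_background: float = 2.0
    front_edge_scale: float = 50.0          # logistic scale, bp (~2-bin edge)
    # peak calls
    peak_fold_range: tuple[float, float] = (2.5, 8.0)
    decoy_fold_range: tuple[float, float] = (1.0, 1.9)
    decoy_fraction: float = 0.3
    summit_jitter_sd: float = 50.0          # bp around the TSS


def _rng(config: SimulationConfig, *tags: str) -> np.random.Generator:
    offsets = [zlib.crc32(t.encode()) for t in tags]
    return np.random.default_rng([config.seed % (2 ** 31), *offsets])


@dataclass(frozen=True)
class SimulatedGenome:
    """Gene models plus generation truth (bound set, pause factors)."""

    genes: tuple[GeneModel, ...]
    contig_sizes: dict[str, int]
    bound_ids: frozenset[str]
    gene_attrs: pd.DataFrame = field(repr=False)  # per-gene truth table
    config: SimulationConfig = field(repr=False)

    @property
    def contig(self) -> str:
        return next(iter(self.contig_sizes))

    def pause_multiplier(self, gene_id: str) -> float:
        return float(self.gene_attrs.set_index("gene_id")
                     .loc[gene_id, "pause_multiplier"])


def simulate_genes(config: SimulationConfig) -> SimulatedGenome:
    """Place non-overlapping, strand-randomized genes on one contig.

    Lengths are log-normal; when ``frac_genes_over_10kb`` is given the
    location parameter is solved so that fraction of genes exceeds
    10 kb in expectation. Most genes get one intron (log-normal size,
    capped to fit) so the largest-intron classes are populated; a
    ``multi_tss_fraction`` of genes carries a second annotated TSS.
    A ``bound_fraction`` subset is recorded as the planted bound set.
    """
    rng = _rng(config, "genes")
    mu = config.length_log_mu
    if config.frac_genes_over_10kb is not None:
        mu = float(np.log(10_000.0)
                   - config.length_log_sigma
                   * norm.ppf(1.0 - config.frac_genes_over_10kb))
    lengths = np.maximum(
        rng.lognormal(mu, config.length_log_sigma, config.n_genes), 400
    ).astype(np.int64)
    gaps = rng.integers(config.min_gene_gap, 3 * config.min_gene_gap,
                        config.n_genes + 1)
    needed = int(lengths.sum() + gaps.sum())
    genome_length = config.genome_length
    if genome_length is None:
        genome_length = needed
    elif genome_length < needed:
        raise ValueError(
            f"genome_length {genome_length} cannot hold {config.n_genes} "
            f"genes needing {needed} bp")
    strands = rng.choice(["+", "-"], config.n_genes)
    has_intron = rng.random(config.n_genes) < config.multi_exon_fraction
    intron_sizes = rng.lognormal(config.intron_log_mu, config.intron_log_sigma,
                                 config.n_genes).astype(np.int64)
    extra_tss = rng.random(config.n_genes) < config.multi_tss_fraction
    tss2_offset = rng.integers(150, 450, config.n_genes)
    exon1_frac = rng.uniform(0.2, 0.6, config.n_genes)
    pause_mult = rng.lognormal(0.0, config.pause_strength_log_sd, config.n_genes)

    genes, rows = [], []
    pos = int(gaps[0])
    for i in range(config.n_genes):
        start, length = pos, int(lengths[i])
        end = start + length
        pos = end + int(gaps[i + 1])
        intron = 0
        if has_intron[i] and length >= 600:
            intron = int(min(intron_sizes[i], length - 400))
            e1 = max(100, int(exon1_frac[i] * (length - intron)))
            blocks = ((start, start + e1), (start + e1 + intron, end))
            if intron <= 0:
                intron, blocks = 0, ((start, end),)
        else:
            blocks = ((start, end),)
        strand = strands[i]
        if strand == "+":
            tss_list, tes = [start], end
            if extra_tss[i] and tss2_offset[i] < length - 100:
                tss_list.append(start + int(tss2_offset[i]))
        else:
            tss_list, tes = [end], start
            if extra_tss[i] and tss2_offset[i] < length - 100:
                tss_list.append(end - int(tss2_offset[i]))
        gene_id = f"g{i:04d}"
        genes.append(GeneModel(gene_id=gene_id, contig=CONTIG, strand=strand,
                               tss_list=tuple(tss_list), tes=tes,
                               exon_blocks=blocks))
        rows.append({"gene_id": gene_id, "length": length,
                     "largest_intron": intron,
                     "pause_multiplier": float(pause_mult[i])})
    n_bound = int(round(config.bound_fraction * config.n_genes))
    bound = frozenset(
        f"g{i:04d}" for i in rng.choice(config.n_genes, n_bound, replace=False))
    attrs = pd.DataFrame(rows, columns=["gene_id", "length", "largest_intron",
                                        "pause_multiplier"])
    attrs["is_bound"] = attrs["gene_id"].isin(bound)
    return SimulatedGenome(tuple(genes), {CONTIG: int(genome_length)},
                           bound, attrs, config)


# ---------------------------------------------------------------------------
# ChIP-style IP/input tracks
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ChIPSim:
    condition: str
    ip: CoverageTrack = field(repr=False)
    input: CoverageTrack = field(repr=False)
    ip_stats: LibraryStats = field(repr=False)
    input_stats: LibraryStats = field(repr=False)
    truth: pd.DataFrame = field(repr=False)  # gene_id, expected_prr, ...


def _expected_ip_rate(genome: SimulatedGenome, pause_strength: float,
                      body_level: float, background: float,
                      peak_sd: float) -> np.ndarray:
    """Expected IP counts/bp per 10 bp bin (value at bin center)."""
    L = genome.contig_sizes[genome.contig]
    n_bins = L // BIN
    rate = np.full(n_bins, background)
    mult = genome.gene_attrs.set_index("gene_id")["pause_multiplier"]
    for gene in genome.genes:
        b0, b1 = gene.start // BIN, min(gene.end // BIN, n_bins)
        rate[b0:b1] += body_level
        amp = pause_strength * float(mult[gene.gene_id])
        if amp > 0:
            tss = gene.tss
            w0 = max(int((tss - 5 * peak_sd) // BIN), 0)
            w1 = min(int((tss + 5 * peak_sd) // BIN) + 1, n_bins)
            centers = np.arange(w0, w1) * BIN + BIN / 2
            rate[w0:w1] += amp * np.exp(-0.5 * ((centers - tss) / peak_sd) ** 2)
    return rate


def _sample_track(rate_per_bp: np.ndarray, scale: float, label: str,
                  assay: str, rng: np.random.Generator) -> CoverageTrack:
    counts = rng.poisson(rate_per_bp * BIN * scale)
    track = CoverageTrack(label=label, assay=assay)
    nz = np.flatnonzero(counts)
    track.add_segments(CONTIG, nz * BIN, (nz + 1) * BIN, counts[nz] / BIN)
    return track


def simulate_chip(genome: SimulatedGenome, condition: str = "control",
                  pause_strength: float | None = None,
                  depth: int | None = None) -> ChIPSim:
    """IP and input tracks with Poisson noise plus library stats.

    Expected IP coverage is ``pause_strength x per-gene multiplier``
    Gaussian at the primary TSS, a ``body_level`` plateau over the
    gene span, and flat background; the input is the flat background
    alone. ``depth`` rescales both tracks relative to the config's
    reference depth (the spike-in fraction stays fixed), emulating a
    deeper or shallower sequencing run of the same material.

    The truth table stores each gene's expected PRR computed
    analytically from the expectation profile (input cancels because
    it is flat), together with window expectations.
    """
    cfg = genome.config
    if pause_strength is None:
        pause_strength = cfg.pause_strength
    if depth is None:
        depth = cfg.depth
    scale = depth / cfg.depth
    rate = _expected_ip_rate(genome, pause_strength, cfg.body_level,
                             cfg.background, cfg.peak_sd)
    rng = _rng(cfg, "chip", condition, str(depth))
    ip = _sample_track(rate, scale, condition, "IP", rng)
    # the input library has the same total depth as the IP, spread
    # uniformly: flat at the IP's genome-wide mean rate
    input_rate = np.full_like(rate, rate.mean())
    inp = _sample_track(input_rate, scale, condition, "input", rng)
    reads_exp = int(round(depth * (1 - cfg.spike_fraction)))
    reads_spike = int(round(depth * cfg.spike_fraction))
    ip_stats = LibraryStats(f"{condition}_IP", reads_exp, reads_spike)
    input_stats = LibraryStats(f"{condition}_input", reads_exp, reads_spike)
    truth = _expected_prr_table(genome, rate)
    return ChIPSim(condition, ip, inp, ip_stats, input_stats, truth)


def _expected_prr_table(genome: SimulatedGenome,
                        rate: np.ndarray) -> pd.DataFrame:
    from polpause.pausing import gene_windows  # local: avoid cycle at import
    rows = []
    for gene in genome.genes:
        win = gene_windows(gene, gene.tss)
        if not win.eligible:
            rows.append({"gene_id": gene.gene_id, "expected_prr": np.nan,
                         "eligible": False})
            continue
        tss_mean = _window_rate_mean(rate, *win.tss_window)
        body_mean = _window_rate_mean(rate, *win.body_window)
        rows.append({"gene_id": gene.gene_id,
                     "expected_tss_rate": tss_mean,
                     "expected_body_rate": body_mean,
                     "expected_prr": float(np.log2(body_mean / tss_mean)),
                     "eligible": True})
    return pd.DataFrame(rows)


def _window_rate_mean(rate: np.ndarray, start: int, end: int) -> float:
    b0, b1 = max(start // BIN, 0), min(-(-end // BIN), len(rate))
    return float(rate[b0:b1].mean())


# ---------------------------------------------------------------------------
# DRB/4sU time course
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DRBSim:
    condition: str
    tracks: Mapping[float, CoverageTrack] = field(repr=False)
    truth: pd.DataFrame = field(repr=False)  # gene_id, timepoint, front_bp


def simulate_drb_timecourse(genome: SimulatedGenome,
                            condition: str = "control",
                            rate_bp_per_min: float | None = None) -> DRBSim:
    """Nascent-signal tracks at each timepoint after release from a
    DRB block, one wave per gene advancing at the elongation rate.

    At time t the expected signal inside a gene is the plateau up to
    ``rate x t`` bp downstream of the TSS, relaxing to background
    over a logistic edge (scale ``front_edge_scale``); intergenic
    bases sit at background. Truth front = ``rate x t`` (clipped to
    the gene end). Poisson counts per 10 bp bin.
    """
    cfg = genome.config
    if rate_bp_per_min is None:
        rate_bp_per_min = cfg.elongation_rate
    if not cfg.timepoints:
        raise ValueError("timepoint list is empty")
    if rate_bp_per_min <= 0:
        raise ValueError("elongation rate must be > 0")
    L = genome.contig_sizes[genome.contig]
    n_bins = L // BIN
    plateau_bp = cfg.drb_plateau / 100.0      # counts/bp
    bg_bp = cfg.drb_background / 100.0
    tracks: dict[float, CoverageTrack] = {}
    truth_rows = []
    for t in cfg.timepoints:
        front = rate_bp_per_min * t
        exp_rate = np.full(n_bins, bg_bp)
        for gene in genome.genes:
            b0, b1 = gene.start // BIN, min(gene.end // BIN, n_bins)
            centers = np.arange(b0, b1) * BIN + BIN / 2
            dist = (centers - gene.tss) if gene.strand == "+" else (gene.tss - centers)
            exp_rate[b0:b1] = bg_bp + (plateau_bp - bg_bp) * expit(
                (front - dist) / cfg.front_edge_scale)
            truth_rows.append({"gene_id": gene.gene_id, "timepoint": t,
                               "front_bp": float(min(front, gene.length))})
        rng = _rng(cfg, "drb", condition, f"t{t:g}")
        tracks[t] = _sample_track(exp_rate, 1.0, f"{condition}_t{t:g}",
                                  "4sU-DRB", rng)
    return DRBSim(condition, tracks, pd.DataFrame(truth_rows))


# ---------------------------------------------------------------------------
# peak calls
# ---------------------------------------------------------------------------

def simulate_peaks(genome: SimulatedGenome,
                   bound_subset: frozenset[str] | None = None,
                   component: str = "factor",
                   with_decoys: bool = True) -> list[PeakCall]:
    """narrowPeak-style calls: one above-cutoff peak at each bound
    gene's TSS (summit jittered), plus optional sub-cutoff decoy
    peaks at unbound genes."""
    cfg = genome.config
    if bound_subset is None:
        bound_subset = genome.bound_ids
    rng = _rng(cfg, "peaks", component)
    by_id = {g.gene_id: g for g in genome.genes}
    unknown = set(bound_subset) - set(by_id)
    if unknown:
        raise ValueError(f"bound_subset contains unknown genes: {sorted(unknown)[:3]}")
    peaks = []
    for k, gid in enumerate(sorted(bound_subset)):
        gene = by_id[gid]
        summit = int(round(rng.normal(gene.tss, cfg.summit_jitter_sd)))
        fold = float(rng.uniform(*cfg.peak_fold_range))
        peaks.append(PeakCall(CONTIG, summit - 150, summit + 150, summit,
                              fold, name=f"{component}_peak_{k}"))
    if with_decoys:
        unbound = sorted(set(by_id) - set(bound_subset))
        n_decoy = int(round(cfg.decoy_fraction * len(bound_subset)))
        for k, gid in enumerate(rng.choice(unbound, min(n_decoy, len(unbound)),
                                           replace=False)):
            gene = by_id[gid]
            summit = int(round(rng.normal(gene.tss, cfg.summit_jitter_sd)))
            fold = float(rng.uniform(*cfg.decoy_fold_range))
            peaks.append(PeakCall(CONTIG, summit - 150, summit + 150, summit,
                                  fold, name=f"{component}_decoy_{k}"))
    return peaks
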