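"""Single-cell whole-genome-amplification uniformity QC.

Binned read-depth tracks are summarized into the standard single-cell
quality metrics: MAPD (median absolute pairwise deviation of genomically
adjacent bin log2 ratios — small-step noise), MDAD (median absolute
deviation from the median — global dispersion), Lorenz curves and the Gini
coefficient (coverage evenness), and a Welch power spectral density that
decomposes depth variability by genomic spatial frequency, separating
fine-scale dropout (the scale of retrotransposons and SNVs) from
large-scale waviness.  Bin boundaries can be recomputed so each bin holds
an equal number of reference reads (~500 kb expected span), and log2 copy
ratios are taken against a designated reference sample with optional sex
chromosome corrections for mismatched-sex references.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal

from .records import CoverageTrack, Log2RatioTrack, ValidationError


@dataclass
class UniformityReport:
    sample_id: str
    mapd: float
    mdad: float
    gini: float
    lorenz_curve: np.ndarray  # (n+1, 2): cum genome fraction, cum read fraction
    bin_scheme: str = ""


@dataclass
class SpectralDensity:
    frequencies: np.ndarray  # cycles per bp, strictly increasing
    power: np.ndarray  # density, variance per (cycles/bp)
    bin_bp: int
    segment_bins: int
    window: str = "hann"

    def band_power(self, f_low: float = 0.0,
                   f_high: float = np.inf) -> float:
        """Integrated power over [f_low, f_high) (trapezoid on the density)."""
        mask = (self.frequencies >= f_low) & (self.frequencies < f_high)
        if mask.sum() < 2:
            raise ValidationError("band contains fewer than two frequencies")
        return float(np.trapezoid(self.power[mask], self.frequencies[mask]))


def equal_read_bins(
    reference: CoverageTrack, target_bin_bp: int = 500_000
) -> pd.DataFrame:
    """Bin boundaries holding equal reference reads, per contig.

    Each contig is cut at source-bin edges so that every output bin holds
    approximately the same number of reference reads; the number of bins per
    contig is chosen so the *expected* span is ``target_bin_bp``.  Returns a
    frame with columns contig, start, end.
    """
    if reference.depths.sum() <= 0:
        raise ValidationError("reference track has zero total reads")
    rows = []
    for contig, grp in reference.bins.groupby("contig", sort=False):
        span = int(grp["end"].iloc[-1] - grp["start"].iloc[0])
        n_bins = max(1, round(span / target_bin_bp))
        reads = grp["depth"].to_numpy(dtype=float)
        cum = np.cumsum(reads)
        total = cum[-1]
        if total <= 0:
            continue
        targets = total * np.arange(1, n_bins) / n_bins
        cut_idx = np.searchsorted(cum, targets, side="left")
        edges = (
            [int(grp["start"].iloc[0])]
            + [int(grp["end"].iloc[i]) for i in cut_idx]
            + [int(grp["end"].iloc[-1])]
        )
        # dedupe while preserving order (possible with zero-depth runs)
        uniq = [edges[0]]
        for e in edges[1:]:
            if e > uniq[-1]:
                uniq.append(e)
        for s, e in zip(uniq[:-1], uniq[1:]):
            rows.append({"contig": contig, "start": s, "end": e})
    return pd.DataFrame(rows)


def _sum_depth_in_bins(track: CoverageTrack, bins: pd.DataFrame) -> np.ndarray:
    """Total reads of ``track`` falling in each target bin (overlap-weighted)."""
    out = np.zeros(len(bins))
    track_by_contig = dict(tuple(track.bins.groupby("contig", sort=False)))
    for i, row in enumerate(bins.itertuples(index=False)):
        grp = track_by_contig.get(row.contig)
        if grp is None:
            continue
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        depth = grp["depth"].to_numpy(dtype=float)
        overlap = np.minimum(ends, row.end) - np.maximum(starts, row.start)
        mask = overlap > 0
        widths = ends - starts
        out[i] = float(np.sum(depth[mask] * overlap[mask] / widths[mask]))
    return out


def normalized_log2(
    sample: CoverageTrack,
    reference: CoverageTrack,
    bins: pd.DataFrame,
    pseudocount: float = 1.0,
    chrx_to_own_median: bool = False,
    chry_zero: bool = False,
    chrx_names: Sequence[str] = ("chrX", "X"),
    chry_names: Sequence[str] = ("chrY", "Y"),
    reference_id: str = "",
) -> Log2RatioTrack:
    """Per-bin log2(sample/reference) ratios, autosomal-median centered.

    A pseudocount of one read-equivalent per bin keeps ratios finite.  With
    ``chrx_to_own_median`` the chrX bins are re-centered to the sample's own
    chrX median (for a female sample against a male reference); with
    ``chry_zero`` the chrY bins are set to 0 so absent-Y dropout does not
    skew genome-wide statistics.
    """
    s = _sum_depth_in_bins(sample, bins)
    r = _sum_depth_in_bins(reference, bins)
    if len(bins) == 0 or (r + s).sum() == 0:
        raise ValidationError("no overlapping coverage in the requested bins")
    # normalize totals so unequal sequencing depth does not shift ratios
    scale = (s.sum() + pseudocount) / (r.sum() + pseudocount)
    ratio = np.log2((s + pseudocount) / ((r * scale) + pseudocount))

    contigs = bins["contig"].to_numpy()
    is_x = np.isin(contigs, chrx_names)
    is_y = np.isin(contigs, chry_names)
    autosomal = ~(is_x | is_y)
    center = float(np.median(ratio[autosomal])) if autosomal.any() else 0.0
    ratio = ratio - center
    if chrx_to_own_median and is_x.any():
        ratio[is_x] -= float(np.median(ratio[is_x]))
    if chry_zero and is_y.any():
        ratio[is_y] = 0.0
    out = bins.copy()
    out["log2_ratio"] = ratio
    return Log2RatioTrack(
        bins=out, reference_id=reference_id or reference.provenance,
        metadata={
            "pseudocount": pseudocount,
            "autosomal_median_centered": True,
            "centering_offset": center,
            "chrx_to_own_median": chrx_to_own_median,
            "chry_zero": chry_zero,
        },
    )


def mapd(track: Log2RatioTrack) -> float:
    """Median absolute deviation of genomically adjacent same-contig pairs."""
    diffs: list[np.ndarray] = []
    for _, grp in track.bins.groupby("contig", sort=False):
        v = grp["log2_ratio"].to_numpy(dtype=float)
        if len(v) >= 2:
            diffs.append(np.abs(np.diff(v)))
    if not diffs:
        raise ValidationError("MAPD needs >= 2 bins on some contig")
    return float(np.median(np.concatenate(diffs)))


def mdad(track: Log2RatioTrack) -> float:
    """Median absolute deviation from the median of all bin log2 ratios."""
    v = track.values
    if len(v) == 0:
        raise ValidationError("MDAD needs >= 1 bin")
    return float(np.median(np.abs(v - np.median(v))))


def lorenz_gini(track: CoverageTrack) -> tuple[np.ndarray, float]:
    """Lorenz curve and Gini coefficient of coverage evenness.

    Bins are sorted by ascending depth; the curve gives the cumulative
    fraction of reads against the cumulative fraction of the genome.
    Perfectly even coverage lies on y = x (Gini 0).
    """
    depths = np.sort(track.depths)
    total = depths.sum()
    if total <= 0:
        raise ValidationError("Lorenz curve undefined for an all-zero track")
    n = len(depths)
    cum_genome = np.arange(n + 1) / n
    cum_reads = np.concatenate([[0.0], np.cumsum(depths)]) / total
    curve = np.column_stack([cum_genome, cum_reads])
    area = float(np.trapezoid(cum_reads, cum_genome))
    return curve, 1.0 - 2.0 * area


def uniformity_report(
    sample_log2: Log2RatioTrack,
    sample_track: CoverageTrack,
    sample_id: str = "",
) -> UniformityReport:
    curve, gini = lorenz_gini(sample_track)
    return UniformityReport(
        sample_id=sample_id,
        mapd=mapd(sample_log2),
        mdad=mdad(sample_log2),
        gini=gini,
        lorenz_curve=curve,
        bin_scheme=sample_track.bin_scheme,
    )


def power_spectral_density(
    track: CoverageTrack,
    segment_bins: int = 2 ** 14,
    window: str = "hann",
    detrend: str = "constant",
) -> SpectralDensity:
    """Welch periodogram of the depth track (50% overlap, Hann window).

    Frequencies are cycles per bp; the density integrates to the track
    variance (Parseval).  The track must be contiguous fixed-width bins.
    """
    if track.bin_scheme != "fixed_width":
        raise ValidationError("PSD requires fixed-width bins")
    bins = track.bins
    if len(bins) < 2:
        raise ValidationError("track too short for a PSD")
    widths = (bins["end"] - bins["start"]).to_numpy()
    if len(np.unique(widths)) != 1:
        raise ValidationError("PSD requires uniform bin width")
    contiguous = (bins["start"].to_numpy()[1:] == bins["end"].to_numpy()[:-1])
    if bins["contig"].nunique() == 1 and not contiguous.all():
        raise ValidationError("PSD requires contiguous bins")
    bin_bp = int(widths[0])
    x = track.depths
    nperseg = min(segment_bins, len(x))
    if len(x) < nperseg:
        raise ValidationError("track shorter than one PSD segment")
    freqs, power = signal.welch(
        x, fs=1.0 / bin_bp, window=window, nperseg=nperseg,
        noverlap=nperseg // 2, detrend=detrend, scaling="density",
    )
    return SpectralDensity(
        frequencies=freqs[1:], power=power[1:], bin_bp=bin_bp,
        segment_bins=nperseg, window=window,
    )


def subsample_track(
    track: CoverageTrack, fraction: float, seed: int = 0
) -> CoverageTrack:
    """Binomially thin per-bin read counts to a fraction of the original."""
    if not 0.0 < fraction <= 1.0:
        raise ValidationError("fraction must be in (0, 1]")
    if fraction == 1.0:
        return CoverageTrack(
            bins=track.bins.copy(), bin_scheme=track.bin_scheme,
            provenance=track.provenance,
        )
    rng = np.random.default_rng(seed)
    counts = np.round(track.depths).astype(np.int64)
    thinned = rng.binomial(counts, fraction).astype(float)
    bins = track.bins.copy()
    bins["depth"] = thinned
    return CoverageTrack(
        bins=bins, bin_scheme=track.bin_scheme,
        provenance=f"{track.provenance}|subsample={fraction}",
    )


def pool_tracks(tracks: Sequence[CoverageTrack]) -> CoverageTrack:
    """Sum depth across cells sharing one bin scheme (pooled pseudo-bulk)."""
    if not tracks:
        raise ValidationError("nothing to pool")
    base = tracks[0].bins[["contig", "start", "end"]]
    depth = np.zeros(len(base))
    for t in tracks:
        if len(t) != len(base) or not (
            t.bins[["contig", "start", "end"]].reset_index(drop=True)
            .equals(base.reset_index(drop=True))
        ):
            raise ValidationError("tracks must share an identical bin scheme")
        depth += t.depths
    bins = base.copy()
    bins["depth"] = depth
    return CoverageTrack(bins=bins, bin_scheme=tracks[0].bin_scheme,
                         provenance=f"pooled:{len(tracks)}")
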