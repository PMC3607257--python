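"""Marker frequency analysis (MFA-seq): S/G2 ratio tracks and origin calling.

Replication origins are mapped by comparing sequence copy number in
replicating (S-phase) versus non-replicating (G2) cells.  Per-nucleotide
read depths are averaged in 2,500 bp bins; the per-bin S/G2 ratio is
normalized so the unreplicated baseline of each chromosome sits at 1.
Peaks in the normalized track are origins of bidirectional replication
(OBRs), named ``OBR:{chromosome}:{position in Mbp}``.  Because the slope
of an MFA peak flank is inversely proportional to the fork speed on that
flank (constant per-cell fork speed, uniform sampling through S), the
left/right slope ratio measures fork-rate asymmetry, the signature of
head-on replication-transcription conflict.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as _signal
from scipy import stats as _stats

from .rnai import smooth_running_median

DEFAULT_BIN_SIZE = 2_500


@dataclass
class RatioTrack:
    """Binned, per-chromosome-normalized S/G2 ratio track."""

    chromosome: str
    bin_size: int
    values: np.ndarray  # NaN where not scorable
    quality_ok: np.ndarray | None = None  # bins kept for peak calling

    def bin_midpoints(self) -> np.ndarray:
        return (np.arange(len(self.values)) + 0.5) * self.bin_size


@dataclass
class OBRPeak:
    """A called origin with amplitude, flank slopes and symmetry class."""

    chromosome: str
    center: float  # bp
    amplitude: float  # ratio units above baseline
    left_slope: float  # ratio units per bp (rising flank, > 0)
    right_slope: float  # ratio units per bp (falling flank, < 0)
    symmetry: str  # "symmetric" | "asymmetric"
    name: str
    apex_bin: int
    left_bin: int
    right_bin: int


def obr_name(chromosome: str, center_bp: float) -> str:
    """Peak naming convention: OBR:{chromosome}:{position in Mbp, 2 dp}."""
    return f"OBR:{chromosome}:{center_bp / 1e6:.2f}"


def bin_depth(depth: np.ndarray, bin_size: int = DEFAULT_BIN_SIZE) -> np.ndarray:
    """Mean per-position depth in consecutive bins.

    The final partial bin is averaged over its true length.
    """
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    depth = np.asarray(depth, dtype=np.float64)
    if depth.size == 0:
        return np.empty(0)
    edges = np.arange(0, depth.size, bin_size)
    sums = np.add.reduceat(depth, edges)
    counts = np.minimum(edges + bin_size, depth.size) - edges
    return sums / counts


def chromosome_baseline(raw_ratio: np.ndarray) -> float:
    """Unreplicated-baseline estimate: median of the lowest quartile of bins.

    Robust against a large replicated fraction in mid-S cells, where the
    mode of the ratio distribution sits at the unreplicated level but the
    mean does not.
    """
    vals = raw_ratio[np.isfinite(raw_ratio)]
    if vals.size == 0:
        raise ValueError("no scorable bins")
    q = np.quantile(vals, 0.25)
    low = vals[vals <= q]
    return float(np.median(low if low.size else vals))


def ratio_and_normalize(
    s_binned: np.ndarray,
    g2_binned: np.ndarray,
    chromosome: str = "?",
    bin_size: int = DEFAULT_BIN_SIZE,
    quality_ok: np.ndarray | None = None,
) -> RatioTrack:
    """Per-bin S/G2 ratio normalized to a baseline of 1 per chromosome.

    Bins with zero G2 depth are flagged and excluded (NaN).  The track is
    scale-invariant: rescaling either sample by a positive constant leaves
    the output unchanged.
    """
    s = np.asarray(s_binned, dtype=np.float64)
    g2 = np.asarray(g2_binned, dtype=np.float64)
    if s.shape != g2.shape:
        raise ValueError("S and G2 tracks must have matching bins")
    if not (g2 > 0).any():
        raise ValueError("all-zero G2 chromosome")
    raw = np.full_like(s, np.nan)
    ok = g2 > 0
    raw[ok] = s[ok] / g2[ok]
    norm = raw / chromosome_baseline(raw)
    return RatioTrack(chromosome, bin_size, norm, quality_ok=quality_ok)


def _noise_sd(values: np.ndarray) -> float:
    """Robust per-bin noise SD from first differences.

    Differencing removes the slowly varying replication signal (fork
    travel spans many bins), leaving sqrt(2) times the bin noise; the MAD
    makes the step edges of real peaks irrelevant.
    """
    vals = values[np.isfinite(values)]
    if vals.size < 2:
        return 0.0
    d = np.abs(np.diff(vals))
    return float(np.median(d) / (0.6745 * np.sqrt(2.0)))


def call_obr_peaks(
    track: RatioTrack,
    min_amplitude: float = 0.15,
    min_width_bins: int = 10,
    smooth_window: int = 5,
    symmetry_band: tuple[float, float] = (0.8, 1.25),
) -> list[OBRPeak]:
    """Call OBR peaks on a normalized ratio track.

    The track is pre-smoothed with a running median (window
    ``smooth_window`` bins); low-quality bins are excluded.  Local maxima
    with amplitude >= ``min_amplitude`` above baseline and width at half
    amplitude >= ``min_width_bins`` become peaks.  Flank slopes are fit by
    least squares between the apex and the return to within one robust SD
    of baseline; a peak is symmetric when |left|/|right| slope lies in
    ``symmetry_band``.
    """
    vals = track.values.copy()
    if track.quality_ok is not None:
        vals[~track.quality_ok] = np.nan
    filled = np.where(np.isfinite(vals), vals, 1.0)
    sm = smooth_running_median(filled, smooth_window)
    sd = _noise_sd(filled)
    apexes, _ = _signal.find_peaks(
        sm, height=1.0 + min_amplitude, prominence=min_amplitude / 2
    )
    mids = track.bin_midpoints()
    peaks: list[OBRPeak] = []
    for apex in apexes:
        amp = sm[apex] - 1.0
        half = 1.0 + amp / 2.0
        lo = apex
        while lo > 0 and sm[lo - 1] >= half:
            lo -= 1
        hi = apex
        while hi < len(sm) - 1 and sm[hi + 1] >= half:
            hi += 1
        if hi - lo + 1 < min_width_bins:
            continue
        # flank extent: apex to return within 1 robust SD of baseline
        lb = apex
        while lb > 0 and sm[lb - 1] > 1.0 + sd:
            lb -= 1
        rb = apex
        while rb < len(sm) - 1 and sm[rb + 1] > 1.0 + sd:
            rb += 1
        left_slope = _flank_slope(mids, sm, lb, apex)
        right_slope = _flank_slope(mids, sm, apex, rb)
        if left_slope and right_slope:
            ratio = abs(left_slope) / abs(right_slope)
            symmetry = (
                "symmetric"
                if symmetry_band[0] <= ratio <= symmetry_band[1]
                else "asymmetric"
            )
        else:
            symmetry = "asymmetric"
        center = mids[apex]
        peaks.append(
            OBRPeak(
                chromosome=track.chromosome,
                center=float(center),
                amplitude=float(amp),
                left_slope=float(left_slope),
                right_slope=float(right_slope),
                symmetry=symmetry,
                name=obr_name(track.chromosome, center),
                apex_bin=int(apex),
                left_bin=int(lb),
                right_bin=int(rb),
            )
        )
    return peaks


def _flank_slope(x: np.ndarray, y: np.ndarray, i0: int, i1: int) -> float:
    if i1 <= i0:
        return 0.0
    xs, ys = x[i0 : i1 + 1], y[i0 : i1 + 1]
    return float(np.polyfit(xs, ys, 1)[0])


def fork_rate_asymmetry(peak: OBRPeak) -> tuple[float, str]:
    """Fold difference in fork rate between the two flanks of a peak.

    Under constant per-cell fork speed and uniform sampling through S the
    MFA flank slope magnitude is inversely proportional to the fork speed,
    so the fold is |steeper| / |shallower|; the shallower flank is the
    faster (transcription-codirectional) one.
    """
    l, r = abs(peak.left_slope), abs(peak.right_slope)
    if l == 0 or r == 0 or not (np.isfinite(l) and np.isfinite(r)):
        raise ValueError(f"{peak.name}: flank slope undefined")
    if l >= r:
        return l / r, "right"
    return r / l, "left"


@dataclass
class ReplicationSummary:
    """Replicated-fraction and origin-density summary."""

    replicated_fraction: float
    fraction_by_class: dict[str, float] = field(default_factory=dict)
    replicated_composition: dict[str, float] = field(default_factory=dict)
    threshold: float = float("nan")


def replicated_fraction(
    tracks: dict[str, RatioTrack],
    region_tracks: dict[str, "object"] | None = None,
    threshold: float | None = None,
) -> ReplicationSummary:
    """Fraction of scorable bins showing replication (ratio > 1 + threshold).

    The default threshold is 3x the robust SD of sub-baseline bins, pooled
    over chromosomes.  When region-class tracks are given, also reports the
    fraction replicated within each class and the class composition of the
    replicated territory (which sums to 1).
    """
    all_vals = np.concatenate([t.values for t in tracks.values()])
    if threshold is None:
        threshold = 3.0 * _noise_sd(all_vals)
    level = 1.0 + threshold

    n_rep = n_scorable = 0
    by_class: dict[str, list[int]] = {}
    comp: dict[str, int] = {}
    for chrom, t in tracks.items():
        vals = t.values
        ok = np.isfinite(vals)
        rep = ok & (vals > level)
        n_rep += int(rep.sum())
        n_scorable += int(ok.sum())
        if region_tracks is not None and chrom in region_tracks:
            mids = t.bin_midpoints()
            rtrack = region_tracks[chrom]
            for i in np.flatnonzero(ok):
                cls = rtrack.class_at(mids[i])
                if cls is None:
                    continue
                cnt = by_class.setdefault(cls, [0, 0])
                cnt[1] += 1
                if rep[i]:
                    cnt[0] += 1
                    comp[cls] = comp.get(cls, 0) + 1
    frac_by_class = {c: (r / n if n else float("nan")) for c, (r, n) in by_class.items()}
    total_rep = sum(comp.values())
    composition = {c: v / total_rep for c, v in comp.items()} if total_rep else {}
    return ReplicationSummary(
        replicated_fraction=n_rep / n_scorable if n_scorable else float("nan"),
        fraction_by_class=frac_by_class,
        replicated_composition=composition,
        threshold=float(threshold),
    )


def extrapolate_origin_count(observed: int, analyzed_s_fraction: float) -> float:
    """Scale the observed peak count by 1 / (fraction of S phase sampled)."""
    if not 0 < analyzed_s_fraction <= 1:
        raise ValueError("analyzed_s_fraction must be in (0, 1]")
    return observed / analyzed_s_fraction


def origin_density(total_genome_length: float, n_origins: float) -> float:
    """Genome length per origin (bp/origin)."""
    if n_origins <= 0:
        return float("nan")
    return total_genome_length / n_origins


def origin_density_and_extrapolation(
    peaks_per_chromosome: dict[str, int],
    chromosome_lengths: dict[str, float],
    analyzed_s_fraction: float = 0.5,
) -> dict[str, float]:
    """Origin count vs chromosome length regression and genome-wide density.

    Fits origins ~ length through the origin (zero-intercept least squares)
    and reports the Pearson correlation across chromosomes; the predicted
    genome-wide origin count scales the observed total by the reciprocal of
    the analyzed S-phase fraction.
    """
    chroms = sorted(peaks_per_chromosome)
    n = np.array([peaks_per_chromosome[c] for c in chroms], dtype=float)
    length = np.array([chromosome_lengths[c] for c in chroms], dtype=float)
    observed = float(n.sum())
    predicted = extrapolate_origin_count(int(observed), analyzed_s_fraction)
    out = {
        "observed_origins": observed,
        "predicted_origins": predicted,
        "density_bp_per_origin": origin_density(float(length.sum()), predicted),
    }
    if len(chroms) >= 2:
        out["slope_origins_per_bp"] = float((n * length).sum() / (length**2).sum())
        out["pearson_r"] = float(_stats.pearsonr(length, n)[0])
    return out


def colocalize_peaks_with_features(
    peaks: list[OBRPeak],
    features: "object",
    tolerance_bins: int = 2,
    bin_size: int = DEFAULT_BIN_SIZE,
    ranked_features: list[tuple[str, int, int]] | None = None,
) -> dict:
    """Match OBR apexes against features (e.g. merged binding sites).

    A peak matches when its apex bin, widened by ``tolerance_bins`` on each
    side, intersects a feature interval.  ``features`` is a DataFrame with
    ``chromosome, start, end``.  When ``ranked_features`` (e.g. mapped
    centromeres) are given, also checks whether the top amplitude-ranked
    peaks each match one — the highest-amplitude peaks are expected to be
    centromeric.
    """
    matches = []
    for p in peaks:
        lo = p.center - (tolerance_bins + 0.5) * bin_size
        hi = p.center + (tolerance_bins + 0.5) * bin_size
        sub = features[features["chromosome"] == p.chromosome]
        hit = bool(((sub["start"] < hi) & (sub["end"] > lo)).any())
        matches.append((p.name, hit))
    out = {
        "n_matched": sum(1 for _, h in matches if h),
        "n_peaks": len(peaks),
        "per_peak": matches,
    }
    if ranked_features is not None:
        top = sorted(peaks, key=lambda p: p.amplitude, reverse=True)[: len(ranked_features)]
        top_hits = []
        for p in top:
            lo = p.center - (tolerance_bins + 0.5) * bin_size
            hi = p.center + (tolerance_bins + 0.5) * bin_size
            hit = any(
                chrom == p.chromosome and s < hi and e > lo
                for chrom, s, e in ranked_features
            )
            top_hits.append((p.name, hit))
        out["top_ranked_matched"] = top_hits
    return out
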