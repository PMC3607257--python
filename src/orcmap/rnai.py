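"""Transcriptional response to initiator knockdown.

After RNAi against the replication initiator, mRNA abundance rises at the
boundaries of the polycistronic transcription units and silent VSG loci
become derepressed.  This module quantifies that response from
per-position read-depth tracks of induced and uninduced samples:
quantile normalization, 250 bp log2 ratio tracks, presence tracks for
loci expressed in only one sample, running-median smoothing, per-gene
fold changes (the >1.4-fold rule), and a permutation test for enrichment
of signal near transcription-unit boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

DEFAULT_BIN_SIZE = 250
ZERO_SUB = 1e-5


def quantile_normalize(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two-sample quantile normalization.

    Each track's values are replaced, rank for rank, by the mean of the two
    tracks' sorted values; tied observations within a track share the mean
    of their tied block.  Rank order within each track is preserved, and on
    tie-free inputs the two outputs have exactly identical sorted values.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("tracks must have equal length")
    ref = (np.sort(a) + np.sort(b)) / 2.0

    def project(x: np.ndarray) -> np.ndarray:
        order = np.argsort(x, kind="stable")
        out = np.empty_like(ref)
        out[order] = ref
        # tied blocks share the mean of their assigned reference values
        r = rankdata(x, method="dense")
        sums = np.bincount(r, weights=out)
        counts = np.bincount(r)
        return sums[r] / counts[r]

    return project(a), project(b)


def smooth_running_median(values: np.ndarray, window: int = 7) -> np.ndarray:
    """Centered running median; edges use shrinking windows."""
    if window % 2 != 1:
        raise ValueError("window must be odd")
    return (
        pd.Series(np.asarray(values, dtype=np.float64))
        .rolling(window, center=True, min_periods=1)
        .median()
        .to_numpy()
    )


@dataclass
class ExpressionRatioTrack:
    """Per-bin log2(induced/uninduced), NaN where no position is scorable."""

    chromosome: str
    bin_size: int
    values: np.ndarray
    smoothed: bool = False

    def smooth(self, window: int = 7) -> "ExpressionRatioTrack":
        return ExpressionRatioTrack(
            self.chromosome,
            self.bin_size,
            smooth_running_median(self.values, window),
            smoothed=True,
        )

    def bin_midpoints(self) -> np.ndarray:
        return (np.arange(len(self.values)) + 0.5) * self.bin_size


@dataclass
class PresenceTrack:
    """Bins with signal in exactly one sample (induced-only / uninduced-only)."""

    chromosome: str
    bin_size: int
    induced_only: np.ndarray  # bool per bin
    uninduced_only: np.ndarray


def _bin_median(values: np.ndarray, bin_size: int) -> np.ndarray:
    n_bins = int(np.ceil(len(values) / bin_size))
    out = np.full(n_bins, np.nan)
    for i in range(n_bins):
        chunk = values[i * bin_size : (i + 1) * bin_size]
        chunk = chunk[np.isfinite(chunk)]
        if chunk.size:
            out[i] = np.median(chunk)
    return out


def ratio_track_250(
    induced: np.ndarray,
    uninduced: np.ndarray,
    bin_size: int = DEFAULT_BIN_SIZE,
    chromosome: str = "?",
) -> ExpressionRatioTrack:
    """Binned log2 ratio of induced/uninduced depth.

    The bin value is the median of the per-position log2 ratios; positions
    where either sample is zero are excluded here (they are the business of
    :func:`presence_track`).
    """
    i = np.asarray(induced, dtype=np.float64)
    u = np.asarray(uninduced, dtype=np.float64)
    if i.shape != u.shape:
        raise ValueError("tracks must have equal length")
    lr = np.full_like(i, np.nan)
    ok = (i > 0) & (u > 0)
    lr[ok] = np.log2(i[ok] / u[ok])
    return ExpressionRatioTrack(chromosome, bin_size, _bin_median(lr, bin_size))


def presence_track(
    induced: np.ndarray,
    uninduced: np.ndarray,
    bin_size: int = DEFAULT_BIN_SIZE,
    zero_sub: float = ZERO_SUB,
    read_floor: float = 1.0,
    chromosome: str = "?",
) -> PresenceTrack:
    """Bins expressed in one sample only.

    Zero positions are replaced by ``zero_sub`` before forming the log2
    ratio, so a locus with reads in one sample and none in the other
    produces an extreme ratio.  A bin is flagged induced-only when its
    median log2 ratio exceeds half of log2(read_floor / zero_sub), i.e.
    well beyond any genuine two-sample ratio; the uninduced-only rule is
    symmetric.  Positions at zero in both samples give a ratio of exactly
    1 and are never flagged.
    """
    i = np.where(np.asarray(induced, dtype=np.float64) > 0, induced, zero_sub)
    u = np.where(np.asarray(uninduced, dtype=np.float64) > 0, uninduced, zero_sub)
    lr = np.log2(i / u)
    med = _bin_median(lr, bin_size)
    bound = np.log2(read_floor / zero_sub) / 2.0
    with np.errstate(invalid="ignore"):
        ind_only = med > bound
        unind_only = med < -bound
    return PresenceTrack(chromosome, bin_size, ind_only, unind_only)


def gene_fold_changes(
    induced: np.ndarray,
    uninduced: np.ndarray,
    genes: list,
    threshold: float = 1.4,
    zero_sub: float = ZERO_SUB,
) -> pd.DataFrame:
    """Per-gene mean depth, fold change and the >1.4-fold significance flag."""
    rows = []
    for g in genes:
        if g.end <= g.start:
            raise ValueError(f"{g.gene_id}: zero-length gene")
        mi = float(np.mean(induced[g.start : g.end]))
        mu = float(np.mean(uninduced[g.start : g.end]))
        fold = max(mi, zero_sub) / max(mu, zero_sub)
        rows.append(
            {
                "gene_id": g.gene_id,
                "mean_induced": mi,
                "mean_uninduced": mu,
                "fold_change": fold,
                "significant": fold > threshold,
            }
        )
    return pd.DataFrame(rows)


def boundary_enrichment(
    tracks: dict[str, np.ndarray],
    boundaries: pd.DataFrame,
    bin_size: int = DEFAULT_BIN_SIZE,
    distance: int = 10_000,
    n_permutations: int = 1_000,
    seed: int = 0,
) -> dict:
    """Mean signal near transcription-unit boundaries vs elsewhere.

    ``tracks`` maps chromosome to a binned signal array (e.g. smoothed
    log2 ratio values); ``boundaries`` has columns
    ``chromosome, position, boundary_type`` (divergent_ssr /
    convergent_ssr / intra_dgc).  The statistic is the mean over bins whose
    midpoint lies within ``distance`` of any boundary minus the mean over
    the remaining bins.  The null cycles each chromosome's track by a
    random offset (structure-preserving) ``n_permutations`` times; the
    p-value is the upper-tail permutation probability.
    """
    if len(boundaries) == 0:
        raise ValueError("no boundaries supplied")
    rng = np.random.default_rng(seed)

    near_masks: dict[str, np.ndarray] = {}
    type_masks: dict[str, dict[str, np.ndarray]] = {}
    for chrom, vals in tracks.items():
        mids = (np.arange(len(vals)) + 0.5) * bin_size
        sub = boundaries[boundaries["chromosome"] == chrom]
        near = np.zeros(len(vals), dtype=bool)
        tmask: dict[str, np.ndarray] = {}
        for btype, bsub in sub.groupby("boundary_type"):
            m = np.zeros(len(vals), dtype=bool)
            for p in bsub["position"].to_numpy():
                m |= np.abs(mids - p) <= distance
            tmask[btype] = m
            near |= m
        near_masks[chrom] = near
        type_masks[chrom] = tmask

    def stat(series: dict[str, np.ndarray]) -> float:
        near_vals, far_vals = [], []
        for chrom, vals in series.items():
            ok = np.isfinite(vals)
            near = near_masks[chrom]
            near_vals.append(vals[ok & near])
            far_vals.append(vals[ok & ~near])
        nv = np.concatenate(near_vals)
        fv = np.concatenate(far_vals)
        if nv.size == 0 or fv.size == 0:
            return float("nan")
        return float(nv.mean() - fv.mean())

    observed = stat(tracks)
    null = np.empty(n_permutations)
    for k in range(n_permutations):
        shifted = {
            chrom: np.roll(vals, rng.integers(len(vals)))
            for chrom, vals in tracks.items()
        }
        null[k] = stat(shifted)
    finite_null = null[np.isfinite(null)]
    p = (1.0 + np.sum(finite_null >= observed)) / (1.0 + finite_null.size)

    per_type = {}
    types = sorted({t for m in type_masks.values() for t in m})
    for btype in types:
        nv, fv = [], []
        for chrom, vals in tracks.items():
            ok = np.isfinite(vals)
            m = type_masks[chrom].get(btype, np.zeros(len(vals), dtype=bool))
            nv.append(vals[ok & m])
            fv.append(vals[ok & ~near_masks[chrom]])
        nv, fv = np.concatenate(nv), np.concatenate(fv)
        per_type[btype] = float(nv.mean() - fv.mean()) if nv.size and fv.size else float("nan")

    return {
        "statistic": observed,
        "p_value": float(p),
        "null_mean": float(finite_null.mean()),
        "null_sd": float(finite_null.std()),
        "per_boundary_type": per_type,
    }
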