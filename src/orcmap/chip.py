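"""Tiling-array ChIP peak calling with randomization-based FDR.

Detects initiator (ORC1/CDC6) binding sites from probe-level log2
sample/input ratios.  The detector slides a 500 bp window over the tiled
probes and flags windows in which at least four probes exceed a cutoff
expressed as a fraction of a "hypothetical maximum" (mean + 6 SD of the
rescaled track).  False-discovery rates per cutoff are estimated by
re-running the detector on tracks whose probe values are permuted within
each chromosome, and each called site carries the most stringent
confidence class its FDR supports: high (FDR <= 0.05), mid (<= 0.1) or
low (<= 0.2).

Probe tables are pandas DataFrames with columns
``probe_id, chromosome, position, log2_ratio``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

PROBE_COLUMNS = ["probe_id", "chromosome", "position", "log2_ratio"]

DEFAULT_CUTOFF_GRID = (0.90, 0.80, 0.70, 0.60, 0.50, 0.40, 0.30, 0.20, 0.15)
FDR_CLASS_BOUNDS = (("high", 0.05), ("mid", 0.10), ("low", 0.20))
_CLASS_RANK = {"high": 0, "mid": 1, "low": 2}


def _validate_probes(track: pd.DataFrame) -> None:
    missing = [c for c in PROBE_COLUMNS if c not in track.columns]
    if missing:
        raise ValueError(f"probe table missing columns: {missing}")
    for _, grp in track.groupby("chromosome", sort=False):
        if not grp["position"].is_monotonic_increasing:
            raise ValueError("probe positions must be sorted within chromosomes")


def rescale_min_zero(track: pd.DataFrame) -> pd.DataFrame:
    """Shift the log2 ratios so the track minimum is exactly zero."""
    if len(track) == 0:
        raise ValueError("empty probe track")
    out = track.copy()
    out["log2_ratio"] = out["log2_ratio"] - out["log2_ratio"].min()
    return out


def hypothetical_maximum(values: np.ndarray) -> float:
    """mean + 6 SD of the (rescaled) probe signals."""
    return float(np.mean(values) + 6.0 * np.std(values))


def _detect_one(
    pos: np.ndarray,
    val: np.ndarray,
    cutoff_fraction: float,
    window: int,
    min_probes: int,
) -> list[tuple[int, int]]:
    if len(pos) < min_probes:
        return []
    thr = cutoff_fraction * hypothetical_maximum(val)
    above = (val > thr).astype(np.int64)
    cum = np.concatenate(([0], np.cumsum(above)))
    half = window / 2.0
    lo = np.searchsorted(pos, pos - half, side="left")
    hi = np.searchsorted(pos, pos + half, side="right")
    hits = (cum[hi] - cum[lo]) >= min_probes
    if not hits.any():
        return []
    starts = np.maximum(pos[hits] - half, 0).astype(np.int64)
    ends = (pos[hits] + half).astype(np.int64)
    merged: list[tuple[int, int]] = []
    for s, e in zip(starts, ends):
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((int(s), int(e)))
    return merged


def detect_enriched_windows(
    track: pd.DataFrame,
    cutoff_fraction: float,
    window: int = 500,
    min_probes: int = 4,
) -> pd.DataFrame:
    """Candidate enriched intervals at one cutoff fraction.

    Windows are anchored at every probe (centered, ``window`` bp wide);
    a window is a hit when at least ``min_probes`` probes inside it exceed
    ``cutoff_fraction`` times the hypothetical maximum, computed per
    chromosome.  Overlapping hit windows are unioned.
    """
    if not 0.0 < cutoff_fraction <= 1.0:
        raise ValueError("cutoff_fraction must be in (0, 1]")
    _validate_probes(track)
    rows = []
    for chrom, grp in track.groupby("chromosome", sort=False):
        pos = grp["position"].to_numpy(dtype=np.float64)
        val = grp["log2_ratio"].to_numpy(dtype=np.float64)
        for s, e in _detect_one(pos, val, cutoff_fraction, window, min_probes):
            rows.append({"chromosome": chrom, "start": s, "end": e})
    return pd.DataFrame(rows, columns=["chromosome", "start", "end"])


def estimate_fdr(
    track: pd.DataFrame,
    cutoff_fraction: float,
    n_randomizations: int = 20,
    seed: int | np.random.Generator = 0,
    window: int = 500,
    min_probes: int = 4,
) -> float:
    """Randomization FDR for the detector at one cutoff.

    Probe values are permuted uniformly across probe positions within each
    chromosome (positions fixed, values shuffled) and the detector re-run;
    the FDR estimate is the mean candidate count over randomizations
    divided by the observed count, capped at 1.  NaN when nothing is
    observed.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    observed = len(detect_enriched_windows(track, cutoff_fraction, window, min_probes))
    if observed == 0:
        return float("nan")
    null_counts = []
    shuffled = track.copy()
    vals = track["log2_ratio"].to_numpy()
    chrom_codes = track["chromosome"].to_numpy()
    for _ in range(n_randomizations):
        perm = np.empty_like(vals)
        for chrom in pd.unique(chrom_codes):
            idx = np.flatnonzero(chrom_codes == chrom)
            perm[idx] = vals[idx[rng.permutation(len(idx))]]
        shuffled["log2_ratio"] = perm
        null_counts.append(
            len(detect_enriched_windows(shuffled, cutoff_fraction, window, min_probes))
        )
    return min(1.0, float(np.mean(null_counts)) / observed)


def call_sites(
    track: pd.DataFrame,
    cutoff_grid: tuple[float, ...] = DEFAULT_CUTOFF_GRID,
    seed: int = 0,
    n_randomizations: int = 20,
    window: int = 500,
    min_probes: int = 4,
) -> pd.DataFrame:
    """Call binding sites and assign FDR confidence classes.

    Runs the detector over the descending cutoff grid, estimates the FDR at
    each cutoff, and keeps every candidate interval detected at a cutoff
    whose FDR is <= 0.2, labelled with the most stringent class achieved
    anywhere on the grid.  Returns a BED-like frame with columns
    ``chromosome, start, end, peak_score, fdr_class``.
    """
    if any(a < b for a, b in zip(cutoff_grid, cutoff_grid[1:])):
        raise ValueError("cutoff_grid must be descending")
    rescaled = rescale_min_zero(track)
    rng = np.random.default_rng(seed)
    tagged: list[tuple[str, int, int, int]] = []  # chrom, start, end, rank
    for cutoff in cutoff_grid:
        fdr = estimate_fdr(
            rescaled, cutoff, n_randomizations, rng, window, min_probes
        )
        cls = next((name for name, bound in FDR_CLASS_BOUNDS if fdr <= bound), None)
        if cls is None:
            continue
        cands = detect_enriched_windows(rescaled, cutoff, window, min_probes)
        for row in cands.itertuples():
            tagged.append((row.chromosome, row.start, row.end, _CLASS_RANK[cls]))
    # union overlapping intervals, keeping the best (lowest-rank) class
    rows = []
    by_chrom: dict[str, list[tuple[int, int, int]]] = {}
    for chrom, s, e, rank in tagged:
        by_chrom.setdefault(chrom, []).append((s, e, rank))
    rank_names = {v: k for k, v in _CLASS_RANK.items()}
    for chrom, ivals in by_chrom.items():
        ivals.sort()
        merged: list[list[int]] = []
        for s, e, rank in ivals:
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
                merged[-1][2] = min(merged[-1][2], rank)
            else:
                merged.append([s, e, rank])
        grp = rescaled[rescaled["chromosome"] == chrom]
        pos = grp["position"].to_numpy()
        val = grp["log2_ratio"].to_numpy()
        for s, e, rank in merged:
            inside = (pos >= s) & (pos < e)
            score = float(val[inside].max()) if inside.any() else float("nan")
            rows.append(
                {
                    "chromosome": chrom,
                    "start": int(s),
                    "end": int(e),
                    "peak_score": score,
                    "fdr_class": rank_names[rank],
                }
            )
    out = pd.DataFrame(
        rows, columns=["chromosome", "start", "end", "peak_score", "fdr_class"]
    )
    return out.sort_values(["chromosome", "start"]).reset_index(drop=True)


def merge_intervals(
    intervals: pd.DataFrame, merge_gap: int = 10_000
) -> pd.DataFrame:
    """Transitive closure of the "edge gap < merge_gap" relation.

    Intervals closer than ``merge_gap`` (strictly) are grouped into one;
    ``merge_gap=0`` therefore merges only genuinely overlapping intervals.
    """
    rows = []
    for chrom, grp in intervals.groupby("chromosome", sort=False):
        grp = grp.sort_values("start")
        cur_s = cur_e = None
        n = 0
        for row in grp.itertuples():
            if cur_e is not None and row.start - cur_e < merge_gap:
                cur_e = max(cur_e, row.end)
                n += 1
            else:
                if cur_s is not None:
                    rows.append(
                        {"chromosome": chrom, "start": cur_s, "end": cur_e, "n_members": n}
                    )
                cur_s, cur_e, n = row.start, row.end, 1
        if cur_s is not None:
            rows.append({"chromosome": chrom, "start": cur_s, "end": cur_e, "n_members": n})
    return pd.DataFrame(rows, columns=["chromosome", "start", "end", "n_members"])


def merge_sites(sites: pd.DataFrame, merge_gap: int = 10_000) -> pd.DataFrame:
    """Group called sites closer than ``merge_gap`` into "unique" sites."""
    return merge_intervals(sites, merge_gap)


def merge_h4k10ac(
    loci: pd.DataFrame, merge_gap: int = 10_000, min_size: int = 1_000
) -> pd.DataFrame:
    """Merge H4K10Ac loci closer than ``merge_gap``; drop merged loci
    spanning less than ``min_size`` (merge first, then filter)."""
    merged = merge_intervals(loci, merge_gap)
    keep = (merged["end"] - merged["start"]) >= min_size
    return merged[keep].reset_index(drop=True)


def mean_spacing(category_length: float, n_merged_sites: int) -> float:
    """Average spacing between adjacent merged sites: length / count."""
    if n_merged_sites <= 0:
        return float("nan")
    return category_length / n_merged_sites


def assign_by_midpoint(
    sites: pd.DataFrame, labelled: dict[str, list[tuple[str, int, int]]]
) -> pd.Series:
    """Label each site by the category containing its midpoint.

    ``labelled`` maps category name to ``(chromosome, start, end)``
    intervals.  Midpoint assignment makes the category counts a partition
    of the site set (ties at boundaries cannot double-count).
    """
    labels = []
    for row in sites.itertuples():
        mid = 0.5 * (row.start + row.end)
        found = None
        for name, ivals in labelled.items():
            for chrom, s, e in ivals:
                if chrom == row.chromosome and s <= mid < e:
                    found = name
                    break
            if found:
                break
        labels.append(found)
    return pd.Series(labels, index=sites.index, name="category")


def occupancy(
    features: list[tuple[str, int, int]], sites: pd.DataFrame
) -> tuple[int, int, float]:
    """(#features with >= 1 overlapping site, #features, fraction)."""
    n_occ = 0
    for chrom, s, e in features:
        sub = sites[sites["chromosome"] == chrom]
        if ((sub["start"] < e) & (sub["end"] > s)).any():
            n_occ += 1
    n = len(features)
    return n_occ, n, (n_occ / n if n else float("nan"))


def associate_sites_with_regions(
    sites: pd.DataFrame,
    region_tracks: dict[str, "object"],
    ssrs: list | None = None,
    dgcs: list | None = None,
    cassettes: list | None = None,
    merge_gap: int = 10_000,
) -> dict[str, pd.DataFrame]:
    """Site/region association summary.

    Returns per-class counts and fractions (midpoint rule), mean spacing of
    merged sites per class, SSR/DGC breakdown of core sites with occupancy,
    and (when cassettes are supplied) counts per cassette component.
    """
    labelled: dict[str, list[tuple[str, int, int]]] = {c: [] for c in ("core", "subtelomere", "vsg_array")}
    class_len = {c: 0 for c in labelled}
    for chrom, track in region_tracks.items():
        for s, e, cls in track.intervals:
            labelled[cls].append((chrom, s, e))
            class_len[cls] += e - s
    cat = assign_by_midpoint(sites, labelled)
    merged = merge_sites(sites, merge_gap)
    merged_cat = assign_by_midpoint(merged, labelled)
    total = len(sites)
    class_rows = []
    for cls in labelled:
        n = int((cat == cls).sum())
        nm = int((merged_cat == cls).sum())
        class_rows.append(
            {
                "category": cls,
                "n_sites": n,
                "fraction": n / total if total else float("nan"),
                "n_merged": nm,
                "length_bp": class_len[cls],
                "mean_spacing_bp": mean_spacing(class_len[cls], nm),
            }
        )
    out = {"by_class": pd.DataFrame(class_rows)}

    if ssrs is not None and dgcs is not None:
        sub: dict[str, list[tuple[str, int, int]]] = {
            "divergent_ssr": [(s.chromosome, s.start, s.end) for s in ssrs if s.ssr_type == "divergent"],
            "convergent_ssr": [(s.chromosome, s.start, s.end) for s in ssrs if s.ssr_type == "convergent"],
            "intra_dgc": [(d.chromosome, d.start, d.end) for d in dgcs],
        }
        core_sites = sites[cat == "core"]
        sub_cat = assign_by_midpoint(core_sites, sub)
        n_core = len(core_sites)
        rows = []
        for name, ivals in sub.items():
            n = int((sub_cat == name).sum())
            occ, total_feat, frac = occupancy(ivals, core_sites)
            rows.append(
                {
                    "category": name,
                    "n_sites": n,
                    "fraction_of_core": n / n_core if n_core else float("nan"),
                    "n_features": total_feat,
                    "n_occupied": occ,
                    "occupancy": frac,
                }
            )
        out["core_breakdown"] = pd.DataFrame(rows)

    if cassettes is not None:
        comp: dict[str, list[tuple[str, int, int]]] = {
            "repeat_70bp": [],
            "flank_5p": [],
            "vsg_orf": [],
            "flank_3p": [],
        }
        for c in cassettes:
            comp["repeat_70bp"].append((c.chromosome, *c.repeat_70bp))
            comp["flank_5p"].append((c.chromosome, *c.flank_5p))
            if c.vsg_orf is not None:
                comp["vsg_orf"].append((c.chromosome, *c.vsg_orf))
            comp["flank_3p"].append((c.chromosome, *c.flank_3p))
        arr_sites = sites[cat == "vsg_array"]
        comp_cat = assign_by_midpoint(arr_sites, comp)
        n_arr = len(arr_sites)
        out["cassette_breakdown"] = pd.DataFrame(
            [
                {
                    "component": name,
                    "n_sites": int((comp_cat == name).sum()),
                    "fraction_of_array_sites": (comp_cat == name).sum() / n_arr
                    if n_arr
                    else float("nan"),
                }
                for name in comp
            ]
        )
    return out


def proximity_and_overlap(
    set_a: pd.DataFrame,
    set_b: pd.DataFrame,
    within: int = 15_000,
    dgcs: list | None = None,
) -> tuple[int, int, pd.DataFrame]:
    """Nearest-neighbour distances from each A interval to set B.

    Distance is 0 for overlapping intervals, else the gap between nearest
    edges.  Returns (#A within ``within`` bp of a B, #A overlapping a B,
    per-A table).  When DGCs are supplied, A members inside a DGC are
    additionally scored for lying upstream (in the transcription direction)
    of their nearest B member.
    """
    rows = []
    n_within = n_overlap = 0
    for row in set_a.itertuples():
        sub = set_b[set_b["chromosome"] == row.chromosome]
        if len(sub) == 0:
            rows.append(
                {"chromosome": row.chromosome, "start": row.start, "end": row.end,
                 "distance": float("nan"), "overlaps": False, "upstream": None}
            )
            continue
        gaps = np.maximum(sub["start"].to_numpy() - row.end,
                          row.start - sub["end"].to_numpy())
        gaps = np.maximum(gaps, 0)
        k = int(np.argmin(gaps))
        dist = int(gaps[k])
        overlaps = dist == 0 and (
            (sub.iloc[k]["start"] < row.end) and (sub.iloc[k]["end"] > row.start)
        )
        if dist <= within:
            n_within += 1
        if overlaps:
            n_overlap += 1
        upstream = None
        if dgcs is not None:
            mid_a = 0.5 * (row.start + row.end)
            mid_b = 0.5 * (sub.iloc[k]["start"] + sub.iloc[k]["end"])
            for d in dgcs:
                if d.chromosome == row.chromosome and d.start <= mid_a < d.end:
                    upstream = mid_a < mid_b if d.strand == "+" else mid_a > mid_b
                    break
        rows.append(
            {"chromosome": row.chromosome, "start": row.start, "end": row.end,
             "distance": dist, "overlaps": overlaps, "upstream": upstream}
        )
    return n_within, n_overlap, pd.DataFrame(rows)
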