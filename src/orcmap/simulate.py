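"""Synthetic genomes, tracks and tables with known ground truth.

Generates the full input side of the pipeline — a trypanosome-style
genome (subtelomeric VSG arrays built from repeat/flank/ORF cassettes,
subtelomere gene families, a core of alternating-strand directional gene
clusters separated by strand switch regions), tiling-array ChIP signals,
S/G2 replication depth tracks, RNAi-induced/uninduced transcriptome
tracks and qPCR Ct tables — together with a :class:`SyntheticTruth`
record of the planted features, so that every analysis stage has a
recovery test against known truth.

The replication model: each origin fires in a given cell with its
efficiency at its firing time; forks then extend bidirectionally at a
constant per-flank speed (faster on the transcription-codirectional
flank).  A cell sampled at time t (uniform over the observed S window)
has replicated locus x iff some fired origin's fork reached x by t, so
the expected copy number at x is 1 + P(replicated).  Read counts are
negative binomial around means proportional to copy number.  The
per-locus probability is computed semi-analytically (exact integration
over the sampling window of the piecewise-constant survival function);
an independent per-cell Monte-Carlo oracle is provided for
cross-checking.

All generators are deterministic given (seed, config).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .annotation import DGC, SSR, GeneRecord, RegionClassTrack, VSGCassette


@dataclass
class Origin:
    """A planted replication origin with per-flank fork speeds (bp per S)."""

    chromosome: str
    position: float
    firing_time: float = 0.0
    efficiency: float = 1.0
    left_speed: float = 300_000.0
    right_speed: float = 300_000.0


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic genome and all signal tracks.

    Chromosome sizes are a scaled-down analog of the eleven megabase
    chromosomes; layout fractions follow the genome-wide class shares
    (core ~87%, arrays ~8%, subtelomere ~5%).  ChIP probes tile at 61 bp;
    planted sites are 4-fold enrichments, matching the low initiator
    enrichment seen on arrays.  The S-phase sampling window covers the
    first half of S, so only early-firing origins are visible.
    """

    chromosomes: dict[str, int] = field(
        default_factory=lambda: {"chr1": 2_000_000, "chr2": 1_400_000, "chr3": 800_000}
    )
    # layout (per chromosome end)
    array_fraction: float = 0.05
    subtelomere_fraction: float = 0.025
    # core gene architecture
    gene_length: int = 1_500
    intergenic_gap: int = 800
    genes_per_dgc: int = 40  # mean cluster size (real clusters average ~50)
    genes_per_dgc_jitter: float = 0.5  # +/- fraction of the mean, per cluster
    ssr_gap: int = 4_000
    hypothetical_every: int = 5  # every k-th core gene is hypothetical
    # VSG cassette layout (fractions of cassette length)
    cassette_length: int = 14_000
    repeat_length: int = 350
    flank5_fraction: float = 0.40
    orf_fraction: float = 0.50
    pseudogene_every: int = 3  # every k-th cassette ORF is a pseudogene
    # subtelomere gene families
    subtelomere_gene_length: int = 1_200
    subtelomere_gap: int = 600
    # sequence composition (AT fraction per region class)
    at_content: dict[str, float] = field(
        default_factory=lambda: {"core": 0.70, "subtelomere": 0.65, "vsg_array": 0.60}
    )
    emit_sequence: bool = False
    # ChIP
    probe_spacing: int = 61
    chip_noise_sd: float = 0.25
    chip_enrichment_fold: float = 4.0
    chip_site_halfwidth: int = 500
    # replication
    s_window: tuple[float, float] = (0.0, 0.5)
    base_fork_speed: float = 150_000.0  # counter-directional, bp per S phase
    codirectional_multiplier: float = 2.0
    origin_spacing: int = 500_000
    depth_mean: float = 30.0
    nb_alpha: float = 0.02  # var = m (1 + alpha m); 0 -> Poisson
    profile_grid: int = 100  # bp grid for the semi-analytic profile
    # RNAi transcriptome
    expression_depth: float = 20.0
    boundary_fold: float = 2.0
    boundary_extent: int = 5_000
    mvsg_basal: float = 2.0
    mvsg_fold: float = 8.0
    bvsg_fold: float = 2.0
    silent_induced_depth: float = 10.0
    # qPCR
    ct_base: float = 20.0
    ct_noise_sd: float = 0.1
    ct_replicates: int = 4

    def validate(self) -> None:
        if 2 * (self.array_fraction + self.subtelomere_fraction) >= 1.0:
            raise ValueError("arm fractions leave no room for a core")
        if not 0.0 <= self.s_window[0] < self.s_window[1] <= 1.0:
            raise ValueError("s_window must be within [0, 1]")
        if self.probe_spacing <= 0 or self.base_fork_speed <= 0:
            raise ValueError("rates and spacings must be positive")
        if self.flank5_fraction + self.orf_fraction >= 1.0:
            raise ValueError("cassette fractions exceed the cassette")


@dataclass
class SyntheticTruth:
    """Ground truth emitted alongside the synthetic data."""

    config: SimulationConfig
    genes: list[GeneRecord] = field(default_factory=list)
    region_tracks: dict[str, RegionClassTrack] = field(default_factory=dict)
    dgcs: list[DGC] = field(default_factory=list)
    ssrs: list[SSR] = field(default_factory=list)
    cassettes: list[VSGCassette] = field(default_factory=list)
    repeats: dict[str, list[tuple[int, int]]] = field(default_factory=dict)
    binding_sites: pd.DataFrame | None = None
    origins: list[Origin] = field(default_factory=list)
    mvsg_genes: list[str] = field(default_factory=list)
    bvsg_genes: list[str] = field(default_factory=list)
    silent_loci: list[tuple[str, int, int]] = field(default_factory=list)


def _draw_counts(rng: np.random.Generator, mean: np.ndarray, alpha: float) -> np.ndarray:
    """Negative binomial counts, var = m (1 + alpha m); Poisson at alpha=0."""
    mean = np.asarray(mean, dtype=np.float64)
    if alpha <= 0:
        return rng.poisson(mean)
    r = 1.0 / alpha
    p = r / (r + np.maximum(mean, 1e-12))
    return rng.negative_binomial(r, p)


def _random_sequence(rng: np.random.Generator, n: int, at_fraction: float) -> np.ndarray:
    probs = [at_fraction / 2, (1 - at_fraction) / 2, (1 - at_fraction) / 2, at_fraction / 2]
    return rng.choice(np.frombuffer(b"ACGT", dtype="S1"), size=n, p=probs)


def _layout_array(
    chrom: str,
    span: tuple[int, int],
    cfg: SimulationConfig,
    mirrored: bool,
    counter: list[int],
) -> tuple[list[GeneRecord], list[tuple[int, int]], list[VSGCassette]]:
    """Tile one telomeric span with VSG cassettes.

    ``mirrored`` lays the right-arm array with cassettes pointing inward
    the same way (repeat first, reading toward the core boundary is not
    required by the downstream analysis, so both arms use telomere-to-core
    cassette order).
    """
    lo, hi = span
    genes: list[GeneRecord] = []
    repeats: list[tuple[int, int]] = []
    cassettes: list[VSGCassette] = []
    rep_len = cfg.repeat_length
    f5_len = int(cfg.cassette_length * cfg.flank5_fraction)
    orf_len = int(cfg.cassette_length * cfg.orf_fraction)
    pos = lo
    k = 0
    while pos + cfg.cassette_length <= hi:
        rep = (pos, pos + rep_len)
        orf_start = rep[1] + f5_len
        orf_end = orf_start + orf_len
        cass_end = pos + cfg.cassette_length
        is_pseudo = cfg.pseudogene_every > 0 and (k + 1) % cfg.pseudogene_every == 0
        # the innermost array gene must be a VSG so the array reaches it
        if pos + 2 * cfg.cassette_length > hi:
            is_pseudo = False
        counter[0] += 1
        cat = "pseudogene" if is_pseudo else "VSG"
        gid = f"{chrom}.vsg{counter[0]}"
        genes.append(GeneRecord(gid, chrom, orf_start, orf_end, "+", cat))
        repeats.append(rep)
        cassettes.append(
            VSGCassette(
                chrom,
                repeat_70bp=rep,
                flank_5p=(rep[1], orf_start),
                vsg_orf=(orf_start, orf_end),
                flank_3p=(orf_end, cass_end),
                orf_status="pseudogene" if is_pseudo else "functional",
            )
        )
        pos = cass_end
        k += 1
    return genes, repeats, cassettes


def _layout_subtelomere(
    chrom: str, span: tuple[int, int], cfg: SimulationConfig, counter: list[int]
) -> list[GeneRecord]:
    cats = ("RHS", "ESAG", "VSG_related", "ESAG3")
    genes = []
    pos = span[0]
    k = 0
    while pos + cfg.subtelomere_gene_length <= span[1]:
        counter[0] += 1
        genes.append(
            GeneRecord(
                f"{chrom}.st{counter[0]}",
                chrom,
                pos,
                pos + cfg.subtelomere_gene_length,
                "-" if k % 2 else "+",
                cats[k % len(cats)],
            )
        )
        pos += cfg.subtelomere_gene_length + cfg.subtelomere_gap
        k += 1
    return genes


def generate_genome(
    config: SimulationConfig, seed: int = 0
) -> tuple[dict[str, str], list[GeneRecord], SyntheticTruth]:
    """Lay out the synthetic genome and its ground truth.

    Each chromosome is [vsg_array | subtelomere | core | subtelomere |
    vsg_array]; the core is tiled with alternating-strand DGCs separated by
    SSR gaps.  Ground-truth region classes use the same midpoint-split
    convention as the demarcation scan, binding sites sit at SSR midpoints,
    and origins occupy divergent SSRs at the configured spacing with
    codirectional-flank fork speedup.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    truth = SyntheticTruth(config=config)
    sequences: dict[str, str] = {}
    all_genes: list[GeneRecord] = []
    site_rows = []

    for chrom, length in config.chromosomes.items():
        a = int(length * config.array_fraction)
        s = int(length * config.subtelomere_fraction)
        spans = {
            "array_l": (0, a),
            "subtel_l": (a, a + s),
            "core": (a + s, length - a - s),
            "subtel_r": (length - a - s, length - a),
            "array_r": (length - a, length),
        }
        counter = [0]
        g_al, rep_l, cas_l = _layout_array(chrom, spans["array_l"], config, False, counter)
        g_sl = _layout_subtelomere(chrom, spans["subtel_l"], config, counter)

        # core DGCs
        core_lo, core_hi = spans["core"]
        g_core: list[GeneRecord] = []
        dgcs: list[DGC] = []
        pos = core_lo + config.ssr_gap // 2
        unit = config.gene_length + config.intergenic_gap
        n_lo = max(2, round(config.genes_per_dgc * (1 - config.genes_per_dgc_jitter)))
        n_hi = max(n_lo, round(config.genes_per_dgc * (1 + config.genes_per_dgc_jitter)))
        strand = "-"
        while True:
            # cluster sizes vary so the core is aperiodic, as in real genomes
            n_genes = int(rng.integers(n_lo, n_hi + 1))
            dgc_len = n_genes * unit - config.intergenic_gap
            if pos + dgc_len > core_hi - config.ssr_gap // 2:
                break
            ids = []
            p = pos
            for j in range(n_genes):
                counter[0] += 1
                cat = (
                    "hypothetical"
                    if config.hypothetical_every
                    and 0 < j < n_genes - 1
                    and j % config.hypothetical_every == config.hypothetical_every - 1
                    else "ordinary"
                )
                gid = f"{chrom}.g{counter[0]}"
                g_core.append(GeneRecord(gid, chrom, p, p + config.gene_length, strand, cat))
                ids.append(gid)
                p += unit
            dgcs.append(DGC(chrom, pos, pos + dgc_len, strand, ids))
            pos += dgc_len + config.ssr_gap
            strand = "+" if strand == "-" else "-"

        g_sr = _layout_subtelomere(chrom, spans["subtel_r"], config, counter)
        g_ar, rep_r, cas_r = _layout_array(chrom, spans["array_r"], config, True, counter)
        # right arm: innermost array gene (the first cassette) must be VSG
        if g_ar and g_ar[0].category != "VSG":
            g_ar[0] = replace(g_ar[0], category="VSG")
            cas_r[0].orf_status = "functional"

        genes = g_al + g_sl + g_core + g_sr + g_ar
        all_genes.extend(genes)
        truth.dgcs.extend(dgcs)
        ssrs = []
        for d1, d2 in zip(dgcs, dgcs[1:]):
            t = "divergent" if (d1.strand, d2.strand) == ("-", "+") else "convergent"
            ssrs.append(SSR(chrom, d1.end, d2.start, t))
        truth.ssrs.extend(ssrs)
        truth.cassettes.extend(cas_l + cas_r)
        truth.repeats[chrom] = rep_l + rep_r

        # truth region classes with the midpoint-split convention
        def _mid(left: list[GeneRecord], right: list[GeneRecord]) -> int:
            return (left[-1].end + right[0].start) // 2

        nonhyp_core = [g for g in g_core if g.category != "hypothetical"]
        if not (g_al and g_sl and nonhyp_core and g_sr and g_ar):
            raise ValueError(
                f"{chrom}: chromosome too short for the configured arm layout"
            )
        b1 = _mid(g_al, g_sl)
        b2 = _mid(g_sl, nonhyp_core)
        b3 = _mid(nonhyp_core, g_sr)
        b4 = _mid(g_sr, g_ar)
        truth.region_tracks[chrom] = RegionClassTrack(
            chrom,
            [
                (0, b1, "vsg_array"),
                (b1, b2, "subtelomere"),
                (b2, b3, "core"),
                (b3, b4, "subtelomere"),
                (b4, length, "vsg_array"),
            ],
        )

        # binding sites at SSR midpoints
        for ssr in ssrs:
            mid = (ssr.start + ssr.end) // 2
            site_rows.append(
                {
                    "chromosome": chrom,
                    "start": mid - config.chip_site_halfwidth,
                    "end": mid + config.chip_site_halfwidth,
                }
            )

        # origins on divergent SSRs at the configured spacing; keep a
        # fork-extent margin from the chromosome ends so flanks are not
        # truncated by the telomere
        fast = config.base_fork_speed * config.codirectional_multiplier
        margin = fast * config.s_window[1]
        last = -np.inf
        for ssr in ssrs:
            if ssr.ssr_type != "divergent":
                continue
            mid = 0.5 * (ssr.start + ssr.end)
            if mid < margin or mid > length - margin:
                continue
            if mid - last < config.origin_spacing:
                continue
            truth.origins.append(
                Origin(chrom, mid, 0.0, 1.0, left_speed=fast, right_speed=fast)
            )
            last = mid

        # RNAi truth: derepressed VSGs and silent presence loci
        if g_al:
            truth.mvsg_genes.append(g_al[-1].gene_id)
        if g_ar:
            truth.bvsg_genes.append(g_ar[0].gene_id)
        if len(cas_l) > 1:
            truth.silent_loci.append((chrom, *cas_l[1].flank_5p))

        if config.emit_sequence:
            arr = np.empty(length, dtype="S1")
            for s0, e0, cls in truth.region_tracks[chrom].intervals:
                arr[s0:e0] = _random_sequence(rng, e0 - s0, config.at_content[cls])
            sequences[chrom] = arr.tobytes().decode("ascii")

    truth.genes = all_genes
    truth.binding_sites = pd.DataFrame(
        site_rows, columns=["chromosome", "start", "end"]
    )
    return sequences, all_genes, truth


# ---------------------------------------------------------------------------
# replication


def expected_replication_profile(
    origins: list[Origin],
    positions: np.ndarray,
    s_window: tuple[float, float],
) -> np.ndarray:
    """P(locus replicated) under uniform sampling over the S window.

    Exact integration: for each position the origin fork-arrival times are
    sorted and the survival function (probability no fired origin has
    arrived) is piecewise constant between them, so the time integral is a
    finite sum.
    """
    w0, w1 = s_window
    positions = np.asarray(positions, dtype=np.float64)
    n = positions.size
    if not origins:
        return np.zeros(n)
    arrivals = np.empty((len(origins), n))
    effs = np.empty((len(origins), n))
    for i, o in enumerate(origins):
        d = positions - o.position
        arrivals[i] = o.firing_time + np.where(
            d < 0, -d / o.left_speed, d / o.right_speed
        )
        effs[i] = o.efficiency
    order = np.argsort(arrivals, axis=0)
    a_sorted = np.take_along_axis(arrivals, order, axis=0)
    e_sorted = np.take_along_axis(effs, order, axis=0)
    survival = np.vstack([np.ones((1, n)), np.cumprod(1.0 - e_sorted, axis=0)])
    edges = np.vstack(
        [np.full((1, n), w0), np.clip(a_sorted, w0, w1), np.full((1, n), w1)]
    )
    seg = np.diff(edges, axis=0)
    integral = (survival * seg).sum(axis=0)
    return 1.0 - integral / (w1 - w0)


def monte_carlo_replication_profile(
    origins: list[Origin],
    positions: np.ndarray,
    s_window: tuple[float, float],
    n_cells: int = 2_000,
    seed: int = 0,
) -> np.ndarray:
    """Brute-force per-cell oracle for :func:`expected_replication_profile`.

    Simulates individual cells: each draws a sampling time uniform over the
    S window and an independent firing outcome per origin; a locus counts
    as replicated when any fired origin's fork reached it in time.
    """
    rng = np.random.default_rng(seed)
    w0, w1 = s_window
    positions = np.asarray(positions, dtype=np.float64)
    hits = np.zeros(positions.size)
    for _ in range(n_cells):
        t = rng.uniform(w0, w1)
        replicated = np.zeros(positions.size, dtype=bool)
        for o in origins:
            if rng.random() >= o.efficiency:
                continue
            d = positions - o.position
            arrival = o.firing_time + np.where(d < 0, -d / o.left_speed, d / o.right_speed)
            replicated |= arrival <= t
        hits += replicated
    return hits / n_cells


def simulate_replication(
    truth: SyntheticTruth, config: SimulationConfig | None = None, seed: int = 0
) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Per-position S and G2 read-depth tracks.

    S-phase mean depth is proportional to expected copy number (1 + P);
    G2 is uniform at copy number 2.  The per-position probability is
    interpolated from a coarse grid (the profile varies on the fork-travel
    scale, tens of kilobases).
    """
    cfg = config or truth.config
    rng = np.random.default_rng(seed)
    s_tracks: dict[str, np.ndarray] = {}
    g2_tracks: dict[str, np.ndarray] = {}
    for chrom, length in cfg.chromosomes.items():
        origins = [o for o in truth.origins if o.chromosome == chrom]
        grid = np.arange(0, length + cfg.profile_grid, cfg.profile_grid, dtype=np.float64)
        grid = np.clip(grid, 0, length - 1)
        p_grid = expected_replication_profile(origins, grid, cfg.s_window)
        p = np.interp(np.arange(length, dtype=np.float64), grid, p_grid)
        s_mean = cfg.depth_mean * (1.0 + p) / 2.0
        g2_mean = np.full(length, cfg.depth_mean)
        s_tracks[chrom] = _draw_counts(rng, s_mean, cfg.nb_alpha)
        g2_tracks[chrom] = _draw_counts(rng, g2_mean, cfg.nb_alpha)
    return s_tracks, g2_tracks


# ---------------------------------------------------------------------------
# ChIP


def simulate_chip(
    truth: SyntheticTruth, config: SimulationConfig | None = None, seed: int = 0
) -> pd.DataFrame:
    """Tiling-probe log2 ratio table with plateau enrichment at truth sites.

    Probes every ``probe_spacing`` bp carry Gaussian baseline noise; probes
    inside a planted site footprint gain log2(enrichment fold).
    """
    cfg = config or truth.config
    rng = np.random.default_rng(seed)
    frames = []
    sites = truth.binding_sites
    for chrom, length in cfg.chromosomes.items():
        pos = np.arange(cfg.probe_spacing // 2, length, cfg.probe_spacing)
        val = rng.normal(0.0, cfg.chip_noise_sd, size=pos.size)
        if sites is not None and cfg.chip_enrichment_fold > 1:
            sub = sites[sites["chromosome"] == chrom]
            for row in sub.itertuples():
                inside = (pos >= row.start) & (pos < row.end)
                val[inside] += np.log2(cfg.chip_enrichment_fold)
        frames.append(
            pd.DataFrame(
                {
                    "probe_id": [f"{chrom}_p{i}" for i in range(pos.size)],
                    "chromosome": chrom,
                    "position": pos,
                    "log2_ratio": val,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# RNAi transcriptome


def simulate_rnai(
    truth: SyntheticTruth, config: SimulationConfig | None = None, seed: int = 0
) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Induced and uninduced per-position expression depth tracks.

    Uninduced cells express uniformly within DGCs and are silent in SSRs,
    subtelomeres and arrays (VSGs keep a small basal level).  Induction
    multiplies expression near DGC boundaries, spills reads past the
    transcription start/stop into the flanks, derepresses the designated
    MVSG-like (strongly) and BVSG-like (weakly) genes, and switches on the
    silent presence loci.
    """
    cfg = config or truth.config
    rng = np.random.default_rng(seed)
    gene_by_id = {g.gene_id: g for g in truth.genes}
    induced: dict[str, np.ndarray] = {}
    uninduced: dict[str, np.ndarray] = {}
    for chrom, length in cfg.chromosomes.items():
        u = np.zeros(length)
        for d in truth.dgcs:
            if d.chromosome == chrom:
                u[d.start : d.end] = cfg.expression_depth
        for gid, fold in [(g, cfg.mvsg_fold) for g in truth.mvsg_genes] + [
            (g, cfg.bvsg_fold) for g in truth.bvsg_genes
        ]:
            g = gene_by_id[gid]
            if g.chromosome == chrom:
                u[g.start : g.end] = cfg.mvsg_basal
        i = u.copy()
        ext = cfg.boundary_extent
        spill = cfg.expression_depth * (cfg.boundary_fold - 1.0)
        for d in truth.dgcs:
            if d.chromosome != chrom:
                continue
            i[d.start : d.start + ext] = u[d.start : d.start + ext] * cfg.boundary_fold
            i[max(0, d.end - ext) : d.end] = (
                u[max(0, d.end - ext) : d.end] * cfg.boundary_fold
            )
            i[max(0, d.start - ext) : d.start] += spill
            i[d.end : min(length, d.end + ext)] += spill
        for gid, fold in [(g, cfg.mvsg_fold) for g in truth.mvsg_genes] + [
            (g, cfg.bvsg_fold) for g in truth.bvsg_genes
        ]:
            g = gene_by_id[gid]
            if g.chromosome == chrom:
                i[g.start : g.end] = cfg.mvsg_basal * fold
        for c, s0, e0 in truth.silent_loci:
            if c == chrom:
                i[s0:e0] += cfg.silent_induced_depth
        induced[chrom] = _draw_counts(rng, i, cfg.nb_alpha)
        uninduced[chrom] = _draw_counts(rng, u, cfg.nb_alpha)
    return induced, uninduced


# ---------------------------------------------------------------------------
# qPCR


def simulate_qpcr(
    true_ratios: dict[str, float],
    config: SimulationConfig | None = None,
    seed: int = 0,
    calibrator: str = "CAL",
) -> pd.DataFrame:
    """Ct table for amplicons with known S:G2 ratios plus a calibrator at 1.

    Ct = base + amplicon offset - log2(quantity) + replicate noise; the
    calibrator is present at equal quantity in both samples.
    """
    cfg = config or SimulationConfig()
    rng = np.random.default_rng(seed)
    rows = []
    ratios = {calibrator: 1.0, **true_ratios}
    for amp, r in ratios.items():
        if r <= 0:
            raise ValueError(f"{amp}: ratio must be positive")
        offset = rng.normal(0.0, 1.0)
        for sample, q in (("G2", 1.0), ("S", r)):
            for _ in range(cfg.ct_replicates):
                noise = rng.normal(0.0, cfg.ct_noise_sd) if cfg.ct_noise_sd > 0 else 0.0
                rows.append(
                    {
                        "amplicon": amp,
                        "sample": sample,
                        "ct": cfg.ct_base + offset - np.log2(q) + noise,
                    }
                )
    return pd.DataFrame(rows)
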