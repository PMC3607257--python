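"""Chromosome demarcation and transcription-unit annotation.

Trypanosome megabase chromosomes have a characteristic architecture:
telomere-proximal arrays of silent *VSG* genes, a buffer of
subtelomere-associated gene families (*RHS*, *ESAG*, *VSG*-related), and a
transcribed core organised into directional gene clusters (DGCs, the
polycistronic transcription units) separated by strand switch regions
(SSRs).  This module demarcates a chromosome into those three region
classes from an ordered gene list, partitions core genes into DGCs,
classifies SSRs as divergent or convergent, decomposes *VSG* arrays into
their repeat/flank/ORF cassettes, and summarises AT content by region.

All coordinates are 0-based, half-open.  File interfaces (GFF3/BED)
convert at the boundary, see :mod:`orcmap.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

GENE_CATEGORIES = frozenset(
    {
        "ordinary",
        "hypothetical",
        "VSG",
        "VSG_related",
        "ESAG",
        "ESAG3",
        "RHS",
        "pseudogene",
    }
)

#: categories whose runs are annotated as subtelomere.  ESAG3 is excluded
#: because it also occurs inside VSG arrays and would bleed the class.
SUBTELOMERE_TRIGGERS = frozenset({"RHS", "VSG_related", "ESAG"})

#: categories that may occur in the terminal (non-core) segment of an arm.
_TERMINAL = frozenset({"VSG", "VSG_related", "ESAG", "ESAG3", "RHS", "pseudogene"})

REGION_CLASSES = ("core", "subtelomere", "vsg_array")


@dataclass(frozen=True)
class GeneRecord:
    """A gene with its functional category, 0-based half-open coordinates."""

    gene_id: str
    chromosome: str
    start: int
    end: int
    strand: str  # "+" or "-"
    category: str = "ordinary"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"{self.gene_id}: start must be < end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        if self.category not in GENE_CATEGORIES:
            raise ValueError(f"{self.gene_id}: unknown category {self.category!r}")

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.start + self.end)


@dataclass
class RegionClassTrack:
    """Partition of one chromosome into core/subtelomere/vsg_array intervals."""

    chromosome: str
    intervals: list[tuple[int, int, str]]
    degenerate: bool = False

    def validate(self, chromosome_length: int | None = None) -> None:
        prev_end = 0
        prev_cls = None
        for start, end, cls in self.intervals:
            if cls not in REGION_CLASSES:
                raise ValueError(f"unknown region class {cls!r}")
            if start != prev_end:
                raise ValueError("intervals must tile the chromosome without gaps")
            if cls == prev_cls:
                raise ValueError("adjacent intervals must have distinct classes")
            prev_end, prev_cls = end, cls
        if chromosome_length is not None and prev_end != chromosome_length:
            raise ValueError("intervals must cover [0, chromosome_length)")

    def class_at(self, position: float) -> str | None:
        for start, end, cls in self.intervals:
            if start <= position < end:
                return cls
        return None

    def class_lengths(self) -> dict[str, int]:
        out: dict[str, int] = {c: 0 for c in REGION_CLASSES}
        for start, end, cls in self.intervals:
            out[cls] += end - start
        return out


@dataclass
class DGC:
    """Directional gene cluster: a maximal run of same-strand genes."""

    chromosome: str
    start: int
    end: int
    strand: str
    gene_ids: list[str] = field(default_factory=list)


@dataclass
class SSR:
    """Strand switch region between two opposite-strand DGCs.

    ``divergent``: transcription initiates outward (reverse-strand cluster
    upstream, forward-strand downstream); ``convergent``: transcription
    terminates inward.
    """

    chromosome: str
    start: int
    end: int
    ssr_type: str  # "divergent" | "convergent"


@dataclass
class VSGCassette:
    """One repeat/flank/ORF/flank unit of a subtelomeric VSG array."""

    chromosome: str
    repeat_70bp: tuple[int, int]
    flank_5p: tuple[int, int]
    vsg_orf: tuple[int, int] | None
    flank_3p: tuple[int, int]
    orf_status: str | None  # "functional" | "pseudogene" | None
    flagged: bool = False


def _check_sorted(genes: Sequence[GeneRecord]) -> None:
    for a, b in zip(genes, genes[1:]):
        if b.start < a.start:
            raise ValueError("genes must be sorted by start coordinate")


def demarcate_chromosome(
    genes: Sequence[GeneRecord],
    chromosome_length: int,
    *,
    min_array_genes: int = 1,
    min_island_run: int = 2,
) -> RegionClassTrack:
    """Demarcate one chromosome into core / subtelomere / vsg_array.

    Scans inward from each chromosome end.  The terminal segment of an arm
    (genes up to the first ``ordinary`` gene) defines a VSG array out to the
    innermost *VSG* of the segment (when the segment carries at least
    ``min_array_genes`` VSGs) and a subtelomere over the remaining
    trigger-category genes.  Hypothetical genes never influence the class
    decision.  Interior runs of at least ``min_island_run`` consecutive
    subtelomere-category genes are labelled subtelomere despite sitting in
    the core (chromosome-fusion relics).  Gaps between genes of one class
    stay in that class; gaps between classes are split at the midpoint and
    the outermost intervals are extended to the chromosome ends.
    """
    _check_sorted(genes)
    for g in genes:
        if g.end > chromosome_length:
            raise ValueError(f"{g.gene_id} extends beyond the chromosome")
    nonhyp = [g for g in genes if g.category != "hypothetical"]
    chrom = genes[0].chromosome if genes else "?"
    if not nonhyp:
        return RegionClassTrack(chrom, [(0, 0, "core")], degenerate=True)

    labels = ["core"] * len(nonhyp)

    def label_arm(order: range) -> int:
        """Label the terminal segment of one arm; return #genes consumed."""
        seg = []
        for i in order:
            if nonhyp[i].category not in _TERMINAL:
                break
            seg.append(i)
        if not seg:
            return 0
        vsg_idx = [i for i in seg if nonhyp[i].category == "VSG"]
        if len(vsg_idx) >= min_array_genes:
            innermost = seg.index(vsg_idx[-1])
            for i in seg[: innermost + 1]:
                labels[i] = "vsg_array"
            rest = seg[innermost + 1 :]
        else:
            rest = seg
        if any(nonhyp[i].category in SUBTELOMERE_TRIGGERS for i in rest):
            for i in rest:
                labels[i] = "subtelomere"
        return len(seg)

    n_left = label_arm(range(len(nonhyp)))
    label_arm(range(len(nonhyp) - 1, n_left - 1, -1))

    # interior subtelomere islands inside the core
    i = n_left
    while i < len(nonhyp):
        if labels[i] == "core" and nonhyp[i].category in SUBTELOMERE_TRIGGERS:
            j = i
            while (
                j < len(nonhyp)
                and labels[j] == "core"
                and nonhyp[j].category in SUBTELOMERE_TRIGGERS
            ):
                j += 1
            if j - i >= min_island_run:
                for k in range(i, j):
                    labels[k] = "subtelomere"
            i = j
        else:
            i += 1

    # run-length encode, then stitch: extend to ends, split gaps at midpoints
    runs: list[tuple[int, int, str]] = []  # (span_start, span_end, class)
    for g, lab in zip(nonhyp, labels):
        if runs and runs[-1][2] == lab:
            runs[-1] = (runs[-1][0], max(runs[-1][1], g.end), lab)
        else:
            runs.append((g.start, g.end, lab))

    intervals: list[tuple[int, int, str]] = []
    for k, (s, e, lab) in enumerate(runs):
        lo = 0 if k == 0 else (runs[k - 1][1] + s) // 2
        hi = chromosome_length if k == len(runs) - 1 else (e + runs[k + 1][0]) // 2
        intervals.append((lo, hi, lab))
    track = RegionClassTrack(chrom, intervals)
    track.validate(chromosome_length)
    return track


def build_dgcs(genes: Sequence[GeneRecord]) -> list[DGC]:
    """Partition a sorted gene list into maximal same-strand runs (DGCs).

    Hypothetical genes are retained as cluster members — they are excluded
    only from region-class decisions, not from transcription units.
    """
    _check_sorted(genes)
    dgcs: list[DGC] = []
    for g in genes:
        if dgcs and dgcs[-1].strand == g.strand:
            d = dgcs[-1]
            d.end = max(d.end, g.end)
            d.gene_ids.append(g.gene_id)
        else:
            dgcs.append(DGC(g.chromosome, g.start, g.end, g.strand, [g.gene_id]))
    return dgcs


def classify_ssrs(dgcs: Sequence[DGC]) -> list[SSR]:
    """Classify inter-DGC gaps flanked by opposite strands.

    Reverse-then-forward adjacency is a divergent SSR (bidirectional
    transcription initiation); forward-then-reverse is convergent
    (termination).  Same-strand adjacencies yield no SSR.
    """
    for a, b in zip(dgcs, dgcs[1:]):
        if b.start < a.end:
            raise ValueError("DGCs overlap; cannot classify SSRs")
    out = []
    for a, b in zip(dgcs, dgcs[1:]):
        if a.strand == b.strand:
            continue
        ssr_type = "divergent" if (a.strand, b.strand) == ("-", "+") else "convergent"
        out.append(SSR(a.chromosome, a.end, b.start, ssr_type))
    return out


def parse_vsg_cassettes(
    array_region: tuple[int, int],
    genes: Sequence[GeneRecord],
    repeats: Sequence[tuple[int, int]],
) -> list[VSGCassette]:
    """Decompose a VSG array into cassettes anchored on 70 bp repeats.

    Each repeat opens a cassette; the first VSG ORF downstream of it (and
    before the next repeat) is assigned to the cassette.  The 5' flank is
    the span between repeat end and ORF start; the 3' flank runs from the
    ORF end to the next repeat or the array boundary.  A repeat with no
    downstream ORF yields a flagged, ORF-less cassette.
    """
    lo, hi = array_region
    reps = sorted(repeats)
    orfs = sorted(
        (g for g in genes if g.category in ("VSG", "pseudogene") and lo <= g.start < hi),
        key=lambda g: g.start,
    )
    cassettes: list[VSGCassette] = []
    chrom = orfs[0].chromosome if orfs else "?"
    for k, (rs, re) in enumerate(reps):
        nxt = reps[k + 1][0] if k + 1 < len(reps) else hi
        orf = next((g for g in orfs if re <= g.start < nxt), None)
        if orf is None:
            cassettes.append(
                VSGCassette(
                    chrom,
                    repeat_70bp=(rs, re),
                    flank_5p=(re, nxt),
                    vsg_orf=None,
                    flank_3p=(nxt, nxt),
                    orf_status=None,
                    flagged=True,
                )
            )
            continue
        status = "functional" if orf.category == "VSG" else "pseudogene"
        cassettes.append(
            VSGCassette(
                orf.chromosome,
                repeat_70bp=(rs, re),
                flank_5p=(re, orf.start),
                vsg_orf=(orf.start, orf.end),
                flank_3p=(orf.end, nxt),
                orf_status=status,
            )
        )
    return cassettes


def cassette_component_fractions(cassettes: Iterable[VSGCassette]) -> dict[str, float]:
    """Length share of each cassette component over the total cassette span."""
    tot = {"repeat_70bp": 0, "flank_5p": 0, "vsg_orf": 0, "flank_3p": 0}
    for c in cassettes:
        tot["repeat_70bp"] += c.repeat_70bp[1] - c.repeat_70bp[0]
        tot["flank_5p"] += c.flank_5p[1] - c.flank_5p[0]
        if c.vsg_orf is not None:
            tot["vsg_orf"] += c.vsg_orf[1] - c.vsg_orf[0]
        tot["flank_3p"] += c.flank_3p[1] - c.flank_3p[0]
    grand = sum(tot.values())
    return {k: (v / grand if grand else np.nan) for k, v in tot.items()}


def at_content_by_class(
    sequence: Mapping[str, str] | str,
    regions: Sequence[tuple[str, int, int, str]],
    bound: Sequence[tuple[str, int, int]] | None = None,
) -> pd.DataFrame:
    """Percent AT per region label, optionally split bound vs unbound.

    ``regions`` are ``(chromosome, start, end, label)``; ``bound`` intervals
    (e.g. initiator binding sites) partition each region's bases into bound
    and unbound fractions.  Returns a tidy table with columns
    ``label, partition, at_percent, n_bases``.
    """
    seqs = {"": sequence} if isinstance(sequence, str) else dict(sequence)

    def arr(chrom: str) -> np.ndarray:
        s = seqs[chrom] if chrom in seqs else seqs[""]
        return np.frombuffer(s.upper().encode("ascii"), dtype="S1")

    masks: dict[str, np.ndarray] = {}
    if bound is not None:
        for chrom, s, e in bound:
            key = chrom if chrom in seqs else ""
            if key not in masks:
                masks[key] = np.zeros(len(seqs[key]), dtype=bool)
            masks[key][s:e] = True

    acc: dict[tuple[str, str], list[int]] = {}
    for chrom, s, e, label in regions:
        key = chrom if chrom in seqs else ""
        if s < 0 or e > len(seqs[key]):
            raise ValueError(f"interval ({s}, {e}) outside sequence of {chrom!r}")
        a = arr(chrom)[s:e]
        is_at = (a == b"A") | (a == b"T")
        if bound is None:
            parts = {"all": np.ones(e - s, dtype=bool)}
        else:
            m = masks.get(key, np.zeros(len(seqs[key]), dtype=bool))[s:e]
            parts = {"bound": m, "unbound": ~m}
        for pname, pmask in parts.items():
            at, n = int(is_at[pmask].sum()), int(pmask.sum())
            prev = acc.setdefault((label, pname), [0, 0])
            prev[0] += at
            prev[1] += n
    rows = [
        {
            "label": label,
            "partition": part,
            "at_percent": 100.0 * at / n if n else np.nan,
            "n_bases": n,
        }
        for (label, part), (at, n) in sorted(acc.items())
    ]
    return pd.DataFrame(rows)
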