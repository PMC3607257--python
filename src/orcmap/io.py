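"""Readers and writers for the pipeline's file dialects.

Internal coordinates are 0-based half-open everywhere; GFF3 converts to
1-based inclusive at this boundary, BED and bedGraph are natively
half-open.  All round trips are identity (``read(write(x)) == x``).
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO

from .annotation import DGC, SSR, GeneRecord, RegionClassTrack, VSGCassette


class FormatError(ValueError):
    """Malformed input line, reported with file/line context."""


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_chrom_lengths(path: str | Path) -> dict[str, int]:
    """Two-column TSV (chromosome, length) — e.g. a FASTA .fai prefix."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", usecols=[0, 1])
    return dict(zip(df[0].astype(str), df[1].astype(int)))


def write_chrom_lengths(lengths: Mapping[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, n in lengths.items():
            fh.write(f"{name}\t{n}\n")


# ---------------------------------------------------------------------------
# GFF3


def _parse_attributes(raw: str) -> dict[str, str]:
    out = {}
    for chunk in raw.strip().split(";"):
        if chunk and "=" in chunk:
            k, v = chunk.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def _fmt_attributes(attrs: Mapping[str, str]) -> str:
    return ";".join(f"{k}={v}" for k, v in attrs.items())


def read_genes_gff3(path: str | Path) -> list[GeneRecord]:
    """Genes from GFF3 (``type == gene``, ``category`` attribute)."""
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 GFF3 columns")
            chrom, _, ftype, start, end, _, strand, _, attrs = fields
            if ftype != "gene":
                continue
            a = _parse_attributes(attrs)
            try:
                s, e = int(start) - 1, int(end)  # 1-based inclusive -> half-open
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: bad coordinates") from exc
            genes.append(
                GeneRecord(
                    gene_id=a.get("ID", f"gene{lineno}"),
                    chromosome=chrom,
                    start=s,
                    end=e,
                    strand=strand,
                    category=a.get("category", "ordinary"),
                )
            )
    return genes


def write_genes_gff3(genes: list[GeneRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = _fmt_attributes({"ID": g.gene_id, "category": g.category})
            fh.write(
                f"{g.chromosome}\torcmap\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\t{attrs}\n"
            )


def write_features_gff3(
    dgcs: list[DGC], ssrs: list[SSR], cassettes: list[VSGCassette], path: str | Path
) -> None:
    """Annotation features (DGCs, SSRs, cassette components) as GFF3."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for k, d in enumerate(dgcs):
            attrs = _fmt_attributes({"ID": f"DGC{k + 1}", "n_genes": str(len(d.gene_ids))})
            fh.write(
                f"{d.chromosome}\torcmap\tDGC\t{d.start + 1}\t{d.end}\t.\t"
                f"{d.strand}\t.\t{attrs}\n"
            )
        for k, s in enumerate(ssrs):
            attrs = _fmt_attributes({"ID": f"SSR{k + 1}", "ssr_type": s.ssr_type})
            fh.write(
                f"{s.chromosome}\torcmap\tSSR\t{s.start + 1}\t{s.end}\t.\t.\t.\t{attrs}\n"
            )
        for k, c in enumerate(cassettes):
            parts = [("repeat_70bp", c.repeat_70bp), ("flank_5p", c.flank_5p)]
            if c.vsg_orf is not None:
                parts.append(("vsg_orf", c.vsg_orf))
            parts.append(("flank_3p", c.flank_3p))
            for name, (s0, e0) in parts:
                if e0 <= s0:
                    continue
                attrs = _fmt_attributes(
                    {"ID": f"cassette{k + 1}.{name}", "orf_status": c.orf_status or "none"}
                )
                fh.write(
                    f"{c.chromosome}\torcmap\t{name}\t{s0 + 1}\t{e0}\t.\t.\t.\t{attrs}\n"
                )


# ---------------------------------------------------------------------------
# BED


def write_region_bed(tracks: Mapping[str, RegionClassTrack], path: str | Path) -> None:
    """Region-class demarcation as BED (name = class)."""
    with open(path, "w") as fh:
        for chrom in tracks:
            for s, e, cls in tracks[chrom].intervals:
                fh.write(f"{chrom}\t{s}\t{e}\t{cls}\n")


def read_region_bed(path: str | Path) -> dict[str, RegionClassTrack]:
    by_chrom: dict[str, list[tuple[int, int, str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise FormatError(f"{path}:{lineno}: expected 4 BED columns")
            chrom, s, e, name = fields[:4]
            by_chrom.setdefault(chrom, []).append((int(s), int(e), name))
    return {c: RegionClassTrack(c, ivals) for c, ivals in by_chrom.items()}


def write_sites_bed(sites: pd.DataFrame, path: str | Path) -> None:
    """Called binding sites: name = fdr_class, score = peak score."""
    with open(path, "w") as fh:
        for row in sites.itertuples():
            fh.write(
                f"{row.chromosome}\t{row.start}\t{row.end}\t{row.fdr_class}\t"
                f"{row.peak_score:.4f}\n"
            )


def read_intervals_bed(path: str | Path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: expected >=3 BED columns")
            rows.append(
                {"chromosome": fields[0], "start": int(fields[1]), "end": int(fields[2])}
            )
    return pd.DataFrame(rows, columns=["chromosome", "start", "end"])


# ---------------------------------------------------------------------------
# bedGraph depth tracks


def read_depth_bedgraph(
    path: str | Path, chrom_lengths: Mapping[str, int]
) -> tuple[dict[str, np.ndarray], list[str]]:
    """Expand a bedGraph into per-position depth arrays.

    Track definition lines and comments are tolerated and returned as
    metadata.  Positions not covered by any interval are zero.
    """
    tracks = {c: np.zeros(n) for c, n in chrom_lengths.items()}
    meta = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith(("#", "track", "browser")):
                meta.append(line)
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise FormatError(f"{path}:{lineno}: expected 4 bedGraph columns")
            chrom, s, e, v = fields
            if chrom not in tracks:
                raise FormatError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
            s_i, e_i = int(s), int(e)
            if e_i > chrom_lengths[chrom]:
                raise FormatError(f"{path}:{lineno}: interval beyond chromosome end")
            tracks[chrom][s_i:e_i] = float(v)
    return tracks, meta


def write_depth_bedgraph(
    tracks: Mapping[str, np.ndarray], path: str | Path, name: str | None = None
) -> None:
    """Run-length encoded bedGraph; zero runs are omitted."""
    with open(path, "w") as fh:
        if name:
            fh.write(f'track type=bedGraph name="{name}"\n')
        for chrom, vals in tracks.items():
            vals = np.asarray(vals)
            if vals.size == 0:
                continue
            change = np.flatnonzero(np.diff(vals)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [vals.size]))
            for s, e in zip(starts, ends):
                v = vals[s]
                if v == 0:
                    continue
                fh.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")


def write_binned_bedgraph(
    chrom: str, values: np.ndarray, bin_size: int, path: str | Path
) -> None:
    with open(path, "w") as fh:
        for i, v in enumerate(values):
            if np.isfinite(v):
                fh.write(f"{chrom}\t{i * bin_size}\t{(i + 1) * bin_size}\t{v:g}\n")


# ---------------------------------------------------------------------------
# TSV tables


def read_probe_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"probe_id", "chromosome", "position", "log2_ratio"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: probe table missing columns {sorted(missing)}")
    return df


def write_probe_tsv(probes: pd.DataFrame, path: str | Path) -> None:
    probes.to_csv(path, sep="\t", index=False)


def read_ct_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = {"amplicon", "sample", "ct"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: Ct table missing columns {sorted(missing)}")
    return df


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)
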