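"""Genomic data model, coordinate conventions, and plain-text I/O.

All coordinates inside the package are 0-based half-open, the native
convention of BED and bedGraph.  GTF (1-based, fully closed) is converted
on read and write.  Strand is one of ``"+"``, ``"-"`` or ``"."``
(unstranded).

The transcription start site (TSS) of a minus-strand gene is the *highest*
genomic coordinate of its first exon, so "exon 1", "upstream" and
"downstream" always refer to the direction of transcription, never to
genomic left/right.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from gffutils.feature import feature_from_line

logger = logging.getLogger(__name__)

STRANDS = ("+", "-", ".")


class GtfParseError(ValueError):
    """Raised for a malformed GTF line; the message carries the line number."""


class BedGraphError(ValueError):
    """Raised for invalid bedGraph input (e.g. overlapping intervals)."""


class NoGeneBodyError(ValueError):
    """Raised when a gene-body definition is undefined (single-exon gene)."""


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic interval ``[start, end)`` on ``chrom``."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}): need 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def __len__(self) -> int:
        return self.length

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end


@dataclass(frozen=True)
class GeneModel:
    """A gene as an ordered exon chain.

    ``exons`` are stored in transcription order: exon 1 is the 5'-most exon
    in the direction of transcription, i.e. the genomically *last* exon for
    a minus-strand gene.
    """

    gene_id: str
    chrom: str
    strand: str
    exons: tuple[GenomicInterval, ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError("gene strand must be '+' or '-'")
        if len(self.exons) < 1:
            raise ValueError(f"gene {self.gene_id}: needs at least one exon")
        for ex in self.exons:
            if ex.chrom != self.chrom:
                raise ValueError(f"gene {self.gene_id}: exon on foreign chrom {ex.chrom}")
        starts = [ex.start for ex in self.exons]
        # transcription order: genomically ascending on '+', descending on '-'
        ordered = starts == sorted(starts) if self.strand == "+" else starts == sorted(starts, reverse=True)
        if not ordered:
            raise ValueError(f"gene {self.gene_id}: exons not in transcription order")
        by_start = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(by_start, by_start[1:]):
            if b.start < a.end:
                raise ValueError(f"gene {self.gene_id}: overlapping exons {a} / {b}")

    @classmethod
    def from_genomic_exons(
        cls,
        gene_id: str,
        chrom: str,
        strand: str,
        exon_bounds: Iterable[tuple[int, int]],
    ) -> "GeneModel":
        """Build a gene from (start, end) pairs in any order."""
        ivs = sorted(
            (GenomicInterval(chrom, s, e, strand) for s, e in exon_bounds),
            key=lambda iv: iv.start,
            reverse=(strand == "-"),
        )
        return cls(gene_id, chrom, strand, tuple(ivs))

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def tss(self) -> int:
        """First transcribed base (genomic coordinate)."""
        first = self.exons[0]
        return first.start if self.strand == "+" else first.end - 1

    @property
    def tes(self) -> int:
        """Last transcribed base (genomic coordinate)."""
        last = self.exons[-1]
        return last.end - 1 if self.strand == "+" else last.start

    @property
    def span(self) -> GenomicInterval:
        """Full transcript span, TSS through TES, as a genomic interval."""
        lo = min(ex.start for ex in self.exons)
        hi = max(ex.end for ex in self.exons)
        return GenomicInterval(self.chrom, lo, hi, self.strand)


def gene_body(gene: GeneModel, definition: str = "exon2_to_tes") -> GenomicInterval:
    """Return the gene-body interval under the chosen definition.

    ``exon2_to_tes`` spans from the transcription-order start of exon 2
    through the TES; it never contains a base of exon 1 and treats exon 1
    as the canonical-initiation zone.  ``tss_to_tes`` is the full
    transcript span (used for metagene display).
    """
    if definition == "tss_to_tes":
        return gene.span
    if definition != "exon2_to_tes":
        raise ValueError(f"unknown gene-body definition {definition!r}")
    if gene.n_exons < 2:
        raise NoGeneBodyError(f"gene {gene.gene_id}: single exon, no exon2_to_tes body")
    exon2 = gene.exons[1]
    if gene.strand == "+":
        return GenomicInterval(gene.chrom, exon2.start, gene.tes + 1, "+")
    return GenomicInterval(gene.chrom, gene.tes, exon2.end, "-")


def promoter(gene: GeneModel, flank: int = 5000) -> GenomicInterval:
    """Promoter window: TSS +/- ``flank`` bases (2*flank+1 wide), left-clipped at 0."""
    if flank <= 0:
        raise ValueError("flank must be positive")
    start = max(0, gene.tss - flank)
    return GenomicInterval(gene.chrom, start, gene.tss + flank + 1, gene.strand)


class SignalTrack:
    """Dense per-base numeric signal, one array per chromosome.

    Raw coverage and tag tracks are non-negative; arrays of any numeric
    dtype are accepted and kept as-is (simulators store integer counts,
    normalized tracks are float).
    """

    def __init__(self, data: dict[str, np.ndarray] | None = None,
                 name: str | None = None, strand: str | None = None):
        self.data: dict[str, np.ndarray] = {}
        self.name = name
        self.strand = strand
        for chrom, values in (data or {}).items():
            arr = np.asarray(values)
            if arr.ndim != 1:
                raise ValueError(f"{chrom}: track values must be 1-D")
            if arr.size and not np.all(np.isfinite(arr.astype(float, copy=False))):
                raise ValueError(f"{chrom}: track values must be finite")
            self.data[chrom] = arr

    @property
    def chroms(self) -> list[str]:
        return sorted(self.data)

    def get(self, chrom: str) -> np.ndarray:
        return self.data.get(chrom, np.zeros(0))

    @property
    def total_mass(self) -> float:
        return float(sum(arr.sum() for arr in self.data.values()))

    def scaled(self, factor: float) -> "SignalTrack":
        return SignalTrack(
            {c: arr.astype(float) * factor for c, arr in self.data.items()},
            name=self.name, strand=self.strand,
        )

    def allclose(self, other: "SignalTrack", rtol: float = 0.0, atol: float = 0.0) -> bool:
        """Equality up to trailing zero runs (which bedGraph round trips drop)."""
        for chrom in set(self.chroms) | set(other.chroms):
            a, b = self.get(chrom).astype(float), other.get(chrom).astype(float)
            n = max(a.size, b.size)
            a = np.pad(a, (0, n - a.size))
            b = np.pad(b, (0, n - b.size))
            if not np.allclose(a, b, rtol=rtol, atol=atol):
                return False
        return True


def read_bedgraph(path: str | Path, name: str | None = None) -> SignalTrack:
    """Read a bedGraph file into a dense :class:`SignalTrack`.

    Intervals must be 0-based half-open and non-overlapping per chromosome;
    an overlap raises :class:`BedGraphError` naming the first offending pair.
    Comment/track lines are skipped; an empty file yields an empty track.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 4:
                raise BedGraphError(f"{path}:{lineno}: expected 4 columns, got {len(parts)}")
            try:
                rows.append((parts[0], int(parts[1]), int(parts[2]), float(parts[3])))
            except ValueError as exc:
                raise BedGraphError(f"{path}:{lineno}: {exc}") from exc
    if not rows:
        return SignalTrack({}, name=name)
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])
    data: dict[str, np.ndarray] = {}
    for chrom, sub in df.groupby("chrom", sort=True):
        sub = sub.sort_values("start")
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        bad = np.flatnonzero(starts[1:] < ends[:-1])
        if bad.size:
            i = bad[0]
            raise BedGraphError(
                f"{path}: overlapping intervals on {chrom}: "
                f"[{starts[i]},{ends[i]}) and [{starts[i + 1]},{ends[i + 1]})"
            )
        arr = np.zeros(int(ends.max()))
        for s, e, v in zip(starts, ends, sub["value"].to_numpy()):
            arr[s:e] = v
        data[chrom] = arr
    return SignalTrack(data, name=name)


def write_bedgraph(track: SignalTrack, path: str | Path, header: str | None = None) -> None:
    """Write a track as bedGraph, run-length encoding constant stretches.

    Zero-valued runs are omitted, so a read-back is identical up to
    trailing zeros (see :meth:`SignalTrack.allclose`).
    """
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        for chrom in track.chroms:
            arr = np.asarray(track.get(chrom), dtype=float)
            if arr.size == 0:
                continue
            breaks = np.flatnonzero(np.diff(arr)) + 1
            starts = np.concatenate(([0], breaks))
            ends = np.concatenate((breaks, [arr.size]))
            for s, e in zip(starts, ends):
                v = arr[s]
                if v == 0:
                    continue
                out = int(v) if v == int(v) else repr(float(v))
                fh.write(f"{chrom}\t{s}\t{e}\t{out}\n")


def read_gtf(path: str | Path) -> list[GeneModel]:
    """Read gene models from GTF (1-based inclusive -> 0-based half-open).

    Exons are grouped per ``gene_id`` and ordered in transcription
    direction.  A malformed line raises :class:`GtfParseError` with its
    line number; a gene that appears only on non-exon features is skipped
    with a warning.
    """
    exons: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, tuple[str, str]] = {}
    seen: dict[str, None] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            try:
                feat = feature_from_line(line)
            except Exception as exc:
                raise GtfParseError(f"{path}:{lineno}: malformed GTF line ({exc})") from exc
            gid = (feat.attributes.get("gene_id") or [None])[0]
            if gid is None:
                raise GtfParseError(f"{path}:{lineno}: feature without gene_id attribute")
            seen.setdefault(gid)
            if feat.featuretype != "exon":
                continue
            if feat.strand not in ("+", "-"):
                raise GtfParseError(f"{path}:{lineno}: exon without strand")
            meta.setdefault(gid, (feat.seqid, feat.strand))
            exons.setdefault(gid, []).append((feat.start - 1, feat.end))
    genes = []
    for gid in seen:
        if gid not in exons:
            logger.warning("gene %s has no exon features; skipped", gid)
            continue
        chrom, strand = meta[gid]
        genes.append(GeneModel.from_genomic_exons(gid, chrom, strand, exons[gid]))
    return genes


def write_gtf(genes: Sequence[GeneModel], path: str | Path, header: str | None = None) -> None:
    """Write exon features in GTF (converting back to 1-based inclusive)."""
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        for gene in genes:
            for iv in sorted(gene.exons, key=lambda e: e.start):
                attrs = f'gene_id "{gene.gene_id}"; transcript_id "{gene.gene_id}.t1";'
                fh.write(
                    f"{gene.chrom}\tspurcatch\texon\t{iv.start + 1}\t{iv.end}\t.\t"
                    f"{gene.strand}\t.\t{attrs}\n"
                )


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path: str | Path, description: str = "") -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description=description)
        for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


BED6_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def read_bed6(path: str | Path) -> pd.DataFrame:
    """Read BED6 into a DataFrame (score column carries tag counts for CTSS files)."""
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None, names=BED6_COLUMNS,
        dtype={"chrom": str, "start": int, "end": int, "name": str, "strand": str},
    )
    if df["strand"].isna().any() or not df["strand"].isin(["+", "-"]).all():
        raise ValueError(f"{path}: every BED6 record must carry strand '+' or '-'")
    return df


def write_bed6(df: pd.DataFrame, path: str | Path, header: str | None = None) -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        df.to_csv(fh, sep="\t", header=False, index=False, columns=BED6_COLUMNS)


@dataclass
class PipelineParams:
    """All tunable thresholds of the detection pipeline.

    min_exons
        Minimum exon count for the exon-ratio analysis; the default 5 keeps
        genes with more than four exons.
    log2_ratio_min
        Strict lower bound on the mean log2(intermediate/first exon RPKM)
        for an exon-ratio call.
    ctss_min_tags
        Exclusive raw-tag threshold for a called CTSS (tags > 8 survive).
    ctss_fold
        Knockout/control fold threshold on intragenic CTSS signal
        (tags-per-million sums, pseudocounted).
    window_nt
        Window length for ChIP input subtraction.
    promoter_flank
        Promoter half-width around the TSS, in bases.
    motif_flank
        Half-width of the sequence window centred on a cryptic CTSS.
    polii_fc_min
        Strict lower bound on gene-body Pol II pSer5 log2(KO/Ctrl) for
        "enhanced intragenic entry"; 0 is the weakest reading.
    rpkm_pseudocount, track_pseudocount, ctss_tpm_pseudocount
        Additive regularisers for the exon-ratio, track log-ratio and CTSS
        fold statistics respectively.
    include_last_exon
        Whether the last exon counts as "intermediate" in the exon ratio.
    pooled_intermediate
        Pool intermediate-exon counts before RPKM instead of averaging
        per-exon RPKMs.
    """

    min_exons: int = 5
    log2_ratio_min: float = 1.0
    ctss_min_tags: int = 8
    ctss_fold: float = 1.3
    window_nt: int = 50
    promoter_flank: int = 5000
    motif_flank: int = 50
    polii_fc_min: float = 0.0
    rpkm_pseudocount: float = 0.1
    track_pseudocount: float = 1.0
    ctss_tpm_pseudocount: float = 1.0
    include_last_exon: bool = False
    pooled_intermediate: bool = False
    ctss_intragenic_exons_only: bool = False

    def __post_init__(self) -> None:
        if self.min_exons < 2:
            raise ValueError("min_exons must be >= 2")
        positives = (
            "log2_ratio_min", "ctss_min_tags", "ctss_fold", "window_nt",
            "promoter_flank", "motif_flank", "rpkm_pseudocount",
            "track_pseudocount", "ctss_tpm_pseudocount",
        )
        for name in positives:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.polii_fc_min < 0:
            raise ValueError("polii_fc_min must be >= 0")
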