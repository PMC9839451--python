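"""Integrated spurious-gene call and CpG/motif window enrichment.

The final call is the conjunction of three evidence streams: the
exon-ratio filter (RNA-seq), KO-specific sense-strand intragenic CTSSs
(CAGE), and enhanced gene-body Pol II pSer5 entry (ChIP, log2 KO/Ctrl
above a configurable floor).  Sequence windows of +/-50 nt around the
KO-specific start sites are then tested for CpG dinucleotide and
consensus-motif enrichment against matched intragenic background
windows, with permutation p-values.
"""
from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .annotation_io import GeneModel, PipelineParams

logger = logging.getLogger(__name__)

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "[AG]", "Y": "[CT]", "S": "[CG]", "W": "[AT]",
    "K": "[GT]", "M": "[AC]", "B": "[CGT]", "D": "[AGT]",
    "H": "[ACT]", "V": "[ACG]", "N": "[ACGT]",
}


@dataclass
class MotifWindowSet:
    """Equal-length sense-oriented sequence windows with their origins."""

    sequences: list[str]
    positions: list[tuple[str, int, str]]
    role: str = "foreground"

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise ValueError(f"windows of mixed lengths {sorted(lengths)}")

    def __len__(self) -> int:
        return len(self.sequences)


def call_spurious_genes(
    exon_set: set[str],
    ctss_set: set[str],
    polii_fc: dict[str, float],
    params: PipelineParams | None = None,
) -> tuple[pd.DataFrame, dict[str, int], float]:
    """Combine the three evidence streams into the final gene call.

    Returns a per-gene table over the union of evidence, the sizes of the
    seven exclusive Venn regions, and the fraction of the CTSS set that
    passes all three filters (0 with a warning if the CTSS set is empty).
    """
    params = params or PipelineParams()
    polii_set = {g for g, v in polii_fc.items() if v > params.polii_fc_min}
    universe = sorted(exon_set | ctss_set | polii_set)
    rows = []
    for g in universe:
        e, c, p = g in exon_set, g in ctss_set, g in polii_set
        rows.append(
            {
                "gene_id": g,
                "exon_ratio_pass": e,
                "ctss_pass": c,
                "polii_pass": p,
                "polii_log2fc": polii_fc.get(g, np.nan),
                "final": e and c and p,
            }
        )
    table = pd.DataFrame(
        rows, columns=["gene_id", "exon_ratio_pass", "ctss_pass", "polii_pass",
                       "polii_log2fc", "final"]
    )
    venn = {
        "exon_only": len(exon_set - ctss_set - polii_set),
        "ctss_only": len(ctss_set - exon_set - polii_set),
        "polii_only": len(polii_set - exon_set - ctss_set),
        "exon_ctss": len((exon_set & ctss_set) - polii_set),
        "exon_polii": len((exon_set & polii_set) - ctss_set),
        "ctss_polii": len((ctss_set & polii_set) - exon_set),
        "all_three": len(exon_set & ctss_set & polii_set),
    }
    if ctss_set:
        fraction = venn["all_three"] / len(ctss_set)
    else:
        logger.warning("empty CTSS gene set; integrated fraction reported as 0")
        fraction = 0.0
    return table, venn, fraction


def extract_ctss_windows(
    genome: dict[str, str],
    positions: list[tuple[str, int, str]],
    flank: int = 50,
) -> MotifWindowSet:
    """Sequence windows of 2*flank+1 nt centred on each start site.

    Minus-strand windows are reverse-complemented so index ``flank`` is
    always the initiating base read in the sense direction.  Positions
    whose window does not fit the contig are skipped with a warning.
    """
    seqs, kept, skipped = [], [], 0
    for chrom, pos, strand in positions:
        contig = genome.get(chrom)
        if contig is None or pos - flank < 0 or pos + flank + 1 > len(contig):
            skipped += 1
            continue
        window = contig[pos - flank:pos + flank + 1]
        if strand == "-":
            window = str(Seq(window).reverse_complement())
        seqs.append(window.upper())
        kept.append((chrom, pos, strand))
    if skipped:
        logger.warning("%d windows skipped at contig boundaries", skipped)
    return MotifWindowSet(seqs, kept, role="foreground")


def sample_background_windows(
    genes: list[GeneModel],
    genome: dict[str, str],
    n: int,
    seed: int,
    excluded: set[tuple[str, int, str]] | None = None,
    flank: int = 50,
) -> MotifWindowSet:
    """Uniform sense-strand intragenic background positions (exon 1 excluded).

    Positions are drawn uniformly over the intragenic bases of ``genes``
    whose window fits the contig, avoiding ``excluded`` positions;
    sampling is deterministic for a fixed seed.
    """
    if n <= 0:
        raise ValueError("background size n must be >= 1")
    excluded = excluded or set()
    spans: list[tuple[str, int, int, str]] = []   # chrom, start, end, strand
    for gene in genes:
        if gene.n_exons < 2:
            continue
        contig = genome.get(gene.chrom)
        if contig is None:
            continue
        span, exon1 = gene.span, gene.exons[0]
        # intragenic = transcript span minus exon 1 -> at most two sub-spans
        pieces = [(span.start, exon1.start), (exon1.end, span.end)]
        for lo, hi in pieces:
            lo = max(lo, flank)
            hi = min(hi, len(contig) - flank)
            if hi > lo:
                spans.append((gene.chrom, lo, hi, gene.strand))
    total = sum(hi - lo for _, lo, hi, _ in spans)
    if total < n:
        raise ValueError(f"insufficient eligible intragenic space ({total} < {n})")
    cumlens = np.cumsum([hi - lo for _, lo, hi, _ in spans])
    rng = np.random.default_rng(seed)
    chosen: list[tuple[str, int, str]] = []
    seen: set[tuple[str, int, str]] = set()
    for _ in range(1000):
        if len(chosen) >= n:
            break
        draws = rng.integers(0, total, size=max(n - len(chosen), 16))
        for d in draws:
            si = int(np.searchsorted(cumlens, d, side="right"))
            chrom, lo, _hi, strand = spans[si]
            offset = int(d) - (int(cumlens[si - 1]) if si else 0)
            key = (chrom, lo + offset, strand)
            if key in excluded or key in seen:
                continue
            seen.add(key)
            chosen.append(key)
            if len(chosen) == n:
                break
    if len(chosen) < n:
        raise ValueError("could not collect enough background positions")
    ws = extract_ctss_windows(genome, chosen, flank=flank)
    return MotifWindowSet(ws.sequences, ws.positions, role="background")


def _count_overlapping(seq: str, pattern: str) -> int:
    return len(re.findall(f"(?={re.escape(pattern)})", seq))


def cpg_count(seq: str) -> int:
    """Number of CG dinucleotides in a window."""
    return _count_overlapping(seq.upper(), "CG")


def _permutation_p(
    fg_vals: np.ndarray,
    bg_vals: np.ndarray,
    n_perm: int,
    seed: int,
) -> float:
    """Two-sided label-permutation p for the difference of means, with the
    +1 correction (p >= 1/(n_perm+1))."""
    rng = np.random.default_rng(seed)
    pooled = np.concatenate([fg_vals, bg_vals]).astype(float)
    n_fg = fg_vals.size
    obs = abs(fg_vals.mean() - bg_vals.mean())
    perms = rng.permuted(np.broadcast_to(pooled, (n_perm, pooled.size)).copy(), axis=1)
    stat = np.abs(perms[:, :n_fg].mean(axis=1) - perms[:, n_fg:].mean(axis=1))
    return float((1 + np.sum(stat >= obs - 1e-12)) / (n_perm + 1))


@dataclass
class EnrichmentResult:
    fold: float
    p_value: float
    fg_mean: float
    bg_mean: float


def cpg_enrichment(
    fg: MotifWindowSet,
    bg: MotifWindowSet,
    n_perm: int = 999,
    seed: int = 0,
) -> EnrichmentResult:
    """CpG-dinucleotide enrichment of foreground over background windows.

    Fold is the ratio of mean per-window CG counts (infinite if the
    background mean is zero); significance is a two-sided permutation
    test on the pooled windows.
    """
    if not len(fg) or not len(bg):
        raise ValueError("both window sets must be non-empty")
    fg_counts = np.array([cpg_count(s) for s in fg.sequences], dtype=float)
    bg_counts = np.array([cpg_count(s) for s in bg.sequences], dtype=float)
    if bg_counts.mean() == 0:
        logger.warning("background CpG mean is 0; fold reported as inf")
        fold = float("inf") if fg_counts.mean() > 0 else 1.0
    else:
        fold = float(fg_counts.mean() / bg_counts.mean())
    p = _permutation_p(fg_counts, bg_counts, n_perm, seed)
    return EnrichmentResult(fold, p, float(fg_counts.mean()), float(bg_counts.mean()))


def iupac_regex(motif: str) -> re.Pattern:
    try:
        return re.compile("".join(IUPAC[ch] for ch in motif.upper()))
    except KeyError as exc:
        raise ValueError(f"invalid IUPAC character {exc.args[0]!r} in motif {motif!r}") from exc


def motif_scan(
    fg: MotifWindowSet,
    bg: MotifWindowSet,
    motifs: list[str],
    n_perm: int = 999,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-motif hit counts, fold enrichment and permutation p-values.

    A window "hits" a motif when the IUPAC consensus matches anywhere on
    the sense orientation.  Fold is the ratio of hit rates (0 when no
    foreground window hits; infinite when only the background is empty
    of hits).
    """
    if not len(fg) or not len(bg):
        raise ValueError("both window sets must be non-empty")
    rows = []
    for mi, motif in enumerate(motifs):
        pat = iupac_regex(motif)
        fg_hits = np.array([bool(pat.search(s)) for s in fg.sequences], dtype=float)
        bg_hits = np.array([bool(pat.search(s)) for s in bg.sequences], dtype=float)
        fg_rate, bg_rate = fg_hits.mean(), bg_hits.mean()
        if fg_rate == 0:
            fold = 0.0
        elif bg_rate == 0:
            fold = float("inf")
        else:
            fold = float(fg_rate / bg_rate)
        p = _permutation_p(fg_hits, bg_hits, n_perm, seed + mi)
        rows.append(
            {
                "motif": motif,
                "fg_hits": int(fg_hits.sum()),
                "bg_hits": int(bg_hits.sum()),
                "fg_rate": float(fg_rate),
                "bg_rate": float(bg_rate),
                "fold": fold,
                "p_value": p,
            }
        )
    return pd.DataFrame(rows)
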