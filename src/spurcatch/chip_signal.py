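"""ChIP background correction, region scoring, grouping and metagenes.

Background correction follows the windowed input-subtraction scheme:
treatment and input tracks are normalised for sequencing depth
(per-million scaling), each chromosome is partitioned into consecutive
windows of fixed length (50 nt by default, anchored at coordinate 0),
and the input window sum is subtracted from the treatment window sum
with negative windows clamped to zero.  Corrected values are stored per
base as the window value divided by the window length, so region scores
integrate naturally.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotation_io import (
    GeneModel,
    GenomicInterval,
    NoGeneBodyError,
    SignalTrack,
    gene_body,
)

logger = logging.getLogger(__name__)


class CorrectedTrack(SignalTrack):
    """Input-subtracted, depth-normalised signal (non-negative by construction)."""

    def __init__(self, data, window_nt: int, treatment: str | None = None,
                 input_name: str | None = None, name: str | None = None):
        super().__init__(data, name=name)
        self.window_nt = window_nt
        self.treatment = treatment
        self.input_name = input_name


def depth_normalize(track: SignalTrack) -> SignalTrack:
    """Scale a track to per-million units (values * 1e6 / total_mass)."""
    mass = track.total_mass
    if mass <= 0:
        raise ValueError("cannot depth-normalize a track with zero total mass")
    return track.scaled(1e6 / mass)


def size_factors(counts: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Median-of-ratios size factors (regions x samples).

    For each region with an all-positive geometric mean across samples,
    compute count/geomean; the per-sample factor is the median of those
    ratios, taken on the log scale exactly as DESeq2 does.  Factors are
    reported unscaled.
    """
    arr = np.asarray(counts, dtype=float)
    if arr.ndim != 2 or arr.shape[1] < 2:
        raise ValueError("need a 2-D regions x samples matrix with >= 2 samples")
    with np.errstate(divide="ignore"):
        logs = np.log(arr)
    usable = np.all(np.isfinite(logs), axis=1)
    if not usable.any():
        raise ValueError("no region has nonzero counts in all samples")
    log_geomean = logs[usable].mean(axis=1, keepdims=True)
    # DESeq2 takes the median on the log scale (matters for even region counts)
    return np.exp(np.median(logs[usable] - log_geomean, axis=0))


def input_subtract(
    treatment: SignalTrack,
    input_track: SignalTrack,
    window: int = 50,
) -> CorrectedTrack:
    """Windowed input subtraction with zero clamping.

    Both tracks must already be depth-normalised.  Chromosomes are split
    into consecutive ``window``-nt windows (the last may be shorter); the
    window value is max(sum(treatment) - sum(input), 0) and is spread
    uniformly over the window's bases.  A treatment chromosome missing
    from the input is corrected against zero input, with a warning.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    missing = set(treatment.chroms) - set(input_track.chroms)
    if missing:
        logger.warning("chromosomes without input (treated as zero): %s", sorted(missing))
    data = {}
    for chrom in treatment.chroms:
        t = np.asarray(treatment.get(chrom), dtype=float)
        i = np.asarray(input_track.get(chrom), dtype=float)
        n = max(t.size, i.size)
        if n == 0:
            data[chrom] = np.zeros(0)
            continue
        t = np.pad(t, (0, n - t.size))
        i = np.pad(i, (0, n - i.size))
        edges = np.arange(0, n, window)
        win_val = np.maximum(np.add.reduceat(t, edges) - np.add.reduceat(i, edges), 0.0)
        win_len = np.diff(np.append(edges, n))
        data[chrom] = np.repeat(win_val / win_len, win_len)
    return CorrectedTrack(data, window_nt=window, treatment=treatment.name,
                          input_name=input_track.name)


def region_score(
    track: SignalTrack,
    region: GenomicInterval,
    mode: str = "mean0",
) -> float:
    """Average (or total) per-base signal over a region.

    ``mean0`` counts bases without coverage data as zero (the mean0
    semantics of BigWigAverageOverBed); ``sum`` returns the raw total.
    A region on an unknown chromosome scores 0 with a warning.
    """
    if mode not in ("mean0", "sum"):
        raise ValueError(f"unknown mode {mode!r}")
    arr = track.get(region.chrom)
    if arr.size == 0 and region.chrom not in track.data:
        logger.warning("region on unknown chromosome %s scores 0", region.chrom)
    total = float(np.sum(arr[region.start:min(region.end, arr.size)])) \
        if region.start < arr.size else 0.0
    return total if mode == "sum" else total / region.length


def gene_body_log2fc(
    ko: SignalTrack,
    ctrl: SignalTrack,
    genes: list[GeneModel],
    pseudocount: float = 1.0,
    definition: str = "exon2_to_tes",
) -> dict[str, float]:
    """Per-gene log2((KO body score + c) / (Ctrl body score + c)).

    Genes without a body under ``definition`` are omitted with a warning.
    """
    if isinstance(ko, CorrectedTrack) and isinstance(ctrl, CorrectedTrack):
        if ko.window_nt != ctrl.window_nt:
            raise ValueError("tracks corrected with different window sizes")
    out: dict[str, float] = {}
    skipped = 0
    for gene in genes:
        try:
            body = gene_body(gene, definition)
        except NoGeneBodyError:
            skipped += 1
            continue
        s_ko = region_score(ko, body)
        s_ctrl = region_score(ctrl, body)
        out[gene.gene_id] = float(np.log2((s_ko + pseudocount) / (s_ctrl + pseudocount)))
    if skipped:
        logger.warning("%d genes without a gene body were omitted", skipped)
    return out


@dataclass
class GroupAssignment:
    """Gene-to-group labels for a quartile or quintile scheme."""

    scheme: str
    labels: dict[str, str]
    bottom_flagged: frozenset[str] = frozenset()

    def members(self, label: str) -> set[str]:
        return {g for g, l in self.labels.items() if l == label}

    @property
    def group_sizes(self) -> dict[str, int]:
        sizes: dict[str, int] = {}
        for l in self.labels.values():
            sizes[l] = sizes.get(l, 0) + 1
        return sizes


def _ranked_split(values: dict[str, float], group_labels: list[str]) -> dict[str, str]:
    """Sort genes descending by value (ties by gene id) and split into
    contiguous groups whose sizes differ by at most one, remainder going
    to the top groups."""
    k = len(group_labels)
    ordered = sorted(values, key=lambda g: (-values[g], g))
    n = len(ordered)
    base, rem = divmod(n, k)
    labels: dict[str, str] = {}
    start = 0
    for gi, glabel in enumerate(group_labels):
        size = base + (1 if gi < rem else 0)
        for g in ordered[start:start + size]:
            labels[g] = glabel
        start += size
    return labels


def assign_quartiles(values: dict[str, float]) -> GroupAssignment:
    """Quartiles a (highest values) .. d (lowest); requires >= 4 genes."""
    if len(values) < 4:
        raise ValueError("need at least 4 genes for quartiles")
    return GroupAssignment("quartile", _ranked_split(values, ["a", "b", "c", "d"]))


def assign_expression_quintiles(
    expression: dict[str, float],
    bottom_pct: float = 5.0,
) -> GroupAssignment:
    """Expression quintiles 1 (highest) .. 5 (lowest), plus a bottom-X% flag.

    The flag marks the ``round(n * bottom_pct / 100)`` lowest-expressed
    genes; for n >= 20 with the default 5% these are a subset of
    quintile 5.
    """
    if len(expression) < 5:
        raise ValueError("need at least 5 genes for quintiles")
    labels = _ranked_split(expression, ["1", "2", "3", "4", "5"])
    n_flag = int(round(len(expression) * bottom_pct / 100.0))
    ordered = sorted(expression, key=lambda g: (-expression[g], g))
    flagged = frozenset(ordered[len(ordered) - n_flag:]) if n_flag else frozenset()
    return GroupAssignment("quintile", labels, bottom_flagged=flagged)


@dataclass
class MetageneProfile:
    """Per-gene and mean signal over [upstream flank | scaled body | downstream flank]."""

    gene_ids: list[str]
    matrix: np.ndarray          # genes x bins
    mean: np.ndarray            # bins
    flank_bins: int
    body_bins: int
    flank_bin_width: int

    @property
    def n_bins(self) -> int:
        return 2 * self.flank_bins + self.body_bins


def metagene_profile(
    track: SignalTrack,
    genes: list[GeneModel],
    body_bins: int = 100,
    flank: int = 2000,
    flank_bin: int = 50,
) -> MetageneProfile:
    """Average signal profile across genes with length-normalised bodies.

    Each gene body (TSS to TES) is rescaled to ``body_bins`` bins of mean
    signal; flanks use fixed ``flank_bin``-bp bins.  Minus-strand genes
    are reversed so every profile runs 5' to 3'; flank bases beyond
    chromosome ends count as zero.  Genes shorter than ``body_bins`` are
    skipped with a warning.
    """
    if flank % flank_bin != 0:
        raise ValueError("flank must be a multiple of flank_bin")
    n_fb = flank // flank_bin
    rows, ids, skipped = [], [], 0
    for gene in genes:
        span = gene.span
        L = span.length
        if L < body_bins:
            skipped += 1
            continue
        arr = track.get(gene.chrom)
        gs, ge = span.start - flank, span.end + flank
        window = np.zeros(ge - gs)
        lo, hi = max(gs, 0), min(ge, arr.size)
        if hi > lo:
            window[lo - gs:hi - gs] = arr[lo:hi]
        if gene.strand == "-":
            window = window[::-1]
        upstream = window[:flank].reshape(n_fb, flank_bin).mean(axis=1)
        downstream = window[flank + L:].reshape(n_fb, flank_bin).mean(axis=1)
        body = window[flank:flank + L]
        edges = np.floor(np.linspace(0, L, body_bins + 1)).astype(int)
        sums = np.add.reduceat(body, edges[:-1])
        body_means = sums / np.diff(edges)
        rows.append(np.concatenate([upstream, body_means, downstream]))
        ids.append(gene.gene_id)
    if skipped:
        logger.warning("%d genes shorter than %d bases were skipped", skipped, body_bins)
    if not rows:
        raise ValueError("no gene was long enough for the requested body bins")
    matrix = np.vstack(rows)
    return MetageneProfile(ids, matrix, matrix.mean(axis=0), n_fb, body_bins, flank_bin)
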