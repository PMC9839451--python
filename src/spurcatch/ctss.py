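"""CAGE tag start sites (CTSSs): collapsing, thresholding and gene calls.

A CAGE read marks the 5' base of a capped transcript; collapsing reads to
single-base tag counts gives CTSSs.  Sites with more than ``ctss_min_tags``
raw tags (default 8, the genome-wide average per-base tag count at
annotated TSSs) count as real initiation events.  Intragenic initiation
for a gene is the sense-strand tag signal inside the transcript span with
every base of exon 1 excluded; introns are included because initiation is
a genomic, not an exonic, event.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation_io import GeneModel, PipelineParams, read_bed6

logger = logging.getLogger(__name__)

CTSS_COLUMNS = ["chrom", "pos", "strand", "tags"]


class NoIntragenicRegionError(ValueError):
    """A single-exon gene has no intragenic region after excluding exon 1."""


@dataclass(eq=False)
class CTSSSet:
    """Single-base stranded tag counts for one sample.

    ``records`` has columns ``chrom``, ``pos`` (0-based), ``strand``,
    ``tags`` with one row per (chrom, pos, strand).  ``total_tags``
    defaults to the sum of tags (the number of sequenced reads) and is
    preserved as the normalisation denominator when a set is thresholded.
    """

    sample: str
    condition: str
    records: pd.DataFrame
    total_tags: int | None = None
    _index: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        df = self.records
        if list(df.columns) != CTSS_COLUMNS:
            df = df[CTSS_COLUMNS]
        if len(df) and (df["tags"] < 1).any():
            raise ValueError("tag counts must be >= 1")
        if df.duplicated(["chrom", "pos", "strand"]).any():
            raise ValueError("duplicate (chrom, pos, strand) keys")
        self.records = df.sort_values(["chrom", "strand", "pos"]).reset_index(drop=True)
        if self.total_tags is None:
            self.total_tags = int(self.records["tags"].sum())
        for (chrom, strand), sub in self.records.groupby(["chrom", "strand"], sort=False):
            self._index[(chrom, strand)] = (
                sub["pos"].to_numpy(dtype=np.int64),
                sub["tags"].to_numpy(dtype=np.int64),
            )

    def __len__(self) -> int:
        return len(self.records)

    @property
    def chroms(self) -> set[str]:
        return set(self.records["chrom"].unique())

    def tpm(self, tags) -> np.ndarray | float:
        """Tags per million total tags of this sample."""
        if not self.total_tags:
            return np.zeros_like(np.asarray(tags, dtype=float))
        out = np.asarray(tags, dtype=float) * 1e6 / self.total_tags
        return float(out) if out.ndim == 0 else out

    def lookup(self, chrom: str, strand: str) -> tuple[np.ndarray, np.ndarray]:
        return self._index.get((chrom, strand), (np.zeros(0, np.int64), np.zeros(0, np.int64)))

    def tags_at(self, chrom: str, pos: int, strand: str) -> int:
        pos_arr, tag_arr = self.lookup(chrom, strand)
        i = np.searchsorted(pos_arr, pos)
        if i < pos_arr.size and pos_arr[i] == pos:
            return int(tag_arr[i])
        return 0

    def to_bed6(self) -> pd.DataFrame:
        df = self.records
        return pd.DataFrame(
            {
                "chrom": df["chrom"],
                "start": df["pos"],
                "end": df["pos"] + 1,
                "name": "ctss",
                "score": df["tags"],
                "strand": df["strand"],
            }
        )

    @classmethod
    def from_bed(cls, path: str | Path, sample: str, condition: str,
                 collapsed: bool = True) -> "CTSSSet":
        """Load from BED6: pre-collapsed per-base tags (score = count) or
        read-level records (one row per read, collapsed here)."""
        df = read_bed6(path)
        if collapsed:
            if ((df["end"] - df["start"]) != 1).any():
                raise ValueError(f"{path}: collapsed CTSS records must be single-base")
            rec = pd.DataFrame(
                {"chrom": df["chrom"], "pos": df["start"],
                 "strand": df["strand"], "tags": df["score"].astype(int)}
            )
            rec = rec.groupby(["chrom", "pos", "strand"], as_index=False)["tags"].sum()
            return cls(sample=sample, condition=condition, records=rec)
        return collapse_five_prime(df, sample=sample, condition=condition)


def collapse_five_prime(reads: pd.DataFrame, sample: str, condition: str = "") -> CTSSSet:
    """Collapse read-level BED6 intervals to single-base CTSS counts.

    Each read contributes one tag at its 5' base: ``start`` on the plus
    strand, ``end - 1`` on the minus strand.  ``total_tags`` equals the
    number of input reads.
    """
    if len(reads) == 0:
        empty = pd.DataFrame(columns=CTSS_COLUMNS).astype(
            {"pos": int, "tags": int, "chrom": str, "strand": str})
        return CTSSSet(sample=sample, condition=condition, records=empty, total_tags=0)
    if not reads["strand"].isin(["+", "-"]).all():
        raise ValueError("every read must carry strand '+' or '-'")
    pos = np.where(reads["strand"] == "+", reads["start"], reads["end"] - 1)
    rec = pd.DataFrame({"chrom": reads["chrom"], "pos": pos, "strand": reads["strand"]})
    rec = rec.groupby(["chrom", "pos", "strand"], as_index=False).size()
    rec = rec.rename(columns={"size": "tags"})
    return CTSSSet(sample=sample, condition=condition, records=rec,
                   total_tags=int(len(reads)))


def threshold_ctss(ctss_set: CTSSSet, min_tags: int = 8) -> CTSSSet:
    """Keep records with tags strictly greater than ``min_tags``.

    The parent set's ``total_tags`` is carried over unchanged so that
    per-million normalisation still refers to the full library.
    """
    if min_tags < 1:
        raise ValueError("min_tags must be >= 1")
    kept = ctss_set.records[ctss_set.records["tags"] > min_tags]
    return CTSSSet(sample=ctss_set.sample, condition=ctss_set.condition,
                   records=kept.reset_index(drop=True), total_tags=ctss_set.total_tags)


def _intragenic_mask(gene: GeneModel, pos: np.ndarray) -> np.ndarray:
    """Boolean mask for positions inside the transcript span minus exon 1."""
    span = gene.span
    exon1 = gene.exons[0]
    mask = (pos >= span.start) & (pos < span.end)
    mask &= ~((pos >= exon1.start) & (pos < exon1.end))
    return mask


def intragenic_sense_signal(
    gene: GeneModel,
    ctss_set: CTSSSet,
    min_tags: int | None = None,
) -> tuple[int, float, list[tuple[int, int]]]:
    """Sense-strand CTSS signal inside the gene, excluding exon 1.

    Returns ``(tag_sum, tpm_sum, positions)`` where ``positions`` is a
    list of (pos, tags) pairs.  ``min_tags`` restricts to records with
    tags strictly above the threshold; ``None`` counts every record.
    Intronic records count — initiation sites are genomic positions.
    """
    if gene.n_exons < 2:
        raise NoIntragenicRegionError(
            f"gene {gene.gene_id}: single exon, no intragenic region")
    pos_arr, tag_arr = ctss_set.lookup(gene.chrom, gene.strand)
    if pos_arr.size == 0:
        return 0, 0.0, []
    span = gene.span
    lo = np.searchsorted(pos_arr, span.start, side="left")
    hi = np.searchsorted(pos_arr, span.end, side="left")
    pos_sel, tag_sel = pos_arr[lo:hi], tag_arr[lo:hi]
    mask = _intragenic_mask(gene, pos_sel)
    if min_tags is not None:
        mask &= tag_sel > min_tags
    pos_sel, tag_sel = pos_sel[mask], tag_sel[mask]
    tag_sum = int(tag_sel.sum())
    tpm_sum = float(np.sum(ctss_set.tpm(tag_sel))) if tag_sel.size else 0.0
    return tag_sum, tpm_sum, list(zip(pos_sel.tolist(), tag_sel.tolist()))


def ko_specific_intragenic_genes(
    ko_sets: list[CTSSSet],
    ctrl_sets: list[CTSSSet],
    genes: list[GeneModel],
    params: PipelineParams | None = None,
) -> tuple[set[str], pd.DataFrame]:
    """Call genes with KO-specific sense-strand intragenic initiation.

    A gene is called iff

    a. some intragenic sense position carries more than ``ctss_min_tags``
       tags in at least one KO sample while staying at or below the
       threshold in *every* control sample (position-level specificity), and
    b. the replicate-mean KO intragenic tags-per-million sum is at least
       ``ctss_fold`` times the control mean, both sides regularised with
       the tpm pseudocount.

    Returns the called gene set and a per-gene table carrying the
    per-sample sums, the fold, and the KO-specific positions.
    """
    params = params or PipelineParams()
    if not ko_sets or not ctrl_sets:
        raise ValueError("need at least one CTSS set per condition")
    set_chroms = set().union(*(s.chroms for s in ko_sets + ctrl_sets))
    gene_chroms = {g.chrom for g in genes}
    if set_chroms and gene_chroms and not (set_chroms & gene_chroms):
        logger.warning("no chromosome overlap between annotation and CTSS sets")
        return set(), pd.DataFrame()

    eps = params.ctss_tpm_pseudocount
    rows = []
    for gene in genes:
        if gene.n_exons < 2:
            continue
        row: dict = {"gene_id": gene.gene_id}
        ko_tpms, ctrl_tpms = [], []
        for cs in ko_sets + ctrl_sets:
            tag_sum, tpm_sum, _ = intragenic_sense_signal(gene, cs)
            row[f"tags_{cs.sample}"] = tag_sum
            row[f"tpm_{cs.sample}"] = tpm_sum
            (ko_tpms if cs in ko_sets else ctrl_tpms).append(tpm_sum)

        specific: set[int] = set()
        for cs in ko_sets:
            _, _, positions = intragenic_sense_signal(gene, cs, min_tags=params.ctss_min_tags)
            for pos, _tags in positions:
                if all(c.tags_at(gene.chrom, pos, gene.strand) <= params.ctss_min_tags
                       for c in ctrl_sets):
                    specific.add(pos)

        mean_ko = float(np.mean(ko_tpms))
        mean_ctrl = float(np.mean(ctrl_tpms))
        fold = (mean_ko + eps) / (mean_ctrl + eps)
        called = bool(specific) and fold >= params.ctss_fold
        row.update(
            mean_tpm_ko=mean_ko, mean_tpm_ctrl=mean_ctrl, fold=fold,
            n_ko_specific=len(specific),
            ko_specific_positions=";".join(str(p) for p in sorted(specific)),
            ko_specific=called,
        )
        rows.append(row)
    table = pd.DataFrame(rows)
    called_set = set(table.loc[table["ko_specific"], "gene_id"]) if len(table) else set()
    return called_set, table
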