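"""Exon-level RPKM and the intermediate/first-exon log2 ratio call.

A gene transcribed only from its canonical promoter has roughly even
exon-level RPKM, so log2(intermediate/first) sits near zero.  Cryptic
initiation inside the gene body inflates intermediate exons relative to
exon 1, pushing the ratio up; genes with more than four exons and a mean
KO log2 ratio strictly above 1 are called by this filter.
"""
from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation_io import PipelineParams

logger = logging.getLogger(__name__)


class TooFewExonsError(ValueError):
    """Signals a gene filtered out by the minimum exon count."""


class ExonCountMatrix:
    """Per-exon raw counts across samples plus per-sample library totals.

    ``counts`` columns: ``gene_id``, ``exon_index`` (1-based, transcription
    order), ``exon_len`` (bp), then one integer column per sample.
    ``samples`` columns: ``sample``, ``condition``, ``total_mapped``.
    """

    def __init__(self, counts: pd.DataFrame, samples: pd.DataFrame):
        required = {"gene_id", "exon_index", "exon_len"}
        if missing := required - set(counts.columns):
            raise ValueError(f"counts table missing columns {sorted(missing)}")
        if missing := {"sample", "condition", "total_mapped"} - set(samples.columns):
            raise ValueError(f"samples table missing columns {sorted(missing)}")
        unknown = set(samples["sample"]) - set(counts.columns)
        if unknown:
            raise ValueError(f"samples absent from counts table: {sorted(unknown)}")
        if (samples["total_mapped"] <= 0).any():
            raise ValueError("total_mapped must be > 0 for every sample")
        for s in samples["sample"]:
            col = counts[s]
            if (col < 0).any():
                raise ValueError(f"negative counts in sample {s}")
        self.counts = counts.reset_index(drop=True)
        self.samples = samples.reset_index(drop=True)

    @property
    def sample_names(self) -> list[str]:
        return list(self.samples["sample"])

    @property
    def conditions(self) -> list[str]:
        return list(dict.fromkeys(self.samples["condition"]))

    def samples_for(self, condition: str) -> list[str]:
        sel = self.samples.loc[self.samples["condition"] == condition, "sample"]
        return list(sel)

    def total_mapped(self, sample: str) -> float:
        row = self.samples.loc[self.samples["sample"] == sample, "total_mapped"]
        return float(row.iloc[0])

    @classmethod
    def from_tsv(cls, counts_path: str | Path, samples_path: str | Path) -> "ExonCountMatrix":
        counts = pd.read_csv(counts_path, sep="\t", comment="#")
        samples = pd.read_csv(samples_path, sep="\t", comment="#")
        return cls(counts, samples)

    def to_tsv(self, counts_path: str | Path, samples_path: str | Path,
               header: str | None = None) -> None:
        for path, df in ((counts_path, self.counts), (samples_path, self.samples)):
            with open(path, "w") as fh:
                if header:
                    fh.write(f"# {header}\n")
                df.to_csv(fh, sep="\t", index=False)


def rpkm(count, exon_len_bp, total_mapped):
    """Reads per kilobase of exon per million mapped reads.

    ``count / ((exon_len_bp / 1e3) * (total_mapped / 1e6))``; accepts
    scalars or arrays.
    """
    exon_len_bp = np.asarray(exon_len_bp, dtype=float)
    total = np.asarray(total_mapped, dtype=float)
    if np.any(exon_len_bp <= 0):
        raise ValueError("exon length must be > 0")
    if np.any(total <= 0):
        raise ValueError("total_mapped must be > 0")
    out = np.asarray(count, dtype=float) / ((exon_len_bp / 1e3) * (total / 1e6))
    return float(out) if out.ndim == 0 else out


def exon_ratio_statistic(
    gene_counts,
    lengths,
    total_mapped: float,
    params: PipelineParams | None = None,
) -> float:
    """log2((mean intermediate-exon RPKM + eps) / (first-exon RPKM + eps)).

    Intermediate exons are exons 2..n-1 in transcription order by default
    (``params.include_last_exon`` adds the last exon); aggregation is the
    unweighted mean of per-exon RPKMs, or pooled counts over pooled
    kilobases when ``params.pooled_intermediate`` is set.

    Raises :class:`TooFewExonsError` for genes below ``params.min_exons``.
    """
    params = params or PipelineParams()
    counts = np.asarray(gene_counts, dtype=float)
    lens = np.asarray(lengths, dtype=float)
    n = counts.size
    if n != lens.size:
        raise ValueError("counts and lengths differ in size")
    if n < params.min_exons:
        raise TooFewExonsError(f"gene has {n} exons, need >= {params.min_exons}")
    stop = n if params.include_last_exon else n - 1
    eps = params.rpkm_pseudocount
    first = rpkm(counts[0], lens[0], total_mapped)
    if params.pooled_intermediate:
        mid = rpkm(counts[1:stop].sum(), lens[1:stop].sum(), total_mapped)
    else:
        mid = float(np.mean(rpkm(counts[1:stop], lens[1:stop], total_mapped)))
    return float(np.log2((mid + eps) / (first + eps)))


def call_spurious_by_exon_ratio(
    matrix: ExonCountMatrix,
    params: PipelineParams | None = None,
    condition: str = "KO",
) -> tuple[set[str], pd.DataFrame]:
    """Apply the exon filter and ratio threshold; return calls plus full table.

    A gene is called iff it has at least ``min_exons`` exons and its
    replicate-mean log2 ratio in ``condition`` exceeds ``log2_ratio_min``
    strictly.  The table reports per-condition first/intermediate RPKM and
    log2 ratio for every gene, with pass/fail flags.
    """
    params = params or PipelineParams()
    if condition not in matrix.conditions:
        raise ValueError(
            f"condition {condition!r} absent; available: {matrix.conditions}"
        )
    eps = params.rpkm_pseudocount
    rows = []
    for gene_id, sub in matrix.counts.groupby("gene_id", sort=True):
        sub = sub.sort_values("exon_index")
        lens = sub["exon_len"].to_numpy(dtype=float)
        n = lens.size
        row: dict = {"gene_id": gene_id, "n_exons": n,
                     "passes_exon_filter": n >= params.min_exons}
        for cond in matrix.conditions:
            firsts, mids, ratios = [], [], []
            for sample in matrix.samples_for(cond):
                counts = sub[sample].to_numpy(dtype=float)
                total = matrix.total_mapped(sample)
                firsts.append(rpkm(counts[0], lens[0], total))
                stop = n if params.include_last_exon else max(n - 1, 1)
                if stop > 1:
                    mids.append(float(np.mean(rpkm(counts[1:stop], lens[1:stop], total))))
                else:
                    mids.append(0.0)
                ratios.append(float(np.log2((mids[-1] + eps) / (firsts[-1] + eps))))
            row[f"rpkm_first_{cond}"] = float(np.mean(firsts))
            row[f"rpkm_intermediate_{cond}"] = float(np.mean(mids))
            row[f"log2_ratio_{cond}"] = float(np.mean(ratios))
        row["called"] = bool(
            row["passes_exon_filter"]
            and row[f"log2_ratio_{condition}"] > params.log2_ratio_min
        )
        rows.append(row)
    table = pd.DataFrame(rows)
    called = set(table.loc[table["called"], "gene_id"])
    return called, table
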