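"""Synthetic genome, annotation, exon counts, CAGE tags and ChIP tracks.

The generator plants a known fraction of "spurious" genes that, in the
knockout (KO) condition only, gain

* intermediate-exon RNA-seq signal (a multiplicative boost of the
  negative-binomial exon means),
* single-base CAGE tag clusters at cryptic intragenic start sites seeded
  with a CpG-containing consensus motif in the genome sequence, and
* Pol II pSer5 ChIP signal in the gene body (secondary initiation peaks
  plus an elevated plateau), while gene-body 5hmC and H3K36me3 drop.

Everything is deterministic for a fixed seed, and the planted truth is
returned as a :class:`TruthTable` so the full detection pipeline can be
scored for precision and recall.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation_io import (
    GeneModel,
    SignalTrack,
    gene_body,
    write_bed6,
    write_bedgraph,
    write_fasta,
    write_gtf,
)
from .ctss import CTSSSet
from .exon_ratio import ExonCountMatrix

logger = logging.getLogger(__name__)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
# i.i.d. base frequencies giving a CpG dinucleotide frequency of
# P(C)*P(G) = 0.1*0.1 = 0.01, the vertebrate-like depletion level.
_BASE_P = np.array([0.4, 0.1, 0.1, 0.4])
_CODE = {b: i for i, b in enumerate("ACGT")}
_COMPLEMENT_CODE = np.array([3, 2, 1, 0])  # A<->T, C<->G in code space


class SimSizeError(ValueError):
    """Raised when the requested gene geometry cannot fit a chromosome."""


@dataclass
class SimConfig:
    """Study conditions for the synthetic dataset.

    Defaults are the conditions under which the pipeline is benchmarked:
    2,000 genes of 5-12 exons, 10% planted spurious genes with a 4-fold
    intermediate-exon gain, Poisson(30) cryptic CAGE tags per planted
    site in KO, negative-binomial exon counts with dispersion 0.1, and
    two replicates per condition.
    """

    n_genes: int = 2000
    exon_count_range: tuple[int, int] = (5, 12)
    exon_len_range: tuple[int, int] = (200, 1000)
    intron_len_range: tuple[int, int] = (200, 2000)
    fraction_spurious: float = 0.10
    spurious_effect: float = 4.0
    expression_log_mean: float = 3.0
    expression_log_sd: float = 1.0
    nb_dispersion: float = 0.1
    library_size: float = 2_000_000.0
    n_replicates: int = 2
    # CAGE
    cage_canonical_rate: float = 1.0   # expected canonical-TSS tags per expression unit
    cage_cryptic_tags: float = 30.0    # expected tags per planted cryptic site in KO
    cage_cryptic_leak: float = 0.0     # expected control-side tags per cryptic site
    cage_noise_rate: float = 1e-4      # background tags per base per strand
    # ChIP (raw expected counts per base)
    pser5_peak_per_expr: float = 0.5   # TSS peak amplitude per expression unit
    pser5_peak_sd: float = 100.0
    pser5_body_per_expr: float = 0.02  # body plateau per expression unit
    pser5_cryptic_peak: float = 5.0    # secondary peak amplitude at cryptic sites (KO)
    pser5_cryptic_peak_sd: float = 50.0
    pser5_cryptic_body: float = 2.0    # absolute KO body-plateau boost, spurious genes
    h3k36_per_tier: float = 0.4        # body signal per expression quintile (1..5)
    hmc_per_tier: float = 0.3
    ko_body_scale: float = 0.3         # KO scaling of 5hmC/H3K36me3 over spurious bodies
    input_rate: float = 1.0            # uniform input coverage
    # geometry / sequence
    genes_per_chrom: int = 50
    gap_len: int = 2000
    chrom_len: int | None = None       # fixed chromosome length; None = auto-size
    cryptic_sites_range: tuple[int, int] = (1, 3)
    motif_consensus: str = "CCGCCC"
    seed: int = 17

    def __post_init__(self) -> None:
        if not 0 <= self.fraction_spurious < 1:
            raise ValueError("fraction_spurious must be in [0, 1)")
        if self.spurious_effect < 1:
            raise ValueError("spurious_effect must be >= 1")
        for name in ("library_size", "cage_canonical_rate", "nb_dispersion",
                     "input_rate", "cage_noise_rate"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.cage_cryptic_tags < 0 or self.cage_cryptic_leak < 0:
            raise ValueError("cryptic tag rates must be >= 0")
        if set(self.motif_consensus) - set("ACGT"):
            raise ValueError("motif_consensus must be an ACGT string")
        if self.exon_count_range[0] < 3:
            raise ValueError("genes need >= 3 exons to host intermediate-exon gains")

    def digest(self) -> str:
        """Short content hash of the configuration, stamped into output files."""
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha1(payload.encode()).hexdigest()[:12]


@dataclass
class GeneTruth:
    gene_id: str
    is_spurious: bool
    cryptic_positions: tuple[int, ...]  # genomic coordinates, sense strand
    expression: float                   # latent expression level (arbitrary units)
    tier: int                           # expression quintile, 1 (lowest) .. 5 (highest)


@dataclass
class TruthTable:
    """Planted ground truth, keyed by gene id."""

    genes: dict[str, GeneTruth]

    @property
    def spurious_genes(self) -> set[str]:
        return {g for g, t in self.genes.items() if t.is_spurious}

    def to_json(self, path: str | Path, extra: dict | None = None) -> None:
        payload = {
            "meta": extra or {},
            "genes": {
                g: {
                    "is_spurious": t.is_spurious,
                    "cryptic_positions": list(t.cryptic_positions),
                    "expression": t.expression,
                    "tier": t.tier,
                }
                for g, t in self.genes.items()
            },
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthTable":
        payload = json.loads(Path(path).read_text())
        return cls(
            {
                g: GeneTruth(g, d["is_spurious"], tuple(d["cryptic_positions"]),
                             d["expression"], d["tier"])
                for g, d in payload["genes"].items()
            }
        )


@dataclass
class SimulatedGenome:
    """Bundle returned by :func:`simulate_genome`."""

    sequences: dict[str, str]
    genes: list[GeneModel]
    truth: TruthTable
    config: SimConfig

    @property
    def genome_length(self) -> int:
        return sum(len(s) for s in self.sequences.values())


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    # independent, reproducible stream per generator
    return np.random.default_rng([config.seed, stream])


def _expression_tiers(expression: np.ndarray) -> np.ndarray:
    """Quintile tier per gene, 1 = lowest fifth .. 5 = highest fifth."""
    order = np.argsort(np.argsort(expression, kind="stable"), kind="stable")
    return 1 + (order * 5) // expression.size


def simulate_genome(config: SimConfig) -> SimulatedGenome:
    """Generate sequence, annotation and planted truth.

    Genes are laid out left to right on synthetic chromosomes of
    ``genes_per_chrom`` genes each, separated by ``gap_len`` spacers.
    For each spurious gene, 1-3 cryptic start sites are chosen inside the
    exon2-to-TES body and the consensus motif is written into the genome
    on the gene's sense strand, starting at the cryptic base.
    """
    rng = _rng(config, 0)
    n = config.n_genes
    n_spurious = int(round(n * config.fraction_spurious))
    spurious_idx = set(rng.choice(n, size=n_spurious, replace=False).tolist()) if n_spurious else set()

    expression = rng.lognormal(config.expression_log_mean, config.expression_log_sd, size=n)
    tiers = _expression_tiers(expression)

    genes: list[tuple] = []
    truth: dict[str, tuple] = {}

    lo_k, hi_k = config.exon_count_range
    lo_e, hi_e = config.exon_len_range
    lo_i, hi_i = config.intron_len_range
    motif_codes = np.array([_CODE[b] for b in config.motif_consensus])
    mlen = motif_codes.size

    for gi in range(n):
        chrom = f"chr{gi // config.genes_per_chrom + 1}"
        gene_id = f"gene{gi:05d}"
        k = int(rng.integers(lo_k, hi_k + 1))
        exon_lens = rng.integers(lo_e, hi_e + 1, size=k)
        intron_lens = rng.integers(lo_i, hi_i + 1, size=k - 1)
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append((gene_id, chrom, strand, exon_lens, intron_lens))
        truth[gene_id] = (gi in spurious_idx, expression[gi], int(tiers[gi]))

    # second pass: place genes, draw sequence, plant motifs
    placed: list[GeneModel] = []
    final_truth: dict[str, GeneTruth] = {}
    cursors: dict[str, int] = {}
    for gene_id, chrom, strand, exon_lens, intron_lens in genes:
        cursor = cursors.get(chrom, config.gap_len)
        bounds = []
        pos = cursor
        for j, elen in enumerate(exon_lens):
            bounds.append((pos, pos + int(elen)))
            pos += int(elen)
            if j < len(intron_lens):
                pos += int(intron_lens[j])
        cursors[chrom] = pos + config.gap_len
        if config.chrom_len is not None and cursors[chrom] > config.chrom_len:
            raise SimSizeError(
                f"{chrom}: gene layout needs {cursors[chrom]} bases, "
                f"budget is {config.chrom_len}"
            )
        if strand == "-":
            bounds = bounds[::-1]  # transcription order for from_genomic_exons
        model = GeneModel.from_genomic_exons(gene_id, chrom, strand, bounds)
        placed.append(model)

        is_spurious, expr, tier = truth[gene_id]
        cryptic: tuple[int, ...] = ()
        if is_spurious:
            body = gene_body(model, "exon2_to_tes")
            m = int(rng.integers(config.cryptic_sites_range[0],
                                 config.cryptic_sites_range[1] + 1))
            margin = 60  # keeps the motif and its +/-50 nt window inside the body
            lo, hi = body.start + margin, body.end - margin
            sites: list[int] = []
            for _ in range(200):
                if len(sites) == m:
                    break
                p = int(rng.integers(lo, hi))
                if all(abs(p - q) >= 200 for q in sites):
                    sites.append(p)
            cryptic = tuple(sorted(sites))
        final_truth[gene_id] = GeneTruth(gene_id, is_spurious, cryptic, float(expr), tier)

    # draw chromosome sequences
    sequences: dict[str, str] = {}
    motif_jobs: dict[str, list[tuple[int, str]]] = {}
    for model in placed:
        t = final_truth[model.gene_id]
        for p in t.cryptic_positions:
            motif_jobs.setdefault(model.chrom, []).append((p, model.strand))
    for chrom in sorted(cursors):
        length = config.chrom_len if config.chrom_len is not None else cursors[chrom]
        codes = rng.choice(4, size=length, p=_BASE_P).astype(np.uint8)
        for p, strand in motif_jobs.get(chrom, []):
            if strand == "+":
                codes[p:p + mlen] = motif_codes
            else:
                # sense sequence of a minus-strand gene reads genomic revcomp,
                # so the motif occupies [p-mlen+1, p+1) reverse-complemented
                codes[p - mlen + 1:p + 1] = _COMPLEMENT_CODE[motif_codes][::-1]
        sequences[chrom] = _BASES[codes].tobytes().decode()

    return SimulatedGenome(sequences, placed, TruthTable(final_truth), config)


def _sample_names(config: SimConfig) -> list[tuple[str, str]]:
    names = [(f"Ctrl_{i + 1}", "Ctrl") for i in range(config.n_replicates)]
    names += [(f"KO_{i + 1}", "KO") for i in range(config.n_replicates)]
    return names


def _negbin(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """NB draw parameterised by mean and dispersion alpha (var = mu + alpha*mu^2)."""
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 1e-8:
        return rng.poisson(mean)
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def simulate_rnaseq_counts(config: SimConfig, sim: SimulatedGenome) -> ExonCountMatrix:
    """Per-exon negative-binomial counts for Ctrl and KO replicates.

    The expected count of exon *e* in gene *g* is
    ``expression_g * exon_len_kb * depth``, with ``depth`` chosen so the
    expected control library totals ``library_size`` reads.  In KO samples
    of spurious genes, the means of exons 2..n-1 are multiplied by
    ``spurious_effect``; exon 1 and the last exon are unchanged.
    """
    rng = _rng(config, 1)
    rows = []
    base_mass = 0.0
    for gene in sim.genes:
        expr = sim.truth.genes[gene.gene_id].expression
        for iv in gene.exons:
            base_mass += expr * iv.length / 1000.0
    depth = config.library_size / base_mass

    samples = _sample_names(config)
    counts: dict[str, list[int]] = {s: [] for s, _ in samples}
    for gene in sim.genes:
        t = sim.truth.genes[gene.gene_id]
        lens = np.array([iv.length for iv in gene.exons], dtype=float)
        mu = t.expression * (lens / 1000.0) * depth
        mu_ko = mu.copy()
        if t.is_spurious and gene.n_exons >= 3:
            mu_ko[1:-1] *= config.spurious_effect
        for idx, iv in enumerate(gene.exons):
            rows.append((gene.gene_id, idx + 1, iv.length))
        for sample, cond in samples:
            m = mu if cond == "Ctrl" else mu_ko
            counts[sample].extend(_negbin(rng, m, config.nb_dispersion).tolist())

    frame = pd.DataFrame(rows, columns=["gene_id", "exon_index", "exon_len"])
    for sample, _ in samples:
        frame[sample] = np.asarray(counts[sample], dtype=np.int64)
    sample_df = pd.DataFrame(
        {
            "sample": [s for s, _ in samples],
            "condition": [c for _, c in samples],
            "total_mapped": [int(frame[s].sum()) for s, _ in samples],
        }
    )
    return ExonCountMatrix(frame, sample_df)


_JITTER_OFFSETS = np.array([-2, -1, 0, 1, 2])
_JITTER_P = np.array([0.1, 0.2, 0.4, 0.2, 0.1])


def simulate_cage(config: SimConfig, sim: SimulatedGenome) -> dict[str, CTSSSet]:
    """Single-base CAGE tag sets per sample.

    Canonical initiation: Poisson tags at each gene's TSS, jittered within
    +/-2 bp, on the sense strand, rate ``cage_canonical_rate * expression``.
    Cryptic initiation: Poisson(``cage_cryptic_tags``) at each planted site
    in KO samples (optionally a small leak in controls).  A uniform noise
    floor drops single tags at random positions on both strands, with an
    expected count well below one tag per base.
    """
    rng = _rng(config, 2)
    glen = sim.genome_length
    chrom_names = sorted(sim.sequences)
    chrom_lens = np.array([len(sim.sequences[c]) for c in chrom_names])
    chrom_p = chrom_lens / chrom_lens.sum()

    out: dict[str, CTSSSet] = {}
    for sample, cond in _sample_names(config):
        chroms: list[str] = []
        poss: list[int] = []
        strands: list[str] = []
        tags: list[int] = []

        for gene in sim.genes:
            t = sim.truth.genes[gene.gene_id]
            n_tags = rng.poisson(config.cage_canonical_rate * t.expression)
            if n_tags > 0:
                split = rng.multinomial(n_tags, _JITTER_P)
                sign = 1 if gene.strand == "+" else -1
                for off, cnt in zip(_JITTER_OFFSETS, split):
                    if cnt == 0:
                        continue
                    pos = gene.tss + sign * int(off)
                    if pos < 0:
                        continue
                    chroms.append(gene.chrom)
                    poss.append(pos)
                    strands.append(gene.strand)
                    tags.append(int(cnt))
            site_rate = config.cage_cryptic_tags if cond == "KO" else config.cage_cryptic_leak
            if site_rate > 0:
                for p in t.cryptic_positions:
                    cnt = int(rng.poisson(site_rate))
                    if cnt:
                        chroms.append(gene.chrom)
                        poss.append(p)
                        strands.append(gene.strand)
                        tags.append(cnt)

        for strand in ("+", "-"):
            n_noise = rng.poisson(config.cage_noise_rate * glen)
            if n_noise == 0:
                continue
            picks = rng.choice(len(chrom_names), size=n_noise, p=chrom_p)
            offsets = rng.integers(0, chrom_lens[picks])
            for ci, off in zip(picks, offsets):
                chroms.append(chrom_names[ci])
                poss.append(int(off))
                strands.append(strand)
                tags.append(1)

        df = pd.DataFrame({"chrom": chroms, "pos": poss, "strand": strands, "tags": tags})
        df = df.groupby(["chrom", "pos", "strand"], as_index=False)["tags"].sum()
        out[sample] = CTSSSet(sample=sample, condition=cond, records=df)
    return out


def _add_gaussian(arr: np.ndarray, center: int, amplitude: float, sd: float) -> None:
    half = int(3 * sd)
    lo, hi = max(0, center - half), min(arr.size, center + half + 1)
    if lo >= hi:
        return
    x = np.arange(lo, hi) - center
    arr[lo:hi] += amplitude * np.exp(-0.5 * (x / sd) ** 2)


def simulate_chip(config: SimConfig, sim: SimulatedGenome) -> dict[str, SignalTrack]:
    """Poisson coverage tracks for Pol II pSer5, H3K36me3, 5hmC and input.

    Returns tracks named ``pSer5_Ctrl``, ``pSer5_KO``, ``input_Ctrl``,
    ``input_KO``, ``H3K36me3_Ctrl``, ``H3K36me3_KO``, ``5hmC_Ctrl`` and
    ``5hmC_KO``; values are non-negative integer counts per base.
    """
    rng = _rng(config, 3)
    chrom_names = sorted(sim.sequences)
    chrom_lens = {c: len(sim.sequences[c]) for c in chrom_names}
    genes_by_chrom: dict[str, list[GeneModel]] = {c: [] for c in chrom_names}
    for gene in sim.genes:
        genes_by_chrom[gene.chrom].append(gene)

    tracks: dict[str, dict[str, np.ndarray]] = {
        name: {} for name in (
            "pSer5_Ctrl", "pSer5_KO", "input_Ctrl", "input_KO",
            "H3K36me3_Ctrl", "H3K36me3_KO", "5hmC_Ctrl", "5hmC_KO",
        )
    }

    for chrom in chrom_names:
        L = chrom_lens[chrom]
        rates = {
            "pSer5_Ctrl": np.zeros(L), "pSer5_KO": np.zeros(L),
            "H3K36me3_Ctrl": np.zeros(L), "H3K36me3_KO": np.zeros(L),
            "5hmC_Ctrl": np.zeros(L), "5hmC_KO": np.zeros(L),
        }
        for gene in genes_by_chrom[chrom]:
            t = sim.truth.genes[gene.gene_id]
            span = gene.span
            sl = slice(span.start, span.end)
            for cond in ("Ctrl", "KO"):
                ps = rates[f"pSer5_{cond}"]
                _add_gaussian(ps, gene.tss, config.pser5_peak_per_expr * t.expression,
                              config.pser5_peak_sd)
                ps[sl] += config.pser5_body_per_expr * t.expression
                body_level = (config.h3k36_per_tier * t.tier,
                              config.hmc_per_tier * t.tier)
                scale = config.ko_body_scale if (cond == "KO" and t.is_spurious) else 1.0
                rates[f"H3K36me3_{cond}"][sl] += body_level[0] * scale
                rates[f"5hmC_{cond}"][sl] += body_level[1] * scale
            if t.is_spurious:
                body = gene_body(gene, "exon2_to_tes")
                ko = rates["pSer5_KO"]
                ko[body.start:body.end] += config.pser5_cryptic_body
                for p in t.cryptic_positions:
                    _add_gaussian(ko, p, config.pser5_cryptic_peak,
                                  config.pser5_cryptic_peak_sd)
        for name, rate in rates.items():
            tracks[name][chrom] = rng.poisson(rate).astype(np.int32)
        for cond in ("Ctrl", "KO"):
            tracks[f"input_{cond}"][chrom] = rng.poisson(
                config.input_rate, size=L).astype(np.int32)

    return {name: SignalTrack(data, name=name) for name, data in tracks.items()}


def write_dataset(outdir: str | Path, config: SimConfig | None = None) -> SimulatedGenome:
    """Run all four generators and write the dataset to ``outdir``.

    Files: ``genome.fa``, ``genes.gtf``, ``exon_counts.tsv``,
    ``samples.tsv``, ``ctss_<sample>.bed``, ``<track>.bedgraph`` and
    ``truth.json``.  Every file records the configuration digest.
    """
    config = config or SimConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stamp = f"spurcatch sim config={config.digest()} seed={config.seed}"

    sim = simulate_genome(config)
    write_fasta(sim.sequences, outdir / "genome.fa", description=stamp)
    write_gtf(sim.genes, outdir / "genes.gtf", header=stamp)
    sim.truth.to_json(outdir / "truth.json", extra={"config_digest": config.digest()})

    matrix = simulate_rnaseq_counts(config, sim)
    matrix.to_tsv(outdir / "exon_counts.tsv", outdir / "samples.tsv", header=stamp)

    for sample, cs in simulate_cage(config, sim).items():
        write_bed6(cs.to_bed6(), outdir / f"ctss_{sample}.bed", header=stamp)

    for name, track in simulate_chip(config, sim).items():
        write_bedgraph(track, outdir / f"{name}.bedgraph", header=stamp)
    return sim
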