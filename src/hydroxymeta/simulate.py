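"""Synthetic TAB-seq data with known truth for every estimator.

The generator emits everything the pipeline consumes: a random toy genome,
non-overlapping gene models with exon blocks, a 16-sample expression table
whose exon-normalised ranks reproduce a configured quintile labelling
exactly, spike-in call tables (fully-5mC lambda, fully-5hmC pUC19), and a
genomic call table with quintile-structured gene-body 5hmC.

Read model (site-level, no read geometry — the pipeline consumes per-site
counts, so fragment simulation would add nothing): per cytosine site,
``total ~ Poisson(coverage)`` and ``protected ~ Binomial(total, p)`` where
p is the site's per-read probability of reading C:

* genomic CG site in a gene body — the quintile's configured probability
  (defaults 0.010..0.038, quintile 5 / quintile 1 = 3.8);
* genomic CG site elsewhere — the flank/background probability;
* genomic CHG/CHH site — ``nonconv_C`` (unmodified-C non-conversion);
* lambda CG site — ``nonconv_5mC`` (the spike-in is fully methylated);
* pUC19 cytosine (any context) — ``protection_rate`` (PCR with 5hmdCTP
  makes every cytosine 5hmC).

The quintile gene-body and background probabilities are *net* per-read
protected probabilities — the level the assay measures — so configured
fold-changes propagate directly to the raw weighted levels the pipeline
reports. Everything is deterministic given the config seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import CallTable, GeneModel, write_calls, write_gene_models_bed12

_BASES = np.array(list("ACGT"))
# integer encoding: 0=A 1=C 2=G 3=T


@dataclass
class SimulationConfig:
    """Parameters of one synthetic dataset; ``seed`` is mandatory.

    ``flank_bin_size`` defaults to 100 bp (20 bins = 2 kb flanks) so the
    toy chromosomes can hold 100 genes each; set 5000 for the full-scale
    100 kb flank geometry on large chromosomes.
    """

    seed: int
    chrom_lengths: tuple[int, ...] = (500_000, 500_000)
    gc_content: float = 0.42
    n_genes: int = 200
    flank_bin_size: int = 100
    n_flank_bins: int = 20
    n_body_bins: int = 20
    gb_protected_probs: tuple[float, ...] = (0.010, 0.017, 0.024, 0.031, 0.038)
    background_cg_prob: float = 0.020
    unmethylated_cg_fraction: float = 0.0
    nonconv_5mC: float = 0.03
    nonconv_C: float = 0.005
    protection_rate: float = 0.52
    coverage: float = 1.0
    spikein_coverage: float = 30.0
    n_expression_samples: int = 16
    expression_noise_sd: float = 0.2
    lambda_length: int = 48_502
    puc19_length: int = 2_686
    sample_id: str = "synthetic"

    def validate(self) -> None:
        probs = (
            *self.gb_protected_probs, self.background_cg_prob, self.nonconv_5mC,
            self.nonconv_C, self.protection_rate, self.unmethylated_cg_fraction,
        )
        if any(not 0 <= p <= 1 for p in probs):
            raise ValidationError("all probabilities must be in [0, 1]")
        if len(self.gb_protected_probs) != 5:
            raise ValidationError("gb_protected_probs needs one value per quintile")
        if self.coverage <= 0 or self.spikein_coverage <= 0:
            raise ValidationError("coverage must be > 0")
        if not 0 < self.gc_content < 1:
            raise ValidationError("gc_content must be in (0, 1)")
        n_chroms = len(self.chrom_lengths)
        per_chrom = -(-self.n_genes // n_chroms)
        slot = min(self.chrom_lengths) // per_chrom
        if slot < 4 * self.n_body_bins:
            raise ValidationError(
                f"chromosomes too short for {self.n_genes} genes "
                f"(slot {slot} bp cannot hold a gene of >= {self.n_body_bins} bp)"
            )


@dataclass
class TruthSet:
    """Ground truth behind one simulated dataset."""

    nonconv_5mC: float
    nonconv_C: float
    protection_rate: float
    gene_quintile: pd.Series = field(repr=False)  # gene_id -> quintile 1..5
    expression_score: pd.Series = field(repr=False)  # gene_id -> true normalised score
    site_probs: pd.DataFrame = field(repr=False)  # chrom,pos,strand,context,prob


@dataclass
class SimulatedDataset:
    """All artefacts of one simulation run."""

    config: SimulationConfig
    genome: dict[str, str] = field(repr=False)
    spikeins: dict[str, str] = field(repr=False)
    genes: list[GeneModel] = field(repr=False)
    exon_blocks: dict[str, list[tuple[int, int]]] = field(repr=False)
    expression: pd.DataFrame = field(repr=False)
    genome_calls: CallTable = field(repr=False)
    lambda_calls: CallTable = field(repr=False)
    puc19_calls: CallTable = field(repr=False)
    truth: TruthSet = field(repr=False)

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.genome.items()}

    @property
    def n_reference_cytosines(self) -> int:
        """Cytosine sites (both strands, any context) in the toy genome."""
        return len(self.truth.site_probs)

    def write(self, outdir, write_site_truth: bool = False) -> dict[str, str]:
        """Emit FASTA, BED12, expression TSV, call TSVs and truth JSON."""
        from Bio import SeqIO
        from Bio.Seq import Seq
        from Bio.SeqRecord import SeqRecord

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        records = [SeqRecord(Seq(s), id=c, description="") for c, s in self.genome.items()]
        records += [SeqRecord(Seq(s), id=c, description="synthetic spike-in")
                    for c, s in self.spikeins.items()]
        paths["genome"] = str(outdir / "genome.fa")
        SeqIO.write(records, paths["genome"], "fasta")
        paths["genes"] = write_gene_models_bed12(self.genes, outdir / "genes.bed", self.exon_blocks)
        paths["expression"] = str(outdir / "expression.tsv")
        self.expression.rename_axis("gene_id").reset_index().to_csv(
            paths["expression"], sep="\t", index=False
        )
        for name, table in (
            ("genome_calls", self.genome_calls),
            ("lambda_calls", self.lambda_calls),
            ("puc19_calls", self.puc19_calls),
        ):
            paths[name] = write_calls(table, outdir / f"{name}.tsv")
        truth = {
            "nonconv_5mC": self.truth.nonconv_5mC,
            "nonconv_C": self.truth.nonconv_C,
            "protection_rate": self.truth.protection_rate,
            "n_reference_cytosines": self.n_reference_cytosines,
            "gene_quintile": {g: int(q) for g, q in self.truth.gene_quintile.items()},
            "config": asdict(self.config),
        }
        paths["truth"] = str(outdir / "truth.json")
        with open(paths["truth"], "w") as fh:
            json.dump(truth, fh, indent=1)
        if write_site_truth:
            paths["site_truth"] = str(outdir / "site_truth.tsv")
            self.truth.site_probs.to_csv(paths["site_truth"], sep="\t", index=False)
        return paths


def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=length, p=p)


def _cytosine_sites(seq: np.ndarray) -> pd.DataFrame:
    """All cytosine sites on both strands with reference-derived context."""
    n = len(seq)
    next1 = np.concatenate([seq[1:], [-1]])
    next2 = np.concatenate([seq[2:], [-1, -1]])
    prev1 = np.concatenate([[-1], seq[:-1]])
    prev2 = np.concatenate([[-1, -1], seq[:-2]])

    plus = np.flatnonzero(seq == 1)  # C on the forward strand
    ctx_p = np.where(next1[plus] == 2, "CG", np.where(next2[plus] == 2, "CHG", "CHH"))
    minus = np.flatnonzero(seq == 2)  # G forward == C on the reverse strand
    ctx_m = np.where(prev1[minus] == 1, "CG", np.where(prev2[minus] == 1, "CHG", "CHH"))

    df = pd.DataFrame(
        {
            "pos": np.concatenate([plus, minus]),
            "strand": np.concatenate([np.repeat("+", len(plus)), np.repeat("-", len(minus))]),
            "context": np.concatenate([ctx_p, ctx_m]),
        }
    )
    return df.sort_values(["pos", "strand"], kind="mergesort").reset_index(drop=True)


def _place_genes(
    rng: np.random.Generator, config: SimulationConfig
) -> tuple[list[GeneModel], dict[str, list[tuple[int, int]]]]:
    """Non-overlapping genes, one per equal slot, with random exon blocks."""
    n_chroms = len(config.chrom_lengths)
    counts = [config.n_genes // n_chroms + (1 if i < config.n_genes % n_chroms else 0)
              for i in range(n_chroms)]
    genes: list[GeneModel] = []
    blocks: dict[str, list[tuple[int, int]]] = {}
    gid = 0
    for ci, (clen, cnt) in enumerate(zip(config.chrom_lengths, counts)):
        chrom = f"chr{ci + 1}"
        slot = clen // cnt
        for k in range(cnt):
            lo = max(config.n_body_bins, slot // 5)
            hi = max(lo + 1, int(slot * 0.8))
            length = int(rng.integers(lo, hi))
            start = slot * k + int(rng.integers(0, slot - length + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            gene_id = f"gene{gid:04d}"
            gid += 1
            n_ex = int(rng.integers(1, 4))
            blk = [(0, length)]
            if n_ex > 1 and length > 2 * n_ex + 2:
                cuts = np.unique(rng.integers(1, length, size=2 * (n_ex - 1)))
                if len(cuts) == 2 * (n_ex - 1):
                    bounds = [0, *cuts.tolist(), length]
                    blk = [
                        (bounds[2 * i], bounds[2 * i + 1] - bounds[2 * i])
                        for i in range(n_ex)
                    ]
            genes.append(
                GeneModel(
                    gene_id=gene_id, chrom=chrom, strand=strand,
                    start=start, end=start + length,
                    exonic_length=sum(z for _, z in blk),
                )
            )
            blocks[gene_id] = blk
    return genes, blocks


def _quintile_truth(rng: np.random.Generator, gene_ids: list[str]) -> pd.Series:
    """Random quintile labels with the partition sizes the pipeline uses
    (floor(n/5) each, the n mod 5 lowest quintiles one larger)."""
    n = len(gene_ids)
    base, extra = divmod(n, 5)
    sizes = [base + (1 if q < extra else 0) for q in range(5)]
    labels = np.repeat(np.arange(1, 6), sizes)
    perm = rng.permutation(n)
    return pd.Series(labels, index=np.array(gene_ids)[perm]).sort_index()


def make_expression(
    rng: np.random.Generator,
    genes: list[GeneModel],
    quintile_truth: pd.Series,
    n_samples: int = 16,
    noise_sd: float = 0.2,
) -> tuple[pd.DataFrame, pd.Series]:
    """Expression table whose exon-normalised mean ranks recover the truth.

    Each gene draws a base score inside a quintile-specific band (bands a
    decade apart, so multiplicative log-normal noise averaged over the
    samples can never move a gene across quintile boundaries), and
    per-sample expression is ``base x exonic_length x sample_factor x noise``.
    Returns (expression table, true normalised score per gene).
    """
    gene_ids = [g.gene_id for g in genes]
    q = quintile_truth.loc[gene_ids].to_numpy()
    base = rng.uniform(1.0, 1.8, size=len(genes)) * 10.0 ** q
    lengths = np.array([g.exonic_length for g in genes], dtype=float)
    sample_factor = rng.lognormal(0.0, 0.3, size=n_samples)
    noise = rng.lognormal(0.0, noise_sd, size=(len(genes), n_samples))
    values = base[:, None] * lengths[:, None] * sample_factor[None, :] * noise
    expr = pd.DataFrame(
        values, index=pd.Index(gene_ids, name="gene_id"),
        columns=[f"S{i + 1:02d}" for i in range(n_samples)],
    )
    return expr, pd.Series(base, index=gene_ids, name="true_score")


def _simulate_calls(
    rng: np.random.Generator,
    sites: pd.DataFrame,
    probs: np.ndarray,
    coverage: float,
    chrom_of: np.ndarray,
    sample_id: str,
    source_kind: str,
) -> CallTable:
    total = rng.poisson(coverage, size=len(sites))
    protected = rng.binomial(total, probs)
    df = pd.DataFrame(
        {
            "chrom": chrom_of,
            "pos": sites["pos"].to_numpy(),
            "strand": sites["strand"].to_numpy(),
            "context": sites["context"].to_numpy(),
            "protected": protected,
            "total": total,
        }
    )
    df = df[df["total"] > 0].reset_index(drop=True)
    return CallTable(sample_id, source_kind, df)


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Run the full generator; deterministic given ``config`` (seed included)."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    genome: dict[str, str] = {}
    site_frames = []
    for ci, clen in enumerate(config.chrom_lengths):
        chrom = f"chr{ci + 1}"
        seq = _random_sequence(rng, clen, config.gc_content)
        genome[chrom] = "".join(_BASES[seq])
        sites = _cytosine_sites(seq)
        sites.insert(0, "chrom", chrom)
        site_frames.append(sites)
    genome_sites = pd.concat(site_frames, ignore_index=True)

    genes, exon_blocks = _place_genes(rng, config)
    quintile_truth = _quintile_truth(rng, [g.gene_id for g in genes])
    expression, true_score = make_expression(
        rng, genes, quintile_truth, config.n_expression_samples, config.expression_noise_sd
    )

    # per-site per-read protected probability
    probs = np.where(
        genome_sites["context"].to_numpy() == "CG",
        config.background_cg_prob,
        config.nonconv_C,
    ).astype(float)
    is_cg = genome_sites["context"].to_numpy() == "CG"
    if config.unmethylated_cg_fraction > 0:
        unmeth = rng.random(len(probs)) < config.unmethylated_cg_fraction
        probs[is_cg & unmeth] = config.nonconv_C
    pos = genome_sites["pos"].to_numpy()
    chrom_arr = genome_sites["chrom"].to_numpy()
    # site rows are grouped by chromosome and position-sorted within each
    offsets: dict[str, tuple[int, int]] = {}
    start_idx = 0
    for frame in site_frames:
        chrom = frame["chrom"].iloc[0] if len(frame) else None
        if chrom is not None:
            offsets[chrom] = (start_idx, start_idx + len(frame))
        start_idx += len(frame)
    for gene in genes:
        q = int(quintile_truth[gene.gene_id])
        off, stop = offsets[gene.chrom]
        cpos = pos[off:stop]
        lo = off + np.searchsorted(cpos, gene.start, side="left")
        hi = off + np.searchsorted(cpos, gene.end, side="left")
        seg = slice(lo, hi)
        probs[seg][is_cg[seg]] = config.gb_protected_probs[q - 1]

    genome_calls = _simulate_calls(
        rng, genome_sites, probs, config.coverage, chrom_arr,
        config.sample_id, "genome",
    )

    spikeins: dict[str, str] = {}
    seq = _random_sequence(rng, config.lambda_length, 0.5)
    spikeins["lambda_synthetic"] = "".join(_BASES[seq])
    lam_sites = _cytosine_sites(seq)
    lam_probs = np.where(
        lam_sites["context"].to_numpy() == "CG", config.nonconv_5mC, config.nonconv_C
    ).astype(float)
    lambda_calls = _simulate_calls(
        rng, lam_sites, lam_probs, config.spikein_coverage,
        np.repeat("lambda_synthetic", len(lam_sites)), config.sample_id, "lambda_5mC",
    )

    seq = _random_sequence(rng, config.puc19_length, 0.5)
    spikeins["pUC19_synthetic"] = "".join(_BASES[seq])
    puc_sites = _cytosine_sites(seq)
    puc_probs = np.full(len(puc_sites), config.protection_rate)
    puc19_calls = _simulate_calls(
        rng, puc_sites, puc_probs, config.spikein_coverage,
        np.repeat("pUC19_synthetic", len(puc_sites)), config.sample_id, "pUC19_5hmC",
    )

    truth = TruthSet(
        nonconv_5mC=config.nonconv_5mC,
        nonconv_C=config.nonconv_C,
        protection_rate=config.protection_rate,
        gene_quintile=quintile_truth,
        expression_score=true_score,
        site_probs=genome_sites.assign(prob=probs),
    )
    return SimulatedDataset(
        config=config, genome=genome, spikeins=spikeins, genes=genes,
        exon_blocks=exon_blocks, expression=expression,
        genome_calls=genome_calls, lambda_calls=lambda_calls,
        puc19_calls=puc19_calls, truth=truth,
    )
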