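"""Strand-aware metagene binning and weighted 5hmCG levels.

Each gene contributes 60 ordered bins in its own 5'->3' orientation:
20 upstream-of-TSS flank bins (UTSS, fixed width, default 5 kb each for
100 kb total), 20 gene-body bins (GB) that evenly partition [start, end)
whatever the gene length, and 20 downstream-of-TTS flank bins (DTTS).
Bin 0 of UTSS is the farthest upstream; for minus-strand genes the genomic
order of bins is reversed so profiles align on transcription direction.

The level in a bin is the weighted methylation level: pooled protected
reads over pooled total reads of all CG-context calls in the bin, pooled
across both strands and (for quintile profiles) across all member genes
before dividing. A bin with no covered CG call is missing (NaN), never 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import HydroxymetaError, ValidationError
from .io import CallTable, GeneModel

logger = logging.getLogger(__name__)

N_FLANK_BINS = 20
N_BODY_BINS = 20
FLANK_BIN_SIZE = 5_000  # bp; 20 x 5 kb = 100 kb each direction
REGIONS = ("UTSS", "GB", "DTTS")


class GeneTooShortError(HydroxymetaError):
    """Gene span shorter than the number of body bins; the gene is skipped."""


BIN_COLUMNS = ["gene_id", "region", "bin_index", "ordinal", "chrom", "start", "end", "clipped"]


def build_gene_bins(
    gene: GeneModel,
    flank_bin_size: int = FLANK_BIN_SIZE,
    n_flank_bins: int = N_FLANK_BINS,
    n_body_bins: int = N_BODY_BINS,
    chrom_length: int | None = None,
) -> pd.DataFrame:
    """The 60 genomic intervals of one gene, ordered 5'->3' of the gene.

    Body bin k covers ``[start + floor(k*L/20), start + floor((k+1)*L/20))``
    for plus-strand genes (mirrored for minus), so body bins partition the
    gene exactly for any length >= the bin count. Flank bins that would run
    off the contig are clipped (possibly to empty) and flagged.
    """
    L = gene.length
    if L < n_body_bins:
        raise GeneTooShortError(
            f"gene {gene.gene_id} length {L} < {n_body_bins} body bins"
        )
    B = flank_bin_size
    rows: list[tuple] = []
    if gene.strand == "+":
        for i in range(n_flank_bins):
            s = gene.start - (n_flank_bins - i) * B
            rows.append(("UTSS", i, s, s + B))
        for k in range(n_body_bins):
            rows.append(("GB", k,
                         gene.start + (k * L) // n_body_bins,
                         gene.start + ((k + 1) * L) // n_body_bins))
        for j in range(n_flank_bins):
            rows.append(("DTTS", j, gene.end + j * B, gene.end + (j + 1) * B))
    else:
        for i in range(n_flank_bins):
            s = gene.end + (n_flank_bins - i - 1) * B
            rows.append(("UTSS", i, s, s + B))
        for k in range(n_body_bins):
            rows.append(("GB", k,
                         gene.end - ((k + 1) * L) // n_body_bins,
                         gene.end - (k * L) // n_body_bins))
        for j in range(n_flank_bins):
            rows.append(("DTTS", j, gene.start - (j + 1) * B, gene.start - j * B))

    out = []
    for ordinal, (region, idx, s, e) in enumerate(rows):
        clipped = False
        if s < 0:
            s, clipped = 0, True
        if e < 0:
            e, clipped = 0, True
        if chrom_length is not None:
            if e > chrom_length:
                e, clipped = chrom_length, True
            if s > chrom_length:
                s, clipped = chrom_length, True
        out.append((gene.gene_id, region, idx, ordinal, gene.chrom, s, e, clipped))
    return pd.DataFrame(out, columns=BIN_COLUMNS)


def weighted_level(calls: CallTable, chrom: str, start: int, end: int):
    """Weighted 5hmCG level of one interval: (sum protected, sum total, level).

    CG-context calls on both strands inside ``[start, end)`` are pooled;
    the level is NaN when no read covers the interval.
    """
    cg = calls.subset_context("CG")
    sel = cg[(cg["chrom"] == chrom) & (cg["pos"] >= start) & (cg["pos"] < end)]
    protected = int(sel["protected"].sum())
    total = int(sel["total"].sum())
    level = protected / total if total > 0 else float("nan")
    return protected, total, level


@dataclass
class MetageneProfile:
    """Weighted 5hmCG level in 60 ordered bins for one quintile of one sample.

    ``frame`` has one row per bin: region, bin_index, ordinal, protected,
    total, level (NaN when uncovered) and the number of genes contributing.
    """

    sample_id: str
    quintile: int
    frame: pd.DataFrame = field(repr=False)
    n_genes: int = 0

    def region_counts(self, region: str) -> tuple[int, int]:
        """Pooled (protected, total) over the 20 bins of *region*."""
        sub = self.frame[self.frame["region"] == region]
        return int(sub["protected"].sum()), int(sub["total"].sum())

    def region_level(self, region: str) -> float:
        p, t = self.region_counts(region)
        return p / t if t > 0 else float("nan")


class _ChromIndex:
    """Cumulative-count index over the sorted CG calls of one chromosome."""

    def __init__(self, cg: pd.DataFrame):
        self.pos = cg["pos"].to_numpy()
        self.cprot = np.concatenate([[0], np.cumsum(cg["protected"].to_numpy())])
        self.ctot = np.concatenate([[0], np.cumsum(cg["total"].to_numpy())])

    def counts(self, start: int, end: int) -> tuple[int, int]:
        lo = np.searchsorted(self.pos, start, side="left")
        hi = np.searchsorted(self.pos, end, side="left")
        return int(self.cprot[hi] - self.cprot[lo]), int(self.ctot[hi] - self.ctot[lo])


def compute_metagene(
    calls: CallTable,
    genes: list[GeneModel],
    assignment,
    flank_bin_size: int = FLANK_BIN_SIZE,
    n_flank_bins: int = N_FLANK_BINS,
    n_body_bins: int = N_BODY_BINS,
    chrom_lengths: dict[str, int] | None = None,
    gene_averaged: bool = False,
    protection_rate: float | None = None,
) -> dict[int, MetageneProfile]:
    """Quintile metagene profiles: pooled weighted 5hmCG level per bin.

    Counts are pooled across all member genes of a quintile before dividing
    (read-weighted). ``gene_averaged=True`` instead averages per-gene bin
    levels (unweighted across genes; counts columns stay pooled).
    ``protection_rate`` optionally divides every level (protection-scaled
    profiles); raw levels are the default.

    Genes shorter than the body bin count are skipped with a log message.
    """
    from .quintiles import QuintileAssignment

    if isinstance(assignment, QuintileAssignment):
        gene_to_q = assignment.assignment
    else:
        gene_to_q = pd.Series(assignment)

    n_bins = 2 * n_flank_bins + n_body_bins
    cg = calls.subset_context("CG")
    index = {chrom: _ChromIndex(sub) for chrom, sub in cg.groupby("chrom", sort=False)}
    quintiles = sorted(set(int(q) for q in gene_to_q.values))
    prot = {q: np.zeros(n_bins, dtype=np.int64) for q in quintiles}
    tot = {q: np.zeros(n_bins, dtype=np.int64) for q in quintiles}
    per_gene_levels: dict[int, list[np.ndarray]] = {q: [] for q in quintiles}
    n_genes = {q: 0 for q in quintiles}
    meta_rows = None
    n_skipped = 0

    for gene in genes:
        if gene.gene_id not in gene_to_q.index:
            continue
        q = int(gene_to_q[gene.gene_id])
        try:
            bins = build_gene_bins(
                gene, flank_bin_size, n_flank_bins, n_body_bins,
                None if chrom_lengths is None else chrom_lengths.get(gene.chrom),
            )
        except GeneTooShortError:
            n_skipped += 1
            continue
        if meta_rows is None:
            meta_rows = bins[["region", "bin_index", "ordinal"]].copy()
        n_genes[q] += 1
        cidx = index.get(gene.chrom)
        gp = np.zeros(n_bins, dtype=np.int64)
        gt = np.zeros(n_bins, dtype=np.int64)
        if cidx is not None:
            starts = bins["start"].to_numpy()
            ends = bins["end"].to_numpy()
            lo = np.searchsorted(cidx.pos, starts, side="left")
            hi = np.searchsorted(cidx.pos, ends, side="left")
            gp = cidx.cprot[hi] - cidx.cprot[lo]
            gt = cidx.ctot[hi] - cidx.ctot[lo]
        prot[q] += gp
        tot[q] += gt
        if gene_averaged:
            with np.errstate(invalid="ignore", divide="ignore"):
                per_gene_levels[q].append(np.where(gt > 0, gp / np.maximum(gt, 1), np.nan))

    if n_skipped:
        logger.info("skipped %d genes shorter than %d bp", n_skipped, n_body_bins)
    if meta_rows is None:
        raise ValidationError("no usable genes in the assignment")

    profiles: dict[int, MetageneProfile] = {}
    for q in quintiles:
        with np.errstate(invalid="ignore", divide="ignore"):
            if gene_averaged and per_gene_levels[q]:
                stacked = np.vstack(per_gene_levels[q])
                all_nan = np.all(np.isnan(stacked), axis=0)
                level = np.full(n_bins, np.nan)
                level[~all_nan] = np.nanmean(stacked[:, ~all_nan], axis=0)
            else:
                level = np.where(tot[q] > 0, prot[q] / np.maximum(tot[q], 1), np.nan)
        if protection_rate is not None:
            level = level / protection_rate
        frame = meta_rows.copy()
        frame["protected"] = prot[q]
        frame["total"] = tot[q]
        frame["level"] = level
        frame["n_genes"] = n_genes[q]
        if tot[q].sum() == 0:
            logger.warning("quintile %d has no covered bins; profile is all-missing", q)
        profiles[q] = MetageneProfile(
            sample_id=calls.sample_id, quintile=q, frame=frame, n_genes=n_genes[q]
        )
    return profiles


def profiles_to_frame(profiles: dict[int, MetageneProfile]) -> pd.DataFrame:
    """Long-format table (sample, quintile, region, bin_index, counts, level)."""
    parts = []
    for q in sorted(profiles):
        p = profiles[q]
        f = p.frame.copy()
        f.insert(0, "quintile", p.quintile)
        f.insert(0, "sample", p.sample_id)
        parts.append(f)
    return pd.concat(parts, ignore_index=True)


def subsample_calls(calls: CallTable, fraction: float, seed: int) -> CallTable:
    """Binomially thin a call table to *fraction* of its read observations.

    Each original read is retained independently with probability
    *fraction* (protected and converted reads thinned as independent
    binomials, which is the read-level retention law); sites left with no
    reads are dropped. ``fraction=1`` returns an identical copy. Coverage of
    the output is ~ fraction x input coverage.
    """
    if not 0 < fraction <= 1:
        raise ValidationError(f"fraction must be in (0, 1], got {fraction}")
    df = calls.calls
    if fraction == 1.0:
        return CallTable(calls.sample_id, calls.source_kind, df.copy())
    rng = np.random.default_rng(seed)
    protected = df["protected"].to_numpy()
    converted = df["total"].to_numpy() - protected
    new_prot = rng.binomial(protected, fraction)
    new_conv = rng.binomial(converted, fraction)
    out = df.copy()
    out["protected"] = new_prot
    out["total"] = new_prot + new_conv
    out = out[out["total"] > 0].reset_index(drop=True)
    return CallTable(calls.sample_id, calls.source_kind, out)


def plot_metagene(profiles: dict[int, MetageneProfile], path, title: str | None = None):
    """Three-panel (UTSS | GB | DTTS) metagene plot, one line per quintile."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 3, figsize=(10, 3.2), sharey=True)
    cmap = plt.get_cmap("viridis")
    for q in sorted(profiles):
        p = profiles[q]
        color = cmap((q - 1) / max(len(profiles) - 1, 1))
        for ax, region in zip(axes, REGIONS):
            sub = p.frame[p.frame["region"] == region]
            ax.plot(sub["bin_index"], sub["level"], color=color, label=f"Q{q}")
    for ax, region in zip(axes, REGIONS):
        ax.set_title(region)
        ax.set_xlabel("bin")
    axes[0].set_ylabel("weighted 5hmCG level")
    axes[-1].legend(fontsize=7)
    if title:
        fig.suptitle(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return str(path)
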