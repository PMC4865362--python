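"""Spike-in calibration and global %5hmCG quantification.

TAB-seq protects 5hmC (via beta-GT glucosylation) and converts everything
else, so a read reporting C is the 5hmC signal. Three rates calibrate the
assay, each a read-weighted pooled ratio (never a mean of per-site ratios):

* ``nonconv_5mC`` — reads-as-C at CG sites of the fully methylated lambda
  spike-in: the false-positive rate for 5mC after TET oxidation + bisulfite.
* ``nonconv_C`` — reads-as-C at genomic non-CG (CHG/CHH) cytosines: the
  false-positive rate for unmodified C after bisulfite.
* ``protection_rate`` — reads-as-C at CG sites of the fully
  hydroxymethylated pUC19 spike-in: the fraction of true 5hmC the assay
  recovers. Raw %5hmCG divided by this rate gives the scaled (true) %5hmCG.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

from .errors import UndefinedRateError, ValidationError
from .io import CallTable

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RateEstimate:
    """A pooled-count rate: ``rate = protected / total`` with its support."""

    rate: float
    protected: int
    total: int


@dataclass(frozen=True)
class CalibrationRates:
    """The three spike-in/control rates for one sample."""

    nonconv_5mC: RateEstimate
    nonconv_C: RateEstimate
    protection_rate: RateEstimate


@dataclass(frozen=True)
class GlobalLevel:
    """Genome-wide %5hmCG of one sample.

    ``pct_5hmCG`` is 100 x (pooled protected reads / pooled total reads) over
    CG-context calls; ``scaled_pct`` is that divided by the sample's pUC19
    protection rate (filled by :func:`scale_pct`). Full precision is kept
    internally; ``pct_display``/``scaled_display`` round half-even to two
    decimals for reporting.
    """

    total_5hmCG: int
    total_CG: int
    pct_5hmCG: float
    scaled_pct: float | None = None

    @property
    def pct_display(self) -> str:
        return f"{round(self.pct_5hmCG, 2):.2f}"

    @property
    def scaled_display(self) -> str:
        if self.scaled_pct is None:
            return "NA"
        return f"{round(self.scaled_pct, 2):.2f}"


def _pooled_rate(df, what: str) -> RateEstimate:
    protected = int(df["protected"].sum())
    total = int(df["total"].sum())
    if total == 0:
        raise UndefinedRateError(f"{what}: zero total coverage in selection")
    return RateEstimate(rate=protected / total, protected=protected, total=total)


def estimate_nonconversion_5mC(lambda_calls: CallTable) -> RateEstimate:
    """5mC non-conversion rate from CG sites of the fully-5mC lambda spike-in."""
    if lambda_calls.source_kind != "lambda_5mC":
        raise ValidationError(
            f"expected source_kind 'lambda_5mC', got {lambda_calls.source_kind!r}"
        )
    return _pooled_rate(lambda_calls.subset_context("CG"), "nonconv_5mC")


def estimate_nonconversion_C(genome_calls: CallTable) -> RateEstimate:
    """Unmodified-C non-conversion rate from genomic CHG/CHH cytosines."""
    return _pooled_rate(genome_calls.subset_context("CHG", "CHH"), "nonconv_C")


def estimate_protection_rate(puc19_calls: CallTable) -> RateEstimate:
    """5hmC protection rate from CG sites of the fully-5hmC pUC19 spike-in."""
    if puc19_calls.source_kind != "pUC19_5hmC":
        raise ValidationError(
            f"expected source_kind 'pUC19_5hmC', got {puc19_calls.source_kind!r}"
        )
    return _pooled_rate(puc19_calls.subset_context("CG"), "protection_rate")


def calibrate(
    lambda_calls: CallTable, genome_calls: CallTable, puc19_calls: CallTable
) -> CalibrationRates:
    """All three calibration rates for one sample."""
    return CalibrationRates(
        nonconv_5mC=estimate_nonconversion_5mC(lambda_calls),
        nonconv_C=estimate_nonconversion_C(genome_calls),
        protection_rate=estimate_protection_rate(puc19_calls),
    )


def global_5hmCG(genome_calls: CallTable, site_level: bool = False) -> GlobalLevel:
    """Global %5hmCG: pooled protected CG reads over pooled total CG reads x 100.

    ``site_level=True`` switches to the unweighted mean of per-site ratios
    (sensitivity analysis only); counts then report the number of sites with
    any protected read and the number of covered CG sites.
    """
    cg = genome_calls.subset_context("CG")
    if len(cg) == 0 or cg["total"].sum() == 0:
        raise UndefinedRateError("global_5hmCG: no covered CG-context calls")
    if site_level:
        covered = cg[cg["total"] > 0]
        pct = 100.0 * float((covered["protected"] / covered["total"]).mean())
        return GlobalLevel(
            total_5hmCG=int((covered["protected"] > 0).sum()),
            total_CG=int(len(covered)),
            pct_5hmCG=pct,
        )
    est = _pooled_rate(cg, "global_5hmCG")
    return GlobalLevel(
        total_5hmCG=est.protected, total_CG=est.total, pct_5hmCG=100.0 * est.rate
    )


def scale_pct(level: GlobalLevel, rates: CalibrationRates | RateEstimate | float) -> GlobalLevel:
    """Fill ``scaled_pct = pct_5hmCG / protection_rate`` (capped at 100%).

    Accepts the full :class:`CalibrationRates`, the protection
    :class:`RateEstimate`, or a bare float.
    """
    if isinstance(rates, CalibrationRates):
        protection = rates.protection_rate.rate
    elif isinstance(rates, RateEstimate):
        protection = rates.rate
    else:
        protection = float(rates)
    if protection <= 0:
        raise UndefinedRateError("protection rate must be > 0 to scale %5hmCG")
    scaled = level.pct_5hmCG / protection
    if scaled > 100.0:
        warnings.warn(
            f"scaled %5hmCG {scaled:.2f} exceeds 100%; capping (protection rate "
            f"{protection:.4f} is implausibly low for this sample)",
            stacklevel=2,
        )
        scaled = 100.0
    return replace(level, scaled_pct=scaled)


def estimate_coverage(genome_calls: CallTable, n_reference_cytosines: int) -> float:
    """Genome-equivalents coverage: mean read depth per reference cytosine.

    Pooled read observations over all calls (any context) divided by the
    number of cytosines in the reference; the proxy for the 'fraction of
    genome equivalents' coverage metric.
    """
    if n_reference_cytosines <= 0:
        raise ValidationError("n_reference_cytosines must be > 0")
    return float(genome_calls.calls["total"].sum()) / float(n_reference_cytosines)
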