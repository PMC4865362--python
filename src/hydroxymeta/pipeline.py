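"""End-to-end conveniences tying the stages together.

These are thin orchestration wrappers over the module APIs; every step is
available individually for custom workflows.
"""

from __future__ import annotations

import pandas as pd

from .calibration import (
    CalibrationRates,
    calibrate,
    estimate_coverage,
    global_5hmCG,
    scale_pct,
)
from .metagene import MetageneProfile, compute_metagene
from .quintiles import QuintileAssignment, assign_quintiles, normalize_expression
from .simulate import SimulatedDataset
from .stats import gene_body_fold_change


def quintile_metagene(
    dataset: SimulatedDataset, gene_averaged: bool = False
) -> tuple[QuintileAssignment, dict[int, MetageneProfile]]:
    """Expression normalisation -> quintile assignment -> metagene profiles."""
    scores = normalize_expression(dataset.expression, dataset.genes)
    assignment = assign_quintiles(scores)
    cfg = dataset.config
    profiles = compute_metagene(
        dataset.genome_calls,
        dataset.genes,
        assignment,
        flank_bin_size=cfg.flank_bin_size,
        n_flank_bins=cfg.n_flank_bins,
        n_body_bins=cfg.n_body_bins,
        chrom_lengths=dataset.chrom_lengths,
        gene_averaged=gene_averaged,
    )
    return assignment, profiles


def dataset_fold_change(dataset: SimulatedDataset) -> float:
    """Full-pipeline quintile-5 / quintile-1 pooled gene-body fold change."""
    _, profiles = quintile_metagene(dataset)
    return gene_body_fold_change(profiles[5], profiles[1])


def calibration_summary(dataset: SimulatedDataset) -> pd.DataFrame:
    """One-row QC summary: rates with counts, raw/scaled %5hmCG, coverage."""
    rates: CalibrationRates = calibrate(
        dataset.lambda_calls, dataset.genome_calls, dataset.puc19_calls
    )
    level = scale_pct(global_5hmCG(dataset.genome_calls), rates)
    coverage = estimate_coverage(dataset.genome_calls, dataset.n_reference_cytosines)
    return pd.DataFrame(
        [
            {
                "sample": dataset.config.sample_id,
                "nonconv_5mC": rates.nonconv_5mC.rate,
                "nonconv_5mC_protected": rates.nonconv_5mC.protected,
                "nonconv_5mC_total": rates.nonconv_5mC.total,
                "nonconv_C": rates.nonconv_C.rate,
                "nonconv_C_protected": rates.nonconv_C.protected,
                "nonconv_C_total": rates.nonconv_C.total,
                "protection_rate": rates.protection_rate.rate,
                "protection_protected": rates.protection_rate.protected,
                "protection_total": rates.protection_rate.total,
                "total_5hmCG": level.total_5hmCG,
                "total_CG": level.total_CG,
                "pct_5hmCG": level.pct_5hmCG,
                "scaled_pct_5hmCG": level.scaled_pct,
                "coverage": coverage,
            }
        ]
    )
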