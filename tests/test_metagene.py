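"""Bin geometry, weighted levels, quintile pooling, and subsampling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hydroxymeta import (
    CallTable,
    GeneModel,
    SimulationConfig,
    build_gene_bins,
    compute_metagene,
    simulate_dataset,
    subsample_calls,
    weighted_level,
)
from hydroxymeta.errors import ValidationError
from hydroxymeta.metagene import GeneTooShortError

COLS = ["chrom", "pos", "strand", "context", "protected", "total"]


def calls_from(rows, sample="s"):
    return CallTable(sample, "genome", pd.DataFrame(rows, columns=COLS))


class TestBinGeometry:
    def test_upstream_flank_spans_exactly_100kb_at_paper_scale(self):
        gene = GeneModel("g", "c", "+", 500_000, 600_000, 1000)
        bins = build_gene_bins(gene, flank_bin_size=5000)
        utss = bins[bins["region"] == "UTSS"]
        assert len(utss) == 20
        assert int((utss["end"] - utss["start"]).sum()) == 100_000
        assert utss["start"].min() == 400_000 and utss["end"].max() == 500_000

    def test_length_20_gene_gets_20_one_bp_body_bins(self):
        gene = GeneModel("g", "c", "+", 100, 120, 10)
        gb = build_gene_bins(gene)[lambda d: d["region"] == "GB"]
        assert list(gb["end"] - gb["start"]) == [1] * 20

    def test_floor_rule_widths_for_length_50(self):
        gene = GeneModel("g", "c", "+", 0, 50, 10)
        gb = build_gene_bins(gene)[lambda d: d["region"] == "GB"]
        widths = list(gb["end"] - gb["start"])
        # floor rule: boundaries floor(k*50/20) -> alternating 2,3 widths
        assert widths == [2, 3] * 10
        assert sum(widths) == 50

    @given(
        length=st.integers(20, 4003),
        start=st.integers(0, 10_000),
        strand=st.sampled_from(["+", "-"]),
    )
    @settings(max_examples=60, deadline=None)
    def test_body_bins_partition_gene_exactly(self, length, start, strand):
        gene = GeneModel("g", "c", strand, start, start + length, 1)
        bins = build_gene_bins(gene, flank_bin_size=50)
        gb = bins[bins["region"] == "GB"].sort_values("start")
        assert gb["start"].iloc[0] == start
        assert gb["end"].iloc[-1] == start + length
        assert (gb["start"].iloc[1:].to_numpy() == gb["end"].iloc[:-1].to_numpy()).all()
        # flanks never intrude into the body
        flanks = bins[bins["region"] != "GB"]
        assert ((flanks["end"] <= start) | (flanks["start"] >= start + length)).all()

    def test_minus_strand_bins_run_in_gene_orientation(self):
        gene = GeneModel("g", "c", "-", 1000, 2000, 10)
        bins = build_gene_bins(gene, flank_bin_size=100)
        utss = bins[bins["region"] == "UTSS"]
        # bin 0 is farthest upstream = genomically rightmost for minus strand
        assert utss.iloc[0]["start"] == 2000 + 1900
        assert utss.iloc[-1]["start"] == 2000  # adjacent to the TSS
        gb = bins[bins["region"] == "GB"]
        assert gb.iloc[0]["end"] == 2000  # first body bin touches the TSS
        dtts = bins[bins["region"] == "DTTS"]
        assert dtts.iloc[0]["end"] == 1000  # first downstream bin touches the TTS

    def test_short_gene_signals_skip(self):
        with pytest.raises(GeneTooShortError):
            build_gene_bins(GeneModel("g", "c", "+", 0, 19, 1))

    def test_flanks_clipped_at_contig_start_and_flagged(self):
        gene = GeneModel("g", "c", "+", 500, 600, 10)
        bins = build_gene_bins(gene, flank_bin_size=100)
        utss = bins[bins["region"] == "UTSS"]
        assert (utss["start"] >= 0).all()
        assert utss["clipped"].any()
        assert not bins[bins["region"] == "GB"]["clipped"].any()


class TestWeightedLevel:
    def test_all_protected_interval_is_one(self):
        calls = calls_from([["c", 5, "+", "CG", 3, 3], ["c", 8, "-", "CG", 2, 2]])
        assert weighted_level(calls, "c", 0, 10)[2] == 1.0

    def test_pooling_distinguishes_weighted_from_site_mean(self):
        calls = calls_from([["c", 1, "+", "CG", 1, 2], ["c", 5, "+", "CG", 1, 18]])
        p, t, level = weighted_level(calls, "c", 0, 10)
        assert (p, t) == (2, 20)
        assert level == pytest.approx(0.10)
        assert level != pytest.approx((0.5 + 1 / 18) / 2)

    def test_interval_without_cg_calls_is_missing(self):
        calls = calls_from([["c", 1, "+", "CHH", 1, 2]])
        p, t, level = weighted_level(calls, "c", 0, 10)
        assert (p, t) == (0, 0) and np.isnan(level)

    def test_non_cg_calls_excluded_from_pool(self):
        calls = calls_from([["c", 1, "+", "CG", 1, 4], ["c", 2, "+", "CHG", 3, 3]])
        assert weighted_level(calls, "c", 0, 10)[:2] == (1, 4)


class TestComputeMetagene:
    def test_single_gene_single_covered_bin_reduces_to_weighted_level(self):
        gene = GeneModel("g", "c", "+", 100, 140, 10)
        calls = calls_from([["c", 105, "+", "CG", 2, 5]])
        profiles = compute_metagene(calls, [gene], {"g": 1}, flank_bin_size=10)
        frame = profiles[1].frame
        covered = frame[frame["total"] > 0]
        assert len(covered) == 1
        row = covered.iloc[0]
        assert (row["region"], row["bin_index"]) == ("GB", 2)  # 105 in [104,106)
        assert row["level"] == pytest.approx(2 / 5)
        assert frame[frame["total"] == 0]["level"].isna().all()

    def test_quintile_pooling_matches_brute_force_read_oracle(self):
        rng = np.random.default_rng(42)
        genes = [
            GeneModel("gA", "c", "+", 1000, 1200, 10),
            GeneModel("gB", "c", "-", 2000, 2300, 10),
            GeneModel("gC", "c", "+", 3000, 3040, 10),
        ]
        assignment = {"gA": 1, "gB": 1, "gC": 2}
        rows = []
        for pos in rng.choice(np.arange(500, 3500), size=300, replace=False):
            total = int(rng.integers(1, 6))
            rows.append(["c", int(pos), rng.choice(["+", "-"]),
                         rng.choice(["CG", "CHH"]), int(rng.integers(0, total + 1)), total])
        calls = calls_from(sorted(rows, key=lambda r: (r[0], r[1], r[2])))
        B = 25
        profiles = compute_metagene(calls, genes, assignment, flank_bin_size=B)

        # oracle: per-read assignment by explicit interval arithmetic
        def bins_of(g):
            out = []
            L = g.end - g.start
            if g.strand == "+":
                for i in range(20):
                    out.append(("UTSS", i, g.start - (20 - i) * B, g.start - (19 - i) * B))
                for k in range(20):
                    out.append(("GB", k, g.start + k * L // 20, g.start + (k + 1) * L // 20))
                for j in range(20):
                    out.append(("DTTS", j, g.end + j * B, g.end + (j + 1) * B))
            else:
                for i in range(20):
                    out.append(("UTSS", i, g.end + (19 - i) * B, g.end + (20 - i) * B))
                for k in range(20):
                    out.append(("GB", k, g.end - (k + 1) * L // 20, g.end - k * L // 20))
                for j in range(20):
                    out.append(("DTTS", j, g.start - (j + 1) * B, g.start - j * B))
            return out

        for q in (1, 2):
            expected = {}
            for g in genes:
                if assignment[g.gene_id] != q:
                    continue
                for ordinal, (region, idx, s, e) in enumerate(bins_of(g)):
                    pr = to = 0
                    for r in calls.calls.itertuples(index=False):
                        if r.context == "CG" and s <= r.pos < e:
                            pr, to = pr + r.protected, to + r.total
                    key = (region, idx)
                    acc = expected.get(key, (0, 0))
                    expected[key] = (acc[0] + pr, acc[1] + to)
            frame = profiles[q].frame
            for row in frame.itertuples(index=False):
                assert (row.protected, row.total) == expected[(row.region, row.bin_index)]

    def test_uniform_methylome_gives_flat_profiles_without_tss_dip(self):
        cfg = SimulationConfig(
            seed=13, chrom_lengths=(120_000, 120_000), n_genes=40, coverage=2.0,
            gb_protected_probs=(0.02,) * 5, background_cg_prob=0.02,
        )
        ds = simulate_dataset(cfg)
        from hydroxymeta.pipeline import quintile_metagene

        _, profiles = quintile_metagene(ds)
        p0 = 0.02
        z_all, tss_bins = [], []
        for q, prof in profiles.items():
            f = prof.frame[prof.frame["total"] > 0]
            z = (f["level"] - p0) / np.sqrt(p0 * (1 - p0) / f["total"])
            z_all.extend(z.tolist())
            tss_bins.extend(z[(f["region"] == "GB") & (f["bin_index"] == 0)].tolist())
        z_all = np.array(z_all)
        assert (np.abs(z_all) <= 3).mean() >= 0.99
        # no systematic depression at the TSS-adjacent body bin
        assert abs(np.mean(tss_bins)) < 2.0

    def test_configured_enrichment_appears_only_in_the_enriched_quintile(self):
        cfg = SimulationConfig(
            seed=17, chrom_lengths=(120_000, 120_000), n_genes=40, coverage=2.0,
            gb_protected_probs=(0.02, 0.02, 0.02, 0.02, 0.08), background_cg_prob=0.02,
        )
        ds = simulate_dataset(cfg)
        from hydroxymeta.pipeline import quintile_metagene

        _, profiles = quintile_metagene(ds)
        for q in (1, 5):
            gb = profiles[q].region_level("GB")
            flank = np.nanmean([profiles[q].region_level("UTSS"),
                                profiles[q].region_level("DTTS")])
            if q == 5:
                assert gb > 2 * flank
            else:
                n = profiles[q].region_counts("GB")[1]
                assert abs(gb - flank) < 4 * np.sqrt(0.02 * 0.98 / n)

    def test_mirror_symmetry_of_profiles(self, small_dataset):
        """Reverse-complementing the genome (mirroring coordinates and
        flipping strands) leaves every quintile profile unchanged."""
        from hydroxymeta.pipeline import quintile_metagene

        ds = small_dataset
        _, profiles = quintile_metagene(ds)
        N = max(ds.chrom_lengths.values())
        flip = {"+": "-", "-": "+"}
        mirrored_calls = ds.genome_calls.calls.copy()
        mirrored_calls["pos"] = N - 1 - mirrored_calls["pos"]
        mirrored_calls["strand"] = mirrored_calls["strand"].map(flip)
        mcalls = CallTable(ds.genome_calls.sample_id, "genome", mirrored_calls)
        mgenes = [
            GeneModel(g.gene_id, g.chrom, flip[g.strand], N - g.end, N - g.start,
                      g.exonic_length)
            for g in ds.genes
        ]
        from hydroxymeta import assign_quintiles, normalize_expression

        assignment = assign_quintiles(normalize_expression(ds.expression, ds.genes))
        mprofiles = compute_metagene(
            mcalls, mgenes, assignment,
            flank_bin_size=ds.config.flank_bin_size,
            chrom_lengths={c: N for c in ds.chrom_lengths},
        )
        for q in profiles:
            a = profiles[q].frame
            b = mprofiles[q].frame
            assert list(a["protected"]) == list(b["protected"])
            assert list(a["total"]) == list(b["total"])


class TestSubsampling:
    def test_fraction_one_is_identity(self, three_row_table):
        assert subsample_calls(three_row_table, 1.0, seed=0) == three_row_table

    def test_fraction_above_one_rejected(self, three_row_table):
        with pytest.raises(ValidationError):
            subsample_calls(three_row_table, 1.5, seed=0)

    def test_half_thinning_halves_read_totals_within_3_sd(self):
        n_sites, depth = 20_000, 5
        df = pd.DataFrame({
            "chrom": "c", "pos": np.arange(n_sites), "strand": "+",
            "context": "CG", "protected": 1, "total": depth,
        })[COLS]
        table = CallTable("s", "genome", df)
        out = subsample_calls(table, 0.5, seed=1)
        n = n_sites * depth
        assert abs(out.calls["total"].sum() - n / 2) <= 3 * np.sqrt(n * 0.25)
        assert (out.calls["total"] > 0).all()

    def test_thinning_is_deterministic_given_seed(self, small_dataset):
        a = subsample_calls(small_dataset.genome_calls, 0.3, seed=5)
        b = subsample_calls(small_dataset.genome_calls, 0.3, seed=5)
        assert a == b

    def test_subsampled_profiles_track_full_profiles(self, small_dataset):
        """Thinned data reproduce bin levels within binomial noise and keep
        the extreme-quintile gene-body contrast at every fraction."""
        from hydroxymeta import assign_quintiles, normalize_expression

        ds = small_dataset
        assignment = assign_quintiles(normalize_expression(ds.expression, ds.genes))
        kwargs = dict(flank_bin_size=ds.config.flank_bin_size,
                      chrom_lengths=ds.chrom_lengths)
        full = compute_metagene(ds.genome_calls, ds.genes, assignment, **kwargs)
        for fraction in (1.0, 0.5, 0.1):
            thin = subsample_calls(ds.genome_calls, fraction, seed=23)
            profiles = compute_metagene(thin, ds.genes, assignment, **kwargs)
            agree, n_bins = 0, 0
            for q in full:
                f, s = full[q].frame, profiles[q].frame
                mask = (f["total"] > 0) & (s["total"] > 0)
                sd = np.sqrt(f["level"] * (1 - f["level"]) / s["total"])
                ok = np.abs(s["level"] - f["level"]) <= 3 * np.maximum(sd, 1e-12)
                agree += int(ok[mask].sum())
                n_bins += int(mask.sum())
            assert agree / n_bins >= 0.98
            assert profiles[5].region_level("GB") > profiles[1].region_level("GB")
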