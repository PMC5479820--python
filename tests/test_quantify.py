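"""Coverage summaries, RPKM, CNV flagging, scaling and the analysis set."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from hybrase import (CnvRegion, PipelineConfig, ScenarioConfig,
                     build_analysis_set, compute_mask, detect_cnv,
                     generate_scenario, scale_chromosome_coverage,
                     simulate_coverage, summarize_all, summarize_unit)
from hybrase.data import CHROMOSOME, CoverageTrack, OrthologUnit, UnitLocus
from hybrase.mappability import MappabilityMask
from hybrase.quantify import UnitCoverageSummary, scale_coverage_sets


def full_mask(n, sp_names=("v", "m"), replicon="chr"):
    return MappabilityMask(
        mappable={sp: {f"{sp}_{replicon}": np.ones(n, dtype=bool)} for sp in sp_names},
        window_length=75)


def gene_unit(oid, start, end, replicon="chr", klass=CHROMOSOME):
    loci = {sp: UnitLocus(f"{sp}_{replicon}", klass, start, end, "+")
            for sp in ("v", "m")}
    return OrthologUnit(oid, "gene", [oid], loci)


class TestSummarizeUnit:
    def test_uniform_coverage_rpkm_arithmetic(self):
        # 1,000 fully mappable bases at coverage 75, read length 75,
        # 1e6 assigned reads -> 1,000 read equivalents, RPKM 1,000
        track = CoverageTrack("v_chr", np.full(2_000, 75.0))
        unit = gene_unit("og1", 500, 1_500)
        s = summarize_unit(track, unit, "v", full_mask(2_000), read_length=75,
                           total_assigned_reads=1e6)
        assert s.reads_equivalent == pytest.approx(1_000.0)
        assert s.rpkm == pytest.approx(1_000.0)

    def test_zero_track_gives_zero_rpkm(self):
        track = CoverageTrack("v_chr", np.zeros(100))
        s = summarize_unit(track, gene_unit("og1", 10, 60), "v", full_mask(100),
                           read_length=75, total_assigned_reads=1e4)
        assert s.sum_coverage == 0
        assert s.rpkm == 0

    def test_masked_positions_excluded(self, rng):
        n = 300
        values = rng.integers(0, 40, n).astype(float)
        mask = full_mask(n)
        keep = rng.random(n) < 0.6
        mask.mappable["v"]["v_chr"] = keep
        unit = gene_unit("og1", 50, 250)
        s = summarize_unit(CoverageTrack("v_chr", values), unit, "v", mask,
                           read_length=75, total_assigned_reads=1e4)
        # position-by-position oracle over the masked index set
        expected = sum(values[i] for i in range(50, 250) if keep[i])
        assert s.sum_coverage == pytest.approx(expected)
        assert s.mappable_length == int(keep[50:250].sum())

    def test_zero_mappable_gives_nan_rpkm(self):
        mask = full_mask(100)
        mask.mappable["v"]["v_chr"][:] = False
        s = summarize_unit(CoverageTrack("v_chr", np.ones(100)),
                           gene_unit("og1", 10, 60), "v", mask,
                           read_length=75, total_assigned_reads=1e4)
        assert s.mappable_length == 0
        assert np.isnan(s.rpkm)

    def test_rpkm_invariant_under_joint_rescaling(self):
        track = CoverageTrack("v_chr", np.arange(100, dtype=float))
        unit = gene_unit("og1", 10, 90)
        a = summarize_unit(track, unit, "v", full_mask(100), 75, 1e5)
        b = summarize_unit(CoverageTrack("v_chr", track.values * 7), unit, "v",
                           full_mask(100), 75, 7e5)
        assert a.rpkm == pytest.approx(b.rpkm)


def summary_frame(rpkms_by_series):
    """Build a DNA summary frame: {(species, replicate): [rpkm per unit]}."""
    rows = []
    for (sp, rep), rpkms in rpkms_by_series.items():
        for i, r in enumerate(rpkms):
            rows.append({"ortholog_id": f"og{i}", "species": sp, "assay": "DNA",
                         "replicate": rep, "rpkm": float(r),
                         "replicon_class": CHROMOSOME})
    return pd.DataFrame(rows)


class TestDetectCnv:
    def test_degenerate_sd_flags_nothing(self):
        df = summary_frame({("v", 1): [10, 10, 10, 10]})
        assert detect_cnv(df, 2.0) == set()

    def test_hand_computed_threshold(self):
        # rpkms (10,10,10,10,40): mean 16, sample SD 13.416 -> 40 inside
        df = summary_frame({("v", 1): [10, 10, 10, 10, 40]})
        assert detect_cnv(df, 2.0) == set()
        # (10,10,10,10,100): mean 28, SD 40.25 -> 100 < 28+80.5 inside;
        # with threshold 1.5 SD: 28+60.4 < 100 -> flagged
        df = summary_frame({("v", 1): [10, 10, 10, 10, 100]})
        assert detect_cnv(df, 2.0) == set()
        assert detect_cnv(df, 1.5) == {"og4"}

    def test_any_of_four_series_flags(self):
        # og0 is an outlier only in the v series, og9 only in the m series;
        # the any-of-series rule takes the union
        df = summary_frame({
            ("v", 1): [30] + [10] * 9,
            ("m", 1): [10] * 9 + [60],
        })
        assert detect_cnv(df, 2.0) == {"og0", "og9"}

    def test_pooled_mode_uses_one_series(self):
        # pooled: mean 13.5, SD 11.8 -> only the 60 crosses 2 SD
        df = summary_frame({
            ("v", 1): [30] + [10] * 9,
            ("m", 1): [10] * 9 + [60],
        })
        assert detect_cnv(df, 2.0, pooling="pooled") == {"og9"}

    def test_planted_cnv_region_flagged_in_simulation(self):
        cfg = ScenarioConfig(
            genome_length=60_000, n_orthologs=80, plasmid_fraction=0.0,
            rng_seed=31, cnv_regions=[CnvRegion("v", "v_chr", 0, 2_500, 4.0)])
        scenario = generate_scenario(cfg)
        coverages = {a: {r: simulate_coverage(scenario, a, r) for r in (1, 2)}
                     for a in ("DNA", "RNA")}
        mask = compute_mask(scenario.pair, 75)
        summaries = summarize_all(coverages, scenario.units, scenario.pair, mask, 75)
        flagged = detect_cnv(summaries, 2.0)
        amplified = {u.ortholog_id for u in scenario.units
                     if u.loci["v"].end <= 2_500}
        assert amplified
        assert amplified <= flagged
        # the 2-SD rule has an inherent chance-flag rate (~5% per series);
        # unamplified units should only be flagged at that background level
        clean = {u.ortholog_id for u in scenario.units if u.loci["v"].start >= 3_000}
        assert len(flagged & clean) / len(clean) < 0.3


class TestScaling:
    def test_equal_totals_returned_unchanged(self):
        high = CoverageTrack("v_chr", np.array([2.0, 3.0, 1.0]))
        low = CoverageTrack("m_chr", np.array([1.0, 1.0, 4.0]))
        scaled = scale_chromosome_coverage(high, low)
        assert np.array_equal(scaled.values, high.values)

    def test_linear_scaling_example(self):
        scaled = scale_chromosome_coverage(
            CoverageTrack("v_chr", np.array([4.0, 6.0])),
            CoverageTrack("m_chr", np.array([2.0, 3.0])))
        assert np.allclose(scaled.values, [2.0, 3.0])

    def test_zero_low_total_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            scale_chromosome_coverage(
                CoverageTrack("v_chr", np.ones(3)),
                CoverageTrack("m_chr", np.zeros(3)))

    @settings(max_examples=40, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_total_conserved_on_random_tracks(self, seed):
        r = np.random.default_rng(seed)
        n = int(r.integers(2, 500))
        high = r.gamma(2.0, 10.0, n)
        low = high * r.uniform(0.1, 1.0)
        scaled = scale_chromosome_coverage(CoverageTrack("a", high),
                                           CoverageTrack("b", low))
        assert abs(scaled.values.sum() - low.sum()) <= 1e-9 * low.sum()

    def test_pipeline_scaling_removes_dna_imbalance(self):
        cfg = ScenarioConfig(genome_length=30_000, n_orthologs=40,
                             plasmid_fraction=0.0, rng_seed=33,
                             replicate_depth_imbalance=1.4)
        scenario = generate_scenario(cfg)
        coverages = {a: {r: simulate_coverage(scenario, a, r) for r in (1, 2)}
                     for a in ("DNA", "RNA")}
        mask = compute_mask(scenario.pair, 75)
        scaled = scale_coverage_sets(coverages, scenario.pair, mask)

        def total(cov, assay, rep, sp):
            return cov[assay][rep][sp][f"{sp}_chr"].values[
                mask.mappable[sp][f"{sp}_chr"]].sum()

        for rep in (1, 2):
            # DNA totals equalized exactly
            assert total(scaled, "DNA", rep, "v") == pytest.approx(
                total(scaled, "DNA", rep, "m"), rel=1e-12)
            # both assays of the high parent shrink by the same DNA factor
            dna_factor = min(
                total(coverages, "DNA", rep, sp2) / total(coverages, "DNA", rep, sp1)
                for sp1, sp2 in (("v", "m"), ("m", "v")))
            high = "v" if total(coverages, "DNA", rep, "v") >= total(coverages, "DNA", rep, "m") else "m"
            assert total(scaled, "RNA", rep, high) == pytest.approx(
                total(coverages, "RNA", rep, high) * dna_factor, rel=1e-12)
            low = "m" if high == "v" else "v"
            assert np.array_equal(scaled["RNA"][rep][low][f"{low}_chr"].values,
                                  coverages["RNA"][rep][low][f"{low}_chr"].values)


class TestAnalysisSet:
    @pytest.fixture(scope="class")
    @staticmethod
    def scenario_run():
        cfg = ScenarioConfig(genome_length=60_000, n_orthologs=80,
                             plasmid_fraction=0.25, rng_seed=35,
                             cnv_regions=[CnvRegion("v", "v_chr", 0, 6_000, 4.0)])
        scenario = generate_scenario(cfg)
        coverages = {a: {r: simulate_coverage(scenario, a, r) for r in (1, 2)}
                     for a in ("DNA", "RNA")}
        mask = compute_mask(scenario.pair, 75)
        summaries = summarize_all(coverages, scenario.units, scenario.pair, mask, 75)
        return scenario, summaries

    def test_plasmid_precedes_other_reasons(self, scenario_run):
        scenario, summaries = scenario_run
        aset = build_analysis_set(summaries, scenario.units, PipelineConfig())
        for u in scenario.units:
            if u.loci["v"].replicon_class == "plasmid":
                assert aset.excluded[u.ortholog_id] == "plasmid"

    def test_retained_matches_set_difference_oracle(self, scenario_run):
        scenario, summaries = scenario_run
        cfg = PipelineConfig()
        cnv = detect_cnv(summaries, cfg.cnv_sd_threshold)
        aset = build_analysis_set(summaries, scenario.units, cfg, cnv)
        rna = summaries[summaries["assay"] == "RNA"]
        low = set()
        for u in scenario.units:
            sub = rna[rna["ortholog_id"] == u.ortholog_id]
            for rep in (1, 2):
                if sub[sub["replicate"] == rep]["reads_equivalent"].sum() < cfg.min_reads:
                    low.add(u.ortholog_id)
        plasmid = {u.ortholog_id for u in scenario.units
                   if u.loci["v"].replicon_class == "plasmid"}
        expected = {u.ortholog_id for u in scenario.units} - plasmid - cnv - low
        assert set(aset.retained) == expected
        assert set(aset.retained) | set(aset.excluded) == \
            {u.ortholog_id for u in scenario.units}

    def test_low_reads_in_one_replicate_excludes(self, scenario_run):
        scenario, summaries = scenario_run
        summaries = summaries.copy()
        target = next(u.ortholog_id for u in scenario.units
                      if u.loci["v"].replicon_class == CHROMOSOME
                      and u.loci["v"].start >= 12_000)
        sel = ((summaries["ortholog_id"] == target)
               & (summaries["assay"] == "RNA") & (summaries["replicate"] == 2))
        summaries.loc[sel, "reads_equivalent"] = 49.0
        aset = build_analysis_set(summaries, scenario.units, PipelineConfig(),
                                  cnv_flagged=set())
        assert aset.excluded[target] == "low_reads"
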