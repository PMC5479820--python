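"""End-to-end orchestration: scenario -> mask -> quantify -> ASE -> selection.

Thin glue over the library modules: each stage function takes and
returns the in-memory objects, and :func:`run_all` chains them on a
(synthetic or loaded) dataset, writing every results table.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import io as hio
from .ase import AseModel, AseResults
from .config import PipelineConfig
from .data import GenomePair, OrthologUnit
from .mappability import MappabilityMask, compute_mask
from .quantify import (AnalysisSet, build_analysis_set, detect_cnv,
                       scale_coverage_sets, summarize_all)
from .selection import (OperonSimilarityTest, OperonTestResults, SignTest,
                        SignTestResults, select_biased)
from .simulate import DNA, RNA, Scenario, ScenarioConfig, generate_scenario, simulate_coverage

__all__ = ["PipelineData", "PipelineRun", "simulate_dataset", "load_dataset", "run_all"]


@dataclass
class PipelineData:
    """The inputs one pipeline run consumes."""

    pair: GenomePair
    units: list[OrthologUnit]
    coverages: dict  # assay -> replicate -> species -> {replicon: CoverageTrack}
    catalog: pd.DataFrame | None = None
    scenario: Scenario | None = None


@dataclass
class PipelineRun:
    """Everything a full run produced, for inspection or writing."""

    data: PipelineData
    config: PipelineConfig
    mask: MappabilityMask
    summaries: pd.DataFrame
    analysis_set: AnalysisSet
    ase: AseResults
    operon: OperonTestResults | None
    sign_tests: dict[str, SignTestResults]

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        cfg = self.config
        for sp in self.data.pair.species:
            self.mask.write_bed(sp, outdir / f"masked_{sp}.bed")
        hio.write_table(self.summaries, outdir / "summaries.tsv", cfg)
        hio.write_table(self.analysis_set.to_frame(), outdir / "analysis_set.tsv", cfg)
        self.ase.to_tsv(outdir / "ase_calls.tsv")
        if self.operon is not None:
            self.operon.to_tsv(outdir / "operon_test.tsv")
        if self.data.catalog is not None:
            frames = [r.results for r in self.sign_tests.values()]
            combined = pd.concat(frames, ignore_index=True) if frames else \
                pd.DataFrame(columns=["category_id", "mode", "n", "k", "chi2",
                                      "nominal_p", "perm_p"])
            hio.write_table(combined, outdir / "sign_test.tsv", cfg)


def simulate_dataset(scenario_config: ScenarioConfig) -> PipelineData:
    """Generate a synthetic hybrid experiment as pipeline input."""
    scenario = generate_scenario(scenario_config)
    coverages = {
        assay: {rep: simulate_coverage(scenario, assay, rep)
                for rep in range(1, scenario_config.n_replicates + 1)}
        for assay in (DNA, RNA)}
    return PipelineData(pair=scenario.pair, units=scenario.units,
                        coverages=coverages, catalog=scenario.catalog,
                        scenario=scenario)


def load_dataset(genome_fasta, annotations_tsv, coverage_paths: dict,
                 catalog_tsv=None) -> PipelineData:
    """Load a dataset from disk.

    ``coverage_paths[assay][replicate][species]`` is a bedGraph path
    covering all of that species' replicons.
    """
    pair = hio.read_genome_pair(genome_fasta)
    units = hio.load_annotations(annotations_tsv)
    coverages = {}
    for assay, by_rep in coverage_paths.items():
        coverages[assay] = {}
        for rep, by_sp in by_rep.items():
            coverages[assay][rep] = {
                sp: hio.load_coverage_set(path, pair.lengths(sp))
                for sp, path in by_sp.items()}
    catalog = hio.load_catalog(catalog_tsv) if catalog_tsv else None
    return PipelineData(pair=pair, units=units, coverages=coverages, catalog=catalog)


def run_all(data: PipelineData, config: PipelineConfig | None = None,
            run_operon_test: bool = True) -> PipelineRun:
    """Run every stage on one dataset and return the bundled results."""
    cfg = config or PipelineConfig()
    mask = compute_mask(data.pair, cfg.read_length)
    summaries = summarize_all(data.coverages, data.units, data.pair, mask,
                              cfg.read_length)
    cnv = detect_cnv(summaries, cfg.cnv_sd_threshold, cfg.cnv_pooling)
    analysis_set = build_analysis_set(summaries, data.units, cfg, cnv)
    scaled = scale_coverage_sets(data.coverages, data.pair, mask)
    rna_scaled = scaled[RNA]

    model = AseModel.from_pipeline(data.pair, data.units, mask, rna_scaled,
                                   analysis_set, cfg)
    ase_results = model.fit()

    operon_results = None
    if run_operon_test:
        try:
            test = OperonSimilarityTest.from_pipeline(
                data.pair, data.units, mask, rna_scaled, analysis_set, cfg)
        except ValueError:
            operon_results = None  # too few pairs in a category on tiny data
        else:
            operon_results = test.fit()

    sign_tests: dict[str, SignTestResults] = {}
    if data.catalog is not None and not data.catalog.empty:
        for mode in cfg.sign_test_thresholds:
            biased = select_biased(ase_results.calls, mode)
            if biased.empty:
                continue
            st = SignTest(biased, data.catalog, min_size=cfg.min_category_size,
                          size_basis=cfg.category_size_basis, config=cfg, mode=mode)
            sign_tests[mode] = st.fit()

    return PipelineRun(data=data, config=cfg, mask=mask, summaries=summaries,
                       analysis_set=analysis_set, ase=ase_results,
                       operon=operon_results, sign_tests=sign_tests)
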