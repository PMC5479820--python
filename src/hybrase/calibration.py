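"""Scenario-level calibration experiments.

Pre-packaged synthetic experiments that measure the pipeline's
operating characteristics: the false-call rate under a pure null, the
fidelity of effect-size recovery, the power and calibration of the
gene-set sign test, and the operon co-regulation contrast.  Each
function generates its scenario from a seed, runs the relevant pipeline
stages from scratch, and returns the measured quantities.

Problem sizes default to desk scale (hundreds to a thousand ortholog
units, ~50x coverage, thousands of resamples/permutations); every
knob is exposed for larger studies.
"""

from __future__ import annotations

import numpy as np
import scipy.stats

from .ase import build_profiles, observed_ratio
from .config import PipelineConfig
from .mappability import compute_mask
from .pipeline import run_all, simulate_dataset
from .quantify import build_analysis_set, detect_cnv, scale_coverage_sets, summarize_all
from .selection import OperonSimilarityTest
from .simulate import PlantedSet, ScenarioConfig

__all__ = [
    "null_false_call_rate", "effect_recovery", "sign_test_power_run",
    "operon_structure_run",
]


def null_false_call_rate(seed: int = 0, n_orthologs: int = 1_000,
                         depth: float = 50.0, n_resamples: int = 2_000,
                         ) -> dict:
    """False-call proportion of the ASE test on a pure-null hybrid.

    Every ortholog's true allelic ratio is 0; the parental genomes
    differ at 13.4% of coding sites with GC-shifted substitutions, so
    the alleles differ in composition and mappable length — exactly the
    nuisance structure the resampling null absorbs.  Returns the number
    of orthologs tested and the number called significant at the
    configured FDR.
    """
    scfg = ScenarioConfig(
        genome_length=int(n_orthologs * 600), n_orthologs=n_orthologs,
        plasmid_fraction=0.0, ase_null_fraction=1.0,
        substitution_gc_bias=0.5, mean_rna_depth=depth, mean_dna_depth=depth,
        n_background_categories=0, rng_seed=seed)
    cfg = PipelineConfig(n_resamples=n_resamples, rng_seed=seed)
    run = run_all(simulate_dataset(scfg), cfg, run_operon_test=False)
    return {
        "n_tested": run.ase.n_tested,
        "n_significant": run.ase.n_significant,
        "significant_fraction": run.ase.n_significant / max(1, run.ase.n_tested),
    }


def effect_recovery(seed: int = 0, n_orthologs: int = 500,
                    depth: float = 50.0, effect_sd: float = 1.0) -> dict:
    """Rank agreement between planted and observed cis ratios.

    Plants N(0, effect_sd) log2 ratios on every ortholog, runs masking,
    filtering and scaling, and correlates the observed mean cis ratio
    with the truth (Spearman).
    """
    scfg = ScenarioConfig(
        genome_length=int(n_orthologs * 600), n_orthologs=n_orthologs,
        plasmid_fraction=0.0, ase_null_fraction=0.0, ase_effect_sd=effect_sd,
        mean_rna_depth=depth, mean_dna_depth=depth,
        n_background_categories=0, rng_seed=seed)
    cfg = PipelineConfig(rng_seed=seed)
    data = simulate_dataset(scfg)
    mask = compute_mask(data.pair, cfg.read_length)
    summaries = summarize_all(data.coverages, data.units, data.pair, mask,
                              cfg.read_length)
    cnv = detect_cnv(summaries, cfg.cnv_sd_threshold, cfg.cnv_pooling)
    aset = build_analysis_set(summaries, data.units, cfg, cnv)
    scaled = scale_coverage_sets(data.coverages, data.pair, mask)
    profiles = build_profiles(data.pair, data.units, mask, scaled["RNA"], aset)
    truth = data.scenario.truth.effects.set_index("ortholog_id")["true_log2_ratio"]
    est, tru = [], []
    for oid, by_rep in profiles.items():
        est.append(float(np.mean([observed_ratio(p) for p in by_rep.values()])))
        tru.append(float(truth[oid]))
    rho = scipy.stats.spearmanr(tru, est).statistic
    return {"spearman": float(rho), "n": len(est)}


def sign_test_power_run(seed: int, n_orthologs: int = 150,
                        depth: float = 50.0, n_resamples: int = 400,
                        n_permutations: int = 2_000,
                        planted: PlantedSet | None = None) -> dict:
    """One full-pipeline run measuring the planted category's sign test.

    A 20-member category with 80% of members shifted one log2 unit
    toward the same lineage sits in a background of half-null orthologs;
    the returned ``perm_p`` is the planted category's multiplicity-
    adjusted permutation p-value (NaN if the category was not eligible).
    """
    planted = planted or PlantedSet(category_id="planted", n_members=20,
                                    directional_fraction=0.8, effect_shift=1.0)
    scfg = ScenarioConfig(
        genome_length=int(n_orthologs * 600), n_orthologs=n_orthologs,
        plasmid_fraction=0.0, ase_null_fraction=0.5,
        mean_rna_depth=depth, mean_dna_depth=depth, planted_set=planted,
        n_background_categories=3, background_category_size=25, rng_seed=seed)
    cfg = PipelineConfig(n_resamples=n_resamples, n_permutations=n_permutations,
                         sign_test_thresholds=("all",), rng_seed=seed)
    run = run_all(simulate_dataset(scfg), cfg, run_operon_test=False)
    out = {"perm_p": float("nan"), "k": 0, "n": 0,
           "n_significant": run.ase.n_significant}
    if "all" in run.sign_tests:
        res = run.sign_tests["all"].results.set_index("category_id")
        if planted.category_id in res.index:
            row = res.loc[planted.category_id]
            out.update(perm_p=float(row.perm_p), k=int(row.k), n=int(row.n))
    return out


def operon_structure_run(seed: int = 0, n_orthologs: int = 150,
                         depth: float = 50.0, n_samples: int = 2_000,
                         n_permutations: int = 1_000) -> dict:
    """Within-operon vs. non-operon ASE-similarity contrast.

    Operons share one planted allelic ratio across their member genes,
    so adjacent within-operon genes should show smaller |delta log2
    ratio| than adjacent independent genes.  Returns per-replicate
    medians and permutation p-values.
    """
    scfg = ScenarioConfig(
        genome_length=int(n_orthologs * 700), n_orthologs=n_orthologs,
        operon_fraction=0.4, plasmid_fraction=0.0, ase_null_fraction=0.3,
        mean_rna_depth=depth, mean_dna_depth=depth,
        n_background_categories=0, rng_seed=seed)
    cfg = PipelineConfig(rng_seed=seed)
    data = simulate_dataset(scfg)
    mask = compute_mask(data.pair, cfg.read_length)
    summaries = summarize_all(data.coverages, data.units, data.pair, mask,
                              cfg.read_length)
    cnv = detect_cnv(summaries, cfg.cnv_sd_threshold, cfg.cnv_pooling)
    aset = build_analysis_set(summaries, data.units, cfg, cnv)
    scaled = scale_coverage_sets(data.coverages, data.pair, mask)
    test = OperonSimilarityTest.from_pipeline(
        data.pair, data.units, mask, scaled["RNA"], aset, cfg)
    res = test.fit(n_samples=n_samples, n_permutations=n_permutations)
    return {"results": res.results}
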