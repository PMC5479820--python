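"""Pipeline configuration.

A single :class:`PipelineConfig` carries every tunable of the analysis:
the mapping read length used for window mappability and RPKM, the Monte
Carlo sizes of the resampling and permutation nulls, the FDR level, and
the filters that define the analysis set.  One global ``rng_seed`` is
declared here; each stochastic stage derives its own independent stream
from ``(rng_seed, stage_name)`` via :func:`stage_rng`, so a stage rerun
in isolation reproduces the full-pipeline result.
"""

from __future__ import annotations

import dataclasses
import zlib
from dataclasses import dataclass, field

import numpy as np
import yaml

__all__ = ["PipelineConfig", "stage_rng"]

_VALID_THRESHOLDS = ("top50", "all")


@dataclass
class PipelineConfig:
    """Settings for the hybrid ASE pipeline.

    Parameters
    ----------
    read_length : int
        Mapping read length in bases. Used as the mappability window
        length and to convert summed base-level coverage into read
        equivalents (default 75).
    n_resamples : int
        Draws per empirical resampling null distribution (default 10,000).
    n_permutations : int
        Permutations for the operon-similarity and sign tests
        (default 10,000).
    fdr_level : float
        Benjamini-Hochberg false-discovery rate for ASE calls
        (default 0.05).
    min_reads : int
        Minimum allele-summed RNA read equivalents a unit needs in
        *every* replicate to enter the analysis set (default 100).
    cnv_sd_threshold : float
        A unit whose DNA RPKM lies more than this many standard
        deviations from the chromosome mean is flagged as a copy-number
        variant (default 2).
    min_category_size : int
        Minimum members a gene-set category needs to be tested by the
        sign test (default 10).
    rng_seed : int
        Global seed; every stochastic stage derives a stream from it.
    sign_test_thresholds : tuple of str
        Which biased-ortholog thresholds to run the sign test at;
        subset of {"top50", "all"}.
    cnv_pooling : str
        "any": CNV mean/SD computed per allele x replicate and a unit
        flagged if any of the four series is an outlier (conservative
        default). "pooled": one mean/SD over all four series combined.
    tail_rule : str
        Two-tailed empirical p-value rule: "min_tail" doubles the
        smaller tail (default); "symmetric" counts |null - median| >=
        |observed - median|.
    category_size_basis : str
        Whether ``min_category_size`` counts members among the *biased*
        set (default) or all *annotated* members.
    """

    read_length: int = 75
    n_resamples: int = 10_000
    n_permutations: int = 10_000
    fdr_level: float = 0.05
    min_reads: int = 100
    cnv_sd_threshold: float = 2.0
    min_category_size: int = 10
    rng_seed: int = 0
    sign_test_thresholds: tuple[str, ...] = ("top50", "all")
    cnv_pooling: str = "any"
    tail_rule: str = "min_tail"
    category_size_basis: str = "biased"

    def __post_init__(self) -> None:
        for name in ("read_length", "n_resamples", "n_permutations",
                     "min_reads", "min_category_size"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 1:
                raise ValueError(f"{name} must be a positive integer, got {v!r}")
        if not 0.0 < self.fdr_level < 1.0:
            raise ValueError(f"fdr_level must lie in (0, 1), got {self.fdr_level!r}")
        if self.cnv_sd_threshold <= 0:
            raise ValueError("cnv_sd_threshold must be positive")
        self.sign_test_thresholds = tuple(self.sign_test_thresholds)
        bad = set(self.sign_test_thresholds) - set(_VALID_THRESHOLDS)
        if bad or not self.sign_test_thresholds:
            raise ValueError(
                f"sign_test_thresholds must be a non-empty subset of "
                f"{_VALID_THRESHOLDS}, got {self.sign_test_thresholds!r}")
        if self.cnv_pooling not in ("any", "pooled"):
            raise ValueError(f"cnv_pooling must be 'any' or 'pooled', got {self.cnv_pooling!r}")
        if self.tail_rule not in ("min_tail", "symmetric"):
            raise ValueError(f"tail_rule must be 'min_tail' or 'symmetric', got {self.tail_rule!r}")
        if self.category_size_basis not in ("biased", "annotated"):
            raise ValueError("category_size_basis must be 'biased' or 'annotated'")

    # ---- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sign_test_thresholds"] = list(self.sign_test_thresholds)
        return d

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        if not isinstance(d, dict):
            raise ValueError(f"config file {path} does not contain a mapping")
        return cls.from_dict(d)


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Independent, reproducible random stream for one pipeline stage.

    The stream is keyed on ``(seed, crc32(stage))`` so that stages are
    decoupled: rerunning one stage with the global seed reproduces its
    in-pipeline randomness exactly.
    """
    key = zlib.crc32(stage.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed), key]))
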