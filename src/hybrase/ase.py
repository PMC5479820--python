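"""The composition- and length-aware resampling test for allelic expression.

An ortholog's observed *cis* ratio is ``log2((sum cov_v + 1)/(sum cov_m
+ 1))`` over its mappable coding positions.  Because the two alleles
differ in mappable length and nucleotide composition, and per-base
coverage depends on local sequence, the ratio's null variation is
estimated by resampling: an empirical null is built from each allele's
own coverage, summing ``length`` draws of the operator ``X(cov, P(pi))``
— pick a nucleotide with probability ``pi``, then pick uniformly one of
the source allele's positions carrying that nucleotide and take its
coverage.  The numerator uses the source allele's own composition and
length; the denominator uses the *other* allele's composition and
length, so the null captures exactly the ratio variation attributable
to sequence differences alone.  Each replicate is compared against both
alleles' nulls; direction-concordant replicates are combined by keeping
the least significant of the four p-values, and calls are made at a
Benjamini-Hochberg FDR.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .config import PipelineConfig, stage_rng
from .data import GenomePair, OrthologUnit
from .mappability import MappabilityMask
from .quantify import AnalysisSet

__all__ = [
    "AlleleProfile", "build_profiles", "resample_null", "observed_ratio",
    "ase_p_value", "combine_replicates", "bh_fdr", "AseModel", "AseResults",
]

_BASE_CODE = np.full(256, 255, dtype=np.uint8)
for i, b in enumerate(b"ACGT"):
    _BASE_CODE[b] = i

FAVORS_FIRST = "favors_v"
FAVORS_SECOND = "favors_m"
DISCORDANT = "discordant"

# max elements materialized per resampling chunk (memory bound)
_CHUNK_ELEMENTS = 4_000_000


def encode_bases(seq: str) -> np.ndarray:
    """A/C/G/T -> 0/1/2/3 (uint8); anything else -> 255."""
    return _BASE_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass
class AlleleProfile:
    """Mappable coding positions of one ortholog, per allele.

    ``cov[sp]`` holds the (scaled) per-base RNA coverage and
    ``bases[sp]`` the 0-3 encoded nucleotide at the same positions.
    The species order fixes the sign convention: positive ratios mean
    the first-listed allele is higher.
    """

    ortholog_id: str
    species: tuple[str, str]
    cov: dict[str, np.ndarray]
    bases: dict[str, np.ndarray]
    replicate: int = 1

    def __post_init__(self) -> None:
        for sp in self.species:
            self.cov[sp] = np.asarray(self.cov[sp], dtype=float)
            self.bases[sp] = np.asarray(self.bases[sp], dtype=np.uint8)
            if len(self.cov[sp]) != len(self.bases[sp]):
                raise ValueError(f"{self.ortholog_id}/{sp}: cov/bases length mismatch")
            if np.any(self.bases[sp] > 3):
                raise ValueError(f"{self.ortholog_id}/{sp}: non-ACGT base in profile")

    def length(self, sp: str) -> int:
        return len(self.cov[sp])

    def pi(self, sp: str) -> np.ndarray:
        """Marginal nucleotide frequencies over this allele's mappable positions."""
        n = self.length(sp)
        if n == 0:
            raise ValueError(f"{self.ortholog_id}/{sp}: empty allele profile")
        return np.bincount(self.bases[sp], minlength=4) / n

    def other(self, sp: str) -> str:
        a, b = self.species
        return b if sp == a else a

    def swapped(self) -> "AlleleProfile":
        """The same profile with allele labels exchanged (for symmetry checks)."""
        a, b = self.species
        return AlleleProfile(self.ortholog_id, (b, a),
                             {a: self.cov[a], b: self.cov[b]},
                             {a: self.bases[a], b: self.bases[b]},
                             self.replicate)


def build_profiles(pair: GenomePair, units: list[OrthologUnit],
                   mask: MappabilityMask, rna_scaled: dict,
                   analysis_set: AnalysisSet | None = None,
                   ) -> dict[str, dict[int, AlleleProfile]]:
    """Assemble per-replicate allele profiles from scaled RNA coverage.

    ``rna_scaled[replicate][species]`` maps replicon name to a
    CoverageTrack (the output of the scaling step).  Only units in
    ``analysis_set`` (all units if None) are profiled.
    """
    keep = set(analysis_set.retained) if analysis_set is not None else None
    base_codes = {
        sp: {rep.name: encode_bases(rep.seq.upper()) for rep in pair.replicons[sp]}
        for sp in pair.species}
    out: dict[str, dict[int, AlleleProfile]] = {}
    for u in units:
        if keep is not None and u.ortholog_id not in keep:
            continue
        by_rep: dict[int, AlleleProfile] = {}
        for replicate, by_sp in rna_scaled.items():
            cov, bases = {}, {}
            for sp in pair.species:
                loc = u.locus(sp)
                m = mask.mappable[sp][loc.replicon][loc.start:loc.end]
                cov[sp] = by_sp[sp][loc.replicon].values[loc.start:loc.end][m]
                bases[sp] = base_codes[sp][loc.replicon][loc.start:loc.end][m]
            by_rep[replicate] = AlleleProfile(
                u.ortholog_id, pair.species, cov, bases, replicate=replicate)
        out[u.ortholog_id] = by_rep
    return out


# --------------------------------------------------------------------------
# resampling null
# --------------------------------------------------------------------------

def _bootstrap_sums(cov: np.ndarray, n_draws: int, n_resamples: int,
                    rng: np.random.Generator) -> np.ndarray:
    """n_resamples sums of n_draws uniform with-replacement picks from cov."""
    out = np.empty(n_resamples)
    chunk = max(1, _CHUNK_ELEMENTS // max(1, n_draws))
    for lo in range(0, n_resamples, chunk):
        hi = min(lo + chunk, n_resamples)
        idx = rng.integers(0, len(cov), size=(hi - lo, n_draws))
        out[lo:hi] = cov[idx].sum(axis=1)
    return out


def _weighted_sums(cov_by_base: list[np.ndarray], pi4: np.ndarray, n_draws: int,
                   n_resamples: int, rng: np.random.Generator) -> np.ndarray:
    """Sums of n_draws X(cov, P(pi)) picks, n_resamples times.

    Exact decomposition of the X operator: the number of picks landing
    on each nucleotide class is multinomial(n_draws, pi4); within a
    class, picks are uniform over that class's positions.  Segment sums
    over a flat array of uniform picks avoid per-resample Python work.
    """
    out = np.zeros(n_resamples)
    chunk = max(1, _CHUNK_ELEMENTS // max(1, n_draws))
    for lo in range(0, n_resamples, chunk):
        hi = min(lo + chunk, n_resamples)
        k = rng.multinomial(n_draws, pi4, size=hi - lo)
        part = np.zeros(hi - lo)
        for b in range(4):
            kb = k[:, b]
            total = int(kb.sum())
            if total == 0:
                continue
            pool = cov_by_base[b]
            vals = pool[rng.integers(0, len(pool), size=total)]
            csum = np.concatenate(([0.0], np.cumsum(vals)))
            ends = np.cumsum(kb)
            part += csum[ends] - csum[ends - kb]
        out[lo:hi] = part
    return out


def _cross_pi(profile: AlleleProfile, source: str) -> np.ndarray:
    """The other allele's nucleotide frequencies, renormalized over the
    bases actually present in the source allele (the X operator cannot
    pick a position of an absent base)."""
    counts = np.bincount(profile.bases[source], minlength=4)
    pi_other = profile.pi(profile.other(source))
    pi4 = np.where(counts > 0, pi_other, 0.0)
    total = pi4.sum()
    if total <= 0:
        # no base shared at all: fall back to the source's own composition
        # so the draw remains well-defined (degenerate, tiny alleles only)
        return profile.pi(source)
    return pi4 / total


def resample_null(profile: AlleleProfile, source: str, n_resamples: int,
                  rng: np.random.Generator) -> np.ndarray:
    """Empirical null distribution of the log2 ratio from one allele.

    Each of the ``n_resamples`` draws forms ``log2((num+1)/(den+1))``
    where ``num`` sums ``length_source`` picks of X(cov_source,
    P(pi_source)) and ``den`` sums ``length_other`` picks of
    X(cov_source, P(pi_other)).  Under the source allele's own
    composition the X operator reduces to a uniform bootstrap of its
    positions (P(pick j) = pi[base_j]/n_base_j = 1/length); the
    cross-composition denominator re-weights the same positions by the
    other allele's base frequencies.
    """
    if n_resamples < 1:
        raise ValueError("n_resamples must be positive")
    if source not in profile.species:
        raise KeyError(source)
    other = profile.other(source)
    L_src, L_other = profile.length(source), profile.length(other)
    if L_src == 0 or L_other == 0:
        raise ValueError(
            f"{profile.ortholog_id}: both alleles need >= 1 mappable position")
    cov = profile.cov[source]
    bases = profile.bases[source]
    num = _bootstrap_sums(cov, L_src, n_resamples, rng)
    cov_by_base = [cov[bases == b] for b in range(4)]
    den = _weighted_sums(cov_by_base, _cross_pi(profile, source), L_other,
                         n_resamples, rng)
    return np.log2(num + 1.0) - np.log2(den + 1.0)


def observed_ratio(profile: AlleleProfile) -> float:
    """Observed cis ratio log2((sum cov_first + 1)/(sum cov_second + 1))."""
    a, b = profile.species
    return float(np.log2(profile.cov[a].sum() + 1.0)
                 - np.log2(profile.cov[b].sum() + 1.0))


def ase_p_value(observed: float, null: np.ndarray, rule: str = "min_tail") -> float:
    """Two-tailed empirical p-value of an observed ratio against a null.

    ``min_tail`` (default): twice the smaller add-one tail probability,
    capped at 1.  ``symmetric``: the add-one frequency of null values at
    least as far from the null median as the observation.
    """
    null = np.asarray(null)
    n = len(null)
    if n == 0:
        raise ValueError("empty null distribution")
    if rule == "min_tail":
        ge = int(np.count_nonzero(null >= observed))
        le = int(np.count_nonzero(null <= observed))
        p = 2.0 * min((1 + ge) / (n + 1), (1 + le) / (n + 1))
    elif rule == "symmetric":
        med = float(np.median(null))
        k = int(np.count_nonzero(np.abs(null - med) >= abs(observed - med)))
        p = (1 + k) / (n + 1)
    else:
        raise ValueError(f"unknown tail rule {rule!r}")
    return min(p, 1.0)


# --------------------------------------------------------------------------
# replicate combination and FDR
# --------------------------------------------------------------------------

def combine_replicates(measurements: list[dict]) -> dict:
    """Combine the two biological replicates of one ortholog.

    Each measurement dict carries ``ratio``, ``p_v`` and ``p_m``.  If
    the replicates agree in the direction of bias (both ratios strictly
    positive or both strictly negative), the least significant of the
    four p-values is retained and the shared sign gives the direction;
    otherwise the call is discordant (a ratio of exactly 0 counts as
    directionless, hence discordant) and carries no combined p.
    """
    if len(measurements) != 2:
        raise ValueError(f"expected exactly 2 replicates, got {len(measurements)}")
    r1, r2 = (m["ratio"] for m in measurements)
    if r1 * r2 > 0:
        combined = max(m[k] for m in measurements for k in ("p_v", "p_m"))
        direction = FAVORS_FIRST if r1 > 0 else FAVORS_SECOND
    else:
        combined, direction = float("nan"), DISCORDANT
    return {"combined_p": combined, "direction": direction}


def bh_fdr(pvalues, fdr_level: float = 0.05):
    """Benjamini-Hochberg step-up with monotone q-values.

    Returns ``(q, significant)`` aligned with the input order.
    """
    p = np.asarray(pvalues, dtype=float)
    if len(p) == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    reject, q, _, _ = multipletests(p, alpha=fdr_level, method="fdr_bh")
    return q, reject


# --------------------------------------------------------------------------
# model / results objects
# --------------------------------------------------------------------------

CALL_COLUMNS = ["ortholog_id", "ratio_rep1", "ratio_rep2",
                "p_v1", "p_m1", "p_v2", "p_m2",
                "combined_p", "q", "direction", "significant"]


class AseModel:
    """Resampling ASE test over an analysis set of orthologs.

    Built from per-replicate :class:`AlleleProfile` objects (most
    conveniently via :meth:`from_pipeline`); :meth:`fit` runs the
    resampling nulls, combines replicates and applies BH FDR, returning
    an :class:`AseResults`.
    """

    def __init__(self, profiles: dict[str, dict[int, AlleleProfile]],
                 config: PipelineConfig | None = None):
        if not profiles:
            raise ValueError("no profiles to test")
        self.profiles = profiles
        self.config = config or PipelineConfig()
        reps = {tuple(sorted(by_rep)) for by_rep in profiles.values()}
        if len(reps) != 1:
            raise ValueError("all orthologs must carry the same replicates")
        self.replicates = list(reps.pop())
        if len(self.replicates) != 2:
            raise ValueError("replicate combination requires exactly 2 replicates")

    @classmethod
    def from_pipeline(cls, pair: GenomePair, units: list[OrthologUnit],
                      mask: MappabilityMask, rna_scaled: dict,
                      analysis_set: AnalysisSet,
                      config: PipelineConfig | None = None) -> "AseModel":
        profiles = build_profiles(pair, units, mask, rna_scaled, analysis_set)
        return cls(profiles, config)

    def fit(self, n_resamples: int | None = None,
            rng: np.random.Generator | None = None) -> "AseResults":
        cfg = self.config
        n = n_resamples or cfg.n_resamples
        if rng is None:
            rng = stage_rng(cfg.rng_seed, "ase")
        first, second = next(iter(self.profiles.values()))[self.replicates[0]].species
        rows = []
        for oid in sorted(self.profiles):
            by_rep = self.profiles[oid]
            meas = []
            for rep in self.replicates:
                prof = by_rep[rep]
                obs = observed_ratio(prof)
                null_v = resample_null(prof, first, n, rng)
                null_m = resample_null(prof, second, n, rng)
                meas.append({
                    "ratio": obs,
                    "p_v": ase_p_value(obs, null_v, cfg.tail_rule),
                    "p_m": ase_p_value(obs, null_m, cfg.tail_rule),
                })
            combined = combine_replicates(meas)
            rows.append({
                "ortholog_id": oid,
                "ratio_rep1": meas[0]["ratio"], "ratio_rep2": meas[1]["ratio"],
                "p_v1": meas[0]["p_v"], "p_m1": meas[0]["p_m"],
                "p_v2": meas[1]["p_v"], "p_m2": meas[1]["p_m"],
                "combined_p": combined["combined_p"],
                "direction": combined["direction"],
            })
        calls = pd.DataFrame(rows)
        concordant = calls["direction"] != DISCORDANT
        calls["q"] = np.nan
        calls["significant"] = False
        if concordant.any():
            q, sig = bh_fdr(calls.loc[concordant, "combined_p"], cfg.fdr_level)
            calls.loc[concordant, "q"] = q
            calls.loc[concordant, "significant"] = sig
        return AseResults(calls[CALL_COLUMNS], self.config, species=(first, second))


class AseResults:
    """Per-ortholog ASE calls with FDR-adjusted significance.

    ``calls`` holds one row per tested ortholog: per-replicate ratios
    and p-values against both alleles' nulls, the combined (max-of-four)
    p-value, BH q-value, direction and significance flag.  Positive
    ratios favor the first-listed allele.
    """

    def __init__(self, calls: pd.DataFrame, config: PipelineConfig,
                 species: tuple[str, str]):
        self.calls = calls.reset_index(drop=True)
        self.config = config
        self.species = species

    @property
    def n_tested(self) -> int:
        return len(self.calls)

    @property
    def n_significant(self) -> int:
        return int(self.calls["significant"].sum())

    @property
    def significant(self) -> pd.DataFrame:
        return self.calls[self.calls["significant"]]

    def mean_ratio(self) -> pd.Series:
        """Mean cis ratio across replicates, indexed by ortholog."""
        return ((self.calls["ratio_rep1"] + self.calls["ratio_rep2"]) / 2.0
                ).set_axis(self.calls["ortholog_id"])

    def direction_counts(self) -> dict[str, int]:
        sig = self.significant
        return {d: int((sig["direction"] == d).sum())
                for d in (FAVORS_FIRST, FAVORS_SECOND)}

    def balance_test(self) -> dict:
        """Goodness-of-fit test of equal allele-direction counts among
        significant calls."""
        from .selection import chi2_goodness
        counts = self.direction_counts()
        k, n = counts[FAVORS_SECOND], sum(counts.values())
        chi2, p = chi2_goodness(k, n)
        return {"n": n, "k_second": k, "chi2": chi2, "p": p}

    def summary(self) -> str:
        counts = self.direction_counts()
        n_disc = int((self.calls["direction"] == DISCORDANT).sum())
        lines = [
            "Allele-specific expression (resampling test)",
            "=" * 44,
            f"orthologs tested:        {self.n_tested}",
            f"replicate-discordant:    {n_disc}",
            f"significant (FDR {self.config.fdr_level:.0%}):  {self.n_significant}",
            f"  favoring {self.species[0]!r}:        {counts[FAVORS_FIRST]}",
            f"  favoring {self.species[1]!r}:        {counts[FAVORS_SECOND]}",
        ]
        if self.n_significant > 0:
            bal = self.balance_test()
            lines.append(
                f"direction balance:       chi2 = {bal['chi2']:.3f}, p = {bal['p']:.3f}")
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        from .io import write_table
        write_table(self.calls, path, config=self.config,
                    extra_comments=[
                        f"sign convention: positive ratio = {self.species[0]!r} "
                        f"(first-listed) allele higher"])

    def plot_replicates(self, ax=None):
        """Scatter of replicate-1 vs replicate-2 cis ratios, significant
        calls highlighted by direction."""
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        c = self.calls
        ns = c[~c["significant"]]
        ax.scatter(ns["ratio_rep1"], ns["ratio_rep2"], s=6, c="0.7", label="n.s.")
        for d, color in ((FAVORS_FIRST, "tab:blue"), (FAVORS_SECOND, "tab:red")):
            sub = c[c["significant"] & (c["direction"] == d)]
            ax.scatter(sub["ratio_rep1"], sub["ratio_rep2"], s=8, c=color, label=d)
        ax.axhline(0, lw=0.5, c="k")
        ax.axvline(0, lw=0.5, c="k")
        ax.set_xlabel("cis ratio, replicate 1 (log2)")
        ax.set_ylabel("cis ratio, replicate 2 (log2)")
        ax.legend(frameon=False, fontsize=8)
        return ax
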