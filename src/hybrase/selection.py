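"""Operon ASE-similarity and gene-set sign tests.

Two downstream analyses of the per-ortholog ASE calls:

* The **operon similarity test** checks that adjacent genes inside
  predicted operons share their allelic ratio more closely than
  adjacent, independently transcribed genes — a positive control on the
  operon annotations, since co-transcribed genes share a promoter.  It
  samples pairs of chromosome-adjacent genes from the two categories,
  takes per-pair absolute log2-ratio differences, and compares the two
  samples with a Kruskal-Wallis statistic whose p-value comes from
  label permutations.

* The **sign test** asks whether a functionally related gene set shows
  ASE coordinately favoring one parental lineage — the signature of
  polygenic lineage-specific selection on cis-regulation, as opposed to
  drift (which scatters directions).  Each eligible category gets a 1-df
  chi-square goodness-of-fit statistic on its direction counts; the
  multiplicity-adjusted p-value comes from a max-statistic permutation
  null: directions are shuffled across all biased orthologs, every
  category's nominal p is recomputed, and the per-shuffle minimum forms
  the reference distribution (a category-specific FWER/FDR control).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .config import PipelineConfig, stage_rng
from .data import CHROMOSOME, GenomePair, OrthologUnit
from .mappability import MappabilityMask
from .quantify import AnalysisSet
from .ase import FAVORS_FIRST, FAVORS_SECOND

__all__ = [
    "chi2_goodness", "per_gene_ratios", "adjacent_gene_pairs",
    "OperonSimilarityTest", "OperonTestResults",
    "select_biased", "SignTest", "SignTestResults",
]

WITHIN_OPERON = "within_operon"
NON_OPERON = "non_operon"


def chi2_goodness(k: int, n: int) -> tuple[float, float]:
    """1-df chi-square goodness-of-fit of k successes in n against 1:1.

    chi2 = (k - n/2)^2/(n/2) + ((n-k) - n/2)^2/(n/2) = (2k - n)^2 / n.
    Returns (chi2, upper tail probability).
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= k <= n:
        raise ValueError(f"k = {k} outside [0, {n}]")
    chi2 = (2.0 * k - n) ** 2 / n
    return float(chi2), float(scipy.stats.chi2.sf(chi2, df=1))


# --------------------------------------------------------------------------
# per-gene ratios and adjacency
# --------------------------------------------------------------------------

def per_gene_ratios(pair: GenomePair, units: list[OrthologUnit],
                    mask: MappabilityMask, rna_scaled_rep: dict,
                    analysis_set: AnalysisSet | None = None) -> pd.Series:
    """Observed cis ratio of every individual chromosome gene.

    Operon member genes are measured from their own coordinates (the
    annotation's ``member_gene_coords``), so operon-internal similarity
    can be assessed gene by gene.  ``rna_scaled_rep[species]`` maps
    replicon name to a CoverageTrack for one replicate.
    """
    keep = set(analysis_set.retained) if analysis_set is not None else None
    sp1, sp2 = pair.species
    ratios = {}
    for u in units:
        if u.loci[sp1].replicon_class != CHROMOSOME:
            continue
        if keep is not None and u.ortholog_id not in keep:
            continue
        for sp in (sp1, sp2):
            if u.loci[sp].member_coords is None:
                raise ValueError(
                    f"ortholog {u.ortholog_id}: member_gene_coords required "
                    f"for per-gene ASE ratios")
        for gi, gene in enumerate(u.members):
            sums = {}
            for sp in (sp1, sp2):
                loc = u.loci[sp]
                s, e = loc.member_coords[gi]
                m = mask.mappable[sp][loc.replicon][s:e]
                sums[sp] = float(rna_scaled_rep[sp][loc.replicon].values[s:e][m].sum())
            ratios[gene] = float(np.log2(sums[sp1] + 1.0) - np.log2(sums[sp2] + 1.0))
    return pd.Series(ratios, name="log2_ratio")


def adjacent_gene_pairs(units: list[OrthologUnit], species: str) -> pd.DataFrame:
    """Chromosome-adjacent gene pairs, categorized by operon membership.

    Genes are ordered by start coordinate on the chromosome of the given
    species; consecutive pairs where both genes share an operon are
    ``within_operon``, pairs where neither gene is in any operon are
    ``non_operon``; mixed pairs are dropped.
    """
    genes = []
    for u in units:
        loc = u.loci[species]
        if loc.replicon_class != CHROMOSOME:
            continue
        coords = loc.member_coords
        if coords is None:
            if u.is_operon:
                raise ValueError(
                    f"operon {u.ortholog_id}: member_gene_coords required")
            coords = [(loc.start, loc.end)]
        operon_id = u.ortholog_id if u.is_operon else None
        for gene, (s, _) in zip(u.members, coords):
            genes.append((s, gene, operon_id))
    genes.sort()
    rows = []
    for (_, a, op_a), (_, b, op_b) in zip(genes, genes[1:]):
        if op_a is not None and op_a == op_b:
            rows.append((a, b, WITHIN_OPERON))
        elif op_a is None and op_b is None:
            rows.append((a, b, NON_OPERON))
    return pd.DataFrame(rows, columns=["gene_a", "gene_b", "category"])


# --------------------------------------------------------------------------
# operon similarity test
# --------------------------------------------------------------------------

def _kruskal_h(ranks_a: np.ndarray, ranks_b: np.ndarray, tie_term: float,
               n_total: int) -> float:
    n1, n2 = len(ranks_a), len(ranks_b)
    r1, r2 = ranks_a.sum(), ranks_b.sum()
    h = 12.0 / (n_total * (n_total + 1)) * (r1 ** 2 / n1 + r2 ** 2 / n2) \
        - 3.0 * (n_total + 1)
    return h / tie_term if tie_term > 0 else 0.0


class OperonSimilarityTest:
    """Are within-operon adjacent genes more ASE-similar than others?

    Construct from per-replicate per-gene log2 ratios and the adjacency
    table (:func:`adjacent_gene_pairs`), or via :meth:`from_pipeline`.
    """

    def __init__(self, gene_ratios: dict[int, pd.Series], pairs: pd.DataFrame,
                 config: PipelineConfig | None = None):
        self.gene_ratios = gene_ratios
        self.config = config or PipelineConfig()
        for cat in (WITHIN_OPERON, NON_OPERON):
            if (pairs["category"] == cat).sum() < 2:
                raise ValueError(f"fewer than 2 adjacent-gene pairs in category {cat!r}")
        self.pairs = pairs

    @classmethod
    def from_pipeline(cls, pair: GenomePair, units: list[OrthologUnit],
                      mask: MappabilityMask, rna_scaled: dict,
                      analysis_set: AnalysisSet | None = None,
                      config: PipelineConfig | None = None) -> "OperonSimilarityTest":
        ratios = {rep: per_gene_ratios(pair, units, mask, by_sp, analysis_set)
                  for rep, by_sp in rna_scaled.items()}
        pairs = adjacent_gene_pairs(units, pair.species[0])
        known = set(next(iter(ratios.values())).index)
        pairs = pairs[pairs["gene_a"].isin(known) & pairs["gene_b"].isin(known)]
        return cls(ratios, pairs.reset_index(drop=True), config)

    def fit(self, n_samples: int | None = None, n_permutations: int | None = None,
            rng: np.random.Generator | None = None) -> "OperonTestResults":
        cfg = self.config
        n_samples = n_samples or cfg.n_resamples
        n_perm = n_permutations or cfg.n_permutations
        if rng is None:
            rng = stage_rng(cfg.rng_seed, "operon-test")
        rows = []
        for rep in sorted(self.gene_ratios):
            ratios = self.gene_ratios[rep]
            deltas = {}
            for cat in (WITHIN_OPERON, NON_OPERON):
                sub = self.pairs[self.pairs["category"] == cat]
                idx = rng.integers(0, len(sub), size=n_samples)
                a = ratios[sub["gene_a"].to_numpy()[idx]].to_numpy()
                b = ratios[sub["gene_b"].to_numpy()[idx]].to_numpy()
                deltas[cat] = np.abs(a - b)
            d_w, d_n = deltas[WITHIN_OPERON], deltas[NON_OPERON]
            pooled = np.concatenate([d_w, d_n])
            ranks = scipy.stats.rankdata(pooled)
            n_total = len(pooled)
            _, counts = np.unique(pooled, return_counts=True)
            tie_term = 1.0 - ((counts ** 3 - counts).sum() / (n_total ** 3 - n_total))
            n1 = len(d_w)
            h_obs = _kruskal_h(ranks[:n1], ranks[n1:], tie_term, n_total)
            # permutation null: reassign category labels over the pooled sample
            exceed = 0
            chunk = max(1, 4_000_000 // n_total)
            done = 0
            while done < n_perm:
                m = min(chunk, n_perm - done)
                perm = rng.permuted(np.tile(ranks, (m, 1)), axis=1)
                r1 = perm[:, :n1].sum(axis=1)
                r2 = ranks.sum() - r1
                h = (12.0 / (n_total * (n_total + 1))
                     * (r1 ** 2 / n1 + r2 ** 2 / (n_total - n1))
                     - 3.0 * (n_total + 1)) / tie_term
                exceed += int(np.count_nonzero(h >= h_obs - 1e-12))
                done += m
            rows.append({
                "replicate": rep,
                "n_pairs_within": int((self.pairs["category"] == WITHIN_OPERON).sum()),
                "n_pairs_non": int((self.pairs["category"] == NON_OPERON).sum()),
                "median_delta_within": float(np.median(d_w)),
                "median_delta_non": float(np.median(d_n)),
                "kruskal_h": float(h_obs),
                "perm_p": (1 + exceed) / (n_perm + 1),
            })
        return OperonTestResults(pd.DataFrame(rows), self.config)


@dataclass
class OperonTestResults:
    """Per-replicate medians, Kruskal-Wallis statistic and permutation p."""

    results: pd.DataFrame
    config: PipelineConfig

    def summary(self) -> str:
        lines = ["Operon ASE-similarity test", "=" * 44]
        for _, r in self.results.iterrows():
            lines.append(
                f"replicate {int(r.replicate)}: median |dlog2| within = "
                f"{r.median_delta_within:.3f}, outside = {r.median_delta_non:.3f}, "
                f"H = {r.kruskal_h:.1f}, permutation p = {r.perm_p:.2e}")
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        from .io import write_table
        write_table(self.results, path, config=self.config)


# --------------------------------------------------------------------------
# sign test
# --------------------------------------------------------------------------

def select_biased(calls: pd.DataFrame, mode: str = "all") -> pd.DataFrame:
    """Rank significant ASE calls by |mean cis ratio| and apply a threshold.

    ``mode="top50"`` keeps the floor(n/2) most biased orthologs;
    ``mode="all"`` keeps every significant call.  Ties in |ratio| break
    lexicographically on ortholog_id, making the ranking deterministic.
    Returns columns ortholog_id, direction, abs_ratio, sorted by rank.
    """
    if mode not in ("top50", "all"):
        raise ValueError(f"mode must be 'top50' or 'all', got {mode!r}")
    sig = calls[calls["significant"]].copy()
    sig["abs_ratio"] = ((sig["ratio_rep1"] + sig["ratio_rep2"]) / 2.0).abs()
    sig = sig.sort_values(["abs_ratio", "ortholog_id"],
                          ascending=[False, True], kind="mergesort")
    if mode == "top50":
        sig = sig.head(len(sig) // 2)
    return sig[["ortholog_id", "direction", "abs_ratio"]].reset_index(drop=True)


class SignTest:
    """Directional-bias test of gene-set categories over biased orthologs.

    ``biased`` is the output of :func:`select_biased` (or any frame with
    ortholog_id and direction columns); ``catalog`` maps category_id to
    ortholog_id.  ``designated`` names the direction counted as k (the
    second-listed allele by default, so k counts orthologs favoring that
    lineage; the chi-square statistic is symmetric in k and n-k).
    """

    def __init__(self, biased: pd.DataFrame, catalog: pd.DataFrame,
                 min_size: int = 10, designated: str = FAVORS_SECOND,
                 size_basis: str = "biased",
                 config: PipelineConfig | None = None, mode: str = "all"):
        if catalog.empty:
            raise ValueError("empty gene-set catalog")
        if designated not in (FAVORS_FIRST, FAVORS_SECOND):
            raise ValueError(f"unknown designated direction {designated!r}")
        self.config = config or PipelineConfig()
        self.mode = mode
        self.min_size = min_size
        self.designated = designated
        self.biased = biased.drop_duplicates("ortholog_id").reset_index(drop=True)
        self.labels = (self.biased["direction"] == designated).to_numpy()
        order = {oid: i for i, oid in enumerate(self.biased["ortholog_id"])}

        members_all = catalog.groupby("category_id")["ortholog_id"].apply(set)
        eligible = []
        for cat, members in members_all.items():
            in_biased = [order[o] for o in members if o in order]
            size = len(in_biased) if size_basis == "biased" else len(members)
            if size >= min_size and len(in_biased) > 0:
                eligible.append((cat, np.array(sorted(in_biased), dtype=int)))
        self.categories = eligible
        n = len(self.biased)
        self.membership = np.zeros((len(eligible), n), dtype=float)
        for ci, (_, idx) in enumerate(eligible):
            self.membership[ci, idx] = 1.0

    def _nominal(self, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        k = self.membership @ labels.astype(float)
        n = self.membership.sum(axis=1)
        chi2 = (2.0 * k - n) ** 2 / n
        return k, chi2, scipy.stats.chi2.sf(chi2, df=1)

    def fit(self, n_permutations: int | None = None,
            rng: np.random.Generator | None = None) -> "SignTestResults":
        cfg = self.config
        n_perm = n_permutations or cfg.n_permutations
        if rng is None:
            rng = stage_rng(cfg.rng_seed, f"sign-test:{self.mode}")
        if not self.categories:
            return SignTestResults(pd.DataFrame(
                columns=["category_id", "mode", "n", "k", "chi2",
                         "nominal_p", "perm_p"]), cfg)
        k_obs, chi2_obs, p_obs = self._nominal(self.labels)
        # max-statistic permutation null: shuffle directions over the biased
        # set, keep each shuffle's most significant nominal p over categories
        minima = np.empty(n_perm)
        chunk = max(1, 2_000_000 // max(1, len(self.labels)))
        done = 0
        while done < n_perm:
            m = min(chunk, n_perm - done)
            perms = rng.permuted(
                np.tile(self.labels.astype(float), (m, 1)), axis=1)
            k = perms @ self.membership.T  # m x C
            n = self.membership.sum(axis=1)[None, :]
            chi2 = (2.0 * k - n) ** 2 / n
            p = scipy.stats.chi2.sf(chi2, df=1)
            minima[done:done + m] = p.min(axis=1)
            done += m
        rows = []
        for ci, (cat, idx) in enumerate(self.categories):
            perm_p = (1 + int(np.count_nonzero(minima <= p_obs[ci] + 1e-15))) \
                / (n_perm + 1)
            rows.append({
                "category_id": cat, "mode": self.mode, "n": int(len(idx)),
                "k": int(k_obs[ci]), "chi2": float(chi2_obs[ci]),
                "nominal_p": float(p_obs[ci]), "perm_p": float(perm_p),
            })
        df = pd.DataFrame(rows).sort_values("perm_p", kind="mergesort") \
            .reset_index(drop=True)
        return SignTestResults(df, cfg)


@dataclass
class SignTestResults:
    """Per-category direction counts, chi-square and permutation p-values.

    ``k`` counts biased members favoring the designated lineage out of
    ``n`` biased members; ``perm_p`` is multiplicity-adjusted via the
    max-statistic permutation null.
    """

    results: pd.DataFrame
    config: PipelineConfig

    def summary(self) -> str:
        lines = ["Gene-set sign test (lineage-specific selection)", "=" * 48]
        if self.results.empty:
            lines.append("no eligible categories")
        for _, r in self.results.iterrows():
            lines.append(
                f"{r.category_id:<16s} {int(r.k):>3d}/{int(r.n):<3d} "
                f"chi2 = {r.chi2:6.3f}  nominal p = {r.nominal_p:.2e}  "
                f"perm p = {r.perm_p:.4f}")
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        from .io import write_table
        write_table(self.results, path, config=self.config)
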