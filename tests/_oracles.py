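"""Independent reference implementations used only to check the package.

These deliberately favor clarity over speed (pure-Python loops,
exhaustive enumeration) and avoid sharing code paths with the
implementation under test.
"""

from __future__ import annotations

import itertools
from collections import Counter

import numpy as np
from Bio.Seq import Seq


def revcomp(s: str) -> str:
    return str(Seq(s).reverse_complement())


def canon(s: str) -> str:
    rc = revcomp(s)
    return s if s <= rc else rc


def mask_oracle(pair, w: int):
    """Brute-force window-multiset mappability: enumerate every window of
    both genomes into one canonical-form multiset, then mark, base by
    base, whether any overlapping window is duplicated or ambiguous."""
    acgt = set("ACGT")
    counts: Counter[str] = Counter()
    for sp in pair.species:
        for rep in pair.replicons[sp]:
            s = rep.seq.upper()
            for i in range(len(s) - w + 1):
                win = s[i:i + w]
                if set(win) <= acgt:
                    counts[canon(win)] += 1
    out = {}
    for sp in pair.species:
        out[sp] = {}
        for rep in pair.replicons[sp]:
            s = rep.seq.upper()
            n = len(s)
            covered = np.zeros(n, dtype=bool)
            bad = np.zeros(n, dtype=bool)
            for i in range(n - w + 1):
                win = s[i:i + w]
                covered[i:i + w] = True
                if not (set(win) <= acgt and counts[canon(win)] == 1):
                    bad[i:i + w] = True
            out[sp][rep.name] = covered & ~bad
    return out


def null_distribution_oracle(cov_src, bases_src, pi_num, pi_den, n_num, n_den):
    """Exact outcome distribution of the resampling null for tiny alleles.

    Enumerates every combination of per-pick position choices for the
    numerator (n_num picks at base probabilities pi_num) and denominator
    (n_den picks at pi_den); each pick lands on position j with
    probability pi[base_j]/count[base_j].  Returns {log2 ratio: prob}.
    """
    cov_src = list(cov_src)
    bases_src = list(bases_src)
    counts = Counter(bases_src)

    def pick_probs(pi):
        total = sum(pi[b] for b in counts)  # renormalize over present bases
        return [pi[b] / counts[b] / total for b in bases_src]

    p_num = pick_probs(pi_num)
    p_den = pick_probs(pi_den)
    dist: dict[float, float] = {}
    positions = range(len(cov_src))
    for num_picks in itertools.product(positions, repeat=n_num):
        pn = np.prod([p_num[j] for j in num_picks])
        sn = sum(cov_src[j] for j in num_picks)
        for den_picks in itertools.product(positions, repeat=n_den):
            pd_ = np.prod([p_den[j] for j in den_picks])
            sd = sum(cov_src[j] for j in den_picks)
            val = round(float(np.log2((sn + 1) / (sd + 1))), 12)
            dist[val] = dist.get(val, 0.0) + float(pn * pd_)
    return dist


def tv_distance(dist: dict[float, float], samples: np.ndarray) -> float:
    """Total-variation distance between an exact atom distribution and an
    empirical sample (values rounded to the same precision)."""
    emp = Counter(round(float(v), 12) for v in samples)
    n = len(samples)
    keys = set(dist) | set(emp)
    return 0.5 * sum(abs(dist.get(k, 0.0) - emp.get(k, 0) / n) for k in keys)


def bh_oracle(pvals):
    """Hand step-up Benjamini-Hochberg with monotone q-values."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q_sorted = np.empty(m)
    prev = 1.0
    for rank in range(m, 0, -1):
        val = min(prev, m * p[order[rank - 1]] / rank)
        q_sorted[rank - 1] = val
        prev = val
    q = np.empty(m)
    q[order] = q_sorted
    return q


def signtest_exact_minp(categories, labels_k, observed_labels, chi2_p):
    """Exact permutation distribution of the minimum nominal p.

    ``categories``: list of index arrays into the biased set;
    ``labels_k``: number of True labels (preserved margin);
    ``observed_labels``: boolean array; ``chi2_p(k, n)`` gives the
    nominal p.  Enumerates all C(N, K) label placements and returns
    (exact_prob_min_leq(p_obs) per category, observed nominal p per
    category).
    """
    n_total = len(observed_labels)
    obs_p = []
    for idx in categories:
        n = len(idx)
        k = int(observed_labels[idx].sum())
        obs_p.append(chi2_p(k, n))
    count_leq = [0] * len(categories)
    total = 0
    for placement in itertools.combinations(range(n_total), labels_k):
        lab = np.zeros(n_total, dtype=bool)
        lab[list(placement)] = True
        min_p = min(chi2_p(int(lab[idx].sum()), len(idx)) for idx in categories)
        total += 1
        for ci, po in enumerate(obs_p):
            if min_p <= po + 1e-15:
                count_leq[ci] += 1
    return [c / total for c in count_leq], obs_p
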