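"""K-mer mappability masking across the two parental genomes.

In a hybrid, a sequencing read can only be assigned to a parent if its
sequence occurs at a single place across *both* genomes (on either
strand).  We slide a read-length window with step 1 over every replicon
of both parents; a window is unique iff its sequence occurs exactly once
among all windows of both genomes, counting reverse complements.  Every
base overlapped by at least one non-unique window is masked; every
other window-covered base is mappable.  Uniqueness is exact-match
(deterministic and oracle-checkable); windows containing non-ACGT
symbols are conservatively treated as non-unique.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np

from .data import GenomePair

__all__ = ["MappabilityMask", "compute_mask", "canonical_window"]

_COMPLEMENT = bytes.maketrans(b"ACGT", b"TGCA")
_ACGT = frozenset(b"ACGT")


def canonical_window(window: bytes) -> bytes:
    """Strand-canonical form: the lexicographic min of a window and its
    reverse complement, so one counter covers both strands."""
    rc = window.translate(_COMPLEMENT)[::-1]
    return window if window <= rc else rc


@dataclass
class MappabilityMask:
    """Per-base mappability of both parental genomes.

    ``mappable[species][replicon]`` is a boolean vector (True = a hybrid
    read covering this base can be placed unambiguously).
    """

    mappable: dict[str, dict[str, np.ndarray]]
    window_length: int

    def masked_fraction(self, species: str) -> float:
        vecs = list(self.mappable[species].values())
        total = sum(len(v) for v in vecs)
        return 1.0 - sum(int(v.sum()) for v in vecs) / total

    def fraction_mappable(self, species: str) -> float:
        return 1.0 - self.masked_fraction(species)

    def masked_intervals(self, species: str) -> list[tuple[str, int, int]]:
        """Masked runs as BED-style (replicon, start, end) intervals."""
        out = []
        for name, vec in self.mappable[species].items():
            masked = ~vec
            if not masked.any():
                continue
            change = np.flatnonzero(np.diff(masked.astype(np.int8)))
            starts = np.concatenate(([0], change + 1))
            ends = np.concatenate((change + 1, [len(masked)]))
            for s, e in zip(starts, ends):
                if masked[s]:
                    out.append((name, int(s), int(e)))
        return out

    def write_bed(self, species: str, path) -> None:
        with open(path, "w") as fh:
            for name, s, e in self.masked_intervals(species):
                fh.write(f"{name}\t{s}\t{e}\n")


def _iter_replicons(pair: GenomePair):
    for sp in pair.species:
        for rep in pair.replicons[sp]:
            yield sp, rep


def compute_mask(pair: GenomePair, window_length: int) -> MappabilityMask:
    """Compute the hybrid mappability mask for both parental genomes.

    Two passes: first count canonical window sequences over all
    replicons of both genomes, then mark, per replicon, the bases
    overlapped by any duplicated (or ambiguous-base) window.  Bases not
    covered by any window (replicons shorter than the window) are masked.
    """
    if window_length < 1:
        raise ValueError(f"window_length must be >= 1, got {window_length}")
    w = window_length

    counts: Counter[bytes] = Counter()
    for _, rep in _iter_replicons(pair):
        s = rep.seq.upper().encode("ascii")
        for i in range(len(s) - w + 1):
            win = s[i:i + w]
            if _ACGT.issuperset(win):
                counts[canonical_window(win)] += 1

    mappable: dict[str, dict[str, np.ndarray]] = {sp: {} for sp in pair.species}
    for sp, rep in _iter_replicons(pair):
        n = len(rep.seq)
        s = rep.seq.upper().encode("ascii")
        # diff-array marking of bases under >=1 bad window / >=1 window
        bad = np.zeros(n + 1, dtype=np.int32)
        covered = np.zeros(n + 1, dtype=np.int32)
        for i in range(n - w + 1):
            covered[i] += 1
            covered[i + w] -= 1
            win = s[i:i + w]
            if not _ACGT.issuperset(win) or counts[canonical_window(win)] > 1:
                bad[i] += 1
                bad[i + w] -= 1
        covered_depth = np.cumsum(covered[:-1])
        bad_depth = np.cumsum(bad[:-1])
        mappable[sp][rep.name] = (covered_depth > 0) & (bad_depth == 0)
    return MappabilityMask(mappable=mappable, window_length=w)
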