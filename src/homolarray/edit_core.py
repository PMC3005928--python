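"""Infix (semi-global) edit distance between a short probe and a long gene.

The specificity screen of the array design asks, for every candidate probe,
how far the probe is from the *closest substring* of every non-target gene:
the minimum unit-cost Levenshtein distance over all infixes of the gene,
with gaps at the gene's ends free.  A 60-mer probe whose nearest non-target
infix is more than 11 edits away is considered safe from cross-hybridization.

Three routes are provided:

* :func:`infix_edit_distance` — the production path, backed by edlib's
  banded semi-global aligner with an early-exit cap.
* :func:`brute_force_infix_distance` — an uncapped full dynamic-programming
  oracle (first DP row zero, answer = min of the last row), used as ground
  truth in tests.
* :func:`qgram_lower_bound` — a cheap provable lower bound from the q-gram
  lemma, used to skip hopeless genes before running the aligner.

``N`` bases never match anything (cost 1 against every character, including
another ``N``): an ambiguous base is treated as maximally non-specific.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import edlib
import numpy as np

__all__ = [
    "CAP_EXCEEDED",
    "DistanceResult",
    "infix_edit_distance",
    "brute_force_infix_distance",
    "qgram_lower_bound",
]


class _CapExceeded:
    """Sentinel returned when the true distance exceeds the requested cap."""

    _instance: Optional["_CapExceeded"] = None

    def __new__(cls) -> "_CapExceeded":
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return "CAP_EXCEEDED"

    def __bool__(self) -> bool:
        return False


CAP_EXCEEDED = _CapExceeded()

Distance = Union[int, _CapExceeded]


@dataclass(frozen=True)
class DistanceResult:
    """Outcome of a capped infix distance computation.

    ``distance`` is the minimum number of Levenshtein operations between the
    probe and the best-matching substring of the gene, or :data:`CAP_EXCEEDED`
    when the true minimum is larger than the cap.  ``end_position`` is the
    0-based half-open end offset of the best match in the gene (the smallest
    such offset when several substrings tie); it is ``None`` iff the cap was
    exceeded.
    """

    distance: Distance
    end_position: Optional[int] = None

    @property
    def exceeded(self) -> bool:
        return self.distance is CAP_EXCEEDED


def _mask_n(probe: str, gene: str) -> tuple[str, str]:
    # Map N to distinct out-of-alphabet letters on each side so that an N
    # never matches any base, not even another N.
    if "N" in probe:
        probe = probe.replace("N", "!")
    if "N" in gene:
        gene = gene.replace("N", "?")
    return probe, gene


def infix_edit_distance(probe: str, gene: str, cap: int) -> DistanceResult:
    """Capped minimum Levenshtein distance from ``probe`` to any substring of ``gene``.

    Parameters
    ----------
    probe:
        Query sequence, length >= 1.
    gene:
        Text sequence; may be empty, in which case the distance is
        ``len(probe)`` (delete every probe base against the empty infix).
    cap:
        Early-exit threshold, >= 0.  If the true minimum distance exceeds
        ``cap`` the result carries :data:`CAP_EXCEEDED` instead of a number.
    """
    if len(probe) < 1:
        raise ValueError("probe must have length >= 1")
    if cap < 0:
        raise ValueError("cap must be >= 0")
    if not gene:
        d = len(probe)
        if d > cap:
            return DistanceResult(CAP_EXCEEDED)
        return DistanceResult(d, end_position=0)
    p, g = _mask_n(probe, gene)
    res = edlib.align(p, g, mode="HW", task="locations", k=cap)
    d = res["editDistance"]
    if d == -1:
        return DistanceResult(CAP_EXCEEDED)
    # edlib locations are (start, end) with an inclusive end offset.
    end = min(loc[1] for loc in res["locations"]) + 1
    return DistanceResult(d, end_position=end)


def brute_force_infix_distance(probe: str, gene: str) -> int:
    """Uncapped semi-global DP oracle; ground truth for the fast path.

    Fills the full (len(probe)+1) x (len(gene)+1) matrix with the first row
    zero (a match may start anywhere in the gene) and returns the minimum of
    the last row (it may end anywhere).  Rows are vectorised: the insertion
    recurrence ``cur[j] = min(cur[j-1] + 1, ...)`` is resolved with a running
    minimum of ``base[j] - j``.
    """
    if len(probe) < 1:
        raise ValueError("probe must have length >= 1")
    n = len(gene)
    if n == 0:
        return len(probe)
    offsets = np.arange(n + 1)
    prev = np.zeros(n + 1, dtype=np.int64)
    gene_arr = np.frombuffer(gene.encode("ascii"), dtype=np.uint8)
    n_code = ord("N")
    for i, pc in enumerate(probe, start=1):
        pc_code = ord(pc)
        if pc_code == n_code:
            mismatch = np.ones(n, dtype=np.int64)  # N matches nothing
        else:
            mismatch = (gene_arr != pc_code).astype(np.int64)
            mismatch[gene_arr == n_code] = 1
        base = np.empty(n + 1, dtype=np.int64)
        base[0] = i
        base[1:] = np.minimum(prev[1:] + 1, prev[:-1] + mismatch)
        prev = np.minimum.accumulate(base - offsets) + offsets
    return int(prev.min())


def qgram_lower_bound(probe: str, gene: str, q: int) -> int:
    """Provable lower bound on the infix edit distance via the q-gram lemma.

    An alignment with d edits destroys at most ``q`` of the probe's
    overlapping q-grams each, so if ``missing`` probe q-gram positions have
    no exact occurrence anywhere in the gene, the distance is at least
    ``ceil(missing / q)``.  Used only as a gate: the bound is always
    <= the true distance, so skipping a gene whose bound already exceeds the
    cap can never change a result.
    """
    if not 1 <= q <= len(probe):
        raise ValueError("require 1 <= q <= len(probe)")
    gene_grams = {gene[i : i + q] for i in range(len(gene) - q + 1)}
    missing = sum(
        1 for i in range(len(probe) - q + 1) if probe[i : i + q] not in gene_grams
    )
    return -(-missing // q)
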