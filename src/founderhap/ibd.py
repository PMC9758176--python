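"""SNP-streak IBD segment detection on unphased genotypes.

Two diploid individuals who share a haplotype identical by descent can
never be opposite homozygotes (one 0/0, the other 1/1) at a site inside
the shared segment. A "SNP streak" is a maximal run of consecutive sites
compatible with that rule; long streaks are evidence of an IBD segment
inherited from a common ancestor (e.g. a founder haplotype around a
recurrent pathogenic variant).

Rules of the detector:

* compatibility is "not opposite homozygotes" — the standard unphased
  IBD1 test; phase is never used;
* missing genotypes are neutral: they never break a streak and never
  count toward the marker tally;
* a streak may contain up to ``max_mismatches`` incompatible sites and is
  trimmed so both boundary markers are informative and compatible;
* reported segments are maximal: extending either end would exceed the
  mismatch budget or run off the panel.

Coordinates are 1-based inclusive (VCF convention); the BED export in
:mod:`founderhap.vcfio` converts to 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np

from ._util import round_half_up
from .matrix import MISSING, GenotypeMatrix


@dataclass(frozen=True)
class StreakParams:
    """Streak acceptance thresholds.

    Defaults are conservative against chance streaks at typical array
    marker density: no mismatches, at least 100 informative markers and
    100 kb of span.
    """

    max_mismatches: int = 0
    min_markers: int = 100
    min_span_bp: int = 100_000

    def __post_init__(self) -> None:
        if min(self.max_mismatches, self.min_markers, self.min_span_bp) < 0:
            raise ValueError("streak parameters must be non-negative")


@dataclass(frozen=True)
class IBDSegment:
    pair: tuple[str, ...]
    chromosome: str
    start: int  # 1-based position of first compatible marker
    end: int  # 1-based position of last compatible marker
    n_markers: int  # informative compatible markers inside
    n_mismatches: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("segment start must not exceed end")

    @property
    def span_bp(self) -> int:
        return self.end - self.start


def segment_span_kb(seg: IBDSegment) -> int:
    """Span in kb, half-up rounded to the nearest 10 kb (reporting style)."""
    return int(round_half_up(seg.span_bp / 10_000, 0)) * 10


def _incompatible(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return ((a == 0) & (b == 2)) | ((a == 2) & (b == 0))


def _maximal_windows(incomp: np.ndarray, n: int, k: int) -> list[tuple[int, int]]:
    """All maximal index windows containing at most k incompatible sites."""
    idx = np.flatnonzero(incomp)
    m = idx.size
    if m <= k:
        return [(0, n - 1)] if n else []
    bounds = np.concatenate(([-1], idx, [n]))
    wins = []
    for j in range(m - k + 1):
        lo = int(bounds[j]) + 1
        hi = int(bounds[j + k + 1]) - 1
        if lo <= hi:
            wins.append((lo, hi))
    return wins


def _windows_to_segments(
    wins: Iterable[tuple[int, int]],
    compat_inform: np.ndarray,
    incomp: np.ndarray,
    pos: np.ndarray,
    chromosome: str,
    pair: tuple[str, ...],
    params: StreakParams,
) -> list[IBDSegment]:
    trimmed: set[tuple[int, int]] = set()
    for lo, hi in wins:
        inside = np.flatnonzero(compat_inform[lo : hi + 1])
        if inside.size:
            trimmed.add((lo + int(inside[0]), lo + int(inside[-1])))

    # trimming boundary mismatches can leave one window inside another;
    # keep only windows not strictly contained in a larger one
    segs: list[IBDSegment] = []
    best_hi = -1
    for lo2, hi2 in sorted(trimmed, key=lambda w: (w[0], -w[1])):
        if hi2 <= best_hi:
            continue
        best_hi = hi2
        n_markers = int(compat_inform[lo2 : hi2 + 1].sum())
        n_mis = int(incomp[lo2 : hi2 + 1].sum())
        start, end = int(pos[lo2]), int(pos[hi2])
        if n_markers >= params.min_markers and end - start >= params.min_span_bp:
            segs.append(
                IBDSegment(pair, chromosome, start, end, n_markers, n_mis)
            )
    return segs


def pairwise_ibd_segments(
    gm: GenotypeMatrix,
    pair: tuple[str, str],
    params: StreakParams = StreakParams(),
) -> list[IBDSegment]:
    """Maximal IBD-compatible streaks between one sample pair."""
    i, j = gm.sample_index(pair[0]), gm.sample_index(pair[1])
    key = tuple(pair)
    out: list[IBDSegment] = []
    for chromosome in gm.chromosomes():
        sl = gm.chrom_slice(chromosome)
        a, b = gm.codes[i, sl], gm.codes[j, sl]
        pos = gm.pos[sl]
        informative = (a != MISSING) & (b != MISSING)
        incomp = _incompatible(a, b)
        compat_inform = informative & ~incomp
        wins = _maximal_windows(incomp, pos.size, params.max_mismatches)
        out.extend(
            _windows_to_segments(
                wins, compat_inform, incomp, pos, chromosome, key, params
            )
        )
    return out


def multiway_shared_segments(
    gm: GenotypeMatrix,
    samples: Sequence[str],
    params: StreakParams = StreakParams(),
) -> list[IBDSegment]:
    """Intervals shared IBD-compatibly by every pair in a sample group.

    Computes pairwise streaks for all pairs, intersects the resulting
    intervals, then re-trims and re-filters each shared interval against
    ``min_markers``/``min_span_bp`` on the marker panel.
    """
    if len(samples) < 2:
        raise ValueError("multiway sharing needs at least 2 samples")
    idxs = [gm.sample_index(s) for s in samples]
    pairs = list(combinations(samples, 2))

    # bp-interval intersection of pairwise segment lists, per chromosome
    shared: dict[str, list[tuple[int, int]]] = {}
    for pi, pair in enumerate(pairs):
        segs = pairwise_ibd_segments(gm, pair, params)
        cur: dict[str, list[tuple[int, int]]] = {}
        for s in segs:
            cur.setdefault(s.chromosome, []).append((s.start, s.end))
        if pi == 0:
            shared = cur
            continue
        nxt: dict[str, list[tuple[int, int]]] = {}
        for chromosome, ivs in shared.items():
            for s1, e1 in ivs:
                for s2, e2 in cur.get(chromosome, []):
                    s, e = max(s1, s2), min(e1, e2)
                    if s <= e:
                        nxt.setdefault(chromosome, []).append((s, e))
        shared = nxt

    key = tuple(samples)
    out: list[IBDSegment] = []
    for chromosome, ivs in shared.items():
        sl = gm.chrom_slice(chromosome)
        pos = gm.pos[sl]
        codes = gm.codes[np.ix_(idxs, range(sl.start, sl.stop))]
        informative = (codes != MISSING).all(axis=0)
        incomp = np.zeros(pos.size, dtype=bool)
        for x, y in combinations(range(len(idxs)), 2):
            incomp |= _incompatible(codes[x], codes[y])
        compat_inform = informative & ~incomp
        for s, e in sorted(set(ivs)):
            lo = int(np.searchsorted(pos, s, side="left"))
            hi = int(np.searchsorted(pos, e, side="right")) - 1
            if lo > hi:
                continue
            out.extend(
                _windows_to_segments(
                    [(lo, hi)], compat_inform, incomp, pos, chromosome, key, params
                )
            )
    return out
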