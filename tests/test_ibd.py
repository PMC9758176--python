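"""SNP-streak detection: oracle equivalence, planted segments, symmetry."""

import numpy as np
import pytest

from founderhap.ibd import (
    IBDSegment,
    StreakParams,
    multiway_shared_segments,
    pairwise_ibd_segments,
    segment_span_kb,
)
from founderhap.matrix import GenotypeMatrix
from founderhap.simulate import (
    FounderSpec,
    PanelSite,
    SampleSpec,
    SimulationConfig,
    founder_demo_config,
    simulate_genotypes,
)

from oracles import brute_force_streaks


def _matrix(codes, pos=None, samples=None):
    codes = np.asarray(codes, dtype=np.int8)
    n = codes.shape[1]
    if pos is None:
        pos = 1000 + 2000 * np.arange(n)
    if samples is None:
        samples = [f"S{i}" for i in range(codes.shape[0])]
    return GenotypeMatrix(
        samples=samples,
        chrom=np.array(["1"] * n, dtype=object),
        pos=np.asarray(pos),
        ref=np.array(["A"] * n, dtype=object),
        alt=np.array(["G"] * n, dtype=object),
        codes=codes,
    )


def _as_tuples(segs):
    return sorted((s.start, s.end, s.n_markers, s.n_mismatches) for s in segs)


def test_identical_samples_single_full_segment(rng):
    g = rng.integers(0, 3, size=500).astype(np.int8)
    pos = np.sort(rng.choice(np.arange(1, 1_000_001), size=500, replace=False))
    gm = _matrix([g, g], pos=pos)
    segs = pairwise_ibd_segments(gm, ("S0", "S1"), StreakParams(0, 10, 0))
    assert len(segs) == 1
    assert (segs[0].start, segs[0].end) == (int(pos[0]), int(pos[-1]))
    assert segs[0].n_markers == 500


def test_opposite_homozygotes_break_streaks():
    # sites 0-2 compatible, site 3 opposite-hom, sites 4-6 compatible
    a = [1, 0, 2, 0, 1, 1, 2]
    b = [1, 0, 2, 2, 1, 1, 2]
    gm = _matrix([a, b])
    segs = pairwise_ibd_segments(gm, ("S0", "S1"), StreakParams(0, 1, 0))
    assert _as_tuples(segs) == [(1000, 5000, 3, 0), (9000, 13000, 3, 0)]


def test_missing_genotypes_are_neutral():
    a = [1, -1, 0, -1, 1]
    b = [1, 2, -1, 0, 1]
    gm = _matrix([a, b])
    (seg,) = pairwise_ibd_segments(gm, ("S0", "S1"), StreakParams(0, 1, 0))
    # streak runs across the no-calls; only fully-called sites are markers
    assert (seg.start, seg.end) == (1000, 9000)
    assert seg.n_markers == 2


def test_symmetry(rng):
    codes = rng.integers(-1, 3, size=(2, 300)).astype(np.int8)
    gm = _matrix(codes)
    p = StreakParams(1, 3, 0)
    assert _as_tuples(pairwise_ibd_segments(gm, ("S0", "S1"), p)) == _as_tuples(
        pairwise_ibd_segments(gm, ("S1", "S0"), p)
    )


def test_unknown_sample_rejected(demo_matrix):
    with pytest.raises(ValueError, match="unknown sample"):
        pairwise_ibd_segments(demo_matrix, ("P1", "nope"), StreakParams())


@pytest.mark.parametrize("max_mismatches", [0, 1, 2])
@pytest.mark.parametrize("min_markers,min_span", [(1, 0), (5, 50_000)])
def test_streaks_equal_brute_force_oracle(max_mismatches, min_markers, min_span):
    """Detector output equals exhaustive maximal-window enumeration."""
    for seed in range(6):
        rng = np.random.default_rng(1000 + seed)
        n = int(rng.integers(50, 201))
        codes = rng.choice(
            [-1, 0, 1, 2], size=(2, n), p=[0.05, 0.3, 0.35, 0.3]
        ).astype(np.int8)
        pos = np.sort(rng.choice(np.arange(1, 2_000_001), size=n, replace=False))
        gm = _matrix(codes, pos=pos)
        params = StreakParams(max_mismatches, min_markers, min_span)
        got = _as_tuples(pairwise_ibd_segments(gm, ("S0", "S1"), params))
        want = brute_force_streaks(
            codes[0], codes[1], pos, max_mismatches, min_markers, min_span
        )
        assert got == want, f"seed={seed}"


def test_random_pairs_rarely_share_long_streaks():
    """Chance streaks above the run-length bound are rare at f=0.5.

    Opposite homozygotes occur w.p. 2*(1/4)^2 = 1/8 per site, so maximal
    compatible runs are geometric with mean 8; among ~125 runs per
    1000-site panel the expected number reaching 60 markers is
    125 * (7/8)^59 ~ 0.05, so almost all seeds yield none.
    """
    hits = 0
    for seed in range(50):
        rng = np.random.default_rng(seed)
        codes = rng.choice([0, 1, 2], size=(2, 1000), p=[0.25, 0.5, 0.25]).astype(np.int8)
        gm = _matrix(codes)
        if pairwise_ibd_segments(gm, ("S0", "S1"), StreakParams(0, 60, 0)):
            hits += 1
    assert hits <= 5  # >= 90% of seeds yield none


@pytest.mark.parametrize(
    "start,end,kb",
    [
        (36_118_198, 37_898_880, 1780),
        (36_137_298, 36_818_382, 680),
        (100, 100, 0),
    ],
)
def test_segment_span_kb_rounds_to_10kb(start, end, kb):
    seg = IBDSegment(("a", "b"), "9", start, end, 10, 0)
    assert segment_span_kb(seg) == kb


def test_planted_founder_segment_recovered_exactly(demo_matrix):
    params = StreakParams(0, 150, 100_000)
    (seg,) = multiway_shared_segments(demo_matrix, ["P1", "P2"], params)
    assert (seg.start, seg.end) == (36_118_198, 37_898_880)
    (seg,) = multiway_shared_segments(demo_matrix, ["P3", "H1"], params)
    assert (seg.start, seg.end) == (36_137_298, 36_818_382)


def test_multiway_topology(demo_matrix):
    """Pair-specific segments do not survive intersection over all four."""
    params = StreakParams(0, 150, 100_000)
    assert multiway_shared_segments(demo_matrix, ["P1", "P2", "P3", "H1"], params) == []
    with pytest.raises(ValueError):
        multiway_shared_segments(demo_matrix, ["P1"], params)


def test_multiway_two_samples_reduces_to_pairwise(demo_matrix):
    params = StreakParams(0, 20, 0)
    multi = multiway_shared_segments(demo_matrix, ["P1", "P2"], params)
    pair = pairwise_ibd_segments(demo_matrix, ("P1", "P2"), params)
    assert _as_tuples(multi) == _as_tuples(pair)


def _recovery_config(seed, error_rate):
    """1 Mb planted span, ~1 marker / 5 kb, founder homozygote + carrier pair.

    Eight forced-incompatible markers cluster at each flank so the streak
    cannot leak past a boundary within the mismatch budget.
    """
    span = (1_500_000, 2_500_000)
    flanks = []
    forced = []
    for base, sign in ((span[0], -1), (span[1], +1)):
        for i in range(1, 9):
            p = base + sign * 60 * i
            flanks.append(PanelSite(p, "A", "G"))
            forced += [("A", p, 0), ("B", p, 2)]
    zones = ((span[0] - 600, span[0] - 1), (span[1] + 1, span[1] + 600))
    return SimulationConfig(
        seed=seed,
        region=("1", 1_000_000, 3_000_000),
        n_sites=420,
        panel_sites=tuple(flanks),
        founders=(FounderSpec("f", span, {}),),
        samples=(SampleSpec("A", "f", "f"), SampleSpec("B", "f", "background")),
        genotype_error_rate=error_rate,
        forced_genotypes=tuple(forced),
        exclude_zones=zones,
    )


def test_planted_span_recovery_with_genotype_errors():
    """Recovered span within 5% of planted for >= 95% of 100 noisy replicates."""
    planted = 1_000_000
    ok = 0
    for seed in range(100):
        gm = simulate_genotypes(_recovery_config(3000 + seed, 0.002))
        segs = pairwise_ibd_segments(gm, ("A", "B"), StreakParams(2, 50, 200_000))
        best = max(
            (s for s in segs if s.start <= 2_000_000 <= s.end),
            default=None,
            key=lambda s: s.span_bp,
        )
        if best is not None and abs(best.span_bp - planted) / planted < 0.05:
            ok += 1
    assert ok >= 95


def test_planted_span_recovery_exact_without_errors():
    for seed in (5, 6, 7):
        gm = simulate_genotypes(_recovery_config(seed, 0.0))
        segs = pairwise_ibd_segments(gm, ("A", "B"), StreakParams(0, 50, 200_000))
        assert any((s.start, s.end) == (1_500_000, 2_500_000) for s in segs)
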