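"""Seeded synthetic-data generator for every pipeline stage.

Emulates the statistical structure the analyses assume, with known truth:

* biallelic SNP panels with site-wise independent background haplotypes
  (linkage equilibrium) at configurable alt-allele frequencies;
* founder haplotypes: a fixed ancestral allele vector planted over a
  configurable span, carrying a marker pattern (e.g. the alpha/beta
  tag-SNP patterns plus the risk allele) at named panel sites; outside
  the planted span a founder chromosome decays to independent background,
  so the IBD-sharing region has exact, known boundaries;
* diploid samples assembled from two haplotype specs (founder label or
  background), with optional symmetric genotype errors (single-step code
  perturbation 0<->1<->2) and missingness applied last;
* Hardy-Weinberg cohort sampling at a focal locus;
* normally distributed group measurements (onset ages, sialylation).

Everything is deterministic given the config seed: one global generator
consumed in a fixed documented order (positions, alleles, frequencies,
founder cores, samples in config order, errors, missingness).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .matrix import MISSING, GenotypeMatrix
from .popgen import MeasurementSet

_BASES = np.array(["A", "C", "G", "T"], dtype=object)


@dataclass(frozen=True)
class PanelSite:
    """A fixed marker site with declared alleles."""

    position: int
    ref: str
    alt: str


@dataclass(frozen=True)
class FounderSpec:
    """An ancestral haplotype with a planted IBD span and marker pattern."""

    label: str
    planted_span: tuple[int, int]
    marker_pattern: dict[int, str] = field(default_factory=dict)
    risk: bool = True


@dataclass(frozen=True)
class SampleSpec:
    """A diploid individual: each haplotype is a founder label or 'background'."""

    id: str
    hap1: str = "background"
    hap2: str = "background"


@dataclass(frozen=True)
class SimulationConfig:
    seed: int
    region: tuple[str, int, int]  # chromosome, start bp, end bp (inclusive)
    n_sites: int
    panel_sites: tuple[PanelSite, ...] = ()
    founders: tuple[FounderSpec, ...] = ()
    samples: tuple[SampleSpec, ...] = ()
    background_freq_range: tuple[float, float] = (0.05, 0.95)
    alt_freq_overrides: dict[int, float] = field(default_factory=dict)
    genotype_error_rate: float = 0.0
    missing_rate: float = 0.0
    #: genotype overrides (sample_id, position, code) applied after assembly,
    #: before the error/missing processes — used to plant incompatible
    #: flanking markers adjacent to span boundaries
    forced_genotypes: tuple[tuple[str, int, int], ...] = ()
    #: bp intervals (inclusive) kept free of random marker positions
    exclude_zones: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        _, lo, hi = self.region
        if not 0 <= self.genotype_error_rate < 1 or not 0 <= self.missing_rate < 1:
            raise ValueError("error/missing rates must be in [0, 1)")
        for f in self.founders:
            s, e = f.planted_span
            if not (lo <= s <= e <= hi):
                raise ValueError(f"planted span of {f.label!r} outside region")
            for p in f.marker_pattern:
                if not lo <= p <= hi:
                    raise ValueError(
                        f"pattern position {p} of {f.label!r} outside region"
                    )
        panel_pos = {ps.position for ps in self.panel_sites}
        for f in self.founders:
            missing = set(f.marker_pattern) - panel_pos
            if missing:
                raise ValueError(
                    f"pattern positions {sorted(missing)} of {f.label!r} are not "
                    "declared panel sites (alleles unknown)"
                )
        known = {f.label for f in self.founders} | {"background"}
        for s in self.samples:
            for h in (s.hap1, s.hap2):
                if h not in known:
                    raise ValueError(f"sample {s.id!r} references unknown haplotype {h!r}")


def _draw_positions(rng: np.random.Generator, cfg: SimulationConfig) -> np.ndarray:
    """Sorted marker positions: panel sites, span endpoints, then random fill."""
    _, lo, hi = cfg.region
    fixed = {ps.position for ps in cfg.panel_sites}
    for f in cfg.founders:
        fixed.update(f.planted_span)  # endpoints are markers: exact boundaries
    banned = set(fixed)
    n_random = max(cfg.n_sites - len(fixed), 0)
    chosen: set[int] = set()
    while len(chosen) < n_random:
        draw = rng.integers(lo, hi + 1, size=2 * (n_random - len(chosen)))
        for p in draw:
            p = int(p)
            if p in banned or p in chosen:
                continue
            if any(zs <= p <= ze for zs, ze in cfg.exclude_zones):
                continue
            chosen.add(p)
            if len(chosen) >= n_random:
                break
    return np.array(sorted(fixed | chosen), dtype=np.int64)


def simulate_genotypes(cfg: SimulationConfig) -> GenotypeMatrix:
    """Generate a VCF-writable genotype matrix per the config (seeded)."""
    rng = np.random.default_rng(cfg.seed)
    chromosome, _, _ = cfg.region
    pos = _draw_positions(rng, cfg)
    n = pos.size
    site_of = {int(p): i for i, p in enumerate(pos)}

    # alleles: declared for panel sites, random distinct pair elsewhere
    ref = np.empty(n, dtype=object)
    alt = np.empty(n, dtype=object)
    panel = {ps.position: ps for ps in cfg.panel_sites}
    for i, p in enumerate(pos):
        p = int(p)
        if p in panel:
            ref[i], alt[i] = panel[p].ref, panel[p].alt
        else:
            r = rng.integers(0, 4)
            a = (r + 1 + rng.integers(0, 3)) % 4
            ref[i], alt[i] = _BASES[r], _BASES[a]

    f_lo, f_hi = cfg.background_freq_range
    freqs = rng.uniform(f_lo, f_hi, size=n)
    for p, q in cfg.alt_freq_overrides.items():
        if p in site_of:
            freqs[site_of[p]] = q

    # founder cores: fixed ancestral allele vectors, defined inside the span
    # and at pattern positions
    cores: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for f in cfg.founders:
        core = (rng.random(n) < freqs).astype(np.int8)
        defined = (pos >= f.planted_span[0]) & (pos <= f.planted_span[1])
        for p, base in f.marker_pattern.items():
            i = site_of[p]
            if base == ref[i]:
                core[i] = 0
            elif base == alt[i]:
                core[i] = 1
            else:
                raise ValueError(
                    f"pattern base {base!r} at {p} is neither ref nor alt"
                )
            defined[i] = True
        cores[f.label] = (core, defined)

    def haplotype(spec: str) -> np.ndarray:
        h = (rng.random(n) < freqs).astype(np.int8)
        if spec != "background":
            core, defined = cores[spec]
            h[defined] = core[defined]
        return h

    codes = np.empty((len(cfg.samples), n), dtype=np.int8)
    for si, s in enumerate(cfg.samples):
        codes[si] = haplotype(s.hap1) + haplotype(s.hap2)

    sample_of = {s.id: i for i, s in enumerate(cfg.samples)}
    for sid, p, code in cfg.forced_genotypes:
        codes[sample_of[sid], site_of[p]] = code

    if cfg.genotype_error_rate > 0:
        err = rng.random(codes.shape) < cfg.genotype_error_rate
        direction = rng.random(codes.shape) < 0.5  # het errors: down vs up
        het = codes == 1
        codes = np.where(err & ~het, 1, codes).astype(np.int8)
        codes = np.where(err & het & direction, 0, codes).astype(np.int8)
        codes = np.where(err & het & ~direction, 2, codes).astype(np.int8)
    if cfg.missing_rate > 0:
        miss = rng.random(codes.shape) < cfg.missing_rate
        codes = np.where(miss, MISSING, codes).astype(np.int8)

    return GenotypeMatrix(
        samples=[s.id for s in cfg.samples],
        chrom=np.array([chromosome] * n, dtype=object),
        pos=pos,
        ref=ref,
        alt=alt,
        codes=codes,
    )


def panel_truth(cfg: SimulationConfig) -> dict:
    """Ground truth of a simulated panel, for oracle comparison."""
    return {
        "seed": cfg.seed,
        "region": list(cfg.region),
        "founders": {
            f.label: {
                "planted_span": list(f.planted_span),
                "risk": f.risk,
                "marker_pattern": {str(k): v for k, v in f.marker_pattern.items()},
            }
            for f in cfg.founders
        },
        "samples": {s.id: [s.hap1, s.hap2] for s in cfg.samples},
    }


# ---------------------------------------------------------------------------
# Hardy-Weinberg cohort sampling


@dataclass(frozen=True)
class CohortSimConfig:
    seed: int
    population_n: int
    allele_freq: float
    replicates: int = 1

    def __post_init__(self) -> None:
        if not 0 <= self.allele_freq <= 1:
            raise ValueError("allele frequency must be in [0, 1]")
        if self.population_n <= 0 or self.replicates <= 0:
            raise ValueError("population_n and replicates must be positive")


def simulate_cohort(cfg: CohortSimConfig) -> list[dict[str, int]]:
    """Per-replicate genotype counts under HWE: (q^2, 2q(1-q), (1-q)^2)."""
    rng = np.random.default_rng(cfg.seed)
    q = cfg.allele_freq
    probs = [q * q, 2 * q * (1 - q), (1 - q) * (1 - q)]
    draws = rng.multinomial(cfg.population_n, probs, size=cfg.replicates)
    return [
        {"hom_alt": int(d[0]), "het": int(d[1]), "hom_ref": int(d[2])}
        for d in draws
    ]


def simulate_measurements(groups, seed: int) -> list[MeasurementSet]:
    """Independent normal draws per group spec {label, mean, sd, n}."""
    rng = np.random.default_rng(seed)
    out = []
    for g in groups:
        label, mean, sd, n = g["label"], g["mean"], g["sd"], g["n"]
        if sd < 0 or n < 1:
            raise ValueError("sd must be >= 0 and n >= 1")
        out.append(MeasurementSet(label, rng.normal(mean, sd, size=n)))
    return out


# ---------------------------------------------------------------------------
# bundled founder-panel scenario

#: GNE region tag-SNP panel (chromosome 9, plus strand)
GNE_PANEL_SITES = (
    PanelSite(36_214_971, "G", "A"),
    PanelSite(36_216_426, "G", "A"),
    PanelSite(36_217_798, "G", "A"),
    PanelSite(36_220_134, "T", "C"),
    PanelSite(36_246_117, "T", "A"),  # risk site: c.620A>T (genomic T>A)
)

ALPHA_SPAN = (36_118_198, 37_898_880)  # 1780 kb
BETA_SPAN = (36_137_298, 36_818_382)  # 680 kb

ALPHA_PATTERN = {
    36_214_971: "G",
    36_216_426: "G",
    36_217_798: "G",
    36_220_134: "C",
    36_246_117: "A",
}
BETA_PATTERN = {
    36_214_971: "A",
    36_216_426: "A",
    36_217_798: "A",
    36_220_134: "T",
    36_246_117: "A",
}


def founder_demo_config(
    seed: int,
    n_sites: int = 1200,
    genotype_error_rate: float = 0.0,
    missing_rate: float = 0.0,
    n_alpha_carriers: int = 3,
    n_beta_carriers: int = 1,
) -> SimulationConfig:
    """Two-founder scenario: four risk homozygotes plus unphased carriers.

    P1/P2 are homozygous for founder alpha (planted span 1780 kb), P3/H1
    for founder beta (680 kb); incompatible markers are forced at the
    sites flanking each span so streak detection recovers the planted
    boundaries exactly. Panel-site background frequencies are pinned to 0
    so non-founder chromosomes carry the background pattern [G,G,G,T] and
    the reference risk allele.
    """
    flank = 200
    a_lo, a_hi = ALPHA_SPAN
    b_lo, b_hi = BETA_SPAN
    flank_sites = (
        PanelSite(a_lo - flank, "A", "G"),
        PanelSite(a_hi + flank, "A", "G"),
        PanelSite(b_lo - flank, "A", "G"),
        PanelSite(b_hi + flank, "A", "G"),
    )
    forced = []
    for p in (a_lo - flank, a_hi + flank):
        forced += [("P1", p, 0), ("P2", p, 2)]
    for p in (b_lo - flank, b_hi + flank):
        forced += [("P3", p, 0), ("H1", p, 2)]
    zones = tuple(
        (s, e)
        for s, e in (
            (a_lo - flank, a_lo - 1),
            (a_hi + 1, a_hi + flank),
            (b_lo - flank, b_lo - 1),
            (b_hi + 1, b_hi + flank),
        )
    )
    samples = [
        SampleSpec("P1", "alpha", "alpha"),
        SampleSpec("P2", "alpha", "alpha"),
        SampleSpec("P3", "beta", "beta"),
        SampleSpec("H1", "beta", "beta"),
    ]
    samples += [
        SampleSpec(f"C{i + 1}", "alpha", "background")
        for i in range(n_alpha_carriers)
    ]
    samples += [
        SampleSpec(f"C{n_alpha_carriers + i + 1}", "beta", "background")
        for i in range(n_beta_carriers)
    ]
    return SimulationConfig(
        seed=seed,
        region=("9", 35_600_000, 38_400_000),
        n_sites=n_sites,
        panel_sites=GNE_PANEL_SITES + flank_sites,
        founders=(
            FounderSpec("alpha", ALPHA_SPAN, ALPHA_PATTERN),
            FounderSpec("beta", BETA_SPAN, BETA_PATTERN),
        ),
        samples=tuple(samples),
        alt_freq_overrides={ps.position: 0.0 for ps in GNE_PANEL_SITES},
        genotype_error_rate=genotype_error_rate,
        missing_rate=missing_rate,
        forced_genotypes=tuple(forced),
        exclude_zones=zones,
    )
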