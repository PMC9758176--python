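"""Rule-based founder-haplotype (diplotype) classification.

A recurrent risk allele that arose independently on two ancestral
chromosomes can be traced through a small panel of discriminating markers
linked to the risk site: founder haplotype alpha carries one allele
pattern across the panel, founder beta another, and non-risk chromosomes
in the population carry a third, background pattern. Because the
discriminating alleles differ between alpha, beta and background at every
site, the unphased diploid genotypes at the panel uniquely identify the
diplotype of clean samples — no statistical phasing is needed.

The default rule is the chromosome-9 GNE c.620A>T panel: four
discriminating variants upstream of the risk site, alpha = [G,G,G,C],
beta = [A,A,A,T], background = [G,G,G,T], risk alt allele A (plus-strand;
the gene is on the minus strand, so cDNA A>T is genomic T>A).

Conflicting or incomplete genotype patterns always yield "unknown" with a
reason — the classifier never forces a call.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from ._util import round_half_up

#: the seven possible diplotype labels
DIPLOTYPES = (
    "alpha/alpha",
    "beta/beta",
    "alpha/beta",
    "alpha/-",
    "beta/-",
    "none",
    "unknown",
)


@dataclass(frozen=True)
class HaplotypeRule:
    """Discriminating-marker panel defining founder haplotypes alpha/beta."""

    chromosome: str = "9"
    discriminating_sites: tuple[int, ...] = (36_214_971, 36_216_426, 36_217_798, 36_220_134)
    risk_site: int = 36_246_117
    alpha_pattern: tuple[str, ...] = ("G", "G", "G", "C")
    beta_pattern: tuple[str, ...] = ("A", "A", "A", "T")
    background_pattern: tuple[str, ...] = ("G", "G", "G", "T")
    risk_ref: str = "T"
    risk_alt: str = "A"

    def __post_init__(self) -> None:
        n = len(self.discriminating_sites)
        if not len(self.alpha_pattern) == len(self.beta_pattern) == len(self.background_pattern) == n:
            raise ValueError("patterns must match the number of discriminating sites")
        same = [
            i for i in range(n) if self.alpha_pattern[i] == self.beta_pattern[i]
        ]
        if same:
            raise ValueError(
                f"alpha and beta patterns agree at site index {same[0]}; "
                "non-discriminating sites must be dropped from the rule"
            )

    @property
    def panel_sites(self) -> tuple[int, ...]:
        return self.discriminating_sites + (self.risk_site,)


DEFAULT_RULE = HaplotypeRule()


@dataclass(frozen=True)
class HaplotypeCall:
    sample: str
    diplotype: str
    evidence: Mapping[int, str | None] = field(default_factory=dict)
    reason: str = ""

    def __post_init__(self) -> None:
        if self.diplotype not in DIPLOTYPES:
            raise ValueError(f"invalid diplotype label {self.diplotype!r}")


def _as_pair(g) -> frozenset | Counter:
    """Genotype as an allele multiset; accepts 'GT', ('G','T') or 'G/T'."""
    if isinstance(g, str):
        g = g.replace("/", "").replace("|", "")
        alleles = tuple(g)
    else:
        alleles = tuple(g)
    if len(alleles) != 2:
        raise ValueError(f"diploid genotype expected, got {g!r}")
    return Counter(a.upper() for a in alleles)


def classify_diplotype(
    genotypes: Mapping[int, object],
    rule: HaplotypeRule = DEFAULT_RULE,
    sample: str = "",
) -> HaplotypeCall:
    """Assign a founder diplotype from unphased genotypes at the panel sites.

    ``genotypes`` maps position -> diploid genotype (e.g. ``"GG"``,
    ``("C", "T")``); ``None`` or an absent position marks a missing call.
    The risk-site genotype is mandatory. Candidate diplotypes are those
    consistent with the risk dosage (hom-alt: alpha/alpha, beta/beta,
    alpha/beta; het: alpha over background, beta over background); a call
    is made only when exactly one candidate matches the observed allele
    multiset at every discriminating site.
    """
    risk_g = genotypes.get(rule.risk_site)
    if risk_g is None:
        raise ValueError("risk-site genotype is required for classification")
    risk = _as_pair(risk_g)
    dose = risk.get(rule.risk_alt.upper(), 0)
    evidence = {p: None if genotypes.get(p) is None else str(genotypes[p]) for p in rule.panel_sites}

    if dose == 0:
        return HaplotypeCall(sample, "none", evidence)

    obs: list[Counter | None] = []
    for p in rule.discriminating_sites:
        g = genotypes.get(p)
        obs.append(None if g is None else _as_pair(g))
    if any(o is None for o in obs):
        return HaplotypeCall(sample, "unknown", evidence, "insufficient markers")

    a, b, bg = rule.alpha_pattern, rule.beta_pattern, rule.background_pattern
    if dose == 2:
        candidates = {
            "alpha/alpha": (a, a),
            "beta/beta": (b, b),
            "alpha/beta": (a, b),
        }
    else:
        candidates = {"alpha/-": (a, bg), "beta/-": (b, bg)}

    matches = [
        label
        for label, (h1, h2) in candidates.items()
        if all(
            obs[i] == Counter((h1[i].upper(), h2[i].upper()))
            for i in range(len(obs))
        )
    ]
    if len(matches) == 1:
        return HaplotypeCall(sample, matches[0], evidence)
    reason = "ambiguous pattern" if matches else "pattern conflict"
    return HaplotypeCall(sample, "unknown", evidence, reason)


def haplotype_frequencies(
    calls: Iterable[HaplotypeCall], stratum: str = ""
) -> dict:
    """Alpha/beta haplotype-copy counts and percentage fractions.

    Each call contributes its risk-haplotype copies (alpha/alpha -> two
    alpha, alpha/- -> one alpha, alpha/beta -> one of each); ``none`` and
    ``unknown`` calls are excluded. Percentages are displayed to one
    decimal, half-up.
    """
    counts = Counter()
    for call in calls:
        if call.diplotype in ("none", "unknown"):
            continue
        h1, h2 = call.diplotype.split("/")
        for h in (h1, h2):
            if h in ("alpha", "beta"):
                counts[h] += 1
    total = counts["alpha"] + counts["beta"]
    out: dict = {"stratum": stratum, "counts": dict(counts), "total": total}
    if total == 0:
        out["warning"] = "no classifiable calls"
        return out
    out["fractions_pct"] = {
        h: round_half_up(counts[h] / total * 100.0, 1) for h in ("alpha", "beta")
    }
    return out
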