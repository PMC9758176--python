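"""Multiplicative route-flux scoring for a dimeric bifunctional enzyme.

GNE carries both a UDP-GlcNAc 2-epimerase domain and a ManNAc kinase
domain and functions as an oligomer; ManNAc produced by the epimerase of
one monomer can be phosphorylated by the kinase of the same monomer
(intramolecular route) or handed to the kinase of the partner monomer
(intermonomer route). Total ManNAc 6-phosphate production of a dimer is
scored as the sum of four production routes, each route the product of
three efficiencies:

    route(source -> dest) = epimerase(source) x transfer x kinase(dest)

Efficiencies are unitless scores in [0, 1]; a wild-type dimer scores 1 on
every component, so its total is 4 and its normalized (relative) total
is 1. Scores given as ranges (e.g. the variable intermonomer transfer of
a dimer containing D207V, 0.3-0.5) propagate by interval arithmetic:
products and sums of non-negative intervals are endpoint-wise, so the
computed total is a sharp enclosure of every point-valued scenario.

Presets:

* ``WT``        — all components 1;
* ``D207V``     — intramolecular ManNAc transfer halved (0.5); its
  presence in a dimer impairs oligomerization, making intermonomer
  transfer variable (0.3-0.5); both enzymatic domains untouched;
* ``catalytic`` — a catalytic-site mutant: both enzymatic reactions at 0.1;
* ``V603L``     — both enzymatic reactions at 0.2;
* ``D207V_invitro`` — alternative D207V parameterization with the in
  vitro epimerase activity (18% of wild type) instead of 1; never the
  default.
"""

from __future__ import annotations

from dataclasses import dataclass, replace


@dataclass(frozen=True)
class Interval:
    """Closed interval [lo, hi] with endpoint-wise non-negative arithmetic."""

    lo: float
    hi: float

    def __post_init__(self) -> None:
        if self.lo > self.hi:
            raise ValueError(f"interval bounds out of order: [{self.lo}, {self.hi}]")
        if self.lo < 0:
            raise ValueError("interval bounds must be non-negative")

    @classmethod
    def point(cls, x: float) -> "Interval":
        return cls(x, x)

    @classmethod
    def coerce(cls, x) -> "Interval":
        if isinstance(x, Interval):
            return x
        if isinstance(x, (int, float)):
            return cls.point(float(x))
        lo, hi = x
        return cls(float(lo), float(hi))

    def __mul__(self, other: "Interval") -> "Interval":
        o = Interval.coerce(other)
        return Interval(self.lo * o.lo, self.hi * o.hi)

    def __add__(self, other: "Interval") -> "Interval":
        o = Interval.coerce(other)
        return Interval(self.lo + o.lo, self.hi + o.hi)

    def __truediv__(self, k: float) -> "Interval":
        return Interval(self.lo / k, self.hi / k)

    def contains(self, x: float) -> bool:
        return self.lo - 1e-12 <= x <= self.hi + 1e-12

    def as_tuple(self) -> tuple[float, float]:
        return (self.lo, self.hi)


def _score(x) -> Interval:
    iv = Interval.coerce(x)
    if iv.hi > 1.0:
        raise ValueError("component scores must lie in [0, 1]")
    return iv


@dataclass(frozen=True)
class MonomerParams:
    """Per-monomer component scores (each an interval within [0, 1])."""

    variant_label: str
    epimerase_score: Interval
    kinase_score: Interval
    intra_transfer_score: Interval
    impairs_oligomerization: bool = False

    def __post_init__(self) -> None:
        for name in ("epimerase_score", "kinase_score", "intra_transfer_score"):
            object.__setattr__(self, name, _score(getattr(self, name)))


@dataclass(frozen=True)
class DimerFluxModel:
    monomer1: MonomerParams
    monomer2: MonomerParams
    inter_transfer_score: Interval | None = None  # None -> preset rule

    def __post_init__(self) -> None:
        if self.inter_transfer_score is not None:
            object.__setattr__(
                self, "inter_transfer_score", _score(self.inter_transfer_score)
            )

    @property
    def inter_transfer(self) -> Interval:
        if self.inter_transfer_score is not None:
            return self.inter_transfer_score
        if self.monomer1.impairs_oligomerization or self.monomer2.impairs_oligomerization:
            return IMPAIRED_INTER_TRANSFER
        return Interval.point(1.0)


@dataclass(frozen=True)
class RouteScores:
    intra_1: Interval
    intra_2: Interval
    inter_1to2: Interval
    inter_2to1: Interval
    total: Interval
    total_relative_to_wt: Interval

    def as_dict(self) -> dict:
        return {
            "routes": {
                "intra_1": self.intra_1.as_tuple(),
                "intra_2": self.intra_2.as_tuple(),
                "inter_1to2": self.inter_1to2.as_tuple(),
                "inter_2to1": self.inter_2to1.as_tuple(),
            },
            "total": self.total.as_tuple(),
            "relative": self.total_relative_to_wt.as_tuple(),
        }


#: intermonomer transfer range when oligomerization is impaired
IMPAIRED_INTER_TRANSFER = Interval(0.3, 0.5)

_PRESETS: dict[str, MonomerParams] = {
    "WT": MonomerParams("WT", Interval.point(1), Interval.point(1), Interval.point(1)),
    "D207V": MonomerParams(
        "D207V",
        Interval.point(1),
        Interval.point(1),
        Interval.point(0.5),
        impairs_oligomerization=True,
    ),
    "catalytic": MonomerParams(
        "catalytic", Interval.point(0.1), Interval.point(0.1), Interval.point(1)
    ),
    "V603L": MonomerParams(
        "V603L", Interval.point(0.2), Interval.point(0.2), Interval.point(1)
    ),
    # alternative parameterization using the in vitro epimerase activity
    "D207V_invitro": MonomerParams(
        "D207V_invitro",
        Interval.point(0.18),
        Interval.point(1),
        Interval.point(0.5),
        impairs_oligomerization=True,
    ),
}


def preset(variant_label: str) -> MonomerParams:
    """Monomer parameter preset by variant label."""
    try:
        return _PRESETS[variant_label]
    except KeyError:
        raise ValueError(
            f"unknown preset {variant_label!r}; known: {sorted(_PRESETS)}"
        ) from None


def preset_labels() -> tuple[str, ...]:
    return tuple(_PRESETS)


def route_score(source: MonomerParams, dest: MonomerParams, transfer) -> Interval:
    """One production route: source epimerase x transfer x dest kinase."""
    return source.epimerase_score * _score(transfer) * dest.kinase_score


def dimer_production(model: DimerFluxModel) -> RouteScores:
    """Total production of a dimer: sum of the four route scores.

    Routes: intramolecular in each monomer (own epimerase x own intra
    transfer x own kinase) and both intermonomer directions through the
    dimer-level transfer score. The relative total divides by the
    wild-type total of 4.
    """
    m1, m2 = model.monomer1, model.monomer2
    t = model.inter_transfer
    intra_1 = route_score(m1, m1, m1.intra_transfer_score)
    intra_2 = route_score(m2, m2, m2.intra_transfer_score)
    inter_12 = route_score(m1, m2, t)
    inter_21 = route_score(m2, m1, t)
    total = intra_1 + intra_2 + inter_12 + inter_21
    return RouteScores(intra_1, intra_2, inter_12, inter_21, total, total / 4.0)


def dimer_from_presets(
    label1: str, label2: str, inter_transfer=None, **overrides
) -> DimerFluxModel:
    """Build a dimer model from two preset labels with optional overrides.

    Overrides are keyword component replacements applied to both monomers'
    copies only when given as e.g. ``epimerase_score=(0.1, 0.2)`` via
    ``monomer1_...``/``monomer2_...`` prefixes.
    """
    m1, m2 = preset(label1), preset(label2)
    for key, val in overrides.items():
        if key.startswith("monomer1_"):
            m1 = replace(m1, **{key[len("monomer1_"):]: Interval.coerce(val)})
        elif key.startswith("monomer2_"):
            m2 = replace(m2, **{key[len("monomer2_"):]: Interval.coerce(val)})
        else:
            raise ValueError(f"unknown override {key!r}")
    it = None if inter_transfer is None else Interval.coerce(inter_transfer)
    return DimerFluxModel(m1, m2, it)
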