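"""Core record types for tree-level biomass data."""

from __future__ import annotations

from dataclasses import dataclass, field

#: The four biomass components of a tree, in canonical order.
COMPONENTS = ("stem", "branch", "twig", "foliage")

#: Components modeled explicitly in the ratio-equation system; foliage is
#: always obtained as the complement so the four ratios sum to one.
SYSTEM_COMPONENTS = ("stem", "branch", "twig")

RATIO_SUM_TOL = 1e-10


@dataclass(frozen=True)
class TreeRecord:
    """One census or sample tree.

    Parameters
    ----------
    tree_id : str
        Unique identifier.
    dbh : float
        Stem diameter at breast height (1.3 m), cm. Must be positive.
    ht : float, optional
        Total tree height, m. May be absent when only dbh-based
        predictors are used.
    diam_class : str, optional
        Diameter-class label (e.g. ``"5-10"``).
    """

    tree_id: str
    dbh: float
    ht: float | None = None
    diam_class: str | None = None

    def __post_init__(self) -> None:
        if not self.dbh > 0:
            raise ValueError(f"dbh must be positive, got {self.dbh!r}")
        if self.ht is not None and not self.ht > 0:
            raise ValueError(f"ht must be positive, got {self.ht!r}")


@dataclass(frozen=True)
class FieldSample:
    """Fresh field weights and subsample fresh/dry pairs for one tree.

    Each mapping is keyed by component name.  ``fresh_field`` holds the
    whole-component fresh weight recorded in the field (kg);
    ``sample_fresh``/``sample_dry`` hold the weights of the subsample
    taken from that component before and after oven drying (kg).
    """

    fresh_field: dict[str, float]
    sample_fresh: dict[str, float]
    sample_dry: dict[str, float]

    def __post_init__(self) -> None:
        for c in COMPONENTS:
            ff = self.fresh_field.get(c, 0.0)
            sf = self.sample_fresh.get(c, 0.0)
            sd = self.sample_dry.get(c, 0.0)
            if ff < 0 or sf < 0 or sd < 0:
                raise ValueError(f"negative weight for component {c!r}")
            if sd > sf:
                raise ValueError(
                    f"sample dry weight exceeds sample fresh weight for {c!r}"
                )


@dataclass(frozen=True)
class BiomassRecord:
    """Oven-dry biomass (kg) of the four components of one tree."""

    b_stem: float
    b_branch: float
    b_twig: float
    b_foliage: float

    def __post_init__(self) -> None:
        for c in COMPONENTS:
            if getattr(self, f"b_{c}") < 0:
                raise ValueError(f"negative biomass for component {c!r}")

    @property
    def agb(self) -> float:
        """Aboveground biomass: the sum of the four component dry masses."""
        return self.b_stem + self.b_branch + self.b_twig + self.b_foliage

    def component(self, name: str) -> float:
        return getattr(self, f"b_{name}")


@dataclass(frozen=True)
class RatioRecord:
    """The four biomass component ratios of one tree.

    ``clamped`` flags records whose raw model predictions fell outside
    [0, 1] and were clamped and renormalized.
    """

    r_stem: float
    r_branch: float
    r_twig: float
    r_foliage: float
    clamped: bool = field(default=False, compare=False)

    def component(self, name: str) -> float:
        return getattr(self, f"r_{name}")

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.r_stem, self.r_branch, self.r_twig, self.r_foliage)

    @property
    def total(self) -> float:
        return sum(self.as_tuple())

    @property
    def is_valid(self) -> bool:
        """True when every ratio lies in [0, 1] and the four sum to one."""
        return all(0.0 <= r <= 1.0 for r in self.as_tuple()) and (
            abs(self.total - 1.0) <= RATIO_SUM_TOL
        )

    def validate(self) -> "RatioRecord":
        if not self.is_valid:
            raise ValueError(
                f"invalid ratio record {self.as_tuple()} (sum={self.total!r})"
            )
        return self
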