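"""Stoichiometry assignment for cross-linked complexes.

Egg-coat filaments digested and trapped with an amine-reactive
cross-linker yield mass-spectrometry peaks whose masses are sums of
integer numbers of subunit fragments. Glycosylated fragments do not have
a single mass but a *glycoform window* — an interval spanned by the
heterogeneous glycan complements — so composition feasibility is decided
by interval arithmetic: a composition is feasible for a peak when the
peak mass falls inside the interval spanned by the summed component
windows (plus one linker adduct per link, widened by an optional
tolerance).

The solver enumerates all integer compositions within per-component count
bounds, reports the feasible set per peak, and flags peaks with a unique
interpretation. A spacing analysis expresses consecutive peak differences
as integer multiples of a reference subunit mass window, the signature of
a repeated subunit structure.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional, Sequence

__all__ = [
    "MassComponent",
    "PeakList",
    "Composition",
    "CompositionAssignment",
    "composition_interval",
    "enumerate_feasible",
    "assign_peaklist",
    "spacing_analysis",
]


@dataclass(frozen=True)
class MassComponent:
    """A mass building block with an interval mass and a count bound.

    ``lo == hi`` denotes a point mass; a glycoform window has ``lo < hi``.
    """

    name: str
    lo_da: float
    hi_da: float
    max_count: int = 4

    def __post_init__(self) -> None:
        if not (0 < self.lo_da <= self.hi_da):
            raise ValueError(
                f"need 0 < lo <= hi for {self.name}: [{self.lo_da}, {self.hi_da}]"
            )
        if self.max_count < 0:
            raise ValueError("max_count must be >= 0")


@dataclass
class PeakList:
    """Observed peak masses (Da), kept sorted and strictly increasing."""

    masses_da: list[float]
    source: str = "unknown"

    def __post_init__(self) -> None:
        if any(m <= 0 for m in self.masses_da):
            raise ValueError("peak masses must be > 0")
        self.masses_da = sorted(float(m) for m in self.masses_da)
        for a, b in zip(self.masses_da, self.masses_da[1:]):
            if a == b:
                raise ValueError(f"duplicate peak mass {a}")

    def __len__(self) -> int:
        return len(self.masses_da)


@dataclass(frozen=True)
class Composition:
    """Integer counts per component name; links = total copies - 1."""

    counts: tuple[tuple[str, int], ...]

    @classmethod
    def from_dict(cls, d: dict[str, int]) -> "Composition":
        return cls(tuple(sorted((k, int(v)) for k, v in d.items() if v)))

    def as_dict(self) -> dict[str, int]:
        return dict(self.counts)

    @property
    def total_copies(self) -> int:
        return sum(v for _, v in self.counts)

    @property
    def n_links(self) -> int:
        return max(self.total_copies - 1, 0)

    def __post_init__(self) -> None:
        if not self.counts or all(v == 0 for _, v in self.counts):
            raise ValueError("composition must have a positive count")
        if any(v < 0 for _, v in self.counts):
            raise ValueError("counts must be >= 0")


@dataclass
class CompositionAssignment:
    """Feasible compositions for one peak; unique iff exactly one."""

    peak_da: float
    feasible: list[tuple[Composition, tuple[float, float]]]

    @property
    def unique(self) -> bool:
        return len(self.feasible) == 1


def composition_interval(
    composition: Composition,
    components: Sequence[MassComponent],
    linker_adduct_da: float = 0.0,
) -> tuple[float, float]:
    """Mass interval [lo, hi] spanned by a composition.

    ``lo`` sums count x window-low per component, ``hi`` the window highs;
    each of the ``total copies - 1`` links adds one adduct mass to both
    bounds.
    """
    by_name = {c.name: c for c in components}
    lo = hi = composition.n_links * linker_adduct_da
    for name, count in composition.counts:
        if name not in by_name:
            raise KeyError(f"unknown component {name!r}")
        comp = by_name[name]
        lo += count * comp.lo_da
        hi += count * comp.hi_da
    return lo, hi


def enumerate_feasible(
    peak_da: float,
    components: Sequence[MassComponent],
    linker_adduct_da: float = 0.0,
    tolerance_da: float = 0.0,
) -> list[Composition]:
    """All compositions whose mass interval (± tolerance) covers the peak.

    Counts run from 0 to each component's ``max_count`` (not all zero);
    results are in lexicographic count order, so output is deterministic.
    """
    if not components:
        raise ValueError("component set must be non-empty")
    if tolerance_da < 0:
        raise ValueError("tolerance must be >= 0")
    names = [c.name for c in components]
    out = []
    for counts in itertools.product(
        *(range(c.max_count + 1) for c in components)
    ):
        if not any(counts):
            continue
        comp = Composition(
            tuple((n, c) for n, c in zip(names, counts) if c)
        )
        lo, hi = composition_interval(comp, components, linker_adduct_da)
        if lo - tolerance_da <= peak_da <= hi + tolerance_da:
            out.append(comp)
    return out


def assign_peaklist(
    peaks: PeakList,
    components: Sequence[MassComponent],
    linker_adduct_da: float = 0.0,
    tolerance_da: float = 0.0,
) -> list[CompositionAssignment]:
    """One assignment per peak, flagging unique and unassignable peaks."""
    out = []
    for m in peaks.masses_da:
        feas = enumerate_feasible(m, components, linker_adduct_da, tolerance_da)
        out.append(
            CompositionAssignment(
                peak_da=m,
                feasible=[
                    (c, composition_interval(c, components, linker_adduct_da))
                    for c in feas
                ],
            )
        )
    return out


@dataclass
class SpacingTerm:
    """One consecutive peak difference and its multiple decomposition."""

    from_da: float
    to_da: float
    difference_da: float
    k: Optional[int]  # integer multiple, None when unexplained
    unit_da: Optional[float]  # difference / k, inside the window when explained

    @property
    def explained(self) -> bool:
        return self.k is not None


def spacing_analysis(
    peaks: PeakList,
    reference_window: tuple[float, float],
    k_max: int = 6,
) -> list[SpacingTerm]:
    """Decompose consecutive peak spacings against a reference mass window.

    Each difference between adjacent peaks is expressed as ``k x m`` with
    integer ``k >= 1`` and ``m`` inside ``reference_window`` (smallest such
    ``k`` wins), or flagged unexplained. Regular spacing at multiples of a
    subunit mass is the hallmark of a repeated subunit structure.
    """
    lo, hi = reference_window
    if not (0 < lo <= hi):
        raise ValueError("reference window must satisfy 0 < lo <= hi")
    terms = []
    for a, b in zip(peaks.masses_da, peaks.masses_da[1:]):
        diff = b - a
        found = None
        for k in range(1, k_max + 1):
            unit = diff / k
            if lo <= unit <= hi:
                found = (k, unit)
                break
        terms.append(
            SpacingTerm(
                from_da=a,
                to_da=b,
                difference_da=diff,
                k=found[0] if found else None,
                unit_da=found[1] if found else None,
            )
        )
    return terms
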