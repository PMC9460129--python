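"""Piecewise log-linear vibrotactile firing-threshold model.

The four glabrous-skin mechanoreceptors -- Meissner corpuscles (FA I),
Pacinian corpuscles (FA II), Merkel disks (SA I) and Ruffini endings
(SA II) -- each fire once the amplitude of a vibratory stimulus at
frequency ``f`` exceeds a frequency-dependent detection threshold.  On a
log-frequency vs dB-amplitude chart each receptor's threshold is well
approximated by a small number of straight-line segments.  This module
represents that piecewise model, evaluates it, and derives the ordered
"firing combination" band structure the four curves induce at any
frequency: slicing the amplitude axis at the sorted threshold values
yields slabs, each labelled by the set of receptors already firing there.

Threshold values are in dB re 1 um peak displacement; a receptor outside
its frequency domain is treated as never firing (threshold +inf, reported
as NaN by :func:`evaluate_threshold`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import yaml

__all__ = [
    "RECEPTORS",
    "ThresholdSegment",
    "ThresholdModel",
    "FiringCombination",
    "Slab",
    "default_model",
    "evaluate_threshold",
    "band_structure",
    "enumerate_combinations",
]

#: Canonical receptor ordering used for combination labels.
RECEPTORS = ("SAI", "SAII", "FAI", "FAII")

#: Frequency range (Hz) over which the model as a whole is defined.
F_RANGE = (0.5, 800.0)

#: Tolerance (dB) for continuity of adjacent segments at breakpoints;
#: the published coefficients are rounded to 4 significant digits.
BREAKPOINT_TOL_DB = 0.05


@dataclass(frozen=True)
class ThresholdSegment:
    """One straight piece ``slope * log10(f) + intercept`` on [f_lo, f_hi]."""

    slope: float  # dB per decade of frequency
    intercept: float  # dB at 1 Hz
    f_lo: float  # Hz, inclusive
    f_hi: float  # Hz, inclusive

    def __post_init__(self) -> None:
        if not (self.f_lo > 0 and self.f_lo < self.f_hi):
            raise ValueError(
                f"segment needs 0 < f_lo < f_hi, got [{self.f_lo}, {self.f_hi}]"
            )

    def __call__(self, f: float) -> float:
        return self.slope * math.log10(f) + self.intercept


@dataclass(frozen=True)
class FiringCombination:
    """A nonempty subset of receptors firing together.

    The canonical label concatenates members in the fixed order SAI,
    SAII, FAI, FAII; the full four-member set is labelled ``ALL``.
    """

    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("firing combination must be nonempty")
        unknown = self.members - set(RECEPTORS)
        if unknown:
            raise ValueError(f"unknown receptors: {sorted(unknown)}")

    @property
    def label(self) -> str:
        if self.members == frozenset(RECEPTORS):
            return "ALL"
        return "".join(r for r in RECEPTORS if r in self.members)

    @classmethod
    def from_members(cls, members: Iterable[str]) -> "FiringCombination":
        return cls(frozenset(members))

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.label


@dataclass(frozen=True)
class Slab:
    """One amplitude band at a fixed frequency.

    ``upper`` is +inf for the topmost (unbounded) slab.  ``combo`` is the
    set of receptors whose thresholds lie at or below ``lower``.
    """

    lower: float
    upper: float
    combo: FiringCombination


@dataclass
class ThresholdModel:
    """Per-receptor ordered segment lists tiling each receptor's domain.

    ``domain_lo_exclusive`` marks receptors whose domain opens exclusively
    at its lower endpoint (FA II starts strictly above 20 Hz in the
    published model); all other endpoints are inclusive.
    """

    segments: dict[str, tuple[ThresholdSegment, ...]]
    domain_lo_exclusive: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.segments = {r: tuple(segs) for r, segs in self.segments.items()}
        for receptor, segs in self.segments.items():
            if receptor not in RECEPTORS:
                raise ValueError(f"unknown receptor {receptor!r}")
            if not segs:
                raise ValueError(f"{receptor}: empty segment list")
            for a, b in zip(segs, segs[1:]):
                if not math.isclose(a.f_hi, b.f_lo, rel_tol=0, abs_tol=1e-9):
                    raise ValueError(
                        f"{receptor}: segments do not tile the domain "
                        f"({a.f_hi} != {b.f_lo})"
                    )
                gap = abs(a(a.f_hi) - b(b.f_lo))
                if gap > BREAKPOINT_TOL_DB:
                    raise ValueError(
                        f"{receptor}: {gap:.3f} dB jump at breakpoint {a.f_hi} Hz"
                    )

    @property
    def receptors(self) -> tuple[str, ...]:
        return tuple(r for r in RECEPTORS if r in self.segments)

    def domain(self, receptor: str) -> tuple[float, float]:
        segs = self.segments[receptor]
        return segs[0].f_lo, segs[-1].f_hi

    def in_domain(self, receptor: str, f: float) -> bool:
        lo, hi = self.domain(receptor)
        if receptor in self.domain_lo_exclusive:
            return lo < f <= hi
        return lo <= f <= hi

    def threshold(self, receptor: str, f: float) -> float:
        """Threshold in dB at ``f`` Hz, or NaN outside the receptor domain."""
        if f <= 0:
            raise ValueError(f"frequency must be positive, got {f}")
        if receptor not in self.segments:
            raise KeyError(receptor)
        if not self.in_domain(receptor, f):
            return math.nan
        segs = self.segments[receptor]
        for seg in segs:
            # half-open (f_lo, f_hi] pieces, first piece closed at the
            # domain start; adjacent pieces agree at breakpoints anyway
            if (seg is segs[0] and f >= seg.f_lo and f <= seg.f_hi) or (
                seg.f_lo < f <= seg.f_hi
            ):
                return seg(f)
        raise AssertionError("unreachable: segments tile the domain")

    # -- serialization ---------------------------------------------------

    def to_yaml(self) -> str:
        obj = {
            r: [
                {
                    "slope": s.slope,
                    "intercept": s.intercept,
                    "f_lo": s.f_lo,
                    "f_hi": s.f_hi,
                }
                for s in segs
            ]
            for r, segs in self.segments.items()
        }
        return yaml.safe_dump(obj, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str, *, domain_lo_exclusive: Iterable[str] = ("FAII",)) -> "ThresholdModel":
        obj = yaml.safe_load(text)
        segments = {
            r: tuple(ThresholdSegment(**d) for d in segs) for r, segs in obj.items()
        }
        return cls(segments, frozenset(domain_lo_exclusive))


def default_model() -> ThresholdModel:
    """The packaged published four-receptor threshold model."""
    text = resources.files("vibrotact.data").joinpath("thresholds.yaml").read_text()
    return ThresholdModel.from_yaml(text)


def evaluate_threshold(model: ThresholdModel, receptor: str, f: float) -> float:
    """Threshold of ``receptor`` at ``f`` Hz in dB; NaN outside its domain."""
    return model.threshold(receptor, f)


def band_structure(model: ThresholdModel, f: float) -> list[Slab]:
    """Amplitude slabs at frequency ``f``, bottom-up.

    The thresholds of all receptors defined at ``f``, sorted ascending,
    delimit contiguous amplitude bands; band ``k``'s firing combination is
    the set of receptors whose thresholds are at or below its lower bound.
    Ties produce zero-height slabs that are kept (they contribute zero
    area downstream); the topmost slab is unbounded above.
    """
    if not (F_RANGE[0] <= f <= F_RANGE[1]):
        raise ValueError(f"frequency {f} Hz outside model range {F_RANGE}")
    defined = [
        (model.threshold(r, f), r) for r in model.receptors if model.in_domain(r, f)
    ]
    if not defined:
        return []
    # Thresholds closer than the coefficient-rounding tolerance are ties:
    # snap them to the first value of their group so near-crossings (the
    # printed FAI and SAII pieces run within 0.01 dB of each other below
    # 10 Hz and cross near 14.7 Hz) produce zero-height slabs ordered by
    # the fixed receptor order, not spurious extra combinations.
    defined.sort(key=lambda t: t[0])
    snapped = []
    group_value = None
    for thr, receptor in defined:
        if group_value is None or thr - group_value > BREAKPOINT_TOL_DB:
            group_value = thr
        snapped.append((group_value, receptor))
    snapped.sort(key=lambda t: (t[0], RECEPTORS.index(t[1])))
    defined = snapped
    slabs: list[Slab] = []
    firing: list[str] = []
    for k, (thr, receptor) in enumerate(defined):
        firing.append(receptor)
        upper = defined[k + 1][0] if k + 1 < len(defined) else math.inf
        slabs.append(Slab(thr, upper, FiringCombination.from_members(firing)))
    return slabs


def enumerate_combinations(
    model: ThresholdModel, f_grid: Sequence[float] | np.ndarray
) -> set[str]:
    """Union of firing-combination labels over the band structures of ``f_grid``.

    With the published model and any dense (>=1000 point) log-spaced grid
    over 0.5-800 Hz this is exactly eight labels.
    """
    f_grid = np.asarray(f_grid, dtype=float)
    if f_grid.size == 0:
        raise ValueError("empty frequency grid")
    labels: set[str] = set()
    for f in f_grid:
        for slab in band_structure(model, float(f)):
            labels.add(slab.combo.label)
    return labels


def canonical_labels(model: ThresholdModel, n_grid: int = 2000) -> list[str]:
    """The model's combination labels in ascending-slab discovery order."""
    grid = np.geomspace(F_RANGE[0], F_RANGE[1], n_grid)
    labels = enumerate_combinations(model, grid)
    # deterministic order: by member count, then canonical receptor order
    def key(label: str) -> tuple:
        combo = parse_label(label)
        return (len(combo.members), tuple(RECEPTORS.index(m) for m in sorted(combo.members, key=RECEPTORS.index)))

    return sorted(labels, key=key)


def parse_label(label: str) -> FiringCombination:
    """Inverse of :attr:`FiringCombination.label`."""
    if label == "ALL":
        return FiringCombination.from_members(RECEPTORS)
    members = []
    rest = label
    # greedy longest-first match avoids SAI/SAII ambiguity
    for receptor in sorted(RECEPTORS, key=len, reverse=True):
        if receptor in rest:
            members.append(receptor)
            rest = rest.replace(receptor, "", 1)
    if rest or not members:
        raise ValueError(f"unparseable combination label {label!r}")
    return FiringCombination.from_members(members)
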