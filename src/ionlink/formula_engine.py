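"""Elemental sum formulas: mass arithmetic, constrained enumeration, plausibility filters.

High-resolution GC-MS can constrain the elemental composition of an ion to a
short list of candidate sum formulas once a mass tolerance (ppm) and per-element
count bounds are given.  This module provides

* :class:`Formula` — an immutable element→count vector with monoisotopic mass,
  Hill-notation serialization and subset (subformula) comparison,
* :func:`enumerate_formulas` — exact enumeration of all formulas whose ion m/z
  falls within a ppm window, by bounded depth-first search with mass pruning,
* :func:`golden_rules_filter` — heuristic element-ratio and ring-double-bond
  plausibility filtering in the spirit of common-range formula heuristics,
* :func:`isotope_pattern_check` — a presence-only A+2 isotopologue check that
  vetoes S/Cl/Br-containing formulas whose diagnostic companion peak is absent.

Two single-charge ion conventions are supported: a generic cation (composition
mass minus one electron; appropriate for electron-ionization fragments) and a
protonated molecule [M+H]+ (neutral mass plus a proton).
"""

from __future__ import annotations

import enum
import math
import re
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

from .errors import ConfigurationError, ResourceLimitError

# Monoisotopic masses (Da) of the most abundant isotope of each supported element.
MONOISOTOPIC_MASS: Dict[str, float] = {
    "C": 12.0,
    "H": 1.00782503207,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "P": 30.97376163,
    "S": 31.97207100,
    "Si": 27.97692653,
    "Cl": 34.96885268,
    "Br": 78.9183371,
}

ELECTRON_MASS = 0.00054857991

# A+2 isotopologue spacings (Da) diagnostic for the rarer elements: 34S, 37Cl, 81Br.
A2_DELTA: Dict[str, float] = {
    "S": 1.99580,
    "Cl": 1.99705,
    "Br": 1.99796,
}

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class Formula(Mapping[str, int]):
    """An immutable elemental composition (element symbol → positive count).

    Behaves as a read-only mapping; ``f["X"]`` returns 0 for absent elements.
    Equality and hashing are by composition, so formulas can key dicts/sets.
    """

    __slots__ = ("_counts", "_key")

    def __init__(self, counts: Mapping[str, int]):
        clean = {}
        for el, n in counts.items():
            n = int(n)
            if n < 0:
                raise ValueError(f"negative count for element {el}")
            if n > 0:
                clean[el] = n
        self._counts = clean
        self._key = tuple(sorted(clean.items()))

    @classmethod
    def from_string(cls, text: str) -> "Formula":
        """Parse ``"C6H12O6"`` style notation (count 1 may be omitted)."""
        counts: Dict[str, int] = {}
        pos = 0
        for m in _FORMULA_TOKEN.finditer(text.strip()):
            if m.start() != pos:
                raise ValueError(f"cannot parse formula {text!r}")
            pos = m.end()
            el = m.group(1)
            counts[el] = counts.get(el, 0) + (int(m.group(2)) if m.group(2) else 1)
        if pos != len(text.strip()) or not counts:
            raise ValueError(f"cannot parse formula {text!r}")
        return cls(counts)

    # Mapping protocol -----------------------------------------------------
    def __getitem__(self, el: str) -> int:
        return self._counts.get(el, 0)

    def __iter__(self):
        return iter(self._counts)

    def __len__(self) -> int:
        return len(self._counts)

    def __contains__(self, el) -> bool:  # Mapping default would use __getitem__
        return el in self._counts

    # Identity -------------------------------------------------------------
    def __eq__(self, other) -> bool:
        return isinstance(other, Formula) and self._key == other._key

    def __hash__(self) -> int:
        return hash(self._key)

    def __repr__(self) -> str:
        return f"Formula({self.hill()!r})"

    # Arithmetic -----------------------------------------------------------
    def __add__(self, other: Mapping[str, int]) -> "Formula":
        counts = dict(self._counts)
        for el, n in other.items():
            counts[el] = counts.get(el, 0) + n
        return Formula(counts)

    def hill(self) -> str:
        """Serialize in Hill order: C, H, then alphabetical (all alphabetical if no C)."""
        if not self._counts:
            return ""
        parts: List[str] = []
        if "C" in self._counts:
            order = ["C"] + (["H"] if "H" in self._counts else [])
            order += sorted(e for e in self._counts if e not in ("C", "H"))
        else:
            order = sorted(self._counts)
        for el in order:
            n = self._counts[el]
            parts.append(el if n == 1 else f"{el}{n}")
        return "".join(parts)


class IonType(enum.Enum):
    """Single-charge positive-ion mass conventions."""

    #: [M+H]+ — neutral mass plus one hydrogen, minus one electron.
    PROTONATED_MOLECULE = "protonated_molecule"
    #: A generic cation whose composition IS the formula: composition mass minus one electron.
    CATION_GENERIC = "cation_generic"


def formula_mass(f: Formula, ion: Optional[IonType] = None) -> float:
    """Monoisotopic mass of a formula: neutral if ``ion`` is None, else the ion m/z (z=1).

    Raises
    ------
    ConfigurationError
        If the formula contains an element without a tabulated mass.
    """
    m = 0.0
    for el, n in f.items():
        try:
            m += n * MONOISOTOPIC_MASS[el]
        except KeyError:
            raise ConfigurationError(f"unknown element symbol {el!r}") from None
    if ion is None:
        return m
    if ion is IonType.PROTONATED_MOLECULE:
        return m + MONOISOTOPIC_MASS["H"] - ELECTRON_MASS
    if ion is IonType.CATION_GENERIC:
        return m - ELECTRON_MASS
    raise ConfigurationError(f"unknown ion type {ion!r}")


@dataclass(frozen=True)
class ElementConstraints:
    """Per-element (min, max) count bounds used by formula enumeration."""

    bounds: Mapping[str, Tuple[int, int]]

    def __post_init__(self):
        for el, (lo, hi) in self.bounds.items():
            if el not in MONOISOTOPIC_MASS:
                raise ConfigurationError(f"unknown element symbol {el!r}")
            if not (0 <= lo <= hi):
                raise ConfigurationError(f"invalid bounds for {el}: ({lo}, {hi})")

    @classmethod
    def default(cls) -> "ElementConstraints":
        """C, H, N, O, S, Si, P each 0–50 — the standard derivatized-metabolite window."""
        return cls({e: (0, 50) for e in ("C", "H", "N", "O", "S", "Si", "P")})

    @classmethod
    def from_string(cls, text: str) -> "ElementConstraints":
        """Parse ``"C:0-50,H:0-50,Cl:0-3"`` style constraint strings."""
        bounds: Dict[str, Tuple[int, int]] = {}
        for chunk in text.split(","):
            chunk = chunk.strip()
            if not chunk:
                continue
            try:
                el, rng = chunk.split(":")
                lo, hi = rng.split("-")
                bounds[el.strip()] = (int(lo), int(hi))
            except ValueError:
                raise ConfigurationError(f"cannot parse element constraint {chunk!r}") from None
        if not bounds:
            raise ConfigurationError("empty element constraint string")
        return cls(bounds)

    def elements(self) -> List[str]:
        return [e for e, (lo, hi) in self.bounds.items() if hi > 0]


def enumerate_formulas(
    mz: float,
    ppm: float,
    constraints: ElementConstraints,
    ion: IonType,
    *,
    visit_cap: int = 10_000_000,
) -> List[Formula]:
    """All formulas whose ion m/z lies within ``±ppm`` of ``mz``, under the constraints.

    The search is a depth-first enumeration over element counts, heaviest
    element outermost, pruned at every level by the minimum/maximum mass still
    achievable with the remaining (lighter) elements.  The lightest element's
    count range is solved directly, so the innermost level costs O(1) per hit.

    Results are sorted by \\|Δppm\\| ascending (then Hill string, for determinism).

    Raises
    ------
    ResourceLimitError
        If more than ``visit_cap`` count combinations are visited; tighten the
        element constraints or the tolerance.
    """
    if mz <= 0:
        raise ValueError("mz must be positive")
    if ppm <= 0:
        raise ValueError("ppm must be positive")

    if ion is IonType.PROTONATED_MOLECULE:
        target = mz - (MONOISOTOPIC_MASS["H"] - ELECTRON_MASS)
    elif ion is IonType.CATION_GENERIC:
        target = mz + ELECTRON_MASS
    else:  # pragma: no cover - exhaustive enum
        raise ConfigurationError(f"unknown ion type {ion!r}")
    tol = mz * ppm * 1e-6

    elems = sorted(constraints.elements(), key=lambda e: -MONOISOTOPIC_MASS[e])
    if not elems or target <= -tol:
        return []
    masses = [MONOISOTOPIC_MASS[e] for e in elems]
    los = [constraints.bounds[e][0] for e in elems]
    his = [constraints.bounds[e][1] for e in elems]
    n_el = len(elems)

    # suffix_min/max[i] = least/greatest mass attainable by elements i..end
    suffix_min = [0.0] * (n_el + 1)
    suffix_max = [0.0] * (n_el + 1)
    for i in range(n_el - 1, -1, -1):
        suffix_min[i] = suffix_min[i + 1] + los[i] * masses[i]
        suffix_max[i] = suffix_max[i + 1] + his[i] * masses[i]

    eps = 1e-9
    visits = 0
    counts = [0] * n_el
    out: List[Tuple[float, Formula]] = []

    def recurse(i: int, rem: float) -> None:
        nonlocal visits
        m = masses[i]
        if i == n_el - 1:
            lo = max(los[i], math.ceil((rem - tol) / m - eps))
            hi = min(his[i], math.floor((rem + tol) / m + eps))
            for n in range(lo, hi + 1):
                visits += 1
                delta = rem - n * m
                if abs(delta) <= tol + 1e-12:
                    counts[i] = n
                    f = Formula({el: c for el, c in zip(elems, counts) if c})
                    if len(f):
                        out.append((abs(delta), f))
            counts[i] = 0
            return
        lo = max(los[i], math.ceil((rem - tol - suffix_max[i + 1]) / m - eps))
        hi = min(his[i], math.floor((rem + tol - suffix_min[i + 1]) / m + eps))
        for n in range(lo, hi + 1):
            visits += 1
            if visits > visit_cap:
                raise ResourceLimitError(
                    f"formula enumeration exceeded {visit_cap} visited combinations; "
                    "tighten element constraints or the ppm tolerance"
                )
            counts[i] = n
            recurse(i + 1, rem - n * m)
        counts[i] = 0

    recurse(0, target)
    out.sort(key=lambda pair: (pair[0], pair[1].hill()))
    return [f for _, f in out]


# Default element-ratio common ranges (relative to carbon); None = unbounded.
DEFAULT_RATIO_BOUNDS: Dict[str, Tuple[Optional[float], Optional[float]]] = {
    "H": (0.1, 6.0),
    "N": (None, 4.0),
    "O": (None, 3.0),
    "P": (None, 2.0),
    "S": (None, 3.0),
    "Si": (None, 1.0),
    "Cl": (None, 2.0),
}


def rdbe(f: Formula) -> float:
    """Ring-and-double-bond equivalents.

    Tetravalent C/Si add one ring/bond each, trivalent N and P half, monovalent
    H and halogens subtract half.  Half-integer values arise for odd-electron
    ions and are deliberately admitted down to −0.5 by the default filter.
    """
    return (
        f["C"]
        + f["Si"]
        - (f["H"] + f["Cl"] + f["Br"]) / 2.0
        + (f["N"] + f["P"]) / 2.0
        + 1.0
    )


def golden_rules_filter(
    formulas: Iterable[Formula],
    *,
    ratio_bounds: Optional[Mapping[str, Tuple[Optional[float], Optional[float]]]] = None,
    rdbe_min: float = -0.5,
) -> List[Formula]:
    """Drop formulas with implausible element ratios or negative unsaturation.

    Ratio bounds are checked against carbon only when C > 0; carbon-free
    formulas pass the ratio checks (ammonia, phosphate, etc. remain legal).
    Order is preserved; the output is always a subset of the input.
    """
    if ratio_bounds is None:
        ratio_bounds = DEFAULT_RATIO_BOUNDS
    kept: List[Formula] = []
    for f in formulas:
        nc = f["C"]
        ok = True
        if nc > 0:
            for el, (lo, hi) in ratio_bounds.items():
                r = f[el] / nc
                if (lo is not None and r < lo) or (hi is not None and r > hi):
                    ok = False
                    break
        if ok and rdbe(f) < rdbe_min:
            ok = False
        if ok:
            kept.append(f)
    return kept


def isotope_pattern_check(
    f: Formula,
    base_mz: float,
    rt: float,
    source,
    ppm: float,
    *,
    rt_window: float = 0.05,
    noise_floor: float = 0.0,
) -> bool:
    """Presence-only A+2 isotopologue veto for S/Cl/Br-containing formulas.

    For every S, Cl or Br in ``f`` the companion peak at ``base_mz + Δ``
    (Δ = 1.99580 / 1.99705 / 1.99796 Da) must be detectable within ``ppm``.
    ``source`` is either a raw run exposing
    ``find_peak(rt_center, rt_window, target_mz, ppm, noise_floor)`` (searched
    within ``rt_window`` of ``rt``) or an iterable of pseudospectrum feature
    m/z values.  Formulas without S/Cl/Br pass unconditionally — the common
    organic elements carry no diagnostic A+2 signature worth testing.
    """
    needed = [el for el in ("S", "Cl", "Br") if f[el] > 0]
    if not needed:
        return True
    use_raw = hasattr(source, "find_peak")
    mzs: Sequence[float] = ()
    if not use_raw:
        mzs = list(source)
    for el in needed:
        target = base_mz + A2_DELTA[el]
        tol = target * ppm * 1e-6
        if use_raw:
            found, _ = source.find_peak(rt, rt_window, target, ppm, noise_floor=noise_floor)
        else:
            found = any(abs(x - target) <= tol for x in mzs)
        if not found:
            return False
    return True


def is_subformula(small: Formula, big: Formula) -> bool:
    """True iff ``small``'s count never exceeds ``big``'s for any element."""
    return all(n <= big[el] for el, n in small.items())
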