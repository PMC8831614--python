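"""Elemental formulas, monoisotopic masses and ion m/z arithmetic.

High-resolution mass spectrometry identifies ions by accurate mass, so the
rest of the package leans on a small set of exact primitives collected here:
parsing elemental formulas (including heavy-nuclide tokens such as ``[13C]``),
monoisotopic mass computation, adduct/charge-aware ion m/z, ppm error
arithmetic, isotope mass shifts, and bounded enumeration of candidate
molecular formulas for an observed m/z.

Mass conventions
----------------
Monoisotopic atomic masses follow the IUPAC values (12C is exactly 12 Da).
Ion m/z is *electron inclusive* by default: ``[M-H]-`` removes one hydrogen
atom and adds one electron mass, ``[M+H]+`` adds one hydrogen and removes one
electron mass. At four printed decimals the electron mass (0.00055 Da)
matters.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Dict, Iterator, List, Mapping, Optional, Sequence, Tuple

__all__ = [
    "ELECTRON_MASS",
    "MONOISOTOPIC_MASS",
    "FormulaError",
    "ElementalFormula",
    "IonSpec",
    "MassTolerance",
    "parse_formula",
    "monoisotopic_mass",
    "ion_mz",
    "neutral_mass",
    "mass_shift",
    "ppm_error",
    "enumerate_formulas",
    "M_MINUS_H",
    "M_PLUS_H",
]

#: Rest mass of the electron in Da.
ELECTRON_MASS = 0.00054858

#: Monoisotopic masses (Da) of the elements handled here, plus heavy
#: nuclides addressable with bracket tokens (``[13C]`` etc.).
MONOISOTOPIC_MASS: Mapping[str, float] = {
    "C": 12.0,
    "H": 1.00782503,
    "N": 14.00307401,
    "O": 15.99491462,
    "P": 30.97376163,
    "S": 31.97207100,
    "Na": 22.98976928,
    "K": 38.96370649,
    "Cl": 34.96885268,
    "F": 18.99840316,
    "13C": 13.00335484,
    "2H": 2.01410178,
    "15N": 15.00010890,
    "18O": 17.99915961,
}

#: Per-label 13C/12C mass difference in Da.
C13_DELTA = MONOISOTOPIC_MASS["13C"] - MONOISOTOPIC_MASS["C"]

#: Methylene homolog spacing in Da (monoisotopic mass of CH2).
CH2_DELTA = MONOISOTOPIC_MASS["C"] + 2 * MONOISOTOPIC_MASS["H"]


class FormulaError(ValueError):
    """Raised for malformed formula strings or impossible compositions."""


_TOKEN = re.compile(r"\[(\d+)([A-Z][a-z]?)\](\d*)|([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class ElementalFormula:
    """An elemental composition: non-negative counts per element symbol.

    Heavy nuclides are distinct symbols (``"13C"`` is not ``"C"``). The empty
    formula is valid and has mass exactly 0.
    """

    counts: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean = {}
        for sym, n in self.counts.items():
            if sym not in MONOISOTOPIC_MASS:
                raise FormulaError(f"unknown element symbol: {sym!r}")
            if n < 0:
                raise FormulaError(f"negative count for {sym}: {n}")
            if n:
                clean[sym] = int(n)
        object.__setattr__(self, "counts", clean)

    # -- arithmetic ---------------------------------------------------
    def __add__(self, other: "ElementalFormula") -> "ElementalFormula":
        merged = dict(self.counts)
        for sym, n in other.counts.items():
            merged[sym] = merged.get(sym, 0) + n
        return ElementalFormula(merged)

    def __sub__(self, other: "ElementalFormula") -> "ElementalFormula":
        merged = dict(self.counts)
        for sym, n in other.counts.items():
            merged[sym] = merged.get(sym, 0) - n
            if merged[sym] < 0:
                raise FormulaError(
                    f"cannot remove {n} {sym} from {self}: composition would go negative"
                )
        return ElementalFormula(merged)

    def __getitem__(self, sym: str) -> int:
        return self.counts.get(sym, 0)

    def __bool__(self) -> bool:
        return bool(self.counts)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, ElementalFormula) and dict(self.counts) == dict(other.counts)

    def __hash__(self) -> int:
        return hash(tuple(sorted(self.counts.items())))

    @property
    def mass(self) -> float:
        """Monoisotopic mass in Da."""
        return sum(MONOISOTOPIC_MASS[s] * n for s, n in self.counts.items())

    def __str__(self) -> str:
        # Hill order: C first (12C then heavy carbons), H next, the rest
        # alphabetically; heavy nuclides sort with their element.
        def fmt(sym: str, n: int) -> str:
            tok = f"[{sym}]" if sym[0].isdigit() else sym
            return tok if n == 1 else f"{tok}{n}"

        def element_of(sym: str) -> str:
            return sym.lstrip("0123456789")

        order: List[str] = []
        for base in ("C", "H"):
            order.extend(sorted(s for s in self.counts if element_of(s) == base))
        order.extend(
            sorted(
                (s for s in self.counts if element_of(s) not in ("C", "H")),
                key=lambda s: (element_of(s), s),
            )
        )
        return "".join(fmt(s, self.counts[s]) for s in order)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"ElementalFormula({str(self)!r})"


def parse_formula(text: str) -> ElementalFormula:
    """Parse a Hill-style formula string into an :class:`ElementalFormula`.

    Grammar: a sequence of ``Element``, ``ElementCount``, ``[nuclide]`` or
    ``[nuclide]Count`` tokens, e.g. ``"C10H17O3"`` or ``"[13C]5C5H13NO2"``.
    Repeated symbols accumulate.

    Raises
    ------
    FormulaError
        On unknown element symbols or text that does not match the grammar;
        the message names the offending token.
    """
    counts: Dict[str, int] = {}
    pos = 0
    for m in _TOKEN.finditer(text):
        if m.start() != pos:
            raise FormulaError(f"malformed formula near {text[pos:m.start()]!r} in {text!r}")
        if m.group(2):  # bracketed nuclide
            sym = f"{m.group(1)}{m.group(2)}"
            count_s = m.group(3)
        else:
            sym = m.group(4)
            count_s = m.group(5)
        if sym not in MONOISOTOPIC_MASS:
            raise FormulaError(f"unknown element symbol: {sym!r} in {text!r}")
        n = int(count_s) if count_s else 1
        counts[sym] = counts.get(sym, 0) + n
        pos = m.end()
    if pos != len(text):
        raise FormulaError(f"malformed formula near {text[pos:]!r} in {text!r}")
    return ElementalFormula(counts)


def monoisotopic_mass(f: "ElementalFormula | str") -> float:
    """Monoisotopic mass (Da) of a formula or formula string."""
    if isinstance(f, str):
        f = parse_formula(f)
    return f.mass


_ADDUCT = re.compile(r"^\[M((?:[+-][A-Za-z0-9]+)*)\](\d*)([+-])$")


@dataclass(frozen=True)
class IonSpec:
    """An ionization rule: composition delta relative to the neutral, charge,
    and whether the electron mass enters the m/z (default: yes).

    ``deltas`` maps element symbols to signed counts, e.g. ``{"H": -1}`` for
    ``[M-H]-``.
    """

    deltas: Mapping[str, int]
    charge: int
    include_electron_mass: bool = True
    name: str = ""

    def __post_init__(self) -> None:
        if self.charge == 0:
            raise ValueError("ion charge must be non-zero")
        for sym in self.deltas:
            if sym not in MONOISOTOPIC_MASS:
                raise FormulaError(f"unknown element symbol in adduct: {sym!r}")

    @classmethod
    def from_string(cls, text: str) -> "IonSpec":
        """Parse adduct notation such as ``"[M-H]-"``, ``"[M+H]+"``,
        ``"[M+Na]+"`` or ``"[M-H2O-H]-"``."""
        m = _ADDUCT.match(text.replace(" ", ""))
        if not m:
            raise FormulaError(f"cannot parse adduct notation: {text!r}")
        deltas: Dict[str, int] = {}
        body = m.group(1)
        for part in re.finditer(r"([+-])([A-Za-z0-9]+)", body):
            sign = 1 if part.group(1) == "+" else -1
            for sym, n in parse_formula(part.group(2)).counts.items():
                deltas[sym] = deltas.get(sym, 0) + sign * n
        z = int(m.group(2)) if m.group(2) else 1
        if m.group(3) == "-":
            z = -z
        return cls(deltas=deltas, charge=z, name=text)

    @property
    def delta_mass(self) -> float:
        return sum(MONOISOTOPIC_MASS[s] * n for s, n in self.deltas.items())


M_MINUS_H = IonSpec.from_string("[M-H]-")
M_PLUS_H = IonSpec.from_string("[M+H]+")


def _as_ion(ion: "IonSpec | str") -> IonSpec:
    return IonSpec.from_string(ion) if isinstance(ion, str) else ion


def ion_mz(neutral: "ElementalFormula | str", ion: "IonSpec | str" = M_MINUS_H) -> float:
    """Theoretical m/z of an ion formed from a neutral composition.

    m/z = (mass(M) + mass(adduct delta) - z * m_e) / |z|, so a negative ion
    gains electron mass and a positive ion loses it.

    Raises
    ------
    FormulaError
        If the adduct removes atoms the neutral does not contain.
    """
    if isinstance(neutral, str):
        neutral = parse_formula(neutral)
    ion = _as_ion(ion)
    # validate the resulting composition is non-negative
    for sym, n in ion.deltas.items():
        if neutral[sym] + n < 0:
            raise FormulaError(
                f"adduct {ion.name or ion.deltas} removes {sym} absent from {neutral}"
            )
    mass = neutral.mass + ion.delta_mass
    if ion.include_electron_mass:
        mass -= ion.charge * ELECTRON_MASS
    return mass / abs(ion.charge)


def neutral_mass(mz: float, ion: "IonSpec | str" = M_MINUS_H) -> float:
    """Invert :func:`ion_mz`: neutral monoisotopic mass implied by an
    observed ion m/z."""
    ion = _as_ion(ion)
    mass = mz * abs(ion.charge) - ion.delta_mass
    if ion.include_electron_mass:
        mass += ion.charge * ELECTRON_MASS
    return mass


def mass_shift(n: int, heavy: str = "13C", light: str = "C") -> float:
    """Mass shift (Da) of incorporating ``n`` heavy nuclides.

    ``mass_shift(5)`` gives the 13C5 shift of ~5.0168 Da used in isotope
    tracing; linear in ``n``.
    """
    if n < 0:
        raise ValueError("label count must be >= 0")
    for sym in (heavy, light):
        if sym not in MONOISOTOPIC_MASS:
            raise FormulaError(f"unknown nuclide: {sym!r}")
    return n * (MONOISOTOPIC_MASS[heavy] - MONOISOTOPIC_MASS[light])


def ppm_error(observed: float, theoretical: float) -> float:
    """Relative mass error in parts per million."""
    if theoretical <= 0:
        raise ValueError("theoretical m/z must be positive")
    return 1e6 * (observed - theoretical) / theoretical


@dataclass(frozen=True)
class MassTolerance:
    """A mass tolerance: a positive value in 'ppm' or 'da'."""

    value: float
    unit: str = "ppm"

    def __post_init__(self) -> None:
        if self.value <= 0:
            raise ValueError("tolerance must be positive")
        if self.unit.lower() not in ("ppm", "da"):
            raise ValueError(f"tolerance unit must be 'ppm' or 'da', got {self.unit!r}")
        object.__setattr__(self, "unit", self.unit.lower())

    def window(self, mz: float) -> float:
        """Half-width of the acceptance window in Da at the given m/z."""
        return mz * self.value * 1e-6 if self.unit == "ppm" else self.value


#: Default per-element caps for formula enumeration (CHNOPS).
DEFAULT_BOUNDS: Mapping[str, int] = {"C": 50, "H": 100, "N": 10, "O": 20, "P": 4, "S": 4}


def rdbe(f: ElementalFormula) -> float:
    """Ring-and-double-bond equivalents, C - H/2 + N/2 + 1 (heavy nuclides
    count with their element)."""
    c = f["C"] + f["13C"]
    h = f["H"] + f["2H"]
    n = f["N"] + f["15N"]
    return c - h / 2.0 + n / 2.0 + 1.0


def enumerate_formulas(
    mz: float,
    ion: "IonSpec | str" = M_MINUS_H,
    tol: MassTolerance = MassTolerance(4.0, "ppm"),
    bounds: Optional[Mapping[str, int]] = None,
    min_rdbe: float = 0.0,
) -> List[ElementalFormula]:
    """Enumerate neutral molecular formulas whose ion matches an observed m/z.

    Exhaustive depth-first search over integer compositions within
    per-element ``bounds`` (default CHNOPS caps), pruned by mass. A candidate
    is kept when the ppm error of its theoretical ion m/z against ``mz`` is
    within ``tol`` and its RDBE is at least ``min_rdbe``. Results are sorted
    by absolute ppm error (ties by formula string).
    """
    ion = _as_ion(ion)
    if bounds is None:
        bounds = DEFAULT_BOUNDS
    bounds = {s: int(n) for s, n in bounds.items() if n > 0}
    for sym in bounds:
        if sym not in MONOISOTOPIC_MASS:
            raise FormulaError(f"unknown element in bounds: {sym!r}")
    target = neutral_mass(mz, ion)
    tol_da = tol.window(mz) * abs(ion.charge)
    if target <= 0 or not bounds:
        return []

    syms = sorted(bounds, key=lambda s: -MONOISOTOPIC_MASS[s])
    masses = [MONOISOTOPIC_MASS[s] for s in syms]
    # max mass attainable from element i onward, for pruning
    suffix_max = [0.0] * (len(syms) + 1)
    for i in range(len(syms) - 1, -1, -1):
        suffix_max[i] = suffix_max[i + 1] + masses[i] * bounds[syms[i]]

    out: List[ElementalFormula] = []
    counts = [0] * len(syms)

    def walk(i: int, acc: float) -> None:
        if acc > target + tol_da:
            return
        if acc + suffix_max[i] < target - tol_da:
            return
        if i == len(syms):
            if abs(acc - target) <= tol_da:
                f = ElementalFormula({s: c for s, c in zip(syms, counts) if c})
                if rdbe(f) >= min_rdbe:
                    try:
                        ion_mz(f, ion)  # composition must support the adduct
                    except FormulaError:
                        return
                    out.append(f)
            return
        m = masses[i]
        nmax = min(bounds[syms[i]], int(math.floor((target + tol_da - acc) / m)))
        for c in range(nmax + 1):
            counts[i] = c
            walk(i + 1, acc + c * m)
        counts[i] = 0

    walk(0, 0.0)
    out.sort(key=lambda f: (abs(ppm_error(ion_mz(f, ion), mz)), str(f)))
    return out
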