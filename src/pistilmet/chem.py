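"""Elemental-formula arithmetic for accurate-mass small-molecule annotation.

Everything downstream of a QTOF measurement — candidate-formula enumeration,
adduct/dimer mass relations, carbon counting from isotopologue ratios — reduces
to a handful of primitives over element-count maps: monoisotopic masses, ion
m/z with explicit electron-mass correction, ring-and-double-bond equivalents
(RDBE), the nitrogen rule, signed ppm errors, and first-isotopologue (A+1)/A
intensity ratios.  This module provides those primitives.

Masses are CODATA/NIST monoisotopic values shipped as a versioned plain-text
table (``data/elements.tsv``).  All internal arithmetic is done in full double
precision; rounding to a printed precision (half-up) is an explicit, separate
step (:func:`round_half_up`).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from typing import Iterable, Mapping

__all__ = [
    "ELECTRON_MASS",
    "PROTON_MASS",
    "ADDUCTS",
    "Formula",
    "AdductSpec",
    "ToleranceModel",
    "CarbonEstimate",
    "FormulaError",
    "parse_formula",
    "monoisotopic_mass",
    "ion_mz",
    "ion_mz_from_mass",
    "neutral_mass_from_ion",
    "even_electron_cation_mz",
    "rdbe",
    "nitrogen_rule_ok",
    "ppm_error",
    "predict_a1_ratio",
    "estimate_carbon_count",
    "round_half_up",
]

#: Rest mass of the electron in Da (CODATA).  Subtracted once for every +1
#: even-electron cation so that e.g. [M+H]+ of C27H48O11 lands on 549.3269.
ELECTRON_MASS = 0.000548579909

#: Mass spacing between a monoisotopic peak and its (A+1) isotopologue,
#: dominated by 13C - 12C.
ISOTOPE_SPACING = 1.0033548378


class FormulaError(ValueError):
    """Malformed formula string, unsupported element, or invalid operand."""


def _load_element_table() -> dict[str, tuple[float, int, int, float]]:
    table: dict[str, tuple[float, int, int, float]] = {}
    text = (
        resources.files("pistilmet").joinpath("data/elements.tsv").read_text()
    )
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        sym, mono, nominal, valence, a1 = line.split("\t")
        table[sym] = (float(mono), int(nominal), int(valence), float(a1))
    return table


_ELEMENTS = _load_element_table()

#: Monoisotopic mass of each supported element, Da.
MONOISOTOPIC = {s: v[0] for s, v in _ELEMENTS.items()}
#: Integer mass number of the most abundant isotope.
NOMINAL = {s: v[1] for s, v in _ELEMENTS.items()}
#: Standard valence used for RDBE.
VALENCE = {s: v[2] for s, v in _ELEMENTS.items()}
#: Default per-atom (A+1)/A contribution, percent.
A1_PERCENT = {s: v[3] for s, v in _ELEMENTS.items()}

#: Conventional per-carbon (A+1)/A contribution (percent) used when turning a
#: measured isotopologue ratio into a carbon-count estimate.
PER_CARBON_A1_PERCENT = 1.08

PROTON_MASS = MONOISOTOPIC["H"] - ELECTRON_MASS


@dataclass(frozen=True)
class Formula:
    """An elemental composition with an integer charge.

    Immutable and hashable; element counts are stored as a sorted tuple of
    ``(symbol, count)`` pairs with all counts > 0.  Use
    :meth:`Formula.from_counts` or :func:`parse_formula` to construct one.
    """

    items: tuple[tuple[str, int], ...]
    charge: int = 0

    @classmethod
    def from_counts(cls, counts: Mapping[str, int], charge: int = 0) -> "Formula":
        clean: dict[str, int] = {}
        for sym, n in counts.items():
            if sym not in MONOISOTOPIC:
                raise FormulaError(f"unsupported element symbol: {sym!r}")
            if not isinstance(n, int) or n < 0:
                raise FormulaError(f"negative or non-integer count for {sym}: {n!r}")
            if n:
                clean[sym] = n
        return cls(tuple(sorted(clean.items())), charge)

    @property
    def counts(self) -> dict[str, int]:
        return dict(self.items)

    def __getitem__(self, sym: str) -> int:
        return dict(self.items).get(sym, 0)

    def __bool__(self) -> bool:
        return bool(self.items)

    def __add__(self, other: "Formula") -> "Formula":
        counts = self.counts
        for sym, n in other.items:
            counts[sym] = counts.get(sym, 0) + n
        return Formula.from_counts(counts, self.charge + other.charge)

    def __sub__(self, other: "Formula") -> "Formula":
        counts = self.counts
        for sym, n in other.items:
            counts[sym] = counts.get(sym, 0) - n
            if counts[sym] < 0:
                raise FormulaError(
                    f"cannot remove {other} from {self}: negative {sym} count"
                )
        return Formula.from_counts(counts, self.charge - other.charge)

    def contains(self, other: "Formula") -> bool:
        """True iff ``other`` is an elemental sub-formula of this one."""
        mine = self.counts
        return all(mine.get(sym, 0) >= n for sym, n in other.items)

    def hill(self) -> str:
        """Canonical Hill-order string: C, H, then other elements A–Z.

        Formulae without carbon list every element alphabetically, per the
        Hill convention.
        """
        counts = self.counts
        parts: list[str] = []
        if "C" in counts:
            order = ["C"] + (["H"] if "H" in counts else [])
            order += sorted(s for s in counts if s not in ("C", "H"))
        else:
            order = sorted(counts)
        for sym in order:
            n = counts[sym]
            parts.append(sym if n == 1 else f"{sym}{n}")
        return "".join(parts)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        s = self.hill()
        if self.charge > 0:
            s += "+" * self.charge
        elif self.charge < 0:
            s += "-" * (-self.charge)
        return s


_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(text: str, charge: int = 0) -> Formula:
    """Parse a Hill-style formula string such as ``"C27H49O11"``.

    A trailing ``+`` or ``-`` run sets the charge (overriding ``charge``).
    Unknown element symbols and malformed tokens raise :class:`FormulaError`
    naming the offending token.
    """
    body = text.strip()
    if not body:
        raise FormulaError("empty formula string")
    m = re.search(r"([+-]+)$", body)
    if m:
        sign = 1 if m.group(1)[0] == "+" else -1
        if len(set(m.group(1))) != 1:
            raise FormulaError(f"mixed charge signs in {text!r}")
        charge = sign * len(m.group(1))
        body = body[: m.start()]
    counts: dict[str, int] = {}
    pos = 0
    while pos < len(body):
        m = _TOKEN.match(body, pos)
        if not m or not m.group(1):
            raise FormulaError(f"malformed token at {body[pos:]!r} in {text!r}")
        sym, digits = m.group(1), m.group(2)
        if sym not in MONOISOTOPIC:
            raise FormulaError(f"unsupported element symbol {sym!r} in {text!r}")
        counts[sym] = counts.get(sym, 0) + (int(digits) if digits else 1)
        pos = m.end()
    return Formula.from_counts(counts, charge)


@dataclass(frozen=True)
class AdductSpec:
    """A positive-mode ionization species: ``mult * M + added - e``.

    ``mult`` is 1 for monomer adducts and 2 for dimers; ``added`` is the
    attached atom set (H, Na or K here); charge is always +1 for the species
    relevant to this pipeline.
    """

    name: str
    mult: int
    added: Formula
    charge: int = 1

    def __post_init__(self) -> None:
        if self.mult not in (1, 2):
            raise FormulaError(f"adduct multiplicity must be 1 or 2: {self.mult}")
        if self.charge != 1:
            raise FormulaError("only +1 adducts are supported")


ADDUCTS: dict[str, AdductSpec] = {
    "M+H": AdductSpec("M+H", 1, parse_formula("H")),
    "M+Na": AdductSpec("M+Na", 1, parse_formula("Na")),
    "M+K": AdductSpec("M+K", 1, parse_formula("K")),
    "2M+Na": AdductSpec("2M+Na", 2, parse_formula("Na")),
    "2M+K": AdductSpec("2M+K", 2, parse_formula("K")),
}


@dataclass(frozen=True)
class ToleranceModel:
    """Two-component mass tolerance: ``abs_mda`` mDa + ``rel_ppm`` ppm.

    A mass match passes when ``|delta| <= abs_mda/1000 + rel_ppm * m / 1e6``.
    The default mirrors a tightened QTOF isotope-spacing setting of
    2 mDa + 3 ppm.
    """

    abs_mda: float = 2.0
    rel_ppm: float = 3.0

    def __post_init__(self) -> None:
        if self.abs_mda < 0 or self.rel_ppm < 0:
            raise ValueError("tolerance components must be non-negative")

    def window(self, m: float) -> float:
        """Half-width of the acceptance window at mass ``m``, in Da."""
        return self.abs_mda / 1000.0 + self.rel_ppm * m / 1e6

    def matches(self, measured: float, theoretical: float) -> bool:
        return abs(measured - theoretical) <= self.window(theoretical)


def monoisotopic_mass(f: Formula) -> float:
    """Neutral monoisotopic mass in Da (sum over most-abundant isotopes)."""
    if not f:
        raise FormulaError("cannot take the mass of an empty formula")
    if f.charge != 0:
        raise FormulaError(
            f"monoisotopic_mass expects a neutral formula, got charge {f.charge}"
        )
    return sum(MONOISOTOPIC[sym] * n for sym, n in f.items)


def _atom_mass_sum(f: Formula) -> float:
    return sum(MONOISOTOPIC[sym] * n for sym, n in f.items)


def ion_mz(neutral: Formula, adduct: AdductSpec) -> float:
    """m/z of ``[mult*M + added]+`` with electron-mass correction."""
    return adduct.mult * monoisotopic_mass(neutral) + _atom_mass_sum(
        adduct.added
    ) - adduct.charge * ELECTRON_MASS


def ion_mz_from_mass(neutral_mass: float, adduct: AdductSpec) -> float:
    """Same as :func:`ion_mz` but starting from a numeric neutral mass."""
    if neutral_mass <= 0:
        raise ValueError("neutral mass must be positive")
    return adduct.mult * neutral_mass + _atom_mass_sum(adduct.added) - ELECTRON_MASS


def neutral_mass_from_ion(mz: float, adduct: AdductSpec) -> float:
    """Invert :func:`ion_mz_from_mass`: neutral mass implied by an ion m/z."""
    return (mz - _atom_mass_sum(adduct.added) + ELECTRON_MASS) / adduct.mult


def even_electron_cation_mz(f: Formula) -> float:
    """m/z of an even-electron +1 cation given its full atom inventory.

    Used for in-source fragment ions written with their charge, e.g.
    C17H33O3+ -> 285.2424.
    """
    if not f:
        raise FormulaError("cannot take the m/z of an empty formula")
    return _atom_mass_sum(f) - ELECTRON_MASS


def rdbe(f: Formula, neutralize: bool = False) -> float:
    """Ring-and-double-bond equivalents, ``1 + sum n_i (v_i - 2) / 2``.

    With ``neutralize=True`` the formula is treated as a protonated even-
    electron cation and one hydrogen is removed first, so the value refers to
    the neutral molecule (the convention of formula-generation reports).
    """
    counts = f.counts
    if neutralize:
        counts["H"] = counts.get("H", 0) - 1
        if counts["H"] < 0:
            raise FormulaError(f"cannot neutralize {f}: no hydrogen to remove")
    return 1.0 + sum(n * (VALENCE[sym] - 2) for sym, n in counts.items()) / 2.0


def nominal_mass(f: Formula) -> int:
    """Integer nominal mass (sum of most-abundant-isotope mass numbers)."""
    return sum(NOMINAL[sym] * n for sym, n in f.items)


def nitrogen_rule_ok(neutral: Formula) -> bool:
    """Nitrogen rule: nominal-mass parity must match nitrogen-count parity.

    For CHNOPS(+Na,K) molecules an even nitrogen count implies an even
    nominal mass and an odd count an odd mass; candidates violating this
    cannot be valid neutral molecules.
    """
    return nominal_mass(neutral) % 2 == neutral["N"] % 2


def ppm_error(measured: float, theoretical: float) -> float:
    """Signed relative mass error ``(measured - theoretical)/theoretical`` in ppm."""
    if theoretical <= 0:
        raise ValueError("theoretical mass must be positive")
    return (measured - theoretical) / theoretical * 1e6


def predict_a1_ratio(
    f: Formula, contributions: Mapping[str, float] | None = None
) -> float:
    """Predicted (A+1)/A isotopologue intensity ratio in percent.

    First-order linear model: each atom contributes its heavy-isotope
    abundance ratio independently, so the total is ``sum(count * r_element)``.
    The per-carbon contribution is fixed at 1.08 %/C (the convention used for
    carbon counting); other elements default to their natural (A+1)/A
    abundance ratios and can be overridden via ``contributions``.
    """
    if not f:
        raise FormulaError("cannot predict isotope ratio of an empty formula")
    table = dict(A1_PERCENT)
    if contributions:
        table.update(contributions)
    return sum(table[sym] * n for sym, n in f.items)


@dataclass(frozen=True)
class CarbonEstimate:
    """Carbon count inferred from a measured (A+1)/A ratio."""

    estimate: float
    window: tuple[int, int]

    def __contains__(self, n_carbon: int) -> bool:
        return self.window[0] <= n_carbon <= self.window[1]


def estimate_carbon_count(
    a1_ratio_percent: float, per_carbon: float = PER_CARBON_A1_PERCENT
) -> CarbonEstimate:
    """Estimate the carbon count as ``ratio / 1.08`` with a +-type window.

    The integer acceptance window is ``[floor(estimate) - 1,
    floor(estimate) + 2]``, reproducing the mapping 28.60 % -> estimate
    26.48 -> allowed carbon counts 25–28.  The window is deliberately
    asymmetric: non-carbon elements only ever inflate the measured ratio,
    so the true carbon count tends to sit at or below ``estimate + 1``.
    """
    if a1_ratio_percent < 0:
        raise ValueError("isotopologue ratio must be non-negative")
    est = a1_ratio_percent / per_carbon
    return CarbonEstimate(est, (max(int(est) - 1, 0), int(est) + 2))


def round_half_up(x: float, ndigits: int) -> float:
    """Round half away from zero at ``ndigits`` decimals (report convention)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def combinations_mass(formulae: Iterable[Formula]) -> float:
    """Sum of neutral monoisotopic masses; convenience for loss ladders."""
    return sum(monoisotopic_mass(f) for f in formulae)
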