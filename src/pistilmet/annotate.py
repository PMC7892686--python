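"""Molecular-formula annotation of accurate-mass ions.

Given a measured ion m/z, every CHNOPS composition whose adduct ion falls
within a ppm tolerance is a candidate formula.  The list is then narrowed
with orthogonal experimental evidence, the way an analyst works through a
formula-generation report:

* the composition of the largest confidently-identified in-source fragment
  sets a lower bound on the carbon count (a fragment cannot contain more
  carbon than its precursor);
* the measured (A+1)/A isotopologue ratio brackets the carbon count;
* the neutral-loss ladder (n x H2O, CH2) sets a lower bound on oxygen.

Every candidate carries an audit trail: at each stage it is either kept or
excluded with a machine-readable reason, and kept + excluded always equals
the initial count (the :class:`AnnotationLedger` conservation invariant).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

from .chem import (
    ADDUCTS,
    ELECTRON_MASS,
    MONOISOTOPIC,
    AdductSpec,
    Formula,
    estimate_carbon_count,
    ion_mz,
    neutral_mass_from_ion,
    nitrogen_rule_ok,
    ppm_error,
    predict_a1_ratio,
    rdbe,
)
from .spectra import NeutralLossStep, loss_counts

__all__ = [
    "ElementBounds",
    "CandidateFormula",
    "ConstraintSet",
    "AnnotationLedger",
    "AnnotationEvidence",
    "AnnotationConfig",
    "enumerate_candidates",
    "score_candidate",
    "constraints_from_evidence",
    "apply_constraints",
    "finalize",
    "annotate_compound",
]

log = logging.getLogger(__name__)

#: Vocabulary of exclusion reasons carried on excluded candidates.
EXCLUSION_REASONS = ("min-carbon", "carbon-window", "min-oxygen", "subformula", "score")

_ENUM_ELEMENTS = ("C", "H", "N", "O", "P", "S")


@dataclass(frozen=True)
class ElementBounds:
    """Per-element [min, max] count limits for candidate enumeration."""

    bounds: dict[str, tuple[int, int]]

    def __post_init__(self) -> None:
        for sym, (lo, hi) in self.bounds.items():
            if lo < 0 or lo > hi:
                raise ValueError(f"invalid bounds for {sym}: [{lo}, {hi}]")

    def range(self, sym: str) -> tuple[int, int]:
        return self.bounds.get(sym, (0, 0))

    @classmethod
    def from_max(cls, **maxima: int) -> "ElementBounds":
        return cls({sym: (0, hi) for sym, hi in maxima.items()})


#: Default enumeration bounds: generous CHNOPS limits for a < 1.5 kDa
#: plant-metabolite search space.
DEFAULT_BOUNDS = ElementBounds.from_max(C=50, H=100, N=20, O=20, P=4, S=3)

#: Safety cap on the number of candidates an enumeration may return.
DEFAULT_CANDIDATE_CAP = 10_000


class CandidateOverflowError(RuntimeError):
    """Enumeration bounds admit more candidates than the configured cap."""


@dataclass
class CandidateFormula:
    """One candidate assignment for a measured ion."""

    neutral: Formula
    ion: Formula
    theoretical_mz: float
    ppm: float
    rdbe_neutral: float
    isotope_fit: float = math.nan
    status: str = "kept"
    exclusion_reason: str = ""

    def exclude(self, reason: str) -> None:
        if reason not in EXCLUSION_REASONS:
            raise ValueError(f"unknown exclusion reason {reason!r}")
        self.status = "excluded"
        self.exclusion_reason = reason


@dataclass(frozen=True)
class ConstraintSet:
    """Evidence-derived element constraints.

    ``min_carbon`` comes from the largest identified fragment,
    ``carbon_window`` from the isotopologue ratio, ``min_oxygen`` from the
    neutral-loss ladder, and ``required_subformulae`` lists fragment
    compositions (minus the losses already spent) the precursor must embed.
    An empty constraint set keeps everything.
    """

    min_carbon: int = 0
    carbon_window: tuple[int, int] | None = None
    min_oxygen: int = 0
    required_subformulae: tuple[Formula, ...] = ()

    def carbon_range(self) -> tuple[int, float]:
        lo, hi = self.min_carbon, math.inf
        if self.carbon_window is not None:
            lo = max(lo, self.carbon_window[0])
            hi = self.carbon_window[1]
        return lo, hi


@dataclass
class AnnotationLedger:
    """Per-candidate audit trail of the enumeration -> narrowing -> pick."""

    measured_mz: float
    adduct: AdductSpec
    candidates: list[CandidateFormula] = field(default_factory=list)
    stages: list[dict] = field(default_factory=list)
    final: CandidateFormula | None = None

    def snapshot(self, stage: str) -> None:
        kept = sum(1 for c in self.candidates if c.status == "kept")
        self.stages.append(
            {
                "stage": stage,
                "kept": kept,
                "excluded": len(self.candidates) - kept,
                "statuses": {
                    c.ion.hill(): (c.status, c.exclusion_reason)
                    for c in self.candidates
                },
            }
        )

    @property
    def kept(self) -> list[CandidateFormula]:
        return [c for c in self.candidates if c.status == "kept"]

    def to_rows(self) -> list[dict]:
        """Candidate report rows mirroring a formula-generation table."""
        return [
            {
                "ion_formula": c.ion.hill(),
                "theoretical_mz": c.theoretical_mz,
                "ppm": c.ppm,
                "score": c.isotope_fit,
                "rdbe": c.rdbe_neutral,
                "status": c.status,
                "reason": c.exclusion_reason,
            }
            for c in self.candidates
        ]


def enumerate_candidates(
    measured: float,
    adduct: AdductSpec = ADDUCTS["M+H"],
    tol_ppm: float = 6.0,
    bounds: ElementBounds = DEFAULT_BOUNDS,
    cap: int = DEFAULT_CANDIDATE_CAP,
) -> list[CandidateFormula]:
    """All CHNOPS neutral formulae whose adduct ion matches ``measured``.

    A composition qualifies when its ion m/z lies within ``tol_ppm`` of the
    measurement, the neutral form satisfies the nitrogen rule, and its
    neutral RDBE is >= 0 (RDBE 0 saturated acyclic molecules are legitimate).
    Results are sorted by |ppm error|, ties broken by Hill string.  The loop
    structure fixes N, O, P, S and C and solves the remaining mass for the
    hydrogen count, so it is exhaustive over the bounds by construction.
    """
    if measured <= 0:
        raise ValueError("measured m/z must be positive")
    target = neutral_mass_from_ion(measured, adduct)
    half = tol_ppm * measured / 1e6 / adduct.mult
    lo_mass, hi_mass = target - half, target + half
    mH = MONOISOTOPIC["H"]
    ranges = {sym: bounds.range(sym) for sym in _ENUM_ELEMENTS}
    out: list[CandidateFormula] = []
    for n in range(ranges["N"][0], ranges["N"][1] + 1):
        m_n = n * MONOISOTOPIC["N"]
        if m_n > hi_mass:
            break
        for o in range(ranges["O"][0], ranges["O"][1] + 1):
            m_no = m_n + o * MONOISOTOPIC["O"]
            if m_no > hi_mass:
                break
            for p in range(ranges["P"][0], ranges["P"][1] + 1):
                m_nop = m_no + p * MONOISOTOPIC["P"]
                if m_nop > hi_mass:
                    break
                for s in range(ranges["S"][0], ranges["S"][1] + 1):
                    m_nops = m_nop + s * MONOISOTOPIC["S"]
                    if m_nops > hi_mass:
                        break
                    for c in range(ranges["C"][0], ranges["C"][1] + 1):
                        rem_lo = lo_mass - m_nops - c * 12.0
                        rem_hi = hi_mass - m_nops - c * 12.0
                        if rem_hi < 0:
                            break
                        h_lo = max(math.ceil(rem_lo / mH), ranges["H"][0])
                        h_hi = min(math.floor(rem_hi / mH), ranges["H"][1])
                        for h in range(h_lo, h_hi + 1):
                            cand = _make_candidate(
                                {"C": c, "H": h, "N": n, "O": o, "P": p, "S": s},
                                measured,
                                adduct,
                                tol_ppm,
                            )
                            if cand is not None:
                                out.append(cand)
                                if len(out) > cap:
                                    raise CandidateOverflowError(
                                        f"more than {cap} candidates within "
                                        f"{tol_ppm} ppm of {measured}"
                                    )
    out.sort(key=lambda cnd: (abs(cnd.ppm), cnd.neutral.hill()))
    return out


def _make_candidate(
    counts: dict[str, int],
    measured: float,
    adduct: AdductSpec,
    tol_ppm: float,
) -> CandidateFormula | None:
    neutral = Formula.from_counts(counts)
    if not neutral:
        return None
    theo = ion_mz(neutral, adduct)
    err = ppm_error(measured, theo)
    if abs(err) > tol_ppm:
        return None
    if not nitrogen_rule_ok(neutral):
        return None
    r = rdbe(neutral)
    if r < 0:
        return None
    ion = neutral + adduct.added if adduct.mult == 1 else None
    if ion is None:  # dimer ion formula: 2M + added atoms
        doubled = neutral + neutral
        ion = doubled + adduct.added
    ion = Formula.from_counts(ion.counts, charge=adduct.charge)
    return CandidateFormula(neutral, ion, theo, err, r)


#: Gaussian decay scales of the candidate score: ppm term (instrument-level
#: mass accuracy) and isotope-ratio term (percentage points).
SCORE_PPM_SCALE = 3.0
SCORE_A1_SCALE = 2.0


def score_candidate(
    c: CandidateFormula, measured_a1_ratio: float | None
) -> float:
    """Composite 0–100 plausibility score for a candidate.

    ``100 * exp(-(ppm/s_m)^2 / 2 - (dA1/s_i)^2 / 2)`` where ``ppm`` is the
    candidate's mass error, ``dA1`` the gap between the measured and
    predicted (A+1)/A ratios in percentage points, and the scales are
    ``s_m = 3`` ppm and ``s_i = 2`` points.  The score is 100 at zero
    discrepancy and strictly decreasing in both |ppm| and |dA1|.  With no
    measured isotope ratio only the mass term applies.
    """
    if measured_a1_ratio is not None and measured_a1_ratio < 0:
        raise ValueError("measured isotopologue ratio must be non-negative")
    z = (c.ppm / SCORE_PPM_SCALE) ** 2
    if measured_a1_ratio is not None:
        d = measured_a1_ratio - predict_a1_ratio(c.neutral)
        z += (d / SCORE_A1_SCALE) ** 2
    return 100.0 * math.exp(-z / 2.0)


def constraints_from_evidence(
    largest_fragment: Formula | None = None,
    a1_ratio: float | None = None,
    ladder: Sequence[NeutralLossStep] | None = None,
    methyl_oxygen_ambiguity: bool = True,
) -> ConstraintSet:
    """Turn fragment, isotope-ratio and neutral-loss evidence into bounds.

    * ``largest_fragment``: its carbon count is a lower bound for the
      precursor and its composition a required sub-formula.
    * ``a1_ratio`` (percent): carbon window via :func:`estimate_carbon_count`.
    * ``ladder``: each H2O loss testifies to one oxygen; a CH2 step adds one
      more when ``methyl_oxygen_ambiguity`` is set, because a CH2 difference
      between fragments cannot distinguish a C-methyl from an O-methyl
      substituent, and the conservative reading books the extra oxygen.
    """
    if largest_fragment is None and a1_ratio is None and ladder is None:
        raise ValueError("at least one piece of evidence is required")
    min_c = 0
    required: tuple[Formula, ...] = ()
    if largest_fragment is not None:
        min_c = largest_fragment["C"]
        required = (largest_fragment,)
    window = None
    if a1_ratio is not None:
        window = estimate_carbon_count(a1_ratio).window
    min_o = 0
    if ladder is not None:
        counts = loss_counts(ladder)
        min_o = counts["H2O"]
        if counts["CH2"] > 0 and methyl_oxygen_ambiguity:
            min_o += 1
    return ConstraintSet(min_c, window, min_o, required)


def apply_constraints(
    candidates: Sequence[CandidateFormula], cs: ConstraintSet
) -> list[CandidateFormula]:
    """Exclude candidates violating the constraint set (in place).

    Order of checks fixes the reported reason when several constraints are
    violated at once: fragment carbon floor, then isotope carbon window,
    then oxygen floor, then required sub-formula embedding.  Conservation
    (kept + excluded = initial) holds by construction.
    """
    lo_c, hi_c = cs.carbon_range()
    for c in candidates:
        if c.status != "kept":
            continue
        n_c, n_o = c.neutral["C"], c.neutral["O"]
        if n_c < cs.min_carbon:
            c.exclude("min-carbon")
        elif not lo_c <= n_c <= hi_c:
            c.exclude("carbon-window")
        elif n_o < cs.min_oxygen:
            c.exclude("min-oxygen")
        elif any(
            not c.neutral.contains(frag - Formula.from_counts({"H": 1}))
            for frag in cs.required_subformulae
            if frag["H"] > 0
        ):
            # fragment cations carry the transferred proton; the precursor
            # must embed the fragment minus that proton
            c.exclude("subformula")
    return list(candidates)


def finalize(
    kept: Sequence[CandidateFormula], measured_a1_ratio: float | None = None
) -> CandidateFormula | None:
    """Pick the winner among surviving candidates.

    Candidates are ranked by (|ppm error|, isotope-ratio discrepancy, Hill
    string): the mass error is the primary instrument-grade criterion and the
    isotopologue fit the secondary one, so the chosen candidate is the one
    with the best agreement on all listed parameters.  Exact ties fall back
    to the lexicographically smaller formula and are logged.  Returns None
    for an empty kept set (a no-assignment outcome, not an error).
    """
    pool = [c for c in kept if c.status == "kept"]
    if not pool:
        return None

    def iso_gap(c: CandidateFormula) -> float:
        if measured_a1_ratio is None:
            return 0.0
        return abs(measured_a1_ratio - predict_a1_ratio(c.neutral))

    ranked = sorted(pool, key=lambda c: (abs(c.ppm), iso_gap(c), c.neutral.hill()))
    winner = ranked[0]
    if len(ranked) > 1:
        runner = ranked[1]
        if abs(winner.ppm) == abs(runner.ppm) and iso_gap(winner) == iso_gap(runner):
            log.info(
                "exact tie between %s and %s; lexicographic tie-break",
                winner.ion.hill(),
                runner.ion.hill(),
            )
        log.debug(
            "final margin over runner-up: d|ppm|=%.2f, d|A1|=%.2f",
            abs(runner.ppm) - abs(winner.ppm),
            iso_gap(runner) - iso_gap(winner),
        )
    return winner


@dataclass
class AnnotationEvidence:
    """Spectral evidence accompanying a measured precursor."""

    a1_ratio: float | None = None
    largest_fragment: Formula | None = None
    ladder: Sequence[NeutralLossStep] | None = None


@dataclass
class AnnotationConfig:
    tol_ppm: float = 6.0
    adduct: AdductSpec = ADDUCTS["M+H"]
    bounds: ElementBounds = DEFAULT_BOUNDS
    cap: int = DEFAULT_CANDIDATE_CAP
    methyl_oxygen_ambiguity: bool = True


def annotate_compound(
    measured_mz: float,
    evidence: AnnotationEvidence | None = None,
    config: AnnotationConfig | None = None,
) -> AnnotationLedger:
    """End-to-end annotation: enumerate, constrain, score, pick.

    Missing evidence degrades gracefully to unconstrained enumeration; the
    returned ledger records every candidate's fate at every stage.
    """
    config = config or AnnotationConfig()
    evidence = evidence or AnnotationEvidence()
    ledger = AnnotationLedger(measured_mz, config.adduct)
    ledger.candidates = enumerate_candidates(
        measured_mz, config.adduct, config.tol_ppm, config.bounds, config.cap
    )
    for c in ledger.candidates:
        c.isotope_fit = score_candidate(c, evidence.a1_ratio)
    ledger.snapshot("enumerated")
    if any(
        x is not None
        for x in (evidence.largest_fragment, evidence.a1_ratio, evidence.ladder)
    ):
        cs = constraints_from_evidence(
            evidence.largest_fragment,
            evidence.a1_ratio,
            evidence.ladder,
            config.methyl_oxygen_ambiguity,
        )
        apply_constraints(ledger.candidates, cs)
        ledger.snapshot("constrained")
    ledger.final = finalize(ledger.kept, evidence.a1_ratio)
    ledger.snapshot("finalized")
    return ledger
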