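"""Co-elution grouping of mass signals into compound components.

A QTOF full-scan run of a plant extract shows each compound not as one peak
but as a constellation: the protonated molecule, sodium/potassium adducts,
sodiated/potassiated dimers, and in-source fragments, all sharing one
chromatographic elution profile.  This module automates the manual
verification of that structure: extracted-ion chromatograms (EICs), Pearson
correlation of elution profiles, partitioning of co-eluting signals into
component groups with adduct/fragment role assignment, consensus neutral-mass
inference, and interpretation of neutral-loss ladders (H2O, CH2) among
fragment ions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .chem import (
    ADDUCTS,
    AdductSpec,
    ToleranceModel,
    ion_mz_from_mass,
    monoisotopic_mass,
    neutral_mass_from_ion,
    parse_formula,
)

__all__ = [
    "Spectrum",
    "SpectrumPeak",
    "EICTrace",
    "ComponentGroup",
    "GroupMember",
    "NeutralLossStep",
    "extract_eic",
    "correlate_traces",
    "group_coeluting",
    "infer_neutral_mass",
    "fragment_ladder",
    "measure_a1_ratio",
    "read_peak_list",
    "write_peak_list",
]

log = logging.getLogger(__name__)

#: Acquisition m/z range of the method; peaks outside it are rejected.
ACQUISITION_RANGE = (100.0, 1700.0)

H2O_MASS = monoisotopic_mass(parse_formula("H2O"))
CH2_MASS = monoisotopic_mass(parse_formula("CH2"))

#: Neutral losses recognised in fragment ladders, by label.
NEUTRAL_LOSSES = {"H2O": H2O_MASS, "CH2": CH2_MASS}

#: Member roles within a component group.
ROLES = (
    "protonated",
    "sodium-adduct",
    "potassium-adduct",
    "dimer-sodium",
    "dimer-potassium",
    "in-source-fragment",
    "unassigned",
)

_ROLE_ADDUCT: dict[str, AdductSpec] = {
    "protonated": ADDUCTS["M+H"],
    "sodium-adduct": ADDUCTS["M+Na"],
    "potassium-adduct": ADDUCTS["M+K"],
    "dimer-sodium": ADDUCTS["2M+Na"],
    "dimer-potassium": ADDUCTS["2M+K"],
}


@dataclass(frozen=True)
class SpectrumPeak:
    """A centroided mass signal: m/z (Da) and intensity (counts)."""

    mz: float
    intensity: float

    def __post_init__(self) -> None:
        if not ACQUISITION_RANGE[0] <= self.mz <= ACQUISITION_RANGE[1]:
            raise ValueError(
                f"m/z {self.mz} outside acquisition range {ACQUISITION_RANGE}"
            )
        if self.intensity < 0:
            raise ValueError("intensity must be non-negative")


@dataclass(frozen=True)
class Spectrum:
    """One scan: retention time (minutes) plus centroid peak arrays."""

    rt: float
    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "mz", np.asarray(self.mz, dtype=float))
        object.__setattr__(
            self, "intensity", np.asarray(self.intensity, dtype=float)
        )
        if self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity arrays must have equal shape")


@dataclass
class EICTrace:
    """Extracted-ion chromatogram for a narrow m/z window."""

    target_mz: float
    tolerance: ToleranceModel
    time: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.time.ndim != 1 or self.time.shape != self.intensity.shape:
            raise ValueError("time and intensity must be 1-D and equal length")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time axis must be strictly increasing")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be non-negative")

    @property
    def apex_rt(self) -> float:
        return float(self.time[int(np.argmax(self.intensity))])


@dataclass
class GroupMember:
    """One signal inside a component group, with its assigned role."""

    mz: float
    intensity: float
    role: str = "unassigned"


@dataclass
class ComponentGroup:
    """Co-eluting signals interpreted as one compound component."""

    members: list[GroupMember]
    apex_rt: float
    inferred_neutral_mass: float | None = None
    neutral_mass_spread: float | None = None
    correlations: np.ndarray = field(default_factory=lambda: np.empty((0, 0)))

    def role_of(self, mz: float) -> str:
        for m in self.members:
            if m.mz == mz:
                return m.role
        raise KeyError(mz)

    @property
    def protonated(self) -> GroupMember | None:
        for m in self.members:
            if m.role == "protonated":
                return m
        return None


@dataclass(frozen=True)
class NeutralLossStep:
    """One step of a fragment ladder: from_mz -> to_mz with an assigned loss."""

    from_mz: float
    to_mz: float
    assigned_loss: str
    delta: float

    def __post_init__(self) -> None:
        if self.from_mz <= self.to_mz:
            raise ValueError("ladder steps must descend in m/z")


def extract_eic(
    spectra: Sequence[Spectrum], target: float, tol: ToleranceModel
) -> EICTrace:
    """Sum, per scan, the intensity of peaks matching ``target`` under ``tol``.

    Scans must be time-ordered; time points with no matching peak contribute
    zero intensity.
    """
    if len(spectra) < 2:
        raise ValueError("need at least two spectra to extract an EIC")
    if not ACQUISITION_RANGE[0] <= target <= ACQUISITION_RANGE[1]:
        raise ValueError(f"target {target} outside acquisition range")
    half = tol.window(target)
    times = np.array([s.rt for s in spectra])
    intensities = np.array(
        [
            float(s.intensity[np.abs(s.mz - target) <= half].sum())
            for s in spectra
        ]
    )
    return EICTrace(target, tol, times, intensities)


def correlate_traces(a: EICTrace, b: EICTrace) -> float:
    """Pearson correlation of two EICs sharing a time axis."""
    if a.time.shape != b.time.shape or not np.allclose(a.time, b.time):
        raise ValueError("traces must share a common time axis")
    if np.ptp(a.intensity) == 0 or np.ptp(b.intensity) == 0:
        raise ValueError(
            "flat (zero-variance) trace: elution correlation is undefined"
        )
    return float(np.corrcoef(a.intensity, b.intensity)[0, 1])


def _assign_roles(group: ComponentGroup, tol: ToleranceModel) -> None:
    """Assign adduct/dimer/fragment roles by known mass relations.

    Each member is tried as the protonated molecule; the hypothesis
    explaining the largest number of other members through Na/K adduct and
    dimer mass relations wins.  When no hypothesis explains anything (e.g. a
    precursor with only in-source fragments) the highest-m/z member is taken
    as protonated.  Ties between equally explanatory hypotheses go to the
    higher m/z, i.e. the interpretation consistent with all adduct relations,
    and are logged.
    """
    members = group.members
    best_idx, best_matches, best_count = 0, {}, -1
    order = sorted(range(len(members)), key=lambda i: members[i].mz)
    for i in order:  # ascending, so later (higher-m/z) ties overwrite
        neutral = neutral_mass_from_ion(members[i].mz, ADDUCTS["M+H"])
        matches: dict[int, str] = {}
        for j, m in enumerate(members):
            if j == i:
                continue
            for role, adduct in _ROLE_ADDUCT.items():
                if role == "protonated":
                    continue
                theo = ion_mz_from_mass(neutral, adduct)
                if tol.matches(m.mz, theo):
                    matches[j] = role
                    break
        if len(matches) >= best_count:
            if len(matches) == best_count:
                log.info(
                    "ambiguous protonated-member choice at rt %.2f: "
                    "m/z %.4f preferred over %.4f",
                    group.apex_rt,
                    members[i].mz,
                    members[best_idx].mz,
                )
            best_idx, best_matches, best_count = i, matches, len(matches)
    prot = members[best_idx]
    prot.role = "protonated"
    for j, role in best_matches.items():
        members[j].role = role
    for j, m in enumerate(members):
        if j == best_idx or j in best_matches:
            continue
        m.role = "in-source-fragment" if m.mz < prot.mz else "unassigned"


def group_coeluting(
    peaks: Sequence[SpectrumPeak],
    traces: Sequence[EICTrace],
    corr_threshold: float = 0.95,
    tol: ToleranceModel = ToleranceModel(),
) -> list[ComponentGroup]:
    """Partition apex peaks into co-eluting component groups.

    Groups are seeded greedily from the most intense unassigned peak; every
    remaining peak whose elution profile correlates with the seed at or above
    ``corr_threshold`` joins the seed's group.  The result is a partition:
    each peak belongs to exactly one group.  Within a group, roles are
    assigned from known adduct/dimer mass relations and the consensus neutral
    mass is inferred.
    """
    if len(peaks) != len(traces):
        raise ValueError("each peak needs exactly one EIC trace")
    if not 0 < corr_threshold <= 1:
        raise ValueError("correlation threshold must be in (0, 1]")
    n = len(peaks)
    corr = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            corr[i, j] = corr[j, i] = correlate_traces(traces[i], traces[j])
    unassigned = set(range(n))
    groups: list[ComponentGroup] = []
    by_intensity = sorted(range(n), key=lambda i: -peaks[i].intensity)
    for seed in by_intensity:
        if seed not in unassigned:
            continue
        idx = [i for i in sorted(unassigned) if corr[seed, i] >= corr_threshold]
        unassigned -= set(idx)
        members = [GroupMember(peaks[i].mz, peaks[i].intensity) for i in idx]
        group = ComponentGroup(
            members=members,
            apex_rt=traces[seed].apex_rt,
            correlations=corr[np.ix_(idx, idx)],
        )
        _assign_roles(group, tol)
        try:
            group.inferred_neutral_mass, group.neutral_mass_spread = (
                infer_neutral_mass(group)
            )
        except ValueError:
            pass
        groups.append(group)
    return groups


def infer_neutral_mass(g: ComponentGroup) -> tuple[float, float]:
    """Consensus neutral mass from all role-assigned members.

    Each assigned member's m/z is inverted through its role's adduct
    arithmetic; the mean is the consensus and the max-min spread (Da) is a
    consistency diagnostic — a large spread flags a mis-assigned relation.
    """
    estimates = [
        neutral_mass_from_ion(m.mz, _ROLE_ADDUCT[m.role])
        for m in g.members
        if m.role in _ROLE_ADDUCT
    ]
    if not estimates:
        raise ValueError("no role-assigned members: cannot infer neutral mass")
    return float(np.mean(estimates)), float(np.ptp(estimates))


def fragment_ladder(
    fragment_mzs: Sequence[float], tol: ToleranceModel = ToleranceModel()
) -> list[NeutralLossStep]:
    """Interpret consecutive deltas of a descending fragment series.

    Each consecutive difference is matched against the H2O (18.01056 Da) and
    CH2 (14.01565 Da) neutral-loss masses within ``tol`` (the relative
    component evaluated at the upper fragment's m/z, since that is the scale
    of the two mass measurements the delta is built from); unmatched deltas
    are labelled ``unassigned``.
    """
    mzs = list(fragment_mzs)
    if len(mzs) < 2:
        raise ValueError("a ladder needs at least two m/z values")
    if any(a <= b for a, b in zip(mzs, mzs[1:])):
        raise ValueError("fragment m/z values must be strictly descending")
    steps: list[NeutralLossStep] = []
    for hi, lo in zip(mzs, mzs[1:]):
        delta = hi - lo
        label = "unassigned"
        err = None
        for name, loss in NEUTRAL_LOSSES.items():
            e = abs(delta - loss)
            if e <= tol.window(hi) and (err is None or e < err):
                label, err = name, e
        steps.append(NeutralLossStep(hi, lo, label, delta))
    return steps


def loss_counts(steps: Iterable[NeutralLossStep]) -> dict[str, int]:
    """Count assigned losses by label (``H2O``, ``CH2``, ``unassigned``)."""
    out = {"H2O": 0, "CH2": 0, "unassigned": 0}
    for s in steps:
        out[s.assigned_loss] += 1
    return out


def measure_a1_ratio(
    spectra: Sequence[Spectrum], target: float, tol: ToleranceModel = ToleranceModel()
) -> float:
    """Measured (A+1)/A isotopologue ratio in percent from full-scan spectra.

    Integrates the EICs of the monoisotopic peak and of its (A+1) satellite
    (one isotope spacing higher) and returns their area ratio.
    """
    from .chem import ISOTOPE_SPACING

    a = extract_eic(spectra, target, tol)
    a1 = extract_eic(spectra, target + ISOTOPE_SPACING, tol)
    area = a.intensity.sum()
    if area <= 0:
        raise ValueError(f"no signal at m/z {target}")
    return float(a1.intensity.sum() / area * 100.0)


def read_peak_list(path) -> list[SpectrumPeak]:
    """Read a two-column (m/z, intensity) whitespace-separated text file."""
    peaks = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            try:
                mz, inten = line.split()[:2]
                peaks.append(SpectrumPeak(float(mz), float(inten)))
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}:{line_no}: bad peak line {line!r}") from exc
    return peaks


def write_peak_list(path, peaks: Iterable[SpectrumPeak]) -> None:
    with open(path, "w") as fh:
        fh.write("# m/z\tintensity\n")
        for p in peaks:
            fh.write(f"{p.mz:.5f}\t{p.intensity:.1f}\n")
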