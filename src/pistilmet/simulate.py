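"""Seeded synthetic LC-MS study generator with planted ground truth.

No raw data accompany the pistil-fingerprinting design this package targets,
so every pipeline stage is exercised against synthetic bundles that emulate
the study's shape: two genotypes (self-compatible SC, self-incompatible SI),
four post-pollination time points (0/3/24/96 h), three biological replicates,
positive and negative ion modes (~4000 and ~1000 aligned features by
default), an internal-standard channel at fixed true concentration, per-
sample injection-scale factors, log-normal replicate noise, random dropout
among null features, and a configurable set of planted differential
compounds following the two archetypal trends:

* ``si-accumulating`` — near-absent before pollination, multiplying by a
  fold > 1 at each time step in the SI genotype only (the macrolide-like
  pattern);
* ``si-decreasing`` — present in both genotypes before pollination,
  decaying by a fold < 1 per time step in SI while staying flat in SC (the
  sphingoid-like pattern).

Everything is a pure function of the bundle seed: the same seed yields
byte-identical CSV output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .chem import (
    ADDUCTS,
    AdductSpec,
    Formula,
    ISOTOPE_SPACING,
    even_electron_cation_mz,
    ion_mz,
    parse_formula,
    predict_a1_ratio,
)
from .screen import GENOTYPES, ION_MODES, REPLICATES, TIME_POINTS, FeatureTable
from .spectra import Spectrum

__all__ = [
    "SyntheticDesign",
    "PlantedFeatureSpec",
    "SyntheticBundle",
    "default_planted_features",
    "generate_feature_table",
    "generate_spectrum",
    "generate_study_bundle",
    "evaluate_screen",
]

ARCHETYPES = ("si-accumulating", "si-decreasing", "null")


@dataclass(frozen=True)
class SyntheticDesign:
    """Study shape and noise model of a synthetic bundle."""

    n_null_features: Mapping[str, int] = field(
        default_factory=lambda: {"positive": 4000, "negative": 1000}
    )
    injection_cv: float = 0.10  # per-sample injection/ionization scale spread
    null_cv: float = 0.20  # replicate noise of null features
    null_dropout: float = 0.10  # missingness among null features
    is_abundance: float = 1.0e5  # true internal-standard level, counts
    null_log10_mean: float = 4.5  # null base abundance: 10**N(mean, sd)
    null_log10_sd: float = 0.6
    mass_range: tuple[float, float] = (120.0, 900.0)
    rt_range: tuple[float, float] = (0.4, 14.0)

    def __post_init__(self) -> None:
        for v in (self.injection_cv, self.null_cv):
            if v < 0:
                raise ValueError("coefficients of variation must be >= 0")
        if not 0 <= self.null_dropout < 1:
            raise ValueError("dropout probability must be in [0, 1)")


@dataclass(frozen=True)
class PlantedFeatureSpec:
    """One planted compound and its trend parameters.

    ``base_abundance`` is the SI level at 0 h; each SI time step multiplies
    it by ``fold_per_time_step`` (> 1 accumulating, < 1 decreasing).  For the
    accumulating archetype the SC genotype sits flat at ``base_abundance *
    sc_ratio`` (near-absent); for the decreasing archetype SC is flat at
    ``base_abundance``.
    """

    compound_id: str
    archetype: str
    base_abundance: float
    fold_per_time_step: float
    neutral_mass: float
    rt: float
    modes: tuple[str, ...] = ("positive",)
    cv: float = 0.20
    dropout: float = 0.0
    sc_ratio: float = 0.15

    def __post_init__(self) -> None:
        if self.archetype not in ARCHETYPES:
            raise ValueError(f"unknown archetype {self.archetype!r}")
        if self.base_abundance <= 0 or self.cv < 0 or not 0 <= self.dropout < 1:
            raise ValueError(f"degenerate parameters for {self.compound_id}")
        if self.fold_per_time_step <= 0:
            raise ValueError("fold per time step must be positive")
        if self.archetype == "si-accumulating" and self.fold_per_time_step <= 1:
            raise ValueError("si-accumulating requires fold > 1")
        if self.archetype == "si-decreasing" and self.fold_per_time_step >= 1:
            raise ValueError("si-decreasing requires fold < 1")

    def expected_level(self, genotype: str, time_index: int) -> float:
        """Noise-free abundance for a design cell."""
        if self.archetype == "null":
            return self.base_abundance
        if genotype == "SI":
            return self.base_abundance * self.fold_per_time_step**time_index
        if self.archetype == "si-accumulating":
            return self.base_abundance * self.sc_ratio
        return self.base_abundance


def default_planted_features() -> list[PlantedFeatureSpec]:
    """The default 15 planted differential compounds.

    Ten accumulating and five decreasing compounds, five of them observable
    in both ion modes, spanning realistic neutral masses and retention
    times; three reuse the neutral mass / retention time coordinates of the
    archetypal macrolide-like (548.3198 Da @ 10.07 min), early-eluting
    (204.0871 Da @ 0.45 min) and sphingoid-like (315.2773 Da @ 9.53 min)
    compounds.
    """
    A, D = "si-accumulating", "si-decreasing"
    both = ("positive", "negative")
    pos = ("positive",)
    neg = ("negative",)
    return [
        PlantedFeatureSpec("cmp01", A, 2.0e4, 2.3, 534.3040, 9.82, both),
        PlantedFeatureSpec("cmp02", A, 3.0e4, 2.2, 432.2254, 7.90, pos),
        PlantedFeatureSpec("cmp03", A, 1.2e4, 2.8, 286.1416, 5.20, pos),
        PlantedFeatureSpec("cmp04", A, 1.5e4, 2.5, 548.3198, 10.07, both),
        PlantedFeatureSpec("cmp05", A, 2.0e4, 2.0, 204.0871, 0.45, pos),
        PlantedFeatureSpec("cmp06", A, 2.5e4, 2.4, 610.3567, 11.30, both),
        PlantedFeatureSpec("cmp07", D, 1.2e5, 0.35, 315.2773, 9.53, pos),
        PlantedFeatureSpec("cmp08", D, 8.0e4, 0.35, 180.0634, 1.20, pos),
        PlantedFeatureSpec("cmp09", A, 1.8e4, 2.6, 370.1886, 6.40, neg),
        PlantedFeatureSpec("cmp10", D, 1.5e5, 0.40, 496.3401, 12.10, both),
        PlantedFeatureSpec("cmp11", A, 1.4e4, 3.0, 258.1103, 3.80, pos),
        PlantedFeatureSpec("cmp12", A, 2.2e4, 2.1, 342.1679, 6.90, pos),
        PlantedFeatureSpec("cmp13", D, 9.0e4, 0.35, 414.2209, 8.60, neg),
        PlantedFeatureSpec("cmp14", A, 1.6e4, 2.7, 528.2938, 10.90, pos),
        PlantedFeatureSpec("cmp15", D, 1.1e5, 0.35, 226.1205, 2.70, both),
    ]


def _lognormal_noise(rng: np.random.Generator, cv: float, shape) -> np.ndarray:
    """Unit-mean multiplicative log-normal noise with the given CV."""
    if cv == 0:
        return np.ones(shape)
    sigma = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(mean=-(sigma**2) / 2.0, sigma=sigma, size=shape)


def _sample_frame(mode: str) -> pd.DataFrame:
    rows = []
    for g in GENOTYPES:
        for t in TIME_POINTS:
            for r in REPLICATES:
                rows.append(
                    {
                        "sample_id": f"{mode[:3]}_{g}_{t}h_r{r}",
                        "genotype": g,
                        "time_h": t,
                        "replicate": r,
                        "ion_mode": mode,
                    }
                )
    return pd.DataFrame(rows).set_index("sample_id")


IS_FEATURE_ID = "IS_tebuconazole"


def generate_feature_table(
    design: SyntheticDesign,
    planted: Sequence[PlantedFeatureSpec],
    mode: str,
    rng: np.random.Generator,
) -> tuple[FeatureTable, pd.DataFrame]:
    """One ion mode's raw feature table plus its ground-truth record.

    Null features are flat log-normal noise with dropout; planted features
    follow their archetype trend; an internal-standard row sits at the fixed
    true level; every value is multiplied by its sample's injection factor.
    Returns (raw table, ground truth indexed by feature id).
    """
    if mode not in ION_MODES:
        raise ValueError(f"unknown ion mode {mode!r}")
    meta = _sample_frame(mode)
    n_samples = len(meta)
    injection = _lognormal_noise(rng, design.injection_cv, n_samples)
    n_null = int(design.n_null_features.get(mode, 0))

    base = 10.0 ** rng.normal(design.null_log10_mean, design.null_log10_sd, n_null)
    null_data = base[:, None] * _lognormal_noise(
        rng, design.null_cv, (n_null, n_samples)
    )
    drop = rng.random((n_null, n_samples)) < design.null_dropout
    null_data[drop] = np.nan
    null_mass = rng.uniform(*design.mass_range, n_null)
    null_rt = rng.uniform(*design.rt_range, n_null)

    specs = [s for s in planted if mode in s.modes]
    time_index = {t: k for k, t in enumerate(TIME_POINTS)}
    planted_rows = []
    for s in specs:
        levels = np.array(
            [
                s.expected_level(meta.loc[sid, "genotype"], time_index[meta.loc[sid, "time_h"]])
                for sid in meta.index
            ]
        )
        vals = levels * _lognormal_noise(rng, s.cv, n_samples)
        if s.dropout:
            vals[rng.random(n_samples) < s.dropout] = np.nan
        planted_rows.append(vals)
    planted_data = (
        np.vstack(planted_rows) if planted_rows else np.empty((0, n_samples))
    )

    data = np.vstack([null_data, planted_data])
    mass = np.concatenate([null_mass, [s.neutral_mass for s in specs]])
    rt = np.concatenate([null_rt, [s.rt for s in specs]])
    compound = [""] * n_null + [s.compound_id for s in specs]
    archetype = ["null"] * n_null + [s.archetype for s in specs]

    order = rng.permutation(len(data))
    prefix = "P" if mode == "positive" else "N"
    ids = [f"{prefix}{k + 1:05d}" for k in range(len(data))]
    data = data[order] * injection[None, :]

    is_row = np.full(n_samples, design.is_abundance) * injection
    frame = pd.DataFrame(
        np.vstack([data, is_row[None, :]]),
        index=ids + [IS_FEATURE_ID],
        columns=meta.index,
    )
    annotations = pd.DataFrame(
        {
            "ion_mode": mode,
            "neutral_mass": np.concatenate([mass[order], [307.1451]]),
            "rt_min": np.concatenate([rt[order], [8.2]]),
        },
        index=frame.index,
    )
    annotations.index.name = "feature_id"
    truth = pd.DataFrame(
        {
            "ion_mode": mode,
            "compound_id": [compound[i] for i in order] + [""],
            "archetype": [archetype[i] for i in order] + ["internal-standard"],
            "differential": [archetype[i] != "null" for i in order] + [False],
        },
        index=frame.index,
    )
    truth.index.name = "feature_id"
    return FeatureTable(frame, meta, annotations), truth


#: Relative intensities of generated ion species (arbitrary units).
DEFAULT_SPECIES_INTENSITY = {
    "M+H": 100.0,
    "M+Na": 60.0,
    "M+K": 35.0,
    "2M+Na": 15.0,
    "2M+K": 8.0,
    "fragment": 30.0,
}


def generate_spectrum(
    neutral: Formula,
    adducts: Sequence[str | AdductSpec] = ("M+H", "M+Na", "M+K"),
    fragments: Sequence[Formula] = (),
    rt: float = 10.0,
    rng: np.random.Generator | None = None,
    ppm_jitter: float = 0.0,
    base_intensity: float = 1.0e5,
    peak_width_min: float = 0.08,
    rt_window: float = 0.5,
    n_scans: int = 41,
    intensities: Mapping[str, float] | None = None,
) -> tuple[list[Spectrum], dict[str, float]]:
    """Synthesize co-eluting full-scan spectra for one compound.

    All species — adducts, dimers and in-source fragment cations — share a
    single Gaussian elution profile (same apex, same width) scaled by their
    relative intensities; each monoisotopic peak gets an (A+1) isotopologue
    satellite sized by :func:`pistilmet.chem.predict_a1_ratio`.  With zero
    ``ppm_jitter`` every m/z equals its theoretical value.  Returns the scan
    list and a map from species label to (possibly jittered) m/z.
    """
    rng = rng or np.random.default_rng(0)
    rel = dict(DEFAULT_SPECIES_INTENSITY)
    if intensities:
        rel.update(intensities)
    species: list[tuple[str, float, float, float]] = []  # label, mz, rel, a1%
    for ad in adducts:
        spec = ADDUCTS[ad] if isinstance(ad, str) else ad
        mz = ion_mz(neutral, spec)
        a1 = predict_a1_ratio(
            neutral + spec.added if spec.mult == 1 else neutral + neutral + spec.added
        )
        species.append((spec.name, mz, rel.get(spec.name, 50.0), a1))
    for frag in fragments:
        mz = even_electron_cation_mz(frag)
        species.append(
            (f"frag_{frag.hill()}", mz, rel["fragment"], predict_a1_ratio(frag))
        )
    out_mz: dict[str, float] = {}
    peaks: list[tuple[float, float, float]] = []  # mz, rel, a1
    for label, mz, intensity, a1 in species:
        if ppm_jitter:
            mz += mz * rng.normal(0.0, ppm_jitter) / 1e6
        out_mz[label] = mz
        peaks.append((mz, intensity, a1))
    times = np.linspace(rt - rt_window, rt + rt_window, n_scans)
    profile = np.exp(-0.5 * ((times - rt) / peak_width_min) ** 2)
    spectra = []
    for t, p in zip(times, profile):
        mzs, intens = [], []
        for mz, intensity, a1 in peaks:
            height = base_intensity * intensity / 100.0 * p
            mzs.extend([mz, mz + ISOTOPE_SPACING])
            intens.extend([height, height * a1 / 100.0])
        order = np.argsort(mzs)
        spectra.append(
            Spectrum(float(t), np.array(mzs)[order], np.array(intens)[order])
        )
    return spectra, out_mz


@dataclass
class SyntheticBundle:
    """A complete seeded study: tables, spectra, and ground truth."""

    seed: int
    design: SyntheticDesign
    planted: list[PlantedFeatureSpec]
    tables: dict[str, FeatureTable]
    ground_truth: pd.DataFrame
    spectra: dict[str, tuple[list[Spectrum], dict[str, float]]]

    def differential_compounds(self) -> set[str]:
        return {s.compound_id for s in self.planted if s.archetype != "null"}

    def compound_of(self, mode: str, feature_id: str) -> str:
        sub = self.ground_truth
        row = sub[(sub["ion_mode"] == mode) & (sub.index == feature_id)]
        return "" if row.empty else str(row["compound_id"].iloc[0])

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for mode, table in self.tables.items():
            table.to_csv(out / f"features_{mode}.csv")
            table.meta.reset_index().to_csv(out / f"samples_{mode}.csv", index=False)
        manifest = {
            "seed": self.seed,
            "planted": [
                {
                    "compound_id": s.compound_id,
                    "archetype": s.archetype,
                    "modes": list(s.modes),
                    "neutral_mass": s.neutral_mass,
                    "rt_min": s.rt,
                    "base_abundance": s.base_abundance,
                    "fold_per_time_step": s.fold_per_time_step,
                }
                for s in self.planted
            ],
            "features": {
                mode: {
                    fid: row["compound_id"]
                    for fid, row in self.ground_truth[
                        self.ground_truth["ion_mode"] == mode
                    ].iterrows()
                    if row["differential"]
                }
                for mode in self.tables
            },
        }
        (out / "ground_truth.json").write_text(json.dumps(manifest, indent=2))
        for name, (scans, mz_map) in self.spectra.items():
            with open(out / f"spectra_{name}.txt", "w") as fh:
                fh.write(f"# species: {json.dumps(mz_map)}\n")
                for s in scans:
                    fh.write(f"BEGIN SCAN rt={s.rt:.4f}\n")
                    for mz, inten in zip(s.mz, s.intensity):
                        fh.write(f"{mz:.6f}\t{inten:.3f}\n")
                    fh.write("END SCAN\n")


#: Spectra fixtures attached to a bundle: the macrolide-like compound with
#: its fragment series (cation formulae of the in-source fragments) and the
#: sphingoid-like compound with no usable fragments.
_SPECTRA_COMPOUNDS: dict[str, dict] = {
    "cmp04": {
        "neutral": "C27H48O11",
        "adducts": ("M+H", "M+Na", "M+K"),
        "fragments": ("C27H47O10+", "C17H33O3+", "C17H31O2+", "C16H29O2+", "C16H27O+", "C16H25+"),
        "rt": 10.07,
    },
    "cmp07": {
        "neutral": "C18H37NO3",
        "adducts": ("M+H", "M+Na"),
        "fragments": (),
        "rt": 9.53,
    },
}


def generate_study_bundle(
    seed: int,
    design: SyntheticDesign | None = None,
    planted: Sequence[PlantedFeatureSpec] | None = None,
    n_null_features: Mapping[str, int] | None = None,
    out_dir=None,
) -> SyntheticBundle:
    """Generate the full default bundle for a seed.

    Independent RNG streams are spawned deterministically from the bundle
    seed for the positive table, the negative table and the spectra, so each
    part can be regenerated on its own.  ``n_null_features`` overrides the
    design's per-mode null counts (e.g. for quick reduced-scale runs).
    """
    design = design or SyntheticDesign()
    if n_null_features is not None:
        design = replace(design, n_null_features=dict(n_null_features))
    planted = list(default_planted_features() if planted is None else planted)
    streams = np.random.SeedSequence(seed).spawn(3)
    rng_pos, rng_neg, rng_spec = (np.random.default_rng(s) for s in streams)
    tables: dict[str, FeatureTable] = {}
    truths = []
    for mode, rng in (("positive", rng_pos), ("negative", rng_neg)):
        table, truth = generate_feature_table(design, planted, mode, rng)
        tables[mode] = table
        truths.append(truth)
    spectra = {}
    for name, cfg in _SPECTRA_COMPOUNDS.items():
        spectra[name] = generate_spectrum(
            parse_formula(cfg["neutral"]),
            cfg["adducts"],
            [parse_formula(f) for f in cfg["fragments"]],
            rt=cfg["rt"],
            rng=rng_spec,
        )
    bundle = SyntheticBundle(
        seed, design, planted, tables, pd.concat(truths), spectra
    )
    if out_dir is not None:
        bundle.write(out_dir)
    return bundle


def evaluate_screen(report, bundle: SyntheticBundle) -> dict:
    """Compare a screen report's final set against the planted truth.

    Returns recovered/missed compound ids, false-discovery feature ids,
    sensitivity (recovered / planted) and the false-discovery count.
    """
    planted = bundle.differential_compounds()
    recovered: set[str] = set()
    false_ids: list[str] = []
    for mf in report.final:
        cids = {
            bundle.compound_of(mode, fid) for mode, fid in mf.feature_ids
        } - {""}
        if cids:
            recovered |= cids
        else:
            false_ids.append(mf.merged_id)
    return {
        "recovered": sorted(recovered),
        "missed": sorted(planted - recovered),
        "false_discoveries": false_ids,
        "sensitivity": len(recovered) / len(planted) if planted else float("nan"),
        "n_false": len(false_ids),
    }
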