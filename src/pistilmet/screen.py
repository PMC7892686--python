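"""Differential-feature screening of aligned LC-MS feature tables.

The screening workflow mirrors how untargeted pistil fingerprints are
reduced to a short list of differential compounds in a two-genotype
(self-compatible SC vs self-incompatible SI), four-time-point (0/3/24/96 h
after pollination), three-replicate design measured in positive and negative
ion mode:

1. discard features whose strongest raw signal never clears the intensity
   floor (low signal-to-noise);
2. normalize every sample to its internal-standard (tebuconazole) channel;
3. keep features detected in 100 % of the replicates of at least one
   genotype (frequency filter);
4. keep features whose replicate-mean trajectory over time is strictly
   monotone in at least one genotype;
5. keep features significant in a two-sample t-test between genotypes
   (p < 0.001, unadjusted, pooled-variance Student by default);
6. merge the surviving features of both ion modes by neutral mass and
   retention time.

Survivor sets are nested by construction, every exclusion is recorded, and
the final differential set is what downstream PCA ranking and formula
annotation consume.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GENOTYPES",
    "TIME_POINTS",
    "FeatureTable",
    "ScreenConfig",
    "ScreenReport",
    "MergedFeature",
    "read_feature_table",
    "normalize_to_is",
    "low_abundance_filter",
    "frequency_filter",
    "monotonic_filter",
    "ttest_screen",
    "merge_modes",
    "run_screen",
    "differential_matrix",
]

log = logging.getLogger(__name__)

GENOTYPES = ("SC", "SI")
TIME_POINTS = (0, 3, 24, 96)
REPLICATES = (1, 2, 3)
ION_MODES = ("positive", "negative")

#: Default raw-intensity floor (counts) below which a feature is not
#: considered reliably detected.
DEFAULT_MIN_ABUNDANCE = 5e3

META_COLUMNS = ["sample_id", "genotype", "time_h", "replicate", "ion_mode"]
ANNOTATION_COLUMNS = ["feature_id", "ion_mode", "neutral_mass", "rt_min"]


@dataclass
class FeatureTable:
    """Aligned feature abundances plus sample metadata for one ion mode.

    ``data`` is features x samples with NaN marking a missing (undetected)
    value — distinct from a measured zero; ``meta`` is indexed by sample id
    with genotype/time/replicate/mode labels; ``annotations`` is indexed by
    feature id with neutral mass (Da) and retention time (min).
    """

    data: pd.DataFrame
    meta: pd.DataFrame
    annotations: pd.DataFrame
    normalized: bool = False

    def __post_init__(self) -> None:
        if list(self.data.columns) != list(self.meta.index):
            raise ValueError("data columns must match metadata sample ids")
        if not self.data.index.equals(self.annotations.index):
            raise ValueError("data rows must match annotation feature ids")

    @property
    def ion_mode(self) -> str:
        modes = set(self.meta["ion_mode"])
        if len(modes) != 1:
            raise ValueError(f"mixed ion modes in one table: {modes}")
        return modes.pop()

    def subset(self, feature_ids: Sequence[str]) -> "FeatureTable":
        ids = [f for f in self.data.index if f in set(feature_ids)]
        return FeatureTable(
            self.data.loc[ids],
            self.meta,
            self.annotations.loc[ids],
            self.normalized,
        )

    def samples_of(self, genotype: str, time_h: int | None = None) -> list[str]:
        m = self.meta["genotype"] == genotype
        if time_h is not None:
            m &= self.meta["time_h"] == time_h
        return list(self.meta.index[m])

    def to_csv(self, path) -> None:
        out = self.annotations.join(self.data)
        out.insert(0, "feature_id", out.index)
        out.to_csv(path, index=False)


def _check_design(meta: pd.DataFrame) -> None:
    for mode in sorted(set(meta["ion_mode"])):
        sub = meta[meta["ion_mode"] == mode]
        have = set(zip(sub["genotype"], sub["time_h"], sub["replicate"]))
        expect = {
            (g, t, r) for g in GENOTYPES for t in TIME_POINTS for r in REPLICATES
        }
        missing = expect - have
        if missing:
            raise ValueError(
                f"incomplete design in {mode} mode; missing "
                f"(genotype, time_h, replicate): {sorted(missing)}"
            )
        if len(sub) != len(expect):
            dup = sub[sub.duplicated(["genotype", "time_h", "replicate"], keep=False)]
            raise ValueError(f"duplicate design cells: {list(dup.index)}")


def read_feature_table(path, meta_path, validate_design: bool = True) -> FeatureTable:
    """Read a feature-table CSV plus its sample-metadata CSV.

    Feature CSV schema: ``feature_id, ion_mode, neutral_mass, rt_min,
    <sample columns...>``; metadata schema: ``sample_id, genotype, time_h,
    replicate, ion_mode``.  Empty cells in sample columns are missing values.
    """
    meta = pd.read_csv(meta_path)
    missing_cols = set(META_COLUMNS) - set(meta.columns)
    if missing_cols:
        raise ValueError(f"{meta_path}: missing metadata columns {sorted(missing_cols)}")
    meta = meta.set_index("sample_id")
    raw = pd.read_csv(path)
    if raw.empty:
        raise ValueError(f"{path}: empty feature table")
    missing_cols = set(ANNOTATION_COLUMNS) - set(raw.columns)
    if missing_cols:
        raise ValueError(f"{path}: missing columns {sorted(missing_cols)}")
    if raw["feature_id"].duplicated().any():
        dup = raw.loc[raw["feature_id"].duplicated(), "feature_id"].tolist()
        raise ValueError(f"{path}: duplicate feature ids {dup}")
    raw = raw.set_index("feature_id")
    sample_cols = [c for c in raw.columns if c not in ANNOTATION_COLUMNS]
    absent = [s for s in meta.index if s not in sample_cols]
    if absent:
        cells = [
            tuple(meta.loc[s, ["genotype", "time_h", "replicate"]]) for s in absent
        ]
        raise ValueError(
            f"{path}: missing sample columns for (genotype, time_h, replicate) {cells}"
        )
    data = raw[list(meta.index)].apply(pd.to_numeric, errors="raise")
    if validate_design:
        _check_design(meta)
    if (data < 0).any().any():
        raise ValueError(f"{path}: negative abundances")
    return FeatureTable(data, meta, raw[ANNOTATION_COLUMNS[1:]].copy())


def normalize_to_is(table: FeatureTable, is_feature_id: str) -> FeatureTable:
    """Divide every sample by its internal-standard abundance.

    Removes per-sample injection/ionization scale, so any global rescaling of
    a sample (including its IS) cancels.  The IS row becomes identically 1.
    """
    if is_feature_id not in table.data.index:
        raise ValueError(f"internal standard {is_feature_id!r} not in table")
    is_row = table.data.loc[is_feature_id]
    bad = [s for s in table.data.columns if not is_row[s] > 0]
    if bad:
        raise ValueError(
            f"internal standard missing or non-positive in sample(s) {bad}"
        )
    return FeatureTable(
        table.data.div(is_row, axis=1), table.meta, table.annotations, normalized=True
    )


def low_abundance_filter(
    table: FeatureTable, min_abundance: float = DEFAULT_MIN_ABUNDANCE
) -> FeatureTable:
    """Drop features whose maximum raw abundance never reaches the floor."""
    if min_abundance < 0:
        raise ValueError("min_abundance must be non-negative")
    keep = table.data.max(axis=1, skipna=True) >= min_abundance
    return table.subset(list(table.data.index[keep]))


def presence_mask(
    table: FeatureTable, floor: float = 0.0
) -> pd.DataFrame:
    """Boolean detected-ness: non-missing and strictly above ``floor``.

    Zeros never count as detected.  For the frequency filter the floor is
    the raw low-abundance threshold, so "present" means reliably detected.
    """
    return table.data.notna() & (table.data > max(floor, 0.0))


def frequency_filter(
    table: FeatureTable, presence: pd.DataFrame | None = None
) -> tuple[FeatureTable, pd.DataFrame]:
    """Keep features present in 100 % of the replicates of some genotype.

    A feature qualifies through a genotype when it is present in all
    replicates of every time point of that genotype.  Returns the filtered
    table plus the per-feature qualification record (one boolean column per
    genotype).
    """
    if presence is None:
        presence = presence_mask(table)
    presence = presence.loc[table.data.index, table.data.columns]
    quals = pd.DataFrame(index=table.data.index)
    for g in GENOTYPES:
        quals[g] = presence[table.samples_of(g)].all(axis=1)
    keep = quals.any(axis=1)
    return table.subset(list(table.data.index[keep])), quals


def _time_means(table: FeatureTable, genotype: str) -> pd.DataFrame:
    cols = {}
    for t in TIME_POINTS:
        cols[t] = table.data[table.samples_of(genotype, t)].mean(axis=1)
    return pd.DataFrame(cols)


def monotonic_filter(table: FeatureTable) -> tuple[FeatureTable, pd.DataFrame]:
    """Keep features with a strictly monotone replicate-mean time course.

    Monotonicity is evaluated per genotype on the mean abundance over
    replicates at the ordered time points; either genotype qualifies a
    feature.  Strict inequality is required at every step (ties break
    monotonicity), and any time point with no usable replicate disqualifies
    the genotype.  Returns the filtered table and per-genotype direction
    labels (``increasing`` / ``decreasing`` / empty).
    """
    directions = pd.DataFrame(
        "", index=table.data.index, columns=list(GENOTYPES), dtype=object
    )
    for g in GENOTYPES:
        means = _time_means(table, g)
        diffs = means.diff(axis=1).iloc[:, 1:]
        ok = means.notna().all(axis=1)
        inc = ok & (diffs.gt(0).all(axis=1))
        dec = ok & (diffs.lt(0).all(axis=1))
        directions.loc[inc, g] = "increasing"
        directions.loc[dec, g] = "decreasing"
    keep = (directions != "").any(axis=1)
    kept = table.subset(list(table.data.index[keep]))
    return kept, directions.loc[kept.data.index]


def ttest_screen(
    table: FeatureTable,
    alpha: float = 0.001,
    contrast: str = "endpoint",
    log_transform: bool = True,
    equal_var: bool = True,
) -> tuple[FeatureTable, pd.Series, dict[str, str]]:
    """Two-sample t-test of SC vs SI abundance per feature.

    ``contrast`` selects the samples compared:

    * ``endpoint`` (default): the final time point only (3 vs 3), where the
      genotypes have diverged most — pooling all time points mixes the time
      trend into the within-group variance and caps the attainable
      significance for features that diverge progressively;
    * ``pooled``: all time points (12 vs 12);
    * ``per-time``: the smallest p over per-time-point contrasts (reported
      unadjusted; note the implied multiplicity).

    Abundances are log10-transformed by default (multiplicative noise), on
    which scale the replicate variances of the two genotypes are comparable;
    the pooled-variance Student test is therefore the default.  This matters
    at triplicate group sizes: the Welch–Satterthwaite correction can shrink
    the degrees of freedom towards 2, where the t quantile for p = 0.001 is
    31.6 and the nominal level is effectively unattainable regardless of
    effect size.  Set ``equal_var=False`` for Welch when group variances
    genuinely differ and groups are larger.

    Features with fewer than two usable values in either group are skipped
    with a recorded reason, not silently dropped as non-significant.
    Returns (survivors, p-values for all tested features, skipped reasons).
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if contrast not in ("endpoint", "pooled", "per-time"):
        raise ValueError(f"unknown contrast {contrast!r}")
    if contrast == "per-time":
        time_sets: list[int | None] = list(TIME_POINTS)
    elif contrast == "endpoint":
        time_sets = [TIME_POINTS[-1]]
    else:
        time_sets = [None]
    pvals: dict[str, float] = {}
    skipped: dict[str, str] = {}
    for fid in table.data.index:
        ps = []
        for t in time_sets:
            a = table.data.loc[fid, table.samples_of("SC", t)].to_numpy(float)
            b = table.data.loc[fid, table.samples_of("SI", t)].to_numpy(float)
            a, b = a[np.isfinite(a)], b[np.isfinite(b)]
            if log_transform:
                a, b = a[a > 0], b[b > 0]
                a, b = np.log10(a), np.log10(b)
            if len(a) < 2 or len(b) < 2:
                continue
            if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
                p = 1.0 if a.mean() == b.mean() else 0.0
                log.info("zero-variance groups for %s: p=%s", fid, p)
            else:
                p = float(stats.ttest_ind(a, b, equal_var=equal_var).pvalue)
            ps.append(p)
        if not ps:
            skipped[fid] = "fewer than 2 usable samples in a genotype group"
            continue
        pvals[fid] = min(ps)
    pseries = pd.Series(pvals, dtype=float)
    keep = list(pseries.index[pseries < alpha])
    return table.subset(keep), pseries, skipped


@dataclass(frozen=True)
class MergedFeature:
    """A differential entity after cross-mode merging."""

    merged_id: str
    mode: str  # mode whose profile is kept
    feature_ids: tuple[tuple[str, str], ...]  # (mode, feature_id)
    neutral_mass: float
    rt_min: float


def merge_modes(
    pos: FeatureTable | None,
    neg: FeatureTable | None,
    mass_tol_ppm: float = 10.0,
    rt_tol_min: float = 0.2,
) -> list[MergedFeature]:
    """Merge positive- and negative-mode survivors into unique entities.

    Features agreeing in neutral mass (within ``mass_tol_ppm``) and
    retention time (within ``rt_tol_min``) are one compound; the mode with
    the higher maximum abundance keeps the profile.  Candidate pairs are
    taken closest-mass-first, so a many-to-many ambiguity resolves to the
    closest pair and the remainder passes through unmerged (with a warning).
    """

    def records(table: FeatureTable, mode: str) -> list[dict]:
        return [
            {
                "mode": mode,
                "fid": fid,
                "mass": float(table.annotations.loc[fid, "neutral_mass"]),
                "rt": float(table.annotations.loc[fid, "rt_min"]),
                "peak": float(table.data.loc[fid].max(skipna=True)),
            }
            for fid in table.data.index
        ]

    pos_recs = records(pos, "positive") if pos is not None else []
    neg_recs = records(neg, "negative") if neg is not None else []
    pairs = []
    for i, pr in enumerate(pos_recs):
        for j, nr in enumerate(neg_recs):
            dm = abs(pr["mass"] - nr["mass"])
            if dm <= mass_tol_ppm * pr["mass"] / 1e6 and abs(pr["rt"] - nr["rt"]) <= rt_tol_min:
                pairs.append((dm, i, j))
    pairs.sort(key=lambda t: t[0])
    used_p: set[int] = set()
    used_n: set[int] = set()
    merged: list[MergedFeature] = []
    for dm, i, j in pairs:
        if i in used_p or j in used_n:
            log.warning(
                "ambiguous cross-mode match near mass %.4f; keeping closest pair",
                pos_recs[i]["mass"],
            )
            continue
        used_p.add(i)
        used_n.add(j)
        pr, nr = pos_recs[i], neg_recs[j]
        lead = pr if pr["peak"] >= nr["peak"] else nr
        merged.append(
            MergedFeature(
                merged_id=f"{pr['fid']}|{nr['fid']}",
                mode=lead["mode"],
                feature_ids=(("positive", pr["fid"]), ("negative", nr["fid"])),
                neutral_mass=lead["mass"],
                rt_min=lead["rt"],
            )
        )
    for recs, used in ((pos_recs, used_p), (neg_recs, used_n)):
        for k, r in enumerate(recs):
            if k not in used:
                merged.append(
                    MergedFeature(
                        merged_id=r["fid"],
                        mode=r["mode"],
                        feature_ids=((r["mode"], r["fid"]),),
                        neutral_mass=r["mass"],
                        rt_min=r["rt"],
                    )
                )
    merged.sort(key=lambda m: (m.rt_min, m.neutral_mass))
    return merged


@dataclass
class ScreenConfig:
    alpha: float = 0.001
    contrast: str = "endpoint"
    log_transform: bool = True
    equal_var: bool = True
    min_abundance: float = DEFAULT_MIN_ABUNDANCE
    is_feature_id: str = "IS_tebuconazole"
    merge_mass_ppm: float = 10.0
    merge_rt_min: float = 0.2


@dataclass
class ScreenReport:
    """Full provenance of one screening run."""

    stages: dict[str, dict[str, list[str]]]  # mode -> stage -> surviving ids
    pvalues: dict[str, pd.Series]
    directions: dict[str, pd.DataFrame]
    skipped: dict[str, dict[str, str]]
    final: list[MergedFeature]
    normalized: dict[str, FeatureTable] = field(default_factory=dict)

    def stage_sets(self, mode: str) -> list[tuple[str, set[str]]]:
        return [(k, set(v)) for k, v in self.stages[mode].items()]


_STAGE_ORDER = ["input", "low_abundance", "frequency", "monotonic", "ttest"]


def run_screen(
    tables: Mapping[str, FeatureTable], config: ScreenConfig | None = None
) -> ScreenReport:
    """Run the full per-mode screen and cross-mode merge.

    ``tables`` maps ion mode to a *raw* feature table containing the
    internal-standard feature.  Stage nesting (each stage's survivors are a
    subset of the previous stage's) is asserted before returning.
    """
    config = config or ScreenConfig()
    stages: dict[str, dict[str, list[str]]] = {}
    pvalues: dict[str, pd.Series] = {}
    directions: dict[str, pd.DataFrame] = {}
    skipped: dict[str, dict[str, str]] = {}
    survivors: dict[str, FeatureTable] = {}
    normalized_tables: dict[str, FeatureTable] = {}
    for mode, raw in tables.items():
        rec: dict[str, list[str]] = {"input": list(raw.data.index)}
        loud = low_abundance_filter(raw, config.min_abundance)
        rec["low_abundance"] = list(loud.data.index)
        norm = normalize_to_is(loud, config.is_feature_id)
        normalized_tables[mode] = norm
        presence = presence_mask(loud, config.min_abundance)
        freq, _ = frequency_filter(norm, presence)
        freq = freq.subset([f for f in freq.data.index if f != config.is_feature_id])
        rec["frequency"] = list(freq.data.index)
        mono, dirs = monotonic_filter(freq)
        rec["monotonic"] = list(mono.data.index)
        sig, pvals, skip = ttest_screen(
            mono, config.alpha, config.contrast, config.log_transform, config.equal_var
        )
        rec["ttest"] = list(sig.data.index)
        for a, b in zip(_STAGE_ORDER, _STAGE_ORDER[1:]):
            if not set(rec[b]) <= set(rec[a]):
                raise AssertionError(f"stage nesting violated: {b} not within {a}")
        stages[mode] = rec
        pvalues[mode] = pvals
        directions[mode] = dirs
        skipped[mode] = skip
        survivors[mode] = sig
    final = merge_modes(
        survivors.get("positive"),
        survivors.get("negative"),
        config.merge_mass_ppm,
        config.merge_rt_min,
    )
    return ScreenReport(stages, pvalues, directions, skipped, final, normalized_tables)


def differential_matrix(report: ScreenReport) -> pd.DataFrame:
    """Biological-samples x differential-compounds abundance matrix.

    Rows are keyed by (genotype, time, replicate) so that profiles taken
    from different ion modes align on the same biological samples; values
    are internal-standard-normalized abundances from each compound's leading
    mode.
    """
    cols = {}
    for mf in report.final:
        table = report.normalized[mf.mode]
        fid = dict(mf.feature_ids)[mf.mode]
        row = table.data.loc[fid]
        keyed = {
            (
                table.meta.loc[s, "genotype"],
                int(table.meta.loc[s, "time_h"]),
                int(table.meta.loc[s, "replicate"]),
            ): v
            for s, v in row.items()
        }
        cols[mf.merged_id] = keyed
    out = pd.DataFrame(cols)
    out.index.names = ["genotype", "time_h", "replicate"]
    return out.sort_index()
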