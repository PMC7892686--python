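"""Differential screen: normalization, filters, t-test, mode merging."""

import math

import numpy as np
import pandas as pd
import pytest

from pistilmet.screen import (
    GENOTYPES,
    TIME_POINTS,
    FeatureTable,
    ScreenConfig,
    frequency_filter,
    low_abundance_filter,
    merge_modes,
    monotonic_filter,
    normalize_to_is,
    presence_mask,
    read_feature_table,
    run_screen,
    ttest_screen,
)
from pistilmet.simulate import (
    IS_FEATURE_ID,
    PlantedFeatureSpec,
    SyntheticDesign,
    evaluate_screen,
    generate_feature_table,
    generate_study_bundle,
)


def make_table(rows: dict, mode="positive", masses=None, rts=None, normalized=False):
    """Small positive-mode table; rows maps feature id -> 24 values."""
    meta_rows = []
    for g in GENOTYPES:
        for t in TIME_POINTS:
            for r in (1, 2, 3):
                meta_rows.append(
                    {"sample_id": f"{g}_{t}_{r}", "genotype": g, "time_h": t,
                     "replicate": r, "ion_mode": mode}
                )
    meta = pd.DataFrame(meta_rows).set_index("sample_id")
    data = pd.DataFrame(rows, index=meta.index).T
    ann = pd.DataFrame(
        {
            "ion_mode": mode,
            "neutral_mass": masses or {f: 300.0 for f in rows},
            "rt_min": rts or {f: 5.0 for f in rows},
        },
        index=data.index,
    )
    return FeatureTable(data, meta, ann, normalized=normalized)


def design_values(sc, si):
    """24-vector from per-time levels [t0, t3, t24, t96] for each genotype."""
    out = []
    for levels in (sc, si):
        for lv in levels:
            out.extend([lv, lv, lv])
    return out


class TestIO:
    def test_bundle_roundtrip(self, bundle, tmp_path):
        table = bundle.tables["positive"]
        table.to_csv(tmp_path / "features_positive.csv")
        table.meta.reset_index().to_csv(tmp_path / "samples_positive.csv", index=False)
        back = read_feature_table(
            tmp_path / "features_positive.csv", tmp_path / "samples_positive.csv"
        )
        assert back.data.shape == table.data.shape
        pd.testing.assert_frame_equal(back.data, table.data, check_names=False)

    def test_missing_sample_column_reported(self, bundle, tmp_path):
        table = bundle.tables["positive"]
        out = table.annotations.join(table.data.drop(columns=["pos_SI_24h_r2"]))
        out.insert(0, "feature_id", out.index)
        out.to_csv(tmp_path / "features.csv", index=False)
        table.meta.reset_index().to_csv(tmp_path / "samples.csv", index=False)
        with pytest.raises(ValueError, match=r"SI.*24.*2"):
            read_feature_table(tmp_path / "features.csv", tmp_path / "samples.csv")

    def test_empty_file_rejected(self, tmp_path):
        (tmp_path / "empty.csv").write_text("feature_id,ion_mode,neutral_mass,rt_min\n")
        (tmp_path / "samples.csv").write_text(
            "sample_id,genotype,time_h,replicate,ion_mode\n"
        )
        with pytest.raises(ValueError):
            read_feature_table(tmp_path / "empty.csv", tmp_path / "samples.csv")

    def test_duplicate_feature_ids_rejected(self, tmp_path, bundle):
        table = bundle.tables["positive"]
        table.to_csv(tmp_path / "f.csv")
        text = (tmp_path / "f.csv").read_text().splitlines()
        text.append(text[1])
        (tmp_path / "f.csv").write_text("\n".join(text) + "\n")
        table.meta.reset_index().to_csv(tmp_path / "s.csv", index=False)
        with pytest.raises(ValueError, match="duplicate"):
            read_feature_table(tmp_path / "f.csv", tmp_path / "s.csv")


class TestNormalization:
    def _table(self):
        rows = {
            "F1": design_values([10, 10, 10, 10], [10, 20, 40, 80]),
            IS_FEATURE_ID: [5.0] * 24,
        }
        return make_table(rows)

    def test_is_row_becomes_one(self):
        norm = normalize_to_is(self._table(), IS_FEATURE_ID)
        assert (norm.data.loc[IS_FEATURE_ID] == 1.0).all()

    def test_global_sample_rescaling_cancels(self):
        t = self._table()
        scaled = t.data.copy()
        scaled.iloc[:, 3] *= 2.0  # whole sample, including the IS
        t2 = FeatureTable(scaled, t.meta, t.annotations)
        a = normalize_to_is(t, IS_FEATURE_ID).data
        b = normalize_to_is(t2, IS_FEATURE_ID).data
        pd.testing.assert_frame_equal(a, b)

    def test_missing_is_named_in_error(self):
        t = self._table()
        broken = t.data.copy()
        broken.loc[IS_FEATURE_ID, broken.columns[5]] = 0.0
        with pytest.raises(ValueError, match=str(broken.columns[5])):
            normalize_to_is(
                FeatureTable(broken, t.meta, t.annotations), IS_FEATURE_ID
            )

    def test_injection_factors_removed_from_planted_truth(self):
        # noise-free planted features measured through noisy injection come
        # back at exactly their expected relative levels after normalization
        design = SyntheticDesign(
            n_null_features={"positive": 0}, injection_cv=0.3, null_cv=0.0
        )
        spec = PlantedFeatureSpec(
            "c", "si-accumulating", 1e4, 2.0, 300.0, 5.0, cv=0.0
        )
        rng = np.random.default_rng(0)
        table, truth = generate_feature_table(design, [spec], "positive", rng)
        norm = normalize_to_is(table, IS_FEATURE_ID)
        fid = truth.index[truth["compound_id"] == "c"][0]
        got = norm.data.loc[fid] * design.is_abundance
        expected = [
            spec.expected_level(norm.meta.loc[s, "genotype"],
                                TIME_POINTS.index(norm.meta.loc[s, "time_h"]))
            for s in norm.data.columns
        ]
        assert np.allclose(got, expected)


class TestFilters:
    def test_low_abundance_threshold(self):
        rows = {
            "dim": [4e3] * 24,
            "bright": [1e6] * 24,
            IS_FEATURE_ID: [1e5] * 24,
        }
        t = make_table(rows)
        kept = low_abundance_filter(t, 5e3)
        assert list(kept.data.index) == ["bright", IS_FEATURE_ID]

    def test_frequency_requires_complete_genotype(self):
        complete = [10.0] * 24
        gapped = [10.0] * 24
        gapped[design_index("SI", 24, 2)] = np.nan
        t = make_table({"full": complete, "gap": gapped})
        kept, quals = frequency_filter(t)
        assert list(kept.data.index) == ["full", "gap"]  # gap complete in SC
        assert quals.loc["gap", "SC"] and not quals.loc["gap", "SI"]
        both_gapped = list(gapped)
        both_gapped[design_index("SC", 3, 1)] = np.nan
        t2 = make_table({"bad": both_gapped})
        kept2, _ = frequency_filter(t2)
        assert list(kept2.data.index) == []

    def test_frequency_survivors_match_recount_oracle(self, bundle):
        table = bundle.tables["positive"]
        presence = presence_mask(table, 5e3)
        kept, _ = frequency_filter(table, presence)
        expect = 0
        for fid in table.data.index:
            ok = False
            for g in GENOTYPES:
                cells = [
                    presence.loc[fid, s]
                    for s in table.data.columns
                    if table.meta.loc[s, "genotype"] == g
                ]
                ok = ok or all(cells)
            expect += ok
        assert len(kept.data) == expect

    def test_monotonic_strictness_and_direction(self):
        rows = {
            "up": design_values([1, 1, 1, 1], [1, 2, 4, 8]),
            "tie": design_values([5, 5, 6, 7], [5, 5, 6, 7]),
            "down_si": design_values([7, 7, 7, 7], [8, 4, 2, 1]),
        }
        t = make_table(rows, normalized=True)
        kept, directions = monotonic_filter(t)
        assert sorted(kept.data.index) == ["down_si", "up"]
        assert directions.loc["up", "SI"] == "increasing"
        assert directions.loc["down_si", "SI"] == "decreasing"
        assert directions.loc["down_si", "SC"] == ""

    def test_monotonic_invariant_under_increasing_transform(self):
        rows = {"up": design_values([1, 1, 1, 1], [1, 2, 4, 8])}
        t1 = make_table(rows)
        t2 = make_table({"up": [math.exp(v) for v in rows["up"]]})
        k1, _ = monotonic_filter(t1)
        k2, _ = monotonic_filter(t2)
        assert list(k1.data.index) == list(k2.data.index) == ["up"]


def design_index(genotype, time_h, replicate):
    g = GENOTYPES.index(genotype)
    t = TIME_POINTS.index(time_h)
    return g * 12 + t * 3 + (replicate - 1)


class TestTTest:
    def test_matches_textbook_student_formula(self):
        a = np.array([1.2, 1.5, 1.1])
        b = np.array([2.9, 3.4, 3.1])
        vals = design_values([1, 1, 1, 1], [1, 1, 1, 1])
        for i, v in enumerate(a):
            vals[design_index("SC", 96, i + 1)] = 10.0**v
        for i, v in enumerate(b):
            vals[design_index("SI", 96, i + 1)] = 10.0**v
        t = make_table({"f": vals}, normalized=True)
        _, pvals, _ = ttest_screen(t, contrast="endpoint", log_transform=True)
        sp2 = ((a.var(ddof=1) + b.var(ddof=1)) / 2.0)
        tstat = (a.mean() - b.mean()) / math.sqrt(sp2 * (2.0 / 3.0))
        from scipy.stats import t as tdist

        expected = 2.0 * tdist.sf(abs(tstat), 4)
        assert pvals["f"] == pytest.approx(expected, abs=1e-12)

    def test_identical_groups_not_significant(self):
        t = make_table({"flat": [7.0] * 24}, normalized=True)
        kept, pvals, _ = ttest_screen(t)
        assert pvals["flat"] == 1.0
        assert list(kept.data.index) == []

    def test_large_planted_effect_detected(self):
        rng = np.random.default_rng(42)
        si = 16.0 * np.exp(rng.normal(0, 0.1, 12))
        sc = 1.0 * np.exp(rng.normal(0, 0.1, 12))
        vals = list(sc) + list(si)
        t = make_table({"hit": vals}, normalized=True)
        kept, pvals, _ = ttest_screen(t)
        assert pvals["hit"] < 1e-3
        assert list(kept.data.index) == ["hit"]

    def test_insufficient_samples_skipped_with_reason(self):
        vals = design_values([1, 1, 1, 1], [2, 2, 2, 2])
        for r in (1, 2):
            vals[design_index("SC", 96, r)] = np.nan
        t = make_table({"thin": vals}, normalized=True)
        kept, pvals, skipped = ttest_screen(t, contrast="endpoint")
        assert "thin" in skipped
        assert "thin" not in pvals.index


class TestMergeModes:
    def _mode_table(self, mode, rows, masses, rts):
        return make_table(rows, mode=mode, masses=masses, rts=rts, normalized=True)

    def test_same_compound_merges_across_modes(self):
        pos = self._mode_table("positive", {"P1": [10.0] * 24}, {"P1": 548.3198},
                               {"P1": 10.07})
        neg = self._mode_table("negative", {"N1": [5.0] * 24}, {"N1": 548.3199},
                               {"N1": 10.10})
        merged = merge_modes(pos, neg)
        assert len(merged) == 1
        assert merged[0].feature_ids == (("positive", "P1"), ("negative", "N1"))
        assert merged[0].mode == "positive"  # higher abundance wins

    def test_disjoint_masses_concatenate(self):
        pos = self._mode_table("positive", {"P1": [10.0] * 24}, {"P1": 300.0}, {"P1": 5.0})
        neg = self._mode_table("negative", {"N1": [5.0] * 24}, {"N1": 400.0}, {"N1": 5.0})
        merged = merge_modes(pos, neg)
        assert {m.merged_id for m in merged} == {"P1", "N1"}

    def test_ambiguous_match_resolves_to_closest(self):
        pos = self._mode_table(
            "positive",
            {"Pa": [10.0] * 24, "Pb": [10.0] * 24},
            {"Pa": 500.0000, "Pb": 500.0010},
            {"Pa": 5.0, "Pb": 5.0},
        )
        neg = self._mode_table("negative", {"N1": [5.0] * 24}, {"N1": 500.0002},
                               {"N1": 5.0})
        merged = merge_modes(pos, neg)
        pair = [m for m in merged if len(m.feature_ids) == 2]
        assert len(pair) == 1
        assert dict(pair[0].feature_ids)["positive"] == "Pa"
        assert {m.merged_id for m in merged if len(m.feature_ids) == 1} == {"Pb"}


class TestRunScreen:
    def test_stage_nesting(self, screen_report):
        for mode in ("positive", "negative"):
            stages = screen_report.stages[mode]
            order = ["input", "low_abundance", "frequency", "monotonic", "ttest"]
            for a, b in zip(order, order[1:]):
                assert set(stages[b]) <= set(stages[a])

    def test_final_set_invariant_under_sample_rescaling(self, bundle, screen_report):
        tables = {}
        for mode, t in bundle.tables.items():
            scaled = t.data.copy()
            scaled.iloc[:, 7] *= 3.0  # rescale one sample wholesale, IS included
            tables[mode] = FeatureTable(scaled, t.meta, t.annotations)
        report2 = run_screen(tables)
        assert {m.merged_id for m in report2.final} == {
            m.merged_id for m in screen_report.final
        }

    def test_recovers_planted_truth(self, bundle, screen_report):
        ev = evaluate_screen(screen_report, bundle)
        assert ev["sensitivity"] == 1.0
        assert ev["n_false"] == 0
        assert ev["missed"] == []

    def test_internal_standard_alone_yields_empty_set(self):
        rows = {IS_FEATURE_ID: [1e5] * 24}
        report = run_screen({"positive": make_table(rows)})
        assert report.final == []

    def test_null_only_bundle_usually_empty(self):
        empty = 0
        n_seeds = 20
        for seed in range(n_seeds):
            b = generate_study_bundle(
                seed, planted=[], n_null_features={"positive": 100, "negative": 50}
            )
            if not run_screen(b.tables).final:
                empty += 1
        assert empty >= n_seeds - 2
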