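"""Synthetic cohort generator: structure, determinism, clinical calibration."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.ndimage import median_filter

import scrsdx as sx
from scrsdx.simulate import _stratified_scores


class TestCohortStructure:
    def test_default_group_sizes(self):
        cohort = sx.generate_cohort(sx.default_config(seed=1), include_spectra=False)
        man = cohort.manifest()
        counts = man["group"].value_counts().to_dict()
        assert counts == {"HC": 16, "MildME": 25, "ModME": 15, "SevME": 21, "MS": 21}
        assert len(cohort.subjects) == 98

    def test_empty_cohort(self):
        cfg = sx.default_config(seed=0, group_sizes={g: 0 for g in sx.GROUPS})
        cohort = sx.generate_cohort(cfg)
        assert cohort.subjects == [] and cohort.spectra == []

    def test_seed_determinism(self, small_config, small_cohort):
        twin = sx.generate_cohort(small_config)
        assert twin.manifest().equals(small_cohort.manifest())
        assert twin.symptom_table.data.equals(small_cohort.symptom_table.data)
        for a, b in zip(small_cohort.spectra, twin.spectra):
            assert a.key == b.key
            assert np.array_equal(a.intensities, b.intensities)

    def test_every_spectrum_has_a_subject(self, small_cohort):
        ids = {s.subject_id for s in small_cohort.subjects}
        assert all(sp.subject_id in ids for sp in small_cohort.spectra)

    def test_acquisitions_per_cell_within_range(self, small_cohort, small_config):
        lo, hi = small_config.acquisitions_per_cell
        counts = pd.Series([sp.cell_id for sp in small_cohort.spectra]).value_counts()
        assert counts.min() >= lo and counts.max() <= hi

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            sx.generate_cohort(sx.default_config(group_sizes={"Nope": 3}))
        with pytest.raises(ValueError):
            sx.generate_cohort(sx.default_config(axis_spec=(3401, 319, 100)))
        with pytest.raises(ValueError):
            sx.generate_cohort(sx.default_config(missing_rate=1.5))


class TestClinicalScores:
    def test_printed_fss_medians_and_ranges(self):
        man = sx.generate_cohort(sx.default_config(seed=3), include_spectra=False).manifest()
        me = man[man["group"].isin(["MildME", "ModME", "SevME"])]["fss"]
        ms = man[man["group"] == "MS"]["fss"]
        hc = man[man["group"] == "HC"]["fss"]
        assert me.median() == 59 and me.min() >= 44 and me.max() <= 63
        assert ms.median() == 54 and ms.min() >= 16 and ms.max() <= 63
        assert hc.median() == 17 and hc.min() >= 11 and hc.max() <= 37

    def test_sf36_pf_severity_definition(self):
        man = sx.generate_cohort(sx.default_config(seed=4), include_spectra=False).manifest()
        assert (man.loc[man["group"] == "MildME", "sf36_pf"] > 25).all()
        assert (man.loc[man["group"] == "ModME", "sf36_pf"] < 25).all()
        assert (man.loc[man["group"] == "SevME", "sf36_pf"] < 25).all()
        assert (man.loc[man["group"].isin(["HC", "MS"]), "sf36_pf"] >= 25).all()

    def test_collapsed_range_gives_constant_scores(self):
        rng = np.random.default_rng(0)
        assert set(_stratified_scores(9, 50, 50, 50, rng)) == {50}

    @pytest.mark.parametrize("n,med,lo,hi", [(61, 59, 44, 63), (21, 54, 16, 63), (16, 17, 11, 37), (7, 30, 10, 40)])
    def test_stratified_scores_hit_the_median_exactly(self, n, med, lo, hi):
        s = _stratified_scores(n, med, lo, hi, np.random.default_rng(1))
        assert len(s) == n
        assert np.median(s) == med
        assert s.min() >= lo and s.max() <= hi


class TestSymptomTable:
    def test_default_63_variables_ordinal_values(self, small_cohort):
        table = small_cohort.symptom_table
        assert table.data.shape[1] == 63
        vals = table.data.to_numpy().ravel()
        vals = vals[~np.isnan(vals)]
        assert set(np.unique(vals)) <= {0.0, 1.0, 2.0, 3.0}

    def test_zero_missing_rate(self):
        cfg = sx.default_config(seed=5, group_sizes={g: 2 for g in sx.GROUPS},
                                cells_per_subject=0, missing_rate=0.0)
        cohort = sx.generate_cohort(cfg)
        assert not cohort.symptom_table.data.isna().any().any()

    def test_severity_gradient(self):
        cohort = sx.generate_cohort(sx.default_config(seed=6), include_spectra=False)
        t = cohort.symptom_table
        means = {g: np.nanmean(t.group_rows(g).to_numpy()) for g in sx.GROUPS}
        assert means["HC"] < means["MildME"] < means["ModME"] < means["SevME"]

    def test_equal_propensities_select_nothing(self):
        from scrsdx.clinical import select_symptoms
        cfg = sx.default_config(
            seed=7, group_sizes={"SevME": 400, "MS": 400}, cells_per_subject=0,
            symptom_multipliers={g: 0.5 for g in sx.GROUPS},
            ms_symptom_tilt=1.0, missing_rate=0.0,
        )
        cohort = sx.generate_cohort(cfg)
        sel = select_symptoms(cohort.symptom_table)
        assert sel["included"].mean() < 0.05


class TestSpectraGeneration:
    def test_spike_free_cohort_triggers_no_spike_detections(self):
        """Scan oracle: with spike probability 0 the cosmic-ray detector
        finds nothing beyond occasional noise-level touch-ups (a genuine
        spike is >= 50x the noise scale and would change its channel by
        that much)."""
        cfg = sx.default_config(seed=8, group_sizes={"HC": 2, "MS": 2},
                                cells_per_subject=3, acquisitions_per_cell=(3, 4),
                                spike_probability=0.0)
        cohort = sx.generate_cohort(cfg)
        n_changed = 0
        for sp in cohort.spectra:
            cleaned = sx.despike(sp)
            delta = np.abs(cleaned.intensities - sp.intensities)
            assert delta.max() < 10 * cfg.noise_sd
            n_changed += int((delta > 0).sum())
        total = len(cohort.spectra) * cfg.axis().n_channels
        assert n_changed / total < 1e-3

    def test_spiked_cohort_triggers_detections(self):
        cfg = sx.default_config(seed=8, group_sizes={"HC": 2, "MS": 2},
                                cells_per_subject=3, acquisitions_per_cell=(3, 4),
                                spike_probability=0.5)
        cohort = sx.generate_cohort(cfg)
        big_changes = sum(
            int(np.max(np.abs(sx.despike(sp).intensities - sp.intensities))
                > 20 * cfg.noise_sd)
            for sp in cohort.spectra
        )
        assert big_changes >= 0.3 * 0.5 * len(cohort.spectra)

    def test_band_center_outside_axis_errors(self):
        cfg = sx.default_config(seed=0, group_sizes={"HC": 1},
                                cells_per_subject=1, axis_spec=(319.0, 900.0, 200))
        with pytest.raises(ValueError):
            sx.generate_cohort(cfg)

    def test_effects_off_group_means_match(self):
        """With effects disabled the per-channel Welch rejection rate across
        channels stays near the nominal alpha = 0.01."""
        common = dict(group_sizes={"HC": 5, "SevME": 5}, cells_per_subject=30,
                      acquisitions_per_cell=(1, 1), effect_table={},
                      spike_probability=0.0)
        cohort = sx.generate_cohort(sx.default_config(seed=9, **common))
        cells, _ = sx.run_preprocess(cohort.spectra)
        groups = cohort.groups_by_subject()
        X = np.vstack([c.intensities for c in cells])
        lab = np.array([groups[c.subject_id] for c in cells])
        res = stats.ttest_ind(X[lab == "HC"], X[lab == "SevME"], equal_var=False, axis=0)
        assert np.mean(res.pvalue < 0.01) < 0.03


class TestMixtureClasses:
    def test_shapes_and_determinism(self):
        X, y = sx.make_mixture_classes(seed=3)
        X2, y2 = sx.make_mixture_classes(seed=3)
        assert X.shape == (400, 12) and len(y) == 400
        assert np.array_equal(X, X2) and np.array_equal(y, y2)
        assert set(np.bincount(y)) == {80}

    def test_not_linearly_separable_but_learnable(self):
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
        from sklearn.ensemble import RandomForestClassifier
        from sklearn.model_selection import cross_val_score
        X, y = sx.make_mixture_classes(seed=4)
        lin = cross_val_score(LinearDiscriminantAnalysis(), X, y, cv=3).mean()
        rf = cross_val_score(RandomForestClassifier(100, random_state=0), X, y, cv=3).mean()
        assert rf > lin + 0.1
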