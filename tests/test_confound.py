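"""Iterative diet-confounder filtering with the model-collapse stopping rule."""

import numpy as np
import pytest

from breedlip import (BootstrapScheme, bin_mz, filter_confounder, generate,
                      metaclass_labels, pc_lda, rank_features)
from breedlip.matrix import bin_map

from conftest import small_config, tiny_matrix

SCHEME = BootstrapScheme(n_bootstraps=6, ntree=80, seed=9)


def setup_cohort(seed=21, **overrides):
    cfg = small_config(seed=seed, effect_log2fc=2.0, **overrides)
    matrix, meta, truth = generate(cfg)
    binned = bin_mz(matrix)
    logm = binned.log2()
    nm = bin_map(matrix, binned)
    labels = metaclass_labels(meta, cfg.group1, (cfg.mixed_diet_breed,))
    mask = np.array([l is not None for l in labels])
    sub = logm.subset_samples([s for s, m in zip(logm.sample_ids, mask) if m])
    ranked = rank_features(sub, labels[mask], SCHEME,
                           classes=("group2", "group1"))
    return cfg, logm, labels, ranked, truth, nm


class TestFilterMechanics:
    def test_empty_schedule_identity(self, rng):
        m = tiny_matrix(rng.uniform(1, 10, size=(12, 20)))
        labels = ["g1", "g2"] * 6
        ranked = rank_features(m, labels, SCHEME)
        out, report = filter_confounder(m, labels, ranked, schedule=[],
                                        scheme=SCHEME)
        assert out.feature_names == m.feature_names
        assert report.cutoff_trajectory == []
        assert not report.collapsed
        assert report.n_before == report.n_after == 20

    def test_schedule_must_decrease(self, rng):
        m = tiny_matrix(rng.uniform(1, 10, size=(12, 10)))
        labels = ["g1", "g2"] * 6
        ranked = rank_features(m, labels, SCHEME)
        with pytest.raises(ValueError, match="decreasing"):
            filter_confounder(m, labels, ranked, schedule=[0.001, 0.01],
                              scheme=SCHEME)
        with pytest.raises(ValueError, match="positive"):
            filter_confounder(m, labels, ranked, schedule=[0.01, -1.0],
                              scheme=SCHEME)

    def test_removal_sets_monotone_in_cutoff(self):
        _, logm, labels, ranked, _, _ = setup_cohort()
        sets = []
        for cutoff in (0.01, 0.003, 0.001):
            _, report = filter_confounder(logm, labels, ranked,
                                          schedule=[cutoff], scheme=SCHEME)
            sets.append(set(report.removed_features))
        assert sets[0] <= sets[1] <= sets[2]

    def test_filtered_matrix_is_column_subset(self):
        _, logm, labels, ranked, _, _ = setup_cohort()
        out, report = filter_confounder(logm, labels, ranked, scheme=SCHEME)
        assert set(out.feature_names) <= set(logm.feature_names)
        assert report.n_after == out.n_features
        assert report.n_before - report.n_after == len(report.removed_features)
        # intensities untouched for surviving features
        np.testing.assert_array_equal(
            out.values(), logm.subset_features(out.feature_names).values())

    def test_trajectory_records_strictly_decreasing_cutoffs(self):
        _, logm, labels, ranked, _, _ = setup_cohort()
        _, report = filter_confounder(logm, labels, ranked, scheme=SCHEME)
        cuts = [s.rfis_cutoff for s in report.cutoff_trajectory]
        assert all(a > b for a, b in zip(cuts, cuts[1:]))


class TestFilterRecovery:
    def test_diet_removed_unique_retained(self):
        _, logm, labels, ranked, truth, nm = setup_cohort(seed=22)
        out, report = filter_confounder(logm, labels, ranked, scheme=SCHEME)
        removed = set(report.removed_features)
        diet = {nm[n] for n in truth.diet_features if n in nm}
        uniq = {nm[n] for b in truth.unique_features.values() for n in b
                if n in nm}
        assert len(diet & removed) / len(diet) >= 0.8
        assert len(uniq & removed) / len(uniq) <= 0.2

    def test_diet_only_cohort_collapses_with_diet_removed(self):
        # no breed effects beyond diet: after filtering, the meta-class
        # model must be collapsed and nearly all diet features gone
        _, logm, labels, ranked, truth, nm = setup_cohort(
            seed=26, n_metaclass1_features=0, n_metaclass2_features=0,
            n_shared_features=0,
            unique_plan=(("Ch", 0, "decreased"),))
        _, report = filter_confounder(logm, labels, ranked, scheme=SCHEME)
        assert report.collapsed
        assert report.cutoff_trajectory[-1].metaclass_margin <= 0.2
        removed = set(report.removed_features)
        diet = {nm[n] for n in truth.diet_features if n in nm}
        assert len(diet & removed) / len(diet) >= 0.9

    def test_collapse_reached_with_default_schedule(self):
        _, logm, labels, ranked, _, _ = setup_cohort(seed=23)
        _, report = filter_confounder(logm, labels, ranked, scheme=SCHEME)
        assert report.collapsed
        assert report.cutoff_trajectory[-1].metaclass_margin <= 0.2

    def test_post_filter_axis_shifts_to_second_metaclass(self):
        # after removing diet-confounded signals, the second meta-class
        # grouping should dominate the discriminant structure
        cfg, logm, labels, ranked, truth, nm = setup_cohort(seed=24)
        out, _ = filter_confounder(logm, labels, ranked, scheme=SCHEME)
        import pandas as pd
        breeds = [s[:2] for s in out.sample_ids]
        mc1 = ["g1" if b in cfg.group1 else "g2" for b in breeds]
        mc2 = ["g1" if b in cfg.metaclass2 else "g2" for b in breeds]
        tw_mc1 = pc_lda(out, mc1).tw[0]
        tw_mc2 = pc_lda(out, mc2).tw[0]
        assert tw_mc2 > tw_mc1

    def test_no_collapse_warns_and_returns_last(self, rng, caplog):
        # pure-noise labels: model starts collapsed... use planted matrix and
        # a schedule too high to remove anything so the model never collapses
        _, logm, labels, ranked, _, _ = setup_cohort(seed=25)
        with caplog.at_level("WARNING"):
            out, report = filter_confounder(logm, labels, ranked,
                                            schedule=[10.0, 5.0],
                                            scheme=SCHEME)
        assert not report.collapsed
        assert out.n_features == logm.n_features
        assert "without collapse" in caplog.text
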