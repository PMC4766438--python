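import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

import odorfusion as of
from odorfusion.merge import (
    EXCL_MD_CAP,
    EXCL_TOO_FEW,
    MergeExclusion,
    best_fit_md,
)

K = of.synthetic_inchikey
SQRT2 = np.sqrt(2.0)


def profile(values, start=0):
    values = np.asarray(values, dtype=float)
    return pd.Series(values, index=[K(i + start) for i in range(len(values))])


class TestMergePair:
    def test_identical_profiles_merge_to_themselves(self):
        a = profile(np.linspace(0, 1, 8))
        merged, fit = of.merge_pair(a, a.copy())
        assert fit.md == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(merged.sort_index(), a.sort_index(), atol=1e-9)

    def test_four_common_odorants_is_too_few(self):
        a = profile([0, 0.25, 0.5, 0.75, 1.0])
        b = profile([0, 0.25, 0.5, 0.75, 1.0], start=1)  # shares 4 keys
        with pytest.raises(MergeExclusion) as exc:
            of.merge_pair(a, b)
        assert exc.value.reason == EXCL_TOO_FEW

    def test_scrambled_relation_exceeds_md_cap(self):
        rng = np.random.default_rng(5)
        a = profile(np.linspace(0, 1, 20))
        b = pd.Series(rng.permutation(a.to_numpy()), index=a.index)
        assert best_fit_md(a, b, of.MergeConfig()).md > 0.1 * SQRT2
        with pytest.raises(MergeExclusion) as exc:
            of.merge_pair(a, b)
        assert exc.value.reason == EXCL_MD_CAP

    def test_union_coverage_and_unit_interval(self):
        rng = np.random.default_rng(1)
        truth = np.sort(rng.uniform(0, 1, 12))
        a = profile(truth[:9])  # odorants 0..8
        b = pd.Series(truth[3:] ** 1.5, index=[K(i) for i in range(3, 12)])
        merged, _ = of.merge_pair(a, b)
        assert set(merged.index) == {K(i) for i in range(12)}
        assert merged.min() == pytest.approx(0.0) and merged.max() == pytest.approx(1.0)

    def test_symmetry_in_ranks(self):
        rng = np.random.default_rng(2)
        x = np.sort(rng.uniform(0, 1, 10))
        a = profile(x)
        b = pd.Series(1 - np.exp(-2 * x), index=a.index)
        b = (b - b.min()) / (b.max() - b.min())
        ab, _ = of.merge_pair(a, b)
        ba, _ = of.merge_pair(b, a)
        assert spearmanr(ab, ba[ab.index]).statistic == pytest.approx(1.0)

    def test_noiseless_monotone_map_preserves_ranks_exactly(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(0, 1, 15)
        x = (x - x.min()) / (x.max() - x.min())
        a = profile(x)
        b = 0.1 + 0.8 * a  # strictly monotone (linear) distortion
        merged, fit = of.merge_pair(a, b)
        assert fit.md == pytest.approx(0.0, abs=1e-8)
        assert (
            merged[a.index].rank().to_numpy() == a.rank().to_numpy()
        ).all()


class TestSelectMergeOrder:
    def test_identical_datasets_tie_to_first_permutation(self):
        a = profile(np.linspace(0, 1, 8))
        profiles = {"s1": a, "s2": a.copy(), "s3": a.copy()}
        plan = of.select_merge_order(profiles, of.MergeConfig(strategy="exhaustive"))
        assert plan.order == ("s1", "s2", "s3")
        assert plan.score == pytest.approx(0.0, abs=1e-9)

    def test_single_dataset_trivial_plan(self):
        plan = of.select_merge_order({"only": profile(np.linspace(0, 1, 6))})
        assert plan.order == ("only",) and plan.strategy == "trivial"

    def test_exhaustive_not_worse_than_greedy(self):
        cfg = of.SimulationConfig(seed=21, n_studies=4, n_odorants=30)
        truth = of.simulate_ground_truth(cfg)
        datasets, _ = of.simulate_studies(truth, cfg)
        profiles = {ds.study_id: ds.scaled() for ds in datasets}
        ex = of.select_merge_order(profiles, of.MergeConfig(strategy="exhaustive"))
        greedy_plan = of.select_merge_order(profiles, of.MergeConfig(strategy="greedy"))
        # score the greedy outcome the same way the exhaustive search scores
        from odorfusion.merge import _avg_md_against_inputs, merge_pair

        working = dict(profiles)
        for left, right in greedy_plan.steps:
            merged, _ = merge_pair(working[left], working[right], of.MergeConfig())
            del working[left], working[right]
            working[f"({left}+{right})"] = merged
        final = working[max(working, key=len)]
        greedy_score = _avg_md_against_inputs(final, profiles, of.MergeConfig())
        assert ex.score <= greedy_score + 1e-12

    def test_auto_switches_on_permutation_cap(self):
        a = profile(np.linspace(0, 1, 8))
        profiles = {f"s{i}": a.copy() for i in range(4)}
        plan = of.select_merge_order(
            profiles, of.MergeConfig(strategy="auto", permutation_cap=6)
        )
        assert plan.strategy == "greedy"  # 4! = 24 > 6


class TestMergeUnit:
    def test_single_dataset_consensus_is_rescaled_copy(self):
        ds = of.StudyDataset(
            study_id="s1", unit_id="u", responses=profile([2.0, 5.0, 8.0]),
            sfr_reported=False,
        )
        # note: constructing with sfr_reported False forces SFR=0
        ds.responses[of.SFR_KEY] = 0.0
        cons = of.merge_unit([ds])
        assert cons.included_studies == ["s1"]
        assert cons.values.drop(of.SFR_KEY).min() >= 0.0
        assert cons.values.max() == pytest.approx(1.0)
        assert cons.merge_log == []

    def test_disjoint_datasets_keep_largest(self):
        d1 = of.StudyDataset("s1", "u", profile(np.linspace(0, 1, 10)))
        d2 = of.StudyDataset("s2", "u", profile(np.linspace(0, 1, 6), start=20))
        cons = of.merge_unit([d1, d2])
        assert cons.included_studies == ["s1"]
        assert cons.excluded_studies == [("s2", EXCL_TOO_FEW)]

    def test_simulation_recovery(self, simulated_unit):
        truth, datasets, _ = simulated_unit
        cons = of.merge_unit(datasets)
        common = cons.values.index.intersection(truth.index)
        rho = spearmanr(cons.values[common], truth[common]).statistic
        assert rho >= 0.95
        assert cons.strategy == "exhaustive"
        assert set(cons.included_studies) == {ds.study_id for ds in datasets}

    def test_determinism_byte_identical_outputs(self, tmp_path, simulated_unit):
        _, datasets, _ = simulated_unit
        paths = []
        for run in ("a", "b"):
            cons = of.merge_unit(datasets)
            out = tmp_path / f"consensus_{run}.tsv"
            log = tmp_path / f"merge_{run}.log"
            m = of.ResponseMatrix(
                values=pd.DataFrame({cons.unit_id: cons.values}),
                scale_state="unit-scaled",
            )
            of.write_matrix(m, out)
            of.write_merge_log(cons, log)
            paths.append((out.read_bytes(), log.read_bytes()))
        assert paths[0] == paths[1]

    def test_exclusions_are_logged_not_fatal(self, tmp_path):
        rng = np.random.default_rng(9)
        base = np.sort(rng.uniform(0, 1, 20))
        d1 = of.StudyDataset("s1", "u", profile(base))
        d2 = of.StudyDataset(
            "s2", "u", pd.Series(base[:12] * 0.9 + 0.05, index=[K(i) for i in range(12)])
        )
        # only 4 odorants shared with the others
        d3 = of.StudyDataset(
            "s3", "u", pd.Series(rng.uniform(0, 1, 4), index=[K(i) for i in range(16, 20)])
        )
        cons = of.merge_unit([d1, d2, d3])
        assert ("s3", EXCL_TOO_FEW) in cons.excluded_studies
        log = tmp_path / "merge.log"
        of.write_merge_log(cons, log)
        text = log.read_text()
        assert EXCL_TOO_FEW in text and "s3" in text


class TestGlobalNormalize:
    def _unit_study(self, study, unit, values, start=0):
        return of.StudyDataset(study, unit, profile(values, start=start))

    def test_factor_ratio_from_multi_unit_study(self):
        # one study measured both units; A's strongest response is twice B's
        a = self._unit_study("multi", "A", [0.0, 2.0, 4.0])
        b = self._unit_study("multi", "B", [0.0, 1.0, 2.0], start=3)
        consensus = {
            "A": profile([0.0, 0.5, 1.0]),
            "B": profile([0.0, 0.5, 1.0], start=3),
        }
        matrix = of.global_normalize(consensus, [a, b])
        col_max = matrix.values.max()
        assert col_max["B"] / col_max["A"] == pytest.approx(0.5)
        assert matrix.values.max().max() == pytest.approx(1.0)

    def test_no_multi_unit_studies_leaves_matrix_unchanged(self):
        a = self._unit_study("s1", "A", [0, 1, 2])
        consensus = {"A": profile([0.0, 0.5, 1.0])}
        matrix = of.global_normalize(consensus, [a])
        assert matrix.normalization_flags == {"A": "no-multi-unit-study"}
        assert np.allclose(matrix.values["A"], consensus["A"])

    def test_global_max_is_one(self, simulated_unit):
        _, datasets, _ = simulated_unit
        # pretend the three studies each measured two units jointly
        studies = []
        for i, ds in enumerate(datasets):
            studies.append(of.StudyDataset(ds.study_id, "U1", ds.responses.copy()))
            studies.append(
                of.StudyDataset(ds.study_id, "U2", ds.responses.copy() * (0.3 + 0.2 * i))
            )
        consensus = {
            "U1": profile(np.linspace(0, 1, 10)),
            "U2": profile(np.linspace(0, 1, 10)),
        }
        matrix = of.global_normalize(consensus, studies)
        assert matrix.values.max().max() == pytest.approx(1.0)
        assert matrix.scale_state == "globally-normalized"


def test_merge_config_from_file(tmp_path):
    cfg_file = tmp_path / "merge.cfg"
    cfg_file.write_text(
        "overlap_min = 3\nmd_cap = 0.2  # loosened\nstrategy = greedy\n"
        "permutation_cap = 500\nallow_flat = true\n"
    )
    cfg = of.MergeConfig.from_file(cfg_file)
    assert (cfg.overlap_min, cfg.md_cap, cfg.strategy) == (3, 0.2, "greedy")
    assert cfg.permutation_cap == 500 and cfg.allow_flat is True
    bad = tmp_path / "bad.cfg"
    bad.write_text("monotonicity = 7\n")
    with pytest.raises(KeyError):
        of.MergeConfig.from_file(bad)
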