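import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import complexome as cx
from complexome import profiles as prof
from complexome import simulate as sim
from complexome.errors import EmptyModuleError
from complexome.tables import LabelingDesign

DESIGN = LabelingDesign({"e1": ("mutant", "control"), "e2": ("control", "mutant")})


def make_table(rows):
    return pd.DataFrame(
        rows,
        columns=["experiment_id", "channel", "protein_id", "peptide_id", "slice", "intensity"],
    )


class TestProteinProfile:
    table = make_table(
        [
            ("e1", "H", "P1", "A", 2, 2.0),
            ("e1", "H", "P1", "B", 1, 1.0),
            ("e1", "H", "P1", "B", 2, 1.0),
        ]
    )

    def test_sum_aggregation(self):
        vec, observed = prof.build_protein_profile(self.table, "P1", "e1", "H", n_slices=3)
        assert observed
        np.testing.assert_allclose(vec, [1.0, 3.0, 0.0])

    def test_top_peptide_picks_most_frequently_observed(self):
        vec, _ = prof.build_protein_profile(
            self.table, "P1", "e1", "H", n_slices=3, method="top_peptide"
        )
        np.testing.assert_allclose(vec, [1.0, 1.0, 0.0])  # B seen in 2 slices, A in 1

    def test_top_peptide_ties_break_by_total_then_id(self):
        table = make_table(
            [
                ("e1", "H", "P1", "A", 1, 5.0),
                ("e1", "H", "P1", "B", 2, 1.0),
                ("e1", "H", "P1", "C", 3, 5.0),
            ]
        )
        vec, _ = prof.build_protein_profile(
            table, "P1", "e1", "H", n_slices=3, method="top_peptide"
        )
        np.testing.assert_allclose(vec, [5.0, 0.0, 0.0])  # A and C tie on count+total; A wins

    def test_absent_protein_flagged_unobserved(self):
        vec, observed = prof.build_protein_profile(self.table, "nope", "e1", "H", n_slices=3)
        assert not observed and not vec.any()


class TestOrientation:
    table = make_table(
        [
            ("e1", "H", "P1", "A", 1, 2.0),
            ("e1", "L", "P1", "A", 1, 8.0),
            ("e2", "H", "P1", "A", 1, 8.0),
            ("e2", "L", "P1", "A", 1, 2.0),
        ]
    )

    def test_heavy_channel_goes_to_heavy_condition(self):
        out1 = prof.orient_experiment(self.table, DESIGN, "e1", n_slices=2)
        out2 = prof.orient_experiment(self.table, DESIGN, "e2", n_slices=2)
        assert out1["P1"]["mutant"][0] == 2.0 and out1["P1"]["control"][0] == 8.0
        assert out2["P1"]["mutant"][0] == 2.0 and out2["P1"]["control"][0] == 8.0

    def test_unknown_experiment_rejected(self):
        with pytest.raises(KeyError):
            prof.orient_experiment(self.table, DESIGN, "e3")

    def test_orientation_depends_only_on_conditions_not_channels(self):
        """Consistently relabeling channels and design leaves condition vectors invariant."""
        flipped = self.table.copy()
        flipped["channel"] = flipped["channel"].map({"H": "L", "L": "H"})
        flipped_design = LabelingDesign(
            {"e1": ("control", "mutant"), "e2": ("mutant", "control")}
        )
        a = prof.orient_experiment(self.table, DESIGN, "e1", n_slices=2)
        b = prof.orient_experiment(flipped, flipped_design, "e1", n_slices=2)
        for cond in ("mutant", "control"):
            np.testing.assert_allclose(a["P1"][cond], b["P1"][cond])


class TestNormalizeJoint:
    def test_joint_maximum_becomes_one(self):
        c, m, ok = prof.normalize_joint([0, 4, 2], [0, 1, 1])
        assert ok
        np.testing.assert_allclose(c, [0, 1.0, 0.5])
        np.testing.assert_allclose(m, [0, 0.25, 0.25])

    def test_equal_vectors_both_reach_one(self):
        c, m, _ = prof.normalize_joint([1, 2], [1, 2])
        assert c.max() == 1.0 and m.max() == 1.0

    def test_all_zero_pair_flagged_unquantifiable(self):
        c, m, ok = prof.normalize_joint([0, 0], [0, 0])
        assert not ok and not c.any() and not m.any()

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(
        st.lists(st.floats(min_value=0.0, max_value=100.0), min_size=3, max_size=8),
        st.lists(st.floats(min_value=0.0, max_value=100.0), min_size=3, max_size=8),
    )
    def test_normalization_preserves_every_ratio(self, a, b):
        n = min(len(a), len(b))
        a, b = np.array(a[:n]), np.array(b[:n])
        c, m, ok = prof.normalize_joint(a, b)
        if not ok:
            return
        stacked_raw = np.concatenate([a, b])
        stacked_norm = np.concatenate([c, m])
        nz = stacked_raw > 0
        if nz.sum() >= 2:
            i = np.flatnonzero(nz)
            ratios_raw = stacked_raw[i] / stacked_raw[i[0]]
            ratios_norm = stacked_norm[i] / stacked_norm[i[0]]
            np.testing.assert_allclose(ratios_norm, ratios_raw, rtol=1e-9)


class TestSharedPeptideRatio:
    def test_identical_channels_give_zero(self):
        table = make_table(
            [("e1", "H", "P1", "A", k, 2.0) for k in (1, 2)]
            + [("e1", "L", "P1", "A", k, 2.0) for k in (1, 2)]
        )
        r = prof.shared_peptide_ratio(table, DESIGN, "P1", "e1", "mutant", "control")
        assert r == pytest.approx(0.0, abs=1e-12)

    def test_quarter_ratio_gives_minus_two(self):
        table = make_table(
            [("e1", "H", "P1", "A", k, 1.0) for k in (1, 2, 3)]
            + [("e1", "L", "P1", "A", k, 4.0) for k in (1, 2, 3)]
        )
        r = prof.shared_peptide_ratio(table, DESIGN, "P1", "e1", "mutant", "control")
        assert r == pytest.approx(-2.0, abs=1e-12)

    def test_no_shared_cells_returns_none(self):
        table = make_table(
            [("e1", "H", "P1", "A", 1, 1.0), ("e1", "L", "P1", "A", 2, 1.0)]
        )
        assert (
            prof.shared_peptide_ratio(table, DESIGN, "P1", "e1", "mutant", "control")
            is None
        )

    def test_median_over_noisy_cells_concentrates_on_planted_ratio(self):
        """Lognormal noise (sigma 0.2 per channel), true log2 ratio -2, 30 shared cells.

        The asymptotic SE of the median is 1.2533 * sqrt(2) * 0.2 / ln(2) /
        sqrt(30) ~ 0.093 log2 units; 0.25 is ~2.7 SE, so well over 95% of
        replicates must land inside it.
        """
        rng = np.random.default_rng(99)
        hits = 0
        errs = []
        n_rep = 200
        for _ in range(n_rep):
            rows = []
            for j in range(30):
                base = 10.0
                ctl = base * np.exp(rng.normal(0, 0.2))
                mut = base * 0.25 * np.exp(rng.normal(0, 0.2))
                rows.append(("e1", "H", "P1", f"p{j}", 1 + j % 20, mut))
                rows.append(("e1", "L", "P1", f"p{j}", 1 + j % 20, ctl))
            # distinct peptide ids ensure 30 distinct shared cells
            r = prof.shared_peptide_ratio(
                make_table(rows), DESIGN, "P1", "e1", "mutant", "control"
            )
            errs.append(r - (-2.0))
            hits += abs(r - (-2.0)) <= 0.25
        assert hits / n_rep >= 0.95
        assert abs(np.mean(errs)) <= 0.03  # unbiased around the planted ratio


class TestMergeReciprocal:
    def test_identical_experiments_have_zero_sem(self):
        exp = {"control": np.array([0.2, 1.0]), "mutant": np.array([0.1, 0.4])}
        merged = prof.merge_reciprocal([exp, exp], subject="P1")
        assert not merged["control"].sem.any()
        assert merged["control"].n_experiments == 2

    def test_two_point_sem_formula(self):
        e1 = {"control": np.array([0.4]), "mutant": np.array([0.0])}
        e2 = {"control": np.array([0.6]), "mutant": np.array([0.0])}
        merged = prof.merge_reciprocal([e1, e2], subject="P1")
        assert merged["control"].values[0] == pytest.approx(0.5)
        assert merged["control"].sem[0] == pytest.approx(0.1)

    def test_single_experiment_passes_through(self):
        e1 = {"control": np.array([0.4, 0.2]), "mutant": np.array([0.1, 0.0])}
        merged = prof.merge_reciprocal([e1], subject="P1")
        np.testing.assert_allclose(merged["control"].values, e1["control"])
        assert not merged["control"].sem.any()
        assert merged["control"].n_experiments == 1

    def test_mismatched_lengths_rejected(self):
        e1 = {"control": np.zeros(3)}
        e2 = {"control": np.zeros(4)}
        with pytest.raises(ValueError):
            prof.merge_reciprocal([e1, e2], subject="P1")


class TestConditionProfiles:
    def test_joint_max_of_merged_pair_is_one(self, digitonin_pair):
        t1, t2, design = digitonin_pair
        out = cx.build_condition_profiles([t1, t2], design)
        for pid, pair in out.items():
            peak = max(p.values.max() for p in pair.values())
            if any(p.observed for p in pair.values()):
                assert peak == pytest.approx(1.0, abs=1e-9), pid
            for p in pair.values():
                assert (p.values >= 0).all() and (p.sem >= 0).all()


class TestModuleProfile:
    def _profiles(self, vectors):
        out = {}
        for pid, vec in vectors.items():
            out[pid] = {
                "control": prof.MigrationProfile(pid, "control", np.array(vec), np.zeros(len(vec)))
            }
        return out

    annotation = pd.DataFrame(
        {"module_name": ["M", "M", "M"], "protein_id": ["P1", "P2", "P3"]}
    )

    def test_single_member_module_equals_member(self):
        profiles = self._profiles({"P1": [0.0, 1.0]})
        out = prof.module_profile(profiles, self.annotation, "M")
        np.testing.assert_allclose(out["control"].values, [0.0, 1.0])

    def test_two_members_average(self):
        profiles = self._profiles({"P1": [0.0, 1.0], "P2": [1.0, 0.0]})
        out = prof.module_profile(profiles, self.annotation, "M")
        np.testing.assert_allclose(out["control"].values, [0.5, 0.5])

    def test_unobserved_module_rejected(self):
        profiles = self._profiles({"P1": [0.0, 0.0]})
        profiles["P1"]["control"].observed = False
        with pytest.raises(EmptyModuleError):
            prof.module_profile(profiles, self.annotation, "M")

    def test_module_mean_matches_brute_force_average(self, digitonin_pair, digitonin_bundle):
        t1, t2, design = digitonin_pair
        out = cx.build_condition_profiles([t1, t2], design)
        annotation = digitonin_bundle.modules
        for module in ("N", "Q", "cV_F1"):
            members = annotation.loc[
                annotation["module_name"] == module, "protein_id"
            ].tolist()
            mod = prof.module_profile(out, annotation, module)
            for cond in ("control", "mutant"):
                brute = np.mean([out[p][cond].values for p in members], axis=0)
                np.testing.assert_allclose(mod[cond].values, brute, atol=1e-12)


class TestHeatmap:
    def test_rows_scaled_to_unit_maximum(self):
        table = make_table(
            [("e1", "H", "P1", "A", 1, 8.0), ("e1", "H", "P1", "A", 2, 4.0)]
        )
        mat = prof.heatmap_matrix(table, ["P1", "P2"], "e1", "H", n_slices=3)
        np.testing.assert_allclose(mat.loc["P1"], [1.0, 0.5, 0.0])
        np.testing.assert_allclose(mat.loc["P2"], [0.0, 0.0, 0.0])  # all-zero row kept

    def test_colormap_anchors_black_yellow_red(self):
        from complexome.plotting import HEAT_CMAP

        black = np.array(HEAT_CMAP(0.0))[:3]
        yellow = np.array(HEAT_CMAP(0.5))[:3]
        red = np.array(HEAT_CMAP(1.0))[:3]
        np.testing.assert_allclose(black, [0, 0, 0], atol=0.01)
        np.testing.assert_allclose(yellow, [1, 1, 0], atol=0.01)
        np.testing.assert_allclose(red, [1, 0, 0], atol=0.01)
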