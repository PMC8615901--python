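"""Mixed ANOVA, contrasts, corrections and the a-priori power computation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from munet.stats import (
    StatsError,
    fdr_bh,
    holm_bonferroni,
    independent_t,
    mixed_anova,
    null_type_one_error,
    one_sample_t,
    paired_t,
    posthoc,
    power_rm_anova,
)

from _oracles import bh_adjust, holm_adjust


def _study_table(rng, n_per_group=12, effects=None):
    effects = effects or {}
    rows = []
    for g in ("dynamic", "static"):
        for s in range(n_per_group):
            sid = f"{g}{s:02d}"
            base = rng.normal(0, 0.5)
            for cl in ("C3", "C4"):
                for emo in ("anger", "happiness", "neutral"):
                    mu = effects.get((g, cl, emo), 0.0)
                    rows.append(
                        {
                            "subject": sid,
                            "condition": g,
                            "cluster": cl,
                            "emotion": emo,
                            "value": base + rng.normal(mu, 1.0),
                        }
                    )
    return pd.DataFrame(rows)


class TestMixedAnova:
    def test_matches_pingouin_one_within(self, rng):
        pg = pytest.importorskip("pingouin")
        df = _study_table(rng)
        df = df[df["cluster"] == "C4"]
        ours = mixed_anova(df, within=("emotion",))
        ref = pg.mixed_anova(
            data=df, dv="value", within="emotion", subject="subject", between="condition"
        )
        for our_effect, ref_source in [
            ("condition", "condition"),
            ("emotion", "emotion"),
            ("condition * emotion", "Interaction"),
        ]:
            a = ours.loc[ours.effect == our_effect].iloc[0]
            b = ref.loc[ref.Source == ref_source].iloc[0]
            assert a.F == pytest.approx(b.F)
            assert a.p == pytest.approx(b.p_unc)
            assert a.partial_eta_sq == pytest.approx(b.np2)

    def test_matches_pingouin_unequal_groups(self, rng):
        pg = pytest.importorskip("pingouin")
        df = _study_table(rng, n_per_group=10)
        df = df[df["cluster"] == "C3"]
        df = df[~df["subject"].isin(["static08", "static09", "static07"])]
        ours = mixed_anova(df, within=("emotion",))
        ref = pg.mixed_anova(
            data=df, dv="value", within="emotion", subject="subject", between="condition"
        )
        assert ours.loc[ours.effect == "emotion", "F"].item() == pytest.approx(
            ref.loc[ref.Source == "emotion", "F"].item()
        )

    def test_three_way_df_structure_matches_study_design(self, rng):
        df = _study_table(rng, n_per_group=19)
        res = mixed_anova(df, within=("cluster", "emotion"))
        by = dict(zip(res.effect, zip(res.df1, res.df2)))
        assert by["emotion"] == (2.0, 72.0)
        assert by["cluster"] == (1.0, 36.0)
        assert by["condition"] == (1.0, 36.0)
        assert by["cluster * emotion"] == (2.0, 72.0)
        assert by["condition * cluster * emotion"] == (2.0, 72.0)

    def test_two_level_within_equals_squared_paired_t(self, rng):
        # single-group design: the within-factor F is exactly the squared
        # paired t on the cell differences
        df = _study_table(rng)
        df = df[(df["emotion"] == "anger") & (df["condition"] == "dynamic")]
        res = mixed_anova(df, within=("cluster",))
        wide = df.pivot_table(index="subject", columns="cluster", values="value")
        t, _, p, _ = paired_t(wide["C3"].to_numpy(), wide["C4"].to_numpy())
        assert res.loc[res.effect == "cluster", "F"].item() == pytest.approx(t**2)
        assert res.loc[res.effect == "cluster", "p"].item() == pytest.approx(p)

    def test_partial_eta_sq_identity(self, rng):
        res = mixed_anova(_study_table(rng), within=("cluster", "emotion"))
        eta = res.df1 * res.F / (res.df1 * res.F + res.df2)
        assert np.allclose(res.partial_eta_sq, eta, atol=1e-9)

    def test_missing_cell_names_subject(self, rng):
        df = _study_table(rng)
        df = df.drop(df[(df.subject == "static03") & (df.emotion == "anger")].index[:1])
        with pytest.raises(StatsError, match="static03"):
            mixed_anova(df, within=("cluster", "emotion"))

    def test_interaction_power_on_designed_effect(self):
        """An injected condition x emotion interaction is detected reliably."""
        from munet.stats import _mixed_anova_cells
        from scipy import stats as sps

        rng = np.random.default_rng(0)
        n_reps, n = 200, 19
        Y = rng.standard_normal((n_reps, 2 * n, 2, 3))
        # designed interaction: +1.2 SD on one emotion for the first group only
        Y[:, :n, :, 0] += 1.2
        hits = 0
        for key, df1, df2, F in _mixed_anova_cells(Y, (n, n)):
            if key == "AC":  # condition x emotion
                p = sps.f.sf(F, df1, df2)
                hits = np.mean(p < 0.05)
        assert hits > 0.8

    def test_null_type_one_error_calibrated(self):
        rates = null_type_one_error(n_reps=500, seed=11)
        assert set(rates) == {"A", "B", "AB", "C", "AC", "BC", "ABC"}
        for rate in rates.values():
            assert 0.02 < rate < 0.08


class TestContrasts:
    def test_paired_t_hand_example(self):
        # differences {1, 2, 3}: t = 2 / (1/sqrt(3)) = 3.464, df = 2
        t, df, p, d = paired_t(np.array([2.0, 4.0, 6.0]), np.array([1.0, 2.0, 3.0]))
        assert t == pytest.approx(2 * np.sqrt(3), rel=1e-6)
        assert df == 2

    def test_one_sample_hand_example(self):
        res = one_sample_t([1.0, 2.0, 3.0])
        assert res.t == pytest.approx(2 * np.sqrt(3), rel=1e-6)
        assert res.cohens_d == pytest.approx(2.0)
        assert res.df == 2

    def test_one_sample_symmetric_values(self):
        res = one_sample_t([-1.0, 1.0, -2.0, 2.0])
        assert res.t == pytest.approx(0.0, abs=1e-12)
        assert res.p_raw == pytest.approx(1.0)

    def test_one_sample_degenerate_inputs(self):
        with pytest.raises(StatsError):
            one_sample_t([1.0])
        with pytest.raises(StatsError):
            one_sample_t([2.0, 2.0, 2.0])

    def test_independent_t_pooled_d(self, rng):
        x, y = rng.normal(1, 1, 20), rng.normal(0, 1, 15)
        t, df, p, d = independent_t(x, y)
        assert df == 33
        from scipy import stats as sps

        ref_t, ref_p = sps.ttest_ind(x, y)
        assert t == pytest.approx(ref_t)


class TestPosthoc:
    def _table(self, rng, shift=0.0):
        rows = []
        for s in range(12):
            base = rng.normal()
            for emo, mu in (("anger", shift), ("happiness", 0.0), ("neutral", 0.0)):
                rows.append(
                    {"subject": f"s{s}", "emotion": emo, "value": base + rng.normal(mu, 0.3)}
                )
        return pd.DataFrame(rows)

    def test_gate_blocks_on_nonsignificant_omnibus(self, rng):
        out = posthoc(self._table(rng), "emotion", omnibus_p=0.20)
        assert out == []

    def test_contrasts_run_when_gate_opens(self, rng):
        out = posthoc(self._table(rng, shift=1.5), "emotion", omnibus_p=0.001)
        assert len(out) == 3
        assert all(c.p_adjusted >= c.p_raw for c in out)
        assert all(c.method == "holm" for c in out)


class TestCorrections:
    def test_holm_hand_example(self):
        adj = holm_bonferroni([0.01, 0.02, 0.04])
        assert np.allclose(adj, [0.03, 0.04, 0.04])

    def test_fdr_hand_example(self):
        reject, _ = fdr_bh([0.01, 0.04, 0.03, 0.005], q=0.05)
        assert reject.all()

    def test_all_ones_not_rejected(self):
        reject, adj = fdr_bh([1.0, 1.0, 1.0])
        assert not reject.any()
        assert np.allclose(adj, 1.0)

    @given(
        p=st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=10),
        q=st.floats(0.01, 0.2),
    )
    def test_against_textbook_definitions(self, p, q):
        p = np.asarray(p)
        assert np.allclose(holm_bonferroni(p), holm_adjust(p), atol=1e-12)
        reject, adj = fdr_bh(p, q)
        assert np.allclose(adj, bh_adjust(p), atol=1e-12)
        # BH rejects a superset of Bonferroni
        bonf = p <= q / p.size
        assert np.all(reject[bonf])


class TestPower:
    def test_study_configuration(self):
        assert power_rm_anova(
            f=0.25, alpha=0.05, power=0.80, n_groups=2, n_measures=3, rho=0.5, epsilon=1.0
        ) == 28

    def test_large_effect_saturates_at_minimum_design(self):
        assert power_rm_anova(f=2.0, n_groups=2, n_measures=3) == 3

    def test_monotone_in_target_power(self):
        targets = [0.6, 0.8, 0.9, 0.95]
        ns = [power_rm_anova(power=p) for p in targets]
        assert ns == sorted(ns)

    def test_invalid_parameters(self):
        with pytest.raises(StatsError):
            power_rm_anova(f=-1.0)
        with pytest.raises(StatsError):
            power_rm_anova(rho=1.0)
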