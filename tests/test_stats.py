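"""Nonparametric test protocols and the Hill-equation dissociation fit."""

import numpy as np
import pandas as pd
import pytest

from catchbond import (
    fit_hill,
    generate_hill_titration,
    kruskal_dunn,
    kruskal_wilcoxon_pairwise,
    normality_screen,
)
from catchbond.stats import compact_letter_display


class TestNormalityScreen:
    def test_size_on_gaussian_samples(self):
        """n=1000 Gaussian groups flagged normal in >= 93% of 100 runs."""
        rng = np.random.default_rng(0)
        flags = [
            normality_screen({"g": rng.normal(size=1000)})["non_normal"].iloc[0]
            for _ in range(100)
        ]
        assert np.mean(flags) <= 0.07

    def test_power_on_bimodal_mixture(self):
        """Modes 4 sd apart: flagged non-normal in >= 99% of runs."""
        rng = np.random.default_rng(1)
        hits = 0
        for _ in range(100)            :
            x = np.concatenate([rng.normal(0, 1, 500), rng.normal(4, 1, 500)])
            hits += normality_screen({"g": x})["non_normal"].iloc[0]
        assert hits >= 99

    def test_tiny_group_skipped(self):
        out = normality_screen({"g": [1.0, 2.0]})
        assert out["skipped"].iloc[0] == "too_few_observations"


class TestKruskalDunn:
    def test_type_I_error_rate_near_alpha(self):
        """Three null groups: omnibus rejects at ~5% over 1000 runs."""
        rng = np.random.default_rng(2)
        rejections = sum(
            kruskal_dunn({k: rng.normal(size=20) for k in "abc"}).omnibus_p < 0.05
            for _ in range(1000)
        )
        assert 25 <= rejections <= 80  # ~5% with binomial slack

    def test_separated_groups_all_pairs_distinct(self):
        rng = np.random.default_rng(3)
        groups = {
            "lo": rng.normal(0, 1, 60),
            "mid": rng.normal(3, 1, 60),
            "hi": rng.normal(6, 1, 60),
        }
        res = kruskal_dunn(groups)
        assert res.omnibus_p < 1e-6
        offdiag = res.pairwise.values[~np.eye(3, dtype=bool)]
        assert np.all(offdiag < 0.05)
        assert len(set(res.letters.values())) == 3

    def test_identical_groups_share_letter_and_p_one(self):
        res = kruskal_dunn({"a": [1.0] * 10, "b": [1.0] * 10})
        assert res.omnibus_p == 1.0
        assert res.letters["a"] == res.letters["b"]

    def test_sidak_adjustment_monotone_and_bounded(self):
        rng = np.random.default_rng(4)
        res = kruskal_dunn({k: rng.normal(size=15) for k in "abcd"})
        p = res.pairwise.values
        assert np.all((p >= 0) & (p <= 1))
        assert np.allclose(p, p.T)

    def test_letters_consistent_with_pairwise_matrix(self):
        """Shared letter iff adjusted p > alpha, on a mixed-signal dataset."""
        rng = np.random.default_rng(5)
        groups = {
            "a": rng.normal(0.0, 1, 40),
            "b": rng.normal(0.9, 1, 40),
            "c": rng.normal(1.8, 1, 40),
            "d": rng.normal(6.0, 1, 40),
        }
        res = kruskal_dunn(groups)
        for g1 in groups:
            for g2 in groups:
                if g1 >= g2:
                    continue
                share = bool(set(res.letters[g1]) & set(res.letters[g2]))
                assert share == (res.pairwise.loc[g1, g2] >= 0.05)


class TestKruskalWilcoxon:
    def test_size_on_identical_distributions(self):
        rng = np.random.default_rng(6)
        ok = 0
        for _ in range(200):
            res = kruskal_wilcoxon_pairwise(
                {"a": rng.normal(size=30), "b": rng.normal(size=30)}
            )
            ok += res.pairwise.loc["a", "b"] > 0.05
        assert ok >= 180  # >= 90%

    def test_power_on_shifted_pair(self):
        """1.5 sd shift at n=50: >= 80% power."""
        rng = np.random.default_rng(7)
        hits = 0
        for _ in range(200):
            res = kruskal_wilcoxon_pairwise(
                {"a": rng.normal(0, 1, 50), "b": rng.normal(1.5, 1, 50)}
            )
            hits += res.pairwise.loc["a", "b"] < 0.05
        assert hits >= 160

    def test_single_group_refused(self):
        with pytest.raises(ValueError):
            kruskal_wilcoxon_pairwise({"a": [1.0, 2.0, 3.0]})


class TestLetterDisplay:
    def test_nonsignificant_chain_shares_letters(self):
        p = pd.DataFrame(
            [[1.0, 0.3, 0.01], [0.3, 1.0, 0.3], [0.01, 0.3, 1.0]],
            index=list("abc"), columns=list("abc"),
        )
        letters = compact_letter_display(p, {"a": 1.0, "b": 2.0, "c": 3.0})
        assert set(letters["a"]) & set(letters["b"])
        assert set(letters["b"]) & set(letters["c"])
        assert not set(letters["a"]) & set(letters["c"])


class TestHillFit:
    def test_noiseless_exact_recovery(self):
        table = generate_hill_titration(kd=45.0, hill_n=1.0, bmax=2.0, noise_sd=0.0)
        fit = fit_hill(table)
        assert fit.kd == pytest.approx(45.0, rel=1e-6)
        assert fit.hill_n == pytest.approx(1.0, rel=1e-4)
        assert fit.bmax == pytest.approx(2.0, rel=1e-4)

    def test_noisy_recovery_within_20_percent(self):
        """5% noise on the 7-point 5-fold design: kd recovered within 20%
        (mean and median over 30 seeds; single noise realisations can
        occasionally deviate more with the Hill coefficient left free)."""
        errors = []
        for seed in range(30):
            table = generate_hill_titration(
                kd=45.0, bmax=1.0, noise_sd=0.05, seed=seed, n_replicates=3
            )
            fit = fit_hill(table)
            errors.append(abs(fit.kd - 45.0) / 45.0)
        assert np.mean(errors) <= 0.20
        assert np.median(errors) <= 0.20

    def test_flat_signal_unidentifiable(self):
        table = pd.DataFrame(
            {"concentration_nM": [1.0, 5.0, 25.0, 125.0, 625.0], "signal": 0.0}
        )
        with pytest.raises(ValueError):
            fit_hill(table)

    def test_too_few_points_refused(self):
        table = generate_hill_titration(kd=45.0, concentrations=[10, 50, 100, 400])
        with pytest.raises(ValueError):
            fit_hill(table)
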