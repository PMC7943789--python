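"""Hit calling (Sidak error control, effect filter) and response-matrix
clustering, with brute-force oracles on small instances."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from phenoscreen.errors import DomainError, MissingControlError
from phenoscreen.screen import (
    build_response_matrix,
    call_hits,
    compound_hits,
    dunn_sidak_alpha,
    hierarchical_cluster,
    normalize_to_control,
    well_growth_rates,
)
from phenoscreen.simulate import simulate_screen_plate


def screen_rates(config):
    counts, truth = simulate_screen_plate(config)
    return well_growth_rates(counts), truth


class TestDunnSidak:
    def test_closed_forms(self):
        assert dunn_sidak_alpha(0.05, 1) == pytest.approx(0.05)
        assert dunn_sidak_alpha(0.05, 10) == pytest.approx(0.005116, abs=1e-6)

    @pytest.mark.parametrize("m", [1, 2, 10, 100, 5000])
    def test_between_bonferroni_and_nominal(self, m):
        thr = dunn_sidak_alpha(0.05, m)
        if m == 1:
            assert thr == pytest.approx(0.05)
        else:
            assert 0.05 / m < thr < 0.05

    def test_domain_errors(self):
        with pytest.raises(DomainError):
            dunn_sidak_alpha(0.05, 0)
        with pytest.raises(DomainError):
            dunn_sidak_alpha(1.5, 3)


class TestNormalizeToControl:
    def test_deltas_vs_matched_control(self, small_screen_config):
        cfg = replace(small_screen_config, noise_cv=0.0)
        rates, _ = screen_rates(cfg)
        out = normalize_to_control(rates)
        # compound identical to control -> delta 0 (noiseless)
        inert = out[out["compound"] == "C5"]
        np.testing.assert_allclose(inert["delta"], 0.0, atol=1e-12)
        # counts are rounded to integers, so the planted delta is exact
        # only up to ~1/N0 rounding on the log scale
        planted = out[out["compound"] == "C0"]
        np.testing.assert_allclose(planted["delta"], -1.0, atol=1e-3)

    def test_missing_control_names_orphan(self, small_screen_config):
        rates, _ = screen_rates(small_screen_config)
        no_ctrl = rates[rates["compound"] != "DMSO"]
        with pytest.raises(MissingControlError, match="L1"):
            normalize_to_control(no_ctrl)

    def test_deltas_unbiased_over_simulations(self, small_screen_config):
        """Mean delta for a planted compound over 300 simulated screens
        is within 3 s.e. of the planted -1.0/day."""
        cfg = replace(
            small_screen_config,
            compounds=("C0", "C1"),
            control_replicates=10,
        )
        deltas = []
        for seed in range(300):
            rates, _ = screen_rates(cfg.with_seed(seed))
            out = normalize_to_control(rates)
            deltas.append(
                out.loc[out["compound"] == "C0", "delta"].mean()
            )
        deltas = np.asarray(deltas)
        se = deltas.std(ddof=1) / np.sqrt(len(deltas))
        assert abs(deltas.mean() - (-1.0)) < 3 * se


class TestCallHits:
    def test_planted_hits_flagged(self, small_screen_config):
        rates, truth = screen_rates(small_screen_config)
        calls = call_hits(rates)
        hits = compound_hits(calls)
        assert set(hits.index[hits]) == set(
            truth.loc[truth["truth_hit"], "compound"]
        )

    def test_effect_filter_blocks_small_effects(self, small_screen_config):
        """A -0.3/day effect with tiny noise is statistically significant
        but below the 0.5/day effect threshold, hence not a hit."""
        cfg = replace(
            small_screen_config,
            noise_cv=0.01,
            planted_effects={"C0": -0.3},
        )
        rates, _ = screen_rates(cfg)
        calls = call_hits(rates)
        c0 = calls[calls["compound"] == "C0"]
        assert (c0["p_raw"] < calls.attrs["p_threshold"]).any()
        assert not c0["significant"].any()

    def test_removing_effect_filter_enlarges_hit_set(self, small_screen_config):
        cfg = replace(
            small_screen_config,
            planted_effects={"C0": -1.0, "C1": -0.3},
        )
        rates, _ = screen_rates(cfg)
        with_filter = call_hits(rates, effect_threshold=0.5)["significant"]
        without = call_hits(rates, effect_threshold=0.0)["significant"]
        assert (without | ~with_filter).all()  # with_filter is a subset
        assert without.sum() >= with_filter.sum()

    def test_family_size_recorded(self, small_screen_config):
        rates, _ = screen_rates(small_screen_config)
        calls = call_hits(rates)
        # 10 compounds x 2 doses x 1 line x 1 MAPK x 2 timepoints
        assert calls.attrs["m"] == 40 == len(calls)

    def test_normalized_effect_scale_option(self, small_screen_config):
        rates, _ = screen_rates(small_screen_config)
        net = call_hits(rates, effect_on="net")
        norm = call_hits(rates, effect_on="normalized", effect_threshold=0.5)
        # control rate is 0.6/day, so normalized effects are larger in
        # magnitude than net ones
        assert (norm["effect"].abs() >= net["effect"].abs() - 1e-12).all()


class TestResponseMatrix:
    @staticmethod
    def _long(rows):
        return pd.DataFrame(
            rows,
            columns=[
                "compound", "readout", "cell_line", "mapk_condition",
                "dose", "timepoint", "delta",
            ],
        )

    def test_dose_timepoint_averaging(self):
        long = self._long(
            [
                ("A", "growth_rate", "L", "DMSO", 0.2, 3.0, -0.4),
                ("A", "growth_rate", "L", "DMSO", 1.0, 3.0, -0.6),
            ]
        )
        matrix, incomplete = build_response_matrix(long)
        assert matrix.loc["A"].iloc[0] == pytest.approx(-0.5)
        assert not incomplete["A"]

    def test_zero_row_and_incomplete_flag(self):
        long = self._long(
            [
                ("A", "growth_rate", "L", "DMSO", 0.2, 3.0, 0.0),
                ("A", "p-Rb", "L", "DMSO", 0.2, 3.0, 0.0),
                ("B", "growth_rate", "L", "DMSO", 0.2, 3.0, -1.0),
            ]
        )
        matrix, incomplete = build_response_matrix(long)
        assert (matrix.loc["A"] == 0).all()
        assert incomplete["B"] and not incomplete["A"]

    def test_matches_groupby_oracle_on_synthetic_screen(
        self, small_screen_config
    ):
        rates, _ = screen_rates(small_screen_config)
        out = normalize_to_control(rates)
        out["readout"] = "growth_rate"
        long = out[
            ["compound", "readout", "cell_line", "mapk_condition", "dose",
             "timepoint", "delta"]
        ]
        matrix, _ = build_response_matrix(long)
        for comp in ("C0", "C7"):
            brute = long.loc[long["compound"] == comp, "delta"].mean()
            assert matrix.loc[comp].iloc[0] == pytest.approx(brute)


def brute_force_complete_linkage(D: np.ndarray) -> list[float]:
    """Naive agglomerative complete linkage; returns sorted merge heights."""
    clusters = [[i] for i in range(len(D))]
    heights = []
    while len(clusters) > 1:
        best = (np.inf, None, None)
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = max(D[a, b] for a in clusters[i] for b in clusters[j])
                if d < best[0]:
                    best = (d, i, j)
        d, i, j = best
        heights.append(d)
        clusters[i] = clusters[i] + clusters[j]
        del clusters[j]
    return heights


class TestHierarchicalCluster:
    @staticmethod
    def _matrix(X, labels):
        return pd.DataFrame(
            X, index=labels, columns=[f"f{k}" for k in range(X.shape[1])]
        )

    def test_duplicate_rows_merge_first(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((4, 5))
        X[1] = X[0]  # duplicated profile
        result = hierarchical_cluster(self._matrix(X, list("abcd")))
        assert result.linkage[0, 2] == pytest.approx(0.0)
        assert set(result.linkage[0, :2].astype(int)) == {0, 1}

    def test_anticorrelated_distance_two(self):
        X = np.array([[1.0, 2.0, 3.0], [3.0, 2.0, 1.0]])
        result = hierarchical_cluster(self._matrix(X, ["up", "down"]))
        assert result.linkage[0, 2] == pytest.approx(2.0)

    def test_heights_match_brute_force_oracle(self):
        rng = np.random.default_rng(13)
        X = rng.standard_normal((8, 6))
        labels = [f"r{i}" for i in range(8)]
        result = hierarchical_cluster(self._matrix(X, labels))
        corr = np.corrcoef(X)
        D = 1 - corr
        expected = brute_force_complete_linkage(D)
        np.testing.assert_allclose(
            sorted(result.linkage[:, 2]), sorted(expected), atol=1e-12
        )

    def test_monotone_heights(self):
        rng = np.random.default_rng(14)
        X = rng.standard_normal((12, 5))
        result = hierarchical_cluster(self._matrix(X, [f"r{i}" for i in range(12)]))
        assert (np.diff(result.linkage[:, 2]) >= -1e-12).all()

    def test_zero_variance_row_excluded(self):
        X = np.vstack([np.ones(4), np.arange(4.0), np.arange(4.0)[::-1]])
        with pytest.warns(UserWarning, match="zero-variance"):
            result = hierarchical_cluster(self._matrix(X, ["flat", "a", "b"]))
        assert "flat" not in result.labels

    def test_newick_has_all_leaves(self):
        rng = np.random.default_rng(15)
        X = rng.standard_normal((5, 4))
        labels = [f"cmp{i}" for i in range(5)]
        result = hierarchical_cluster(self._matrix(X, labels))
        for lab in labels:
            assert lab in result.newick
        assert sorted(result.leaf_order) == sorted(labels)
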