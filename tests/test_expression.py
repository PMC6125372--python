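import numpy as np
import pandas as pd
import pytest

from orthocore.expression import (ExpressionMatrix, ScanConfig,
                                  category_summary, detect_outlier_samples,
                                  de_results_frame, differential_expression,
                                  log_transform, quantile_normalize,
                                  read_expression_tsv,
                                  sliding_window_profile,
                                  write_expression_tsv)
from orthocore.simulate import simulate_expression

from oracles import window_counts_oracle


def matrix_from(values: dict, conditions: dict) -> ExpressionMatrix:
    return ExpressionMatrix(values=pd.DataFrame(values),
                            conditions=conditions)


class TestQuantileNormalize:
    def test_worked_two_by_two_example(self):
        df = pd.DataFrame({"s1": [1.0, 3.0], "s2": [2.0, 4.0]})
        out = quantile_normalize(df)
        assert list(out["s1"]) == [1.5, 3.5]
        assert list(out["s2"]) == [1.5, 3.5]

    def test_identical_columns_fixed_point(self):
        df = pd.DataFrame({"a": [5.0, 1.0, 3.0], "b": [5.0, 1.0, 3.0]})
        out = quantile_normalize(df)
        pd.testing.assert_frame_equal(out, df)

    def test_sorted_columns_identical_on_random_matrices(self):
        rng = np.random.default_rng(7)
        for _ in range(30):
            n, m = int(rng.integers(3, 60)), int(rng.integers(2, 8))
            df = pd.DataFrame(rng.lognormal(5, 1, size=(n, m)),
                              columns=[f"s{j}" for j in range(m)])
            out = quantile_normalize(df)
            ref = np.sort(out.iloc[:, 0].to_numpy())
            for j in range(1, m):
                assert np.allclose(np.sort(out.iloc[:, j].to_numpy()), ref)

    def test_ranks_preserved_within_column(self):
        rng = np.random.default_rng(9)
        df = pd.DataFrame(rng.lognormal(5, 1, size=(40, 4)))
        out = quantile_normalize(df)
        for j in range(4):
            a = df.iloc[:, j].rank().to_numpy()
            b = out.iloc[:, j].rank().to_numpy()
            assert (a == b).all()


class TestLogTransform:
    def test_zero_with_unit_pseudocount(self):
        df = pd.DataFrame({"s": [0.0, 3.0]})
        out = log_transform(df, pseudocount=1.0)
        assert list(out["s"]) == [0.0, 2.0]

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            log_transform(pd.DataFrame({"s": [-1.0]}))

    def test_monotone(self):
        rng = np.random.default_rng(3)
        vals = rng.lognormal(3, 2, size=100)
        out = log_transform(pd.DataFrame({"s": np.sort(vals)}))
        assert (np.diff(out["s"]) >= 0).all()


class TestOutlierDetection:
    def build(self, n_genes=300, seed=1):
        rng = np.random.default_rng(seed)
        base = rng.lognormal(6, 1, size=n_genes)
        cols = {f"s{i}": base * np.exp(rng.normal(0, 0.05, n_genes))
                for i in range(3)}
        cols["weird"] = rng.lognormal(6, 1, size=n_genes)  # unrelated
        return pd.DataFrame(cols)

    def test_independent_noise_sample_flagged(self):
        df = np.log2(self.build() + 1)
        assert detect_outlier_samples(df) == ["weird"]

    def test_identical_samples_none_flagged(self):
        df = pd.DataFrame({f"s{i}": [1.0, 2.0, 3.0] for i in range(4)})
        assert detect_outlier_samples(df) == []

    def test_permutation_invariant(self):
        df = np.log2(self.build(seed=5) + 1)
        shuffled = df[["weird", "s2", "s0", "s1"]]
        assert detect_outlier_samples(shuffled) == \
            detect_outlier_samples(df)

    def test_needs_three_samples(self):
        with pytest.raises(ValueError):
            detect_outlier_samples(pd.DataFrame({"a": [1.0], "b": [2.0]}))


class TestDifferentialExpression:
    def conditions(self, nt=4, nc=4):
        cond = {f"T{i}": "treatment" for i in range(nt)}
        cond.update({f"C{i}": "control" for i in range(nc)})
        return cond

    def test_identical_conditions_not_significant(self):
        rng = np.random.default_rng(2)
        row = rng.normal(8, 1, size=4)
        values = {f"T{i}": [row[i]] for i in range(4)}
        values.update({f"C{i}": [row[i]] for i in range(4)})
        matrix = matrix_from(values, self.conditions())
        res = differential_expression(matrix)[0]
        assert res.log2fc == 0.0
        assert res.call == "ns"

    def test_fourfold_shift_called_up(self):
        rng = np.random.default_rng(4)
        control = 8 + rng.normal(0, 0.05, 4)
        treatment = control + 2.0  # 4-fold on log2 scale
        values = {f"T{i}": [treatment[i]] for i in range(4)}
        values.update({f"C{i}": [control[i]] for i in range(4)})
        matrix = matrix_from(values, self.conditions())
        res = differential_expression(matrix)[0]
        assert res.call == "up"
        assert res.log2fc == pytest.approx(2.0, abs=0.1)

    def test_zero_variance_equal_means_p_one(self):
        values = {f"T{i}": [5.0] for i in range(4)}
        values.update({f"C{i}": [5.0] for i in range(4)})
        matrix = matrix_from(values, self.conditions())
        res = differential_expression(matrix)[0]
        assert res.p_value == 1.0
        assert res.call == "ns"

    def test_undetected_gene_flagged(self):
        values = {f"T{i}": [5.0, 6.0] for i in range(4)}
        values.update({f"C{i}": [5.0, 6.0] for i in range(4)})
        detected = pd.DataFrame(
            {s: [False, True] for s in values},
            index=[0, 1])
        matrix = ExpressionMatrix(values=pd.DataFrame(values),
                                  conditions=self.conditions(),
                                  detected=detected)
        res = differential_expression(matrix)
        assert res[0].call == "undetected"
        assert res[1].call == "ns"

    def test_call_consistent_with_thresholds(self):
        rng = np.random.default_rng(8)
        config = ScanConfig()
        n = 400
        vt = rng.normal(8, 1, size=(n, 4))
        vc = rng.normal(8, 1, size=(n, 4))
        values = {}
        for i in range(4):
            values[f"T{i}"] = vt[:, i]
            values[f"C{i}"] = vc[:, i]
        matrix = matrix_from(values, self.conditions())
        for r in differential_expression(matrix, config):
            if r.call == "up":
                assert r.p_value <= config.p_threshold
                assert 2 ** r.log2fc >= config.fc_threshold
            elif r.call == "down":
                assert r.p_value <= config.p_threshold
                assert 2 ** (-r.log2fc) >= config.fc_threshold

    def test_requires_two_replicates(self):
        values = {"T0": [1.0], "C0": [1.0], "C1": [2.0]}
        matrix = matrix_from(values, {"T0": "treatment", "C0": "control",
                                      "C1": "control"})
        with pytest.raises(ValueError):
            differential_expression(matrix)


def fake_results(calls):
    from orthocore.expression import DEResult
    return [DEResult(gene_id=f"g{i}", log2fc=0.0, p_value=0.5, call=c)
            for i, c in enumerate(calls)]


class TestSlidingWindow:
    def order(self, n, rep="chr"):
        return [(rep, f"g{i}") for i in range(n)]

    def test_saturated_window(self):
        calls = ["ns"] * 5 + ["up"] * 15 + ["ns"] * 5
        profile = sliding_window_profile(fake_results(calls),
                                         self.order(25))
        table = profile.table
        saturated = table[table["up_count"] == 15]
        assert list(saturated["start_rank"]) == [5]

    def test_no_de_genes_all_zero(self):
        profile = sliding_window_profile(fake_results(["ns"] * 40),
                                         self.order(40))
        assert (profile.table[["up_count", "down_count"]] == 0).all().all()

    def test_matches_bruteforce_recount(self):
        rng = np.random.default_rng(21)
        for _ in range(25):
            n = int(rng.integers(15, 200))
            calls = [str(rng.choice(["up", "down", "ns"])) for _ in
                     range(n)]
            profile = sliding_window_profile(fake_results(calls),
                                             self.order(n))
            expected = window_counts_oracle(calls, 15)
            got = [(int(r.start_rank), int(r.up_count), int(r.down_count))
                   for r in profile.table.itertuples()]
            assert got == expected

    def test_windows_do_not_cross_replicons(self):
        order = [("chr", f"g{i}") for i in range(20)] + \
                [("pla", f"p{i}") for i in range(20)]
        calls = fake_results(["up"] * 40)
        # names must match the order entries
        for r, (rep, gid) in zip(calls, order):
            r.gene_id = gid
        profile = sliding_window_profile(calls, order)
        table = profile.table
        assert set(table["replicon"]) == {"chr", "pla"}
        assert len(table[table["replicon"] == "chr"]) == 6
        assert len(table[table["replicon"] == "pla"]) == 6

    def test_short_replicon_contributes_no_windows(self):
        profile = sliding_window_profile(fake_results(["up"] * 5),
                                         self.order(5))
        assert profile.table.empty


class TestCategorySummary:
    def test_motility_like_fraction(self):
        calls = ["up"] * 83 + ["down"] * 13 + ["ns"] * 100
        mapping = {f"g{i}": "motility" for i in range(96)}
        summary = category_summary(fake_results(calls), mapping)
        row = summary[summary["category"] == "motility"].iloc[0]
        assert row["n_up"] == 83
        assert row["n_down"] == 13
        assert row["frac_up_of_de"] == pytest.approx(83 / 96, abs=1e-4)

    def test_totals_conserved(self):
        rng = np.random.default_rng(6)
        calls = [str(rng.choice(["up", "down", "ns", "undetected"]))
                 for _ in range(300)]
        mapping = {f"g{i}": f"cat{i % 5}" for i in range(200)}
        summary = category_summary(fake_results(calls), mapping)
        assert summary[["n_up", "n_down", "n_ns",
                        "n_undetected"]].to_numpy().sum() == 300

    def test_empty_category_absent(self):
        summary = category_summary(fake_results(["ns"]), {"g0": "x"})
        assert list(summary["category"]) == ["x"]


class TestRoundTrip:
    def test_expression_tsv_roundtrip(self, tmp_path):
        matrix = simulate_expression(n_genes=30, planted_block=range(5, 9),
                                     seed=3)
        p = tmp_path / "expr.tsv"
        d = tmp_path / "det.tsv"
        write_expression_tsv(p, matrix, detected_path=d)
        back = read_expression_tsv(p, detected_path=d)
        pd.testing.assert_frame_equal(back.values, matrix.values)
        assert back.conditions == matrix.conditions
        pd.testing.assert_frame_equal(back.detected, matrix.detected)

    def test_de_results_frame_columns(self):
        frame = de_results_frame(fake_results(["up", "ns"]))
        assert list(frame.columns) == ["gene_id", "log2fc", "p_value",
                                       "call"]
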