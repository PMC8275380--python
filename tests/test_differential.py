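"""Detection filter, DAR/DEG calls, ranking, paired test and direction agreement."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from atacgrn.differential import (
    call_differential,
    direction_agreement,
    filter_expressed,
    paired_nb_test,
    rank_features,
)
from atacgrn.synthetic import generate_counts


def _table(rows):
    return pd.DataFrame(rows, columns=["feature", "log2FC", "PValue", "FDR"])


class TestFilterExpressed:
    def _counts(self, cpm_rows, lib=1_000_000):
        # library size 1e6 makes counts equal CPM directly
        data = {f"s{i+1}": [] for i in range(len(cpm_rows[0]))}
        index = []
        for j, row in enumerate(cpm_rows):
            index.append(f"g{j+1}")
            for i, v in enumerate(row):
                data[f"s{i+1}"].append(v)
        df = pd.DataFrame(data, index=index)
        # pad with a filler feature so each library sums to `lib`
        filler = [lib - df[c].sum() for c in df.columns]
        df.loc["filler"] = filler
        return df

    def test_three_samples_above_one_cpm_retained(self):
        counts = self._counts([[2, 2, 2, 0]])
        assert "g1" in filter_expressed(counts)

    def test_two_samples_above_dropped(self):
        counts = self._counts([[2, 2, 0, 0]])
        assert "g1" not in filter_expressed(counts)

    def test_all_zero_dropped(self):
        counts = self._counts([[0, 0, 0, 0]])
        assert "g1" not in filter_expressed(counts)

    def test_strictly_greater_than_cutoff(self):
        counts = self._counts([[1, 1, 1, 1]])  # exactly 1 CPM, not > 1
        assert "g1" not in filter_expressed(counts)

    def test_invariant_under_sample_reordering(self, rng):
        counts = pd.DataFrame(
            rng.integers(0, 50, size=(30, 6)),
            index=[f"g{i}" for i in range(30)],
            columns=[f"s{i}" for i in range(6)],
        )
        a = filter_expressed(counts)
        b = filter_expressed(counts[counts.columns[::-1]])
        assert list(a) == list(b)

    def test_zero_library_rejected(self):
        counts = pd.DataFrame({"s1": [0, 0], "s2": [1, 2]})
        with pytest.raises(ValueError):
            filter_expressed(counts)


class TestCallDifferential:
    @pytest.mark.parametrize(
        "log2fc, fdr, expected",
        [
            (np.log2(1.30), 0.04, True),   # passes both thresholds
            (np.log2(1.10), 0.04, False),  # fold change inside (0.75, 1.25)
            (np.log2(3.00), 0.06, False),  # FDR fails
            (np.log2(1.25), 0.04, True),   # boundary: >= 1.25 qualifies
            (np.log2(0.75), 0.04, True),   # boundary: <= 0.75 qualifies
            (np.log2(0.60), 0.01, True),
        ],
    )
    def test_threshold_rules(self, log2fc, fdr, expected):
        out = call_differential(_table([("f", log2fc, fdr, fdr)]))
        assert bool(out["significant"].iloc[0]) is expected

    def test_monotone_in_cutoffs(self, rng):
        df = _table(
            [
                (f"f{i}", float(l), float(p), float(p))
                for i, (l, p) in enumerate(
                    zip(rng.normal(0, 1, 200), rng.uniform(0, 1, 200))
                )
            ]
        )
        strict = call_differential(df, 0.05, 1.25, 0.75)["significant"]
        relaxed = call_differential(df, 0.10, 1.10, 0.90)["significant"]
        assert (relaxed | ~strict).all()  # strict implies relaxed

    def test_missing_fdr_rejected(self):
        df = _table([("f", 1.0, 0.01, np.nan)])
        with pytest.raises(ValueError):
            call_differential(df)


class TestRankFeatures:
    def test_score_arithmetic(self):
        df = _table(
            [("up", 1.0, 0.01, 0.01), ("null", 0.5, 1.0, 1.0), ("down", -1.0, 0.01, 0.01)]
        )
        scores = rank_features(df)
        assert scores["up"] == pytest.approx(2.0)
        assert scores["null"] == pytest.approx(0.0)
        assert scores["down"] == pytest.approx(-2.0)
        assert list(scores.index) == ["up", "null", "down"]

    def test_pvalue_field_supported(self):
        df = _table([("f", 1.0, 0.001, 0.5)])
        assert rank_features(df, "pvalue")["f"] == pytest.approx(3.0)
        assert rank_features(df, "FDR")["f"] == pytest.approx(np.log10(2))

    def test_sign_reversal_reverses_order(self, rng):
        df = _table(
            [
                (f"f{i}", float(l), float(p), float(p))
                for i, (l, p) in enumerate(
                    zip(rng.normal(0, 1, 50), rng.uniform(1e-6, 1, 50))
                )
            ]
        )
        fwd = rank_features(df)
        flipped = df.assign(log2FC=-df["log2FC"])
        rev = rank_features(flipped)
        assert list(rev.index) == list(fwd.index[::-1])

    def test_zero_significance_floored_not_infinite(self):
        df = _table([("f", 1.0, 0.0, 0.0)])
        assert np.isfinite(rank_features(df)["f"])


class TestPairedNbTest:
    def _run(self, counts):
        groups = {c: c.split("_")[0] for c in counts.columns}
        donors = {c: c.split("_")[1] for c in counts.columns}
        return paired_nb_test(counts, groups, donors)

    def test_identical_columns_nothing_significant(self):
        base = np.arange(10, 110, 10)
        counts = pd.DataFrame(
            {f"{g}_d{d}": base for g in "AB" for d in range(1, 5)},
            index=[f"f{i}" for i in range(10)],
        )
        out = self._run(counts)
        assert (out["PValue"] == 1.0).all()

    def test_recovers_planted_effects(self):
        recalls = []
        for seed in range(3):
            counts, truth = generate_counts(
                [f"f{i}" for i in range(500)],
                n_donors=6,
                diff_fraction=0.1,
                effect_log2fc=2.0,
                dispersion=0.1,
                seed=seed,
            )
            out = self._run(counts)
            hits = set(out.index[out["FDR"] < 0.05])
            planted = set(truth.true_differential)
            recalls.append(len(hits & planted) / len(planted))
        assert np.mean(recalls) >= 0.8

    def test_null_type_one_error_calibrated(self):
        counts, _ = generate_counts(
            [f"f{i}" for i in range(2000)],
            n_donors=6,
            diff_fraction=0.0,
            effect_log2fc=0.0,
            dispersion=0.1,
            seed=11,
        )
        out = self._run(counts)
        frac = float((out["PValue"] < 0.05).mean())
        tol = 3 * np.sqrt(0.05 * 0.95 / 2000)
        assert abs(frac - 0.05) <= tol + 0.01

    def test_estimated_log2fc_sign_matches_planted(self):
        counts, truth = generate_counts(
            [f"f{i}" for i in range(300)],
            n_donors=6,
            diff_fraction=0.2,
            effect_log2fc=2.0,
            seed=5,
        )
        out = self._run(counts)
        signs = [
            np.sign(out.loc[f, "log2FC"]) == d
            for f, (d, _) in truth.true_differential.items()
        ]
        assert np.mean(signs) > 0.95

    def test_unpaired_design_rejected(self):
        counts = pd.DataFrame(
            {"A_d1": [1], "B_d1": [2], "A_d2": [3], "B_d3": [4]}, index=["f"]
        )
        with pytest.raises(ValueError, match="unpaired"):
            self._run(counts)


class TestDirectionAgreement:
    def _tables(self, n, agree_frac, rng):
        signs_a = rng.choice([-1.0, 1.0], size=n)
        agree = rng.random(n) < agree_frac
        signs_r = np.where(agree, signs_a, -signs_a)
        rna = _table([(f"g{i}", signs_r[i] * 2, 0.001, 0.001) for i in range(n)])
        atac = _table([(f"g{i}", signs_a[i] * 2, 0.001, 0.001) for i in range(n)])
        return rna, atac

    def test_concordant_signs_give_small_p(self, rng):
        rna, atac = self._tables(40, 1.0, rng)
        table, p = direction_agreement(rna, atac, n_mc=999, seed=0)
        assert p <= 0.01
        assert table.values.trace() == 40  # all on the concordant diagonal

    def test_null_p_roughly_uniform(self, rng):
        ps = []
        for i in range(100):
            rna, atac = self._tables(60, 0.5, np.random.default_rng(i))
            _, p = direction_agreement(rna, atac, n_mc=199, seed=i)
            ps.append(p)
        ps = np.array(ps)
        # upper-tail MC p on a discrete statistic is conservative but must
        # not concentrate: check coarse uniformity
        assert (ps < 0.05).mean() <= 0.10
        assert 0.35 <= ps.mean() <= 0.75

    def test_single_joint_feature_rejected(self):
        rna = _table([("g1", 1.0, 0.001, 0.001), ("g2", 1.0, 0.5, 0.9)])
        atac = _table([("g1", 1.0, 0.001, 0.001), ("g2", 1.0, 0.5, 0.9)])
        with pytest.raises(ValueError):
            direction_agreement(rna, atac)

    def test_peak_to_gene_mapping(self):
        rna = _table([("g1", 2.0, 0.001, 0.001), ("g2", -2.0, 0.001, 0.001)])
        atac = _table(
            [
                ("p1", 1.5, 0.001, 0.001),
                ("p1b", -1.0, 0.001, 0.002),  # worse FDR, dropped per gene
                ("p2", -1.5, 0.001, 0.001),
            ]
        )
        table, p = direction_agreement(
            rna, atac, n_mc=199, seed=0,
            feature_map={"p1": "g1", "p1b": "g1", "p2": "g2"},
        )
        assert table.values.trace() == 2
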