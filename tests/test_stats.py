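"""Nonparametric tests against enumeration oracles; summary-table conventions."""

from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import pytest

from mifquant.datasets import PUBLISHED_COVARIATES, published_cohort_manifest
from mifquant.stats import (
    compare_markers,
    display_p,
    fisher_exact,
    mann_whitney,
    pearson_chi2,
    summary_table,
)

# ---------------------------------------------------------------------------
# independent oracles


def mw_permutation_p(x, y):
    """Two-sided Mann-Whitney p by enumerating all C(n+m, n) labelings."""
    pooled = list(x) + list(y)
    n, m = len(x), len(y)

    def ustat(xs, ys):
        u = 0.0
        for a in xs:
            for b in ys:
                u += 1.0 if a > b else (0.5 if a == b else 0.0)
        return u

    centre = n * m / 2.0
    obs = abs(ustat(x, y) - centre)
    hits = total = 0
    for idx in combinations(range(n + m), n):
        chosen = set(idx)
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(n + m) if i not in chosen]
        if abs(ustat(xs, ys) - centre) >= obs - 1e-12:
            hits += 1
        total += 1
    return hits / total


def fisher_enumeration_p(a, b, c, d):
    """Two-sided Fisher p: hypergeometric mass of tables no more probable."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def prob(x):
        return comb(r1, x) * comb(r2, c1 - x) / comb(n, c1)

    p_obs = prob(a)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    return sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs * (1 + 1e-9))


# ---------------------------------------------------------------------------


class TestMannWhitney:
    def test_identical_samples_p_one(self):
        assert mann_whitney([1, 2, 3], [1, 2, 3]).p_value == 1.0

    def test_constant_samples_p_one(self):
        assert mann_whitney([5, 5], [5, 5, 5]).p_value == 1.0

    def test_disjoint_triples_exact(self):
        res = mann_whitney([1, 2, 3], [4, 5, 6])
        assert res.p_value == pytest.approx(0.1)
        assert not res.significant

    def test_exact_path_equals_enumeration(self, rng):
        for n in (2, 4, 6):
            for m in (3, 5):
                x = rng.permutation(100)[: n].astype(float)
                y = rng.permutation(100)[50 : 50 + m].astype(float)
                ours = mann_whitney(x, y).p_value
                assert ours == pytest.approx(mw_permutation_p(x, y), abs=1e-12)

    def test_asymptotic_close_to_enumeration_with_ties(self, rng):
        for n in (6, 8):
            x = rng.integers(0, 20, size=n).astype(float)
            y = rng.integers(0, 20, size=n).astype(float)
            x[0] = y[0]  # guarantee at least one tie -> asymptotic path
            res = mann_whitney(x, y)
            assert res.method == "mann_whitney"
            assert res.p_value == pytest.approx(
                mw_permutation_p(list(x), list(y)), abs=0.02
            )

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])


class TestFisher:
    def test_diagonal_three(self):
        assert fisher_exact([[3, 0], [0, 3]]).p_value == pytest.approx(0.1)

    def test_two_by_two_singletons(self):
        assert fisher_exact([[1, 0], [0, 1]]).p_value == pytest.approx(1.0)

    def test_zero_row_margin(self):
        assert fisher_exact([[0, 0], [3, 4]]).p_value == pytest.approx(1.0)

    def test_matches_hypergeometric_enumeration(self, rng):
        for _ in range(60):
            a, b, c, d = (int(v) for v in rng.integers(0, 9, size=4))
            if (a + b) == 0 or (c + d) == 0:
                continue
            ours = fisher_exact([[a, b], [c, d]]).p_value
            assert ours == pytest.approx(
                fisher_enumeration_p(a, b, c, d), abs=1e-9
            )

    def test_non_2x2_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact([[1, 2, 3], [4, 5, 6]])


class TestChi2:
    def test_grade_counts_display(self):
        res = pearson_chi2([[6, 43], [10, 41]])
        assert res.display_p == "0.3"

    def test_xrt_counts_display(self):
        res = pearson_chi2([[41, 8], [31, 13]])
        assert res.display_p == "0.13"

    def test_identical_proportions_gives_zero_statistic(self):
        res = pearson_chi2([[10, 20], [5, 10]])
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_zero_expected_suggests_fisher(self):
        with pytest.raises(ValueError, match="fisher"):
            pearson_chi2([[0, 0], [3, 4]])


class TestDisplayRule:
    @pytest.mark.parametrize(
        "p,shown",
        [
            (0.0005, "<0.001"),
            (0.009, "0.009"),
            (0.0102, "0.01"),
            (0.1279, "0.13"),
            (0.186, "0.19"),
            (0.315, "0.3"),
            (0.5, "0.5"),
            (0.84, "0.8"),
        ],
    )
    def test_examples(self, p, shown):
        assert display_p(p) == shown

    def test_round_trip(self, rng):
        for p in rng.random(100):
            shown = display_p(float(p))
            if shown.startswith("<"):
                assert p < 0.001
            else:
                back = float(shown)
                decimals = len(shown.split(".")[1]) if "." in shown else 0
                assert back == pytest.approx(p, abs=0.5 * 10 ** -decimals + 1e-12)


@pytest.fixture(scope="module")
def table():
    return summary_table(published_cohort_manifest(), PUBLISHED_COVARIATES)


class TestSummaryTable:
    def _cell(self, table, characteristic, level, col):
        sub = table[
            (table["characteristic"] == characteristic)
            & (table["level"] == level)
        ]
        return sub.iloc[0][col]

    def test_xrt_unknown_exclusion_denominator(self, table):
        # 31 of 51 received XRT but 7 unknown: 31/44 -> 70%
        assert self._cell(table, "XRT", "Yes", "NAA") == "31 (70%)"
        assert self._cell(table, "XRT", "Yes", "AA") == "41 (84%)"

    def test_chemotherapy_full_denominator(self, table):
        assert self._cell(table, "Chemotherapy", "Yes", "AA") == "37 (76%)"

    def test_histology_idc_percentages(self, table):
        assert self._cell(table, "Histology", "IDC", "AA") == "40 (87%)"
        assert self._cell(table, "Histology", "IDC", "NAA") == "44 (86%)"

    def test_stage_small_percentages(self, table):
        assert self._cell(table, "Stage", "IIB", "AA") == "13 (27%)"
        assert self._cell(table, "Stage", "IIIA", "AA") == "2 (4.1%)"

    def test_chi2_p_values_match_published_display(self, table):
        grade = table[table["characteristic"] == "Grade"].iloc[0]
        xrt = table[table["characteristic"] == "XRT"].iloc[0]
        assert grade["display_p"] == "0.3"
        assert xrt["display_p"] == "0.13"

    def test_unknowns_listed_without_percent(self, table):
        unk = table[
            (table["characteristic"] == "XRT") & (table["level"] == "Unknown")
        ].iloc[0]
        assert unk["NAA"] == "7" and unk["AA"] == "0"

    def test_single_level_covariate_gets_no_test(self):
        m = pd.DataFrame(
            {
                "section_id": list("abcd"),
                "group": ["x", "x", "y", "y"],
                "site": ["breast"] * 4,
            }
        )
        out = summary_table(m, {"site": "categorical"})
        assert out.iloc[0]["display_p"] == "-"

    def test_continuous_covariate_median_iqr(self):
        m = pd.DataFrame(
            {
                "section_id": [f"s{i}" for i in range(8)],
                "group": ["x"] * 4 + ["y"] * 4,
                "age": [40, 50, 60, 70, 45, 55, 65, np.nan],
            }
        )
        out = summary_table(m, {"age": "continuous"})
        assert out.iloc[0]["x"] == "55 (47.5, 62.5)"
        assert "Unknown" in set(out["level"])


class TestCompareMarkers:
    def _sections(self, scores_a, scores_b, marker="CD45"):
        rows = []
        for i, s in enumerate(scores_a):
            rows.append(
                {"section_id": f"a{i}", "group": "a", "marker": marker,
                 "compartment": "stromal", "median_score": s}
            )
        for i, s in enumerate(scores_b):
            rows.append(
                {"section_id": f"b{i}", "group": "b", "marker": marker,
                 "compartment": "stromal", "median_score": s}
            )
        return pd.DataFrame(rows)

    def test_identical_groups_p_one(self):
        vals = [1.0, 2.0, 3.0, 4.0]
        out = compare_markers(self._sections(vals, vals))
        assert (out["p_value"] == 1.0).all()

    def test_section_order_invariance(self, rng):
        df = self._sections(list(rng.random(10)), list(rng.random(10)))
        base = compare_markers(df)
        shuffled = compare_markers(df.sample(frac=1, random_state=1))
        assert base["p_value"].tolist() == shuffled["p_value"].tolist()

    def test_activation_contingency_appended(self):
        df = self._sections([1, 2, 3], [4, 5, 6])
        act = pd.DataFrame(
            {
                "section_id": ["a0", "a1", "a2", "b0", "b1", "b2"],
                "group": ["a"] * 3 + ["b"] * 3,
                "status": ["active"] * 3 + ["dormant"] * 3,
            }
        )
        out = compare_markers(df, activation=act)
        fish = out[out["method"] == "fisher_exact"].iloc[0]
        assert fish["p_value"] == pytest.approx(0.1)

    def test_marker_missing_in_one_group_skipped(self):
        df = self._sections([1, 2, 3], [4, 5, 6])
        extra = self._sections([1, 2, 3], [], marker="CD3")
        out = compare_markers(pd.concat([df, extra], ignore_index=True))
        assert out["marker"].tolist() == ["CD45"]

    def test_bh_column_optional(self, rng):
        df = pd.concat(
            [
                self._sections(list(rng.random(6)), list(rng.random(6)), marker=m)
                for m in ("CD45", "CD3", "CD8")
            ]
        )
        out = compare_markers(df, bh_adjust=True)
        assert "p_bh" in out.columns
        assert (out["p_bh"] >= out["p_value"] - 1e-12).all()
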