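"""Case-control statistics and cohort reporting.

Section-level marker scores are compared between the two patient groups with
the two-sided Mann-Whitney U test; categorical status (active vs dormant
T cells) with Fisher's exact test; cohort summary tables use Pearson's
chi-squared (no continuity correction) unless expected counts are small.
Significance is declared at alpha = 0.05 with no multiplicity adjustment by
default (an optional Benjamini-Hochberg column is available).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TestResult",
    "display_p",
    "mann_whitney",
    "fisher_exact",
    "pearson_chi2",
    "summary_table",
    "compare_markers",
    "ALPHA",
]

logger = logging.getLogger(__name__)

ALPHA = 0.05
_EXACT_MAX_N = 16  # total n at or below which the exact MW null is enumerated


@dataclass(frozen=True)
class TestResult:
    method: str
    statistic: float
    p_value: float
    significant: bool
    display_p: str

    @classmethod
    def from_p(cls, method: str, statistic: float, p: float) -> "TestResult":
        p = float(min(1.0, max(0.0, p)))
        return cls(method, float(statistic), p, p < ALPHA, display_p(p))


def display_p(p: float) -> str:
    """Journal-style p display: "<0.001"; 2 significant figures below 0.2;
    1 significant figure at or above 0.2."""
    if p < 0.001:
        return "<0.001"
    if p < 0.2:
        return f"{p:.2g}"
    return f"{p:.1g}"


def mann_whitney(x, y) -> TestResult:
    """Two-sided Mann-Whitney U comparison of two score samples.

    The exact null distribution is used when the pooled sample is small
    (n <= 16) and tie-free; otherwise the normal approximation with tie and
    continuity corrections.  Two identical constant samples are maximally
    compatible with the null: p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 1 or y.size < 1:
        raise ValueError("both groups need at least one observation")
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        return TestResult.from_p("mann_whitney", x.size * y.size / 2.0, 1.0)
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (pooled.size <= _EXACT_MAX_N and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    p = res.pvalue
    if res.statistic == x.size * y.size / 2.0:
        # U at the null centre: every assignment is at least as extreme, so
        # the two-sided p is exactly 1 (the normal approximation understates
        # this for tied data)
        p = 1.0
    return TestResult.from_p("mann_whitney", res.statistic, p)


def _as_table(t) -> np.ndarray:
    arr = np.asarray(t)
    if arr.ndim != 2 or min(arr.shape) < 2:
        raise ValueError("contingency table must be at least 2x2")
    if (arr < 0).any():
        raise ValueError("contingency table counts must be non-negative")
    return arr


def fisher_exact(table) -> TestResult:
    """Two-sided Fisher's exact test on a 2x2 table.

    p is the total hypergeometric probability of all margin-preserving tables
    no more probable than the observed one.  A zero margin makes every table
    equally extreme: p = 1.
    """
    arr = _as_table(table)
    if arr.shape != (2, 2):
        raise ValueError("fisher_exact requires a 2x2 table")
    odds, p = sps.fisher_exact(arr, alternative="two-sided")
    return TestResult.from_p("fisher_exact", odds, p)


def pearson_chi2(table, *, continuity_correction: bool = False) -> TestResult:
    """Pearson chi-squared test of independence on an r x c table.

    No Yates correction by default.  A zero expected count leaves the
    statistic undefined; use :func:`fisher_exact` instead.
    """
    arr = _as_table(table)
    expected = sps.contingency.expected_freq(arr)
    if (expected == 0).any():
        raise ValueError(
            "zero expected count: chi-squared undefined, use fisher_exact"
        )
    res = sps.chi2_contingency(arr, correction=continuity_correction)
    return TestResult.from_p("pearson_chi2", res.statistic, res.pvalue)


def _categorical_test(sub: pd.DataFrame, value_col: str, group_col: str) -> TestResult | None:
    """Expected-count dispatch: Fisher for sparse 2x2, chi-squared otherwise."""
    tab = pd.crosstab(sub[value_col], sub[group_col])
    if tab.shape[0] < 2 or tab.shape[1] < 2:
        return None
    arr = tab.to_numpy()
    expected = sps.contingency.expected_freq(arr)
    if arr.shape == (2, 2) and (expected < 5).any():
        return fisher_exact(arr)
    if (expected == 0).any():
        logger.warning("zero expected count for %s; no test reported", value_col)
        return None
    return pearson_chi2(arr)


def _fmt_pct(n: int, denom: int) -> str:
    if denom == 0:
        return f"{n}"
    pct = 100.0 * n / denom
    if pct < 10:
        return f"{n} ({pct:.1f}%)"
    return f"{n} ({pct:.0f}%)"


def _fmt_cont(vals: np.ndarray) -> str:
    q1, med, q3 = np.percentile(vals, [25, 50, 75])
    return f"{med:.3g} ({q1:.3g}, {q3:.3g})"


def summary_table(
    manifest: pd.DataFrame,
    covariates: dict[str, str],
    *,
    group_col: str = "group",
    unknown_token: str = "Unknown",
) -> pd.DataFrame:
    """Cohort characteristics table in the n (%) / median (IQR) convention.

    ``covariates`` maps column name to "continuous" or "categorical".
    Continuous rows show median (Q1, Q3) per group with a Mann-Whitney p;
    categorical rows show n (%) per level where the percentage denominator
    excludes unknowns, and unknowns are listed as bare counts outside both
    the denominator and the test.  A single-level covariate gets no test.

    Returns a tidy frame: characteristic, level, one display column per
    group, p_value (on the first row of each characteristic), display_p,
    method.
    """
    groups = list(pd.unique(manifest[group_col]))
    if len(groups) != 2:
        raise ValueError("summary_table expects exactly two groups")
    rows = []
    for cov, kind in covariates.items():
        if kind == "continuous":
            vals = {g: manifest.loc[manifest[group_col] == g, cov] for g in groups}
            known = {g: v[~pd.isna(v)].to_numpy(dtype=float) for g, v in vals.items()}
            res = (
                mann_whitney(known[groups[0]], known[groups[1]])
                if all(v.size for v in known.values())
                else None
            )
            rows.append(
                {
                    "characteristic": cov,
                    "level": "",
                    groups[0]: _fmt_cont(known[groups[0]]),
                    groups[1]: _fmt_cont(known[groups[1]]),
                    "p_value": res.p_value if res else np.nan,
                    "display_p": res.display_p if res else "-",
                    "method": res.method if res else "-",
                }
            )
            n_unk = {g: int(pd.isna(vals[g]).sum()) for g in groups}
            if any(n_unk.values()):
                rows.append(
                    {
                        "characteristic": cov,
                        "level": unknown_token,
                        groups[0]: str(n_unk[groups[0]]),
                        groups[1]: str(n_unk[groups[1]]),
                        "p_value": np.nan,
                        "display_p": "",
                        "method": "",
                    }
                )
        elif kind == "categorical":
            col = manifest[cov].astype(object)
            is_unknown = pd.isna(col) | (col == unknown_token)
            known = manifest[~is_unknown]
            res = _categorical_test(known, cov, group_col)
            denom = {
                g: int((known[group_col] == g).sum()) for g in groups
            }
            levels = sorted(pd.unique(known[cov]).tolist(), key=str)
            first = True
            for lev in levels:
                cnt = {
                    g: int(
                        ((known[cov] == lev) & (known[group_col] == g)).sum()
                    )
                    for g in groups
                }
                rows.append(
                    {
                        "characteristic": cov,
                        "level": str(lev),
                        groups[0]: _fmt_pct(cnt[groups[0]], denom[groups[0]]),
                        groups[1]: _fmt_pct(cnt[groups[1]], denom[groups[1]]),
                        "p_value": (res.p_value if res and first else np.nan),
                        "display_p": (res.display_p if res else "-") if first else "",
                        "method": (res.method if res else "-") if first else "",
                    }
                )
                first = False
            n_unk = {
                g: int((is_unknown & (manifest[group_col] == g)).sum())
                for g in groups
            }
            if any(n_unk.values()):
                rows.append(
                    {
                        "characteristic": cov,
                        "level": unknown_token,
                        groups[0]: str(n_unk[groups[0]]),
                        groups[1]: str(n_unk[groups[1]]),
                        "p_value": np.nan,
                        "display_p": "",
                        "method": "",
                    }
                )
        else:
            raise ValueError(f"covariate {cov!r}: unknown kind {kind!r}")
    return pd.DataFrame(rows)


def compare_markers(
    sections: pd.DataFrame,
    *,
    group_col: str = "group",
    score_col: str = "median_score",
    activation: pd.DataFrame | None = None,
    bh_adjust: bool = False,
) -> pd.DataFrame:
    """Per-(marker, compartment) group comparison on section-level scores.

    ``sections`` is long-format: section_id, group, marker, compartment,
    median_score.  Each pair gets a two-sided Mann-Whitney U on the section
    medians; pairs missing in one group are skipped with a logged reason.
    When ``activation`` (columns section_id, group, status) is given a
    Fisher's exact test of active/dormant x group is appended.  No
    multiplicity adjustment by default; ``bh_adjust`` adds a
    Benjamini-Hochberg column.
    """
    groups = list(pd.unique(sections[group_col]))
    if len(groups) != 2:
        raise ValueError("need exactly two groups")
    rows = []
    for (marker, comp), grp in sections.groupby(
        ["marker", "compartment"], sort=False
    ):
        x = grp.loc[grp[group_col] == groups[0], score_col].dropna()
        y = grp.loc[grp[group_col] == groups[1], score_col].dropna()
        if x.size < 2 or y.size < 2:
            logger.warning(
                "%s/%s: fewer than 2 sections in a group; skipped", marker, comp
            )
            continue
        res = mann_whitney(x, y)
        rows.append(
            {
                "marker": marker,
                "compartment": comp,
                "method": res.method,
                "statistic": res.statistic,
                "p_value": res.p_value,
                "significant": res.significant,
                "display_p": res.display_p,
                "n_a": int(x.size),
                "n_b": int(y.size),
            }
        )
    if activation is not None and len(activation):
        tab = pd.crosstab(activation["status"], activation[group_col])
        tab = tab.reindex(
            index=["active", "dormant"], columns=groups, fill_value=0
        )
        res = fisher_exact(tab.to_numpy())
        rows.append(
            {
                "marker": "T-cell status",
                "compartment": "CD3",
                "method": res.method,
                "statistic": res.statistic,
                "p_value": res.p_value,
                "significant": res.significant,
                "display_p": res.display_p,
                "n_a": int(tab[groups[0]].sum()),
                "n_b": int(tab[groups[1]].sum()),
            }
        )
    out = pd.DataFrame(rows)
    if bh_adjust and len(out):
        out["p_bh"] = sps.false_discovery_control(out["p_value"], method="bh")
    return out
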