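"""Two-tier nonparametric feature screening.

For every feature of a labelled per-test table:

1. a Kruskal–Wallis test over the populated class distributions asks
   whether *any* class differs;
2. pairwise Mann–Whitney U tests compare class distributions directly —
   Binary Analysis (BA) compares the relaxed baseline (class 0) against
   each altered class (4 pairs), Overall Analysis (OA) compares all
   C(5,2) = 10 pairs — with Benjamini–Hochberg false-discovery-rate
   correction applied within each feature's family of pairwise p-values
   (optionally pooled across all features).

Summary counts mirror the study's reporting: *test significance* is the
number of features with Kruskal–Wallis p < α, and *feature
significance(>n)* the number of features significant (after BH) in at
least n+1 pairwise comparisons.  A bullet matrix marks, per test, the
features significant in all four baseline comparisons; features bulleted
in every test form the common list.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .dataset import FeatureTable

logger = logging.getLogger(__name__)

N_CLASSES = 5
BA_PAIRS = tuple((0, c) for c in range(1, N_CLASSES))
OA_PAIRS = tuple(itertools.combinations(range(N_CLASSES), 2))


@dataclass
class ScreeningConfig:
    alpha_kw: float = 0.05
    fdr_q: float = 0.05
    mode: str = "BA"                 # "BA" | "OA"
    exact_threshold: int = 8         # max per-group n for exact M-W enumeration
    bh_scope: str = "per_feature"    # "per_feature" | "pooled"

    def __post_init__(self) -> None:
        if not (0 < self.alpha_kw < 1 and 0 < self.fdr_q < 1):
            raise ValueError("alpha_kw and fdr_q must lie in (0, 1)")
        if self.mode not in ("BA", "OA"):
            raise ValueError("mode must be 'BA' or 'OA'")
        if self.bh_scope not in ("per_feature", "pooled"):
            raise ValueError("bh_scope must be 'per_feature' or 'pooled'")

    @property
    def pairs(self) -> tuple:
        return BA_PAIRS if self.mode == "BA" else OA_PAIRS


@dataclass
class TestResult:
    """One rank-test outcome (H for Kruskal–Wallis, U for Mann–Whitney)."""

    statistic: float
    p_value: float
    group_sizes: tuple
    tie_corrected: bool
    method: str

    def __post_init__(self) -> None:
        if not 0 <= self.p_value <= 1:
            raise ValueError(f"p-value out of range: {self.p_value}")


@dataclass
class PairResult:
    classes: tuple
    result: TestResult
    p_adjusted: float = float("nan")
    reject: bool = False


@dataclass
class FeatureScreen:
    feature: str
    kw: TestResult | None
    pairs: list[PairResult] = field(default_factory=list)
    skipped_pairs: list[tuple] = field(default_factory=list)

    @property
    def n_significant_pairs(self) -> int:
        return sum(p.reject for p in self.pairs)


@dataclass
class ScreeningReport:
    test: str
    config: ScreeningConfig
    features: dict[str, FeatureScreen]

    def kw_significant_features(self) -> list[str]:
        a = self.config.alpha_kw
        return [f for f, s in self.features.items()
                if s.kw is not None and s.kw.p_value < a]

    def bulleted_features(self) -> list[str]:
        """Features significant in ALL class-0 pairwise comparisons (BA)."""
        n_pairs = len(self.config.pairs)
        return [f for f, s in self.features.items()
                if len(s.pairs) == n_pairs and s.n_significant_pairs == n_pairs]

    def to_dict(self) -> dict:
        return {
            "test": self.test,
            "mode": self.config.mode,
            "alpha_kw": self.config.alpha_kw,
            "fdr_q": self.config.fdr_q,
            "features": {
                f: {
                    "kw_statistic": None if s.kw is None else s.kw.statistic,
                    "kw_p": None if s.kw is None else s.kw.p_value,
                    "pairs": [
                        {"classes": list(p.classes), "U": p.result.statistic,
                         "p": p.result.p_value, "p_adj": p.p_adjusted,
                         "reject": bool(p.reject)}
                        for p in s.pairs
                    ],
                    "skipped_pairs": [list(p) for p in s.skipped_pairs],
                }
                for f, s in self.features.items()
            },
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)


# ----------------------------------------------------------------------
# elementary tests
# ----------------------------------------------------------------------

def _clean(sample) -> np.ndarray:
    a = np.asarray(sample, dtype=float)
    return a[np.isfinite(a)]


def kruskal_wallis(groups) -> TestResult:
    """Mid-rank Kruskal–Wallis H with tie correction; chi-square p-value."""
    groups = [_clean(g) for g in groups]
    if len(groups) < 2 or any(g.size == 0 for g in groups):
        raise ValueError("Kruskal-Wallis requires >= 2 non-empty groups")
    sizes = tuple(g.size for g in groups)
    pooled = np.concatenate(groups)
    ties = np.unique(pooled).size < pooled.size
    if np.all(pooled == pooled[0]):
        return TestResult(0.0, 1.0, sizes, True, "kruskal-wallis")
    h, p = stats.kruskal(*groups)
    return TestResult(float(h), float(p), sizes, ties, "kruskal-wallis")


def mann_whitney_u(x, y, exact_threshold: int = 8) -> TestResult:
    """Two-sided Mann–Whitney U.

    Exact null enumeration for small tie-free samples (both n ≤
    ``exact_threshold``); otherwise the normal approximation with
    mid-ranks, tie-corrected variance and continuity correction.
    """
    x, y = _clean(x), _clean(y)
    if x.size == 0 or y.size == 0:
        raise ValueError("Mann-Whitney requires two non-empty samples")
    sizes = (x.size, y.size)
    pooled = np.concatenate([x, y])
    ties = np.unique(pooled).size < pooled.size
    if np.all(pooled == pooled[0]):
        return TestResult(x.size * y.size / 2.0, 1.0, sizes, True, "mann-whitney-tie-degenerate")
    exact = (not ties) and max(sizes) <= exact_threshold
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided",
        method="exact" if exact else "asymptotic",
        use_continuity=True,
    )
    return TestResult(float(res.statistic), float(min(res.pvalue, 1.0)), sizes,
                      ties, "mann-whitney-exact" if exact else "mann-whitney-normal")


def bh_adjust(p_values, q: float = 0.05):
    """Benjamini–Hochberg step-up; returns (reject flags, adjusted p)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return reject, p_adj


# ----------------------------------------------------------------------
# table-level screening
# ----------------------------------------------------------------------

def run_screening(table: FeatureTable, cfg: ScreeningConfig | None = None) -> ScreeningReport:
    """Screen every catalogue feature of one test's table.

    Uses normalized values when present, raw values otherwise.  A pairwise
    comparison whose classes have fewer than 2 observations for a feature
    is skipped and logged; the Kruskal–Wallis test runs over whichever
    classes are populated (needs at least 2).
    """
    cfg = cfg or ScreeningConfig()
    value_col = "normalized" if "normalized" in table.data else "value"
    df = table.data
    screens: dict[str, FeatureScreen] = {}
    for feature, sub in df.groupby("feature", sort=False):
        by_class = {
            c: _clean(sub.loc[sub["class"] == c, value_col])
            for c in range(N_CLASSES)
        }
        populated = [c for c in range(N_CLASSES) if by_class[c].size > 0]
        kw = None
        if len(populated) >= 2:
            kw = kruskal_wallis([by_class[c] for c in populated])
        pairs, skipped = [], []
        for a, b in cfg.pairs:
            if by_class[a].size < 2 or by_class[b].size < 2:
                skipped.append((a, b))
                logger.warning("%s / %s: pair %s skipped (class with <2 observations)",
                               table.test, feature, (a, b))
                continue
            res = mann_whitney_u(by_class[a], by_class[b], cfg.exact_threshold)
            pairs.append(PairResult(classes=(a, b), result=res))
        screens[feature] = FeatureScreen(feature=feature, kw=kw, pairs=pairs,
                                         skipped_pairs=skipped)
    if len({c for _, sub in df.groupby("feature") for c in sub["class"].unique()}) < 2:
        raise ValueError("screening requires at least 2 populated classes")

    # BH correction
    if cfg.bh_scope == "per_feature":
        for s in screens.values():
            if not s.pairs:
                continue
            reject, p_adj = bh_adjust([p.result.p_value for p in s.pairs], cfg.fdr_q)
            for pr, r, pa in zip(s.pairs, reject, p_adj):
                pr.reject, pr.p_adjusted = bool(r), float(pa)
    else:
        flat = [p for s in screens.values() for p in s.pairs]
        if flat:
            reject, p_adj = bh_adjust([p.result.p_value for p in flat], cfg.fdr_q)
            for pr, r, pa in zip(flat, reject, p_adj):
                pr.reject, pr.p_adjusted = bool(r), float(pa)
    return ScreeningReport(test=table.test, config=cfg, features=screens)


def significance_counts(report: ScreeningReport,
                        alpha_kw: float | None = None) -> pd.DataFrame:
    """Summary rows: KW-significant feature count, then feature counts
    significant in more than n pairwise comparisons (n = 1..#pairs−1)."""
    alpha = report.config.alpha_kw if alpha_kw is None else alpha_kw
    n_pairs = len(report.config.pairs)
    rows = [{"row": "test_significance",
             "count": sum(s.kw is not None and s.kw.p_value < alpha
                          for s in report.features.values())}]
    for n in range(1, n_pairs):
        rows.append({
            "row": f"feature_significance_gt{n}",
            "count": sum(s.n_significant_pairs > n for s in report.features.values()),
        })
    return pd.DataFrame(rows)


def bullet_matrix(reports: dict[str, ScreeningReport]):
    """Feature × test boolean matrix of all-baseline-pairs significance.

    All reports must be BA-mode over the same feature set.  Returns
    ``(matrix, common_features)`` where ``common_features`` are the
    features bulleted in every test.
    """
    if not reports:
        raise ValueError("no reports given")
    feature_sets = [tuple(r.features.keys()) for r in reports.values()]
    if len(set(map(frozenset, feature_sets))) != 1:
        raise ValueError("reports cover mismatched feature sets")
    for name, r in reports.items():
        if r.config.mode != "BA":
            raise ValueError(f"bullet matrix requires BA-mode reports (test {name!r} is "
                             f"{r.config.mode})")
    features = feature_sets[0]
    matrix = pd.DataFrame(
        {name: [f in set(r.bulleted_features()) for f in features]
         for name, r in reports.items()},
        index=list(features),
    )
    common = [f for f in features if bool(matrix.loc[f].all())]
    return matrix, common
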