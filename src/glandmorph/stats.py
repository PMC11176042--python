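"""Nonparametric group statistics and implantation-table arithmetic.

The statistical layer used for gland morphometry and implantation data:
two-sided Mann–Whitney (exact enumeration for small tie-free samples,
tie-corrected normal approximation otherwise), Kruskal–Wallis with Dunn's
pairwise post-hoc z-tests, the pooled two-proportion Z-test for category
counts, and the pure-integer arithmetic of implantation/rescue tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb, erf, sqrt

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TestResult",
    "ImplantationTable",
    "mann_whitney",
    "kruskal_wallis_dunn",
    "two_proportion_ztest",
    "embryos_per_mouse",
    "rescue_percentages",
]

EXACT_MW_MAX_N = 12


@dataclass
class TestResult:
    test_name: str
    groups: list[str]
    statistic: float
    p_value: float
    method_detail: str = ""
    adjusted_p: float | None = None
    pairwise: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p-value must lie in [0, 1]")
        if self.adjusted_p is not None and self.adjusted_p < self.p_value - 1e-12:
            raise ValueError("adjusted p cannot be below the raw p")

    def as_row(self) -> dict:
        return {
            "test_name": self.test_name,
            "groups": "|".join(self.groups),
            "statistic": self.statistic,
            "p_value": self.p_value,
            "adjusted_p": self.adjusted_p,
            "method_detail": self.method_detail,
        }


def _midranks(values: np.ndarray) -> np.ndarray:
    return sps.rankdata(values, method="average")


def _norm_sf2(z: float) -> float:
    """Two-sided normal tail probability."""
    return 2.0 * 0.5 * (1.0 - erf(abs(z) / sqrt(2.0)))


def _exact_mw(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Exact two-sided Mann–Whitney by enumeration over rank assignments.

    Midranks are used so tied data remain well-defined; under the null the
    U distribution is symmetric about n1*n2/2, and the two-sided p-value is
    the probability of a U at least as far from that center as observed.
    """
    n1, n2 = len(a), len(b)
    pooled = np.concatenate([a, b])
    ranks = _midranks(pooled)
    u_obs = float(np.sum(ranks[:n1])) - n1 * (n1 + 1) / 2.0
    center = n1 * n2 / 2.0
    n = n1 + n2
    total = comb(n, n1)
    hits = 0
    obs_dev = abs(u_obs - center)
    for idx in combinations(range(n), n1):
        u = float(ranks[list(idx)].sum()) - n1 * (n1 + 1) / 2.0
        if abs(u - center) >= obs_dev - 1e-12:
            hits += 1
    return u_obs, hits / total


def mann_whitney(a, b, mode: str = "auto") -> TestResult:
    """Two-sided Mann–Whitney U test.

    ``mode="exact"`` enumerates all rank assignments (midranks for ties);
    ``"auto"`` uses the exact test when ``n_a + n_b <= 12`` and no ties are
    present, and the tie-corrected normal approximation (with continuity
    correction) otherwise.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be nonempty")
    if mode not in ("exact", "auto"):
        raise ValueError(f"unknown mode {mode!r}")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    small = len(pooled) <= EXACT_MW_MAX_N
    if mode == "exact" and len(pooled) > 2 * EXACT_MW_MAX_N:
        raise ValueError("exact mode is limited to n_a + n_b <= 24")
    if mode == "exact" or (small and not has_ties):
        u, p = _exact_mw(a, b)
        detail = "exact enumeration over midranks" if has_ties else "exact enumeration"
    else:
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        u, p = float(res.statistic), float(res.pvalue)
        detail = "normal approximation, tie-corrected, continuity-corrected"
    return TestResult(
        test_name="mann_whitney",
        groups=["a", "b"],
        statistic=u,
        p_value=min(p, 1.0),
        method_detail=detail,
    )


def _dunn_pairwise(
    groups: list[np.ndarray], names: list[str], adjust: str
) -> pd.DataFrame:
    pooled = np.concatenate(groups)
    n = len(pooled)
    ranks = _midranks(pooled)
    mean_ranks = []
    start = 0
    for g in groups:
        mean_ranks.append(float(ranks[start : start + len(g)].mean()))
        start += len(g)
    # tie correction to the rank variance
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts)) / (12.0 * (n - 1)) if n > 1 else 0.0
    var_base = n * (n + 1) / 12.0 - tie_term
    m = comb(len(groups), 2)
    rows = []
    for (i, j) in combinations(range(len(groups)), 2):
        se = sqrt(var_base * (1.0 / len(groups[i]) + 1.0 / len(groups[j])))
        z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
        p = _norm_sf2(z) if se > 0 else 1.0
        rows.append(
            {
                "group_a": names[i],
                "group_b": names[j],
                "z": z,
                "p_value": p,
            }
        )
    df = pd.DataFrame(rows)
    if adjust == "bonferroni":
        df["adjusted_p"] = np.minimum(df["p_value"] * m, 1.0)
    elif adjust == "holm":
        order = np.argsort(df["p_value"].to_numpy())
        adj = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * df["p_value"].iloc[idx])
            adj[idx] = min(running, 1.0)
        df["adjusted_p"] = adj
    elif adjust == "none":
        df["adjusted_p"] = df["p_value"]
    else:
        raise ValueError(f"unknown adjustment {adjust!r}")
    return df


def kruskal_wallis_dunn(
    groups,
    names: list[str] | None = None,
    adjust: str = "bonferroni",
) -> TestResult:
    """Kruskal–Wallis H (tie-corrected) with Dunn's pairwise post-hoc tests.

    With exactly two groups the comparison delegates to the Mann–Whitney
    test.  Degenerate input (all values identical across all groups) is
    reported as H = 0, p = 1.
    """
    arrs = [np.asarray(g, float) for g in groups]
    if any(len(g) == 0 for g in arrs):
        raise ValueError("every group must be nonempty")
    if len(arrs) < 2:
        raise ValueError("need at least two groups")
    names = names or [f"g{i}" for i in range(len(arrs))]
    if len(names) != len(arrs):
        raise ValueError("one name per group required")
    if len(arrs) == 2:
        return mann_whitney(arrs[0], arrs[1])
    pooled = np.concatenate(arrs)
    if np.ptp(pooled) == 0:
        pw = _dunn_pairwise(arrs, names, adjust)
        return TestResult(
            test_name="kruskal_wallis",
            groups=names,
            statistic=0.0,
            p_value=1.0,
            method_detail="degenerate: all values identical",
            pairwise=pw,
        )
    h, p = sps.kruskal(*arrs)
    pw = _dunn_pairwise(arrs, names, adjust)
    return TestResult(
        test_name="kruskal_wallis",
        groups=names,
        statistic=float(h),
        p_value=float(p),
        method_detail=f"tie-corrected H; Dunn post-hoc with {adjust} adjustment",
        pairwise=pw,
    )


def two_proportion_ztest(x1: int, n1: int, x2: int, n2: int) -> TestResult:
    """Pooled-variance two-proportion Z-test, two-sided.

    A pooled proportion of exactly 0 or 1 makes the variance vanish; that
    degenerate case is flagged and reported as z = 0, p = 1.
    """
    for x, n in ((x1, n1), (x2, n2)):
        if n < 1:
            raise ValueError("sample sizes must be >= 1")
        if not (0 <= x <= n):
            raise ValueError("counts must satisfy 0 <= x <= n")
    p_pool = (x1 + x2) / (n1 + n2)
    if p_pool in (0.0, 1.0):
        return TestResult(
            test_name="two_proportion_z",
            groups=["1", "2"],
            statistic=0.0,
            p_value=1.0,
            method_detail="degenerate: pooled proportion 0 or 1",
        )
    se = sqrt(p_pool * (1.0 - p_pool) * (1.0 / n1 + 1.0 / n2))
    z = (x1 / n1 - x2 / n2) / se
    return TestResult(
        test_name="two_proportion_z",
        groups=["1", "2"],
        statistic=z,
        p_value=_norm_sf2(z),
        method_detail="pooled variance, normal approximation",
    )


@dataclass
class ImplantationTable:
    """Per-group implantation bookkeeping (mice and embryo counts)."""

    rows: dict[str, dict[str, int]]

    REQUIRED = (
        "n_mice_injected",
        "n_mice_with_embryos",
        "n_mice_with_IS",
        "n_embryos_total",
        "n_embryos_implanted",
    )

    def __post_init__(self) -> None:
        for group, row in self.rows.items():
            missing = [k for k in self.REQUIRED if k not in row]
            if missing:
                raise ValueError(f"group {group!r} missing fields {missing}")
            if any(row[k] < 0 for k in self.REQUIRED):
                raise ValueError(f"group {group!r} has negative counts")
            if not (
                row["n_mice_with_IS"]
                <= row["n_mice_with_embryos"]
                <= row["n_mice_injected"]
            ):
                raise ValueError(
                    f"group {group!r}: need mice_with_IS <= mice_with_embryos"
                    " <= mice_injected"
                )
            if row["n_embryos_implanted"] > row["n_embryos_total"]:
                raise ValueError(
                    f"group {group!r}: implanted embryos exceed total embryos"
                )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, group_col: str = "group") -> "ImplantationTable":
        rows = {
            str(r[group_col]): {k: int(r[k]) for k in cls.REQUIRED}
            for _, r in df.iterrows()
        }
        return cls(rows=rows)

    def __getitem__(self, group: str) -> dict[str, int]:
        return self.rows[group]


def embryos_per_mouse(table: ImplantationTable, group: str) -> float:
    """Average embryos per mouse, over mice where embryos are present."""
    row = table[group]
    if row["n_mice_with_embryos"] < 1:
        raise ValueError(f"group {group!r} has no mice with embryos")
    return row["n_embryos_total"] / row["n_mice_with_embryos"]


def rescue_percentages(table: ImplantationTable, group: str) -> dict[str, float]:
    """Mouse-level and embryo-level implantation rescue percentages.

    Mouse level: mice with implantation sites among mice with embryos.
    Embryo level: implanted embryos among all embryos observed.  Display
    values are rounded to integer percent; full precision is retained.
    """
    row = table[group]
    if row["n_mice_with_embryos"] < 1 or row["n_embryos_total"] < 1:
        raise ValueError(f"group {group!r} has empty denominators")
    mouse = 100.0 * row["n_mice_with_IS"] / row["n_mice_with_embryos"]
    embryo = 100.0 * row["n_embryos_implanted"] / row["n_embryos_total"]
    return {
        "mouse_level_pct": mouse,
        "embryo_level_pct": embryo,
        "mouse_level_display": int(round(mouse)),
        "embryo_level_display": int(round(embryo)),
    }
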