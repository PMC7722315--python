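"""Statistical kernels shared across the pipeline.

Each test is verified against an exact enumeration oracle in the test suite.
Where a scipy routine reproduces the oracle bit-for-bit it is used directly;
the 2x2 chi-square (with the capped Yates continuity correction) and the
Benjamini-Hochberg step-up are implemented in closed form.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts with rows = group, columns = outcome."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("negative count in 2x2 table")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("empty 2x2 table")

    @property
    def margins(self) -> tuple[int, int, int, int]:
        return (self.a + self.b, self.c + self.d, self.a + self.c, self.b + self.d)


def chi_square_2x2(table: ContingencyTable2x2, yates: bool = True) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 table, df=1.

    With ``yates`` the continuity correction |O-E| - 0.5 is applied, capped at
    zero so the correction can never overshoot. Returns (statistic, p); (nan,
    nan) when any margin is zero.
    """
    r1, r2, c1, c2 = table.margins
    if min(r1, r2, c1, c2) == 0:
        return (float("nan"), float("nan"))
    n = r1 + r2
    obs = np.array([[table.a, table.b], [table.c, table.d]], dtype=float)
    exp = np.outer([r1, r2], [c1, c2]) / n
    dev = np.abs(obs - exp)
    if yates:
        dev = np.maximum(dev - 0.5, 0.0)
    stat = float((dev**2 / exp).sum())
    return stat, float(sps.chi2.sf(stat, df=1))


def fisher_one_tailed(table: ContingencyTable2x2, direction: str = "greater") -> float:
    """One-tailed Fisher's exact test (hypergeometric tail at fixed margins)."""
    if direction not in ("greater", "less"):
        raise ValueError(f"invalid direction {direction!r}")
    _, p = sps.fisher_exact(
        [[table.a, table.b], [table.c, table.d]], alternative=direction
    )
    return float(p)


def wilcoxon_rank_sum(
    x: np.ndarray, y: np.ndarray, alternative: str = "two-sided"
) -> float:
    """Wilcoxon rank-sum (Mann-Whitney U) p-value.

    Exact null distribution when min(n) <= 25 and there are no ties; otherwise
    the normal approximation with tie and continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("empty sample")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return 1.0
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (min(len(x), len(y)) <= 25 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative=alternative, method=method)
    return float(res.pvalue)


def welch_t_test(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Welch's unequal-variance t-test with Satterthwaite df."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("Welch t-test needs >=2 observations per group")
    if np.var(x, ddof=1) == 0 and np.var(y, ddof=1) == 0:
        if np.mean(x) == np.mean(y):
            return (0.0, 1.0)
        return (float("nan"), float("nan"))
    res = sps.ttest_ind(x, y, equal_var=False)
    return float(res.statistic), float(res.pvalue)


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1, monotone."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values outside [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty_like(p)
    out[order] = np.minimum(adj, 1.0)
    return out


def empirical_p(observed: float, resampled: np.ndarray) -> float:
    """Add-one empirical upper-tail p-value: (1 + #{resampled >= observed}) / (1 + B).

    The plus-one estimator keeps p strictly positive with finite resamples,
    giving a floor of 1/(B+1) (0.0099 at B=100).
    """
    resampled = np.asarray(resampled, dtype=float)
    return float((1 + np.sum(resampled >= observed)) / (1 + resampled.size))


def go_enrichment(
    subset_rbps: set[str],
    all_rbps: set[str],
    go_annotations: pd.DataFrame,
    min_rbps_per_term: int = 2,
) -> pd.DataFrame:
    """Per-GO-term fold enrichment and one-tailed Fisher p for a subset of RBPs.

    ``go_annotations`` has columns rbp, go_term, domain. Terms annotated in
    fewer than ``min_rbps_per_term`` RBPs (within the background) are excluded.
    Fold = (k/n) / (K/N) with k subset hits, n subset size, K background hits,
    N background size.
    """
    if not subset_rbps <= all_rbps:
        raise ValueError("subset RBPs must be contained in the background set")
    ann = go_annotations[go_annotations["rbp"].isin(all_rbps)]
    n = len(subset_rbps)
    N = len(all_rbps)
    rows = []
    for (term, domain), grp in ann.groupby(["go_term", "domain"], sort=True):
        annotated = set(grp["rbp"])
        K = len(annotated)
        if K < min_rbps_per_term:
            continue
        k = len(annotated & subset_rbps)
        table = ContingencyTable2x2(k, n - k, K - k, (N - n) - (K - k))
        p = fisher_one_tailed(table, direction="greater")
        fold = (k / n) / (K / N) if n > 0 else float("nan")
        rows.append(
            {"go_term": term, "domain": domain, "subset_hits": k, "background_hits": K,
             "fold": fold, "p": p}
        )
    out = pd.DataFrame(rows, columns=["go_term", "domain", "subset_hits",
                                      "background_hits", "fold", "p"])
    if len(out):
        out["fdr"] = bh_adjust(out["p"].to_numpy())
    else:
        out["fdr"] = pd.Series(dtype=float)
    return out


def colocalization_fraction(
    interactions: list[tuple[str, str]],
    circ_compartments: dict[str, set[str]],
    rbp_compartments: dict[str, set[str]],
) -> tuple[float, int, int]:
    """Percent of (circRNA, RBP) pairs sharing a subcellular compartment.

    Pairs whose circRNA or RBP is absent from the localization tables are
    excluded and counted in the returned ``unresolved`` tally.
    Returns (percent_colocalized, n_resolved, n_unresolved).
    """
    resolved = 0
    coloc = 0
    unresolved = 0
    for circ_id, rbp in interactions:
        cc = circ_compartments.get(circ_id)
        rc = rbp_compartments.get(rbp)
        if not cc or not rc:
            unresolved += 1
            continue
        resolved += 1
        if cc & rc:
            coloc += 1
    pct = 100.0 * coloc / resolved if resolved else float("nan")
    return pct, resolved, unresolved
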