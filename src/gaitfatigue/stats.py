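"""Repeated-measures nonparametric battery over normalized gait ratios.

For each of the 90 (channel, feature) outcome blocks the cohort supplies
an n_subjects x 3 matrix of baseline-normalized ratios (columns baseline,
min30, min60; the baseline column is identically 1). The battery runs a
Shapiro-Wilk normality screen (diagnostic only), a tie-corrected Friedman
omnibus test per block, and — for blocks with a significant omnibus — the
three pairwise Wilcoxon signed-rank contrasts with Bonferroni adjustment
(adjusted p = min(1, 3 * raw p), equivalently raw p tested against
0.05/3 ~= 0.017).

The Friedman statistic uses the tie-corrected chi-square form with k-1
degrees of freedom; an exact permutation null (dynamic programming over
all within-row rank permutations) is available behind ``method="exact"``
for small cohorts. The Wilcoxon test discards zero differences before
ranking (Wilcoxon's original rule) and uses the exact null distribution
of the positive-rank sum for n <= 25 — computed by convolution over the
(possibly tied, average) ranks, which equals full enumeration of the 2^n
sign assignments — and a tie-corrected normal approximation beyond.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import PipelineError
from .features import FEATURES, NormalizedFeatureTable
from .io import CHANNELS, WINDOW_LABELS

logger = logging.getLogger(__name__)

#: Pairwise contrast labels, in (column i, column j) order.
CONTRASTS: tuple[tuple[str, int, int], ...] = (
    ("baseline-min30", 0, 1),
    ("baseline-min60", 0, 2),
    ("min30-min60", 1, 2),
)


# ---------------------------------------------------------------------------
# elementary tests


def normality_screen(values: Sequence[float]) -> tuple[float, float]:
    """Shapiro-Wilk W and p for one sample (3 <= n <= 5000).

    Used only to justify the nonparametric path; the result is recorded,
    never used to gate any computation. Constant input is degenerate.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3 or x.size > 5000:
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    if np.ptp(x) == 0:
        raise ValueError("Shapiro-Wilk undefined for a constant sample")
    w, p = sps.shapiro(x)
    return float(w), float(p)


@lru_cache(maxsize=32)
def _friedman_exact_sf(n: int) -> tuple[tuple[float, ...], tuple[float, ...]]:
    """Exact null survival function of the k=3 Friedman statistic.

    Enumerates column rank sums over all 6^n equally likely within-row
    rank permutations by dynamic programming on (R1, R2). Returns sorted
    statistic values and P(Q >= value).
    """
    perms = list(itertools.permutations((1, 2, 3)))
    dist: dict[tuple[int, int], float] = {(0, 0): 1.0}
    for _ in range(n):
        new: dict[tuple[int, int], float] = {}
        for (r1, r2), pr in dist.items():
            for pm in perms:
                key = (r1 + pm[0], r2 + pm[1])
                new[key] = new.get(key, 0.0) + pr / 6.0
        dist = new
    k = 3
    total = n * k * (k + 1) // 2
    qprob: dict[float, float] = {}
    for (r1, r2), pr in dist.items():
        r3 = total - r1 - r2
        q = 12.0 / (n * k * (k + 1)) * (r1**2 + r2**2 + r3**2) - 3.0 * n * (k + 1)
        q = round(q, 10)
        qprob[q] = qprob.get(q, 0.0) + pr
    qs = sorted(qprob)
    sf = np.cumsum([qprob[q] for q in reversed(qs)])[::-1]
    return tuple(qs), tuple(float(v) for v in sf)


def friedman_test(
    block: np.ndarray, method: str = "chisq"
) -> tuple[float, float]:
    """Friedman test across the k=3 repeated conditions of one block.

    ``block`` is an n_subjects x 3 matrix; ties within a subject's row
    receive average ranks. Returns the tie-corrected chi-square-scale
    statistic and its p-value from chi-square with k-1 df
    (``method="chisq"``) or from the exact permutation null
    (``method="exact"``, valid when rows have no ties).
    """
    block = np.asarray(block, dtype=float)
    if block.ndim != 2 or block.shape[1] != 3:
        raise ValueError("block must be an n x 3 matrix")
    n, k = block.shape
    if n < 2:
        raise ValueError("Friedman test requires at least 2 subjects")
    if np.isnan(block).any():
        raise ValueError("block contains missing values; exclude rows upstream")
    ranks = sps.rankdata(block, axis=1)
    col_sums = ranks.sum(axis=0)
    # tie-corrected form: (k-1) * sum (Rj - n(k+1)/2)^2 / (sum r^2 - n k (k+1)^2 / 4)
    denom = float((ranks**2).sum() - n * k * (k + 1) ** 2 / 4.0)
    if denom == 0.0:  # every row fully tied
        return 0.0, 1.0
    num = float((k - 1) * ((col_sums - n * (k + 1) / 2.0) ** 2).sum())
    stat = num / denom
    if method == "chisq":
        p = float(sps.chi2.sf(stat, k - 1))
    elif method == "exact":
        has_ties = any(len(np.unique(row)) < k for row in block)
        if has_ties:
            raise ValueError("exact Friedman null assumes no within-row ties")
        qs, sf = _friedman_exact_sf(n)
        idx = np.searchsorted(np.asarray(qs), stat - 1e-9)
        p = float(sf[idx]) if idx < len(sf) else 0.0
    else:
        raise ValueError(f"unknown method {method!r}")
    return stat, min(p, 1.0)


@dataclass
class WilcoxonResult:
    """Outcome of one paired signed-rank contrast."""

    statistic: float  # positive-rank sum W+
    pvalue: float
    n_used: int
    n_zeros: int
    method: str  # "exact", "approx", or "degenerate"

    @property
    def degenerate(self) -> bool:
        return self.method == "degenerate"


def _wilcoxon_exact_p(ranks2: np.ndarray, w2: int) -> float:
    """Two-sided exact p for doubled ranks ``ranks2`` and doubled W+ ``w2``.

    Convolves the distribution of the positive-rank sum over all 2^n sign
    assignments (each rank included with probability 1/2); average ranks
    are doubled so every value is integral.
    """
    total = int(ranks2.sum())
    pmf = np.zeros(total + 1)
    pmf[0] = 1.0
    for r in ranks2:
        r = int(r)
        shifted = np.zeros_like(pmf)
        shifted[r:] = pmf[: total + 1 - r]
        pmf = 0.5 * (pmf + shifted)
    lower = float(pmf[: w2 + 1].sum())
    upper = float(pmf[w2:].sum())
    return min(1.0, 2.0 * min(lower, upper))


def wilcoxon_signed_rank(
    a: Sequence[float], b: Sequence[float], exact_max_n: int = 25
) -> WilcoxonResult:
    """Two-sided Wilcoxon signed-rank test on paired samples ``a``, ``b``.

    Zero differences are discarded before ranking (count logged and
    reported). The exact null distribution is used for n <= exact_max_n
    after discards, a tie-corrected normal approximation (no continuity
    correction) otherwise. All differences zero is degenerate: p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    d = a - b
    n_zeros = int(np.sum(d == 0))
    d = d[d != 0]
    n = d.size
    if n_zeros:
        logger.debug("discarded %d zero difference(s)", n_zeros)
    if n == 0:
        return WilcoxonResult(0.0, 1.0, 0, n_zeros, "degenerate")
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= exact_max_n:
        ranks2 = np.rint(2.0 * ranks).astype(int)
        w2 = int(round(2.0 * w_plus))
        p = _wilcoxon_exact_p(ranks2, w2)
        return WilcoxonResult(w_plus, p, n, n_zeros, "exact")
    mean = n * (n + 1) / 4.0
    var = float((ranks**2).sum()) / 4.0  # tie-corrected: sum r_i^2 / 4
    if var == 0:
        return WilcoxonResult(w_plus, 1.0, n, n_zeros, "degenerate")
    z = (w_plus - mean) / np.sqrt(var)
    p = float(2.0 * sps.norm.sf(abs(z)))
    return WilcoxonResult(w_plus, min(p, 1.0), n, n_zeros, "approx")


def bonferroni_adjust(raw_p: float, m: int = 3) -> float:
    """Bonferroni-adjusted p-value: min(1, m * raw_p)."""
    if not 0.0 <= raw_p <= 1.0:
        raise ValueError("raw_p must lie in [0, 1]")
    if m < 1:
        raise ValueError("m must be at least 1")
    return min(1.0, m * raw_p)


# ---------------------------------------------------------------------------
# cohort containers and the battery


@dataclass
class CohortTable:
    """Per-(channel, feature) matrices of normalized ratios for a cohort.

    ``blocks[(channel, feature)]`` is an n x 3 array with columns in
    :data:`~gaitfatigue.io.WINDOW_LABELS` order. Subjects with a missing
    (NaN) value in a block are excluded listwise from that block.
    """

    blocks: dict[tuple[str, str], np.ndarray]
    n_subjects: int
    exclusions: dict[tuple[str, str], list[str]] = field(default_factory=dict)

    @classmethod
    def from_subject_tables(
        cls, tables: Sequence[NormalizedFeatureTable]
    ) -> "CohortTable":
        """Assemble cohort blocks from per-subject normalized tables."""
        if not tables:
            raise PipelineError("no subjects supplied")
        blocks: dict[tuple[str, str], np.ndarray] = {}
        exclusions: dict[tuple[str, str], list[str]] = {}
        stacked = {
            w: np.stack([t.ratios[w].to_numpy() for t in tables]) for w in WINDOW_LABELS
        }  # each (n_subj, 9, 10)
        subject_ids = [t.subject_id for t in tables]
        for ci, channel in enumerate(CHANNELS):
            for fi, feature in enumerate(FEATURES):
                mat = np.column_stack(
                    [stacked[w][:, ci, fi] for w in WINDOW_LABELS]
                )
                keep = ~np.isnan(mat).any(axis=1)
                if not keep.all():
                    dropped = [s for s, k in zip(subject_ids, keep) if not k]
                    exclusions[(channel, feature)] = dropped
                    logger.warning(
                        "block (%s, %s): excluded subject(s) %s",
                        channel, feature, dropped,
                    )
                blocks[(channel, feature)] = mat[keep]
        return cls(blocks=blocks, n_subjects=len(tables), exclusions=exclusions)


@dataclass
class StatReport:
    """Results of the full battery over all (channel, feature) blocks.

    ``friedman_p`` / ``friedman_stat`` are features x channels tables
    (the omnibus test per block); ``posthoc`` is a long table of the three
    pairwise contrasts for omnibus-significant blocks with raw and
    Bonferroni-adjusted p-values; ``normality`` records the diagnostic
    Shapiro-Wilk screen of the min30/min60 ratio columns.
    """

    alpha: float
    posthoc_alpha: float
    m_comparisons: int
    n_subjects: int
    friedman_stat: pd.DataFrame
    friedman_p: pd.DataFrame
    posthoc: pd.DataFrame
    normality: pd.DataFrame
    omitted_blocks: list[tuple[str, str]] = field(default_factory=list)

    def significant_blocks(self) -> list[tuple[str, str]]:
        """(channel, feature) pairs with omnibus p < alpha."""
        out = []
        for feature in self.friedman_p.index:
            for channel in self.friedman_p.columns:
                p = self.friedman_p.loc[feature, channel]
                if pd.notna(p) and p < self.alpha:
                    out.append((channel, feature))
        return out

    def count_significant(self) -> int:
        return len(self.significant_blocks())

    def friedman_table(self, stars: bool = True, decimals: int = 3) -> pd.DataFrame:
        """Features x channels table of omnibus p-values, starred at alpha."""
        def fmt(p):
            if pd.isna(p):
                return ""
            s = f"{p:.{decimals}f}"
            return s + " *" if stars and p < self.alpha else s
        return self.friedman_p.map(fmt)

    def posthoc_table(self, decimals: int = 3) -> pd.DataFrame:
        """Wide post hoc table: one row per block, raw/adjusted per contrast."""
        if self.posthoc.empty:
            return pd.DataFrame()
        rows = []
        for (channel, feature), grp in self.posthoc.groupby(
            ["channel", "feature"], sort=False
        ):
            row: dict[str, object] = {"signal": channel, "feature": feature}
            for _, rec in grp.iterrows():
                c = rec["contrast"]
                star = " *" if rec["adjusted_p"] < self.alpha else ""
                row[f"{c} p"] = f"{rec['raw_p']:.{decimals}f}"
                row[f"{c} adjusted p"] = f"{rec['adjusted_p']:.{decimals}f}{star}"
            rows.append(row)
        return pd.DataFrame(rows)


def run_battery(
    cohort: CohortTable,
    alpha: float = 0.05,
    m_comparisons: int = 3,
    friedman_method: str = "chisq",
) -> StatReport:
    """Run the omnibus + post hoc battery over every cohort block.

    Friedman is computed for all blocks; the pairwise Wilcoxon trio (with
    Bonferroni adjustment over ``m_comparisons``) only for blocks whose
    omnibus p is below ``alpha`` — the gating is on the omnibus alone, so
    a significant block may still show no starred pairwise contrast.
    Blocks left with fewer than 2 subjects after exclusions are omitted
    with a log entry.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    fstat = pd.DataFrame(np.nan, index=list(FEATURES), columns=list(CHANNELS))
    fp = pd.DataFrame(np.nan, index=list(FEATURES), columns=list(CHANNELS))
    posthoc_rows = []
    normality_rows = []
    omitted: list[tuple[str, str]] = []
    for (channel, feature), block in cohort.blocks.items():
        if block.shape[0] < 2:
            omitted.append((channel, feature))
            logger.warning(
                "block (%s, %s): fewer than 2 subjects after exclusions; omitted",
                channel, feature,
            )
            continue
        stat, p = friedman_test(block, method=friedman_method)
        fstat.loc[feature, channel] = stat
        fp.loc[feature, channel] = p
        for col, label in ((1, WINDOW_LABELS[1]), (2, WINDOW_LABELS[2])):
            vals = block[:, col]
            try:
                w, sp_ = normality_screen(vals)
            except ValueError:
                w, sp_ = np.nan, np.nan
            normality_rows.append(
                {"channel": channel, "feature": feature, "window": label,
                 "shapiro_w": w, "shapiro_p": sp_}
            )
        if p < alpha:
            for contrast, i, j in CONTRASTS:
                res = wilcoxon_signed_rank(block[:, i], block[:, j])
                adj = bonferroni_adjust(res.pvalue, m_comparisons)
                posthoc_rows.append({
                    "channel": channel, "feature": feature, "contrast": contrast,
                    "statistic": res.statistic, "raw_p": res.pvalue,
                    "adjusted_p": adj, "significant": adj < alpha,
                    "n_used": res.n_used, "n_zeros": res.n_zeros,
                    "method": res.method,
                })
    posthoc = pd.DataFrame(
        posthoc_rows,
        columns=["channel", "feature", "contrast", "statistic", "raw_p",
                 "adjusted_p", "significant", "n_used", "n_zeros", "method"],
    )
    return StatReport(
        alpha=alpha,
        posthoc_alpha=alpha / m_comparisons,
        m_comparisons=m_comparisons,
        n_subjects=cohort.n_subjects,
        friedman_stat=fstat,
        friedman_p=fp,
        posthoc=posthoc,
        normality=pd.DataFrame(normality_rows),
        omitted_blocks=omitted,
    )
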