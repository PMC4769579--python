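"""Resampling-based uncertainty and multiple-testing machinery.

Delete-one block jackknife over contiguous genomic blocks, the moving
block bootstrap with the n^(1/3) block-length rule, two-tailed z-tests,
and Benjamini–Hochberg step-up FDR control.

Ratio statistics (D, f_d) are resampled by recomputing the ratio from
summed block numerators and denominators, matching their definition as
ratios of genome-wide sums rather than means of per-block ratios.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .genotype_io import InsufficientDataError


@dataclass
class ResamplingConfig:
    """Knobs for the resampling schemes.

    jackknife_block_size : genomic block size in bp (default 50 kb,
        larger than typical insect linkage disequilibrium).
    n_bootstrap : moving-block bootstrap replicates B.
    seed : RNG seed, recorded in every stochastic result.
    """

    jackknife_block_size: int = 50_000
    n_bootstrap: int = 1_000
    seed: int = 0

    def __post_init__(self):
        if self.jackknife_block_size <= 0:
            raise ValueError("jackknife block size must be positive")
        if self.n_bootstrap < 100:
            raise ValueError("bootstrap replicate count must be at least 100")


@dataclass
class TestResult:
    """Point estimate with resampling SE and two-tailed z-test."""

    estimate: float
    se: float
    z: float
    p: float
    method: str          # "jackknife" | "bootstrap"
    n_units: int         # blocks (jackknife) or values (bootstrap)
    seed: int | None = None
    significant: bool | None = None  # set after FDR adjustment


def block_jackknife(num: np.ndarray, pos: np.ndarray,
                    block_size: int, den: np.ndarray | None = None) -> TestResult:
    """Delete-one block jackknife of a ratio statistic Σnum / Σden.

    Sites are partitioned into contiguous genomic blocks of ``block_size``
    bp by position; blocks with zero denominator are dropped. With
    ``den=None`` the statistic is the mean of ``num``. The SE follows
    SE² = ((m−1)/m) Σ_i (θ_(−i) − θ̄_(−·))² over m blocks.
    """
    num = np.asarray(num, dtype=float)
    if den is None:
        den = np.ones_like(num)
    den = np.asarray(den, dtype=float)
    pos = np.asarray(pos)
    blocks = pos // block_size
    uniq = np.unique(blocks)
    bn = np.array([num[blocks == b].sum() for b in uniq])
    bd = np.array([den[blocks == b].sum() for b in uniq])
    keep = bd != 0
    bn, bd = bn[keep], bd[keep]
    m = len(bn)
    if m < 2:
        raise InsufficientDataError(f"need >=2 non-empty blocks, got {m}")
    tot_n, tot_d = bn.sum(), bd.sum()
    estimate = tot_n / tot_d
    loo = (tot_n - bn) / (tot_d - bd)
    se = math.sqrt((m - 1) / m * ((loo - loo.mean()) ** 2).sum())
    z, p = z_test_two_tailed(estimate, se)
    return TestResult(float(estimate), float(se), z, p, "jackknife", m)


def bootstrap_block_length(n: int) -> int:
    """Optimal moving-block length ⌈n^(1/3)⌉ (guarding float cube roots)."""
    return int(math.ceil(n ** (1.0 / 3.0) - 1e-9))


def moving_block_bootstrap(num: np.ndarray, B: int, seed: int,
                           den: np.ndarray | None = None) -> TestResult:
    """Moving-block bootstrap SE of a ratio statistic over an ordered series.

    Blocks of length L = ⌈n^(1/3)⌉ starting uniformly on [0, n−L] are
    drawn with replacement, ⌈n/L⌉ per replicate, concatenated and
    truncated to n values; the statistic is recomputed per replicate and
    the SE is the standard deviation over B replicates. Deterministic
    for a fixed seed.
    """
    num = np.asarray(num, dtype=float)
    n = len(num)
    if n < 8:
        raise InsufficientDataError(f"need >=8 values for the bootstrap, got {n}")
    if den is None:
        den = np.ones_like(num)
    den = np.asarray(den, dtype=float)

    L = bootstrap_block_length(n)
    k = math.ceil(n / L)
    rng = np.random.default_rng(seed)
    starts = rng.integers(0, n - L + 1, size=(B, k))
    idx = (starts[:, :, None] + np.arange(L)[None, None, :]).reshape(B, k * L)[:, :n]
    rep_n = num[idx].sum(axis=1)
    rep_d = den[idx].sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        reps = rep_n / rep_d
    reps = reps[np.isfinite(reps)]
    tot_d = den.sum()
    estimate = num.sum() / tot_d if tot_d != 0 else float("nan")
    se = float(np.std(reps, ddof=1)) if len(reps) > 1 else float("nan")
    z, p = z_test_two_tailed(estimate, se)
    return TestResult(float(estimate), se, z, p, "bootstrap", n, seed=seed)


def z_test_two_tailed(estimate: float, se: float) -> tuple[float, float]:
    """Two-tailed normal test of estimate against zero: p = 2(1 − Φ(|z|))."""
    if not np.isfinite(estimate) or not np.isfinite(se):
        return float("nan"), float("nan")
    if se == 0:
        if estimate == 0:
            return 0.0, 1.0
        warnings.warn("zero SE with nonzero estimate; reporting p = 0")
        return math.copysign(math.inf, estimate), 0.0
    z = estimate / se
    return float(z), float(2.0 * stats.norm.sf(abs(z)))


@dataclass
class BHResult:
    """Benjamini–Hochberg step-up outcome for one family of tests."""

    reject: np.ndarray        # bool per hypothesis (input order)
    critical_value: float     # i*q/m at the stopping rank (0 if none)
    adjusted: np.ndarray      # monotone cummin-adjusted p-values
    stop_rank: int            # largest i with p_(i) <= i*q/m (0 if none)


def bh_fdr(p: np.ndarray, q: float) -> BHResult:
    """Benjamini–Hochberg step-up FDR control at level ``q``.

    Sorts p ascending, finds the largest rank i with p_(i) ≤ i·q/m,
    rejects every hypothesis with p ≤ p_(i) (ties rejected together),
    and reports the critical value i·q/m plus cummin-adjusted p-values.
    NaN p-values are never rejected and do not count toward m.
    """
    p = np.asarray(p, dtype=float)
    if not (0 < q < 1):
        raise ValueError("q must lie in (0, 1)")
    finite = np.isfinite(p)
    if p[finite].size and (p[finite].min() < 0 or p[finite].max() > 1):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return BHResult(np.zeros(0, bool), 0.0, np.zeros(0), 0)

    pv = p[finite]
    m = len(pv)
    reject = np.zeros(len(p), dtype=bool)
    adjusted = np.full(len(p), np.nan)
    if m == 0:
        return BHResult(reject, 0.0, adjusted, 0)

    order = np.argsort(pv, kind="mergesort")
    sp = pv[order]
    ranks = np.arange(1, m + 1)
    passed = sp <= ranks * q / m
    if passed.any():
        stop = int(ranks[passed][-1])
        crit = stop * q / m
        rej_f = pv <= sp[stop - 1]
    else:
        stop, crit = 0, 0.0
        rej_f = np.zeros(m, dtype=bool)
    adj_sorted = np.minimum.accumulate((sp * m / ranks)[::-1])[::-1]
    adj_f = np.empty(m)
    adj_f[order] = np.minimum(adj_sorted, 1.0)
    reject[finite] = rej_f
    adjusted[finite] = adj_f
    return BHResult(reject, float(crit), adjusted, stop)
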