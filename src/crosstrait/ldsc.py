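"""LD-score regression: per-trait SNP heritability and cross-trait genetic
correlation with block-jackknife uncertainty.

Univariate model:  E[z_j^2]      = intercept + N * h2 * ell_j / m
Cross-trait model: E[zA_j zB_j]  = intercept + sqrt(NA*NB) * rho_gcov * ell_j / m

with ell_j the SNP's LD score. Regressions are weighted by 1/ell_j (a
heteroskedasticity proxy); rg = rho_gcov / sqrt(h2_A * h2_B), clamped to
[-1, 1]. Sample overlap loads on the cross-trait intercept, not the slope.
Standard errors come from a delete-one block jackknife over contiguous SNP
blocks, and p-values are two-sided normal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .ld import LDStructure, ld_scores  # noqa: F401  (re-exported operation)

logger = logging.getLogger(__name__)


@dataclass
class RgEstimate:
    rg: float | None
    gcov: float
    h2_a: float
    h2_b: float
    intercept_a: float
    intercept_b: float
    intercept_ab: float
    se: float | None
    p: float | None
    bonferroni_significant: bool | None = None
    reason: str | None = None


def _wls_sums(x: np.ndarray, y: np.ndarray, w: np.ndarray):
    """Per-point contributions to the weighted normal equations for
    y = a + b x; returned per observation so block-jackknife deletion is a
    subtraction of block sums."""
    return np.column_stack([w, w * x, w * x * x, w * y, w * x * y])


def _solve(s: np.ndarray):
    sw, swx, swxx, swy, swxy = s
    det = sw * swxx - swx**2
    if det <= 0:
        raise ZeroDivisionError("degenerate regression (constant LD scores?)")
    slope = (sw * swxy - swx * swy) / det
    intercept = (swxx * swy - swx * swxy) / det
    return slope, intercept


def univariate_h2(s: pd.DataFrame, scores: np.ndarray, m: int) -> tuple[float, float]:
    """Heritability slope and intercept from the weighted regression of z^2
    on N*ell/m. A negative fitted h2 is returned as-is, with a warning."""
    z2 = s["Z"].to_numpy(dtype=np.float64) ** 2
    x = s["N"].to_numpy(dtype=np.float64) * np.asarray(scores) / m
    w = 1.0 / np.asarray(scores)
    slope, intercept = _solve(_wls_sums(x, z2, w).sum(axis=0))
    if slope < 0:
        logger.warning("univariate_h2: negative fitted h2 = %.3g", slope)
    return float(slope), float(intercept)


class LdScoreRegression(BaseEstimator):
    """Cross-trait LD-score regression on a harmonized pair.

    Parameters
    ----------
    m : int or None
        Number of SNPs the heritability refers to; defaults to the number of
        SNPs in the fitted pair.
    n_blocks_jk : int
        Delete-one jackknife blocks (contiguous in SNP order).

    Attributes (after fit)
    ----------
    h2_a_, h2_b_ : heritability slopes
    gcov_ : genetic covariance slope
    rg_ : genetic correlation, clamped to [-1, 1]; None when undefined
    se_, p_ : jackknife SE of rg and two-sided normal p
    intercept_a_, intercept_b_, intercept_ab_ : regression intercepts
    """

    def __init__(self, m: int | None = None, n_blocks_jk: int = 200):
        self.m = m
        self.n_blocks_jk = n_blocks_jk

    def fit(self, X: pd.DataFrame, y=None, *, scores: np.ndarray):
        pair = X
        n = len(pair)
        if n < self.n_blocks_jk * 10:
            logger.warning("LdScoreRegression: only %d SNPs for %d jackknife "
                           "blocks", n, self.n_blocks_jk)
        m = self.m if self.m is not None else n
        ell = np.asarray(scores, dtype=np.float64)
        za = pair["Z_A"].to_numpy(dtype=np.float64)
        zb = pair["Z_B"].to_numpy(dtype=np.float64)
        na = pair["N_A"].to_numpy(dtype=np.float64)
        nb = pair["N_B"].to_numpy(dtype=np.float64)
        w = 1.0 / ell

        sums_a = _wls_sums(na * ell / m, za**2, w)
        sums_b = _wls_sums(nb * ell / m, zb**2, w)
        sums_ab = _wls_sums(np.sqrt(na * nb) * ell / m, za * zb, w)

        tot_a, tot_b, tot_ab = (s.sum(axis=0) for s in (sums_a, sums_b, sums_ab))
        try:
            self.h2_a_, self.intercept_a_ = _solve(tot_a)
            self.h2_b_, self.intercept_b_ = _solve(tot_b)
            self.gcov_, self.intercept_ab_ = _solve(tot_ab)
        except ZeroDivisionError as exc:
            logger.warning("LdScoreRegression: %s", exc)
            self.h2_a_ = self.h2_b_ = self.gcov_ = np.nan
            self.intercept_a_ = self.intercept_b_ = self.intercept_ab_ = np.nan
            self.rg_ = self.se_ = self.p_ = None
            self.reason_ = str(exc)
            return self

        def rg_of(h2a, h2b, gcov):
            if h2a <= 0 or h2b <= 0:
                return None
            return float(np.clip(gcov / np.sqrt(h2a * h2b), -1.0, 1.0))

        self.rg_ = rg_of(self.h2_a_, self.h2_b_, self.gcov_)
        if self.rg_ is None:
            self.se_ = self.p_ = None
            self.reason_ = "non-positive heritability slope"
            return self

        # delete-one block jackknife over contiguous SNP blocks
        edges = np.linspace(0, n, self.n_blocks_jk + 1).astype(int)
        block_a = np.add.reduceat(sums_a, edges[:-1], axis=0)
        block_b = np.add.reduceat(sums_b, edges[:-1], axis=0)
        block_ab = np.add.reduceat(sums_ab, edges[:-1], axis=0)
        pseudo = []
        for k in range(self.n_blocks_jk):
            try:
                h2a, _ = _solve(tot_a - block_a[k])
                h2b, _ = _solve(tot_b - block_b[k])
                gcov, _ = _solve(tot_ab - block_ab[k])
            except ZeroDivisionError:
                continue
            r = rg_of(h2a, h2b, gcov)
            if r is not None:
                pseudo.append(r)
        pseudo = np.asarray(pseudo)
        g = len(pseudo)
        if g < 2:
            self.se_ = self.p_ = None
            self.reason_ = "jackknife failed"
            return self
        self.se_ = float(np.sqrt((g - 1) / g * ((pseudo - pseudo.mean())**2).sum()))
        if self.se_ == 0:
            self.p_ = 1.0
        else:
            self.p_ = float(2 * stats.norm.sf(abs(self.rg_) / self.se_))
        self.reason_ = None
        return self

    def estimate_(self) -> RgEstimate:
        return RgEstimate(
            rg=self.rg_, gcov=float(self.gcov_),
            h2_a=float(self.h2_a_), h2_b=float(self.h2_b_),
            intercept_a=float(self.intercept_a_),
            intercept_b=float(self.intercept_b_),
            intercept_ab=float(self.intercept_ab_),
            se=self.se_, p=self.p_, reason=self.reason_,
        )


def cross_trait_rg(pair: pd.DataFrame, scores: np.ndarray, m: int | None = None,
                   n_blocks_jk: int = 200) -> RgEstimate:
    """Genetic correlation between the two traits of a harmonized pair."""
    est = LdScoreRegression(m=m, n_blocks_jk=n_blocks_jk)
    est.fit(pair, scores=scores)
    return est.estimate_()


def bonferroni_flag(estimates: list[RgEstimate], n_tests: int) -> list[bool]:
    """Bonferroni significance: p < 0.05 / n_tests (e.g. p < 0.05/11 when
    eleven secondary traits are tested against the same primary trait)."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    flags = []
    for e in estimates:
        flag = bool(e.p is not None and e.p < 0.05 / n_tests)
        e.bonferroni_significant = flag if e.p is not None else None
        flags.append(flag)
    return flags
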