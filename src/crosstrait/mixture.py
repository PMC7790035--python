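"""Bivariate Gaussian causal-mixture model of polygenic overlap.

Each LD-pruned SNP's z-score pair (z_A, z_B) is modelled as a four-component
zero-mean bivariate Gaussian mixture: a null component with covariance
Sigma0 = [[s0A, rho0*sqrt(s0A*s0B)], [., s0B]], an A-only component adding
nA*sigma_bA^2 to the (A,A) entry, a B-only component adding nB*sigma_bB^2 to
(B,B), and a shared component adding both plus the cross term
rho12*sqrt(nA*nB*sigma_bA^2*sigma_bB^2). Component weights (pi0, piA, piB,
pi12) are the fractions of SNPs that are null, causal for one trait only, or
causal for both; pi12*m is the number of shared causal variants.

The likelihood treats pruned SNPs as independent — a deliberate
approximation that replaces the full LD-convolution likelihood and is what
makes the model fit in seconds at desk scale. Venn counts are reported on
the "variants explaining 90% of SNP heritability" scale (see
:func:`n_causal_90`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit
from scipy import optimize, stats
from scipy.special import expit
from sklearn.base import BaseEstimator

from .ld import LDStructure, greedy_prune
from .qq import QQTable, conditional_qq
from .simulate import derive_seed

logger = logging.getLogger(__name__)

_LOG2PI = np.log(2.0 * np.pi)

WEIGHT_TOL = 1e-9


@dataclass
class MixtureParams:
    """Weights and (co)variances of the four-component bivariate mixture."""

    pi0: float
    pi_a: float
    pi_b: float
    pi_ab: float
    sigma_b2_a: float
    sigma_b2_b: float
    sigma0_2_a: float
    sigma0_2_b: float
    rho_beta: float
    rho0: float

    def __post_init__(self) -> None:
        w = np.array([self.pi0, self.pi_a, self.pi_b, self.pi_ab])
        if (w < -WEIGHT_TOL).any() or abs(w.sum() - 1.0) > WEIGHT_TOL:
            raise ValueError(f"weights {w} not on the simplex")
        if min(self.sigma_b2_a, self.sigma_b2_b) <= 0:
            raise ValueError("effect variances must be positive")
        if min(self.sigma0_2_a, self.sigma0_2_b) <= 0:
            raise ValueError("residual variances must be positive")
        if abs(self.rho_beta) > 1 or abs(self.rho0) > 1:
            raise ValueError("|rho| must be <= 1")

    @property
    def weights(self) -> np.ndarray:
        return np.array([self.pi0, self.pi_a, self.pi_b, self.pi_ab])

    def component_covs(self, n_a: float, n_b: float) -> np.ndarray:
        """The four 2x2 component covariances of (z_A, z_B)."""
        s0 = np.array([
            [self.sigma0_2_a, self.rho0 * np.sqrt(self.sigma0_2_a * self.sigma0_2_b)],
            [self.rho0 * np.sqrt(self.sigma0_2_a * self.sigma0_2_b), self.sigma0_2_b],
        ])
        va = n_a * self.sigma_b2_a
        vb = n_b * self.sigma_b2_b
        cab = self.rho_beta * np.sqrt(va * vb)
        covs = np.stack([s0, s0.copy(), s0.copy(), s0.copy()])
        covs[1, 0, 0] += va
        covs[2, 1, 1] += vb
        covs[3] += np.array([[va, cab], [cab, vb]])
        for c, cov in enumerate(covs):
            det = cov[0, 0] * cov[1, 1] - cov[0, 1] ** 2
            if det <= 0 or cov[0, 0] <= 0:
                raise ValueError(f"component {c} covariance not positive definite")
        return covs

    def rg(self) -> float:
        """Genetic correlation implied by the mixture:
        rho12 * pi12 / sqrt((piA + pi12) * (piB + pi12))."""
        den = np.sqrt((self.pi_a + self.pi_ab) * (self.pi_b + self.pi_ab))
        return 0.0 if den == 0 else float(self.rho_beta * self.pi_ab / den)


def pair_neg_log_likelihood(params: MixtureParams, z: np.ndarray,
                            n_a: float, n_b: float) -> float:
    """Negative log-likelihood of pruned z-score pairs under the mixture."""
    z = np.asarray(z, dtype=np.float64)
    za2 = z[:, 0] ** 2
    zb2 = z[:, 1] ** 2
    zab = z[:, 0] * z[:, 1]
    return _nll_core(params.weights, params.component_covs(n_a, n_b), za2, zb2, zab)


@njit(cache=True)
def _nll_kernel(logw, sxx, syy, sxy, za2, zb2, zab):
    n_comp = logw.size
    const = np.empty(n_comp)
    ixx = np.empty(n_comp)
    iyy = np.empty(n_comp)
    ixy = np.empty(n_comp)
    for c in range(n_comp):
        det = sxx[c] * syy[c] - sxy[c] * sxy[c]
        const[c] = logw[c] - _LOG2PI - 0.5 * np.log(det)
        iyy[c] = syy[c] / det
        ixx[c] = sxx[c] / det
        ixy[c] = sxy[c] / det
    total = 0.0
    lp = np.empty(n_comp)
    for j in range(za2.size):
        mx = -np.inf
        for c in range(n_comp):
            lp[c] = const[c] - 0.5 * (iyy[c] * za2[j] - 2.0 * ixy[c] * zab[j]
                                      + ixx[c] * zb2[j])
            if lp[c] > mx:
                mx = lp[c]
        s = 0.0
        for c in range(n_comp):
            s += np.exp(lp[c] - mx)
        total += mx + np.log(s)
    return -total


def _nll_core(weights, covs, za2, zb2, zab) -> float:
    active = np.asarray(weights) > 0
    covs = np.asarray(covs)[active]
    return float(_nll_kernel(
        np.log(np.asarray(weights)[active]),
        np.ascontiguousarray(covs[:, 0, 0]), np.ascontiguousarray(covs[:, 1, 1]),
        np.ascontiguousarray(covs[:, 0, 1]), za2, zb2, zab))


# --------------------------------------------------------------------- pruning

def prune_for_fit(pair: pd.DataFrame, ld: LDStructure, r2_max: float = 0.1,
                  seed: int = 0) -> pd.DataFrame:
    """Greedy random pruning: visit SNPs in a seeded random order, keep a SNP
    iff r2 < r2_max with every previously kept SNP in its block."""
    if not 0 < r2_max <= 1:
        raise ValueError("r2_max must lie in (0, 1]")
    rng = np.random.default_rng(derive_seed(seed, "prune"))
    pos = {s: i for i, s in enumerate(ld.snp_id)}
    rows = pair["SNP"].map(pos)
    if rows.isna().any():
        raise ValueError("pair contains SNPs absent from the LD structure")
    order = rng.permutation(ld.n_snps)
    kept = greedy_prune(ld, order, r2_max)
    out = pair[kept[rows.to_numpy(dtype=np.int64)]].reset_index(drop=True)
    out.attrs.update(pair.attrs)
    return out


# ------------------------------------------------------------- transformations

_WEIGHT_NAMES = ("pi_a", "pi_b", "pi_ab")
_LOGIT_CLIP = 30.0


def _pack_names(fix: dict, rho0_free: bool) -> list:
    names = [w for w in _WEIGHT_NAMES if w not in fix]
    names += ["log_sb2_a", "log_sb2_b", "log_s02_a", "log_s02_b"]
    if "pi_ab" not in fix:
        names.append("atanh_rho_beta")
    if rho0_free:
        names.append("atanh_rho0")
    return names


def _unpack(theta: np.ndarray, names: list, fix: dict) -> MixtureParams:
    d = dict(zip(names, theta))
    logits = np.array([np.clip(d.get(w, -np.inf), -_LOGIT_CLIP, _LOGIT_CLIP)
                       if w not in fix else -np.inf for w in _WEIGHT_NAMES])
    # softmax with pi0 as the reference category (logit 0)
    expl = np.exp(logits)
    denom = 1.0 + np.nansum(expl)
    w = expl / denom
    weights = {n: (0.0 if n in fix else w[i]) for i, n in enumerate(_WEIGHT_NAMES)}
    pi0 = 1.0 - sum(weights.values())
    rho_b = np.tanh(d["atanh_rho_beta"]) if "atanh_rho_beta" in d else 0.0
    rho0 = np.tanh(d["atanh_rho0"]) if "atanh_rho0" in d else 0.0
    return MixtureParams(
        pi0=pi0, pi_a=weights["pi_a"], pi_b=weights["pi_b"], pi_ab=weights["pi_ab"],
        sigma_b2_a=np.exp(d["log_sb2_a"]), sigma_b2_b=np.exp(d["log_sb2_b"]),
        sigma0_2_a=np.exp(d["log_s02_a"]), sigma0_2_b=np.exp(d["log_s02_b"]),
        rho_beta=rho_b, rho0=rho0,
    )


def _logit_of(pi: float) -> float:
    pi = np.clip(pi, 1e-10, 1 - 1e-6)
    return float(np.clip(np.log(pi / (1 - pi)), -_LOGIT_CLIP, _LOGIT_CLIP))


# ------------------------------------------------------------ univariate stage

def fit_univariate(z: np.ndarray, n: float, seed: int = 0,
                   maxfev: int = 1500) -> tuple:
    """Two-component point-normal fit of one trait's z-scores.

    Returns (pi_causal, sigma_b2, sigma0_2). Used to initialize the joint fit.
    """
    z2 = np.asarray(z, dtype=np.float64) ** 2
    s02_init = np.median(z2) / 0.4549  # median of chi2_1
    excess = max(float(z2.mean()) - s02_init, 1e-6)

    def nll(theta):
        pi = expit(np.clip(theta[0], -_LOGIT_CLIP, _LOGIT_CLIP))
        sb2 = np.exp(theta[1])
        s02 = np.exp(theta[2])
        v0, v1 = s02, s02 + n * sb2
        lp0 = -0.5 * (np.log(2 * np.pi * v0) + z2 / v0) + np.log1p(-pi)
        lp1 = -0.5 * (np.log(2 * np.pi * v1) + z2 / v1) + np.log(pi)
        return -np.logaddexp(lp0, lp1).sum()

    best = None
    for pi_init in (1e-4, 1e-3, 1e-2):
        theta0 = np.array([_logit_of(pi_init),
                           np.log(excess / (n * pi_init)),
                           np.log(s02_init)])
        res = optimize.minimize(nll, theta0, method="Nelder-Mead",
                                options={"maxfev": maxfev, "xatol": 1e-6,
                                         "fatol": 1e-6})
        if best is None or res.fun < best.fun:
            best = res
    pi = float(expit(np.clip(best.x[0], -_LOGIT_CLIP, _LOGIT_CLIP)))
    return pi, float(np.exp(best.x[1])), float(np.exp(best.x[2]))


# --------------------------------------------------------------- the estimator

class BivariateCausalMixture(BaseEstimator):
    """Four-component bivariate causal mixture fitted to pruned z-score pairs.

    Parameters
    ----------
    n_starts : int
        Seeded multi-start count for the derivative-free local search.
    rho0_free : bool
        Free the residual z correlation (sample overlap); fixed at 0 by
        default, matching analyses run on disjoint cohorts.
    random_state : int
        Seed for start jitter; fits are bit-reproducible given data and seed.
    maxfev_coarse, maxfev_polish, polish_top : int
        Budget of the coarse pass per start, of the polishing pass, and how
        many of the best coarse solutions are polished.

    Attributes
    ----------
    params_ : MixtureParams
    nll_ : float
    aic_ : float        2*k + 2*nll with k the number of free parameters
    n_snps_ : int
    converged_ : bool
    """

    def __init__(self, n_starts: int = 8, rho0_free: bool = False,
                 random_state: int = 0, maxfev_coarse: int = 200,
                 maxfev_polish: int = 2000, polish_top: int = 2,
                 xatol: float = 1e-5, fatol: float = 1e-5):
        self.n_starts = n_starts
        self.rho0_free = rho0_free
        self.random_state = random_state
        self.maxfev_coarse = maxfev_coarse
        self.maxfev_polish = maxfev_polish
        self.polish_top = polish_top
        self.xatol = xatol
        self.fatol = fatol

    # -------------------------------------------------------------------- fit
    def fit(self, X, y=None, *, n_a: float, n_b: float, fix: dict | None = None):
        """Fit the mixture to X, an (m, 2) array of pruned (z_A, z_B).

        ``fix`` pins mixture weights at zero, e.g. {"pi_ab": 0.0} for the
        minimum-overlap model or {"pi_a": 0.0} for maximum overlap; only
        zero is supported as a pinned value. ``init`` starts may also come
        from a previous fit via ``warm_start_params``.
        """
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError("X must be an (m, 2) array of z-score pairs")
        if not np.isfinite(X).all():
            raise ValueError("X contains non-finite z-scores")
        fix = dict(fix or {})
        for k, v in fix.items():
            if k not in _WEIGHT_NAMES or v != 0.0:
                raise ValueError(f"can only fix mixture weights to 0, got {k}={v}")
        m = X.shape[0]
        if m < 10_000:
            logger.warning("fit on %d SNPs; >= 10000 pruned SNPs recommended", m)

        za2, zb2, zab = X[:, 0] ** 2, X[:, 1] ** 2, X[:, 0] * X[:, 1]
        names = _pack_names(fix, self.rho0_free)

        def objective(theta):
            try:
                p = _unpack(theta, names, fix)
                return _nll_core(p.weights, p.component_covs(n_a, n_b),
                                 za2, zb2, zab)
            except (ValueError, FloatingPointError):
                return 1e300

        starts = self._starts(X, n_a, n_b, names, fix)
        coarse = []
        for theta0 in starts:
            res = optimize.minimize(objective, theta0, method="Nelder-Mead",
                                    options={"maxfev": self.maxfev_coarse,
                                             "xatol": self.xatol,
                                             "fatol": self.fatol})
            coarse.append(res)
        coarse.sort(key=lambda r: r.fun)
        best = None
        for res in coarse[: max(1, self.polish_top)]:
            pol = optimize.minimize(objective, res.x, method="Nelder-Mead",
                                    options={"maxfev": self.maxfev_polish,
                                             "xatol": self.xatol,
                                             "fatol": self.fatol})
            if best is None or pol.fun < best.fun:
                best = pol
        if best is None or not np.isfinite(best.fun) or best.fun >= 1e299:
            raise RuntimeError("no optimizer start converged to a finite likelihood")

        self.params_ = _unpack(best.x, names, fix)
        self.nll_ = float(best.fun)
        self.k_free_ = len(names)
        self.aic_ = 2.0 * self.k_free_ + 2.0 * self.nll_
        self.n_snps_ = m
        self.n_a_ = float(n_a)
        self.n_b_ = float(n_b)
        self.fix_ = fix
        self.converged_ = bool(best.success or best.fun < 1e299)
        self.theta_ = best.x
        self._names = names
        return self

    def _starts(self, X, n_a, n_b, names, fix):
        rng = np.random.default_rng(derive_seed(self.random_state, "starts"))
        pa_tot, sb2a, s02a = fit_univariate(X[:, 0], n_a, seed=self.random_state)
        pb_tot, sb2b, s02b = fit_univariate(X[:, 1], n_b, seed=self.random_state)
        self.univariate_ = {"A": (pa_tot, sb2a, s02a), "B": (pb_tot, sb2b, s02b)}
        pa_tot = max(pa_tot, 1e-6)
        pb_tot = max(pb_tot, 1e-6)
        zab_mean = float((X[:, 0] * X[:, 1]).mean())
        fractions = (0.5, 0.15, 0.85, 0.35, 0.65, 0.25, 0.75, 0.95)
        starts = []
        for s in range(self.n_starts):
            f = fractions[s % len(fractions)]
            pab = f * min(pa_tot, pb_tot)
            pa = max(pa_tot - pab, 1e-8)
            pb = max(pb_tot - pab, 1e-8)
            denom = pab * np.sqrt(n_a * n_b * sb2a * sb2b)
            rho_init = np.clip(zab_mean / denom if denom > 0 else 0.0, -0.9, 0.9)
            d = {"pi_a": _logit_of(pa), "pi_b": _logit_of(pb),
                 "pi_ab": _logit_of(pab),
                 "log_sb2_a": np.log(sb2a), "log_sb2_b": np.log(sb2b),
                 "log_s02_a": np.log(s02a), "log_s02_b": np.log(s02b),
                 "atanh_rho_beta": np.arctanh(rho_init), "atanh_rho0": 0.0}
            theta = np.array([d[n] for n in names])
            if s > 0:
                theta = theta + rng.normal(0.0, 0.25, theta.size)
            starts.append(theta)
        return starts

    # ----------------------------------------------------------------- extras
    def score(self, X, y=None) -> float:
        """Mean log-likelihood per SNP (sklearn convention: higher is better)."""
        nll = pair_neg_log_likelihood(self.params_, np.asarray(X), self.n_a_, self.n_b_)
        return -nll / len(X)

    def sample(self, m: int, random_state: int = 0) -> np.ndarray:
        """Draw m z-score pairs from the fitted mixture."""
        rng = np.random.default_rng(derive_seed(random_state, "model_qq"))
        covs = self.params_.component_covs(self.n_a_, self.n_b_)
        labels = rng.choice(4, size=m, p=np.clip(self.params_.weights, 0, None)
                            / self.params_.weights.sum())
        z = np.empty((m, 2))
        for c in range(4):
            mask = labels == c
            if mask.any():
                chol = np.linalg.cholesky(covs[c])
                z[mask] = rng.standard_normal((int(mask.sum()), 2)) @ chol.T
        return z

    def rg_implied(self) -> float:
        return self.params_.rg()

    def venn_counts(self, m_total: int) -> dict:
        return venn_summary(self, m_total)


# ------------------------------------------------------------- thin operations

def fit_bivariate(pair: pd.DataFrame, **options) -> BivariateCausalMixture:
    """Fit the bivariate mixture to a pruned harmonized pair."""
    est = BivariateCausalMixture(**{k: v for k, v in options.items()
                                    if k != "fix"})
    Z = pair[["Z_A", "Z_B"]].to_numpy()
    n_a = float(np.median(pair["N_A"]))
    n_b = float(np.median(pair["N_B"]))
    est.fit(Z, n_a=n_a, n_b=n_b, fix=options.get("fix"))
    return est


_T90 = stats.chi2.ppf(0.10, df=3)
Q90 = float(stats.chi2.sf(_T90, df=1))


def n_causal_90(n_causal: float) -> float:
    """Causal-variant count rescaled to "variants explaining 90% of SNP
    heritability".

    For i.i.d. Gaussian effects the heritability carried by variants whose
    standardized squared effect exceeds t is P(chi2_3 > t) (the identity
    E[X 1{X>t}] = k P(chi2_{k+2} > t) for X ~ chi2_k at k = 1), so the
    smallest set explaining 90%% keeps the fraction q* = P(chi2_1 > t*) of
    variants, with t* solving P(chi2_3 > t*) = 0.90. q* ~= 0.445.
    """
    if n_causal < 0:
        raise ValueError("n_causal must be >= 0")
    return Q90 * n_causal


def venn_summary(fit: BivariateCausalMixture, m: int) -> dict:
    """Venn counts (thousands, 1 decimal) on the 90%-heritability scale.

    The transform is applied per component, so unique + shared adds up to
    each trait's total by construction.
    """
    p = fit.params_
    unique_a = n_causal_90(p.pi_a * m)
    unique_b = n_causal_90(p.pi_b * m)
    shared = n_causal_90(p.pi_ab * m)
    to_k = lambda x: round(x / 1000.0, 1)
    return {
        "unique_a_k": to_k(unique_a),
        "unique_b_k": to_k(unique_b),
        "shared_k": to_k(shared),
        "total_a_k": to_k(unique_a + shared),
        "total_b_k": to_k(unique_b + shared),
    }


def overlap_aic(fit: BivariateCausalMixture, pair: pd.DataFrame) -> dict:
    """AIC separation of the best fit from min- and max-overlap scenarios.

    Refits with pi12 pinned to 0 (minimum overlap) and with the smaller
    trait's unique weight pinned to 0 (pi12 at its maximum, the smaller total
    polygenicity). Positive deltas (constrained AIC minus best AIC) mean the
    data can distinguish the best fit from that scenario.
    """
    Z = pair[["Z_A", "Z_B"]].to_numpy()
    p = fit.params_
    ta, tb = p.pi_a + p.pi_ab, p.pi_b + p.pi_ab
    fix_max = {"pi_a": 0.0} if ta <= tb else {"pi_b": 0.0}
    out = {}
    for tag, fix in (("min", {"pi_ab": 0.0}), ("max", fix_max)):
        est = BivariateCausalMixture(**fit.get_params())
        est.set_params(n_starts=4)
        try:
            est.fit(Z, n_a=fit.n_a_, n_b=fit.n_b_, fix=fix)
            out[f"aic_{tag}"] = est.aic_
            out[f"delta_aic_vs_{tag}"] = est.aic_ - fit.aic_
        except RuntimeError as exc:  # constrained fit failure: flagged, missing
            logger.warning("constrained (%s) fit failed: %s", tag, exc)
            out[f"aic_{tag}"] = np.nan
            out[f"delta_aic_vs_{tag}"] = np.nan
    deltas = [out["delta_aic_vs_min"], out["delta_aic_vs_max"]]
    out["distinguishable"] = bool(np.nanmin(deltas) > 0)
    return out


def model_vs_actual_qq(fit: BivariateCausalMixture, pair: pd.DataFrame,
                       seed: int = 0, **qq_kwargs) -> tuple[QQTable, QQTable]:
    """Conditional Q-Q of data simulated from the fitted mixture next to the
    actual data's, for visual model-fit assessment."""
    z = fit.sample(len(pair), random_state=seed)
    p = 2 * stats.norm.sf(np.abs(z))
    sim = pd.DataFrame({"P_A": np.maximum(p[:, 0], 1e-300),
                        "P_B": np.maximum(p[:, 1], 1e-300)})
    actual = pair[["P_A", "P_B"]]
    return conditional_qq(sim, **qq_kwargs), conditional_qq(actual, **qq_kwargs)
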