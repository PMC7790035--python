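"""Synthetic two- and three-trait GWAS summary statistics with known truth.

Per-SNP causal effects are drawn from a point-normal bivariate mixture
(null / A-only / B-only / shared), and z-scores follow the standard
summary-statistic linear model

    z_j = sqrt(N) * sum_k r_jk * beta_k + eps_j,   eps_j ~ Normal(0, sigma0^2),

with corr(eps_A, eps_B) = rho0 at each SNP capturing residual inflation and
sample overlap. Genotypes are never materialized: with standardized
genotypes the marginal z of SNP j has mean sqrt(N) times the LD-weighted
sum of causal effects, which is all any downstream stage sees.

Defaults describe a desk-scale genome: 50,000 SNPs in 1,000 exchangeable
LD blocks of 50 SNPs spaced 5 kb apart, polygenicity ~1e-3 per trait, a
shared component of 2e-3, per-causal-variant variance 2e-4 and n = 1e5 so
that a typical causal SNP carries a noncentrality of ~20 — comparable,
after scaling, to well-powered GWAS of polygenic traits.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .ld import LDStructure

__all__ = [
    "GenerativeParams",
    "simulate_ld_blocks",
    "simulate_joint_effects",
    "simulate_zscores",
    "simulate_pair",
    "simulate_trio",
]

_ALLELES = np.array(["A", "G"], dtype=object)

# seed-derivation offsets: one global seed, independent substreams per stage
_SUBSEED = {"ld": 11, "effects": 23, "noise": 37, "alleles": 41, "prune": 53,
            "starts": 67, "model_qq": 71}


def derive_seed(seed: int, stage: str, rep: int = 0) -> int:
    """Deterministic per-stage substream seed, kept below 2**31."""
    return (seed * 1_000_003 + _SUBSEED[stage] * 7919 + rep) % (2**31 - 1)


@dataclass
class GenerativeParams:
    """Parameters of the bivariate causal-mixture generator.

    pi_a / pi_b / pi_ab are the fractions of SNPs causal for A only, B only
    and both; sigma_b2_* the per-causal-SNP effect variance on the
    standardized-genotype scale; rho_beta the effect-size correlation inside
    the shared component (0 gives the mixed-direction overlap regime);
    sigma0_* the residual z standard deviations; rho0 the residual z
    correlation from sample overlap (0 when cohorts are disjoint).
    """

    m: int = 50_000
    pi_a: float = 1e-3
    pi_b: float = 1e-3
    pi_ab: float = 2e-3
    sigma_b2_a: float = 2e-4
    sigma_b2_b: float = 2e-4
    rho_beta: float = 0.5
    sigma0_a: float = 1.0
    sigma0_b: float = 1.0
    rho0: float = 0.0
    n_a: float = 100_000.0
    n_b: float = 100_000.0
    seed: int = 0
    n_blocks: int = 1000
    block_size: int = 50
    # cycled across blocks: real LD is heterogeneous, and varying LD scores
    # are what identifies the LD-score regression slope
    rho_within: float | tuple = (0.2, 0.4, 0.6, 0.8)

    def __post_init__(self) -> None:
        pis = np.array([self.pi_a, self.pi_b, self.pi_ab])
        if (pis < 0).any() or pis.sum() > 1:
            raise ValueError("mixture weights must be >= 0 and sum to <= 1")
        if min(self.sigma_b2_a, self.sigma_b2_b) <= 0:
            raise ValueError("effect variances must be positive")
        if min(self.sigma0_a, self.sigma0_b) <= 0:
            raise ValueError("residual sds must be positive")
        if abs(self.rho_beta) > 1 or abs(self.rho0) > 1:
            raise ValueError("|rho| must be <= 1")
        if self.n_blocks * self.block_size != self.m:
            raise ValueError("m must equal n_blocks * block_size")

    @property
    def pi0(self) -> float:
        return 1.0 - self.pi_a - self.pi_b - self.pi_ab

    def h2(self, trait: str) -> float:
        """Generative SNP heritability: m * pi_causal * sigma_b2."""
        if trait == "A":
            return self.m * (self.pi_a + self.pi_ab) * self.sigma_b2_a
        return self.m * (self.pi_b + self.pi_ab) * self.sigma_b2_b

    def rg(self) -> float:
        """Generative genetic correlation implied by the mixture."""
        den = np.sqrt((self.pi_a + self.pi_ab) * (self.pi_b + self.pi_ab))
        return 0.0 if den == 0 else self.rho_beta * self.pi_ab / den

    def to_dict(self) -> dict:
        return asdict(self)


def simulate_ld_blocks(n_blocks: int, block_size: int, rho_within,
                       seed: int = 0) -> LDStructure:
    """Exchangeable-correlation LD blocks with synthetic ids and positions.

    ``rho_within`` may be a scalar or a sequence cycled across blocks
    (heterogeneous LD scores are needed e.g. for LD-score regression).
    Positions are spaced 5 kb apart, blocks laid round-robin on chr1-22.
    """
    if n_blocks < 1 or block_size < 1:
        raise ValueError("counts must be >= 1")
    if np.ndim(rho_within) == 0:
        rhos = np.full(n_blocks, float(rho_within))
    else:
        rhos = np.resize(np.asarray(rho_within, dtype=float), n_blocks)
    k = block_size
    lo = -1.0 / (k - 1) if k > 1 else -1.0
    if (np.abs(rhos) >= 1).any() or (k > 1 and (rhos <= lo).any()):
        raise ValueError("rho_within outside the positive-semidefinite range")

    m = n_blocks * block_size
    snp_id = np.array([f"rs{j:08d}" for j in range(m)], dtype=object)
    n_chrom = min(22, n_blocks)
    chrom_of_block = (np.arange(n_blocks) % n_chrom) + 1
    chrom = np.repeat(chrom_of_block.astype(str), block_size).astype(object)
    # per-chromosome running positions, 5 kb spacing
    pos = np.empty(m, dtype=np.int64)
    next_pos = {str(c): 1 for c in range(1, n_chrom + 1)}
    ptr = 0
    for b in range(n_blocks):
        c = str(chrom_of_block[b])
        start = next_pos[c]
        pos[ptr:ptr + k] = start + 5000 * np.arange(k)
        next_pos[c] = start + 5000 * k
        ptr += k
    mats = []
    for b in range(n_blocks):
        mat = np.full((k, k), rhos[b])
        np.fill_diagonal(mat, 1.0)
        mats.append(mat)
    block_id = np.repeat(np.arange(n_blocks), block_size)
    return LDStructure(snp_id=snp_id, chrom=chrom, pos=pos,
                       block_id=block_id, matrices=mats)


def simulate_joint_effects(gp: GenerativeParams) -> pd.DataFrame:
    """Draw per-SNP component labels and causal effects.

    Returns an EffectTable with columns SNP-index-free: ``component`` in
    {null, A-only, B-only, shared}, ``beta_a``, ``beta_b``.
    """
    rng = np.random.default_rng(derive_seed(gp.seed, "effects"))
    labels = rng.choice(4, size=gp.m,
                        p=[gp.pi0, gp.pi_a, gp.pi_b, gp.pi_ab])
    beta_a = np.zeros(gp.m)
    beta_b = np.zeros(gp.m)
    ia = labels == 1
    ib = labels == 2
    ish = labels == 3
    beta_a[ia] = rng.normal(0.0, np.sqrt(gp.sigma_b2_a), ia.sum())
    beta_b[ib] = rng.normal(0.0, np.sqrt(gp.sigma_b2_b), ib.sum())
    if ish.any():
        cov = np.array([
            [gp.sigma_b2_a, gp.rho_beta * np.sqrt(gp.sigma_b2_a * gp.sigma_b2_b)],
            [gp.rho_beta * np.sqrt(gp.sigma_b2_a * gp.sigma_b2_b), gp.sigma_b2_b],
        ])
        both = rng.multivariate_normal([0.0, 0.0], cov, size=int(ish.sum()),
                                       method="cholesky")
        beta_a[ish] = both[:, 0]
        beta_b[ish] = both[:, 1]
    comp = np.array(["null", "A-only", "B-only", "shared"], dtype=object)[labels]
    return pd.DataFrame({"component": comp, "beta_a": beta_a, "beta_b": beta_b})


def _ld_smooth(beta: np.ndarray, ld: LDStructure) -> np.ndarray:
    """R @ beta, block by block."""
    out = np.empty_like(beta)
    ptr = 0
    for mat in ld.matrices:
        k = mat.shape[0]
        out[ptr:ptr + k] = mat @ beta[ptr:ptr + k]
        ptr += k
    return out


def simulate_zscores(effects: pd.DataFrame, ld: LDStructure,
                     gp: GenerativeParams) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate the two traits' SummaryStats from effects and LD."""
    if len(effects) != ld.n_snps:
        raise ValueError(f"effects ({len(effects)}) and LD ({ld.n_snps}) cover "
                         "different SNP counts")
    rng = np.random.default_rng(derive_seed(gp.seed, "noise"))
    mean_a = np.sqrt(gp.n_a) * _ld_smooth(effects["beta_a"].to_numpy(), ld)
    mean_b = np.sqrt(gp.n_b) * _ld_smooth(effects["beta_b"].to_numpy(), ld)
    eps = rng.standard_normal((ld.n_snps, 2))
    eps_b = gp.rho0 * eps[:, 0] + np.sqrt(1 - gp.rho0**2) * eps[:, 1]
    z_a = mean_a + gp.sigma0_a * eps[:, 0]
    z_b = mean_b + gp.sigma0_b * eps_b

    arng = np.random.default_rng(derive_seed(gp.seed, "alleles"))
    a1 = _ALLELES[arng.integers(0, 2, ld.n_snps)]
    a2 = np.where(a1 == "A", "G", "A").astype(object)

    def table(z, n):
        return pd.DataFrame({
            "SNP": ld.snp_id, "CHR": ld.chrom, "BP": ld.pos,
            "A1": a1, "A2": a2, "Z": z, "N": float(n),
            "P": np.maximum(2 * stats.norm.sf(np.abs(z)), 1e-300),
        })

    return table(z_a, gp.n_a), table(z_b, gp.n_b)


def simulate_pair(gp: GenerativeParams):
    """Full generator: LD + effects + z-scores.

    Returns (stats_a, stats_b, ld, effects).
    """
    ld = simulate_ld_blocks(gp.n_blocks, gp.block_size, gp.rho_within,
                            seed=derive_seed(gp.seed, "ld"))
    effects = simulate_joint_effects(gp)
    sa, sb = simulate_zscores(effects, ld, gp)
    return sa, sb, ld, effects


def simulate_trio(gp: GenerativeParams, weights: dict | None = None,
                  rho_beta: float | None = None):
    """Three-trait generator with all seven causal components.

    ``weights`` maps subsets of {a, b, c} ("a", "ab", "abc", ...) to mixture
    fractions; omitted keys default to pair-style values derived from ``gp``
    (singles = pi_a, pairs = pi_ab / 2, triple = pi_ab / 2). Within any shared
    component the involved traits' effects are equicorrelated at ``rho_beta``
    (default: gp.rho_beta). Returns (stats_list, ld, effects frame with
    beta_a/beta_b/beta_c and component label).
    """
    rho = gp.rho_beta if rho_beta is None else rho_beta
    w = {"a": gp.pi_a, "b": gp.pi_b, "c": gp.pi_a,
         "ab": gp.pi_ab / 2, "ac": gp.pi_ab / 2, "bc": gp.pi_ab / 2,
         "abc": gp.pi_ab / 2}
    if weights:
        w.update(weights)
    keys = ["a", "b", "c", "ab", "ac", "bc", "abc"]
    probs = np.array([w[k] for k in keys])
    if (probs < 0).any() or probs.sum() > 1:
        raise ValueError("trio weights must be >= 0 and sum to <= 1")
    ld = simulate_ld_blocks(gp.n_blocks, gp.block_size, gp.rho_within,
                            seed=derive_seed(gp.seed, "ld"))
    rng = np.random.default_rng(derive_seed(gp.seed, "effects"))
    labels = rng.choice(len(keys) + 1, size=gp.m,
                        p=np.concatenate([[1 - probs.sum()], probs]))
    sig = np.sqrt(gp.sigma_b2_a)
    betas = np.zeros((gp.m, 3))
    for li, key in enumerate(keys, start=1):
        mask = labels == li
        if not mask.any():
            continue
        traits = [i for i, t in enumerate("abc") if t in key]
        d = len(traits)
        cov = sig**2 * (np.full((d, d), rho) + (1 - rho) * np.eye(d))
        draw = rng.multivariate_normal(np.zeros(d), cov, size=int(mask.sum()),
                                       method="cholesky")
        for col, t in enumerate(traits):
            betas[mask, t] = draw[:, col]

    arng = np.random.default_rng(derive_seed(gp.seed, "alleles"))
    a1 = _ALLELES[arng.integers(0, 2, gp.m)]
    a2 = np.where(a1 == "A", "G", "A").astype(object)
    nrng = np.random.default_rng(derive_seed(gp.seed, "noise"))
    out = []
    for t in range(3):
        z = np.sqrt(gp.n_a) * _ld_smooth(betas[:, t], ld) \
            + gp.sigma0_a * nrng.standard_normal(gp.m)
        out.append(pd.DataFrame({
            "SNP": ld.snp_id, "CHR": ld.chrom, "BP": ld.pos,
            "A1": a1, "A2": a2, "Z": z, "N": float(gp.n_a),
            "P": np.maximum(2 * stats.norm.sf(np.abs(z)), 1e-300),
        }))
    comp = np.array(["null"] + keys, dtype=object)[labels]
    eff = pd.DataFrame({"component": comp, "beta_a": betas[:, 0],
                        "beta_b": betas[:, 1], "beta_c": betas[:, 2]})
    return out, ld, eff
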