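"""Conditional and conjunctional FDR from pruning-averaged 2D lookup tables.

The condFDR of a primary trait given a secondary one is the empirical-Bayes
quantity

    condFDR(p1 | p2) = min(1, p1 * C2(p2) / C12(p1, p2))

where C2 counts SNPs with secondary p <= p2 and C12 counts SNPs passing both
thresholds, each count averaged over random LD prunings so that clusters of
correlated SNPs do not dominate the empirical cdf. The null proportion is
conservatively fixed at 1. Re-ranking the primary trait's test statistics by
the secondary association is what buys the power gain at pleiotropic SNPs.

conjFDR is the maximum of the two reciprocal condFDR values — a conservative
FDR for association with both traits; the trio extension takes the maximum
of the three pairwise conjFDR values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import RegularGridInterpolator
from sklearn.base import BaseEstimator, TransformerMixin

from .ld import LDStructure, greedy_prune
from .simulate import derive_seed

logger = logging.getLogger(__name__)

DEFAULT_GRID_STEP = 0.1
DEFAULT_GRID_MAX = 20.0
DEFAULT_N_PRUNE = 100
DEFAULT_R2_PRUNE = 0.1

SCORED_COLUMNS = ["SNP", "CHR", "BP", "Z_A", "Z_B", "P_A", "P_B",
                  "CONDFDR_A_B", "CONDFDR_B_A", "CONJFDR"]


@dataclass
class FDRGrid:
    """condFDR lookup over binned (-log10 p_primary, -log10 p_secondary).

    ``values`` is the monotone-enforced table used for assignment;
    ``raw_values`` the pre-enforcement table (NaN where the averaged joint
    count fell below 1 and the cell inherited a neighbour).
    """

    axis1: np.ndarray
    axis2: np.ndarray
    values: np.ndarray
    raw_values: np.ndarray
    c2: np.ndarray
    c12: np.ndarray
    meta: dict = field(default_factory=dict)

    def interpolator(self) -> RegularGridInterpolator:
        return RegularGridInterpolator((self.axis1, self.axis2), self.values,
                                       method="linear", bounds_error=False,
                                       fill_value=None)


def _bin_index(v: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Bin of each value; a value exactly on an edge belongs to that edge's bin."""
    v = np.clip(v, edges[0], edges[-1])
    return np.minimum(np.searchsorted(edges, v, side="right") - 1, edges.size - 1)


def build_lookup(pair: pd.DataFrame, ld: LDStructure, primary: str = "A",
                 grid_step: float = DEFAULT_GRID_STEP,
                 grid_max: float = DEFAULT_GRID_MAX,
                 n_prune: int = DEFAULT_N_PRUNE,
                 r2_prune: float = DEFAULT_R2_PRUNE,
                 seed: int = 0) -> FDRGrid:
    """Build the condFDR grid of ``primary`` conditioned on the other trait.

    Counts are averaged as real numbers over ``n_prune`` random greedy LD
    prunings at r2 < ``r2_prune`` before the ratio is formed; the region
    mask is expected to have been applied already.
    """
    if len(pair) == 0:
        raise ValueError("empty pair")
    p1 = pair["P_A" if primary == "A" else "P_B"].to_numpy(dtype=np.float64)
    p2 = pair["P_B" if primary == "A" else "P_A"].to_numpy(dtype=np.float64)
    if np.unique(p1).size == 1 or np.unique(p2).size == 1:
        raise ValueError("degenerate input: all p-values identical")

    n_nodes = int(round(grid_max / grid_step)) + 1
    edges = np.linspace(0.0, grid_max, n_nodes)
    i1 = _bin_index(-np.log10(p1), edges)
    i2 = _bin_index(-np.log10(p2), edges)

    pos = {s: i for i, s in enumerate(ld.snp_id)}
    rows = pair["SNP"].map(pos)
    if rows.isna().any():
        raise ValueError("pair contains SNPs absent from the LD structure")
    rows = rows.to_numpy(dtype=np.int64)

    rng = np.random.default_rng(derive_seed(seed, "prune"))
    hist = np.zeros(n_nodes * n_nodes, dtype=np.float64)
    flat = i1 * n_nodes + i2
    for _ in range(n_prune):
        kept = greedy_prune(ld, rng.permutation(ld.n_snps), r2_prune)[rows]
        hist += np.bincount(flat[kept], minlength=n_nodes * n_nodes)
    hist = hist.reshape(n_nodes, n_nodes) / n_prune

    # survival counts: c12[i, j] = avg count of kept SNPs with
    # -log10 p1 >= edges[i] and -log10 p2 >= edges[j]
    c12 = hist[::-1, ::-1].cumsum(axis=0).cumsum(axis=1)[::-1, ::-1]
    c2 = c12[0, :]

    p1_nodes = 10.0 ** (-edges)
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = np.minimum(p1_nodes[:, None] * c2[None, :] / c12, 1.0)
    raw[c12 < 1.0] = np.nan

    filled = raw.copy()
    for j in range(n_nodes):
        if np.isnan(filled[0, j]):
            # whole column undefined (fewer than one SNP passes the secondary
            # threshold on average): inherit the less stringent column
            filled[:, j] = filled[:, j - 1] if j else 1.0
            continue
        for i in range(1, n_nodes):
            if np.isnan(filled[i, j]):
                filled[i, j] = filled[i - 1, j]

    # monotone enforcement: running maximum toward less-significant p1
    values = np.maximum.accumulate(filled[::-1, :], axis=0)[::-1, :]

    return FDRGrid(axis1=edges, axis2=edges.copy(), values=values,
                   raw_values=raw, c2=c2, c12=c12,
                   meta={"primary": primary, "n_prune": n_prune,
                         "r2_prune": r2_prune, "seed": seed,
                         "n_snps": len(pair)})


def condfdr_assign(pair: pd.DataFrame, grid: FDRGrid) -> np.ndarray:
    """Per-SNP condFDR by bilinear interpolation in (-log10 p1, -log10 p2);
    coordinates beyond the grid are clamped to the edge. Every SNP receives a
    value, not only pruned ones."""
    primary = grid.meta.get("primary", "A")
    p1 = pair["P_A" if primary == "A" else "P_B"].to_numpy(dtype=np.float64)
    p2 = pair["P_B" if primary == "A" else "P_A"].to_numpy(dtype=np.float64)
    x1 = np.clip(-np.log10(p1), grid.axis1[0], grid.axis1[-1])
    x2 = np.clip(-np.log10(p2), grid.axis2[0], grid.axis2[-1])
    return grid.interpolator()(np.column_stack([x1, x2]))


def conjfdr_assign(pair: pd.DataFrame, grid_ab: FDRGrid,
                   grid_ba: FDRGrid) -> pd.DataFrame:
    """ScoredSnps: both condFDRs and their maximum, the conjFDR, per SNP."""
    fdr_ab = condfdr_assign(pair, grid_ab)
    fdr_ba = condfdr_assign(pair, grid_ba)
    out = pair[["SNP", "CHR", "BP", "Z_A", "Z_B", "P_A", "P_B"]].copy()
    out["CONDFDR_A_B"] = fdr_ab
    out["CONDFDR_B_A"] = fdr_ba
    out["CONJFDR"] = np.maximum(fdr_ab, fdr_ba)
    return out


def trio_conjfdr(scored_ab: pd.DataFrame, scored_ac: pd.DataFrame,
                 scored_bc: pd.DataFrame) -> pd.DataFrame:
    """Trio conjFDR: the maximum of the three pairwise conjFDR values on the
    common SNP intersection. A SNP significant at tau is therefore
    significant in all three pairwise analyses at tau."""
    a = scored_ab[["SNP", "CHR", "BP", "CONJFDR"]].rename(
        columns={"CONJFDR": "CONJFDR_AB"})
    b = scored_ac[["SNP", "CONJFDR"]].rename(columns={"CONJFDR": "CONJFDR_AC"})
    c = scored_bc[["SNP", "CONJFDR"]].rename(columns={"CONJFDR": "CONJFDR_BC"})
    m = a.merge(b, on="SNP").merge(c, on="SNP")
    if len(m) == 0:
        raise ValueError("empty SNP intersection across the three pairs")
    m["TRIO_CONJFDR"] = m[["CONJFDR_AB", "CONJFDR_AC", "CONJFDR_BC"]].max(axis=1)
    return m


class ConditionalFDR(BaseEstimator, TransformerMixin):
    """Reciprocal condFDR / conjFDR scorer for a harmonized trait pair.

    ``fit`` builds both pruning-averaged lookup grids (A given B and B given
    A); ``transform`` assigns per-SNP condFDR and conjFDR values by bilinear
    interpolation, to any table sharing the fitted SNP universe.
    """

    def __init__(self, grid_step: float = DEFAULT_GRID_STEP,
                 grid_max: float = DEFAULT_GRID_MAX,
                 n_prune: int = DEFAULT_N_PRUNE,
                 r2_prune: float = DEFAULT_R2_PRUNE,
                 random_state: int = 0):
        self.grid_step = grid_step
        self.grid_max = grid_max
        self.n_prune = n_prune
        self.r2_prune = r2_prune
        self.random_state = random_state

    def fit(self, X: pd.DataFrame, y=None, *, ld: LDStructure):
        kw = dict(grid_step=self.grid_step, grid_max=self.grid_max,
                  n_prune=self.n_prune, r2_prune=self.r2_prune,
                  seed=self.random_state)
        self.grid_ab_ = build_lookup(X, ld, primary="A", **kw)
        self.grid_ba_ = build_lookup(X, ld, primary="B", **kw)
        self.n_snps_ = len(X)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return conjfdr_assign(X, self.grid_ab_, self.grid_ba_)


def plot_manhattan(scored: pd.DataFrame, path, fdr_col: str = "CONJFDR",
                   sig_thresh: float = 0.05) -> None:
    """Manhattan-style plot of -log10 FDR; significant SNPs enlarged
    (FDR < 0.05, i.e. -log10 FDR > 1.3)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = scored.copy()
    df["CHRN"] = pd.to_numeric(df["CHR"].replace({"X": 23}), errors="coerce")
    df = df.sort_values(["CHRN", "BP"]).reset_index(drop=True)
    offsets, off = {}, 0
    for c, sub in df.groupby("CHRN", sort=True):
        offsets[c] = off
        off += sub["BP"].max() + 1
    x = df["BP"] + df["CHRN"].map(offsets)
    y = -np.log10(np.maximum(df[fdr_col], 1e-300))
    sig = df[fdr_col] < sig_thresh
    fig, ax = plt.subplots(figsize=(9, 3))
    colors = df["CHRN"].astype(int) % 2
    ax.scatter(x[~sig], y[~sig], s=2, c=np.where(colors[~sig], "#888888", "#bbbbbb"))
    ax.scatter(x[sig], y[sig], s=14, c="#d62728")
    ax.axhline(-np.log10(sig_thresh), color="k", ls="--", lw=0.7)
    ax.set_xlabel("genomic position")
    ax.set_ylabel(f"-log10 {fdr_col.lower()}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
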