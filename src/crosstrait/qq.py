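"""Conditional Q-Q tables: cross-trait pleiotropic enrichment.

For each secondary-trait p-value stratum (p_B <= 1, 0.1, 0.01, 0.001 by
default) the primary trait's -log10 p quantiles are compared with the
uniform null. Successive leftward/upward deflection of the strata curves
is the classic visual signature of pleiotropic enrichment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

DEFAULT_THRESHOLDS = (1.0, 0.1, 0.01, 0.001)
MLOG10_CAP = 20.0
MIN_STRATUM = 100


@dataclass
class QQTable:
    """Long-format conditional Q-Q curves plus per-stratum SNP counts."""

    table: pd.DataFrame          # stratum, expected, observed
    counts: dict                 # stratum threshold -> SNP count
    flagged: dict                # stratum threshold -> True when count < MIN_STRATUM

    def stratum(self, threshold: float) -> pd.DataFrame:
        return self.table[self.table["stratum"] == threshold].reset_index(drop=True)


def conditional_qq(pair: pd.DataFrame, thresholds=DEFAULT_THRESHOLDS,
                   n_points: int = 1000, primary: str = "A",
                   cap: float = MLOG10_CAP) -> QQTable:
    """Conditional Q-Q table of the primary trait stratified on the secondary.

    For threshold t the stratum holds SNPs with secondary p <= t; observed
    -log10 primary-p is evaluated at ``n_points`` evenly spaced empirical
    quantile levels, and the expected curve is -log10 of those same levels.
    Swapping ``primary`` to "B" gives the reverse conditional Q-Q.
    """
    if len(pair) == 0:
        raise ValueError("empty pair")
    thresholds = tuple(thresholds)
    if any(t <= 0 or t > 1 for t in thresholds):
        raise ValueError("thresholds must lie in (0, 1]")
    if list(thresholds) != sorted(thresholds, reverse=True):
        raise ValueError("thresholds must be strictly decreasing")
    p1 = pair["P_A" if primary == "A" else "P_B"].to_numpy()
    p2 = pair["P_B" if primary == "A" else "P_A"].to_numpy()
    levels = (np.arange(n_points) + 0.5) / n_points       # ascending in (0,1)
    rows, counts, flagged = [], {}, {}
    for t in thresholds:
        sel = np.sort(p1[p2 <= t])
        counts[t] = sel.size
        flagged[t] = sel.size < MIN_STRATUM
        if sel.size == 0:
            continue
        observed = -np.log10(np.quantile(sel, levels))
        expected = -np.log10(levels)
        # ascending expected: reverse so both curves increase together
        df = pd.DataFrame({
            "stratum": t,
            "expected": expected[::-1],
            "observed": np.minimum(observed, cap)[::-1],
            "n": sel.size,
        })
        rows.append(df)
    return QQTable(table=pd.concat(rows, ignore_index=True), counts=counts,
                   flagged=flagged)


def qq_to_tsv(qq: QQTable, path) -> None:
    qq.table.to_csv(path, sep="\t", index=False)


def dkw_band(n: int, alpha: float = 0.05) -> float:
    """Dvoretzky-Kiefer-Wolfowitz band half-width for an n-point ecdf."""
    return np.sqrt(np.log(2.0 / alpha) / (2.0 * n))


def max_null_deviation(p_values: np.ndarray) -> float:
    """sup |ecdf(p) - p|: Kolmogorov distance of a stratum's p-values from uniform."""
    p = np.sort(np.asarray(p_values))
    n = p.size
    ecdf_hi = np.arange(1, n + 1) / n
    ecdf_lo = np.arange(0, n) / n
    return float(max(np.max(ecdf_hi - p), np.max(p - ecdf_lo)))


def plot_qq(qq: QQTable, path, title: str = "") -> None:
    """Quick-look conditional Q-Q plot (one curve per stratum)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    for t in sorted(qq.counts, reverse=True):
        sub = qq.stratum(t)
        if len(sub):
            ax.plot(sub["expected"], sub["observed"], label=f"p2 <= {t:g}")
    lim = qq.table["expected"].max()
    ax.plot([0, lim], [0, lim], "k--", lw=0.8, label="null")
    ax.set_xlabel("expected -log10 p")
    ax.set_ylabel("observed -log10 p")
    ax.legend(fontsize=8)
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
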