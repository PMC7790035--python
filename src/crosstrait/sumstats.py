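"""Reading, validation, harmonization and region filtering of GWAS summary statistics.

A summary-statistic set is a pandas DataFrame with the canonical columns
``SNP, CHR, BP, A1, A2, Z, N, P`` (1-based positions, A1 the effect allele).
Harmonized two-trait tables carry ``Z_A/Z_B`` etc. and are the substrate for
every downstream comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

COLUMNS = ["SNP", "CHR", "BP", "A1", "A2", "Z", "N", "P"]
PAIR_COLUMNS = ["SNP", "CHR", "BP", "A1", "A2", "Z_A", "Z_B", "N_A", "N_B", "P_A", "P_B"]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_VALID = frozenset("ACGT")

DEFAULT_P_FLOOR = 1e-300


def _z_cap(p_floor: float) -> float:
    return float(stats.norm.isf(p_floor / 2))


@dataclass
class RegionMask:
    """Genomic intervals to exclude, 1-based inclusive at both ends."""

    intervals: list = field(default_factory=list)  # (chrom, start, end)

    def __post_init__(self) -> None:
        for chrom, start, end in self.intervals:
            if start > end or start < 0:
                raise ValueError(f"bad interval {chrom}:{start}-{end}")

    @classmethod
    def default(cls) -> "RegionMask":
        """MHC (chr6:26-34 Mb) and the 8p23.1 inversion (chr8:7-13 Mb):
        long-range LD regions conventionally excluded before FDR lookup
        construction."""
        return cls([("6", 26_000_000, 34_000_000), ("8", 7_000_000, 13_000_000)])

    @classmethod
    def from_bed(cls, path) -> "RegionMask":
        """Read a BED file (0-based half-open) and convert to 1-based inclusive."""
        bed = pd.read_csv(path, sep="\t", header=None, comment="#",
                          usecols=[0, 1, 2], names=["chrom", "start", "end"],
                          dtype={"chrom": str})
        ivs = [(c.removeprefix("chr"), int(s) + 1, int(e)) for c, s, e in
               bed.itertuples(index=False)]
        return cls(ivs)

    def contains(self, chrom: np.ndarray, pos: np.ndarray) -> np.ndarray:
        """Boolean mask: True where (chrom, pos) falls inside any interval."""
        hit = np.zeros(len(pos), dtype=bool)
        chrom = np.asarray(chrom, dtype=object)
        pos = np.asarray(pos)
        for c, s, e in self.intervals:
            hit |= (chrom == str(c)) & (pos >= s) & (pos <= e)
        return hit


DEFAULT_COLUMN_MAP = {
    "SNP": "SNP", "CHR": "CHR", "BP": "BP", "A1": "A1", "A2": "A2",
    "Z": "Z", "N": "N", "P": "P", "BETA": "BETA", "SE": "SE",
}


def read_sumstats(path, column_map: dict | None = None, sep: str | None = None,
                  p_floor: float = DEFAULT_P_FLOOR,
                  p_z_tol: float = 1e-4) -> pd.DataFrame:
    """Read and validate one trait's summary statistics.

    ``column_map`` maps canonical names (SNP, CHR, BP, A1, A2, Z, N, P and
    optionally BETA, SE) to the file's column names. Z is derived as BETA/SE
    when absent; when only P and a signed BETA are present, Z is recovered
    from the p-value quantile with BETA's sign. P is derived from Z when
    absent. Rows failing validation are dropped and counted in
    ``df.attrs['dropped']``.
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    df = pd.read_csv(path, sep=sep if sep is not None else r"\s+",
                     dtype={cmap["SNP"]: str, cmap["CHR"]: str})

    for col in ("SNP", "CHR", "BP", "A1", "A2", "N"):
        if cmap[col] not in df.columns:
            raise ValueError(f"missing column {cmap[col]}")
    have = lambda k: cmap[k] in df.columns
    if not (have("Z") or (have("BETA") and have("SE")) or (have("P") and have("BETA"))):
        raise ValueError("need one of Z, BETA+SE, or P+signed BETA; "
                         f"missing column {cmap['Z']}")

    out = pd.DataFrame({
        "SNP": df[cmap["SNP"]].astype(str),
        "CHR": df[cmap["CHR"]].astype(str).str.removeprefix("chr"),
        "BP": pd.to_numeric(df[cmap["BP"]], errors="coerce"),
        "A1": df[cmap["A1"]].astype(str).str.upper(),
        "A2": df[cmap["A2"]].astype(str).str.upper(),
        "N": pd.to_numeric(df[cmap["N"]], errors="coerce"),
    })
    if have("Z"):
        out["Z"] = pd.to_numeric(df[cmap["Z"]], errors="coerce")
    elif have("BETA") and have("SE"):
        out["Z"] = (pd.to_numeric(df[cmap["BETA"]], errors="coerce")
                    / pd.to_numeric(df[cmap["SE"]], errors="coerce"))
    else:
        p = pd.to_numeric(df[cmap["P"]], errors="coerce").clip(lower=p_floor)
        sign = np.sign(pd.to_numeric(df[cmap["BETA"]], errors="coerce"))
        out["Z"] = sign * stats.norm.isf(p / 2)
    if have("P"):
        out["P"] = pd.to_numeric(df[cmap["P"]], errors="coerce")
    else:
        out["P"] = 2 * stats.norm.sf(np.abs(out["Z"]))

    dropped: dict[str, int] = {}

    def drop(mask: np.ndarray, reason: str) -> None:
        n = int(mask.sum())
        if n:
            dropped[reason] = dropped.get(reason, 0) + n
            logger.warning("read_sumstats: dropping %d rows (%s)", n, reason)
        out.drop(index=out.index[mask], inplace=True)

    drop(out[["SNP", "BP", "Z", "N", "P"]].isna().any(axis=1).to_numpy(), "missing value")
    n_floor = int((out["P"] <= 0).sum())
    if n_floor:
        logger.warning("read_sumstats: clamping %d p-values to floor %.3g", n_floor, p_floor)
    out["P"] = out["P"].clip(lower=p_floor)
    drop((out["P"] > 1).to_numpy(), "p > 1")
    drop((out["BP"] < 1).to_numpy(), "position < 1")
    drop((~out["A1"].isin(_VALID) | ~out["A2"].isin(_VALID)).to_numpy(), "non-ACGT allele")
    drop((out["A1"] == out["A2"]).to_numpy(), "identical alleles")
    drop(out.duplicated("SNP", keep="first").to_numpy(), "duplicate id")
    # p/z consistency where both were supplied
    if have("Z") and have("P"):
        p_from_z = 2 * stats.norm.sf(np.minimum(np.abs(out["Z"]), _z_cap(p_floor)))
        drop((np.abs(out["P"] - np.maximum(p_from_z, p_floor)) > p_z_tol).to_numpy(),
             "p inconsistent with z")

    zc = _z_cap(p_floor)
    out["Z"] = out["Z"].clip(-zc, zc)
    out["BP"] = out["BP"].astype(np.int64)
    if len(out) == 0:
        raise ValueError("no rows survived validation")
    out = out[COLUMNS].reset_index(drop=True)
    out.attrs["dropped"] = dropped
    return out


def validate_sumstats(df: pd.DataFrame) -> pd.DataFrame:
    """Check the SummaryStats invariants on an in-memory frame; returns df."""
    if df["SNP"].duplicated().any():
        raise ValueError("duplicate SNP ids")
    if ((df["P"] <= 0) | (df["P"] > 1)).any():
        raise ValueError("p outside (0, 1]")
    if (df["BP"] < 1).any():
        raise ValueError("position < 1")
    if (df["A1"] == df["A2"]).any():
        raise ValueError("identical alleles")
    return df


def _is_ambiguous(a1: pd.Series, a2: pd.Series) -> pd.Series:
    comp = a1.map(_COMPLEMENT)
    return comp == a2  # A/T, T/A, C/G, G/C


def harmonize_pair(a: pd.DataFrame, b: pd.DataFrame, drop_ambiguous: bool = True,
                   join_on_position: bool = False) -> pd.DataFrame:
    """Merge two traits on shared SNPs with allele-aligned z-scores.

    Trait B's z is negated when its alleles are the swap of A's; strand
    complements are mapped before matching. Strand-ambiguous SNPs (A/T, C/G)
    are dropped by default since they cannot be oriented without allele
    frequencies. Counts of each action land in ``attrs['harmonize']``.
    """
    key = ["CHR", "BP"] if join_on_position else ["SNP"]
    m = a.merge(b, on=key, suffixes=("_A", "_B"), how="inner")
    if join_on_position:
        m = m.rename(columns={"SNP_A": "SNP"}).drop(columns=["SNP_B"])
    else:
        m = m.rename(columns={"CHR_A": "CHR", "BP_A": "BP"}).drop(columns=["CHR_B", "BP_B"])
    if len(m) == 0:
        raise ValueError("no shared SNPs between the two traits")
    if len(m) < 1000:
        logger.warning("harmonize_pair: only %d shared SNPs", len(m))

    counts = {"same": 0, "swap": 0, "complement": 0, "complement_swap": 0,
              "ambiguous_dropped": 0, "unresolvable_dropped": 0}
    a1a, a2a = m["A1_A"], m["A2_A"]
    a1b, a2b = m["A1_B"], m["A2_B"]
    c1b = a1b.map(_COMPLEMENT)
    c2b = a2b.map(_COMPLEMENT)

    same = (a1b == a1a) & (a2b == a2a)
    swap = (a1b == a2a) & (a2b == a1a) & ~same
    comp = (c1b == a1a) & (c2b == a2a) & ~same & ~swap
    comp_swap = (c1b == a2a) & (c2b == a1a) & ~same & ~swap & ~comp
    ambiguous = _is_ambiguous(a1a, a2a) & (same | swap | comp | comp_swap)

    if drop_ambiguous:
        keep_amb = ~ambiguous
        counts["ambiguous_dropped"] = int(ambiguous.sum())
    else:
        # without frequencies an ambiguous SNP is taken at face value
        keep_amb = pd.Series(True, index=m.index)

    resolvable = same | swap | comp | comp_swap
    counts["unresolvable_dropped"] = int((~resolvable & keep_amb).sum())
    keep = resolvable & keep_amb
    flip = (swap | comp_swap) & keep
    counts["same"] = int((same & keep).sum())
    counts["swap"] = int((swap & keep).sum())
    counts["complement"] = int((comp & keep).sum())
    counts["complement_swap"] = int((comp_swap & keep).sum())

    m.loc[flip, "Z_B"] = -m.loc[flip, "Z_B"]
    m = m[keep].copy()
    if len(m) == 0:
        raise ValueError("no shared SNPs survived allele harmonization")
    m["A1"] = m["A1_A"]
    m["A2"] = m["A2_A"]
    m = m[PAIR_COLUMNS].reset_index(drop=True)
    m.attrs["harmonize"] = counts
    logger.info("harmonize_pair: %d SNPs kept (%s)", len(m), counts)
    return m


def exclude_regions(s: pd.DataFrame, mask: RegionMask) -> pd.DataFrame:
    """Remove SNPs falling inside any mask interval (inclusive at both ends)."""
    if not mask.intervals:
        return s.reset_index(drop=True)
    hit = mask.contains(s["CHR"].to_numpy(), s["BP"].to_numpy())
    out = s[~hit].reset_index(drop=True)
    out.attrs.update(s.attrs)
    logger.info("exclude_regions: removed %d of %d SNPs", int(hit.sum()), len(s))
    return out


def write_sumstats(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_pair(path) -> pd.DataFrame:
    """Read a harmonized-pair TSV written by write_pair."""
    df = pd.read_csv(path, sep="\t", dtype={"SNP": str, "CHR": str})
    missing = [c for c in PAIR_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing column {missing[0]}")
    return df


def write_pair(df: pd.DataFrame, path) -> None:
    df[PAIR_COLUMNS].to_csv(path, sep="\t", index=False)


def pair_to_single(pair: pd.DataFrame, trait: str) -> pd.DataFrame:
    """Extract one trait's SummaryStats view from a harmonized pair."""
    suf = {"A": "_A", "B": "_B"}[trait]
    return pd.DataFrame({
        "SNP": pair["SNP"], "CHR": pair["CHR"], "BP": pair["BP"],
        "A1": pair["A1"], "A2": pair["A2"],
        "Z": pair["Z" + suf], "N": pair["N" + suf], "P": pair["P" + suf],
    })
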