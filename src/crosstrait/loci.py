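"""FUMA-style genomic locus definition and effect-direction concordance.

Tiers, in order: independent significant SNPs (conjFDR < 0.05, mutually
r2 < 0.6, greedy by ascending conjFDR), lead SNPs (a subset mutually
r2 < 0.1), candidate SNPs (conjFDR < 0.10 and r2 >= 0.6 with an independent
significant SNP). Candidate envelopes within 250 kb of each other merge
into one locus; the merged locus' lead is its smallest-conjFDR independent
significant SNP. Concordance compares the sign of the two traits' z-scores
at each locus' lead SNP.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ld import LDStructure

logger = logging.getLogger(__name__)


@dataclass
class Locus:
    chrom: str
    start: int
    end: int
    lead_snp: str
    lead_conjfdr: float
    ind_sig_snps: list
    cand_snps: list
    z_a: float
    z_b: float
    concordant: bool | None = field(default=None)

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("locus start > end")
        if np.isfinite(self.z_a) and np.isfinite(self.z_b) \
                and self.z_a != 0 and self.z_b != 0:
            self.concordant = bool(np.sign(self.z_a) == np.sign(self.z_b))
        else:
            self.concordant = None  # "na": effect direction unavailable


def define_loci(scored: pd.DataFrame, ld: LDStructure,
                sig_thresh: float = 0.05, cand_thresh: float = 0.10,
                r2_indep: float = 0.6, r2_lead: float = 0.1,
                merge_kb: float = 250.0,
                fdr_col: str = "CONJFDR") -> list[Locus]:
    """Collapse scored SNPs into independent genomic loci.

    Ties in conjFDR are broken by ascending (chrom, pos), making the greedy
    selection deterministic and row-order independent.
    """
    df = scored.copy()
    df["_chr"] = df["CHR"].astype(str)
    df = df.sort_values([fdr_col, "_chr", "BP"], kind="mergesort").reset_index(drop=True)

    sig = df[df[fdr_col] < sig_thresh]
    if len(sig) == 0:
        return []

    # tier 1: independent significant SNPs, greedy by ascending conjFDR
    ind_sig: list[str] = []
    for snp in sig["SNP"]:
        if all(ld.r2(snp, kept) < r2_indep for kept in ind_sig):
            ind_sig.append(snp)
    # tier 2: lead SNPs, mutually r2 < r2_lead (subset of independent sig)
    leads: list[str] = []
    for snp in ind_sig:
        if all(ld.r2(snp, kept) < r2_lead for kept in leads):
            leads.append(snp)

    cand_pool = df[df[fdr_col] < cand_thresh]
    info = df.set_index("SNP")

    # tier 3: candidate envelope per independent significant SNP
    envelopes = []
    for snp in ind_sig:
        r2s = ld.r2_with(snp, cand_pool["SNP"].to_numpy())
        cands = set(cand_pool["SNP"].to_numpy()[r2s >= r2_indep])
        cands.add(snp)  # an independent significant SNP is its own candidate
        positions = info.loc[list(cands), "BP"]
        envelopes.append({
            "chrom": info.at[snp, "_chr"],
            "start": int(positions.min()),
            "end": int(positions.max()),
            "ind_sig": [snp],
            "cands": cands,
        })

    # tier 4: merge envelopes on the same chromosome within merge_kb
    envelopes.sort(key=lambda e: (e["chrom"], e["start"], e["end"]))
    merged = []
    gap = merge_kb * 1000.0
    for env in envelopes:
        if merged and env["chrom"] == merged[-1]["chrom"] \
                and env["start"] - merged[-1]["end"] <= gap:
            top = merged[-1]
            top["end"] = max(top["end"], env["end"])
            top["ind_sig"].extend(env["ind_sig"])
            top["cands"] |= env["cands"]
        else:
            merged.append(env)

    loci = []
    for env in merged:
        lead = min(env["ind_sig"],
                   key=lambda s: (info.at[s, fdr_col], info.at[s, "_chr"],
                                  info.at[s, "BP"]))
        cands_sorted = sorted(env["cands"], key=lambda s: info.at[s, "BP"])
        loci.append(Locus(
            chrom=env["chrom"], start=env["start"], end=env["end"],
            lead_snp=lead, lead_conjfdr=float(info.at[lead, fdr_col]),
            ind_sig_snps=sorted(env["ind_sig"], key=lambda s: info.at[s, "BP"]),
            cand_snps=cands_sorted,
            z_a=float(info.at[lead, "Z_A"]) if "Z_A" in info.columns else np.nan,
            z_b=float(info.at[lead, "Z_B"]) if "Z_B" in info.columns else np.nan,
        ))
    loci.sort(key=lambda l: (l.chrom, l.start))
    logger.info("define_loci: %d loci from %d significant SNPs "
                "(%d independent, %d lead-tier)",
                len(loci), len(sig), len(ind_sig), len(leads))
    return loci


@dataclass
class ConcordanceReport:
    n_loci: int
    n_concordant: int
    n_na: int
    percentage: float | None


def effect_concordance(loci: list[Locus]) -> ConcordanceReport:
    """Share of loci whose lead SNP has the same z sign in both traits.

    Loci with a zero or missing z in either trait are excluded from the
    percentage and counted as "na"."""
    usable = [l for l in loci if l.concordant is not None]
    n_conc = sum(l.concordant for l in usable)
    pct = round(100.0 * n_conc / len(usable), 1) if usable else None
    return ConcordanceReport(n_loci=len(loci), n_concordant=n_conc,
                             n_na=len(loci) - len(usable), percentage=pct)


def loci_to_frame(loci: list[Locus]) -> pd.DataFrame:
    return pd.DataFrame([{
        "CHR": l.chrom, "START": l.start, "END": l.end,
        "LEAD_SNP": l.lead_snp, "CONJFDR": l.lead_conjfdr,
        "N_IND_SIG": len(l.ind_sig_snps), "N_CAND": len(l.cand_snps),
        "Z_A": l.z_a, "Z_B": l.z_b,
        "CONCORDANT": "na" if l.concordant is None else str(l.concordant),
    } for l in loci])


def loci_to_bed(loci: list[Locus], path) -> None:
    """Write locus intervals as BED (converted to 0-based half-open)."""
    with open(path, "w") as fh:
        for l in loci:
            fh.write(f"chr{l.chrom}\t{l.start - 1}\t{l.end}\t{l.lead_snp}\n")
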