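"""End-to-end orchestration: simulate/load -> harmonize -> Q-Q -> mixture ->
cond/conjFDR -> loci -> concordance -> rg, from a single flat config.

Every stage seeds its randomness from the config seed through the package's
seed-derivation scheme, so a re-run with the same config reproduces every
output file bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cfdr import ConditionalFDR, trio_conjfdr, plot_manhattan
from .ld import LDStructure, ld_scores
from .ldsc import cross_trait_rg
from .loci import define_loci, effect_concordance, loci_to_frame
from .mixture import fit_bivariate, overlap_aic, prune_for_fit, venn_summary
from .qq import conditional_qq, plot_qq, qq_to_tsv
from .simulate import GenerativeParams, simulate_pair, simulate_trio
from .sumstats import (RegionMask, exclude_regions, harmonize_pair, read_sumstats,
                       write_pair)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Flat key-value run configuration; every threshold the analysis uses
    appears here explicitly with its default."""

    seed: int = 0
    out_dir: str = "crosstrait_run"
    # --- input: either simulate=True with the generator block, or file paths
    simulate: bool = True
    sumstats_a: str | None = None
    sumstats_b: str | None = None
    sumstats_c: str | None = None
    ld_triplets: str | None = None
    # generator (see GenerativeParams for meaning/units)
    m: int = 50_000
    n_blocks: int = 1000
    block_size: int = 50
    rho_within: float | tuple = (0.2, 0.4, 0.6, 0.8)
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
    # --- region exclusion (long-range LD): MHC chr6:26-34 Mb, 8p23.1 chr8:7-13 Mb
    use_default_mask: bool = True
    exclude_bed: str | None = None
    # --- conditional Q-Q
    qq_thresholds: tuple = (1.0, 0.1, 0.01, 0.001)
    qq_points: int = 1000
    # --- mixture model
    run_mixer: bool = True
    mixer_prune_r2: float = 0.1
    mixer_starts: int = 8
    # --- cond/conjFDR
    fdr_grid_step: float = 0.1
    fdr_grid_max: float = 20.0
    fdr_n_prune: int = 100
    fdr_r2_prune: float = 0.1
    conjfdr_thresh: float = 0.05
    # --- loci (FUMA-style)
    loci_sig_thresh: float = 0.05
    loci_cand_thresh: float = 0.10
    loci_r2_indep: float = 0.6
    loci_r2_lead: float = 0.1
    loci_merge_kb: float = 250.0
    # --- LD-score regression
    rg_jackknife_blocks: int = 200
    # --- output
    write_plots: bool = False

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if not self.simulate:
            for key in ("sumstats_a", "sumstats_b"):
                p = getattr(self, key)
                if p is None or not Path(p).exists():
                    raise FileNotFoundError(f"{key}: missing input file {p!r}")
            if self.ld_triplets is None or not Path(self.ld_triplets).exists():
                raise FileNotFoundError(
                    f"ld_triplets: missing input file {self.ld_triplets!r}")
        if self.exclude_bed is not None and not Path(self.exclude_bed).exists():
            raise FileNotFoundError(f"exclude_bed: missing file {self.exclude_bed!r}")
        for key, lo, hi in (("conjfdr_thresh", 0, 1), ("loci_sig_thresh", 0, 1),
                            ("loci_cand_thresh", 0, 1), ("loci_r2_indep", 0, 1),
                            ("loci_r2_lead", 0, 1), ("fdr_r2_prune", 0, 1),
                            ("mixer_prune_r2", 0, 1)):
            v = getattr(self, key)
            if not (lo < v <= hi):
                raise ValueError(f"{key}={v} outside ({lo}, {hi}]")

    def generative_params(self) -> GenerativeParams:
        return GenerativeParams(
            m=self.m, n_blocks=self.n_blocks, block_size=self.block_size,
            rho_within=self.rho_within, pi_a=self.pi_a, pi_b=self.pi_b,
            pi_ab=self.pi_ab, sigma_b2_a=self.sigma_b2_a,
            sigma_b2_b=self.sigma_b2_b, rho_beta=self.rho_beta,
            sigma0_a=self.sigma0_a, sigma0_b=self.sigma0_b, rho0=self.rho0,
            n_a=self.n_a, n_b=self.n_b, seed=self.seed,
        )

    def digest(self) -> str:
        """Hash of the scientific configuration (output location excluded)."""
        d = asdict(self)
        d.pop("out_dir")
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class ResultBundle:
    """All stage outputs of one run, plus provenance."""

    pair: pd.DataFrame
    qq_ab: object
    qq_ba: object
    mixer: dict | None
    scored: pd.DataFrame
    loci: list
    concordance: object
    rg: object
    provenance: dict
    trio: dict | None = None

    def summary(self) -> dict:
        out = {
            "n_snps": int(len(self.pair)),
            "qq_counts": {str(k): int(v) for k, v in self.qq_ab.counts.items()},
            "n_conjfdr_significant": int(
                (self.scored["CONJFDR"] < self.provenance["conjfdr_thresh"]).sum()),
            "n_loci": len(self.loci),
            "concordance": dataclasses.asdict(self.concordance),
            "rg": dataclasses.asdict(self.rg),
            "provenance": self.provenance,
        }
        if self.mixer is not None:
            out["mixer"] = self.mixer
        if self.trio is not None:
            out["trio"] = {"n_trio_significant": self.trio["n_trio_significant"],
                           "n_trio_loci": len(self.trio["loci"])}
        return out


def _mask(cfg: RunConfig) -> RegionMask:
    if cfg.exclude_bed is not None:
        return RegionMask.from_bed(cfg.exclude_bed)
    if cfg.use_default_mask:
        return RegionMask.default()
    return RegionMask([])


def _load_pair(cfg: RunConfig):
    if cfg.simulate:
        gp = cfg.generative_params()
        sa, sb, ld, effects = simulate_pair(gp)
        m_total = gp.m
    else:
        sa = read_sumstats(cfg.sumstats_a)
        sb = read_sumstats(cfg.sumstats_b)
        ld = LDStructure.from_triplets(cfg.ld_triplets)
        effects = None
        m_total = len(sa)
    mask = _mask(cfg)
    sa = exclude_regions(sa, mask)
    sb = exclude_regions(sb, mask)
    pair = harmonize_pair(sa, sb)
    ld_sub = ld.subset(pair["SNP"])
    return pair, ld_sub, effects, m_total


def run_pair_analysis(cfg: RunConfig) -> ResultBundle:
    """Execute every stage in order; outputs land in cfg.out_dir."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    pair, ld_sub, effects, m_total = _load_pair(cfg)
    logger.info("stage harmonize: %d SNPs in, %d analyzed", m_total, len(pair))
    write_pair(pair, out / "pair.tsv")

    qq_ab = conditional_qq(pair, cfg.qq_thresholds, cfg.qq_points, primary="A")
    qq_ba = conditional_qq(pair, cfg.qq_thresholds, cfg.qq_points, primary="B")
    qq_to_tsv(qq_ab, out / "qq_ab.tsv")
    qq_to_tsv(qq_ba, out / "qq_ba.tsv")
    logger.info("stage qq: strata counts %s", qq_ab.counts)

    mixer_report = None
    if cfg.run_mixer:
        pruned = prune_for_fit(pair, ld_sub, r2_max=cfg.mixer_prune_r2,
                               seed=cfg.seed)
        fit = fit_bivariate(pruned, n_starts=cfg.mixer_starts,
                            random_state=cfg.seed)
        venn = venn_summary(fit, m_total)
        aic = overlap_aic(fit, pruned)
        mixer_report = {
            "params": dataclasses.asdict(fit.params_),
            "nll": fit.nll_, "aic": fit.aic_, "n_snps": fit.n_snps_,
            "venn": venn, "rg_implied": fit.rg_implied(),
            **{k: (None if isinstance(v, float) and np.isnan(v) else v)
               for k, v in aic.items()},
        }
        logger.info("stage mixer: venn %s", venn)

    scorer = ConditionalFDR(grid_step=cfg.fdr_grid_step, grid_max=cfg.fdr_grid_max,
                            n_prune=cfg.fdr_n_prune, r2_prune=cfg.fdr_r2_prune,
                            random_state=cfg.seed)
    scored = scorer.fit(pair, ld=ld_sub).transform(pair)
    scored.to_csv(out / "scored.tsv", sep="\t", index=False)
    n_sig = int((scored["CONJFDR"] < cfg.conjfdr_thresh).sum())
    logger.info("stage conjfdr: %d of %d SNPs significant", n_sig, len(scored))

    loci = define_loci(scored, ld_sub, sig_thresh=cfg.loci_sig_thresh,
                       cand_thresh=cfg.loci_cand_thresh,
                       r2_indep=cfg.loci_r2_indep, r2_lead=cfg.loci_r2_lead,
                       merge_kb=cfg.loci_merge_kb)
    loci_to_frame(loci).to_csv(out / "loci.tsv", sep="\t", index=False)
    conc = effect_concordance(loci)
    logger.info("stage loci: %d loci, %s%% concordant", len(loci), conc.percentage)

    scores = ld_scores(ld_sub)
    rg = cross_trait_rg(pair, scores, m=m_total,
                        n_blocks_jk=cfg.rg_jackknife_blocks)
    logger.info("stage rg: rg=%s se=%s", rg.rg, rg.se)

    if cfg.write_plots:
        plot_qq(qq_ab, out / "qq_ab.png", title="A | B")
        plot_manhattan(scored, out / "manhattan.png",
                       sig_thresh=cfg.conjfdr_thresh)

    provenance = {"config_digest": cfg.digest(), "seed": cfg.seed,
                  "version": __version__, "m_total": m_total,
                  "conjfdr_thresh": cfg.conjfdr_thresh}
    bundle = ResultBundle(pair=pair, qq_ab=qq_ab, qq_ba=qq_ba,
                          mixer=mixer_report, scored=scored, loci=loci,
                          concordance=conc, rg=rg, provenance=provenance)
    with open(out / "report.json", "w") as fh:
        json.dump(bundle.summary(), fh, indent=2, sort_keys=True, default=str)
    return bundle


def run_trio_analysis(cfg: RunConfig, trio_weights: dict | None = None) -> ResultBundle:
    """Three pairwise analyses plus trio conjFDR and trio locus definition.

    In simulate mode a three-trait generator with all seven causal
    components is used; the pairwise A-B bundle's stages are reported in
    full, with the trio table and loci attached.
    """
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    mask = _mask(cfg)
    if cfg.simulate:
        stats_list, ld, _ = simulate_trio(cfg.generative_params(),
                                          weights=trio_weights)
        m_total = cfg.m
    else:
        if cfg.sumstats_c is None or not Path(cfg.sumstats_c).exists():
            raise FileNotFoundError(
                f"sumstats_c: missing input file {cfg.sumstats_c!r}")
        stats_list = [read_sumstats(p) for p in
                      (cfg.sumstats_a, cfg.sumstats_b, cfg.sumstats_c)]
        ld = LDStructure.from_triplets(cfg.ld_triplets)
        m_total = len(stats_list[0])
    stats_list = [exclude_regions(s, mask) for s in stats_list]

    scored = {}
    for tag, (i, j) in {"ab": (0, 1), "ac": (0, 2), "bc": (1, 2)}.items():
        pair = harmonize_pair(stats_list[i], stats_list[j])
        ld_sub = ld.subset(pair["SNP"])
        scorer = ConditionalFDR(grid_step=cfg.fdr_grid_step,
                                grid_max=cfg.fdr_grid_max,
                                n_prune=cfg.fdr_n_prune,
                                r2_prune=cfg.fdr_r2_prune,
                                random_state=cfg.seed)
        scored[tag] = scorer.fit(pair, ld=ld_sub).transform(pair)
        scored[tag].to_csv(out / f"scored_{tag}.tsv", sep="\t", index=False)

    trio = trio_conjfdr(scored["ab"], scored["ac"], scored["bc"])
    trio = trio.merge(scored["ab"][["SNP", "Z_A", "Z_B"]], on="SNP")
    trio.to_csv(out / "trio_scored.tsv", sep="\t", index=False)
    ld_trio = ld.subset(trio["SNP"])
    trio_loci = define_loci(trio, ld_trio, sig_thresh=cfg.loci_sig_thresh,
                            cand_thresh=cfg.loci_cand_thresh,
                            r2_indep=cfg.loci_r2_indep,
                            r2_lead=cfg.loci_r2_lead,
                            merge_kb=cfg.loci_merge_kb,
                            fdr_col="TRIO_CONJFDR")
    loci_to_frame(trio_loci).to_csv(out / "trio_loci.tsv", sep="\t", index=False)
    n_trio_sig = int((trio["TRIO_CONJFDR"] < cfg.conjfdr_thresh).sum())
    logger.info("stage trio: %d SNPs, %d loci", n_trio_sig, len(trio_loci))

    # full pairwise bundle for A-B (re-uses the scored table computed above)
    pair_ab = harmonize_pair(stats_list[0], stats_list[1])
    ld_ab = ld.subset(pair_ab["SNP"])
    qq_ab = conditional_qq(pair_ab, cfg.qq_thresholds, cfg.qq_points, primary="A")
    qq_ba = conditional_qq(pair_ab, cfg.qq_thresholds, cfg.qq_points, primary="B")
    loci_ab = define_loci(scored["ab"], ld_ab, sig_thresh=cfg.loci_sig_thresh,
                          cand_thresh=cfg.loci_cand_thresh,
                          r2_indep=cfg.loci_r2_indep, r2_lead=cfg.loci_r2_lead,
                          merge_kb=cfg.loci_merge_kb)
    conc = effect_concordance(loci_ab)
    rg = cross_trait_rg(pair_ab, ld_scores(ld_ab), m=m_total,
                        n_blocks_jk=cfg.rg_jackknife_blocks)
    provenance = {"config_digest": cfg.digest(), "seed": cfg.seed,
                  "version": __version__, "m_total": m_total,
                  "conjfdr_thresh": cfg.conjfdr_thresh}
    bundle = ResultBundle(pair=pair_ab, qq_ab=qq_ab, qq_ba=qq_ba, mixer=None,
                          scored=scored["ab"], loci=loci_ab, concordance=conc,
                          rg=rg, provenance=provenance,
                          trio={"table": trio, "loci": trio_loci,
                                "n_trio_significant": n_trio_sig})
    with open(out / "report.json", "w") as fh:
        json.dump(bundle.summary(), fh, indent=2, sort_keys=True, default=str)
    return bundle
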