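"""End-to-end orchestration: simulate/load -> enrich -> conjFDR -> tier ->
coloc -> motif -> MR -> report.

Each stage writes plain-text artifacts (TSV/BED/FASTA/JSON) into the output
directory and reads only prior-stage artifacts, so any stage can be rerun or
audited standalone; with ``resume=True`` completed stages are skipped. Every
output carries a header with the package version, a config hash, and the
master seed, and a rerun with the same config reproduces outputs
byte-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, coloc, loci, motif, mr, pleiofdr, simulate
from .sumstats_io import SummaryStats, write_sumstats, read_sumstats

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of a full synthetic study run."""

    seed: int = 0
    outdir: str = "pleiomr_run"
    resume: bool = False
    # simulation (study conditions)
    n_background_blocks: int = 400
    block_size: int = 50
    ld_rho: float = 0.6
    n_gwas: int = 50_000
    # stage thresholds
    tier: loci.TierConfig = field(default_factory=loci.TierConfig)
    priors: coloc.ColocPriors = field(default_factory=coloc.ColocPriors)
    motif_cfg: motif.MotifConfig = field(default_factory=motif.MotifConfig)
    instruments: mr.InstrumentConfig = field(default_factory=mr.InstrumentConfig)
    # motif stage
    n_promoters: int = 30
    promoter_length: int = 500
    plant_rate_target: float = 0.6
    plant_rate_background: float = 0.05
    # MR stage
    n_boot: int = 500
    known_loci: list = field(default_factory=list)
    # report enrichment against a null secondary trait alongside the real one
    negative_control: bool = False

    def hash(self) -> str:
        # outdir/resume are execution details, not analysis conditions
        payload = asdict(self)
        payload.pop("outdir", None)
        payload.pop("resume", None)
        payload = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _header(cfg: RunConfig) -> str:
    return (
        f"# pleiomr {__version__} seed={cfg.seed} config={cfg.hash()}\n"
    )


def _write_tsv(df: pd.DataFrame, path: Path, cfg: RunConfig) -> None:
    with open(path, "w") as fh:
        fh.write(_header(cfg))
        df.to_csv(fh, sep="\t", index=False)


def _vid_index(stats: SummaryStats) -> dict:
    return {v: i for i, v in enumerate(stats.df["variant_id"])}


def run_all(config: RunConfig) -> dict:
    """Execute the full study and return the run report (also written to disk)."""
    cfg = config
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "config_hash": cfg.hash(),
    }

    # ---- stage: simulate -------------------------------------------------
    study = simulate.simulate_study(
        seed=cfg.seed,
        n_background_blocks=cfg.n_background_blocks,
        block_size=cfg.block_size,
        rho=cfg.ld_rho,
        n_gwas=cfg.n_gwas,
    )
    stage_files = {
        "ad_female": out / "ad_female.tsv",
        "ad_male": out / "ad_male.tsv",
        "hormone_female": out / "hormone_female.tsv",
    }
    if not (cfg.resume and all(f.exists() for f in stage_files.values())):
        for key, path in stage_files.items():
            write_sumstats(study[key], path)
    ad_f, ad_m, horm = study["ad_female"], study["ad_male"], study["hormone_female"]
    ld = study["ld"]
    report["n_variants"] = len(ad_f)

    # ---- stage: enrichment ----------------------------------------------
    enrich_path = out / "enrichment.tsv"
    if cfg.resume and enrich_path.exists():
        curves = pd.read_csv(enrich_path, sep="\t", comment="#")
    else:
        curves = pleiofdr.fold_enrichment(ad_f, horm)
        _write_tsv(curves, enrich_path, cfg)
    report["enrichment_max"] = float(curves["enrichment"].max())
    if cfg.negative_control:
        ctrl_path = out / "enrichment_control.tsv"
        if not (cfg.resume and ctrl_path.exists()):
            null_cfg = simulate.SimConfig(
                n_variants=len(ad_f),
                block_size=cfg.block_size,
                ld_rho=cfg.ld_rho,
                pi_null=1.0,
                pi_A=0.0,
                pi_B=0.0,
                pi_shared=0.0,
                seed=cfg.seed + 909,
            )
            control, _, _ = simulate.simulate_gwas_pair(null_cfg)
            control.trait_label = "control"
            ctrl = pleiofdr.fold_enrichment(ad_f, control)
            _write_tsv(ctrl, ctrl_path, cfg)
            report["enrichment_control_max"] = float(ctrl["enrichment"].max())

    # ---- stage: conjFDR --------------------------------------------------
    conj_path = out / "conjfdr.tsv"
    if cfg.resume and conj_path.exists():
        table = pd.read_csv(conj_path, sep="\t", comment="#", dtype={"chrom": str})
    else:
        res = pleiofdr.ConjFdrModel(ad_f, horm, ld=ld).fit(seed=cfg.seed)
        table = res.table
        _write_tsv(table, conj_path, cfg)
    discoveries = table[table["conjfdr"] < cfg.tier.conjfdr_threshold].reset_index(drop=True)
    report["n_pleiotropic_variants"] = int(len(discoveries))

    # ---- stage: clump + coloc + tiers -----------------------------------
    idx = _vid_index(ad_f)
    tiers_path = out / "tiers.tsv"
    coloc_path = out / "coloc_cross_trait.tsv"
    if cfg.resume and tiers_path.exists():
        tiers = pd.read_csv(tiers_path, sep="\t", comment="#", dtype={"chrom": str})
    else:
        clumps = loci.ld_clump(
            discoveries,
            ld,
            r2_threshold=cfg.tier.clump_r2,
            id_to_index=idx,
            merge_distance=cfg.tier.merge_distance,
        )
        f = ad_f.df.set_index("variant_id")
        m_ = ad_m.df.set_index("variant_id")
        effects = pd.DataFrame(
            {
                "beta_women": f["beta"],
                "se_women": f["se"],
                "beta_men": m_["beta"],
                "se_men": m_["se"],
            }
        )
        coloc_results, coloc_rows = {}, []
        block = ld.block
        for clump in clumps:
            b = block[idx[clump.lead]]
            sel = np.flatnonzero(block == b)
            r1 = ad_f.df.iloc[sel]
            r2_ = horm.df.iloc[sel]
            res_c = coloc.coloc_posteriors(r1, r2_, priors=cfg.priors)
            coloc_results[clump.lead] = res_c
            coloc_rows.append(
                {
                    "lead_variant_id": clump.lead,
                    "pp0": res_c.pp0,
                    "pp1": res_c.pp1,
                    "pp2": res_c.pp2,
                    "pp3": res_c.pp3,
                    "pp4": res_c.pp4,
                    "top_shared_variant_id": res_c.top_shared_variant_id,
                }
            )
        tiers = loci.assign_tiers(clumps, effects, coloc_results, cfg.tier)
        tiers = loci.annotate_novelty(tiers, cfg.known_loci, cfg.tier.novelty_window)
        _write_tsv(tiers, tiers_path, cfg)
        _write_tsv(pd.DataFrame(coloc_rows), coloc_path, cfg)
        bed = tiers.assign(start=tiers["pos"] - 1, end=tiers["pos"])
        with open(out / "tiers.bed", "w") as fh:
            fh.write(_header(cfg))
            bed[["chrom", "start", "end", "lead_variant_id", "tier"]].to_csv(
                fh, sep="\t", index=False, header=False
            )
    tier_counts = tiers["tier"].value_counts().to_dict() if len(tiers) else {}
    n3 = int(len(tiers))
    n2 = int((tiers["tier"] <= 2).sum()) if len(tiers) else 0
    n1 = int((tiers["tier"] == 1).sum()) if len(tiers) else 0
    report["tier_counts"] = {"tier3": n3, "tier2": n2, "tier1": n1}
    report["sex_bias_directions"] = (
        tiers.loc[tiers["tier"] <= 2, "sex_bias_direction"].value_counts().to_dict()
        if len(tiers)
        else {}
    )
    report["n_novel"] = int(tiers["novel"].sum()) if len(tiers) else 0

    # ---- stage: motif ----------------------------------------------------
    motif_path = out / "motif_enrichment.tsv"
    if cfg.resume and motif_path.exists():
        motif_table = pd.read_csv(motif_path, sep="\t", comment="#")
    else:
        pwm = motif.hormone_receptor_pwm()
        targets, background, _ = simulate.simulate_promoters(
            n_genes=cfg.n_promoters,
            length=cfg.promoter_length,
            pwm=pwm,
            plant_rate_target=cfg.plant_rate_target,
            plant_rate_background=cfg.plant_rate_background,
            seed=cfg.seed + 101,
        )
        p, counts = motif.motif_set_enrichment(
            targets, background, pwm, cfg.motif_cfg.score_threshold
        )
        motif_table = pd.DataFrame([{"motif": pwm.name, "p": p, **counts}])
        _write_tsv(motif_table, motif_path, cfg)
    report["motif_enrichment"] = motif_table.to_dict("records")

    # ---- stage: MR -------------------------------------------------------
    mr_path = out / "mr_results.tsv"
    if cfg.resume and mr_path.exists():
        mr_table = pd.read_csv(mr_path, sep="\t", comment="#")
    else:
        try:
            model = mr.MRModel.from_sumstats(
                horm, ad_f, ld, cfg.instruments, id_to_index=idx
            )
            battery = model.fit_all(seed=cfg.seed + 202, n_boot=cfg.n_boot)
            mr_table = battery.table()
            ivw_mask = mr_table["method"].str.startswith("IVW")
            mr_table["fdr_p"] = np.nan
            mr_table.loc[ivw_mask, "fdr_p"] = mr.bh_fdr(
                mr_table.loc[ivw_mask, "p"], family_label="female"
            )
        except ValueError as exc:
            log.warning("MR stage produced no estimate: %s", exc)
            mr_table = pd.DataFrame()
        _write_tsv(mr_table, mr_path, cfg)
    report["mr"] = mr_table.to_dict("records") if len(mr_table) else []

    # ---- report ----------------------------------------------------------
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=str)
    return report


def robustness_check(
    primary: SummaryStats,
    alternate: SummaryStats,
    lead_variants: list[str],
) -> pd.DataFrame:
    """Compare lead-variant effects between two outcome GWAS versions.

    Per lead: sign concordance, effect ratio, and a heterogeneity Z between
    the two estimates. Leads missing from the alternate stats are flagged
    rather than fatal.
    """
    a = primary.indexed()
    b = alternate.indexed()
    rows = []
    for vid in lead_variants:
        if vid not in a.index:
            raise KeyError(f"lead {vid} absent from primary stats")
        if vid not in b.index:
            rows.append(
                {
                    "variant_id": vid,
                    "missing_in_alternate": True,
                    "sign_concordant": None,
                    "ratio": np.nan,
                    "het_z": np.nan,
                }
            )
            continue
        b1, s1 = float(a.loc[vid, "beta"]), float(a.loc[vid, "se"])
        b2, s2 = float(b.loc[vid, "beta"]), float(b.loc[vid, "se"])
        het_z = (b2 - b1) / np.sqrt(s1**2 + s2**2)
        rows.append(
            {
                "variant_id": vid,
                "missing_in_alternate": False,
                "sign_concordant": bool(np.sign(b1) == np.sign(b2)),
                "ratio": b2 / b1 if b1 != 0 else np.inf,
                "het_z": float(het_z),
            }
        )
    return pd.DataFrame(rows)
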