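"""LD clumping of pleiotropic variants and tiered sex-biased prioritization.

Pleiotropic variants (conjFDR < 0.05) are collapsed into independent signals
by greedy LD clumping (r^2 < 0.01 between leads). Each signal is then run
through a three-tier cascade:

* Tier 3 — every pleiotropic signal;
* Tier 2 — the signal additionally shows a sex-biased outcome effect: some
  member variant passes the sex-heterogeneity test (P < 0.05) or shows a
  >1.5-fold effect-size difference between women and men;
* Tier 1 — the signal additionally colocalizes across the trait pair
  (posterior probability of a shared causal variant PP4 >= 0.7).

The heterogeneity statistic is Z = (beta_men - beta_women) /
sqrt(se_men^2 + se_women^2) with a two-sided normal p-value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .simulate import BlockLD
from .sumstats_io import LDMatrix

log = logging.getLogger(__name__)

_FOLD_EPS = 1e-8


@dataclass
class TierConfig:
    """Thresholds of the prioritization cascade."""

    clump_r2: float = 0.01
    het_p: float = 0.05
    fold_threshold: float = 1.5
    pp4_threshold: float = 0.7
    novelty_window: int = 1_000_000
    conjfdr_threshold: float = 0.05
    merge_distance: int = 250_000


@dataclass
class Clump:
    """One independent pleiotropic signal."""

    lead: str
    members: list[str]
    chrom: str
    pos: int


def _pairwise_r2(ids, idx_map, ld) -> callable:
    if isinstance(ld, LDMatrix):
        r2 = ld.r2()
        pos = ld.index
        missing = [v for v in ids if v not in pos]
        if missing:
            raise KeyError(f"variants absent from LD matrix: {missing[:5]}")
        return lambda a, b: r2[pos[a], pos[b]]
    if isinstance(ld, BlockLD):
        missing = [v for v in ids if v not in idx_map]
        if missing:
            raise KeyError(f"variants absent from LD index: {missing[:5]}")
        return lambda a, b: ld.r2(idx_map[a], idx_map[b])
    raise TypeError(f"unsupported LD type {type(ld)!r}")


def ld_clump(
    variants: pd.DataFrame,
    ld,
    r2_threshold: float = 0.01,
    id_to_index: dict | None = None,
    merge_distance: int = 250_000,
) -> list[Clump]:
    """Greedy LD clumping of scored variants into independent signals.

    ``variants`` needs columns variant_id, chrom, pos, conjfdr and
    p_primary. The unassigned variant with the smallest conjFDR (ties broken
    by p_primary, then ID) repeatedly becomes a lead; unassigned variants
    with r^2 >= ``r2_threshold`` to the lead join its clump. Clumps whose
    leads are within ``merge_distance`` bp on the same chromosome and in LD
    (r^2 >= threshold) are merged afterwards.
    """
    required = {"variant_id", "chrom", "pos", "conjfdr", "p_primary"}
    if not required <= set(variants.columns):
        raise ValueError(f"variants table needs columns {sorted(required)}")
    df = variants.sort_values(
        ["conjfdr", "p_primary", "variant_id"], kind="mergesort"
    ).reset_index(drop=True)
    ids = df["variant_id"].tolist()
    r2 = _pairwise_r2(ids, id_to_index or {}, ld)
    info = df.set_index("variant_id")[["chrom", "pos"]]

    assigned: set[str] = set()
    clumps: list[Clump] = []
    for lead in ids:
        if lead in assigned:
            continue
        members = [lead]
        assigned.add(lead)
        for other in ids:
            if other in assigned:
                continue
            if r2(lead, other) >= r2_threshold:
                members.append(other)
                assigned.add(other)
        clumps.append(
            Clump(
                lead=lead,
                members=members,
                chrom=str(info.loc[lead, "chrom"]),
                pos=int(info.loc[lead, "pos"]),
            )
        )

    # merge near-identical signals: leads close by and in LD
    merged: list[Clump] = []
    for c in sorted(clumps, key=lambda c: (c.chrom, c.pos)):
        target = None
        for m in merged:
            if (
                m.chrom == c.chrom
                and abs(m.pos - c.pos) <= merge_distance
                and r2(m.lead, c.lead) >= r2_threshold
            ):
                target = m
                break
        if target is None:
            merged.append(c)
        else:
            target.members.extend(c.members)
    return merged


def sex_heterogeneity_test(beta_women, se_women, beta_men, se_men):
    """Sex-difference Z test of per-variant effects.

    Z = (beta_men - beta_women) / sqrt(se_men^2 + se_women^2), with a
    two-sided normal p-value. Vectorized.
    """
    se_w = np.asarray(se_women, dtype=float)
    se_m = np.asarray(se_men, dtype=float)
    if np.any(se_w <= 0) or np.any(se_m <= 0):
        raise ValueError("standard errors must be positive")
    z = (np.asarray(beta_men, dtype=float) - np.asarray(beta_women, dtype=float)) / np.sqrt(
        se_m**2 + se_w**2
    )
    p = 2.0 * sps.norm.sf(np.abs(z))
    return z, p


def fold_difference_flag(beta_women, beta_men, fold_threshold: float = 1.5):
    """Fold-difference sex-bias rule.

    fold_ratio = max(|bw|,|bm|) / max(min(|bw|,|bm|), eps); the flag is set
    when the ratio exceeds ``fold_threshold`` or the betas have opposite
    signs (both nonzero) — the ratio rule is undefined under sign flips, so
    any true sign reversal counts as sex-biased.
    """
    bw = np.asarray(beta_women, dtype=float)
    bm = np.asarray(beta_men, dtype=float)
    hi = np.maximum(np.abs(bw), np.abs(bm))
    lo = np.maximum(np.minimum(np.abs(bw), np.abs(bm)), _FOLD_EPS)
    ratio = hi / lo
    opposite = (np.sign(bw) * np.sign(bm) < 0) & (np.abs(bw) > 0) & (np.abs(bm) > 0)
    flag = (ratio > fold_threshold) | opposite
    return flag, ratio


def _member_bias(effects: pd.DataFrame, members: list[str], cfg: TierConfig):
    """Per-member sex-bias evaluation; returns a frame indexed by variant."""
    sub = effects.loc[[m for m in members if m in effects.index]]
    if sub.empty:
        return sub.assign(het_z=[], het_p=[], fold_ratio=[], biased=[])
    z, p = sex_heterogeneity_test(
        sub["beta_women"], sub["se_women"], sub["beta_men"], sub["se_men"]
    )
    flag, ratio = fold_difference_flag(sub["beta_women"], sub["beta_men"], cfg.fold_threshold)
    return sub.assign(het_z=z, het_p=p, fold_ratio=ratio, biased=(p < cfg.het_p) | flag)


def assign_tiers(
    clumps: list[Clump],
    effects: pd.DataFrame,
    coloc_results: dict | None = None,
    config: TierConfig | None = None,
) -> pd.DataFrame:
    """Run the Tier-3 -> 2 -> 1 cascade over clumped pleiotropic signals.

    ``effects`` is indexed by variant_id with columns beta_women, se_women,
    beta_men, se_men; ``coloc_results`` maps clump lead IDs to fitted
    colocalization results (``.pp4`` and ``.top_shared_variant_id``).
    Returns one row per signal with tier, heterogeneity statistics at the
    most sex-biased member, sex-bias direction, and whether the best
    colocalizing variant itself passes the sex-bias criterion.
    """
    cfg = config or TierConfig()
    coloc_results = coloc_results or {}
    rows = []
    for clump in clumps:
        bias = _member_bias(effects, clump.members, cfg)
        tier = 3
        het_z = het_p = fold_ratio = np.nan
        direction = "none"
        lead_sex_biased = None
        pp4 = np.nan
        if len(bias) and bias["biased"].any():
            tier = 2
            best = bias[bias["biased"]].sort_values("het_p").iloc[0]
            het_z, het_p, fold_ratio = best["het_z"], best["het_p"], best["fold_ratio"]
            direction = "female" if abs(best["beta_women"]) > abs(best["beta_men"]) else "male"
            res = coloc_results.get(clump.lead)
            if res is None:
                log.warning(
                    "no colocalization result for clump %s; capped at Tier 2",
                    clump.lead,
                )
            else:
                pp4 = float(res.pp4)
                if pp4 >= cfg.pp4_threshold:
                    tier = 1
                top = getattr(res, "top_shared_variant_id", None)
                if top is not None and top in bias.index:
                    lead_sex_biased = bool(bias.loc[top, "biased"])
        elif clump.lead in coloc_results:
            pp4 = float(coloc_results[clump.lead].pp4)
        rows.append(
            {
                "lead_variant_id": clump.lead,
                "chrom": clump.chrom,
                "pos": clump.pos,
                "n_members": len(clump.members),
                "members": ",".join(clump.members),
                "tier": tier,
                "het_z": het_z,
                "het_p": het_p,
                "fold_ratio": fold_ratio,
                "sex_bias_direction": direction,
                "coloc_pp4": pp4,
                "lead_sex_biased": lead_sex_biased,
            }
        )
    return pd.DataFrame(rows)


def annotate_novelty(
    loci: pd.DataFrame,
    known_loci: list[tuple[str, int]],
    window: int = 1_000_000,
) -> pd.DataFrame:
    """Flag loci with no known risk locus within ``window`` bp (strict).

    ``known_loci`` is a list of (chrom, pos) of previously reported
    genome-wide-significant loci; a lead exactly ``window`` bp away is novel.
    """
    known = pd.DataFrame(known_loci, columns=["chrom", "pos"]) if known_loci else None
    flags = []
    for row in loci.itertuples():
        if known is None:
            flags.append(True)
            continue
        same = known[known["chrom"].astype(str) == str(row.chrom)]
        flags.append(bool((np.abs(same["pos"] - row.pos) < window).sum() == 0))
    return loci.assign(novel=flags)
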