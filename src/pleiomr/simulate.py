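"""Seeded generators for synthetic GWAS/QTL summary statistics and promoters.

The generators reproduce the statistical structure the analysis stages assume:

* AR(1) linkage disequilibrium within non-overlapping blocks (``r[i,j] =
  rho^|i-j|``), independence across blocks;
* standardized causal effects drawn from a four-component spike-slab mixture
  (null / trait-A-only / trait-B-only / shared), with shared components using
  a common effect;
* marginal GWAS z-scores ``z = sqrt(n) * R @ gamma + eps`` with noise
  covariance ``R`` per trait and cross-trait noise covariance
  ``overlap_corr * R`` to emulate sample overlap;
* records on the standardized scale: ``se = 1/sqrt(n)``, ``beta = z * se``,
  two-sided normal p-values.

Every generator is a pure function of its configuration and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .sumstats_io import LDMatrix, SummaryStats, COLUMNS

# per-variant causal labels
LABEL_NULL, LABEL_A, LABEL_B, LABEL_SHARED = 0, 1, 2, 3
LABEL_NAMES = {LABEL_NULL: "null", LABEL_A: "A-only", LABEL_B: "B-only", LABEL_SHARED: "shared"}

_P_FLOOR = 1e-300


@dataclass
class SimConfig:
    """Configuration of a paired-GWAS simulation.

    Defaults describe a polygenic pair of traits measured in two large
    biobank-scale GWAS: 100k variants in LD blocks of 100 with AR(1)
    rho=0.6, 0.6% of variants causal (split evenly between trait-specific
    and shared), standardized effect SD 0.02 (per-variant z of ~6 at
    n=100k), and no sample overlap.
    """

    n_variants: int = 100_000
    block_size: int = 100
    ld_rho: float = 0.6
    n_A: int = 100_000
    n_B: int = 100_000
    pi_null: float = 0.994
    pi_A: float = 0.002
    pi_B: float = 0.002
    pi_shared: float = 0.002
    effect_sd: float = 0.02
    sex_bias_loci: list[tuple[int, float]] = field(default_factory=list)
    overlap_corr: float = 0.0
    seed: int = 0

    def __post_init__(self):
        total = self.pi_null + self.pi_A + self.pi_B + self.pi_shared
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"mixture proportions sum to {total}, not 1")
        if not (0 <= self.ld_rho < 1):
            raise ValueError("ld_rho must be in [0, 1)")
        if not (-1 <= self.overlap_corr <= 1):
            raise ValueError("overlap_corr must be in [-1, 1]")


@dataclass
class SimTruth:
    """Ground truth of a simulation run."""

    labels: np.ndarray  # per-variant label in {0..3}
    block: np.ndarray  # per-variant block index
    ld_rho: float
    true_gamma_a: np.ndarray | None = None
    true_gamma_b: np.ndarray | None = None
    sex_bias_blocks: dict[int, float] = field(default_factory=dict)
    causal_indices: dict[str, int] = field(default_factory=dict)

    def causal_mask(self, trait: str) -> np.ndarray:
        """Boolean mask of variants causal for trait 'A' or 'B'."""
        if trait == "A":
            return (self.labels == LABEL_A) | (self.labels == LABEL_SHARED)
        if trait == "B":
            return (self.labels == LABEL_B) | (self.labels == LABEL_SHARED)
        raise ValueError(trait)


class BlockLD:
    """Block-diagonal AR(1) LD: r[i,j] = rho^|i-j| within a block, 0 across.

    A compact stand-in for a full LD matrix at genome-wide scale; exposes the
    neighborhood queries that pruning and clumping need.
    """

    def __init__(self, block: np.ndarray, rho: float):
        self.block = np.asarray(block)
        self.rho = float(rho)
        self.n = len(self.block)

    def r2_window(self, r2_threshold: float) -> int:
        """Max distance d with rho^(2d) > r2_threshold."""
        if self.rho == 0.0:
            return 0
        if r2_threshold <= 0:
            return self.n
        d = math.log(r2_threshold) / (2.0 * math.log(self.rho))
        return max(int(math.floor(d)), 0) if self.rho ** (2 * math.floor(d)) > r2_threshold or True else 0

    def r2(self, i: int, j: int) -> float:
        if self.block[i] != self.block[j]:
            return 0.0
        return self.rho ** (2 * abs(i - j))

    def neighbors(self, i: int, r2_threshold: float) -> np.ndarray:
        """Indices j != i with r2(i,j) >= r2_threshold."""
        if self.rho == 0.0:
            return np.empty(0, dtype=int)
        d = self._dmax_ge(r2_threshold)
        lo, hi = max(0, i - d), min(self.n - 1, i + d)
        idx = np.arange(lo, hi + 1)
        idx = idx[(idx != i) & (self.block[idx] == self.block[i])]
        return idx

    def _dmax_ge(self, r2_threshold: float) -> int:
        # max d with rho^(2d) >= threshold
        if r2_threshold <= 0:
            return self.n
        if self.rho == 0.0:
            return 0
        d = math.log(r2_threshold) / (2.0 * math.log(self.rho))
        return max(int(math.floor(d + 1e-12)), 0)


def simulate_ld_matrix(m: int, rho: float) -> LDMatrix:
    """Exact AR(1) correlation matrix: r[i,j] = rho^|i-j|."""
    if m < 1:
        raise ValueError("m must be >= 1")
    if not (0 <= rho < 1):
        raise ValueError("rho must be in [0, 1)")
    idx = np.arange(m)
    r = rho ** np.abs(idx[:, None] - idx[None, :])
    ids = [f"v{i + 1:06d}" for i in range(m)]
    return LDMatrix(ids, r)


def _variant_frame(z: np.ndarray, n: int, eaf: np.ndarray, pos0: int = 0) -> pd.DataFrame:
    m = len(z)
    se = 1.0 / math.sqrt(n)
    p = np.maximum(2.0 * sps.norm.sf(np.abs(z)), _P_FLOOR)
    return pd.DataFrame(
        {
            "variant_id": [f"v{pos0 + i + 1:06d}" for i in range(m)],
            "chrom": "1",
            "pos": np.arange(pos0 + 1, pos0 + m + 1) * 1000,
            "effect_allele": "A",
            "other_allele": "G",
            "eaf": eaf,
            "beta": z * se,
            "se": se,
            "p": p,
            "n": n,
        }
    )


def _block_structure(n_variants: int, block_size: int) -> tuple[np.ndarray, list[tuple[int, int]]]:
    block = np.arange(n_variants) // block_size
    bounds = []
    for b in range(int(block[-1]) + 1):
        lo = b * block_size
        hi = min(lo + block_size, n_variants)
        bounds.append((lo, hi))
    return block, bounds


def _correlated_noise(rng, chol, n_blocks, bs, overlap_corr):
    """Noise for two traits: per-trait cov R, cross-trait cov overlap_corr*R."""
    a = rng.standard_normal((n_blocks, bs))
    b = rng.standard_normal((n_blocks, bs))
    eps_a = a @ chol.T
    mix = overlap_corr * a + math.sqrt(max(1.0 - overlap_corr**2, 0.0)) * b
    eps_b = mix @ chol.T
    return eps_a, eps_b


def _marginal_z(gamma_blocks: np.ndarray, corr: np.ndarray, n: int) -> np.ndarray:
    # z mean = sqrt(n) * R @ gamma, vectorized over blocks (rows)
    return math.sqrt(n) * gamma_blocks @ corr


def simulate_gwas_pair(config: SimConfig) -> tuple[SummaryStats, SummaryStats, SimTruth]:
    """Simulate marginal summary statistics for two traits sharing causal variants.

    Per LD block with correlation ``R``: standardized joint effects are drawn
    from the spike-slab mixture; shared variants use a common effect for both
    traits. Sex-bias blocks multiply trait A's effects by the configured fold
    factor. Marginal z-scores follow ``z_t = sqrt(n_t) R gamma_t + eps`` with
    noise covariance ``R`` per trait, ``overlap_corr * R`` across traits.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    m = cfg.n_variants
    block, bounds = _block_structure(m, cfg.block_size)

    labels = rng.choice(
        4, size=m, p=[cfg.pi_null, cfg.pi_A, cfg.pi_B, cfg.pi_shared]
    )
    gamma_a = np.zeros(m)
    gamma_b = np.zeros(m)
    shared = labels == LABEL_SHARED
    g_shared = rng.normal(0.0, cfg.effect_sd, size=int(shared.sum()))
    gamma_a[shared] = g_shared
    gamma_b[shared] = g_shared
    a_only = labels == LABEL_A
    gamma_a[a_only] = rng.normal(0.0, cfg.effect_sd, size=int(a_only.sum()))
    b_only = labels == LABEL_B
    gamma_b[b_only] = rng.normal(0.0, cfg.effect_sd, size=int(b_only.sum()))

    bias = {}
    for b_idx, fold in cfg.sex_bias_loci:
        lo, hi = bounds[b_idx]
        gamma_a[lo:hi] *= fold
        bias[b_idx] = fold

    bs = cfg.block_size
    n_full = m // bs
    corr = simulate_ld_matrix(bs, cfg.ld_rho).r if bs > 1 else np.ones((1, 1))
    chol = np.linalg.cholesky(corr)

    ga = gamma_a[: n_full * bs].reshape(n_full, bs)
    gb = gamma_b[: n_full * bs].reshape(n_full, bs)
    za = _marginal_z(ga, corr, cfg.n_A)
    zb = _marginal_z(gb, corr, cfg.n_B)
    ea, eb = _correlated_noise(rng, chol, n_full, bs, cfg.overlap_corr)
    z_a = (za + ea).ravel()
    z_b = (zb + eb).ravel()

    rem = m - n_full * bs
    if rem:
        # truncated trailing block
        corr_r = simulate_ld_matrix(rem, cfg.ld_rho).r if rem > 1 else np.ones((1, 1))
        chol_r = np.linalg.cholesky(corr_r)
        ga_r = gamma_a[n_full * bs:][None, :]
        gb_r = gamma_b[n_full * bs:][None, :]
        ea_r, eb_r = _correlated_noise(rng, chol_r, 1, rem, cfg.overlap_corr)
        z_a = np.concatenate([z_a, (_marginal_z(ga_r, corr_r, cfg.n_A) + ea_r).ravel()])
        z_b = np.concatenate([z_b, (_marginal_z(gb_r, corr_r, cfg.n_B) + eb_r).ravel()])

    eaf = rng.uniform(0.05, 0.95, size=m)
    df_a = _variant_frame(z_a, cfg.n_A, eaf)
    df_b = _variant_frame(z_b, cfg.n_B, eaf)
    truth = SimTruth(
        labels=labels,
        block=block,
        ld_rho=cfg.ld_rho,
        true_gamma_a=gamma_a,
        true_gamma_b=gamma_b,
        sex_bias_blocks=bias,
    )
    return (
        SummaryStats(df_a, trait_label="traitA", sex_stratum="combined"),
        SummaryStats(df_b, trait_label="traitB", sex_stratum="combined"),
        truth,
    )


def simulate_sex_pair(
    config: SimConfig, tau: float
) -> tuple[SummaryStats, SummaryStats, SimTruth]:
    """Simulate female and male summary statistics for one trait.

    Causal variants (probability ``1 - pi_null``) carry a shared base effect
    plus independent per-sex Gaussian deviations with SD ``tau``. Blocks
    listed in ``sex_bias_loci`` instead receive an exact female:male effect
    ratio equal to the fold factor (no deviations), planting clean sex-biased
    loci.
    """
    if tau < 0:
        raise ValueError("tau must be >= 0")
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    m = cfg.n_variants
    block, bounds = _block_structure(m, cfg.block_size)

    causal = rng.random(m) < (1.0 - cfg.pi_null)
    base = np.zeros(m)
    base[causal] = rng.normal(0.0, cfg.effect_sd, size=int(causal.sum()))
    dev_f = np.zeros(m)
    dev_m = np.zeros(m)
    dev_f[causal] = rng.normal(0.0, tau, size=int(causal.sum()))
    dev_m[causal] = rng.normal(0.0, tau, size=int(causal.sum()))

    gamma_f = base + dev_f
    gamma_m = base + dev_m
    bias = {}
    for b_idx, fold in cfg.sex_bias_loci:
        lo, hi = bounds[b_idx]
        gamma_f[lo:hi] = fold * base[lo:hi]
        gamma_m[lo:hi] = base[lo:hi]
        bias[b_idx] = fold

    bs = cfg.block_size
    n_full = m // bs
    corr = simulate_ld_matrix(bs, cfg.ld_rho).r if bs > 1 else np.ones((1, 1))
    chol = np.linalg.cholesky(corr)

    def _z(gamma, n):
        g = gamma[: n_full * bs].reshape(n_full, bs)
        noise = rng.standard_normal((n_full, bs)) @ chol.T
        z = (_marginal_z(g, corr, n) + noise).ravel()
        rem = m - n_full * bs
        if rem:
            corr_r = simulate_ld_matrix(rem, cfg.ld_rho).r if rem > 1 else np.ones((1, 1))
            chol_r = np.linalg.cholesky(corr_r)
            g_r = gamma[n_full * bs:][None, :]
            noise_r = rng.standard_normal((1, rem)) @ chol_r.T
            z = np.concatenate([z, (_marginal_z(g_r, corr_r, n) + noise_r).ravel()])
        return z

    z_f = _z(gamma_f, cfg.n_A)
    z_m = _z(gamma_m, cfg.n_B)
    eaf = rng.uniform(0.05, 0.95, size=m)

    labels = np.where(causal, LABEL_SHARED, LABEL_NULL)
    truth = SimTruth(
        labels=labels,
        block=block,
        ld_rho=cfg.ld_rho,
        true_gamma_a=gamma_f,
        true_gamma_b=gamma_m,
        sex_bias_blocks=bias,
    )
    return (
        SummaryStats(_variant_frame(z_f, cfg.n_A, eaf), trait_label="trait", sex_stratum="female"),
        SummaryStats(_variant_frame(z_m, cfg.n_B, eaf), trait_label="trait", sex_stratum="male"),
        truth,
    )


def simulate_qtl_region(
    m: int,
    rho: float,
    n_gwas: int,
    n_qtl: int,
    mode: str,
    causal_var_explained: float,
    seed: int,
    r2_cap: float = 0.3,
) -> tuple[SummaryStats, SummaryStats, LDMatrix, SimTruth]:
    """Simulate one region of GWAS + QTL summary statistics.

    ``mode`` plants the causal configuration: ``shared`` (one causal variant
    for both), ``distinct`` (two causal variants with r2 below ``r2_cap``),
    ``gwas_only``, or ``null``. The causal variant explains
    ``causal_var_explained`` of trait variance, so its expected marginal
    chi-square is ``1 + n * causal_var_explained``.
    """
    if mode not in {"shared", "distinct", "gwas_only", "null"}:
        raise ValueError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(seed)
    ld = simulate_ld_matrix(m, rho)
    corr = ld.r
    chol = np.linalg.cholesky(corr)
    gamma_scale = math.sqrt(causal_var_explained)

    j_gwas = j_qtl = None
    if mode != "null":
        j_gwas = int(rng.integers(m))
    if mode == "shared":
        j_qtl = j_gwas
    elif mode == "distinct":
        r2_to_j = corr[j_gwas] ** 2
        feasible = np.flatnonzero(r2_to_j < r2_cap)
        if len(feasible) == 0:
            raise ValueError(
                f"no variant pair with r2 < {r2_cap} in a {m}-variant rho={rho} region"
            )
        j_qtl = int(rng.choice(feasible))

    def _region_z(j, n):
        mean = np.zeros(m)
        if j is not None:
            mean = math.sqrt(n) * gamma_scale * corr[:, j]
        return mean + chol @ rng.standard_normal(m)

    z_gwas = _region_z(j_gwas, n_gwas)
    z_qtl = _region_z(j_qtl if mode != "gwas_only" else None, n_qtl)
    eaf = rng.uniform(0.05, 0.95, size=m)

    truth = SimTruth(
        labels=np.zeros(m, dtype=int),
        block=np.zeros(m, dtype=int),
        ld_rho=rho,
        causal_indices={
            k: v for k, v in {"gwas": j_gwas, "qtl": j_qtl if mode != "gwas_only" else None}.items()
            if v is not None
        },
    )
    gwas = SummaryStats(_variant_frame(z_gwas, n_gwas, eaf), trait_label="gwas")
    qtl = SummaryStats(_variant_frame(z_qtl, n_qtl, eaf), trait_label="qtl")
    return gwas, qtl, ld, truth


def simulate_promoters(
    n_genes: int,
    length: int,
    pwm,
    plant_rate_target: float,
    plant_rate_background: float,
    seed: int,
    n_background: int | None = None,
) -> tuple[dict[str, str], dict[str, str], dict]:
    """Simulate promoter sequence sets with planted motif occurrences.

    Sequences are i.i.d. uniform over ACGT; a planted sequence receives one
    copy of the PWM consensus at a uniform random position. Returns target
    set, background set, and a truth dict of planted positions (None when
    unplanted).
    """
    if not (0 <= plant_rate_target <= 1 and 0 <= plant_rate_background <= 1):
        raise ValueError("plant rates must be in [0, 1]")
    motif_len = pwm.length
    if length < motif_len:
        raise ValueError(f"promoter length {length} < motif length {motif_len}")
    rng = np.random.default_rng(seed)
    consensus = pwm.consensus
    n_background = n_genes if n_background is None else n_background

    def _make(n, rate, prefix):
        seqs, planted = {}, {}
        bases = np.array(list("ACGT"))
        for i in range(n):
            seq = bases[rng.integers(0, 4, size=length)]
            pos = None
            if rng.random() < rate:
                pos = int(rng.integers(0, length - motif_len + 1))
                seq[pos: pos + motif_len] = list(consensus)
            name = f"{prefix}{i + 1:04d}"
            seqs[name] = "".join(seq)
            planted[name] = pos
        return seqs, planted

    targets, planted_t = _make(n_genes, plant_rate_target, "tgt")
    background, planted_b = _make(n_background, plant_rate_background, "bkg")
    truth = {"target_planted": planted_t, "background_planted": planted_b}
    return targets, background, truth


def simulate_mr_instruments(
    k: int = 50,
    true_effect: float = 0.2,
    n_exposure: int = 100_000,
    n_outcome: int = 200_000,
    gamma_mean: float = 0.1,
    gamma_sd: float = 0.02,
    pleiotropy_offset: float = 0.0,
    invalid_fraction: float = 0.0,
    invalid_offset: float = 0.0,
    seed: int = 0,
):
    """Simulate a harmonized instrument set for two-sample MR.

    True instrument-exposure effects are N(gamma_mean, gamma_sd^2); outcome
    effects are ``true_effect * gamma`` plus ``pleiotropy_offset`` on every
    instrument (directional pleiotropy affecting all instruments) and
    ``invalid_offset`` on a leading ``invalid_fraction`` of instruments
    (a cluster of invalid instruments). Estimates carry sampling noise with
    ``se = 1/sqrt(n)`` per study. Returns a ready
    :class:`~pleiomr.mr.HarmonizedPair`.
    """
    from .mr import HarmonizedPair
    import pandas as pd

    rng = np.random.default_rng(seed)
    se_x = 1.0 / math.sqrt(n_exposure)
    se_y = 1.0 / math.sqrt(n_outcome)
    gamma = rng.normal(gamma_mean, gamma_sd, size=k)
    alpha = np.full(k, pleiotropy_offset)
    n_invalid = int(round(invalid_fraction * k))
    alpha[:n_invalid] += invalid_offset
    bx = gamma + rng.normal(0.0, se_x, size=k)
    by = true_effect * gamma + alpha + rng.normal(0.0, se_y, size=k)
    table = pd.DataFrame(
        {
            "variant_id": [f"iv{i + 1:03d}" for i in range(k)],
            "beta_exposure": bx,
            "se_exposure": se_x,
            "beta_outcome": by,
            "se_outcome": se_y,
        }
    )
    return HarmonizedPair(
        table,
        exposure_label="exposure",
        outcome_label="outcome",
        n_exposure=n_exposure,
        n_outcome=n_outcome,
    )


def true_pleiotropy_tags(truth: SimTruth, r2_threshold: float = 0.01) -> np.ndarray:
    """Variants that genuinely tag causal signal in both traits.

    A variant counts as a true pleiotropic tag if some trait-A causal variant
    and some trait-B causal variant (possibly the same shared variant) lie in
    its block within LD r2 >= ``r2_threshold``. The default threshold is the
    clumping cutoff below which two variants are considered independent
    signals, so "true" means the variant shares a signal with causals of
    both traits. Used to score conjunctional FDR discoveries against
    simulation truth.
    """
    m = len(truth.labels)
    ld = BlockLD(truth.block, truth.ld_rho)
    d = ld._dmax_ge(r2_threshold)

    def _tagged(causal_mask):
        out = np.zeros(m, dtype=bool)
        for i in np.flatnonzero(causal_mask):
            lo, hi = max(0, i - d), min(m, i + d + 1)
            sel = np.arange(lo, hi)
            out[sel[truth.block[sel] == truth.block[i]]] = True
        return out

    return _tagged(truth.causal_mask("A")) & _tagged(truth.causal_mask("B"))


@dataclass
class PlantedLocus:
    """One planted locus in a study-level simulation."""

    kind: str  # shared_sexbiased | shared | sexbiased | null
    block: int
    causal_index: int
    fold: float = 1.0


def simulate_study(
    seed: int,
    n_background_blocks: int = 400,
    block_size: int = 50,
    rho: float = 0.6,
    n_gwas: int = 50_000,
    planted: Sequence[str] = (
        "shared_sexbiased",
        "shared_sexbiased",
        "shared",
        "sexbiased",
        "null",
    ),
    z_ad_male: float = 7.0,
    z_hormone: float = 9.0,
    fold: float = 2.0,
    n_trait_specific: int = 3,
    z_specific: float = 7.0,
) -> dict:
    """Simulate a complete sex-stratified cross-trait study.

    Generates female AD, male AD, and female hormone summary statistics over
    a blocked genome with explicitly planted loci:

    * ``shared_sexbiased`` — causal for AD and hormone; female AD effect is
      ``fold`` times the male effect (colocalizing, sex-biased);
    * ``shared`` — causal for both traits, equal effects in both sexes;
    * ``sexbiased`` — causal for AD only, with the fold ratio;
    * ``null`` — no effect anywhere.

    A few additional AD-only and hormone-only background loci are planted so
    the conditional-FDR strata are populated realistically. Planted causal
    variants sit at block centers. Effect sizes are specified as target
    z-scores at the causal variant (``gamma = z / sqrt(n)``).
    """
    rng = np.random.default_rng(seed)
    n_planted = len(planted) + 2 * n_trait_specific
    n_blocks = n_background_blocks + n_planted
    m = n_blocks * block_size
    block, bounds = _block_structure(m, block_size)

    # planted blocks occupy the tail, spaced out deterministically
    planted_blocks = list(range(n_background_blocks, n_blocks))
    loci: list[PlantedLocus] = []
    gamma_ad_f = np.zeros(m)
    gamma_ad_m = np.zeros(m)
    gamma_horm = np.zeros(m)
    g_m = z_ad_male / math.sqrt(n_gwas)
    g_h = z_hormone / math.sqrt(n_gwas)
    g_s = z_specific / math.sqrt(n_gwas)

    for kind, b in zip(planted, planted_blocks):
        lo, hi = bounds[b]
        c = (lo + hi) // 2
        this_fold = fold if "sexbiased" in kind else 1.0
        loci.append(PlantedLocus(kind=kind, block=b, causal_index=c, fold=this_fold))
        if kind == "null":
            continue
        if kind in ("shared_sexbiased", "shared"):
            gamma_horm[c] = g_h
        if kind == "sexbiased":
            gamma_ad_m[c] = g_m
            gamma_ad_f[c] = fold * g_m
        elif kind == "shared_sexbiased":
            gamma_ad_m[c] = g_m
            gamma_ad_f[c] = fold * g_m
        elif kind == "shared":
            gamma_ad_m[c] = g_m
            gamma_ad_f[c] = g_m

    # trait-specific background loci (AD-only then hormone-only)
    offset = n_background_blocks + len(planted)
    for k in range(n_trait_specific):
        b = planted_blocks[len(planted) + k]
        c = (bounds[b][0] + bounds[b][1]) // 2
        gamma_ad_m[c] = g_s
        gamma_ad_f[c] = g_s
    for k in range(n_trait_specific):
        b = planted_blocks[len(planted) + n_trait_specific + k]
        c = (bounds[b][0] + bounds[b][1]) // 2
        gamma_horm[c] = g_s

    corr = simulate_ld_matrix(block_size, rho).r
    chol = np.linalg.cholesky(corr)

    def _z(gamma, n):
        g = gamma.reshape(n_blocks, block_size)
        noise = rng.standard_normal((n_blocks, block_size)) @ chol.T
        return (_marginal_z(g, corr, n) + noise).ravel()

    z_f = _z(gamma_ad_f, n_gwas)
    z_m = _z(gamma_ad_m, n_gwas)
    z_h = _z(gamma_horm, n_gwas)
    eaf = rng.uniform(0.05, 0.95, size=m)

    ad_f = SummaryStats(_variant_frame(z_f, n_gwas, eaf), trait_label="AD", sex_stratum="female")
    ad_m = SummaryStats(_variant_frame(z_m, n_gwas, eaf), trait_label="AD", sex_stratum="male")
    horm = SummaryStats(_variant_frame(z_h, n_gwas, eaf), trait_label="hormone", sex_stratum="female")

    labels = np.zeros(m, dtype=int)
    labels[(gamma_ad_f != 0) & (gamma_horm != 0)] = LABEL_SHARED
    labels[(gamma_ad_f != 0) & (gamma_horm == 0)] = LABEL_A
    labels[(gamma_ad_f == 0) & (gamma_horm != 0)] = LABEL_B
    truth = SimTruth(
        labels=labels,
        block=block,
        ld_rho=rho,
        true_gamma_a=gamma_ad_f,
        true_gamma_b=gamma_horm,
        sex_bias_blocks={l.block: l.fold for l in loci if l.fold != 1.0},
    )
    return {
        "ad_female": ad_f,
        "ad_male": ad_m,
        "hormone_female": horm,
        "ld": BlockLD(block, rho),
        "block_corr": corr,
        "truth": truth,
        "planted_loci": loci,
        "n_gwas": n_gwas,
    }
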