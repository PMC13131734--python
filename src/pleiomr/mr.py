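"""Two-sample Mendelian randomization with a full sensitivity suite.

Instruments are independent (r^2 < 0.001) genome-wide-significant (P < 5e-8)
variants for the exposure; exposure and outcome estimates are harmonized to
a common effect allele with palindromic variants excluded. The primary
estimator is random-effects inverse-variance-weighted (IVW) regression of
outcome on exposure effects through the origin; sensitivity analyses cover
MR-Egger (slope + directional-pleiotropy intercept), weighted median,
weighted mode, Cochran Q under IVW and Egger, leave-one-out, a
PRESSO-style simulation-based global heterogeneity test, sample-overlap SE
inflation, and multivariable IVW. Per-sex families of exposure-outcome
tests are adjusted by Benjamini-Hochberg FDR.

Random-effects SEs use multiplicative overdispersion: the fixed-effect SE is
scaled by sqrt(max(Q/df, 1)).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .sumstats_io import (
    AlleleMismatchError,
    SummaryStats,
    align_to_reference,
    is_palindromic,
)
from .loci import ld_clump  # noqa: F401  (re-exported for CLI use)

log = logging.getLogger(__name__)

_Z95 = sps.norm.ppf(0.975)


@dataclass
class InstrumentConfig:
    """Instrument-selection thresholds."""

    p_threshold: float = 5e-8
    clump_r2: float = 0.001


@dataclass
class HarmonizedPair:
    """Instrument-level exposure and outcome estimates on a common allele."""

    table: pd.DataFrame  # variant_id, beta_exposure, se_exposure, beta_outcome, se_outcome
    exposure_label: str = ""
    outcome_label: str = ""
    sex_stratum: str = "combined"
    n_exposure: int | None = None
    n_outcome: int | None = None

    def __post_init__(self):
        required = {
            "variant_id",
            "beta_exposure",
            "se_exposure",
            "beta_outcome",
            "se_outcome",
        }
        if not required <= set(self.table.columns):
            raise ValueError(f"harmonized table needs columns {sorted(required)}")
        if len(self.table) == 0:
            raise ValueError("no instruments in harmonized pair")
        if (self.table["se_exposure"] <= 0).any() or (self.table["se_outcome"] <= 0).any():
            raise ValueError("standard errors must be positive")

    @property
    def k(self) -> int:
        return len(self.table)

    def arrays(self):
        t = self.table
        return (
            t["beta_exposure"].to_numpy(float),
            t["se_exposure"].to_numpy(float),
            t["beta_outcome"].to_numpy(float),
            t["se_outcome"].to_numpy(float),
        )

    def wald_ratios(self):
        """Per-instrument ratio estimates with first-order delta SEs."""
        bx, sx, by, sy = self.arrays()
        return by / bx, sy / np.abs(bx)


@dataclass
class MRResult:
    """One causal estimate with its uncertainty and diagnostics."""

    method: str
    beta_causal: float
    se: float
    p: float
    n_instruments: int
    ci_low: float = np.nan
    ci_high: float = np.nan
    q_statistic: float = np.nan
    q_df: int | None = None
    q_p: float = np.nan
    egger_intercept: float = np.nan
    egger_intercept_se: float = np.nan
    egger_intercept_p: float = np.nan
    fdr_p: float = np.nan
    notes: str = ""

    def __post_init__(self):
        if np.isnan(self.ci_low):
            self.ci_low = self.beta_causal - _Z95 * self.se
            self.ci_high = self.beta_causal + _Z95 * self.se

    @property
    def odds_ratio(self) -> float:
        return math.exp(self.beta_causal)

    @property
    def or_ci(self) -> tuple[float, float]:
        return math.exp(self.ci_low), math.exp(self.ci_high)

    def summary(self) -> str:
        lo, hi = self.or_ci
        lines = [
            f"{self.method}: beta = {self.beta_causal:.4f} (SE {self.se:.4f}), "
            f"p = {self.p:.3g}",
            f"  OR = {self.odds_ratio:.3f} (95% CI {lo:.3f}-{hi:.3f}), "
            f"k = {self.n_instruments}",
        ]
        if np.isfinite(self.q_statistic):
            lines.append(
                f"  Cochran Q = {self.q_statistic:.2f} (df {self.q_df}), p = {self.q_p:.3g}"
            )
        if np.isfinite(self.egger_intercept):
            lines.append(
                f"  Egger intercept = {self.egger_intercept:.4f} "
                f"(p = {self.egger_intercept_p:.3g})"
            )
        if self.notes:
            lines.append(f"  note: {self.notes}")
        return "\n".join(lines)


def select_instruments(
    exposure: SummaryStats,
    ld,
    config: InstrumentConfig | None = None,
    id_to_index: dict | None = None,
) -> list[str]:
    """Independent genome-wide-significant instruments for an exposure.

    Filters to P below the threshold, then greedily clumps at
    r^2 < ``clump_r2`` keeping the smallest-p variant of each group.
    """
    cfg = config or InstrumentConfig()
    df = exposure.df[exposure.df["p"] < cfg.p_threshold].copy()
    if len(df) == 0:
        raise ValueError(
            f"no instruments: no variant with p < {cfg.p_threshold} "
            f"for exposure {exposure.trait_label!r}"
        )
    clump_in = df.assign(conjfdr=df["p"], p_primary=df["p"])
    clumps = ld_clump(
        clump_in,
        ld,
        r2_threshold=cfg.clump_r2,
        id_to_index=id_to_index,
        merge_distance=0,
    )
    return [c.lead for c in clumps]


def harmonize_pair(
    exposure: SummaryStats,
    outcome: SummaryStats,
    instruments: list[str],
) -> HarmonizedPair:
    """Align instrument-level outcome estimates to the exposure effect allele.

    Palindromic (A/T, C/G) instruments and instruments absent from the
    outcome are dropped with log entries; losing every instrument is fatal.
    """
    exp = exposure.indexed()
    out = outcome.indexed()
    rows = []
    for vid in instruments:
        if vid not in exp.index:
            raise KeyError(f"instrument {vid} absent from exposure stats")
        e = exp.loc[vid]
        if is_palindromic(e["effect_allele"], e["other_allele"]):
            log.info("dropping palindromic instrument %s", vid)
            continue
        if vid not in out.index:
            log.info("instrument %s absent from outcome; dropped", vid)
            continue
        from .sumstats_io import VariantRecord

        o = out.loc[vid]
        rec = VariantRecord(*[o[c] for c in out.columns])
        try:
            rec = align_to_reference(rec, e["effect_allele"], e["other_allele"])
        except AlleleMismatchError as exc:
            log.warning("instrument %s: %s; dropped", vid, exc)
            continue
        rows.append(
            {
                "variant_id": vid,
                "beta_exposure": float(e["beta"]),
                "se_exposure": float(e["se"]),
                "beta_outcome": float(rec.beta),
                "se_outcome": float(rec.se),
            }
        )
    if not rows:
        raise ValueError("all instruments lost during harmonization")
    return HarmonizedPair(
        pd.DataFrame(rows),
        exposure_label=exposure.trait_label,
        outcome_label=outcome.trait_label,
        sex_stratum=exposure.sex_stratum,
        n_exposure=int(exposure.df["n"].max()),
        n_outcome=int(outcome.df["n"].max()),
    )


def _ivw_core(bx, by, w):
    """Weighted regression through the origin; returns (slope, fixed var, Q)."""
    sw = np.sum(w * bx * bx)
    if sw == 0:
        raise ValueError("no identification: all exposure betas are zero")
    slope = np.sum(w * bx * by) / sw
    var = 1.0 / sw
    q = float(np.sum(w * (by - slope * bx) ** 2))
    return slope, var, q


def mr_ivw(pair: HarmonizedPair) -> MRResult:
    """Random-effects inverse-variance-weighted estimate.

    Weighted regression of outcome on exposure betas through the origin with
    weights 1/se_outcome^2; the SE is inflated by sqrt(max(Q/(k-1), 1)). A
    single instrument reduces to the Wald ratio with its first-order SE.
    """
    bx, sx, by, sy = pair.arrays()
    k = pair.k
    if np.all(bx == 0):
        raise ValueError("no identification: all exposure betas are zero")
    if k == 1:
        beta = float(by[0] / bx[0])
        se = float(sy[0] / abs(bx[0]))
        p = 2.0 * sps.norm.sf(abs(beta / se))
        return MRResult("Wald ratio", beta, se, p, 1, notes="single instrument")
    w = 1.0 / sy**2
    slope, var, q = _ivw_core(bx, by, w)
    scale = math.sqrt(max(q / (k - 1), 1.0))
    se = math.sqrt(var) * scale
    p = 2.0 * sps.norm.sf(abs(slope / se))
    return MRResult(
        "IVW (random effects)",
        float(slope),
        se,
        float(p),
        k,
        q_statistic=q,
        q_df=k - 1,
        q_p=float(sps.chi2.sf(q, k - 1)),
    )


def mr_egger(pair: HarmonizedPair) -> MRResult:
    """MR-Egger regression: slope as causal estimate, intercept as pleiotropy test.

    Instruments are oriented so all exposure betas are non-negative before
    fitting; weights are 1/se_outcome^2 and both SEs carry the
    multiplicative overdispersion scaling with k-2 degrees of freedom.
    """
    if pair.k < 3:
        raise ValueError("MR-Egger needs >= 3 instruments")
    bx, sx, by, sy = pair.arrays()
    flip = np.sign(bx)
    flip[flip == 0] = 1.0
    bx, by = bx * flip, by * flip
    w = 1.0 / sy**2
    X = np.column_stack([np.ones_like(bx), bx])
    WX = X * w[:, None]
    xtwx = X.T @ WX
    try:
        cov = np.linalg.inv(xtwx)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular Egger design (constant exposure betas)") from exc
    coef = cov @ (WX.T @ by)
    resid = by - X @ coef
    q = float(np.sum(w * resid**2))
    k = pair.k
    scale2 = max(q / (k - 2), 1.0)
    se_int, se_slope = np.sqrt(np.diag(cov) * scale2)
    slope, intercept = float(coef[1]), float(coef[0])
    p_slope = 2.0 * sps.norm.sf(abs(slope / se_slope))
    p_int = 2.0 * sps.norm.sf(abs(intercept / se_int))
    return MRResult(
        "MR-Egger",
        slope,
        float(se_slope),
        float(p_slope),
        k,
        q_statistic=q,
        q_df=k - 2,
        q_p=float(sps.chi2.sf(q, k - 2)),
        egger_intercept=intercept,
        egger_intercept_se=float(se_int),
        egger_intercept_p=float(p_int),
    )


def _weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(values)
    v, w = values[order], weights[order]
    cum = np.cumsum(w) - 0.5 * w
    cum /= np.sum(w)
    return float(np.interp(0.5, cum, v))


def mr_weighted_median(
    pair: HarmonizedPair, n_boot: int = 5000, seed: int = 0
) -> MRResult:
    """Weighted median of Wald ratios (inverse-variance weights).

    Consistent when instruments carrying at least half the weight are valid.
    The SE comes from a seeded parametric bootstrap of the ratio estimates.
    """
    if pair.k < 3:
        raise ValueError("weighted median needs >= 3 instruments")
    ratios, se_r = pair.wald_ratios()
    w = 1.0 / se_r**2
    est = _weighted_median(ratios, w)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        draw = rng.normal(ratios, se_r)
        boots[b] = _weighted_median(draw, w)
    se = float(np.std(boots, ddof=1))
    p = 2.0 * sps.norm.sf(abs(est / se)) if se > 0 else (0.0 if est != 0 else 1.0)
    return MRResult("Weighted median", est, se, float(p), pair.k)


def mr_weighted_mode(
    pair: HarmonizedPair,
    bandwidth_factor: float = 1.0,
    n_boot: int = 5000,
    seed: int = 0,
) -> MRResult:
    """Mode of the weighted kernel-smoothed Wald-ratio density.

    Gaussian kernel with a MAD-based default bandwidth scaled by
    ``bandwidth_factor``; consistent when the largest group of instruments
    sharing a ratio is valid (plurality validity). Bootstrap SE, seeded.
    """
    if pair.k < 3:
        raise ValueError("weighted mode needs >= 3 instruments")
    ratios, se_r = pair.wald_ratios()
    w = 1.0 / se_r**2

    def _mode(vals):
        mad = np.median(np.abs(vals - np.median(vals)))
        s = 1.4826 * mad
        if s == 0:
            return float(np.median(vals))
        h = bandwidth_factor * 0.9 * s * len(vals) ** (-0.2)
        grid = np.linspace(vals.min() - 3 * h, vals.max() + 3 * h, 512)
        dens = (w[None, :] * np.exp(-0.5 * ((grid[:, None] - vals[None, :]) / h) ** 2)).sum(
            axis=1
        )
        return float(grid[np.argmax(dens)])

    est = _mode(ratios)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        boots[b] = _mode(rng.normal(ratios, se_r))
    se = float(np.std(boots, ddof=1))
    p = 2.0 * sps.norm.sf(abs(est / se)) if se > 0 else (0.0 if est != 0 else 1.0)
    return MRResult("Weighted mode", est, se, float(p), pair.k)


def cochran_q(pair: HarmonizedPair, model: str = "ivw"):
    """Heterogeneity Q about the fitted model, on first-order ratio weights.

    Q = sum_i w_i (ratio_i - fit_i)^2 with w_i = bx_i^2 / se_y_i^2; df = k-1
    under IVW, k-2 under Egger. With df <= 0 the p-value is omitted (None).
    """
    bx, sx, by, sy = pair.arrays()
    w = 1.0 / sy**2
    k = pair.k
    if model == "ivw":
        slope, _, q = _ivw_core(bx, by, w)
        df = k - 1
    elif model == "egger":
        res = mr_egger(pair)
        q, df = res.q_statistic, res.q_df
    else:
        raise ValueError(f"unknown model {model!r}")
    p = float(sps.chi2.sf(q, df)) if df > 0 else None
    return float(q), df, p


def leave_one_out(pair: HarmonizedPair) -> pd.DataFrame:
    """IVW refits excluding each instrument in turn.

    Flags instruments whose exclusion moves the estimate by more than one
    SE of the refit (an influential instrument inflates the full-model SE
    through the heterogeneity scaling, so the refit SE is the sharper
    yardstick) or flips nominal significance at 0.05.
    """
    if pair.k < 3:
        raise ValueError("leave-one-out needs >= 3 instruments")
    full = mr_ivw(pair)
    rows = []
    for i in range(pair.k):
        sub = HarmonizedPair(
            pair.table.drop(pair.table.index[i]).reset_index(drop=True),
            exposure_label=pair.exposure_label,
            outcome_label=pair.outcome_label,
        )
        res = mr_ivw(sub)
        flagged = (
            abs(res.beta_causal - full.beta_causal) > res.se
            or (res.p < 0.05) != (full.p < 0.05)
        )
        rows.append(
            {
                "excluded": pair.table["variant_id"].iloc[i],
                "beta_causal": res.beta_causal,
                "se": res.se,
                "p": res.p,
                "flagged": flagged,
            }
        )
    return pd.DataFrame(rows)


def presso_global(
    pair: HarmonizedPair, n_sim: int = 1000, seed: int = 0
) -> tuple[float, dict, float]:
    """PRESSO-style global horizontal-pleiotropy test.

    The observed statistic is the standardized residual sum of squares of
    outcome betas about leave-one-out IVW predictions. Its null distribution
    is simulated parametrically: exposure betas are redrawn from
    N(beta_exposure, se_exposure) and outcome betas from
    N(loo-prediction, se_outcome), and the statistic recomputed with fresh
    leave-one-out fits, ``n_sim`` times. Resampling the exposure side as
    well keeps the test calibrated when instrument-exposure estimates carry
    non-negligible sampling error. The global p is the fraction of simulated
    statistics at or above the observed one.
    """
    if pair.k < 4:
        raise ValueError("global test needs >= 4 instruments")
    bx, sx, by, sy = pair.arrays()
    w = 1.0 / sy**2

    def _loo_rss(bx_vec, by_vec):
        swx = np.sum(w * bx_vec * bx_vec)
        swxy = np.sum(w * bx_vec * by_vec)
        # leave-one-out slopes via sum subtraction
        slopes = (swxy - w * bx_vec * by_vec) / (swx - w * bx_vec * bx_vec)
        resid = (by_vec - slopes * bx_vec) / sy
        return float(np.sum(resid**2)), slopes

    obs, slopes = _loo_rss(bx, by)
    rng = np.random.default_rng(seed)
    sims = np.empty(n_sim)
    pred = slopes * bx
    for s in range(n_sim):
        bx_s = rng.normal(bx, sx)
        by_s = rng.normal(pred, sy)
        sims[s] = _loo_rss(bx_s, by_s)[0]
    p = float((np.sum(sims >= obs) + 1) / (n_sim + 1))
    summary = {
        "observed_rss": obs,
        "expected_rss_mean": float(sims.mean()),
        "expected_rss_sd": float(sims.std(ddof=1)),
        "n_sim": n_sim,
    }
    return obs, summary, p


def overlap_adjusted_ivw(
    pair: HarmonizedPair,
    overlap_fraction: float,
    n_exposure: int | None = None,
    n_outcome: int | None = None,
    phenotype_corr: float = 0.2,
) -> MRResult:
    """IVW with SEs inflated for exposure-outcome sample overlap.

    Shared participants induce a correlation between instrument-exposure and
    instrument-outcome errors of approximately ``overlap_fraction *
    min(nE,nO)/sqrt(nE*nO) * phenotype_corr``; the resulting covariance term
    is propagated through the Wald-ratio variance, inflating each
    instrument's outcome variance by ``2 * c * |beta| * se_x * se_y``. The
    point estimate is unchanged; only the SE (and p) grow with overlap.
    """
    if not (0 <= overlap_fraction <= 1):
        raise ValueError("overlap_fraction must be in [0, 1]")
    base = mr_ivw(pair)
    if overlap_fraction == 0:
        base.notes = "overlap adjustment: none (overlap_fraction=0)"
        return base
    n_e = n_exposure or pair.n_exposure
    n_o = n_outcome or pair.n_outcome
    if n_e is None or n_o is None:
        raise ValueError("sample sizes required for overlap adjustment")
    c = overlap_fraction * (min(n_e, n_o) / math.sqrt(n_e * n_o)) * phenotype_corr
    bx, sx, by, sy = pair.arrays()
    var_i = sy**2 + 2.0 * c * abs(base.beta_causal) * sx * sy
    w = 1.0 / var_i
    _, var, q = _ivw_core(bx, by, w)
    k = pair.k
    scale = math.sqrt(max(q / (k - 1), 1.0)) if k > 1 else 1.0
    se = math.sqrt(var) * scale
    p = 2.0 * sps.norm.sf(abs(base.beta_causal / se))
    return MRResult(
        "IVW (overlap-adjusted)",
        base.beta_causal,
        se,
        float(p),
        k,
        q_statistic=q,
        q_df=k - 1,
        q_p=float(sps.chi2.sf(q, k - 1)),
        notes=(
            f"overlap_fraction={overlap_fraction}, phenotype_corr={phenotype_corr}, "
            f"error corr={c:.4f}"
        ),
    )


def mvmr_ivw(
    outcome_betas: np.ndarray,
    outcome_ses: np.ndarray,
    exposure_betas: np.ndarray,
    exposure_labels: list[str] | None = None,
) -> list[MRResult]:
    """Multivariable IVW: joint conditional effects of several exposures.

    Weighted multivariable regression (no intercept) of outcome betas on the
    (k x p) exposure-beta matrix with weights 1/se_outcome^2; random-effects
    SE scaling with k-p degrees of freedom. A rank-deficient exposure matrix
    is an error naming the collinear exposures.
    """
    by = np.asarray(outcome_betas, float)
    sy = np.asarray(outcome_ses, float)
    BX = np.atleast_2d(np.asarray(exposure_betas, float))
    if BX.shape[0] != len(by):
        BX = BX.T
    k, p = BX.shape
    labels = exposure_labels or [f"exposure{j + 1}" for j in range(p)]
    if k < p + 1:
        raise ValueError(f"need >= {p + 1} instruments for {p} exposures, have {k}")
    # an exposure with no instrument effects carries no information: drop it
    # (reported as NaN) rather than failing the rank check
    zero = np.all(BX == 0, axis=0)
    active = np.flatnonzero(~zero)
    if len(active) == 0:
        raise ValueError("no identification: all exposure betas are zero")
    BXa = BX[:, active]
    active_labels = [labels[j] for j in active]
    if np.linalg.matrix_rank(BXa) < len(active):
        raise ValueError(
            f"rank-deficient exposure matrix; collinear exposures {active_labels}"
        )
    if zero.any():
        log.warning(
            "exposures with all-zero instrument effects dropped: %s",
            [labels[j] for j in np.flatnonzero(zero)],
        )
    pa = len(active)
    w = 1.0 / sy**2
    WX = BXa * w[:, None]
    xtwx = BXa.T @ WX
    cov = np.linalg.inv(xtwx)
    coef = cov @ (WX.T @ by)
    resid = by - BXa @ coef
    q = float(np.sum(w * resid**2))
    scale2 = max(q / (k - pa), 1.0)
    ses = np.sqrt(np.diag(cov) * scale2)
    out = []
    for j in range(p):
        if zero[j]:
            out.append(
                MRResult(
                    f"MVMR-IVW ({labels[j]})",
                    float("nan"),
                    float("nan"),
                    float("nan"),
                    k,
                    notes="no instrument effects for this exposure",
                )
            )
            continue
        ja = int(np.flatnonzero(active == j)[0])
        pv = 2.0 * sps.norm.sf(abs(coef[ja] / ses[ja]))
        out.append(
            MRResult(
                f"MVMR-IVW ({labels[j]})",
                float(coef[ja]),
                float(ses[ja]),
                float(pv),
                k,
                q_statistic=q,
                q_df=k - pa,
                q_p=float(sps.chi2.sf(q, k - pa)),
            )
        )
    return out


def bh_fdr(p_values, family_label: str = "") -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values for one testing family.

    Families are per sex: all exposure traits tested against the outcome
    within one sex stratum form one family.
    """
    p = np.asarray(p_values, dtype=float)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must be in (0, 1]")
    if len(p) == 0:
        return p
    adj = multipletests(p, method="fdr_bh")[1]
    if family_label:
        log.info("BH family %s: %d tests", family_label, len(p))
    return adj


class MRModel:
    """Two-sample MR model over a harmonized instrument set.

    statsmodels-style entry point: construct from a :class:`HarmonizedPair`
    (or via :meth:`from_sumstats`) and call :meth:`fit` for the IVW estimate
    or :meth:`fit_all` for the whole estimator/sensitivity battery.
    """

    def __init__(self, pair: HarmonizedPair):
        self.pair = pair

    @classmethod
    def from_sumstats(
        cls,
        exposure: SummaryStats,
        outcome: SummaryStats,
        ld,
        config: InstrumentConfig | None = None,
        id_to_index: dict | None = None,
    ) -> "MRModel":
        instruments = select_instruments(exposure, ld, config, id_to_index)
        return cls(harmonize_pair(exposure, outcome, instruments))

    def fit(self, method: str = "ivw", **kwargs) -> MRResult:
        fits = {
            "ivw": mr_ivw,
            "egger": mr_egger,
            "weighted_median": mr_weighted_median,
            "weighted_mode": mr_weighted_mode,
        }
        if method not in fits:
            raise ValueError(f"unknown method {method!r}")
        return fits[method](self.pair, **kwargs)

    def fit_all(self, seed: int = 0, n_boot: int = 5000) -> "MRBattery":
        pair = self.pair
        results = [mr_ivw(pair)]
        extras: dict = {}
        if pair.k >= 3:
            results.append(mr_egger(pair))
            results.append(mr_weighted_median(pair, n_boot=n_boot, seed=seed))
            results.append(mr_weighted_mode(pair, n_boot=n_boot, seed=seed + 1))
            extras["leave_one_out"] = leave_one_out(pair)
        if pair.k >= 4:
            obs, summary, p = presso_global(pair, seed=seed + 2)
            extras["presso"] = {"observed_rss": obs, **summary, "global_p": p}
        return MRBattery(pair, results, extras)


@dataclass
class MRBattery:
    """Primary estimate plus the sensitivity suite for one exposure-outcome pair."""

    pair: HarmonizedPair
    results: list[MRResult]
    extras: dict = field(default_factory=dict)

    def table(self) -> pd.DataFrame:
        rows = []
        for r in self.results:
            lo, hi = r.or_ci
            rows.append(
                {
                    "exposure": self.pair.exposure_label,
                    "outcome": self.pair.outcome_label,
                    "sex": self.pair.sex_stratum,
                    "method": r.method,
                    "beta": r.beta_causal,
                    "se": r.se,
                    "p": r.p,
                    "or": r.odds_ratio,
                    "or_ci_low": lo,
                    "or_ci_high": hi,
                    "k": r.n_instruments,
                    "q": r.q_statistic,
                    "q_p": r.q_p,
                    "egger_intercept": r.egger_intercept,
                    "egger_intercept_p": r.egger_intercept_p,
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        parts = [r.summary() for r in self.results]
        if "presso" in self.extras:
            parts.append(f"Global pleiotropy test p = {self.extras['presso']['global_p']:.3g}")
        return "\n".join(parts)
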