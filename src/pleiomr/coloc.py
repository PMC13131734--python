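"""Bayesian colocalization under the single-causal-variant assumption.

For a region with summary statistics for two traits, five hypotheses are
weighed: H0 no association, H1/H2 association with one trait only, H3 both
traits with distinct causal variants, H4 a shared causal variant. Evidence
per variant is the Wakefield approximate Bayes factor computed from (beta,
se) under a N(0, W) effect prior:

    log ABF = 0.5 * [log(1 - r) + r * z^2],   r = W / (se^2 + W),  z = beta/se

Hypothesis posteriors combine per-variant ABFs with configuration priors
(p1, p2 per-trait causality, p12 shared causality); all accumulation is done
with log-sum-exp so regions with |z| > 40 do not overflow. PP4 >= 0.7 is the
conventional "strong colocalization" call used for both the cross-trait
Tier-1 gate and QTL-based gene prioritization.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .sumstats_io import SummaryStats

log = logging.getLogger(__name__)

STRONG_PP4 = 0.70


@dataclass
class ColocPriors:
    """Per-variant configuration priors and effect-prior variances.

    ``p1``/``p2`` are the prior probabilities that a variant is causal for
    trait 1/2 only, ``p12`` that it is causal for both. ``w1``/``w2`` are the
    prior variances of true effects for the ABF: 0.15^2 suits log-OR effects
    of case-control traits, 0.2^2 SD-unit effects of quantitative traits.
    """

    p1: float = 1e-4
    p2: float = 1e-4
    p12: float = 1e-5
    w1: float = 0.15**2
    w2: float = 0.15**2

    def __post_init__(self):
        if not (0 < self.p12 <= min(self.p1, self.p2)):
            raise ValueError("require 0 < p12 <= min(p1, p2)")
        if self.p1 + self.p2 + self.p12 >= 1:
            raise ValueError("configuration priors too large")
        if self.w1 <= 0 or self.w2 <= 0:
            raise ValueError("prior variances must be positive")


def log_abf(beta, se, w):
    """Wakefield log approximate Bayes factor for one association estimate."""
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise ValueError("se must be positive")
    if w <= 0:
        raise ValueError("prior variance must be positive")
    r = w / (se**2 + w)
    z = beta / se
    return 0.5 * (np.log1p(-r) + r * z**2)


@dataclass
class ColocResults:
    """Posterior hypothesis probabilities for one region/trait pair."""

    pp: np.ndarray  # [pp0..pp4]
    variant_ids: list[str]
    h4_contrib: np.ndarray  # per-variant posterior weight within H4
    trait1_label: str = ""
    trait2_label: str = ""

    @property
    def pp0(self) -> float:
        return float(self.pp[0])

    @property
    def pp1(self) -> float:
        return float(self.pp[1])

    @property
    def pp2(self) -> float:
        return float(self.pp[2])

    @property
    def pp3(self) -> float:
        return float(self.pp[3])

    @property
    def pp4(self) -> float:
        return float(self.pp[4])

    @property
    def n_variants(self) -> int:
        return len(self.variant_ids)

    @property
    def top_shared_variant_id(self) -> str:
        return self.variant_ids[int(np.argmax(self.h4_contrib))]

    @property
    def strong(self) -> bool:
        return self.pp4 >= STRONG_PP4

    def summary(self) -> str:
        names = ["PP0", "PP1", "PP2", "PP3", "PP4"]
        lines = [
            f"Colocalization: {self.trait1_label} vs {self.trait2_label} "
            f"({self.n_variants} variants)"
        ]
        lines += [f"  {n} = {v:.4f}" for n, v in zip(names, self.pp)]
        lines.append(f"  top shared variant: {self.top_shared_variant_id}")
        return "\n".join(lines)


class ColocModel:
    """Single-causal-variant colocalization model for one region.

    Built from two aligned region slices; :meth:`fit` evaluates the hypothesis
    posteriors. Regions are intersected on variant_id; variants missing from
    either side are dropped, not imputed.
    """

    def __init__(
        self,
        region1: SummaryStats | pd.DataFrame,
        region2: SummaryStats | pd.DataFrame,
        priors: ColocPriors | None = None,
    ):
        self.priors = priors or ColocPriors()
        df1 = region1.df if isinstance(region1, SummaryStats) else region1
        df2 = region2.df if isinstance(region2, SummaryStats) else region2
        self.trait1_label = getattr(region1, "trait_label", "")
        self.trait2_label = getattr(region2, "trait_label", "")
        merged = df1[["variant_id", "beta", "se"]].merge(
            df2[["variant_id", "beta", "se"]],
            on="variant_id",
            suffixes=("_1", "_2"),
        )
        if len(merged) == 0:
            raise ValueError("empty variant intersection between regions")
        if len(merged) < 10:
            log.warning("only %d shared variants in region", len(merged))
        self._merged = merged

    def fit(self) -> ColocResults:
        pri = self.priors
        m = self._merged
        l1 = log_abf(m["beta_1"].to_numpy(), m["se_1"].to_numpy(), pri.w1)
        l2 = log_abf(m["beta_2"].to_numpy(), m["se_2"].to_numpy(), pri.w2)

        s1 = logsumexp(l1)
        s2 = logsumexp(l2)
        s12 = logsumexp(l1 + l2)

        lh = np.empty(5)
        lh[0] = 0.0
        lh[1] = math.log(pri.p1) + s1
        lh[2] = math.log(pri.p2) + s2
        # H3: sum over ordered distinct pairs = s1+s2 minus the diagonal
        cross = s1 + s2
        diff = 1.0 - math.exp(min(s12 - cross, 0.0))
        lh[3] = (
            math.log(pri.p1) + math.log(pri.p2) + cross + math.log(diff)
            if diff > 0
            else -np.inf
        )
        lh[4] = math.log(pri.p12) + s12

        pp = np.exp(lh - logsumexp(lh))
        pp /= pp.sum()
        h4 = np.exp((l1 + l2) - s12)
        return ColocResults(
            pp=pp,
            variant_ids=m["variant_id"].tolist(),
            h4_contrib=h4,
            trait1_label=self.trait1_label,
            trait2_label=self.trait2_label,
        )


def coloc_posteriors(
    region1, region2, priors: ColocPriors | None = None
) -> ColocResults:
    """Fit colocalization posteriors for one pair of region slices."""
    return ColocModel(region1, region2, priors=priors).fit()


def qtl_coloc_scan(
    trait_region,
    qtl_datasets: list[tuple[str, str, str, object]],
    priors: ColocPriors | None = None,
) -> pd.DataFrame:
    """Colocalize one trait region against a series of QTL datasets.

    ``qtl_datasets`` holds (dataset label, category label, feature id,
    region slice) tuples. Unalignable datasets are skipped with a warning.
    Rows with PP4 >= 0.70 are flagged strong.
    """
    rows = []
    for dataset, category, feature, region in qtl_datasets:
        try:
            res = coloc_posteriors(trait_region, region, priors=priors)
        except ValueError as exc:
            log.warning("skipping %s/%s: %s", dataset, feature, exc)
            continue
        rows.append(
            {
                "dataset": dataset,
                "category": category,
                "feature": feature,
                "n_variants": res.n_variants,
                "pp0": res.pp0,
                "pp1": res.pp1,
                "pp2": res.pp2,
                "pp3": res.pp3,
                "pp4": res.pp4,
                "top_shared_variant_id": res.top_shared_variant_id,
                "strong": res.strong,
            }
        )
    return pd.DataFrame(rows)


def best_pp4_by_category(results: pd.DataFrame, group_cols: list[str] | None = None) -> pd.DataFrame:
    """Collapse a QTL colocalization table to the best PP4 per category.

    Per (feature, category) the maximum PP4 across member datasets is
    reported together with the dataset that achieved it; empty categories
    produce no row.
    """
    if results.empty:
        return results.copy()
    group_cols = group_cols or ["feature", "category"]
    idx = results.groupby(group_cols)["pp4"].idxmax()
    best = results.loc[idx, group_cols + ["pp4", "dataset", "strong"]]
    return best.rename(columns={"pp4": "best_pp4", "dataset": "best_dataset"}).reset_index(
        drop=True
    )
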