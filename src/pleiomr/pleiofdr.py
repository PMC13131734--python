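"""Cross-trait pleiotropy: conditional QQ/fold-enrichment and cond/conjFDR.

The conditional FDR (condFDR) of a variant for a primary trait given a
secondary trait is the estimated posterior probability that the variant is
null for the primary trait given its observed p-values in both traits:

    condFDR(p1 | p2) = p1 / F_hat(p1 | p2 < c)

where ``F_hat`` is the empirical CDF of primary p-values among variants whose
secondary p-value falls below a cutoff ``c``. Cross-trait enrichment makes
``F_hat`` grow faster than ``p`` in the conditioned strata, shrinking the FDR
of variants supported by both traits. The conjunctional FDR (conjFDR) is the
maximum of the two directional condFDRs; variants with conjFDR < 0.05 are
flagged pleiotropic.

Empirical CDFs are estimated on random LD-pruned subsets (one variant kept
per r^2 > 0.1 neighborhood, redrawn each iteration) and averaged across
iterations, so that LD does not over-count correlated variants.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import maximum_filter1d

from .simulate import BlockLD
from .sumstats_io import LDMatrix, SummaryStats

log = logging.getLogger(__name__)

#: pleiotropy call threshold on conjFDR
CONJFDR_THRESHOLD = 0.05

#: regions excluded from FDR grid fitting by default (long-range LD):
#: extended MHC and the APOE region
DEFAULT_EXCLUDED_REGIONS = [
    ("6", 25_000_000, 35_000_000),
    ("19", 45_000_000, 46_000_000),
]


@dataclass
class EnrichmentConfig:
    """Cutoffs and evaluation grid for conditional enrichment curves."""

    secondary_cutoffs: list[float] = field(default_factory=lambda: [0.1, 0.01, 0.001])
    primary_grid: list[float] = field(
        default_factory=lambda: list(np.linspace(0.5, 3.0, 11))
    )  # -log10(p) evaluation points

    def __post_init__(self):
        c = self.secondary_cutoffs
        if any(not (0 < x <= 1) for x in c) or any(
            c[i] <= c[i + 1] for i in range(len(c) - 1)
        ):
            raise ValueError("secondary cutoffs must be strictly descending in (0,1]")


def _merge_pair(primary: SummaryStats, secondary: SummaryStats) -> pd.DataFrame:
    a = primary.df[["variant_id", "chrom", "pos", "p"]].rename(columns={"p": "p_primary"})
    b = secondary.df[["variant_id", "p"]].rename(columns={"p": "p_secondary"})
    return a.merge(b, on="variant_id", how="inner")


def fold_enrichment(
    primary: SummaryStats,
    secondary: SummaryStats,
    config: EnrichmentConfig | None = None,
) -> pd.DataFrame:
    """Conditional fold-enrichment curves of the primary trait.

    For each secondary-trait cutoff ``c`` and each primary threshold ``t``
    (on -log10 p), the enrichment is the fraction of variants in the
    conditioned stratum (p_secondary < c) with p_primary <= 10^-t, divided by
    the same fraction among all shared variants. Values near 1 indicate no
    cross-trait enrichment.
    """
    config = config or EnrichmentConfig()
    df = _merge_pair(primary, secondary)
    if len(df) < 1000:
        raise ValueError(f"only {len(df)} shared variants; need >= 1000")
    thresholds = 10.0 ** (-np.asarray(config.primary_grid))
    p1 = df["p_primary"].to_numpy()
    p2 = df["p_secondary"].to_numpy()
    base = np.array([(p1 <= t).mean() for t in thresholds])

    rows = []
    for c in config.secondary_cutoffs:
        stratum = p2 < c
        n_s = int(stratum.sum())
        if n_s == 0:
            log.warning("empty secondary stratum at cutoff %g; curve omitted", c)
            continue
        ps = p1[stratum]
        for t, neglog, b in zip(thresholds, config.primary_grid, base):
            frac = (ps <= t).mean()
            rows.append(
                {
                    "cutoff": c,
                    "neglog10_p": neglog,
                    "enrichment": frac / b if b > 0 else np.nan,
                    "n_stratum": n_s,
                    "n_stratum_hits": int((ps <= t).sum()),
                }
            )
    return pd.DataFrame(rows)


@dataclass
class FdrGrid:
    """Stratified empirical CDF of primary p-values, ready for condFDR lookup.

    ``cdf_table[s, b]`` is the (pruning-averaged) fraction of stratum-``s``
    variants with p_primary <= primary_breaks[b]; strata are nested secondary
    cutoffs in descending order starting at 1.0.
    """

    primary_breaks: np.ndarray  # ascending p values
    secondary_strata: np.ndarray  # descending cutoffs, starting at 1.0
    cdf_table: np.ndarray  # (n_strata, n_breaks)
    stratum_counts: np.ndarray
    pruning_iterations: int
    excluded_regions: list = field(default_factory=list)
    collapsed_strata: list = field(default_factory=list)


def _prune_mask(n: int, ld, rng) -> np.ndarray:
    """One random LD pruning: keep a variant iff its random priority is the
    maximum within its r^2>0.1 neighborhood.

    With AR(1) block LD the neighborhood is a symmetric window; identity LD
    keeps everything.
    """
    pri = rng.random(n)
    if ld is None:
        return np.ones(n, dtype=bool)
    if isinstance(ld, BlockLD):
        d = ld._dmax_ge(0.1)
        if d == 0:
            return np.ones(n, dtype=bool)
        win = maximum_filter1d(pri, size=2 * d + 1, mode="nearest")
        return pri >= win
    if isinstance(ld, LDMatrix):
        r2 = ld.r2()
        keep = np.ones(n, dtype=bool)
        for i in range(n):
            nb = np.flatnonzero(r2[i] > 0.1)
            nb = nb[nb != i]
            if len(nb) and pri[nb].max() > pri[i]:
                keep[i] = False
        return keep
    raise TypeError(f"unsupported LD type {type(ld)!r}")


def fit_fdr_grid(
    primary: SummaryStats,
    secondary: SummaryStats,
    ld=None,
    pruning_iterations: int = 10,
    seed: int = 0,
    excluded_regions: list | None = None,
    n_breaks: int = 121,
    max_neglog: float = 12.0,
    min_stratum: int = 100,
    secondary_cutoffs: tuple[float, ...] = (1.0, 0.1, 0.01, 0.001),
) -> FdrGrid:
    """Fit the stratified empirical CDF grid for condFDR lookup.

    Variants inside ``excluded_regions`` are omitted from fitting (they can
    still be scored); strata with fewer than ``min_stratum`` pruned variants
    collapse into their parent stratum. The CDF is averaged over
    ``pruning_iterations`` random LD prunings and made monotone along the
    primary breaks by a running maximum.
    """
    if excluded_regions is None:
        excluded_regions = DEFAULT_EXCLUDED_REGIONS
    df = _merge_pair(primary, secondary)
    fit_mask = np.ones(len(df), dtype=bool)
    for chrom, start, end in excluded_regions:
        fit_mask &= ~(
            (df["chrom"] == str(chrom)) & (df["pos"] >= start) & (df["pos"] <= end)
        )
    fit = df[fit_mask].reset_index(drop=True)
    n = len(fit)
    if n == 0:
        raise ValueError("no variants left for grid fitting after exclusions")

    breaks = 10.0 ** (-np.linspace(max_neglog, 0.0, n_breaks))  # ascending p
    strata = np.asarray(sorted(secondary_cutoffs, reverse=True), dtype=float)
    if strata[0] != 1.0:
        strata = np.concatenate([[1.0], strata])

    rng = np.random.default_rng(seed)
    p1 = fit["p_primary"].to_numpy()
    p2 = fit["p_secondary"].to_numpy()

    acc = np.zeros((len(strata), n_breaks))
    counts = np.zeros(len(strata))
    collapsed: set[int] = set()
    for _ in range(pruning_iterations):
        keep = _prune_mask(n, ld, rng)
        kp1, kp2 = p1[keep], p2[keep]
        order = np.argsort(kp1)
        kp1s = kp1[order]
        kp2s = kp2[order]
        prev = None
        for si, cutoff in enumerate(strata):
            mask = kp2s <= cutoff if cutoff >= 1.0 else kp2s < cutoff
            ps = kp1s[mask]
            cnt = len(ps)
            counts[si] += cnt
            if cnt < min_stratum and prev is not None:
                acc[si] += prev
                collapsed.add(si)
                continue
            cdf = np.searchsorted(ps, breaks, side="right") / max(cnt, 1)
            cdf = np.maximum(cdf, 1.0 / max(cnt, 1))
            acc[si] += cdf
            prev = cdf
    cdf_table = acc / pruning_iterations
    cdf_table = np.maximum.accumulate(cdf_table, axis=1)  # monotone in p
    return FdrGrid(
        primary_breaks=breaks,
        secondary_strata=strata,
        cdf_table=cdf_table,
        stratum_counts=counts / pruning_iterations,
        pruning_iterations=pruning_iterations,
        excluded_regions=list(excluded_regions),
        collapsed_strata=sorted(collapsed),
    )


def condfdr_lookup(grid: FdrGrid, p_primary, p_secondary):
    """condFDR = p_primary / F_hat(p_primary | stratum(p_secondary)), capped at 1.

    The CDF is interpolated linearly in log10 space along the primary breaks.
    All strata whose cutoff the secondary p-value satisfies are applicable and
    the minimum over them is returned, which enforces that tightening the
    secondary stratum never increases the condFDR.
    """
    p1 = np.atleast_1d(np.asarray(p_primary, dtype=float))
    p2 = np.atleast_1d(np.asarray(p_secondary, dtype=float))
    if np.any((p1 <= 0) | (p1 > 1)) or np.any((p2 <= 0) | (p2 > 1)):
        raise ValueError("p-values must be in (0, 1]")
    x = -np.log10(np.clip(p1, grid.primary_breaks[0], 1.0))
    xb = -np.log10(grid.primary_breaks)  # descending along breaks axis
    # np.interp needs ascending xp
    order = np.argsort(xb)
    out = np.full(p1.shape, np.inf)
    for si, cutoff in enumerate(grid.secondary_strata):
        applicable = p2 <= cutoff if cutoff >= 1.0 else p2 < cutoff
        if not applicable.any():
            continue
        logF = np.log10(grid.cdf_table[si])
        interp = np.interp(x[applicable], xb[order], logF[order])
        cf = 10.0 ** (np.log10(p1[applicable]) - interp)
        out[applicable] = np.minimum(out[applicable], cf)
    out = np.minimum(out, 1.0)
    if np.isscalar(p_primary) and np.isscalar(p_secondary):
        return float(out[0])
    return out


def conjfdr(condfdr_primary_given_secondary, condfdr_secondary_given_primary):
    """Conjunctional FDR: the maximum of the two directional condFDRs."""
    return np.maximum(condfdr_primary_given_secondary, condfdr_secondary_given_primary)


class ConjFdrModel:
    """Two-directional conditional FDR model for a trait pair.

    Fits a stratified empirical-CDF grid in each conditioning direction on
    LD-pruned subsets; :meth:`fit` returns a :class:`ConjFdrResults` holding
    per-variant condFDR and conjFDR values.
    """

    def __init__(
        self,
        primary: SummaryStats,
        secondary: SummaryStats,
        ld=None,
        excluded_regions: list | None = None,
    ):
        self.primary = primary
        self.secondary = secondary
        self.ld = ld
        self.excluded_regions = excluded_regions

    def fit(self, pruning_iterations: int = 10, seed: int = 0) -> "ConjFdrResults":
        grid_ab = fit_fdr_grid(
            self.primary,
            self.secondary,
            ld=self.ld,
            pruning_iterations=pruning_iterations,
            seed=seed,
            excluded_regions=self.excluded_regions,
        )
        grid_ba = fit_fdr_grid(
            self.secondary,
            self.primary,
            ld=self.ld,
            pruning_iterations=pruning_iterations,
            seed=seed + 1,
            excluded_regions=self.excluded_regions,
        )
        df = _merge_pair(self.primary, self.secondary)
        cf_ab = condfdr_lookup(grid_ab, df["p_primary"], df["p_secondary"])
        cf_ba = condfdr_lookup(grid_ba, df["p_secondary"], df["p_primary"])
        table = df.assign(
            condfdr_primary_given_secondary=cf_ab,
            condfdr_secondary_given_primary=cf_ba,
            conjfdr=conjfdr(cf_ab, cf_ba),
        )
        return ConjFdrResults(self, grid_ab, grid_ba, table)


@dataclass
class ConjFdrResults:
    """Fitted conjunctional-FDR results for one trait pair."""

    model: ConjFdrModel
    grid_primary_given_secondary: FdrGrid
    grid_secondary_given_primary: FdrGrid
    table: pd.DataFrame

    @property
    def discoveries(self) -> pd.DataFrame:
        """Variants flagged pleiotropic (conjFDR < 0.05)."""
        return self.table[self.table["conjfdr"] < CONJFDR_THRESHOLD].reset_index(
            drop=True
        )

    def summary(self) -> str:
        t = self.table
        lines = [
            "Conjunctional FDR results",
            f"  trait pair: {self.model.primary.trait_label} / "
            f"{self.model.secondary.trait_label}",
            f"  variants scored: {len(t)}",
            f"  pleiotropic (conjFDR<{CONJFDR_THRESHOLD}): {len(self.discoveries)}",
            f"  min conjFDR: {t['conjfdr'].min():.3g}",
        ]
        return "\n".join(lines)


def conjfdr_table(
    primary: SummaryStats,
    secondary: SummaryStats,
    ld=None,
    pruning_iterations: int = 10,
    seed: int = 0,
    excluded_regions: list | None = None,
) -> pd.DataFrame:
    """Convenience wrapper: fit both directions and return the per-variant table."""
    return (
        ConjFdrModel(primary, secondary, ld=ld, excluded_regions=excluded_regions)
        .fit(pruning_iterations=pruning_iterations, seed=seed)
        .table
    )
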