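"""Grid-matching inference of founder size and growth rate.

Simulated (B, lambda) scenarios are compared with the observed census range
and the observed mean allele number per locus.  A growth rate lambda is
accepted when at least one non-extinct founder size produces a mean census
inside the observed range at the evaluation year; a founder size B is
accepted when the observed allele number falls inside the central interval
(mean +/- 1 SD across surviving iterations, or a quantile band) of its
terminal allele number for at least one accepted lambda.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .forward_sim import TrajectoryResult

Grid = dict[tuple[int, float], TrajectoryResult]


@dataclass
class GridMatchResult:
    accepted_lambdas: set[float]
    accepted_founder_sizes: set[int]
    evaluation_year: int
    nc_range: tuple[float, float] | None = None
    observed_na: float | None = None
    cells: dict = field(default_factory=dict)


def match_lambda(
    grid: Grid,
    nc_range: tuple[float, float],
    year: int = 90,
    include_extinct: bool = True,
) -> set[float]:
    """Growth rates whose mean census at ``year`` falls in the observed range
    for at least one non-extinct founder size.

    The census mean is by default taken over *all* iterations with extinct
    replicates counting zero: the question posed is which growth rates make
    the introduction, as planned, expected to produce the observed census —
    an expectation over demographic outcomes.  Pass ``include_extinct=False``
    to condition on persistence instead (both aggregations are available on
    the trajectory objects)."""
    if not grid:
        raise ValueError("empty scenario grid")
    lo, hi = nc_range
    if not (0 < lo <= hi):
        raise ValueError("invalid census range")
    accepted: set[float] = set()
    for (b, lam), traj in grid.items():
        if traj.extinction_fraction >= 1.0:
            continue
        mean_nc = traj.mean_census(year, include_extinct=include_extinct)
        if not math.isnan(mean_nc) and lo <= mean_nc <= hi:
            accepted.add(lam)
    return accepted


def match_founder_size(
    grid: Grid,
    observed_na: float,
    accepted_lambdas: set[float] | None = None,
    year: int = 90,
    rule: str = "mean_sd",
    quantiles: tuple[float, float] = (2.5, 97.5),
) -> set[int]:
    """Founder sizes whose terminal allele-number distribution is consistent
    with the observed value under at least one accepted growth rate.

    ``rule="mean_sd"`` uses mean +/- 1 SD across surviving iterations
    (the default containment rule); ``rule="quantile"`` uses the given
    percentile band of the surviving iterations.
    """
    if not grid:
        raise ValueError("empty scenario grid")
    if observed_na <= 0:
        raise ValueError("observed allele number must be positive")
    accepted: set[int] = set()
    any_survivor = False
    for (b, lam), traj in grid.items():
        if accepted_lambdas is not None and lam not in accepted_lambdas:
            continue
        col = traj.na[:, year]
        col = col[~np.isnan(col)]
        if col.size < 2:
            continue
        any_survivor = True
        if rule == "mean_sd":
            lo, hi = col.mean() - col.std(ddof=1), col.mean() + col.std(ddof=1)
        elif rule == "quantile":
            lo, hi = np.percentile(col, list(quantiles))
        else:
            raise ValueError(f"unknown rule {rule!r}")
        if lo <= observed_na <= hi:
            accepted.add(b)
    if not any_survivor:
        import warnings

        warnings.warn("all scenarios extinct: no founder size can be assessed")
    return accepted


def match_grid(
    grid: Grid,
    observed_na: float,
    nc_range: tuple[float, float],
    year: int = 90,
    rule: str = "mean_sd",
    include_extinct: bool = True,
) -> GridMatchResult:
    """Joint acceptance of growth rates and founder sizes."""
    lams = match_lambda(grid, nc_range, year=year, include_extinct=include_extinct)
    bs = match_founder_size(grid, observed_na, accepted_lambdas=lams, year=year, rule=rule)
    cells = {
        f"B={b},lambda={lam}": {
            "mean_na": traj.mean_na(year),
            "sd_na": traj.sd_na(year),
            "mean_census": traj.mean_census(year),
            "extinction_fraction": traj.extinction_fraction,
        }
        for (b, lam), traj in grid.items()
    }
    return GridMatchResult(
        accepted_lambdas=lams,
        accepted_founder_sizes=bs,
        evaluation_year=year,
        nc_range=nc_range,
        observed_na=observed_na,
        cells=cells,
    )


def _round_sig(x: float, sig: int) -> float:
    if x == 0:
        return 0.0
    return round(x, -int(math.floor(math.log10(abs(x)))) + (sig - 1))


def ne_nc_ratio(
    ne_range: tuple[float, float],
    nc_range: tuple[float, float],
    sig_figs: int = 1,
) -> tuple[float, float]:
    """Ne/Nc ratio range: [min(ne)/max(nc), max(ne)/min(nc)], rounded to
    significant figures (default 1, matching how such ranges are reported)."""
    ne_lo, ne_hi = min(ne_range), max(ne_range)
    nc_lo, nc_hi = min(nc_range), max(nc_range)
    if ne_lo <= 0 or nc_lo <= 0:
        raise ValueError("ranges must be strictly positive")
    return _round_sig(ne_lo / nc_hi, sig_figs), _round_sig(ne_hi / nc_lo, sig_figs)
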