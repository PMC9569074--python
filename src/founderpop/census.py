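"""Mark-recapture census estimation and range extrapolation."""

from __future__ import annotations

from dataclasses import dataclass


@dataclass
class CensusEstimate:
    """Lincoln-Petersen estimate from a single mark-recapture session."""

    M: int  # marked at first visit
    C: int  # captured at second visit
    R: int  # marked recaptures
    N_c_hat: int  # point estimate, rounded to nearest integer


def lincoln_petersen(M: int, C: int, R: int) -> CensusEstimate:
    """Point abundance estimate N_hat = M*C/R, rounded to the nearest integer."""
    if R < 1:
        raise ValueError("no marked recaptures: estimate undefined")
    if M < R or C < R:
        raise ValueError("recaptures cannot exceed either capture count")
    return CensusEstimate(M=M, C=C, R=R, N_c_hat=round(M * C / R))


def extrapolate_nc(
    per_site_estimate: tuple[float, float], n_sites_range: tuple[int, int]
) -> tuple[float, float]:
    """Total census range: per-site abundance range x breeding-site count range."""
    lo_a, hi_a = per_site_estimate
    lo_s, hi_s = n_sites_range
    if lo_a <= 0 or lo_s <= 0 or hi_a < lo_a or hi_s < lo_s:
        raise ValueError("ranges must be positive and ordered")
    return (lo_a * lo_s, hi_a * hi_s)
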