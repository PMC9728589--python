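"""Closed-form growth-rate, fitness and recombination-rate calculators.

Fitness gain is measured as the ratio of the evolved to the ancestral
population growth rate.  The ancestral rate assumes a culture that just
survives a daily 10-fold dilution, growing 10-fold per ``window_h``
hours: r0 = ln(10)/window_h.  The evolved rate comes from the slope m
of a regression of log10 cell counts on time in hours via r12 = e * m,
so the fold change is r12/r0 = window_h * e * m / ln(10) (~= 28.3 m at
the 24 h default).  Note the e factor: a strictly dimensional
conversion of a log10 slope to a per-hour exponential rate would use
ln(10) instead; both conventions are provided, with ``convention="e"``
the default (matching the fold-change coefficient 28.3) and
``convention="ln10"`` the alternative.

Recombination rates compare facultatively sexual budding yeast with
obligately sexual Drosophila on a common per-cell-division scale:
crossovers per meiosis times the meiosis fraction of divisions, divided
by genome size (per Mb) or gene count (per gene).  As yeast fitness
rises, more mitotic divisions occur per weekly meiosis, so the
effective rate drops: the adjusted rate replaces 1/mitoses with
1/(fitness_gain * 10 + 10).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "GrowthAssay",
    "base_growth_rate",
    "evolved_growth_rate",
    "fitness_fold_change",
    "recombination_rates",
]


@dataclass(frozen=True)
class GrowthAssay:
    """Fitted growth assay: slope of log10 counts on hours and the
    derived per-hour rates."""

    times_h: tuple
    log10_counts: tuple
    slope: float  # log10 counts per hour
    r0: float  # per hour
    r12: float  # per hour
    fold_change: float


def base_growth_rate(window_h: float = 24.0) -> float:
    """Ancestral growth rate per hour: ln(10)/window_h.

    A population that barely survives a daily 10x dilution grows
    10-fold per 24 h, so exp(r0 * 24) = 10.
    """
    if window_h <= 0:
        raise ValueError("window_h must be positive")
    return float(np.log(10.0) / window_h)


def evolved_growth_rate(
    times_h, log10_counts, convention: str = "e"
) -> tuple[float, float]:
    """(slope m, evolved rate) from a log10-count growth curve.

    m is the ordinary least-squares slope of log10 counts on hours;
    the rate is e*m under the default convention, ln(10)*m under
    ``convention="ln10"``.
    """
    t = np.asarray(times_h, dtype=float)
    y = np.asarray(log10_counts, dtype=float)
    if np.unique(t).size < 2:
        raise ValueError("need at least 2 distinct time points")
    m = float(stats.linregress(t, y).slope)
    factor = _rate_factor(convention)
    return m, factor * m


def _rate_factor(convention: str) -> float:
    if convention == "e":
        return float(np.e)
    if convention == "ln10":
        return float(np.log(10.0))
    raise ValueError(f"unknown convention {convention!r}")


def fitness_fold_change(
    m: float, window_h: float = 24.0, convention: str = "e"
) -> float:
    """r12/r0 = window_h * e * m / ln(10) (~ 28.3 m at 24 h)."""
    return _rate_factor(convention) * m * window_h / float(np.log(10.0))


def fit_growth_assay(times_h, log10_counts, window_h: float = 24.0,
                     convention: str = "e") -> GrowthAssay:
    m, r12 = evolved_growth_rate(times_h, log10_counts, convention)
    return GrowthAssay(
        times_h=tuple(float(t) for t in times_h),
        log10_counts=tuple(float(y) for y in log10_counts),
        slope=m,
        r0=base_growth_rate(window_h),
        r12=r12,
        fold_change=fitness_fold_change(m, window_h, convention),
    )


def recombination_rates(
    crossovers_per_meiosis: float,
    mitoses_per_meiosis: float,
    genome_mb: float | None = None,
    n_genes: float | None = None,
    fitness_gain: float | None = None,
) -> dict[str, float]:
    """Per-cell-division recombination rates per Mb and per gene.

    per_mb   = crossovers * (1/mitoses) / genome_mb
    per_gene = crossovers * (1/mitoses) / n_genes
    adjusted_* replaces 1/mitoses with 1/(fitness_gain*10 + 10): a
    fitter yeast population completes more asexual divisions per weekly
    meiosis, diluting the recombination each division sees.

    Yeast defaults in the literature: 90 crossovers per meiosis, ~20
    mitoses per meiosis, 12 Mb, ~6,000 genes; fly: 5 crossovers
    (females only, so 5*(1/2) sex-averaged), 120 Mb, ~14,000 genes.
    """
    if crossovers_per_meiosis <= 0 or mitoses_per_meiosis <= 0:
        raise ValueError("crossovers and mitoses must be positive")
    out: dict[str, float] = {}
    meiosis_frac = 1.0 / mitoses_per_meiosis
    if genome_mb is not None:
        if genome_mb <= 0:
            raise ValueError("genome_mb must be positive")
        out["per_mb"] = crossovers_per_meiosis * meiosis_frac / genome_mb
    if n_genes is not None:
        if n_genes <= 0:
            raise ValueError("n_genes must be positive")
        out["per_gene"] = crossovers_per_meiosis * meiosis_frac / n_genes
    if fitness_gain is not None:
        if fitness_gain <= 0:
            raise ValueError("fitness_gain must be positive")
        adj = 1.0 / (fitness_gain * 10.0 + 10.0)
        if genome_mb is not None:
            out["adjusted_per_mb"] = crossovers_per_meiosis * adj / genome_mb
        if n_genes is not None:
            out["adjusted_per_gene"] = crossovers_per_meiosis * adj / n_genes
    if not out:
        raise ValueError("provide genome_mb and/or n_genes")
    return out
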