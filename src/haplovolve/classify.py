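"""Heterozygosity-based classification of evolved populations.

Forced weekly outcrossing can be subverted by asexual "cheater" clones
that sweep a population.  A swept population is recognizable from its
per-site haplotype heterozygosity, H = 1 - sum_k p_k^2: a doubled
haploid clone collapses H to ~0 genome-wide (except the mating-type
locus), a heterozygous diploid clone yields a bimodal H profile with
modes at 0 and 0.5, while outbred sexual populations keep high,
unimodally distributed H.  The thresholds that operationalize these
qualitative signatures are configurable; the defaults are engineering
choices recorded in the classification report.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .tables import HaplotypeFrequencyTable

__all__ = [
    "ClassifierThresholds",
    "PopulationRecord",
    "per_site_heterozygosity",
    "heterozygosity_reduction",
    "classify_population",
    "cladogram_filter",
    "select_sexual_treatments",
]

ANEUPLOID_HAPLOID = "aneuploid_haploid"
CLONAL_DIPLOID = "clonal_diploid"
OUTBRED_SEXUAL = "outbred_sexual"


@dataclass(frozen=True)
class ClassifierThresholds:
    """Numeric thresholds separating the three population classes.

    aneuploid_haploid: mean H < ``haploid_mean_h`` and at least
    ``haploid_fixed_fraction`` of non-mating-type loci fixed (max
    haplotype frequency > ``haploid_fixed_freq``).
    clonal_diploid: at least ``diploid_modal_fraction`` of loci in the
    0 mode (H < ``low_h``) or the 0.5 mode (H in [``mid_h_lo``,
    ``mid_h_hi``]), with each mode holding at least
    ``diploid_min_mode_fraction`` of loci.
    """

    haploid_mean_h: float = 0.1
    haploid_fixed_fraction: float = 0.9
    haploid_fixed_freq: float = 0.9
    low_h: float = 0.1
    mid_h_lo: float = 0.4
    mid_h_hi: float = 0.6
    diploid_modal_fraction: float = 0.8
    diploid_min_mode_fraction: float = 0.1


@dataclass
class PopulationRecord:
    treatment: str
    replicate: str
    classification: str
    mean_heterozygosity: float
    heterozygosity_skew: float
    retained: bool = True
    reason: str = ""


def per_site_heterozygosity(freqs: np.ndarray, tol: float = 0.01) -> np.ndarray:
    """H = 1 - sum of squared haplotype frequencies, per locus.

    Accepts a single frequency vector or an (n_loci, n_haplotypes)
    matrix; each vector must sum to 1 within ``tol``.
    """
    arr = np.atleast_2d(np.asarray(freqs, dtype=float))
    sums = arr.sum(axis=1)
    if np.any(np.abs(sums - 1.0) > tol):
        raise ValueError("frequency vector does not sum to 1")
    h = 1.0 - np.sum(arr**2, axis=1)
    return h[0] if np.asarray(freqs).ndim == 1 else h


def heterozygosity_reduction(
    base: HaplotypeFrequencyTable, evolved: HaplotypeFrequencyTable
) -> float:
    """Mean over loci of (H_base - H_evolved)."""
    if not base.same_grid(evolved):
        raise ValueError("base and evolved tables are on different grids")
    h_base = per_site_heterozygosity(base.freqs)
    h_evo = per_site_heterozygosity(evolved.freqs)
    return float(np.mean(h_base - h_evo))


def classify_population(
    table: HaplotypeFrequencyTable,
    mating_type_window: tuple[str, int, int] | None = None,
    thresholds: ClassifierThresholds | None = None,
    min_loci: int = 100,
) -> PopulationRecord:
    """Assign exactly one of the three population classes.

    ``mating_type_window`` (chrom, start, end) excludes the region where
    haploid cheaters legitimately retain heterozygosity.  Skewness of
    the H distribution is reported but not used as a criterion.
    """
    if table.n_loci < min_loci:
        raise ValueError(
            f"population {table.population}: {table.n_loci} loci < {min_loci}"
        )
    th = thresholds or ClassifierThresholds()
    h = per_site_heterozygosity(table.freqs)
    non_mt = np.ones(table.n_loci, dtype=bool)
    if mating_type_window is not None:
        c, s, e = mating_type_window
        non_mt &= ~((table.chrom == c) & (table.pos >= s) & (table.pos <= e))
    max_freq = table.freqs.max(axis=1)

    mean_h = float(h.mean())
    skew = float(stats.skew(h))
    fixed_frac = float(np.mean(max_freq[non_mt] > th.haploid_fixed_freq))
    low_frac = float(np.mean(h < th.low_h))
    mid_frac = float(np.mean((h >= th.mid_h_lo) & (h <= th.mid_h_hi)))

    if mean_h < th.haploid_mean_h and fixed_frac >= th.haploid_fixed_fraction:
        label = ANEUPLOID_HAPLOID
    elif (
        low_frac + mid_frac >= th.diploid_modal_fraction
        and low_frac >= th.diploid_min_mode_fraction
        and mid_frac >= th.diploid_min_mode_fraction
    ):
        label = CLONAL_DIPLOID
    else:
        label = OUTBRED_SEXUAL

    treatment, _, replicate = table.population.rpartition("_")
    return PopulationRecord(
        treatment=treatment or table.population,
        replicate=replicate or table.population,
        classification=label,
        mean_heterozygosity=mean_h,
        heterozygosity_skew=skew,
    )


def cladogram_filter(
    tables_by_treatment: dict[str, list[HaplotypeFrequencyTable]],
    q: int = 3,
) -> set[str]:
    """Replicate-retention filter based on between-population distances.

    Distance between two populations is 1 - Spearman correlation of
    their concatenated genome-wide haplotype-frequency vectors.  A
    population is retained iff a majority of its q nearest neighbors
    come from its own treatment (the neighbor relation a treatment-wise
    cladogram expresses).  Returns the retained population names;
    invariant to input order.
    """
    pops: list[tuple[str, str, np.ndarray]] = []
    for treatment, tables in tables_by_treatment.items():
        for t in tables:
            pops.append((treatment, t.population, t.freqs.ravel()))
    n = len(pops)
    if len(tables_by_treatment) < 2 or any(
        len(v) < 2 for v in tables_by_treatment.values()
    ):
        raise ValueError("need >= 2 treatments with >= 2 populations each")
    if q >= n:
        raise ValueError(f"q = {q} must be smaller than {n} total populations")
    mat = np.stack([v for _, _, v in pops])
    rho = stats.spearmanr(mat, axis=1).statistic
    rho = np.atleast_2d(rho)
    dist = 1.0 - rho
    retained: set[str] = set()
    # deterministic neighbor ordering: distance, then name
    names = [name for _, name, _ in pops]
    for i in range(n):
        order = sorted(
            (j for j in range(n) if j != i),
            key=lambda j: (dist[i, j], names[j]),
        )
        neighbors = order[:q]
        same = sum(1 for j in neighbors if pops[j][0] == pops[i][0])
        if same * 2 > q:
            retained.add(names[i])
    return retained


def select_sexual_treatments(
    records: list[PopulationRecord],
    min_reps: int = 6,
    exempt: set[str] = frozenset({"YPD"}),
) -> set[str]:
    """Treatments keeping >= ``min_reps`` retained sexual replicates.

    Treatments in ``exempt`` (the no-drug control by default) are
    retained regardless of their count.
    """
    counts: dict[str, int] = {}
    for rec in records:
        if rec.classification == OUTBRED_SEXUAL and rec.retained:
            counts[rec.treatment] = counts.get(rec.treatment, 0) + 1
    treatments = {rec.treatment for rec in records}
    return {
        t for t in treatments if counts.get(t, 0) >= min_reps or t in exempt
    }


def classification_report(records: list[PopulationRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "population": [f"{r.treatment}_{r.replicate}" for r in records],
            "treatment": [r.treatment for r in records],
            "class": [r.classification for r in records],
            "mean_H": [r.mean_heterozygosity for r in records],
            "skew_H": [r.heterozygosity_skew for r in records],
            "retained": [r.retained for r in records],
            "reason": [r.reason for r in records],
        }
    )
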