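"""Chi-square scan for replicated haplotype-frequency change and peak calling.

At each grid locus, the K haplotypes starting at frequency >= 0.5% in
the base population are tested for consistent change across the R
replicate evolved populations.  With

    delta_{k,r} = asin(sqrt(evolved_{k,r})) - asin(sqrt(base_k)),

the mean change delta_bar_k over replicates is standardized by a shared
variance estimate

    var(delta_bar) = [ mean_k var_hat(delta_k) + R (eps_B^2 + eps_E^2) ] / R,

the average between-replicate variance over the K tested haplotypes
plus the variance contributed by haplotype-estimation error in the base
(eps_B) and evolved (eps_E) tables.  Each Delta_k =
delta_bar_k / sqrt(var(delta_bar)) is treated as a unit normal under
the null, so S = sum_k Delta_k^2 is chi-squared with K degrees of
freedom; support is reported as LOD = -log10(P).  Because the variance
estimate double-counts measurement error, the test is deliberately
conservative.

Peaks are local maxima of the LOD track required to be at least
2 x min_separation grid steps (100 kb at the defaults) from any other
called peak on the chromosome; among conflicting maxima the higher LOD
wins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .tables import HaplotypeFrequencyTable

__all__ = [
    "ScanResult",
    "Peak",
    "asin_sqrt",
    "haplotype_deltas",
    "chi_square_scan",
    "significance_fraction",
    "call_peaks",
]

LOG10 = np.log(10.0)
P_FLOOR = 1e-300


def asin_sqrt(p):
    """Arcsine square-root (variance-stabilizing) transform, in radians.

    Values outside [0, 1] by at most 1e-9 are clipped; larger excursions
    raise a domain error.
    """
    arr = np.asarray(p, dtype=float)
    if np.any(arr < -1e-9) or np.any(arr > 1 + 1e-9):
        raise ValueError("frequency outside [0, 1]")
    return np.arcsin(np.sqrt(np.clip(arr, 0.0, 1.0)))


@dataclass
class ScanResult:
    """Per-locus chi-square scan output.

    ``k`` is the number of tested haplotypes at the locus, ``chisq`` the
    statistic S, ``p`` the upper-tail probability (floored at 1e-300)
    and ``lod`` = -log10 P computed in log space so that extreme loci
    remain ordered.  ``delta_bar`` and ``delta_std`` (per-locus lists,
    aligned with ``tested_labels``) are kept for diagnostics.
    """

    chrom: np.ndarray
    pos: np.ndarray
    k: np.ndarray
    chisq: np.ndarray
    p: np.ndarray
    lod: np.ndarray
    tested_labels: list[tuple[str, ...]]
    delta_bar: list[np.ndarray]
    delta_std: list[np.ndarray]

    @property
    def n_loci(self) -> int:
        return self.pos.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": self.chrom,
                "pos": self.pos,
                "K": self.k,
                "chisq": self.chisq,
                "p": self.p,
                "lod": self.lod,
            }
        )


@dataclass(frozen=True)
class Peak:
    chrom: str
    pos: int
    lod: float
    left_min: int  # position of nearest flanking minimum (or chromosome end)
    right_min: int


def _chi2_logsf(s: float, k: int) -> float:
    """log upper-tail chi-square probability, stable for extreme s.

    Falls back to the leading term of the incomplete-gamma asymptotic
    series, Q(a, x) ~ x^(a-1) e^-x / Gamma(a) with a = k/2, x = s/2,
    where the library routine underflows; keeps extreme loci strictly
    ordered instead of collapsing to -inf.
    """
    val = float(stats.chi2.logsf(s, k))
    if np.isfinite(val):
        return val
    a, x = k / 2.0, s / 2.0
    from scipy.special import gammaln

    return float(-x + (a - 1.0) * np.log(x) - gammaln(a))


def haplotype_deltas(
    base_freqs: np.ndarray,
    evolved_reps: np.ndarray,
    eps_base: float = 0.004,
    eps_evolved: float = 0.01,
    min_base_freq: float = 0.005,
):
    """Standardized mean changes (delta_bar_k, Delta_k) at one locus.

    Parameters
    ----------
    base_freqs:
        Base haplotype frequency vector (length n_haplotypes).
    evolved_reps:
        (R, n_haplotypes) evolved frequencies, R >= 2 replicates.
    min_base_freq:
        Haplotypes below this base frequency are excluded from the K
        tested haplotypes.

    Returns
    -------
    (tested_index, delta_bar, delta_std, var_delta_bar):
        indices of the K tested haplotypes, their mean transformed
        change, the standardized Delta_k, and the shared variance.
    """
    base = np.asarray(base_freqs, dtype=float)
    evo = np.atleast_2d(np.asarray(evolved_reps, dtype=float))
    r = evo.shape[0]
    if r < 2:
        raise ValueError("need at least 2 replicate evolved populations")
    tested = np.flatnonzero(base >= min_base_freq)
    if tested.size == 0:
        raise ValueError("no haplotypes pass the minimum base frequency")
    delta = asin_sqrt(evo[:, tested]) - asin_sqrt(base[tested])  # (R, K)
    delta_bar = delta.mean(axis=0)
    # shared variance over the K tested haplotypes (unbiased over replicates)
    mean_var = delta.var(axis=0, ddof=1).mean()
    var_delta_bar = (mean_var + r * (eps_base**2 + eps_evolved**2)) / r
    if var_delta_bar > 0:
        delta_std = delta_bar / np.sqrt(var_delta_bar)
    else:
        # degenerate: no replicate spread and no assumed measurement error
        delta_std = np.zeros_like(delta_bar)
        nz = delta_bar != 0.0
        delta_std[nz] = np.sign(delta_bar[nz]) * np.inf
    return tested, delta_bar, delta_std, var_delta_bar


def chi_square_scan(
    base: HaplotypeFrequencyTable,
    evolved: list[HaplotypeFrequencyTable],
    eps_base: float = 0.004,
    eps_evolved: float = 0.01,
    min_base_freq: float = 0.005,
) -> ScanResult:
    """Genome-wide chi-square scan of replicated haplotype change."""
    if len(evolved) < 2:
        raise ValueError("need at least 2 replicate evolved populations")
    for t in evolved:
        if not base.same_grid(t):
            raise ValueError(
                f"population {t.population} is not on the base table's grid"
            )
        if t.labels != base.labels:
            raise ValueError(
                f"population {t.population} has different haplotype labels"
            )
    evo = np.stack([t.freqs for t in evolved])  # (R, n_loci, n_hap)
    n_loci = base.n_loci
    k_arr = np.zeros(n_loci, dtype=np.int64)
    s_arr = np.zeros(n_loci)
    p_arr = np.ones(n_loci)
    lod_arr = np.zeros(n_loci)
    labels_out: list[tuple[str, ...]] = []
    dbar_out: list[np.ndarray] = []
    dstd_out: list[np.ndarray] = []
    labels = np.asarray(base.labels, dtype=object)
    for i in range(n_loci):
        tested, dbar, dstd, _ = haplotype_deltas(
            base.freqs[i], evo[:, i, :], eps_base, eps_evolved, min_base_freq
        )
        k = tested.size
        s = float(np.sum(dstd**2))
        k_arr[i] = k
        s_arr[i] = s
        # log-space survival function keeps extreme loci ordered; the
        # reported p is floored at 1e-300
        log_sf = _chi2_logsf(s, k)
        lod_arr[i] = -log_sf / LOG10
        p_arr[i] = max(float(np.exp(log_sf)), P_FLOOR)
        labels_out.append(tuple(labels[tested]))
        dbar_out.append(dbar)
        dstd_out.append(dstd)
    return ScanResult(
        chrom=base.chrom.copy(),
        pos=base.pos.copy(),
        k=k_arr,
        chisq=s_arr,
        p=p_arr,
        lod=lod_arr,
        tested_labels=labels_out,
        delta_bar=dbar_out,
        delta_std=dstd_out,
    )


def significance_fraction(scan: ScanResult, lod_cutoff: float = 5.0) -> float:
    """Fraction of scanned loci with LOD >= cutoff."""
    if scan.n_loci == 0:
        raise ValueError("empty scan")
    return float(np.mean(scan.lod >= lod_cutoff))


def _strict_local_maxima(values: np.ndarray) -> np.ndarray:
    """Indices of local maxima; plateaus contribute their leftmost index."""
    n = values.size
    if n == 0:
        return np.empty(0, dtype=np.int64)
    if n == 1:
        return np.array([0], dtype=np.int64)
    out = []
    i = 0
    while i < n:
        j = i
        while j + 1 < n and values[j + 1] == values[i]:
            j += 1
        left_ok = i == 0 or values[i - 1] < values[i]
        right_ok = j == n - 1 or values[j + 1] < values[i]
        if left_ok and right_ok:
            out.append(i)
        i = j + 1
    return np.asarray(out, dtype=np.int64)


def call_peaks(
    chrom: np.ndarray,
    pos: np.ndarray,
    lod: np.ndarray,
    min_separation: int = 50,
    step: int = 1_000,
) -> list[Peak]:
    """Local-maxima peak caller with enforced separation.

    Candidate peaks are strict local maxima of the LOD track (plateaus
    take their leftmost locus).  Candidates are accepted greedily in
    decreasing LOD order (ties to the left); a candidate within
    ``2 * min_separation * step`` bp of an already accepted peak on the
    same chromosome is discarded, so called peaks are pairwise at least
    100 kb apart at the defaults.  Peaks never span chromosomes.
    """
    chrom = np.asarray(chrom, dtype=object)
    pos = np.asarray(pos, dtype=np.int64)
    lod = np.asarray(lod, dtype=float)
    min_dist = 2 * min_separation * step
    peaks: list[Peak] = []
    for c in dict.fromkeys(chrom):
        mask = chrom == c
        cp = pos[mask]
        cl = lod[mask]
        order = np.argsort(cp)
        cp, cl = cp[order], cl[order]
        cand = _strict_local_maxima(cl)
        if cand.size == 0:
            continue
        # higher LOD wins; ties to the left
        cand = cand[np.lexsort((cand, -cl[cand]))]
        accepted: list[int] = []
        for idx in cand:
            if all(abs(int(cp[idx]) - int(cp[a])) >= min_dist for a in accepted):
                accepted.append(int(idx))
        minima = _strict_local_maxima(-cl)
        for idx in sorted(accepted):
            left_candidates = minima[minima < idx]
            right_candidates = minima[minima > idx]
            left = int(cp[left_candidates[-1]]) if left_candidates.size else int(cp[0])
            right = int(cp[right_candidates[0]]) if right_candidates.size else int(cp[-1])
            peaks.append(
                Peak(
                    chrom=str(c),
                    pos=int(cp[idx]),
                    lod=float(cl[idx]),
                    left_min=left,
                    right_min=right,
                )
            )
    return peaks
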