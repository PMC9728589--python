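"""Which founder drives adaptation, how repeatable it is, and where
treatments overlap.

At any locus the most increased haplotype (MIH) is the founder with the
largest mean raw frequency gain over replicate evolved populations; the
gap between the MIH and the next MIH quantifies how strongly adaptation
is dominated by a single haplotype.  Repeatability across replicates is
measured three ways: the mean pairwise Spearman correlation of
per-locus haplotype frequencies, the Spearman correlation of LOD tracks
from two random halves of the replicates, and the genome-average
absolute deviation of a held-out replicate's MIH frequency from the
mean of the others (0 = perfect repeatability).  Pleiotropy between
treatments is screened via the pairwise Spearman correlation of
genome-wide LOD tracks and shared regions where both treatments'
z-scored LOD exceeds 1.96.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .scan import ScanResult
from .tables import HaplotypeFrequencyTable

__all__ = [
    "MIHRecord",
    "most_increased_haplotype",
    "mih_summary",
    "replicate_spearman",
    "split_half_lod_correlation",
    "zscore_lod",
    "mih_deviation",
    "pleiotropy_screen",
]


@dataclass(frozen=True)
class MIHRecord:
    chrom: str
    pos: int
    mih: str
    mih_change: float
    next_mih: str
    next_change: float
    mih_base: float
    next_base: float


def _mean_change(base: np.ndarray, evolved_reps: np.ndarray) -> np.ndarray:
    evo = np.atleast_2d(evolved_reps)
    return evo.mean(axis=0) - base


def most_increased_haplotype(
    base_freqs: np.ndarray,
    evolved_reps: np.ndarray,
    labels,
    chrom: str = "",
    pos: int = 0,
) -> MIHRecord:
    """Top two haplotypes ranked by mean raw frequency change.

    Exact ties are broken toward the lexicographically smaller label.
    """
    labels = list(labels)
    if len(labels) < 2:
        raise ValueError("need at least 2 haplotypes to rank")
    base = np.asarray(base_freqs, dtype=float)
    change = _mean_change(base, np.asarray(evolved_reps, dtype=float))
    order = sorted(range(len(labels)), key=lambda i: (-change[i], labels[i]))
    first, second = order[0], order[1]
    return MIHRecord(
        chrom=chrom,
        pos=int(pos),
        mih=labels[first],
        mih_change=float(change[first]),
        next_mih=labels[second],
        next_change=float(change[second]),
        mih_base=float(base[first]),
        next_base=float(base[second]),
    )


def mih_table(
    base: HaplotypeFrequencyTable,
    evolved: list[HaplotypeFrequencyTable],
    positions=None,
) -> list[MIHRecord]:
    """MIH records over all grid loci (or a subset of (chrom, pos))."""
    evo = np.stack([t.freqs for t in evolved])
    wanted = None if positions is None else set(positions)
    records = []
    for i in range(base.n_loci):
        key = (base.chrom[i], int(base.pos[i]))
        if wanted is not None and key not in wanted:
            continue
        records.append(
            most_increased_haplotype(
                base.freqs[i], evo[:, i, :], base.labels, key[0], key[1]
            )
        )
    return records


class EmptySummaryError(ValueError):
    """Conditioning left no records to summarize."""


def mih_summary(
    records: list[MIHRecord], condition: str | None = None
) -> tuple[float, float, float]:
    """(mean MIH change, mean next-MIH change, ratio) over records.

    ``condition='next-MIH-starts-higher'`` restricts to loci where the
    next MIH started at a higher base frequency than the MIH, the
    control for initial-frequency effects.
    """
    if condition not in (None, "next-MIH-starts-higher"):
        raise ValueError(f"unknown condition {condition!r}")
    if condition:
        records = [r for r in records if r.next_base > r.mih_base]
    if not records:
        raise EmptySummaryError("no records after conditioning")
    mih_mean = float(np.mean([r.mih_change for r in records]))
    next_mean = float(np.mean([r.next_change for r in records]))
    ratio = mih_mean / next_mean if next_mean != 0 else np.inf
    return mih_mean, next_mean, ratio


def replicate_spearman(tables: list[HaplotypeFrequencyTable]) -> float:
    """Mean over loci and replicate pairs of per-locus Spearman rho."""
    if len(tables) < 2:
        raise ValueError("need at least 2 replicates")
    freqs = np.stack([t.freqs for t in tables])  # (R, n_loci, n_hap)
    r = freqs.shape[0]
    # average ranks per replicate x locus, then Pearson over ranks ==
    # Spearman with average-rank ties
    ranks = stats.rankdata(freqs, axis=2)
    vals = []
    for a in range(r):
        for b in range(a + 1, r):
            xa = ranks[a] - ranks[a].mean(axis=1, keepdims=True)
            xb = ranks[b] - ranks[b].mean(axis=1, keepdims=True)
            num = (xa * xb).sum(axis=1)
            den = np.sqrt((xa**2).sum(axis=1) * (xb**2).sum(axis=1))
            ok = den > 0
            vals.append(num[ok] / den[ok])
    return float(np.concatenate(vals).mean())


def split_half_lod_correlation(
    base: HaplotypeFrequencyTable,
    tables: list[HaplotypeFrequencyTable],
    eps_base: float = 0.004,
    eps_evolved: float = 0.01,
    seed: int = 0,
) -> tuple[float, tuple[tuple[str, ...], tuple[str, ...]]]:
    """Spearman rho between LOD tracks of two random replicate halves.

    Deterministic given ``seed``; returns (rho, (half1, half2)) with the
    halves given as population-name tuples.
    """
    from .scan import chi_square_scan

    if len(tables) < 4:
        raise ValueError("need at least 4 replicates (2 per half)")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(tables))
    half_n = len(tables) // 2
    g1 = [tables[i] for i in order[:half_n]]
    g2 = [tables[i] for i in order[half_n : 2 * half_n]]
    lod1 = chi_square_scan(base, g1, eps_base, eps_evolved).lod
    lod2 = chi_square_scan(base, g2, eps_base, eps_evolved).lod
    rho = float(stats.spearmanr(lod1, lod2).statistic)
    return rho, (
        tuple(t.population for t in g1),
        tuple(t.population for t in g2),
    )


def zscore_lod(lod: np.ndarray) -> np.ndarray:
    """Standardize a LOD track to mean 0, SD 1 (mutes major genes)."""
    arr = np.asarray(lod, dtype=float)
    if arr.size < 2:
        raise ValueError("need at least 2 loci")
    sd = arr.std()
    if sd == 0:
        raise ValueError("LOD track has zero variance")
    return (arr - arr.mean()) / sd


def mih_deviation(
    base: HaplotypeFrequencyTable,
    tables: list[HaplotypeFrequencyTable],
    held_out: str,
) -> tuple[np.ndarray, float]:
    """Per-locus |MIH freq in held-out - mean MIH freq of the others|.

    The MIH at each locus is defined from the mean change over the
    non-held-out replicates.  Returns the per-locus deviations and
    their genome average (0 under perfect repeatability).
    """
    if len(tables) < 3:
        raise ValueError("need at least 3 replicates")
    names = [t.population for t in tables]
    if held_out not in names:
        raise ValueError(f"held-out replicate {held_out!r} not found")
    held = tables[names.index(held_out)]
    rest = [t for t in tables if t.population != held_out]
    evo = np.stack([t.freqs for t in rest])
    change = evo.mean(axis=0) - base.freqs  # (n_loci, n_hap)
    mih_idx = np.argmax(change, axis=1)
    rows = np.arange(base.n_loci)
    dev = np.abs(held.freqs[rows, mih_idx] - evo.mean(axis=0)[rows, mih_idx])
    return dev, float(dev.mean())


def pleiotropy_screen(
    scans_by_treatment: dict[str, ScanResult],
    mih_by_treatment: dict[str, list[MIHRecord]] | None = None,
    z_cutoff: float = 1.96,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cross-treatment LOD correlations and shared high-scoring regions.

    Returns (rho_matrix, shared_regions).  ``rho_matrix`` is the
    symmetric pairwise Spearman matrix of genome-wide LOD tracks.
    ``shared_regions`` lists maximal runs of consecutive grid loci where
    both treatments' z-scored LOD >= ``z_cutoff``, flagged ``same_mih``
    when the treatments' MIH agrees somewhere in the region (requires
    ``mih_by_treatment``).
    """
    names = list(scans_by_treatment)
    if len(names) < 2:
        raise ValueError("need at least 2 treatments")
    ref = scans_by_treatment[names[0]]
    for n in names[1:]:
        s = scans_by_treatment[n]
        if s.n_loci != ref.n_loci or np.any(s.pos != ref.pos) or np.any(
            s.chrom != ref.chrom
        ):
            raise ValueError(f"scan for {n} is on a different grid")
    lods = {n: scans_by_treatment[n].lod for n in names}
    rho = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    for i, a in enumerate(names):
        for j in range(i + 1, len(names)):
            b = names[j]
            r = float(stats.spearmanr(lods[a], lods[b]).statistic)
            rho.loc[a, b] = rho.loc[b, a] = r
    zs = {n: zscore_lod(lods[n]) for n in names}

    mih_lookup = {}
    if mih_by_treatment:
        for n, recs in mih_by_treatment.items():
            mih_lookup[n] = {(r.chrom, r.pos): r.mih for r in recs}

    regions = []
    for i, a in enumerate(names):
        for j in range(i + 1, len(names)):
            b = names[j]
            both = (zs[a] >= z_cutoff) & (zs[b] >= z_cutoff)
            k = 0
            while k < both.size:
                if both[k]:
                    m = k
                    while (
                        m + 1 < both.size
                        and both[m + 1]
                        and ref.chrom[m + 1] == ref.chrom[k]
                    ):
                        m += 1
                    same = None
                    if mih_lookup:
                        for idx in range(k, m + 1):
                            key = (ref.chrom[idx], int(ref.pos[idx]))
                            ma = mih_lookup.get(a, {}).get(key)
                            mb = mih_lookup.get(b, {}).get(key)
                            if ma is not None and mb is not None:
                                same = bool(ma == mb)
                                if same:
                                    break
                    regions.append(
                        {
                            "treatment_a": a,
                            "treatment_b": b,
                            "chrom": ref.chrom[k],
                            "start": int(ref.pos[k]),
                            "end": int(ref.pos[m]),
                            "same_mih": same,
                        }
                    )
                    k = m + 1
                else:
                    k += 1
    shared = pd.DataFrame(
        regions,
        columns=["treatment_a", "treatment_b", "chrom", "start", "end", "same_mih"],
    )
    return rho, shared
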