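"""Aneuploidy detection from coverage ratios and de novo SNV filtering.

Whole-chromosome and segmental duplications are detected from the ratio
of relative coverage (evolved over base) in 2 kb bins: bins at
normalized fold-coverage >= 1.25 are binarized and decoded with a
two-state (normal/duplicated) hidden Markov model; maximal duplicated
intervals become calls, labelled whole-chromosome when they span >= 95%
of the chromosome.

Candidate de novo single-nucleotide variants pass four filters: not
present in any founder, not present in the base population, sequencing
depth >= 10x, and alt-read fraction >= 20%; variants recurring in more
than five different chemical treatments are discarded as culture
artifacts.  Genes hit by filtered SNVs in two or more replicates of the
same treatment are flagged as multi-hit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from hmmlearn.hmm import CategoricalHMM
from intervaltree import IntervalTree

__all__ = [
    "CoverageProfile",
    "DuplicationCall",
    "HMMParams",
    "normalized_fold_coverage",
    "call_duplications",
    "filter_denovo_snvs",
    "multihit_genes",
]


@dataclass
class CoverageProfile:
    """Per-bin read coverage on a tiled 2 kb grid (1-based closed bins)."""

    chrom: np.ndarray
    start: np.ndarray
    end: np.ndarray
    coverage: np.ndarray

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.start = np.asarray(self.start, dtype=np.int64)
        self.end = np.asarray(self.end, dtype=np.int64)
        self.coverage = np.asarray(self.coverage, dtype=float)
        if np.any(self.coverage < 0):
            raise ValueError("coverage must be non-negative")

    @property
    def n_bins(self) -> int:
        return self.start.size

    def relative(self) -> np.ndarray:
        """Bin coverage divided by the genome-wide mean coverage."""
        mean = self.coverage.mean()
        if mean <= 0:
            raise ValueError("genome-mean coverage must be positive")
        return self.coverage / mean

    def same_bins(self, other: "CoverageProfile") -> bool:
        return (
            self.n_bins == other.n_bins
            and bool(np.all(self.chrom == other.chrom))
            and bool(np.all(self.start == other.start))
            and bool(np.all(self.end == other.end))
        )

    def write_bed(self, path) -> None:
        # BED is 0-based half-open; internal coordinates are 1-based closed
        with open(path, "wt", encoding="utf-8") as fh:
            fh.write("#chrom\tstart\tend\tcoverage\n")
            for c, s, e, v in zip(self.chrom, self.start, self.end, self.coverage):
                fh.write(f"{c}\t{s - 1}\t{e}\t{v:g}\n")

    @classmethod
    def read_bed(cls, path) -> "CoverageProfile":
        rows = []
        with open(path, "rt", encoding="utf-8") as fh:
            for line in fh:
                if line.startswith("#") or not line.strip():
                    continue
                c, s, e, v = line.rstrip("\n").split("\t")[:4]
                rows.append((c, int(s) + 1, int(e), float(v)))
        chrom, start, end, cov = zip(*rows)
        return cls(np.array(chrom, dtype=object), np.array(start),
                   np.array(end), np.array(cov))


@dataclass(frozen=True)
class DuplicationCall:
    chrom: str
    start: int  # 1-based closed
    end: int
    mean_fold_coverage: float
    kind: str  # "whole_chromosome" | "segmental"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("call start must precede end")


@dataclass(frozen=True)
class HMMParams:
    """Two-state Bernoulli HMM over the binarized fold-coverage track.

    The duplicated state emits an above-threshold bin with probability
    ``p_emit_dup``; the normal state with ``p_emit_normal``.  Symmetric
    switching probability ``p_switch`` controls segment granularity.
    """

    p_emit_dup: float = 0.9
    p_emit_normal: float = 0.05
    p_switch: float = 1e-4
    start_dup: float = 0.01


def normalized_fold_coverage(
    base: CoverageProfile, evolved: CoverageProfile
) -> np.ndarray:
    """(evolved bin / evolved mean) / (base bin / base mean) per bin.

    Bins with zero base relative coverage are masked (NaN); the masked
    count is reported via a warning.
    """
    if not base.same_bins(evolved):
        raise ValueError("coverage profiles are on different bin grids")
    rel_base = base.relative()
    rel_evo = evolved.relative()
    ratio = np.full(rel_base.shape, np.nan)
    ok = rel_base > 0
    ratio[ok] = rel_evo[ok] / rel_base[ok]
    n_masked = int((~ok).sum())
    if n_masked:
        warnings.warn(f"{n_masked} bins with zero base coverage masked")
    return ratio


def _viterbi_duplicated(indicator: np.ndarray, params: HMMParams) -> np.ndarray:
    """Most-probable state path (True = duplicated) for one chromosome."""
    model = CategoricalHMM(n_components=2, init_params="")
    model.startprob_ = np.array([1.0 - params.start_dup, params.start_dup])
    model.transmat_ = np.array(
        [
            [1.0 - params.p_switch, params.p_switch],
            [params.p_switch, 1.0 - params.p_switch],
        ]
    )
    model.emissionprob_ = np.array(
        [
            [1.0 - params.p_emit_normal, params.p_emit_normal],
            [1.0 - params.p_emit_dup, params.p_emit_dup],
        ]
    )
    states = model.predict(indicator.reshape(-1, 1).astype(int))
    return states.astype(bool)


def call_duplications(
    base: CoverageProfile,
    evolved: CoverageProfile,
    threshold: float = 1.25,
    params: HMMParams | None = None,
    whole_chromosome_span: float = 0.95,
) -> list[DuplicationCall]:
    """Decode duplicated intervals from the normalized fold-coverage track.

    Bins at fold-coverage >= ``threshold`` are binarized and fed to the
    two-state HMM per chromosome; maximal runs of the duplicated state
    become calls.  Calls spanning at least ``whole_chromosome_span`` of
    their chromosome are labelled whole_chromosome, the rest segmental.
    """
    params = params or HMMParams()
    ratio = normalized_fold_coverage(base, evolved)
    calls: list[DuplicationCall] = []
    for chrom in dict.fromkeys(base.chrom):  # preserve order
        mask = base.chrom == chrom
        r = ratio[mask]
        ok = ~np.isnan(r)
        if not ok.any():
            warnings.warn(f"chromosome {chrom} fully masked; skipped")
            continue
        starts = base.start[mask]
        ends = base.end[mask]
        indicator = np.zeros(r.size, dtype=int)
        indicator[ok] = (r[ok] >= threshold).astype(int)
        dup = _viterbi_duplicated(indicator, params)
        chrom_len = int(ends.max())
        i = 0
        while i < dup.size:
            if dup[i]:
                j = i
                while j + 1 < dup.size and dup[j + 1]:
                    j += 1
                s, e = int(starts[i]), int(ends[j])
                span = (e - s + 1) / chrom_len
                kind = "whole_chromosome" if span >= whole_chromosome_span else "segmental"
                calls.append(
                    DuplicationCall(
                        chrom=str(chrom),
                        start=s,
                        end=e,
                        mean_fold_coverage=float(np.nanmean(r[i : j + 1])),
                        kind=kind,
                    )
                )
                i = j + 1
            else:
                i += 1
    return calls


# ---------------------------------------------------------------------------
# de novo SNVs

SNV_COLUMNS = ["chrom", "pos", "ref", "alt", "depth", "alt_frac",
               "population", "treatment"]


def filter_denovo_snvs(
    candidates: pd.DataFrame,
    founder_positions,
    base_positions,
    min_depth: int = 10,
    min_alt_frac: float = 0.20,
    max_treatments: int = 5,
) -> pd.DataFrame:
    """Apply the de novo SNV filters; annotate every record with its fate.

    A candidate passes iff its (chrom, pos) is absent from the founder
    panel and the base population, depth >= ``min_depth``, alt fraction
    >= ``min_alt_frac``, and the identical variant (chrom, pos, alt)
    does not recur in more than ``max_treatments`` distinct treatments.
    Returns a copy of ``candidates`` with boolean column ``passed`` and a
    string ``filter_flag`` naming the first failing filter ("PASS" for
    survivors); idempotent and order-invariant.
    """
    df = candidates.copy().reset_index(drop=True)
    founder_set = set(map(tuple, founder_positions))
    base_set = set(map(tuple, base_positions))
    keys = list(zip(df["chrom"], df["pos"]))
    in_founder = np.array([k in founder_set for k in keys])
    in_base = np.array([k in base_set for k in keys])
    low_depth = df["depth"].to_numpy() < min_depth
    low_frac = df["alt_frac"].to_numpy() < min_alt_frac

    # treatment recurrence of the exact variant, counted before other filters
    n_treat = (
        df.groupby(["chrom", "pos", "alt"])["treatment"]
        .transform("nunique")
        .to_numpy()
    )
    too_many = n_treat > max_treatments

    flag = np.full(len(df), "PASS", dtype=object)
    flag[too_many] = "recurrent_across_treatments"
    flag[low_frac] = "low_alt_fraction"
    flag[low_depth] = "low_depth"
    flag[in_base] = "in_base_population"
    flag[in_founder] = "founder_variant"
    df["filter_flag"] = flag
    df["passed"] = flag == "PASS"
    return df


def multihit_genes(
    snvs: pd.DataFrame, genes: pd.DataFrame
) -> pd.DataFrame:
    """Genes hit by SNVs in >= 2 distinct replicates of one treatment.

    ``snvs``: filtered records (rows with ``passed`` False are ignored
    if the column is present).  ``genes``: columns chrom, start, end,
    name with 1-based closed intervals.  Returns a DataFrame with
    columns treatment, gene, n_replicates, n_snvs.
    """
    if "passed" in snvs.columns:
        snvs = snvs[snvs["passed"]]
    trees: dict[str, IntervalTree] = {}
    for _, g in genes.iterrows():
        if g["end"] <= g["start"]:
            raise ValueError(f"degenerate gene interval {g['name']}")
        trees.setdefault(g["chrom"], IntervalTree()).addi(
            int(g["start"]), int(g["end"]) + 1, g["name"]
        )
    hits: dict[tuple[str, str], set] = {}
    counts: dict[tuple[str, str], int] = {}
    for _, row in snvs.iterrows():
        tree = trees.get(row["chrom"])
        if tree is None:
            continue
        for iv in tree[int(row["pos"])]:
            key = (row["treatment"], iv.data)
            hits.setdefault(key, set()).add(row["population"])
            counts[key] = counts.get(key, 0) + 1
    rows = [
        {
            "treatment": t,
            "gene": g,
            "n_replicates": len(reps),
            "n_snvs": counts[(t, g)],
        }
        for (t, g), reps in sorted(hits.items())
        if len(reps) >= 2
    ]
    return pd.DataFrame(rows, columns=["treatment", "gene", "n_replicates", "n_snvs"])
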