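"""Haplotype-frequency tables, synthetic-founder merging and the windowed
frequency estimator.

A :class:`HaplotypeFrequencyTable` holds, for one population, the vector of
founder (or merged "synthetic founder") frequencies at every locus of a
1 kb grid.  Founders that are locally indistinguishable — identical
genotype vectors over a window's SNPs — are merged into a synthetic
founder whose label concatenates the member names and whose frequency is
the sum of the members' frequencies.

The windowed estimator regresses observed pooled SNP frequencies on the
merged founder genotype matrix under non-negativity and sum-to-one
constraints.  It is a deliberately simple constrained least-squares
stand-in with the same contract as a full sliding-window haplotype
caller: output is always a probability vector and its accuracy improves
with coverage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import nnls

__all__ = [
    "HaplotypeFrequencyTable",
    "SyntheticFounderMap",
    "ValidationError",
    "read_table",
    "write_table",
    "parse_merged_label",
    "collapse_indistinguishable",
    "estimate_window_frequencies",
    "estimate_genome_frequencies",
]

SUM_TOL = 0.01  # per-locus sum-to-one tolerance for tables on disk

TABLE_COLUMNS = ["chrom", "pos", "population", "haplotype", "freq"]


class ValidationError(ValueError):
    """A table violates one of its invariants."""


@dataclass
class HaplotypeFrequencyTable:
    """Founder-haplotype frequencies for one population on a locus grid.

    ``freqs`` is an (n_loci, n_labels) matrix; each row sums to one.
    Merged synthetic founders appear as concatenated labels (e.g.
    ``"A11A12"``) whose frequency is the sum of the members'.
    """

    population: str
    chrom: np.ndarray  # (n_loci,) chromosome name per locus
    pos: np.ndarray  # (n_loci,) 1-based position
    labels: tuple[str, ...]
    freqs: np.ndarray  # (n_loci, n_labels)

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.freqs.shape != (self.pos.size, len(self.labels)):
            raise ValidationError("freqs shape does not match loci x labels")

    @property
    def n_loci(self) -> int:
        return self.pos.size

    def validate(self, tol: float = SUM_TOL) -> None:
        if np.any(self.freqs < -1e-12) or np.any(self.freqs > 1 + 1e-12):
            raise ValidationError(
                f"population {self.population}: frequencies outside [0, 1]"
            )
        sums = self.freqs.sum(axis=1)
        bad = np.flatnonzero(np.abs(sums - 1.0) > tol)
        if bad.size:
            i = int(bad[0])
            raise ValidationError(
                f"population {self.population}: frequencies at "
                f"{self.chrom[i]}:{self.pos[i]} sum to {sums[i]:.4f}, "
                f"outside 1 +/- {tol}"
            )

    def copy(self) -> "HaplotypeFrequencyTable":
        return replace(
            self,
            chrom=self.chrom.copy(),
            pos=self.pos.copy(),
            freqs=self.freqs.copy(),
        )

    def same_grid(self, other: "HaplotypeFrequencyTable") -> bool:
        return (
            self.pos.size == other.pos.size
            and bool(np.all(self.pos == other.pos))
            and bool(np.all(self.chrom == other.chrom))
        )

    def to_frame(self, drop_zero: bool = False) -> pd.DataFrame:
        n, k = self.freqs.shape
        df = pd.DataFrame(
            {
                "chrom": np.repeat(self.chrom, k),
                "pos": np.repeat(self.pos, k),
                "population": self.population,
                "haplotype": np.tile(np.asarray(self.labels, dtype=object), n),
                "freq": self.freqs.ravel(),
            }
        )
        if drop_zero:
            df = df[df["freq"] > 0.0].reset_index(drop=True)
        return df


def _tables_from_frame(df: pd.DataFrame) -> list[HaplotypeFrequencyTable]:
    tables = []
    for pop, sub in df.groupby("population", sort=False):
        wide = sub.pivot_table(
            index=["chrom", "pos"],
            columns="haplotype",
            values="freq",
            fill_value=0.0,
            sort=False,
        )
        wide = wide.sort_index(level=["chrom", "pos"])
        chrom = wide.index.get_level_values("chrom").to_numpy(dtype=object)
        pos = wide.index.get_level_values("pos").to_numpy(dtype=np.int64)
        table = HaplotypeFrequencyTable(
            population=str(pop),
            chrom=chrom,
            pos=pos,
            labels=tuple(str(c) for c in wide.columns),
            freqs=wide.to_numpy(dtype=float),
        )
        tables.append(table)
    return tables


def read_table(path) -> list[HaplotypeFrequencyTable]:
    """Read a haplotype-frequency TSV; one table per population found.

    Format: ``#``-prefixed header line then tab-separated columns
    chrom, pos, population, haplotype, freq.  Every table is validated on
    read (frequencies in [0, 1], per-locus sums within 0.01 of 1).
    """
    with open(path, "rt", encoding="utf-8") as fh:
        header = fh.readline()
        if not header.startswith("#"):
            raise ValidationError(f"{path}: missing '#'-prefixed header line")
        cols = header.lstrip("#").strip().split("\t")
        if cols != TABLE_COLUMNS:
            raise ValidationError(
                f"{path}: header {cols} does not match schema {TABLE_COLUMNS}"
            )
        rows = []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 5:
                raise ValidationError(
                    f"{path}:{lineno}: expected 5 tab-separated fields, "
                    f"got {len(parts)}"
                )
            try:
                rows.append(
                    (parts[0], int(parts[1]), parts[2], parts[3], float(parts[4]))
                )
            except ValueError as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from None
    df = pd.DataFrame(rows, columns=TABLE_COLUMNS)
    tables = _tables_from_frame(df)
    for t in tables:
        t.validate()
    return tables


def write_table(tables, path, drop_zero: bool = False, header_extra=()) -> None:
    """Write one table or an iterable of tables as a TSV (see read_table)."""
    if isinstance(tables, HaplotypeFrequencyTable):
        tables = [tables]
    with open(path, "wt", encoding="utf-8") as fh:
        for line in header_extra:
            fh.write(f"#{line}\n")
        fh.write("#" + "\t".join(TABLE_COLUMNS) + "\n")
        for table in tables:
            table.validate()
            df = table.to_frame(drop_zero=drop_zero)
            df.to_csv(fh, sep="\t", header=False, index=False)


def parse_merged_label(label: str, founders) -> frozenset:
    """Split a (possibly merged) haplotype label into its member founders.

    ``"A11A12"`` with founders containing A11 and A12 parses to
    ``{"A11", "A12"}``.  Member names are matched greedily, longest
    first, so founder names that are prefixes of one another are handled.
    """
    names = sorted(founders, key=len, reverse=True)
    members = []
    rest = label
    while rest:
        for name in names:
            if rest.startswith(name):
                members.append(name)
                rest = rest[len(name):]
                break
        else:
            raise ValueError(
                f"label {label!r} cannot be split into founder names"
            )
    return frozenset(members)


# ---------------------------------------------------------------------------
# synthetic-founder merging


@dataclass(frozen=True)
class SyntheticFounderMap:
    """Partition of the founder set into locally indistinguishable groups.

    Each group is an ordered tuple of founder labels; the merged label is
    the concatenation of the member names in founder-panel order.
    Singleton groups keep the original label.
    """

    groups: tuple[tuple[str, ...], ...]

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple("".join(g) for g in self.groups)

    def merge_frequencies(self, founder_freqs: np.ndarray, founder_labels) -> np.ndarray:
        """Sum per-founder frequencies within each group."""
        index = {name: i for i, name in enumerate(founder_labels)}
        out = np.empty(len(self.groups), dtype=float)
        for j, group in enumerate(self.groups):
            out[j] = sum(founder_freqs[index[name]] for name in group)
        return out


def collapse_indistinguishable(panel, window: tuple[str, int, int]) -> SyntheticFounderMap:
    """Group founders with identical genotypes over the SNPs in ``window``.

    ``window`` is (chrom, start, end), closed 1-based.  With zero SNPs in
    the window no founder can be told apart, so all founders merge into a
    single group.
    """
    chrom, start, end = window
    mask = (panel.chrom == chrom) & (panel.pos >= start) & (panel.pos <= end)
    sub = panel.genotypes[mask]  # (n_snps_in_window, n_founders)
    order = {name: i for i, name in enumerate(panel.labels)}
    seen: dict[bytes, list[str]] = {}
    for i, name in enumerate(panel.labels):
        key = sub[:, i].tobytes()
        seen.setdefault(key, []).append(name)
    groups = sorted(
        (tuple(g) for g in seen.values()), key=lambda g: order[g[0]]
    )
    return SyntheticFounderMap(groups=tuple(groups))


# ---------------------------------------------------------------------------
# windowed constrained least-squares estimator


def _constrained_lsq(G: np.ndarray, y: np.ndarray, sum_weight: float = 100.0) -> np.ndarray:
    """min ||Gx - y||^2 s.t. x >= 0, sum(x) = 1.

    The equality constraint is imposed by augmenting the system with a
    heavily weighted row of ones, then renormalizing the NNLS solution;
    for consistent systems the solution is exact.
    """
    n_founders = G.shape[1]
    A = np.vstack([G, np.full((1, n_founders), sum_weight)])
    b = np.concatenate([y, [sum_weight]])
    x, _ = nnls(A, b)
    total = x.sum()
    if total <= 0:
        return np.full(n_founders, 1.0 / n_founders)
    return x / total


def estimate_window_frequencies(
    snp_freqs: np.ndarray,
    panel,
    window: tuple[str, int, int],
    fmap: SyntheticFounderMap | None = None,
) -> tuple[np.ndarray, SyntheticFounderMap]:
    """Estimate synthetic-founder frequencies in one window.

    Parameters
    ----------
    snp_freqs:
        Observed pooled allele frequencies for the SNPs inside ``window``,
        in panel order.
    panel:
        FounderPanel providing the genotype matrix.
    window:
        (chrom, start, end), closed 1-based.
    fmap:
        Precomputed synthetic-founder map for this window; computed from
        the panel if omitted.

    Returns
    -------
    (freqs, fmap):
        Frequency vector over the map's merged labels (non-negative,
        sums to 1) and the map used.
    """
    chrom, start, end = window
    mask = (panel.chrom == chrom) & (panel.pos >= start) & (panel.pos <= end)
    G_full = panel.genotypes[mask].astype(float)
    y = np.asarray(snp_freqs, dtype=float)
    if G_full.shape[0] == 0:
        raise ValueError(f"no SNPs in window {chrom}:{start}-{end}")
    if y.shape[0] != G_full.shape[0]:
        raise ValueError(
            f"{y.shape[0]} observed frequencies for {G_full.shape[0]} SNPs "
            f"in window {chrom}:{start}-{end}"
        )
    if fmap is None:
        fmap = collapse_indistinguishable(panel, window)
    index = {name: i for i, name in enumerate(panel.labels)}
    # one column per merged group (columns of members are identical)
    cols = [index[group[0]] for group in fmap.groups]
    G = G_full[:, cols]
    if len(cols) > 1 and np.linalg.matrix_rank(G) < len(cols):
        warnings.warn(
            f"window {chrom}:{start}-{end}: merged genotype matrix is "
            "rank-deficient; estimates for dependent founders are not "
            "separately identifiable",
            stacklevel=2,
        )
    x = _constrained_lsq(G, y)
    return x, fmap


def estimate_genome_frequencies(
    snp_table: pd.DataFrame,
    panel,
    grid,
    population: str = "pool",
) -> HaplotypeFrequencyTable:
    """Sliding-window haplotype-frequency estimation over a whole grid.

    ``snp_table`` needs columns chrom, pos, freq (observed pooled allele
    frequencies at panel SNP positions).  At each grid locus the centered
    window's SNPs are regressed on the merged founder matrix; merged
    frequencies are then shared equally among group members so that every
    output table has the full founder label set (downstream scans re-merge
    as needed).  Loci whose window holds no SNPs are skipped with a
    warning.
    """
    obs = {
        (c, int(p)): float(f)
        for c, p, f in zip(snp_table["chrom"], snp_table["pos"], snp_table["freq"])
    }
    chroms_out, pos_out, rows = [], [], []
    n_founders = len(panel.labels)
    index = {name: i for i, name in enumerate(panel.labels)}
    for chrom in grid.chromosomes:
        for pos in grid.loci(chrom):
            start, end = grid.window_of(chrom, int(pos))
            mask = (panel.chrom == chrom) & (panel.pos >= start) & (panel.pos <= end)
            snp_pos = panel.pos[mask]
            if snp_pos.size == 0:
                warnings.warn(f"no SNP data in window at {chrom}:{pos}; skipped")
                continue
            y = np.array([obs.get((chrom, int(p)), np.nan) for p in snp_pos])
            keep = ~np.isnan(y)
            if not keep.any():
                warnings.warn(f"no SNP data in window at {chrom}:{pos}; skipped")
                continue
            sub_window = (chrom, start, end)
            fmap = collapse_indistinguishable(panel, sub_window)
            x, _ = estimate_window_frequencies(
                np.where(keep, y, 0.0), panel, sub_window, fmap=fmap
            )
            row = np.zeros(n_founders)
            for j, group in enumerate(fmap.groups):
                share = x[j] / len(group)
                for name in group:
                    row[index[name]] = share
            chroms_out.append(chrom)
            pos_out.append(int(pos))
            rows.append(row)
    return HaplotypeFrequencyTable(
        population=population,
        chrom=np.asarray(chroms_out, dtype=object),
        pos=np.asarray(pos_out, dtype=np.int64),
        labels=tuple(panel.labels),
        freqs=np.asarray(rows, dtype=float),
    )
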