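"""Synthetic data with the statistical structure the pipeline assumes.

This module emulates a multiparent evolve-and-resequence design: an
outbred base population founded by 18 sequenced strains, evolved in
replicate at large effective size under weekly cycles of mitotic growth
(under selection) punctuated by forced sex.  It generates every input
the downstream stages consume — founder genotype panels, base and
evolved haplotype-frequency tables, cheater populations, coverage
tracks with planted duplications, and pooled SNP frequencies — together
with the ground truth needed for parameter-recovery tests.

Selection model
---------------
At a selected locus the favored founder haplotype follows the
deterministic haploid-selection recursion per sexual cycle of ``G``
mitotic generations,

    p' = p (1+s)^G / (p (1+s)^G + (1 - p)),

with the remaining haplotypes rescaled proportionally.  Linked neutral
loci are dragged along (draft) with an effective coefficient decaying as
``s * exp(-d_kb * r_kb)`` where ``d_kb`` is map distance in kb and
``r_kb`` the per-kb recombination probability per sexual cycle.
Multinomial drift at the effective population size is applied per locus
after each cycle; an infinite-Ne neutral run is exactly
frequency-preserving.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np

from .grid import GenomeGrid
from .structural import CoverageProfile
from .tables import HaplotypeFrequencyTable

__all__ = [
    "FounderPanel",
    "SimulationConfig",
    "SimulatedTruth",
    "default_founder_labels",
    "simulate_founder_panel",
    "simulate_evolution",
    "add_measurement_noise",
    "simulate_cheater",
    "simulate_coverage",
    "simulate_pool_reads",
]


def default_founder_labels(n: int) -> tuple[str, ...]:
    return tuple(f"A{i + 1}" for i in range(n))


@dataclass
class FounderPanel:
    """Biallelic SNP x founder genotype matrix with private-SNP flags."""

    labels: tuple[str, ...]
    chrom: np.ndarray  # (n_snps,)
    pos: np.ndarray  # (n_snps,) 1-based
    genotypes: np.ndarray  # (n_snps, n_founders) values 0/1

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.genotypes = np.asarray(self.genotypes, dtype=np.uint8)
        counts = self.genotypes.sum(axis=1)
        if np.any(counts == 0) or np.any(counts == len(self.labels)):
            raise ValueError("panel contains non-segregating SNPs")

    @property
    def n_snps(self) -> int:
        return self.pos.size

    @property
    def private(self) -> np.ndarray:
        """True where the minor allele occurs in exactly one founder."""
        counts = self.genotypes.sum(axis=1)
        n = len(self.labels)
        return (counts == 1) | (counts == n - 1)

    def write_tsv(self, path) -> None:
        with open(path, "wt", encoding="utf-8") as fh:
            fh.write("#chrom\tpos\t" + "\t".join(self.labels) + "\n")
            for i in range(self.n_snps):
                row = "\t".join(str(int(g)) for g in self.genotypes[i])
                fh.write(f"{self.chrom[i]}\t{self.pos[i]}\t{row}\n")

    @classmethod
    def read_tsv(cls, path) -> "FounderPanel":
        with open(path, "rt", encoding="utf-8") as fh:
            header = fh.readline().lstrip("#").strip().split("\t")
            labels = tuple(header[2:])
            chrom, pos, rows = [], [], []
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                chrom.append(parts[0])
                pos.append(int(parts[1]))
                rows.append([int(x) for x in parts[2:]])
        return cls(labels, np.array(chrom, dtype=object),
                   np.array(pos), np.array(rows, dtype=np.uint8))


@dataclass
class SimulationConfig:
    """Generative-model parameters for one evolved treatment.

    Defaults match the experimental design being emulated: Ne close to
    750,000; 12 weekly sexual cycles of ~18 mitotic generations each
    (216 selective generations); haplotype-estimate errors of 0.004 in
    the deeply sequenced base and 0.01 in evolved populations; ~0.0075
    recombination events per kb per meiosis (90 crossovers over a 12 Mb
    genome).
    """

    ne: float = 750_000.0  # np.inf disables drift
    gens_per_cycle: int = 18
    n_cycles: int = 12
    selected_loci: tuple = ()  # ((chrom, pos), ...)
    selection_coefficients: tuple = ()  # s per selected locus, per mitotic gen
    target_haplotypes: tuple = ()  # favored founder label per selected locus
    r_per_kb_per_cycle: float = 0.0075
    eps_base: float = 0.004
    eps_evolved: float = 0.01
    n_replicates: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s < 0 for s in self.selection_coefficients):
            raise ValueError("selection coefficients must be >= 0")
        if self.eps_base < 0 or self.eps_evolved < 0:
            raise ValueError("error sigmas must be >= 0")
        if not (
            len(self.selected_loci)
            == len(self.selection_coefficients)
            == len(self.target_haplotypes)
        ):
            raise ValueError("selected loci, s and targets must be parallel")


@dataclass
class SimulatedTruth:
    """Ground truth of a simulation run, for parameter-recovery tests."""

    selected_loci: tuple = ()
    target_haplotypes: tuple = ()
    selection_coefficients: tuple = ()
    # per selected locus: target-haplotype frequency after each cycle,
    # expected (drift-free) trajectory
    expected_trajectories: tuple = ()
    duplications: tuple = ()  # ((chrom, start, end, extra_copies), ...)
    snvs: tuple = ()  # ((chrom, pos, true_frequency), ...)
    population_classes: tuple = ()  # (replicate, class) pairs

    def to_json(self, path) -> None:
        with open(path, "wt", encoding="utf-8") as fh:
            json.dump(asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "SimulatedTruth":
        with open(path, "rt", encoding="utf-8") as fh:
            raw = json.load(fh)

        def detuple(x):
            return tuple(detuple(v) for v in x) if isinstance(x, list) else x

        return cls(**{k: detuple(v) for k, v in raw.items()})


def _child_rng(seed: int, *key: int) -> np.random.Generator:
    # one master seed; fixed spawn keys give independent per-operation streams
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


# ---------------------------------------------------------------------------
# founder panel and base population


def simulate_founder_panel(
    grid: GenomeGrid,
    n_founders: int = 18,
    snp_density: float = 5.0,
    private_fraction: float = 0.3,
    twin_fraction: float = 0.1,
    base_concentration: float = 20.0,
    seed: int = 0,
) -> tuple[FounderPanel, HaplotypeFrequencyTable]:
    """Segregating founder panel plus near-uniform base haplotype table.

    Parameters
    ----------
    snp_density:
        SNPs per kb.
    private_fraction:
        Fraction of SNPs whose minor allele is carried by exactly one
        founder; the rest are shared by 2..n-1 founders.
    twin_fraction:
        Approximate fraction of windows in which one founder's genotypes
        are copied from another, producing locally indistinguishable
        pairs (exercises synthetic-founder merging).
    base_concentration:
        Dirichlet concentration per founder for the base frequencies;
        larger values are closer to uniform.
    """
    if n_founders < 2:
        raise ValueError("need at least 2 founders")
    if snp_density <= 0:
        raise ValueError("snp_density must be positive")
    rng = _child_rng(seed, 1)
    labels = default_founder_labels(n_founders)

    chroms, positions, genos = [], [], []
    for chrom in grid.chromosomes:
        length = grid.length_of(chrom)
        n_snps = max(1, int(round(snp_density * length / 1000.0)))
        pos = np.sort(rng.choice(length, size=min(n_snps, length), replace=False)) + 1
        g = np.zeros((pos.size, n_founders), dtype=np.uint8)
        is_private = rng.random(pos.size) < private_fraction
        for i in range(pos.size):
            if is_private[i]:
                g[i, rng.integers(n_founders)] = 1
            else:
                carriers = rng.integers(2, n_founders)
                idx = rng.choice(n_founders, size=carriers, replace=False)
                g[i, idx] = 1
        chroms.append(np.full(pos.size, chrom, dtype=object))
        positions.append(pos)
        genos.append(g)
    chrom_arr = np.concatenate(chroms)
    pos_arr = np.concatenate(positions)
    geno = np.concatenate(genos, axis=0)

    # plant one locally indistinguishable founder pair per chromosome over a
    # tract long enough that ~twin_fraction of windows see identical columns
    if twin_fraction > 0:
        for chrom in grid.chromosomes:
            loci = grid.loci(chrom)
            span = int(round(twin_fraction * loci.size))
            if span == 0 or loci.size == 0:
                continue
            first = int(rng.integers(0, max(1, loci.size - span)))
            start = int(loci[first]) - grid.window // 2
            end = int(loci[min(first + span, loci.size - 1)]) + grid.window // 2
            a, b = rng.choice(n_founders, size=2, replace=False)
            mask = (chrom_arr == chrom) & (pos_arr >= start) & (pos_arr <= end)
            geno[mask, b] = geno[mask, a]

    # drop SNPs made non-segregating by twin copying
    counts = geno.sum(axis=1)
    keep = (counts > 0) & (counts < n_founders)
    panel = FounderPanel(labels, chrom_arr[keep], pos_arr[keep], geno[keep])

    gchrom, gpos = grid.all_loci()
    alpha = np.full(n_founders, base_concentration)
    freqs = rng.dirichlet(alpha, size=gpos.size)
    base = HaplotypeFrequencyTable(
        population="base",
        chrom=gchrom,
        pos=gpos,
        labels=labels,
        freqs=freqs,
    )
    return panel, base


# ---------------------------------------------------------------------------
# forward evolution


def _selection_response(
    base: HaplotypeFrequencyTable, cfg: SimulationConfig
) -> list[tuple[int, float, np.ndarray]]:
    """Per selected locus: (target column, s, per-locus map distance in kb).

    Draft: the selective drag felt at a linked locus decays with the
    recombination accumulated since the sweep began, so in cycle c (1-based)
    the effective coefficient at map distance d_kb is
    s * exp(-d_kb * r_per_kb_per_cycle * c); unlinked chromosomes feel
    nothing (distance infinite).
    """
    out = []
    label_index = {name: i for i, name in enumerate(base.labels)}
    for (chrom, pos), s, target in zip(
        cfg.selected_loci, cfg.selection_coefficients, cfg.target_haplotypes
    ):
        if target not in label_index:
            raise ValueError(f"target haplotype {target!r} not in base table")
        on_chrom = base.chrom == chrom
        if not np.any(on_chrom & (base.pos == pos)):
            raise ValueError(f"selected locus {chrom}:{pos} not on the grid")
        d_kb = np.where(on_chrom, np.abs(base.pos - pos) / 1000.0, np.inf)
        out.append((label_index[target], float(s), d_kb))
    return out


def expected_selected_frequency(p0: float, s: float, generations: int) -> float:
    """Drift-free closed form of the haploid-selection recursion."""
    a = (1.0 + s) ** generations
    return p0 * a / (p0 * a + (1.0 - p0))


def simulate_evolution(
    base: HaplotypeFrequencyTable, cfg: SimulationConfig
) -> tuple[list[HaplotypeFrequencyTable], SimulatedTruth]:
    """Evolve ``cfg.n_replicates`` populations forward from ``base``.

    Returns the true (noise-free) evolved haplotype-frequency tables and
    the planted ground truth.  Measurement noise is added separately via
    :func:`add_measurement_noise`.
    """
    responses = _selection_response(base, cfg)
    # skip selected loci whose target starts at frequency zero
    active: list[tuple[int, float, np.ndarray]] = []
    kept_idx: list[int] = []
    for j, (col, s, d_kb) in enumerate(responses):
        chrom, pos = cfg.selected_loci[j]
        at = np.flatnonzero((base.chrom == chrom) & (base.pos == pos))[0]
        if base.freqs[at, col] <= 0.0:
            warnings.warn(
                f"target {cfg.target_haplotypes[j]} absent at selected locus "
                f"{chrom}:{pos}; locus skipped"
            )
            continue
        active.append((col, s, d_kb))
        kept_idx.append(j)

    drift = np.isfinite(cfg.ne)
    ne = int(cfg.ne) if drift else 0

    replicates = []
    for r in range(cfg.n_replicates):
        rng = _child_rng(cfg.seed, 2, r)
        freqs = base.freqs.copy()
        for cycle in range(1, cfg.n_cycles + 1):
            for col, s, d_kb in active:
                with np.errstate(over="ignore"):
                    decay = np.exp(-d_kb * cfg.r_per_kb_per_cycle * cycle)
                growth = (1.0 + s * decay) ** cfg.gens_per_cycle
                p = freqs[:, col]
                w = p * growth + (1.0 - p)
                p_new = p * growth / w
                scale = np.ones_like(p)
                nonfixed = p < 1.0
                scale[nonfixed] = (1.0 - p_new[nonfixed]) / (1.0 - p[nonfixed])
                freqs *= scale[:, None]
                freqs[:, col] = p_new
            if drift:
                rows = freqs / freqs.sum(axis=1, keepdims=True)
                freqs = rng.multinomial(ne, rows).astype(float) / ne
        freqs /= freqs.sum(axis=1, keepdims=True)
        replicates.append(
            HaplotypeFrequencyTable(
                population=f"rep{r + 1}",
                chrom=base.chrom.copy(),
                pos=base.pos.copy(),
                labels=base.labels,
                freqs=freqs,
            )
        )

    trajectories = []
    label_index = {name: i for i, name in enumerate(base.labels)}
    for j in kept_idx:
        chrom, pos = cfg.selected_loci[j]
        at = np.flatnonzero((base.chrom == chrom) & (base.pos == pos))[0]
        p0 = float(base.freqs[at, label_index[cfg.target_haplotypes[j]]])
        traj = tuple(
            expected_selected_frequency(
                p0, cfg.selection_coefficients[j], cfg.gens_per_cycle * c
            )
            for c in range(1, cfg.n_cycles + 1)
        )
        trajectories.append(traj)
    truth = SimulatedTruth(
        selected_loci=tuple(cfg.selected_loci[j] for j in kept_idx),
        target_haplotypes=tuple(cfg.target_haplotypes[j] for j in kept_idx),
        selection_coefficients=tuple(cfg.selection_coefficients[j] for j in kept_idx),
        expected_trajectories=tuple(trajectories),
        population_classes=tuple(
            (t.population, "outbred_sexual") for t in replicates
        ),
    )
    return replicates, truth


def add_measurement_noise(
    table: HaplotypeFrequencyTable, sigma: float, seed: int = 0
) -> HaplotypeFrequencyTable:
    """Gaussian haplotype-estimation noise on the raw frequency scale.

    Independent N(0, sigma) per entry, clipped to [0, 1] and renormalized
    per locus.  sigma = 0 is the identity.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    out = table.copy()
    if sigma == 0:
        return out
    rng = _child_rng(seed, 3)
    noisy = np.clip(out.freqs + rng.normal(0.0, sigma, out.freqs.shape), 0.0, 1.0)
    sums = noisy.sum(axis=1, keepdims=True)
    sums[sums == 0] = 1.0
    out.freqs = noisy / sums
    return out


# ---------------------------------------------------------------------------
# cheater populations


def _recombinant_mosaic(
    table: HaplotypeFrequencyTable, rng: np.random.Generator,
    junction_rate_per_kb: float,
) -> np.ndarray:
    """Founder index per locus of a random recombinant haploid genome."""
    n_founders = len(table.labels)
    out = np.empty(table.n_loci, dtype=np.int64)
    for chrom in np.unique(table.chrom):
        idx = np.flatnonzero(table.chrom == chrom)
        pos = table.pos[idx]
        span_kb = (pos[-1] - pos[0]) / 1000.0 if pos.size > 1 else 0.0
        n_junctions = rng.poisson(junction_rate_per_kb * span_kb)
        cuts = np.sort(rng.choice(pos.size, size=min(n_junctions, pos.size - 1),
                                  replace=False)) if pos.size > 1 else np.empty(0, int)
        segments = np.split(np.arange(pos.size), cuts) if cuts.size else [np.arange(pos.size)]
        for seg in segments:
            out[idx[seg]] = rng.integers(n_founders)
    return out


def simulate_cheater(
    base: HaplotypeFrequencyTable,
    kind: str,
    seed: int = 0,
    mating_type_window: tuple[str, int, int] | None = None,
    junction_rate_per_kb: float = 0.02,
    relatedness: float = 0.35,
    population: str | None = None,
) -> HaplotypeFrequencyTable:
    """A population swept by a single asexual clone.

    ``aneuploid_haploid``: one recombinant haploid mosaic fixed
    genome-wide (heterozygosity 0), except the mating-type window where
    two haplotypes sit at 0.5 each.  ``clonal_diploid``: a single
    heterozygous recombinant diploid clone — per locus either one
    haplotype at 1.0 (where its two genomes share a founder) or two at
    0.5/0.5.  ``relatedness`` is the per-segment probability that the
    second genome copies the first, which sets the homozygous fraction;
    genomes drawn from a 12-generation intercross share substantial
    ancestry, so both heterozygosity modes (0 and 0.5) are well
    populated.
    """
    if base.n_loci == 0:
        raise ValueError("base table is empty")
    if kind not in ("aneuploid_haploid", "clonal_diploid"):
        raise ValueError(f"unknown cheater kind {kind!r}")
    rng = _child_rng(seed, 4)
    n_founders = len(base.labels)
    freqs = np.zeros_like(base.freqs)
    mosaic_a = _recombinant_mosaic(base, rng, junction_rate_per_kb)

    if kind == "aneuploid_haploid":
        freqs[np.arange(base.n_loci), mosaic_a] = 1.0
        if mating_type_window is None:
            chrom = base.chrom[0]
            pos_on = base.pos[base.chrom == chrom]
            center = int(pos_on[pos_on.size // 2])
            mating_type_window = (chrom, center - 5_000, center + 5_000)
        mchrom, mstart, mend = mating_type_window
        mt = (base.chrom == mchrom) & (base.pos >= mstart) & (base.pos <= mend)
        other = (mosaic_a[mt] + 1 + rng.integers(n_founders - 1)) % n_founders
        freqs[mt] = 0.0
        freqs[np.flatnonzero(mt), mosaic_a[mt]] = 0.5
        freqs[np.flatnonzero(mt), other] = 0.5
    else:
        mosaic_b = _recombinant_mosaic(base, rng, junction_rate_per_kb)
        # re-link a fraction of the second genome's segments to the first
        share = rng.random(base.n_loci) < relatedness
        # apply sharing segment-wise so tracts stay contiguous
        seg_id = np.cumsum(np.concatenate([[0], (mosaic_b[1:] != mosaic_b[:-1]).astype(int)]))
        for s in np.unique(seg_id):
            members = np.flatnonzero(seg_id == s)
            if share[members[0]]:
                mosaic_b[members] = mosaic_a[members]
        rows = np.arange(base.n_loci)
        same = mosaic_a == mosaic_b
        freqs[rows[same], mosaic_a[same]] = 1.0
        freqs[rows[~same], mosaic_a[~same]] = 0.5
        freqs[rows[~same], mosaic_b[~same]] = 0.5

    return HaplotypeFrequencyTable(
        population=population or f"{kind}_clone",
        chrom=base.chrom.copy(),
        pos=base.pos.copy(),
        labels=base.labels,
        freqs=freqs,
    )


# ---------------------------------------------------------------------------
# coverage and pooled reads


def simulate_coverage(
    grid: GenomeGrid,
    duplications,
    mean_cov: float = 50.0,
    seed: int = 0,
) -> tuple[CoverageProfile, CoverageProfile]:
    """Poisson bin coverage for a base and an evolved population.

    ``duplications``: iterable of ((chrom, start, end), extra_copies);
    evolved bins inside a duplication with ``g`` extra copies on a
    diploid baseline have expectation scaled by (2+g)/2 (proportionally
    for partially overlapping bins).
    """
    if mean_cov <= 0:
        raise ValueError("mean_cov must be positive")
    dups = [((c, int(s), int(e)), int(g)) for (c, s, e), g in duplications]
    by_chrom: dict[str, list[tuple[int, int, int]]] = {}
    for (c, s, e), g in dups:
        if c not in grid.chromosomes:
            raise ValueError(f"duplication chromosome {c!r} not in grid")
        if not (1 <= s < e <= grid.length_of(c)):
            raise ValueError(f"duplication {c}:{s}-{e} outside chromosome")
        by_chrom.setdefault(c, []).append((s, e, g))
    for c, ivs in by_chrom.items():
        ivs.sort()
        for (s1, e1, _), (s2, _, _) in zip(ivs, ivs[1:]):
            if s2 <= e1:
                raise ValueError(f"overlapping duplications on {c}")

    rng = _child_rng(seed, 5)
    chroms, starts, ends, base_cov, evo_cov = [], [], [], [], []
    for chrom in grid.chromosomes:
        bs, be = grid.bins(chrom)
        frac = (be - bs + 1) / grid.bin_size
        lam_base = mean_cov * frac
        scale = np.ones(bs.size)
        for s, e, g in by_chrom.get(chrom, []):
            overlap = np.maximum(
                0, np.minimum(be, e) - np.maximum(bs, s) + 1
            ) / (be - bs + 1)
            scale += overlap * (g / 2.0)
        base_cov.append(rng.poisson(lam_base))
        evo_cov.append(rng.poisson(lam_base * scale))
        chroms.append(np.full(bs.size, chrom, dtype=object))
        starts.append(bs)
        ends.append(be)
    chrom_arr = np.concatenate(chroms)
    start_arr = np.concatenate(starts)
    end_arr = np.concatenate(ends)
    base = CoverageProfile(chrom_arr, start_arr, end_arr,
                           np.concatenate(base_cov).astype(float))
    evolved = CoverageProfile(chrom_arr.copy(), start_arr.copy(), end_arr.copy(),
                              np.concatenate(evo_cov).astype(float))
    return base, evolved


def simulate_pool_reads(
    table: HaplotypeFrequencyTable,
    panel: FounderPanel,
    coverage: int,
    seed: int = 0,
    window: int = 60_000,
):
    """Pooled sequencing of the population described by ``table``.

    Per SNP the true allele frequency is the genotype-weighted sum of
    the local haplotype frequencies (nearest grid locus); the observed
    count is Binomial(coverage, truth).  Returns a DataFrame with
    columns chrom, pos, freq, depth, count.  SNPs farther than half a
    window from any grid locus are skipped with a warning.
    """
    import pandas as pd

    if coverage <= 0:
        raise ValueError("coverage must be positive")
    rng = _child_rng(seed, 6)
    half = window // 2
    chroms, positions, truths = [], [], []
    n_skipped = 0
    for chrom in np.unique(panel.chrom):
        snp_mask = panel.chrom == chrom
        snp_pos = panel.pos[snp_mask]
        geno = panel.genotypes[snp_mask].astype(float)
        loc_mask = table.chrom == chrom
        loc_pos = table.pos[loc_mask]
        if loc_pos.size == 0:
            n_skipped += snp_pos.size
            continue
        nearest = np.clip(np.searchsorted(loc_pos, snp_pos), 0, loc_pos.size - 1)
        left = np.clip(nearest - 1, 0, loc_pos.size - 1)
        use_left = np.abs(loc_pos[left] - snp_pos) < np.abs(loc_pos[nearest] - snp_pos)
        nearest = np.where(use_left, left, nearest)
        in_reach = np.abs(loc_pos[nearest] - snp_pos) <= half
        n_skipped += int((~in_reach).sum())
        hap = table.freqs[loc_mask][nearest[in_reach]]
        truth = np.clip((geno[in_reach] * hap).sum(axis=1), 0.0, 1.0)
        chroms.append(np.full(truth.size, chrom, dtype=object))
        positions.append(snp_pos[in_reach])
        truths.append(truth)
    if n_skipped:
        warnings.warn(f"{n_skipped} SNPs outside any grid window; skipped")
    chrom_arr = np.concatenate(chroms) if chroms else np.empty(0, dtype=object)
    pos_arr = np.concatenate(positions) if positions else np.empty(0, dtype=np.int64)
    truth_arr = np.concatenate(truths) if truths else np.empty(0)
    counts = rng.binomial(coverage, truth_arr)
    return pd.DataFrame(
        {
            "chrom": chrom_arr,
            "pos": pos_arr,
            "freq": counts / coverage,
            "depth": coverage,
            "count": counts,
        }
    )
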