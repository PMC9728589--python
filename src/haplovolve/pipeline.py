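"""End-to-end orchestration: simulate or load inputs, classify, filter,
scan, call peaks, summarise haplotype dynamics, detect CNVs and de novo
SNVs, and export analysis-ready tables.

Every output file carries a provenance header (config hash, seed,
package version); re-running with the same config and seed reproduces
all outputs byte-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classify import (
    OUTBRED_SEXUAL,
    classification_report,
    classify_population,
    cladogram_filter,
    select_sexual_treatments,
)
from .dynamics import (
    mih_deviation,
    mih_summary,
    mih_table,
    pleiotropy_screen,
    replicate_spearman,
    split_half_lod_correlation,
)
from .grid import GenomeGrid, default_toy_grid
from .scan import call_peaks, chi_square_scan, significance_fraction
from .simulate import (
    SimulationConfig,
    add_measurement_noise,
    simulate_cheater,
    simulate_coverage,
    simulate_evolution,
    simulate_founder_panel,
)
from .structural import call_duplications, filter_denovo_snvs
from .tables import HaplotypeFrequencyTable, read_table, write_table

logger = logging.getLogger("haplovolve")

__all__ = ["run_pipeline", "export_manhattan", "load_config"]


def load_config(path) -> dict:
    import yaml

    with open(path, "rt", encoding="utf-8") as fh:
        return yaml.safe_load(fh)


def _config_hash(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _provenance(config: dict, seed: int) -> list[str]:
    return [
        f"haplovolve_version={__version__}",
        f"config_hash={_config_hash(config)}",
        f"seed={seed}",
    ]


def _write_frame(df: pd.DataFrame, path: Path, header: list[str]) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        for line in header:
            fh.write(f"#{line}\n")
        df.to_csv(fh, sep="\t", index=False)


def export_manhattan(chrom, pos, values) -> pd.DataFrame:
    """Plot-ready genome-wide track with a cumulative coordinate.

    Returns a DataFrame (chrom, pos, value, cum_pos) whose ``cum_pos``
    is strictly increasing across chromosome boundaries; per-chromosome
    offsets are stored in ``df.attrs['boundaries']``.  Chromosomes
    without loci are dropped with a warning.
    """
    chrom = np.asarray(chrom, dtype=object)
    pos = np.asarray(pos, dtype=np.int64)
    values = np.asarray(values, dtype=float)
    if chrom.size == 0:
        raise ValueError("empty scan")
    offset = 0
    boundaries: dict[str, int] = {}
    cum = np.empty(pos.size, dtype=np.int64)
    for c in dict.fromkeys(chrom):
        mask = chrom == c
        if not mask.any():
            warnings.warn(f"chromosome {c} has no loci; dropped")
            continue
        boundaries[str(c)] = offset
        cum[mask] = pos[mask] + offset
        offset += int(pos[mask].max())
    df = pd.DataFrame({"chrom": chrom, "pos": pos, "value": values, "cum_pos": cum})
    df.attrs["boundaries"] = boundaries
    return df


# ---------------------------------------------------------------------------


def _simulate_inputs(config: dict, seed: int):
    """Build the full synthetic study described by ``config['simulate']``."""
    sim = config["simulate"]
    grid = default_toy_grid(
        n_chromosomes=int(sim.get("n_chromosomes", 4)),
        chrom_length=int(sim.get("chrom_length", 300_000)),
    )
    panel, base = simulate_founder_panel(
        grid,
        n_founders=int(sim.get("n_founders", 18)),
        snp_density=float(sim.get("snp_density", 5.0)),
        seed=seed,
    )
    eps_base = float(sim.get("eps_base", 0.004))
    eps_evolved = float(sim.get("eps_evolved", 0.01))
    base_obs = add_measurement_noise(base, eps_base, seed=seed * 7 + 1)
    base_obs.population = "base"

    treatments: dict[str, list[HaplotypeFrequencyTable]] = {}
    truths = {}
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(9,)))
    for t_idx, tconf in enumerate(sim["treatments"]):
        name = tconf["name"]
        loci = [tuple(l) for l in tconf.get("selected_loci", [])]
        cfg = SimulationConfig(
            ne=float(tconf.get("ne", sim.get("ne", 750_000.0))),
            selected_loci=tuple((c, int(p)) for c, p in loci),
            selection_coefficients=tuple(tconf.get("s", [0.05] * len(loci))),
            target_haplotypes=tuple(tconf.get("targets", [])),
            n_replicates=int(tconf.get("n_replicates", 8)),
            eps_base=eps_base,
            eps_evolved=eps_evolved,
            seed=seed * 101 + t_idx,
        )
        reps, truth = simulate_evolution(base, cfg)
        noisy = []
        for r_idx, rep in enumerate(reps):
            n = add_measurement_noise(rep, eps_evolved, seed=seed * 1009 + t_idx * 31 + r_idx)
            n.population = f"{name}_{r_idx + 1}"
            noisy.append(n)
        n_cheaters = int(tconf.get("n_cheaters", 0))
        for c_idx in range(n_cheaters):
            kind = "aneuploid_haploid" if c_idx % 2 == 0 else "clonal_diploid"
            cheater = simulate_cheater(
                base, kind, seed=seed * 503 + t_idx * 17 + c_idx,
                population=f"{name}_cheater{c_idx + 1}",
            )
            noisy.append(cheater)
        treatments[name] = noisy
        truths[name] = truth
    return grid, panel, base_obs, treatments, truths


def run_pipeline(config: dict, out_dir) -> dict:
    """Run classify -> filter -> scan -> peaks -> dynamics -> CNV/SNV.

    ``config`` either contains a ``simulate`` section (all inputs are
    generated) or paths ``base_table`` plus ``treatment_tables`` (a
    mapping treatment -> TSV path).  Results are written under
    ``out_dir`` and also returned as a dict of DataFrames/objects.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    header = _provenance(config, seed)
    results: dict = {}

    if "simulate" in config:
        grid, panel, base, treatments, truths = _simulate_inputs(config, seed)
    else:
        for key in ("base_table", "treatment_tables"):
            if key not in config:
                raise ValueError(f"config missing required key {key!r}")
            paths = (
                [config[key]]
                if key == "base_table"
                else list(config[key].values())
            )
            for p in paths:
                if not Path(p).exists():
                    raise FileNotFoundError(f"input path {p} does not exist")
        base = read_table(config["base_table"])[0]
        treatments = {
            name: read_table(path)
            for name, path in config["treatment_tables"].items()
        }
        grid = None

    mt_window = config.get("mating_type_window")
    if mt_window is not None:
        mt_window = (mt_window[0], int(mt_window[1]), int(mt_window[2]))

    # --- stage 1: classification -----------------------------------------
    logger.info("stage classify: %d treatments", len(treatments))
    records = []
    rec_by_pop = {}
    for name, tables in treatments.items():
        for t in tables:
            rec = classify_population(t, mating_type_window=mt_window)
            rec.treatment = name
            rec.replicate = t.population
            records.append(rec)
            rec_by_pop[t.population] = rec

    # --- stage 2: retention filters --------------------------------------
    sexual = {
        name: [t for t in tables if rec_by_pop[t.population].classification == OUTBRED_SEXUAL]
        for name, tables in treatments.items()
    }
    sexual = {k: v for k, v in sexual.items() if v}
    if len(sexual) >= 2 and all(len(v) >= 2 for v in sexual.values()):
        q = int(config.get("cladogram_q", 3))
        retained_pops = cladogram_filter(sexual, q=q)
        for rec in records:
            if rec.classification == OUTBRED_SEXUAL:
                rec.retained = rec.replicate in retained_pops
                if not rec.retained:
                    rec.reason = "cladogram_filter"
            else:
                rec.retained = False
                rec.reason = "cheater"
    else:
        for rec in records:
            rec.retained = rec.classification == OUTBRED_SEXUAL
            if not rec.retained:
                rec.reason = "cheater"
    retained_treatments = select_sexual_treatments(
        records,
        min_reps=int(config.get("min_sexual_replicates", 6)),
        exempt=set(config.get("exempt_treatments", ["YPD"])),
    )
    report = classification_report(records)
    _write_frame(report, out / "classification.tsv", header)
    results["classification"] = report

    # --- stage 3/4: scan and peaks ----------------------------------------
    eps_base = float(config.get("eps_base", 0.004))
    eps_evolved = float(config.get("eps_evolved", 0.01))
    lod_cutoff = float(config.get("lod_cutoff", 5.0))
    min_sep = int(config.get("min_separation", 50))
    scans = {}
    peaks_frames = []
    for name in sorted(retained_treatments):
        tables = [
            t
            for t in treatments.get(name, [])
            if rec_by_pop[t.population].retained
        ]
        if len(tables) < 2:
            logger.warning("treatment %s: <2 retained replicates; no scan", name)
            continue
        logger.info("stage scan: %s (%d replicates)", name, len(tables))
        scan = chi_square_scan(base, tables, eps_base, eps_evolved,
                               float(config.get("min_base_freq", 0.005)))
        scans[name] = (scan, tables)
        _write_frame(scan.to_frame(), out / f"scan_{name}.tsv", header)
        man = export_manhattan(scan.chrom, scan.pos, scan.lod)
        _write_frame(man, out / f"manhattan_{name}.tsv", header)
        peaks = call_peaks(scan.chrom, scan.pos, scan.lod, min_separation=min_sep)
        pf = pd.DataFrame(
            {
                "treatment": name,
                "chrom": [p.chrom for p in peaks],
                "pos": [p.pos for p in peaks],
                "lod": [p.lod for p in peaks],
                "left_min": [p.left_min for p in peaks],
                "right_min": [p.right_min for p in peaks],
            }
        )
        peaks_frames.append(pf)
    if peaks_frames:
        all_peaks = pd.concat(peaks_frames, ignore_index=True)
        _write_frame(all_peaks, out / "peaks.tsv", header)
        results["peaks"] = all_peaks
    results["scans"] = {name: s for name, (s, _) in scans.items()}

    # --- stage 5: MIH, repeatability, pleiotropy ---------------------------
    mih_by_treatment = {}
    dynamics_rows = []
    for name, (scan, tables) in scans.items():
        recs = mih_table(base, tables)
        mih_by_treatment[name] = recs
        mih_df = pd.DataFrame(
            {
                "chrom": [r.chrom for r in recs],
                "pos": [r.pos for r in recs],
                "mih": [r.mih for r in recs],
                "mih_change": [r.mih_change for r in recs],
                "next": [r.next_mih for r in recs],
                "next_change": [r.next_change for r in recs],
                "mih_base": [r.mih_base for r in recs],
                "next_base": [r.next_base for r in recs],
            }
        )
        _write_frame(mih_df, out / f"mih_{name}.tsv", header)
        mih_mean, next_mean, ratio = mih_summary(recs)
        row = {
            "treatment": name,
            "sig_fraction": significance_fraction(scan, lod_cutoff),
            "mih_mean_change": mih_mean,
            "next_mean_change": next_mean,
            "mih_ratio": ratio,
            "replicate_spearman": replicate_spearman(tables),
            "mih_deviation": mih_deviation(base, tables, tables[0].population)[1]
            if len(tables) >= 3
            else np.nan,
        }
        if len(tables) >= 4:
            rho, _halves = split_half_lod_correlation(
                base, tables, eps_base, eps_evolved, seed=seed
            )
            row["split_half_rho"] = rho
        dynamics_rows.append(row)
    if dynamics_rows:
        dyn = pd.DataFrame(dynamics_rows)
        _write_frame(dyn, out / "dynamics_summary.tsv", header)
        results["dynamics"] = dyn
    if len(scans) >= 2:
        rho, shared = pleiotropy_screen(
            {n: s for n, (s, _) in scans.items()},
            mih_by_treatment,
            z_cutoff=float(config.get("z_cutoff", 1.96)),
        )
        _write_frame(rho.reset_index(names="treatment"), out / "pleiotropy_rho.tsv", header)
        _write_frame(shared, out / "pleiotropy_regions.tsv", header)
        results["pleiotropy"] = (rho, shared)

    # --- stage 6: CNV and de novo SNVs ------------------------------------
    if "simulate" in config and grid is not None:
        sim = config["simulate"]
        dups = [
            ((d[0], int(d[1]), int(d[2])), int(d[3]))
            for d in sim.get("duplications", [])
        ]
        cov_base, cov_evo = simulate_coverage(
            grid, dups, mean_cov=float(sim.get("mean_coverage", 50.0)), seed=seed
        )
        calls = call_duplications(cov_base, cov_evo)
        cnv = pd.DataFrame(
            {
                "chrom": [c.chrom for c in calls],
                "start": [c.start for c in calls],
                "end": [c.end for c in calls],
                "fold": [c.mean_fold_coverage for c in calls],
                "kind": [c.kind for c in calls],
            }
        )
        _write_frame(cnv, out / "duplications.tsv", header)
        results["duplications"] = cnv
    if "snv_candidates" in config:
        cand = pd.read_csv(config["snv_candidates"], sep="\t", comment="#")
        founder_pos = [tuple(x) for x in config.get("founder_snv_positions", [])]
        base_pos = [tuple(x) for x in config.get("base_snv_positions", [])]
        snvs = filter_denovo_snvs(cand, founder_pos, base_pos)
        _write_frame(snvs, out / "denovo_snvs.tsv", header)
        results["snvs"] = snvs

    logger.info("pipeline complete: outputs in %s", out)
    return results
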