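"""Synthetic single-seed-descent breeding program and field trials.

The generator emulates the structure the analysis assumes: several yearly
"sets" of biparental crosses among fully inbred founders, advanced to F5 by
single-seed descent (per-marker Mendelian gene dropping, so relatives share
real marker segments); each set's lines get one unreplicated F5 plot and,
the following years, replicated multi-location F6 trials of 22 lines plus
repeated checks laid out as randomized complete blocks on a grid.

Phenotypes follow the fitted models' own generative form: a year-location-
trial effect per environment cell, bivariate true breeding values from
correlated marker effects (genetic correlation ``r_g`` between the F5 and
F6 expressions), a spatial surface built in the same moving-average /
row-column form the models use, and independent plot residuals.  The true
marker effects, breeding values and variance components are returned so
parameter-recovery tests have an exact target.

All randomness flows from one seeded generator in a fixed draw order, so a
given (config, seed) pair is bit-reproducible.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import GenotypeMatrix, Pedigree, validate_plots

__all__ = ["SimConfig", "SyntheticTruth", "simulate_population", "simulate_trials", "simulate"]


@dataclass
class SimConfig:
    """Study-design and variance settings for the simulated program.

    Defaults mirror a spring-barley breeding program: four yearly sets of
    ~330 single-seed-descent lines, trials of 22 lines plus 3 checks, three
    locations per year, three replicates in a set's first F6 year and two in
    the second, yield around 6.6 kg per plot, genomic and residual variances
    of 0.017 and 0.057 kg^2 for F6 (0.003 and 0.066 for F5), and a genetic
    correlation of 0.7 between the F5 and F6 yield expressions.
    """

    n_founders: int = 40
    n_markers: int = 4000
    n_sets: int = 4
    lines_per_set: int = 330
    n_checks: int = 3
    trial_lines: int = 22
    replicates: tuple[int, ...] = (3, 2)  # per F6 year of each set
    locations: int = 3
    ssd_selfing: int = 4  # F1 -> F5
    founder_selfing: int = 9
    missing_rate: float = 0.01
    r_g: float = 0.7
    sigma_g2_f5: float = 0.003
    sigma_g2_f6: float = 0.017
    sigma_e2_f5: float = 0.066
    sigma_e2_f6: float = 0.057
    sigma_s2: float = 0.005
    sigma_ylt2: float = 0.25
    yield_mean_f5: float = 6.11
    yield_mean_f6: float = 6.60
    base_year: int = 2013
    f5_grid_width: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (
            self.n_founders,
            self.n_markers,
            self.n_sets,
            self.lines_per_set,
            self.trial_lines,
            self.locations,
        )
        if min(counts) < 1:
            raise ValueError("all design counts must be >= 1")
        if not -1.0 <= self.r_g <= 1.0:
            raise ValueError("r_g must lie in [-1, 1]")
        variances = (
            self.sigma_g2_f5,
            self.sigma_g2_f6,
            self.sigma_e2_f5,
            self.sigma_e2_f6,
            self.sigma_s2,
            self.sigma_ylt2,
        )
        if min(variances) < 0:
            raise ValueError("variances must be non-negative")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), sort_keys=True)


@dataclass
class SyntheticTruth:
    """Ground truth saved alongside a simulated dataset."""

    marker_effects: np.ndarray  # markers x 2 (F5, F6)
    breeding_values: pd.DataFrame  # line x (F5, F6)
    variance_components: dict[str, float]
    spatial_effects: pd.Series = field(repr=False)  # per plot_id
    seed: int = 0


@dataclass
class _Population:
    genotypes: GenotypeMatrix  # lines + checks, with missing calls masked
    pedigree: Pedigree
    full_counts: np.ndarray  # unmasked counts, same shape as genotypes
    set_of_line: dict[str, int]  # 0 marks checks
    check_ids: list[str]


def _self_once(haplos: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One generation of selfing: each of the two gametes is an independent
    per-marker draw from the parent's two haplotypes."""
    n, _, m = haplos.shape
    out = np.empty_like(haplos)
    for k in range(2):
        pick = rng.integers(0, 2, size=(n, m))
        out[:, k, :] = np.take_along_axis(
            haplos, pick[:, None, :], axis=1
        )[:, 0, :]
    return out


def simulate_population(cfg: SimConfig, rng: np.random.Generator | None = None):
    """Founders, crosses and SSD lines; returns (_Population, Pedigree is inside).

    Founders are fully inbred (homozygous at every marker, with nine
    recorded selfing cycles); each line is an F1 of two distinct random
    founders selfed ``ssd_selfing`` times by gene dropping.  About
    ``missing_rate`` of the emitted genotype calls are masked.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    m = cfg.n_markers
    p = rng.uniform(0.05, 0.5, size=m)
    founder_allele = (rng.random((cfg.n_founders, m)) < p).astype(np.int8)

    n_lines = cfg.n_sets * cfg.lines_per_set + cfg.n_checks
    crosses = np.empty((n_lines, 2), dtype=int)
    for i in range(n_lines):
        crosses[i] = rng.choice(cfg.n_founders, size=2, replace=False)
    # F1 haplotypes: one (homozygous) gamete from each founder
    haplos = np.stack(
        [founder_allele[crosses[:, 0]], founder_allele[crosses[:, 1]]], axis=1
    )
    for _ in range(cfg.ssd_selfing):
        haplos = _self_once(haplos, rng)
    counts = haplos.sum(axis=1).astype(float)

    founder_ids = [f"P{k + 1:03d}" for k in range(cfg.n_founders)]
    line_ids, set_of_line = [], {}
    for s in range(1, cfg.n_sets + 1):
        for i in range(cfg.lines_per_set):
            lid = f"S{s}L{i + 1:04d}"
            line_ids.append(lid)
            set_of_line[lid] = s
    check_ids = [f"CHK{k + 1}" for k in range(cfg.n_checks)]
    for cid in check_ids:
        set_of_line[cid] = 0
    all_ids = line_ids + check_ids

    masked = counts.copy()
    if cfg.missing_rate > 0:
        mask = rng.random(masked.shape) < cfg.missing_rate
        masked[mask] = np.nan
    genotypes = GenotypeMatrix(all_ids, [f"M{j + 1:05d}" for j in range(m)], masked)

    ped_rows = [
        {"id": fid, "parent1": None, "parent2": None, "selfing_cycles": cfg.founder_selfing}
        for fid in founder_ids
    ]
    for i, lid in enumerate(all_ids):
        ped_rows.append(
            {
                "id": lid,
                "parent1": founder_ids[crosses[i, 0]],
                "parent2": founder_ids[crosses[i, 1]],
                "selfing_cycles": cfg.ssd_selfing,
            }
        )
    pedigree = Pedigree(pd.DataFrame(ped_rows))
    return _Population(genotypes, pedigree, counts, set_of_line, check_ids)


def _partition_trials(ids: list[str], size: int) -> list[list[str]]:
    return [ids[i : i + size] for i in range(0, len(ids), size)]


def simulate_trials(cfg: SimConfig, pop: _Population, rng: np.random.Generator | None = None):
    """Field-trial phenotypes for a simulated population.

    Returns ``(plots, truth)``: a validated plot table and the ground truth.
    Set ``s`` has its F5 plots (one per line, single location) in year
    ``base_year + s - 1`` and replicated multi-location F6 trials in the
    following ``len(replicates)`` years, so later sets are genuinely in the
    program's future — the forward validation split relies on that.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed + 1)
    m = cfg.n_markers

    # correlated marker effects on the genomic-relationship scale: with
    # alpha_t ~ N(0, sigma_gt^2 / (2 sum p(1-p))) iid per marker, the true
    # breeding values g = Z alpha satisfy Var(g) = G sigma_g^2 exactly for
    # the VanRaden G of the true counts, so the configured variances are the
    # model-scale parameters REML estimates (the scale on which
    # mixed-model software reports them); realized
    # BV variance across lines is then about d(G) sigma_g^2
    chol = np.linalg.cholesky(np.array([[1.0, cfg.r_g], [cfg.r_g, 1.0]]))
    alpha = rng.standard_normal((m, 2)) @ chol.T
    p_true = pop.full_counts.mean(axis=0) / 2.0
    denom = 2.0 * np.sum(p_true * (1.0 - p_true))
    alpha *= np.sqrt(np.array([cfg.sigma_g2_f5, cfg.sigma_g2_f6]) / denom)
    centred = pop.full_counts - 2.0 * p_true
    bv = centred @ alpha
    bv_frame = pd.DataFrame(bv, index=pop.genotypes.line_ids, columns=["F5", "F6"])
    bv_of = {lid: bv[i] for i, lid in enumerate(pop.genotypes.line_ids)}

    records: list[dict] = []
    plot_no = 0

    def add_plot(line_id, gen, s, year, loc, trial, rep, x, y_coord):
        nonlocal plot_no
        plot_no += 1
        records.append(
            {
                "plot_id": f"PL{plot_no:06d}",
                "line_id": line_id,
                "generation": gen,
                "set": s,
                "year": year,
                "location": loc,
                "trial": trial,
                "replicate": rep,
                "x": x,
                "y": y_coord,
                "is_check": line_id in pop.check_ids,
            }
        )

    for s in range(1, cfg.n_sets + 1):
        set_lines = [lid for lid, ss in pop.set_of_line.items() if ss == s]
        trials = _partition_trials(set_lines, cfg.trial_lines)
        f5_year = cfg.base_year + s - 1
        for k, trial_lines in enumerate(trials):
            trial_id = f"S{s}T{k + 1:02d}"
            entries = list(trial_lines) + list(pop.check_ids)
            order = rng.permutation(len(entries))
            for pos, idx in enumerate(order):
                add_plot(
                    entries[idx], "F5", s, f5_year, "L1", trial_id, 1,
                    pos % cfg.f5_grid_width, pos // cfg.f5_grid_width,
                )
            for year_off, n_rep in enumerate(cfg.replicates):
                year = f5_year + 1 + year_off
                for loc in range(1, cfg.locations + 1):
                    for rep in range(1, n_rep + 1):
                        order = rng.permutation(len(entries))
                        for pos, idx in enumerate(order):
                            add_plot(
                                entries[idx], "F6", s, year, f"L{loc}", trial_id,
                                rep, rep - 1, pos,
                            )

    plots = pd.DataFrame(records)

    ylt_keys = plots[["year", "location", "trial"]].apply(tuple, axis=1)
    levels = sorted(set(ylt_keys))
    ylt_effect = dict(zip(levels, rng.normal(0.0, np.sqrt(cfg.sigma_ylt2), len(levels))))

    # spatial surfaces, in the same form the models fit
    spatial = np.zeros(len(plots))
    sd_s = np.sqrt(cfg.sigma_s2)
    for (gen, _key), idx in plots.groupby(["generation", ylt_keys]).groups.items():
        sub = plots.loc[idx]
        if gen == "F5":
            w_x = {v: rng.normal(0.0, sd_s) for v in sorted(sub["x"].unique())}
            w_y = {v: rng.normal(0.0, sd_s) for v in sorted(sub["y"].unique())}
            spatial[plots.index.get_indexer(idx)] = [
                w_x[x] + w_y[y] for x, y in zip(sub["x"], sub["y"])
            ]
        else:
            pos = {(x, y): rng.normal(0.0, sd_s) for x, y in zip(sub["x"], sub["y"])}
            vals = []
            for x, y in zip(sub["x"], sub["y"]):
                tot = 0.0
                for dx in (-1, 0, 1):
                    for dy in (-1, 0, 1):
                        tot += pos.get((x + dx, y + dy), 0.0)
                vals.append(tot)
            spatial[plots.index.get_indexer(idx)] = vals

    gen_idx = (plots["generation"] == "F6").astype(int).to_numpy()
    means = np.where(gen_idx, cfg.yield_mean_f6, cfg.yield_mean_f5)
    sigma_e = np.where(gen_idx, np.sqrt(cfg.sigma_e2_f6), np.sqrt(cfg.sigma_e2_f5))
    bv_col = np.array([bv_of[lid][t] for lid, t in zip(plots["line_id"], gen_idx)])
    ylt_col = np.array([ylt_effect[k] for k in ylt_keys])
    resid = rng.standard_normal(len(plots)) * sigma_e
    plots["yield"] = means + ylt_col + bv_col + spatial + resid
    plots.loc[plots["yield"] <= 0, "yield"] = 0.01  # physical floor, ~never hit

    plots = validate_plots(plots)
    truth = SyntheticTruth(
        marker_effects=alpha,
        breeding_values=bv_frame,
        variance_components={
            "sigma_g2_f5": cfg.sigma_g2_f5,
            "sigma_g2_f6": cfg.sigma_g2_f6,
            "sigma_e2_f5": cfg.sigma_e2_f5,
            "sigma_e2_f6": cfg.sigma_e2_f6,
            "sigma_s2": cfg.sigma_s2,
            "sigma_ylt2": cfg.sigma_ylt2,
            "r_g": cfg.r_g,
        },
        spatial_effects=pd.Series(spatial, index=plots["plot_id"]),
        seed=cfg.seed,
    )
    return plots, truth


def simulate(cfg: SimConfig):
    """Full dataset: (GenotypeMatrix, Pedigree, plots, SyntheticTruth)."""
    rng = np.random.default_rng(cfg.seed)
    pop = simulate_population(cfg, rng)
    plots, truth = simulate_trials(cfg, pop, rng)
    return pop.genotypes, pop.pedigree, plots, truth
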