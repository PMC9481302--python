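"""Synthetic breeding-programme data generator.

Emulates a multi-year, multi-location winter-wheat line trial: breeding
cycles of inbred lines with cycle-structured relatedness, daily weather
with a seasonal temperature/radiation cycle long enough to accumulate
more than 2,700 GDD per season, depth-layered soil profiles per
location, replicated field layouts of blocks on an X-Y grid, and
bivariate phenotypes drawn from the full reaction-norm generative model

``y = Xb + Z1 l + Z2 f + Z3 s + Z4 g + Z5 gw + e``

with every random effect drawn against its kernel (I, I, S, G,
(Zg G Zg') o Omega) and a configurable 2x2 between-trait covariance.
Because the generating parameters are known exactly, parameter recovery
and the orderings of predictive ability across models become testable
without any external download.

Defaults describe the emulated study conditions: 300 lines in 3
breeding cycles, 1,000 SNPs, 3 locations x 2 years (6 environments),
two replicate plots per line per environment, two negatively correlated
traits (genomic correlation -0.5), and strong marker-by-EC interaction
variance.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .env_covariates import (
    SOIL_DEPTHS,
    SOIL_EC_CODES,
    WeatherSeries,
    build_W,
    build_omega,
    environment_covariates,
    qc_ecs,
)
from .kernels import build_grm, build_gw_kernel, qc_snps
from .models import ModelDesign, _eigh_psd
from .spatial import build_spatial_matrix

__all__ = [
    "SimulationConfig",
    "SyntheticDataset",
    "simulate_genotypes",
    "simulate_weather",
    "simulate_soil",
    "simulate_layout",
    "simulate_phenotypes",
    "simulate_dataset",
]


def _default_variances() -> dict[str, tuple[float, float]]:
    # per-trait variances (trait 1, trait 2); magnitudes follow the
    # scale of commercial yield/protein trial variance components
    return {
        "l": (0.050, 0.035),
        "f": (0.050, 0.020),
        "s": (0.065, 0.050),
        "g": (0.055, 0.065),
        "gw": (0.110, 0.040),
        "e": (0.055, 0.048),
    }


def _default_correlations() -> dict[str, float]:
    return {"l": -0.5, "f": -0.6, "s": -0.25, "g": -0.5, "gw": -0.65, "e": 0.0}


@dataclass
class SimulationConfig:
    """Generating conditions for one synthetic dataset."""

    n_cycles: int = 3
    lines_per_cycle: int = 100
    n_locations: int = 3
    n_years: int = 2
    n_snps: int = 1000
    maf_range: tuple[float, float] = (0.10, 0.50)
    inbreeding: float = 0.90          # expected homozygosity excess; d(G) ~ 1 + F
    cycle_drift: float = 0.08         # allele-frequency drift between cycles
    missing_rate: float = 0.0         # genotype missingness (for QC exercises)
    block_lines: int = 21             # lines per block (each with 2 replicate plots)
    n_checks: int = 2                 # check lines, one plot each per block
    reps: int = 2
    field_cols: int = 24              # plots per grid row
    trial_effect_sd: float = 0.7
    traits: tuple[str, ...] = ("yield", "protein")
    variances: dict = field(default_factory=_default_variances)
    correlations: dict = field(default_factory=_default_correlations)
    stage_size: float = 100.0
    base_year: int = 2014
    max_plots_per_env: int | None = None

    def n_lines(self) -> int:
        return self.n_cycles * self.lines_per_cycle

    def covariance(self, effect: str) -> np.ndarray:
        """Between-trait covariance matrix for one effect."""
        v = np.asarray(self.variances[effect], dtype=float)[: len(self.traits)]
        T = len(self.traits)
        cov = np.diag(v)
        if T == 2:
            rho = float(self.correlations.get(effect, 0.0))
            cov[0, 1] = cov[1, 0] = rho * np.sqrt(v[0] * v[1])
        eig = np.linalg.eigvalsh(cov)
        if eig.min() < -1e-12:
            raise ValueError(f"configured covariance for {effect!r} is not PSD")
        return cov


@dataclass
class SyntheticDataset:
    """A generated dataset bundle with its derived kernels and truth."""

    config: SimulationConfig
    seed: int
    phenos: pd.DataFrame
    genotypes: pd.DataFrame
    line_table: pd.DataFrame
    weather: dict[str, WeatherSeries]
    soil: pd.DataFrame
    layout: pd.DataFrame
    ec: pd.DataFrame
    W: pd.DataFrame
    omega: pd.DataFrame
    S: pd.DataFrame
    G: pd.DataFrame
    truth: dict

    def design(self, traits=None, **kwargs) -> ModelDesign:
        """Assemble a :class:`~gddrn.models.ModelDesign` for fitting."""
        return ModelDesign(
            self.phenos,
            traits or self.config.traits,
            G=self.G,
            S=self.S,
            omega=self.omega,
            **kwargs,
        )


# ----------------------------------------------------------------------
def simulate_genotypes(
    cfg: SimulationConfig, rng: np.random.Generator
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cycle-structured inbred-line genotypes coded -1/0/1.

    Founder allele frequencies are drawn from ``maf_range``; each
    cycle's frequencies drift around the founders (Beta with variance
    ``cycle_drift * p(1-p)``), making lines within a cycle more related
    than lines across cycles.  Inbreeding is emulated by drawing a
    fraction ``inbreeding`` of loci as forced homozygotes, so the mean
    GRM diagonal sits near ``1 + inbreeding``.

    Returns ``(genotypes, line_table)`` where ``line_table`` has
    ``line_id``, ``cycle`` and ``is_check`` columns.
    """
    lo, hi = cfg.maf_range
    if not (0 < lo < hi <= 0.5):
        raise ValueError("maf_range must satisfy 0 < low < high <= 0.5")
    p0 = rng.uniform(lo, hi, cfg.n_snps)
    snp_ids = [f"snp{j:05d}" for j in range(cfg.n_snps)]

    def draw_lines(n_lines: int, p: np.ndarray) -> np.ndarray:
        hom = rng.random((n_lines, cfg.n_snps)) < cfg.inbreeding
        hom_allele = rng.random((n_lines, cfg.n_snps)) < p
        a1 = rng.random((n_lines, cfg.n_snps)) < p
        a2 = rng.random((n_lines, cfg.n_snps)) < p
        het_geno = a1.astype(int) + a2.astype(int) - 1
        hom_geno = 2 * hom_allele.astype(int) - 1
        return np.where(hom, hom_geno, het_geno).astype(float)

    blocks, ids, cycles, checks = [], [], [], []
    for c in range(1, cfg.n_cycles + 1):
        if cfg.cycle_drift > 0:
            t = cfg.cycle_drift
            a = p0 * (1 - t) / t
            b = (1 - p0) * (1 - t) / t
            pc = rng.beta(a, b)
        else:
            pc = p0
        blocks.append(draw_lines(cfg.lines_per_cycle, pc))
        ids += [f"c{c}_l{i:04d}" for i in range(cfg.lines_per_cycle)]
        cycles += [c] * cfg.lines_per_cycle
        checks += [False] * cfg.lines_per_cycle
    if cfg.n_checks:
        blocks.append(draw_lines(cfg.n_checks, p0))
        ids += [f"chk{i:02d}" for i in range(cfg.n_checks)]
        cycles += [0] * cfg.n_checks
        checks += [True] * cfg.n_checks
    M = np.vstack(blocks)
    if cfg.missing_rate > 0:
        drop = rng.random(M.shape) < cfg.missing_rate
        M = np.where(drop, np.nan, M)
    geno = pd.DataFrame(M, index=pd.Index(ids, name="line_id"), columns=snp_ids)
    line_table = pd.DataFrame(
        {"line_id": ids, "cycle": cycles, "is_check": checks}
    ).set_index("line_id")
    return geno, line_table


def simulate_weather(
    cfg: SimulationConfig, rng: np.random.Generator
) -> tuple[dict[str, WeatherSeries], dict[str, str]]:
    """Seasonal daily weather per year-location.

    Temperature follows a sinusoidal annual cycle (coastal-temperate
    parameters) plus day-to-day noise; radiation, evaporation and VPD
    track the season; precipitation is intermittent exponential.  The
    sowing-to-mid-August window accumulates comfortably above 2,700 GDD
    so at least 27 complete 100-GDD stages exist in every environment.

    Returns ``(weather, env_location)``.
    """
    weather: dict[str, WeatherSeries] = {}
    env_location: dict[str, str] = {}
    for li in range(cfg.n_locations):
        loc = f"loc{li + 1}"
        for yi in range(cfg.n_years):
            year = cfg.base_year + yi
            env = f"{loc}_{year}"
            sowing = pd.Timestamp(year - 1, 10, 1)
            end = pd.Timestamp(year, 8, 15)
            dates = pd.date_range(sowing, end, freq="D")
            doy = dates.dayofyear.to_numpy(dtype=float)
            base = rng.normal(10.0, 0.4)
            amp = rng.normal(8.0, 0.3)
            phase = 2 * np.pi * (doy - 196.0) / 365.0
            tavg = base - amp * np.cos(phase) + rng.normal(0.0, 1.3, len(dates))
            tmin = tavg - rng.uniform(1.0, 4.0, len(dates))
            tmax = tavg + rng.uniform(1.0, 4.0, len(dates))
            wet = rng.random(len(dates)) < 0.55
            precip = np.where(wet, rng.exponential(3.5, len(dates)), 0.0)
            evap = np.clip(
                0.2 + 1.6 * (1 - np.cos(phase)) + rng.normal(0.0, 0.3, len(dates)), 0.0, None
            )
            glorad = np.clip(
                11.0 - 9.5 * np.cos(2 * np.pi * (doy - 172.0) / 365.0)
                + rng.normal(0.0, 1.5, len(dates)),
                0.2,
                None,
            )
            vpd = np.clip(
                0.12 + 0.05 * np.clip(tavg, 0.0, None) + rng.normal(0.0, 0.04, len(dates)),
                0.02,
                None,
            )
            records = pd.DataFrame(
                {"tmin": tmin, "tavg": tavg, "tmax": tmax, "precip": precip,
                 "evap": evap, "glorad": glorad, "vpd": vpd},
                index=dates,
            )
            weather[env] = WeatherSeries(env, records, sowing, end)
            env_location[env] = loc
    return weather, env_location


def simulate_soil(cfg: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Depth-layered soil table per location (texture, carbon, water)."""
    rows = []
    for li in range(cfg.n_locations):
        loc = f"loc{li + 1}"
        clay0 = rng.uniform(5, 25)
        fsand0 = rng.uniform(20, 45)
        for k, (top, bottom) in enumerate(SOIL_DEPTHS):
            clay = np.clip(clay0 + 2.0 * k + rng.normal(0, 1), 1, 60)
            fsand = np.clip(fsand0 - 1.5 * k + rng.normal(0, 2), 5, 70)
            gsand = np.clip(rng.uniform(10, 35) - k + rng.normal(0, 2), 2, 60)
            silt = np.clip(100 - clay - fsand - gsand, 1, 60)
            rows.append(
                {
                    "location": loc,
                    "depth_top_cm": top,
                    "depth_bottom_cm": bottom,
                    "pvt": np.clip(rng.uniform(10, 22) - k, 2, 40),
                    "claynor": clay,
                    "fsandno": fsand,
                    "gsandno": gsand,
                    "siltnor": silt,
                    "kulstof": np.clip(rng.uniform(0.5, 2.5) / (k + 1), 0.01, 5),
                    "Ks_250": np.clip(rng.uniform(20, 90), 0, 100),
                    "wscmm": np.clip(rng.uniform(30, 90) + 10 * k, 5, 250),
                }
            )
    return pd.DataFrame(rows)


def simulate_layout(
    cfg: SimulationConfig,
    line_table: pd.DataFrame,
    envs: list[str],
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Field layout: blocks of replicated line plots on an X-Y grid.

    Every non-check line gets ``reps`` plots in every environment,
    grouped in blocks of ``block_lines`` lines within its cycle's trial;
    each check line contributes one plot per block.  Grid coordinates
    are unique within environment.
    """
    rows = []
    check_ids = list(line_table.index[line_table["is_check"]])
    for env in envs:
        pos = 0
        counter = 0
        for cycle, grp in line_table[~line_table["is_check"]].groupby("cycle"):
            lines = list(grp.index)
            rng.shuffle(lines)
            trial = f"{env}|c{cycle}"
            for bi in range(0, len(lines), cfg.block_lines):
                chunk = lines[bi: bi + cfg.block_lines]
                block = f"{trial}|b{bi // cfg.block_lines + 1}"
                plots = [(ln, False) for ln in chunk for _ in range(cfg.reps)]
                plots += [(ck, True) for ck in check_ids]
                order = rng.permutation(len(plots))
                for j in order:
                    ln, is_check = plots[j]
                    rows.append(
                        {
                            "obs_id": f"{env}:{counter:05d}",
                            "env_id": env,
                            "trial": trial,
                            "block": block,
                            "x": pos // cfg.field_cols,
                            "y": pos % cfg.field_cols,
                            "line_id": ln,
                            "cycle": int(line_table.loc[ln, "cycle"]),
                            "is_check": is_check,
                            "is_virtual": False,
                        }
                    )
                    pos += 1
                    counter += 1
        if cfg.max_plots_per_env is not None and counter > cfg.max_plots_per_env:
            raise ValueError(
                f"{env}: {counter} plots exceed capacity {cfg.max_plots_per_env}"
            )
    return pd.DataFrame(rows).sort_values("obs_id").reset_index(drop=True)


def _cov_factor(cov: np.ndarray) -> np.ndarray:
    """Square root of a PSD (possibly singular) covariance matrix."""
    d, U = np.linalg.eigh(cov)
    return U * np.sqrt(np.clip(d, 0.0, None))


def _draw_kernel_effect(rng, d, U, cov):
    """Draw ``u ~ MVN(0, K (x) cov)`` given ``K = U diag(d) U'``."""
    T = cov.shape[0]
    Z = rng.standard_normal((len(d), T)) @ _cov_factor(cov).T
    return (U * np.sqrt(d)) @ Z


def simulate_phenotypes(
    cfg: SimulationConfig,
    layout: pd.DataFrame,
    G: pd.DataFrame,
    S: pd.DataFrame,
    omega: pd.DataFrame,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, dict]:
    """Draw phenotypes from the full generative reaction-norm model."""
    T = len(cfg.traits)
    layout = layout.sort_values("obs_id").reset_index(drop=True)
    obs_ids = pd.Index(layout["obs_id"])
    n = len(layout)

    lines = pd.Index(sorted(layout["line_id"].unique()))
    line_pos = lines.get_indexer(layout["line_id"])
    pairs = layout["line_id"].astype(str) + "|" + layout["env_id"].astype(str)
    pair_levels = pd.Index(sorted(pairs.unique()))
    pair_pos = pair_levels.get_indexer(pairs)
    trials = pd.Index(sorted(layout["trial"].unique()))
    trial_pos = trials.get_indexer(layout["trial"])

    cov = {e: cfg.covariance(e) for e in ("l", "f", "s", "g", "gw", "e")}

    u_l = rng.standard_normal((len(lines), T)) @ _cov_factor(cov["l"]).T
    u_f = rng.standard_normal((len(pair_levels), T)) @ _cov_factor(cov["f"]).T

    Smat = S.loc[obs_ids, obs_ids].to_numpy(dtype=float)
    dS, US = _eigh_psd(Smat, "S", 1e-10)
    u_s = _draw_kernel_effect(rng, dS, US, cov["s"])

    Gsub = G.loc[lines, lines].to_numpy(dtype=float)
    dGk, UG = _eigh_psd(Gsub, "G", 1e-10)
    u_g = _draw_kernel_effect(rng, dGk, UG, cov["g"])

    obs_line = pd.Series(layout["line_id"].values, index=obs_ids)
    GW = build_gw_kernel(
        pd.DataFrame(Gsub, index=lines, columns=lines), obs_line, omega
    ).to_numpy(dtype=float)
    dGW, UGW = _eigh_psd(GW, "GW", 1e-10)
    u_gw = _draw_kernel_effect(rng, dGW, UGW, cov["gw"])

    b_trial = rng.normal(0.0, cfg.trial_effect_sd, (len(trials), T))
    e = rng.standard_normal((n, T)) @ _cov_factor(cov["e"]).T

    y = (
        b_trial[trial_pos]
        + u_l[line_pos]
        + u_f[pair_pos]
        + u_s
        + u_g[line_pos]
        + u_gw
        + e
    )
    phenos = layout.drop(columns=["is_virtual"]).copy()
    for t, trait in enumerate(cfg.traits):
        phenos[trait] = y[:, t]
    truth = {
        "covariances": {k: v.tolist() for k, v in cov.items()},
        "correlations": dict(cfg.correlations),
        "variances": {k: list(map(float, np.diag(v))) for k, v in cov.items()},
        "trial_effects": pd.DataFrame(b_trial, index=trials, columns=cfg.traits),
        "effects": {
            "l": pd.DataFrame(u_l, index=lines, columns=cfg.traits),
            "f": pd.DataFrame(u_f, index=pair_levels, columns=cfg.traits),
            "s": pd.DataFrame(u_s, index=obs_ids, columns=cfg.traits),
            "g": pd.DataFrame(u_g, index=lines, columns=cfg.traits),
            "gw": pd.DataFrame(u_gw, index=obs_ids, columns=cfg.traits),
        },
    }
    return phenos, truth


def simulate_dataset(cfg: SimulationConfig | None = None, seed: int = 0) -> SyntheticDataset:
    """Generate a complete dataset and its derived kernels.

    Deterministic: the same config and seed reproduce every table
    bit-for-bit.
    """
    cfg = cfg or SimulationConfig()
    rng = np.random.default_rng(seed)
    genotypes, line_table = simulate_genotypes(cfg, rng)
    weather, env_location = simulate_weather(cfg, rng)
    soil = simulate_soil(cfg, rng)
    envs = sorted(env_location)
    layout = simulate_layout(cfg, line_table, envs, rng)

    geno_qc = qc_snps(genotypes)
    G = build_grm(geno_qc)
    S = build_spatial_matrix(layout)
    raw_ec = environment_covariates(
        weather, soil, env_location, stage_size=cfg.stage_size
    )
    ec = qc_ecs(raw_ec)
    obs_env = pd.Series(layout["env_id"].values, index=pd.Index(layout["obs_id"], name="obs_id"))
    W = build_W(ec, obs_env, scale="environment")
    omega = build_omega(W)

    phenos, truth = simulate_phenotypes(cfg, layout, G, S, omega, rng)
    truth["seed"] = seed
    truth["config"] = asdict(cfg)
    return SyntheticDataset(
        config=cfg,
        seed=seed,
        phenos=phenos,
        genotypes=genotypes,
        line_table=line_table,
        weather=weather,
        soil=soil,
        layout=layout,
        ec=ec,
        W=W,
        omega=omega,
        S=S,
        G=G,
        truth=truth,
    )
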