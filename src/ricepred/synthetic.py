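"""Synthetic data generator emulating the study system end to end.

Generates a biparental RIL population (recombination via the Haldane map
function, repeated selfing), additive trait architectures with target
heritabilities, sinusoid + AR(1) weather, multi-environment heading-date
trials, longitudinal leaf/tiller observations, and forward-simulated
biomass.  The generator and the predictor share the same growth-model and
phenology code paths, so zero-noise scenarios admit exact closed-loop
recovery — the primary oracle of the whole package.

Default scenario scale mirrors the study system: 123 RILs × 315 SNPs on
12 chromosomes (F₈ after 7 selfing generations), two sowing-date
environments about one month apart at 36 °N, and a 112-line panel across
8 synthetic site-years for the heading-date model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cgm import simulate_biomass
from .config import CGMConstants, DVRCardinals, PSOSettings
from .gp import MarkerMatrix
from .growth import GrowthParams, WeatherSeries, growth_curves, heat_units
from .io import Dataset
from .phenology import (DVRParams, METData, METRecord, day_length,
                        simulate_dvs_heading)

GENE_NAMES = ("Hd1", "Hd3a", "Hd6", "Hd16", "Hd17", "Ghd7")


@dataclass
class TraitArchitecture:
    """Additive architecture of one intermediate trait.

    mean/genetic_sd on the trait's own scale; h2 partitions line-level
    variance into genetic and per-environment residual; obs_sigma is
    measurement noise added to longitudinal observations (not to the
    trait value itself).
    """

    n_causal: int
    mean: float
    genetic_sd: float
    h2: float = 0.8
    lower: float = 1e-4

    def __post_init__(self) -> None:
        if not (0.0 < self.h2 <= 1.0):
            raise ValueError("h2 must lie in (0, 1]")


@dataclass
class EnvironmentSpec:
    """One field environment: location, season, and weather-generator knobs."""

    env_id: str
    latitude: float
    sowing_date: str
    season_days: int = 250
    t_base: float = 14.5      # annual mean temperature, °C
    t_amplitude: float = 11.5  # seasonal half-range, °C
    t_peak_doy: int = 212      # day of year of the temperature peak
    t_ar1: float = 0.7
    t_sigma: float = 1.5
    par_base: float = 8.0     # MJ m⁻² d⁻¹
    par_amplitude: float = 3.5
    par_peak_doy: int = 172
    par_sigma: float = 1.2


def _default_environments() -> list[EnvironmentSpec]:
    return [
        EnvironmentSpec("2014", 36.01, "2014-04-22"),
        EnvironmentSpec("2015", 36.01, "2015-05-19"),
    ]


def _default_traits() -> dict[str, TraitArchitecture]:
    # Typical japonica ranges: final leaf age ~14, ~20 tillers, leaf-age
    # slope ~0.011 per °C·d, leaf-length increment ~5 cm per leaf.
    return {
        "delta_leaf": TraitArchitecture(10, 0.011, 0.0012),
        "leaf_max": TraitArchitecture(10, 14.0, 0.8, lower=8.0),
        "delta_till": TraitArchitecture(10, 0.016, 0.002),
        "till_max": TraitArchitecture(10, 20.0, 2.5, lower=5.0),
        "delta_ll": TraitArchitecture(10, 0.050, 0.006),
        "harvest_index": TraitArchitecture(10, 0.45, 0.04, lower=0.05),
    }


@dataclass
class SyntheticScenario:
    """Everything the generator needs; defaults are the study conditions."""

    n_lines: int = 123
    n_markers: int = 315
    n_chromosomes: int = 12
    chromosome_length_cm: float = 110.0
    selfing_generations: int = 7
    traits: dict[str, TraitArchitecture] = field(
        default_factory=_default_traits)
    # DVR parameters: additive over the six heading-date gene loci
    dvr_means: tuple[float, float, float] = (1.5, 2.0, 65.0)
    dvr_sds: tuple[float, float, float] = (0.3, 0.6, 7.0)
    environments: list[EnvironmentSpec] = field(
        default_factory=_default_environments)
    met_panel_size: int = 112
    met_trials: int = 8
    heading_noise_days: int = 1       # uniform integer rounding noise, ±days
    obs_sigma_leaf: float = 0.15
    obs_sigma_till: float = 0.5
    biomass_env_sigma: float = 0.12   # sd of log-normal multiplicative noise
    tau_true: float = 1.0
    seed: int = 0

    def child_seed(self, stage: str) -> int:
        """Deterministic per-stage child seed below 2^31."""
        h = np.uint32(2166136261)
        for ch in f"{self.seed}:{stage}":
            h = np.uint32((int(h) ^ ord(ch)) * 16777619 & 0xFFFFFFFF)
        return int(h) % (2 ** 31 - 1)

    def rng(self, stage: str) -> np.random.Generator:
        return np.random.default_rng(self.child_seed(stage))

    def zero_noise(self) -> "SyntheticScenario":
        """A copy with all noise off and h²=1: the closed-loop oracle setting."""
        import copy
        sc = copy.deepcopy(self)
        for t in sc.traits.values():
            t.h2 = 1.0
        sc.heading_noise_days = 0
        sc.obs_sigma_leaf = 0.0
        sc.obs_sigma_till = 0.0
        sc.biomass_env_sigma = 0.0
        sc.tau_true = 1.0
        return sc


@dataclass
class TrueParams:
    """Ground truth per line: the generator's recovery-scoring payload."""

    growth: dict[str, pd.DataFrame]        # env → line × growth params
    dvr: pd.DataFrame                      # line × (alpha, beta_p, g)
    harvest_index: dict[str, pd.Series]    # env → per-line HI
    heading_day: dict[str, pd.Series]      # env → days after sowing
    biomass: dict[str, pd.Series]          # env → noiseless BM_TSG·τ
    genetic_values: pd.DataFrame           # line × trait (genetic component)
    gene_effects: pd.DataFrame             # gene × (alpha, beta_p, g)
    panel_gene_codes: np.ndarray | None = None
    panel_dvr: pd.DataFrame | None = None


def _marker_map(scenario: SyntheticScenario, rng: np.random.Generator
                ) -> tuple[list[str], np.ndarray, np.ndarray]:
    per = np.full(scenario.n_chromosomes,
                  scenario.n_markers // scenario.n_chromosomes)
    per[:scenario.n_markers % scenario.n_chromosomes] += 1
    chroms, pos, ids = [], [], []
    for c, n in enumerate(per, start=1):
        p = np.sort(rng.uniform(0, scenario.chromosome_length_cm, n))
        for j in range(n):
            ids.append(f"S{c:02d}_{j + 1:03d}")
        chroms.extend([c] * n)
        pos.extend(p)
    return ids, np.array(chroms), np.array(pos)


def sim_genotypes(scenario: SyntheticScenario,
                  rng: np.random.Generator | None = None) -> MarkerMatrix:
    """Simulate RIL genotypes by recombination and repeated selfing.

    The F₁ is heterozygous everywhere; each selfing generation forms two
    gametes per line with crossovers between adjacent markers at the
    Haldane recombination fraction r = (1 − e^{−2d/100})/2 for map
    distance d cM.  After ``selfing_generations`` rounds the residual
    heterozygosity per locus is ≈ (1/2)^generations.
    """
    rng = rng or scenario.rng("genotypes")
    ids, chroms, pos = _marker_map(scenario, rng)
    n, m = scenario.n_lines, scenario.n_markers

    rec = np.zeros(m)  # recombination fraction with the previous marker
    for c in np.unique(chroms):
        idx = np.nonzero(chroms == c)[0]
        d = np.diff(pos[idx])
        rec[idx[0]] = 0.5  # chromosome start: independent
        rec[idx[1:]] = 0.5 * (1.0 - np.exp(-2.0 * d / 100.0))

    def gamete(h1: np.ndarray, h2: np.ndarray) -> np.ndarray:
        switch = rng.random((n, m)) < rec
        pick = np.cumsum(switch, axis=1) % 2  # 0 → h1 strand, 1 → h2
        start = rng.integers(0, 2, size=(n, 1))
        pick = (pick + start) % 2
        return np.where(pick == 0, h1, h2)

    h1 = np.zeros((n, m), dtype=np.int8)  # parent A alleles
    h2 = np.ones((n, m), dtype=np.int8)   # parent B alleles
    for _ in range(scenario.selfing_generations):
        g1 = gamete(h1, h2)
        g2 = gamete(h1, h2)
        h1, h2 = g1, g2
    codes = 1.0 - (h1 + h2).astype(float)  # AA→+1, BB→−1, het→0
    lines = [f"RIL{i + 1:03d}" for i in range(n)]
    return MarkerMatrix(lines, ids, chroms, pos, codes)


def sim_trait_architecture(markers: MarkerMatrix,
                           traits: dict[str, TraitArchitecture],
                           rng: np.random.Generator
                           ) -> tuple[pd.DataFrame, dict[str, np.ndarray],
                                      dict[str, np.ndarray]]:
    """Draw causal loci and effects; return genetic values per trait.

    Effects are rescaled so the realized genetic standard deviation across
    the simulated lines matches each trait's target exactly (an affine
    rescale, harmless for additivity).  Returns (genetic value table,
    causal index map, effect map).
    """
    gv = {}
    loci: dict[str, np.ndarray] = {}
    effs: dict[str, np.ndarray] = {}
    for name, arch in traits.items():
        if arch.n_causal == 0:
            gv[name] = np.zeros(markers.n_lines)
            loci[name] = np.array([], dtype=int)
            effs[name] = np.array([])
            continue
        if arch.n_causal > markers.n_markers:
            raise ValueError(f"{name}: more causal loci than markers")
        idx = rng.choice(markers.n_markers, size=arch.n_causal,
                         replace=False)
        eff = rng.standard_normal(arch.n_causal)
        g = markers.codes[:, idx] @ eff
        sd = g.std()
        if sd == 0:
            if arch.genetic_sd > 0:
                raise ValueError(f"{name}: target genetic variance "
                                 "unreachable (zero-variance causal loci)")
            scale = 0.0
        else:
            scale = arch.genetic_sd / sd
        gv[name] = (g - g.mean()) * scale
        loci[name] = idx
        effs[name] = eff * scale
    return pd.DataFrame(gv, index=markers.line_ids), loci, effs


def sim_weather(env: EnvironmentSpec, rng: np.random.Generator,
                twilight_angle: float = -0.833,
                start_offset_days: int = 5) -> WeatherSeries:
    """Seasonal sinusoid + AR(1) temperature; clipped sinusoid PAR."""
    if env.season_days < 220:
        raise ValueError("season length must be >= 220 days")
    start = pd.Timestamp(env.sowing_date) - pd.Timedelta(
        days=start_offset_days)
    dates = pd.date_range(start, periods=env.season_days, freq="D")
    doy = dates.dayofyear.to_numpy(dtype=float)
    t_det = env.t_base + env.t_amplitude * np.cos(
        2.0 * np.pi * (doy - env.t_peak_doy) / 365.25)
    noise = np.zeros(len(doy))
    if env.t_sigma > 0:
        eps = rng.normal(0.0, env.t_sigma, len(doy))
        for i in range(1, len(doy)):
            noise[i] = env.t_ar1 * noise[i - 1] + eps[i]
        noise[0] = eps[0]
    t = t_det + noise
    par_det = env.par_base + env.par_amplitude * np.cos(
        2.0 * np.pi * (doy - env.par_peak_doy) / 365.25)
    par = par_det + (rng.normal(0.0, env.par_sigma, len(doy))
                     if env.par_sigma > 0 else 0.0)
    par = np.clip(par, 0.0, None)
    dl = day_length(env.latitude, doy, twilight_angle)
    return WeatherSeries(dates, t, par, dl, env.latitude)


def _dvr_from_genes(gene_codes: np.ndarray, gene_effects: np.ndarray,
                    means: tuple, sds: tuple,
                    pso: PSOSettings = PSOSettings()) -> np.ndarray:
    """Additive gene → (α, β_P, G) map, clipped into the PSO bounds box."""
    raw = gene_codes @ gene_effects  # (n, 3)
    lb = np.array([pso.alpha_bounds[0], pso.beta_bounds[0], pso.g_bounds[0]])
    ub = np.array([pso.alpha_bounds[1], pso.beta_bounds[1], pso.g_bounds[1]])
    return np.clip(np.asarray(means) + raw, lb, ub)


def sim_met_trials(dvr_params: pd.DataFrame, scenario: SyntheticScenario,
                   rng: np.random.Generator,
                   cardinals: DVRCardinals = DVRCardinals()) -> METData:
    """Heading-date trials across site-years for the parameter panel.

    Trials span latitudes 33.5–39.5 °N and April–June sowing dates, giving
    the temperature and photoperiod contrasts that make (α, β_P, G)
    identifiable.  Observed heading dates carry ± ``heading_noise_days``
    uniform integer noise.
    """
    lats = [39.5, 36.0, 34.9, 34.5, 33.6]
    sows = ["-04-20", "-05-05", "-05-20", "-06-03"]
    specs = []
    for t in range(scenario.met_trials):
        year = 2004 + t
        lat = lats[t % len(lats)]
        sow = f"{year}{sows[t % len(sows)]}"
        t_base = 14.5 + (36.0 - lat) * 0.7  # southern sites are warmer
        specs.append(EnvironmentSpec(f"T{t + 1:02d}", lat, sow,
                                     season_days=250, t_base=t_base))
    records = []
    for spec in specs:
        w = sim_weather(spec, rng)
        sowing = pd.Timestamp(spec.sowing_date)
        for line_id, row in dvr_params.iterrows():
            params = DVRParams(row["alpha"], row["beta_p"], row["g"])
            res = simulate_dvs_heading(params, w, sowing, cardinals)
            if not res.headed:
                continue
            jitter = (int(rng.integers(-scenario.heading_noise_days,
                                       scenario.heading_noise_days + 1))
                      if scenario.heading_noise_days > 0 else 0)
            hd = sowing + pd.Timedelta(days=res.heading_day - 1 + jitter)
            records.append(METRecord(str(line_id), spec.env_id, spec.latitude,
                                     sowing, hd, w))
    return METData(records)


def sim_met_panel(scenario: SyntheticScenario, gene_effects: np.ndarray,
                  rng: np.random.Generator
                  ) -> tuple[np.ndarray, pd.DataFrame]:
    """Genotypes and true DVR parameters of the MET cultivar panel.

    Panel lines are unrelated cultivars: the six heading-gene genotypes are
    drawn i.i.d. ±1, and parameters follow the same additive gene map as
    the RILs.
    """
    codes = rng.choice([-1.0, 1.0],
                       size=(scenario.met_panel_size, len(GENE_NAMES)))
    params = _dvr_from_genes(codes, gene_effects, scenario.dvr_means,
                             scenario.dvr_sds)
    ids = [f"CV{i + 1:03d}" for i in range(scenario.met_panel_size)]
    return codes, pd.DataFrame(params, index=ids,
                               columns=["alpha", "beta_p", "g"])


def _leaf_obs_days(sowing: pd.Timestamp) -> list[pd.Timestamp]:
    return [sowing + pd.Timedelta(days=d) for d in range(27, 70, 7)]


def _till_obs_days(sowing: pd.Timestamp) -> list[pd.Timestamp]:
    return [sowing + pd.Timedelta(days=d) for d in range(50, 80, 7)]


def sim_dataset(scenario: SyntheticScenario,
                constants: CGMConstants = CGMConstants(),
                cardinals: DVRCardinals = DVRCardinals()
                ) -> tuple[Dataset, TrueParams]:
    """Generate a full input bundle plus ground truth for recovery scoring."""
    markers = sim_genotypes(scenario)
    rng_arch = scenario.rng("architecture")
    genetic, _, _ = sim_trait_architecture(markers, scenario.traits,
                                           rng_arch)

    # heading-gene loci: one marker on each of six distinct chromosomes
    gene_rng = scenario.rng("genes")
    gene_chroms = gene_rng.choice(np.arange(1, scenario.n_chromosomes + 1),
                                  size=len(GENE_NAMES), replace=False)
    gene_idx = []
    for c in gene_chroms:
        cand = np.nonzero(markers.chromosome == c)[0]
        gene_idx.append(int(gene_rng.choice(cand)))
    gene_marker_map = {g: markers.marker_ids[i]
                       for g, i in zip(GENE_NAMES, gene_idx)}

    eff = gene_rng.standard_normal((len(GENE_NAMES), 3))
    eff /= np.sqrt((eff ** 2).sum(axis=0))
    eff *= np.asarray(scenario.dvr_sds)
    gene_codes = markers.codes[:, gene_idx]
    dvr_vals = _dvr_from_genes(gene_codes, eff, scenario.dvr_means,
                               scenario.dvr_sds)
    dvr_df = pd.DataFrame(dvr_vals, index=markers.line_ids,
                          columns=["alpha", "beta_p", "g"])

    weather: dict[str, WeatherSeries] = {}
    sowing_dates: dict[str, pd.Timestamp] = {}
    phenotypes: dict[str, pd.DataFrame] = {}
    growth_obs: dict[str, pd.DataFrame] = {}
    true_growth: dict[str, pd.DataFrame] = {}
    true_hi: dict[str, pd.Series] = {}
    true_heading: dict[str, pd.Series] = {}
    true_biomass: dict[str, pd.Series] = {}

    env_rng = scenario.rng("environments")
    for env in scenario.environments:
        w = sim_weather(env, env_rng)
        weather[env.env_id] = w
        sowing = pd.Timestamp(env.sowing_date)
        sowing_dates[env.env_id] = sowing

        # per-environment trait values: genetic + environment-level residual
        vals = {}
        for name, arch in scenario.traits.items():
            resid_sd = (arch.genetic_sd
                        * np.sqrt((1.0 - arch.h2) / arch.h2)
                        if arch.h2 < 1.0 else 0.0)
            resid = (env_rng.normal(0.0, resid_sd, scenario.n_lines)
                     if resid_sd > 0 else 0.0)
            vals[name] = np.clip(arch.mean + genetic[name].to_numpy()
                                 + resid, arch.lower, None)
        trait_df = pd.DataFrame(vals, index=markers.line_ids)

        heading, biomass = [], []
        obs_rows = []
        hu = heat_units(w, sowing)
        leaf_days = _leaf_obs_days(sowing)
        till_days = _till_obs_days(sowing)
        w0 = w.index_of(sowing)
        for li, line in enumerate(markers.line_ids):
            gp_line = GrowthParams(*(trait_df.loc[line, t]
                                     for t in GrowthParams.TRAITS))
            params = DVRParams(*dvr_df.loc[line])
            res = simulate_dvs_heading(params, w, sowing, cardinals)
            if not res.headed:
                raise RuntimeError(f"line {line} in {env.env_id} never "
                                   "headed; widen the season")
            heading.append(res.heading_day)
            sim = simulate_biomass(gp_line, res.heading_day, w, sowing,
                                   constants)
            biomass.append(sim.bm_tsg)
            leaf_curve, till_curve = growth_curves(
                gp_line, hu, constants.tiller_hu_threshold)
            for d in leaf_days:
                i = w.index_of(d) - w0
                noise = (env_rng.normal(0, scenario.obs_sigma_leaf)
                         if scenario.obs_sigma_leaf > 0 else 0.0)
                obs_rows.append((line, d.date(), "leaf_age",
                                 max(0.0, leaf_curve[i] + noise)))
            for d in till_days:
                i = w.index_of(d) - w0
                noise = (env_rng.normal(0, scenario.obs_sigma_till)
                         if scenario.obs_sigma_till > 0 else 0.0)
                obs_rows.append((line, d.date(), "tillers",
                                 max(0.0, till_curve[i] + noise)))

        heading = np.array(heading)
        bm_true = scenario.tau_true * np.array(biomass)
        if scenario.biomass_env_sigma > 0:
            bm_obs = bm_true * np.exp(env_rng.normal(
                0.0, scenario.biomass_env_sigma, scenario.n_lines))
        else:
            bm_obs = bm_true.copy()
        if scenario.heading_noise_days > 0:
            heading_obs = heading + env_rng.integers(
                -scenario.heading_noise_days,
                scenario.heading_noise_days + 1, scenario.n_lines)
        else:
            heading_obs = heading.copy()

        pheno = trait_df.copy()
        pheno["heading_day"] = heading_obs
        pheno["biomass"] = bm_obs
        pheno.index.name = "line"
        phenotypes[env.env_id] = pheno
        growth_obs[env.env_id] = pd.DataFrame(
            obs_rows, columns=["line", "date", "trait", "value"])
        true_growth[env.env_id] = trait_df[list(GrowthParams.TRAITS)]
        true_hi[env.env_id] = trait_df["harvest_index"]
        true_heading[env.env_id] = pd.Series(heading,
                                             index=markers.line_ids)
        true_biomass[env.env_id] = pd.Series(bm_true,
                                             index=markers.line_ids)

    panel_codes, panel_dvr = sim_met_panel(scenario, eff,
                                           scenario.rng("panel"))
    met = sim_met_trials(panel_dvr, scenario, scenario.rng("met"),
                         cardinals)

    ds = Dataset(markers, phenotypes, growth_obs, weather, met,
                 gene_marker_map, sowing_dates)
    ds.validate()
    truth = TrueParams(true_growth, dvr_df, true_hi, true_heading,
                       true_biomass, genetic,
                       pd.DataFrame(eff, index=list(GENE_NAMES),
                                    columns=["alpha", "beta_p", "g"]),
                       panel_codes, panel_dvr)
    return ds, truth
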