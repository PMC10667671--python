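"""Synthetic reservoir time-series generator.

Emulates a year-long, ~10-day-interval sampling campaign at two depths
(surface, bottom) of a deep monomictic reservoir that undergoes one
complete water-mixing event: 34 visits per depth split into
before (14) / mixing (11) / after (9) periods.

What is simulated, per depth:

* a latent total microeukaryote load (18S copies per mL) that crashes
  by ``crash_multiplier`` during mixing, returns to its pre-mixing mean
  where ``recovery`` is true (surface) and remains depressed and
  erratic where it is false (bottom);
* a taxon pool of core (high occupancy, high abundance), intermediate
  and satellite (sporadic, low abundance) taxa whose relative
  composition shifts during mixing (taxa are mixing-suppressed,
  mixing-favoured or neutral) and either reverts (surface) or stays in
  the altered state (bottom);
* sequencing counts drawn multinomially from the latent composition at
  a fixed depth, and qPCR totals equal to the latent load times
  log-normal measurement noise — separating compositional sampling
  from total-load measurement;
* environmental drivers with the matching trajectories (surface
  temperature rebounds, bottom oxygen pulses during mixing, bottom
  Chl-a/TN/TP decline after mixing) and water-column temperature
  profiles that are thermally stratified outside the mixing period and
  vertically uniform within it.

Effect sizes are generator parameters chosen to encode this qualitative
structure; see the methods note for the rationale behind each default.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .community import CommunityTable
from .hydrology import TemperatureProfile

DEPTHS = ("surface", "bottom")

# latent-load geometry (natural-log scale)
_LOG_BASE_TOTAL = np.log(1e6)  # 1e6 copies/mL, typical for 18S qPCR
_SD_LOG_STABLE = 0.15  # before, and after at recovering depths
_SD_LOG_MIXING = 0.30
_SD_LOG_ALTERED = 0.25  # after, at non-recovering depths
_ALTERED_DRIFT = -0.1  # continued per-sample log decline when unrecovered
_ALTERED_PULSE = np.log(25.0)  # one boom-bust pulse mid-way through 'after'

# taxon pool
_CORE_LOG_WEIGHT = np.log(20.0)
_INTERMEDIATE_LOG_WEIGHT = np.log(1.5)
_SATELLITE_LOG_WEIGHT = np.log(0.3)
_WEIGHT_SD = {"core": 1.0, "intermediate": 1.0, "satellite": 1.3}
_PRESENCE = {"core": 1.0, "intermediate": 0.62, "satellite": 0.25}
# mixing response: multiplicative shift of a taxon's weight during mixing;
# 'down' taxa additionally go locally extinct in part of the mixing samples.
# Core taxa decline less steeply than sporadic taxa (they persist, by
# definition, even through the disturbance)
_RESPONSE_MULT = {"down": 0.02, "neutral": 1.0, "up": 8.0}
_CORE_DOWN_MULT = 0.1
_RESPONSE_PROBS = (0.4, 0.4, 0.2)
_DOWN_DISTURBED_PRESENCE = 0.55
_JITTER_SD = {"surface": 0.45, "bottom": 0.2}  # per-sample composition noise
# shared per-sample log-factor within a response group: taxa that respond
# alike also fluctuate together, which is what co-occurrence edges detect
_GROUP_FACTOR_SD = 0.5
_FACTOR_LOADING_SD = 0.2
# satellite guilds: blocks of sporadic taxa sharing presence windows and a
# common magnitude factor (shared-niche dynamics)
_GUILD_SIZE = 10
_N_GUILDS = 12
_GUILD_PRESENCE_RANGE = (0.25, 0.45)
_GUILD_MEMBER_P = 0.9  # presence of a member when its guild window is open
_GUILD_FACTOR_SD = 0.8


@dataclass(frozen=True)
class ScenarioConfig:
    """Design of one synthetic campaign.

    ``period_sizes`` must sum to ``n_timepoints_per_depth``;
    ``crash_multiplier`` in (0, 1] scales the latent total load during
    mixing; ``recovery`` says per depth whether the load (and the
    composition) returns to its pre-mixing state afterwards.
    """

    n_timepoints_per_depth: int = 34
    period_sizes: tuple = (14, 11, 9)
    n_core_taxa: int = 40
    n_intermediate_taxa: int = 60
    n_satellite_taxa: int = 400
    depth_layers: tuple = DEPTHS
    crash_multiplier: float = 0.2
    recovery: dict = field(
        default_factory=lambda: {"surface": True, "bottom": False}
    )
    seed: int = 0
    sequencing_depth: int = 20_000
    qpcr_noise_cv: float = 0.1
    origin_date: str = "2015-07-01"
    sampling_interval_days: int = 10

    def __post_init__(self):
        if sum(self.period_sizes) != self.n_timepoints_per_depth:
            raise ValueError(
                f"period sizes {self.period_sizes} do not sum to "
                f"{self.n_timepoints_per_depth}"
            )
        if len(self.period_sizes) != 3 or any(s < 0 for s in self.period_sizes):
            raise ValueError("period_sizes must be three non-negative integers")
        if not 0 < self.crash_multiplier <= 1:
            raise ValueError("crash_multiplier must be in (0, 1]")
        if self.sequencing_depth <= 0:
            raise ValueError("sequencing_depth must be positive")
        if self.qpcr_noise_cv <= 0:
            raise ValueError("qpcr_noise_cv must be positive")
        for d in self.depth_layers:
            if d not in self.recovery:
                raise ValueError(f"recovery flag missing for depth {d!r}")

    def periods(self) -> np.ndarray:
        nb, nm, na = self.period_sizes
        return np.array(["before"] * nb + ["mixing"] * nm + ["after"] * na)

    def dates(self) -> pd.DatetimeIndex:
        return pd.date_range(
            self.origin_date,
            periods=self.n_timepoints_per_depth,
            freq=f"{self.sampling_interval_days}D",
        )

    def sample_ids(self, depth: str) -> list[str]:
        prefix = {"surface": "S", "bottom": "B"}.get(depth, depth[:1].upper())
        return [f"{prefix}{i:02d}" for i in range(1, self.n_timepoints_per_depth + 1)]


@dataclass
class SyntheticDataset:
    """All inputs of the analysis plus the generating truth."""

    community: dict  # depth -> CommunityTable
    qpcr: pd.Series  # copies/mL per sample id
    environment: pd.DataFrame  # per sample id: depth, date, period, variables
    profiles: pd.DataFrame  # visit_id, depth_m, temperature_C
    truth: dict


def _rng_for(config: ScenarioConfig, stream: str) -> np.random.Generator:
    # crc32 gives a process-independent stream offset (str hash is salted)
    return np.random.default_rng([config.seed, zlib.crc32(stream.encode())])


def _lognorm_sigma(cv: float) -> float:
    return float(np.sqrt(np.log1p(cv**2)))


def _latent_totals(config: ScenarioConfig, depth: str, rng) -> np.ndarray:
    periods = config.periods()
    log_t = np.empty(len(periods))
    crash = np.log(config.crash_multiplier)
    after_i = 0
    for i, p in enumerate(periods):
        if p == "before":
            log_t[i] = rng.normal(_LOG_BASE_TOTAL, _SD_LOG_STABLE)
        elif p == "mixing":
            log_t[i] = rng.normal(_LOG_BASE_TOTAL + crash, _SD_LOG_MIXING)
        elif config.recovery[depth]:
            log_t[i] = rng.normal(_LOG_BASE_TOTAL, _SD_LOG_STABLE)
        else:
            # unrecovered: depressed, drifting, with one boom-bust pulse
            # mid-way through the after period (erratic regime)
            n_after = int(np.sum(periods == "after"))
            pulse = _ALTERED_PULSE if after_i == n_after // 2 else 0.0
            log_t[i] = rng.normal(
                _LOG_BASE_TOTAL + crash + _ALTERED_DRIFT * after_i + pulse,
                _SD_LOG_ALTERED,
            )
            after_i += 1
    return np.exp(log_t)


def _taxon_pool(config: ScenarioConfig, rng) -> pd.DataFrame:
    rows = []
    specs = [
        ("core", config.n_core_taxa, _CORE_LOG_WEIGHT),
        ("intermediate", config.n_intermediate_taxa, _INTERMEDIATE_LOG_WEIGHT),
        ("satellite", config.n_satellite_taxa, _SATELLITE_LOG_WEIGHT),
    ]
    responses = list(_RESPONSE_MULT)
    for pool, n, logw in specs:
        for k in range(n):
            resp = responses[rng.choice(3, p=_RESPONSE_PROBS)]
            guild = -1
            if pool == "satellite" and k < _GUILD_SIZE * _N_GUILDS:
                guild = k // _GUILD_SIZE
            rows.append(
                {
                    "taxon_id": f"{pool[:3]}_{k + 1:04d}",
                    "pool": pool,
                    "weight": float(
                        np.exp(rng.normal(logw, _WEIGHT_SD[pool]))
                    ),
                    "response": resp,
                    "mixing_mult": (
                        _CORE_DOWN_MULT
                        if resp == "down" and pool == "core"
                        else _RESPONSE_MULT[resp]
                    )
                    * float(np.exp(rng.normal(0, 0.1))),
                    "guild": guild,
                    "factor_loading": float(rng.normal(1.0, _FACTOR_LOADING_SD)),
                }
            )
    return pd.DataFrame(rows).set_index("taxon_id")


def _community_for_depth(
    config: ScenarioConfig, depth: str, pool: pd.DataFrame, rng
) -> tuple[CommunityTable, pd.DataFrame]:
    periods = config.periods()
    n_samp = len(periods)
    taxa = pool.index
    w = pool["weight"].to_numpy()
    mix_mult = pool["mixing_mult"].to_numpy()
    presence_p = pool["pool"].map(_PRESENCE).to_numpy()
    loading = pool["factor_loading"].to_numpy()
    guild = pool["guild"].to_numpy()
    jitter_sd = _JITTER_SD.get(depth, 0.3)

    responses = list(_RESPONSE_MULT)
    resp_idx = pool["response"].map({r: k for k, r in enumerate(responses)}).to_numpy()
    group_factor = rng.normal(0, _GROUP_FACTOR_SD, (n_samp, len(responses)))
    n_guilds = int(guild.max()) + 1 if (guild >= 0).any() else 0
    guild_p = rng.uniform(*_GUILD_PRESENCE_RANGE, n_guilds)
    guild_open = rng.random((n_samp, n_guilds)) < guild_p
    guild_factor = rng.normal(0, _GUILD_FACTOR_SD, (n_samp, n_guilds))

    counts = np.zeros((n_samp, len(taxa)), dtype=np.int64)
    latent_rel = np.zeros_like(counts, dtype=float)
    guilded = guild >= 0
    down = (pool["response"] == "down").to_numpy()
    up = (pool["response"] == "up").to_numpy()
    # at a non-recovering depth the after period is a third state, not a
    # prolonged mixing state: suppressed taxa stay suppressed, but the
    # mixing-favoured bloom fades most of the way back
    altered_mult = np.where(up, mix_mult**0.25, mix_mult)
    for i, p in enumerate(periods):
        if p == "mixing":
            mult = mix_mult
        elif p == "after" and not config.recovery[depth]:
            mult = altered_mult
        else:
            mult = 1.0
        p_eff = presence_p.copy()
        if p == "mixing":
            # detection-level dropout of suppressed taxa while the water
            # column is mixed; afterwards persistence of the altered state
            # is carried by the weight multiplier, not by local extinction
            p_eff[down] = p_eff[down] * _DOWN_DISTURBED_PRESENCE
        present = rng.random(len(taxa)) < p_eff
        present[guilded] = guild_open[i, guild[guilded]] & (
            rng.random(guilded.sum()) < _GUILD_MEMBER_P
        )
        shared_log = group_factor[i, resp_idx].copy()
        shared_log[guilded] += guild_factor[i, guild[guilded]]
        lam = (
            w
            * mult
            * present
            * np.exp(loading * shared_log)
            * np.exp(rng.normal(0, jitter_sd, len(taxa)))
        )
        if lam.sum() == 0:
            lam[:] = 1.0
        rel = lam / lam.sum()
        latent_rel[i] = rel
        counts[i] = rng.multinomial(config.sequencing_depth, rel)

    ids = config.sample_ids(depth)
    meta = pd.DataFrame(
        {"depth": depth, "date": config.dates(), "period": periods}, index=ids
    )
    table = CommunityTable(pd.DataFrame(counts, index=ids, columns=taxa), meta)
    latent = pd.DataFrame(latent_rel, index=ids, columns=taxa)
    return table, latent


# environmental trajectories: per depth, per period (mean, SD); surface WT is
# a piecewise-linear seasonal ramp instead (see _surface_wt)
_ENV_DESIGN = {
    "surface": {
        "DO": ((8.5, 0.5), (9.5, 0.6), (8.5, 0.5)),
        "pH": ((7.8, 0.2), (7.5, 0.15), (7.8, 0.2)),
        "Chla": ((12.0, 4.0), (4.0, 1.5), (12.0, 4.0)),
        "TC": ((12.0, 1.0), (12.5, 1.0), (12.0, 1.0)),
        "TN": ((0.9, 0.1), (1.0, 0.1), (0.9, 0.1)),
        "NH4": ((0.10, 0.03), (0.12, 0.03), (0.10, 0.03)),
        "NO3": ((0.30, 0.06), (0.35, 0.06), (0.30, 0.06)),
        "NO2": ((0.020, 0.008), (0.025, 0.008), (0.020, 0.008)),
        "TP": ((0.050, 0.008), (0.055, 0.008), (0.050, 0.008)),
        "PO4": ((0.020, 0.005), (0.022, 0.005), (0.020, 0.005)),
    },
    # bottom waters do not restratify into their pre-mixing state: the
    # driver shifts that begin during mixing persist (or deepen) in the
    # after period, matching the persistently altered bottom community
    "bottom": {
        "WT": ((12.5, 0.4), (13.5, 1.0), (10.5, 0.4)),
        "DO": ((0.3, 0.15), (7.85, 0.8), (0.5, 0.2)),
        "pH": ((7.1, 0.15), (7.35, 0.15), (7.3, 0.15)),
        "Chla": ((5.0, 1.5), (2.5, 0.8), (1.5, 0.5)),
        "TC": ((13.0, 1.0), (12.5, 1.0), (13.0, 1.0)),
        "TN": ((1.2, 0.15), (0.9, 0.12), (0.7, 0.10)),
        "NH4": ((0.50, 0.08), (0.18, 0.05), (0.20, 0.05)),
        "NO3": ((0.20, 0.05), (0.55, 0.08), (0.45, 0.08)),
        "NO2": ((0.020, 0.008), (0.030, 0.008), (0.028, 0.008)),
        "TP": ((0.080, 0.010), (0.055, 0.009), (0.040, 0.008)),
        "PO4": ((0.020, 0.005), (0.014, 0.004), (0.010, 0.004)),
    },
}

ENV_VARIABLES = ("WT", "DO", "pH", "Chla", "TC", "TOC", "TN", "NH4", "NO3", "NO2", "TP", "PO4")


def _surface_wt(config: ScenarioConfig, rng) -> np.ndarray:
    """Piecewise-linear seasonal ramp: cools into mixing, rewarms after.

    Before and after cover near-mirrored temperature ranges so the two
    periods are statistically indistinguishable (the recovery claim).
    """
    nb, nm, na = config.period_sizes
    before = np.linspace(29.0, 17.0, nb)
    mixing = np.full(nm, 13.5)
    after = np.linspace(17.0, 28.0, na)
    wt = np.concatenate([before, mixing, after])
    return wt + rng.normal(0, 0.8, len(wt))


def _environment_for_depth(config: ScenarioConfig, depth: str, rng) -> pd.DataFrame:
    periods = config.periods()
    period_idx = {"before": 0, "mixing": 1, "after": 2}
    design = _ENV_DESIGN.get(depth, _ENV_DESIGN["bottom"])
    env = {}
    for var, spec in design.items():
        mu = np.array([spec[period_idx[p]][0] for p in periods])
        sd = np.array([spec[period_idx[p]][1] for p in periods])
        env[var] = np.maximum(mu + rng.normal(0, 1, len(periods)) * sd, 1e-3)
    if depth == "surface":
        env["WT"] = _surface_wt(config, rng)
    # TOC tracks TC (deliberately collinear: exercises the rho^2 filter)
    env["TOC"] = np.maximum(
        0.3 * env["TC"] + rng.normal(0, 0.15, len(periods)), 1e-3
    )
    ids = config.sample_ids(depth)
    out = pd.DataFrame(env, index=ids).loc[:, list(ENV_VARIABLES)]
    out.insert(0, "period", periods)
    out.insert(0, "date", config.dates())
    out.insert(0, "depth", depth)
    return out


def generate_temperature_profiles(
    config: ScenarioConfig,
    surface_wt: np.ndarray | None = None,
    bottom_wt: np.ndarray | None = None,
    max_depth_m: float = 30.0,
) -> pd.DataFrame:
    """Water-column temperature profiles, one per visit.

    Outside the mixing period the column is stratified: a sigmoidal
    thermocline around 8 m whose top-bottom contrast is at least 3 degC,
    giving a maximal 1-m gradient well above the 0.2 degC/m criterion.
    During mixing the column is vertically uniform within 0.1 degC.
    """
    rng = _rng_for(config, "profiles")
    periods = config.periods()
    n = len(periods)
    if surface_wt is None:
        surface_wt = _surface_wt(config, _rng_for(config, "profiles-wt"))
    if bottom_wt is None:
        spec = _ENV_DESIGN["bottom"]["WT"]
        idx = {"before": 0, "mixing": 1, "after": 2}
        bottom_wt = np.array([spec[idx[p]][0] for p in periods])
    z = np.arange(1.0, max_depth_m + 1.0)
    rows = []
    for i in range(n):
        if periods[i] == "mixing":
            t_mixed = surface_wt[i]
            temps = t_mixed + rng.uniform(-0.02, 0.02, len(z))
        else:
            ts = surface_wt[i]
            tb = min(bottom_wt[i], ts - 3.0)  # keep the column stratified
            temps = tb + (ts - tb) / (1 + np.exp((z - 8.0) / 1.2))
        for depth_m, t in zip(z, temps):
            rows.append((i + 1, float(depth_m), float(t)))
    return pd.DataFrame(rows, columns=["visit_id", "depth_m", "temperature_C"])


def profiles_by_visit(profiles: pd.DataFrame) -> dict[int, TemperatureProfile]:
    """Split a long-format profile table into per-visit profiles."""
    out = {}
    for vid, grp in profiles.groupby("visit_id"):
        grp = grp.sort_values("depth_m")
        out[int(vid)] = TemperatureProfile(
            grp["depth_m"].to_numpy(), grp["temperature_C"].to_numpy()
        )
    return out


def generate_scenario(config: ScenarioConfig | None = None) -> SyntheticDataset:
    """Generate a complete synthetic dataset for every configured depth.

    Identical configs (including the seed) give identical datasets.
    """
    if config is None:
        config = ScenarioConfig()
    pool = _taxon_pool(config, _rng_for(config, "pool"))
    community: dict = {}
    latent_totals: dict = {}
    latent_rel: dict = {}
    qpcr_parts = []
    env_parts = []
    for depth in config.depth_layers:
        rng = _rng_for(config, f"community-{depth}")
        table, latent = _community_for_depth(config, depth, pool, rng)
        community[depth] = table
        latent_rel[depth] = latent
        totals = _latent_totals(config, depth, _rng_for(config, f"totals-{depth}"))
        latent_totals[depth] = pd.Series(totals, index=config.sample_ids(depth))
        sigma = _lognorm_sigma(config.qpcr_noise_cv)
        noise = np.exp(
            _rng_for(config, f"qpcr-{depth}").normal(0, sigma, len(totals))
        )
        qpcr_parts.append(pd.Series(totals * noise, index=config.sample_ids(depth)))
        env_parts.append(
            _environment_for_depth(config, depth, _rng_for(config, f"env-{depth}"))
        )
    environment = pd.concat(env_parts)
    surface_wt = (
        environment.loc[environment["depth"] == "surface", "WT"].to_numpy()
        if "surface" in config.depth_layers
        else None
    )
    bottom_wt = (
        environment.loc[environment["depth"] == "bottom", "WT"].to_numpy()
        if "bottom" in config.depth_layers
        else None
    )
    profiles = generate_temperature_profiles(config, surface_wt, bottom_wt)
    qpcr = pd.concat(qpcr_parts)
    qpcr.name = "copies_per_ml"
    qpcr.index.name = "sample_id"
    truth = {
        "config": config,
        "periods": config.periods(),
        "taxon_pool": pool,
        "latent_totals": latent_totals,
        "latent_relative_abundance": latent_rel,
    }
    return SyntheticDataset(community, qpcr, environment, profiles, truth)
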