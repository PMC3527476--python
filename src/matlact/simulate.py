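"""Synthetic Holstein herd generator with planted maternal-programming effects.

The generator emulates the structure of national milk-recording data that the
two-stage analysis assumes: a multi-generation half-sib pedigree, additive
genetic (co)variation, herd-year / year-region / age-at-first-parity
environmental effects, dam lactation histories with monthly test days,
conception timing calibrated so the days-in-milk (DIM) at conception have
mode 73 d with 80% of mass in [54, 160] d, somatic-cell counts with planted
mastitis episodes, and maternal-circumstance effects (lactation concurrence
group, dam yield decile, mastitis exposure, and an optional genetic-merit x
concurrence interaction) planted into three first-lactation traits:

* ``MY``  -- 305-d standardized milk yield, kg
* ``FP``  -- milk fat/protein ratio, percent scale
* ``DIM`` -- lifetime days in milk (functional-longevity proxy), d

Every planted quantity is exported as ground truth so the full pipeline is
testable by parameter recovery without any external data.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .pedigree import Pedigree, inbreeding, validate_and_order

TRAITS = ("MY", "FP", "DIM")

#: Maternal-effect sizes reported in the literature for Spanish Holstein,
#: used as the planted ground truth of the recovery preset.  Lactation-group
#: effects are relative to gestation in a non-lactating dam (group 0).
REPORTED_EFFECTS: dict[str, dict] = {
    "lact_group": {
        "MY": (0.0, -18.0, -47.0, -91.0),
        "DIM": (0.0, -23.0, -15.0, -9.0),
        "FP": (0.0, 0.49, 0.36, 0.40),
    },
    "mastitis": {"MY": -18.0, "DIM": -11.0, "FP": 0.0},
    "merit_interaction": {"MY": -90.0, "DIM": 0.0, "FP": 0.0},
    "mastitis_incidence": 0.13,
}

#: Observation shares of the maternal-lactation groups 0/1/2/3+ in the
#: published Table-1 style summary (45,065 observations).
LACT_GROUP_SHARES = (0.3614, 0.3102, 0.2044, 0.1240)


# ---------------------------------------------------------------------------
# conception-timing distribution
# ---------------------------------------------------------------------------

def conception_dim_sigma(
    mode: float = 73.0,
    window: tuple[float, float] = (54.0, 160.0),
    mass: float = 0.80,
    shift: float = 30.0,
) -> tuple[float, float]:
    """Solve the shifted log-normal for DIM at conception.

    ``DIM = shift + LogNormal(mu, sigma)`` with the density mode at ``mode``
    (so ``mu = log(mode - shift) + sigma^2``) and probability ``mass`` inside
    ``window``.  The shift of 30 d stands for the voluntary waiting period
    before first insemination.  Returns ``(mu, sigma)``.

    Raises ``ValueError`` when the requested mode/window combination is
    unattainable.
    """
    lo, hi = window
    if not (shift < lo < mode < hi):
        raise ValueError("conception-DIM calibration infeasible: need shift < lo < mode < hi")
    m = mode - shift

    def mass_at(s: float) -> float:
        mu = np.log(m) + s * s
        return float(
            stats.norm.cdf((np.log(hi - shift) - mu) / s)
            - stats.norm.cdf((np.log(lo - shift) - mu) / s)
        )

    try:
        sigma = optimize.brentq(lambda s: mass_at(s) - mass, 1e-3, 3.0)
    except ValueError as err:  # no sign change: window too narrow/wide
        raise ValueError("conception-DIM calibration infeasible for requested mass") from err
    return float(np.log(m) + sigma * sigma), float(sigma)


def draw_conception_dim(
    rng: np.random.Generator,
    n: int,
    mode: float = 73.0,
    window: tuple[float, float] = (54.0, 160.0),
    mass: float = 0.80,
    shift: float = 30.0,
) -> np.ndarray:
    mu, sigma = conception_dim_sigma(mode, window, mass, shift)
    return shift + rng.lognormal(mu, sigma, size=n)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

def _zero_effects() -> dict[str, tuple]:
    return {t: (0.0, 0.0, 0.0, 0.0) for t in TRAITS}


@dataclass
class SimulationConfig:
    """All knobs of the generator.  Defaults are the recovery preset.

    The recovery preset plants the literature-reported lactation-group
    effects and keeps the genetic standard deviation at one fifth of the
    residual standard deviation so that posterior-mean breeding values
    absorb less than ~2% of any planted cow-level effect (the two-stage
    scheme's intrinsic shrinkage leakage grows with sigma_u/sigma_e).
    """

    # pedigree structure
    n_founders: int = 2000            # founder females
    sires_per_generation: int = 120
    n_generations: int = 3
    cows_per_generation: int = 10_000
    generation_sizes: tuple[int, ...] | None = (3000, 10_000, 10_000)

    # environment structure; herd count sized so herd-year cells hold ~50
    # cows (large commercial herds) — tiny cells would mechanically absorb
    # part of any cow-level signal into the herd-year estimates
    n_herds: int = 8
    n_regions: int = 3
    base_year: int = 2000
    # dam birth dates span this many years, emulating a long-running
    # recording scheme; a narrow span would confound maternal parity with
    # the cow's birth-year cohort and the year effects would then absorb
    # part of any maternal-circumstance signal
    recording_span_years: float = 15.0

    # trait scale
    mean: Mapping[str, float] = field(
        default_factory=lambda: {"MY": 8500.0, "FP": 118.0, "DIM": 1000.0}
    )
    sigma_u: Mapping[str, float] = field(
        default_factory=lambda: {"MY": 10.0, "FP": 0.015, "DIM": 3.0}
    )
    sigma_e: Mapping[str, float] = field(
        default_factory=lambda: {"MY": 100.0, "FP": 0.15, "DIM": 30.0}
    )
    herd_year_sd: Mapping[str, float] = field(
        default_factory=lambda: {"MY": 60.0, "FP": 0.08, "DIM": 15.0}
    )
    year_region_sd: Mapping[str, float] = field(
        default_factory=lambda: {"MY": 40.0, "FP": 0.05, "DIM": 10.0}
    )
    age_effect_sd: Mapping[str, float] = field(
        default_factory=lambda: {"MY": 30.0, "FP": 0.04, "DIM": 8.0}
    )

    # maternal circumstances
    lact_group_probs: tuple[float, float, float, float] = LACT_GROUP_SHARES
    conception_mode: float = 73.0
    conception_window: tuple[float, float] = (54.0, 160.0)
    conception_mass: float = 0.80
    conception_shift: float = 30.0
    mastitis_incidence: float = 0.13  # overall share of cows with exposed dams
    scc_threshold: float = 400.0      # 1000 cells/ml

    # planted effects (per trait); lact tuples are (group0, 1, 2, 3+)
    maternal_lact: Mapping[str, tuple] = field(
        default_factory=lambda: {t: tuple(REPORTED_EFFECTS["lact_group"][t]) for t in TRAITS}
    )
    maternal_yield: Mapping[str, tuple] = field(
        default_factory=lambda: {t: (0.0,) * 11 for t in TRAITS}
    )
    maternal_mastitis: Mapping[str, float] = field(
        default_factory=lambda: {t: 0.0 for t in TRAITS}
    )
    merit_interaction: Mapping[str, float] = field(
        default_factory=lambda: {t: 0.0 for t in TRAITS}
    )
    merit_interaction_quantile: float = 0.90

    # culling model: lifetime DIM depends on first-lactation milk
    milk_longevity_slope: float = 0.02  # d per kg of first-lactation MY
    lifespan_noise: str = "normal"      # or "exponential"

    # dam lactation-curve shape (Wood): y(t) ~ t^b * exp(-c t)
    wood_b: float = 0.25
    wood_c: float = 0.0035
    parity_yield_factor: tuple = (1.0, 1.10, 1.15, 1.15, 1.15)

    # records that exist only to exercise the record filters
    abortion_rate: float = 0.01
    low_yield_rate: float = 0.005

    seed: int = 20120

    def __post_init__(self) -> None:
        for t in TRAITS:
            if self.sigma_u[t] < 0 or self.sigma_e[t] <= 0:
                raise ValueError("variances must be positive")
        for p in (*self.lact_group_probs, self.mastitis_incidence,
                  self.abortion_rate, self.low_yield_rate):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")
        if abs(sum(self.lact_group_probs) - 1.0) > 1e-9:
            raise ValueError("lact_group_probs must sum to 1")
        for t in TRAITS:
            if self.maternal_lact[t][0] != 0.0 or self.maternal_yield[t][0] != 0.0:
                raise ValueError("planted effect for the reference level 0 must be 0")


def recovery_preset(**overrides) -> SimulationConfig:
    """The parameter-recovery study conditions (~10k cows, ~25k pedigree)."""
    return dataclasses.replace(SimulationConfig(), **overrides)


def smoke_preset(**overrides) -> SimulationConfig:
    """A miniature configuration for fast tests."""
    cfg = SimulationConfig(
        n_founders=150,
        sires_per_generation=15,
        n_generations=2,
        cows_per_generation=400,
        generation_sizes=(400, 400),
        n_herds=4,
    )
    return dataclasses.replace(cfg, **overrides)


def paper_scale_preset(**overrides) -> SimulationConfig:
    """Full-scale magnitudes (mean MY ~8,500 kg, sd ~1,550 kg, h^2 ~ 0.3)."""
    cfg = SimulationConfig(
        sigma_u={"MY": 850.0, "FP": 0.25, "DIM": 120.0},
        sigma_e={"MY": 1300.0, "FP": 0.38, "DIM": 330.0},
        herd_year_sd={"MY": 400.0, "FP": 0.10, "DIM": 60.0},
        year_region_sd={"MY": 250.0, "FP": 0.06, "DIM": 40.0},
        age_effect_sd={"MY": 150.0, "FP": 0.05, "DIM": 25.0},
        lifespan_noise="exponential",
    )
    return dataclasses.replace(cfg, **overrides)


# ---------------------------------------------------------------------------
# pedigree simulation
# ---------------------------------------------------------------------------

def simulate_pedigree(config: SimulationConfig) -> Pedigree:
    """Discrete-generation pedigree with reused sires (half-sib families).

    Generation 0 holds unrelated founders.  Every non-founder has a sire
    drawn from the previous generation's males and a dam from the previous
    generation's females.  Females of the final generation are the analysis
    cows; their dams are assigned bijectively (one recorded daughter per
    dam) so each cow has a well-defined maternal lactation history.
    """
    if config.n_founders < 2:
        raise ValueError("need at least 2 founders")
    rng = np.random.default_rng(config.seed)
    sizes = config.generation_sizes or (config.cows_per_generation,) * config.n_generations
    rows: list[tuple[str, str, str]] = []
    females = [f"G0F{i}" for i in range(config.n_founders)]
    males = [f"G0M{i}" for i in range(config.sires_per_generation)]
    rows += [(x, "0", "0") for x in females + males]
    for g, n_f in enumerate(sizes, start=1):
        last = g == len(sizes)
        new_f = [f"G{g}F{i}" for i in range(n_f)]
        new_m = [] if last else [f"G{g}M{i}" for i in range(config.sires_per_generation)]
        if last:
            if len(females) < n_f:
                raise ValueError("final generation needs one distinct dam per cow")
            dams = list(rng.permutation(females)[:n_f])
        else:
            dams = [females[i] for i in rng.integers(0, len(females), n_f)]
        sires = [males[i] for i in rng.integers(0, len(males), n_f + len(new_m))]
        for k, ind in enumerate(new_f + new_m):
            dam = dams[k] if k < n_f else females[int(rng.integers(0, len(females)))]
            rows.append((ind, sires[k], dam))
        females, males = new_f, new_m
    return validate_and_order(rows)


def simulate_breeding_values(
    ped: Pedigree, sigma_u: Mapping[str, float], seed: int
) -> pd.DataFrame:
    """True breeding values per trait: founders ~ N(0, sigma_u^2); offspring
    are the parent average plus a Mendelian-sampling deviate with variance
    ``sigma_u^2 * (0.5 - 0.25 (F_sire + F_dam))`` (0.75/1.0 factors when one
    or both parents are unknown)."""
    rng = np.random.default_rng(seed)
    F = inbreeding(ped)
    n = len(ped)
    sire, dam = ped.sire, ped.dam
    ms_ratio = np.ones(n)
    both = (sire >= 0) & (dam >= 0)
    one_s = (sire >= 0) & (dam < 0)
    one_d = (sire < 0) & (dam >= 0)
    ms_ratio[both] = 0.5 - 0.25 * (F[sire[both]] + F[dam[both]])
    ms_ratio[one_s] = 0.75 - 0.25 * F[sire[one_s]]
    ms_ratio[one_d] = 0.75 - 0.25 * F[dam[one_d]]
    out = {}
    for t in TRAITS:
        su = float(sigma_u[t])
        z = rng.standard_normal(n) * su * np.sqrt(ms_ratio)
        u = np.zeros(n)
        for i in range(n):
            pa = 0.0
            if sire[i] >= 0:
                pa += 0.5 * u[sire[i]]
            if dam[i] >= 0:
                pa += 0.5 * u[dam[i]]
            u[i] = pa + z[i]
        out[t] = u if su > 0 else np.zeros(n)
    return pd.DataFrame(out, index=pd.Index(ped.ids, name="id"))


# ---------------------------------------------------------------------------
# record simulation
# ---------------------------------------------------------------------------

@dataclass
class GroundTruth:
    """Everything needed to score recovery of every pipeline estimate."""

    cows: pd.DataFrame          # per-cow true circumstance levels, u, flags
    planted: dict               # planted maternal effects per factor/trait
    fixed_effects: dict         # trait -> {factor -> {level: value}}
    variance_components: dict   # trait -> (sigma2_u, sigma2_e)
    decile_bounds: np.ndarray   # true dam daily-milk decile boundaries


def _wood_daily(dim: np.ndarray, total_305: np.ndarray, b: float, c: float) -> np.ndarray:
    """Daily yield at ``dim`` for a Wood-type curve scaled to a 305-d total."""
    t = np.arange(1.0, 306.0)
    norm = np.sum(t**b * np.exp(-c * t))
    return total_305 * (np.maximum(dim, 1.0) ** b * np.exp(-c * dim)) / norm


def simulate_records(
    ped: Pedigree, u: pd.DataFrame, config: SimulationConfig
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Compose cow phenotypes, dam test-day records and the ground truth.

    Returns ``(phenotypes, testdays, truth)``.  ``phenotypes`` has one row
    per analysis cow (final-generation female); ``testdays`` has the monthly
    dam milk-recording tests (kg and somatic cells) that the preprocessing
    stage uses to reconstruct each cow's maternal circumstances.
    """
    rng = np.random.default_rng(config.seed + 1)
    origin = np.datetime64(f"{config.base_year}-01-01")

    gmax = len(config.generation_sizes or [0] * config.n_generations)
    cow_ids = [e.individual_id for e in ped.entries
               if e.individual_id.startswith(f"G{gmax}F")]
    n = len(cow_ids)
    dam_ids = np.array([ped.entries[ped.rank(c)].dam_id for c in cow_ids])

    # --- maternal circumstance assignment -------------------------------
    lact_group = rng.choice(4, size=n, p=np.asarray(config.lact_group_probs))
    dam_parity = lact_group.copy()  # parity of the open lactation; 0 = heifer
    is3 = lact_group == 3
    dam_parity[is3] = rng.choice([3, 4, 5], size=int(is3.sum()), p=[0.6, 0.3, 0.1])

    conc_dim = np.zeros(n)
    lactating = lact_group > 0
    conc_dim[lactating] = draw_conception_dim(
        rng, int(lactating.sum()), config.conception_mode,
        config.conception_window, config.conception_mass, config.conception_shift,
    )

    # --- dam calendar ----------------------------------------------------
    # Conception dates are drawn uniformly over the recording window and the
    # dam's calving history is reconstructed backwards from them.  This is
    # the steady state of a recording scheme running for decades: the mix of
    # maternal parities is the same in every birth-year cohort, so maternal
    # circumstance is not confounded with the year effects (edge cohorts of
    # a forward construction would be nearly pure single-parity groups).
    span = max(config.recording_span_years * 365.25, 1.0)
    conception = rng.uniform(0.0, span, n)
    civ = np.clip(rng.normal(400.0, 30.0, (n, 6)), 330, 520)  # calving intervals
    lact_len = np.clip(civ - 60.0, 240, 400)  # lactation p ends before calving p+1
    cum = np.concatenate([np.zeros((n, 1)), np.cumsum(civ, axis=1)], axis=1)

    par_open = np.maximum(dam_parity - 1, 0)  # row index of the open lactation
    conc_dim = np.minimum(
        conc_dim, np.where(lactating, lact_len[np.arange(n), par_open] - 5.0, 0.0)
    )
    dam_first_calving = np.where(
        lactating,
        conception - conc_dim - cum[np.arange(n), par_open],
        conception + 280.0,  # group 0: the cow is the dam's first calf
    )
    calvings = dam_first_calving[:, None] + cum  # calving date of parities 1..7
    cow_birth = conception + 280.0

    # --- herds, ages, environmental levels ------------------------------
    herd = rng.integers(0, config.n_herds, n)
    region = herd % config.n_regions
    afp_mo = np.clip(rng.normal(26.7, 2.5, n), 22, 40)
    first_calving = cow_birth + afp_mo * 30.4
    birth_year = config.base_year + (cow_birth // 365.25).astype(int)
    calv_year = config.base_year + (first_calving // 365.25).astype(int)
    age_class = np.round(afp_mo).astype(int)
    herd_year = np.array([f"H{h:03d}_Y{y}" for h, y in zip(herd, calv_year)])
    year_region = np.array([f"Y{y}_R{r}" for y, r in zip(birth_year, region)])

    # --- dam production and yield deciles -------------------------------
    pf = np.asarray(config.parity_yield_factor)
    u_my_dam = u["MY"].reindex(dam_ids).to_numpy()
    dam_base_305 = (
        config.mean["MY"] + u_my_dam
        + rng.normal(0.0, config.sigma_e["MY"], n)
    )
    par_idx = np.clip(dam_parity - 1, 0, len(pf) - 1)
    dam_305_at_conc = dam_base_305 * pf[par_idx]
    daily_at_conc = np.zeros(n)
    daily_at_conc[lactating] = _wood_daily(
        conc_dim[lactating], dam_305_at_conc[lactating], config.wood_b, config.wood_c
    )
    bounds = np.percentile(daily_at_conc[lactating], np.arange(10, 100, 10))
    yield_group = np.zeros(n, dtype=int)
    yield_group[lactating] = np.searchsorted(bounds, daily_at_conc[lactating],
                                             side="left") + 1

    # --- mastitis exposure ----------------------------------------------
    p_lact = 1.0 - config.lact_group_probs[0]
    p_mast = min(config.mastitis_incidence / p_lact, 1.0) if p_lact > 0 else 0.0
    mastitis = np.zeros(n, dtype=int)
    mastitis[lactating] = rng.random(int(lactating.sum())) < p_mast
    # episode day inside [conception, conception + 220] and inside the lactation
    epi_hi = np.minimum(
        conc_dim + 220.0, lact_len[np.arange(n), np.maximum(dam_parity - 1, 0)] - 1.0
    )
    episode_dim = conc_dim + rng.random(n) * np.maximum(epi_hi - conc_dim, 1.0)

    # --- fixed-effect level values --------------------------------------
    fixed_effects: dict[str, dict[str, dict]] = {}
    for t in TRAITS:
        fixed_effects[t] = {
            "herd_year": {
                lv: rng.normal(0.0, config.herd_year_sd[t])
                for lv in sorted(set(herd_year))
            },
            "year_region": {
                lv: rng.normal(0.0, config.year_region_sd[t])
                for lv in sorted(set(year_region))
            },
            "age_class": {
                lv: rng.normal(0.0, config.age_effect_sd[t])
                for lv in sorted(set(age_class))
            },
        }

    # --- trait composition ----------------------------------------------
    u_cows = u.reindex(cow_ids)
    top_merit = (
        u_cows["MY"].to_numpy()
        >= np.quantile(u_cows["MY"].to_numpy(), config.merit_interaction_quantile)
    )
    y = {}
    for t in TRAITS:
        fe = fixed_effects[t]
        yt = (
            config.mean[t]
            + np.array([fe["herd_year"][lv] for lv in herd_year])
            + np.array([fe["year_region"][lv] for lv in year_region])
            + np.array([fe["age_class"][lv] for lv in age_class])
            + u_cows[t].to_numpy()
            + np.asarray(config.maternal_lact[t])[lact_group]
            + np.asarray(config.maternal_yield[t])[yield_group]
            + config.maternal_mastitis[t] * mastitis
            + config.merit_interaction[t] * (top_merit & lactating)
        )
        if t == "DIM":
            noise = (
                rng.exponential(config.sigma_e[t], n) - config.sigma_e[t]
                if config.lifespan_noise == "exponential"
                else rng.normal(0.0, config.sigma_e[t], n)
            )
            yt = yt + noise + config.milk_longevity_slope * (y["MY"] - config.mean["MY"])
        else:
            yt = yt + rng.normal(0.0, config.sigma_e[t], n)
        y[t] = yt

    # --- first-lactation bookkeeping and filter-exercise rows -----------
    lact1_len = np.clip(rng.normal(330.0, 25.0, n), 200.0, 450.0)
    milk_cum = y["MY"] * lact1_len / 305.0
    low = rng.random(n) < config.low_yield_rate
    milk_cum[low] = rng.uniform(300.0, 999.0, int(low.sum()))
    abortion = (rng.random(n) < config.abortion_rate).astype(int)
    dim_life = np.maximum(y["DIM"], lact1_len)

    phenotypes = pd.DataFrame(
        {
            "cow_id": cow_ids,
            "dam_id": dam_ids,
            "herd": herd,
            "region": region,
            "herd_year": herd_year,
            "year_region": year_region,
            "age_first_parity_mo": np.round(afp_mo, 2),
            "age_class": age_class,
            "birth_date": origin + cow_birth.astype("timedelta64[D]"),
            "conception_date": origin + conception.astype("timedelta64[D]"),
            "first_calving_date": origin + first_calving.astype("timedelta64[D]"),
            "lactation_length_d": np.round(lact1_len, 1),
            "milk_cum_kg": np.round(milk_cum, 1),
            "MY": y["MY"],
            "FP": y["FP"],
            "DIM_life": dim_life,
            "abortion_before_first": abortion,
        }
    )

    testdays = _dam_testdays(
        rng, config, origin, cow_ids, dam_ids, dam_parity, calvings, lact_len,
        dam_base_305, mastitis, episode_dim, np.maximum(dam_parity, 1),
    )

    truth_cows = pd.DataFrame(
        {
            "cow_id": cow_ids,
            "lact_group": lact_group,
            "yield_group": yield_group,
            "mastitis": mastitis,
            "conception_dim": np.where(lactating, conc_dim, np.nan),
            "dam_daily_at_conception": np.where(lactating, daily_at_conc, np.nan),
            "top_merit": top_merit.astype(int),
            **{f"u_{t}": u_cows[t].to_numpy() for t in TRAITS},
        }
    )
    truth = GroundTruth(
        cows=truth_cows,
        planted={
            "lact_group": {t: tuple(config.maternal_lact[t]) for t in TRAITS},
            "yield_group": {t: tuple(config.maternal_yield[t]) for t in TRAITS},
            "mastitis": dict(config.maternal_mastitis),
            "merit_interaction": dict(config.merit_interaction),
        },
        fixed_effects=fixed_effects,
        variance_components={
            t: (float(config.sigma_u[t]) ** 2, float(config.sigma_e[t]) ** 2)
            for t in TRAITS
        },
        decile_bounds=bounds,
    )
    return phenotypes, testdays, truth


def _dam_testdays(
    rng, config, origin, cow_ids, dam_ids, dam_parity, calvings, lact_len,
    dam_base_305, mastitis, episode_dim, n_parities,
):
    """Monthly milk-recording tests for each dam lactation.

    SCC baseline is log-normal around 100 (x1000 cells/ml); a planted
    mastitis episode inserts one test above the clinical threshold inside
    the cow's gestation window.
    """
    pf = np.asarray(config.parity_yield_factor)
    frames = []
    n = len(cow_ids)
    for p in range(1, int(n_parities.max()) + 1):
        has = n_parities >= p
        idx = np.nonzero(has)[0]
        if idx.size == 0:
            continue
        length = lact_len[idx, p - 1]
        calv = calvings[idx, p - 1]
        total = dam_base_305[idx] * pf[min(p - 1, len(pf) - 1)]
        n_tests = np.maximum(((length - 15.0) // 30.0).astype(int) + 1, 1)
        reps = np.repeat(np.arange(idx.size), n_tests)
        test_no = np.concatenate([np.arange(k) for k in n_tests])
        dim = 15.0 + 30.0 * test_no
        milk = _wood_daily(dim, total[reps], config.wood_b, config.wood_c)
        milk = np.maximum(milk + rng.normal(0.0, 0.8, milk.size), 0.5)
        scc = rng.lognormal(np.log(100.0), 0.40, milk.size)
        frames.append(
            pd.DataFrame(
                {
                    "dam_id": dam_ids[idx][reps],
                    "parity": p,
                    "calving_date": origin + calv[reps].astype("timedelta64[D]"),
                    "dryoff_date": origin + (calv[reps] + length[reps]).astype("timedelta64[D]"),
                    "test_date": origin + (calv[reps] + dim).astype("timedelta64[D]"),
                    "dim": dim,
                    "milk_kg": np.round(milk, 2),
                    "scc_1000": np.round(scc, 1),
                }
            )
        )
    td = pd.concat(frames, ignore_index=True)

    # planted mastitis spike: one extra test above threshold in the window
    mi = np.nonzero(mastitis == 1)[0]
    if mi.size:
        p_open = np.maximum(dam_parity[mi], 1)
        calv = calvings[mi, p_open - 1]
        dim = episode_dim[mi]
        spike = pd.DataFrame(
            {
                "dam_id": dam_ids[mi],
                "parity": p_open,
                "calving_date": origin + calv.astype("timedelta64[D]"),
                "dryoff_date": origin + (calv + lact_len[mi, p_open - 1]).astype("timedelta64[D]"),
                "test_date": origin + (calv + dim).astype("timedelta64[D]"),
                "dim": np.round(dim, 1),
                "milk_kg": np.round(
                    np.maximum(
                        _wood_daily(dim, dam_base_305[mi], config.wood_b, config.wood_c)
                        * 0.8, 0.5,
                    ), 2,
                ),
                "scc_1000": np.round(rng.uniform(500.0, 1500.0, mi.size), 1),
            }
        )
        td = pd.concat([td, spike], ignore_index=True)
    return td.sort_values(["dam_id", "parity", "dim"], kind="stable").reset_index(drop=True)


@dataclass
class SimResult:
    pedigree: Pedigree
    phenotypes: pd.DataFrame
    testdays: pd.DataFrame
    truth: GroundTruth
    breeding_values: pd.DataFrame
    config: SimulationConfig


def simulate_herd(config: SimulationConfig | None = None) -> SimResult:
    """Run the full generator: pedigree, breeding values, records, truth."""
    config = config or SimulationConfig()
    ped = simulate_pedigree(config)
    u = simulate_breeding_values(ped, config.sigma_u, config.seed + 7)
    phenotypes, testdays, truth = simulate_records(ped, u, config)
    return SimResult(ped, phenotypes, testdays, truth, u, config)
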