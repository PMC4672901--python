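"""Synthetic review datasets with the structure the analysis assumes.

Two generators are provided:

* :func:`simulate_dataset` builds a full iteration-level corpus —
  study-clustered effects, driver effects proportional to cell counts,
  moderator effects, shared-control blocks and truncated-normal
  iteration noise — then summarises each arm to a mean/SEM record.
* :func:`simulate_frame` draws effects directly from the regression
  model (given weights and design), which is the generator of choice for
  checking that the variance-component estimators are unbiased.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .corpus import Dataset, ExperimentRecord
from .regression import ModelFrame, _scaled_cov

__all__ = [
    "SimConfig",
    "SimTruth",
    "DEFAULT_DRIVERS",
    "simulate_iterations",
    "simulate_dataset",
    "simulate_frame",
]

DEFAULT_DRIVERS = (
    ("drv-100", 100, "gamma"),
    ("drv-350", 350, "alphaprime_betaprime"),
    ("drv-600", 600, "alphabeta"),
    ("drv-850", 850, "gamma"),
    ("drv-1100", 1100, "alphabeta_gamma"),
    ("drv-1400", 1400, "alphabeta"),
    ("drv-1700", 1700, "all_lobes"),
    ("drv-2000", 2000, "alphabeta_gamma"),
)

_ODOR_PAIRS = ("MCH-OCT", "EA-IA", "MCH-BEN", "OCT-BEN")
_DELAYS = (0.0, 2.0, 3.0)


@dataclass(frozen=True)
class SimConfig:
    n_studies: int = 8
    experiments_per_study: tuple[int, int] = (6, 14)
    iterations_per_arm: tuple[int, int] = (3, 24)
    control_pi_mean: float = 0.75
    control_pi_sd: float = 0.05
    tau: float = 5.0  # study-cluster SD, learning-percent scale
    rho: float = 0.3  # within shared-control-block residual correlation
    sigma_effect: float = 8.0  # extra effect-level residual SD (percent)
    sigma_iter: float = 0.12  # iteration-level PI SD
    drivers: tuple = DEFAULT_DRIVERS
    slope_per_cell: float = 0.02  # percent learning per Kenyon cell
    mutant_learning: float = 40.0
    heat_effect: float = -17.0
    time_effect: float = 0.0  # percent per minute of delay
    benzaldehyde_effect: float = 0.0  # percent if the odor pair has BEN
    include_mutants: bool = True  # emit mutant-alone records per study
    include_shi: bool = True  # emit heat-control + inactivation records
    seed: int = 0

    def __post_init__(self):
        fails = []
        if self.tau < 0 or self.sigma_iter < 0 or self.sigma_effect < 0:
            fails.append("SDs must be >= 0")
        if not 0.0 <= self.rho <= 0.99:
            fails.append(f"rho must lie in [0, 0.99], got {self.rho}")
        if self.iterations_per_arm[0] < 2:
            fails.append("need >= 2 iterations per arm")
        if self.experiments_per_study[0] < 1 or self.n_studies < 1:
            fails.append("need >= 1 study with >= 1 experiment")
        if not self.drivers:
            fails.append("need at least one driver")
        if fails:
            raise ValueError("; ".join(fails))

    @property
    def cell_counts(self) -> dict:
        return {name: count for name, count, _ in self.drivers}


@dataclass
class SimTruth:
    config: dict
    study_effects: dict = field(default_factory=dict)
    experiment_effects: list = field(default_factory=list)
    driver_effects: dict = field(default_factory=dict)


def simulate_iterations(mu: float, sigma: float, n: int, rng) -> tuple[float, float]:
    """Mean and SEM of ``n`` truncated-normal PI draws in [-1, 1]."""
    if not -1.0 <= mu <= 1.0:
        raise ValueError(f"PI mean must lie in [-1, 1], got {mu}")
    if n < 2:
        raise ValueError(f"need n >= 2 iterations, got {n}")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    if sigma == 0.0:
        return mu, 0.0
    a, b = (-1.0 - mu) / sigma, (1.0 - mu) / sigma
    draws = stats.truncnorm.rvs(a, b, loc=mu, scale=sigma, size=n, random_state=rng)
    return float(np.mean(draws)), float(np.std(draws, ddof=1) / math.sqrt(n))


def simulate_dataset(cfg: SimConfig) -> tuple[Dataset, SimTruth]:
    """Generate a summary-level corpus plus its ground truth.

    Within each study, experiments are paired into shared-control blocks
    whose members reuse one simulated control arm; the configured rho is
    induced by a block-level effect component with variance
    rho * sigma_effect^2 (individual component (1-rho) * sigma_effect^2).
    Deterministic under the config seed.
    """
    rng = np.random.default_rng(cfg.seed)
    truth = SimTruth(config=asdict(cfg))
    records = []
    driver_cycle = 0
    lo_e, hi_e = cfg.experiments_per_study
    lo_it, hi_it = cfg.iterations_per_arm
    shi_drivers = [
        d for d in cfg.drivers if d[2] in ("alphabeta", "alphabeta_gamma")
    ]

    def draw_control():
        n_ctrl = int(rng.integers(lo_it, hi_it + 1))
        m_ctrl_true = float(
            np.clip(rng.normal(cfg.control_pi_mean, cfg.control_pi_sd), 0.1, 0.95)
        )
        mean, sem = simulate_iterations(m_ctrl_true, cfg.sigma_iter, n_ctrl, rng)
        return n_ctrl, m_ctrl_true, mean, sem

    def emit(study, b_i, panel, genotype_exp, genotype_ctrl, intervention,
             lobe, driver, core_learning, block_id, ctrl, extra_noise):
        n_ctrl, m_ctrl_true, ctrl_mean, ctrl_sem = ctrl
        delay = float(rng.choice(_DELAYS))
        odor = str(rng.choice(_ODOR_PAIRS))
        ben = "BEN" in odor
        learning = (
            core_learning
            + cfg.time_effect * delay
            + (cfg.benzaldehyde_effect if ben else 0.0)
            + b_i
            + extra_noise
        )
        pct = learning - 100.0
        m_exp_true = float(np.clip(m_ctrl_true * (1.0 + pct / 100.0), -1.0, 1.0))
        n_exp = int(rng.integers(lo_it, hi_it + 1))
        exp_mean, exp_sem = simulate_iterations(m_exp_true, cfg.sigma_iter, n_exp, rng)
        records.append(
            ExperimentRecord(
                study_id=study,
                figure_panel=panel,
                genotype_exp=genotype_exp,
                genotype_ctrl=genotype_ctrl,
                n_exp=n_exp,
                n_ctrl=n_ctrl,
                pi_exp_mean=exp_mean,
                pi_exp_sem=exp_sem,
                pi_ctrl_mean=ctrl_mean,
                pi_ctrl_sem=ctrl_sem,
                intervention=intervention,
                lobe_category=lobe,
                driver=driver,
                odor_pair=odor,
                benzaldehyde=ben,
                temperature_c=25.0 if intervention.startswith("rut") else 32.0,
                shock_v=90.0,
                current_type="DC",
                delay_min=delay,
                rh_pct=None,
                shared_control_id=block_id,
            )
        )
        truth.experiment_effects.append(
            {
                "study_id": study,
                "figure_panel": panel,
                "driver": driver,
                "intervention": intervention,
                "true_percent": float(pct),
                "observable_percent": float(100.0 * (m_exp_true / m_ctrl_true - 1.0)),
            }
        )

    for s in range(cfg.n_studies):
        study = f"sim-study-{s:02d}"
        b_i = rng.normal(0.0, cfg.tau)
        truth.study_effects[study] = float(b_i)
        n_rescue = int(rng.integers(lo_e, hi_e + 1))
        # every study cycles the full driver panel in its own random order,
        # so shared-control blocks pair different drivers across studies
        study_order = rng.permutation(len(cfg.drivers))
        # consecutive pairs form shared-control blocks; odd tail is unblocked
        k = 0
        block_no = 0
        while k < n_rescue:
            size = min(2, n_rescue - k)
            block_no += 1
            block_id = f"{study}-B{block_no}" if size >= 2 else None
            ctrl = draw_control()
            u_block = rng.normal(0.0, math.sqrt(cfg.rho) * cfg.sigma_effect)
            for _ in range(size):
                driver, cells, lobe = cfg.drivers[
                    study_order[driver_cycle % len(cfg.drivers)]
                ]
                driver_cycle += 1
                e_ind = rng.normal(0.0, math.sqrt(1.0 - cfg.rho) * cfg.sigma_effect)
                emit(
                    study, b_i, f"E{k + 1}", f"rut; {driver}; UAS-rut",
                    "wild type", "rut_rescue", lobe, driver,
                    cfg.mutant_learning + cfg.slope_per_cell * cells,
                    block_id, ctrl, u_block + e_ind,
                )
                k += 1
        if cfg.include_mutants:
            for allele in ("rut2080", "rut1"):
                emit(
                    study, b_i, f"M-{allele}", allele, "wild type",
                    "rut_mutant", "none", None, cfg.mutant_learning,
                    None, draw_control(), rng.normal(0.0, cfg.sigma_effect),
                )
        if cfg.include_shi:
            emit(
                study, b_i, "HC", "w; UAS-shi/+", "w; UAS-shi/+",
                "heat_control", "none", None, 100.0 + cfg.heat_effect,
                None, draw_control(), rng.normal(0.0, cfg.sigma_effect),
            )
            for j in range(2):
                driver, cells, lobe = shi_drivers[
                    (2 * s + j) % max(1, len(shi_drivers))
                ]
                emit(
                    study, b_i, f"S{j + 1}", f"{driver}; UAS-shi",
                    f"{driver}; UAS-shi", "shi_inactivation", lobe, driver,
                    100.0 + cfg.heat_effect - cfg.slope_per_cell * cells,
                    None, draw_control(), rng.normal(0.0, cfg.sigma_effect),
                )
    for driver, cells, _ in cfg.drivers:
        truth.driver_effects[driver] = float(cfg.slope_per_cell * cells)
    return Dataset(records, provenance=f"simulated(seed={cfg.seed})"), truth


def simulate_frame(
    n_studies: int = 10,
    per_study: int = 8,
    beta: Sequence[float] = (0.0, 1.0),
    tau2: float = 25.0,
    rho: float = 0.3,
    sigma2: float = 1.0,
    weight_range: tuple[float, float] = (0.5, 2.0),
    block_size: int = 2,
    seed: int = 0,
) -> tuple[ModelFrame, np.ndarray]:
    """Draw a model frame directly from the regression generative model.

    Returns the frame and the exact covariance used, so estimator checks
    can compare against the true parameter values without any
    summary-level approximation.
    """
    rng = np.random.default_rng(seed)
    n = n_studies * per_study
    x = rng.uniform(0.0, 10.0, size=n)
    X = np.column_stack([np.ones(n), x])
    weights = rng.uniform(*weight_range, size=n)
    clusters = np.repeat(np.arange(n_studies), per_study)
    blocks = np.arange(n) // block_size if block_size >= 2 else np.full(n, -1)
    frame = ModelFrame(
        y=np.zeros(n),
        X=X,
        columns=["Intercept", "x"],
        weights=weights,
        clusters=clusters,
        blocks=blocks,
        records=[],
    )
    lam = tau2 / sigma2
    v = sigma2 * _scaled_cov(frame, lam, rho)
    mean = X @ np.asarray(beta, dtype=float)
    frame.y = rng.multivariate_normal(mean, v, method="cholesky")
    return frame, v
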