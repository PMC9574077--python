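"""Synthetic provincial panels with known ground truth.

Two generators back the test strategy:

* :func:`generate_dea_panel` builds indicator panels whose true stage-1
  efficiencies are known *exactly* by construction.  Per year, a price
  system (a, b) defines one facet of each stage's constant-returns frontier;
  frontier units get intermediate/final-output profiles lying on the facet,
  non-frontier units are convex combinations of frontier profiles with the
  initial input inflated by a radial factor f1 >= 1 (so true stage-1
  efficiency is exactly 1/f1 -- single-input radial distance to the common
  facet) and final outputs deflated by f2 >= 1.  Because stage 2 has
  multiple inputs, 1/f2 is only a bound on the stage-2 score (it is
  attainable at the generator's own price system, so the LP score is >= 1/f2);
  exact stage-2 truth is recomputed with the LP itself on small instances.
  Indicator magnitudes are scaled into the ranges typical of Chinese
  provincial health statistics (expenditure near 900 yuan per capita,
  0.75 institutions / 5.9 technicians / 5.0 beds per thousand population,
  and incidence/mortality rates near 0.005 / 0.1 / 2.0); the three
  negative-direction indicators are emitted as reciprocals of the generated
  benefit outputs, so that positivization restores them exactly.

* :func:`generate_sdm_panel` simulates the spatial Durbin data-generating
  process y_t = (I - rho W)^-1 (X_t beta + W X_t eta + mu + v_t + e_t) with
  log-normal covariates (so that the logged regressors used in estimation
  are Gaussian) and records all true parameters.

All randomness flows from a single seed through named substreams, so adding
a new draw site never shifts existing draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel import CHINA_PROVINCES, validate_panel, INDICATOR_COLUMNS, COVARIATE_COLUMNS
from .spatial import SpatialWeights

__all__ = [
    "SyntheticDEAConfig",
    "SyntheticSDMConfig",
    "generate_dea_panel",
    "generate_sdm_panel",
    "china_adjacency",
    "CHINA_ISLAND_LINKS",
]

# magnitude anchors for indicator scaling (typical provincial values)
_X_SCALE = 900.0
_Z_TARGET = np.array([0.75, 5.9, 5.0])
# benefit-direction final outputs: diagnoses, bed utilization %, and the
# reciprocals of incidence / maternal mortality / perinatal mortality
_Y_TARGET = np.array([23650.0, 84.0, 1 / 0.0046, 1 / 0.0975, 1 / 1.96])


@dataclass(frozen=True)
class SyntheticDEAConfig:
    """Design of a synthetic indicator panel (defaults: 31 units x 12 years)."""

    n_units: int = 31
    start_year: int = 2009
    n_years: int = 12
    n_frontier: int = 4
    stage1_inefficiency: tuple = (1.0, 3.0)   # uniform radial factor f1
    stage2_inefficiency: tuple = (1.0, 1.8)   # uniform radial factor f2
    direction_sd: float = 0.25                # log-sd of facet directions
    input_sd: float = 0.45                    # log-sd of input scale
    spatial_rho: float = 0.0                  # planted clustering of f1
    seed: int = 0

    def __post_init__(self):
        if self.n_frontier < 1 or self.n_frontier > self.n_units:
            raise ValueError("need 1 <= n_frontier <= n_units")
        if self.stage1_inefficiency[0] < 1 or self.stage2_inefficiency[0] < 1:
            raise ValueError("inefficiency factors must be >= 1")


def _substream(seed: int, name: str) -> np.random.Generator:
    """Independent named stream derived from the master seed."""
    h = np.frombuffer(name.encode(), dtype=np.uint8)
    return np.random.default_rng(np.random.SeedSequence([seed, *h.tolist()]))


def _facet_directions(rng, n, target, sd):
    """Positive profiles on the hyperplane a.z = 1, near the target scale."""
    a = 1.0 / (len(target) * target)
    d = target * np.exp(sd * rng.standard_normal((n, len(target))))
    return d / (d @ a)[:, None], a


def generate_dea_panel(config: SyntheticDEAConfig,
                       units=None,
                       weights: SpatialWeights | None = None):
    """Generate an indicator panel plus its ground truth.

    Returns ``(panel, truth)``: the panel in raw (un-positivized) form with
    F3-F5 as negative-direction rates, and a truth frame with the exact true
    stage-1 efficiency (``stage1_true``) and the stage-2 bound
    (``stage2_bound`` = 1/f2, attainable at the generator's price system).

    With ``spatial_rho`` nonzero and ``weights`` supplied, the stage-1
    inefficiency factors follow a spatially autocorrelated latent field, so
    the resulting efficiency surface carries planted positive spatial
    autocorrelation.
    """
    cfg = config
    if units is None:
        units = (CHINA_PROVINCES if cfg.n_units == 31
                 else [f"U{i:02d}" for i in range(1, cfg.n_units + 1)])
    if len(units) != cfg.n_units:
        raise ValueError("units list length must equal n_units")
    n = cfg.n_units
    years = range(cfg.start_year, cfg.start_year + cfg.n_years)

    rows = []
    truth_rows = []
    z_targets = _Z_TARGET / _X_SCALE
    y_targets = _Y_TARGET / _X_SCALE
    for year in years:
        tag = f"{cfg.seed}:{year}"
        rng_f = _substream(cfg.seed, f"frontier:{year}")
        rng_x = _substream(cfg.seed, f"inputs:{year}")
        rng_m = _substream(cfg.seed, f"mix:{year}")
        rng_e = _substream(cfg.seed, f"ineff:{year}")

        lo1, hi1 = cfg.stage1_inefficiency
        lo2, hi2 = cfg.stage2_inefficiency
        if cfg.spatial_rho != 0.0:
            if weights is None or not weights.standardized:
                raise ValueError(
                    "spatial_rho requires row-standardized weights")
            shock = rng_e.standard_normal(n)
            latent = np.linalg.solve(
                np.eye(n) - cfg.spatial_rho * weights.matrix, shock)
            latent = (latent - latent.mean()) / max(latent.std(), 1e-12)
            f1 = lo1 + (hi1 - lo1) * 0.5 * (1 + np.tanh(latent))
            # the frontier is the efficient end of the planted field, so
            # frontier spikes do not break the spatial pattern
            frontier = np.argsort(latent)[: cfg.n_frontier]
        else:
            f1 = rng_e.uniform(lo1, hi1, size=n)
            frontier = rng_f.choice(n, size=cfg.n_frontier, replace=False)
        f2 = rng_e.uniform(lo2, hi2, size=n)
        f1[frontier] = 1.0
        f2[frontier] = 1.0
        is_front = np.zeros(n, dtype=bool)
        is_front[frontier] = True

        zdir_f, a = _facet_directions(rng_f, cfg.n_frontier, z_targets,
                                      cfg.direction_sd)
        ydir_f, b = _facet_directions(rng_f, cfg.n_frontier, y_targets,
                                      cfg.direction_sd)
        mix = rng_m.dirichlet(np.ones(cfg.n_frontier), size=n)
        zdir = mix @ zdir_f          # convex combinations stay on the facet
        ymix = rng_m.dirichlet(np.ones(cfg.n_frontier), size=n)
        ydir = ymix @ ydir_f
        zdir[frontier] = zdir_f
        ydir[frontier] = ydir_f

        x = _X_SCALE * np.exp(cfg.input_sd * rng_x.standard_normal(n))
        Z = x[:, None] * zdir / f1[:, None]
        # weighted intermediate input a.Z = x / f1; frontier output b.Y = a.Z
        Ypos = (x / f1)[:, None] * ydir / f2[:, None]

        for i, u_label in enumerate(units):
            rows.append({
                "unit": u_label, "year": year,
                "I1": x[i],
                "M1": Z[i, 0], "M2": Z[i, 1], "M3": Z[i, 2],
                "F1": Ypos[i, 0], "F2": Ypos[i, 1],
                "F3": 1.0 / Ypos[i, 2], "F4": 1.0 / Ypos[i, 3],
                "F5": 1.0 / Ypos[i, 4],
            })
            truth_rows.append({
                "unit": u_label, "year": year,
                "stage1_true": 1.0 / f1[i],
                "stage2_bound": 1.0 / f2[i],
                "frontier": bool(is_front[i]),
            })

    panel = validate_panel(pd.DataFrame(rows), INDICATOR_COLUMNS)
    truth = pd.DataFrame(truth_rows).sort_values(["unit", "year"],
                                                 kind="mergesort").reset_index(drop=True)
    return panel, truth


@dataclass(frozen=True)
class SyntheticSDMConfig:
    """Spatial Durbin DGP parameters (defaults sized for recovery runs)."""

    rho: float = 0.4
    beta: tuple = (-0.6, 0.3)
    eta: tuple = (1.2, -0.5)
    sigma: float = 0.1
    unit_effect_sd: float = 0.1
    time_effect_sd: float = 0.05
    n_units: int = 49
    T: int = 12
    seed: int = 0

    def __post_init__(self):
        if not abs(self.rho) < 1:
            raise ValueError("|rho| must be < 1 for row-standardized weights")
        if len(self.beta) != len(self.eta):
            raise ValueError("beta and eta must have equal length")


def generate_sdm_panel(config: SyntheticSDMConfig, weights: SpatialWeights):
    """Simulate the spatial Durbin DGP; returns ``(covariates, y, truth)``.

    ``covariates`` is a (T, n, k) array of *positive* log-normal covariates
    (log them before fitting); ``y`` is (T, n); ``truth`` records the DGP
    parameters and the drawn unit/time effects.
    """
    cfg = config
    if not weights.standardized:
        raise ValueError("weights must be row-standardized")
    W = weights.matrix
    n = weights.n
    if n != cfg.n_units:
        raise ValueError(f"weights have {n} units, config says {cfg.n_units}")
    k = len(cfg.beta)
    beta = np.asarray(cfg.beta, float)
    eta = np.asarray(cfg.eta, float)

    rng_x = _substream(cfg.seed, "sdm:x")
    rng_fx = _substream(cfg.seed, "sdm:effects")
    rng_e = _substream(cfg.seed, "sdm:noise")

    logX = rng_x.standard_normal((cfg.T, n, k))
    mu = cfg.unit_effect_sd * rng_fx.standard_normal(n)
    v = cfg.time_effect_sd * rng_fx.standard_normal(cfg.T)
    eps = cfg.sigma * rng_e.standard_normal((cfg.T, n))

    A = np.eye(n) - cfg.rho * W
    WlogX = np.einsum("ij,tjk->tik", W, logX)
    rhs = logX @ beta + WlogX @ eta + mu[None, :] + v[:, None] + eps
    if cfg.rho == 0.0:
        y = rhs
    else:
        y = np.linalg.solve(A, rhs.T).T  # solve once for all periods
    truth = {
        "rho": cfg.rho, "beta": beta, "eta": eta, "sigma": cfg.sigma,
        "unit_effects": mu, "time_effects": v,
    }
    return np.exp(logX), y, truth


def sdm_panel_frames(config: SyntheticSDMConfig, weights: SpatialWeights,
                     units=None, start_year: int = 2009):
    """Long-format covariate and efficiency frames for pipeline-style use.

    The k generated covariates are mapped onto the regression covariate
    names (pgdp, fiscal, ...), rescaled to plausible magnitudes.
    """
    Xpos, y, truth = generate_sdm_panel(config, weights)
    n, T, k = config.n_units, config.T, len(config.beta)
    if units is None:
        units = (CHINA_PROVINCES if n == 31
                 else [f"U{i:02d}" for i in range(1, n + 1)])
    names = COVARIATE_COLUMNS[:k]
    scales = dict(zip(COVARIATE_COLUMNS, [45800.0, 7.0, 0.57, 6.1, 14.0]))
    rows = []
    yrows = []
    for t in range(T):
        for i, u in enumerate(units):
            rec = {"unit": u, "year": start_year + t}
            for j, nm in enumerate(names):
                rec[nm] = scales[nm] * Xpos[t, i, j]
            rows.append(rec)
            yrows.append({"unit": u, "year": start_year + t,
                          "overall": y[t, i]})
    cov = validate_panel(pd.DataFrame(rows), names)
    eff = pd.DataFrame(yrows).sort_values(["unit", "year"],
                                          kind="mergesort").reset_index(drop=True)
    return cov, eff, truth


# ------------------------------------------------------------- China fixture

#: Hainan is an island; it is linked to its nearest mainland province.
CHINA_ISLAND_LINKS = {"Hainan": "Guangdong"}

_CHINA_PAIRS = [
    ("Beijing", "Tianjin"), ("Beijing", "Hebei"),
    ("Tianjin", "Hebei"),
    ("Hebei", "Shanxi"), ("Hebei", "Inner Mongolia"), ("Hebei", "Liaoning"),
    ("Hebei", "Shandong"), ("Hebei", "Henan"),
    ("Shanxi", "Inner Mongolia"), ("Shanxi", "Shaanxi"), ("Shanxi", "Henan"),
    ("Inner Mongolia", "Liaoning"), ("Inner Mongolia", "Jilin"),
    ("Inner Mongolia", "Heilongjiang"), ("Inner Mongolia", "Shaanxi"),
    ("Inner Mongolia", "Ningxia"), ("Inner Mongolia", "Gansu"),
    ("Liaoning", "Jilin"),
    ("Jilin", "Heilongjiang"),
    ("Shanghai", "Jiangsu"), ("Shanghai", "Zhejiang"),
    ("Jiangsu", "Zhejiang"), ("Jiangsu", "Anhui"), ("Jiangsu", "Shandong"),
    ("Zhejiang", "Anhui"), ("Zhejiang", "Fujian"), ("Zhejiang", "Jiangxi"),
    ("Anhui", "Jiangxi"), ("Anhui", "Henan"), ("Anhui", "Hubei"),
    ("Anhui", "Shandong"),
    ("Fujian", "Jiangxi"), ("Fujian", "Guangdong"),
    ("Jiangxi", "Hunan"), ("Jiangxi", "Hubei"), ("Jiangxi", "Guangdong"),
    ("Shandong", "Henan"),
    ("Henan", "Hubei"), ("Henan", "Shaanxi"),
    ("Hubei", "Hunan"), ("Hubei", "Chongqing"), ("Hubei", "Shaanxi"),
    ("Hunan", "Guangdong"), ("Hunan", "Guangxi"), ("Hunan", "Guizhou"),
    ("Hunan", "Chongqing"),
    ("Guangdong", "Guangxi"),
    ("Guangxi", "Guizhou"), ("Guangxi", "Yunnan"),
    ("Chongqing", "Sichuan"), ("Chongqing", "Guizhou"),
    ("Chongqing", "Shaanxi"),
    ("Sichuan", "Yunnan"), ("Sichuan", "Tibet"), ("Sichuan", "Qinghai"),
    ("Sichuan", "Gansu"), ("Sichuan", "Shaanxi"), ("Sichuan", "Guizhou"),
    ("Guizhou", "Yunnan"),
    ("Yunnan", "Tibet"),
    ("Tibet", "Xinjiang"), ("Tibet", "Qinghai"),
    ("Shaanxi", "Gansu"), ("Shaanxi", "Ningxia"),
    ("Gansu", "Qinghai"), ("Gansu", "Ningxia"), ("Gansu", "Xinjiang"),
    ("Qinghai", "Xinjiang"),
]


def china_adjacency(include_island_links: bool = True) -> list[tuple[str, str]]:
    """First-order contiguity pairs for the 31 provincial units.

    With ``include_island_links`` the declared island policy (Hainan linked
    to Guangdong) is appended, so every unit has at least one neighbor.
    """
    pairs = list(_CHINA_PAIRS)
    if include_island_links:
        pairs.extend(CHINA_ISLAND_LINKS.items())
    return pairs
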