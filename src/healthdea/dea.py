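"""Relational two-stage network DEA under constant returns to scale.

The production system is a series chain: an initial input vector X feeds
stage 1 (resource allocation), which produces intermediate outputs Z; stage 2
(service operation) consumes Z and produces final outputs Y.  Efficiencies
are measured in multiplier (ratio) form with a common multiplier system
across the two stages, so that for every decision-making unit the overall
efficiency factors exactly into the product of the stage efficiencies:

    E_overall = E_stage1 * E_stage2.

All programs are solved as linear programs after the Charnes-Cooper
normalization (weighted input of the evaluated unit fixed at 1).  Multipliers
are bounded below by a non-Archimedean epsilon expressed *relative to the
column scale* (bound = epsilon / max of the column), which keeps every score
strictly positive while making efficiencies exactly invariant to the units
in which any indicator is measured.

The overall score of the relational model is unique, but its split into
stage scores may not be; the decomposition therefore fixes the overall score
and optimizes one stage's score subject to it, in either priority order.
When the two orders disagree the result is flagged as non-unique.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linprog

from .panel import INDICATOR_COLUMNS, PanelError

__all__ = [
    "DEAConfig",
    "DEAResult",
    "TwoStageNetworkDEA",
    "ccr_efficiency",
    "relational_overall",
    "decompose_stages",
    "run_dea_year",
    "run_dea_panel",
]

#: panel columns forming the instance: X = inputs, Z = intermediates,
#: Y = final outputs (F3-F5 already positivized).
X_COLUMNS = ["I1"]
Z_COLUMNS = ["M1", "M2", "M3"]
Y_COLUMNS = ["F1", "F2", "F3", "F4", "F5"]


@dataclass(frozen=True)
class DEAConfig:
    """Solver configuration.

    epsilon
        Non-Archimedean lower bound on multipliers, applied relative to each
        column's maximum (bound = epsilon / max_j value_j).
    lp_tolerance
        Primal/dual feasibility tolerance passed to the LP solver.
    priority
        Which stage's efficiency is maximized first in the decomposition.
    """

    epsilon: float = 1e-6
    lp_tolerance: float = 1e-9
    priority: str = "stage1_first"

    def __post_init__(self):
        if not (0 < self.epsilon < 1):
            raise ValueError("epsilon must be in (0, 1)")
        if self.priority not in ("stage1_first", "stage2_first"):
            raise ValueError("priority must be stage1_first or stage2_first")


class DEAError(RuntimeError):
    """LP failure (infeasible / unbounded), annotated with context."""


def _check_matrix(name: str, a: np.ndarray) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    if a.ndim != 2 or a.size == 0:
        raise ValueError(f"{name} must be a nonempty 2-D matrix")
    if not np.all(np.isfinite(a)) or np.any(a <= 0):
        raise ValueError(f"{name} entries must be finite and strictly positive")
    return a


def _bounds(eps: float, *mats: np.ndarray) -> list[tuple[float, None]]:
    """Scale-relative multiplier lower bounds, one per column of each matrix."""
    out: list[tuple[float, None]] = []
    for m in mats:
        out.extend((eps / float(m[:, j].max()), None) for j in range(m.shape[1]))
    return out


def _solve(c, A_ub, b_ub, A_eq, b_eq, bounds, tol):
    res = linprog(
        c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq, bounds=bounds,
        method="highs",
        options={"primal_feasibility_tolerance": tol,
                 "dual_feasibility_tolerance": tol},
    )
    return res


def ccr_efficiency(inputs, outputs, k: int, config: DEAConfig | None = None):
    """Single-technology CCR efficiency of unit ``k`` in multiplier form.

    Maximizes weighted output of unit ``k`` subject to its weighted input
    equal to 1 and every unit's output/input ratio at most 1.  Used for the
    independent overall (X -> Y), stage-1 (X -> Z) and stage-2 (Z -> Y)
    technologies alike.

    Returns ``(score, input_weights, output_weights, status)``.
    """
    config = config or DEAConfig()
    X = _check_matrix("inputs", inputs)
    Y = _check_matrix("outputs", outputs)
    n, m = X.shape
    s = Y.shape[1]
    if Y.shape[0] != n:
        raise ValueError("inputs and outputs must have the same number of units")
    if not 0 <= k < n:
        raise ValueError(f"unit index {k} out of range for n={n}")

    # variables: [v (m input weights), u (s output weights)]
    c = np.concatenate([np.zeros(m), -Y[k]])
    A_eq = np.concatenate([X[k], np.zeros(s)])[None, :]
    A_ub = np.hstack([-X, Y])  # u.Y_j - v.X_j <= 0
    res = _solve(c, A_ub, np.zeros(n), A_eq, np.array([1.0]),
                 _bounds(config.epsilon, X, Y), config.lp_tolerance)
    if res.status != 0:
        raise DEAError(
            f"CCR LP for unit {k} failed ({res.message}); "
            "an infeasible program usually means epsilon is too large "
            "for the instance dimensions"
        )
    return -res.fun, res.x[:m], res.x[m:], "optimal"


def relational_overall(X, Z, Y, k: int, config: DEAConfig | None = None):
    """Overall efficiency of unit ``k`` under the relational series model.

    One multiplier system (v for X, w for Z, u for Y) serves both stages:
    maximize u.Y_k subject to v.X_k = 1 and, for every unit j, the overall
    (u.Y_j <= v.X_j), stage-1 (w.Z_j <= v.X_j) and stage-2 (u.Y_j <= w.Z_j)
    ratio caps.  Returns ``(score, v, w, u, status)``.
    """
    config = config or DEAConfig()
    X, Z, Y = (_check_matrix(nm, a) for nm, a in (("X", X), ("Z", Z), ("Y", Y)))
    n, m = X.shape
    q, s = Z.shape[1], Y.shape[1]
    if Z.shape[0] != n or Y.shape[0] != n:
        raise ValueError("X, Z, Y must have the same number of units")
    if not 0 <= k < n:
        raise ValueError(f"unit index {k} out of range for n={n}")

    zm, zq, zs = np.zeros((n, m)), np.zeros((n, q)), np.zeros((n, s))
    # variables: [v (m), w (q), u (s)]
    c = np.concatenate([np.zeros(m + q), -Y[k]])
    A_eq = np.concatenate([X[k], np.zeros(q + s)])[None, :]
    A_ub = np.vstack([
        np.hstack([-X, zq, Y]),   # u.Y_j - v.X_j <= 0
        np.hstack([-X, Z, zs]),   # w.Z_j - v.X_j <= 0
        np.hstack([zm, -Z, Y]),   # u.Y_j - w.Z_j <= 0
    ])
    res = _solve(c, A_ub, np.zeros(3 * n), A_eq, np.array([1.0]),
                 _bounds(config.epsilon, X, Z, Y), config.lp_tolerance)
    if res.status != 0:
        raise DEAError(f"relational LP for unit {k} failed ({res.message})")
    v, w, u = res.x[:m], res.x[m:m + q], res.x[m + q:]
    return -res.fun, v, w, u, "optimal"


def decompose_stages(X, Z, Y, k: int, e_overall: float,
                     config: DEAConfig | None = None,
                     priority: str | None = None):
    """Split a relational overall score into stage-1 and stage-2 scores.

    With ``stage1_first`` the stage-1 score w.Z_k is maximized subject to the
    relational constraints and the overall score held fixed at ``e_overall``;
    stage 2 follows from the product identity E2 = E / E1.  With
    ``stage2_first`` the same program *minimizes* w.Z_k, which maximizes the
    stage-2 score E2 = E / (w.Z_k).  The overall-score pin uses a 1e-9 slack
    band to avoid spurious infeasibility from floating point.
    """
    config = config or DEAConfig()
    priority = priority or config.priority
    X, Z, Y = (np.asarray(a, float) for a in (X, Z, Y))
    n, m = X.shape
    q, s = Z.shape[1], Y.shape[1]
    zm, zq, zs = np.zeros((n, m)), np.zeros((n, q)), np.zeros((n, s))

    sign = 1.0 if priority == "stage1_first" else -1.0
    c = np.concatenate([np.zeros(m), -sign * Z[k], np.zeros(s)])
    A_eq = np.concatenate([X[k], np.zeros(q + s)])[None, :]
    slack = 1e-9
    pin = np.concatenate([-e_overall * X[k], np.zeros(q), Y[k]])
    A_ub = np.vstack([
        np.hstack([-X, zq, Y]),
        np.hstack([-X, Z, zs]),
        np.hstack([zm, -Z, Y]),
        pin[None, :],        # u.Y_k - E v.X_k <= slack
        -pin[None, :],       # -(u.Y_k - E v.X_k) <= slack
    ])
    b_ub = np.concatenate([np.zeros(3 * n), [slack, slack]])
    res = _solve(c, A_ub, b_ub, A_eq, np.array([1.0]),
                 _bounds(config.epsilon, X, Z, Y), config.lp_tolerance)
    if res.status != 0:
        raise DEAError(
            f"stage decomposition LP for unit {k} infeasible at fixed overall "
            f"score {e_overall:.12f} ({res.message}); this signals a solver "
            "tolerance mismatch between the overall and decomposition solves"
        )
    # stage-1 score is w.Z_k (weighted input of the evaluated unit is 1);
    # maximizing it favors stage 1, minimizing it favors stage 2 = E/E1.
    e1 = float(res.x[m:m + q] @ Z[k])
    # E <= E1 <= 1 holds exactly in the model; the pin slack can leak a few
    # nano-units past either bound, which would put E2 just above 1
    if e1 > 1 + 1e-6 or e1 < e_overall - 1e-6:
        raise DEAError(
            f"stage-1 score {e1} outside [{e_overall}, 1] beyond tolerance "
            f"for unit {k}"
        )
    e1 = min(max(e1, e_overall), 1.0)
    return e1, e_overall / e1, "optimal"


@dataclass
class DEAResult:
    """Container for one cross-section's efficiency measurement."""

    labels: list
    overall: np.ndarray
    stage1: np.ndarray
    stage2: np.ndarray
    status: list
    nonunique: np.ndarray
    multipliers: list = field(repr=False, default_factory=list)
    config: DEAConfig | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "unit": self.labels,
            "overall": self.overall,
            "stage1": self.stage1,
            "stage2": self.stage2,
            "status": self.status,
            "nonunique_decomposition": self.nonunique,
        })


class TwoStageNetworkDEA:
    """Relational two-stage DEA scorer in the fit/attributes style.

    Parameters
    ----------
    epsilon : float
        Non-Archimedean multiplier bound (relative to column scale).
    priority : str
        Reported decomposition order, ``stage1_first`` or ``stage2_first``.
        Both orders are always computed; a unit is flagged non-unique when
        they disagree by more than 1e-6.
    lp_tolerance : float
        LP feasibility/optimality tolerance.

    Fitted attributes (per unit): ``overall_``, ``stage1_``, ``stage2_``,
    ``stage1_alt_``, ``stage2_alt_`` (the other priority), ``multipliers_``,
    ``status_``, ``nonunique_``.
    """

    def __init__(self, epsilon: float = 1e-6, priority: str = "stage1_first",
                 lp_tolerance: float = 1e-9):
        self.epsilon = epsilon
        self.priority = priority
        self.lp_tolerance = lp_tolerance

    # minimal sklearn-compatible parameter plumbing
    def get_params(self, deep: bool = True) -> dict:
        return {"epsilon": self.epsilon, "priority": self.priority,
                "lp_tolerance": self.lp_tolerance}

    def set_params(self, **params):
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k}")
            setattr(self, k, v)
        return self

    @property
    def _config(self) -> DEAConfig:
        return DEAConfig(epsilon=self.epsilon, lp_tolerance=self.lp_tolerance,
                         priority=self.priority)

    def fit(self, X, Z, Y, labels=None):
        """Score every unit of the cross-section (X, Z, Y)."""
        cfg = self._config
        X = _check_matrix("X", X)
        Z = _check_matrix("Z", Z)
        Y = _check_matrix("Y", Y)
        n = X.shape[0]
        labels = list(labels) if labels is not None else list(range(n))

        overall = np.empty(n)
        e1_a = np.empty(n)
        e1_b = np.empty(n)
        mults = []
        status = []
        for k in range(n):
            e, v, w, u, st = relational_overall(X, Z, Y, k, cfg)
            overall[k] = e
            mults.append({"v": v, "w": w, "u": u})
            e1_a[k], _, _ = decompose_stages(X, Z, Y, k, e, cfg, "stage1_first")
            e1_b[k], _, _ = decompose_stages(X, Z, Y, k, e, cfg, "stage2_first")
            status.append(st)

        primary = e1_a if cfg.priority == "stage1_first" else e1_b
        alt = e1_b if cfg.priority == "stage1_first" else e1_a
        self.labels_ = labels
        self.overall_ = overall
        self.stage1_ = primary
        self.stage2_ = overall / primary
        self.stage1_alt_ = alt
        self.stage2_alt_ = overall / alt
        self.multipliers_ = mults
        self.status_ = status
        self.nonunique_ = np.abs(e1_a - e1_b) > 1e-6
        self.config_ = cfg
        self._warn_epsilon_sensitivity(X, Z, Y)
        return self

    def _warn_epsilon_sensitivity(self, X, Z, Y) -> None:
        """Flag scores whose distance to a bound is comparable to epsilon."""
        dim = X.shape[1] + Z.shape[1] + Y.shape[1]
        margin = 10 * self.epsilon * dim
        close = (self.overall_ < margin) | (self.overall_ > 1 - margin) & (
            self.overall_ < 1)
        self.epsilon_sensitive_ = close

    def result_(self) -> DEAResult:
        return DEAResult(
            labels=self.labels_, overall=self.overall_, stage1=self.stage1_,
            stage2=self.stage2_, status=self.status_,
            nonunique=self.nonunique_, multipliers=self.multipliers_,
            config=self.config_,
        )


def panel_to_instance(panel: pd.DataFrame, year: int):
    """Extract the (X, Z, Y, labels) cross-section for one year."""
    if not panel.attrs.get("positivized", False):
        raise PanelError(
            "panel must be positivized before DEA (negative-direction "
            "indicators F3-F5 still in raw form)"
        )
    cross = panel[panel["year"] == year]
    if cross.empty:
        raise PanelError(f"year {year} not present in panel")
    cross = cross.sort_values("unit", kind="mergesort")
    X = cross[X_COLUMNS].to_numpy(float)
    Z = cross[Z_COLUMNS].to_numpy(float)
    Y = cross[Y_COLUMNS].to_numpy(float)
    return X, Z, Y, list(cross["unit"])


def run_dea_year(panel: pd.DataFrame, year: int,
                 config: DEAConfig | None = None) -> pd.DataFrame:
    """Score all units of one year's cross-section (per-year frontier)."""
    config = config or DEAConfig()
    X, Z, Y, labels = panel_to_instance(panel, year)
    model = TwoStageNetworkDEA(epsilon=config.epsilon,
                               priority=config.priority,
                               lp_tolerance=config.lp_tolerance)
    try:
        model.fit(X, Z, Y, labels=labels)
    except DEAError as err:
        raise DEAError(f"year {year}: {err}") from err
    out = model.result_().to_frame()
    out.insert(1, "year", year)
    return out


def run_dea_panel(panel: pd.DataFrame,
                  config: DEAConfig | None = None,
                  years=None) -> pd.DataFrame:
    """Score every year of a positivized panel; frontiers are per-year."""
    years = sorted(panel["year"].unique()) if years is None else list(years)
    return pd.concat(
        [run_dea_year(panel, y, config) for y in years], ignore_index=True
    )
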