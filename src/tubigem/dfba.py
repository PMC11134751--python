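"""Dynamic FBA (static-optimisation approach) of a glucose-xylose
citric-acid fermentation.

At each Euler step the extracellular state sets substrate-uptake bounds
through Michaelis-Menten kinetics with two switching rules:

* xylose transporter-mediated uptake is disabled while extracellular
  glucose exceeds a repression threshold (default 5 mM); a passive,
  concentration-proportional xylose influx remains;
* a low-affinity glucose transport term is added above a high-glucose
  threshold (default 75 g/L).

Non-growth-associated maintenance (NGAM, default 1.9 mmol gDW^-1 h^-1) is
imposed as a lower bound on the ATP-maintenance reaction. The objective is
growth; once phosphate exhaustion drives the optimal growth rate to ~0 the
policy switches to maximising citrate secretion under the same uptake
bounds (the citrate-overflow phase).

Units: sugars/citrate g/L, phosphate mM, biomass gDW/L, fluxes
mmol gDW^-1 h^-1, time h.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd

from .core import MetabolicModel
from .io import to_cobra
from .units import MOLAR_MASS_G_PER_MOL, g_per_l_to_mm

__all__ = [
    "KineticParameters", "FermentationState", "Trajectory", "ReactionRoles",
    "glucose_uptake_bound", "xylose_uptake_components", "xylose_uptake_bound",
    "apply_kinetic_bounds", "dfba_step", "run_dfba", "carbon_balance",
    "with_lag_phase", "FermentationModel", "FermentationFitResult",
    "DfbaStepError",
]


@dataclass
class KineticParameters:
    """Uptake kinetics, switching thresholds and maintenance.

    Monod/Michaelis-Menten Vmax in mmol gDW^-1 h^-1, Km in g/L.
    """

    vmax_glc_high: float = 2.0
    km_glc_high: float = 0.1
    vmax_glc_low: float = 1.0
    km_glc_low: float = 15.0
    #: low-affinity glucose transport active above this concentration, g/L
    glc_low_affinity_threshold: float = 75.0
    vmax_xyl: float = 1.0
    km_xyl: float = 1.0
    #: transporter-mediated xylose uptake disabled above this glucose
    #: concentration, mM
    xyl_repression_threshold: float = 5.0
    #: passive xylose influx, mmol gDW^-1 h^-1 per g/L xylose
    k_passive_xyl: float = 0.005
    #: non-growth-associated maintenance ATP, mmol gDW^-1 h^-1
    ngam: float = 1.9
    #: simulation start offset after inoculation, h
    t_start: float = 10.0
    #: phosphate uptake cap while extracellular P remains, mmol gDW^-1 h^-1
    vmax_pi: float = 0.3
    #: growth rate below which the objective switches to citrate, h^-1
    growth_switch_threshold: float = 1e-4

    def __post_init__(self) -> None:
        for f in fields(self):
            value = getattr(self, f.name)
            if value < 0:
                raise ValueError(f"{f.name} must be non-negative, got {value}")
        for name in ("glc_low_affinity_threshold", "xyl_repression_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def replace(self, **kwargs) -> "KineticParameters":
        data = asdict(self)
        data.update(kwargs)
        return KineticParameters(**data)

    def to_file(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "KineticParameters":
        return cls(**json.loads(Path(path).read_text()))


@dataclass
class FermentationState:
    t: float            # h
    biomass: float      # gDW/L
    glucose: float      # g/L
    xylose: float       # g/L
    citrate: float      # g/L
    phosphate: float    # mM

    def __post_init__(self) -> None:
        for name in ("biomass", "glucose", "xylose", "citrate", "phosphate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def as_dict(self) -> dict[str, float]:
        return {"t": self.t, "biomass": self.biomass, "glucose": self.glucose,
                "xylose": self.xylose, "citrate": self.citrate,
                "phosphate": self.phosphate}


@dataclass
class ReactionRoles:
    """Which model reactions play which role in the fermentation."""

    glucose_exchange: str = "EX_glc__D_e"
    xylose_exchange: str = "EX_xyl__D_e"
    phosphate_exchange: str = "EX_pi_e"
    citrate_exchange: str = "EX_cit_e"
    co2_exchange: str = "EX_co2_e"
    atp_maintenance: str = "ATPM"


@dataclass
class Trajectory:
    """Time course of a dFBA run plus per-step solver diagnostics."""

    states: list[FermentationState] = field(default_factory=list)
    diagnostics: list[dict] = field(default_factory=list)
    termination: str = "completed"

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame([s.as_dict() for s in self.states])

    def diagnostics_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.diagnostics)

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False, float_format="%.10g")

    @property
    def final(self) -> FermentationState:
        return self.states[-1]

    def __len__(self) -> int:
        return len(self.states)


class DfbaStepError(RuntimeError):
    """An integration step failed (infeasible LP); carries diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


# ---------------------------------------------------------------------------
# Kinetic rules
# ---------------------------------------------------------------------------

def glucose_uptake_bound(glc_g_l: float, p: KineticParameters) -> float:
    """Allowed glucose uptake: high-affinity Monod term always, plus the
    low-affinity term above the high-glucose threshold."""
    if glc_g_l <= 0:
        return 0.0
    rate = p.vmax_glc_high * glc_g_l / (p.km_glc_high + glc_g_l)
    if glc_g_l > p.glc_low_affinity_threshold:
        rate += p.vmax_glc_low * glc_g_l / (p.km_glc_low + glc_g_l)
    return rate


def xylose_uptake_components(xyl_g_l: float, glc_mm: float,
                             p: KineticParameters) -> tuple[float, float]:
    """(passive, transporter) xylose uptake terms.

    The transporter term is exactly zero while glucose exceeds the
    repression threshold; passive influx is linear in xylose concentration.
    """
    if xyl_g_l <= 0:
        return 0.0, 0.0
    passive = p.k_passive_xyl * xyl_g_l
    transporter = 0.0
    if glc_mm <= p.xyl_repression_threshold:
        transporter = p.vmax_xyl * xyl_g_l / (p.km_xyl + xyl_g_l)
    return passive, transporter


def xylose_uptake_bound(xyl_g_l: float, glc_mm: float,
                        p: KineticParameters) -> float:
    passive, transporter = xylose_uptake_components(xyl_g_l, glc_mm, p)
    return passive + transporter


def _state_bounds(state: FermentationState, p: KineticParameters) -> dict[str, float]:
    glc_mm = g_per_l_to_mm(state.glucose, "glucose")
    passive, transporter = xylose_uptake_components(state.xylose, glc_mm, p)
    return {
        "glc_uptake": glucose_uptake_bound(state.glucose, p),
        "xyl_uptake_passive": passive,
        "xyl_uptake_transporter": transporter,
        "pi_uptake": p.vmax_pi if state.phosphate > 0 else 0.0,
        "glc_mM": glc_mm,
    }


def apply_kinetic_bounds(model: MetabolicModel, state: FermentationState,
                         p: KineticParameters,
                         roles: ReactionRoles | None = None) -> MetabolicModel:
    """Return a copy of the model with state-dependent exchange bounds.

    Glucose/xylose exchange lower bounds are set to minus the kinetic
    uptake limits, phosphate uptake is capped (closed once depleted),
    citrate secretion is open and the ATP-maintenance lower bound is NGAM.
    """
    roles = roles or ReactionRoles()
    bounded = model.copy()
    known = set(bounded.reaction_ids)
    for role_name in ("glucose_exchange", "xylose_exchange", "phosphate_exchange",
                      "citrate_exchange", "atp_maintenance"):
        if getattr(roles, role_name) not in known:
            raise KeyError(f"model lacks a reaction for role {role_name!r} "
                           f"({getattr(roles, role_name)!r})")
    b = _state_bounds(state, p)
    bounded.reaction(roles.glucose_exchange).lower_bound = -b["glc_uptake"]
    bounded.reaction(roles.xylose_exchange).lower_bound = -(
        b["xyl_uptake_passive"] + b["xyl_uptake_transporter"])
    bounded.reaction(roles.phosphate_exchange).lower_bound = -b["pi_uptake"]
    cit = bounded.reaction(roles.citrate_exchange)
    cit.lower_bound = max(cit.lower_bound, 0.0)
    cit.upper_bound = max(cit.upper_bound, 1000.0)
    atpm = bounded.reaction(roles.atp_maintenance)
    atpm.lower_bound = p.ngam
    atpm.upper_bound = max(atpm.upper_bound, p.ngam)
    return bounded


# ---------------------------------------------------------------------------
# Integration engine
# ---------------------------------------------------------------------------

class _DfbaEngine:
    """Persistent cobra LPs for the growth and citrate objectives."""

    def __init__(self, model: MetabolicModel, p: KineticParameters,
                 roles: ReactionRoles, objective_policy: str):
        if objective_policy not in ("growth", "growth_then_citrate"):
            raise ValueError(f"unknown objective policy {objective_policy!r}")
        if model.objective is None:
            raise ValueError("dFBA requires a model objective (biomass) reaction")
        self.p = p
        self.roles = roles
        self.policy = objective_policy
        self.biomass_id = model.objective
        # validate roles once against the source model
        apply_kinetic_bounds(model, FermentationState(p.t_start, 0, 0, 0, 0, 0),
                             p, roles)
        self.growth_lp = to_cobra(model)
        self.growth_lp.objective = self.biomass_id
        self.citrate_lp = to_cobra(model)
        self.citrate_lp.objective = roles.citrate_exchange
        for lp in (self.growth_lp, self.citrate_lp):
            cit = lp.reactions.get_by_id(roles.citrate_exchange)
            cit.lower_bound = max(cit.lower_bound, 0.0)
            cit.upper_bound = max(cit.upper_bound, 1000.0)

    def _set_bounds(self, lp, b: dict[str, float]) -> None:
        r = self.roles
        lp.reactions.get_by_id(r.glucose_exchange).lower_bound = -b["glc_uptake"]
        lp.reactions.get_by_id(r.xylose_exchange).lower_bound = -(
            b["xyl_uptake_passive"] + b["xyl_uptake_transporter"])
        lp.reactions.get_by_id(r.phosphate_exchange).lower_bound = -b["pi_uptake"]
        atpm = lp.reactions.get_by_id(r.atp_maintenance)
        atpm.upper_bound = max(atpm.upper_bound, self.p.ngam)
        atpm.lower_bound = self.p.ngam

    def _fluxes(self, lp) -> dict[str, float]:
        r = self.roles
        out = {}
        for key, rid in (("mu", self.biomass_id), ("v_glc", r.glucose_exchange),
                         ("v_xyl", r.xylose_exchange), ("v_cit", r.citrate_exchange),
                         ("v_pi", r.phosphate_exchange), ("v_co2", r.co2_exchange)):
            if rid in lp.reactions:
                out[key] = float(lp.reactions.get_by_id(rid).flux)
            else:
                out[key] = 0.0
        return out

    def solve(self, state: FermentationState) -> dict:
        b = _state_bounds(state, self.p)
        self._set_bounds(self.growth_lp, b)
        mu = self.growth_lp.slim_optimize(error_value=float("nan"))
        diag = {"t": state.t, **b, "phase": "growth", "lp_status": "optimal"}
        if mu is None or math.isnan(mu):
            diag["lp_status"] = str(self.growth_lp.solver.status)
            raise DfbaStepError(
                f"growth LP infeasible at t={state.t:.3f} h "
                f"(status {diag['lp_status']})", diag)
        if self.policy == "growth_then_citrate" and mu < self.p.growth_switch_threshold:
            self._set_bounds(self.citrate_lp, b)
            v_cit = self.citrate_lp.slim_optimize(error_value=float("nan"))
            if v_cit is None or math.isnan(v_cit):
                diag["lp_status"] = str(self.citrate_lp.solver.status)
                raise DfbaStepError(
                    f"citrate LP infeasible at t={state.t:.3f} h", diag)
            diag["phase"] = "citrate"
            fluxes = self._fluxes(self.citrate_lp)
        else:
            fluxes = self._fluxes(self.growth_lp)
        diag.update(fluxes)
        return diag

    def step(self, state: FermentationState, dt: float) -> tuple[FermentationState, dict]:
        if dt <= 0:
            raise ValueError("dt must be positive")
        diag = self.solve(state)
        X = state.biomass
        mu = diag["mu"]

        def conc_update(old: float, flux: float, species: str) -> float:
            return old + flux * X * dt * MOLAR_MASS_G_PER_MOL[species] / 1000.0

        new = {
            "t": state.t + dt,
            "biomass": X * (1.0 + mu * dt),
            "glucose": conc_update(state.glucose, diag["v_glc"], "glucose"),
            "xylose": conc_update(state.xylose, diag["v_xyl"], "xylose"),
            "citrate": conc_update(state.citrate, diag["v_cit"], "citrate"),
            "phosphate": state.phosphate + diag["v_pi"] * X * dt,  # mM
        }
        clamped = [k for k in ("biomass", "glucose", "xylose", "citrate", "phosphate")
                   if new[k] < 0]
        for k in clamped:
            new[k] = 0.0
        diag["clamped"] = ",".join(clamped)
        return FermentationState(**new), diag


def dfba_step(model: MetabolicModel, state: FermentationState,
              p: KineticParameters, dt: float,
              objective_policy: str = "growth_then_citrate",
              roles: ReactionRoles | None = None,
              ) -> tuple[FermentationState, dict]:
    """One forward-Euler dFBA step. Returns (new state, diagnostics)."""
    engine = _DfbaEngine(model, p, roles or ReactionRoles(), objective_policy)
    return engine.step(state, dt)


def run_dfba(model: MetabolicModel, p: KineticParameters,
             initial: FermentationState, t_end: float, dt: float = 0.1,
             objective_policy: str = "growth_then_citrate",
             roles: ReactionRoles | None = None) -> Trajectory:
    """Integrate the fermentation from ``initial`` (at t_start) to t_end.

    On an infeasible step (e.g. NGAM unsatisfiable after substrate
    exhaustion) the trajectory is truncated cleanly, never zero-padded;
    the reason is recorded in ``Trajectory.termination``.
    """
    if abs(initial.t - p.t_start) > 1e-9:
        raise ValueError(
            f"initial state at t={initial.t} h but t_start={p.t_start} h")
    if t_end <= initial.t:
        raise ValueError("t_end must exceed the start time")
    engine = _DfbaEngine(model, p, roles or ReactionRoles(), objective_policy)
    traj = Trajectory(states=[initial])
    state = initial
    n_steps = int(round((t_end - initial.t) / dt))
    for _ in range(n_steps):
        try:
            state, diag = engine.step(state, dt)
        except DfbaStepError as exc:
            traj.diagnostics.append(exc.diagnostics)
            traj.termination = f"infeasible: {exc}"
            break
        traj.states.append(state)
        traj.diagnostics.append(diag)
    return traj


def with_lag_phase(traj: Trajectory, t0: float = 0.0, dt: float = 1.0) -> pd.DataFrame:
    """Prepend constant pre-start states so plots span from inoculation."""
    df = traj.to_dataframe()
    start = traj.states[0]
    lag_times = np.arange(t0, start.t, dt)
    lag = pd.DataFrame([{**start.as_dict(), "t": t} for t in lag_times])
    return pd.concat([lag, df], ignore_index=True)


# ---------------------------------------------------------------------------
# Carbon bookkeeping
# ---------------------------------------------------------------------------

def biomass_carbon_content(model: MetabolicModel) -> float:
    """mmol carbon incorporated per gDW of biomass formed.

    Signed sum over the biomass reaction's stoichiometry, so cycling
    currency metabolites (GAM ATP turnover) cancels out.
    """
    from .formulas import element_count

    if model.objective is None:
        raise ValueError("model has no biomass/objective reaction")
    biomass = model.reaction(model.objective)
    total = 0.0
    for met_id, coeff in biomass.stoichiometry.items():
        formula = model.metabolite(met_id).formula
        if formula is None:
            continue  # the biomass pseudo-metabolite itself
        total -= coeff * element_count(formula, "C")
    return total


_CARBON_PER_SPECIES = {"glucose": 6, "xylose": 5, "citrate": 6}


def carbon_balance(traj: Trajectory, model: MetabolicModel,
                   roles: ReactionRoles | None = None) -> pd.Series:
    """Per-step carbon recovery: C into biomass + citrate + CO2 over C from
    consumed sugars.

    NaN where nothing was consumed and on steps where a concentration was
    clamped at zero (there the recorded delta deliberately truncates the
    flux, so the ratio is not a conservation check; clamps are logged in
    the step diagnostics).
    """
    df = traj.to_dataframe()
    diag = traj.diagnostics_frame()
    c_biomass = biomass_carbon_content(model)

    def mmol_c(series_g_l: pd.Series, species: str) -> pd.Series:
        return (series_g_l / MOLAR_MASS_G_PER_MOL[species] * 1000.0
                * _CARBON_PER_SPECIES[species])

    out = []
    for i in range(1, len(df)):
        consumed = (mmol_c(df["glucose"], "glucose").iloc[i - 1]
                    - mmol_c(df["glucose"], "glucose").iloc[i]
                    + mmol_c(df["xylose"], "xylose").iloc[i - 1]
                    - mmol_c(df["xylose"], "xylose").iloc[i])
        produced = ((df["biomass"].iloc[i] - df["biomass"].iloc[i - 1]) * c_biomass
                    + mmol_c(df["citrate"], "citrate").iloc[i]
                    - mmol_c(df["citrate"], "citrate").iloc[i - 1])
        clamped = False
        if not diag.empty and "v_co2" in diag.columns:
            step = diag.iloc[i - 1]
            dt = df["t"].iloc[i] - df["t"].iloc[i - 1]
            produced += step["v_co2"] * df["biomass"].iloc[i - 1] * dt
            clamped = bool(step.get("clamped"))
        out.append(produced / consumed
                   if consumed > 1e-12 and not clamped else np.nan)
    return pd.Series(out, index=df["t"].iloc[1:].to_numpy(), name="carbon_recovery")


# ---------------------------------------------------------------------------
# Model/Results pair for simulation and parameter fitting
# ---------------------------------------------------------------------------

class FermentationModel:
    """Dynamic-FBA fermentation model bound to a metabolic network.

    Construct from a :class:`MetabolicModel`, kinetic parameters and an
    initial state; ``simulate`` integrates the fermentation and ``fit``
    estimates selected kinetic parameters from observed concentration
    time series by nonlinear least squares.
    """

    def __init__(self, model: MetabolicModel,
                 params: KineticParameters | None = None,
                 initial_state: FermentationState | None = None,
                 roles: ReactionRoles | None = None,
                 objective_policy: str = "growth_then_citrate"):
        self.model = model
        self.params = params or KineticParameters()
        self.roles = roles or ReactionRoles()
        self.objective_policy = objective_policy
        self.initial_state = initial_state or FermentationState(
            t=self.params.t_start, biomass=0.05, glucose=80.0, xylose=40.0,
            citrate=0.0, phosphate=2.0)

    @classmethod
    def from_dataframe(cls, model: MetabolicModel, initial: pd.Series | dict,
                       params: KineticParameters | None = None,
                       **kwargs) -> "FermentationModel":
        """Construct with the initial state taken from a data row."""
        params = params or KineticParameters()
        state = FermentationState(
            t=params.t_start,
            biomass=float(initial["biomass"]), glucose=float(initial["glucose"]),
            xylose=float(initial["xylose"]), citrate=float(initial["citrate"]),
            phosphate=float(initial["phosphate"]))
        return cls(model, params=params, initial_state=state, **kwargs)

    def simulate(self, t_end: float, dt: float = 0.1,
                 params: KineticParameters | None = None) -> Trajectory:
        return run_dfba(self.model, params or self.params, self.initial_state,
                        t_end, dt, self.objective_policy, self.roles)

    def fit(self, data: pd.DataFrame,
            param_names: tuple[str, ...] = ("vmax_glc_high",),
            species: tuple[str, ...] = ("glucose",),
            dt: float = 0.25, n_grid: int = 7,
            grid_span: float = 2.0) -> "FermentationFitResult":
        """Least-squares fit of kinetic parameters to observed time series.

        ``data`` is wide: a ``t`` column plus one column per fitted species
        (replicates may simply be stacked as extra rows).

        Discrete events (phase switches, substrate depletion crossing a
        sample point) make the objective piecewise smooth, so a coarse
        multiplicative grid around the starting values locates the basin
        before the derivative-based polish. ``grid_span`` is the factor
        covered on each side (log-spaced, ``n_grid`` points per parameter).
        """
        from itertools import product as _product

        from scipy.optimize import least_squares

        t_obs = data["t"].to_numpy(float)
        t_end = float(t_obs.max())
        x0 = np.array([getattr(self.params, n) for n in param_names])
        scales = {
            s: max(float(np.abs(data[s]).max()), 1e-6) for s in species}

        def residuals(x: np.ndarray) -> np.ndarray:
            trial = self.params.replace(**dict(zip(param_names, x)))
            traj = self.simulate(t_end + dt, dt=dt, params=trial)
            sim = traj.to_dataframe()
            res = []
            for s in species:
                sim_at_obs = np.interp(t_obs, sim["t"], sim[s])
                res.append((sim_at_obs - data[s].to_numpy(float)) / scales[s])
            return np.concatenate(res)

        best_x, best_sse = x0, float(np.sum(residuals(x0) ** 2))
        if n_grid > 1:
            factors = np.logspace(-np.log10(grid_span), np.log10(grid_span),
                                  n_grid)
            for combo in _product(factors, repeat=len(x0)):
                x = x0 * np.asarray(combo)
                sse = float(np.sum(residuals(x) ** 2))
                if sse < best_sse:
                    best_x, best_sse = x, sse
        result = least_squares(residuals, best_x, bounds=(1e-9, np.inf),
                               diff_step=1e-3, xtol=1e-10)
        n, k = result.fun.size, x0.size
        dof = max(n - k, 1)
        sigma2 = 2.0 * result.cost / dof
        JtJ = result.jac.T @ result.jac
        try:
            cov = np.linalg.inv(JtJ) * sigma2
            bse = np.sqrt(np.diag(cov))
        except np.linalg.LinAlgError:
            bse = np.full(k, np.nan)
        params = dict(zip(param_names, result.x))
        fitted = self.params.replace(**params)
        return FermentationFitResult(
            params=params, bse=dict(zip(param_names, bse)),
            cost=float(result.cost), n_obs=n, success=bool(result.success),
            fitted_params=fitted, model=self, scipy_result=result)


@dataclass
class FermentationFitResult:
    """Estimates, standard errors and diagnostics from a kinetic fit."""

    params: dict[str, float]
    bse: dict[str, float]
    cost: float
    n_obs: int
    success: bool
    fitted_params: KineticParameters
    model: FermentationModel
    scipy_result: object = None

    def summary(self) -> str:
        lines = [
            "Fermentation kinetic fit (nonlinear least squares)",
            "=" * 52,
            f"{'parameter':<22}{'estimate':>12}{'std err':>12}",
            "-" * 52,
        ]
        for name, value in self.params.items():
            se = self.bse.get(name, float("nan"))
            lines.append(f"{name:<22}{value:>12.5g}{se:>12.3g}")
        lines += [
            "-" * 52,
            f"observations: {self.n_obs}    cost: {self.cost:.6g}    "
            f"converged: {self.success}",
        ]
        return "\n".join(lines)
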