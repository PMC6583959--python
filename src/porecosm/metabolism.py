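"""Stoichiometric models and the FBA/dFBA engine.

A :class:`MetabolicModel` is a plain stoichiometric matrix with reaction
bounds, a biomass objective and an exchange map (solute name -> exchange
reaction).  Flux balance analysis maximises the biomass flux subject to
S v = 0 and the bounds; uptake follows the standard sign convention
(negative exchange flux = uptake).

Linear programs are solved with GLPK through swiglpk: each model keeps one
persistent problem object whose bounds are updated in place between solves,
so the warm-started simplex costs microseconds — the property that makes
node-pooled dynamic FBA affordable at every node of a network every step.

Dynamic FBA at a node converts local nutrient moles into uptake bounds:

    bound_s = min(max_uptake_s, moles_available / (B_gDW * dt))

(in mmol gDW^-1 h^-1), which guarantees the step never consumes more than
the node holds.  When several species pools share a node, available moles
are first divided equally per cell, with unclaimed surplus redistributed
among still-hungry pools (water-filling), so that no pool is oversubscribed
and allocation does not depend on any iteration order.

Model reduction itself is out of scope; the consistency of a reduced model
against its full-scale parent is assessed with the flux-variability
comparison scheme: FVA envelopes of all common reactions over a grid of
uptake-rate fractions, binned by envelope difference.
"""

from __future__ import annotations

import itertools
import math
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

import swiglpk as glp

from . import units

__all__ = [
    "MetabolicModel",
    "FluxSolution",
    "read_model",
    "write_tabular",
    "fba",
    "fva",
    "node_dfba",
    "allocate_node_moles",
    "condition_grid",
    "compare_models_fva",
    "DIFF_BINS",
]

#: Flux-difference bin edges (mmol gDW^-1 h^-1) for model comparison.
DIFF_BINS = (0.1, 1.0, 10.0)
BIN_LABELS = ("<0.1", "0.1-1", "1-10", ">10")

_INF = 1e30


@dataclass
class FluxSolution:
    """Result of one FBA solve."""

    status: str  # "optimal" | "infeasible"
    mu: float  # growth rate, h^-1
    exchange_fluxes: dict[str, float]  # mmol/gDW/h per mapped solute
    fluxes: dict[str, float] | None = None

    @property
    def mu_per_second(self) -> float:
        return units.per_hour_to_per_second(self.mu)


@dataclass
class MetabolicModel:
    """Stoichiometric model with biomass objective and exchange map."""

    name: str
    metabolites: list[str]
    reactions: list[str]
    S: np.ndarray  # metabolites x reactions
    lb: np.ndarray
    ub: np.ndarray
    biomass: str
    exchanges: dict[str, str]  # solute name -> reaction id
    max_uptake: dict[str, float] = field(default_factory=dict)
    carbon: dict[str, float] = field(default_factory=dict)  # C atoms per metabolite
    biomass_carbon: float = 0.0  # mmol C fixed per unit biomass flux
    equations: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=float)
        self.lb = np.asarray(self.lb, dtype=float)
        self.ub = np.asarray(self.ub, dtype=float)
        if self.S.shape != (len(self.metabolites), len(self.reactions)):
            raise ValueError("S shape does not match metabolite/reaction lists")
        if self.biomass not in self.reactions:
            raise ValueError(f"biomass reaction {self.biomass!r} missing from model")
        for sol, rid in self.exchanges.items():
            if rid not in self.reactions:
                raise ValueError(f"exchange for {sol!r} maps to missing reaction {rid!r}")
        self._ridx = {r: j for j, r in enumerate(self.reactions)}
        self._solver: _GlpkProblem | None = None

    def reaction_index(self, rid: str) -> int:
        return self._ridx[rid]

    @property
    def biomass_index(self) -> int:
        return self._ridx[self.biomass]

    def solver(self) -> "_GlpkProblem":
        if self._solver is None:
            self._solver = _GlpkProblem(self)
        return self._solver

    def check_consistency(self) -> None:
        """All-uptakes-closed FBA must give zero growth."""
        sol = fba(self, {})
        if sol.status == "optimal" and sol.mu > 1e-9:
            raise ValueError(
                f"model {self.name!r} grows (mu={sol.mu:g}/h) with every uptake closed"
            )

    def carbon_imbalance(self) -> dict[str, float]:
        """Net carbon created per unit flux for internal reactions.

        Exchange reactions and the biomass reaction are exempt (they move
        carbon across the system boundary by design).
        """
        out = {}
        cvec = np.array([self.carbon.get(m, 0.0) for m in self.metabolites])
        exchange_ids = set(self.exchanges.values()) | {
            r for j, r in enumerate(self.reactions)
            if np.count_nonzero(self.S[:, j]) == 1
        }
        for j, r in enumerate(self.reactions):
            if r == self.biomass or r in exchange_ids:
                continue
            out[r] = float(cvec @ self.S[:, j])
        return out


# -- equation-string dialect ----------------------------------------------

_ARROW = re.compile(r"<->|->")


def parse_equation(rid: str, text: str) -> dict[str, float]:
    """Parse ``"2 A + B -> C"`` into a stoichiometry dict (products +)."""
    m = _ARROW.search(text)
    if m is None:
        raise ValueError(f"reaction {rid!r}: no '->' or '<->' arrow in {text!r}")
    left, right = text[: m.start()], text[m.end():]
    stoich: dict[str, float] = {}

    def add(side: str, sign: float) -> None:
        for term in side.split("+"):
            term = term.strip()
            if not term:
                continue
            parts = term.split()
            if len(parts) == 1:
                coef, met = 1.0, parts[0]
            elif len(parts) == 2:
                try:
                    coef = float(parts[0])
                except ValueError as exc:
                    raise ValueError(
                        f"reaction {rid!r}: bad stoichiometric coefficient "
                        f"{parts[0]!r}"
                    ) from exc
                met = parts[1]
            else:
                raise ValueError(f"reaction {rid!r}: cannot parse term {term!r}")
            stoich[met] = stoich.get(met, 0.0) + sign * coef

    add(left, -1.0)
    add(right, +1.0)
    return stoich


def format_equation(stoich: dict[str, float], reversible: bool) -> str:
    def side(items):
        return " + ".join(
            (f"{abs(c):g} {m}" if abs(c) != 1.0 else m) for m, c in items
        )

    left = [(m, c) for m, c in stoich.items() if c < 0]
    right = [(m, c) for m, c in stoich.items() if c > 0]
    arrow = "<->" if reversible else "->"
    return f"{side(left)} {arrow} {side(right)}".strip()


def _parse_kv(text: str) -> dict[str, float | str]:
    out: dict[str, float | str] = {}
    for item in text.split(","):
        if not item.strip():
            continue
        k, v = item.split("=")
        k, v = k.strip(), v.strip()
        try:
            out[k] = float(v)
        except ValueError:
            out[k] = v
    return out


def read_tabular(path) -> MetabolicModel:
    """Read the tab-separated stoichiometry dialect.

    Leading ``# key: value`` comment lines carry the annotations: ``name``,
    ``biomass``, ``exchange`` (solute=reaction pairs), ``max_uptake``,
    ``carbon`` (metabolite=C-count pairs) and ``biomass_carbon``.
    """
    path = Path(path)
    meta: dict[str, str] = {}
    rows = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    body = []
    for line in lines:
        if line.startswith("#"):
            if ":" in line:
                k, v = line.lstrip("#").split(":", 1)
                meta[k.strip()] = v.strip()
        elif line.strip():
            body.append(line)
    header = body[0].split("\t")
    if header[:4] != ["id", "equation", "lb", "ub"]:
        raise ValueError(f"{path}: expected header id/equation/lb/ub, got {header}")
    for line in body[1:]:
        fields = line.split("\t")
        if len(fields) != 4:
            raise ValueError(f"{path}: malformed row {line!r}")
        rows.append(fields)
    if "biomass" not in meta:
        raise ValueError(f"{path}: missing '# biomass:' annotation")

    reactions, equations, lb, ub = [], {}, [], []
    stoichs = {}
    mets: list[str] = []
    seen = set()
    for rid, eq, lo, hi in rows:
        reactions.append(rid)
        equations[rid] = eq
        stoich = parse_equation(rid, eq)
        stoichs[rid] = stoich
        for m in stoich:
            if m not in seen:
                seen.add(m)
                mets.append(m)
        try:
            lb.append(float(lo))
            ub.append(float(hi))
        except ValueError as exc:
            raise ValueError(f"reaction {rid!r}: bad bound {lo!r}/{hi!r}") from exc
    S = np.zeros((len(mets), len(reactions)))
    midx = {m: i for i, m in enumerate(mets)}
    for j, rid in enumerate(reactions):
        for m, c in stoichs[rid].items():
            S[midx[m], j] = c
    exchanges = {k: str(v) for k, v in _parse_kv(meta.get("exchange", "")).items()}
    max_uptake = {k: float(v) for k, v in _parse_kv(meta.get("max_uptake", "")).items()}
    carbon = {k: float(v) for k, v in _parse_kv(meta.get("carbon", "")).items()}
    return MetabolicModel(
        name=meta.get("name", path.stem),
        metabolites=mets,
        reactions=reactions,
        S=S,
        lb=np.array(lb),
        ub=np.array(ub),
        biomass=meta["biomass"],
        exchanges=exchanges,
        max_uptake=max_uptake,
        carbon=carbon,
        biomass_carbon=float(meta.get("biomass_carbon", 0.0)),
        equations=equations,
    )


def write_tabular(model: MetabolicModel, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# name: {model.name}\n")
        fh.write(f"# biomass: {model.biomass}\n")
        if model.exchanges:
            fh.write(
                "# exchange: "
                + ", ".join(f"{k}={v}" for k, v in model.exchanges.items())
                + "\n"
            )
        if model.max_uptake:
            fh.write(
                "# max_uptake: "
                + ", ".join(f"{k}={v:g}" for k, v in model.max_uptake.items())
                + "\n"
            )
        if model.carbon:
            fh.write(
                "# carbon: "
                + ", ".join(f"{k}={v:g}" for k, v in model.carbon.items())
                + "\n"
            )
        if model.biomass_carbon:
            fh.write(f"# biomass_carbon: {model.biomass_carbon:g}\n")
        fh.write("id\tequation\tlb\tub\n")
        for j, rid in enumerate(model.reactions):
            eq = model.equations.get(rid)
            if eq is None:
                stoich = {
                    m: model.S[i, j]
                    for i, m in enumerate(model.metabolites)
                    if model.S[i, j] != 0
                }
                eq = format_equation(stoich, model.lb[j] < 0)
            fh.write(f"{rid}\t{eq}\t{model.lb[j]:g}\t{model.ub[j]:g}\n")


def read_sbml(path, exchanges: dict[str, str] | None = None,
              max_uptake: dict[str, float] | None = None) -> MetabolicModel:
    """Read an SBML (FBC) model via cobrapy and convert.

    The biomass reaction is taken from the model objective; the exchange
    map defaults to cobra's boundary reactions keyed by the exchanged
    metabolite id.
    """
    import cobra.io

    cm = cobra.io.read_sbml_model(str(path))
    reactions = [r.id for r in cm.reactions]
    mets = [m.id for m in cm.metabolites]
    midx = {m: i for i, m in enumerate(mets)}
    S = np.zeros((len(mets), len(reactions)))
    lb, ub = [], []
    for j, r in enumerate(cm.reactions):
        for m, c in r.metabolites.items():
            S[midx[m.id], j] = c
        lb.append(r.lower_bound)
        ub.append(r.upper_bound)
    objective = [r.id for r in cm.reactions if r.objective_coefficient]
    if len(objective) != 1:
        raise ValueError(f"{path}: expected a single biomass objective, got {objective}")
    if exchanges is None:
        exchanges = {
            list(r.metabolites)[0].id: r.id for r in cm.boundary if len(r.metabolites) == 1
        }
    return MetabolicModel(
        name=cm.id or Path(str(path)).stem,
        metabolites=mets,
        reactions=reactions,
        S=S,
        lb=np.array(lb),
        ub=np.array(ub),
        biomass=objective[0],
        exchanges=exchanges,
        max_uptake=dict(max_uptake or {}),
    )


def read_model(path, **kwargs) -> MetabolicModel:
    """Dispatch on extension: ``.xml``/``.sbml`` via SBML, else tabular."""
    suffix = Path(path).suffix.lower()
    if suffix in (".xml", ".sbml"):
        return read_sbml(path, **kwargs)
    return read_tabular(path)


# -- GLPK backend ---------------------------------------------------------


class _GlpkProblem:
    """Persistent GLPK LP for one model; bounds mutated between solves."""

    def __init__(self, model: MetabolicModel) -> None:
        self.model = model
        n_m, n_r = model.S.shape
        lp = glp.glp_create_prob()
        glp.glp_set_obj_dir(lp, glp.GLP_MAX)
        glp.glp_add_rows(lp, n_m)
        for i in range(n_m):
            glp.glp_set_row_bnds(lp, i + 1, glp.GLP_FX, 0.0, 0.0)
        glp.glp_add_cols(lp, n_r)
        for j in range(n_r):
            self._set_col(lp, j, model.lb[j], model.ub[j])
        nz = np.nonzero(model.S)
        k = len(nz[0])
        ia, ja, ar = glp.intArray(k + 1), glp.intArray(k + 1), glp.doubleArray(k + 1)
        for idx, (i, j) in enumerate(zip(*nz), start=1):
            ia[idx], ja[idx], ar[idx] = int(i) + 1, int(j) + 1, float(model.S[i, j])
        glp.glp_load_matrix(lp, k, ia, ja, ar)
        self.lp = lp
        self.parm = glp.glp_smcp()
        glp.glp_init_smcp(self.parm)
        self.parm.msg_lev = glp.GLP_MSG_OFF
        self._obj: dict[int, float] = {}

    @staticmethod
    def _set_col(lp, j: int, lo: float, hi: float) -> None:
        lo = -_INF if lo < -1e29 or math.isinf(lo) and lo < 0 else lo
        hi = _INF if hi > 1e29 or math.isinf(hi) and hi > 0 else hi
        if lo == hi:
            glp.glp_set_col_bnds(lp, j + 1, glp.GLP_FX, lo, hi)
        elif lo <= -_INF and hi >= _INF:
            glp.glp_set_col_bnds(lp, j + 1, glp.GLP_FR, 0.0, 0.0)
        elif lo <= -_INF:
            glp.glp_set_col_bnds(lp, j + 1, glp.GLP_UP, 0.0, hi)
        elif hi >= _INF:
            glp.glp_set_col_bnds(lp, j + 1, glp.GLP_LO, lo, 0.0)
        else:
            glp.glp_set_col_bnds(lp, j + 1, glp.GLP_DB, lo, hi)

    def set_bounds(self, j: int, lo: float, hi: float) -> None:
        self._set_col(self.lp, j, lo, hi)

    def set_objective(self, cols: dict[int, float]) -> None:
        if cols == self._obj:
            return
        for j in self._obj:
            glp.glp_set_obj_coef(self.lp, j + 1, 0.0)
        for j, c in cols.items():
            glp.glp_set_obj_coef(self.lp, j + 1, c)
        self._obj = dict(cols)

    def solve(self, columns=None) -> tuple[str, float, np.ndarray]:
        """Optimise; return fluxes for ``columns`` (default: all)."""
        ret = glp.glp_simplex(self.lp, self.parm)
        status = glp.glp_get_status(self.lp)
        if ret != 0 or status != glp.GLP_OPT:
            # cold-start retry covers rare warm-basis failures
            glp.glp_std_basis(self.lp)
            glp.glp_simplex(self.lp, self.parm)
            status = glp.glp_get_status(self.lp)
        cols = range(len(self.model.reactions)) if columns is None else columns
        if status != glp.GLP_OPT:
            return "infeasible", 0.0, np.zeros(len(list(cols)))
        prim = glp.glp_get_col_prim
        lp = self.lp
        v = np.array([prim(lp, int(j) + 1) for j in cols])
        return "optimal", glp.glp_get_obj_val(lp), v

    def __del__(self) -> None:  # pragma: no cover
        try:
            glp.glp_delete_prob(self.lp)
        except Exception:
            pass


def _apply_uptake_bounds(model: MetabolicModel, uptake_bounds: dict[str, float]):
    """Set exchange lower bounds to -bound (0 for unmentioned solutes)."""
    prob = model.solver()
    for sol, rid in model.exchanges.items():
        j = model.reaction_index(rid)
        bound = float(uptake_bounds.get(sol, 0.0))
        if bound < 0:
            raise ValueError(f"uptake bound for {sol!r} must be >= 0, got {bound}")
        prob.set_bounds(j, -bound, model.ub[j])
    return prob


def fba(model: MetabolicModel, uptake_bounds: dict[str, float]) -> FluxSolution:
    """Maximise biomass flux under the given uptake-rate magnitudes.

    Solutes in the exchange map that are absent from ``uptake_bounds`` are
    closed; unmapped reactions keep their stored bounds.
    """
    prob = _apply_uptake_bounds(model, uptake_bounds)
    prob.set_objective({model.biomass_index: 1.0})
    status, obj, v = prob.solve()
    if status != "optimal":
        return FluxSolution(status="infeasible", mu=0.0, exchange_fluxes={})
    exch = {}
    for sol, rid in model.exchanges.items():
        flux = float(v[model.reaction_index(rid)])
        bound = float(uptake_bounds.get(sol, 0.0))
        exch[sol] = max(flux, -bound)  # clamp solver jitter at the bound
    return FluxSolution(
        status="optimal",
        mu=max(float(obj), 0.0),
        exchange_fluxes=exch,
        fluxes=dict(zip(model.reactions, v.tolist())),
    )


def fva(
    model: MetabolicModel,
    uptake_bounds: dict[str, float],
    fraction: float = 1.0,
    reactions: list[str] | None = None,
) -> dict[str, tuple[float, float]]:
    """Flux envelopes (min, max) per reaction with the biomass flux held at
    ``fraction`` of its FBA optimum."""
    base = fba(model, uptake_bounds)
    if base.status != "optimal":
        return {}
    prob = _apply_uptake_bounds(model, uptake_bounds)
    b = model.biomass_index
    prob.set_bounds(b, fraction * base.mu, model.ub[b])
    out = {}
    try:
        for rid in reactions if reactions is not None else model.reactions:
            j = model.reaction_index(rid)
            lo_hi = []
            for sense in (-1.0, 1.0):
                prob.set_objective({j: sense})
                status, obj, _ = prob.solve()
                if status != "optimal":
                    lo_hi = None
                    break
                lo_hi.append(sense * obj)
            if lo_hi is not None:
                out[rid] = (lo_hi[0], lo_hi[1])
    finally:
        prob.set_bounds(b, model.lb[b], model.ub[b])
    return out


# -- dynamic FBA ----------------------------------------------------------


def uptake_bounds_from_environment(
    model: MetabolicModel,
    biomass_kg: float,
    concentrations: dict[str, float],
    v_w: float,
    dt: float,
    allocation: dict[str, float] | None = None,
) -> dict[str, float]:
    """Per-solute uptake bounds from local moles, biomass and step length.

    ``allocation`` overrides the available moles per solute (used when
    several pools share a node); otherwise availability is C * V_w.
    """
    bounds = {}
    for sol in model.exchanges:
        if allocation is not None and sol in allocation:
            avail = allocation[sol]
        else:
            avail = concentrations.get(sol, 0.0) * v_w  # mol
        cap = units.moles_to_flux(max(avail, 0.0), biomass_kg, dt)
        bounds[sol] = min(model.max_uptake.get(sol, 0.0), cap)
    return bounds


def node_dfba(
    model: MetabolicModel,
    biomass_kg: float,
    concentrations: dict[str, float],
    v_w: float,
    dt: float,
    allocation: dict[str, float] | None = None,
) -> tuple[FluxSolution, dict[str, float]]:
    """One dFBA step for one species pool at one node.

    Returns the flux solution and the moles *added to the environment* per
    mapped solute (negative = consumed); consumption can never exceed the
    local availability because the uptake bound is capped by it.
    """
    if biomass_kg <= 0:
        raise ValueError("node_dfba needs positive biomass")
    if v_w <= 0:
        raise ValueError("node_dfba needs positive water volume")
    bounds = uptake_bounds_from_environment(
        model, biomass_kg, concentrations, v_w, dt, allocation
    )
    sol = fba(model, bounds)
    moles = {
        s: units.flux_to_moles(f, biomass_kg, dt)
        for s, f in sol.exchange_fluxes.items()
    }
    return sol, moles


def allocate_node_moles(
    available: float, cells: np.ndarray, demand: np.ndarray
) -> np.ndarray:
    """Divide ``available`` moles among pools of ``cells`` cells with mole
    ``demand`` caps: equal share per cell, surplus redistributed among
    pools still below their cap until exhausted (water-filling)."""
    cells = np.asarray(cells, dtype=float)
    demand = np.asarray(demand, dtype=float)
    alloc = np.zeros_like(demand)
    remaining = max(float(available), 0.0)
    active = (cells > 0) & (demand > alloc)
    for _ in range(len(demand)):
        if remaining <= 0 or not active.any():
            break
        share = remaining / cells[active].sum()
        grant = np.minimum(demand[active] - alloc[active], share * cells[active])
        alloc[active] += grant
        remaining -= float(grant.sum())
        newly_full = np.zeros_like(active)
        newly_full[active] = grant >= (demand[active] - alloc[active]) - 1e-30
        active &= demand - alloc > 1e-30
        if remaining <= available * 1e-15:
            break
    return alloc


# -- model comparison -----------------------------------------------------


def condition_grid(
    substrates: list[str],
    max_uptakes: dict[str, float],
    fractions: tuple[float, ...] = (1.0, 0.6, 0.2),
) -> list[dict[str, float]]:
    """Cartesian product of uptake-rate fractions over substrates:
    len(fractions) ** len(substrates) bound-sets."""
    if not substrates:
        raise ValueError("need at least one substrate")
    grid = []
    for combo in itertools.product(fractions, repeat=len(substrates)):
        grid.append({s: f * max_uptakes[s] for s, f in zip(substrates, combo)})
    return grid


def compare_models_fva(
    model_full: MetabolicModel,
    model_reduced: MetabolicModel,
    conditions: list[dict[str, float]],
    fraction: float = 1.0,
) -> pd.DataFrame:
    """Binned FVA-envelope agreement between a full and a reduced model.

    For every condition and every common reaction the comparison statistic
    is max(|d min|, |d max|) of the flux envelope, binned into
    ``<0.1 / 0.1-1 / 1-10 / >10`` mmol gDW^-1 h^-1.  Returns one row per
    condition with the bin fractions; medians and standard deviations
    across conditions are available via :func:`summarize_comparison`.
    """
    common = [r for r in model_full.reactions if r in set(model_reduced.reactions)]
    if not common:
        raise ValueError("models have no common reactions")
    rows = []
    for cond in conditions:
        env_f = fva(model_full, cond, fraction, reactions=common)
        env_r = fva(model_reduced, cond, fraction, reactions=common)
        diffs = []
        for rid in common:
            if rid not in env_f or rid not in env_r:
                continue
            dmin = abs(env_f[rid][0] - env_r[rid][0])
            dmax = abs(env_f[rid][1] - env_r[rid][1])
            diffs.append(max(dmin, dmax))
        diffs = np.asarray(diffs)
        counts = np.histogram(diffs, bins=(-np.inf, *DIFF_BINS, np.inf))[0]
        fracs = counts / counts.sum()
        row = {"condition": str(cond)}
        row.update(dict(zip(BIN_LABELS, fracs)))
        rows.append(row)
    return pd.DataFrame(rows)


def summarize_comparison(table: pd.DataFrame) -> pd.DataFrame:
    """Median and standard deviation of each bin fraction across conditions."""
    stats = {
        label: (table[label].median(), table[label].std(ddof=1))
        for label in BIN_LABELS
    }
    return pd.DataFrame(
        {"bin": list(stats), "median": [v[0] for v in stats.values()],
         "sd": [v[1] for v in stats.values()]}
    )
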