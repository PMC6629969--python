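"""Inverse utility estimation: constraints from an observed network + LP.

Assuming the observed attributed network is pairwise stable, every unordered
pair of neurons yields two linear inequalities in the six utility
coefficients — one per endpoint — built from the difference between the
endpoint's utility with the pair linked and with it unlinked:

    delta = (D_ij, B_ij, S_i - S'_i, P_i - P'_i, C_i - C'_i, Be_i - Be'_i)

(the link-cost terms D and B exist only in the linked state, so they enter
un-differenced).  Two sense conventions are first-class:

* ``as_printed`` — linked pairs constrain ``delta . c <= 0`` and unlinked
  pairs ``delta . c >= 0``; this is the orientation that produces the
  all-negative coefficient signature on real connectome data.
* ``standard`` — the reverse, which is the literal pairwise-stability
  direction (an existing link must not profit from deletion).

The estimate minimizes the sum of linked-state utilities over the
constraints within box bounds (default [-1, 1], where the interesting
solutions saturate).  The system is homogeneous, so the zero vector is
always feasible; the objective plus bounds select a non-trivial vertex.
``mode='soft'`` attaches a non-negative penalized slack to every constraint,
which is the right tool when the per-endpoint inequalities slightly
over-constrain a genuinely stable network (pairwise stability only forbids
*joint* profitable additions).  Global optimality is not required — any
feasible bounded optimum from the solver is accepted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.optimize import linprog

from .game import (
    FEATURE_NAMES,
    GameConfig,
    UtilityCoefficients,
    _Evaluator,
    all_pairs,
)
from .netio import AttributeTable

COEFF_NAMES = ("alpha", "beta", "lam", "rho", "theta", "omega")


@dataclass(frozen=True)
class ConstraintRecord:
    pair: tuple
    endpoint: str
    linked: bool
    feature_delta: np.ndarray  # length 6: multipliers of (alpha..omega)
    sense: str  # 'le0' or 'ge0'
    linked_features: np.ndarray  # endpoint's 6-vector in the linked state


@dataclass
class ConstraintSet:
    records: list[ConstraintRecord]
    n_nodes: int
    convention: str

    def __len__(self):
        return len(self.records)

    def delta_matrix(self) -> np.ndarray:
        return np.array([r.feature_delta for r in self.records])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            row = {
                "node_i": r.pair[0], "node_j": r.pair[1],
                "endpoint": r.endpoint, "linked": r.linked, "sense": r.sense,
            }
            row.update({f"d_{n}": v for n, v in zip(FEATURE_NAMES, r.feature_delta)})
            rows.append(row)
        return pd.DataFrame(rows)


@dataclass
class FitResult:
    coefficients: UtilityCoefficients | None
    objective_value: float
    n_satisfied: int
    n_violated: int
    solver_status: str
    slack_total: float = 0.0
    feature_scale: np.ndarray = field(default_factory=lambda: np.ones(6))

    def raw_coefficients(self) -> UtilityCoefficients:
        """Coefficients applicable to raw-unit features (D in µm, B in min)."""
        if self.coefficients is None:
            raise ValueError("no coefficients (solver failed)")
        if not self.coefficients.normalized_features:
            return self.coefficients
        return UtilityCoefficients.from_array(
            self.coefficients.as_array() / self.feature_scale,
            normalized_features=False,
        )


def build_constraints(g: nx.DiGraph, attrs: AttributeTable,
                      convention: str = "as_printed",
                      config: GameConfig | None = None) -> ConstraintSet:
    """Build the n(n-1) per-endpoint stability inequalities for *g*.

    All six features are evaluated in both pair states with every other
    edge fixed; each record carries only its own endpoint's feature
    differences.
    """
    if convention not in ("as_printed", "standard"):
        raise ValueError("convention must be 'as_printed' or 'standard'")
    cfg = config or GameConfig()
    missing = set(g.nodes) - set(attrs.ids)
    if missing:
        raise KeyError(f"attributes missing for nodes: {sorted(missing)[:5]}")
    ev = _Evaluator(g.copy(), attrs, cfg, need_pagerank=True, need_betweenness=True)
    records: list[ConstraintRecord] = []
    for i, j in all_pairs(g.nodes):
        linked = ev.linked(i, j)
        (fi_l, fj_l), (fi_u, fj_u) = ev.pair_state_features(i, j)
        if convention == "as_printed":
            sense = "le0" if linked else "ge0"
        else:
            sense = "ge0" if linked else "le0"
        for endpoint, f_l, f_u in ((i, fi_l, fi_u), (j, fj_l, fj_u)):
            delta = f_l.as_array() - f_u.as_array()  # D, B survive untouched
            records.append(ConstraintRecord(
                pair=(i, j), endpoint=endpoint, linked=linked,
                feature_delta=delta, sense=sense,
                linked_features=f_l.as_array(),
            ))
    return ConstraintSet(records=records, n_nodes=g.number_of_nodes(),
                         convention=convention)


def residual_check(constraints: ConstraintSet, coeffs: UtilityCoefficients,
                   tol: float = 1e-7,
                   feature_scale: np.ndarray | None = None) -> tuple[int, int]:
    """(n_satisfied, n_violated) recomputed independently of the solver.

    *feature_scale* maps normalized-space coefficients onto the raw feature
    deltas; pass the fit's ``feature_scale`` when checking a normalized
    estimate.
    """
    c = coeffs.as_array()
    if feature_scale is not None and coeffs.normalized_features:
        c = c / np.asarray(feature_scale, dtype=float)
    sat = 0
    for r in constraints.records:
        v = float(r.feature_delta @ c)
        ok = v <= tol if r.sense == "le0" else v >= -tol
        sat += ok
    return sat, len(constraints.records) - sat


def _interval_midpoint(c_vec, A_full, var_bounds, res, rel_tol: float) -> np.ndarray:
    """Coefficient ranging over the near-optimal set; midpoint per coefficient."""
    z = float(c_vec @ res.x)
    budget = z + max(abs(z) * rel_tol, 1e-9)
    m = A_full.shape[0]
    A2 = np.vstack([A_full, c_vec])
    b2 = np.concatenate([np.zeros(m), [budget]])
    mid = np.array(res.x[:6])
    for k in range(6):
        ends = []
        for sgn in (1.0, -1.0):
            d = np.zeros(len(c_vec))
            d[k] = sgn
            rr = linprog(d, A_ub=A2, b_ub=b2, bounds=var_bounds, method="highs")
            if not rr.success:
                break
            ends.append(rr.x[k])
        if len(ends) == 2:
            mid[k] = 0.5 * (ends[0] + ends[1])
    return mid


def fit_coefficients(constraints: ConstraintSet,
                     bounds: tuple[float, float] = (-1.0, 1.0),
                     mode: str = "hard",
                     penalty: float = 100.0,
                     normalize: bool = False,
                     objective: np.ndarray | None = None,
                     refine: str | None = None,
                     refine_rel_tol: float = 0.01) -> FitResult:
    """Estimate the coefficients by linear programming.

    Minimizes ``objective . c`` (default: the sum of linked-state utilities,
    linear in c) subject to the constraint senses and box *bounds* on each
    coefficient.  ``mode='soft'`` relaxes every constraint with its own
    non-negative slack, penalized at *penalty* per unit, and reports the
    satisfied/violated split from an independent residual check.
    ``normalize=True`` rescales each feature column to unit maximum
    magnitude before solving and reports the coefficients *in that
    normalized feature space* (``normalized_features=True``; the per-column
    scale is returned as ``feature_scale``) — this conditions the LP, keeps
    the reported coefficients inside the box bounds, and is the space in
    which saturated-at-the-bound estimates are meaningful.  Divide by
    ``feature_scale`` to apply them to raw-unit features
    (:meth:`FitResult.raw_coefficients`).

    ``refine='interval_midpoint'`` applies standard LP coefficient ranging
    to resolve degenerate optima: within the near-optimal set (total cost
    at most ``(1 + refine_rel_tol)`` of the optimum) each coefficient's
    attainable minimum and maximum are computed by two auxiliary LPs and
    the interval midpoint is reported.  A coefficient whose sign the data
    pin down keeps it; one that merely sits on an arbitrary vertex of a
    degenerate face moves to the centre of its admissible interval.
    """
    if not constraints.records:
        raise ValueError("empty constraint set")
    A = constraints.delta_matrix()
    if objective is None:
        linked_rows = [r.linked_features for r in constraints.records if r.linked]
        objective = (np.sum(linked_rows, axis=0) if linked_rows else np.zeros(6))
    obj = np.asarray(objective, dtype=float).copy()

    scale = np.ones(6)
    if normalize:
        col_max = np.max(np.abs(A), axis=0)
        scale = np.where(col_max > 0, col_max, 1.0)
        A = A / scale
        obj = obj / scale

    # orient every row as a_row . x <= 0
    signs = np.array([1.0 if r.sense == "le0" else -1.0 for r in constraints.records])
    A_ub = A * signs[:, None]
    m = len(constraints.records)

    if mode == "hard":
        c_vec = obj
        A_full = A_ub
        var_bounds = [tuple(bounds)] * 6
    elif mode == "soft":
        # variables: 6 coefficients + one slack per record
        c_vec = np.concatenate([obj, np.full(m, penalty)])
        A_full = np.hstack([A_ub, -np.eye(m)])
        var_bounds = [tuple(bounds)] * 6 + [(0, None)] * m
    else:
        raise ValueError("mode must be 'hard' or 'soft'")

    res = linprog(c_vec, A_ub=A_full, b_ub=np.zeros(m), bounds=var_bounds,
                  method="highs")
    if not res.success:
        return FitResult(coefficients=None, objective_value=float("nan"),
                         n_satisfied=0, n_violated=m,
                         solver_status=res.message, feature_scale=scale)
    x = res.x[:6]
    if refine == "interval_midpoint":
        x = _interval_midpoint(c_vec, A_full, var_bounds, res,
                               rel_tol=refine_rel_tol)
    elif refine is not None:
        raise ValueError(f"unknown refine {refine!r}")
    # a coefficient that appears in no constraint and no objective term is
    # reported as 0, not at an arbitrary vertex
    inert = (np.all(A == 0, axis=0)) & (obj == 0)
    x = np.where(inert, 0.0, x)
    coeffs = UtilityCoefficients.from_array(x, normalized_features=normalize)
    sat, vio = residual_check(constraints, coeffs, feature_scale=scale)
    slack_total = float(np.sum(res.x[6:])) if mode == "soft" else 0.0
    return FitResult(
        coefficients=coeffs,
        objective_value=float(obj @ x),
        n_satisfied=sat,
        n_violated=vio,
        solver_status=str(res.message),
        slack_total=slack_total,
        feature_scale=scale,
    )
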