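"""Hazel-Lush selection indices combining breeding values and IDL.

Three scenarios on a unit genetic scale with heritability-based accuracy
rho = sqrt(h2):

* Index 1 — EBV as criterion and objective; the expected genetic response
  reduces to intensity * sqrt(h2).
* Index 2 — IDL as the sole criterion, EBV as the objective.
* Index 3 — both EBV and IDL as criteria and objectives under economic
  weights p' summing to one.

The machinery is the general one: index weights b = P^-1 Gm p' with P the
criterion covariance matrix and Gm the criterion-objective genetic
covariances; the expected genetic response on the (EBV) objective is
intensity * (Gm' b)_objective / sqrt(b' P b).  Responses are reported
relative to Index 1 fixed at 100%.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class IndexScenario:
    """Genetic assumptions behind one set of index calculations."""

    h2: float
    r_ebv_idl: float = 0.0
    weights: tuple = (1.0, 0.0)      # economic weights on (EBV, IDL)
    selection_intensity: float = 1.0
    additive_variance: float = 1.0

    def __post_init__(self):
        if not 0.0 < self.h2 <= 1.0:
            raise ValueError("h2 must be in (0, 1]")
        if not -1.0 <= self.r_ebv_idl <= 1.0:
            raise ValueError("r_ebv_idl must be in [-1, 1]")
        if self.selection_intensity <= 0:
            raise ValueError("selection intensity must be positive")
        if min(self.weights) < 0:
            raise ValueError("economic weights must be nonnegative")


@dataclass
class IndexResult:
    egr: float                      # objective-trait genetic SD units
    relative_vs_index1: float       # percent; index 1 = 100 by construction
    index_type: int = 1
    weights: tuple = field(default=(1.0, 0.0))


def _pg_matrices(scenario: IndexScenario, criteria: list):
    """Criterion covariance P and criterion-objective covariances Gm.

    Estimated criteria have variance rho^2 * sigma_g^2 and covariance
    rho^2 * sigma_g^2 with their own true value (the BLUP property); the
    cross trait enters through the genetic correlation r.
    """
    rho2 = scenario.h2
    vg = scenario.additive_variance
    r = scenario.r_ebv_idl
    m = len(criteria)
    P = np.empty((m, m))
    Gm = np.empty((m, 2))            # objectives ordered (EBV, IDL)
    for a, ca in enumerate(criteria):
        for b, cb in enumerate(criteria):
            P[a, b] = rho2 * vg * (1.0 if ca == cb else r)
        for o, obj in enumerate(("ebv", "idl")):
            Gm[a, o] = rho2 * vg * (1.0 if ca == obj else r)
    return P, Gm


def _expected_genetic_response(P: np.ndarray, Gm: np.ndarray,
                               weights: np.ndarray, intensity: float,
                               objective: int = 0) -> float:
    """i * (Gm' b)_objective / sqrt(b' P b) with b = P^-1 Gm p'."""
    try:
        b = np.linalg.solve(P, Gm @ weights)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular criterion covariance matrix P") from exc
    denom = float(np.sqrt(b @ P @ b))
    if denom == 0:
        raise ValueError("index has zero variance")
    return intensity * float((Gm.T @ b)[objective]) / denom


def expected_response(scenario: IndexScenario, index_type: int) -> IndexResult:
    """Expected genetic response on the EBV objective for one index."""
    if index_type not in (1, 2, 3):
        raise ValueError("index_type must be 1, 2 or 3")
    if index_type == 1:
        criteria, weights = ["ebv"], np.array([1.0, 0.0])
    elif index_type == 2:
        # all selection emphasis on the IDL criterion; the response is still
        # reported on the EBV objective, so its sign follows r_ebv_idl
        criteria, weights = ["idl"], np.array([0.0, 1.0])
    else:
        criteria = ["ebv", "idl"]
        weights = np.asarray(scenario.weights, dtype=float)
        if abs(weights.sum() - 1.0) > 1e-9:
            raise ValueError("economic weights must sum to 1")
    P, Gm = _pg_matrices(scenario, criteria)
    egr = _expected_genetic_response(P, Gm, weights,
                                     scenario.selection_intensity)
    base = IndexScenario(h2=scenario.h2, r_ebv_idl=scenario.r_ebv_idl,
                         selection_intensity=scenario.selection_intensity,
                         additive_variance=scenario.additive_variance)
    P1, Gm1 = _pg_matrices(base, ["ebv"])
    egr1 = _expected_genetic_response(P1, Gm1, np.array([1.0, 0.0]),
                                      scenario.selection_intensity)
    if index_type == 1:
        rel = 100.0
    else:
        rel = 100.0 * (egr - egr1) / abs(egr1)
    return IndexResult(egr=egr, relative_vs_index1=rel,
                       index_type=index_type,
                       weights=tuple(weights) if index_type == 3 else (1.0, 0.0))


def weight_sweep(scenario: IndexScenario,
                 grid: list | None = None) -> pd.DataFrame:
    """Index-3 responses over a grid of (EBV, IDL) economic weights.

    Defaults to the (0.9, 0.1) ... (0.5, 0.5) ladder.
    """
    if grid is None:
        grid = [(0.9, 0.1), (0.8, 0.2), (0.7, 0.3), (0.6, 0.4), (0.5, 0.5)]
    rows = []
    for w in grid:
        sc = IndexScenario(h2=scenario.h2, r_ebv_idl=scenario.r_ebv_idl,
                           weights=tuple(w),
                           selection_intensity=scenario.selection_intensity,
                           additive_variance=scenario.additive_variance)
        res = expected_response(sc, 3)
        rows.append({"w_ebv": w[0], "w_idl": w[1], "egr": res.egr,
                     "relative_vs_index1": res.relative_vs_index1})
    return pd.DataFrame(rows)
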