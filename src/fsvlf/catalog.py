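"""Catalog of the published benchmark experiments and their printed values.

Each entry names the model and solver parameters of one published table and
stores the printed values so a rerun can be placed side by side with them.
The comparator results (polynomial least-squares method, PLSM, and the
ANN/GA/AST hybrids) are fixtures for display and difference curves only; they
are never recomputed here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from .basis import BasisParams
from .diagnostics import max_residual, residual, convergence_order
from .solver import ModelSpec, SolverConfig, solve_qlm, evaluate

__all__ = [
    "PLSM_INTEGER",
    "PLSM_FRACTIONAL",
    "CatalogEntry",
    "CATALOG",
    "reproduce",
]

# Printed six-degree PLSM comparator polynomials: (exponents, coefficients).
PLSM_INTEGER = (
    [0, 2, 3, 4, 5, 6],
    [1.16081982, -0.05220539, 0.00000296, -0.00082464, 0.00000795, -0.00002000],
)
PLSM_FRACTIONAL = (
    [0, 2, 3, 4, 5, 6],
    [1.18592781, -0.12362096, 0.14497311, -0.16311024, 0.09852304, -0.02436348],
)

_R_GRID = [round(0.1 * i, 1) for i in range(11)]

# Printed solution/REF columns, keyed "h" / "ref" per (K, alpha) run.
_TABLE1 = {
    "r": _R_GRID,
    "h_K6": [1.16081984, 1.16029771, 1.15873032, 1.15611475, 1.15244604,
             1.14771725, 1.14191934, 1.13504119, 1.12706948, 1.11798864, 1.10778071],
    "ref_K6": [0.0, 8.4065e-7, 6.1609e-7, 2.2439e-7, 2.7801e-9, 3.4620e-8,
               8.4479e-10, 1.4206e-8, 4.4394e-9, 3.4191e-9, 6.4787e-9],
    "h_K10": [1.160819819590251, 1.160297689006561, 1.158730315153458,
              1.156114745851976, 1.152446041158113, 1.147717243637097,
              1.141919336227521, 1.135041187162281, 1.127069481241230,
              1.117988636563056, 1.107780705616379],
    "ref_K10": [0.0, 2.0152e-11, 2.6535e-13, 1.3948e-13, 2.2824e-13, 1.8269e-13,
                9.1822e-14, 1.9870e-14, 8.9165e-15, 7.0406e-15, 4.3711e-14],
    "plsm": [1.16081983, 1.16029769, 1.15873032, 1.15611475, 1.15244604,
             1.14771725, 1.14191934, 1.13504119, 1.12706949, 1.11798864, 1.10778071],
    "plsm_err": [0.0, 6.725e-8, 1.978e-8, 4.388e-8, 5.158e-9, 2.308e-8,
                 2.141e-9, 4.642e-8, 2.416e-8, 8.311e-8, 4.629e-9],
}

_TABLE2 = {
    "r": _R_GRID,
    "h_K8": [1.160819819659, 1.160297689045, 1.158730315169, 1.156114745862,
             1.152446041165, 1.147717243642, 1.141919336231, 1.135041187165,
             1.127069481243, 1.117988636564, 1.107780705617],
    "ref_K8": [0.0, 5.3263e-9, 1.4361e-9, 1.7157e-10, 5.7457e-11, 7.6349e-11,
               2.1342e-11, 1.9892e-11, 2.6313e-11, 2.0657e-11, 1.6943e-11],
}

_TABLE3 = {
    "K": [2, 4, 8, 16],
    "e_inf_m1": [6.0552e-3, 8.8287e-5, 5.8803e-9, 1.9231e-15],
    "ord_m1": [None, 6.0998, 13.874, 21.544],
    "cpu_m1": [0.37765, 0.45875, 0.63598, 1.06565],
    "e_inf_m05": [8.5582e-3, 1.0514e-4, 4.9241e-9, 3.2476e-15],
    "ord_m05": [None, 6.3469, 14.382, 20.532],
    "e_inf_m2": [1.7392e-3, 1.9290e-5, 7.3248e-10, 7.3347e-16],
    "ord_m2": [None, 6.4945, 14.685, 19.930],
}

_TABLE4 = {
    "K": [2, 4, 8, 16],
    "e_inf_lam5": [7.8704e-2, 4.0836e-3, 3.8235e-6, 3.9429e-13],
    "ord_lam5": [None, 4.2685, 10.061, 23.209],
    "e_inf_Bi5": [7.1703e-3, 1.1312e-4, 8.9189e-9, 2.0829e-15],
    "ord_Bi5": [None, 5.9861, 13.631, 22.030],
    "e_inf_A025": [1.1076e-2, 2.8244e-4, 5.4736e-8, 1.9878e-16],
    "ord_A025": [None, 5.2933, 12.333, 28.037],
}

_TABLE5 = {
    "r": _R_GRID,
    "h_a1": [1.18587014, 1.18480830, 1.18196899, 1.17772081, 1.17228067,
             1.16576606, 1.15823600, 1.14972066, 1.14023972, 1.12980937, 1.11843798],
    "ref_a1": [0.0, 3.6771e-3, 1.9265e-3, 5.5686e-4, 5.7501e-6, 6.1427e-5,
               1.3109e-6, 1.9547e-5, 5.4729e-6, 3.8068e-6, 6.5566e-6],
    "h_a17": [1.186078708050383, 1.184762989665008, 1.181798785635447,
              1.177537074846438, 1.172118584802979, 1.165624795848758,
              1.158108073063764, 1.149603273305191, 1.140133388637926,
              1.129712674036530, 1.118348529287161],
    "ref_a17": [0.0, 3.5729e-9, 4.9691e-9, 4.1642e-9, 2.2938e-9, 6.6587e-10,
                4.6515e-11, 5.0383e-11, 3.2844e-11, 1.7034e-11, 1.1143e-11],
    "plsm": [1.18592781, 1.18482122, 1.18191175, 1.17761666, 1.17216020,
             1.16564798, 1.15812382, 1.14960897, 1.14012396, 1.12969271, 1.11832927],
    "plsm_err": [0.0, 1.438e-3, 3.193e-4, 4.895e-4, 6.580e-6, 2.022e-4,
                 5.054e-5, 3.427e-4, 1.437e-4, 4.717e-4, 3.310e-5],
}

_TABLE6 = {
    "K": [1, 2, 4, 8],
    "e_inf_g15": [3.6788e-1, 7.8809e-3, 1.2137e-5, 1.2088e-11],
    "ord_g15": [None, 5.5447, 9.3428, 19.938],
    "e_inf_g17": [3.6788e-1, 7.3924e-3, 7.3823e-6, 2.4847e-12],
    "ord_g17": [None, 5.6371, 9.9677, 21.503],
    "e_inf_g19": [3.6788e-1, 6.7762e-3, 4.2754e-6, 4.6821e-13],
    "ord_g19": [None, 5.7626, 10.630, 23.122],
}

_TABLE7 = {
    "r": _R_GRID,
    "h_g18": [1.17800442, 1.17703384, 1.17462167, 1.17097668, 1.16618847,
              1.16030974, 1.15337399, 1.14540258, 1.13640822, 1.12639692, 1.11536923],
    "ref_g18": [0.0, 1.97e-9, 2.88e-9, 2.56e-9, 1.53e-9, 5.15e-10,
                6.89e-12, 3.77e-11, 1.77e-11, 8.52e-12, 5.92e-12],
    "h_g19": [1.16955055, 1.16883733, 1.16688696, 1.16378969, 1.15958555,
              1.15429709, 1.14793690, 1.14051068, 1.13201881, 1.12245723, 1.11181790],
    "ref_g19": [0.0, 1.073e-9, 1.635e-9, 1.531e-9, 9.767e-10, 3.718e-10,
                2.861e-11, 2.495e-11, 8.855e-12, 4.044e-12, 3.125e-12],
}

_TABLE8 = {
    "K": [1, 2, 4, 8],
    "e_inf_Bi05": [3.6788e-1, 5.9895e-3, 4.4530e-6, 7.8675e-13],
    "ord_Bi05": [None, 5.9407, 10.393, 22.432],
    "e_inf_Bi1": [3.6788e-1, 7.2480e-3, 6.4672e-6, 1.6509e-12],
    "ord_Bi1": [None, 5.6655, 10.130, 21.901],
    "e_inf_Bi2": [3.6788e-1, 8.0910e-3, 8.0143e-6, 2.5276e-12],
    "ord_Bi2": [None, 5.5068, 9.9795, 21.596],
    "e_inf_Bi5": [3.6788e-1, 8.6963e-3, 9.2211e-6, 3.3394e-12],
    "ord_Bi5": [None, 5.4027, 9.8812, 21.397],
}


@dataclass(frozen=True)
class CatalogEntry:
    """One published experiment: parameters, layout and printed values."""

    table_id: str
    source: str
    kind: str  # "pointwise" (r, h, REF columns) or "sweep" (K, E_inf, ord)
    runs: List[dict]  # per-column run specs
    printed: Dict[str, list]
    tolerances: Dict[str, float] = field(
        default_factory=lambda: {"h": 1e-7, "ref": 0.05, "e_inf": 0.05, "ord": 0.5}
    )


def _m(gamma=2.0, sigma=1.0, A=2.0, lam=1.0, m=1.0, Bi=1.0):
    return dict(gamma=gamma, sigma=sigma, A=A, lam=lam, m=m, Bi=Bi)


CATALOG: Dict[str, CatalogEntry] = {
    "table1": CatalogEntry(
        table_id="table1",
        source="pointwise solutions/REFs, integer orders (2, 1), lam=m=Bi=1, A=2, K=6 and 10",
        kind="pointwise",
        runs=[
            dict(label="K6", model=_m(), K=6, alpha=1.0),
            dict(label="K10", model=_m(), K=10, alpha=1.0),
        ],
        printed=_TABLE1,
    ),
    "table2": CatalogEntry(
        table_id="table2",
        source="pointwise solutions/REFs vs ANN hybrids, integer orders, K=8",
        kind="pointwise",
        runs=[dict(label="K8", model=_m(), K=8, alpha=1.0)],
        printed=_TABLE2,
    ),
    "table3": CatalogEntry(
        table_id="table3",
        source="E_inf/ord sweep, integer orders, lam=Bi=1, A=2, m in {1, 0.5, 2} (CPU column not compared)",
        kind="sweep",
        runs=[
            dict(label="m1", model=_m(m=1.0), K_values=[2, 4, 8, 16], alpha=1.0),
            dict(label="m05", model=_m(m=0.5), K_values=[2, 4, 8, 16], alpha=1.0),
            dict(label="m2", model=_m(m=2.0), K_values=[2, 4, 8, 16], alpha=1.0),
        ],
        printed=_TABLE3,
    ),
    "table4": CatalogEntry(
        table_id="table4",
        source="E_inf/ord sweep, integer orders, worst cases lam=5, Bi=5, A=0.25",
        kind="sweep",
        runs=[
            dict(label="lam5", model=_m(lam=5.0), K_values=[2, 4, 8, 16], alpha=1.0),
            dict(label="Bi5", model=_m(Bi=5.0), K_values=[2, 4, 8, 16], alpha=1.0),
            dict(label="A025", model=_m(A=0.25), K_values=[2, 4, 8, 16], alpha=1.0),
        ],
        printed=_TABLE4,
    ),
    "table5": CatalogEntry(
        table_id="table5",
        source="pointwise solutions/REFs, fractional orders (1.7, 0.7), K=6, alpha in {1, 1.7}",
        kind="pointwise",
        runs=[
            dict(label="a1", model=_m(gamma=1.7, sigma=0.7), K=6, alpha=1.0),
            dict(label="a17", model=_m(gamma=1.7, sigma=0.7), K=6, alpha=1.7),
        ],
        printed=_TABLE5,
    ),
    "table6": CatalogEntry(
        table_id="table6",
        source="E_inf/ord sweep, alpha=gamma, (gamma, sigma) in {(1.5,0.5), (1.7,0.7), (1.9,0.9)}",
        kind="sweep",
        runs=[
            dict(label="g15", model=_m(gamma=1.5, sigma=0.5), K_values=[1, 2, 4, 8], alpha=1.5),
            dict(label="g17", model=_m(gamma=1.7, sigma=0.7), K_values=[1, 2, 4, 8], alpha=1.7),
            dict(label="g19", model=_m(gamma=1.9, sigma=0.9), K_values=[1, 2, 4, 8], alpha=1.9),
        ],
        printed=_TABLE6,
    ),
    "table7": CatalogEntry(
        table_id="table7",
        source="pointwise solutions/REFs, (gamma, sigma) = (1.8, 0.8) and (1.9, 0.9), K=6, alpha=gamma",
        kind="pointwise",
        runs=[
            dict(label="g18", model=_m(gamma=1.8, sigma=0.8), K=6, alpha=1.8),
            dict(label="g19", model=_m(gamma=1.9, sigma=0.9), K=6, alpha=1.9),
        ],
        printed=_TABLE7,
    ),
    "table8": CatalogEntry(
        table_id="table8",
        source="E_inf/ord sweep, (gamma, sigma) = (1.75, 0.75), alpha=gamma, Bi in {0.5, 1, 2, 5}",
        kind="sweep",
        runs=[
            dict(label="Bi05", model=_m(gamma=1.75, sigma=0.75, Bi=0.5), K_values=[1, 2, 4, 8], alpha=1.75),
            dict(label="Bi1", model=_m(gamma=1.75, sigma=0.75, Bi=1.0), K_values=[1, 2, 4, 8], alpha=1.75),
            dict(label="Bi2", model=_m(gamma=1.75, sigma=0.75, Bi=2.0), K_values=[1, 2, 4, 8], alpha=1.75),
            dict(label="Bi5", model=_m(gamma=1.75, sigma=0.75, Bi=5.0), K_values=[1, 2, 4, 8], alpha=1.75),
        ],
        printed=_TABLE8,
    ),
}


def _rel_diff(computed, printed):
    if printed in (None, 0.0) or printed != printed:
        return np.nan
    return abs(computed - printed) / abs(printed)


def reproduce(table_id: str, n_grid: int = 2001) -> pd.DataFrame:
    """Recompute every recomputable cell of a published table.

    Returns a DataFrame holding, per run column, the recomputed values, the
    printed values, and their relative differences.  Comparator columns
    (PLSM, ANN) are carried through unchanged when present.
    """
    if table_id not in CATALOG:
        raise KeyError(f"unknown table id {table_id!r}; known: {sorted(CATALOG)}")
    entry = CATALOG[table_id]
    if entry.kind == "pointwise":
        return _reproduce_pointwise(entry, n_grid)
    return _reproduce_sweep(entry, n_grid)


def _reproduce_pointwise(entry: CatalogEntry, n_grid: int) -> pd.DataFrame:
    r_grid = np.array(entry.printed["r"], dtype=float)
    data = {"r": r_grid}
    for run in entry.runs:
        model = ModelSpec(**run["model"])
        cfg = SolverConfig(basis=BasisParams(K=run["K"], alpha=run["alpha"]))
        sol = solve_qlm(model, cfg)
        h = evaluate(sol, r_grid)
        refs = np.array([residual(sol, model, float(r)) for r in r_grid])
        lab = run["label"]
        data[f"h_{lab}"] = h
        data[f"ref_{lab}"] = refs
        printed_h = entry.printed.get(f"h_{lab}")
        printed_ref = entry.printed.get(f"ref_{lab}")
        if printed_h is not None:
            data[f"h_{lab}_printed"] = printed_h
            data[f"h_{lab}_reldiff"] = [_rel_diff(c, p) for c, p in zip(h, printed_h)]
        if printed_ref is not None:
            data[f"ref_{lab}_printed"] = printed_ref
            data[f"ref_{lab}_reldiff"] = [_rel_diff(c, p) for c, p in zip(refs, printed_ref)]
    for key in ("plsm", "plsm_err"):
        if key in entry.printed:
            data[key] = entry.printed[key]
    return pd.DataFrame(data)


def _reproduce_sweep(entry: CatalogEntry, n_grid: int) -> pd.DataFrame:
    K_values = entry.printed["K"]
    data = {"K": K_values}
    for run in entry.runs:
        model = ModelSpec(**run["model"])
        lab = run["label"]
        e_vals, ords = [], [None]
        for K in run["K_values"]:
            cfg = SolverConfig(basis=BasisParams(K=K, alpha=run["alpha"]))
            sol = solve_qlm(model, cfg)
            e_vals.append(max_residual(sol, model, n_grid=n_grid).e_inf)
        for prev, cur in zip(e_vals, e_vals[1:]):
            ords.append(convergence_order(prev, cur) if prev > 0 and cur > 0 else None)
        data[f"e_inf_{lab}"] = e_vals
        data[f"ord_{lab}"] = ords
        printed_e = entry.printed.get(f"e_inf_{lab}")
        if printed_e is not None:
            data[f"e_inf_{lab}_printed"] = printed_e
            data[f"e_inf_{lab}_reldiff"] = [_rel_diff(c, p) for c, p in zip(e_vals, printed_e)]
        printed_o = entry.printed.get(f"ord_{lab}")
        if printed_o is not None:
            data[f"ord_{lab}_printed"] = printed_o
    for key in ("cpu_m1",):
        if key in entry.printed:
            data[f"{key}_not_compared"] = entry.printed[key]
    return pd.DataFrame(data)
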