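"""Independent oracles used by the tests.

The vertex-enumeration oracle solves max c'x s.t. Ax <= b, x >= 0 by
brute force over all basic solutions; it shares no code with the LP
backend under test and is only usable for a handful of variables.
"""

from __future__ import annotations

import itertools

import numpy as np

from casemix.model import (Activity, DemandBounds, Location, Mobility,
                           NetworkModel, Profitability, Resource,
                           ResourceCategory, Service, UsageMatrix)


def vertex_enumeration_optimum(c, A, b, tol=1e-7):
    """Optimum of max c'x s.t. Ax <= b, x >= 0 by enumerating vertices.

    Returns None when no feasible vertex exists (with b >= 0 the origin is
    always feasible, so None signals a caller bug).
    """
    c = np.asarray(c, dtype=float)
    A = np.asarray(A, dtype=float)
    b = np.asarray(b, dtype=float)
    m, n = A.shape
    G = np.vstack([A, -np.eye(n)])
    h = np.concatenate([b, np.zeros(n)])
    best = None
    for idx in itertools.combinations(range(m + n), n):
        M = G[list(idx)]
        if abs(np.linalg.det(M)) < 1e-10:
            continue
        v = np.linalg.solve(M, h[list(idx)])
        if np.all(G @ v <= h + tol * np.maximum(1.0, np.abs(h))):
            val = float(c @ v)
            if best is None or val > best:
                best = val
    return best


def random_small_model(rng: np.random.Generator) -> NetworkModel:
    """A random single-location instance with <= 4 services and <= 3 resources,
    margins of either sign and finite demand ceilings (so the polytope is
    bounded and the origin is feasible)."""
    n_p = int(rng.integers(2, 5))
    n_r = int(rng.integers(1, 4))
    loc = Location("main")
    services = [Service(f"P{i}", specialty="general") for i in range(n_p)]
    act = Activity("surgery", 2)
    resources = [
        Resource(f"R{j}", ResourceCategory.B, Mobility.fixed,
                 capacity=float(rng.uniform(50, 400)), location="main")
        for j in range(n_r)
    ]
    usage = UsageMatrix()
    for i in range(n_p):
        for j in range(n_r):
            if rng.uniform() < 0.8:
                usage.set(f"P{i}", "surgery", f"R{j}", "main", float(rng.uniform(0.5, 5.0)))
    pi = {(f"P{i}", "main"): float(rng.uniform(-2.0, 10.0)) for i in range(n_p)}
    demand = DemandBounds(
        location_upper={(f"P{i}", "main"): float(rng.uniform(5, 60)) for i in range(n_p)})
    return NetworkModel(locations=[loc], services=services, activities=[act],
                        resources=resources, usage=usage,
                        profitability=Profitability(pi=pi), demand=demand)
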