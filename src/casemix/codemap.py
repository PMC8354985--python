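"""Empirical frequency mappings between external coding systems and
internal service codes.

Claims and financial data arrive indexed by DRG or ICD-9 codes, while the
network model is indexed by internal surgical service codes, and the two
systems are many-to-many. The mapping is fitted from labeled historical
records: w[d -> p] is the empirical conditional frequency with which
external code d co-occurred with internal service p. Leakage claims are
then converted to unmet demand per service, and encounter payments are
apportioned to services, by pushing counts and dollars through these
weights. Mass is conserved up to explicitly logged exclusions; unseen
codes are never imputed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import pandas as pd

__all__ = [
    "CodeMap",
    "fit_code_map",
    "map_leakage_to_unmet_demand",
    "map_financials_to_service_revenue",
]


@dataclass
class CodeMap:
    """Conditional weights w[external code][service], with support counts."""

    weights: dict[str, dict[str, float]] = field(default_factory=dict)
    support: dict[str, int] = field(default_factory=dict)
    #: codes seen with support below the fitting threshold
    low_support: dict[str, int] = field(default_factory=dict)
    #: codes encountered during application but absent from the map
    unmapped_log: dict[str, float] = field(default_factory=dict)

    def services_for(self, code: str) -> dict[str, float]:
        return self.weights.get(code, {})

    def __contains__(self, code: str) -> bool:
        return code in self.weights


def fit_code_map(records: pd.DataFrame, min_support: int = 1) -> CodeMap:
    """Fit w[d -> p] = count(d, p) / count(d) from labeled records.

    ``records`` has columns external_code and service. Codes with fewer
    than ``min_support`` observations are fitted but flagged in
    ``low_support``.
    """
    required = {"external_code", "service"}
    if not required.issubset(records.columns):
        raise ValueError(f"records need columns {sorted(required)}")
    if len(records) == 0:
        raise ValueError("fit_code_map requires at least one record")
    cm = CodeMap()
    counts = records.groupby(["external_code", "service"]).size()
    totals = records.groupby("external_code").size()
    for code, n in totals.items():
        cm.support[code] = int(n)
        if n < min_support:
            cm.low_support[code] = int(n)
        w = (counts[code] / n).to_dict()
        cm.weights[code] = {str(p): float(v) for p, v in sorted(w.items())}
    return cm


def map_leakage_to_unmet_demand(leakage: pd.DataFrame, cmap: CodeMap
                                ) -> tuple[dict[tuple[str, str], float], dict[str, float]]:
    """Convert leaked claim counts into unmet demand per (service, location).

    ``leakage`` has columns external_code, location, count; each claim has
    already been assigned to its nearest in-network location. Counts of a
    code split across services by the fitted weights, so total mapped
    counts are conserved. Codes absent from the map are excluded and
    returned (and recorded on the map) as an exclusion log.
    """
    required = {"external_code", "location", "count"}
    if not required.issubset(leakage.columns):
        raise ValueError(f"leakage needs columns {sorted(required)}")
    unmet: dict[tuple[str, str], float] = {}
    excluded: dict[str, float] = {}
    for _, row in leakage.iterrows():
        code, loc, n = str(row["external_code"]), str(row["location"]), float(row["count"])
        if code not in cmap:
            excluded[code] = excluded.get(code, 0.0) + n
            continue
        for p, w in cmap.services_for(code).items():
            if w == 0.0:
                continue
            unmet[(p, loc)] = unmet.get((p, loc), 0.0) + n * w
    for code, n in excluded.items():
        cmap.unmapped_log[code] = cmap.unmapped_log.get(code, 0.0) + n
    return unmet, excluded


def map_financials_to_service_revenue(
    encounters: pd.DataFrame,
    cmap: CodeMap,
    mode: Literal["apportion", "primary"] = "apportion",
) -> tuple[pd.DataFrame, list[str]]:
    """Average revenue per (service, location) from encounter-level payments.

    ``encounters`` has columns encounter_id, codes (";"-separated external
    codes), payment, location. Each encounter's payment is split across
    services: in ``apportion`` mode the weights of all its mappable codes
    are renormalized over the encounter and dollars plus case-equivalents
    flow proportionally; ``primary`` mode uses only the first mappable
    code. Average revenue = apportioned dollars / apportioned
    case-equivalents. Encounters with no mappable code are excluded and
    their ids returned.
    """
    required = {"encounter_id", "codes", "payment", "location"}
    if not required.issubset(encounters.columns):
        raise ValueError(f"encounters need columns {sorted(required)}")
    dollars: dict[tuple[str, str], float] = {}
    cases: dict[tuple[str, str], float] = {}
    excluded: list[str] = []
    for _, row in encounters.iterrows():
        payment = float(row["payment"])
        if payment < 0:
            raise ValueError(f"negative payment on encounter {row['encounter_id']!r}")
        codes = [c for c in str(row["codes"]).split(";") if c]
        mappable = [c for c in codes if c in cmap]
        if not mappable:
            excluded.append(str(row["encounter_id"]))
            continue
        if mode == "primary":
            mappable = mappable[:1]
        # renormalize weights over the codes present in this encounter
        combined: dict[str, float] = {}
        for c in mappable:
            for p, w in cmap.services_for(c).items():
                combined[p] = combined.get(p, 0.0) + w
        total_w = sum(combined.values())
        loc = str(row["location"])
        for p, w in combined.items():
            share = w / total_w
            dollars[(p, loc)] = dollars.get((p, loc), 0.0) + payment * share
            cases[(p, loc)] = cases.get((p, loc), 0.0) + share
    rows = [
        {"service": p, "location": l, "revenue_total": dollars[(p, l)],
         "case_equivalents": cases[(p, l)],
         "average_revenue": dollars[(p, l)] / cases[(p, l)]}
        for (p, l) in sorted(dollars)
    ]
    return pd.DataFrame(rows, columns=["service", "location", "revenue_total",
                                       "case_equivalents", "average_revenue"]), excluded
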