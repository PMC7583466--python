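"""Street-tree inventory metrics: density, dominance, and importance values.

A street-tree inventory is a table with one row per measured tree (route,
species label, origin, DBH in cm, position along the walking route).  The
availability of each tree species as a foraging substrate is summarized by
its *importance value* (IV): the mean of its relative density (share of
stems) and relative dominance (share of basal area), expressed in percent.
The frequency term of the classical IV is omitted by construction, which is
appropriate for full-census street-tree transects rather than plotless
forest sampling.
"""

from __future__ import annotations

from collections.abc import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "LA_INCOME_THRESHOLDS",
    "basal_area_from_dbh",
    "standardize_per_km",
    "classify_income",
    "importance_values",
]

#: Income-tercile cut points (USD, 2010 census) used for the Los Angeles
#: gradient: low <= 53,219 < medium < 70,720 <= high.
LA_INCOME_THRESHOLDS = (53_219.0, 70_720.0)

#: Required columns of an inventory table.
INVENTORY_COLUMNS = ["route_id", "species", "origin", "dbh_cm", "position_m"]

#: Required columns of a route-metadata table.
ROUTE_COLUMNS = ["route_id", "length_km", "income_class"]


def basal_area_from_dbh(dbh_cm):
    """Convert diameter at breast height (cm) to basal area (m^2).

    The trunk cross-section is treated as a circle of diameter ``dbh_cm``:
    ``area = pi * (dbh_cm / 200)**2``, the standard forestry definition.

    Parameters
    ----------
    dbh_cm : float or array-like
        Diameter(s) at breast height in centimetres; must be > 0.

    Returns
    -------
    float or ndarray
        Basal area in square metres.
    """
    arr = np.asarray(dbh_cm, dtype=float)
    if arr.size == 0:
        return arr * 0.0
    if not np.all(np.isfinite(arr)) or np.any(arr <= 0):
        raise ValueError("DBH values must be finite and > 0 cm")
    area = np.pi * (arr / 200.0) ** 2
    return float(area) if np.isscalar(dbh_cm) or arr.ndim == 0 else area


def standardize_per_km(total, length_km):
    """Express a route total as a per-kilometre rate.

    Parameters
    ----------
    total : float or array-like
        Summed quantity over the route (tree count, basal area, ...).
    length_km : float or array-like
        Route length in km; must be > 0.
    """
    length = np.asarray(length_km, dtype=float)
    if not np.all(np.isfinite(length)) or np.any(length <= 0):
        raise ValueError("route length must be finite and > 0 km")
    out = np.asarray(total, dtype=float) / length
    if np.isscalar(total) and np.isscalar(length_km):
        return float(out)
    return out


def classify_income(median_income, thresholds=LA_INCOME_THRESHOLDS):
    """Assign an income class from a median household income.

    ``low`` if income <= ``thresholds[0]``, ``high`` if income >=
    ``thresholds[1]``, ``medium`` otherwise.
    """
    low_max, high_min = float(thresholds[0]), float(thresholds[1])
    if not low_max < high_min:
        raise ValueError("thresholds must satisfy low_max < high_min")
    income = float(median_income)
    if income < 0:
        raise ValueError("median income must be non-negative")
    if income <= low_max:
        return "low"
    if income >= high_min:
        return "high"
    return "medium"


def _validate_inventory(trees: pd.DataFrame, routes: pd.DataFrame) -> None:
    if len(trees) == 0:
        raise ValueError("empty inventory: cannot compute importance values")
    missing = set(["route_id", "species", "dbh_cm"]) - set(trees.columns)
    if missing:
        raise ValueError(f"inventory is missing columns: {sorted(missing)}")
    unknown = set(trees["route_id"]) - set(routes["route_id"])
    if unknown:
        raise ValueError(f"inventory references unknown route_id(s): {sorted(map(str, unknown))}")


def importance_values(
    trees: pd.DataFrame,
    routes: pd.DataFrame,
    grouping: Mapping[str, str] | None = None,
    per_route: bool = False,
) -> pd.DataFrame:
    """Compute per-species density, dominance, and importance values.

    Relative density is each species' percentage of the total stem count and
    relative dominance its percentage of the total basal area; the importance
    value is their mean, so the IV column sums to 100 over the table.

    Parameters
    ----------
    trees : DataFrame
        Inventory with columns ``route_id``, ``species``, ``dbh_cm``.
    routes : DataFrame
        Route metadata with ``route_id`` and ``length_km``; every tree's
        route must be present.
    grouping : mapping, optional
        Map from species label to a coarser group (e.g. native/nonnative).
        Unmapped species keep their own label.  Counts and basal areas are
        pooled before relative values are computed, so a group's IV equals
        the IV obtained from its members' summed raw quantities.
    per_route : bool, default False
        If True, compute relative values within each route (MultiIndex
        ``(route_id, species)``) instead of over the pooled inventory.

    Returns
    -------
    DataFrame
        Indexed by species (or group), with columns ``count``,
        ``density_per_km``, ``basal_area_m2_per_km``, ``rel_density``,
        ``rel_dominance``, ``importance_value``.
    """
    _validate_inventory(trees, routes)
    work = trees[["route_id", "species", "dbh_cm"]].copy()
    work["basal_area_m2"] = basal_area_from_dbh(work["dbh_cm"].to_numpy())
    if grouping is not None:
        work["species"] = work["species"].map(lambda s: grouping.get(s, s))

    if per_route:
        lengths = routes.set_index("route_id")["length_km"]
        parts = []
        for route_id, sub in work.groupby("route_id", sort=True):
            tab = _relative_table(sub, float(lengths.loc[route_id]))
            tab.index = pd.MultiIndex.from_product(
                [[route_id], tab.index], names=["route_id", "species"]
            )
            parts.append(tab)
        return pd.concat(parts)

    total_length = float(
        routes.loc[routes["route_id"].isin(work["route_id"].unique()), "length_km"].sum()
    )
    return _relative_table(work, total_length)


def _relative_table(work: pd.DataFrame, length_km: float) -> pd.DataFrame:
    agg = work.groupby("species", sort=True).agg(
        count=("species", "size"), basal_area_m2=("basal_area_m2", "sum")
    )
    total_count = int(agg["count"].sum())
    total_ba = float(agg["basal_area_m2"].sum())
    out = pd.DataFrame(index=agg.index)
    out["count"] = agg["count"]
    out["density_per_km"] = standardize_per_km(agg["count"].to_numpy(float), length_km)
    out["basal_area_m2_per_km"] = standardize_per_km(
        agg["basal_area_m2"].to_numpy(float), length_km
    )
    out["rel_density"] = 100.0 * agg["count"] / total_count
    out["rel_dominance"] = 100.0 * agg["basal_area_m2"] / total_ba
    out["importance_value"] = (out["rel_density"] + out["rel_dominance"]) / 2.0
    out.index.name = "species"
    return out
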