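"""Glue between modules: route summaries and the end-to-end analysis."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from . import observations as obs_mod
from . import preference as pref_mod
from .inventory import basal_area_from_dbh, importance_values

__all__ = ["species_counts_matrix", "route_summary", "run_preference_pipeline"]


def species_counts_matrix(
    frame: pd.DataFrame, routes: pd.DataFrame, column: str = "species"
) -> pd.DataFrame:
    """Route x label count matrix (e.g. trees per species, or bird species).

    Rows cover every route in ``routes`` (all-zero rows for routes without
    records), which keeps group sizes intact for ANOSIM.
    """
    mat = (
        frame.groupby(["route_id", column]).size().unstack(fill_value=0)
        if len(frame)
        else pd.DataFrame()
    )
    mat = mat.reindex(routes["route_id"], fill_value=0).fillna(0).astype(int)
    mat.index.name = "route_id"
    return mat


def route_summary(
    trees: pd.DataFrame, routes: pd.DataFrame, observations: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Per-route predictors (and responses) for the GLM model sets.

    Returns one row per route: income class, street-tree species richness
    per km, Shannon diversity (not length-standardized), total / native /
    nonnative tree densities and basal areas per km, and — when reduced
    foraging observations are supplied — migratory, year-round, and total
    feeding-bird densities per km.
    """
    lengths = routes.set_index("route_id")["length_km"]
    out = routes.set_index("route_id")[["income_class", "length_km"]].copy()

    work = trees.copy()
    work["ba"] = basal_area_from_dbh(work["dbh_cm"].to_numpy(float))
    is_native = work["origin"] == "native"

    counts = work.groupby("route_id").size().reindex(lengths.index, fill_value=0)
    out["tree_density"] = counts / lengths
    for label, mask in (("native", is_native), ("nonnative", ~is_native)):
        c = work[mask].groupby("route_id").size().reindex(lengths.index, fill_value=0)
        out[f"{label}_tree_density"] = c / lengths
        b = work[mask].groupby("route_id")["ba"].sum().reindex(lengths.index, fill_value=0.0)
        out[f"{label}_basal_area"] = b / lengths
    out["basal_area"] = (
        work.groupby("route_id")["ba"].sum().reindex(lengths.index, fill_value=0.0) / lengths
    )
    rich = work.groupby("route_id")["species"].nunique().reindex(lengths.index, fill_value=0)
    out["richness_per_km"] = rich / lengths
    shannon = (
        work.groupby("route_id")["species"]
        .apply(lambda s: float(stats.entropy(s.value_counts().to_numpy(float))))
        .reindex(lengths.index, fill_value=0.0)
    )
    out["shannon"] = shannon

    if observations is not None:
        out["migratory_density"] = obs_mod.feeding_density(observations, routes, "migratory")
        out["year_round_density"] = obs_mod.feeding_density(observations, routes, "year_round")
        out["total_density"] = obs_mod.feeding_density(observations, routes)
    return out.reset_index()


def run_preference_pipeline(
    trees: pd.DataFrame,
    routes: pd.DataFrame,
    raw_detections: pd.DataFrame,
    min_iv: float = pref_mod.MIN_IV_PCT,
    min_n: int = pref_mod.MIN_N_OBS,
    grouping: dict | None = None,
) -> dict:
    """Reduce raw detections and run the full use-vs-availability analysis.

    Returns a dict with the reduced observations, the importance table
    (optionally group-level via ``grouping``), the preference table for the
    total / migratory / year-round pools and each bird species, and the
    chi-square results per grouping (``None`` where a grouping fell below
    ``min_n``).
    """
    reduced = obs_mod.reduce_observations(raw_detections)
    iv = importance_values(trees, routes, grouping=grouping)
    groupings = {
        "total": reduced,
        "migratory": reduced[reduced["group"] == "migratory"],
        "year_round": reduced[reduced["group"] == "year_round"],
    }
    for bird, sub in reduced.groupby("bird_species"):
        groupings[str(bird)] = sub
    groupings = {k: v for k, v in groupings.items() if len(v) > 0}
    table = pref_mod.preference_table(reduced, iv, groupings=groupings)
    chisq = {}
    for name, sub in groupings.items():
        counts = sub.groupby("tree_species").size()
        chisq[name] = pref_mod.use_availability_chisq(
            counts, iv, min_iv=min_iv, min_n=min_n
        )
    return {
        "reduced": reduced,
        "importance": iv,
        "preference": table,
        "chisq": chisq,
    }
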