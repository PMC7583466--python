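"""Use-vs-availability analysis of bird foraging on street trees.

For a pool of feeding observations (a bird grouping: one species, the
migratory pool, the year-round pool, or all birds), each tree species gets:

* ``use_pct`` — its share of the grouping's feeding observations (%),
* ``iv_pct`` — its importance value, the availability measure (%),
* ``preference_index`` — PI = use_pct - iv_pct (percentage points;
  positive = preference, negative = aversion),
* ``proportional_use`` — 100 * use_pct / iv_pct (% of availability).

PI is computed against the raw importance values of the full inventory, so
a species never fed on has PI = -IV exactly and PI sums to zero over the
complete species set.  The chi-square goodness-of-fit test compares
observed feeding counts with counts expected from availability over the
common species (IV above a cutoff), with expectations renormalized so they
sum to the observed total.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "feeding_proportions",
    "preference_index",
    "proportional_use",
    "preference_table",
    "use_availability_chisq",
    "ChiSquareResult",
]

log = logging.getLogger(__name__)

#: Importance-value cutoff (%) for inclusion in the chi-square test
#: (strictly greater than).
MIN_IV_PCT = 1.5

#: Minimum number of feeding observations for a grouping to be tested.
MIN_N_OBS = 30


def feeding_proportions(observations: pd.DataFrame, species=None) -> pd.Series:
    """Percentage of a grouping's feeding observations per tree species.

    Parameters
    ----------
    observations : DataFrame
        Reduced foraging observations (one row per unit) with a
        ``tree_species`` column; must be non-empty.
    species : sequence, optional
        Species universe; species without observations get 0.  Defaults to
        the species present in the observations.
    """
    if len(observations) == 0:
        raise ValueError("empty grouping: no feeding observations")
    counts = observations.groupby("tree_species").size()
    if species is not None:
        counts = counts.reindex(list(species), fill_value=0)
        extra = set(observations["tree_species"]) - set(species)
        if extra:
            raise ValueError(f"observations on species outside the universe: {sorted(extra)}")
    use = 100.0 * counts / counts.sum()
    use.name = "use_pct"
    return use


def _check_iv(iv_pct) -> np.ndarray:
    iv = np.asarray(iv_pct, dtype=float)
    if np.any(iv <= 0) or np.any(iv > 100):
        raise ValueError("importance values must lie in (0, 100]")
    return iv


def preference_index(use_pct, iv_pct):
    """Preference (positive) / aversion (negative) index in percentage points.

    ``PI = use_pct - iv_pct``.
    """
    iv = _check_iv(iv_pct)
    use = np.asarray(use_pct, dtype=float)
    if np.any(use < 0) or np.any(use > 100):
        raise ValueError("use percentages must lie in [0, 100]")
    out = use - iv
    return float(out) if out.ndim == 0 else out


def proportional_use(use_pct, iv_pct):
    """Use expressed as a percentage of availability: 100 * use_pct / iv_pct.

    Equivalently ``100 * (iv_pct + PI) / iv_pct``; 100% means a species is
    used exactly in proportion to its availability.
    """
    iv = _check_iv(iv_pct)
    out = 100.0 * np.asarray(use_pct, dtype=float) / iv
    return float(out) if out.ndim == 0 else out


def preference_table(
    observations: pd.DataFrame,
    importance: pd.DataFrame,
    groupings: dict[str, pd.DataFrame] | None = None,
) -> pd.DataFrame:
    """Per tree-species preference table for one or more bird groupings.

    Parameters
    ----------
    observations : DataFrame
        Reduced foraging observations with ``tree_species``, ``group`` and
        ``bird_species`` columns.
    importance : DataFrame
        Species importance table (index = tree species, column
        ``importance_value``); defines the species universe, so every
        observed tree species must appear in it.
    groupings : dict, optional
        Map from grouping name to the observation subset it covers.  The
        default provides ``total``, ``migratory``, and ``year_round``.

    Returns
    -------
    DataFrame
        Long form, one row per grouping x tree species, with columns
        ``grouping``, ``n_obs``, ``use_pct``, ``iv_pct``,
        ``preference_index``, ``proportional_use``.
    """
    if groupings is None:
        groupings = {
            "total": observations,
            "migratory": observations[observations["group"] == "migratory"],
            "year_round": observations[observations["group"] == "year_round"],
        }
    universe = list(importance.index)
    iv = importance["importance_value"]
    parts = []
    for name, obs in groupings.items():
        if len(obs) == 0:
            log.info("grouping %r has no observations; skipped", name)
            continue
        counts = obs.groupby("tree_species").size().reindex(universe, fill_value=0)
        use = feeding_proportions(obs, species=universe)
        part = pd.DataFrame(
            {
                "grouping": name,
                "n_obs": counts,
                "use_pct": use,
                "iv_pct": iv,
                "preference_index": preference_index(use.to_numpy(), iv.to_numpy()),
                "proportional_use": proportional_use(use.to_numpy(), iv.to_numpy()),
            }
        )
        part.index.name = "tree_species"
        parts.append(part.reset_index())
    if not parts:
        raise ValueError("no grouping had any observations")
    return pd.concat(parts, ignore_index=True)


@dataclass
class ChiSquareResult:
    """Chi-square goodness-of-fit of observed feeding vs availability."""

    statistic: float
    df: int
    p: float
    included_species: list
    observed: np.ndarray
    expected: np.ndarray
    n: int

    def to_dict(self) -> dict:
        return {
            "statistic": self.statistic,
            "df": self.df,
            "p": self.p,
            "n": self.n,
            "included_species": list(map(str, self.included_species)),
            "observed": [float(v) for v in self.observed],
            "expected": [float(v) for v in self.expected],
        }


def use_availability_chisq(
    observed_counts: pd.Series,
    importance: pd.DataFrame,
    min_iv: float = MIN_IV_PCT,
    min_n: int = MIN_N_OBS,
    renormalize: bool = True,
) -> ChiSquareResult | None:
    """Chi-square goodness-of-fit test of feeding use against availability.

    Species with importance value strictly greater than ``min_iv`` percent
    are included; observed counts are restricted to those species.  Under
    the availability-only null, expected counts are ``N * IV_i /
    sum(IV_included)`` (``renormalize=True``, so expected sums to observed)
    or ``N * IV_i / 100`` otherwise.  The statistic is the textbook
    ``sum((O - E)^2 / E)`` with ``k - 1`` degrees of freedom.

    A grouping with fewer than ``min_n`` total observations is not tested:
    the function logs the exclusion and returns ``None``.
    """
    iv = importance["importance_value"]
    included = iv[iv > min_iv].index
    if len(included) < 2:
        raise ValueError(f"fewer than two species exceed the IV cutoff of {min_iv}%")
    obs = observed_counts.reindex(included, fill_value=0).to_numpy(dtype=float)
    n = float(obs.sum())
    if n < min_n:
        log.info(
            "grouping excluded from chi-square: %d observations < min_n=%d",
            int(n), min_n,
        )
        return None
    iv_inc = iv.loc[included].to_numpy(dtype=float)
    if renormalize:
        expected = n * iv_inc / iv_inc.sum()
    else:
        expected = n * iv_inc / 100.0
    if np.any(expected <= 0):
        raise ValueError("zero expected count: cannot form the chi-square statistic")
    stat = float(((obs - expected) ** 2 / expected).sum())
    df = len(included) - 1
    p = float(stats.chi2.sf(stat, df))
    return ChiSquareResult(
        statistic=stat, df=df, p=p, included_species=list(included),
        observed=obs, expected=expected, n=int(n),
    )
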