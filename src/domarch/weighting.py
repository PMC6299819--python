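"""Proportional species weighting of domain-profile states.

Genome databases over-represent heavily sequenced species (hundreds of
*E. coli* strains vs. one strain for most species). To keep such species from
dominating taxon-level profile distributions, each strain contributes a
*relative count* of 1 / (number of strains of its species), so every species
carries total weight 1 regardless of how many strains were sequenced.
"""

from __future__ import annotations

from typing import Dict, Mapping, Sequence

import pandas as pd

from .profiles import STATES, StrainState

__all__ = ["relative_counts", "representative_leaf_states", "taxon_frequencies"]


def relative_counts(states: Sequence[StrainState]) -> pd.DataFrame:
    """Per-species strain counts and relative counts of each profile state.

    Returns a DataFrame with columns (species, state, strain_count,
    relative_count); within each species the relative counts sum to 1. Weights
    are exact fractions of the strain totals — rounding is left to
    presentation.
    """
    if not states:
        return pd.DataFrame(
            columns=["species", "state", "strain_count", "relative_count"]
        )
    df = pd.DataFrame(
        {"species": [s.species for s in states], "state": [s.state for s in states]}
    )
    counts = (
        df.groupby(["species", "state"], sort=True).size().rename("strain_count").reset_index()
    )
    totals = counts.groupby("species")["strain_count"].transform("sum")
    counts["relative_count"] = counts["strain_count"] / totals
    return counts


def representative_leaf_states(table: pd.DataFrame) -> Dict[str, str]:
    """Dominant state per species, for one-leaf-per-species phylogenies.

    Ties are broken by the fixed state order NC < C < DC < CL < DCL < OTHER.
    """
    order = {s: i for i, s in enumerate(STATES)}
    result: Dict[str, str] = {}
    for species, grp in table.groupby("species", sort=True):
        best = min(
            grp.itertuples(index=False),
            key=lambda r: (-r.relative_count, order[r.state]),
        )
        result[species] = best.state
    return result


def taxon_frequencies(
    table: pd.DataFrame, taxon_map: Mapping[str, str]
) -> pd.DataFrame:
    """Aggregate species relative counts into per-taxon state frequencies.

    frequency(taxon, state) = sum of relative counts of that state over the
    taxon's species, divided by the taxon's total relative count (= its number
    of species). Frequencies sum to 1 within each taxon. Unmapped species
    raise ``KeyError`` listing the offenders.
    """
    species = sorted(set(table["species"]))
    missing = [sp for sp in species if sp not in taxon_map]
    if missing:
        raise KeyError(f"species without taxon assignment: {missing}")
    df = table.copy()
    df["taxon"] = df["species"].map(taxon_map)
    sums = (
        df.groupby(["taxon", "state"], sort=True)["relative_count"]
        .sum()
        .rename("frequency")
        .reset_index()
    )
    totals = sums.groupby("taxon")["frequency"].transform("sum")
    sums["frequency"] = sums["frequency"] / totals
    return sums
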