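"""Species importance values and family/genus overall relative importance.

The importance value (IV) of a species averages three percentage shares:

* relative density   RD_i = 100 * n_i / N
* relative frequency RF_i = 100 * F_i / sum_j F_j, with F_i the fraction of
  quadrats occupied by species i
* relative dominance Rd_i = 100 * d_i / sum_j d_j, with d_i the basal area
  of species i per unit survey area

so IV_i = (RD_i + RF_i + Rd_i) / 3 and the IVs sum to 100 over species.

At the family or genus level the overall relative importance (ORI) of a
taxon is its relative abundance plus its relative frequency,
ORI = R.Ab + R.Fr, where frequencies are quadrat-occupancy shares summed
over the taxon's species.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .plot_data import AbundanceTable, StemRecord, basal_area, load_taxonomy

__all__ = [
    "species_iv",
    "taxon_ori",
    "overall_relative_importance",
    "iv_from_stems",
    "ori_from_stems",
]


def overall_relative_importance(r_ab: float, r_fr: float) -> float:
    """ORI combination rule for a taxon: relative abundance + relative frequency."""
    return r_ab + r_fr


def species_iv(
    quadrat_counts: AbundanceTable,
    basal_areas: pd.Series,
    quadrat_count: int | None = None,
    rf_denominator: str = "total_frequency",
) -> pd.DataFrame:
    """Importance values from quadrat-level counts and per-species basal areas.

    Parameters
    ----------
    quadrat_counts
        Species x quadrat abundance table.
    basal_areas
        Total basal area per species (any consistent unit; IV is invariant
        under rescaling).
    quadrat_count
        Total number of quadrats; defaults to the table's unit count.
    rf_denominator
        ``"total_frequency"`` (default) divides each species' frequency by
        the summed frequencies of all species, so relative frequencies sum
        to 100. ``"species_count"`` is a literal variant dividing by the
        number of species; it does not produce percentages that sum to 100
        and is provided only for comparison with legacy reports.

    Returns
    -------
    DataFrame indexed by species with columns D (per-quadrat density), RD,
    F, RF, d, Rd, IV, sorted by IV descending. Percentages are kept at full
    precision; round only when reporting.
    """
    counts = quadrat_counts.counts
    q = quadrat_count if quadrat_count is not None else len(counts.columns)
    if q <= 0:
        raise ValueError("quadrat count must be positive")

    n_i = counts.sum(axis=1).astype(float)
    N = n_i.sum()
    if N <= 0:
        raise ValueError("no individuals in abundance table")

    F = (counts > 0).sum(axis=1) / q
    if F.sum() <= 0:
        raise ValueError("all frequencies zero")

    d = basal_areas.reindex(n_i.index).astype(float)
    if d.isna().any():
        missing = list(d.index[d.isna()])
        raise ValueError(f"basal area missing for species: {missing}")
    if d.sum() <= 0:
        raise ValueError("total basal area must be positive")

    RD = 100.0 * n_i / N
    if rf_denominator == "total_frequency":
        RF = 100.0 * F / F.sum()
    elif rf_denominator == "species_count":
        RF = 100.0 * F / len(F)
    else:
        raise ValueError(f"unknown rf_denominator {rf_denominator!r}")
    Rd = 100.0 * d / d.sum()
    IV = (RD + RF + Rd) / 3.0

    out = pd.DataFrame({"D": n_i / q, "RD": RD, "F": F, "RF": RF, "d": d, "Rd": Rd, "IV": IV})
    return out.sort_values("IV", ascending=False)


def taxon_ori(
    quadrat_counts: AbundanceTable,
    taxonomy: pd.DataFrame | None = None,
    rank: str = "family",
) -> pd.DataFrame:
    """Overall relative importance of families or genera.

    R.Ab_t = 100 * (individuals in taxon t) / N.
    R.Fr_t = 100 * (summed quadrat frequencies of taxon t's species) /
    (summed frequencies of all species), i.e. taxon frequency shares on the
    same denominator as the species-level relative frequency.
    ORI_t = R.Ab_t + R.Fr_t; rows sorted by ORI descending.
    """
    if rank not in ("family", "genus"):
        raise ValueError("rank must be 'family' or 'genus'")
    if taxonomy is None:
        taxonomy = load_taxonomy()

    counts = quadrat_counts.counts
    taxa = pd.Series(
        [taxonomy.loc[sp, rank] if sp in taxonomy.index else "unknown" for sp in counts.index],
        index=counts.index,
    )
    n_i = counts.sum(axis=1).astype(float)
    F_i = (counts > 0).sum(axis=1).astype(float)  # occupied-quadrat counts
    N = n_i.sum()
    F_total = F_i.sum()

    r_ab = 100.0 * n_i.groupby(taxa).sum() / N
    r_fr = 100.0 * F_i.groupby(taxa).sum() / F_total
    out = pd.DataFrame({"R.Ab": r_ab, "R.Fr": r_fr})
    out["ORI"] = overall_relative_importance(out["R.Ab"], out["R.Fr"])
    out.index.name = rank
    return out.sort_values("ORI", ascending=False)


def iv_from_stems(stems: Sequence[StemRecord], rf_denominator: str = "total_frequency") -> pd.DataFrame:
    """Convenience wrapper: species IV table straight from stem records."""
    table = _plot_table(stems)
    ba = pd.Series(0.0, index=table.counts.index)
    for s in stems:
        ba[s.species] += basal_area(s.dbh)
    return species_iv(table, ba, rf_denominator=rf_denominator)


def ori_from_stems(
    stems: Sequence[StemRecord],
    rank: str = "family",
    taxonomy: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Convenience wrapper: family/genus ORI table straight from stem records."""
    return taxon_ori(_plot_table(stems), taxonomy=taxonomy, rank=rank)


def _plot_table(stems: Sequence[StemRecord]) -> AbundanceTable:
    from .plot_data import abundance_table

    return abundance_table(stems, group_by="plot")
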