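"""Segregation testing, recombinant-count linkage mapping, co-segregation.

The mapping design mirrors classic recessive-selection linkage analysis of
an epiallele: F2 plants showing the recessive (unmethylated-only) Chop-PCR
phenotype are selected, and for each marker the chromosomes carrying the
"wrong" (methylated-parent) allele are counted as recombinants.  The causal
locus is the marker with the fewest recombinants; the interval is bounded
by the nearest flanking markers with strictly more recombinants.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .synthgen import CrossPopulation

__all__ = [
    "SegregationResult",
    "MarkerLinkage",
    "LocusInterval",
    "segregation_test",
    "band_phenotypes",
    "count_recombinants",
    "linkage_table",
    "map_locus",
    "cosegregation_summary",
]


@dataclass
class SegregationResult:
    observed: tuple[int, ...]
    expected_ratio: tuple[float, ...]
    chi2: float
    df: int
    p_value: float


@dataclass
class MarkerLinkage:
    marker: str
    position: float
    recombinants: int
    chromosomes: int  # 2n


@dataclass
class LocusInterval:
    """Interval estimate for the causal locus from a linkage table."""

    best_marker: str
    best_position: float
    lo_position: float | None  # None when unbounded on that side
    hi_position: float | None
    flagged: str | None = None


def segregation_test(
    observed: tuple[int, ...] | list[int],
    expected_ratio: tuple[float, ...] | list[float],
    yates: bool = False,
) -> SegregationResult:
    """Pearson chi-square goodness of fit against an expected ratio.

    No continuity correction by default (large F2 designs); set
    ``yates=True`` for Yates' correction with two classes.
    """
    obs = np.asarray(observed, float)
    ratio = np.asarray(expected_ratio, float)
    if obs.sum() <= 0:
        raise ValueError("total observed count must be positive")
    if np.any(ratio <= 0):
        raise ValueError("expected class proportions must be positive")
    if obs.size != ratio.size:
        raise ValueError("observed and expected_ratio must have equal length")
    exp = ratio / ratio.sum() * obs.sum()
    dev = np.abs(obs - exp)
    if yates:
        dev = np.maximum(dev - 0.5, 0.0)
    chi2 = float((dev**2 / exp).sum())
    df = obs.size - 1
    p = float(stats.chi2.sf(chi2, df))
    return SegregationResult(tuple(int(x) for x in obs), tuple(ratio), chi2, df, p)


def band_phenotypes(population: CrossPopulation) -> np.ndarray:
    """Dominant Chop-PCR band phenotype per plant.

    'methylated' when at least one epiallele copy is methylated (the
    methylated band is dominant on the gel), else 'unmethylated'.
    """
    return np.where(population.n_methylated_alleles > 0, "methylated", "unmethylated")


def count_recombinants(
    population: CrossPopulation,
    marker: str,
    selected_phenotype: str = "unmethylated",
    codominant: bool = False,
) -> MarkerLinkage:
    """Recombinant chromosomes at a marker among phenotype-selected plants.

    In the default recessive-selection mode, plants with the recessive
    ('unmethylated') band phenotype are selected; each of their 2n
    chromosomes carrying the methylated-parent (A) marker allele records a
    recombination between the marker and the epiallele locus.  The
    codominant mode instead counts marker alleles discordant with the
    same-chromosome epiallele state over all plants.
    """
    names = list(population.config.marker_names)
    if marker not in names:
        raise ValueError(f"unknown marker {marker!r}")
    j = names.index(marker)
    position = population.config.marker_cm[j]
    if codominant:
        # discordant = A-origin marker allele on a 'u' haplotype or vice versa
        disc = population.marker[:, j, :] != population.epi
        return MarkerLinkage(marker, position, int(disc.sum()), 2 * len(population))
    selected = band_phenotypes(population) == selected_phenotype
    alleles = population.marker[selected, j, :]
    recomb = int((alleles == 0).sum())  # parent-A allele in a recessive plant
    return MarkerLinkage(marker, position, recomb, 2 * int(selected.sum()))


def linkage_table(
    population: CrossPopulation,
    selected_phenotype: str = "unmethylated",
) -> pd.DataFrame:
    """Recombinant counts for every marker (columns: marker, position_cm,
    recombinants, chromosomes)."""
    rows = [
        count_recombinants(population, m, selected_phenotype)
        for m in population.config.marker_names
    ]
    return pd.DataFrame(
        {
            "marker": [r.marker for r in rows],
            "position_cm": [r.position for r in rows],
            "recombinants": [r.recombinants for r in rows],
            "chromosomes": [r.chromosomes for r in rows],
        }
    )


def linkage_table_from_frame(
    frame: pd.DataFrame,
    marker_positions: dict[str, float],
    selected_phenotype: str = "unmethylated",
) -> pd.DataFrame:
    """Recombinant counts from a population table (as written to TSV).

    Expects ``epi_genotype`` plus ``<marker>_1``/``<marker>_2`` allele
    columns ('A' = methylated-parent origin).  Plants with a missing
    marker genotype are skipped for that marker.
    """
    if selected_phenotype == "unmethylated":
        selected = frame[frame["epi_genotype"] == "uu"]
    else:
        selected = frame[frame["epi_genotype"].isin(["mm", "mu"])]
    rows = []
    for marker, pos in marker_positions.items():
        cols = [f"{marker}_1", f"{marker}_2"]
        if not set(cols) <= set(frame.columns):
            raise ValueError(f"missing genotype columns for marker {marker!r}")
        geno = selected[cols].dropna()
        recomb = int((geno.to_numpy() == "A").sum())
        rows.append(
            {
                "marker": marker,
                "position_cm": pos,
                "recombinants": recomb,
                "chromosomes": 2 * len(geno),
            }
        )
    return pd.DataFrame(rows)


def map_locus(table: pd.DataFrame) -> LocusInterval:
    """Locate the causal locus from a marker/recombinant table.

    Point estimate: the marker with the minimum recombinant count (ties
    flagged and spanned).  Interval: the nearest marker on each side with
    strictly more recombinants; an end of the marker panel reached first
    leaves that side unbounded (None) and flagged.

    The table needs columns ``marker``, a position column (``position_cm``
    or ``position``), and ``recombinants``; at least 3 markers.
    """
    pos_col = "position_cm" if "position_cm" in table.columns else "position"
    if len(table) < 3:
        raise ValueError("need at least 3 markers to map a locus")
    tbl = table.sort_values(pos_col, ignore_index=True)
    rec = tbl["recombinants"].to_numpy()
    best = int(rec.min())
    winners = np.flatnonzero(rec == best)
    flagged = None
    if winners.size == len(tbl):
        return LocusInterval(
            str(tbl["marker"].iloc[winners[0]]),
            float(tbl[pos_col].iloc[winners[0]]),
            None,
            None,
            flagged="all markers have equal recombinant counts",
        )
    if winners.size > 1:
        flagged = "tied minimum recombinant count; interval widened"
    first, last = winners[0], winners[-1]
    lo = hi = None
    for i in range(first - 1, -1, -1):
        if rec[i] > best:
            lo = float(tbl[pos_col].iloc[i])
            break
    for i in range(last + 1, len(tbl)):
        if rec[i] > best:
            hi = float(tbl[pos_col].iloc[i])
            break
    if lo is None or hi is None:
        side = "left" if lo is None else "right"
        note = f"interval unbounded on the {side}"
        flagged = f"{flagged}; {note}" if flagged else note
    mid = winners[winners.size // 2]
    return LocusInterval(
        str(tbl["marker"].iloc[mid]), float(tbl[pos_col].iloc[mid]), lo, hi, flagged
    )


def cosegregation_summary(
    individuals: pd.DataFrame,
    genotype_col: str = "epi_genotype",
    value_cols: tuple[str, ...] = ("pph_expression", "chlorophyll"),
) -> pd.DataFrame:
    """Per-genotype means with s.e.m. and a Welch two-tailed t-test.

    Groups plants by their Chop-PCR genotype (mm/mu/uu); for each measured
    variable reports group mean, s.e.m. and n, plus the Welch (unequal
    variance) two-tailed t-test between the homozygous classes.  Groups
    with fewer than two plants yield means only (p set to NaN).
    """
    if genotype_col not in individuals.columns:
        raise ValueError(f"missing genotype column {genotype_col!r}")
    rows = []
    for col in value_cols:
        groups = {
            g: sub[col].dropna().to_numpy(float)
            for g, sub in individuals.groupby(genotype_col)
        }
        stats_row: dict[str, object] = {"variable": col}
        for g in ("mm", "mu", "uu"):
            vals = groups.get(g, np.array([]))
            stats_row[f"mean_{g}"] = float(vals.mean()) if vals.size else np.nan
            stats_row[f"sem_{g}"] = (
                float(vals.std(ddof=1) / np.sqrt(vals.size)) if vals.size > 1 else np.nan
            )
            stats_row[f"n_{g}"] = int(vals.size)
        a, b = groups.get("mm", np.array([])), groups.get("uu", np.array([]))
        if a.size >= 2 and b.size >= 2:
            if a.std(ddof=1) == 0 and b.std(ddof=1) == 0 and a.mean() == b.mean():
                t, p = 0.0, 1.0  # identical constant groups
            else:
                t, p = stats.ttest_ind(a, b, equal_var=False)
            stats_row["welch_t"] = float(t)
            stats_row["p_value"] = float(p)
        else:
            stats_row["welch_t"] = np.nan
            stats_row["p_value"] = np.nan
        rows.append(stats_row)
    return pd.DataFrame(rows)
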