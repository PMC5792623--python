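"""Methylation quantification, in-silico Chop-PCR, and epiallele classification.

Levels are *weighted* methylation: summed methylated read counts divided by
summed total counts over the covered cytosines of a region and context —
robust to uneven depth.  Chop-PCR (methylation-sensitive-enzyme digestion
followed by PCR) is modelled at the molecule level: a template survives
digestion only if every enzyme site inside the amplicon is protected by
methylation, so the uncut fraction is the product of per-site methylation
levels, averaged over alleles; a band appears when enough template survives.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RegionMethylation",
    "Enzyme",
    "ChopResult",
    "weighted_level",
    "chop_pcr",
    "chop_band_from_alleles",
    "fisher_region_compare",
    "classify_accession",
    "CATEGORIES",
]

CATEGORIES = ("NMR19-16u", "NMR19-4m", "NMR19-4m/16m", "NMR19-4u", "deletion")

CONTEXTS = ("CG", "CHG", "CHH")


@dataclass
class RegionMethylation:
    """Weighted methylation of one region, total and per context.

    ``levels`` maps 'total'/'CG'/'CHG'/'CHH' to a level in [0,1] or None
    when no cytosine of that context is covered (undefined, *not* zero).
    ``covered`` gives the number of covered cytosines per key.
    """

    region: tuple[str, int, int]
    levels: dict[str, float | None]
    covered: dict[str, int]

    @property
    def total(self) -> float | None:
        return self.levels["total"]


def _select(records: pd.DataFrame, region: tuple[str, int, int]) -> pd.DataFrame:
    chrom, start, end = region
    mask = (records["chrom"] == chrom) & (records["pos"] >= start) & (records["pos"] < end)
    return records.loc[mask]


def weighted_level(
    records: pd.DataFrame,
    region: tuple[str, int, int],
    context: str | None = None,
) -> RegionMethylation:
    """Weighted methylation level of a region.

    ``records`` is a cytosine table (chrom, pos, strand, context,
    count_methylated, count_total).  With ``context`` given, only that
    context contributes to ``total``; otherwise all contexts are pooled and
    per-context levels are reported as well.
    """
    sub = _select(records, region)
    if context is not None:
        if context not in CONTEXTS:
            raise ValueError(f"unknown context {context!r}")
        sub = sub[sub["context"] == context]
    if (sub["count_methylated"] > sub["count_total"]).any():
        raise ValueError("count_methylated exceeds count_total")
    levels: dict[str, float | None] = {}
    covered: dict[str, int] = {}

    def level_of(frame: pd.DataFrame) -> tuple[float | None, int]:
        frame = frame[frame["count_total"] > 0]
        total = int(frame["count_total"].sum())
        if total == 0:
            return None, 0
        return float(frame["count_methylated"].sum() / total), int(len(frame))

    levels["total"], covered["total"] = level_of(sub)
    for ctx in CONTEXTS:
        levels[ctx], covered[ctx] = level_of(sub[sub["context"] == ctx])
    return RegionMethylation(region, levels, covered)


# ---------------------------------------------------------------------------
# Chop-PCR


@dataclass
class Enzyme:
    """A methylation-sensitive restriction enzyme.

    ``recognition`` is the recognition sequence, ``diagnostic_offset`` the
    0-based offset of the cytosine whose methylation blocks digestion.
    ``blocked_contexts`` lists which methylation contexts protect the site
    (MspI, C^CGG, is insensitive to inner-CG methylation but blocked by
    outer-C (CHG) methylation; HhaI, GCG^C, is blocked by CG methylation).
    """

    name: str
    recognition: str
    diagnostic_offset: int
    blocked_contexts: tuple[str, ...] = ("CG", "CHG", "CHH")


MSPI = Enzyme("MspI", "CCGG", 0, blocked_contexts=("CHG",))
HHAI = Enzyme("HhaI", "GCGC", 1, blocked_contexts=("CG",))


@dataclass
class ChopResult:
    band: str  # "present" or "absent"
    uncut_fraction: float
    n_sites: int


def chop_pcr(
    site_levels: Sequence[float] | Sequence[Sequence[float]],
    threshold: float = 0.1,
) -> ChopResult:
    """Score a Chop-PCR assay from methylation levels at the enzyme sites.

    ``site_levels`` is either a flat list of per-site methylation levels
    (one template population) or one list per allele at equal dosage.  The
    surviving (uncut) template fraction is the product over sites of the
    diagnostic-cytosine methylation level, averaged over alleles; a band is
    scored present when the uncut fraction reaches ``threshold``.

    With no enzyme site inside the amplicon the assay is a control
    amplicon: the band is always present (uncut fraction 1).
    """
    if len(site_levels) == 0:
        return ChopResult("present", 1.0, 0)
    first = site_levels[0]
    alleles: list[Sequence[float]]
    if np.isscalar(first):
        alleles = [site_levels]  # type: ignore[list-item]
    else:
        alleles = list(site_levels)  # type: ignore[arg-type]
    fractions = []
    n_sites = 0
    for allele in alleles:
        levels = np.asarray(allele, float)
        if np.any((levels < 0) | (levels > 1)):
            raise ValueError("methylation levels must be in [0, 1]")
        n_sites = max(n_sites, levels.size)
        fractions.append(float(np.prod(levels)) if levels.size else 1.0)
    uncut = float(np.mean(fractions))
    return ChopResult("present" if uncut >= threshold else "absent", uncut, n_sites)


def chop_band_from_alleles(allele_states: Sequence[str], threshold: float = 0.1) -> str:
    """Dominant band scoring from binary allele states ('m'/'u').

    A methylated allele protects its template completely, an unmethylated
    one not at all, so a heterozygote has uncut fraction 0.5 and still
    shows the methylated band (dominance) — the basis of the 3:1 F2 ratio.
    """
    levels = [[1.0] if s == "m" else [0.0] for s in allele_states]
    return chop_pcr(levels, threshold=threshold).band


# ---------------------------------------------------------------------------
# Region comparison and classification


def fisher_region_compare(
    records_a: pd.DataFrame,
    records_b: pd.DataFrame,
    region: tuple[str, int, int],
    context: str | None = None,
) -> float:
    """Two-sided Fisher exact test of pooled methylated/unmethylated counts.

    Reads are pooled across the region's cytosines (of the given context)
    into a 2x2 table (methylated, unmethylated) x (sample a, sample b).
    Returns the exact two-sided p-value; raises if a margin is empty.
    """
    table = []
    for records in (records_a, records_b):
        sub = _select(records, region)
        if context is not None:
            sub = sub[sub["context"] == context]
        meth = int(sub["count_methylated"].sum())
        tot = int(sub["count_total"].sum())
        if tot == 0:
            raise ValueError("empty margin: no covered cytosines in one sample")
        table.append([meth, tot - meth])
    if sum(row[0] for row in table) == 0 and sum(row[1] for row in table) == 0:
        raise ValueError("empty margin")
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def classify_accession(
    presence_4: bool,
    presence_16: bool,
    level_4: float | None,
    level_16: float | None,
    meth_threshold: float = 0.2,
) -> str:
    """Assign one accession to one of the five NMR19 categories.

    Categories follow the element's position (4.45 Mb and/or 16.75 Mb copy
    present) and methylation: deletion (neither copy), NMR19-4m / NMR19-4u
    (4.45 Mb copy, methylated or not, regardless of a 16.75 Mb copy unless
    both are methylated, which gives NMR19-4m/16m), and NMR19-16u (only
    the 16.75 Mb copy).  ``meth_threshold`` binarises the CG-level where a
    gel-based call is unavailable.  A methylation level for an absent copy
    is inconsistent input.
    """
    if not presence_4 and level_4 is not None:
        raise ValueError("methylation level given for absent NMR19-4")
    if not presence_16 and level_16 is not None:
        raise ValueError("methylation level given for absent NMR19-16")
    if not presence_4 and not presence_16:
        return "deletion"
    meth_4 = presence_4 and level_4 is not None and level_4 >= meth_threshold
    meth_16 = presence_16 and level_16 is not None and level_16 >= meth_threshold
    if presence_4:
        if meth_4 and meth_16:
            return "NMR19-4m/16m"
        return "NMR19-4m" if meth_4 else "NMR19-4u"
    return "NMR19-16u"
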