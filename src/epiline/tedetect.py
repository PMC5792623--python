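"""Non-reference TE insertion calling from read pairs, with TSD identification.

The caller follows the classic discordant-pair strategy used to find new
LINE1 copies: read pairs with one mate on the element sequence and the
other mate mapped uniquely elsewhere in the genome anchor a candidate
insertion; anchors upstream of the breakpoint align to the + strand and
anchors downstream to the - strand, and the breakpoint is bracketed
between them.  The target-site duplication (TSD) — the short direct repeat
created at integration — is then read off by comparing the insertion
allele with the empty reference allele.

Split (junction-spanning) reads are deliberately ignored: the strategy is
pair-based only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._util import reverse_complement
from .synthgen import GenomeModel, ReadPair

__all__ = [
    "TEInsertionCall",
    "InsertionCandidate",
    "naive_map",
    "find_discordant_pairs",
    "call_insertion",
    "call_insertions",
    "detect_tsd",
    "tsd_from_genomes",
]


@dataclass
class TEInsertionCall:
    chrom: str
    lo: int  # breakpoint interval, 0-based half-open
    hi: int
    orientation: str  # "same" or "inverted"
    left_support: int
    right_support: int
    tsd_length: int = 0
    tsd_sequence: str = ""
    tsd_ambiguous: bool = False

    def __post_init__(self) -> None:
        if self.lo >= self.hi:
            raise ValueError("breakpoint interval must be non-empty")
        if self.tsd_length != len(self.tsd_sequence):
            raise ValueError("tsd_length must equal len(tsd_sequence)")


@dataclass
class InsertionCandidate:
    """A cluster that did not reach a call, with the reason."""

    chrom: str
    lo: int
    hi: int
    left_support: int
    right_support: int
    reason: str


# ---------------------------------------------------------------------------
# Mapping


def naive_map(
    reads: list[ReadPair],
    genome: GenomeModel,
    te_sequences: dict[str, str],
    k: int = 31,
) -> pd.DataFrame:
    """Exact k-mer anchored placement of (near) error-free reads.

    A stand-in for a production aligner on synthetic data: each mate is
    anchored by its leading k-mer (with the trailing k-mer as fallback),
    verified by full-string comparison against the reference, on both
    strands.  Reads with more than one perfect placement are flagged
    non-unique; unplaced reads are omitted.

    Returns columns: read_id, mate, contig, start, strand, length, unique,
    is_te.
    """
    contigs = dict(genome.sequences) | dict(te_sequences)
    if not contigs or any(len(s) == 0 for s in contigs.values()):
        raise ValueError("empty reference contig")
    te_names = set(te_sequences)

    index: dict[str, list[tuple[str, int]]] = {}
    for name, seq in contigs.items():
        for i in range(0, len(seq) - k + 1):
            index.setdefault(seq[i: i + k], []).append((name, i))

    rows = []
    for pair in reads:
        for mate, seq in ((1, pair.seq1), (2, pair.seq2)):
            placements = _place(seq, contigs, index, k)
            if not placements:
                continue
            contig, start, strand = placements[0]
            rows.append(
                {
                    "read_id": pair.read_id,
                    "mate": mate,
                    "contig": contig,
                    "start": start,
                    "strand": strand,
                    "length": len(seq),
                    "unique": len(placements) == 1,
                    "is_te": contig in te_names,
                }
            )
    return pd.DataFrame(
        rows, columns=["read_id", "mate", "contig", "start", "strand", "length", "unique", "is_te"]
    )


def _place(seq: str, contigs: dict[str, str], index, k: int) -> list[tuple[str, int, str]]:
    found: set[tuple[str, int, str]] = set()
    for oriented, strand in ((seq, "+"), (reverse_complement(seq), "-")):
        if len(oriented) < k:
            continue
        for offset in (0, len(oriented) - k):
            for contig, pos in index.get(oriented[offset: offset + k], ()):
                start = pos - offset
                if start < 0:
                    continue
                if contigs[contig][start: start + len(oriented)] == oriented:
                    found.add((contig, start, strand))
    return sorted(found)


# ---------------------------------------------------------------------------
# Discordant pairs and clustering


@dataclass
class DiscordantCluster:
    """Genome-side anchors (one per discordant pair) for one candidate locus."""

    chrom: str
    anchors: pd.DataFrame = field(repr=False)  # start, end, strand, te_strand

    @property
    def left(self) -> pd.DataFrame:
        return self.anchors[self.anchors["strand"] == "+"]

    @property
    def right(self) -> pd.DataFrame:
        return self.anchors[self.anchors["strand"] == "-"]


def find_discordant_pairs(
    alignments: pd.DataFrame,
    te_names: set[str],
    insert_mean: float = 500.0,
    insert_sd: float = 50.0,
) -> list[DiscordantCluster]:
    """Cluster read pairs with exactly one mate on a TE contig.

    The genome-side mate must be uniquely mapped.  Anchors on the same
    chromosome within ``insert_mean + 3*insert_sd`` of each other join one
    cluster; + strand anchors sit left of the breakpoint, - strand anchors
    right of it.
    """
    if alignments.empty:
        return []
    aln = alignments.copy()
    if "is_te" not in aln:
        aln["is_te"] = aln["contig"].isin(te_names)
    merged = aln[aln["mate"] == 1].merge(
        aln[aln["mate"] == 2], on="read_id", suffixes=("_1", "_2")
    )
    # exactly one mate on a TE contig, the genome-side mate uniquely placed
    discordant = merged[merged["is_te_1"] != merged["is_te_2"]]
    if discordant.empty:
        return []
    te_is_1 = discordant["is_te_1"].to_numpy()
    g_side = np.where(te_is_1, "2", "1")
    t_side = np.where(te_is_1, "1", "2")

    def pick(col: str, side: np.ndarray) -> np.ndarray:
        a = discordant[f"{col}_1"].to_numpy()
        b = discordant[f"{col}_2"].to_numpy()
        return np.where(side == "1", a, b)

    unique_g = pick("unique", g_side).astype(bool)
    anchors = pd.DataFrame(
        {
            "read_id": discordant["read_id"].to_numpy(),
            "chrom": pick("contig", g_side),
            "start": pick("start", g_side).astype(int),
            "end": (pick("start", g_side) + pick("length", g_side)).astype(int),
            "strand": pick("strand", g_side),
            "te_strand": pick("strand", t_side),
        }
    )[unique_g]
    if anchors.empty:
        return []
    anchors = anchors.sort_values(["chrom", "start"], ignore_index=True)
    max_gap = insert_mean + 3 * insert_sd
    clusters: list[DiscordantCluster] = []
    for chrom, sub in anchors.groupby("chrom", sort=False):
        sub = sub.reset_index(drop=True)
        breaks = np.flatnonzero(np.diff(sub["start"].to_numpy()) > max_gap)
        pieces = np.split(np.arange(len(sub)), breaks + 1)
        for idx in pieces:
            clusters.append(DiscordantCluster(str(chrom), sub.iloc[idx].reset_index(drop=True)))
    return clusters


def call_insertion(
    cluster: DiscordantCluster,
    insert_mean: float = 500.0,
    insert_sd: float = 50.0,
    min_support: int = 3,
) -> TEInsertionCall | InsertionCandidate:
    """Call a breakpoint from one discordant cluster.

    The breakpoint interval is [max end of left anchors, min start of right
    anchors]; if deep coverage makes those overlap, the interval collapses
    to the single base at their midpoint.  Orientation is voted from the
    TE-side mate strands: a pair anchored left of a same-orientation
    insertion has its TE mate on the - strand (and mirrored on the right).
    Clusters with fewer than ``min_support`` anchors on either side are
    reported as candidates, not calls.
    """
    left, right = cluster.left, cluster.right
    nl, nr = len(left), len(right)
    span_lo = int(cluster.anchors["start"].min())
    span_hi = int(cluster.anchors["end"].max())
    if nl < min_support or nr < min_support:
        return InsertionCandidate(
            cluster.chrom, span_lo, max(span_hi, span_lo + 1), nl, nr,
            reason=f"support below threshold (left={nl}, right={nr}, min={min_support})",
        )
    lo = int(left["end"].max())
    hi = int(right["start"].min())
    if lo >= hi:
        mid = (lo + hi) // 2
        lo, hi = mid, mid + 1
    votes_same = int((left["te_strand"] == "-").sum() + (right["te_strand"] == "+").sum())
    votes_inv = (nl + nr) - votes_same
    orientation = "same" if votes_same >= votes_inv else "inverted"
    return TEInsertionCall(cluster.chrom, lo, hi, orientation, nl, nr)


def call_insertions(
    alignments: pd.DataFrame,
    te_names: set[str],
    insert_mean: float = 500.0,
    insert_sd: float = 50.0,
    min_support: int = 3,
) -> tuple[list[TEInsertionCall], list[InsertionCandidate]]:
    """Convenience wrapper: cluster discordant pairs and call every cluster."""
    calls: list[TEInsertionCall] = []
    candidates: list[InsertionCandidate] = []
    for cluster in find_discordant_pairs(alignments, te_names, insert_mean, insert_sd):
        result = call_insertion(cluster, insert_mean, insert_sd, min_support)
        if isinstance(result, TEInsertionCall):
            calls.append(result)
        else:
            candidates.append(result)
    return calls, candidates


# ---------------------------------------------------------------------------
# Target-site duplication


def detect_tsd(
    ref_flanks: tuple[str, str],
    insertion_allele: str,
    te_sequence: str,
    max_tsd: int = 30,
) -> tuple[int, str]:
    """Identify the target-site duplication at an insertion junction.

    ``ref_flanks`` are the reference-allele sequences immediately left and
    right of the insertion point (each with at least ``max_tsd`` bases of
    context); ``insertion_allele`` is the corresponding sequence of the
    carrier haplotype, containing exactly one copy of ``te_sequence`` in
    either orientation.  The TSD is the longest s (|s| <= max_tsd) that
    immediately precedes and follows the element in the insertion allele
    while occurring once, at the breakpoint, in the reference allele —
    i.e. removing one copy of s restores the reference.  Returns
    (0, "") when the junction is blunt.
    """
    left_ref, right_ref = ref_flanks
    te = te_sequence
    pos = insertion_allele.find(te)
    if pos < 0:
        te = reverse_complement(te_sequence)
        pos = insertion_allele.find(te)
    if pos < 0:
        raise ValueError("TE sequence not found in the insertion allele")
    if insertion_allele.find(te, pos + 1) >= 0:
        raise ValueError("insertion allele contains more than one TE copy")
    pre = insertion_allele[:pos]
    post = insertion_allele[pos + len(te):]

    # the pre-TE part must come from the reference left flank
    overlap = min(len(pre), len(left_ref))
    if overlap and pre[-overlap:] != left_ref[-overlap:]:
        raise ValueError("insertion allele inconsistent with the reference left flank")

    best: tuple[int, str] | None = None
    limit = min(max_tsd, len(pre), len(post))
    for length in range(limit + 1):
        s = pre[len(pre) - length:] if length else ""
        if length and post[:length] != s:
            continue
        # after removing the duplicated copy, the remainder must restore the
        # reference right flank (this pins the TSD length uniquely)
        rest = post[length:]
        w = min(len(rest), len(right_ref))
        if w == 0 or rest[:w] == right_ref[:w]:
            best = (length, s)
    return best if best is not None else (0, "")


def tsd_from_genomes(
    reference: GenomeModel,
    carrier: GenomeModel,
    call: TEInsertionCall,
    te_sequence: str,
    max_tsd: int = 30,
    context: int = 200,
) -> tuple[int, str]:
    """Call the TSD for a breakpoint using reference and carrier genomes.

    ``te_sequence`` is the element as inserted (e.g. obtained by sequencing
    the carrier's insertion allele); it is searched in both orientations.
    The insertion point is anchored in the reference via the left context
    and the junction is delegated to :func:`detect_tsd`.
    """
    ref_seq = reference.sequences[call.chrom]
    alt_seq = carrier.sequences[call.chrom]
    te = te_sequence
    i = alt_seq.find(te)
    if i < 0:
        te = reverse_complement(te_sequence)
        i = alt_seq.find(te)
    if i < 0:
        raise ValueError("element not found in carrier genome")
    lo = max(i - context, 0)
    left_alt = alt_seq[lo:i]
    p = ref_seq.find(left_alt)
    if p < 0 or ref_seq.find(left_alt, p + 1) >= 0:
        raise ValueError("could not anchor the insertion point uniquely in the reference")
    point = p + len(left_alt)
    ref_flanks = (ref_seq[max(point - context, 0): point], ref_seq[point: point + context])
    allele = alt_seq[lo: i + len(te) + context]
    return detect_tsd(ref_flanks, allele, te, max_tsd=max_tsd)
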