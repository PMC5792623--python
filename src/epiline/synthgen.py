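"""Synthetic inputs with known ground truth for every pipeline stage.

This module emulates the data behind a LINE1 epiallele study in
*Arabidopsis thaliana*: a reference genome with a planted, possibly
truncated and inverted, TE insertion flanked by a target-site duplication
(TSD); paired-end reads over it; per-cytosine bisulfite methylation calls;
Mendelian crosses in which an epiallele's methylation state travels in cis
(with optional stochastic, irreversible loss in a ddm1-mutant background);
star-phylogeny sequence evolution under the TN93 model at a stated rate and
age; and accession tables with 19 bioclimatic variables at two epochs and a
planted monotone methylation–bio9 relation.

All generators are bit-reproducible given (seed, parameters).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._util import BASES, reverse_complement
from .tedate import AlignedSet, TN93Params, tn93_rate_matrix

from scipy.linalg import expm

__all__ = [
    "Annotation",
    "GenomeModel",
    "PlantedInsertion",
    "ReadPair",
    "CrossConfig",
    "CrossPopulation",
    "EvolutionConfig",
    "make_reference",
    "plant_insertion",
    "simulate_read_pairs",
    "cytosine_contexts",
    "simulate_bisulfite_calls",
    "simulate_cross",
    "simulate_selfing_series",
    "simulate_phenotypes",
    "evolve_star",
    "simulate_climate_table",
    "BIOCLIM_BASELINES",
]


# ---------------------------------------------------------------------------
# Genomes and insertions


@dataclass
class Annotation:
    name: str
    chrom: str
    start: int  # 0-based half-open
    end: int
    strand: str = "+"


@dataclass
class GenomeModel:
    """Chromosome name -> sequence, plus interval annotations (0-based half-open)."""

    sequences: dict[str, str]
    annotations: list[Annotation] = field(default_factory=list)

    def __post_init__(self) -> None:
        for name, seq in self.sequences.items():
            if not seq:
                raise ValueError(f"chromosome {name!r} is empty")
        for ann in self.annotations:
            if ann.chrom not in self.sequences:
                raise ValueError(f"annotation {ann.name!r} on unknown chromosome")
            if not (0 <= ann.start < ann.end <= len(self.sequences[ann.chrom])):
                raise ValueError(f"annotation {ann.name!r} out of bounds")

    def length(self, chrom: str) -> int:
        return len(self.sequences[chrom])

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.sequences.values())


@dataclass
class PlantedInsertion:
    """A TE insertion to plant: point, element, orientation, truncation, TSD."""

    chrom: str
    point: int  # 0-based, between-base
    te_sequence: str
    inverted: bool = False
    truncation: int = 0  # bases removed from the element 5' end
    tsd_length: int = 0
    name: str = "TE_insertion"

    def __post_init__(self) -> None:
        if self.tsd_length < 0:
            raise ValueError("tsd_length must be >= 0")
        if not (0 <= self.truncation < len(self.te_sequence)):
            raise ValueError("truncation must be smaller than the element length")

    @property
    def inserted_sequence(self) -> str:
        """The element as it appears in the derived genome (truncated, oriented)."""
        seq = self.te_sequence[self.truncation:]
        return reverse_complement(seq) if self.inverted else seq


def make_reference(
    seed: int,
    chrom_lengths: Mapping[str, int],
    gc_fraction: float = 0.36,
) -> GenomeModel:
    """Random reference genome with the given GC content.

    Lengths must be at least 1 kb; base composition converges to
    ``gc_fraction`` by the law of large numbers (within ~2% for >=100 kb).
    """
    if not 0.0 <= gc_fraction <= 1.0:
        raise ValueError("gc_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    at = (1.0 - gc_fraction) / 2
    gc = gc_fraction / 2
    probs = [at, gc, gc, at]  # A C G T
    base_arr = np.frombuffer(BASES.encode(), np.uint8)
    sequences = {}
    for name, length in chrom_lengths.items():
        if length < 1000:
            raise ValueError(f"chromosome {name!r} shorter than 1 kb")
        draws = rng.choice(4, size=length, p=probs)
        sequences[name] = base_arr[draws].tobytes().decode()
    return GenomeModel(sequences)


def plant_insertion(genome: GenomeModel, insertion: PlantedInsertion) -> GenomeModel:
    """Derived genome carrying the insertion with its target-site duplication.

    At the insertion point the derived chromosome reads: left flank
    (which already ends in the future TSD) + element + TSD + right flank,
    the TSD being the ``tsd_length`` bases immediately 5' of the point in
    the source genome.  Total length grows by element length + tsd_length.
    """
    chrom = insertion.chrom
    if chrom not in genome.sequences:
        raise ValueError(f"unknown chromosome {chrom!r}")
    src = genome.sequences[chrom]
    p = insertion.point
    if not 0 <= p <= len(src):
        raise ValueError("insertion point outside chromosome")
    if insertion.tsd_length > p:
        raise ValueError("tsd_length larger than available left flank")
    te = insertion.inserted_sequence
    tsd = src[p - insertion.tsd_length: p]
    derived = src[:p] + te + tsd + src[p:]
    shift = len(te) + len(tsd)

    sequences = dict(genome.sequences)
    sequences[chrom] = derived
    annotations = []
    for ann in genome.annotations:
        if ann.chrom == chrom and ann.start >= p:
            ann = replace(ann, start=ann.start + shift, end=ann.end + shift)
        elif ann.chrom == chrom and ann.end > p:
            ann = replace(ann, end=ann.end + shift)
        annotations.append(ann)
    annotations.append(
        Annotation(insertion.name, chrom, p, p + len(te), "-" if insertion.inverted else "+")
    )
    return GenomeModel(sequences, annotations)


# ---------------------------------------------------------------------------
# Paired-end reads


@dataclass
class ReadPair:
    """An inner-facing read pair with its truth tag (source fragment)."""

    read_id: str
    seq1: str  # forward-strand mate (fragment 5' end)
    seq2: str  # reverse-complemented mate (fragment 3' end)
    chrom: str
    frag_start: int
    frag_end: int


def simulate_read_pairs(
    genome: GenomeModel,
    read_len: int = 150,
    insert_mean: float = 500.0,
    insert_sd: float = 50.0,
    coverage: float = 30.0,
    error_rate: float = 0.0,
    seed: int = 0,
) -> list[ReadPair]:
    """Uniformly sampled inner-facing read pairs with truth tags.

    Fragment lengths are normal (clamped to [2*read_len, chromosome]);
    substitution errors are applied per base at ``error_rate``.  Realized
    coverage is within ~10% of target for genomes >= 100 kb.
    """
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    if insert_mean <= 2 * read_len:
        raise ValueError("insert_mean must exceed twice the read length")
    rng = np.random.default_rng(seed)
    pairs: list[ReadPair] = []
    base_arr = np.frombuffer(BASES.encode(), np.uint8)
    for chrom, seq in genome.sequences.items():
        length = len(seq)
        n_pairs = int(round(coverage * length / (2 * read_len)))
        sizes = rng.normal(insert_mean, insert_sd, size=n_pairs)
        sizes = np.clip(np.rint(sizes), 2 * read_len, length).astype(int)
        starts = rng.integers(0, np.maximum(length - sizes + 1, 1))
        for i, (start, size) in enumerate(zip(starts, sizes)):
            frag = seq[start: start + size]
            r1 = frag[:read_len]
            r2 = reverse_complement(frag[-read_len:])
            if error_rate > 0:
                r1 = _mutate(r1, error_rate, rng, base_arr)
                r2 = _mutate(r2, error_rate, rng, base_arr)
            pairs.append(ReadPair(f"{chrom}_pair{i}", r1, r2, chrom, int(start), int(start + size)))
    return pairs


def _mutate(read: str, rate: float, rng: np.random.Generator, base_arr: np.ndarray) -> str:
    arr = np.frombuffer(read.encode(), np.uint8).copy()
    hits = np.flatnonzero(rng.random(arr.size) < rate)
    if hits.size:
        # replace with one of the three other bases
        subs = base_arr[rng.integers(0, 4, size=hits.size)]
        same = subs == arr[hits]
        while same.any():
            subs[same] = base_arr[rng.integers(0, 4, size=int(same.sum()))]
            same = subs == arr[hits]
        arr[hits] = subs
    return arr.tobytes().decode()


# ---------------------------------------------------------------------------
# Bisulfite methylation calls

METHYLATED_MEANS = {"CG": 0.85, "CHG": 0.65, "CHH": 0.10}
UNMETHYLATED_MEANS = {"CG": 0.02, "CHG": 0.02, "CHH": 0.02}


def cytosine_contexts(seq: str) -> pd.DataFrame:
    """All cytosines of both strands with their CG/CHG/CHH context.

    The context is read from the cytosine's own strand (H = A, C or T);
    cytosines lacking two downstream bases on their strand are skipped.
    Returns columns pos (0-based), strand, context.
    """
    arr = np.frombuffer(seq.encode(), np.uint8)
    c, g = ord("C"), ord("G")
    length = arr.size

    plus = np.flatnonzero(arr == c)
    plus = plus[plus <= length - 3]
    nxt, nxt2 = arr[plus + 1], arr[plus + 2]
    plus_ctx = np.where(nxt == g, "CG", np.where(nxt2 == g, "CHG", "CHH"))

    minus = np.flatnonzero(arr == g)
    minus = minus[minus >= 2]
    prv, prv2 = arr[minus - 1], arr[minus - 2]
    minus_ctx = np.where(prv == c, "CG", np.where(prv2 == c, "CHG", "CHH"))

    return pd.DataFrame(
        {
            "pos": np.concatenate([plus, minus]),
            "strand": np.repeat(["+", "-"], [plus.size, minus.size]),
            "context": np.concatenate([plus_ctx, minus_ctx]),
        }
    ).sort_values("pos", kind="stable", ignore_index=True)


def simulate_bisulfite_calls(
    genome: GenomeModel,
    region_states: Sequence[tuple[str, int, int, str | Mapping[str, float]]],
    depth_mean: float = 30.0,
    conversion_error: float = 0.0,
    seed: int = 0,
    overdispersion: float = 0.1,
) -> pd.DataFrame:
    """Per-cytosine methylation counts for the given regions.

    Each region carries a state: ``"methylated"`` / ``"unmethylated"`` (with
    context-specific default means) or an explicit {context: mean} mapping.
    Depths are Poisson(depth_mean); cytosines with zero depth are omitted.
    Per-cytosine levels are beta-distributed around the context mean with
    the given overdispersion; ``conversion_error`` is the probability that
    an unmethylated cytosine reads as methylated (failed conversion).

    Returns columns: chrom, pos, strand, context, count_methylated, count_total.
    """
    if depth_mean <= 0:
        raise ValueError("depth_mean must be positive")
    rng = np.random.default_rng(seed)
    frames = []
    for chrom, start, end, state in region_states:
        if chrom not in genome.sequences:
            raise ValueError(f"unknown chromosome {chrom!r}")
        means = _state_means(state)
        ctx = cytosine_contexts(genome.sequences[chrom])
        ctx = ctx[(ctx["pos"] >= start) & (ctx["pos"] < end)].reset_index(drop=True)
        depth = rng.poisson(depth_mean, size=len(ctx))
        mu = ctx["context"].map(means).to_numpy(float)
        if overdispersion > 0:
            conc = 1.0 / overdispersion - 1.0
            level = rng.beta(np.maximum(mu * conc, 1e-6), np.maximum((1 - mu) * conc, 1e-6))
        else:
            level = mu
        p_obs = level + (1.0 - level) * conversion_error
        meth = rng.binomial(depth, p_obs)
        frame = ctx.assign(chrom=chrom, count_methylated=meth, count_total=depth)
        frames.append(frame[frame["count_total"] > 0])
    out = pd.concat(frames, ignore_index=True)
    return out[["chrom", "pos", "strand", "context", "count_methylated", "count_total"]]


def _state_means(state: str | Mapping[str, float]) -> Mapping[str, float]:
    if isinstance(state, str):
        if state == "methylated":
            return METHYLATED_MEANS
        if state == "unmethylated":
            return UNMETHYLATED_MEANS
        raise ValueError(f"unknown region state {state!r}")
    return state


# ---------------------------------------------------------------------------
# Crosses and inheritance


@dataclass
class CrossConfig:
    """A biparental cross segregating markers and a cis-inherited epiallele.

    Marker and epiallele positions are genetic (centimorgan) on one
    chromosome; crossovers follow the Haldane (no-interference) map
    function.  The epiallele's methylation state is transmitted unchanged
    with the haplotype, except that a ddm1-homozygous-mutant parent loses
    a transmitted methylated allele with probability ``epsilon`` per
    meiosis, irreversibly.  The ddm1 locus is unlinked.
    """

    marker_cm: tuple[float, ...] = (0.0, 20.0, 40.0, 60.0, 80.0)
    marker_names: tuple[str, ...] | None = None
    epi_locus_cm: float = 40.0
    parent_a_epi: tuple[str, str] = ("m", "m")
    parent_b_epi: tuple[str, str] = ("u", "u")
    parent_a_ddm1: tuple[str, str] = ("D", "D")
    parent_b_ddm1: tuple[str, str] = ("D", "D")
    epsilon: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.epsilon <= 1.0:
            raise ValueError("epsilon must be in [0, 1]")
        if list(self.marker_cm) != sorted(self.marker_cm):
            raise ValueError("marker map positions must be non-decreasing")
        if self.marker_names is None:
            self.marker_names = tuple(f"M{i + 1}" for i in range(len(self.marker_cm)))
        if len(self.marker_names) != len(self.marker_cm):
            raise ValueError("marker_names must match marker_cm")
        for state in (*self.parent_a_epi, *self.parent_b_epi):
            if state not in ("m", "u"):
                raise ValueError("epiallele states must be 'm' or 'u'")


_EPI = np.array(["m", "u"])
_DDM1 = np.array(["D", "d"])
_MARK = np.array(["A", "B"])


@dataclass
class CrossPopulation:
    """Diploid individuals: marker origins, epiallele states, ddm1 genotypes.

    ``marker`` has shape (n, n_markers, 2) with 0 = parent-A allele and
    1 = parent-B allele; ``epi`` has shape (n, 2) with 0 = methylated 'm'
    and 1 = unmethylated 'u'; ``ddm1`` has shape (n, 2) with 0 = 'D' wild
    type and 1 = 'd' mutant.
    """

    marker: np.ndarray
    epi: np.ndarray
    ddm1: np.ndarray
    config: CrossConfig
    generation: str

    def __len__(self) -> int:
        return self.marker.shape[0]

    @property
    def n_methylated_alleles(self) -> np.ndarray:
        return (self.epi == 0).sum(axis=1)

    def epi_genotype(self) -> np.ndarray:
        """Per-individual epiallele genotype string: 'mm', 'mu' or 'uu'."""
        codes = np.sort(self.epi, axis=1)
        return np.char.add(_EPI[codes[:, 0]], _EPI[codes[:, 1]])

    def to_frame(self) -> pd.DataFrame:
        cols: dict[str, np.ndarray] = {"plant_id": np.arange(len(self))}
        for j, name in enumerate(self.config.marker_names):
            cols[f"{name}_1"] = _MARK[self.marker[:, j, 0]]
            cols[f"{name}_2"] = _MARK[self.marker[:, j, 1]]
        cols["epi_1"] = _EPI[self.epi[:, 0]]
        cols["epi_2"] = _EPI[self.epi[:, 1]]
        cols["ddm1_1"] = _DDM1[self.ddm1[:, 0]]
        cols["ddm1_2"] = _DDM1[self.ddm1[:, 1]]
        cols["epi_genotype"] = self.epi_genotype()
        return pd.DataFrame(cols)


def _haldane_theta(d_cm: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 - np.exp(-2.0 * d_cm / 100.0))


def _loci(config: CrossConfig) -> tuple[np.ndarray, int, np.ndarray]:
    """Sorted locus positions (markers + epiallele), epi index, marker indices."""
    pos = np.append(np.asarray(config.marker_cm, float), config.epi_locus_cm)
    order = np.argsort(pos, kind="stable")
    epi_idx = int(np.flatnonzero(order == len(config.marker_cm))[0])
    marker_idx = np.empty(len(config.marker_cm), int)
    for rank, original in enumerate(order):
        if original < len(config.marker_cm):
            marker_idx[original] = rank
    return pos[order], epi_idx, marker_idx


def _meiosis(
    marker: np.ndarray,
    epi: np.ndarray,
    ddm1: np.ndarray,
    positions: np.ndarray,
    epi_idx: int,
    marker_idx: np.ndarray,
    epsilon: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One gamete per parent row; applies ddm1 loss on transmission."""
    n = marker.shape[0]
    n_loci = positions.size
    # chromosomal loci: interleave markers and epiallele in map order
    chrom = np.empty((n, n_loci, 2), dtype=marker.dtype)
    chrom[:, marker_idx, :] = marker
    chrom[:, epi_idx, :] = epi

    theta = _haldane_theta(np.diff(positions))
    start = rng.integers(0, 2, size=n)
    switches = rng.random((n, n_loci - 1)) < theta[None, :]
    hap = np.concatenate([start[:, None], switches], axis=1).cumsum(axis=1) % 2
    gamete = np.take_along_axis(chrom, hap[:, :, None], axis=2)[:, :, 0]

    g_marker = gamete[:, marker_idx]
    g_epi = gamete[:, epi_idx]
    g_ddm1 = np.take_along_axis(ddm1, rng.integers(0, 2, size=(n, 1)), axis=1)[:, 0]

    if epsilon > 0:
        dd_parent = (ddm1 == 1).all(axis=1)
        lose = dd_parent & (g_epi == 0) & (rng.random(n) < epsilon)
        g_epi = np.where(lose, 1, g_epi)
    return g_marker, g_epi, g_ddm1


def _parent_arrays(n: int, marker_code: int, epi: tuple[str, str], ddm1: tuple[str, str], n_markers: int):
    marker = np.full((n, n_markers, 2), marker_code, dtype=np.int8)
    epi_arr = np.tile([0 if s == "m" else 1 for s in epi], (n, 1)).astype(np.int8)
    ddm1_arr = np.tile([0 if s == "D" else 1 for s in ddm1], (n, 1)).astype(np.int8)
    return marker, epi_arr, ddm1_arr


def _self(pop: CrossPopulation, rng: np.random.Generator, generation: str) -> CrossPopulation:
    positions, epi_idx, marker_idx = _loci(pop.config)
    eps = pop.config.epsilon
    g1 = _meiosis(pop.marker, pop.epi, pop.ddm1, positions, epi_idx, marker_idx, eps, rng)
    g2 = _meiosis(pop.marker, pop.epi, pop.ddm1, positions, epi_idx, marker_idx, eps, rng)
    marker = np.stack([g1[0], g2[0]], axis=2)
    epi = np.stack([g1[1], g2[1]], axis=1)
    ddm1 = np.stack([g1[2], g2[2]], axis=1)
    return CrossPopulation(marker, epi, ddm1, pop.config, generation)


def simulate_cross(config: CrossConfig, generation: str = "F2", n: int = 100) -> CrossPopulation:
    """Simulate F1/F2/F3 individuals of a biparental cross.

    Parents are homozygous lines; meioses are independent, crossovers follow
    Haldane's map function, and the epiallele state travels in cis (subject
    to ddm1 loss, see :class:`CrossConfig`).  F2 individuals come from
    selfing F1, F3 from selfing one F2 offspring per lineage.
    """
    if n <= 0:
        raise ValueError("population size must be positive")
    if generation not in ("F1", "F2", "F3"):
        raise ValueError("generation must be 'F1', 'F2' or 'F3'")
    rng = np.random.default_rng(config.seed)
    n_markers = len(config.marker_cm)
    positions, epi_idx, marker_idx = _loci(config)

    pa = _parent_arrays(n, 0, config.parent_a_epi, config.parent_a_ddm1, n_markers)
    pb = _parent_arrays(n, 1, config.parent_b_epi, config.parent_b_ddm1, n_markers)
    ga = _meiosis(*pa, positions, epi_idx, marker_idx, config.epsilon, rng)
    gb = _meiosis(*pb, positions, epi_idx, marker_idx, config.epsilon, rng)
    f1 = CrossPopulation(
        np.stack([ga[0], gb[0]], axis=2),
        np.stack([ga[1], gb[1]], axis=1),
        np.stack([ga[2], gb[2]], axis=1),
        config,
        "F1",
    )
    if generation == "F1":
        return f1
    f2 = _self(f1, rng, "F2")
    if generation == "F2":
        return f2
    return _self(f2, rng, "F3")


def simulate_selfing_series(
    config: CrossConfig,
    founder_epi: tuple[str, str] = ("m", "m"),
    founder_ddm1: tuple[str, str] = ("d", "d"),
    n_generations: int = 5,
    n: int = 100,
) -> list[CrossPopulation]:
    """Self a founder line for several generations, tracking epiallele states.

    Models inbreeding of a ddm1-mutant (or wild-type) line: with a
    ddm1-homozygous founder, each transmitted methylated allele is lost
    with probability epsilon per meiosis, and losses are irreversible, so
    the methylated-allele frequency decays geometrically.
    """
    rng = np.random.default_rng(config.seed)
    n_markers = len(config.marker_cm)
    marker, epi, ddm1 = _parent_arrays(n, 0, founder_epi, founder_ddm1, n_markers)
    pop = CrossPopulation(marker, epi, ddm1, config, "S0")
    series = [pop]
    for g in range(1, n_generations + 1):
        pop = _self(pop, rng, f"S{g}")
        series.append(pop)
    return series


def simulate_phenotypes(
    population: CrossPopulation,
    seed: int = 0,
    pph_base: float = 1.0,
    pph_repression: float = 0.35,
    chl_base: float = 0.30,
    chl_gain: float = 0.25,
    noise_sd: float = 0.08,
) -> pd.DataFrame:
    """Per-plant PPH expression and post-dark chlorophyll with a planted effect.

    Each methylated epiallele copy represses PPH expression additively by
    ``pph_repression`` and (because chlorophyll degradation slows) raises
    retained chlorophyll by ``chl_gain``; Gaussian measurement noise is
    added.  Mirrors a design where methylation of the element suppresses
    the downstream senescence gene.
    """
    rng = np.random.default_rng(seed)
    n_m = population.n_methylated_alleles
    n = len(population)
    expr = pph_base - pph_repression * n_m + rng.normal(0, noise_sd, n)
    chl = chl_base + chl_gain * n_m + rng.normal(0, noise_sd, n)
    frame = population.to_frame()
    frame["pph_expression"] = np.maximum(expr, 0.0)
    frame["chlorophyll"] = np.maximum(chl, 0.0)
    return frame


# ---------------------------------------------------------------------------
# Star-phylogeny sequence evolution


@dataclass
class EvolutionConfig:
    """Independent evolution of n tips from one ancestor for T years.

    The TN93 rate matrix is scaled so the expected substitution rate is
    ``rate`` per site per year; each tip then evolves along a branch of
    ``age_years`` (a star phylogeny).
    """

    ancestor: str | None = None
    length: int = 3000
    n_tips: int = 50
    age_years: float = 5e5
    rate: float = 6.8e-9
    params: TN93Params = field(
        default_factory=lambda: TN93Params((0.32, 0.18, 0.18, 0.32), 2.0, 2.0, 1.0)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rate < 0 or self.age_years < 0:
            raise ValueError("rate and age must be non-negative")
        if self.ancestor is not None and len(self.ancestor) == 0:
            raise ValueError("ancestor sequence must be non-empty")
        if self.ancestor is None and self.length <= 0:
            raise ValueError("length must be positive")


def evolve_star(config: EvolutionConfig) -> AlignedSet:
    """Evolve tips independently from the ancestor under TN93 (gap-free).

    The ancestor is drawn from the model's stationary distribution when not
    supplied; it is retained on the returned alignment as ground truth.
    """
    rng = np.random.default_rng(config.seed)
    pi = np.asarray(config.params.freqs)
    base_arr = np.frombuffer(BASES.encode(), np.uint8)
    if config.ancestor is None:
        anc_codes = rng.choice(4, size=config.length, p=pi)
        ancestor = base_arr[anc_codes].tobytes().decode()
    else:
        ancestor = config.ancestor.upper()
        lookup = {b: i for i, b in enumerate(BASES)}
        try:
            anc_codes = np.array([lookup[b] for b in ancestor], dtype=np.int64)
        except KeyError as exc:
            raise ValueError(f"ancestor contains non-ACGT base {exc}") from exc

    q = tn93_rate_matrix(config.params)
    branch = config.rate * config.age_years  # expected substitutions per site
    p = expm(q * branch)
    length = anc_codes.size
    tips = []
    for _ in range(config.n_tips):
        codes = np.empty(length, dtype=np.int64)
        for state in range(4):
            sites = anc_codes == state
            k = int(sites.sum())
            if k:
                codes[sites] = rng.choice(4, size=k, p=p[state])
        tips.append(base_arr[codes].tobytes().decode())
    names = [f"tip_{i + 1}" for i in range(config.n_tips)]
    return AlignedSet(names, tips, ancestor=ancestor)


# ---------------------------------------------------------------------------
# Accession / climate tables

#: Plausible present-day means and spreads for the 19 bioclim variables
#: (temperatures in deg C, precipitation in mm) used by the null generator.
BIOCLIM_BASELINES: dict[str, tuple[float, float]] = {
    "bio1": (9.0, 5.0), "bio2": (10.0, 2.0), "bio3": (35.0, 5.0),
    "bio4": (700.0, 150.0), "bio5": (25.0, 4.0), "bio6": (-5.0, 5.0),
    "bio7": (30.0, 5.0), "bio8": (12.0, 5.0), "bio9": (15.0, 4.0),
    "bio10": (18.0, 3.0), "bio11": (1.0, 4.0), "bio12": (700.0, 250.0),
    "bio13": (90.0, 30.0), "bio14": (30.0, 15.0), "bio15": (30.0, 10.0),
    "bio16": (250.0, 80.0), "bio17": (110.0, 50.0), "bio18": (180.0, 70.0),
    "bio19": (160.0, 70.0),
}


def simulate_climate_table(
    n_accessions: int = 137,
    group_proportions: tuple[float, float, float] = (21 / 137, 39 / 137, 77 / 137),
    bio9_effect: float = 8.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Accession table with methylation groups, phenotypes and bioclim values.

    Groups are (methylated, unmethylated, deletion) with the given expected
    proportions.  bio9 (mean temperature of the driest quarter) carries a
    planted monotone *decreasing* relation with total methylation of size
    ``bio9_effect`` (deg C shift at full methylation); all other bioclim
    variables are independent of methylation.  At the last-interglacial
    (LIG) epoch, deletion and unmethylated accessions sit at sites that
    have warmed since, while methylated accessions have not, and the
    planted bio9 effect is weaker than at present.  Methylation is 0 when
    the element is absent.
    """
    if abs(sum(group_proportions) - 1.0) > 1e-8:
        raise ValueError("group proportions must sum to 1")
    rng = np.random.default_rng(seed)
    groups = rng.choice(
        ["methylated", "unmethylated", "deletion"], size=n_accessions, p=group_proportions
    )
    is_m = groups == "methylated"
    is_u = groups == "unmethylated"
    is_d = groups == "deletion"

    def beta_around(mean: np.ndarray, conc: float = 30.0) -> np.ndarray:
        return rng.beta(np.maximum(mean * conc, 1e-6), np.maximum((1 - mean) * conc, 1e-6))

    meth_cg = np.where(is_m, beta_around(np.full(n_accessions, 0.85)),
                       np.where(is_u, beta_around(np.full(n_accessions, 0.03)), 0.0))
    meth_chg = np.where(is_m, beta_around(np.full(n_accessions, 0.65)),
                        np.where(is_u, beta_around(np.full(n_accessions, 0.02)), 0.0))
    meth_chh = np.where(is_m, beta_around(np.full(n_accessions, 0.10)),
                        np.where(is_u, beta_around(np.full(n_accessions, 0.02)), 0.0))
    meth_total = 0.4 * meth_cg + 0.3 * meth_chg + 0.3 * meth_chh

    pph = np.where(is_m, rng.normal(0.35, 0.15, n_accessions), rng.normal(1.0, 0.30, n_accessions))
    pph = np.maximum(pph, 0.01)
    chl = np.where(is_m, rng.normal(0.80, 0.10, n_accessions), rng.normal(0.35, 0.10, n_accessions))
    chl = np.maximum(chl, 0.01)

    table: dict[str, np.ndarray] = {
        "accession": np.array([f"acc{i + 1:03d}" for i in range(n_accessions)]),
        "group": groups,
        "presence_4": ~is_d,
        "presence_16": np.zeros(n_accessions, bool),
        "meth_total": meth_total,
        "meth_CG": meth_cg,
        "meth_CHG": meth_chg,
        "meth_CHH": meth_chh,
        "pph_expression": pph,
        "chlorophyll": chl,
        "latitude": rng.uniform(35.0, 62.0, n_accessions),
        "longitude": rng.uniform(-10.0, 40.0, n_accessions),
    }

    scale = np.clip(meth_total / 0.55, 0.0, 1.2)  # ~1 for a typical methylated accession
    for name, (mean, sd) in BIOCLIM_BASELINES.items():
        present = rng.normal(mean, sd, n_accessions)
        if name == "bio9":
            present = present - bio9_effect * scale
            # sites of deletion/unmethylated accessions have warmed since the
            # LIG; methylated ones have not, so the LIG effect is weaker
            warming = np.where(is_m, 0.0, 2.0)
            lig = present - warming + rng.normal(0, 0.8, n_accessions)
        else:
            lig = present + rng.normal(0, sd / 4, n_accessions)
        table[name] = present
        table[f"{name}_lig"] = lig
    return pd.DataFrame(table)
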