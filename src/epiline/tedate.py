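"""Molecular dating of a retrotransposon insertion from aligned element copies.

The age of an insertion shared by a set of accessions is estimated two ways:

* **star estimate** — assuming every copy diverged independently from the
  element that integrated, the mean pairwise distance ``d`` between copies
  accumulates at twice the substitution rate, so ``T_star = d / (2 r)``.
  Shared post-insertion ancestry between close accessions deflates ``d``,
  so this is treated as a lower bound.
* **MRCA estimate** — the ancestral sequence at the root is reconstructed by
  marginal maximum likelihood (Felsenstein pruning) under the Tamura–Nei
  (TN93) model, substitutions between each copy and the ancestor are
  counted, and ``T_mrca = d_anc / r``.  Reconstruction uncertainty tends to
  inflate this estimate, so it is treated as an upper bound.

The substitution rate ``r`` is calibrated from the divergence of orthologous
copies in two species whose split time is known: ``r = d_ortholog / (2 T_div)``.

Distances use the TN93 closed form, which separates purine transitions
(A<->G), pyrimidine transitions (C<->T) and transversions, with base
frequencies estimated empirically per pair.  Sites with a gap or N in either
sequence are excluded pair by pair.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from io import StringIO
from typing import Sequence

import numpy as np
from scipy.linalg import expm
from skbio import TreeNode

__all__ = [
    "AlignedSet",
    "TN93Params",
    "DatingResult",
    "tn93_rate_matrix",
    "tn93_distance",
    "mean_pairwise_distance",
    "nj_tree",
    "calibrate_rate",
    "star_age",
    "ancestral_sequence",
    "mrca_age",
    "date_insertion",
    "raw_distance",
]

_ALPHABET = "ACGT"
_INDEX = {b: i for i, b in enumerate(_ALPHABET)}


class SaturatedDistanceError(ValueError):
    """Raised when a TN93 log argument is non-positive (distance saturated)."""


@dataclass
class AlignedSet:
    """Gap-aware aligned nucleotide sequences of one TE family."""

    names: list[str]
    sequences: list[str]
    ancestor: str | None = None  # known truth when simulated

    def __post_init__(self) -> None:
        if len(self.sequences) < 2:
            raise ValueError("an alignment needs at least 2 sequences")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) != 1:
            raise ValueError("aligned sequences must have equal length")
        if len(self.names) != len(self.sequences):
            raise ValueError("names and sequences differ in number")

    @property
    def length(self) -> int:
        return len(self.sequences[0])

    def __len__(self) -> int:
        return len(self.sequences)

    def drop_all_gap_columns(self) -> "AlignedSet":
        """Return a copy without columns that are gap/N in every row."""
        arr = _encode_rows(self.sequences)
        keep = ~np.all(arr < 0, axis=0)
        seqs = ["".join(np.array(list(s))[keep]) for s in self.sequences]
        anc = None
        if self.ancestor is not None:
            anc = "".join(np.array(list(self.ancestor))[keep])
        return AlignedSet(list(self.names), seqs, anc)


@dataclass
class TN93Params:
    """Tamura–Nei model parameters.

    ``alpha1``/``alpha2``/``beta`` are relative rates of purine transitions,
    pyrimidine transitions and transversions; only their ratios matter
    because the rate matrix is rescaled to one expected substitution per
    site per unit branch length.
    """

    freqs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)  # A C G T
    alpha1: float = 1.0
    alpha2: float = 1.0
    beta: float = 1.0

    def __post_init__(self) -> None:
        f = np.asarray(self.freqs, float)
        if np.any(f <= 0) or abs(f.sum() - 1.0) > 1e-8:
            raise ValueError("base frequencies must be positive and sum to 1")
        if min(self.alpha1, self.alpha2, self.beta) < 0:
            raise ValueError("rates must be non-negative")


@dataclass
class DatingResult:
    rate: float
    mean_pairwise: float
    mean_to_ancestor: float
    t_star: float
    t_mrca: float
    t_div_used: float
    t_star_range: tuple[float, float] = (0.0, 0.0)  # over the T_div interval
    t_mrca_range: tuple[float, float] = (0.0, 0.0)
    notes: list[str] = field(default_factory=list)

    @property
    def age_range(self) -> tuple[float, float]:
        """Reported insertion-age interval [T_star, T_mrca] (lower, upper)."""
        return (self.t_star, self.t_mrca)


def tn93_rate_matrix(params: TN93Params) -> np.ndarray:
    """TN93 instantaneous rate matrix (A,C,G,T order), scaled to 1 sub/site.

    Off-diagonal rate to base j is pi_j times alpha1 (A<->G), alpha2 (C<->T)
    or beta (transversions).
    """
    pa, pc, pg, pt = params.freqs
    pi = np.array([pa, pc, pg, pt])
    q = np.empty((4, 4))
    for i in range(4):
        for j in range(4):
            if i == j:
                continue
            pair = {i, j}
            if pair == {0, 2}:  # A<->G
                rate = params.alpha1
            elif pair == {1, 3}:  # C<->T
                rate = params.alpha2
            else:
                rate = params.beta
            q[i, j] = rate * pi[j]
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    mu = -float(np.dot(pi, np.diag(q)))
    if mu <= 0:
        raise ValueError("degenerate rate matrix (all rates zero)")
    return q / mu


def _encode_rows(seqs: Sequence[str]) -> np.ndarray:
    """Encode sequences as int8: 0..3 for ACGT, -1 for gap/N/other."""
    out = np.full((len(seqs), len(seqs[0])), -1, dtype=np.int8)
    raw = np.frombuffer("".join(seqs).encode(), np.uint8).reshape(len(seqs), -1)
    for base, idx in _INDEX.items():
        out[raw == ord(base)] = idx
        out[raw == ord(base.lower())] = idx
    return out


def _pair_counts(a: str, b: str) -> tuple[int, int, int, int, np.ndarray]:
    """(n_sites, P1, P2, Q, pooled base counts) over gap-free sites."""
    enc = _encode_rows([a, b])
    ok = np.all(enc >= 0, axis=0)
    x, y = enc[0, ok], enc[1, ok]
    n = int(ok.sum())
    diff = x != y
    pur = ((x == 0) & (y == 2)) | ((x == 2) & (y == 0))
    pyr = ((x == 1) & (y == 3)) | ((x == 3) & (y == 1))
    p1 = int(pur.sum())
    p2 = int(pyr.sum())
    q = int(diff.sum()) - p1 - p2
    counts = np.bincount(np.concatenate([x, y]), minlength=4).astype(float)
    return n, p1, p2, q, counts


def tn93_distance(seq_a: str, seq_b: str) -> float:
    """Closed-form TN93 distance between two aligned sequences.

    Uses the pair's empirical base frequencies; sites with a gap or N in
    either sequence are excluded.  Raises :class:`SaturatedDistanceError`
    when a logarithm argument is non-positive (too-divergent pair).
    """
    n, np1, np2, nq, counts = _pair_counts(seq_a, seq_b)
    if n == 0:
        raise ValueError("no comparable (gap-free) sites")
    p1, p2, q = np1 / n, np2 / n, nq / n
    if p1 == 0 and p2 == 0 and q == 0:
        return 0.0
    fa, fc, fg, ft = counts / counts.sum()
    gr, gy = fa + fg, fc + ft
    if min(fa, fc, fg, ft) == 0:
        # fall back to uniform composition for degenerate pairs
        fa = fc = fg = ft = 0.25
        gr = gy = 0.5
    k1 = 2 * fa * fg / gr
    k2 = 2 * ft * fc / gy
    k3 = 2 * (gr * gy - fa * fg * gy / gr - ft * fc * gr / gy)
    w1 = 1 - p1 / k1 - q / (2 * gr)
    w2 = 1 - p2 / k2 - q / (2 * gy)
    w3 = 1 - q / (2 * gr * gy)
    if min(w1, w2, w3) <= 0:
        raise SaturatedDistanceError("TN93 distance undefined (saturated pair)")
    return -k1 * math.log(w1) - k2 * math.log(w2) - k3 * math.log(w3)


def raw_distance(seq_a: str, seq_b: str) -> float:
    """Raw mismatch proportion over gap-free sites (no multiple-hit correction)."""
    n, p1, p2, q, _ = _pair_counts(seq_a, seq_b)
    if n == 0:
        raise ValueError("no comparable (gap-free) sites")
    return (p1 + p2 + q) / n


def mean_pairwise_distance(aligned: AlignedSet, corrected: bool = True) -> float:
    """Mean pairwise distance over all sequence pairs.

    Saturated pairs (undefined TN93 distance) are excluded; raises if every
    pair is undefined.
    """
    dist = tn93_distance if corrected else raw_distance
    total, used = 0.0, 0
    for a, b in itertools.combinations(aligned.sequences, 2):
        try:
            total += dist(a, b)
        except SaturatedDistanceError:
            continue
        used += 1
    if used == 0:
        raise SaturatedDistanceError("all pairwise distances undefined")
    return total / used


# ---------------------------------------------------------------------------
# Neighbor joining


def nj_tree(distance_matrix: np.ndarray, names: Sequence[str]) -> str:
    """Saitou–Nei neighbor joining; returns a newick string.

    Negative branch-length estimates are clamped to zero and the deficit is
    transferred to the sister branch, preserving the pair's summed length.
    The root is the final unresolved trifurcation (unrooted tree).
    """
    d = np.asarray(distance_matrix, dtype=float).copy()
    n = d.shape[0]
    if d.shape != (n, n) or n != len(names):
        raise ValueError("distance matrix must be square and match names")
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    if not np.allclose(d, d.T) or not np.allclose(np.diag(d), 0):
        raise ValueError("distance matrix must be symmetric with zero diagonal")

    nodes = [f"{name}" for name in names]
    active = list(range(n))
    while len(active) > 2:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        qmat = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(qmat, np.inf)
        i_, j_ = np.unravel_index(np.argmin(qmat), qmat.shape)
        if i_ > j_:
            i_, j_ = j_, i_
        a, b = active[i_], active[j_]
        dij = sub[i_, j_]
        li = 0.5 * dij + (r[i_] - r[j_]) / (2 * (m - 2))
        lj = dij - li
        if li < 0:
            lj += -li  # transfer deficit to sister
            li = 0.0
        if lj < 0:
            li += -lj
            lj = 0.0
        new = f"({nodes[a]}:{li:.10g},{nodes[b]}:{lj:.10g})"
        # distances from the new node u to every other active node k
        others = [k for k in active if k not in (a, b)]
        du = {k: 0.5 * (d[a, k] + d[b, k] - dij) for k in others}
        nodes.append(new)
        d = np.pad(d, ((0, 1), (0, 1)))
        u = d.shape[0] - 1
        for k, val in du.items():
            d[u, k] = d[k, u] = max(val, 0.0)
        active = others + [u]

    # Final join: attach the last lineage to the remaining (composite) node,
    # yielding the conventional unrooted trifurcating NJ tree.
    a, b = active
    dab = max(d[a, b], 0.0)
    na, nb = nodes[a], nodes[b]
    if nb.startswith("("):
        return f"({nb[1:-1]},{na}:{dab:.10g});"
    if na.startswith("("):
        return f"({na[1:-1]},{nb}:{dab:.10g});"
    return f"({na}:{dab / 2:.10g},{nb}:{dab / 2:.10g});"


# ---------------------------------------------------------------------------
# Rate calibration and age estimators


def calibrate_rate(d_ortholog: float, t_div: float) -> float:
    """Substitution rate per site per year from ortholog divergence.

    Two lineages separated ``t_div`` years ago accumulate ``2 r t_div``
    substitutions per site between them, hence ``r = d / (2 t_div)``.
    """
    if t_div <= 0:
        raise ValueError("divergence time must be positive")
    if d_ortholog < 0:
        raise ValueError("divergence must be non-negative")
    return d_ortholog / (2.0 * t_div)


def star_age(aligned: AlignedSet, rate: float) -> float:
    """Insertion age assuming a star phylogeny: mean pairwise distance / (2r)."""
    if rate <= 0:
        raise ValueError("substitution rate must be positive")
    return mean_pairwise_distance(aligned, corrected=True) / (2.0 * rate)


def mean_ancestor_divergence(aligned: AlignedSet, ancestor: str, corrected: bool = False) -> float:
    """Mean per-site divergence of each sequence from the ancestor.

    Raw substitution proportion by default (substitution *counting*); a
    model-corrected variant is available.
    """
    if len(ancestor) != aligned.length:
        raise ValueError("ancestor length must match the alignment")
    dist = tn93_distance if corrected else raw_distance
    return float(np.mean([dist(s, ancestor) for s in aligned.sequences]))


def mrca_age(aligned: AlignedSet, ancestor: str, rate: float, corrected: bool = False) -> float:
    """Insertion age from the MRCA: mean tip-to-ancestor divergence / r."""
    if rate <= 0:
        raise ValueError("substitution rate must be positive")
    return mean_ancestor_divergence(aligned, ancestor, corrected=corrected) / rate


# ---------------------------------------------------------------------------
# Ancestral reconstruction


def estimate_tn93_params(aligned: AlignedSet) -> TN93Params:
    """Moment estimate of TN93 parameters from an alignment.

    Base frequencies are empirical over all non-gap characters; relative
    rates are derived from the pooled proportions of purine transitions,
    pyrimidine transitions and transversions across all pairs (each divided
    by the expected collision mass of its class).  At the low divergences
    this package targets, reconstruction is insensitive to the exact ratios.
    """
    enc = _encode_rows(aligned.sequences)
    counts = np.bincount(enc[enc >= 0].ravel(), minlength=4).astype(float)
    if counts.sum() == 0:
        raise ValueError("alignment contains no unambiguous bases")
    freqs = counts / counts.sum()
    freqs = np.maximum(freqs, 1e-6)  # keep the model proper when a base is absent
    freqs = freqs / freqs.sum()
    tp1 = tp2 = tq = tn = 0
    for a, b in itertools.combinations(aligned.sequences, 2):
        n, p1, p2, q, _ = _pair_counts(a, b)
        tp1, tp2, tq, tn = tp1 + p1, tp2 + p2, tq + q, tn + n
    fa, fc, fg, ft = freqs
    gr, gy = fa + fg, fc + ft
    # class collision masses under stationarity
    m1, m2, m3 = 2 * fa * fg, 2 * fc * ft, 2 * gr * gy
    a1 = (tp1 / tn) / m1 if tn and m1 > 0 else 1.0
    a2 = (tp2 / tn) / m2 if tn and m2 > 0 else 1.0
    b = (tq / tn) / m3 if tn and m3 > 0 else 1.0
    if max(a1, a2, b) == 0:
        a1 = a2 = b = 1.0
    scale = max(a1, a2, b)
    return TN93Params(tuple(freqs), a1 / scale or 1e-9, a2 / scale or 1e-9, b / scale or 1e-9)


def ancestral_sequence(
    aligned: AlignedSet,
    tree_newick: str,
    params: TN93Params | None = None,
) -> str:
    """Marginal ML root-state reconstruction under TN93 (pruning algorithm).

    Per-site posterior ties are broken by the higher stationary frequency,
    then alphabetically.  Sites that are gap/N in every sequence yield '-'.
    Leaf names in the tree must match the alignment names.
    """
    if params is None:
        params = estimate_tn93_params(aligned)
    q = tn93_rate_matrix(params)
    pi = np.asarray(params.freqs)
    tree = TreeNode.read(StringIO(tree_newick), convert_underscores=False)
    leaf_names = {t.name for t in tree.tips()}
    if leaf_names != set(aligned.names):
        raise ValueError("tree leaves do not match alignment names")

    enc = _encode_rows(aligned.sequences)
    length = aligned.length
    row = {name: i for i, name in enumerate(aligned.names)}

    partials: dict[int, np.ndarray] = {}
    pcache: dict[float, np.ndarray] = {}

    def pmat(bl: float) -> np.ndarray:
        bl = max(float(bl or 0.0), 0.0)
        if bl not in pcache:
            pcache[bl] = expm(q * bl)
        return pcache[bl]

    for node in tree.postorder():
        if node.is_tip():
            states = enc[row[node.name]]
            part = np.zeros((length, 4))
            known = states >= 0
            part[known, states[known]] = 1.0
            part[~known, :] = 1.0  # missing data
        else:
            part = np.ones((length, 4))
            for child in node.children:
                p = pmat(child.length)
                part *= partials.pop(id(child)) @ p.T
        partials[id(node)] = part

    root_part = partials[id(tree)]
    post = root_part * pi[None, :]
    all_gap = np.all(enc < 0, axis=0)
    # tie-break: higher stationary frequency, then alphabetical (A<C<G<T)
    order = np.lexsort((np.arange(4), -pi))  # preference order of states
    ranked = post[:, order]
    best = order[np.argmax(np.isclose(ranked, ranked.max(axis=1, keepdims=True)), axis=1)]
    chars = np.array(list(_ALPHABET))[best]
    chars[all_gap] = "-"
    return "".join(chars)


def date_insertion(
    aligned: AlignedSet,
    ortholog_pair: tuple[str, str],
    t_div_range: tuple[float, float] = (3.5e6, 5.8e6),
    corrected_calibration: bool = True,
) -> DatingResult:
    """Full two-estimator dating of an insertion.

    Calibrates the substitution rate from an aligned ortholog pair at the
    midpoint of ``t_div_range`` (endpoints reported as sensitivity), then
    computes the star-phylogeny lower estimate and the ancestral-sequence
    (MRCA) upper estimate, reconstructing the ancestor on the NJ tree of
    the alignment.
    """
    lo, hi = t_div_range
    if lo <= 0 or hi < lo:
        raise ValueError("invalid divergence-time range")
    t_div = 0.5 * (lo + hi)
    dist = tn93_distance if corrected_calibration else raw_distance
    d_orth = dist(*ortholog_pair)
    rate = calibrate_rate(d_orth, t_div)
    notes: list[str] = []

    d_bar = mean_pairwise_distance(aligned)
    if d_bar == 0.0:
        return DatingResult(rate, 0.0, 0.0, 0.0, 0.0, t_div, (0.0, 0.0), (0.0, 0.0), notes)

    t_star = d_bar / (2 * rate)

    n = len(aligned)
    dm = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        dm[i, j] = dm[j, i] = tn93_distance(aligned.sequences[i], aligned.sequences[j])
    newick = nj_tree(dm, aligned.names)
    ancestor = ancestral_sequence(aligned, newick)
    d_anc = mean_ancestor_divergence(aligned, ancestor)
    t_mrca = d_anc / rate

    if t_mrca < t_star:
        notes.append("T_mrca < T_star on these data (soft ordering violated)")

    def at(tdiv: float) -> float:
        return calibrate_rate(d_orth, tdiv)

    star_rng = tuple(sorted((d_bar / (2 * at(lo)), d_bar / (2 * at(hi)))))
    mrca_rng = tuple(sorted((d_anc / at(lo), d_anc / at(hi))))
    return DatingResult(rate, d_bar, d_anc, t_star, t_mrca, t_div, star_rng, mrca_rng, notes)
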