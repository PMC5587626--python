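"""Peak-list registration analysis: self and pairwise.

The algorithm maps peaks of an "input" list onto peaks of a "root" list by
looking for *concordant* peak-mapping pairs: a candidate mapping
``(i, j)`` (input peak ``i`` -> root peak ``j``) is supported by another
mapping ``(m, n)`` when the two lists' internal geometry agrees, i.e. for
every comparable dimension ``l``

    |(input_i[l] - input_m[l]) - (root_j[l] - root_n[l])| <= tol * std[l].

The set of such ``(m, n)`` is the support set ``SS_{i,j}``.  Each candidate
is scored by a robustness score: the sum over its supporters of the Jaccard
similarity between support sets, weighted by the chi-square probability of
the difference-of-differences statistic

    chi2(i,j,m,n) = sum_l (((in_i[l]-in_m[l]) - (root_j[l]-root_n[l]))
                           / (std[l] * std_factor))^2 .

The support list of the most robust candidate yields matched peak pairs,
from which per-dimension offsets and standard deviations are computed; the
procedure iterates with the refreshed stds until they stop changing.

Self-registration runs the same machinery with the list as both input and
root, excludes identical peak mappings (``i == j``, ``m == n``), and pins
the translation offsets at zero; the statistics it produces characterize
the within-spin-system positional scatter of a single peak list.

Internally the difference-of-differences criterion is recast as a
fixed-radius neighbor search: with ``v_{i,j}[l] = input_i[l] - root_j[l]``,
``(m, n)`` supports ``(i, j)`` iff ``|v_{i,j} - v_{m,n}| <= tol * std``
per dimension, so support sets are Chebyshev-ball neighborhoods among the
``n_input * n_root`` difference vectors (a k-d tree query).  The robustness
arg-max uses the exact upper bound ``robustness(i,j) <= sum of supporter
probabilities`` to skip hopeless candidates; results are identical to the
direct evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Literal, Mapping

import numpy as np
from scipy.spatial import cKDTree
from scipy.stats import chi2 as _chi2

from .peaklist import DimensionStats, PeakList

__all__ = [
    "RegistrationConfig",
    "RegistrationResult",
    "SupportMatrix",
    "RegistrationError",
    "InsufficientDataError",
    "distance_matrix",
    "chi_square_pair",
    "build_support_matrix",
    "robustness",
    "register",
    "default_initial_stds",
]

Mode = Literal["self", "pairwise"]


def _chi2_sf(stat: np.ndarray, df: int) -> np.ndarray:
    """Upper-tail chi-square probability; df = 2 has the closed form
    exp(-stat/2), worth special-casing on millions of support edges."""
    if df == 2:
        return np.exp(-0.5 * np.asarray(stat))
    return _chi2.sf(stat, df)

#: Floor applied to per-dimension stds so the chi-square statistic stays
#: finite on duplicate-rich (e.g. 0-variance simulated) peak lists.
MIN_STD = 1e-6


class RegistrationError(RuntimeError):
    """No concordant peak mapping found (robustness zero everywhere), or the
    support of the best mapping is too small to derive statistics."""


class InsufficientDataError(ValueError):
    """Operation requires more peaks than the list provides."""


def default_initial_stds(pl: PeakList) -> tuple[float, ...]:
    """First-iteration std guesses, before any statistics exist: 0.02 ppm for
    proton dimensions, 0.2 ppm for carbon/nitrogen dimensions (typical match
    tolerances in assignment practice), keyed off the dimension labels."""
    out = []
    for d in pl.comparable_dims:
        label = pl.dim_labels[d].upper()
        out.append(0.02 if label.startswith("H") else 0.2)
    return tuple(out)


@dataclass
class RegistrationConfig:
    """Tunable parameters of the registration analysis.

    ``tolerance_units`` is the support match tolerance in standard-deviation
    units (default four).  ``std_factor`` scales the std in the chi-square
    denominator; 2 is the default, sqrt(2) is the linear-error-propagation
    alternative.  ``initial_stds`` (ppm, per comparable dimension) seeds the
    first iteration; when omitted they are derived from the dimension labels
    by :func:`default_initial_stds`.
    """

    tolerance_units: float = 4.0
    std_factor: float = 2.0
    initial_stds: tuple[float, ...] | None = None
    convergence_tol: float = 1e-3
    max_iterations: int = 20
    std_estimator: str = "mad"

    def __post_init__(self) -> None:
        if self.tolerance_units <= 0 or self.std_factor <= 0:
            raise ValueError("tolerance_units and std_factor must be positive")
        if self.std_estimator not in ("mad", "rms"):
            raise ValueError("std_estimator must be 'mad' or 'rms'")
        if self.convergence_tol <= 0 or self.max_iterations < 1:
            raise ValueError("convergence_tol and max_iterations must be positive")
        if self.initial_stds is not None:
            self.initial_stds = tuple(float(s) for s in self.initial_stds)
            if any(s <= 0 for s in self.initial_stds):
                raise ValueError("initial_stds must be positive")


@dataclass
class SupportMatrix:
    """Sparse support matrix: ``(i, j) -> SS_{i,j}`` (only non-empty sets
    are stored)."""

    n_input: int
    n_root: int
    mode: Mode
    entries: dict[tuple[int, int], frozenset[tuple[int, int]]] = field(default_factory=dict)

    def support(self, i: int, j: int) -> frozenset[tuple[int, int]]:
        return self.entries.get((i, j), frozenset())


@dataclass
class RegistrationResult:
    mode: Mode
    stats: DimensionStats
    best_pair: tuple[int, int]
    mapped_pairs: list[tuple[int, int]]
    robustness_best: float
    trace: list[tuple[float, ...]]
    converged: bool
    low_confidence: bool

    def __post_init__(self) -> None:
        if self.robustness_best < 0:
            raise ValueError("robustness must be >= 0")


# ---------------------------------------------------------------------------
# Elementary operations


def distance_matrix(pl: PeakList) -> np.ndarray:
    """Euclidean distance between every pair of peaks over the comparable
    dimensions (symmetric, zero diagonal)."""
    if len(pl) < 2:
        raise InsufficientDataError("distance matrix needs at least 2 peaks")
    coords = np.array([pl.comparable_shifts(i) for i in range(len(pl))])
    diff = coords[:, None, :] - coords[None, :, :]
    return np.sqrt((diff**2).sum(axis=2))


def _check_stds(stds, df: int) -> np.ndarray:
    stds = np.asarray(stds, dtype=float)
    if stds.shape != (df,):
        raise ValueError(f"expected {df} per-dimension stds, got shape {stds.shape}")
    if np.any(stds <= 0):
        raise ValueError(
            "per-dimension stds must be positive; floor near-zero estimates at "
            f"{MIN_STD} ppm before use"
        )
    return stds


def chi_square_pair(
    input_pl: PeakList,
    root_pl: PeakList,
    i: int,
    j: int,
    m: int,
    n: int,
    stds,
    std_factor: float = 2.0,
) -> tuple[float, float]:
    """Difference-of-differences chi-square statistic and its upper-tail
    probability for the mapping pair ((i, j), (m, n)).

    The statistic sums, over the ``df`` comparable dimensions, the squared
    difference between the input-side peak difference ``in_i - in_m`` and
    the root-side difference ``root_j - root_n``, scaled by
    ``std * std_factor``; the probability is the chi-square survival
    function at ``df`` degrees of freedom (concordant pairs score near 1).
    """
    df = input_pl.df
    stds = _check_stds(stds, df)
    a = np.array(input_pl.comparable_shifts(i)) - np.array(input_pl.comparable_shifts(m))
    b = np.array(root_pl.comparable_shifts(j)) - np.array(root_pl.comparable_shifts(n))
    stat = float(np.sum(((a - b) / (stds * std_factor)) ** 2))
    return stat, float(_chi2.sf(stat, df))


def robustness(
    sm: SupportMatrix,
    i: int,
    j: int,
    chi_probs: Callable[[int, int], float] | Mapping[tuple[int, int], float],
) -> float:
    """Robustness score of candidate mapping (i, j): the sum over its
    supporters (m, n) of ``Jaccard(SS_{i,j}, SS_{m,n})`` times the
    chi-square probability of (i, j, m, n).  Empty support scores 0."""
    ss = sm.support(i, j)
    if not ss:
        return 0.0
    prob = chi_probs if callable(chi_probs) else lambda m, n: chi_probs[(m, n)]
    total = 0.0
    for m, n in ss:
        other = sm.support(m, n)
        inter = len(ss & other)
        union = len(ss | other)
        total += (inter / union) * prob(m, n)
    return total


# ---------------------------------------------------------------------------
# Difference-vector machinery


def _comparable_coords(pl: PeakList) -> np.ndarray:
    return np.array([pl.comparable_shifts(i) for i in range(len(pl))], dtype=float)


def _difference_points(
    input_pl: PeakList, root_pl: PeakList, mode: Mode
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """All candidate mappings as difference vectors v_{i,j} = in_i - root_j.

    Returns (i_idx, j_idx, V); in self mode the diagonal (i == j) is
    excluded, which simultaneously removes identical peak mappings from
    every support set.
    """
    a = _comparable_coords(input_pl)
    b = _comparable_coords(root_pl)
    ni, nr = len(a), len(b)
    ii, jj = np.meshgrid(np.arange(ni), np.arange(nr), indexing="ij")
    ii, jj = ii.ravel(), jj.ravel()
    if mode == "self":
        keep = ii != jj
        ii, jj = ii[keep], jj[keep]
    v = a[ii] - b[jj]
    return ii, jj, v


def _support_edges(v: np.ndarray, tol_box: np.ndarray) -> np.ndarray:
    """Undirected edges (p, q) between difference vectors that lie within the
    per-dimension tolerance box of one another."""
    scaled = v / tol_box
    tree = cKDTree(scaled)
    pairs = tree.query_pairs(r=1.0, p=np.inf, output_type="ndarray")
    return pairs


def build_support_matrix(
    input_pl: PeakList,
    root_pl: PeakList,
    stds,
    cfg: RegistrationConfig | None = None,
    mode: Mode = "pairwise",
) -> SupportMatrix:
    """Materialize the support matrix at the given per-dimension stds.

    ``(m, n)`` belongs to ``SS_{i,j}`` iff the difference-of-differences is
    within ``tolerance_units * std`` in every comparable dimension; in self
    mode candidates and supporters on the identity (``i == j`` or
    ``m == n``) are excluded, as is ``(m, n) == (i, j)`` always.
    """
    cfg = cfg or RegistrationConfig()
    df = input_pl.df
    if root_pl.df != df:
        raise ValueError("input and root lists must share comparable dimensionality")
    stds = _check_stds(stds, df)
    ii, jj, v = _difference_points(input_pl, root_pl, mode)
    entries: dict[tuple[int, int], set[tuple[int, int]]] = {}
    if len(v):
        edges = _support_edges(v, cfg.tolerance_units * stds)
        for p, q in edges:
            cp = (int(ii[p]), int(jj[p]))
            cq = (int(ii[q]), int(jj[q]))
            entries.setdefault(cp, set()).add(cq)
            entries.setdefault(cq, set()).add(cp)
    return SupportMatrix(
        n_input=len(input_pl),
        n_root=len(root_pl),
        mode=mode,
        entries={k: frozenset(s) for k, s in entries.items()},
    )


# ---------------------------------------------------------------------------
# The iterative registration loop


def _csr_adjacency(n_points: int, edges: np.ndarray, probs: np.ndarray):
    """Directed CSR adjacency (both directions of each undirected edge),
    neighbor lists sorted by target index."""
    src = np.concatenate([edges[:, 0], edges[:, 1]])
    dst = np.concatenate([edges[:, 1], edges[:, 0]])
    pr = np.concatenate([probs, probs])
    order = np.lexsort((dst, src))
    src, dst, pr = src[order], dst[order], pr[order]
    counts = np.bincount(src, minlength=n_points)
    indptr = np.concatenate([[0], np.cumsum(counts)])
    return indptr, dst, pr


def _best_candidate(
    n_points: int,
    edges: np.ndarray,
    probs: np.ndarray,
    ii: np.ndarray,
    jj: np.ndarray,
) -> tuple[int, float] | None:
    """Arg-max of the robustness score over all candidate mappings.

    Uses the bound ``robustness(P) <= sum of incident edge probabilities``
    (Jaccard <= 1) to evaluate candidates in descending bound order and stop
    once no remaining bound can beat the best exact score.  Ties are broken
    by larger support size, then lexicographically smallest (i, j).
    """
    if len(edges) == 0:
        return None
    indptr, dst, pr = _csr_adjacency(n_points, edges, probs)
    degree = np.diff(indptr)
    bound = np.bincount(edges[:, 0], weights=probs, minlength=n_points) + np.bincount(
        edges[:, 1], weights=probs, minlength=n_points
    )
    order = np.argsort(-bound, kind="stable")

    best_p, best_rob, best_deg = -1, 0.0, 0
    for p in order:
        if bound[p] < best_rob - 1e-12 or bound[p] <= 0:
            break
        rob = _exact_robustness(int(p), indptr, dst, pr, degree)
        better = rob > best_rob + 1e-12
        if not better and abs(rob - best_rob) <= 1e-12 and best_p >= 0:
            if degree[p] > best_deg or (
                degree[p] == best_deg
                and (ii[p], jj[p]) < (ii[best_p], jj[best_p])
            ):
                better = True
        if better or best_p < 0:
            best_p, best_rob, best_deg = int(p), rob, int(degree[p])
    if best_rob <= 0:
        return None
    return best_p, best_rob


def _exact_robustness(
    p: int, indptr: np.ndarray, dst: np.ndarray, pr: np.ndarray, degree: np.ndarray
) -> float:
    """Exact robustness of candidate ``p`` from the CSR support graph,
    computed with one vectorized pass over the neighbors-of-neighbors."""
    nbrs = dst[indptr[p] : indptr[p + 1]]  # sorted
    probs = pr[indptr[p] : indptr[p + 1]]
    if len(nbrs) == 0:
        return 0.0
    starts, ends = indptr[nbrs], indptr[nbrs + 1]
    sizes = ends - starts
    # concatenated neighbor lists of all supporters q, tagged by supporter
    flat = np.concatenate([dst[s:e] for s, e in zip(starts, ends)])
    seg = np.repeat(np.arange(len(nbrs)), sizes)
    pos = np.searchsorted(nbrs, flat)
    pos[pos == len(nbrs)] = len(nbrs) - 1
    hit = nbrs[pos] == flat
    inter = np.bincount(seg, weights=hit, minlength=len(nbrs))
    union = len(nbrs) + degree[nbrs] - inter
    return float(((inter / union) * probs).sum())


#: MAD-to-sigma factor for a normal distribution (1 / Phi^-1(3/4)).
_MAD_SCALE = 1.482602218505602


def _scale_estimate(d: np.ndarray, estimator: str) -> np.ndarray:
    """Per-column scale of (already centered) matched-pair differences.

    ``"mad"`` (default) is the normal-consistent median absolute deviation,
    robust to the larger-variance peak population that later pipeline tiers
    are meant to capture: a plain standard deviation over the matched pairs
    absorbs that contamination and inflates the tolerances of the current
    tier.  ``"rms"`` is the plain standard-deviation estimate.
    """
    if estimator == "mad":
        return _MAD_SCALE * np.median(np.abs(d), axis=0)
    return np.sqrt((d**2).mean(axis=0))


def _one_to_one(
    candidates: list[tuple[float, int, int]], mode: Mode
) -> list[tuple[int, int]]:
    """Greedy one-to-one resolution of mapped pairs by descending chi-square
    probability (then lexicographic order, for determinism)."""
    candidates = sorted(candidates, key=lambda t: (-t[0], t[1], t[2]))
    used_in: set[int] = set()
    used_root: set[int] = set()
    accepted = []
    for _, m, n in candidates:
        if mode == "self":
            if m in used_in or n in used_in:
                continue
            used_in.update((m, n))
        else:
            if m in used_in or n in used_root:
                continue
            used_in.add(m)
            used_root.add(n)
        accepted.append((m, n))
    return accepted


def register(
    input_pl: PeakList,
    root_pl: PeakList | None = None,
    cfg: RegistrationConfig | None = None,
    mode: Mode = "pairwise",
) -> RegistrationResult:
    """Run the iterative registration analysis (see module docstring).

    In ``"self"`` mode ``root_pl`` may be omitted (the input list plays both
    roles); offsets are pinned at zero and the reported per-dimension stds
    estimate the *per-peak* positional scatter: matched within-list pairs
    are canonicalized to ``m < n``, their coordinate differences pooled
    about zero, and the RMS divided by sqrt(2) (a difference of two
    sigma-noised coordinates has std sqrt(2)*sigma).

    Raises :class:`RegistrationError` when no concordant mapping exists or
    when fewer than two matched pairs survive (no statistics derivable).
    """
    cfg = cfg or RegistrationConfig()
    if mode == "self":
        if root_pl is not None and root_pl is not input_pl:
            raise ValueError("self mode registers a peak list against itself")
        root_pl = input_pl
    elif root_pl is None:
        raise ValueError("pairwise mode needs a root peak list")
    if len(input_pl) < 2 or len(root_pl) < 2:
        raise InsufficientDataError("registration needs at least 2 peaks per list")
    df = input_pl.df
    if root_pl.df != df:
        raise ValueError("input and root lists must share comparable dimensionality")

    stds = np.asarray(
        cfg.initial_stds if cfg.initial_stds is not None else default_initial_stds(input_pl),
        dtype=float,
    )
    stds = np.maximum(_check_stds(stds, df), MIN_STD)

    ii, jj, v = _difference_points(input_pl, root_pl, mode)
    in_coords = _comparable_coords(input_pl)

    trace: list[tuple[float, ...]] = []
    converged = False
    last: tuple | None = None
    for _it in range(cfg.max_iterations):
        edges = _support_edges(v, cfg.tolerance_units * stds)
        if len(edges):
            dv = v[edges[:, 0]] - v[edges[:, 1]]
            stat = ((dv / (cfg.std_factor * stds)) ** 2).sum(axis=1)
            probs = _chi2_sf(stat, df)
        else:
            probs = np.empty(0)
        found = _best_candidate(len(v), edges, probs, ii, jj)
        if found is None:
            raise RegistrationError(
                "registration failed: no candidate mapping has support "
                f"(iteration {_it + 1}, stds={tuple(stds)})"
            )
        best_p, best_rob = found
        nbr_slice = np.nonzero((edges[:, 0] == best_p) | (edges[:, 1] == best_p))[0]
        cand = [(1.0, int(ii[best_p]), int(jj[best_p]))]
        for e in nbr_slice:
            q = int(edges[e, 1] if edges[e, 0] == best_p else edges[e, 0])
            m, n = int(ii[q]), int(jj[q])
            if mode == "self" and m > n:
                m, n = n, m
            cand.append((float(probs[e]), m, n))
        if mode == "self":
            bi, bj = cand[0][1], cand[0][2]
            if bi > bj:
                cand[0] = (1.0, bj, bi)
            # both orders of one unordered pair may appear; keep the best
            dedup: dict[tuple[int, int], float] = {}
            for prob, m, n in cand:
                dedup[(m, n)] = max(dedup.get((m, n), 0.0), prob)
            cand = [(prob, m, n) for (m, n), prob in dedup.items()]
        mapped = _one_to_one(cand, mode)
        if len(mapped) < 2:
            raise RegistrationError(
                f"registration failed: only {len(mapped)} matched pair(s); "
                "cannot derive per-dimension statistics"
            )
        m_idx = np.array([m for m, _ in mapped])
        n_idx = np.array([n for _, n in mapped])
        root_coords = in_coords if mode == "self" else _comparable_coords(root_pl)
        d = root_coords[n_idx] - in_coords[m_idx]  # translation input -> root
        if mode == "self":
            offsets = np.zeros(df)
            new_stds = _scale_estimate(d, cfg.std_estimator) / np.sqrt(2.0)
        else:
            offsets = d.mean(axis=0)
            new_stds = _scale_estimate(d - offsets, cfg.std_estimator)
        new_stds = np.maximum(new_stds, MIN_STD)
        trace.append(tuple(float(s) for s in new_stds))
        last = (best_p, best_rob, mapped, offsets)
        rel = np.abs(new_stds - stds) / np.maximum(stds, MIN_STD)
        stds = new_stds
        if float(rel.max()) < cfg.convergence_tol:
            converged = True
            break

    best_p, best_rob, mapped, offsets = last
    stats = DimensionStats(
        offsets=tuple(float(o) for o in offsets),
        stds=tuple(float(s) for s in stds),
        n_matched=len(mapped),
        iterations=len(trace),
    )
    return RegistrationResult(
        mode=mode,
        stats=stats,
        best_pair=(int(ii[best_p]), int(jj[best_p])),
        mapped_pairs=mapped,
        robustness_best=float(best_rob),
        trace=trace,
        converged=converged,
        low_confidence=len(mapped) < 3,
    )
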