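"""Evolutionary optimization of the expected -> measured peak mapping.

The assignment unknown is which measured HMQC peak carries the resonances
of each methyl group.  Once a methyl is anchored to an HMQC peak its 1H
and 13C shifts are fixed, and every expected NOESY/geminal peak involving
two anchored methyls maps to the best-matching measured peak inside the
tolerance box (several expected peaks may share one measured peak; genuine
shift degeneracy is discouraged by a penalty, not forbidden).

The score of a state is

    sum over mapped expected peaks of p * prod_dims exp(-delta^2 / 2 sigma^2)
    - lambda_degen * #(same-nucleus atom pairs closer than the tolerance)

with sigma the nucleus tolerance and delta the deviation of the measured
coordinate from the atom's state shift.  Mapping an expected peak can only
add non-negative alignment mass, unmapped expected peaks simply forfeit
their probability; higher scores are better.

Because atom shifts coincide with measured HMQC coordinates, the best match
for an expected peak between methyls (a, b) depends only on the pair of
HMQC peaks they are anchored to.  Those best matches are precomputed into
per-list lookup tables, making score deltas O(degree) and the local search
cheap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .expected import EXPERIMENTS, ExpectedPeak
from .geometry import MethylGroup
from .peaklists import PeakList
from .prep import ResidueTyping, Tolerances, UNTYPED_KEY, _hmqc_hc

__all__ = [
    "OptimizerConfig",
    "AssignmentProblem",
    "AssignmentState",
    "RunResult",
    "compile_problem",
    "score_state",
    "local_optimize",
    "evolve",
    "derive_run_shifts",
    "brute_force_assign",
]

_EPS = 1e-12


@dataclass
class OptimizerConfig:
    """Evolutionary-optimizer parameters.

    ``local_iterations`` is the iteration count of each local-optimization
    call (one per offspring per generation).  ``runs_per_cutoff``
    independent runs are performed per distance cutoff, run i using seed
    ``seed + i``.
    """

    population: int = 200
    local_iterations: int = 15_000
    runs_per_cutoff: int = 100
    seed: int = 0
    tolerances: Tolerances = field(default_factory=Tolerances)
    generations: int = 40
    stagnation: int = 10
    mutation_rate: float = 0.05
    unassign_rate: float = 0.1
    swap_prob: float = 0.25
    lambda_degen: float = 0.5
    offspring: int | None = None

    def __post_init__(self):
        for name in ("population", "local_iterations", "runs_per_cutoff",
                     "generations", "stagnation"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def n_offspring(self) -> int:
        return self.offspring or max(2, self.population // 3)


@dataclass
class AssignmentState:
    """A candidate solution: per-methyl HMQC peak index (-1 = unassigned)."""

    anchors: np.ndarray
    score: float = np.nan

    def copy(self) -> "AssignmentState":
        return AssignmentState(anchors=self.anchors.copy(), score=self.score)


@dataclass
class RunResult:
    """Per-atom shifts and NOE support from one optimization run."""

    methyl_ids: list[str]
    shift_c: np.ndarray
    shift_h: np.ndarray
    noe_count: np.ndarray
    anchors: np.ndarray
    mapped_noe_peaks: frozenset[int]
    score: float
    n_measured_noe: int


def _side_dims(exp_name: str, dims: int, dim_nuclei=()):
    """Per-side (H dim, C dim) indices for a list of a given experiment."""
    exp = EXPERIMENTS.get(exp_name.split("_")[0]) if exp_name else None
    if exp is None:
        if dims == 4:
            exp = EXPERIMENTS["CCNOESY"]
        elif dims == 3 and tuple(dim_nuclei[:1]) == ("C",):
            exp = EXPERIMENTS["CCNOESY3D"]
        elif dims == 3:
            exp = EXPERIMENTS["C13NOESY"]
        elif dims == 2:
            exp = EXPERIMENTS["C13HSQC"]
        else:
            raise ValueError(f"cannot infer experiment for a {dims}D list")
    sides: list[list[int | None]] = [[None, None], [None, None]]
    for k, (nucleus, side) in enumerate(exp.dims):
        sides[side][0 if nucleus == "H" else 1] = k
    return tuple((h, c) for h, c in sides)


class AssignmentProblem:
    """Compiled arrays for one (dataset, cutoff) assignment instance."""

    def __init__(
        self,
        methyls: list[MethylGroup],
        hmqc: PeakList,
        typing: ResidueTyping,
        tolerances: Tolerances,
        lambda_degen: float,
    ):
        self.methyls = methyls
        self.tolerances = tolerances
        self.lambda_degen = lambda_degen
        self.n = len(methyls)
        self.methyl_index = {g.id: i for i, g in enumerate(methyls)}

        self.hmqc_peaks = sorted(hmqc.peaks, key=lambda p: p.id)
        if not self.hmqc_peaks:
            raise ValueError("empty measured HMQC list")
        pos = _hmqc_hc(hmqc.copy_with(self.hmqc_peaks))
        self.Hq = pos[:, 0].copy()
        self.Cq = pos[:, 1].copy()
        self.nq = len(self.hmqc_peaks)

        self.compat = np.zeros((self.n, self.nq), dtype=bool)
        for q, p in enumerate(self.hmqc_peaks):
            labels = typing.of(p.id)
            for i, g in enumerate(methyls):
                self.compat[i, q] = g.res_type in labels

        # Degeneracy penalty: lambda per same-nucleus atom pair whose state
        # shifts differ by less than the tolerance, counted for methyl pairs
        # that are degenerate as resonances (both nuclei coincide, hence 2
        # atom pairs).  Near-degeneracy in a single nucleus is a property of
        # the measured data, not of the assignment, and is not penalized —
        # otherwise discarding assignments would outscore making them.
        lam = lambda_degen
        dH = np.abs(self.Hq[:, None] - self.Hq[None, :]) < tolerances.tol_h
        dC = np.abs(self.Cq[:, None] - self.Cq[None, :]) < tolerances.tol_c
        self.pen = 2.0 * lam * (dH & dC).astype(float)

        # filled by _finalize
        self.exp_a = np.zeros(0, dtype=np.int64)
        self.exp_b = np.zeros(0, dtype=np.int64)
        self.exp_p = np.zeros(0)
        self.exp_g = np.zeros(0, dtype=np.int64)
        self.exp_is_noe = np.zeros(0, dtype=bool)
        self.M = np.zeros((0, self.nq, self.nq))
        self.Marg = np.zeros((0, self.nq, self.nq), dtype=np.int64)
        self.out_idx: list[np.ndarray] = []
        self.in_idx: list[np.ndarray] = []
        self.measured_peaks: list[tuple[PeakList, int]] = []
        self.n_measured_noe = 0

    # -- compilation ----------------------------------------------------

    def _list_table(self, plist: PeakList, global_ids: list[int]):
        """Best-match lookup A[q1, q2] and argmax table for one list."""
        sigH, sigC = self.tolerances.tol_h, self.tolerances.tol_c
        (h0, c0), (h1, c1) = _side_dims(
            plist.experiment or plist.name, plist.dims, plist.dim_nuclei
        )
        A = np.zeros((self.nq, self.nq))
        Arg = np.full((self.nq, self.nq), -1, dtype=np.int64)
        for gid, m in zip(global_ids, plist.peaks):
            g0 = np.ones(self.nq)
            g1 = np.ones(self.nq)
            for g, hdim, cdim in ((g0, h0, c0), (g1, h1, c1)):
                if hdim is not None:
                    d = self.Hq - m.position[hdim]
                    g *= np.exp(-(d ** 2) / (2 * sigH ** 2)) * (np.abs(d) <= sigH)
                if cdim is not None:
                    d = self.Cq - m.position[cdim]
                    g *= np.exp(-(d ** 2) / (2 * sigC ** 2)) * (np.abs(d) <= sigC)
            contrib = np.outer(g0, g1)
            better = contrib > A
            A[better] = contrib[better]
            Arg[better] = gid
        return A, Arg


def compile_problem(
    methyls: list[MethylGroup],
    expected_noesy: list[ExpectedPeak],
    hmqc: PeakList,
    noesy_lists: dict[tuple[str, str], PeakList],
    typing: ResidueTyping,
    tolerances: Tolerances = Tolerances(),
    expected_geminal: list[ExpectedPeak] | None = None,
    geminal_list: PeakList | None = None,
    lambda_degen: float = 0.5,
) -> AssignmentProblem:
    """Build the lookup tables for one assignment instance.

    ``noesy_lists`` is keyed by unordered type-pair label strings as
    produced by :func:`methylassign.prep.attribute_noesy_types`; the
    catch-all key ``('?', '?')`` is matched against every expected peak.
    """
    prob = AssignmentProblem(methyls, hmqc, typing, tolerances, lambda_degen)

    tables: list[tuple[np.ndarray, np.ndarray]] = []
    list_keys: list[tuple[str, str]] = []
    gid = 0
    for key, plist in noesy_lists.items():
        ids = list(range(gid, gid + len(plist.peaks)))
        gid += len(plist.peaks)
        for local in range(len(plist.peaks)):
            prob.measured_peaks.append((plist, local))
        tables.append(prob._list_table(plist, ids))
        list_keys.append(key)
    prob.n_measured_noe = gid
    gem_table = None
    if geminal_list is not None and len(geminal_list):
        ids = list(range(gid, gid + len(geminal_list.peaks)))
        gid += len(geminal_list.peaks)
        for local in range(len(geminal_list.peaks)):
            prob.measured_peaks.append((geminal_list, local))
        gem_table = prob._list_table(geminal_list, ids)

    def covers(label: str, letter: str) -> bool:
        return label == "?" or letter in label

    # group expected peaks by their candidate measured-list sets
    groups: dict[frozenset[int], int] = {}
    g_members: list[list[int]] = []
    exp_a, exp_b, exp_p, exp_g, exp_is_noe = [], [], [], [], []

    def add_expected(e: ExpectedPeak, lists: frozenset[int], is_noe: bool):
        if not lists:
            return
        if lists not in groups:
            groups[lists] = len(g_members)
            g_members.append(sorted(lists))
        exp_a.append(prob.methyl_index[e.methyl_pair[0]])
        exp_b.append(prob.methyl_index[e.methyl_pair[1]])
        exp_p.append(e.probability)
        exp_g.append(groups[lists])
        exp_is_noe.append(is_noe)

    for e in expected_noesy:
        ta, tb = e.type_pair
        cand = set()
        for li, key in enumerate(list_keys):
            s0, s1 = key
            if key == UNTYPED_KEY or (covers(s0, ta) and covers(s1, tb)) or (
                covers(s0, tb) and covers(s1, ta)
            ):
                cand.add(li)
        add_expected(e, frozenset(cand), True)

    n_noesy_groups = len(g_members)
    if expected_geminal and gem_table is not None:
        gem_group = frozenset({-1})  # sentinel: the geminal table
        for e in expected_geminal:
            add_expected(e, gem_group, False)

    G = len(g_members)
    all_lists = list(noesy_lists.values())
    prob.group_lists = [
        [geminal_list] if members == [-1] else [all_lists[li] for li in members]
        for members in g_members
    ]
    prob.M = np.zeros((G, prob.nq, prob.nq))
    prob.Marg = np.full((G, prob.nq, prob.nq), -1, dtype=np.int64)
    for gi, members in enumerate(g_members):
        if members == [-1]:
            prob.M[gi], prob.Marg[gi] = gem_table
            continue
        for li in members:
            A, Arg = tables[li]
            better = A > prob.M[gi]
            prob.M[gi][better] = A[better]
            prob.Marg[gi][better] = Arg[better]

    prob.exp_a = np.array(exp_a, dtype=np.int64)
    prob.exp_b = np.array(exp_b, dtype=np.int64)
    prob.exp_p = np.array(exp_p)
    prob.exp_g = np.array(exp_g, dtype=np.int64)
    prob.exp_is_noe = np.array(exp_is_noe, dtype=bool)
    prob.out_idx = [
        np.flatnonzero((prob.exp_a == i) & (prob.exp_b != i)) for i in range(prob.n)
    ]
    prob.in_idx = [
        np.flatnonzero((prob.exp_b == i) & (prob.exp_a != i)) for i in range(prob.n)
    ]
    prob.diag_idx = [
        np.flatnonzero((prob.exp_a == i) & (prob.exp_b == i)) for i in range(prob.n)
    ]

    # geminal methyl index pairs and the anchor pairs compatible with the
    # measured geminal list — used for joint two-anchor proposal moves
    pairs = []
    for i, g in enumerate(methyls):
        if g.geminal_partner and g.id < g.geminal_partner:
            pairs.append((i, prob.methyl_index[g.geminal_partner]))
    prob.gem_pairs = pairs
    prob.gem_anchor_pairs = np.zeros((0, 2), dtype=np.int64)
    gem_key = frozenset({-1})
    if gem_key in groups:
        gtab = prob.M[groups[gem_key]]
        prob.gem_anchor_pairs = np.argwhere(gtab > 0.2)

    # recombination blocks: a geminal pair travels as one unit
    block = np.arange(prob.n)
    for i, j in pairs:
        block[j] = block[i]
    prob.blocks = block

    # per-group anchor pairs strongly supported by some measured peak,
    # used for data-driven joint moves on expected-peak endpoints
    pair_rows: list[np.ndarray] = []
    off = [0]
    for gi in range(G):
        rows = np.argwhere(prob.M[gi] > 0.5)
        pair_rows.append(rows)
        off.append(off[-1] + len(rows))
    prob.group_pair_off = np.array(off, dtype=np.int64)
    prob.group_pairs = (
        np.concatenate(pair_rows, axis=0).astype(np.int64)
        if off[-1] else np.zeros((0, 2), dtype=np.int64)
    )
    return prob


# -- scoring -------------------------------------------------------------


def score_state(problem: AssignmentProblem, anchors: np.ndarray) -> float:
    """Full score of a state (alignment + completeness - degeneracy)."""
    S = anchors
    assigned = S >= 0
    base = float(assigned.sum())
    ok = assigned[problem.exp_a] & assigned[problem.exp_b]
    noe = 0.0
    if np.any(ok):
        vals = problem.M[
            problem.exp_g[ok], S[problem.exp_a[ok]], S[problem.exp_b[ok]]
        ]
        noe = float(np.dot(problem.exp_p[ok], vals))
    qa = S[assigned]
    pen = 0.0
    if qa.size > 1:
        block = problem.pen[np.ix_(qa, qa)]
        pen = float((block.sum() - np.trace(block)) / 2.0)
    return base + noe - pen


def _contrib_vector(problem: AssignmentProblem, S: np.ndarray, i: int) -> np.ndarray:
    """Score contribution of methyl i as a function of its anchor q."""
    out = np.ones(problem.nq)
    oe = problem.out_idx[i]
    if oe.size:
        sel = oe[S[problem.exp_b[oe]] >= 0]
        if sel.size:
            vals = problem.M[problem.exp_g[sel], :, S[problem.exp_b[sel]]]
            out += problem.exp_p[sel] @ vals
    ie = problem.in_idx[i]
    if ie.size:
        sel = ie[S[problem.exp_a[ie]] >= 0]
        if sel.size:
            vals = problem.M[problem.exp_g[sel], S[problem.exp_a[sel]], :]
            out += problem.exp_p[sel] @ vals
    de = problem.diag_idx[i]
    for e in de:
        out += problem.exp_p[e] * np.diagonal(problem.M[problem.exp_g[e]])
    others = np.flatnonzero(S >= 0)
    others = others[others != i]
    if others.size:
        out -= problem.pen[:, S[others]].sum(axis=1)
    return out


def _contrib_scalar(problem: AssignmentProblem, S: np.ndarray, i: int) -> float:
    if S[i] < 0:
        return 0.0
    return float(_contrib_vector(problem, S, i)[S[i]])


def _pair_cross(problem: AssignmentProblem, S: np.ndarray, i: int, j: int) -> float:
    """Terms counted twice when summing the contributions of i and j."""
    if S[i] < 0 or S[j] < 0:
        return 0.0
    cross = -float(problem.pen[S[i], S[j]])
    for e in np.concatenate((problem.out_idx[i], problem.in_idx[i])):
        a, b = problem.exp_a[e], problem.exp_b[e]
        if {a, b} == {i, j}:
            cross += problem.exp_p[e] * problem.M[problem.exp_g[e], S[a], S[b]]
    return cross


def _pack_kernel_arrays(problem: "AssignmentProblem"):
    """Flattened adjacency/candidate arrays for the compiled local search."""
    if getattr(problem, "_packed", None) is not None:
        return problem._packed
    n = problem.n
    nq = problem.nq

    def flatten(lists, count):
        start = np.zeros(count + 1, dtype=np.int64)
        for i, arr in enumerate(lists):
            start[i + 1] = start[i] + len(arr)
        flat = np.concatenate([np.asarray(a, dtype=np.int64) for a in lists]) \
            if start[-1] else np.zeros(0, dtype=np.int64)
        return flat, start

    cand = [np.flatnonzero(problem.compat[i]) for i in range(n)]
    cand_flat, cand_start = flatten(cand, n)
    out_flat, out_start = flatten(problem.out_idx, n)
    in_flat, in_start = flatten(problem.in_idx, n)
    dia_flat, dia_start = flatten(problem.diag_idx, n)
    # sparse penalty neighbourhood: per anchor q, the anchors q' (including
    # q itself) with a non-zero degeneracy penalty
    pen_nbr = [np.flatnonzero(problem.pen[q] > 0) for q in range(nq)]
    pen_nbr_flat, pen_start = flatten(pen_nbr, nq)
    pen_val_flat = (
        np.concatenate([problem.pen[q, nb] for q, nb in enumerate(pen_nbr)])
        if pen_start[-1] else np.zeros(0)
    )
    gp = np.array(getattr(problem, "gem_pairs", []), dtype=np.int64).reshape(-1, 2)
    gap = np.asarray(
        getattr(problem, "gem_anchor_pairs", np.zeros((0, 2))), dtype=np.int64
    ).reshape(-1, 2)
    gpairs = np.asarray(
        getattr(problem, "group_pairs", np.zeros((0, 2))), dtype=np.int64
    ).reshape(-1, 2)
    goff = np.asarray(
        getattr(problem, "group_pair_off", np.zeros(1)), dtype=np.int64
    )
    problem._packed = (
        cand_flat, cand_start, out_flat, out_start, in_flat, in_start,
        dia_flat, dia_start, pen_nbr_flat, pen_start, pen_val_flat,
        problem.exp_a, problem.exp_b, problem.exp_p,
        problem.exp_g, problem.M, problem.pen, problem.compat, gp, gap,
        gpairs, goff,
    )
    return problem._packed


@njit(cache=True)
def _k_delta_set(S, occ, i, q, out_flat, out_start, in_flat, in_start,
                 dia_flat, dia_start, pen_nbr, pen_start, pen_val,
                 exp_a, exp_b, exp_p, exp_g, M):
    """Exact score change of re-anchoring methyl i to q (no mutation)."""
    old = S[i]
    if q == old:
        return 0.0
    d = (1.0 if q >= 0 else 0.0) - (1.0 if old >= 0 else 0.0)
    for idx in range(out_start[i], out_start[i + 1]):
        e = out_flat[idx]
        sj = S[exp_b[e]]
        if sj >= 0:
            v = 0.0
            if q >= 0:
                v += M[exp_g[e], q, sj]
            if old >= 0:
                v -= M[exp_g[e], old, sj]
            d += exp_p[e] * v
    for idx in range(in_start[i], in_start[i + 1]):
        e = in_flat[idx]
        sj = S[exp_a[e]]
        if sj >= 0:
            v = 0.0
            if q >= 0:
                v += M[exp_g[e], sj, q]
            if old >= 0:
                v -= M[exp_g[e], sj, old]
            d += exp_p[e] * v
    for idx in range(dia_start[i], dia_start[i + 1]):
        e = dia_flat[idx]
        v = 0.0
        if q >= 0:
            v += M[exp_g[e], q, q]
        if old >= 0:
            v -= M[exp_g[e], old, old]
        d += exp_p[e] * v
    # degeneracy penalty against the other anchored methyls
    if q >= 0:
        for idx in range(pen_start[q], pen_start[q + 1]):
            q2 = pen_nbr[idx]
            c = occ[q2]
            if old == q2:
                c -= 1
            d -= pen_val[idx] * c
    if old >= 0:
        for idx in range(pen_start[old], pen_start[old + 1]):
            q2 = pen_nbr[idx]
            c = occ[q2]
            if old == q2:
                c -= 1
            d += pen_val[idx] * c
    return d


@njit(cache=True)
def _k_set(S, occ, i, q):
    if S[i] >= 0:
        occ[S[i]] -= 1
    S[i] = q
    if q >= 0:
        occ[q] += 1


@njit(cache=True)
def _k_local(S, occ, iterations, seed, cand_flat, cand_start, out_flat,
             out_start, in_flat, in_start, dia_flat, dia_start, pen_nbr,
             pen_start, pen_val, exp_a, exp_b, exp_p, exp_g, M, pen, compat,
             gp, gap, gpairs, goff, p_gem, p_edge, p_swap, patience):
    np.random.seed(seed)
    n = S.shape[0]
    n_exp = exp_a.shape[0]
    eps = 1e-12
    mi = np.empty(4, dtype=np.int64)  # move slots: methyl, new anchor, old
    mq = np.empty(4, dtype=np.int64)
    mo = np.empty(4, dtype=np.int64)
    since_accept = 0
    for _ in range(iterations):
        since_accept += 1
        if patience > 0 and since_accept > patience:
            break
        r = np.random.random()
        nm = 0  # number of slots in the proposed move
        if r < p_gem and gp.shape[0] > 0 and gap.shape[0] > 0:
            if gp.shape[0] >= 2 and np.random.random() < 0.3:
                # simultaneous stereo swap within two geminal pairs
                k1 = np.random.randint(gp.shape[0])
                k2 = np.random.randint(gp.shape[0])
                if k1 == k2:
                    continue
                i, j = gp[k1, 0], gp[k1, 1]
                k, l = gp[k2, 0], gp[k2, 1]
                if S[i] == S[j] or S[k] == S[l]:
                    continue
                mi[0], mq[0] = i, S[j]
                mi[1], mq[1] = j, S[i]
                mi[2], mq[2] = k, S[l]
                mi[3], mq[3] = l, S[k]
                nm = 4
            else:
                # geminal pair onto an anchor pair supported by the
                # measured geminal correlation list
                k = np.random.randint(gp.shape[0])
                m = np.random.randint(gap.shape[0])
                mi[0], mq[0] = gp[k, 0], gap[m, 0]
                mi[1], mq[1] = gp[k, 1], gap[m, 1]
                nm = 2
        elif r < p_gem + p_edge and n_exp > 0 and gpairs.shape[0] > 0:
            # expected peak's endpoints onto an anchor pair strongly
            # supported by some measured peak
            e = np.random.randint(n_exp)
            i, j = exp_a[e], exp_b[e]
            if i == j:
                continue
            g = exp_g[e]
            lo, hi = goff[g], goff[g + 1]
            if hi <= lo:
                continue
            m = lo + np.random.randint(hi - lo)
            mi[0], mq[0] = i, gpairs[m, 0]
            mi[1], mq[1] = j, gpairs[m, 1]
            nm = 2
        elif n >= 3 and r < p_gem + p_edge + 0.3 * p_swap:
            # cyclic rotation of three anchors
            i = np.random.randint(n)
            j = np.random.randint(n)
            k = np.random.randint(n)
            if i == j or j == k or i == k:
                continue
            mi[0], mq[0] = i, S[j]
            mi[1], mq[1] = j, S[k]
            mi[2], mq[2] = k, S[i]
            nm = 3
        elif n >= 4 and r < p_gem + p_edge + 0.6 * p_swap:
            # two simultaneous anchor swaps (coupled-swap optima)
            i = np.random.randint(n)
            j = np.random.randint(n)
            k = np.random.randint(n)
            l = np.random.randint(n)
            if i == j or k == l or i == k or i == l or j == k or j == l:
                continue
            mi[0], mq[0] = i, S[j]
            mi[1], mq[1] = j, S[i]
            mi[2], mq[2] = k, S[l]
            mi[3], mq[3] = l, S[k]
            nm = 4
        elif n >= 2 and r < p_gem + p_edge + p_swap:
            i = np.random.randint(n)
            j = np.random.randint(n)
            if i == j or S[i] == S[j]:
                continue
            mi[0], mq[0] = i, S[j]
            mi[1], mq[1] = j, S[i]
            nm = 2
        else:
            # re-anchor one random methyl: usually one random candidate,
            # sometimes a full best-improvement scan
            i = np.random.randint(n)
            lo, hi = cand_start[i], cand_start[i + 1]
            if hi == lo:
                continue
            if np.random.random() < 0.2:
                best = 0.0
                best_q = S[i]
                for c in range(lo, hi):
                    q = cand_flat[c]
                    d = _k_delta_set(S, occ, i, q, out_flat, out_start,
                                     in_flat, in_start, dia_flat, dia_start,
                                     pen_nbr, pen_start, pen_val,
                                     exp_a, exp_b, exp_p, exp_g, M)
                    if d > best:
                        best = d
                        best_q = q
                d = _k_delta_set(S, occ, i, np.int64(-1), out_flat, out_start,
                                 in_flat, in_start, dia_flat, dia_start,
                                 pen_nbr, pen_start, pen_val,
                                 exp_a, exp_b, exp_p, exp_g, M)
                if d > best:
                    best = d
                    best_q = np.int64(-1)
                if best > eps:
                    _k_set(S, occ, i, best_q)
                    since_accept = 0
                continue
            c = np.random.randint(hi - lo + 1)
            q = np.int64(-1) if c == hi - lo else cand_flat[lo + c]
            mi[0], mq[0] = i, q
            nm = 1
        # validate and execute the proposed anchor sets
        ok = True
        for tix in range(nm):
            if mq[tix] >= 0 and not compat[mi[tix], mq[tix]]:
                ok = False
        if not ok:
            continue
        changed = False
        for tix in range(nm):
            if S[mi[tix]] != mq[tix]:
                changed = True
        if not changed:
            continue
        tot = 0.0
        for tix in range(nm):
            mo[tix] = S[mi[tix]]
            tot += _k_delta_set(S, occ, mi[tix], mq[tix], out_flat, out_start,
                                in_flat, in_start, dia_flat, dia_start,
                                pen_nbr, pen_start, pen_val,
                                exp_a, exp_b, exp_p, exp_g, M)
            _k_set(S, occ, mi[tix], mq[tix])
        if tot > eps:
            since_accept = 0
        else:
            for tix in range(nm - 1, -1, -1):
                _k_set(S, occ, mi[tix], mo[tix])
    return S


def local_optimize(
    problem: AssignmentProblem,
    state: AssignmentState,
    iterations: int,
    rng: np.random.Generator,
) -> AssignmentState:
    """Greedy local search over one state.

    Each iteration proposes re-anchoring a randomly chosen methyl to a
    random compatible HMQC peak (or unanchoring it), swapping two methyls'
    anchors, or jointly re-anchoring a connected pair (geminal or
    NOE-linked) onto an anchor pair supported by the measured data.  Only
    strictly improving moves are accepted, so the score trace is monotone
    non-decreasing.  Deterministic given the rng state; runs in a compiled
    kernel.
    """
    if iterations <= 0:
        return state.copy()
    packed = _pack_kernel_arrays(problem)
    (cand_flat, cand_start, out_flat, out_start, in_flat, in_start,
     dia_flat, dia_start, pen_nbr_flat, pen_start, pen_val_flat,
     exp_a, exp_b, exp_p, exp_g, M, pen, compat, gp, gap, gpairs,
     goff) = packed
    p_gem = 0.15 if (len(gp) and len(gap)) else 0.0
    p_edge = 0.3 if len(gpairs) else 0.0
    p_swap = problem_swap_prob(problem) * (1.0 - p_gem - p_edge)
    # stop early once no proposal has been accepted for a while; purely a
    # compute saver on converged states (the trace stays monotone)
    patience = int(getattr(problem, "patience",
                           max(20 * problem.n, int(iterations) // 4)))
    seed = int(rng.integers(0, 2**31 - 1))
    S = state.anchors.copy()
    occ = np.bincount(S[S >= 0], minlength=problem.nq).astype(np.int64)
    S = _k_local(
        S, occ, int(iterations), seed, cand_flat, cand_start,
        out_flat, out_start, in_flat, in_start, dia_flat, dia_start,
        pen_nbr_flat, pen_start, pen_val_flat,
        exp_a, exp_b, exp_p, exp_g, M, pen, compat, gp, gap, gpairs, goff,
        p_gem, p_edge, p_swap, patience,
    )
    return AssignmentState(anchors=S, score=score_state(problem, S))


def problem_swap_prob(problem: AssignmentProblem) -> float:
    return getattr(problem, "swap_prob", 0.25)


def _random_state(
    problem: AssignmentProblem, rng: np.random.Generator
) -> AssignmentState:
    S = np.full(problem.n, -1, dtype=np.int64)
    for i in range(problem.n):
        cand = np.flatnonzero(problem.compat[i])
        if cand.size:
            S[i] = int(rng.choice(cand))
    return AssignmentState(anchors=S, score=score_state(problem, S))


def evolve(
    problem: AssignmentProblem,
    config: OptimizerConfig,
    rng: np.random.Generator | int,
) -> AssignmentState:
    """One optimization run: evolutionary search over anchor states.

    A steady-state evolutionary algorithm: tournament selection,
    per-methyl recombination (each methyl's anchor — and hence all of its
    peak mappings — inherited from one parent), mutation, and greedy local
    optimization of every offspring.  Deterministic given the rng seed; the
    returned state never scores below the best initial-population member.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    problem.swap_prob = config.swap_prob
    P = config.population
    pop = [_random_state(problem, rng) for _ in range(P)]
    scores = np.array([s.score for s in pop])
    best = pop[int(np.argmax(scores))].copy()

    L = config.local_iterations
    K = config.n_offspring if P > 1 else 2
    stagn = 0
    for _ in range(config.generations):
        improved = False
        for _ in range(K):
            if P > 1:
                t1 = rng.integers(0, P, size=2)
                t2 = rng.integers(0, P, size=2)
                p1 = pop[int(t1[np.argmax(scores[t1])])]
                p2 = pop[int(t2[np.argmax(scores[t2])])]
            else:
                p1 = p2 = pop[0]
            blocks = getattr(problem, "blocks", np.arange(problem.n))
            pick = rng.random(problem.n) < 0.5
            mask = pick[blocks]  # a geminal pair inherits from one parent
            child = np.where(mask, p1.anchors, p2.anchors)
            mut = np.flatnonzero(rng.random(problem.n) < config.mutation_rate)
            for i in mut:
                cand = np.flatnonzero(problem.compat[i])
                if cand.size == 0 or rng.random() < config.unassign_rate:
                    child[i] = -1
                else:
                    child[i] = int(rng.choice(cand))
            st = AssignmentState(anchors=child, score=score_state(problem, child))
            st = local_optimize(problem, st, L, rng)
            worst = int(np.argmin(scores))
            if st.score > scores[worst]:
                pop[worst] = st
                scores[worst] = st.score
            if st.score > best.score + _EPS:
                best = st.copy()
                improved = True
        stagn = 0 if improved else stagn + 1
        if stagn >= config.stagnation:
            break
    return best


# -- run post-processing --------------------------------------------------


def derive_run_shifts(
    problem: AssignmentProblem, state: AssignmentState
) -> RunResult:
    """Per-atom shifts (median over mapped measured coordinates) and the
    number of mapped methyl-methyl NOESY peaks supporting each methyl."""
    S = state.anchors
    n = problem.n
    shift_c = np.full(n, np.nan)
    shift_h = np.full(n, np.nan)
    noe_count = np.zeros(n, dtype=np.int64)
    mapped: set[int] = set()

    coords_c: list[list[float]] = [[] for _ in range(n)]
    coords_h: list[list[float]] = [[] for _ in range(n)]
    for i in range(n):
        if S[i] >= 0:
            coords_h[i].append(problem.Hq[S[i]])
            coords_c[i].append(problem.Cq[S[i]])

    ok = (S[problem.exp_a] >= 0) & (S[problem.exp_b] >= 0)
    for e in np.flatnonzero(ok):
        a, b = problem.exp_a[e], problem.exp_b[e]
        qa, qb = S[a], S[b]
        val = problem.M[problem.exp_g[e], qa, qb]
        if val <= 0.0:
            continue
        gid = int(problem.Marg[problem.exp_g[e], qa, qb])
        plist, local = problem.measured_peaks[gid]
        m = plist.peaks[local]
        sides = _side_dims(plist.experiment or plist.name, plist.dims,
                           plist.dim_nuclei)
        for side, meth in ((0, a), (1, b)):
            hdim, cdim = sides[side]
            if hdim is not None:
                coords_h[meth].append(m.position[hdim])
            if cdim is not None:
                coords_c[meth].append(m.position[cdim])
        if problem.exp_is_noe[e]:
            mapped.add(gid)
            noe_count[a] += 1
            noe_count[b] += 1

    for i in range(n):
        if coords_c[i]:
            shift_c[i] = float(np.median(coords_c[i]))
        if coords_h[i]:
            shift_h[i] = float(np.median(coords_h[i]))
    return RunResult(
        methyl_ids=[g.id for g in problem.methyls],
        shift_c=shift_c,
        shift_h=shift_h,
        noe_count=noe_count,
        anchors=S.copy(),
        mapped_noe_peaks=frozenset(mapped),
        score=state.score,
        n_measured_noe=problem.n_measured_noe,
    )


# -- exhaustive oracle ----------------------------------------------------


def brute_force_assign(
    problem: AssignmentProblem,
    include_unassigned: bool = False,
    max_states: int = 2_000_000,
) -> AssignmentState:
    """Enumerate anchor bijections consistent with the type labels and
    return the global score optimum.  Intended as an independent oracle on
    small instances (factorial search space); refuses large ones."""
    n, nq = problem.n, problem.nq
    if n > 9:
        raise ValueError("brute force is limited to <= 9 methyls")

    rows: list[np.ndarray] = []
    S = np.full(n, -1, dtype=np.int64)
    used = np.zeros(nq, dtype=bool)

    def rec(i: int):
        if len(rows) > max_states:
            raise ValueError("search space exceeds max_states")
        if i == n:
            rows.append(S.copy())
            return
        if include_unassigned:
            S[i] = -1
            rec(i + 1)
        for q in np.flatnonzero(problem.compat[i]):
            if not used[q]:
                used[q] = True
                S[i] = q
                rec(i + 1)
                used[q] = False
        S[i] = -1

    rec(0)
    if not rows:
        raise ValueError("no type-consistent assignment exists")
    Q = np.array(rows)
    assigned = Q >= 0
    base = assigned.sum(axis=1).astype(float)
    ok = assigned[:, problem.exp_a] & assigned[:, problem.exp_b]
    Qa = np.where(ok, Q[:, problem.exp_a], 0)
    Qb = np.where(ok, Q[:, problem.exp_b], 0)
    vals = problem.M[problem.exp_g[None, :], Qa, Qb] * ok
    noe = vals @ problem.exp_p
    pen = np.zeros(len(Q))
    for i in range(n):
        for j in range(i + 1, n):
            both = assigned[:, i] & assigned[:, j]
            pen += problem.pen[Q[:, i], Q[:, j]] * both
    scores = base + noe - pen
    best = int(np.argmax(scores))
    return AssignmentState(anchors=Q[best], score=float(scores[best]))
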