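"""Consolidation of independent optimization runs into consensus assignments.

The shift values an atom received across the pooled runs (three cutoff
batches by default) are summarized by the global maximum of a sum of
Gaussians centered at the per-run values, with standard deviation equal to
the chemical-shift tolerance.  An assignment is classified *strong*
(reliable) when more than a threshold fraction (default 80%) of the runs
agree with the consensus within the tolerance — for both nuclei — and at
least one methyl-methyl NOE is mapped to the methyl, so that no strong
assignment lacks an experimental basis.

Geminal Leu/Val methyls carry no a-priori stereospecific identity, so in
every run the two (13C, 1H) shift pairs of a geminal pair are redistributed
by size (smaller 13C first, 1H following its own 13C) before consolidation;
the 1H and 13C consensus therefore stay mutually consistent and no
stereospecific claim is made.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .assign import RunResult
from .geometry import MethylGroup, ONE_TO_THREE
from .peaklists import ShiftEntry, ShiftList, UNASSIGNED_SHIFT, write_shifts
from .prep import Tolerances

__all__ = [
    "ConsensusConfig",
    "ConsensusAssignment",
    "EvaluationReport",
    "consensus_shift",
    "consolidate_geminal",
    "consolidate",
    "evaluate_vs_reference",
    "explained_fraction",
    "write_reports",
]


@dataclass
class ConsensusConfig:
    threshold: float = 0.8
    k_alternatives: int = 3
    tolerances: Tolerances = field(default_factory=Tolerances)


@dataclass
class ConsensusAssignment:
    methyl_id: str
    res_number: int
    res_type: str
    carbon_name: str
    shift_c: float
    shift_h: float
    frac_c: float
    frac_h: float
    strong: bool
    noe_support: float
    alternatives: list[tuple[float, float, float]] = field(default_factory=list)

    @property
    def agreement(self) -> float:
        return min(self.frac_c, self.frac_h)


@dataclass
class EvaluationReport:
    n_strong: int
    n_correct: int
    n_erroneous: int
    n_no_reference: int
    explained_noe_fraction: float | None = None

    def __post_init__(self):
        if self.n_correct + self.n_erroneous + self.n_no_reference != self.n_strong:
            raise ValueError("evaluation counts must sum to the strong count")


def consensus_shift(
    values, tolerance: float, n_runs: int | None = None
) -> tuple[float, float]:
    """Gaussian-kernel consensus of per-run shift values.

    Returns (consensus ppm, agreement fraction).  The consensus is the
    argmax of sum_k exp(-(x - v_k)^2 / 2 tol^2) over candidate positions:
    the values themselves, refined by a local grid of spacing tol/20; ties
    break toward the lowest ppm.  The agreement fraction counts values
    within +/- tolerance of the consensus, relative to the number of runs.
    """
    v = np.asarray([x for x in np.atleast_1d(values) if np.isfinite(x)], dtype=float)
    if v.size == 0:
        raise ValueError("consensus of an empty value set is undefined")
    if n_runs is None:
        n_runs = v.size

    def ksum(x):
        return np.exp(
            -((np.atleast_1d(x)[:, None] - v[None, :]) ** 2) / (2 * tolerance ** 2)
        ).sum(axis=1)

    cand = np.unique(v)
    heights = ksum(cand)
    x0 = cand[int(np.argmax(heights))]
    grid = np.arange(x0 - tolerance, x0 + tolerance + tolerance / 40.0, tolerance / 20.0)
    grid = np.unique(np.concatenate((cand, grid)))
    heights = ksum(grid)
    best = np.max(heights)
    consensus = float(grid[np.flatnonzero(heights >= best - 1e-12)[0]])
    frac = float(np.sum(np.abs(v - consensus) <= tolerance)) / float(n_runs)
    return consensus, frac


def consolidate_geminal(
    c1, h1, c2, h2
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Redistribute per-run geminal shift pairs by size.

    Inputs are per-run arrays for the two methyl slots; runs where either
    methyl is unassigned contribute nothing for the pair (NaN in output).
    In each run the two (13C, 1H) pairs are ordered by 13C (tie: by 1H);
    slot 1 receives the smaller pair, slot 2 the larger, each 1H staying
    attached to its own 13C.
    """
    c1 = np.asarray(c1, dtype=float).copy()
    h1 = np.asarray(h1, dtype=float).copy()
    c2 = np.asarray(c2, dtype=float).copy()
    h2 = np.asarray(h2, dtype=float).copy()
    both = np.isfinite(c1) & np.isfinite(c2)
    only_one = ~both
    for arr in (c1, h1, c2, h2):
        arr[only_one] = np.nan
    swap = both & ((c1 > c2) | ((c1 == c2) & (h1 > h2)))
    c1[swap], c2[swap] = c2[swap], c1[swap].copy()
    h1[swap], h2[swap] = h2[swap], h1[swap].copy()
    return c1, h1, c2, h2


def consolidate(
    run_batches: list[list[RunResult]],
    methyls: list[MethylGroup],
    config: ConsensusConfig = ConsensusConfig(),
) -> list[ConsensusAssignment]:
    """Pool all runs of all cutoff batches into consensus assignments.

    ``run_batches`` holds one list of RunResults per distance cutoff (three
    in the standard protocol, one in the degraded single-cutoff mode).
    """
    import warnings

    sizes = {len(b) for b in run_batches}
    if len(sizes) > 1:
        warnings.warn("cutoff batches have differing run counts; pooling anyway")
    runs = [r for batch in run_batches for r in batch]
    if not runs:
        raise ValueError("no runs to consolidate")
    n_runs = len(runs)
    index = {mid: k for k, mid in enumerate(runs[0].methyl_ids)}
    n = len(methyls)

    C = np.array([r.shift_c for r in runs])  # (n_runs, n)
    H = np.array([r.shift_h for r in runs])
    NOE = np.array([r.noe_count for r in runs])

    by_id = {g.id: g for g in methyls}
    done = set()
    for g in methyls:
        if g.geminal_partner and g.id not in done:
            done.update({g.id, g.geminal_partner})
            # slot 1 = the lower-numbered methyl name (CD1 before CD2 etc.)
            first, second = sorted(
                [g.id, g.geminal_partner], key=lambda mid: by_id[mid].carbon_name
            )
            i, j = index[first], index[second]
            C[:, i], H[:, i], C[:, j], H[:, j] = consolidate_geminal(
                C[:, i], H[:, i], C[:, j], H[:, j]
            )

    out: list[ConsensusAssignment] = []
    for g in methyls:
        i = index[g.id]
        cvals, hvals = C[:, i], H[:, i]
        valid = np.isfinite(cvals) & np.isfinite(hvals)
        noe_med = float(np.median(NOE[:, i]))
        if not np.any(valid):
            out.append(
                ConsensusAssignment(
                    methyl_id=g.id, res_number=g.res_number, res_type=g.res_type,
                    carbon_name=g.carbon_name, shift_c=np.nan, shift_h=np.nan,
                    frac_c=0.0, frac_h=0.0, strong=False, noe_support=noe_med,
                )
            )
            continue
        cons_c, frac_c = consensus_shift(cvals[valid], config.tolerances.tol_c, n_runs)
        cons_h, frac_h = consensus_shift(hvals[valid], config.tolerances.tol_h, n_runs)
        strong = (
            frac_c > config.threshold
            and frac_h > config.threshold
            and noe_med >= 1.0
        )
        alts = _alternatives(
            cvals[valid], hvals[valid], cons_c, config.tolerances, n_runs,
            config.k_alternatives,
        )
        out.append(
            ConsensusAssignment(
                methyl_id=g.id, res_number=g.res_number, res_type=g.res_type,
                carbon_name=g.carbon_name, shift_c=cons_c, shift_h=cons_h,
                frac_c=frac_c, frac_h=frac_h, strong=strong,
                noe_support=noe_med, alternatives=alts,
            )
        )
    return out


def _alternatives(cvals, hvals, cons_c, tolerances, n_runs, k):
    """Top-k alternative (13C, 1H, fraction) clusters beyond the consensus."""
    alts: list[tuple[float, float, float]] = []
    remaining_c = np.asarray(cvals, dtype=float)
    remaining_h = np.asarray(hvals, dtype=float)
    drop = np.abs(remaining_c - cons_c) <= tolerances.tol_c
    remaining_c, remaining_h = remaining_c[~drop], remaining_h[~drop]
    while remaining_c.size and len(alts) < k:
        c, _ = consensus_shift(remaining_c, tolerances.tol_c)
        near = np.abs(remaining_c - c) <= tolerances.tol_c
        h = float(np.median(remaining_h[near]))
        alts.append((float(c), h, float(near.sum()) / n_runs))
        remaining_c, remaining_h = remaining_c[~near], remaining_h[~near]
    return alts


def explained_fraction(runs: list[RunResult]) -> float:
    """Mean over runs of the fraction of measured NOESY peaks mapped."""
    fracs = []
    for r in runs:
        total = r.n_measured_noe
        fracs.append(len(r.mapped_noe_peaks) / total if total else 0.0)
    return float(np.mean(fracs)) if fracs else 0.0


def _reference_pairs(
    consensus: list[ConsensusAssignment],
    reference: ShiftList,
    methyls: list[MethylGroup],
) -> dict[str, tuple[float | None, float | None]]:
    """Reference (C, H) per methyl id, geminal pairs sorted the same way
    as the consensus redistribution (by 13C, tie by 1H)."""
    by_id = {g.id: g for g in methyls}
    ref: dict[str, tuple[float | None, float | None]] = {}
    for g in methyls:
        c = reference.get(g.carbon_name, g.res_number)
        h = reference.get(g.proton_name, g.res_number)
        ref[g.id] = (c, h)
    done = set()
    for g in methyls:
        if not g.geminal_partner or g.id in done:
            continue
        partner = by_id[g.geminal_partner]
        done.update({g.id, partner.id})
        first, second = sorted([g, partner], key=lambda m: m.carbon_name)
        pa, pb = ref[first.id], ref[second.id]
        if None in pa or None in pb:
            continue
        # slot 1 (lower methyl name) holds the smaller (13C, 1H) pair,
        # matching the consolidation-side redistribution
        lo, hi = sorted([pa, pb])
        ref[first.id], ref[second.id] = lo, hi
    return ref


def evaluate_vs_reference(
    consensus: list[ConsensusAssignment],
    reference: ShiftList,
    methyls: list[MethylGroup],
    tolerances: Tolerances = Tolerances(),
    explained: float | None = None,
) -> EvaluationReport:
    """Count correct/erroneous/unreferenced strong assignments.

    A strong assignment is correct when both its 13C and 1H consensus
    shifts fall within the tolerances of the reference shifts of the same
    atom; geminal pairs are compared as ordered pairs after the same
    smaller/larger redistribution used in consolidation.
    """
    ref = _reference_pairs(consensus, reference, methyls)
    n_strong = n_corr = n_err = n_noref = 0
    for a in consensus:
        if not a.strong:
            continue
        n_strong += 1
        c_ref, h_ref = ref.get(a.methyl_id, (None, None))
        if c_ref is None or h_ref is None:
            n_noref += 1
        elif (
            abs(a.shift_c - c_ref) <= tolerances.tol_c
            and abs(a.shift_h - h_ref) <= tolerances.tol_h
        ):
            n_corr += 1
        else:
            n_err += 1
    return EvaluationReport(
        n_strong=n_strong, n_correct=n_corr, n_erroneous=n_err,
        n_no_reference=n_noref, explained_noe_fraction=explained,
    )


def write_reports(
    consensus: list[ConsensusAssignment],
    out_dir,
    peaklist_stats: dict[str, tuple[int, int, float]] | None = None,
    evaluation: EvaluationReport | None = None,
) -> None:
    """Write consol.prot, consol.tab and flya.txt to ``out_dir``.

    ``peaklist_stats`` maps peak-list name -> (expected, measured, assigned)
    counts for flya.txt.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    entries = []
    aid = 1
    for a in sorted(consensus, key=lambda x: (x.res_number, x.carbon_name)):
        proton = "Q" + a.carbon_name[1:]
        for name, shift, nuc in ((a.carbon_name, a.shift_c, "C"),
                                 (proton, a.shift_h, "H")):
            val = shift if np.isfinite(shift) else UNASSIGNED_SHIFT
            err = 0.4 if nuc == "C" else 0.04
            entries.append(ShiftEntry(aid, round(val, 3), err, name, a.res_number))
            aid += 1
    write_shifts(ShiftList(entries=entries), out / "consol.prot")

    lines = [
        "# residue type methyl  13C      1H     agreement%  label  NOEs  alternatives"
    ]
    for a in sorted(consensus, key=lambda x: (x.res_number, x.carbon_name)):
        label = "strong" if a.strong else "weak"
        alts = "; ".join(
            f"{c:.3f}/{h:.3f} ({f * 100:.0f}%)" for c, h, f in a.alternatives
        )
        cs = f"{a.shift_c:8.3f}" if np.isfinite(a.shift_c) else "       -"
        hs = f"{a.shift_h:7.3f}" if np.isfinite(a.shift_h) else "      -"
        lines.append(
            f"{a.res_number:5d} {ONE_TO_THREE[a.res_type]:>4s} {a.carbon_name:<6s}"
            f"{cs} {hs} {a.agreement * 100:9.1f}  {label:<7s}"
            f"{a.noe_support:5.1f}  {alts}"
        )
    (out / "consol.tab").write_text("\n".join(lines) + "\n")

    flya = ["# peak list              expected  measured  assigned"]
    for name, (n_exp, n_meas, n_asg) in (peaklist_stats or {}).items():
        flya.append(f"{name:<24s}{n_exp:9d}{n_meas:10d}{n_asg:10.0f}")
    n_strong = sum(a.strong for a in consensus)
    flya.append(f"# strong assignments: {n_strong} / {len(consensus)} methyls")
    if evaluation is not None:
        flya.append(
            f"# evaluation: correct {evaluation.n_correct}, erroneous "
            f"{evaluation.n_erroneous}, no reference {evaluation.n_no_reference}"
        )
    (out / "flya.txt").write_text("\n".join(flya) + "\n")
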