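"""Filtering, residue typing, and type-splitting of measured peak lists.

Measured NOESY peaks are (i) optionally filtered for donor/acceptor
reciprocity and signal-to-noise, (ii) attributed to the residue types of
the two HMQC peaks with the closest matching chemical shifts, and (iii)
written to separate lists per unordered type pair.  Residue typing of HMQC
peaks can come from the user (labeling schemes, annotations) or be guessed
from packaged chemical-shift statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .expected import EXPERIMENTS, ExperimentDef
from .peaklists import Peak, PeakList

__all__ = [
    "Tolerances",
    "ResidueTyping",
    "METHYL_SHIFT_STATS",
    "TYPE_REGIONS",
    "filter_noesy",
    "attribute_noesy_types",
    "split_hmqc_by_type",
    "bmrb_best_guess_typing",
    "label_string",
]

UNTYPED_KEY = ("?", "?")


@dataclass(frozen=True)
class Tolerances:
    """Chemical-shift matching tolerances (ppm)."""

    tol_c: float = 0.4
    tol_h: float = 0.04

    def __post_init__(self):
        if self.tol_c <= 0 or self.tol_h <= 0:
            raise ValueError("tolerances must be positive")

    def for_nucleus(self, nucleus: str) -> float:
        return self.tol_c if nucleus.upper().startswith("C") else self.tol_h


# Packaged per-methyl chemical-shift statistics (ppm): mean/sd of 13C and
# 1H resonances, approximating published database distributions for
# protein methyl groups.  Used by the synthetic-data generator and the
# best-guess residue typing.
METHYL_SHIFT_STATS: dict[tuple[str, str], tuple[float, float, float, float]] = {
    # (res, methyl): (C mean, C sd, H mean, H sd)
    ("A", "CB"): (18.9, 1.8, 1.35, 0.25),
    ("I", "CD1"): (13.4, 1.7, 0.67, 0.28),
    ("I", "CG2"): (17.4, 1.4, 0.77, 0.24),
    ("L", "CD1"): (24.6, 1.6, 0.75, 0.26),
    ("L", "CD2"): (24.1, 1.7, 0.73, 0.26),
    ("V", "CG1"): (21.5, 1.4, 0.82, 0.26),
    ("V", "CG2"): (21.3, 1.6, 0.80, 0.27),
    ("M", "CE"): (17.3, 1.6, 1.86, 0.40),
    ("T", "CG2"): (21.6, 1.1, 1.14, 0.22),
}


def _region(keys) -> tuple[float, float, float, float]:
    """mean +/- 1 sd bounding box (C lo, C hi, H lo, H hi) over methyls."""
    clo = min(METHYL_SHIFT_STATS[k][0] - METHYL_SHIFT_STATS[k][1] for k in keys)
    chi = max(METHYL_SHIFT_STATS[k][0] + METHYL_SHIFT_STATS[k][1] for k in keys)
    hlo = min(METHYL_SHIFT_STATS[k][2] - METHYL_SHIFT_STATS[k][3] for k in keys)
    hhi = max(METHYL_SHIFT_STATS[k][2] + METHYL_SHIFT_STATS[k][3] for k in keys)
    return (clo, chi, hlo, hhi)


#: Typing regions for the three discriminable classes: Ala, Ile(d1), and the
#: merged Leu/Val class whose average shifts overlap too much to separate.
TYPE_REGIONS: dict[str, tuple[float, float, float, float]] = {
    "A": _region([("A", "CB")]),
    "I": _region([("I", "CD1")]),
    "LV": _region([("L", "CD1"), ("L", "CD2"), ("V", "CG1"), ("V", "CG2")]),
}


def label_string(labels: frozenset[str] | set[str]) -> str:
    """Canonical string for a residue-type label set, e.g. {L,V} -> 'LV'."""
    return "".join(sorted(labels))


@dataclass
class ResidueTyping:
    """Map HMQC peak id -> set of candidate residue-type letters."""

    labels: dict[int, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self):
        for pid, s in self.labels.items():
            if not s:
                raise ValueError(f"empty type label set for HMQC peak {pid}")

    def of(self, peak_id: int) -> frozenset[str]:
        return self.labels[peak_id]


def _noesy_sides(plist: PeakList) -> tuple[tuple[int | None, int | None], ...]:
    """Per-side (H dim index, C dim index) for a NOESY list.

    The experiment definition (from ``plist.experiment`` or inferred from
    the dimension count) names which dimension belongs to the donor
    (side 0) and acceptor (side 1) methyl.
    """
    name = plist.experiment.split("_")[0] if plist.experiment else ""
    exp: ExperimentDef | None = EXPERIMENTS.get(name)
    if exp is None or not exp.is_noesy:
        if name and name in EXPERIMENTS:
            raise ValueError(f"{name} is not a NOESY experiment")
        if plist.dims == 4:
            exp = EXPERIMENTS["CCNOESY"]
        elif plist.dims == 3 and plist.dim_nuclei[:1] == ("C",):
            exp = EXPERIMENTS["CCNOESY3D"]
        elif plist.dims == 3:
            exp = EXPERIMENTS["C13NOESY"]
        else:
            raise ValueError(
                f"list {plist.name!r} ({plist.dims}D) is not a NOESY list"
            )
    sides: list[list[int | None]] = [[None, None], [None, None]]
    for k, (nucleus, side) in enumerate(exp.dims):
        sides[side][0 if nucleus == "H" else 1] = k
    return tuple((h, c) for h, c in sides)


def filter_noesy(
    noesy: PeakList,
    min_sn: float = 2.0,
    tolerances: Tolerances = Tolerances(),
) -> PeakList:
    """Keep reciprocated NOESY peaks above the signal-to-noise threshold.

    The S/N cut is applied first; reciprocity is then required among the
    surviving candidates, so a peak whose mirror partner fails the S/N cut
    is removed as well.  Peaks without an S/N value pass the S/N test.
    The operation is idempotent.
    """
    sides = _noesy_sides(noesy)
    (h0, c0), (h1, c1) = sides
    cand = [p for p in noesy.peaks if p.sn is None or p.sn >= min_sn]
    pos = np.array([p.position for p in cand]) if cand else np.zeros((0, noesy.dims))

    def reciprocated(p: Peak) -> bool:
        ok = np.ones(len(cand), dtype=bool)
        # compare each transposable coordinate pair that exists in both sides
        for da, db, tol in (
            (h0, h1, tolerances.tol_h),
            (c0, c1, tolerances.tol_c),
        ):
            if da is None or db is None:
                continue
            ok &= np.abs(pos[:, da] - p.position[db]) <= tol
            ok &= np.abs(pos[:, db] - p.position[da]) <= tol
        return bool(np.any(ok))

    kept = [p for p in cand if reciprocated(p)]
    return noesy.copy_with(kept, name=(noesy.name or "NOESY"))


def _match_side(
    h: float | None,
    c: float | None,
    hmqc_pos: np.ndarray,
    tolerances: Tolerances,
) -> tuple[int, float]:
    """Best HMQC row for one NOESY side; returns (row index, scaled distance).

    The metric is the maximum of the per-nucleus tolerance-scaled
    deviations over the coordinates available on that side; ties go to the
    lower row index (hence lower peak id for id-sorted input).
    """
    parts = []
    if h is not None:
        parts.append(np.abs(hmqc_pos[:, 0] - h) / tolerances.tol_h)
    if c is not None:
        parts.append(np.abs(hmqc_pos[:, 1] - c) / tolerances.tol_c)
    metric = np.max(parts, axis=0)
    idx = int(np.argmin(metric))
    return idx, float(metric[idx])


def _hmqc_hc(hmqc: PeakList) -> np.ndarray:
    """(n, 2) array of HMQC (H, C) coordinates, whatever the dim order."""
    if hmqc.dims != 2:
        raise ValueError("HMQC list must be 2-dimensional")
    pos = np.array([p.position for p in hmqc.peaks])
    if hmqc.dim_nuclei and hmqc.dim_nuclei[0].upper().startswith("C"):
        pos = pos[:, ::-1]
    return pos


def attribute_noesy_types(
    noesy: PeakList,
    hmqc: PeakList,
    typing: ResidueTyping,
    tolerances: Tolerances = Tolerances(),
) -> dict[tuple[str, str], PeakList]:
    """Split a NOESY list by the residue types of the nearest HMQC peaks.

    Each side of every NOESY peak is matched to the HMQC peak minimizing
    max(|dH|/tol_H, |dC|/tol_C) over that side's available coordinates.
    Peaks whose best match exceeds the tolerance on either side go to an
    untyped catch-all list (key ``('?', '?')``) that downstream matching
    checks against all type pairs.  No peak is lost.
    """
    if len(hmqc) == 0:
        raise ValueError("empty HMQC list")
    sides = _noesy_sides(noesy)
    hmqc_sorted = sorted(hmqc.peaks, key=lambda p: p.id)
    hmqc_pos = _hmqc_hc(hmqc.copy_with(hmqc_sorted))
    out: dict[tuple[str, str], list[Peak]] = {}
    for p in noesy.peaks:
        labels = []
        ok = True
        for h_dim, c_dim in sides:
            h = p.position[h_dim] if h_dim is not None else None
            c = p.position[c_dim] if c_dim is not None else None
            idx, dist = _match_side(h, c, hmqc_pos, tolerances)
            if dist > 1.0:
                ok = False
                break
            labels.append(label_string(typing.of(hmqc_sorted[idx].id)))
        key = tuple(sorted(labels)) if ok else UNTYPED_KEY  # type: ignore[assignment]
        out.setdefault(key, []).append(p)
    base = noesy.experiment or noesy.name or "NOESY"
    return {
        key: noesy.copy_with(
            peaks,
            name=f"{base}_{''.join(key)}" if key != UNTYPED_KEY else f"{base}_untyped",
        )
        for key, peaks in out.items()
    }


def split_hmqc_by_type(
    hmqc: PeakList, typing: ResidueTyping
) -> dict[str, PeakList]:
    """Partition an HMQC list into per-type lists.

    A peak with an ambiguous label set beyond one class (e.g. {A, L, V})
    is duplicated into each candidate class list and tagged ``shared`` so
    that a consumer can enforce at-most-once use of the underlying peak.
    """
    classes: dict[str, list[Peak]] = {}
    for p in hmqc.peaks:
        labels = typing.of(p.id)
        keys = sorted({_class_of(l) for l in labels})
        for key in keys:
            tags = p.tags | ({"shared"} if len(keys) > 1 else set())
            classes.setdefault(key, []).append(
                Peak(id=p.id, position=p.position, volume=p.volume,
                     volume_error=p.volume_error, sn=p.sn,
                     assignment=p.assignment, tags=frozenset(tags))
            )
    base = hmqc.experiment or hmqc.name or "C13HSQC"
    return {
        key: hmqc.copy_with(peaks, name=f"{base}_{key}")
        for key, peaks in classes.items()
    }


def _class_of(letter: str) -> str:
    return "LV" if letter in ("L", "V") else letter


def bmrb_best_guess_typing(
    hmqc: PeakList,
    sequence_counts: dict[str, int],
    strategy: str = "max-ala",
    type_stats: dict[str, tuple[float, float, float, float]] | None = None,
) -> ResidueTyping:
    """Guess residue-type classes of HMQC peaks from shift statistics.

    Each type class (Ala, Ile, merged Leu/Val) owns the mean +/- 1 sd box
    of its 13C and 1H shifts.  Peaks inside exactly one box get that label.
    Peaks in the Ala/LeuVal overlap are resolved by ``strategy``:

    * ``"max-ala"`` — fill the Ala class up to the number of Ala methyls in
      the sequence, nearest-to-the-Ala-mean first; the rest become Leu/Val.
    * ``"ambiguous"`` — label them with the full ambiguous set {A, L, V}.

    Peaks outside all boxes are attributed to the nearest box, with a
    warning.
    """
    regions = type_stats or TYPE_REGIONS
    pos = _hmqc_hc(hmqc)
    order = [p.id for p in hmqc.peaks]
    label_sets: dict[int, frozenset[str]] = {}

    def _expand(key: str) -> frozenset[str]:
        return frozenset(key) if key != "LV" else frozenset({"L", "V"})

    def box_distance(hc, box) -> float:
        clo, chi, hlo, hhi = box
        # sd-scaled distance outside the box (0 inside)
        csd = (chi - clo) / 2.0
        hsd = (hhi - hlo) / 2.0
        dc = max(clo - hc[1], 0.0, hc[1] - chi) / csd
        dh = max(hlo - hc[0], 0.0, hc[0] - hhi) / hsd
        return max(dc, dh)

    overlap: list[tuple[float, int]] = []
    n_ala_sure = 0
    for pid, hc in zip(order, pos):
        inside = [k for k, box in regions.items() if box_distance(hc, box) == 0.0]
        if len(inside) == 1:
            label_sets[pid] = _expand(inside[0])
            if inside[0] == "A":
                n_ala_sure += 1
        elif len(inside) == 0:
            nearest = min(regions, key=lambda k: box_distance(hc, regions[k]))
            warnings.warn(
                f"HMQC peak {pid} at (H {hc[0]:.2f}, C {hc[1]:.2f}) ppm is "
                f"outside all type regions; attributed to nearest ({nearest})"
            )
            label_sets[pid] = _expand(nearest)
        else:
            if strategy == "ambiguous":
                label_sets[pid] = frozenset({"A", "L", "V"})
            else:
                ca, _, ha, _ = (
                    METHYL_SHIFT_STATS[("A", "CB")][0],
                    None,
                    METHYL_SHIFT_STATS[("A", "CB")][2],
                    None,
                )
                csd = METHYL_SHIFT_STATS[("A", "CB")][1]
                hsd = METHYL_SHIFT_STATS[("A", "CB")][3]
                d = max(abs(hc[1] - ca) / csd, abs(hc[0] - ha) / hsd)
                overlap.append((d, pid))
    if strategy == "max-ala" and overlap:
        n_ala_target = sequence_counts.get("A", 0)
        budget = max(n_ala_target - n_ala_sure, 0)
        for rank, (_, pid) in enumerate(sorted(overlap)):
            label_sets[pid] = (
                frozenset({"A"}) if rank < budget else frozenset({"L", "V"})
            )
    return ResidueTyping(labels=label_sets)
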