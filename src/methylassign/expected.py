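"""Expected peak lists derived from sequence, structure and experiment types.

An *expected peak* names the atoms observed in each spectral dimension of an
experiment, carries an observation probability, and (for NOESY peaks) the
effective inter-methyl distance that generated it.  Expected peaks are the
"theoretical" side of the assignment problem: the optimizer maps them onto
measured peaks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .geometry import MethylGroup, effective_distance

__all__ = [
    "ExperimentDef",
    "EXPERIMENTS",
    "GenerationConfig",
    "ExpectedPeak",
    "generate_expected_hmqc",
    "generate_expected_noesy",
    "generate_expected_geminal",
    "cutoff_triplet",
]


@dataclass(frozen=True)
class ExperimentDef:
    """An NMR experiment type: observed dimensions and transfer pathway.

    ``dims`` is an ordered tuple of (nucleus, side) pairs, where side 0 is
    the originating methyl and side 1 the destination methyl of the
    magnetization transfer.  ``pathway`` is "bond" for through-bond
    correlations (HMQC, geminal HCcCH) and "noe" for through-space NOESY
    transfers (exactly one NOE link).
    """

    name: str
    dims: tuple[tuple[str, int], ...]
    pathway: str  # "bond" | "noe"
    probability: float = 1.0

    def __post_init__(self):
        if not 0.0 < self.probability <= 1.0:
            raise ValueError("observation probability must be in (0, 1]")
        if len(self.dims) not in (2, 3, 4):
            raise ValueError("experiments have 2-4 dimensions")
        if self.pathway not in ("bond", "noe"):
            raise ValueError("pathway must be 'bond' or 'noe'")

    @property
    def is_noesy(self) -> bool:
        return self.pathway == "noe"

    @property
    def dim_nuclei(self) -> tuple[str, ...]:
        return tuple(n for n, _ in self.dims)


#: Standard experiment library.  Probabilities follow the calibrated
#: defaults: 0.1 for expected NOESY peaks, 1 for through-bond peaks.
EXPERIMENTS: dict[str, ExperimentDef] = {
    # 2D [1H,13C]-HMQC (historically registered as C13HSQC).
    "C13HSQC": ExperimentDef("C13HSQC", (("H", 0), ("C", 0)), "bond", 1.0),
    # 4D HCCH NOESY.
    "CCNOESY": ExperimentDef(
        "CCNOESY", (("H", 0), ("C", 0), ("C", 1), ("H", 1)), "noe", 0.1
    ),
    # 3D HCH NOESY.
    "C13NOESY": ExperimentDef(
        "C13NOESY", (("H", 0), ("C", 1), ("H", 1)), "noe", 0.1
    ),
    # 3D CCH NOESY.
    "CCNOESY3D": ExperimentDef(
        "CCNOESY3D", (("C", 0), ("C", 1), ("H", 1)), "noe", 0.1
    ),
    # Short-mixing-time HCCH correlating geminal Leu/Val methyls, treated as
    # an HCcCH-TOCSY (through-bond, always observed).
    "HCcCH": ExperimentDef(
        "HCcCH", (("H", 0), ("C", 0), ("C", 1), ("H", 1)), "bond", 1.0
    ),
}


@dataclass
class GenerationConfig:
    """Parameters for expected-NOESY generation.

    ``d_cut`` is the effective-distance cutoff in Angstrom; the assignment
    protocol runs the triplet {d_cut - 0.5, d_cut, d_cut + 0.5} jointly.
    ``p_noe`` is the observation probability attached to expected NOESY
    peaks (through-bond peaks always get 1).
    """

    d_cut: float = 5.0
    p_noe: float = 0.1
    include_geminal_noes: bool = True
    include_diagonal: bool = False

    def __post_init__(self):
        if self.d_cut <= 0:
            raise ValueError("d_cut must be positive")
        if not 0.0 < self.p_noe <= 1.0:
            raise ValueError("p_noe must be in (0, 1]")

    @property
    def triplet(self) -> tuple[float, float, float]:
        return (self.d_cut - 0.5, self.d_cut, self.d_cut + 0.5)


def cutoff_triplet(d_cut: float) -> tuple[float, float, float]:
    return (d_cut - 0.5, d_cut, d_cut + 0.5)


@dataclass(frozen=True)
class ExpectedPeak:
    """One expected peak: experiment, per-dimension atoms, probability.

    ``atoms`` holds one (methyl id, nucleus) pair per dimension, where the
    proton entry stands for the averaged methyl-proton pseudo-shift.
    ``type_pair`` tags the residue types of the originating/destination
    methyls (equal for 2D peaks).
    """

    experiment: str
    atoms: tuple[tuple[str, str], ...]
    probability: float
    type_pair: tuple[str, str]
    distance: float | None = None
    methyl_pair: tuple[str, str] = field(default=("", ""))


def _dims_to_atoms(
    exp: ExperimentDef, a: MethylGroup, b: MethylGroup
) -> tuple[tuple[str, str], ...]:
    sides = (a, b)
    return tuple((sides[side].id, nucleus) for nucleus, side in exp.dims)


def generate_expected_hmqc(
    methyls: list[MethylGroup], experiment: ExperimentDef | None = None
) -> list[ExpectedPeak]:
    """One (1H, 13C) expected peak per methyl, probability 1."""
    exp = experiment or EXPERIMENTS["C13HSQC"]
    return [
        ExpectedPeak(
            experiment=exp.name,
            atoms=_dims_to_atoms(exp, g, g),
            probability=exp.probability,
            type_pair=(g.type_label, g.type_label),
            methyl_pair=(g.id, g.id),
        )
        for g in methyls
    ]


def generate_expected_noesy(
    methyls: list[MethylGroup],
    config: GenerationConfig,
    experiment: ExperimentDef | None = None,
) -> list[ExpectedPeak]:
    """Directional expected NOESY peaks for methyl pairs within the cutoff.

    For every ordered pair (a, b) with effective distance <= d_cut one peak
    per direction is produced with probability ``p_noe``.  Intra-residue
    geminal contacts are included by default (they are genuine short
    contacts); diagonal peaks (a == b) are excluded by default.
    """
    exp = experiment or EXPERIMENTS["CCNOESY"]
    if not exp.is_noesy:
        raise ValueError(f"{exp.name} is not a NOESY experiment")
    peaks: list[ExpectedPeak] = []
    n = len(methyls)
    for i, j in combinations(range(n), 2):
        a, b = methyls[i], methyls[j]
        if not config.include_geminal_noes and a.geminal_partner == b.id:
            continue
        d = effective_distance(a, b)
        if d > config.d_cut:
            continue
        for x, y in ((a, b), (b, a)):
            peaks.append(
                ExpectedPeak(
                    experiment=exp.name,
                    atoms=_dims_to_atoms(exp, x, y),
                    probability=config.p_noe,
                    type_pair=(x.type_label, y.type_label),
                    distance=d,
                    methyl_pair=(x.id, y.id),
                )
            )
    if config.include_diagonal:
        for g in methyls:
            peaks.append(
                ExpectedPeak(
                    experiment=exp.name,
                    atoms=_dims_to_atoms(exp, g, g),
                    probability=config.p_noe,
                    type_pair=(g.type_label, g.type_label),
                    distance=0.0,
                    methyl_pair=(g.id, g.id),
                )
            )
    return peaks


def generate_expected_geminal(
    methyls: list[MethylGroup], experiment: ExperimentDef | None = None
) -> list[ExpectedPeak]:
    """One peak per ordered geminal pair (Leu d1/d2, Val g1/g2), prob. 1."""
    exp = experiment or EXPERIMENTS["HCcCH"]
    by_id = {g.id: g for g in methyls}
    peaks: list[ExpectedPeak] = []
    for g in methyls:
        partner = by_id.get(g.geminal_partner) if g.geminal_partner else None
        if partner is None:
            continue
        peaks.append(
            ExpectedPeak(
                experiment=exp.name,
                atoms=_dims_to_atoms(exp, g, partner),
                probability=exp.probability,
                type_pair=(g.type_label, partner.type_label),
                methyl_pair=(g.id, partner.id),
            )
        )
    return peaks
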