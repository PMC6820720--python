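"""Methyl-group model built from a 3D protein structure.

A selectively protonated methyl group (CH3 in an otherwise deuterated
protein) is represented by its carbon position and the positions of its
three protons.  The inter-methyl "effective distance" is the r^-6 sum over
the nine inter-proton distances,

    d_eff = ( sum_{i=1..3} sum_{j=1..3} d_ij^-6 )^(-1/6),

which is the quantity the NOE cross-peak intensity between two rapidly
rotating methyl groups reports on.  When all nine distances are equal this
reduces to d_eff = 9^(-1/6) d = 0.693 d, so a 5 A effective cutoff admits
inter-carbon separations of up to 5.0/0.693 + 2 * 1.1 ~ 9.4 A.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "AtomRecord",
    "Structure",
    "MethylGroup",
    "METHYL_TOPOLOGY",
    "CH_BOND_LENGTH",
    "read_pdb",
    "build_methyl_protons",
    "effective_distance",
    "extract_methyl_groups",
    "parse_labeling_scheme",
]

#: Idealized aliphatic C-H bond length in Angstrom.
CH_BOND_LENGTH = 1.1

#: Ideal tetrahedral angle in degrees.
TETRAHEDRAL_ANGLE = 109.47

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

# Methyl topology per residue type: methyl carbon, bonded heavy stem atom,
# reference substituent on the stem (defines the proton torsion origin).
# Greek-letter shorthand used in labeling schemes is given alongside.
METHYL_TOPOLOGY: dict[str, list[tuple[str, str, str]]] = {
    "A": [("CB", "CA", "N")],
    "I": [("CD1", "CG1", "CB"), ("CG2", "CB", "CA")],
    "L": [("CD1", "CG", "CB"), ("CD2", "CG", "CB")],
    "V": [("CG1", "CB", "CA"), ("CG2", "CB", "CA")],
    "M": [("CE", "SD", "CG")],
    "T": [("CG2", "CB", "CA")],
}

#: Geminal methyl pairs (same side chain, stereospecific identity unknown).
GEMINAL_PAIRS = {"L": ("CD1", "CD2"), "V": ("CG1", "CG2")}

#: Greek selector -> carbon name, for labeling scheme strings like "I(d1)LV".
_SELECTORS = {
    "b": "CB", "g1": "CG1", "g2": "CG2", "d1": "CD1", "d2": "CD2", "e": "CE",
}

#: Default methyl selection per residue type (Ile: delta1 only, the common
#: biosynthetic labeling).
DEFAULT_SELECTION = {
    "A": ["CB"],
    "I": ["CD1"],
    "L": ["CD1", "CD2"],
    "V": ["CG1", "CG2"],
    "M": ["CE"],
    "T": ["CG2"],
}


@dataclass(frozen=True)
class AtomRecord:
    """One atom of the input structure (coordinates in Angstrom)."""

    element: str
    name: str
    res_number: int
    res_type: str  # one-letter code
    chain: str
    pos: tuple[float, float, float]


@dataclass
class Structure:
    """A parsed 3D structure, possibly multi-chain.

    Identical chains of a homo-multimer are kept as symmetry copies: the
    assignment problem is posed per unique subunit sequence position, since
    chemically equivalent subunits share one set of resonances.
    """

    atoms: list[AtomRecord] = field(default_factory=list)

    def chains(self) -> list[str]:
        seen: list[str] = []
        for a in self.atoms:
            if a.chain not in seen:
                seen.append(a.chain)
        return seen

    def chain_sequence(self, chain: str) -> list[tuple[int, str]]:
        """(residue number, one-letter type) pairs of one chain, in order."""
        out: list[tuple[int, str]] = []
        for a in self.atoms:
            if a.chain == chain and (not out or out[-1][0] != a.res_number):
                out.append((a.res_number, a.res_type))
        return out

    def atom(self, chain: str, res_number: int, name: str) -> AtomRecord | None:
        for a in self.atoms:
            if a.chain == chain and a.res_number == res_number and a.name == name:
                return a
        return None


def read_pdb(path) -> Structure:
    """Read ATOM/HETATM coordinate records from a PDB file.

    Alternate locations other than blank or 'A' are ignored.  Waters and
    non-polymer heteroatoms are dropped.
    """
    import gemmi

    st = gemmi.read_structure(str(path))
    st.setup_entities()
    atoms: list[AtomRecord] = []
    model = st[0]
    for chain in model:
        for residue in chain:
            res3 = residue.name.upper()
            if res3 not in THREE_TO_ONE:
                continue
            for atom in residue:
                if atom.altloc not in ("", "A", "\0"):
                    continue
                atoms.append(
                    AtomRecord(
                        element=atom.element.name,
                        name=atom.name,
                        res_number=residue.seqid.num,
                        res_type=THREE_TO_ONE[res3],
                        chain=chain.name,
                        pos=(atom.pos.x, atom.pos.y, atom.pos.z),
                    )
                )
    if not atoms:
        raise ValueError(f"no polymer ATOM records found in {path}")
    for a in atoms:
        if not np.all(np.isfinite(a.pos)):
            raise ValueError(f"non-finite coordinates for atom {a}")
    return Structure(atoms=atoms)


@dataclass
class MethylGroup:
    """One labeled 13CH3 group, possibly with symmetry copies.

    ``carbons`` has shape (k, 3) and ``protons`` (k, 3, 3) where k is the
    number of chain copies in a homo-multimer (k = 1 for a monomer).
    """

    res_number: int
    res_type: str  # one-letter
    carbon_name: str  # e.g. "CD1"
    carbons: np.ndarray
    protons: np.ndarray
    geminal_partner: str | None = None
    type_label: str = ""

    @property
    def id(self) -> str:
        return f"{self.res_number}-{self.carbon_name}"

    @property
    def proton_name(self) -> str:
        """CYANA-style pseudo-atom name for the three averaged protons."""
        return "Q" + self.carbon_name[1:]

    def __post_init__(self):
        self.carbons = np.atleast_2d(np.asarray(self.carbons, dtype=float))
        self.protons = np.asarray(self.protons, dtype=float)
        if self.protons.ndim == 2:
            self.protons = self.protons[None, :, :]
        if self.protons.shape[1:] != (3, 3):
            raise ValueError("each methyl copy needs exactly 3 protons")
        if not self.type_label:
            self.type_label = self.res_type


def build_methyl_protons(
    carbon: Sequence[float],
    stem: Sequence[float],
    reference: Sequence[float],
    bond_length: float = CH_BOND_LENGTH,
) -> np.ndarray:
    """Place three methyl protons with ideal staggered tetrahedral geometry.

    The protons sit at ``bond_length`` from the carbon, at 109.47 deg from
    the carbon-stem bond, at torsions 60/180/300 deg from the reference
    substituent on the stem.  Methyl rotation is fast on the NMR timescale;
    the r^-6 distance sum is insensitive to the torsion origin, so a single
    rotamer suffices.
    """
    c = np.asarray(carbon, dtype=float)
    s = np.asarray(stem, dtype=float)
    r = np.asarray(reference, dtype=float)
    axis = c - s
    norm = np.linalg.norm(axis)
    if norm < 1e-6:
        raise ValueError("carbon and stem coincide")
    axis /= norm
    # In-plane vector orthogonal to the C-S axis, pointing toward the
    # reference substituent.
    v = r - s
    v = v - np.dot(v, axis) * axis
    vnorm = np.linalg.norm(v)
    if vnorm < 1e-6:
        raise ValueError("degenerate geometry: reference collinear with the bond")
    v /= vnorm
    w = np.cross(axis, v)
    theta = np.deg2rad(TETRAHEDRAL_ANGLE)
    protons = []
    for tau_deg in (60.0, 180.0, 300.0):
        tau = np.deg2rad(tau_deg)
        direction = (
            np.cos(np.pi - theta) * axis
            + np.sin(np.pi - theta) * (np.cos(tau) * v + np.sin(tau) * w)
        )
        protons.append(c + bond_length * direction)
    return np.array(protons)


def effective_distance(a: MethylGroup, b: MethylGroup) -> float:
    """r^-6-summed effective distance between two methyl groups, in Angstrom.

    For symmetry copies of a homo-multimer the minimum over all copy pairs
    is returned, because any inter-copy contact produces a cross peak
    between the same pair of resonances.
    """
    if a is b or (a.id == b.id and a.res_number == b.res_number):
        raise ValueError("effective distance requires two distinct methyl groups")
    best = np.inf
    for pa in a.protons:
        for pb in b.protons:
            d = np.linalg.norm(pa[:, None, :] - pb[None, :, :], axis=-1)
            if np.any(d < 1e-9):
                raise ValueError(
                    f"coincident protons between {a.id} and {b.id}"
                )
            # summing in sorted order makes the result exactly symmetric
            deff = float(np.sum(np.sort(d.ravel() ** -6.0)) ** (-1.0 / 6.0))
            best = min(best, deff)
    return best


def parse_labeling_scheme(scheme: str) -> dict[str, list[str]]:
    """Parse a labeling scheme string into residue type -> methyl carbons.

    Grammar: residue one-letter codes, each optionally followed by a
    parenthesized comma-separated list of Greek methyl selectors, e.g.
    ``"AILV"``, ``"ILV"``, ``"I(d1)LV"``, ``"I(d1,g2)LV"``.
    """
    out: dict[str, list[str]] = {}
    i = 0
    while i < len(scheme):
        letter = scheme[i].upper()
        if letter not in METHYL_TOPOLOGY:
            raise ValueError(f"unknown residue letter {scheme[i]!r} in labeling scheme")
        i += 1
        if i < len(scheme) and scheme[i] == "(":
            j = scheme.index(")", i)
            carbons = []
            for sel in scheme[i + 1 : j].split(","):
                sel = sel.strip().lower()
                if sel not in _SELECTORS:
                    raise ValueError(f"unknown methyl selector {sel!r}")
                carbon = _SELECTORS[sel]
                valid = [m[0] for m in METHYL_TOPOLOGY[letter]]
                if carbon not in valid:
                    raise ValueError(f"residue {letter} has no methyl {carbon}")
                carbons.append(carbon)
            out[letter] = carbons
            i = j + 1
        else:
            out[letter] = list(DEFAULT_SELECTION[letter])
    return out


def _residue_protons(
    structure: Structure, chain: str, res_number: int, carbon_name: str
) -> np.ndarray | None:
    """Existing methyl protons named H<stem><1..3> (e.g. HD11..HD13), if any."""
    prefix = "H" + carbon_name[1:]
    hits = [
        a
        for a in structure.atoms
        if a.chain == chain
        and a.res_number == res_number
        and a.name.startswith(prefix)
        and a.element.upper() in ("H", "D", "")
    ]
    if len(hits) == 3:
        return np.array([h.pos for h in hits])
    return None


def extract_methyl_groups(
    structure: Structure,
    sequence: Sequence[tuple[int, str]] | Sequence[str],
    labeling: str = "AILV",
) -> list[MethylGroup]:
    """Extract the labeled methyl groups of a structure.

    ``sequence`` is either a list of one-letter residue types (numbered from
    the structure's first residue) or (residue number, type) pairs.  Chains
    with identical sequences are collapsed into symmetry copies of one set
    of methyl groups.  Hydrogens present in the structure are used verbatim;
    otherwise ideal methyl protons are constructed.
    """
    scheme = parse_labeling_scheme(labeling)
    chains = structure.chains()
    chain_seqs = {c: structure.chain_sequence(c) for c in chains}
    # Group chains by their residue-type sequence.
    ref_chain = chains[0]
    copies = [c for c in chains if
              [t for _, t in chain_seqs[c]] == [t for _, t in chain_seqs[ref_chain]]]
    if len(copies) < len(chains):
        warnings.warn(
            "structure contains chains with differing sequences; only chains "
            f"matching chain {ref_chain!r} are used as symmetry copies"
        )

    seq_map: dict[int, str] = {}
    if sequence:
        first = sequence[0]
        if isinstance(first, (tuple, list)):
            seq_map = {int(n): t.upper() for n, t in sequence}  # type: ignore[misc]
        else:
            start = chain_seqs[ref_chain][0][0]
            seq_map = {
                start + k: str(t).upper() for k, t in enumerate(sequence)
            }

    for letter in scheme:
        if seq_map and letter not in seq_map.values():
            warnings.warn(f"labeled residue type {letter} absent from sequence")

    groups: list[MethylGroup] = []
    for res_number, res_type in chain_seqs[ref_chain]:
        if seq_map:
            expected = seq_map.get(res_number)
            if expected is not None and expected != res_type:
                raise ValueError(
                    f"sequence/structure mismatch at residue {res_number}: "
                    f"sequence says {expected}, structure says {res_type}"
                )
        if res_type not in scheme:
            continue
        for carbon_name, stem_name, ref_name in METHYL_TOPOLOGY[res_type]:
            if carbon_name not in scheme[res_type]:
                continue
            carbons, protons = [], []
            for chain in copies:
                c_at = structure.atom(chain, res_number, carbon_name)
                if c_at is None:
                    raise ValueError(
                        f"residue {res_type}{res_number} (chain {chain}) is "
                        f"missing methyl carbon {carbon_name}"
                    )
                h = _residue_protons(structure, chain, res_number, carbon_name)
                if h is None:
                    s_at = structure.atom(chain, res_number, stem_name)
                    r_at = structure.atom(chain, res_number, ref_name)
                    if s_at is None or r_at is None:
                        raise ValueError(
                            f"residue {res_type}{res_number} (chain {chain}) is "
                            f"missing stem atoms for {carbon_name}"
                        )
                    h = build_methyl_protons(c_at.pos, s_at.pos, r_at.pos)
                carbons.append(c_at.pos)
                protons.append(h)
            groups.append(
                MethylGroup(
                    res_number=res_number,
                    res_type=res_type,
                    carbon_name=carbon_name,
                    carbons=np.array(carbons),
                    protons=np.array(protons),
                )
            )
    _link_geminal(groups)
    return groups


def _link_geminal(groups: Iterable[MethylGroup]) -> None:
    by_id = {g.id: g for g in groups}
    for g in by_id.values():
        pair = GEMINAL_PAIRS.get(g.res_type)
        if pair is None:
            continue
        other_name = pair[1] if g.carbon_name == pair[0] else pair[0]
        partner = by_id.get(f"{g.res_number}-{other_name}")
        if partner is not None:
            g.geminal_partner = partner.id
            partner.geminal_partner = g.id
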