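"""Shared fixtures: synthetic structures and peak lists, all generated in
memory or in tmp paths at test time."""

from __future__ import annotations

import numpy as np
import pytest

from methylassign.geometry import (
    CH_BOND_LENGTH,
    MethylGroup,
    build_methyl_protons,
)

# side-chain heavy atoms per residue type, with crude but valid internal
# offsets from CA (bond geometry only needs to be non-degenerate)
_SIDECHAINS = {
    "ALA": {"CB": (0.6, 1.3, 0.4)},
    "VAL": {"CB": (0.6, 1.3, 0.4), "CG1": (0.4, 2.6, -0.3), "CG2": (1.9, 1.8, 1.0)},
    "LEU": {"CB": (0.6, 1.3, 0.4), "CG": (0.5, 2.7, 0.1),
            "CD1": (-0.3, 3.4, 1.2), "CD2": (1.7, 3.5, -0.4)},
    "ILE": {"CB": (0.6, 1.3, 0.4), "CG1": (0.4, 2.6, -0.3), "CG2": (2.0, 1.5, 0.9),
            "CD1": (0.2, 4.0, 0.2)},
    "GLY": {},
    "MET": {"CB": (0.6, 1.3, 0.4), "CG": (0.5, 2.7, 0.1), "SD": (0.4, 3.6, 1.4),
            "CE": (1.2, 5.0, 1.2)},
    "THR": {"CB": (0.6, 1.3, 0.4), "CG2": (0.4, 2.6, -0.3)},
}


def make_pdb_text(residue_types, spacing: float = 7.0, chain: str = "A",
                  start: int = 1) -> str:
    """Synthetic PDB text with backbone N/CA and side-chain heavy atoms,
    residues spaced along x.  No hydrogens (they are built on extraction)."""
    lines = []
    serial = 1
    for k, res3 in enumerate(residue_types):
        base = np.array([spacing * k, 0.0, 0.0])
        atoms = {"N": (-1.2, 0.9, 0.1), "CA": (0.0, 0.0, 0.0)}
        atoms.update(_SIDECHAINS[res3])
        for name, off in atoms.items():
            x, y, z = base + np.array(off)
            elem = name[0] if name[0] in ("N", "C", "S", "O") else "C"
            lines.append(
                f"ATOM  {serial:5d}  {name:<3s} {res3:<3s} {chain}"
                f"{start + k:4d}    {x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00"
                f"          {elem:>2s}"
            )
            serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"


@pytest.fixture
def pdb_file(tmp_path):
    """A small 6-residue synthetic structure (A, V, L, I, G, A)."""
    path = tmp_path / "toy.pdb"
    path.write_text(make_pdb_text(["ALA", "VAL", "LEU", "ILE", "GLY", "ALA"]))
    return path


def ideal_methyl(res_number, res_type, carbon_name, position, rng,
                 geminal=None) -> MethylGroup:
    """A methyl group with ideal protons at a given carbon position."""
    pos = np.asarray(position, dtype=float)
    stem_dir = rng.normal(size=3)
    stem_dir /= np.linalg.norm(stem_dir)
    stem = pos + 1.53 * stem_dir
    ref_dir = rng.normal(size=3)
    ref_dir -= ref_dir @ stem_dir * stem_dir
    ref_dir /= np.linalg.norm(ref_dir)
    protons = build_methyl_protons(pos, stem, stem + 1.5 * ref_dir,
                                   CH_BOND_LENGTH)
    return MethylGroup(res_number=res_number, res_type=res_type,
                       carbon_name=carbon_name, carbons=np.array([pos]),
                       protons=protons, geminal_partner=geminal)


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)
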