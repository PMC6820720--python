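"""Peak lists, chemical-shift lists, and the text formats that carry them.

Supported formats:

* XEASY ``.peaks`` (read/write) — the canonical peak-list exchange format:
  a ``# Number of dimensions N`` header, then one line per peak with id,
  N ppm coordinates, color code, spectrum-type character, volume, volume
  error, integration flag, a zero, and N assignment atom ids.  Signal-to-
  noise has no standard XEASY column; this package appends it as a trailing
  ``#SN <x>`` comment token which its own reader understands.
* Sparky ``.list`` (read) — assignment label followed by ppm coordinates.
* ``.prot`` chemical-shift lists (read/write) — atom id, shift, error,
  atom name, residue number; unassigned shifts are written as 999.000.
* Plain-text sequence files (read) — one- or three-letter residues.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path

from .geometry import ONE_TO_THREE, THREE_TO_ONE

__all__ = [
    "Peak",
    "PeakList",
    "ShiftEntry",
    "ShiftList",
    "read_peaklist",
    "write_peaklist",
    "read_shifts",
    "write_shifts",
    "read_sequence",
]

#: Sentinel shift value for unassigned atoms in .prot files.
UNASSIGNED_SHIFT = 999.0


@dataclass
class Peak:
    """One measured peak: ppm coordinates plus bookkeeping."""

    id: int
    position: tuple[float, ...]
    volume: float = 0.0
    volume_error: float = 0.0
    sn: float | None = None
    assignment: tuple[int, ...] = ()
    tags: frozenset[str] = frozenset()

    def __post_init__(self):
        if self.id <= 0:
            raise ValueError("peak ids are positive integers")
        if not self.assignment:
            self.assignment = (0,) * len(self.position)


@dataclass
class PeakList:
    """A homogeneous list of peaks from one spectrum (or one split of it)."""

    dims: int
    peaks: list[Peak] = field(default_factory=list)
    name: str = ""
    experiment: str = ""
    dim_nuclei: tuple[str, ...] = ()

    def __post_init__(self):
        for p in self.peaks:
            if len(p.position) != self.dims:
                raise ValueError(
                    f"peak {p.id} has {len(p.position)} coordinates in a "
                    f"{self.dims}D list"
                )
        ids = [p.id for p in self.peaks]
        if len(ids) != len(set(ids)):
            raise ValueError(f"duplicate peak ids in list {self.name!r}")

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)

    def copy_with(self, peaks: list[Peak], name: str | None = None) -> "PeakList":
        return PeakList(
            dims=self.dims,
            peaks=peaks,
            name=self.name if name is None else name,
            experiment=self.experiment,
            dim_nuclei=self.dim_nuclei,
        )


@dataclass(frozen=True)
class ShiftEntry:
    atom_id: int
    shift: float
    error: float
    atom_name: str
    res_number: int


@dataclass
class ShiftList:
    entries: list[ShiftEntry] = field(default_factory=list)

    def __post_init__(self):
        keys = [(e.atom_name, e.res_number) for e in self.entries]
        if len(keys) != len(set(keys)):
            raise ValueError("duplicate (atom name, residue number) in shift list")

    def get(self, atom_name: str, res_number: int) -> float | None:
        for e in self.entries:
            if e.atom_name == atom_name and e.res_number == res_number:
                return e.shift if e.shift != UNASSIGNED_SHIFT else None
        return None

    def __len__(self) -> int:
        return len(self.entries)


_SPECTRUM_TYPE = {"C13HSQC": "H", "CCNOESY": "N", "C13NOESY": "N",
                  "CCNOESY3D": "N", "HCcCH": "T"}


def write_peaklist(plist: PeakList, path, fmt: str = "xeasy") -> None:
    """Write a peak list; only the XEASY dialect is emitted."""
    if fmt != "xeasy":
        raise ValueError(f"unsupported output format {fmt!r}")
    type_char = _SPECTRUM_TYPE.get(plist.experiment.split("_")[0], "U")
    lines = [f"# Number of dimensions {plist.dims}"]
    for i, nuc in enumerate(plist.dim_nuclei, start=1):
        lines.append(f"#INAME {i} {nuc}{i}")
    for p in plist.peaks:
        coords = "".join(f"{x:9.3f}" for x in p.position)
        asg = "".join(f"{a:7d}" for a in p.assignment)
        line = (
            f"{p.id:5d}{coords} 1 {type_char} "
            f"{p.volume:13.6E} {p.volume_error:13.6E} e 0{asg}"
        )
        if p.sn is not None:
            line += f" #SN {p.sn:.3f}"
        lines.append(line)
    Path(path).write_text("\n".join(lines) + "\n")


def _parse_xeasy(text: str, path) -> PeakList:
    dims = None
    nuclei: dict[int, str] = {}
    peaks: list[Peak] = []
    for ln, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        m = re.match(r"#\s*Number of dimensions\s+(\d+)", line, re.I)
        if m:
            dims = int(m.group(1))
            continue
        m = re.match(r"#INAME\s+(\d+)\s+(\S+)", line, re.I)
        if m:
            nuclei[int(m.group(1))] = m.group(2).rstrip("0123456789")
            continue
        if line.startswith("#"):
            continue
        if dims is None:
            raise ValueError(f"{path}:{ln}: peak line before dimension header")
        sn = None
        if "#SN" in line:
            line, sn_part = line.split("#SN")
            sn = float(sn_part)
        tokens = line.split()
        try:
            pid = int(tokens[0])
            coords = tuple(float(t) for t in tokens[1 : 1 + dims])
            # color, spectrum type char
            volume = float(tokens[dims + 3])
            volume_error = float(tokens[dims + 4])
            asg = tuple(int(t) for t in tokens[dims + 7 : dims + 7 + dims])
        except (ValueError, IndexError) as err:
            raise ValueError(f"{path}:{ln}: malformed XEASY peak line") from err
        if not asg:
            asg = (0,) * dims
        peaks.append(
            Peak(id=pid, position=coords, volume=volume,
                 volume_error=volume_error, sn=sn, assignment=asg)
        )
    if dims is None:
        raise ValueError(f"{path}: missing '# Number of dimensions' header")
    dim_nuclei = tuple(nuclei.get(i + 1, "") for i in range(dims)) if nuclei else ()
    return PeakList(dims=dims, peaks=peaks, name=Path(str(path)).stem,
                    dim_nuclei=dim_nuclei)


def _parse_sparky(text: str, path) -> PeakList:
    peaks: list[Peak] = []
    dims = None
    next_id = 1
    for ln, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.lower().startswith("assignment"):
            continue
        tokens = line.split()
        label = tokens[0]
        floats = []
        for t in tokens[1:]:
            try:
                floats.append(float(t))
            except ValueError:
                break
        n_label = label.count("-") + 1 if "-" in label else None
        if dims is None:
            dims = n_label if n_label and n_label <= len(floats) else len(floats)
        if len(floats) < dims:
            raise ValueError(f"{path}:{ln}: expected {dims} coordinates")
        coords = tuple(floats[:dims])
        extra = floats[dims:]
        volume = extra[0] if extra else 0.0
        sn = extra[1] if len(extra) > 1 else None
        peaks.append(Peak(id=next_id, position=coords, volume=volume, sn=sn))
        next_id += 1
    if dims is None:
        raise ValueError(f"{path}: no peaks found")
    return PeakList(dims=dims, peaks=peaks, name=Path(str(path)).stem)


def read_peaklist(path, fmt: str = "xeasy") -> PeakList:
    """Read an XEASY or Sparky peak list.

    Sparky assignment labels are parsed for dimensionality but the peaks are
    returned unassigned; reference assignments belong in evaluation inputs,
    not in the optimizer's view of the data.
    """
    text = Path(path).read_text()
    if fmt == "xeasy":
        return _parse_xeasy(text, path)
    if fmt == "sparky":
        return _parse_sparky(text, path)
    raise ValueError(f"unknown peak list format {fmt!r}")


def write_shifts(shifts: ShiftList, path) -> None:
    lines = [
        f"{e.atom_id:5d} {e.shift:9.3f} {e.error:7.3f} {e.atom_name:<6s}{e.res_number:5d}"
        for e in shifts.entries
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def read_shifts(path) -> ShiftList:
    entries: list[ShiftEntry] = []
    for ln, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        tokens = line.split()
        try:
            entries.append(
                ShiftEntry(
                    atom_id=int(tokens[0]),
                    shift=float(tokens[1]),
                    error=float(tokens[2]),
                    atom_name=tokens[3],
                    res_number=int(tokens[4]),
                )
            )
        except (ValueError, IndexError) as err:
            raise ValueError(f"{path}:{ln}: malformed shift line") from err
    return ShiftList(entries=entries)


def read_sequence(path) -> list[tuple[int, str]]:
    """Read a sequence file into (residue number, one-letter type) pairs.

    Tokens are one- or three-letter residue codes, case-insensitive.  An
    integer token sets the number of the *next* residue (so a leading start
    number or per-line numbering both work); numbering is 1-based otherwise.
    """
    counter = None
    out: list[tuple[int, str]] = []
    pending_number = None
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#")[0].strip()
        if not line:
            continue
        for token in line.split():
            if re.fullmatch(r"[+-]?\d+", token):
                n = int(token)
                if out and pending_number is None:
                    # trailing number on the residue just read: renumber it
                    num, typ = out[-1]
                    out[-1] = (n, typ)
                    counter = n + 1
                else:
                    pending_number = n
                continue
            t = token.upper()
            if len(t) == 3 and t in THREE_TO_ONE:
                code = THREE_TO_ONE[t]
            elif len(t) == 1 and t in ONE_TO_THREE:
                code = t
            else:
                raise ValueError(f"unknown residue token {token!r}")
            if pending_number is not None:
                counter = pending_number
                pending_number = None
            if counter is None:
                counter = 1
            out.append((counter, code))
            counter += 1
    if not out:
        raise ValueError(f"{path}: empty sequence")
    return out
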