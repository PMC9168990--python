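"""Glycoform nomenclature, subclass peptide backbones, and the theoretical
glycopeptide mass library.

Glycoform shorthand grammar::

    G<0|1|2> [-N | N] [F] [S | S2]

where the digit counts galactoses on the biantennary core, ``N`` adds a
bisecting GlcNAc, ``-N`` removes one antennary GlcNAc, ``F`` adds a core
fucose and ``S``/``S2`` add one/two N-acetylneuraminic acids.  All masses are
monoisotopic and glycopeptide m/z values are singly protonated ([M+H]+),
which is the species observed in positive linear-mode MALDI-TOF.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "GlycanComposition",
    "PeptideBackbone",
    "TheoreticalGlycopeptide",
    "GlycoformError",
    "parse_glycoform_name",
    "format_glycoform",
    "glycopeptide_mz",
    "build_library",
    "library_to_frame",
    "frame_to_library",
    "write_library",
    "read_library",
    "calibrant_mzs",
    "qc_target_mzs",
    "VOCABULARY",
    "SUBCLASSES",
    "BACKBONES",
]

# Monoisotopic residue masses (Da).
HEX = 162.05282
HEXNAC = 203.07937
FUC = 146.05791
NEUAC = 291.09542
WATER = 18.01056
PROTON = 1.00728

# Monoisotopic amino-acid residue masses (Da).
AA_RESIDUE_MASS = {
    "G": 57.02146, "A": 71.03711, "S": 87.03203, "P": 97.05276,
    "V": 99.06841, "T": 101.04768, "C": 103.00919, "L": 113.08406,
    "I": 113.08406, "N": 114.04293, "D": 115.02694, "Q": 128.05858,
    "K": 128.09496, "E": 129.04259, "M": 131.04049, "H": 137.05891,
    "F": 147.06841, "R": 156.10111, "Y": 163.06333, "W": 186.07931,
}

#: The 22 glycoform names of the derived-trait vocabulary, grouped by
#: galactosylation degree.
G0_NAMES = ("G0", "G0F", "G0N", "G0NF", "G0-NF")
G1_NAMES = ("G1", "G1F", "G1FS", "G1-N", "G1N", "G1NF", "G1-NF", "G1NFS", "G1S")
G2_NAMES = ("G2", "G2F", "G2FS", "G2N", "G2NF", "G2NFS", "G2S", "G2S2")
VOCABULARY: tuple[str, ...] = G0_NAMES + G1_NAMES + G2_NAMES

SUBCLASSES = ("IgG1", "IgG2", "IgG3/4")


class GlycoformError(ValueError):
    """Raised for glycoform names outside the shorthand grammar."""


@dataclass(frozen=True)
class GlycanComposition:
    """Monosaccharide composition decoded from a shorthand glycoform name."""

    hex: int
    hexnac: int
    fuc: int
    neuac: int
    name: str

    def __post_init__(self) -> None:
        for field in ("hex", "hexnac", "fuc", "neuac"):
            if getattr(self, field) < 0:
                raise GlycoformError(f"negative {field} count in {self.name!r}")

    @property
    def residue_mass(self) -> float:
        """Summed monosaccharide residue mass (Da)."""
        return (
            self.hex * HEX
            + self.hexnac * HEXNAC
            + self.fuc * FUC
            + self.neuac * NEUAC
        )


@dataclass(frozen=True)
class PeptideBackbone:
    """Tryptic Fc peptide moiety of one IgG subclass."""

    subclass: str
    sequence: str

    @property
    def residue_mass_sum(self) -> float:
        return sum(AA_RESIDUE_MASS[aa] for aa in self.sequence)


# IgG3 (EEQYNSTFR) and IgG4 (EEQFNSTYR) are isomers and are treated as one
# class; either sequence gives the same residue-mass sum.
BACKBONES = {
    "IgG1": PeptideBackbone("IgG1", "EEQYNSTYR"),
    "IgG2": PeptideBackbone("IgG2", "EEQFNSTFR"),
    "IgG3/4": PeptideBackbone("IgG3/4", "EEQYNSTFR"),
}


@dataclass(frozen=True)
class TheoreticalGlycopeptide:
    """One (subclass, glycoform) library entry with its theoretical [M+H]+."""

    backbone: PeptideBackbone
    glycan: GlycanComposition
    mz_theoretical: float
    overlapped: bool = False

    @property
    def key(self) -> tuple[str, str]:
        return (self.backbone.subclass, self.glycan.name)


_NAME_RE = re.compile(r"^G(?P<gal>\d)(?P<bisect>-N|N)?(?P<fuc>F)?(?P<sial>S2|S)?$")


def parse_glycoform_name(name: str) -> GlycanComposition:
    """Decode a shorthand glycoform name into monosaccharide counts.

    Raises
    ------
    GlycoformError
        If the name is outside the grammar ``G<0|1|2> [-N|N] [F] [S|S2]``.
    """
    m = _NAME_RE.match(name)
    if m is None:
        raise GlycoformError(f"unparseable glycoform name {name!r}")
    gal = int(m.group("gal"))
    if gal > 2:
        raise GlycoformError(f"galactose digit {gal} > 2 in {name!r}")
    bisect = m.group("bisect")
    hexnac = 4 + (1 if bisect == "N" else 0) - (1 if bisect == "-N" else 0)
    fuc = 1 if m.group("fuc") else 0
    sial = m.group("sial")
    neuac = {None: 0, "S": 1, "S2": 2}[sial]
    return GlycanComposition(hex=3 + gal, hexnac=hexnac, fuc=fuc, neuac=neuac, name=name)


def format_glycoform(comp: GlycanComposition) -> str:
    """Inverse of :func:`parse_glycoform_name`."""
    if comp.hex not in (3, 4, 5):
        raise GlycoformError(f"hex count {comp.hex} outside vocabulary")
    if comp.hexnac not in (3, 4, 5):
        raise GlycoformError(f"hexnac count {comp.hexnac} outside vocabulary")
    out = f"G{comp.hex - 3}"
    if comp.hexnac == 5:
        out += "N"
    elif comp.hexnac == 3:
        out += "-N"
    if comp.fuc:
        out += "F"
    if comp.neuac == 1:
        out += "S"
    elif comp.neuac == 2:
        out += "S2"
    return out


def glycopeptide_mz(
    backbone: PeptideBackbone,
    glycan: GlycanComposition,
    adduct: str = "proton",
) -> float:
    """Theoretical monoisotopic m/z of the singly protonated glycopeptide."""
    if adduct != "proton":
        raise ValueError(f"unsupported adduct {adduct!r}")
    return backbone.residue_mass_sum + WATER + glycan.residue_mass + PROTON


def build_library(
    glycoform_names: Sequence[str] | None = None,
    subclasses: Sequence[str] | None = None,
    overlap_tol: float = 1.0,
) -> list[TheoreticalGlycopeptide]:
    """Build the annotated theoretical library, sorted by m/z.

    IgG3/4 entries falling within ``overlap_tol`` Da of any IgG1 or IgG2
    entry are flagged ``overlapped`` (those signals cannot be attributed to
    IgG3/4 in a linear-mode spectrum and are ignored downstream).
    """
    names = tuple(glycoform_names) if glycoform_names is not None else VOCABULARY
    subs = tuple(subclasses) if subclasses is not None else SUBCLASSES
    seen: set[tuple[str, str]] = set()
    entries: list[TheoreticalGlycopeptide] = []
    for sub in subs:
        if sub not in BACKBONES:
            raise GlycoformError(f"unknown subclass {sub!r}")
        backbone = BACKBONES[sub]
        for name in names:
            key = (sub, name)
            if key in seen:
                raise GlycoformError(f"duplicate library entry {key}")
            seen.add(key)
            glycan = parse_glycoform_name(name)
            entries.append(
                TheoreticalGlycopeptide(backbone, glycan, glycopeptide_mz(backbone, glycan))
            )
    major = [e.mz_theoretical for e in entries if e.backbone.subclass != "IgG3/4"]
    flagged: list[TheoreticalGlycopeptide] = []
    for e in entries:
        overlapped = e.backbone.subclass == "IgG3/4" and any(
            abs(e.mz_theoretical - m) <= overlap_tol for m in major
        )
        flagged.append(
            TheoreticalGlycopeptide(e.backbone, e.glycan, e.mz_theoretical, overlapped)
        )
    flagged.sort(key=lambda e: e.mz_theoretical)
    return flagged


#: Internal calibrants: (subclass, glycoform) whose theoretical masses match
#: the instrument-method calibration list (~2602.1, 2796.1, 2958.2, 3217.3).
CALIBRANT_KEYS = (
    ("IgG2", "G0F"),
    ("IgG1", "G1F"),
    ("IgG1", "G2F"),
    ("IgG2", "G2FS"),
)

#: QC repeatability targets: six minor components
#: (~2602.1, 2634.0, 2764.1, 2796.1, 2926.2, 2958.2).
QC_TARGET_KEYS = (
    ("IgG2", "G0F"),
    ("IgG1", "G0F"),
    ("IgG2", "G1F"),
    ("IgG1", "G1F"),
    ("IgG2", "G2F"),
    ("IgG1", "G2F"),
)


def _keyed_mzs(keys: Iterable[tuple[str, str]]) -> list[float]:
    return [
        glycopeptide_mz(BACKBONES[sub], parse_glycoform_name(name)) for sub, name in keys
    ]


def calibrant_mzs() -> list[float]:
    """Theoretical m/z of the four internal calibrants, ascending."""
    return sorted(_keyed_mzs(CALIBRANT_KEYS))


def qc_target_mzs() -> list[float]:
    """Theoretical m/z of the six repeatability QC targets, ascending."""
    return sorted(_keyed_mzs(QC_TARGET_KEYS))


def library_to_frame(library: Sequence[TheoreticalGlycopeptide]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "subclass": [e.backbone.subclass for e in library],
            "glycoform": [e.glycan.name for e in library],
            "hex": [e.glycan.hex for e in library],
            "hexnac": [e.glycan.hexnac for e in library],
            "fuc": [e.glycan.fuc for e in library],
            "neuac": [e.glycan.neuac for e in library],
            "mz": [e.mz_theoretical for e in library],
            "overlapped": [e.overlapped for e in library],
        }
    )


def frame_to_library(frame: pd.DataFrame) -> list[TheoreticalGlycopeptide]:
    entries = []
    for row in frame.itertuples(index=False):
        backbone = BACKBONES[row.subclass]
        glycan = parse_glycoform_name(row.glycoform)
        entries.append(
            TheoreticalGlycopeptide(backbone, glycan, float(row.mz), bool(row.overlapped))
        )
    return entries


def write_library(library: Sequence[TheoreticalGlycopeptide], path: str | Path) -> None:
    library_to_frame(library).to_csv(path, index=False)


def read_library(path: str | Path) -> list[TheoreticalGlycopeptide]:
    return frame_to_library(pd.read_csv(path))
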