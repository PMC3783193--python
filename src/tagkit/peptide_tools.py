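"""Protein-level sequence operations for the C-terminal tagging system.

The tag fused to a bait protein is Quant-remnant + TEV cleavage site +
reporter (protein A, FLAG or EGFP). TEV protease elutes the bait from the
affinity resin and leaves an 11-residue remnant (KLAADITSLYK + ENLYFQ) on
the bait; trypsin then releases the 10-residue Quant peptide LAADITSLYK
in 1:1 stoichiometry with the bait, enabling absolute quantification
against a heavy-lysine-labelled internal standard.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

from .errors import SequenceError

#: Monoisotopic residue masses (Da), standard 20 amino acids.
RESIDUE_MONO = {
    "G": 57.02146, "A": 71.03711, "S": 87.03203, "P": 97.05276,
    "V": 99.06841, "T": 101.04768, "C": 103.00919, "L": 113.08406,
    "I": 113.08406, "N": 114.04293, "D": 115.02694, "Q": 128.05858,
    "K": 128.09496, "E": 129.04259, "M": 131.04049, "H": 137.05891,
    "F": 147.06841, "R": 156.10111, "Y": 163.06333, "W": 186.07931,
}

WATER_MONO = 18.010565
PROTON_MONO = 1.007276

#: Residue elemental composition (C, H, N, O, S), for isotope-label checks.
RESIDUE_FORMULA = {
    "G": (2, 3, 1, 1, 0), "A": (3, 5, 1, 1, 0), "S": (3, 5, 1, 2, 0),
    "P": (5, 7, 1, 1, 0), "V": (5, 9, 1, 1, 0), "T": (4, 7, 1, 2, 0),
    "C": (3, 5, 1, 1, 1), "L": (6, 11, 1, 1, 0), "I": (6, 11, 1, 1, 0),
    "N": (4, 6, 2, 2, 0), "D": (4, 5, 1, 3, 0), "Q": (5, 8, 2, 2, 0),
    "K": (6, 12, 2, 1, 0), "E": (5, 7, 1, 3, 0), "M": (5, 9, 1, 1, 1),
    "H": (6, 7, 3, 1, 0), "F": (9, 9, 1, 1, 0), "R": (6, 12, 4, 1, 0),
    "Y": (9, 9, 1, 2, 0), "W": (11, 10, 2, 1, 0),
}
_ELEMENT_INDEX = {"C": 0, "H": 1, "N": 2, "O": 3, "S": 4}

#: Monoisotopic mass difference heavy-isotope minus light, per atom.
ISOTOPE_DELTA = {
    "13C": 13.0033548378 - 12.0,
    "15N": 15.0001088989 - 14.0030740048,
    "2H": 2.0141017781 - 1.0078250319,
    "18O": 17.9991604 - 15.9949146221,
}

_LABEL_TOKEN = re.compile(r"(\d+[A-Z][a-z]?)(\d*)")


@dataclass
class Peptide:
    """An amino-acid sequence with optional fixed modifications
    (position, monoisotopic mass shift in Da, label)."""

    sequence: str
    mods: list[tuple[int, float, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        bad = set(self.sequence) - set(RESIDUE_MONO)
        if bad:
            raise SequenceError(f"unknown residues {sorted(bad)} in peptide")
        for pos, shift, _label in self.mods:
            if not 0 <= pos < len(self.sequence):
                raise SequenceError(f"modification position {pos} outside peptide")
            if not shift == shift or shift in (float("inf"), float("-inf")):
                raise SequenceError("modification mass shift must be finite")

    def __len__(self) -> int:
        return len(self.sequence)


def tev_cleave(protein: str, motif: str = "ENLYFQ", p1_prime: str = "GS") -> list[str]:
    """Cut after the Q of every recognition motif occurrence (ENLYFQ|G or
    ENLYFQ|S by default). The fragments concatenate back to the input;
    a protein without the motif is returned intact."""
    cuts = [
        m.end()
        for m in re.finditer(re.escape(motif), protein)
        if m.end() < len(protein) and protein[m.end()] in p1_prime
    ]
    frags, prev = [], 0
    for c in cuts:
        frags.append(protein[prev:c])
        prev = c
    frags.append(protein[prev:])
    return frags


def tryptic_digest(protein: str, missed: int = 0) -> list[Peptide]:
    """Trypsin digestion: cleave C-terminal of K or R except before P
    (Keil rule). ``missed`` > 0 additionally returns every concatenation
    of up to ``missed``+1 adjacent fully-cleaved peptides."""
    if missed < 0:
        raise ValueError("missed cleavages must be >= 0")
    cuts = [
        i + 1
        for i, aa in enumerate(protein)
        if aa in "KR" and (i + 1 == len(protein) or protein[i + 1] != "P")
    ]
    bounds = [0] + [c for c in cuts if c < len(protein)] + [len(protein)]
    pieces = [protein[a:b] for a, b in zip(bounds, bounds[1:])]
    out = []
    for span in range(1, missed + 2):
        for i in range(len(pieces) - span + 1):
            out.append(Peptide("".join(pieces[i : i + span])))
    return out


def monoisotopic_mass(peptide: Peptide | str) -> float:
    """Sum of residue monoisotopic masses + one water + modification
    shifts; deterministic to 1e-4 Da."""
    if isinstance(peptide, str):
        peptide = Peptide(peptide)
    mass = WATER_MONO + sum(RESIDUE_MONO[aa] for aa in peptide.sequence)
    mass += sum(shift for _pos, shift, _label in peptide.mods)
    return mass


def mz(peptide: Peptide | str, charge: int) -> float:
    if charge < 1:
        raise ValueError("charge must be >= 1")
    return (monoisotopic_mass(peptide) + charge * PROTON_MONO) / charge


def heavy_label_shift(residue: str, label: str) -> float:
    """Exact monoisotopic mass shift for a stable-isotope label on one
    residue, e.g. ``heavy_label_shift("K", "13C6 15N2")`` -> 8.0142 Da
    (printed as +8 Da).

    The label string lists isotopes with atom counts; each count must not
    exceed the residue's elemental composition.
    """
    if residue not in RESIDUE_FORMULA:
        raise SequenceError(f"unknown residue {residue!r}")
    if not label.strip():
        return 0.0
    formula = RESIDUE_FORMULA[residue]
    shift = 0.0
    for token in re.split(r"[,\s;]+", label.strip()):
        if not token:
            continue
        m = re.fullmatch(r"(\d+)([A-Z][a-z]?)(\d*)", token)
        if m is None:
            raise ValueError(f"malformed isotope token {token!r}")
        iso = m.group(1) + m.group(2)
        count = int(m.group(3) or 1)
        if iso not in ISOTOPE_DELTA:
            raise ValueError(f"no isotope table entry for {iso}")
        element = m.group(2)
        if element not in _ELEMENT_INDEX:
            raise ValueError(f"element {element} not tracked for residues")
        available = formula[_ELEMENT_INDEX[element]]
        if count > available:
            raise ValueError(
                f"label {token} needs {count} {element} atoms but {residue} has {available}"
            )
        shift += count * ISOTOPE_DELTA[iso]
    return shift


@dataclass
class TagArchitecture:
    """Layout of the C-terminal tag: quantification remnant, TEV site,
    reporter. The remnant stays on the bait after TEV elution; its tryptic
    product is the Quant peptide."""

    quant_remnant: str = "KLAADITSLYK"
    tev_site: str = "ENLYFQG"
    reporter: str = "EGFP"

    @property
    def tev_motif(self) -> str:
        """Recognition motif up to the scissile bond (P6..P1)."""
        return self.tev_site[:-1]

    @property
    def quant_peptide(self) -> str:
        """The unique tryptic reporter peptide of the remnant."""
        peptides = tryptic_digest(self.quant_remnant)
        return max((p.sequence for p in peptides), key=len)

    def tag_protein(self, reporter_seq: str) -> str:
        return self.quant_remnant + self.tev_site + reporter_seq

    def build_fusion(self, bait: str, reporter_seq: str) -> str:
        return bait + self.tag_protein(reporter_seq)


def extract_quant_peptide(arch: TagArchitecture, fusion: str) -> Peptide:
    """TEV cleavage followed by tryptic digestion of a tagged fusion;
    returns the peptide in 1:1 stoichiometry with the bait.

    Exactly one copy per fusion molecule is expected; a bait that happens
    to contain the Quant peptide internally produces extra copies and
    triggers a non-uniqueness warning.
    """
    fragments = tev_cleave(fusion, motif=arch.tev_motif, p1_prime=arch.tev_site[-1])
    bait_side = [f for f in fragments if f.endswith(arch.quant_remnant + arch.tev_motif)]
    if not bait_side:
        raise SequenceError("fusion does not contain the tag architecture")
    target = arch.quant_peptide
    count = 0
    for frag in fragments:
        count += sum(1 for p in tryptic_digest(frag) if p.sequence == target)
    if count != 1:
        warnings.warn(
            f"non-unique quant peptide: {count} copies of {target} per fusion molecule",
            stacklevel=2,
        )
    return Peptide(target)
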