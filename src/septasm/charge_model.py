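"""Net-charge arithmetic for septin terminal extensions.

The N- and C-terminal extensions of the yeast septins are unresolved in
crystal structures, but their sequence composition fixes their net charge:
Asp/Glu count -1, Lys/Arg +1, everything else 0 (His configurable, default
neutral; set ``histidine_charge=+1`` for a fully protonated, low-pH view).
Along a palindromic filament (rod order Cdc11-Cdc12-Cdc3-Cdc10-Cdc10-Cdc3-
Cdc12-Cdc11) the per-subunit terminal charges produce an alternating sign
pattern on each face — a candidate electrostatic code for lipid binding on
the C-terminal face and filament pairing on the N-terminal face.

The terminal-extension boundaries are user input: this module ships no
hard-coded residue ranges.
"""

from __future__ import annotations

from dataclasses import dataclass, field

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class ChargeScheme:
    """Integer per-residue charges: D/E -> -1, K/R -> +1, H configurable."""

    histidine_charge: int = 0
    include_termini: bool = False  # +1 N-terminus / -1 C-terminus if True

    def __post_init__(self) -> None:
        if self.histidine_charge not in (-1, 0, 1):
            raise ValueError("histidine_charge must be one of -1, 0, +1")

    def charge_of(self, residue: str) -> int:
        if residue in "DE":
            return -1
        if residue in "KR":
            return +1
        if residue == "H":
            return self.histidine_charge
        return 0


def net_charge(seq: str, scheme: ChargeScheme | None = None) -> int:
    """Sum of per-residue charges of an amino-acid sequence.

    Accepts the 20-letter alphabet plus X (unknown, charge 0).  Illegal
    characters raise a ValueError naming the offending position (1-based).
    """
    if scheme is None:
        scheme = ChargeScheme()
    total = 0
    for i, ch in enumerate(seq.upper()):
        if ch == "X":
            continue
        if ch not in AMINO_ACIDS:
            raise ValueError(
                f"illegal residue {ch!r} at position {i + 1}"
            )
        total += scheme.charge_of(ch)
    if scheme.include_termini and len(seq) > 0:
        total += 1 - 1  # amino (+1) and carboxyl (-1) termini cancel
    return total


@dataclass
class SubunitCharges:
    """Terminal-extension net charges of one septin subunit."""

    name: str
    n_charge: int
    c_charge: int


#: Published terminal-extension net charges (Cdc12 termini not printed; 0 assumed).
PUBLISHED_CHARGES = {
    "Cdc3": SubunitCharges("Cdc3", n_charge=-12, c_charge=+9),
    "Cdc11": SubunitCharges("Cdc11", n_charge=+5, c_charge=-4),
    "Cdc10": SubunitCharges("Cdc10", n_charge=-3, c_charge=+2),
    "Cdc12": SubunitCharges("Cdc12", n_charge=0, c_charge=0),
}

PALINDROME = ("Cdc11", "Cdc12", "Cdc3", "Cdc10", "Cdc10", "Cdc3", "Cdc12", "Cdc11")


def published_rod() -> list:
    """The palindromic rod assembled from the published terminal charges."""
    return [PUBLISHED_CHARGES[name] for name in PALINDROME]


@dataclass
class ChargePattern:
    """Per-face charge profile along an n-rod filament.

    ``n_face[k]`` / ``c_face[k]`` is the terminal charge of subunit k
    (8 per rod).  ``blocks(face)`` summarizes contiguous same-sign runs.
    """

    subunit_names: list
    n_face: list
    c_face: list
    warnings: list = field(default_factory=list)

    def blocks(self, face: str) -> list:
        """Sign blocks of one face: (sign, start, end_exclusive, total)."""
        charges = {"N": self.n_face, "C": self.c_face}[face.upper()]
        out = []
        i = 0
        while i < len(charges):
            if charges[i] == 0:
                i += 1
                continue
            sign = 1 if charges[i] > 0 else -1
            j = i
            total = 0
            while j < len(charges) and (charges[j] == 0 or (charges[j] > 0) == (sign > 0)):
                # zeros inside a run do not break it unless followed by a flip
                if charges[j] != 0 and (charges[j] > 0) != (sign > 0):
                    break
                total += charges[j]
                j += 1
            # trim trailing zeros out of the block
            k = j
            while k > i and charges[k - 1] == 0:
                k -= 1
            out.append((sign, i, k, sum(charges[i:k])))
            i = j
        return out

    def alternating(self, face: str) -> bool:
        """True if consecutive sign blocks on the face alternate in sign."""
        bl = self.blocks(face)
        return len(bl) >= 2 and all(
            bl[i][0] != bl[i + 1][0] for i in range(len(bl) - 1)
        )


def filament_charge_pattern(rod: list, n_rods: int) -> ChargePattern:
    """Concatenate per-subunit terminal charges along an n-rod filament.

    ``rod`` is the ordered list of 8 :class:`SubunitCharges`; a
    non-palindromic order is accepted with a recorded warning.  With the
    published charges the C-terminal face alternates between positive
    blocks over the central Cdc3-Cdc10-Cdc10-Cdc3 tetramers and negative
    blocks at the Cdc11-Cdc11 rod junctions (and inverted on the N face).
    """
    if len(rod) != 8:
        raise ValueError("a rod must list exactly 8 subunits")
    if n_rods < 1:
        raise ValueError("n_rods must be >= 1")
    warnings = []
    names = [s.name for s in rod]
    if names != names[::-1]:
        warnings.append("rod subunit order is not palindromic")
    sub_names, n_face, c_face = [], [], []
    for _ in range(n_rods):
        for s in rod:
            sub_names.append(s.name)
            n_face.append(s.n_charge)
            c_face.append(s.c_charge)
    return ChargePattern(subunit_names=sub_names, n_face=n_face,
                         c_face=c_face, warnings=warnings)
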