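"""Mass and charge accounting for synthetic peptide constructs.

Models the chemistry of custom-synthesized peptides as used in amyloid
binding studies: a core sequence of the 20 standard amino acids, an
optionally amidated C-terminus, N-terminal adducts coupled through amide
bonds (beta-alanine spacers, biotin, acetyl caps, a DOTA chelator macrocycle
for lanthanide loading), and intramolecular disulfide bridges.

Average (not monoisotopic) masses are used throughout because synthesis
certificates report average molecular mass.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

__all__ = [
    "PeptideConstruct",
    "average_mass",
    "net_charge",
    "sequence_length",
    "RESIDUE_MASS",
    "ADDUCT_DELTA",
    "IAPP_SEQUENCE",
]

# Average residue masses (Da), standard 20 amino acids (residue = amino acid
# minus water, i.e. the in-chain mass). ExPASy convention.
RESIDUE_MASS: dict[str, float] = {
    "G": 57.0519, "A": 71.0788, "S": 87.0782, "P": 97.1167, "V": 99.1326,
    "T": 101.1051, "C": 103.1388, "L": 113.1594, "I": 113.1594,
    "N": 114.1038, "D": 115.0886, "Q": 128.1307, "K": 128.1741,
    "E": 129.1155, "M": 131.1926, "H": 137.1411, "F": 147.1766,
    "R": 156.1875, "Y": 163.1760, "W": 186.2132,
}

WATER = 18.01524
# OH -> NH2 on the C-terminal carboxyl.
AMIDATION_DELTA = -0.98476
# two S-H hydrogens lost per S-S bond
DISULFIDE_DELTA = -2.01588

# Mass added per N-terminal adduct: average mass of the free molecule minus
# one water for the amide bond formed.  beta-alanine behaves exactly like a
# residue; biotin couples through its valeric acid arm; DOTA through one of
# its four acetate arms (mono-amide linkage).
ADDUCT_DELTA: dict[str, float] = {
    "beta_alanine": 71.0788,            # H2N-CH2-CH2-COOH (89.09) - H2O
    "biotinyl": 244.31 - WATER,         # biotin C10H16N2O3S
    "acetyl": 42.0367,                  # CH3CO-
    "dota": 404.42 - WATER,             # C16H28N4O8 tetraacetic macrocycle
}

# 37-residue human islet amyloid polypeptide (amylin)
IAPP_SEQUENCE = "KCNTATCATQRLANFLVHSSNNFGAILSSTNVGSNTY"


@dataclass(frozen=True)
class PeptideConstruct:
    """A synthesized peptide: core sequence plus covalent modifications.

    Parameters
    ----------
    sequence:
        One-letter core sequence (standard 20 amino acids only).
    c_term:
        ``"free_acid"`` or ``"amide"`` (C-terminal amidation).
    n_term_adducts:
        Ordered adduct names, outermost first, e.g.
        ``("biotinyl", "beta_alanine", "beta_alanine")`` for
        biotinyl-[β-Ala]-[β-Ala]-peptide. Names must be in
        :data:`ADDUCT_DELTA`.
    disulfides:
        Pairs of 1-based residue indices bridged by S-S bonds; both
        partners must be cysteine.
    """

    sequence: str
    c_term: str = "free_acid"
    n_term_adducts: tuple[str, ...] = ()
    disulfides: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("sequence must be non-empty")
        for pos, aa in enumerate(self.sequence, start=1):
            if aa not in RESIDUE_MASS:
                raise ValueError(f"unknown residue {aa!r} at position {pos}")
        if self.c_term not in ("free_acid", "amide"):
            raise ValueError(f"unknown c_term {self.c_term!r}")
        for name in self.n_term_adducts:
            if name not in ADDUCT_DELTA:
                raise ValueError(f"unknown adduct {name!r}")
        for i, j in self.disulfides:
            for k in (i, j):
                if not (1 <= k <= len(self.sequence)):
                    raise ValueError(f"disulfide index {k} out of range")
                if self.sequence[k - 1] != "C":
                    raise ValueError(
                        f"disulfide partner at position {k} is "
                        f"{self.sequence[k - 1]!r}, not cysteine"
                    )


def average_mass(p: PeptideConstruct) -> float:
    """Average molecular mass in Da.

    Sum of average residue masses plus one water, with corrections for
    C-terminal amidation (−0.985 Da), each disulfide bond (−2.016 Da) and
    each N-terminal adduct (its registered delta, which already accounts
    for the water lost in amide-bond formation).  Report to 0.1 Da, the
    precision of synthesis certificates; the unrounded value is returned
    so mass differences stay exact.
    """
    mass = sum(RESIDUE_MASS[aa] for aa in p.sequence) + WATER
    if p.c_term == "amide":
        mass += AMIDATION_DELTA
    mass += DISULFIDE_DELTA * len(p.disulfides)
    mass += sum(ADDUCT_DELTA[name] for name in p.n_term_adducts)
    return mass


def net_charge(p: PeptideConstruct, convention: str = "side_chain") -> int:
    """Formal net charge at neutral pH.

    ``side_chain`` (default): Arg/Lys +1, Asp/Glu −1, His neutral, termini
    ignored — the convention under which a peptide's sequence charge is
    quoted irrespective of terminal chemistry.  ``full`` additionally counts
    a free (unmodified) N-terminus as +1 and a free-acid C-terminus as −1;
    amidation or any N-terminal adduct neutralizes the respective terminus.
    """
    if convention not in ("side_chain", "full"):
        raise ValueError(f"unknown charge convention {convention!r}")
    charge = 0
    for aa in p.sequence:
        if aa in ("K", "R"):
            charge += 1
        elif aa in ("D", "E"):
            charge -= 1
    if convention == "full":
        if not p.n_term_adducts:
            charge += 1
        if p.c_term == "free_acid":
            charge -= 1
    return charge


def sequence_length(p: PeptideConstruct) -> int:
    """Number of core residues; N-terminal adducts are not counted."""
    return len(p.sequence)


def human_iapp(biotinylated: bool = False, dota: bool = False) -> PeptideConstruct:
    """The human IAPP constructs used in chaperone-binding work.

    Amidated C-terminus and a Cys2–Cys7 disulfide; optionally an N-terminal
    biotinyl-[β-Ala]-[β-Ala]- tag (for BLI sensor immobilization) or a
    DOTA-[β-Ala]-[β-Ala]- tag (for paramagnetic lanthanide loading).
    """
    if biotinylated and dota:
        raise ValueError("construct carries either biotin or DOTA, not both")
    adducts: tuple[str, ...] = ()
    if biotinylated:
        adducts = ("biotinyl", "beta_alanine", "beta_alanine")
    elif dota:
        adducts = ("dota", "beta_alanine", "beta_alanine")
    return PeptideConstruct(
        sequence=IAPP_SEQUENCE,
        c_term="amide",
        n_term_adducts=adducts,
        disulfides=((2, 7),),
    )
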