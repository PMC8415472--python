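"""Physico-chemical amino-acid properties and sequence encoding.

The central primitive of the package: an aligned protein sequence (letters
over the 20 standard residues plus the gap symbol) is rewritten as a *number
string* — the vector of one measured physico-chemical property per position,
with gaps encoded as 0.  Every downstream analysis (distance trees,
correlation, mutual information, fractal dimension, wavelets) operates on
these number strings.

The embedded table holds 12 measured properties for the 20 standard amino
acids: molecular mass (Da), solvent-accessible surface (Å²), volume (Å³),
hydropathy index, hydrophobicity, water solubility (g/kg H₂O), the
octanol–interface / octanol / interface free-energy transfer scales
(kcal/mol), isoelectric point at 25 °C, and the pKa of the α-amino and
α-carboxyl groups.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

__all__ = [
    "PROPERTY_NAMES",
    "DEFAULT_PROPERTIES",
    "BOXDIM_PROPERTIES",
    "PROPERTY_UNITS",
    "RESIDUES",
    "GAP",
    "PropertyTable",
    "GappedSequence",
    "EncodedSequence",
    "load_property_table",
    "encode_sequence",
    "encode_alignment",
    "decode_sequence",
    "property_table_tsv",
    "load_property_table_tsv",
]

GAP = "-"

RESIDUES = "ACDEFGHIKLMNPQRSTVWY"

PROPERTY_NAMES: Tuple[str, ...] = (
    "molecular_mass",
    "surface",
    "volume",
    "hydropathy_index",
    "hydrophobicity",
    "solubility",
    "octanol_interface",
    "octanol",
    "interface",
    "pI_25C",
    "pKa_NH2",
    "pKa_COOH",
)

#: The five properties used by default for encoding, trees, correlation and AMI.
DEFAULT_PROPERTIES: Tuple[str, ...] = (
    "volume",
    "hydropathy_index",
    "solubility",
    "octanol_interface",
    "pI_25C",
)

#: The three properties used by default for the box-counting dimension.
BOXDIM_PROPERTIES: Tuple[str, ...] = ("volume", "pI_25C", "solubility")

PROPERTY_UNITS: Dict[str, str] = {
    "molecular_mass": "Da",
    "surface": "Å²",
    "volume": "Å³",
    "hydropathy_index": "dimensionless",
    "hydrophobicity": "dimensionless",
    "solubility": "g/kg H₂O",
    "octanol_interface": "kcal/mol",
    "octanol": "kcal/mol",
    "interface": "kcal/mol",
    "pI_25C": "pH units",
    "pKa_NH2": "pH units",
    "pKa_COOH": "pH units",
}

# One row per residue, columns in PROPERTY_NAMES order.  Keyed by the
# unambiguous one-letter code.
_TABLE: Dict[str, Tuple[float, ...]] = {
    #     mass     surf  vol    hydro  hphob  solub  oct-if octan  interf pI     pKaNH2 pKaCOOH
    "A": (89.094, 115, 88.6, 1.8, 0.616, 166.9, 0.33, 0.5, 0.17, 6.11, 9.87, 2.35),
    "R": (174.203, 225, 173.4, -4.5, 0.0, 182.6, 1.0, 1.81, 0.81, 10.76, 9.09, 2.18),
    "N": (132.119, 150, 111.1, -3.5, 0.236, 25.1, 0.43, 0.85, 0.42, 10.76, 8.8, 2.02),
    "D": (133.104, 160, 114.1, -3.5, 0.028, 5.04, 2.41, 3.64, 1.23, 2.98, 9.6, 1.88),
    "C": (121.154, 135, 108.5, 2.5, 0.68, 277.0, 0.22, -0.02, -0.24, 5.02, 10.78, 1.71),
    "E": (147.131, 190, 138.4, -3.5, 0.043, 8.6, 0.19, 0.77, 0.58, 3.08, 9.67, 2.19),
    "Q": (146.146, 180, 143.8, -3.5, 0.251, 42.0, 1.61, 3.63, 2.02, 5.65, 9.13, 2.17),
    "G": (75.067, 75, 60.1, -0.4, 0.501, 239.0, 1.14, 1.15, 0.01, 6.06, 9.6, 2.34),
    "H": (155.156, 195, 153.2, -3.2, 0.165, 43.5, 1.37, 2.33, 0.96, 7.64, 8.97, 1.78),
    "I": (131.175, 175, 166.7, 4.5, 0.943, 34.2, -0.81, -1.12, -0.31, 6.04, 9.76, 2.32),
    "L": (131.175, 170, 166.7, 3.8, 0.943, 23.8, -0.69, -1.25, -0.56, 6.04, 9.6, 2.36),
    "K": (146.189, 200, 168.6, -3.9, 0.283, 5.8, 1.81, 2.8, 0.99, 9.47, 10.28, 2.18),
    "M": (149.208, 185, 162.9, 1.9, 0.738, 56.0, -0.44, -0.67, -0.23, 5.74, 9.21, 2.28),
    "F": (165.192, 210, 189.9, 2.8, 1.0, 27.9, -0.58, -1.71, -1.13, 5.91, 9.24, 2.58),
    "P": (115.132, 145, 112.7, -1.6, 0.711, 50.0, -0.31, 0.14, 0.45, 6.3, 10.6, 1.99),
    "S": (105.093, 115, 89.0, -0.8, 0.359, 250.0, 0.33, 0.46, 0.13, 5.68, 9.15, 2.21),
    "T": (119.119, 140, 116.1, -0.7, 0.45, 90.6, 0.11, 0.25, 0.14, 5.6, 9.12, 2.15),
    "W": (204.228, 225, 227.8, -0.9, 0.878, 13.2, -0.24, -2.09, -1.85, 5.88, 9.39, 2.38),
    "Y": (181.191, 230, 193.6, -1.3, 0.88, 0.51, 0.23, -0.71, -0.94, 5.63, 9.11, 2.2),
    "V": (117.148, 155, 140.0, 4.2, 0.825, 88.0, -0.53, -0.46, 0.07, 6.02, 9.72, 2.29),
}


@dataclass(frozen=True)
class PropertyTable:
    """One property column of the amino-acid table: residue → measured value."""

    property_name: str
    units: str
    values: Mapping[str, float]

    def __post_init__(self) -> None:
        if set(self.values) != set(RESIDUES):
            raise ValueError(
                "PropertyTable must be keyed by exactly the 20 standard residues"
            )

    def __getitem__(self, residue: str) -> float:
        try:
            return self.values[residue]
        except KeyError:
            raise KeyError(
                f"{residue!r} is not one of the 20 standard residues"
            ) from None

    def is_invertible(self) -> bool:
        """True when the 20 values (plus the gap value 0) are all distinct,
        so a number string determines its letter sequence."""
        vals = list(self.values.values())
        return len(set(vals)) == 20 and 0.0 not in vals


@dataclass(frozen=True)
class GappedSequence:
    """One taxon's row of an alignment: residues and ``-`` gaps."""

    taxon: str
    letters: str

    def __post_init__(self) -> None:
        normalized = self.letters.upper().replace(".", GAP)
        object.__setattr__(self, "letters", normalized)
        allowed = set(RESIDUES) | {GAP}
        for i, ch in enumerate(normalized, start=1):
            if ch not in allowed:
                raise ValueError(
                    f"sequence {self.taxon!r}: unknown symbol {ch!r} at position {i}"
                )

    def __len__(self) -> int:
        return len(self.letters)


@dataclass(frozen=True)
class EncodedSequence:
    """A number string: one taxon's alignment row under one property.

    ``values[i]`` is the property value of the residue at (1-based) position
    ``i+1``, or exactly 0.0 at gap positions.
    """

    taxon: str
    property_name: str
    values: Tuple[float, ...]

    def __len__(self) -> int:
        return len(self.values)

    def as_array(self):
        import numpy as np

        return np.asarray(self.values, dtype=float)


def load_property_table(property_name: str) -> PropertyTable:
    """Return the embedded table column for one property.

    Raises ``KeyError`` naming the valid options for an unknown name.
    """
    if property_name not in PROPERTY_NAMES:
        raise KeyError(
            f"unknown property {property_name!r}; valid options: "
            + ", ".join(PROPERTY_NAMES)
        )
    col = PROPERTY_NAMES.index(property_name)
    return PropertyTable(
        property_name=property_name,
        units=PROPERTY_UNITS[property_name],
        values={aa: row[col] for aa, row in _TABLE.items()},
    )


def encode_sequence(seq: GappedSequence, table: PropertyTable) -> EncodedSequence:
    """Replace letters with property values; gaps become exactly 0."""
    values = tuple(
        0.0 if ch == GAP else table.values[ch] for ch in seq.letters
    )
    return EncodedSequence(seq.taxon, table.property_name, values)


def decode_sequence(encoded: EncodedSequence) -> GappedSequence:
    """Invert :func:`encode_sequence` where the property permits it.

    Only possible when the property's 20 values are distinct and nonzero
    (true for volume, solubility and molecular mass); otherwise raises.
    """
    table = load_property_table(encoded.property_name)
    if not table.is_invertible():
        raise ValueError(
            f"property {encoded.property_name!r} does not have 20 distinct "
            "nonzero values; decoding is ambiguous"
        )
    inverse = {v: aa for aa, v in table.values.items()}
    letters = "".join(
        GAP if v == 0.0 else inverse[v] for v in encoded.values
    )
    return GappedSequence(encoded.taxon, letters)


def encode_alignment(
    seqs: Sequence[GappedSequence],
    property_names: Iterable[str] = DEFAULT_PROPERTIES,
) -> Dict[Tuple[str, str], EncodedSequence]:
    """Encode every sequence under every requested property.

    Returns a map ``(taxon, property_name) -> EncodedSequence``.  All input
    sequences must share a common (aligned) length.
    """
    seqs = list(seqs)
    if not seqs:
        return {}
    widths = {len(s) for s in seqs}
    if len(widths) > 1:
        detail = ", ".join(f"{s.taxon}={len(s)}" for s in seqs)
        raise ValueError(f"sequences are not aligned (unequal lengths): {detail}")
    out: Dict[Tuple[str, str], EncodedSequence] = {}
    for name in property_names:
        table = load_property_table(name)
        for s in seqs:
            out[(s.taxon, name)] = encode_sequence(s, table)
    return out


def property_table_tsv() -> str:
    """The embedded table as TSV: residue, then one column per property.

    Values are rendered with ``repr`` so that re-parsing reproduces the
    embedded constants bit-identically.
    """
    buf = io.StringIO()
    buf.write("residue\t" + "\t".join(PROPERTY_NAMES) + "\n")
    for aa in RESIDUES:
        row = _TABLE[aa]
        buf.write(aa + "\t" + "\t".join(repr(v) for v in row) + "\n")
    return buf.getvalue()


def load_property_table_tsv(text: str, property_name: str) -> PropertyTable:
    """Load one property column from a user TSV in the export schema."""
    lines = [ln for ln in text.splitlines() if ln.strip()]
    header = lines[0].split("\t")
    if header[0] != "residue" or property_name not in header[1:]:
        raise ValueError(
            f"TSV must have a 'residue' column and a {property_name!r} column"
        )
    col = header.index(property_name)
    values: Dict[str, float] = {}
    for ln in lines[1:]:
        parts = ln.split("\t")
        values[parts[0]] = float(parts[col])
    units = PROPERTY_UNITS.get(property_name, "")
    return PropertyTable(property_name, units, values)
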