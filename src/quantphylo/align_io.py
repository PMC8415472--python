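"""Alignment input/output, group consensus and positional variability.

Alignments are consumed already aligned (aligned FASTA or Clustal); no
alignment is computed here.  Consensus building follows the majority rule:
per column the most frequent symbol wins, with gaps voting like residues.
"""

from __future__ import annotations

import io
from collections import Counter
from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
from Bio import AlignIO

from .properties import GAP, EncodedSequence, GappedSequence

__all__ = [
    "AlignmentSet",
    "read_alignment",
    "write_fasta",
    "build_consensus",
    "positional_variability",
    "encoded_to_tsv",
]


@dataclass(frozen=True)
class AlignmentSet:
    """An ordered set of equal-length gapped sequences with unique labels."""

    records: Tuple[GappedSequence, ...]

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("alignment contains no records")
        widths = {len(r) for r in self.records}
        if len(widths) > 1:
            detail = ", ".join(f"{r.taxon}={len(r)}" for r in self.records)
            raise ValueError(f"ragged alignment: {detail}")
        labels = [r.taxon for r in self.records]
        dupes = [t for t, c in Counter(labels).items() if c > 1]
        if dupes:
            raise ValueError(f"duplicate taxon labels: {dupes}")

    @property
    def width(self) -> int:
        return len(self.records[0])

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def taxa(self) -> List[str]:
        return [r.taxon for r in self.records]


def read_alignment(path, format: str = "fasta") -> AlignmentSet:
    """Read an aligned FASTA or Clustal file.

    Record order is preserved; the Clustal conservation line is ignored by
    the parser.  Ragged input, duplicate labels and empty files are errors.
    """
    if format not in ("fasta", "clustal"):
        raise ValueError(f"unsupported format {format!r}; use 'fasta' or 'clustal'")
    try:
        msa = AlignIO.read(str(path), format)
    except ValueError as exc:
        raise ValueError(f"could not parse {path} as {format}: {exc}") from exc
    records = tuple(
        GappedSequence(rec.id, str(rec.seq)) for rec in msa
    )
    return AlignmentSet(records)


def write_fasta(aln: AlignmentSet | Sequence[GappedSequence], path) -> None:
    records = list(aln)
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.taxon}\n{rec.letters}\n")


def build_consensus(group: AlignmentSet, taxon: str = "consensus") -> GappedSequence:
    """Majority-rule consensus: per column the most common symbol.

    Gaps participate in the vote, so a mostly-gap column yields a gap.
    Ties are broken deterministically: a residue beats the gap symbol, and
    among tied residues the alphabetically first wins.
    """
    cols = zip(*(r.letters for r in group.records))
    out = []
    for col in cols:
        counts = Counter(col)
        # sort: highest count first, then residues before gap, then alphabetical
        best = min(counts.items(), key=lambda kv: (-kv[1], kv[0] == GAP, kv[0]))
        out.append(best[0])
    return GappedSequence(taxon, "".join(out))


def positional_variability(
    encoded: Sequence[EncodedSequence],
) -> Tuple[np.ndarray, np.ndarray]:
    """Per-position mean and sample standard deviation across taxa.

    The profile of means against 1-based position, with the scatter at each
    position, localizes conserved stretches (sd ≈ 0) versus mutable ones.
    Requires at least two taxa (the sample sd is undefined otherwise).
    """
    encoded = list(encoded)
    if len(encoded) < 2:
        raise ValueError("positional variability needs at least 2 taxa")
    lengths = {len(e) for e in encoded}
    if len(lengths) > 1:
        raise ValueError(f"encoded sequences have unequal lengths: {lengths}")
    mat = np.array([e.values for e in encoded], dtype=float)
    return mat.mean(axis=0), mat.std(axis=0, ddof=1)


def encoded_to_tsv(encoded: Dict[Tuple[str, str], EncodedSequence]) -> str:
    """Number strings as TSV: taxon, property, then one column per position."""
    buf = io.StringIO()
    if encoded:
        width = len(next(iter(encoded.values())))
        buf.write(
            "taxon\tproperty\t"
            + "\t".join(str(i) for i in range(1, width + 1))
            + "\n"
        )
    for (taxon, prop), enc in encoded.items():
        buf.write(
            f"{taxon}\t{prop}\t" + "\t".join(repr(v) for v in enc.values) + "\n"
        )
    return buf.getvalue()
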