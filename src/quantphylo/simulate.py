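"""Synthetic aligned protein families with a planted phylogeny.

Generates test families for the whole pipeline: a uniform-random root
sequence evolves down a user-specified binary topology, each branch applying
a fixed number of random substitutions (position uniform outside protected
blocks; replacement residue uniform over the other 19).  Gap blocks are
painted onto named leaves afterwards, fully masking the underlying residues
— emulating alignment gap stretches such as the one downstream of the RGD
motif.  The substitution model is deliberately uniform (no exchangeability
matrix, no rate heterogeneity beyond protected blocks): these families
exercise the analysis pipeline, they do not model real protein evolution.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple, Union

import numpy as np

from .align_io import AlignmentSet
from .properties import GAP, RESIDUES, GappedSequence

__all__ = [
    "Topology",
    "FamilyConfig",
    "parse_topology",
    "random_root",
    "evolve_family",
    "family_to_json",
]

#: A topology is a taxon label or a pair of sub-topologies.
Topology = Union[str, Tuple["Topology", "Topology"]]


def parse_topology(text: str) -> Topology:
    """Parse a nested-pair topology string like ``((A,B),(C,D))``."""
    text = text.strip().rstrip(";")
    pos = 0

    def parse() -> Topology:
        nonlocal pos
        if pos >= len(text):
            raise ValueError(f"unexpected end of topology string {text!r}")
        if text[pos] == "(":
            pos += 1
            left = parse()
            if pos >= len(text) or text[pos] != ",":
                raise ValueError(f"expected ',' at position {pos} in {text!r}")
            pos += 1
            right = parse()
            if pos >= len(text) or text[pos] != ")":
                raise ValueError(f"expected ')' at position {pos} in {text!r}")
            pos += 1
            return (left, right)
        start = pos
        while pos < len(text) and text[pos] not in "(),":
            pos += 1
        label = text[start:pos].strip()
        if not label:
            raise ValueError(f"empty taxon label at position {start} in {text!r}")
        return label

    top = parse()
    if pos != len(text):
        raise ValueError(f"trailing characters at position {pos} in {text!r}")
    return top


def _leaf_labels(top: Topology) -> List[str]:
    if isinstance(top, str):
        return [top]
    return _leaf_labels(top[0]) + _leaf_labels(top[1])


def _edges(top: Topology, prefix: str = "root") -> List[str]:
    """Edge names: one per child subtree, named by the subtree's leaf set."""
    if isinstance(top, str):
        return []
    names = []
    for child in top:
        name = "+".join(_leaf_labels(child))
        names.append(name)
        names.extend(_edges(child))
    return names


@dataclass(frozen=True)
class FamilyConfig:
    """Configuration of one synthetic family.

    ``substitutions_per_branch`` maps an edge name (the '+'-joined leaf set
    of the subtree below the edge, e.g. ``"A+B"`` or ``"C"``) to the number
    of substitutions on that branch; ``default_substitutions`` fills any
    unmapped edge.  ``protected_blocks`` are 1-based inclusive intervals
    never mutated.  ``gap_blocks`` maps a leaf taxon to intervals replaced
    by gaps after evolution.
    """

    topology: Topology
    root_length: int = 356
    substitutions_per_branch: Dict[str, int] = field(default_factory=dict)
    default_substitutions: int = 0
    protected_blocks: Tuple[Tuple[int, int], ...] = ()
    gap_blocks: Dict[str, Tuple[Tuple[int, int], ...]] = field(default_factory=dict)
    rng_seed: int = 1

    def __post_init__(self) -> None:
        labels = _leaf_labels(self.topology)
        if len(set(labels)) != len(labels):
            raise ValueError(f"duplicate taxon labels in topology: {labels}")
        if self.root_length < 1:
            raise ValueError("root_length must be >= 1")
        for lo, hi in self.protected_blocks:
            if not 1 <= lo <= hi <= self.root_length:
                raise ValueError(f"protected block ({lo},{hi}) outside 1..{self.root_length}")
        for taxon, blocks in self.gap_blocks.items():
            for lo, hi in blocks:
                if not 1 <= lo <= hi <= self.root_length:
                    raise ValueError(f"gap block ({lo},{hi}) outside 1..{self.root_length}")


def random_root(length: int, rng: np.random.Generator) -> GappedSequence:
    """A uniform-random ungapped root sequence."""
    if length < 1:
        raise ValueError("length must be >= 1")
    idx = rng.integers(0, 20, size=length)
    return GappedSequence("root", "".join(RESIDUES[i] for i in idx))


def _mutate(
    letters: List[str],
    n_subs: int,
    mutable: np.ndarray,
    rng: np.random.Generator,
) -> List[str]:
    if n_subs > len(mutable):
        raise ValueError(
            f"{n_subs} substitutions requested but only {len(mutable)} "
            "mutable positions available"
        )
    out = letters.copy()
    sites = rng.choice(mutable, size=n_subs, replace=False)
    for site in sites:
        current = out[site]
        others = [aa for aa in RESIDUES if aa != current]
        out[site] = others[rng.integers(0, 19)]
    return out


def evolve_family(config: FamilyConfig) -> Tuple[AlignmentSet, Dict]:
    """Evolve a family down the planted topology.

    Returns the leaf alignment and a truth record with the topology, the
    root sequence and the per-branch substitution counts actually applied.
    """
    rng = np.random.default_rng(config.rng_seed)
    root = random_root(config.root_length, rng)
    protected = np.zeros(config.root_length, dtype=bool)
    for lo, hi in config.protected_blocks:
        protected[lo - 1 : hi] = True
    mutable = np.flatnonzero(~protected)

    applied: Dict[str, int] = {}
    leaves: Dict[str, List[str]] = {}

    def walk(top: Topology, letters: List[str]) -> None:
        if isinstance(top, str):
            leaves[top] = letters
            return
        for child in top:
            edge = "+".join(_leaf_labels(child))
            n_subs = config.substitutions_per_branch.get(
                edge, config.default_substitutions
            )
            applied[edge] = n_subs
            walk(child, _mutate(letters, n_subs, mutable, rng))

    walk(config.topology, list(root.letters))

    records = []
    for taxon in _leaf_labels(config.topology):
        letters = leaves[taxon]
        for lo, hi in config.gap_blocks.get(taxon, ()):
            for i in range(lo - 1, hi):
                letters[i] = GAP
        records.append(GappedSequence(taxon, "".join(letters)))
    truth = {
        "topology": _topology_str(config.topology),
        "root": root.letters,
        "substitutions_per_branch": applied,
        "rng_seed": config.rng_seed,
    }
    return AlignmentSet(tuple(records)), truth


def _topology_str(top: Topology) -> str:
    if isinstance(top, str):
        return top
    return "(" + ",".join(_topology_str(c) for c in top) + ")"


def family_to_json(truth: Dict) -> str:
    return json.dumps(truth, indent=2)
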