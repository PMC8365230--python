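"""Coarse-grained structure parsing and residue correspondence.

A macromolecular complex is reduced to one node per residue: the Cα atom for
amino acids and the backbone P atom for nucleotides.  All downstream analyses
(superposition, elastic network models, perturbation response scanning,
residue networks, communication paths) operate on this representation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import gemmi
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Node",
    "CoarseGrainedStructure",
    "ChainMap",
    "StructureError",
    "ParseError",
    "MappingError",
    "parse_structure",
    "read_structure",
    "write_structure",
    "map_chains",
]


class StructureError(ValueError):
    """Base class for structure-handling errors."""


class ParseError(StructureError):
    """Raised when PDB text cannot be parsed or yields no representative atoms."""


class MappingError(StructureError):
    """Raised when a chain alias map cannot be applied."""


@dataclass(frozen=True)
class Node:
    """One coarse-grained interaction site.

    ``node_kind`` is ``"CA"`` for amino acids and ``"P"`` for nucleotides.
    ``icode`` (PDB insertion code) is part of the residue identity.
    """

    chain_id: str
    residue_number: int
    residue_name: str
    node_kind: str
    position: np.ndarray
    bfactor: float | None = None
    icode: str = ""

    @property
    def residue_id(self) -> tuple[str, int, str]:
        return (self.chain_id, self.residue_number, self.icode)

    def __repr__(self) -> str:  # compact: used in error messages
        return (
            f"Node({self.chain_id}/{self.residue_name}"
            f"{self.residue_number}{self.icode}:{self.node_kind})"
        )


@dataclass
class CoarseGrainedStructure:
    """Ordered list of coarse-grained nodes with a name.

    Node order is deterministic: chains in input-file order, residues in file
    order within a chain (ascending for well-formed depositions).
    """

    nodes: list[Node]
    name: str = ""

    def __post_init__(self) -> None:
        coords = self.coords
        if len(self.nodes) and not np.all(np.isfinite(coords)):
            raise StructureError(f"{self.name}: non-finite node coordinates")

    def __len__(self) -> int:
        return len(self.nodes)

    @property
    def coords(self) -> np.ndarray:
        """(N, 3) array of node positions in Å."""
        if not self.nodes:
            return np.empty((0, 3))
        return np.asarray([n.position for n in self.nodes], dtype=float)

    @property
    def chain_ids(self) -> list[str]:
        """Distinct chain identifiers in file order."""
        seen: dict[str, None] = {}
        for n in self.nodes:
            seen.setdefault(n.chain_id, None)
        return list(seen)

    @property
    def bfactors(self) -> np.ndarray:
        """Per-node experimental B-factors (NaN where absent)."""
        return np.asarray(
            [np.nan if n.bfactor is None else n.bfactor for n in self.nodes],
            dtype=float,
        )

    def chain_indices(self, chain_id: str) -> np.ndarray:
        idx = np.asarray(
            [i for i, n in enumerate(self.nodes) if n.chain_id == chain_id], dtype=int
        )
        if idx.size == 0:
            raise StructureError(f"{self.name}: no chain {chain_id!r}")
        return idx

    def with_coords(self, coords: np.ndarray, name: str | None = None) -> "CoarseGrainedStructure":
        """Copy of the structure with replaced coordinates."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.nodes), 3):
            raise StructureError("coordinate array shape mismatch")
        nodes = [
            Node(n.chain_id, n.residue_number, n.residue_name, n.node_kind,
                 coords[i].copy(), n.bfactor, n.icode)
            for i, n in enumerate(self.nodes)
        ]
        return CoarseGrainedStructure(nodes, self.name if name is None else name)


@dataclass
class ChainMap:
    """One-to-one partial matching between nodes of two structures."""

    pairs: list[tuple[int, int]]
    unmatched_a: list[int] = field(default_factory=list)
    unmatched_b: list[int] = field(default_factory=list)

    @property
    def index_a(self) -> np.ndarray:
        return np.asarray([p[0] for p in self.pairs], dtype=int)

    @property
    def index_b(self) -> np.ndarray:
        return np.asarray([p[1] for p in self.pairs], dtype=int)

    def restrict(self, indices_a: set[int] | np.ndarray) -> "ChainMap":
        """Sub-map keeping only pairs whose A-index is in ``indices_a``."""
        keep = set(int(i) for i in indices_a)
        pairs = [p for p in self.pairs if p[0] in keep]
        un_a = [i for i in self.unmatched_a if i in keep]
        return ChainMap(pairs, un_a, list(self.unmatched_b))


def _pick_representative(residue: gemmi.Residue) -> gemmi.Atom | None:
    """Return the CA (preferred) or P atom; highest occupancy among altlocs."""
    for atom_name in ("CA", "P"):
        candidates = [a for a in residue if a.name == atom_name]
        if candidates:
            # highest occupancy wins; ties resolved by file order (stable max)
            best = candidates[0]
            for a in candidates[1:]:
                if a.occ > best.occ:
                    best = a
            return best
    return None


def parse_structure(pdb_text: str, name: str = "") -> CoarseGrainedStructure:
    """Parse PDB text into a coarse-grained structure.

    One node per residue possessing a CA (amino acid) or P (nucleotide) atom;
    residues lacking a representative atom are skipped with a logged warning.
    Only the first model of multi-model files is read.  Altloc conformers are
    resolved to the highest-occupancy one.
    """
    if not pdb_text or not pdb_text.strip():
        raise ParseError(f"{name or 'structure'}: empty PDB input")
    try:
        st = gemmi.read_pdb_string(pdb_text)
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"{name or 'structure'}: cannot parse PDB input: {exc}") from exc
    if len(st) == 0:
        raise ParseError(f"{name or 'structure'}: no models in PDB input")
    if len(st) > 1:
        logger.warning("%s: %d models in file; using the first", name, len(st))

    nodes: list[Node] = []
    for chain in st[0]:
        for residue in chain:
            atom = _pick_representative(residue)
            if atom is None:
                if residue.name != "HOH":
                    logger.warning(
                        "%s: residue %s/%s%s%s has no CA or P atom; skipped",
                        name, chain.name, residue.name,
                        residue.seqid.num, (residue.seqid.icode or "").strip(),
                    )
                continue
            nodes.append(
                Node(
                    chain_id=chain.name,
                    residue_number=residue.seqid.num,
                    residue_name=residue.name,
                    node_kind=atom.name,
                    position=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                    bfactor=float(atom.b_iso),
                    icode=(residue.seqid.icode or "").strip(),
                )
            )
    if not nodes:
        raise ParseError(f"{name or 'structure'}: no CA or P atoms found")
    return CoarseGrainedStructure(nodes, name=name)


def read_structure(path, name: str | None = None) -> CoarseGrainedStructure:
    """Read a PDB file from disk (thin wrapper over :func:`parse_structure`)."""
    from pathlib import Path

    p = Path(path)
    return parse_structure(p.read_text(), name=name if name is not None else p.stem)


def write_structure(s: CoarseGrainedStructure, bfactors: np.ndarray | None = None) -> str:
    """Serialize the coarse-grained structure as PDB text.

    ``bfactors`` overrides the B-factor column (e.g. to paint per-residue
    deviations or Z-scores for visualisation).
    """
    if bfactors is not None:
        bfactors = np.asarray(bfactors, dtype=float)
        if bfactors.shape != (len(s),):
            raise StructureError("bfactor override length mismatch")

    st = gemmi.Structure()
    st.name = s.name or "cg"
    model = gemmi.Model("1")
    chain_order: dict[str, gemmi.Chain] = {}
    for i, node in enumerate(s.nodes):
        chain = chain_order.get(node.chain_id)
        if chain is None:
            chain = gemmi.Chain(node.chain_id)
            chain_order[node.chain_id] = chain
        res = gemmi.Residue()
        res.name = node.residue_name
        res.seqid = gemmi.SeqId(node.residue_number, node.icode or " ")
        atom = gemmi.Atom()
        atom.name = node.node_kind
        atom.element = gemmi.Element("C" if node.node_kind == "CA" else "P")
        atom.pos = gemmi.Position(*node.position)
        atom.occ = 1.0
        if bfactors is not None:
            atom.b_iso = float(bfactors[i])
        else:
            atom.b_iso = 0.0 if node.bfactor is None else float(node.bfactor)
        res.add_atom(atom)
        chain.add_residue(res)
    for chain in chain_order.values():
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    return st.make_pdb_string()


def map_chains(
    a: CoarseGrainedStructure,
    b: CoarseGrainedStructure,
    chain_aliases: dict[str, str] | None = None,
) -> ChainMap:
    """Match residues of two structures by (aliased chain, residue id, node kind).

    ``chain_aliases`` maps chain ids of *a* to the corresponding chain ids of
    *b*; ``None`` means identity aliases over the chains shared by name.
    Unmatched residues are reported in the map, never silently dropped.
    """
    if chain_aliases is None:
        shared = set(a.chain_ids) & set(b.chain_ids)
        chain_aliases = {c: c for c in a.chain_ids if c in shared}
    chains_b = set(b.chain_ids)
    for src, dst in chain_aliases.items():
        if src not in set(a.chain_ids):
            raise MappingError(f"alias source chain {src!r} absent from {a.name or 'A'}")
        if dst not in chains_b:
            raise MappingError(f"alias target chain {dst!r} absent from {b.name or 'B'}")

    # index B nodes by (chain, resnum, icode, kind)
    lookup_b: dict[tuple, int] = {}
    for j, n in enumerate(b.nodes):
        key = (n.chain_id, n.residue_number, n.icode, n.node_kind)
        if key in lookup_b:
            logger.warning("%s: duplicate residue key %s; keeping first", b.name, key)
            continue
        lookup_b[key] = j

    pairs: list[tuple[int, int]] = []
    unmatched_a: list[int] = []
    used_b: set[int] = set()
    for i, n in enumerate(a.nodes):
        if n.chain_id not in chain_aliases:
            continue
        key = (chain_aliases[n.chain_id], n.residue_number, n.icode, n.node_kind)
        j = lookup_b.get(key)
        if j is None or j in used_b:
            unmatched_a.append(i)
        else:
            pairs.append((i, j))
            used_b.add(j)

    aliased_targets = set(chain_aliases.values())
    unmatched_b = [
        j for j, n in enumerate(b.nodes)
        if n.chain_id in aliased_targets and j not in used_b
    ]
    if unmatched_a or unmatched_b:
        logger.info(
            "map_chains: %d pairs, %d unmatched in %s, %d unmatched in %s",
            len(pairs), len(unmatched_a), a.name or "A", len(unmatched_b), b.name or "B",
        )
    return ChainMap(pairs, unmatched_a, unmatched_b)
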