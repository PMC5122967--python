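"""Multi-model PDB I/O, the ensemble coordinate model and the atom-selection language.

All downstream analysis (geometry, surfaces, restraints) consumes the
:class:`StructureEnsemble` produced here.  The ensemble stores one immutable
atom table shared by every model plus an ``(n_models, n_atoms, 3)`` coordinate
array, which is the natural layout for NMR ensembles whose models contain the
identical atom set by construction.

Residue numbers used in selections are *logical* numbers: the file (author)
number plus a per-chain integer offset supplied through the chain map.  This
lets a deposited file whose chains are numbered from 1 be addressed with the
biological numbering (e.g. calmodulin C-domain residues 76-148) without ever
rewriting the file.
"""

from __future__ import annotations

import dataclasses
import re
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

try:  # gemmi is the PDB-format workhorse; import guarded only for doc builds
    import gemmi
except ImportError:  # pragma: no cover
    gemmi = None

__all__ = [
    "AtomSite",
    "StructureEnsemble",
    "Selection",
    "StructureError",
    "ParseError",
    "SelectionError",
    "read_pdb",
    "write_pdb",
    "select",
    "STANDARD_AA",
    "BACKBONE_ATOMS",
]

STANDARD_AA = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}

BACKBONE_ATOMS = {"N", "CA", "C", "O"}


class StructureError(ValueError):
    """Inconsistent or invalid structural data (e.g. atom sets differ across models)."""


class ParseError(StructureError):
    """A PDB file could not be parsed."""


class SelectionError(ValueError):
    """A selection expression is malformed or resolves to nothing."""


@dataclasses.dataclass(frozen=True)
class AtomSite:
    """One atom's identity, shared across all models of an ensemble."""

    chain_id: str
    res_seq: int
    res_name: str
    atom_name: str
    element: str
    occupancy: float = 1.0
    altloc: str = ""

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() == "H"

    @property
    def is_standard(self) -> bool:
        return self.res_name in STANDARD_AA

    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.res_seq, self.atom_name)


@dataclasses.dataclass
class StructureEnsemble:
    """A multi-model structure with an identical atom set in every model.

    Parameters
    ----------
    atoms
        Atom table, ordered (chain_id, res_seq, atom_name).
    coords
        Array of shape ``(n_models, n_atoms, 3)`` in A.
    chain_map
        Logical entity name -> chain id (e.g. ``{"C-CaM": "A"}``).
    offsets
        Chain id -> integer added to file numbering to obtain logical
        numbering (0 when the file already uses it).
    """

    atoms: list[AtomSite]
    coords: np.ndarray
    chain_map: dict[str, str] = dataclasses.field(default_factory=dict)
    offsets: dict[str, int] = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise StructureError("coords must have shape (n_models, n_atoms, 3)")
        if self.coords.shape[1] != len(self.atoms):
            raise StructureError(
                f"coordinate table has {self.coords.shape[1]} atoms, "
                f"atom table has {len(self.atoms)}"
            )
        if self.coords.shape[0] < 1:
            raise StructureError("ensemble must contain at least one model")
        if len(self.atoms) == 0:
            raise StructureError("ensemble must contain at least one atom")
        if not np.all(np.isfinite(self.coords)):
            raise StructureError("non-finite coordinates")

    # -- basic accessors ---------------------------------------------------
    @property
    def n_models(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def model(self, i: int) -> np.ndarray:
        """Coordinates of model ``i`` (0-based), shape (n_atoms, 3)."""
        return self.coords[i]

    def chain_of(self, entity: str) -> str:
        """Resolve an entity name or literal chain id to a chain id."""
        if entity in self.chain_map:
            return self.chain_map[entity]
        chains = {a.chain_id for a in self.atoms}
        if entity in chains:
            return entity
        raise SelectionError(
            f"unknown entity/chain {entity!r}; known entities {sorted(self.chain_map)}, "
            f"chains {sorted(chains)}"
        )

    def logical_resseq(self, atom: AtomSite) -> int:
        return atom.res_seq + self.offsets.get(atom.chain_id, 0)

    def residues(self, chain_id: str | None = None) -> list[tuple[str, int, str]]:
        """Ordered unique (chain, file res_seq, res_name) triples."""
        seen: dict[tuple[str, int], str] = {}
        for a in self.atoms:
            if chain_id is not None and a.chain_id != chain_id:
                continue
            seen.setdefault((a.chain_id, a.res_seq), a.res_name)
        return [(c, r, n) for (c, r), n in sorted(seen.items())]

    def atom_index(self) -> dict[tuple[str, int, str], int]:
        """(chain, file res_seq, atom_name) -> column index."""
        return {a.key(): i for i, a in enumerate(self.atoms)}

    def subset(self, indices: Sequence[int]) -> "StructureEnsemble":
        """A new ensemble restricted to the given atom columns."""
        idx = np.asarray(indices, dtype=int)
        return StructureEnsemble(
            atoms=[self.atoms[i] for i in idx],
            coords=self.coords[:, idx, :],
            chain_map=dict(self.chain_map),
            offsets=dict(self.offsets),
        )

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "StructureEnsemble":
        """Apply a rigid-body transform x -> R x + t to every model."""
        R = np.asarray(rotation, float)
        t = np.asarray(translation, float)
        return StructureEnsemble(
            atoms=list(self.atoms),
            coords=self.coords @ R.T + t,
            chain_map=dict(self.chain_map),
            offsets=dict(self.offsets),
        )


# ---------------------------------------------------------------------------
# Selection language
# ---------------------------------------------------------------------------

_RANGE_RE = re.compile(r"^(-?\d+)(?:-(-?\d+))?$")


@dataclasses.dataclass(frozen=True)
class Selection:
    """Parsed form of ``ENTITY:RANGES:ATOMSPEC``.

    * ENTITY - entity name from the chain map, a literal chain id, or ``*``.
    * RANGES - comma-separated residue numbers/ranges in logical numbering
      (``81-128,135-146``) or ``*`` for all residues.
    * ATOMSPEC - ``backbone`` | ``sidechain`` | ``heavy`` | ``all`` |
      ``named NAME [NAME ...]``.  Defaults to ``all`` when omitted.
    """

    entity: str
    ranges: tuple[tuple[int, int], ...]  # inclusive; empty tuple = all residues
    atom_class: str
    atom_names: tuple[str, ...] = ()

    @classmethod
    def parse(cls, expression: str) -> "Selection":
        parts = expression.strip().split(":")
        if len(parts) == 1:
            parts += ["*", "all"]
        elif len(parts) == 2:
            parts.append("all")
        if len(parts) != 3:
            raise SelectionError(f"cannot parse selection {expression!r}")
        entity, ranges_s, atoms_s = (p.strip() for p in parts)
        if not entity:
            raise SelectionError("empty entity in selection")
        ranges: list[tuple[int, int]] = []
        if ranges_s not in ("*", ""):
            for token in ranges_s.split(","):
                m = _RANGE_RE.match(token.strip())
                if not m:
                    raise SelectionError(f"bad residue range {token!r}")
                lo = int(m.group(1))
                hi = int(m.group(2)) if m.group(2) is not None else lo
                if hi < lo:
                    raise SelectionError(f"inverted range {token!r}")
                ranges.append((lo, hi))
        atoms_s = atoms_s or "all"
        names: tuple[str, ...] = ()
        if atoms_s.startswith("named"):
            names = tuple(atoms_s.split()[1:])
            if not names:
                raise SelectionError("'named' atom spec requires atom names")
            atom_class = "named"
        else:
            atom_class = atoms_s.lower()
            if atom_class not in ("backbone", "sidechain", "heavy", "all"):
                raise SelectionError(f"unknown atom class {atom_class!r}")
        return cls(entity, tuple(ranges), atom_class, names)

    def covers_residue(self, logical_res: int) -> bool:
        if not self.ranges:
            return True
        return any(lo <= logical_res <= hi for lo, hi in self.ranges)


def _atom_matches(sel: Selection, atom: AtomSite) -> bool:
    name = atom.atom_name
    if sel.atom_class == "all":
        return True
    if sel.atom_class == "named":
        return name in sel.atom_names
    if sel.atom_class == "backbone":
        return name in BACKBONE_ATOMS
    if sel.atom_class == "heavy":
        return not atom.is_hydrogen
    if sel.atom_class == "sidechain":
        # side chain = everything from CB outward, hydrogens included;
        # amide H/HA belong to the backbone for this purpose
        return name not in BACKBONE_ATOMS and name not in ("H", "HA", "HA2", "HA3", "OXT", "H1", "H2", "H3")
    raise SelectionError(f"unknown atom class {sel.atom_class!r}")


def select(
    ensemble: StructureEnsemble,
    selection: Selection | str,
    allow_empty: bool = False,
) -> np.ndarray:
    """Resolve a selection to atom column indices (stable, sorted order).

    Raises :class:`SelectionError` on an empty result unless
    ``allow_empty=True`` — an empty selection is almost always a numbering or
    chain-map mistake, not a legitimate answer.
    """
    if isinstance(selection, str):
        selection = Selection.parse(selection)
    if selection.entity == "*":
        chains = None
    else:
        chains = {ensemble.chain_of(selection.entity)}
    out = []
    for i, atom in enumerate(ensemble.atoms):
        if chains is not None and atom.chain_id not in chains:
            continue
        if not selection.covers_residue(ensemble.logical_resseq(atom)):
            continue
        if _atom_matches(selection, atom):
            out.append(i)
    if not out and not allow_empty:
        raise SelectionError(f"selection {selection} matched no atoms")
    order = sorted(out, key=lambda i: (ensemble.atoms[i].chain_id,
                                       ensemble.atoms[i].res_seq,
                                       ensemble.atoms[i].atom_name))
    return np.asarray(order, dtype=int)


# ---------------------------------------------------------------------------
# PDB reading / writing
# ---------------------------------------------------------------------------

def read_pdb(
    path: str | Path,
    chain_map: Mapping[str, str] | None = None,
    offsets: Mapping[str, int] | None = None,
    keep_het: bool = False,
) -> StructureEnsemble:
    """Read a (possibly multi-model) PDB file into a :class:`StructureEnsemble`.

    Waters and non-polymer heteroatoms are dropped unless ``keep_het``;
    alternate locations are resolved to the highest-occupancy conformer
    (ties broken by altloc letter, so 'A' wins).  Every model must contain
    the identical (chain, residue, atom) set; NMR depositions do, and a file
    violating it raises :class:`StructureError` naming the offending atoms.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        st = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as exc:  # gemmi reports the line in its message
        raise ParseError(f"{path}: {exc}") from exc
    st.setup_entities()

    models: list[dict[tuple[str, int, str], tuple[AtomSite, np.ndarray]]] = []
    for model in st:
        table: dict[tuple[str, int, str], tuple[AtomSite, np.ndarray]] = {}
        for chain in model:
            for res in chain:
                if res.name == "HOH":
                    continue
                if not keep_het and res.name not in STANDARD_AA and not res.is_amino_acid():
                    continue
                best: dict[str, gemmi.Atom] = {}
                for atom in res:
                    prev = best.get(atom.name)
                    if prev is None:
                        best[atom.name] = atom
                    elif (atom.occ, -ord(atom.altloc or "A")) > (prev.occ, -ord(prev.altloc or "A")):
                        best[atom.name] = atom
                for atom in best.values():
                    site = AtomSite(
                        chain_id=chain.name,
                        res_seq=res.seqid.num,
                        res_name=res.name,
                        atom_name=atom.name,
                        element=atom.element.name if atom.element else "",
                        occupancy=atom.occ,
                        altloc=atom.altloc or "",
                    )
                    table[site.key()] = (site, np.array([atom.pos.x, atom.pos.y, atom.pos.z]))
        if table:
            models.append(table)
    if not models:
        raise ParseError(f"{path}: no atoms read")

    keys0 = set(models[0])
    for i, table in enumerate(models[1:], start=2):
        if set(table) != keys0:
            missing = sorted(keys0 ^ set(table))[:10]
            raise StructureError(
                f"model {i} atom set differs from model 1; first differences: {missing}"
            )
    order = sorted(keys0)
    atoms = [models[0][k][0] for k in order]
    coords = np.stack([[t[k][1] for k in order] for t in models])
    return StructureEnsemble(
        atoms=atoms,
        coords=coords,
        chain_map=dict(chain_map or {}),
        offsets=dict(offsets or {}),
    )


def write_pdb(ensemble: StructureEnsemble, path: str | Path) -> Path:
    """Write the ensemble as a fixed-column multi-model PDB file."""
    if ensemble.n_atoms == 0:
        raise StructureError("refusing to write an empty ensemble")
    for a in ensemble.atoms:
        if a.res_seq > 9999 or a.res_seq < -999:
            raise StructureError(f"residue number {a.res_seq} does not fit PDB format")
        if len(a.chain_id) != 1:
            raise StructureError(f"chain id {a.chain_id!r} is not a single character")
    path = Path(path)
    lines: list[str] = []
    multi = ensemble.n_models > 1
    for m in range(ensemble.n_models):
        if multi:
            lines.append(f"MODEL     {m + 1:4d}")
        serial = 0
        for i, a in enumerate(ensemble.atoms):
            serial += 1
            x, y, z = ensemble.coords[m, i]
            name = a.atom_name
            # PDB atom-name justification: 1-char elements start in column 14
            if len(name) < 4 and len(a.element) == 1:
                name_f = f" {name:<3s}"
            else:
                name_f = f"{name:<4s}"
            lines.append(
                f"ATOM  {serial % 100000:5d} {name_f}{a.altloc or ' ':1s}{a.res_name:>3s} "
                f"{a.chain_id}{a.res_seq:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{a.occupancy:6.2f}{0.0:6.2f}"
                f"          {a.element:>2s}"
            )
        lines.append("TER")
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")
    return path
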