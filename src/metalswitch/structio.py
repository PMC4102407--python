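"""Crystallographic structure I/O and metal-center extraction.

Structures are held as flat lists of :class:`AtomRecord` with author (PDB)
residue numbering, mouse ShhN convention (E127, H135, ...).  Coordinates are
internal in Å throughout the package; ensemble statistics are converted to nm
at the reporting layer only.

Parsing and crystal symmetry operators are delegated to :mod:`gemmi`; the
altloc policy, residue-range restriction and lattice-contact expansion logic
live here.
"""

from __future__ import annotations

import dataclasses
import re
from typing import Iterable, Sequence

import gemmi
import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "AtomRecord",
    "StructureModel",
    "CenterGroup",
    "CenterTemplate",
    "ParseError",
    "EmptyStructureError",
    "IdentityCheckError",
    "ExtractionError",
    "UnsupportedOperationError",
    "read_structure",
    "write_structure",
    "restrict_residues",
    "expand_symmetry",
    "extract_center",
    "SHHN_CENTER_SPEC",
]


class ParseError(ValueError):
    """Malformed PDB input."""


class EmptyStructureError(ValueError):
    """Input contained no atoms."""


class IdentityCheckError(ValueError):
    """A residue label did not match the residue found in the structure."""


class ExtractionError(KeyError):
    """Residues or metal required for a center template are absent."""


class UnsupportedOperationError(RuntimeError):
    """Operation requires information (e.g. a unit cell) that is absent."""


# one-letter <-> three-letter residue codes (standard amino acids + water)
THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    "HOH": "O", "WAT": "O",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items() if k not in ("HOH", "WAT")}

# side-chain functional atoms used for metal-center templates
FUNCTIONAL_ATOMS = {
    "ASP": ("CG", "OD1", "OD2"),
    "GLU": ("CD", "OE1", "OE2"),
    "HIS": ("ND1", "NE2"),
    "ASN": ("CG", "OD1", "ND2"),
    "GLN": ("CD", "OE1", "NE2"),
    "HOH": ("O",),
}
# index pairs within the atom tuple that are crystallographically
# interchangeable (carboxylate oxygens; the two imidazole nitrogens)
SWAP_PAIRS = {
    "ASP": ((1, 2),),
    "GLU": ((1, 2),),
    "HIS": ((0, 1),),
}
CHEMICAL_CLASS = {
    "ASP": "carboxylate",
    "GLU": "carboxylate",
    "HIS": "imidazole",
    "ASN": "amide",
    "GLN": "amide",
    "HOH": "water",
}

# the eight groups of the ShhN putative catalytic center (mouse numbering)
SHHN_CENTER_SPEC = ("E127", "H135", "H141", "D148", "E177", "H181", "H183")


@dataclasses.dataclass
class AtomRecord:
    serial: int
    atom_name: str
    element: str
    residue_name: str
    residue_number: int
    insertion_code: str
    chain_id: str
    position: np.ndarray
    occupancy: float = 1.0
    b_factor: float = 0.0
    is_het: bool = False
    altloc: str = ""

    @property
    def key(self) -> tuple:
        return (self.chain_id, self.residue_number, self.insertion_code,
                self.atom_name)

    def copy(self) -> "AtomRecord":
        new = dataclasses.replace(self)
        new.position = np.array(self.position, dtype=float)
        return new


@dataclasses.dataclass
class StructureModel:
    atoms: list
    unit_cell: tuple | None = None  # (a, b, c, alpha, beta, gamma)
    symmetry_ops: list = dataclasses.field(default_factory=list)
    model_id: int = 1
    source_id: str = ""

    def __post_init__(self):
        self._index = None

    # -- lookups ----------------------------------------------------------
    def _build_index(self):
        self._index = {}
        for a in self.atoms:
            self._index.setdefault(a.key, a)

    def atom(self, chain_id: str, residue_number: int, atom_name: str,
             insertion_code: str = "") -> AtomRecord:
        if self._index is None:
            self._build_index()
        try:
            return self._index[(chain_id, residue_number, insertion_code,
                                atom_name)]
        except KeyError:
            raise KeyError(
                f"atom {chain_id}/{residue_number}{insertion_code}/{atom_name}"
                f" not found in {self.source_id or 'structure'}")

    def find_atoms(self, atom_name: str | None = None,
                   residue_name: str | None = None,
                   element: str | None = None) -> list:
        out = []
        for a in self.atoms:
            if atom_name is not None and a.atom_name != atom_name:
                continue
            if residue_name is not None and a.residue_name != residue_name:
                continue
            if element is not None and a.element.upper() != element.upper():
                continue
            out.append(a)
        return out

    def coords(self, atoms: Iterable[AtomRecord] | None = None) -> np.ndarray:
        src = self.atoms if atoms is None else atoms
        return np.array([a.position for a in src], dtype=float)

    def residues(self):
        """Yield ((chain, resnum, icode, resname), [atoms]) in file order."""
        seen: dict = {}
        order = []
        for a in self.atoms:
            rk = (a.chain_id, a.residue_number, a.insertion_code,
                  a.residue_name)
            if rk not in seen:
                seen[rk] = []
                order.append(rk)
            seen[rk].append(a)
        for rk in order:
            yield rk, seen[rk]

    def copy(self) -> "StructureModel":
        return StructureModel(
            atoms=[a.copy() for a in self.atoms],
            unit_cell=self.unit_cell,
            symmetry_ops=[(np.array(R), np.array(t))
                          for R, t in self.symmetry_ops],
            model_id=self.model_id,
            source_id=self.source_id,
        )


@dataclasses.dataclass
class CenterGroup:
    label: str                # e.g. "E127"
    chain_id: str
    residue_class: str        # one-letter code, "ZN" etc. for metals
    atom_names: tuple
    chemical_class: str       # carboxylate / imidazole / metal:ZN / water
    coords: np.ndarray        # (n_atoms, 3) Å
    swap_pairs: tuple = ()


@dataclasses.dataclass
class CenterTemplate:
    groups: list              # CenterGroup, metal last by convention
    metal_index: int
    source_id: str = ""

    def __post_init__(self):
        if len(self.groups) < 3:
            raise ValueError("a center template needs at least 3 groups")
        n_metal = sum(g.chemical_class.startswith("metal")
                      for g in self.groups)
        if n_metal != 1:
            raise ValueError(f"expected exactly one metal group, got {n_metal}")

    @property
    def n_atoms(self) -> int:
        return sum(len(g.atom_names) for g in self.groups)

    def all_coords(self) -> np.ndarray:
        return np.vstack([g.coords for g in self.groups])


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------

def _ops_from_gemmi(st: gemmi.Structure) -> list:
    ops = []
    sg = None
    if st.spacegroup_hm:
        sg = gemmi.find_spacegroup_by_name(st.spacegroup_hm)
    if sg is None:
        sg = gemmi.find_spacegroup_by_name("P 1")
    for op in sg.operations():
        R = np.array(op.rot, dtype=float) / op.DEN
        t = np.array(op.tran, dtype=float) / op.DEN
        ops.append((R, t))
    return ops


def _resolve_altlocs(atoms: list) -> list:
    """Keep one altloc per atom key: highest occupancy, ties alphabetical."""
    best: dict = {}
    order = []
    for a in atoms:
        k = a.key
        if k not in best:
            best[k] = a
            order.append(k)
        else:
            b = best[k]
            if (a.occupancy, _altloc_rank(a.altloc)) > \
               (b.occupancy, _altloc_rank(b.altloc)):
                best[k] = a
    out = []
    for k in order:
        a = best[k]
        a.altloc = ""
        a.occupancy = min(max(a.occupancy, 0.0), 1.0)
        out.append(a)
    return out


def _altloc_rank(altloc: str) -> int:
    # alphabetical tie-break: 'A' preferred over 'B' -> higher rank for 'A'
    return -ord(altloc) if altloc else 0


def read_structure(pdb_text: str, model: int | str = "all",
                   source_id: str = ""):
    """Parse PDB text into one :class:`StructureModel` per MODEL.

    Altlocs are resolved to the highest-occupancy conformer (alphabetical
    tie-break); waters and metals are retained as het atoms.  Returns a
    single model when ``model`` is an integer or the file has one model,
    otherwise a list.
    """
    try:
        st = gemmi.read_pdb_string(pdb_text)
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"cannot parse PDB input: {exc}") from exc
    st.setup_entities()

    cell = None
    if st.cell and st.cell.a > 0 and not (
            st.cell.a == st.cell.b == st.cell.c == 1.0):
        cell = (st.cell.a, st.cell.b, st.cell.c,
                st.cell.alpha, st.cell.beta, st.cell.gamma)
    ops = _ops_from_gemmi(st) if cell is not None else []

    models = []
    for i, m in enumerate(st):
        atoms = []
        for chain in m:
            for res in chain:
                het = res.het_flag == "H"
                for at in res:
                    pos = np.array([at.pos.x, at.pos.y, at.pos.z], dtype=float)
                    if not np.all(np.isfinite(pos)):
                        raise ParseError(
                            f"non-finite coordinates for atom {at.serial}")
                    atoms.append(AtomRecord(
                        serial=at.serial,
                        atom_name=at.name,
                        element=at.element.name.upper(),
                        residue_name=res.name,
                        residue_number=res.seqid.num,
                        insertion_code=(res.seqid.icode or "").strip(),
                        chain_id=chain.name,
                        position=pos,
                        occupancy=at.occ,
                        b_factor=at.b_iso,
                        is_het=het,
                        altloc=(at.altloc or "").strip(),
                    ))
        if not atoms:
            continue
        atoms = _resolve_altlocs(atoms)
        models.append(StructureModel(
            atoms=atoms, unit_cell=cell, symmetry_ops=ops,
            model_id=i + 1, source_id=source_id))

    if not models:
        raise EmptyStructureError("no atoms found in input")
    if model == "all":
        return models if len(models) > 1 else models[0]
    idx = int(model) - 1
    if idx < 0 or idx >= len(models):
        raise ValueError(f"model {model} not present ({len(models)} models)")
    return models[idx]


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------

def _chain_char(chain_id: str, mapping: dict) -> str:
    if chain_id in mapping:
        return mapping[chain_id]
    if len(chain_id) == 1 and chain_id not in mapping.values():
        mapping[chain_id] = chain_id
        return chain_id
    alphabet = "ABCDEFGHIJKLMNOPQRSTUVWXYZabcdefghijklmnopqrstuvwxyz0123456789"
    for c in alphabet:
        if c not in mapping.values():
            mapping[chain_id] = c
            return c
    mapping[chain_id] = "Z"
    return "Z"


def write_structure(models, out=None) -> str:
    """Write one or more models as PDB-format text (fixed 0.001 Å precision).

    Multi-character chain ids produced by symmetry expansion are remapped to
    single characters for the chain-id column.
    """
    if isinstance(models, StructureModel):
        models = [models]
    lines = []
    m0 = models[0]
    if m0.unit_cell is not None:
        a, b, c, al, be, ga = m0.unit_cell
        lines.append(
            f"CRYST1{a:9.3f}{b:9.3f}{c:9.3f}{al:7.2f}{be:7.2f}{ga:7.2f} P 1")
    multi = len(models) > 1
    chain_map: dict = {}
    for m in models:
        if multi:
            lines.append(f"MODEL     {m.model_id:4d}")
        serial = 0
        for atom in m.atoms:
            serial += 1
            rec = "HETATM" if atom.is_het else "ATOM  "
            name = atom.atom_name
            # PDB atom-name column convention
            if len(name) < 4 and len(atom.element) == 1:
                name = f" {name}"
            name = f"{name:<4.4s}"
            ch = _chain_char(atom.chain_id, chain_map)
            x, y, z = atom.position
            lines.append(
                f"{rec}{serial:5d} {name} "
                f"{atom.residue_name:<3.3s} {ch}{atom.residue_number:4d}"
                f"{atom.insertion_code or ' ':1.1s}   "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{atom.occupancy:6.2f}"
                f"{atom.b_factor:6.2f}          {atom.element:>2.2s}")
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    text = "\n".join(lines) + "\n"
    if out is not None:
        with open(out, "w") as fh:
            fh.write(text)
    return text


# ---------------------------------------------------------------------------
# residue-range restriction
# ---------------------------------------------------------------------------

_LABEL_RE = re.compile(r"^([A-Za-z])(\d+)$")


def parse_residue_label(label: str) -> tuple:
    """Parse labels like 'L40' -> ('L', 40)."""
    m = _LABEL_RE.match(label.strip())
    if not m:
        raise ValueError(f"cannot parse residue label {label!r}")
    return m.group(1).upper(), int(m.group(2))


def restrict_residues(s: StructureModel, first: str, last: str,
                      keep_het: bool = True,
                      het_envelope: float = 6.0) -> StructureModel:
    """Clip to the author-numbered residue range [first, last].

    ``first``/``last`` are labels such as ``"L40"``/``"E189"``; the residue
    type is verified against the structure (identity check).  Het groups
    (metals, waters) within ``het_envelope`` Å of the retained polymer atoms
    are kept when ``keep_het`` is true.  Atom order is preserved.
    """
    (c1, n1), (c2, n2) = parse_residue_label(first), parse_residue_label(last)
    if n1 > n2:
        raise ValueError("first residue after last in author numbering")

    for code, num in ((c1, n1), (c2, n2)):
        found = [a for a in s.atoms
                 if a.residue_number == num and not a.is_het]
        if not found:
            raise IdentityCheckError(f"residue {num} not present")
        rname = found[0].residue_name
        if THREE_TO_ONE.get(rname, "X") != code:
            raise IdentityCheckError(
                f"residue {num} is {rname}, not {ONE_TO_THREE.get(code, code)}")

    polymer = [a for a in s.atoms
               if not a.is_het and n1 <= a.residue_number <= n2]
    kept = list(polymer)
    if keep_het:
        tree = cKDTree(np.array([a.position for a in polymer]))
        het_keep = set()
        for a in s.atoms:
            if not a.is_het:
                continue
            d, _ = tree.query(a.position)
            if d <= het_envelope:
                het_keep.add(id(a))
        kept = [a for a in s.atoms
                if (not a.is_het and n1 <= a.residue_number <= n2)
                or id(a) in het_keep]
    return StructureModel(atoms=[a.copy() for a in kept],
                          unit_cell=s.unit_cell,
                          symmetry_ops=list(s.symmetry_ops),
                          model_id=s.model_id, source_id=s.source_id)


# ---------------------------------------------------------------------------
# crystal symmetry expansion
# ---------------------------------------------------------------------------

def _cell_matrices(cell):
    a, b, c, alpha, beta, gamma = cell
    g = gemmi.UnitCell(a, b, c, alpha, beta, gamma)
    frac = np.array(g.frac.mat.tolist(), dtype=float)
    orth = np.array(g.orth.mat.tolist(), dtype=float)
    return frac, orth


def expand_symmetry(s: StructureModel, cutoff: float) -> StructureModel:
    """Add symmetry/lattice-translated copies with atoms within ``cutoff`` Å.

    Applies every crystallographic operator combined with lattice translations
    in [-1, 1]^3 (sufficient for nearest-neighbour contacts); copies with at
    least one atom within ``cutoff`` of any original atom are appended with
    distinguishable chain ids.  Original atoms are unchanged.
    """
    if s.unit_cell is None or not s.symmetry_ops:
        raise UnsupportedOperationError(
            "symmetry expansion needs a unit cell and symmetry operators")
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")

    frac_m, orth_m = _cell_matrices(s.unit_cell)
    xyz = s.coords()
    fxyz = xyz @ frac_m.T
    tree = cKDTree(xyz)

    new_models = []
    image = 0
    for i_op, (R, t) in enumerate(s.symmetry_ops):
        for da in (-1, 0, 1):
            for db in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    if i_op == 0 and da == db == dc == 0 \
                            and np.allclose(R, np.eye(3)) \
                            and np.allclose(t, 0):
                        continue  # identity: the original itself
                    shift = t + np.array([da, db, dc], dtype=float)
                    f_new = fxyz @ R.T + shift
                    x_new = f_new @ orth_m.T
                    dmin, _ = tree.query(x_new, k=1)
                    if dmin.min() > cutoff:
                        continue
                    image += 1
                    new_models.append((image, i_op, (da, db, dc), x_new))

    out = s.copy()
    for image, i_op, (da, db, dc), x_new in new_models:
        suffix = f"_sym{i_op}_{da}{db}{dc}"
        for a, pos in zip(s.atoms, x_new):
            na = a.copy()
            na.position = np.array(pos, dtype=float)
            na.chain_id = a.chain_id + suffix
            out.atoms.append(na)
    out._index = None
    return out


# ---------------------------------------------------------------------------
# center extraction
# ---------------------------------------------------------------------------

def extract_center(s: StructureModel, spec: Sequence[str] = SHHN_CENTER_SPEC,
                   metal_name: str = "ZN",
                   chain_id: str | None = None) -> CenterTemplate:
    """Extract a functional-group constellation template.

    ``spec`` lists residue labels (e.g. the eight-group ShhN center residues
    E127, H135, H141, D148, E177, H181, H183 around the zinc).  For each
    residue the side-chain functional atoms are collected (carboxylate C/O
    for D/E, imidazole N for H) plus the metal atom, with coordinates copied.
    """
    missing = []
    groups = []
    for label in spec:
        code, num = parse_residue_label(label)
        three = ONE_TO_THREE.get(code)
        cands = [a for a in s.atoms
                 if a.residue_number == num and not a.is_het
                 and (chain_id is None or a.chain_id == chain_id)
                 and a.residue_name == three]
        if not cands:
            missing.append(label)
            continue
        ch = cands[0].chain_id
        names = FUNCTIONAL_ATOMS[three]
        try:
            coords = np.array([s.atom(ch, num, nm).position for nm in names])
        except KeyError:
            missing.append(label)
            continue
        groups.append(CenterGroup(
            label=label, chain_id=ch, residue_class=code,
            atom_names=names, chemical_class=CHEMICAL_CLASS[three],
            coords=coords, swap_pairs=SWAP_PAIRS.get(three, ())))

    metals = [a for a in s.atoms
              if a.atom_name.upper() == metal_name.upper()
              or a.element.upper() == metal_name.upper()]
    if not metals:
        missing.append(metal_name)
    if missing:
        raise ExtractionError(
            f"cannot build center template; missing: {', '.join(missing)}")
    metal = metals[0]
    groups.append(CenterGroup(
        label=metal_name, chain_id=metal.chain_id,
        residue_class=metal.element.upper(),
        atom_names=(metal.atom_name,),
        chemical_class=f"metal:{metal.element.upper()}",
        coords=metal.position.reshape(1, 3)))
    return CenterTemplate(groups=groups, metal_index=len(groups) - 1,
                          source_id=s.source_id)
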