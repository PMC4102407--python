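"""Electrostatics and empirical ion-affinity estimation.

Two independent energetic readouts of the calcium switch:

* an empirical calcium-affinity estimate from the solvent exposure of the
  ion (probe radius 0.5 Å): the more exposed the ion, the weaker the
  affinity.  Only affinity *differences* between the buried (Ca1) and the
  exposed (Ca2) site are meaningful, since the model ignores ion–ion
  interaction and conformational entropy;

* the electrostatic binding free energy of the zinc-coordinating water,
  computed from a finite-difference linearized Poisson–Boltzmann solution
  via the standard thermodynamic cycle
  ``dG = G(protein·water) − G(protein) − G(water)``, differenced between
  calcium states.  Identical grids and charge discretization across all
  cycle legs make grid self-energies cancel in the differences.

Units: lengths Å, charges e, potentials kT/e, energies kJ/mol.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd

from .geometry import DEFAULT_RADII, sasa
from .structio import AtomRecord, StructureModel

__all__ = [
    "IonSite",
    "ChargeModel",
    "PotentialGrid",
    "ConfigurationError",
    "TableCoverageError",
    "DivergenceError",
    "ComparabilityError",
    "EQ1_COEFFICIENTS",
    "PBOptions",
    "ion_affinity",
    "ion_sites",
    "affinity_difference",
    "assign_charges",
    "solve_pb",
    "binding_energy",
    "water_binding_ddg",
    "surface_potential",
]

# physical constants
KB_KJMOL = 8.31446261815324e-3          # kJ/(mol K)
COULOMB_KJMOL_A = 1389.35457644382      # e^2/(4 pi eps0), kJ/mol * Å
AVOGADRO_PER_L_TO_A3 = 6.02214076e-4    # mol/l -> particles per Å^3


class ConfigurationError(RuntimeError):
    pass


class TableCoverageError(KeyError):
    pass


class DivergenceError(RuntimeError):
    def __init__(self, message, residuals=None):
        super().__init__(message)
        self.residuals = residuals or []


class ComparabilityError(ValueError):
    pass


# ---------------------------------------------------------------------------
# empirical calcium affinity from ion exposure
# ---------------------------------------------------------------------------

# linear exposure->affinity coefficients (kJ/mol and kJ/(mol Å²)).  The
# empirical correlation is monotone: larger accessible surface, weaker
# (less negative) binding free energy.  The slope/intercept are configurable;
# the package's conclusions rest only on differences and on monotonicity.
EQ1_COEFFICIENTS = {"intercept": -58.0, "slope": 1.0}

CA_PROBE = 0.5  # Å, probe radius for ion-exposure surfaces


@dataclasses.dataclass
class IonSite:
    ion: AtomRecord
    site_label: str     # "Ca1" (buried) or "Ca2" (exposed)
    sasa_05: float      # Å², probe 0.5 Å
    dg_est: float       # kJ/mol


def ion_affinity(site_sasa: float, coefficients: dict | None = None) -> float:
    """Empirical binding free-energy estimate (kJ/mol) from ion exposure."""
    if site_sasa < 0:
        raise ValueError("surface area cannot be negative")
    c = EQ1_COEFFICIENTS if coefficients is None else coefficients
    if c is None or "slope" not in c or "intercept" not in c:
        raise ConfigurationError("exposure-affinity coefficients are not set")
    if c["slope"] <= 0:
        raise ConfigurationError(
            "slope must be positive: affinity weakens with exposure")
    return float(c["intercept"] + c["slope"] * site_sasa)


def ion_sites(s: StructureModel, element: str = "CA",
              coefficients: dict | None = None) -> list:
    """Locate calcium ions and label them by exposure: Ca1 buried, Ca2 exposed.

    Exposure is computed in the context of the full structure (the other ion
    present) with a 0.5 Å probe.
    """
    ions = [(i, a) for i, a in enumerate(s.atoms)
            if a.is_het and a.element.upper() == element.upper()]
    if not ions:
        return []
    areas = sasa(s, probe=CA_PROBE, targets=[i for i, _ in ions])
    order = np.argsort(areas, kind="stable")
    sites = []
    for rank, k in enumerate(order):
        label = f"Ca{rank + 1}"
        a = ions[k][1]
        sites.append(IonSite(ion=a, site_label=label,
                             sasa_05=float(areas[k]),
                             dg_est=ion_affinity(areas[k], coefficients)))
    return sites


def affinity_difference(s: StructureModel, ca1_serial: int | None = None,
                        ca2_serial: int | None = None,
                        coefficients: dict | None = None):
    """ΔΔG = ΔG(Ca2 site) − ΔG(Ca1 site), kJ/mol, for a Ca2-state structure.

    Positive values mean the Ca1 ion is bound more tightly than the Ca2 ion.
    Labels default to the exposure ordering (Ca1 buried); passing explicit
    ion serial numbers overrides the assignment (swapping them negates the
    difference).
    """
    sites = ion_sites(s, coefficients=coefficients)
    if len(sites) < 2:
        raise ComparabilityError(
            f"need two calcium ions, found {len(sites)}")
    sites = sites[:2]
    if ca1_serial is not None or ca2_serial is not None:
        by_serial = {site.ion.serial: site for site in sites}
        try:
            s1, s2 = by_serial[ca1_serial], by_serial[ca2_serial]
        except KeyError as exc:
            raise ComparabilityError(f"no calcium with serial {exc}") from exc
        s1.site_label, s2.site_label = "Ca1", "Ca2"
        sites = [s1, s2]
    ddg = sites[1].dg_est - sites[0].dg_est
    return float(ddg), sites


def affinity_difference_panel(structures, coefficients=None) -> pd.DataFrame:
    """Per-structure ΔΔG(Ca2−Ca1) table with mean ± sd in ``attrs``."""
    rows = []
    for s in structures:
        ddg, sites = affinity_difference(s, coefficients=coefficients)
        rows.append({"structure": s.source_id, "ddg_kJmol": ddg,
                     "sasa_Ca1_A2": sites[0].sasa_05,
                     "sasa_Ca2_A2": sites[1].sasa_05})
    table = pd.DataFrame(rows)
    table.attrs["mean_ddg"] = float(table["ddg_kJmol"].mean())
    table.attrs["sd_ddg"] = float(table["ddg_kJmol"].std(ddof=1)) \
        if len(table) > 1 else 0.0
    return table


# ---------------------------------------------------------------------------
# charge model
# ---------------------------------------------------------------------------

# Compact bundled charge set: integer formal charges localized on ionizable
# groups, balanced backbone and side-chain dipoles (each standard residue
# sums to its formal charge exactly), SPC/E 3-point water, +2 divalent
# metals.  Atom names are PDB convention.  Users may pass their own
# force-field table to assign_charges.
_BACKBONE_Q = {"N": -0.35, "CA": 0.35, "C": 0.55, "O": -0.55}
_CTERM_Q = {"C": 0.30, "O": -0.65, "OXT": -0.65}
_NTERM_N_Q = 0.65
_SIDECHAIN_Q = {
    "ASP": {"CG": 0.30, "OD1": -0.65, "OD2": -0.65},
    "GLU": {"CD": 0.30, "OE1": -0.65, "OE2": -0.65},
    "LYS": {"NZ": 1.00},
    "ARG": {"CZ": 0.20, "NH1": 0.40, "NH2": 0.40},
    # neutral His: ring dipole across the two nitrogens (balances even on
    # reduced ring fragments that carry only ND1/NE2)
    "HIS": {"ND1": -0.30, "NE2": 0.30},
    "SER": {"CB": 0.40, "OG": -0.40},
    "THR": {"CB": 0.40, "OG1": -0.40},
    "ASN": {"CG": 0.55, "OD1": -0.55},
    "GLN": {"CD": 0.55, "OE1": -0.55},
    "TYR": {"CZ": 0.40, "OH": -0.40},
    "TRP": {"CD1": 0.30, "NE1": -0.30},
    "CYS": {"CB": 0.20, "SG": -0.20},
    "ALA": {}, "GLY": {}, "ILE": {}, "LEU": {}, "MET": {}, "PHE": {},
    "PRO": {}, "VAL": {},
}
_WATER_Q = {"O": -0.8476, "OW": -0.8476,
            "H1": 0.4238, "H2": 0.4238, "HW1": 0.4238, "HW2": 0.4238}
_ION_Q = {"ZN": 2.0, "CA": 2.0, "MG": 2.0, "MN": 2.0, "FE": 2.0,
          "NA": 1.0, "K": 1.0, "CL": -1.0}

FORMAL_CHARGE = {"ASP": -1, "GLU": -1, "LYS": 1, "ARG": 1}


@dataclasses.dataclass
class ChargeModel:
    charges: np.ndarray     # e, aligned with structure atoms
    radii: np.ndarray       # Å
    provenance: str = "metalswitch bundled dipole/formal-charge set"
    notes: list = dataclasses.field(default_factory=list)

    @property
    def total_charge(self) -> float:
        return float(self.charges.sum())


def assign_charges(s: StructureModel, table: dict | None = None,
                   radii: dict | None = None,
                   his_tautomers: dict | None = None) -> ChargeModel:
    """Per-atom charges and radii for PB calculations.

    ``table`` optionally maps (residue_name, atom_name) to a charge and
    overrides the bundled set.  Histidine tautomers affect only the proton
    placement, which heavy-atom-only X-ray inputs lack; the bundled set
    keeps histidine neutral with a ring dipole.  Waters lacking explicit
    hydrogens are assigned zero charge and noted (a point charge on O alone
    would break residue neutrality).
    """
    rtab = dict(DEFAULT_RADII)
    if radii:
        rtab.update({k.upper(): v for k, v in radii.items()})
    notes = []
    q = np.zeros(len(s.atoms))
    r = np.zeros(len(s.atoms))

    # group atoms per residue to handle termini and waters
    res_atoms: dict = {}
    order = []
    for i, a in enumerate(s.atoms):
        rk = (a.chain_id, a.residue_number, a.insertion_code, a.residue_name)
        if rk not in res_atoms:
            res_atoms[rk] = []
            order.append(rk)
        res_atoms[rk].append(i)

    first_per_chain: dict = {}
    last_per_chain: dict = {}
    for rk in order:
        ch = rk[0]
        if not s.atoms[res_atoms[rk][0]].is_het:
            first_per_chain.setdefault(ch, rk)
            last_per_chain[ch] = rk

    for rk in order:
        ch, num, icode, rname = rk
        idx = res_atoms[rk]
        names = {s.atoms[i].atom_name: i for i in idx}
        is_water = rname in ("HOH", "WAT")
        first = first_per_chain.get(ch) == rk
        for i in idx:
            a = s.atoms[i]
            el = a.element.upper()
            if el not in rtab:
                raise TableCoverageError(
                    f"no radius for element {el} ({a.atom_name} "
                    f"{ch}/{num})")
            r[i] = rtab[el]
            if table is not None and (rname, a.atom_name) in table:
                q[i] = table[(rname, a.atom_name)]
                continue
            if is_water:
                q[i] = _WATER_Q.get(a.atom_name, 0.0)
            elif a.is_het and len(idx) == 1 and el in _ION_Q:
                q[i] = _ION_Q[el]
            elif rname in _SIDECHAIN_Q:
                if a.atom_name in ("N",) and first:
                    q[i] = _NTERM_N_Q
                elif "OXT" in names and a.atom_name in _CTERM_Q:
                    q[i] = _CTERM_Q[a.atom_name]
                elif a.atom_name in _BACKBONE_Q:
                    q[i] = _BACKBONE_Q[a.atom_name]
                else:
                    q[i] = _SIDECHAIN_Q[rname].get(a.atom_name, 0.0)
            elif a.is_het:
                q[i] = 0.0
            else:
                raise TableCoverageError(
                    f"residue {rname} {ch}/{num} not covered by charge table")
        if is_water and not any(n in names for n in
                                ("H1", "H2", "HW1", "HW2")):
            for i in idx:
                q[i] = 0.0
            notes.append(f"water {ch}/{num} has no hydrogens; "
                         "assigned zero charge")
    if notes:
        warnings.warn("; ".join(notes))
    return ChargeModel(charges=q, radii=r, notes=notes)


# ---------------------------------------------------------------------------
# finite-difference linearized Poisson-Boltzmann
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class PBOptions:
    spacing: float = 0.6            # Å
    padding: float = 10.0           # Å beyond the molecule
    eps_in: float = 2.0
    eps_out: float = 79.0
    ionic_strength: float = 0.1     # mol/l, 1:1 salt, outside only
    temperature: float = 298.15     # K
    probe: float = 1.4              # Å, dielectric-surface water probe
    tol: float = 1e-6               # relative residual
    max_iter: int = 20000
    omega: float = 1.9              # SOR relaxation


@dataclasses.dataclass
class PotentialGrid:
    origin: np.ndarray
    spacing: float
    dims: tuple
    phi: np.ndarray                 # kT/e
    options: PBOptions
    residuals: list = dataclasses.field(default_factory=list)

    def interpolate(self, points: np.ndarray) -> np.ndarray:
        """Trilinear interpolation of the potential at Cartesian points."""
        pts = (np.atleast_2d(points) - self.origin) / self.spacing
        nx, ny, nz = self.dims
        i0 = np.clip(np.floor(pts).astype(int), 0,
                     np.array([nx - 2, ny - 2, nz - 2]))
        f = pts - i0
        out = np.zeros(len(pts))
        for dx in (0, 1):
            for dy in (0, 1):
                for dz in (0, 1):
                    w = (np.where(dx, f[:, 0], 1 - f[:, 0])
                         * np.where(dy, f[:, 1], 1 - f[:, 1])
                         * np.where(dz, f[:, 2], 1 - f[:, 2]))
                    out += w * self.phi[i0[:, 0] + dx, i0[:, 1] + dy,
                                        i0[:, 2] + dz]
        return out

    def write_dx(self, path):
        """OpenDX-style volumetric output."""
        nx, ny, nz = self.dims
        with open(path, "w") as fh:
            fh.write(f"object 1 class gridpositions counts {nx} {ny} {nz}\n")
            fh.write("origin {:.6f} {:.6f} {:.6f}\n".format(*self.origin))
            fh.write(f"delta {self.spacing:.6f} 0 0\n")
            fh.write(f"delta 0 {self.spacing:.6f} 0\n")
            fh.write(f"delta 0 0 {self.spacing:.6f}\n")
            fh.write(f"object 2 class gridconnections counts {nx} {ny} {nz}\n")
            fh.write(f"object 3 class array type double rank 0 items "
                     f"{nx * ny * nz} data follows\n")
            flat = self.phi.ravel(order="C")
            for i in range(0, len(flat), 3):
                fh.write(" ".join(f"{v:.6e}" for v in flat[i:i + 3]) + "\n")
            fh.write('attribute "dep" string "positions"\n')
            fh.write('object "regular positions regular connections" '
                     'class field\n')


def _coulomb_constant(temperature: float) -> float:
    """e^2/(4 pi eps0 kT) in Å (vacuum Bjerrum length)."""
    return COULOMB_KJMOL_A / (KB_KJMOL * temperature)


def _kappa2(opt: PBOptions) -> float:
    """Debye screening kappa² (Å⁻²) in the solvent dielectric."""
    if opt.ionic_strength <= 0:
        return 0.0
    lb = _coulomb_constant(opt.temperature) / opt.eps_out
    n = 2.0 * opt.ionic_strength * AVOGADRO_PER_L_TO_A3
    return 4.0 * np.pi * lb * n


def _inside_mask(origin, spacing, dims, centers, radii):
    """Boolean grid: nodes inside any sphere (atom radius + probe)."""
    nx, ny, nz = dims
    mask = np.zeros((nx, ny, nz), dtype=bool)
    for c, rad in zip(centers, radii):
        lo = np.floor((c - rad - origin) / spacing).astype(int)
        hi = np.ceil((c + rad - origin) / spacing).astype(int)
        lo = np.maximum(lo, 0)
        hi = np.minimum(hi, [nx - 1, ny - 1, nz - 1])
        if np.any(lo > hi):
            continue
        xs = origin[0] + spacing * np.arange(lo[0], hi[0] + 1)
        ys = origin[1] + spacing * np.arange(lo[1], hi[1] + 1)
        zs = origin[2] + spacing * np.arange(lo[2], hi[2] + 1)
        d2 = ((xs - c[0])[:, None, None] ** 2
              + (ys - c[1])[None, :, None] ** 2
              + (zs - c[2])[None, None, :] ** 2)
        mask[lo[0]:hi[0] + 1, lo[1]:hi[1] + 1, lo[2]:hi[2] + 1] |= \
            d2 <= rad * rad
    return mask


def _spread_charges(origin, spacing, dims, positions, charges):
    """Trilinear assignment of point charges to grid nodes."""
    grid = np.zeros(dims)
    pts = (positions - origin) / spacing
    i0 = np.floor(pts).astype(int)
    f = pts - i0
    nx, ny, nz = dims
    for (ix, iy, iz), (fx, fy, fz), qv in zip(i0, f, charges):
        if qv == 0.0:
            continue
        if not (0 <= ix < nx - 1 and 0 <= iy < ny - 1 and 0 <= iz < nz - 1):
            raise ValueError("charge outside the grid; increase padding")
        for dx in (0, 1):
            for dy in (0, 1):
                for dz in (0, 1):
                    w = ((fx if dx else 1 - fx) * (fy if dy else 1 - fy)
                         * (fz if dz else 1 - fz))
                    grid[ix + dx, iy + dy, iz + dz] += w * qv
    return grid


def _boundary_condition(phi, origin, spacing, dims, positions, charges, opt):
    """Debye–Hückel screened-Coulomb potential on the box faces."""
    C = _coulomb_constant(opt.temperature)
    kappa = np.sqrt(_kappa2(opt)) if opt.ionic_strength > 0 else 0.0
    nx, ny, nz = dims
    axes = [origin[d] + spacing * np.arange(dims[d]) for d in range(3)]

    def fill(face_slices, pts):
        val = np.zeros(pts.shape[:-1])
        for p, qv in zip(positions, charges):
            if qv == 0.0:
                continue
            r = np.linalg.norm(pts - p, axis=-1)
            r = np.maximum(r, spacing)
            val += C * qv * np.exp(-kappa * r) / (opt.eps_out * r)
        phi[face_slices] = val

    X, Y, Z = np.meshgrid(axes[0], axes[1], axes[2], indexing="ij")
    for d, idx in ((0, 0), (0, nx - 1), (1, 0), (1, ny - 1),
                   (2, 0), (2, nz - 1)):
        sl = [slice(None)] * 3
        sl[d] = idx
        sl = tuple(sl)
        pts = np.stack([X[sl], Y[sl], Z[sl]], axis=-1)
        fill(sl, pts)


def solve_pb(s: StructureModel, q: ChargeModel,
             options: PBOptions | None = None) -> PotentialGrid:
    """Solve the linearized Poisson–Boltzmann equation on a uniform grid.

    Red–black successive over-relaxation on the standard seven-point
    finite-difference stencil with harmonic face dielectrics from the
    probe-inflated atom spheres, Debye-screened salt outside the molecule,
    trilinear charge spreading and Debye–Hückel boundary values.  Raises
    :class:`DivergenceError` (with the residual history) when the relative
    residual fails to reach ``options.tol`` within ``options.max_iter``.
    """
    opt = options or PBOptions()
    pos = s.coords()
    lo = pos.min(axis=0) - opt.padding
    hi = pos.max(axis=0) + opt.padding
    return _solve_fixed_box(s, q, opt, lo, hi)


def grid_energy(grid: PotentialGrid, positions: np.ndarray,
                charges: np.ndarray) -> float:
    """G = ½ Σ qᵢ φ(rᵢ) in kJ/mol (includes grid self-energy).

    Only meaningful in differences between legs computed on identical grids,
    where the self-energies cancel.
    """
    phi = grid.interpolate(positions)
    kT = KB_KJMOL * grid.options.temperature
    return float(0.5 * np.sum(charges * phi) * kT)


# ---------------------------------------------------------------------------
# thermodynamic cycle for the zinc-coordinating water
# ---------------------------------------------------------------------------

def _subset(s: StructureModel, keep) -> StructureModel:
    out = StructureModel(atoms=[a.copy() for i, a in enumerate(s.atoms)
                                if keep(i, a)],
                         unit_cell=s.unit_cell,
                         symmetry_ops=list(s.symmetry_ops),
                         model_id=s.model_id, source_id=s.source_id)
    return out


def _water_indices(s: StructureModel, water_key=None):
    if water_key is not None:
        ch, num = water_key[0], int(water_key[1])
        idx = [i for i, a in enumerate(s.atoms)
               if a.residue_name in ("HOH", "WAT")
               and a.chain_id == ch and a.residue_number == num]
    else:
        idx = [i for i, a in enumerate(s.atoms)
               if a.residue_name in ("HOH", "WAT")]
    if not idx:
        raise ComparabilityError("no catalytic water found in structure")
    return idx


def binding_energy(s: StructureModel, water_key=None,
                   options: PBOptions | None = None,
                   charge_table: dict | None = None,
                   _grid_box=None) -> float:
    """Electrostatic water-binding free energy via the thermodynamic cycle.

    ``dG = G(protein·water) − G(protein) − G(water)`` with all three legs
    solved on an identical grid.
    """
    opt = options or PBOptions()
    widx = set(_water_indices(s, water_key))
    q_all = assign_charges(s, table=charge_table)
    pos = s.coords()
    lo = pos.min(axis=0) - opt.padding
    hi = pos.max(axis=0) + opt.padding
    if _grid_box is not None:
        lo, hi = _grid_box
    # one dielectric/salt map, built from the full complex, shared by every
    # leg: cavity and grid self-energy terms then cancel exactly in the
    # difference, and discharging the water gives dG = 0 identically
    maps = _build_maps(pos, q_all.radii, opt, lo, hi)
    masks = {
        "complex": np.ones(len(s.atoms), dtype=bool),
        "protein": np.array([i not in widx for i in range(len(s.atoms))]),
        "water": np.array([i in widx for i in range(len(s.atoms))]),
    }
    g = {}
    for name, mask in masks.items():
        grid = _solve_on_maps(maps, pos[mask], q_all.charges[mask], opt)
        g[name] = grid_energy(grid, pos[mask], q_all.charges[mask])
    return g["complex"] - g["protein"] - g["water"]


def _build_maps(pos, radii, opt, lo, hi):
    """Grid frame, face dielectrics and salt map for a fixed box."""
    h = opt.spacing
    dims = tuple(int(v) for v in np.ceil((hi - lo) / h) + 1)
    origin = np.asarray(lo, dtype=float)
    eps_faces = []
    for d in range(3):
        off = np.zeros(3)
        off[d] = 0.5 * h
        fdims = list(dims)
        fdims[d] -= 1
        inside = _inside_mask(origin + off, h, tuple(fdims), pos,
                              radii + opt.probe)
        eps_faces.append(np.where(inside, opt.eps_in, opt.eps_out))
    inside_nodes = _inside_mask(origin, h, dims, pos, radii + opt.probe)
    kbar2 = np.where(inside_nodes, 0.0, _kappa2(opt) * opt.eps_out)
    return {"origin": origin, "dims": dims, "eps_faces": eps_faces,
            "kbar2": kbar2}


def _solve_on_maps(maps, positions, charges, opt):
    """Red-black SOR solve for a charge set on prebuilt dielectric maps."""
    origin, dims = maps["origin"], maps["dims"]
    ex, ey, ez = maps["eps_faces"]
    kbar2 = maps["kbar2"]
    h = opt.spacing
    charged = np.asarray(charges) != 0
    phi = np.zeros(dims)
    if not charged.any():
        return PotentialGrid(origin=origin, spacing=h, dims=dims, phi=phi,
                             options=opt, residuals=[0.0])
    C = _coulomb_constant(opt.temperature)
    qgrid = _spread_charges(origin, h, dims, positions[charged],
                            np.asarray(charges)[charged])
    src = 4.0 * np.pi * C * qgrid / h
    _boundary_condition(phi, origin, h, dims, positions[charged],
                        np.asarray(charges)[charged], opt)

    interior = (slice(1, -1), slice(1, -1), slice(1, -1))
    den = (ex[:-1, 1:-1, 1:-1] + ex[1:, 1:-1, 1:-1]
           + ey[1:-1, :-1, 1:-1] + ey[1:-1, 1:, 1:-1]
           + ez[1:-1, 1:-1, :-1] + ez[1:-1, 1:-1, 1:]
           + kbar2[interior] * h * h)
    ii, jj, kk = np.meshgrid(np.arange(1, dims[0] - 1),
                             np.arange(1, dims[1] - 1),
                             np.arange(1, dims[2] - 1), indexing="ij")
    red = ((ii + jj + kk) % 2 == 0)
    residuals = []
    for _ in range(opt.max_iter):
        max_delta = 0.0
        for mask in (red, ~red):
            num = (ex[:-1, 1:-1, 1:-1] * phi[:-2, 1:-1, 1:-1]
                   + ex[1:, 1:-1, 1:-1] * phi[2:, 1:-1, 1:-1]
                   + ey[1:-1, :-1, 1:-1] * phi[1:-1, :-2, 1:-1]
                   + ey[1:-1, 1:, 1:-1] * phi[1:-1, 2:, 1:-1]
                   + ez[1:-1, 1:-1, :-1] * phi[1:-1, 1:-1, :-2]
                   + ez[1:-1, 1:-1, 1:] * phi[1:-1, 1:-1, 2:]
                   + src[interior])
            new = num / den
            delta = new - phi[interior]
            upd = phi[interior]
            upd[mask] += opt.omega * delta[mask]
            phi[interior] = upd
            md = np.abs(delta[mask]).max() if mask.any() else 0.0
            max_delta = max(max_delta, float(md))
        rel = max_delta / max(np.abs(phi).max(), 1e-30)
        residuals.append(rel)
        if rel < opt.tol:
            break
    else:
        raise DivergenceError(
            f"PB solver did not converge (last residual {residuals[-1]:.3e})",
            residuals=residuals)
    return PotentialGrid(origin=origin, spacing=h, dims=dims, phi=phi,
                         options=opt, residuals=residuals)


def _solve_fixed_box(s, q, opt, lo, hi):
    """solve_pb with an externally fixed grid box (identical-grid cycles)."""
    pos = s.coords()
    maps = _build_maps(pos, q.radii, opt, lo, hi)
    return _solve_on_maps(maps, pos, q.charges, opt)


def water_binding_ddg(states: dict, water_key=None,
                      options: PBOptions | None = None,
                      charge_table: dict | None = None) -> dict:
    """ΔΔG of zinc-water binding between calcium states, kJ/mol.

    ``states`` maps labels (``Ca0``, ``Ca1``, ``Ca2``) to structures that
    differ only by calcium content, with the catalytic water placed
    identically.  Returns per-state ΔG plus ``ddg_Ca1_Ca0``, ``ddg_Ca2_Ca1``
    and ``ddg_Ca2_Ca0`` (the cycle closes by construction).
    """
    opt = options or PBOptions()
    labels = list(states)
    ref = states[labels[0]]

    def comparable_keys(s):
        return sorted(a.key for a in s.atoms
                      if not (a.is_het and a.element.upper() == "CA"))

    base = comparable_keys(ref)
    for lab in labels[1:]:
        if comparable_keys(states[lab]) != base:
            raise ComparabilityError(
                f"state {lab} differs from {labels[0]} beyond calcium content")

    # one shared grid box framing the largest state
    all_pos = np.vstack([states[k].coords() for k in labels])
    lo = all_pos.min(axis=0) - opt.padding
    hi = all_pos.max(axis=0) + opt.padding

    out = {}
    for lab in labels:
        out[f"dg_{lab}"] = binding_energy(states[lab], water_key=water_key,
                                          options=opt,
                                          charge_table=charge_table,
                                          _grid_box=(lo, hi))
    if "Ca0" in states and "Ca1" in states:
        out["ddg_Ca1_Ca0"] = out["dg_Ca1"] - out["dg_Ca0"]
    if "Ca1" in states and "Ca2" in states:
        out["ddg_Ca2_Ca1"] = out["dg_Ca2"] - out["dg_Ca1"]
    if "Ca0" in states and "Ca2" in states:
        out["ddg_Ca2_Ca0"] = out["dg_Ca2"] - out["dg_Ca0"]
    return out


# ---------------------------------------------------------------------------
# surface potential
# ---------------------------------------------------------------------------

def _sas_points(s: StructureModel, radii: np.ndarray, probe: float,
                n_points: int = 240) -> np.ndarray:
    """Sample points on the solvent-accessible surface (golden spiral)."""
    k = np.arange(n_points)
    z = 1 - (2 * k + 1) / n_points
    theta = np.pi * (3 - np.sqrt(5)) * k
    r = np.sqrt(1 - z * z)
    unit = np.stack([r * np.cos(theta), r * np.sin(theta), z], axis=1)

    pos = s.coords()
    inflated = radii + probe
    points = []
    from scipy.spatial import cKDTree
    tree = cKDTree(pos)
    rmax = inflated.max()
    for i, (c, ri) in enumerate(zip(pos, inflated)):
        sphere = c + ri * unit
        neigh = tree.query_ball_point(c, 2 * rmax)
        keep = np.ones(len(sphere), dtype=bool)
        for j in neigh:
            if j == i:
                continue
            keep &= np.linalg.norm(sphere - pos[j], axis=1) >= inflated[j] \
                - 1e-9
        points.append(sphere[keep])
    return np.vstack([p for p in points if len(p)]) \
        if any(len(p) for p in points) else np.zeros((0, 3))


def surface_potential(s: StructureModel, q: ChargeModel,
                      grid: PotentialGrid | None = None,
                      options: PBOptions | None = None,
                      patches: dict | None = None,
                      patch_radius: float = 8.0):
    """Potential (kT/e) interpolated at solvent-accessible surface points.

    ``patches`` maps names to lists of atom keys; for each patch the mean
    potential over SAS points within ``patch_radius`` Å of the patch atoms
    is reported (e.g. a zinc-center patch and a calcium-pocket patch).
    Returns ``(points, values, patch_means)``.
    """
    opt = options or (grid.options if grid is not None else PBOptions())
    if grid is None:
        grid = solve_pb(s, q, opt)
    pts = _sas_points(s, q.radii, opt.probe)
    vals = grid.interpolate(pts) if len(pts) else np.zeros(0)
    patch_means = {}
    if patches:
        for name, keys in patches.items():
            centers = []
            for key in keys:
                from .geometry import _normalize_key
                ch, num, icode, nm = _normalize_key(key)
                centers.append(s.atom(ch, num, nm, icode).position)
            if not centers:
                raise ValueError(f"patch {name!r} is empty")
            centers = np.array(centers)
            d = np.linalg.norm(pts[:, None, :] - centers[None, :, :],
                               axis=-1).min(axis=1)
            sel = d <= patch_radius
            if not sel.any():
                raise ValueError(f"patch {name!r} has no surface points")
            patch_means[name] = float(vals[sel].mean())
    return pts, vals, patch_means
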