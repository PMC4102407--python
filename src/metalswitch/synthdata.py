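"""Synthetic fixtures for every pipeline stage.

The generators encode the qualitative contrasts of the calcium-switch
model — not MD physics:

* an idealized tetrahedral zinc center (two histidine ring fragments, an
  aspartate carboxylate, a water at the fourth coordination site) flanked
  by the substrate-clamping H135/E177 pair, the calcium-coupled E127, the
  H-bond anchors G128/E54 and the two calcium sites (Ca1 caged by acidic
  oxygens and buried, Ca2 sparsely coordinated and solvent-exposed);
* Gaussian-perturbation conformational ensembles with loop-specific
  amplitudes (Ca0 boosts the calcium-binding loops 66–72, 88–94, 128–139),
  the H135–E177 clamp widening and the G128 carbonyl twist in Ca2;
* water shells with a fixed tetrahedral pose (Ca0/Ca1) or two angular
  basins with switching and identity exchange (Ca2);
* aligned Hedgehog-like families (vertebrate clade with EHHDEHH, fly clade
  with EHHTVHY, calcium-site acids conserved throughout);
* noisy exponential decay series at 0/3/6/18 h for the ShhN_AAA vs
  ShhN_AAAA stability assay.

All generators are deterministic: one global seed, per-generator substreams
derived by stable hashing of the generator name, and ground truth emitted
alongside each output.
"""

from __future__ import annotations

import dataclasses
import zlib

import numpy as np

from .decayfit import DecaySeries
from .geometry import ConformationEnsemble
from .seqcons import AlignedSet
from .structio import AtomRecord, StructureModel

__all__ = [
    "GeneratorConfig",
    "gen_center",
    "gen_shhn_like",
    "gen_ensemble",
    "gen_water_frames",
    "gen_family",
    "gen_decay",
    "LOOPS",
]

LOOPS = ((66, 72), (88, 94), (128, 139))


@dataclasses.dataclass
class GeneratorConfig:
    seed: int = 0
    state_label: str = "Ca2"
    # ensemble regime, Å
    background_amplitude: float = 0.5
    loop_amplitude: float = 1.55
    het_jitter: float = 0.1
    kernel_width: float = 3.0          # residues
    clamp_offset: float = 1.0          # H135–E177 widening in Ca2
    g128_twist: float = 1.2            # G128 carbonyl shift in Ca2
    loops: tuple = LOOPS
    # center generation
    center_sigma: float = 0.0          # isotropic Gaussian perturbation, Å
    n_decoys: int = 0
    # water regime
    water_regime: str = "fixed"        # or "bimodal"
    water_jitter: float = 0.08
    basin_angle: float = 40.0          # ° separation of the second basin
    p_basin_switch: float = 0.05
    p_exchange: float = 0.03
    # family spec
    n_vertebrates: int = 17
    n_flies: int = 13
    vert_rate: float = 0.03
    fly_rate: float = 0.08
    fly_shared_rate: float = 0.35
    rat_h181r: bool = True
    rat_d197: bool = False
    dana_e90d: bool = True
    # decay spec: (variant, pH) -> rate /h
    decay_rates: dict = dataclasses.field(default_factory=lambda: {
        ("AAA", "low"): 0.20,
        ("AAAA", "low"): 0.04,
        ("AAA", "neutral"): 0.002,
        ("AAAA", "neutral"): 0.002,
    })
    sigma_log: float = 0.1
    n_replicates: int = 3
    time_points: tuple = (0.0, 3.0, 6.0, 18.0)

    def rng(self, name: str) -> np.random.Generator:
        """Per-generator substream: seed + stable hash of the name."""
        return np.random.default_rng(
            [self.seed, zlib.crc32(name.encode("ascii"))])


# ---------------------------------------------------------------------------
# the idealized active-site constellation
# ---------------------------------------------------------------------------

def _unit(v):
    return np.asarray(v, dtype=float) / np.linalg.norm(v)


def _constellation():
    """Coordinates of the active-site and calcium-site functional atoms.

    Returns (atom dict, metadata).  The zinc sits at the origin with
    tetrahedral ligands: H141 Nδ1, H183 Nε2, D148 Oδ1, and the catalytic
    water O at 2.0 Å (the fourth site).  Both calcium positions lie on the
    hydrogen-facing flank of the water, mirroring the pocket that couples
    E127 to the calcium center.
    """
    t1 = _unit([1, 1, 1])
    t2 = _unit([1, -1, -1])
    t3 = _unit([-1, 1, -1])
    t4 = _unit([-1, -1, 1])
    p1 = _unit(np.cross(t1, t2))
    p2 = _unit(np.cross(t2, t3))
    p3 = _unit(np.cross(t3, t1))
    m = _unit(np.cross(t4, t1))

    A = {}

    def put(resnum, resname, atom_name, pos):
        A[(resnum, resname, atom_name)] = np.asarray(pos, dtype=float)

    # zinc ligand 1: H141, Nδ1 coordinates the zinc
    nd1_141 = 2.05 * t1
    ne2_141 = nd1_141 + 2.2 * _unit(0.6 * t1 + p1)
    put(141, "HIS", "ND1", nd1_141)
    put(141, "HIS", "NE2", ne2_141)
    # G128 carbonyl H-bonds the H141 ring N-H
    put(128, "GLY", "O", ne2_141 + 2.9 * _unit(ne2_141))

    # zinc ligand 2: H183, Nε2 coordinates the zinc; E54 anchors its Nδ1
    ne2_183 = 2.05 * t2
    nd1_183 = ne2_183 + 2.2 * _unit(0.6 * t2 + p2)
    put(183, "HIS", "NE2", ne2_183)
    put(183, "HIS", "ND1", nd1_183)
    d54 = _unit(nd1_183 - ne2_183)
    oe1_54 = nd1_183 + 2.7 * d54
    cd_54 = oe1_54 + 1.25 * _unit(d54 + 0.8 * p2)
    put(54, "GLU", "OE1", oe1_54)
    put(54, "GLU", "CD", cd_54)
    put(54, "GLU", "OE2", cd_54 + 1.25 * _unit(d54 - 0.8 * p2))

    # zinc ligand 3: D148 carboxylate
    od1_148 = 2.0 * t3
    cg_148 = od1_148 + 1.25 * _unit(t3 + 0.7 * p3)
    put(148, "ASP", "OD1", od1_148)
    put(148, "ASP", "CG", cg_148)
    put(148, "ASP", "OD2", cg_148 + 1.25 * _unit(t3 - 0.7 * p3))

    # catalytic water at the fourth tetrahedral site, hydrogens outward
    o_w = 2.0 * t4
    half = np.deg2rad(104.5 / 2)
    put(501, "HOH", "O", o_w)
    put(501, "HOH", "H1",
        o_w + 0.96 * (np.cos(half) * t4 + np.sin(half) * m))
    put(501, "HOH", "H2",
        o_w + 0.96 * (np.cos(half) * t4 - np.sin(half) * m))

    # E177 catalytic base, H-bonded to the water
    e_dir = _unit(m + 0.35 * t4)
    oe1_177 = o_w + 2.7 * e_dir
    cd_177 = oe1_177 + 1.25 * _unit(e_dir + 0.6 * t4)
    oe2_177 = cd_177 + 1.25 * _unit(e_dir - 0.6 * t4)
    put(177, "GLU", "OE1", oe1_177)
    put(177, "GLU", "CD", cd_177)
    put(177, "GLU", "OE2", oe2_177)

    # H181 fixates E177
    d181 = _unit(oe2_177 - cd_177)
    nd1_181 = oe2_177 + 2.8 * d181
    put(181, "HIS", "ND1", nd1_181)
    put(181, "HIS", "NE2", nd1_181 + 2.2 * d181)

    # substrate clamp: H135 across the groove from E177
    c_dir = _unit(np.cross(m, t4))
    ne2_135 = oe1_177 + 4.5 * c_dir
    nd1_135 = ne2_135 + 2.2 * _unit(c_dir + 0.5 * t4)
    put(135, "HIS", "NE2", ne2_135)
    put(135, "HIS", "ND1", nd1_135)

    # calcium positions on the hydrogen-facing flank of the water: both lie
    # near the water's H-H bisector so the ions face the positive end of the
    # dipole (the construction that makes added calcium destabilize the
    # zinc-coordinating water, as in the modelled pocket)
    ca1 = 7.2 * t4
    ca2 = 7.8 * _unit(t4 + 0.6 * m)

    # E127 couples H135 to the calcium center (coordinates both ions)
    d127 = _unit(ca1 - nd1_135)
    oe1_127 = nd1_135 + 2.7 * d127
    cd_127 = oe1_127 + 1.25 * _unit(ca1 - oe1_127)
    put(127, "GLU", "OE1", oe1_127)
    put(127, "GLU", "CD", cd_127)
    put(127, "GLU", "OE2", cd_127 + 1.25 * _unit(ca2 - cd_127))

    # Ca1 cage: six acidic oxygens in near-octahedral directions -> buried
    axes = [np.array(v, dtype=float) for v in
            ([1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0],
             [0, 0, 1], [0, 0, -1])]
    cage = [(90, "GLU", "OE1"), (90, "GLU", "OE2"),
            (91, "GLU", "OE1"), (91, "GLU", "OE2"),
            (96, "ASP", "OD1"), (96, "ASP", "OD2")]
    for (resnum, resname, aname), ax in zip(cage, axes):
        put(resnum, resname, aname, ca1 + 2.4 * ax)
    put(90, "GLU", "CD", ca1 + 3.4 * _unit(axes[0] + axes[1] + [0, 0.3, 0.2]))
    put(91, "GLU", "CD", ca1 + 3.4 * _unit(axes[2] + [0.3, 0, 0.2]))
    put(96, "ASP", "CG", ca1 + 3.4 * _unit(axes[4] + [0.2, 0.3, 0]))

    # Ca2 coordination: only three oxygens -> solvent-exposed
    u1, u2 = _unit(m + 0.4 * t4), _unit(np.cross(m, t1))
    od1_130 = ca2 + 2.4 * u1
    od1_132 = ca2 + 2.4 * u2
    put(130, "ASP", "OD1", od1_130)
    put(130, "ASP", "CG", od1_130 + 1.25 * u1)
    put(130, "ASP", "OD2", od1_130 + 1.25 * u1 + 1.25 * u2)
    put(132, "ASP", "OD1", od1_132)
    put(132, "ASP", "CG", od1_132 + 1.25 * u2)
    put(132, "ASP", "OD2", od1_132 + 1.25 * u2 + 1.25 * u1)

    meta = {"zn": np.zeros(3), "ca1": ca1, "ca2": ca2,
            "tet": (t1, t2, t3, t4), "m": m, "water_o": o_w,
            "clamp_pair": (("A", 135, "NE2"), ("A", 177, "OE1"))}
    return A, meta


_RESNAME_ONE = {"GLU": "E", "ASP": "D", "HIS": "H", "GLY": "G", "HOH": "O"}

_ELEMENT_OF = {"N": "N", "O": "O", "C": "C", "H": "H", "S": "S"}


def _element_for(atom_name: str) -> str:
    return _ELEMENT_OF.get(atom_name[0], atom_name[0])


def _mk_atom(serial, name, resname, resnum, pos, chain="A", het=False):
    return AtomRecord(serial=serial, atom_name=name,
                      element=_element_for(name) if not het
                      else name if name in ("ZN", "CA") else _element_for(name),
                      residue_name=resname, residue_number=resnum,
                      insertion_code="", chain_id=chain,
                      position=np.asarray(pos, dtype=float),
                      occupancy=1.0, b_factor=0.0, is_het=het)


# ---------------------------------------------------------------------------
# centers
# ---------------------------------------------------------------------------

_DECOY_RESIDUES = (
    ("GLU", ("CD", "OE1", "OE2")),
    ("ASP", ("CG", "OD1", "OD2")),
    ("HIS", ("ND1", "NE2")),
    ("ASN", ("CG", "OD1", "ND2")),
    ("GLN", ("CD", "OE1", "NE2")),
)


def gen_center(cfg: GeneratorConfig, state: str | None = None,
               include_second_water: bool = False) -> StructureModel:
    """Standalone active-site constellation with optional noise and decoys.

    ``state`` (default ``cfg.state_label``) selects the calcium content:
    Ca0 none, Ca1 the buried ion, Ca2 both.  ``cfg.center_sigma`` adds
    isotropic Gaussian noise to every atom; ``cfg.n_decoys`` appends decoy
    residues at random positions 10–25 Å from the zinc.  The planted
    ground-truth correspondence is stored in ``model.ground_truth``.
    """
    state = state or cfg.state_label
    A, meta = _constellation()
    rng = cfg.rng("center")
    atoms = []
    serial = 0
    for (resnum, resname, aname), pos in sorted(
            A.items(), key=lambda kv: (kv[0][0], kv[0][2])):
        if resname == "HOH":
            continue
        serial += 1
        atoms.append(_mk_atom(serial, aname, resname, resnum, pos))
    serial += 1
    atoms.append(_mk_atom(serial, "ZN", "ZN", 401, meta["zn"], het=True))
    if state in ("Ca1", "Ca2"):
        serial += 1
        atoms.append(_mk_atom(serial, "CA", "CA", 402, meta["ca1"], het=True))
    if state == "Ca2":
        serial += 1
        atoms.append(_mk_atom(serial, "CA", "CA", 403, meta["ca2"], het=True))
    for aname in ("O", "H1", "H2"):
        serial += 1
        atoms.append(_mk_atom(serial, aname, "HOH", 501,
                              A[(501, "HOH", aname)], het=True))
    if include_second_water:
        far = meta["water_o"] + 6.0 * _unit(meta["m"] + meta["tet"][3])
        for aname, off in (("O", [0, 0, 0]), ("H1", [0.76, 0.59, 0]),
                           ("H2", [-0.76, 0.59, 0])):
            serial += 1
            atoms.append(_mk_atom(serial, aname, "HOH", 502,
                                  far + np.array(off, dtype=float), het=True))

    truth = {}
    for label, resnum in (("E127", 127), ("H135", 135), ("H141", 141),
                          ("D148", 148), ("E177", 177), ("H181", 181),
                          ("H183", 183)):
        truth[label] = f"{label[0]}{resnum}"
    truth["ZN"] = "ZN401"

    if cfg.center_sigma > 0:
        for a in atoms:
            a.position = a.position + rng.normal(0.0, cfg.center_sigma, 3)

    # decoy residues scattered around the site
    for k in range(cfg.n_decoys):
        resname, names = _DECOY_RESIDUES[
            int(rng.integers(0, len(_DECOY_RESIDUES)))]
        direction = rng.normal(size=3)
        center = _unit(direction) * rng.uniform(10.0, 25.0)
        base = rng.normal(scale=1.0, size=(len(names), 3)) * 0.8
        base -= base.mean(axis=0)
        for nm, off in zip(names, base):
            serial += 1
            atoms.append(_mk_atom(serial, nm, resname, 300 + k,
                                  center + off))

    model = StructureModel(atoms=atoms, source_id=f"synthetic-center-{state}")
    model.ground_truth = truth
    model.site_meta = meta
    return model


# ---------------------------------------------------------------------------
# full ShhN-like scaffold chain
# ---------------------------------------------------------------------------

def gen_shhn_like(cfg: GeneratorConfig, state: str | None = None,
                  first: int = 40, last: int = 189) -> StructureModel:
    """Scaffold chain (residues ``first``..``last``) merged with the site.

    The backbone is a smooth helical curve — a geometric scaffold carrying
    residue identity for per-residue statistics, not a protein fold.  Site
    residues carry their constellation side-chain atoms; metals and the
    catalytic water follow the calcium ``state``.
    """
    state = state or cfg.state_label
    A, meta = _constellation()
    by_res: dict = {}
    for (resnum, resname, aname), pos in A.items():
        if resname == "HOH":
            continue
        by_res.setdefault(resnum, (resname, []))[1].append((aname, pos))

    # helical scaffold offset away from the active-site region
    theta, rise, radius = 0.35, 2.15, 9.0
    offset = np.array([28.0, 0.0, -120.0])
    atoms = []
    serial = 0
    names_three = {"E": "GLU", "D": "ASP", "H": "HIS", "G": "GLY"}
    for i, resnum in enumerate(range(first, last + 1)):
        ca = offset + np.array([radius * np.cos(theta * i),
                                radius * np.sin(theta * i), rise * i])
        tangent = _unit([-np.sin(theta * i), np.cos(theta * i),
                         rise / (radius * theta)])
        normal = _unit([np.cos(theta * i), np.sin(theta * i), 0.0])
        resname, site_atoms = by_res.get(resnum, (None, []))
        if resname is None:
            resname = "ALA" if resnum % 3 else "LEU"
        else:
            resname = names_three.get(_RESNAME_ONE[resname], resname)
        backbone = {
            "N": ca - 1.46 * tangent,
            "CA": ca,
            "C": ca + 1.52 * tangent,
            "O": ca + 1.52 * tangent + 1.23 * normal,
        }
        site_names = {nm for nm, _ in site_atoms}
        for nm in ("N", "CA", "C", "O"):
            if nm in site_names:
                continue  # the constellation version wins (e.g. G128 O)
            serial += 1
            atoms.append(_mk_atom(serial, nm, resname, resnum, backbone[nm]))
        for nm, pos in sorted(site_atoms):
            serial += 1
            atoms.append(_mk_atom(serial, nm, resname, resnum, pos))
    serial += 1
    atoms.append(_mk_atom(serial, "ZN", "ZN", 401, meta["zn"], het=True))
    if state in ("Ca1", "Ca2"):
        serial += 1
        atoms.append(_mk_atom(serial, "CA", "CA", 402, meta["ca1"], het=True))
    if state == "Ca2":
        serial += 1
        atoms.append(_mk_atom(serial, "CA", "CA", 403, meta["ca2"], het=True))
    for aname in ("O", "H1", "H2"):
        serial += 1
        atoms.append(_mk_atom(serial, aname, "HOH", 501,
                              A[(501, "HOH", aname)], het=True))
    model = StructureModel(atoms=atoms, source_id=f"synthetic-shhn-{state}")
    model.site_meta = meta
    return model


# ---------------------------------------------------------------------------
# conformational ensembles
# ---------------------------------------------------------------------------

def _smoothing_weights(n_res: int, width: float) -> np.ndarray:
    """Row-normalized (unit L2) Gaussian kernel along the chain index."""
    idx = np.arange(n_res)
    W = np.exp(-0.5 * ((idx[:, None] - idx[None, :]) / max(width, 1e-9)) ** 2)
    W /= np.sqrt((W ** 2).sum(axis=1, keepdims=True))
    return W


def gen_ensemble(cfg: GeneratorConfig, base: StructureModel | None = None,
                 n_frames: int = 500) -> ConformationEnsemble:
    """State-labelled Gaussian-perturbation ensemble around ``base``.

    Displacements are correlated along the chain (Gaussian kernel, width
    ``cfg.kernel_width`` residues) with per-residue marginal standard
    deviation ``background_amplitude``; the Ca0 regime adds an extra
    backbone-only boost in the calcium-binding loops so that the loop RMSF
    reaches ``loop_amplitude``.  The Ca2 regime widens the H135–E177 clamp
    by ``clamp_offset`` (mean shift of the E177 side chain) and twists the
    G128 carbonyl away from H141.  Ground truth is in ``ens.ground_truth``.
    """
    if n_frames < 2:
        raise ValueError("an ensemble needs at least 2 frames")
    state = cfg.state_label
    if base is None:
        base = gen_shhn_like(cfg, state=state)
    rng = cfg.rng(f"ensemble-{state}")

    polymer_res = sorted({a.residue_number for a in base.atoms
                          if not a.is_het})
    res_index = {rn: i for i, rn in enumerate(polymer_res)}
    n_res = len(polymer_res)
    W = _smoothing_weights(n_res, cfg.kernel_width)

    in_loop = np.zeros(n_res, dtype=bool)
    for lo, hi in cfg.loops:
        for rn in polymer_res:
            if lo <= rn <= hi:
                in_loop[res_index[rn]] = True
    boost = 0.0
    if state == "Ca0":
        boost = np.sqrt(max(cfg.loop_amplitude ** 2
                            - cfg.background_amplitude ** 2, 0.0))

    base_coords = base.coords()
    # Ca2 mean-structure modifications
    mean_coords = base_coords.copy()
    shift_atoms = {}
    if state == "Ca2":
        a135 = base.atom("A", 135, "NE2").position
        for i, a in enumerate(base.atoms):
            if a.residue_number == 177 and a.atom_name in ("CD", "OE1", "OE2"):
                d = _unit(a.position - a135)
                shift_atoms[i] = cfg.clamp_offset * d
            if a.residue_number == 128 and a.atom_name == "O":
                away = _unit(a.position - base.atom("A", 141, "NE2").position)
                shift_atoms[i] = cfg.g128_twist * away
        for i, sh in shift_atoms.items():
            mean_coords[i] = mean_coords[i] + sh

    bb_names = {"N", "CA", "C", "O"}
    coords = np.empty((n_frames, len(base.atoms), 3))
    for f in range(n_frames):
        field = W @ rng.normal(size=(n_res, 3))          # unit marginal var
        boost_field = rng.normal(size=(n_res, 3)) if boost else None
        frame = mean_coords.copy()
        for i, a in enumerate(base.atoms):
            if a.is_het:
                frame[i] += rng.normal(0.0, cfg.het_jitter, 3)
                continue
            r = res_index[a.residue_number]
            disp = cfg.background_amplitude * field[r]
            if boost and in_loop[r] and a.atom_name in bb_names:
                disp = disp + boost * boost_field[r]
            if state == "Ca2" and i in shift_atoms and a.atom_name == "O" \
                    and a.residue_number == 128:
                disp = disp + rng.normal(0.0, cfg.background_amplitude, 3)
            frame[i] += disp
        coords[f] = frame

    ens = ConformationEnsemble(base.copy(), coords, state_label=state)
    ens.ground_truth = {
        "background_amplitude": cfg.background_amplitude,
        "loop_amplitude": cfg.loop_amplitude if state == "Ca0"
        else cfg.background_amplitude,
        "clamp_offset": cfg.clamp_offset if state == "Ca2" else 0.0,
        "loops": cfg.loops,
    }
    return ens


# ---------------------------------------------------------------------------
# water-shell frames
# ---------------------------------------------------------------------------

def _rotation_about(axis, angle_deg):
    axis = _unit(axis)
    a = np.deg2rad(angle_deg)
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(a) * K + (1 - np.cos(a)) * (K @ K)


def gen_water_frames(cfg: GeneratorConfig,
                     center: StructureModel | None = None,
                     n: int = 300) -> ConformationEnsemble:
    """Frames emulating the catalytic-water behaviour across states.

    ``fixed`` regime (Ca0/Ca1-like): the water jitters about the fourth
    tetrahedral site; one angular mode, no identity exchange.  ``bimodal``
    regime (Ca2-like): the water hops between two angular basins separated
    by ``basin_angle`` degrees (Markov switching) and occasionally swaps
    identity with a second, outer water.  Ground truth (basin occupancy and
    exchange count) is stored in ``ens.ground_truth``.
    """
    if center is None:
        center = gen_center(cfg, include_second_water=True)
    rng = cfg.rng(f"water-{cfg.water_regime}")
    meta = center.site_meta
    t1, _, _, t4 = meta["tet"]
    axis = _unit(np.cross(t4, t1))
    Rb = _rotation_about(axis, cfg.basin_angle)

    idx_w1 = [i for i, a in enumerate(center.atoms)
              if a.residue_number == 501 and a.residue_name == "HOH"]
    idx_w2 = [i for i, a in enumerate(center.atoms)
              if a.residue_number == 502 and a.residue_name == "HOH"]
    if not idx_w1 or not idx_w2:
        raise ValueError("center must include both waters "
                         "(gen_center(include_second_water=True))")
    base = center.coords()
    w1_home = base[idx_w1].copy()
    w2_home = base[idx_w2].copy()
    w1_basin_b = (Rb @ w1_home.T).T

    coords = np.empty((n, len(center.atoms), 3))
    basin = 0
    swapped = False
    n_exchanges = 0
    basins = []
    for f in range(n):
        frame = base + rng.normal(0.0, 0.05, base.shape)
        if cfg.water_regime == "bimodal":
            if rng.random() < cfg.p_basin_switch:
                basin = 1 - basin
            if rng.random() < cfg.p_exchange:
                swapped = not swapped
                n_exchanges += 1
        w1 = (w1_basin_b if basin else w1_home) \
            + rng.normal(0.0, cfg.water_jitter, (len(idx_w1), 3))
        w2 = w2_home + rng.normal(0.0, cfg.water_jitter, (len(idx_w2), 3))
        if swapped:
            frame[idx_w1], frame[idx_w2] = w2, w1
        else:
            frame[idx_w1], frame[idx_w2] = w1, w2
        basins.append(basin)
        coords[f] = frame
    label = "Ca2" if cfg.water_regime == "bimodal" else cfg.state_label
    ens = ConformationEnsemble(center.copy(), coords, state_label=label)
    ens.ground_truth = {"regime": cfg.water_regime,
                        "basins": np.array(basins),
                        "n_exchanges": n_exchanges,
                        "basin_angle": cfg.basin_angle}
    return ens


# ---------------------------------------------------------------------------
# sequence families
# ---------------------------------------------------------------------------

_AA = "ACDEFGHIKLMNPQRSTVWY"
# background columns avoid G/A so that conserved glycines and GA/GG
# dipeptides are exactly the pinned, designed ones
_AA_BG = "CDEFHIKLMNPQRSTVWY"

# reference positions pinned across the family (mouse ShhN numbering)
_PINNED = {
    54: "E", 58: "G", 59: "A", 90: "E", 91: "E", 94: "G", 95: "A",
    96: "D", 127: "E", 128: "G", 130: "D", 132: "D", 135: "H", 141: "H",
    148: "D", 177: "E", 181: "H", 183: "H", 197: "G", 198: "G",
}
_FLY_PINNED = {148: "T", 177: "V", 183: "Y",   # EHHTVHY motif
               58: "S", 59: "T",               # G58-A59 GA lost in flies
               197: "N", 198: "S"}             # C-terminal GG lost in flies

_VERT_NAMES = ("Mouse_Shh", "Rat_Shh", "Human_Shh", "Chick_Shh",
               "Zebrafish_Shh", "Frog_Shh", "Human_Ihh", "Mouse_Ihh",
               "Chick_Ihh", "Human_Dhh", "Mouse_Dhh", "Zebrafish_Twhh",
               "Platypus_Shh", "Lizard_Shh", "Turtle_Shh", "Newt_Shh",
               "Medaka_Shh")
_FLY_NAMES = ("Dmel_Hh", "Dsim_Hh", "Dana_Hh", "Dyak_Hh", "Dere_Hh",
              "Dsec_Hh", "Dpse_Hh", "Dper_Hh", "Dwil_Hh", "Dmoj_Hh",
              "Dvir_Hh", "Dgri_Hh", "Dbus_Hh")

FAMILY_REF_START = 40
FAMILY_REF_END = 198


def gen_family(cfg: GeneratorConfig) -> AlignedSet:
    """Aligned Hedgehog-like family with pinned motif columns.

    Vertebrates carry the EHHDEHH catalytic motif (rat optionally H181R),
    flies carry EHHTVHY; the calcium-site acids are conserved everywhere
    (one fly optionally E90D).  Background columns diverge by seeded
    substitution at clade-specific rates, so the two clades separate
    cleanly in any distance tree.
    """
    rng = cfg.rng("family")
    length = FAMILY_REF_END - FAMILY_REF_START + 1
    positions = list(range(FAMILY_REF_START, FAMILY_REF_END + 1))
    root = [
        _PINNED.get(p, _AA_BG[int(rng.integers(0, len(_AA_BG)))]) for p in positions
    ]
    pinned_cols = {i for i, p in enumerate(positions) if p in _PINNED}

    fly_root = list(root)
    for i, p in enumerate(positions):
        if p in _FLY_PINNED:
            fly_root[i] = _FLY_PINNED[p]
        elif i not in pinned_cols and rng.random() < cfg.fly_shared_rate:
            fly_root[i] = _AA_BG[int(rng.integers(0, len(_AA_BG)))]

    def mutate(template, rate):
        seq = list(template)
        for i in range(length):
            if i in pinned_cols:
                continue
            if rng.random() < rate:
                seq[i] = _AA_BG[int(rng.integers(0, len(_AA_BG)))]
        return seq

    ids, seqs = [], []
    n_vert = min(cfg.n_vertebrates, len(_VERT_NAMES))
    for k in range(n_vert):
        name = _VERT_NAMES[k]
        seq = list(root) if name == "Mouse_Shh" else mutate(root,
                                                            cfg.vert_rate)
        if name == "Rat_Shh":
            if cfg.rat_h181r:
                seq[positions.index(181)] = "R"
            if cfg.rat_d197:
                seq[positions.index(197)] = "D"
        ids.append(name)
        seqs.append("".join(seq))
    n_fly = min(cfg.n_flies, len(_FLY_NAMES))
    for k in range(n_fly):
        name = _FLY_NAMES[k]
        seq = mutate(fly_root, cfg.fly_rate)
        for i, p in enumerate(positions):       # keep fly motif pinned
            if p in _FLY_PINNED:
                seq[i] = _FLY_PINNED[p]
        if name == "Dana_Hh" and cfg.dana_e90d:
            seq[positions.index(90)] = "D"
        ids.append(name)
        seqs.append("".join(seq))

    fam = AlignedSet(ids=ids, sequences=seqs, reference_id="Mouse_Shh",
                     ref_start=FAMILY_REF_START,
                     vertebrate_ids=frozenset(ids[:n_vert]))
    fam.ground_truth = {
        "vertebrates": tuple(ids[:n_vert]),
        "flies": tuple(ids[n_vert:]),
        "complete_motif": tuple(
            i for i in ids[:n_vert]
            if not (i == "Rat_Shh" and cfg.rat_h181r)),
    }
    return fam


# ---------------------------------------------------------------------------
# decay assays
# ---------------------------------------------------------------------------

def gen_decay(cfg: GeneratorConfig) -> dict:
    """Noisy exponential decay series per (variant, pH) condition.

    Intensities follow exp(−k t) with multiplicative lognormal noise
    (σ_log), normalized per replicate to the maximum observed content.
    Neutral-pH rates default to ~0 (stable for many hours).  Returns a dict
    keyed by (variant, pH) with ``DecaySeries`` values; generating rates
    are stored in ``series.ground_truth``.
    """
    rng = cfg.rng("decay")
    out = {}
    for (variant, ph), k in sorted(cfg.decay_rates.items()):
        obs = []
        for rep in range(cfg.n_replicates):
            raw = []
            for t in cfg.time_points:
                noise = np.exp(rng.normal(0.0, cfg.sigma_log)) \
                    if cfg.sigma_log > 0 else 1.0
                raw.append(np.exp(-k * t) * noise)
            peak = max(raw)
            for t, v in zip(cfg.time_points, raw):
                obs.append((float(t), float(v / peak), f"rep{rep + 1}"))
        series = DecaySeries(variant=variant, ph_label=ph, observations=obs)
        series.ground_truth = {"rate": k, "sigma_log": cfg.sigma_log}
        out[(variant, ph)] = series
    return out
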