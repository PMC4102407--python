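"""Ensemble and single-structure geometry.

Covers solvent-accessible surface areas (Shrake–Rupley), distance/angle
measurements, hydrogen-bond switch distance series (E127–H135, H135–E177,
G128–H141, E54–H183), RMSF/RMSD after least-squares superposition, greedy
RMSD clustering, catalytic-water tracking at the zinc, and the rank-based
state comparisons.

Internal coordinates are Å; RMSF/RMSD are reported in nm, matching common
usage for ensemble statistics.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .structio import StructureModel, write_structure

__all__ = [
    "ConformationEnsemble",
    "DistanceSeries",
    "WaterPose",
    "FrameCluster",
    "RankSumResult",
    "sasa",
    "measure",
    "hbond_series",
    "rmsf_profile",
    "rmsd_series",
    "cluster_frames",
    "track_water",
    "rank_sum_test",
    "DEFAULT_RADII",
]

BACKBONE_NAMES = ("N", "CA", "C", "O")

# van der Waals radii (Bondi/Mantina) for common elements; bare metal ions
# carry ionic radii since they are probed as desolvated cations
DEFAULT_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "F": 1.47, "P": 1.80,
    "S": 1.80, "CL": 1.75, "SE": 1.90, "BR": 1.85, "I": 1.98,
    "ZN": 0.74, "CA": 1.00, "MG": 0.72, "MN": 0.83, "FE": 0.78,
    "NI": 0.69, "CU": 0.73, "NA": 1.02, "K": 1.38, "CD": 0.95, "HG": 1.02,
}


# ---------------------------------------------------------------------------
# ensemble container
# ---------------------------------------------------------------------------

class ConformationEnsemble:
    """An ordered set of frames over a fixed atom set.

    Stored as a template :class:`StructureModel` (atom identities) plus a
    ``(n_frames, n_atoms, 3)`` coordinate array.  Stands in for an MD
    trajectory; multi-model PDB is the interchange format.
    """

    def __init__(self, template: StructureModel, coords: np.ndarray,
                 frame_times: np.ndarray | None = None,
                 state_label: str = "other"):
        coords = np.asarray(coords, dtype=float)
        if coords.ndim != 3 or coords.shape[2] != 3:
            raise ValueError("coords must have shape (frames, atoms, 3)")
        if coords.shape[0] < 1:
            raise ValueError("an ensemble needs at least one frame")
        if coords.shape[1] != len(template.atoms):
            raise ValueError("frame atom count differs from template")
        self.template = template
        self.coords = coords
        self.frame_times = frame_times
        self.state_label = state_label
        self._key_index = {a.key: i for i, a in enumerate(template.atoms)}

    # -- basics -----------------------------------------------------------
    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def atom_index(self, key) -> int:
        """Column index of an atom key (chain, resnum, icode, name)."""
        key = _normalize_key(key)
        try:
            return self._key_index[key]
        except KeyError:
            raise KeyError(f"atom {key} not present in ensemble")

    def frame(self, i: int) -> StructureModel:
        m = self.template.copy()
        for a, pos in zip(m.atoms, self.coords[i]):
            a.position = np.array(pos, dtype=float)
        m.model_id = i + 1
        return m

    def frames(self):
        for i in range(self.n_frames):
            yield self.frame(i)

    # -- interchange ------------------------------------------------------
    @classmethod
    def from_models(cls, models: Sequence[StructureModel],
                    state_label: str = "other") -> "ConformationEnsemble":
        keys = [a.key for a in models[0].atoms]
        for m in models[1:]:
            if [a.key for a in m.atoms] != keys:
                raise ValueError("frames do not share an identical atom set")
        coords = np.stack([m.coords() for m in models])
        return cls(models[0].copy(), coords, state_label=state_label)

    def to_pdb(self, out=None) -> str:
        return write_structure(list(self.frames()), out=out)

    def selection_indices(self, selection="backbone") -> np.ndarray:
        """Resolve a selection to atom column indices.

        ``selection`` may be ``"backbone"`` (N, CA, C, O of polymer
        residues), ``"CA"``, an iterable of atom names, or an iterable of
        integer indices.
        """
        atoms = self.template.atoms
        if isinstance(selection, str):
            names = BACKBONE_NAMES if selection == "backbone" else (selection,)
            idx = np.array([i for i, a in enumerate(atoms)
                            if not a.is_het and a.atom_name in names],
                           dtype=int)
        else:
            selection = list(selection)
            if selection and isinstance(selection[0], (int, np.integer)):
                idx = np.asarray(selection, dtype=int)
            else:
                names = set(selection)
                idx = np.array([i for i, a in enumerate(atoms)
                                if a.atom_name in names], dtype=int)
        if len(idx) == 0:
            raise ValueError(f"selection {selection!r} matches no atoms")
        return idx


def _normalize_key(key):
    """Accept (chain, resnum, name) or (chain, resnum, icode, name)."""
    if isinstance(key, str):
        parts = key.split(":")
        if len(parts) == 3:
            return (parts[0], int(parts[1]), "", parts[2])
        raise ValueError(f"cannot parse atom key {key!r}; use 'chain:res:name'")
    key = tuple(key)
    if len(key) == 3:
        return (key[0], int(key[1]), "", key[2])
    return (key[0], int(key[1]), key[2], key[3])


# ---------------------------------------------------------------------------
# SASA
# ---------------------------------------------------------------------------

class _EntityShim:
    level = "M"

    def __init__(self, atoms):
        self._atoms = atoms

    def get_atoms(self):
        return iter(self._atoms)


class _AtomShim:
    __slots__ = ("coord", "element", "sasa")

    def __init__(self, coord, element):
        self.coord = coord
        self.element = element
        self.sasa = 0.0


def sasa(s: StructureModel, probe: float = 1.4,
         targets: Iterable | None = None, n_points: int = 960,
         radii: dict | None = None) -> np.ndarray:
    """Per-atom Shrake–Rupley accessible surface areas, Å².

    All atoms of ``s`` occlude; areas are returned for ``targets`` (atom
    records or indices; default every atom).  The calcium-ion exposure that
    underlies the empirical affinity model uses ``probe=0.5``.
    """
    from Bio.PDB.SASA import ShrakeRupley

    table = dict(DEFAULT_RADII)
    if radii:
        table.update({k.upper(): v for k, v in radii.items()})
    for a in s.atoms:
        if a.element.upper() not in table:
            raise ValueError(
                f"no radius for element {a.element!r} (atom {a.atom_name} "
                f"{a.chain_id}/{a.residue_number})")
    shims = [_AtomShim(np.asarray(a.position, dtype=np.float64),
                       a.element.upper()) for a in s.atoms]
    sr = ShrakeRupley(probe_radius=probe, n_points=n_points, radii_dict=table)
    sr.compute(_EntityShim(shims), level="A")
    areas = np.array([sh.sasa for sh in shims], dtype=float)
    if targets is None:
        return areas
    idx = []
    for t in targets:
        if isinstance(t, (int, np.integer)):
            idx.append(int(t))
        else:
            idx.append(s.atoms.index(t))
    return areas[np.array(idx, dtype=int)]


# ---------------------------------------------------------------------------
# distances and angles
# ---------------------------------------------------------------------------

def measure(s: StructureModel, spec) -> float:
    """Distance (2 atom keys, Å) or planar angle at the middle atom (3, °)."""
    keys = [_normalize_key(k) for k in spec]
    if len(keys) not in (2, 3):
        raise ValueError("spec must name 2 (distance) or 3 (angle) atoms")
    pts = []
    for ch, num, icode, name in keys:
        pts.append(s.atom(ch, num, name, icode).position)
    pts = np.array(pts, dtype=float)
    if len(pts) == 2:
        return float(np.linalg.norm(pts[0] - pts[1]))
    return _angle(pts[0], pts[1], pts[2])


def _angle(a, b, c) -> float:
    v1, v2 = a - b, c - b
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


# ---------------------------------------------------------------------------
# hydrogen-bond switch series
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class DistanceSeries:
    pair_label: str
    values: np.ndarray          # per-frame, Å
    state_label: str = "other"
    used_proton: bool = False

    @property
    def median(self) -> float:
        return float(np.median(self.values))

    @property
    def variance(self) -> float:
        return float(np.var(self.values))


def hbond_series(e: ConformationEnsemble, pairs) -> list:
    """Per-frame donor–acceptor distances for H-bond pairs.

    Each pair is ``(donor_key, acceptor_key)`` or
    ``(donor_key, acceptor_key, proton_name)``.  When the named proton (or
    any hydrogen bonded to the donor by naming convention) is present it is
    used; otherwise the donor heavy atom is used and the series is flagged
    (X-ray inputs typically lack hydrogens).
    """
    out = []
    for pair in pairs:
        proton_name = None
        if len(pair) == 3:
            donor_key, acceptor_key, proton_name = pair
        else:
            donor_key, acceptor_key = pair
        dk = _normalize_key(donor_key)
        ak = _normalize_key(acceptor_key)
        used_proton = False
        src_key = dk
        if proton_name is not None:
            hk = (dk[0], dk[1], dk[2], proton_name)
            if hk in e._key_index:
                src_key = hk
                used_proton = True
        i, j = e.atom_index(src_key), e.atom_index(ak)
        d = np.linalg.norm(e.coords[:, i, :] - e.coords[:, j, :], axis=1)
        label = (f"{dk[0]}:{dk[1]}:{src_key[3]}"
                 f"–{ak[0]}:{ak[1]}:{ak[3]}")
        out.append(DistanceSeries(pair_label=label, values=d,
                                  state_label=e.state_label,
                                  used_proton=used_proton))
    return out


# ---------------------------------------------------------------------------
# superposition-based ensemble statistics
# ---------------------------------------------------------------------------

def _kabsch(P, Q):
    """Rotation matrix minimizing RMSD(P R^T, Q) for centered P, Q."""
    H = P.T @ Q
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    return Vt.T @ np.diag([1.0, 1.0, d]) @ U.T


def _superpose_frames(coords, sel, n_iter=3):
    """Least-squares fit every frame onto the iterated ensemble average.

    The fit uses the ``sel`` atom columns; the transform is applied to all
    atoms.  Returns the fitted coordinate array.
    """
    fitted = coords.copy()
    ref = fitted[0, sel]
    ref = ref - ref.mean(axis=0)
    for _ in range(n_iter):
        for f in range(fitted.shape[0]):
            P = fitted[f, sel]
            cp = P.mean(axis=0)
            R = _kabsch(P - cp, ref - ref.mean(axis=0))
            fitted[f] = (fitted[f] - cp) @ R.T + ref.mean(axis=0)
        ref = fitted[:, sel].mean(axis=0)
    return fitted


def rmsf_profile(e: ConformationEnsemble, selection="backbone",
                 superpose_selection=None):
    """Per-residue RMSF about the ensemble mean, in nm.

    Frames are least-squares superposed onto the (iteratively refined)
    ensemble average using ``superpose_selection`` (default: the analysis
    selection itself), then per-atom mean-square fluctuations are averaged
    within each residue.  Returns a pandas Series indexed by residue number.
    """
    import pandas as pd

    if e.n_frames < 2:
        raise ValueError("RMSF is undefined for a single frame")
    sel = e.selection_indices(selection)
    fit_sel = sel if superpose_selection is None \
        else e.selection_indices(superpose_selection)
    fitted = _superpose_frames(e.coords, fit_sel)
    mean = fitted.mean(axis=0)
    msf = ((fitted - mean) ** 2).sum(axis=2).mean(axis=0)  # per atom, Å²

    resnums = np.array([e.template.atoms[i].residue_number for i in sel])
    order = []
    acc: dict = {}
    for i, rn in zip(sel, resnums):
        if rn not in acc:
            acc[rn] = []
            order.append(rn)
        acc[rn].append(msf[i])
    values = [np.sqrt(np.mean(acc[rn])) / 10.0 for rn in order]  # Å -> nm
    return pd.Series(values, index=order, name=f"rmsf_nm_{e.state_label}")


def rmsd_series(e: ConformationEnsemble, reference: StructureModel,
                selection="backbone") -> np.ndarray:
    """Per-frame least-squares-superposed RMSD to ``reference``, in nm."""
    if e.n_frames < 1:
        raise ValueError("empty ensemble")
    sel = e.selection_indices(selection)
    ref_coords = np.array(
        [reference.atom(*_split_key(e.template.atoms[i].key)).position
         for i in sel])
    ref0 = ref_coords - ref_coords.mean(axis=0)
    out = np.empty(e.n_frames)
    for f in range(e.n_frames):
        P = e.coords[f, sel]
        P0 = P - P.mean(axis=0)
        R = _kabsch(P0, ref0)
        out[f] = np.sqrt((((P0 @ R.T) - ref0) ** 2).sum() / len(sel))
    return out / 10.0  # Å -> nm


def _split_key(key):
    ch, num, icode, name = key
    return (ch, num, name, icode)


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class FrameCluster:
    center: int
    members: list


def cluster_frames(e: ConformationEnsemble, cutoff: float = 0.1,
                   selection="backbone") -> list:
    """Greedy leader clustering on mutual superposed RMSD.

    ``cutoff`` is in nm.  The frame with the largest neighbourhood becomes a
    cluster center, its members are removed, and the procedure repeats;
    clusters are returned sorted by size (ties: earlier center first).
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if e.n_frames < 2:
        return [FrameCluster(center=0, members=list(range(e.n_frames)))]
    sel = e.selection_indices(selection)
    X = e.coords[:, sel, :]
    X0 = X - X.mean(axis=1, keepdims=True)
    n = e.n_frames
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            R = _kabsch(X0[j], X0[i])
            d = np.sqrt((((X0[j] @ R.T) - X0[i]) ** 2).sum() / len(sel)) / 10.0
            dist[i, j] = dist[j, i] = d

    remaining = list(range(n))
    clusters = []
    while remaining:
        sizes = [(sum(dist[i, j] <= cutoff for j in remaining), -i)
                 for i in remaining]
        best = max(range(len(remaining)), key=lambda k: sizes[k])
        center = remaining[best]
        members = [j for j in remaining if dist[center, j] <= cutoff]
        clusters.append(FrameCluster(center=center, members=members))
        remaining = [j for j in remaining if j not in set(members)]
    clusters.sort(key=lambda c: (-len(c.members), c.center))
    return clusters


# ---------------------------------------------------------------------------
# catalytic-water tracking
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class WaterPose:
    frame_index: int
    water_id: tuple | None
    d_zn: float | None
    alpha: float | None
    beta: float | None
    exchanged: bool
    absent: bool = False


def track_water(e: ConformationEnsemble, zn_key, ref_atom_key,
                beta_ref_key=None, d_max: float = 3.0) -> list:
    """Track the water oxygen nearest the zinc ion, frame by frame.

    For each frame the closest water O within ``d_max`` Å of the zinc is
    reported with its Zn distance, the angle alpha = O–Zn–N(H141 reference
    atom), the second pose angle beta = O–Zn–(beta reference atom, default
    the D148 carboxylate carbon when given), and a flag marking frames where
    the identity of the nearest water changed.  Frames with no water within
    ``d_max`` yield an absent pose.
    """
    if d_max <= 0:
        raise ValueError("d_max must be positive")
    i_zn = e.atom_index(zn_key)
    i_ref = e.atom_index(ref_atom_key)
    i_beta = e.atom_index(beta_ref_key) if beta_ref_key is not None else None

    waters = [(i, a.key) for i, a in enumerate(e.template.atoms)
              if a.residue_name in ("HOH", "WAT") and a.atom_name in ("O", "OW")]
    poses = []
    prev_id = None
    for f in range(e.n_frames):
        zn = e.coords[f, i_zn]
        if waters:
            wc = e.coords[f, [i for i, _ in waters], :]
            d = np.linalg.norm(wc - zn, axis=1)
            k = int(np.argmin(d))
        if not waters or d[k] > d_max:
            poses.append(WaterPose(frame_index=f, water_id=None, d_zn=None,
                                   alpha=None, beta=None, exchanged=False,
                                   absent=True))
            continue
        wkey = waters[k][1]
        o = wc[k]
        alpha = _angle(o, zn, e.coords[f, i_ref])
        beta = _angle(o, zn, e.coords[f, i_beta]) \
            if i_beta is not None else None
        poses.append(WaterPose(
            frame_index=f, water_id=wkey, d_zn=float(d[k]),
            alpha=alpha, beta=beta,
            exchanged=(prev_id is not None and wkey != prev_id)))
        prev_id = wkey
    return poses


# ---------------------------------------------------------------------------
# rank-sum test
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class RankSumResult:
    statistic: float            # Mann-Whitney U of the first sample
    p_value: float
    method: str                 # "exact" or "asymptotic"
    degenerate: bool = False


def rank_sum_test(x, y, alternative: str = "two-sided") -> RankSumResult:
    """Wilcoxon–Mann–Whitney rank-sum test for two independent samples.

    Uses the exact null distribution when both samples have n <= 12 and no
    ties are present, and the normal approximation with tie correction
    otherwise.  Two identical constant samples are degenerate: p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 1 or len(y) < 1:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return RankSumResult(statistic=len(x) * len(y) / 2.0, p_value=1.0,
                             method="degenerate", degenerate=True)
    has_ties = len(np.unique(pooled)) < len(pooled)
    exact = (len(x) <= 12 and len(y) <= 12 and not has_ties)
    res = stats.mannwhitneyu(x, y, alternative=alternative,
                             method="exact" if exact else "asymptotic")
    return RankSumResult(statistic=float(res.statistic),
                         p_value=float(res.pvalue),
                         method="exact" if exact else "asymptotic")
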