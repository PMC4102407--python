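"""Local metal-center constellation matching.

Superimposes an ordered constellation of functional groups (e.g. the
eight-group ShhN zinc center) onto candidate groups in a target structure,
sequence-order-free: correspondences are enumerated between chemically
compatible groups, pruned by pairwise-distance compatibility, rigidly
superposed, and ranked by coverage (descending) then RMSD (ascending).

Carboxylate oxygens and the two imidazole nitrogens are treated as
symmetry-equivalent: both pairings are tried and the better one kept.
"""

from __future__ import annotations

import dataclasses
import itertools
import logging
import warnings

import numpy as np
import pandas as pd

from .structio import (CenterGroup, CenterTemplate, StructureModel,
                       FUNCTIONAL_ATOMS, SWAP_PAIRS, CHEMICAL_CLASS,
                       THREE_TO_ONE)

__all__ = [
    "SuperpositionResult",
    "MatchResult",
    "MatchBudgetError",
    "superpose",
    "match_center",
    "scan_structures",
    "align_calpha",
    "CONSERVATIVE_CLASSES",
]

logger = logging.getLogger(__name__)

# physico-chemical substitution classes for conservative matching;
# H<->K/R via generic N-donor is deliberately disabled by default
CONSERVATIVE_CLASSES = (
    {"D", "E"},
    {"N", "Q"},
    {"S", "T"},
    {"K", "R"},
    {"I", "L", "V", "M"},
    {"F", "Y", "W"},
)


class MatchBudgetError(RuntimeError):
    """Combinatorial budget exceeded; ``partial`` holds results found so far."""

    def __init__(self, message, partial=None):
        super().__init__(message)
        self.partial = partial or []


@dataclasses.dataclass
class SuperpositionResult:
    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    degenerate: bool = False

    def __iter__(self):
        return iter((self.rotation, self.translation, self.rmsd))


@dataclasses.dataclass
class MatchResult:
    rotation: np.ndarray
    translation: np.ndarray
    correspondence: list        # (template group label, target group label)
    coverage: int
    rmsd: float
    target_id: str = ""
    mode: str = "identical"


def superpose(coords_a: np.ndarray, coords_b: np.ndarray) -> SuperpositionResult:
    """Least-squares rigid superposition of paired point sets (Kabsch).

    Returns the proper rotation R and translation t minimizing
    ``RMSD(R a + t, b)``; improper solutions are excluded.  Collinear or
    coincident sets are flagged degenerate but a solution is still returned.
    """
    A = np.asarray(coords_a, dtype=float)
    B = np.asarray(coords_b, dtype=float)
    if A.shape != B.shape or A.ndim != 2 or A.shape[1] != 3:
        raise ValueError("coordinate sets must be paired n x 3 arrays")
    n = A.shape[0]
    if n < 3:
        raise ValueError("superposition is underdetermined for n < 3 points")

    ca, cb = A.mean(axis=0), B.mean(axis=0)
    A0, B0 = A - ca, B - cb
    H = A0.T @ B0
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cb - R @ ca
    diff = (A0 @ R.T) - B0
    rmsd = float(np.sqrt((diff ** 2).sum() / n))
    # rank deficiency of the covariance => collinear/coplanar degeneracy
    degenerate = bool(np.linalg.matrix_rank(A0, tol=1e-8) < 2
                      or S[1] < 1e-10 * max(S[0], 1.0))
    return SuperpositionResult(rotation=R, translation=t, rmsd=rmsd,
                               degenerate=degenerate)


# ---------------------------------------------------------------------------
# target group harvesting
# ---------------------------------------------------------------------------

_METAL_ELEMENTS = {"ZN", "CA", "MG", "MN", "FE", "NI", "CU", "CO", "CD", "NA",
                   "K", "HG"}


def harvest_groups(target: StructureModel, include_water: bool = False) -> list:
    """Collect candidate functional groups (and metals) from a structure."""
    groups = []
    for (ch, num, icode, rname), atoms in target.residues():
        if rname in ("HOH", "WAT") and not include_water:
            continue
        names = FUNCTIONAL_ATOMS.get(rname)
        if names is not None:
            by_name = {a.atom_name: a for a in atoms}
            if all(nm in by_name for nm in names):
                coords = np.array([by_name[nm].position for nm in names])
                groups.append(CenterGroup(
                    label=f"{THREE_TO_ONE.get(rname, 'X')}{num}",
                    chain_id=ch,
                    residue_class=THREE_TO_ONE.get(rname, "X"),
                    atom_names=names,
                    chemical_class=CHEMICAL_CLASS[rname],
                    coords=coords,
                    swap_pairs=SWAP_PAIRS.get(rname, ())))
    for a in target.atoms:
        if a.is_het and a.element.upper() in _METAL_ELEMENTS:
            groups.append(CenterGroup(
                label=f"{a.element.upper()}{a.residue_number}",
                chain_id=a.chain_id,
                residue_class=a.element.upper(),
                atom_names=(a.atom_name,),
                chemical_class=f"metal:{a.element.upper()}",
                coords=a.position.reshape(1, 3)))
    return groups


def _compatible(tpl: CenterGroup, tgt: CenterGroup, mode: str) -> bool:
    if tpl.chemical_class.startswith("metal"):
        return tpl.residue_class == tgt.residue_class \
            and tgt.chemical_class.startswith("metal")
    if tgt.chemical_class.startswith("metal"):
        return False
    if len(tpl.atom_names) != len(tgt.atom_names):
        return False
    if tpl.residue_class == tgt.residue_class:
        return True
    if mode == "conservative":
        for cls in CONSERVATIVE_CLASSES:
            if tpl.residue_class in cls and tgt.residue_class in cls:
                return True
    return False


def _swap_variants(group: CenterGroup):
    """All coordinate orderings generated by symmetry-equivalent atom swaps."""
    variants = [group.coords]
    for (i, j) in group.swap_pairs:
        new = []
        for c in variants:
            cs = c.copy()
            cs[[i, j]] = cs[[j, i]]
            new.append(cs)
        variants.extend(new)
    return variants


def _best_superposition(tpl_groups, tgt_groups):
    """Superpose matched groups, enumerating swap-equivalent pairings exactly."""
    variant_sets = [_swap_variants(g) for g in tgt_groups]
    tpl_coords = np.vstack([g.coords for g in tpl_groups])
    best = None
    for combo in itertools.product(*variant_sets):
        tgt_coords = np.vstack(combo)
        sp = superpose(tpl_coords, tgt_coords)
        if best is None or sp.rmsd < best.rmsd:
            best = sp
    return best


# ---------------------------------------------------------------------------
# matching
# ---------------------------------------------------------------------------

def match_center(template: CenterTemplate, target: StructureModel,
                 mode: str = "identical", max_rmsd: float = 2.5,
                 min_coverage: int | None = None,
                 budget: int = 10 ** 6) -> list:
    """Find placements of ``template`` among the groups of ``target``.

    Enumerates injective correspondences between template groups and
    chemically compatible target groups (same residue class, or same
    substitution class in ``conservative`` mode), prunes partial assignments
    whose pairwise centroid distances disagree beyond ``2*max_rmsd + 0.2`` Å,
    superposes the survivors and ranks by coverage then RMSD.  Results with
    coverage below ``min_coverage`` or RMSD above ``max_rmsd`` are dropped.
    """
    if mode not in ("identical", "conservative"):
        raise ValueError(f"unknown mode {mode!r}")
    if max_rmsd <= 0:
        raise ValueError("max_rmsd must be positive")
    n_groups = len(template.groups)
    if min_coverage is None:
        min_coverage = n_groups
    tol = 2.0 * max_rmsd + 0.2

    tgt_groups = harvest_groups(target)
    candidates = []
    for tg in template.groups:
        candidates.append([i for i, g in enumerate(tgt_groups)
                           if _compatible(tg, g, mode)])
    if all(not c for c in candidates):
        return []

    tpl_centroids = np.array([g.coords.mean(axis=0) for g in template.groups])
    tgt_centroids = np.array([g.coords.mean(axis=0) for g in tgt_groups]) \
        if tgt_groups else np.zeros((0, 3))
    tpl_dist = np.linalg.norm(
        tpl_centroids[:, None, :] - tpl_centroids[None, :, :], axis=-1)
    tgt_dist = np.linalg.norm(
        tgt_centroids[:, None, :] - tgt_centroids[None, :, :], axis=-1) \
        if len(tgt_groups) else np.zeros((0, 0))

    max_skips = n_groups - min_coverage
    results = []
    nodes = [0]

    # search template groups in order of increasing candidate count
    order = sorted(range(n_groups), key=lambda i: (len(candidates[i]), i))

    def recurse(pos, assigned, used, skips):
        nodes[0] += 1
        if nodes[0] > budget:
            raise MatchBudgetError(
                f"combinatorial budget of {budget} assignments exceeded",
                partial=results)
        if pos == n_groups:
            if len(assigned) >= min_coverage:
                _finish(assigned)
            return
        i = order[pos]
        for j in candidates[i]:
            if j in used:
                continue
            ok = True
            for (k, jj) in assigned:
                if abs(tpl_dist[i, k] - tgt_dist[j, jj]) > tol:
                    ok = False
                    break
            if ok:
                assigned.append((i, j))
                used.add(j)
                recurse(pos + 1, assigned, used, skips)
                used.discard(j)
                assigned.pop()
        if skips < max_skips:
            recurse(pos + 1, assigned, used, skips + 1)

    def _finish(assigned):
        pairs = sorted(assigned)
        tpl_sel = [template.groups[i] for i, _ in pairs]
        tgt_sel = [tgt_groups[j] for _, j in pairs]
        sp = _best_superposition(tpl_sel, tgt_sel)
        if sp.rmsd > max_rmsd:
            return
        results.append(MatchResult(
            rotation=sp.rotation, translation=sp.translation,
            correspondence=[(template.groups[i].label, tgt_groups[j].label)
                            for i, j in pairs],
            coverage=len(pairs), rmsd=sp.rmsd,
            target_id=target.source_id, mode=mode))

    recurse(0, [], set(), 0)

    results.sort(key=lambda r: (-r.coverage, r.rmsd,
                                tuple(r.correspondence)))
    # drop duplicate correspondences dominated by better partial variants
    seen = set()
    unique = []
    for r in results:
        key = tuple(r.correspondence)
        if key not in seen:
            seen.add(key)
            unique.append(r)
    return unique


def align_calpha(source: StructureModel, target: StructureModel,
                 initial_rotation: np.ndarray | None = None,
                 initial_translation: np.ndarray | None = None,
                 pair_cutoff: float = 5.0, max_iter: int = 50):
    """Sequence-order-free Cα alignment by iterative closest point.

    Starting from an optional initial transform (e.g. from a metal-center
    match), Cα atoms of ``source`` are greedily paired one-to-one with their
    nearest ``target`` Cα within ``pair_cutoff`` Å, refit by least squares,
    and iterated to convergence.  Returns ``(rmsd, n_pairs, rotation,
    translation)`` over the final pairing — the global-fold comparison used
    for e.g. ShhN vs the VanX dipeptidase.
    """
    src = np.array([a.position for a in source.atoms
                    if a.atom_name == "CA" and not a.is_het])
    tgt = np.array([a.position for a in target.atoms
                    if a.atom_name == "CA" and not a.is_het])
    if len(src) < 3 or len(tgt) < 3:
        raise ValueError("both structures need at least 3 CA atoms")
    R = np.eye(3) if initial_rotation is None else initial_rotation
    t = np.zeros(3) if initial_translation is None else initial_translation
    prev_pairs = None
    rmsd = np.inf
    for _ in range(max_iter):
        moved = src @ R.T + t
        d = np.linalg.norm(moved[:, None, :] - tgt[None, :, :], axis=-1)
        order = np.dstack(np.unravel_index(np.argsort(d, axis=None),
                                           d.shape))[0]
        used_s, used_t, pairs = set(), set(), []
        for i, j in order:
            if d[i, j] > pair_cutoff:
                break
            if i in used_s or j in used_t:
                continue
            used_s.add(i)
            used_t.add(j)
            pairs.append((int(i), int(j)))
        if len(pairs) < 3:
            return np.inf, len(pairs), R, t
        pairs.sort()
        sp = superpose(src[[i for i, _ in pairs]],
                       tgt[[j for _, j in pairs]])
        R, t, rmsd = sp.rotation, sp.translation, sp.rmsd
        if pairs == prev_pairs:
            break
        prev_pairs = pairs
    return rmsd, len(prev_pairs or pairs), R, t


def scan_structures(template: CenterTemplate, targets, mode: str = "identical",
                    max_rmsd: float = 2.5, min_coverage: int | None = None,
                    budget: int = 10 ** 6) -> pd.DataFrame:
    """Best match per target structure, as a deterministic hit table.

    ``targets`` is a list of :class:`StructureModel` (their ``source_id``
    labels the rows).  Unmatchable targets yield no row; unreadable or
    failing targets are skipped with a logged warning.
    """
    if not targets:
        raise ValueError("no target structures given")
    rows = []
    hits = {}
    for t in targets:
        try:
            res = match_center(template, t, mode=mode, max_rmsd=max_rmsd,
                               min_coverage=min_coverage, budget=budget)
        except MatchBudgetError as exc:
            logger.warning("budget exceeded for %s: %s", t.source_id, exc)
            res = exc.partial
        except Exception as exc:  # noqa: BLE001 - scan must not be fatal
            warnings.warn(f"skipping target {t.source_id!r}: {exc}")
            continue
        if not res:
            continue
        best = res[0]
        hits[t.source_id] = best
        rows.append({
            "target_id": t.source_id,
            "coverage": best.coverage,
            "rmsd_A": best.rmsd,
            "rmsd_nm": best.rmsd / 10.0,
            "matched_groups": ";".join(
                f"{a}>{b}" for a, b in best.correspondence),
        })
    table = pd.DataFrame(rows, columns=["target_id", "coverage", "rmsd_A",
                                        "rmsd_nm", "matched_groups"])
    table = table.sort_values(
        by=["coverage", "rmsd_A", "target_id"],
        ascending=[False, True, True]).reset_index(drop=True)
    table.attrs["results"] = hits
    return table
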