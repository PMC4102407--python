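"""Conservation analysis of Hedgehog families and distance phylogeny.

Works on pre-aligned families (aligned FASTA; alignment construction is out
of scope).  Positions are reported in the reference numbering of the mouse
ShhN sequence (the catalytic motif EHHDEHH = E127, H135, H141, D148, E177,
H181, H183; calcium-site acids E90, E91, D96, E127, D130, D132; candidate
glycine cleavage sites such as the C-terminal G197–G198 GG and the G58/G94
GA motifs).

The tree is a BioNJ agglomeration (variance-weighted neighbor joining) on
p-distances, with column-resampling bootstrap support.
"""

from __future__ import annotations

import dataclasses
import io

import dendropy
import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "AlignedSet",
    "MotifReport",
    "MOTIF_POSITIONS",
    "CA_SITE_POSITIONS",
    "scan_catalytic_motif",
    "scan_calcium_site",
    "find_cleavage_candidates",
    "distance_matrix",
    "build_tree",
    "bootstrap_support",
    "tree_splits",
]

MOTIF_POSITIONS = (127, 135, 141, 148, 177, 181, 183)
MOTIF_REFERENCE = "EHHDEHH"
CA_SITE_POSITIONS = (90, 91, 96, 127, 130, 132)

# physico-chemical classes used to annotate conservative exchanges
# (H joins the basic class here: H181->R in rat is a conservative exchange)
SUBSTITUTION_CLASSES = (
    {"D", "E"},
    {"N", "Q"},
    {"S", "T"},
    {"H", "K", "R"},
    {"I", "L", "V", "M"},
    {"F", "Y", "W"},
)

KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5,
    "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9,
    "M": 1.9, "F": 2.8, "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9,
    "Y": -1.3, "V": 4.2,
}


def _is_conservative(a: str, b: str) -> bool:
    if a == b:
        return True
    return any(a in cls and b in cls for cls in SUBSTITUTION_CLASSES)


@dataclasses.dataclass
class AlignedSet:
    """A gapped, equal-length protein family with a numbered reference."""

    ids: list
    sequences: list                 # aligned, uppercase, '-' gaps
    reference_id: str
    ref_start: int = 1              # author number of first reference residue
    species: dict = dataclasses.field(default_factory=dict)
    vertebrate_ids: frozenset = frozenset()

    def __post_init__(self):
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise ValueError("aligned sequences differ in length")
        if self.reference_id not in self.ids:
            raise ValueError(f"reference {self.reference_id!r} not in set")
        self.sequences = [s.upper() for s in self.sequences]
        self._by_id = dict(zip(self.ids, self.sequences))
        # column -> reference position map (None at reference gaps)
        ref = self._by_id[self.reference_id]
        self.col_to_refpos = []
        pos = self.ref_start - 1
        for c in ref:
            if c == "-":
                self.col_to_refpos.append(None)
            else:
                pos += 1
                self.col_to_refpos.append(pos)
        self.refpos_to_col = {p: i for i, p in enumerate(self.col_to_refpos)
                              if p is not None}

    @property
    def n_columns(self) -> int:
        return len(self.sequences[0])

    def sequence(self, seq_id: str) -> str:
        return self._by_id[seq_id]

    def column_of(self, ref_position: int) -> int:
        try:
            return self.refpos_to_col[ref_position]
        except KeyError:
            raise KeyError(
                f"reference position {ref_position} maps to a gap or lies "
                "outside the alignment")

    def subset_ids(self, subset: str = "all") -> list:
        if subset == "vertebrate":
            return [i for i in self.ids if i in self.vertebrate_ids]
        return list(self.ids)

    def resample_columns(self, columns) -> "AlignedSet":
        new_seqs = ["".join(s[c] for c in columns) for s in self.sequences]
        out = AlignedSet(ids=list(self.ids), sequences=new_seqs,
                         reference_id=self.reference_id,
                         ref_start=self.ref_start,
                         species=dict(self.species),
                         vertebrate_ids=self.vertebrate_ids)
        return out

    # -- FASTA interchange ------------------------------------------------
    @classmethod
    def from_fasta(cls, handle_or_text, reference_id: str,
                   ref_start: int = 1,
                   vertebrate_ids=()) -> "AlignedSet":
        if isinstance(handle_or_text, str) and "\n" in handle_or_text:
            handle = io.StringIO(handle_or_text)
        elif isinstance(handle_or_text, str):
            handle = open(handle_or_text)
        else:
            handle = handle_or_text
        records = list(SeqIO.parse(handle, "fasta"))
        if not records:
            raise ValueError("no sequences in FASTA input")
        return cls(ids=[r.id for r in records],
                   sequences=[str(r.seq) for r in records],
                   reference_id=reference_id, ref_start=ref_start,
                   vertebrate_ids=frozenset(vertebrate_ids))

    def to_fasta(self) -> str:
        return "".join(f">{i}\n{s}\n"
                       for i, s in zip(self.ids, self.sequences))


@dataclasses.dataclass
class MotifReport:
    motif_table: pd.DataFrame           # per-sequence catalytic motif
    calcium_table: pd.DataFrame | None = None
    cleavage_table: pd.DataFrame | None = None


# ---------------------------------------------------------------------------
# motif and site scanning
# ---------------------------------------------------------------------------

def scan_catalytic_motif(a: AlignedSet) -> MotifReport:
    """Seven-position catalytic-motif string per sequence.

    Completeness means the exact reference motif EHHDEHH; deviations are
    listed as substitutions and annotated as conservative where the exchange
    stays within a physico-chemical class (e.g. H181R).
    """
    cols = []
    for pos in MOTIF_POSITIONS:
        c = a.column_of(pos)
        if a.sequence(a.reference_id)[c] == "-":
            raise ValueError(f"reference gap at motif position {pos}")
        cols.append(c)
    rows = []
    for sid in a.ids:
        seq = a.sequence(sid)
        motif = "".join(seq[c] for c in cols)
        subs = []
        all_conservative = True
        for ref_res, res, pos in zip(MOTIF_REFERENCE, motif, MOTIF_POSITIONS):
            if res != ref_res:
                subs.append(f"{ref_res}{pos}{res}")
                if not _is_conservative(ref_res, res):
                    all_conservative = False
        rows.append({
            "id": sid,
            "motif": motif,
            "complete": motif == MOTIF_REFERENCE,
            "n_substitutions": len(subs),
            "substitutions": ";".join(subs),
            "conservative_only": bool(subs) and all_conservative,
        })
    return MotifReport(motif_table=pd.DataFrame(rows))


def scan_calcium_site(a: AlignedSet) -> pd.DataFrame:
    """Residue distribution at the six calcium-coordinating acidic positions.

    D and E both count as conserved-acidic.
    """
    rows = []
    for pos in CA_SITE_POSITIONS:
        c = a.column_of(pos)
        ref_res = a.sequence(a.reference_id)[c]
        counts: dict = {}
        for sid in a.ids:
            res = a.sequence(sid)[c]
            counts[res] = counts.get(res, 0) + 1
        n = len(a.ids)
        rows.append({
            "position": pos,
            "reference": ref_res,
            "distribution": ";".join(f"{k}:{v}"
                                     for k, v in sorted(counts.items())),
            "identical_fraction": counts.get(ref_res, 0) / n,
            "acidic_fraction": (counts.get("D", 0) + counts.get("E", 0)) / n,
            "conserved_identical": counts.get(ref_res, 0) == n,
            "conserved_acidic": (counts.get("D", 0) + counts.get("E", 0)) == n,
        })
    return pd.DataFrame(rows)


def find_cleavage_candidates(a: AlignedSet, hydrophobic_window: int = 2,
                             conservation_threshold: float = 1.0,
                             subset: str = "vertebrate") -> pd.DataFrame:
    """Conserved reference glycines annotated as GG/GA/G cleavage candidates.

    A glycine qualifies when the fraction of ``subset`` sequences carrying G
    at its column reaches ``conservation_threshold``.  The dipeptide type
    follows the next reference residue (GG, GA, else G) and the mean
    Kyte–Doolittle hydropathy of a ±window context is attached (windows
    truncated at the termini are flagged).
    """
    ids = a.subset_ids(subset)
    if not ids:
        raise ValueError(f"no sequences in subset {subset!r}")
    ref_seq = a.sequence(a.reference_id)
    ref_positions = sorted(a.refpos_to_col)
    rows = []
    for pos in ref_positions:
        c = a.refpos_to_col[pos]
        if ref_seq[c] != "G":
            continue
        frac = sum(a.sequence(sid)[c] == "G" for sid in ids) / len(ids)
        if frac < conservation_threshold:
            continue
        nxt = ref_seq[a.refpos_to_col[pos + 1]] \
            if pos + 1 in a.refpos_to_col else ""
        kind = "GG" if nxt == "G" else ("GA" if nxt == "A" else "G")
        lo, hi = pos - hydrophobic_window, pos + hydrophobic_window
        ctx = [ref_seq[a.refpos_to_col[p]]
               for p in range(lo, hi + 1) if p in a.refpos_to_col]
        truncated = len(ctx) < 2 * hydrophobic_window + 1
        hyd = [KYTE_DOOLITTLE[r] for r in ctx if r in KYTE_DOOLITTLE]
        rows.append({
            "position": pos,
            "type": kind,
            "context": "".join(ctx),
            "mean_hydropathy": float(np.mean(hyd)) if hyd else np.nan,
            "conserved_fraction": frac,
            "window_truncated": truncated,
        })
    return pd.DataFrame(rows, columns=["position", "type", "context",
                                       "mean_hydropathy",
                                       "conserved_fraction",
                                       "window_truncated"])


# ---------------------------------------------------------------------------
# distances and BioNJ
# ---------------------------------------------------------------------------

def distance_matrix(a: AlignedSet, model: str = "p") -> pd.DataFrame:
    """Pairwise p-distances (proportion of differing non-gap columns).

    ``model="poisson"`` applies the Poisson correction −ln(1−p).
    """
    n = len(a.ids)
    if n < 2:
        raise ValueError("need at least two sequences")
    seqs = [np.frombuffer(s.encode(), dtype="S1") for s in a.sequences]
    gap = np.bytes_(b"-")
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = (seqs[i] != gap) & (seqs[j] != gap)
            m = int(ok.sum())
            if m == 0:
                raise ValueError(
                    f"no comparable columns between {a.ids[i]} and {a.ids[j]}")
            p = float((seqs[i][ok] != seqs[j][ok]).sum()) / m
            if model == "poisson":
                if p >= 1.0:
                    raise ValueError("Poisson correction undefined at p=1")
                p = -np.log(1.0 - p)
            d[i, j] = d[j, i] = p
    return pd.DataFrame(d, index=a.ids, columns=a.ids)


def build_tree(d: pd.DataFrame,
               taxon_namespace: dendropy.TaxonNamespace | None = None,
               clamp_negative: bool = True) -> dendropy.Tree:
    """BioNJ agglomeration of a symmetric distance matrix.

    Variance-weighted neighbor joining: at each step the pair minimizing the
    Q criterion is joined; the reduction weight λ minimizes the variance of
    the new distances.  Ties are broken by taxon label order, so repeated
    runs are byte-identical.  Negative branch lengths are clamped to zero
    when ``clamp_negative``.  n < 3 yields a trivial tree (annotated
    ``trivial=True``).
    """
    labels = list(d.index)
    D = d.to_numpy(dtype=float).copy()
    if not np.allclose(D, D.T):
        raise ValueError("distance matrix is not symmetric")
    if (D < 0).any():
        raise ValueError("distance matrix has negative entries")
    ns = taxon_namespace or dendropy.TaxonNamespace(labels)
    tree = dendropy.Tree(taxon_namespace=ns)
    nodes = []
    for lab in labels:
        node = dendropy.Node()
        node.taxon = ns.get_taxon(lab) or ns.new_taxon(lab)
        nodes.append(node)
    n = len(labels)
    if n < 3:
        tree.seed_node.annotations.add_new("trivial", True)
        for node in nodes:
            node.edge.length = D[0, 1] / 2.0 if n == 2 else 0.0
            tree.seed_node.add_child(node)
        return tree

    V = D.copy()
    active = list(range(n))
    tiebreak = {i: (labels[i],) for i in range(n)}

    def q_pair():
        r = len(active)
        S = {i: sum(D[i, j] for j in active if j != i) for i in active}
        best = None
        for ai in range(len(active)):
            for aj in range(ai + 1, len(active)):
                i, j = active[ai], active[aj]
                qv = (r - 2) * D[i, j] - S[i] - S[j]
                key = (qv, tuple(sorted((tiebreak[i], tiebreak[j]))))
                if best is None or key < best[0]:
                    best = (key, i, j, S)
        return best[1], best[2], best[3]

    node_of = dict(enumerate(nodes))
    next_idx = n
    Dg = np.pad(D, ((0, 2 * n), (0, 2 * n)))
    Vg = np.pad(V, ((0, 2 * n), (0, 2 * n)))
    D, V = Dg, Vg

    while len(active) > 3:
        i, j, S = q_pair()
        r = len(active)
        bi = 0.5 * D[i, j] + (S[i] - S[j]) / (2.0 * (r - 2))
        bj = D[i, j] - bi
        if clamp_negative:
            bi, bj = max(bi, 0.0), max(bj, 0.0)
        u = next_idx
        next_idx += 1
        # variance-minimizing reduction weight
        others = [k for k in active if k not in (i, j)]
        if V[i, j] > 0:
            lam = 0.5 + sum(V[j, k] - V[i, k] for k in others) \
                / (2.0 * (r - 2) * V[i, j])
            lam = min(max(lam, 0.0), 1.0)
        else:
            lam = 0.5
        for k in others:
            D[u, k] = D[k, u] = lam * (D[i, k] - bi) \
                + (1.0 - lam) * (D[j, k] - bj)
            V[u, k] = V[k, u] = lam * V[i, k] + (1.0 - lam) * V[j, k] \
                - lam * (1.0 - lam) * V[i, j]
        parent = dendropy.Node()
        ci, cj = node_of.pop(i), node_of.pop(j)
        parent.add_child(ci)
        parent.add_child(cj)
        ci.edge.length = bi
        cj.edge.length = bj
        node_of[u] = parent
        tiebreak[u] = min(tiebreak[i], tiebreak[j])
        active = [k for k in active if k not in (i, j)] + [u]

    # join the last three nodes in a star (unrooted resolution)
    i, j, k = active
    bi = 0.5 * (D[i, j] + D[i, k] - D[j, k])
    bj = 0.5 * (D[i, j] + D[j, k] - D[i, k])
    bk = 0.5 * (D[i, k] + D[j, k] - D[i, j])
    if clamp_negative:
        bi, bj, bk = max(bi, 0.0), max(bj, 0.0), max(bk, 0.0)
    for idx, b in ((i, bi), (j, bj), (k, bk)):
        node = node_of[idx]
        node.edge.length = b
        tree.seed_node.add_child(node)
    tree.is_rooted = False
    return tree


def tree_splits(tree: dendropy.Tree) -> set:
    """Non-trivial splits as frozensets of taxon labels.

    Each internal edge is represented by the leaf-label side not containing
    the alphabetically first taxon, giving a canonical form for unrooted
    comparison.
    """
    labels = sorted(t.label for t in tree.taxon_namespace)
    anchor = labels[0]
    all_set = frozenset(labels)
    splits = set()
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node or edge.head_node.is_leaf():
            continue
        side = frozenset(lf.taxon.label
                         for lf in edge.head_node.leaf_iter())
        if anchor in side:
            side = all_set - side
        if 1 < len(side) < len(labels) - 1:
            splits.add(side)
    return splits


def bootstrap_support(a: AlignedSet, n: int = 100, seed: int = 0,
                      model: str = "p") -> dict:
    """Column-resampling bootstrap support for the splits of the BioNJ tree.

    A single seeded stream drives all replicates (replicate r consumes draw
    r), so runs are reproducible.  Returns a mapping from canonical splits
    of the full-alignment tree to support percentages.
    """
    if n < 1:
        raise ValueError("need at least one replicate")
    base = build_tree(distance_matrix(a, model=model))
    base_splits = tree_splits(base)
    counts = {sp: 0 for sp in base_splits}
    rng = np.random.default_rng(seed)
    ncol = a.n_columns
    ns = base.taxon_namespace
    for _ in range(n):
        cols = rng.integers(0, ncol, size=ncol)
        rep = a.resample_columns(cols)
        rep_tree = build_tree(distance_matrix(rep, model=model),
                              taxon_namespace=ns)
        rep_splits = tree_splits(rep_tree)
        for sp in counts:
            if sp in rep_splits:
                counts[sp] += 1
    return {sp: 100.0 * c / n for sp, c in counts.items()}
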