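"""Protein phylogenetics: multiple alignment, percent-identity matrices,
neighbor-joining trees with bootstrap, tree comparison, and phylogeny-based
subgroup classification.

Distances are p-distances from the alignment-based percent identity
(d = 1 - pid/100, pairwise deletion of gap columns); trees are built with
the Saitou-Nei neighbor-joining algorithm, exact on additive matrices, with
deterministic tie-breaking (smallest index pair in the current matrix) and
negative branch lengths clamped to zero.  Bootstrap supports come from
column resampling with replacement.  A query is assigned to a subgroup when
its smallest enclosing clade contains references of exactly one subgroup at
support >= 75, with a best-identity fallback at >= 20% identity.
"""

from __future__ import annotations

import dataclasses
import io as _stdio
import warnings
from typing import Sequence

import numpy as np
from numba import njit
from scipy.cluster.hierarchy import linkage
from skbio import TreeNode
from Bio.Align import substitution_matrices

from .errors import MicromineError
from .io import SequenceRecord

AA20 = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {ch: i for i, ch in enumerate(AA20)}
_GAP = ord("-")


def _blosum_matrix() -> np.ndarray:
    b = substitution_matrices.load("BLOSUM62")
    m = np.zeros((20, 20))
    for i, a in enumerate(AA20):
        for j, c in enumerate(AA20):
            m[i, j] = b[a][c]
    return m


_B62 = _blosum_matrix()


@dataclasses.dataclass
class ProteinAlignment:
    """A gap-padded multiple protein alignment (rows in input order)."""

    ids: list[str]
    rows: list[str]

    def __post_init__(self):
        if len(self.ids) != len(self.rows) or len(self.rows) < 2:
            raise MicromineError("alignment needs >= 2 rows with matching ids")
        if len({len(r) for r in self.rows}) != 1:
            raise MicromineError("alignment rows must have equal length")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0])

    def degapped(self, i: int) -> str:
        return self.rows[i].replace("-", "")

    def as_array(self) -> np.ndarray:
        return np.array([np.frombuffer(r.encode(), dtype=np.uint8) for r in self.rows])


@dataclasses.dataclass
class IdentityMatrix:
    ids: list[str]
    values: np.ndarray  # symmetric, diagonal 100, percent in [0, 100]


# -- progressive MSA -------------------------------------------------------

@njit(cache=True)
def _profile_dp(S, gap_open, gap_ext):
    """Global affine-gap profile-profile DP; a gap of length g costs
    gap_open + g * gap_ext.  Returns (steps, score): steps are 0=diagonal,
    1=consume A (gap in B), 2=consume B (gap in A), in reverse order."""
    n, m = S.shape
    NEG = -1e30
    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)
    Y = np.full((n + 1, m + 1), NEG)
    pM = np.zeros((n + 1, m + 1), dtype=np.int8)
    pX = np.zeros((n + 1, m + 1), dtype=np.int8)
    pY = np.zeros((n + 1, m + 1), dtype=np.int8)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = -(gap_open + i * gap_ext)
        pX[i, 0] = 1
    for j in range(1, m + 1):
        Y[0, j] = -(gap_open + j * gap_ext)
        pY[0, j] = 2
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            best = M[i - 1, j - 1]
            p = 0
            if X[i - 1, j - 1] > best:
                best = X[i - 1, j - 1]
                p = 1
            if Y[i - 1, j - 1] > best:
                best = Y[i - 1, j - 1]
                p = 2
            M[i, j] = best + S[i - 1, j - 1]
            pM[i, j] = p
            a = M[i - 1, j] - (gap_open + gap_ext)
            b = X[i - 1, j] - gap_ext
            if a >= b:
                X[i, j] = a
                pX[i, j] = 0
            else:
                X[i, j] = b
                pX[i, j] = 1
            a = M[i, j - 1] - (gap_open + gap_ext)
            c = Y[i, j - 1] - gap_ext
            if a >= c:
                Y[i, j] = a
                pY[i, j] = 0
            else:
                Y[i, j] = c
                pY[i, j] = 2
    state = 0
    score = M[n, m]
    if X[n, m] > score:
        score = X[n, m]
        state = 1
    if Y[n, m] > score:
        score = Y[n, m]
        state = 2
    steps = np.empty(n + m, dtype=np.int8)
    k = 0
    i, j = n, m
    while i > 0 or j > 0:
        if state == 0:
            steps[k] = 0
            nxt = pM[i, j]
            i -= 1
            j -= 1
        elif state == 1:
            steps[k] = 1
            nxt = pX[i, j]
            i -= 1
        else:
            steps[k] = 2
            nxt = pY[i, j]
            j -= 1
        state = nxt
        k += 1
    return steps[:k], score


def _profile_freqs(rows: list[str]) -> np.ndarray:
    ncols = len(rows[0])
    f = np.zeros((ncols, 20))
    for row in rows:
        for c, ch in enumerate(row):
            idx = _AA_INDEX.get(ch, -1)
            if idx >= 0:
                f[c, idx] += 1
    return f / len(rows)


def _align_profiles(rows_a, rows_b, gap_open, gap_ext):
    fa = _profile_freqs(rows_a)
    fb = _profile_freqs(rows_b)
    S = fa @ _B62 @ fb.T
    steps, _score = _profile_dp(S, gap_open, gap_ext)
    out_a = [[] for _ in rows_a]
    out_b = [[] for _ in rows_b]
    ia = ib = 0
    for step in steps[::-1]:
        if step == 0:
            for r, row in zip(out_a, rows_a):
                r.append(row[ia])
            for r, row in zip(out_b, rows_b):
                r.append(row[ib])
            ia += 1
            ib += 1
        elif step == 1:
            for r, row in zip(out_a, rows_a):
                r.append(row[ia])
            for r in out_b:
                r.append("-")
            ia += 1
        else:
            for r in out_a:
                r.append("-")
            for r, row in zip(out_b, rows_b):
                r.append(row[ib])
            ib += 1
    return ["".join(r) for r in out_a], ["".join(r) for r in out_b]


def _kmer_distance(a: str, b: str, k: int = 3) -> float:
    ka = {a[i : i + k] for i in range(len(a) - k + 1)}
    kb = {b[i : i + k] for i in range(len(b) - k + 1)}
    if not ka or not kb:
        return 1.0
    return 1.0 - len(ka & kb) / min(len(ka), len(kb))


def progressive_msa(
    seqs: Sequence[SequenceRecord],
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
) -> ProteinAlignment:
    """Progressive multiple alignment.

    Guide tree from 3-mer distances via UPGMA (average linkage); profiles
    merged by global affine-gap profile-profile alignment in guide-tree
    order.
    """
    if len(seqs) < 2:
        raise MicromineError("progressive_msa needs >= 2 sequences")
    n = len(seqs)
    if n == 2:
        a, b = _align_profiles([seqs[0].residues], [seqs[1].residues], gap_open, gap_extend)
        return ProteinAlignment(ids=[s.id for s in seqs], rows=[a[0], b[0]])
    cond = []
    for i in range(n):
        for j in range(i + 1, n):
            cond.append(_kmer_distance(seqs[i].residues, seqs[j].residues))
    merges = linkage(np.array(cond), method="average")
    clusters: dict[int, tuple[list[int], list[str]]] = {
        i: ([i], [seqs[i].residues]) for i in range(n)
    }
    for step, (a, b, _d, _cnt) in enumerate(merges):
        ia, ib = int(a), int(b)
        idx_a, rows_a = clusters.pop(ia)
        idx_b, rows_b = clusters.pop(ib)
        new_a, new_b = _align_profiles(rows_a, rows_b, gap_open, gap_extend)
        clusters[n + step] = (idx_a + idx_b, new_a + new_b)
    (_, (order, rows)), = clusters.items()
    by_input = sorted(zip(order, rows))
    return ProteinAlignment(ids=[seqs[i].id for i, _ in by_input], rows=[r for _, r in by_input])


# -- identity matrix -------------------------------------------------------

def percent_identity_matrix(aln: ProteinAlignment, include_gaps: bool = False) -> IdentityMatrix:
    """Pairwise percent identity over co-aligned (both non-gap) columns.

    With ``include_gaps`` the denominator instead counts all columns where
    at least one of the pair has a residue.  Pairs with no co-aligned
    columns get 0 with a warning.
    """
    vals = _pid_from_array(aln.as_array(), include_gaps, ids=aln.ids)
    return IdentityMatrix(ids=list(aln.ids), values=vals)


def _pid_from_array(arr: np.ndarray, include_gaps: bool, ids=None) -> np.ndarray:
    n = arr.shape[0]
    vals = np.full((n, n), 100.0)
    nongap = arr != _GAP
    for i in range(n):
        both = nongap[i] & nongap[i + 1 :]
        if include_gaps:
            denom = (nongap[i] | nongap[i + 1 :]).sum(axis=1)
        else:
            denom = both.sum(axis=1)
        matches = ((arr[i] == arr[i + 1 :]) & both).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            pid = np.where(denom > 0, 100.0 * matches / np.maximum(denom, 1), 0.0)
        if ids is not None and (denom == 0).any():
            for j in np.nonzero(denom == 0)[0]:
                warnings.warn(f"no co-aligned columns for {ids[i]} / {ids[i + 1 + j]}")
        vals[i, i + 1 :] = pid
        vals[i + 1 :, i] = pid
    return vals


def identity_to_distance(idm: IdentityMatrix) -> np.ndarray:
    d = 1.0 - idm.values / 100.0
    np.fill_diagonal(d, 0.0)
    return d


# -- trees -----------------------------------------------------------------

class PhyloTree:
    """Unrooted tree (trifurcating root node) with branch lengths >= 0 and
    optional per-split bootstrap supports."""

    def __init__(self, root: TreeNode):
        self.root = root

    def leaf_names(self) -> list[str]:
        return [t.name for t in self.root.tips()]

    def splits(self) -> set:
        """Canonical non-trivial splits as frozensets of two leaf-name sets."""
        all_leaves = frozenset(self.leaf_names())
        out = set()
        for node in self.root.traverse(include_self=False):
            if node.is_tip():
                continue
            side = frozenset(t.name for t in node.tips())
            if 2 <= len(side) <= len(all_leaves) - 2:
                out.add(frozenset((side, all_leaves - side)))
        return out

    def split_supports(self) -> dict:
        all_leaves = frozenset(self.leaf_names())
        out = {}
        for node in self.root.traverse(include_self=False):
            if node.is_tip():
                continue
            side = frozenset(t.name for t in node.tips())
            if 2 <= len(side) <= len(all_leaves) - 2:
                out[frozenset((side, all_leaves - side))] = getattr(node, "support", None)
        return out

    def clade_sides_with_support(self):
        """(clade leaf set, support) for every internal edge, both sides."""
        all_leaves = frozenset(self.leaf_names())
        out = []
        for node in self.root.traverse(include_self=False):
            if node.is_tip():
                continue
            side = frozenset(t.name for t in node.tips())
            sup = getattr(node, "support", None)
            out.append((side, sup))
            out.append((all_leaves - side, sup))
        return out

    def to_newick(self) -> str:
        tree = self.root.copy()
        for node in tree.traverse(include_self=False):
            sup = getattr(node, "support", None)
            if not node.is_tip() and sup is not None:
                # skbio writes the support attribute as the internal label;
                # keep integral supports free of a trailing ".0"
                node.support = int(sup) if float(sup).is_integer() else float(sup)
        buf = _stdio.StringIO()
        tree.write(buf, format="newick")
        return buf.getvalue().strip()

    @classmethod
    def from_newick(cls, text: str) -> "PhyloTree":
        root = TreeNode.read(_stdio.StringIO(text), format="newick", convert_underscores=False)
        for node in root.traverse(include_self=False):
            if not node.is_tip() and node.name:
                try:
                    node.support = float(node.name)
                    node.name = None
                except ValueError:
                    pass
        return cls(root)

    def restrict(self, taxa) -> "PhyloTree":
        kept = self.root.copy().shear(sorted(taxa))
        kept.prune()
        return PhyloTree(kept)


def nj_tree(ids: Sequence[str], distances: np.ndarray) -> PhyloTree:
    """Saitou-Nei neighbor joining.

    Requires a symmetric matrix with zero diagonal and n >= 3; Q-matrix
    ties are broken toward the smallest (i, j) index pair in the current
    matrix; negative branch lengths are clamped to 0.
    """
    D = np.asarray(distances, dtype=float).copy()
    n = len(ids)
    if D.shape != (n, n):
        raise MicromineError("distance matrix shape does not match ids")
    if n < 3:
        raise MicromineError("neighbor joining needs >= 3 taxa")
    if not np.allclose(D, D.T, atol=1e-10):
        raise MicromineError("distance matrix must be symmetric")
    if np.any(np.abs(np.diag(D)) > 1e-10):
        raise MicromineError("distance matrix diagonal must be zero")
    if len(set(ids)) != n:
        raise MicromineError("duplicate taxon labels")
    nodes = [TreeNode(name=str(i)) for i in ids]
    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=1)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        flat = int(np.argmin(Q))
        i, j = divmod(flat, m)
        if i > j:
            i, j = j, i
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = D[i, j] - li
        nodes[i].length = max(0.0, li)
        nodes[j].length = max(0.0, lj)
        parent = TreeNode(children=[nodes[i], nodes[j]])
        dnew = 0.5 * (D[i, :] + D[j, :] - D[i, j])
        keep = [x for x in range(m) if x not in (i, j)]
        D = np.vstack([np.hstack([D[np.ix_(keep, keep)], dnew[keep, None]]),
                       np.hstack([dnew[None, keep], [[0.0]]])])
        nodes = [nodes[x] for x in keep] + [parent]
    d01, d02, d12 = D[0, 1], D[0, 2], D[1, 2]
    nodes[0].length = max(0.0, 0.5 * (d01 + d02 - d12))
    nodes[1].length = max(0.0, 0.5 * (d01 + d12 - d02))
    nodes[2].length = max(0.0, 0.5 * (d02 + d12 - d01))
    return PhyloTree(TreeNode(children=list(nodes)))


def bootstrap_support(
    aln: ProteinAlignment,
    n_reps: int = 100,
    seed: int = 0,
    include_gaps: bool = False,
) -> PhyloTree:
    """NJ tree with bootstrap supports from column resampling.

    Support of each original split is the percentage of replicates (columns
    resampled with replacement, identity -> p-distance -> NJ) containing it.
    """
    if n_reps < 1:
        raise MicromineError("n_reps must be >= 1")
    idm = percent_identity_matrix(aln, include_gaps=include_gaps)
    tree = nj_tree(idm.ids, identity_to_distance(idm))
    counts = {s: 0 for s in tree.splits()}
    rng = np.random.default_rng([seed, 71])
    C = aln.n_columns
    arr = aln.as_array()
    for _ in range(n_reps):
        cols = rng.integers(0, C, C)
        rep_vals = _pid_from_array(arr[:, cols], include_gaps)
        d = 1.0 - rep_vals / 100.0
        np.fill_diagonal(d, 0.0)
        rep_tree = nj_tree(idm.ids, d)
        for s in rep_tree.splits():
            if s in counts:
                counts[s] += 1
    supports = {s: 100.0 * c / n_reps for s, c in counts.items()}
    all_leaves = frozenset(tree.leaf_names())
    for node in tree.root.traverse(include_self=False):
        if node.is_tip():
            continue
        side = frozenset(t.name for t in node.tips())
        key = frozenset((side, all_leaves - side))
        if key in supports:
            node.support = supports[key]
    return tree


def rf_distance(t1: PhyloTree, t2: PhyloTree) -> int:
    """Robinson-Foulds distance: size of the symmetric difference of the
    non-trivial split sets.  Leaf sets must match."""
    l1, l2 = set(t1.leaf_names()), set(t2.leaf_names())
    if l1 != l2:
        raise MicromineError("trees have different leaf sets; restrict to shared taxa first")
    return len(t1.splits() ^ t2.splits())


# -- classification --------------------------------------------------------

@dataclasses.dataclass
class SubgroupCall:
    genome_id: str
    subgroup: str  # subgroup name or "unclassified"
    method: str | None  # 'clade' | 'identity' | None
    support: float | None = None
    identity: float | None = None


def classify_subgroup(
    queries: Sequence[SequenceRecord],
    references: Sequence[tuple[SequenceRecord, str]],
    support_threshold: float = 75.0,
    identity_floor: float = 20.0,
    n_reps: int = 100,
    seed: int = 0,
) -> dict[str, SubgroupCall]:
    """Classify query VP1 proteins into subgroups on a joint bootstrap tree.

    A query joins subgroup X when its smallest enclosing clade whose
    references are all X has support >= 75; otherwise it falls back to the
    subgroup of its highest-identity reference if identity >= 20%; otherwise
    it is unclassified.  The fallback uses the gap-inclusive identity
    (denominator counts columns where either sequence has a residue):
    pairwise-deletion identity of unrelated proteins is inflated toward
    ~20% by alignment artifacts, so it cannot screen out random sequences.
    """
    if not references:
        raise MicromineError("no labeled references")
    ref_label = {rec.id: lab for rec, lab in references}
    seqs = list(queries) + [rec for rec, _ in references]
    if len({s.id for s in seqs}) != len(seqs):
        raise MicromineError("duplicate sequence ids between queries and references")
    aln = progressive_msa(seqs)
    idm = percent_identity_matrix(aln, include_gaps=True)
    tree = bootstrap_support(aln, n_reps=n_reps, seed=seed)
    sides = sorted(tree.clade_sides_with_support(), key=lambda t: len(t[0]))
    out: dict[str, SubgroupCall] = {}
    idx = {gid: k for k, gid in enumerate(idm.ids)}
    all_leaves = frozenset(idm.ids)
    for q in queries:
        call = None
        for side, sup in sides:
            if q.id not in side or len(side) >= len(all_leaves):
                continue
            labels = {ref_label[x] for x in side if x in ref_label}
            if len(labels) != 1:
                continue  # no references yet, or already mixed
            if sup is not None and sup >= support_threshold:
                call = SubgroupCall(q.id, labels.pop(), "clade", support=sup)
                break
        if call is None:
            best_lab, best_pid = None, -1.0
            for rid, lab in ref_label.items():
                pid = idm.values[idx[q.id], idx[rid]]
                if pid > best_pid:
                    best_lab, best_pid = lab, pid
            if best_pid >= identity_floor:
                call = SubgroupCall(q.id, best_lab, "identity", identity=best_pid)
            else:
                call = SubgroupCall(q.id, "unclassified", None, identity=best_pid)
        out[q.id] = call
    return out
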