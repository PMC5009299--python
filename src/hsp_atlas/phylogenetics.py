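"""Protein alignment, distance estimation and Neighbor-Joining trees.

Pairwise global alignment is Needleman-Wunsch with affine gaps under a
BLOSUM62 scheme.  The multiple aligner is progressive: k-mer guide
distances, an NJ guide tree, then profile-profile merges.  Trees are
built with the Saitou-Nei Neighbor-Joining algorithm and annotated with
bootstrap bipartition supports.  NJ is exact on additive distance
matrices, which is what the test-suite exploits.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
from Bio.Align import PairwiseAligner, substitution_matrices
from numba import njit


@dataclass
class Msa:
    """A multiple sequence alignment: equal-length gapped rows."""

    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in number")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate ids in MSA")
        if self.rows and any(len(r) != len(self.rows[0]) for r in self.rows):
            raise ValueError("MSA rows have unequal lengths")

    @property
    def length(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def __len__(self) -> int:
        return len(self.rows)


# ---------------------------------------------------------------------------
# Pairwise global alignment


def _make_aligner(gap_open: float, gap_extend: float) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.mode = "global"
    # first gap residue costs gap_open, each further one gap_extend
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner


def align_pair_global(
    a: str,
    b: str,
    gap_open: float = -10.0,
    gap_extend: float = -0.5,
) -> tuple[tuple[str, str, float], float]:
    """Optimal global alignment of two proteins and its identity.

    Returns ``((gapped_a, gapped_b, score), identity)`` where identity
    is matches divided by alignment columns.  A gap of length k costs
    ``gap_open + (k-1) * gap_extend``.
    """
    if not a or not b:
        raise ValueError("cannot align empty sequences")
    aligner = _make_aligner(gap_open, gap_extend)
    aln = aligner.align(a.rstrip("*"), b.rstrip("*"))[0]
    row_a, row_b = str(aln[0]), str(aln[1])
    matches = sum(1 for x, y in zip(row_a, row_b) if x == y and x != "-")
    identity = matches / len(row_a)
    return (row_a, row_b, float(aln.score)), identity


def pairwise_identity(a: str, b: str) -> float:
    return align_pair_global(a, b)[1]


# ---------------------------------------------------------------------------
# Progressive multiple alignment


def _kmer_distance(a: str, b: str, k: int = 3) -> float:
    if len(a) < k or len(b) < k:
        return 1.0
    ka = {a[i : i + k] for i in range(len(a) - k + 1)}
    kb = {b[i : i + k] for i in range(len(b) - k + 1)}
    shared = len(ka & kb)
    return 1.0 - shared / min(len(ka), len(kb))


_BLOSUM = substitution_matrices.load("BLOSUM62")
_ALPHA = "ACDEFGHIKLMNPQRSTVWYX"
_BL_MATRIX = np.zeros((len(_ALPHA), len(_ALPHA)))
for _i, _x in enumerate(_ALPHA):
    for _j, _y in enumerate(_ALPHA):
        try:
            _BL_MATRIX[_i, _j] = _BLOSUM[_x, _y]
        except (KeyError, IndexError):
            _BL_MATRIX[_i, _j] = 0.0
_ALPHA_INDEX = {c: i for i, c in enumerate(_ALPHA)}


def _profile_of(msa_rows: list[str]) -> np.ndarray:
    """(columns, |alphabet|) residue frequency profile; gaps ignored."""
    n_cols = len(msa_rows[0])
    prof = np.zeros((n_cols, len(_ALPHA)))
    for row in msa_rows:
        for j, c in enumerate(row):
            if c not in "-.":
                prof[j, _ALPHA_INDEX[c]] += 1
    sums = prof.sum(axis=1, keepdims=True)
    sums[sums == 0] = 1.0
    return prof / sums


@njit(cache=True)
def _affine_profile_dp(score, gap_open, gap_extend):  # pragma: no cover - jitted
    """Global affine DP over a precomputed column-score matrix.

    Returns the edit operations (0 = match column, 1 = gap in B,
    2 = gap in A) in alignment order.
    """
    la, lb = score.shape
    NEG = -1e30
    M = np.full((la + 1, lb + 1), NEG)
    X = np.full((la + 1, lb + 1), NEG)
    Y = np.full((la + 1, lb + 1), NEG)
    tb_m = np.zeros((la + 1, lb + 1), dtype=np.int8)
    tb_x = np.zeros((la + 1, lb + 1), dtype=np.int8)
    tb_y = np.zeros((la + 1, lb + 1), dtype=np.int8)
    M[0, 0] = 0.0
    for i in range(1, la + 1):
        X[i, 0] = gap_open + (i - 1) * gap_extend
        tb_x[i, 0] = 1
    for j in range(1, lb + 1):
        Y[0, j] = gap_open + (j - 1) * gap_extend
        tb_y[0, j] = 1
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            dm, dx, dy = M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]
            best = dm
            tb = 0
            if dx > best:
                best = dx
                tb = 1
            if dy > best:
                best = dy
                tb = 2
            M[i, j] = best + score[i - 1, j - 1]
            tb_m[i, j] = tb
            xo = M[i - 1, j] + gap_open
            xe = X[i - 1, j] + gap_extend
            if xo >= xe:
                X[i, j] = xo
                tb_x[i, j] = 0
            else:
                X[i, j] = xe
                tb_x[i, j] = 1
            yo = M[i, j - 1] + gap_open
            ye = Y[i, j - 1] + gap_extend
            if yo >= ye:
                Y[i, j] = yo
                tb_y[i, j] = 0
            else:
                Y[i, j] = ye
                tb_y[i, j] = 1
    state = 0
    best = M[la, lb]
    if X[la, lb] > best:
        best = X[la, lb]
        state = 1
    if Y[la, lb] > best:
        state = 2
    ops = np.empty(la + lb, dtype=np.int8)
    k = la + lb
    i, j = la, lb
    while i > 0 or j > 0:
        k -= 1
        if state == 0:
            ops[k] = 0
            state = tb_m[i, j]
            i -= 1
            j -= 1
        elif state == 1:
            ops[k] = 1
            state = 0 if tb_x[i, j] == 0 else 1
            i -= 1
        else:
            ops[k] = 2
            state = 0 if tb_y[i, j] == 0 else 2
            j -= 1
    return ops[k:]


def _align_profiles(
    rows_a: list[str], rows_b: list[str], gap_open: float = -10.0, gap_extend: float = -0.5
) -> tuple[list[str], list[str]]:
    """Global profile-profile alignment; returns gapped row groups."""
    pa, pb = _profile_of(rows_a), _profile_of(rows_b)
    score = pa @ _BL_MATRIX @ pb.T  # (la, lb) expected column score
    ops = _affine_profile_dp(np.ascontiguousarray(score), gap_open, gap_extend)
    out_a = ["" for _ in rows_a]
    out_b = ["" for _ in rows_b]
    ia = ib = 0
    for op_code in ops:
        op = ("M", "X", "Y")[op_code]
        if op == "M":
            for k, r in enumerate(rows_a):
                out_a[k] += r[ia]
            for k, r in enumerate(rows_b):
                out_b[k] += r[ib]
            ia += 1
            ib += 1
        elif op == "X":
            for k, r in enumerate(rows_a):
                out_a[k] += r[ia]
            for k in range(len(rows_b)):
                out_b[k] += "-"
            ia += 1
        else:
            for k in range(len(rows_a)):
                out_a[k] += "-"
            for k, r in enumerate(rows_b):
                out_b[k] += r[ib]
            ib += 1
    return out_a, out_b


def progressive_msa(
    seqs: list[tuple[str, str]] | dict[str, str], guide_kmer: int = 3
) -> Msa:
    """Progressive alignment: k-mer distances -> NJ guide -> profile merges.

    Deterministic for a fixed input order.  A single sequence is
    returned as-is.
    """
    if isinstance(seqs, dict):
        items = list(seqs.items())
    else:
        items = list(seqs)
    ids = [i for i, _ in items]
    sequences = [s.rstrip("*") for _, s in items]
    if len(items) == 0:
        raise ValueError("no sequences to align")
    if len(items) == 1:
        return Msa(ids, sequences)
    if len(items) == 2:
        (ra, rb, _), _ = align_pair_global(sequences[0], sequences[1])
        return Msa(ids, [ra, rb])
    n = len(items)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dist[i, j] = dist[j, i] = _kmer_distance(sequences[i], sequences[j], guide_kmer)
    order = _merge_order(dist)
    groups: dict[int, tuple[list[int], list[str]]] = {
        i: ([i], [sequences[i]]) for i in range(n)
    }
    next_id = n
    for left, right in order:
        idx_a, rows_a = groups.pop(left)
        idx_b, rows_b = groups.pop(right)
        out_a, out_b = _align_profiles(rows_a, rows_b)
        groups[next_id] = (idx_a + idx_b, out_a + out_b)
        next_id += 1
    final_idx, final_rows = groups.popitem()[1]
    ordered = sorted(zip(final_idx, final_rows))
    return Msa([ids[i] for i, _ in ordered], [r for _, r in ordered])


def _merge_order(dist: np.ndarray) -> list[tuple[int, int]]:
    """Join order from NJ-style agglomeration on the guide distances."""
    n = dist.shape[0]
    active = list(range(n))
    D = {(i, j): dist[i, j] for i in range(n) for j in range(n) if i < j}

    def d(x: int, y: int) -> float:
        return D[(x, y) if x < y else (y, x)]

    order: list[tuple[int, int]] = []
    next_id = n
    while len(active) > 1:
        r = len(active)
        if r == 2:
            i, j = active
            order.append((i, j))
            break
        sums = {i: sum(d(i, k) for k in active if k != i) for i in active}
        best = None
        for ii in range(r):
            for jj in range(ii + 1, r):
                i, j = active[ii], active[jj]
                q = (r - 2) * d(i, j) - sums[i] - sums[j]
                if best is None or q < best[0] - 1e-12:
                    best = (q, i, j)
        _, i, j = best
        order.append((i, j))
        for k in active:
            if k in (i, j):
                continue
            D[(min(k, next_id), max(k, next_id))] = 0.5 * (d(i, k) + d(j, k) - d(i, j))
        active = [k for k in active if k not in (i, j)] + [next_id]
        next_id += 1
    return order


# ---------------------------------------------------------------------------
# Distances


def distance_matrix(msa: Msa, model: str = "p-distance") -> np.ndarray:
    """Pairwise distances with pairwise deletion of gap columns.

    ``p-distance``: mismatches / compared columns.  ``poisson``:
    d = -ln(1 - p), undefined (error) at p = 1.
    """
    if model not in ("p-distance", "poisson"):
        raise ValueError(f"unknown distance model {model!r}")
    if len(msa) < 2:
        raise ValueError("need at least 2 sequences")
    n = len(msa)
    arr = np.array([list(r) for r in msa.rows])
    gap = (arr == "-") | (arr == ".")
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            use = ~(gap[i] | gap[j])
            compared = int(use.sum())
            if compared == 0:
                raise ValueError(f"no comparable columns between rows {i} and {j}")
            p = float((arr[i, use] != arr[j, use]).sum()) / compared
            if model == "poisson":
                if p >= 1.0:
                    raise ValueError("Poisson distance undefined at p = 1")
                p = -np.log(1.0 - p)
            D[i, j] = D[j, i] = p
    return D


# ---------------------------------------------------------------------------
# Neighbor-Joining


def nj_tree(
    dist: np.ndarray, ids: list[str], taxon_namespace: dendropy.TaxonNamespace | None = None
) -> dendropy.Tree:
    """Saitou-Nei Neighbor-Joining tree (unrooted, trifurcating root).

    Negative branch-length estimates are clamped to zero and flagged on
    ``tree.clamped_edges``.  Ties in the Q criterion break on the
    smallest (i, j) node-creation index pair.
    """
    D = np.asarray(dist, dtype=float)
    n = D.shape[0]
    if n < 3:
        raise ValueError("NJ needs at least 3 taxa")
    if D.shape != (n, n) or len(ids) != n:
        raise ValueError("distance matrix / ids size mismatch")
    if np.isnan(D).any():
        raise ValueError("NaN in distance matrix")
    if not np.allclose(D, D.T):
        raise ValueError("distance matrix not symmetric")
    ns = taxon_namespace or dendropy.TaxonNamespace(ids)
    taxa = {name: ns.get_taxon(name) or ns.new_taxon(name) for name in ids}
    nodes: dict[int, dendropy.Node] = {}
    for k, name in enumerate(ids):
        node = dendropy.Node(taxon=taxa[name])
        nodes[k] = node
    clamped: list[int] = []

    def edge_len(x: float) -> float:
        if x < 0:
            clamped.append(1)
            return 0.0
        return x

    active = list(range(n))
    Dm = {(i, j): float(D[i, j]) for i in range(n) for j in range(n) if i < j}

    def d(x: int, y: int) -> float:
        return 0.0 if x == y else Dm[(x, y) if x < y else (y, x)]

    next_id = n
    while len(active) > 3:
        r = len(active)
        sums = {i: sum(d(i, k) for k in active) for i in active}
        best = None
        for ii in range(r):
            for jj in range(ii + 1, r):
                i, j = active[ii], active[jj]
                q = (r - 2) * d(i, j) - sums[i] - sums[j]
                if best is None or q < best[0] - 1e-12:
                    best = (q, i, j)
        _, i, j = best
        li = 0.5 * d(i, j) + (sums[i] - sums[j]) / (2 * (r - 2))
        lj = d(i, j) - li
        parent = dendropy.Node()
        ni, nj = nodes.pop(i), nodes.pop(j)
        parent.add_child(ni)
        parent.add_child(nj)
        ni.edge.length = edge_len(li)
        nj.edge.length = edge_len(lj)
        for k in active:
            if k in (i, j):
                continue
            Dm[(min(k, next_id), max(k, next_id))] = 0.5 * (d(i, k) + d(j, k) - d(i, j))
        nodes[next_id] = parent
        active = [k for k in active if k not in (i, j)] + [next_id]
        next_id += 1
    a, b, c = active
    root = dendropy.Node()
    la = 0.5 * (d(a, b) + d(a, c) - d(b, c))
    lb = 0.5 * (d(a, b) + d(b, c) - d(a, c))
    lc = 0.5 * (d(a, c) + d(b, c) - d(a, b))
    for k, lk in zip((a, b, c), (la, lb, lc)):
        child = nodes.pop(k)
        root.add_child(child)
        child.edge.length = edge_len(lk)
    tree = dendropy.Tree(taxon_namespace=ns, seed_node=root)
    tree.is_rooted = False
    tree.clamped_edges = len(clamped)
    return tree


def tree_from_msa(
    msa: Msa, model: str = "p-distance", taxon_namespace=None
) -> dendropy.Tree:
    return nj_tree(distance_matrix(msa, model), msa.ids, taxon_namespace)


# ---------------------------------------------------------------------------
# Bootstrap


def _internal_bipartitions(tree: dendropy.Tree) -> set[int]:
    tree.encode_bipartitions()
    full = tree.seed_node.edge.bipartition.leafset_bitmask
    out = set()
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node or edge.head_node.is_leaf():
            continue
        mask = edge.bipartition.split_bitmask
        if mask not in (0, full):
            out.add(mask)
    return out


def bootstrap_support(
    msa: Msa,
    n_replicates: int = 1000,
    seed: int = 0,
    model: str = "p-distance",
) -> dendropy.Tree:
    """NJ tree of the full MSA with bootstrap bipartition supports.

    Columns are resampled with replacement ``n_replicates`` times; the
    support of each internal bipartition of the reference tree is the
    percentage of replicate trees containing it.  Supports are stored as
    internal-node labels and on ``node.support``.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be at least 1")
    if len(msa) < 4:
        raise ValueError("bootstrap needs at least 4 sequences")
    ns = dendropy.TaxonNamespace(msa.ids)
    reference = tree_from_msa(msa, model, taxon_namespace=ns)
    reference.encode_bipartitions()
    rng = np.random.default_rng(seed)
    counts: dict[int, int] = {m: 0 for m in _internal_bipartitions(reference)}
    n_cols = msa.length
    rows = np.array([list(r) for r in msa.rows])
    for _ in range(n_replicates):
        cols = rng.integers(0, n_cols, size=n_cols)
        rep_rows = ["".join(row[cols]) for row in rows]
        rep_msa = Msa(msa.ids, rep_rows)
        try:
            rep_tree = tree_from_msa(rep_msa, model, taxon_namespace=ns)
        except ValueError:  # degenerate replicate (e.g. saturated distances)
            continue
        rep_bips = _internal_bipartitions(rep_tree)
        for m in counts:
            if m in rep_bips:
                counts[m] += 1
    for node in reference.preorder_node_iter():
        if node.is_leaf() or node is reference.seed_node:
            continue
        mask = node.edge.bipartition.split_bitmask
        if mask in counts:
            support = 100.0 * counts[mask] / n_replicates
            node.support = support
            node.label = f"{support:.0f}"
    return reference
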