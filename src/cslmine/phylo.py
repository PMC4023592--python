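"""Multiple alignment, distance trees with resampling supports, and newick IO.

Peptides and panel proteins are aligned with MAFFT (L-INS-i); trees are
built by neighbor joining on Poisson-corrected p-distances, and edge
supports are the fraction of column-bootstrap replicates whose NJ tree
contains the same bipartition.  This trades the approximate-ML machinery of
the original tool chain for a transparent, deterministic stack; downstream
classification only consumes the support threshold (0.70 by convention).
"""

from __future__ import annotations

import copy
import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

_DIST_CAP_PRAW = 0.95  # p-distances above this are capped before -ln(1-p)


@dataclass
class MSA:
    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in length")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate ids in MSA")
        if len({len(r) for r in self.rows}) > 1:
            raise ValueError("MSA rows differ in length")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def degapped(self, idx: int) -> str:
        return self.rows[idx].replace("-", "")


@dataclass(frozen=True)
class TreeConfig:
    distance_correction: str = "poisson"  # or "raw"
    n_resamples: int = 1000
    support_display_min: float = 0.70
    seed: int = 0

    def __post_init__(self) -> None:
        if self.distance_correction not in ("raw", "poisson"):
            raise ValueError("distance_correction must be 'raw' or 'poisson'")
        if self.n_resamples < 1:
            raise ValueError("n_resamples must be >= 1")
        if not (0 <= self.support_display_min <= 1):
            raise ValueError("support_display_min must be in [0, 1]")


@dataclass
class Node:
    name: Optional[str] = None
    length: Optional[float] = None
    support: Optional[float] = None
    children: list["Node"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Node):
            return NotImplemented
        return (
            self.name == other.name
            and self.length == other.length
            and self.support == other.support
            and self.children == other.children
        )


@dataclass
class PhyloTree:
    """Unrooted tree stored with a (usually trifurcating) root node."""

    root: Node

    def leaves(self) -> list[Node]:
        out: list[Node] = []

        def walk(n: Node) -> None:
            if n.is_leaf:
                out.append(n)
            for c in n.children:
                walk(c)

        walk(self.root)
        return out

    def leaf_names(self) -> list[str]:
        return [n.name or "" for n in self.leaves()]

    def edges(self, include_leaves: bool = True) -> list[tuple[frozenset, Optional[float], Node]]:
        """(leafset below the edge, support, node) for every non-root edge."""
        out: list[tuple[frozenset, Optional[float], Node]] = []

        def walk(n: Node) -> frozenset:
            if n.is_leaf:
                below = frozenset([n.name])
                if include_leaves:
                    out.append((below, 1.0, n))
                return below
            below = frozenset().union(*(walk(c) for c in n.children))
            if n is not self.root:
                out.append((below, n.support, n))
            return below

        walk(self.root)
        return out

    def bipartitions(self) -> dict[frozenset, Optional[float]]:
        """Nontrivial bipartitions keyed by the side excluding the min leaf."""
        all_leaves = frozenset(self.leaf_names())
        ref = min(all_leaves)
        out: dict[frozenset, Optional[float]] = {}
        for below, support, _node in self.edges(include_leaves=False):
            side = below if ref not in below else all_leaves - below
            if 1 < len(side) < len(all_leaves) - 1:
                out[side] = support
        return out

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PhyloTree):
            return NotImplemented
        return self.root == other.root


# ---------------------------------------------------------------------------
# multiple sequence alignment (delegated to MAFFT L-INS-i)


def build_msa(sequences: Mapping[str, str], method: str = "linsi") -> MSA:
    """Align amino-acid sequences with MAFFT; contract-checked.

    Every output row degaps back to its input, and the alignment is at least
    as wide as the longest input.  ``method`` is ``linsi`` (iterative local
    pairwise, the default), ``ginsi`` (iterative global pairwise; places
    terminal gaps optimally on very short fragments) or ``auto``.
    """
    ids = list(sequences)
    if len(ids) < 2:
        raise ValueError("need >= 2 sequences to align")
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate ids")
    seqs = [str(sequences[i]).upper() for i in ids]
    if any(not s for s in seqs):
        raise ValueError("empty sequence in MSA input")
    if shutil.which("mafft") is None:  # pragma: no cover - environment guard
        raise RuntimeError("mafft executable not found on PATH")
    with tempfile.TemporaryDirectory() as tmp:
        fa = Path(tmp) / "in.fasta"
        with open(fa, "w") as fh:
            for k, s in enumerate(seqs):
                fh.write(f">s{k}\n{s}\n")
        args = ["mafft", "--amino", "--quiet"]
        if method == "linsi":
            args += ["--localpair", "--maxiterate", "1000"]
        elif method == "ginsi":
            args += ["--globalpair", "--maxiterate", "1000"]
        else:
            args += ["--auto"]
        res = subprocess.run(
            args + [str(fa)], capture_output=True, text=True, check=True
        )
    rows: dict[str, str] = {}
    current = None
    for line in res.stdout.splitlines():
        if line.startswith(">"):
            current = line[1:].split()[0]
            rows[current] = ""
        elif current is not None:
            rows[current] += line.strip()
    aligned = [rows[f"s{k}"].upper() for k in range(len(ids))]
    msa = MSA(ids=ids, rows=aligned)
    for k, s in enumerate(seqs):
        if msa.degapped(k) != s:
            raise RuntimeError(f"alignment does not round-trip for {ids[k]!r}")
    return msa


# ---------------------------------------------------------------------------
# distances


def _encode_msa(msa: MSA) -> tuple[np.ndarray, np.ndarray]:
    arr = np.array([list(r) for r in msa.rows])
    nongap = arr != "-"
    codes = np.zeros(arr.shape, dtype=np.int16)
    # stable per-character codes; identity of characters is all that matters
    uniq = np.unique(arr)
    for k, ch in enumerate(uniq):
        codes[arr == ch] = k
    return codes, nongap


def _distances_from_counts(
    mism: np.ndarray, shared: np.ndarray, correction: str, on_disjoint: str, ids
) -> np.ndarray:
    n = mism.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if shared[i, j] == 0:
                if on_disjoint == "error":
                    raise ValueError(
                        f"no shared non-gap columns between {ids[i]!r} and {ids[j]!r}"
                    )
                praw = _DIST_CAP_PRAW
            else:
                praw = mism[i, j] / shared[i, j]
            if correction == "poisson":
                praw = min(praw, _DIST_CAP_PRAW)
                val = -np.log(1.0 - praw)
            else:
                val = praw
            d[i, j] = d[j, i] = val
    return d


def pairwise_distance(
    msa: MSA, correction: str = "poisson", on_disjoint: str = "error"
) -> np.ndarray:
    """Symmetric distance matrix from an MSA.

    ``raw`` is the mismatch fraction over columns where both rows are
    non-gap; ``poisson`` applies -ln(1 - p), capped at p = 0.95.  A pair with
    zero shared non-gap columns raises (naming the pair) unless
    ``on_disjoint='cap'``.
    """
    codes, nongap = _encode_msa(msa)
    both = nongap[:, None, :] & nongap[None, :, :]
    diff = (codes[:, None, :] != codes[None, :, :]) & both
    return _distances_from_counts(
        diff.sum(axis=2), both.sum(axis=2), correction, on_disjoint, msa.ids
    )


# ---------------------------------------------------------------------------
# neighbor joining


def nj_tree(matrix: np.ndarray, ids: Sequence[str]) -> PhyloTree:
    """Standard neighbor joining with deterministic tie-breaking.

    Ties in the Q criterion resolve to the smallest (i, j) index pair under
    the current ordering (inputs first, then created internal nodes in
    creation order).  Negative branch lengths are clamped to zero with the
    deficit moved to the sibling edge.
    """
    D = np.asarray(matrix, dtype=float)
    if D.shape[0] != D.shape[1] or D.shape[0] != len(ids):
        raise ValueError("matrix/ids shape mismatch")
    if not np.allclose(D, D.T):
        raise ValueError("distance matrix is not symmetric")
    if len(ids) < 3:
        raise ValueError("need >= 3 taxa")
    nodes: list[Node] = [Node(name=i) for i in ids]
    D = D.copy()
    while len(nodes) > 3:
        n = len(nodes)
        r = D.sum(axis=0)
        # r_i + r_j first: keeps Q exactly symmetric in floating point
        Q = (n - 2) * D - (r[:, None] + r[None, :])
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        # smallest (i, j), i < j, among the minimizers
        cand = np.argwhere(Q == qmin)
        cand = cand[cand[:, 0] < cand[:, 1]]
        i, j = map(int, cand[0])
        dij = D[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2.0 * (n - 2))
        lj = dij - li
        if li < 0:
            li, lj = 0.0, dij
        elif lj < 0:
            li, lj = dij, 0.0
        parent = Node(children=[nodes[i], nodes[j]])
        nodes[i].length = li
        nodes[j].length = lj
        dnew = 0.5 * (D[i] + D[j] - dij)
        dnew = np.maximum(dnew, 0.0)
        keep = [k for k in range(n) if k not in (i, j)]
        D2 = np.empty((n - 1, n - 1))
        D2[:-1, :-1] = D[np.ix_(keep, keep)]
        D2[-1, :-1] = dnew[keep]
        D2[:-1, -1] = dnew[keep]
        D2[-1, -1] = 0.0
        D = D2
        nodes = [nodes[k] for k in keep] + [parent]
    # resolve the final three around an unrooted trifurcation
    d01, d02, d12 = D[0, 1], D[0, 2], D[1, 2]
    l0 = max(0.0, 0.5 * (d01 + d02 - d12))
    l1 = max(0.0, 0.5 * (d01 + d12 - d02))
    l2 = max(0.0, 0.5 * (d02 + d12 - d01))
    for node, ln in zip(nodes, (l0, l1, l2)):
        node.length = ln
    return PhyloTree(root=Node(children=list(nodes)))


# ---------------------------------------------------------------------------
# supports


def support_values(msa: MSA, tree: PhyloTree, config: TreeConfig) -> PhyloTree:
    """Annotate internal edges with column-bootstrap NJ support fractions."""
    if config.n_resamples < 1:
        raise ValueError("n_resamples must be >= 1")
    tree_leaves = set(tree.leaf_names())
    if not tree_leaves.issubset(set(msa.ids)):
        raise ValueError("tree leaves must be a subset of MSA ids")
    idx = [k for k, i in enumerate(msa.ids) if i in tree_leaves]
    ids = [msa.ids[k] for k in idx]
    codes, nongap = _encode_msa(msa)
    codes, nongap = codes[idx], nongap[idx]
    both = nongap[:, None, :] & nongap[None, :, :]
    diff = (codes[:, None, :] != codes[None, :, :]) & both
    L = codes.shape[1]
    rng = np.random.default_rng([config.seed, 7])
    counts: dict[frozenset, int] = {bp: 0 for bp in tree.bipartitions()}
    for _ in range(config.n_resamples):
        cols = rng.integers(0, L, L)
        mism = diff[:, :, cols].sum(axis=2)
        shared = both[:, :, cols].sum(axis=2)
        d = _distances_from_counts(
            mism, shared, config.distance_correction, "cap", ids
        )
        rep = nj_tree(d, ids)
        rep_bps = set(rep.bipartitions())
        for bp in counts:
            if bp in rep_bps:
                counts[bp] += 1
    out = copy.deepcopy(tree)
    all_leaves = frozenset(out.leaf_names())
    ref = min(all_leaves)
    for below, _, node in out.edges(include_leaves=False):
        side = below if ref not in below else all_leaves - below
        if len(side) > 1 and len(side) < len(all_leaves) - 1:
            node.support = counts[side] / config.n_resamples
        else:
            node.support = 1.0  # trivial bipartition: always present
    return out


# ---------------------------------------------------------------------------
# newick serialization

_NEWICK_UNSAFE = set("()[]{}:;,='\" \t\n")


def _quote(label: str) -> str:
    if any(c in _NEWICK_UNSAFE for c in label):
        return "'" + label.replace("'", "''") + "'"
    return label


def _fmt_float(x: float) -> str:
    return repr(float(x))


def to_newick(tree: PhyloTree) -> str:
    """Newick text with branch lengths and supports as internal labels."""

    def render(n: Node) -> str:
        if n.is_leaf:
            body = _quote(n.name or "")
        else:
            body = "(" + ",".join(render(c) for c in n.children) + ")"
            if n.support is not None:
                body += _fmt_float(n.support)
        if n.length is not None:
            body += f":{_fmt_float(n.length)}"
        return body

    return render(tree.root) + ";"


def parse_newick(text: str) -> PhyloTree:
    """Parse the subset of newick produced by :func:`to_newick`."""
    s = text.strip()
    if not s.endswith(";"):
        raise ValueError("newick must end with ';'")
    s = s[:-1]
    pos = 0

    def parse_label() -> str:
        nonlocal pos
        if pos < len(s) and s[pos] == "'":
            pos += 1
            out = []
            while True:
                if s[pos] == "'":
                    if pos + 1 < len(s) and s[pos + 1] == "'":
                        out.append("'")
                        pos += 2
                    else:
                        pos += 1
                        break
                else:
                    out.append(s[pos])
                    pos += 1
            return "".join(out)
        start = pos
        while pos < len(s) and s[pos] not in "(),:;":
            pos += 1
        return s[start:pos]

    def parse_node() -> Node:
        nonlocal pos
        node = Node()
        if pos < len(s) and s[pos] == "(":
            pos += 1
            while True:
                node.children.append(parse_node())
                if s[pos] == ",":
                    pos += 1
                    continue
                if s[pos] == ")":
                    pos += 1
                    break
            label = parse_label()
            if label:
                node.support = float(label)
        else:
            node.name = parse_label()
        if pos < len(s) and s[pos] == ":":
            pos += 1
            start = pos
            while pos < len(s) and s[pos] not in "(),:;":
                pos += 1
            node.length = float(s[start:pos])
        return node

    tree = PhyloTree(root=parse_node())
    if pos != len(s):
        raise ValueError(f"trailing characters in newick at position {pos}")
    return tree


def write_msa_fasta(msa: MSA, path) -> None:
    with open(path, "w") as fh:
        for i, row in zip(msa.ids, msa.rows):
            fh.write(f">{i}\n{row}\n")
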