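"""Compact maximum-parsimony engine for morphological character matrices.

Characters are unordered (Fitch) multistate; cells are state *sets* encoded
as bitmasks — a singleton for a scored state, the full set for missing
('?'), a multi-element set for polymorphic '(01)' cells.  Tree length is
the Fitch downpass step count summed over characters; exact search is
branch-and-bound over stepwise taxon insertion, heuristic search is
random-addition + SPR hill climbing.  Ensemble consistency and retention
indices and strict consensus trees round out the statistics usually
reported alongside a parsimony analysis.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np


class StructureError(ValueError):
    pass


class FormatError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Character matrix
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CharacterMatrix:
    """Taxa × unordered multistate characters, cells as state-set bitmasks."""

    taxa: tuple[str, ...]
    masks: np.ndarray  # (n_taxa, n_chars) int64 bitmasks over symbol indices
    symbols: str = "01"

    def __post_init__(self) -> None:
        m = np.asarray(self.masks, dtype=np.int64)
        if m.ndim != 2 or m.shape[0] != len(self.taxa):
            raise ValueError("masks must be (n_taxa, n_chars)")
        if (m <= 0).any():
            raise ValueError("every cell needs a non-empty state set")
        object.__setattr__(self, "masks", m)

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_chars(self) -> int:
        return int(self.masks.shape[1])

    @property
    def full_mask(self) -> int:
        return (1 << len(self.symbols)) - 1

    @classmethod
    def from_strings(
        cls, rows: Mapping[str, str], symbols: str = "01", missing: str = "?"
    ) -> "CharacterMatrix":
        """Build from per-taxon character strings ('(01)' = polymorphic)."""
        taxa = tuple(rows)
        parsed: list[list[int]] = []
        full = (1 << len(symbols)) - 1
        for taxon in taxa:
            row: list[int] = []
            chars = iter(rows[taxon])
            for ch in chars:
                if ch == missing or ch == "-":
                    row.append(full)
                elif ch == "(" or ch == "{":
                    mask = 0
                    for sub in chars:
                        if sub in ")}":
                            break
                        mask |= 1 << symbols.index(sub)
                    row.append(mask)
                elif ch in symbols:
                    row.append(1 << symbols.index(ch))
                elif ch.isspace():
                    continue
                else:
                    raise FormatError(f"unknown state symbol {ch!r} for taxon {taxon}")
            parsed.append(row)
        lens = {len(r) for r in parsed}
        if len(lens) != 1:
            raise FormatError(f"ragged matrix: row lengths {sorted(lens)}")
        return cls(taxa=taxa, masks=np.array(parsed, dtype=np.int64), symbols=symbols)

    def cell_states(self, taxon_index: int, char_index: int) -> frozenset[str]:
        mask = int(self.masks[taxon_index, char_index])
        return frozenset(s for i, s in enumerate(self.symbols) if mask >> i & 1)


def read_nexus(path: str | Path) -> CharacterMatrix:
    """Read a NEXUS DATA/CHARACTERS block (sequential or interleaved)."""
    try:
        dmat = dendropy.StandardCharacterMatrix.get(path=str(path), schema="nexus")
    except Exception as exc:  # dendropy raises its own hierarchy
        raise FormatError(f"cannot parse NEXUS file {path}: {exc}") from exc
    alphabet = dmat.default_state_alphabet
    symbols = "".join(
        s.symbol for s in alphabet.fundamental_state_iter() if s.symbol not in ("-",)
    )
    sym_index = {s: i for i, s in enumerate(symbols)}
    full = (1 << len(symbols)) - 1
    taxa = tuple(t.label.replace(" ", "_") for t in dmat.taxon_namespace)
    rows: list[list[int]] = []
    for taxon in dmat.taxon_namespace:
        seq = dmat[taxon]
        row: list[int] = []
        for state in seq:
            fundamentals = state.fundamental_states
            mask = 0
            for fs in fundamentals:
                if fs.symbol in sym_index:
                    mask |= 1 << sym_index[fs.symbol]
            row.append(mask if mask else full)
        rows.append(row)
    lens = {len(r) for r in rows}
    if len(lens) != 1:
        raise FormatError(f"ragged NEXUS matrix in {path}")
    return CharacterMatrix(taxa=taxa, masks=np.array(rows, dtype=np.int64), symbols=symbols)


def write_nexus(
    matrix: CharacterMatrix, path: str | Path, interleave_every: int | None = None
) -> None:
    """Write a DATA block; ``interleave_every`` columns per block if given."""

    def cell_str(mask: int) -> str:
        states = [s for i, s in enumerate(matrix.symbols) if mask >> i & 1]
        if len(states) == len(matrix.symbols):
            return "?"
        if len(states) > 1:
            return "(" + "".join(states) + ")"
        return states[0]

    rows = {
        t: "".join(cell_str(int(m)) for m in matrix.masks[i])
        for i, t in enumerate(matrix.taxa)
    }
    # note: polymorphic cells make row strings longer than n_chars; interleave
    # blocks are split on character counts, so resplit per taxon by cell
    cells = {
        t: [cell_str(int(m)) for m in matrix.masks[i]] for i, t in enumerate(matrix.taxa)
    }
    lines = [
        "#NEXUS",
        "BEGIN DATA;",
        f"  DIMENSIONS NTAX={matrix.n_taxa} NCHAR={matrix.n_chars};",
        "  FORMAT SYMBOLS=\"{}\" MISSING=? GAP=-{};".format(
            matrix.symbols, " INTERLEAVE" if interleave_every else ""
        ),
        "  MATRIX",
    ]
    name_w = max(len(t) for t in matrix.taxa) + 2
    if interleave_every:
        for start in range(0, matrix.n_chars, interleave_every):
            for t in matrix.taxa:
                chunk = "".join(cells[t][start : start + interleave_every])
                lines.append(f"  {t.replace(' ', '_'):<{name_w}}{chunk}")
            lines.append("")
    else:
        for t in matrix.taxa:
            lines.append(f"  {t.replace(' ', '_'):<{name_w}}{rows[t]}")
    lines += ["  ;", "END;"]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------


@dataclass
class SimpleTree:
    """Unrooted tree over a fixed taxon set.

    Tips are nodes ``0..n_taxa-1`` (in ``taxa`` order); internal nodes carry
    higher ids.  Binary for search/scoring; strict consensus trees may hold
    polytomies.
    """

    taxa: tuple[str, ...]
    adj: dict[int, set[int]]

    # -- construction -------------------------------------------------------
    @classmethod
    def from_newick(cls, newick: str, taxa: Sequence[str] | None = None) -> "SimpleTree":
        t = dendropy.Tree.get(data=newick, schema="newick")
        labels = sorted(lf.taxon.label for lf in t.leaf_node_iter())
        if taxa is None:
            taxa = labels
        elif sorted(taxa) != labels:
            raise StructureError("newick leaf set does not match the given taxa")
        index = {label: i for i, label in enumerate(taxa)}
        adj: dict[int, set[int]] = {}
        next_id = len(taxa)
        node_ids: dict = {}
        for node in t.postorder_node_iter():
            if node.is_leaf():
                node_ids[node] = index[node.taxon.label]
            else:
                node_ids[node] = next_id
                next_id += 1
            adj.setdefault(node_ids[node], set())
        for node in t.preorder_node_iter():
            for child in node.child_nodes():
                a, b = node_ids[node], node_ids[child]
                adj[a].add(b)
                adj[b].add(a)
        tree = cls(taxa=tuple(taxa), adj=adj)
        tree._suppress_degree_two()
        return tree

    def _suppress_degree_two(self) -> None:
        """Remove degree-2 nodes a rooted newick leaves behind."""
        for node in [n for n in list(self.adj) if n >= len(self.taxa)]:
            while node in self.adj and len(self.adj[node]) == 2:
                a, b = self.adj[node]
                self.adj[a].discard(node)
                self.adj[b].discard(node)
                self.adj[a].add(b)
                self.adj[b].add(a)
                del self.adj[node]

    @classmethod
    def random_topology(cls, taxa: Sequence[str], rng: np.random.Generator) -> "SimpleTree":
        order = list(range(len(taxa)))
        rng.shuffle(order)
        return cls.from_insertion_order(taxa, order, lambda edges: int(rng.integers(len(edges))))

    @classmethod
    def from_insertion_order(
        cls, taxa: Sequence[str], order: Sequence[int], choose=None
    ) -> "SimpleTree":
        """Stepwise-addition skeleton used by random and heuristic builders."""
        n = len(taxa)
        if n < 4:
            raise StructureError("need >= 4 taxa for an unrooted binary tree")
        a, b, c = order[0], order[1], order[2]
        hub = n
        adj: dict[int, set[int]] = {a: {hub}, b: {hub}, c: {hub}, hub: {a, b, c}}
        tree = cls(taxa=tuple(taxa), adj=adj)
        next_internal = n + 1
        for tip in order[3:]:
            edges = tree.edges()
            k = choose(edges) if choose else 0
            tree.insert_tip(tip, edges[k], next_internal)
            next_internal += 1
        return tree

    # -- basic structure ----------------------------------------------------
    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    def edges(self) -> list[tuple[int, int]]:
        return [(u, v) for u in sorted(self.adj) for v in sorted(self.adj[u]) if u < v]

    def is_binary(self) -> bool:
        return all(
            len(nb) == (1 if n < self.n_taxa else 3) for n, nb in self.adj.items()
        )

    def copy(self) -> "SimpleTree":
        return SimpleTree(taxa=self.taxa, adj={k: set(v) for k, v in self.adj.items()})

    def insert_tip(self, tip: int, edge: tuple[int, int], new_internal: int) -> None:
        u, v = edge
        self.adj[u].discard(v)
        self.adj[v].discard(u)
        self.adj[new_internal] = {u, v, tip}
        self.adj[u].add(new_internal)
        self.adj[v].add(new_internal)
        self.adj.setdefault(tip, set()).add(new_internal)

    def remove_tip(self, tip: int, internal: int) -> tuple[int, int]:
        """Inverse of insert_tip; returns the restored edge."""
        u, v = sorted(self.adj[internal] - {tip})
        del self.adj[internal]
        del self.adj[tip]
        self.adj[u].discard(internal)
        self.adj[v].discard(internal)
        self.adj[u].add(v)
        self.adj[v].add(u)
        return (u, v)

    # -- traversal ----------------------------------------------------------
    def rooted_edges(self, root: int | None = None) -> list[tuple[int, int]]:
        """(parent, child) edges in preorder, rooted at ``root``.

        Default root is the neighbour of tip 0, giving a rooting along an
        existing edge — Fitch counts are rooting-invariant.
        """
        if root is None:
            root = next(iter(self.adj[0]))
        out: list[tuple[int, int]] = []
        stack = [(root, -1)]
        while stack:
            node, parent = stack.pop()
            for nb in self.adj[node]:
                if nb != parent:
                    out.append((node, nb))
                    stack.append((nb, node))
        return out

    def bipartitions(self) -> frozenset[frozenset[int]]:
        """Non-trivial splits, each as the taxon side not containing tip 0."""
        splits: set[frozenset[int]] = set()
        n = self.n_taxa
        for parent, child in self.rooted_edges(root=0):
            side = self._clade_tips(child, parent)
            if 1 < len(side) < n - 1:
                splits.add(frozenset(side))
        return frozenset(splits)

    def _clade_tips(self, node: int, parent: int) -> set[int]:
        tips: set[int] = set()
        stack = [(node, parent)]
        while stack:
            cur, par = stack.pop()
            if cur < self.n_taxa:
                tips.add(cur)
            for nb in self.adj[cur]:
                if nb != par:
                    stack.append((nb, cur))
        return tips

    def topology_id(self) -> frozenset[frozenset[int]]:
        return self.bipartitions()

    def to_newick(self) -> str:
        root = next(iter(self.adj[0]))

        def sub(node: int, parent: int) -> str:
            if node < self.n_taxa:
                return self.taxa[node].replace(" ", "_")
            parts = [sub(nb, node) for nb in sorted(self.adj[node]) if nb != parent]
            return "(" + ",".join(parts) + ")"

        parts = [sub(nb, root) for nb in sorted(self.adj[root])]
        return "(" + ",".join(parts) + ");"


def enumerate_topologies(taxa: Sequence[str]) -> Iterable[SimpleTree]:
    """All distinct unrooted binary topologies ((2n−5)!! of them)."""
    n = len(taxa)
    if n < 4:
        raise StructureError("need >= 4 taxa")

    def expand(tree: SimpleTree, tip: int, next_internal: int):
        if tip == n:
            yield tree.copy()
            return
        for edge in list(tree.edges()):
            tree.insert_tip(tip, edge, next_internal)
            yield from expand(tree, tip + 1, next_internal + 1)
            tree.remove_tip(tip, next_internal)

    base = SimpleTree(
        taxa=tuple(taxa), adj={0: {n}, 1: {n}, 2: {n}, n: {0, 1, 2}}
    )
    yield from expand(base, 3, n + 1)


# ---------------------------------------------------------------------------
# Fitch scoring
# ---------------------------------------------------------------------------


def fitch_length(tree: SimpleTree, matrix: CharacterMatrix) -> tuple[int, np.ndarray]:
    """Fitch downpass tree length and per-character step counts.

    Per character: child state sets are intersected where possible, else
    unioned at the cost of one step; missing/polymorphic cells enter as
    their state sets.
    """
    if set(range(matrix.n_taxa)) - set(tree.adj):
        missing = [matrix.taxa[i] for i in range(matrix.n_taxa) if i not in tree.adj]
        raise StructureError(f"tree lacks taxa: {missing}")
    if len(tree.taxa) != matrix.n_taxa or tuple(tree.taxa) != tuple(matrix.taxa):
        raise StructureError("tree and matrix taxa differ (order-sensitive ids)")
    edges = tree.rooted_edges()
    n_nodes = max(tree.adj) + 1
    sets = np.zeros((n_nodes, matrix.n_chars), dtype=np.int64)
    sets[: matrix.n_taxa] = matrix.masks
    internal_ready = np.zeros(n_nodes, dtype=bool)
    internal_ready[: matrix.n_taxa] = True
    steps = np.zeros(matrix.n_chars, dtype=np.int64)
    for parent, child in reversed(edges):  # postorder: children before parents
        if not internal_ready[child]:
            raise StructureError("traversal order broken (non-tree adjacency?)")
        if not internal_ready[parent]:
            sets[parent] = sets[child]
            internal_ready[parent] = True
        else:
            inter = sets[parent] & sets[child]
            empty = inter == 0
            steps += empty
            sets[parent] = np.where(empty, sets[parent] | sets[child], inter)
    return int(steps.sum()), steps


# ---------------------------------------------------------------------------
# Per-character step bounds and CI/RI
# ---------------------------------------------------------------------------


def _min_steps_per_char(matrix: CharacterMatrix) -> np.ndarray:
    """m: minimum steps attainable on *any* tree, per character.

    With polymorphism this is (size of the smallest state set hitting every
    non-missing cell) − 1, found by exact enumeration over subsets of the
    observed states; for singleton-only data it reduces to
    (number of observed states) − 1.
    """
    full = matrix.full_mask
    m = np.zeros(matrix.n_chars, dtype=np.int64)
    for c in range(matrix.n_chars):
        cells = [int(x) for x in matrix.masks[:, c] if int(x) != full]
        if not cells:
            continue
        union = 0
        for x in cells:
            union |= x
        states = [i for i in range(len(matrix.symbols)) if union >> i & 1]
        best = len(states)
        found = False
        for k in range(1, len(states) + 1):
            for combo in itertools.combinations(states, k):
                mask = 0
                for s in combo:
                    mask |= 1 << s
                if all(cell & mask for cell in cells):
                    best = k
                    found = True
                    break
            if found:
                break
        m[c] = best - 1
    return m


def _max_steps_per_char(matrix: CharacterMatrix) -> np.ndarray:
    """g: steps on the worst tree (star phylogeny), per character.

    g = (non-missing taxa) − (count of the most frequent state), resolving
    polymorphism in favour of the modal state.
    """
    full = matrix.full_mask
    g = np.zeros(matrix.n_chars, dtype=np.int64)
    for c in range(matrix.n_chars):
        cells = [int(x) for x in matrix.masks[:, c] if int(x) != full]
        if not cells:
            continue
        counts = [
            sum(1 for cell in cells if cell >> i & 1) for i in range(len(matrix.symbols))
        ]
        g[c] = len(cells) - max(counts)
    return g


def ci_ri(
    matrix: CharacterMatrix, best_length: int, per_char_steps: np.ndarray | None = None
) -> tuple[float, float]:
    """Ensemble consistency and retention indices at a given tree length.

    CI = Σm / S; RI = (Σg − S) / (Σg − Σm).  All included characters enter
    the sums (parsimony-uninformative ones too).
    """
    m = _min_steps_per_char(matrix)
    g = _max_steps_per_char(matrix)
    M, G, S = int(m.sum()), int(g.sum()), int(best_length)
    if S < M:
        raise ValueError(f"impossible score: length {S} < minimum {M}")
    ci = M / S if S > 0 else 1.0
    ri = (G - S) / (G - M) if G > M else 1.0
    return float(ci), float(ri)


# ---------------------------------------------------------------------------
# Search
# ---------------------------------------------------------------------------


@dataclass
class ParsimonyResult:
    best_length: int
    trees: list[SimpleTree]
    ci: float
    ri: float
    per_char_steps: np.ndarray
    truncated: bool = False
    search_log: list[str] = field(default_factory=list)

    @property
    def n_mpts(self) -> int:
        return len(self.trees)


MAX_BB_TAXA = 25
MPT_CAP = 1000


def _branch_and_bound(matrix: CharacterMatrix, cap: int = MPT_CAP):
    n = matrix.n_taxa
    full = matrix.full_mask
    # addition order: most divergent taxa first tightens bounds early
    nonmissing = matrix.masks != full
    div = nonmissing.sum(axis=1)
    order = list(np.argsort(-div, kind="stable"))

    # per-character states definitely present among *unplaced* taxa only:
    # each such state forces at least one extra step when its taxon joins
    singleton = (matrix.masks & (matrix.masks - 1)) == 0  # power-of-two masks

    best = {"length": None, "ids": set(), "trees": [], "truncated": False}

    def future_bound(placed: list[int]) -> np.ndarray:
        placed_mask = np.zeros(matrix.n_chars, dtype=np.int64)
        for t in placed:
            placed_mask |= matrix.masks[t]
        extra = np.zeros(matrix.n_chars, dtype=np.int64)
        for t in order:
            if t in placed:
                continue
            only = singleton[t] & ((matrix.masks[t] & ~placed_mask) == matrix.masks[t])
            extra += only
            placed_mask |= np.where(only, matrix.masks[t], 0)
        return extra

    def recurse(tree: SimpleTree, k: int, next_internal: int, placed: list[int]):
        length, _ = fitch_length_partial(tree, matrix, placed)
        bound = length + int(future_bound(placed).sum())
        if best["length"] is not None and bound > best["length"]:
            return
        if k == n:
            if best["length"] is None or length < best["length"]:
                best["length"] = length
                best["ids"] = {tree.topology_id()}
                best["trees"] = [tree.copy()]
                best["truncated"] = False
            elif length == best["length"]:
                tid = tree.topology_id()
                if tid not in best["ids"]:
                    if len(best["trees"]) < cap:
                        best["ids"].add(tid)
                        best["trees"].append(tree.copy())
                    else:
                        best["truncated"] = True
            return
        tip = order[k]
        for edge in list(tree.edges()):
            tree.insert_tip(tip, edge, next_internal)
            placed.append(tip)
            recurse(tree, k + 1, next_internal + 1, placed)
            placed.pop()
            tree.remove_tip(tip, next_internal)

    hub = n
    a, b, c = order[0], order[1], order[2]
    base = SimpleTree(taxa=matrix.taxa, adj={a: {hub}, b: {hub}, c: {hub}, hub: {a, b, c}})
    recurse(base, 3, n + 1, [a, b, c])
    return best


def fitch_length_partial(
    tree: SimpleTree, matrix: CharacterMatrix, placed: Sequence[int]
) -> tuple[int, np.ndarray]:
    """Fitch length of a tree over a subset of the matrix taxa."""
    root_tip = placed[0]
    edges = tree.rooted_edges(root=next(iter(tree.adj[root_tip])))
    n_nodes = max(tree.adj) + 1
    sets = np.zeros((n_nodes, matrix.n_chars), dtype=np.int64)
    for t in placed:
        sets[t] = matrix.masks[t]
    ready = np.zeros(n_nodes, dtype=bool)
    for t in placed:
        ready[t] = True
    steps = np.zeros(matrix.n_chars, dtype=np.int64)
    for parent, child in reversed(edges):
        if not ready[parent]:
            sets[parent] = sets[child]
            ready[parent] = True
        else:
            inter = sets[parent] & sets[child]
            empty = inter == 0
            steps += empty
            sets[parent] = np.where(empty, sets[parent] | sets[child], inter)
    return int(steps.sum()), steps


def _spr_neighbors(tree: SimpleTree):
    """Yield tip-prune-regraft neighbours (as fresh trees).

    Pruning single tips and regrafting on every other edge is a compact SPR
    move set that still reaches any topology through chains of moves.
    """
    n = tree.n_taxa
    for tip in range(n):
        internal = next(iter(tree.adj[tip]))
        if len(tree.adj[internal]) != 3:
            continue
        work = tree.copy()
        restored = work.remove_tip(tip, internal)
        for edge in list(work.edges()):
            if edge == restored:
                continue  # reinsertion there recreates the original tree
            cand = work.copy()
            cand.insert_tip(tip, edge, internal)
            yield cand


def _heuristic(matrix: CharacterMatrix, seed: int, n_starts: int = 10, cap: int = MPT_CAP):
    rng = np.random.default_rng(seed)
    n = matrix.n_taxa
    best_len: int | None = None
    ids: set = set()
    trees: list[SimpleTree] = []
    truncated = False
    for _ in range(n_starts):
        order = list(range(n))
        rng.shuffle(order)
        # greedy stepwise addition
        hub = n
        a, b, c = order[0], order[1], order[2]
        tree = SimpleTree(
            taxa=matrix.taxa, adj={a: {hub}, b: {hub}, c: {hub}, hub: {a, b, c}}
        )
        placed = [a, b, c]
        next_internal = n + 1
        for tip in order[3:]:
            best_edge, best_l = None, None
            for edge in list(tree.edges()):
                tree.insert_tip(tip, edge, next_internal)
                placed.append(tip)
                l, _ = fitch_length_partial(tree, matrix, placed)
                placed.pop()
                tree.remove_tip(tip, next_internal)
                if best_l is None or l < best_l:
                    best_edge, best_l = edge, l
            tree.insert_tip(tip, best_edge, next_internal)
            placed.append(tip)
            next_internal += 1
        length, _ = fitch_length(tree, matrix)
        # SPR hill climb to a local optimum
        improved = True
        while improved:
            improved = False
            for cand in _spr_neighbors(tree):
                l, _ = fitch_length(cand, matrix)
                if l < length:
                    tree, length = cand, l
                    improved = True
                    break
        if best_len is None or length < best_len:
            best_len, ids, trees, truncated = length, set(), [], False
        if length == best_len:
            tid = tree.topology_id()
            if tid not in ids:
                if len(trees) < cap:
                    ids.add(tid)
                    trees.append(tree)
                else:
                    truncated = True
            # sweep equal-length SPR neighbours into the MPT set
            for cand in _spr_neighbors(tree):
                l, _ = fitch_length(cand, matrix)
                if l == best_len:
                    tid = cand.topology_id()
                    if tid not in ids:
                        if len(trees) < cap:
                            ids.add(tid)
                            trees.append(cand)
                        else:
                            truncated = True
    return {"length": best_len, "trees": trees, "truncated": truncated}


def search(
    matrix: CharacterMatrix, mode: str = "branch_and_bound", seed: int = 0
) -> ParsimonyResult:
    """Maximum-parsimony search; retains all tied-best distinct topologies.

    ``branch_and_bound`` is exact (refused above 25 taxa); ``heuristic`` is
    10 random-addition replicates with SPR hill climbing, seeded.
    """
    if matrix.n_taxa < 4:
        raise StructureError("search needs >= 4 taxa")
    if mode == "branch_and_bound":
        if matrix.n_taxa > MAX_BB_TAXA:
            raise ValueError(f"branch_and_bound refuses > {MAX_BB_TAXA} taxa")
        res = _branch_and_bound(matrix)
    elif mode == "heuristic":
        res = _heuristic(matrix, seed=seed)
    else:
        raise ValueError(f"unknown search mode {mode!r}")
    best_tree = res["trees"][0]
    length, per_char = fitch_length(best_tree, matrix)
    ci, ri = ci_ri(matrix, length)
    return ParsimonyResult(
        best_length=int(res["length"]),
        trees=res["trees"],
        ci=ci,
        ri=ri,
        per_char_steps=per_char,
        truncated=bool(res["truncated"]),
        search_log=[f"mode={mode}", f"n_mpts={len(res['trees'])}"],
    )


# ---------------------------------------------------------------------------
# Consensus
# ---------------------------------------------------------------------------


def strict_consensus(trees: Sequence[SimpleTree]) -> SimpleTree:
    """Tree retaining exactly the bipartitions present in every input tree."""
    if not trees:
        raise StructureError("need at least one tree")
    taxa = trees[0].taxa
    for t in trees[1:]:
        if t.taxa != taxa:
            raise StructureError("trees have different leaf sets")
    common = trees[0].bipartitions()
    for t in trees[1:]:
        common = common & t.bipartitions()
    n = len(taxa)
    # Each retained split (its side excluding tip 0) is a clade of the tree
    # rooted at tip 0; the retained splits are mutually compatible, so they
    # form a laminar family nested by containment.
    clades = sorted(common, key=len, reverse=True)  # enclosing clades first
    root = n
    adj: dict[int, set[int]] = {i: set() for i in range(n)}
    adj[root] = set()
    node_of = {}
    next_id = n + 1
    for cl in clades:
        node_of[cl] = next_id
        adj[next_id] = set()
        next_id += 1

    def attach(child: int, parent: int) -> None:
        adj[child].add(parent)
        adj[parent].add(child)

    for i, cl in enumerate(clades):
        enclosing = None
        for other in clades[:i]:
            if cl < other and (enclosing is None or len(other) < len(enclosing)):
                enclosing = other
        attach(node_of[cl], node_of[enclosing] if enclosing else root)
    for tip in range(1, n):
        smallest = None
        for cl in clades:
            if tip in cl and (smallest is None or len(cl) < len(smallest)):
                smallest = cl
        attach(tip, node_of[smallest] if smallest else root)
    attach(0, root)
    tree = SimpleTree(taxa=taxa, adj=adj)
    tree._suppress_degree_two()
    return tree
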