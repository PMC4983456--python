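"""Convolution (subset-tree) kernel between interaction pattern trees.

The kernel counts common subset-tree fragments of two constituency trees: a
fragment takes any node and expands each included node with either none or
all of its children, preserving the grammar productions.  The recursive
Delta function evaluates, for a node pair with equal productions, the
lambda-decayed count of common fragments rooted there:

    Delta = 0                         if the productions differ,
    Delta = lambda                    if both nodes are pre-terminals,
    Delta = lambda * prod_k (1 + Delta(child_k, child'_k))   otherwise,

and K(T1, T2) = sum over all node pairs of Delta.  Pre-terminals terminate
the recursion, so lexical leaves are not themselves kernel nodes.  A
brute-force fragment enumeration (weight lambda^{#productions}) provides an
independent oracle on small trees.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np

from .formats_io import RunConfig
from .tree import ParseNode

__all__ = [
    "KernelConfig",
    "GramMatrix",
    "delta",
    "ctk",
    "gram_matrix",
    "kernel_rows",
    "enumerate_subset_trees",
    "phi_inner_product",
]


@dataclass(frozen=True)
class KernelConfig:
    lambda_decay: float = 0.4
    normalize: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.lambda_decay < 1.0):
            raise ValueError(f"lambda_decay must lie in (0, 1), got {self.lambda_decay}")

    @classmethod
    def from_run_config(cls, config: RunConfig) -> "KernelConfig":
        return cls(lambda_decay=config.lambda_decay, normalize=config.normalize_kernel)


@dataclass
class GramMatrix:
    """Square symmetric kernel matrix over a list of candidate ids."""

    values: np.ndarray
    index: list[str]

    def __post_init__(self) -> None:
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1] or v.shape[0] != len(self.index):
            raise ValueError("Gram matrix must be square and match its index")


def delta(n1: ParseNode, n2: ParseNode, lam: float, _memo: dict | None = None) -> float:
    """The three-case Delta recursion (reference implementation, memoized)."""
    if _memo is None:
        _memo = {}
    key = (id(n1), id(n2))
    if key in _memo:
        return _memo[key]
    if n1.production() != n2.production():
        val = 0.0
    elif n1.is_preterminal and n2.is_preterminal:
        val = lam
    else:
        val = lam
        for c1, c2 in zip(n1.children, n2.children):
            if c1.is_leaf:  # identical words under equal productions
                continue
            val *= 1.0 + delta(c1, c2, lam, _memo)
    _memo[key] = val
    return val


def ctk(t1: ParseNode, t2: ParseNode, config: KernelConfig | None = None) -> float:
    """Convolution tree kernel: sum of Delta over all internal node pairs.

    With ``normalize`` the value is divided by sqrt(K(t1,t1) * K(t2,t2)),
    putting self-similarity at 1 regardless of tree size.
    """
    config = config or KernelConfig()
    raw = _ctk_raw(_compile(t1), _compile(t2), config.lambda_decay)
    if not config.normalize:
        return raw
    s1 = _ctk_raw(_compile(t1), _compile(t1), config.lambda_decay)
    s2 = _ctk_raw(_compile(t2), _compile(t2), config.lambda_decay)
    if s1 <= 0.0 or s2 <= 0.0:
        return 0.0
    return raw / np.sqrt(s1 * s2)


# -- fast compiled form -----------------------------------------------------


@dataclass
class _Compiled:
    """Post-order arrays of internal nodes for O(matching pairs) evaluation."""

    productions: list[tuple]
    children: list[list[int]]    # internal-child positions per node
    preterminal: list[bool]
    by_production: dict[tuple, list[int]]


def _compile(tree: ParseNode) -> _Compiled:
    productions: list[tuple] = []
    children: list[list[int]] = []
    preterminal: list[bool] = []
    index: dict[int, int] = {}

    def visit(node: ParseNode) -> int:
        ch = [visit(c) for c in node.children if not c.is_leaf]
        pos = len(productions)
        productions.append(node.production())
        children.append(ch)
        preterminal.append(node.is_preterminal)
        index[id(node)] = pos
        return pos

    visit(tree)
    by_prod: dict[tuple, list[int]] = {}
    for i, p in enumerate(productions):
        by_prod.setdefault(p, []).append(i)
    return _Compiled(productions, children, preterminal, by_prod)


def _ctk_raw(c1: _Compiled, c2: _Compiled, lam: float) -> float:
    d: dict[tuple[int, int], float] = {}
    total = 0.0
    for i in range(len(c1.productions)):  # post-order: children before parents
        prod = c1.productions[i]
        for j in c2.by_production.get(prod, ()):
            if c1.preterminal[i]:
                val = lam
            else:
                val = lam
                for ci, cj in zip(c1.children[i], c2.children[j]):
                    val *= 1.0 + d.get((ci, cj), 0.0)
            d[(i, j)] = val
            total += val
    return total


def gram_matrix(trees: list[ParseNode], config: KernelConfig | None = None,
                index: list[str] | None = None) -> GramMatrix:
    """Symmetric positive-semidefinite kernel matrix over a tree list."""
    config = config or KernelConfig()
    if not trees:
        raise ValueError("gram_matrix needs at least one tree")
    lam = config.lambda_decay
    compiled = [_compile(t) for t in trees]
    n = len(trees)
    K = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            K[i, j] = K[j, i] = _ctk_raw(compiled[i], compiled[j], lam)
    if config.normalize:
        diag = np.sqrt(np.clip(np.diag(K), 1e-300, None))
        K = K / np.outer(diag, diag)
    ids = index if index is not None else [str(i) for i in range(n)]
    return GramMatrix(values=K, index=ids)


def kernel_rows(test_trees: list[ParseNode], train_trees: list[ParseNode],
                config: KernelConfig | None = None) -> np.ndarray:
    """Kernel values of each test tree against every training tree."""
    config = config or KernelConfig()
    lam = config.lambda_decay
    ctrain = [_compile(t) for t in train_trees]
    ctest = [_compile(t) for t in test_trees]
    rows = np.zeros((len(ctest), len(ctrain)))
    for i, ci in enumerate(ctest):
        for j, cj in enumerate(ctrain):
            rows[i, j] = _ctk_raw(ci, cj, lam)
    if config.normalize:
        s_test = np.array([max(_ctk_raw(c, c, lam), 1e-300) for c in ctest])
        s_train = np.array([max(_ctk_raw(c, c, lam), 1e-300) for c in ctrain])
        rows = rows / np.sqrt(np.outer(s_test, s_train))
    return rows


# -- brute-force oracle -----------------------------------------------------


def enumerate_subset_trees(t: ParseNode, max_nodes: int = 12) -> Counter:
    """All subset-tree fragments of ``t`` as a multiset (the explicit phi(T)).

    A fragment is rooted at any internal node; every included internal node
    is either expanded with all its children or left as a bare label, and
    lexical leaves appear as words.  Fragments are returned as hashable
    nested tuples mapped to occurrence counts.  Guarded to trees with at most
    ``max_nodes`` internal nodes (the representation is exponential).
    """
    internal = t.internal_nodes()
    if len(internal) > max_nodes:
        raise ValueError(
            f"tree has {len(internal)} internal nodes; oracle guard is {max_nodes}")

    def fragments(node: ParseNode) -> list[tuple]:
        """All fragments rooted at (and expanding) this internal node."""
        options_per_child: list[list[tuple]] = []
        for c in node.children:
            if c.is_leaf:
                options_per_child.append([("W", c.word)])
            else:
                opts = [("N", c.label)] + [f for f in fragments(c)]
                options_per_child.append(opts)
        out: list[tuple] = []
        stack: list[tuple[int, tuple]] = [(0, ())]
        while stack:
            k, acc = stack.pop()
            if k == len(options_per_child):
                out.append(("E", node.label, acc))
                continue
            for opt in options_per_child[k]:
                stack.append((k + 1, acc + (opt,)))
        return out

    counts: Counter = Counter()
    for node in internal:
        counts.update(fragments(node))
    return counts


def _n_productions(fragment: tuple) -> int:
    tag = fragment[0]
    if tag in ("W", "N"):
        return 0
    return 1 + sum(_n_productions(c) for c in fragment[2])


def phi_inner_product(phi1: Counter, phi2: Counter, lam: float) -> float:
    """lambda-weighted inner product of two explicit fragment multisets.

    Each common fragment type contributes count1 * count2 * lambda^p with p
    its number of productions; this equals the recursive kernel exactly.
    """
    total = 0.0
    for frag, c1 in phi1.items():
        c2 = phi2.get(frag)
        if c2:
            total += c1 * c2 * lam ** _n_productions(frag)
    return total
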