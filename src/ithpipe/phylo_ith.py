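"""Per-patient mutation matrices, parsimony trees and the ITH score.

Each patient's passing somatic calls (silent and non-silent alike) are
collapsed into a binary presence/absence matrix of region-samples by
mutations.  Mutations present in every region are *trunk*, in more
than one but not all regions *shared*, and in exactly one region
*private*; shared + private together are *non-trunk*.

Tree search operates on unrooted topologies over the region-samples
plus an all-absent germline outgroup; the trunk is the edge joining
the outgroup to the ingroup.  Characters are binary (absent/present)
and scored with the Fitch small-parsimony algorithm.  Two search modes
are provided: exact exhaustive enumeration (practical for the cohort's
3-9 regions) and the parsimony ratchet - iterated subtree-prune-regraft hill
climbing alternating between a perturbed scoring (a random ~25% of
characters upweighted) and the original weights.

Branch lengths are mutation counts: each character's state changes are
placed on edges by a minimal Fitch backtrace (the ancestral, absent
state is retained wherever optimal, so trunk mutations land on the
outgroup-adjacent edge and private mutations on terminal edges);
characters needing more than one change are flagged as homoplastic.

Two ITH definitions are supported and always reported explicitly:
``methods`` = 100 * trunk / non-trunk, and ``nontrunk_fraction`` =
100 * non-trunk / total.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterator, Union

import numpy as np
import pandas as pd

Topology = Union[int, tuple]  # leaf index, or (left, right) internal node

GERMLINE = "germline"

SILENT_EXONIC_FUNCS = {"synonymous", "synonymous snv", "synonymous_snv"}


# ---------------------------------------------------------------------------
# Binary matrix and tree-free classification


@dataclass
class BinaryMutationMatrix:
    """Region-samples x mutations presence/absence grid for one patient."""

    patient_id: str
    sample_ids: list[str]
    mutation_ids: list[str]
    presence: np.ndarray  # bool, shape (n_samples, n_mutations)
    silent: np.ndarray | None = None  # bool per mutation

    def __post_init__(self) -> None:
        self.presence = np.asarray(self.presence, dtype=bool)
        if self.presence.shape != (len(self.sample_ids), len(self.mutation_ids)):
            raise ValueError("presence grid shape mismatch")
        if len(self.sample_ids) < 2:
            raise ValueError(
                f"patient {self.patient_id}: phylogenetic analysis needs >=2 "
                f"region-samples, got {len(self.sample_ids)}"
            )
        if len(set(self.mutation_ids)) != len(self.mutation_ids):
            raise ValueError("duplicate mutation ids")
        if self.presence.shape[1] and not self.presence.any(axis=0).all():
            raise ValueError("every mutation must be present in >=1 sample")
        if self.silent is None:
            self.silent = np.zeros(len(self.mutation_ids), dtype=bool)
        else:
            self.silent = np.asarray(self.silent, dtype=bool)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_mutations(self) -> int:
        return len(self.mutation_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.presence.astype(int), index=self.sample_ids, columns=self.mutation_ids
        )


def mutation_key(chrom, pos, ref, alt) -> str:
    return f"{chrom}:{pos}:{ref}>{alt}"


def build_matrix(
    records: pd.DataFrame,
    include_silent: bool = True,
    sample_ids: list[str] | None = None,
) -> BinaryMutationMatrix:
    """Collapse one patient's passing calls into a presence/absence matrix.

    One column per unique (chrom, pos, ref, alt); duplicate calls of a
    mutation within one sample collapse to a single cell.  Silent
    (synonymous) mutations are included by default, matching the use of
    both silent and non-silent mutations for tree building.
    """
    patients = records["patient"].unique()
    if len(patients) != 1:
        raise ValueError(f"build_matrix expects a single patient, got {list(patients)}")
    df = records.copy()
    ef = df.get("exonic_func")
    silent_row = (
        ef.astype(str).str.lower().isin(SILENT_EXONIC_FUNCS)
        if ef is not None
        else pd.Series(False, index=df.index)
    )
    if not include_silent:
        df = df[~silent_row]
        silent_row = silent_row[~silent_row]
    keys = [
        mutation_key(c, p, r, a)
        for c, p, r, a in zip(df["chrom"], df["pos"], df["ref"], df["alt"])
    ]
    df = df.assign(_key=keys)
    samples = sample_ids if sample_ids is not None else sorted(df["sample"].unique())
    order = list(dict.fromkeys(df["_key"]))
    sidx = {s: i for i, s in enumerate(samples)}
    midx = {m: i for i, m in enumerate(order)}
    presence = np.zeros((len(samples), len(order)), dtype=bool)
    silent = np.zeros(len(order), dtype=bool)
    for (_, row), is_sil in zip(df.iterrows(), silent_row):
        if row["sample"] not in sidx:
            raise ValueError(f"sample {row['sample']!r} not in sample_ids")
        presence[sidx[row["sample"]], midx[row["_key"]]] = True
        if is_sil:
            silent[midx[row["_key"]]] = True
    return BinaryMutationMatrix(
        patient_id=str(patients[0]),
        sample_ids=list(samples),
        mutation_ids=order,
        presence=presence,
        silent=silent,
    )


def classify_mutations(matrix: BinaryMutationMatrix) -> np.ndarray:
    """Label each mutation trunk / shared / private from presence counts.

    Trunk: present in all samples; private: in exactly one; shared:
    in more than one but not all.  Independent of any tree.
    """
    counts = matrix.presence.sum(axis=0)
    n = matrix.n_samples
    labels = np.where(counts == n, "trunk", np.where(counts == 1, "private", "shared"))
    return labels.astype(object)


def ith_score(labels, definition: str = "methods") -> float:
    """Heterogeneity score from trunk/shared/private labels, as a percentage.

    ``definition="methods"`` returns 100 * trunk / (shared + private);
    ``definition="nontrunk_fraction"`` returns
    100 * (shared + private) / total.  With no non-trunk mutations the
    methods ratio is undefined: NaN is returned with a warning.
    """
    labels = np.asarray(labels, dtype=object)
    if labels.size == 0:
        raise ValueError("no mutation labels")
    trunk = int((labels == "trunk").sum())
    nontrunk = int(labels.size - trunk)
    if definition == "methods":
        if nontrunk == 0:
            warnings.warn("no non-trunk mutations: trunk/non-trunk ratio undefined", stacklevel=2)
            return float("nan")
        return 100.0 * trunk / nontrunk
    if definition == "nontrunk_fraction":
        return 100.0 * nontrunk / labels.size
    raise ValueError(f"unknown ITH definition {definition!r}")


# ---------------------------------------------------------------------------
# Fitch scoring on topologies


def _leaf_masks(presence: np.ndarray) -> np.ndarray:
    """Per-leaf per-character state sets as 2-bit masks (bit0=absent, bit1=present)."""
    return np.where(presence, 2, 1).astype(np.uint8)


def fitch_changes(tree: Topology, masks: np.ndarray) -> np.ndarray:
    """Per-character minimum change counts on one topology.

    `tree` is a nested-tuple topology over ingroup leaf indices; the
    all-absent germline outgroup is attached above the root, so a root
    state set lacking the absent state contributes one trunk change.
    """
    ncols = masks.shape[1]
    changes = np.zeros(ncols, dtype=np.int32)

    def rec(node) -> np.ndarray:
        if isinstance(node, (int, np.integer)):
            return masks[node]
        left = rec(node[0])
        right = rec(node[1])
        inter = left & right
        empty = inter == 0
        changes[empty] += 1
        return np.where(empty, left | right, inter)

    root = rec(tree)
    changes[(root & 1) == 0] += 1  # change on the germline/trunk edge
    return changes


def fitch_score(
    tree: Topology, matrix: BinaryMutationMatrix, weights: np.ndarray | None = None
) -> int:
    """Weighted Fitch parsimony score of `matrix` on `tree` (+ germline outgroup)."""
    leaves = sorted(_collect_leaves(tree))
    if leaves != list(range(matrix.n_samples)):
        raise ValueError("tree leaves must be exactly the sample indices 0..n-1")
    ch = fitch_changes(tree, _leaf_masks(matrix.presence))
    if weights is None:
        return int(ch.sum())
    return int((ch * np.asarray(weights)).sum())


def _collect_leaves(tree: Topology) -> list[int]:
    if isinstance(tree, (int, np.integer)):
        return [int(tree)]
    return _collect_leaves(tree[0]) + _collect_leaves(tree[1])


# ---------------------------------------------------------------------------
# Topology enumeration and rearrangement


def _insert_everywhere(tree: Topology, leaf: int) -> Iterator[Topology]:
    yield (tree, leaf)  # on the edge above this node
    if isinstance(tree, tuple):
        left, right = tree
        for nl in _insert_everywhere(left, leaf):
            yield (nl, right)
        for nr in _insert_everywhere(right, leaf):
            yield (left, nr)


def enumerate_topologies(n_samples: int) -> Iterator[Topology]:
    """All unrooted topologies over n samples + germline, rooted at the trunk.

    Yields (2n-3)!! nested-tuple trees.  Practical for n <= 8.
    """
    if n_samples < 2:
        raise ValueError("need >=2 samples")

    def build(k: int) -> Iterator[Topology]:
        if k == 2:
            yield (0, 1)
            return
        for t in build(k - 1):
            yield from _insert_everywhere(t, k - 1)

    if n_samples == 2:
        yield (0, 1)
    else:
        yield from build(n_samples)


def nni_neighbors(tree: Topology) -> list[Topology]:
    """All nearest-neighbour-interchange rearrangements of a topology."""
    out: list[Topology] = []

    def visit(node: Topology, rebuild) -> None:
        if not isinstance(node, tuple):
            return
        left, right = node
        if isinstance(left, tuple):
            a, b = left
            out.append(rebuild(((right, b), a)))
            out.append(rebuild(((a, right), b)))
        if isinstance(right, tuple):
            c, d = right
            out.append(rebuild((c, (left, d))))
            out.append(rebuild((d, (c, left))))
        visit(left, lambda nl, right=right, rebuild=rebuild: rebuild((nl, right)))
        visit(right, lambda nr, left=left, rebuild=rebuild: rebuild((left, nr)))

    visit(tree, lambda t: t)
    return out


def spr_neighbors(tree: Topology) -> list[Topology]:
    """All subtree-prune-regraft rearrangements (a superset of NNI).

    Every proper subtree is detached (its sibling promoted) and
    reattached on every edge of the remainder.  With at most nine
    region-samples this neighbourhood is small enough for steepest-
    descent search and escapes the shallow local optima that pure
    nearest-neighbour interchange can stall in on conflict-heavy data.
    """
    out: list[Topology] = []
    if not isinstance(tree, tuple):
        return out

    def subtrees(node, rebuild):
        # rebuild(keep) -> the tree with `node` replaced by `keep`; pruning
        # a child therefore promotes its sibling via rebuild(sibling)
        left, right = node
        yield left, (lambda right=right, rb=rebuild: rb(right))
        yield right, (lambda left=left, rb=rebuild: rb(left))
        if isinstance(left, tuple):
            yield from subtrees(left, lambda keep, right=right, rb=rebuild: rb((keep, right)))
        if isinstance(right, tuple):
            yield from subtrees(right, lambda keep, left=left, rb=rebuild: rb((left, keep)))

    for sub, detach in subtrees(tree, lambda keep: keep):
        rest = detach()
        for cand in _insert_everywhere(rest, sub):
            out.append(cand)
    return out


def exhaustive_search(
    matrix: BinaryMutationMatrix, max_samples: int = 8
) -> tuple[Topology, int]:
    """Exact minimum-parsimony topology by full enumeration (small n).

    Ties broken by first-found in enumeration order, which is
    deterministic.
    """
    n = matrix.n_samples
    if n > max_samples:
        raise ValueError(f"exhaustive search limited to {max_samples} samples, got {n}")
    masks = _leaf_masks(matrix.presence)
    best_tree, best_score = None, None
    for t in enumerate_topologies(n):
        s = int(fitch_changes(t, masks).sum())
        if best_score is None or s < best_score:
            best_tree, best_score = t, s
    return best_tree, best_score


def _greedy_start(masks: np.ndarray, order: np.ndarray) -> Topology:
    """Stepwise-addition starting tree: each leaf inserted at its best edge."""
    order = list(order)
    tree: Topology = (int(order[0]), int(order[1])) if len(order) > 1 else int(order[0])
    for leaf in order[2:]:
        best, best_s = None, None
        for cand in _insert_everywhere(tree, int(leaf)):
            sub = sorted(_collect_leaves(cand))
            s = int(fitch_changes(cand, masks).sum()) if sub else 0
            if best_s is None or s < best_s:
                best, best_s = cand, s
        tree = best
    return tree


def _hill_climb(
    tree: Topology, masks: np.ndarray, weights: np.ndarray | None
) -> tuple[Topology, int]:
    """Steepest-descent SPR search from `tree` (strict improvements only)."""

    def score(t):
        ch = fitch_changes(t, masks)
        return int(ch.sum()) if weights is None else int((ch * weights).sum())

    cur, cur_s = tree, score(tree)
    while True:
        best, best_s = None, cur_s
        for nb in spr_neighbors(cur):
            s = score(nb)
            if s < best_s:
                best, best_s = nb, s
        if best is None:
            return cur, cur_s
        cur, cur_s = best, best_s


# ---------------------------------------------------------------------------
# Branch lengths via Fitch backtrace


def _edge_assignments(
    tree: Topology, masks: np.ndarray, sample_ids: list[str]
) -> tuple[dict[tuple[str, ...], int], list[list[tuple[str, ...]]]]:
    """Place each character's changes on edges by minimal Fitch backtrace.

    Edges are identified by the sorted tuple of sample ids below them;
    the trunk edge is the full-sample tuple.  Returns per-edge mutation
    counts and per-character lists of changed edges.
    """
    ncols = masks.shape[1]
    down: dict[int, np.ndarray] = {}
    clades: dict[int, tuple[str, ...]] = {}
    counter = iter(range(10**9))

    def post(node) -> tuple[int, np.ndarray]:
        nid = next(counter)
        if isinstance(node, (int, np.integer)):
            down[nid] = masks[node]
            clades[nid] = (sample_ids[int(node)],)
            return nid, masks[node]
        lid, lm = post(node[0])
        rid, rm = post(node[1])
        inter = lm & rm
        m = np.where(inter == 0, lm | rm, inter)
        down[nid] = m
        clades[nid] = tuple(sorted(clades[lid] + clades[rid]))
        node_children[nid] = (lid, rid, node)
        return nid, m

    node_children: dict[int, tuple] = {}
    root_id, root_mask = post(tree)

    per_char_edges: list[list[tuple[str, ...]]] = [[] for _ in range(ncols)]
    edge_counts: dict[tuple[str, ...], int] = {}

    # states: 1 = absent, 2 = present; germline parent state is 1
    def assign(nid: int, parent_state: np.ndarray) -> None:
        m = down[nid]
        keep = (m & parent_state) != 0
        state = np.where(keep, parent_state, m)
        changed = np.flatnonzero(state != parent_state)
        if changed.size:
            clade = clades[nid]
            edge_counts[clade] = edge_counts.get(clade, 0) + changed.size
            for j in changed:
                per_char_edges[j].append(clade)
        if nid in node_children:
            lid, rid, _ = node_children[nid]
            assign(lid, state)
            assign(rid, state)

    assign(root_id, np.full(ncols, 1, dtype=np.uint8))
    return edge_counts, per_char_edges


def _to_newick(
    tree: Topology, sample_ids: list[str], edge_counts: dict[tuple[str, ...], int]
) -> str:
    def clade(node) -> tuple[str, ...]:
        return tuple(sorted(sample_ids[i] for i in _collect_leaves(node)))

    def rec(node) -> str:
        length = edge_counts.get(clade(node), 0)
        if isinstance(node, (int, np.integer)):
            return f"{sample_ids[int(node)]}:{length}"
        return f"({rec(node[0])},{rec(node[1])}):{length}"

    return f"({GERMLINE}:0,{rec(tree)});"


# ---------------------------------------------------------------------------
# Search drivers


@dataclass
class PhyloResult:
    """Tree, per-mutation classes and ITH scores for one patient."""

    patient_id: str
    sample_ids: list[str]
    newick: str
    parsimony_score: int
    branch_lengths: dict[tuple[str, ...], int]
    labels: np.ndarray
    mutation_ids: list[str]
    mutation_edges: list[list[tuple[str, ...]]]
    homoplastic: np.ndarray
    ith: dict[str, float]
    method: str
    ratchet_iterations: int = 0
    seed: int | None = None
    topology: Topology = None

    def labels_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "mutation": self.mutation_ids,
                "label": self.labels,
                "homoplastic": self.homoplastic.astype(int),
            }
        )


def _finalize(
    matrix: BinaryMutationMatrix,
    tree: Topology,
    score: int,
    method: str,
    iterations: int,
    seed: int | None,
) -> PhyloResult:
    masks = _leaf_masks(matrix.presence)
    edge_counts, per_char = _edge_assignments(tree, masks, matrix.sample_ids)
    labels = classify_mutations(matrix)
    homop = np.array([len(e) > 1 for e in per_char])
    ith = {
        "methods": ith_score(labels, "methods") if labels.size else float("nan"),
        "nontrunk_fraction": ith_score(labels, "nontrunk_fraction") if labels.size else float("nan"),
    }
    return PhyloResult(
        patient_id=matrix.patient_id,
        sample_ids=list(matrix.sample_ids),
        newick=_to_newick(tree, matrix.sample_ids, edge_counts),
        parsimony_score=int(score),
        branch_lengths=edge_counts,
        labels=labels,
        mutation_ids=list(matrix.mutation_ids),
        mutation_edges=per_char,
        homoplastic=homop,
        ith=ith,
        method=method,
        ratchet_iterations=iterations,
        seed=seed,
        topology=tree,
    )


def parsimony_ratchet(
    matrix: BinaryMutationMatrix,
    iterations: int = 100,
    seed: int = 0,
    perturb_fraction: float = 0.25,
) -> PhyloResult:
    """Parsimony-ratchet tree search; deterministic under a fixed seed.

    Each iteration upweights a random ~25% of characters (weight 2),
    hill-climbs (steepest-descent SPR) from the incumbent under the
    perturbed weights, restores the original unit weights and climbs
    again, and keeps the result only on strict improvement (ties keep
    the incumbent).
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    n = matrix.n_samples
    rng = np.random.default_rng(seed)
    masks = _leaf_masks(matrix.presence)
    if n == 2:
        tree: Topology = (0, 1)
        score = int(fitch_changes(tree, masks).sum())
        return _finalize(matrix, tree, score, "ratchet", iterations, seed)
    order = rng.permutation(n)
    tree = _greedy_start(masks, order)
    tree, score = _hill_climb(tree, masks, None)
    ncols = masks.shape[1]
    k = max(1, round(perturb_fraction * ncols))
    for _ in range(iterations):
        w = np.ones(ncols, dtype=np.int64)
        w[rng.choice(ncols, size=k, replace=False)] = 2
        t1, _ = _hill_climb(tree, masks, w)
        t2, s2 = _hill_climb(t1, masks, None)
        if s2 < score:
            tree, score = t2, s2
    return _finalize(matrix, tree, score, "ratchet", iterations, seed)


def exact_tree(matrix: BinaryMutationMatrix) -> PhyloResult:
    """Exhaustive-search (exact) maximum-parsimony tree for small patients."""
    tree, score = exhaustive_search(matrix)
    return _finalize(matrix, tree, score, "exhaustive", 0, None)


def write_outputs(result: PhyloResult, outdir) -> None:
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    (out / f"{result.patient_id}.nwk").write_text(result.newick + "\n")
    result.labels_frame().to_csv(out / f"{result.patient_id}_labels.tsv", sep="\t", index=False)
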