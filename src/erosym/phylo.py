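"""Distance-based tree inference and tree-comparison machinery.

Neighbor joining with bootstrap stands in for likelihood/Bayesian inference
at desk scale; the comparison layer provides Robinson–Foulds distances,
unrooted monophyly tests, minimum-transition (parsimony) counts for a binary
lifestyle character, and tanglegram congruence between host and symbiont
phylogenies.

All functions accept and return :class:`dendropy.Tree`. Bipartitions are
represented as frozensets of tip labels, canonicalized to the side not
containing the lexicographically smallest tip, which makes every operation
polytomy-safe and rooting-invariant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np


def tree_from_newick(newick: str) -> dendropy.Tree:
    return dendropy.Tree.get(
        data=newick,
        schema="newick",
        preserve_underscores=True,
        suppress_internal_node_taxa=True,
    )


def tip_labels(tree: dendropy.Tree) -> list[str]:
    return [lf.taxon.label for lf in tree.leaf_node_iter()]


# ---------------------------------------------------------------------------
# Bipartitions


def bipartitions(tree: dendropy.Tree, include_trivial: bool = False) -> set[frozenset]:
    """Non-trivial bipartitions of an (un)rooted tree as canonical tip-label sets.

    Each internal edge splits the tips in two; the side NOT containing the
    lexicographically smallest tip represents the bipartition. Polytomies
    simply yield fewer bipartitions.
    """
    labels = sorted(tip_labels(tree))
    n = len(labels)
    ref = labels[0]
    all_tips = frozenset(labels)
    out: set[frozenset] = set()
    below: dict = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            below[node] = frozenset([node.taxon.label])
        else:
            below[node] = frozenset().union(*(below[c] for c in node.child_nodes()))
        side = below[node]
        if ref in side:
            side = all_tips - side
        lo = 1 if include_trivial else 2
        if lo <= len(side) <= n - lo:
            out.add(side)
    return out


def rf_distance(t1: dendropy.Tree, t2: dendropy.Tree) -> tuple[int, float]:
    """Robinson–Foulds distance: raw bipartition symmetric difference and the
    value normalized by 2(n−3)."""
    l1, l2 = set(tip_labels(t1)), set(tip_labels(t2))
    if l1 != l2:
        raise ValueError(
            f"tip sets differ: only-in-first={sorted(l1 - l2)}, only-in-second={sorted(l2 - l1)}"
        )
    b1, b2 = bipartitions(t1), bipartitions(t2)
    raw = len(b1 ^ b2)
    n = len(l1)
    denom = 2 * (n - 3)
    return raw, (raw / denom if denom > 0 else 0.0)


def is_monophyletic(tree: dendropy.Tree, taxon_set) -> bool:
    """Unrooted monophyly: some bipartition separates exactly ``taxon_set``.

    Singletons are monophyletic by definition; the empty set and the full tip
    set are errors.
    """
    taxon_set = frozenset(taxon_set)
    tips = set(tip_labels(tree))
    if not taxon_set or taxon_set == tips:
        raise ValueError("taxon set must be a nonempty proper subset of the tips")
    missing = taxon_set - tips
    if missing:
        raise ValueError(f"taxa not in tree: {sorted(missing)}")
    if len(taxon_set) == 1 or len(taxon_set) == len(tips) - 1:
        return True
    ref = min(sorted(tips))
    canonical = taxon_set if ref not in taxon_set else frozenset(tips) - taxon_set
    return canonical in bipartitions(tree)


# ---------------------------------------------------------------------------
# Parsimony


def fitch_min_transitions(tree: dendropy.Tree, tip_states: dict[str, object]) -> int:
    """Minimum number of state changes explaining binary tip states.

    Uses Hartigan's generalization of the Fitch recursion so the count is
    exact on polytomies too; the result is invariant to rooting.
    """
    for lf in tree.leaf_node_iter():
        if lf.taxon.label not in tip_states:
            raise ValueError(f"unlabeled tip: {lf.taxon.label!r}")
    changes = 0
    upper: dict = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            upper[node] = frozenset([tip_states[node.taxon.label]])
            continue
        votes: dict = {}
        for c in node.child_nodes():
            for s in upper[c]:
                votes[s] = votes.get(s, 0) + 1
        k = max(votes.values())
        upper[node] = frozenset(s for s, v in votes.items() if v == k)
        changes += len(node.child_nodes()) - k
    return changes


# ---------------------------------------------------------------------------
# Distances from alignments


def pdistance_matrix(
    loci: dict[str, dict[str, str]],
    concatenate: bool = True,
    jc_correction: bool = False,
    min_locus_fraction: float = 0.5,
):
    """Pairwise p-distances from per-locus aligned homologous sequences.

    ``loci`` maps locus id -> {taxon -> aligned sequence}; within a locus all
    sequences must have equal length. Taxa present in fewer than
    ``min_locus_fraction`` of loci are dropped (with a warning attribute on
    the result). Sites where either sequence has a gap ('-') or 'N' are
    excluded pairwise. With ``jc_correction`` the Jukes–Cantor transform
    −(3/4)·ln(1 − (4/3)p) is applied.

    Returns ``(labels, matrix)`` with a symmetric numpy array.
    """
    if not loci:
        raise ValueError("no loci")
    n_loci = len(loci)
    counts: dict[str, int] = {}
    for seqs in loci.values():
        lens = {len(s) for s in seqs.values()}
        if len(lens) > 1:
            raise ValueError("unequal sequence lengths within a locus")
        for t in seqs:
            counts[t] = counts.get(t, 0) + 1
    taxa = sorted(t for t, c in counts.items() if c / n_loci >= min_locus_fraction)
    if len(taxa) < 2:
        raise ValueError("fewer than two taxa after locus-presence filtering")

    # Build per-taxon concatenation with gap fill for missing loci
    order = sorted(loci)
    cat: dict[str, str] = {}
    for t in taxa:
        parts = []
        for og in order:
            seqs = loci[og]
            L = len(next(iter(seqs.values())))
            parts.append(seqs.get(t, "-" * L))
        cat[t] = "".join(parts)

    enc = {"A": 0, "C": 1, "G": 2, "T": 3, "-": 4, "N": 4}
    arrs = {
        t: np.frombuffer(cat[t].upper().encode(), dtype=np.uint8) for t in taxa
    }
    lut = np.full(256, 4, dtype=np.uint8)
    for ch, v in enc.items():
        lut[ord(ch)] = v
    arrs = {t: lut[a] for t, a in arrs.items()}

    m = len(taxa)
    D = np.zeros((m, m))
    for i in range(m):
        ai = arrs[taxa[i]]
        for j in range(i + 1, m):
            aj = arrs[taxa[j]]
            ok = (ai < 4) & (aj < 4)
            shared = int(ok.sum())
            if shared == 0:
                raise ValueError(f"zero shared sites for pair ({taxa[i]}, {taxa[j]})")
            p = float(((ai != aj) & ok).sum()) / shared
            D[i, j] = D[j, i] = jukes_cantor(p) if jc_correction else p
    return taxa, D


def jukes_cantor(p: float) -> float:
    """JC69 distance correction; saturates (p ≥ 0.75) → raises."""
    if p == 0.0:
        return 0.0
    if p >= 0.75:
        raise ValueError(f"p-distance {p} saturated under Jukes–Cantor")
    return -0.75 * np.log1p(-(4.0 / 3.0) * p)


# ---------------------------------------------------------------------------
# Neighbor joining


def nj_tree(labels: list[str], matrix) -> dendropy.Tree:
    """Canonical neighbor joining (Saitou–Nei Q criterion).

    Ties in Q are broken by the lexicographically smallest (label_i, label_j)
    pair, labels of merged nodes being the smaller of the children's, so the
    result is deterministic. Negative branch lengths are clamped to zero with
    the deficit moved to the sister branch.
    """
    D = np.asarray(matrix, dtype=float)
    n = len(labels)
    if n < 3:
        raise ValueError("need at least 3 taxa")
    if D.shape != (n, n) or not np.allclose(D, D.T, atol=1e-12):
        raise ValueError("matrix must be square and symmetric")

    # active nodes: (sort_label, newick_subtree)
    nodes = [(labels[i], labels[i]) for i in range(n)]
    D = D.copy()
    active = list(range(n))

    def pair_key(i, j):
        a, b = nodes[i][0], nodes[j][0]
        return (a, b) if a <= b else (b, a)

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        cands = [
            (pair_key(active[a], active[b]), a, b)
            for a, b in zip(*np.where(np.isclose(Q, qmin, rtol=0, atol=1e-10)))
            if a < b
        ]
        _, ai, bi = min(cands)
        i, j = active[ai], active[bi]
        dij = sub[ai, bi]
        li = 0.5 * dij + (r[ai] - r[bi]) / (2.0 * (m - 2))
        lj = dij - li
        # clamp negatives, moving the deficit to the sister branch
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        li, lj = max(li, 0.0), max(lj, 0.0)
        new_lab = min(nodes[i][0], nodes[j][0])
        new_nwk = f"({nodes[i][1]}:{li:.10g},{nodes[j][1]}:{lj:.10g})"
        # distances to the new node
        newd = np.zeros(D.shape[0] + 1)
        for k in active:
            if k in (i, j):
                continue
            newd[k] = 0.5 * (D[i, k] + D[j, k] - dij)
        D = np.pad(D, ((0, 1), (0, 1)))
        D[-1, : len(newd) - 1] = newd[:-1]
        D[: len(newd) - 1, -1] = newd[:-1]
        nodes.append((new_lab, new_nwk))
        active = [k for k in active if k not in (i, j)] + [len(nodes) - 1]

    # join the last three on a central node (three-point formulas)
    a, b, c = active
    la = 0.5 * (D[a, b] + D[a, c] - D[b, c])
    lb = 0.5 * (D[a, b] + D[b, c] - D[a, c])
    lc = 0.5 * (D[a, c] + D[b, c] - D[a, b])
    la, lb, lc = (max(x, 0.0) for x in (la, lb, lc))
    trio = sorted([a, b, c], key=lambda k: nodes[k][0])
    lens = {a: la, b: lb, c: lc}
    newick = (
        "("
        + ",".join(f"{nodes[k][1]}:{lens[k]:.10g}" for k in trio)
        + ");"
    )
    return tree_from_newick(newick)


def nj_from_pdistance(loci, jc_correction=False) -> dendropy.Tree:
    taxa, D = pdistance_matrix(loci, jc_correction=jc_correction)
    return nj_tree(taxa, D)


def bootstrap_support(
    loci: dict[str, dict[str, str]],
    n_replicates: int = 100,
    seed: int = 0,
    jc_correction: bool = False,
) -> dendropy.Tree:
    """NJ tree with bipartition bootstrap supports (percent of replicates).

    Columns of the concatenated alignment are resampled with replacement;
    supports are attached to internal node labels of the point-estimate tree.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    taxa, D = pdistance_matrix(loci)
    point = nj_tree(taxa, jc_matrix(D) if jc_correction else D)

    # concatenate once, then resample columns
    order = sorted(loci)
    cat = {}
    for t in taxa:
        parts = []
        for og in order:
            seqs = loci[og]
            L = len(next(iter(seqs.values())))
            parts.append(seqs.get(t, "-" * L))
        cat[t] = "".join(parts)
    L = len(next(iter(cat.values())))
    mats = np.vstack(
        [np.frombuffer(cat[t].upper().encode(), dtype=np.uint8) for t in taxa]
    )
    rng = np.random.default_rng(seed)
    counts: dict[frozenset, int] = {}
    for _ in range(n_replicates):
        cols = rng.integers(0, L, size=L)
        sub = mats[:, cols]
        Drep = _pdist_from_matrix(sub)
        try:
            rep_tree = nj_tree(taxa, jc_matrix(Drep) if jc_correction else Drep)
        except ValueError:
            continue
        for bp in bipartitions(rep_tree):
            counts[bp] = counts.get(bp, 0) + 1

    for node in point.postorder_internal_node_iter():
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        ref = min(sorted(taxa))
        allt = frozenset(taxa)
        if ref in side:
            side = allt - side
        if 2 <= len(side) <= len(taxa) - 2:
            node.label = f"{100.0 * counts.get(side, 0) / n_replicates:.0f}"
    return point


def jc_matrix(D):
    out = np.zeros_like(D)
    for i in range(D.shape[0]):
        for j in range(D.shape[1]):
            if i != j:
                out[i, j] = jukes_cantor(D[i, j])
    return out


def _pdist_from_matrix(mat) -> np.ndarray:
    gapA, gapN, gapDash = ord("-"), ord("N"), ord("-")
    ok_base = (mat != gapA) & (mat != gapN) & (mat != gapDash)
    m = mat.shape[0]
    D = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            ok = ok_base[i] & ok_base[j]
            shared = int(ok.sum())
            p = float(((mat[i] != mat[j]) & ok).sum()) / shared if shared else 0.0
            D[i, j] = D[j, i] = p
    return D


# ---------------------------------------------------------------------------
# Tanglegram congruence


@dataclass
class CongruenceReport:
    """Topological congruence between two trees on a shared (mapped) tip set."""

    tree_a_id: str
    tree_b_id: str
    tip_mapping: dict[str, str]
    shared_bipartition_fraction: float
    normalized_rf: float
    node_congruence: dict[frozenset, bool] = field(default_factory=dict)


def tanglegram_congruence(
    tree_a: dendropy.Tree,
    tree_b: dendropy.Tree,
    tip_mapping: dict[str, str],
    tree_a_id: str = "a",
    tree_b_id: str = "b",
) -> CongruenceReport:
    """Congruence between tree_a (e.g. symbionts) and tree_b (e.g. hosts).

    ``tip_mapping`` maps tree_a tips to tree_b tips; many-to-one maps are
    collapsed by keeping, per tree_b tip, the lexicographically smallest
    tree_a tip. Both trees are restricted to the mapped tips, tree_a tips are
    relabeled by their mapped partner, and the bipartition sets compared.
    Per-node flags mark each internal bipartition of tree_a found in tree_b
    (the congruent-node "gray dot" analogue).
    """
    a_tips = set(tip_labels(tree_a))
    b_tips = set(tip_labels(tree_b))
    mapping = {a: b for a, b in tip_mapping.items() if a in a_tips and b in b_tips}
    # collapse many-to-one
    byb: dict[str, list[str]] = {}
    for a, b in sorted(mapping.items()):
        byb.setdefault(b, []).append(a)
    kept = {min(alist): b for b, alist in byb.items()}
    if len(kept) < 4:
        raise ValueError(f"only {len(kept)} mapped tips; need >= 4")

    ra = restrict_tree(tree_a, set(kept))
    rb = restrict_tree(tree_b, set(kept.values()))
    # relabel tree_a tips with the host names
    for lf in ra.leaf_node_iter():
        lf.taxon.label = kept[lf.taxon.label]
    ba, bb = bipartitions(ra), bipartitions(rb)
    union = len(ba) + len(bb)
    raw = len(ba ^ bb)
    nrf = raw / union if union else 0.0
    shared = 1.0 - nrf
    node_flags = {bp: (bp in bb) for bp in ba}
    return CongruenceReport(
        tree_a_id=tree_a_id,
        tree_b_id=tree_b_id,
        tip_mapping=dict(kept),
        shared_bipartition_fraction=shared,
        normalized_rf=nrf,
        node_congruence=node_flags,
    )


def restrict_tree(tree: dendropy.Tree, keep_labels: set[str]) -> dendropy.Tree:
    """Copy of the tree restricted to ``keep_labels`` (degree-2 nodes suppressed)."""
    missing = keep_labels - set(tip_labels(tree))
    if missing:
        raise ValueError(f"labels not in tree: {sorted(missing)}")
    clone = tree.clone(depth=1)
    taxa = [t for t in clone.taxon_namespace if t.label in keep_labels]
    clone.retain_taxa(taxa)
    return tree_from_newick(
        clone.as_string(schema="newick", unquoted_underscores=True, suppress_rooting=True)
    )
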