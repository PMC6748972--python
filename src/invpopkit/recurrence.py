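"""Orientation assignment, haplotype clustering and recurrence inference.

A unique-origin inversion produces a single clade of same-orientation
haplotypes; a recurrent one (typically mediated by inverted repeats) shows
opposite-orientation haplotypes scattered across the clustering.  The
minimum number of orientation events is obtained by small parsimony on the
haplotype dendrogram (the clustering tree standing in for the genealogy),
after pruning likely phasing errors, and minus one because the original
inversion is not recurrence.  The same small-parsimony machinery applied to
the chromosome-Y genealogical tree, where recombination is absent, yields
clean event counts and a per-generation inversion rate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import pdist, squareform
from scipy.stats import chi2

from .core_io import GenotypeTable, HaplotypeSet, InvpopkitError

logger = logging.getLogger("invpopkit")


# ---------------------------------------------------------------------------
# Orientation assignment on phased haplotypes
# ---------------------------------------------------------------------------

def assign_orientation(haps: HaplotypeSet, gt: GenotypeTable, inversion: str,
                       tags: pd.DataFrame | None = None) -> HaplotypeSet:
    """Label each haplotype's inversion orientation.

    With perfect tag variants (r² = 1), the orientation is imputed from the
    tag allele carried by the haplotype; haplotypes with conflicting
    perfect tags are flagged and left unknown.  Without perfect tags, only
    the haplotypes of inversion homozygotes/hemizygotes can be labeled
    (their orientation is unambiguous from the genotype alone); all others
    stay unknown.

    ``tags`` is the output of :func:`invpopkit.linkage.find_tag_variants`;
    rows with ``perfect == True`` are used, matched to haplotype sites by
    position.
    """
    orientation = np.array(["unknown"] * haps.n_haplotypes, dtype=object)
    perfect = None
    if tags is not None and not tags.empty:
        perfect = tags[tags["perfect"]]
        pos_to_col = {int(p): i for i, p in enumerate(haps.positions)}
        tag_cols, tag_o2 = [], []
        for row in perfect.itertuples(index=False):
            col = pos_to_col.get(int(row.position))
            if col is not None:
                tag_cols.append(col)
                tag_o2.append(int(row.o2_allele))
        if tag_cols:
            for h in range(haps.n_haplotypes):
                votes = set()
                for col, o2_allele in zip(tag_cols, tag_o2):
                    allele = haps.haplotypes[h, col]
                    if allele < 0:
                        continue
                    votes.add("O2" if allele == o2_allele else "O1")
                if len(votes) == 1:
                    orientation[h] = votes.pop()
                elif len(votes) == 2:
                    logger.warning("haplotype %d: conflicting perfect tags; excluded", h)
            out = HaplotypeSet(
                haplotypes=haps.haplotypes.copy(),
                positions=haps.positions.copy(),
                orientation=orientation,
                sample_id=haps.sample_id.copy(),
                population=haps.population.copy(),
                accessible=haps.accessible.copy(),
            )
            return out

    # no usable perfect tags: restrict to homozygotes / hemizygotes
    for h in range(haps.n_haplotypes):
        alleles = set(gt.alleles(str(haps.sample_id[h]), inversion))
        if len(alleles) == 1:
            orientation[h] = alleles.pop()
    return HaplotypeSet(
        haplotypes=haps.haplotypes.copy(),
        positions=haps.positions.copy(),
        orientation=orientation,
        sample_id=haps.sample_id.copy(),
        population=haps.population.copy(),
        accessible=haps.accessible.copy(),
    )


# ---------------------------------------------------------------------------
# Hierarchical clustering (iHPlot backbone)
# ---------------------------------------------------------------------------

@dataclass
class HaplotypeClustering:
    """Dendrogram over haplotypes with annotations.

    ``order`` maps dendrogram leaf rank -> original haplotype index;
    ``distances`` is the symmetric Hamming-count matrix in original index
    space.  The input rows are canonicalised (lexicographic sort) before
    clustering so the result is invariant to input row permutation.
    """

    linkage: np.ndarray
    order: np.ndarray
    distances: np.ndarray
    haps: HaplotypeSet
    canonical: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    @property
    def leaf_orientations(self) -> np.ndarray:
        return self.haps.orientation[self.order]


def cluster_haplotypes(haps: HaplotypeSet,
                       linkage_method: str = "complete") -> HaplotypeClustering:
    """Deterministic hierarchical clustering by Hamming distance.

    Distances count differing alleles over accessible sites.  Ties are
    broken by the canonical (lexicographic) haplotype order, so the leaf
    order is a pure function of the haplotype contents.
    """
    if linkage_method not in ("complete", "average"):
        raise InvpopkitError("linkage_method must be 'complete' or 'average'")
    if haps.n_haplotypes < 3 or haps.n_sites < 1:
        raise InvpopkitError("need at least 3 haplotypes and 1 variant")
    acc = haps.accessible.astype(bool)
    mat = haps.haplotypes[:, acc]

    keys = ["".join(map(str, row)) for row in mat]
    canonical = np.array(
        sorted(range(len(keys)), key=lambda i: (keys[i], str(haps.sample_id[i]))),
        dtype=int,
    )
    sorted_mat = mat[canonical]
    condensed = pdist(sorted_mat, metric="hamming") * mat.shape[1]
    z = sch.linkage(condensed, method=linkage_method)
    leaves = sch.leaves_list(z)
    order = canonical[leaves]
    dist = squareform(pdist(mat, metric="hamming") * mat.shape[1])
    return HaplotypeClustering(linkage=z, order=order, distances=dist,
                               haps=haps, canonical=canonical)


# ---------------------------------------------------------------------------
# Small parsimony (Sankoff DP, exact on any rooted tree)
# ---------------------------------------------------------------------------

def _sankoff(node, states, state_of_tip):
    """Min change counts per state for the subtree at ``node``."""
    children = node.child_nodes()
    if not children:
        s = state_of_tip(node)
        return {x: (0 if x == s else np.inf) for x in states}
    cost = {x: 0.0 for x in states}
    for child in children:
        sub = _sankoff(child, states, state_of_tip)
        for x in states:
            cost[x] += min(sub[y] + (0 if x == y else 1) for y in states)
    return cost


def fitch_parsimony_events(tree: dendropy.Tree, tip_states: dict[str, str],
                           root_state: str | None = None) -> int:
    """Minimum number of state changes explaining the tip states.

    Exact small parsimony (dynamic programming over the rooted tree, valid
    for multifurcations); if ``root_state`` is given, the count is
    conditioned on that root state.  Tips missing from ``tip_states`` are
    dropped with a warning; an effectively empty tree is an error.
    """
    states = sorted(set(tip_states.values()) | ({root_state} if root_state else set()))
    if not states:
        raise InvpopkitError("no tip states supplied")

    missing = [l.taxon.label for l in tree.leaf_node_iter()
               if l.taxon.label not in tip_states]
    work = tree
    if missing:
        logger.warning("dropping %d tips without states", len(missing))
        work = tree.clone(depth=1)
        keep = [t for t in work.taxon_namespace if t.label in tip_states]
        if not keep:
            raise InvpopkitError("no tips with states remain")
        work.retain_taxa(keep)

    if not work.seed_node.child_nodes() and work.seed_node.taxon is None:
        raise InvpopkitError("empty tree")

    cost = _sankoff(work.seed_node, states,
                    lambda n: tip_states[n.taxon.label])
    if root_state is not None:
        value = cost[root_state]
    else:
        value = min(cost.values())
    if not np.isfinite(value):
        raise InvpopkitError("no consistent labeling found")
    return int(value)


def total_branch_generations(tree: dendropy.Tree) -> float:
    """Sum of branch lengths (assumed to be in generations)."""
    return float(sum(e.length or 0.0 for e in tree.preorder_edge_iter()))


def inversion_rate(events: int, total_branch_generations: float,
                   alpha: float = 0.05) -> dict:
    """Events per generation along a genealogy, with a Poisson exact CI."""
    if total_branch_generations <= 0:
        raise InvpopkitError("total branch length must be > 0")
    rate = events / total_branch_generations
    lo = 0.0 if events == 0 else chi2.ppf(alpha / 2, 2 * events) / 2
    hi = chi2.ppf(1 - alpha / 2, 2 * events + 2) / 2
    return {
        "rate": rate,
        "ci_low": lo / total_branch_generations,
        "ci_high": hi / total_branch_generations,
        "events": events,
        "generations": total_branch_generations,
    }


# ---------------------------------------------------------------------------
# Recurrence estimation from the dendrogram
# ---------------------------------------------------------------------------

@dataclass
class RecurrenceEstimate:
    """Minimum inversion/re-inversion event count beyond the original."""

    n_events: int
    n_state_changes: int
    clusters: list[dict]
    n_reassigned: int
    by_group: dict[str, int]


def _dendrogram_tree(clust: HaplotypeClustering) -> tuple[dendropy.Tree, list[str]]:
    """Convert a scipy linkage matrix into a rooted dendropy tree whose tip
    labels are original haplotype indices (as strings)."""
    n = clust.linkage.shape[0] + 1
    taxa = dendropy.TaxonNamespace([str(i) for i in range(n)])
    nodes = {}
    for i in range(n):
        orig = clust.canonical[i]
        node = dendropy.Node(taxon=taxa.get_taxon(str(orig)))
        nodes[i] = node
    for row_idx, (a, b, height, _) in enumerate(clust.linkage):
        parent = dendropy.Node()
        parent.add_child(nodes[int(a)])
        parent.add_child(nodes[int(b)])
        nodes[n + row_idx] = parent
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.seed_node = nodes[n + clust.linkage.shape[0] - 1]
    return tree, [str(i) for i in range(n)]


def _heterokaryotype_haplotypes(haps: HaplotypeSet) -> np.ndarray:
    """Mask of haplotypes whose sample carries both orientations."""
    het = np.zeros(haps.n_haplotypes, dtype=bool)
    for sample in np.unique(haps.sample_id):
        idx = np.flatnonzero(haps.sample_id == sample)
        labels = {haps.orientation[i] for i in idx} - {"unknown"}
        if labels == {"O1", "O2"}:
            het[idx] = True
    return het


def estimate_recurrence(clust: HaplotypeClustering, min_support: int = 1,
                        max_error_diff: int = 2) -> RecurrenceEstimate:
    """Minimum orientation events on the haplotype dendrogram.

    1. Haplotypes from inversion-heterozygous samples lying within
       ``max_error_diff`` Hamming distance of an opposite-orientation
       haplotype are reassigned as putative phasing errors (this step can
       only relabel haplotypes of heterokaryotypes).
    2. The minimum number of orientation state changes on the dendrogram is
       computed by small parsimony over labeled leaves.
    3. ``events = changes - 1``: the original inversion event is not
       recurrence.  Supporting clusters (maximal same-orientation subtrees
       introduced by a change) are reported with their sizes and population
       composition; clusters smaller than ``min_support`` are flagged.
    """
    haps = clust.haps
    labeled_mask = haps.orientation != "unknown"
    if not labeled_mask.any():
        raise InvpopkitError("no labeled haplotypes")
    orientation = haps.orientation.copy()

    het = _heterokaryotype_haplotypes(haps)
    n_reassigned = 0
    dist = clust.distances
    original = haps.orientation  # reassignments judged against input labels
    for h in np.flatnonzero(labeled_mask & het):
        opp = np.flatnonzero(labeled_mask & (original != original[h])
                             & (original != "unknown"))
        same = np.flatnonzero(labeled_mask & (original == original[h]))
        opp, same = opp[opp != h], same[same != h]
        if not len(opp):
            continue
        d_opp = dist[h, opp].min()
        d_same = dist[h, same].min() if len(same) else np.inf
        # a switch-error haplotype sits closer to the opposite orientation
        # than to its own; identical haplotypes in both orientations
        # (d_opp == d_same == 0) are genuine recurrence evidence, not errors
        if d_opp <= max_error_diff and d_opp < d_same:
            orientation[h] = "O1" if original[h] == "O2" else "O2"
            n_reassigned += 1

    tree, _ = _dendrogram_tree(clust)
    tip_states = {
        str(i): orientation[i]
        for i in range(haps.n_haplotypes)
        if orientation[i] != "unknown"
    }
    if len(set(tip_states.values())) < 2:
        changes = 0
    else:
        changes = fitch_parsimony_events(tree, tip_states)

    clusters = _event_clusters(tree, tip_states, haps)
    by_group = {"global": 0, "african": 0, "non_african": 0}
    # the largest cluster of each orientation is taken as that orientation's
    # founding background; every other cluster is an additional event
    extra = _additional_clusters(clusters)
    for c in extra:
        by_group[c["group_class"]] += 1
    n_events = max(changes - 1, 0)
    return RecurrenceEstimate(
        n_events=n_events,
        n_state_changes=changes,
        clusters=clusters,
        n_reassigned=n_reassigned,
        by_group=by_group,
    )


def _additional_clusters(clusters: list[dict]) -> list[dict]:
    """Clusters counted as additional events: drop the root background and
    the largest remaining cluster (the orientation's founding event)."""
    extra = clusters[1:]
    if not extra:
        return []
    largest = max(range(len(extra)), key=lambda i: extra[i]["size"])
    return [c for i, c in enumerate(extra) if i != largest]


def _event_clusters(tree, tip_states, haps) -> list[dict]:
    """Maximal same-orientation leaf groups under one parsimony labeling.

    Labels internal nodes top-down from the Sankoff tables (parent-state
    preference on ties) and collects, for the orientation with fewer
    founding clusters, each maximal subtree of constant state.
    """
    states = sorted(set(tip_states.values()))
    if len(states) < 2:
        return []

    costs = {}

    def down(node):
        children = node.child_nodes()
        if not children:
            s = tip_states.get(node.taxon.label)
            costs[id(node)] = {x: (0 if x == s else np.inf) for x in states}
            return costs[id(node)]
        c = {x: 0.0 for x in states}
        for child in children:
            sub = down(child)
            for x in states:
                c[x] += min(sub[y] + (0 if x == y else 1) for y in states)
        costs[id(node)] = c
        return c

    root_cost = down(tree.seed_node)
    root_state = min(states, key=lambda s: root_cost[s])

    assignment = {}

    def up(node, parent_state):
        c = costs[id(node)]
        best = min(c[s] for s in states)
        # keep the parent state on ties, otherwise take the cheapest state
        if c[parent_state] == best:
            state = parent_state
        else:
            state = min(s for s in states if c[s] == best)
        assignment[id(node)] = state
        for child in node.child_nodes():
            up(child, state)

    up(tree.seed_node, root_state)

    clusters = []

    def collect(node, parent_state):
        state = assignment[id(node)]
        if state != parent_state:
            members = [int(l.taxon.label) for l in node.leaf_iter()
                       if assignment[id(l)] == state]
            if members:
                groups = set()
                for m in members:
                    pop = str(haps.population[m])
                    groups.add("AFR" if pop.upper().startswith(("AFR", "YRI", "LWK"))
                               else "nonAFR")
                group_class = ("global" if groups == {"AFR", "nonAFR"}
                               else ("african" if groups == {"AFR"} else "non_african"))
                clusters.append(
                    {
                        "orientation": state,
                        "size": len(members),
                        "members": members,
                        "group_class": group_class,
                    }
                )
        for child in node.child_nodes():
            collect(child, state)

    collect(tree.seed_node, root_state)
    # the root's own background is also a cluster (state == root_state)
    root_members = [int(l.taxon.label) for l in tree.seed_node.leaf_iter()
                    if assignment[id(l)] == root_state]
    if root_members:
        clusters.insert(0, {
            "orientation": root_state,
            "size": len(root_members),
            "members": root_members,
            "group_class": "global",
        })
    return clusters


# ---------------------------------------------------------------------------
# iHPlot rendering
# ---------------------------------------------------------------------------

def render_ihplot(clust: HaplotypeClustering, out) -> None:
    """Integrated haplotype plot: dendrogram + distance heatmap + allele
    matrix + orientation/population side bars, in dendrogram leaf order."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    order = clust.order
    haps = clust.haps
    n = len(order)

    fig, axes = plt.subplots(
        1, 4, figsize=(12, max(3, 0.25 * n)),
        gridspec_kw={"width_ratios": [2, 2, 4, 0.6]},
    )
    sch.dendrogram(clust.linkage, orientation="left", ax=axes[0],
                   no_labels=True, color_threshold=0, link_color_func=lambda _: "k")
    axes[0].set_title("clustering")

    axes[1].imshow(clust.distances[np.ix_(order, order)], cmap="viridis",
                   aspect="auto", interpolation="nearest")
    axes[1].set_title("distance")

    axes[2].imshow(haps.haplotypes[order][:, haps.accessible.astype(bool)],
                   cmap="Greys", aspect="auto", interpolation="nearest")
    axes[2].set_title("alleles")

    colors = {"O1": 0.0, "O2": 1.0, "unknown": 0.5}
    strip = np.array([[colors[o] for o in haps.orientation[order]]]).T
    axes[3].imshow(strip, cmap="coolwarm", aspect="auto",
                   interpolation="nearest", vmin=0, vmax=1)
    axes[3].set_title("orient.")
    for ax in axes[1:]:
        ax.set_yticks([])
    fig.tight_layout()
    fig.savefig(out, dpi=100)
    plt.close(fig)
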