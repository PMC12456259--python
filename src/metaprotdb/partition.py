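"""Sample hierarchy construction and size-budgeted database partitioning.

Pairwise assembly similarities (from :mod:`metaprotdb.sketching`) are turned
into a dendrogram by agglomerative clustering on distance ``1 - similarity``.
The tree is then cut top-down: any subtree whose pooled protein set fits the
database size budget becomes one sample group; oversized subtrees are
recursively split until every group fits, so more closely related samples
end up sharing a database. A single sample that alone exceeds the budget is
emitted as an overflow-flagged singleton.

The agglomeration is written out explicitly (rather than through
scipy.cluster.hierarchy) so that ties in the merge distance are broken
deterministically by the lexicographic order of each cluster's smallest
member id; scipy's linkage does not expose its tie-breaking. For the
single/complete/average linkages used here merge heights are monotone
non-decreasing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .models import ProteinRecord, SampleGroup
from .sketching import Sketch, containment

logger = logging.getLogger(__name__)

LINKAGES = ("single", "complete", "average")


@dataclass
class Dendrogram:
    """Binary merge tree over samples. Leaves carry ``sample_id``."""

    sample_id: str | None = None
    left: "Dendrogram | None" = None
    right: "Dendrogram | None" = None
    height: float = 0.0

    @property
    def is_leaf(self) -> bool:
        return self.sample_id is not None

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.sample_id]
        return self.left.leaves() + self.right.leaves()

    def merges(self) -> list[tuple[frozenset, frozenset, float]]:
        """Post-order list of (left leaves, right leaves, height)."""
        if self.is_leaf:
            return []
        out = self.left.merges() + self.right.merges()
        out.append(
            (frozenset(self.left.leaves()), frozenset(self.right.leaves()), self.height)
        )
        return out


# ---------------------------------------------------------------------------
# replicate merging


def merge_replicates(sample_to_replicates, per_replicate_records):
    """Pool replicate protein sets into per-sample sets.

    Technical/biological replicates of one sample are unioned before any
    database is built. Exact-duplicate sequences within a sample collapse
    to a single record (first-seen accession) whose origins are merged.
    """
    seen: dict[str, str] = {}
    for sample, reps in sample_to_replicates.items():
        for rep in reps:
            if rep in seen and seen[rep] != sample:
                raise ValueError(
                    f"replicate {rep!r} mapped to both {seen[rep]!r} and {sample!r}"
                )
            seen[rep] = sample

    out: dict[str, list[ProteinRecord]] = {}
    for sample, reps in sample_to_replicates.items():
        by_seq: dict[str, ProteinRecord] = {}
        order: list[str] = []
        for rep in reps:
            for rec in per_replicate_records.get(rep, []):
                if rec.sequence in by_seq:
                    kept = by_seq[rec.sequence]
                    by_seq[rec.sequence] = ProteinRecord(
                        accession=kept.accession,
                        sequence=kept.sequence,
                        category=kept.category,
                        origins=kept.origins | rec.origins,
                        merged_from=kept.merged_from + (rec.accession,),
                        description=kept.description,
                    )
                else:
                    by_seq[rec.sequence] = rec
                    order.append(rec.sequence)
        out[sample] = [by_seq[s] for s in order]
    return out


# ---------------------------------------------------------------------------
# tree building


def build_tree(sample_ids, similarity, linkage: str = "average") -> Dendrogram:
    """Agglomerate samples on distance ``1 - similarity``.

    ``similarity`` is a square matrix aligned with ``sample_ids``
    (symmetric, unit diagonal, values in [0, 1], no NaN). Ties in the
    minimum inter-cluster distance are broken by the lexicographically
    smallest member id of the candidate pair. Inter-cluster distances
    follow the Lance-Williams update for the configured linkage.
    """
    if linkage not in LINKAGES:
        raise ValueError(f"unknown linkage {linkage!r}")
    sample_ids = list(sample_ids)
    if len(set(sample_ids)) != len(sample_ids):
        raise ValueError("duplicate sample ids")
    sim = np.asarray(similarity, dtype=float)
    n = len(sample_ids)
    if sim.shape != (n, n):
        raise ValueError(f"similarity matrix shape {sim.shape} != ({n},{n})")
    if np.isnan(sim).any():
        raise ValueError("similarity matrix contains NaN")
    if not np.allclose(sim, sim.T, atol=1e-9):
        raise ValueError("similarity matrix is not symmetric")
    if not np.allclose(np.diag(sim), 1.0, atol=1e-9):
        raise ValueError("similarity matrix diagonal must be 1")
    if ((sim < -1e-9) | (sim > 1 + 1e-9)).any():
        raise ValueError("similarity values must lie in [0, 1]")
    if n == 0:
        raise ValueError("no samples")
    if n == 1:
        return Dendrogram(sample_id=sample_ids[0])

    dist = 1.0 - sim
    # active clusters: id -> (node, size, sorted member ids)
    clusters: dict[int, tuple[Dendrogram, int, list[str]]] = {
        i: (Dendrogram(sample_id=s), 1, [s]) for i, s in enumerate(sample_ids)
    }
    d: dict[frozenset, float] = {
        frozenset((i, j)): float(dist[i, j])
        for i in range(n)
        for j in range(i + 1, n)
    }
    next_id = n
    while len(clusters) > 1:

        def order_key(pair: frozenset):
            i, j = sorted(pair)
            lo, hi = sorted((clusters[i][2][0], clusters[j][2][0]))
            return (d[pair], lo, hi)

        best = min(d, key=order_key)
        a, b = sorted(best)
        height = d[best]
        node_a, size_a, mem_a = clusters.pop(a)
        node_b, size_b, mem_b = clusters.pop(b)
        if mem_a[0] <= mem_b[0]:
            merged = Dendrogram(left=node_a, right=node_b, height=height)
        else:
            merged = Dendrogram(left=node_b, right=node_a, height=height)

        for c, (_, size_c, _) in clusters.items():
            dac = d.pop(frozenset((a, c)))
            dbc = d.pop(frozenset((b, c)))
            if linkage == "single":
                dn = min(dac, dbc)
            elif linkage == "complete":
                dn = max(dac, dbc)
            else:  # average (UPGMA)
                dn = (dac * size_a + dbc * size_b) / (size_a + size_b)
            d[frozenset((next_id, c))] = dn
        del d[best]
        clusters[next_id] = (merged, size_a + size_b, sorted(mem_a + mem_b))
        next_id += 1

    (root, _, _) = next(iter(clusters.values()))
    return root


def similarity_matrix(sketches: list[Sketch], metric) -> np.ndarray:
    """Square sample-sample similarity matrix (unit diagonal)."""
    n = len(sketches)
    sim = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            sim[i, j] = sim[j, i] = metric(sketches[i], sketches[j])
    return sim


# ---------------------------------------------------------------------------
# budget partitioning


def partition_by_budget(
    tree: Dendrogram, size_estimates, budget_bytes: int
) -> list[SampleGroup]:
    """Cut the dendrogram into groups whose pooled DB estimate fits the budget.

    Depth-first from the root: a subtree whose aggregate size estimate is
    at or under the budget is emitted whole; otherwise both children are
    visited. A single sample over budget on its own becomes an
    overflow-flagged singleton (with a warning), so the traversal always
    terminates with a complete partition of the samples.
    """
    if tree is None:
        raise ValueError("empty tree")
    missing = [s for s in tree.leaves() if s not in size_estimates]
    if missing:
        raise ValueError(f"no size estimate for sample(s) {missing}")

    groups: list[SampleGroup] = []

    def visit(node: Dendrogram) -> None:
        leaves = node.leaves()
        agg = sum(size_estimates[s] for s in leaves)
        if agg <= budget_bytes:
            groups.append(
                SampleGroup(
                    group_id="",
                    sample_ids=frozenset(leaves),
                    estimated_db_bytes=int(agg),
                    overflow_flag=False,
                )
            )
        elif node.is_leaf:
            logger.warning(
                "sample %s alone exceeds budget (%d > %d bytes); "
                "emitting overflow singleton",
                node.sample_id,
                agg,
                budget_bytes,
            )
            groups.append(
                SampleGroup(
                    group_id="",
                    sample_ids=frozenset(leaves),
                    estimated_db_bytes=int(agg),
                    overflow_flag=True,
                )
            )
        else:
            visit(node.left)
            visit(node.right)

    visit(tree)
    for i, g in enumerate(groups, start=1):
        g.group_id = f"group{i:03d}"
    return groups


# ---------------------------------------------------------------------------
# catalogue matching


def match_catalogue(
    sample_sketches: list[Sketch],
    catalogue_sketches: list[Sketch],
    containment_threshold: float,
) -> set[str]:
    """Catalogue genomes contained (at the threshold) in any sample assembly.

    A genome is selected iff the maximum over samples of
    ``containment(genome, sample)`` reaches the threshold. With an empty
    catalogue the result is empty. At threshold 0, genomes sharing no
    hash with any sample are still excluded (their containment is 0 only
    vacuously; selection requires at least one shared hash).
    """
    selected: set[str] = set()
    for genome in catalogue_sketches:
        best = 0.0
        shared = False
        for sample in sample_sketches:
            c = containment(genome, sample)
            shared = shared or bool(genome.hashes & sample.hashes)
            best = max(best, c)
        if best >= containment_threshold and shared:
            selected.add(genome.name)
    return selected
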