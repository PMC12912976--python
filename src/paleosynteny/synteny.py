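"""Collinear synteny-block detection, syntenic depth, and microsynteny clusters.

The chaining step is a greedy best-chain-first decomposition: within
each (query chromosome, target chromosome) cell the highest-scoring
collinear chain (score = anchor count) is extracted by dynamic
programming, its anchors and any anchors sharing one of its genes are
removed from the pool (so tandem-array anchors compete), and the
search repeats until no chain reaches ``block_size``.  Anchors in a
chain are strictly monotone in both genomes — increasing in the target
for '+' blocks, decreasing for '-' — and consecutive anchors may skip
at most ``gap_size`` gene ranks on either side.
"""

from __future__ import annotations

import itertools
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist

from .io import AnchorPair, GenomeAnnotation, ValidationError

__all__ = [
    "ChainParams",
    "AnchorHit",
    "SyntenyBlock",
    "SyntenyCluster",
    "chain_anchors",
    "syntenic_depth",
    "syntenic_gene_pairs",
    "build_clusters",
    "phylogenomic_profile",
    "shared_cluster_counts",
    "blocks_frame",
]


@dataclass(frozen=True)
class ChainParams:
    block_size: int = 5   # minimum anchors per retained block
    gap_size: int = 5     # max gene ranks skipped between consecutive anchors
    exact_limit: int = 12  # cells up to this many anchors get an exact decomposition

    def __post_init__(self):
        if self.block_size < 2:
            raise ValidationError("block_size must be >= 2")
        if self.gap_size < 1:
            raise ValidationError("gap_size must be >= 1")


class AnchorHit(NamedTuple):
    gene_a: str
    gene_b: str
    q_rank: int
    t_rank: int


@dataclass
class SyntenyBlock:
    block_id: str
    query_chrom: str
    target_chrom: str
    orientation: str          # '+' or '-'
    anchors: list             # AnchorHit, ordered by query rank
    q_start: int
    q_end: int
    t_start: int
    t_end: int

    @property
    def n_anchors(self) -> int:
        return len(self.anchors)


def _best_chain(q: np.ndarray, t: np.ndarray, orientation: str, gap: int):
    """Longest valid chain by DP; deterministic first-argmax tie-break.

    ``q``/``t`` must be pre-sorted by (q, t) for '+' and (q, -t) for '-'.
    Returns (indices into the arrays, length).
    """
    n = len(q)
    L = np.ones(n, dtype=int)
    pred = np.full(n, -1, dtype=int)
    step = gap + 1  # a gap of g skipped genes is a rank difference of g+1
    for i in range(1, n):
        dq = q[i] - q[:i]
        dt = (t[i] - t[:i]) if orientation == "+" else (t[:i] - t[i])
        ok = (dq >= 1) & (dq <= step) & (dt >= 1) & (dt <= step)
        if ok.any():
            cand = np.where(ok, L[:i], 0)
            j = int(np.argmax(cand))
            if cand[j] > 0:
                L[i] = cand[j] + 1
                pred[i] = j
    end = int(np.argmax(L))
    chain = []
    i = end
    while i != -1:
        chain.append(i)
        i = pred[i]
    chain.reverse()
    return chain, int(L[end])


def _chain_ok(hits, gap_size):
    """Validity of a candidate chain (both monotonicity directions allowed)."""
    hits = sorted(hits, key=lambda h: h.q_rank)
    step = gap_size + 1
    qs = [h.q_rank for h in hits]
    ts = [h.t_rank for h in hits]
    if len(set(qs)) != len(qs) or len(set(ts)) != len(ts):
        return None
    if not all(1 <= b - a <= step for a, b in zip(qs, qs[1:])):
        return None
    if all(1 <= b - a <= step for a, b in zip(ts, ts[1:])):
        return "+"
    if all(1 <= a - b <= step for a, b in zip(ts, ts[1:])):
        return "-"
    return None


def _exact_cell(pool, params: ChainParams):
    """Optimal decomposition of a small cell: maximize total chained
    anchors over anchor-disjoint valid chains (branch and bound).

    Only used when no two anchors in the cell share a gene, so tandem
    competition cannot arise.  Deterministic: candidate chains are
    explored longest-first with positional tie-breaks and only strict
    improvements are kept.
    """
    n = len(pool)
    candidates = []
    for r in range(params.block_size, n + 1):
        for combo in itertools.combinations(range(n), r):
            orientation = _chain_ok([pool[i] for i in combo], params.gap_size)
            if orientation:
                hits = sorted((pool[i] for i in combo), key=lambda h: h.q_rank)
                candidates.append((frozenset(combo), orientation, hits))
    candidates.sort(key=lambda c: (-len(c[0]), c[2][0].q_rank, c[2][0].t_rank))
    best = {"total": 0, "picked": []}

    def dfs(idx, used, total, picked):
        if total > best["total"]:
            best["total"] = total
            best["picked"] = list(picked)
        if idx == len(candidates) or total + (n - len(used)) <= best["total"]:
            return
        for i in range(idx, len(candidates)):
            ids, orientation, hits = candidates[i]
            if not (ids & used):
                picked.append((orientation, hits))
                dfs(i + 1, used | ids, total + len(ids), picked)
                picked.pop()

    dfs(0, frozenset(), 0, [])
    return best["picked"]


def chain_anchors(
    anchors: Sequence[AnchorPair],
    query: GenomeAnnotation,
    target: GenomeAnnotation,
    params: ChainParams = ChainParams(),
) -> list:
    """Decompose anchors into collinear blocks.

    Cells with at most ``exact_limit`` anchors (and no gene shared by
    two anchors) are decomposed optimally; larger cells use the greedy
    best-chain-first heuristic with bounded-box tandem competition.
    """
    cells = defaultdict(list)
    seen = set()
    for a in anchors:
        key = (a.gene_a, a.gene_b)
        if key in seen:
            continue
        seen.add(key)
        qc, qr = query.chrom_of(a.gene_a), query.rank_of(a.gene_a)
        tc, tr = target.chrom_of(a.gene_b), target.rank_of(a.gene_b)
        cells[(qc, tc)].append(AnchorHit(a.gene_a, a.gene_b, qr, tr))

    blocks = []
    for (qc, tc) in sorted(cells):
        pool = cells[(qc, tc)]
        no_dups = (
            len({h.gene_a for h in pool}) == len(pool)
            and len({h.gene_b for h in pool}) == len(pool)
        )
        if len(pool) <= params.exact_limit and no_dups:
            for orientation, hits in _exact_cell(pool, params):
                blocks.append(
                    SyntenyBlock(
                        block_id="", query_chrom=qc, target_chrom=tc,
                        orientation=orientation, anchors=hits,
                        q_start=hits[0].q_rank, q_end=hits[-1].q_rank,
                        t_start=min(h.t_rank for h in hits),
                        t_end=max(h.t_rank for h in hits),
                    )
                )
            continue
        while len(pool) >= params.block_size:
            best = None  # (length, orient_pref, hits)
            for orientation in "+-":
                order = sorted(
                    range(len(pool)),
                    key=lambda i: (
                        pool[i].q_rank,
                        pool[i].t_rank if orientation == "+" else -pool[i].t_rank,
                    ),
                )
                q = np.array([pool[i].q_rank for i in order])
                t = np.array([pool[i].t_rank for i in order])
                chain, length = _best_chain(q, t, orientation, params.gap_size)
                hits = [pool[order[i]] for i in chain]
                key = (length, 0 if orientation == "+" else 1)
                if best is None or (key[0], -key[1]) > (best[0][0], -best[0][1]):
                    best = (key, orientation, hits)
            (length, _), orientation, hits = best
            if length < params.block_size:
                break
            blocks.append(
                SyntenyBlock(
                    block_id="",
                    query_chrom=qc,
                    target_chrom=tc,
                    orientation=orientation,
                    anchors=hits,
                    q_start=hits[0].q_rank,
                    q_end=hits[-1].q_rank,
                    t_start=min(h.t_rank for h in hits),
                    t_end=max(h.t_rank for h in hits),
                )
            )
            # Tandem-array competition: anchors sharing a gene with the
            # extracted chain are consumed, but only inside the chain's
            # bounding box — a genuine second homoeologous copy on the
            # same chromosome pair lies outside the box and must stay
            # chainable.
            used_a = {h.gene_a for h in hits}
            used_b = {h.gene_b for h in hits}
            q0, q1 = hits[0].q_rank, hits[-1].q_rank
            t_lo = min(h.t_rank for h in hits)
            t_hi = max(h.t_rank for h in hits)
            pool = [
                h for h in pool
                if not (
                    (h.gene_a in used_a or h.gene_b in used_b)
                    and q0 <= h.q_rank <= q1
                    and t_lo <= h.t_rank <= t_hi
                )
            ]

    blocks.sort(key=lambda b: (b.query_chrom, b.q_start, b.target_chrom, b.t_start))
    for i, b in enumerate(blocks, start=1):
        b.block_id = f"B{i:05d}"
    return blocks


def syntenic_depth(blocks: Iterable[SyntenyBlock], reference: GenomeAnnotation) -> pd.Series:
    """Per-reference-gene block coverage (blocks computed with reference as query).

    Depth counts *blocks*, and a block's span covers non-anchor genes
    inside it — the dot-plot notion of regional multiplicity.
    """
    depth = {c: np.zeros(reference.n_genes_on(c), dtype=int) for c in reference.chromosomes}
    for b in blocks:
        depth[b.query_chrom][b.q_start : b.q_end + 1] += 1
    out = {}
    for c in reference.chromosomes:
        for g, d in zip(reference.genes_on(c), depth[c]):
            out[g] = int(d)
    return pd.Series(out, name="depth", dtype=int)


def syntenic_gene_pairs(blocks: Iterable[SyntenyBlock]) -> list:
    """Deduplicated union of anchors inside retained blocks."""
    seen = {}
    for b in blocks:
        for h in b.anchors:
            seen.setdefault((h.gene_a, h.gene_b), AnchorPair(h.gene_a, h.gene_b))
    return [seen[k] for k in sorted(seen)]


@dataclass
class SyntenyCluster:
    cluster_id: str
    members: frozenset            # of (species, gene_id)
    copy_number: dict = field(default_factory=dict)

    @property
    def species(self) -> set:
        return set(self.copy_number)


def build_clusters(
    pairs: Iterable[AnchorPair],
    species_of: Mapping[str, str],
    min_species: int = 2,
) -> list:
    """Microsynteny clusters = connected components of the syntenic-pair graph.

    ``species_of`` maps every gene id to its species; components
    spanning fewer than ``min_species`` species are dropped.
    """
    g = nx.Graph()
    for p in pairs:
        g.add_edge(p.gene_a, p.gene_b)
    comps = []
    for comp in nx.connected_components(g):
        members = frozenset((species_of[m], m) for m in comp)
        cn = Counter(sp for sp, _ in members)
        if len(cn) < min_species:
            continue
        comps.append((tuple(sorted(m for _, m in members)), members, dict(cn)))
    comps.sort(key=lambda c: c[0])
    return [
        SyntenyCluster(f"C{i:05d}", members, cn)
        for i, (_, members, cn) in enumerate(comps, start=1)
    ]


def phylogenomic_profile(clusters: Sequence[SyntenyCluster], species_order: Sequence[str]):
    """Copy-number matrix (species x clusters) with columns ordered by
    average-linkage hierarchical clustering on Euclidean distance."""
    if not clusters:
        raise ValidationError("phylogenomic_profile needs at least one cluster")
    clusters = sorted(clusters, key=lambda c: c.cluster_id)
    mat = pd.DataFrame(
        {c.cluster_id: [c.copy_number.get(sp, 0) for sp in species_order] for c in clusters},
        index=list(species_order),
    )
    if mat.shape[1] > 2:
        z = linkage(pdist(mat.T.values.astype(float)), method="average")
        order = [mat.columns[i] for i in leaves_list(z)]
    else:
        order = list(mat.columns)
    return mat[order], order


def shared_cluster_counts(
    clusters: Iterable[SyntenyCluster], clade_of: Mapping[str, str]
) -> dict:
    """Count clusters by the exact set of clades they span.

    Keys are sorted clade tuples; a cluster found in exactly one clade
    is that clade's lineage-specific count, and the full-clade tuple is
    the conserved count.
    """
    counts: Counter = Counter()
    for c in clusters:
        clades = set()
        for sp in c.species:
            if sp not in clade_of:
                raise ValidationError(f"species {sp!r} has no clade assignment")
            clades.add(clade_of[sp])
        counts[tuple(sorted(clades))] += 1
    return dict(counts)


def blocks_frame(blocks: Iterable[SyntenyBlock]) -> pd.DataFrame:
    """Tabular export of blocks (the riparian-ribbon data)."""
    return pd.DataFrame(
        [
            dict(
                block_id=b.block_id,
                query_chrom=b.query_chrom,
                q_start_rank=b.q_start,
                q_end_rank=b.q_end,
                target_chrom=b.target_chrom,
                t_start_rank=b.t_start,
                t_end_rank=b.t_end,
                orientation=b.orientation,
                n_anchors=b.n_anchors,
            )
            for b in blocks
        ],
        columns=[
            "block_id", "query_chrom", "q_start_rank", "q_end_rank",
            "target_chrom", "t_start_rank", "t_end_rank", "orientation", "n_anchors",
        ],
    )
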