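"""Whole-paranome inference: bit-score normalization and Markov clustering.

Raw bit-scores grow with gene length irrespective of similarity, which
biases graph-based family clustering. The correction fits an ordinary
least-squares regression of log10(bitscore) on log10(proxy length) over the
top-scoring hits of equal-count proxy-length bins, and divides each
bit-score by its regression-expected value. Families are then obtained with
the Markov Cluster algorithm (expansion by matrix squaring, inflation by
entrywise powers) on the normalized-score graph.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .formats import Hit


@dataclass
class NormalizationFit:
    """OLS fit of log10 bitscore on log10 proxy length over upper-bin hits."""

    n_bins: int
    top_percent: float
    slope: float
    intercept: float
    r_squared_upper: float
    r_squared_all_before: float
    r_squared_all_after: float
    skipped: bool = False


@dataclass
class GeneFamily:
    family_id: str
    members: frozenset[str]
    species_of: dict[str, str] = field(default_factory=dict)

    @property
    def is_singleton(self) -> bool:
        return len(self.members) == 1


def _ols_r2(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Return (slope, intercept, R^2) of y on x."""
    if len(x) < 2 or np.ptp(x) == 0:
        return 0.0, float(np.mean(y)), 0.0
    slope, intercept = np.polyfit(x, y, 1)
    pred = slope * x + intercept
    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return float(slope), float(intercept), r2


def normalize_bitscores(hits: Sequence[Hit], n_bins: int = 100,
                        top_percent: float = 5.0) -> tuple[list[Hit], NormalizationFit]:
    """Remove gene-length bias from bit-scores.

    Hits are sorted by proxy length and split into ``n_bins`` equal-count
    bins (remainder spread over the leading bins); within each bin the top
    ceil(top_percent% x bin size) hits by bit-score (at least one) enter an
    OLS regression of log10(bitscore) on log10(proxy_len). Each hit's
    ``norm_score`` is its bit-score divided by the regression expectation.
    """
    if not hits:
        raise ValueError("no hits to normalize")
    if not (0 < top_percent <= 100):
        raise ValueError("top_percent must lie in (0, 100]")
    hits = list(hits)
    log_len = np.log10([h.proxy_len for h in hits])
    log_score = np.log10([h.bitscore for h in hits])
    _, _, r2_before = _ols_r2(log_len, log_score)

    if len(set(h.proxy_len for h in hits)) < 2:
        warnings.warn("all hits share one proxy length; normalization skipped, "
                      "scores scaled by their geometric mean")
        gm = float(np.exp(np.mean(np.log([h.bitscore for h in hits]))))
        for h in hits:
            h.norm_score = h.bitscore / gm
        fit = NormalizationFit(n_bins=n_bins, top_percent=top_percent, slope=0.0,
                               intercept=float(np.log10(gm)), r_squared_upper=0.0,
                               r_squared_all_before=r2_before,
                               r_squared_all_after=0.0, skipped=True)
        return hits, fit

    if n_bins > len(hits):
        warnings.warn(f"n_bins {n_bins} exceeds hit count {len(hits)}; clamped")
        n_bins = len(hits)
    order = np.argsort([h.proxy_len for h in hits], kind="stable")
    sel_idx: list[int] = []
    for bin_idx in np.array_split(order, n_bins):
        k = max(1, int(np.ceil(top_percent / 100.0 * len(bin_idx))))
        top = sorted(bin_idx, key=lambda i: hits[i].bitscore, reverse=True)[:k]
        sel_idx.extend(top)
    sel = np.array(sel_idx)
    slope, intercept, r2_upper = _ols_r2(log_len[sel], log_score[sel])
    expected = 10.0 ** (intercept + slope * log_len)
    for h, e in zip(hits, expected):
        h.norm_score = h.bitscore / float(e)
    _, _, r2_after = _ols_r2(log_len, np.log10([h.norm_score for h in hits]))
    fit = NormalizationFit(n_bins=n_bins, top_percent=top_percent, slope=slope,
                           intercept=intercept, r_squared_upper=r2_upper,
                           r_squared_all_before=r2_before,
                           r_squared_all_after=r2_after)
    return hits, fit


def hits_to_edges(hits: Iterable[Hit], use_norm: bool = True,
                  evalue_cutoff: float | None = 1e-10
                  ) -> dict[tuple[str, str], float]:
    """Collapse hits to undirected edges; multiple rows keep the max score."""
    edges: dict[tuple[str, str], float] = {}
    for h in hits:
        if evalue_cutoff is not None and h.evalue > evalue_cutoff:
            continue
        w = h.norm_score if (use_norm and h.norm_score is not None) else h.bitscore
        key = (min(h.query, h.target), max(h.query, h.target))
        if key[0] == key[1]:
            continue
        edges[key] = max(edges.get(key, 0.0), float(w))
    return edges


def markov_cluster(edges: Mapping[tuple[str, str], float],
                   inflation: float = 2.0, max_iter: int = 100,
                   tol: float = 1e-6, prune: float = 1e-8,
                   nodes: Sequence[str] | None = None) -> list[GeneFamily]:
    """Markov clustering of a weighted gene-similarity graph.

    Builds a column-stochastic matrix from the symmetrized weights with
    self-loops set to each node's maximum incident weight, then alternates
    expansion (matrix squaring) and inflation (entrywise power ``inflation``
    followed by column renormalization) until the largest entry change drops
    below ``tol``. Clusters are read off as connected components of the
    converged matrix; every input gene lands in exactly one family.
    """
    if inflation <= 1:
        raise ValueError("inflation must be > 1")
    for (a, b), w in edges.items():
        if w < 0:
            raise ValueError(f"negative edge weight for ({a}, {b})")
    node_set = {g for pair in edges for g in pair}
    if nodes is not None:
        node_set |= set(nodes)
    names = sorted(node_set)
    if not names:
        return []
    idx = {g: i for i, g in enumerate(names)}
    n = len(names)
    m = np.zeros((n, n))
    for (a, b), w in edges.items():
        i, j = idx[a], idx[b]
        m[i, j] = m[j, i] = max(m[i, j], w)
    loop = m.max(axis=0)
    loop[loop == 0] = 1.0
    np.fill_diagonal(m, loop)
    m = m / m.sum(axis=0, keepdims=True)
    for _ in range(max_iter):
        prev = m
        m = m @ m
        m = np.power(m, inflation)
        m[m < prune] = 0.0
        colsum = m.sum(axis=0, keepdims=True)
        colsum[colsum == 0] = 1.0
        m = m / colsum
        if np.max(np.abs(m - prev)) < tol:
            break
    import networkx as nx
    g = nx.Graph()
    g.add_nodes_from(range(n))
    rows, cols = np.nonzero(m > prune)
    g.add_edges_from(zip(rows.tolist(), cols.tolist()))
    comps = [sorted(names[i] for i in comp) for comp in nx.connected_components(g)]
    comps.sort(key=lambda c: (-len(c), c[0]))
    return [GeneFamily(family_id=f"fam{i:05d}", members=frozenset(c))
            for i, c in enumerate(comps)]


def reciprocal_best_hits(hits: Iterable[Hit],
                         species_of: Mapping[str, str],
                         species_a: str, species_b: str) -> list[tuple[str, str]]:
    """Reciprocal best hits between two species.

    A pair (a, b) is returned iff b is a's best hit in species B and a is
    b's best hit in species A, by bit-score; ties prefer lower e-value, then
    the lexicographically smaller partner id.
    """
    best_ab: dict[str, tuple] = {}
    best_ba: dict[str, tuple] = {}

    def consider(table, gene, partner, h):
        key = (-h.bitscore, h.evalue, partner)
        if gene not in table or key < table[gene][0]:
            table[gene] = (key, partner)

    for h in hits:
        for g1, g2 in ((h.query, h.target), (h.target, h.query)):
            s1, s2 = species_of.get(g1), species_of.get(g2)
            if s1 == species_a and s2 == species_b:
                consider(best_ab, g1, g2, h)
            elif s1 == species_b and s2 == species_a:
                consider(best_ba, g1, g2, h)
    pairs = []
    for a, (_, b) in best_ab.items():
        if best_ba.get(b, (None, None))[1] == a:
            pairs.append((a, b))
    return sorted(pairs)


@dataclass
class Orthogroup:
    """An anchor pair plus its RBH partners in other species, for dating."""

    group_id: str
    focal_pair: tuple[str, str]
    members_by_species: dict[str, list[str]]

    @property
    def members(self) -> list[str]:
        out = list(self.focal_pair)
        for sp in sorted(self.members_by_species):
            out.extend(self.members_by_species[sp])
        return out


def assemble_dating_orthogroups(anchor_pairs: Iterable[tuple[str, str]],
                                rbh_sets: Mapping[str, Iterable[tuple[str, str]]],
                                max_missing: int = 0) -> list[Orthogroup]:
    """One orthogroup per anchor pair: the two focal paralogs plus, for each
    other species, the RBH partner(s) of either paralog. Groups missing more
    than ``max_missing`` species are dropped (default: all required)."""
    rbh_of: dict[str, dict[str, list[str]]] = {}
    for sp, pairs in rbh_sets.items():
        table: dict[str, list[str]] = {}
        for focal_gene, other_gene in pairs:
            table.setdefault(focal_gene, []).append(other_gene)
        rbh_of[sp] = table
    groups = []
    for i, (a, b) in enumerate(sorted(anchor_pairs)):
        by_sp: dict[str, list[str]] = {}
        missing = 0
        for sp in sorted(rbh_sets):
            partners = sorted(set(rbh_of[sp].get(a, []) + rbh_of[sp].get(b, [])))
            if partners:
                by_sp[sp] = partners
            else:
                missing += 1
        if missing > max_missing:
            continue
        groups.append(Orthogroup(group_id=f"og{i:05d}", focal_pair=(a, b),
                                 members_by_species=by_sp))
    return groups
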