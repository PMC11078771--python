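"""Collinear-segment detection and synteny summaries.

Homeologous segments ("multiplicons") are found by gap-bounded diagonal
chaining of homologous gene pairs in rank space: within each chromosome
pair, matches are chained when both rank increments stay within ``max_gap``
(ascending or descending on the second axis). Gene pairs that survive in a
chain of at least ``min_genes`` anchors, spanning at least ``min_length_bp``
on both regions, are anchor pairs — duplicates born in a large-scale
(typically WGD) event. Summaries: per-chromosome stacked segment intervals
("dupStack"), multiplication-level counts ("syndepth"), and homology
dot-plot tables.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .formats import GeneLocus, SequenceRecord
from . import ksdist


@dataclass
class CollinearSegment:
    """A chained run of anchor pairs between two genomic regions."""

    segment_id: str
    region_a: tuple[str, int, int]  # (chromosome, start_rank, end_rank) inclusive
    region_b: tuple[str, int, int]
    anchors: list[tuple[str, str]]
    span_bp_a: int = 0
    span_bp_b: int = 0
    intra: bool = True

    @property
    def n_anchors(self) -> int:
        return len(self.anchors)


@dataclass
class SyndepthProfile:
    """Counts of homeologous-segment groups per multiplication level."""

    counts: dict[int, int]
    scope: str = "intra"


def _index(loci: Sequence[GeneLocus]) -> dict[str, GeneLocus]:
    return {l.gene_id: l for l in loci}


def _chain_matches(matches: list[tuple[int, int, str, str]], max_gap: int,
                   descending: bool) -> list[list[tuple[int, int, str, str]]]:
    """Longest-chain extraction among rank matches for one orientation.

    A match j can follow i when 1 <= ra_j - ra_i <= max_gap and the rank
    step on the second axis lies in [1, max_gap] (or [-max_gap, -1] for
    inverted blocks). Chains are peeled off longest-first.
    """
    ms = sorted(matches)
    n = len(ms)
    dp = [1] * n
    pred = [-1] * n
    for j in range(n):
        for i in range(j):
            dra = ms[j][0] - ms[i][0]
            drb = ms[j][1] - ms[i][1]
            if not (1 <= dra <= max_gap):
                continue
            ok = (-max_gap <= drb <= -1) if descending else (1 <= drb <= max_gap)
            if ok and dp[i] + 1 > dp[j]:
                dp[j] = dp[i] + 1
                pred[j] = i
    used = [False] * n
    chains = []
    for j in sorted(range(n), key=lambda j: -dp[j]):
        if used[j]:
            continue
        chain = []
        k = j
        while k != -1 and not used[k]:
            chain.append(ms[k])
            used[k] = True
            k = pred[k]
        chains.append(chain[::-1])
    return chains


def detect_segments(loci_a: Sequence[GeneLocus], loci_b: Sequence[GeneLocus],
                    homolog_pairs: Iterable[tuple[str, str]],
                    max_gap: int = 25, min_genes: int = 3,
                    min_length_bp: int = 100_000,
                    intra: bool | None = None) -> list[CollinearSegment]:
    """Detect collinear segments from gene order and homology.

    ``homolog_pairs`` are (gene in a, gene in b). For intra-genome searches
    pass the same loci twice; self-pairs and tandem pairs (both genes within
    ``max_gap`` ranks on one chromosome) are excluded, and each relation is
    considered in one orientation only.
    """
    idx_a, idx_b = _index(loci_a), _index(loci_b)
    if intra is None:
        intra = {l.gene_id for l in loci_a} == {l.gene_id for l in loci_b}
    by_chrom: dict[tuple[str, str], list[tuple[int, int, str, str]]] = {}
    seen: set[tuple[str, str]] = set()
    for ga, gb in homolog_pairs:
        if ga == gb:
            continue
        if ga not in idx_a or gb not in idx_b:
            continue
        la, lb = idx_a[ga], idx_b[gb]
        if intra:
            # one orientation per unordered pair, and no tandem arrays
            if (la.chromosome, la.rank) > (lb.chromosome, lb.rank):
                la, lb = lb, la
                ga, gb = gb, ga
            if la.chromosome == lb.chromosome and abs(la.rank - lb.rank) <= max_gap:
                continue
        if (ga, gb) in seen:
            continue
        seen.add((ga, gb))
        by_chrom.setdefault((la.chromosome, lb.chromosome), []).append(
            (la.rank, lb.rank, ga, gb))

    segments: list[CollinearSegment] = []
    for (ca, cb), matches in sorted(by_chrom.items()):
        for descending in (False, True):
            for chain in _chain_matches(matches, max_gap, descending):
                if len(chain) < min_genes:
                    continue
                ranks_a = [m[0] for m in chain]
                ranks_b = [m[1] for m in chain]
                genes_a = [m[2] for m in chain]
                genes_b = [m[3] for m in chain]
                span_a = (max(idx_a[g].end for g in genes_a) -
                          min(idx_a[g].start for g in genes_a))
                span_b = (max(idx_b[g].end for g in genes_b) -
                          min(idx_b[g].start for g in genes_b))
                if span_a < min_length_bp or span_b < min_length_bp:
                    continue
                segments.append(CollinearSegment(
                    segment_id="",
                    region_a=(ca, min(ranks_a), max(ranks_a)),
                    region_b=(cb, min(ranks_b), max(ranks_b)),
                    anchors=list(zip(genes_a, genes_b)),
                    span_bp_a=span_a, span_bp_b=span_b, intra=intra))

    segments = _remove_redundant(segments)
    segments.sort(key=lambda s: (-s.n_anchors, s.region_a, s.region_b))
    for i, seg in enumerate(segments):
        seg.segment_id = f"seg{i:04d}"
    return segments


def _remove_redundant(segments: list[CollinearSegment],
                      overlap: float = 0.5) -> list[CollinearSegment]:
    """Drop segments whose anchor set overlaps a larger one by >= ``overlap``."""
    kept: list[CollinearSegment] = []
    for seg in sorted(segments, key=lambda s: (-s.n_anchors, s.region_a, s.region_b)):
        anchors = {frozenset(p) for p in seg.anchors}
        redundant = False
        for other in kept:
            oa = {frozenset(p) for p in other.anchors}
            if len(anchors & oa) >= overlap * min(len(anchors), len(oa)):
                redundant = True
                break
        if not redundant:
            kept.append(seg)
    return kept


def dupstack(segments: Sequence[CollinearSegment],
             loci: Sequence[GeneLocus]) -> pd.DataFrame:
    """Per-chromosome stacked interval table of segment projections.

    Each segment contributes one bp interval on each chromosome it touches;
    intervals are packed into non-overlapping lanes, longest first.
    """
    idx = _index(loci)
    rank_bp: dict[tuple[str, int], tuple[int, int]] = {
        (l.chromosome, l.rank): (l.start, l.end) for l in loci}
    rows = []
    for seg in segments:
        for region, span in ((seg.region_a, seg.span_bp_a), (seg.region_b, seg.span_bp_b)):
            chrom, r0, r1 = region
            if (chrom, r0) not in rank_bp:
                continue
            start = rank_bp[(chrom, r0)][0]
            end = rank_bp[(chrom, r1)][1]
            rows.append({"chromosome": chrom, "start": start, "end": end,
                         "segment_id": seg.segment_id,
                         "scope": "intra" if seg.intra else "inter"})
    df = pd.DataFrame(rows, columns=["chromosome", "start", "end", "segment_id", "scope"])
    lanes = []
    for chrom, grp in df.groupby("chromosome", sort=True):
        occupied: list[list[tuple[int, int]]] = []
        order = grp.assign(length=grp.end - grp.start).sort_values(
            ["length", "start", "segment_id"], ascending=[False, True, True])
        for i, row in order.iterrows():
            lane = 0
            while lane < len(occupied) and any(
                    not (row.end <= s or row.start >= e) for s, e in occupied[lane]):
                lane += 1
            if lane == len(occupied):
                occupied.append([])
            occupied[lane].append((row.start, row.end))
            lanes.append((i, lane))
    lane_of = dict(lanes)
    df["lane"] = [lane_of.get(i, 0) for i in df.index]
    return df.sort_values(["chromosome", "lane", "start"]).reset_index(drop=True)


def _regions_overlap(r1: tuple[str, int, int], r2: tuple[str, int, int],
                     frac: float) -> bool:
    if r1[0] != r2[0]:
        return False
    lo = max(r1[1], r2[1])
    hi = min(r1[2], r2[2])
    if hi < lo:
        return False
    shorter = min(r1[2] - r1[1], r2[2] - r2[1]) + 1
    return (hi - lo + 1) >= frac * shorter


def syndepth(segments: Sequence[CollinearSegment],
             overlap: float = 0.5) -> SyndepthProfile:
    """Multiplication-level profile of homeologous segment groups.

    Segment regions sharing >= ``overlap`` rank overlap are the same region;
    regions linked by a segment belong to one homeologous group, and the
    group's level is its number of distinct regions.
    """
    regions: list[tuple[str, int, int]] = []
    edges: list[tuple[int, int]] = []

    def add_region(r) -> int:
        regions.append(r)
        return len(regions) - 1

    for seg in segments:
        ia = add_region(seg.region_a)
        ib = add_region(seg.region_b)
        edges.append((ia, ib))

    n = len(regions)
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    # merge region instances that are "the same" region
    for i, j in itertools.combinations(range(n), 2):
        if _regions_overlap(regions[i], regions[j], overlap):
            union(i, j)
    region_cluster = [find(i) for i in range(n)]

    # connect distinct regions through their segments
    m = len(set(region_cluster))
    gparent = {c: c for c in set(region_cluster)}

    def gfind(x):
        while gparent[x] != x:
            gparent[x] = gparent[gparent[x]]
            x = gparent[x]
        return x

    for ia, ib in edges:
        ca, cb = region_cluster[ia], region_cluster[ib]
        ra, rb = gfind(ca), gfind(cb)
        if ra != rb:
            gparent[rb] = ra

    groups: dict[int, set[int]] = {}
    for c in set(region_cluster):
        groups.setdefault(gfind(c), set()).add(c)
    counts: dict[int, int] = {}
    for members in groups.values():
        level = len(members)
        if level >= 2:
            counts[level] = counts.get(level, 0) + 1
    scope = "intra" if all(s.intra for s in segments) else "inter"
    return SyndepthProfile(counts=counts, scope=scope)


def dotplot_table(loci_a: Sequence[GeneLocus], loci_b: Sequence[GeneLocus],
                  homolog_pairs: Iterable[tuple[str, str]],
                  anchor_set: set[frozenset] | None = None,
                  ks_lookup: Mapping[tuple[str, str], float] | None = None) -> pd.DataFrame:
    """Gene-homology dot-plot table with cumulative gene indices.

    Chromosomes are concatenated in descending bp length (ties by name);
    each homolog pair yields one dot, flagged when it is an anchor pair and
    annotated with Ks where available.
    """
    anchor_set = anchor_set or set()
    ks_lookup = ks_lookup or {}

    def cumulative(loci: Sequence[GeneLocus]) -> dict[str, int]:
        lengths: dict[str, int] = {}
        counts: dict[str, int] = {}
        for l in loci:
            lengths[l.chromosome] = max(lengths.get(l.chromosome, 0), l.end)
            counts[l.chromosome] = counts.get(l.chromosome, 0) + 1
        order = sorted(lengths, key=lambda c: (-lengths[c], c))
        offset, out = 0, {}
        for c in order:
            out[c] = offset
            offset += counts[c]
        return out

    off_a, off_b = cumulative(loci_a), cumulative(loci_b)
    idx_a, idx_b = _index(loci_a), _index(loci_b)
    rows = []
    for ga, gb in homolog_pairs:
        if ga not in idx_a or gb not in idx_b:
            continue
        la, lb = idx_a[ga], idx_b[gb]
        key = frozenset((ga, gb))
        ks = ks_lookup.get((ga, gb), ks_lookup.get((gb, ga), np.nan))
        rows.append({
            "gene_a": ga, "gene_b": gb,
            "x": off_a[la.chromosome] + la.rank,
            "y": off_b[lb.chromosome] + lb.rank,
            "is_anchor": key in anchor_set,
            "ks": ks,
        })
    return pd.DataFrame(rows, columns=["gene_a", "gene_b", "x", "y", "is_anchor", "ks"])


def anchor_pairs(segments: Sequence[CollinearSegment]) -> set[frozenset]:
    return {frozenset(p) for seg in segments for p in seg.anchors}


def anchor_ks(segments: Sequence[CollinearSegment],
              cds: Mapping[str, SequenceRecord] | None = None,
              ks_estimates: Mapping[tuple[str, str], float] | None = None,
              mode: str = "node_weighted",
              ks_cap: float = 5.0) -> ksdist.WeightedKsDistribution:
    """Weighted Ks distribution restricted to anchor pairs.

    Anchor pairs are grouped into connected "anchor families"; within each,
    an average-linkage tree assigns event-level weights exactly as for the
    whole paranome, and only entries that are anchor pairs are kept.
    """
    import networkx as nx

    pairs = anchor_pairs(segments)
    if not pairs:
        return ksdist.WeightedKsDistribution()
    g = nx.Graph()
    for p in pairs:
        a, b = sorted(p)
        g.add_edge(a, b)
    ks_known: dict[tuple[str, str], float] = {}
    if ks_estimates:
        for (a, b), v in ks_estimates.items():
            ks_known[(min(a, b), max(a, b))] = float(v)
    n_skipped = 0
    dist = ksdist.WeightedKsDistribution()
    for ci, comp in enumerate(sorted(nx.connected_components(g), key=sorted)):
        members = sorted(comp)
        pair_ks: dict[tuple[str, str], float] = {}
        ok = True
        for a, b in itertools.combinations(members, 2):
            key = (a, b)
            if key in ks_known:
                pair_ks[key] = ks_known[key]
            elif cds is not None and a in cds and b in cds:
                est = ksdist.ks_ng86(cds[a].seq, cds[b].seq, a, b)
                pair_ks[key] = est.ks if not est.saturated else ks_cap
            else:
                ok = False
        if not ok:
            n_skipped += 1
            continue
        fam_id = f"anchorfam{ci:04d}"
        tree = ksdist.family_tree_alc(pair_ks, members=members, ks_cap=ks_cap)
        full = ksdist.deduplicate(tree, pair_ks, mode=mode, family_id=fam_id)
        if mode == "node_weighted":
            # keep only anchor-pair entries; renormalize per node so each
            # retained duplication event still carries total weight 1
            by_node: dict[str, list[tuple[float, float]]] = {}
            node_pairs: dict[str, list[tuple[str, str]]] = {}
            for node in tree.nodes:
                nid = f"{fam_id}.n{node.node_id}"
                kept = [p for p in node.pairs if frozenset(p) in pairs]
                if not kept:
                    continue
                w = 1.0 / len(kept)
                for a, b in kept:
                    dist.entries.append((pair_ks[(a, b)], w, nid, fam_id))
        else:
            # node-averaged entries over anchor pairs only
            for node in tree.nodes:
                kept = [pair_ks[p] for p in node.pairs if frozenset(p) in pairs]
                if kept:
                    nid = f"{fam_id}.n{node.node_id}"
                    dist.entries.append((float(np.mean(kept)), 1.0, nid, fam_id))
    return dist


def segments_to_table(segments: Sequence[CollinearSegment]) -> pd.DataFrame:
    rows = []
    for seg in segments:
        rows.append({
            "segment_id": seg.segment_id,
            "chrom_a": seg.region_a[0], "start_rank_a": seg.region_a[1],
            "end_rank_a": seg.region_a[2],
            "chrom_b": seg.region_b[0], "start_rank_b": seg.region_b[1],
            "end_rank_b": seg.region_b[2],
            "n_anchors": seg.n_anchors,
            "span_bp_a": seg.span_bp_a, "span_bp_b": seg.span_bp_b,
            "intra": seg.intra,
            "anchors": ";".join(f"{a}|{b}" for a, b in seg.anchors),
        })
    return pd.DataFrame(rows)


def read_segments_table(path) -> list[CollinearSegment]:
    """Import a segment table (e.g. exported from an external collinearity
    engine) in the format written by :func:`segments_to_table`."""
    df = pd.read_csv(path, sep="\t")
    out = []
    for row in df.itertuples(index=False):
        anchors = [tuple(p.split("|")) for p in str(row.anchors).split(";") if p]
        out.append(CollinearSegment(
            segment_id=str(row.segment_id),
            region_a=(str(row.chrom_a), int(row.start_rank_a), int(row.end_rank_a)),
            region_b=(str(row.chrom_b), int(row.start_rank_b), int(row.end_rank_b)),
            anchors=anchors, span_bp_a=int(row.span_bp_a),
            span_bp_b=int(row.span_bp_b), intra=bool(row.intra)))
    return out
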