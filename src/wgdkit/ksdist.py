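"""Ks age distributions for paralogous and orthologous gene pairs.

The synonymous distance estimator is the Nei–Gojobori (1986) counting method
with Jukes–Cantor multiple-hit correction: synonymous and nonsynonymous
sites are counted fractionally per codon, differences between codons are
averaged over all minimal substitution paths (paths through stop codons
excluded), and

    Ks = -(3/4) * ln(1 - (4/3) * ps),    ps = synonymous differences / sites.

Family trees are built by average-linkage (UPGMA) clustering on the pairwise
Ks matrix; the tree roots itself, and each internal node represents one
duplication event. Redundancy in the raw pairwise distribution is removed
either node-weighted (all pairs below a node share total weight 1) or
node-averaged (one mean Ks per node).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Mapping, Sequence

import numpy as np

from .formats import SequenceRecord

_BASES = "ACGT"

_CODON_TABLE = {}
_STANDARD = (
    "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
)
for _i, (_b1, _b2, _b3) in enumerate(itertools.product("TCAG", repeat=3)):
    _CODON_TABLE[_b1 + _b2 + _b3] = _STANDARD[_i]

STOP_CODONS = {c for c, aa in _CODON_TABLE.items() if aa == "*"}


def translate_codon(codon: str) -> str:
    return _CODON_TABLE[codon]


@lru_cache(maxsize=None)
def _syn_sites(codon: str) -> float:
    """Fractional number of synonymous sites in a codon (NG86).

    Each position contributes (# synonymous single-nucleotide changes)/3;
    changes creating a stop codon count as nonsynonymous.
    """
    aa = _CODON_TABLE[codon]
    s = 0.0
    for pos in range(3):
        for b in _BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1:]
            if _CODON_TABLE[alt] == aa and alt not in STOP_CODONS:
                s += 1.0 / 3.0
    return s


@lru_cache(maxsize=None)
def _codon_diffs(c1: str, c2: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) differences between two codons.

    Averaged over all orderings of the minimal substitution path; orderings
    passing through a stop codon are excluded unless all do.
    """
    positions = [i for i in range(3) if c1[i] != c2[i]]
    if not positions:
        return 0.0, 0.0
    paths = []
    for order in itertools.permutations(positions):
        cur = c1
        sd = nd = 0.0
        through_stop = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if nxt in STOP_CODONS:
                through_stop = True
            if _CODON_TABLE[cur] == _CODON_TABLE[nxt]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        paths.append((through_stop, sd, nd))
    valid = [(s, n) for stop, s, n in paths if not stop]
    if not valid:
        valid = [(s, n) for _, s, n in paths]
    sd = sum(s for s, _ in valid) / len(valid)
    nd = sum(n for _, n in valid) / len(valid)
    return sd, nd


@dataclass
class KsEstimate:
    """NG86 synonymous/nonsynonymous distance for one gene pair."""

    gene_a: str
    gene_b: str
    S: float
    N: float
    sd_count: float
    nd_count: float
    ps: float
    pn: float
    ks: float
    ka: float
    saturated: bool = False


def _jc_correct(p: float) -> tuple[float, bool]:
    arg = 1.0 - (4.0 / 3.0) * p
    if arg <= 0.0:
        return float("inf"), True
    return -0.75 * float(np.log(arg)), False


def ks_ng86(codon_a: str, codon_b: str, gene_a: str = "a", gene_b: str = "b") -> KsEstimate:
    """NG86 Ks/Ka between two gap-free, positionally matched CDS.

    Codons containing ambiguous bases or gaps, and stop codons, are skipped
    entirely (excluded from both site and difference counts).
    """
    if len(codon_a) != len(codon_b):
        raise ValueError(
            f"sequence length mismatch: {gene_a} has {len(codon_a)} nt, "
            f"{gene_b} has {len(codon_b)} nt"
        )
    if len(codon_a) % 3:
        raise ValueError("sequence length not a multiple of 3")
    codon_a, codon_b = codon_a.upper(), codon_b.upper()
    S = N = sd = nd = 0.0
    for i in range(0, len(codon_a), 3):
        ca, cb = codon_a[i:i + 3], codon_b[i:i + 3]
        if any(b not in _BASES for b in ca + cb):
            continue
        if ca in STOP_CODONS or cb in STOP_CODONS:
            continue
        s_a, s_b = _syn_sites(ca), _syn_sites(cb)
        S += 0.5 * (s_a + s_b)
        N += 3.0 - 0.5 * (s_a + s_b)
        dsd, dnd = _codon_diffs(ca, cb)
        sd += dsd
        nd += dnd
    if S <= 0.0:
        raise ValueError(f"zero synonymous sites for pair ({gene_a}, {gene_b})")
    ps = sd / S
    pn = nd / N if N > 0 else 0.0
    ks, sat_s = _jc_correct(ps)
    ka, sat_n = _jc_correct(pn)
    return KsEstimate(gene_a, gene_b, S, N, sd, nd, ps, pn, ks, ka,
                      saturated=sat_s or ps >= 0.75)


def backtranslate(protein_msa: Sequence[SequenceRecord],
                  cds: Mapping[str, SequenceRecord]) -> list[SequenceRecord]:
    """Back-translate an aligned protein MSA into a codon-level MSA.

    Each amino-acid column becomes the corresponding codon; gap columns
    become ``---``. The ungapped protein of each row must translate exactly
    from its CDS under the standard code.
    """
    out = []
    for row in protein_msa:
        if row.id not in cds:
            raise KeyError(f"no CDS for aligned protein {row.id!r}")
        nt = cds[row.id].seq.upper()
        if len(nt) % 3:
            raise ValueError(f"CDS of {row.id} has length not divisible by 3")
        codons = [nt[i:i + 3] for i in range(0, len(nt), 3)]
        # allow a trailing stop codon in the CDS
        if codons and codons[-1] in STOP_CODONS:
            codons = codons[:-1]
        aligned = []
        k = 0
        for pos, aa in enumerate(row.seq):
            if aa == "-":
                aligned.append("---")
                continue
            if k >= len(codons):
                raise ValueError(f"CDS of {row.id} shorter than aligned protein")
            codon = codons[k]
            if _CODON_TABLE.get(codon, "X") != aa:
                raise ValueError(
                    f"translation mismatch for {row.id} at alignment position {pos}: "
                    f"codon {codon} is not {aa}"
                )
            aligned.append(codon)
            k += 1
        if k != len(codons):
            raise ValueError(f"CDS of {row.id} longer than aligned protein")
        out.append(SequenceRecord(id=row.id, seq="".join(aligned)))
    return out


# ---------------------------------------------------------------------------
# Family trees and event-level deduplication


@dataclass
class TreeNode:
    node_id: int
    height: float
    left: tuple[str, ...]   # leaves of the first joined cluster
    right: tuple[str, ...]  # leaves of the second joined cluster
    pairs: tuple[tuple[str, str], ...]  # leaf pairs whose MRCA is this node

    @property
    def leaves(self) -> tuple[str, ...]:
        return tuple(sorted(self.left + self.right))


@dataclass
class FamilyTree:
    """Ultrametric average-linkage tree over a gene family.

    ``nodes`` are the internal nodes in merge order; each records its height
    (the average Ks between the joined clusters) and the leaf pairs whose
    most recent common ancestor it is.
    """

    leaves: tuple[str, ...]
    nodes: list[TreeNode] = field(default_factory=list)

    @property
    def n_internal(self) -> int:
        return len(self.nodes)

    def newick(self) -> str:
        """Topology-only Newick string (branch lengths omitted)."""
        if not self.nodes:
            return (self.leaves[0] if self.leaves else "") + ";"
        tree_of = {(lf,): lf for lf in self.leaves}
        for node in self.nodes:
            la, lb = tuple(sorted(node.left)), tuple(sorted(node.right))
            tree_of[node.leaves] = f"({tree_of[la]},{tree_of[lb]})"
        return tree_of[self.nodes[-1].leaves] + ";"


def family_tree_alc(ks_matrix: Mapping[tuple[str, str], float],
                    members: Sequence[str] | None = None,
                    ks_cap: float = 5.0) -> FamilyTree:
    """Average-linkage (UPGMA) tree from a pairwise Ks dictionary.

    Saturated / missing entries are replaced by ``ks_cap``. Ties between
    candidate merges are broken by the lexicographically smallest pair of
    cluster representative ids, making the topology deterministic.
    """
    if members is None:
        members = sorted({g for pair in ks_matrix for g in pair})
    members = list(members)
    if len(members) == 1:
        return FamilyTree(leaves=tuple(members))

    def d0(a: str, b: str) -> float:
        v = ks_matrix.get((a, b), ks_matrix.get((b, a)))
        if v is None or not np.isfinite(v):
            return ks_cap
        return min(float(v), ks_cap)

    clusters: dict[str, list[str]] = {m: [m] for m in members}
    dist: dict[frozenset, float] = {
        frozenset((a, b)): d0(a, b) for a, b in itertools.combinations(members, 2)
    }
    tree = FamilyTree(leaves=tuple(sorted(members)))
    node_id = 0
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(sorted(clusters), 2):
            d = dist[frozenset((a, b))]
            key = (d, a, b)
            if best is None or key < best:
                best = key
        d, ra, rb = best
        la, lb = clusters.pop(ra), clusters.pop(rb)
        pairs = tuple(sorted((min(x, y), max(x, y)) for x in la for y in lb))
        tree.nodes.append(TreeNode(node_id=node_id, height=d,
                                   left=tuple(sorted(la)), right=tuple(sorted(lb)),
                                   pairs=pairs))
        node_id += 1
        rep = min(ra, rb)
        merged = la + lb
        for rc in list(clusters):
            dc = (len(la) * dist.pop(frozenset((ra, rc))) +
                  len(lb) * dist.pop(frozenset((rb, rc)))) / (len(la) + len(lb))
            dist[frozenset((rep, rc))] = dc
        dist.pop(frozenset((ra, rb)), None)
        clusters[rep] = merged
    return tree


@dataclass
class WeightedKsDistribution:
    """Ks values with per-entry weights summing to 1 per duplication event."""

    entries: list[tuple[float, float, str, str]] = field(default_factory=list)
    # (ks, weight, node_id, family_id)

    @property
    def values(self) -> np.ndarray:
        return np.array([e[0] for e in self.entries], dtype=float)

    @property
    def weights(self) -> np.ndarray:
        return np.array([e[1] for e in self.entries], dtype=float)

    def __len__(self) -> int:
        return len(self.entries)

    def extend(self, other: "WeightedKsDistribution") -> None:
        self.entries.extend(other.entries)


def deduplicate(tree: FamilyTree, pair_ks: Mapping[tuple[str, str], float],
                mode: str = "node_weighted",
                family_id: str = "fam") -> WeightedKsDistribution:
    """Collapse a family's pairwise Ks values to one unit of weight per event.

    node_weighted: every pair whose MRCA is node m gets weight 1/|pairs(m)|.
    node_averaged: a single entry per node with the arithmetic mean Ks.
    """
    if mode not in ("node_weighted", "node_averaged"):
        raise ValueError(f"unknown deduplication mode {mode!r}")
    out = WeightedKsDistribution()
    for node in tree.nodes:
        ks_vals = []
        for a, b in node.pairs:
            v = pair_ks.get((a, b), pair_ks.get((b, a)))
            if v is None:
                raise KeyError(f"missing Ks for pair ({a}, {b})")
            ks_vals.append(float(v))
        nid = f"{family_id}.n{node.node_id}"
        if mode == "node_weighted":
            w = 1.0 / len(ks_vals)
            for (a, b), v in zip(node.pairs, ks_vals):
                out.entries.append((v, w, nid, family_id))
        else:
            out.entries.append((float(np.mean(ks_vals)), 1.0, nid, family_id))
    return out


def family_ks(members: Sequence[str], cds: Mapping[str, SequenceRecord],
              ks_cap: float = 5.0) -> dict[tuple[str, str], KsEstimate]:
    """All pairwise NG86 estimates within a family (positionally matched CDS)."""
    out = {}
    for a, b in itertools.combinations(sorted(members), 2):
        out[(a, b)] = ks_ng86(cds[a].seq, cds[b].seq, a, b)
    return out


def paranome_ks_distribution(families: Mapping[str, Sequence[str]],
                             cds: Mapping[str, SequenceRecord],
                             mode: str = "node_weighted",
                             ks_cap: float = 5.0) -> WeightedKsDistribution:
    """Whole-paranome weighted Ks distribution across all families."""
    dist = WeightedKsDistribution()
    for fam_id in sorted(families):
        members = sorted(families[fam_id])
        if len(members) < 2:
            continue
        est = family_ks(members, cds, ks_cap=ks_cap)
        pair_ks = {k: (v.ks if not v.saturated else ks_cap) for k, v in est.items()}
        tree = family_tree_alc(pair_ks, members=members, ks_cap=ks_cap)
        dist.extend(deduplicate(tree, pair_ks, mode=mode, family_id=fam_id))
    return dist


def paranome_ks_table(families: Mapping[str, Sequence[str]],
                      cds: Mapping[str, SequenceRecord],
                      mode: str = "node_weighted", ks_cap: float = 5.0):
    """Tabular whole-paranome Ks distribution (one row per weighted entry).

    Columns: family_id, node_id, gene_a, gene_b, ks, ka, weight. In
    node-averaged mode the gene columns hold the node's leaf pairs joined
    with ``;`` and ks is the node mean.
    """
    import pandas as pd

    rows = []
    for fam_id in sorted(families):
        members = sorted(families[fam_id])
        if len(members) < 2:
            continue
        est = family_ks(members, cds, ks_cap=ks_cap)
        pair_ks = {k: (v.ks if not v.saturated else ks_cap) for k, v in est.items()}
        tree = family_tree_alc(pair_ks, members=members, ks_cap=ks_cap)
        for node in tree.nodes:
            nid = f"{fam_id}.n{node.node_id}"
            if mode == "node_weighted":
                w = 1.0 / len(node.pairs)
                for a, b in node.pairs:
                    rows.append({"family_id": fam_id, "node_id": nid,
                                 "gene_a": a, "gene_b": b,
                                 "ks": pair_ks[(a, b)], "ka": est[(a, b)].ka,
                                 "weight": w})
            else:
                vals = [pair_ks[p] for p in node.pairs]
                rows.append({"family_id": fam_id, "node_id": nid,
                             "gene_a": ";".join(p[0] for p in node.pairs),
                             "gene_b": ";".join(p[1] for p in node.pairs),
                             "ks": float(np.mean(vals)),
                             "ka": float(np.mean([est[p].ka for p in node.pairs])),
                             "weight": 1.0})
    return pd.DataFrame(rows, columns=["family_id", "node_id", "gene_a", "gene_b",
                                       "ks", "ka", "weight"])


def ortholog_ks(cds_a: Mapping[str, SequenceRecord],
                cds_b: Mapping[str, SequenceRecord],
                pairs: Iterable[tuple[str, str]]) -> tuple[list[float], int]:
    """One NG86 Ks per ortholog (RBH) pair; returns (values, n_saturated).

    Orthologous pairs each represent a single speciation event, so no tree
    weighting is needed. Saturated pairs are excluded and counted.
    """
    values: list[float] = []
    n_sat = 0
    for a, b in pairs:
        est = ks_ng86(cds_a[a].seq, cds_b[b].seq, a, b)
        if est.saturated:
            n_sat += 1
            continue
        values.append(est.ks)
    return values, n_sat


def trio_branch_ks(mode_fo: float, mode_so: float, mode_fs: float) -> tuple[float, float]:
    """Three-point decomposition of pairwise Ks modes into branch lengths.

    For a trio (focal, sister, outgroup) with additive branch contributions,
    b_focal = (d(f,s) + d(f,o) - d(s,o)) / 2 and symmetrically for the
    sister. Negative estimates are reported as-is with a warning.
    """
    b_focal = 0.5 * (mode_fs + mode_fo - mode_so)
    b_sister = 0.5 * (mode_fs + mode_so - mode_fo)
    if b_focal < 0 or b_sister < 0:
        warnings.warn("negative branch Ks estimate from three-point decomposition")
    return b_focal, b_sister
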