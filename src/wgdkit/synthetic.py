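"""Synthetic data generation for every stage of the pipeline.

Provides (i) Ks samples from specified exponential + lognormal mixtures,
(ii) codon sequence pairs evolved by synonymous-only substitutions to a
target NG86 Ks, and (iii) whole genomes with implanted duplicated or
triplicated collinear segments of known age. Ground-truth labels (mixture
component of origin, true families, implanted segments) are carried
alongside so downstream modules can be tested for parameter and structure
recovery without any external data.

The generator deliberately omits several features of real data: no indels,
no codon-usage bias, no among-site rate variation, no gene loss within
duplicated blocks. This keeps the NG86 estimator an exact oracle for the
simulated divergence.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .formats import GeneLocus, Hit, SequenceRecord
from .collinearity import CollinearSegment
from . import ksdist

_SENSE_CODONS = sorted(c for c in ksdist._CODON_TABLE if c not in ksdist.STOP_CODONS)


@dataclass
class MixtureSpec:
    """An exponential background plus lognormal peaks on the Ks scale.

    ``components`` are (weight, log_mean, log_sd) triples; the exponential
    background takes the remaining weight 1 - sum(component weights).
    """

    exp_rate: float = 1.0
    components: list[tuple[float, float, float]] = field(default_factory=list)

    def __post_init__(self):
        if self.exp_rate <= 0:
            raise ValueError("exp_rate must be positive")
        wsum = sum(w for w, _, _ in self.components)
        if wsum > 1.0 + 1e-9:
            raise ValueError(f"component weights sum to {wsum} > 1")
        for w, _, sd in self.components:
            if not (0 < w <= 1):
                raise ValueError("component weights must lie in (0, 1]")
            if sd <= 0:
                raise ValueError("log_sd must be positive")

    @property
    def background_weight(self) -> float:
        return 1.0 - sum(w for w, _, _ in self.components)


@dataclass
class KsSample:
    values: np.ndarray
    labels: np.ndarray  # -1 = exponential background, j >= 0 = lognormal j


def sample_ks(spec: MixtureSpec, n: int, seed: int, max_ks: float = 5.0) -> KsSample:
    """Draw ``n`` Ks values from the mixture; values above ``max_ks`` are
    resampled (practical Ks-range truncation). Labels record the component
    of origin for recovery tests and are never used by fitting code."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    weights = [spec.background_weight] + [w for w, _, _ in spec.components]
    values = np.empty(n)
    labels = np.empty(n, dtype=int)
    for i in range(n):
        while True:
            j = rng.choice(len(weights), p=weights)
            if j == 0:
                v = rng.exponential(1.0 / spec.exp_rate)
            else:
                _, mu, sd = spec.components[j - 1]
                v = float(np.exp(rng.normal(mu, sd)))
            if v <= max_ks:
                break
        values[i] = v
        labels[i] = j - 1
    return KsSample(values=values, labels=labels)


def random_cds(n_codons: int, rng: np.random.Generator) -> str:
    """A random coding sequence of sense codons starting with ATG."""
    codons = ["ATG"] + [
        _SENSE_CODONS[i] for i in rng.integers(0, len(_SENSE_CODONS), n_codons - 1)
    ]
    return "".join(codons)


def _synonymous_options(seq: str) -> list[tuple[int, int, str]]:
    """All (codon index, position, new base) single-nt synonymous changes."""
    opts = []
    for ci in range(0, len(seq), 3):
        codon = seq[ci:ci + 3]
        aa = ksdist.translate_codon(codon)
        for pos in range(3):
            for b in "ACGT":
                if b == codon[pos]:
                    continue
                alt = codon[:pos] + b + codon[pos + 1:]
                if alt not in ksdist.STOP_CODONS and ksdist.translate_codon(alt) == aa:
                    opts.append((ci // 3, pos, b))
    return opts


def evolve_codon_pair(n_codons: int, target_ks: float, seed: int,
                      saturation_guard: float = 3.0,
                      start_seq: str | None = None
                      ) -> tuple[SequenceRecord, SequenceRecord, int]:
    """Create a CDS pair whose NG86-expected Ks reaches ``target_ks``.

    The second sequence is derived from the first by repeatedly applying a
    synonymous single-nucleotide substitution drawn uniformly from all
    current options, until the NG86 estimate of the pair reaches the target
    (within one-substitution granularity). The protein translation is never
    changed and stop codons are never introduced.
    """
    if n_codons < 10:
        raise ValueError("n_codons must be >= 10")
    if target_ks < 0:
        raise ValueError("target_ks must be non-negative")
    if target_ks > saturation_guard:
        raise ValueError(
            f"target_ks {target_ks} exceeds saturation guard {saturation_guard}")
    rng = np.random.default_rng(seed)
    seq_a = start_seq if start_seq is not None else random_cds(n_codons, rng)
    if len(seq_a) != 3 * n_codons:
        raise ValueError("start_seq length does not match n_codons")
    seq_b = seq_a
    n_subs = 0
    if target_ks == 0:
        return (SequenceRecord("anc", seq_a), SequenceRecord("der", seq_b), 0)
    max_steps = 200 * n_codons
    ks = 0.0
    for _ in range(max_steps):
        opts = _synonymous_options(seq_b)
        if not opts:
            raise ValueError("no synonymous substitution options left")
        ci, pos, b = opts[rng.integers(0, len(opts))]
        i = 3 * ci + pos
        seq_b = seq_b[:i] + b + seq_b[i + 1:]
        n_subs += 1
        est = ksdist.ks_ng86(seq_a, seq_b)
        if est.saturated:
            raise ValueError(
                f"target Ks {target_ks} unreachable: pair saturated after {n_subs} "
                "substitutions (too few synonymous sites)")
        ks = est.ks
        if ks >= target_ks:
            break
    else:
        raise ValueError(f"target Ks {target_ks} unreachable within {max_steps} steps")
    return (SequenceRecord("anc", seq_a), SequenceRecord("der", seq_b), n_subs)


@dataclass
class SegmentDuplication:
    """One implant request: duplicate ``length`` consecutive genes starting
    at ``start_rank`` on ``chromosome`` into ``copies`` total copies, each
    new copy diverging from the source block by Ks ``ks``."""

    chromosome: str
    start_rank: int
    length: int
    copies: int = 2
    ks: float = 1.0


@dataclass
class SyntheticGenome:
    loci: list[GeneLocus]
    cds: dict[str, SequenceRecord]
    true_families: dict[str, list[str]]
    true_segments: list[CollinearSegment]

    @property
    def protein(self) -> dict[str, SequenceRecord]:
        return {g: SequenceRecord(g, r.translate()) for g, r in self.cds.items()}

    def aa_lengths(self) -> dict[str, int]:
        return {g: len(r.seq) // 3 for g, r in self.cds.items()}


def build_genome(n_chromosomes: int, genes_per_chromosome: int,
                 duplications: Sequence[SegmentDuplication] = (),
                 seed: int = 0, gene_spacing: int = 12_000,
                 codon_range: tuple[int, int] = (150, 300)) -> SyntheticGenome:
    """Build a genome with implanted collinear duplications of known age.

    Background genes are independent random CDS (no homology); each implant
    appends its extra copies as contiguous gene runs at the end of the
    chromosome, preserving gene order, so implanted blocks form perfect
    diagonals in rank space. ``true_segments`` records every pairwise
    homeologous relation among the copies of a block.
    """
    rng = np.random.default_rng(seed)
    for d1, d2 in itertools.combinations(duplications, 2):
        if d1.chromosome == d2.chromosome and not (
                d1.start_rank + d1.length <= d2.start_rank or
                d2.start_rank + d2.length <= d1.start_rank):
            raise ValueError("overlapping implant requests")
    chrom_names = [f"chr{i + 1}" for i in range(n_chromosomes)]
    genes: dict[str, list[tuple[str, str]]] = {c: [] for c in chrom_names}  # (id, cds)
    for c in chrom_names:
        for i in range(genes_per_chromosome):
            gid = f"{c}g{i:04d}"
            n_codons = int(rng.integers(codon_range[0], codon_range[1] + 1))
            genes[c].append((gid, random_cds(n_codons, rng)))

    true_families: dict[str, list[str]] = {}
    true_segments: list[CollinearSegment] = []
    fam_members: dict[str, list[str]] = {gid: [gid] for c in chrom_names
                                         for gid, _ in genes[c]}

    for d in duplications:
        if d.chromosome not in genes:
            raise ValueError(f"unknown chromosome {d.chromosome}")
        src = genes[d.chromosome][d.start_rank:d.start_rank + d.length]
        if len(src) < d.length:
            raise ValueError("implant does not fit within chromosome")
        copy_blocks: list[list[tuple[str, str]]] = [src]
        for c in range(1, d.copies):
            block = []
            for gid, cds in src:
                n_codons = len(cds) // 3
                sub_seed = int(rng.integers(0, 2**31 - 1))
                _, der, _ = evolve_codon_pair(n_codons, d.ks, sub_seed, start_seq=cds)
                new_id = f"{gid}_d{c}"
                block.append((new_id, der.seq))
                fam_members[gid].append(new_id)
            copy_blocks.append(block)
        # append new copies at the end of the chromosome
        block_ranks: list[tuple[int, int]] = [(d.start_rank, d.start_rank + d.length - 1)]
        for block in copy_blocks[1:]:
            start = len(genes[d.chromosome])
            genes[d.chromosome].extend(block)
            block_ranks.append((start, start + d.length - 1))
        for (i, j) in itertools.combinations(range(d.copies), 2):
            anchors = [(copy_blocks[i][k][0], copy_blocks[j][k][0])
                       for k in range(d.length)]
            true_segments.append(CollinearSegment(
                segment_id=f"true{len(true_segments):03d}",
                region_a=(d.chromosome, *block_ranks[i]),
                region_b=(d.chromosome, *block_ranks[j]),
                anchors=anchors, intra=True))

    loci: list[GeneLocus] = []
    cds: dict[str, SequenceRecord] = {}
    for c in chrom_names:
        for rank, (gid, seq) in enumerate(genes[c]):
            start = rank * gene_spacing
            loci.append(GeneLocus(gid, c, start, start + len(seq), "+", rank=rank))
            cds[gid] = SequenceRecord(gid, seq)
    for i, (root, members) in enumerate(sorted(fam_members.items())):
        true_families[f"fam{i:05d}"] = sorted(members)
    # fill bp spans for the implanted segments
    rank_bp = {(l.chromosome, l.rank): (l.start, l.end) for l in loci}
    for seg in true_segments:
        for attr, region in (("span_bp_a", seg.region_a), ("span_bp_b", seg.region_b)):
            chrom, r0, r1 = region
            setattr(seg, attr, rank_bp[(chrom, r1)][1] - rank_bp[(chrom, r0)][0])
    return SyntheticGenome(loci=loci, cds=cds, true_families=true_families,
                           true_segments=true_segments)


def genome_hits(genome: SyntheticGenome, seed: int = 0,
                length_exponent: float = 0.8, noise_sd: float = 0.1,
                scale: float = 1e-3) -> list[Hit]:
    """Similarity hits among true homologs, with gene-length-biased scores.

    Bit-scores follow ``scale * proxy_len**length_exponent`` times lognormal
    noise, emulating the length bias that bit-score normalization removes.
    """
    rng = np.random.default_rng(seed)
    lens = genome.aa_lengths()
    hits = []
    for members in genome.true_families.values():
        for a, b in itertools.combinations(sorted(members), 2):
            proxy = lens[a] * lens[b]
            score = scale * proxy ** length_exponent * float(
                np.exp(rng.normal(0.0, noise_sd)))
            hits.append(Hit(query=a, target=b, evalue=1e-50, bitscore=score,
                            qlen=lens[a], tlen=lens[b]))
    return sorted(hits, key=lambda h: (h.query, h.target))


def simulate_length_biased_hits(n: int, exponent: float = 0.8,
                                noise_sd: float = 0.3, seed: int = 0,
                                len_range: tuple[int, int] = (100, 2000)) -> list[Hit]:
    """Standalone hit simulation with bitscore = proxy_len**exponent x noise."""
    rng = np.random.default_rng(seed)
    hits = []
    for i in range(n):
        qlen = int(rng.integers(*len_range))
        tlen = int(rng.integers(*len_range))
        score = (qlen * tlen) ** exponent * float(np.exp(rng.normal(0.0, noise_sd)))
        hits.append(Hit(query=f"q{i:06d}", target=f"t{i:06d}", evalue=1e-30,
                        bitscore=score, qlen=qlen, tlen=tlen))
    return hits
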