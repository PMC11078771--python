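"""Readers and writers for the standard formats the pipeline touches.

Internal coordinate convention: 0-based half-open intervals. GFF3 input is
1-based inclusive; the conversion happens exactly once, at the file boundary,
so ``end - start`` internally equals the gene length in base pairs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

HIT_COLUMNS = [
    "query", "target", "identity", "length", "mismatches", "gapopens",
    "qstart", "qend", "tstart", "tend", "evalue", "bitscore",
]


@dataclass
class SequenceRecord:
    """A named sequence (CDS nucleotides or protein amino acids)."""

    id: str
    seq: str

    def __len__(self) -> int:
        return len(self.seq)

    def translate(self) -> str:
        """Translate a CDS with the standard genetic code."""
        return str(Seq(self.seq).translate())


@dataclass(frozen=True)
class GeneLocus:
    """A gene's position on a chromosome.

    ``start``/``end`` are 0-based half-open; ``rank`` is the 0-based order
    index of the gene along its chromosome (dense per chromosome).
    """

    gene_id: str
    chromosome: str
    start: int
    end: int
    strand: str = "+"
    rank: int = -1

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(
                f"gene {self.gene_id}: start ({self.start}) must be < end ({self.end})"
            )


@dataclass
class Hit:
    """One similarity-search match between two genes.

    ``proxy_len`` is the product of query and target amino-acid lengths and
    serves as the gene-length covariate for bit-score normalization.
    ``norm_score`` is unset until normalization has been run.
    """

    query: str
    target: str
    evalue: float
    bitscore: float
    qlen: int
    tlen: int
    proxy_len: int = field(init=False)
    norm_score: float | None = None

    def __post_init__(self):
        self.proxy_len = self.qlen * self.tlen


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file into a list of :class:`SequenceRecord`.

    Order is preserved; duplicate ids raise; an empty file yields an empty
    list with a warning.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(SequenceRecord(id=rec.id, seq=str(rec.seq).strip()))
    if not records:
        warnings.warn(f"no sequences found in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 80) -> None:
    bio = [
        _BioSeqRecord(Seq(r.seq), id=r.id, description="") for r in records
    ]
    with open(path, "w") as fh:
        SeqIO.write(bio, fh, "fasta")
    # Biopython hard-wraps at 60; width kept for API symmetry only.


def assign_ranks(loci: Sequence[GeneLocus]) -> list[GeneLocus]:
    """Assign dense per-chromosome ranks by ascending start (ties by gene_id)."""
    out: list[GeneLocus] = []
    by_chrom: dict[str, list[GeneLocus]] = {}
    for loc in loci:
        by_chrom.setdefault(loc.chromosome, []).append(loc)
    for chrom in sorted(by_chrom):
        ordered = sorted(by_chrom[chrom], key=lambda l: (l.start, l.gene_id))
        for i, loc in enumerate(ordered):
            out.append(GeneLocus(loc.gene_id, loc.chromosome, loc.start, loc.end,
                                 loc.strand, rank=i))
    return out


def read_gff_genes(path: str | Path, feature: str = "gene",
                   attribute_key: str = "ID") -> list[GeneLocus]:
    """Read gene loci from a GFF3 file.

    Selects rows whose type equals ``feature`` and takes the gene id from
    ``attribute_key`` in column 9. GFF 1-based inclusive coordinates are
    converted to the internal 0-based half-open convention, and ranks are
    assigned per chromosome.
    """
    loci: list[GeneLocus] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 columns, got {len(cols)}")
            if cols[2] != feature:
                continue
            attrs = {}
            for kv in cols[8].split(";"):
                kv = kv.strip()
                if "=" in kv:
                    k, v = kv.split("=", 1)
                    attrs[k] = v
            if attribute_key not in attrs:
                raise ValueError(
                    f"{path}:{lineno}: attribute {attribute_key!r} missing on {feature} row"
                )
            start1, end1 = int(cols[3]), int(cols[4])
            if end1 < start1:
                raise ValueError(f"{path}:{lineno}: end < start")
            loci.append(GeneLocus(attrs[attribute_key], cols[0], start1 - 1, end1,
                                  cols[6] if cols[6] in "+-" else "+"))
    return assign_ranks(loci)


def write_gff_genes(loci: Iterable[GeneLocus], path: str | Path,
                    feature: str = "gene", source: str = "wgdkit") -> None:
    """Write loci as GFF3 (converting back to 1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for loc in sorted(loci, key=lambda l: (l.chromosome, l.start, l.gene_id)):
            fh.write("\t".join([
                loc.chromosome, source, feature, str(loc.start + 1), str(loc.end),
                ".", loc.strand, ".", f"ID={loc.gene_id}",
            ]) + "\n")


def _dedup_hits(hits: list[Hit]) -> list[Hit]:
    # One row per unordered gene pair: keep higher bitscore; ties keep the
    # lexicographically smaller (query, target).
    best: dict[frozenset, Hit] = {}
    for h in hits:
        key = frozenset((h.query, h.target))
        cur = best.get(key)
        if cur is None or h.bitscore > cur.bitscore or (
            h.bitscore == cur.bitscore and (h.query, h.target) < (cur.query, cur.target)
        ):
            best[key] = h
    return sorted(best.values(), key=lambda h: (h.query, h.target))


def read_hits(path: str | Path, lengths: Mapping[str, int],
              deduplicate: bool = True) -> list[Hit]:
    """Read a 12-column tab-separated similarity hit table.

    Gene lengths (amino acids) come from ``lengths``; self-hits are dropped;
    reciprocal duplicate rows are reduced to one row per pair.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     float_precision="round_trip")
    if df.shape[1] != 12:
        raise ValueError(f"{path}: expected 12 columns, got {df.shape[1]}")
    df.columns = HIT_COLUMNS
    hits: list[Hit] = []
    for row in df.itertuples(index=False):
        if row.query == row.target:
            continue
        for gid in (row.query, row.target):
            if gid not in lengths:
                raise KeyError(f"gene id {gid!r} in hit table has no known length")
        hits.append(Hit(query=str(row.query), target=str(row.target),
                        evalue=float(row.evalue), bitscore=float(row.bitscore),
                        qlen=int(lengths[str(row.query)]),
                        tlen=int(lengths[str(row.target)])))
    return _dedup_hits(hits) if deduplicate else hits


def write_hits(hits: Iterable[Hit], path: str | Path) -> None:
    """Write hits back as a 12-column table (placeholder alignment columns)."""
    with open(path, "w") as fh:
        for h in sorted(hits, key=lambda h: (h.query, h.target)):
            fh.write("\t".join(map(str, [
                h.query, h.target, 100.0, max(h.qlen, h.tlen), 0, 0,
                1, h.qlen, 1, h.tlen, h.evalue, h.bitscore,
            ])) + "\n")


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)
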