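"""Reading, writing and basic summarisation of CDR3 repertoires and germline databases.

A CDR3 dataset is a multiset of nucleotide strings over {A,C,G,T}: the third
complementarity-determining regions of antibody heavy chains, spanning the
V(D)J junction. A germline database is a set of named D-gene alleles
(IMGT-style ``gene*allele`` headers). This module also builds consensus CDR3s
(grouping near-identical sequences that differ by sample-preparation errors)
and counts k-mer abundances, the raw material for seed selection.
"""

from __future__ import annotations

import logging
import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, NamedTuple

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

VALID_ALPHABET = frozenset("ACGT")


class EmptyDatasetError(ValueError):
    """Raised when an input file yields zero valid CDR3 sequences."""


@dataclass
class CDR3Set:
    """A set of distinct CDR3 nucleotide strings with multiplicities.

    ``counts`` maps each distinct uppercase A/C/G/T string to a positive
    integer abundance (number of reads, or of consensus-group members).
    ``dropped`` records how many input records were discarded for containing
    symbols outside the alphabet. ``below_min_size`` is set by the readers
    when the distinct-sequence count falls under the configured floor.
    """

    counts: dict[str, int] = field(default_factory=dict)
    label: str = ""
    dropped: int = 0
    below_min_size: bool = False

    @property
    def sequences(self) -> list[str]:
        return list(self.counts.keys())

    @property
    def multiplicity(self) -> list[int]:
        return list(self.counts.values())

    def __len__(self) -> int:
        return len(self.counts)

    def __iter__(self) -> Iterator[str]:
        return iter(self.counts)

    def items(self):
        return self.counts.items()

    def total_multiplicity(self) -> int:
        return sum(self.counts.values())

    @classmethod
    def from_sequences(
        cls, sequences: Iterable[str], label: str = "", counts: Iterable[int] | None = None
    ) -> "CDR3Set":
        """Aggregate raw (possibly repeated, mixed-case) sequences into a CDR3Set.

        Sequences with symbols outside {A,C,G,T} are dropped and tallied.
        """
        agg: Counter[str] = Counter()
        dropped = 0
        if counts is None:
            counts = (1 for _ in iter(int, 1))  # infinite ones
        for seq, n in zip(sequences, counts):
            seq = seq.strip().upper()
            if not seq:
                continue
            if not set(seq) <= VALID_ALPHABET:
                dropped += 1
                continue
            if n < 1:
                raise ValueError(f"multiplicity must be >= 1, got {n}")
            agg[seq] += int(n)
        return cls(counts=dict(agg), label=label, dropped=dropped)


class GermlineEntry(NamedTuple):
    gene: str
    allele: str
    sequence: str

    @property
    def name(self) -> str:
        return f"{self.gene}*{self.allele}"


@dataclass
class GermlineDB:
    """A germline D-gene database: (gene, allele, sequence) entries.

    (gene, allele) pairs are unique; duplicate sequences may appear under
    different names (IMGT lists identical D genes under several strains).
    """

    entries: list[GermlineEntry] = field(default_factory=list)
    species: str = ""

    def __post_init__(self) -> None:
        seen = set()
        for e in self.entries:
            if not e.sequence:
                raise ValueError(f"empty sequence for {e.gene}*{e.allele}")
            key = (e.gene, e.allele)
            if key in seen:
                raise ValueError(f"duplicate entry {e.gene}*{e.allele}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[GermlineEntry]:
        return iter(self.entries)

    def genes(self) -> dict[str, list[GermlineEntry]]:
        """Entries grouped by gene name, preserving input order."""
        out: dict[str, list[GermlineEntry]] = {}
        for e in self.entries:
            out.setdefault(e.gene, []).append(e)
        return out

    @classmethod
    def from_fasta(cls, path: str | Path, species: str = "") -> "GermlineDB":
        """Parse an IMGT-dialect FASTA: header ``<gene>*<allele>``.

        Everything after the first ``*`` is the allele; headers lacking a
        ``*`` get allele "01".
        """
        entries = []
        for rec in SeqIO.parse(str(path), "fasta"):
            name = rec.id
            if "*" in name:
                gene, allele = name.split("*", 1)
            else:
                gene, allele = name, "01"
            entries.append(GermlineEntry(gene, allele, str(rec.seq).upper()))
        return cls(entries=entries, species=species)

    def to_fasta(self, path: str | Path) -> None:
        recs = [
            SeqRecord(Seq(e.sequence), id=f"{e.gene}*{e.allele}", description="")
            for e in self.entries
        ]
        SeqIO.write(recs, str(path), "fasta")


@dataclass
class KmerTable:
    """Abundances of all k-mers of a CDR3 dataset (multiplicity-weighted)."""

    k: int
    counts: Counter = field(default_factory=Counter)

    def most_common(self, m: int | None = None):
        return self.counts.most_common(m)


def read_cdr3_dataset(
    path: str | Path,
    format: str = "fasta",
    min_size: int = 15000,
    label: str | None = None,
) -> CDR3Set:
    """Read a CDR3 dataset from FASTA, one-sequence-per-line text, or TSV.

    TSV input must have a ``sequence`` column and may have a ``count``
    column; without one every record counts 1. Distinct sequences are
    aggregated; records with non-ACGT symbols are dropped (count kept in
    ``.dropped``). Datasets with fewer than ``min_size`` distinct sequences
    are flagged ``below_min_size`` (the inference default ignores such
    datasets, mirroring the 15,000-consensus-CDR3 floor).
    """
    path = Path(path)
    if label is None:
        label = path.stem
    if format == "fasta":
        # honour an optional count=N tag in the description (written by
        # write_cdr3_dataset); absent tag means multiplicity 1
        seqs, nums = [], []
        for rec in SeqIO.parse(str(path), "fasta"):
            m = re.search(r"count=(\d+)", rec.description)
            seqs.append(str(rec.seq))
            nums.append(int(m.group(1)) if m else 1)
        out = CDR3Set.from_sequences(seqs, label=label, counts=nums)
    elif format == "lines":
        with open(path) as fh:
            out = CDR3Set.from_sequences((line for line in fh), label=label)
    elif format == "tsv":
        import pandas as pd

        df = pd.read_csv(path, sep="\t")
        if "sequence" not in df.columns:
            raise ValueError(f"{path}: TSV input needs a 'sequence' column")
        counts = df["count"].astype(int).tolist() if "count" in df.columns else None
        out = CDR3Set.from_sequences(df["sequence"].astype(str), label=label, counts=counts)
    else:
        raise ValueError(f"unknown format {format!r}")

    if len(out) == 0:
        raise EmptyDatasetError(f"{path}: no valid CDR3 sequences")
    if out.dropped:
        logger.warning("%s: dropped %d records with non-ACGT symbols", path, out.dropped)
    if len(out) < min_size:
        out.below_min_size = True
        logger.warning(
            "%s: %d distinct CDR3s < min_size=%d", path, len(out), min_size
        )
    return out


def write_cdr3_dataset(cdr3s: CDR3Set, path: str | Path, format: str = "fasta") -> None:
    """Write a CDR3Set; FASTA records carry the multiplicity in the header."""
    path = Path(path)
    if format == "fasta":
        with open(path, "w") as fh:
            for i, (seq, n) in enumerate(cdr3s.items()):
                fh.write(f">cdr3_{i}|count={n}\n{seq}\n")
    elif format == "lines":
        with open(path, "w") as fh:
            for seq, n in cdr3s.items():
                for _ in range(n):
                    fh.write(seq + "\n")
    elif format == "tsv":
        with open(path, "w") as fh:
            fh.write("sequence\tcount\n")
            for seq, n in cdr3s.items():
                fh.write(f"{seq}\t{n}\n")
    else:
        raise ValueError(f"unknown format {format!r}")


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def build_consensus_cdr3s(raw: CDR3Set, max_mismatches: int = 3) -> CDR3Set:
    """Group CDR3s within ``max_mismatches`` Hamming distance and take consensus.

    Greedy seed-centric clustering: distinct CDR3s are visited in decreasing
    multiplicity (ties lexicographic); each joins the first existing group
    whose seed has equal length and Hamming distance <= max_mismatches, else
    founds a group. The consensus is the multiplicity-weighted per-position
    majority, with ties resolved toward the group seed's nucleotide; the
    output multiplicity is the group total. Groups never chain: membership is
    always tested against the founding seed.
    """
    if max_mismatches < 0:
        raise ValueError("max_mismatches must be >= 0")
    if max_mismatches == 0:
        return CDR3Set(counts=dict(raw.counts), label=raw.label, dropped=raw.dropped)

    order = sorted(raw.items(), key=lambda kv: (-kv[1], kv[0]))
    # seeds bucketed by length to avoid all-pairs scans
    buckets: dict[int, list[int]] = {}
    groups: list[list[tuple[str, int]]] = []
    seeds: list[str] = []
    for seq, n in order:
        placed = False
        for gi in buckets.get(len(seq), ()):
            if _hamming(seeds[gi], seq) <= max_mismatches:
                groups[gi].append((seq, n))
                placed = True
                break
        if not placed:
            seeds.append(seq)
            groups.append([(seq, n)])
            buckets.setdefault(len(seq), []).append(len(groups) - 1)

    out: Counter[str] = Counter()
    for seed, members in zip(seeds, groups):
        total = sum(n for _, n in members)
        if len(members) == 1:
            out[seed] += total
            continue
        cons = []
        for pos in range(len(seed)):
            tally: Counter[str] = Counter()
            for seq, n in members:
                tally[seq[pos]] += n
            best = max(tally.values())
            winners = [sym for sym, c in tally.items() if c == best]
            cons.append(seed[pos] if seed[pos] in winners else min(winners))
        out["".join(cons)] += total
    return CDR3Set(counts=dict(out), label=raw.label, dropped=raw.dropped)


def count_kmers(cdr3s: CDR3Set, k: int) -> KmerTable:
    """Count every k-length substring, weighted by CDR3 multiplicity.

    A k-mer occurring twice in one CDR3 contributes twice. CDR3s shorter
    than k contribute nothing.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    counts: Counter[str] = Counter()
    for seq, n in cdr3s.items():
        for i in range(len(seq) - k + 1):
            counts[seq[i : i + k]] += n
    return KmerTable(k=k, counts=counts)
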