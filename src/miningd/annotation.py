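"""Classification of inferred candidates against a germline database.

Each consolidated candidate is labelled:

* ``in_db`` — equal to a database sequence, a substring of one, or a
  substring extended by at most ``extension`` extra nucleotides at the start
  and/or end (default 3);
* ``novel_variation`` — best percent identity against the database exceeds
  the threshold (default 75%);
* ``novel_gene`` — identity <= threshold against every database entry.

Identity uses an ungapped overlap scan over all relative offsets with the
shorter sequence's length as denominator: known D-gene variants differ by
substitutions and end truncations, not internal indels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .io import GermlineDB, GermlineEntry

logger = logging.getLogger(__name__)

DEFAULT_EXTENSION = 3
DEFAULT_IDENTITY_THRESHOLD = 75.0


@dataclass
class CandidateGene:
    sequence: str
    classification: str  # in_db | novel_variation | novel_gene
    closest: tuple[str, str] | None  # (gene, allele)
    identity: float
    offset: int | None = None  # offset of candidate start relative to closest entry
    provenance: dict | None = None


def best_overlap(a: str, b: str) -> tuple[int, int, int]:
    """Best ungapped overlap of a against b over all relative offsets.

    Returns (matches, overlap_length, offset) where ``offset`` is the
    position of a's first symbol relative to b's first symbol (may be
    negative). Ties prefer more matches, then longer overlap, then the
    smaller offset.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    best = (-1, 0, 0)
    for off in range(-(len(a) - 1), len(b)):
        lo = max(0, off)
        hi = min(len(b), off + len(a))
        if hi <= lo:
            continue
        matches = sum(1 for j in range(lo, hi) if b[j] == a[j - off])
        cand = (matches, hi - lo, -off)
        if (cand[0], cand[1], cand[2]) > (best[0], best[1], -best[2]):
            best = (matches, hi - lo, off)
    return best


def percent_identity(a: str, b: str) -> float:
    """Identity of the best ungapped overlap, as matches / min(|a|,|b|) * 100."""
    matches, _, _ = best_overlap(a, b)
    return 100.0 * matches / min(len(a), len(b))


def _in_db_relation(cand: str, entry_seq: str, extension: int) -> bool:
    """cand equals / is a substring of entry, possibly with <= ``extension``
    extra nucleotides appended at the start and/or end of that substring."""
    n = len(cand)
    for i in range(0, extension + 1):
        for j in range(0, extension + 1):
            core = cand[i : n - j]
            if core and core in entry_seq:
                return True
    return False


def classify_candidate(
    cand: str,
    db: GermlineDB,
    extension: int = DEFAULT_EXTENSION,
    identity_threshold: float = DEFAULT_IDENTITY_THRESHOLD,
) -> CandidateGene:
    """Classify one candidate against the database.

    The closest entry is the identity argmax; ties prefer longer overlap,
    then the lexicographically smallest gene*allele name.
    """
    if extension < 0:
        raise ValueError("extension must be >= 0")
    if not 0 < identity_threshold < 100:
        raise ValueError("identity_threshold must be in (0, 100)")
    if len(db) == 0:
        logger.warning("empty database: %r labelled novel_gene", cand)
        return CandidateGene(cand, "novel_gene", None, 0.0)

    best_entry: GermlineEntry | None = None
    best_key = None
    best_stats = (0.0, 0)
    for e in sorted(db, key=lambda e: (e.gene, e.allele)):
        matches, overlap, off = best_overlap(cand, e.sequence)
        ident = 100.0 * matches / min(len(cand), len(e.sequence))
        key = (ident, overlap)
        if best_key is None or key > best_key:
            best_key, best_entry, best_stats = key, e, (ident, off)

    for e in sorted(db, key=lambda e: (e.gene, e.allele)):
        if _in_db_relation(cand, e.sequence, extension):
            matches, overlap, off = best_overlap(cand, e.sequence)
            ident = 100.0 * matches / min(len(cand), len(e.sequence))
            return CandidateGene(cand, "in_db", (e.gene, e.allele), ident, off)

    ident, off = best_stats
    if ident > identity_threshold:
        return CandidateGene(cand, "novel_variation", (best_entry.gene, best_entry.allele), ident, off)
    return CandidateGene(cand, "novel_gene", (best_entry.gene, best_entry.allele), ident, off)


def annotate_candidates(
    candidates: list[str],
    db: GermlineDB,
    extension: int = DEFAULT_EXTENSION,
    identity_threshold: float = DEFAULT_IDENTITY_THRESHOLD,
) -> list[CandidateGene]:
    return [classify_candidate(c, db, extension, identity_threshold) for c in candidates]
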