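"""Seed selection and chi-square-driven bidirectional seed extension.

The inference core: the m most abundant k-mers of a CDR3 dataset (seeds,
default k=10) are each grown into candidate D-gene strings. At every step
the abundances of the four possible single-nucleotide extensions on each
side are tested against a uniform null with the statistic

    S = sum_i (N_i - E_i)^2 / E_i,   E_i = total/4,

approximately chi-square with 3 degrees of freedom. A side whose null is
rejected is extended by its most abundant symbol (both rejected: the side
with the smaller p-value); extension stops when both sides accept. After
each step, the remaining three extensions of the extended side are tested
against uniform (E = remaining/3, df 2): rejection means the current string
sits inside two distinct D genes, and an independent branch is forked from
the runner-up. Inference is fully deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from scipy.stats import chi2

from .io import CDR3Set, KmerTable

logger = logging.getLogger(__name__)

DNA = ("A", "C", "G", "T")

DEFAULT_ALPHA = 1e-30
DEFAULT_MAX_LEN = 50
MAX_BRANCHES = 8


def select_seeds(kmers: KmerTable, m: int) -> list[str]:
    """The m most abundant k-mers; ties broken lexicographically.

    Returns all k-mers when fewer than m exist; empty table yields an empty
    list with a warning.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    if not kmers.counts:
        logger.warning("empty k-mer table: no seeds selected")
        return []
    ranked = sorted(kmers.counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return [kmer for kmer, _ in ranked[:m]]


@dataclass
class ExtensionTest:
    """Outcome of the uniformity test on single-symbol extension abundances."""

    counts: tuple[int, int, int, int]
    expected: tuple[float, float, float, float]
    S_stat: float
    p_value: float
    alpha: float

    @property
    def reject(self) -> bool:
        return self.p_value < self.alpha


def extension_test(counts, alpha: float = DEFAULT_ALPHA, df: int = 3) -> ExtensionTest:
    """Chi-square goodness-of-fit of extension counts against uniform.

    ``counts`` has df+1 entries (4 for the side test, 3 for the branch
    test); expected counts are total/(df+1). All-zero counts are a "no
    data" outcome: S=0, p=1, null accepted.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    counts = tuple(int(c) for c in counts)
    if len(counts) != df + 1:
        raise ValueError(f"expected {df + 1} counts for df={df}")
    if any(c < 0 for c in counts):
        raise ValueError("counts must be non-negative")
    total = sum(counts)
    if total == 0:
        return ExtensionTest(counts, (0.0,) * len(counts), 0.0, 1.0, alpha)
    E = total / len(counts)
    S = sum((c - E) ** 2 / E for c in counts)
    p = float(chi2.sf(S, df))
    return ExtensionTest(counts, (E,) * len(counts), S, p, alpha)


@dataclass
class Extension:
    """A candidate string grown from a seed k-mer."""

    sequence: str
    seed: str
    left_steps: int
    right_steps: int
    branch_path: list[str] = field(default_factory=list)
    support: int = 0  # multiplicity-weighted number of CDR3s containing sequence

    def __post_init__(self) -> None:
        assert self.seed in self.sequence
        assert self.left_steps + self.right_steps == len(self.sequence) - len(self.seed)


@dataclass
class _Branch:
    sequence: str
    left_steps: int
    right_steps: int
    branch_path: list[str]
    groups: list[tuple[int, list[str]]]  # (multiplicity, CDR3s containing sequence)
    texts: list[tuple[int, str]]  # (multiplicity, '#'-joined CDR3s)


class ExtensionEngine:
    """Extends seed k-mers over one CDR3 dataset.

    CDR3s are grouped by multiplicity and concatenated (with a separator)
    so that candidate (j+1)-mer abundances are computed with C-level
    substring counting; a k-mer postings index accelerates the initial
    restriction to CDR3s containing a seed. A CDR3 in which the current
    string abuts the boundary contributes to no extension on that side.
    """

    def __init__(self, cdr3s: CDR3Set, seed_len: int = 10):
        self.cdr3s = cdr3s
        self.seed_len = seed_len
        self._postings: dict[str, list[str]] = {}
        by_mult: dict[int, list[str]] = {}
        for seq, n in cdr3s.items():
            by_mult.setdefault(n, []).append(seq)
            for i in range(len(seq) - seed_len + 1):
                kmer = seq[i : i + seed_len]
                bucket = self._postings.get(kmer)
                if bucket is None:
                    self._postings[kmer] = [seq]
                elif bucket[-1] is not seq:
                    bucket.append(seq)
        self._by_mult = by_mult
        self._mult_of = cdr3s.counts

    def _initial_groups(self, start: str) -> list[tuple[int, list[str]]]:
        if len(start) >= self.seed_len:
            candidates = self._postings.get(start[: self.seed_len], [])
            if len(start) > self.seed_len:
                candidates = [c for c in candidates if start in c]
        else:  # shorter than the index k: full scan
            candidates = [c for c in self.cdr3s if start in c]
        groups: dict[int, list[str]] = {}
        for seq in candidates:
            groups.setdefault(self._mult_of[seq], []).append(seq)
        return sorted(groups.items())

    @staticmethod
    def _texts(groups) -> list[tuple[int, str]]:
        return [(mult, "#".join(seqs)) for mult, seqs in groups]

    @staticmethod
    def _side_counts(texts, candidates) -> list[int]:
        return [sum(m * txt.count(c) for m, txt in texts) for c in candidates]

    def support(self, sequence: str) -> int:
        groups = self._initial_groups(sequence)
        return sum(m * len(seqs) for m, seqs in groups)

    def extend(
        self,
        seed: str,
        alpha: float = DEFAULT_ALPHA,
        branch_alpha: float | None = None,
        max_len: int = DEFAULT_MAX_LEN,
        branching: bool = True,
    ) -> list[Extension]:
        """All terminal extensions of one seed (deterministic, depth-first).

        At most MAX_BRANCHES branches are pursued per seed; forks beyond the
        cap are dropped with a log message (deepest-first traversal keeps
        the highest-support main lines).
        """
        if branch_alpha is None:
            branch_alpha = alpha
        groups = self._initial_groups(seed)
        if not groups:
            raise ValueError(f"seed {seed!r} does not occur in the dataset")
        stack = [_Branch(seed, 0, 0, [], groups, self._texts(groups))]
        finished: list[Extension] = []
        n_spawned = 1
        while stack:
            br = stack.pop()
            while True:
                if len(br.sequence) >= max_len:
                    break
                left = self._side_counts(br.texts, [b + br.sequence for b in DNA])
                right = self._side_counts(br.texts, [br.sequence + b for b in DNA])
                t_left = extension_test(left, alpha)
                t_right = extension_test(right, alpha)
                if not t_left.reject and not t_right.reject:
                    break
                if t_left.reject and (not t_right.reject or t_left.p_value <= t_right.p_value):
                    side, counts = "L", left
                else:
                    side, counts = "R", right
                order = sorted(range(4), key=lambda i: (-counts[i], DNA[i]))
                sym = DNA[order[0]]
                # branch test: do the remaining three extensions look uniform?
                rest = [counts[i] for i in order[1:]]
                if branching and sum(rest) > 0 and n_spawned < MAX_BRANCHES:
                    t_branch = extension_test(rest, branch_alpha, df=2)
                    if t_branch.reject and max(rest) > 0:
                        alt = DNA[order[1]]
                        alt_seq = alt + br.sequence if side == "L" else br.sequence + alt
                        alt_groups = self._filter_groups(br.groups, alt_seq)
                        if alt_groups:
                            stack.append(
                                _Branch(
                                    alt_seq,
                                    br.left_steps + (side == "L"),
                                    br.right_steps + (side == "R"),
                                    br.branch_path + [f"{side}:{alt}"],
                                    alt_groups,
                                    self._texts(alt_groups),
                                )
                            )
                            n_spawned += 1
                elif branching and n_spawned >= MAX_BRANCHES:
                    logger.debug("branch cap reached for seed %s", seed)
                new_seq = sym + br.sequence if side == "L" else br.sequence + sym
                br.groups = self._filter_groups(br.groups, new_seq)
                br.texts = self._texts(br.groups)
                br.sequence = new_seq
                if side == "L":
                    br.left_steps += 1
                else:
                    br.right_steps += 1
            finished.append(
                Extension(
                    sequence=br.sequence,
                    seed=seed,
                    left_steps=br.left_steps,
                    right_steps=br.right_steps,
                    branch_path=br.branch_path,
                    support=sum(m * len(seqs) for m, seqs in br.groups),
                )
            )
        # distinct terminal sequences; keep the first (deepest-first) record
        seen: dict[str, Extension] = {}
        for ext in finished:
            seen.setdefault(ext.sequence, ext)
        return list(seen.values())

    @staticmethod
    def _filter_groups(groups, sub: str):
        out = []
        for mult, seqs in groups:
            kept = [s for s in seqs if sub in s]
            if kept:
                out.append((mult, kept))
        return out

    def reextend(
        self,
        start: str,
        alpha: float = DEFAULT_ALPHA,
        max_len: int = DEFAULT_MAX_LEN,
    ) -> str:
        """Branch-free run of the stopping rule from an arbitrary string.

        Used to re-extend the common core of a merged clique; returns the
        start string unchanged when it does not occur in the dataset.
        """
        if not self._initial_groups(start):
            return start
        exts = self.extend(start, alpha=alpha, max_len=max_len, branching=False)
        return exts[0].sequence


def extend_kmer(
    seed: str,
    cdr3s: CDR3Set,
    alpha: float = DEFAULT_ALPHA,
    branch_alpha: float | None = None,
    max_len: int = DEFAULT_MAX_LEN,
) -> list[Extension]:
    """Convenience wrapper: build an engine for one dataset and extend one seed."""
    engine = ExtensionEngine(cdr3s, seed_len=len(seed))
    return engine.extend(seed, alpha=alpha, branch_alpha=branch_alpha, max_len=max_len)
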