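"""Probabilistic models of CDR3 generation.

Two models live here. The *simple model* captures one-sided trimming of a
single seed string s: a trimming integer k is drawn uniformly from
[0, |s|], the suffix of length k is removed and replaced by k uniform random
symbols. Its likelihood has the closed form

    P(c | s) = K(|s|, |A|) * (|A|^(m+1) - 1),
    K(|s|, |A|) = 1 / ((|s|+1) * |A|^|s| * (|A|-1)),

where m is the length of the longest shared prefix of s and c. Maximising
P(C|s) over seed strings for a set C of modified strings is therefore
equivalent to maximising score(C|s) = sum_i log(|A|^(m_i+1) - 1), a trace-
reconstruction-style objective solved here greedily and by a brute-force
oracle.

The *generative model* is the full V(D)J abstraction: a D gene (seed) is
trimmed on both ends (p from the left, q from the right, p+q <= |s|),
flanked by random insertions e_l, e_r, and embedded between a V-gene suffix
v_l and a J-gene prefix j_r. It is the synthetic-data engine of the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from itertools import product
from math import log

import numpy as np
import pandas as pd
import yaml

from .io import CDR3Set

DNA = ("A", "C", "G", "T")


def _as_counts(C) -> dict[str, int]:
    """Accept a CDR3Set, a mapping, or an iterable of strings."""
    if isinstance(C, CDR3Set):
        return C.counts
    if isinstance(C, dict):
        return C
    out: dict[str, int] = {}
    for s in C:
        out[s] = out.get(s, 0) + 1
    return out


def _shared_prefix_len(a: str, b: str) -> int:
    m = 0
    for x, y in zip(a, b):
        if x != y:
            break
        m += 1
    return m


@dataclass
class SimpleModel:
    """One-sided trimming model: seed string s over an ordered alphabet."""

    s: str
    alphabet: tuple[str, ...] = DNA

    def __post_init__(self) -> None:
        if not self.s:
            raise ValueError("seed string must be non-empty")
        if len(self.alphabet) < 2:
            raise ValueError("alphabet must have >= 2 symbols")
        if not set(self.s) <= set(self.alphabet):
            raise ValueError("seed uses symbols outside the alphabet")


def trim_extend_probability(model: SimpleModel, c: str, trim: int, exact: bool = False):
    """Probability that trimming exactly ``trim`` symbols produces ``c``.

    Equals 1/(|s|+1) * |A|^(-trim) when the retained prefix of s matches the
    corresponding prefix of c, else 0. With ``exact=True`` returns a Fraction.
    """
    s, A = model.s, len(model.alphabet)
    if len(c) != len(s):
        raise ValueError("modified string must have the seed's length")
    if not 0 <= trim <= len(s):
        raise ValueError("trim must be in [0, |s|]")
    keep = len(s) - trim
    if s[:keep] != c[:keep]:
        return Fraction(0) if exact else 0.0
    if exact:
        return Fraction(1, (len(s) + 1) * A**trim)
    return 1.0 / ((len(s) + 1) * A**trim)


def prob_modified_given_seed(model: SimpleModel, c: str, exact: bool = False):
    """P(c|s): total probability over all trimming integers.

    Computed via the closed form K(|s|,|A|) * (|A|^(m+1) - 1) with m the
    longest shared prefix of s and c.
    """
    s, A = model.s, len(model.alphabet)
    if len(c) != len(s):
        raise ValueError("modified string must have the seed's length")
    m = _shared_prefix_len(s, c)
    if exact:
        K = Fraction(1, (len(s) + 1) * A ** len(s) * (A - 1))
        return K * (A ** (m + 1) - 1)
    K = 1.0 / ((len(s) + 1) * A ** len(s) * (A - 1))
    return K * (A ** (m + 1) - 1)


def score_set(C, s: str, alphabet: tuple[str, ...] = DNA) -> float:
    """Log-likelihood score of seed s for a set of equal-length modified strings.

    score(C|s) = sum_i n_i * log(|A|^(m_i+1) - 1) with natural log; the
    additive constant N*log K is dropped, so the argmax over s is unchanged.
    """
    counts = _as_counts(C)
    A = len(alphabet)
    total = 0.0
    for c, n in counts.items():
        if len(c) != len(s):
            raise ValueError("all strings in C must have the seed's length")
        m = _shared_prefix_len(s, c)
        total += n * log(A ** (m + 1) - 1)
    return total


def reconstruct_seed_greedy(C, target_len: int, alphabet: tuple[str, ...] = DNA) -> str:
    """Greedy seed reconstruction: majority symbol per position with discards.

    At step j the most abundant (multiplicity-weighted) symbol at position j
    among retained strings is appended, and strings disagreeing at j are
    discarded. Ties choose the alphabetically smallest symbol.
    """
    counts = _as_counts(C)
    retained = [(c, n) for c, n in counts.items()]
    if any(len(c) < target_len for c, _ in retained):
        raise ValueError("all strings must have length >= target_len")
    out = []
    for j in range(target_len):
        tally: dict[str, int] = {}
        for c, n in retained:
            tally[c[j]] = tally.get(c[j], 0) + n
        best = max(tally.values())
        sym = min(s for s, v in tally.items() if v == best)
        out.append(sym)
        retained = [(c, n) for c, n in retained if c[j] == sym]
    return "".join(out)


BRUTE_FORCE_CAP = 10**7


def brute_force_reconstruct(C, target_len: int, alphabet: tuple[str, ...] = DNA) -> str:
    """Exhaustive maximiser of score_set over all |A|^target_len strings.

    Testing oracle: ties broken lexicographically; refuses search spaces
    above 10^7 candidates.
    """
    if len(alphabet) ** target_len > BRUTE_FORCE_CAP:
        raise ValueError("search space exceeds brute-force cap")
    counts = _as_counts(C)
    best_s, best_score = None, -float("inf")
    for tup in product(sorted(alphabet), repeat=target_len):
        s = "".join(tup)
        sc = score_set(counts, s, alphabet)
        if sc > best_score:  # lexicographic order of enumeration breaks ties
            best_s, best_score = s, sc
    return best_s


def simulate_simple(model: SimpleModel, N: int, rng_seed: int) -> CDR3Set:
    """Draw N i.i.d. modified strings from the simple one-sided model."""
    if N < 1:
        raise ValueError("N must be >= 1")
    rng = np.random.default_rng(rng_seed)
    s, alphabet = model.s, model.alphabet
    L = len(s)
    trims = rng.integers(0, L + 1, size=N)
    seqs = []
    for k in trims:
        k = int(k)
        tail = "".join(rng.choice(alphabet, size=k)) if k else ""
        seqs.append(s[: L - k] + tail)
    return CDR3Set.from_sequences(seqs, label=f"simple_sim_{rng_seed}")


@dataclass
class GenerativeModel:
    """Full V(D)J CDR3 generator.

    ``seeds``: named D-gene sequences with selection weights.
    ``trim_r``: both-end trimming is geometric-like, P(t) proportional to
    trim_r**t; the left trim p is drawn capped at |s|, then the right trim q
    capped at |s|-p, so p+q <= |s| always holds.
    ``insertion_len_range``: insertion lengths l_l, l_r uniform on the
    inclusive range; insertion symbols uniform over the alphabet.
    ``v_suffixes`` / ``j_prefixes``: weighted V_cdr3 / J_cdr3 string sets.
    """

    seeds: list[tuple[str, str, float]]  # (name, sequence, weight)
    v_suffixes: list[tuple[str, str, float]]
    j_prefixes: list[tuple[str, str, float]]
    trim_r: float = 0.7
    insertion_len_range: tuple[int, int] = (0, 6)
    alphabet: tuple[str, ...] = DNA

    def __post_init__(self) -> None:
        for group, what in (
            (self.seeds, "seed"),
            (self.v_suffixes, "V suffix"),
            (self.j_prefixes, "J prefix"),
        ):
            if not group:
                raise ValueError(f"at least one {what} is required")
            if any(w < 0 for _, _, w in group):
                raise ValueError(f"{what} weights must be non-negative")
            if sum(w for _, _, w in group) <= 0:
                raise ValueError(f"{what} weights must be normalizable")

    @classmethod
    def default(
        cls,
        rng_seed: int,
        n_genes: int = 10,
        gene_length_range: tuple[int, int] = (12, 35),
        gene_weights: list[float] | None = None,
        genes: list[str] | None = None,
    ) -> "GenerativeModel":
        """A realistic synthetic locus: random D genes plus trimmed V/J flanks.

        Gene lengths are evenly spread over ``gene_length_range``. V_cdr3 and
        J_cdr3 are the length-3..8 suffixes/prefixes of three base V/J
        sequences, emulating variable V/J end trimming; this keeps the first
        symbol beyond a D gene close to uniformly distributed, as in real
        CDR3s.
        """
        rng = np.random.default_rng(rng_seed)
        if genes is None:
            lo, hi = gene_length_range
            lengths = np.linspace(lo, hi, n_genes).round().astype(int)
            genes = ["".join(rng.choice(DNA, size=int(L))) for L in lengths]
        if gene_weights is None:
            gene_weights = [1.0] * len(genes)
        seeds = [(f"D{i + 1}", g, w) for i, (g, w) in enumerate(zip(genes, gene_weights))]
        v_suffixes, j_prefixes = [], []
        for b in range(3):
            v_base = "".join(rng.choice(DNA, size=12))
            j_base = "".join(rng.choice(DNA, size=12))
            for L in range(3, 9):
                v_suffixes.append((f"V{b + 1}.{L}", v_base[-L:], 1.0))
                j_prefixes.append((f"J{b + 1}.{L}", j_base[:L], 1.0))
        return cls(seeds=seeds, v_suffixes=v_suffixes, j_prefixes=j_prefixes)

    def to_yaml(self, path) -> None:
        data = {
            "seeds": [list(t) for t in self.seeds],
            "v_suffixes": [list(t) for t in self.v_suffixes],
            "j_prefixes": [list(t) for t in self.j_prefixes],
            "trim_r": self.trim_r,
            "insertion_len_range": list(self.insertion_len_range),
            "alphabet": list(self.alphabet),
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh)

    @classmethod
    def from_yaml(cls, path) -> "GenerativeModel":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(
            seeds=[tuple(t) for t in data["seeds"]],
            v_suffixes=[tuple(t) for t in data["v_suffixes"]],
            j_prefixes=[tuple(t) for t in data["j_prefixes"]],
            trim_r=data["trim_r"],
            insertion_len_range=tuple(data["insertion_len_range"]),
            alphabet=tuple(data["alphabet"]),
        )


def _weighted_choice(rng, items):
    names = np.arange(len(items))
    w = np.asarray([t[2] for t in items], dtype=float)
    return names, w / w.sum()


def _trunc_geometric(rng, r: float, cap: int) -> int:
    """Draw t with P(t) proportional to r**t on 0..cap."""
    if cap <= 0:
        return 0
    w = r ** np.arange(cap + 1)
    return int(rng.choice(cap + 1, p=w / w.sum()))


def simulate_cdr3s(
    model: GenerativeModel, N: int, rng_seed: int
) -> tuple[CDR3Set, pd.DataFrame]:
    """Simulate N CDR3s: v_l + e_l + trimmed(s) + e_r + j_r, with truth labels.

    Returns the aggregated CDR3Set and a per-read truth table with columns
    read_id, seed_name, p, q, l_l, l_r, v_id, j_id, sequence. A single
    integer seed fully determines the output.
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    rng = np.random.default_rng(rng_seed)
    s_idx, s_p = _weighted_choice(rng, model.seeds)
    v_idx, v_p = _weighted_choice(rng, model.v_suffixes)
    j_idx, j_p = _weighted_choice(rng, model.j_prefixes)
    lo, hi = model.insertion_len_range
    alphabet = model.alphabet

    seed_draws = rng.choice(s_idx, size=N, p=s_p)
    v_draws = rng.choice(v_idx, size=N, p=v_p)
    j_draws = rng.choice(j_idx, size=N, p=j_p)
    ll_draws = rng.integers(lo, hi + 1, size=N)
    lr_draws = rng.integers(lo, hi + 1, size=N)

    rows = []
    seqs = []
    for i in range(N):
        name, sseq, _ = model.seeds[int(seed_draws[i])]
        p = _trunc_geometric(rng, model.trim_r, len(sseq))
        q = _trunc_geometric(rng, model.trim_r, len(sseq) - p)
        core = sseq[p : len(sseq) - q]
        l_l, l_r = int(ll_draws[i]), int(lr_draws[i])
        e_l = "".join(rng.choice(alphabet, size=l_l)) if l_l else ""
        e_r = "".join(rng.choice(alphabet, size=l_r)) if l_r else ""
        v_id, v_seq, _ = model.v_suffixes[int(v_draws[i])]
        j_id, j_seq, _ = model.j_prefixes[int(j_draws[i])]
        seq = v_seq + e_l + core + e_r + j_seq
        seqs.append(seq)
        rows.append((f"read_{i}", name, p, q, l_l, l_r, v_id, j_id, seq))

    truth = pd.DataFrame(
        rows,
        columns=["read_id", "seed_name", "p", "q", "l_l", "l_r", "v_id", "j_id", "sequence"],
    )
    return CDR3Set.from_sequences(seqs, label=f"vdj_sim_{rng_seed}"), truth


def mutate_cdr3s(cdr3s: CDR3Set, rate: float, rng_seed: int) -> CDR3Set:
    """Inject per-base point mutations at the given rate.

    Confounder-injection utility emulating somatic hypermutation on already-
    generated CDR3s; deliberately not part of the generative model, whose
    scope is recombination only.
    """
    if not 0 <= rate <= 1:
        raise ValueError("rate must be in [0, 1]")
    rng = np.random.default_rng(rng_seed)
    out: list[str] = []
    counts: list[int] = []
    for seq, n in cdr3s.items():
        for _ in range(n):
            if rate == 0:
                out.append(seq)
            else:
                chars = list(seq)
                hits = np.nonzero(rng.random(len(chars)) < rate)[0]
                for pos in hits:
                    alternatives = [b for b in DNA if b != chars[pos]]
                    chars[pos] = alternatives[int(rng.integers(3))]
                out.append("".join(chars))
            counts.append(1)
    return CDR3Set.from_sequences(out, label=cdr3s.label + "_shm", counts=counts)
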