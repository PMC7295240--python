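"""D-gene usage, decoy-allele robustness, over-usage and V-gene haplotyping.

A substring (length >= K_min, default 8) is *unique* to a D gene if it
occurs in at least one allele of that gene and in no sequence of any other
gene. A CDR3 is *formed* by gene d when it contains a unique substring of d
and no equally long or longer unique substring of another gene; such CDR3s
are *traceable*. Usage of d = fraction of traceable (distinct) CDR3s formed
by d. The same rule at allele resolution, restricted to the alleles of the
assigned gene, yields per-allele shares.

Decoy ("false") alleles probe the robustness of allele-level assignment to
somatic hypermutation: hypermutated CDR3s that would otherwise inflate a
rare true allele get absorbed by the decoys.

Haplotyping links the alleles of heterozygous V genes to alleles of
heterozygous D genes through their joint usage across distinct CDR3s.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import product

import pandas as pd

from .io import CDR3Set, GermlineDB, GermlineEntry

logger = logging.getLogger(__name__)

DEFAULT_K_MIN = 8
DEFAULT_MIN_CDR3S = 1000
DEFAULT_OVERUSE_FACTOR = 2.0


class UniqueKmerIndex:
    """Maps unique substrings (length >= K_min) to their owning group.

    ``groups`` maps a group name (gene, or allele name at allele
    resolution) to the set of sequences it owns. Assignment scans a query's
    windows from the longest length downward and stops at the first length
    with any hit: the genes hit there are exactly those achieving the
    maximal unique-substring length (any longer substring containing a
    unique one is itself unique to the same group).
    """

    def __init__(self, groups: dict[str, list[str]], k_min: int = DEFAULT_K_MIN):
        if k_min < 1:
            raise ValueError("K_min must be >= 1")
        self.k_min = k_min
        owner: dict[str, str | None] = {}
        for name, seqs in groups.items():
            for seq in seqs:
                for L in range(k_min, len(seq) + 1):
                    for i in range(len(seq) - L + 1):
                        sub = seq[i : i + L]
                        prev = owner.get(sub, sub)
                        if prev is sub:
                            owner[sub] = name
                        elif prev != name:
                            owner[sub] = None  # shared: unique to no group
        self._owner = {sub: g for sub, g in owner.items() if g is not None}
        self.max_len = max((len(s) for s in self._owner), default=0)

    def unique_substrings(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for sub, g in self._owner.items():
            out.setdefault(g, set()).add(sub)
        return out

    def assign(self, c: str) -> str | None:
        """Group forming CDR3 c, or None (non-traceable: tie or no hit)."""
        top = min(self.max_len, len(c))
        for L in range(top, self.k_min - 1, -1):
            hits = {
                self._owner[c[i : i + L]]
                for i in range(len(c) - L + 1)
                if c[i : i + L] in self._owner
            }
            if hits:
                return hits.pop() if len(hits) == 1 else None
        return None


def find_unique_kmers(db: GermlineDB, k_min: int = DEFAULT_K_MIN) -> dict[str, set[str]]:
    """All substrings of length >= K_min unique to a single gene (across alleles)."""
    groups = {g: [e.sequence for e in ents] for g, ents in db.genes().items()}
    return UniqueKmerIndex(groups, k_min).unique_substrings()


def assign_cdr3(c: str, index: UniqueKmerIndex) -> str | None:
    return index.assign(c)


@dataclass
class UsageProfile:
    """Per-gene usage fractions over traceable distinct CDR3s."""

    gene_usage: dict[str, float]
    allele_shares: dict[str, dict[str, float]]
    traceable_fraction: float
    n_cdr3s: int
    n_traceable: int
    k_min: int = DEFAULT_K_MIN
    gene_counts: dict[str, int] = field(default_factory=dict)
    allele_counts: dict[str, dict[str, int]] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene": list(self.gene_usage),
                "usage": list(self.gene_usage.values()),
                "n_cdr3s": [self.gene_counts.get(g, 0) for g in self.gene_usage],
            }
        )


def gene_index(db: GermlineDB, k_min: int = DEFAULT_K_MIN) -> UniqueKmerIndex:
    groups = {g: [e.sequence for e in ents] for g, ents in db.genes().items()}
    return UniqueKmerIndex(groups, k_min)


def allele_index(entries: list[GermlineEntry], k_min: int = DEFAULT_K_MIN) -> UniqueKmerIndex:
    return UniqueKmerIndex({e.name: [e.sequence] for e in entries}, k_min)


def compute_usage(cdr3s: CDR3Set, db: GermlineDB, k_min: int = DEFAULT_K_MIN) -> UsageProfile:
    """Usage over distinct CDR3s (unweighted by multiplicity).

    Allele shares are fractions of each gene's allele-assignable CDR3s;
    CDR3s ambiguous between alleles of the assigned gene contribute to the
    gene's usage but to no allele.
    """
    gidx = gene_index(db, k_min)
    by_gene = db.genes()
    aidx = {g: allele_index(ents, k_min) for g, ents in by_gene.items() if len(ents) > 1}

    gene_counts: dict[str, int] = {}
    allele_counts: dict[str, dict[str, int]] = {}
    n_traceable = 0
    for c in cdr3s:
        g = gidx.assign(c)
        if g is None:
            continue
        n_traceable += 1
        gene_counts[g] = gene_counts.get(g, 0) + 1
        if g in aidx:
            a = aidx[g].assign(c)
        else:
            a = by_gene[g][0].name
        if a is not None:
            allele_counts.setdefault(g, {})[a] = allele_counts.get(g, {}).get(a, 0) + 1

    n = len(cdr3s)
    if n_traceable == 0:
        logger.warning("no traceable CDR3s")
        return UsageProfile({}, {}, 0.0, n, 0, k_min)
    gene_usage = {g: cnt / n_traceable for g, cnt in sorted(gene_counts.items())}
    allele_shares = {
        g: {a: cnt / sum(al.values()) for a, cnt in sorted(al.items())}
        for g, al in allele_counts.items()
    }
    return UsageProfile(
        gene_usage=gene_usage,
        allele_shares=allele_shares,
        traceable_fraction=n_traceable / n,
        n_cdr3s=n,
        n_traceable=n_traceable,
        k_min=k_min,
        gene_counts=gene_counts,
        allele_counts=allele_counts,
    )


def add_decoy_alleles(
    db: GermlineDB,
    gene: str,
    sites: list[int],
    alternatives: list[list[str]],
    cap: int = 64,
) -> GermlineDB:
    """Add false-allele (FA) decoys for one gene.

    All combinations of the per-site symbol choices ({original} plus the
    given alternatives at each site) applied to the gene's first allele,
    excluding sequences already in the database, labelled FA1, FA2, ...;
    truncated at ``cap``.
    """
    if cap < 1:
        raise ValueError("cap must be >= 1")
    ents = db.genes().get(gene)
    if not ents:
        raise ValueError(f"gene {gene!r} not in database")
    base = ents[0].sequence
    for s in sites:
        if not 0 <= s < len(base):
            raise ValueError(f"site {s} out of range for {gene}")
    if not sites:
        return GermlineDB(entries=list(db.entries), species=db.species)
    existing = {e.sequence for e in db}
    choices = [
        sorted({base[s], *alts}) for s, alts in zip(sites, alternatives)
    ]
    decoys: list[str] = []
    for combo in product(*choices):
        chars = list(base)
        for s, sym in zip(sites, combo):
            chars[s] = sym
        seq = "".join(chars)
        if seq not in existing and seq not in decoys:
            decoys.append(seq)
        if len(decoys) >= cap:
            break
    new_entries = list(db.entries) + [
        GermlineEntry(gene, f"FA{i + 1}", seq) for i, seq in enumerate(decoys)
    ]
    return GermlineDB(entries=new_entries, species=db.species)


def detect_overuse(
    target: UsageProfile,
    references: list[UsageProfile],
    factor: float = DEFAULT_OVERUSE_FACTOR,
) -> tuple[list[tuple[str, float]], list[str]]:
    """Genes whose usage is >= factor times their maximum reference usage.

    Returns (overused, absent_in_reference): ``overused`` holds (gene,
    over_usage ratio) pairs; genes used in the target but never in any
    reference are reported separately (their ratio is undefined).
    """
    if factor <= 0:
        raise ValueError("factor must be > 0")
    if not references:
        raise ValueError("at least one reference profile is required")
    overused: list[tuple[str, float]] = []
    absent: list[str] = []
    for gene, usage in target.gene_usage.items():
        ref_max = max(r.gene_usage.get(gene, 0.0) for r in references)
        if ref_max == 0:
            if usage > 0:
                absent.append(gene)
            continue
        ratio = usage / ref_max
        if ratio >= factor:
            overused.append((gene, ratio))
    return overused, absent


@dataclass
class HaplotypeReport:
    """Haplotype phasing of heterozygous V genes via heterozygous D genes.

    ``matrices[v_gene]`` is a DataFrame indexed by V alleles whose columns
    are "Dgene*allele"; within each D gene the rows are normalized over that
    gene's alleles. ``assignments[v_gene][d_gene][v_allele]`` is the paired D
    allele; ``haplotypes[v_gene]`` lists (v_allele, {d_gene: d_allele}).
    """

    v_genes: list[str]
    matrices: dict[str, pd.DataFrame]
    assignments: dict[str, dict[str, dict[str, str]]]
    haplotypes: dict[str, list[tuple[str, dict[str, str]]]]
    consistent: dict[str, bool]
    d_genes: list[str]


def _split_call(call: str) -> tuple[str, str]:
    if "*" in call:
        g, a = call.split("*", 1)
        return g, a
    return call, "01"


def haplotype_v_genes(
    annotated: pd.DataFrame,
    db: GermlineDB,
    min_cdr3s: int = DEFAULT_MIN_CDR3S,
    k_min: int = DEFAULT_K_MIN,
) -> HaplotypeReport:
    """Phase heterozygous V genes using heterozygous D genes.

    ``annotated`` needs a CDR3 column (``cdr3`` or ``junction``) and a
    ``v_call`` column (IMGT-style ``gene*allele``). V alleles with fewer
    than ``min_cdr3s`` distinct CDR3s are ignored; V genes retaining >= 2
    alleles are haplotyped. For each heterozygous D gene, the joint count
    of distinct CDR3s per (V allele, D allele) is row-normalized over the D
    gene's alleles, and each V allele pairs with its argmax D allele. A V
    gene is flagged inconsistent when two of its alleles pair with the same
    D allele for some D gene.
    """
    cols = {c.lower(): c for c in annotated.columns}
    cdr3_col = cols.get("cdr3") or cols.get("junction")
    if cdr3_col is None or "v_call" not in cols:
        raise ValueError("annotated table needs a cdr3/junction column and v_call")
    v_col = cols["v_call"]

    df = annotated[[cdr3_col, v_col]].dropna().drop_duplicates()
    df = df.rename(columns={cdr3_col: "cdr3", v_col: "v_call"})
    df[["v_gene", "v_allele"]] = df["v_call"].map(_split_call).apply(pd.Series)

    # retain V alleles with enough distinct CDR3s, then heterozygous V genes
    counts = df.groupby(["v_gene", "v_allele"])["cdr3"].nunique()
    kept_alleles = counts[counts >= min_cdr3s]
    het_v = [
        g for g, sub in kept_alleles.groupby(level=0) if len(sub) >= 2
    ]
    if not het_v:
        raise ValueError("no heterozygous V gene passes the min_cdr3s filter")

    by_gene = db.genes()
    het_d = [g for g, ents in by_gene.items() if len(ents) > 1]
    gidx = gene_index(db, k_min)
    aidx = {g: allele_index(by_gene[g], k_min) for g in het_d}
    if not het_d:
        logger.warning("no heterozygous D gene in the database")
        return HaplotypeReport(het_v, {}, {}, {}, {g: True for g in het_v}, [])

    # assign each distinct CDR3 once
    uniq = df.drop_duplicates("cdr3").set_index("cdr3")
    d_call: dict[str, str | None] = {}
    for c in uniq.index:
        g = gidx.assign(c)
        if g in aidx:
            a = aidx[g].assign(c)
            d_call[c] = f"{g}*{a.split('*', 1)[1]}" if a else None
        else:
            d_call[c] = None
    df["d_call"] = df["cdr3"].map(d_call)

    matrices, assignments, haplotypes, consistent = {}, {}, {}, {}
    observed_d: set[str] = set()
    for vg in het_v:
        alleles = sorted(kept_alleles.loc[vg].index)
        sub = df[(df["v_gene"] == vg) & df["v_allele"].isin(alleles) & df["d_call"].notna()]
        joint = (
            sub.groupby(["v_allele", "d_call"])["cdr3"].nunique().unstack(fill_value=0)
        )
        assignments[vg] = {}
        norm_cols = {}
        ok = True
        for dg in het_d:
            dcols = [c for c in joint.columns if c.split("*", 1)[0] == dg]
            if len(dcols) < 2:
                continue
            observed_d.add(dg)
            block = joint[dcols].reindex(alleles, fill_value=0).astype(float)
            totals = block.sum(axis=1)
            if (totals == 0).any():
                continue
            block = block.div(totals, axis=0)
            pairing = {va: block.loc[va].idxmax() for va in alleles}
            assignments[vg][dg] = {va: da.split("*", 1)[1] for va, da in pairing.items()}
            if len(set(pairing.values())) < len(alleles):
                ok = False
            for c in dcols:
                norm_cols[c] = block[c]
        matrices[vg] = pd.DataFrame(norm_cols, index=alleles)
        consistent[vg] = ok
        haplotypes[vg] = [
            (va, {dg: m[va] for dg, m in assignments[vg].items()}) for va in alleles
        ]
    return HaplotypeReport(
        v_genes=het_v,
        matrices=matrices,
        assignments=assignments,
        haplotypes=haplotypes,
        consistent=consistent,
        d_genes=sorted(observed_d),
    )
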