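# Methods

## Generative model of CDR3 formation

A CDR3 is modelled as `v_l + e_l + s[p : |s|−q] + e_r + j_r`: a D gene `s`
drawn from a weighted set, trimmed by `p` (left) and `q` (right) with
`p + q ≤ |s|`, flanked by uniform random insertions `e_l`, `e_r`, and
embedded between a V-gene suffix `v_l` and a J-gene prefix `j_r` drawn from
weighted sets. All draws come from a single integer-seeded RNG, so one seed
fully determines a simulated dataset.

The defaults of `GenerativeModel.default` define the synthetic world used
throughout the tests:

* **Genes** — 10 random sequences, lengths evenly spread over 12–35 nt
  (the observed length range of known D genes), uniform selection weights.
* **Trimming** — P(t) ∝ 0.7ᵗ, left trim capped at |s| and right trim at
  |s|−p. Mean ≈ 2.3 nt per side, matching the qualitative picture of heavy
  but mostly partial exonuclease removal.
* **Insertions** — lengths uniform on [0, 6]; symbols uniform over ACGT.
* **V/J flanks** — the length-3…8 suffixes (prefixes) of three base V (J)
  sequences, uniformly weighted. Realising `V_cdr3`/`J_cdr3` as graded-
  length trims of a few base sequences emulates variable V/J end trimming;
  it also keeps the first nucleotide beyond a D gene close to uniformly
  distributed, as in real repertoires where the J entry point varies. A
  single fixed-length J prefix would instead create an artificial non-D
  abundance signal that walks the extension into the J gene.

What the simulator deliberately does **not** model: somatic hypermutation
(available separately as the `mutate_cdr3s` confounder utility), selection,
clonal expansion, D–D fusions, and non-uniform insertion composition. A
green planted-recovery test therefore establishes correctness of the
inference machinery under recombination-like statistics, not robustness to
every artefact of real Rep-seq data.

## The one-sided trimming model and seed reconstruction

For a single seed `s` with uniform trimming integer k ∈ [0, |s|] and uniform
replacement symbols, P(c|s) = K(|s|,|A|)·(|A|^(m+1) − 1) with m the longest
shared prefix of s and c and K = 1/((|s|+1)·|A|^|s|·(|A|−1)). Both the
per-trim form and the closed form are implemented, with optional exact
rational arithmetic used by the normalisation tests.

`score_set` uses the natural logarithm; any base is a positive rescaling and
leaves the argmax unchanged. The greedy reconstructor resolves abundance
ties by the alphabetically smallest symbol, making reruns deterministic.
`brute_force_reconstruct` is an exhaustive argmax (capped at 10⁷ candidates,
ties lexicographic) that serves as the testing oracle for the reconstruction
objective; it stands in for an exact algorithm whose construction is not
public.

## Extension engine

* Candidate (j+1)-mer abundances are multiplicity-weighted occurrence
  counts. CDR3s are grouped by multiplicity and joined with a separator so
  counts use C-level substring search; occurrences are counted
  non-overlapping, which differs from overlapping counting only for
  periodic strings and is negligible at j ≥ 10.
* A CDR3 where the current string abuts the boundary contributes to no
  extension on that side.
* Significance threshold α = 10⁻³⁰ (both sides and the 3-way branch test):
  the stopping rule is meant to fire only on extreme departures from
  uniformity, i.e. when one extension symbol is essentially templated.
  With this α a side needs roughly S ≳ 140 to extend, so seeds supported by
  fewer than ~50 CDR3s never grow — an intentional guard against noise
  seeds.
* Branching forks at most 8 branches per seed (deepest-first; the cap is
  logged when hit). Termination is guaranteed by `max_len` = 50 nt, above
  the longest known D gene (42 nt).

## Filtering and merging choices

* **Unidirectional filter** — an extension with zero steps on either side is
  dropped. Such extensions arise from seeds straddling a gene edge and
  random sequence; their bidirectional counterparts reconstruct the same
  gene. This is our interpretation of a filter whose exact published rule
  is not public; `keep_unidirectional=True` disables it.
* **Relative-position clustering** — deterministic 1-D k-means, k = 3,
  fixed initial centroids (0.1, 0.5, 0.9), ≤ 100 iterations; empty clusters
  keep their centroid. The middle final centroid is the D cluster. Fewer
  than three extensions, or fully degenerate positions, are all labelled D
  with a warning rather than guessed.
* **Clique merging** — maximal cliques via Bron–Kerbosch with pivoting;
  cliques processed in decreasing size (ties: lexicographically smallest
  member), each node consumed once, so overlapping maximal cliques cannot
  make the output order-dependent. The clique core (longest common
  substring of all members, ties lexicographic) is re-extended with the
  branch-free stopping rule; cores shorter than 6 nt abort the merge and
  pass members through. Cross-dataset consolidation drops substrings and
  merges near-duplicates without re-extension (there is no single dataset
  to re-extend on).

## Annotation conventions

Percent identity is computed by an ungapped overlap scan over all relative
offsets, with denominator min(|a|, |b|): known D-gene variants differ by
substitutions and end truncations, so gaps are not modelled, and the
min-length denominator penalises neither direction of truncation. The
`in_db` relation strips up to `extension` (default 3) nucleotides from each
candidate end and asks whether the remaining core occurs in a database
entry. Closest-entry ties resolve by identity, then overlap length, then
gene name.

## Usage, decoys and haplotyping

* Usage counts **distinct** CDR3s, not read-weighted multiplicities.
* Assignment scans a CDR3's substrings from the longest length downward and
  stops at the first length with a unique-substring hit; a tie between
  genes at that length makes the CDR3 non-traceable (no gene wins the
  longest-unique-match criterion).
* Allele resolution re-applies the same rule among the assigned gene's
  alleles only; allele-ambiguous CDR3s count toward the gene but toward no
  allele, so allele shares are over allele-assignable CDR3s.
* Decoy alleles are generated as all per-site substitution combinations of
  the gene's first allele (minus sequences already present), labelled
  `FA<n>` and truncated at a cap. Sites and alternatives are user-supplied:
  the reference sites are published only as a figure, not machine-readable.
* Haplotyping keeps V alleles with ≥ `min_cdr3s` (default 1000) distinct
  CDR3s, builds the joint (V allele × D allele) distinct-CDR3 matrix,
  row-normalises within each D gene, and pairs each V allele with its
  argmax D allele. A V gene is flagged inconsistent when two of its alleles
  pair with the same D allele of some D gene.

## Numerical and degenerate-input notes

* All-zero extension counts are a "no data" outcome: S = 0, p = 1, accept.
* `extension_test` requires exactly df+1 counts (4-way side test df 3,
  3-way branch test df 2); expected counts are total/(df+1).
* Consensus construction groups equal-length sequences only (Hamming
  distance is undefined otherwise), visits sequences in decreasing
  multiplicity, never chains groups, and resolves per-position ties toward
  the group seed.
* Inference contains no randomness; only the simulator consumes an RNG
  seed. Pipeline reruns with identical inputs and configuration produce
  byte-identical outputs.

## Known limitations

* The V/D/J position classifier assumes all three clusters are populated;
  datasets whose abundant k-mers are exclusively D-derived fall back to
  "everything is D", which is safe for candidate inference but weakens the
  V/J filter.
* Percent identity is ungapped; a germline variant with a true internal
  indel would be under-scored (a gapped mode exists behind the
  `best_overlap` building block but is not the default).
* The unique-k-mer usage assignment ignores sequencing errors inside the
  matched k-mer; heavily hypermutated repertoires should be analysed with
  decoy alleles, as the robustness utilities demonstrate.
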