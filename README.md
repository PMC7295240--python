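# miningd

De novo inference of immunoglobulin **D (diversity) germline genes** from
antibody-repertoire CDR3 sequences, for immunogenomics researchers working
with AIRR-seq data — including species whose germline loci are poorly
characterised.

## The problem and the method

During V(D)J recombination a D gene is trimmed on both ends, flanked by
untemplated insertions and joined between a V-gene suffix and a J-gene
prefix to form the CDR3. Because D genes are short and heavily trimmed,
alignment-based germline inference (which works for V and J) fails for D.
This package infers D genes directly from the statistics of CDR3 k-mers:

1. **Seeds.** The *m* most abundant 10-mers of a CDR3 dataset are taken as
   seeds (trimmed D-gene substrings dominate the abundance ranking).
2. **Extension.** Each seed is grown one nucleotide at a time. For the four
   possible extensions on a side with abundances N_A, N_C, N_G, N_T, the
   statistic

   S = Σᵢ (Nᵢ − Eᵢ)² / Eᵢ,  Eᵢ = (Σ Nⱼ)/4,

   is ~χ² with 3 df under the null that the neighbouring base is a uniform
   random insertion. A rejected side (p < α, default α = 10⁻³⁰) is extended
   by its most abundant symbol; extension stops when both sides accept.
   After each step the remaining three extensions are tested against
   uniform (χ², 2 df): rejection means the seed sits in *two* D genes, and
   an independent branch is forked from the runner-up.
3. **Filtering.** Extensions that grew on one side only are dropped; the
   mean *relative position* RP_c(s) = I_c(s)/(|c|−|s|+1) across CDR3s
   separates V-, D- and J-derived extensions into three 1-D clusters, and
   only the central (D) cluster is kept.
4. **Merging.** Extensions with Dist(e₁,e₂) = min(|e₁|,|e₂|) − |LCS(e₁,e₂)|
   ≤ 2 form cliques in a similarity graph; each clique is replaced by the
   longest common substring of its members, re-extended with the stopping
   rule.
5. **Annotation & analytics.** Candidates are classified against a germline
   database (`in_db` / `novel_variation` / `novel_gene`, 75 % identity
   threshold), and downstream tools compute per-gene/allele **usage** via
   unique k-mers (≥ 8 nt), decoy-allele robustness checks, over-usage
   against reference cohorts, and V-gene **haplotyping** through
   heterozygous D genes.

The package also implements the underlying probabilistic model of CDR3
generation — including the exact likelihood of the one-sided trimming model,
P(c|s) = K(|s|,|A|)·(|A|^(m+1)−1), greedy and brute-force seed
reconstruction — and a full V(D)J simulator used as the synthetic-data
engine for all tests.

## Worked example

```python
from miningd import GenerativeModel, PipelineConfig, simulate_cdr3s
from miningd.pipeline import infer_genes

model = GenerativeModel.default(1)                 # 10 random D genes, 12-35 nt
cdr3s, truth = simulate_cdr3s(model, 50_000, rng_seed=1)
res = infer_genes(cdr3s, PipelineConfig(min_dataset_size=0))
print(res.funnel)
```

prints

```
{'seeds': 600, 'extensions': 600, 'after_unidirectional_filter': 126,
 'unique': 11, 'central_cluster': 10, 'post_merge': 10}
```

— 600 seeds collapse to exactly 10 candidate genes: the unidirectional
filter removes boundary-straddling seeds, relative-position clustering
removes V/J-derived extensions, and clique merging collapses duplicate
reconstructions. All 10 candidates match the planted genes, and the
unique-k-mer usage machinery traces 93 % of the simulated CDR3s to their
generating gene.

The same pipeline is available from the shell:

```bash
mine simulate --n 50000 --rng-seed 1 --out sim.fasta
mine run sim.fasta --out-dir run/          # candidates + manifest.json
mine annotate run/candidates_consolidated.fasta germline_d.fasta --out ann.tsv
```

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
re-runs the package's main computation from scratch: it simulates a 50,000-
CDR3 repertoire from a fresh synthetic locus, infers D genes with the
default configuration, classifies them against the true locus and computes
gene usage, then writes the results JSON to `--out`.
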