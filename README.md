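# its2gc

Structure-partitioned GC-evolution analysis of ITS2 allele families.

The internal transcribed spacer 2 (ITS2) of nuclear ribosomal DNA is a
multicopy marker that is homogenized within a genome by concerted evolution
(unequal crossing-over and gene conversion).  Because the mismatch repair that
accompanies gene conversion favors G/C over A/T alleles (GC-biased gene
conversion, gBGC), homogenization and GC enrichment are predicted to go hand
in hand — and the effect should be strongest in the base-paired stems of
ITS2's conserved secondary structure, where GC pairs are also thermodynamically
favored.  `its2gc` is a pipeline for testing these predictions on per-species
allele sets given as aligned sequence–structure matrices (Vienna triplets:
header / sequence / dot-bracket).

For each species the pipeline

1. removes single-copy alleles (likely assembly artifacts),
2. derives the consensus secondary structure (base pairs supported by at
   least a threshold fraction of alleles, default 0.70) and partitions
   alignment columns into *paired* and *unpaired* regions,
3. computes GC content per region, its homogeneity (SD across alleles), and
   the allele diversity K (mean pairwise nucleotide differences),
4. fits substitution models by maximum likelihood on a neighbor-joining guide
   tree and selects among candidates by AICc — unpaired columns under a
   4-state DNA model (HKY85 or REV), stem pairs under a 16- or 7-state
   base-pair (doublet) model in which both nucleotides of a pair never change
   simultaneously, so pair turnover passes through intermediates
   (GC – GU – AU); an optional Metropolis–Hastings sampler provides
   posterior (equilibrium-state) parameter estimates,
5. derives the GC-dynamics statistics from the fitted rate matrix Q with
   stationary frequencies π (normalized to unit mean rate, −Σ πᵢ qᵢᵢ = 1):
   * **GC\*** (equilibrium GC): for unpaired regions
     GC\* = u/(u+v) with u the stationary A/T→G/C rate per A/T base and v the
     reverse; for paired regions the GC composition of the doublet chain's
     stationary distribution (solve πQ = 0),
   * **formation rates**: the six single-change routes into GC-type pairs
     {GC, CG} versus the six into AU-type pairs {AU, UA}, and their ratio,
   * **mismatch-conversion bias**: for the four heteroduplex mismatches
     (A·G, A·C, C·U, G·U), the one-side repair rates toward GC-type versus
     AU-type pairs,
6. correlates K with GC per region across species (Spearman) — the gBGC
   signature is a negative K–GC correlation in paired regions.

A synthetic allele-family generator (`its2gc.synth`) reproduces the assumed
generative process — four-stem structure, GC-rich stems, Yule species tree,
doublet substitution with a tunable gBGC multiplier λ, incomplete
homogenization h — so every stage runs and is testable without external data.

## Worked example

```python
from its2gc import (SynthConfig, simulate_family, consensus_structure,
                    partition_columns, gc_report, avg_nucleotide_differences,
                    select_model, formation_rates, gc_star_pair,
                    gc_star_nucleotide, gc_trend)

matrices, truth = simulate_family(SynthConfig(n_species=3, alleles_per_species=8,
                                              homogenization=0.4, seed=1))
m = matrices[0]
cons = consensus_structure(m, threshold=0.70)
part = partition_columns(cons, m.ncols)
rep = gc_report(m, part)
print(rep.gc_total, rep.gc_paired, rep.gc_unpaired,
      avg_nucleotide_differences(m.records))

best, ranking = select_model(m, part, ["HKY85+RNA7", "HKY85"], maxiter=100)
print(ranking[["family", "logL", "k", "AICc"]])
print(formation_rates(best.pair_model).ratio)
print(gc_trend(rep.gc_paired, gc_star_pair(best.pair_model), region="paired"))
```

Output:

```
sp01: 8 alleles, GC 76.83%  GCp 81.98%  GCup 72.41%  K 18.54
    family        logL  k        AICc
HKY85+RNA7 -611.174755 19 1264.571733
     HKY85 -694.067117  4 1396.339361
formation-rate ratio GC:AU = 3.79
paired   GC 81.98% -> GC* 81.82%  (decreasing)
```

Reading: this simulated species carries 8 retained alleles whose stems are
~10 GC-percentage-points richer than the loops (GCp vs GCup), as expected
when pair formation is GC-biased.  The mixed DNA+doublet candidate beats the
DNA-only model by >130 AICc units — the stems evolve as correlated pairs, not
as independent sites.  The fitted formation-rate ratio of 3.8 means
single-nucleotide routes into GC/CG pairs run ~4× faster than routes into
AU/UA (the family was simulated at λ = 3), and GC* ≈ current GC says the
paired region is near its compositional equilibrium.

The same analysis runs from the shell:

```bash
its2gc simulate --out family/ --n-species 6 --seed 1
its2gc analyze --input family/ --out run/ --seed 1
its2gc report --run run/
```

`analyze` writes `gc_table.tsv`, `diversity_table.tsv`, `correlations.tsv`,
`model_selection.tsv`, `transformation_rates.tsv`, `gcstar_table.tsv` and
`run_metadata.json`.

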