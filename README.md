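# genrelate

Comparative-genomics relatedness analysis for fungal strains, built around
the workflow used to place an entomopathogenic fungal isolate (an EPF —
a fungus that infects and kills arthropods) taxonomically and to quantify
how its insecticidal-factor gene repertoire is conserved across relatives:

* **ANIb** — fragment-based average nucleotide identity: the query genome is
  cut into 1020 nt fragments, each is locally aligned to the subject with a
  self-contained BLASTN-style aligner, and ANIb is the mean identity
  percentage over fragments passing the conventional 30%-identity /
  70%-coverage filters.  ANIb ≥ 95–96% is the usual conspecificity rule.
* **dDDH** — digital DNA–DNA hybridization: all high-scoring segment pairs
  (HSPs) between two genomes are summed into a distance
  `d = 1 − Σ identities / Σ alignment columns`, then mapped through a
  logistic curve onto the 0–100% dDDH scale (70% = species boundary).
* **BSR** — BLAST score ratio: each gene's best bit score against a target
  genome divided by its self-score against its source genome; ratios are in
  [0, 1] and values over 0.4 call a homolog.  Per-category summaries give
  the percentage of exoenzyme / toxin / NRPS / PKS genes with homologs.
* **Relatedness statistics** — the ordinal taxonomic-relatedness degree
  (1 = same species, 2 genus, 3 family, 4 order, 5 subphylum), linear
  regression of ANIb/dDDH on degree with 95% confidence and prediction
  bands, and the Pearson correlation matrix over ANIb, dDDH and the four
  homolog percentages.
* **Bioassay statistics** — one-way ANOVA on replicate-level mortality
  percentages with Fisher's protected LSD and a compact-letter display.
* **Synthetic data** — genomes at controlled divergence (substitutions,
  indels, rearrangements), degree-stratified gene families with a
  ground-truth presence table, and binomial dose–mortality tables, so every
  stage is testable with no downloads.

Bit scores use the Karlin–Altschul normalisation
`S' = (λ·S − ln K) / ln 2` with BLASTN-like defaults (match +2, mismatch
−3, gap open −5, gap extend −2, λ = 0.625, K = 0.41, word size 11).

A relatedness table for *Beauveria pseudobassiana* RGM 2184 against 27 EPF
strains ships with the package, so the headline statistics are computable
in under a second without any genome download.

## Worked example

```python
>>> from genrelate import generate_ancestor, evolve_genome, EvolutionParams, anib
>>> ancestor = generate_ancestor(length=50_000, gc_content=0.517, seed=1)
>>> evolved, realized = evolve_genome(ancestor, EvolutionParams(substitution_rate=0.05, seed=2))
>>> res = anib(evolved, ancestor)
>>> round(res.anib_percent, 2), res.n_accepted, res.n_fragments
(95.12, 49, 49)
```

The pair was simulated at a 4.9% realised per-site divergence, so ANIb
lands at 95.1% — the method recovers `100·(1−δ)` and the pair sits right at
the 95–96% species boundary.  On the packaged 27-strain table:

```python
>>> from genrelate import load_reference_table, pearson
>>> t = load_reference_table()
>>> round(pearson(t["anib"], t["degree"]), 2)
-0.96
>>> round(pearson(t["anib"], t["exo_pct"]), 2)
0.96
```

ANIb decays almost linearly with the relatedness degree, and the fraction
of the reference strain's exoenzyme genes with BSR homologs tracks ANIb
closely — the genomic signature that the insecticidal-factor repertoire is
largely genus-specific.

The `examples/` directory has one short script per capability
(simulation, ANIb, dDDH, BSR screen, relatedness statistics, bioassay
ANOVA/LSD, and the end-to-end pipeline).  A thin CLI exposes the same
stages as `genrelate simulate|anib|ddh|bsr|relate|bioassay|run`.

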