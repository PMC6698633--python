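# rhizodem

Population genetics and demographic inference for multilocus sequence
typing (MLST) data from haploid bacteria.

Rhizobial symbiosis genes — the nodulation (*nod/nol*) and nitrogen-fixation
(*nif*) loci that let *Mesorhizobium* and relatives nodulate legumes such as
black locust (*Robinia pseudoacacia*) — travel on mobile elements and have
evolutionary histories of their own, distinct from the chromosomes that
carry them. Reconstructing those histories from aligned multilocus sequence
data means answering a chain of questions: how much variation is there and
is it neutral; do loci recombine or are they clonal; how are haplotypes
related; when did populations expand; and which explicit demographic
scenario (sequential divergence, simultaneous radiation, ghost-lineage
ancestry) best explains the clade structure. `rhizodem` implements that
chain for researchers analysing bacterial MLST datasets of a few hundred
strains at a handful of loci.

## What it computes

* **Diversity and neutrality** (`popgen_stats`): segregating sites S, mean
  pairwise differences π, Watterson's θ_w = S/a_{n−1}, haplotype diversity
  Hd, Tajima's D, Fu's F_s = ln(S′/(1−S′)) with S′ = P(K ≥ k_obs | θ = π̂)
  from the Ewens sampling formula, and Nei–Gojobori p_N/p_S and d_N/d_S.
  D and F_s p-values come from neutral coalescent simulation conditional on
  (n, S).
* **Linkage and homoplasy** (`linkage_recomb`): the index of association
  I_A = V_O/V_E − 1 over per-locus allele mismatches with a permutation
  test on clone-corrected data, and the homoplasy index
  H = (L_obs − L_min)/(L_free − L_min) from Fitch parsimony against a
  column-shuffling free-recombination expectation.
* **Haplotype networks** (`haplotype_network`): minimum spanning networks
  with tie retention (all co-minimal edges kept), GraphML/TSV output.
* **Mismatch distributions** (`mismatch_demography`): observed spectra;
  closed-form expectations under constant size
  (F_i = θ^i/(1+θ)^{i+1}), sudden demographic expansion (τ, θ0, θ1) and
  infinite-island spatial expansion (τ, θ, M); least-squares fitting;
  Harpending's raggedness; parametric-bootstrap goodness of fit and τ
  confidence intervals; τ = 2ut time conversions.
* **Coalescent simulation** (`coalescent_sim`): a native multi-deme
  structured-coalescent engine (haploid scale, θ = 2NμL) with divergence
  events, ghost demes, exponential growth, migration, and infinite-sites
  mutation; an exact infinite-island sampler; YAML scenario files.
* **ABC model choice** (`abc_inference`, `scenarios`): prior sampling,
  reference tables over a 21-statistic panel, Euclidean rejection,
  linear-Gaussian ABC-GLM posterior model probabilities and Bayes factors
  (BF > 3 decision rule), regression-adjusted parameter posteriors, and
  validation by pseudo-observed datasets: type I/II error, posterior
  predictive p-values, and posterior-quantile coverage (KS uniformity).
* **Synthetic study emulation** (`synthetic_data`): a generator that
  reproduces the three-clade, 286-strain, eleven-locus sampling design of
  the motivating system, with known ground truth for every parameter.

See `docs/methods.md` for the models, conventions (haploid θ = 2Nu
everywhere), and known limitations.

## Worked example

Generate a small synthetic dataset (43 strains, 11 loci, three clades) and
run the per-locus summary, linkage test, and mismatch dating:

```bash
rhizodem synth --seed 7 --out data --scale 0.15
rhizodem stats --data data --out stats.tsv --reps 200 --seed 1
rhizodem linkage --data data --n-perm 1000 --seed 2 --out ia.tsv
rhizodem mismatch --data data --seed 4 --bootstrap 100 --out mm.tsv
```

`stats.tsv` (abridged) shows the engineered order-of-magnitude diversity
gap between symbiotic and housekeeping loci — per-site π × 10³ of 1–6 for
*nodA*–*nolT* versus 31–48 for *recA*–*gryB* — with no locus deviating
significantly from neutrality:

```
locus  n  alleles   S  pi_per_site_x1000  tajima_d  tajima_p
 nodA 43        5   4              0.965    -1.037     0.145
 nodC 43       12  17              5.648     0.471     0.735
 recA 43       19  96             48.144     0.111     0.625
 gryB 43       28 119             31.440    -0.674     0.225
```

`ia.tsv` detects the clonal multilocus structure: on the 38 clone-corrected
strains the symbiotic loci give I_A = 1.42 with p = 0.001 (no permutation
out of 1,000 reached the observed value), while the per-locus homoplasy
indices are 0 — no recombination signal inside loci:

```
I_A     1.4212
p_value 0.000999
H_nodA  0.0
```

`mm.tsv` dates expansions per clade. Clade II — simulated with a recent
100-fold expansion — has a mean of only 0.25 pairwise mismatches and an
expansion fit at τ ≈ 0.31 (95% CI 0–0.95), i.e. a very young clade, whereas
Clade III shows τ ≈ 5.5 and the whole mixed sample τ ≈ 18:

```
group  n  mean_mismatches  tau_dem  p_ssd_dem      tau_ci_dem
  All 43           12.930   18.167       0.00       13.5,22.9
  CII 15            0.248    0.306       0.72  6.64e-18,0.946
 CIII 13            6.436    5.458       0.27       4.27,9.54
```

With τ = 2μLt, μ = 10⁻⁸/site/generation and L = 3,308 bp, Clade II's
τ ≈ 0.31 converts to ≈ 4,600 generations — `rhizodem` simulated it at
3,690 — and at ≤ 30 bacterial generations per year that is on the order of
a few centuries.

ABC scenario comparison runs the same way from the shell
(`rhizodem abc sim|choose|estimate|validate`) or from Python; see
`tests/test_acceptance.py::test_abc_model_choice_end_to_end` for a complete
in-code example.

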