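# dietcnv

Phylogenetic comparative analysis of diet-associated gene copy-number
convergence in mammals.

Mammalian lineages have shifted repeatedly among herbivory, carnivory and
omnivory, and some gene families (amylases, olfactory receptors,
xenobiotic-metabolism enzymes) expand convergently with those shifts.
`dietcnv` implements the full analysis chain for asking whether gene-family
copy numbers track trophic ecology once phylogeny is accounted for, and
whether trophic ecology can be predicted back from copy numbers:

1. **Screen** — nominate families whose copy-number distribution is
   strikingly elevated in one trophic category: median ratio in/out ≥ 2,
   ≥ 90% of in-group species with ≥ 1 copy, ≥ 70% of out-group species with
   ≤ 2 copies.
2. **Phylogenetic correction** — a Bayesian Poisson mixed model per family,
   y_s ~ Poisson(exp(a + β x_s + u_s + e_s)) with u ~ MVN(0, σ²ₚC) where C
   is the Brownian-motion covariance of the tree, inverse-Wishart(V=1,
   ν=0.002) priors on the variances, and the two-sided tail probability
   pMCMC = 2·min(P(β>0), P(β<0)) for the category effect.
3. **Phylogenetic signal** — Pagel's λ by profile maximum likelihood with a
   likelihood-ratio test, and Blomberg's K with a tip-permutation test.
4. **Discriminant functions** — Fisher LDA between herbivores and
   carnivores (w ∝ S⁻¹(m_h − m_c)), Wilks'-λ stepwise forward selection,
   leave-one-out and clade-holdout validation, and a phylogenetic variant
   (pFDA) that whitens the data by the Cholesky factor of the λ-scaled
   covariance before discriminating, scanning λ from 0 to 0.1.
5. **Duplication modes** — tandem vs interchromosomal calls by the 5-Mb
   same-chromosome co-location rule.
6. **Quantitative trophic levels** — TL_i = 1 + Σⱼ DC_ij·TL_j / Σⱼ DC_ij
   from diet compositions, regressed against copy numbers and discriminant
   scores with the same phylogenetic mixed model.

A synthetic-data generator (pure-birth tree, Markov-chain trophic states,
Poisson log-normal copy numbers with planted category effects, locus tables
and diet compositions) makes every stage testable end to end without any
downloads. It draws from exactly the generative model the mixed model fits,
so parameter recovery is a fair check of the inference.

## Worked example

The `analysis/` scripts run the whole pipeline on one synthetic dataset
(32 species, 100 families, 10 planted herbivore-high families with a log
effect of ln 4):

```sh
cd analysis
python 01_simulate.py && python 02_screen.py && python 03_comparative.py
python 04_discriminant.py && python 05_pfda.py
python 06_dupmode.py && python 07_trophic_levels.py
```

Output from `02_screen.py` and `04_discriminant.py`:

```
herbivore: 10 families pass: fam1, fam10, fam2, fam3, fam4, fam5, fam6, fam7, fam8, fam9
planted recovery: 10/10 herbivore-high families found

discriminant families: 10 -> 3 after stepwise selection (fam4, fam8, fam9)
Wilks' lambda: 0.130 (full) vs 0.169 (selected)
LOOCV accuracy: 77.3% (full), 100.0% (selected)
```

The screen recovers all ten planted families; stepwise selection keeps
three of them at a modest cost in Wilks' λ (0.169 vs 0.130 — smaller means
better separation) while leave-one-out accuracy improves, the usual sign
that the full model overfits. `05_pfda.py` reports an optimal λ of 0 —
with labels this well separated, phylogenetic whitening does not improve
the training misclassification — and `07_trophic_levels.py` shows the
planted families' copy numbers and the discriminant score falling with
quantitative trophic level (herbivores sit at TL = 2), e.g.
`df_score beta=-14.24 pMCMC=<0.0004`.

The same pipeline is scriptable through the CLI:

```sh
dietcnv all --config pipeline.yaml --seed 7 --outdir results/
```

Every output table carries a header with the config hash and seed; two
runs with the same config are byte-identical.

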