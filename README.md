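# seedtrans

Seed-to-seed transmission analysis of plant-associated bacterial and
fungal communities.

When a plant passes microbes to its offspring through seeds, the signal
is longitudinal: OTUs that persist from parent seeds through the growing
plant into progeny seeds, abundance trajectories that rise toward
ripening, progeny communities that converge on the parental one, and
source-sink structure that points at the tissues the colonists came
through. `seedtrans` turns an OTU count table with compartment/age/replicate
metadata into that full analysis:

- **Data model and statistics** — count tables, CSS (cumulative-sum
  scaling) and CLR normalization, Bray-Curtis/Jaccard dissimilarity,
  PCoA, one-factor PERMANOVA with R², Kruskal-Wallis + Dunn post-hoc
  tests with compact letter displays, BH-FDR throughout.
- **Transmission** — vertically transmitted OTUs (detected in all three
  seed generation groups on across-replicate means), successional modes
  (Early / Mid-no-trend / Late by the sign and significance of the OLS
  slope of relative abundance on host age), parent-progeny convergence
  trajectories, core OTUs by prevalence, Venn overlaps.
- **Niche vs neutrality** — per-OTU niche responsiveness
  h² = Var(age effect) / (Var(age effect) + σ²_replicate + σ²_residual)
  from a REML linear mixed model with a parametric bootstrap
  (High > 0.4, Moderate 0.2–0.4, Low ≤ 0.2), and Sloan's neutral
  community model: occurrence frequency predicted from metacommunity
  abundance p, community size N and migration rate m via
  `1 − I_d(Nmp, Nm(1−p))` with d = 1/N, OTUs partitioned
  above / neutral / below the 95% interval.
- **Source tracking** — mixture-of-multinomials EM with a latent
  Unknown source: sink distribution `Σ_j α_j γ_j`, responsibilities
  `r_ij ∝ α_j γ_j(i)`, closed-form α updates, optional joint profile
  updates, monotone log-likelihood asserted at every iteration.
- **Networks** — SparCC-style compositional correlation inference
  (Dirichlet resampling, log-ratio variation matrix, basis-variance
  linear system, exclusion iterations, median over resamples),
  permutation p-values, |ρ| > 0.3 ∧ FDR < 0.05 edges, node metrics,
  10-node hub sets, ABC / GA / Bertz complexity indices, meta-network
  merging with per-edge context provenance, Louvain modules,
  hypergeometric and binomial taxon-pair enrichment, edge-set Jaccard
  similarity between networks.
- **Synthetic data** — every stage has a generator dual that plants a
  known truth (migration rate, source mixture, trend OTUs, transmitted
  set, basis correlations), so the whole pipeline is testable end to
  end without field data.

## Worked example

```bash
python examples/03_neutral_model.py
```

```
true m = 0.1, fitted m = 0.0965 (3.5% off), R2 = 0.991
Sloan threshold approximation fits m = 0.1196 (biased up on read-sampled data; see docs/methods.md)
partition  n_otus  mean_abundance  mean_freq_obs
    above      19        0.021035       0.928154
    below      12        0.001837       0.195106
  neutral     164        0.003526       0.364547
```

126 local communities were sampled from the neutral model itself
(N = 1000, m = 0.1) and refit: the migration rate comes back within a
few percent, the occurrence-abundance relationship explains 99% of the
variance, and most OTUs are (correctly) called neutral — the `above`
and `below` tails are the OTUs whose sampled occurrence fell outside
the 95% band. The other examples cover ordination/PERMANOVA (`01`),
transmitted-OTU calls, succession and convergence (`02`), EM source
tracking (`04`) and SparCC networks plus the meta-network (`05`);
each prints the planted truth next to its estimate.

A config-driven pipeline runs all stages and writes TSV/JSON artifacts
with a reproducibility manifest:

```bash
seedtrans run --stages simulate,normalize,transmission,sources --seed 7 --out-dir results/
```

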