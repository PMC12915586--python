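# amplitrait

Trait-based temporal analysis of 16S amplicon communities.

Microbial succession is often summarised taxonomically, but community-level
*genomic traits* — average genome size and rRNA operon copy number (RRN) —
track life-history strategy directly: high-RRN, small-genome bacteria grow
fast and dominate early, resource-rich stages; low-RRN, large-genome
bacteria are slower growers favoured as habitats mature. `amplitrait`
implements the full analysis chain needed to test for such a fast-to-slow
shift in amplicon time series from plant-associated (air / leaf / root)
communities under a nitrogen-addition treatment:

1. **Trait annotation.** Each OTU representative sequence is matched against
   a trait reference (16S regions keyed by genome accession, with genome
   size in Mb and RRN) by semi-global pairwise alignment. A hit is accepted
   only at identity ≥ 95% **and** query coverage ≥ 95% (both configurable).
2. **Community-weighted means (CWM).** Per sample,
   CWM(t) = Σᵢ nᵢ tᵢ / Σᵢ nᵢ over trait-assigned OTUs i with read counts
   nᵢ, reported together with the assigned read fraction per trait.
3. **Temporal statistics**, implemented from their definitions: rarefaction
   to uniform depth (default 2000 reads), Shannon/richness, Bray–Curtis
   dissimilarity, PCoA, PERMANOVA (sequential SS, permutation p, optional
   strata), Mantel tests of community dissimilarity against temporal
   distance, Spearman trait–time trends, Kruskal–Wallis with Bonferroni.
4. **Threshold indicator taxa analysis.** Per taxon, candidate change
   points along the time gradient are scored by the indicator value
   IndVal = 100·A·B; the change point maximises a permutation z-score, and
   bootstrap purity/reliability (both ≥ 0.95) decide retention. Retained
   increasers vs decreasers are then contrasted in genome size and RRN.
5. **Synthetic study generator.** A fully seeded generator emulates the
   air/leaf/root × 7-time-point × control/N-addition design with planted
   guild turnover (a large-genome/low-RRN guild rising in roots, a
   small-genome/high-RRN guild declining), Dirichlet–multinomial counts,
   site effects, and partial reference coverage — so the whole pipeline is
   testable without any external database or download.

## Worked example

```python
import amplitrait as at

bundle = at.simulate_study(seed=1)
rare, dropped = at.rarefy(bundle.counts, depth=2000, seed=1)
print(f"{rare.shape[0]} samples retained at 2000 reads ({len(dropped)} dropped)")

assignments = at.assign_traits(bundle.otus, bundle.reference)
n_ok = sum(a.assigned for a in assignments.values())
print(f"{n_ok}/{len(assignments)} OTUs assigned traits at >=95% identity/coverage")

profiles = at.community_weighted_traits(rare, assignments)
meta = bundle.metadata.loc[rare.index]
for comp in ("root", "air"):
    idx = meta[meta.compartment == comp].index
    res = at.spearman_trend(
        meta.loc[idx, "time_point"].to_numpy(float),
        profiles.loc[idx, "mean_genome_size_mb"].to_numpy(),
    )
    print(f"{comp}: genome-size trend rho = {res.rho:+.3f} (p = {res.p_value:.2g}, n = {res.n})")
```

prints

```
220 samples retained at 2000 reads (32 dropped)
50/60 OTUs assigned traits at >=95% identity/coverage
root: genome-size trend rho = +0.959 (p = 4.1e-40, n = 72)
air: genome-size trend rho = +0.017 (p = 0.89, n = 71)
```

The root community's weighted mean genome size climbs strongly with time
while the airborne community — the colonisation source — stays flat: the
planted fast-to-slow succession signal, recovered end to end through
rarefaction, alignment-based annotation and the trend test.

The same analysis is available from the shell:

```bash
amplitrait run --seed 1 --out-dir runs/demo
```

which writes every intermediate (rarefied counts, assignments, trait
profiles, Bray–Curtis matrix, PERMANOVA/Mantel/trend tables, indicator
screen, trait contrast) as tab-separated files plus a `report.json`.
`amplitrait simulate / annotate / stats / indicators` run the individual
stages on your own files.

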