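# cophylokit

Cophylogenetic analysis of host–parasite systems: who speciated with
whom, and how.

Built for the kind of study where a clade of host-specific parasites
(here motivated by *Cichlidogyrus* monogenean flatworms on Lake
Tanganyika's tropheine cichlids) is sampled with nuclear and
mitochondrial markers and the questions are:

1. **How many parasite species are in the sample?** Haplotypes are
   clustered by pairwise genetic distance against marker-specific
   cut-offs (1% for ITS rDNA, 2% for COI): the species estimate is the
   number of single-linkage clusters of the `d < θ` graph.  Distances
   are p, Jukes–Cantor, or gamma-corrected JC
   (`d = (3α/4)[(1 − 4p/3)^(−1/α) − 1]`, α = 0.40 for ITS, 0.11 for COI).
2. **Are host and parasite phylogenies congruent?** Two independent
   routes: a ParaFit-style distance-based permutation test (global
   statistic ‖C′AB‖²_F on principal coordinates of the two distance
   matrices, host identities permuted; per-link contributions tested the
   same way), and a topology-based randomization test of the maximum
   cospeciation count against uniform (PDA) random topologies.
3. **Which event mix explains the parasite tree?** Event-based
   reconciliation with cospeciation, sorting (loss), duplication and
   host-switch events, solved exactly by dynamic programming for any
   cost scheme, with data-adaptive cost estimation (costs
   anti-proportional to the event frequencies they induce), a
   biological-plausibility filter for degenerate solutions, and a
   chronological-consistency check on the inferred switches.
4. **Did the parasite's diversification rate change over time?**
   Branching-time ML fits of rate-constant (pure birth, birth–death)
   versus rate-variable (DDL, DDX, yule2rate) models;
   `ΔAIC_RC = AIC(best constant) − AIC(best variable)` is tested
   against pure-birth trees of the same size.

A synthetic-data module generates joint host–parasite histories with
known event tallies, uniform random topologies, (density-dependent)
birth trees, and sequences evolved along trees — the ground truth every
statistical claim in the test suite is checked against.

## Worked example

Simulate a 10-host tanglegram with a cospeciation-dominated history,
then reconcile it:

```sh
$ cophylo simulate --hosts 10 --seed 7 --out data
wrote host/parasite/links/truth to data (tally {'cospeciation': 12, 'sorting': 2,
'duplication': 9, 'host_switch': 1})

$ cophylo reconcile --host data/host.nwk --parasite data/parasite.nwk \
      --links data/links.tsv --costs 0 1 1 2
{
  "counts": {"cospeciation": 11, "sorting": 1, "duplication": 8, "host_switch": 2},
  "total_cost": 13.0,
  ...
}
```

Under cospeciation-favoring costs the inferred counts (11, 1, 8, 2)
closely track the generating history (12, 2, 9, 1): the parasite tree
is read as mostly codivergence plus within-host speciation, with
host-switching rare.  Omitting `--costs` switches to adaptive cost
estimation, which ranks self-consistent cost schemes by a quality
criterion and filters implausible solutions (ones whose zero event
counts are bought with extreme costs) — see `docs/methods.md` for why
degenerate solutions arise and how they are handled.

Test for a diversification slowdown on an ultrametric tree (here a
simulated strong density-dependent tree with 37 tips):

```sh
$ cophylo ratetest --tree chrono.nwk --n-null 999 --seed 1
n_tips 37   dAIC_RC 10.61   p 0.0090
  pureBirth  AIC -46.35
  birthDeath AIC -44.35
  DDL        AIC -56.96
  DDX        AIC -55.72
  yule2rate  AIC -56.20
```

The positive ΔAIC_RC (best rate-variable model beats the best
rate-constant model by 10.6 AIC units) exceeds the statistic on 999
constant-rate trees of the same size in all but a handful of cases
(p = 0.009): the speciation rate slowed toward the present.

The full pipeline (`cophylo run --config cfg.yaml`) chains delimitation,
preprocessing (bootstrap-support collapsing, terminal single-host clade
collapsing), reconciliation with adaptive costs, both congruence tests,
the rate-shift test, and the molecular-rate calibration (e.g. 2–7%
pairwise ITS divergence over a 2.4 My host radiation ⇒ a per-lineage
rate of 0.4–1.5% my⁻¹) into one machine-readable JSON report, fully
reproducible from its master seed.

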