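# fragsar

Landscape-scale species–area relationships under simulated late-stage
habitat fragmentation.

## What it is for

In late-stage fragmentation, total habitat area and the number of habitat
patches shrink together as whole patches disappear — think of the islands of
a reservoir archipelago as the surviving fragments of a drowned landscape.
`fragsar` is for ecologists who want to ask how much of the resulting
richness loss is an *area* effect and how much is *fragmentation per se*
(spatial configuration: patch number, patch size variability, shape
complexity, isolation) — and where along the patch-loss gradient the regime
changes.

The core object is the landscape-scale species–area relationship (LSAR),

    S = c A^z,   i.e.   log10 S = log10 c + z log10 A,

fitted over *simulated landscapes*: random island subsets of fixed patch
number pn, drawn so their total areas spread evenly across a common range
(five equal-width sections, 200 replicates each; for pn = 2..50 that is
49 × 5 × 200 = 49,000 landscapes). One z per pn level yields a z-vs-PN
series, computed for five incidence views: observed, rare species only,
common species only, and two per-island-richness-preserving null models
(RDM: species identities uniform; OWRDM: weighted by observed occupancy).
A two-segment continuous regression of z on pn locates the threshold ψ
between the "responsive" phase (few patches, z rising steeply as patches
are lost) and the "stable" phase (many patches, z nearly flat), and
adjusted-R² variation partitioning splits the variance of z between total
area and the fragmentation set {PN, PSV, LSI, MDM} within each phase.

A seeded synthetic archipelago generator (152 islands, 383 species,
heavy-tailed areas, ~2/3 rare species, patch-scale SAR slope calibrated to
z = 0.16) makes the whole pipeline runnable and testable without any survey
data; real data enter as two CSVs (an island attribute table and a 0/1
species × island matrix).

## Worked example

```python
from fragsar import RunConfig, SamplerConfig, SynthConfig, run_all

cfg = RunConfig(
    synth=SynthConfig(),                  # 152 islands, 383 species
    sampler=SamplerConfig(n_reps=50),     # 49 pn-levels x 5 sections x 50
    null_replicates=20,
    outdir="scratch/readme", seed=7,
)
manifest = run_all(cfg)
```

The run (a few seconds) writes every intermediate table. Highlights of what
it printed for this seed:

```
n_rare: 261 n_common: 122 landscapes: 12250

    view    psi     r2   p
observed 7.3843 0.9615 0.0
     RDM 7.4489 0.9723 0.0
   OWRDM 6.6455 0.9714 0.0
    rare 7.7622 0.9497 0.0
  common 7.4443 0.9638 0.0

 pn_level      z  mean_richness  richness_sd   n
        2 0.2409         97.444      14.1594 250
        3 0.1781        116.004      14.4904 250
        4 0.1572        131.288      14.1494 250
        5 0.1407        144.116      14.1205 250
        6 0.1016        156.580      12.7652 250

    view      phase  frac_a  frac_b  frac_c  frac_d
observed responsive   0.001  -0.001   0.922   0.078
observed     stable   0.009  -0.005   0.783   0.213
```

Reading this: 261 of 383 synthetic species are rare (≤10% occupancy). The
observed z-series starts high (z ≈ 0.24 at 2 patches) and flattens with
more patches; the breakpoint fit puts the threshold near ψ ≈ 7.4 patches
(R² ≈ 0.96). In the responsive phase (pn < ψ) the fragmentation set
{PN, PSV, LSI, MDM} uniquely explains ~92% of the variance in z (`frac_c`)
while total area alone explains essentially none (`frac_a`) — the signature
that below the threshold, configuration, not amount, drives the area
effect. The full outputs include the two null-model z-series (RDM z
collapses toward 0 at high pn), the rare/common contrast, Spearman and
partial-Spearman tables, and a JSON manifest with all derived stage seeds.

The same pipeline is available from the shell:

```bash
fragsar synth --outdir data --seed 7
fragsar resample data/islands.csv --incidence data/incidence.csv --out landscapes.csv
fragsar lsar landscapes.csv --out zseries.csv
fragsar breakpoint zseries.csv
fragsar run-all --synthetic --seed 7 --outdir out
```

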