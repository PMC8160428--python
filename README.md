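# germfilter

Trait-based analysis of how nitrogen addition filters seed-germination
strategies in plant communities — a tested, reproducible pipeline from raw
germination-trial counts and vegetation quadrats to species- and
community-level inference.

## The scientific problem

Nitrogen enrichment (fertilization, atmospheric deposition) changes which
plant species persist in a grassland. One underexplored mechanism is
selection on *seed germination traits*: if a denser, darker, moister canopy
after fertilization changes the conditions seeds experience, the
environmental filter should favour particular germination strategies —
high and fast germination, germination cued by temperature fluctuation (a
canopy-gap signal), a broad thermal niche — and select against others, such
as a cold-stratification requirement.

`germfilter` implements the quantitative machinery for testing this:

**Species-level indices** from germination trials (3 replicates × 50 seeds
per condition, checked daily for 60 days, at constant 5/10/15/20/25 °C and
an alternating 5/25 °C regime, with a dry-warm vs dry-warm + wet-cold
storage contrast):

- germination percentage `GP = G_fin / n` and germination rate
  `GR = (1/n) Σᵢ Gᵢ/i` (a Maguire-type speed index; 1 when every seed
  germinates on day 1);
- responses to alternating temperature and wet-cold storage,
  `R_5/25 = (GP_5/25 − GP_15)/(GP_5/25 + GP_15)` and
  `R_wc = (GP_wc − GP_dr)/(GP_wc + GP_dr)`;
- temperature-niche occupation `O_j = g_j/g_max`, niche proportion
  `P_j = O_j/ΣO_j`, and niche breadth `BTN = (1/R) Σ O_j ∈ [1/R, 1]`
  over the R = 5 constant temperatures.

**Community-level quantities** from blocked vegetation quadrats (5 blocks ×
4 doses: 0, 5, 10, 20 g N m⁻² yr⁻¹, one 50 × 50 cm quadrat each):

- the fertilization response of each species,
  `R_f = (RA_N3 − RA_N0)/(RA_N3 + RA_N0)` with `RA_i = n_i/N`;
- community-weighted means `CWM = Σ trait_i · RA_i` of 22 trait variables;
- the Villéger functional-diversity indices FRic (convex-hull volume),
  FEve (minimum-spanning-tree evenness) and FDiv (divergence) over a
  7-variable germination-trait space.

**Inference**: beta regression (mean–precision parameterization, ML with
analytic gradients) of the transformed response `(R_f + 1)/2` on each
germination index, with boundary values ±1 removed first; Gaussian linear
mixed models with a block random intercept fitted by profiled maximum
likelihood, compared by likelihood-ratio χ² tests; Tukey HSD letters from
the studentized range; and correlation-matrix PCA of the CWM profiles.

Because raw multi-species germination datasets of this kind are rarely
public, the package includes a first-class synthetic-data generator that
emulates the field and laboratory designs with known ground truth (Gaussian
thermal-response curves, logit-scale regime effects, softmax abundance with
trait-coupled fertilization slopes), so every stage is validated by
parameter recovery.

## Worked example

```python
from germfilter import SimulationConfig, run_pipeline, report

cfg = SimulationConfig(
    coupling={"BTN": 2.0, "alt_effect": 1.0, "coldstrat_effect": -1.0},
    rng_seed=1,
)
run_pipeline(simulation=cfg, out_dir="out")
print(report("out"))
```

This simulates the default study (63 species, 5 blocks × 4 doses), couples
each species' fertilization response to its niche breadth and regime
effects, and runs every stage. With seed 1 the species-level regression of
transformed `R_f` on BTN reports

```
slope = 7.822,  z = 5.341,  p = 9.2e-08,  pseudo-R² = 0.455,  n = 42
```

(21 of 63 species sit on the R_f boundary ±1 and are removed before the
beta regression). The community level shows the filtering signal the
coupling built in: mean CWM_BTN rises from 0.595 (N0) to 0.829 (N3),
CWM_R5/25 from 0.029 to 0.107, CWM_Rwc falls from 0.060 to −0.006, and
mean functional richness FRic collapses from 13.87 (N0) to 0.32 (N3).
The fertilization likelihood-ratio test for CWM_BTN gives
χ² = 96.14 on 3 df. The report also prints Tukey letters per dose and the
PCA variance shares (86.2% / 10.9% for PC1/PC2 in this run).

The same pipeline runs from the command line:

```bash
germfilter run --seed 1 --out-dir out
germfilter report --out-dir out
```

and each stage is available as its own subcommand
(`simulate`, `traits`, `cwm`, `fd`, `fit-species`, `fit-community`, `pca`)
reading and writing plain CSV.

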