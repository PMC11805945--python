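# phenoshift

Community flowering phenology across decades: circular statistics,
co-flowering reassembly, climate trends and phylogenetic signal.

## The problem

Mediterranean plant communities are strongly seasonal: most species flower
between late winter and early summer, a minority in summer or autumn. As
the climate warms, species shift their flowering — some strongly, some not
at all — and because the shifts are species-specific the *community*
reassembles: the order in which species start flowering changes, pairs that
never flowered together now overlap, old co-flowering partnerships
dissolve, and species that share pollinators gain or lose potential
competitors.

`phenoshift` is an analysis pipeline for exactly this question, built for
weekly flower-count censuses of marked individuals repeated in two
observation windows decades apart. Because flowering dates live on an
annual cycle, all date statistics are circular: day-of-year *d* becomes the
angle *d*·360/365, a date sample is summarised by its mean angle μ and
resultant length *r* ∈ [0, 1], seasonality is tested with the Rayleigh test
(Z = n r²), decade differences in mean date with the Watson–Williams
*F*-test, differences in concentration with an equal-κ test, and peak-date
differences with a seeded permutation rank-sum on circular ranks. Species
decade intervals feed co-flowering overlap matrices (share of the focal
species' flowering days overlapped by each neighbour), a signed
change matrix (0.2 → 0.4 scores 2; 0.4 → 0.2 scores −0.5; new and lost
overlaps score "gain"/"loss"), and a shared-pollinator competition summary.
Pagel's λ, fitted by profile maximum likelihood on a species tree, asks
whether related species shifted by similar amounts. A seeded synthetic-data
module generates counts, guilds, climate and trees with known ground truth,
so every stage is testable without any field data.

See `docs/methods.md` for the models, defaults and numerical conventions.

## Worked example

The numbered scripts under `analysis/` run the whole study on a synthetic
51-species community (ground truth: 42 species advance by a mean of ~28
days, duration change = 0.5·shift + noise, warming climate, signal-free
traits on a Yule tree):

```sh
python analysis/01_simulate.py --seed 1     # writes scratch/inputs/
python analysis/02_phenology.py --seed 1
python analysis/03_coflowering.py
python analysis/04_climate.py
python analysis/05_phylo_signal.py
```

Step 02 prints, for seed 1:

```
51 species compared across decades
significant start advance: 82% of species
pattern counts:
  full_advance                  26  (51%)
  start_only_advance            15  (29%)
  no_change                      5  (10%)
  other                          3  (6%)
  end_only_advance               1  (2%)
  start_delay_end_unchanged      1  (2%)
community mean peak shift: +19.8 d (advance), Watson-Williams p = 8.76e-33; r: 0.43 -> 0.39
```

82% of species show a significant start advance (42/51 were injected), the
community mean flowering date advances by ~20 days (near the ~24-day mean
injected advance, attenuated by the non-shifting species), and seasonality
(*r*) barely moves. Step 03 then reports the reassembly bookkeeping
(increased / decreased / gained / lost co-flowering pairs and the
shared-pollinator net sums), step 04 recovers the injected warming trends
(tmin +0.057 °C/yr) and the positive duration ~ start-shift slope, and step
05 finds no phylogenetic signal (λ = 0, p = 1), as it must for traits
generated independently of the tree.

The same machinery accepts real data: a long-format counts CSV
(`species_id,individual_id,date,count`), a guild table, a daily climate CSV
and a Newick tree — see `phenoshift.pipeline.RunConfig` and
`phenoshift.pipeline.run`, which produce the full report bundle in one
call.

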