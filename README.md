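# benthems

Elements-of-metacommunity-structure (EMS) analysis for depth-structured
binary community data, built for the kind of question a benthic ecologist
asks of historical survey records: *has the depth distribution structure of
a soft-bottom invertebrate fauna changed between survey periods, and which
species moved?*

The package takes binary site-by-species incidence matrices (sites with
known water depths, one matrix per survey period) and provides:

- **EMS classification.** Matrices are ordered by reciprocal averaging
  (RA, the first correspondence-analysis axis). Three elements are then
  measured on the ordered matrix: *coherence* (embedded absences — gaps
  inside species and site ranges), *species turnover* (replacements:
  Σ<sub>i&lt;j</sub> of the product of exclusive-site counts for each
  species pair, after range filling), and *boundary clumping* (Morisita's
  index *I* of range endpoints over sites, χ² = *I*(F−1) + Q − F). Coherence
  and turnover are tested against a fixed-proportional (**r1**) null model —
  site richness fixed, species drawn with probability proportional to their
  observed prevalence, empty sites allowed, every null matrix re-ordinated —
  with z-scores and two-tailed normal p-values from the null mean/SD. The
  three results map onto the idealized structures: Checkerboard, Random,
  Nested, Clementsian, Gleasonian, EvenlySpaced and their Quasi- variants.
- **Axis–depth correlation.** Pearson r between first-axis site scores and
  water depth (axis oriented so r ≥ 0, since CA sign is arbitrary).
- **Subsampling robustness.** Repeated uniform draws of k sites from a
  dense matrix, full EMS + correlation rerun per draw, with label tallies,
  strong/significant-correlation counts, and rarefied richness
  (mean ± SD, with the hypergeometric closed form
  E[S_k] = Σ_j [1 − C(n−n_j, k)/C(n, k)] as analytic check).
- **Depth-shift accounting.** Per-species maximal depth of occurrence per
  period, change categories, paired t-tests, low/high fishing-pressure
  (LFP/HFP) zone transitions at a configurable depth threshold, and
  taxon/trait contingency tables.
- **Synthetic generators** for all idealized structures and for two-period
  depth-gradient surveys with trait-dependent range contraction — every
  stage is testable against known ground truth without any survey data.

## Worked example

Simulate a two-period survey (30 sites on a 19–80 m gradient, 100 species,
a third of them contracting their maximal depth by ~20 m in the recent
period), then classify the recent matrix and account for the shifts:

```bash
benthems simulate --spec survey.json --out-dir data   # survey.json: {"kind":"survey","n_sites":30,"n_species":100,"seed":42}
benthems ems --incidence data/incidence_recent.csv --sites data/sites.csv \
             --seed 7 --n-sim 1000 --out ems.json
```

prints (abridged):

```json
{
  "coherence":  {"absences": 365.0,    "z": -33.2, "mean": 2407.7, "sd": 61.6},
  "turnover":   {"replacements": 220203.0, "z": 51.0, "mean": 25675.7},
  "boundary_clumping": {"morisita": 2.34, "p": 4.8e-45, "df": 27},
  "label": "Clementsian",
  "depth_correlation": {"r": 0.966, "p": 5.0e-18, "n": 30}
}
```

Far fewer embedded absences than the r1 null expects (z = −33: coherent
ranges), far more replacements (z = +51: species substitute each other
along the axis), clumped range boundaries (I = 2.34 > 1): a Clementsian
structure whose axis is almost perfectly aligned with depth (r = 0.97).

```bash
benthems depth-change --old data/incidence_old.csv --recent data/incidence_recent.csv \
                      --sites data/sites.csv --out dc.json
```

reports 96 species shared between periods, 32 with decreased maximal depth
(paired t = 12.3, df = 31, mean 64.7 m → 48.0 m), and 4.2% of species
moving their deepest record from the HFP (> 30 m) to the LFP (< 30 m)
zone.

The same operations are available as a library (`benthems.run_ems`,
`benthems.compare_periods`, `benthems.permutation_study`, ...), which is
the more convenient surface for scripted analyses.

## Data formats

- incidence CSV: header row of species names, first column site ids, 0/1
  cells;
- site metadata CSV: `site_id, depth_m, period[, lat, lon]`;
- species metadata CSV: `species_id, taxon_group, size_class,
  position_class`;
- synonym CSV: `recorded_name, accepted_name` (many-to-one; used by
  `benthems.harmonize` to OR-merge columns across period-specific
  taxonomies).

See `docs/methods.md` for the statistical details and design choices.
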