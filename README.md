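# xenotrack

Identification and longitudinal tracking of donor-reactive T cell clones
in transplant recipients, from bulk TCR-beta CDR3 clone tables,
RNA-derived biopsy repertoires and mixed-species single-cell data.

## The problem

After an organ transplant — including pig-to-human xenotransplants — the
recipient's T cell response against the donor is carried by particular
T cell clones. Each clone is identifiable by its TCR-beta CDR3 sequence,
so the anti-donor repertoire can be defined *in vitro* and then tracked
*in vivo*: donor-reactive clones are the ones that proliferate in a
mixed lymphocyte reaction (MLR) against donor antigen, presented either
directly (intact donor MHC on donor cells) or indirectly (donor antigen
processed by recipient antigen-presenting cells). Once defined, those
clonotypes can be followed across post-transplant blood draws, graft
biopsies and other compartments, and matched inside single-cell
transcriptomes of graft-infiltrating leukocytes.

The statistical core is small and sharp:

* **Reactive-clone calling.** A clonotype is donor-reactive when its
  frequency in the divided (CFSE-low) MLR population is at least twice
  its pre-transplant unstimulated frequency — a rule that excludes
  bystander proliferation and sorting errors. Clones absent from the
  baseline are admitted with at least 2 templates in the divided pool
  (fold recorded as infinite). A clone expanded only in direct MLRs is
  *direct*, only in indirect MLRs *indirect*, and one expanded in both
  responses — or detected only in a late post-transplant MLR — is
  *undefined*. The control ("non-reactive") set holds every
  pre-transplant blood clone absent from all proliferated populations.
* **Diversity.** Clonality `1 − H/ln R` (Shannon entropy over clone
  frequencies), `R20` (fraction of clonotypes, largest first, covering
  20% of templates), and the hyperexpanded compartment (clones > 1% of
  the repertoire), with Fisher's exact test against baseline.
* **Tracking.** For a clone set `S` with sample frequency sum
  `F(S, t)`: fold change `F(S, post) / F(S, pre)`; relative detection
  rate — the reactive set's post/pre detection ratio divided by the
  non-reactive set's, at the clone level (counts of re-detected clones)
  or the template level (cumulative frequencies); pooled two-proportion
  z tests for significance; and clonal convergence, the mean number of
  distinct nucleotide rearrangements per amino-acid CDR3, a signature
  of antigen-driven selection.
* **Cross-compartment.** Clone tracing across blood / lymphocele /
  biopsy samples under a cross-platform clonotype key (amino-acid CDR3
  + V-gene family, since biopsy and single-cell data are RNA-derived
  while blood calling is DNA-based); per-cell human/pig species calls
  from species-resolved transcript counts; matching of single-cell
  TCR-beta clonotypes to the reactive set and per-cluster occupancy.

Everything is exercised against a synthetic-data generator with known
ground truth that emulates the study conditions: a heavy-tailed
baseline repertoire, MLR divided pools dominated by reactive clones
with weak bystander contamination, lymphopenia-driven post-transplant
expansion that is far stronger for reactive clones (with clone-specific
immunodominance), codon-degenerate variant generation, reactive-enriched
compartment subsamples, and barnyard-style mixed human/pig single cells.

## Worked example

```python
from xenotrack import simulate as sim, longitudinal as lg, call_reactive

cfg = sim.SimulationConfig(seed=1)
baseline, truth = sim.simulate_baseline(cfg)

# call reactive clones from a direct CD8 MLR against the unstimulated baseline
mlr = sim.simulate_mlr(baseline, truth, "direct", cfg, subset="CD8")
called = call_reactive(mlr, baseline)
print(len(called))                      # 25 clones called (all 25 truth-reactive)

# track the reactive set across sorted CD8 post-transplant samples
pre  = sim.simulate_longitudinal(baseline, truth, cfg, ["pre"], subset="CD8")[0]
pod49 = sim.simulate_longitudinal(baseline, truth, cfg, subset="CD8")[3]
rk = truth.reactive_keys("nt", subset="CD8")
print(round(lg.cumulative_frequency(rk, pre), 4))    # 0.0807
print(round(lg.cumulative_frequency(rk, pod49), 4))  # 0.3303
print(round(lg.fold_change(rk, pod49, pre), 2))      # 4.09

d = lg.diversity(pod49)
print(d.hyperexpanded_clones, round(d.hyperexpanded_fraction, 4))  # 11 0.2495
```

The reactive set climbs from 8% to 33% of the sorted CD8 repertoire by
the late rejection timepoint, and eleven clones above 1% frequency carry
a quarter of all templates — the oligoclonal takeover the tracking
statistics are built to quantify.

The same pipeline runs from the shell:

```bash
xenotrack simulate --output study --seed 7
xenotrack call     --input study --output sets
xenotrack track    --input study --sets sets --output tracking
xenotrack sc       --input study --sets sets --output cells
xenotrack report   --output report.json sets tracking cells
```

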