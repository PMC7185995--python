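# ontosleep

Sleep-ontogeny analysis for *Drosophila* activity-monitor screens.

Young flies sleep far more than mature flies, and this developmental
decline in sleep — sleep *ontogeny* — is a behavioral trait with its own
genetics, distinct from the genetics of sleep duration. `ontosleep` is a
tested, reusable implementation of the desk-side analysis used to study
it: ingesting Trikinetics Drosophila Activity Monitor (DAM) recordings,
scoring sleep from minute-binned beam-break counts, quantifying sleep
architecture, screening genotypes by ontogeny ratio, measuring
free-running rhythmicity, quantifying confocal images of the sleep
circuitry, and intersecting transcriptomic and ChIP-derived gene sets.
It is aimed at chronobiology and behavioral-genetics labs running DAM
screens, and at anyone who wants those analyses reproducible outside a
spreadsheet.

Because raw screen recordings and imaging stacks are large and
lab-specific, the package ships a first-class synthetic-data module: a
generative sleep–wake model with analytically controlled ontogeny
ratios, image stacks with known puncta, and omics tables with planted
memberships, so every stage of the pipeline is testable against ground
truth.

## The core quantities

**Sleep.** Activity is recorded in 1-min bins; sleep is ≥ 5 consecutive
minutes of inactivity. Every maximal run of ≥ 5 zero-count minutes is
one sleep bout; architecture is summarized per fly per day as total /
day / night sleep minutes, bout numbers, and mean bout lengths.

**Ontogeny ratio.** For a genotype with day-1 ("young") and day-4–5
("mature") cohorts,

    OR = mean daytime sleep (young) / mean daytime sleep (mature).

Wild-type genotypes sit around 1.5–2.0; OR ≈ 1 means no developmental
decline. Screen hits are genotypes with OR ≤ 1.2 (inclusive), subject to
a minimum group size (default n ≥ 8 per age).

**Statistics.** Families of two-sample t tests with Holm–Šidák step-down
correction (α = 0.05), Welch's t for single contrasts, and one-way ANOVA
with Tukey's HSD — the conventions of published DAM-screen figures.

**Rhythmicity.** The "FFT value" of a fly in constant darkness is the
band-limited relative spectral power: activity is binned (30 min),
mean-subtracted, and Fourier transformed; the FFT value is the largest
fraction of non-DC power at a period in the 18–30 h circadian band.

**Imaging.** Innervation density = (thresholded area) / (ROI area);
3-D synaptic puncta are 26-connected components with intensity ≥ 52 and
size 2–80 voxels (inclusive); corrected total cell fluorescence
CTCF = integrated density − area × mean background; reporter signals are
normalized to an adjacent-background or same-ROI reference.

**Gene sets.** DE genes are selected by strict thresholds
(padj < 0.05, |log2FC| > 1.0 by default), ChIP genes by best-peak
p-value rank (top 200, deterministic tie-breaks), and the two sets are
intersected for a Venn count.

## Worked example

Simulate a two-genotype mini-screen — a control with target OR 1.75 and
a knockdown-like genotype with target OR 1.0 — then score it end to end:

```python
from ontosleep import sleep_metrics, ontogeny_screen, synthetic_data

models = {
    "control": synthetic_data.GenotypeModel.wild_type(),  # target OR 1.75
    "kd": synthetic_data.GenotypeModel.wild_type(target_ontogeny_ratio=1.0),
}
sim = synthetic_data.simulate_screen_experiment(models, n_flies_per_group=16, seed=42)
summaries = sleep_metrics.summarize_monitors(sim.monitors, sim.schedule)
merged = summaries.merge(sim.design[["fly", "genotype", "age_class"]], on="fly")
results = ontogeny_screen.ratios_from_day_sleep(merged, day_policy="mean")
screen = ontogeny_screen.call_screen_hits(results, cutoff=1.2, min_n=8)
print(screen[["genotype", "n_young", "n_mature", "young_mean",
              "mature_mean", "ontogeny_ratio", "hit"]].round(3).to_string(index=False))
```

```
genotype  n_young  n_mature  young_mean  mature_mean  ontogeny_ratio   hit
      kd       16        16     244.594      248.781           0.983  True
 control       16        16     450.688      268.188           1.680 False
```

The control's young flies sleep ~451 min by day versus ~268 min when
mature (OR 1.68, inside the wild-type band); the flat genotype's ratio
is ~0.98 and it is called a hit at the 1.2 cutoff.

The same pipeline is scriptable from the shell:

```sh
ontosleep simulate dam --genotypes 4 --n-flies 8 --seed 3 --out sim/
ontosleep ingest --monitor sim/Monitor1.txt --monitor sim/Monitor2.txt \
    --design sim/design.tsv --out ingested/
ontosleep sleep --in ingested/normalized.tsv --out scored/
ontosleep ontogeny --summaries scored/sleep_summaries.tsv \
    --design sim/design.tsv --out screen/
```

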