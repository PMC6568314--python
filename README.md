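# pamscreen

Analysis of comprehensive trinucleotide **PAM** (protospacer adjacent motif)
libraries for the *Escherichia coli* Type I-E CRISPR-Cas system: how well
each of the 64 possible trinucleotides supports **CRISPR interference**
(plasmid depletion) and **primed adaptation** (acquisition of new spacers).

The package is aimed at researchers analyzing pooled plasmid-loss screens
and qPCR adaptation assays. It implements the complete computational
pipeline — amplicon read counting, compositional normalization, kinetic
classification and adaptation scoring — together with a first-class
synthetic-data generator, so every stage can be validated by recovering
planted ground truth.

## What it computes

**Interference arm.** Paired CRISPR ON / CRISPR OFF cultures are sampled at
t = 0, 0.5, 1, 3, 6 and 24 h post-induction and the amplicon spanning the
PAM + protospacer is sequenced. For each PAM the pipeline computes the
control- and t0-normalized ratio

    r(t) = [f_ON(t) / f_OFF(t)] / [f_ON(t0) / f_OFF(t0)]

using depletion-corrected frequencies (PAMs whose frequency drops below
0.5/64 = 1/128 are "depleted"; surviving frequencies are deflated by one
minus the depleted mass so that compositional inflation does not mimic
enrichment), then

    log2fold(t_i) = log2( r(t_i) / r(t0) ),
    d log2fold / dt = (log2fold(t_i) − log2fold(t_{i−1})) / (t_i − t_{i−1})

and clusters the 64 derivative time series hierarchically with bootstrap
resampling (2000 iterations). The three-way cut is named by marker PAMs:
the cluster with the AAG/ATG consensus is *interfering*, the cluster with
the repeat-derived CCG is *stable*, the rest is *intermediate*.

**Adaptation arm.** Hotspot-spacer qPCR signals are normalized against the
single-copy *gyrA* gene (efficiency-2 ΔCq), converted to an **adaptation
score** — the percentage of cells whose array acquired the hotspot spacer —
through a calibration curve fitted on defined cell mixtures, normalized
across hotspots via a shared reference PAM (CAA), averaged, and optionally
bridged with a changed-context (AGN\*) set through the AGC PAM.

**Spacer mapping.** Acquired spacers are exact-matched to the circular
source plasmid on both strands, giving per-position acquisition profiles,
profile-to-profile Pearson correlations, and PAM-usage tables for
naive-vs-primed comparisons.

## Worked example

```python
import tempfile
from pamscreen import pipeline
from pamscreen.simulate import default_config

with tempfile.TemporaryDirectory() as td:
    cfg = default_config(seed=0, reads_per_sample=20_000)
    bundle = pipeline.run_simulate(td, seed=0, config=cfg, write_files=False)
    res = pipeline.run_interference(bundle.manifest, cfg.protospacer,
                                    n_boot=500, seed=0)
    print(res.groups["group"].value_counts().to_dict())
    print(res.log2fold.loc["GAC"].round(2).to_dict())
    scores = pipeline.run_adaptation(bundle.cq_table, bundle.calibration)
    print(scores.sort_values("score", ascending=False).head(3))
```

prints

```
{'stable': 36, 'interfering': 17, 'intermediate': 11}
{0.0: 0.0, 0.5: -0.14, 1.0: -0.11, 3.0: -0.57, 6.0: -1.25, 24.0: -6.21}
         score   source
pam
AGA  25.069902  general
ACA  23.244154  general
CAA  22.982905  general
```

The recovered group sizes match the planted 17 interfering / 36 stable /
11 intermediate structure exactly. The log2fold series for GAC shows the
intermediate signature — flat through the 1 h induction lag, then a slow
decline reaching about −6 log2 units by 24 h — while interfering PAMs
collapse to the sequencing-error floor by 3 h. The top adaptation scores
(percent of cells with an expanded array) all belong to intermediate-group
PAMs: slow, extended interference supplies degradation products for spacer
acquisition for far longer than the rapid destruction caused by consensus
PAMs, and stable PAMs such as CCG score 0 like the water control.

A command-line interface mirrors the library
(`pamscreen simulate | count | normalize | classify | adapt-score |
spacer-map | all`); see `pamscreen --help`.

## Layout

| module                  | role                                                  |
| ----------------------- | ----------------------------------------------------- |
| `pamscreen.simulate`    | generative models: FASTQ time courses, qPCR, spacers  |
| `pamscreen.counting`    | read filters, protospacer search, 64-way PAM counts   |
| `pamscreen.normalize`   | frequencies, depletion correction, ratio series       |
| `pamscreen.kinetics`    | log2fold/derivative features, bootstrap clustering    |
| `pamscreen.adaptation`  | calibration curve, adaptation scores, normalizations  |
| `pamscreen.mapping`     | circular spacer mapping, profiles, PAM usage          |
| `pamscreen.pipeline`    | orchestration and tabular outputs                     |
| `pamscreen.cli`         | `pamscreen` command                                   |

See `docs/methods.md` for the models, parameter choices and limitations.
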