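# chirpinv

Phase-invariance analysis of electrosensory communication-signal coding.

Wave-type weakly electric fish (*Apteronotus leptorhynchus*) sense nearby
conspecifics through a sinusoidal amplitude modulation (the **beat**) of
their electric organ discharge (EOD), and communicate with **chirps** —
brief Gaussian EOD-frequency excursions riding on the beat.  The same chirp
(same frequency excursion Δf and duration) can begin at any **beat phase**,
and each onset phase produces a radically different stimulus waveform at
the receiver.  How does the nervous system recognize these heterogeneous
waveforms as one and the same signal?

`chirpinv` provides a tested, seeded pipeline for studying this question
*in silico*: it synthesizes the chirp-on-beat AM waveform family, simulates
spike trains across the electrosensory hierarchy (P-unit afferents →
ON/OFF pyramidal cells of the hindbrain ELL → midbrain TS neurons) and the
behavioral echo response, and quantifies how invariant each representation
is to the chirp's onset phase.

## The invariance score

For a unit responding to the eight canonical waveforms S₁…S₈ (onset phases
0°–315° in 45° steps), the response to waveform *i* is its trial-averaged
firing-rate time course FRᵢ(t) over a 30 ms window after chirp onset.  The
phase-invariance score compares response distances to stimulus distances:

    Invariance = 1 − ⟨ D(FRᵢ, FRⱼ) / D(Sᵢ, Sⱼ) ⟩_{i≠j}

where D(x, y) is the RMS difference of the mean-centered, normalized
traces divided by the larger half-range (a squared-numerator variant is
available).  A unit that faithfully re-encodes each waveform scores ≈ 0; a
unit whose responses are identical for all onset phases scores 1.  Scalar
tuning uses the log rate ratio `Response = ln(FR_chirp / FR_beat)`, and
pairwise afferent synchrony is measured by a time-varying correlation
coefficient ρ(t) (31.25 ms windows stepped by 0.25 ms) that can itself be
scored for invariance.  The behavioral branch detects echo chirps as >30 Hz
EOD-frequency excursions and scores the pooled response PSTHs the same way.

## Worked example

```bash
chirpinv demo --seed 0
```

prints (about 5 s on one CPU; reduced population sizes):

```
Phase-invariance hierarchy (population means):
              afferent: +0.035
                ELL_ON: +0.104
               ELL_OFF: +0.145
                    TS: +0.349
   correlated_afferent: +0.466
              behavior: +0.779
```

Reading: single afferents encode the AM faithfully, so their responses are
as heterogeneous as the stimuli (score ≈ 0).  The *correlated activity* of
afferent pairs rises transiently at every chirp regardless of onset phase
(score ≈ 0.5).  ON/OFF pyramidal cells partially decode that synchrony
(≈ 0.1–0.2), midbrain units summing rectified ON and OFF drive respond
with excitation to both chirp polarities (≈ 0.35), and the behavioral echo
response is almost phase-blind (≈ 0.8).  Invariance emerges and is refined
along the pathway.

The same machinery is scriptable:

```python
from chirpinv.pipeline import RunConfig, run_pipeline

result = run_pipeline(RunConfig(seed=1, outdir="runs/demo"))
print(result.summary["stages"]["TS"])       # mean/sem/max/min/population
print(result.invariance.head())             # tidy per-unit score table
```

Full runs write delimited tables (`invariance.tsv`, `responses.tsv`,
`behavior.tsv`) plus a JSON summary carrying the seed and config hash.
Other CLI subcommands: `stimulus` (write the waveform set), `simulate`
(per-stage spike tables), `analyze` (full pipeline), `behavior` (echo
branch only), `report`.

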