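# stopem

Reverse-transcription stop counting and Poisson-mixture modification
calling for RNA structure probing (SHAPE / DMS) with paired-end sequencing.

## The problem

Chemical probes such as DMS, 1M7 or NAI modify flexible nucleotides in an
RNA. Reverse transcription of randomly primed cDNA terminates one
nucleotide 3′ of each adduct, so with paired-end sequencing every fragment
reports both an RT drop-off position (read 1) and a priming site (read 2).
For each nucleotide *x* the **drop-off rate** is

    r_x = (reads stopping at x) / (reads covering x).

Raw rates mix chemistry with background: some positions stop the
polymerase regardless of treatment (natural modifications, RT pauses).
`stopem` separates these signals with a **two-channel Poisson mixture**
fitted jointly to a treated and a solvent-control library. Stop counts are
modelled as d ~ Poisson(λ·n) with coverage n as exposure and two RNA-wide
rates, λ_low and λ_high, assumed approximately constant along the
molecule. Each nucleotide belongs to one of three latent classes:

| class | treated | control | meaning |
|-------|---------|---------|---------|
| U     | λ_low   | λ_low   | unmodified background |
| H     | λ_high  | λ_high  | natural strong stop |
| M     | λ_high  | λ_low   | chemically modified |

An EM algorithm estimates (λ_low, λ_high, π_U, π_H, π_M) and the
per-nucleotide class posteriors γ_x; a nucleotide is called modified when
γ_x(M) > 0.90. The package also computes normalized chemical reactivities
(log-rate difference of the channels, 2–8% normalized, capped at 3) and
compares call sets between samples, e.g. ribosome assembly intermediates
at different maturation stages.

## Worked example

```python
import numpy as np
import stopem

scn = stopem.SimulationScenario(length=3000, mod_density=1/150, seed=42)
truth = stopem.simulate_pair(scn)                      # synthetic treated/control pair
model = stopem.TwoChannelPoissonEM.from_pair(truth.pair)
res = model.fit()
print(res.summary())
```

```
Two-channel Poisson mixture (EM)
========================================
sample:            sim_seed42
positions used:    3000 / 3000
lambda_low:        0.00205302
lambda_high:       0.0207085
pi_U / pi_H / pi_M: 0.9701 / 0.0248 / 0.0052
log-likelihood:    -8238.7881
iterations:        8 (converged: True)
```

The generative truth was λ_low = 0.002, λ_high = 0.02, with one modified
nucleotide per 150 nt — the fitted rates land within ~3% and π_M ≈ 0.005
matches the planted density. Calling and reactivity:

```python
calls = res.call_modified(threshold=0.90)
print("called modified:", calls.n_called, "of", int(truth.modified_mask.sum()))
prof = stopem.reactivity(truth.pair)
print("max reactivity:", round(float(np.nanmax(prof.reactivity[prof.defined_mask])), 3))
```

```
called modified: 9 of 18
max reactivity: 1.472
```

At mean coverage 500 and a strict 0.90 posterior cut roughly half the
planted sites clear the threshold while essentially no background position
does; sensitivity rises steeply with depth (see `docs/methods.md`).

The same workflow is available from the shell:

```sh
stopem simulate --length 3000 --mod-density 0.005 --seed 7 --sam --out-prefix sim
stopem count --bam sim_treated.sam --fasta sim_ref.fa --channel treated --out counts_T.tsv
stopem reactivity --treated sim_treated.tsv --control sim_control.tsv \
    --fasta sim_ref.fa --cap 3 --out react.tsv
stopem call --treated sim_treated.tsv --control sim_control.tsv \
    --fasta sim_ref.fa --threshold 0.90 --out calls.tsv
stopem compare --a calls_early.tsv --b calls_late.tsv --fasta sim_ref.fa --out diff.tsv
```

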