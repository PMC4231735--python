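# Methods

## Signal model

A randomly primed, paired-end library of cDNAs from a chemically probed
RNA yields, per fragment, an RT drop-off position (the 5′ end of read 1)
and a priming site (read 2). Reverse transcriptase terminates one
nucleotide 3′ of an adduct, so the drop-off event of a fragment whose
read-1 5′ end aligns at 1-based position q is recorded at p = q − 1. The
offset is configurable (`stop_offset`, default −1) so 0-offset counting
dialects can be reproduced. A fragment covers every position from its stop
p through its rightmost aligned position (the priming site), inclusive;
drop-off-rate denominators use this fragment-span coverage, which
guarantees stops[x] ≤ coverage[x] and hence rates in [0, 1]. Coordinates
are 1-based and closed throughout; analysis is single-transcript and
unstranded — antisense fragments are discarded and counted in the track
metadata. Stops that would fall before position 1 are discarded (counted);
stops within an optional window of the transcript 3′ end
(`exclusion_window_3p`, default 0) are kept in coverage but flagged, since
they cannot be distinguished from random-priming artifacts. Reads
truncated by sequencing length rather than RT drop-off are not filtered;
every read-1 5′ end is treated as a drop-off event, with the exclusion
window available where that assumption is doubtful. Alignments below
`min_mapq` (default 10) and secondary/supplementary/duplicate records are
skipped.

## Mixture model and EM

Stop counts are Poisson with coverage as exposure, d ~ Poisson(λ·n), with
two RNA-wide drop-off rates shared across channels and positions
(λ_low background, λ_high strong-stop) — the rates are assumed
approximately constant along the RNA. Three latent classes tie the treated
(T) and control (C) channels together: U = (λ_low, λ_low),
H = (λ_high, λ_high), M = (λ_high, λ_low). The fourth combination (low
treated, high control) is deliberately absent; positions resembling it are
absorbed by U/H. The observed-data log-likelihood is

    Σ_x log Σ_k π_k · Pois(d_x^T; λ_k^T n_x^T) · Pois(d_x^C; λ_k^C n_x^C)

over positions with nonzero coverage in both channels; zero-coverage
positions carry no posterior and are reported as missing, never as
unmodified. All Poisson terms are computed in log space via log-gamma, so
large counts cannot overflow.

EM updates are closed-form weighted ratios: π_k is the posterior mean;
λ_low pools the U class (both channels) with the M-class control channel,
λ_high pools the H class (both channels) with the M-class treated
channel. The ordering λ_high ≥ λ_low is enforced at parameter
construction by swapping rates and relabelling the U/H weights, which
makes the fit invariant to a label-swapped initialization. A class whose
posterior mass vanishes keeps its previous rate and has its weight floored
at 1e−12. Initialization is deterministic: λ_low and λ_high start at the
25th and 99th percentiles of the pooled per-position rates (floored at
1e−6 and kept at least a factor 2 apart), weights at (0.90, 0.05, 0.05);
optional seeded random restarts are available but off by default.
Convergence is declared when the relative log-likelihood change falls
below `tol` (default 1e−8, max 1,000 iterations); a decrease beyond 1e−8
relative slack raises an assertion, since EM guarantees monotonicity and a
violation indicates an implementation fault. Class weights are estimated
by default; `fix_weights` keeps them at their initial values for users who
prefer a fixed prior.

A nucleotide is called modified when its M-class posterior is strictly
greater than the threshold (default 0.90). Thresholding 1 − P(U) instead
of P(M) is exposed as an alternative calling statistic, since the two
differ when P(H) is appreciable.

## Reactivity

Per-position reactivity is max(0, f(r_T) − f(r_C)) with
f(r) = ln(r + 1e−4) by default; a plain rate difference
(`transform="raw-difference"`) is available. The log transform with a
small pseudocount follows the structure-seq family of reactivity
calculations while keeping both dialects reproducible; the pseudocount and
the coverage floor (`min_coverage`, default 20 for rates and reactivities)
are recorded in output headers. Profiles are 2–8% normalized — sort
descending, exclude the top 2% of defined values, divide by the mean of
the next 6% — so the reference set has mean 1, then capped (default 3).
Positions failing the coverage floor are excluded from the normalization
reference. A profile with no defined positions is a degenerate-profile
error; a profile whose raw values are all zero (e.g. identical channels)
is returned as all zeros unscaled, since there is nothing to normalize
against.

## Synthetic data

The simulator draws from exactly the generative model the EM assumes:
class labels i.i.d. with P(M) = round(L·density)/L and P(H) =
`frac_high_both` (default 0.02, emulating natural strong stops); coverage
per position per channel from a negative binomial (mean 500, dispersion 5
by default — the conventional sequencing-depth model; a fixed-coverage
option exists); stops Poisson(λ·n). Default rates are λ_low = 0.002 and
λ_high = 0.02 and the default modification density is 1/200, inside the
one-per-100–300-nt regime the probing conditions are designed for. A 3′
coverage decay (RT processivity) is not simulated, matching libraries
selected for little signal decay; sequencing and alignment errors and
base-specific reactivity preferences are also not simulated, so passing
tests demonstrate correctness of the counting and inference machinery, not
robustness to mapping artifacts. One global seed drives all draws through
deterministically derived substreams.

`simulate_alignments` materializes a simulated pair as paired-end SAM
records whose read-1 5′ ends sit one nucleotide past each drawn stop.
Because per-position coverage is drawn independently of stops, an
arbitrary (stops, coverage) pair is generally not realizable as fragment
spans; the function therefore reproduces the stop vector exactly and
returns the fragment-induced coverage as the consistent ground truth
(stops at the final position, which cannot be encoded by a read starting
inside the transcript, are dropped from it). Fragment lengths are
truncated-normal (mean 80, sd 20), reads 30 nt.

## Cross-sample comparison

Two samples are compared through their calls at the shared posterior
threshold: a position differs when called in one sample and not the
other; no additional two-sample test is layered on. Positions undefined
(low/zero coverage) in either sample are reported as `undefined`, never as
`neither`. Named regions (1-based closed; BED conversion handled
explicitly) aggregate per-position statuses, with an optional per-region
Fisher exact two-proportion summary offered as diagnostics only. Grayscale
heat-map export writes value/max intensities per nucleotide for external
rendering.

## Problem sizes and checks

The test suite and the acceptance script run entirely on simulated data at
desk scale: oracle equivalence of the likelihood and E-step against
brute-force enumeration on pairs of ≤ 20 positions (1e−10 relative);
EM monotonicity and posterior normalization over 20 seeded fits of 1,200
nt; parameter recovery on the reference scenario (5,000 nt, NB(500, 5)
coverage, λ = 0.002/0.02, weights (0.94, 0.02, 0.04), 20 seeds) with
median rate errors under 10% and median |π̂_M − 0.04| under 0.01; null
calibration (no planted modifications, 20 seeds) with the called fraction
below 0.5%; sensitivity averaged over 10 seeds per coverage level
(50/200/1,000) monotone in depth with specificity ≥ 0.99; exact
stop/coverage round trips through SAM; and the reactivity cap and
normalization contracts. These sizes give stable statistics in seconds per
check while exercising every code path end to end.

## Known limitations

λ_low and λ_high are point estimates shared along the RNA; no positional
smoothing, per-base-identity priors, or Bayesian uncertainty on λ. Calling
power at low coverage is limited — at mean coverage 50 and the strict 0.90
threshold essentially nothing is called, by design of the threshold rather
than a defect. Mutation-based (mutational-profiling) signal extraction,
multi-transcript joint quantification and secondary-structure prediction
are out of scope.
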