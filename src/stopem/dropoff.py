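"""Drop-off rates and normalized chemical reactivities.

The drop-off rate of a nucleotide is the number of reads whose reverse
transcription stopped there divided by the number of reads covering it.
Reactivity is the background-subtracted treated-minus-control signal,
scaled by the 2-8% rule and capped (default 3).
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .tracks import ChannelPair, DropoffRateTrack, ReactivityProfile, StopCountTrack

DEFAULT_PSEUDOCOUNT = 1e-4
DEFAULT_MIN_COVERAGE = 20


def dropoff_rates(track: StopCountTrack, min_coverage: int = DEFAULT_MIN_COVERAGE) -> DropoffRateTrack:
    """Per-nucleotide stop/coverage ratio, masked below a coverage floor."""
    if min_coverage < 1:
        raise ValueError("min_coverage must be >= 1")
    defined = track.coverage >= min_coverage
    rates = np.full(track.transcript.length, np.nan)
    np.divide(track.stops, track.coverage, out=rates, where=defined)
    # stop position is inside the fragment span, so stops <= coverage and
    # the ratio cannot exceed 1
    return DropoffRateTrack(transcript=track.transcript, rates=rates, defined_mask=defined)


def _two_eight_reference(values: np.ndarray) -> np.ndarray:
    """Indices (into ``values``) of the 2-8% normalization reference set.

    Sort descending, drop the top 2% of entries, average the next 6%
    (at least one entry).
    """
    n = values.size
    order = np.argsort(values)[::-1]
    n_exclude = int(np.floor(0.02 * n))
    n_ref = max(1, int(np.floor(0.06 * n)))
    return order[n_exclude : n_exclude + n_ref]


def reactivity(
    pair: ChannelPair,
    cap: float = 3.0,
    min_coverage: int = DEFAULT_MIN_COVERAGE,
    transform: str = "log",
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    normalization: str = "two_eight_percent",
) -> ReactivityProfile:
    """Normalized, capped reactivity profile for a treated/control pair.

    raw[x] = max(0, f(rate_T[x]) - f(rate_C[x])) with f = ln(. + pseudocount)
    (``transform="log"``, default) or identity (``transform="raw-difference"``).
    Raw values are scaled so the mean of the 2-8% reference set is 1, then
    capped at ``cap``.
    """
    if cap <= 0:
        raise ValueError("cap must be positive")
    if transform not in ("log", "raw-difference"):
        raise ValueError(f"unknown transform {transform!r}")
    rt = dropoff_rates(pair.treated, min_coverage)
    rc = dropoff_rates(pair.control, min_coverage)
    defined = rt.defined_mask & rc.defined_mask
    raw = np.full(pair.length, np.nan)
    if transform == "log":
        raw[defined] = np.log(rt.rates[defined] + pseudocount) - np.log(
            rc.rates[defined] + pseudocount
        )
    else:
        raw[defined] = rt.rates[defined] - rc.rates[defined]
    raw[defined] = np.maximum(raw[defined], 0.0)

    scale = 1.0
    ref_idx = np.array([], dtype=int)
    scaled = raw.copy()
    if normalization == "two_eight_percent":
        def_idx = np.flatnonzero(defined)
        if def_idx.size == 0:
            raise ValueError("degenerate profile: normalization reference empty")
        vals = raw[def_idx]
        if (vals > 0).any():
            ref_local = _two_eight_reference(vals)
            ref_idx = def_idx[ref_local]
            scale = float(vals[ref_local].mean())
            if scale > 0:
                scaled[defined] = raw[defined] / scale
            else:
                # reference fell entirely on zeros; leave profile unscaled
                scale = 1.0
                ref_idx = np.array([], dtype=int)
        # an all-zero raw profile (e.g. identical channels) stays all zero
    elif normalization != "none":
        raise ValueError(f"unknown normalization {normalization!r}")

    capped = scaled.copy()
    capped[defined] = np.minimum(capped[defined], cap)
    return ReactivityProfile(
        transcript=pair.transcript,
        reactivity=capped,
        defined_mask=defined,
        cap=cap,
        normalization=normalization,
        raw=raw,
        scale=scale,
        reference_index=ref_idx,
    )


def write_reactivity_table(
    pair: ChannelPair,
    profile: ReactivityProfile,
    out,
    min_coverage: int = DEFAULT_MIN_COVERAGE,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    transform: str = "log",
    header_comments: dict | None = None,
) -> None:
    """Full per-position TSV: counts, rates per channel, and reactivity."""
    rt = dropoff_rates(pair.treated, min_coverage)
    rc = dropoff_rates(pair.control, min_coverage)
    tr = pair.transcript

    def fmt(v):
        return "NA" if np.isnan(v) else f"{v:.6g}"

    with open(out, "w") as fh:
        fh.write(f"# transform={transform} cap={profile.cap} ")
        fh.write(f"pseudocount={pseudocount} min_coverage={min_coverage}\n")
        for key, val in (header_comments or {}).items():
            fh.write(f"# {key}={val}\n")
        fh.write(
            "position\tbase\tstops_T\tcov_T\tstops_C\tcov_C\trate_T\trate_C\treactivity\n"
        )
        for i in range(tr.length):
            fh.write(
                f"{i + 1}\t{tr.base(i + 1)}\t{pair.treated.stops[i]}\t"
                f"{pair.treated.coverage[i]}\t{pair.control.stops[i]}\t"
                f"{pair.control.coverage[i]}\t{fmt(rt.rates[i])}\t{fmt(rc.rates[i])}\t"
                f"{fmt(profile.reactivity[i])}\n"
            )


def write_shape(profile: ReactivityProfile, out) -> None:
    """Export in the two-column .shape dialect (undefined positions -999)."""
    with open(out, "w") as fh:
        for i in range(len(profile.reactivity)):
            v = profile.reactivity[i] if profile.defined_mask[i] else -999.0
            fh.write(f"{i + 1}\t{v:.4f}\n")


def write_bedgraph(track: DropoffRateTrack, out) -> None:
    """bedGraph export of defined drop-off rates (0-based half-open)."""
    with open(out, "w") as fh:
        fh.write(f'track type=bedGraph name="{track.transcript.name} dropoff"\n')
        for i in np.flatnonzero(track.defined_mask):
            fh.write(f"{track.transcript.name}\t{i}\t{i + 1}\t{track.rates[i]:.6g}\n")


def replicate_correlation(a: DropoffRateTrack, b: DropoffRateTrack) -> float:
    """Pearson correlation of two rate tracks over jointly defined positions."""
    if a.transcript.name != b.transcript.name or a.transcript.length != b.transcript.length:
        raise ValueError("replicate tracks must share a transcript")
    joint = a.defined_mask & b.defined_mask
    if joint.sum() < 3:
        raise ValueError(f"only {int(joint.sum())} jointly defined positions; need >= 3")
    r, _ = stats.pearsonr(a.rates[joint], b.rates[joint])
    return float(r)
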