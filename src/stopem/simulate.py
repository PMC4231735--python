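"""Synthetic treated/control stop-count data with known ground truth.

Emulates the statistical structure the mixture model assumes: background
stop rates approximately constant along the RNA, a small fraction of
positions with high stops in both channels (natural RT pauses and natural
modifications), and treatment-induced stops at a density of roughly one
modified nucleotide per 100-300 nt — the probing regime the protocol is
designed for. Counts are drawn from exactly the model's generative process
(class labels i.i.d., coverage per channel, stops Poisson with coverage as
exposure), so fitted parameters can be compared to generative truth.

Also writes toy paired-end SAM alignments whose read-1 5' ends encode the
drawn stop positions, for end-to-end exercise of the alignment counter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pysam

from .model import CLASS_NAMES, MixtureParams
from .tracks import ChannelPair, StopCountTrack, TranscriptRef


@dataclass
class SimulationScenario:
    """Generative settings for one synthetic treated/control pair.

    ``mod_density`` defaults to 1/200 (one modified nucleotide per 200 nt,
    inside the designed 1-per-100-to-300 probing regime); ``frac_high_both``
    is the fraction of natural strong-stop positions. Coverage is drawn per
    position per channel, negative binomial by default (the conventional
    sequencing-depth model), or fixed.
    """

    length: int = 3000
    mod_density: float = 1 / 200
    frac_high_both: float = 0.02
    lambda_low: float = 0.002
    lambda_high: float = 0.02
    coverage_model: str = "negative_binomial"  # or "fixed"
    coverage_mean: float = 500.0
    coverage_dispersion: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("length must be positive")
        if not (0.0 <= self.mod_density < 1.0) or not (0.0 <= self.frac_high_both <= 1.0):
            raise ValueError("mod_density and frac_high_both must lie in [0, 1)")
        for lam in (self.lambda_low, self.lambda_high):
            if not (0.0 < lam < 1.0):
                raise ValueError("drop-off rates must lie in (0, 1)")
        if self.mod_density > 0 and round(self.length * self.mod_density) < 1:
            raise ValueError(
                "infeasible scenario: expected modified count below 1 "
                f"(L={self.length}, density={self.mod_density})"
            )


@dataclass
class SimulatedTruth:
    """A synthetic ChannelPair plus its generative class labels.

    ``class_labels`` holds integers 0/1/2 for U/H/M (names in
    ``CLASS_NAMES``); ``modified_mask`` marks the truly modified positions.
    """

    class_labels: np.ndarray
    pair: ChannelPair
    scenario: SimulationScenario | None = None

    @property
    def modified_mask(self) -> np.ndarray:
        return self.class_labels == 2


def _random_sequence(length: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


def simulate_pair(scn: SimulationScenario, transcript: TranscriptRef | None = None) -> SimulatedTruth:
    """Draw one treated/control pair from the generative mixture model.

    Class labels are i.i.d. with P(M) = round(L * mod_density) / L (so the
    expected number of modified positions is the rounded target) and
    P(H) = frac_high_both. Fully reproducible from ``scn.seed``; per-stage
    substreams are derived deterministically from it.
    """
    ss = np.random.SeedSequence(scn.seed)
    rng_seq, rng_labels, rng_cov, rng_stops = (np.random.default_rng(s) for s in ss.spawn(4))
    L = scn.length
    if transcript is None:
        transcript = TranscriptRef(name="sim", sequence=_random_sequence(L, rng_seq))
    elif transcript.length != L:
        raise ValueError("supplied transcript length differs from scenario length")

    p_m = round(L * scn.mod_density) / L
    p_h = scn.frac_high_both
    p_u = 1.0 - p_m - p_h
    if p_u < 0:
        raise ValueError("class probabilities exceed 1; lower density or frac_high_both")
    labels = rng_labels.choice(3, size=L, p=[p_u, p_h, p_m])

    if scn.coverage_model == "fixed":
        n_t = np.full(L, int(round(scn.coverage_mean)), dtype=np.int64)
        n_c = n_t.copy()
    elif scn.coverage_model == "negative_binomial":
        r = scn.coverage_dispersion
        p = r / (r + scn.coverage_mean)
        n_t = rng_cov.negative_binomial(r, p, size=L).astype(np.int64)
        n_c = rng_cov.negative_binomial(r, p, size=L).astype(np.int64)
    else:
        raise ValueError(f"unknown coverage model {scn.coverage_model!r}")

    rates = MixtureParams(scn.lambda_low, scn.lambda_high).rate_table  # (3, 2)
    d_t = rng_stops.poisson(rates[labels, 0] * n_t)
    d_c = rng_stops.poisson(rates[labels, 1] * n_c)

    pair = ChannelPair(
        treated=StopCountTrack(transcript, d_t, n_t, channel="treated"),
        control=StopCountTrack(transcript, d_c, n_c, channel="control"),
        sample_name=f"sim_seed{scn.seed}",
    )
    return SimulatedTruth(class_labels=labels, pair=pair, scenario=scn)


def _write_fragments_sam(path, transcript, fragments, read_len):
    """Write properly paired fragments (read1 forward, read2 reverse) as SAM."""
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": transcript.name, "LN": transcript.length}],
    }
    seq = transcript.sequence
    with pysam.AlignmentFile(str(path), "w", header=header) as sam:
        for i, (start1, flen) in enumerate(fragments):  # start1: 0-based read1 start
            r1_len = min(read_len, flen)
            r2_len = min(read_len, flen)
            r2_start = start1 + flen - r2_len
            a = pysam.AlignedSegment(sam.header)
            a.query_name = f"frag{i}"
            a.flag = 0x1 | 0x2 | 0x40 | 0x20  # paired, proper, read1, mate reverse
            a.reference_id = 0
            a.reference_start = start1
            a.mapping_quality = 60
            a.cigarstring = f"{r1_len}M"
            a.query_sequence = seq[start1 : start1 + r1_len]
            a.next_reference_id = 0
            a.next_reference_start = r2_start
            a.template_length = flen
            b = pysam.AlignedSegment(sam.header)
            b.query_name = f"frag{i}"
            b.flag = 0x1 | 0x2 | 0x80 | 0x10  # paired, proper, read2, reverse
            b.reference_id = 0
            b.reference_start = r2_start
            b.mapping_quality = 60
            b.cigarstring = f"{r2_len}M"
            b.query_sequence = seq[r2_start : r2_start + r2_len]
            b.next_reference_id = 0
            b.next_reference_start = start1
            b.template_length = -flen
            sam.write(a)
            sam.write(b)


def simulate_alignments(
    truth: SimulatedTruth,
    out_prefix: str | Path,
    fragment_length_mean: float = 80.0,
    fragment_length_sd: float = 20.0,
    read_len: int = 30,
    seed: int | None = None,
) -> tuple[dict, SimulatedTruth]:
    """Materialize a SimulatedTruth as paired-end SAM files plus FASTA.

    For every truth stop at position p a fragment is written whose read-1
    5' end aligns at p + 1, so the alignment counter's -1 convention
    recovers p exactly. Fragment lengths are drawn from a truncated normal.
    Coverage is induced by the fragment spans rather than copied from the
    input pair (independent per-position coverage draws are generally not
    realizable as fragment spans), so the returned SimulatedTruth carries
    the span-consistent pair; stops at the last transcript position cannot
    be encoded and are dropped from it.

    Returns (paths, consistent_truth) with paths for keys "treated",
    "control" and "fasta".
    """
    scn_seed = truth.scenario.seed if truth.scenario is not None else 0
    rng = np.random.default_rng(seed if seed is not None else scn_seed + 10_000)
    transcript = truth.pair.transcript
    L = transcript.length
    out_prefix = Path(out_prefix)
    paths = {
        "treated": out_prefix.with_name(out_prefix.name + "_treated.sam"),
        "control": out_prefix.with_name(out_prefix.name + "_control.sam"),
        "fasta": out_prefix.with_name(out_prefix.name + "_ref.fa"),
    }
    with open(paths["fasta"], "w") as fh:
        fh.write(f">{transcript.name}\n")
        for i in range(0, L, 70):
            fh.write(transcript.sequence[i : i + 70] + "\n")

    tracks = {}
    for channel in ("treated", "control"):
        src = getattr(truth.pair, channel)
        fragments = []
        stops_out = np.zeros(L, dtype=np.int64)
        cov_diff = np.zeros(L + 1, dtype=np.int64)
        for p in range(1, L):  # stop at position L has no room for read1 at L+1
            for _ in range(int(src.stops[p - 1])):
                flen = int(round(rng.normal(fragment_length_mean, fragment_length_sd)))
                flen = max(1, min(flen, L - p))  # fragment sits in (p+1 .. p+flen)
                fragments.append((p, flen))  # 0-based read1 start = p (1-based p+1)
                stops_out[p - 1] += 1
                cov_diff[p - 1] += 1  # span covers p .. p+flen (1-based)
                cov_diff[p + flen] -= 1
        _write_fragments_sam(paths[channel], transcript, fragments, read_len)
        tracks[channel] = StopCountTrack(
            transcript, stops_out, np.cumsum(cov_diff[:-1]), channel=channel
        )

    consistent = SimulatedTruth(
        class_labels=truth.class_labels,
        pair=ChannelPair(tracks["treated"], tracks["control"], truth.pair.sample_name),
        scenario=truth.scenario,
    )
    return {k: str(v) for k, v in paths.items()}, consistent
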