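"""Core per-transcript data containers.

All coordinates are 1-based, closed intervals on a single transcript.
Array attributes are numpy arrays of length L indexed 0..L-1, where array
index i corresponds to transcript position i + 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

VALID_BASES = set("ACGTUN")


@dataclass(frozen=True)
class TranscriptRef:
    """A single-transcript reference sequence.

    ``sequence`` is stored uppercase with U mapped to T internally;
    ``source_alphabet`` remembers whether the input used RNA (U) or DNA (T)
    so the original spelling can be reported back.
    """

    name: str
    sequence: str
    source_alphabet: str = "DNA"

    def __post_init__(self) -> None:
        if len(self.sequence) == 0:
            raise ValueError(f"transcript {self.name!r} has empty sequence")
        bad = set(self.sequence.upper()) - VALID_BASES
        if bad:
            raise ValueError(
                f"transcript {self.name!r} contains invalid characters: {sorted(bad)}"
            )
        norm = self.sequence.upper().replace("U", "T")
        object.__setattr__(self, "sequence", norm)

    @property
    def length(self) -> int:
        return len(self.sequence)

    def base(self, position: int) -> str:
        """Base at a 1-based transcript position, in the source alphabet."""
        b = self.sequence[position - 1]
        if self.source_alphabet == "RNA" and b == "T":
            return "U"
        return b


@dataclass
class StopCountTrack:
    """Per-nucleotide RT stop counts and fragment coverage for one channel.

    ``stops[i]`` counts fragments whose reverse transcriptase dropped off at
    position i + 1; ``coverage[i]`` counts fragments whose span (stop
    position through priming-site end) covers position i + 1.
    """

    transcript: TranscriptRef
    stops: np.ndarray
    coverage: np.ndarray
    channel: str  # "treated" | "control"
    n_discarded_out_of_range: int = 0
    n_discarded_antisense: int = 0
    n_flagged_3p_window: int = 0

    def __post_init__(self) -> None:
        self.stops = np.asarray(self.stops, dtype=np.int64)
        self.coverage = np.asarray(self.coverage, dtype=np.int64)
        L = self.transcript.length
        if self.stops.shape != (L,) or self.coverage.shape != (L,):
            raise ValueError(
                f"track arrays must have length {L}; got stops {self.stops.shape}, "
                f"coverage {self.coverage.shape}"
            )
        if (self.stops < 0).any() or (self.coverage < 0).any():
            raise ValueError("stop and coverage counts must be non-negative")
        if self.channel not in ("treated", "control"):
            raise ValueError(f"channel must be 'treated' or 'control', got {self.channel!r}")


@dataclass
class ChannelPair:
    """Matched treated/control stop-count tracks for one sample.

    The unit on which the two-channel Poisson mixture is fitted.
    """

    treated: StopCountTrack
    control: StopCountTrack
    sample_name: str = "sample"

    def __post_init__(self) -> None:
        if self.treated.transcript.name != self.control.transcript.name:
            raise ValueError(
                "treated and control tracks reference different transcripts: "
                f"{self.treated.transcript.name!r} vs {self.control.transcript.name!r}"
            )
        if self.treated.transcript.length != self.control.transcript.length:
            raise ValueError("treated and control tracks have different lengths")

    @property
    def transcript(self) -> TranscriptRef:
        return self.treated.transcript

    @property
    def length(self) -> int:
        return self.treated.transcript.length


@dataclass
class DropoffRateTrack:
    """Per-nucleotide RT drop-off rate: stops / coverage.

    Positions below the coverage floor are masked out (``defined_mask``
    False) and their rate is NaN, never reported as zero.
    """

    transcript: TranscriptRef
    rates: np.ndarray
    defined_mask: np.ndarray

    def __post_init__(self) -> None:
        self.rates = np.asarray(self.rates, dtype=float)
        self.defined_mask = np.asarray(self.defined_mask, dtype=bool)
        ok = self.rates[self.defined_mask]
        if ok.size and ((ok < 0).any() or (ok > 1).any()):
            raise ValueError("defined drop-off rates must lie in [0, 1]")


@dataclass
class ReactivityProfile:
    """Normalized, capped chemical reactivity per nucleotide.

    ``reactivity`` holds the capped values; ``raw`` the pre-normalization
    background-subtracted signal; ``scale`` the 2-8% normalization divisor;
    ``reference_index`` the (0-based) positions whose scaled mean is 1.
    """

    transcript: TranscriptRef
    reactivity: np.ndarray
    defined_mask: np.ndarray
    cap: float = 3.0
    normalization: str = "two_eight_percent"
    raw: np.ndarray | None = None
    scale: float = 1.0
    reference_index: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def __post_init__(self) -> None:
        self.reactivity = np.asarray(self.reactivity, dtype=float)
        self.defined_mask = np.asarray(self.defined_mask, dtype=bool)
        ok = self.reactivity[self.defined_mask]
        if ok.size and ((ok < 0).any() or (ok > self.cap + 1e-12).any()):
            raise ValueError(f"defined reactivities must lie in [0, {self.cap}]")


@dataclass
class ModificationCallSet:
    """Per-nucleotide modified/unmodified calls at a posterior threshold.

    ``called[x]`` is True iff the posterior probability of the modified
    class strictly exceeds ``threshold``. Positions without a posterior
    (zero coverage in either channel) carry NaN in ``p_modified`` and are
    never called.
    """

    transcript: TranscriptRef
    p_modified: np.ndarray
    called: np.ndarray
    threshold: float
    sample_name: str = "sample"

    def __post_init__(self) -> None:
        self.p_modified = np.asarray(self.p_modified, dtype=float)
        self.called = np.asarray(self.called, dtype=bool)
        if not (0.0 < self.threshold < 1.0):
            raise ValueError("threshold must lie strictly inside (0, 1)")

    @property
    def defined_mask(self) -> np.ndarray:
        return ~np.isnan(self.p_modified)

    @property
    def n_called(self) -> int:
        return int(self.called.sum())

    def called_positions(self) -> np.ndarray:
        """1-based transcript positions called modified."""
        return np.flatnonzero(self.called) + 1
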