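"""Cross-sample comparison of modification calls and track export.

Samples (e.g. early / middle / late assembly intermediates) are compared
through their per-nucleotide calls at the shared posterior threshold: a
position differs between two samples when it is called in one and not the
other. Region annotations (named 1-based closed intervals, e.g. helices)
aggregate the per-position statuses.
"""

from __future__ import annotations

from dataclasses import dataclass
from os import PathLike

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .tracks import (
    DropoffRateTrack,
    ModificationCallSet,
    ReactivityProfile,
    TranscriptRef,
)

STATUSES = ("both", "a_only", "b_only", "neither", "undefined")


@dataclass
class RegionAnnotation:
    """Named regions in 1-based closed transcript coordinates."""

    regions: pd.DataFrame  # columns: name, start, end

    def __post_init__(self) -> None:
        df = self.regions
        required = {"name", "start", "end"}
        if not required.issubset(df.columns):
            raise ValueError(f"region table needs columns {sorted(required)}")
        if df["name"].duplicated().any():
            raise ValueError("region names must be unique")
        if ((df["start"] < 1) | (df["start"] > df["end"])).any():
            raise ValueError("regions must satisfy 1 <= start <= end")

    @classmethod
    def from_tsv(cls, source) -> "RegionAnnotation":
        return cls(pd.read_csv(source, sep="\t", comment="#"))

    @classmethod
    def from_bed(cls, source) -> "RegionAnnotation":
        """Read BED (0-based half-open) and convert to 1-based closed."""
        df = pd.read_csv(
            source, sep="\t", comment="#", header=None,
            usecols=[0, 1, 2, 3], names=["chrom", "bed_start", "bed_end", "name"],
        )
        return cls(
            pd.DataFrame(
                {"name": df["name"], "start": df["bed_start"] + 1, "end": df["bed_end"]}
            )
        )

    def to_bed(self, out, chrom: str) -> None:
        with open(out, "w") as fh:
            for row in self.regions.itertuples():
                fh.write(f"{chrom}\t{row.start - 1}\t{row.end}\t{row.name}\n")


def summarize_calls(calls: ModificationCallSet, ref: TranscriptRef) -> dict:
    """Per-sample totals: called count, defined count, base composition.

    Base composition of called positions is the quantity behind per-sample
    specificity checks (e.g. the A+C fraction expected for a base-specific
    probe such as DMS).
    """
    if len(calls.called) != ref.length:
        raise ValueError("call set length does not match reference")
    called_pos = calls.called_positions()
    by_base: dict[str, int] = {}
    for p in called_pos:
        b = ref.base(int(p))
        by_base[b] = by_base.get(b, 0) + 1
    n_called = int(calls.n_called)
    ac = by_base.get("A", 0) + by_base.get("C", 0)
    return {
        "sample_name": calls.sample_name,
        "n_called": n_called,
        "n_defined": int(calls.defined_mask.sum()),
        "calls_by_base": by_base,
        "ac_fraction": ac / n_called if n_called else float("nan"),
    }


def compare_calls(
    a: ModificationCallSet,
    b: ModificationCallSet,
    regions: RegionAnnotation | None = None,
    fisher: bool = False,
) -> pd.DataFrame:
    """Per-position differential status between two call sets.

    Status is ``both`` / ``a_only`` / ``b_only`` / ``neither`` over
    positions defined in both samples, ``undefined`` elsewhere (low
    coverage in either sample is reported as undefined, never as neither).
    Returns a per-position frame; with ``regions``, a ``region_counts``
    frame is attached in ``df.attrs`` (optionally with a two-proportion
    Fisher exact p-value per region, as diagnostics only).
    """
    if a.transcript.name != b.transcript.name or len(a.called) != len(b.called):
        raise ValueError("call sets must share a transcript")
    L = len(a.called)
    defined = a.defined_mask & b.defined_mask
    status = np.full(L, "undefined", dtype=object)
    status[defined & a.called & b.called] = "both"
    status[defined & a.called & ~b.called] = "a_only"
    status[defined & ~a.called & b.called] = "b_only"
    status[defined & ~a.called & ~b.called] = "neither"
    df = pd.DataFrame(
        {
            "position": np.arange(1, L + 1),
            "called_a": a.called,
            "called_b": b.called,
            "status": status,
        }
    )
    if regions is not None:
        rows = []
        for reg in regions.regions.itertuples():
            sl = status[reg.start - 1 : reg.end]
            row = {"name": reg.name, "start": reg.start, "end": reg.end}
            for s in STATUSES:
                row[s] = int((sl == s).sum())
            if fisher:
                n_def = reg.end - reg.start + 1 - row["undefined"]
                ca = row["both"] + row["a_only"]
                cb = row["both"] + row["b_only"]
                _, p = _stats.fisher_exact([[ca, n_def - ca], [cb, n_def - cb]])
                row["fisher_p"] = p
            rows.append(row)
        df.attrs["region_counts"] = pd.DataFrame(rows)
    return df


def export_heatmap_track(
    values: DropoffRateTrack | ReactivityProfile, out: str | PathLike
) -> None:
    """Write per-position grayscale intensities (value / max) as TSV.

    One block per nucleotide, 0-1 scale, suitable for external heat-map
    rendering; undefined positions are left blank.
    """
    if isinstance(values, DropoffRateTrack):
        vec = values.rates
    else:
        vec = values.reactivity
    mask = values.defined_mask
    if not mask.any():
        raise ValueError("cannot export an empty track")
    vmax = float(np.nanmax(vec[mask]))
    with open(out, "w") as fh:
        fh.write("position\tintensity\n")
        for i in range(len(vec)):
            if mask[i]:
                inten = vec[i] / vmax if vmax > 0 else 0.0
                fh.write(f"{i + 1}\t{inten:.6g}\n")
            else:
                fh.write(f"{i + 1}\t\n")
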