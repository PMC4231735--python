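"""Reading references, alignments and count tables.

Converts paired-end alignments (SAM/BAM) or pre-computed TSV tables into
per-nucleotide stop-count and coverage tracks under a fixed coordinate
convention: 1-based, closed intervals; the RT drop-off event of a fragment
is recorded at (read-1 5' aligned position + stop_offset), with
stop_offset = -1 by default because reverse transcriptase terminates one
nucleotide 3' of the adduct.
"""

from __future__ import annotations

from os import PathLike

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO

from .tracks import ChannelPair, StopCountTrack, TranscriptRef

COUNT_TABLE_COLUMNS = ("position", "stops", "coverage")


def load_reference(fasta_source: str | PathLike, name: str | None = None) -> TranscriptRef:
    """Load one transcript record from a FASTA file.

    Parameters
    ----------
    fasta_source : path to a FASTA file
    name : record id to select; may be omitted when the file holds exactly
        one record.
    """
    records = list(SeqIO.parse(str(fasta_source), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records found in {fasta_source}")
    if name is None:
        if len(records) > 1:
            raise ValueError(
                f"{fasta_source} holds {len(records)} records; a record name is required"
            )
        rec = records[0]
    else:
        by_name = {r.id: r for r in records}
        if name not in by_name:
            raise KeyError(f"record {name!r} not found in {fasta_source} (has {sorted(by_name)})")
        rec = by_name[name]
    seq = str(rec.seq).upper()
    alphabet = "RNA" if "U" in seq else "DNA"
    return TranscriptRef(name=rec.id, sequence=seq, source_alphabet=alphabet)


def count_stops(
    alignments: str | PathLike | pysam.AlignmentFile,
    ref: TranscriptRef,
    channel: str,
    min_mapq: int = 10,
    stop_offset: int = -1,
    exclusion_window_3p: int = 0,
) -> StopCountTrack:
    """Count RT drop-off events and fragment coverage from paired-end alignments.

    For every properly paired, primary fragment mapped sense to ``ref``:

    * the drop-off position is p = (read-1 5' aligned position) + ``stop_offset``
      in 1-based coordinates; p < 1 is discarded (and counted);
    * the fragment covers every position from p through its rightmost
      aligned position (the priming-site end), inclusive;
    * stops within ``exclusion_window_3p`` of the transcript 3' end are kept
      in coverage but flagged (excluded from the stop vector), since they
      cannot be distinguished from random-priming artifacts.

    Read 1 carries the cDNA 3' end under the adopted library orientation and
    must map to the forward strand; antisense fragments are discarded and
    counted.
    """
    if min_mapq < 0:
        raise ValueError("min_mapq must be >= 0")
    if exclusion_window_3p < 0:
        raise ValueError("exclusion_window_3p must be >= 0")

    own = False
    if not isinstance(alignments, pysam.AlignmentFile):
        alignments = pysam.AlignmentFile(str(alignments), check_sq=False)
        own = True

    L = ref.length
    stops = np.zeros(L, dtype=np.int64)
    coverage_diff = np.zeros(L + 1, dtype=np.int64)  # difference array for span sums
    n_out_of_range = 0
    n_antisense = 0
    n_flagged = 0
    n_read1 = 0
    n_paired = 0
    try:
        for read in alignments:
            if not read.is_read1 or read.is_unmapped or read.is_secondary:
                continue
            if read.is_supplementary or read.is_duplicate:
                continue
            n_read1 += 1
            if not read.is_proper_pair:
                continue
            n_paired += 1
            if read.mapping_quality < min_mapq:
                continue
            if read.reference_name != ref.name:
                raise ValueError(
                    f"alignment reference {read.reference_name!r} does not match "
                    f"transcript {ref.name!r}"
                )
            if read.is_reverse:
                n_antisense += 1
                continue
            tlen = read.template_length
            if tlen <= 0:
                continue
            read1_5p = read.reference_start + 1  # 1-based leftmost = 5' end on forward strand
            p = read1_5p + stop_offset
            frag_end = min(read.reference_start + tlen, L)  # 1-based rightmost
            if p < 1:
                n_out_of_range += 1
                cov_start = read1_5p
            elif p > L:
                n_out_of_range += 1
                continue
            else:
                cov_start = p
                if p > L - exclusion_window_3p:
                    n_flagged += 1
                else:
                    stops[p - 1] += 1
            coverage_diff[cov_start - 1] += 1
            coverage_diff[frag_end] -= 1
    finally:
        if own:
            alignments.close()

    if n_read1 > 0 and n_paired == 0:
        raise ValueError(
            f"{n_read1} mapped read-1 records but none properly paired; "
            "paired-end input is required"
        )
    coverage = np.cumsum(coverage_diff[:-1])
    return StopCountTrack(
        transcript=ref,
        stops=stops,
        coverage=coverage,
        channel=channel,
        n_discarded_out_of_range=n_out_of_range,
        n_discarded_antisense=n_antisense,
        n_flagged_3p_window=n_flagged,
    )


def write_count_table(track: StopCountTrack, out, header_comments: dict | None = None) -> None:
    """Write a StopCountTrack as a dense TSV (position, stops, coverage)."""
    close = False
    if isinstance(out, (str, PathLike)):
        out = open(out, "w")
        close = True
    try:
        for key, val in (header_comments or {}).items():
            out.write(f"# {key}={val}\n")
        out.write("\t".join(COUNT_TABLE_COLUMNS) + "\n")
        for i in range(track.transcript.length):
            out.write(f"{i + 1}\t{track.stops[i]}\t{track.coverage[i]}\n")
    finally:
        if close:
            out.close()


def load_count_table(
    tsv_source, ref: TranscriptRef, channel: str = "treated"
) -> StopCountTrack:
    """Load a per-nucleotide count table into a dense StopCountTrack.

    The TSV must have a header line with columns position, stops, coverage;
    positions are 1-based and unique; absent positions become zeros.
    """
    df = pd.read_csv(tsv_source, sep="\t", comment="#")
    missing = set(COUNT_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"count table missing required columns: {sorted(missing)}")
    pos = df["position"].to_numpy(dtype=np.int64)
    if (pos < 1).any() or (pos > ref.length).any():
        bad = pos[(pos < 1) | (pos > ref.length)]
        raise ValueError(f"positions out of range [1, {ref.length}]: {bad[:5].tolist()}")
    if len(np.unique(pos)) != len(pos):
        raise ValueError("duplicate positions in count table")
    if (df["stops"].to_numpy() < 0).any() or (df["coverage"].to_numpy() < 0).any():
        raise ValueError("negative counts in count table")
    stops = np.zeros(ref.length, dtype=np.int64)
    coverage = np.zeros(ref.length, dtype=np.int64)
    stops[pos - 1] = df["stops"].to_numpy(dtype=np.int64)
    coverage[pos - 1] = df["coverage"].to_numpy(dtype=np.int64)
    return StopCountTrack(transcript=ref, stops=stops, coverage=coverage, channel=channel)


def load_channel_pair(
    treated_tsv, control_tsv, ref: TranscriptRef, sample_name: str = "sample"
) -> ChannelPair:
    """Convenience loader: two count tables -> ChannelPair."""
    return ChannelPair(
        treated=load_count_table(treated_tsv, ref, channel="treated"),
        control=load_count_table(control_tsv, ref, channel="control"),
        sample_name=sample_name,
    )
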