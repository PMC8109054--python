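"""Read-to-guide counting: FASTQ streams to a guide x sample count table.

Screen sequencing reads share a fixed layout: a vector-derived constant
region (the 3' end of the U6 promoter / scaffold junction) immediately 5'
of the 20-nt spacer.  Counting therefore does not need a general aligner:
we locate the constant-region anchor, extract the following 20-mer, and
assign it to the unique library guide it matches exactly (optionally, to a
unique guide at Hamming distance 1).  Every read lands in exactly one
bucket — one guide or "unassigned" — so per-sample totals are conserved.

Coordinates are 0-based, half-open throughout.
"""

from __future__ import annotations

import gzip
import io
import json
import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import pandas as pd

from .library import SgRNALibrary

# default anchor: 3' end of the human U6 promoter as present in common
# lentiGuide-style sgRNA vectors, immediately upstream of the spacer
DEFAULT_ANCHOR = "CGAAACACCG"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ReadMatchConfig:
    """How to locate the spacer within each read.

    ``anchor`` is the constant sequence expected immediately 5' of the
    spacer; ``search_window`` restricts where in the read the anchor may
    start (half-open, ``None`` end = read end).  ``max_mismatches`` is the
    budget for spacer matching (0 or 1); the anchor itself is matched
    exactly.  ``both_strands`` additionally searches the reverse
    complement of reads whose forward orientation lacks the anchor —
    off by default because amplicon primers fix read orientation.
    """

    anchor: str = DEFAULT_ANCHOR
    spacer_length: int = 20
    max_mismatches: int = 0
    search_window: tuple[int, int | None] = (0, None)
    both_strands: bool = False

    def __post_init__(self) -> None:
        if self.max_mismatches not in (0, 1):
            raise ValueError("max_mismatches must be 0 or 1")
        if not self.anchor:
            raise ValueError("anchor must be non-empty")


def extract_spacer(read: str, config: ReadMatchConfig) -> str | None:
    """Return the spacer-length subsequence following the first anchor
    occurrence inside the search window, or None if the read is unusable
    (no anchor, or too short to hold a full spacer after it)."""
    spacer = _extract_forward(read, config)
    if spacer is None and config.both_strands:
        spacer = _extract_forward(reverse_complement(read), config)
    return spacer


def _extract_forward(read: str, config: ReadMatchConfig) -> str | None:
    start, stop = config.search_window
    stop = len(read) if stop is None else min(stop, len(read))
    idx = read.find(config.anchor, start, stop + len(config.anchor) - 1)
    if idx == -1 or idx >= stop:
        return None
    begin = idx + len(config.anchor)
    end = begin + config.spacer_length
    if end > len(read):
        return None
    return read[begin:end]


@dataclass
class CountTable:
    """Guide x sample integer counts plus per-sample bookkeeping.

    ``samples`` is indexed by sample_id with columns ``timepoint`` (T0 or
    T12) and ``replicate_id``.  ``unassigned`` tallies reads that matched
    no guide (including ambiguous ones, which are additionally tracked in
    ``ambiguous``).  For every sample: assigned + unassigned = reads
    processed.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame
    unassigned: pd.Series
    ambiguous: pd.Series = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.ambiguous is None:
            self.ambiguous = pd.Series(0, index=self.counts.columns, dtype=int)
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        missing = [s for s in self.counts.columns if s not in self.samples.index]
        if missing:
            raise ValueError(f"samples sheet missing entries for: {missing}")

    @property
    def total_reads(self) -> pd.Series:
        return self.counts.sum(axis=0) + self.unassigned

    def diagnostics(self) -> dict:
        return {
            "n_guides": int(self.counts.shape[0]),
            "samples": {
                s: {
                    "assigned": int(self.counts[s].sum()),
                    "unassigned": int(self.unassigned[s]),
                    "ambiguous": int(self.ambiguous[s]),
                    "total": int(self.total_reads[s]),
                }
                for s in self.counts.columns
            },
        }


class FastqError(ValueError):
    """Malformed FASTQ input (truncated or out-of-register record)."""


def _open_maybe_gzip(source) -> io.TextIOBase:
    if hasattr(source, "read"):
        return source
    with open(source, "rb") as probe:
        magic = probe.read(2)
    if magic == b"\x1f\x8b":
        return io.TextIOWrapper(gzip.open(source, "rb"))
    return open(source, "r")


def read_fastq(source) -> Iterator[tuple[str, str, str]]:
    """Stream (id, sequence, quality) tuples from a FASTQ(.gz) file.

    Four-line records only.  A truncated trailing record raises
    :class:`FastqError` naming the record index.  (Hand-rolled rather than
    delegated so truncation errors carry the record index and gzip
    autodetection works on content, not file extension.)
    """
    fh = _open_maybe_gzip(source)
    close = not hasattr(source, "read")
    try:
        record_index = 0
        while True:
            header = fh.readline()
            if header == "":
                return
            lines = [fh.readline() for _ in range(3)]
            if any(l == "" for l in lines):
                raise FastqError(
                    f"truncated FASTQ record at record index {record_index}"
                )
            if not header.startswith("@") or not lines[1].startswith("+"):
                raise FastqError(
                    f"malformed FASTQ record at record index {record_index}"
                )
            yield header[1:].rstrip("\n"), lines[0].rstrip("\n"), lines[2].rstrip("\n")
            record_index += 1
    finally:
        if close:
            fh.close()


def _hamming1_variants(spacer: str) -> Iterator[str]:
    for i, base in enumerate(spacer):
        for alt in "ACGT":
            if alt != base:
                yield spacer[:i] + alt + spacer[i + 1 :]


def count_reads(
    read_streams: Mapping[str, Iterable],
    library: SgRNALibrary,
    config: ReadMatchConfig | None = None,
    sample_meta: pd.DataFrame | None = None,
) -> CountTable:
    """Count reads per guide per sample against the library universe.

    ``read_streams`` maps sample_id to an iterable of reads — plain
    sequence strings or (id, sequence, quality) tuples as produced by
    :func:`read_fastq`; qualities are ignored.  Each read increments
    exactly one guide (exact spacer match first; with a mismatch budget of
    1 and no exact match, a unique Hamming-1 library neighbor) or the
    sample's unassigned tally.  A read matching two guides at distance 1
    is ambiguous: counted unassigned and tallied in ``ambiguous``.
    """
    if config is None:
        config = ReadMatchConfig()
    if len(library) and config.spacer_length != len(library.guides[0].spacer):
        raise ValueError("config.spacer_length does not match library spacers")
    sample_ids = list(read_streams)
    if len(set(sample_ids)) != len(sample_ids):
        raise ValueError("sample labels must be unique")

    spacer_to_guide = library.spacer_to_guide
    counts = pd.DataFrame(
        0, index=pd.Index(library.guide_ids, name="guide_id"), columns=sample_ids, dtype=int
    )
    unassigned = pd.Series(0, index=sample_ids, dtype=int)
    ambiguous = pd.Series(0, index=sample_ids, dtype=int)

    for sample, stream in read_streams.items():
        tally: dict[str, int] = {}
        n_unassigned = 0
        n_ambiguous = 0
        for read in stream:
            seq = read[1] if isinstance(read, tuple) else read
            spacer = extract_spacer(seq, config)
            guide = None
            if spacer is not None:
                guide = spacer_to_guide.get(spacer)
                if guide is None and config.max_mismatches == 1:
                    hits = {
                        spacer_to_guide[v]
                        for v in _hamming1_variants(spacer)
                        if v in spacer_to_guide
                    }
                    if len(hits) == 1:
                        guide = hits.pop()
                    elif len(hits) > 1:
                        n_ambiguous += 1
            if guide is None:
                n_unassigned += 1
            else:
                tally[guide] = tally.get(guide, 0) + 1
        if tally:
            counts.loc[list(tally), sample] = list(tally.values())
        unassigned[sample] = n_unassigned
        ambiguous[sample] = n_ambiguous

    if sample_meta is None:
        sample_meta = pd.DataFrame(
            {"timepoint": "", "replicate_id": ""}, index=pd.Index(sample_ids, name="sample_id")
        )
    return CountTable(counts, sample_meta, unassigned, ambiguous)


UNASSIGNED_ROW = "__unassigned__"
AMBIGUOUS_ROW = "__ambiguous__"


def write_count_tsv(table: CountTable, path: str | os.PathLike) -> None:
    """Write the count matrix as TSV: one row per guide plus footer rows
    for unassigned and ambiguous tallies."""
    out = table.counts.copy()
    out.loc[UNASSIGNED_ROW] = table.unassigned
    out.loc[AMBIGUOUS_ROW] = table.ambiguous
    out.to_csv(path, sep="\t", index_label="guide_id")


def read_count_tsv(
    path: str | os.PathLike, samples: pd.DataFrame | None = None
) -> CountTable:
    df = pd.read_csv(path, sep="\t", index_col="guide_id")
    unassigned = (
        df.loc[UNASSIGNED_ROW]
        if UNASSIGNED_ROW in df.index
        else pd.Series(0, index=df.columns)
    )
    ambiguous = (
        df.loc[AMBIGUOUS_ROW]
        if AMBIGUOUS_ROW in df.index
        else pd.Series(0, index=df.columns)
    )
    counts = df.drop(index=[r for r in (UNASSIGNED_ROW, AMBIGUOUS_ROW) if r in df.index])
    if samples is None:
        samples = pd.DataFrame(
            {"timepoint": "", "replicate_id": ""},
            index=pd.Index(counts.columns, name="sample_id"),
        )
    return CountTable(counts.astype(int), samples, unassigned.astype(int), ambiguous.astype(int))


SAMPLE_SHEET_COLUMNS = ["sample_id", "timepoint", "replicate_id"]


def read_sample_sheet(path: str | os.PathLike) -> pd.DataFrame:
    """Load a sample sheet TSV (sample_id, timepoint, replicate_id and
    optionally fastq_path), indexed by sample_id."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"sample sheet missing columns: {missing}")
    return df.set_index("sample_id")


def write_sample_sheet(samples: pd.DataFrame, path: str | os.PathLike) -> None:
    samples.to_csv(path, sep="\t", index_label="sample_id")


def write_diagnostics(table: CountTable, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        json.dump(table.diagnostics(), fh, indent=2)
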