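"""Amplicon-based CRISPR editing quantification.

Cas9 guided by a 20-nt spacer cuts bluntly 3 bp 5' of the PAM, i.e.
between protospacer positions 17 and 18; repair by end joining leaves
indels centered on that cut.  Editing efficiency is therefore measured
the way the field's amplicon tools do: globally align each sequencing
read to the PCR amplicon, and call the read "edited" when it carries at
least one indel overlapping a small window around the predicted cut site.
Substitution-only differences (sequencing noise, SNPs) never count as
editing; reads whose best alignment is still poor (edit distance above a
fraction of read length) are treated as unalignable chimeras/garbage and
excluded from the denominator.

Alignment is Needleman-Wunsch with unit mismatch and gap costs and
deterministic tie-breaking (mismatch preferred over gap, deletion over
insertion); indels are reported left-aligned, so a deletion inside a
homopolymer always appears at the leftmost equivalent position.  All
coordinates are 0-based; a cut site c denotes the bond between reference
bases c-1 and c.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .counting import reverse_complement


@dataclass(frozen=True)
class Amplicon:
    """A PCR amplicon around a guide's genomic target.

    The 20-nt protospacer (``spacer``, given in guide orientation) must
    occur exactly once in the amplicon, on either strand; the matched
    strand is detected at construction.
    """

    name: str
    sequence: str
    spacer: str
    strand: str = field(init=False)
    spacer_start: int = field(init=False)

    def __post_init__(self) -> None:
        seq, sp = self.sequence.upper(), self.spacer.upper()
        object.__setattr__(self, "sequence", seq)
        object.__setattr__(self, "spacer", sp)
        if len(seq) < len(sp) + 10:
            raise ValueError("amplicon too short relative to spacer")
        fwd = _occurrences(seq, sp)
        rev = _occurrences(seq, reverse_complement(sp))
        hits = [(p, "+") for p in fwd] + [(p, "-") for p in rev]
        if len(hits) == 0:
            raise ValueError(f"spacer not found in amplicon {self.name!r}")
        if len(hits) > 1:
            raise ValueError(f"spacer occurs {len(hits)} times in amplicon {self.name!r}")
        pos, strand = hits[0]
        object.__setattr__(self, "strand", strand)
        object.__setattr__(self, "spacer_start", pos)


def _occurrences(haystack: str, needle: str) -> list[int]:
    out, start = [], 0
    while (idx := haystack.find(needle, start)) != -1:
        out.append(idx)
        start = idx + 1
    return out


def predict_cut_site(amplicon: Amplicon) -> int:
    """Predicted blunt-cut coordinate: the bond 3 bp 5' of the PAM
    (between protospacer positions 17 and 18), mapped to forward amplicon
    coordinates for either strand."""
    if amplicon.strand == "+":
        return amplicon.spacer_start + len(amplicon.spacer) - 3
    return amplicon.spacer_start + 3


@dataclass(frozen=True)
class EditingConfig:
    """cut_window: half-width (bp) of the window around the cut site in
    which an indel counts as editing.  max_edit_distance_fraction: reads
    aligning worse than this fraction of their length are discarded."""

    cut_window: int = 3
    max_edit_distance_fraction: float = 0.3

    def __post_init__(self) -> None:
        if self.cut_window < 0:
            raise ValueError("cut_window must be >= 0")


@dataclass(frozen=True)
class Indel:
    """A single gap in the read/amplicon alignment.

    ``pos`` is the left-aligned reference coordinate: for a deletion, the
    first deleted reference base; for an insertion, the reference bond the
    inserted bases sit at.  ``seq`` holds the deleted reference bases or
    the inserted read bases, enabling equivalence-range computation in
    repetitive sequence.
    """

    pos: int
    length: int
    kind: str  # "insertion" | "deletion"
    seq: str

    def placement_range(self, ref: str) -> tuple[int, int]:
        """(leftmost_pos, rightmost_pos) of equivalent placements of this
        indel along the reference (identical alignment cost)."""
        left = self.pos
        right, seq = self.pos, self.seq
        if self.kind == "deletion":
            end = right + self.length
            while end < len(ref) and ref[right] == ref[end]:
                right += 1
                end += 1
        else:
            while right < len(ref) and ref[right] == seq[0]:
                seq = seq[1:] + ref[right]
                right += 1
        return left, right


@dataclass
class Alignment:
    edit_distance: int
    indels: list[Indel]
    ref_length: int


def _nw_matrix(read: str, ref: str) -> np.ndarray:
    """Full edit-distance DP matrix (unit costs), rows = read prefix."""
    m, n = len(read), len(ref)
    D = np.empty((m + 1, n + 1), dtype=np.int32)
    D[0] = np.arange(n + 1)
    col = np.arange(1, n + 1, dtype=np.int32)
    rcodes = np.frombuffer(read.encode("ascii"), dtype=np.uint8)
    fcodes = np.frombuffer(ref.encode("ascii"), dtype=np.uint8)
    for i in range(1, m + 1):
        prev = D[i - 1]
        sub = (rcodes[i - 1] != fcodes).astype(np.int32)
        best_in = np.minimum(prev[:-1] + sub, prev[1:] + 1)
        # within-row (deletion) closure: D[i,j] = j + min(i, min_{k<=j}(best_in[k]-k))
        acc = np.minimum.accumulate(best_in - col)
        D[i, 0] = i
        D[i, 1:] = col + np.minimum(i, acc)
    return D


def _left_align(indel: Indel, ref: str) -> Indel:
    pos, seq = indel.pos, indel.seq
    if indel.kind == "deletion":
        while pos > 0 and ref[pos - 1] == ref[pos + indel.length - 1]:
            pos -= 1
        seq = ref[pos : pos + indel.length]
    else:
        while pos > 0 and ref[pos - 1] == seq[-1]:
            seq = ref[pos - 1] + seq[:-1]
            pos -= 1
    return Indel(pos, indel.length, indel.kind, seq)


def align_read(read: str, amplicon: Amplicon | str) -> Alignment:
    """Global alignment of a read against the amplicon reference.

    Unit mismatch/gap costs; ties broken deterministically (mismatch over
    gap, then deletion over insertion); gap runs canonicalized to their
    leftmost equivalent placement.  Returns the edit distance and the
    indel list in reference coordinates.
    """
    if not read:
        raise ValueError("read must be non-empty")
    ref = amplicon.sequence if isinstance(amplicon, Amplicon) else amplicon
    read = read.upper()
    D = _nw_matrix(read, ref)
    m, n = len(read), len(ref)

    # Traceback; preference at gap opening is mismatch > deletion >
    # insertion, but an already-open gap run is extended whenever cost
    # permits, so equal-cost paths never fragment one indel into several
    # (the contiguity an affine gap penalty would enforce).
    ops: list[tuple[str, int]] = []  # (op, ref_pos) with op in M/D/I
    i, j = m, n
    prev = "M"
    while i > 0 or j > 0:
        here = D[i, j]
        can_m = i > 0 and j > 0 and here == D[i - 1, j - 1] + (read[i - 1] != ref[j - 1])
        can_d = j > 0 and here == D[i, j - 1] + 1
        can_i = i > 0 and here == D[i - 1, j] + 1
        if prev == "D" and can_d:
            op = "D"
        elif prev == "I" and can_i:
            op = "I"
        elif can_m:
            op = "M"
        elif can_d:
            op = "D"
        else:
            op = "I"
        if op == "M":
            ops.append(("M", j - 1))
            i -= 1
            j -= 1
        elif op == "D":
            ops.append(("D", j - 1))
            j -= 1
        else:
            ops.append(("I", j))
            i -= 1
        prev = op
    ops.reverse()

    indels: list[Indel] = []
    k = 0
    read_pos = 0
    while k < len(ops):
        op, ref_pos = ops[k]
        if op == "M":
            read_pos += 1
            k += 1
        elif op == "D":
            start = ref_pos
            length = 0
            while k < len(ops) and ops[k][0] == "D":
                length += 1
                k += 1
            indels.append(
                _left_align(Indel(start, length, "deletion", ref[start : start + length]), ref)
            )
        else:  # insertion run at reference bond ref_pos
            start_read = read_pos
            length = 0
            while k < len(ops) and ops[k][0] == "I":
                length += 1
                read_pos += 1
                k += 1
            seq = read[start_read : start_read + length]
            indels.append(_left_align(Indel(ref_pos, length, "insertion", seq), ref))

    return Alignment(edit_distance=int(D[m, n]), indels=indels, ref_length=n)


@dataclass
class EditingResult:
    """Read-level editing summary.  ``editing_fraction`` is computed over
    aligned reads; the histogram keys are signed indel sizes (insertions
    positive, deletions negative) of cut-window indels."""

    n_reads_total: int
    n_reads_aligned: int
    n_edited: int
    editing_fraction: float
    indel_size_histogram: dict[int, int]

    def to_dict(self) -> dict:
        return {
            "n_reads_total": self.n_reads_total,
            "n_reads_aligned": self.n_reads_aligned,
            "n_edited": self.n_edited,
            "editing_fraction": self.editing_fraction,
            "indel_size_histogram": {str(k): v for k, v in sorted(self.indel_size_histogram.items())},
        }


def indel_overlaps_window(indel: Indel, ref: str, cut: int, half_width: int) -> bool:
    """Whether any cost-equivalent placement of the indel touches the
    cut window.  The window covers reference bases [cut-w, cut+w) — the
    2w bases flanking the cut bond — for deletions, and bonds
    [cut-w, cut+w] for insertions.  Using the full equivalence range makes
    the call independent of which canonical placement the aligner picked
    inside repetitive sequence."""
    left, right = indel.placement_range(ref)
    if indel.kind == "deletion":
        # union of equivalent spans is [left, right + length)
        return left < cut + half_width and right + indel.length > cut - half_width
    return left <= cut + half_width and right >= cut - half_width


def quantify_editing(
    reads: Iterable,
    amplicon: Amplicon,
    config: EditingConfig | None = None,
) -> EditingResult:
    """Fraction of aligned reads carrying >= 1 indel at the cut window.

    ``reads`` is an iterable of sequence strings or (id, sequence,
    quality) tuples.  A read counts once regardless of how many cut-window
    indels it carries (read-level "% gene editing").
    """
    if config is None:
        config = EditingConfig()
    cut = predict_cut_site(amplicon)
    ref = amplicon.sequence
    n_total = n_aligned = n_edited = 0
    hist: Counter[int] = Counter()
    for read in reads:
        seq = read[1] if isinstance(read, tuple) else read
        n_total += 1
        aln = align_read(seq, amplicon)
        if aln.edit_distance > config.max_edit_distance_fraction * len(seq):
            continue
        n_aligned += 1
        cut_indels = [
            ind
            for ind in aln.indels
            if indel_overlaps_window(ind, ref, cut, config.cut_window)
        ]
        if cut_indels:
            n_edited += 1
            for ind in cut_indels:
                hist[ind.length if ind.kind == "insertion" else -ind.length] += 1
    if n_aligned == 0:
        raise ValueError("no reads passed the alignment filter; editing fraction undefined")
    return EditingResult(
        n_reads_total=n_total,
        n_reads_aligned=n_aligned,
        n_edited=n_edited,
        editing_fraction=n_edited / n_aligned,
        indel_size_histogram=dict(hist),
    )
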