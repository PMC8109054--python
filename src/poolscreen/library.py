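"""sgRNA library modeling.

A pooled CRISPR screen is defined by its guide library: a set of single
guide RNAs (sgRNAs), each carrying a 20-nt spacer that directs Cas9 to one
genomic target.  The library here mirrors a typical in vivo dependency
screen layout: several guides per target gene, a handful of guides against
an essential positive-control gene, and one nontargeting control (NTC)
guide that should behave neutrally.

The library is the reference universe for read counting: every sequenced
read is assigned to exactly one spacer (or to "unassigned"), so spacer
uniqueness is a hard invariant, not a warning.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

SPACER_LENGTH = 20
SPACER_ALPHABET = frozenset("ACGT")
NTC_GENE = "NTC"

ROLES = ("targeting", "positive_control", "nontargeting")


@dataclass(frozen=True)
class SgRNA:
    """A single guide: identifier, target gene symbol, role and 20-nt spacer.

    Construction does not validate the spacer; malformed entries are
    surfaced by :func:`validate_library` so that broken library tables can
    be loaded and inspected rather than rejected wholesale.
    """

    guide_id: str
    gene: str
    role: str
    spacer: str

    def is_malformed(self) -> str | None:
        """Return a human-readable defect description, or None if valid."""
        if self.role not in ROLES:
            return f"unknown role {self.role!r}"
        if len(self.spacer) != SPACER_LENGTH:
            return f"spacer length {len(self.spacer)} != {SPACER_LENGTH}"
        if not set(self.spacer) <= SPACER_ALPHABET:
            bad = sorted(set(self.spacer) - SPACER_ALPHABET)
            return f"spacer contains non-ACGT characters {bad}"
        if self.role == "nontargeting" and self.gene != NTC_GENE:
            return f"nontargeting guide must have gene {NTC_GENE!r}, got {self.gene!r}"
        return None


class LibraryError(ValueError):
    """Raised when a library violates a hard invariant (duplicate ids/spacers)."""


@dataclass(frozen=True)
class SgRNALibrary:
    """An ordered sgRNA collection with unique guide ids and unique spacers."""

    guides: tuple[SgRNA, ...]
    name: str = "library"

    def __post_init__(self) -> None:
        ids = [g.guide_id for g in self.guides]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise LibraryError(f"duplicate guide ids: {dupes}")
        spacers = [g.spacer for g in self.guides]
        if len(set(spacers)) != len(spacers):
            seen: dict[str, str] = {}
            dupes = []
            for g in self.guides:
                if g.spacer in seen:
                    dupes.append((seen[g.spacer], g.guide_id))
                seen[g.spacer] = g.guide_id
            raise LibraryError(f"duplicate spacers shared by guide pairs: {dupes}")

    def __len__(self) -> int:
        return len(self.guides)

    def __iter__(self) -> Iterator[SgRNA]:
        return iter(self.guides)

    @property
    def guide_ids(self) -> list[str]:
        return [g.guide_id for g in self.guides]

    @property
    def spacer_to_guide(self) -> dict[str, str]:
        return {g.spacer: g.guide_id for g in self.guides}

    def genes(self) -> list[str]:
        """Target gene symbols in library order (NTC excluded), deduplicated."""
        out: list[str] = []
        for g in self.guides:
            if g.role != "nontargeting" and g.gene not in out:
                out.append(g.gene)
        return out

    def guides_for_gene(self, gene: str) -> list[SgRNA]:
        return [g for g in self.guides if g.gene == gene]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "guide_id": [g.guide_id for g in self.guides],
                "gene": [g.gene for g in self.guides],
                "role": [g.role for g in self.guides],
                "spacer": [g.spacer for g in self.guides],
            }
        )


def _random_spacer(rng: np.random.Generator) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, SPACER_LENGTH)])


def build_library(
    gene_names: Sequence[str],
    sgrnas_per_gene: int,
    positive_control: tuple[str, int] | None = None,
    n_nontargeting: int = 0,
    spacers: Sequence[str] | None = None,
    seed: int = 0,
    name: str = "library",
) -> SgRNALibrary:
    """Assemble a screen library from a gene list plus control guides.

    Guides are ordered deterministically: targeting guides gene by gene in
    input order, then positive-control guides, then NTC guides.  When
    explicit ``spacers`` are not supplied, unique placeholder spacers are
    drawn from a seeded generator (collisions are re-drawn); actual guide
    design against a genome is outside the scope of screen analysis.

    Parameters
    ----------
    gene_names
        Unique target gene symbols.
    sgrnas_per_gene
        Guides designed per target gene.
    positive_control
        Optional ``(gene_symbol, n_guides)`` for an essential-gene control.
    n_nontargeting
        Number of nontargeting control guides (gene label "NTC").
    spacers
        Optional explicit spacer list covering the whole library, in the
        ordering above.  Must be unique, length-20, ACGT.
    seed
        Seed for placeholder spacer generation.
    """
    if len(gene_names) == 0:
        raise ValueError("gene_names must be non-empty")
    if len(set(gene_names)) != len(gene_names):
        dupes = sorted({g for g in gene_names if list(gene_names).count(g) > 1})
        raise ValueError(f"duplicate gene names: {dupes}")
    if sgrnas_per_gene < 0 or n_nontargeting < 0:
        raise ValueError("guide counts must be non-negative")
    pc_gene, pc_count = (None, 0)
    if positive_control is not None:
        pc_gene, pc_count = positive_control
        if pc_count < 0:
            raise ValueError("positive_control count must be non-negative")

    total = len(gene_names) * sgrnas_per_gene + pc_count + n_nontargeting

    if spacers is not None:
        if len(spacers) != total:
            raise ValueError(
                f"{len(spacers)} spacers supplied for a library of {total} guides"
            )
        if len(set(spacers)) != len(spacers):
            raise ValueError("supplied spacers are not unique")
        for s in spacers:
            if len(s) != SPACER_LENGTH or not set(s) <= SPACER_ALPHABET:
                raise ValueError(f"malformed spacer {s!r}")
        spacer_iter: Iterator[str] = iter(spacers)
    else:
        rng = np.random.default_rng(seed)
        drawn: list[str] = []
        seen: set[str] = set()
        while len(drawn) < total:
            s = _random_spacer(rng)
            if s not in seen:  # collisions re-drawn
                seen.add(s)
                drawn.append(s)
        spacer_iter = iter(drawn)

    guides: list[SgRNA] = []
    for gene in gene_names:
        for i in range(1, sgrnas_per_gene + 1):
            guides.append(SgRNA(f"{gene}_sg{i}", gene, "targeting", next(spacer_iter)))
    for i in range(1, pc_count + 1):
        assert pc_gene is not None
        guides.append(
            SgRNA(f"{pc_gene}_sg{i}", pc_gene, "positive_control", next(spacer_iter))
        )
    for i in range(1, n_nontargeting + 1):
        guides.append(SgRNA(f"NTC_sg{i}", NTC_GENE, "nontargeting", next(spacer_iter)))

    return SgRNALibrary(tuple(guides), name=name)


def example_screen_library(
    n_genes: int = 96,
    sgrnas_per_gene: int = 5,
    positive_control: tuple[str, int] = ("Hoxa9", 5),
    n_nontargeting: int = 1,
    seed: int = 7,
) -> SgRNALibrary:
    """A library with the layout of a typical in vivo surfaceome screen:
    96 genes x 5 guides + 5 essential-control guides + 1 NTC = 486 guides."""
    genes = [f"Gene{i:03d}" for i in range(1, n_genes + 1)]
    return build_library(
        genes,
        sgrnas_per_gene,
        positive_control=positive_control,
        n_nontargeting=n_nontargeting,
        seed=seed,
        name=f"screen_{n_genes}x{sgrnas_per_gene}",
    )


def write_reference(library: SgRNALibrary, destination) -> None:
    """Write the library as a multi-FASTA reference (header = guide_id,
    sequence = spacer); counting aligns/extracts against this universe."""
    records = [
        SeqRecord(Seq(g.spacer), id=g.guide_id, description="") for g in library
    ]
    if hasattr(destination, "write"):
        SeqIO.write(records, destination, "fasta")
    else:
        with open(destination, "w") as fh:
            SeqIO.write(records, fh, "fasta")


def read_reference(source) -> dict[str, str]:
    """Parse a guide reference FASTA back into a guide_id -> spacer map."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(source, "fasta")}


@dataclass
class ValidationReport:
    """Outcome of library validation; empty lists mean all invariants hold."""

    duplicate_ids: list[str] = field(default_factory=list)
    duplicate_spacers: list[list[str]] = field(default_factory=list)
    malformed: list[tuple[str, str]] = field(default_factory=list)
    near_matches: list[tuple[str, str]] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not (
            self.duplicate_ids
            or self.duplicate_spacers
            or self.malformed
            or self.near_matches
        )


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def validate_library(
    guides: Iterable[SgRNA], check_near_matches: bool = False
) -> ValidationReport:
    """Check library invariants, reporting (never raising).

    Accepts any iterable of guides so that collections violating the
    hard ``SgRNALibrary`` invariants can still be diagnosed.  With
    ``check_near_matches`` the report also flags spacer pairs within
    Hamming distance 1 — guides that close can cross-react (multi-locus
    homology is a known source of false positives in screens), so the
    check is available but off by default.
    """
    guides = list(guides)
    report = ValidationReport()

    ids = [g.guide_id for g in guides]
    report.duplicate_ids = sorted({i for i in ids if ids.count(i) > 1})

    by_spacer: dict[str, list[str]] = {}
    for g in guides:
        by_spacer.setdefault(g.spacer, []).append(g.guide_id)
    report.duplicate_spacers = [v for v in by_spacer.values() if len(v) > 1]

    for g in guides:
        defect = g.is_malformed()
        if defect is not None:
            report.malformed.append((g.guide_id, defect))

    if check_near_matches:
        for i, a in enumerate(guides):
            for b in guides[i + 1 :]:
                if (
                    a.spacer != b.spacer
                    and len(a.spacer) == len(b.spacer)
                    and _hamming(a.spacer, b.spacer) <= 1
                ):
                    report.near_matches.append((a.guide_id, b.guide_id))
    return report


LIBRARY_COLUMNS = ["guide_id", "gene", "role", "spacer"]


def write_library_tsv(library: SgRNALibrary, path: str | os.PathLike) -> None:
    library.to_frame().to_csv(path, sep="\t", index=False)


def read_library_tsv(path: str | os.PathLike | io.TextIOBase, name: str | None = None) -> SgRNALibrary:
    """Load a library table (TSV with guide_id, gene, role, spacer columns)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in LIBRARY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"library table missing columns: {missing}")
    guides = tuple(
        SgRNA(r.guide_id, r.gene, r.role, r.spacer) for r in df.itertuples()
    )
    if name is None:
        name = os.path.splitext(os.path.basename(str(getattr(path, "name", path))))[0]
    return SgRNALibrary(guides, name=name)
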