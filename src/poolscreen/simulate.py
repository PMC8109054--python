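"""Synthetic in vivo screen and amplicon-read generation with ground truth.

The generator mirrors the statistical structure of a pooled dropout screen
run through transplantation: (1) the plasmid pool is skewed (lognormal
abundances — cloning never yields a uniform pool); (2) a finite number of
cells is transduced, sampled multinomially from the pool; (3) each
recipient mouse is seeded by an engraftment bottleneck — a multinomial
subsample of the transplanted pool, the dominant noise source of in vivo
screens; (4) cells carrying a guide split into an edited fraction (whose
growth over the assay is multiplied by 2**effect, with effect the guide's
log2 fitness effect over the whole assay) and an unedited, neutral
fraction; (5) sequencing counts are drawn Dirichlet-multinomially, i.e.
overdispersed relative to a pure multinomial, for the shared T0 sample
and each mouse's T12 sample.

Selection acts on expected abundances; stochasticity enters only at the
sampling stages.  Every stage is seeded from a single root seed, so runs
are reproducible bit for bit.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterator, Mapping

import numpy as np
import pandas as pd

from .counting import DEFAULT_ANCHOR, CountTable
from .editing import Amplicon, predict_cut_site
from .library import SgRNALibrary, example_screen_library
from .scoring import GeneScores


@dataclass(frozen=True)
class SimConfig:
    """Screen-simulation parameters.

    Defaults follow a typical in vivo AML dependency screen: 1e6 cells
    transduced with a 486-guide library, five recipient mice each seeded
    by ~2e5 engrafting cells (~400 cells/guide at the bottleneck), 12 days
    of selection, ~90% functional knockout among transduced cells, and
    deep overdispersed sequencing of one shared T0 plus one T12 per mouse.

    ``seq_dispersion`` is the mean per-guide Dirichlet concentration of
    the sequencing stage (the Dirichlet parameter is
    proportions * n_guides * seq_dispersion): larger values approach a
    pure multinomial, smaller values add overdispersion.
    ``gene_effects`` maps gene symbols to log2 fitness effects applied to
    knocked-out cells over the whole assay; unlisted genes are neutral.
    Per-guide effects add a normal deviation with sd ``guide_effect_sd``.
    """

    library: SgRNALibrary = field(default_factory=example_screen_library)
    plasmid_log_sd: float = 0.5
    cells_transduced: int = 1_000_000
    engrafting_cells_per_mouse: int = 200_000
    n_mice: int = 5
    days: float = 12.0
    doubling_time_days: float = 1.0
    read_depth: int = 5_000_000
    seq_dispersion: float = 1000.0
    editing_efficiency: float = 0.9
    guide_effect_sd: float = 0.3
    gene_effects: Mapping[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.editing_efficiency <= 1):
            raise ValueError("editing_efficiency must be in [0, 1]")
        for name, val in (
            ("cells_transduced", self.cells_transduced),
            ("engrafting_cells_per_mouse", self.engrafting_cells_per_mouse),
            ("n_mice", self.n_mice),
            ("read_depth", self.read_depth),
        ):
            if val <= 0:
                raise ValueError(f"{name} must be positive")
        if self.engrafting_cells_per_mouse > self.cells_transduced:
            raise ValueError("bottleneck larger than the transduced pool is infeasible")
        unknown = set(self.gene_effects) - set(self.library.genes())
        if unknown:
            raise ValueError(f"gene_effects reference unknown genes: {sorted(unknown)}")


@dataclass
class SimTruth:
    """Ground truth emitted alongside simulated counts.

    ``guide_effects`` are realized per-guide log2 fitness effects
    (gene effect + guide deviation; exactly 0 for nontargeting guides).
    ``t0_cells`` / ``engrafted`` / ``t12_expected`` are the per-guide cell
    abundances at the corresponding stages (expected, not resampled, for
    T12).
    """

    gene_effects: dict[str, float]
    guide_effects: pd.Series
    t0_cells: pd.Series
    engrafted: pd.DataFrame
    t12_expected: pd.DataFrame


@dataclass
class SimulatedScreen:
    count_table: CountTable
    truth: SimTruth
    config: SimConfig


def _dirichlet_multinomial(
    rng: np.random.Generator, n: int, proportions: np.ndarray, concentration: float
) -> np.ndarray:
    """Overdispersed counts: p ~ Dirichlet(proportions * concentration),
    counts ~ Multinomial(n, p).  Zero-proportion categories stay zero."""
    counts = np.zeros(len(proportions), dtype=np.int64)
    pos = proportions > 0
    alpha = proportions[pos] * concentration
    p = rng.dirichlet(alpha)
    counts[pos] = rng.multinomial(n, p)
    return counts


def draw_guide_effects(config: SimConfig, rng: np.random.Generator) -> pd.Series:
    """Per-guide realized effects: gene effect plus N(0, guide_effect_sd)
    deviation for every targeting/positive-control guide; 0 for NTC."""
    effects = {}
    for g in config.library:
        if g.role == "nontargeting":
            effects[g.guide_id] = 0.0
        else:
            base = float(config.gene_effects.get(g.gene, 0.0))
            effects[g.guide_id] = base + float(rng.normal(0.0, config.guide_effect_sd))
    return pd.Series(effects, name="log2_effect").loc[[g.guide_id for g in config.library]]


def expected_t12_abundance(
    engrafted: np.ndarray, effects: np.ndarray, editing_efficiency: float
) -> np.ndarray:
    """Expected relative abundance after selection: each guide's cells are
    a mixture of an edited fraction growing by 2**effect over the assay
    and an unedited neutral fraction.  The common baseline expansion
    cancels when proportions are formed, so it is omitted."""
    return engrafted * (
        editing_efficiency * np.power(2.0, effects) + (1.0 - editing_efficiency)
    )


def simulate_screen(config: SimConfig) -> SimulatedScreen:
    """Run the full generative pipeline and return counts plus truth.

    Sample layout: one shared "T0" column (the transduced pool, sequenced
    once) and one "T12_m<i>" column per mouse, with replicate ids m1..mN.
    """
    lib = config.library
    n_guides = len(lib)
    guide_ids = lib.guide_ids
    ss = np.random.SeedSequence(config.seed)
    rngs = [np.random.default_rng(s) for s in ss.spawn(5)]
    rng_plasmid, rng_effects, rng_t0, rng_engraft, rng_seq = rngs

    # (1) skewed plasmid pool
    plasmid = rng_plasmid.lognormal(mean=0.0, sigma=config.plasmid_log_sd, size=n_guides)
    plasmid_p = plasmid / plasmid.sum()

    effects = draw_guide_effects(config, rng_effects)

    # (2) transduced cells at T0
    t0_cells = rng_t0.multinomial(config.cells_transduced, plasmid_p)
    t0_p = t0_cells / t0_cells.sum()

    # (3) per-mouse engraftment bottleneck, (4) deterministic selection
    concentration = n_guides * config.seq_dispersion
    engrafted_cols = {}
    t12_expected_cols = {}
    count_cols = {}
    eff_arr = effects.to_numpy()
    for m in range(1, config.n_mice + 1):
        mouse = f"m{m}"
        engrafted = rng_engraft.multinomial(config.engrafting_cells_per_mouse, t0_p)
        w = expected_t12_abundance(
            engrafted.astype(float), eff_arr, config.editing_efficiency
        )
        engrafted_cols[mouse] = engrafted
        t12_expected_cols[mouse] = w
        # (5) overdispersed sequencing of the T12 sample
        props = w / w.sum()
        count_cols[f"T12_{mouse}"] = _dirichlet_multinomial(
            rng_seq, config.read_depth, props, concentration
        )

    # (5) shared T0 sequencing
    t0_counts = _dirichlet_multinomial(rng_seq, config.read_depth, t0_p, concentration)

    index = pd.Index(guide_ids, name="guide_id")
    counts = pd.DataFrame({"T0": t0_counts, **count_cols}, index=index)
    samples = pd.DataFrame(
        {
            "timepoint": ["T0"] + ["T12"] * config.n_mice,
            "replicate_id": [""] + [f"m{m}" for m in range(1, config.n_mice + 1)],
        },
        index=pd.Index(counts.columns, name="sample_id"),
    )
    table = CountTable(
        counts,
        samples,
        unassigned=pd.Series(0, index=counts.columns),
    )
    truth = SimTruth(
        gene_effects=dict(config.gene_effects),
        guide_effects=effects,
        t0_cells=pd.Series(t0_cells, index=index, name="t0_cells"),
        engrafted=pd.DataFrame(engrafted_cols, index=index),
        t12_expected=pd.DataFrame(t12_expected_cols, index=index),
    )
    return SimulatedScreen(count_table=table, truth=truth, config=config)


def reads_for_sample(
    table: CountTable,
    library: SgRNALibrary,
    sample: str,
    anchor: str = DEFAULT_ANCHOR,
    read_length: int = 60,
    seed: int = 0,
) -> Iterator[tuple[str, str, str]]:
    """Emit FASTQ-style records realizing a sample's counts: each read is
    anchor + spacer + random tail, shuffled, enabling end-to-end tests of
    the counting stage.  Unassigned tallies become junk reads without the
    anchor."""
    rng = np.random.default_rng(seed)
    spacers = {g.guide_id: g.spacer for g in library}
    order = []
    for guide_id, n in table.counts[sample].items():
        order.extend([guide_id] * int(n))
    order.extend([None] * int(table.unassigned[sample]))
    rng.shuffle(order)
    bases = np.array(list("ACGT"))
    for i, guide_id in enumerate(order):
        if guide_id is None:
            seq = "".join(bases[rng.integers(0, 4, read_length)])
        else:
            core = anchor + spacers[guide_id]
            tail_len = max(0, read_length - len(core))
            seq = core + "".join(bases[rng.integers(0, 4, tail_len)])
        yield f"{sample}:{i}", seq, "I" * len(seq)


def write_fastq(records, path: str | os.PathLike) -> None:
    import gzip as _gzip

    opener = _gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as fh:
        for rid, seq, qual in records:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")


def random_amplicon(
    length: int = 200, spacer_length: int = 20, seed: int = 0, name: str = "synthetic_amplicon"
) -> Amplicon:
    """A random amplicon whose central 20-mer serves as the protospacer
    (forward strand), for editing-quantification fixtures."""
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    while True:
        seq = "".join(bases[rng.integers(0, 4, length)])
        start = (length - spacer_length) // 2
        spacer = seq[start : start + spacer_length]
        # regenerate in the (unlikely) case the 20-mer recurs
        if seq.count(spacer) == 1 and seq.count(
            spacer.translate(str.maketrans("ACGT", "TGCA"))[::-1]
        ) == 0:
            return Amplicon(name, seq, spacer)


def simulate_amplicon_reads(
    amplicon: Amplicon,
    editing_fraction: float,
    n_reads: int,
    indel_size_range: tuple[int, int] = (1, 10),
    substitution_error_rate: float = 0.01,
    cut_window: int = 3,
    seed: int = 0,
) -> tuple[list[tuple[str, str, str]], np.ndarray]:
    """Generate amplicon sequencing reads with known editing status.

    An ``editing_fraction`` share of reads carries exactly one indel
    (size uniform over ``indel_size_range``, insertion/deletion by coin
    flip) whose reference span intersects the +/- ``cut_window`` window
    around the predicted cut site; every read then receives independent
    per-base substitution noise.  Returns the records and a boolean truth
    vector (True = carries a planted cut-site indel).
    """
    if not (0 <= editing_fraction <= 1):
        raise ValueError("editing_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    ref = amplicon.sequence
    cut = predict_cut_site(amplicon)
    lo, hi = indel_size_range
    bases = np.array(list("ACGT"))
    n_edited = int(round(editing_fraction * n_reads))
    edited_flags = np.zeros(n_reads, dtype=bool)
    edited_flags[:n_edited] = True
    rng.shuffle(edited_flags)

    records = []
    for i in range(n_reads):
        seq = ref
        if edited_flags[i]:
            size = int(rng.integers(lo, hi + 1))
            if rng.random() < 0.5:  # deletion: span [s, s+size) hits [cut-w, cut+w)
                s_lo = max(0, cut - cut_window - size + 1)
                s_hi = min(len(ref) - size, cut + cut_window - 1)
                s = int(rng.integers(s_lo, s_hi + 1))
                seq = seq[:s] + seq[s + size :]
            else:  # insertion at a bond in [cut-w, cut+w]
                p = int(rng.integers(cut - cut_window, cut + cut_window + 1))
                ins = "".join(bases[rng.integers(0, 4, size)])
                seq = seq[:p] + ins + seq[p:]
        if substitution_error_rate > 0:
            arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
            hit = rng.random(len(arr)) < substitution_error_rate
            if hit.any():
                originals = arr[hit]
                subs = bases[rng.integers(0, 4, hit.sum())].astype("S1").view(np.uint8)
                # re-draw identical substitutions so an "error" always changes the base
                same = subs == originals
                while same.any():
                    subs[same] = (
                        bases[rng.integers(0, 4, same.sum())].astype("S1").view(np.uint8)
                    )
                    same = subs == originals
                arr[hit] = subs
                seq = arr.tobytes().decode("ascii")
        records.append((f"read{i}", seq, "I" * len(seq)))
    return records, edited_flags


@dataclass
class RecoveryReport:
    """How well scoring recovered the simulator's planted truth.

    ``sensitivity`` is None when the screen was all-null (no positives to
    recover).  Ranks are positions in the direction-appropriate hit list.
    """

    true_hit_ranks: dict[str, int]
    sensitivity: float | None
    specificity: float
    n_true_positive: int
    n_true_null: int

    def to_dict(self) -> dict:
        return {
            "true_hit_ranks": self.true_hit_ranks,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "n_true_positive": self.n_true_positive,
            "n_true_null": self.n_true_null,
        }


def truth_recovery_report(screen: SimulatedScreen, scores: GeneScores) -> RecoveryReport:
    """Compare gene classifications against planted effect signs.

    A gene with effect < 0 should classify as positive_regulator (its
    loss depletes the cells); effect > 0 as negative_regulator; effect 0
    (or absent) as none.
    """
    scored_genes = {s.gene for s in scores.depletion}
    truth_genes = set(screen.config.library.genes())
    if scored_genes != truth_genes:
        raise ValueError("scored gene set does not match the simulated library")

    expected: dict[str, str] = {}
    for gene in truth_genes:
        eff = screen.truth.gene_effects.get(gene, 0.0)
        expected[gene] = (
            "positive_regulator" if eff < 0 else "negative_regulator" if eff > 0 else "none"
        )
    called = {s.gene: s.classification for s in scores.depletion}
    dep_rank = {s.gene: s.rank for s in scores.depletion}
    enr_rank = {s.gene: s.rank for s in scores.enrichment}

    positives = [g for g, e in expected.items() if e != "none"]
    nulls = [g for g, e in expected.items() if e == "none"]
    ranks = {
        g: (dep_rank[g] if expected[g] == "positive_regulator" else enr_rank[g])
        for g in positives
    }
    sensitivity = (
        sum(called[g] == expected[g] for g in positives) / len(positives)
        if positives
        else None
    )
    specificity = (
        sum(called[g] == "none" for g in nulls) / len(nulls) if nulls else 1.0
    )
    return RecoveryReport(
        true_hit_ranks=ranks,
        sensitivity=sensitivity,
        specificity=specificity,
        n_true_positive=len(positives),
        n_true_null=len(nulls),
    )
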