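"""Fold-change scoring and gene-level hit calling for pooled screens.

The screen statistic is simple and deliberately so: raw guide counts are
normalized per sample to reads per million (with a pseudocount so that
strongly depleted guides with zero endpoint reads remain finite), each
guide's fold change is the ratio of its end-of-assay (T12) representation
to its pre-transplant (T0) representation, the per-guide median of those
fold changes across replicate animals is the ranking statistic, and a gene
is called a hit when at least ``min_guides_for_hit`` of its guides pass a
symmetric 2-fold threshold in the same direction.

"Positive regulator" means loss of the gene depletes the cells (the gene
supports growth/survival); "negative regulator" means loss enriches them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .counting import CountTable
from .library import SgRNALibrary


@dataclass(frozen=True)
class ScoringConfig:
    pseudocount: float = 1.0
    fc_threshold: float = 2.0
    min_guides_for_hit: int = 2
    scale: float = 1e6  # reads per million

    def __post_init__(self) -> None:
        if self.fc_threshold <= 1:
            raise ValueError("fc_threshold must be > 1")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be >= 0")


def normalize(
    counts: CountTable | pd.DataFrame, config: ScoringConfig | None = None
) -> pd.DataFrame:
    """Total-count normalization to reads per million.

    rep[g, s] = (count[g, s] + pseudocount) / sum_g(count[g, s] + pseudocount) * scale

    The pseudocount is added before scaling so every guide has strictly
    positive representation (required downstream: fold changes of fully
    depleted guides must be finite).
    """
    if config is None:
        config = ScoringConfig()
    raw = counts.counts if isinstance(counts, CountTable) else counts
    shifted = raw.astype(float) + config.pseudocount
    totals = shifted.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(
            f"sample(s) with zero total count and zero pseudocount: {list(zero.index)}"
        )
    return shifted / totals * config.scale


def build_pairing(samples: pd.DataFrame) -> dict[str, tuple[str, str]]:
    """Derive the replicate -> (T12 sample, T0 sample) pairing from a
    sample sheet.  A single shared T0 (the transduced pool, sequenced
    once) pairs with every replicate; if T0 samples carry replicate ids
    matching the T12 replicates, they are paired per replicate instead."""
    t0 = samples[samples["timepoint"] == "T0"]
    t12 = samples[samples["timepoint"] == "T12"]
    if len(t0) == 0 or len(t12) == 0:
        raise ValueError("sample sheet must contain both T0 and T12 samples")
    pairing: dict[str, tuple[str, str]] = {}
    t0_by_rep = {r.replicate_id: idx for idx, r in t0.iterrows()}
    shared_t0 = t0.index[0]
    for idx, row in t12.iterrows():
        rep = row.replicate_id
        t0_sample = t0_by_rep.get(rep, shared_t0) if len(t0) > 1 else shared_t0
        pairing[rep] = (idx, t0_sample)
    return pairing


def fold_change(
    rep: pd.DataFrame, pairing: Mapping[str, tuple[str, str]]
) -> pd.DataFrame:
    """Per-guide, per-replicate fold change: T12 representation / T0
    representation.  One shared T0 sample may appear in every pair."""
    missing = sorted(
        {s for pair in pairing.values() for s in pair if s not in rep.columns}
    )
    if missing:
        raise ValueError(f"pairing references samples absent from table: {missing}")
    out = {}
    for replicate, (t12, t0) in pairing.items():
        denom = rep[t0]
        if (denom <= 0).any():
            raise ValueError(f"non-positive T0 representation in sample {t0!r}")
        out[replicate] = rep[t12] / denom
    fc = pd.DataFrame(out)
    fc.columns.name = "replicate_id"
    return fc


def median_fold_change(fc: pd.DataFrame) -> pd.DataFrame:
    """Median across replicates per guide, and its log2.

    An even replicate count uses the classical sample median (midpoint of
    the central pair).  The log2 is applied after the median.
    """
    if fc.shape[1] < 1:
        raise ValueError("at least one replicate required")
    med = fc.median(axis=1)
    return pd.DataFrame({"median_fc": med, "log2_median_fc": np.log2(med)})


@dataclass(frozen=True)
class GeneScore:
    """Per-gene hit summary.

    ``summary_log2fc`` is the median of the gene's guide-level log2 median
    fold changes.  Classification: positive_regulator when at least
    ``min_guides_for_hit`` guides are depleted past threshold and
    depletion dominates; negative_regulator symmetrically; none otherwise.
    """

    gene: str
    n_guides: int
    n_depleted: int
    n_enriched: int
    summary_log2fc: float
    classification: str
    rank: int


@dataclass
class GeneScores:
    """Ranked hit lists for both screen directions plus the NTC report."""

    depletion: list[GeneScore]
    enrichment: list[GeneScore]
    ntc: pd.DataFrame

    def gene_table(self, direction: str = "depletion") -> pd.DataFrame:
        scores = self.depletion if direction == "depletion" else self.enrichment
        return pd.DataFrame(
            {
                "gene": [s.gene for s in scores],
                "rank": [s.rank for s in scores],
                "n_guides": [s.n_guides for s in scores],
                "n_depleted": [s.n_depleted for s in scores],
                "n_enriched": [s.n_enriched for s in scores],
                "summary_log2fc": [s.summary_log2fc for s in scores],
                "classification": [s.classification for s in scores],
            }
        )

    def hits(self) -> dict[str, list[str]]:
        return {
            "positive_regulators": [
                s.gene for s in self.depletion if s.classification == "positive_regulator"
            ],
            "negative_regulators": [
                s.gene for s in self.enrichment if s.classification == "negative_regulator"
            ],
        }


def _classify(n_dep: int, n_enr: int, min_guides: int) -> str:
    if n_dep >= min_guides and n_dep > n_enr:
        return "positive_regulator"
    if n_enr >= min_guides and n_enr > n_dep:
        return "negative_regulator"
    return "none"


def score_genes(
    medians: pd.DataFrame,
    library: SgRNALibrary,
    config: ScoringConfig | None = None,
) -> GeneScores:
    """Count threshold-passing guides per gene and emit ranked hit lists.

    A guide is depleted when its median FC <= 1/fc_threshold and enriched
    when >= fc_threshold.  Nontargeting guides are excluded from gene
    scoring and reported separately.  Ranking is deterministic: the
    direction-relevant guide count (descending), then |summary_log2fc|
    (descending), then gene name.
    """
    if config is None:
        config = ScoringConfig()
    known = set(library.guide_ids)
    unknown = [g for g in medians.index if g not in known]
    if unknown:
        raise ValueError(f"guides absent from library: {unknown[:5]}")

    ntc_ids = [g.guide_id for g in library if g.role == "nontargeting"]
    ntc = medians.loc[[g for g in ntc_ids if g in medians.index]].copy()

    rows = []
    for gene in library.genes():
        gids = [
            g.guide_id
            for g in library.guides_for_gene(gene)
            if g.guide_id in medians.index
        ]
        if not gids:
            continue
        med = medians.loc[gids, "median_fc"]
        n_dep = int((med <= 1.0 / config.fc_threshold).sum())
        n_enr = int((med >= config.fc_threshold).sum())
        summary = float(medians.loc[gids, "log2_median_fc"].median())
        rows.append((gene, len(gids), n_dep, n_enr, summary))

    def ranked(direction: str) -> list[GeneScore]:
        key_col = 2 if direction == "depletion" else 3
        ordered = sorted(rows, key=lambda r: (-r[key_col], -abs(r[4]), r[0]))
        return [
            GeneScore(
                gene=r[0],
                n_guides=r[1],
                n_depleted=r[2],
                n_enriched=r[3],
                summary_log2fc=r[4],
                classification=_classify(r[2], r[3], config.min_guides_for_hit),
                rank=i + 1,
            )
            for i, r in enumerate(ordered)
        ]

    return GeneScores(ranked("depletion"), ranked("enrichment"), ntc)


def waterfall(
    medians: pd.DataFrame,
    library: SgRNALibrary,
    config: ScoringConfig | None = None,
) -> pd.DataFrame:
    """Guide-level ranked table behind the classic screen waterfall plot:
    log2 median fold change sorted descending (stable for ties), with the
    symmetric log2 threshold annotated as boolean enriched/depleted
    columns (|log2 FC| >= 1 at the default 2-fold threshold)."""
    if config is None:
        config = ScoringConfig()
    lib = library.to_frame().set_index("guide_id")
    df = medians.join(lib[["gene", "role"]], how="left")
    df = df.sort_values("log2_median_fc", ascending=False, kind="stable")
    log2_thr = math.log2(config.fc_threshold)
    df["enriched"] = df["log2_median_fc"] >= log2_thr
    df["depleted"] = df["log2_median_fc"] <= -log2_thr
    df.attrs["log2_threshold"] = log2_thr
    df.index.name = "guide_id"
    return df


def plot_waterfall(wf: pd.DataFrame, path, config: ScoringConfig | None = None) -> None:
    """Render the ranked guide log2 fold changes with threshold lines."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if config is None:
        config = ScoringConfig()
    thr = math.log2(config.fc_threshold)
    fig, ax = plt.subplots(figsize=(7, 4))
    x = np.arange(len(wf))
    ax.bar(x, wf["log2_median_fc"].to_numpy(), width=1.0, color="#808080")
    ntc_mask = (wf["role"] == "nontargeting").to_numpy()
    if ntc_mask.any():
        ax.scatter(x[ntc_mask], wf.loc[ntc_mask, "log2_median_fc"], color="red", s=12,
                   zorder=3, label="NTC")
        ax.legend(frameon=False)
    ax.axhline(thr, color="red", linestyle=":")
    ax.axhline(-thr, color="blue", linestyle=":")
    ax.set_xlabel("sgRNA rank")
    ax.set_ylabel("log2 median fold change (T12/T0)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def normalize_to_input(percent_out: float, percent_in: float) -> float:
    """Competition/homing assay normalization: output marker-positive
    percentage divided by the input percentage measured shortly after
    transduction (compensates for transduction-efficiency differences)."""
    if not (0 < percent_in <= 100):
        raise ValueError("percent_in must be in (0, 100]")
    if not (0 <= percent_out <= 100):
        raise ValueError("percent_out must be in [0, 100]")
    return percent_out / percent_in


def score_pipeline(
    counts: CountTable,
    library: SgRNALibrary,
    config: ScoringConfig | None = None,
    pairing: Mapping[str, tuple[str, str]] | None = None,
) -> dict:
    """Convenience composition: normalize -> fold_change -> medians ->
    score_genes + waterfall.  Returns a dict of the intermediate tables."""
    if config is None:
        config = ScoringConfig()
    if pairing is None:
        pairing = build_pairing(counts.samples)
    rep = normalize(counts, config)
    fc = fold_change(rep, pairing)
    med = median_fold_change(fc)
    scores = score_genes(med, library, config)
    wf = waterfall(med, library, config)
    return {
        "representation": rep,
        "fold_change": fc,
        "medians": med,
        "scores": scores,
        "waterfall": wf,
        "pairing": dict(pairing),
    }
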