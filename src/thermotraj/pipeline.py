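"""End-to-end per-history analysis: filter, normalize, fit, call, classify.

Composes the module operations the way the study design dictates: for one
history (PT or NL), candidates at each generation come from the
Selection-only model (M3) fitted to that generation's six samples, dynamic
candidates from the Generation x Selection model (M4) fitted to all twelve
samples of the history, and each analysis subset is filtered and
median-of-ratios normalized independently before fitting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .de_models import (
    FdrSpec,
    GeneFitResult,
    ModelSpec,
    detect_candidates,
    fdr_threshold,
    fit_genes,
    select_family_and_structure,
)
from .dynamics import GENE_SETS, DynamicsSummary, RatioPoint, classify_genes, compute_ratio, summarize
from .io_core import AnalysisConfig, CountMatrix, SampleDesign, logger
from .normalization import compute_size_factors, filter_low_data_genes, normalize_counts


def prepare_subset(
    counts: CountMatrix,
    designs: Sequence[SampleDesign],
    history: str | None = None,
    generation: str | None = None,
    min_samples: int = 3,
) -> tuple[CountMatrix, list[SampleDesign]]:
    """Subset samples by factor level, filter low-data genes, and normalize.

    Filtering and size factors are computed on the subset alone, mirroring
    the independent per-analysis normalization protocols.
    """
    keep = [
        d
        for d in designs
        if (history is None or d.history == history)
        and (generation is None or d.generation == generation)
    ]
    if not keep:
        raise ValueError(f"no samples for history={history!r}, generation={generation!r}")
    sub = counts.subset_samples([d.sample_id for d in keep])
    sub = filter_low_data_genes(sub, min_samples=min_samples)
    factors = compute_size_factors(sub)
    return normalize_counts(sub, factors), keep


@dataclass
class HistoryDynamics:
    """Everything the trajectory analysis produces for one history."""

    history: str
    family: str
    points: list[RatioPoint]
    candidates_g9: set[str]
    candidates_g23: set[str]
    candidates_interaction: set[str]
    interaction_significant: dict[str, bool]
    fits_g9: list[GeneFitResult]
    fits_g23: list[GeneFitResult]
    fits_dynamic: list[GeneFitResult]
    plateau_flags: dict[str, bool] = field(default_factory=dict)
    classification: pd.DataFrame | None = None
    summaries: dict[str, DynamicsSummary] = field(default_factory=dict)


def analyze_history(
    counts: CountMatrix,
    designs: Sequence[SampleDesign],
    history: str,
    config: AnalysisConfig | None = None,
    family: str = "negative_binomial",
) -> HistoryDynamics:
    """Candidate detection and trajectory classification for one history.

    ``family='auto'`` first runs the per-gene AIC vote between negative
    binomial and Poisson on the all-history-samples subset (model 4 design)
    and uses the winner for every subsequent fit, matching the study's
    procedure of choosing one family for all genes.
    """
    cfg = config or AnalysisConfig()
    designs = list(designs)

    norm_all, des_all = prepare_subset(
        counts, designs, history=history, min_samples=cfg.min_samples
    )
    if family == "auto":
        winner = select_family_and_structure(
            norm_all,
            des_all,
            [ModelSpec("M4", "poisson"), ModelSpec("M4", "negative_binomial")],
        )
        family = winner.family
        logger.info("analyze_history %s: AIC vote selected %s", history, family)

    # per-generation Selection-only fits (model 3)
    per_gen: dict[str, tuple[CountMatrix, list[GeneFitResult], set[str]]] = {}
    for gen in ("G9", "G23"):
        norm, des = prepare_subset(
            counts, designs, history=history, generation=gen,
            min_samples=cfg.min_samples,
        )
        fits = fit_genes(norm, des, ModelSpec("M3", family), terms_to_test=["Selection"])
        cand = detect_candidates(
            fits, "Selection", FdrSpec(alpha=cfg.alpha, n_genes=len(fits))
        )
        per_gen[gen] = (norm, fits, cand)

    # across-generation dynamics fits (model 4)
    fits_dyn = fit_genes(
        norm_all, des_all, ModelSpec("M4", family),
        terms_to_test=["Generation:Selection"],
    )
    cand_int = detect_candidates(
        fits_dyn, "Generation:Selection", FdrSpec(alpha=cfg.alpha, n_genes=len(fits_dyn))
    )
    cutoff_int = fdr_threshold(FdrSpec(alpha=cfg.alpha, n_genes=len(fits_dyn)))
    interaction_sig = {
        r.gene_id: (r.converged and r.p_values["Generation:Selection"] < cutoff_int)
        for r in fits_dyn
    }

    norm_g9, fits_g9, cand_g9 = per_gen["G9"]
    norm_g23, fits_g23, cand_g23 = per_gen["G23"]
    ratio_g9 = compute_ratio(
        norm_g9, designs, "G9", history, pseudocount=cfg.pseudocount
    )
    ratio_g23 = compute_ratio(
        norm_g23, designs, "G23", history, pseudocount=cfg.pseudocount
    )
    shared = [g for g in ratio_g9.index if g in set(ratio_g23.index)]
    points = [
        RatioPoint(
            gene_id=g,
            x=float(ratio_g9[g]),
            y=float(ratio_g23[g]),
            candidate_g9=g in cand_g9,
            candidate_g23=g in cand_g23,
            candidate_interaction=g in cand_int,
        )
        for g in shared
    ]

    classification = classify_genes(
        points, interaction_sig, tie_tol=cfg.tie_tol, plateau_delta=cfg.plateau_delta
    )
    plateau_flags = dict(zip(classification["gene_id"], classification["plateau"]))
    summaries = {
        gs: summarize(points, gs, tie_tol=cfg.tie_tol, plateau_flags=plateau_flags)
        for gs in GENE_SETS
    }
    return HistoryDynamics(
        history=history,
        family=family,
        points=points,
        candidates_g9=cand_g9,
        candidates_g23=cand_g23,
        candidates_interaction=cand_int,
        interaction_significant=interaction_sig,
        fits_g9=fits_g9,
        fits_g23=fits_g23,
        fits_dynamic=fits_dyn,
        plateau_flags=plateau_flags,
        classification=classification,
        summaries=summaries,
    )
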