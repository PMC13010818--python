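"""Synthetic count data with the study's 24-sample structure and planted dynamics.

The generator emulates a replicated experimental-evolution transcriptome
assay: 2 histories x 2 selection regimes x 3 replicate ancestral populations
x 2 generations, with negative-binomially distributed gene counts. Each gene
is assigned a dynamic archetype describing how its warming/control log2
fold-change evolves between generation 9 and generation 23 (progressive,
slowing, reversal, plateau, or null), which provides ground truth for the
candidate-detection and trajectory-classification stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_core import CountMatrix, SampleDesign, logger

_LN2 = float(np.log(2.0))


@dataclass(frozen=True)
class GeneArchetype:
    """A named expression-trajectory archetype with its planted log2 effects.

    ``lfc_g9`` / ``lfc_g23`` are the warming-vs-control log2 fold-changes at
    the two assay generations. The archetype name constrains their geometry:
    progressive = same sign, growing magnitude; slowing = same sign,
    shrinking magnitude; reversal = opposite signs; plateau = identical
    non-zero effects; null = no effect.
    """

    name: str
    lfc_g9: float
    lfc_g23: float

    def __post_init__(self) -> None:
        n, a, b = self.name, self.lfc_g9, self.lfc_g23
        ok = {
            "null": a == 0 and b == 0,
            "progressive_up": b > a > 0,
            "progressive_down": b < a < 0,
            "slowing_up": a > b > 0,
            "slowing_down": a < b < 0,
            "reversal_up_down": a > 0 > b,
            "reversal_down_up": a < 0 < b,
            "plateau": a == b != 0,
        }
        if n not in ok:
            raise ValueError(f"unknown archetype {n!r}; allowed: {sorted(ok)}")
        if not ok[n]:
            raise ValueError(
                f"effects (lfc_g9={a}, lfc_g23={b}) violate archetype {n!r}"
            )

    def lfc(self, generation: str) -> float:
        return self.lfc_g9 if generation == "G9" else self.lfc_g23


#: Default archetype effect sizes (log2 units). A |log2FC| of 1 is a clear,
#: biologically plausible selective response; the progressive/slowing pairs
#: use 0.5 vs 1.0 so that the two generations differ by a factor sqrt(2).
ARCHETYPES: dict[str, GeneArchetype] = {
    a.name: a
    for a in [
        GeneArchetype("null", 0.0, 0.0),
        GeneArchetype("progressive_up", 0.5, 1.0),
        GeneArchetype("progressive_down", -0.5, -1.0),
        GeneArchetype("slowing_up", 1.0, 0.5),
        GeneArchetype("slowing_down", -1.0, -0.5),
        GeneArchetype("reversal_up_down", 1.0, -1.0),
        GeneArchetype("reversal_down_up", -1.0, 1.0),
        GeneArchetype("plateau", 1.0, 1.0),
    ]
}


@dataclass
class SimulationSpec:
    """Parameters of one synthetic dataset.

    archetype_fractions must sum to 1; keys are archetype names (resolved in
    ``archetypes``, defaulting to :data:`ARCHETYPES`). Baseline log-means are
    uniform on ``baseline_log_mean_range`` (natural log of the expected
    count), dispersions uniform on ``dispersion_range`` (NB variance =
    mu + phi * mu^2; phi = 0 gives Poisson). ``ap_sd`` is the SD of the
    gene x ancestral-population random intercept on the natural-log scale;
    ``generation_effect_sd`` the SD of gene-wise Generation main effects
    applied to all samples (emulating the large between-generation batch
    signal seen in real assays). ``library_size_factors`` maps sample ids to
    depth multipliers (default: all 1).
    """

    n_genes: int = 10_000
    archetype_fractions: Mapping[str, float] = field(
        default_factory=lambda: {
            "null": 0.80,
            "progressive_up": 0.025,
            "progressive_down": 0.025,
            "slowing_up": 0.025,
            "slowing_down": 0.025,
            "reversal_up_down": 0.025,
            "reversal_down_up": 0.025,
            "plateau": 0.05,
        }
    )
    baseline_log_mean_range: tuple[float, float] = (np.log(20.0), np.log(2000.0))
    dispersion_range: tuple[float, float] = (0.01, 0.3)
    ap_sd: float = 0.1
    generation_effect_sd: float = 0.2
    library_size_factors: Mapping[str, float] | None = None
    seed: int = 0
    archetypes: Mapping[str, GeneArchetype] = field(
        default_factory=lambda: dict(ARCHETYPES)
    )

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        total = float(sum(self.archetype_fractions.values()))
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"archetype fractions sum to {total}, not 1")
        unknown = set(self.archetype_fractions) - set(self.archetypes)
        if unknown:
            raise ValueError(f"fractions given for unknown archetypes: {sorted(unknown)}")
        lo, hi = self.baseline_log_mean_range
        if not (np.isfinite(lo) and np.isfinite(hi) and lo <= hi):
            raise ValueError("invalid baseline_log_mean_range")
        lo, hi = self.dispersion_range
        if not (0 <= lo <= hi):
            raise ValueError("dispersion_range must be non-negative")
        if self.ap_sd < 0 or self.generation_effect_sd < 0:
            raise ValueError("standard deviations must be >= 0")


@dataclass
class SyntheticTruth:
    """Ground truth for a simulated dataset.

    ``genes``: one row per gene (archetype, true log2 effects at G9/G23,
    baseline natural-log mean, dispersion, generation effect).
    ``ap_intercepts``: genes x AP-level matrix of random intercepts.
    """

    genes: pd.DataFrame
    ap_intercepts: pd.DataFrame

    def write(self, path: str) -> None:
        merged = self.genes.join(self.ap_intercepts.add_prefix("b_"))
        merged.to_csv(path, sep="\t", index=True, index_label="gene_id")


def make_paper_design() -> list[SampleDesign]:
    """The study's 24-sample design: 2 histories x 2 regimes x 3 APs x 2 generations.

    Sample ids follow the field's naming: warming populations carry a W
    prefix (WPT1_G9 is the warming descendant of ancestral population PT1
    assayed at generation 9).
    """
    designs = []
    for history in ("PT", "NL"):
        for rep in (1, 2, 3):
            ap = f"{history}{rep}"
            for selection in ("Control", "Warming"):
                prefix = "W" if selection == "Warming" else ""
                for generation in ("G9", "G23"):
                    designs.append(
                        SampleDesign(
                            sample_id=f"{prefix}{ap}_{generation}",
                            history=history,
                            selection=selection,
                            generation=generation,
                            ap=ap,
                        )
                    )
    return designs


def simulate_dataset(
    spec: SimulationSpec, design: Sequence[SampleDesign]
) -> tuple[CountMatrix, SyntheticTruth]:
    """Draw a counts matrix from the generative model and record ground truth.

    For sample s and gene g the expected count is

        sizefactor_s * exp(beta0_g + b_{AP(s),g} + betaGen_g * [gen = G23]
                           + ln(2) * lfc_g(gen) * [selection = Warming])

    and the count is NB-distributed with dispersion phi_g (Poisson when
    phi_g = 0). AP intercepts are drawn once per gene x AP and shared by the
    control population and its warming descendant at both generations,
    reproducing the paired lineage structure. Draws use per-gene substreams
    keyed by (seed, gene index), so results do not depend on evaluation
    order and are fully reproducible.
    """
    spec.validate()
    if not design:
        raise ValueError("design must contain at least one sample")
    logger.info("simulate_dataset: %d genes x %d samples, seed=%d",
                spec.n_genes, len(design), spec.seed)

    sample_ids = [d.sample_id for d in design]
    ap_levels = sorted({d.ap for d in design})
    ap_index = {a: i for i, a in enumerate(ap_levels)}
    is_g23 = np.array([d.generation == "G23" for d in design])
    is_warm = np.array([d.selection == "Warming" for d in design])
    ap_of_sample = np.array([ap_index[d.ap] for d in design])

    if spec.library_size_factors is None:
        size_factors = np.ones(len(design))
    else:
        missing = [s for s in sample_ids if s not in spec.library_size_factors]
        if missing:
            raise ValueError(f"library_size_factors missing samples: {missing}")
        size_factors = np.array([spec.library_size_factors[s] for s in sample_ids])
        if np.any(size_factors <= 0):
            raise ValueError("library size factors must be > 0")

    names = list(spec.archetype_fractions)
    probs = np.array([spec.archetype_fractions[n] for n in names], dtype=float)
    assign_rng = np.random.default_rng([spec.seed, 0])
    assigned = assign_rng.choice(len(names), size=spec.n_genes, p=probs / probs.sum())

    counts = np.empty((spec.n_genes, len(design)), dtype=float)
    truth_rows = []
    intercepts = np.empty((spec.n_genes, len(ap_levels)))
    lo_b, hi_b = spec.baseline_log_mean_range
    lo_d, hi_d = spec.dispersion_range

    for g in range(spec.n_genes):
        rng = np.random.default_rng([spec.seed, 1, g])
        arch = spec.archetypes[names[assigned[g]]]
        beta0 = rng.uniform(lo_b, hi_b)
        phi = rng.uniform(lo_d, hi_d)
        beta_gen = rng.normal(0.0, spec.generation_effect_sd) if spec.generation_effect_sd > 0 else 0.0
        b_ap = (
            rng.normal(0.0, spec.ap_sd, size=len(ap_levels))
            if spec.ap_sd > 0
            else np.zeros(len(ap_levels))
        )
        lfc = np.where(is_g23, arch.lfc_g23, arch.lfc_g9)
        eta = (
            beta0
            + b_ap[ap_of_sample]
            + beta_gen * is_g23
            + _LN2 * lfc * is_warm
        )
        mu = size_factors * np.exp(eta)
        if phi > 0:
            r = 1.0 / phi
            counts[g, :] = rng.negative_binomial(r, r / (r + mu))
        else:
            counts[g, :] = rng.poisson(mu)
        intercepts[g, :] = b_ap
        truth_rows.append(
            {
                "archetype": arch.name,
                "lfc_g9": arch.lfc_g9,
                "lfc_g23": arch.lfc_g23,
                "baseline_log_mean": beta0,
                "dispersion": phi,
                "generation_effect": beta_gen,
            }
        )

    gene_ids = [f"gene{g:05d}" for g in range(spec.n_genes)]
    truth = SyntheticTruth(
        genes=pd.DataFrame(truth_rows, index=gene_ids),
        ap_intercepts=pd.DataFrame(intercepts, index=gene_ids, columns=ap_levels),
    )
    return CountMatrix(gene_ids, sample_ids, counts), truth
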