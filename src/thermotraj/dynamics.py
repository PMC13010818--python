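"""Warming/control expression-ratio trajectories and their zone classification.

For each gene, x is the ratio of mean normalized expression in the warming
replicates to the control replicates at generation 9, and y the same ratio
at generation 23. The (x, y) plane, with the neutral point at (1, 1),
partitions gene trajectories into:

* pink zones   — consistent directional change (Q1 with y > x: steadily
  increasing upregulation; Q3 with y < x: steadily increasing
  downregulation);
* blue zones   — same sign but shrinking magnitude of change (Q1 with
  y < x; Q3 with y > x);
* green zones  — sign reversal between generations (all of Q4: up then
  down; all of Q2: down then up);
* the diagonal — unchanged ratio (plateau geometry);
* boundaries   — points exactly at ratio 1 on either axis, reported
  separately and excluded from percentage denominators.

Magnitude of expression change is distance from 1 on the ratio scale; within
Q1/Q3 comparing |x - 1| vs |y - 1| reduces to comparing x vs y.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_core import CountMatrix, SampleDesign, logger

ZONES = (
    "pink_up",
    "pink_down",
    "blue_up",
    "blue_down",
    "green_up_down",
    "green_down_up",
    "diagonal",
    "boundary",
)
GREEN_ZONES = ("green_up_down", "green_down_up")
BLUE_ZONES = ("blue_up", "blue_down")
PINK_ZONES = ("pink_up", "pink_down")

GENE_SETS = ("g9_candidates", "g23_candidates", "both", "interaction")


@dataclass
class RatioPoint:
    """One gene's (G9 ratio, G23 ratio) pair with its candidacy flags."""

    gene_id: str
    x: float
    y: float
    candidate_g9: bool = False
    candidate_g23: bool = False
    candidate_interaction: bool = False

    def __post_init__(self) -> None:
        if not (np.isfinite(self.x) and np.isfinite(self.y) and self.x > 0 and self.y > 0):
            raise ValueError(
                f"gene {self.gene_id!r}: ratios must be finite and > 0, "
                f"got ({self.x}, {self.y})"
            )


@dataclass(frozen=True)
class ZoneLabel:
    """Quadrant (reference point (1,1)) and trajectory zone of a RatioPoint."""

    quadrant: str  # Q1..Q4 or "boundary"
    zone: str      # one of ZONES


def classify_zone(p: RatioPoint, tie_tol: float = 1e-9) -> ZoneLabel:
    """Assign a RatioPoint to its quadrant and trajectory zone.

    Points within ``tie_tol`` of ratio 1 on either axis are labelled
    boundary; points within relative ``tie_tol`` of the y = x diagonal are
    labelled diagonal (their quadrant is still reported).
    """
    x, y = p.x, p.y
    if abs(x - 1.0) <= tie_tol or abs(y - 1.0) <= tie_tol:
        return ZoneLabel("boundary", "boundary")
    if abs(y - x) <= tie_tol * max(x, y):
        return ZoneLabel("Q1" if x > 1 else "Q3", "diagonal")
    if x > 1 and y > 1:
        return ZoneLabel("Q1", "pink_up" if y > x else "blue_up")
    if x < 1 and y > 1:
        return ZoneLabel("Q2", "green_down_up")
    if x < 1 and y < 1:
        return ZoneLabel("Q3", "pink_down" if y < x else "blue_down")
    return ZoneLabel("Q4", "green_up_down")


def compute_ratio(
    norm_counts: CountMatrix,
    designs: Sequence[SampleDesign],
    generation: str,
    history: str,
    pseudocount: float = 0.5,
) -> pd.Series:
    """Per-gene warming/control ratio of mean normalized expression.

    Restricted to the samples of the given generation and history; the
    numerator averages the warming replicates and the denominator the
    control replicates. When either mean is zero, ``pseudocount`` is added
    to both means and the gene is logged.
    """
    by_id = {d.sample_id: d for d in designs}
    warm_idx, ctrl_idx = [], []
    for j, s in enumerate(norm_counts.sample_ids):
        d = by_id.get(s)
        if d is None or d.generation != generation or d.history != history:
            continue
        (warm_idx if d.selection == "Warming" else ctrl_idx).append(j)
    if not warm_idx or not ctrl_idx:
        raise ValueError(
            f"subset {history}/{generation} needs >= 1 Warming and >= 1 Control sample"
        )
    warm_mean = norm_counts.counts[:, warm_idx].mean(axis=1)
    ctrl_mean = norm_counts.counts[:, ctrl_idx].mean(axis=1)
    needs_eps = (ctrl_mean == 0) | (warm_mean == 0)
    if needs_eps.any():
        flagged = [g for g, f in zip(norm_counts.gene_ids, needs_eps) if f]
        logger.info(
            "compute_ratio %s/%s: pseudocount %.2g applied to %d gene(s): %s%s",
            history, generation, pseudocount, len(flagged),
            ", ".join(flagged[:5]), "..." if len(flagged) > 5 else "",
        )
    warm_mean = np.where(needs_eps, warm_mean + pseudocount, warm_mean)
    ctrl_mean = np.where(needs_eps, ctrl_mean + pseudocount, ctrl_mean)
    return pd.Series(warm_mean / ctrl_mean, index=norm_counts.gene_ids)


def detect_plateau(
    p: RatioPoint, interaction_significant: bool, delta: float = 0.05
) -> bool:
    """Plateau rule: candidate at both generations, non-significant
    Generation x Selection interaction, and |y - x| < delta on the ratio
    scale (less than 5% of temporal change at the default)."""
    return (
        p.candidate_g9
        and p.candidate_g23
        and not interaction_significant
        and abs(p.y - p.x) < delta
    )


@dataclass
class DynamicsSummary:
    """Zone and quadrant counts for one gene set; percentages are always
    recomputed from the counts."""

    gene_set: str
    zone_counts: dict[str, int]
    quadrant_counts: dict[str, int]
    plateau_genes: list[str] = field(default_factory=list)

    @property
    def n_boundary(self) -> int:
        return self.zone_counts.get("boundary", 0) + self.zone_counts.get("diagonal", 0)

    @property
    def total(self) -> int:
        """Classified genes (pink + blue + green); boundary/diagonal excluded."""
        return sum(
            self.zone_counts.get(z, 0) for z in PINK_ZONES + BLUE_ZONES + GREEN_ZONES
        )

    @property
    def progressive_count(self) -> int:
        return sum(self.zone_counts.get(z, 0) for z in PINK_ZONES)

    @property
    def reversal_fraction(self) -> float:
        if self.total == 0:
            return float("nan")
        return sum(self.zone_counts.get(z, 0) for z in GREEN_ZONES) / self.total

    @property
    def slowing_plus_reversal_fraction(self) -> float:
        if self.total == 0:
            return float("nan")
        return (
            sum(self.zone_counts.get(z, 0) for z in BLUE_ZONES + GREEN_ZONES)
            / self.total
        )

    @property
    def reversal_pct(self) -> int | None:
        f = self.reversal_fraction
        return None if np.isnan(f) else round(100.0 * f)

    @property
    def slowing_plus_reversal_pct(self) -> int | None:
        f = self.slowing_plus_reversal_fraction
        return None if np.isnan(f) else round(100.0 * f)

    def to_dict(self) -> dict:
        return {
            "gene_set": self.gene_set,
            **{f"zone_{z}": self.zone_counts.get(z, 0) for z in ZONES},
            **{f"quadrant_{q}": self.quadrant_counts.get(q, 0) for q in
               ("Q1", "Q2", "Q3", "Q4", "boundary")},
            "total": self.total,
            "n_boundary": self.n_boundary,
            "progressive_count": self.progressive_count,
            "reversal_pct": self.reversal_pct,
            "slowing_plus_reversal_pct": self.slowing_plus_reversal_pct,
            "n_plateau": len(self.plateau_genes),
        }


def _in_set(p: RatioPoint, gene_set: str) -> bool:
    if gene_set == "g9_candidates":
        return p.candidate_g9
    if gene_set == "g23_candidates":
        return p.candidate_g23
    if gene_set == "both":
        return p.candidate_g9 and p.candidate_g23
    if gene_set == "interaction":
        return p.candidate_interaction
    raise ValueError(f"unknown gene set {gene_set!r}; allowed: {GENE_SETS}")


def summarize(
    points: Sequence[RatioPoint],
    gene_set: str,
    tie_tol: float = 1e-9,
    plateau_flags: Mapping[str, bool] | None = None,
) -> DynamicsSummary:
    """Zone/quadrant counts and derived percentages for one candidate gene set.

    Restricts to the requested set, classifies every point, and counts per
    zone and quadrant. Reversal percentage = green / classified total;
    slowing-plus-reversal = (blue + green) / classified total; both rounded
    to the nearest integer. An empty set yields zero counts and undefined
    (None) percentages.
    """
    zone_counts: dict[str, int] = {}
    quadrant_counts: dict[str, int] = {}
    plateau_genes: list[str] = []
    for p in points:
        if not _in_set(p, gene_set):
            continue
        label = classify_zone(p, tie_tol=tie_tol)
        zone_counts[label.zone] = zone_counts.get(label.zone, 0) + 1
        quadrant_counts[label.quadrant] = quadrant_counts.get(label.quadrant, 0) + 1
        if plateau_flags is not None and plateau_flags.get(p.gene_id, False):
            plateau_genes.append(p.gene_id)
    return DynamicsSummary(
        gene_set=gene_set,
        zone_counts=zone_counts,
        quadrant_counts=quadrant_counts,
        plateau_genes=plateau_genes,
    )


def classify_genes(
    points: Sequence[RatioPoint],
    interaction_significant: Mapping[str, bool],
    tie_tol: float = 1e-9,
    plateau_delta: float = 0.05,
) -> pd.DataFrame:
    """Per-gene classification table (the zone TSV layout).

    Columns: gene_id, x_ratio, y_ratio, quadrant, zone, candidate flags, and
    the plateau flag (which needs the interaction test's verdict per gene).
    """
    rows = []
    for p in points:
        label = classify_zone(p, tie_tol=tie_tol)
        rows.append(
            {
                "gene_id": p.gene_id,
                "x_ratio": p.x,
                "y_ratio": p.y,
                "quadrant": label.quadrant,
                "zone": label.zone,
                "candidate_g9": p.candidate_g9,
                "candidate_g23": p.candidate_g23,
                "candidate_interaction": p.candidate_interaction,
                "plateau": detect_plateau(
                    p,
                    bool(interaction_significant.get(p.gene_id, False)),
                    delta=plateau_delta,
                ),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id", "x_ratio", "y_ratio", "quadrant", "zone",
            "candidate_g9", "candidate_g23", "candidate_interaction", "plateau",
        ],
    )
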