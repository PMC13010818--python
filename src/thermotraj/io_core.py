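"""Core containers and I/O: count matrices, sample designs, result tables, config.

The experimental design encoded here is a 2 x 2 x 3 x 2 factorial: two
biogeographic histories (PT, low latitude; NL, high latitude), two thermal
selection regimes (Control at constant temperature vs. a progressively
Warming regime), three replicate ancestral populations per history (PT1-3,
NL1-3, each shared by a control population and its warming-derived
descendant), and two assay generations (G9 and G23).
"""

from __future__ import annotations

import logging
import os
import re
import sys
from dataclasses import dataclass, fields, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("thermotraj")
if not logger.handlers:
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.addHandler(_h)
    logger.setLevel(logging.INFO)

HISTORIES = ("PT", "NL")
SELECTIONS = ("Control", "Warming")
GENERATIONS = ("G9", "G23")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SampleDesign:
    """Factor levels for one RNA-seq sample.

    ``ap`` is the ancestral replicate population (PT1..PT3 or NL1..NL3); it is
    nested in ``history`` and shared between a control population and its
    warming descendant, which is what makes it the natural random-intercept
    grouping for the per-gene models.
    """

    sample_id: str
    history: str
    selection: str
    generation: str
    ap: str

    def __post_init__(self) -> None:
        if self.history not in HISTORIES:
            raise ValueError(
                f"unknown history {self.history!r}; allowed: {HISTORIES}"
            )
        if self.selection not in SELECTIONS:
            raise ValueError(
                f"unknown selection {self.selection!r}; allowed: {SELECTIONS}"
            )
        if self.generation not in GENERATIONS:
            raise ValueError(
                f"unknown generation {self.generation!r}; allowed: {GENERATIONS}"
            )
        if not self.ap.startswith(self.history):
            raise ValueError(
                f"sample {self.sample_id!r}: ancestral population {self.ap!r} "
                f"is not nested in history {self.history!r}"
            )


class CountMatrix:
    """Genes x samples matrix of non-negative expression values.

    Raw counts are integers; median-of-ratios normalized counts may be
    fractional, so values are stored as floats throughout.
    """

    def __init__(
        self,
        gene_ids: Sequence[str],
        sample_ids: Sequence[str],
        counts: np.ndarray,
    ) -> None:
        gene_ids = [str(g) for g in gene_ids]
        sample_ids = [str(s) for s in sample_ids]
        counts = np.asarray(counts, dtype=float)
        if counts.ndim != 2 or counts.shape != (len(gene_ids), len(sample_ids)):
            raise ValueError(
                f"counts shape {counts.shape} does not match "
                f"{len(gene_ids)} genes x {len(sample_ids)} samples"
            )
        dup = _duplicates(gene_ids)
        if dup:
            raise ValueError(f"duplicate gene ids: {sorted(dup)}")
        dup = _duplicates(sample_ids)
        if dup:
            raise ValueError(f"duplicate sample ids: {sorted(dup)}")
        if not np.all(np.isfinite(counts)):
            g, s = np.argwhere(~np.isfinite(counts))[0]
            raise ValueError(
                f"non-finite count for gene {gene_ids[g]!r}, sample {sample_ids[s]!r}"
            )
        if np.any(counts < 0):
            g, s = np.argwhere(counts < 0)[0]
            raise ValueError(
                f"negative count for gene {gene_ids[g]!r}, sample {sample_ids[s]!r}"
            )
        self.gene_ids = gene_ids
        self.sample_ids = sample_ids
        self.counts = counts

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=self.gene_ids, columns=self.sample_ids
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CountMatrix":
        return cls(list(df.index), list(df.columns), df.to_numpy(dtype=float))

    def subset_samples(self, sample_ids: Sequence[str]) -> "CountMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return CountMatrix(self.gene_ids, list(sample_ids), self.counts[:, idx])

    def subset_genes(self, gene_ids: Sequence[str]) -> "CountMatrix":
        pos = {g: i for i, g in enumerate(self.gene_ids)}
        idx = [pos[g] for g in gene_ids]
        return CountMatrix(list(gene_ids), self.sample_ids, self.counts[idx, :])

    def gene(self, gene_id: str) -> np.ndarray:
        return self.counts[self.gene_ids.index(gene_id), :]

    def __repr__(self) -> str:  # pragma: no cover
        return f"CountMatrix({self.n_genes} genes x {self.n_samples} samples)"


def _duplicates(items: Iterable[str]) -> set:
    seen: set = set()
    dup: set = set()
    for x in items:
        if x in seen:
            dup.add(x)
        seen.add(x)
    return dup


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass
class AnalysisConfig:
    """Analysis thresholds, all overridable from a YAML/JSON file or CLI flags.

    alpha: nominal FDR level divided by the harmonic number of the gene count
        to obtain the per-gene p-value cutoff.
    plateau_delta: maximum absolute change in the warming/control expression
        ratio between generations for a gene to count as a plateau.
    min_samples: a gene must have non-zero counts in at least this many
        samples of the analysis subset to be retained.
    tie_tol: relative tolerance for boundary/diagonal calls in the
        trajectory-zone classifier.
    pseudocount: added to both ratio means when a denominator is zero.
    """

    alpha: float = 0.01
    plateau_delta: float = 0.05
    min_samples: int = 3
    tie_tol: float = 1e-9
    pseudocount: float = 0.5

    @classmethod
    def from_file(cls, path: str) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"config file {path!r} must contain a mapping")
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(
                f"unknown config keys {sorted(unknown)}; allowed: {sorted(known)}"
            )
        return cls(**raw)

    def override(self, **kwargs) -> "AnalysisConfig":
        clean = {k: v for k, v in kwargs.items() if v is not None}
        return replace(self, **clean)


# ---------------------------------------------------------------------------
# Count-table I/O
# ---------------------------------------------------------------------------

_FEATURECOUNTS_ANNOT = ["Chr", "Start", "End", "Strand", "Length"]


def _strip_sample_name(name: str) -> str:
    """Strip path prefixes and alignment-file extensions from a column header.

    featureCounts uses BAM paths as column names; `results/S1.bam` -> `S1`.
    """
    base = os.path.basename(name.strip())
    return re.sub(r"\.(bam|sam|cram)$", "", base, flags=re.IGNORECASE)


def read_count_table(
    path: str, dialect: str = "plain_tsv", strip_names: bool = True
) -> CountMatrix:
    """Read a genes x samples count table.

    dialect 'featurecounts': '#'-prefixed comment lines allowed; columns
    Geneid, Chr, Start, End, Strand, Length, then one column per sample
    (annotation columns are dropped). dialect 'plain_tsv': first column is
    the gene id, remaining columns are samples. Genes are rows in both; no
    auto-transposition is attempted.
    """
    if dialect not in ("featurecounts", "plain_tsv"):
        raise ValueError(f"unknown dialect {dialect!r}")
    df = pd.read_csv(path, sep="\t", comment="#", dtype={0: str})
    if df.shape[1] < 2:
        raise ValueError(f"{path!r}: need a gene-id column plus >=1 sample column")
    gene_col = df.columns[0]
    df = df.set_index(gene_col)
    if dialect == "featurecounts":
        missing = [c for c in _FEATURECOUNTS_ANNOT if c not in df.columns]
        if missing:
            raise ValueError(
                f"{path!r}: featurecounts dialect expects annotation columns "
                f"{_FEATURECOUNTS_ANNOT}, missing {missing}"
            )
        df = df.drop(columns=_FEATURECOUNTS_ANNOT)
    if strip_names:
        df.columns = [_strip_sample_name(c) for c in df.columns]
    dup = _duplicates(df.index)
    if dup:
        raise ValueError(f"{path!r}: duplicate gene id(s): {sorted(dup)}")
    for col in df.columns:
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna() & df[col].notna()
        if bad.any():
            gene = df.index[bad.to_numpy().nonzero()[0][0]]
            raise ValueError(
                f"{path!r}: non-numeric count for gene {gene!r}, sample {col!r}"
            )
        df[col] = numeric
    if df.isna().any().any():
        g, s = np.argwhere(df.isna().to_numpy())[0]
        raise ValueError(
            f"{path!r}: missing count for gene {df.index[g]!r}, "
            f"sample {df.columns[s]!r}"
        )
    arr = df.to_numpy(dtype=float)
    if np.any(arr < 0):
        g, s = np.argwhere(arr < 0)[0]
        raise ValueError(
            f"{path!r}: negative count for gene {df.index[g]!r}, "
            f"sample {df.columns[s]!r}"
        )
    return CountMatrix(list(df.index), list(df.columns), arr)


def write_count_table(counts: CountMatrix, path: str) -> None:
    """Write a CountMatrix as a plain TSV (gene id first column)."""
    df = counts.to_frame()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t", float_format="%.6g")


# ---------------------------------------------------------------------------
# Design I/O
# ---------------------------------------------------------------------------

_DESIGN_COLUMNS = ["sample_id", "history", "selection", "generation", "ap"]

_CASE_MAPS = {
    "history": {h.lower(): h for h in HISTORIES},
    "selection": {s.lower(): s for s in SELECTIONS},
    "generation": {g.lower(): g for g in GENERATIONS},
}


def _normalize_level(column: str, value: str) -> str:
    v = str(value).strip()
    mapping = _CASE_MAPS[column]
    # accept bare generation numbers ("9", "23") as well as G9/G23
    if column == "generation" and v in ("9", "23"):
        v = "g" + v
    if v.lower() not in mapping:
        raise ValueError(
            f"unknown {column} level {value!r}; allowed: {sorted(mapping.values())}"
        )
    return mapping[v.lower()]


def read_design(path: str) -> list[SampleDesign]:
    """Read a sample-metadata TSV with columns sample_id, history, selection,
    generation, ap; factor levels are case-normalized."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _DESIGN_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path!r}: missing design columns {missing}")
    designs = []
    for _, row in df.iterrows():
        designs.append(
            SampleDesign(
                sample_id=str(row["sample_id"]).strip(),
                history=_normalize_level("history", row["history"]),
                selection=_normalize_level("selection", row["selection"]),
                generation=_normalize_level("generation", row["generation"]),
                ap=str(row["ap"]).strip().upper(),
            )
        )
    dup = _duplicates(d.sample_id for d in designs)
    if dup:
        raise ValueError(f"{path!r}: duplicate sample id(s): {sorted(dup)}")
    return designs


def write_design(designs: Sequence[SampleDesign], path: str) -> None:
    pd.DataFrame(
        [
            {
                "sample_id": d.sample_id,
                "history": d.history,
                "selection": d.selection,
                "generation": d.generation,
                "ap": d.ap,
            }
            for d in designs
        ],
        columns=_DESIGN_COLUMNS,
    ).to_csv(path, sep="\t", index=False)


def match_design(
    counts: CountMatrix, designs: Sequence[SampleDesign]
) -> list[SampleDesign]:
    """Return designs reordered to match counts.sample_ids (exact id match)."""
    by_id = {d.sample_id: d for d in designs}
    missing = [s for s in counts.sample_ids if s not in by_id]
    if missing:
        raise ValueError(f"samples without a design row: {missing}")
    return [by_id[s] for s in counts.sample_ids]


# ---------------------------------------------------------------------------
# Result tables
# ---------------------------------------------------------------------------


def write_results(
    records: Sequence[Mapping],
    path: str,
    summary_path: str | None = None,
    p_cutoff: float | None = None,
) -> None:
    """Write per-gene result records to a TSV, one row per gene.

    Column order follows the first record's key order; missing values are
    encoded as "NA". If ``summary_path`` and ``p_cutoff`` are given, a
    companion summary TSV reports, for every ``p_<term>`` column, the number
    of genes with p below the cutoff (the layout of a per-factor
    significant-gene count table).
    """
    if records:
        columns: list[str] = []
        for rec in records:
            for key in rec:
                if key not in columns:
                    columns.append(key)
        df = pd.DataFrame(list(records), columns=columns)
    else:
        df = pd.DataFrame(columns=["gene_id"])
    df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.6g")
    if summary_path is not None:
        if p_cutoff is None:
            raise ValueError("summary_path requires p_cutoff")
        rows = []
        for col in df.columns:
            if not col.startswith("p_"):
                continue
            p = pd.to_numeric(df[col], errors="coerce")
            rows.append(
                {
                    "factor": col[2:],
                    "n_significant": int((p < p_cutoff).sum()),
                    "n_tested": int(p.notna().sum()),
                    "p_cutoff": p_cutoff,
                }
            )
        pd.DataFrame(
            rows, columns=["factor", "n_significant", "n_tested", "p_cutoff"]
        ).to_csv(summary_path, sep="\t", index=False)


def read_results(path: str) -> pd.DataFrame:
    """Read a per-gene result TSV written by :func:`write_results`."""
    return pd.read_csv(path, sep="\t", na_values="NA")
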