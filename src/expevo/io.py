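"""Readers and writers for every external artifact of the pipeline.

All tabular files are TSV (tab separated, UTF-8, "." decimal) — one dialect,
no sniffing. Readers validate strictly and reject rather than coerce;
anything dropped, floored or defaulted is logged at warning level.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .tree import DEFAULT_BRANCH_EPSILON, parse_newick  # noqa: F401  (re-export)

logger = logging.getLogger(__name__)

DEFAULT_STAGES = ("S0", "S1", "S2", "S3", "S4", "S5")

# U+2212, the sign Table-style transition labels are printed with
MINUS = "−"


class FormatError(ValueError):
    """Malformed or invariant-violating input file."""


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Per-species genes x developmental-stages matrix of RPKM values."""

    species: str
    data: pd.DataFrame  # index = gene ids, columns = stage labels

    def __post_init__(self):
        idx = self.data.index
        if idx.has_duplicates:
            dup = idx[idx.duplicated()].unique().tolist()
            raise FormatError(f"{self.species}: duplicate gene ids: {dup}")
        if self.data.shape[1] < 2:
            raise FormatError(f"{self.species}: need >= 2 stages")
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise FormatError(f"{self.species}: non-numeric expression values")
        if not np.isfinite(values).all():
            raise FormatError(f"{self.species}: non-finite expression values")
        if (values < 0).any():
            g, s = np.argwhere(values < 0)[0]
            raise FormatError(
                f"{self.species}: negative value at gene {idx[g]!r}, "
                f"stage {self.data.columns[s]!r}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def stages(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    def values_for(self, gene_id: str) -> np.ndarray:
        return self.data.loc[gene_id].to_numpy(dtype=float)


def read_expression_table(path: str | Path, species_name: str) -> ExpressionMatrix:
    """Read a TSV of RPKM values: first column gene id, header = stage labels."""
    path = Path(path)
    raw = pd.read_csv(path, sep="\t", header=0, dtype={0: str})
    if raw.shape[1] < 3:
        raise FormatError(f"{path}: expected gene-id column plus >= 2 stages")
    stage_labels = list(raw.columns[1:])
    for lab in stage_labels:
        try:
            float(lab)
        except ValueError:
            continue
        raise FormatError(f"{path}: numeric header cell {lab!r}; missing header row?")
    dup = raw.iloc[:, 0][raw.iloc[:, 0].duplicated()]
    if not dup.empty:
        raise FormatError(f"{path}: gene id listed twice: {dup.iloc[0]!r}")
    data = raw.set_index(raw.columns[0])
    data.index.name = "gene_id"
    for col in stage_labels:
        coerced = pd.to_numeric(data[col], errors="coerce")
        bad = coerced.isna() & data[col].notna()
        if bad.any() or data[col].isna().any():
            gene = data.index[(bad | data[col].isna())][0]
            raise FormatError(
                f"{path}: non-numeric or missing value at gene {gene!r}, column {col!r}"
            )
        data[col] = coerced.astype(float)
    return ExpressionMatrix(species=species_name, data=data)


def write_expression_table(matrix: ExpressionMatrix, path: str | Path) -> None:
    """Write the canonical TSV form (``%.12g`` floats); round-trips losslessly."""
    df = matrix.data.copy()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t", float_format="%.12g")


# ---------------------------------------------------------------------------
# SCOG map
# ---------------------------------------------------------------------------


@dataclass
class ScogMap:
    """Single-copy ortholog clusters: one member gene id per species."""

    table: pd.DataFrame  # index = cluster_id, one column per species

    def __post_init__(self):
        if self.table.index.has_duplicates:
            dup = self.table.index[self.table.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate cluster ids: {dup}")
        if self.table.isna().any().any() or (self.table == "").any().any():
            bad = self.table.index[
                (self.table.isna() | (self.table == "")).any(axis=1)
            ][0]
            raise FormatError(f"cluster {bad!r} is missing a species member")
        for sp in self.table.columns:
            col = self.table[sp]
            if col.duplicated().any():
                g = col[col.duplicated()].iloc[0]
                raise FormatError(
                    f"gene {g!r} ({sp}) appears in more than one cluster"
                )

    @property
    def species(self) -> list[str]:
        return list(self.table.columns)

    @property
    def cluster_ids(self) -> list[str]:
        return list(self.table.index)

    def __len__(self) -> int:
        return len(self.table)

    def member(self, cluster_id: str, species: str) -> str:
        return self.table.at[cluster_id, species]

    def restrict(self, cluster_ids) -> "ScogMap":
        return ScogMap(self.table.loc[list(cluster_ids)].copy())


def read_scog_map(path: str | Path, expected_species: list[str]) -> ScogMap:
    """Read a cluster TSV (first column cluster_id, one column per species)."""
    path = Path(path)
    raw = pd.read_csv(path, sep="\t", header=0, dtype=str, keep_default_na=False)
    raw = raw.mask(raw == "")
    table = raw.set_index(raw.columns[0])
    missing = [sp for sp in expected_species if sp not in table.columns]
    if missing:
        raise FormatError(f"{path}: species column(s) absent: {missing}")
    table = table[list(expected_species)]
    return ScogMap(table)


def write_scog_map(scog: ScogMap, path: str | Path) -> None:
    df = scog.table.copy()
    df.index.name = "cluster_id"
    df.to_csv(path, sep="\t")


def validate_scog_against(scog: ScogMap, matrices: dict[str, ExpressionMatrix]) -> None:
    """Check every member gene is present in its species' expression matrix."""
    for sp in scog.species:
        if sp not in matrices:
            raise FormatError(f"no expression matrix for species {sp!r}")
        known = set(matrices[sp].gene_ids)
        absent = [g for g in scog.table[sp] if g not in known]
        if absent:
            raise FormatError(
                f"{len(absent)} SCOG member(s) absent from {sp} expression matrix, "
                f"e.g. {absent[0]!r}"
            )


# ---------------------------------------------------------------------------
# annotation flags (protein-domain evidence)
# ---------------------------------------------------------------------------


def read_annotation_flags(
    path: str | Path, required_genes: list[str] | None = None
) -> dict[str, bool]:
    """Read gene_id -> is_functional flags (TSV columns: gene_id, is_functional).

    ``is_functional`` stands for "has at least one predicted protein domain
    at stringent E-value". Genes listed in ``required_genes`` but missing
    from the file are defaulted to False with a warning.
    """
    path = Path(path)
    raw = pd.read_csv(path, sep="\t", header=0, dtype=str)
    if raw.shape[1] < 2:
        raise FormatError(f"{path}: expected columns gene_id, is_functional")
    flags: dict[str, bool] = {}
    truthy = {"1", "true", "True", "TRUE", "yes"}
    falsy = {"0", "false", "False", "FALSE", "no"}
    for gene, val in zip(raw.iloc[:, 0], raw.iloc[:, 1]):
        if gene in flags:
            raise FormatError(f"{path}: duplicate flag for gene {gene!r}")
        if val in truthy:
            flags[gene] = True
        elif val in falsy:
            flags[gene] = False
        else:
            raise FormatError(f"{path}: non-boolean flag {val!r} for gene {gene!r}")
    if required_genes is not None:
        missing = [g for g in required_genes if g not in flags]
        if missing:
            logger.warning(
                "%d gene(s) missing annotation flags; defaulting to False (e.g. %r)",
                len(missing),
                missing[0],
            )
            for g in missing:
                flags[g] = False
    return flags


def write_annotation_flags(flags: dict[str, bool], path: str | Path) -> None:
    df = pd.DataFrame(
        {"gene_id": list(flags), "is_functional": [int(v) for v in flags.values()]}
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# ranked priority list
# ---------------------------------------------------------------------------


def transition_label(t: int) -> str:
    """Stage-transition label, e.g. t=0 -> "S0−S1" (typographic minus)."""
    return f"S{t}{MINUS}S{t + 1}"


def write_ranked_list(records, path: str | Path) -> None:
    """Write a ranked priority list as TSV.

    Columns: rank, cluster_id, gene_id, FCD (linear scale, 1 decimal),
    transition. Records must already be ranked 1..N in order.
    """
    ranks = [r.rank for r in records]
    if ranks != sorted(ranks):
        raise FormatError("records not sorted by rank")
    if ranks and ranks != list(range(1, len(ranks) + 1)):
        raise FormatError(f"ranks must be contiguous 1..{len(ranks)}, got {ranks[:5]}...")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("rank\tcluster_id\tgene_id\tFCD\ttransition\n")
        for r in records:
            fh.write(
                f"{r.rank}\t{r.cluster_id}\t{r.gene_id}\t"
                f"{r.fcd_linear:.1f}\t{r.transition_label}\n"
            )


# ---------------------------------------------------------------------------
# phylostratigraphy inputs
# ---------------------------------------------------------------------------


def read_presence_table(path: str | Path) -> pd.DataFrame:
    """Ortholog presence/absence matrix: rows genes, columns taxa, 0/1 cells."""
    raw = pd.read_csv(path, sep="\t", header=0, dtype={0: str})
    table = raw.set_index(raw.columns[0])
    if table.index.has_duplicates:
        raise FormatError(f"{path}: duplicate gene ids in presence matrix")
    vals = table.to_numpy()
    if not np.isin(vals, (0, 1)).all():
        raise FormatError(f"{path}: presence matrix cells must be 0 or 1")
    return table.astype(bool)


def read_hierarchy(path: str | Path) -> list[tuple[str, frozenset[str]]]:
    """Ordered stratum hierarchy TSV (columns: stratum, taxon), oldest first."""
    raw = pd.read_csv(path, sep="\t", header=0, dtype=str)
    if raw.shape[1] < 2:
        raise FormatError(f"{path}: expected columns stratum, taxon")
    order: list[str] = []
    members: dict[str, set[str]] = {}
    for stratum, taxon in zip(raw.iloc[:, 0], raw.iloc[:, 1]):
        if stratum not in members:
            order.append(stratum)
            members[stratum] = set()
        members[stratum].add(taxon)
    return [(s, frozenset(members[s])) for s in order]


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class Config:
    """All pipeline thresholds in one place.

    z_threshold            active-gene cutoff on mean z-transformed log2 RPKM
    pseudocount            RPKM added before log2 fold changes (guards zeros)
    epsilon                floor for zero-length branches (time units)
    functional_min_members annotated members needed to call a cluster functional
    fcd_scale              "log2" (rank on log2 differences) or
                           "linear_difference" (difference of linear fold changes)
    seed                   RNG seed for the synthetic generator
    """

    z_threshold: float = -3.0
    pseudocount: float = 1.0
    epsilon: float = DEFAULT_BRANCH_EPSILON
    functional_min_members: int = 2
    fcd_scale: str = "log2"
    seed: int = 42

    def __post_init__(self):
        if self.fcd_scale not in ("log2", "linear_difference"):
            raise ValueError(f"unknown fcd_scale {self.fcd_scale!r}")
        if self.pseudocount < 0 or self.epsilon <= 0:
            raise ValueError("pseudocount must be >= 0 and epsilon > 0")


def load_config(path: str | Path) -> Config:
    """Load a config file: YAML mapping, or plain ``key=value`` lines."""
    text = Path(path).read_text(encoding="utf-8")
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        data = {}
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise FormatError(f"config line not key=value: {line!r}")
            k, v = line.split("=", 1)
            data[k.strip()] = yaml.safe_load(v.strip())
    known = set(Config.__dataclass_fields__)
    unknown = set(data) - known
    if unknown:
        raise FormatError(f"unknown config key(s): {sorted(unknown)}")
    return Config(**data)
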