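"""In-memory containers shared across the pipeline.

Omics matrices are genes x samples pandas DataFrames wrapped in a thin
dataclass that records the molecular level and enforces the identifier
invariants every downstream operation relies on.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

LEVELS = ("cnv", "mrna", "protein")

#: covariates every cohort table is expected to carry; extra columns are allowed
COVARIATE_COLUMNS = ("age", "gender", "tumour_type", "technology")


@dataclass
class OmicsMatrix:
    """A genes x samples measurement matrix at one molecular level.

    Parameters
    ----------
    values
        DataFrame indexed by gene identifier with sample identifiers as
        columns.  Missing measurements are NaN.
    level
        One of ``cnv`` (GISTIC-like integer states in [-2, 2]), ``mrna``
        (log expression) or ``protein`` (relative abundance).
    """

    values: pd.DataFrame
    level: str

    def __post_init__(self) -> None:
        if self.level not in LEVELS:
            raise ValueError(f"level must be one of {LEVELS}, got {self.level!r}")
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ValueError(f"duplicate gene identifier: {dup!r}")
        if self.values.columns.has_duplicates:
            dup = self.values.columns[self.values.columns.duplicated()][0]
            raise ValueError(f"duplicate sample identifier: {dup!r}")
        self.values.index.name = "gene_id"
        self.values.columns.name = None
        if self.level == "cnv":
            arr = self.values.to_numpy(dtype=float)
            finite = arr[np.isfinite(arr)]
            if finite.size and (
                np.any(finite != np.round(finite))
                or finite.min() < -2
                or finite.max() > 2
            ):
                raise ValueError("cnv level requires integer states in [-2, 2]")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_genes(self, genes) -> "OmicsMatrix":
        return OmicsMatrix(self.values.loc[list(genes)], self.level)

    def subset_samples(self, samples) -> "OmicsMatrix":
        return OmicsMatrix(self.values[list(samples)], self.level)

    def to_tsv(self, path: str | Path) -> None:
        """Write as TSV: gene ids in the first column, ``NA`` for missing."""
        self.values.to_csv(path, sep="\t", index_label="gene_id", na_rep="NA")

    @classmethod
    def from_tsv(cls, path: str | Path, level: str) -> "OmicsMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
        return cls(df, level)


def validate_covariates(cov: pd.DataFrame) -> pd.DataFrame:
    """Check a per-sample covariate table (one row per sample)."""
    if cov.index.has_duplicates:
        dup = cov.index[cov.index.duplicated()][0]
        raise ValueError(f"duplicate sample identifier in covariates: {dup!r}")
    for col in cov.columns:
        if cov[col].dtype == object and cov[col].dropna().empty:
            raise ValueError(f"covariate {col!r} has no categories")
    return cov


def read_covariates_tsv(path: str | Path) -> pd.DataFrame:
    cov = pd.read_csv(path, sep="\t", index_col=0)
    return validate_covariates(cov)


def write_covariates_tsv(cov: pd.DataFrame, path: str | Path) -> None:
    cov.to_csv(path, sep="\t", index_label="sample_id")


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read gene sets in GMT format (name, description, members...)."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            sets[parts[0]] = {g for g in parts[2:] if g}
    return sets


def write_gmt(sets: dict[str, set[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in sorted(sets):
            members = "\t".join(sorted(sets[name]))
            fh.write(f"{name}\tna\t{members}\n")


def read_complex_membership(path: str | Path) -> dict[str, set[str]]:
    """Two-column membership table (complex_id, gene_id) -> id -> member set."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError("complex membership table needs two columns")
    cid, gid = df.columns[:2]
    out: dict[str, set[str]] = {}
    for c, g in zip(df[cid], df[gid]):
        out.setdefault(c, set()).add(g)
    return out


def write_complex_membership(complexes: dict[str, set[str]], path: str | Path) -> None:
    rows = [
        {"complex_id": c, "gene_id": g}
        for c in sorted(complexes)
        for g in sorted(complexes[c])
    ]
    pd.DataFrame(rows, columns=["complex_id", "gene_id"]).to_csv(
        path, sep="\t", index=False
    )


def read_edge_list(path: str | Path) -> pd.DataFrame:
    """Scored edge list TSV with at least columns gene_a, gene_b[, score]."""
    df = pd.read_csv(path, sep="\t")
    if not {"gene_a", "gene_b"}.issubset(df.columns):
        raise ValueError("edge list requires columns gene_a and gene_b")
    return df
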