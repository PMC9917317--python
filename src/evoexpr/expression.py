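"""Replicated expression tables and their flattening into observation vectors.

The canonical in-memory container is a long-format pandas DataFrame with
columns ``gene, species, replicate, value``. For the likelihood, one gene's
values are flattened species-major / replicate-minor (species in tree tip
order, replicates sorted by label), the order in which the weight matrix W
and the covariance are built.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .trees import PhyloTree

__all__ = [
    "ExpressionMatrix",
    "ObservationVector",
    "read_expression",
    "filter_expressed",
    "replicate_mean",
    "observation_vector",
    "expression_from_frame",
]

LONG_COLUMNS = ["gene", "species", "replicate", "value"]


class ExpressionError(ValueError):
    pass


@dataclass(frozen=True)
class ExpressionMatrix:
    """Genes × (species, replicate) expression observations, long format."""

    data: pd.DataFrame  # columns gene, species, replicate, value

    def __post_init__(self) -> None:
        dup = self.data.duplicated(subset=["gene", "species", "replicate"])
        if dup.any():
            bad = self.data.loc[dup, ["gene", "species", "replicate"]].iloc[0].tolist()
            raise ExpressionError(f"duplicate (gene, species, replicate) triple: {bad}")

    @property
    def genes(self) -> list:
        return list(pd.unique(self.data["gene"]))

    @property
    def species(self) -> list:
        return list(pd.unique(self.data["species"]))

    @property
    def n_species(self) -> int:
        return self.data["species"].nunique()

    def replicate_counts(self, gene) -> pd.Series:
        sub = self.data[self.data["gene"] == gene]
        return sub.groupby("species", sort=False)["replicate"].nunique()

    def log2_transform(self) -> "ExpressionMatrix":
        """log2(x+1) convenience transform."""
        out = self.data.copy()
        out["value"] = np.log2(out["value"] + 1.0)
        return ExpressionMatrix(out)


@dataclass(frozen=True)
class ObservationVector:
    """One gene's flattened observations with the row → (species, replicate) map.

    ``species_index[p]`` is the tree tip index of row p; the same index maps
    rows of the weight matrix W and the covariance.
    """

    y: np.ndarray
    species_index: np.ndarray
    pairs: list[tuple[str, str]]  # (species, replicate) per row
    gene: object = None

    @property
    def n(self) -> int:
        return len(self.y)


def expression_from_frame(frame: pd.DataFrame) -> ExpressionMatrix:
    """Build an ExpressionMatrix from any DataFrame with the long columns."""
    missing = [c for c in LONG_COLUMNS if c not in frame.columns]
    if missing:
        raise ExpressionError(f"missing columns: {missing}")
    df = frame[LONG_COLUMNS].copy()
    df["value"] = df["value"].astype(float)
    return ExpressionMatrix(df.reset_index(drop=True))


def _sniff_sep(path: str) -> str:
    import gzip

    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        for line in fh:
            if line.strip() and not line.startswith("#"):
                return "\t" if "\t" in line else ","
    return ","


def read_expression(path: str, format: str = "long") -> ExpressionMatrix:
    """Read a delimited expression table (CSV or TSV; gzip transparent).

    ``long``: header ``gene,species,replicate,value``. ``wide``: one row per
    gene, first column the gene id, remaining columns named
    ``species.replicate``. Values round-trip exactly.
    """
    sep = _sniff_sep(path)
    if format == "long":
        df = pd.read_csv(path, sep=sep, comment="#", float_precision="round_trip")
        return expression_from_frame(df)
    if format == "wide":
        df = pd.read_csv(path, sep=sep, comment="#", index_col=0,
                         float_precision="round_trip")
        records = []
        for col in df.columns:
            if "." not in col:
                raise ExpressionError(f"wide column {col!r} is not 'species.replicate'")
            sp, rep = col.rsplit(".", 1)
            for gene, val in df[col].items():
                records.append((gene, sp, rep, float(val)))
        return ExpressionMatrix(pd.DataFrame(records, columns=LONG_COLUMNS))
    raise ExpressionError(f"unknown format {format!r}")


def filter_expressed(mat: ExpressionMatrix, threshold: float = 1.0) -> ExpressionMatrix:
    """Keep genes whose value exceeds ``threshold`` strictly in every
    (species, replicate) observation."""
    if len(mat.data) == 0:
        return mat
    ok = mat.data.groupby("gene", sort=False)["value"].transform("min") > threshold
    return ExpressionMatrix(mat.data[ok].reset_index(drop=True))


def replicate_mean(mat: ExpressionMatrix) -> pd.DataFrame:
    """Mean over replicates per (gene, species); columns gene, species, value."""
    out = (
        mat.data.groupby(["gene", "species"], sort=False)["value"]
        .mean()
        .reset_index()
    )
    return out


def averaged_matrix(mat: ExpressionMatrix) -> ExpressionMatrix:
    """Collapse replicates to their mean (single pseudo-replicate per species)."""
    means = replicate_mean(mat)
    means["replicate"] = "mean"
    return ExpressionMatrix(means[LONG_COLUMNS].copy())


def observation_vector(
    mat: ExpressionMatrix, gene, tree: PhyloTree
) -> ObservationVector:
    """Flatten one gene's values in canonical (tip-order, replicate-sorted) order."""
    sub = mat.data[mat.data["gene"] == gene]
    if len(sub) == 0:
        raise ExpressionError(f"gene {gene!r} not present")
    tip_labels = tree.tip_labels
    present = set(sub["species"])
    missing = [t for t in tip_labels if t not in present]
    if missing:
        raise ExpressionError(f"gene {gene!r} lacks observations for tips: {missing}")
    extra = sorted(present - set(tip_labels))
    if extra:
        raise ExpressionError(f"species not in tree: {extra}")
    ys, idx, pairs = [], [], []
    for i, sp in enumerate(tip_labels):
        block = sub[sub["species"] == sp].sort_values("replicate", kind="stable")
        ys.extend(block["value"].tolist())
        idx.extend([i] * len(block))
        pairs.extend((sp, str(r)) for r in block["replicate"])
    return ObservationVector(np.asarray(ys, dtype=float), np.asarray(idx, dtype=int), pairs, gene)
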