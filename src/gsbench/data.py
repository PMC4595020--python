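"""Core data model for genomic-selection benchmarks.

Genotypes are stored as sample-by-marker minor-allele dosage matrices with
entries in {0, 1, 2} and a distinguished missing code (-1 internally, "NA" on
disk).  Phenotypes are per-sample real vectors (binary traits coded 0/1) with
an explicit missing mask.  Cross-validation folds are first-class objects so
that one precomputed partition can be shared by every prediction method.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1  # in-memory missing dosage code
NA_TOKEN = "NA"  # on-disk missing code


class GenotypeParseError(ValueError):
    """Raised when a genotype file cannot be parsed under the named dialect."""


class ValidationError(ValueError):
    """Raised when parsed data violate a dosage/shape invariant."""


@dataclass
class GenotypeMatrix:
    """Samples x markers dosage matrix with an optional marker map.

    Parameters
    ----------
    values : ndarray of shape (n_samples, n_markers)
        Integer dosages; non-missing entries must be in {0, 1, 2} and missing
        entries equal :data:`MISSING`.
    sample_ids, marker_ids : sequences of str
        Ordered unique identifiers for rows and columns.
    chrom : ndarray of str, optional
        Per-marker chromosome label.
    pos : ndarray of int, optional
        Per-marker 1-based base-pair position, non-negative.
    """

    values: np.ndarray
    sample_ids: list[str]
    marker_ids: list[str]
    chrom: np.ndarray | None = None
    pos: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValidationError("genotype values must be 2-dimensional")
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.marker_ids = [str(m) for m in self.marker_ids]
        n, p = self.values.shape
        if len(self.sample_ids) != n:
            raise ValidationError(
                f"{len(self.sample_ids)} sample ids for {n} genotype rows"
            )
        if len(self.marker_ids) != p:
            raise ValidationError(
                f"{len(self.marker_ids)} marker ids for {p} genotype columns"
            )
        if len(set(self.marker_ids)) != p:
            raise ValidationError("marker ids are not unique")
        if len(set(self.sample_ids)) != n:
            raise ValidationError("sample ids are not unique")
        bad = ~np.isin(self.values, (0, 1, 2, MISSING))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"dosage {self.values[i, j]!r} at sample {self.sample_ids[i]!r}, "
                f"marker {self.marker_ids[j]!r} is not in {{0, 1, 2}} or missing"
            )
        for name in ("chrom", "pos"):
            arr = getattr(self, name)
            if arr is not None:
                arr = np.asarray(arr)
                if arr.shape != (p,):
                    raise ValidationError(f"{name} length does not match marker count")
                setattr(self, name, arr)
        if self.pos is not None and (np.asarray(self.pos) < 0).any():
            raise ValidationError("marker positions must be non-negative")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_markers(self) -> int:
        return self.values.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        return self.values == MISSING

    def dosages(self) -> np.ndarray:
        """Dosage matrix as float with NaN for missing entries."""
        out = self.values.astype(float)
        out[self.missing_mask] = np.nan
        return out

    def allele_frequencies(self) -> np.ndarray:
        """Per-marker allele frequency of the counted allele (NaN-aware)."""
        d = self.dosages()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(d, axis=0) / 2.0

    def minor_allele_frequencies(self) -> np.ndarray:
        p = self.allele_frequencies()
        return np.minimum(p, 1.0 - p)

    def subset_markers(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(
            values=self.values[:, index],
            sample_ids=list(self.sample_ids),
            marker_ids=[self.marker_ids[j] for j in index],
            chrom=None if self.chrom is None else self.chrom[index],
            pos=None if self.pos is None else self.pos[index],
        )

    def subset_samples(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(
            values=self.values[index, :],
            sample_ids=[self.sample_ids[i] for i in index],
            marker_ids=list(self.marker_ids),
            chrom=self.chrom,
            pos=self.pos,
        )


@dataclass
class PhenotypeVector:
    """A named per-sample trait vector; binary traits are coded 0/1."""

    trait_name: str
    values: np.ndarray
    binary: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValidationError("phenotype values must be 1-dimensional")
        if self.binary:
            obs = self.values[~np.isnan(self.values)]
            if not np.isin(obs, (0.0, 1.0)).all():
                raise ValidationError(
                    f"binary trait {self.trait_name!r} has values outside {{0, 1}}"
                )

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.values)

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class FoldAssignment:
    """Per-sample fold index in 1..k, with the seed that generated it."""

    fold_index: np.ndarray
    k: int
    seed: int | None = None

    def __post_init__(self) -> None:
        self.fold_index = np.asarray(self.fold_index, dtype=int)
        if self.fold_index.min() < 1 or self.fold_index.max() > self.k:
            raise ValidationError("fold indices must lie in 1..k")
        sizes = np.bincount(self.fold_index, minlength=self.k + 1)[1:]
        if sizes.max() - sizes.min() > 1:
            raise ValidationError("fold sizes differ by more than 1")

    def test_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_index == fold)

    def train_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_index != fold)


@dataclass
class Dataset:
    """A genotype matrix with one or more phenotypes and a fold partition."""

    genotypes: GenotypeMatrix
    phenotypes: dict[str, PhenotypeVector]
    folds: FoldAssignment | None = None
    name: str = "dataset"

    def __post_init__(self) -> None:
        n = self.genotypes.n_samples
        for trait, ph in self.phenotypes.items():
            if len(ph) != n:
                raise ValidationError(
                    f"trait {trait!r} has {len(ph)} values for {n} samples"
                )
        if self.folds is not None and len(self.folds.fold_index) != n:
            raise ValidationError("fold assignment length does not match samples")


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

_PLINK_RAW_HEADER = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]


def _parse_dosage_frame(df: pd.DataFrame, path) -> np.ndarray:
    raw = df.to_numpy()
    values = np.full(raw.shape, MISSING, dtype=np.int16)
    for i in range(raw.shape[0]):
        for j in range(raw.shape[1]):
            cell = raw[i, j]
            if (isinstance(cell, float) and np.isnan(cell)) or (
                isinstance(cell, str) and cell.strip() in (NA_TOKEN, "")
            ):
                continue
            try:
                val = float(cell)
            except (TypeError, ValueError):
                raise ValidationError(
                    f"{path}: non-numeric dosage {cell!r} at row {i + 1}, "
                    f"column {df.columns[j]!r}"
                ) from None
            if val not in (0.0, 1.0, 2.0):
                raise ValidationError(
                    f"{path}: dosage {cell!r} at row {i + 1}, column "
                    f"{df.columns[j]!r} is not in {{0, 1, 2}} or {NA_TOKEN!r}"
                )
            values[i, j] = int(val)
    return values


def read_genotypes(path, dialect: str = "csv") -> GenotypeMatrix:
    """Read a genotype matrix from CSV/TSV (sample_id + marker columns) or a
    PLINK ``.raw``-dialect file (six pedigree fields then dosage columns)."""
    if dialect in ("csv", "tsv"):
        sep = "," if dialect == "csv" else "\t"
        try:
            df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
        except pd.errors.ParserError as exc:
            raise GenotypeParseError(f"{path}: {exc}") from exc
        if df.shape[1] < 2:
            raise GenotypeParseError(f"{path}: expected sample_id plus markers")
        sample_ids = df.iloc[:, 0].tolist()
        marker_ids = list(df.columns[1:])
        values = _parse_dosage_frame(df.iloc[:, 1:], path)
    elif dialect == "plink_raw":
        try:
            df = pd.read_csv(path, sep=r"\s+", dtype=str, keep_default_na=False)
        except pd.errors.ParserError as exc:
            raise GenotypeParseError(f"{path}: {exc}") from exc
        if list(df.columns[:6]) != _PLINK_RAW_HEADER:
            raise GenotypeParseError(
                f"{path}: header does not start with {' '.join(_PLINK_RAW_HEADER)}"
            )
        sample_ids = df["IID"].tolist()
        marker_ids = list(df.columns[6:])
        values = _parse_dosage_frame(df.iloc[:, 6:], path)
    else:
        raise ValueError(f"unknown genotype dialect {dialect!r}")
    return GenotypeMatrix(values=values, sample_ids=sample_ids, marker_ids=marker_ids)


def write_genotypes(g: GenotypeMatrix, path, dialect: str = "csv") -> None:
    sep = "," if dialect == "csv" else "\t"
    if dialect not in ("csv", "tsv"):
        raise ValueError(f"unsupported output dialect {dialect!r}")
    cells = g.values.astype(object)
    cells[g.missing_mask] = NA_TOKEN
    df = pd.DataFrame(cells, columns=g.marker_ids)
    df.insert(0, "sample_id", g.sample_ids)
    df.to_csv(path, sep=sep, index=False)


def read_phenotypes(path) -> list[PhenotypeVector]:
    """Read a TSV phenotype table (sample_id, then one column per trait)."""
    df = pd.read_csv(path, sep="\t", na_values=[NA_TOKEN])
    out = []
    for col in df.columns[1:]:
        values = pd.to_numeric(df[col], errors="raise").to_numpy(dtype=float)
        obs = values[~np.isnan(values)]
        if obs.size == 0:
            warnings.warn(f"trait {col!r} has no observed values")
            binary = False
        else:
            binary = np.isin(obs, (0.0, 1.0)).all() and np.unique(obs).size <= 2
        out.append(PhenotypeVector(trait_name=col, values=values, binary=bool(binary)))
    return out


def write_phenotypes(phenos: list[PhenotypeVector], sample_ids, path) -> None:
    df = pd.DataFrame({"sample_id": list(sample_ids)})
    for ph in phenos:
        df[ph.trait_name] = ph.values
    df.to_csv(path, sep="\t", index=False, na_rep=NA_TOKEN)


def read_folds(path) -> FoldAssignment:
    df = pd.read_csv(path, sep="\t")
    idx = df.iloc[:, 1].to_numpy(dtype=int)
    return FoldAssignment(fold_index=idx, k=int(idx.max()))


def write_folds(folds: FoldAssignment, sample_ids, path) -> None:
    pd.DataFrame({"sample_id": list(sample_ids), "fold_index": folds.fold_index}).to_csv(
        path, sep="\t", index=False
    )


def read_marker_map(path) -> pd.DataFrame:
    """Optional marker map: TSV with columns marker_id, chrom, pos."""
    return pd.read_csv(path, sep="\t", dtype={"marker_id": str, "chrom": str})


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------


def impute_missing(g: GenotypeMatrix) -> GenotypeMatrix:
    """Replace each missing dosage by the per-marker mode of observed dosages.

    Simple and deterministic; haplotype-model imputers are out of scope.  Ties
    between equally frequent dosages resolve to the smaller dosage.
    """
    values = g.values.copy()
    for j in range(g.n_markers):
        col = values[:, j]
        miss = col == MISSING
        if not miss.any():
            continue
        obs = col[~miss]
        if obs.size == 0:
            raise ValidationError(
                f"marker {g.marker_ids[j]!r} has no observed genotypes to impute from"
            )
        counts = np.bincount(obs, minlength=3)
        values[miss, j] = int(np.argmax(counts))
    return GenotypeMatrix(
        values=values,
        sample_ids=list(g.sample_ids),
        marker_ids=list(g.marker_ids),
        chrom=g.chrom,
        pos=g.pos,
    )


def filter_markers(
    g: GenotypeMatrix,
    max_missing_rate: float = 0.10,
    min_maf: float = 0.0,
    drop_monomorphic: bool = True,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Remove markers failing missing-rate, MAF, or monomorphism filters.

    Returns the filtered matrix and a report of removed markers with the first
    reason that triggered removal.  Defaults mirror common SNP-chip QC: drop
    markers with >10% missing calls and monomorphic markers.
    """
    if not 0 <= max_missing_rate <= 1:
        raise ValueError("max_missing_rate must be in [0, 1]")
    if not 0 <= min_maf <= 0.5:
        raise ValueError("min_maf must be in [0, 0.5]")
    removed: list[tuple[str, str]] = []
    keep = np.ones(g.n_markers, dtype=bool)
    miss_rate = g.missing_mask.mean(axis=0)
    maf = g.minor_allele_frequencies()
    for j in range(g.n_markers):
        if miss_rate[j] > max_missing_rate:
            removed.append((g.marker_ids[j], "missing_rate"))
            keep[j] = False
            continue
        col = g.values[:, j]
        obs = col[col != MISSING]
        if drop_monomorphic and (obs.size == 0 or np.unique(obs).size == 1):
            removed.append((g.marker_ids[j], "monomorphic"))
            keep[j] = False
            continue
        if obs.size and maf[j] < min_maf:
            removed.append((g.marker_ids[j], "maf"))
            keep[j] = False
    if not keep.any():
        raise ValidationError("all markers removed by filters")
    report = pd.DataFrame(removed, columns=["marker_id", "reason"])
    return g.subset_markers(np.flatnonzero(keep)), report


def make_folds(sample_ids, k: int = 10, seed: int = 0) -> FoldAssignment:
    """Seeded uniform permutation followed by round-robin fold assignment."""
    n = len(sample_ids)
    if k < 2:
        raise ValueError("k must be at least 2")
    if k > n:
        raise ValueError(f"cannot split {n} samples into {k} folds")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    fold_index = np.empty(n, dtype=int)
    fold_index[perm] = np.arange(n) % k + 1
    return FoldAssignment(fold_index=fold_index, k=k, seed=seed)


def correct_population_structure(
    y: PhenotypeVector, g: GenotypeMatrix, n_components: int = 4
) -> PhenotypeVector:
    """Residualize a phenotype on the leading genotype principal components.

    PC scores are computed on the column-centered (not scaled) dosage matrix;
    the phenotype is regressed on an intercept plus the top ``n_components``
    scores and the zero-mean residuals are returned.
    """
    X = np.asarray(g.values, dtype=float)
    if (X == MISSING).any():
        raise ValidationError("impute missing genotypes before PC correction")
    if n_components > min(g.n_samples, g.n_markers):
        raise ValueError("n_components exceeds matrix dimensions")
    Xc = X - X.mean(axis=0)
    u, s, _ = np.linalg.svd(Xc, full_matrices=False)
    rank = int((s > s[0] * 1e-12).sum()) if s.size else 0
    if n_components > rank:
        raise ValueError(f"n_components={n_components} exceeds genotype rank {rank}")
    scores = u[:, :n_components] * s[:n_components]
    design = np.column_stack([np.ones(g.n_samples), scores])
    yv = np.asarray(y.values, dtype=float)
    obs = ~np.isnan(yv)
    coef, *_ = np.linalg.lstsq(design[obs], yv[obs], rcond=None)
    resid = np.full_like(yv, np.nan)
    resid[obs] = yv[obs] - design[obs] @ coef
    resid[obs] -= resid[obs].mean()
    return PhenotypeVector(trait_name=f"{y.trait_name}_pc_corrected", values=resid)
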