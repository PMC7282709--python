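"""Reading, validation and pre-processing of metabolomics study tables.

A study consists of three tables:

* an abundance matrix (samples x metabolites, positive semi-quantitative
  intensities, empty cells = below detection),
* a metabolite annotation table (biochemical name, super-pathway,
  sub-pathway, optional lipid-structure fields),
* a sample metadata table (individual, condition pre/post, covariates, BMI).

Pre-processing follows the platform-conventional scheme for semi-quantitative
UPLC-MS/MS panels: per-metabolite minimum (or half-minimum) imputation of
left-censored values, log10 transformation, then least-squares residualization
of nuisance covariates (sex, age, ethnicity, run day).  The condition label
and the individual are never residualized here; they are the business of the
paired differential stage.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger("leptomet")

#: Metabolite classes reported by the profiling platform.
SUPER_PATHWAYS = (
    "Lipid",
    "Amino Acid",
    "Nucleotide",
    "Peptide",
    "Cofactors and Vitamins",
    "Carbohydrate",
    "Energy",
)

#: Analysis-wide significance conventions: nominal two-sided p, and the
#: liberal FDR tier used for multi-test stages.
NOMINAL_P = 0.05
FDR_THRESHOLD = 0.2

#: Age (years) at or below which a participant counts as a child.
CHILD_MAX_AGE = 18.0

ANNOTATION_COLUMNS = ("metabolite_id", "biochemical_name", "super_pathway", "sub_pathway")
METADATA_COLUMNS = (
    "sample_id",
    "individual_id",
    "condition",
    "sex",
    "age",
    "ethnicity",
    "run_day",
)


class SchemaError(ValueError):
    """A required column is missing or mis-named."""


class StudyValidationError(ValueError):
    """Cross-table identifiers or invariants are inconsistent."""


class IntensityParseError(ValueError):
    """A cell of the abundance table is not a number."""


@dataclass
class AbundanceMatrix:
    """Samples x metabolites intensity grid.

    ``data`` is indexed by sample_id (rows) and metabolite_id (columns).
    ``log_scale`` records whether values are log10 intensities; on the raw
    scale every non-missing entry must be positive.
    """

    data: pd.DataFrame
    log_scale: bool = False

    def __post_init__(self) -> None:
        if not self.log_scale:
            vals = self.data.to_numpy(dtype=float)
            if np.any(vals[np.isfinite(vals)] <= 0):
                raise StudyValidationError("raw intensities must be positive")

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.index

    @property
    def metabolite_ids(self) -> pd.Index:
        return self.data.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def copy(self) -> "AbundanceMatrix":
        return AbundanceMatrix(self.data.copy(), self.log_scale)


def _read_table(path) -> pd.DataFrame:
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else None
    return pd.read_csv(path, sep=sep, engine="python")


def _check_columns(df: pd.DataFrame, required, what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} table is missing required column(s): {', '.join(missing)}")


def validate_annotations(annotations: pd.DataFrame) -> pd.DataFrame:
    _check_columns(annotations, ANNOTATION_COLUMNS, "annotation")
    dup = annotations["metabolite_id"][annotations["metabolite_id"].duplicated()]
    if len(dup):
        raise StudyValidationError(f"duplicated metabolite_id(s): {', '.join(map(str, dup.unique()))}")
    if "chain_length" in annotations.columns:
        cl = pd.to_numeric(annotations["chain_length"], errors="coerce")
        if (cl.dropna() < 2).any():
            raise StudyValidationError("chain_length must be >= 2 carbons")
    if "double_bonds" in annotations.columns:
        db = pd.to_numeric(annotations["double_bonds"], errors="coerce")
        if (db.dropna() < 0).any():
            raise StudyValidationError("double_bonds must be >= 0")
    return annotations.set_index("metabolite_id", drop=False)


def validate_metadata(metadata: pd.DataFrame) -> pd.DataFrame:
    _check_columns(metadata, METADATA_COLUMNS, "metadata")
    dup = metadata["sample_id"][metadata["sample_id"].duplicated()]
    if len(dup):
        raise StudyValidationError(f"duplicated sample_id(s): {', '.join(map(str, dup.unique()))}")
    bad = set(metadata["condition"]) - {"pre", "post"}
    if bad:
        raise StudyValidationError(f"condition must be 'pre' or 'post', got {sorted(bad)}")
    counts = metadata.groupby(["individual_id", "condition"]).size()
    over = counts[counts > 1]
    if len(over):
        pairs = ", ".join(f"{i}/{c}" for i, c in over.index)
        raise StudyValidationError(f"more than one sample per individual/condition: {pairs}")
    metadata = metadata.copy()
    metadata["age_group"] = np.where(
        pd.to_numeric(metadata["age"]) <= CHILD_MAX_AGE, "child", "adult"
    )
    return metadata.set_index("sample_id", drop=False)


def read_study(abundance_path, annotation_path, metadata_path):
    """Read and cross-validate the three study tables.

    Returns ``(AbundanceMatrix, annotations, metadata)`` with annotations
    indexed by metabolite_id and metadata by sample_id.  Samples or
    metabolites present in the matrix but unknown to the other tables are
    errors; the reverse (annotated but unmeasured) is tolerated with a log
    message, as panels routinely annotate more than they detect.
    """
    raw = _read_table(abundance_path)
    if raw.shape[1] < 2:
        raise SchemaError("abundance table needs a sample_id column plus metabolite columns")
    raw = raw.rename(columns={raw.columns[0]: "sample_id"}).set_index("sample_id")

    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & raw.notna() & (raw.astype(str).apply(lambda s: s.str.strip()) != "")
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise IntensityParseError(
            f"non-numeric intensity {raw.iat[r, c]!r} at sample {raw.index[r]!r}, "
            f"metabolite {raw.columns[c]!r}"
        )

    annotations = validate_annotations(_read_table(annotation_path))
    metadata = validate_metadata(_read_table(metadata_path))

    unknown_mets = numeric.columns.difference(annotations.index)
    if len(unknown_mets):
        raise StudyValidationError(
            f"metabolites absent from annotation table: {', '.join(map(str, unknown_mets[:5]))}"
        )
    unknown_samples = numeric.index.difference(metadata.index)
    if len(unknown_samples):
        raise StudyValidationError(
            f"samples absent from metadata table: {', '.join(map(str, unknown_samples[:5]))}"
        )
    extra = annotations.index.difference(numeric.columns)
    if len(extra):
        logger.info("%d annotated metabolites not present in the abundance matrix", len(extra))
    metadata = metadata.loc[metadata.index.intersection(numeric.index)]

    return AbundanceMatrix(numeric, log_scale=False), annotations, metadata


def impute_and_log(matrix: AbundanceMatrix, method: str = "min") -> AbundanceMatrix:
    """Impute left-censored values per metabolite and log10-transform.

    ``method`` is ``"min"`` (minimum observed value of the metabolite) or
    ``"halfmin"`` (half of it).  Metabolites with no observed value at all
    are dropped with a warning.
    """
    if matrix.log_scale:
        raise StudyValidationError("matrix is already on the log scale")
    if method not in ("min", "halfmin"):
        raise ValueError(f"unknown imputation method {method!r}")

    data = matrix.data.copy()
    all_missing = data.columns[data.isna().all()]
    if len(all_missing):
        warnings.warn(
            f"dropping {len(all_missing)} metabolite(s) with no observed values: "
            f"{', '.join(map(str, all_missing[:5]))}",
            stacklevel=2,
        )
        data = data.drop(columns=all_missing)

    fill = data.min(axis=0)
    if method == "halfmin":
        fill = fill / 2.0
    data = data.fillna(fill)
    return AbundanceMatrix(np.log10(data), log_scale=True)


def adjust_covariates(
    matrix: AbundanceMatrix, metadata: pd.DataFrame, covariates: list[str]
) -> AbundanceMatrix:
    """Residualize each metabolite on nuisance covariates, keeping the mean.

    Numeric covariates enter as-is; categorical ones as indicator contrasts
    (first level dropped).  The per-metabolite grand mean is added back so
    downstream effect sizes stay on the log-intensity scale.  ``condition``
    and ``individual_id`` are refused: the paired stage absorbs them.
    """
    if not matrix.log_scale:
        raise StudyValidationError("adjust_covariates expects log-scale data")
    forbidden = {"condition", "individual_id"} & set(covariates)
    if forbidden:
        raise StudyValidationError(
            f"{sorted(forbidden)} must not be residualized; the paired stage handles them"
        )
    if not covariates:
        return matrix.copy()
    missing = [c for c in covariates if c not in metadata.columns]
    if missing:
        raise SchemaError(f"covariate(s) not in metadata: {', '.join(missing)}")

    meta = metadata.loc[matrix.sample_ids]
    blocks = [pd.Series(1.0, index=meta.index, name="intercept")]
    for cov in covariates:
        col = meta[cov]
        if pd.api.types.is_numeric_dtype(col):
            blocks.append(col.astype(float))
        else:
            blocks.append(pd.get_dummies(col.astype(str), prefix=cov, drop_first=True, dtype=float))
    X = pd.concat(blocks, axis=1).to_numpy(dtype=float)

    n, p = X.shape
    if p > n:
        raise StudyValidationError(f"{p} covariate parameters for {n} samples")
    if "condition" in meta.columns:
        cond = (meta["condition"] == "post").astype(float).to_numpy()
        rank_x = np.linalg.matrix_rank(X)
        if np.linalg.matrix_rank(np.column_stack([X, cond])) == rank_x:
            raise StudyValidationError("covariates are perfectly confounded with condition")

    Y = matrix.data.to_numpy(dtype=float)
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    adjusted = resid + Y.mean(axis=0, keepdims=True)
    return AbundanceMatrix(
        pd.DataFrame(adjusted, index=matrix.sample_ids, columns=matrix.metabolite_ids),
        log_scale=True,
    )
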