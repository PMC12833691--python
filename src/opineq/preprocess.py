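"""From raw inpatient records to analysis-ready health vectors and environment matrix.

The raw outcome is the discharge diagnosis, an ordinal four-category variable
(1 = cured, 2 = improved, 3 = not cured, 4 = death).  The preprocessing chain is

1. study filters: age >= 45, circulatory-chapter ICD-10 groups, and only
   diagnosis groups with more than 30 cases;
2. mean imputation (ordinal/binary levels rounded to the nearest valid code);
3. two-sided 1% winsorization of total medical expenses;
4. rank-based inverse normal transformation (RINT) of the ordinal outcome at
   cumulative-frequency midpoints, value reversal (higher = better health) and
   a positivity shift so the mean-log-deviation index is defined;
5. a per-diagnosis cost-variance feature: the variance of winsorized expenses
   within each ICD-10 group, quantile-binned into ordinal codes.

The environment matrix holds the thirteen circumstance covariates used by the
environment-only health models.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ENV_COLUMNS",
    "BINARY_COLUMNS",
    "ORDINAL_LEVELS",
    "RintMap",
    "HealthVector",
    "rint_fit",
    "filter_study_population",
    "impute_means",
    "winsorize",
    "make_health",
    "cost_variance_feature",
    "build_environment_matrix",
    "preprocess",
    "PreprocessResult",
    "EmptyPopulationError",
]

#: the 13 environmental (circumstance) covariates entering the models
ENV_COLUMNS = [
    "age",
    "gender",
    "ethnicity",
    "marital_status",
    "occupational_risk",
    "beds_per_1000",
    "doctors_per_1000",
    "rail_transit",
    "old_area",
    "cost_variance",
    "surgical_level",
    "emergency_admission",
    "admission_condition",
]

BINARY_COLUMNS = {
    "gender", "ethnicity", "marital_status", "rail_transit", "old_area",
    "emergency_admission",
}

#: valid integer level ranges for ordinal codes (inclusive)
ORDINAL_LEVELS = {
    "occupational_risk": (0, 2),
    "surgical_level": (0, 2),
    "admission_condition": (1, 4),
    "cost_variance": (0, 4),
    "primary_dx": (1, 4),
}


class EmptyPopulationError(ValueError):
    """Raised when the study filters leave no records."""


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------

def filter_study_population(records: pd.DataFrame, *, min_age: float = 45.0,
                            icd10_prefixes: tuple[str, ...] = ("I",),
                            min_cases: int = 31) -> pd.DataFrame:
    """Apply the study-population restrictions.

    Keeps rows with ``age >= min_age`` and an ``icd10_group`` starting with one
    of ``icd10_prefixes`` (default: the ICD-10 circulatory chapter), then drops
    diagnosis groups with fewer than ``min_cases`` members — the default keeps
    groups with *more than 30* cases, i.e. a group of exactly 30 is dropped and
    one of 31 is kept.
    """
    if "age" not in records or "icd10_group" not in records:
        raise KeyError("records must carry 'age' and 'icd10_group'")
    out = records[records["age"] >= min_age]
    if icd10_prefixes:
        mask = out["icd10_group"].astype(str).str.startswith(tuple(icd10_prefixes))
        out = out[mask]
    if len(out):
        sizes = out.groupby("icd10_group")["icd10_group"].transform("size")
        out = out[sizes >= min_cases]
    if out.empty:
        raise EmptyPopulationError(
            "study filters removed every record "
            f"(min_age={min_age}, prefixes={icd10_prefixes}, min_cases={min_cases})"
        )
    return out.copy()


# ---------------------------------------------------------------------------
# imputation and winsorization
# ---------------------------------------------------------------------------

def _round_to_level(value: float, col: str) -> float:
    """Round an imputed mean to the nearest valid code for ordinal/binary columns."""
    if col in BINARY_COLUMNS:
        lo, hi = 0, 1
    elif col in ORDINAL_LEVELS:
        lo, hi = ORDINAL_LEVELS[col]
    else:
        return value
    return float(min(max(int(np.floor(value + 0.5)), lo), hi))


def impute_means(matrix: pd.DataFrame, columns=None) -> pd.DataFrame:
    """Replace missing entries by the column mean.

    Continuous columns get the raw mean; ordinal and binary columns get the
    mean rounded to the nearest valid level so codings stay valid.  A column
    with no observed value at all is an error.
    """
    out = matrix.copy()
    cols = list(columns) if columns is not None else [
        c for c in out.columns if pd.api.types.is_numeric_dtype(out[c])
    ]
    counts = {}
    for col in cols:
        n_missing = int(out[col].isna().sum())
        if n_missing == 0:
            continue
        if n_missing == len(out):
            raise ValueError(f"impute_means: column {col!r} is fully missing")
        fill = _round_to_level(float(out[col].mean()), col)
        out[col] = out[col].fillna(fill)
        counts[col] = n_missing
    out.attrs["imputation_counts"] = counts
    return out


def winsorize(values, lower_pct: float = 1.0, upper_pct: float = 99.0):
    """Two-sided winsorization at percentile bounds (linear-interpolation quantiles).

    Values below the ``lower_pct`` percentile are set to it and values above
    the ``upper_pct`` percentile are set to it.  Idempotent at fixed bounds.
    """
    if not 0.0 <= lower_pct <= upper_pct <= 100.0:
        raise ValueError("need 0 <= lower_pct <= upper_pct <= 100")
    arr = np.asarray(values, dtype=float)
    lo = np.percentile(arr, lower_pct)
    hi = np.percentile(arr, upper_pct)
    clipped = np.clip(arr, lo, hi)
    if isinstance(values, pd.Series):
        return pd.Series(clipped, index=values.index, name=values.name)
    return clipped


# ---------------------------------------------------------------------------
# RINT
# ---------------------------------------------------------------------------

@dataclass
class RintMap:
    """Category -> z-score map for an ordinal variable.

    ``z_k = Phi^{-1}(F_{k-1} + f_k / 2)`` where ``f_k`` is the relative
    frequency of category ``k`` and ``F_{k-1}`` the cumulative frequency of
    lower categories (midpoint convention).  The mapping is strictly
    increasing over categories with positive frequency.
    """

    categories: np.ndarray
    z: np.ndarray
    freqs: np.ndarray
    n: int

    def apply(self, values) -> np.ndarray:
        values = np.asarray(values)
        lut = {c: z for c, z in zip(self.categories, self.z)}
        try:
            return np.array([lut[v] for v in values.ravel()], dtype=float).reshape(values.shape)
        except KeyError as err:
            raise ValueError(f"value {err} not in fitted categories {list(self.categories)}") from None


def rint_fit(counts) -> RintMap:
    """Fit a rank-based inverse normal transformation from category counts.

    Parameters
    ----------
    counts : mapping category -> count, or pandas Series of raw ordinal values
        (value counts are taken), or a sequence of (category, count) pairs.
    """
    if isinstance(counts, pd.Series) and not counts.index.is_unique:
        counts = counts.value_counts()
    if isinstance(counts, pd.Series):
        items = list(counts.items())
    elif isinstance(counts, dict):
        items = list(counts.items())
    else:
        items = list(counts)
    items = sorted(items)
    cats = np.array([c for c, _ in items])
    cnt = np.array([n for _, n in items], dtype=float)
    if np.any(cnt < 0) or cnt.sum() <= 0:
        raise ValueError("rint_fit: counts must be nonnegative with positive total")
    keep = cnt > 0
    cats, cnt = cats[keep], cnt[keep]
    n = cnt.sum()
    f = cnt / n
    cum = np.concatenate([[0.0], np.cumsum(f)[:-1]])
    z = stats.norm.ppf(cum + f / 2.0)
    if len(cats) == 1:
        warnings.warn("rint_fit: single observed category; transformed variable is "
                      "degenerate (all mass at z=0)", stacklevel=2)
        z = np.array([0.0])
    return RintMap(categories=cats, z=z, freqs=f, n=int(n))


# ---------------------------------------------------------------------------
# health vectors
# ---------------------------------------------------------------------------

@dataclass
class HealthVector:
    """Continuous transformed health outcome, strictly positive after shift."""

    values: np.ndarray
    variant: str  # "primary" | "composite"
    shift: float
    rint_map: RintMap | None = field(default=None, repr=False)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)

    def __len__(self):
        return len(self.values)


def _reversed_scores(dx, rint_map: RintMap) -> np.ndarray:
    # reversal: negate the z-score so higher = better health
    return -rint_map.apply(np.asarray(dx))


def make_health(records: pd.DataFrame, variant: str, rint_map: RintMap,
                shift: float = 5.0) -> HealthVector:
    """Build the continuous health variable.

    ``primary``: reversed RINT score of the primary discharge diagnosis.
    ``composite``: mean of the reversed RINT scores of the primary and all
    secondary diagnoses (transformed scores are averaged, not raw codes).
    The ``shift`` is then added; it must leave every value strictly positive.
    Secondary diagnoses are read from a ``secondary_dx`` column holding lists
    (possibly empty) of ordinal codes.
    """
    if variant not in ("primary", "composite"):
        raise ValueError(f"unknown health variant {variant!r}")
    prim = _reversed_scores(records["primary_dx"].to_numpy(), rint_map)
    if variant == "primary":
        vals = prim
    else:
        sec = records["secondary_dx"] if "secondary_dx" in records else None
        vals = np.empty_like(prim)
        for i, (p, s) in enumerate(zip(prim, sec if sec is not None else [[]] * len(prim))):
            codes = list(s) if isinstance(s, (list, tuple, np.ndarray)) else []
            if codes:
                vals[i] = (p + _reversed_scores(codes, rint_map).sum()) / (1 + len(codes))
            else:
                vals[i] = p
    shifted = vals + shift
    if np.any(shifted <= 0):
        min_shift = float(-vals.min())
        raise ValueError(
            f"shift {shift} leaves non-positive health values; "
            f"minimum feasible shift is just above {min_shift:.6f}"
        )
    return HealthVector(values=shifted, variant=variant, shift=shift, rint_map=rint_map)


# ---------------------------------------------------------------------------
# cost-variance feature
# ---------------------------------------------------------------------------

def cost_variance_feature(records: pd.DataFrame, n_bins: int = 5,
                          expenses_col: str = "total_expenses") -> pd.Series:
    """Within-diagnosis-group variance of expenses, quantile-binned to ordinal codes.

    For every ICD-10 group the (population) variance of ``expenses_col`` across
    the group's patients is computed and assigned to each member; the patient-
    level variance column is then split at its quantiles into ``n_bins`` levels
    coded ``0 .. n_bins-1``.  Singleton groups get variance 0 by convention
    (with a warning).  If ties collapse bin edges the number of distinct codes
    shrinks accordingly.
    """
    if expenses_col not in records or "icd10_group" not in records:
        raise KeyError(f"records must carry {expenses_col!r} and 'icd10_group'")
    grp = records.groupby("icd10_group")[expenses_col]
    sizes = grp.transform("size")
    if (sizes == 1).any():
        warnings.warn("cost_variance_feature: singleton diagnosis group(s); "
                      "variance set to 0 by convention", stacklevel=2)
    var = grp.transform(lambda s: float(np.var(s.to_numpy())))
    if var.nunique() == 1:
        codes = np.zeros(len(var), dtype=int)
    else:
        edges = np.unique(np.percentile(var, np.linspace(0, 100, n_bins + 1)[1:-1]))
        codes = np.searchsorted(edges, var, side="left")
    return pd.Series(codes, index=records.index, name="cost_variance")


# ---------------------------------------------------------------------------
# environment matrix and the full chain
# ---------------------------------------------------------------------------

def build_environment_matrix(records: pd.DataFrame) -> pd.DataFrame:
    """Assemble the 13-covariate environment matrix (cost_variance computed if absent)."""
    df = records
    if "cost_variance" not in df:
        df = df.assign(cost_variance=cost_variance_feature(df))
    missing = [c for c in ENV_COLUMNS if c not in df]
    if missing:
        raise KeyError(f"records missing environmental columns: {missing}")
    env = df[ENV_COLUMNS].astype(float)
    if env.isna().any().any():
        raise ValueError("environment matrix contains missing values; impute first")
    return env


@dataclass
class PreprocessResult:
    env: pd.DataFrame
    health: dict  # variant -> HealthVector
    records: pd.DataFrame
    rint_map: RintMap
    report: dict


def preprocess(records: pd.DataFrame, *, shift: float = 5.0, min_age: float = 45.0,
               icd10_prefixes: tuple[str, ...] = ("I",), min_cases: int = 31,
               winsor_pcts: tuple[float, float] = (1.0, 99.0),
               cost_bins: int = 5,
               variants: tuple[str, ...] = ("primary", "composite")) -> PreprocessResult:
    """Run the full preprocessing chain and return matrix, health vectors and report."""
    n0 = len(records)
    df = filter_study_population(records, min_age=min_age,
                                 icd10_prefixes=icd10_prefixes, min_cases=min_cases)
    n_filtered = len(df)
    impute_cols = [c for c in ENV_COLUMNS if c in df and c != "cost_variance"]
    if "total_expenses" in df:
        impute_cols.append("total_expenses")
    df = impute_means(df, columns=impute_cols)
    imput_counts = df.attrs.get("imputation_counts", {})
    lo_hi = {}
    if "total_expenses" in df:
        lo_hi = {"lower": float(np.percentile(df["total_expenses"], winsor_pcts[0])),
                 "upper": float(np.percentile(df["total_expenses"], winsor_pcts[1]))}
        df["total_expenses"] = winsorize(df["total_expenses"], *winsor_pcts)
    df["cost_variance"] = cost_variance_feature(df, n_bins=cost_bins)
    rmap = rint_fit(df["primary_dx"].value_counts())
    health = {v: make_health(df, v, rmap, shift=shift) for v in variants}
    env = build_environment_matrix(df)
    report = {
        "n_input": n0,
        "n_after_filters": n_filtered,
        "rows_dropped": n0 - n_filtered,
        "imputation_counts": imput_counts,
        "winsorization_bounds": lo_hi,
        "rint": {"categories": rmap.categories.tolist(), "z": rmap.z.tolist(),
                 "freqs": rmap.freqs.tolist(), "n": rmap.n},
        "shift": shift,
    }
    return PreprocessResult(env=env, health=health, records=df, rint_map=rmap,
                            report=report)
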