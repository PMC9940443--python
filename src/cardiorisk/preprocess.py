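"""Patient-table schema, risk-zone labeling, and the preprocessing recipe.

The table follows the processed UCI heart-disease dialect restricted to the
attributes obtainable without in-hospital tests (``ca`` and ``thal`` are
dropped): 11 features plus the ordinal disease-severity target ``num``
(0–4).  Severity maps onto traffic-light risk zones — three-level: 0 green,
1 yellow, 2–4 red; two-level: 0 green, 1–4 red.

The recipe is: MICE imputation -> robust scaling of continuous columns ->
0..K-1 encoding of categoricals -> random oversampling to class balance ->
70/30 split.  By default oversampling happens *before* the split, which
leaks duplicated records into the test set; a prominent warning is logged
and ``split_first`` order is available (see `run` in the pipeline module).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.experimental import enable_iterative_imputer  # noqa: F401
from sklearn.impute import IterativeImputer
from sklearn.preprocessing import RobustScaler

from .errors import ConfigurationError, InvalidInputError

logger = logging.getLogger(__name__)

#: The 11 feature columns, in table order, plus the optional target.
FEATURE_COLUMNS = (
    "age", "sex", "cp", "trestbps", "chol", "fbs",
    "restecg", "thalach", "exang", "oldpeak", "slope",
)
TARGET_COLUMN = "num"
ZONE_COLUMN = "zone"

CONTINUOUS_COLUMNS = ("age", "trestbps", "chol", "thalach", "oldpeak")
CATEGORICAL_COLUMNS = ("sex", "cp", "fbs", "restecg", "exang", "slope")

#: Valid values for each categorical attribute.
CATEGORICAL_DOMAINS: dict[str, tuple[int, ...]] = {
    "sex": (0, 1),
    "cp": (1, 2, 3, 4),
    "fbs": (0, 1),
    "restecg": (0, 1, 2),
    "exang": (0, 1),
    "slope": (1, 2, 3),
    TARGET_COLUMN: (0, 1, 2, 3, 4),
}

#: Plausible ranges for the continuous attributes (used by range checks and
#: the synthetic generator).
CONTINUOUS_RANGES: dict[str, tuple[float, float]] = {
    "age": (29.0, 77.0),
    "trestbps": (94.0, 200.0),
    "chol": (126.0, 564.0),
    "thalach": (71.0, 202.0),
    "oldpeak": (0.0, 6.2),
}

STAGES = ("raw", "imputed", "scaled", "encoded", "oversampled")

ZONES_THREE = ("green", "yellow", "red")
ZONES_TWO = ("green", "red")

#: Integer codes used when zones feed a classifier.
ZONE_CODES = {"green": 0, "yellow": 1, "red": 2}


@dataclass(frozen=True)
class FeatureTable:
    """An ordered patient table plus its position in the recipe.

    Columns must be a subset of the 11 feature attributes plus optional
    ``num`` and ``zone``; missing values are NaN (the UCI "?" marker is
    translated on read, never stored).
    """

    data: pd.DataFrame
    stage: str = "raw"

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise InvalidInputError(f"unknown stage {self.stage!r}")
        allowed = set(FEATURE_COLUMNS) | {TARGET_COLUMN, ZONE_COLUMN}
        unknown = [c for c in self.data.columns if c not in allowed]
        if unknown:
            raise InvalidInputError(f"unknown column(s): {unknown}")
        object.__setattr__(self, "data", self.data.reset_index(drop=True))

    def __len__(self) -> int:
        return len(self.data)

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.data.isna()

    def _advance(self, data: pd.DataFrame, stage: str) -> "FeatureTable":
        if STAGES.index(stage) <= STAGES.index(self.stage):
            raise InvalidInputError(
                f"stage may only advance along {STAGES}; "
                f"{self.stage!r} -> {stage!r} is not allowed"
            )
        return FeatureTable(data, stage)


def map_num_to_zone(num: int, scheme: str = "three") -> str:
    """Severity 0–4 to a risk zone under the two- or three-level scheme."""
    if num not in CATEGORICAL_DOMAINS[TARGET_COLUMN]:
        raise InvalidInputError(f"num must be in 0..4, got {num!r}")
    if scheme == "three":
        return "green" if num == 0 else ("yellow" if num == 1 else "red")
    if scheme == "two":
        return "green" if num == 0 else "red"
    raise InvalidInputError(f"scheme must be 'two' or 'three', got {scheme!r}")


def add_zone_column(table: FeatureTable, scheme: str = "three") -> FeatureTable:
    """Attach the zone label derived from ``num`` (rows with missing num
    get a missing zone)."""
    if TARGET_COLUMN not in table.data.columns:
        raise InvalidInputError("table has no 'num' column to map")
    data = table.data.copy()
    data[ZONE_COLUMN] = [
        map_num_to_zone(int(v), scheme) if pd.notna(v) else np.nan
        for v in data[TARGET_COLUMN]
    ]
    return FeatureTable(data, table.stage)


# ---------------------------------------------------------------------------
# MICE
# ---------------------------------------------------------------------------

def mice_impute(
    table: FeatureTable,
    max_iter: int = 10,
    seed: int = 0,
    tol: float = 1e-3,
) -> FeatureTable:
    """Fill missing values by chained-equation imputation (single dataset).

    Each column with missing entries is iteratively regressed on the others
    until ``max_iter`` rounds or the imputations change by less than
    ``tol``; observed values are never altered and categorical columns are
    rounded/clamped back into their domains afterwards.
    """
    feature_cols = [c for c in table.data.columns if c != ZONE_COLUMN]
    data = table.data[feature_cols]
    entirely_missing = [c for c in feature_cols if data[c].isna().all()]
    if entirely_missing:
        raise ConfigurationError(
            f"column(s) with no observed values cannot be imputed: {entirely_missing}"
        )
    if not data.isna().any().any():
        return table._advance(table.data.copy(), "imputed")

    imputer = IterativeImputer(
        max_iter=max_iter, tol=tol, random_state=seed, sample_posterior=False,
        keep_empty_features=False,
    )
    filled = imputer.fit_transform(data.to_numpy(dtype=float))
    out = pd.DataFrame(filled, columns=feature_cols)
    for col, domain in CATEGORICAL_DOMAINS.items():
        if col in out.columns:
            dom = np.asarray(domain, dtype=float)
            vals = out[col].to_numpy()
            snapped = dom[np.argmin(np.abs(vals[:, None] - dom[None, :]), axis=1)]
            out[col] = snapped
    # observed entries pass through untouched
    out = out.where(data.isna(), data)
    if ZONE_COLUMN in table.data.columns:
        out[ZONE_COLUMN] = table.data[ZONE_COLUMN].to_numpy()
    return table._advance(out, "imputed")


# ---------------------------------------------------------------------------
# Robust scaling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScalerState:
    """Per-column median/IQR frozen at fit time; reusable on new records."""

    columns: tuple[str, ...]
    center: np.ndarray
    scale: np.ndarray

    def transform(self, records: pd.DataFrame) -> pd.DataFrame:
        out = records.copy()
        for i, c in enumerate(self.columns):
            out[c] = (records[c] - self.center[i]) / self.scale[i]
        return out

    def inverse_transform(self, records: pd.DataFrame) -> pd.DataFrame:
        out = records.copy()
        for i, c in enumerate(self.columns):
            out[c] = records[c] * self.scale[i] + self.center[i]
        return out


def robust_scale(
    table: FeatureTable, continuous_cols=None
) -> tuple[FeatureTable, ScalerState]:
    """Center continuous columns by the median and scale by the IQR.

    Post-condition: each scaled column has median 0 and IQR 1 exactly.  A
    zero-IQR column is centered only (scale 1) with a warning.
    """
    cols = tuple(continuous_cols) if continuous_cols is not None else tuple(
        c for c in CONTINUOUS_COLUMNS if c in table.data.columns
    )
    missing = [c for c in cols if table.data[c].isna().any()]
    if missing:
        raise InvalidInputError(f"continuous column(s) contain missing values: {missing}")
    scaler = RobustScaler(with_centering=True, with_scaling=True)
    scaler.fit(table.data[list(cols)].to_numpy(dtype=float))
    scale = np.asarray(scaler.scale_, dtype=float)
    center = np.asarray(scaler.center_, dtype=float)
    degenerate = [c for c, s_raw in zip(cols, np.asarray(scaler.scale_)) if s_raw == 1.0
                  and float(np.subtract(*np.percentile(table.data[c], [75, 25]))) == 0.0]
    if degenerate:
        warnings.warn(
            f"zero IQR in column(s) {degenerate}; centering only", stacklevel=2
        )
    state = ScalerState(columns=cols, center=center, scale=scale)
    out = state.transform(table.data)
    return table._advance(out, "scaled"), state


# ---------------------------------------------------------------------------
# Categorical encoding
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EncoderState:
    """Fixed 0..K-1 codes per categorical column, invertible."""

    mappings: dict[str, dict[int, int]]

    def transform(self, records: pd.DataFrame) -> pd.DataFrame:
        out = records.copy()
        for col, mapping in self.mappings.items():
            if col not in records.columns:
                continue
            vals = records[col]
            for v in vals.dropna().unique():
                if int(v) not in mapping:
                    raise InvalidInputError(
                        f"unseen category {v!r} in column {col!r}"
                    )
            out[col] = vals.map(
                lambda v: mapping[int(v)] if pd.notna(v) else v
            ).astype(float)
        return out

    def inverse_transform(self, records: pd.DataFrame) -> pd.DataFrame:
        out = records.copy()
        for col, mapping in self.mappings.items():
            if col not in records.columns:
                continue
            inverse = {code: orig for orig, code in mapping.items()}
            out[col] = records[col].map(
                lambda v: inverse[int(v)] if pd.notna(v) else v
            ).astype(float)
        return out


def build_encoder() -> EncoderState:
    """Codes derived from the fixed attribute domains (e.g. cp 1..4 -> 0..3)."""
    mappings = {
        col: {orig: code for code, orig in enumerate(dom)}
        for col, dom in CATEGORICAL_DOMAINS.items()
        if col != TARGET_COLUMN
    }
    return EncoderState(mappings=mappings)


def encode_categoricals(table: FeatureTable) -> tuple[FeatureTable, EncoderState]:
    """Replace categorical values with 0..K-1 codes; invertible."""
    state = build_encoder()
    out = state.transform(table.data)
    return table._advance(out, "encoded"), state


# ---------------------------------------------------------------------------
# Oversampling and split
# ---------------------------------------------------------------------------

def _label_series(table: FeatureTable, label_col: str) -> pd.Series:
    if label_col not in table.data.columns:
        raise InvalidInputError(f"table has no label column {label_col!r}")
    labels = table.data[label_col]
    if labels.isna().any():
        raise InvalidInputError(f"label column {label_col!r} contains missing values")
    return labels


def oversample(
    table: FeatureTable, seed: int = 0, label_col: str = ZONE_COLUMN
) -> FeatureTable:
    """Duplicate minority-class records (with replacement) up to the
    majority count; originals are all retained."""
    labels = _label_series(table, label_col)
    counts = labels.value_counts()
    if len(counts) < 2:
        raise InvalidInputError("oversampling needs at least two classes")
    majority = int(counts.max())
    rng = np.random.default_rng(seed)
    parts = [table.data]
    for cls, cnt in counts.items():
        deficit = majority - int(cnt)
        if deficit > 0:
            pool = table.data.index[labels == cls].to_numpy()
            picks = rng.choice(pool, size=deficit, replace=True)
            parts.append(table.data.loc[picks])
    out = pd.concat(parts, ignore_index=True)
    if len(out) == len(table.data):
        out = table.data.copy()
    return table._advance(out, "oversampled")


def split_70_30(
    table: FeatureTable,
    seed: int = 0,
    stratified: bool = False,
    label_col: str = ZONE_COLUMN,
    train_fraction: float = 0.7,
) -> tuple[FeatureTable, FeatureTable]:
    """Disjoint train/test partition with |train| = round(0.7 n).

    Stratification keeps per-class proportions within one record of the
    global split fraction.
    """
    n = len(table)
    n_train = int(np.floor(train_fraction * n + 0.5))
    rng = np.random.default_rng(seed)
    if stratified:
        labels = _label_series(table, label_col)
        classes = labels.unique()
        if n < len(classes) or n_train < len(classes):
            raise InvalidInputError(
                "too few records to stratify over all classes"
            )
        takes = {}
        fracs = {}
        for cls in classes:
            n_c = int((labels == cls).sum())
            exact = train_fraction * n_c
            takes[cls] = int(np.floor(exact + 0.5))
            fracs[cls] = exact - np.floor(exact)
        # reconcile per-class half-up rounding with the global target size
        diff = n_train - sum(takes.values())
        order = sorted(classes, key=lambda c: fracs[c], reverse=(diff > 0))
        i = 0
        while diff != 0 and i < len(order):
            cls = order[i]
            step = 1 if diff > 0 else -1
            n_c = int((labels == cls).sum())
            if 0 <= takes[cls] + step <= n_c:
                takes[cls] += step
                diff -= step
            i += 1
        train_idx = []
        for cls in classes:
            pool = table.data.index[labels == cls].to_numpy()
            rng.shuffle(pool)
            train_idx.extend(pool[: takes[cls]])
        train_idx = np.sort(np.asarray(train_idx))
    else:
        perm = rng.permutation(n)
        train_idx = np.sort(perm[:n_train])
    mask = np.zeros(n, dtype=bool)
    mask[train_idx] = True
    train = FeatureTable(table.data[mask], table.stage)
    test = FeatureTable(table.data[~mask], table.stage)
    return train, test
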