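"""Data model for the four ISAAC Wheezing Module severity items.

The ISAAC-WM asks parents (or older children) about wheezing over the past
twelve months.  Four items carry the severity signal used here:

* ``episodes`` -- number of wheezing attacks (Never / 1-3 / 4-12 / 13+),
* ``sleep``    -- wheeze-related sleep disturbance (Never / <1 night per
  week / 1+ nights per week),
* ``speech``   -- wheeze severe enough to limit speech (Absent / Present),
* ``exercise`` -- wheezing during or after exercise (Absent / Present).

Categories are coded 0-based in ascending severity.  A second category
system covers the two-wave aggregation used for small cohorts assessed at
60 and 72 months, where each item is recoded to a single severity level
summarising both assessments (see :func:`recode_ehaas_two_wave`).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: integer code marking a missing item response
MISSING = -1

DEFAULT_MISSING_TOKENS = ("", "NA", "Missing")


@dataclass(frozen=True)
class OrdinalItemSpec:
    """An ordered-categorical item: labels in ascending severity, coded 0..c-1."""

    name: str
    categories: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.categories) < 2:
            raise ValueError(f"item {self.name!r} needs >= 2 categories")
        if len(set(self.categories)) != len(self.categories):
            raise ValueError(f"item {self.name!r} has duplicate category labels")

    @property
    def n_categories(self) -> int:
        return len(self.categories)

    def code(self, label: str) -> int:
        return self.categories.index(label)


# Annual (single-wave) item specs.
ISAAC_ITEMS: tuple[OrdinalItemSpec, ...] = (
    OrdinalItemSpec("episodes", ("Never", "1 to 3", "4 to 12", "13+")),
    OrdinalItemSpec("sleep", ("Never", "< 1 night/week", "1+ nights/week")),
    OrdinalItemSpec("speech", ("Absent", "Present")),
    OrdinalItemSpec("exercise", ("Absent", "Present")),
)

# Two-wave aggregated item specs (60- and 72-month assessments combined).
EHAAS_ITEMS: tuple[OrdinalItemSpec, ...] = (
    OrdinalItemSpec(
        "episodes", ("Very infrequent", "Infrequent", "Frequent", "Very frequent")
    ),
    OrdinalItemSpec("sleep", ("Never", "Infrequent", "Frequent")),
    OrdinalItemSpec("speech", ("Absent", "Present")),
    OrdinalItemSpec("exercise", ("Absent", "Present")),
)

ITEM_NAMES = tuple(s.name for s in ISAAC_ITEMS)


@dataclass
class ItemResponseTable:
    """Child-level coded responses: items, covariates, optional clusters/wave."""

    ids: np.ndarray  # opaque string identifiers, length n
    specs: dict[str, OrdinalItemSpec]
    codes: dict[str, np.ndarray]  # int arrays, MISSING == -1
    covariates: pd.DataFrame | None = None
    cluster_ids: pd.DataFrame | None = None  # columns like 'school', 'site'
    wave: str | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.ids)
        for name, arr in self.codes.items():
            if len(arr) != n:
                raise ValueError(f"column {name!r} length {len(arr)} != n {n}")
            spec = self.specs[name]
            obs = arr[arr != MISSING]
            if obs.size and (obs.min() < 0 or obs.max() >= spec.n_categories):
                raise ValueError(f"codes out of range for item {name!r}")
        if self.covariates is not None and len(self.covariates) != n:
            raise ValueError("covariate rows inconsistent with n")
        if self.cluster_ids is not None:
            if len(self.cluster_ids) != n:
                raise ValueError("cluster id rows inconsistent with n")
            for col in self.cluster_ids:
                if self.cluster_ids[col].isna().any():
                    raise ValueError(f"cluster column {col!r} has empty ids")
        if len(set(self.ids)) != n:
            raise ValueError("duplicate child identifier")

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def item_names(self) -> list[str]:
        return list(self.codes)

    def item_matrix(self, names: Sequence[str] | None = None) -> np.ndarray:
        names = list(names) if names is not None else self.item_names
        return np.column_stack([self.codes[k] for k in names])

    def category_counts(self, name: str) -> np.ndarray:
        spec = self.specs[name]
        arr = self.codes[name]
        return np.bincount(arr[arr != MISSING], minlength=spec.n_categories)


def load_item_table(
    path: str | Path,
    specs: Sequence[OrdinalItemSpec] = ISAAC_ITEMS,
    schema: Mapping[str, str] | None = None,
    *,
    id_column: str = "child_id",
    covariate_columns: Sequence[str] = (),
    cluster_columns: Sequence[str] = (),
    missing_tokens: Sequence[str] = DEFAULT_MISSING_TOKENS,
    wave: str | None = None,
) -> ItemResponseTable:
    """Read a child-level CSV and map category labels to 0-based codes.

    ``schema`` maps item name -> CSV column (defaults to the item name).
    Cells are mapped through each item's category labels; integer codes in
    range are also accepted.  Anything else must be a declared missing token.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    schema = dict(schema or {})
    missing = set(missing_tokens)

    def col_for(name: str) -> str:
        col = schema.get(name, name)
        if col not in df.columns:
            raise KeyError(f"column {col!r} for item {name!r} not in {path.name}")
        return col

    codes: dict[str, np.ndarray] = {}
    for spec in specs:
        col = col_for(spec.name)
        raw = df[col].to_numpy()
        out = np.full(len(raw), MISSING, dtype=np.int64)
        lut = {lab: k for k, lab in enumerate(spec.categories)}
        # accept pre-coded integers as well as labels
        for k in range(spec.n_categories):
            lut.setdefault(str(k), k)
        for i, cell in enumerate(raw):
            cell = cell.strip()
            if cell in lut:
                out[i] = lut[cell]
            elif cell in missing:
                out[i] = MISSING
            else:
                raise ValueError(
                    f"unknown category label {cell!r} in column {col!r}, row {i}"
                )
        codes[spec.name] = out

    if id_column in df.columns:
        ids = df[id_column].to_numpy()
    else:
        ids = np.array([f"c{i}" for i in range(len(df))])

    cov = None
    if covariate_columns:
        cov = df[list(covariate_columns)].apply(pd.to_numeric, errors="coerce")
        cov = cov.reset_index(drop=True)
    clusters = None
    if cluster_columns:
        clusters = df[list(cluster_columns)].reset_index(drop=True)

    return ItemResponseTable(
        ids=ids,
        specs={s.name: s for s in specs},
        codes=codes,
        covariates=cov,
        cluster_ids=clusters,
        wave=wave,
    )


def write_item_table(table: ItemResponseTable, path: str | Path) -> Path:
    """Write integer-coded responses to CSV with a sidecar JSON metadata file."""
    path = Path(path)
    out = {"child_id": table.ids}
    for name, arr in table.codes.items():
        out[name] = arr
    df = pd.DataFrame(out)
    if table.covariates is not None:
        df = pd.concat([df, table.covariates.reset_index(drop=True)], axis=1)
    if table.cluster_ids is not None:
        df = pd.concat([df, table.cluster_ids.reset_index(drop=True)], axis=1)
    df.to_csv(path, index=False)
    meta = {
        "items": {
            name: list(spec.categories) for name, spec in table.specs.items()
        },
        "missing_code": MISSING,
        "wave": table.wave,
        "covariates": list(table.covariates.columns) if table.covariates is not None else [],
        "clusters": list(table.cluster_ids.columns) if table.cluster_ids is not None else [],
    }
    meta_path = path.with_suffix(path.suffix + ".meta.json")
    meta_path.write_text(json.dumps(meta, indent=1))
    return path


def load_coded_table(path: str | Path) -> ItemResponseTable:
    """Reload a table written by :func:`write_item_table` (codes + sidecar)."""
    path = Path(path)
    meta = json.loads(path.with_suffix(path.suffix + ".meta.json").read_text())
    specs = [OrdinalItemSpec(n, tuple(c)) for n, c in meta["items"].items()]
    return load_item_table(
        path,
        specs=specs,
        covariate_columns=meta.get("covariates", ()),
        cluster_columns=meta.get("clusters", ()),
        missing_tokens=(str(MISSING), "", "NA"),
        wave=meta.get("wave"),
    )


# ---------------------------------------------------------------------------
# Two-wave aggregation (60- and 72-month assessments combined)
# ---------------------------------------------------------------------------

# (code@60, code@72) -> derived code; episodes coded Never=0,1-3=1,4-12=2,13+=3
_EPISODES_MAP: dict[tuple[int, int], int] = {
    (0, 1): 0, (1, 0): 0,
    (1, 1): 1, (0, 2): 1, (2, 0): 1,
    (1, 2): 2, (2, 1): 2, (0, 3): 2, (3, 0): 2,
    (2, 2): 3, (2, 3): 3, (3, 2): 3, (3, 3): 3,
}
# sleep coded Never=0, <1 night/week=1, 1+ nights/week=2
_SLEEP_MAP: dict[tuple[int, int], int] = {
    (0, 0): 0,
    (0, 1): 1, (1, 0): 1,
    (0, 2): 2, (2, 0): 2, (1, 1): 2, (1, 2): 2, (2, 1): 2, (2, 2): 2,
}


def recode_ehaas_two_wave(
    wave60: ItemResponseTable, wave72: ItemResponseTable
) -> ItemResponseTable:
    """Aggregate the four items across two assessment waves.

    Episode frequency and sleep disturbance follow the published two-wave
    rule set exactly (four and three derived levels); the binary items are
    scored Present if endorsed at either wave.  Wave pairs outside the rule
    set -- including children who wheezed in neither year -- are flagged and
    set missing: the analysis population is children who wheezed at some
    point during follow-up.
    """
    if list(wave60.ids) != list(wave72.ids):
        order = {cid: i for i, cid in enumerate(wave72.ids)}
        try:
            perm = np.array([order[cid] for cid in wave60.ids])
        except KeyError as e:
            raise ValueError(f"child {e.args[0]!r} missing from second wave") from None
        wave72 = ItemResponseTable(
            ids=wave72.ids[perm],
            specs=wave72.specs,
            codes={k: v[perm] for k, v in wave72.codes.items()},
            covariates=None if wave72.covariates is None
            else wave72.covariates.iloc[perm].reset_index(drop=True),
            wave=wave72.wave,
        )
    n = wave60.n
    flagged: dict[str, int] = {}

    def combine(name: str, mapping: dict[tuple[int, int], int]) -> np.ndarray:
        a, b = wave60.codes[name], wave72.codes[name]
        out = np.full(n, MISSING, dtype=np.int64)
        bad = 0
        for i in range(n):
            if a[i] == MISSING or b[i] == MISSING:
                continue
            key = (int(a[i]), int(b[i]))
            if key in mapping:
                out[i] = mapping[key]
            else:
                bad += 1
        flagged[name] = bad
        return out

    codes = {
        "episodes": combine("episodes", _EPISODES_MAP),
        "sleep": combine("sleep", _SLEEP_MAP),
    }
    for name in ("speech", "exercise"):
        a, b = wave60.codes[name], wave72.codes[name]
        out = np.full(n, MISSING, dtype=np.int64)
        either = (a == 1) | (b == 1)
        both0 = (a == 0) & (b == 0)
        out[either] = 1
        out[both0] = 0
        codes[name] = out
        flagged[name] = 0

    total_bad = sum(flagged.values())
    if total_bad:
        log.warning("two-wave recode: %d wave-pairs outside rule set set missing", total_bad)
    return ItemResponseTable(
        ids=wave60.ids.copy(),
        specs={s.name: s for s in EHAAS_ITEMS},
        codes=codes,
        covariates=wave60.covariates,
        wave="60-72m",
        meta={"uncovered_pairs": flagged},
    )


# ---------------------------------------------------------------------------
# Discrete severity comparator
# ---------------------------------------------------------------------------

def discrete_severity_count(
    table_or_codes: ItemResponseTable | np.ndarray,
    *,
    require_complete: bool = True,
) -> np.ndarray:
    """Number of the four items endorsed to any degree (0..4), -1 if missing.

    An item is endorsed when its code exceeds the lowest category.  With
    ``require_complete`` (default) the score is missing whenever any item is
    missing -- an endorsement count over partial items is not comparable
    across children.  ``require_complete=False`` counts observed items only,
    for sensitivity analyses.
    """
    if isinstance(table_or_codes, ItemResponseTable):
        Y = table_or_codes.item_matrix(ITEM_NAMES)
    else:
        Y = np.atleast_2d(np.asarray(table_or_codes, dtype=np.int64))
    if Y.shape[1] != 4:
        raise ValueError("expected four item columns")
    endorsed = (Y > 0).sum(axis=1)
    anymiss = (Y == MISSING).any(axis=1)
    out = endorsed.astype(np.int64)
    if require_complete:
        out[anymiss] = MISSING
    else:
        allmiss = (Y == MISSING).all(axis=1)
        out[allmiss] = MISSING
    return out


# ---------------------------------------------------------------------------
# Covariate design matrices
# ---------------------------------------------------------------------------

@dataclass
class DesignMatrix:
    """Dummy-coded covariate matrix (reference levels excluded)."""

    names: list[str]
    X: np.ndarray  # n x q
    coding: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2 or self.X.shape[1] != len(self.names):
            raise ValueError("design matrix shape inconsistent with names")

    @property
    def q(self) -> int:
        return len(self.names)

    def median_profile(self) -> np.ndarray:
        """Per-column median; for 0/1 dummies this is the modal value."""
        return np.median(self.X, axis=0)


# Canonical covariate column names expected in ItemResponseTable.covariates.
# Each dummy is 1 for the named non-reference state.
_FULL_COLUMNS = [
    ("maternal_asthma", "present vs absent"),
    ("prenatal_smoking", "any vs none"),
    ("single_mother", "single vs married"),
    ("medicaid", "Medicaid vs private insurance"),
    ("cesarean", "cesarean vs vaginal birth"),
    ("female", "female vs male"),
    ("race_black", "African American vs white (reference)"),
    ("race_other", "all other race groups vs white (reference)"),
]

SCHEMES: dict[str, list[str]] = {
    # seven risk factors; race enters as two dummies against a white reference
    "cohort1_full": [c for c, _ in _FULL_COLUMNS],
    # the same scheme without child sex, for sex-grouped invariance models
    "cohort1_nosex": [c for c, _ in _FULL_COLUMNS if c != "female"],
    "cohort3": ["female", "race_nonwhite"],
}


def encode_covariates(
    table: ItemResponseTable,
    scheme: str | Sequence[str] = "cohort1_full",
) -> DesignMatrix:
    """Build the dummy-coded design matrix for a named covariate scheme.

    Covariates are read from ``table.covariates`` and must already be 0/1
    indicators under the canonical column names; a sequence of column names
    acts as a custom scheme.
    """
    if isinstance(scheme, str):
        if scheme not in SCHEMES:
            raise KeyError(f"unknown covariate scheme {scheme!r}")
        columns = SCHEMES[scheme]
    else:
        columns = list(scheme)
    if table.covariates is None:
        raise ValueError("table has no covariates")
    missing = [c for c in columns if c not in table.covariates.columns]
    if missing:
        raise KeyError(f"covariate columns absent: {missing}")
    X = table.covariates[columns].to_numpy(dtype=float)
    bad = [
        c for j, c in enumerate(columns)
        if not np.isin(X[:, j][~np.isnan(X[:, j])], (0.0, 1.0)).all()
    ]
    if bad:
        raise ValueError(f"non-binary level in dummy columns: {bad}")
    coding = dict(_FULL_COLUMNS)
    return DesignMatrix(names=columns, X=X, coding={c: coding.get(c, "") for c in columns})
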