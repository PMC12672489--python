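"""Readers, writers and validated containers for soil-indicator and stand tables.

All tabular interchange is plain CSV (comma separated, UTF-8, ``.`` decimal,
mandatory header row).  Missing cells are rejected rather than imputed: the
downstream soil-quality pipeline assumes complete cases.

The module also ships a packaged fixture of the published six-component
loading matrix for the 20-indicator total data set (eigenvalues, norm values,
communalities, group labels) together with the pairwise correlation
statements needed to replay the minimum-data-set selection.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

MORE_IS_BETTER = "more_is_better"
LESS_IS_BETTER = "less_is_better"

#: The 20 indicators of the total data set, in published table order.
TDS_INDICATORS: tuple[str, ...] = (
    "SM", "BD", "TN", "TP", "SOC", "MBC", "NH4", "NO3", "MBN", "MBP",
    "AP", "POD", "LAP", "BX", "ALP", "URE", "CBH", "NAG", "ACP", "BG",
)

_ID_COLUMNS = ("sample_id", "pattern_id", "plot_id")


class TableValidationError(ValueError):
    """Raised when a table fails a structural or numeric validity check."""


@dataclass(frozen=True)
class IndicatorSpec:
    """Declaration of one soil indicator: short name, unit, scoring direction.

    ``orientation`` is ``"more_is_better"`` for indicators whose larger values
    indicate better soil function (the usual case) or ``"less_is_better"``
    (bulk density).
    """

    name: str
    unit: str = ""
    orientation: str = MORE_IS_BETTER

    def __post_init__(self) -> None:
        if self.orientation not in (MORE_IS_BETTER, LESS_IS_BETTER):
            raise ValueError(
                f"orientation of {self.name!r} must be "
                f"{MORE_IS_BETTER!r} or {LESS_IS_BETTER!r}, got {self.orientation!r}"
            )


def default_indicator_specs(names: Sequence[str] = TDS_INDICATORS) -> list[IndicatorSpec]:
    """Specs for the standard total data set: everything is more-is-better
    except bulk density (BD)."""
    return [
        IndicatorSpec(n, orientation=LESS_IS_BETTER if n == "BD" else MORE_IS_BETTER)
        for n in names
    ]


@dataclass
class IndicatorTable:
    """Validated samples x indicators table with plot/pattern metadata.

    ``data`` holds the columns ``sample_id``, ``pattern_id``, ``plot_id``
    followed by one numeric column per declared indicator, in declared order.
    """

    specs: list[IndicatorSpec]
    data: pd.DataFrame

    def __post_init__(self) -> None:
        self.data = _validate_indicator_frame(self.data, self.specs)

    @property
    def indicator_names(self) -> list[str]:
        return [s.name for s in self.specs]

    @property
    def n_samples(self) -> int:
        return len(self.data)

    @property
    def values(self) -> pd.DataFrame:
        """Indicator columns only, indexed by sample_id, in declared order."""
        return self.data.set_index("sample_id")[self.indicator_names]

    @property
    def patterns(self) -> pd.Series:
        return self.data.set_index("sample_id")["pattern_id"]

    @property
    def plots(self) -> pd.Series:
        return self.data.set_index("sample_id")["plot_id"]

    def orientation_of(self, name: str) -> str:
        for s in self.specs:
            if s.name == name:
                return s.orientation
        raise KeyError(name)

    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False)


def _validate_indicator_frame(df: pd.DataFrame, specs: Sequence[IndicatorSpec]) -> pd.DataFrame:
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise TableValidationError(f"duplicate indicator names in specs: {dupes}")
    for col in _ID_COLUMNS:
        if col not in df.columns:
            raise TableValidationError(f"missing required column {col!r}")
    missing = [n for n in names if n not in df.columns]
    if missing:
        raise TableValidationError(f"missing indicator column(s): {missing}")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise TableValidationError(f"duplicate sample_id {dup!r}")
    out = df.loc[:, list(_ID_COLUMNS) + names].copy()
    for name in names:
        col = pd.to_numeric(out[name], errors="coerce")
        bad = col.isna() | ~np.isfinite(col)
        if bad.any():
            row = out.loc[bad, "sample_id"].iloc[0]
            raise TableValidationError(
                f"non-numeric or non-finite value in column {name!r} at sample {row!r}"
            )
        if (col < 0).any():
            row = out.loc[col < 0, "sample_id"].iloc[0]
            raise TableValidationError(
                f"negative value in column {name!r} at sample {row!r}; "
                "soil concentrations/activities must be non-negative"
            )
        out[name] = col.astype(float)
    out = out.reset_index(drop=True)
    return out


def read_indicator_table(path: str | Path, specs: Sequence[IndicatorSpec]) -> IndicatorTable:
    """Read and validate a soil-indicator CSV against the declared specs."""
    df = pd.read_csv(path)
    return IndicatorTable(list(specs), df)


def write_indicator_table(table: IndicatorTable, path: str | Path) -> None:
    table.to_csv(path)


# ---------------------------------------------------------------------------
# Tree inventories, plot metadata, allometric coefficients
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TreeRecord:
    plot_id: str
    species: str
    is_broadleaf: bool
    dbh: float  # cm
    height: float  # m

    def __post_init__(self) -> None:
        if not self.dbh > 0:
            raise TableValidationError(f"tree in plot {self.plot_id!r}: dbh must be > 0")
        if not self.height > 0:
            raise TableValidationError(f"tree in plot {self.plot_id!r}: height must be > 0")


@dataclass
class TreeInventory:
    """Collection of tree records, DataFrame-backed."""

    data: pd.DataFrame

    _COLS = ("plot_id", "species", "is_broadleaf", "dbh", "height")

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in self._COLS if c not in df.columns]
        if missing:
            raise TableValidationError(f"inventory missing column(s): {missing}")
        df = df.loc[:, list(self._COLS)].copy()
        for col in ("dbh", "height"):
            vals = pd.to_numeric(df[col], errors="coerce")
            if vals.isna().any() or not np.isfinite(vals).all():
                raise TableValidationError(f"non-numeric value in inventory column {col!r}")
            if (vals <= 0).any():
                bad_plot = df.loc[vals <= 0, "plot_id"].iloc[0]
                raise TableValidationError(
                    f"non-positive {col} in plot {bad_plot!r}: dbh and height must be > 0"
                )
            df[col] = vals.astype(float)
        df["is_broadleaf"] = df["is_broadleaf"].map(_to_bool)
        self.data = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def records(self) -> list[TreeRecord]:
        return [
            TreeRecord(r.plot_id, r.species, bool(r.is_broadleaf), r.dbh, r.height)
            for r in self.data.itertuples(index=False)
        ]

    def for_plot(self, plot_id: str) -> "TreeInventory":
        return TreeInventory(self.data[self.data["plot_id"] == plot_id])

    @property
    def plot_ids(self) -> list[str]:
        return list(dict.fromkeys(self.data["plot_id"]))

    def species_missing_coefs(self, coefs: Mapping[str, "AllometricCoef"]) -> list[str]:
        return sorted(set(self.data["species"]) - set(coefs))

    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False)


def _to_bool(x) -> bool:
    if isinstance(x, (bool, np.bool_)):
        return bool(x)
    if isinstance(x, str):
        s = x.strip().lower()
        if s in ("true", "1", "yes", "y"):
            return True
        if s in ("false", "0", "no", "n"):
            return False
        raise TableValidationError(f"cannot interpret {x!r} as boolean")
    return bool(int(x))


@dataclass(frozen=True)
class PlotMeta:
    plot_id: str
    pattern_id: str
    area: float = 600.0  # m^2; study plots are 20 m x 30 m
    stand_age: float = 20.0  # years since the 2003 logging event

    def __post_init__(self) -> None:
        if not self.area > 0:
            raise TableValidationError(f"plot {self.plot_id!r}: area must be > 0")
        if not self.stand_age > 0:
            raise TableValidationError(f"plot {self.plot_id!r}: stand_age must be > 0")


@dataclass(frozen=True)
class AllometricCoef:
    """Coefficients of the power-law biomass model W = a (D^2 H)^b."""

    species: str
    a: float
    b: float

    def __post_init__(self) -> None:
        if not self.a > 0:
            raise TableValidationError(f"species {self.species!r}: coefficient a must be > 0")


def read_tree_inventory(path: str | Path) -> TreeInventory:
    return TreeInventory(pd.read_csv(path))


def read_plot_meta(path: str | Path) -> list[PlotMeta]:
    df = pd.read_csv(path)
    required = {"plot_id", "pattern_id"}
    missing = required - set(df.columns)
    if missing:
        raise TableValidationError(f"plot-meta missing column(s): {sorted(missing)}")
    metas = []
    for r in df.itertuples(index=False):
        kwargs = {}
        if "area" in df.columns:
            kwargs["area"] = float(r.area)
        if "stand_age" in df.columns:
            kwargs["stand_age"] = float(r.stand_age)
        metas.append(PlotMeta(str(r.plot_id), str(r.pattern_id), **kwargs))
    return metas


def read_allometric_coefs(path: str | Path) -> dict[str, AllometricCoef]:
    df = pd.read_csv(path)
    missing = {"species", "a", "b"} - set(df.columns)
    if missing:
        raise TableValidationError(f"coefficient table missing column(s): {sorted(missing)}")
    coefs: dict[str, AllometricCoef] = {}
    for r in df.itertuples(index=False):
        coefs[str(r.species)] = AllometricCoef(str(r.species), float(r.a), float(r.b))
    return coefs


def write_allometric_coefs(coefs: Mapping[str, AllometricCoef], path: str | Path) -> None:
    pd.DataFrame(
        [{"species": c.species, "a": c.a, "b": c.b} for c in coefs.values()]
    ).to_csv(path, index=False)


def write_plot_meta(metas: Iterable[PlotMeta], path: str | Path) -> None:
    pd.DataFrame(
        [
            {"plot_id": m.plot_id, "pattern_id": m.pattern_id, "area": m.area,
             "stand_age": m.stand_age}
            for m in metas
        ]
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Packaged published-table fixture
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CorrelationFact:
    """One pairwise Pearson-correlation statement: r (when printed) and
    whether the pair was reported as significant at p < 0.05."""

    pair: frozenset
    r: float | None
    significant: bool
    source: str = "stated"


@dataclass
class PublishedPCATable:
    """The published 20 x 6 loading matrix with eigenvalues, printed norm
    values, communalities, group labels and the in-text correlation facts."""

    indicators: list[str]
    loadings: pd.DataFrame          # 20 x 6, columns PC1..PC6
    eigenvalues: np.ndarray         # length 6
    contribution_rate: np.ndarray   # printed, %
    cumulative_rate: np.ndarray     # printed, %
    norms: pd.Series                # printed norm values
    communalities: pd.Series        # printed communality values
    groups: pd.Series               # printed group labels (1-based)
    correlation_facts: list[CorrelationFact] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.loadings.shape[1] != 6 or len(self.eigenvalues) != 6:
            raise TableValidationError("fixture must have exactly 6 components")
        if not (self.eigenvalues >= 1).all():
            raise TableValidationError("all fixture eigenvalues must be >= 1")
        lo = self.loadings.to_numpy()
        if not ((lo >= -1) & (lo <= 1)).all():
            raise TableValidationError("fixture loadings must lie in [-1, 1]")

    def correlation_lookup(self) -> dict[frozenset, tuple[float | None, bool]]:
        return {f.pair: (f.r, f.significant) for f in self.correlation_facts}


def load_published_pca_table() -> PublishedPCATable:
    """Load the packaged published-table fixture exactly as printed."""
    try:
        raw = json.loads(
            resources.files("soilqualkit").joinpath("data/published_pca_table.json").read_text("utf-8")
        )
        names = [row["name"] for row in raw["indicators"]]
        loadings = pd.DataFrame(
            [row["loadings"] for row in raw["indicators"]],
            index=names, columns=raw["components"], dtype=float,
        )
        fixture = PublishedPCATable(
            indicators=names,
            loadings=loadings,
            eigenvalues=np.asarray(raw["eigenvalues"], dtype=float),
            contribution_rate=np.asarray(raw["contribution_rate"], dtype=float),
            cumulative_rate=np.asarray(raw["cumulative_rate"], dtype=float),
            norms=pd.Series({row["name"]: row["norm"] for row in raw["indicators"]}, dtype=float),
            communalities=pd.Series(
                {row["name"]: row["communality"] for row in raw["indicators"]}, dtype=float
            ),
            groups=pd.Series({row["name"]: int(row["group"]) for row in raw["indicators"]}),
            correlation_facts=[
                CorrelationFact(
                    pair=frozenset(f["pair"]),
                    r=None if f["r"] is None else float(f["r"]),
                    significant=bool(f["significant"]),
                    source=f.get("source", "stated"),
                )
                for f in raw["correlation_facts"]
            ],
        )
    except (KeyError, ValueError, TypeError, json.JSONDecodeError) as exc:
        raise TableValidationError(f"packaged fixture is corrupted: {exc}") from exc
    return fixture


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

def load_run_config(path: str | Path) -> dict:
    """Load a JSON run configuration.

    Recognised keys (all optional): ``indicators`` (list of
    ``{name, unit, orientation}``), ``orientation_overrides`` (name -> value),
    ``stand_age``, ``plot_area``, ``seed``.
    """
    with open(path, encoding="utf-8") as fh:
        cfg = json.load(fh)
    if not isinstance(cfg, dict):
        raise TableValidationError("run configuration must be a JSON object")
    return cfg


def specs_from_config(cfg: Mapping) -> list[IndicatorSpec]:
    if "indicators" in cfg:
        specs = [
            IndicatorSpec(
                d["name"], d.get("unit", ""), d.get("orientation", MORE_IS_BETTER)
            )
            for d in cfg["indicators"]
        ]
    else:
        specs = default_indicator_specs()
    overrides = cfg.get("orientation_overrides", {})
    if overrides:
        specs = [
            IndicatorSpec(s.name, s.unit, overrides.get(s.name, s.orientation))
            for s in specs
        ]
    return specs
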