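"""Synthetic soil-indicator tables and stand inventories.

The soil generator draws samples from a latent factor model
``x = shift + Lambda f + eps`` with standard-normal factors and diagonal
Gaussian noise, then maps each indicator affinely onto a positive measurement
scale (mean = a typical field value, coefficient of variation ~20%).  Affine
mapping preserves the designed correlation structure ``Lambda Lambda' + Psi``
exactly, which the pipeline's PCA consumes; values are floored at 1% of the
indicator mean so scoring stays defined (the floor binds with probability
~3e-7 per cell at the default scale).

The default design mirrors the study layout: 20 indicators in six correlated
blocks, 10 planting patterns x 3 plot-level samples.  The stand generator
draws lognormal DBH, a power-law height-diameter relation with lognormal
noise, and Bernoulli broadleaf labels.

All generators are deterministic given (spec, seed); seeds are mandatory in
the specs and no global random state is touched.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .tables import (
    AllometricCoef,
    IndicatorSpec,
    IndicatorTable,
    LESS_IS_BETTER,
    MORE_IS_BETTER,
    PlotMeta,
    TreeInventory,
    default_indicator_specs,
)

__all__ = [
    "FactorModelSpec", "StandSimSpec", "generate_indicator_table",
    "generate_inventory", "generate_quality_gradient",
    "default_factor_spec", "three_factor_spec", "published_loading_matrix",
    "DEFAULT_LOADING_PLAN", "TYPICAL_MEANS", "DEFAULT_ALLOMETRIC_COEFS",
]

#: Typical plot-level means used as positive measurement scales
#: (units as in the field tables: %, g cm^-3, g kg^-1, ug g^-1, mg kg^-1,
#: umol d^-1 g^-1 as appropriate per indicator).
TYPICAL_MEANS: dict[str, float] = {
    "SM": 29.8, "BD": 1.27, "TN": 1.62, "TP": 0.38, "SOC": 23.3,
    "MBC": 1109.0, "NH4": 3.99, "NO3": 0.68, "MBN": 60.8, "MBP": 2.33,
    "AP": 0.57, "POD": 38.2, "LAP": 11.2, "BX": 8.15, "ALP": 11.6,
    "URE": 233.7, "CBH": 22.1, "NAG": 34.3, "ACP": 17.3, "BG": 78.9,
}

#: Six-block loading plan mirroring the published grouping of the 20-indicator
#: total data set (primary loadings taken at the published magnitudes).
DEFAULT_LOADING_PLAN: dict[int, tuple[tuple[str, float], ...]] = {
    1: (("SM", 0.60), ("BD", -0.55), ("TN", 0.85), ("SOC", 0.85),
        ("MBC", 0.85), ("MBN", 0.85), ("MBP", 0.73), ("AP", 0.55),
        ("LAP", 0.57), ("ALP", 0.90), ("URE", 0.58)),
    2: (("NO3", 0.61), ("CBH", -0.65), ("ACP", 0.47), ("BG", 0.51)),
    3: (("NH4", 0.69),),
    4: (("POD", -0.62), ("BX", 0.67)),
    5: (("NAG", 0.56),),
    6: (("TP", 0.63),),
}

DEFAULT_PATTERNS: tuple[str, ...] = (
    "ML", "MM", "MME", "CP", "CH", "CB", "LF", "MC", "SS", "MO",
)


@dataclass(frozen=True)
class FactorModelSpec:
    """Latent factor design for a synthetic soil-indicator table.

    The factor loadings come either from ``loading_plan`` (factor ->
    (indicator, primary loading) pairs, zero cross-loadings) or, when given,
    from ``loading_matrix`` (a full indicators x factors frame; each
    indicator's designed factor is the column where it loads strongest).
    ``pattern_shifts`` give a per-pattern mean shift in latent sd units,
    applied to more-is-better indicators (degraded-vs-improved soil moves
    every beneficial indicator together).  ``uniqueness_sd`` defaults to
    sqrt(1 - sum of squared loadings) so each latent indicator has unit
    variance.
    """

    loading_plan: Mapping[int, Sequence[tuple[str, float]]] = field(
        default_factory=lambda: DEFAULT_LOADING_PLAN
    )
    loading_matrix: pd.DataFrame | None = None
    pattern_shifts: Mapping[str, float] = field(
        default_factory=lambda: {p: 0.0 for p in DEFAULT_PATTERNS}
    )
    samples_per_pattern: int = 3
    uniqueness_sd: Mapping[str, float] | None = None
    base_means: Mapping[str, float] | None = None
    cv: float = 0.2
    orientations: Mapping[str, str] | None = None
    seed: int = 0

    def _lambda(self) -> pd.DataFrame:
        """Loading matrix, indicators x factors (factor columns 1-based)."""
        if self.loading_matrix is not None:
            out = self.loading_matrix.astype(float).copy()
            out.columns = range(1, out.shape[1] + 1)
            return out
        names = []
        for f in sorted(self.loading_plan):
            names.extend(n for n, _ in self.loading_plan[f])
        if len(set(names)) != len(names):
            raise ValueError("an indicator appears under more than one factor")
        factors = sorted(self.loading_plan)
        out = pd.DataFrame(0.0, index=names, columns=factors)
        for f in factors:
            for name, lam in self.loading_plan[f]:
                out.loc[name, f] = lam
        return out

    def indicator_names(self) -> list[str]:
        return list(self._lambda().index)

    def n_factors(self) -> int:
        return self._lambda().shape[1]

    def factor_of(self) -> dict[str, int]:
        """Designed factor per indicator: column of largest |loading|."""
        lam = self._lambda()
        idx = np.argmax(np.abs(lam.to_numpy()), axis=1)
        return {name: int(lam.columns[j]) for name, j in zip(lam.index, idx)}

    def _psi_series(self) -> pd.Series:
        lam = self._lambda()
        default = np.sqrt(np.clip(1.0 - (lam ** 2).sum(axis=1), 0.0, None))
        if self.uniqueness_sd is not None:
            for name, sd in self.uniqueness_sd.items():
                default[name] = float(sd)
        return default

    def validate(self) -> None:
        psi = self._psi_series()
        bad = psi[psi <= 0]
        if len(bad):
            raise ValueError(
                "implied covariance not positive definite; indicators with "
                f"non-positive uniqueness sd: {list(bad.index)}"
            )
        if self.samples_per_pattern < 1:
            raise ValueError("samples_per_pattern must be >= 1")
        if not self.cv > 0:
            raise ValueError("cv must be > 0")


def published_loading_matrix() -> pd.DataFrame:
    """The published 20 x 6 loading matrix, used as the default synthetic
    factor structure (communalities stay below 1, so uniqueness is positive)."""
    from .tables import load_published_pca_table

    return load_published_pca_table().loadings.copy()


def default_factor_spec(
    samples_per_pattern: int = 3, seed: int = 0, **kwargs
) -> FactorModelSpec:
    """The study-like design: the published 20 x 6 loading structure,
    10 planting patterns, ``samples_per_pattern`` plot-level samples each."""
    kwargs.setdefault("loading_matrix", published_loading_matrix())
    return FactorModelSpec(
        samples_per_pattern=samples_per_pattern, seed=seed, **kwargs
    )


def three_factor_spec(
    samples_per_pattern: int = 30,
    loading: float = 0.8,
    seed: int = 0,
    n_patterns: int = 1,
) -> FactorModelSpec:
    """Small 9-indicator, 3-factor design (3 indicators per factor) used for
    parameter-recovery checks."""
    plan = {
        1: tuple((f"A{i}", loading) for i in range(1, 4)),
        2: tuple((f"B{i}", loading) for i in range(1, 4)),
        3: tuple((f"C{i}", loading) for i in range(1, 4)),
    }
    base = {n: 10.0 for f in plan.values() for n, _ in f}
    patterns = {f"P{i + 1}": 0.0 for i in range(n_patterns)}
    return FactorModelSpec(
        loading_plan=plan,
        pattern_shifts=patterns,
        samples_per_pattern=samples_per_pattern,
        base_means=base,
        seed=seed,
    )


def _spec_tables(spec: FactorModelSpec):
    lam_df = spec._lambda()
    names = list(lam_df.index)
    lam = lam_df.to_numpy()
    psi = spec._psi_series().to_numpy()
    total_sd = np.sqrt((lam ** 2).sum(axis=1) + psi ** 2)
    return names, lam, psi, total_sd


def _orientation_map(spec: FactorModelSpec, names: Sequence[str]) -> dict[str, str]:
    out = {n: LESS_IS_BETTER if n == "BD" else MORE_IS_BETTER for n in names}
    if spec.orientations:
        out.update(spec.orientations)
    return out


def generate_indicator_table(spec: FactorModelSpec) -> IndicatorTable:
    """Draw a validated indicator table from the latent factor design."""
    spec.validate()
    names, lam, psi, total_sd = _spec_tables(spec)
    orientations = _orientation_map(spec, names)
    base = dict(TYPICAL_MEANS)
    if spec.base_means:
        base.update(spec.base_means)
    missing = [n for n in names if n not in base]
    if missing:
        raise ValueError(f"no base mean for indicator(s): {missing}")
    rng = np.random.default_rng(spec.seed)

    rows = []
    for pattern in spec.pattern_shifts:
        shift = float(spec.pattern_shifts[pattern])
        for j in range(spec.samples_per_pattern):
            f = rng.standard_normal(lam.shape[1])
            eps = rng.standard_normal(len(names)) * psi
            z = (lam @ f + eps) / total_sd  # unit-sd latent per indicator
            row = {}
            for i, name in enumerate(names):
                zi = z[i] + (shift if orientations[name] == MORE_IS_BETTER else 0.0)
                value = base[name] * (1.0 + spec.cv * zi)
                row[name] = max(value, 0.01 * base[name])
            plot = f"{pattern}_plot{(j % 3) + 1}"
            rows.append(
                {"sample_id": f"{pattern}_s{j + 1}", "pattern_id": pattern,
                 "plot_id": plot, **row}
            )
    specs = [
        IndicatorSpec(n, orientation=orientations[n]) for n in names
    ]
    return IndicatorTable(specs, pd.DataFrame(rows))


def generate_quality_gradient(
    base: FactorModelSpec, gradient: Sequence[float]
) -> IndicatorTable:
    """Table whose patterns follow a designed soil-quality ordering.

    ``gradient`` lists one mean shift (latent sd units, applied to
    more-is-better indicators) per pattern; shifts must be monotone so the
    designed ordering is a usable ground truth.
    """
    g = list(map(float, gradient))
    diffs = np.diff(g)
    if len(g) >= 2 and not ((diffs >= 0).all() or (diffs <= 0).all()):
        raise ValueError("gradient shifts must be monotone across patterns")
    shifts = {f"Q{i + 1}": s for i, s in enumerate(g)}
    return generate_indicator_table(replace(base, pattern_shifts=shifts))


# ---------------------------------------------------------------------------
# Stand inventories
# ---------------------------------------------------------------------------

DEFAULT_ALLOMETRIC_COEFS: dict[str, AllometricCoef] = {
    "chinese_fir": AllometricCoef("chinese_fir", 0.0581, 0.894),
    "schima_superba": AllometricCoef("schima_superba", 0.0719, 0.885),
}


@dataclass(frozen=True)
class StandSimSpec:
    """One planting pattern's stand simulation.

    DBH ~ lognormal(mu, sigma); height H = c D^d x lognormal(0, noise);
    broadleaf labels ~ Bernoulli(fraction).  Defaults give a ~20-year-old
    subtropical mixed stand: median DBH 15 cm, ~100 stems per 600 m^2 plot
    (about 1670 per hectare, inside the reported 675-3450 range).
    """

    pattern_id: str = "MIX"
    n_trees: int = 100            # per plot
    n_plots: int = 3
    dbh_mu: float = math.log(15.0)
    dbh_sigma: float = 0.3
    height_coef: float = 1.5      # c in H = c D^d
    height_exp: float = 0.8       # d
    height_noise_sd: float = 0.1  # lognormal sd on H
    broadleaf_fraction: float = 0.5
    conifer_species: str = "chinese_fir"
    broadleaf_species: str = "schima_superba"
    plot_area: float = 600.0      # m^2 (20 m x 30 m)
    stand_age: float = 20.0       # years
    seed: int = 0

    def validate(self) -> None:
        if self.n_trees < 2:
            raise ValueError("n_trees must be >= 2 (structural metrics undefined)")
        if self.n_plots < 1:
            raise ValueError("n_plots must be >= 1")
        for name in ("height_coef", "plot_area", "stand_age"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        if self.dbh_sigma < 0 or self.height_noise_sd < 0:
            raise ValueError("scale parameters must be >= 0")
        if not 0.0 <= self.broadleaf_fraction <= 1.0:
            raise ValueError("broadleaf_fraction must lie in [0, 1]")


def generate_inventory(
    spec: StandSimSpec,
) -> tuple[TreeInventory, list[PlotMeta], dict[str, AllometricCoef]]:
    """Simulate the pattern's plots: inventory, plot metadata, coefficients."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    rows = []
    metas = []
    for p in range(spec.n_plots):
        plot_id = f"{spec.pattern_id}_plot{p + 1}"
        metas.append(
            PlotMeta(plot_id, spec.pattern_id, spec.plot_area, spec.stand_age)
        )
        dbh = np.exp(spec.dbh_mu + spec.dbh_sigma * rng.standard_normal(spec.n_trees))
        noise = np.exp(spec.height_noise_sd * rng.standard_normal(spec.n_trees))
        height = spec.height_coef * dbh ** spec.height_exp * noise
        broadleaf = rng.random(spec.n_trees) < spec.broadleaf_fraction
        for i in range(spec.n_trees):
            rows.append(
                {
                    "plot_id": plot_id,
                    "species": spec.broadleaf_species if broadleaf[i]
                    else spec.conifer_species,
                    "is_broadleaf": bool(broadleaf[i]),
                    "dbh": float(dbh[i]),
                    "height": float(height[i]),
                }
            )
    coefs = {
        spec.conifer_species: DEFAULT_ALLOMETRIC_COEFS.get(
            spec.conifer_species, AllometricCoef(spec.conifer_species, 0.06, 0.89)
        ),
        spec.broadleaf_species: DEFAULT_ALLOMETRIC_COEFS.get(
            spec.broadleaf_species, AllometricCoef(spec.broadleaf_species, 0.07, 0.89)
        ),
    }
    return TreeInventory(pd.DataFrame(rows)), metas, coefs
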