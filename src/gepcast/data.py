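"""Dataset schema, CSV I/O, normalization, splitting and simulation.

One row per year: mean temperature and rainfall for January, February,
March (overwintering / emergence months) and July, August, September
(oviposition months of the preceding generation), annual accumulated
temperature, annual total precipitation, and an ordinal outbreak level
in {1, 2, 3} (1 = no infested fields recorded, 3 = widespread
infestation).

The synthetic generator emulates the documented climate-outbreak
structure for wheat blossom midge in central Shaanxi: outbreak severity
is *negatively* associated with January-March temperature (cold winters
favor larval survival in diapause) and *positively* associated with
July-September rainfall of the previous year (moist soil favors
oviposition and larval establishment).  Severity is produced by
thresholding a latent continuous score, preserving the ordinal nature
of the grading scale.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "FEATURE_COLUMNS",
    "LEVEL_COLUMN",
    "LAGGED_RAIN_COLUMNS",
    "TERMINAL_NAMES",
    "terminal_names",
    "terminal_map",
    "add_lagged_rain",
    "read_pest_csv",
    "write_pest_csv",
    "NormalizationSpec",
    "fit_normalizer",
    "apply_normalizer",
    "invert_normalizer",
    "chronological_split",
    "GeneratorParams",
    "generate_synthetic",
]

#: The 14 numeric predictors, in schema order.
FEATURE_COLUMNS: tuple[str, ...] = (
    "temp_jan",
    "temp_feb",
    "temp_mar",
    "temp_jul",
    "temp_aug",
    "temp_sep",
    "rain_jan",
    "rain_feb",
    "rain_mar",
    "rain_jul",
    "rain_aug",
    "rain_sep",
    "accum_temp",
    "annual_precip",
)
LEVEL_COLUMN = "level"
ALL_COLUMNS: tuple[str, ...] = ("year",) + FEATURE_COLUMNS + (LEVEL_COLUMN,)

#: Terminal symbols x1..x14 mapped onto the feature columns in order.
TERMINAL_NAMES: tuple[str, ...] = tuple(
    f"x{i + 1}" for i in range(len(FEATURE_COLUMNS))
)


def terminal_names(columns: tuple[str, ...] = FEATURE_COLUMNS) -> tuple[str, ...]:
    """Terminal symbols x1..xK for a feature-column tuple, in order."""
    return tuple(f"x{i + 1}" for i in range(len(columns)))


def terminal_map(
    df: pd.DataFrame, columns: tuple[str, ...] = FEATURE_COLUMNS
) -> dict[str, np.ndarray]:
    """Map terminal symbols x1..xK to their feature columns as arrays."""
    return {
        t: df[c].to_numpy(dtype=float)
        for t, c in zip(terminal_names(columns), columns)
    }


#: Optional feature-engineering switch: previous-year summer rainfall as
#: distinct columns (the documented positive correlate of outbreaks).
LAGGED_RAIN_COLUMNS: tuple[str, ...] = (
    "rain_jul_prev",
    "rain_aug_prev",
    "rain_sep_prev",
)


def add_lagged_rain(df: pd.DataFrame) -> pd.DataFrame:
    """Append previous-year July-September rainfall columns; the first
    year, which has no predecessor, is dropped.  Apply to the full
    table *before* splitting so test years keep their lag."""
    out = df.sort_values("year").reset_index(drop=True).copy()
    for src, dst in zip(("rain_jul", "rain_aug", "rain_sep"), LAGGED_RAIN_COLUMNS):
        out[dst] = out[src].shift(1)
    return out.iloc[1:].reset_index(drop=True)


def _validate_table(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in ALL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing required columns: {missing}")
    df = df.loc[:, list(ALL_COLUMNS)].copy()
    for col in ALL_COLUMNS:
        try:
            df[col] = pd.to_numeric(df[col], errors="raise")
        except (ValueError, TypeError) as exc:
            raise ValueError(f"non-numeric values in column {col!r}") from exc
    if df["year"].duplicated().any():
        dup = sorted(df.loc[df["year"].duplicated(), "year"].unique())
        raise ValueError(f"duplicate years: {dup}")
    df = df.sort_values("year").reset_index(drop=True)
    df["year"] = df["year"].astype(int)
    bad = ~df[LEVEL_COLUMN].isin([1, 2, 3])
    if bad.any():
        raise ValueError(
            f"levels outside {{1,2,3}} in years {df.loc[bad, 'year'].tolist()}"
        )
    df[LEVEL_COLUMN] = df[LEVEL_COLUMN].astype(int)
    return df


def read_pest_csv(path: str | Path) -> pd.DataFrame:
    """Read and validate a per-year pest/climate table."""
    return _validate_table(pd.read_csv(path))


def write_pest_csv(df: pd.DataFrame, path: str | Path) -> None:
    """Validate and write; round-trips losslessly through
    :func:`read_pest_csv` for finite values."""
    _validate_table(df).to_csv(path, index=False)


@dataclass
class NormalizationSpec:
    """Per-feature min/max learned from training rows only.

    The transform maps the training range of each feature onto [0, 1];
    test rows use the stored training extrema and may map outside
    [0, 1] — they are deliberately not clipped, so no information leaks
    from the test period into the scaling.
    """

    mins: dict[str, float]
    maxs: dict[str, float]

    def __post_init__(self) -> None:
        for col in self.mins:
            if self.maxs[col] <= self.mins[col]:
                raise ValueError(f"constant feature {col!r}: zero range")


def fit_normalizer(
    train_df: pd.DataFrame, columns: tuple[str, ...] = FEATURE_COLUMNS
) -> NormalizationSpec:
    if len(train_df) == 0:
        raise ValueError("empty training table")
    mins = {c: float(train_df[c].min()) for c in columns}
    maxs = {c: float(train_df[c].max()) for c in columns}
    return NormalizationSpec(mins=mins, maxs=maxs)


def apply_normalizer(spec: NormalizationSpec, df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in spec.mins if c not in df.columns]
    if missing:
        raise ValueError(f"missing feature columns: {missing}")
    out = df.copy()
    for col in spec.mins:
        out[col] = (df[col] - spec.mins[col]) / (spec.maxs[col] - spec.mins[col])
    return out


def invert_normalizer(spec: NormalizationSpec, df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    for col in spec.mins:
        out[col] = df[col] * (spec.maxs[col] - spec.mins[col]) + spec.mins[col]
    return out


def chronological_split(
    df: pd.DataFrame, last_train_year: int
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition by year: rows up to ``last_train_year`` inclusive train,
    later rows test.  Both sides must be nonempty."""
    train = df[df["year"] <= last_train_year].reset_index(drop=True)
    test = df[df["year"] > last_train_year].reset_index(drop=True)
    if len(train) == 0:
        raise ValueError(f"no training rows at or before {last_train_year}")
    if len(test) == 0:
        raise ValueError(f"no test rows after {last_train_year}")
    return train, test


# Seasonal climate marginals (mean, sd) chosen to match the magnitudes
# of the historical central-Shaanxi record: cold-to-mild winters, hot
# wet summers, ~5400 degree-day accumulated temperature, ~300-600 mm
# annual precipitation.
_CLIMATE_MARGINALS: dict[str, tuple[float, float]] = {
    "temp_jan": (1.5, 1.5),
    "temp_feb": (4.0, 2.0),
    "temp_mar": (8.5, 2.0),
    "temp_jul": (27.5, 1.2),
    "temp_aug": (26.5, 1.3),
    "temp_sep": (21.5, 1.2),
    "rain_jan": (5.0, 4.0),
    "rain_feb": (9.0, 7.0),
    "rain_mar": (25.0, 12.0),
    "rain_jul": (100.0, 40.0),
    "rain_aug": (90.0, 35.0),
    "rain_sep": (45.0, 20.0),
    "accum_temp": (5450.0, 110.0),
    "annual_precip": (470.0, 110.0),
}


@dataclass
class GeneratorParams:
    """Latent-score generator for ordinal outbreak levels.

    The latent severity for year ``t`` is

        s_t = beta0 - beta_temp * z(winter_temp_t)
                    + beta_rain * z(prev_rain_t)
                    + beta_precip * sin(annual_precip_t / precip_scale)
                    + Normal(0, noise_sd)

    where ``winter_temp`` is the January-March mean temperature,
    ``prev_rain`` the previous year's July-September mean rainfall, and
    ``z(.)`` standardizes by the generator's own population moments
    (not the sample), keeping the planted effect sizes exact.  Levels
    are ``1`` below the first threshold, ``2`` between the thresholds
    and ``3`` above the second.
    """

    beta0: float = 2.0
    beta_temp: float = 0.6
    beta_rain: float = 0.6
    beta_precip: float = 0.2
    precip_scale: float = 150.0
    noise_sd: float = 0.3
    thresholds: tuple[float, float] = (1.5, 2.5)

    def __post_init__(self) -> None:
        lo, hi = self.thresholds
        if not lo < hi:
            raise ValueError("thresholds must be strictly increasing")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "GeneratorParams":
        raw = json.loads(Path(path).read_text())
        raw["thresholds"] = tuple(raw["thresholds"])
        return cls(**raw)


def _population_moments(cols: tuple[str, ...]) -> tuple[float, float]:
    """Mean and sd of the average of independent Gaussian monthly
    marginals."""
    mu = float(np.mean([_CLIMATE_MARGINALS[c][0] for c in cols]))
    var = float(np.sum([_CLIMATE_MARGINALS[c][1] ** 2 for c in cols])) / len(cols) ** 2
    return mu, float(np.sqrt(var))


def generate_synthetic(
    n_years: int = 78,
    seed: int = 0,
    params: GeneratorParams | None = None,
    start_year: int = 1933,
) -> pd.DataFrame:
    """Simulate a per-year climate/outbreak table.

    Climate features are drawn from seasonal Gaussian marginals
    (rainfall truncated at zero); the ordinal level comes from the
    latent score of :class:`GeneratorParams`.  An extra burn-in year of
    climate is drawn so the first output year has a defined previous
    summer.  The parameters used are attached as
    ``df.attrs["generator_params"]`` for recovery tests.
    """
    if n_years < 10:
        raise ValueError("n_years must be >= 10")
    params = params or GeneratorParams()
    rng = np.random.default_rng(seed)

    total = n_years + 1  # burn-in year for the previous-summer lag
    climate: dict[str, np.ndarray] = {}
    for col, (mu, sd) in _CLIMATE_MARGINALS.items():
        draw = rng.normal(mu, sd, size=total)
        if col.startswith("rain") or col == "annual_precip":
            draw = np.maximum(draw, 0.0)
        # record at measurement precision; the latent score below uses the
        # recorded values, so the table fully determines the noiseless score
        climate[col] = np.round(draw, 1)

    winter_cols = ("temp_jan", "temp_feb", "temp_mar")
    summer_cols = ("rain_jul", "rain_aug", "rain_sep")
    w_mu, w_sd = _population_moments(winter_cols)
    s_mu, s_sd = _population_moments(summer_cols)

    winter = np.mean([climate[c] for c in winter_cols], axis=0)
    summer = np.mean([climate[c] for c in summer_cols], axis=0)
    z_winter = (winter[1:] - w_mu) / w_sd  # current year
    z_prev_rain = (summer[:-1] - s_mu) / s_sd  # previous year

    score = (
        params.beta0
        - params.beta_temp * z_winter
        + params.beta_rain * z_prev_rain
        + params.beta_precip * np.sin(climate["annual_precip"][1:] / params.precip_scale)
        + rng.normal(0.0, params.noise_sd, size=n_years)
    )
    lo, hi = params.thresholds
    level = np.ones(n_years, dtype=int)
    level[score >= lo] = 2
    level[score >= hi] = 3

    data = {"year": np.arange(start_year, start_year + n_years)}
    for col in FEATURE_COLUMNS:
        data[col] = climate[col][1:]
    data[LEVEL_COLUMN] = level
    df = pd.DataFrame(data)
    df.attrs["generator_params"] = params
    return df
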