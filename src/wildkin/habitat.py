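"""Habitat-level summaries, between-population contrasts and distance models.

Population differences in inbreeding, coancestry and similarity measures are
tested with a one-way fixed-effect linear model ``y = mu + population + e``
fitted by ordinary least squares; pairwise population differences come out
as OLS contrasts (t-tests on the pooled residual degrees of freedom).
Pairwise observations are treated as independent even though pairs sharing
an individual are correlated — a deliberate fidelity-over-rigor choice that
mirrors how such contrasts are conventionally reported.

Geographic separation uses the great-circle (haversine) distance on a sphere
of radius 6371 km, and coancestry is regressed on distance with a linear or
low-degree polynomial model, reporting the slope per 100 km and the distance
at which predicted coancestry crosses zero.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0


class HabitatError(ValueError):
    """Raised for unusable grouping or regression input."""


def summarize_by_habitat(values: pd.Series, habitats: pd.Series) -> pd.DataFrame:
    """Mean/SD/min/max of a coefficient per habitat (or habitat pair) label.

    ``values`` and ``habitats`` are aligned by position.  Single-member
    groups report an empty SD; empty groups are omitted.  Raises if any
    observation lacks a label.
    """
    values = pd.Series(np.asarray(values, dtype=float))
    habitats = pd.Series(np.asarray(habitats, dtype=object))
    if len(values) != len(habitats):
        raise HabitatError("values and habitat labels differ in length")
    unlabeled = habitats.isna() | (habitats == "")
    if unlabeled.any():
        raise HabitatError(
            f"unlabeled observations at positions {list(np.flatnonzero(unlabeled))}"
        )
    rows = []
    for name, grp in values.groupby(habitats):
        rows.append(
            {
                "habitat": name,
                "n": len(grp),
                "mean": grp.mean(),
                "sd": grp.std(ddof=1) if len(grp) > 1 else np.nan,
                "min": grp.min(),
                "max": grp.max(),
            }
        )
    return pd.DataFrame(rows).sort_values("habitat").reset_index(drop=True)


def group_contrasts(y, groups) -> pd.DataFrame:
    """All pairwise population contrasts from a one-way OLS fit.

    Groups with fewer than 2 observations are dropped from the model (they
    contribute no residual degrees of freedom and their contrasts would be
    untestable).  For two groups this reduces exactly to the classical
    pooled-variance two-sample t-test.  Returns columns group_a, group_b,
    estimate (mean_a - mean_b), se, t, p, df.
    """
    import statsmodels.api as sm

    y = pd.Series(np.asarray(y, dtype=float), name="y")
    groups = pd.Series(np.asarray(groups, dtype=object), name="group")
    if len(y) != len(groups):
        raise HabitatError("y and groups differ in length")
    sizes = groups.value_counts()
    usable = sorted(sizes.index[sizes >= 2])
    dropped = sorted(sizes.index[sizes < 2])
    if dropped:
        logger.info("dropping single-observation groups from contrasts: %s", dropped)
    if len(usable) < 2:
        raise HabitatError("need at least 2 groups with >= 2 observations")
    mask = groups.isin(usable).values
    yv, gv = y[mask].reset_index(drop=True), groups[mask].reset_index(drop=True)
    design = pd.get_dummies(gv, dtype=float)[usable]  # cell-means coding
    fit = sm.OLS(yv, design).fit()
    rows = []
    for a, b in itertools.combinations(usable, 2):
        contrast = np.zeros(len(usable))
        contrast[usable.index(a)] = 1.0
        contrast[usable.index(b)] = -1.0
        tt = fit.t_test(contrast)
        rows.append(
            {
                "group_a": a,
                "group_b": b,
                "estimate": float(np.squeeze(tt.effect)),
                "se": float(np.squeeze(tt.sd)),
                "t": float(np.squeeze(tt.tvalue)),
                "p": float(np.squeeze(tt.pvalue)),
                "df": int(fit.df_resid),
            }
        )
    return pd.DataFrame(rows)


def haversine_km(a: tuple[float, float], b: tuple[float, float]) -> float:
    """Great-circle distance in km between (lat, lon) points in degrees."""
    for lat, lon in (a, b):
        if not (-90.0 <= lat <= 90.0 and -180.0 <= lon <= 180.0):
            raise HabitatError(f"coordinates out of range: ({lat}, {lon})")
    lat1, lon1, lat2, lon2 = map(np.radians, (*a, *b))
    s = (
        np.sin((lat2 - lat1) / 2.0) ** 2
        + np.cos(lat1) * np.cos(lat2) * np.sin((lon2 - lon1) / 2.0) ** 2
    )
    return float(2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(s)))


@dataclass
class DistanceModel:
    """A fitted coancestry-on-distance model.

    ``coefficients`` are in increasing powers of distance (km).
    ``slope_per_100km`` is 100x the fitted derivative — at any distance for
    the linear model, at the mean observed distance for the polynomial one.
    ``zero_crossing_km`` is the smallest non-negative distance at which the
    fitted curve predicts zero coancestry (NaN if it never crosses).
    """

    model: str
    degree: int
    coefficients: np.ndarray
    slope_per_100km: float
    zero_crossing_km: float
    n: int = 0


def distance_regression(
    f_jk, distance_km, model: str = "linear", *, degree: int = 2
) -> DistanceModel:
    """Least-squares fit of pairwise coancestry on geographic distance.

    ``model`` is ``linear`` or ``polynomial`` (default degree 2 — the degree
    is a config knob, not a fact of nature).  Needs at least ``degree + 2``
    pairs so a residual degree of freedom remains.
    """
    y = np.asarray(f_jk, dtype=float)
    x = np.asarray(distance_km, dtype=float)
    if y.shape != x.shape or y.ndim != 1:
        raise HabitatError("f_jk and distance_km must be equal-length vectors")
    if model == "linear":
        deg = 1
    elif model == "polynomial":
        deg = int(degree)
        if deg < 2:
            raise HabitatError("polynomial model needs degree >= 2")
    else:
        raise HabitatError(f"unknown model {model!r}")
    if len(y) < deg + 2:
        raise HabitatError(f"{model} model needs at least {deg + 2} pairs")
    poly = np.polynomial.Polynomial.fit(x, y, deg).convert()
    deriv = poly.deriv()
    at = float(x.mean()) if deg > 1 else 0.0
    slope100 = 100.0 * float(deriv(at))
    # ignore numerically-null terms (a constant fit has no crossing)
    coef = poly.coef.copy()
    xscale = max(1.0, float(np.abs(x).max()))
    yscale = max(float(np.abs(y).max()), 1e-300)
    powers = np.arange(coef.size)
    coef[(np.abs(coef) * xscale**powers < 1e-9 * yscale) & (powers > 0)] = 0.0
    poly = np.polynomial.Polynomial(coef)
    roots = poly.roots()
    real = roots[np.isreal(roots)].real if roots.size else np.array([])
    real = real[real >= 0.0]
    crossing = float(real.min()) if real.size else float("nan")
    return DistanceModel(
        model=model,
        degree=deg,
        coefficients=poly.coef.copy(),
        slope_per_100km=slope100,
        zero_crossing_km=crossing,
        n=len(y),
    )


def pairwise_distances_km(meta: pd.DataFrame) -> pd.DataFrame:
    """Great-circle distance for every unordered sample pair in ``meta``.

    ``meta`` needs columns id, latitude, longitude.  Returns id1, id2,
    distance_km in the same pair order as the similarity tables.
    """
    ids = meta["id"].tolist()
    lat = meta["latitude"].to_numpy(dtype=float)
    lon = meta["longitude"].to_numpy(dtype=float)
    rows = []
    for j, k in itertools.combinations(range(len(ids)), 2):
        rows.append(
            {
                "id1": ids[j],
                "id2": ids[k],
                "distance_km": haversine_km((lat[j], lon[j]), (lat[k], lon[k])),
            }
        )
    return pd.DataFrame(rows)
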