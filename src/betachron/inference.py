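"""Group-level inference on per-assemblage summaries.

The unit of inference is the assemblage: one row per retained study holding
the median of each change metric, the invaded/uninvaded flag and the study
location.  The group contrast is a Gaussian GLM (identity link)

    metric ~ intercept + alien_flag + latitude + longitude

with the geographic coordinates as fixed covariates; spatial structure is
screened separately with Moran's I (inverse great-circle-distance weights,
randomization variance, normal-approximation p) and distance-decay
diagnostics, and within-assemblage acceleration of change is tested with a
Spearman correlation of pair dissimilarity against time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .core import ValidationError
from .dissimilarity import BetaSeries

__all__ = [
    "EARTH_RADIUS_KM",
    "TermResult",
    "GroupModelResult",
    "MoranResult",
    "AccelerationResult",
    "fit_group_model",
    "haversine_km",
    "pairwise_distances_km",
    "inverse_distance_weights",
    "morans_i",
    "distance_decay",
    "acceleration_test",
]

EARTH_RADIUS_KM = 6371.0

#: per-assemblage summary metrics the group model accepts as responses
RESPONSES = (
    "median_beta_jac",
    "median_beta_jtu",
    "median_beta_jne",
    "median_richness",
    "median_richness_diff",
    "median_rank_diff",
)


@dataclass(frozen=True)
class TermResult:
    coef: float
    se: float
    stat: float
    p: float


@dataclass(frozen=True)
class GroupModelResult:
    """Fitted group contrast for one response metric."""

    response: str
    n: int
    terms: dict[str, TermResult] = field(default_factory=dict)

    @property
    def alien(self) -> TermResult:
        return self.terms["alien_flag"]


def fit_group_model(summaries: pd.DataFrame, response: str) -> GroupModelResult:
    """Gaussian GLM of one summary metric on alien status plus coordinates.

    Parameters
    ----------
    summaries
        One row per assemblage with columns ``alien_flag`` (bool),
        ``latitude``, ``longitude`` and the response metric.
    response
        Column name of the metric to model.

    Returns
    -------
    GroupModelResult with coefficient, SE, t statistic and two-sided p for
    the intercept, the alien term and each coordinate.

    Raises
    ------
    ValidationError
        If the response column is absent, a group has fewer than two
        assemblages, or the design matrix is rank-deficient (the error names
        the collinear column).
    """
    if response not in summaries.columns:
        raise ValidationError(f"response column {response!r} not in summaries")
    data = summaries.dropna(subset=[response, "alien_flag", "latitude", "longitude"])
    counts = data["alien_flag"].astype(bool).value_counts()
    if len(counts) < 2 or counts.min() < 2:
        raise ValidationError(
            "degenerate design: need >= 2 assemblages in each of the invaded and "
            f"uninvaded groups, have {counts.to_dict()}"
        )
    y = data[response].to_numpy(dtype=float)
    X = np.column_stack(
        [
            np.ones(len(data)),
            data["alien_flag"].astype(bool).to_numpy(dtype=float),
            data["latitude"].to_numpy(dtype=float),
            data["longitude"].to_numpy(dtype=float),
        ]
    )
    names = ["intercept", "alien_flag", "latitude", "longitude"]
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        for j in range(1, X.shape[1]):
            reduced = np.delete(X, j, axis=1)
            if np.linalg.matrix_rank(reduced) == rank:
                raise ValidationError(f"rank-deficient design: column {names[j]!r} is collinear")
        raise ValidationError("rank-deficient design")
    fit = sm.OLS(y, X).fit()
    terms = {
        name: TermResult(
            coef=float(fit.params[j]),
            se=float(fit.bse[j]),
            stat=float(fit.tvalues[j]),
            p=float(fit.pvalues[j]),
        )
        for j, name in enumerate(names)
    }
    return GroupModelResult(response=response, n=int(fit.nobs), terms=terms)


# --------------------------------------------------------------- geography


def haversine_km(lat1, lon1, lat2, lon2) -> np.ndarray:
    """Great-circle distance in km between points in decimal degrees."""
    lat1, lon1, lat2, lon2 = map(np.radians, (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


def pairwise_distances_km(coords: np.ndarray) -> np.ndarray:
    """Symmetric distance matrix from an (n, 2) array of (lat, lon)."""
    coords = np.asarray(coords, dtype=float)
    lat = coords[:, 0][:, None]
    lon = coords[:, 1][:, None]
    return haversine_km(lat, lon, lat.T, lon.T)


def inverse_distance_weights(coords: np.ndarray) -> np.ndarray:
    """w_ij = 1 / d_ij with zero diagonal.

    Coincident distinct sites (d = 0 off the diagonal) receive the largest
    finite weight observed, with a warning.
    """
    d = pairwise_distances_km(coords)
    n = d.shape[0]
    off = ~np.eye(n, dtype=bool)
    if np.all(d[off] == 0):
        raise ValidationError("all sites coincident: spatial weights undefined")
    w = np.zeros_like(d)
    pos = off & (d > 0)
    w[pos] = 1.0 / d[pos]
    zero_off = off & (d == 0)
    if zero_off.any():
        warnings.warn(
            "coincident sites: assigning the maximum finite inverse-distance weight",
            stacklevel=2,
        )
        w[zero_off] = w[pos].max()
    return w


@dataclass(frozen=True)
class MoranResult:
    I: float
    expected: float
    sd: float
    p: float
    n: int


def morans_i(
    values,
    coords=None,
    weights: np.ndarray | None = None,
    row_standardize: bool = False,
) -> MoranResult:
    """Moran's I spatial autocorrelation with a normal-approximation test.

    I = (n / W) * sum_ij w_ij (x_i - xbar)(x_j - xbar) / sum_i (x_i - xbar)^2,
    with w_ii = 0 and W the sum of weights; the expectation under no spatial
    autocorrelation is -1/(n-1) and the variance uses the randomization
    (kurtosis-corrected) formula.  Weights default to inverse great-circle
    distance from ``coords``; set ``row_standardize=True`` to divide each row
    by its sum first (the convention of the ape implementation).
    """
    x = np.asarray(values, dtype=float)
    n = len(x)
    if n < 3:
        raise ValidationError(f"Moran's I needs n >= 3 sites, have {n}")
    if np.ptp(x) == 0:
        raise ValidationError("constant values: autocorrelation undefined")
    if weights is None:
        if coords is None:
            raise ValidationError("provide coords or a weight matrix")
        weights = inverse_distance_weights(np.asarray(coords))
    w = np.array(weights, dtype=float)
    if w.shape != (n, n):
        raise ValidationError(f"weight matrix shape {w.shape} does not match n={n}")
    np.fill_diagonal(w, 0.0)
    if row_standardize:
        rowsum = w.sum(axis=1, keepdims=True)
        rowsum[rowsum == 0] = 1.0
        w = w / rowsum
    s0 = w.sum()
    if s0 <= 0:
        raise ValidationError("weight matrix sums to zero")
    y = x - x.mean()
    denom = (y**2).sum()
    observed = (n / s0) * (y @ w @ y) / denom
    expected = -1.0 / (n - 1)
    s1 = 0.5 * ((w + w.T) ** 2).sum()
    s2 = ((w.sum(axis=1) + w.sum(axis=0)) ** 2).sum()
    k = ((y**4).sum() / n) / ((y**2).sum() / n) ** 2
    var = (
        n * ((n**2 - 3 * n + 3) * s1 - n * s2 + 3 * s0**2)
        - k * (n * (n - 1) * s1 - 2 * n * s2 + 6 * s0**2)
    ) / ((n - 1) * (n - 2) * (n - 3) * s0**2) - expected**2
    sd = float(np.sqrt(var))
    z = stats.norm.cdf(observed, loc=expected, scale=sd)
    p = float(2 * z if observed <= expected else 2 * (1 - z))
    return MoranResult(I=float(observed), expected=expected, sd=sd, p=p, n=n)


def distance_decay(values, coords) -> tuple[pd.DataFrame, float, float]:
    """Pairwise |metric difference| against great-circle distance.

    Returns the unordered-pair table (i, j, distance_km, abs_diff) plus the
    Spearman rho and p of difference vs distance.  When all differences are
    identical rho is undefined and reported as NaN with a warning.
    """
    x = np.asarray(values, dtype=float)
    n = len(x)
    if n < 3:
        raise ValidationError(f"distance decay needs n >= 3 sites, have {n}")
    d = pairwise_distances_km(np.asarray(coords))
    iu, ju = np.triu_indices(n, k=1)
    table = pd.DataFrame(
        {
            "i": iu,
            "j": ju,
            "distance_km": d[iu, ju],
            "abs_diff": np.abs(x[iu] - x[ju]),
        }
    )
    if np.ptp(table["abs_diff"].to_numpy()) == 0 or np.ptp(table["distance_km"].to_numpy()) == 0:
        warnings.warn("degenerate distance-decay input: Spearman rho undefined", stacklevel=2)
        return table, float("nan"), float("nan")
    rho, p = stats.spearmanr(table["distance_km"], table["abs_diff"])
    return table, float(rho), float(p)


@dataclass(frozen=True)
class AccelerationResult:
    """Spearman test of whether consecutive-step change accelerates in time."""

    study_id: str
    applicable: bool
    n_pairs: int
    rho: float = float("nan")
    p: float = float("nan")


#: minimum census years for the acceleration test to apply
MIN_YEARS_ACCELERATION = 4


def acceleration_test(bs: BetaSeries, metric: str = "beta_jac") -> AccelerationResult:
    """Correlate pair dissimilarity with the pair's later census year.

    Applies only to assemblages with at least four census years (three
    consecutive pairs); otherwise a not-applicable marker is returned.
    Constant dissimilarities give rho = NaN with a warning.
    """
    n_pairs = len(bs.pairs)
    if n_pairs < MIN_YEARS_ACCELERATION - 1:
        return AccelerationResult(study_id=bs.study_id, applicable=False, n_pairs=n_pairs)
    values = np.array([getattr(p, metric) for p in bs.pairs], dtype=float)
    years = np.array([p.year_to for p in bs.pairs], dtype=float)
    if np.ptp(values) == 0:
        warnings.warn(
            f"study {bs.study_id!r}: constant {metric}; acceleration rho undefined",
            stacklevel=2,
        )
        return AccelerationResult(study_id=bs.study_id, applicable=True, n_pairs=n_pairs)
    rho, p = stats.spearmanr(years, values)
    return AccelerationResult(
        study_id=bs.study_id, applicable=True, n_pairs=n_pairs, rho=float(rho), p=float(p)
    )
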