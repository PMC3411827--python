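"""Deterministic feasible-solution isotope mixing model.

Given k source endmembers and a consumer mixture measured on up to two
isotope axes (d13C, d15N), the model exhaustively enumerates every
source-proportion vector on the k-simplex at a fixed percentage
increment and retains those whose predicted mixture signature,

    predicted_j = sum_i p_i * source_i_mean_j,

falls within a mass-balance tolerance of the observed signature on each
isotope axis. The retained set — the *feasible solutions* — is
summarised per source by percentiles (5/25/50/75/95) and min/max. With
more sources than isotopes + 1 the system is underdetermined and the
model deliberately reports the full range of feasible contributions
rather than a unique solution; narrow ranges indicate a well
characterised diet, while solutions are flagged *indeterminable* when
the tolerance must exceed a ceiling or when feasible ranges are broad
(spanning from 0% upwards for many sources).

Proportions are held internally as integer percentages summing to exactly
100, avoiding floating-point drift on the simplex; fractions appear only
in reported summaries.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd

from .isotopes import ConsumerSample, IsotopeSignature, SourceSet

__all__ = [
    "MixingConfig",
    "FeasibleSet",
    "enumerate_simplex",
    "feasible_solutions",
    "site_profile",
    "profile_table",
    "sensitivity_resample",
]

PERCENTILES = (5, 25, 50, 75, 95)


@dataclass(frozen=True)
class MixingConfig:
    """Tuning knobs of the feasible-solution search.

    increment
        Simplex step in percent; must divide 100. 1% enumerates
        C(100/inc + k - 1, k - 1) vectors (4,598,126 for k=5 at 1%).
    tol_start, tol_step, tol_max
        Mass-balance tolerance schedule in per mil. The search starts at
        ``tol_start`` and escalates by ``tol_step`` until at least
        ``min_solutions`` vectors are feasible or ``tol_max`` is hit;
        solutions requiring tolerance beyond the ceiling are
        indeterminable.
    metric
        ``"per-isotope"`` (absolute deviation within tolerance on every
        informative axis; the cited model's convention) or
        ``"euclidean"``.
    broad_fraction, broad_span
        A feasible set is also flagged indeterminable when at least
        ``broad_fraction`` of the sources have feasible ranges running
        from 0 up past ``broad_span``.
    """

    increment: int = 1
    tol_start: float = 0.1
    tol_step: float = 0.1
    tol_max: float = 0.5
    metric: str = "per-isotope"
    min_solutions: int = 1
    broad_fraction: float = 0.5
    broad_span: float = 0.9

    def __post_init__(self) -> None:
        if 100 % self.increment != 0:
            raise ValueError(f"increment must divide 100, got {self.increment}")
        if not (0 < self.tol_start <= self.tol_max):
            raise ValueError("need 0 < tol_start <= tol_max")
        if self.tol_step <= 0:
            raise ValueError("tol_step must be positive")
        if self.metric not in ("per-isotope", "euclidean"):
            raise ValueError(f"unknown metric {self.metric!r}")

    def tolerance_schedule(self) -> list[float]:
        tols = [self.tol_start]
        while tols[-1] + self.tol_step <= self.tol_max + 1e-12:
            tols.append(round(tols[-1] + self.tol_step, 12))
        return tols


@dataclass
class FeasibleSet:
    """All source-proportion vectors consistent with a mixture.

    ``proportions`` is an (n_feasible, k) integer-percent matrix whose
    rows sum to exactly 100; ``summary`` is a per-source DataFrame of
    percentiles and min/max expressed as fractions.
    """

    source_names: list[str]
    proportions: np.ndarray  # integer percent, rows sum to 100
    tolerance_used: float
    indeterminable: bool
    summary: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    @property
    def n_solutions(self) -> int:
        return int(self.proportions.shape[0])

    def medians(self) -> pd.Series:
        return self.summary["p50"]


def _fill_compositions(view: np.ndarray, total: int) -> None:
    # writes all compositions of `total` into the preallocated view,
    # first coordinate ascending (lexicographic)
    k = view.shape[1]
    if k == 1:
        view[:, 0] = total
        return
    if k == 2:
        view[:, 0] = np.arange(total + 1, dtype=np.int16)
        view[:, 1] = total - view[:, 0]
        return
    row = 0
    for first in range(total + 1):
        m = math.comb(total - first + k - 2, k - 2)
        view[row : row + m, 0] = first
        _fill_compositions(view[row : row + m, 1:], total - first)
        row += m


@lru_cache(maxsize=32)
def _compositions(k: int, total: int) -> np.ndarray:
    """All length-k vectors of non-negative ints summing to ``total``."""
    out = np.empty((math.comb(total + k - 1, k - 1), k), dtype=np.int16)
    _fill_compositions(out, total)
    out.setflags(write=False)
    return out


def enumerate_simplex(k: int, increment: int = 1) -> np.ndarray:
    """Every proportion vector of k sources on the percent grid.

    Returns an (M, k) read-only int array in percent units with rows
    summing to exactly 100; M = C(100/increment + k - 1, k - 1).
    """
    if k < 2:
        raise ValueError(f"need at least 2 sources, got k={k}")
    if 100 % increment != 0:
        raise ValueError(f"increment must divide 100, got {increment}")
    n = 100 // increment
    grid = _compositions(k, n)
    if increment == 1:
        return grid
    out = (grid.astype(np.int16)) * np.int16(increment)
    out.setflags(write=False)
    return out


@lru_cache(maxsize=8)
def _predicted_cached(means_key: tuple, increment: int) -> np.ndarray:
    means = np.array(means_key, dtype=float)  # k x 2
    grid = enumerate_simplex(means.shape[0], increment)
    pred = (grid.astype(np.float64) / 100.0) @ means
    pred.setflags(write=False)
    return pred


def _predicted(means: np.ndarray, increment: int, *, cache: bool = True) -> np.ndarray:
    if cache:
        key = tuple(map(tuple, means.tolist()))
        return _predicted_cached(key, increment)
    grid = enumerate_simplex(means.shape[0], increment)
    return (grid.astype(np.float64) / 100.0) @ means


def _mixture_array(mixture) -> np.ndarray:
    if isinstance(mixture, IsotopeSignature):
        return mixture.as_array()
    arr = np.asarray(mixture, dtype=float)
    if arr.shape != (2,):
        raise ValueError("mixture must be an IsotopeSignature or length-2 array")
    return arr


def _feasible_mask(pred: np.ndarray, mix: np.ndarray, tol: float, metric: str) -> np.ndarray:
    axes = np.isfinite(mix)
    if not axes.any():
        raise ValueError("mixture has no informative isotope axis")
    dev = pred[:, axes] - mix[axes]
    if metric == "per-isotope":
        return (np.abs(dev) <= tol).all(axis=1)
    return np.sqrt((dev**2).sum(axis=1)) <= tol


def _summarise(grid: np.ndarray, names: list[str]) -> pd.DataFrame:
    cols = [f"p{p:02d}" for p in PERCENTILES] + ["min", "max"]
    if grid.shape[0] == 0:
        return pd.DataFrame(np.nan, index=pd.Index(names, name="source"), columns=cols)
    frac = grid.astype(float) / 100.0
    pct = np.percentile(frac, PERCENTILES, axis=0)  # linear interpolation
    data = np.vstack([pct, frac.min(axis=0), frac.max(axis=0)]).T
    return pd.DataFrame(data, index=pd.Index(names, name="source"), columns=cols)


def feasible_solutions(
    mixture,
    sources: SourceSet,
    config: MixingConfig = MixingConfig(),
    *,
    _cache: bool = True,
) -> FeasibleSet:
    """Enumerate and filter the simplex for one consumer mixture.

    ``mixture`` may be an :class:`IsotopeSignature` or a length-2 array
    (d13C, d15N); pass NaN on one axis to run a single-isotope model.
    Source means must already be corrected for trophic fractionation.

    The tolerance escalates from ``tol_start`` in ``tol_step`` steps
    until at least ``min_solutions`` vectors are feasible or ``tol_max``
    is reached; an empty set at the ceiling is returned (not raised)
    with ``indeterminable=True``.
    """
    if len(sources.sources) < 2:
        raise ValueError("mixing requires at least 2 sources")
    mix = _mixture_array(mixture)
    means = sources.mean_matrix()
    grid = enumerate_simplex(means.shape[0], config.increment)
    pred = _predicted(means, config.increment, cache=_cache)

    mask = None
    tol_used = config.tol_max
    for tol in config.tolerance_schedule():
        mask = _feasible_mask(pred, mix, tol, config.metric)
        if int(mask.sum()) >= config.min_solutions:
            tol_used = tol
            break
    feasible = grid[mask] if mask is not None else grid[:0]

    summary = _summarise(feasible, sources.names)
    if feasible.shape[0] == 0:
        indeterminable = True
    else:
        broad = (summary["min"] <= 1e-12) & (summary["max"] > config.broad_span)
        indeterminable = (tol_used > config.tol_max) or (
            broad.mean() >= config.broad_fraction
        )
    return FeasibleSet(
        source_names=sources.names,
        proportions=feasible,
        tolerance_used=tol_used,
        indeterminable=bool(indeterminable),
        summary=summary,
        metadata={
            "metric": config.metric,
            "increment": config.increment,
            "percentile_method": "linear",
            "n_enumerated": int(grid.shape[0]),
            "mixture": mix.tolist(),
        },
    )


def site_profile(
    consumers: list[ConsumerSample] | pd.DataFrame,
    sources: SourceSet,
    config: MixingConfig = MixingConfig(),
    *,
    per_individual: bool = False,
) -> dict[str, FeasibleSet]:
    """Run the mixing model for every site along the gradient.

    Individuals are averaged per site (arithmetic mean signature) before
    mixing — the model targets the site, not the individual — unless
    ``per_individual`` is set, in which case keys are
    ``"{site_id}/{index}"``. Returns a dict keyed by site_id, ordered by
    distance_rank; each FeasibleSet's metadata records the rank.
    """
    if isinstance(consumers, pd.DataFrame):
        df = consumers
    else:
        df = pd.DataFrame(
            {
                "site_id": [c.site_id for c in consumers],
                "distance_rank": [c.distance_rank for c in consumers],
                "d13C": [c.signature.d13c for c in consumers],
                "d15N": [c.signature.d15n for c in consumers],
            }
        )
    out: dict[str, FeasibleSet] = {}
    for (rank, site), grp in sorted(
        df.groupby(["distance_rank", "site_id"], sort=False),
        key=lambda kv: (kv[0][0], str(kv[0][1])),
    ):
        if len(grp) == 0:  # pragma: no cover - groupby never yields empties
            warnings.warn(f"site {site}: no consumers, skipped")
            continue
        if per_individual:
            for i, row in enumerate(grp.itertuples()):
                fs = feasible_solutions(np.array([row.d13C, row.d15N]), sources, config)
                fs.metadata.update(site_id=str(site), distance_rank=int(rank), individual=i)
                out[f"{site}/{i}"] = fs
        else:
            mix = np.array([grp["d13C"].mean(), grp["d15N"].mean()])
            fs = feasible_solutions(mix, sources, config)
            fs.metadata.update(site_id=str(site), distance_rank=int(rank), n_consumers=len(grp))
            out[str(site)] = fs
    return out


def profile_table(profiles: dict[str, FeasibleSet]) -> pd.DataFrame:
    """Flatten site profiles to the tabular twin of a box-plot figure.

    Columns: site_id, distance_rank, source, p05..p95, min, max,
    tolerance_used, indeterminable, n_solutions.
    """
    rows = []
    for key, fs in profiles.items():
        site = fs.metadata.get("site_id", key)
        rank = fs.metadata.get("distance_rank", np.nan)
        for source, s in fs.summary.iterrows():
            rows.append(
                {
                    "site_id": site,
                    "distance_rank": rank,
                    "source": source,
                    **{c: s[c] for c in fs.summary.columns},
                    "tolerance_used": fs.tolerance_used,
                    "indeterminable": fs.indeterminable,
                    "n_solutions": fs.n_solutions,
                }
            )
    return pd.DataFrame(rows)


def sensitivity_resample(
    mixture,
    sources: SourceSet,
    config: MixingConfig = MixingConfig(),
    *,
    draws: int = 100,
    seed: int,
) -> pd.DataFrame:
    """Propagate endmember SEs through the deterministic model.

    The feasible-solution model consumes only source means; this helper
    redraws the means from Gaussian(mean, SE) ``draws`` times and reruns
    the model, returning a (draws x sources) DataFrame of per-source
    median feasible contributions. Fully reproducible under ``seed``.
    """
    if draws < 1:
        raise ValueError("draws must be >= 1")
    rng = np.random.default_rng(seed)
    means = sources.mean_matrix()
    ses = sources.se_matrix()
    rows = []
    for _ in range(draws):
        perturbed = means + rng.standard_normal(means.shape) * ses
        grid_pred = _predicted(perturbed, config.increment, cache=False)
        mix = _mixture_array(mixture)
        mask = None
        for tol in config.tolerance_schedule():
            mask = _feasible_mask(grid_pred, mix, tol, config.metric)
            if int(mask.sum()) >= config.min_solutions:
                break
        grid = enumerate_simplex(means.shape[0], config.increment)
        rows.append(_summarise(grid[mask], sources.names)["p50"].to_numpy())
    return pd.DataFrame(rows, columns=sources.names)
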