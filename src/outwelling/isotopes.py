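"""Stable-isotope data types and source-endmember corrections.

Carbon and nitrogen stable-isotope compositions are expressed in delta
notation: the per-mil deviation of the sample isotope ratio from an
international reference (V-PDB for carbon, atmospheric N2 for nitrogen),

    delta = (R_sample / R_standard - 1) * 1000  [per mil]

Source endmembers (estuarine and marine suspended particulate organic
matter, seagrass detritus, microphytobenthos, fringing vegetation) are
summarised as replicate means with standard errors, then corrected for
trophic fractionation before entering the mixing model: consumer tissue
is systematically enriched relative to diet by roughly one trophic
enrichment factor (TEF) per trophic level, so source means are shifted
*toward consumer space* by adding the TEF — algebraically equivalent to
shifting consumers down, and the convention of the feasible-solution
mixing software this module feeds.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = [
    "IsotopeSignature",
    "SourceEndmember",
    "SourceSet",
    "Tef",
    "DEFAULT_TEF",
    "ConsumerSample",
    "ImplausibleSignatureWarning",
    "delta_from_ratios",
    "check_plausible",
    "apply_tef",
    "correct_sources",
    "pool_sources",
    "degrade_average",
    "read_sources",
    "read_consumers",
]

#: Advisory plausibility windows for marine/estuarine organic matter, per mil.
D13C_BOUNDS = (-50.0, 0.0)
D15N_BOUNDS = (-10.0, 30.0)


class ImplausibleSignatureWarning(UserWarning):
    """A delta value fell outside the advisory plausibility window."""


def delta_from_ratios(r_sample: float, r_standard: float) -> float:
    """Convert raw isotope ratios to per-mil delta notation.

    Parameters
    ----------
    r_sample, r_standard
        Heavy/light isotope abundance ratios of the sample and of the
        international standard. ``r_standard`` must be positive.

    Returns
    -------
    float
        ``(r_sample / r_standard - 1) * 1000`` in per mil.
    """
    if not (r_standard > 0):
        raise ValueError(f"standard ratio must be positive, got {r_standard!r}")
    if r_sample < 0:
        raise ValueError(f"sample ratio must be non-negative, got {r_sample!r}")
    return (r_sample / r_standard - 1.0) * 1000.0


@dataclass(frozen=True)
class IsotopeSignature:
    """A paired (d13C, d15N) measurement in per mil.

    ``d13C`` is relative to V-PDB, ``d15N`` relative to atmospheric N2.
    NaN on one axis marks that isotope as uninformative (single-isotope
    mixing); use :func:`check_plausible` on ingest for range screening.
    """

    d13c: float
    d15n: float

    def as_array(self) -> np.ndarray:
        return np.array([self.d13c, self.d15n], dtype=float)

    def __add__(self, other: "IsotopeSignature | Tef") -> "IsotopeSignature":
        return IsotopeSignature(self.d13c + other.d13c, self.d15n + other.d15n)


def check_plausible(sig: IsotopeSignature, *, allow_implausible: bool = False) -> IsotopeSignature:
    """Screen a signature against advisory plausibility bounds.

    Detrital material can legitimately exceed the windows (bacterially
    enriched seagrass detritus reaches d15N > 20 per mil), so violations
    warn rather than fail unless ``allow_implausible`` is False *and*
    the value is non-finite.
    """
    for name, value in (("d13C", sig.d13c), ("d15N", sig.d15n)):
        if math.isnan(value):
            continue  # deliberately uninformative axis
        if not math.isfinite(value):
            raise ValueError(f"{name} must be finite, got {value!r}")
    lo, hi = D13C_BOUNDS
    nlo, nhi = D15N_BOUNDS
    out_c = math.isfinite(sig.d13c) and not (lo <= sig.d13c <= hi)
    out_n = math.isfinite(sig.d15n) and not (nlo <= sig.d15n <= nhi)
    if (out_c or out_n) and not allow_implausible:
        warnings.warn(
            f"signature ({sig.d13c}, {sig.d15n}) outside plausibility bounds "
            f"d13C {D13C_BOUNDS}, d15N {D15N_BOUNDS}; pass allow_implausible=True "
            "to silence",
            ImplausibleSignatureWarning,
            stacklevel=2,
        )
    return sig


@dataclass(frozen=True)
class Tef:
    """Trophic enrichment factor: per-mil shift per trophic level."""

    d13c: float = 0.4
    d15n: float = 2.3

    def negated(self) -> "Tef":
        return Tef(-self.d13c, -self.d15n)


#: Literature mean diet-to-tissue enrichment for one trophic level.
DEFAULT_TEF = Tef(0.4, 2.3)


@dataclass(frozen=True)
class SourceEndmember:
    """A named primary-producer endmember: replicate mean, SE and n."""

    name: str
    mean: IsotopeSignature
    se: tuple[float, float] = (0.0, 0.0)  # (se d13C, se d15N), per mil
    n: int = 1

    def __post_init__(self) -> None:
        if self.se[0] < 0 or self.se[1] < 0:
            raise ValueError(f"standard errors must be >= 0, got {self.se}")
        if self.n < 1:
            raise ValueError(f"replicate count must be >= 1, got {self.n}")


@dataclass(frozen=True)
class SourceSet:
    """Ordered endmembers for one estuary; defines the mixing polygon."""

    estuary: str
    sources: tuple[SourceEndmember, ...]

    def __post_init__(self) -> None:
        names = [s.name for s in self.sources]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate source names in SourceSet: {names}")

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.sources]

    def mean_matrix(self) -> np.ndarray:
        """k x 2 array of (d13C, d15N) source means."""
        return np.array([s.mean.as_array() for s in self.sources])

    def se_matrix(self) -> np.ndarray:
        return np.array([s.se for s in self.sources], dtype=float)


@dataclass(frozen=True)
class ConsumerSample:
    """One consumer tissue measurement at a gradient site."""

    site_id: str
    distance_rank: int
    species: str
    tissue: str
    signature: IsotopeSignature

    def __post_init__(self) -> None:
        if self.distance_rank < 1:
            raise ValueError(f"distance_rank must be >= 1, got {self.distance_rank}")


def apply_tef(source: SourceEndmember, tef: Tef = DEFAULT_TEF) -> SourceEndmember:
    """Shift a source mean into consumer space by one trophic level.

    SE and replicate count are unchanged: the TEF is treated as a fixed
    offset (its own uncertainty is not propagated here).
    """
    return replace(source, mean=source.mean + tef)


def correct_sources(sources: SourceSet, tef: Tef = DEFAULT_TEF) -> SourceSet:
    """Apply the trophic fractionation correction to every endmember."""
    return replace(sources, sources=tuple(apply_tef(s, tef) for s in sources.sources))


def _pooled_se(means: np.ndarray, ses: np.ndarray) -> tuple[float, float]:
    # Conservative pooling: the larger of the mean member SE and a
    # range-based dispersion (half-range / sqrt(k)) per isotope.
    k = len(means)
    half_range = (means.max(axis=0) - means.min(axis=0)) / 2.0
    pooled = np.maximum(ses.mean(axis=0), half_range / math.sqrt(k))
    return float(pooled[0]), float(pooled[1])


def pool_sources(members: list[SourceEndmember], name: str) -> SourceEndmember:
    """Pool functionally similar endmembers into one (e.g. saltmarsh +
    mangrove detritus -> fringing vegetation).

    The pooled mean is the unweighted arithmetic mean of member means
    per isotope. The pooled SE is the larger of (a) the mean of member
    SEs and (b) half the between-member range divided by sqrt(k) — a
    conservative rule recorded here because no standard convention
    exists; supply precomputed endmembers to use a different one.
    """
    if len(members) < 2:
        raise ValueError("pool_sources requires at least 2 members")
    means = np.array([m.mean.as_array() for m in members])
    ses = np.array([m.se for m in members], dtype=float)
    mean = means.mean(axis=0)
    return SourceEndmember(
        name=name,
        mean=IsotopeSignature(float(mean[0]), float(mean[1])),
        se=_pooled_se(means, ses),
        n=sum(m.n for m in members),
    )


def degrade_average(
    fresh: SourceEndmember, detrital: SourceEndmember, name: str | None = None
) -> SourceEndmember:
    """Average fresh and degraded material of the same producer.

    Bacterial degradation enriches detritus in 15N (degraded seagrass can
    exceed d15N 20 per mil); the unweighted mean of fresh and detrital
    signatures is used as the endmember so the correction tracks isotope
    discrimination as food quality changes during decay.
    """
    pooled = pool_sources([fresh, detrital], name or fresh.name)
    return pooled


# ---------------------------------------------------------------------------
# CSV ingest

SOURCES_COLUMNS = ["source", "estuary", "replicate", "d13C", "d15N"]
CONSUMERS_COLUMNS = [
    "site_id",
    "distance_rank",
    "species",
    "tissue",
    "individual",
    "d13C",
    "d15N",
]


def read_sources(path, *, allow_implausible: bool = False) -> dict[str, SourceSet]:
    """Read per-replicate source measurements and aggregate to SourceSets.

    The file has one row per replicate with columns
    ``source,estuary,replicate,d13C,d15N``; replicates are aggregated to
    mean, standard error and count per (estuary, source).
    """
    df = pd.read_csv(path)
    missing = set(SOURCES_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"sources table missing columns: {sorted(missing)}")
    out: dict[str, SourceSet] = {}
    for estuary, grp in df.groupby("estuary", sort=True):
        members = []
        for source, rep in grp.groupby("source", sort=False):
            mean = IsotopeSignature(float(rep["d13C"].mean()), float(rep["d15N"].mean()))
            check_plausible(mean, allow_implausible=allow_implausible)
            n = len(rep)
            se = (
                float(rep["d13C"].std(ddof=1) / math.sqrt(n)) if n > 1 else 0.0,
                float(rep["d15N"].std(ddof=1) / math.sqrt(n)) if n > 1 else 0.0,
            )
            members.append(SourceEndmember(str(source), mean, se, n))
        out[str(estuary)] = SourceSet(str(estuary), tuple(members))
    return out


def read_consumers(path, *, allow_implausible: bool = False) -> pd.DataFrame:
    """Read per-individual consumer measurements.

    Returns the validated DataFrame (columns ``site_id, distance_rank,
    species, tissue, individual, d13C, d15N``); use
    :func:`consumer_samples` for typed records.
    """
    df = pd.read_csv(path)
    missing = set(CONSUMERS_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"consumers table missing columns: {sorted(missing)}")
    for _, row in df.iterrows():
        check_plausible(
            IsotopeSignature(float(row["d13C"]), float(row["d15N"])),
            allow_implausible=allow_implausible,
        )
    df["distance_rank"] = df["distance_rank"].astype(int)
    if (df["distance_rank"] < 1).any():
        raise ValueError("distance_rank must be >= 1")
    return df


def consumer_samples(df: pd.DataFrame) -> list[ConsumerSample]:
    """Convert a consumers table to typed records."""
    return [
        ConsumerSample(
            site_id=str(r.site_id),
            distance_rank=int(r.distance_rank),
            species=str(r.species),
            tissue=str(r.tissue),
            signature=IsotopeSignature(float(r.d13C), float(r.d15N)),
        )
        for r in df.itertuples()
    ]
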