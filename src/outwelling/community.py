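"""Community structure: incidence-based richness, dissimilarity, traits.

Macrofaunal counts from replicate sediment cores form a samples x taxa
matrix. Total richness per location is estimated with the incidence
(presence/absence across samples) Chao2 estimator, which adds to the
observed richness a term driven by the taxa seen in exactly one (Q1) or
exactly two (Q2) samples. Compositional differences use Bray-Curtis
dissimilarity, and community function is profiled by expanding taxon
counts through a taxon x trait score table (biological traits analysis,
supporting fuzzy-coded scores).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import braycurtis as _scipy_braycurtis
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "CommunityMatrix",
    "IncidenceSummary",
    "TraitMatrix",
    "Chao2Result",
    "chao2",
    "accumulation_curve",
    "bray_curtis",
    "dissimilarity_matrix",
    "trait_expand",
    "location_dissimilarity",
    "within_similarity",
]


@dataclass
class CommunityMatrix:
    """Counts of taxa per sample with optional site/location metadata.

    ``counts`` is a samples x taxa DataFrame of non-negative integers;
    ``sample_meta`` (if given) is indexed like ``counts`` with columns
    ``site_id`` and ``location``.
    """

    counts: pd.DataFrame
    sample_meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        c = self.counts
        if c.index.has_duplicates or c.columns.has_duplicates:
            raise ValueError("duplicate sample or taxon labels")
        arr = c.to_numpy()
        if (arr < 0).any():
            raise ValueError("counts must be non-negative")
        if not np.allclose(arr, np.round(arr)):
            raise ValueError("counts must be integral")
        if self.sample_meta is not None and not c.index.equals(self.sample_meta.index):
            raise ValueError("sample_meta index must match counts index")

    @classmethod
    def from_long(cls, df: pd.DataFrame) -> "CommunityMatrix":
        """Build from long format ``sample_id,site_id,location,taxon,count``."""
        counts = (
            df.pivot_table(
                index="sample_id", columns="taxon", values="count", aggfunc="sum", fill_value=0
            )
            .sort_index()
            .sort_index(axis=1)
        )
        counts = counts.astype(int)
        meta = (
            df[["sample_id", "site_id", "location"]]
            .drop_duplicates("sample_id")
            .set_index("sample_id")
            .loc[counts.index]
        )
        return cls(counts, meta)

    def to_long(self) -> pd.DataFrame:
        long = (
            self.counts.stack()
            .rename("count")
            .reset_index()
            .rename(columns={"level_0": "sample_id", "level_1": "taxon"})
        )
        long.columns = ["sample_id", "taxon", "count"]
        if self.sample_meta is not None:
            long = long.merge(
                self.sample_meta.reset_index().rename(columns={"index": "sample_id"}),
                on="sample_id",
            )
            long = long[["sample_id", "site_id", "location", "taxon", "count"]]
        return long[long["count"] > 0].reset_index(drop=True)

    def presence(self) -> pd.DataFrame:
        return self.counts > 0

    def subset(self, samples) -> "CommunityMatrix":
        meta = self.sample_meta.loc[samples] if self.sample_meta is not None else None
        return CommunityMatrix(self.counts.loc[samples], meta)

    def pool_by(self, key: str) -> pd.DataFrame:
        """Sum counts over samples grouped by a metadata column."""
        if self.sample_meta is None:
            raise ValueError("pool_by requires sample_meta")
        return self.counts.groupby(self.sample_meta[key]).sum()

    def incidence_summary(self) -> "IncidenceSummary":
        pres = self.presence()
        freq = pres.sum(axis=0)
        return IncidenceSummary(
            m=int(pres.shape[0]),
            s_obs=int((freq > 0).sum()),
            q1=int((freq == 1).sum()),
            q2=int((freq == 2).sum()),
        )


@dataclass(frozen=True)
class IncidenceSummary:
    """Sufficient statistics of the Chao2 estimator."""

    m: int  # number of samples
    s_obs: int  # observed taxa
    q1: int  # taxa in exactly one sample (uniques)
    q2: int  # taxa in exactly two samples (duplicates)

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("need at least one sample")
        if self.q1 + self.q2 > self.s_obs:
            raise ValueError("Q1 + Q2 cannot exceed S_obs")


@dataclass(frozen=True)
class Chao2Result:
    estimate: float
    se: float
    summary: IncidenceSummary
    variant: str  # "bias-corrected" | "classic" (+ variance formula id)


def _chao2_point(inc: IncidenceSummary, bias_corrected: bool) -> float:
    m, s, q1, q2 = inc.m, inc.s_obs, inc.q1, inc.q2
    if bias_corrected:
        return s + (m - 1) / m * q1 * (q1 - 1) / (2 * (q2 + 1))
    return s + q1 * q1 / (2 * q2)


def chao2(incidence, *, bias_corrected: bool = True) -> Chao2Result:
    """Incidence-based (Chao2) total-richness estimate with SE.

    Accepts a :class:`CommunityMatrix` or :class:`IncidenceSummary`. The
    bias-corrected form

        S_obs + ((m-1)/m) * Q1(Q1-1) / (2(Q2+1))

    is the default; the classic form ``S_obs + Q1^2 / (2 Q2)`` is
    available when Q2 > 0. Standard errors use the conventional
    incidence-based variance formulas, with the Q2 = 0 fallback variance.
    """
    inc = incidence.incidence_summary() if isinstance(incidence, CommunityMatrix) else incidence
    if inc.m < 2:
        raise ValueError("Chao2 requires at least 2 samples")
    if inc.s_obs == 0:
        return Chao2Result(0.0, 0.0, inc, "empty")
    m, q1, q2 = inc.m, inc.q1, inc.q2
    a = (m - 1) / m

    if not bias_corrected and q2 == 0:
        warnings.warn("classic Chao2 undefined with Q2=0; falling back to bias-corrected")
        bias_corrected = True
    est = _chao2_point(inc, bias_corrected)

    if q1 == 0:
        var = 0.0
        formula = "q1_zero"
    elif q2 > 0 and not bias_corrected:
        r = q1 / q2
        var = q2 * (r**2 / 2 + r**3 + r**4 / 4)
        formula = "classic_q2_pos"
    elif q2 > 0:
        var = (
            a * q1 * (q1 - 1) / (2 * (q2 + 1))
            + a**2 * q1 * (2 * q1 - 1) ** 2 / (4 * (q2 + 1) ** 2)
            + a**2 * q1**2 * q2 * (q1 - 1) ** 2 / (4 * (q2 + 1) ** 4)
        )
        formula = "bc_q2_pos"
    else:
        var = (
            a * q1 * (q1 - 1) / 2
            + a**2 * q1 * (2 * q1 - 1) ** 2 / 4
            - a**2 * q1**4 / (4 * est)
        )
        formula = "bc_q2_zero"
    variant = ("bias-corrected" if bias_corrected else "classic") + f"/{formula}"
    return Chao2Result(float(est), float(math.sqrt(max(var, 0.0))), inc, variant)


def accumulation_curve(
    community: CommunityMatrix,
    *,
    permutations: int = 100,
    seed: int,
    bias_corrected: bool = True,
) -> pd.DataFrame:
    """Sample-based Chao2 accumulation curve.

    For each number of samples t = 2..m, ``permutations`` random subsets
    of t samples are drawn (without replacement within a subset) and
    Chao2 computed on each; at t = m the single full-matrix estimate is
    used. Returns a DataFrame with columns ``t, chao2_mean, chao2_sd,
    se_analytic`` where ``chao2_sd`` is the spread across subsets and
    ``se_analytic`` the mean analytic SE.
    """
    if permutations < 1:
        raise ValueError("permutations must be >= 1")
    rng = np.random.default_rng(seed)
    pres = community.presence().to_numpy()
    m = pres.shape[0]
    rows = []
    for t in range(2, m + 1):
        n_draws = 1 if t == m else permutations
        ests, ses = [], []
        for _ in range(n_draws):
            idx = np.arange(m) if t == m else rng.choice(m, size=t, replace=False)
            freq = pres[idx].sum(axis=0)
            inc = IncidenceSummary(
                m=t,
                s_obs=int((freq > 0).sum()),
                q1=int((freq == 1).sum()),
                q2=int((freq == 2).sum()),
            )
            res = chao2(inc, bias_corrected=bias_corrected)
            ests.append(res.estimate)
            ses.append(res.se)
        ests = np.asarray(ests)
        rows.append(
            {
                "t": t,
                "chao2_mean": float(ests.mean()),
                "chao2_sd": float(ests.std(ddof=1)) if n_draws > 1 else 0.0,
                "se_analytic": float(np.mean(ses)),
            }
        )
    return pd.DataFrame(rows)


def bray_curtis(a, b) -> float:
    """Bray-Curtis dissimilarity, 1 - 2*sum(min)/(sum(a)+sum(b)), in [0, 1]."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("vectors must have equal length")
    if (a < 0).any() or (b < 0).any():
        raise ValueError("abundances must be non-negative")
    if a.sum() == 0 and b.sum() == 0:
        raise ValueError("Bray-Curtis undefined for two all-zero vectors")
    return float(_scipy_braycurtis(a, b))


def dissimilarity_matrix(abundance: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Bray-Curtis matrix for rows of an abundance table."""
    arr = abundance.to_numpy(dtype=float)
    if (arr.sum(axis=1) == 0).any():
        raise ValueError("every row must have positive total abundance")
    d = squareform(pdist(arr, metric="braycurtis"))
    return pd.DataFrame(d, index=abundance.index, columns=abundance.index)


@dataclass
class TraitMatrix:
    """Taxon x trait scores; fuzzy-coded (non-integer) weights allowed."""

    scores: pd.DataFrame
    categories: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        arr = self.scores.to_numpy(dtype=float)
        if (arr < 0).any():
            raise ValueError("trait scores must be non-negative")
        if (arr.sum(axis=1) <= 0).any():
            bad = list(self.scores.index[arr.sum(axis=1) <= 0])
            raise ValueError(f"taxa with no positive trait score: {bad}")

    @classmethod
    def from_wide(cls, df: pd.DataFrame) -> "TraitMatrix":
        """Build from wide CSV layout ``taxon,<trait columns...>``."""
        return cls(df.set_index("taxon").astype(float))

    @property
    def traits(self) -> list[str]:
        return list(self.scores.columns)


def trait_expand(
    counts: pd.DataFrame | CommunityMatrix,
    traits: TraitMatrix,
    *,
    on_missing: str = "error",
) -> pd.DataFrame:
    """Abundance-weighted trait profile: counts @ scores.

    ``entry(sample, trait) = sum_taxa counts(sample, taxon) *
    score(taxon, trait)`` — linear in counts, so expansion commutes with
    pooling samples. Taxa absent from the trait table raise by default
    (``on_missing="error"``) or are dropped with a warning
    (``on_missing="warn"``).
    """
    c = counts.counts if isinstance(counts, CommunityMatrix) else counts
    missing = [t for t in c.columns if t not in traits.scores.index]
    if missing:
        if on_missing == "error":
            raise KeyError(f"taxa missing from trait table: {missing}")
        warnings.warn(f"excluding {len(missing)} taxa missing from trait table: {missing}")
        c = c.drop(columns=missing)
    scores = traits.scores.loc[c.columns]
    return c.astype(float) @ scores


def location_dissimilarity(community: CommunityMatrix) -> float:
    """Bray-Curtis between location-pooled abundance vectors (2 locations)."""
    pooled = community.pool_by("location")
    if pooled.shape[0] != 2:
        raise ValueError(f"expected 2 locations, found {pooled.shape[0]}")
    return bray_curtis(pooled.iloc[0], pooled.iloc[1])


def within_similarity(community: CommunityMatrix, location: str) -> float:
    """Percent similarity among a location's site-pooled vectors.

    100 * (1 - mean pairwise Bray-Curtis) over the location's sites.
    """
    if community.sample_meta is None:
        raise ValueError("requires sample_meta")
    mask = community.sample_meta["location"] == location
    sub = community.subset(community.counts.index[mask])
    by_site = sub.counts.groupby(sub.sample_meta.loc[mask, "site_id"]).sum()
    d = dissimilarity_matrix(by_site).to_numpy()
    iu = np.triu_indices_from(d, k=1)
    return float(100.0 * (1.0 - d[iu].mean()))
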