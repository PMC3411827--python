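"""Distance-based linear modelling and gradient statistics.

The central tool regresses the variation of a Bray-Curtis (or any)
distance matrix on environmental covariates. The squared distances are
Gower-centred,

    G = C (-1/2 D∘D) C,   C = I - 11'/n,

and for a covariate design with hat projector H the explained variation
is tr(HGH)/tr(G), tested with the pseudo-F statistic

    F = [tr(HGH)/m] / [tr((I-H)G(I-H))/(n-m-1)]

whose null distribution is obtained by permuting the sample labels of
the distance matrix. Model search is backwards elimination on adjusted
R^2 or an AIC defined on the distance-variation partition,
``n*ln(SS_res/n) + 2(m+1)`` (conventions for distance-based AIC differ
between packages; the one used is recorded in the result metadata).

Also here: one-way ANOVA, Tukey HSD, Bonferroni-adjusted categorical
site comparisons, and simple linear / exponential-decay distance
regressions used to describe per-covariate spatial patterns.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "DblmResult",
    "GradientFit",
    "normalize_env",
    "gower_center",
    "dblm_fit",
    "dblm_select",
    "principal_coordinates",
    "oneway_anova",
    "tukey_hsd",
    "gradient_fit",
]

EXACT_PERM_LIMIT = 500_000  # enumerate all n! permutations below this


def normalize_env(env: pd.DataFrame, covariates: list[str], by: str | None = None) -> pd.DataFrame:
    """Z-score covariate columns, optionally within groups (e.g. location)."""
    out = env.copy()

    def z(g):
        sd = g.std(ddof=1)
        return (g - g.mean()) / sd.replace(0, 1.0)

    if by is None:
        out[covariates] = z(out[covariates])
    else:
        out[covariates] = out.groupby(by, group_keys=False)[covariates].apply(z)
    return out


def gower_center(d: np.ndarray) -> np.ndarray:
    """Gower-centred inner-product matrix of a distance matrix.

    G = C A C with A = -1/2 d∘d; G is symmetric with zero row sums.
    """
    d = np.asarray(d, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    if (np.diag(d) > 1e-10).any() or (d < -1e-12).any():
        raise ValueError("distances must be non-negative with zero diagonal")
    a = -0.5 * d * d
    row = a.mean(axis=1, keepdims=True)
    col = a.mean(axis=0, keepdims=True)
    return a - row - col + a.mean()


def _hat(x: np.ndarray) -> tuple[np.ndarray, int]:
    """Hat projector of a centred design; returns (H, rank)."""
    xc = x - x.mean(axis=0)
    u, s, _ = np.linalg.svd(xc, full_matrices=False)
    rank = int((s > s.max() * 1e-10).sum()) if s.size and s.max() > 0 else 0
    u = u[:, :rank]
    return u @ u.T, rank


def _perm_stats(g: np.ndarray, h: np.ndarray, perms: np.ndarray, m: int, n: int) -> np.ndarray:
    """Pseudo-F for each row of ``perms`` (label permutations of G)."""
    ss_tot = np.trace(g)
    out = np.empty(perms.shape[0])
    batch = 20_000
    for lo in range(0, perms.shape[0], batch):
        p = perms[lo : lo + batch]
        gp = g[p[:, :, None], p[:, None, :]]  # B x n x n
        ss_mod = np.einsum("ij,bij->b", h, gp)
        ss_res = ss_tot - ss_mod
        out[lo : lo + batch] = (ss_mod / m) / (ss_res / (n - m - 1))
    return out


def _permutations(n: int, n_perm, seed) -> tuple[np.ndarray, str]:
    """Permutation index matrix and scheme id ("exact" or "mc")."""
    if n_perm in (None, "auto") and math.factorial(n) <= EXACT_PERM_LIMIT:
        perms = np.array(list(itertools.permutations(range(n))), dtype=np.int64)
        return perms, "exact"
    n_mc = 999 if n_perm in (None, "auto") else int(n_perm)
    if n_mc < 99:
        warnings.warn(f"n_perm={n_mc} is low; p-value resolution is 1/{n_mc + 1}")
    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(n) for _ in range(n_mc)], dtype=np.int64)
    return perms, "mc"


@dataclass
class DblmResult:
    """Fit of a distance-based linear model."""

    selected: list[str]
    r2: float
    adj_r2: float
    aic: float
    pseudo_f: float
    perm_p: float
    n_perm: int
    terms: pd.DataFrame  # per-term sequential SS, pseudo-F, perm p
    marginal_r2: dict[str, float]
    metadata: dict = field(default_factory=dict)
    path: list = field(default_factory=list)  # backwards-selection trail


def _fit_stats(g: np.ndarray, x: np.ndarray) -> tuple[float, float, float, int]:
    """(ss_model, ss_res, ss_total, rank) for a covariate block."""
    ss_tot = float(np.trace(g))
    if x.shape[1] == 0:
        return 0.0, ss_tot, ss_tot, 0
    h, rank = _hat(x)
    ss_mod = float(np.sum(h * g))  # tr(HG); H idempotent, G symmetric
    return ss_mod, ss_tot - ss_mod, ss_tot, rank


def _aic(n: int, ss_res: float, m: int) -> float:
    return n * math.log(max(ss_res, 1e-300) / n) + 2 * (m + 1)


def dblm_fit(
    d: np.ndarray | pd.DataFrame,
    env: pd.DataFrame,
    covariates: list[str],
    *,
    n_perm="auto",
    seed: int | None = None,
) -> DblmResult:
    """Regress distance-matrix variation on environmental covariates.

    ``d`` rows must align with ``env`` rows. ``n_perm="auto"`` uses
    exact enumeration of all n! label permutations when feasible
    (n! <= 500,000) and 999 Monte-Carlo draws otherwise; an explicit
    integer forces Monte-Carlo with that many draws. p-values are
    ``#{F_perm >= F_obs}/n!`` (exact) or ``(#+1)/(n_perm+1)`` (MC).
    Per-term rows report sequential (conditional, in the given order)
    partitions; ``marginal_r2`` reports each covariate fitted alone.
    """
    dm = d.to_numpy() if isinstance(d, pd.DataFrame) else np.asarray(d, dtype=float)
    n = dm.shape[0]
    if len(env) != n:
        raise ValueError("env rows must align with the distance matrix")
    if not covariates:
        raise ValueError("need at least one covariate")
    g = gower_center(dm)
    x_full = env[covariates].to_numpy(dtype=float)
    if not np.isfinite(x_full).all():
        raise ValueError("covariates must be finite")

    ss_mod, ss_res, ss_tot, m = _fit_stats(g, x_full)
    if m < len(covariates):
        warnings.warn(f"design is rank deficient (rank {m} < {len(covariates)} covariates)")
    if n - m - 1 <= 0:
        raise ValueError("not enough residual degrees of freedom")
    if ss_tot <= 1e-300:
        # degenerate response: no distance variation to explain
        return DblmResult(
            selected=list(covariates), r2=0.0, adj_r2=0.0, aic=_aic(n, 0.0, m),
            pseudo_f=0.0, perm_p=1.0, n_perm=0,
            terms=pd.DataFrame(
                {"term": covariates, "seq_ss": 0.0, "seq_pseudo_f": 0.0,
                 "marginal_pseudo_f": 0.0, "perm_p": 1.0}
            ),
            marginal_r2=dict.fromkeys(covariates, 0.0),
            metadata={"permutation_scheme": "none", "aic_form": "n*ln(SS_res/n)+2(m+1)",
                      "seed": seed, "n": n, "ss_total": 0.0},
        )
    r2 = ss_mod / ss_tot if ss_tot > 0 else 0.0
    adj_r2 = 1 - (1 - r2) * (n - 1) / (n - m - 1)
    f_obs = (ss_mod / m) / (ss_res / (n - m - 1)) if m else 0.0

    h_full, _ = _hat(x_full)
    perms, scheme = _permutations(n, n_perm, seed)
    f_perm = _perm_stats(g, h_full, perms, m, n)
    if scheme == "exact":
        p = float(np.mean(f_perm >= f_obs - 1e-12))
    else:
        p = float((np.sum(f_perm >= f_obs - 1e-12) + 1) / (len(perms) + 1))

    # sequential per-term partition, permutation-tested with the term's
    # marginal hat projector (unrestricted label permutation scheme)
    rows = []
    prev_ss = 0.0
    for t in range(1, len(covariates) + 1):
        x_t = env[covariates[:t]].to_numpy(dtype=float)
        ss_t, _, _, _ = _fit_stats(g, x_t)
        seq_ss = ss_t - prev_ss
        prev_ss = ss_t
        f_t = (seq_ss / 1) / (ss_res / (n - m - 1))
        h_t, rank_t = _hat(env[[covariates[t - 1]]].to_numpy(dtype=float))
        f_marg = _perm_stats(g, h_t, perms, max(rank_t, 1), n)
        ss_m, ss_r, _, _ = _fit_stats(g, env[[covariates[t - 1]]].to_numpy(dtype=float))
        f_marg_obs = (ss_m / max(rank_t, 1)) / (ss_r / (n - max(rank_t, 1) - 1))
        if scheme == "exact":
            p_t = float(np.mean(f_marg >= f_marg_obs - 1e-12))
        else:
            p_t = float((np.sum(f_marg >= f_marg_obs - 1e-12) + 1) / (len(perms) + 1))
        rows.append(
            {
                "term": covariates[t - 1],
                "seq_ss": seq_ss,
                "seq_pseudo_f": f_t,
                "marginal_pseudo_f": f_marg_obs,
                "perm_p": p_t,
            }
        )
    marginal = {}
    for c in covariates:
        ss_c, _, _, _ = _fit_stats(g, env[[c]].to_numpy(dtype=float))
        marginal[c] = ss_c / ss_tot if ss_tot > 0 else 0.0

    return DblmResult(
        selected=list(covariates),
        r2=float(r2),
        adj_r2=float(adj_r2),
        aic=float(_aic(n, ss_res, m)),
        pseudo_f=float(f_obs),
        perm_p=p,
        n_perm=int(len(perms)),
        terms=pd.DataFrame(rows),
        marginal_r2=marginal,
        metadata={
            "permutation_scheme": scheme,
            "aic_form": "n*ln(SS_res/n)+2(m+1)",
            "seed": seed,
            "n": n,
            "ss_total": ss_tot,
        },
    )


def dblm_select(
    d: np.ndarray | pd.DataFrame,
    env: pd.DataFrame,
    candidates: list[str],
    *,
    criterion: str = "aic",
    n_perm="auto",
    seed: int | None = None,
) -> DblmResult:
    """Backwards elimination on adjusted R^2 or AIC.

    Starting from the full candidate set, repeatedly drop the covariate
    whose removal most improves the criterion until no removal improves
    it (the empty model is a legal endpoint under AIC). Deterministic
    given the candidate order and seed; the elimination trail is
    returned in ``result.path``.
    """
    if criterion not in ("aic", "adj_r2"):
        raise ValueError("criterion must be 'aic' or 'adj_r2'")
    dm = d.to_numpy() if isinstance(d, pd.DataFrame) else np.asarray(d, dtype=float)
    g = gower_center(dm)
    n = dm.shape[0]
    ss_tot = float(np.trace(g))

    def crit(cols: list[str]) -> float:
        ss_mod, ss_res, _, m = _fit_stats(g, env[cols].to_numpy(dtype=float)) if cols else (
            0.0,
            ss_tot,
            ss_tot,
            0,
        )
        if n - m - 1 <= 0:
            return math.inf
        if criterion == "aic":
            return _aic(n, ss_res, m)
        r2 = ss_mod / ss_tot if ss_tot > 0 else 0.0
        return -(1 - (1 - r2) * (n - 1) / (n - m - 1))  # lower = better

    current = list(candidates)
    path = [("start", list(current), crit(current))]
    while current:
        best_drop, best_val = None, crit(current)
        for c in current:
            trial = [x for x in current if x != c]
            v = crit(trial)
            if v < best_val - 1e-12:
                best_drop, best_val = c, v
        if best_drop is None:
            break
        current.remove(best_drop)
        path.append((f"drop {best_drop}", list(current), best_val))

    if not current:
        res = DblmResult(
            selected=[],
            r2=0.0,
            adj_r2=0.0,
            aic=float(_aic(n, ss_tot, 0)),
            pseudo_f=0.0,
            perm_p=1.0,
            n_perm=0,
            terms=pd.DataFrame(columns=["term", "seq_ss", "seq_pseudo_f", "marginal_pseudo_f", "perm_p"]),
            marginal_r2={},
        )
    else:
        res = dblm_fit(dm, env, current, n_perm=n_perm, seed=seed)
    res.path = path
    res.metadata["criterion"] = criterion
    return res


def principal_coordinates(d: np.ndarray | pd.DataFrame, n_axes: int = 2) -> pd.DataFrame:
    """Principal-coordinate (metric MDS) axes of a distance matrix."""
    dm = d.to_numpy() if isinstance(d, pd.DataFrame) else np.asarray(d, dtype=float)
    g = gower_center(dm)
    vals, vecs = np.linalg.eigh(g)
    order = np.argsort(vals)[::-1][:n_axes]
    coords = vecs[:, order] * np.sqrt(np.clip(vals[order], 0, None))
    # sign convention: largest-magnitude loading positive
    for j in range(coords.shape[1]):
        k = np.argmax(np.abs(coords[:, j]))
        if coords[k, j] < 0:
            coords[:, j] = -coords[:, j]
    index = d.index if isinstance(d, pd.DataFrame) else pd.RangeIndex(dm.shape[0])
    return pd.DataFrame(coords, index=index, columns=[f"axis{j + 1}" for j in range(coords.shape[1])])


# ---------------------------------------------------------------------------
# light gradient statistics


def oneway_anova(groups: list) -> tuple[float, tuple[int, int], float]:
    """Classical one-way ANOVA: returns (F, (df_between, df_within), p)."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    ns = [len(g) for g in groups]
    df1, df2 = len(groups) - 1, sum(ns) - len(groups)
    if df2 < 1:
        raise ValueError("need at least 2 total residual degrees of freedom")
    allv = np.concatenate(groups)
    if np.ptp(allv) == 0:
        return 0.0, (df1, df2), 1.0
    f, p = stats.f_oneway(*groups)
    return float(f), (df1, df2), float(p)


def tukey_hsd(groups: list, *, alpha: float = 0.05, labels: list[str] | None = None) -> pd.DataFrame:
    """All-pairs Tukey honest significant differences.

    Studentized-range quantiles come from scipy. Returns a tidy frame
    with columns ``a, b, diff, p, low, high, significant``.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    labels = labels or [str(i) for i in range(len(groups))]
    allv = np.concatenate(groups)
    rows = []
    if np.ptp(allv) == 0:
        for i, j in itertools.combinations(range(len(groups)), 2):
            rows.append({"a": labels[i], "b": labels[j], "diff": 0.0, "p": 1.0,
                         "low": 0.0, "high": 0.0, "significant": False})
        return pd.DataFrame(rows)
    res = stats.tukey_hsd(*groups)
    ci = res.confidence_interval(confidence_level=1 - alpha)
    for i, j in itertools.combinations(range(len(groups)), 2):
        rows.append(
            {
                "a": labels[i],
                "b": labels[j],
                "diff": float(np.mean(groups[i]) - np.mean(groups[j])),
                "p": float(res.pvalue[i, j]),
                "low": float(ci.low[i, j]),
                "high": float(ci.high[i, j]),
                "significant": bool(res.pvalue[i, j] < alpha),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class GradientFit:
    """Summary of a per-covariate distance-gradient regression."""

    family: str
    params: dict[str, float]
    r2: float
    p: float
    pairwise: pd.DataFrame | None = None  # categorical family only


def gradient_fit(y, x, family: str = "linear") -> GradientFit:
    """Describe a spatial pattern along the gradient.

    family="linear"
        OLS of y on x; params slope/intercept.
    family="exponential-decay"
        Least squares fit of ``y = a * exp(-b * x)``; params a (scale)
        and b (decay rate per rank unit); p from the F test against the
        constant model.
    family="categorical"
        One-way model with x as group labels (replicated y) and
        Bonferroni-adjusted pairwise Welch comparisons.
    """
    if family == "categorical":
        df = pd.DataFrame({"y": np.asarray(y, dtype=float), "g": np.asarray(x)})
        groups = [g["y"].to_numpy() for _, g in df.groupby("g", sort=True)]
        labels = [str(k) for k, _ in df.groupby("g", sort=True)]
        f, (df1, df2), p = oneway_anova(groups)
        grand = df["y"].mean()
        ss_tot = float(((df["y"] - grand) ** 2).sum())
        ss_b = float(sum(len(g) * (g.mean() - grand) ** 2 for g in groups))
        n_pairs = len(groups) * (len(groups) - 1) // 2
        rows = []
        for i, j in itertools.combinations(range(len(groups)), 2):
            if np.ptp(np.concatenate([groups[i], groups[j]])) == 0:
                p_ij = 1.0
            else:
                p_ij = float(stats.ttest_ind(groups[i], groups[j], equal_var=False).pvalue)
            rows.append(
                {
                    "a": labels[i],
                    "b": labels[j],
                    "diff": float(groups[i].mean() - groups[j].mean()),
                    "p_bonferroni": min(1.0, p_ij * n_pairs),
                }
            )
        return GradientFit(
            family="categorical",
            params={"F": f, "df1": df1, "df2": df2},
            r2=ss_b / ss_tot if ss_tot > 0 else 0.0,
            p=p,
            pairwise=pd.DataFrame(rows),
        )

    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if len(y) != len(x):
        raise ValueError("y and x must have equal length")
    if len(y) < 3:
        raise ValueError("need at least 3 sites")

    if family == "linear":
        if np.ptp(y) == 0:
            return GradientFit("linear", {"slope": 0.0, "intercept": float(y[0])}, 0.0, 1.0)
        res = stats.linregress(x, y)
        return GradientFit(
            family="linear",
            params={"slope": float(res.slope), "intercept": float(res.intercept)},
            r2=float(res.rvalue**2),
            p=float(res.pvalue),
        )
    if family == "exponential-decay":
        y_pos = np.maximum(np.abs(y), 1e-12)
        b0 = -np.polyfit(x, np.log(y_pos), 1)[0]
        a0 = float(np.exp(np.polyfit(x, np.log(y_pos), 1)[1]))
        popt, _ = optimize.curve_fit(
            lambda t, a, b: a * np.exp(-b * t), x, y, p0=[a0, max(b0, 1e-6)], maxfev=10000
        )
        fitted = popt[0] * np.exp(-popt[1] * x)
        ss_res = float(((y - fitted) ** 2).sum())
        ss_tot = float(((y - y.mean()) ** 2).sum())
        r2 = 1 - ss_res / ss_tot if ss_tot > 0 else 0.0
        n, k = len(y), 2
        if ss_res <= 0 or ss_tot <= 0:
            p = 0.0 if ss_tot > 0 else 1.0
        else:
            f = ((ss_tot - ss_res) / (k - 1)) / (ss_res / (n - k))
            p = float(stats.f.sf(f, k - 1, n - k))
        return GradientFit(
            family="exponential-decay",
            params={"a": float(popt[0]), "b": float(popt[1])},
            r2=float(r2),
            p=p,
        )
    raise ValueError(f"unknown family {family!r}")
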