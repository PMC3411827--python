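"""End-to-end composition of the analysis stages.

isotope ingest -> trophic correction -> feasible-solution mixing per
site -> community richness/accumulation/traits -> distance-based model
selection, with tidy CSV outputs and a reproducibility manifest.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from . import community as comm
from . import inference, mixing, simulate
from .io import RunManifest, validate_tables
from .isotopes import DEFAULT_TEF, correct_sources, read_consumers, read_sources

__all__ = ["run_pipeline", "DEFAULT_COVARIATES"]

log = logging.getLogger("outwelling")

DEFAULT_COVARIATES = [
    "distance_rank",
    "organic_pct",
    "carbonate_pct",
    "chla_ug_g",
    "dosinia_density",
    "dosinia_size_mm",
]


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, lineterminator="\n", float_format="%.10g")


def run_pipeline(
    outdir: str | Path,
    *,
    seed: int = 0,
    scenario: simulate.ScenarioConfig | None = None,
    inputs: dict[str, str] | None = None,
    mixing_config: mixing.MixingConfig | None = None,
    covariates: list[str] | None = None,
    criterion: str = "aic",
    n_perm="auto",
    accumulation_permutations: int = 50,
) -> dict[str, Path]:
    """Run every stage and write outputs + manifest into ``outdir``.

    Either ``scenario`` (synthetic mode: inputs are generated into
    ``outdir/inputs``) or ``inputs`` (paths to sources/consumers/
    community/traits/env CSVs) must be given. Returns name -> path of
    outputs. All randomness (generation, accumulation subsampling,
    Monte-Carlo permutations) derives from ``seed``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = mixing_config or mixing.MixingConfig()
    covariates = covariates or DEFAULT_COVARIATES

    if scenario is None and inputs is None:
        scenario = simulate.ScenarioConfig(seed=seed)
    if scenario is not None:
        bundle = simulate.generate_all(scenario)
        inputs = simulate.write_bundle(bundle, outdir / "inputs")
        log.info("generated synthetic scenario (seed %d) in %s", scenario.seed, outdir / "inputs")

    report = validate_tables({k: v for k, v in inputs.items() if k in ("sources", "consumers", "community", "traits", "env")})
    report.raise_if_invalid()
    for issue in report.warnings:
        log.warning("%s: %s", issue.table, issue.message)

    outputs: dict[str, Path] = {}

    # --- isotope mixing per estuary ---------------------------------------
    sources = read_sources(inputs["sources"], allow_implausible=True)
    consumers = read_consumers(inputs["consumers"], allow_implausible=True)
    env = pd.read_csv(inputs["env"])
    site_loc = dict(zip(env["site_id"].astype(str), env["location"]))
    log.info("mixing: TEF=(%.1f, %.1f), increment=%d%%, tolerance %.1f..%.1f step %.1f, metric=%s",
             DEFAULT_TEF.d13c, DEFAULT_TEF.d15n, cfg.increment, cfg.tol_start, cfg.tol_max,
             cfg.tol_step, cfg.metric)
    tables = []
    for estuary, sset in sources.items():
        corrected = correct_sources(sset, DEFAULT_TEF)
        sub = consumers[consumers["site_id"].map(site_loc) == estuary]
        if sub.empty:
            log.warning("no consumers mapped to estuary %s; skipped", estuary)
            continue
        profiles = mixing.site_profile(sub, corrected, cfg)
        tab = mixing.profile_table(profiles)
        tab.insert(0, "location", estuary)
        tables.append(tab)
    feasible = pd.concat(tables, ignore_index=True)
    _write(feasible, outdir / "feasible.csv")
    outputs["feasible"] = outdir / "feasible.csv"

    # --- community stage ---------------------------------------------------
    community = comm.CommunityMatrix.from_long(pd.read_csv(inputs["community"]))
    rich_rows, accum = [], []
    for location in sorted(env["location"].unique()):
        mask = community.sample_meta["location"] == location
        sub = community.subset(community.counts.index[mask])
        res = comm.chao2(sub)
        rich_rows.append(
            {
                "location": location,
                "m": res.summary.m,
                "s_obs": res.summary.s_obs,
                "q1": res.summary.q1,
                "q2": res.summary.q2,
                "chao2": res.estimate,
                "se": res.se,
                "variant": res.variant,
            }
        )
        curve = comm.accumulation_curve(sub, permutations=accumulation_permutations, seed=seed + 101)
        curve.insert(0, "location", location)
        accum.append(curve)
    _write(pd.DataFrame(rich_rows), outdir / "richness.csv")
    _write(pd.concat(accum, ignore_index=True), outdir / "accumulation.csv")
    outputs["richness"] = outdir / "richness.csv"
    outputs["accumulation"] = outdir / "accumulation.csv"

    by_site = community.pool_by("site_id")
    trait_table = None
    if "traits" in inputs and Path(inputs["traits"]).exists():
        traits = comm.TraitMatrix.from_wide(pd.read_csv(inputs["traits"]))
        trait_table = comm.trait_expand(by_site, traits, on_missing="warn")
        out = trait_table.reset_index().rename(columns={"index": "site_id"})
        _write(out, outdir / "trait_abundance.csv")
        outputs["trait_abundance"] = outdir / "trait_abundance.csv"
    else:
        log.warning("traits table missing; trait stage skipped")

    # --- distance-based models per location --------------------------------
    dblm_rows, ord_tables = [], []
    env = env.set_index("site_id")
    for location in sorted(env["location"].unique()):
        loc_env = env[env["location"] == location]
        loc_sites = [s for s in by_site.index if s in loc_env.index]
        loc_env = loc_env.loc[loc_sites]
        norm = inference.normalize_env(loc_env.reset_index(), covariates).set_index("site_id")
        responses = {"community": by_site.loc[loc_sites]}
        if trait_table is not None:
            responses["traits"] = trait_table.loc[loc_sites]
        for resp_name, matrix in responses.items():
            d = comm.dissimilarity_matrix(matrix)
            res = inference.dblm_select(
                d, norm, list(covariates), criterion=criterion, n_perm=n_perm, seed=seed + 202
            )
            dblm_rows.append(
                {
                    "location": location,
                    "response": resp_name,
                    "selected": ";".join(res.selected),
                    "r2": res.r2,
                    "adj_r2": res.adj_r2,
                    "aic": res.aic,
                    "pseudo_f": res.pseudo_f,
                    "perm_p": res.perm_p,
                    "n_perm": res.n_perm,
                    "distance_marginal_r2": inference.dblm_fit(
                        d, norm, ["distance_rank"], n_perm=199, seed=seed + 203
                    ).r2,
                }
            )
            if resp_name == "community":
                coords = inference.principal_coordinates(d)
                coords.insert(0, "location", location)
                ord_tables.append(coords.reset_index().rename(columns={"index": "site_id"}))
    _write(pd.DataFrame(dblm_rows), outdir / "dblm.csv")
    _write(pd.concat(ord_tables, ignore_index=True), outdir / "ordination.csv")
    outputs["dblm"] = outdir / "dblm.csv"
    outputs["ordination"] = outdir / "ordination.csv"

    manifest = RunManifest.create(
        seed=seed,
        parameters={
            "tef": [DEFAULT_TEF.d13c, DEFAULT_TEF.d15n],
            "increment": cfg.increment,
            "tol_start": cfg.tol_start,
            "tol_step": cfg.tol_step,
            "tol_max": cfg.tol_max,
            "metric": cfg.metric,
            "criterion": criterion,
            "n_perm": str(n_perm),
            "accumulation_permutations": accumulation_permutations,
            "covariates": covariates,
        },
        input_paths=inputs,
    )
    manifest.write(outdir / "manifest.json")
    outputs["manifest"] = outdir / "manifest.json"
    return outputs
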