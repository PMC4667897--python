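"""End-to-end orchestration of the three analyses.

``run_all`` wires the stages together: simulate (or load) the stomach,
survey and trial tables; run the dietary analysis (diet summaries, the
all/sympatric/allopatric × {%IRI, %N, %W} Pianka overlap grid with RA3
null models, per-species diet PERMANOVA on %W and SIMPER for significant
terms); the spatial analysis (co-occurrence summary, MaxN strata,
community PERMANOVA); and the mesocosm analysis (trial summaries,
consumption contrasts, both regressions).  Every stage writes one JSON
result file plus a run manifest recording seed, config hash and input
checksums; identical config + seed reproduces identical bytes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import community, diet, io, mesocosm, overlap, spatial, synthetic
from .schemas import CategoryMap, ValidationError, depth_bin_label

DEFAULT_CONFIG: dict[str, Any] = {
    "simulate": {
        "stomachs": {"n_per_species": {"RS": 216, "VS": 154}},
        "survey": {},
        "trials": {},
        "sympatric_prob": 0.67,
    },
    "diet": {
        "estimator": "pooled",
        "iri_variant": "additive",
        "category_map": "identity",
        "permanova_terms": [
            "season", "reef_type", "depth_bin", "cohabitation",
            "season:reef_type", "season:depth_bin", "season:cohabitation",
            "reef_type:depth_bin", "reef_type:cohabitation", "depth_bin:cohabitation",
        ],
        "perms": 999,
        "depth_preset": "diet_2_bins",
        "dummy_value": 1.0,
        "simper_alpha": 0.05,
    },
    "overlap": {"algorithm": "RA3", "reps": 1000,
                "metrics": ["pctIRI", "pctN", "pctW"]},
    "spatial": {"bin_preset": "community_20m_bins", "perms": 999,
                "dummy_value": 1.0},
    "mesocosm": {"method": "welch", "grid_minutes": None, "pool_trials": False},
}


def load_config(path: str | Path | None) -> dict[str, Any]:
    """YAML config merged over the defaults (two levels deep)."""
    cfg = {k: (dict(v) if isinstance(v, dict) else v) for k, v in DEFAULT_CONFIG.items()}
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        for k, v in user.items():
            if isinstance(v, Mapping) and isinstance(cfg.get(k), dict):
                cfg[k].update(v)
            else:
                cfg[k] = v
    return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage_seed(seed: int, offset: int) -> int:
    return (int(seed) * 1009 + offset) % (2**31 - 1)


def _cohabitation_by_site(survey_obs) -> dict[str, str]:
    presence = spatial.combine_detections(survey_obs)
    if presence.empty:
        return {}
    by_site = presence.groupby(level="site_id").any()
    return {site: ("sympatric" if row["RS"] and row["VS"] else "allopatric")
            for site, row in by_site.iterrows()}


def _diet_w_matrix(samples, categories, depth_preset):
    """Per-stomach %W matrix (stomachs with identifiable prey only) plus
    the factor table for the diet PERMANOVA."""
    kept = [s for s in samples if s.has_identifiable_prey]
    ids, rows, fac = [], [], []
    for s in kept:
        w = pd.Series(0.0, index=list(categories))
        for item in s.identifiable_items:
            w[item.taxon] += item.weight
        if w.sum() == 0:
            continue  # all weights below scale resolution
        ids.append(s.fish_id)
        rows.append(100.0 * w / w.sum())
        fac.append({"season": s.season, "reef_type": s.reef_type,
                    "depth_bin": depth_bin_label(s.depth, depth_preset),
                    "cohabitation": s.cohabitation or "allopatric"})
    values = np.vstack([r.to_numpy() for r in rows]) if rows else np.empty((0, len(categories)))
    return community.SampleMatrix(
        sample_ids=tuple(ids), variables=tuple(categories), values=values,
        factors=pd.DataFrame(fac, index=ids))


def _usable_terms(factors: pd.DataFrame, terms) -> tuple[list[str], list[str]]:
    """Filter a term list to those estimable on this factor table
    (>= 2 levels per factor, nonzero incremental rank)."""
    usable, dropped = [], []
    design = np.ones((len(factors), 1))
    rank = 1
    for t in terms:
        facs = [f.strip() for f in t.split(":")]
        if any(factors[f].nunique() < 2 for f in facs):
            dropped.append(t)
            continue
        cols = community._term_design(factors, t)
        cand = np.column_stack([design, cols])
        _, r = community._hat(cand)
        if r == rank or r >= len(factors):  # aliased, or no residual df left
            dropped.append(t)
            continue
        design, rank = cand, r
        usable.append(t)
    return usable, dropped


def run_dietary_analysis(samples, cmap: CategoryMap | None, cfg: Mapping[str, Any],
                         seed: int, cohab_by_site: Mapping[str, str] | None = None
                         ) -> dict[str, Any]:
    dcfg, ocfg = cfg["diet"], cfg["overlap"]
    if cmap is not None:
        samples = diet.condense_categories(samples, cmap)
    samples = diet.filter_contents(samples)
    if cohab_by_site:
        samples = [dataclasses.replace(s, cohabitation=s.cohabitation
                                       or cohab_by_site.get(s.site_id))
                   for s in samples]
    categories = sorted({i.taxon for s in samples for i in s.identifiable_items})

    # diet summaries and the overlap grid over cohabitation strata
    strata = {"all": lambda s: True,
              "sympatric": lambda s: s.cohabitation == "sympatric",
              "allopatric": lambda s: s.cohabitation == "allopatric"}
    summaries: dict[str, dict[str, diet.DietSummary]] = {}
    grid: dict[str, dict[str, overlap.NullModelResult]] = {}
    for si, (stratum, pred) in enumerate(strata.items()):
        summaries[stratum] = {}
        for sp in ("RS", "VS"):
            sub = [s for s in samples if s.species == sp and pred(s)]
            if not any(s.has_identifiable_prey for s in sub):
                continue
            summaries[stratum][sp] = diet.diet_summary(
                sub, estimator=dcfg["estimator"], iri_variant=dcfg["iri_variant"],
                species=sp, stratum=stratum, categories=categories)
        if set(summaries[stratum]) != {"RS", "VS"}:
            continue
        grid[stratum] = {}
        for mi, metric in enumerate(ocfg["metrics"]):
            mat = overlap.UtilizationMatrix(
                species=("RS", "VS"), categories=tuple(categories),
                values=np.vstack([getattr(summaries[stratum][sp], metric).to_numpy()
                                  for sp in ("RS", "VS")]))
            grid[stratum][metric] = overlap.null_model_test(
                mat, algorithm=ocfg["algorithm"], reps=int(ocfg["reps"]),
                seed=_stage_seed(seed, 100 + 10 * si + mi))
    # per-species PERMANOVA on %W and SIMPER for significant terms
    permanova_results: dict[str, Any] = {}
    simper_results: dict[str, Any] = {}
    for pi, sp in enumerate(("RS", "VS")):
        sm = _diet_w_matrix([s for s in samples if s.species == sp],
                            categories, dcfg["depth_preset"])
        if len(sm.sample_ids) < 6:
            permanova_results[sp] = {"skipped": "fewer than 6 stomachs with prey"}
            continue
        transformed = community.sqrt_transform(sm.values)
        dist = community.zero_adjusted_bray_curtis(transformed, dcfg["dummy_value"])
        terms, dropped = _usable_terms(sm.factors, dcfg["permanova_terms"])
        if not terms:
            permanova_results[sp] = {"skipped": "no estimable model terms"}
            continue
        res = community.permanova(dist, sm.factors, terms, perms=int(dcfg["perms"]),
                                  seed=_stage_seed(seed, 200 + pi))
        permanova_results[sp] = {"result": res, "dropped_terms": dropped}
        simper_results[sp] = {}
        for t in res.terms:
            if ":" in t.term or t.p_perm is None or t.p_perm > dcfg["simper_alpha"]:
                continue
            levels = sorted(sm.factors[t.term].unique())
            simper_results[sp][t.term] = community.simper(
                transformed, categories, sm.factors[t.term].to_numpy(),
                (levels[0], levels[1]), dummy_value=dcfg["dummy_value"])
    return {"summaries": summaries, "overlap_grid": grid,
            "permanova": permanova_results, "simper": simper_results}


def run_spatial_analysis(observations, cfg: Mapping[str, Any], seed: int) -> dict[str, Any]:
    scfg = cfg["spatial"]
    presence = spatial.combine_detections(observations)
    cooc = spatial.cooccurrence_summary(presence)
    strata = (spatial.maxn_by_stratum(observations, ("reef_type",))
              + spatial.maxn_by_stratum(observations, ("depth_bin",), scfg["bin_preset"])
              + spatial.maxn_by_stratum(observations, ("reef_type", "depth_bin"),
                                        scfg["bin_preset"]))
    values, sample_ids, species, factors = spatial.maxn_sample_matrix(
        observations, scfg["bin_preset"])
    out: dict[str, Any] = {"cooccurrence": cooc, "strata": strata}
    if values.sum() == 0:
        out["permanova"] = {"skipped": "all MaxN zero: no community structure to test"}
        return out
    dist = community.zero_adjusted_bray_curtis(
        community.sqrt_transform(values), scfg["dummy_value"])
    terms, dropped = _usable_terms(factors, ["depth_bin", "reef_type",
                                             "depth_bin:reef_type"])
    res = community.permanova(dist, factors, terms, perms=int(scfg["perms"]),
                              seed=_stage_seed(seed, 300))
    pairwise = {}
    bins = sorted(factors["depth_bin"].unique())
    for i, a in enumerate(bins):
        for b in bins[i + 1:]:
            try:
                pw = community.pairwise_permanova(dist, factors, "depth_bin", (a, b),
                                                  perms=int(scfg["perms"]),
                                                  seed=_stage_seed(seed, 310 + i))
                pairwise[f"{a} vs {b}"] = pw
            except ValidationError as e:
                pairwise[f"{a} vs {b}"] = {"skipped": str(e)}
    out["permanova"] = {"result": res, "dropped_terms": dropped, "pairwise": pairwise}
    return out


def run_mesocosm_analysis(events, trial_treatments: Mapping[str, str],
                          cfg: Mapping[str, Any], seed: int) -> dict[str, Any]:
    mcfg = cfg["mesocosm"]
    summaries = mesocosm.summarize_trials(events, trial_treatments)
    contrast_pairs = [
        ("RS_alone_vs_VS_alone", ("RS6", "RS"), ("VS6", "VS")),
        ("RS_mixed_vs_VS_mixed", ("MIX33", "RS"), ("MIX33", "VS")),
        ("RS_mixed_vs_RS_alone", ("MIX33", "RS"), ("RS6", "RS")),
        ("VS_mixed_vs_VS_alone", ("MIX33", "VS"), ("VS6", "VS")),
    ]
    contrasts: dict[str, Any] = {}
    for ci, (name, a, b) in enumerate(contrast_pairs):
        entry = {}
        for method in ("welch", "permutation"):
            try:
                entry[method] = mesocosm.compare_consumption(
                    summaries, a, b, method=method, seed=_stage_seed(seed, 400 + ci))
            except ValidationError as e:
                entry[method] = {"skipped": str(e)}
        contrasts[name] = entry
    out: dict[str, Any] = {"trials": summaries, "contrasts": contrasts}
    try:
        out["success_rate_regression"] = mesocosm.success_rate_regression(summaries)
    except ValidationError as e:
        out["success_rate_regression"] = {"skipped": str(e)}
    try:
        out["feeding_rate_model"] = mesocosm.feeding_rate_model(
            list(events), grid_minutes=mcfg["grid_minutes"],
            pool_trials=bool(mcfg["pool_trials"]))
    except ValidationError as e:
        out["feeding_rate_model"] = {"skipped": str(e)}
    return out


def run_all(config: str | Path | Mapping[str, Any] | None, seed: int,
            outdir: str | Path) -> dict[str, Any]:
    """Simulate inputs, run the three analyses, write results + manifest.

    Returns the in-memory results; on disk, ``inputs/`` holds the
    generated tables, ``results/`` one JSON file per analysis, and
    ``manifest.json`` the reproducibility record.
    """
    if seed is None:
        raise ValidationError("a seed is required in pipeline mode")
    cfg = config if isinstance(config, Mapping) else load_config(config)
    cfg = {**{k: v for k, v in DEFAULT_CONFIG.items()}, **cfg}
    outdir = Path(outdir)
    inputs_dir = outdir / "inputs"
    results_dir = outdir / "results"
    inputs_dir.mkdir(parents=True, exist_ok=True)
    results_dir.mkdir(parents=True, exist_ok=True)

    sim = cfg["simulate"]
    rng_sites = np.random.default_rng(_stage_seed(seed, 1))
    sites = synthetic.make_sites(
        sim.get("survey", {}).get("n_sites", 40), (20.0, 100.0), rng_sites,
        sympatric_prob=float(sim.get("sympatric_prob", 0.67)))

    stomach_df = synthetic.simulate_stomachs(
        synthetic.DietGeneratorParams(),
        sim["stomachs"]["n_per_species"], seed=_stage_seed(seed, 2), sites=sites)
    survey_df = synthetic.simulate_survey(
        synthetic.SurveyGeneratorParams(**sim.get("survey", {})),
        seed=_stage_seed(seed, 3), sites=sites)
    trials_df, design = synthetic.simulate_trials(
        synthetic.TrialGeneratorParams(**sim.get("trials", {})),
        seed=_stage_seed(seed, 4))

    paths = {}
    for name, df in [("stomachs.csv", stomach_df), ("survey.csv", survey_df),
                     ("trials.csv", trials_df)]:
        p = inputs_dir / name
        df.to_csv(p, index=False)
        paths[name] = p
    design_path = inputs_dir / "trial_design.csv"
    pd.DataFrame(sorted(design.items()), columns=["trial_id", "treatment"]
                 ).to_csv(design_path, index=False)
    paths["trial_design.csv"] = design_path

    # everything below consumes the written files through the readers —
    # the generators' round-trip contract is exercised on every run
    samples = io.read_stomach_table(paths["stomachs.csv"])
    observations = io.read_survey_table(paths["survey.csv"])
    events = io.read_trial_log(paths["trials.csv"])

    cohab = _cohabitation_by_site(observations)
    results = {
        "dietary": run_dietary_analysis(samples, None, cfg, seed, cohab),
        "spatial": run_spatial_analysis(observations, cfg, seed),
        "mesocosm": run_mesocosm_analysis(events, design, cfg, seed),
    }
    stage_files = {}
    for stage, res in results.items():
        f = results_dir / f"{stage}.json"
        io.write_result(res, f)
        stage_files[stage] = f.name

    cfg_hash = hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()
    manifest = {
        "seed": int(seed),
        "config_sha256": cfg_hash,
        "inputs": {n: _sha256(p) for n, p in paths.items()},
        "stages": {s: {"status": "ok", "output": f} for s, f in stage_files.items()},
    }
    io.write_result(manifest, outdir / "manifest.json")
    return results
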