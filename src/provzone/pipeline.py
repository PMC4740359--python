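"""Full-analysis orchestration: diversity -> AMOVA -> ANOSIM -> delineation ->
outlier scan -> neutral/outlier subset re-analysis -> Mantel tests.

Stage seeds are derived from one master seed with fixed offsets, so a report
is reproducible end to end.  The marker set is re-analysed three ways — all
loci, the outlier subset and the neutral complement — because the scientific
question is whether putatively selected loci delineate the same provenance
distance as neutral variation and whether only they track climate.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import amova, anosim, delineation, diversity, mantel, outliers
from .io import (
    ClimateTable,
    DistMatrix,
    MarkerMatrix,
    SiteTable,
    ValidationError,
    geographic_distance_matrix,
    read_climate_table,
    read_marker_matrix,
    read_site_table,
)

log = logging.getLogger("provzone")

_STAGE_SEED_OFFSETS = {
    "amova": 11,
    "anosim_global": 23,
    "anosim_pairs": 37,
    "phi_pairs": 41,
    "outliers": 53,
    "mantel": 67,
}


@dataclasses.dataclass
class PipelineConfig:
    genotypes: str
    sites: str
    seed: int
    climate: str | None = None
    out_dir: str = "provzone_out"
    n_perm: int = 9999
    n_perm_pairwise: int = 999
    significance_rule: str = "sig_perm"  # or "sig_globalR"
    alpha: float = 0.05
    fit_degree: int = 2
    log10_po_threshold: float = 2.0
    prior_odds_neutral: float = 10.0
    mcmc_profile: str = "default"  # or "fast"
    missing_max_fraction: float = 0.05

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if self.seed is None:
            raise ValidationError("seed is mandatory")
        for p in (self.genotypes, self.sites, self.climate):
            if p is not None and not Path(p).exists():
                raise ValidationError(f"input path does not exist: {p}")
        if self.significance_rule not in ("sig_perm", "sig_globalR"):
            raise ValidationError("significance_rule must be sig_perm or sig_globalR")
        if self.mcmc_profile not in ("default", "fast"):
            raise ValidationError("mcmc_profile must be default or fast")

    def template_yaml(self) -> str:
        """All keys spelled out, so a published run is self-documenting."""
        return yaml.safe_dump(dataclasses.asdict(self), sort_keys=False)


def _stage_seed(master: int, stage: str) -> int:
    return (int(master) * 1_000 + _STAGE_SEED_OFFSETS[stage]) % (2**31 - 1)


def _genetic_analyses(
    m: MarkerMatrix,
    sites: SiteTable,
    climate_dist: DistMatrix | None,
    geo_dist_log: DistMatrix,
    cfg: PipelineConfig,
    seed_tag: int,
) -> dict:
    """AMOVA + ANOSIM + delineation (+ Mantel) for one marker set."""
    out: dict = {}
    res_amova = amova.phi_pt_test(m, n_perm=cfg.n_perm, seed=_stage_seed(seed_tag, "amova"))
    out["amova"] = {
        "phi_pt": res_amova.phi_pt,
        "p_value": res_amova.p_value,
        "pct_among": res_amova.pct_among,
        "sigma2_among": res_amova.sigma2_among,
        "sigma2_within": res_amova.sigma2_within,
        "n_perm": cfg.n_perm,
    }
    log.info("AMOVA: Phi_PT=%.3f p=%.4g (n_perm=%d seed=%d)", res_amova.phi_pt,
             res_amova.p_value, cfg.n_perm, _stage_seed(seed_tag, "amova"))

    res_global = anosim.global_anosim(
        m, n_perm=cfg.n_perm, seed=_stage_seed(seed_tag, "anosim_global")
    )
    out["anosim_global"] = {
        "R": res_global.R, "p_value": res_global.p_value, "n_perm": cfg.n_perm,
    }

    pairs_r = anosim.pairwise_anosim(
        m, n_perm=cfg.n_perm_pairwise, seed=_stage_seed(seed_tag, "anosim_pairs")
    )
    pairs_phi = amova.pairwise_phi_pt(
        m, n_perm=cfg.n_perm_pairwise, seed=_stage_seed(seed_tag, "phi_pairs")
    )
    pairs = pairs_r.merge(
        pairs_phi.drop(columns=["p_value"]), on=["pop_a", "pop_b"]
    )
    pairs = anosim.global_R_rule(pairs, res_global.R, alpha=cfg.alpha)
    pairs = delineation.build_pair_table(pairs, sites)
    out["pair_table"] = pairs

    prov = delineation.delineate(
        pairs, res_global.R, degree=cfg.fit_degree, rule=cfg.significance_rule,
        global_p=res_global.p_value, alpha=cfg.alpha,
    )
    out["provenance"] = prov.as_dict()

    # Mantel comparisons on the linearized-Phi population matrix
    gen_dist = amova.pairwise_phi_matrix(pairs, m.populations())
    mantel_results: dict[str, mantel.MantelResult] = {}
    seed_m = _stage_seed(seed_tag, "mantel")
    mantel_results["geography"] = mantel.mantel(
        gen_dist, geo_dist_log, n_perm=cfg.n_perm, seed=seed_m
    )
    if climate_dist is not None:
        mantel_results["climate"] = mantel.mantel(
            gen_dist, climate_dist, n_perm=cfg.n_perm, seed=seed_m + 1
        )
        mantel_results["climate_given_geography"] = mantel.partial_mantel(
            gen_dist, climate_dist, geo_dist_log,
            n_perm=cfg.n_perm, seed=seed_m + 2, controlled_label="geography",
        )
        mantel_results["geography_given_climate"] = mantel.partial_mantel(
            gen_dist, geo_dist_log, climate_dist,
            n_perm=cfg.n_perm, seed=seed_m + 3, controlled_label="climate",
        )
    out["mantel"] = mantel.mantel_table(mantel_results)
    return out


def run_analysis(
    m: MarkerMatrix,
    sites: SiteTable,
    climate: ClimateTable | None,
    cfg: PipelineConfig,
) -> dict:
    """Run every stage in memory and return the report bundle (dict of results)."""
    sites.cross_check(m)
    if m.has_missing():
        m = m.drop_missing(cfg.missing_max_fraction)

    bundle: dict = {"config": dataclasses.asdict(cfg)}

    div = diversity.population_diversity(m)
    try:
        regression = diversity.diversity_size_regression(
            div.per_population["n"], div.per_population["plp"]
        )
    except ValidationError as exc:  # e.g. equal sample sizes everywhere
        regression = {"undefined": str(exc)}
    bundle["diversity"] = {
        "per_population": div.per_population,
        "means": div.means.to_dict(),
        "size_regression": regression,
    }

    # climate preparation (shared across marker subsets)
    climate_dist = None
    if climate is not None:
        pruned, dropped = (climate, [])
        if len(climate.variables) >= 2:
            pruned, dropped = mantel.prune_correlated(climate)
        transformed = mantel.log_transform(pruned)
        climate_dist = mantel.climate_distance(transformed)
        bundle["climate"] = {"dropped_variables": dropped,
                            "used_variables": pruned.variables}
    geo = geographic_distance_matrix(sites)
    geo_log = DistMatrix(geo.labels, np.log10(geo.values + 1.0))

    bundle["full"] = _genetic_analyses(m, sites, climate_dist, geo_log, cfg, cfg.seed)

    profile = (
        outliers.MCMCProfile.fast() if cfg.mcmc_profile == "fast" else outliers.MCMCProfile()
    )
    scan = outliers.scan_markers(
        m,
        profile=profile,
        prior_odds_neutral=cfg.prior_odds_neutral,
        seed=_stage_seed(cfg.seed, "outliers"),
        log10_po_threshold=cfg.log10_po_threshold,
    )
    calls = outliers.call_outliers(scan, cfg.log10_po_threshold)
    bundle["outliers"] = {
        "per_locus": scan.per_locus,
        "per_population": scan.per_population,
        "dropped_loci": scan.dropped_loci,
        "calls": calls,
        "diagnostics": scan.diagnostics,
    }

    outlier_loci = calls["loci"]
    neutral_loci = [l for l in m.locus_ids if l not in set(outlier_loci)]
    bundle["locus_partition"] = {"outlier": outlier_loci, "neutral": neutral_loci}
    for name, loci in (("outlier_subset", outlier_loci), ("neutral_subset", neutral_loci)):
        if len(loci) < 2:
            bundle[name] = {"skipped": f"only {len(loci)} loci in subset"}
            continue
        bundle[name] = _genetic_analyses(
            amova.subset_loci(m, loci), sites, climate_dist, geo_log, cfg,
            cfg.seed + (1 if name == "outlier_subset" else 2),
        )
    return bundle


def run_pipeline(cfg: PipelineConfig) -> dict:
    """File-based entry point: read inputs, run all stages, write the report."""
    cfg.validate()
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    m = read_marker_matrix(cfg.genotypes)
    sites = read_site_table(cfg.sites)
    climate = read_climate_table(cfg.climate) if cfg.climate else None
    try:
        bundle = run_analysis(m, sites, climate, cfg)
        bundle["status"] = "ok"
    except Exception as exc:  # partial report with a failure record
        bundle = {"config": dataclasses.asdict(cfg), "status": "failed",
                  "error": f"{type(exc).__name__}: {exc}"}
        _write_bundle(bundle, out_dir)
        raise
    _write_bundle(bundle, out_dir)
    return bundle


def _jsonify(obj):
    if isinstance(obj, pd.DataFrame):
        return obj.reset_index().to_dict(orient="records")
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {k: _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def _write_bundle(bundle: dict, out_dir: Path) -> None:
    (out_dir / "report.json").write_text(
        json.dumps(_jsonify(bundle), indent=2, sort_keys=True), encoding="utf-8"
    )
    for key in ("full", "outlier_subset", "neutral_subset"):
        sub = bundle.get(key)
        if isinstance(sub, dict) and isinstance(sub.get("pair_table"), pd.DataFrame):
            sub["pair_table"].to_csv(out_dir / f"{key}_pairs.csv", index=False)
    div = bundle.get("diversity", {}).get("per_population")
    if isinstance(div, pd.DataFrame):
        div.to_csv(out_dir / "diversity.csv")
    ol = bundle.get("outliers", {}).get("per_locus")
    if isinstance(ol, pd.DataFrame):
        ol.to_csv(out_dir / "outlier_loci.csv")
    (out_dir / "summary.txt").write_text(summarize_report(bundle), encoding="utf-8")


def summarize_report(bundle: dict) -> str:
    """One-page human-readable summary of the headline quantities."""
    lines = ["provenance-zone analysis summary", "=" * 34]
    full = bundle.get("full")
    if isinstance(full, dict):
        am = full.get("amova", {})
        an = full.get("anosim_global", {})
        pr = full.get("provenance", {})
        lines.append(f"Phi_PT (all loci):        {am.get('phi_pt', float('nan')):.3f} "
                     f"(p = {am.get('p_value', float('nan')):.4g})")
        lines.append(f"global ANOSIM R:          {an.get('R', float('nan')):.3f} "
                     f"(p = {an.get('p_value', float('nan')):.4g})")
        d_min = pr.get("d_min_sig")
        d_prov = pr.get("d_provenance")
        d_full = pr.get("d_full_diff")
        lines.append(f"min significant distance: "
                     f"{'undefined' if d_min is None else f'{d_min:.1f} km'}")
        lines.append(f"global provenance dist.:  "
                     f"{'undefined' if d_prov is None else f'{d_prov:.1f} km'}")
        lines.append(f"full differentiation at:  "
                     f"{'n/a' if d_full is None else f'{d_full:.1f} km'}")
    else:
        lines.append("NOTICE: full-dataset stage missing")
    ol = bundle.get("outliers")
    if isinstance(ol, dict):
        calls = ol.get("calls", {})
        n = len(calls.get("loci", []))
        fdr = calls.get("fdr")
        lines.append(f"outlier loci (decisive):  {n}"
                     + (f" (FDR = {fdr:.3g})" if fdr is not None else ""))
    else:
        lines.append("NOTICE: outlier stage missing")
    for key in ("full", "outlier_subset", "neutral_subset"):
        sub = bundle.get(key)
        if isinstance(sub, dict) and isinstance(sub.get("mantel"), pd.DataFrame):
            lines.append(f"\nMantel tests ({key}):")
            for _, row in sub["mantel"].iterrows():
                ctrl = f" | {row['controlled']}" if row["controlled"] else ""
                lines.append(f"  {row['comparison']:<26s}{ctrl:<14s} "
                             f"r = {row['r']: .3f}  p = {row['p_value']:.4g}")
        elif isinstance(sub, dict) and "skipped" in sub:
            lines.append(f"\nNOTICE: {key} skipped ({sub['skipped']})")
    return "\n".join(lines) + "\n"
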