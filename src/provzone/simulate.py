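"""Synthetic dominant-marker datasets under isolation by distance.

The generator emulates the sampling design the pipeline targets: a linear
north-south transect of populations, hierarchical isolation by distance, a
monotone climate gradient, and a minority of loci whose allele frequencies
track the climate.  Population allele frequencies follow a stepping-stone
random walk on the logit scale — divergence per km is controlled directly by
``drift_scale`` rather than via explicit Wright-Fisher generations, because
divergence-per-km is exactly the quantity the delineation estimates.  Selected
loci additionally shift by ``selection_slope`` times the standardized local
climate.  Band presence for a diploid outcrossing individual is Bernoulli
with probability 1 - (1 - p)^2.

One master seed drives independent per-component bit generators (sites,
ancestral frequencies, drift walk, climate, genotypes), so changing the locus
count does not perturb site placement.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    ClimateTable,
    MarkerMatrix,
    SiteTable,
    ValidationError,
    write_climate_table,
    write_marker_matrix,
    write_site_table,
)

_KM_PER_DEG_LAT = 111.195  # pi * R / 180 at R = 6371.0088 km


@dataclasses.dataclass
class SimConfig:
    """Generator parameters; defaults mirror the study design being emulated."""

    n_pops: int = 16
    n_per_pop: int = 32
    n_loci: int = 134
    n_selected: int = 13
    transect_km: float = 160.0
    drift_scale: float = 0.02  # logit-frequency random-walk sd per km
    selection_slope: float = 1.5  # logit shift per unit standardized climate
    climate_noise: float = 0.3
    origin_lat: float = -31.5
    origin_lon: float = 116.1
    seed: int = 0

    def validate(self) -> None:
        if self.n_pops < 2:
            raise ValidationError("need >=2 populations")
        if min(self.n_per_pop, self.n_loci) < 1 or self.n_selected < 0:
            raise ValidationError("counts must be >= 1 (n_selected >= 0)")
        if self.n_selected > self.n_loci:
            raise ValidationError("n_selected exceeds n_loci")
        if min(self.drift_scale, self.selection_slope, self.climate_noise) < 0:
            raise ValidationError("scales must be >= 0")
        if self.transect_km <= 0:
            raise ValidationError("transect length must be positive")


@dataclasses.dataclass
class SimTruth:
    """Generator-side ground truth for a simulated dataset."""

    ancestral_freq: np.ndarray  # (n_loci,)
    pop_freq: np.ndarray  # (n_loci, n_pops) band-allele frequency p_ij
    selected: np.ndarray  # (n_loci,) bool
    climate: np.ndarray  # (n_pops,) standardized climate driver
    locus_ids: list[str]
    populations: list[str]

    def to_json(self) -> str:
        return json.dumps(
            {
                "ancestral_freq": self.ancestral_freq.tolist(),
                "pop_freq": self.pop_freq.tolist(),
                "selected": self.selected.astype(int).tolist(),
                "climate": self.climate.tolist(),
                "locus_ids": self.locus_ids,
                "populations": self.populations,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "SimTruth":
        d = json.loads(text)
        return cls(
            ancestral_freq=np.asarray(d["ancestral_freq"], float),
            pop_freq=np.asarray(d["pop_freq"], float),
            selected=np.asarray(d["selected"], int).astype(bool),
            climate=np.asarray(d["climate"], float),
            locus_ids=list(d["locus_ids"]),
            populations=list(d["populations"]),
        )


def band_presence_probability(p) -> np.ndarray:
    """P(band present) for a diploid under random mating: 1 - (1 - p)^2."""
    p = np.asarray(p, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValidationError("allele frequency outside [0, 1]")
    return 1.0 - (1.0 - p) ** 2


def _logit(p: np.ndarray) -> np.ndarray:
    return np.log(p) - np.log1p(-p)


def _expit(x: np.ndarray) -> np.ndarray:
    # inverse-logit keeps frequencies in (0, 1); no post-hoc truncation needed
    return 1.0 / (1.0 + np.exp(-x))


def simulate_dataset(
    cfg: SimConfig,
) -> tuple[MarkerMatrix, SiteTable, ClimateTable, SimTruth]:
    """Generate (markers, sites, climate, truth) reproducibly from cfg.seed."""
    cfg.validate()
    children = np.random.SeedSequence(cfg.seed).spawn(5)
    rng_sites, rng_freq, rng_walk, rng_clim, rng_geno = (
        np.random.default_rng(c) for c in children
    )

    pops = [f"P{k + 1:02d}" for k in range(cfg.n_pops)]
    locus_ids = [f"L{j + 1:03d}" for j in range(cfg.n_loci)]

    # evenly spaced sites heading south along a meridian, tiny longitude jitter
    step_km = cfg.transect_km / (cfg.n_pops - 1)
    lats = cfg.origin_lat - np.arange(cfg.n_pops) * step_km / _KM_PER_DEG_LAT
    lons = cfg.origin_lon + rng_sites.normal(0.0, 0.005, cfg.n_pops)
    sites = SiteTable(
        pd.DataFrame({"population": pops, "latitude": lats, "longitude": lons})
    )

    # climate driver: monotone north-south gradient plus noise, standardized
    position = np.linspace(-1.0, 1.0, cfg.n_pops)
    raw_precip = position + rng_clim.normal(0.0, cfg.climate_noise, cfg.n_pops)
    z = (raw_precip - raw_precip.mean()) / raw_precip.std()
    # emitted table: a precipitation-like and an (anticorrelated) temperature-like
    # variable on plausible physical scales
    precip_mm = 700.0 + 250.0 * (raw_precip + 1.0)
    temp_c = 20.0 - 2.5 * (position + rng_clim.normal(0.0, cfg.climate_noise, cfg.n_pops))
    climate = ClimateTable(
        pd.DataFrame(
            {"population": pops, "annual_precip_mm": precip_mm, "mean_temp_c": temp_c}
        )
    )

    # allele frequencies: ancestral + stepping-stone logit walk (+ cline)
    pi = rng_freq.uniform(0.1, 0.9, cfg.n_loci)
    selected = np.zeros(cfg.n_loci, dtype=bool)
    if cfg.n_selected:
        selected[rng_freq.choice(cfg.n_loci, size=cfg.n_selected, replace=False)] = True
    steps = rng_walk.normal(
        0.0, cfg.drift_scale * step_km, size=(cfg.n_loci, cfg.n_pops - 1)
    )
    walk = np.concatenate(
        [np.zeros((cfg.n_loci, 1)), np.cumsum(steps, axis=1)], axis=1
    )
    logit_p = _logit(pi)[:, None] + walk
    logit_p[selected] += cfg.selection_slope * z[None, :]
    p = _expit(logit_p)

    # genotypes: dominant band presence per diploid individual
    band_prob = band_presence_probability(p)  # (n_loci, n_pops)
    bands = np.empty((cfg.n_pops * cfg.n_per_pop, cfg.n_loci), dtype=np.int8)
    labels: list[str] = []
    ids: list[str] = []
    for k, pop in enumerate(pops):
        draw = rng_geno.random((cfg.n_per_pop, cfg.n_loci)) < band_prob[:, k][None, :]
        bands[k * cfg.n_per_pop : (k + 1) * cfg.n_per_pop] = draw.astype(np.int8)
        labels.extend([pop] * cfg.n_per_pop)
        ids.extend(f"{pop}_i{i + 1:03d}" for i in range(cfg.n_per_pop))

    markers = MarkerMatrix(ids, labels, locus_ids, bands)
    truth = SimTruth(
        ancestral_freq=pi,
        pop_freq=p.copy(),
        selected=selected,
        climate=z,
        locus_ids=locus_ids,
        populations=pops,
    )
    return markers, sites, climate, truth


# named fixture configurations used throughout the test suite (desk scale)
FIXTURE_CONFIGS: dict[str, SimConfig] = {
    "null": SimConfig(
        n_pops=8, n_per_pop=12, n_loci=40, n_selected=0, drift_scale=0.0,
        selection_slope=0.0, seed=101,
    ),
    "strong_ibd": SimConfig(
        n_pops=8, n_per_pop=12, n_loci=40, n_selected=0, drift_scale=0.03,
        selection_slope=0.0, seed=202,
    ),
    "selected_loci": SimConfig(
        n_pops=8, n_per_pop=16, n_loci=50, n_selected=5, drift_scale=0.01,
        selection_slope=2.0, seed=303,
    ),
}


def make_fixture_suite(out_dir) -> dict[str, dict[str, Path]]:
    """Write the named fixture datasets (markers/sites/climate/truth) to disk."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, dict[str, Path]] = {}
    for name, cfg in FIXTURE_CONFIGS.items():
        markers, sites, climate, truth = simulate_dataset(cfg)
        base = out_dir / name
        base.mkdir(exist_ok=True)
        paths = {
            "markers": write_marker_matrix(markers, base / "markers.csv"),
            "sites": write_site_table(sites, base / "sites.csv"),
            "climate": write_climate_table(climate, base / "climate.csv"),
            "truth": base / "truth.json",
            "config": base / "config.json",
        }
        paths["truth"].write_text(truth.to_json(), encoding="utf-8")
        paths["config"].write_text(
            json.dumps(dataclasses.asdict(cfg), sort_keys=True), encoding="utf-8"
        )
        written[name] = paths
    return written
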