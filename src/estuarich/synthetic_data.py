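"""Synthetic inputs with known ground truth.

Generates a complete, internally consistent set of pipeline inputs —
watershed landscape compositions, daily precipitation series, and trawl
surveys whose per-taxon counts are expanded from functional-group richness
draws of the generative model — so every stage is testable end to end
without external data.
"""

from __future__ import annotations

import json
import pathlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import trawl_prep
from .model import ModelData, ModelParams, N_BETA, simulate_counts
from .runoff import (
    CCAP_TO_GROUP,
    LULC_GROUPS,
    SOIL_GROUPS,
    CurveNumberTable,
    PrecipSeries,
    RunoffByClass,
    WatershedComposition,
    annual_runoff_by_class,
)
from .trawl_prep import FUNCTIONAL_GROUPS, TrawlRecord

__all__ = [
    "SyntheticConfig",
    "SyntheticDataset",
    "default_true_beta",
    "generate_landscape",
    "generate_survey",
    "generate_dataset",
]

_CODES_BY_GROUP: dict[str, list[int]] = {}
for _code, _group in CCAP_TO_GROUP.items():
    _CODES_BY_GROUP.setdefault(_group, []).append(_code)

#: Mean watershed fraction per land-cover group before dispersion.
DEFAULT_CLASS_FRACTIONS = {
    "developed": 0.06,
    "cropland": 0.10,
    "forest": 0.30,
    "palustrine_wetland": 0.15,
    "estuarine_wetland": 0.08,
    "barren": 0.02,
}


def default_true_beta() -> np.ndarray:
    """True coefficients at the magnitudes of the reported posterior
    medians (land-cover effects in roughly [-0.5, 0.9])."""
    return np.array(
        [
            1.00,   # intercept -> baseline richness ~ e
            0.20,   # salinity
            0.30,   # temperature
            -0.45,  # developed
            0.35,   # cropland
            0.55,   # forest
            0.30,   # palustrine wetland
            0.86,   # estuarine wetland
            -0.20,  # barren
        ]
    )


@dataclass
class SyntheticConfig:
    """Knobs of the synthetic world.  Defaults are desk scale (J=10, K=3);
    paper scale would be J=33, K=7."""

    n_estuaries: int = 10
    n_programs: int = 3
    trawls_per_estuary: int = 50
    seed: int = 0

    true_beta: np.ndarray = field(default_factory=default_true_beta)
    true_sigma2_s: float = 0.10
    re_intercept_sd: float = 0.15
    re_slope_sd: float = 0.05

    salinity_mean_range: tuple[float, float] = (5.0, 30.0)
    salinity_sd: float = 3.0
    temperature_mean_range: tuple[float, float] = (18.0, 30.0)
    temperature_sd: float = 3.0

    lulc_dispersion: float = 0.8
    class_fractions: dict = field(
        default_factory=lambda: dict(DEFAULT_CLASS_FRACTIONS)
    )
    watershed_area_range_km2: tuple[float, float] = (200.0, 2000.0)
    years_precip: int = 3
    precip_start_year: int = 2001

    def __post_init__(self) -> None:
        self.true_beta = np.asarray(self.true_beta, dtype=float)
        if self.true_beta.shape != (N_BETA,):
            raise ValueError(f"true_beta must have length {N_BETA}")
        if min(self.n_estuaries, self.n_programs, self.trawls_per_estuary) < 1:
            raise ValueError("counts must be >= 1")
        if self.true_sigma2_s < 0 or self.lulc_dispersion < 0:
            raise ValueError("variances/dispersions must be non-negative")

    def re_cov(self) -> np.ndarray:
        return np.diag(
            [self.re_intercept_sd**2, self.re_slope_sd**2, self.re_slope_sd**2]
        )

    def estuary_ids(self) -> list[str]:
        return [f"E{i + 1:03d}" for i in range(self.n_estuaries)]

    def program_ids(self) -> list[str]:
        return [f"P{i + 1:02d}" for i in range(self.n_programs)]


def generate_landscape(
    config: SyntheticConfig,
) -> tuple[list[WatershedComposition], list[PrecipSeries]]:
    """Draw per-estuary landscape compositions and daily precipitation.

    Class areas get an estuary-specific log-normal spread
    (``lulc_dispersion`` on the log scale) around the configured mean
    fractions; precipitation is a seasonal wet-day gamma process.
    Reproducible from ``config.seed``.
    """
    rng = np.random.default_rng([config.seed, 1])
    comps, precips = [], []
    start = f"{config.precip_start_year}-01-01"
    end = f"{config.precip_start_year + config.years_precip - 1}-12-31"
    dates = pd.date_range(start, end, freq="D")
    doy = dates.dayofyear.to_numpy()

    for estuary_id in config.estuary_ids():
        area_km2 = float(rng.uniform(*config.watershed_area_range_km2))
        disp = config.lulc_dispersion
        weights = {
            g: config.class_fractions[g]
            * float(np.exp(rng.normal(-0.5 * disp**2, disp)))
            for g in LULC_GROUPS
        }
        classified_frac = float(rng.uniform(0.6, 0.9))
        w_total = sum(weights.values())
        rows = []
        for g in LULC_GROUPS:
            area_g = weights[g] / w_total * classified_frac * area_km2 * 1e6
            soil_shares = rng.dirichlet(np.full(len(SOIL_GROUPS), 2.0))
            codes = _CODES_BY_GROUP[g]
            for soil, share in zip(SOIL_GROUPS, soil_shares):
                per_code = area_g * share / len(codes)
                for code in codes:
                    rows.append(
                        {
                            "ccap_code": code,
                            "soil_group": soil,
                            "area_m2": per_code,
                        }
                    )
        comps.append(
            WatershedComposition(
                estuary_id=estuary_id,
                rows=pd.DataFrame(rows),
                watershed_area_km2=area_km2,
            )
        )

        wet_p = 0.25 + 0.10 * np.sin(2 * np.pi * doy / 365.0)
        wet = rng.random(len(dates)) < wet_p
        depths = np.where(
            wet, rng.gamma(shape=0.7, scale=12.0, size=len(dates)), 0.0
        )
        precips.append(
            PrecipSeries(
                estuary_id=estuary_id, dates=dates, depths_mm=depths
            )
        )
    return comps, precips


def _expand_taxa(
    richness: int, taxa: list[str], rng: np.random.Generator
) -> dict[str, int]:
    chosen = rng.choice(len(taxa), size=richness, replace=False)
    return {taxa[i]: int(rng.integers(1, 20)) for i in chosen}


def generate_survey(
    config: SyntheticConfig,
    runoff_covariates: list[RunoffByClass],
    fg_table: dict[str, str] | None = None,
) -> tuple[list[TrawlRecord], dict]:
    """Draw trawl records whose per-taxon counts realize functional-group
    richness values simulated from the generative model.

    Covariates are transformed exactly as the preparation stage will
    transform them (log + centering), so a round trip through the pipeline
    recovers the true parameters.  Returns ``(records, truth)`` where
    ``truth`` records every generative quantity.
    """
    if fg_table is None:
        fg_table = trawl_prep.load_fg_table()
    taxa_by_group: dict[str, list[str]] = {g: [] for g in FUNCTIONAL_GROUPS}
    for taxon, group in fg_table.items():
        taxa_by_group[group].append(taxon)

    rng = np.random.default_rng([config.seed, 2])
    J, K = config.n_estuaries, config.n_programs
    estuary_ids = config.estuary_ids()
    program_ids = config.program_ids()
    cov_of = {r.estuary_id: r for r in runoff_covariates}
    missing = [e for e in estuary_ids if e not in cov_of]
    if missing:
        raise ValueError(f"runoff covariates missing for {missing}")

    sal_mu = rng.uniform(*config.salinity_mean_range, J)
    temp_mu = rng.uniform(*config.temperature_mean_range, J)

    n = J * config.trawls_per_estuary
    j_idx = np.repeat(np.arange(J), config.trawls_per_estuary)
    k_idx = rng.integers(0, K, n)
    salinity = np.clip(
        rng.normal(sal_mu[j_idx], config.salinity_sd), 0.05, None
    )
    temperature = np.clip(
        rng.normal(temp_mu[j_idx], config.temperature_sd), 5.5, 34.5
    )

    # transforms mirror trawl_prep: log + estuary-mean centering (X1, X2),
    # log(v+1) + grand-mean centering (X3..X8)
    log_sal, log_temp = np.log(salinity), np.log(temperature)
    x1 = log_sal.copy()
    x2 = log_temp.copy()
    for j in range(J):
        m = j_idx == j
        x1[m] -= log_sal[m].mean()
        x2[m] -= log_temp[m].mean()
    raw_cov = np.array(
        [cov_of[e].as_vector() for e in estuary_ids], dtype=float
    )
    log_cov = np.log(raw_cov + trawl_prep.RUNOFF_LOG_OFFSET)
    x_est = log_cov - log_cov.mean(axis=0)

    alpha_est = rng.multivariate_normal(np.zeros(3), config.re_cov(), J)
    alpha_prog = rng.multivariate_normal(np.zeros(3), config.re_cov(), K)
    params = ModelParams(
        beta=config.true_beta,
        alpha_est=alpha_est,
        alpha_prog=alpha_prog,
        sigma2_s=config.true_sigma2_s,
        Sigma1=config.re_cov(),
        Sigma2=config.re_cov(),
    )
    design = ModelData(
        j=j_idx, k=k_idx, y=np.zeros(n, dtype=int), x1=x1, x2=x2, x_est=x_est
    )

    richness = {}
    resampled: dict[str, int] = {}
    for gi, group in enumerate(FUNCTIONAL_GROUPS):
        cap = len(taxa_by_group[group])
        y = simulate_counts(params, design, seed=int(rng.integers(2**31)))
        tries = 0
        while (y > cap).any():
            over = y > cap
            resampled[group] = resampled.get(group, 0) + int(over.sum())
            y_new = simulate_counts(
                params, design, seed=int(rng.integers(2**31))
            )
            y = np.where(over, y_new, y)
            tries += 1
            if tries > 100:
                raise RuntimeError(
                    f"richness persistently exceeds taxa available for {group}"
                )
        richness[group] = y

    base_date = pd.Timestamp("2001-06-15")
    records = []
    for i in range(n):
        counts: dict[str, int] = {}
        for group in FUNCTIONAL_GROUPS:
            r = int(richness[group][i])
            if r > 0:
                counts.update(_expand_taxa(r, taxa_by_group[group], rng))
        records.append(
            TrawlRecord(
                sample_id=f"S{i + 1:06d}",
                estuary_id=estuary_ids[j_idx[i]],
                program_id=program_ids[k_idx[i]],
                date=(base_date + pd.Timedelta(days=int(i % 365))).date(),
                salinity=float(salinity[i]),
                temperature=float(temperature[i]),
                counts=counts,
            )
        )
    truth = {
        "beta": config.true_beta.tolist(),
        "sigma2_s": config.true_sigma2_s,
        "Sigma1": config.re_cov().tolist(),
        "Sigma2": config.re_cov().tolist(),
        "alpha_est": alpha_est.tolist(),
        "alpha_prog": alpha_prog.tolist(),
        "salinity_means": sal_mu.tolist(),
        "temperature_means": temp_mu.tolist(),
        "x_est": x_est.tolist(),
        "resampled_richness_draws": resampled,
        "seed": config.seed,
    }
    return records, truth


@dataclass
class SyntheticDataset:
    config: SyntheticConfig
    compositions: list[WatershedComposition]
    precips: list[PrecipSeries]
    runoff: list[RunoffByClass]
    records: list[TrawlRecord]
    truth: dict

    def write(self, out_dir) -> dict[str, str]:
        """Write the CSV dialects the real pipeline reads, plus truth.json."""
        out = pathlib.Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        comp_rows = []
        for c in self.compositions:
            for r in c.rows.itertuples():
                comp_rows.append(
                    {
                        "estuary_id": c.estuary_id,
                        "ccap_code": r.ccap_code,
                        "soil_group": r.soil_group,
                        "area_m2": r.area_m2,
                        "watershed_area_km2": c.watershed_area_km2,
                    }
                )
        pd.DataFrame(comp_rows).to_csv(out / "composition.csv", index=False)
        precip_rows = []
        for p in self.precips:
            precip_rows.append(
                pd.DataFrame(
                    {
                        "estuary_id": p.estuary_id,
                        "date": p.dates.strftime("%Y-%m-%d"),
                        "precip_mm": p.depths_mm,
                    }
                )
            )
        pd.concat(precip_rows).to_csv(out / "precip.csv", index=False)

        trawl_rows, count_rows = [], []
        for r in self.records:
            trawl_rows.append(
                {
                    "sample_id": r.sample_id,
                    "estuary_id": r.estuary_id,
                    "program_id": r.program_id,
                    "date": r.date.isoformat() if r.date else "",
                    "salinity_ppt": r.salinity,
                    "temperature_c": r.temperature,
                }
            )
            for taxon, cnt in r.counts.items():
                count_rows.append(
                    {"sample_id": r.sample_id, "taxon": taxon, "count": cnt}
                )
        pd.DataFrame(trawl_rows).to_csv(out / "trawls.csv", index=False)
        pd.DataFrame(count_rows).to_csv(out / "trawl_counts.csv", index=False)
        with open(out / "truth.json", "w") as fh:
            json.dump(self.truth, fh, indent=2)
        return {
            "composition": str(out / "composition.csv"),
            "precip": str(out / "precip.csv"),
            "trawls": str(out / "trawls.csv"),
            "trawl_counts": str(out / "trawl_counts.csv"),
            "truth": str(out / "truth.json"),
        }


def generate_dataset(
    config: SyntheticConfig, cn_table: CurveNumberTable | None = None
) -> SyntheticDataset:
    """Landscape -> runoff covariates -> survey, in one deterministic call."""
    comps, precips = generate_landscape(config)
    cn = cn_table or CurveNumberTable.default()
    runoff = [
        annual_runoff_by_class(c, p, cn) for c, p in zip(comps, precips)
    ]
    records, truth = generate_survey(config, runoff)
    return SyntheticDataset(
        config=config,
        compositions=comps,
        precips=precips,
        runoff=runoff,
        records=records,
        truth=truth,
    )
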