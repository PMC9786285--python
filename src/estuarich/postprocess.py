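"""Posterior summary products.

Credible-interval tables for the land-cover coefficients, proportional
changes in expected richness across the observed covariate range, and
richness-vs-covariate prediction curves with credible bands.

Quantile convention throughout: linear interpolation between order
statistics (numpy default).
"""

from __future__ import annotations

import pathlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import PosteriorDraws
from .runoff import LULC_GROUPS

__all__ = [
    "CredibleSummary",
    "ProportionalChange",
    "PredictionCurve",
    "credible_table",
    "proportional_change",
    "prediction_curve",
    "summarize_to_dir",
]

#: beta index of the first land-cover coefficient.
_LULC_OFFSET = 3


@dataclass
class CredibleSummary:
    """Posterior percentiles of the land-cover coefficients."""

    table: pd.DataFrame  # columns: covariate, p2.5, p50, p97.5

    def __post_init__(self) -> None:
        t = self.table
        if not ((t["p2.5"] <= t["p50"]).all() and (t["p50"] <= t["p97.5"]).all()):
            raise ValueError("percentiles out of order")


@dataclass
class ProportionalChange:
    """Change in expected richness from the lowest to the highest observed
    covariate value, exp(median(beta) * dx) - 1."""

    table: pd.DataFrame      # columns: covariate, change
    distributions: dict[str, np.ndarray]


@dataclass
class PredictionCurve:
    covariate: str
    grid: np.ndarray
    mean: np.ndarray
    band90: tuple[np.ndarray, np.ndarray]
    band95: tuple[np.ndarray, np.ndarray]

    def __post_init__(self) -> None:
        lo90, hi90 = self.band90
        lo95, hi95 = self.band95
        if not ((lo95 <= lo90).all() and (hi90 <= hi95).all()):
            raise ValueError("95% band must contain the 90% band")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "x": self.grid,
                "mean": self.mean,
                "lo90": self.band90[0],
                "hi90": self.band90[1],
                "lo95": self.band95[0],
                "hi95": self.band95[1],
            }
        )


def credible_table(
    draws: PosteriorDraws,
    percentiles: tuple[float, ...] = (2.5, 50.0, 97.5),
) -> CredibleSummary:
    """Empirical percentiles of each land-cover coefficient across pooled
    post-warmup draws."""
    beta = draws.beta_flat()
    if beta.size == 0:
        raise ValueError("empty draws")
    recs = []
    for m, name in enumerate(LULC_GROUPS):
        col = beta[:, _LULC_OFFSET + m]
        pcts = np.percentile(col, percentiles)
        recs.append(
            {
                "covariate": name,
                **{f"p{p:g}": v for p, v in zip(percentiles, pcts)},
            }
        )
    return CredibleSummary(table=pd.DataFrame(recs))


def proportional_change(
    draws: PosteriorDraws,
    covariate_ranges: dict[str, tuple[float, float]],
) -> ProportionalChange:
    """Proportional change in expected richness over the observed
    (transformed) covariate range, using the posterior median of beta as
    the point summary; full per-draw distributions are returned too."""
    beta = draws.beta_flat()
    recs, dists = [], {}
    for m, name in enumerate(LULC_GROUPS):
        if name not in covariate_ranges:
            continue
        x_min, x_max = covariate_ranges[name]
        if x_max < x_min:
            raise ValueError(f"x_max < x_min for {name}")
        dx = x_max - x_min
        col = beta[:, _LULC_OFFSET + m]
        recs.append(
            {
                "covariate": name,
                "change": float(np.exp(np.median(col) * dx) - 1.0),
            }
        )
        dists[name] = np.exp(col * dx) - 1.0
    return ProportionalChange(table=pd.DataFrame(recs), distributions=dists)


def prediction_curve(
    draws: PosteriorDraws,
    covariate: str,
    grid,
    include_sigma_correction: bool = True,
) -> PredictionCurve:
    """Expected richness vs one covariate, other covariates at 0 (their
    grand mean) and random effects at 0.

    Per draw and grid point: lambda* = exp(beta0 + beta_m x + sigma2_s/2).
    The lognormal mean correction uses the posterior-mean sigma2_s so the
    bands reflect coefficient (mean-curve) uncertainty only; disable it
    for the conditional-median curve.
    """
    if covariate not in LULC_GROUPS:
        raise KeyError(f"covariate {covariate!r} not in model")
    grid = np.asarray(grid, dtype=float)
    beta = draws.beta_flat()
    m = _LULC_OFFSET + LULC_GROUPS.index(covariate)
    correction = 0.0
    if include_sigma_correction:
        sig2 = draws.flat("sigma2_s")
        correction = float(np.mean(sig2)) / 2.0
    log_curve = beta[:, [0]] + np.outer(beta[:, m], grid) + correction
    curves = np.exp(log_curve)  # (draws, len(grid))
    lo90, hi90 = np.percentile(curves, [5.0, 95.0], axis=0)
    lo95, hi95 = np.percentile(curves, [2.5, 97.5], axis=0)
    return PredictionCurve(
        covariate=covariate,
        grid=grid,
        mean=curves.mean(axis=0),
        band90=(lo90, hi90),
        band95=(lo95, hi95),
    )


def summarize_to_dir(
    draws: PosteriorDraws,
    x_est: np.ndarray,
    out_dir,
    group: str = "",
    n_grid: int = 50,
    plots: bool = True,
) -> dict:
    """Write Table-3/Table-4-shaped CSVs and per-covariate curves."""
    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    prefix = f"{group}_" if group else ""

    cred = credible_table(draws)
    cred.table.to_csv(out / f"{prefix}credible_intervals.csv", index=False)

    x_est = np.atleast_2d(np.asarray(x_est, dtype=float))
    ranges = {
        name: (float(x_est[:, i].min()), float(x_est[:, i].max()))
        for i, name in enumerate(LULC_GROUPS)
    }
    prop = proportional_change(draws, ranges)
    prop.table.to_csv(out / f"{prefix}proportional_change.csv", index=False)

    curve_files = {}
    for i, name in enumerate(LULC_GROUPS):
        lo, hi = ranges[name]
        grid = np.linspace(lo, hi, n_grid)
        curve = prediction_curve(draws, name, grid)
        path = out / f"{prefix}curve_{name}.csv"
        curve.to_frame().to_csv(path, index=False)
        curve_files[name] = str(path)
        if plots:
            import matplotlib

            matplotlib.use("Agg")
            import matplotlib.pyplot as plt

            fig, ax = plt.subplots(figsize=(5, 4))
            ax.fill_between(grid, *curve.band95, alpha=0.2, label="95% CrI")
            ax.fill_between(grid, *curve.band90, alpha=0.3, label="90% CrI")
            ax.plot(grid, curve.mean, label="mean expected richness")
            ax.set_xlabel(f"{name} (log, grand-mean centered)")
            ax.set_ylabel("expected richness")
            ax.legend()
            fig.tight_layout()
            fig.savefig(out / f"{prefix}curve_{name}.png", dpi=100)
            plt.close(fig)
    return {
        "credible_intervals": str(out / f"{prefix}credible_intervals.csv"),
        "proportional_change": str(out / f"{prefix}proportional_change.csv"),
        "curves": curve_files,
    }
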