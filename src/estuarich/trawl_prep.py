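"""Trawl-sample preparation.

QC filtering, functional-group richness, per-estuary subsampling, and the
covariate transforms (log + centering) that produce fitting-ready data.
"""

from __future__ import annotations

import importlib.resources
import json
import logging
import pathlib
from dataclasses import dataclass, field
from datetime import date

import numpy as np
import pandas as pd
from scipy import stats

from .runoff import LULC_GROUPS, RunoffByClass

logger = logging.getLogger(__name__)

__all__ = [
    "FUNCTIONAL_GROUPS",
    "TrawlRecord",
    "PreparedDataset",
    "load_fg_table",
    "load_trawls_csv",
    "qc_filter",
    "fg_richness",
    "subsample",
    "distribution_check",
    "transform_covariates",
    "holdout_count",
]

FUNCTIONAL_GROUPS = ("pelagic", "forage_finfish", "shrimp")

#: Offset added to zero salinity before the log transform (ppt).
SALINITY_ZERO_OFFSET = 1e-6
#: Offset added to runoff covariates before the log transform (m^3/km^2).
RUNOFF_LOG_OFFSET = 1.0

QC_TEMP_MIN = 5.0
QC_TEMP_MAX = 35.0


@dataclass
class TrawlRecord:
    """One trawl event: ids, environment measurements, per-taxon counts."""

    sample_id: str
    estuary_id: str
    program_id: str
    date: date | None
    salinity: float | None
    temperature: float | None
    counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.sample_id or not self.estuary_id or not self.program_id:
            raise ValueError("sample/estuary/program ids must be non-empty")
        for taxon, n in self.counts.items():
            if n < 0:
                raise ValueError(f"negative count for {taxon!r}")


def load_fg_table(path=None) -> dict[str, str]:
    """Species -> functional-group mapping; packaged table by default."""
    if path is None:
        res = importlib.resources.files("estuarich.assets") / "fg_table.csv"
        with importlib.resources.as_file(res) as p:
            df = pd.read_csv(p)
    else:
        df = pd.read_csv(path)
    table = dict(zip(df["taxon"].astype(str), df["functional_group"].astype(str)))
    bad = set(table.values()) - set(FUNCTIONAL_GROUPS)
    if bad:
        raise ValueError(f"unknown functional groups in table: {sorted(bad)}")
    return table


_META_COLS = ("sample_id", "estuary_id", "program_id", "date",
              "salinity_ppt", "temperature_c")


def load_trawls_csv(path, counts_path=None) -> list[TrawlRecord]:
    """Load trawl records from CSV.

    Wide format: one column per taxon after the metadata columns.
    Long format: pass ``counts_path`` with columns (sample_id, taxon, count).
    """
    df = pd.read_csv(path)
    counts_by_sample: dict[str, dict[str, int]] = {}
    if counts_path is not None:
        cdf = pd.read_csv(counts_path)
        for r in cdf.itertuples():
            counts_by_sample.setdefault(str(r.sample_id), {})[str(r.taxon)] = int(
                r.count
            )
        taxon_cols: list[str] = []
    else:
        taxon_cols = [c for c in df.columns if c not in _META_COLS]
    records = []
    for _, row in df.iterrows():
        sid = str(row["sample_id"])
        if counts_path is not None:
            counts = counts_by_sample.get(sid, {})
        else:
            counts = {
                c: int(row[c]) for c in taxon_cols if pd.notna(row[c]) and row[c] > 0
            }
        d = row.get("date")
        records.append(
            TrawlRecord(
                sample_id=sid,
                estuary_id=str(row["estuary_id"]),
                program_id=str(row["program_id"]),
                date=pd.Timestamp(d).date() if pd.notna(d) else None,
                salinity=float(row["salinity_ppt"])
                if pd.notna(row["salinity_ppt"])
                else None,
                temperature=float(row["temperature_c"])
                if pd.notna(row["temperature_c"])
                else None,
                counts=counts,
            )
        )
    return records


def qc_filter(
    records: list[TrawlRecord],
    t_min: float = QC_TEMP_MIN,
    t_max: float = QC_TEMP_MAX,
) -> tuple[list[TrawlRecord], list[tuple[TrawlRecord, str]]]:
    """Remove outlier trawl events.

    A record is kept iff salinity and temperature are present,
    ``t_min <= T <= t_max``, and salinity >= 0.  Returns
    ``(kept, [(record, reason), ...])``.
    """
    kept, removed = [], []
    for rec in records:
        if rec.temperature is None or rec.salinity is None:
            removed.append((rec, "missing salinity or temperature"))
        elif rec.temperature < t_min:
            removed.append((rec, f"temperature below {t_min}"))
        elif rec.temperature > t_max:
            removed.append((rec, f"temperature above {t_max}"))
        elif rec.salinity < 0:
            removed.append((rec, "negative salinity"))
        else:
            kept.append(rec)
    for rec, reason in removed:
        logger.debug("removed %s: %s", rec.sample_id, reason)
    return kept, removed


def fg_richness(
    record: TrawlRecord, fg_table: dict[str, str]
) -> dict[str, int]:
    """Distinct taxa with positive counts per functional group.

    Taxa absent from the table are ignored (and logged once per record).
    """
    richness = {g: 0 for g in FUNCTIONAL_GROUPS}
    unmapped = []
    for taxon, n in record.counts.items():
        if n <= 0:
            continue
        group = fg_table.get(taxon)
        if group is None:
            unmapped.append(taxon)
            continue
        richness[group] += 1
    if unmapped:
        logger.debug("sample %s: unmapped taxa %s", record.sample_id, unmapped)
    return richness


def subsample(
    records: list[TrawlRecord],
    n_per_estuary: int = 150,
    seed: int = 0,
) -> tuple[list[TrawlRecord], list[TrawlRecord]]:
    """Per-estuary without-replacement subsample.

    Estuaries with more than ``n_per_estuary`` records contribute a uniform
    sample of that size; the rest contribute all records.  Remainder goes
    to the holdout set.  Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    by_estuary: dict[str, list[TrawlRecord]] = {}
    for rec in records:
        by_estuary.setdefault(rec.estuary_id, []).append(rec)
    fitted, holdout = [], []
    for estuary_id in sorted(by_estuary):
        group = by_estuary[estuary_id]
        if len(group) > n_per_estuary:
            idx = rng.choice(len(group), size=n_per_estuary, replace=False)
            chosen = set(idx.tolist())
            for i, rec in enumerate(group):
                (fitted if i in chosen else holdout).append(rec)
        else:
            fitted.extend(group)
    return fitted, holdout


def distribution_check(
    fitted: list[TrawlRecord],
    all_records: list[TrawlRecord],
    variables: tuple[str, ...] = ("salinity", "temperature"),
    plot_path=None,
) -> dict[str, float]:
    """Two-sample KS distance per variable between the fitted subset and
    the full record set.  Advisory only; optionally writes side-by-side
    histograms to ``plot_path``."""
    if not fitted or not all_records:
        raise ValueError("both record sets must be non-empty")
    report = {}
    for var in variables:
        a = np.array([getattr(r, var) for r in fitted], dtype=float)
        b = np.array([getattr(r, var) for r in all_records], dtype=float)
        report[var] = float(stats.ks_2samp(a, b, method="asymp").statistic)
    if plot_path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, axes = plt.subplots(1, len(variables), figsize=(5 * len(variables), 4))
        axes = np.atleast_1d(axes)
        for ax, var in zip(axes, variables):
            a = [getattr(r, var) for r in fitted]
            b = [getattr(r, var) for r in all_records]
            ax.hist(b, bins=30, alpha=0.5, density=True, label="all")
            ax.hist(a, bins=30, alpha=0.5, density=True, label="fitted")
            ax.set_title(f"{var} (KS={report[var]:.3f})")
            ax.legend()
        fig.tight_layout()
        fig.savefig(plot_path)
        plt.close(fig)
    return report


class DegenerateCovariateError(ValueError):
    """An estuary-level covariate column is identically zero."""


@dataclass
class PreparedDataset:
    """Fitting-ready rows plus the estuary covariate matrix.

    ``rows`` columns: sample_id, estuary_id, program_id, j, k,
    y_pelagic, y_forage_finfish, y_shrimp, x1, x2.
    ``x_est`` is (J, 6) in LULC_GROUPS order (covariates X3..X8 after the
    log + grand-mean-centering transform).
    """

    rows: pd.DataFrame
    x_est: np.ndarray
    estuary_ids: list[str]
    program_ids: list[str]
    holdout_rows: pd.DataFrame
    meta: dict

    @property
    def n_estuaries(self) -> int:
        return len(self.estuary_ids)

    @property
    def n_programs(self) -> int:
        return len(self.program_ids)

    def save(self, out_dir) -> None:
        out = pathlib.Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.rows.to_csv(out / "rows.csv", index=False)
        self.holdout_rows.to_csv(out / "holdout_rows.csv", index=False)
        pd.DataFrame(
            self.x_est, columns=list(LULC_GROUPS)
        ).assign(estuary_id=self.estuary_ids).to_csv(out / "x_est.csv", index=False)
        with open(out / "meta.json", "w") as fh:
            json.dump(
                {
                    **self.meta,
                    "estuary_ids": self.estuary_ids,
                    "program_ids": self.program_ids,
                },
                fh,
                indent=2,
                default=float,
            )

    @classmethod
    def load(cls, in_dir) -> "PreparedDataset":
        p = pathlib.Path(in_dir)
        with open(p / "meta.json") as fh:
            meta = json.load(fh)
        estuary_ids = meta.pop("estuary_ids")
        program_ids = meta.pop("program_ids")
        x_est = pd.read_csv(p / "x_est.csv")[list(LULC_GROUPS)].to_numpy()
        return cls(
            rows=pd.read_csv(p / "rows.csv"),
            x_est=x_est,
            estuary_ids=estuary_ids,
            program_ids=program_ids,
            holdout_rows=pd.read_csv(p / "holdout_rows.csv"),
            meta=meta,
        )


def _log_salinity(values: np.ndarray) -> np.ndarray:
    return np.log(np.where(values > 0, values, SALINITY_ZERO_OFFSET))


def transform_covariates(
    fitted: list[TrawlRecord],
    estuary_covariates: list[RunoffByClass] | pd.DataFrame,
    fg_table: dict[str, str] | None = None,
    holdout: list[TrawlRecord] | None = None,
    center_group: str = "estuary",
    subsample_seed: int | None = None,
) -> PreparedDataset:
    """Build the fitting-ready dataset.

    Sample-level covariates (salinity, temperature) are log-transformed and
    group-mean-centered (by estuary by default, by program via
    ``center_group="program"``); estuary-level runoff covariates are
    log(value + 1)-transformed and grand-mean-centered across estuaries.
    Centering means are computed on the fitted rows and recorded in
    ``meta`` for back-transformation; holdout rows reuse them.
    """
    if center_group not in ("estuary", "program"):
        raise ValueError("center_group must be 'estuary' or 'program'")
    if fg_table is None:
        fg_table = load_fg_table()
    holdout = holdout or []

    if isinstance(estuary_covariates, pd.DataFrame):
        cov_df = estuary_covariates.set_index("estuary_id")
    else:
        cov_df = pd.DataFrame(
            {r.estuary_id: r.values for r in estuary_covariates}
        ).T
    estuary_ids = sorted(
        {r.estuary_id for r in fitted} | {r.estuary_id for r in holdout}
    )
    missing = [e for e in estuary_ids if e not in cov_df.index]
    if missing:
        raise ValueError(f"no runoff covariates for estuaries {missing}")
    program_ids = sorted(
        {r.program_id for r in fitted} | {r.program_id for r in holdout}
    )
    j_of = {e: i for i, e in enumerate(estuary_ids)}
    k_of = {p: i for i, p in enumerate(program_ids)}

    raw = cov_df.loc[estuary_ids, list(LULC_GROUPS)].to_numpy(dtype=float)
    for m, g in enumerate(LULC_GROUPS):
        if np.all(raw[:, m] == 0):
            raise DegenerateCovariateError(f"covariate {g} is identically zero")
    log_cov = np.log(raw + RUNOFF_LOG_OFFSET)
    grand_means = log_cov.mean(axis=0)
    x_est = log_cov - grand_means

    def frame(records: list[TrawlRecord]) -> pd.DataFrame:
        recs = []
        for r in records:
            rich = fg_richness(r, fg_table)
            recs.append(
                {
                    "sample_id": r.sample_id,
                    "estuary_id": r.estuary_id,
                    "program_id": r.program_id,
                    "j": j_of[r.estuary_id],
                    "k": k_of[r.program_id],
                    "y_pelagic": rich["pelagic"],
                    "y_forage_finfish": rich["forage_finfish"],
                    "y_shrimp": rich["shrimp"],
                    "log_sal": _log_salinity(np.array(r.salinity)),
                    "log_temp": np.log(r.temperature),
                }
            )
        return pd.DataFrame(recs)

    fit_df = frame(fitted)
    hold_df = frame(holdout) if holdout else pd.DataFrame(
        columns=fit_df.columns
    )

    group_col = "estuary_id" if center_group == "estuary" else "program_id"
    means = fit_df.groupby(group_col)[["log_sal", "log_temp"]].mean()
    fallback = fit_df[["log_sal", "log_temp"]].mean()

    def center(df: pd.DataFrame) -> pd.DataFrame:
        if df.empty:
            df = df.copy()
            df["x1"] = df["x2"] = pd.Series(dtype=float)
        else:
            m = means.reindex(df[group_col]).fillna(fallback)
            df = df.copy()
            df["x1"] = df["log_sal"].to_numpy() - m["log_sal"].to_numpy()
            df["x2"] = df["log_temp"].to_numpy() - m["log_temp"].to_numpy()
        return df.drop(columns=["log_sal", "log_temp"])

    meta = {
        "center_group": center_group,
        "centering_means": {
            g: {"log_sal": float(v["log_sal"]), "log_temp": float(v["log_temp"])}
            for g, v in means.iterrows()
        },
        "grand_means_log_cov": {
            g: float(m) for g, m in zip(LULC_GROUPS, grand_means)
        },
        "salinity_zero_offset": SALINITY_ZERO_OFFSET,
        "runoff_log_offset": RUNOFF_LOG_OFFSET,
        "subsample_seed": subsample_seed,
    }
    return PreparedDataset(
        rows=center(fit_df),
        x_est=x_est,
        estuary_ids=estuary_ids,
        program_ids=program_ids,
        holdout_rows=center(hold_df),
        meta=meta,
    )


def holdout_count(total_samples: int, fitted_samples: int) -> int:
    """Held-out sample count from partition accounting: total - fitted."""
    if fitted_samples > total_samples:
        raise ValueError("fitted subset larger than the full collection")
    return int(total_samples) - int(fitted_samples)
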