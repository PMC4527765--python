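"""Reading observation tables, validity parsing and CMAC-cohort statistics.

The experimental dataset ships as three row-aligned sheets — ``features``
(150 columns), ``processes`` (Cell Speed, Protrusion/Retraction/Short-lived
Pixels, Dynamic Cell Area, CMD) and ``index`` (experiment date, cell trace,
positions, frame number). The same layout is accepted either as a
spreadsheet with those three sheet names or as a directory of three CSV
files; the synthetic generator writes the CSV form.

Cohort descriptors summarize the distribution of one CMAC feature over all
adhesion complexes of a cell at one time point: the quartiles q1..q3, the
quartile dispersion QD = (q3 − q1)/2, the quartile skewness
QS = (q2 − (q1 + q3)/2)/QD and the coefficient of variation CoV = QD/q2,
plus cohort sums (total CMAC area, total paxillin and LifeAct content) and
the mean CMAC lifetime.
"""

from __future__ import annotations

import re
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "PROCESS_COLUMNS",
    "INDEX_COLUMNS",
    "read_dataset",
    "write_csv_triplet",
    "parse_validity",
    "standardize_intensities",
    "cohort_descriptors",
]

PROCESS_COLUMNS = (
    "cell_speed",
    "protrusion_pixels",
    "retraction_pixels",
    "short_lived_pixels",
    "dynamic_cell_area",
    "cmd",
)
INDEX_COLUMNS = ("experiment_id", "cell_trace_id", "frame_number")

# loose header -> canonical name mapping for the spreadsheet dialect
_CANON = {
    "cellspeed": "cell_speed",
    "speed": "cell_speed",
    "protrusionpixels": "protrusion_pixels",
    "retractionpixels": "retraction_pixels",
    "shortlivedpixels": "short_lived_pixels",
    "dynamiccellarea": "dynamic_cell_area",
    "correctedmembranedynamics": "cmd",
    "cmd": "cmd",
    "experimentdate": "experiment_id",
    "experimentid": "experiment_id",
    "celltrace": "cell_trace_id",
    "celltraceid": "cell_trace_id",
    "celltraceidentifier": "cell_trace_id",
    "framenumber": "frame_number",
    "frame": "frame_number",
}


def _canonical(name: str) -> str:
    key = re.sub(r"[^a-z0-9]", "", str(name).lower())
    return _CANON.get(key, str(name))


def _read_sheets(path: Path, dialect: str) -> dict[str, pd.DataFrame]:
    names = ("features", "processes", "index")
    if dialect == "csv-triplet":
        if not path.is_dir():
            raise FileNotFoundError(f"expected a directory of CSVs at {path}")
        out = {}
        for name in names:
            f = path / f"{name}.csv"
            if not f.exists():
                raise FileNotFoundError(f"missing sheet file {f}")
            out[name] = pd.read_csv(f)
        return out
    if dialect == "s1-spreadsheet":
        if not path.exists():
            raise FileNotFoundError(path)
        if path.suffix.lower() == ".xlsb":
            raise ValueError(
                "XLSB is not supported; convert the workbook to .xlsx or "
                "export the three sheets as a CSV triplet"
            )
        return {n: pd.read_excel(path, sheet_name=n) for n in names}
    raise ValueError(f"unknown dialect {dialect!r}")


def read_dataset(path: str | Path, dialect: str = "csv-triplet") -> pd.DataFrame:
    """Read and row-align the three sheets into one observation table.

    The sheets carry no join key: rows are aligned by position, which the
    dataset guarantees ("the order of the observations is the same in each
    sheet"), so mismatching row counts abort the read.

    Returns a DataFrame whose feature columns are exactly the columns of
    the features sheet (``table.attrs["feature_columns"]`` lists them);
    index and process columns are normalized to canonical snake_case names.
    """
    path = Path(path)
    sheets = _read_sheets(path, dialect)
    n = {name: len(df) for name, df in sheets.items()}
    if len(set(n.values())) != 1:
        raise ValueError(f"sheets are misaligned: row counts {n}")

    features = sheets["features"].reset_index(drop=True)
    processes = sheets["processes"].rename(columns=_canonical).reset_index(drop=True)
    index = sheets["index"].rename(columns=_canonical).reset_index(drop=True)

    missing = [c for c in PROCESS_COLUMNS if c not in processes.columns]
    if missing:
        raise ValueError(f"processes sheet lacks required columns: {missing}")
    for col in ("cell_trace_id", "frame_number"):
        if col not in index.columns:
            raise ValueError(f"index sheet lacks required column {col!r}")
    if "experiment_id" not in index.columns:
        index["experiment_id"] = "exp00"

    clash = set(features.columns) & (set(PROCESS_COLUMNS) | set(INDEX_COLUMNS))
    if clash:
        raise ValueError(f"feature columns collide with reserved names: {clash}")
    dup = index[["cell_trace_id", "frame_number"]].duplicated()
    if dup.any():
        raise ValueError("duplicate (cell_trace_id, frame_number) pairs in index")

    index_cols = [c for c in index.columns]
    table = pd.concat(
        [index, processes[list(PROCESS_COLUMNS)], features], axis=1
    )
    if "valid" not in table.columns:
        table["valid"] = True
    table.attrs["feature_columns"] = list(features.columns)
    table.attrs["index_columns"] = index_cols
    return table


def feature_columns(table: pd.DataFrame) -> list[str]:
    """Feature columns of a table: the recorded list, else everything that
    is neither an index/process column nor the validity flag."""
    if "feature_columns" in table.attrs:
        return list(table.attrs["feature_columns"])
    reserved = set(PROCESS_COLUMNS) | set(INDEX_COLUMNS) | {"valid", "position_x", "position_y"}
    return [c for c in table.columns if c not in reserved]


def write_csv_triplet(table: pd.DataFrame, out_dir: str | Path) -> None:
    """Write a table back out as the features/processes/index CSV triplet."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    feats = feature_columns(table)
    idx_cols = [c for c in table.columns
                if c not in feats and c not in PROCESS_COLUMNS and c != "valid"]
    table[feats].to_csv(out / "features.csv", index=False)
    table[list(PROCESS_COLUMNS)].to_csv(out / "processes.csv", index=False)
    table[idx_cols].to_csv(out / "index.csv", index=False)


def parse_validity(table: pd.DataFrame) -> pd.DataFrame:
    """Flag rows whose dynamic measures are undefined.

    Protrusions are undefined at the first frame of a trace and retractions
    at the last, so both endpoints are invalid, as is any frame adjacent to
    a gap in the frame numbering. Returns a copy with the ``valid`` column
    set; downstream statistics use valid rows only.
    """
    out = table.copy()
    valid = np.zeros(len(out), dtype=bool)
    for _, grp in out.groupby("cell_trace_id", sort=False):
        frames = grp["frame_number"].to_numpy()
        present = set(frames.tolist())
        ok = np.array([(f - 1) in present and (f + 1) in present for f in frames])
        valid[grp.index.to_numpy()] = ok
    out["valid"] = valid
    return out


# --------------------------------------------------------------------------
# CMAC records
# --------------------------------------------------------------------------


def standardize_intensities(
    cmacs: pd.DataFrame,
    intensity_columns: list[str],
    area_column: str = "area",
    experiment_column: str = "experiment_id",
    percentile_cut: float = 3.0,
) -> pd.DataFrame:
    """Standardize CMAC intensities to the reference of the smallest objects.

    Per experiment and per intensity channel, the median intensity of the
    CMACs in the smallest ``percentile_cut`` area-percentiles is taken as a
    reference (in the experimental data these are objects of ~0.15–0.2 μm²,
    near the detection limit, whose intensity approximates the local
    background-corrected unit signal) and every intensity in that
    experiment/channel is divided by it. Experiments with an unusable
    reference (empty set or zero median) are dropped with a warning.
    """
    out = []
    for exp, grp in cmacs.groupby(experiment_column, sort=False):
        areas = grp[area_column].to_numpy(float)
        cut = np.percentile(areas, percentile_cut)
        ref_rows = grp[areas <= cut]
        if ref_rows.empty:
            warnings.warn(f"experiment {exp!r}: empty reference set, excluded")
            continue
        g = grp.copy()
        bad = False
        for col in intensity_columns:
            ref = float(ref_rows[col].median())
            if not np.isfinite(ref) or ref == 0:
                warnings.warn(f"experiment {exp!r}: degenerate reference for {col!r}, excluded")
                bad = True
                break
            g[col] = g[col] / ref
        if not bad:
            out.append(g)
    if not out:
        raise ValueError("no experiment had a usable reference set")
    return pd.concat(out).loc[[i for g in out for i in g.index]]


def _quartiles(x: np.ndarray, method: str) -> tuple[float, float, float]:
    q1, q2, q3 = np.quantile(x, [0.25, 0.5, 0.75], method=method)
    return float(q1), float(q2), float(q3)


def cohort_descriptors(
    cmacs: pd.DataFrame,
    feature_cols: list[str],
    by: tuple[str, ...] = ("cell_trace_id", "frame_number"),
    area_column: str | None = "area",
    lifetime_column: str | None = "lifetime",
    content_columns: tuple[str, ...] = (),
    method: str = "linear",
    literal_formulas: bool = False,
) -> pd.DataFrame:
    """Per-cohort distribution summaries of CMAC features.

    One output row per group in ``by`` (a cohort = one cell at one time
    point). For each feature: q1/q2/q3 under the chosen quantile ``method``,
    QD, QS and CoV. QS is undefined (NaN) when QD = 0 and CoV when q2 = 0.
    Cohort sums are emitted for ``area_column`` and each ``content_columns``
    entry, and the mean of ``lifetime_column``.

    ``literal_formulas=True`` switches to the alternative operator placement
    QD = 2(q3 − q1), QS = q2 − (q3 − q1)/(2·QD) for sensitivity analysis.
    """
    rows = []
    for key, grp in cmacs.groupby(list(by), sort=False):
        if not isinstance(key, tuple):
            key = (key,)
        rec: dict[str, object] = dict(zip(by, key))
        rec["n_cmacs"] = len(grp)
        for col in feature_cols:
            x = grp[col].to_numpy(float)
            q1, q2, q3 = _quartiles(x, method)
            if literal_formulas:
                qd = 2.0 * (q3 - q1)
                qs = q2 - (q3 - q1) / (2.0 * qd) if qd != 0 else np.nan
            else:
                qd = (q3 - q1) / 2.0
                qs = (q2 - (q1 + q3) / 2.0) / qd if qd != 0 else np.nan
            cov = qd / q2 if q2 != 0 else np.nan
            rec.update(
                {
                    f"{col}_q1": q1,
                    f"{col}_median": q2,
                    f"{col}_q3": q3,
                    f"{col}_QD": qd,
                    f"{col}_QS": qs,
                    f"{col}_CoV": cov,
                }
            )
        if area_column and area_column in grp:
            rec["total_area"] = float(grp[area_column].sum())
        for col in content_columns:
            rec[f"total_{col}"] = float(grp[col].sum())
        if lifetime_column and lifetime_column in grp:
            rec["mean_lifetime"] = float(grp[lifetime_column].mean())
        rows.append(rec)
    if not rows:
        raise ValueError("no cohorts to summarize")
    return pd.DataFrame(rows)
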