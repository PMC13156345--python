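"""Dataset I/O, configuration, and the end-to-end pipeline runner.

The interchange format is long-format delimited text (CSV) with one row per
sample: ``subject_id, period, analyte, time_h, conc_nM, censored``.
Censored (below-LOQ) rows carry an empty concentration field.  Times are
decimal hours post dose; predose samples are encoded with negative times.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import nca as _nca
from . import nmr as _nmr
from . import simulate as _sim
from . import stats as _stats

__all__ = [
    "PipelineConfig",
    "PipelineResults",
    "read_dataset",
    "render_report",
    "run_pipeline",
    "write_dataset",
]

logger = logging.getLogger("crosspk")

REQUIRED_COLUMNS = ["subject_id", "period", "analyte", "time_h", "conc_nM", "censored"]


# ---------------------------------------------------------------------------
# Dataset read/write
# ---------------------------------------------------------------------------

def write_dataset(records: pd.DataFrame | _sim.StudyDataset, path) -> None:
    """Write long-format records as UTF-8 CSV with deterministic row order."""
    if isinstance(records, _sim.StudyDataset):
        records = records.records
    df = records[REQUIRED_COLUMNS].sort_values(
        ["subject_id", "period", "analyte", "time_h"], kind="mergesort"
    )
    out = df.copy()
    out["censored"] = out["censored"].map({True: "true", False: "false"})
    out.to_csv(path, index=False, float_format="%.10g", encoding="utf-8")


def read_dataset(path) -> pd.DataFrame:
    """Read and validate a long-format concentration dataset.

    Rejects schema mismatches (naming the missing column), duplicate
    (subject, period, analyte, time) rows, negative concentrations (with the
    offending row number), censored rows carrying a value, and non-monotone
    times within a profile.
    """
    df = pd.read_csv(path, dtype={"subject_id": str, "period": str, "analyte": str})
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"dataset is missing required column {col!r}")
    df["censored"] = (
        df["censored"].astype(str).str.strip().str.lower().map(
            {"true": True, "false": False, "1": True, "0": False}
        )
    )
    if df["censored"].isna().any():
        raise ValueError("censored column must be true/false")
    df["time_h"] = pd.to_numeric(df["time_h"])
    df["conc_nM"] = pd.to_numeric(df["conc_nM"])

    neg = df.index[df["conc_nM"] < 0]
    if len(neg):
        raise ValueError(f"negative concentration at data row {int(neg[0]) + 2}")
    bad_cens = df.index[df["censored"] & df["conc_nM"].notna()]
    if len(bad_cens):
        raise ValueError(
            f"censored row {int(bad_cens[0]) + 2} carries a numeric concentration"
        )
    bad_obs = df.index[~df["censored"] & df["conc_nM"].isna()]
    if len(bad_obs):
        raise ValueError(f"uncensored row {int(bad_obs[0]) + 2} has no concentration")

    keys = ["subject_id", "period", "analyte", "time_h"]
    if df.duplicated(subset=keys).any():
        dup = df[df.duplicated(subset=keys, keep=False)].iloc[0]
        raise ValueError(
            "duplicate sample for "
            f"({dup.subject_id}, {dup.period}, {dup.analyte}, t={dup.time_h})"
        )
    for (s, p, a), grp in df.groupby(["subject_id", "period", "analyte"]):
        if np.any(np.diff(grp["time_h"].to_numpy()) <= 0):
            raise ValueError(f"times not strictly increasing for ({s}, {p}, {a})")
    return df.reset_index(drop=True)


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Configuration of one pipeline run (one drug arm)."""

    drug: str = "nicotine"                    # nicotine | letrozole
    input_path: str | None = None             # read this dataset instead of simulating
    n_subjects: int = 16
    seed: int = 0
    iiv_cv: float | None = None               # None -> drug-specific default
    intra_cv: float | None = None
    prop_error_cv: float | None = None
    phi0: float = 1.0
    activity_mode: str = "constant"
    k_change: float = 0.0
    ci_level: float = 0.90
    bounds: tuple[float, float] = _stats.NO_EFFECT_BOUNDS
    nmr_rel_tol: float = 0.10
    pauc_convention: str = "metabolite_auc_ratio"
    auc_method: str = "linear_up_log_down"
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if self.drug not in ("nicotine", "letrozole"):
            raise ValueError("drug must be 'nicotine' or 'letrozole'")
        if not 0 < self.ci_level < 1:
            raise ValueError("ci_level must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "bounds" in raw:
            raw["bounds"] = tuple(raw["bounds"])
        return cls(**raw)

    def parameters(self) -> _sim.CascadeParameters:
        return (
            _sim.nicotine_parameters()
            if self.drug == "nicotine"
            else _sim.letrozole_parameters()
        )

    def design(self) -> _sim.SimulationDesign:
        activity = _sim.Cyp2A6Activity(
            phi0=self.phi0, mode=self.activity_mode, k_change=self.k_change
        )
        maker = (
            _sim.nicotine_study_design
            if self.drug == "nicotine"
            else _sim.letrozole_study_design
        )
        kwargs = dict(n_subjects=self.n_subjects, seed=self.seed, activity_exposure=activity)
        for name in ("iiv_cv", "intra_cv", "prop_error_cv"):
            if getattr(self, name) is not None:
                kwargs[name] = getattr(self, name)
        return maker(**kwargs)


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

#: Endpoints compared between periods as GMRs, per analyte role.
_PARENT_ENDPOINTS = [
    ("cmax_nM", "Cmax (nM)"),
    ("auc_window_nMh", "AUC (h*nM)"),
    ("t_half_h", "t1/2 (h)"),
    ("cl_f_Lh", "CL/F (L/h)"),
]
_METABOLITE_ENDPOINTS = [
    ("cmax_nM", "Cmax (nM)"),
    ("auc_window_nMh", "AUC (h*nM)"),
]
_NMR_ENDPOINTS = [
    ("nmr_4h", "NMR at 4 h"),
    ("nmr_6h", "NMR at 6 h"),
    ("nmr_8h", "NMR at 8 h"),
    ("pauc_ratio_3_8", "NMR AUC3-8h ratio"),
    ("slope_all", "NMR slope, all time points (1/h)"),
    ("slope_linear", "NMR slope, linear window (1/h)"),
]


@dataclass
class PipelineResults:
    """Everything one pipeline run produces."""

    config: PipelineConfig
    records: pd.DataFrame
    nca_table: pd.DataFrame
    nmr_table: pd.DataFrame | None
    gmr_table: pd.DataFrame
    tmax_table: pd.DataFrame
    exclusions: list[str] = field(default_factory=list)
    report: str = ""


def _paired_values(table: pd.DataFrame, column: str) -> tuple[np.ndarray, list[str]]:
    """Pivot one endpoint to complete (baseline, exposure) pairs.

    Returns the (n, 2) pair array and the list of excluded subjects (missing
    either period or a nonpositive/NaN value).
    """
    wide = table.pivot_table(
        index="subject_id", columns="period", values=column, aggfunc="first",
        dropna=False,
    )
    for per in _sim.PERIODS:
        if per not in wide:
            wide[per] = np.nan
    ok = wide[list(_sim.PERIODS)].gt(0).all(axis=1) & wide[list(_sim.PERIODS)].notna().all(axis=1)
    excluded = [str(s) for s in wide.index[~ok]]
    pairs = wide.loc[ok, list(_sim.PERIODS)].to_numpy(dtype=float)
    return pairs, excluded


def _endpoint_rows(
    table: pd.DataFrame,
    endpoints: list[tuple[str, str]],
    label_prefix: str,
    config: PipelineConfig,
    exclusions: list[str],
) -> list[dict]:
    rows = []
    for column, label in endpoints:
        if column not in table.columns:
            continue
        name = f"{label_prefix}{label}"
        pairs, excluded = _paired_values(table, column)
        if excluded:
            msg = f"{name}: excluded {len(excluded)} subject(s) {excluded}"
            exclusions.append(msg)
            logger.info(msg)
        if pairs.shape[0] < 2:
            exclusions.append(f"{name}: fewer than 2 complete pairs; endpoint skipped")
            logger.warning("endpoint %s skipped: fewer than 2 complete pairs", name)
            continue
        res = _stats.paired_gmr(
            _stats.PairedEndpoint(endpoint_name=name, pairs=pairs),
            level=config.ci_level,
            bounds=config.bounds,
        )
        rows.append(
            {
                "endpoint": name,
                "n": res.n,
                "gm_baseline": res.gm_baseline[0],
                "gm_baseline_lo": res.gm_baseline[1],
                "gm_baseline_hi": res.gm_baseline[2],
                "gm_exposure": res.gm_exposure[0],
                "gm_exposure_lo": res.gm_exposure[1],
                "gm_exposure_hi": res.gm_exposure[2],
                "gmr": res.gmr,
                "ci_low": res.ci_low,
                "ci_high": res.ci_high,
                "p_value": res.p_value,
                "decision": res.decision,
            }
        )
    return rows


def run_pipeline(config: PipelineConfig) -> PipelineResults:
    """Run simulate/read → NCA → NMR → paired statistics → report.

    Subjects missing either period for an endpoint are excluded listwise for
    that endpoint and counted in ``results.exclusions``.  Writes CSV outputs
    and the rendered report into ``config.output_dir`` when set.
    """
    params = config.parameters()
    if config.input_path:
        records = read_dataset(config.input_path)
        logger.info("read %d rows from %s", len(records), config.input_path)
    else:
        dataset = _sim.simulate_crossover_study(config.design(), params)
        records = dataset.records
        logger.info(
            "simulated %s study: n=%d, seed=%d, phi0=%.3g (%s)",
            config.drug, config.n_subjects, config.seed, config.phi0, config.activity_mode,
        )

    dose_map = {params.analytes[0]: params.dose_nmol}
    nca_table = _nca.nca_dataset(records, dose_nmol=dose_map, method=config.auc_method)

    nmr_table = None
    if "cotinine" in set(records.analyte):
        nmr_table = _nmr.nmr_dataset(
            records,
            rel_tol=config.nmr_rel_tol,
            pauc_convention=config.pauc_convention,
        )

    exclusions: list[str] = []
    rows: list[dict] = []
    parent = params.analytes[0]
    for analyte in params.analytes:
        sub = nca_table[nca_table.analyte == analyte]
        endpoints = _PARENT_ENDPOINTS if analyte == parent else _METABOLITE_ENDPOINTS
        rows += _endpoint_rows(sub, endpoints, f"{analyte} ", config, exclusions)
    if nmr_table is not None and not nmr_table.empty:
        rows += _endpoint_rows(nmr_table, _NMR_ENDPOINTS, "", config, exclusions)
    gmr_table = pd.DataFrame(rows)

    # tmax is summarised descriptively: median (min-max), no test.
    tmax_rows = []
    for (analyte, period), grp in nca_table.groupby(["analyte", "period"]):
        vals = grp["tmax_h"].dropna()
        if vals.empty:
            continue
        tmax_rows.append(
            {
                "analyte": analyte,
                "period": period,
                "median_h": float(vals.median()),
                "min_h": float(vals.min()),
                "max_h": float(vals.max()),
                "n": int(vals.size),
            }
        )
    tmax_table = pd.DataFrame(tmax_rows)

    results = PipelineResults(
        config=config,
        records=records,
        nca_table=nca_table,
        nmr_table=nmr_table,
        gmr_table=gmr_table,
        tmax_table=tmax_table,
        exclusions=exclusions,
    )
    results.report = render_report(results)

    if config.output_dir:
        outdir = Path(config.output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_dataset(records, outdir / "concentrations.csv")
        nca_table.to_csv(outdir / "nca.csv", index=False, float_format="%.6g")
        if nmr_table is not None:
            nmr_table.to_csv(outdir / "nmr.csv", index=False, float_format="%.6g")
        gmr_table.to_csv(outdir / "gmr.csv", index=False, float_format="%.6g")
        (outdir / "report.md").write_text(results.report, encoding="utf-8")
        logger.info("wrote outputs to %s", outdir)
    return results


# ---------------------------------------------------------------------------
# Report rendering
# ---------------------------------------------------------------------------

EM_DASH = "–"


def _fmt(x: float, digits: int = 3) -> str:
    if x is None or (isinstance(x, float) and not math.isfinite(x)):
        return EM_DASH
    return f"{x:.{digits}g}"


def _fmt_ci(value: float, lo: float, hi: float) -> str:
    if not (math.isfinite(value) and math.isfinite(lo) and math.isfinite(hi)):
        return EM_DASH
    return f"{_fmt(value)} ({_fmt(lo)}{EM_DASH}{_fmt(hi)})"


def render_report(results: PipelineResults) -> str:
    """Render the paired-comparison summary as deterministic markdown.

    Cells are geometric mean (CI); tmax rows are median (min–max); missing
    endpoints render as an en-dash.
    """
    cfg = results.config
    lines = [
        f"# Crossover interaction analysis: {cfg.drug}",
        "",
        f"CI level {cfg.ci_level:.2f}; no-effect bounds "
        f"{cfg.bounds[0]:.2f}{EM_DASH}{cfg.bounds[1]:.2f}.",
        "",
        "| Endpoint | n | Baseline | Exposure | exposure/Baseline | p | Decision |",
        "|---|---|---|---|---|---|---|",
    ]
    for _, row in results.gmr_table.iterrows():
        lines.append(
            "| {endpoint} | {n} | {base} | {expo} | {ratio} | {p} | {dec} |".format(
                endpoint=row["endpoint"],
                n=int(row["n"]),
                base=_fmt_ci(row["gm_baseline"], row["gm_baseline_lo"], row["gm_baseline_hi"]),
                expo=_fmt_ci(row["gm_exposure"], row["gm_exposure_lo"], row["gm_exposure_hi"]),
                ratio=_fmt_ci(row["gmr"], row["ci_low"], row["ci_high"]),
                p=_fmt(row["p_value"], 4),
                dec=row["decision"],
            )
        )
    if not results.tmax_table.empty:
        lines += [
            "",
            "| tmax (h) | period | median (min" + EM_DASH + "max) | n |",
            "|---|---|---|---|",
        ]
        for _, row in results.tmax_table.iterrows():
            lines.append(
                f"| {row['analyte']} | {row['period']} | "
                f"{_fmt(row['median_h'])} ({_fmt(row['min_h'])}{EM_DASH}{_fmt(row['max_h'])}) | "
                f"{int(row['n'])} |"
            )
    if results.exclusions:
        lines += ["", "## Exclusions", ""]
        lines += [f"- {msg}" for msg in results.exclusions]
    lines.append("")
    return "\n".join(lines)
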