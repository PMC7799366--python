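"""Reading, validation and writing of cohort tables.

Canonical interchange is long (tidy) CSV: one row per (tumor, condition,
analyte) measurement, which tolerates untested cells without sentinel
values.  Below-LLOQ concentrations are stored as the reported LLOQ with a
flag rather than as zero, preserving the information the fold-ratio policy
needs.  Sample eligibility mirrors the assay's entry criteria (viable
CD45+ fraction strictly above 0.2% and more than one million cells), and
tumor-supernatant concentrations can be normalized by total protein.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import yaml

from .errors import DomainError, ValidationError
from .synthetic import PANEL_27

#: Packaged analyte vocabulary: the 27-plex panel plus the 1-plex CXCL13 assay.
ANALYTE_REGISTRY = list(PANEL_27) + ["CXCL13"]

CONCENTRATION_COLUMNS = ["tumor_id", "condition", "analyte", "concentration", "censor_flag"]
CENSOR_FLAGS = {"in_range", "below_lloq", "above_uloq", "missing"}
METADATA_COLUMNS = [
    "tumor_id", "histotype", "cd45_viable_pct", "total_cells",
    "supernatant_total_protein", "provenance",
]
SURVIVAL_COLUMNS = ["patient_id", "time", "event", "biomarker", "cohort"]
PHENOTYPE_COLUMNS = ["tumor_id", "subset", "marker", "value", "n_events"]

#: Flow features acquired on fewer events than this are flagged unusable.
MIN_FLOW_EVENTS = 500

CD45_VIABLE_CUTOFF_PCT = 0.2
TOTAL_CELLS_CUTOFF = 1_000_000


def validate_concentration_table(df: pd.DataFrame, allow_unknown: bool = False) -> pd.DataFrame:
    """Validate a long concentration table in place and return it."""
    missing_cols = [c for c in CONCENTRATION_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValidationError(f"missing required columns: {missing_cols}")
    dup = df.duplicated(subset=["tumor_id", "condition", "analyte"], keep=False)
    if dup.any():
        keys = (
            df.loc[dup, ["tumor_id", "condition", "analyte"]]
            .drop_duplicates()
            .itertuples(index=False, name=None)
        )
        raise ValidationError(f"duplicate (tumor, condition, analyte) keys: {list(keys)}")
    bad_flags = set(df["censor_flag"].dropna()) - CENSOR_FLAGS
    if bad_flags:
        raise ValidationError(f"unknown censor flags: {sorted(bad_flags)}")
    conc = pd.to_numeric(df["concentration"], errors="coerce")
    neg = conc < 0
    if neg.any():
        raise ValidationError(
            f"negative concentrations for rows {df.index[neg].tolist()}"
        )
    # missing concentration iff flagged missing
    is_na = conc.isna()
    flagged = df["censor_flag"] == "missing"
    if (is_na != flagged).any():
        raise ValidationError("concentration must be missing iff censor_flag == 'missing'")
    if not allow_unknown:
        unknown = set(df["analyte"]) - set(ANALYTE_REGISTRY)
        if unknown:
            raise ValidationError(
                f"unknown analytes {sorted(unknown)}; pass allow_unknown=True to accept"
            )
    df = df.copy()
    df["concentration"] = conc
    return df


def read_concentration_table(path, allow_unknown: bool = False) -> pd.DataFrame:
    """Read and validate a long concentration CSV."""
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"no such file: {path}")
    df = pd.read_csv(path)
    return validate_concentration_table(df, allow_unknown=allow_unknown)


def qc_eligibility(meta) -> tuple[bool, list[str]]:
    """Eligibility of one sample for the ex vivo assay.

    Eligible iff viable CD45+ > 0.2% AND absolute cell count > 1,000,000
    (both strict).  ``meta`` is a mapping/Series with ``cd45_viable_pct``
    and ``total_cells``.  Returns (eligible, list of failed criteria).
    """
    for f in ("cd45_viable_pct", "total_cells"):
        if f not in meta or pd.isna(meta[f]):
            raise ValidationError(f"missing metadata field {f!r}")
    reasons = []
    if not meta["cd45_viable_pct"] > CD45_VIABLE_CUTOFF_PCT:
        reasons.append(f"CD45 <= {CD45_VIABLE_CUTOFF_PCT}%")
    if not meta["total_cells"] > TOTAL_CELLS_CUTOFF:
        reasons.append(f"cell count <= {TOTAL_CELLS_CUTOFF:,}")
    return (len(reasons) == 0, reasons)


def qc_cohort(metadata: pd.DataFrame) -> pd.DataFrame:
    """Apply :func:`qc_eligibility` row-wise; adds eligible / reasons columns."""
    out = metadata.copy()
    flags = out.apply(lambda r: qc_eligibility(r), axis=1)
    out["eligible"] = [f[0] for f in flags]
    out["qc_reasons"] = ["; ".join(f[1]) for f in flags]
    return out


def normalize_by_protein(conc: float, total_protein: float) -> float:
    """pg/ml divided by mg/ml total protein -> pg per mg protein."""
    if not total_protein > 0:
        raise DomainError(f"total_protein must be positive, got {total_protein}")
    return conc / total_protein


def flag_low_event_features(phenotype: pd.DataFrame) -> pd.DataFrame:
    """Mark flow features acquired on < 500 events as unusable (kept, flagged)."""
    out = phenotype.copy()
    out["usable"] = out["n_events"] >= MIN_FLOW_EVENTS
    return out


def wide_matrix(conc: pd.DataFrame, condition: str, value: str = "concentration") -> pd.DataFrame:
    """Tumors x analytes wide export of one condition."""
    sub = conc[conc["condition"] == condition]
    return sub.pivot_table(index="tumor_id", columns="analyte", values=value, aggfunc="first")


def write_cohort(outdir, concentrations, metadata, truth=None, phenotype=None,
                 survival=None, config=None) -> dict:
    """Write a cohort bundle to CSV (+ YAML config); returns the path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    tables = {
        "concentrations.csv": concentrations,
        "metadata.csv": metadata,
        "truth.csv": truth,
        "phenotype.csv": phenotype,
        "survival.csv": survival,
    }
    for name, df in tables.items():
        if df is not None:
            p = outdir / name
            df.to_csv(p, index=False)
            paths[name] = p
    if config is not None:
        p = outdir / "config.yaml"
        with open(p, "w") as fh:
            yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
        paths["config.yaml"] = p
    return paths


def read_cohort(indir) -> dict:
    """Read back a cohort bundle written by :func:`write_cohort`."""
    indir = Path(indir)
    out = {}
    conc_path = indir / "concentrations.csv"
    if conc_path.exists():
        out["concentrations"] = read_concentration_table(conc_path)
    for name in ("metadata", "truth", "phenotype", "survival"):
        p = indir / f"{name}.csv"
        if p.exists():
            out[name] = pd.read_csv(p)
    cfg = indir / "config.yaml"
    if cfg.exists():
        with open(cfg) as fh:
            out["config"] = yaml.safe_load(fh)
    return out


def write_report(bundle: dict, outdir) -> dict:
    """Write a results bundle: CSV per table, JSON summary.

    ``bundle`` maps names to DataFrames, plus an optional ``"summary"``
    dict serialized to ``report.json``.  CSV floats round-trip exactly
    (pandas writes shortest-repr floats).
    """
    outdir = Path(outdir)
    try:
        outdir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise IOError(f"cannot create report directory {outdir}: {exc}") from exc
    paths = {}
    for name, obj in bundle.items():
        if name == "summary":
            p = outdir / "report.json"
            with open(p, "w") as fh:
                json.dump(obj, fh, indent=2, default=str)
            paths["report.json"] = p
        elif isinstance(obj, pd.DataFrame):
            p = outdir / f"{name}.csv"
            obj.to_csv(p, index=not isinstance(obj.index, pd.RangeIndex))
            paths[f"{name}.csv"] = p
    return paths
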