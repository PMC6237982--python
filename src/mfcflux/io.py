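"""CSV/JSON interchange and the end-to-end analysis pipeline.

Interchange format: plain CSV with ``#``-prefixed ``key=value`` metadata
comment lines for the reactor constants, columns ``time_h, voltage_v,
cod_mg_l, no3n_mg_l, no2n_mg_l, nh4n_mg_l`` (blank cell = not measured).
Files holding several concatenated cycles are split wherever the voltage
stays below the 20 mV cycle-end threshold for at least 3 consecutive
samples.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable

import numpy as np
import pandas as pd

from .balance import (
    BatchCycleRecord,
    CYCLE_END_VOLTAGE_V,
    ElectronBalance,
    ReactorSpec,
    net_cod_n_ratio,
    partition,
)
from .electrochem import (
    PolarizationCurve,
    Voltammogram,
    detect_redox_peaks,
    polarization_analysis,
)
from .exceptions import DomainError, NoInputError, SchemaError
from .kinetics import fit_first_order, volumetric_removal_rate
from .stoichiometry import DEFAULT_CONSTANTS, StoichiometryConstants

__all__ = [
    "RunConfig",
    "read_cycle_csv",
    "write_cycle_csv",
    "read_polarization_csv",
    "read_voltammogram_csv",
    "balance_to_dict",
    "run_pipeline",
    "split_cycles",
]

logger = logging.getLogger("mfcflux")

REPORT_SCHEMA_VERSION = "1"

CYCLE_COLUMNS = ["time_h", "voltage_v", "cod_mg_l", "no3n_mg_l", "no2n_mg_l", "nh4n_mg_l"]
MANDATORY_CYCLE_COLUMNS = ["time_h", "voltage_v", "cod_mg_l", "no3n_mg_l"]


@dataclass
class RunConfig:
    """Everything one reproducible pipeline run needs."""

    inputs: list[str] = field(default_factory=list)
    output_dir: str = "mfcflux_out"
    reactor: ReactorSpec = field(default_factory=ReactorSpec)
    constants: StoichiometryConstants = field(default_factory=lambda: DEFAULT_CONSTANTS)
    include_nitrite_correction: bool = False
    cod_n_mode: str = "residual"
    cv_smooth_window: int = 11
    kinetics_method: str = "log-linear"
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        try:
            data = json.loads(text)
        except json.JSONDecodeError:
            import yaml

            data = yaml.safe_load(text)
        reactor = ReactorSpec(**data.pop("reactor", {}))
        constants = StoichiometryConstants.from_mapping(data.pop("constants", {}))
        return cls(reactor=reactor, constants=constants, **data)


def _read_header_metadata(path: Path) -> dict[str, float]:
    meta: dict[str, float] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line.lstrip("#").strip()
            if "=" in body:
                key, _, value = body.partition("=")
                try:
                    meta[key.strip()] = float(value.strip())
                except ValueError:
                    pass
    return meta


def split_cycles(
    df: pd.DataFrame,
    threshold_v: float = CYCLE_END_VOLTAGE_V,
    debounce: int = 3,
) -> list[pd.DataFrame]:
    """Split a multi-cycle table at sustained sub-threshold voltage runs.

    A cycle ends with (and includes) the first run of at least ``debounce``
    consecutive samples below ``threshold_v``; the next cycle starts at the
    next above-threshold sample.
    """
    v = df["voltage_v"].to_numpy(dtype=float)
    below = v < threshold_v
    cycles: list[pd.DataFrame] = []
    start = 0
    run = 0
    in_gap = False
    for i, b in enumerate(below):
        if in_gap:
            if not b:  # cycle restart
                cycles.append(df.iloc[start:i])
                start = i
                in_gap = False
                run = 0
            continue
        run = run + 1 if b else 0
        if run >= debounce:
            in_gap = True
    cycles.append(df.iloc[start:])
    return [c.reset_index(drop=True) for c in cycles if len(c)]


def _df_to_record(df: pd.DataFrame, reactor: ReactorSpec) -> BatchCycleRecord:
    def col(name: str) -> np.ndarray | None:
        if name not in df.columns:
            return None
        return df[name].to_numpy(dtype=float)

    return BatchCycleRecord(
        time_h=df["time_h"].to_numpy(dtype=float),
        voltage_v=df["voltage_v"].to_numpy(dtype=float),
        cod_mg_l=col("cod_mg_l"),
        no3n_mg_l=col("no3n_mg_l"),
        no2n_mg_l=col("no2n_mg_l"),
        nh4n_mg_l=col("nh4n_mg_l"),
        reactor=reactor,
    )


def read_cycle_csv(
    path: str | Path,
    reactor: ReactorSpec | None = None,
    split: bool = True,
) -> list[BatchCycleRecord]:
    """Read one cycle CSV into records, splitting concatenated cycles.

    Reactor metadata in ``# key=value`` header comments is used unless a
    ``reactor`` override is given.  Missing mandatory columns raise a
    SchemaError naming them; non-monotone time raises with the row index.
    """
    path = Path(path)
    df = pd.read_csv(path, comment="#", skip_blank_lines=True)
    missing = [c for c in MANDATORY_CYCLE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{path.name}: missing mandatory column(s) {missing}; "
            f"expected {MANDATORY_CYCLE_COLUMNS} (plus optional no2n_mg_l, nh4n_mg_l)"
        )
    if reactor is None:
        meta = _read_header_metadata(path)
        reactor = ReactorSpec(
            anolyte_volume_l=meta.get("anolyte_volume_l", 0.015),
            external_resistance_ohm=meta.get("external_resistance_ohm", 1000.0),
            cathode_area_m2=meta.get("cathode_area_m2", 7e-4),
        )
    frames = split_cycles(df) if split else [df]
    return [_df_to_record(f, reactor) for f in frames]


def write_cycle_csv(path: str | Path, record: BatchCycleRecord, float_format: str = "%.10g") -> None:
    """Write one record in the dialect :func:`read_cycle_csv` consumes."""
    path = Path(path)
    data: dict[str, np.ndarray] = {
        "time_h": record.time_h,
        "voltage_v": record.voltage_v,
        "cod_mg_l": record.cod_mg_l,
        "no3n_mg_l": record.no3n_mg_l,
    }
    if record.no2n_mg_l is not None:
        data["no2n_mg_l"] = record.no2n_mg_l
    if record.nh4n_mg_l is not None:
        data["nh4n_mg_l"] = record.nh4n_mg_l
    header = "".join(
        f"# {k}={getattr(record.reactor, k):.10g}\n"
        for k in ("anolyte_volume_l", "external_resistance_ohm", "cathode_area_m2")
    )
    with open(path, "w") as fh:
        fh.write(header)
        pd.DataFrame(data).to_csv(fh, index=False, float_format=float_format)


def read_polarization_csv(path: str | Path, cathode_area_m2: float | None = None) -> PolarizationCurve:
    """Read a resistance sweep: columns ``resistance_ohm, voltage_v``."""
    path = Path(path)
    df = pd.read_csv(path, comment="#")
    missing = [c for c in ("resistance_ohm", "voltage_v") if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing column(s) {missing}")
    if cathode_area_m2 is None:
        cathode_area_m2 = _read_header_metadata(path).get("cathode_area_m2", 7e-4)
    return PolarizationCurve(
        resistance_ohm=df["resistance_ohm"].to_numpy(dtype=float),
        voltage_v=df["voltage_v"].to_numpy(dtype=float),
        cathode_area_m2=cathode_area_m2,
    )


def read_voltammogram_csv(path: str | Path, scan_rate_v_s: float = 0.001) -> Voltammogram:
    """Read a CV sweep: columns ``potential_v, current_a`` (+ optional ``segment``)."""
    path = Path(path)
    df = pd.read_csv(path, comment="#")
    missing = [c for c in ("potential_v", "current_a") if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing column(s) {missing}")
    segment = df["segment"].to_numpy(dtype=object) if "segment" in df.columns else None
    return Voltammogram(
        potential_v=df["potential_v"].to_numpy(dtype=float),
        current_a=df["current_a"].to_numpy(dtype=float),
        scan_rate_v_s=scan_rate_v_s,
        segment=segment,
    )


def _clean(value: Any) -> Any:
    if isinstance(value, float) and math.isnan(value):
        return None
    return value


def balance_to_dict(balance: ElectronBalance) -> dict[str, Any]:
    out = {
        "c_t": balance.c_t,
        "c_an": balance.c_an,
        "c_de": balance.c_de,
        "c_ot": balance.c_ot,
        "ce_pct": _clean(balance.ce_pct),
        "cce_pct": _clean(balance.cce_pct),
    }
    if balance.c_t > 0:
        out["fractions"] = balance.fractions
    return out


def _analyze_cycle(record: BatchCycleRecord, config: RunConfig) -> dict[str, Any]:
    bal = partition(
        record,
        include_nitrite_correction=config.include_nitrite_correction,
        constants=config.constants,
    )
    result: dict[str, Any] = {"balance": balance_to_dict(bal), "duration_h": record.duration_h}
    n_removed = record.delta("no3n_mg_l")
    if record.no3n_mg_l[0] > 0 and n_removed > 0:
        fit = fit_first_order(record.time_h, record.no3n_mg_l, method=config.kinetics_method)
        rate = volumetric_removal_rate(
            float(record.no3n_mg_l[0]),
            min(max(n_removed / record.no3n_mg_l[0], 0.0), 1.0),
            record.duration_h,
        )
        result["kinetics"] = {
            "k_per_h": fit.k,
            "c0_mg_l": fit.c0,
            "r_squared": fit.r_squared,
            "method": fit.method,
        }
        result["removal_rate"] = {
            "mg_n_per_l_h": rate.mg_n_per_l_h,
            "kg_n_per_m3_d": rate.kg_n_per_m3_d,
        }
        result["net_cod_n_ratio"] = net_cod_n_ratio(record, mode=config.cod_n_mode, constants=config.constants)
    return result


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Analyze every input file cycle-by-cycle and write the report bundle.

    Produces ``report.json`` and ``summary.csv`` under ``output_dir``.  A
    failing cycle is recorded under its key with an ``error`` field and
    does not abort the remaining cycles.  Given identical inputs and
    configuration the emitted JSON is byte-identical across runs.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    paths: list[Path] = []
    for entry in config.inputs:
        p = Path(entry)
        if p.is_dir():
            paths.extend(sorted(p.glob("*.csv")))
        elif p.exists():
            paths.append(p)
        else:
            raise NoInputError(f"input path does not exist: {p}")
    if not paths:
        raise NoInputError("no input CSV files found")

    constants = config.constants
    logger.info(
        "constants: faraday=%g, e_per_acetate=%d, e_per_nitrate_to_n2=%d, "
        "mw_o2=%g, mw_n=%g, mw_sodium_acetate=%g, cod_per_g_sodium_acetate=%g",
        constants.faraday,
        constants.e_per_acetate,
        constants.e_per_nitrate_to_n2,
        constants.mw_o2,
        constants.mw_n,
        constants.mw_sodium_acetate,
        constants.cod_per_g_sodium_acetate,
    )

    report: dict[str, Any] = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "constants": dataclasses.asdict(constants),
        "settings": {
            "include_nitrite_correction": config.include_nitrite_correction,
            "cod_n_mode": config.cod_n_mode,
            "kinetics_method": config.kinetics_method,
            "seed": config.seed,
        },
        "cycles": {},
    }
    rows: list[dict[str, Any]] = []
    for path in paths:
        try:
            records = read_cycle_csv(path, reactor=config.reactor)
        except Exception as exc:  # noqa: BLE001 - per-file fault isolation
            report["cycles"][path.name] = {"error": f"{type(exc).__name__}: {exc}"}
            logger.error("failed to read %s: %s", path, exc)
            continue
        for i, record in enumerate(records):
            key = f"{path.name}#{i}"
            try:
                result = _analyze_cycle(record, config)
            except Exception as exc:  # noqa: BLE001
                report["cycles"][key] = {"error": f"{type(exc).__name__}: {exc}"}
                logger.error("cycle %s failed: %s", key, exc)
                continue
            report["cycles"][key] = result
            row = {
                "cycle": key,
                "duration_h": result["duration_h"],
                "ce_pct": result["balance"]["ce_pct"],
                "cce_pct": result["balance"]["cce_pct"],
                "f_anode": result["balance"].get("fractions", {}).get("anode_respiration"),
                "f_denit": result["balance"].get("fractions", {}).get("anodic_denitrification"),
                "f_others": result["balance"].get("fractions", {}).get("others"),
                "k_per_h": result.get("kinetics", {}).get("k_per_h"),
                "removal_kg_n_m3_d": result.get("removal_rate", {}).get("kg_n_per_m3_d"),
                "net_cod_n": result.get("net_cod_n_ratio"),
            }
            rows.append(row)

    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    pd.DataFrame(rows).to_csv(outdir / "summary.csv", index=False, float_format="%.6g")
    return report
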