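"""Readers, writers and the end-to-end pipeline orchestration.

File formats are plain text: CSV with '#' comment lines for spectra and
absorbance traces, a CSV manifest tying files to sample metadata, JSON for
results. Floats are serialized with 12 significant digits and keys are
sorted, so identical inputs give byte-identical outputs.
"""

from __future__ import annotations

import csv
import json
import logging
import math
from pathlib import Path

import numpy as np
import pandas as pd

from . import constants as C
from .correlation import CorrelationInput, linear_fit, report
from .dielectric_model import DielectricSpectrum
from .hydration import SolutionComposition, sensitivity_sweep
from .kinetics import AbsorbanceTrace, fit_decay, normalize_rates
from .spectral_fit import FitConfig, fit_pure_water

__all__ = [
    "read_spectrum", "write_spectrum", "read_trace", "write_trace",
    "read_manifest", "read_traces", "write_study", "run_pipeline",
    "analyze_study", "analyze_synthetic", "dump_json", "validate_summary",
]

log = logging.getLogger(__name__)

MANIFEST_COLUMNS = ["path", "kind", "osmolyte", "bottle_id", "replicate_id",
                    "molarity", "density", "molar_mass", "temperature"]
_KINDS = {"spectrum", "spectrum_ternary", "trace"}


class ParseError(ValueError):
    pass


def _read_table(path, columns_required):
    """Parse a commented CSV; returns (rows, meta) with line-numbered errors."""
    path = Path(path)
    meta: dict = {}
    rows: list[list[float]] = []
    header: list[str] | None = None
    with open(path, newline="") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if ":" in body:
                    key, _, val = body.partition(":")
                    meta[key.strip()] = val.strip()
                continue
            cells = next(csv.reader([line]))
            if header is None:
                header = [c.strip() for c in cells]
                missing = [c for c in columns_required if c not in header]
                if missing:
                    raise ParseError(f"{path}:{lineno}: missing columns {missing}")
                continue
            try:
                rows.append([float(c) for c in cells])
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-numeric cell in {cells!r}")
    if header is None or not rows:
        raise ParseError(f"{path}: no data rows found")
    idx = {name: header.index(name) for name in header}
    return rows, idx, meta


def read_spectrum(path) -> DielectricSpectrum:
    """Load a spectrum CSV (frequency_thz, eps_imag[, eps_real])."""
    rows, idx, meta = _read_table(path, ["frequency_thz", "eps_imag"])
    freq = [r[idx["frequency_thz"]] for r in rows]
    for i in range(len(freq)):
        if freq[i] <= 0:
            raise ParseError(f"{path}: non-positive frequency in data row {i + 1}")
        if i and freq[i] <= freq[i - 1]:
            raise ParseError(f"{path}: non-increasing frequency at data row {i + 1}")
    eps_imag = [r[idx["eps_imag"]] for r in rows]
    eps_real = [r[idx["eps_real"]] for r in rows] if "eps_real" in idx else None
    return DielectricSpectrum(
        frequencies=np.array(freq), eps_imag=np.array(eps_imag),
        eps_real=None if eps_real is None else np.array(eps_real),
        temperature=float(meta.get("temperature_C", 20.0)),
        label=meta.get("label", Path(path).stem),
    )


def write_spectrum(spectrum: DielectricSpectrum, path) -> None:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        fh.write(f"# label: {spectrum.label}\n")
        fh.write(f"# temperature_C: {_fmt(spectrum.temperature)}\n")
        cols = "frequency_thz,eps_imag"
        has_real = spectrum.eps_real is not None
        if has_real:
            cols += ",eps_real"
        fh.write(cols + "\n")
        for i in range(len(spectrum)):
            row = f"{_fmt(spectrum.frequencies[i])},{_fmt(spectrum.eps_imag[i])}"
            if has_real:
                row += f",{_fmt(spectrum.eps_real[i])}"
            fh.write(row + "\n")


def read_trace(path, osmolyte="water", bottle_id="", replicate_id="") -> AbsorbanceTrace:
    """Load a trace CSV (time_s, absorbance); metadata from args or comments."""
    rows, idx, meta = _read_table(path, ["time_s", "absorbance"])
    times = [r[idx["time_s"]] for r in rows]
    for i in range(1, len(times)):
        if times[i] <= times[i - 1]:
            raise ParseError(f"{path}: non-increasing time at data row {i + 1}")
    return AbsorbanceTrace(
        times=np.array(times),
        absorbance=np.array([r[idx["absorbance"]] for r in rows]),
        osmolyte=meta.get("osmolyte", osmolyte),
        bottle_id=meta.get("bottle_id", bottle_id),
        replicate_id=meta.get("replicate_id", replicate_id),
    )


def write_trace(trace: AbsorbanceTrace, path) -> None:
    with open(path, "w", newline="") as fh:
        fh.write(f"# osmolyte: {trace.osmolyte}\n")
        fh.write(f"# bottle_id: {trace.bottle_id}\n")
        fh.write(f"# replicate_id: {trace.replicate_id}\n")
        fh.write("time_s,absorbance\n")
        for t, a in zip(trace.times, trace.absorbance):
            fh.write(f"{_fmt(t)},{_fmt(a)}\n")


def read_manifest(path) -> pd.DataFrame:
    """Load and validate the study manifest; paths resolve relative to it."""
    path = Path(path)
    df = pd.read_csv(path, comment="#", dtype={"bottle_id": str, "replicate_id": str})
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: manifest missing columns {missing}")
    bad_kind = sorted(set(df["kind"]) - _KINDS)
    if bad_kind:
        raise ParseError(f"{path}: unknown sample kinds {bad_kind}")
    base = path.parent
    absent = [str(p) for p in df["path"] if not (base / p).exists()]
    if absent:
        raise ParseError(f"{path}: referenced files do not exist: {absent}")
    df["path"] = [str(base / p) for p in df["path"]]
    return df


def read_traces(manifest: pd.DataFrame) -> list[AbsorbanceTrace]:
    rows = manifest[manifest["kind"] == "trace"]
    return [
        read_trace(r["path"], osmolyte=r["osmolyte"], bottle_id=str(r["bottle_id"]),
                   replicate_id=str(r["replicate_id"]))
        for _, r in rows.iterrows()
    ]


def write_study(study, outdir) -> Path:
    """Emit a SyntheticStudy as the CSV/manifest bundle the pipeline reads.

    Returns the manifest path. Also writes ground_truth.json.
    """
    outdir = Path(outdir)
    (outdir / "traces").mkdir(parents=True, exist_ok=True)
    records = []

    def add(path, kind, osmolyte, bottle="", rep="", comp=None, volfrac=""):
        records.append({
            "path": path, "kind": kind, "osmolyte": osmolyte,
            "bottle_id": bottle, "replicate_id": rep,
            "molarity": "" if comp is None else comp.molarity,
            "density": "" if comp is None else comp.density,
            "molar_mass": "" if comp is None else comp.molar_mass_osmolyte,
            "temperature": 20.0,
            "volume_fraction": volfrac,
        })

    write_spectrum(study.water_spectrum, outdir / "water.csv")
    add("water.csv", "spectrum", "water")
    for name, spec in study.solution_spectra.items():
        fn = f"{name}.csv"
        write_spectrum(spec, outdir / fn)
        add(fn, "spectrum", name, comp=study.compositions[name])
    for name, spec in study.ternary_spectra.items():
        fn = f"{name}_amylase.csv"
        write_spectrum(spec, outdir / fn)
        add(fn, "spectrum_ternary", name, comp=study.compositions[name],
            volfrac=_fmt(study.ternary_c[name]))
    for tr in study.traces:
        fn = f"traces/{tr.osmolyte}_{tr.bottle_id}_{tr.replicate_id}.csv"
        write_trace(tr, outdir / fn)
        add(fn, "trace", tr.osmolyte, bottle=tr.bottle_id, rep=tr.replicate_id)

    mpath = outdir / "manifest.csv"
    cols = MANIFEST_COLUMNS + ["volume_fraction"]
    with open(mpath, "w", newline="") as fh:
        w = csv.DictWriter(fh, fieldnames=cols)
        w.writeheader()
        w.writerows(records)
    dump_json(study.ground_truth, outdir / "ground_truth.json")
    return mpath


def run_pipeline(
    manifest_path,
    out_path=None,
    fit_band: tuple[float, float] = C.FIT_BAND,
    a_s_sweep: tuple[float, ...] = C.AS_SWEEP,
    start_trim_s: float = C.START_TRIM_S,
) -> dict:
    """Execute fit -> hydration -> kinetics -> correlation on a manifest.

    Deterministic given the inputs; returns (and optionally writes) the
    study summary mirroring the two correlation panels.
    """
    manifest = read_manifest(Path(manifest_path))

    spectra = manifest[manifest["kind"] == "spectrum"]
    water_rows = spectra[spectra["osmolyte"] == "water"]
    if len(water_rows) == 0:
        raise ValueError("pipeline requires a pure-water spectrum in the manifest")
    water_spec = read_spectrum(water_rows.iloc[0]["path"])

    solutions: dict = {}
    for _, row in spectra[spectra["osmolyte"] != "water"].iterrows():
        comp = SolutionComposition(
            molarity=float(row["molarity"]), density=float(row["density"]),
            molar_mass_osmolyte=float(row["molar_mass"]),
        )
        solutions[row["osmolyte"]] = (read_spectrum(row["path"]), comp)

    ternary: dict = {}
    for _, row in manifest[manifest["kind"] == "spectrum_ternary"].iterrows():
        name = row["osmolyte"]
        if "volume_fraction" not in row or row.isna().get("volume_fraction", True):
            raise ValueError(f"ternary spectrum {name!r} needs a volume_fraction column")
        ternary[name] = (read_spectrum(row["path"]), float(row["volume_fraction"]))

    summary = analyze_study(
        water_spec, solutions, ternary, read_traces(manifest),
        fit_band=fit_band, a_s_sweep=a_s_sweep, start_trim_s=start_trim_s,
    )
    if out_path is not None:
        dump_json(summary, out_path)
    return summary


def analyze_study(
    water_spec: DielectricSpectrum,
    solutions: dict,
    ternary: dict,
    traces: list[AbsorbanceTrace],
    fit_band: tuple[float, float] = C.FIT_BAND,
    a_s_sweep: tuple[float, ...] = C.AS_SWEEP,
    start_trim_s: float = C.START_TRIM_S,
) -> dict:
    """In-memory pipeline: the same stages run_pipeline runs after loading.

    ``solutions`` maps osmolyte name -> (spectrum, SolutionComposition);
    ``ternary`` maps name -> (spectrum, water volume fraction).
    """
    cfg = FitConfig(fit_band=fit_band)
    log.info("effective config: %s", C.effective_config())
    try:
        water_fit = fit_pure_water(water_spec, cfg)
    except Exception as exc:
        raise RuntimeError(f"stage spectral_fit failed on sample 'water': {exc}") from exc

    hydration_table: dict = {}
    for name, (spec, comp) in solutions.items():
        try:
            res = sensitivity_sweep(
                spec, water_spec, composition=comp,
                a_s_values=a_s_sweep, config=cfg,
            )
        except Exception as exc:
            raise RuntimeError(f"stage hydration failed on sample {name!r}: {exc}") from exc
        hydration_table[name] = res

    ternary_table: dict = {}
    for name, (spec, c3) in ternary.items():
        try:
            res = sensitivity_sweep(
                spec, water_spec, c_override=c3,
                a_s_values=a_s_sweep, config=cfg,
            )
        except Exception as exc:
            raise RuntimeError(f"stage hydration (ternary) failed on {name!r}: {exc}") from exc
        ternary_table[name] = res

    runs = []
    for tr in traces:
        try:
            runs.append(fit_decay(tr, start_trim_s=start_trim_s))
        except Exception as exc:
            raise RuntimeError(
                f"stage kinetics failed on trace {tr.osmolyte}/{tr.bottle_id}"
                f"/{tr.replicate_id}: {exc}"
            ) from exc
    rates, rejects = normalize_rates(runs)
    rates_by_osm = {r.osmolyte: r for r in rates}

    def _panel(table: dict, axis: str):
        names = [n for n in table if n in rates_by_osm]
        if len(names) < 3:
            return None, None
        x = [table[n].n_hyd if axis == "n_hyd" else table[n].a_hyd for n in names]
        x_err = [
            ((table[n].n_hyd_hi - table[n].n_hyd_lo) / 2.0) if axis == "n_hyd"
            else ((table[n].a_hyd_hi - table[n].a_hyd_lo) / 2.0)
            for n in names
        ]
        inp = CorrelationInput(
            x=np.array(x),
            y=np.array([rates_by_osm[n].mean_ratio for n in names]),
            y_err=np.array([rates_by_osm[n].sd_ratio for n in names]),
            x_err=np.array(x_err),
            labels=names, axis_kind=axis,
        )
        return inp, linear_fit(inp)

    bin_inp, bin_res = _panel(hydration_table, "n_hyd")
    if bin_res is None:
        raise ValueError("pipeline needs >= 3 osmolytes with spectra and rates")
    ter_inp, ter_res = _panel(ternary_table, "a_hyd")

    summary = {
        "config": C.effective_config(),
        "water_fit": water_fit.to_dict(),
        "hydration": {n: h.to_dict() for n, h in hydration_table.items()},
        "hydration_ternary": {n: h.to_dict() for n, h in ternary_table.items()},
        "normalized_rates": {r.osmolyte: r.to_dict() for r in rates},
        "rejected_runs": [r.to_dict() for r in rejects],
        "correlation": report(bin_res, ter_res, bin_inp, ter_inp),
    }
    return summary


def analyze_synthetic(study, **kwargs) -> dict:
    """Run the in-memory pipeline directly on a SyntheticStudy bundle."""
    solutions = {
        name: (spec, study.compositions[name])
        for name, spec in study.solution_spectra.items()
    }
    ternary = {
        name: (spec, study.ternary_c[name])
        for name, spec in study.ternary_spectra.items()
    }
    return analyze_study(study.water_spectrum, solutions, ternary,
                         study.traces, **kwargs)


def _fmt(x) -> str:
    return format(float(x), ".12g")


def _round12(obj):
    if isinstance(obj, dict):
        return {k: _round12(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round12(v) for v in obj]
    if isinstance(obj, (bool, np.bool_)):
        return bool(obj)
    if isinstance(obj, (float, np.floating)):
        if math.isnan(obj):
            return None
        return float(_fmt(obj))
    if isinstance(obj, (int, np.integer)):
        return int(obj)
    return obj


def dump_json(obj, path) -> None:
    """Write JSON with sorted keys and 12-significant-digit floats."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(_round12(obj), fh, indent=2, sort_keys=True)
        fh.write("\n")


def validate_summary(summary: dict) -> None:
    """Check a pipeline summary against the shipped schema (required keys)."""
    from importlib import resources

    schema = json.loads(
        resources.files("thzhyd.data").joinpath("summary.schema.json").read_text()
    )
    _check(summary, schema, "summary")


def _check(obj, schema, where: str) -> None:
    typ = schema.get("type")
    if typ == "object":
        if not isinstance(obj, dict):
            raise ValueError(f"{where}: expected object")
        for key, sub in schema.get("required_properties", {}).items():
            if key not in obj:
                raise ValueError(f"{where}: missing required key {key!r}")
            _check(obj[key], sub, f"{where}.{key}")
    elif typ == "number":
        if obj is not None and not isinstance(obj, (int, float)):
            raise ValueError(f"{where}: expected number, got {type(obj).__name__}")
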