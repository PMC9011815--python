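"""End-to-end pipeline stages: simulate -> analyze -> qualify / kinetics.

Sample ids written by the simulator encode the battery each trace belongs
to (``ladder``, ``blank_*``, ``lin_*`` linearity series, ``dil_*`` dilution
series, ``rec_*`` recovery design, ``T*_d*`` stability study), and the
qualification stage groups results by those prefixes plus the sample-sheet
role column. A run is reproducible from (config, seed) alone: every trace's
noise seed is derived deterministically from the global seed and its
sample id.
"""

from __future__ import annotations

import warnings
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import calibration as cal_mod
from . import integration as integ
from . import qualification as qual
from . import synthetic as synth
from . import traceio
from .config import RunConfig
from .errors import RibotraceError
from .kinetics import DegradationStudy
from .synthetic import SampleScenario, child_seed
from .traceio import Trace, TraceMeta


def calibration_from_model(model: synth.MigrationModel) -> cal_mod.SizeCalibration:
    """Nominal size calibration implied by a migration model (no ladder fit)."""
    return cal_mod.SizeCalibration(
        intercept=model.t_ref - model.slope * np.log10(model.s_ref),
        slope=model.slope,
        size_range=(synth.SIZE_MIN, synth.SIZE_MAX),
    )


def simulate_batch(config: RunConfig, out_dir: str | Path) -> Path:
    """Generate the full demonstration batch and write traces + sample sheet.

    The batch contains a ladder injection, empty-LNP blanks, a linearity
    series, a high/low/1:1-mix recovery design, a dilution series down to
    0.01 ug/mL, and a multi-temperature stability study.

    Returns the path of the written sample sheet.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = config.seed
    records: list[dict] = []

    def _noise(sample_id: str) -> synth.NoiseModel:
        return config.noise.with_seed(child_seed(seed, sample_id))

    def _emit(trace: Trace, record: dict) -> None:
        path = out_dir / f"{record['sample_id']}.csv"
        traceio.write_trace(trace, path)
        record["path"] = path.name
        records.append(record)

    # ladder
    tr = synth.generate_trace(
        None, model=config.migration, ladder=config.ladder, noise=_noise("ladder"),
        meta=TraceMeta(sample_id="ladder", role="ladder"),
    )
    _emit(tr, {"sample_id": "ladder", "role": "ladder"})

    # blanks (empty LNP: no mRNA, marker only)
    blank = replace(config.scenario, concentration=0.0)
    for i in range(config.qualification.n_blanks):
        sid = f"blank_{i}"
        tr = synth.generate_trace(
            blank, model=config.migration, noise=_noise(sid),
            meta=TraceMeta(sample_id=sid, role="blank"),
        )
        _emit(tr, {"sample_id": sid, "role": "blank"})

    # system-suitability replicates: the same control sample injected repeatedly
    for i in range(config.qualification.n_suitability):
        sid = f"suit_{i}"
        tr = synth.generate_trace(
            config.scenario, model=config.migration, noise=_noise(sid),
            meta=TraceMeta(sample_id=sid, role="sample",
                           conc_ug_ml=config.scenario.concentration),
        )
        _emit(tr, {"sample_id": sid, "role": "sample",
                   "conc_ug_ml": config.scenario.concentration})

    # linearity series
    for conc in config.qualification.linearity_concs:
        sid = f"lin_{conc:g}"
        scen = replace(config.scenario, concentration=float(conc))
        tr = synth.generate_trace(
            scen, model=config.migration, noise=_noise(sid),
            meta=TraceMeta(sample_id=sid, role="sample", conc_ug_ml=float(conc)),
        )
        _emit(tr, {"sample_id": sid, "role": "sample", "conc_ug_ml": float(conc)})

    # recovery design: high-purity, low-purity, and their 1:1 mixture
    q = config.qualification
    designs = {
        "rec_high": q.recovery_purity_high / 100.0,
        "rec_low": q.recovery_purity_low / 100.0,
        "rec_mix": (q.recovery_mix_fraction * q.recovery_purity_high
                    + (1 - q.recovery_mix_fraction) * q.recovery_purity_low) / 100.0,
    }
    for sid, intact in designs.items():
        scen = replace(config.scenario, intact_fraction=float(intact))
        tr = synth.generate_trace(
            scen, model=config.migration, noise=_noise(sid),
            meta=TraceMeta(sample_id=sid, role="sample",
                           conc_ug_ml=config.scenario.concentration),
        )
        _emit(tr, {"sample_id": sid, "role": "sample",
                   "conc_ug_ml": config.scenario.concentration})

    # dilution series for LOD/LOQ (single intact peak, as at low concentration
    # the fragment smear is the first thing lost in the baseline)
    for conc in q.dilution_concs:
        sid = f"dil_{conc:g}"
        scen = replace(config.scenario, concentration=float(conc), intact_fraction=1.0)
        tr = synth.generate_trace(
            scen, model=config.migration, noise=_noise(sid),
            meta=TraceMeta(sample_id=sid, role="sample", conc_ug_ml=float(conc)),
        )
        _emit(tr, {"sample_id": sid, "role": "sample", "conc_ug_ml": float(conc)})

    # stability study
    study = synth.simulate_stability_study(
        config.kinetic_truth,
        start_integrity=config.study.start_integrity,
        temperatures=config.study.temperatures,
        timepoints=config.study.timepoints,
        scenario=config.scenario,
        noise=config.noise,
        model=config.migration,
        seed=seed,
    )
    for tr in study.traces:
        m = tr.meta
        _emit(tr, {"sample_id": m.sample_id, "role": "sample",
                   "conc_ug_ml": m.conc_ug_ml, "temp_C": m.temp_C,
                   "time_days": m.time_days})

    sheet = pd.DataFrame(records)
    for col in traceio.SHEET_OPTIONAL:
        if col not in sheet.columns:
            sheet[col] = np.nan
    sheet_path = out_dir / "samples.csv"
    traceio.write_sample_sheet(
        sheet[list(traceio.SHEET_REQUIRED + traceio.SHEET_OPTIONAL)], sheet_path
    )
    return sheet_path


def analyze_sheet(
    sheet_path: str | Path, config: RunConfig
) -> tuple[pd.DataFrame, dict]:
    """Calibrate from the ladder trace(s) and integrate every sample/blank.

    Returns the result table plus a JSON-serialisable annotation payload
    (calibration and per-trace boundaries). Without a ladder trace the
    nominal migration-model calibration places the boundaries, sizes are not
    reported, and a warning is issued.
    """
    sheet_path = Path(sheet_path)
    sheet = traceio.read_sample_sheet(sheet_path)
    base = sheet_path.parent

    def _resolve(p: str) -> Path:
        path = Path(p)
        return path if path.is_absolute() else base / path

    cal = None
    cal_payload = None
    ladders = sheet[sheet["role"] == "ladder"]
    if len(ladders):
        rec = ladders.iloc[0]
        tr = traceio.read_trace(_resolve(rec["path"]), traceio.meta_from_record(rec))
        bl = integ.estimate_baseline(tr)
        peaks = cal_mod.detect_peaks(tr, bl)
        cal = cal_mod.fit_ladder(peaks, config.ladder,
                                 marker_window=config.integration.marker_window)
        cal_payload = cal.to_dict()
    else:
        warnings.warn("no ladder trace in sheet: calibration skipped, sizes unreported")
        cal = calibration_from_model(config.migration)

    results = []
    annotations = {}
    for _, rec in sheet[sheet["role"] != "ladder"].iterrows():
        tr = traceio.read_trace(_resolve(rec["path"]), traceio.meta_from_record(rec))
        bl = integ.estimate_baseline(tr)
        res = integ.integrate_regions(
            tr, bl, cal, config.scenario.construct_size,
            marker_window=config.integration.marker_window,
            marker_halfwidth=config.integration.marker_halfwidth,
            snr_floor=config.integration.snr_floor,
        )
        if cal_payload is None:
            res.main_size_nt = float("nan")
            res.hmw_size_nt = None
            if "no-calibration" not in res.flags:
                res.flags.append("no-calibration")
        results.append(res)
        annotations[res.sample_id] = {
            "boundaries": res.boundaries,
            "flags": res.flags,
            "frag_snr": res.frag_snr,
            "main_snr": res.main_snr,
        }

    table = traceio.results_to_frame(results)
    table["main_snr"] = [r.main_snr for r in results]
    table["frag_snr"] = [r.frag_snr for r in results]
    payload = {"calibration": cal_payload, "annotations": annotations}
    return table, payload


def qualify_results(
    table: pd.DataFrame, sheet: pd.DataFrame, config: RunConfig
) -> qual.QualificationReport:
    """Assemble the qualification report from an analysed batch."""
    merged = table.merge(
        sheet[["sample_id", "role", "conc_ug_ml"]], on="sample_id", how="left"
    )
    report = qual.QualificationReport()

    blanks = merged[merged["role"] == "blank"]
    if len(blanks):
        report.specificity_pass = bool(
            all("no-signal" in str(f) for f in blanks["flags"])
        )

    lin = merged[merged["sample_id"].str.startswith("lin_")]
    if len(lin) >= 3:
        slope, intercept, r2 = qual.linearity(
            lin["conc_ug_ml"].to_numpy(float), lin["total_area"].to_numpy(float)
        )
        report.linearity_slope = slope
        report.linearity_intercept = intercept
        report.r_squared = r2

    rec_ids = {"rec_high", "rec_low", "rec_mix"}
    rec = merged[merged["sample_id"].isin(rec_ids)].set_index("sample_id")
    if rec_ids <= set(rec.index):
        theoretical, pct = qual.recovery(
            observed_purity=float(rec.loc["rec_mix", "pct_main"]),
            purity_high=float(rec.loc["rec_high", "pct_main"]),
            purity_low=float(rec.loc["rec_low", "pct_main"]),
            mix_fraction=config.qualification.recovery_mix_fraction,
        )
        report.theoretical_purity = theoretical
        report.observed_purity = float(rec.loc["rec_mix", "pct_main"])
        report.recovery_pct = pct

    dil = merged[merged["sample_id"].str.startswith("dil_")].sort_values("conc_ug_ml")
    if len(dil) >= 2:
        series = list(zip(dil["conc_ug_ml"].to_numpy(float),
                          dil["main_snr"].to_numpy(float)))
        # enforce overall monotone S/N for interpolation via running maximum
        concs = [c for c, _ in series]
        snrs = np.maximum.accumulate([s for _, s in series])
        lod, loq = qual.lod_loq(
            list(zip(concs, snrs)),
            lod_snr=config.qualification.lod_snr,
            loq_snr=config.qualification.loq_snr,
        )
        report.lod = lod
        report.loq = loq

    return report


def fit_kinetics(table: pd.DataFrame, sheet: pd.DataFrame, mode: str = "initial-rate"):
    """Fit the stability-study rows of an analysed batch."""
    study_sheet = sheet.dropna(subset=["temp_C", "time_days"])
    if study_sheet.empty:
        raise RibotraceError("sheet contains no stability-study rows (temp_C/time_days)")
    model = DegradationStudy.from_result_table(table, study_sheet)
    return model.fit(mode=mode)


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict:
    """simulate -> analyze -> qualify + kinetics, with a JSON manifest.

    Returns the report payload; all outputs are also written under
    ``out_dir`` (traces, sample sheet, result table, report JSON).
    """
    out_dir = Path(out_dir)
    traces_dir = out_dir / "traces"
    sheet_path = simulate_batch(config, traces_dir)
    sheet = traceio.read_sample_sheet(sheet_path)

    table, annotations = analyze_sheet(sheet_path, config)
    traceio.write_result_table(table, out_dir / "results.csv")

    report = qualify_results(table, sheet, config)
    suitability = qual.system_suitability_summary(
        table[table["sample_id"].str.startswith("suit_")]
    )

    kin = fit_kinetics(table, sheet)
    payload = {
        "qualification": report.to_dict(),
        "system_suitability": suitability.to_dict(),
        "kinetics": {
            "rate_table": kin.rate_table.to_dict(orient="records"),
            "Ea_kJ_mol": kin.arrhenius.Ea_kJ_mol,
            "Ea_se": kin.arrhenius.Ea_se,
            "lnA": kin.arrhenius.lnA,
            "lnA_se": kin.arrhenius.lnA_se,
            "r_squared": kin.arrhenius.r_squared,
            "excluded_temperatures": kin.arrhenius.excluded_temperatures,
        },
        "analysis": annotations,
    }
    traceio.write_run_report(
        out_dir / "report.json", config=config.to_dict(), seed=config.seed,
        payload=payload,
    )
    return payload
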