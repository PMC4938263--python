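"""Study orchestration: one declarative config in, one structured report out.

A study config (YAML) lists, per protein, the titration table per
temperature, optional site-marker titrations with a site map, an optional
FRET block (donor emission + acceptor spectrum + intensities) and an
optional hydrodynamic-sizing table.  ``run_study`` validates the config
(fail-fast on missing files), executes spectra → quenching →
thermodynamics → FRET → hydrodynamics in order, and emits a JSON-ready
report in which every numeric field carries a unit string, plus a
provenance block (config hash, package version, seed, timestamp).

``simulate_study`` writes a complete synthetic study (titration tables,
marker tables, FRET spectra, sizing table, ground-truth manifest and a
ready-to-run config) so the full pipeline can be exercised with a known
answer.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, replace
from datetime import datetime, timezone
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import ConfigurationError
from .fret import FretConfig, fret_analysis
from .hydrodynamics import HydroMeasurement, size_change_report
from .quenching import (DEFAULT_TAU0_S, classify_mechanism,
                        displacement_analysis, modified_sv_fit,
                        read_titration, stern_volmer_fit, write_titration)
from .spectra import (absorbance_to_molar_absorptivity, read_spectrum,
                      write_spectrum)
from .synthetic import (DEFAULT_Q_GRID_M, DEFAULT_TEMPS_K, GroundTruth,
                        generate_displacement_set, generate_overlap_pair,
                        generate_temperature_series)
from .thermodynamics import R_CAL_MOL_K, vant_hoff_fit

__all__ = [
    "load_config",
    "run_study",
    "render_tables",
    "validate_report",
    "simulate_study",
]


def q(value: float, unit: str) -> dict:
    """Wrap a numeric value with its unit string for the report."""
    return {"value": float(value), "unit": unit}


def load_config(path: str | Path) -> dict:
    path = Path(path)
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigurationError(f"{path}: config must be a mapping")
    cfg.setdefault("_base_dir", str(path.parent))
    return cfg


def _resolve(base: Path, rel: str) -> Path:
    p = Path(rel)
    return p if p.is_absolute() else base / p


def _validate_files(cfg: Mapping, base: Path) -> None:
    missing = []
    for prot in cfg.get("proteins", []):
        for path in (prot.get("titrations") or {}).values():
            if not _resolve(base, path).exists():
                missing.append(path)
        for path in (prot.get("markers") or {}).values():
            if not _resolve(base, path).exists():
                missing.append(path)
    fret_cfg = cfg.get("fret") or {}
    for key in ("donor_emission", "acceptor", "acceptor_absorbance"):
        if key in fret_cfg and not _resolve(base, fret_cfg[key]).exists():
            missing.append(fret_cfg[key])
    hydro_cfg = cfg.get("hydro") or {}
    if "measurements" in hydro_cfg:
        if not _resolve(base, hydro_cfg["measurements"]).exists():
            missing.append(hydro_cfg["measurements"])
    if missing:
        raise ConfigurationError(
            "missing input files: " + ", ".join(sorted(set(missing)))
        )


def _quenching_block(fit, binding, dg) -> dict:
    block = {
        "stern_volmer": {
            "ksv": q(fit.ksv_M_inv, "M^-1"),
            "intercept": q(fit.intercept, "1"),
            "intercept_flagged": fit.intercept_flagged,
            "kq": q(fit.kq_M_inv_s_inv, "M^-1 s^-1"),
            "tau0": q(fit.tau0_s, "s"),
            "r_squared": q(fit.r_squared, "1"),
            "n_points_used": q(fit.n_points_used, "count"),
        },
        "binding": {
            "kb": q(binding.kb_M_inv, "M^-1"),
            "n_sites": q(binding.n_sites, "1"),
            "log10_kb": q(binding.log10_kb, "1"),
            "r_squared": q(binding.r_squared, "1"),
            "n_points_used": q(binding.n_points_used, "count"),
            "excluded_points": list(binding.excluded_points),
        },
        "delta_g": q(dg, "kcal mol^-1"),
    }
    return block


def run_study(cfg: Mapping[str, Any],
              base_dir: str | Path | None = None) -> dict:
    """Execute every configured stage and return the unit-labelled report."""
    base = Path(base_dir if base_dir is not None
                else cfg.get("_base_dir", "."))
    _validate_files(cfg, base)
    constants = dict(cfg.get("constants") or {})
    tau0 = float(constants.get("tau0_s", DEFAULT_TAU0_S))
    r_gas = float(constants.get("r_cal_mol_K", R_CAL_MOL_K))
    resolved_constants = {
        "tau0": q(tau0, "s"),
        "r_gas": q(r_gas, "cal mol^-1 K^-1"),
        "kappa_squared": q(float(constants.get("kappa_squared", 2.0 / 3.0)), "1"),
        "refractive_index": q(float(constants.get("refractive_index", 1.336)), "1"),
        "quantum_yield": q(float(constants.get("quantum_yield", 0.15)), "1"),
        "secondary_site_threshold": q(
            float(constants.get("secondary_site_threshold", 0.5)), "1"),
        "compaction_threshold": q(
            float(constants.get("compaction_threshold_pct", 5.0)), "%"),
    }
    report: dict[str, Any] = {"proteins": [], "constants": resolved_constants}

    for prot in cfg.get("proteins", []):
        label = prot["label"]
        entry: dict[str, Any] = {"label": label, "temperatures": []}
        fits, temps, tk_pairs = [], [], []
        for t_str, rel in sorted((prot.get("titrations") or {}).items(),
                                 key=lambda kv: float(kv[0])):
            t_k = float(t_str)
            series = read_titration(
                _resolve(base, rel), protein_label=label,
                temperature_K=t_k,
                protein_conc_M=prot.get("protein_conc_M"))
            fit = stern_volmer_fit(series, tau0_s=tau0)
            binding = modified_sv_fit(series)
            from .thermodynamics import delta_g as _dg
            dg = _dg(binding.kb_M_inv, t_k, r_gas)
            block = _quenching_block(fit, binding, dg)
            block["temperature"] = q(t_k, "K")
            block["source_file"] = rel
            entry["temperatures"].append(block)
            fits.append(fit)
            temps.append(t_k)
            tk_pairs.append((t_k, binding.kb_M_inv))
        if len(fits) >= 2:
            mech = classify_mechanism(fits, temps)
            entry["mechanism"] = {
                "call": mech.call,
                "ksv_temperature_trend": mech.ksv_temperature_trend,
                "kq_exceeds_diffusion_limit": mech.kq_exceeds_diffusion_limit,
                "diffusion_limit": q(mech.diffusion_limit_M_inv_s_inv,
                                     "M^-1 s^-1"),
            }
            thermo = vant_hoff_fit(tk_pairs, r=r_gas)
            entry["thermodynamics"] = {
                "delta_h": q(thermo.delta_h_kcal_mol, "kcal mol^-1"),
                "delta_s": q(thermo.delta_s_cal_mol_K, "cal mol^-1 K^-1"),
                "per_temperature": [
                    {"temperature": q(t, "K"),
                     "kb": q(kb, "M^-1"),
                     "delta_g": q(dg, "kcal mol^-1"),
                     "t_delta_s": q(tds, "kcal mol^-1")}
                    for t, kb, dg, tds in zip(
                        thermo.temperatures_K, thermo.kb_M_inv,
                        thermo.delta_g_kcal_mol, thermo.t_delta_s_kcal_mol)
                ],
                "r_squared": q(thermo.r_squared, "1"),
                "force_call": thermo.force_call,
            }
        markers = prot.get("markers") or {}
        if markers:
            site_map = prot.get("site_map") or {}
            marker_t = float(prot.get("marker_temperature_K", temps[0]
                                      if temps else 298.0))
            free_rel = (prot.get("titrations") or {}).get(
                str(int(marker_t)), None)
            if free_rel is None and temps:
                free_rel = sorted((prot.get("titrations") or {}).items(),
                                  key=lambda kv: float(kv[0]))[0][1]
            if free_rel is None:
                raise ConfigurationError(
                    f"{label}: marker analysis needs a marker-free titration"
                )
            free_fit = stern_volmer_fit(
                read_titration(_resolve(base, free_rel)), tau0_s=tau0)
            marker_fits = {
                m: stern_volmer_fit(read_titration(_resolve(base, rel)),
                                    tau0_s=tau0)
                for m, rel in markers.items()
            }
            disp = displacement_analysis(
                free_fit, marker_fits, site_map,
                secondary_threshold=resolved_constants[
                    "secondary_site_threshold"]["value"])
            entry["displacement"] = {
                "ksv_free": q(disp.ksv_free_M_inv, "M^-1"),
                "markers": {
                    m: {"ksv": q(d["ksv_M_inv"], "M^-1"),
                        "fractional_decrease": q(d["fractional_decrease"], "1"),
                        "site": d["site"]}
                    for m, d in disp.markers.items()
                },
                "primary_site_call": disp.primary_site_call,
                "primary_marker": disp.primary_marker,
                "secondary_sites": list(disp.secondary_sites),
            }
        report["proteins"].append(entry)

    fret_cfg = cfg.get("fret") or {}
    if fret_cfg:
        donor = read_spectrum(_resolve(base, fret_cfg["donor_emission"]),
                              "emission")
        if "acceptor" in fret_cfg:
            acceptor = read_spectrum(_resolve(base, fret_cfg["acceptor"]),
                                     "molar_absorptivity")
        else:
            absorb = read_spectrum(
                _resolve(base, fret_cfg["acceptor_absorbance"]), "absorbance")
            acceptor = absorbance_to_molar_absorptivity(
                absorb, float(fret_cfg["acceptor_conc_M"]),
                float(fret_cfg.get("path_cm", 1.0)))
        fconf = FretConfig(
            kappa_squared=resolved_constants["kappa_squared"]["value"],
            refractive_index=resolved_constants["refractive_index"]["value"],
            quantum_yield=resolved_constants["quantum_yield"]["value"])
        rng = tuple(fret_cfg.get("range_nm", (300.0, 400.0)))
        res = fret_analysis(donor, acceptor, float(fret_cfg["f"]),
                            float(fret_cfg["f0"]), fconf, rng)
        report["fret"] = {
            "j": q(res.j_nm4_M_inv_cm_inv, "nm^4 M^-1 cm^-1"),
            "j_cm3": q(res.j_cm3_M_inv, "cm^3 M^-1"),
            "r0": q(res.r0_nm, "nm"),
            "efficiency": q(res.efficiency, "1"),
            "r": q(res.r_nm, "nm"),
            "forster_window_ok": res.forster_window_ok,
        }

    hydro_cfg = cfg.get("hydro") or {}
    if hydro_cfg:
        df = pd.read_csv(_resolve(base, hydro_cfg["measurements"]))
        measurements = []
        for _, row in df.iterrows():
            def _opt(col):
                return (float(row[col])
                        if col in df.columns and pd.notna(row[col]) else None)
            measurements.append(HydroMeasurement(
                label=str(row["label"]), protein=str(row["protein"]),
                rh_nm=_opt("rh_nm"), diffusion_m2_s=_opt("diffusion_m2_s"),
                temperature_K=_opt("temperature_K"),
                viscosity_Pa_s=_opt("viscosity_Pa_s"),
                polydispersity_pct=_opt("polydispersity_pct"),
                baseline=bool(row.get("baseline", False)),
            ))
        reports = size_change_report(
            measurements,
            threshold_pct=resolved_constants["compaction_threshold"]["value"])
        report["hydrodynamics"] = [
            {"protein": r.protein,
             "baseline_label": r.baseline_label,
             "baseline_rh": q(r.baseline_rh_nm, "nm"),
             "overall_call": r.overall_call,
             "conditions": [
                 {"label": c["label"], "rh": q(c["rh_nm"], "nm"),
                  "change": q(c["change_pct"], "%"),
                  "polydispersity": (q(c["polydispersity_pct"], "%")
                                     if c["polydispersity_pct"] is not None
                                     else None),
                  "call": c["call"]}
                 for c in r.conditions]}
            for r in reports
        ]

    public_cfg = {k: v for k, v in cfg.items() if not k.startswith("_")}
    cfg_hash = hashlib.sha256(
        json.dumps(public_cfg, sort_keys=True, default=str).encode()
    ).hexdigest()
    report["provenance"] = {
        "config_sha256": cfg_hash,
        "package": "specbind",
        "version": __version__,
        "seed": cfg.get("seed"),
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    validate_report(report)
    return report


def validate_report(report: Mapping, _path: str = "report") -> None:
    """Reject any numeric leaf not wrapped as {"value": x, "unit": "..."}.

    The provenance block is exempt: its numbers (seed, hash) are
    identifiers, not physical quantities.
    """

    def walk(node: Any, path: str) -> None:
        if isinstance(node, Mapping):
            if set(node) >= {"value", "unit"}:
                if not isinstance(node["unit"], str) or not node["unit"]:
                    raise ConfigurationError(f"{path}: empty unit string")
                return
            for key, val in node.items():
                if key == "provenance":
                    continue
                walk(val, f"{path}.{key}")
        elif isinstance(node, (list, tuple)):
            for i, val in enumerate(node):
                walk(val, f"{path}[{i}]")
        elif isinstance(node, bool) or node is None or isinstance(node, str):
            return
        elif isinstance(node, (int, float, np.integer, np.floating)):
            raise ConfigurationError(f"{path}: unit-less numeric field")

    walk(report, _path)


def _fmt(block: Mapping, key: str, digits: int = 4) -> str:
    item = block.get(key)
    if item is None:
        return "-"
    return f"{item['value']:.{digits}g}"


def render_tables(report: Mapping) -> str:
    """Delimited text tables mirroring the customary binding-study layout."""
    lines: list[str] = []
    if report.get("proteins"):
        lines.append("# Binding and thermodynamic parameters")
        lines.append("protein\ttemp_K\tn\tKsv_M^-1\tkq_M^-1s^-1\tKb_M^-1"
                     "\tdH_kcal_mol\tdG_kcal_mol\tTdS_kcal_mol")
        for prot in report["proteins"]:
            thermo = prot.get("thermodynamics", {})
            per_t = {round(p["temperature"]["value"], 6): p
                     for p in thermo.get("per_temperature", [])}
            for block in prot.get("temperatures", []):
                t = block["temperature"]["value"]
                tp = per_t.get(round(t, 6), {})
                lines.append("\t".join([
                    prot["label"], f"{t:g}",
                    _fmt(block["binding"], "n_sites", 3),
                    _fmt(block["stern_volmer"], "ksv"),
                    _fmt(block["stern_volmer"], "kq"),
                    _fmt(block["binding"], "kb"),
                    _fmt(thermo, "delta_h") if thermo else "-",
                    _fmt(block, "delta_g"),
                    _fmt(tp, "t_delta_s") if tp else "-",
                ]))
        disp_rows = [(p["label"], p["displacement"])
                     for p in report["proteins"] if "displacement" in p]
        if disp_rows:
            lines.append("")
            lines.append("# Site-marker displacement")
            lines.append("protein\tKsv_free_M^-1\tmarker\tsite"
                         "\tKsv_with_M^-1\tfractional_decrease\tprimary_site")
            for label, disp in disp_rows:
                for marker, d in disp["markers"].items():
                    lines.append("\t".join([
                        label, f"{disp['ksv_free']['value']:.4g}", marker,
                        d["site"], f"{d['ksv']['value']:.4g}",
                        f"{d['fractional_decrease']['value']:.3f}",
                        disp["primary_site_call"],
                    ]))
    if "fret" in report:
        f = report["fret"]
        lines.append("")
        lines.append("# FRET parameters")
        lines.append("J_nm4_M^-1cm^-1\tJ_cm3_M^-1\tR0_nm\tr_nm\tE\twindow_ok")
        lines.append("\t".join([
            f"{f['j']['value']:.4g}", f"{f['j_cm3']['value']:.4g}",
            f"{f['r0']['value']:.3f}", f"{f['r']['value']:.3f}",
            f"{f['efficiency']['value']:.3f}", str(f["forster_window_ok"]),
        ]))
    if "hydrodynamics" in report:
        lines.append("")
        lines.append("# Hydrodynamic radii")
        lines.append("protein\tcondition\tRh_nm\tchange_pct\tcall")
        for r in report["hydrodynamics"]:
            for c in r["conditions"]:
                lines.append("\t".join([
                    r["protein"], c["label"], f"{c['rh']['value']:.3g}",
                    f"{c['change']['value']:+.1f}", c["call"],
                ]))
    return "\n".join(lines) + ("\n" if lines else "")


def simulate_study(out_dir: str | Path, seed: int = 0,
                   truth: GroundTruth | None = None,
                   marker_factors: Mapping[str, float] | None = None,
                   ) -> Path:
    """Write a full synthetic study + manifest + config; return config path.

    The generated directory is directly consumable by ``run_study`` and
    the manifest records the generating ground truth for verification.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    truth = truth if truth is not None else GroundTruth(seed=seed)
    truth = replace(truth, seed=seed)
    if marker_factors is None:
        # emulate a site-II binder: the site-II marker competes hardest
        marker_factors = {"DIA": 0.125, "PBZ": 0.24, "WAR": 0.34}
    site_map = {"DIA": "site II", "PBZ": "site I", "WAR": "site I"}

    titration_files: dict[str, str] = {}
    for t, series in generate_temperature_series(truth):
        rel = f"titration_{truth.protein_label}_{int(t)}K.csv"
        write_titration(series, out / rel)
        titration_files[str(int(t))] = rel
    marker_files: dict[str, str] = {}
    disp = generate_displacement_set(truth, marker_factors)
    for label, series in disp.items():
        if label == "free":
            continue
        rel = f"titration_{truth.protein_label}_{label}.csv"
        write_titration(series, out / rel)
        marker_files[label] = rel

    donor, acceptor, analytic_j = generate_overlap_pair()
    write_spectrum(donor, out / "donor_emission.csv")
    write_spectrum(acceptor, out / "acceptor_epsilon.csv")
    f0 = 1000.0
    efficiency_truth = 0.71
    f = (1.0 - efficiency_truth) * f0

    rows = [
        {"protein": truth.protein_label, "label": "1:0", "rh_nm": 3.6,
         "polydispersity_pct": 11.0, "baseline": True},
        {"protein": truth.protein_label, "label": "1:5", "rh_nm": 3.0,
         "polydispersity_pct": 11.9, "baseline": False},
        {"protein": truth.protein_label, "label": "1:10", "rh_nm": 2.7,
         "polydispersity_pct": 12.5, "baseline": False},
    ]
    pd.DataFrame(rows).to_csv(out / "hydro.csv", index=False)

    manifest = {
        "ground_truth": asdict(truth),
        "marker_factors": dict(marker_factors),
        "site_map": site_map,
        "analytic_j_nm4_M_inv_cm_inv": analytic_j,
        "fret_efficiency": efficiency_truth,
        "temperatures_K": list(DEFAULT_TEMPS_K),
        "q_grid_M": [float(x) for x in DEFAULT_Q_GRID_M],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))

    cfg = {
        "seed": seed,
        "constants": {"tau0_s": 1e-9, "r_cal_mol_K": R_CAL_MOL_K},
        "proteins": [{
            "label": truth.protein_label,
            "protein_conc_M": truth.protein_conc_M,
            "titrations": titration_files,
            "markers": marker_files,
            "site_map": site_map,
            "marker_temperature_K": 298,
        }],
        "fret": {
            "donor_emission": "donor_emission.csv",
            "acceptor": "acceptor_epsilon.csv",
            "f": f, "f0": f0,
            "range_nm": [270, 410],
        },
        "hydro": {"measurements": "hydro.csv"},
        "output": "report.json",
    }
    cfg_path = out / "study.yaml"
    cfg_path.write_text(yaml.safe_dump(cfg, sort_keys=False))
    return cfg_path
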