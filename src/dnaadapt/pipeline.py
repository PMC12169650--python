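"""End-to-end orchestration: simulate -> analyze -> report.

A single YAML/dict config drives every stage; a fixed seed makes the whole
run byte-for-byte reproducible.  Each stage writes CSV/JSON into the output
directory and a manifest records the config hash, seed, package version and
produced files.  Stage failures abort the run with the stage name.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__

_FLOAT_FMT = "%.10g"

DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 0,
    "sequence": "GCATATATATGC",
    "form": "B",
    "ensemble": {
        "n_frames": 50,
        "step_sds": {"twist": 3.0, "roll": 3.0, "tilt": 2.0,
                     "rise": 0.2, "slide": 0.3, "shift": 0.3},
        "pair_sds": {"buckle": 5.0, "propeller": 5.0, "opening": 3.0},
        "rho_twist": -0.5,
    },
    "contacts": {"cutoff": 4.5},
    "fes": {
        "potential": "double_well", "minima": [25.0, 45.0], "barrier": 5.0,
        "duration_ns": 52.0, "every_ns": 2.0, "window_ns": [10.0, 50.0],
    },
    "binding": {
        "titration": {"K": 1.57e4, "n": 1.38, "F0": 100.0, "F_inf": 20.0,
                      "noise_sd": 0.0, "n_points": 14,
                      "c_min": 1e2, "c_max": 1e7},
        "decay": {"amplitudes": [0.7, 0.3], "lifetimes": [1.0, 4.0],
                  "total_counts": 1e6, "irf_fwhm_ns": 1.0,
                  "dt_ns": 0.02, "n_channels": 2048},
    },
}


class StageError(RuntimeError):
    def __init__(self, stage: str, exc: Exception):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {exc}")


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


@dataclass
class RunConfig:
    """Fully serialisable run description (seed + per-stage parameters)."""

    values: dict[str, Any] = field(default_factory=dict)
    output_dir: Path = Path("dnaadapt_run")

    def __post_init__(self):
        self.values = _merge(DEFAULT_CONFIG, self.values)
        self.output_dir = Path(self.output_dir)

    @classmethod
    def from_yaml(cls, path, output_dir=None) -> "RunConfig":
        import yaml

        with open(path) as fh:
            values = yaml.safe_load(fh) or {}
        out = values.pop("output_dir", "dnaadapt_run")
        return cls(values, Path(output_dir or out))

    @property
    def seed(self) -> int:
        return int(self.values["seed"])

    def config_hash(self) -> str:
        canon = json.dumps(self.values, sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _write_csv(df: pd.DataFrame, path: Path) -> Path:
    df.to_csv(path, index=False, float_format=_FLOAT_FMT, lineterminator="\n")
    return path


def _write_json(obj, path: Path) -> Path:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=float)
        fh.write("\n")
    return path


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Execute all stages in dependency order; returns the file map."""
    from .binding import fit_decay, hill_fit, mean_lifetime
    from .conformation import fraction_profiles
    from .contacts import (contact_series, contact_density_2d, is_bound,
                           ContactSeries, qgr_minor_contacts,
                           trp_sugar_contacts)
    from .helixgeom import ensemble_bend, groove_widths
    from .metad import (fes_minimum_and_width, free_diffusion_check,
                        windowed_profiles, write_hills)
    from .rigidbase import parameter_timeseries
    from .structure import write_pdb
    from .synthetic import (CanonicalFormSpec, DoubleWellPotential,
                            DuplexSpec, EnsembleSpec, FlatPotential,
                            HarmonicPotential, ProbeAtomSpec,
                            build_probe_complex, generate_decay,
                            generate_hills, generate_titration)

    cfg = config.values
    out = config.output_dir
    out.mkdir(parents=True, exist_ok=True)
    files: dict[str, Path] = {}
    seed = config.seed

    def stage(name):
        def deco(fn):
            try:
                fn()
            except Exception as exc:
                raise StageError(name, exc) from exc
        return deco

    form = (CanonicalFormSpec.a_form() if cfg["form"].upper() == "A"
            else CanonicalFormSpec.b_form())
    dspec = DuplexSpec(cfg["sequence"], form)
    holder: dict[str, Any] = {}

    @stage("simulate")
    def _simulate():
        ens_cfg = cfg["ensemble"]
        espec = EnsembleSpec(
            n_frames=int(ens_cfg["n_frames"]), seed=seed,
            step_sds=dict(ens_cfg.get("step_sds", {})),
            pair_sds=dict(ens_cfg.get("pair_sds", {})),
            rho_twist=float(ens_cfg.get("rho_twist", 0.0)))
        from .synthetic import sample_ensemble

        holder["duplex"] = dspec.build()
        holder["ensemble"] = sample_ensemble(dspec, espec)
        files["duplex_pdb"] = write_pdb(holder["duplex"], out / "duplex.pdb")
        files["ensemble_pdb"] = write_pdb(holder["ensemble"],
                                          out / "ensemble.pdb")

    @stage("analyze-conformation")
    def _conf():
        prof = fraction_profiles(holder["ensemble"])
        files["conformation_csv"] = _write_csv(prof.to_frame(),
                                               out / "conformation.csv")

    @stage("analyze-rigid-base")
    def _rigid():
        ts = parameter_timeseries(holder["ensemble"])
        files["rigid_base_csv"] = _write_csv(ts.summary(),
                                             out / "rigid_base.csv")
        holder["timeseries"] = ts

    @stage("analyze-grooves")
    def _grooves():
        rows = []
        for i, snap in enumerate(holder["ensemble"]):
            gp = groove_widths(snap)
            df = gp.to_frame()
            df.insert(0, "frame", i)
            rows.append(df)
        files["grooves_csv"] = _write_csv(pd.concat(rows, ignore_index=True),
                                          out / "grooves.csv")

    @stage("analyze-bend")
    def _bend():
        files["bend_csv"] = _write_csv(ensemble_bend(holder["ensemble"]),
                                       out / "bend.csv")

    @stage("analyze-contacts")
    def _contacts():
        # bound-state fixture: probe atoms planted into the minor groove
        dup = holder["duplex"]
        specs = [ProbeAtomSpec("NE1", "TRP", 109, ("A", 6, "C1'"), 4.0,
                               direction=None)]
        acceptors = [("A", i, "O4'") for i in range(2, 11)] + \
                    [("B", i, "O4'") for i in range(2, 11)] + \
                    [("A", i, "N3") for i in (3, 5, 7, 9)] + \
                    [("B", i, "N3") for i in (3, 5, 7, 9)] + \
                    [("A", i, "O2") for i in (4, 6, 8, 10)] + \
                    [("B", i, "O2") for i in (4, 6, 8, 10)]
        for k, tgt in enumerate(acceptors[:26]):
            specs.append(ProbeAtomSpec(f"C{k}", "QGR", 112 + k % 3, tgt, 4.0))
        cx = build_probe_complex(dup, specs, avoid_names=("N3", "O2", "O4'"))
        cutoff = float(cfg["contacts"]["cutoff"])
        summary = {
            "C_minor_QGR": qgr_minor_contacts(cx, cutoff),
            "C_sugar_Trp": trp_sugar_contacts(cx, cutoff),
            "bound": bool(is_bound(cx, cutoff)),
        }
        files["contacts_json"] = _write_json(summary, out / "contacts.json")

    @stage("fes")
    def _fes():
        fcfg = cfg["fes"]
        kind = fcfg["potential"]
        if kind == "flat":
            pot = FlatPotential()
        elif kind == "harmonic":
            pot = HarmonicPotential(center=float(fcfg.get("center", 35.0)),
                                    k=float(fcfg.get("k", 0.05)))
        else:
            pot = DoubleWellPotential(tuple(fcfg["minima"]),
                                      float(fcfg["barrier"]))
        hills, (tt, cv) = generate_hills(
            pot, duration_ns=float(fcfg["duration_ns"]), seed=seed + 1,
            return_trajectory=True)
        files["hills"] = write_hills(hills, out / "HILLS")
        prof = windowed_profiles(hills, every_ns=float(fcfg["every_ns"]),
                                 window_ns=tuple(fcfg["window_ns"]))
        files["fes_csv"] = _write_csv(prof.to_frame(), out / "fes.csv")
        diag = free_diffusion_check(tt, cv)
        diag.update(fes_minimum_and_width(prof))
        files["fes_diagnostics"] = _write_json(diag, out / "fes_diag.json")

    @stage("binding")
    def _binding():
        bcfg = cfg["binding"]["titration"]
        conc = np.geomspace(float(bcfg["c_min"]), float(bcfg["c_max"]),
                            int(bcfg["n_points"]))
        series = generate_titration(float(bcfg["K"]), float(bcfg["n"]),
                                    float(bcfg["F0"]), float(bcfg["F_inf"]),
                                    conc, float(bcfg["noise_sd"]), seed + 2)
        files["titration_csv"] = _write_csv(series.to_frame(),
                                            out / "titration.csv")
        fit = hill_fit(series)
        dcfg = cfg["binding"]["decay"]
        hist = generate_decay(dcfg["amplitudes"], dcfg["lifetimes"],
                              float(dcfg["irf_fwhm_ns"]), float(dcfg["dt_ns"]),
                              int(dcfg["n_channels"]),
                              float(dcfg["total_counts"]), seed + 3)
        files["decay_csv"] = _write_csv(hist.to_frame(), out / "decay.csv")
        dfit = fit_decay(hist, n_components=len(dcfg["lifetimes"]))
        files["binding_json"] = _write_json({
            "K_nM": fit.K, "n": fit.n, "K_se_nM": fit.K_se, "n_se": fit.n_se,
            "delta_G_kcal_mol": fit.delta_G,
            "decay_amplitudes": list(dfit.amplitudes),
            "decay_lifetimes_ns": list(dfit.lifetimes),
            "decay_chi2_reduced": dfit.chi2_reduced,
            "mean_lifetime_ns": mean_lifetime(dfit),
        }, out / "binding.json")

    manifest = {
        "package": "dnaadapt", "version": __version__,
        "seed": seed, "config_hash": config.config_hash(),
        "config": cfg,
        "files": {k: str(p.name) for k, p in files.items()},
    }
    files["manifest"] = _write_json(manifest, out / "manifest.json")
    return files
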