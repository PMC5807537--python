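"""End-to-end orchestration: one entry point that regenerates every
desk-scale result from the packaged defaults.

``reproduce`` runs, per variant: synthetic spectrum -> charge-state
analysis; synthetic CIU records -> fingerprint -> state/transition
detection; the metavinculin ensemble -> extended-fraction profile; and the
FA time-lapse -> bleach-corrected decay fit.  Structure-dependent stages
(interfaces, anchoring spots, theoretical CCS) run only when the caller
points ``pdb_dir`` at user-supplied coordinate files — nothing is ever
downloaded.

Stages are isolated: a failing stage is recorded in the report and does
not corrupt the outputs of earlier stages.
"""

from __future__ import annotations

import json
import traceback
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd

from . import ciu as _ciu
from . import famorph as _fa
from . import imms as _imms
from . import synthgen as _sg
from .config import VARIANT_NAMES, load_variant

__all__ = ["RunConfig", "run_pipeline", "reproduce"]


@dataclass
class RunConfig:
    """Validated run configuration; unknown keys are rejected."""

    seed: int = 7
    variants: tuple[str, ...] = VARIANT_NAMES
    out_dir: str | None = None
    pdb_dir: str | None = None
    n_fas: int = 1000
    fa_frames: int = 60
    fa_dt_min: float = 1.0
    ensemble_ions: int = 10000
    ciu_mean_ions: int = 3000
    min_rel_intensity: float = 0.05
    presence_threshold: float = 0.10
    verbosity: int = 1

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        if isinstance(cfg.variants, list):
            cfg.variants = tuple(cfg.variants)
        return cfg

    def resolved(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def _spectrum_stage(v, cfg, seed):
    sp = _sg.gen_spectrum(v, seed=seed)
    css = _imms.detect_charge_states(sp, min_rel_intensity=cfg.min_rel_intensity)
    return {
        "n_major_charge_states": css.n_major,
        "envelope_center_mz": round(css.envelope_center_mz, 1),
        "inferred_mass_da": round(css.inferred_mass, 1),
        "mass_error_frac": abs(css.inferred_mass - v.mass_da) / v.mass_da,
        "major_charges": css.major_charges,
    }


def _ciu_stage(v, cfg, seed):
    cal = _sg.gen_calibrants(noise=0.0, seed=seed)
    model = _imms.fit_calibration(cal)
    records = _sg.gen_ciu(v, model=model, mean_ions_per_voltage=cfg.ciu_mean_ions,
                          seed=seed)
    fp = _ciu.build_fingerprint(records, model, v.mass_da)
    states = _ciu.detect_states(fp, max_states=3, seed=seed,
                                presence_threshold=cfg.presence_threshold)
    out = {
        "states": [
            {"label": st.label, "centroid_A2": round(st.centroid, 0),
             "width_A2": round(st.width, 0)}
            for st in states
        ],
    }
    if len(states) >= 2:
        reports = _ciu.detect_transitions(states)
        out["transitions"] = [
            {"step": f"{r.from_state}->{r.to_state}", "onset_v": r.onset_voltage,
             "completion_v": r.completion_voltage,
             "coexistence_v": r.coexistence_width, "mode": r.mode}
            for r in reports
        ]
        out["dwell"] = _ciu.stability_profile(states).to_dict("records")
    return out, fp


def _ensemble_stage(v, cfg, seed):
    model = _sg.default_calibration()
    records = _sg.gen_ensemble(v, n_ions=cfg.ensemble_ions, model=model,
                               seed=seed)
    table, frac = _imms.ensemble_profile(records, v.mass_da, model)
    return {
        "extended_fraction": round(frac, 3),
        "max_ccs_A2": round(table.attrs["max_ccs"], 0),
        "compact_centroid_A2": round(table.attrs["compact_centroid"], 0),
    }


def _fa_stage(v, cfg, seed):
    ds = _sg.gen_fa_dataset(v, n_fas=cfg.n_fas, frames=cfg.fa_frames,
                            dt_min=cfg.fa_dt_min, seed=seed)
    fas = _fa.measure_fas(ds.label_image, ds.frames[0], ds.pixel_size)
    size_fit = _fa.fit_size_distribution(fas["area"].to_numpy())
    per_fa = _fa.fa_intensity_series(ds.label_image, ds.frames)
    background = float(np.median(ds.frames[0][ds.label_image == 0]))
    per_fa = np.clip(per_fa - background, 1e-6, None)
    series = per_fa.mean(axis=1)
    corrected = _fa.bleach_correct(series, ds.reference)
    per_fa_corr = per_fa * (ds.reference[0] / ds.reference)[:, None]
    fit = _fa.fit_decay(ds.times_min, corrected / corrected[0],
                        per_fa=per_fa_corr, seed=seed)
    return {
        "n_fas": int(len(fas)),
        "small_fraction": float((fas["size_class"] == "small").mean()),
        "lognormal_mu": round(size_fit.mu, 3),
        "lognormal_sigma": round(size_fit.sigma, 3),
        "decay_rate_per_min": round(fit.rate, 4),
        "plateau": round(fit.plateau, 3),
        "initial_slope_pct_per_min": round(fit.initial_slope, 3),
        "slope_ci95": [round(x, 3) for x in fit.slope_ci95],
    }


def run_pipeline(config: RunConfig | dict) -> dict:
    """Run all stages for every configured variant; see module docstring."""
    cfg = config if isinstance(config, RunConfig) else RunConfig.from_dict(config)
    report: dict = {"config": cfg.resolved(), "stages": {}, "errors": {}}
    rng_root = np.random.SeedSequence(cfg.seed)
    variant_seeds = {name: int(child.generate_state(1)[0] % (2**31))
                     for name, child in zip(cfg.variants,
                                            rng_root.spawn(len(cfg.variants)))}
    fingerprints = {}
    for name in cfg.variants:
        v = load_variant(name)
        seed = variant_seeds[name]
        vrep: dict = {}
        for stage, fn in [("spectrum", _spectrum_stage), ("ciu", _ciu_stage),
                          ("fa", _fa_stage)]:
            try:
                if stage == "ciu":
                    out, fp = fn(v, cfg, seed)
                    fingerprints[name] = fp
                    vrep[stage] = out
                else:
                    vrep[stage] = fn(v, cfg, seed)
            except Exception as exc:  # stage isolation
                report["errors"][f"{name}/{stage}"] = (
                    f"{type(exc).__name__}: {exc}"
                )
                if cfg.verbosity > 1:
                    traceback.print_exc()
        if v.extended_fraction > 0:
            try:
                vrep["ensemble"] = _ensemble_stage(v, cfg, seed)
            except Exception as exc:
                report["errors"][f"{name}/ensemble"] = (
                    f"{type(exc).__name__}: {exc}"
                )
        report["stages"][name] = vrep

    if len(fingerprints) >= 2:
        try:
            cmp = _ciu.compare_variants(fingerprints)
            report["variant_comparison"] = cmp["onsets"].to_dict("records")
        except Exception as exc:
            report["errors"]["variant_comparison"] = f"{type(exc).__name__}: {exc}"

    if cfg.out_dir:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(json.dumps(report, indent=2,
                                                    default=str))
        for name, fp in fingerprints.items():
            fp.to_csv(out / f"fingerprint_{name}.csv")
    return report


def reproduce(seed: int = 7, out_dir: str | None = None,
              fast: bool = False) -> dict:
    """Regenerate the full desk-scale result bundle from packaged defaults.

    ``fast`` shrinks the simulations (fewer FAs/frames/ions) for smoke
    tests; the defaults match the stated experimental scale (~1,000 FAs,
    60 one-minute frames, the 50-240 V CIU grid).
    """
    cfg = RunConfig(seed=seed, out_dir=out_dir)
    if fast:
        cfg.n_fas = 150
        cfg.fa_frames = 20
        cfg.ensemble_ions = 2000
        cfg.ciu_mean_ions = 800
    return run_pipeline(cfg)
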