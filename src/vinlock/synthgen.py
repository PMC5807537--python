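"""Synthetic instrument and microscope data for the four vinculin forms.

No raw spectra, mobility records or imaging data are publicly deposited
for this system, so every consumer module is exercised against a
generator whose defaults transcribe the printed observations: charge-state
envelopes (7 / 11 / 16 major states, a broad 29+-55+ metavinculin wing),
per-state CIU cross sections, transition placements on the 50-240 V grid,
the ~40% extended metavinculin population reaching 13,200 A^2, log-normal
FA sizes, and 1.2 %/min initial fluorescence decay after Y27632.  Values
the printed record does not pin down (peak widths, noise levels, masses)
are single documented choices in the variant YAML files.

Everything is driven by a NumPy Generator seeded from VariantParams.seed
(or an explicit argument), so identical parameters give byte-identical
outputs — the manifest test relies on that.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import VariantParams, load_variant
from .imms import (
    PROTON_MASS, DEFAULT_EDC, DEFAULT_GAS_MASS,
    CalibrantSet, CalibrationModel, Spectrum, drift_from_ccs, fit_calibration,
)

__all__ = [
    "DEFAULT_VOLTAGE_GRID",
    "default_calibration",
    "GeneratorManifest",
    "gen_spectrum",
    "gen_calibrants",
    "gen_ciu",
    "gen_ensemble",
    "gen_fa_dataset",
    "FaDataset",
]

DEFAULT_VOLTAGE_GRID = np.arange(50.0, 245.0, 5.0)  # 50-240 V in 5 V steps

# ground-truth power law used to synthesise drift times; recovered by
# fit_calibration in the round-trip tests
_TRUTH_A = 350.0
_TRUTH_B = 0.55


def default_calibration(edc: float = DEFAULT_EDC,
                        gas_mass: float = DEFAULT_GAS_MASS) -> CalibrationModel:
    """The generator's own drift-time model (a=350, b=0.55)."""
    return CalibrationModel(
        coeff_a=_TRUTH_A, exponent_b=_TRUTH_B, edc_coefficient=edc,
        gas_mass=gas_mass, fit_residuals=np.zeros(0), drift_range=(1.0, 80.0),
    )


@dataclass
class GeneratorManifest:
    """Reproducibility record: rerunning with the same snapshot and seed
    must reproduce byte-identical outputs."""

    seed: int
    variant: str
    parameter_snapshot: dict
    files: dict[str, str] = field(default_factory=dict)  # name -> sha256
    schema_version: str = "1"

    def add_array(self, name: str, arr: np.ndarray):
        self.files[name] = hashlib.sha256(
            np.ascontiguousarray(arr).tobytes()
        ).hexdigest()

    def add_frame(self, name: str, df: pd.DataFrame):
        self.files[name] = hashlib.sha256(
            df.to_csv(index=False).encode()
        ).hexdigest()

    def to_json(self, path=None) -> str:
        text = json.dumps(self.__dict__, indent=2, default=str)
        if path is not None:
            Path(path).write_text(text)
        return text


def _rng(v: VariantParams, seed: int | None) -> np.random.Generator:
    return np.random.default_rng(v.seed if seed is None else seed)


# ---------------------------------------------------------------------------
# Native spectra

def gen_spectrum(
    v: VariantParams,
    seed: int | None = None,
    mz_range: tuple[float, float] = (1800.0, 8200.0),
    mz_step: float = 1.0,
    baseline_noise: float = 0.003,
) -> Spectrum:
    """Gaussian charge-state envelope at (M + z*mp)/z plus baseline noise."""
    rng = _rng(v, seed)
    weights = v.charge_weights
    total = sum(weights.values())
    if total <= 0:
        raise ValueError("charge weights must sum to a positive value")
    mz = np.arange(*mz_range, mz_step)
    intensity = np.zeros_like(mz)
    for z, w in weights.items():
        center = (v.mass_da + z * PROTON_MASS) / z
        intensity += w * np.exp(-0.5 * ((mz - center) / v.peak_width_mz) ** 2)
    intensity /= intensity.max()
    intensity += np.abs(rng.normal(0.0, baseline_noise, len(mz)))
    return Spectrum(mz, intensity, metadata={"variant": v.name, "synthetic": True})


# ---------------------------------------------------------------------------
# Calibrants

def gen_calibrants(
    model_truth: tuple[float, float, float, float] | None = None,
    n: int = 8,
    noise: float = 0.0,
    seed: int = 0,
) -> CalibrantSet:
    """Fictional but physically plausible calibrant table.

    Drift times are solved from the inverse power law (truth defaults to
    the generator's a=350, b=0.55 model) with optional multiplicative
    noise.  Masses/charges/CCS span the vinculin drift range so analyte
    conversions interpolate rather than extrapolate.
    """
    if n < 3:
        raise ValueError("need >= 3 calibrants")
    a, b, edc, gas = model_truth or (_TRUTH_A, _TRUTH_B, DEFAULT_EDC,
                                     DEFAULT_GAS_MASS)
    model = CalibrationModel(coeff_a=a, exponent_b=b, edc_coefficient=edc,
                             gas_mass=gas, fit_residuals=np.zeros(0),
                             drift_range=(0.1, 100.0))
    rng = np.random.default_rng(seed)
    masses = np.linspace(40000.0, 320000.0, n)
    charges = np.clip(np.round(masses / 9000.0), 5, None).astype(int)
    # plausible globular scaling: CCS ~ m^(2/3)
    ccs = 2.9 * masses ** (2.0 / 3.0)
    rows = []
    for i, (m, z, c) in enumerate(zip(masses, charges, ccs)):
        drift = float(drift_from_ccs(c, int(z), m, model))
        if noise > 0:
            drift *= 1.0 + rng.normal(0.0, noise)
        rows.append({"name": f"CAL-{chr(65 + i)}", "mass_da": m, "z": int(z),
                     "ccs_lit": float(c), "drift_ms": drift})
    return CalibrantSet(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# CIU mobility records

def state_occupancies(v: VariantParams, voltages: np.ndarray) -> np.ndarray:
    """(n_voltages, 3) true C/SO/O weights from two sequential logistic gates."""
    volts = np.asarray(voltages, dtype=float)
    t1 = v.transitions["c_so"]
    t2 = v.transitions["so_o"]
    p1 = 1.0 / (1.0 + np.exp(-(volts - t1.midpoint_v) / t1.sharpness_v))
    p2 = 1.0 / (1.0 + np.exp(-(volts - t2.midpoint_v) / t2.sharpness_v))
    w = np.stack([1.0 - p1, p1 * (1.0 - p2), p1 * p2], axis=1)
    return w


def gen_ciu(
    v: VariantParams,
    grid: np.ndarray | None = None,
    model: CalibrationModel | None = None,
    mean_ions_per_voltage: int = 3000,
    drift_bin_ms: float = 0.1,
    seed: int | None = None,
) -> pd.DataFrame:
    """Mobility records (z, voltage, drift_ms, intensity) for one variant.

    Per voltage: Poisson ion count split multinomially over the C/SO/O
    occupancies, per-state CCS drawn Gaussian, mapped to drift time through
    the calibration model and binned.  Charge is the CIU charge state
    (17+ after charge reduction).
    """
    grid = DEFAULT_VOLTAGE_GRID if grid is None else np.asarray(grid, float)
    if grid.min() < 50.0 or grid.max() > 240.0:
        raise ValueError("voltage grid must lie within 50-240 V")
    model = model or default_calibration()
    rng = _rng(v, seed)
    occ = state_occupancies(v, grid)
    labels = [k for k in ("C", "SO", "O") if k in v.state_ccs]
    rows = []
    for i, volt in enumerate(grid):
        n_ions = rng.poisson(mean_ions_per_voltage)
        counts = rng.multinomial(n_ions, occ[i] / occ[i].sum())
        ccs_samples = []
        for k, lab in enumerate(labels):
            st = v.state_ccs[lab]
            if counts[k] > 0:
                ccs_samples.append(rng.normal(st.centroid, st.width, counts[k]))
        if not ccs_samples:
            continue
        ccs = np.clip(np.concatenate(ccs_samples), 1000.0, None)
        drift = drift_from_ccs(ccs, v.ciu_charge, v.mass_da, model)
        bins = np.round(drift / drift_bin_ms).astype(int)
        uniq, cnt = np.unique(bins, return_counts=True)
        for bctr, c in zip(uniq * drift_bin_ms, cnt):
            rows.append((v.ciu_charge, float(volt), float(bctr), int(c)))
    return pd.DataFrame(rows, columns=["z", "voltage", "drift_ms", "intensity"])


# ---------------------------------------------------------------------------
# Solution ensembles (single low-activation frame)

def gen_ensemble(
    v: VariantParams,
    n_ions: int = 10000,
    model: CalibrationModel | None = None,
    drift_bin_ms: float = 0.1,
    seed: int | None = None,
) -> pd.DataFrame:
    """Compact + extended conformer mixture mapped onto the charge axis.

    Compact ions (vinculin-like CCS, the variant's C state) populate the
    low charge states; extended ions draw CCS uniformly up to
    ``extended_ccs_max`` and populate the high-charge wing, mirroring the
    charge/conformation correlation of electrospray.
    """
    if n_ions < 1000:
        raise ValueError("need >= 1000 ions for a stable ensemble profile")
    model = model or default_calibration()
    rng = _rng(v, seed)
    frac = v.extended_fraction
    n_ext = int(round(n_ions * frac))
    n_cmp = n_ions - n_ext
    c_state = v.state_ccs["C"]
    rows = []
    z_lo, z_hi = v.compact_charge_range
    z_cmp = rng.integers(z_lo, z_hi + 1, n_cmp)
    ccs_cmp = rng.normal(c_state.centroid, c_state.width, n_cmp)
    z_ext = rng.integers(v.extended_charge_range[0],
                         v.extended_charge_range[1] + 1, n_ext)
    ccs_ext = rng.uniform(v.extended_ccs_min, v.extended_ccs_max, n_ext)
    z_all = np.concatenate([z_cmp, z_ext]).astype(int)
    ccs_all = np.clip(np.concatenate([ccs_cmp, ccs_ext]), 1000.0, None)
    for z in np.unique(z_all):
        sel = z_all == z
        drift = drift_from_ccs(ccs_all[sel], int(z), v.mass_da, model)
        bins = np.round(drift / drift_bin_ms).astype(int)
        uniq, cnt = np.unique(bins, return_counts=True)
        for bctr, c in zip(uniq * drift_bin_ms, cnt):
            rows.append((int(z), float(bctr), int(c)))
    return pd.DataFrame(rows, columns=["z", "drift_ms", "intensity"])


# ---------------------------------------------------------------------------
# Focal-adhesion imaging

@dataclass
class FaDataset:
    label_image: np.ndarray            # int32 labels, 0 = background
    times_min: np.ndarray              # frame times
    frames: list[np.ndarray]           # intensity images, float
    reference: np.ndarray              # bleaching reference trace
    truth: pd.DataFrame                # per-FA ground truth
    pixel_size: float
    manifest: GeneratorManifest

    def write(self, out_dir):
        """Optional TIFF + CSV export (large; goes to the caller's scratch)."""
        import tifffile

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        tifffile.imwrite(out / "labels.tif", self.label_image.astype(np.uint16))
        for i, frame in enumerate(self.frames):
            tifffile.imwrite(out / f"intensity_t{i:03d}.tif",
                             np.clip(frame, 0, 65535).astype(np.uint16))
        self.truth.to_csv(out / "truth.csv", index=False)
        pd.DataFrame({"time_min": self.times_min,
                      "reference": self.reference}).to_csv(
            out / "reference.csv", index=False)
        self.manifest.to_json(out / "manifest.json")


def gen_fa_dataset(
    v: VariantParams,
    n_fas: int = 1000,
    frames: int = 60,
    dt_min: float = 1.0,
    pixel_size: float = 0.1,
    seed: int | None = None,
    base_intensity: float = 3000.0,
    background: float = 50.0,
    fa_noise: float = 0.05,
    pixel_noise: float = 30.0,
    aspect_sigma: float = 0.35,
) -> FaDataset:
    """Labelled elliptical FAs with log-normal areas and decaying intensity.

    FAs sit on a jittered grid (no overlaps), areas follow the variant's
    log-normal law (um^2), and the fluorescence of FA *i* at time *t* is

        base_i * [plateau + (1-plateau) exp(-rate t)] * exp(-bleach t)
               * (1 + eps_{i,t}) + background + pixel noise.

    The bleaching reference trace exp(-bleach t) is returned alongside, as
    the experiment's control channel.
    """
    if n_fas < 1:
        raise ValueError("n_fas must be >= 1")
    rng = _rng(v, seed)
    mu, sigma = v.fa_lognormal

    cell_px = 40
    grid_n = int(np.ceil(np.sqrt(n_fas)))
    size = grid_n * cell_px
    label = np.zeros((size, size), dtype=np.int32)

    areas_um2 = np.exp(rng.normal(mu, sigma, n_fas))
    max_area_px = (cell_px / 2 - 2) ** 2 * np.pi / 3.0  # keep inside the cell
    areas_px = np.clip(areas_um2 / pixel_size**2, 4.0, max_area_px)
    aspect = np.exp(rng.normal(np.log(2.5), aspect_sigma, n_fas))
    theta = rng.uniform(0, np.pi, n_fas)
    base = np.exp(rng.normal(np.log(base_intensity), 0.25, n_fas))

    yy, xx = np.mgrid[0:cell_px, 0:cell_px]
    cells = rng.permutation(grid_n * grid_n)[:n_fas]
    rows_truth = []
    for i, cell in enumerate(cells):
        cy, cx = divmod(int(cell), grid_n)
        a = np.sqrt(areas_px[i] * aspect[i] / np.pi)   # semi-major, px
        b = areas_px[i] / (np.pi * a)                  # semi-minor
        jy, jx = rng.uniform(-3, 3, 2)
        y0, x0 = cell_px / 2 + jy, cell_px / 2 + jx
        ct, st = np.cos(theta[i]), np.sin(theta[i])
        u = (xx - x0) * ct + (yy - y0) * st
        w = -(xx - x0) * st + (yy - y0) * ct
        mask = (u / a) ** 2 + (w / b) ** 2 <= 1.0
        block = label[cy * cell_px:(cy + 1) * cell_px,
                      cx * cell_px:(cx + 1) * cell_px]
        block[mask] = i + 1
        rows_truth.append({
            "id": i + 1, "area_um2": float(mask.sum() * pixel_size**2),
            "base_intensity": float(base[i]),
            "sampled_area_um2": float(areas_um2[i]),
        })

    times = np.arange(frames, dtype=float) * dt_min
    decay = v.decay_plateau + (1.0 - v.decay_plateau) \
        * np.exp(-v.decay_rate_per_min * times)
    bleach = np.exp(-v.bleach_rate_per_min * times)
    reference = bleach * (1.0 + rng.normal(0.0, 0.002, frames))

    lab_flat = label.ravel()
    frames_out: list[np.ndarray] = []
    for t in range(frames):
        eps = rng.normal(0.0, fa_noise, n_fas)
        level = base * decay[t] * bleach[t] * (1.0 + eps)
        img = np.concatenate([[0.0], level])[lab_flat].reshape(label.shape)
        img += background + rng.normal(0.0, pixel_noise, label.shape)
        frames_out.append(np.clip(img, 0.0, None))

    truth = pd.DataFrame(rows_truth)
    manifest = GeneratorManifest(
        seed=v.seed if seed is None else seed, variant=v.name,
        parameter_snapshot={
            "fa_lognormal": v.fa_lognormal,
            "decay": (v.decay_rate_per_min, v.decay_plateau),
            "bleach_rate_per_min": v.bleach_rate_per_min,
            "n_fas": n_fas, "frames": frames, "dt_min": dt_min,
            "pixel_size": pixel_size,
        },
    )
    manifest.add_array("labels", label)
    manifest.add_array("frame_000", frames_out[0])
    manifest.add_frame("truth", truth)
    return FaDataset(label, times, frames_out, reference, truth, pixel_size,
                     manifest)
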