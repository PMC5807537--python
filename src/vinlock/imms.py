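"""Native-spectrum charge-state analysis and traveling-wave CCS calibration.

A native electrospray spectrum of a folded protein is a short envelope of
charge states; partially unfolded conformers carry more charge and widen
the envelope.  ``detect_charge_states`` picks peaks, infers the charge
ladder by brute-force consistency of the implied neutral mass, and counts
"major" states above a relative-intensity threshold (default 5% of the
base peak).

Traveling-wave drift times have no first-principles CCS relation and are
calibrated against standards of known cross section with the usual
power-law protocol:

    t' = t - EDC * sqrt(m/z) / 1000          (instrument delay correction)
    omega' = omega_lit / (z * sqrt(1/m + 1/m_gas))   (reduced CCS)
    ln omega' = ln a + b ln t'               (least squares)

after which an analyte CCS is  omega = a t'^b z sqrt(1/m + 1/m_gas).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

__all__ = [
    "PROTON_MASS",
    "Spectrum",
    "ChargeStateSet",
    "CalibrantSet",
    "CalibrationModel",
    "detect_charge_states",
    "fit_calibration",
    "ccs_from_drift",
    "ensemble_profile",
]

PROTON_MASS = 1.00728  # Da
DEFAULT_GAS_MASS = 28.0134  # Da, N2 (standard TWIMS drift gas)
DEFAULT_EDC = 1.57


@dataclass
class Spectrum:
    """An (m/z, intensity) trace with free-text acquisition metadata."""

    mz: np.ndarray
    intensity: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity must have equal length")
        if np.any(np.diff(self.mz) <= 0):
            raise ValueError("mz must be strictly increasing")
        if np.any(self.intensity < 0):
            raise ValueError("negative intensities")

    @classmethod
    def from_csv(cls, path, mz_col: str = "mz", intensity_col: str = "intensity"):
        df = pd.read_csv(path)
        return cls(df[mz_col].to_numpy(), df[intensity_col].to_numpy())

    def to_csv(self, path):
        pd.DataFrame({"mz": self.mz, "intensity": self.intensity}).to_csv(
            path, index=False
        )


@dataclass
class ChargeStateSet:
    """Detected charge ladder: (z, centroid m/z, relative intensity) triples."""

    entries: pd.DataFrame          # columns: z, centroid_mz, relative_intensity, major
    inferred_mass: float           # Da
    envelope_center_mz: float      # intensity-weighted mean m/z

    @property
    def n_major(self) -> int:
        return int(self.entries["major"].sum())

    @property
    def major_charges(self) -> list[int]:
        return self.entries.loc[self.entries["major"], "z"].astype(int).tolist()


def _peak_centroids(sp: Spectrum, min_prominence_frac: float = 0.02,
                    window: int = 3):
    """Local maxima with prominence, centroided over a +-window bin span.

    The trace is lightly smoothed first so single-bin baseline spikes do
    not register as peaks.
    """
    from scipy.ndimage import gaussian_filter1d

    smoothed = gaussian_filter1d(sp.intensity, 1.5)
    base = smoothed.max()
    idx, _ = find_peaks(smoothed, prominence=min_prominence_frac * base,
                        distance=5)
    cents, heights = [], []
    for i in idx:
        lo, hi = max(0, i - window), min(len(sp.mz), i + window + 1)
        w = smoothed[lo:hi]
        cents.append(float(np.average(sp.mz[lo:hi], weights=w)))
        heights.append(float(smoothed[i]))
    order = np.argsort(cents)
    return np.array(cents)[order], np.array(heights)[order]


def detect_charge_states(
    sp: Spectrum,
    min_rel_intensity: float = 0.05,
    max_charge: int = 80,
    min_prominence_frac: float = 0.02,
) -> ChargeStateSet:
    """Assign a charge ladder to spectrum peaks and infer the neutral mass.

    Charges are found by brute force: hypothesise the charge of the
    highest-m/z peak, derive every other peak's charge from the implied
    mass, and keep the hypothesis with the smallest relative spread of
    implied masses.  "Major" states have relative intensity >=
    ``min_rel_intensity`` of the base peak.
    """
    cents, heights = _peak_centroids(sp, min_prominence_frac)
    if len(cents) < 2:
        raise ValueError("charge indeterminate: need >= 2 resolvable peaks")

    # brute force over the charge of the highest-m/z peak; every multiple of
    # the true charge fits equally well (harmonic degeneracy), so among
    # near-optimal hypotheses take the smallest charge / lightest mass
    candidates = []
    for z_top in range(1, max_charge + 1):
        mass = z_top * (cents[-1] - PROTON_MASS)
        zs = np.clip(np.round(mass / (cents - PROTON_MASS)), 1, None)
        masses = zs * (cents - PROTON_MASS)
        spread = masses.std() / masses.mean()
        if len(np.unique(zs)) < len(zs):   # two peaks mapping to one charge
            spread += 1.0
        candidates.append((spread, z_top, zs.astype(int), masses))
    min_spread = min(c[0] for c in candidates)
    tol = max(2.0 * min_spread, 1e-4)
    _, _, zs, masses = next(c for c in candidates if c[0] <= tol)
    inferred_mass = float(np.average(masses, weights=heights))
    rel = heights / heights.max()
    entries = pd.DataFrame({
        "z": zs,
        "centroid_mz": cents,
        "relative_intensity": rel,
        "major": rel >= min_rel_intensity,
    }).sort_values("z", ascending=False).reset_index(drop=True)
    center = float(np.average(cents, weights=heights))
    return ChargeStateSet(entries, inferred_mass, center)


# ---------------------------------------------------------------------------
# Calibration

@dataclass
class CalibrantSet:
    """Per-calibrant (mass Da, charge, literature CCS A^2, drift time ms)."""

    table: pd.DataFrame  # columns: name, mass_da, z, ccs_lit, drift_ms

    def __post_init__(self):
        need = {"mass_da", "z", "ccs_lit", "drift_ms"}
        if not need <= set(self.table.columns):
            raise ValueError(f"calibrant table needs columns {sorted(need)}")

    def __len__(self) -> int:
        return len(self.table)

    @classmethod
    def from_csv(cls, path):
        return cls(pd.read_csv(path))

    def to_csv(self, path):
        self.table.to_csv(path, index=False)


@dataclass
class CalibrationModel:
    coeff_a: float
    exponent_b: float
    edc_coefficient: float
    gas_mass: float
    fit_residuals: np.ndarray       # per-calibrant relative error
    drift_range: tuple[float, float]  # corrected drift range spanned

    def __post_init__(self):
        if self.coeff_a <= 0:
            raise ValueError("coeff_a must be positive")
        if not 0.2 < self.exponent_b < 1.2:
            raise ValueError(
                f"exponent_b {self.exponent_b:.3f} outside the physical band (0.2, 1.2)"
            )

    def corrected_drift(self, drift_ms: float, mz: float) -> float:
        return drift_ms - self.edc_coefficient * np.sqrt(mz) / 1000.0

    def reduced_mass_term(self, mass_da: float) -> float:
        return float(np.sqrt(1.0 / mass_da + 1.0 / self.gas_mass))


def fit_calibration(
    cal: CalibrantSet,
    edc: float = DEFAULT_EDC,
    gas_mass: float = DEFAULT_GAS_MASS,
    max_rel_residual: float = 0.15,
) -> CalibrationModel:
    """Least-squares power-law fit of reduced CCS against corrected drift."""
    if len(cal) < 3:
        raise ValueError("need >= 3 calibrants for the power-law fit")
    t = cal.table["drift_ms"].to_numpy(dtype=float)
    m = cal.table["mass_da"].to_numpy(dtype=float)
    z = cal.table["z"].to_numpy(dtype=float)
    ccs = cal.table["ccs_lit"].to_numpy(dtype=float)
    mz = (m + z * PROTON_MASS) / z
    t_prime = t - edc * np.sqrt(mz) / 1000.0
    if np.any(t_prime <= 0):
        bad = cal.table.iloc[int(np.argmin(t_prime))]
        name = bad.get("name", f"row {int(np.argmin(t_prime))}")
        raise ValueError(f"non-positive corrected drift for calibrant {name}")
    omega_red = ccs / (z * np.sqrt(1.0 / m + 1.0 / gas_mass))
    b, ln_a = np.polyfit(np.log(t_prime), np.log(omega_red), 1)
    a = float(np.exp(ln_a))
    pred = a * t_prime**b * z * np.sqrt(1.0 / m + 1.0 / gas_mass)
    residuals = (pred - ccs) / ccs
    if np.max(np.abs(residuals)) > max_rel_residual:
        warnings.warn(
            f"calibration residuals up to {np.max(np.abs(residuals)):.1%}; "
            "check calibrant assignments"
        )
    return CalibrationModel(
        coeff_a=a, exponent_b=float(b), edc_coefficient=edc, gas_mass=gas_mass,
        fit_residuals=residuals,
        drift_range=(float(t_prime.min()), float(t_prime.max())),
    )


def ccs_from_drift(
    drift_ms: float | np.ndarray,
    charge: int,
    analyte_mass: float,
    model: CalibrationModel,
    mz: float | None = None,
    flag_extrapolation: bool = True,
):
    """CCS (A^2) of an analyte ion from its drift time.

    Accepts a scalar or an array of drift times (replicates, e.g. the three
    wave heights); arrays return (mean CcsValue with replicate sd).
    """
    from .ccs3d import CcsValue

    if mz is None:
        mz = (analyte_mass + charge * PROTON_MASS) / charge
    drift = np.atleast_1d(np.asarray(drift_ms, dtype=float))
    t_prime = drift - model.edc_coefficient * np.sqrt(mz) / 1000.0
    if np.any(t_prime <= 0):
        raise ValueError("non-positive corrected drift time")
    if flag_extrapolation:
        lo, hi = model.drift_range
        if np.any(t_prime < lo) or np.any(t_prime > hi):
            warnings.warn("drift time outside the calibrant range: extrapolating")
    omega = (model.coeff_a * t_prime**model.exponent_b * charge
             * model.reduced_mass_term(analyte_mass))
    if np.isscalar(drift_ms):
        return CcsValue(float(omega[0]), 0.0, "calibrated_experimental")
    sd = float(omega.std(ddof=1)) if len(omega) > 1 else 0.0
    return CcsValue(float(omega.mean()), sd, "calibrated_experimental")


def drift_from_ccs(
    ccs: float | np.ndarray, charge: int, analyte_mass: float,
    model: CalibrationModel, mz: float | None = None,
) -> np.ndarray:
    """Inverse of :func:`ccs_from_drift`; used by the synthetic generator."""
    if mz is None:
        mz = (analyte_mass + charge * PROTON_MASS) / charge
    omega_red = np.asarray(ccs, dtype=float) / (
        charge * model.reduced_mass_term(analyte_mass)
    )
    t_prime = (omega_red / model.coeff_a) ** (1.0 / model.exponent_b)
    return t_prime + model.edc_coefficient * np.sqrt(mz) / 1000.0


# ---------------------------------------------------------------------------
# Conformer ensembles

def ensemble_profile(
    records: pd.DataFrame,
    analyte_mass: float,
    model: CalibrationModel,
    k_sd: float = 3.0,
    compact_window: float = 0.10,
    no_mode_rel_sd: float = 0.04,
) -> tuple[pd.DataFrame, float]:
    """Per-charge-state CCS table plus the extended-population fraction.

    ``records`` columns: z, drift_ms, intensity (one low-activation frame).
    The compact mode is located from the intensity-weighted CCS histogram;
    everything beyond (compact centroid + k_sd * compact sd) counts as
    extended.  A genuine folded mode is narrow — if the material around the
    histogram mode spreads wider than ``no_mode_rel_sd`` (relative), there
    is no compact population and the whole ensemble counts as extended.
    Returns (table with z / ccs / relative population, fraction).
    """
    need = {"z", "drift_ms", "intensity"}
    if not need <= set(records.columns):
        raise ValueError(f"records need columns {sorted(need)}")
    if records["z"].nunique() < 2:
        raise ValueError("need >= 2 charge states for an ensemble profile")
    ccs_all = np.concatenate([
        np.atleast_1d(
            (model.coeff_a
             * np.clip(sub["drift_ms"].to_numpy()
                       - model.edc_coefficient
                       * np.sqrt((analyte_mass + z * PROTON_MASS) / z) / 1000.0,
                       1e-9, None) ** model.exponent_b)
            * z * model.reduced_mass_term(analyte_mass)
        )
        for z, sub in records.groupby("z")
    ])
    w_all = np.concatenate([
        sub["intensity"].to_numpy(dtype=float) for _, sub in records.groupby("z")
    ])
    # compact mode from the weighted histogram
    hist, edges = np.histogram(ccs_all, bins=200, weights=w_all)
    mode = 0.5 * (edges[np.argmax(hist)] + edges[np.argmax(hist) + 1])
    near = np.abs(ccs_all - mode) <= compact_window * mode
    centroid = float(np.average(ccs_all[near], weights=w_all[near]))
    sd = float(np.sqrt(np.average((ccs_all[near] - centroid) ** 2,
                                  weights=w_all[near])))
    has_compact_mode = sd <= no_mode_rel_sd * centroid
    if has_compact_mode:
        threshold = centroid + k_sd * max(sd, 1e-9)
    else:  # structureless ensemble: everything is extended
        threshold = -np.inf
        centroid, sd = float("nan"), float("nan")

    rows = []
    total = w_all.sum()
    i = 0
    for z, sub in records.groupby("z"):
        n = len(sub)
        ccs_z, w_z = ccs_all[i:i + n], w_all[i:i + n]
        i += n
        rows.append({
            "z": int(z),
            "ccs": float(np.average(ccs_z, weights=w_z)) if w_z.sum() else np.nan,
            "population": float(w_z.sum() / total),
            "max_ccs": float(ccs_z[w_z > 0].max()) if (w_z > 0).any() else np.nan,
        })
    table = pd.DataFrame(rows).sort_values("z").reset_index(drop=True)
    extended_fraction = float(w_all[ccs_all > threshold].sum() / total)
    table.attrs["compact_centroid"] = centroid
    table.attrs["compact_sd"] = sd
    table.attrs["threshold"] = threshold
    table.attrs["has_compact_mode"] = has_compact_mode
    table.attrs["max_ccs"] = float(ccs_all[w_all > 0].max())
    return table, extended_fraction
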