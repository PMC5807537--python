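"""Collision-induced unfolding fingerprints and C -> SO -> O state detection.

A CIU fingerprint is a matrix of arrival-intensity over (collision voltage,
CCS), one charge state at a time, each voltage row normalised to unit sum.
The central model is a *shared-component* Gaussian mixture: the same small
set of conformer states (centroid + width on the CCS axis) is present at
every voltage, and only their weights change with voltage.  Sharing the
components across the whole fingerprint is what stabilises centroids for
states that are only transiently populated.

States are ordered by centroid and labelled C (closed), SO (semi-open) and
O (open).  A transition between adjacent states is characterised by the
voltage at which the new state first reaches a presence threshold (onset),
the voltage at which the old state last holds it (completion), and the
width of their coexistence window — wide coexistence is a gradual,
force-tunable transition, narrow coexistence an abrupt switch.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .imms import CalibrationModel, PROTON_MASS

__all__ = [
    "CIUFingerprint",
    "ConformerState",
    "TransitionReport",
    "build_fingerprint",
    "detect_states",
    "detect_transitions",
    "stability_profile",
    "compare_variants",
    "STATE_LABELS",
]

STATE_LABELS = ("C", "SO", "O")
DEFAULT_PRESENCE_THRESHOLD = 0.10
DEFAULT_GRADUAL_MIN_WIDTH = 15.0  # V (= 3 grid steps)


@dataclass
class CIUFingerprint:
    voltages: np.ndarray        # V, strictly increasing
    ccs_axis: np.ndarray        # A^2 bin centers, strictly increasing
    intensity: np.ndarray       # (n_voltages, n_bins), rows sum to 1
    charge_state: int
    row_counts: np.ndarray | None = None   # raw counts per row, for likelihoods
    row_valid: np.ndarray | None = None    # False where the raw row was empty

    def __post_init__(self):
        self.voltages = np.asarray(self.voltages, dtype=float)
        self.ccs_axis = np.asarray(self.ccs_axis, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if np.any(np.diff(self.voltages) <= 0) or np.any(np.diff(self.ccs_axis) <= 0):
            raise ValueError("voltage and CCS axes must be strictly increasing")
        if self.intensity.shape != (len(self.voltages), len(self.ccs_axis)):
            raise ValueError("intensity shape mismatch")
        if self.row_valid is None:
            self.row_valid = np.ones(len(self.voltages), dtype=bool)
        sums = self.intensity.sum(axis=1)
        ok = self.row_valid
        if np.any(np.abs(sums[ok] - 1.0) > 1e-6):
            raise ValueError("valid rows must be normalised to unit sum")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.intensity, columns=np.round(self.ccs_axis, 2))
        df.insert(0, "voltage", self.voltages)
        return df

    def to_csv(self, path):
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, charge_state: int) -> "CIUFingerprint":
        volts = df["voltage"].to_numpy(dtype=float)
        ccs = np.array([float(c) for c in df.columns if c != "voltage"])
        mat = df.drop(columns="voltage").to_numpy(dtype=float)
        return cls(volts, ccs, mat, charge_state)


@dataclass
class ConformerState:
    label: str                  # C / SO / O
    centroid: float             # A^2
    width: float                # A^2 (gaussian sd)
    occupancy: np.ndarray       # per-voltage weight
    voltages: np.ndarray
    presence_threshold: float = DEFAULT_PRESENCE_THRESHOLD

    @property
    def voltage_range(self) -> tuple[float, float] | None:
        """(first, last) voltage at which occupancy >= presence threshold."""
        idx = np.where(self.occupancy >= self.presence_threshold)[0]
        if len(idx) == 0:
            return None
        return (float(self.voltages[idx[0]]), float(self.voltages[idx[-1]]))


@dataclass
class TransitionReport:
    from_state: str
    to_state: str
    onset_voltage: float | None       # new state first >= threshold
    completion_voltage: float | None  # old state last >= threshold
    coexistence_width: float | None   # V
    mode: str                         # gradual / abrupt / absent


# ---------------------------------------------------------------------------
# Fingerprint construction

def build_fingerprint(
    records: pd.DataFrame,
    model: CalibrationModel,
    analyte_mass: float,
    ccs_bins: int = 160,
    smoothing_sigma_bins: float = 0.0,
    ccs_range: tuple[float, float] | None = None,
) -> CIUFingerprint:
    """Histogram mobility records at many voltages onto a shared CCS axis.

    ``records`` columns: z, voltage, drift_ms, intensity — all one charge.
    Rows are normalised to unit sum; all-zero rows are flagged, not
    normalised.  Optional Gaussian smoothing along the CCS axis preserves
    row sums.
    """
    need = {"z", "voltage", "drift_ms", "intensity"}
    if not need <= set(records.columns):
        raise ValueError(f"records need columns {sorted(need)}")
    charges = records["z"].unique()
    if len(charges) != 1:
        raise ValueError(f"mixed charge states {sorted(charges)}; filter to one")
    z = int(charges[0])
    voltages = np.sort(records["voltage"].unique())
    if len(voltages) < 5:
        raise ValueError("need >= 5 distinct collision voltages")

    mz = (analyte_mass + z * PROTON_MASS) / z
    t_prime = records["drift_ms"].to_numpy(dtype=float) \
        - model.edc_coefficient * np.sqrt(mz) / 1000.0
    t_prime = np.clip(t_prime, 1e-9, None)
    ccs = (model.coeff_a * t_prime**model.exponent_b
           * z * model.reduced_mass_term(analyte_mass))
    w = records["intensity"].to_numpy(dtype=float)
    if ccs_range is None:
        lo, hi = float(ccs[w > 0].min()), float(ccs[w > 0].max())
        pad = 0.02 * (hi - lo)
        lo, hi = lo - pad, hi + pad
    else:
        lo, hi = ccs_range
    edges = np.linspace(lo, hi, ccs_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])

    mat = np.zeros((len(voltages), ccs_bins))
    vcol = records["voltage"].to_numpy(dtype=float)
    for i, v in enumerate(voltages):
        sel = vcol == v
        mat[i], _ = np.histogram(np.clip(ccs[sel], lo, hi), bins=edges,
                                 weights=w[sel])
    row_counts = mat.sum(axis=1)
    valid = row_counts > 0
    if smoothing_sigma_bins > 0:
        mat = gaussian_filter1d(mat, smoothing_sigma_bins, axis=1, mode="constant")
    out = np.zeros_like(mat)
    out[valid] = mat[valid] / mat[valid].sum(axis=1, keepdims=True)
    if not valid.all():
        warnings.warn(f"{(~valid).sum()} all-zero voltage rows flagged")
    return CIUFingerprint(voltages, centers, out, z, row_counts, valid)


# ---------------------------------------------------------------------------
# Shared-component mixture fit

def _em_fit(x, weights, counts, k, mu0, sigma0, n_iter=300, tol=1e-9):
    """EM for k shared Gaussians over rows with per-row mixing weights.

    x: (B,) bin centers; weights: (V, B) normalised rows; counts: (V,)
    effective counts per row.  Returns (mu, sigma, w, loglik).
    """
    V, B = weights.shape
    c = weights * counts[:, None]          # (V, B) effective counts
    mu = np.array(mu0, dtype=float)
    sigma = np.array(sigma0, dtype=float)
    w = np.full((V, k), 1.0 / k)
    span = x[-1] - x[0]
    min_sigma = max((x[1] - x[0]) * 0.75, 1e-6)
    prev = -np.inf
    for _ in range(n_iter):
        # E step
        dens = np.exp(-0.5 * ((x[None, :, None] - mu[None, None, :])
                              / sigma[None, None, :]) ** 2) \
            / (sigma[None, None, :] * np.sqrt(2 * np.pi))          # (1, B, k)
        num = w[:, None, :] * dens                                  # (V, B, k)
        denom = num.sum(axis=2, keepdims=True)
        denom = np.where(denom <= 1e-300, 1e-300, denom)
        resp = num / denom                                          # (V, B, k)
        ll = float(np.sum(c * np.log(denom[..., 0])))
        # M step
        cw = c[..., None] * resp                                    # (V, B, k)
        per_row = cw.sum(axis=1)                                    # (V, k)
        w = per_row / np.clip(per_row.sum(axis=1, keepdims=True), 1e-300, None)
        tot = cw.sum(axis=(0, 1))                                   # (k,)
        tot = np.clip(tot, 1e-300, None)
        mu = (cw * x[None, :, None]).sum(axis=(0, 1)) / tot
        var = (cw * (x[None, :, None] - mu[None, None, :]) ** 2).sum(axis=(0, 1)) / tot
        sigma = np.clip(np.sqrt(var), min_sigma, span)
        if abs(ll - prev) < tol * max(1.0, abs(ll)):
            prev = ll
            break
        prev = ll
    return mu, sigma, w, prev


def detect_states(
    fp: CIUFingerprint,
    max_states: int = 3,
    seed: int = 7,
    n_starts: int = 6,
    presence_threshold: float = DEFAULT_PRESENCE_THRESHOLD,
    min_separation_sigma: float = 2.0,
) -> list[ConformerState]:
    """Fit the shared-component mixture and label states C/SO/O.

    The number of components (1..max_states) is chosen by BIC computed on
    the effective counts; components are ordered by centroid.  Multi-start
    EM is seeded and the best-likelihood fit kept.  If adjacent centroids
    collapse (closer than ``min_separation_sigma`` pooled widths) the
    smaller model wins, so unimodal data yield exactly one state.
    """
    valid = fp.row_valid
    x = fp.ccs_axis
    rows = fp.intensity[valid]
    counts = (fp.row_counts[valid] if fp.row_counts is not None
              else np.full(valid.sum(), 1000.0))
    counts = np.clip(counts, 1.0, None)
    rng = np.random.default_rng(seed)
    pooled = rows.mean(axis=0)
    pooled_mu = float(np.average(x, weights=pooled))
    pooled_sd = float(np.sqrt(np.average((x - pooled_mu) ** 2, weights=pooled)))
    span = x[-1] - x[0]

    best_per_k = {}
    for k in range(1, max_states + 1):
        best = None
        # one deterministic evenly-spread start plus seeded random restarts:
        # the pooled profile is dominated by the closed state, so quantile
        # inits collapse onto it for transient components
        inits = [np.linspace(x[0] + 0.15 * span, x[-1] - 0.15 * span, k)]
        for _ in range(max(n_starts - 1, 0)):
            inits.append(np.sort(
                rng.uniform(x[0] + 0.05 * span, x[-1] - 0.05 * span, k)
            ))
        for mu0 in inits:
            sigma0 = np.full(k, max(pooled_sd / max(k, 1), (x[1] - x[0])))
            fit = _em_fit(x, rows, counts, k, mu0, sigma0)
            if best is None or fit[3] > best[3]:
                best = fit
        mu, sigma, w, ll = best
        n_params = 2 * k + (k - 1) * rows.shape[0]
        bic = -2.0 * ll + n_params * np.log(max(counts.sum(), 2.0))
        best_per_k[k] = (bic, mu, sigma, w)

    # discard models whose adjacent components collapse onto each other
    def separated(mu, sigma):
        order = np.argsort(mu)
        m, s = mu[order], sigma[order]
        return np.all(np.diff(m) >= min_separation_sigma *
                      0.5 * (s[:-1] + s[1:]))

    candidates = {k: v for k, v in best_per_k.items()
                  if separated(v[1], v[2]) or k == 1}
    k_best = min(candidates, key=lambda k: candidates[k][0])
    _, mu, sigma, w = candidates[k_best]
    if k_best < 2:
        warnings.warn(
            f"only {k_best} resolvable conformer state(s) in this fingerprint"
        )

    order = np.argsort(mu)
    states = []
    for rank, j in enumerate(order):
        occ = np.zeros(len(fp.voltages))
        occ[valid] = w[:, j]
        label = STATE_LABELS[rank] if rank < len(STATE_LABELS) else f"S{rank}"
        states.append(ConformerState(
            label=label, centroid=float(mu[j]), width=float(sigma[j]),
            occupancy=occ, voltages=fp.voltages,
            presence_threshold=presence_threshold,
        ))
    return states


# ---------------------------------------------------------------------------
# Transitions and stability

def detect_transitions(
    states: list[ConformerState],
    step: float = 5.0,
    presence_threshold: float | None = None,
    gradual_min_width: float = DEFAULT_GRADUAL_MIN_WIDTH,
) -> list[TransitionReport]:
    """Onset / completion / coexistence for each adjacent state pair.

    onset = first voltage at which the *new* state holds >= the presence
    threshold; completion = last voltage at which the *old* state does.
    mode = "gradual" iff the coexistence window is at least
    ``gradual_min_width`` (default three 5 V steps), else "abrupt".
    """
    if len(states) < 2:
        raise ValueError("need >= 2 states to report transitions")
    reports = []
    ordered = sorted(states, key=lambda st: st.centroid)
    for old, new in zip(ordered, ordered[1:]):
        thr = presence_threshold
        old_rng = (old.voltage_range if thr is None else
                   _voltage_range(old, thr))
        new_rng = (new.voltage_range if thr is None else
                   _voltage_range(new, thr))
        if new_rng is None or old_rng is None:
            reports.append(TransitionReport(old.label, new.label,
                                            None, None, None, "absent"))
            continue
        onset = new_rng[0]
        completion = old_rng[1]
        width = completion - onset
        mode = "gradual" if width >= gradual_min_width else "abrupt"
        reports.append(TransitionReport(old.label, new.label,
                                        onset, completion, width, mode))
    return reports


def _voltage_range(state: ConformerState, thr: float):
    idx = np.where(state.occupancy >= thr)[0]
    if len(idx) == 0:
        return None
    return (float(state.voltages[idx[0]]), float(state.voltages[idx[-1]]))


def stability_profile(states: list[ConformerState], step: float = 5.0) -> pd.DataFrame:
    """Dwell width (V) of each state at its presence threshold."""
    rows = []
    for st in states:
        rng = st.voltage_range
        dwell = 0.0 if rng is None else rng[1] - rng[0] + step
        rows.append({"state": st.label, "first_v": None if rng is None else rng[0],
                     "last_v": None if rng is None else rng[1], "dwell_v": dwell})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Cross-variant comparison

def _rebin(fp: CIUFingerprint, axis: np.ndarray) -> CIUFingerprint:
    mat = np.zeros((len(fp.voltages), len(axis)))
    for i in range(len(fp.voltages)):
        mat[i] = np.interp(axis, fp.ccs_axis, fp.intensity[i], left=0.0, right=0.0)
        tot = mat[i].sum()
        if tot > 0:
            mat[i] /= tot
    return CIUFingerprint(fp.voltages, axis, mat, fp.charge_state,
                          fp.row_counts, fp.row_valid)


def compare_variants(
    fingerprints: dict[str, CIUFingerprint],
    overlay_voltages: tuple[float, ...] = (100.0, 125.0, 230.0),
    **detect_kwargs,
) -> dict:
    """Aligned per-voltage CCS profiles and an onset table across variants.

    Fingerprints are rebinned onto a shared CCS axis.  Returns a dict with
    ``overlays`` (voltage -> DataFrame of profiles, one column per variant)
    and ``onsets`` (DataFrame of C->SO onset/completion/mode per variant).
    """
    if not fingerprints:
        raise ValueError("no fingerprints given")
    lo = min(fp.ccs_axis[0] for fp in fingerprints.values())
    hi = max(fp.ccs_axis[-1] for fp in fingerprints.values())
    n = max(len(fp.ccs_axis) for fp in fingerprints.values())
    axis = np.linspace(lo, hi, n)
    aligned = {name: _rebin(fp, axis) for name, fp in fingerprints.items()}

    overlays = {}
    for v in overlay_voltages:
        cols = {"ccs": axis}
        for name, fp in aligned.items():
            i = int(np.argmin(np.abs(fp.voltages - v)))
            cols[name] = fp.intensity[i]
        overlays[v] = pd.DataFrame(cols)

    onset_rows = []
    for name, fp in aligned.items():
        states = detect_states(fp, **detect_kwargs)
        if len(states) >= 2:
            tr = detect_transitions(states)[0]
            onset_rows.append({"variant": name, "onset_v": tr.onset_voltage,
                               "completion_v": tr.completion_voltage,
                               "mode": tr.mode})
        else:
            onset_rows.append({"variant": name, "onset_v": None,
                               "completion_v": None, "mode": "absent"})
    return {"overlays": overlays, "onsets": pd.DataFrame(onset_rows)}
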