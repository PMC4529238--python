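"""Poisson-fluence dose realizations and compartmental dose statistics.

A dose realization at a target dose draws the number of beams from a Poisson
distribution around the expected beam count, selects that many distinct
trials from a coincidence library and pools their coincident voxels in the
fixed neuron frame.  The coefficient of variation of the realized neuron dose
across realizations falls with dose as ~Dose^-1/2 (Poisson counting), which
the power-law fit quantifies.

The expected beam count can be calibrated against either the library's mean
per-trial neuron dose (basis "neuron": realizations are unbiased for the
target neuron dose) or the nominal dose per beam (basis "fluence": the target
is the fluence dose and the realized neuron dose is smaller by the library's
electronic-equilibrium capture ratio).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .morphology import COMPARTMENT_TYPES
from .scoring import EV_UM3_TO_GY, CoincidenceLibrary

__all__ = [
    "DoseRealization",
    "CompartmentStats",
    "PowerLawFit",
    "sample_realization",
    "compartment_stats",
    "cv_curve",
    "fit_power_law",
]


@dataclass
class DoseRealization:
    """One Poisson-sampled irradiation at a target dose."""

    target_dose_gy: float
    basis: str
    expected_beams: float
    n_beams: int
    trial_ids: np.ndarray
    neuron_ed_ev: float
    neuron_dose_gy: float
    compartment_ed_ev: np.ndarray
    compartment_dose_gy: np.ndarray
    seed: int | None = None

    @property
    def n_compartments_hit(self) -> int:
        return int((self.compartment_ed_ev > 0).sum())


def _expected_beams(lib: CoincidenceLibrary, target_dose_gy: float, basis: str) -> float:
    if basis == "neuron":
        per_trial = lib.mean_trial_neuron_dose_gy
    elif basis == "fluence":
        per_trial = lib.dose_per_beam_gy
    else:
        raise ValueError(f"unknown dose basis {basis!r}")
    if per_trial <= 0:
        raise ValueError("library has no deposited energy to calibrate against")
    return target_dose_gy / per_trial


def sample_realization(lib: CoincidenceLibrary, target_dose_gy: float,
                       seed: int | np.random.Generator,
                       basis: str = "neuron") -> DoseRealization:
    """Draw one dose realization from a coincidence library.

    N ~ Poisson(target / dose-per-trial); N distinct trials are drawn without
    replacement and their voxel EDs pooled per compartment.  The library must
    hold at least 10x the expected beam count so the without-replacement draw
    stays close to independent sampling.
    """
    if target_dose_gy < 0:
        raise ValueError("target dose must be non-negative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_comp = lib.decorated.n_compartments
    if target_dose_gy == 0:
        return DoseRealization(0.0, basis, 0.0, 0, np.empty(0, int), 0.0, 0.0,
                               np.zeros(n_comp), np.zeros(n_comp))
    expect = _expected_beams(lib, target_dose_gy, basis)
    if lib.n_trials < 10 * expect:
        raise ValueError(
            f"library of {lib.n_trials} trials is too small for a "
            f"{1e3 * target_dose_gy:.3g} mGy realization: "
            f">= {int(np.ceil(10 * expect))} trials required")
    n = int(rng.poisson(expect))
    n = min(n, lib.n_trials)
    ids = rng.choice(lib.n_trials, size=n, replace=False)
    comp_ed = np.zeros(n_comp)
    if n:
        comp, ed, _ = lib.trial_records(ids)
        np.add.at(comp_ed, comp, ed)
    neuron_ed = float(comp_ed.sum())
    comp_dose = comp_ed * EV_UM3_TO_GY / lib.decorated.compartment_volume
    return DoseRealization(
        target_dose_gy=target_dose_gy, basis=basis, expected_beams=expect,
        n_beams=n, trial_ids=ids, neuron_ed_ev=neuron_ed,
        neuron_dose_gy=neuron_ed * EV_UM3_TO_GY / lib.neuron_volume_um3,
        compartment_ed_ev=comp_ed, compartment_dose_gy=comp_dose)


@dataclass
class CompartmentStats:
    """Per-type hit-dose and hit-percentage statistics over realizations.

    ``table`` rows: one per compartment group (soma, dendrite, spine pooled,
    filopodium) with the mean and SD over realizations of (a) the mean dose
    among hit compartments and (b) the percentage of compartments hit, plus
    the mean within-realization SD across hit compartments.
    """

    table: pd.DataFrame
    n_realizations: int


_GROUPS = ("soma", "dendrite", "spine", "filopodium")


def _group_codes(types: np.ndarray) -> np.ndarray:
    names = np.array([COMPARTMENT_TYPES[t] for t in types])
    out = np.empty(types.size, dtype=np.int8)
    out[names == "soma"] = 0
    out[names == "dendrite"] = 1
    out[np.char.startswith(names, "spine")] = 2
    out[names == "filopodium"] = 3
    return out


def compartment_stats(realizations: list[DoseRealization],
                      lib: CoincidenceLibrary) -> CompartmentStats:
    """Hit percentages and hit-compartment doses per type.

    A compartment counts as hit when it contains at least one coincident
    voxel; dose statistics are computed over hit compartments only.
    """
    if len(realizations) < 2:
        raise ValueError("need at least two realizations")
    g = _group_codes(lib.decorated.compartment_type)
    n_per_group = np.bincount(g, minlength=4).astype(float)
    rows = {name: {"hit_dose": [], "pct_hit": [], "within_sd": []} for name in _GROUPS}
    for r in realizations:
        hit = r.compartment_ed_ev > 0
        for code, name in enumerate(_GROUPS):
            sel = g == code
            nh = int((hit & sel).sum())
            rows[name]["pct_hit"].append(100.0 * nh / max(n_per_group[code], 1))
            doses = r.compartment_dose_gy[hit & sel]
            rows[name]["hit_dose"].append(doses.mean() if nh else np.nan)
            rows[name]["within_sd"].append(doses.std(ddof=1) if nh > 1 else np.nan)
    recs = []
    for name in _GROUPS:
        hd = np.asarray(rows[name]["hit_dose"])
        ph = np.asarray(rows[name]["pct_hit"])
        ws = np.asarray(rows[name]["within_sd"])
        recs.append({
            "group": name,
            "n_compartments": int(n_per_group[_GROUPS.index(name)]),
            "hit_dose_mean_gy": np.nanmean(hd) if np.any(~np.isnan(hd)) else np.nan,
            "hit_dose_sd_gy": np.nanstd(hd, ddof=1) if np.sum(~np.isnan(hd)) > 1 else np.nan,
            "hit_dose_within_sd_gy": np.nanmean(ws) if np.any(~np.isnan(ws)) else np.nan,
            "pct_hit_mean": ph.mean(),
            "pct_hit_sd": ph.std(ddof=1),
        })
    return CompartmentStats(pd.DataFrame(recs), len(realizations))


def cv_curve(lib: CoincidenceLibrary, dose_grid_gy, n_realizations: int,
             seed: int, basis: str = "neuron") -> pd.DataFrame:
    """Mean, SD and CV = SD/mean of realized neuron dose per grid dose."""
    dose_grid_gy = np.asarray(dose_grid_gy, dtype=float)
    if np.any(dose_grid_gy <= 0):
        raise ValueError("dose grid must be positive")
    rng = np.random.default_rng(seed)
    per_trial_ed = lib.trial_neuron_ed_ev
    to_gy = EV_UM3_TO_GY / lib.neuron_volume_um3
    rows = []
    for d in dose_grid_gy:
        expect = _expected_beams(lib, d, basis)
        if lib.n_trials < 10 * expect:
            raise ValueError(
                f"library of {lib.n_trials} trials too small for "
                f"{1e3 * d:.3g} mGy (needs >= {int(np.ceil(10 * expect))})")
        counts = rng.poisson(expect, n_realizations)
        doses = np.empty(n_realizations)
        for k, n in enumerate(counts):
            n = min(int(n), lib.n_trials)
            ids = rng.choice(lib.n_trials, size=n, replace=False)
            doses[k] = per_trial_ed[ids].sum() * to_gy
        rows.append({"dose_gy": d, "mean_gy": doses.mean(),
                     "sd_gy": doses.std(ddof=1),
                     "cv": doses.std(ddof=1) / doses.mean()})
    return pd.DataFrame(rows)


@dataclass
class PowerLawFit:
    """CV = amplitude * dose^power, fitted by log-log least squares."""

    amplitude: float
    power: float
    dose_gy: np.ndarray
    cv: np.ndarray
    residuals: np.ndarray

    def predict(self, dose_gy) -> np.ndarray:
        return self.amplitude * np.asarray(dose_gy) ** self.power


def fit_power_law(curve: pd.DataFrame | tuple) -> PowerLawFit:
    """Ordinary least squares of log CV on log dose.

    Accepts the :func:`cv_curve` table or a (dose, cv) pair.  Non-positive CV
    values are excluded with a warning; at least three positive points are
    required.
    """
    if isinstance(curve, pd.DataFrame):
        dose = curve["dose_gy"].to_numpy(float)
        cv = curve["cv"].to_numpy(float)
    else:
        dose, cv = (np.asarray(a, dtype=float) for a in curve)
    ok = cv > 0
    if not np.all(ok):
        warnings.warn(f"excluding {int((~ok).sum())} non-positive CV values")
        dose, cv = dose[ok], cv[ok]
    if dose.size < 3:
        raise ValueError("need at least three positive (dose, CV) points")
    slope, intercept = np.polyfit(np.log(dose), np.log(cv), 1)
    resid = np.log(cv) - (intercept + slope * np.log(dose))
    return PowerLawFit(float(np.exp(intercept)), float(slope), dose, cv, resid)
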