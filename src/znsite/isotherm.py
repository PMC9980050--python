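"""Binding-isotherm fits for thermophoresis-style titrations and buffered
free-metal arithmetic.

The normalized signal F of a dilution series against free Zn2+
concentration C is fitted either with the law of mass action including
ligand depletion by the protein (quadratic form)

    F(C) = F_u + (F_b - F_u) * [ (C + P + Kd) - sqrt((C + P + Kd)^2 - 4 P C) ] / (2 P)

with P the protein concentration, or with the Hill equation

    F(C) = F_u + (F_b - F_u) / (1 + (EC50 / C)^n).

Free Zn2+ during the titration is set by a 1:1 chelator (nitrilotriacetate,
Kd = 14 nM, or citrate, Kd = 12 uM); the mass balance gives the free
concentration as the positive root of a quadratic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator

#: dissociation constants of the chelators used to buffer free Zn2+ (molar)
NTA_KD = 14e-9
CITRATE_KD = 12e-6


@dataclass(frozen=True)
class Chelator:
    name: str
    kd_molar: float
    total_molar: float


@dataclass
class MSTDataset:
    """Binding-titration points plus the assay's protein concentration.

    ``points`` columns: ph, c_zn_molar, signal, replicate.
    """

    points: pd.DataFrame
    protein_conc_molar: float
    chelator: Optional[Chelator] = None

    def __post_init__(self):
        required = {"ph", "c_zn_molar", "signal", "replicate"}
        missing = required - set(self.points.columns)
        if missing:
            raise ValueError(f"points missing columns {sorted(missing)}")
        if self.protein_conc_molar <= 0:
            raise ValueError("protein concentration must be positive")
        if (self.points["c_zn_molar"] < 0).any():
            raise ValueError("free Zn2+ concentrations must be >= 0")

    def series(self, ph: float) -> pd.DataFrame:
        sel = self.points[np.isclose(self.points["ph"], ph)]
        if sel["c_zn_molar"].nunique() < 6:
            raise ValueError(
                f"need >= 6 distinct concentrations at pH {ph}, "
                f"got {sel['c_zn_molar'].nunique()}"
            )
        return sel

    @property
    def ph_values(self):
        return sorted(self.points["ph"].unique())


# ---------------------------------------------------------------------------
# Chelator buffering


def free_zinc(total_zn: float, chelator_total: float, chelator_kd: float) -> float:
    """Free Zn2+ concentration with a 1:1 chelator (molar).

    Positive root of ``f^2 + f (L_T - Zn_T + K_d) - K_d Zn_T = 0`` from the
    1:1 complex mass balance; degenerate inputs are handled analytically.
    """
    if total_zn < 0 or chelator_total < 0:
        raise ValueError("concentrations must be >= 0")
    if chelator_kd <= 0:
        raise ValueError("chelator K_d must be positive")
    if total_zn == 0:
        return 0.0
    if chelator_total == 0:
        return float(total_zn)
    b = chelator_total - total_zn + chelator_kd
    disc = b * b + 4.0 * chelator_kd * total_zn
    # numerically stable quadratic root
    if b >= 0:
        return 2.0 * chelator_kd * total_zn / (b + math.sqrt(disc))
    return 0.5 * (-b + math.sqrt(disc))


def total_zinc_for_free(
    free: float, chelator_total: float, chelator_kd: float
) -> float:
    """Total Zn2+ to add for a desired free concentration (inverse map)."""
    if free < 0 or chelator_total < 0:
        raise ValueError("concentrations must be >= 0")
    if chelator_kd <= 0:
        raise ValueError("chelator K_d must be positive")
    return free + chelator_total * free / (chelator_kd + free)


# ---------------------------------------------------------------------------
# Mass-action (quadratic depletion) fit


def mass_action_signal(c_zn, kd, f_u, f_b, protein_conc):
    """Law-of-mass-action signal with ligand depletion by the protein."""
    c = np.asarray(c_zn, dtype=float)
    p = protein_conc
    s = c + p + kd
    frac = (s - np.sqrt(np.maximum(s * s - 4.0 * p * c, 0.0))) / (2.0 * p)
    return f_u + (f_b - f_u) * frac


class MassActionIsotherm(BaseEstimator):
    """Least-squares (K_d, F_u, F_b) fit of a single-pH dilution series.

    Parameters
    ----------
    protein_conc : float
        Protein concentration during the titration (molar).

    Fitted attributes: ``kd_``, ``f_unbound_``, ``f_bound_``, ``residual_``
    (RMS), ``kd_stderr_`` (linearized standard error), ``tight_binding_``
    (True when the fitted K_d falls below the protein concentration — the
    assay is then in the titration rather than the binding regime and the
    K_d is poorly determined), and ``bound_fraction_`` (signal rescaled to
    [0, 1] by the fitted plateaus, for downstream inference).
    """

    def __init__(self, protein_conc=None):
        self.protein_conc = protein_conc

    def fit(self, X, y):
        if self.protein_conc is None or self.protein_conc <= 0:
            raise ValueError("protein_conc must be a positive concentration")
        c = np.asarray(X, dtype=float).ravel()
        f = np.asarray(y, dtype=float).ravel()
        pos = c[c > 0]
        if pos.size < 2 or pos.max() / pos.min() < 10.0:
            raise ValueError(
                "series must span at least one decade of concentration"
            )
        order = np.argsort(c)
        f_u0, f_b0 = float(f[order[0]]), float(f[order[-1]])
        kd0 = float(np.exp(np.mean(np.log(pos))))
        span = abs(f_b0 - f_u0) or 1.0

        def resid(theta):
            log_kd, fu, fb = theta
            return mass_action_signal(c, np.exp(log_kd), fu, fb, self.protein_conc) - f

        lb = [math.log(pos.min()) - 14.0, -np.inf, -np.inf]
        ub = [math.log(pos.max()) + 14.0, np.inf, np.inf]
        sol = least_squares(resid, [math.log(kd0), f_u0, f_b0], bounds=(lb, ub))
        for dk in (-3.0, 3.0):
            alt = least_squares(
                resid, [math.log(kd0) + dk, f_u0, f_b0], bounds=(lb, ub)
            )
            if alt.cost < sol.cost:
                sol = alt
        rms = float(np.sqrt(np.mean(sol.fun**2)))
        if rms > 0.25 * span:
            raise ValueError(
                f"mass-action fit failed: RMS residual {rms:.3g} vs signal "
                f"span {span:.3g}"
            )
        self.kd_ = float(np.exp(sol.x[0]))
        self.f_unbound_ = float(sol.x[1])
        self.f_bound_ = float(sol.x[2])
        self.residual_ = rms
        self.kd_stderr_ = self._kd_stderr(sol)
        self.tight_binding_ = bool(self.kd_ < self.protein_conc)
        denom = self.f_bound_ - self.f_unbound_
        self.bound_fraction_ = (f - self.f_unbound_) / (denom if denom else 1.0)
        return self

    def _kd_stderr(self, sol):
        # linearized covariance from the least-squares Jacobian
        m, p = sol.jac.shape
        if m <= p:
            return float("inf")
        dof = m - p
        s2 = 2.0 * sol.cost / dof
        try:
            cov = np.linalg.inv(sol.jac.T @ sol.jac) * s2
        except np.linalg.LinAlgError:
            return float("inf")
        sd_log = math.sqrt(max(cov[0, 0], 0.0))
        return float(np.exp(sol.x[0]) * sd_log)  # delta method on log Kd

    def predict(self, X):
        return mass_action_signal(
            np.asarray(X, dtype=float).ravel(),
            self.kd_,
            self.f_unbound_,
            self.f_bound_,
            self.protein_conc,
        )


# ---------------------------------------------------------------------------
# Hill isotherm fit


def hill_signal(c_zn, ec50, n, f_u, f_b):
    c = np.asarray(c_zn, dtype=float)
    with np.errstate(divide="ignore"):
        ratio = np.where(c > 0, (ec50 / np.where(c > 0, c, 1.0)) ** n, np.inf)
    return f_u + (f_b - f_u) / (1.0 + ratio)


class HillIsotherm(BaseEstimator):
    """Least-squares (EC50, n, F_u, F_b) Hill fit to assess cooperativity.

    Fitted attributes: ``ec50_``, ``hill_n_``, ``f_unbound_``, ``f_bound_``,
    ``residual_``, ``n_at_bounds_`` (True when the Hill coefficient pinned
    at a box bound, flagging an untrustworthy slope).
    """

    def __init__(self, n_max=6.0):
        self.n_max = n_max

    def fit(self, X, y):
        c = np.asarray(X, dtype=float).ravel()
        f = np.asarray(y, dtype=float).ravel()
        pos = c[c > 0]
        if pos.size < 2 or pos.max() / pos.min() < 10.0:
            raise ValueError(
                "series must span at least one decade of concentration"
            )
        order = np.argsort(c)
        f_u0, f_b0 = float(f[order[0]]), float(f[order[-1]])
        ec0 = float(np.exp(np.mean(np.log(pos))))
        span = abs(f_b0 - f_u0) or 1.0

        def resid(theta):
            log_ec, n, fu, fb = theta
            return hill_signal(c, np.exp(log_ec), n, fu, fb) - f

        lb = [math.log(pos.min()) - 14.0, 0.05, -np.inf, -np.inf]
        ub = [math.log(pos.max()) + 14.0, self.n_max, np.inf, np.inf]
        sol = least_squares(resid, [math.log(ec0), 1.0, f_u0, f_b0], bounds=(lb, ub))
        for n0 in (0.5, 2.0, 3.0):
            alt = least_squares(
                resid, [math.log(ec0), n0, f_u0, f_b0], bounds=(lb, ub)
            )
            if alt.cost < sol.cost:
                sol = alt
        rms = float(np.sqrt(np.mean(sol.fun**2)))
        if rms > 0.25 * span:
            raise ValueError(
                f"Hill fit failed: RMS residual {rms:.3g} vs span {span:.3g}"
            )
        self.ec50_ = float(np.exp(sol.x[0]))
        self.hill_n_ = float(sol.x[1])
        self.f_unbound_ = float(sol.x[2])
        self.f_bound_ = float(sol.x[3])
        self.residual_ = rms
        self.n_at_bounds_ = bool(
            self.hill_n_ <= lb[1] * (1 + 1e-6) or self.hill_n_ >= ub[1] * (1 - 1e-6)
        )
        return self

    def predict(self, X):
        return hill_signal(
            np.asarray(X, dtype=float).ravel(),
            self.ec50_,
            self.hill_n_,
            self.f_unbound_,
            self.f_bound_,
        )


# ---------------------------------------------------------------------------
# Dataset-level wrappers


def mass_action_fit(
    data: MSTDataset, ph: float, per_replicate: bool = False
):
    """Fit one pH series; replicates share parameters unless per_replicate."""
    series = data.series(ph)
    if per_replicate:
        return {
            rep: MassActionIsotherm(data.protein_conc_molar).fit(
                grp["c_zn_molar"], grp["signal"]
            )
            for rep, grp in series.groupby("replicate")
        }
    return MassActionIsotherm(data.protein_conc_molar).fit(
        series["c_zn_molar"], series["signal"]
    )


def hill_isotherm_fit(data: MSTDataset, ph: float, per_replicate: bool = False):
    series = data.series(ph)
    if per_replicate:
        return {
            rep: HillIsotherm().fit(grp["c_zn_molar"], grp["signal"])
            for rep, grp in series.groupby("replicate")
        }
    return HillIsotherm().fit(series["c_zn_molar"], series["signal"])


def affinity_table(data: MSTDataset, model: str = "mass-action") -> pd.DataFrame:
    """Per-pH affinity summary (K_d or EC50 with Hill n) across the dataset."""
    rows = []
    for ph in data.ph_values:
        if model == "mass-action":
            fit = mass_action_fit(data, ph)
            rows.append(
                {
                    "ph": ph,
                    "kd_molar": fit.kd_,
                    "kd_stderr_molar": fit.kd_stderr_,
                    "residual": fit.residual_,
                    "tight_binding": fit.tight_binding_,
                }
            )
        elif model == "hill":
            fit = hill_isotherm_fit(data, ph)
            rows.append(
                {
                    "ph": ph,
                    "ec50_molar": fit.ec50_,
                    "hill_n": fit.hill_n_,
                    "residual": fit.residual_,
                }
            )
        else:
            raise ValueError(f"unknown model {model!r}")
    return pd.DataFrame(rows)
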