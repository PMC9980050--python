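"""Titration analysis: lambda-series classification, microstate histograms,
Hill-Langmuir and coupled-titration pKa fits, and coupling energies.

Constant-pH simulations emit a continuous titration coordinate lambda in
[0, 1] per titratable residue per frame.  A frame counts as deprotonated
when lambda > 0.8 and protonated when lambda < 0.2; intermediate frames
are excluded from all counts.  Deprotonation fractions across a pH replica
ladder are fitted with the generalized Henderson-Hasselbalch (Hill)
equation

    S(pH) = 1 / (1 + 10^(n (pKa - pH)))

and strongly coupled residue pairs, which a single Hill curve cannot
describe, are fitted jointly through the two-proton coupled titration
model written with stepwise association constants

    N_prot(pH) = (10^(pK1-pH) + 2*10^(pK1+pK2-2 pH))
                 / (1 + 10^(pK1-pH) + 10^(pK1+pK2-2 pH)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator

from .model import LN10, SiteModel

#: the 30-replica pH ladder used for constant-pH titration sampling
PH_LADDER_30 = (
    1.5, 1.75, 2.0, 2.5, 2.75, 3.0, 3.25, 3.5, 3.75, 4.0,
    4.25, 4.5, 4.75, 5.0, 5.25, 5.5, 6.0, 6.5, 7.0, 7.5,
    8.0, 8.5, 8.75, 9.0, 9.5, 10.0, 10.25, 10.5, 11.0, 11.5,
)

DEFAULT_LO = 0.2
DEFAULT_HI = 0.8


@dataclass
class TitrationSeries:
    """Titration coordinates of one residue at one replica pH."""

    residue: str
    ph: float
    frames: np.ndarray

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.size < 1:
            raise ValueError("a titration series needs at least one frame")
        if np.any((self.frames < 0) | (self.frames > 1)):
            raise ValueError("titration coordinates must lie in [0, 1]")


@dataclass
class ClassifiedSeries:
    """Per-frame protonation labels and the resulting deprotonation fraction.

    ``labels``: +1 deprotonated, -1 protonated, 0 excluded (intermediate).
    ``s`` is NaN (and ``missing`` True) when no frame is classifiable.
    """

    labels: np.ndarray
    n_deprot: int
    n_prot: int
    s: float
    missing: bool


def classify_series(
    series, lo: float = DEFAULT_LO, hi: float = DEFAULT_HI
) -> ClassifiedSeries:
    """Classify lambda frames and compute S = N_deprot / (N_deprot + N_prot).

    Accepts a :class:`TitrationSeries` or a bare array of lambda values.
    Frames with lo <= lambda <= hi are excluded from the counts; if nothing
    remains the point is flagged missing rather than raising.
    """
    if not 0 < lo < hi < 1:
        raise ValueError(f"need 0 < lo < hi < 1, got lo={lo}, hi={hi}")
    lam = series.frames if isinstance(series, TitrationSeries) else np.asarray(
        series, dtype=float
    )
    labels = np.zeros(lam.shape, dtype=int)
    labels[lam > hi] = 1
    labels[lam < lo] = -1
    n_dep = int(np.sum(labels == 1))
    n_pro = int(np.sum(labels == -1))
    total = n_dep + n_pro
    if total == 0:
        return ClassifiedSeries(labels, 0, 0, float("nan"), True)
    return ClassifiedSeries(labels, n_dep, n_pro, n_dep / total, False)


@dataclass
class DeprotonationCurve:
    """Per-pH deprotonation fractions of one residue over a ladder."""

    residue: str
    ph: np.ndarray
    s: np.ndarray
    counted: np.ndarray

    def __post_init__(self):
        self.ph = np.asarray(self.ph, dtype=float)
        self.s = np.asarray(self.s, dtype=float)
        self.counted = np.asarray(self.counted, dtype=int)

    @property
    def usable(self) -> np.ndarray:
        return self.counted > 0


def deprotonation_curve(
    series_list: Sequence[TitrationSeries],
    lo: float = DEFAULT_LO,
    hi: float = DEFAULT_HI,
) -> DeprotonationCurve:
    """Build a deprotonation curve from one residue's series over a ladder."""
    names = {s.residue for s in series_list}
    if len(names) != 1:
        raise ValueError(f"series mix residues: {sorted(names)}")
    series_list = sorted(series_list, key=lambda s: s.ph)
    ph, s, counted = [], [], []
    for ser in series_list:
        c = classify_series(ser, lo, hi)
        ph.append(ser.ph)
        s.append(c.s)
        counted.append(c.n_deprot + c.n_prot)
    return DeprotonationCurve(names.pop(), ph, s, counted)


def microstate_histogram(
    lam: np.ndarray, lo: float = DEFAULT_LO, hi: float = DEFAULT_HI
) -> np.ndarray:
    """Histogram joint protonation microstates from per-frame lambdas.

    ``lam`` has shape (frames, R) with residues in model bit order (series
    from two protomers may simply be concatenated along the frame axis to
    pool sampling).  Frames where any residue is unclassifiable are
    dropped.  Returns probabilities over the 2^R protonation states,
    indexed little-endian (bit r set = residue r protonated).
    """
    if not 0 < lo < hi < 1:
        raise ValueError(f"need 0 < lo < hi < 1, got lo={lo}, hi={hi}")
    lam = np.atleast_2d(np.asarray(lam, dtype=float))
    n_frames, R = lam.shape
    prot = lam < lo
    deprot = lam > hi
    usable = np.all(prot | deprot, axis=1)
    if not np.any(usable):
        raise ValueError("no frame has all residues classifiable")
    bits = prot[usable].astype(int)
    idx = bits @ (1 << np.arange(R))
    counts = np.bincount(idx, minlength=1 << R)
    return counts / counts.sum()


# ---------------------------------------------------------------------------
# Hill-Langmuir fit


def hill_langmuir(ph, pka, n=1.0):
    """Deprotonation fraction S(pH) of the generalized HH (Hill) equation."""
    ph = np.asarray(ph, dtype=float)
    return 1.0 / (1.0 + 10.0 ** (n * (pka - ph)))


class HillLangmuirCurve(BaseEstimator):
    """Least-squares fit of a deprotonation curve to the Hill equation.

    Fitted attributes: ``pka_``, ``hill_``, ``residual_`` (root-mean-square
    residual).  Deterministic: starting values follow a fixed rule (pKa at
    the pH whose S is nearest 0.5, n = 1) with a fixed 3x3 restart grid if
    the first residual exceeds ``restart_tol``.
    """

    def __init__(self, restart_tol=1e-6, saturation_margin=0.02):
        self.restart_tol = restart_tol
        self.saturation_margin = saturation_margin

    def fit(self, X, y):
        ph = np.asarray(X, dtype=float).ravel()
        s = np.asarray(y, dtype=float).ravel()
        ok = np.isfinite(ph) & np.isfinite(s)
        ph, s = ph[ok], s[ok]
        if ph.size < 4:
            raise ValueError("need at least 4 usable titration points")
        m = self.saturation_margin
        if np.all(s < m) or np.all(s > 1 - m):
            raise ValueError(
                "titration curve is saturated (all S near 0 or 1): "
                "pKa is unidentifiable on this ladder"
            )
        pka0 = float(ph[np.argmin(np.abs(s - 0.5))])
        lb = [ph.min() - 10.0, 1e-3]
        ub = [ph.max() + 10.0, 20.0]

        def resid(theta):
            return hill_langmuir(ph, *theta) - s

        best = least_squares(resid, [pka0, 1.0], bounds=(lb, ub))
        if 0.5 * np.sum(best.fun**2) > self.restart_tol:
            for dp in (-1.0, 0.0, 1.0):
                for n0 in (0.5, 1.0, 2.0):
                    x0 = [np.clip(pka0 + dp, lb[0], ub[0]), n0]
                    sol = least_squares(resid, x0, bounds=(lb, ub))
                    if sol.cost < best.cost:
                        best = sol
        self.pka_ = float(best.x[0])
        self.hill_ = float(best.x[1])
        self.residual_ = float(np.sqrt(np.mean(best.fun**2)))
        return self

    def predict(self, X):
        return hill_langmuir(np.asarray(X, dtype=float).ravel(), self.pka_, self.hill_)


def hill_langmuir_fit(curve: DeprotonationCurve) -> HillLangmuirCurve:
    """Fit a deprotonation curve; skips flagged-missing points."""
    ok = curve.usable
    return HillLangmuirCurve().fit(curve.ph[ok], curve.s[ok])


def aggregate_protomer_pka(pka_a: float, pka_b: float) -> Tuple[float, float]:
    """Mean and half-difference of two protomer pKa estimates.

    The two protomers titrate independently, so their per-residue pKa's
    are averaged and the reported error is |a - b| / 2.
    """
    if not (math.isfinite(pka_a) and math.isfinite(pka_b)):
        raise ValueError("protomer pKa values must be finite")
    mean = 0.5 * (pka_a + pka_b)
    return mean, abs(pka_a - mean)


# ---------------------------------------------------------------------------
# Coupled titration model


def coupled_titration_nprot(ph, pk1, pk2):
    """Total protons bound by a coupled two-site system.

    ``pk1`` is the stepwise pKa for binding the first proton to the empty
    pair, ``pk2`` for the second; the curve runs from 2 at low pH to 0 at
    high pH.  For two independent identical sites with microscopic pKa p
    the statistical factors give pk1 = p + log10 2, pk2 = p - log10 2.
    """
    ph = np.asarray(ph, dtype=float)
    # overflow-safe via log-space terms
    a = (pk1 - ph) * LN10
    b = (pk1 + pk2 - 2.0 * ph) * LN10
    top = np.logaddexp(a, math.log(2.0) + b)
    bot = np.logaddexp(0.0, np.logaddexp(a, b))
    return np.exp(top - bot)


class CoupledTitrationCurve(BaseEstimator):
    """Least-squares fit of N_prot(pH) to the coupled titration model.

    Fitted attributes ``pk1_`` (first proton), ``pk2_`` (second proton),
    ``residual_``.  In the strongly anti-cooperative limit pk1 and pk2 are
    the two separated effective pKa's of the pair (pk1 >= pk2); a fit with
    pk1_ < pk2_ indicates cooperative (steep) joint titration.
    """

    def __init__(self, restart_tol=1e-6, flat_margin=0.1):
        self.restart_tol = restart_tol
        self.flat_margin = flat_margin

    def fit(self, X, y):
        ph = np.asarray(X, dtype=float).ravel()
        n = np.asarray(y, dtype=float).ravel()
        ok = np.isfinite(ph) & np.isfinite(n)
        ph, n = ph[ok], n[ok]
        if ph.size < 5:
            raise ValueError("need at least 5 usable points")
        if np.any((n < -1e-6) | (n > 2 + 1e-6)):
            raise ValueError("N_prot values must lie in [0, 2]")
        if n.max() - n.min() < self.flat_margin:
            raise ValueError("flat N_prot curve: pK1/pK2 are unidentifiable")
        mid = float(ph[np.argmin(np.abs(n - 1.0))])
        lb = [ph.min() - 15.0, ph.min() - 15.0]
        ub = [ph.max() + 15.0, ph.max() + 15.0]

        def resid(theta):
            return coupled_titration_nprot(ph, *theta) - n

        best = least_squares(resid, [mid + 1.0, mid - 1.0], bounds=(lb, ub))
        if 0.5 * np.sum(best.fun**2) > self.restart_tol:
            for d1 in (0.0, 2.0, 4.0):
                for d2 in (0.0, -2.0, -4.0):
                    sol = least_squares(
                        resid, [mid + d1, mid + d2 - 0.5], bounds=(lb, ub)
                    )
                    if sol.cost < best.cost:
                        best = sol
        self.pk1_ = float(best.x[0])
        self.pk2_ = float(best.x[1])
        self.residual_ = float(np.sqrt(np.mean(best.fun**2)))
        return self

    def predict(self, X):
        return coupled_titration_nprot(
            np.asarray(X, dtype=float).ravel(), self.pk1_, self.pk2_
        )


def coupled_titration_fit(ph, nprot) -> CoupledTitrationCurve:
    return CoupledTitrationCurve().fit(ph, nprot)


# ---------------------------------------------------------------------------
# Coupling energy


@dataclass(frozen=True)
class CouplingEnergy:
    """Protonation coupling between two residues in a fixed context.

    W (pKa units) is the drop in residue r's pKa caused by protonating
    residue s: W > 0 is anti-cooperative, W < 0 cooperative.  On a
    consistent potential graph W is symmetric in (r, s) by cycle closure.
    """

    w: float
    residue_r: str
    residue_s: str
    context: Tuple[Tuple[str, int], ...]
    zn_bound: bool = False


def coupling_energy(
    source,
    residue_r: str,
    residue_s: str,
    context: Optional[Mapping[str, int]] = None,
    zn_bound: bool = False,
) -> CouplingEnergy:
    """W = pKa(r | s deprotonated) - pKa(r | s protonated).

    ``source`` is a :class:`SiteModel` or a mapping
    ``{(residue, s_occupancy): pKa}`` giving the four microscopic pKa's of
    the 2x2 sub-lattice.  ``context`` fixes the occupancy of the remaining
    residues (all deprotonated by default).
    """
    if isinstance(source, SiteModel):
        names = set(source.residue_names)
        for r in (residue_r, residue_s):
            if r not in names:
                raise ValueError(f"unknown residue {r!r}")
        ctx = {n: 0 for n in names - {residue_r, residue_s}}
        if context:
            ctx.update({k: int(v) for k, v in context.items() if k in ctx})
        w = source.implied_pka(
            residue_r, {**ctx, residue_s: 0}, zn_bound
        ) - source.implied_pka(residue_r, {**ctx, residue_s: 1}, zn_bound)
        frozen = tuple(sorted(ctx.items()))
        return CouplingEnergy(float(w), residue_r, residue_s, frozen, zn_bound)
    try:
        w = source[(residue_r, 0)] - source[(residue_r, 1)]
    except KeyError as err:
        raise ValueError(f"missing microscopic pKa: {err}") from None
    frozen = tuple(sorted((context or {}).items()))
    return CouplingEnergy(float(w), residue_r, residue_s, frozen, zn_bound)


# ---------------------------------------------------------------------------
# Effective pKa's of a site model


@dataclass
class EffectivePka:
    residue: str
    pka: float
    hill: Optional[float]
    residual: float
    route: str  # "hill" or "coupled"
    partner: Optional[str] = None


def effective_pkas(
    model: SiteModel,
    ph_ladder: Sequence[float] = PH_LADDER_30,
    x_molar: float = 1e-20,
    coupled_pairs: Optional[Sequence[Tuple[str, str]]] = None,
    hill_residual_threshold: float = 0.02,
) -> Dict[str, EffectivePka]:
    """Effective (macroscopic) pKa per residue under metal-free conditions.

    Deprotonation fractions are generated from the model on the pH ladder
    at a vanishing ligand concentration and fitted per residue with the
    Hill equation.  For a designated pair (default: residues sharing a
    tie_group) whose individual Hill fits are poor, the joint proton count
    N_prot = (1 - S_r) + (1 - S_s) is fitted with the coupled titration
    model instead, yielding two effective pKa's (assigned pk1 to the first
    member, pk2 to the second; the labels are interchangeable).
    """
    ph = np.asarray(ph_ladder, dtype=float)
    S = {name: np.empty(ph.size) for name in model.residue_names}
    for k, p in enumerate(ph):
        frac = model.deprotonation_fractions(p, x_molar)
        for name in S:
            S[name][k] = frac[name]

    def fit_one(name) -> HillLangmuirCurve:
        # a residue whose transition falls outside the ladder saturates
        # there; refit on a ladder centered on its model-generated midpoint
        try:
            return HillLangmuirCurve().fit(ph, S[name])
        except ValueError:
            wide = np.arange(-12.0, 24.0, 0.5)
            s_wide = np.array(
                [
                    model.deprotonation_fractions(p, x_molar)[name]
                    for p in wide
                ]
            )
            mid = wide[np.argmin(np.abs(s_wide - 0.5))]
            local = np.arange(mid - 3.0, mid + 3.01, 0.25)
            s_local = np.array(
                [
                    model.deprotonation_fractions(p, x_molar)[name]
                    for p in local
                ]
            )
            return HillLangmuirCurve().fit(local, s_local)

    if coupled_pairs is None:
        groups: Dict[str, list] = {}
        for r in model.residues:
            if r.tie_group:
                groups.setdefault(r.tie_group, []).append(r.name)
        coupled_pairs = [tuple(v) for v in groups.values() if len(v) == 2]
    paired = {n for pair in coupled_pairs for n in pair}

    out: Dict[str, EffectivePka] = {}
    for name in model.residue_names:
        if name in paired:
            continue
        f = fit_one(name)
        out[name] = EffectivePka(name, f.pka_, f.hill_, f.residual_, "hill")

    for r, s in coupled_pairs:
        fr = fit_one(r)
        fs = fit_one(s)
        if max(fr.residual_, fs.residual_) <= hill_residual_threshold:
            out[r] = EffectivePka(r, fr.pka_, fr.hill_, fr.residual_, "hill")
            out[s] = EffectivePka(s, fs.pka_, fs.hill_, fs.residual_, "hill")
            continue
        nprot = (1.0 - S[r]) + (1.0 - S[s])
        cf = CoupledTitrationCurve().fit(ph, nprot)
        out[r] = EffectivePka(r, cf.pk1_, None, cf.residual_, "coupled", s)
        out[s] = EffectivePka(s, cf.pk2_, None, cf.residual_, "coupled", r)
    return out
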