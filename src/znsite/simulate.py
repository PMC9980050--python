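"""Synthetic datasets from ground-truth microstate models.

Two generators make every pipeline stage testable without external data:

* binding titrations — per-pH dilution series whose signal follows the
  law of mass action at the ground-truth model's apparent K_d, plus
  Gaussian noise, mimicking a thermophoresis experiment;
* titration-coordinate series — per-frame microstates drawn from the
  ground-truth Boltzmann distribution across a pH replica ladder, emitted
  as lambda values in the classified regions (with an optional fraction of
  intermediate frames to exercise the exclusion rule), mimicking
  constant-pH simulation output.

The reference fixtures encode the two experimentally characterized binding
sites of a zinc/proton antiporter: a high-affinity transport site with a
strongly cooperative His/Asp pair ("site A"), and a lower-affinity loop
site with a symmetric, strongly anti-cooperative histidine pair
("site B").  Fixture pKa's and affinities are taken from published
refinement results for that transporter and are documented qualitative
anchors, not quantities this package can re-derive from scratch.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence

import numpy as np
import pandas as pd

from .isotherm import MSTDataset, mass_action_signal
from .model import SiteModel, pairwise_coupled_site_model
from .titration import PH_LADDER_30, TitrationSeries

#: default pH ladder of the binding-titration experiments
MST_PH_LADDER = (5.6, 6.0, 6.5, 7.0, 7.4)


@dataclass
class GeneratorSpec:
    """Study-condition settings shared by the generators.

    The defaults are the conditions of the emulated experiments: a
    16-point 2-fold dilution series auto-centered on the apparent K_d,
    three replicates with Gaussian signal noise, 50 nM protein; and for
    titration sampling the 30-replica pH ladder.
    """

    model: SiteModel
    seed: int
    ph_ladder: Sequence[float] = MST_PH_LADDER
    points_per_series: int = 16
    dilution_factor: float = 2.0
    decades_above_kd: float = 2.4  # c_max = kd * 10**decades_above_kd
    noise_sd: float = 0.02
    n_replicates: int = 3
    protein_conc_molar: float = 50e-9
    frames_per_ph: int = 2000
    titration_ladder: Sequence[float] = PH_LADDER_30
    intermediate_fraction: float = 0.0

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("a seed is mandatory")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be >= 0")


def generate_mst_dataset(spec: GeneratorSpec) -> MSTDataset:
    """Noisy per-pH dilution series from the ground-truth apparent K_d.

    Signal plateaus are 0 (unbound) and 1 (bound); the concentration
    design is a geometric dilution centered so the series brackets the
    apparent K_d by about two decades on the high side.
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    for ph in spec.ph_ladder:
        kd = spec.model.apparent_kd(ph)
        c_max = kd * 10.0 ** spec.decades_above_kd
        conc = c_max / spec.dilution_factor ** np.arange(spec.points_per_series)
        clean = mass_action_signal(conc, kd, 0.0, 1.0, spec.protein_conc_molar)
        for rep in range(spec.n_replicates):
            noisy = clean + rng.normal(0.0, spec.noise_sd, size=clean.shape)
            for c, s in zip(conc, noisy):
                rows.append((ph, c, s, rep))
    points = pd.DataFrame(
        rows, columns=["ph", "c_zn_molar", "signal", "replicate"]
    )
    return MSTDataset(points, spec.protein_conc_molar)


@dataclass
class TitrationSample:
    """Per-pH lambda matrices drawn from a ground-truth model."""

    residues: tuple
    ph_ladder: tuple
    lambdas: Dict[float, np.ndarray]  # ph -> (frames, R)

    def frame_matrix(self, ph: float) -> np.ndarray:
        return self.lambdas[ph]

    def series(self, residue: str) -> List[TitrationSeries]:
        bit = self.residues.index(residue)
        return [
            TitrationSeries(residue, ph, self.lambdas[ph][:, bit])
            for ph in self.ph_ladder
        ]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for ph in self.ph_ladder:
            lam = self.lambdas[ph]
            for f in range(lam.shape[0]):
                for b, name in enumerate(self.residues):
                    rows.append((ph, name, f, lam[f, b]))
        return pd.DataFrame(rows, columns=["ph", "residue", "frame", "lambda"])


def generate_titration_series(spec: GeneratorSpec) -> TitrationSample:
    """Per-frame microstates sampled from the metal-free distribution.

    At each ladder pH a microstate is drawn per frame from the
    ground-truth protonation-state probabilities (ligand concentration
    1e-20 M); each residue's lambda is emitted as 0.9 + 0.1 U(0,1) when
    deprotonated and 0.1 U(0,1) when protonated.  A configurable fraction
    of (frame, residue) entries is replaced by an intermediate lambda in
    the excluded band [0.2, 0.8].
    """
    rng = np.random.default_rng(spec.seed)
    model = spec.model
    R = model.n_residues
    names = model.residue_names
    out: Dict[float, np.ndarray] = {}
    for ph in spec.titration_ladder:
        p = model.unbound_probabilities(ph, 1e-20)
        states = rng.choice(p.size, size=spec.frames_per_ph, p=p)
        bits = (states[:, None] >> np.arange(R)) & 1  # 1 = protonated
        u = rng.random(bits.shape)
        lam = np.where(bits == 1, 0.1 * u, 0.9 + 0.1 * u)
        if spec.intermediate_fraction > 0:
            mask = rng.random(bits.shape) < spec.intermediate_fraction
            lam = np.where(mask, 0.2 + 0.6 * rng.random(bits.shape), lam)
        out[ph] = lam
    return TitrationSample(tuple(names), tuple(spec.titration_ladder), out)


# ---------------------------------------------------------------------------
# Reference fixtures


def site_a_model() -> SiteModel:
    """Transport-site-like model: 4 residues, cooperative His/Asp pair.

    The His155/Asp159 pair couples cooperatively (W = -5 pKa units):
    microscopic pKa 5.3 for the first proton onto the pair and 10.3 for
    the second, so the joint titration is steep with an effective midpoint
    near 7.8 and the singly protonated state is suppressed.  Asp51
    titrates at 6.51 and recruits a third proton below pH ~6; Asp47 stays
    deprotonated throughout.  The metal-bound branch is fully
    deprotonation-favoring (bound pKa 0), and the intrinsic binding free
    energy -21.94 kBT places the apparent K_d near 16 nM at pH 7.
    """
    return pairwise_coupled_site_model(
        pkas={"D47": -0.20, "D51": 6.51, "H155": 5.3, "D159": 5.3},
        coupling={("H155", "D159"): -5.0},
        bound_pkas={"D47": 0.0, "D51": 0.0, "H155": 0.0, "D159": 0.0},
        dg0_bind=-21.94,
    )


def site_b_model() -> SiteModel:
    """Loop-site-like model: 3 residues, tied anti-cooperative His pair.

    His73/His77 are symmetric (shared tie group) with microscopic pKa
    12.07 and a strong anti-cooperative coupling W = +6.5 pKa units,
    giving separated effective pKa's near 12.4 and 5.3 (statistical
    factors included).  Asp70 titrates at 1.12.  The intrinsic binding
    free energy -26.04 kBT places the apparent K_d near 1.2 uM at pH 7.
    """
    return pairwise_coupled_site_model(
        pkas={"D70": 1.12, "H73": 12.07, "H77": 12.07},
        coupling={("H73", "H77"): 6.5},
        bound_pkas={"D70": 0.0, "H73": 0.0, "H77": 0.0},
        dg0_bind=-26.04,
        tie_groups={"his_pair": ["H73", "H77"]},
    )


def two_residue_model() -> SiteModel:
    """Small ground truth for parameter-recovery simulations.

    Both titration midpoints (7.0 and 6.0) lie inside the experimental pH
    window 5.6-7.4 so the binding data can constrain them; the bound
    branch is deprotonation-favoring and the intrinsic binding free energy
    -18.4 kBT puts the apparent K_d in the low-nanomolar range at pH 7.
    """
    return pairwise_coupled_site_model(
        pkas={"R1": 7.0, "R2": 6.0},
        bound_pkas={"R1": 2.0, "R2": 2.0},
        dg0_bind=-18.4,
    )


def reference_fixtures() -> Dict[str, SiteModel]:
    """Named ground-truth models for tests and examples."""
    return {
        "siteA-like": site_a_model(),
        "siteB-like": site_b_model(),
        "two-residue": two_residue_model(),
    }
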