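"""Shared fixtures and the independent brute-force oracle.

The oracle evaluates equilibrium observables of a pairwise-interaction
protonation/binding Hamiltonian by explicit state enumeration in pure
Python, without touching the package's potential-graph projection or its
vectorized evaluation paths.
"""

import math

import numpy as np
import pytest

LN10 = math.log(10.0)


def brute_force_observables(pkas, ph, x, dg0=None, coupling=None, bound_pkas=None):
    """Explicit Boltzmann enumeration of a pairwise-coupled site.

    Energies (kBT): protonating residue r adds ln10*(pH - pKa_r); a doubly
    protonated coupled pair (r, s) adds ln10*W_rs; the metal-bound branch
    adds dg0 - ln(x) and uses ``bound_pkas``.  Returns a dict with
    probabilities (canonical state order), bound fraction, per-residue
    deprotonation fractions, and mean bound protons.
    """
    names = list(pkas)
    R = len(names)
    coupling = dict(coupling or {})
    W = {}
    for (a, b), w in coupling.items():
        W[(a, b)] = w
        W[(b, a)] = w
    bound = dict(bound_pkas) if bound_pkas is not None else dict(pkas)
    branches = (0,) if dg0 is None else (0, 1)
    states, energies = [], []
    for zn in branches:
        base = bound if zn else pkas
        for k in range(1 << R):
            bits = [(k >> i) & 1 for i in range(R)]
            e = 0.0
            for i, n in enumerate(names):
                if bits[i]:
                    e += LN10 * (ph - base[n])
            for i in range(R):
                for j in range(i + 1, R):
                    if bits[i] and bits[j]:
                        e += LN10 * W.get((names[i], names[j]), 0.0)
            if zn:
                e += dg0 - math.log(x)
            states.append((tuple(bits), zn))
            energies.append(e)
    emin = min(energies)
    weights = [math.exp(-(e - emin)) for e in energies]
    z_tot = math.fsum(weights)
    probs = [w / z_tot for w in weights]
    bound_frac = math.fsum(
        p for p, (_, zn) in zip(probs, states) if zn
    )
    deprot = {
        n: math.fsum(
            p for p, (bits, _) in zip(probs, states) if bits[i] == 0
        )
        for i, n in enumerate(names)
    }
    nprot = math.fsum(
        p * sum(bits) for p, (bits, _) in zip(probs, states)
    )
    return {
        "probabilities": np.array(probs),
        "bound_fraction": bound_frac,
        "deprotonation": deprot,
        "mean_protons": nprot,
    }


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_small_site(rng, n_residues, with_zn=True, with_coupling=True):
    """Random pairwise-coupled parameter set for a small site."""
    names = [f"r{i}" for i in range(n_residues)]
    pkas = {n: float(rng.uniform(3.0, 10.0)) for n in names}
    bound = {n: float(rng.uniform(0.0, 7.0)) for n in names}
    coupling = {}
    if with_coupling and n_residues >= 2:
        for i in range(n_residues):
            for j in range(i + 1, n_residues):
                if rng.random() < 0.6:
                    coupling[(names[i], names[j])] = float(rng.uniform(-3, 3))
    dg0 = float(rng.uniform(-25.0, -10.0)) if with_zn else None
    return {
        "pkas": pkas,
        "bound_pkas": bound if with_zn else None,
        "coupling": coupling,
        "dg0": dg0,
    }
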