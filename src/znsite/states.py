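"""Microstate enumeration for metal binding sites with titratable residues.

A binding site with R titratable residues and one metal-occupancy flag has
2^R protonation microstates in the metal-free branch and 2^R mirrored states
in the metal-bound branch.  States are labelled S0..S(2^R - 1) within each
branch; proton occupancy bits are little-endian with respect to the residue
list, so state S0 is the fully deprotonated state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

MAX_RESIDUES = 12


@dataclass(frozen=True)
class Residue:
    """A titratable residue of a binding site.

    Parameters
    ----------
    name : str
        Short identifier, e.g. ``"D51"`` or ``"H155"``.
    kind : str, optional
        ``"acid"`` or ``"base"``; retained for reporting only, it affects
        nothing numerically.
    tie_group : str, optional
        Residues sharing a tie_group are constrained to identical
        microscopic parameters during inference (symmetrized pair).
    """

    name: str
    kind: Optional[str] = None
    tie_group: Optional[str] = None


@dataclass(frozen=True)
class Microstate:
    """One protonation pattern x metal-occupancy flag.

    ``protons`` holds one occupancy bit per residue (1 = protonated) in
    residue-list order; ``index`` is the canonical position in the full
    enumeration (unbound block first).
    """

    index: int
    protons: tuple
    zn_bound: bool
    n_protons: int = field(init=False)

    def __post_init__(self):
        object.__setattr__(self, "n_protons", sum(self.protons))

    @property
    def label(self) -> str:
        """Branch-local label S0..S(2^R-1), suffixed ':Zn' when bound."""
        k = sum(b << i for i, b in enumerate(self.protons))
        return f"S{k}:Zn" if self.zn_bound else f"S{k}"


def check_residues(residues: Sequence[Residue]) -> None:
    names = [r.name for r in residues]
    if len(set(names)) != len(names):
        raise ValueError(f"residue names must be unique, got {names}")
    if len(residues) > MAX_RESIDUES:
        raise ValueError(
            f"{len(residues)} residues would enumerate 2^{len(residues) + 1} "
            f"states; at most {MAX_RESIDUES} residues are supported"
        )


def proton_bits(k: int, n_residues: int) -> tuple:
    """Little-endian proton occupancy bits of branch-local state index k."""
    return tuple((k >> i) & 1 for i in range(n_residues))


def enumerate_microstates(
    residues: Sequence[Residue], has_zn_site: bool = True
) -> list:
    """Enumerate all microstates in canonical order.

    Returns 2^R states without a metal site and 2^(R+1) with one: the
    unbound block first (proton bits as a little-endian binary integer),
    then the mirrored bound block.
    """
    check_residues(residues)
    R = len(residues)
    n_block = 1 << R
    states = [
        Microstate(k, proton_bits(k, R), False) for k in range(n_block)
    ]
    if has_zn_site:
        states += [
            Microstate(n_block + k, proton_bits(k, R), True)
            for k in range(n_block)
        ]
    return states


def state_index(protons: Sequence[int], zn_bound: bool, n_residues: int) -> int:
    """Canonical index of the state with the given occupancy pattern."""
    k = sum((int(b) & 1) << i for i, b in enumerate(protons))
    return k + (1 << n_residues) * int(zn_bound)
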