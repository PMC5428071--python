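"""Coarse-grained C-alpha chain: geometry, energies, conformational bookkeeping.

The chain is a bead-spring homopeptide in reduced units (sigma = kBT = xi0 = 1,
time unit tau0 = sigma^2 * xi0 / kBT).  Each residue is one bead.  The potential
energy contains

* harmonic bonds about ``sigma``,
* harmonic bending about ``theta0``,
* a three-fold hindered-rotation term ``V_dih = eps*(1 - cos 3*phi)/2`` whose
  three minima sit at phi = 0, +2*pi/3, -2*pi/3 and whose barriers equal
  ``eps``,
* a purely repulsive, truncated-and-shifted ``r**-12`` excluded-volume term
  acting between beads at least four bonds apart (closer pairs are governed by
  the bonded terms).

Conformations are plain ``(N, 3)`` float arrays; :func:`check_conformation`
asserts their invariants.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict, replace

import numpy as np

__all__ = [
    "WELL_CENTERS",
    "CGChainConfig",
    "EnergyBreakdown",
    "ChainConstructionError",
    "build_chain",
    "check_conformation",
    "bond_lengths",
    "bend_angles",
    "dihedral_angles",
    "well_of",
    "potential_energy",
]

#: Angular positions (radians) of the three minima of eps*(1 - cos 3*phi)/2.
#: Well labels 0, 1, 2 used throughout the package refer to these centers.
WELL_CENTERS = np.array([0.0, 2.0 * np.pi / 3.0, -2.0 * np.pi / 3.0])

#: Minimum sequence separation |i - j| for the excluded-volume pair sum.
EV_MIN_SEPARATION = 4


class ChainConstructionError(RuntimeError):
    """Raised when rejection sampling cannot place a bead without a clash."""


@dataclass(frozen=True)
class CGChainConfig:
    """Physical parameters of the bead-spring chain, in reduced units.

    Parameters
    ----------
    N : int
        Number of beads (one per residue); at least 4.
    sigma : float
        Equilibrium bond length; the reduced length unit.
    k_bond : float
        Harmonic bond constant (kBT / sigma**2).
    theta0 : float
        Equilibrium bending angle at each bead (radians).  The default,
        100 degrees, is calibrated so that the full model (bending plus
        excluded volume) has a Kuhn length of about three bond lengths,
        matching the stiffness of real polypeptides.
    k_bend : float
        Harmonic bending constant (kBT / rad**2).
    eps_dih : float
        Dihedral barrier height (kBT); zero switches hindered rotation off.
    ev_strength : float
        Excluded-volume prefactor (kBT).
    ev_cutoff : float
        Excluded-volume cutoff distance (sigma); zero disables the term.
    xi0 : float
        Per-bead friction coefficient.
    kBT : float
        Thermal energy (reduced).
    dt : float
        Langevin integration timestep (tau0).
    """

    N: int = 20
    sigma: float = 1.0
    k_bond: float = 200.0
    theta0: float = np.deg2rad(100.0)
    k_bend: float = 20.0
    eps_dih: float = 0.0
    ev_strength: float = 1.0
    ev_cutoff: float = 2.0
    xi0: float = 1.0
    kBT: float = 1.0
    dt: float = 5.0e-4

    def __post_init__(self) -> None:
        if self.N < 4:
            raise ValueError(f"need N >= 4 beads, got {self.N}")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.eps_dih < 0:
            raise ValueError("eps_dih must be non-negative")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.xi0 <= 0:
            raise ValueError("xi0 must be positive")
        if self.kBT <= 0:
            raise ValueError("kBT must be positive")
        if self.ev_cutoff < 0:
            raise ValueError("ev_cutoff must be non-negative")
        if not 0 < self.theta0 < np.pi:
            raise ValueError("theta0 must lie in (0, pi)")

    @property
    def n_dihedrals(self) -> int:
        return self.N - 3

    @property
    def tau0(self) -> float:
        """Monomer diffusion time sigma^2 * xi0 / kBT (the reduced time unit)."""
        return self.sigma**2 * self.xi0 / self.kBT

    def ideal(self) -> "CGChainConfig":
        """Phantom-chain variant: excluded volume and dihedral barrier off."""
        return replace(self, eps_dih=0.0, ev_strength=0.0)

    def gaussian(self) -> "CGChainConfig":
        """Gaussian-chain variant: phantom with the bending stiffness off as
        well, so only the harmonic bonds remain (the discrete analogue of an
        ideal Gaussian chain, for Rouse-theory reference runs)."""
        return replace(self, eps_dih=0.0, ev_strength=0.0, k_bend=0.0)

    def to_dict(self) -> dict:
        d = asdict(self)
        return {k: (int(v) if k == "N" else float(v)) for k, v in d.items()}

    @classmethod
    def from_dict(cls, d: dict) -> "CGChainConfig":
        return cls(**d)


@dataclass(frozen=True)
class EnergyBreakdown:
    """Per-term potential energy of a conformation (kBT)."""

    bond: float
    bend: float
    dihedral: float
    excluded_volume: float

    @property
    def total(self) -> float:
        return self.bond + self.bend + self.dihedral + self.excluded_volume


def check_conformation(positions: np.ndarray, N: int | None = None) -> np.ndarray:
    """Validate a conformation array and return it as float64 ``(N, 3)``."""
    pos = np.asarray(positions, dtype=float)
    if pos.ndim != 2 or pos.shape[1] != 3:
        raise ValueError(f"conformation must have shape (N, 3), got {pos.shape}")
    if N is not None and pos.shape[0] != N:
        raise ValueError(f"expected {N} beads, got {pos.shape[0]}")
    if not np.all(np.isfinite(pos)):
        raise ValueError("conformation contains non-finite coordinates")
    if np.any(bond_lengths(pos) <= 0):
        raise ValueError("zero-length bond in conformation")
    return pos


def bond_lengths(positions: np.ndarray) -> np.ndarray:
    """Lengths of the N-1 consecutive bonds."""
    d = np.diff(np.asarray(positions, dtype=float), axis=0)
    return np.linalg.norm(d, axis=-1)


def bend_angles(positions: np.ndarray) -> np.ndarray:
    """Bending angles (radians) at the N-2 interior beads.

    The angle at bead ``i`` is measured between the bonds to beads ``i-1``
    and ``i+1``; a straight chain has angle pi.
    """
    pos = np.asarray(positions, dtype=float)
    u = pos[:-2] - pos[1:-1]
    v = pos[2:] - pos[1:-1]
    c = np.einsum("ij,ij->i", u, v)
    c /= np.linalg.norm(u, axis=1) * np.linalg.norm(v, axis=1)
    return np.arccos(np.clip(c, -1.0, 1.0))


def dihedral_angles(positions: np.ndarray) -> np.ndarray:
    """Torsion angles (radians, in (-pi, pi]) of the N-3 consecutive quadruples.

    IUPAC sign convention: looking along the central bond, a clockwise
    rotation of the far bond relative to the near bond is positive.  Works on
    a single conformation ``(N, 3)`` or a stack of frames ``(T, N, 3)``; in
    the latter case returns ``(T, N-3)``.
    """
    pos = np.asarray(positions, dtype=float)
    single = pos.ndim == 2
    if single:
        pos = pos[None]
    b1 = pos[:, 1:-2] - pos[:, :-3]
    b2 = pos[:, 2:-1] - pos[:, 1:-2]
    b3 = pos[:, 3:] - pos[:, 2:-1]
    m = np.cross(b1, b2)
    n = np.cross(b2, b3)
    b2n = np.linalg.norm(b2, axis=-1)
    if np.any(np.linalg.norm(m, axis=-1) < 1e-12 * b2n * np.linalg.norm(b1, axis=-1)) or np.any(
        np.linalg.norm(n, axis=-1) < 1e-12 * b2n * np.linalg.norm(b3, axis=-1)
    ):
        raise ValueError("undefined torsion: three consecutive beads are collinear")
    y = np.einsum("...i,...i->...", np.cross(m, n), b2) / b2n
    x = np.einsum("...i,...i->...", m, n)
    phi = np.arctan2(y, x)
    return phi[0] if single else phi


def well_of(phi: np.ndarray) -> np.ndarray:
    """Map dihedral angles to the index (0, 1, 2) of the nearest well center."""
    phi = np.asarray(phi, dtype=float)
    d = np.abs(np.angle(np.exp(1j * (phi[..., None] - WELL_CENTERS))))
    return np.argmin(d, axis=-1)


def _ev_pair_energy(r2: np.ndarray, config: CGChainConfig) -> np.ndarray:
    """Truncated-and-shifted repulsive r^-12 pair energies for squared distances."""
    s6 = (config.sigma**2 / r2) ** 3
    shift = (config.sigma / config.ev_cutoff) ** 12
    return config.ev_strength * (s6 * s6 - shift)


def potential_energy(positions: np.ndarray, config: CGChainConfig) -> EnergyBreakdown:
    """Potential energy of a conformation, broken down by term."""
    pos = check_conformation(positions, config.N)
    bl = bond_lengths(pos)
    e_bond = 0.5 * config.k_bond * float(np.sum((bl - config.sigma) ** 2))
    th = bend_angles(pos)
    e_bend = 0.5 * config.k_bend * float(np.sum((th - config.theta0) ** 2))
    phi = dihedral_angles(pos)
    e_dih = 0.5 * config.eps_dih * float(np.sum(1.0 - np.cos(3.0 * phi)))
    e_ev = 0.0
    if config.ev_strength > 0 and config.ev_cutoff > 0:
        i, j = np.triu_indices(config.N, k=EV_MIN_SEPARATION)
        if i.size:
            r2 = np.sum((pos[i] - pos[j]) ** 2, axis=1)
            close = r2 < config.ev_cutoff**2
            if np.any(close):
                e_ev = float(np.sum(_ev_pair_energy(r2[close], config)))
    return EnergyBreakdown(bond=e_bond, bend=e_bend, dihedral=e_dih, excluded_volume=e_ev)


def _place_bead(prev3: np.ndarray, b: float, theta: float, phi: float) -> np.ndarray:
    """Internal-coordinate (NeRF) placement of the next bead.

    Given the three preceding beads, append a bead at bond length ``b``,
    bending angle ``theta`` at the last bead, and torsion ``phi`` for the
    resulting quadruple (same sign convention as :func:`dihedral_angles`).
    """
    r1, r2, r3 = prev3
    bc = r3 - r2
    bc = bc / np.linalg.norm(bc)
    ab = r2 - r1
    n = np.cross(ab, bc)
    nn = np.linalg.norm(n)
    if nn < 1e-12:
        raise ValueError("cannot place bead after collinear triple")
    n = n / nn
    m = np.cross(n, bc)
    # local displacement: theta is the bead angle, so the new bond makes an
    # angle (pi - theta) with the previous bond direction bc
    d = np.array(
        [
            -b * math.cos(theta),
            b * math.sin(theta) * math.cos(phi),
            b * math.sin(theta) * math.sin(phi),
        ]
    )
    return r3 + d[0] * bc + d[1] * m + d[2] * n


def build_chain(
    config: CGChainConfig,
    seed: int,
    method: str = "auto",
    max_restarts: int | None = None,
) -> np.ndarray:
    """Initial conformation with exact geometry and random well choices.

    All bonds have length ``sigma``, all bending angles equal ``theta0`` and
    every dihedral sits exactly at one of the three well minima, drawn
    uniformly.  Beads at least :data:`EV_MIN_SEPARATION` bonds apart must not
    come closer than ``ev_cutoff`` (when excluded volume is active).
    Deterministic given ``seed``.

    Two construction methods:

    * ``"reject"`` — draw all dihedrals, build, discard the whole chain on
      any clash.  Samples the clash-constrained rotational-isomeric ensemble
      exactly, but the acceptance rate decays exponentially with N (chain
      attrition); practical up to N ~ 35.
    * ``"grow"`` — place beads sequentially, retrying the well choice of a
      clashing bead.  Always fast, but the survivorship reweighting biases
      the ensemble slightly; fine for initial conditions that are
      equilibrated away.

    ``"auto"`` picks ``"reject"`` for N <= 35 and ``"grow"`` above.
    """
    if method == "auto":
        method = "reject" if config.N <= 35 else "grow"
    if method not in ("reject", "grow"):
        raise ValueError(f"unknown construction method {method!r}")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x6B75686E]))
    b, th = config.sigma, config.theta0
    check_clash = config.ev_strength > 0 and config.ev_cutoff > 0
    cut2 = config.ev_cutoff**2

    if method == "reject":
        from . import _kernels  # local import: avoid cycle at module load

        if max_restarts is None:
            max_restarts = 500_000
        iu, ju = np.triu_indices(config.N, k=EV_MIN_SEPARATION)
        pos = np.empty((config.N, 3))
        for _ in range(max_restarts):
            phis = WELL_CENTERS[rng.integers(0, 3, size=config.N - 3)]
            _kernels.reconstruct_positions(phis, b, th, pos)
            if not check_clash or iu.size == 0:
                return pos.copy()
            r2 = np.sum((pos[iu] - pos[ju]) ** 2, axis=1)
            bad = r2 < cut2
            if not np.any(bad):
                return pos.copy()
            first_bad = int(ju[np.argmax(bad)])
        raise ChainConstructionError(
            f"could not build a clash-free chain after {max_restarts} rejection "
            f"attempts; last clash at bead {first_bad} "
            f"(N={config.N}, ev_cutoff={config.ev_cutoff}); try method='grow'"
        )

    if max_restarts is None:
        max_restarts = 500
    last_fail = 3
    for _ in range(max_restarts):
        pos = np.empty((config.N, 3))
        pos[0] = 0.0
        pos[1] = (b, 0.0, 0.0)
        pos[2] = pos[1] + (b * math.cos(np.pi - th), b * math.sin(np.pi - th), 0.0)
        ok = True
        for i in range(3, config.N):
            placed = False
            for w in rng.permutation(3):
                cand = _place_bead(pos[i - 3 : i], b, th, WELL_CENTERS[w])
                if check_clash and i >= EV_MIN_SEPARATION:
                    r2 = np.sum((pos[: i - EV_MIN_SEPARATION + 1] - cand) ** 2, axis=1)
                    if np.any(r2 < cut2):
                        continue
                pos[i] = cand
                placed = True
                break
            if not placed:
                ok = False
                last_fail = i
                break
        if ok:
            return pos
    raise ChainConstructionError(
        f"could not place bead {last_fail} without a clash after "
        f"{max_restarts} restarts (N={config.N}, ev_cutoff={config.ev_cutoff})"
    )
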