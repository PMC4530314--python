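"""Passive attenuation along the dendrite and the decay matrix.

Fast ionic ("linear") input propagates passively, attenuating as a negative
exponential of path distance with an empirical functional length constant
lambda (not Rall's steady-state cable constant).  Before the NMDAR system of a
compartment opens, its own local input decays temporally through the leak;
input arriving from other compartments decays spatially.  Both effects reduce
to constants, collected in a decay matrix Phi whose diagonal holds the expected
leak decay at channel opening and whose off-diagonals hold inter-site spatial
attenuation.  The potentials at channel opening are then a single matrix-vector
product Phi @ v0.

Forward travel (toward the soma) and back-propagation may use different length
constants; contributions to *spike generation* use a reduced fraction (default
half) of the respective length constant, which concentrates spike cooperation
into a small zone without altering passive transients reaching the soma.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .distributions import MultiExpDistribution

__all__ = [
    "DendriteGeometry",
    "InputPattern",
    "attenuation",
    "expected_open_decay",
    "build_decay_matrix",
    "potentials_at_opening",
    "soma_decay_weights",
]


@dataclass(frozen=True)
class DendriteGeometry:
    """Ordered input sites along one dendritic branch.

    Parameters
    ----------
    positions
        Path distances from the soma in micrometres, strictly increasing
        (least to most distal), all > 0.
    lambda_to_soma
        Functional length constant (um) for somatically directed transients.
    lambda_back
        Length constant (um) for back-propagating contributions.  ``None``
        means symmetric decay (equal to ``lambda_to_soma``).
    spike_lambda_fraction
        Fraction of the respective length constant used for contributions to
        spike generation (default 0.5).
    """

    positions: tuple[float, ...]
    lambda_to_soma: float
    lambda_back: float | None = None
    spike_lambda_fraction: float = 0.5

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        if pos.size < 1:
            raise ValueError("at least one input site is required")
        if np.any(pos <= 0):
            raise ValueError("positions must be > 0 um (path distance from soma)")
        if pos.size > 1 and np.any(np.diff(pos) <= 0):
            raise ValueError("positions must be strictly increasing (least to most distal)")
        if self.lambda_to_soma <= 0:
            raise ValueError("lambda_to_soma must be > 0 um")
        lb = self.lambda_to_soma if self.lambda_back is None else self.lambda_back
        if lb <= 0:
            raise ValueError("lambda_back must be > 0 um")
        if not 0 < self.spike_lambda_fraction <= 1:
            raise ValueError("spike_lambda_fraction must be in (0, 1]")
        object.__setattr__(self, "positions", tuple(float(x) for x in pos))
        object.__setattr__(self, "lambda_back", float(lb))

    @property
    def n_sites(self) -> int:
        return len(self.positions)

    @property
    def symmetric(self) -> bool:
        return self.lambda_back == self.lambda_to_soma

    def site(self, i: int) -> "DendriteGeometry":
        """Single-site sub-geometry at index ``i`` (same length constants)."""
        return DendriteGeometry(
            (self.positions[i],),
            self.lambda_to_soma,
            self.lambda_back,
            self.spike_lambda_fraction,
        )


@dataclass(frozen=True)
class InputPattern:
    """Induced local depolarisations (mV relative to rest), one per site."""

    v0: tuple[float, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "v0", tuple(float(x) for x in np.asarray(self.v0, float)))

    def __len__(self) -> int:
        return len(self.v0)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.v0, dtype=float)


def attenuation(distance: float, lam: float) -> float:
    """Spatial attenuation factor exp(-distance/lambda), in (0, 1].

    ``distance`` is the intervening path distance in um, ``lam`` the functional
    length constant in um.
    """
    if distance < 0:
        raise ValueError("distance must be >= 0 um")
    if lam <= 0:
        raise ValueError("length constant must be > 0 um")
    return float(np.exp(-distance / lam))


def expected_open_decay(open_dist: MultiExpDistribution, tau_m: float) -> float:
    """Expected leak-decay factor at channel opening.

    With the closed time prior to opening mixture-exponentially distributed
    (weights theta_i, means tau_i) and a membrane time constant tau_m = Rm*C,
    the expected fraction of a local depolarisation remaining when the NMDAR
    system first opens is  sum_i theta_i * tau_m / (tau_i + tau_m), in (0, 1).
    """
    if tau_m <= 0:
        raise ValueError("tau_m must be > 0 ms")
    w = np.asarray(open_dist.weights)
    tau = np.asarray(open_dist.time_constants)
    return float(np.sum(w * tau_m / (tau + tau_m)))


def build_decay_matrix(
    geom: DendriteGeometry,
    open_dist: MultiExpDistribution,
    tau_m: float,
    for_spike_generation: bool = True,
) -> np.ndarray:
    """Decay matrix Phi combining temporal (diagonal) and spatial decay.

    ``Phi[i, i]`` is the expected leak decay at channel opening (identical for
    all sites).  ``Phi[i, j]`` for i != j attenuates input travelling from site
    j to site i: toward the soma (i < j) with ``lambda_to_soma``, backward
    (i > j) with ``lambda_back``; when ``for_spike_generation`` is set each
    length constant is multiplied by ``spike_lambda_fraction``.
    """
    pos = np.asarray(geom.positions)
    n = pos.size
    frac = geom.spike_lambda_fraction if for_spike_generation else 1.0
    lam_fwd = geom.lambda_to_soma * frac
    lam_back = geom.lambda_back * frac
    phi_diag = expected_open_decay(open_dist, tau_m)

    dist = np.abs(pos[None, :] - pos[:, None])
    phi = np.where(
        np.arange(n)[:, None] < np.arange(n)[None, :],
        np.exp(-dist / lam_fwd),
        np.exp(-dist / lam_back),
    )
    np.fill_diagonal(phi, phi_diag)
    return phi


def potentials_at_opening(phi: np.ndarray, pattern: InputPattern) -> np.ndarray:
    """Per-site depolarisation at NMDAR opening: the product Phi @ v0 (mV)."""
    phi = np.asarray(phi, dtype=float)
    v0 = pattern.as_array()
    if phi.ndim != 2 or phi.shape[0] != phi.shape[1]:
        raise ValueError("Phi must be a square matrix")
    if phi.shape[1] != v0.size:
        raise ValueError(
            f"dimension mismatch: Phi is {phi.shape}, pattern has {v0.size} sites"
        )
    return phi @ v0


def soma_decay_weights(geom: DendriteGeometry) -> np.ndarray:
    """Somatic arrival weights delta_i = exp(-x_i / lambda_to_soma)."""
    return np.exp(-np.asarray(geom.positions) / geom.lambda_to_soma)
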