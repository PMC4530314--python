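"""Dendritic transfer functions: boundary, artificial, and biophysical forms.

All three map synaptic input to the peak somatic depolarisation (mV, relative
to rest) without simulating a time course.

* ``boundary_G`` is a locally linear "soft saturation" built from integrals of
  sigmoids: near-identity inside (b_L, b_U), asymptoting to the bounds.  It
  mimics dendritic saturation — summed NMDA spikes cannot meaningfully exceed
  the NMDAR reversal potential at the branch.
* ``artificial_transfer`` is the location-agnostic "linear hook": the boundary
  of the sum of the raw linear input and a single sigmoidal nonlinear
  component.
* ``transfer_bio`` composes the cable and membrane pieces: decay matrix ->
  opening potentials -> per-site NMDA components (limit-state or
  burst-distribution expectation) -> soma-ward attenuation -> boundary.
* ``transfer_single`` is the boundary-free single-synapse, single-pulse form
  using the relative spike amplitude.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .cable import (
    DendriteGeometry,
    InputPattern,
    build_decay_matrix,
    potentials_at_opening,
    soma_decay_weights,
)
from .distributions import MultiExpDistribution
from .membrane import (
    MembraneParams,
    expected_vnmda,
    gate_B,
    saturation_amplitude,
    simple_vnmda,
)

__all__ = [
    "BoundaryParams",
    "ArtificialParams",
    "boundary_G",
    "artificial_transfer",
    "transfer_bio",
    "transfer_bio_detailed",
    "transfer_single",
    "sum_branches",
    "fit_artificial",
    "check_boundary_saturation",
]


@dataclass(frozen=True)
class BoundaryParams:
    """Parameters of the linear-boundary function G."""

    b_l: float = -12.0   # mV, lower bound
    b_u: float = 12.0    # mV, upper bound
    alpha_l: float = 0.5  # 1/mV, lower-edge curvature
    alpha_u: float = 0.5  # 1/mV, upper-edge curvature

    def __post_init__(self) -> None:
        if not self.b_l < self.b_u:
            raise ValueError("require b_l < b_u")
        if self.alpha_l <= 0 or self.alpha_u <= 0:
            raise ValueError("edge curvatures must be > 0")

    @classmethod
    def symmetric(cls, bound: float, alpha: float = 0.5) -> "BoundaryParams":
        return cls(-bound, bound, alpha, alpha)


@dataclass(frozen=True)
class ArtificialParams:
    """Nonlinear component of the artificial transfer function."""

    c_d: float   # mV, nonlinear maximum
    a_d: float   # 1/mV, curvature
    b_d: float   # mV, midpoint (threshold-related)

    def __post_init__(self) -> None:
        if self.c_d <= 0 or self.a_d <= 0:
            raise ValueError("c_d and a_d must be > 0")


def _softplus(x):
    """log(1 + exp(x)) computed without overflow."""
    return np.logaddexp(0.0, x)


def boundary_G(v, bp: BoundaryParams):
    """Locally linear boundary function with soft limits (b_L, b_U).

    Defined as the integral of the difference of two sigmoids (lower edge at
    b_L with curvature alpha_L, upper edge at b_U with curvature alpha_U),
    which integrates in closed form to

        G(V) = softplus(alpha_L (V - b_L))/alpha_L
             - softplus(alpha_U (V - b_U))/alpha_U + b_L.

    Monotone nondecreasing, with G -> b_L as V -> -inf and G -> b_U as
    V -> +inf; for symmetric parameters G(0) = 0 exactly.
    """
    v = np.asarray(v, dtype=float)
    out = (
        _softplus(bp.alpha_l * (v - bp.b_l)) / bp.alpha_l
        - _softplus(bp.alpha_u * (v - bp.b_u)) / bp.alpha_u
        + bp.b_l
    )
    return out if out.ndim else float(out)


def artificial_transfer(x, ap: ArtificialParams, bp: BoundaryParams) -> float:
    """Location-agnostic transfer: G(c_d * sigma(a_d (sum X - b_d)) + sum X).

    The nonlinear component is a single logistic of the scaled summed input
    (midpoint b_d, curvature a_d, maximum c_d); the result is permutation
    invariant in the inputs.
    """
    s = float(np.sum(np.asarray(x, dtype=float)))
    sig = 1.0 / (1.0 + math.exp(-min(max(ap.a_d * (s - ap.b_d), -700.0), 700.0)))
    return boundary_G(ap.c_d * sig + s, bp)


def _per_site_nmda(
    v_open: np.ndarray,
    active: np.ndarray,
    p: MembraneParams,
    model: str,
    burst_dist: MultiExpDistribution | None,
    nmda_component: str,
) -> np.ndarray:
    if model == "simple":
        vn = simple_vnmda(v_open, p)
    elif model == "distribution":
        if burst_dist is None:
            raise ValueError("model='distribution' requires burst_dist")
        vn = expected_vnmda(v_open, p, burst_dist)
    else:
        raise ValueError("model must be 'simple' or 'distribution'")
    vn = np.asarray(vn, dtype=float)
    if nmda_component == "relative":
        # relative spike amplitude: excess over the opening potential, driven
        # toward the saturation amplitude (single-synapse form generalised)
        sat = saturation_amplitude(p)
        b_arg = (v_open - p.v_mid + p.k * math.log(p.g * p.r_abs + 1.0)) / p.k
        with np.errstate(over="ignore"):
            sig = 1.0 / (1.0 + np.exp(-b_arg))
        vn = (sat - v_open) * sig
    elif nmda_component != "total":
        raise ValueError("nmda_component must be 'total' or 'relative'")
    return np.where(active, vn, 0.0)


def transfer_bio(
    pattern: InputPattern,
    geom: DendriteGeometry,
    p: MembraneParams,
    bp: BoundaryParams,
    model: str = "simple",
    open_dist: MultiExpDistribution | None = None,
    burst_dist: MultiExpDistribution | None = None,
    nmda_component: str = "total",
) -> float:
    """Peak somatic EPSP for a pattern of local depolarisations on one branch.

    Pipeline: the spike-generation decay matrix Phi gives per-site potentials
    at channel opening V0 = Phi v; each *stimulated* site contributes a
    nonlinear NMDA component of its opening potential (limit-state or
    burst-length expectation); linear terms use the raw local inputs.  Both
    are attenuated toward the soma by delta_i = exp(-x_i/lambda) and the
    bounded sum is returned:  G(sum_i delta_i (v_i + V_NMDA(x_i))).

    Sites with zero input receive no glutamate, hence contribute no NMDA
    component (their NMDARs are unbound).
    """
    return transfer_bio_detailed(
        pattern, geom, p, bp, model, open_dist, burst_dist, nmda_component
    )["soma_mv"]


def transfer_bio_detailed(
    pattern: InputPattern,
    geom: DendriteGeometry,
    p: MembraneParams,
    bp: BoundaryParams,
    model: str = "simple",
    open_dist: MultiExpDistribution | None = None,
    burst_dist: MultiExpDistribution | None = None,
    nmda_component: str = "total",
) -> dict:
    """As :func:`transfer_bio` but returning the intermediate stages."""
    v = pattern.as_array()
    if v.size != geom.n_sites:
        raise ValueError(
            f"pattern has {v.size} inputs but geometry has {geom.n_sites} sites"
        )
    if open_dist is None:
        raise ValueError("open_dist (closed-time distribution prior to opening) is required")
    phi = build_decay_matrix(geom, open_dist, p.tau_m, for_spike_generation=True)
    v_open = potentials_at_opening(phi, pattern)
    active = v > 0
    vn = _per_site_nmda(v_open, active, p, model, burst_dist, nmda_component)
    delta = soma_decay_weights(geom)
    soma = boundary_G(float(np.dot(delta, v + vn)), bp)
    return {
        "inputs_mv": v.tolist(),
        "v0_at_opening_mv": np.asarray(v_open).tolist(),
        "per_site_nmda_mv": np.asarray(vn).tolist(),
        "soma_decay": delta.tolist(),
        "soma_mv": float(soma),
    }


def transfer_single(v0: float, p: MembraneParams, delta: float = 1.0) -> float:
    """Single-synapse, single-pulse transfer (no boundary function needed).

    The relative spike amplitude drives the local potential from v0 toward the
    saturation amplitude:

        T = delta * (v0 + (sat - v0) * sigma((v0 - V_mid + k ln(g R + 1))/k)),

    where ``delta`` is the soma-ward attenuation of the site.  For one synapse
    the spike cannot exceed the plateau, so no artificial bound is required.
    """
    if not 0 < delta <= 1:
        raise ValueError("delta must be in (0, 1]")
    sat = saturation_amplitude(p)
    arg = (v0 - p.v_mid + p.k * math.log(p.g * p.r_abs + 1.0)) / p.k
    sig = 1.0 / (1.0 + math.exp(-min(max(arg, -700.0), 700.0)))
    return delta * (v0 + (sat - v0) * sig)


def sum_branches(*branch_outputs: float) -> float:
    """Inter-branch integration: somatic EPSPs from separate branches sum linearly."""
    return float(sum(branch_outputs))


def check_boundary_saturation(
    geom: DendriteGeometry,
    p: MembraneParams,
    bp: BoundaryParams,
    fraction: float = 0.95,
) -> bool:
    """Warn unless one full spike from the most proximal site nearly saturates G.

    The upper bound should be set so a single full-amplitude spike from the
    most proximal synapse approaches saturation; otherwise subthreshold EPSPs
    and spikes would keep summing linearly through the boundary.
    """
    delta0 = float(soma_decay_weights(geom)[0])
    one_spike = delta0 * saturation_amplitude(p)
    ok = one_spike >= fraction * bp.b_u
    if not ok:
        warnings.warn(
            f"one proximal spike reaches {one_spike:.2f} mV at the soma, "
            f"below {fraction:.0%} of the upper bound b_u = {bp.b_u} mV",
            stacklevel=2,
        )
    return ok


def fit_artificial(
    geom: DendriteGeometry,
    p: MembraneParams,
    bp: BoundaryParams,
    open_dist: MultiExpDistribution,
    v_grid: np.ndarray,
    model: str = "simple",
    burst_dist: MultiExpDistribution | None = None,
) -> ArtificialParams:
    """Least-squares (c_d, a_d, b_d) matching the artificial to the biophysical form.

    With every input at a single location the biophysical transfer reduces to
    a bounded linear + sigmoid shape, so an artificial parameterisation exists
    that reproduces it.  Inputs to the artificial function are the soma-scaled
    effective inputs x = delta * v (the artificial form is location-agnostic,
    so attenuation must be folded into its input scale).
    """
    from scipy.optimize import least_squares

    if geom.n_sites != 1:
        raise ValueError("artificial correspondence is defined for a single location")
    delta = float(soma_decay_weights(geom)[0])
    v_grid = np.asarray(v_grid, dtype=float)
    target = np.array([
        transfer_bio(InputPattern((v,)), geom, p, bp, model, open_dist, burst_dist)
        for v in v_grid
    ])
    x_grid = delta * v_grid

    def resid(theta):
        c, a, b = theta
        ap = ArtificialParams(abs(c) + 1e-9, abs(a) + 1e-9, b)
        return np.array([
            artificial_transfer([x], ap, bp) for x in x_grid
        ]) - target

    sat = delta * saturation_amplitude(p)
    # start near the known biophysical scale: max c ~ soma-scale spike, midpoint
    # near the soma-scaled opening threshold
    phi0 = float(np.dot(open_dist.weights,
                        p.tau_m / (np.asarray(open_dist.time_constants) + p.tau_m)))
    b0 = delta * (p.v_mid - p.k * math.log(p.g * p.r_abs + 1.0)) / phi0
    sol = least_squares(resid, x0=[max(sat, 0.5), 1.0, b0], method="lm")
    c, a, b = sol.x
    return ArtificialParams(abs(c) + 1e-9, abs(a) + 1e-9, b)
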