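"""Reduced leak + NMDAR membrane of a single dendritic compartment.

The compartment keeps only two currents: the ohmic leak and the NMDAR current
gated by voltage-dependent Mg2+ blockade,

    C dV/dt = -V/R + g * B(V) * (E - V),        B(V) = 1 / (1 + exp(-(V - V_mid)/k))

with all potentials translated so that rest (the leak reversal) is 0 mV.  Mg2+
unblocking is orders of magnitude faster than channel closing, so B(V) is taken
as its nullcline (instantaneous).  Because every other voltage-gated current is
dropped, the blockade slope k must be steepened (here 2.5 mV, a fifth of the
standard 12.5 mV) for the system to stay bistable: with the standard slope a
leak+NMDAR membrane has a single, spike-like equilibrium except at very low
conductance.

Units are mV, ms, nS, GOhm, pF, pA throughout (mV/GOhm = nS*mV = pA).

The closed-form spike solutions used by the transfer functions come from
freezing the blockade at its value at channel opening, B(V0): the membrane
equation becomes linear and relaxes exponentially toward

    Veq(V0) = g E B(V0) / (g B(V0) + 1/R),

which, averaged over a multi-exponential burst/cluster-length distribution,
gives the expected NMDA component (``expected_vnmda``); letting the burst
length go to infinity gives the limit-state "Simple Model" sigmoid
(``simple_vnmda``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import brentq

from .distributions import MultiExpDistribution

__all__ = [
    "MembraneParams",
    "gate_B",
    "net_current",
    "find_equilibria",
    "rest_spike_threshold_conductance",
    "vnmda_constant_blockade",
    "expected_vnmda",
    "simple_vnmda",
    "saturation_amplitude",
]


@dataclass(frozen=True)
class MembraneParams:
    """Electrical and gating constants of one dendritic compartment.

    Defaults: Rm = 10 kOhm cm2, C = 1 uF/cm2, a 10 um x 1 um cylindrical
    compartment, g = 3.9 nS, E_NMDA = 70 mV, V_mid = 46.3 mV and k = 2.5 mV
    (steepened Mg2+ blockade), all on the rest-translated voltage scale.
    """

    rm_specific: float = 10.0        # kOhm cm2
    c_specific: float = 1.0          # uF/cm2
    compartment_length: float = 10.0  # um
    compartment_diameter: float = 1.0  # um
    g: float = 3.9                   # nS, max NMDAR conductance of the segment
    e_nmda: float = 70.0             # mV (0 mV absolute, rest-translated)
    v_mid: float = 46.3              # mV (-23.7 mV absolute, rest-translated)
    k: float = 2.5                   # mV, Mg2+ blockade slope factor

    def __post_init__(self) -> None:
        for name in ("rm_specific", "c_specific", "compartment_length",
                     "compartment_diameter", "k"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.g < 0:
            raise ValueError("g must be >= 0 nS")
        if not self.e_nmda > self.v_mid > 0:
            raise ValueError("expected E > V_mid > 0 on the rest-translated scale")

    # -- derived absolute quantities (lateral cylinder area, no end caps) ---

    @property
    def area_cm2(self) -> float:
        # um * um -> cm2: 1 um2 = 1e-8 cm2
        return math.pi * self.compartment_diameter * self.compartment_length * 1e-8

    @property
    def r_abs(self) -> float:
        """Absolute leak resistance in GOhm: Rm / (pi d L)."""
        return self.rm_specific * 1e3 / self.area_cm2 / 1e9

    @property
    def c_abs(self) -> float:
        """Absolute capacitance in pF."""
        return self.c_specific * self.area_cm2 * 1e6

    @property
    def g_leak(self) -> float:
        """Leak conductance 1/R in nS."""
        return 1.0 / self.r_abs

    @property
    def tau_m(self) -> float:
        """Membrane time constant Rm*C in ms (area-invariant)."""
        return self.r_abs * self.c_abs

    def with_g(self, g: float) -> "MembraneParams":
        return replace(self, g=g)

    def with_k(self, k: float) -> "MembraneParams":
        return replace(self, k=k)


def gate_B(v, p: MembraneParams):
    """Mg2+ blockade nullcline B(V) = 1/(1 + exp(-(V - V_mid)/k)), in (0, 1)."""
    v = np.asarray(v, dtype=float)
    with np.errstate(over="ignore"):
        out = 1.0 / (1.0 + np.exp(-(v - p.v_mid) / p.k))
    return out if out.ndim else float(out)


def net_current(v, p: MembraneParams):
    """Net membrane current in pA: -V/R + g B(V) (E - V).

    Positive values depolarise.  mV/GOhm and nS*mV both equal pA, so the units
    work out without conversion factors.
    """
    v = np.asarray(v, dtype=float)
    out = -v / p.r_abs + p.g * gate_B(v, p) * (p.e_nmda - v)
    return out if out.ndim else float(out)


def saturation_amplitude(p: MembraneParams) -> float:
    """Plateau potential g E / (g + 1/R), the open-channel equilibrium (mV)."""
    return p.g * p.e_nmda / (p.g + p.g_leak)


def find_equilibria(
    p: MembraneParams,
    v_range: tuple[float, float] = (-5.0, 75.0),
    grid: int = 5000,
) -> list[tuple[float, bool]]:
    """Equilibria of the reduced membrane with stability flags.

    Scans ``net_current`` on a dense grid over ``v_range``, brackets every sign
    change, refines each root by bisection (Brent) to |I| < 1e-9 pA, and marks
    a root stable when the slope of the net current there is negative.

    Returns a list of ``(root_mV, stable)`` sorted by voltage.  Depending on
    parameters there are one to three equilibria; in the bistable case the
    lower (rest) and upper (plateau) roots are stable and the middle one is the
    all-or-none spike threshold.
    """
    if grid < 1000:
        raise ValueError("grid must be >= 1000 for reliable bracketing")
    vs = np.linspace(v_range[0], v_range[1], grid)
    cur = net_current(vs, p)
    roots: list[tuple[float, bool]] = []
    for i in np.flatnonzero(np.signbit(cur[:-1]) != np.signbit(cur[1:])):
        a, b = vs[i], vs[i + 1]
        root = brentq(lambda v: net_current(v, p), a, b, xtol=1e-13, rtol=1e-15)
        h = 1e-6
        slope = (net_current(root + h, p) - net_current(root - h, p)) / (2 * h)
        roots.append((float(root), bool(slope < 0)))
    # exact roots sitting on a grid point (e.g. V=0 with g=0) are rare; catch them
    for i in np.flatnonzero(cur == 0.0):
        v = float(vs[i])
        if not any(abs(v - r) < 1e-9 for r, _ in roots):
            h = 1e-6
            slope = (net_current(v + h, p) - net_current(v - h, p)) / (2 * h)
            roots.append((v, bool(slope < 0)))
    roots.sort()
    return roots


def rest_spike_threshold_conductance(
    p: MembraneParams,
    g_range: tuple[float, float] = (0.01, 0.5),
    tol: float = 1e-4,
    v_range: tuple[float, float] = (-5.0, 75.0),
    grid: int = 5000,
) -> float:
    """Conductance (nS) separating rest-like from spike-like equilibrium structure.

    For a given blockade slope (typically the standard k = 12.5 mV, where the
    reduced membrane is never bistable) the single equilibrium sits near rest
    for small g and near the NMDAR reversal for large g.  This bisects on g for
    that transition, classifying a parameter set as spike-like when *all* its
    equilibria lie above the blockade midpoint — so in a bistable window the
    returned value is the lower boundary of spike-only behaviour.
    """

    def spike_only(g: float) -> bool:
        roots = find_equilibria(p.with_g(g), v_range, grid)
        return all(r > p.v_mid for r, _ in roots)

    lo, hi = g_range
    if spike_only(lo) == spike_only(hi):
        raise ValueError(
            f"no rest/spike transition inside g_range {g_range} nS"
        )
    # orient so lo is rest-like
    flip = spike_only(lo)
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if spike_only(mid) != flip:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


def _frozen_rate(v0: float, p: MembraneParams) -> float:
    """Relaxation rate (1/ms) of the membrane with blockade frozen at B(V0)."""
    return (p.g * gate_B(v0, p) + p.g_leak) / p.c_abs


def _frozen_equilibrium(v0: float, p: MembraneParams) -> float:
    """Target potential g E B(V0) / (g B(V0) + 1/R) with frozen blockade (mV)."""
    b = gate_B(v0, p)
    return p.g * p.e_nmda * b / (p.g * b + p.g_leak)


def vnmda_constant_blockade(v0: float, t: float, p: MembraneParams) -> float:
    """Membrane potential t ms after opening with Mg2+ blockade frozen at B(V0).

    The linearised membrane relaxes exponentially from V0 toward the frozen
    equilibrium:  V0 + (Veq(V0) - V0) (1 - exp(-(g B(V0) + 1/R) t / C)).
    """
    if t < 0:
        raise ValueError("t must be >= 0 ms")
    veq = _frozen_equilibrium(v0, p)
    return v0 + (veq - v0) * (1.0 - math.exp(-_frozen_rate(v0, p) * t))


def expected_vnmda(
    v0,
    p: MembraneParams,
    burst_dist: MultiExpDistribution,
):
    """Expected potential at NMDAR closing over a burst-length mixture (mV).

    Averaging the frozen-blockade solution over burst/cluster lengths that are
    mixture-exponential (weights omega_i, means a_i) gives

        V0 + (Veq(V0) - V0) * [1 - sum_i omega_i / (1 + a_i (g B(V0) + 1/R)/C)].

    As every a_i grows this converges (monotonically in each a_i) to the
    limit-state value ``simple_vnmda``; as a_i -> 0 it returns V0.
    """
    v0 = np.asarray(v0, dtype=float)
    b = np.asarray(gate_B(v0, p))
    veq = p.g * p.e_nmda * b / (p.g * b + p.g_leak)
    rate = (p.g * b + p.g_leak) / p.c_abs
    w = np.asarray(burst_dist.weights)
    a = np.asarray(burst_dist.time_constants)
    frac = np.sum(w / (1.0 + a * rate[..., None]), axis=-1)
    out = v0 + (veq - v0) * (1.0 - frac)
    return out if out.ndim else float(out)


def simple_vnmda(v0, p: MembraneParams):
    """Limit-state ("Simple Model") NMDA component: the frozen equilibrium (mV).

    With burst/cluster durations long enough for the membrane to reach its
    frozen-blockade equilibrium, the NMDA component reduces to a sigmoid of the
    opening potential,

        (g E / (g + 1/R)) / (1 + exp(-(V0 - V_mid + k ln(g R + 1)) / k)),

    which is algebraically identical to Veq(V0).  Strictly increasing in V0 and
    bounded by the saturation amplitude.
    """
    v0 = np.asarray(v0, dtype=float)
    sat = saturation_amplitude(p)
    shift = p.v_mid - p.k * math.log(p.g * p.r_abs + 1.0)
    with np.errstate(over="ignore"):
        out = sat / (1.0 + np.exp(-(v0 - shift) / p.k))
    return out if out.ndim else float(out)
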