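"""Multi-exponential dwell-time distributions for NMDAR gating.

Single-channel NMDAR dwell times (durations prior to opening, and the lengths of
the bursts/super-clusters that carry the macroscopic current) are conventionally
described as mixtures of exponentials.  The transfer-function machinery only ever
needs expectations of simple functionals of these mixtures, so the distribution
object is deliberately light: a weight vector and a time-constant vector, with
the weights kept normalised to unit mass.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["EmptyDistributionError", "MultiExpDistribution"]

_WEIGHT_TOL = 1e-12


class EmptyDistributionError(ValueError):
    """Raised when a filtering operation would remove every mixture component."""


@dataclass(frozen=True)
class MultiExpDistribution:
    """A finite mixture of exponential distributions over dwell times (ms).

    Parameters
    ----------
    weights
        Component amplitudes, all > 0.  They are renormalised to sum to one at
        construction, so callers may pass raw (un-normalised) amplitudes.
    time_constants
        Component means in milliseconds, all > 0, aligned with ``weights``.
    """

    weights: tuple[float, ...]
    time_constants: tuple[float, ...]

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        tau = np.asarray(self.time_constants, dtype=float)
        if w.ndim != 1 or tau.ndim != 1 or w.size != tau.size:
            raise ValueError("weights and time_constants must be 1-D and aligned")
        if w.size == 0:
            raise EmptyDistributionError("mixture must contain at least one component")
        if np.any(w <= 0):
            raise ValueError("all weights must be > 0")
        if np.any(tau <= 0):
            raise ValueError("all time constants must be > 0 ms")
        w = w / w.sum()
        object.__setattr__(self, "weights", tuple(float(x) for x in w))
        object.__setattr__(self, "time_constants", tuple(float(x) for x in tau))

    # -- basic quantities ---------------------------------------------------

    @property
    def n_components(self) -> int:
        return len(self.weights)

    def mean(self) -> float:
        """Mixture mean in ms: sum_i w_i * tau_i."""
        return float(np.dot(self.weights, self.time_constants))

    # -- operations ---------------------------------------------------------

    def filter_and_reweight(self, min_tau: float) -> "MultiExpDistribution":
        """Drop components with time constant below ``min_tau`` and renormalise.

        This reproduces the dwell-time filtering used throughout: fast opening
        components are removed so that nonlocal input has time to reach the
        spike-generation site, and fast burst-length components are removed to
        emphasise the slow components that carry most of the charge.

        Raises
        ------
        EmptyDistributionError
            If every component falls below ``min_tau``.
        """
        keep = [i for i, tau in enumerate(self.time_constants) if tau >= min_tau]
        if not keep:
            raise EmptyDistributionError(
                f"no components with time constant >= {min_tau} ms"
            )
        w = np.array([self.weights[i] for i in keep])
        tau = [self.time_constants[i] for i in keep]
        return MultiExpDistribution(tuple(w / w.sum()), tuple(tau))

    def sample(self, n: int, seed: int | np.random.Generator | None = None) -> np.ndarray:
        """Draw ``n`` dwell times (ms): pick a component by weight, then Exp(tau)."""
        if n < 1:
            raise ValueError("n must be >= 1")
        rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
        comp = rng.choice(self.n_components, size=n, p=self.weights)
        tau = np.asarray(self.time_constants)[comp]
        return rng.exponential(tau)

    # -- (de)serialisation --------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "weights": list(self.weights),
            "time_constants_ms": list(self.time_constants),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MultiExpDistribution":
        return cls(tuple(d["weights"]), tuple(d["time_constants_ms"]))
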