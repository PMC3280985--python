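"""Continuous-time Markov model of channel gating on a linear chain of states.

States are connected in a single chain (e.g. C1 - C2 - O); each adjacent
pair carries a forward and a backward rate law of the exponential form
``prefactor * exp(coeff * V)``.  Occupancy evolves by the master equation
dp/dt = Q(V) p with the generator Q built from the rate laws; propagation
under piecewise-constant voltage is exact (matrix-exponential semantics),
so the output sampling interval never affects accuracy.

Units: time ms, rates ms^-1, voltage mV.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import expm

from .params import (
    COEFF_K1, COEFF_KM1, COEFF_K2, COEFF_KM2, ModelParams,
)

__all__ = [
    "RateLaw", "GatingScheme", "DegenerateSpectrumWarning",
    "build_scheme1", "rate_at", "generator_matrix",
    "equilibrium_occupancy", "relax_piecewise", "macroscopic_taus",
]


class DegenerateSpectrumWarning(UserWarning):
    """Raised when the generator has (numerically) repeated eigenvalues."""


@dataclass(frozen=True)
class RateLaw:
    """One voltage-dependent transition rate, prefactor*exp(coeff*V)."""

    prefactor: float  # ms^-1 at 0 mV
    voltage_coeff: float  # mV^-1, signed

    def __post_init__(self) -> None:
        if not (self.prefactor > 0):
            raise ValueError(f"prefactor must be > 0, got {self.prefactor!r}")
        if not np.isfinite(self.voltage_coeff):
            raise ValueError("voltage_coeff must be finite")

    def rate(self, v: float) -> float:
        return self.prefactor * np.exp(self.voltage_coeff * v)


def rate_at(law: RateLaw, v: float) -> float:
    """Rate of `law` at membrane potential `v` (mV), in ms^-1."""
    return law.rate(v)


@dataclass(frozen=True)
class GatingScheme:
    """A linear chain of gating states with per-edge forward/backward rates.

    ``forward[i]`` is the rate law for states[i] -> states[i+1] and
    ``backward[i]`` for the reverse step.  ``conducting`` names the
    open (current-passing) states.
    """

    states: tuple[str, ...]
    forward: tuple[RateLaw, ...]
    backward: tuple[RateLaw, ...]
    conducting: frozenset[str]

    def __post_init__(self) -> None:
        n = len(self.states)
        if n < 2:
            raise ValueError("a chain needs at least two states")
        if len(set(self.states)) != n:
            raise ValueError("state labels must be unique")
        if len(self.forward) != n - 1 or len(self.backward) != n - 1:
            raise ValueError("need exactly one forward and one backward "
                             "rate law per adjacent pair")
        if not self.conducting:
            raise ValueError("at least one conducting state is required")
        unknown = self.conducting - set(self.states)
        if unknown:
            raise ValueError(f"conducting labels not in chain: {sorted(unknown)}")

    @property
    def n_states(self) -> int:
        return len(self.states)

    def conducting_mask(self) -> np.ndarray:
        return np.array([s in self.conducting for s in self.states])

    def index(self, label: str) -> int:
        return self.states.index(label)

    def extended(self, state: str, forward: RateLaw,
                 backward: RateLaw) -> "GatingScheme":
        """Append a terminal state (e.g. an inactivated state after O)."""
        return GatingScheme(self.states + (state,),
                            self.forward + (forward,),
                            self.backward + (backward,),
                            self.conducting)


def build_scheme1(params: ModelParams | None = None) -> GatingScheme:
    """The C1 - C2 - O activation scheme with its fixed voltage coefficients.

    The first step (C1-C2) has low voltage sensitivity, the second (C2-O)
    high; prefactors default to the calibrated wild-type set.
    """
    if params is None:
        from .params import WT_PARAMS
        params = WT_PARAMS
    return GatingScheme(
        states=("C1", "C2", "O"),
        forward=(RateLaw(params.A1_0, COEFF_K1),
                 RateLaw(params.A2_0, COEFF_K2)),
        backward=(RateLaw(params.B1_0, COEFF_KM1),
                  RateLaw(params.B2_0, COEFF_KM2)),
        conducting=frozenset({"O"}),
    )


def generator_matrix(scheme: GatingScheme, v: float) -> np.ndarray:
    """Generator Q(V) of the master equation dp/dt = Q p.

    Off-diagonal Q[j, i] is the rate i -> j; columns sum to zero so total
    occupancy is conserved.
    """
    n = scheme.n_states
    q = np.zeros((n, n))
    for i in range(n - 1):
        kf = scheme.forward[i].rate(v)
        kb = scheme.backward[i].rate(v)
        q[i + 1, i] += kf
        q[i, i] -= kf
        q[i, i + 1] += kb
        q[i + 1, i + 1] -= kb
    return q


def _check_occupancy(p: np.ndarray, n: int) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.shape != (n,):
        raise ValueError(f"occupancy must have shape ({n},), got {p.shape}")
    if not np.all(np.isfinite(p)):
        raise ValueError("occupancy entries must be finite")
    if np.any(p < -1e-12) or abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("occupancy entries must be >= 0 and sum to 1")
    return np.clip(p, 0.0, None)


def equilibrium_occupancy(scheme: GatingScheme, v: float) -> np.ndarray:
    """Stationary occupancy at voltage `v`: the normalised null vector of Q.

    For a chain obeying detailed balance this equals the product formula
    p_i proportional to prod_{j<i} K_j with K_j = kf_j/kb_j.
    """
    q = generator_matrix(scheme, v)
    # Null space of a singular generator; solved as an eigenproblem for
    # robustness across rate magnitudes.
    w, vecs = np.linalg.eig(q)
    idx = int(np.argmin(np.abs(w)))
    p = np.real(vecs[:, idx])
    p = p / p.sum()
    return _check_occupancy(p, scheme.n_states)


def _propagate_times(q: np.ndarray, p0: np.ndarray,
                     times: np.ndarray) -> np.ndarray:
    """Exact solutions p(t) = expm(Q t) p0 at the requested times.

    Uses the eigendecomposition of Q when its eigenbasis is well
    conditioned, falling back to per-time matrix exponentials otherwise.
    """
    try:
        w, vr = np.linalg.eig(q)
        cond = np.linalg.cond(vr)
        if not np.isfinite(cond) or cond > 1e10:
            raise np.linalg.LinAlgError("ill-conditioned eigenbasis")
        coeff = np.linalg.solve(vr, p0.astype(complex))
    except np.linalg.LinAlgError:
        return np.stack([expm(q * t) @ p0 for t in times])
    modes = np.exp(np.outer(times, w))  # (T, n)
    return np.real((vr[None, :, :] * (modes * coeff)[:, None, :]).sum(axis=2))


def relax_piecewise(scheme: GatingScheme, p0: np.ndarray,
                    segments: list[tuple[float, float]],
                    dt: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
    """Propagate occupancy through piecewise-constant voltage segments.

    Parameters
    ----------
    p0 : initial occupancy.
    segments : list of (voltage mV, duration ms) pairs.
    dt : output sampling interval, ms.  Controls only where the exact
        solution is sampled, never its accuracy.

    Returns
    -------
    times, occupancies : (T,), (T, n_states); includes t = 0 and every
    segment boundary.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    p = _check_occupancy(np.asarray(p0, dtype=float), scheme.n_states)
    all_t = [0.0]
    all_p = [p]
    t0 = 0.0
    for v, duration in segments:
        if not (np.isfinite(v) and np.isfinite(duration) and duration > 0):
            raise ValueError(f"bad segment (V={v!r}, duration={duration!r})")
        q = generator_matrix(scheme, v)
        local = np.arange(dt, duration, dt)
        if local.size == 0 or not np.isclose(local[-1], duration):
            local = np.append(local, duration)
        sol = _propagate_times(q, p, local)
        all_t.extend((t0 + local).tolist())
        all_p.extend(list(sol))
        p = sol[-1]
        t0 += duration
    times = np.array(all_t)
    occ = np.vstack(all_p)
    occ = np.clip(occ, 0.0, None)
    occ /= occ.sum(axis=1, keepdims=True)
    return times, occ


def macroscopic_taus(scheme: GatingScheme, v: float,
                     _retry: bool = True) -> np.ndarray:
    """Relaxation time constants at `v`: tau_i = -1/lambda_i, ascending.

    The zero eigenvalue (stationary mode) is excluded.  A numerically
    degenerate spectrum is resolved by perturbing V by 1e-9 mV, with a
    warning (at most once; for voltage-insensitive rate laws the
    degeneracy is structural and the values are returned as-is).
    """
    q = generator_matrix(scheme, v)
    w = np.linalg.eigvals(q)
    w = np.real(w)
    nz = np.delete(w, int(np.argmin(np.abs(w))))
    if nz.size > 1:
        s = np.sort(nz)
        if np.any(np.abs(np.diff(s)) <= 1e-9 * np.abs(s[:-1])):
            warnings.warn("degenerate generator spectrum; perturbing V by "
                          "1e-9 mV", DegenerateSpectrumWarning)
            if _retry:
                return macroscopic_taus(scheme, v + 1e-9, _retry=False)
    taus = np.sort(-1.0 / nz)
    return taus
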