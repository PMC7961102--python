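"""Sigmoid crossover model for twist/flatness transitions at a boundary.

Across a decoration boundary the per-subunit twist (and the flatness
dihedral phi) switches between its bare-actin and cofilactin values over a
characteristic crossover length.  The transition is modelled as

    theta(n) = A2 - (A2 - A1) / (1 + exp((n - n0) / N))

where n is subunit position relative to the interfacial subunit, A1 and A2
are the barbed- and pointed-side asymptotes (degrees), n0 the crossover
center and N > 0 the crossover (exponential decay) length in subunits.
"""

from __future__ import annotations

from dataclasses import dataclass
import json
from pathlib import Path

import numpy as np
from scipy.optimize import curve_fit

from cofilsev.errors import ConfigurationError, InputError, NoTransitionError
from cofilsev.geometry_analysis import AngleProfile

#: Representative boundary-transition parameter sets for the twist and
#: flatness observables at slow- and fast-severing boundaries, used as
#: generating truth by the synthetic-data module and in recovery tests.
REFERENCE_TRANSITIONS: dict[str, "TransitionParams"]


@dataclass(frozen=True)
class TransitionParams:
    """(A1, A2, n0, N) of the boundary transition model."""

    a1: float
    a2: float
    n0: float
    crossover: float  # N, subunits

    def __post_init__(self) -> None:
        if self.crossover <= 0:
            raise ConfigurationError("crossover length N must be positive")


@dataclass(frozen=True)
class TransitionFitResult:
    params: TransitionParams
    rss: float
    converged: bool
    stderr: tuple[float, float, float, float] | None = None

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {
                "A1_deg": self.params.a1,
                "A2_deg": self.params.a2,
                "n0": self.params.n0,
                "N": self.params.crossover,
                "rss": self.rss,
                "converged": self.converged,
            },
            indent=1,
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload


REFERENCE_TRANSITIONS = {
    "slow_twist": TransitionParams(165.1, 155.1, 1.4, 1.1),
    "fast_twist": TransitionParams(150.0, 169.4, 0.1, 2.9),
    "slow_phi": TransitionParams(-9.0, -28.9, -0.3, 1.1),
    "fast_phi": TransitionParams(-29.4, -4.2, 2.2, 2.8),
}


def evaluate_transition(params: TransitionParams, n: float | np.ndarray) -> float | np.ndarray:
    """theta(n) = A2 - (A2 - A1) / (1 + exp((n - n0)/N)).

    Limits: theta -> A1 as n -> -inf (barbed side), theta -> A2 as n -> +inf.
    """
    n = np.asarray(n, dtype=float)
    # clip the exponent to avoid overflow far from the boundary
    z = np.clip((n - params.n0) / params.crossover, -500.0, 500.0)
    out = params.a2 - (params.a2 - params.a1) / (1.0 + np.exp(z))
    return float(out) if out.ndim == 0 else out


def _initial_guess(pos: np.ndarray, mean: np.ndarray) -> tuple[float, float, float, float]:
    a1 = float(mean[:3].mean())   # barbed side = lowest positions
    a2 = float(mean[-3:].mean())
    mid = 0.5 * (a1 + a2)
    n0 = float(pos[len(pos) // 2])
    for j in range(len(pos) - 1):
        lo, hi = mean[j] - mid, mean[j + 1] - mid
        if lo == 0.0:
            n0 = float(pos[j])
            break
        if lo * hi < 0:
            frac = lo / (lo - hi)
            n0 = float(pos[j] + frac * (pos[j + 1] - pos[j]))
            break
    return a1, a2, n0, 1.0


def fit_transition(
    profile: AngleProfile, weighting: str = "none"
) -> TransitionFitResult:
    """Nonlinear least-squares fit of the transition model to a profile.

    Fits the per-position means (optionally weighted by the inverse
    per-position variance).  Raises :class:`NoTransitionError` when the two
    side estimates differ by less than 0.5 degrees.
    """
    pos = np.asarray(profile.positions, dtype=float)
    mean = profile.position_mean
    finite = np.isfinite(mean)
    pos, mean = pos[finite], mean[finite]
    if pos.size < 5:
        raise InputError(f"need at least 5 positions to fit, got {pos.size}")
    if weighting not in ("none", "inverse-variance"):
        raise ConfigurationError(f"unknown weighting '{weighting}'")

    a1, a2, n0, width = _initial_guess(pos, mean)
    if abs(a1 - a2) < 0.5:
        raise NoTransitionError(
            f"no transition detected: side estimates {a1:.2f} and {a2:.2f} "
            "within 0.5 degrees"
        )

    sigma = None
    if weighting == "inverse-variance":
        sd = profile.position_sd[finite]
        sigma = np.where(sd > 1e-12, sd, np.nanmax([sd.max(), 1e-12]))

    def model(n, a1_, a2_, n0_, width_):
        return evaluate_transition(TransitionParams(a1_, a2_, n0_, width_), n)

    lower = [-np.inf, -np.inf, -np.inf, 0.05]
    upper = [np.inf, np.inf, np.inf, np.inf]
    try:
        popt, pcov = curve_fit(
            model,
            pos,
            mean,
            p0=[a1, a2, n0, max(width, 0.05)],
            sigma=sigma,
            bounds=(lower, upper),
            maxfev=20000,
        )
        converged = bool(np.all(np.isfinite(popt)))
    except RuntimeError:
        popt, pcov = np.array([a1, a2, n0, width]), None
        converged = False

    params = TransitionParams(*[float(v) for v in popt])
    resid = mean - np.asarray(evaluate_transition(params, pos))
    stderr = None
    if pcov is not None and np.all(np.isfinite(pcov)):
        stderr = tuple(float(v) for v in np.sqrt(np.diag(pcov)))
    return TransitionFitResult(
        params=params,
        rss=float(np.sum(resid**2)),
        converged=converged,
        stderr=stderr,
    )
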