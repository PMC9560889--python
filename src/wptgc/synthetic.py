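"""Ground-truth generators: coupled polynomial difference-equation pairs,
time-varying coupling profiles, and narrowband oscillatory pairs.

Every generator is deterministic given its seed.  Fixture specs in
`FIXTURES` freeze the canonical test systems; their truth records carry
enough structure to compute expected causality for the linear cases in
closed form.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as sps

from .narx import ModelTerm

__all__ = [
    "SimSpec",
    "CouplingProfile",
    "simulate_narx_pair",
    "simulate_banded_pair",
    "make_fixture",
    "FIXTURES",
]

_DIVERGENCE_LIMIT = 1e6


@dataclass(frozen=True)
class CouplingProfile:
    """Time-indexed multiplier applied to cross (input-bearing) terms.

    kind: "constant" (always ``level``), "step" (0 before ``t_switch``
    fraction of the horizon, ``level`` after), or "ramp" (linear 0 ->
    ``level`` across the horizon).
    """

    kind: str = "constant"
    level: float = 1.0
    t_switch: float = 0.5     # fraction of the post-burn-in horizon

    def __post_init__(self):
        if self.kind not in ("constant", "step", "ramp"):
            raise ValueError(f"unknown coupling profile kind {self.kind!r}")

    def multiplier(self, t: int, n: int) -> float:
        if self.kind == "constant":
            return self.level
        frac = t / max(n - 1, 1)
        if self.kind == "step":
            return self.level if frac >= self.t_switch else 0.0
        return self.level * frac  # ramp


@dataclass(frozen=True)
class SimSpec:
    """Generative description of a coupled pair of difference equations.

    In ``y_terms`` a ModelTerm's y_lags index y itself and x_lags index
    x; in ``x_terms`` the roles flip (y_lags index x, x_lags index y).
    The coupling profile scales every input-bearing (cross) term.
    """

    n_samples: int
    fs: float
    y_terms: dict[ModelTerm, float]
    x_terms: dict[ModelTerm, float]
    coupling_profile: CouplingProfile = CouplingProfile()
    noise_sd: tuple[float, float] = (1.0, 1.0)   # (y, x)
    burn_in: int = 500
    seed: int = 0

    def __post_init__(self):
        max_lag = self.max_lag
        if self.burn_in < 10 * max_lag:
            raise ValueError(
                f"burn_in {self.burn_in} < 10 * max lag ({10 * max_lag})"
            )
        if self.n_samples < 1:
            raise ValueError("n_samples must be positive")

    @property
    def max_lag(self) -> int:
        lags = [1]
        for terms in (self.y_terms, self.x_terms):
            for t in terms:
                lags.extend(t.y_lags)
                lags.extend(t.x_lags)
        return max(lags)


def _eval_term(term: ModelTerm, own: np.ndarray, other: np.ndarray,
               t: int) -> float:
    v = 1.0
    for l in term.y_lags:
        v *= own[t - l]
    for l in term.x_lags:
        v *= other[t - l]
    return v


def simulate_narx_pair(spec: SimSpec):
    """Iterate the pair of difference equations with Gaussian innovations.

    Returns (x, y, truth) where ``truth`` records active terms, base
    coefficients, coupling direction(s) and the switch time if any.
    Raises on divergence (any |sample| > 1e6), naming the first sample.
    """
    rng = np.random.default_rng(spec.seed)
    total = spec.burn_in + spec.n_samples
    ey = rng.standard_normal(total) * spec.noise_sd[0]
    ex = rng.standard_normal(total) * spec.noise_sd[1]
    y = np.zeros(total)
    x = np.zeros(total)
    prof = spec.coupling_profile
    for t in range(spec.max_lag, total):
        # profile time runs over the post-burn-in horizon
        tp = max(t - spec.burn_in, 0)
        c = prof.multiplier(tp, spec.n_samples)
        vy = ey[t]
        for term, coef in spec.y_terms.items():
            mult = c if term.uses_input else 1.0
            vy += mult * coef * _eval_term(term, y, x, t)
        vx = ex[t]
        for term, coef in spec.x_terms.items():
            mult = c if term.uses_input else 1.0
            vx += mult * coef * _eval_term(term, x, y, t)
        if abs(vy) > _DIVERGENCE_LIMIT or abs(vx) > _DIVERGENCE_LIMIT:
            raise RuntimeError(
                f"simulation diverged at sample {t - spec.burn_in} "
                f"(|value| > {_DIVERGENCE_LIMIT:g}); check stability of the "
                "declared system"
            )
        y[t] = vy
        x[t] = vx
    truth = {
        "y_terms": {t.label(): c for t, c in spec.y_terms.items()},
        "x_terms": {t.label(): c for t, c in spec.x_terms.items()},
        "coupling_x_to_y": any(t.uses_input for t in spec.y_terms),
        "coupling_y_to_x": any(t.uses_input for t in spec.x_terms),
        "profile": spec.coupling_profile.kind,
        "t_switch_s": (
            spec.coupling_profile.t_switch * spec.n_samples / spec.fs
            if spec.coupling_profile.kind == "step" else None
        ),
        "noise_sd": spec.noise_sd,
        "seed": spec.seed,
        "fs": spec.fs,
    }
    sl = slice(spec.burn_in, None)
    return x[sl].copy(), y[sl].copy(), truth


def simulate_banded_pair(f_c: float, lag: int = 2, coupling: float = 0.8,
                         snr: float = 5.0, n: int = 3584, fs: float = 250.0,
                         seed: int = 0, bandwidth: float = 1.5):
    """Narrowband stochastic pair with a lagged unidirectional coupling.

    x is clean band-limited noise centred at ``f_c`` plus broadband noise
    whose spectrum is notched out around ``f_c`` (so x's driving band is
    noise-free but every analysis band of x carries signal); y is
    ``coupling * x_band(t - lag)`` plus white noise scaled so the
    coupled-band to noise-band power ratio at ``f_c`` is ``snr``.  Both
    outputs are z-scored.  A ~1 Hz analysis band holds roughly
    fs/2^(levels+1) independent samples per second, so detection needs
    tens of seconds of data: the default n is ~14 s at 250 Hz.
    """
    if not 0 < f_c < fs / 2:
        raise ValueError(f"f_c must lie in (0, {fs / 2})")
    if snr <= 0:
        raise ValueError(f"snr must be positive, got {snr}")
    if lag < 0:
        raise ValueError("lag must be non-negative")
    rng = np.random.default_rng(seed)
    pad = 4 * lag + 300
    total = n + pad
    lo = max(f_c - bandwidth / 2, 0.1)
    hi = min(f_c + bandwidth / 2, fs / 2 - 0.1)
    sos = sps.butter(2, [lo, hi], btype="bandpass", fs=fs, output="sos")
    x_nb = sps.sosfiltfilt(sos, rng.standard_normal(total))
    x_nb /= x_nb.std()
    coupled = coupling * np.roll(x_nb, lag)
    noise = rng.standard_normal(total)
    # white noise puts ~bandwidth/(fs/2) of its power into the f_c band;
    # an uncoupled pair keeps unit-power noise so y is pure noise
    ref_var = coupled.var() if coupling != 0 else x_nb.var()
    noise *= np.sqrt(ref_var / (snr * bandwidth / (fs / 2)))
    y = coupled + noise
    stop_lo = max(f_c - 2 * bandwidth, 0.5)
    stop_hi = min(f_c + 2 * bandwidth, fs / 2 - 1.0)
    sos_stop = sps.butter(2, [stop_lo, stop_hi], btype="bandstop", fs=fs,
                          output="sos")
    x = x_nb + 0.3 * sps.sosfiltfilt(sos_stop, rng.standard_normal(total))
    x, y = x[pad:], y[pad:]
    x = (x - x.mean()) / x.std()
    y = (y - y.mean()) / y.std()
    return x, y


def _fixture_specs() -> dict[str, SimSpec]:
    y1 = ModelTerm(y_lags=(1,))
    x1 = ModelTerm(x_lags=(1,))
    return {
        # two independent AR(1) processes, zero cross coefficients
        "null_pair": SimSpec(
            n_samples=5000, fs=250.0,
            y_terms={y1: 0.8}, x_terms={y1: 0.8},
            noise_sd=(1.0, 1.0), seed=101,
        ),
        # y(t) = 0.8 y(t-1) + 0.5 x(t-1) + e, x white: GC x->y = ln(1.25)
        "linear_unidirectional": SimSpec(
            n_samples=10000, fs=250.0,
            y_terms={y1: 0.8, x1: 0.5}, x_terms={},
            noise_sd=(1.0, 1.0), seed=202,
        ),
        # y(t) = 0.5 y(t-1) + 0.3 x(t-1)^2 + e, x white: invisible to a
        # linear model in expectation (all odd cross-moments vanish)
        "quadratic_unidirectional": SimSpec(
            n_samples=4000, fs=250.0,
            y_terms={y1: 0.5, ModelTerm(x_lags=(1, 1)): 0.3},
            x_terms={},
            noise_sd=(1.0, 1.0), seed=303,
        ),
        # weak coupling both ways, stable
        "bidirectional": SimSpec(
            n_samples=5000, fs=250.0,
            y_terms={y1: 0.6, x1: 0.4},
            x_terms={y1: 0.6, x1: 0.3},
            noise_sd=(1.0, 1.0), seed=404,
        ),
        # coupling switched on at the midpoint of a 7 s segment
        "step_coupling": SimSpec(
            n_samples=1750, fs=250.0,
            y_terms={y1: 0.5, x1: 0.5}, x_terms={},
            coupling_profile=CouplingProfile(kind="step", level=1.0,
                                             t_switch=0.5),
            noise_sd=(1.0, 1.0), seed=505,
        ),
    }


FIXTURES = tuple(sorted(_fixture_specs()) + ["banded_20hz"])

#: parameters of the banded_20hz fixture (consumed by simulate_banded_pair)
BANDED_20HZ_PARAMS = dict(f_c=20.0, lag=2, coupling=0.8, snr=5.0, n=3584,
                          fs=250.0, seed=606)


def make_fixture(name: str, seed: int | None = None,
                 n_samples: int | None = None) -> SimSpec:
    """Return the canonical frozen spec for a registered fixture.

    ``banded_20hz`` is generated by `simulate_banded_pair`, not a
    difference-equation spec; request it via `generate_fixture` instead.
    """
    specs = _fixture_specs()
    if name not in specs:
        raise KeyError(
            f"unknown fixture {name!r}; registered fixtures: "
            f"{', '.join(FIXTURES)}"
        )
    spec = specs[name]
    if seed is not None:
        spec = replace(spec, seed=seed)
    if n_samples is not None:
        spec = replace(spec, n_samples=n_samples)
    return spec


def generate_fixture(name: str, seed: int | None = None,
                     n_samples: int | None = None):
    """Generate (x, y, truth) for any registered fixture by name."""
    if name == "banded_20hz":
        params = dict(BANDED_20HZ_PARAMS)
        if seed is not None:
            params["seed"] = seed
        if n_samples is not None:
            params["n"] = n_samples
        x, y = simulate_banded_pair(**params)
        truth = {"coupling_x_to_y": True, "coupling_y_to_x": False,
                 "f_c": params["f_c"], "lag": params["lag"],
                 "seed": params["seed"], "fs": params["fs"]}
        return x, y, truth
    return simulate_narx_pair(make_fixture(name, seed=seed,
                                           n_samples=n_samples))
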