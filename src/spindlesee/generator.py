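"""Synthetic series-elastic MTU + muscle spindle trial generator.

The generator produces :class:`~spindlesee.records.TrialRecord` objects with
the mechanical and firing structure the analysis pipeline assumes, under
CTRL and SEE conditions with known ground truth.

Mechanics
---------
The muscle–tendon unit is a passive fascicle in series with an elastic
element. The fascicle is a quasi-static nonlinear spring (``k_lin`` +
``k_quad``) with a viscous damper (``c_damp``) and a single Maxwell branch
(``k_relax``, ``tau_relax``) that produces hold-phase stress relaxation and
fascicle creep. The series element is Hookean with stiffness ``k_tendon``
(CTRL) or the series combination of ``k_tendon`` and the added spring
``k_see`` (SEE condition), which is always softer than ``k_tendon`` alone.
At every sample the fascicle force balances the series-element force
``k_series * (L_MTU - x_fas)``.

Firing
------
The afferent rate is a rectified force/yank model:

    r(t) = max(0, r0 + kF * F(t) + kY * [dF/dt]_+ * g(t))

with ``g = 1`` on the first stretch of a trial and ``1 - slack_gain`` on
subsequent stretches — a phenomenological stand-in for the history-dependent
(thixotropic) loss of intrafusal stiffness that abolishes the initial burst
on repeated stretches. Spikes are drawn by deterministic
integrate-to-threshold on the rate trace, optionally perturbed by seeded
Gaussian rate noise (``noise_sd``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict, replace
from typing import Iterable, Optional, Sequence

import numpy as np

from .protocols import ProtocolSpec, make_command, PRESETS
from .records import TrialRecord

logger = logging.getLogger(__name__)


class SolverError(RuntimeError):
    """Raised when the series force-balance cannot be solved."""


@dataclass(frozen=True)
class GeneratorParams:
    """Ground-truth parameters of the synthetic MTU + spindle.

    Stiffnesses in N/mm, damping in N·s/mm, rate gains in pps/N (``kF``)
    and pps·s/N (``kY``), times in s, rates in pps.
    """

    k_lin: float = 0.25        # fascicle linear stiffness
    k_quad: float = 0.08       # fascicle stiffening, N/mm^2
    c_damp: float = 0.08       # fascicle viscous damping
    k_tendon: float = 2.0      # baseline series stiffness (CTRL)
    k_see: float = 2.0         # added spring, series-combined in SEE trials
    k_relax: float = 0.15      # Maxwell-branch stiffness (stress relaxation)
    tau_relax: float = 0.4     # Maxwell relaxation time constant
    kF: float = 6.0            # rate gain on force
    kY: float = 16.0           # rate gain on positive yank
    r0: float = 5.0            # baseline rate
    slack_gain: float = 0.85   # second-stretch yank attenuation, in [0, 1]
    noise_sd: float = 2.0      # Gaussian rate noise, pps
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("k_lin", "k_tendon", "k_see"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        for name in ("k_quad", "c_damp", "k_relax", "tau_relax", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if not 0.0 <= self.slack_gain <= 1.0:
            raise ValueError(f"slack_gain must be in [0, 1], got {self.slack_gain}")

    def series_stiffness(self, condition: str) -> float:
        """Effective series stiffness for a condition (N/mm).

        SEE places the added spring in series with the tendon, so the
        combined stiffness ``(1/k_tendon + 1/k_see)^-1`` is always below
        ``k_tendon``.
        """
        if condition == "CTRL":
            return self.k_tendon
        if condition == "SEE":
            return 1.0 / (1.0 / self.k_tendon + 1.0 / self.k_see)
        raise ValueError(f"unknown condition {condition!r}")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorParams":
        return cls(**d)

    def replace(self, **kw) -> "GeneratorParams":
        return replace(self, **kw)


def solve_series_mechanics(
    time: np.ndarray,
    command: np.ndarray,
    params: GeneratorParams,
    condition: str = "CTRL",
    return_internals: bool = False,
):
    """Partition an MTU length command between fascicle and series element.

    Steps the force balance with an implicit-Euler scheme whose per-sample
    update reduces to one quadratic root (exact when damping and relaxation
    are zero, i.e. the purely algebraic spring-in-series case).

    Parameters
    ----------
    time, command : ndarray
        Uniform time grid (s) and commanded MTU displacement (mm); the
        command must start at 0 (stretch from rest).
    condition : {"CTRL", "SEE"}

    Returns
    -------
    fascicle_length, mtu_force : ndarray
        Fascicle displacement (mm) and MTU force (N). With
        ``return_internals=True`` also returns a dict with the Maxwell-branch
        force ``q`` and backward-difference fascicle velocity ``v``.
    """
    time = np.asarray(time, float)
    L = np.asarray(command, float)
    if L.shape != time.shape:
        raise ValueError("time and command must have the same shape")
    if abs(L[0]) > 1e-12:
        raise ValueError(f"command must start at 0 mm, got {L[0]}")
    k_s = params.series_stiffness(condition)
    dt = float(time[1] - time[0])
    kq, kl, c = params.k_quad, params.k_lin, params.c_damp
    kr, tau = params.k_relax, params.tau_relax
    use_relax = kr > 0 and tau > 0
    alpha = 1.0 / (1.0 + dt / tau) if use_relax else 0.0
    cdt = c / dt
    B = kl + k_s + cdt + alpha * kr

    n = time.size
    x = np.zeros(n)
    q = np.zeros(n)
    xi = 0.0
    qi = 0.0
    for i in range(1, n):
        # balance: kq*x^2 + B*x = R  (fascicle force + damper + Maxwell
        # branch against the series spring at sample i)
        R = k_s * L[i] + cdt * xi + alpha * (kr * xi - qi)
        if kq > 0.0:
            disc = B * B + 4.0 * kq * R
            if disc < 0.0:
                raise SolverError(
                    f"series force balance has no real solution at sample {i} "
                    f"(t = {time[i]:.6f} s)")
            xn = (-B + disc ** 0.5) / (2.0 * kq)
        else:
            xn = R / B
        qi = alpha * (qi + kr * (xn - xi)) if use_relax else 0.0
        xi = xn
        x[i] = xn
        q[i] = qi
    force = k_s * (L - x)
    if return_internals:
        v = np.empty(n)
        v[0] = 0.0
        v[1:] = np.diff(x) / dt
        return x, force, {"q": q, "v": v, "k_series": k_s}
    return x, force


def force_balance_residual(
    time: np.ndarray,
    command: np.ndarray,
    fascicle_length: np.ndarray,
    params: GeneratorParams,
    condition: str = "CTRL",
) -> np.ndarray:
    """Residual fascicle-minus-series force (N) for a solved trajectory.

    Independent bookkeeping of the solver's discretization: reconstructs the
    damper and Maxwell-branch forces from the fascicle trajectory alone and
    returns ``F_fascicle - F_series`` at every sample.
    """
    time = np.asarray(time, float)
    L = np.asarray(command, float)
    x = np.asarray(fascicle_length, float)
    dt = float(time[1] - time[0])
    k_s = params.series_stiffness(condition)
    use_relax = params.k_relax > 0 and params.tau_relax > 0
    alpha = 1.0 / (1.0 + dt / params.tau_relax) if use_relax else 0.0
    v = np.zeros_like(x)
    v[1:] = np.diff(x) / dt
    q = np.zeros_like(x)
    if use_relax:
        for i in range(1, x.size):
            q[i] = alpha * (q[i - 1] + params.k_relax * (x[i] - x[i - 1]))
    f_fas = params.k_lin * x + params.k_quad * x ** 2 + params.c_damp * v + q
    f_ser = k_s * (L - x)
    res = f_fas - f_ser
    res[0] = 0.0
    return res


def spindle_rate(
    time: np.ndarray,
    mtu_force: np.ndarray,
    params: GeneratorParams,
    stretch_onsets: Optional[Sequence[float]] = None,
) -> np.ndarray:
    """Rectified force/yank firing-rate trace (pps).

    ``stretch_onsets`` are the onset times of successive stretches (or
    sinusoid cycles) within the trial; the yank term is scaled by
    ``1 - slack_gain`` from the second onset onwards.
    """
    time = np.asarray(time, float)
    F = np.asarray(mtu_force, float)
    if not np.all(np.isfinite(F)):
        raise ValueError("mtu_force must be finite")
    yank = np.gradient(F, time)
    yank_pos = np.clip(yank, 0.0, None)
    g = np.ones_like(F)
    if stretch_onsets is not None and len(stretch_onsets) > 1:
        g[time >= stretch_onsets[1]] = 1.0 - params.slack_gain
    r = params.r0 + params.kF * F + params.kY * yank_pos * g
    return np.clip(r, 0.0, None)


def rate_to_spikes(
    time: np.ndarray,
    rate: np.ndarray,
    rng: Optional[np.random.Generator] = None,
    noise_sd: float = 0.0,
) -> np.ndarray:
    """Deterministic integrate-to-threshold spike generation.

    A spike is emitted each time the integrated rate crosses a successive
    integer; crossing times are located by linear interpolation within the
    sample interval. Optional seeded Gaussian noise (``noise_sd``, pps) is
    added to the rate trace before integration.
    """
    time = np.asarray(time, float)
    r = np.asarray(rate, float)
    if np.any(r < 0):
        raise ValueError("rate must be >= 0 everywhere")
    if noise_sd > 0.0:
        if rng is None:
            raise ValueError("noise_sd > 0 requires an rng")
        r = np.clip(r + rng.normal(0.0, noise_sd, r.shape), 0.0, None)
    dt = float(time[1] - time[0])
    # cumulative trapezoid of the rate = expected spike count up to t
    phi = np.concatenate(([0.0], np.cumsum((r[1:] + r[:-1]) * 0.5 * dt)))
    total = phi[-1]
    n_spk = int(np.floor(total + 1e-9))
    if n_spk < 1:
        return np.empty(0)
    thresholds = np.arange(1, n_spk + 1, dtype=float)
    idx = np.searchsorted(phi, thresholds)
    idx = np.clip(idx, 1, phi.size - 1)
    lo, hi = phi[idx - 1], phi[idx]
    frac = np.where(hi > lo, (thresholds - lo) / np.where(hi > lo, hi - lo, 1.0), 1.0)
    spikes = time[idx - 1] + frac * dt
    spikes = np.minimum(spikes, time[-1])
    # guard against ties from flat (zero-rate) segments
    keep = np.concatenate(([True], np.diff(spikes) > 0))
    return spikes[keep]


# --------------------------------------------------------------------- #
# Trial / dataset assembly
# --------------------------------------------------------------------- #

def generate_trial(
    protocol: ProtocolSpec,
    params: GeneratorParams = GeneratorParams(),
    condition: str = "CTRL",
    animal_id: str = "A1",
    afferent_id: str = "A1.u1",
    trial_id: str = "",
    seed: Optional[int] = None,
) -> TrialRecord:
    """Generate one synthetic stretch trial with known ground truth.

    All randomness is routed through one ``numpy`` generator seeded with
    ``seed`` (falling back to ``params.seed``), so an identical seed yields
    a bit-identical trial.
    """
    seed = params.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    t, cmd = make_command(protocol)
    x_fas, force = solve_series_mechanics(t, cmd, params, condition)
    rate = spindle_rate(t, force, params, protocol.stretch_onsets())
    spikes = rate_to_spikes(t, rate, rng=rng, noise_sd=params.noise_sd)
    return TrialRecord(
        time=t, mtu_length=cmd, mtu_force=force, fascicle_length=x_fas,
        spike_times=spikes, animal_id=animal_id, afferent_id=afferent_id,
        condition=condition, protocol=protocol,
        trial_id=trial_id or f"{afferent_id}.{condition}.{protocol.kind}.{seed}",
        ground_truth=params,
        provenance={"source": "synthetic", "seed": int(seed)},
    )


def generate_dataset(
    protocols: Iterable[ProtocolSpec] | Iterable[str] = ("ramp_hold",),
    params: GeneratorParams = GeneratorParams(),
    n_animals: int = 5,
    afferents_per_animal: int = 2,
    trials_per_condition: int = 4,
    conditions: Sequence[str] = ("CTRL", "SEE"),
    seed: int = 0,
    animal_sd: float = 0.15,
    afferent_sd: float = 0.2,
    trial_sd: float = 0.05,
) -> list[TrialRecord]:
    """Generate a multi-animal, multi-afferent synthetic dataset.

    Between-animal variability scales the mechanical stiffnesses by a
    log-normal factor (``animal_sd``, log scale) and between-afferent
    variability scales the rate gains (``afferent_sd``), giving the
    random-intercept structure the mixed-model stage assumes. Each trial's
    spike noise is seeded independently from the master ``seed``.
    """
    master = np.random.default_rng(seed)
    protos = [PRESETS[p]() if isinstance(p, str) else p for p in protocols]
    trials: list[TrialRecord] = []
    for a in range(n_animals):
        mech = float(np.exp(master.normal(0.0, animal_sd)))
        animal = f"A{a + 1}"
        p_animal = params.replace(
            k_lin=params.k_lin * mech, k_quad=params.k_quad * mech,
            k_tendon=params.k_tendon * mech)
        for u in range(afferents_per_animal):
            gain = float(np.exp(master.normal(0.0, afferent_sd)))
            p_aff = p_animal.replace(
                kF=params.kF * gain, kY=params.kY * gain, r0=params.r0 * gain)
            afferent = f"{animal}.u{u + 1}"
            for proto in protos:
                for cond in conditions:
                    for k in range(trials_per_condition):
                        trial_seed = int(master.integers(0, 2 ** 31 - 1))
                        tg = float(np.exp(master.normal(0.0, trial_sd)))
                        p_trial = p_aff.replace(kF=p_aff.kF * tg,
                                                kY=p_aff.kY * tg)
                        trials.append(generate_trial(
                            proto, p_trial, cond, animal, afferent,
                            trial_id=f"{afferent}.{cond}.{proto.kind}.{k}",
                            seed=trial_seed))
    logger.info("generated %d synthetic trials (seed %d)", len(trials), seed)
    return trials
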