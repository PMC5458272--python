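"""Surface plasmon resonance: stepwise-injection simulation and fitting.

Covers the in-vitro arm of the screening cascade:

* **FastStep simulation** — 1:1 Langmuir kinetics under a stepwise
  injection program (doubling analyte concentrations in one run, a single
  dissociation phase).  With piecewise-constant analyte concentration the
  ODE ``dR/dt = kon*C*(Rmax - R) - koff*R`` has an exponential closed
  form per step, which is what the simulator evaluates (no numerical
  integrator, no drift).

* **Scatchard fitting** — equilibrium responses at each concentration are
  linearised as RU/C against RU; the slope is ``-1/Kd`` and the
  x-intercept ``Rmax``.

* **Kinetic fitting** — full-trace nonlinear least squares on
  ``(kon, koff, Rmax)`` for ladders too fast-stepped to equilibrate.

* **Competition** — equilibrium competitive binding of a small molecule
  against a high-affinity partner protein injected at fixed
  concentration; the read-out is the partner's RU signal (the inhibitor's
  own mass contribution is assumed subtracted).  IC50 comes from a
  four-parameter logistic fit and relates to the inhibition constant via
  the competitive-binding relation ``IC50 = Ki * (1 + [P]/Kd_P)``.

Units: concentrations in molar, time in seconds, responses in RU.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit, least_squares

__all__ = [
    "InjectionProgram",
    "Sensorgram",
    "BindingFit",
    "CompetitionFit",
    "FASTSTEP_LADDER_UM",
    "simulate_faststep",
    "equilibrium_response",
    "step_end_response",
    "scatchard_fit",
    "kinetic_fit",
    "simulate_equilibrium_titration",
    "competition_response",
    "simulate_competition",
    "ic50_fit",
    "ki_to_ic50",
]

#: The six-step doubling ladder used for compound titrations (micromolar).
FASTSTEP_LADDER_UM = (0.94, 1.875, 3.75, 7.5, 15.0, 30.0)

#: Default association rate for simulations (1/(M*s)); configurable
#: everywhere it is used.
DEFAULT_KON = 1e5


@dataclass(frozen=True)
class InjectionProgram:
    """Contiguous injection steps followed by a dissociation phase."""

    steps: tuple[tuple[float, float, float], ...]  # (start s, end s, conc M)
    dissociation_end: float

    def __post_init__(self) -> None:
        if not self.steps:
            raise ValueError("program needs at least one step")
        prev_end = self.steps[0][0]
        for start, end, conc in self.steps:
            if end <= start:
                raise ValueError("step end must exceed start")
            if abs(start - prev_end) > 1e-9:
                raise ValueError("steps must be contiguous and non-overlapping")
            if conc < 0:
                raise ValueError("concentrations must be >= 0")
            prev_end = end
        if self.dissociation_end < prev_end:
            raise ValueError("dissociation phase must follow the last step")

    @classmethod
    def faststep(
        cls,
        concentrations_molar,
        step_seconds: float = 25.0,
        dissociation_seconds: float = 300.0,
    ) -> "InjectionProgram":
        """Serial doubling-style program: equal-length steps, one dissociation."""
        steps = tuple(
            (i * step_seconds, (i + 1) * step_seconds, float(c))
            for i, c in enumerate(concentrations_molar)
        )
        return cls(steps=steps, dissociation_end=steps[-1][1] + dissociation_seconds)

    @property
    def concentrations(self) -> np.ndarray:
        return np.array([c for _, _, c in self.steps])

    @property
    def association_end(self) -> float:
        return self.steps[-1][1]

    def concentration_at(self, t: float) -> float:
        for start, end, conc in self.steps:
            if start <= t < end:
                return conc
        return 0.0


@dataclass
class Sensorgram:
    time: np.ndarray
    ru: np.ndarray
    program: InjectionProgram
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.ru = np.asarray(self.ru, dtype=float)
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time grid must be strictly increasing")
        if not np.all(np.isfinite(self.ru)):
            raise ValueError("non-finite RU values")

    def to_csv(self) -> str:
        lines = ["# ppiscreen sensorgram v1"]
        for start, end, conc in self.program.steps:
            lines.append(f"# step,{start:.6g},{end:.6g},{conc:.8g}")
        lines.append(f"# dissociation_end,{self.program.dissociation_end:.6g}")
        lines.append(f"# noise_sd,{self.noise_sd:.8g}")
        lines.append("time_s,ru")
        lines += [f"{t:.6f},{r:.6f}" for t, r in zip(self.time, self.ru)]
        return "\n".join(lines) + "\n"

    @classmethod
    def from_csv(cls, text: str) -> "Sensorgram":
        steps = []
        diss = None
        noise_sd = 0.0
        rows = []
        for line in text.splitlines():
            line = line.strip()
            if not line or line == "time_s,ru":
                continue
            if line.startswith("# step,"):
                _, start, end, conc = line[2:].split(",")
                steps.append((float(start), float(end), float(conc)))
            elif line.startswith("# dissociation_end,"):
                diss = float(line.split(",")[1])
            elif line.startswith("# noise_sd,"):
                noise_sd = float(line.split(",")[1])
            elif line.startswith("#"):
                continue
            else:
                t, r = line.split(",")
                rows.append((float(t), float(r)))
        if diss is None or not steps:
            raise ValueError("missing sensorgram header")
        program = InjectionProgram(steps=tuple(steps), dissociation_end=diss)
        time, ru = zip(*rows)
        return cls(time=np.array(time), ru=np.array(ru), program=program, noise_sd=noise_sd)


@dataclass
class BindingFit:
    """Fitted 1:1 equilibrium/kinetic binding parameters."""

    kd: float | None
    rmax: float | None
    ok: bool
    method: str
    r2: float = float("nan")
    residual_sd: float = float("nan")
    kon: float | None = None
    message: str = ""


@dataclass
class CompetitionFit:
    ic50: float | None
    top: float | None
    bottom: float | None
    hill: float | None
    ic50_stderr: float | None
    non_competing: bool
    r2: float = float("nan")
    message: str = ""


# --------------------------------------------------------------------------
# simulation
# --------------------------------------------------------------------------


def _piecewise_langmuir(
    time: np.ndarray, kon: float, koff: float, rmax: float, program: InjectionProgram
) -> np.ndarray:
    """Exact per-interval exponential solution of the 1:1 binding ODE."""
    boundaries = [s for s, _, _ in program.steps] + [
        program.association_end,
        program.dissociation_end,
    ]
    ru = np.empty_like(time)
    r0 = 0.0
    t0 = 0.0
    intervals = list(zip(boundaries[:-1], boundaries[1:]))
    for start, end in intervals:
        conc = program.concentration_at(start)
        kobs = kon * conc + koff
        req = kon * conc * rmax / kobs if kobs > 0 else 0.0
        mask = (time >= start) & (time <= end if end == boundaries[-1] else time < end)
        ru[mask] = req + (r0 - req) * np.exp(-kobs * (time[mask] - start))
        r0 = req + (r0 - req) * np.exp(-kobs * (end - start))
        t0 = end
    ru[time > t0] = r0 * np.exp(-koff * (time[time > t0] - t0))
    return ru


def simulate_faststep(
    kd: float,
    kon: float,
    rmax: float,
    program: InjectionProgram,
    noise_sd: float = 0.0,
    seed: int | None = None,
    dt: float = 0.25,
) -> Sensorgram:
    """Simulate a stepwise-injection sensorgram with 1:1 Langmuir kinetics.

    ``koff = kon * kd``; after the last step the analyte concentration is
    zero (dissociation).  Gaussian noise of standard deviation
    ``noise_sd`` RU is added pointwise.
    """
    if kd <= 0 or kon <= 0 or rmax <= 0:
        raise ValueError("kd, kon and rmax must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    time = np.arange(0.0, program.dissociation_end + dt / 2, dt)
    ru = _piecewise_langmuir(time, kon, kon * kd, rmax, program)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        ru = ru + rng.normal(0.0, noise_sd, size=ru.shape)
    return Sensorgram(time=time, ru=ru, program=program, noise_sd=noise_sd)


def equilibrium_response(kd: float, rmax: float, concentrations) -> np.ndarray:
    """True equilibrium RU per concentration: ``Rmax*C/(Kd+C)``."""
    c = np.asarray(concentrations, dtype=float)
    return rmax * c / (kd + c)


def step_end_response(sensorgram: Sensorgram) -> tuple[np.ndarray, np.ndarray]:
    """Observed RU at the end of each injection step (with its concentration).

    At slow kinetics these have not reached equilibrium; comparing
    Scatchard fits on step-end versus true-equilibrium responses makes
    that bias measurable instead of hidden.
    """
    concs, rus = [], []
    for _, end, conc in sensorgram.program.steps:
        idx = int(np.searchsorted(sensorgram.time, end - 1e-9, side="right")) - 1
        concs.append(conc)
        rus.append(sensorgram.ru[idx])
    return np.array(concs), np.array(rus)


def simulate_equilibrium_titration(
    kd: float,
    rmax: float,
    concentrations,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> np.ndarray:
    """Noisy equilibrium responses for a multi-concentration titration."""
    if kd <= 0 or rmax <= 0:
        raise ValueError("kd and rmax must be positive")
    ru = equilibrium_response(kd, rmax, concentrations)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        ru = ru + rng.normal(0.0, noise_sd, size=ru.shape)
    return ru


# --------------------------------------------------------------------------
# fitting
# --------------------------------------------------------------------------


def scatchard_fit(concentrations, rus) -> BindingFit:
    """Scatchard linearisation: least-squares line of RU/C against RU.

    Slope is ``-1/Kd``; the x-intercept is ``Rmax``.  A non-negative
    slope (no saturation in the data) yields a failed fit result rather
    than an exception.
    """
    c = np.asarray(concentrations, dtype=float)
    r = np.asarray(rus, dtype=float)
    keep = (c > 0) & (r > 0)
    c, r = c[keep], r[keep]
    if len(np.unique(c)) < 3:
        return BindingFit(None, None, False, "scatchard", message="need >=3 concentrations with positive RU")
    y = r / c
    A = np.vstack([r, np.ones_like(r)]).T
    (slope, intercept), res, *_ = np.linalg.lstsq(A, y, rcond=None)
    if slope >= 0:
        return BindingFit(None, None, False, "scatchard", message="non-negative Scatchard slope: no saturation")
    kd = -1.0 / slope
    rmax = -intercept / slope
    pred = slope * r + intercept
    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    resid_sd = float(np.sqrt(ss_res / max(len(y) - 2, 1)))
    return BindingFit(float(kd), float(rmax), True, "scatchard", r2=r2, residual_sd=resid_sd)


def kinetic_fit(
    sensorgram: Sensorgram,
    kon_starts=(1e4, 1e5, 1e6, 1e7),
) -> BindingFit:
    """Full-trace 1:1 kinetic fit of (kon, koff, Rmax); Kd = koff/kon.

    Multi-start over ``kon_starts`` in log-parameter space; the best
    residual wins.  Used where injection steps are too short for the
    per-step responses to approximate equilibrium.
    """
    t, r = sensorgram.time, sensorgram.ru
    program = sensorgram.program
    rmax0 = max(float(np.max(r)) * 2.0, 1e-6)
    cmid = float(np.median(program.concentrations[program.concentrations > 0]))

    def residual(logp):
        kon, koff, rmax = np.exp(np.clip(logp, -45.0, 45.0))
        return _piecewise_langmuir(t, kon, koff, rmax, program) - r

    best = None
    for kon0 in kon_starts:
        x0 = np.log([kon0, kon0 * cmid, rmax0])
        try:
            sol = least_squares(residual, x0, method="lm", max_nfev=2000)
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None or not np.all(np.isfinite(best.x)):
        return BindingFit(None, None, False, "kinetic", message="kinetic fit failed")
    kon, koff, rmax = np.exp(best.x)
    resid = best.fun
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((r - r.mean()) ** 2))
    return BindingFit(
        kd=float(koff / kon),
        rmax=float(rmax),
        ok=True,
        method="kinetic",
        r2=1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0,
        residual_sd=float(np.sqrt(ss_res / max(len(r) - 3, 1))),
        kon=float(kon),
    )


# --------------------------------------------------------------------------
# competition
# --------------------------------------------------------------------------


def ki_to_ic50(ki: float, partner_conc: float, partner_kd: float) -> float:
    """Competitive-binding relation: ``IC50 = Ki * (1 + [P]/Kd_P)``."""
    return ki * (1.0 + partner_conc / partner_kd)


def competition_response(
    kd_partner: float,
    partner_conc: float,
    ki_inhibitor: float,
    inhibitor_concs,
    rmax_partner: float,
) -> np.ndarray:
    """Equilibrium partner-protein RU against inhibitor concentration.

    Trace immobilised receptor, so free concentrations equal totals; the
    partner site's fractional occupancy under competitive inhibition is
    ``(P/Kd) / (1 + P/Kd + I/Ki)``.
    """
    i = np.asarray(inhibitor_concs, dtype=float)
    p_term = partner_conc / kd_partner
    return rmax_partner * p_term / (1.0 + p_term + i / ki_inhibitor)


def simulate_competition(
    kd_partner: float,
    partner_conc: float,
    ki_inhibitor: float,
    inhibitor_concs,
    rmax_partner: float,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> np.ndarray:
    """Noisy competition read-out at the post-association read point.

    Models the protocol where the partner protein is co-injected at fixed
    concentration with increasing inhibitor concentrations, and the RU
    value attributable to partner binding is read at a fixed time after
    the end of each association phase (rapid inhibitor binding/dissociation
    already subtracted).
    """
    for name, v in (
        ("kd_partner", kd_partner),
        ("partner_conc", partner_conc),
        ("ki_inhibitor", ki_inhibitor),
        ("rmax_partner", rmax_partner),
    ):
        if v <= 0:
            raise ValueError(f"{name} must be positive")
    ru = competition_response(
        kd_partner, partner_conc, ki_inhibitor, inhibitor_concs, rmax_partner
    )
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        ru = ru + rng.normal(0.0, noise_sd, size=ru.shape)
    return ru


def _logistic4(logc, top, bottom, logic50, hill):
    return bottom + (top - bottom) / (1.0 + np.exp(hill * (logc - logic50)))


def ic50_fit(
    inhibitor_concs,
    rus,
    min_drop: float = 0.2,
) -> CompetitionFit:
    """Four-parameter logistic fit of RU against log inhibitor concentration.

    The inflection is the IC50; its standard error comes from the fit
    covariance.  A profile that never drops by more than ``min_drop`` of
    its top signal yields a *non-competing* verdict (no exception), the
    behaviour expected from compounds that bind without displacing the
    partner.
    """
    c = np.asarray(inhibitor_concs, dtype=float)
    r = np.asarray(rus, dtype=float)
    keep = c > 0
    c, r = c[keep], r[keep]
    if len(c) < 4:
        return CompetitionFit(None, None, None, None, None, False, message="need >=4 positive concentrations")
    order = np.argsort(c)
    c, r = c[order], r[order]
    top0 = float(np.max(r))
    bottom0 = float(np.min(r))
    if top0 <= 0 or (top0 - bottom0) / top0 < min_drop:
        return CompetitionFit(
            None, float(top0), float(bottom0), None, None, True,
            message="signal does not decrease: non-competing",
        )
    logc = np.log(c)
    p0 = [top0, max(bottom0, 0.0), float(np.median(logc)), 1.0]
    try:
        popt, pcov = curve_fit(
            _logistic4, logc, r, p0=p0,
            bounds=([0, 0, logc.min() - 10, 0.1], [np.inf, np.inf, logc.max() + 10, 10]),
            maxfev=20000,
        )
    except Exception as exc:
        return CompetitionFit(None, None, None, None, None, False, message=f"fit failed: {exc}")
    top, bottom, logic50, hill = popt
    ic50 = float(np.exp(logic50))
    stderr = None
    if np.all(np.isfinite(pcov)):
        stderr = float(np.sqrt(pcov[2, 2]) * ic50)  # delta method on log IC50
    pred = _logistic4(logc, *popt)
    ss_res = float(np.sum((r - pred) ** 2))
    ss_tot = float(np.sum((r - r.mean()) ** 2))
    return CompetitionFit(
        ic50=ic50,
        top=float(top),
        bottom=float(bottom),
        hill=float(hill),
        ic50_stderr=stderr,
        non_competing=False,
        r2=1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0,
    )
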