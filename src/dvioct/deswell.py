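"""Simplified 1-D osmotic de-swelling model of the corneal stroma.

The stroma is discretised into ``N`` elements of equal dry thickness.  Each
element carries a hydration ``H = M_W / M_D`` (wet-to-dry mass ratio); with
unit densities for both components its wet thickness is
``(D_dry / N) (1 + H)``.  Water moves between elements by Darcy flow driven
by the gradient of the element fluid pressure ``P = -Pi(H)``, where ``Pi``
is the hydration-dependent swelling (imbibition) pressure, and leaves the
tissue across the endothelial membrane at the posterior face with flux
``L (pi_ext - Pi(H_post))`` when the bath is hypertonic.  The anterior face
is sealed by default (osmotic flow through an intact epithelium is
negligible), or may be an open face or a second membrane.

Only the rapid initial osmotic phase is modelled: solute (dextran) ingress
and the hydration dependence of the permeability are deliberately excluded,
so the late re-swelling seen in long experiments is out of scope.  CGS
units are used internally (dyne/cm^2, cm, s); I/O converts to um and nm/s.

The swelling-pressure law is pluggable: the default is a power law
``Pi(H) = C H^(-gamma)`` with the classical empirical constant
``C = 2.41e6 dyne/cm^2`` and ``gamma = 2``, any strictly decreasing
positive law may be substituted.  All conservation and parameter-recovery
behaviour is law-agnostic.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from numba import njit
from scipy import optimize

from .dvi import AxialVelocityProfile

__all__ = [
    "DeswellModelParams",
    "ModelState",
    "ModelTrajectory",
    "FitResult",
    "swelling_pressure",
    "stability_dt",
    "step",
    "simulate",
    "model_velocity_profile",
    "fit_to_dvi",
]

CM_TO_UM = 1.0e4
CM_S_TO_NM_S = 1.0e7


def swelling_pressure(H, C: float = 2.41e6, gamma: float = 2.0):
    """Swelling (imbibition) pressure of the stroma at hydration H, dyne/cm^2.

    Power-law form ``Pi = C H^(-gamma)``: positive, strictly decreasing in
    H, vanishing as H -> infinity.
    """
    H = np.asarray(H, dtype=float)
    if np.any(H <= 0):
        raise ValueError("hydration must be strictly positive")
    return C * H ** (-gamma)


@dataclass(frozen=True)
class DeswellModelParams:
    """Constants of the 1-D osmotic de-swelling model (CGS units).

    Attributes
    ----------
    C, gamma
        Swelling-pressure law constants (``Pi = C H^-gamma``), dyne/cm^2
        and dimensionless.  Ignored if ``pressure_law`` is supplied.
    k_over_mu
        Stromal flow conductivity (Darcy permeability over viscosity),
        cm^4/(s dyne).
    L_endo
        Endothelial membrane hydraulic conductivity, cm^3/(s dyne)
        (volume flux per unit area per unit pressure difference).
    H0
        Initial (swollen) hydration, uniform across the depth.
    H_eq
        De-swollen equilibrium hydration; the bath osmotic pressure is
        ``pi_ext = Pi(H_eq)``.
    anterior
        Anterior boundary condition: ``sealed`` (intact epithelium),
        ``membrane`` (conductivity ``L_epi``) or ``open`` (Darcy contact
        with the bath).
    n_elements
        Number of equal-dry-thickness elements.
    D_dry
        Total dry thickness, cm.
    pressure_law
        Optional replacement swelling-pressure law ``Pi(H)``; must be
        positive and strictly decreasing.
    """

    C: float = 2.41e6
    gamma: float = 2.0
    k_over_mu: float = 10e-12
    L_endo: float = 179e-12
    H0: float = 7.6
    H_eq: float = 2.44
    anterior: str = "sealed"
    L_epi: float = 0.0
    n_elements: int = 50
    D_dry: float = 0.0116
    pressure_law: Callable | None = None

    def __post_init__(self) -> None:
        if self.k_over_mu < 0 or self.L_endo < 0 or self.L_epi < 0:
            raise ValueError("conductivities must be >= 0")
        if self.n_elements < 2:
            raise ValueError("need at least two elements")
        if not self.H0 > self.H_eq >= 0:
            raise ValueError("de-swelling requires H0 > H_eq >= 0")
        if self.anterior not in ("sealed", "membrane", "open"):
            raise ValueError(f"unknown anterior boundary {self.anterior!r}")

    def pressure(self, H):
        if self.pressure_law is not None:
            return self.pressure_law(H)
        return swelling_pressure(H, self.C, self.gamma)

    @property
    def pi_ext(self) -> float:
        """Bath osmotic pressure, dyne/cm^2 (sets the de-swollen equilibrium)."""
        return float(self.pressure(self.H_eq))

    @property
    def element_dry_thickness(self) -> float:
        return self.D_dry / self.n_elements


@dataclass
class ModelState:
    """Hydration of every element at one instant."""

    H: np.ndarray
    time: float = 0.0

    def __post_init__(self) -> None:
        self.H = np.asarray(self.H, dtype=float)
        if np.any(self.H < 0):
            raise ValueError("hydration must be >= 0")

    def wet_thicknesses(self, params: DeswellModelParams) -> np.ndarray:
        """Per-element wet thickness ``(D_dry/N)(1 + H)``, cm."""
        return params.element_dry_thickness * (1.0 + self.H)

    def total_thickness(self, params: DeswellModelParams) -> float:
        return float(self.wet_thicknesses(params).sum())


def _pressure_slope_max(params: DeswellModelParams) -> float:
    """max |dPi/dH| over the hydration range of a de-swelling run."""
    # a de-swelling run stays in [H_eq, H0] up to small Euler overshoot
    H_lo = max(0.9 * params.H_eq, 1e-3)
    H = np.linspace(H_lo, params.H0, 64)
    eps = 1e-5
    dPi = np.abs(
        (np.asarray(params.pressure(H * (1 + eps))) - np.asarray(params.pressure(H * (1 - eps))))
        / (2 * eps * H)
    )
    return float(dPi.max())


def stability_dt(params: DeswellModelParams, safety: float = 0.4) -> float:
    """Largest explicit-Euler time step expected to stay stable, seconds.

    The binding constraint is the internal Darcy exchange between adjacent
    elements (a nonlinear diffusion); the endothelial boundary flux gives a
    second, usually looser, bound.
    """
    delta = params.element_dry_thickness
    dx_min = delta * (1.0 + params.H_eq)  # closest element spacing during the run
    slope = _pressure_slope_max(params)
    bounds = []
    if params.k_over_mu > 0 and slope > 0:
        bounds.append(0.5 * delta * dx_min / (params.k_over_mu * slope))
    L_max = max(params.L_endo, params.L_epi)
    if L_max > 0 and slope > 0:
        bounds.append(delta / (L_max * slope))
    if not bounds:
        return np.inf
    return safety * min(bounds)


def _face_fluxes(H: np.ndarray, params: DeswellModelParams) -> np.ndarray:
    """Volume flux (cm/s) across each of the N+1 element faces.

    Positive flux points toward larger element index (the posterior).
    Face 0 is the anterior exterior face; face N is the endothelium.
    """
    Pi = np.asarray(params.pressure(H), dtype=float)
    P = -Pi  # element fluid pressure
    delta = params.element_dry_thickness
    h = delta * (1.0 + H)
    f = np.zeros(len(H) + 1)
    dx = 0.5 * (h[:-1] + h[1:])  # centre-to-centre distances
    f[1:-1] = params.k_over_mu * (P[:-1] - P[1:]) / dx
    # posterior membrane: outward when the bath is hypertonic
    f[-1] = params.L_endo * (params.pi_ext - Pi[-1])
    if params.anterior == "sealed":
        f[0] = 0.0
    elif params.anterior == "membrane":
        # outward (toward the anterior bath) is negative face flux
        f[0] = -params.L_epi * (params.pi_ext - Pi[0])
    else:  # open: Darcy contact with the bath over half an element
        f[0] = -params.k_over_mu * (params.pi_ext - Pi[0]) / (0.5 * h[0])
    return f


def step(state: ModelState, params: DeswellModelParams, dt: float) -> ModelState:
    """One explicit-Euler step of the water-exchange dynamics.

    Water bookkeeping is exact by construction: each face flux is applied
    antisymmetrically to its two neighbours, and the total water change
    equals ``dt (f_anterior - f_posterior)``.
    """
    f = _face_fluxes(state.H, params)
    delta = params.element_dry_thickness
    H_new = state.H + dt * (f[:-1] - f[1:]) / delta
    if np.any(H_new < 0):
        raise RuntimeError(
            "hydration went negative: the step is unstable, use a smaller dt "
            f"(stability bound ~{stability_dt(params):.3g} s)"
        )
    return ModelState(H=H_new, time=state.time + dt)


@dataclass
class ModelTrajectory:
    """Sampled output of a de-swelling simulation.

    ``positions[k, j]`` is the distance (cm) of element face ``j`` from the
    anterior face (face 0 at 0, face N at the total thickness) at sample
    ``k``; ``velocities`` are the face velocities relative to the anterior
    face, cm/s, from central finite differences of the positions between
    adjacent samples.
    """

    times: np.ndarray
    thickness: np.ndarray  # cm
    hydration: np.ndarray  # (n_samples, N)
    positions: np.ndarray  # (n_samples, N + 1), cm
    velocities: np.ndarray  # (n_samples, N + 1), cm/s
    params: DeswellModelParams
    water_balance_error: float = 0.0

    @property
    def thickness_um(self) -> np.ndarray:
        return self.thickness * CM_TO_UM

    def thickness_at(self, t: float) -> float:
        """Total thickness at time t, cm (linear interpolation)."""
        return float(np.interp(t, self.times, self.thickness))

    def velocity_at(self, x_um, t: float):
        """Axial velocity (nm/s) at depth ``x_um`` from the anterior face.

        Linear interpolation in time between samples and in depth along the
        element faces; depths beyond the posterior face clamp to the
        posterior-face velocity.
        """
        if t < self.times[0] or t > self.times[-1]:
            raise ValueError("time outside the sampled trajectory range")
        x = np.asarray(x_um, dtype=float) / CM_TO_UM
        k = int(np.searchsorted(self.times, t, side="right") - 1)
        k = min(k, len(self.times) - 2)
        t0, t1 = self.times[k], self.times[k + 1]
        w = 0.0 if t1 == t0 else (t - t0) / (t1 - t0)
        v0 = np.interp(x, self.positions[k], self.velocities[k])
        v1 = np.interp(x, self.positions[k + 1], self.velocities[k + 1])
        v = (1 - w) * v0 + w * v1
        return np.where(x <= 0, 0.0, v) * CM_S_TO_NM_S


@njit(cache=True)
def _euler_kernel(
    H0: float,
    n: int,
    delta: float,
    kmu: float,
    L_post: float,
    L_epi: float,
    pi_ext: float,
    C: float,
    gamma: float,
    ant_code: int,  # 0 sealed, 1 membrane, 2 open
    sample_times: np.ndarray,
    t_end: float,
    dt_base: float,
):
    """Explicit-Euler integration with the power-law pressure, compiled.

    Returns (hydration samples, net boundary inflow integral, ok flag).
    """
    H = np.full(n, H0)
    samples = np.zeros((len(sample_times), n))
    boundary_integral = 0.0
    t = 0.0
    next_idx = 0
    ok = True
    while True:
        while next_idx < len(sample_times) and abs(t - sample_times[next_idx]) < 1e-12:
            samples[next_idx] = H
            next_idx += 1
        if next_idx >= len(sample_times) and t >= t_end - 1e-12:
            break
        target = sample_times[next_idx] if next_idx < len(sample_times) else t_end
        dt_k = min(dt_base, target - t)
        Pi = C * H**-gamma
        h = delta * (1.0 + H)
        f_post = L_post * (pi_ext - Pi[n - 1])
        if ant_code == 0:
            f_ant = 0.0
        elif ant_code == 1:
            f_ant = -L_epi * (pi_ext - Pi[0])
        else:
            f_ant = -kmu * (pi_ext - Pi[0]) / (0.5 * h[0])
        prev = f_ant
        for i in range(n):
            if i < n - 1:
                nxt = kmu * (Pi[i + 1] - Pi[i]) / (0.5 * (h[i] + h[i + 1]))
            else:
                nxt = f_post
            H[i] = H[i] + (dt_k / delta) * (prev - nxt)
            prev = nxt
        for i in range(n):
            if H[i] < 0:
                ok = False
        if not ok:
            break
        boundary_integral += dt_k * (f_ant - f_post)
        t += dt_k
    return samples, boundary_integral, ok


def simulate(
    params: DeswellModelParams,
    t_end: float,
    sample_times: Sequence[float] | None = None,
    dt: float | None = None,
) -> ModelTrajectory:
    """Integrate the model from uniform hydration ``H0`` to ``t_end``.

    Explicit Euler with a fixed step at (or below) the stability bound;
    steps are shortened to land exactly on each requested sample time.
    """
    if sample_times is None:
        sample_times = np.linspace(0.0, t_end, 25)
    sample_times = np.asarray(sorted(set(float(t) for t in sample_times)))
    if sample_times[0] < 0 or sample_times[-1] > t_end:
        raise ValueError("sample times must lie in [0, t_end]")
    if 0.0 not in sample_times:
        sample_times = np.concatenate([[0.0], sample_times])
    dt_base = dt if dt is not None else stability_dt(params)
    if not np.isfinite(dt_base) or dt_base <= 0:
        raise ValueError("no finite stability bound; supply dt explicitly")

    delta = params.element_dry_thickness
    water0 = float(delta * params.H0 * params.n_elements)
    if params.pressure_law is None:
        ant_code = ("sealed", "membrane", "open").index(params.anterior)
        hydration, boundary_integral, ok = _euler_kernel(
            float(params.H0),
            params.n_elements,
            delta,
            params.k_over_mu,
            params.L_endo,
            params.L_epi,
            params.pi_ext,
            params.C,
            params.gamma,
            ant_code,
            sample_times,
            float(t_end),
            float(dt_base),
        )
        if not ok:
            raise RuntimeError(
                "hydration went negative during simulate; reduce dt "
                f"(stability bound ~{stability_dt(params):.3g} s)"
            )
    else:
        # generic (pluggable-law) path: plain python stepping
        state = ModelState(H=np.full(params.n_elements, float(params.H0)))
        boundary_integral = 0.0
        samples_H = []
        next_idx = 0
        while True:
            while (
                next_idx < len(sample_times)
                and abs(state.time - sample_times[next_idx]) < 1e-12
            ):
                samples_H.append(state.H.copy())
                next_idx += 1
            if next_idx >= len(sample_times) and state.time >= t_end - 1e-12:
                break
            target = (
                sample_times[next_idx] if next_idx < len(sample_times) else t_end
            )
            dt_k = min(dt_base, target - state.time)
            f = _face_fluxes(state.H, params)
            boundary_integral += dt_k * (f[0] - f[-1])
            state = step(state, params, dt_k)
        hydration = np.array(samples_H)
    h = delta * (1.0 + hydration)  # (n_samples, N)
    positions = np.concatenate(
        [np.zeros((len(sample_times), 1)), np.cumsum(h, axis=1)], axis=1
    )
    thickness = positions[:, -1]
    velocities = np.gradient(positions, sample_times, axis=0)

    water_final = float(delta * hydration[-1].sum())
    flux_change = boundary_integral  # net inflow
    water_error = abs((water_final - water0) - flux_change) / max(water0, 1e-30)
    return ModelTrajectory(
        times=sample_times,
        thickness=thickness,
        hydration=hydration,
        positions=positions,
        velocities=velocities,
        params=params,
        water_balance_error=water_error,
    )


def model_velocity_profile(trajectory: ModelTrajectory, time: float) -> AxialVelocityProfile:
    """Model velocity profile versus distance from the endothelial face.

    Velocities are relative to the anterior face (the DVI reference
    convention for corneas with an intact epithelium), in nm/s; distance is
    geometric micrometres increasing from the posterior (endothelial) face
    into the cornea.
    """
    if time < trajectory.times[0] or time > trajectory.times[-1]:
        raise ValueError("time outside the sampled trajectory range")
    t = trajectory.times
    k = min(int(np.searchsorted(t, time, side="right") - 1), len(t) - 2)
    w = 0.0 if t[k + 1] == t[k] else (time - t[k]) / (t[k + 1] - t[k])
    pos = (1 - w) * trajectory.positions[k] + w * trajectory.positions[k + 1]
    vel = (1 - w) * trajectory.velocities[k] + w * trajectory.velocities[k + 1]
    T = pos[-1]
    distance_cm = T - pos  # 0 at posterior face, T at anterior
    order = np.argsort(distance_cm)
    return AxialVelocityProfile(
        distance_um=distance_cm[order] * CM_TO_UM,
        velocity_nm_s=vel[order] * CM_S_TO_NM_S,
        n_columns=np.ones(len(order), dtype=int),
        from_interface="posterior",
    )


@dataclass
class FitResult:
    """Best-fit model constants and diagnostics from a DVI profile fit."""

    params: DeswellModelParams
    objective: float
    time_offset_s: float
    start_thickness_um: float
    residuals: dict
    n_evaluations: int


def _profile_arrays(profile) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(profile, AxialVelocityProfile):
        d, v = profile.distance_um, profile.velocity_nm_s
    else:
        d, v = profile
    d = np.asarray(d, dtype=float)
    v = np.asarray(v, dtype=float)
    ok = np.isfinite(v)
    return d[ok], v[ok]


def fit_to_dvi(
    measured_profiles: Sequence[tuple[float, object]],
    measured_thickness_um: Sequence[float],
    template: DeswellModelParams | None = None,
    bounds: dict | None = None,
    grid_points: int = 3,
    fit_time_offset: bool = False,
    max_offset_s: float = 600.0,
    refine: bool = True,
    maxiter: int = 2000,
) -> FitResult:
    """Fit (k/mu, L, H0, H_eq) to measured DVI profiles and thicknesses.

    ``measured_profiles`` is a sequence of ``(time_s, profile)`` pairs
    (``profile`` an :class:`AxialVelocityProfile` or a ``(distance_um,
    velocity_nm_s)`` pair, distances from the endothelial face) at three or
    more times; ``measured_thickness_um`` gives the mean thickness at the
    same times.  A deterministic coarse grid search inside ``bounds``
    (conductivities gridded in log space) seeds a Nelder-Mead refinement of
    the summed squared profile and thickness misfit.  The model's start-time
    offset before the first measurement can optionally be fitted as a
    nuisance parameter.
    """
    if len(measured_profiles) < 3:
        raise ValueError("need profiles at >= 3 times")
    template = template or DeswellModelParams()
    default_bounds = {
        "k_over_mu": (0.3e-12, 29e-12),
        "L_endo": (5e-12, 500e-12),
        "H0": (1.5, 8.0),
        "H_eq": (1.5, 8.0),
    }
    bounds = {**default_bounds, **(bounds or {})}
    for key, (lo, hi) in bounds.items():
        if not hi > lo > 0:
            raise ValueError(f"degenerate bounds for {key}: ({lo}, {hi})")

    times = np.array([t for t, _ in measured_profiles], dtype=float)
    profiles = [_profile_arrays(p) for _, p in measured_profiles]
    thickness = np.asarray(measured_thickness_um, dtype=float)
    if thickness.shape != times.shape:
        raise ValueError("one thickness per profile time required")
    order = np.argsort(times)
    times, thickness = times[order], thickness[order]
    profiles = [profiles[i] for i in order]

    v_scale = max(1.0, float(np.sqrt(np.mean(np.concatenate([v for _, v in profiles]) ** 2))))
    T_scale = max(1.0, 0.01 * float(np.mean(thickness)))
    half_window = 2.5  # s; matches the DVI measurement half-window
    n_eval = 0

    def unpack(theta):
        kmu = 10.0 ** theta[0]
        L = 10.0 ** theta[1]
        H0, Heq = theta[2], theta[3]
        t_off = theta[4] if fit_time_offset else 0.0
        return kmu, L, H0, Heq, t_off

    def objective(theta) -> float:
        nonlocal n_eval
        kmu, L, H0, Heq, t_off = unpack(theta)
        if not (
            bounds["k_over_mu"][0] <= kmu <= bounds["k_over_mu"][1]
            and bounds["L_endo"][0] <= L <= bounds["L_endo"][1]
            and bounds["H0"][0] <= H0 <= bounds["H0"][1]
            and bounds["H_eq"][0] <= Heq <= bounds["H_eq"][1]
            and Heq < H0
            and 0.0 <= t_off <= max_offset_s
        ):
            return 1e30
        n_eval += 1
        params = replace(template, k_over_mu=kmu, L_endo=L, H0=H0, H_eq=Heq)
        model_times = times + t_off
        sample = np.unique(
            np.concatenate(
                [model_times - half_window, model_times, model_times + half_window]
            )
        )
        sample = sample[sample >= 0]
        t_end = float(sample.max())
        try:
            traj = simulate(params, t_end, sample_times=sample)
        except RuntimeError:
            return 1e30
        sse = 0.0
        for (d_meas, v_meas), t_m, T_meas in zip(profiles, model_times, thickness):
            prof = model_velocity_profile(traj, t_m)
            v_model = np.interp(d_meas, prof.distance_um, prof.velocity_nm_s)
            sse += float(np.sum(((v_model - v_meas) / v_scale) ** 2))
            sse += ((traj.thickness_at(t_m) * CM_TO_UM - T_meas) / T_scale) ** 2
        return sse

    axes = [
        np.linspace(*np.log10(bounds["k_over_mu"]), grid_points),
        np.linspace(*np.log10(bounds["L_endo"]), grid_points),
        np.linspace(*bounds["H0"], grid_points),
        np.linspace(*bounds["H_eq"], grid_points),
    ]
    if fit_time_offset:
        axes.append(np.linspace(0.0, max_offset_s, grid_points))
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, len(axes))
    grid_vals = np.array([objective(theta) for theta in grid])
    order = np.argsort(grid_vals)
    if grid_vals[order[0]] >= 1e30:
        raise RuntimeError("grid search found no feasible parameter set")

    # refine from the few best grid points: the misfit surface has long
    # curved valleys and a single simplex start can stall in the wrong one
    best_theta, best_val = grid[order[0]].copy(), float(grid_vals[order[0]])
    if refine:
        for idx in order[:3]:
            if grid_vals[idx] >= 1e30:
                continue
            res = optimize.minimize(
                objective,
                grid[idx],
                method="Nelder-Mead",
                options={
                    "xatol": 1e-7,
                    "fatol": 1e-12,
                    "maxiter": maxiter,
                    "maxfev": 2 * maxiter,
                },
            )
            if res.fun < best_val:
                best_theta, best_val = res.x.copy(), float(res.fun)
    theta = best_theta

    kmu, L, H0, Heq, t_off = unpack(theta)
    fitted = replace(template, k_over_mu=kmu, L_endo=L, H0=H0, H_eq=Heq)
    # per-time residual curves at the optimum
    model_times = times + t_off
    sample = np.unique(
        np.concatenate([model_times - half_window, model_times, model_times + half_window])
    )
    sample = sample[sample >= 0]
    traj = simulate(fitted, float(sample.max()), sample_times=sample)
    residuals = {}
    for (d_meas, v_meas), t_raw, t_m in zip(profiles, times, model_times):
        prof = model_velocity_profile(traj, t_m)
        v_model = np.interp(d_meas, prof.distance_um, prof.velocity_nm_s)
        residuals[float(t_raw)] = (d_meas.copy(), v_model - v_meas)
    return FitResult(
        params=fitted,
        objective=best_val,
        time_offset_s=float(t_off),
        start_thickness_um=fitted.D_dry * (1.0 + fitted.H0) * CM_TO_UM,
        residuals=residuals,
        n_evaluations=n_eval,
    )
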