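"""Steady-state heat conduction around a laser-heated magnetic bead.

The bead absorbs laser power in a thin magnetite shell just inside its
surface.  With no interior source the bead interior is isothermal at
the surface temperature Ts; in an infinite bath the exterior excess
temperature decays as R/r (a 1/x dependence close to the surface),
with

    Ts = T_inf + P_abs / (4 * pi * k_water * R).

A finite-volume solver on an axisymmetric (rho, z) grid adds a glass
half-space below the bead: conduction into the coverslip lowers
temperatures near the glass and distorts the exterior decay away from
the pure 1/x law.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.linalg import spsolve

__all__ = [
    "BeadThermalModel", "TemperatureProfile", "ALKANE_MELTING_POINTS_C",
    "analytic_profile", "numeric_profile", "invert_wax_interfaces",
]

#: Melting points (deg C) of the alkane waxes used as in-situ
#: thermometers, from standard reference tables (synthetic stand-in
#: values, not measured in this work): nonadecane, icosane, docosane.
ALKANE_MELTING_POINTS_C = {"C19": 32.1, "C20": 36.7, "C22": 44.0}


@dataclass
class BeadThermalModel:
    bead_radius_um: float = 1.5
    shell_thickness_nm: float = 100.0
    absorbed_power_mW: float | None = None
    k_water_W_mK: float = 0.6
    k_glass_W_mK: float = 1.0
    k_bead_W_mK: float = 0.2
    ambient_T_C: float = 25.0
    coverslip_distance_um: float = 1.0
    surface_T_C: float | None = 45.0

    def __post_init__(self):
        if self.shell_thickness_nm * 1e-3 >= self.bead_radius_um:
            raise ValueError("shell must lie inside the bead")
        for k in (self.k_water_W_mK, self.k_glass_W_mK, self.k_bead_W_mK):
            if k <= 0:
                raise ValueError("conductivities must be positive")
        if self.absorbed_power_mW is None and self.surface_T_C is None:
            raise ValueError("give absorbed power or surface temperature")
        if self.absorbed_power_mW is None:
            # P = 4*pi*k*R*(Ts - Tinf); R in m, P in W -> mW
            dT = self.surface_T_C - self.ambient_T_C
            self.absorbed_power_mW = (4 * math.pi * self.k_water_W_mK
                                      * self.bead_radius_um * 1e-6 * dT
                                      * 1e3)
        if self.surface_T_C is None:
            self.surface_T_C = (self.ambient_T_C
                                + self.absorbed_power_mW * 1e-3
                                / (4 * math.pi * self.k_water_W_mK
                                   * self.bead_radius_um * 1e-6))


@dataclass
class TemperatureProfile:
    """Temperature vs distance from the bead surface (um; negative
    values are interior points)."""

    distance_um: np.ndarray
    temperature_C: np.ndarray

    def __post_init__(self):
        self.distance_um = np.asarray(self.distance_um, float)
        self.temperature_C = np.asarray(self.temperature_C, float)

    def at(self, x_um) -> np.ndarray:
        return np.interp(np.asarray(x_um, float), self.distance_um,
                         self.temperature_C)


def analytic_profile(model: BeadThermalModel,
                     distances_um=None) -> TemperatureProfile:
    """Shell-source solution in an infinite water bath (no coverslip):
    isothermal interior at Ts, exterior excess decaying as R/r."""
    R = model.bead_radius_um
    if distances_um is None:
        distances_um = np.concatenate([np.linspace(-R * 0.99, 0, 25),
                                       np.linspace(0.001, 10 * R, 400)])
    x = np.asarray(distances_um, float)
    Ts, Tinf = model.surface_T_C, model.ambient_T_C
    r = R + np.maximum(x, 0.0)
    T = np.where(x <= 0, Ts, Tinf + (Ts - Tinf) * R / r)
    return TemperatureProfile(x, T)


def _grid_1d(fine_to: float, fine_step: float, far: float,
             stretch: float = 1.12) -> np.ndarray:
    """Cell-edge coordinates: uniform `fine_step` out to `fine_to`,
    then geometrically stretched to `far`."""
    edges = list(np.arange(0.0, fine_to + fine_step / 2, fine_step))
    h = fine_step
    while edges[-1] < far:
        h *= stretch
        edges.append(edges[-1] + h)
    return np.asarray(edges)


def numeric_profile(model: BeadThermalModel, fine_step_um: float = 0.025,
                    domain_factor: float = 10.0, stretch: float = 1.12,
                    matched_far_field: bool | None = None) -> dict:
    """Finite-volume steady conduction on an axisymmetric (rho, z)
    grid with a glass half-space below the bead.

    The magnetite shell is a uniform volumetric source normalised to
    the absorbed power.  Far boundaries are Dirichlet: ambient by
    default; when glass and water conductivities are equal the exact
    far field is the point-source 1/r tail, and imposing it (matched
    far field) removes the domain-truncation error so the solution can
    be compared against the analytic profile.

    Returns the profile along the radial midline plus the grid and the
    conservation diagnostics.
    """
    R = model.bead_radius_um
    shell_um = model.shell_thickness_nm * 1e-3
    if fine_step_um > shell_um / 4:
        raise ValueError("grid must resolve the shell with >= 4 cells")
    uniform = abs(model.k_glass_W_mK - model.k_water_W_mK) < 1e-12
    if matched_far_field is None:
        matched_far_field = uniform
    far = domain_factor * R
    gap = model.coverslip_distance_um
    zc = gap + R                       # bead centre height above glass
    # edges: fine cells around bead and glass interface, geometric
    # stretching to the far boundaries
    rho_e = _grid_1d(R + 0.3, fine_step_um, far, stretch)
    z_up = _grid_1d(zc + R + 0.3, fine_step_um, zc + far, stretch)
    z_dn = _grid_1d(0.3, fine_step_um, 0.6 * far, stretch)
    z_e = np.concatenate([-z_dn[::-1][:-1], z_up])
    nr, nz = rho_e.size - 1, z_e.size - 1
    rho_c = 0.5 * (rho_e[:-1] + rho_e[1:])
    z_c = 0.5 * (z_e[:-1] + z_e[1:])
    drho = np.diff(rho_e)
    dz = np.diff(z_e)

    RR, ZZ = np.meshgrid(rho_c, z_c, indexing="ij")
    rad = np.sqrt(RR ** 2 + (ZZ - zc) ** 2)
    K = np.full((nr, nz), model.k_water_W_mK)
    K[rad < R] = model.k_bead_W_mK
    K[ZZ < 0] = model.k_glass_W_mK

    # cell volumes (axisymmetric): pi*(rho_out^2-rho_in^2)*dz, in um^3
    vol = np.pi * (rho_e[1:, None] ** 2 - rho_e[:-1, None] ** 2) \
        * dz[None, :]
    # shell source smoothed by sub-cell volume fractions (5x5
    # subsampling) so the staircase discretisation of the sphere does
    # not imprint on the interior temperature
    frac = np.zeros((nr, nz))
    near = np.abs(rad - (R - shell_um / 2)) < shell_um / 2 \
        + np.hypot(np.maximum.outer(drho, dz), 0)
    sub = (np.arange(5) + 0.5) / 5
    for fi in sub:
        rr = rho_e[:-1, None] + fi * drho[:, None]
        for fj in sub:
            zz = z_e[None, :-1] + fj * dz[None, :]
            rsub = np.sqrt(rr ** 2 + (zz - zc) ** 2)
            frac += (rsub >= R - shell_um) & (rsub < R)
    frac /= 25.0
    frac[~near] = 0.0
    P_W = model.absorbed_power_mW * 1e-3
    vshell = float(np.sum(frac * vol))
    src = P_W * frac / vshell          # W per um^3

    Tinf = model.ambient_T_C
    Ts = model.surface_T_C

    def boundary_T(rho, z):
        if not matched_far_field:
            return np.full(np.broadcast(rho, z).shape, Tinf)
        r = np.maximum(np.sqrt(rho ** 2 + (z - zc) ** 2), R)
        return Tinf + (Ts - Tinf) * R / r

    idx = np.arange(nr * nz).reshape(nr, nz)
    um = 1e-6   # conductance: k[W/m/K] * area[um^2] / dist[um] * 1e-6 -> W/K

    # interior face conductances, harmonic-mean conductivity
    area_r = 2 * np.pi * rho_e[1:-1, None] * dz[None, :]      # (nr-1, nz)
    kh_r = 2 * K[:-1, :] * K[1:, :] / (K[:-1, :] + K[1:, :])
    g_r = kh_r * area_r / np.diff(rho_c)[:, None] * um
    area_z = np.pi * (rho_e[1:, None] ** 2 - rho_e[:-1, None] ** 2)
    kh_z = 2 * K[:, :-1] * K[:, 1:] / (K[:, :-1] + K[:, 1:])
    g_z = kh_z * area_z / np.diff(z_c)[None, :] * um          # (nr, nz-1)

    diag = np.zeros((nr, nz))
    b = (src * vol).astype(float)
    rows, cols, vals = [], [], []

    def couple(gfc, ia, ja, ib, jb):
        rows.extend(idx[ia, ja].ravel())
        cols.extend(idx[ib, jb].ravel())
        vals.extend((-gfc).ravel())

    diag[:-1, :] += g_r
    diag[1:, :] += g_r
    couple(g_r, np.s_[:-1], np.s_[:], np.s_[1:], np.s_[:])
    couple(g_r, np.s_[1:], np.s_[:], np.s_[:-1], np.s_[:])
    diag[:, :-1] += g_z
    diag[:, 1:] += g_z
    couple(g_z, np.s_[:], np.s_[:-1], np.s_[:], np.s_[1:])
    couple(g_z, np.s_[:], np.s_[1:], np.s_[:], np.s_[:-1])

    # Dirichlet far boundaries (axis rho=0 is a no-flux boundary)
    g_out = K[-1, :] * (2 * np.pi * rho_e[-1] * dz) \
        / (rho_e[-1] - rho_c[-1]) * um
    diag[-1, :] += g_out
    b[-1, :] += g_out * boundary_T(rho_e[-1], z_c)
    g_top = K[:, -1] * area_z[:, 0] / (z_e[-1] - z_c[-1]) * um
    diag[:, -1] += g_top
    b[:, -1] += g_top * boundary_T(rho_c, z_e[-1])
    g_bot = K[:, 0] * area_z[:, 0] / (z_c[0] - z_e[0]) * um
    diag[:, 0] += g_bot
    b[:, 0] += g_bot * boundary_T(rho_c, z_e[0])

    rows.extend(idx.ravel())
    cols.extend(idx.ravel())
    vals.extend(diag.ravel())
    b = b.ravel()
    A = coo_matrix((vals, (rows, cols)), shape=(nr * nz, nr * nz)).tocsr()
    T = spsolve(A, b).reshape(nr, nz)
    if not np.all(np.isfinite(T)):
        raise RuntimeError("linear solve failed (non-finite temperatures)")
    resid = float(np.linalg.norm(A @ T.ravel() - b)
                  / max(np.linalg.norm(b), 1e-30))
    if resid > 1e-8:
        raise RuntimeError(f"linear solve residual {resid:.2e} too large")

    # radial midline profile through the bead centre
    jz = int(np.argmin(np.abs(z_c - zc)))
    dist_um = rho_c - R
    prof = TemperatureProfile(dist_um, T[:, jz])

    # flux through a control box enclosing the bead (exact FV fluxes)
    def box_flux(half_um):
        i = np.searchsorted(rho_e, half_um) - 1
        j0 = np.searchsorted(z_e, zc - half_um) - 1
        j1 = np.searchsorted(z_e, zc + half_um) - 1
        flux = float(np.sum(g_r[i, j0:j1 + 1]
                            * (T[i, j0:j1 + 1] - T[i + 1, j0:j1 + 1])))
        flux += float(np.sum(g_z[:i + 1, j1]
                             * (T[:i + 1, j1] - T[:i + 1, j1 + 1])))
        flux += float(np.sum(g_z[:i + 1, j0 - 1]
                             * (T[:i + 1, j0] - T[:i + 1, j0 - 1])))
        return flux

    flux_W = box_flux(R + 0.1)
    interior = rad < R - shell_um
    return {"profile": prof, "temperature": T,
            "rho_um": rho_c, "z_um": z_c, "bead_centre_z_um": zc,
            "flux_out_W": flux_W, "absorbed_W": P_W,
            "interior_sd_C": float(T[interior].std()),
            "interior_mean_C": float(T[interior].mean()),
            "residual": resid}


def invert_wax_interfaces(observations, model: BeadThermalModel,
                          n_boot: int = 200, seed: int | None = None
                          ) -> dict:
    """Fit the bead surface temperature from wax melting interfaces.

    Each observation (interface_distance_um, melting_T_C) pins the
    temperature at one distance from the bead surface; with the
    analytic R/(R+x) profile the model is linear in Ts, so the
    least-squares solution is closed-form.  CI by case-resampling
    bootstrap (needs >= 3 observations); non-monotone observations only
    warn.
    """
    obs = [(float(x), float(Tm)) for x, Tm in observations]
    if len(obs) < 1:
        raise ValueError("need at least one observation")
    import warnings
    xs = np.array([o[0] for o in obs])
    Ts_obs = np.array([o[1] for o in obs])
    order = np.argsort(xs)
    if np.any(np.diff(Ts_obs[order]) > 0):
        warnings.warn("observations are non-monotone in distance; fit "
                      "returned anyway", stacklevel=2)
    R = model.bead_radius_um
    Tinf = model.ambient_T_C
    w = R / (R + xs)                  # T = Tinf + (Ts - Tinf) * w

    def solve(x_w, y):
        return Tinf + float(np.sum(x_w * (y - Tinf)) / np.sum(x_w ** 2))

    Ts_hat = solve(w, Ts_obs)
    out = {"surface_T_C": Ts_hat, "n_obs": len(obs), "ci95": None}
    if len(obs) >= 3 and n_boot > 0:
        rng = np.random.default_rng(seed)
        reps = []
        for _ in range(n_boot):
            idx = rng.integers(0, len(obs), len(obs))
            reps.append(solve(w[idx], Ts_obs[idx]))
        lo, hi = np.percentile(reps, [2.5, 97.5])
        out["ci95"] = (float(lo), float(hi))
    return out
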