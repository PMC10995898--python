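"""Independent numerical oracle for membrane bending energies.

Integrates (kappa/2) * (c1 + c2)^2 over a parametrized wrapping surface
using only differential geometry evaluated numerically: first and second
fundamental forms from finite differences of the parametrization, mean
curvature H = (EN + GL - 2FM) / (2(EG - F^2)), area element
sqrt(EG - F^2), trapezoidal quadrature. No closed-form curvature or
energy expressions are used, so this is an independent check of the
closed forms in the package.
"""

from __future__ import annotations

import numpy as np


def _extend(axis: np.ndarray, pad: int) -> np.ndarray:
    step = axis[1] - axis[0]
    left = axis[0] - step * np.arange(pad, 0, -1)
    right = axis[-1] + step * np.arange(1, pad + 1)
    return np.concatenate([left, axis, right])


def bending_energy_quadrature(r_func, u, v, kappa, pad=4):
    """Quadrature of the Helfrich integrand over r_func(u, v).

    ``r_func`` maps parameter grids (U, V) to an (..., 3) surface; the
    parameter grid is extended by ``pad`` steps on each side (the
    parametrization must be analytic there) so that only central-difference
    derivatives enter the integration window.
    """
    u_ext, v_ext = _extend(np.asarray(u, float), pad), _extend(np.asarray(v, float), pad)
    U, V = np.meshgrid(u_ext, v_ext, indexing="ij")
    X = r_func(U, V)

    Xu = np.gradient(X, u_ext, axis=0)
    Xv = np.gradient(X, v_ext, axis=1)
    Xuu = np.gradient(Xu, u_ext, axis=0)
    Xuv = np.gradient(Xu, v_ext, axis=1)
    Xvv = np.gradient(Xv, v_ext, axis=1)

    E = (Xu * Xu).sum(-1)
    F = (Xu * Xv).sum(-1)
    G = (Xv * Xv).sum(-1)
    normal = np.cross(Xu, Xv)
    normal /= np.linalg.norm(normal, axis=-1, keepdims=True)
    L = (Xuu * normal).sum(-1)
    M = (Xuv * normal).sum(-1)
    N = (Xvv * normal).sum(-1)

    denom = E * G - F**2
    H = (E * N + G * L - 2 * F * M) / (2 * denom)
    integrand = (kappa / 2.0) * (2.0 * H) ** 2 * np.sqrt(denom)

    core = integrand[pad:-pad, pad:-pad]
    inner = np.trapezoid(core, v_ext[pad:-pad], axis=1)
    return float(np.trapezoid(inner, u_ext[pad:-pad]))


def sphere_energy(radius: float, kappa: float, n: int = 400) -> float:
    eps = 1e-3
    theta = np.linspace(eps, np.pi - eps, n)
    phi = np.linspace(0.0, 2 * np.pi, n)

    def param(T, P):
        return radius * np.stack(
            [np.sin(T) * np.cos(P), np.sin(T) * np.sin(P), np.cos(T)], axis=-1
        )

    return bending_energy_quadrature(param, theta, phi, kappa)


def _hemisphere_energy(radius: float, kappa: float, n: int = 400) -> float:
    eps = 1e-3
    theta = np.linspace(eps, np.pi / 2, n)
    phi = np.linspace(0.0, 2 * np.pi, n)

    def param(T, P):
        return radius * np.stack(
            [np.sin(T) * np.cos(P), np.sin(T) * np.sin(P), np.cos(T)], axis=-1
        )

    return bending_energy_quadrature(param, theta, phi, kappa)


def cylinder_energy(radius: float, length: float, kappa: float,
                    n: int = 400) -> float:
    z = np.linspace(0.0, length, n)
    phi = np.linspace(0.0, 2 * np.pi, n)

    def param(Z, P):
        return np.stack(
            [radius * np.cos(P), radius * np.sin(P), Z], axis=-1
        )

    return bending_energy_quadrature(param, z, phi, kappa)


def spherocylinder_energy(radius: float, total_length: float, kappa: float,
                          n: int = 400) -> float:
    """Cylinder body (tip-to-tip length minus both caps) plus two hemispheres."""
    body = total_length - 2 * radius
    return cylinder_energy(radius, body, kappa, n) + 2 * _hemisphere_energy(
        radius, kappa, n
    )


def tile_rim_energy(width: float, height: float, thickness: float,
                    kappa: float, n: int = 400) -> float:
    """Half-cylinder of radius thickness/2 swept along the plate perimeter.

    The sweep is straight, so one half-cylinder segment of total length
    equal to the perimeter has the same energy as the four edge pieces;
    corner contributions are excluded by construction, matching the model.
    """
    perimeter = 2 * (width + height)
    rho = thickness / 2.0
    u = np.linspace(0.0, perimeter, n)
    angle = np.linspace(-np.pi / 2, np.pi / 2, n)

    def param(U, A):
        return np.stack([U, rho * np.cos(A), rho * np.sin(A)], axis=-1)

    return bending_energy_quadrature(param, u, angle, kappa)
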