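"""Circuit solvers: complex nodal (phasor) analysis and a brute-force
transient integrator used as an independent oracle, plus a power audit.

Phasor convention: a real signal x(t) = A*sin(w*t + phi) is represented by
the complex phasor X = A*exp(j*phi), i.e. x(t) = Im(X * exp(j*w*t)).  The
drive phasor is amplitude*exp(j*phase).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import scipy.linalg

__all__ = [
    "PhasorSolution",
    "TransientSolution",
    "PowerReport",
    "solve_phasor",
    "solve_transient",
    "power_audit",
    "kcl_residual",
    "phasor_fit",
]

logger = logging.getLogger(__name__)


class SolveError(RuntimeError):
    pass


@dataclass
class PhasorSolution:
    """Sinusoidal steady state at the drive frequency.

    node_voltages[i] and branch_currents[k] are complex phasors; branch
    current k is positive from elements[k].node_a to .node_b.
    """

    node_voltages: np.ndarray
    branch_currents: np.ndarray
    frequency: float
    source_current: complex
    linear_residual: float = 0.0  # ||Y v - i|| / ||i|| of the nodal solve


@dataclass
class TransientSolution:
    """Time-domain solution from zero initial state (capacitors uncharged)."""

    times: np.ndarray
    node_voltages: np.ndarray  # (n_steps, n_nodes)
    branch_currents: np.ndarray  # (n_steps, n_elements)


def _element_admittance(element, omega: float) -> complex:
    if element.kind == "R":
        return 1.0 / element.value
    return 1j * omega * element.value


def solve_phasor(network, drive) -> PhasorSolution:
    """Solve the network at the drive frequency by complex nodal analysis.

    Unknowns are all node voltages except ground (0 V) and the source node
    (held at the drive phasor).  Mixed-precision iterative refinement
    polishes the dense direct solve; the final relative residual
    ||Y v - i||/||i|| is reported on the solution.
    """
    omega = drive.omega
    v_src = drive.amplitude * np.exp(1j * drive.phase)
    unknown = [
        i for i in range(network.n_nodes)
        if i not in (network.ground_node, network.source_node)
    ]
    index = {node: k for k, node in enumerate(unknown)}
    m = len(unknown)
    Y = np.zeros((m, m), dtype=complex)
    rhs = np.zeros(m, dtype=complex)
    for e in network.elements:
        y = _element_admittance(e, omega)
        for a, b in ((e.node_a, e.node_b), (e.node_b, e.node_a)):
            if a not in index:
                continue
            ia = index[a]
            Y[ia, ia] += y
            if b in index:
                Y[ia, index[b]] -= y
            elif b == network.source_node:
                rhs[ia] += y * v_src
            # ground contributes nothing
    if m:
        try:
            lu = scipy.linalg.lu_factor(Y)
        except (scipy.linalg.LinAlgError, ValueError) as exc:
            raise SolveError(f"singular admittance matrix: {exc}") from exc
        v = scipy.linalg.lu_solve(lu, rhs)
        if not np.all(np.isfinite(v)):
            bad = [network.node_labels[unknown[i]] for i in np.where(~np.isfinite(v))[0][:5]]
            raise SolveError(f"singular admittance matrix (floating subgraph near {bad})")
        # mixed-precision iterative refinement (residual in extended precision)
        Yx, rx = Y.astype(np.clongdouble), rhs.astype(np.clongdouble)
        for _ in range(2):
            r = np.asarray(rx - Yx @ v.astype(np.clongdouble), dtype=complex)
            v = v + scipy.linalg.lu_solve(lu, r)
        rhs_norm = np.linalg.norm(rhs)
        lin_res = float(np.linalg.norm(rhs - Y @ v) / rhs_norm) if rhs_norm > 0 else 0.0
    else:
        v = np.zeros(0, dtype=complex)
        lin_res = 0.0

    voltages = np.zeros(network.n_nodes, dtype=complex)
    voltages[network.source_node] = v_src
    voltages[unknown] = v
    currents = np.array(
        [
            (voltages[e.node_a] - voltages[e.node_b]) * _element_admittance(e, omega)
            for e in network.elements
        ],
        dtype=complex,
    )
    i_src = 0j
    for e, i_b in zip(network.elements, currents):
        if e.node_a == network.source_node:
            i_src += i_b
        elif e.node_b == network.source_node:
            i_src -= i_b
    return PhasorSolution(
        node_voltages=voltages,
        branch_currents=currents,
        frequency=drive.frequency,
        source_current=i_src,
        linear_residual=lin_res,
    )


def kcl_residual(solution: PhasorSolution, network) -> float:
    """Worst-case Kirchhoff current-law residual over internal nodes,
    relative to the largest current incident on each node."""
    net = np.zeros(network.n_nodes, dtype=complex)
    scale = np.zeros(network.n_nodes)
    for e, i_b in zip(network.elements, solution.branch_currents):
        net[e.node_a] -= i_b
        net[e.node_b] += i_b
        mag = abs(i_b)
        scale[e.node_a] = max(scale[e.node_a], mag)
        scale[e.node_b] = max(scale[e.node_b], mag)
    worst = 0.0
    for i in range(network.n_nodes):
        if i in (network.ground_node, network.source_node) or scale[i] == 0:
            continue
        worst = max(worst, abs(net[i]) / scale[i])
    return worst


def solve_transient(network, drive, dt: float, t_end: float) -> TransientSolution:
    """Brute-force time stepping with the trapezoidal rule (A-stable),
    from zero initial state.

    Serves as an independent oracle for the phasor solver: after the
    startup transient decays, per-cycle waveforms are periodic and their
    fitted phasors must match the nodal analysis.
    """
    if dt > drive.period / 200:
        est = (2 * math.pi * drive.frequency * dt) ** 2 / 12
        logger.warning(
            "dt=%.3g resolves < 200 steps/cycle; trapezoidal phase error ~%.2g rad/step",
            dt, est,
        )
    n_nodes = network.n_nodes
    G = np.zeros((n_nodes, n_nodes))
    C = np.zeros((n_nodes, n_nodes))
    for e in network.elements:
        M = G if e.kind == "R" else C
        w = 1.0 / e.value if e.kind == "R" else e.value
        M[e.node_a, e.node_a] += w
        M[e.node_b, e.node_b] += w
        M[e.node_a, e.node_b] -= w
        M[e.node_b, e.node_a] -= w

    unknown = np.array(
        [i for i in range(n_nodes) if i not in (network.ground_node, network.source_node)],
        dtype=int,
    )
    src = network.source_node
    Guu, Cuu = G[np.ix_(unknown, unknown)], C[np.ix_(unknown, unknown)]
    Gus, Cus = G[unknown, src], C[unknown, src]

    times = np.arange(0.0, t_end + 0.5 * dt, dt)
    omega = drive.omega
    vs = drive.amplitude * np.sin(omega * times + drive.phase)
    dvs = drive.amplitude * omega * np.cos(omega * times + drive.phase)
    s = np.outer(vs, Gus) + np.outer(dvs, Cus)  # (n_steps, m)

    A = Cuu + 0.5 * dt * Guu
    B = Cuu - 0.5 * dt * Guu
    lu = scipy.linalg.lu_factor(A)
    x = np.zeros(len(unknown))
    X = np.zeros((len(times), len(unknown)))
    for k in range(1, len(times)):
        rhs = B @ x - 0.5 * dt * (s[k - 1] + s[k])
        x = scipy.linalg.lu_solve(lu, rhs)
        X[k] = x

    V = np.zeros((len(times), n_nodes))
    V[:, src] = vs
    V[:, unknown] = X

    I = np.zeros((len(times), len(network.elements)))
    for k, e in enumerate(network.elements):
        u = V[:, e.node_a] - V[:, e.node_b]
        if e.kind == "R":
            I[:, k] = u / e.value
        else:
            I[:, k] = e.value * np.gradient(u, dt)
    return TransientSolution(times=times, node_voltages=V, branch_currents=I)


def phasor_fit(times: np.ndarray, values: np.ndarray, frequency: float) -> complex:
    """Least-squares fit of A*sin(wt)+B*cos(wt); returns the phasor A+jB
    under the x(t)=Im(X exp(jwt)) convention."""
    w = 2 * math.pi * frequency
    M = np.column_stack([np.sin(w * times), np.cos(w * times)])
    coef, *_ = np.linalg.lstsq(M, values, rcond=None)
    return complex(coef[0], coef[1])


@dataclass
class PowerReport:
    """Cycle-averaged power balance of a phasor solution (all in watt)."""

    source_power: float
    resistive_power: float
    capacitive_power: float  # sum of average capacitor powers, ~0
    relative_imbalance: float


def power_audit(solution: PhasorSolution, network) -> PowerReport:
    """Check conservation: mean source power 0.5*Re(V conj(I)) must equal
    the summed resistive dissipation 0.5*|I|^2*R; capacitors average to
    zero power over a cycle."""
    v_src = solution.node_voltages[network.source_node]
    p_src = 0.5 * (v_src * np.conj(solution.source_current)).real
    p_res = 0.0
    p_cap = 0.0
    for e, i_b in zip(network.elements, solution.branch_currents):
        u = solution.node_voltages[e.node_a] - solution.node_voltages[e.node_b]
        p = 0.5 * (u * np.conj(i_b)).real
        if e.kind == "R":
            p_res += p
        else:
            p_cap += p
    denom = max(abs(p_src), abs(p_res), 1e-300)
    return PowerReport(
        source_power=p_src,
        resistive_power=p_res,
        capacitive_power=p_cap,
        relative_imbalance=abs(p_src - p_res) / denom,
    )
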