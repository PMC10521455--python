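"""Synthetic expression matrices with known ground truth.

Emulates, at reduced scale, a dense circadian time course: a few hundred
genes observed at hundreds of time points across one daily cycle. The
matrix contains (a) background genes drawn from cluster archetypes —
phase-shifted sinusoids spanning one period plus a monotone-trend
archetype — with per-gene Gaussian noise, (b) a small regulatory core that
evolves as a stable VAR(1) process, and (c) a designated target gene inside
the core whose planted regulators are the recoverable ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_io import ExpressionMatrix

__all__ = ["GroundTruth", "default_core_adjacency", "simulate_dataset"]

_BURN_IN = 200


@dataclass(frozen=True)
class GroundTruth:
    """What was planted: background cluster labels (background genes only),
    the target id, and the core VAR coefficients aligned with ``core_ids``
    (entry [i, j] drives gene i at t+1 from gene j at t)."""

    cluster_labels: dict[str, int]
    target_id: str
    core_adjacency: np.ndarray
    core_ids: tuple[str, ...]
    noise_sd: float
    seed: int

    @property
    def regulator_ids(self) -> tuple[str, ...]:
        """Planted direct regulators of the target (nonzero incoming
        coefficients, self-lag excluded)."""
        t = self.core_ids.index(self.target_id)
        row = self.core_adjacency[t]
        return tuple(
            g for j, g in enumerate(self.core_ids) if j != t and row[j] != 0
        )


def default_core_adjacency(
    p_core: int = 6,
    n_regulators: int = 3,
    self_coef: float = 0.85,
    target_self_coef: float = 0.3,
    coupling: float = 0.45,
) -> np.ndarray:
    """Stable regulatory core: persistent regulators, sharply induced target.

    Non-target core genes carry a strong self-lag (``self_coef``) —
    expression is autocorrelated over a dense sampling grid — while the
    target's own memory is weak (``target_self_coef``) so its level is
    dominated by its ``n_regulators`` upstream drivers (positive coupling),
    the regime of a sharply induced output gene. Two design constraints
    shape this: a similarity-based selection stage can only discover
    regulators that share the target's temporal shape (anti-phased
    repressors are a documented limitation, hence activating couplings),
    and a strongly autoregressive target would absorb its regulators'
    lagged signal into its own lag, leaving little detectable partial
    correlation. The matrix is triangular apart from the diagonal, so its
    spectral radius equals the largest diagonal entry and stability is
    guaranteed.
    """
    if not 0 < n_regulators < p_core:
        raise ValueError("need 0 < n_regulators < p_core")
    A = np.eye(p_core) * self_coef
    A[0, 0] = target_self_coef
    A[0, 1 : n_regulators + 1] = coupling
    return A


def _archetypes(n_clusters: int, times: np.ndarray) -> np.ndarray:
    """n_clusters standardized temporal archetypes over one cycle."""
    span = times[-1] - times[0]
    phase = 2.0 * np.pi * (times - times[0]) / span
    profiles = [
        np.sin(phase + 2.0 * np.pi * k / n_clusters) for k in range(n_clusters - 1)
    ]
    profiles.append(np.linspace(-1.0, 1.0, len(times)))  # monotone trend
    arr = np.asarray(profiles)
    arr = arr - arr.mean(axis=1, keepdims=True)
    return arr / arr.std(axis=1, ddof=1, keepdims=True)


def simulate_dataset(
    n_genes: int = 300,
    T: int = 480,
    n_clusters: int = 4,
    core_adjacency: np.ndarray | None = None,
    noise_sd: float = 0.2,
    seed: int = 0,
    times: np.ndarray | None = None,
) -> tuple[ExpressionMatrix, GroundTruth]:
    """Generate a matrix with planted clusters and a planted regulatory core.

    Background genes are a cluster archetype plus N(0, noise_sd^2)
    observation noise, assigned to archetypes round-robin. Core genes follow
    a VAR(1) with a shared exogenous circadian drive,

        y(t+1) = A y(t) + g * pattern(t+1) + eps,   eps ~ N(0, noise_sd^2),

    where ``pattern`` is a distinctive standardized temporal shape (a sharp
    nocturnal pulse, unlike any background archetype) and the gain vector
    g = (I - A) 1 makes every core gene's deterministic component track the
    pattern at steady state; the planted couplings act on the deviations
    around it. The process is simulated past a burn-in (the drive held at
    its initial value) so it starts near steady state, and per-gene
    observation noise of the same noise_sd is added on top. Core genes are
    appended after the background genes and the first core gene is the
    target. Identical seed gives identical output.
    """
    if n_clusters < 1:
        raise ValueError(f"n_clusters must be >= 1, got {n_clusters}")
    if core_adjacency is None:
        core_adjacency = default_core_adjacency()
    A = np.asarray(core_adjacency, dtype=float)
    p_core = len(A)
    if A.shape != (p_core, p_core):
        raise ValueError("core_adjacency must be square")
    radius = float(np.max(np.abs(np.linalg.eigvals(A))))
    if radius >= 1.0:
        raise ValueError(
            f"core_adjacency is unstable (spectral radius {radius:.3f} >= 1)"
        )
    if n_genes < n_clusters + p_core:
        raise ValueError(
            f"need n_genes >= n_clusters + core size = {n_clusters + p_core}"
        )

    rng = np.random.default_rng(seed)
    if times is None:
        times = np.arange(T, dtype=float)
    else:
        times = np.asarray(times, dtype=float)
        T = len(times)

    n_bg = n_genes - p_core
    archetypes = _archetypes(n_clusters, times)
    labels = np.arange(n_bg) % n_clusters
    background = archetypes[labels] + rng.normal(0.0, noise_sd, size=(n_bg, T))

    s = (times - times[0]) / (times[-1] - times[0])
    pulse = np.exp(-0.5 * ((s - 0.75) / 0.08) ** 2)  # sharp nocturnal pulse
    pattern = (pulse - pulse.mean()) / pulse.std(ddof=1)
    gain = (np.eye(p_core) - A) @ np.ones(p_core)

    core = np.zeros((p_core, T))
    y = np.full(p_core, pattern[0])
    for step in range(_BURN_IN + T):
        drive = pattern[0] if step < _BURN_IN else pattern[step - _BURN_IN]
        y = A @ y + gain * drive + rng.normal(0.0, noise_sd, size=p_core)
        if step >= _BURN_IN:
            core[:, step - _BURN_IN] = y
    core += rng.normal(0.0, noise_sd, size=core.shape)

    bg_ids = tuple(f"BG{i:04d}" for i in range(n_bg))
    core_ids = ("TGT",) + tuple(f"CORE{j:02d}" for j in range(1, p_core))
    X = ExpressionMatrix(
        bg_ids + core_ids, times, np.vstack([background, core])
    )
    truth = GroundTruth(
        cluster_labels={g: int(l) for g, l in zip(bg_ids, labels)},
        target_id="TGT",
        core_adjacency=A,
        core_ids=core_ids,
        noise_sd=float(noise_sd),
        seed=int(seed),
    )
    return X, truth
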