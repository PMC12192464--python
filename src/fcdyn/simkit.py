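"""Synthetic SEEG-like session generator with known ground-truth networks.

Patient intracranial recordings cannot be shared, so every quantitative
claim in this package is exercised on surrogate sessions whose directed
coupling structure is known exactly.  Signals are produced by stable
multivariate autoregressive (MVAR) dynamics on a directed weighted network:
each channel's present value is a linear combination of all channels'
recent past plus white innovation noise.  A session concatenates task
blocks whose underlying networks differ, mimicking task-specific network
reconfiguration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .recording import Recording

__all__ = [
    "GroundTruthNetwork",
    "MVARGenerator",
    "TaskSession",
    "make_network",
    "mvar_from_network",
    "simulate_block",
    "simulate_session",
]

logger = logging.getLogger(__name__)

#: samples dropped at the start of each simulated block to remove the
#: transient from the zero initial condition
BURN_IN_SAMPLES = 1000

#: stationarity margin: companion spectral radius is shrunk to this bound
STABILITY_RADIUS = 0.95


@dataclass(frozen=True)
class GroundTruthNetwork:
    """Directed weighted adjacency used as simulation ground truth.

    ``adjacency[i, j]`` is the coupling strength of the directed edge
    i -> j; the diagonal is zero.
    """

    n_nodes: int
    adjacency: np.ndarray
    density: float
    seed: int

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency, dtype=float)
        if a.shape != (self.n_nodes, self.n_nodes):
            raise ValueError("adjacency shape does not match n_nodes")
        if (a < 0).any():
            raise ValueError("adjacency must be nonnegative")
        if np.diag(a).any():
            raise ValueError("adjacency diagonal must be zero")
        object.__setattr__(self, "adjacency", a)

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(self.adjacency))

    def edge_mask(self) -> np.ndarray:
        """Boolean n x n mask of true directed edges."""
        return self.adjacency > 0


@dataclass
class MVARGenerator:
    """Stable MVAR(p) process derived from a ground-truth network.

    ``coeff_tensor[k]`` is the n x n coefficient matrix at lag k+1 in the
    convention ``x(t) = sum_k A_k x(t-k) + e(t)`` with ``A_k[target, source]``.
    """

    order: int
    coeff_tensor: np.ndarray
    noise_cov: np.ndarray
    fs: float = 1000.0

    def companion_spectral_radius(self) -> float:
        return companion_spectral_radius(self.coeff_tensor)

    def simulate(self, n_samples: int, rng: np.random.Generator,
                 burn_in: int = BURN_IN_SAMPLES) -> np.ndarray:
        """Simulate ``n_samples`` post-burn-in samples, shape (n, n_samples)."""
        p, n, _ = self.coeff_tensor.shape
        total = n_samples + burn_in
        chol = np.linalg.cholesky(self.noise_cov)
        innov = rng.standard_normal((total, n)) @ chol.T
        x = np.zeros((total, n))
        for t in range(total):
            acc = innov[t].copy()
            for k in range(min(p, t)):
                acc += self.coeff_tensor[k] @ x[t - k - 1]
            x[t] = acc
        return x[burn_in:].T.copy()


@dataclass
class TaskSession:
    """A simulated session: recording + task annotations + truth networks."""

    recording: Recording
    annotations: list[tuple[float, float, str]]
    truth_networks: dict[str, GroundTruthNetwork] = field(default_factory=dict)

    def __post_init__(self) -> None:
        prev_end = 0.0
        dur = self.recording.duration_s
        for start, end, label in self.annotations:
            if start < prev_end - 1e-9 or end > dur + 1e-6:
                raise ValueError(
                    f"annotation ({start}, {end}, {label}) overlaps or exceeds duration"
                )
            prev_end = end
        missing = {lab for _, _, lab in self.annotations} - set(self.truth_networks)
        if self.truth_networks and missing:
            raise ValueError(f"no truth network for task(s) {sorted(missing)}")

    @property
    def task_labels(self) -> list[str]:
        seen: list[str] = []
        for _, _, lab in self.annotations:
            if lab not in seen:
                seen.append(lab)
        return seen


def make_network(n_nodes: int, density: float,
                 weight_range: tuple[float, float] = (0.3, 0.8),
                 seed: int = 0) -> GroundTruthNetwork:
    """Draw a random directed network with an exact edge count.

    Exactly ``round(density * n * (n-1))`` off-diagonal directed edges are
    placed uniformly at random, with weights uniform in ``weight_range``.
    """
    if n_nodes < 2:
        raise ValueError("need at least 2 nodes")
    if not 0 < density <= 1:
        raise ValueError("density must be in (0, 1]")
    n_possible = n_nodes * (n_nodes - 1)
    n_edges = int(round(density * n_possible))
    if n_edges == 0:
        raise ValueError(
            f"density {density} yields zero edges on {n_nodes} nodes; "
            "increase density or n_nodes"
        )
    rng = np.random.default_rng(seed)
    # enumerate off-diagonal slots and sample without replacement
    slots = [(i, j) for i in range(n_nodes) for j in range(n_nodes) if i != j]
    chosen = rng.choice(len(slots), size=n_edges, replace=False)
    lo, hi = weight_range
    adjacency = np.zeros((n_nodes, n_nodes))
    weights = rng.uniform(lo, hi, size=n_edges)
    for k, s in enumerate(chosen):
        i, j = slots[s]
        adjacency[i, j] = weights[k]
    return GroundTruthNetwork(n_nodes, adjacency, density, seed)


def companion_spectral_radius(coeff_tensor: np.ndarray) -> float:
    """Spectral radius of the VAR companion matrix (stationarity iff < 1)."""
    p, n, _ = coeff_tensor.shape
    comp = np.zeros((n * p, n * p))
    for k in range(p):
        comp[:n, k * n:(k + 1) * n] = coeff_tensor[k]
    if p > 1:
        comp[n:, :-n] = np.eye(n * (p - 1))
    return float(np.max(np.abs(np.linalg.eigvals(comp))))


def mvar_from_network(net: GroundTruthNetwork, order: int = 1,
                      self_decay: float = 0.5, noise_scale: float = 1.0,
                      fs: float = 1000.0,
                      max_shrink_iter: int = 50) -> MVARGenerator:
    """Map a directed network onto stable MVAR coefficients.

    The edge weight i -> j becomes the lag-1 cross coefficient (split evenly
    across lags when ``order > 1``); the diagonal carries a lag-1 self-decay.
    Coefficients are uniformly shrunk until the companion spectral radius is
    at most :data:`STABILITY_RADIUS`, keeping the generator stationary while
    preserving relative edge strengths.
    """
    n = net.n_nodes
    coeffs = np.zeros((order, n, n))
    # A_k[target, source]: transpose of the (source row -> target col) adjacency
    cross = net.adjacency.T / order
    for k in range(order):
        coeffs[k] += cross
    coeffs[0] += self_decay * np.eye(n)
    for _ in range(max_shrink_iter):
        rho = companion_spectral_radius(coeffs)
        if rho <= STABILITY_RADIUS:
            break
        coeffs *= (STABILITY_RADIUS / rho) * 0.999
    else:
        raise RuntimeError(
            f"could not stabilize MVAR coefficients (radius {rho:.3f}) "
            f"after {max_shrink_iter} shrink iterations"
        )
    noise_cov = (noise_scale ** 2) * np.eye(n)
    return MVARGenerator(order, coeffs, noise_cov, fs)


def _one_over_f_noise(shape: tuple[int, int], fs: float,
                      rng: np.random.Generator) -> np.ndarray:
    """Spectrally shaped (1/f amplitude) Gaussian noise, unit variance."""
    n_ch, n_s = shape
    freqs = np.fft.rfftfreq(n_s, d=1.0 / fs)
    amp = np.ones_like(freqs)
    amp[1:] = 1.0 / np.sqrt(freqs[1:])
    amp[0] = 0.0
    spec = (rng.standard_normal((n_ch, freqs.size))
            + 1j * rng.standard_normal((n_ch, freqs.size))) * amp
    x = np.fft.irfft(spec, n=n_s, axis=1)
    x /= x.std(axis=1, keepdims=True)
    return x


def simulate_block(net: GroundTruthNetwork, duration_s: float, fs: float,
                   order: int, noise_scale: float,
                   rng: np.random.Generator,
                   obs_noise_1f: float = 0.0) -> np.ndarray:
    """One stationary task block; shape (n_nodes, duration_s * fs)."""
    gen = mvar_from_network(net, order=order, noise_scale=noise_scale, fs=fs)
    n_samples = int(round(duration_s * fs))
    data = gen.simulate(n_samples, rng)
    if obs_noise_1f > 0:
        data = data + obs_noise_1f * data.std() * _one_over_f_noise(
            data.shape, fs, rng)
    return data


def simulate_session(truth_networks: dict[str, GroundTruthNetwork],
                     block_plan: list[tuple[str, float]],
                     fs: float = 1000.0, order: int = 1,
                     noise_scale: float = 1.0, seed: int = 0,
                     obs_noise_1f: float = 0.0) -> TaskSession:
    """Concatenate per-task MVAR blocks into one annotated session.

    Parameters
    ----------
    truth_networks
        Map task label -> ground-truth network; all must share ``n_nodes``.
    block_plan
        Ordered ``(task_label, duration_s)`` blocks.
    obs_noise_1f
        Relative amplitude of optional 1/f-shaped additive observation
        noise (0 disables it).
    """
    if not block_plan:
        raise ValueError("block_plan is empty")
    sizes = {net.n_nodes for net in truth_networks.values()}
    if len(sizes) != 1:
        raise ValueError(f"networks disagree on n_nodes: {sorted(sizes)}")
    missing = {lab for lab, _ in block_plan} - set(truth_networks)
    if missing:
        raise ValueError(f"block_plan references unknown task(s) {sorted(missing)}")

    rng = np.random.default_rng(seed)
    blocks, annotations = [], []
    t = 0.0
    for label, duration_s in block_plan:
        try:
            blocks.append(simulate_block(
                truth_networks[label], duration_s, fs, order, noise_scale,
                rng, obs_noise_1f=obs_noise_1f))
        except RuntimeError as exc:
            raise RuntimeError(f"block '{label}': {exc}") from exc
        annotations.append((t, t + duration_s, label))
        t += duration_s
    data = np.concatenate(blocks, axis=1)
    rec = Recording(data, fs)
    return TaskSession(rec, annotations, dict(truth_networks))
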