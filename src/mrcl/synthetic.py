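"""Linear structural-equation simulator with knockout-style interventions.

The generator produces everything the rest of the package consumes: an
observational data matrix, per-target interventional matrices emulating a
gene-knockout design (the target clamped to a strongly negative value on
the standardized scale), and direct/ancestral ground-truth adjacencies.

The model is z = B' z + eps at equilibrium, i.e. z = (I - B')^{-1} eps,
where B[i, j] is the direct effect of variable i on variable j and eps are
independent Gaussians. Cyclic systems are supported provided the spectral
radius of B stays below one (stability); an intervention replaces the
target's structural equation by the clamped value (graph surgery), leaving
all other equations intact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .pair_featurization import DataMatrix

DEFAULT_CLAMP = -3.0  # strong knockdown on the standardized scale
_CYCLIC_RADIUS = 0.9


def _names(p: int) -> list[str]:
    return [f"V{i:02d}" for i in range(p)]


@dataclass
class SEMSpec:
    """Weighted structure of a linear SEM.

    ``B[i, j]`` is the direct effect of variable i on variable j; the
    diagonal is zero and the spectral radius is strictly below one so the
    equilibrium distribution exists.
    """

    B: np.ndarray
    noise_scale: np.ndarray
    cyclic: bool
    seed: int

    def __post_init__(self) -> None:
        self.B = np.asarray(self.B, dtype=float)
        self.noise_scale = np.asarray(self.noise_scale, dtype=float)
        p = self.B.shape[0]
        if self.B.shape != (p, p):
            raise ValueError("B must be square")
        if np.any(np.diag(self.B) != 0):
            raise ValueError("B must have zero diagonal")
        if np.any(self.noise_scale <= 0):
            raise ValueError("noise scales must be positive")
        if self.spectral_radius() >= 1.0:
            raise ValueError(
                f"unstable system: spectral radius "
                f"{self.spectral_radius():.3f} >= 1"
            )

    @property
    def p(self) -> int:
        return self.B.shape[0]

    def spectral_radius(self) -> float:
        return float(np.max(np.abs(np.linalg.eigvals(self.B))))


def sample_sem_spec(
    p: int,
    edge_density: float,
    cyclic: bool = False,
    seed: int = 0,
    noise_scale: float = 1.0,
) -> SEMSpec:
    """Draw a random SEM structure.

    Each admissible ordered pair carries an edge with probability
    ``edge_density``; nonzero weights have magnitude uniform in [0.5, 1.5]
    and random sign. Acyclic systems restrict support to a random
    topological order (B is then permutation-similar to strictly
    triangular); cyclic systems admit every off-diagonal entry and are
    rescaled, if necessary, to spectral radius 0.9.
    """
    if p < 2:
        raise ValueError("p must be >= 2")
    if not 0 < edge_density < 1:
        raise ValueError("edge_density must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    B = np.zeros((p, p))
    mask = rng.random((p, p)) < edge_density
    np.fill_diagonal(mask, False)
    if not cyclic:
        order = rng.permutation(p)
        pos = np.empty(p, dtype=int)
        pos[order] = np.arange(p)
        admissible = pos[:, None] < pos[None, :]
        mask &= admissible
    mags = rng.uniform(0.5, 1.5, size=(p, p))
    signs = rng.choice([-1.0, 1.0], size=(p, p))
    B[mask] = (mags * signs)[mask]
    if cyclic:
        sr = np.max(np.abs(np.linalg.eigvals(B)))
        if sr > _CYCLIC_RADIUS:
            B *= _CYCLIC_RADIUS / sr
    return SEMSpec(B=B, noise_scale=np.full(p, float(noise_scale)),
                   cyclic=cyclic, seed=seed)


def simulate_observational(spec: SEMSpec, n: int, seed: int = 0) -> DataMatrix:
    """Draw n equilibrium samples z = (I - B')^{-1} eps."""
    rng = np.random.default_rng(seed)
    eps = rng.normal(scale=spec.noise_scale, size=(n, spec.p))
    # row-wise: Z = eps @ (I - B)^{-1}
    Z = np.linalg.solve((np.eye(spec.p) - spec.B).T, eps.T).T
    return DataMatrix(Z, _names(spec.p))


def simulate_intervention(
    spec: SEMSpec,
    target: int,
    n: int,
    clamp_value: float = DEFAULT_CLAMP,
    seed: int = 0,
) -> DataMatrix:
    """Draw n samples with the target variable clamped (graph surgery).

    The target's structural equation is replaced by the constant
    ``clamp_value`` (all incoming effects removed, zero noise); the other
    variables solve the reduced equilibrium as usual.
    """
    if not 0 <= target < spec.p:
        raise IndexError(f"target {target} out of range for p={spec.p}")
    rng = np.random.default_rng(seed)
    B = spec.B.copy()
    B[:, target] = 0.0  # sever incoming edges
    eps = rng.normal(scale=spec.noise_scale, size=(n, spec.p))
    eps[:, target] = clamp_value
    Z = np.linalg.solve((np.eye(spec.p) - B).T, eps.T).T
    return DataMatrix(Z, _names(spec.p))


def ground_truth(
    spec: SEMSpec, effect_threshold: float = 0.1
) -> tuple[np.ndarray, np.ndarray]:
    """Direct and ancestral truth adjacencies of a SEM.

    The direct truth marks nonzero entries of B. Total effects are
    T = (I - B)^{-1} - I (the sum over all directed paths of their weight
    products); the ancestral truth marks |T| above ``effect_threshold``,
    discarding the many tiny propagated effects that are scientifically
    irrelevant. Diagonals are zero.
    """
    truth_direct = (spec.B != 0).astype(int)
    T = np.linalg.inv(np.eye(spec.p) - spec.B) - np.eye(spec.p)
    truth_ancestral = (np.abs(T) > effect_threshold).astype(int)
    np.fill_diagonal(truth_direct, 0)
    np.fill_diagonal(truth_ancestral, 0)
    return truth_direct, truth_ancestral


def total_effects(spec: SEMSpec) -> np.ndarray:
    """Total (ancestral) effect matrix T = (I - B)^{-1} - I."""
    return np.linalg.inv(np.eye(spec.p) - spec.B) - np.eye(spec.p)


@dataclass
class SyntheticSystem:
    """A SEM together with simulated data and ground truth."""

    spec: SEMSpec
    observational: DataMatrix
    interventional: dict[int, DataMatrix]  # target -> samples
    clamp_value: float
    truth_direct: np.ndarray
    truth_ancestral: np.ndarray
    seed: int = 0


def simulate_system(
    p: int = 20,
    edge_density: float = 0.1,
    n_obs: int = 1000,
    n_int_per_target: int = 25,
    cyclic: bool = False,
    clamp_value: float = DEFAULT_CLAMP,
    effect_threshold: float = 0.1,
    seed: int = 0,
) -> SyntheticSystem:
    """Generate a complete study: structure, data, interventions, truth.

    Every variable is intervened on in turn (the knockout-compendium
    design). All randomness descends from the single ``seed`` through a
    spawned seed sequence: child 0 draws the structure, child 1 the
    observational samples, children 2..p+1 the per-target interventions.
    """
    children = np.random.SeedSequence(seed).spawn(p + 2)
    sub = [int(c.generate_state(1)[0] % (2**31)) for c in children]
    spec = sample_sem_spec(p, edge_density, cyclic=cyclic, seed=sub[0])
    obs = simulate_observational(spec, n_obs, seed=sub[1])
    inter = {
        t: simulate_intervention(spec, t, n_int_per_target,
                                 clamp_value=clamp_value, seed=sub[2 + t])
        for t in range(p)
    }
    truth_direct, truth_ancestral = ground_truth(spec, effect_threshold)
    return SyntheticSystem(
        spec=spec, observational=obs, interventional=inter,
        clamp_value=clamp_value, truth_direct=truth_direct,
        truth_ancestral=truth_ancestral, seed=seed,
    )


def intervention_effects(system: SyntheticSystem) -> np.ndarray:
    """Aggregate per-target interventional samples into a p x p effect table.

    Entry (i, j) is the mean level of variable j across the samples where
    variable i was clamped — the single interventional measurement the gold
    standard consumes.
    """
    p = system.spec.p
    Z = np.empty((p, p))
    for t, dm in system.interventional.items():
        Z[t] = dm.values.mean(axis=0)
    return Z
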