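"""Synthetic profiled libraries and viability screens.

The generator emulates the statistical structure the regression method
assumes: drugs inhibit a sparse subset of kinases (profiles near 1 for
untouched kinases, well below 1 for targets), drug pairs act independently
per kinase (activities multiply), and viability follows the multiplicative
model

    v = exp(-b0) * prod_k A_k^(b_k) * exp(-noise)

equivalently, -log v is linear in the -log activities with additive
Gaussian noise. Each cell line has its own sparse true coefficient vector;
the cancer line shares half of its active kinases with the normal line and
owns the other half exclusively, so the differential ranking beta^C -
beta^N has a known answer by construction.

Default sizes mirror a realistic kinome screen: 140 profiled inhibitors,
291 assayed kinases, ~15 appreciably inhibited kinases per drug, 10 active
kinases per cell line with effects of magnitude ~0.5 on the -log scale and
noise of s.d. 0.1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import ActivityMatrix, ScreenRecord, ScreenTable
from .treatments import DEFAULT_EPSILON, Treatment

__all__ = ["SimulationConfig", "simulate_activity_matrix", "simulate_screen"]


@dataclass(frozen=True)
class SimulationConfig:
    n_drugs: int = 140
    n_kinases: int = 291
    targets_per_drug: float = 15.0
    n_active_kinases: int = 10
    true_beta_scale: float = 0.5
    noise_sd: float = 0.1
    pair_fraction: float = 1.0
    true_intercept: float = 0.0
    epsilon: float = DEFAULT_EPSILON
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_drugs < 1 or self.n_kinases < 1:
            raise ValueError("n_drugs and n_kinases must be positive")
        if not 0 <= self.n_active_kinases <= self.n_kinases:
            raise ValueError("n_active_kinases must be in [0, n_kinases]")
        if self.noise_sd < 0 or self.targets_per_drug < 0:
            raise ValueError("noise_sd and targets_per_drug must be >= 0")
        if not 0 <= self.pair_fraction <= 1:
            raise ValueError("pair_fraction must be in [0, 1]")


def simulate_activity_matrix(config: SimulationConfig) -> ActivityMatrix:
    """Draw a sparse drug x kinase residual-activity matrix.

    Each drug inhibits a Poisson(targets_per_drug)-sized random kinase
    subset with activities uniform on (0, 0.5); all other activities are
    uniform on (0.8, 1.0]. Deterministic given the seed.
    """
    rng = np.random.default_rng(config.seed)
    n_d, n_k = config.n_drugs, config.n_kinases
    values = 1.0 - rng.uniform(0.0, 0.2, size=(n_d, n_k))  # background near 1
    for i in range(n_d):
        n_targets = min(int(rng.poisson(config.targets_per_drug)), n_k)
        if n_targets == 0:
            continue
        targets = rng.choice(n_k, size=n_targets, replace=False)
        values[i, targets] = rng.uniform(0.0, 0.5, size=n_targets)
    width = max(3, len(str(max(n_d, n_k))))
    return ActivityMatrix(
        drug_ids=[f"D{i + 1:0{width}d}" for i in range(n_d)],
        kinase_ids=[f"K{j + 1:0{width}d}" for j in range(n_k)],
        values=values,
    )


def _draw_treatments(
    rng: np.random.Generator, drug_ids: list[str], pair_fraction: float
) -> list[Treatment]:
    n = len(drug_ids)
    n_pairs = round(pair_fraction * n)
    n_singles = n - n_pairs
    treatments: list[Treatment] = []
    singles = rng.choice(n, size=n_singles, replace=False)
    treatments.extend(Treatment([drug_ids[i]]) for i in singles)
    seen: set[tuple[str, str]] = set()
    max_pairs = n * (n - 1) // 2
    if n_pairs > max_pairs:
        raise ValueError(f"cannot draw {n_pairs} distinct pairs from {n} drugs")
    while len(seen) < n_pairs:
        i, j = rng.choice(n, size=2, replace=False)
        key = tuple(sorted((drug_ids[i], drug_ids[j])))
        if key not in seen:
            seen.add(key)
            treatments.append(Treatment(key))
    return treatments


def _draw_true_betas(
    rng: np.random.Generator, config: SimulationConfig
) -> dict[str, np.ndarray]:
    """Sparse positive effects; cancer shares half its actives with normal."""
    n_k, n_a = config.n_kinases, config.n_active_kinases
    n_shared = n_a // 2
    n_specific = n_a - n_shared
    pool = rng.permutation(n_k)
    normal_idx = pool[:n_a]
    shared = normal_idx[:n_shared]
    cancer_only = pool[n_a : n_a + n_specific]
    betas = {}
    for label, idx in (("normal", normal_idx), ("cancer", np.concatenate([shared, cancer_only]))):
        beta = np.zeros(n_k)
        if len(idx):
            beta[np.asarray(idx, dtype=int)] = config.true_beta_scale * rng.uniform(
                0.5, 1.5, size=len(idx)
            )
        betas[label] = beta
    return betas


def simulate_screen(
    profiles: ActivityMatrix,
    config: SimulationConfig,
    cell_lines: tuple[str, str] = ("IMR90", "A549"),
) -> tuple[ScreenTable, dict]:
    """Simulate a viability screen over the profiled drugs.

    Draws n_drugs treatments (singles and unordered pairs per
    ``pair_fraction``; pair activities multiply kinase-wise), a sparse true
    coefficient vector per cell line, and viabilities from the
    multiplicative model with additive Gaussian noise on the -log scale.
    The first cell line plays the normal role, the second the cancer role.

    Returns the screen plus the generating truth: per cell line the true
    intercept, coefficient vector and active kinase ids.
    """
    rng = np.random.default_rng(config.seed + 1)  # independent of the profile draw
    treatments = _draw_treatments(rng, profiles.drug_ids, config.pair_fraction)
    betas = _draw_true_betas(rng, config)
    roles = {"normal": cell_lines[0], "cancer": cell_lines[1]}

    neglog_rows = np.empty((len(treatments), profiles.n_kinases))
    for i, t in enumerate(treatments):
        a = profiles.values[profiles.drug_index[t.drugs[0]]].copy()
        for d in t.drugs[1:]:
            a = a * profiles.values[profiles.drug_index[d]]
        neglog_rows[i] = -np.log(np.maximum(a, config.epsilon))

    viab = {}
    for role, label in roles.items():
        y = config.true_intercept + neglog_rows @ betas[role]
        if config.noise_sd > 0:
            y = y + rng.normal(0.0, config.noise_sd, size=len(treatments))
        viab[label] = np.maximum(np.exp(-y), config.epsilon)

    records = [
        ScreenRecord(
            treatment=t,
            viability={label: float(viab[label][i]) for label in viab},
        )
        for i, t in enumerate(treatments)
    ]
    screen = ScreenTable(records=records, cell_lines=list(cell_lines))
    truth = {
        roles[role]: {
            "role": role,
            "intercept": config.true_intercept,
            "beta": betas[role],
            "active_kinases": [
                profiles.kinase_ids[j] for j in np.flatnonzero(betas[role])
            ],
        }
        for role in roles
    }
    return screen, truth
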