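"""Synthetic sparse compositional datasets with known ground truth.

The generator emulates the data regime of a 16S rRNA genus-level survey:
non-negative relative abundances (rows sum to 100), a modest number of
features of which a few are informative, strong within-group redundancy
(blocks of highly correlated informative taxa), and many sparse,
class-independent noise taxa.

Construction is on the log scale: an informative feature in redundancy group
g with target correlation ρ is

    log x = μ_f + σ·(δ_c + √ρ · z_g + √(1−ρ) · ε)

with a per-feature baseline μ_f, a class offset δ_c spanning ``effect_size``
within-class standard deviations, a shared group latent z_g and independent
noise ε (z_g, ε standard normal), so within-class pairwise correlation
inside a group is ρ by construction.  The informative within-class log-scale
SD σ is kept moderate (0.4) so that the requested correlation survives the
exponential map and the compositional closure — at σ = 1 the
lognormal-to-Pearson attenuation would push an abundance-scale correlation
well below its log-scale target.  Noise features have no class offset, unit
log-scale SD, and receive structural zeros at the ``sparsity`` rate.
Finally rows are closed to percentages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data_model import AbundanceTable, to_relative_abundance

__all__ = ["SyntheticSpec", "SyntheticTruth", "generate"]

#: within-class log-scale SD of informative features (see module docstring)
_SIGMA_LOG = 0.4
#: log-scale baseline offset of noise features relative to informative taxa;
#: sparse class-independent taxa are the rare tail of a survey, so their
#: baseline abundance sits well below the informative genera — this also
#: keeps row totals (hence closure noise) governed by the informative taxa
_NOISE_LOG_OFFSET = -1.5


@dataclass(frozen=True)
class SyntheticSpec:
    """Ground-truth recipe for one synthetic dataset.

    Defaults mirror a two-class cohort with three blocks of four strongly
    correlated informative taxa among many sparse noise taxa.
    """

    n_per_class: tuple[int, ...] = (60, 60)
    n_features: int = 52
    n_informative: int = 12
    redundancy_groups: tuple[tuple[int, float], ...] = ((4, 0.95),) * 3
    sparsity: float = 0.6
    effect_size: float = 1.5
    seed: int = 0

    def validate(self) -> None:
        if self.n_informative > self.n_features:
            raise ValueError("n_informative exceeds n_features")
        if sum(s for s, _ in self.redundancy_groups) > self.n_informative:
            raise ValueError("redundancy groups exceed n_informative")
        if not 0 <= self.sparsity < 1:
            raise ValueError("sparsity must be in [0, 1)")
        if any(not 0 < r <= 1 for _, r in self.redundancy_groups):
            raise ValueError("group correlation must be in (0, 1]")
        if len(self.n_per_class) < 2:
            raise ValueError("need at least 2 classes")
        if any(n < 2 for n in self.n_per_class):
            raise ValueError("each class needs at least 2 samples")


@dataclass(frozen=True)
class SyntheticTruth:
    """Which generated features carry signal, and their group structure."""

    informative_indices: tuple[int, ...]
    group_of_feature: dict[int, int]
    noise_indices: tuple[int, ...]


def _class_offsets(K: int, effect_size: float, group: int | None, rng) -> np.ndarray:
    """Centered class offsets with adjacent means ``effect_size`` apart.

    Redundancy group g receives the base offsets cyclically rotated by g
    (a Latin-square assignment): different groups discriminate along
    different class contrasts, and the per-class total shift summed over
    groups is (near) zero.  The balance matters because the table is closed
    to percentages — relative abundances carry only compositional contrasts,
    so class signal placed in the total microbial load would be removed by
    the closure.  Ungrouped informative features get a random rotation.
    """
    base = (np.arange(K) - (K - 1) / 2.0) * effect_size
    shift = group if group is not None else int(rng.integers(K))
    return np.roll(base, shift)


def generate(spec: SyntheticSpec) -> tuple[AbundanceTable, SyntheticTruth]:
    """Draw one dataset; bit-identical for identical specs."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    K = len(spec.n_per_class)
    n = int(sum(spec.n_per_class))
    labels = np.repeat([f"C{k}" for k in range(K)], spec.n_per_class)
    class_idx = np.repeat(np.arange(K), spec.n_per_class)

    d = spec.n_features
    log_x = np.empty((n, d))
    baseline = rng.normal(0.0, 1.0, size=d)

    informative: list[int] = []
    group_of: dict[int, int] = {}
    col = 0
    for g, (size, rho) in enumerate(spec.redundancy_groups):
        z = rng.normal(0.0, 1.0, size=n)
        delta = _class_offsets(K, spec.effect_size, g, rng)
        for _ in range(size):
            eps = rng.normal(0.0, 1.0, size=n)
            log_x[:, col] = baseline[col] + _SIGMA_LOG * (
                delta[class_idx] + np.sqrt(rho) * z + np.sqrt(1.0 - rho) * eps
            )
            informative.append(col)
            group_of[col] = g
            col += 1
    # ungrouped informative features: independent class-shifted taxa
    while col < spec.n_informative:
        delta = _class_offsets(K, spec.effect_size, None, rng)
        log_x[:, col] = baseline[col] + _SIGMA_LOG * (
            delta[class_idx] + rng.normal(0.0, 1.0, size=n)
        )
        informative.append(col)
        col += 1
    noise_cols = list(range(col, d))
    for j in noise_cols:
        log_x[:, j] = (
            baseline[j] + _NOISE_LOG_OFFSET + rng.normal(0.0, 1.0, size=n)
        )

    abundances = np.exp(log_x)
    if noise_cols:
        zeros = rng.random((n, len(noise_cols))) < spec.sparsity
        abundances[:, noise_cols] *= ~zeros

    # shuffle feature order so structure is not positional
    perm = rng.permutation(d)
    abundances = abundances[:, perm]
    where = np.empty(d, dtype=int)  # where[old] = new position
    where[perm] = np.arange(d)

    table = AbundanceTable(
        values=abundances,
        sample_ids=[f"S{i}" for i in range(n)],
        feature_labels=[f"taxon_{j}" for j in range(d)],
        labels=labels,
    )
    table = to_relative_abundance(table)
    truth = SyntheticTruth(
        informative_indices=tuple(int(where[j]) for j in informative),
        group_of_feature={int(where[j]): g for j, g in group_of.items()},
        noise_indices=tuple(int(where[j]) for j in noise_cols),
    )
    return table, truth
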