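"""Synthetic multi-region expression generator with planted ground truth.

The generator emulates the structure of a multi-region case/control microarray
study: several brain-region sub-datasets over one probe universe, two classes
per region, a fraction of individuals contributing samples to more than one
region (with the disease class preserved), a planted set of features
differential in every region, per-region planted features, and uninformative
noise features.  The model is additive Gaussian on the log2 scale:

    value(f, s) = baseline_f + class(s) * effect(f, region(s))
                  + individual_effect(individual(s), f) + noise

with effect(f, r) = ±δ for planted features active in region r and 0
otherwise.  Everything is reproducible from the configured seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import Dataset, SampleMeta

__all__ = ["GeneratorConfig", "SyntheticTruth", "RecoveryScore", "generate", "score_recovery"]

#: default region composition: five cortical/limbic regions, balanced classes
DEFAULT_REGIONS: dict[str, tuple[int, int]] = {
    "EC": (10, 10),
    "HIP": (10, 10),
    "MTG": (10, 10),
    "PC": (10, 10),
    "SFG": (10, 10),
}


@dataclass
class GeneratorConfig:
    """Study-design parameters of the generator.

    Defaults encode the reference simulation conditions: 200 probes of which
    30 are differential in all regions and 10 per region are region-specific,
    five regions with 10 control + 10 affected samples each, a planted shift
    of δ = 3 log2 units against unit-SD noise, and 30% of individuals
    re-appearing in further regions with an additive per-individual effect.
    """

    n_features: int = 200
    n_shared_de: int = 30
    n_specific_de: int = 10  # per region
    regions: dict[str, tuple[int, int]] = field(
        default_factory=lambda: dict(DEFAULT_REGIONS)
    )  # region -> (n_control, n_affected)
    effect_size: float = 3.0  # δ, log2 units
    baseline_mean: float = 8.0
    baseline_sd: float = 2.0
    noise_sd: float = 1.0  # σ
    individual_overlap: float = 0.3  # fraction of samples drawn from returning donors
    individual_sd: float = 0.3  # SD of the additive per-individual effect
    seed: int = 0

    def validate(self) -> None:
        if self.n_features <= 0:
            raise ValueError("n_features must be positive")
        counts = (self.n_shared_de, self.n_specific_de)
        if any(c < 0 for c in counts):
            raise ValueError("planted feature counts must be >= 0")
        total_planted = self.n_shared_de + self.n_specific_de * len(self.regions)
        if total_planted > self.n_features:
            raise ValueError(
                f"{total_planted} planted features exceed n_features={self.n_features}"
            )
        if not 0.0 <= self.individual_overlap <= 1.0:
            raise ValueError("individual_overlap must be in [0, 1]")
        if self.noise_sd < 0 or self.individual_sd < 0 or self.baseline_sd < 0:
            raise ValueError("SDs must be non-negative")
        for r, (nc, na) in self.regions.items():
            if nc < 1 or na < 1:
                raise ValueError(f"region {r!r} needs >= 1 sample per class")


@dataclass
class SyntheticTruth:
    """Ground truth of a generated dataset."""

    shared_features: list[str]
    specific_features: dict[str, list[str]]  # region -> feature ids
    effects: pd.Series  # signed δ per planted feature (0 elsewhere implied)
    individuals: dict[str, str]  # sample_id -> individual id

    @property
    def planted(self) -> set[str]:
        out = set(self.shared_features)
        for feats in self.specific_features.values():
            out.update(feats)
        return out


def generate(config: GeneratorConfig) -> tuple[Dataset, SyntheticTruth]:
    """Draw one dataset + ground truth from the configured study design."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_features
    feature_ids = [f"probe_{i:04d}" for i in range(n)]
    # planted assignment: a random draw of disjoint shared / specific blocks
    perm = rng.permutation(n)
    shared_idx = perm[: config.n_shared_de]
    specific_idx: dict[str, np.ndarray] = {}
    offset = config.n_shared_de
    for r in config.regions:
        specific_idx[r] = perm[offset : offset + config.n_specific_de]
        offset += config.n_specific_de
    # signed effect per planted feature (direction randomised, as real
    # signatures mix up- and down-regulation)
    sign = rng.choice([-1.0, 1.0], size=n)
    effect = np.zeros(n)
    effect[shared_idx] = sign[shared_idx] * config.effect_size
    for r in config.regions:
        effect[specific_idx[r]] = sign[specific_idx[r]] * config.effect_size
    baseline = rng.normal(config.baseline_mean, config.baseline_sd, size=n)

    # individuals: per class, returning donors are re-drawn from the roster
    rosters: dict[int, list[str]] = {0: [], 1: []}
    indiv_effects: dict[str, np.ndarray] = {}
    counter = 0

    def new_individual(klass: int) -> str:
        nonlocal counter
        name = f"ind_{counter:03d}"
        counter += 1
        rosters[klass].append(name)
        indiv_effects[name] = rng.normal(0.0, config.individual_sd, size=n)
        return name

    samples: list[SampleMeta] = []
    columns: list[np.ndarray] = []
    individuals: dict[str, str] = {}
    for region, (n_c, n_a) in config.regions.items():
        used_here: set[str] = set()
        for klass, count in ((0, n_c), (1, n_a)):
            for i in range(count):
                available = [p for p in rosters[klass] if p not in used_here]
                if available and rng.random() < config.individual_overlap:
                    ind = available[rng.integers(len(available))]
                else:
                    ind = new_individual(klass)
                used_here.add(ind)
                sid = f"{region}_{'C' if klass == 0 else 'A'}{i:02d}"
                samples.append(
                    SampleMeta(sample_id=sid, region=region, klass=klass, individual=ind)
                )
                individuals[sid] = ind
                active = np.zeros(n)
                active[shared_idx] = 1.0
                active[specific_idx[region]] = 1.0
                col = (
                    baseline
                    + klass * effect * active
                    + indiv_effects[ind]
                    + rng.normal(0.0, config.noise_sd, size=n)
                )
                columns.append(col)
    matrix = pd.DataFrame(
        np.column_stack(columns), index=feature_ids,
        columns=[s.sample_id for s in samples],
    )
    truth = SyntheticTruth(
        shared_features=[feature_ids[i] for i in sorted(shared_idx)],
        specific_features={
            r: [feature_ids[i] for i in sorted(idx)] for r, idx in specific_idx.items()
        },
        effects=pd.Series(effect, index=feature_ids),
        individuals=individuals,
    )
    return Dataset(matrix=matrix, samples=samples), truth


@dataclass
class RecoveryScore:
    shared_recall: float
    specific_recall: float
    precision: float  # vs all planted features


def score_recovery(truth: SyntheticTruth, selected) -> RecoveryScore:
    """Precision/recall of a selected feature set against the planted truth."""
    from .featureset import FeatureSetSolution, SignatureReport

    if isinstance(selected, SignatureReport):
        selected = set(selected.solution.selected) if selected.solution else set()
    elif isinstance(selected, FeatureSetSolution):
        selected = set(selected.selected)
    else:
        selected = set(selected)
    shared = set(truth.shared_features)
    specific = {f for feats in truth.specific_features.values() for f in feats}
    planted = shared | specific
    return RecoveryScore(
        shared_recall=len(selected & shared) / len(shared) if shared else 0.0,
        specific_recall=len(selected & specific) / len(specific) if specific else 0.0,
        precision=len(selected & planted) / len(selected) if selected else 0.0,
    )
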