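"""Synthetic trait battery with a planted latent affective factor.

The cohort carries 18 questionnaire subscale scores (general and borderline
personality-disorder screens, depression/anxiety, four psychopathy facets,
three apathy facets, three alexithymia facets, four empathy facets).  A
single standard-normal latent factor A — the "broad affective cluster" —
loads on a configurable subset of traits (positively on empathic concern and
perspective taking, negatively on emotional apathy, externally oriented
thinking, and the affective/interpersonal psychopathy facets by default) and
drives both prosociality indices through independent noise.

The noise on the indices is calibrated analytically so the *population* first
canonical correlation between the 18-trait set and the 2-index set equals a
target value: with traits x_j = l_j A + √(1−l_j²) ε_j the best trait
combination correlates with A at R_X = √(s/(1+s)), s = Σ l_j²/(1−l_j²), and
with both indices loading c on A the best index combination correlates at
R_Y = √(t/(1+t)), t = 2c²/(1−c²); the sets relate only through A, so
r₁ = R_X · R_Y and c follows from the target.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

TRAIT_NAMES = (
    "SAPAS",
    "MSI-BPD",
    "DASS-Dep",
    "DASS-Anx",
    "SRP-I",
    "SRP-Aff",
    "SRP-L",
    "SRP-Ant",
    "AMI-BA",
    "AMI-SM",
    "AMI-ES",
    "TAS-DDF",
    "TAS-DIF",
    "TAS-EOT",
    "IRI-PT",
    "IRI-FT",
    "IRI-EC",
    "IRI-PD",
)

#: plausible instrument-scale (mean, sd) used to place the standardized
#: scores on each questionnaire's numeric range; affine, hence cosmetic for
#: every rank- or correlation-based downstream stage.
TRAIT_SCALES = {
    "SAPAS": (3.0, 1.8),
    "MSI-BPD": (3.5, 2.5),
    "DASS-Dep": (5.0, 4.5),
    "DASS-Anx": (4.0, 4.0),
    "SRP-I": (17.0, 5.5),
    "SRP-Aff": (16.0, 5.0),
    "SRP-L": (19.0, 5.5),
    "SRP-Ant": (11.0, 4.0),
    "AMI-BA": (12.0, 5.0),
    "AMI-SM": (11.0, 5.0),
    "AMI-ES": (10.0, 5.0),
    "TAS-DDF": (12.0, 4.5),
    "TAS-DIF": (14.0, 5.5),
    "TAS-EOT": (18.0, 4.5),
    "IRI-PT": (17.0, 5.5),
    "IRI-FT": (16.0, 6.0),
    "IRI-EC": (19.0, 5.5),
    "IRI-PD": (11.0, 5.5),
}

DEFAULT_LOADINGS = {
    "IRI-EC": 0.60,
    "IRI-PT": 0.45,
    "AMI-ES": -0.55,
    "TAS-EOT": -0.45,
    "SRP-Aff": -0.45,
    "SRP-I": -0.40,
}

GROUND_TRUTH_COLUMNS = (
    "participant_id",
    "kappa_self",
    "kappa_other",
    "beta_self",
    "beta_other",
    "lambda_self",
    "lambda_other",
    "beta_effort",
    "latent_A",
    "hyperaltruism",
    "prosocial_effort",
)


@dataclass(frozen=True)
class PlantedStructure:
    """Latent-factor structure planted in a synthetic cohort.

    ``loadings`` maps trait names to standardized loadings on the latent
    factor (unnamed traits load 0); ``r_target`` is the population first
    canonical correlation between traits and the two prosociality indices.
    Index means/sds place the indices on the parameter-difference scale:
    hyperaltruism = κ_other − κ_self, prosocial effort = −(λ_other − λ_self).
    """

    loadings: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_LOADINGS))
    r_target: float = 0.4
    mean_hyperaltruism: float = 0.08
    sd_hyperaltruism: float = 0.20
    mean_prosocial_effort: float = -0.08
    sd_prosocial_effort: float = 0.12

    @classmethod
    def null(cls) -> "PlantedStructure":
        """No latent structure: traits and indices independent."""
        return cls(loadings={}, r_target=0.0)

    def loading_vector(self) -> np.ndarray:
        unknown = set(self.loadings) - set(TRAIT_NAMES)
        if unknown:
            raise ValueError(f"unknown trait names: {sorted(unknown)}")
        return np.array([self.loadings.get(name, 0.0) for name in TRAIT_NAMES])

    def index_factor_loading(self) -> float:
        """Loading c of each index on the latent factor implied by r_target."""
        if not 0.0 <= self.r_target <= 0.95:
            raise ValueError("r_target must be in [0, 0.95]")
        if self.r_target == 0.0:
            return 0.0
        load = self.loading_vector()
        if np.any(np.abs(load) >= 1):
            raise ValueError("trait loadings must lie in (-1, 1)")
        s = float(np.sum(load**2 / (1.0 - load**2)))
        if s == 0.0:
            raise ValueError("r_target > 0 requires at least one nonzero loading")
        r_x = np.sqrt(s / (1.0 + s))
        r_y = self.r_target / r_x
        if r_y >= 1.0:
            raise ValueError(
                f"r_target={self.r_target} infeasible: trait set caps the "
                f"canonical correlation at {r_x:.3f}"
            )
        t = r_y**2 / (1.0 - r_y**2)
        return float(np.sqrt(t / (2.0 + t)))


def generate_trait_cohort(
    n: int, planted: PlantedStructure | None = None, seed: int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate ``n`` trait profiles plus ground-truth parameters and indices.

    Returns ``(traits, ground_truth)``: the 18-column trait table and a table
    of true per-participant model parameters (κ's clipped to [0,1], λ's to
    [0,0.5]), latent factor scores, and the planted prosociality indices.
    The ground truth is for recovery harnesses only and must never feed the
    fitting stages.
    """
    if n <= 0:
        raise ValueError("cohort size must be positive")
    planted = planted if planted is not None else PlantedStructure()
    rng = np.random.default_rng(seed)

    load = planted.loading_vector()
    c = planted.index_factor_loading()

    A = rng.standard_normal(n)
    eps = rng.standard_normal((n, len(TRAIT_NAMES)))
    z = A[:, None] * load[None, :] + eps * np.sqrt(1.0 - load**2)[None, :]
    traits = pd.DataFrame(
        {
            name: TRAIT_SCALES[name][0] + TRAIT_SCALES[name][1] * z[:, j]
            for j, name in enumerate(TRAIT_NAMES)
        }
    )
    traits.insert(0, "participant_id", np.arange(n))

    noise = np.sqrt(1.0 - c**2)
    hyper = planted.mean_hyperaltruism + planted.sd_hyperaltruism * (
        c * A + noise * rng.standard_normal(n)
    )
    pros_eff = planted.mean_prosocial_effort + planted.sd_prosocial_effort * (
        c * A + noise * rng.standard_normal(n)
    )

    kappa_self = np.clip(rng.normal(0.37, 0.22, n), 0.0, 1.0)
    kappa_other = np.clip(kappa_self + hyper, 0.0, 1.0)
    lambda_self = np.clip(rng.normal(0.02, 0.04, n), 0.0, 0.5)
    lambda_other = np.clip(lambda_self - pros_eff, 0.0, 0.5)
    beta_harm_self = np.clip(rng.lognormal(np.log(5.0), 0.4, n), 0.5, 50.0)
    beta_harm_other = np.clip(rng.lognormal(np.log(5.0), 0.4, n), 0.5, 50.0)
    beta_effort = np.clip(rng.lognormal(np.log(2.0), 0.4, n), 0.2, 20.0)

    ground_truth = pd.DataFrame(
        {
            "participant_id": np.arange(n),
            "kappa_self": kappa_self,
            "kappa_other": kappa_other,
            "beta_self": beta_harm_self,
            "beta_other": beta_harm_other,
            "lambda_self": lambda_self,
            "lambda_other": lambda_other,
            "beta_effort": beta_effort,
            "latent_A": A,
            "hyperaltruism": hyper,
            "prosocial_effort": pros_eff,
        }
    )
    return traits, ground_truth
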