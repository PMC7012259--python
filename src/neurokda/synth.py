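"""Synthetic cohorts and volumes with the structure the decomposition assumes.

Each generated feature matrix is the sum of four planted parts::

    X = class_component + confound_component + sparse_corruption + dense_noise

* **class component** -- low-rank within-class variation (loading vectors
  shared across classes) plus collinear class-mean offsets restricted to a
  designated set of "signal" rows, so between-class separation is
  ``effect`` in units of the within-class standard deviation;
* **confound component** -- a low-rank factor shared by all subjects
  regardless of label, emulating scanner/processing variation;
* **sparse corruption** -- a uniformly random support of entries replaced
  by large-amplitude outliers;
* **dense noise** -- i.i.d. Gaussian, truncated at five standard
  deviations so the additive ground-truth bookkeeping is exact.

The ground-truth parts are returned alongside the data so solver and
pipeline behaviour can be checked against a known answer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .features import FeatureMatrix, Volume3D, write_labels, write_matrix, write_volume

__all__ = [
    "SynthSpec",
    "SynthCohort",
    "generate_cohort",
    "generate_volume",
    "default_cohort_spec",
    "TABLE1_GROUP_SIZES",
    "write_cohort",
]

#: Default demo cohort group sizes (AD, pMCI, sMCI, NC order).
TABLE1_GROUP_SIZES = (198, 167, 236, 229)

#: Fraction of feature rows carrying class signal.
SIGNAL_ROW_FRACTION = 0.2


@dataclass(frozen=True)
class SynthSpec:
    """Parameters of a synthetic cohort.

    ``effect`` is the between-class mean separation on signal rows in
    units of the within-class standard deviation (which is 1 by
    construction).  ``confound_strength`` scales the per-row standard
    deviation of the shared confound relative to the within-class
    variation; ``sparse_amplitude`` is the uniform range (in units of the
    clean-signal scale) from which outlier magnitudes are drawn.
    """

    n_per_class: tuple[int, ...]
    dim: int
    rank_class: int
    rank_confound: int
    sparsity: float = 0.05
    effect: float = 3.0
    noise_sd: float = 0.0
    seed: int = 0
    confound_strength: float = 1.0
    sparse_amplitude: tuple[float, float] = (1.0, 2.0)

    def __post_init__(self) -> None:
        object.__setattr__(self, "n_per_class", tuple(int(n) for n in self.n_per_class))
        if len(self.n_per_class) < 2:
            raise ValueError("n_per_class must list at least 2 classes")
        if any(n < 1 for n in self.n_per_class):
            raise ValueError(f"subject counts must be positive, got {self.n_per_class}")
        if self.dim < 1:
            raise ValueError(f"dim must be a positive integer, got {self.dim}")
        if self.rank_class < 1 or self.rank_confound < 1:
            raise ValueError(
                f"ranks must be positive integers, got rank_class={self.rank_class}, "
                f"rank_confound={self.rank_confound}"
            )
        total = sum(self.n_per_class)
        if self.rank_class + self.rank_confound > min(self.dim, total):
            raise ValueError(
                f"rank_class + rank_confound = {self.rank_class + self.rank_confound} exceeds "
                f"min(dim, total subjects) = {min(self.dim, total)}"
            )
        if not (0.0 <= self.sparsity < 1.0):
            raise ValueError(f"sparsity must lie in [0, 1), got {self.sparsity}")
        if self.effect < 0:
            raise ValueError(f"effect must be >= 0, got {self.effect}")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.confound_strength < 0:
            raise ValueError(f"confound_strength must be >= 0, got {self.confound_strength}")

    @property
    def n_total(self) -> int:
        return sum(self.n_per_class)

    @property
    def n_classes(self) -> int:
        return len(self.n_per_class)


@dataclass
class SynthCohort:
    """A generated cohort together with its planted ground truth."""

    features: FeatureMatrix
    truth_class_component: np.ndarray
    truth_confound_component: np.ndarray
    truth_sparse: np.ndarray
    spec: SynthSpec
    signal_rows: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))

    @property
    def confound_rows(self) -> np.ndarray:
        """Rows touched only by the confound (no planted class signal)."""
        mask = np.ones(self.spec.dim, dtype=bool)
        mask[self.signal_rows] = False
        return np.flatnonzero(mask)


def generate_cohort(spec: SynthSpec) -> SynthCohort:
    """Draw a cohort from the additive low-rank + low-rank + sparse model.

    Deterministic given ``spec`` (including its seed); labels come out in
    class blocks ``0..C-1``.
    """
    rng = np.random.default_rng(spec.seed)
    M, N, C = spec.dim, spec.n_total, spec.n_classes
    labels = np.repeat(np.arange(C), spec.n_per_class)

    n_signal = max(int(round(SIGNAL_ROW_FRACTION * M)), 1)
    signal_rows = np.sort(rng.choice(M, size=n_signal, replace=False))

    # class component: shared low-rank loadings on signal rows + collinear
    # class-mean offsets => rank <= rank_class + 1 <= rank_class + C - 1
    loadings = np.zeros((M, spec.rank_class))
    loadings[signal_rows] = rng.normal(0.0, 1.0 / np.sqrt(spec.rank_class),
                                       size=(n_signal, spec.rank_class))
    scores = rng.normal(size=(spec.rank_class, N))
    offsets = spec.effect * (labels - (C - 1) / 2.0)
    pattern = np.zeros(M)
    pattern[signal_rows] = rng.choice([-1.0, 1.0], size=n_signal)
    class_component = loadings @ scores + np.outer(pattern, offsets)

    # shared confound: dense low-rank factor, label-independent
    conf_loadings = rng.normal(0.0, 1.0 / np.sqrt(spec.rank_confound), size=(M, spec.rank_confound))
    conf_scores = rng.normal(size=(spec.rank_confound, N))
    confound_component = spec.confound_strength * (conf_loadings @ conf_scores)

    clean = class_component + confound_component
    scale = float(clean.std()) or 1.0

    sparse = np.zeros((M, N))
    if spec.sparsity > 0:
        support = rng.random((M, N)) < spec.sparsity
        lo, hi = spec.sparse_amplitude
        amplitudes = rng.uniform(lo, hi, size=(M, N)) * rng.choice([-1.0, 1.0], size=(M, N))
        sparse[support] = (amplitudes * scale)[support]

    noise = np.zeros((M, N))
    if spec.noise_sd > 0:
        noise = rng.normal(0.0, spec.noise_sd, size=(M, N))
        bound = 5.0 * spec.noise_sd
        noise = np.clip(noise, -bound, bound)

    X = clean + sparse + noise
    features = FeatureMatrix(X, labels)
    return SynthCohort(
        features=features,
        truth_class_component=class_component,
        truth_confound_component=confound_component,
        truth_sparse=sparse,
        spec=spec,
        signal_rows=signal_rows,
    )


def generate_volume(
    side: int,
    pattern: str,
    seed: int = 0,
    value: float = 1.0,
) -> Volume3D:
    """Generate a deterministic nonnegative density volume fixture.

    ``pattern`` is one of ``constant`` (all voxels = ``value``),
    ``impulse`` (single unit voxel at the grid center) or ``blocks``
    (4x4x4 grid of uniform-random constant blocks; requires ``side``
    divisible by 4).
    """
    side = int(side)
    if side < 1:
        raise ValueError(f"side must be positive, got {side}")
    if pattern == "constant":
        return Volume3D(np.full((side, side, side), float(value)))
    if pattern == "impulse":
        values = np.zeros((side, side, side))
        c = side // 2
        values[c, c, c] = 1.0
        return Volume3D(values)
    if pattern == "blocks":
        if side < 4 or side % 4 != 0:
            raise ValueError(f"block pattern requires side >= 4 and divisible by 4, got {side}")
        rng = np.random.default_rng(seed)
        block = side // 4
        coarse = rng.random((4, 4, 4))
        values = np.kron(coarse, np.ones((block, block, block)))
        return Volume3D(values)
    raise ValueError(f"unknown pattern {pattern!r}; expected constant|impulse|blocks")


def default_cohort_spec(dim: int = 4096, seed: int = 0, **overrides) -> SynthSpec:
    """Demo cohort spec mirroring the study's four diagnostic group sizes."""
    base = dict(
        n_per_class=TABLE1_GROUP_SIZES,
        dim=dim,
        rank_class=5,
        rank_confound=8,
        sparsity=0.05,
        effect=3.0,
        noise_sd=0.1,
        seed=seed,
    )
    base.update(overrides)
    return SynthSpec(**base)  # type: ignore[arg-type]


def write_cohort(cohort: SynthCohort, out_dir: str | Path) -> None:
    """Write a cohort to disk: features/truth as TSV, labels as CSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_matrix(cohort.features.X, out / "features.tsv")
    write_matrix(cohort.truth_class_component, out / "truth_class.tsv")
    write_matrix(cohort.truth_confound_component, out / "truth_confound.tsv")
    write_matrix(cohort.truth_sparse, out / "truth_sparse.tsv")
    ids = [f"sub-{i:04d}" for i in range(cohort.features.n_subjects)]
    write_labels(ids, cohort.features.labels, out / "labels.csv")
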