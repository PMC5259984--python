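"""Class-separable synthetic protein datasets for testing the pipeline.

Real positive/negative protein sets (and their predicted secondary
structures) require external databases and a structure predictor; the
generators here emulate their statistical shape instead:

* Negatives are drawn from a mixture of background residue-frequency
  components, mimicking a pool spanning many protein families.
* Positives share the same mixture backbone but are tilted — by
  ``signal_strength`` in [0, 1] — toward the neutral-hydrophobicity residue
  group, and their secondary structures carry longer helix runs. At
  ``signal_strength = 0`` the two classes are exchangeable by construction.
* :func:`generate_feature_table` skips sequence space entirely and produces
  a Gaussian feature table with a known informative-column mask, the direct
  fixture for feature-ranking and dimension-search tests.
* :func:`generate_hard_negative_pool` plants "boundary" negatives between
  the class centroids for the negative-refinement strategies.

All randomness flows through one seeded generator per call; equal seeds give
byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ctd import HYDROPHOBICITY_GROUPS
from .seqio import (
    AMINO_ALPHABET,
    LABEL_NEGATIVE,
    LABEL_POSITIVE,
    FeatureTable,
    ProteinRecord,
    SSRecord,
)

SS_STATES = "HEC"
N_MIXTURE_COMPONENTS = 5


@dataclass
class SynthConfig:
    n_pos: int = 200
    n_neg: int = 200
    min_length: int = 50
    max_length: int = 120
    signal_strength: float = 1.0
    n_boundary: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pos < 0 or self.n_neg < 0:
            raise ValueError("counts must be >= 0")
        if self.min_length > self.max_length:
            raise ValueError("min_length must be <= max_length")
        if not (0.0 <= self.signal_strength <= 1.0):
            raise ValueError("signal_strength must be in [0, 1]")


def _mixture_components(rng: np.random.Generator) -> np.ndarray:
    """Residue-frequency components emulating distinct protein families."""
    return rng.dirichlet(np.full(20, 2.0), size=N_MIXTURE_COMPONENTS)


def _tilt_toward_neutral(freqs: np.ndarray, s: float) -> np.ndarray:
    """Move fraction s of probability mass onto the neutral residue group."""
    neutral = np.array([a in HYDROPHOBICITY_GROUPS[0] for a in AMINO_ALPHABET])
    target = np.where(neutral, 1.0 / neutral.sum(), 0.0)
    out = (1.0 - s) * freqs + s * target
    return out / out.sum()


def _draw_sequence(rng: np.random.Generator, freqs: np.ndarray, length: int) -> str:
    letters = rng.choice(list(AMINO_ALPHABET), size=length, p=freqs)
    return "".join(letters)


def _draw_ss(rng: np.random.Generator, length: int, helix_bias: float) -> str:
    """Markov-chain H/E/C string; helix_bias in [0,1] lengthens H runs."""
    stay = 0.70 + 0.25 * helix_bias          # H self-transition
    start_p = np.array([1 + 2 * helix_bias, 1.0, 1.0])
    start_p = start_p / start_p.sum()
    states = []
    cur = int(rng.choice(3, p=start_p))
    for _ in range(length):
        states.append(SS_STATES[cur])
        if cur == 0:
            if rng.random() < stay:
                continue
            cur = int(rng.choice([1, 2]))
        else:
            if rng.random() < 0.6:
                continue
            cur = int(rng.choice(3, p=start_p))
    return "".join(states)


def generate_sequences(config: SynthConfig):
    """(protein records, paired SS records, labels) under the configured signal.

    Every sequence draws its residue frequencies from the same family-mixture;
    positives are additionally tilted toward the neutral group and given
    helix-rich structures, proportionally to ``signal_strength``. The last
    ``n_boundary`` negatives receive a partial (70%) tilt, planting them near
    the class boundary.
    """
    rng = np.random.default_rng(config.seed)
    comps = _mixture_components(rng)
    s = config.signal_strength
    proteins: list[ProteinRecord] = []
    ss_records: list[SSRecord] = []
    labels: list[str] = []

    def make(rid: str, tilt: float, helix: float):
        length = int(rng.integers(config.min_length, config.max_length + 1))
        comp = comps[int(rng.integers(N_MIXTURE_COMPONENTS))]
        freqs = _tilt_toward_neutral(comp, tilt)
        proteins.append(ProteinRecord(id=rid, seq=_draw_sequence(rng, freqs, length)))
        ss_records.append(SSRecord(id=rid, ss=_draw_ss(rng, length, helix)))

    for i in range(config.n_pos):
        make(f"pos{i:04d}", tilt=0.6 * s, helix=s)
        labels.append(LABEL_POSITIVE)
    n_plain = config.n_neg - config.n_boundary
    for i in range(config.n_neg):
        boundary = i >= n_plain
        make(f"neg{i:04d}", tilt=0.6 * s * (0.7 if boundary else 0.0),
             helix=s * (0.7 if boundary else 0.0))
        labels.append(LABEL_NEGATIVE)
    return proteins, ss_records, labels


def generate_feature_table(
    n_rows: int,
    n_informative: int,
    n_noise: int,
    effect: float,
    seed: int = 0,
) -> tuple[FeatureTable, np.ndarray]:
    """Gaussian feature table with a known informative mask.

    Rows split evenly into positives and negatives. Informative columns are
    ``label * effect`` plus unit Gaussian noise; noise columns are pure unit
    noise. Column order is randomized; the returned boolean mask marks the
    informative columns in the emitted order (tests read the mask, they never
    re-derive it).
    """
    rng = np.random.default_rng(seed)
    p = n_informative + n_noise
    n_pos = n_rows // 2
    y = np.array([1] * n_pos + [0] * (n_rows - n_pos))
    X = rng.standard_normal((n_rows, p))
    X[:, :n_informative] += y[:, None] * effect
    mask = np.array([True] * n_informative + [False] * n_noise)
    perm = rng.permutation(p)
    X = X[:, perm]
    mask = mask[perm]
    names = [
        f"{'inf' if mask[j] else 'noise'}_{j:03d}" for j in range(p)
    ]
    labels = [LABEL_POSITIVE if v == 1 else LABEL_NEGATIVE for v in y]
    table = FeatureTable(
        row_ids=[f"r{i:04d}" for i in range(n_rows)],
        feature_names=names,
        values=X,
        labels=labels,
    )
    return table, mask


def generate_hard_negative_pool(
    n_pos: int,
    n_pool: int,
    n_boundary: int,
    n_features: int = 10,
    separation: float = 4.0,
    boundary_shrink: float = 0.85,
    seed: int = 0,
) -> tuple[FeatureTable, FeatureTable, np.ndarray]:
    """Positive cloud + negative pool with planted boundary negatives.

    Positives sit at +separation/2 on every axis and ordinary pool negatives
    at -separation/2, both with unit noise. Boundary negatives are moved
    ``boundary_shrink`` of the way from the negative centroid toward (and
    past the midpoint to) the positive centroid, so a model trained on a
    random negative draw misclassifies them as positive. Returns
    (positives, pool, boundary-mask over pool rows).
    """
    rng = np.random.default_rng(seed)
    mu = separation / 2.0
    pos = rng.standard_normal((n_pos, n_features)) + mu
    n_plain = n_pool - n_boundary
    plain = rng.standard_normal((n_plain, n_features)) - mu
    boundary = rng.standard_normal((n_boundary, n_features))
    boundary = boundary + (-mu + boundary_shrink * separation)
    pool_values = np.vstack([plain, boundary])
    mask = np.array([False] * n_plain + [True] * n_boundary)
    perm = rng.permutation(n_pool)
    pool_values = pool_values[perm]
    mask = mask[perm]
    names = [f"f{j:02d}" for j in range(n_features)]
    pos_table = FeatureTable(
        row_ids=[f"pos{i:04d}" for i in range(n_pos)],
        feature_names=names, values=pos,
        labels=[LABEL_POSITIVE] * n_pos,
    )
    pool_table = FeatureTable(
        row_ids=[f"pool{i:04d}" for i in range(n_pool)],
        feature_names=names, values=pool_values,
        labels=[LABEL_NEGATIVE] * n_pool,
    )
    return pos_table, pool_table, mask
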