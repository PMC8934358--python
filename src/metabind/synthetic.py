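"""Seeded synthetic drug-target affinity datasets with latent structure.

Affinities follow an inner-product ("guilt-by-association") model: each
drug and target gets an i.i.d. standard-normal latent vector, the
noise-free affinity is an affine map of the latent inner product onto the
requested range, and Gaussian noise is added.  Similarity matrices are the
min-max-normalized cosine similarities of the latents, so similar drugs
really do bind similar targets and graph features are informative by
construction.  Sequence strings (protein-like and SMILES-like) are random;
they exercise tokenization and encoding, not chemistry.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import AffinityDataset, Orientation, SequenceRecord, SimilarityMatrix
from .graph import minmax_normalize

__all__ = ["SyntheticSpec", "SyntheticData", "generate"]

_AA = "ACDEFGHIKLMNPQRSTVWY"
_SMILES_TOKENS = ["C", "c", "N", "n", "O", "o", "S", "F", "Cl", "Br", "=", "#", "(", ")", "1", "2", "[nH]"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for a generated dataset.

    Defaults emulate a dense Davis-style kinase panel at desk scale: a
    fully observed drug x target matrix on a pKd-like scale (5.0-10.8,
    higher = stronger) with noise at 10% of the affinity range.  Set
    ``density=0.244`` for a KIBA-style sparse regime.
    """

    n_drugs: int = 60
    m_targets: int = 50
    latent_dim: int = 5
    density: float = 1.0
    noise_sd: float = 0.58
    orientation: Orientation = Orientation.HIGHER_IS_STRONGER
    affinity_range: tuple[float, float] = (5.0, 10.8)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.density <= 1:
            raise ValueError("density must lie in (0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        lo, hi = self.affinity_range
        if not lo < hi:
            raise ValueError("affinity_range must satisfy lo < hi")
        if int(self.density * self.n_drugs * self.m_targets) < 1:
            raise ValueError("density * n_drugs * m_targets must be >= 1")


@dataclass
class SyntheticData:
    dataset: AffinityDataset
    drug_similarity: SimilarityMatrix
    target_similarity: SimilarityMatrix
    drug_latents: np.ndarray
    target_latents: np.ndarray
    noise_free: np.ndarray
    smiles: list[SequenceRecord]
    proteins: list[SequenceRecord]


def _cosine_minmax(latents: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(latents, axis=1, keepdims=True)
    unit = latents / norms
    sim = unit @ unit.T
    sim = minmax_normalize(sim)
    return (sim + sim.T) / 2.0


def _random_protein(rng: np.random.Generator) -> str:
    length = int(rng.integers(120, 400))
    return "".join(rng.choice(list(_AA), size=length))


def _random_smiles(rng: np.random.Generator) -> str:
    length = int(rng.integers(15, 60))
    return "".join(rng.choice(_SMILES_TOKENS, size=length))


def generate(spec: SyntheticSpec = SyntheticSpec()) -> SyntheticData:
    """Draw one dataset under ``spec``; deterministic given ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    n, m, d = spec.n_drugs, spec.m_targets, spec.latent_dim
    u = rng.standard_normal((n, d))
    w = rng.standard_normal((m, d))
    raw = u @ w.T
    lo, hi = spec.affinity_range
    # affine map of the latent inner products onto the affinity range:
    # mean +/- 3 sd -> range endpoints, giving a Davis-like spread
    # (std approx range/6) without min/max compression of the signal
    noise_free = (lo + hi) / 2 + (raw - raw.mean()) / (6 * raw.std()) * (hi - lo)
    observed_values = noise_free + rng.normal(0.0, spec.noise_sd, size=(n, m))

    n_obs = int(spec.density * n * m)
    flat = rng.permutation(n * m)[:n_obs]
    mask = np.zeros(n * m, dtype=bool)
    mask[flat] = True
    mask = mask.reshape(n, m)

    affinities = np.where(mask, observed_values, np.nan)
    drug_ids = [f"D{i:03d}" for i in range(n)]
    target_ids = [f"T{j:03d}" for j in range(m)]
    dataset = AffinityDataset(
        drug_ids=drug_ids,
        target_ids=target_ids,
        affinities=affinities,
        observed=mask,
        orientation=spec.orientation,
        unit_label="synthetic affinity",
    )
    return SyntheticData(
        dataset=dataset,
        drug_similarity=SimilarityMatrix(list(drug_ids), _cosine_minmax(u)),
        target_similarity=SimilarityMatrix(list(target_ids), _cosine_minmax(w)),
        drug_latents=u,
        target_latents=w,
        noise_free=noise_free,
        smiles=[SequenceRecord(i, _random_smiles(rng)) for i in drug_ids],
        proteins=[SequenceRecord(j, _random_protein(rng)) for j in target_ids],
    )
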