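"""Default codebook and substitution matrix.

The original encoder's published codebook and matrix are not distributed, so
the package ships defaults trained by the documented procedures on synthetic
geometry: helices across a range of twists and radii, strands, and
self-avoiding random walks, plus noise-0.3 A perturbed copies of each (the
same noise level assumed for remote homologs throughout).  Training is fully
seeded and cached per process, so every run of a given version sees the same
codebook and SASM.
"""

from __future__ import annotations

from functools import lru_cache

from . import fixtures
from .alphabet import SASM, Codebook, build_sasm, compute_angles, encode, train_codebook

_TRAIN_SEED = 20120
_TRAIN_NOISE_SD = 0.3


def _training_chains(seed: int):
    chains = [
        fixtures.make_varied_chain(60, rng_seed=seed + i) for i in range(8)
    ]
    chains.append(fixtures.make_helix(40, seq_seed=seed + 50))
    chains.append(fixtures.make_strand(40, seq_seed=seed + 51))
    for i in range(4):
        chains.append(fixtures.make_random_walk(40, rng_seed=seed + 100 + i))
    return chains


@lru_cache(maxsize=None)
def default_codebook(seed: int = _TRAIN_SEED) -> Codebook:
    """23-letter codebook clustered from the synthetic training geometry."""
    angles = []
    for chain in _training_chains(seed):
        angles.extend(compute_angles(chain))
    return train_codebook(angles, k=23, rng_seed=seed)


@lru_cache(maxsize=None)
def default_sasm(seed: int = _TRAIN_SEED) -> SASM:
    """SASM from positionally aligned (parent, perturbed-copy) string pairs.

    Perturbed copies carry the homolog-level coordinate noise, so the matrix
    learns which letter substitutions rigid-body noise induces — exactly the
    tolerance the segment search needs.
    """
    codebook = default_codebook(seed)
    pairs = []
    for i, chain in enumerate(_training_chains(seed)):
        parent = fixtures.Complex(
            id=f"train{i}",
            chain=chain,
            ligand=fixtures.Ligand(
                het_code="TRN",
                atoms=[fixtures.Atom(name="C1", element="C", coords=(0.0, 0.0, 0.0))],
            ),
        )
        for rep in range(3):
            copy = fixtures.perturb_homolog(
                parent,
                noise_sd=_TRAIN_NOISE_SD,
                mutation_rate=0.0,
                rng_seed=seed + 31 * i + rep,
            )
            pairs.append(
                (
                    encode(chain, codebook).letters,
                    encode(copy.chain, codebook).letters,
                )
            )
    return build_sasm(pairs)
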