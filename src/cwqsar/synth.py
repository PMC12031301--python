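"""Synthetic SMILES datasets with known ground truth.

Real correlation-weight QSAR studies train on literature datasets (for
instance hERG inhibition collections with continuous pIC50 values or
balanced active/inactive labels).  This module emulates such data at a
controllable scale: random grammar-constrained SMILES strings — chains of
vocabulary atoms with optional matched ring-closure digits and balanced
branch parentheses — and an endpoint that is linear in the single-token
counts plus Gaussian noise:

    y_i = sum_t  w_t * count_t(i)  +  N(0, noise_sd)

For classification the latent y is thresholded at its median, which keeps
the classes balanced by construction (mirroring the balanced sampling of
inactives used in classification QSAR studies).

Because the endpoint depends only on single-token counts, the pair/triple,
local-symmetry and atom-proportion families act as nuisance attributes:
recovery experiments also test that the optimizer tolerates irrelevant
descriptors.  Every generated string tokenizes losslessly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .attributes import tokenize
from .errors import GenerationError

DEFAULT_VOCAB: tuple[str, ...] = ("C", "c", "N", "n", "O", "S", "Cl", "F")

#: endpoint contribution per single-token occurrence; chosen so that typical
#: chains (4-20 atoms) span a few log units, like a pIC50 scale
DEFAULT_TRUE_WEIGHTS: dict[str, float] = {
    "C": 0.10,
    "c": 0.30,
    "N": 0.50,
    "n": 0.60,
    "O": -0.40,
    "S": -0.20,
    "Cl": 0.40,
    "F": -0.30,
}


@dataclass
class GeneratorConfig:
    """Settings for one synthetic dataset.

    ``noise_sd`` defaults to 0.3 — small against the several-unit signal
    spread, emulating a well-measured continuous endpoint.  ``max_length``
    is the maximum number of atom tokens per molecule (ring digits and
    parentheses come on top).
    """

    n: int = 200
    vocab: tuple[str, ...] = DEFAULT_VOCAB
    max_length: int = 20
    min_length: int = 4
    ring_p: float = 0.3
    branch_p: float = 0.3
    true_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TRUE_WEIGHTS)
    )
    noise_sd: float = 0.3
    task: str = "regression"
    seed: int = 0


def generate_smiles(cfg: GeneratorConfig) -> list[str]:
    """Random tokenizable SMILES strings, deterministic per seed."""
    if not cfg.vocab:
        raise GenerationError("vocabulary must be non-empty")
    if cfg.max_length < 1 or cfg.min_length < 1 or cfg.min_length > cfg.max_length:
        raise GenerationError("need 1 <= min_length <= max_length")
    if cfg.branch_p >= 1.0 and cfg.max_length < 4:
        raise GenerationError(
            "branches need at least 4 atoms; branch_p = 1 is unsatisfiable"
        )
    if cfg.ring_p >= 1.0 and cfg.max_length < 3:
        raise GenerationError(
            "rings need at least 3 atoms; ring_p = 1 is unsatisfiable"
        )
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0]))
    out: list[str] = []
    vocab = list(cfg.vocab)
    for _ in range(cfg.n):
        length = int(rng.integers(cfg.min_length, cfg.max_length + 1))
        atoms = [vocab[int(i)] for i in rng.integers(0, len(vocab), size=length)]
        tokens: list[str] = list(atoms)
        # one balanced branch around a single interior atom
        if length >= 4 and rng.random() < cfg.branch_p:
            pos = int(rng.integers(1, length - 1))
            tokens = tokens[:pos] + ["("] + [tokens[pos]] + [")"] + tokens[pos + 1 :]
        # one matched ring-closure digit pair: after the first atom and at the end
        if length >= 3 and rng.random() < cfg.ring_p:
            digit = str(int(rng.integers(1, 10)))
            tokens = [tokens[0], digit] + tokens[1:] + [digit]
        out.append("".join(tokens))
    return out


def generate_endpoint(smiles: list[str], cfg: GeneratorConfig) -> np.ndarray:
    """Endpoint values for generated SMILES.

    Regression: the linear single-token model plus Gaussian noise.
    Classification: the latent value thresholded at the sample median
    (label 1 for y >= median), giving near-50/50 classes.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    latent = np.array(
        [
            sum(cfg.true_weights.get(t, 0.0) for t in tokenize(s))
            for s in smiles
        ]
    )
    y = latent + rng.normal(0.0, cfg.noise_sd, size=len(smiles))
    if cfg.task == "classification":
        return (y >= np.median(y)).astype(int)
    return y


def generate_dataset(cfg: GeneratorConfig) -> pd.DataFrame:
    """Convenience wrapper: id, smiles, endpoint columns."""
    smiles = generate_smiles(cfg)
    y = generate_endpoint(smiles, cfg)
    return pd.DataFrame(
        {
            "id": [f"mol{i:05d}" for i in range(len(smiles))],
            "smiles": smiles,
            "endpoint": y,
        }
    )


def ground_truth(cfg: GeneratorConfig) -> dict:
    """The generating model, for provenance files next to synthetic data."""
    return {
        "true_weights": dict(cfg.true_weights),
        "noise_sd": cfg.noise_sd,
        "task": cfg.task,
        "seed": cfg.seed,
    }
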