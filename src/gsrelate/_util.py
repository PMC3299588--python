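"""Seed derivation and shared error types."""
from __future__ import annotations

import zlib

import numpy as np


class ParameterError(ValueError):
    """An argument is outside its valid domain."""


class DataError(ValueError):
    """Input data violate a structural requirement (e.g. cyclic pedigree)."""


class DesignError(ValueError):
    """A reference/test design cannot be built from the given population."""


class StateError(RuntimeError):
    """An operation was called before its prerequisites were computed."""


def seed_sequence(master_seed: int, *labels) -> np.random.SeedSequence:
    """Labelled seed derivation.

    Streams are keyed by (master_seed, crc32(label)...), so adding a new
    stage with a fresh label never shifts the draws of existing stages.
    """
    entropy = [int(master_seed) & 0x7FFFFFFF]
    for lab in labels:
        entropy.append(zlib.crc32(str(lab).encode("utf8")))
    return np.random.SeedSequence(entropy)


def derive_rng(master_seed: int, *labels) -> np.random.Generator:
    return np.random.default_rng(seed_sequence(master_seed, *labels))


def derive_int_seed(master_seed: int, *labels) -> int:
    """A positive 31-bit seed for libraries that take a plain integer."""
    return int(derive_rng(master_seed, *labels).integers(1, 2**31 - 1))
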