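"""Shared helpers: seeded stream splitting and error types."""

from __future__ import annotations

import zlib

import numpy as np


class ConfigurationError(ValueError):
    """A configuration value violates its contract."""


class DomainError(ValueError):
    """An input value is outside the mathematical domain of an operation."""


class DegenerateDataError(ValueError):
    """Data carry no information for the requested operation (e.g. zero spread)."""


class EstimationError(RuntimeError):
    """A model fit could not be completed."""


class SeparationError(EstimationError):
    """The likelihood is unbounded (complete separation)."""

    def __init__(self, term: str):
        self.term = term
        super().__init__(
            f"complete separation: likelihood unbounded in coefficient {term!r}"
        )


def stream_rng(master_seed: int, stream: str) -> np.random.Generator:
    """Deterministic per-component generator derived from one master seed.

    Each named stream is independent, so any single sub-generator can be
    reproduced in isolation.
    """
    key = zlib.crc32(stream.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(master_seed), key]))


def child_seed(master_seed: int, stream: str) -> int:
    """A 31-bit integer seed for a named sub-stream."""
    return int(stream_rng(master_seed, stream).integers(0, 2**31 - 1))
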