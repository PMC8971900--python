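"""Shared helpers: error types and named, reproducible random substreams."""

from __future__ import annotations

import zlib

import numpy as np


class OralsiteError(Exception):
    """Base class for all package errors."""


class ParseError(OralsiteError):
    """A file violated the expected dialect (duplicate ids, bad counts...)."""


class ConfigurationError(OralsiteError):
    """Inconsistent or out-of-range configuration."""


class EmptyTableError(OralsiteError):
    """An operation produced or received a table with no usable content."""


def substream(seed: int, label: str) -> np.random.Generator:
    """Return a generator for the named substream of a master seed.

    Every stochastic stage draws from its own substream so that adding a
    stage never shifts the randomness consumed by another one.  The label
    is folded in via CRC32, which is stable across platforms and sessions.
    """
    ss = np.random.SeedSequence([int(seed) & 0x7FFFFFFF, zlib.crc32(label.encode("utf8"))])
    return np.random.default_rng(ss)


def stream_seed(seed: int, label: str) -> int:
    """A derived integer seed (< 2**31) for APIs that want a plain int."""
    return int(substream(seed, label).integers(2**31))
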