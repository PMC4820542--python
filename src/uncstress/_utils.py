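"""Small shared helpers: seeding, errors, z-scoring."""

from __future__ import annotations

import numpy as np


class ConfigurationError(ValueError):
    """An input configuration violates a structural constraint."""


class DegenerateInputError(ValueError):
    """Input has no variance (or is otherwise statistically degenerate)."""


class FitError(RuntimeError):
    """A model fit failed across all restarts."""


def subject_seed(master_seed: int, subject: int, stream: str = "") -> int:
    """Derive a per-subject (and per-stream) seed below 2**31.

    Uses numpy's SeedSequence hashing so that streams for different
    subjects/stages are statistically independent and reproducible.
    """
    entropy = [int(master_seed), int(subject)] + [ord(c) for c in stream]
    ss = np.random.SeedSequence(entropy)
    return int(ss.generate_state(1)[0] % (2**31))


def zscore(x: np.ndarray, ddof: int = 0) -> np.ndarray:
    """z-score, raising on zero variance."""
    x = np.asarray(x, dtype=float)
    sd = x.std(ddof=ddof)
    if sd == 0 or not np.isfinite(sd):
        raise DegenerateInputError("cannot z-score a constant series")
    return (x - x.mean()) / sd
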