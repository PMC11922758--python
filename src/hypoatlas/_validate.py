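"""Shared input-validation helpers."""

from __future__ import annotations

import numpy as np
import pandas as pd


class ValidationError(ValueError):
    """Raised when an input violates a documented precondition."""


def require(condition: bool, message: str) -> None:
    if not condition:
        raise ValidationError(message)


def require_columns(df: pd.DataFrame, columns, what: str = "table") -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValidationError(f"{what} is missing required column(s): {', '.join(missing)}")


def as_rng(seed) -> np.random.Generator:
    """Accept an int seed or an existing Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)
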