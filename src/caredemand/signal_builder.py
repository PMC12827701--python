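"""Turn one tabular health record into a 1D "health signal".

Each individual's variables are min-max normalized with statistics
frozen at fit time, arranged in a fixed order, and the resulting base
vector is tiled head-to-tail and truncated to a power-of-two length so
a multilevel wavelet transform applies.  The induced periodicity is a
documented artifact of synthesising a signal from static variables,
not a claim about temporal structure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic_cohort import LABEL_COLUMN, VARIABLES

__all__ = [
    "NormalizerState",
    "HealthSignal",
    "default_variable_order",
    "fit_normalizer",
    "build_signal",
    "build_signals",
    "DEFAULT_SIGNAL_LENGTH",
]

DEFAULT_SIGNAL_LENGTH = 64


@dataclass(frozen=True)
class NormalizerState:
    """Frozen per-variable training min/max plus the variable order."""

    variable_order: tuple[str, ...]
    mins: tuple[float, ...]
    maxs: tuple[float, ...]

    def transform(self, values: np.ndarray) -> np.ndarray:
        """Min-max map columns of ``values`` (ordered) into [0, 1].

        Degenerate variables (min == max at fit time) map to 0.5;
        out-of-range test values clip to the unit interval.
        """
        mins = np.asarray(self.mins)
        maxs = np.asarray(self.maxs)
        span = maxs - mins
        degenerate = span == 0.0
        safe_span = np.where(degenerate, 1.0, span)
        out = (np.asarray(values, dtype=float) - mins) / safe_span
        out = np.clip(out, 0.0, 1.0)
        if degenerate.any():
            out[..., degenerate] = 0.5
        return out


@dataclass(frozen=True)
class HealthSignal:
    """A length-L normalized sequence synthesized for one individual."""

    values: np.ndarray
    source_id: object = None

    @property
    def length(self) -> int:
        return self.values.size


def default_variable_order(table: pd.DataFrame) -> tuple[str, ...]:
    """Core variables in canonical order, then extras alphabetically."""
    core = [v for v in VARIABLES if v in table.columns]
    extras = sorted(
        c for c in table.columns if c not in VARIABLES and c != LABEL_COLUMN
    )
    return tuple(core + extras)


def fit_normalizer(table: pd.DataFrame, variable_order=None) -> NormalizerState:
    """Capture per-variable training min/max (label column excluded)."""
    if len(table) == 0:
        raise ValueError("cannot fit a normalizer on an empty table")
    order = tuple(variable_order) if variable_order is not None else default_variable_order(table)
    if LABEL_COLUMN in order:
        raise ValueError("variable order must not include the label column")
    for name in order:
        if name not in table.columns:
            raise ValueError(f"unknown variable in order: {name!r}")
    cols = table.loc[:, list(order)].to_numpy(float)
    return NormalizerState(
        variable_order=order,
        mins=tuple(cols.min(axis=0)),
        maxs=tuple(cols.max(axis=0)),
    )


def _check_length(L: int) -> None:
    if L < 1 or (L & (L - 1)) != 0:
        raise ValueError(f"signal length must be a power of two, got {L}")


def build_signal(record, state: NormalizerState, L: int = DEFAULT_SIGNAL_LENGTH) -> HealthSignal:
    """Normalize one record and tile-and-truncate it to length ``L``.

    ``record`` is any mapping (or pandas Series) with every variable in
    ``state.variable_order``.
    """
    _check_length(L)
    try:
        base = np.array([float(record[name]) for name in state.variable_order])
    except KeyError as exc:
        raise ValueError(f"record is missing variable {exc.args[0]!r}") from None
    normalized = state.transform(base)
    source_id = getattr(record, "name", None)
    return HealthSignal(values=np.resize(normalized, L), source_id=source_id)


def build_signals(table: pd.DataFrame, state: NormalizerState,
                  L: int = DEFAULT_SIGNAL_LENGTH) -> np.ndarray:
    """Vectorized :func:`build_signal` over a table; returns (n, L)."""
    _check_length(L)
    for name in state.variable_order:
        if name not in table.columns:
            raise ValueError(f"table is missing variable {name!r}")
    base = state.transform(table.loc[:, list(state.variable_order)].to_numpy(float))
    m = base.shape[1]
    reps = int(np.ceil(L / m))
    return np.tile(base, reps)[:, :L]
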