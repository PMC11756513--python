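"""Two-step fluorescence normalization producing the model feature vector.

Each cycle's reporter signal is first standardized against the passive ROX
reference dye, ``Fstand = reporter / rox``, which cancels well-to-well optical
variation.  The standardized curve is then shifted so its per-trace minimum is
exactly 1::

    Fnorm = Fstand - (Fmin - 1)

where ``Fmin`` is the minimum standardized value across the trace's own
cycles.  The resulting 40-value vector is the only input the calling models
see — no smoothing, baseline regression, or curve-feature extraction is
applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .curve_io import FluorescenceTrace
from .errors import CurveIOError

__all__ = ["NormalizedTrace", "standardize", "normalize", "normalize_trace", "normalize_batch"]


@dataclass(eq=False)
class NormalizedTrace:
    """Per-cycle normalized fluorescence (Fnorm) for one reaction."""

    reaction_id: str
    dye: str
    values: np.ndarray
    well: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    @property
    def cycles(self) -> int:
        return len(self.values)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, NormalizedTrace):
            return NotImplemented
        return (
            self.reaction_id == other.reaction_id
            and self.dye == other.dye
            and np.array_equal(self.values, other.values)
        )


def standardize(trace: FluorescenceTrace) -> np.ndarray:
    """Divide reporter by ROX, cycle by cycle.

    Raises :class:`CurveIOError` identifying the first offending cycle if any
    ROX value is non-positive.
    """
    rox = np.asarray(trace.rox, dtype=float)
    if np.any(rox <= 0):
        bad = int(np.flatnonzero(rox <= 0)[0]) + 1
        raise CurveIOError(
            f"reaction {trace.reaction_id!r}: non-positive ROX at cycle {bad}"
        )
    return np.asarray(trace.reporter, dtype=float) / rox


def normalize(standardized: Sequence[float] | np.ndarray) -> np.ndarray:
    """Shift a standardized curve so its minimum equals exactly 1."""
    values = np.asarray(standardized, dtype=float)
    if values.size == 0:
        raise CurveIOError("cannot normalize an empty sequence")
    return values - (values.min() - 1.0)


def normalize_trace(trace: FluorescenceTrace) -> NormalizedTrace:
    """Standardize then normalize a single trace."""
    return NormalizedTrace(
        reaction_id=trace.reaction_id,
        dye=trace.dye,
        values=normalize(standardize(trace)),
        well=trace.well,
    )


def normalize_batch(traces: Iterable[FluorescenceTrace]) -> list[NormalizedTrace]:
    """Normalize every trace, preserving order; errors carry the reaction id."""
    out: list[NormalizedTrace] = []
    for trace in traces:
        try:
            out.append(normalize_trace(trace))
        except CurveIOError:
            raise
        except Exception as exc:  # pragma: no cover - defensive context wrap
            raise CurveIOError(f"reaction {trace.reaction_id!r}: {exc}") from exc
    return out
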