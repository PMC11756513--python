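"""Reading and writing the canonical tabular formats.

The package exchanges three kinds of flat CSV files:

* **traces** — long format, one row per cycle per dye, header
  ``reaction_id,well,target,dye,cycle,reporter,rox``.  A duplex well appears
  as two reaction records (one per dye) sharing the ``well`` value.
* **labels** — gold-standard calls, header ``reaction_id,amplified,ct``;
  ``ct`` is empty whenever ``amplified`` is false.
* **calls** — model output, header
  ``reaction_id,probability,amplified,ct,flagged``.

Cycles are 1-based and must be contiguous (1..C).  No instrument-native
binary run formats are supported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import CurveIOError

__all__ = [
    "FluorescenceTrace",
    "ReactionLabel",
    "CallRecord",
    "make_call",
    "read_curves",
    "write_curves",
    "read_labels",
    "write_labels",
    "read_calls",
    "write_calls",
    "roundtrip_calls",
]

DYES = ("FAM", "VIC")

TRACE_COLUMNS = ["reaction_id", "well", "target", "dye", "cycle", "reporter", "rox"]
LABEL_COLUMNS = ["reaction_id", "amplified", "ct"]
CALL_COLUMNS = ["reaction_id", "probability", "amplified", "ct", "flagged"]


@dataclass(eq=False)
class FluorescenceTrace:
    """One reaction's raw reporter and ROX fluorescence across cycles.

    ``reporter`` holds the raw FAM or VIC signal per cycle and ``rox`` the
    passive reference dye for the same cycles; both are in instrument units.
    Cycles are implicitly ``1..C`` in order.
    """

    reaction_id: str
    dye: str
    reporter: np.ndarray
    rox: np.ndarray
    target: str | None = None
    well: str | None = None

    def __post_init__(self) -> None:
        self.reporter = np.asarray(self.reporter, dtype=float)
        self.rox = np.asarray(self.rox, dtype=float)
        if self.dye not in DYES:
            raise CurveIOError(
                f"reaction {self.reaction_id!r}: dye must be one of {DYES}, got {self.dye!r}"
            )
        if self.reporter.ndim != 1 or self.rox.ndim != 1:
            raise CurveIOError(f"reaction {self.reaction_id!r}: traces must be 1-D")
        if len(self.reporter) != len(self.rox):
            raise CurveIOError(
                f"reaction {self.reaction_id!r}: reporter has {len(self.reporter)} "
                f"cycles but rox has {len(self.rox)}"
            )
        if len(self.reporter) < 2:
            raise CurveIOError(
                f"reaction {self.reaction_id!r}: needs at least 2 cycles"
            )
        if np.any(self.rox <= 0) or not np.all(np.isfinite(self.rox)):
            bad = int(np.flatnonzero(~(self.rox > 0))[0]) + 1
            raise CurveIOError(
                f"reaction {self.reaction_id!r}: non-positive ROX value at cycle {bad}"
            )

    @property
    def cycles(self) -> int:
        return len(self.reporter)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FluorescenceTrace):
            return NotImplemented
        return (
            self.reaction_id == other.reaction_id
            and self.dye == other.dye
            and self.target == other.target
            and self.well == other.well
            and np.array_equal(self.reporter, other.reporter)
            and np.array_equal(self.rox, other.rox)
        )


@dataclass(frozen=True)
class ReactionLabel:
    """Gold-standard call: amplified flag, with a Ct only when amplified."""

    reaction_id: str
    amplified: bool
    ct: float | None = None

    def __post_init__(self) -> None:
        if self.amplified and self.ct is None:
            raise CurveIOError(
                f"reaction {self.reaction_id!r}: amplified label requires a ct"
            )
        if not self.amplified and self.ct is not None:
            raise CurveIOError(
                f"reaction {self.reaction_id!r}: non-amplified label must not carry a ct"
            )
        if self.ct is not None and not self.ct > 0:
            raise CurveIOError(
                f"reaction {self.reaction_id!r}: ct must be positive, got {self.ct}"
            )


@dataclass(frozen=True)
class CallRecord:
    """Model output for one reaction: probability, call, conditional Ct, flag."""

    reaction_id: str
    probability: float
    amplified: bool
    ct: float | None
    flagged: bool

    def __post_init__(self) -> None:
        if not 0.0 <= self.probability <= 1.0:
            raise CurveIOError(
                f"reaction {self.reaction_id!r}: probability {self.probability} outside [0, 1]"
            )
        if self.amplified and self.ct is None:
            raise CurveIOError(
                f"reaction {self.reaction_id!r}: amplified call requires a ct"
            )
        if not self.amplified and self.ct is not None:
            raise CurveIOError(
                f"reaction {self.reaction_id!r}: ct present on a non-amplified call"
            )


def make_call(
    reaction_id: str,
    probability: float,
    ct: float | None,
    threshold: float = 0.5,
    flag_interval: tuple[float, float] = (0.1, 0.9),
) -> CallRecord:
    """Build a :class:`CallRecord` applying the decision and flagging rules.

    The call is positive only for probability strictly greater than
    ``threshold``; a probability inside the closed ``flag_interval`` marks the
    record for manual review.  ``ct`` is kept only on positive calls.
    """
    amplified = probability > threshold
    flagged = flag_interval[0] <= probability <= flag_interval[1]
    return CallRecord(
        reaction_id=reaction_id,
        probability=float(probability),
        amplified=amplified,
        ct=float(ct) if (amplified and ct is not None) else None,
        flagged=flagged,
    )


def _require_columns(df: pd.DataFrame, required: Sequence[str], path: Path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise CurveIOError(f"{path}: missing required columns {missing}")


def read_curves(path: str | Path, expected_cycles: int = 40) -> list[FluorescenceTrace]:
    """Read a long-format trace CSV into one trace per (reaction_id, dye) pair.

    Every reaction must supply exactly cycles ``1..expected_cycles``; missing
    cycles, duplicated rows, and non-positive ROX values raise
    :class:`CurveIOError` naming the offending reaction.
    """
    path = Path(path)
    if not path.exists():
        raise CurveIOError(f"trace file not found: {path}")
    df = pd.read_csv(path, dtype={"reaction_id": str, "dye": str},
                     float_precision="round_trip")
    _require_columns(df, ["reaction_id", "dye", "cycle", "reporter", "rox"], path)

    traces: list[FluorescenceTrace] = []
    # sort=False keeps file order of first appearance
    for (rid, dye), grp in df.groupby(["reaction_id", "dye"], sort=False):
        cycles = grp["cycle"].to_numpy()
        if len(np.unique(cycles)) != len(cycles):
            dupes = sorted({int(c) for c in cycles[pd.Series(cycles).duplicated()]})
            raise CurveIOError(
                f"reaction {rid!r} ({dye}): duplicate rows for cycles {dupes}"
            )
        expected = set(range(1, expected_cycles + 1))
        got = {int(c) for c in cycles}
        if got != expected:
            missing = sorted(expected - got)
            extra = sorted(got - expected)
            parts = []
            if missing:
                parts.append(f"missing cycles {missing}")
            if extra:
                parts.append(f"unexpected cycles {extra}")
            raise CurveIOError(f"reaction {rid!r} ({dye}): " + "; ".join(parts))
        grp = grp.sort_values("cycle")
        well = grp["well"].iloc[0] if "well" in grp.columns else None
        target = grp["target"].iloc[0] if "target" in grp.columns else None
        traces.append(
            FluorescenceTrace(
                reaction_id=str(rid),
                dye=str(dye),
                reporter=grp["reporter"].to_numpy(dtype=float),
                rox=grp["rox"].to_numpy(dtype=float),
                well=None if pd.isna(well) else str(well),
                target=None if pd.isna(target) else str(target),
            )
        )
    return traces


def write_curves(traces: Iterable[FluorescenceTrace], path: str | Path) -> None:
    """Write traces to the canonical long CSV (one row per cycle per dye)."""
    rows = []
    for t in traces:
        for c in range(t.cycles):
            rows.append(
                {
                    "reaction_id": t.reaction_id,
                    "well": t.well if t.well is not None else "",
                    "target": t.target if t.target is not None else "",
                    "dye": t.dye,
                    "cycle": c + 1,
                    "reporter": repr(float(t.reporter[c])),
                    "rox": repr(float(t.rox[c])),
                }
            )
    pd.DataFrame(rows, columns=TRACE_COLUMNS).to_csv(path, index=False)


_TRUE = {"true", "1", "yes", "y", "t"}
_FALSE = {"false", "0", "no", "n", "f"}


def _parse_bool(raw: object, context: str) -> bool:
    s = str(raw).strip().lower()
    if s in _TRUE:
        return True
    if s in _FALSE:
        return False
    raise CurveIOError(f"{context}: cannot parse boolean from {raw!r}")


def read_labels(path: str | Path, max_ct: float = 40.0) -> list[ReactionLabel]:
    """Read gold-standard labels; ct is parsed only on amplified rows.

    A ct on a non-amplified row, or a ct above ``max_ct``, is an error.
    """
    path = Path(path)
    if not path.exists():
        raise CurveIOError(f"label file not found: {path}")
    df = pd.read_csv(path, dtype={"reaction_id": str}, float_precision="round_trip")
    _require_columns(df, ["reaction_id", "amplified", "ct"], path)
    labels: list[ReactionLabel] = []
    for row in df.itertuples(index=False):
        rid = str(row.reaction_id)
        amplified = _parse_bool(row.amplified, f"reaction {rid!r}")
        ct_raw = row.ct
        has_ct = not (ct_raw is None or (isinstance(ct_raw, float) and math.isnan(ct_raw)))
        if amplified:
            if not has_ct:
                raise CurveIOError(f"reaction {rid!r}: amplified row without a ct")
            ct = float(ct_raw)
            if ct > max_ct:
                raise CurveIOError(
                    f"reaction {rid!r}: ct {ct} exceeds the {max_ct}-cycle run"
                )
            labels.append(ReactionLabel(rid, True, ct))
        else:
            if has_ct:
                raise CurveIOError(
                    f"reaction {rid!r}: non-amplified row carries ct {ct_raw!r}"
                )
            labels.append(ReactionLabel(rid, False, None))
    return labels


def write_labels(labels: Iterable[ReactionLabel], path: str | Path) -> None:
    rows = [
        {
            "reaction_id": lab.reaction_id,
            "amplified": str(lab.amplified).lower(),
            "ct": repr(float(lab.ct)) if lab.ct is not None else "",
        }
        for lab in labels
    ]
    pd.DataFrame(rows, columns=LABEL_COLUMNS).to_csv(path, index=False)


def read_calls(path: str | Path) -> list[CallRecord]:
    """Read model calls written by :func:`write_calls`."""
    path = Path(path)
    if not path.exists():
        raise CurveIOError(f"call file not found: {path}")
    df = pd.read_csv(path, dtype={"reaction_id": str}, float_precision="round_trip")
    _require_columns(df, CALL_COLUMNS, path)
    calls: list[CallRecord] = []
    for row in df.itertuples(index=False):
        rid = str(row.reaction_id)
        ct_raw = row.ct
        has_ct = not (ct_raw is None or (isinstance(ct_raw, float) and math.isnan(ct_raw)))
        calls.append(
            CallRecord(
                reaction_id=rid,
                probability=float(row.probability),
                amplified=_parse_bool(row.amplified, f"reaction {rid!r}"),
                ct=float(ct_raw) if has_ct else None,
                flagged=_parse_bool(row.flagged, f"reaction {rid!r}"),
            )
        )
    return calls


def write_calls(calls: Iterable[CallRecord], path: str | Path) -> None:
    """Write calls to CSV; probabilities keep full float precision (repr)."""
    rows = [
        {
            "reaction_id": c.reaction_id,
            "probability": repr(float(c.probability)),
            "amplified": str(c.amplified).lower(),
            "ct": repr(float(c.ct)) if c.ct is not None else "",
            "flagged": str(c.flagged).lower(),
        }
        for c in calls
    ]
    pd.DataFrame(rows, columns=CALL_COLUMNS).to_csv(path, index=False)


def roundtrip_calls(calls: Sequence[CallRecord], path: str | Path) -> list[CallRecord]:
    """Write ``calls`` to ``path`` and read them back (lossless persistence)."""
    write_calls(calls, path)
    return read_calls(path)
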