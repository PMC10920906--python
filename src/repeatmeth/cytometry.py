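"""Flow-cytometry readout: control-based gating and relative median MFI.

Event tables are tidy CSV frames with columns ``sample_id, intensity`` (a
``condition`` column is carried through when present).  The reporter-positive
gate is a high percentile of a parental (non-fluorescent) control sample, so
the control's gated fraction is ~(100 − percentile)% by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["FlowSample", "derive_gate", "relative_median_mfi", "mfi_ratio"]


@dataclass
class FlowSample:
    sample_id: str
    events: np.ndarray
    condition: str | None = None
    is_control: bool = False

    def __post_init__(self) -> None:
        self.events = np.asarray(self.events, dtype=float)
        if self.events.ndim != 1:
            raise ValueError("events must be a 1-D intensity array")
        if self.events.size and not (np.isfinite(self.events).all() and (self.events > 0).all()):
            raise ValueError("intensities must be finite and > 0")


def derive_gate(control, percentile: float = 99.5) -> float:
    """Positive-population threshold: a percentile of the parental control."""
    events = control.events if isinstance(control, FlowSample) else np.asarray(control, dtype=float)
    if events.size < 100:
        raise ValueError(f"control has {events.size} events; need at least 100 for a stable gate")
    if not 0 < percentile <= 100:
        raise ValueError("percentile must be in (0, 100]")
    return float(np.percentile(events, percentile))


def relative_median_mfi(
    samples: pd.DataFrame, threshold: float, gated: bool = True
) -> pd.DataFrame:
    """Median fluorescence intensity per sample, over gated events by default.

    Samples with zero gated events are flagged (NaN median) so downstream
    aggregation can exclude them.  Returns columns ``sample_id, n_events,
    n_gated, median_mfi, flagged``.
    """
    if not {"sample_id", "intensity"} <= set(samples.columns):
        raise ValueError("event table needs columns sample_id, intensity")
    rows = []
    for sid, grp in samples.groupby("sample_id", sort=True):
        events = grp["intensity"].to_numpy(dtype=float)
        selected = events[events > threshold] if gated else events
        rows.append(
            {
                "sample_id": sid,
                "n_events": len(events),
                "n_gated": int((events > threshold).sum()),
                "median_mfi": float(np.median(selected)) if selected.size else np.nan,
                "flagged": selected.size == 0,
            }
        )
    return pd.DataFrame(rows)


def mfi_ratio(mfi_table: pd.DataFrame, sample_a: str, sample_b: str) -> float:
    """Ratio of median MFIs of two samples (a / b)."""
    idx = mfi_table.set_index("sample_id")["median_mfi"]
    for sid in (sample_a, sample_b):
        if sid not in idx.index:
            raise KeyError(f"sample {sid!r} not in MFI table")
    return float(idx[sample_a] / idx[sample_b])
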